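"""Cued-threat pain task: schedules, threat-bias score, bias-group assignment.

The task presents a visual threat cue (a 10-point percentage range, or
"unknown") before each contact-heat stimulus and collects a 0-100 numerical
pain rating.  Four run types exist:

* ``matched`` — cue deciles map linearly onto temperature (0.4 deg C per
  decile from a 43.8 deg C floor, clamped at 47.0).
* ``mismatch_level1`` — cues 1-40 get 45.0 deg C, cues 60-100 get 47.0.
* ``mismatch_level2_high`` — every trial at the 47.0 deg C maximum.
* ``mismatch_level2_low`` — every trial at 45.0 deg C.

The top-down threat bias is the mean rating for low cues (8-32) minus the
mean rating for high cues (70-98) on the constant-temperature
``mismatch_level2_high`` runs; more negative means stronger reliance on the
cue rather than the stimulus.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "RUN_TYPES",
    "Trial",
    "Schedule",
    "BiasScore",
    "GroupAssignment",
    "matched_temperature",
    "level1_temperature",
    "build_schedule",
    "compute_threat_bias",
    "compute_threat_bias_table",
    "assign_bias_groups",
]

RUN_TYPES = (
    "matched",
    "mismatch_level1",
    "mismatch_level2_high",
    "mismatch_level2_low",
)

#: cue bands (inclusive, on the stored cue value) entering the bias score
LOW_CUE_BAND = (8.0, 32.0)
HIGH_CUE_BAND = (70.0, 98.0)

TEMP_FLOOR_C = 43.8
TEMP_STEP_C = 0.4
TEMP_MAX_C = 47.0
LEVEL1_LOW_C = 45.0
LEVEL1_HIGH_C = 47.0


@dataclass(frozen=True)
class Trial:
    """One cue/stimulus pairing within a run."""

    cue_kind: str  # "range" or "unknown"
    cue_low: float | None
    cue_high: float | None
    temperature: float

    @property
    def cue_value(self) -> float:
        """Midpoint of the cued range; NaN for unknown cues."""
        if self.cue_kind != "range":
            return math.nan
        return 0.5 * (self.cue_low + self.cue_high)


@dataclass
class Schedule:
    run_type: str
    trials: list[Trial] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.run_type not in RUN_TYPES:
            raise ValueError(f"unknown run_type {self.run_type!r}")
        for t in self.trials:
            if t.cue_kind == "range" and abs(t.cue_high - t.cue_low - 10) > 1e-9:
                raise ValueError(
                    f"range cue must span exactly 10 points, got {t.cue_low}-{t.cue_high}"
                )
            if not (TEMP_FLOOR_C - 1e-9 <= t.temperature <= TEMP_MAX_C + 1e-9):
                raise ValueError(f"temperature {t.temperature} outside [43.8, 47.0]")
        if self.run_type == "mismatch_level2_high":
            if any(abs(t.temperature - TEMP_MAX_C) > 1e-9 for t in self.trials):
                raise ValueError("level-2 high run must hold 47.0 deg C on every trial")


def matched_temperature(cue_low: float) -> float:
    """Temperature for a matched-run cue bin with lower bound ``cue_low``.

    Each 10-point cue decile raises the temperature by 0.4 deg C from the
    43.8 deg C floor; the top deciles are clamped at the 47.0 deg C maximum.
    """
    decile = math.floor((cue_low - 1) / 10)
    return min(TEMP_FLOOR_C + TEMP_STEP_C * decile, TEMP_MAX_C)


def level1_temperature(cue_value: float) -> float:
    """Level-1 mismatched mapping: cues 1-40 -> 45.0 deg C, 60-100 -> 47.0."""
    if 1 <= cue_value <= 40:
        return LEVEL1_LOW_C
    if 60 <= cue_value <= 100:
        return LEVEL1_HIGH_C
    raise ValueError(f"cue value {cue_value} outside the level-1 bands (1-40, 60-100)")


# cue_low values used when building level-2 schedules; the resulting 10-point
# ranges have midpoints inside the scoring bands [8, 32] and [70, 98]
_LEVEL2_LOW_CUE_LOWS = (8.0, 12.0, 16.0, 20.0, 22.0, 27.0)
_LEVEL2_HIGH_CUE_LOWS = (70.0, 74.0, 79.0, 84.0, 88.0, 93.0)
_LEVEL1_LOW_CUE_LOWS = (1.0, 11.0, 21.0, 30.0)
_LEVEL1_HIGH_CUE_LOWS = (60.0, 70.0, 80.0, 90.0)


def build_schedule(run_type: str, seed: int = 0, n_unknown: int = 2) -> Schedule:
    """Construct a trial schedule of the given run type.

    Trial order is shuffled reproducibly from ``seed``; the cue set and the
    cue-to-temperature map are fixed by the run type.
    """
    if run_type not in RUN_TYPES:
        raise ValueError(f"unknown run_type {run_type!r}")
    rng = np.random.default_rng(seed)
    trials: list[Trial] = []
    if run_type == "matched":
        for lo in np.arange(1.0, 92.0, 10.0):
            trials.append(Trial("range", lo, lo + 10, matched_temperature(lo)))
    elif run_type == "mismatch_level1":
        for lo in _LEVEL1_LOW_CUE_LOWS:
            trials.append(Trial("range", lo, lo + 10, LEVEL1_LOW_C))
        for lo in _LEVEL1_HIGH_CUE_LOWS:
            trials.append(Trial("range", lo, lo + 10, LEVEL1_HIGH_C))
        for _ in range(n_unknown):
            temp = float(rng.choice([LEVEL1_LOW_C, LEVEL1_HIGH_C]))
            trials.append(Trial("unknown", None, None, temp))
    else:
        temp = TEMP_MAX_C if run_type == "mismatch_level2_high" else LEVEL1_LOW_C
        for lo in _LEVEL2_LOW_CUE_LOWS + _LEVEL2_HIGH_CUE_LOWS:
            trials.append(Trial("range", lo, lo + 10, temp))
        for _ in range(n_unknown):
            trials.append(Trial("unknown", None, None, temp))
    order = rng.permutation(len(trials))
    return Schedule(run_type, [trials[i] for i in order])


@dataclass(frozen=True)
class BiasScore:
    subject_id: str
    bias: float
    n_low_trials: int
    n_high_trials: int


def compute_threat_bias(trials: pd.DataFrame) -> BiasScore:
    """Top-down threat bias from a single subject's trial table.

    Uses only ``mismatch_level2_high`` rows at 47.0 deg C with a range cue;
    bias = mean rating for cues in [8, 32] minus mean rating for cues in
    [70, 98].  Negative values indicate stronger top-down bias.

    Raises ``ValueError`` naming the missing band if either band is empty.
    """
    subjects = trials["subject_id"].unique()
    if len(subjects) != 1:
        raise ValueError("compute_threat_bias expects a single subject's trials")
    sel = trials[
        (trials["run_type"] == "mismatch_level2_high")
        & (np.isclose(trials["temperature_c"], TEMP_MAX_C))
        & (trials["cue_kind"] == "range")
    ]
    cue = sel["cue_value"].to_numpy(dtype=float)
    rating = sel["rating"].to_numpy(dtype=float)
    low = (cue >= LOW_CUE_BAND[0]) & (cue <= LOW_CUE_BAND[1])
    high = (cue >= HIGH_CUE_BAND[0]) & (cue <= HIGH_CUE_BAND[1])
    if not low.any():
        raise ValueError("no trials with cue values in the low band [8, 32]")
    if not high.any():
        raise ValueError("no trials with cue values in the high band [70, 98]")
    bias = float(rating[low].mean() - rating[high].mean())
    return BiasScore(str(subjects[0]), bias, int(low.sum()), int(high.sum()))


def compute_threat_bias_table(trials: pd.DataFrame) -> pd.DataFrame:
    """Per-subject bias scores for a cohort trial table."""
    rows = []
    for sid, sub in trials.groupby("subject_id", sort=True):
        b = compute_threat_bias(sub)
        rows.append(
            {
                "subject_id": b.subject_id,
                "bias": b.bias,
                "n_low_trials": b.n_low_trials,
                "n_high_trials": b.n_high_trials,
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class GroupAssignment:
    subject_id: str
    group: str  # high_bias | low_bias | excluded
    stability: float


def _kmeans_1d(x: np.ndarray, init: np.ndarray, max_iter: int = 100) -> np.ndarray:
    """Lloyd's algorithm for k=2 on 1-D data; returns labels (0/1)."""
    centers = init.astype(float).copy()
    labels = np.zeros(len(x), dtype=int)
    for _ in range(max_iter):
        d = np.abs(x[:, None] - centers[None, :])
        new_labels = d.argmin(axis=1)
        if np.array_equal(new_labels, labels) and _ > 0:
            break
        labels = new_labels
        for k in range(2):
            if (labels == k).any():
                centers[k] = x[labels == k].mean()
    return labels


def assign_bias_groups(
    scores: Sequence[BiasScore],
    n_restarts: int = 100,
    stability_cutoff: float = 0.9,
    seed: int = 0,
) -> list[GroupAssignment]:
    """Split subjects into high/low threat-bias groups with 1-D 2-means.

    K-means (k=2) is run ``n_restarts`` times from seeded random
    initializations.  Each subject's group is the modal label across
    restarts; subjects whose label agrees with the mode on fewer than
    ``stability_cutoff`` of the restarts are marked ``excluded``.  The
    cluster with the more negative centroid (stronger bias) is
    ``high_bias``.
    """
    finite = [s for s in scores if np.isfinite(s.bias)]
    if len(finite) < 4:
        raise ValueError("need at least 4 subjects with finite bias scores")
    x = np.array([s.bias for s in finite], dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("all bias scores identical; 2-means clustering is degenerate")
    rng = np.random.default_rng(seed)
    votes_high = np.zeros(len(x), dtype=int)
    for _ in range(n_restarts):
        uniq = np.unique(x)
        init = rng.choice(uniq, size=2, replace=False)
        labels = _kmeans_1d(x, init)
        centers = np.array([x[labels == k].mean() if (labels == k).any() else np.inf
                            for k in range(2)])
        high_label = int(np.argmin(centers))  # more negative centroid = high bias
        votes_high += (labels == high_label).astype(int)
    frac_high = votes_high / n_restarts
    out: list[GroupAssignment] = []
    for i, s in enumerate(finite):
        stability = float(max(frac_high[i], 1 - frac_high[i]))
        if stability < stability_cutoff:
            group = "excluded"
        else:
            group = "high_bias" if frac_high[i] >= 0.5 else "low_bias"
        out.append(GroupAssignment(s.subject_id, group, stability))
    return out
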