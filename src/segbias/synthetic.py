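"""Synthetic cohorts with planted brain-behavior structure.

Generates, for each subject, (a) ROI time series from a network-factor
model whose within/between-network coupling is controlled by a latent
segregation parameter, (b) pain-task trial tables whose ratings mix
cue-driven expectation with temperature-driven input according to a latent
bias weight, (c) motion-parameter tables with optional injected spikes, and
(d) psychological scores coupled to the segregation latent.

Latents are tied through a Gaussian copula.  ``brain_behavior_rho`` is the
planted correlation between the segregation latent and the *bias score*
(negative = more segregated subjects show stronger bias, the direction the
analysis tests); because the bias score decreases in the bias weight, the
copula plants ``-brain_behavior_rho`` between the segregation latent and
the bias weight.  Copula correlations are pre-warped (2 sin(pi r / 6)) so
the planted Pearson correlations hold exactly for the uniform marginals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .segregation import Parcellation
from .task import Schedule, build_schedule

__all__ = [
    "GeneratorConfig",
    "SubjectLatents",
    "default_parcellation",
    "generate_cohort",
    "generate_roi_timeseries",
    "generate_trials",
    "generate_motion",
    "generate_psych_scores",
    "task_schedules",
    "effective_latent",
    "SCANS",
]

SCANS = ("rest", "task1", "task2a", "task2b")

# named substreams so each artifact draws from an independent seeded stream
_STREAM_LATENTS = 1
_STREAM_TIMESERIES = 2
_STREAM_TRIALS = 3
_STREAM_MOTION = 4
_STREAM_PSYCH = 5


@dataclass
class GeneratorConfig:
    n_subjects: int = 40
    n_networks: int = 5
    rois_per_network: int = 6
    n_timepoints: int = 500
    within_coupling_range: tuple[float, float] = (0.4, 0.8)
    between_coupling_range: tuple[float, float] = (0.05, 0.3)
    brain_behavior_rho: float = -0.4
    psych_rho: float = 0.3
    noise_sd: float = 0.0
    rating_noise_sd: float = 5.0
    task_latent_shift: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.within_coupling_range = tuple(self.within_coupling_range)
        self.between_coupling_range = tuple(self.between_coupling_range)
        wlo, whi = self.within_coupling_range
        blo, bhi = self.between_coupling_range
        if not (0 < wlo <= whi <= 1):
            raise ValueError("within_coupling_range must satisfy 0 < lo <= hi <= 1")
        if not (0 <= blo <= bhi):
            raise ValueError("between_coupling_range must satisfy 0 <= lo <= hi")
        if bhi >= wlo:
            raise ValueError(
                "between coupling must stay below within coupling for every draw"
            )
        for name in ("brain_behavior_rho", "psych_rho"):
            if abs(getattr(self, name)) > 1:
                raise ValueError(f"|{name}| must be <= 1")
        if self.n_subjects < 1 or self.n_networks < 2 or self.rois_per_network < 2:
            raise ValueError("need >= 1 subject and >= 2 networks of >= 2 ROIs")
        if self.n_timepoints < 10:
            raise ValueError("n_timepoints must be >= 10")

    @property
    def n_rois(self) -> int:
        return self.n_networks * self.rois_per_network


@dataclass(frozen=True)
class SubjectLatents:
    subject_id: str
    index: int
    segregation_latent: float  # in [0, 1]; higher = more segregated networks
    bias_weight: float  # in [0, 1]; reliance on cue vs temperature
    psych_latent: float


def default_parcellation(config: GeneratorConfig) -> Parcellation:
    labels = [
        f"net{k + 1}" for k in range(config.n_networks) for _ in range(config.rois_per_network)
    ]
    return Parcellation("synthetic", labels)


def _copula_r(target: float) -> float:
    """Gaussian-copula correlation producing Pearson ``target`` on uniforms."""
    return 2.0 * np.sin(np.pi * target / 6.0)


def generate_cohort(config: GeneratorConfig) -> list[SubjectLatents]:
    """Draw subject latents from the seeded Gaussian copula."""
    rho_sb = _copula_r(-config.brain_behavior_rho)  # seg vs bias weight
    rho_sp = _copula_r(config.psych_rho)
    # bias-psych coupling set to the product => conditional independence given seg
    corr = np.array(
        [
            [1.0, rho_sb, rho_sp],
            [rho_sb, 1.0, rho_sb * rho_sp],
            [rho_sp, rho_sb * rho_sp, 1.0],
        ]
    )
    chol = np.linalg.cholesky(corr)
    rng = np.random.default_rng([config.seed, _STREAM_LATENTS])
    z = rng.standard_normal((config.n_subjects, 3)) @ chol.T
    u = sps.norm.cdf(z)
    width = len(str(config.n_subjects))
    return [
        SubjectLatents(
            subject_id=f"sub{i + 1:0{width}d}",
            index=i,
            segregation_latent=float(u[i, 0]),
            bias_weight=float(u[i, 1]),
            psych_latent=float(u[i, 2]),
        )
        for i in range(config.n_subjects)
    ]


def _coupling_targets(
    latent: float, config: GeneratorConfig
) -> tuple[float, float]:
    wlo, whi = config.within_coupling_range
    blo, bhi = config.between_coupling_range
    r_w = wlo + latent * (whi - wlo)
    r_b = bhi - latent * (bhi - blo)  # higher latent -> lower between coupling
    return r_w, r_b


def effective_latent(latents: SubjectLatents, scan: str, config: GeneratorConfig) -> float:
    """Scan-specific segregation latent; tasks shift it by bias weight."""
    rank = SCANS.index(scan)
    shifted = latents.segregation_latent - config.task_latent_shift * rank * latents.bias_weight
    return float(np.clip(shifted, 0.0, 1.0))


def generate_roi_timeseries(
    latents: SubjectLatents,
    parcellation: Parcellation,
    config: GeneratorConfig,
    scan: str = "rest",
) -> np.ndarray:
    """T x N BOLD-like series from the network + global factor model.

    Each ROI is sqrt(a) * network factor + sqrt(b) * global factor + noise
    with a = r_w - r_b, b = r_b chosen from the subject's segregation
    latent, so expected within/between-network correlations equal the
    subject's coupling targets (scaled by 1/(1 + noise_sd^2) when extra
    measurement noise is enabled).
    """
    if scan not in SCANS:
        raise ValueError(f"unknown scan {scan!r}; expected one of {SCANS}")
    n = parcellation.n_nodes
    if n != config.n_rois:
        raise ValueError("parcellation does not cover the configured ROIs")
    t = config.n_timepoints
    lat = effective_latent(latents, scan, config)
    r_w, r_b = _coupling_targets(lat, config)
    a, b = r_w - r_b, r_b
    resid = max(1.0 - r_w, 0.0)
    rng = np.random.default_rng(
        [config.seed, _STREAM_TIMESERIES, latents.index, SCANS.index(scan)]
    )
    nets = np.asarray(parcellation.labels)
    net_names = list(dict.fromkeys(nets))
    factors = rng.standard_normal((t, len(net_names)))
    net_idx = np.array([net_names.index(l) for l in nets])
    g = rng.standard_normal((t, 1))
    e = rng.standard_normal((t, n))
    x = (
        np.sqrt(a) * factors[:, net_idx]
        + np.sqrt(b) * g
        + np.sqrt(resid) * e
    )
    if config.noise_sd > 0:
        x = x + config.noise_sd * rng.standard_normal((t, n))
    return x


def _temperature_drive(temp_c: np.ndarray) -> np.ndarray:
    """Map temperature to a [0, 1] nociceptive drive (linear over 43.8-47)."""
    return np.clip((np.asarray(temp_c) - 43.8) / (47.0 - 43.8), 0.0, 1.0)


def generate_trials(
    latents: SubjectLatents,
    schedules: Sequence[Schedule],
    config: GeneratorConfig,
) -> pd.DataFrame:
    """Trial table for one subject across the given run schedules.

    Range-cue ratings are 100 * [w * cue/100 + (1 - w) * g(temp)] + noise
    clamped to [0, 100], with w the subject's bias weight; unknown-cue
    ratings use the temperature drive alone.  Raises if no level-2
    high-temperature run is present (the bias score would be undefined).
    """
    if isinstance(schedules, Schedule):
        schedules = [schedules]
    if not any(s.run_type == "mismatch_level2_high" for s in schedules):
        raise ValueError(
            "no mismatch_level2_high run in schedule set; threat bias undefined"
        )
    rng = np.random.default_rng([config.seed, _STREAM_TRIALS, latents.index])
    w = latents.bias_weight
    rows = []
    for sched in schedules:
        for trial in sched.trials:
            drive = float(_temperature_drive(np.array(trial.temperature)))
            if trial.cue_kind == "range":
                cue = trial.cue_value
                mean = 100.0 * (w * cue / 100.0 + (1.0 - w) * drive)
            else:
                cue = np.nan
                mean = 100.0 * drive
            rating = mean + rng.normal(0.0, config.rating_noise_sd)
            rows.append(
                {
                    "subject_id": latents.subject_id,
                    "run_type": sched.run_type,
                    "cue_kind": trial.cue_kind,
                    "cue_value": cue,
                    "temperature_c": trial.temperature,
                    "rating": float(np.clip(rating, 0.0, 100.0)),
                }
            )
    return pd.DataFrame(rows)


def generate_motion(
    latents: SubjectLatents,
    config: GeneratorConfig,
    scan: str = "rest",
    jitter_sd: float = 0.01,
    spike_mm: float = 0.0,
    spike_frame: int | None = None,
) -> np.ndarray:
    """T x 6 motion table (translations mm, rotations rad) with optional spike.

    ``spike_mm`` adds a sustained translation jump at ``spike_frame``
    (default mid-scan), producing a framewise displacement of that size.
    """
    t = config.n_timepoints
    rng = np.random.default_rng(
        [config.seed, _STREAM_MOTION, latents.index, SCANS.index(scan)]
    )
    motion = rng.normal(0.0, jitter_sd, size=(t, 6))
    motion[:, 3:] *= 0.02  # rotations jitter far smaller than translations
    if spike_mm:
        frame = t // 2 if spike_frame is None else spike_frame
        motion[frame:, 0] += spike_mm
    return motion


def generate_psych_scores(
    cohort: Sequence[SubjectLatents],
    config: GeneratorConfig,
    score_noise_sd: float = 0.12,
) -> pd.DataFrame:
    """Questionnaire-style scores coupled to each subject's psych latent.

    PCS subscales (rumination 0-16, magnification 0-12, helplessness 0-24)
    sum to the PCS total; state/trait anxiety span 20-80.
    """
    rng = np.random.default_rng([config.seed, _STREAM_PSYCH])
    rows = []
    for lat in cohort:
        u = lat.psych_latent

        def scaled(lo: float, hi: float) -> int:
            v = u + rng.normal(0.0, score_noise_sd)
            return int(np.clip(round(lo + v * (hi - lo)), lo, hi))

        rum = scaled(0, 16)
        mag = scaled(0, 12)
        helpless = scaled(0, 24)
        rows.append(
            {
                "subject_id": lat.subject_id,
                "rumination": rum,
                "magnification": mag,
                "helplessness": helpless,
                "pcs_total": rum + mag + helpless,
                "state_anxiety": scaled(20, 80),
                "trait_anxiety": scaled(20, 80),
                "age": int(rng.integers(19, 46)),
                "sex": str(rng.choice(["F", "M"])),
            }
        )
    return pd.DataFrame(rows)


def task_schedules(seed: int = 0) -> list[Schedule]:
    """The three analyzed task runs: level-1 mismatch and the two level-2 runs."""
    return [
        build_schedule("mismatch_level1", seed=seed),
        build_schedule("mismatch_level2_high", seed=seed + 1),
        build_schedule("mismatch_level2_high", seed=seed + 2),
    ]
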