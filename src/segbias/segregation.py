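"""System segregation over a network parcellation.

System segregation (SS) of a connectivity matrix under a node-to-network
labeling is (z_w - z_b) / z_w, where z_w is the mean Fisher-z weight over
all possible within-network node pairs and z_b the mean over all possible
between-network pairs; absent (thresholded-out) edges contribute 0 weight
but still count in the denominator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .connectivity import (
    ConnectivityMatrix,
    DEFAULT_THRESHOLD_GRID,
    correlation_matrix,
    fisher_z,
    proportional_threshold,
)

__all__ = [
    "Parcellation",
    "SegregationResult",
    "system_segregation",
    "segregation_profile",
    "connection_counts",
]


@dataclass
class Parcellation:
    """Assignment of node indices to named networks.

    ``labels[i]`` is the network label of node ``i``.  Valid parcellations
    have at least two networks and at least two ROIs per network.
    """

    name: str
    labels: list[str]

    def __post_init__(self) -> None:
        labels = [str(l) for l in self.labels]
        nets, counts = np.unique(labels, return_counts=True)
        if len(nets) < 2:
            raise ValueError("parcellation needs at least 2 networks")
        small = [n for n, c in zip(nets, counts) if c < 2]
        if small:
            raise ValueError(f"networks with fewer than 2 ROIs: {small}")
        self.labels = labels

    @property
    def n_nodes(self) -> int:
        return len(self.labels)

    @property
    def networks(self) -> list[str]:
        return sorted(set(self.labels))

    @property
    def n_networks(self) -> int:
        return len(set(self.labels))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"roi_id": np.arange(self.n_nodes), "network_label": self.labels}
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, name: str = "parcellation") -> "Parcellation":
        df = df.sort_values("roi_id")
        if not np.array_equal(df["roi_id"].to_numpy(), np.arange(len(df))):
            raise ValueError("roi_id must be 0..N-1 with every ROI labeled once")
        return cls(name, df["network_label"].astype(str).tolist())

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read(cls, path: str | Path, name: str | None = None) -> "Parcellation":
        df = pd.read_csv(path, sep="\t")
        return cls.from_frame(df, name or Path(path).stem)


@dataclass(frozen=True)
class SegregationResult:
    scope: str  # "whole_brain" or a network label
    z_within: float
    z_between: float
    ss: float


def _masked_mean(values: np.ndarray, mask: np.ndarray) -> float:
    n = int(mask.sum())
    return float(values[mask].sum() / n) if n else np.nan


def _result(scope: str, zw: float, zb: float) -> SegregationResult:
    if not np.isfinite(zw) or zw <= 0:
        warnings.warn(f"z_within is 0 for scope {scope!r}; segregation undefined")
        return SegregationResult(scope, zw, zb, np.nan)
    return SegregationResult(scope, zw, zb, (zw - zb) / zw)


def system_segregation(
    cm: ConnectivityMatrix, parc: Parcellation
) -> tuple[SegregationResult, dict[str, SegregationResult]]:
    """Whole-brain and per-network system segregation.

    Whole-brain pools every same-network pair against every cross-network
    pair; a network's own result restricts to pairs touching that network.
    """
    if cm.state != "fisher_z":
        raise ValueError("system_segregation expects a fisher_z matrix")
    if parc.n_nodes != cm.n_nodes:
        raise ValueError(
            f"parcellation covers {parc.n_nodes} nodes, matrix has {cm.n_nodes}"
        )
    lab = np.asarray(parc.labels)
    iu, ju = np.triu_indices(cm.n_nodes, k=1)
    w = cm.values[iu, ju]
    same = lab[iu] == lab[ju]
    whole = _result("whole_brain", _masked_mean(w, same), _masked_mean(w, ~same))
    per_net: dict[str, SegregationResult] = {}
    for net in parc.networks:
        in_i = lab[iu] == net
        in_j = lab[ju] == net
        within = in_i & in_j
        between = in_i ^ in_j
        per_net[net] = _result(net, _masked_mean(w, within), _masked_mean(w, between))
    return whole, per_net


def connection_counts(cm: ConnectivityMatrix, parc: Parcellation) -> pd.DataFrame:
    """Surviving-edge counts per network-pair block of a thresholded matrix.

    Rows cover every unordered network pair including same-network blocks;
    counts sum to the total number of surviving edges.
    """
    lab = np.asarray(parc.labels)
    iu, ju = np.triu_indices(cm.n_nodes, k=1)
    alive = cm.values[iu, ju] > 0
    rows = []
    nets = parc.networks
    for a_idx, a in enumerate(nets):
        for b in nets[a_idx:]:
            if a == b:
                mask = (lab[iu] == a) & (lab[ju] == a)
            else:
                mask = ((lab[iu] == a) & (lab[ju] == b)) | (
                    (lab[iu] == b) & (lab[ju] == a)
                )
            rows.append(
                {
                    "network_a": a,
                    "network_b": b,
                    "kind": "within" if a == b else "between",
                    "count": int((alive & mask).sum()),
                }
            )
    return pd.DataFrame(rows)


def segregation_profile(
    timeseries: Mapping[tuple[str, str], np.ndarray],
    parcellations: Sequence[Parcellation],
    grid: Sequence[float] = DEFAULT_THRESHOLD_GRID,
    binarize: bool = False,
    r_max: float | None = 0.999999,
) -> pd.DataFrame:
    """Run correlation -> Fisher z -> threshold -> segregation over a cohort.

    ``timeseries`` maps (subject, scan) to a T x N array.  Returns a
    long-format table with one row per subject, scan, parcellation,
    threshold and scope (whole_brain plus each network).
    """
    rows = []
    for (subject, scan), ts in sorted(timeseries.items()):
        cm_r = correlation_matrix(ts)
        cm_z = fisher_z(cm_r, r_max=r_max)
        for parc in parcellations:
            for p in grid:
                thr = proportional_threshold(cm_z, p, binarize=binarize)
                whole, per_net = system_segregation(thr, parc)
                for res in [whole, *per_net.values()]:
                    rows.append(
                        {
                            "subject": subject,
                            "scan": scan,
                            "parcellation": parc.name,
                            "threshold": p,
                            "scope": res.scope,
                            "z_within": res.z_within,
                            "z_between": res.z_between,
                            "ss": res.ss,
                        }
                    )
    return pd.DataFrame(rows)
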