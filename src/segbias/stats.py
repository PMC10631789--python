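"""Inferential layer: normality-gated correlations, group tests, mixed ANOVA.

Correlations between segregation and behavior default to Pearson but fall
back to Spearman when a Shapiro-Wilk test rejects normality for either
variable; nuisance covariates are handled by residualizing both variables
and correlating the residuals.  The repeated-measures model has two
within-subject factors (scan type, threshold) and one between-subject
factor (bias group), with Greenhouse-Geisser corrected p-values reported
alongside the uncorrected ones.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "StatsResult",
    "normality_gate",
    "brain_behavior_correlation",
    "group_difference",
    "rm_anova",
    "rest_to_task_change",
]


@dataclass(frozen=True)
class StatsResult:
    method: str
    estimate: float
    p_value: float
    df: float | tuple[float, float] | None
    n: int


def normality_gate(x, alpha: float = 0.05) -> StatsResult:
    """Shapiro-Wilk normality check; method is 'normal' or 'non_normal'."""
    x = np.asarray(x, dtype=float)
    if x.size < 3:
        raise ValueError("normality test needs n >= 3")
    if np.ptp(x) == 0:
        raise ValueError("constant sample: normality test undefined")
    w, p = sps.shapiro(x)
    return StatsResult(
        "normal" if p >= alpha else "non_normal", float(w), float(p), None, x.size
    )


def _residualize(y: np.ndarray, covs: np.ndarray) -> np.ndarray:
    design = np.column_stack([np.ones(len(y)), covs])
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    return y - design @ beta


def brain_behavior_correlation(
    x,
    y,
    covariates=None,
    method: str = "auto",
    alpha: float = 0.05,
) -> StatsResult:
    """Correlation between two samples, optionally partialling out covariates.

    With ``method='auto'`` the Pearson coefficient is used when both
    (residualized) variables pass the Shapiro-Wilk gate at ``alpha``, and
    Spearman otherwise.  Covariates are removed by least-squares
    residualization of both variables before correlating.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D samples of equal length")
    n_cov = 0
    if covariates is not None:
        covs = np.column_stack([np.asarray(c, dtype=float) for c in covariates])
        if covs.shape[0] != x.size:
            raise ValueError("covariates must match the sample length")
        n_cov = covs.shape[1]
    if x.size < 4 + n_cov:
        raise ValueError(f"need n >= {4 + n_cov} observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero-variance sample")
    if covariates is not None:
        sx, sy = x.std(), y.std()
        x = _residualize(x, covs)
        y = _residualize(y, covs)
        if x.std() < 1e-10 * sx or y.std() < 1e-10 * sy:
            # a variable fully explained by covariates has no partial association
            return StatsResult("partial_degenerate", 0.0, 1.0, None, x.size)
    if method == "auto":
        gx, gy = normality_gate(x, alpha), normality_gate(y, alpha)
        method = "pearson" if gx.method == "normal" and gy.method == "normal" else "spearman"
    if method == "pearson":
        r, p = sps.pearsonr(x, y)
    elif method == "spearman":
        r, p = sps.spearmanr(x, y)
    else:
        raise ValueError(f"unknown method {method!r}")
    label = ("partial_" if n_cov else "") + method
    df = x.size - 2 - n_cov
    return StatsResult(label, float(r), float(p), df, x.size)


def group_difference(high, low, welch: bool = False) -> StatsResult:
    """Two-sided independent-samples t-test (pooled variance unless ``welch``)."""
    high = np.asarray(high, dtype=float)
    low = np.asarray(low, dtype=float)
    if high.size < 2 or low.size < 2:
        raise ValueError("each group needs n >= 2")
    res = sps.ttest_ind(high, low, equal_var=not welch)
    return StatsResult(
        "welch_t" if welch else "student_t",
        float(res.statistic),
        float(res.pvalue),
        float(res.df),
        high.size + low.size,
    )


# ---------------------------------------------------------------------------
# mixed repeated-measures ANOVA: within factors A, B; between factor G
# ---------------------------------------------------------------------------


def _reduction(df: pd.DataFrame, cols: list[str], value: str) -> float:
    """Sum over cells of (cell total)^2 / cell size."""
    if not cols:
        tot = df[value].sum()
        return float(tot * tot / len(df))
    g = df.groupby(cols, observed=True)[value]
    return float((g.sum() ** 2 / g.size()).sum())


def _gg_epsilon(scores: np.ndarray, contrast: np.ndarray, groups: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon for a within-subject effect.

    ``scores`` is subjects x cells; ``contrast`` is cells x df_effect with
    orthonormal columns spanning the effect space; covariance is pooled
    within between-subject groups.
    """
    k = contrast.shape[1]
    centered = scores.copy()
    for g in np.unique(groups):
        m = groups == g
        centered[m] -= scores[m].mean(axis=0)
    n = scores.shape[0] - len(np.unique(groups))
    if n < 1:
        return 1.0
    s = centered.T @ centered / n
    m = contrast.T @ s @ contrast
    tr = np.trace(m)
    denom = k * float((m * m).sum())
    if denom <= 0:
        return 1.0
    return float(min(1.0, tr * tr / denom))


def _helmert(k: int) -> np.ndarray:
    """k x (k-1) orthonormal contrast matrix orthogonal to the constant."""
    h = np.zeros((k, k - 1))
    for j in range(1, k):
        h[:j, j - 1] = 1.0
        h[j, j - 1] = -j
        h[:, j - 1] /= np.linalg.norm(h[:, j - 1])
    return h


def rm_anova(
    data: pd.DataFrame,
    dv: str = "ss",
    subject: str = "subject",
    within: tuple[str, str] = ("scan", "threshold"),
    between: str = "group",
) -> pd.DataFrame:
    """Mixed ANOVA with two within-subject factors and one between factor.

    Requires a complete within-subject grid; subjects with missing or
    duplicated cells are dropped with a warning.  Returns one row per
    effect with sums of squares, df, F, uncorrected p, and for
    within-subject effects the Greenhouse-Geisser epsilon and corrected p.
    """
    wa, wb = within
    cols = [subject, between, wa, wb, dv]
    df = data[cols].dropna().copy()
    a_levels = sorted(df[wa].unique())
    b_levels = sorted(df[wb].unique())
    a, b = len(a_levels), len(b_levels)
    if a < 2 or b < 2:
        raise ValueError("each within factor needs at least 2 levels")
    # drop subjects without exactly one observation per cell
    counts = df.groupby(subject, observed=True).size()
    keep = counts[counts == a * b].index
    cellcounts = df.groupby([subject, wa, wb], observed=True).size()
    bad = set(df[subject]) - set(keep) | set(
        cellcounts[cellcounts != 1].index.get_level_values(0)
    )
    if bad:
        warnings.warn(f"dropping subjects with incomplete cells: {sorted(map(str, bad))}")
        df = df[~df[subject].isin(bad)]
    subjects = sorted(df[subject].unique())
    n = len(subjects)
    groups = df.groupby(subject, observed=True)[between].first()
    g = groups.nunique()
    if n - g < 1:
        raise ValueError("not enough subjects for the between-subject error stratum")

    r = lambda cols_: _reduction(df, cols_, dv)
    cf = r([])
    ss = {}
    ss["group"] = r([between]) - cf
    ss["subject(group)"] = r([subject]) - r([between])
    ss[wa] = r([wa]) - cf
    ss[f"{wa}*group"] = r([between, wa]) - r([between]) - r([wa]) + cf
    ss[f"{wa}*subject(group)"] = r([subject, wa]) - r([subject]) - r([between, wa]) + r([between])
    ss[wb] = r([wb]) - cf
    ss[f"{wb}*group"] = r([between, wb]) - r([between]) - r([wb]) + cf
    ss[f"{wb}*subject(group)"] = r([subject, wb]) - r([subject]) - r([between, wb]) + r([between])
    ss[f"{wa}*{wb}"] = r([wa, wb]) - r([wa]) - r([wb]) + cf
    ss[f"{wa}*{wb}*group"] = (
        r([between, wa, wb]) - r([between, wa]) - r([between, wb]) - r([wa, wb])
        + r([between]) + r([wa]) + r([wb]) - cf
    )
    ss[f"{wa}*{wb}*subject(group)"] = (
        r([subject, wa, wb]) - r([subject, wa]) - r([subject, wb]) - r([between, wa, wb])
        + r([subject]) + r([between, wa]) + r([between, wb]) - r([between])
    )

    dfree = {
        "group": g - 1,
        "subject(group)": n - g,
        wa: a - 1,
        f"{wa}*group": (a - 1) * (g - 1),
        f"{wa}*subject(group)": (a - 1) * (n - g),
        wb: b - 1,
        f"{wb}*group": (b - 1) * (g - 1),
        f"{wb}*subject(group)": (b - 1) * (n - g),
        f"{wa}*{wb}": (a - 1) * (b - 1),
        f"{wa}*{wb}*group": (a - 1) * (b - 1) * (g - 1),
        f"{wa}*{wb}*subject(group)": (a - 1) * (b - 1) * (n - g),
    }
    error_of = {
        "group": "subject(group)",
        wa: f"{wa}*subject(group)",
        f"{wa}*group": f"{wa}*subject(group)",
        wb: f"{wb}*subject(group)",
        f"{wb}*group": f"{wb}*subject(group)",
        f"{wa}*{wb}": f"{wa}*{wb}*subject(group)",
        f"{wa}*{wb}*group": f"{wa}*{wb}*subject(group)",
    }

    # subject x cell matrix (cells ordered a-major) for GG epsilon
    pivot = df.pivot_table(index=subject, columns=[wa, wb], values=dv)
    pivot = pivot.reindex(
        columns=pd.MultiIndex.from_product([a_levels, b_levels], names=[wa, wb]),
        index=subjects,
    )
    scores = pivot.to_numpy()
    grp_arr = groups.reindex(subjects).to_numpy()
    ha, hb = _helmert(a), _helmert(b)
    ones_a = np.full((a, 1), 1 / np.sqrt(a))
    ones_b = np.full((b, 1), 1 / np.sqrt(b))
    eps = {
        wa: _gg_epsilon(scores, np.kron(ha, ones_b), grp_arr),
        wb: _gg_epsilon(scores, np.kron(ones_a, hb), grp_arr),
        f"{wa}*{wb}": _gg_epsilon(scores, np.kron(ha, hb), grp_arr),
    }
    eps[f"{wa}*group"] = eps[wa]
    eps[f"{wb}*group"] = eps[wb]
    eps[f"{wa}*{wb}*group"] = eps[f"{wa}*{wb}"]

    rows = []
    for effect, err in error_of.items():
        ms_e = ss[err] / dfree[err] if dfree[err] > 0 else np.nan
        ms = ss[effect] / dfree[effect] if dfree[effect] > 0 else np.nan
        f_val = ms / ms_e if ms_e and np.isfinite(ms_e) and ms_e > 0 else np.nan
        p = (
            float(sps.f.sf(f_val, dfree[effect], dfree[err]))
            if np.isfinite(f_val)
            else np.nan
        )
        row = {
            "effect": effect,
            "ss": ss[effect],
            "df1": dfree[effect],
            "df2": dfree[err],
            "ms": ms,
            "F": f_val,
            "p": p,
            "gg_eps": np.nan,
            "p_gg": np.nan,
        }
        if effect in eps and np.isfinite(f_val):
            e = eps[effect]
            row["gg_eps"] = e
            row["p_gg"] = float(sps.f.sf(f_val, dfree[effect] * e, dfree[err] * e))
        rows.append(row)
    return pd.DataFrame(rows)


def rest_to_task_change(
    profile: pd.DataFrame,
    groups: pd.DataFrame,
    dv: str = "ss",
    scan_order: tuple[str, ...] = ("rest", "task1", "task2a", "task2b"),
    leave_out: str | None = None,
) -> dict:
    """Scan-wise segregation change per bias group with paired post hocs.

    ``profile`` is a long table (subject, scan, threshold, dv); ``groups``
    maps subject -> group.  Returns per-group scan x threshold means, paired
    t-tests between consecutive scans and the (task1, last-task) pair, and
    optionally a leave-one-scan-out RM-ANOVA rerun.
    """
    df = profile.merge(groups[["subject", "group"]], on="subject")
    df = df[df["group"].isin(["high_bias", "low_bias"])]
    scans = [s for s in scan_order if s in set(df["scan"])]
    if len(scans) < 2:
        raise ValueError("need rest plus at least one task scan")
    means = (
        df.groupby(["group", "scan", "threshold"], observed=True)[dv]
        .mean()
        .reset_index()
    )
    pairs = list(zip(scans[:-1], scans[1:]))
    if ("task1" in scans) and (scans[-1] != "task1") and ("task1", scans[-1]) not in pairs:
        pairs.append(("task1", scans[-1]))
    posthoc_rows = []
    for grp, gdf in df.groupby("group", observed=True):
        for s1, s2 in pairs:
            for thr, tdf in gdf.groupby("threshold", observed=True):
                w = tdf.pivot_table(index="subject", columns="scan", values=dv)
                if s1 not in w or s2 not in w:
                    continue
                w = w[[s1, s2]].dropna()
                if len(w) < 2:
                    raise ValueError(f"group {grp!r} has < 2 subjects for {s1} vs {s2}")
                t, p = sps.ttest_rel(w[s1], w[s2])
                posthoc_rows.append(
                    {
                        "group": grp,
                        "scan_a": s1,
                        "scan_b": s2,
                        "threshold": thr,
                        "t": float(t),
                        "p": float(p),
                        "n": len(w),
                    }
                )
    out = {"means": means, "posthoc": pd.DataFrame(posthoc_rows)}
    if leave_out is not None:
        sub = df[df["scan"] != leave_out]
        out["leave_one_out_anova"] = rm_anova(sub, dv=dv)
    return out
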