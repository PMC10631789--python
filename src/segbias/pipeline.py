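"""End-to-end orchestration: simulate -> QC -> connectivity -> segregation
-> communities -> bias -> stats, driven by one YAML config and one seed.

Every stage writes plain-text tables under the output directory and a
manifest (JSON) records the config, seeds and SHA-256 digests of every
emitted file, so a rerun with the same config is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .communities import louvain, subject_specific_segregation
from .connectivity import (
    DEFAULT_THRESHOLD_GRID,
    correlation_matrix,
    fisher_z,
    proportional_threshold,
    qc_metrics,
)
from .segregation import Parcellation, segregation_profile, system_segregation
from .stats import (
    brain_behavior_correlation,
    group_difference,
    rest_to_task_change,
    rm_anova,
)
from .synthetic import (
    SCANS,
    GeneratorConfig,
    default_parcellation,
    generate_cohort,
    generate_motion,
    generate_psych_scores,
    generate_roi_timeseries,
    generate_trials,
    task_schedules,
)
from .task import assign_bias_groups, compute_threat_bias_table, BiasScore

log = logging.getLogger("segbias")

_FLOAT_FMT = "%.10g"


@dataclass
class PipelineConfig:
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    threshold_grid: tuple[float, ...] = DEFAULT_THRESHOLD_GRID
    binarize: bool = False
    scans: tuple[str, ...] = SCANS
    community_method: str = "louvain"
    community_n_runs: int = 20
    n_restarts: int = 100
    stability_cutoff: float = 0.9
    use_motion_covariates: bool = False
    out_dir: str = "segbias_out"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        gen = GeneratorConfig(**raw.pop("generator", {}))
        cfg = cls(generator=gen, **{
            k: tuple(v) if isinstance(v, list) else v for k, v in raw.items()
        })
        return cfg

    def to_dict(self) -> dict:
        def plain(v):
            if isinstance(v, tuple):
                return [plain(x) for x in v]
            if isinstance(v, dict):
                return {k: plain(x) for k, x in v.items()}
            return v

        return plain(dataclasses.asdict(self))


def _write_table(df: pd.DataFrame, path: Path) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def _write_matrix(m: np.ndarray, path: Path) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savetxt(path, m, delimiter="\t", fmt=_FLOAT_FMT)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def simulate(config: PipelineConfig, out: Path) -> dict:
    """Emit time series, motion, trials, latents and psych scores."""
    gen = config.generator
    cohort = generate_cohort(gen)
    parc = default_parcellation(gen)
    parc.write(out / "parcellation.tsv")
    latents_df = pd.DataFrame(
        [
            {
                "subject_id": l.subject_id,
                "segregation_latent": l.segregation_latent,
                "bias_weight": l.bias_weight,
                "psych_latent": l.psych_latent,
            }
            for l in cohort
        ]
    )
    _write_table(latents_df, out / "latents.tsv")
    schedules = task_schedules(seed=gen.seed)
    trials = pd.concat(
        [generate_trials(l, schedules, gen) for l in cohort], ignore_index=True
    )
    _write_table(trials, out / "trials.tsv")
    _write_table(generate_psych_scores(cohort, gen), out / "psych.tsv")
    ts_dir = out / "timeseries"
    mo_dir = out / "motion"
    paths = []
    for l in cohort:
        for scan in config.scans:
            ts = generate_roi_timeseries(l, parc, gen, scan=scan)
            p = ts_dir / f"{l.subject_id}_{scan}.tsv"
            _write_matrix(ts, p)
            m = generate_motion(l, gen, scan=scan)
            mp = mo_dir / f"{l.subject_id}_{scan}.tsv"
            _write_matrix(m, mp)
            paths.append(str(p.relative_to(out)))
            paths.append(str(mp.relative_to(out)))
    manifest = {"files": sorted(paths), "n_subjects": gen.n_subjects}
    (out / "simulate_manifest.json").write_text(json.dumps(manifest, indent=2))
    return {"cohort": cohort, "parcellation": parc, "trials": trials}


def run_qc(config: PipelineConfig, out: Path) -> pd.DataFrame:
    rows = []
    for ts_path in sorted((out / "timeseries").glob("*_*.tsv")):
        subject, scan = ts_path.stem.rsplit("_", 1)
        ts = np.loadtxt(ts_path, delimiter="\t")
        motion = np.loadtxt(out / "motion" / ts_path.name, delimiter="\t")
        qc = qc_metrics(motion, ts)
        rows.append(
            {
                "subject": subject,
                "scan": scan,
                "max_fd": qc.max_fd,
                "dvars_outlier_fraction": qc.dvars_outlier_fraction,
                "excluded": qc.excluded,
            }
        )
    df = pd.DataFrame(rows)
    _write_table(df, out / "qc.tsv")
    return df


def run_segregation(config: PipelineConfig, out: Path, qc: pd.DataFrame) -> pd.DataFrame:
    excluded = set(qc.loc[qc["excluded"], "subject"])
    if excluded:
        log.warning("QC-excluded subjects: %s", sorted(excluded))
    parc = Parcellation.read(out / "parcellation.tsv", name="synthetic")
    series = {}
    for ts_path in sorted((out / "timeseries").glob("*_*.tsv")):
        subject, scan = ts_path.stem.rsplit("_", 1)
        if subject in excluded or scan not in config.scans:
            continue
        series[(subject, scan)] = np.loadtxt(ts_path, delimiter="\t")
    profile = segregation_profile(
        series, [parc], grid=config.threshold_grid, binarize=config.binarize
    )
    _write_table(profile, out / "segregation.tsv")
    return profile


def run_communities(config: PipelineConfig, out: Path, qc: pd.DataFrame) -> pd.DataFrame:
    """Louvain modules on each subject's rest scan plus module-based SS."""
    excluded = set(qc.loc[qc["excluded"], "subject"])
    rows = []
    part_rows = []
    for ts_path in sorted((out / "timeseries").glob("*_rest.tsv")):
        subject = ts_path.stem.rsplit("_", 1)[0]
        if subject in excluded:
            continue
        ts = np.loadtxt(ts_path, delimiter="\t")
        cm = proportional_threshold(
            fisher_z(correlation_matrix(ts), r_max=0.999999),
            config.threshold_grid[0],
            binarize=config.binarize,
        )
        part = louvain(cm, seed=config.generator.seed, n_runs=config.community_n_runs)
        res = subject_specific_segregation(cm, part)
        rows.append(
            {
                "subject": subject,
                "n_modules": part.n_communities,
                "q": part.q,
                "ss": res.ss,
                "z_within": res.z_within,
                "z_between": res.z_between,
            }
        )
        for node, comm in enumerate(part.assignment):
            part_rows.append({"subject": subject, "node_id": node, "community_id": int(comm)})
    df = pd.DataFrame(rows)
    _write_table(df, out / "subject_modules.tsv")
    _write_table(pd.DataFrame(part_rows), out / "partitions.tsv")
    return df


def run_bias(config: PipelineConfig, out: Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    trials = pd.read_csv(out / "trials.tsv", sep="\t")
    bias = compute_threat_bias_table(trials)
    _write_table(bias, out / "bias.tsv")
    scores = [
        BiasScore(r.subject_id, r.bias, r.n_low_trials, r.n_high_trials)
        for r in bias.itertuples()
    ]
    assigns = assign_bias_groups(
        scores,
        n_restarts=config.n_restarts,
        stability_cutoff=config.stability_cutoff,
        seed=config.generator.seed,
    )
    groups = pd.DataFrame(
        [{"subject": a.subject_id, "group": a.group, "stability": a.stability} for a in assigns]
    )
    _write_table(groups, out / "groups.tsv")
    return bias, groups


def run_stats(
    config: PipelineConfig,
    out: Path,
    profile: pd.DataFrame,
    bias: pd.DataFrame,
    groups: pd.DataFrame,
    qc: pd.DataFrame,
) -> dict:
    """Brain-behavior correlations, group tests and the rest-to-task ANOVA."""
    rest = profile[(profile["scan"] == "rest") & (profile["scope"] == "whole_brain")]
    merged_groups = bias.merge(groups, left_on="subject_id", right_on="subject")
    report: dict = {"correlations": [], "group_tests": []}
    covs = None
    if config.use_motion_covariates:
        qrest = qc[qc["scan"] == "rest"].set_index("subject")
    for (parc, thr), sub in rest.groupby(["parcellation", "threshold"]):
        m = sub.merge(bias, left_on="subject", right_on="subject_id")
        if config.use_motion_covariates:
            aligned = qrest.reindex(m["subject"])
            covs = [aligned["max_fd"].to_numpy(), aligned["dvars_outlier_fraction"].to_numpy()]
        res = brain_behavior_correlation(m["ss"], m["bias"], covariates=covs)
        report["correlations"].append(
            {
                "parcellation": parc,
                "threshold": float(thr),
                "method": res.method,
                "R": res.estimate,
                "p": res.p_value,
                "n": res.n,
            }
        )
        gm = sub.merge(merged_groups, on="subject")
        hi = gm.loc[gm["group"] == "high_bias", "ss"]
        lo = gm.loc[gm["group"] == "low_bias", "ss"]
        if len(hi) >= 2 and len(lo) >= 2:
            t = group_difference(hi, lo)
            report["group_tests"].append(
                {
                    "parcellation": parc,
                    "threshold": float(thr),
                    "t": t.estimate,
                    "p": t.p_value,
                    "df": t.df,
                }
            )
    wb = profile[profile["scope"] == "whole_brain"].merge(
        groups[groups["group"].isin(["high_bias", "low_bias"])], on="subject"
    )
    anova_tbl = rm_anova(wb, dv="ss", within=("scan", "threshold"), between="group")
    _write_table(anova_tbl, out / "rm_anova.tsv")
    change = rest_to_task_change(
        profile[profile["scope"] == "whole_brain"], groups, leave_out="task2b"
    )
    _write_table(change["means"], out / "scan_means.tsv")
    _write_table(change["posthoc"], out / "scan_posthoc.tsv")
    _write_table(change["leave_one_out_anova"], out / "rm_anova_no_task2b.tsv")
    report["rm_anova"] = anova_tbl.to_dict(orient="records")
    corr_df = pd.DataFrame(report["correlations"])
    _write_table(corr_df, out / "correlations.tsv")
    if report["group_tests"]:
        _write_table(pd.DataFrame(report["group_tests"]), out / "group_tests.tsv")
    (out / "stats.json").write_text(json.dumps(report, indent=2, default=float))
    return report


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and write a manifest; returns the stats report."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "simulate"
    try:
        simulate(config, out)
        stage = "qc"
        qc = run_qc(config, out)
        stage = "segregation"
        profile = run_segregation(config, out, qc)
        stage = "communities"
        run_communities(config, out, qc)
        stage = "bias"
        bias, groups = run_bias(config, out)
        stage = "stats"
        report = run_stats(config, out, profile, bias, groups, qc)
    except Exception as exc:  # noqa: BLE001 - annotate failing stage
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
    files = sorted(p for p in out.rglob("*") if p.is_file() and p.name != "manifest.json")
    manifest = {
        "version": __version__,
        "seed": config.generator.seed,
        "config": config.to_dict(),
        "digests": {str(p.relative_to(out)): _sha256(p) for p in files},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return report
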