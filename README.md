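# segbias

Analysis pipeline linking resting-state brain-network segregation to
top-down threat bias in pain perception, exercised end-to-end on synthetic
cohorts with planted effects.

The package covers:

* **synthetic** — cohort generator: ROI time series from a network/global
  factor model, cued pain-task trial tables, motion parameters, and
  psychological scores, with planted brain-behavior correlations via a
  Gaussian copula.
* **task** — cued-threat task schedules (matched and mismatched runs), the
  threat-bias score (mean low-cue minus mean high-cue rating on
  constant-temperature runs), and K-means bias-group assignment with a
  restart-stability exclusion rule.
* **connectivity** — Pearson correlation matrices, Fisher z transform,
  proportional thresholding (0.20-0.50 grid), and FD/DVARS motion QC with
  exclusion rules.
* **segregation** — system segregation (z̄w − z̄b)/z̄w per network and
  whole-brain, across thresholds, scans and parcellations.
* **communities** — modularity (configuration null), Louvain and
  Girvan-Newman community detection, and segregation over detected
  subject-specific modules.
* **stats** — normality-gated (Pearson/Spearman) brain-behavior
  correlations with optional nuisance covariates, independent t-tests,
  a two-within-factor mixed repeated-measures ANOVA with
  Greenhouse-Geisser correction, and rest-to-task post hocs.
* **pipeline / cli** — one-config orchestration with manifests and
  byte-identical reruns.

## CLI

Run the whole synthetic pipeline:

```sh
segbias run --seed 7 --out segbias_out
```

or individual stages from files:

```sh
segbias simulate --seed 7 --out segbias_out
segbias connectivity --timeseries segbias_out/timeseries/sub01_rest.tsv \
    --threshold-grid 0.2 0.35 0.5 --out-dir conn_out
segbias bias --trials segbias_out/trials.tsv --out bias.tsv --seed 7
segbias detect --matrix conn_out/thresholded_0.20.tsv --method louvain \
    --out partition.tsv
segbias stats --out segbias_out
```

A YAML config (`--config`) can override the generator, threshold grid,
clustering and stats options; see `segbias.pipeline.PipelineConfig`.

All tabular inputs and outputs are plain delimited text: time series are
headerless T×N TSV files named `<subject>_<scan>.tsv`, parcellations are
`roi_id, network_label` tables, trial tables carry
`subject_id, run_type, cue_kind, cue_value, temperature_c, rating`.

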