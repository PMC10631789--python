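import math

import numpy as np
import pandas as pd
import pytest

from segbias.stats import (
    brain_behavior_correlation,
    group_difference,
    normality_gate,
    rest_to_task_change,
    rm_anova,
)


class TestNormalityGate:
    def test_gaussian_passes(self):
        x = np.random.default_rng(0).standard_normal(200)
        assert normality_gate(x).method == "normal"

    def test_exponential_rejected(self):
        x = np.random.default_rng(0).exponential(size=200)
        assert normality_gate(x).method == "non_normal"

    def test_null_calibration(self):
        # about 5% of clean normal samples should fail the gate
        rejections = sum(
            normality_gate(np.random.default_rng(s).standard_normal(50)).method
            == "non_normal"
            for s in range(200)
        )
        assert 2 <= rejections <= 25

    def test_tiny_sample_rejected(self):
        with pytest.raises(ValueError):
            normality_gate([1.0, 2.0])

    def test_constant_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            normality_gate([3.0] * 10)


class TestCorrelation:
    def test_perfect_negative(self):
        x = np.random.default_rng(1).standard_normal(30)
        res = brain_behavior_correlation(x, -x, method="pearson")
        assert res.estimate == pytest.approx(-1.0)

    def test_covariate_identical_to_y(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal(25)
        y = rng.standard_normal(25)
        res = brain_behavior_correlation(x, y, covariates=[y])
        assert res.estimate == pytest.approx(0.0, abs=1e-10)

    def test_eight_point_hand_table(self):
        x = np.array([1.0, 2, 3, 4, 5, 6, 7, 8])
        y = np.array([2.0, 1, 4, 3, 7, 5, 8, 6])
        # textbook formula oracle
        n = 8
        num = (x * y).sum() - x.sum() * y.sum() / n
        den = math.sqrt(
            ((x**2).sum() - x.sum() ** 2 / n) * ((y**2).sum() - y.sum() ** 2 / n)
        )
        res = brain_behavior_correlation(x, y, method="pearson")
        assert res.estimate == pytest.approx(num / den)
        assert res.n == 8 and res.df == 6

    def test_partial_correlation_removes_confound(self):
        rng = np.random.default_rng(3)
        c = rng.standard_normal(200)
        x = c + 0.1 * rng.standard_normal(200)
        y = c + 0.1 * rng.standard_normal(200)
        raw = brain_behavior_correlation(x, y, method="pearson")
        partial = brain_behavior_correlation(x, y, covariates=[c], method="pearson")
        assert raw.estimate > 0.9
        assert abs(partial.estimate) < 0.2
        assert partial.method == "partial_pearson"

    def test_auto_gate_switches_to_spearman(self):
        rng = np.random.default_rng(4)
        x = rng.exponential(size=100) ** 3
        y = x + rng.exponential(size=100)
        res = brain_behavior_correlation(x, y)
        assert res.method == "spearman"

    def test_spearman_monotone_invariance(self):
        rng = np.random.default_rng(5)
        x = rng.standard_normal(50)
        y = x + rng.standard_normal(50)
        r1 = brain_behavior_correlation(x, y, method="spearman").estimate
        r2 = brain_behavior_correlation(np.exp(x), y**3 + 5 * y, method="spearman").estimate
        assert r1 == pytest.approx(r2)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            brain_behavior_correlation([1.0] * 10, list(range(10)))

    def test_sample_size_guard(self):
        with pytest.raises(ValueError, match="n >="):
            brain_behavior_correlation([1.0, 2, 3], [3.0, 2, 1])


class TestGroupDifference:
    def test_identical_groups(self):
        g = [1.0, 2.0, 3.0]
        res = group_difference(g, g)
        assert res.estimate == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_hand_computed_pooled_t(self):
        # {1,2,3} vs {4,5,6}: means 2, 5; each var 1 -> pooled sd 1
        # t = (2 - 5) / sqrt(1 * (1/3 + 1/3)) = -3.6742, df = 4
        res = group_difference([1.0, 2, 3], [4.0, 5, 6])
        assert res.estimate == pytest.approx(-3 / math.sqrt(2 / 3))
        assert res.df == 4

    def test_antisymmetry(self):
        a, b = [1.0, 2, 3, 4], [2.0, 4, 6, 9]
        r1 = group_difference(a, b)
        r2 = group_difference(b, a)
        assert r1.estimate == pytest.approx(-r2.estimate)
        assert r1.p_value == pytest.approx(r2.p_value)

    def test_welch_flag(self):
        a = [1.0, 2, 3, 4, 5]
        b = [10.0, 30, 50, 70, 90]
        student = group_difference(a, b)
        welch = group_difference(a, b, welch=True)
        assert welch.method == "welch_t"
        assert welch.df < student.df

    def test_group_size_guard(self):
        with pytest.raises(ValueError):
            group_difference([1.0], [2.0, 3.0])


def _make_design(effects, noise_seed=0, noise_sd=0.0, n_per_group=3):
    """Full 2-group x scans x thresholds table from an effects callable."""
    rng = np.random.default_rng(noise_seed)
    rows = []
    sid = 0
    for g in ("g1", "g2"):
        for _ in range(n_per_group):
            sid += 1
            for a in ("rest", "task"):
                for b in (0.2, 0.5):
                    rows.append(
                        {
                            "subject": f"s{sid}",
                            "group": g,
                            "scan": a,
                            "threshold": b,
                            "ss": effects(g, f"s{sid}", a, b)
                            + noise_sd * rng.standard_normal(),
                        }
                    )
    return pd.DataFrame(rows)


class TestRmAnova:
    def test_pure_group_offset(self):
        # constant within subject: within-subject SS vanish, group effect is real
        subject_offsets = {f"s{i}": 0.01 * i for i in range(1, 9)}

        def eff(g, s, a, b):
            return (1.0 if g == "g2" else 0.0) + subject_offsets[s]

        tbl = rm_anova(_make_design(eff, n_per_group=4))
        get = lambda name: tbl[tbl["effect"] == name].iloc[0]
        assert get("group")["F"] > 100
        assert get("group")["p"] < 0.001
        for eff_name in ("scan", "threshold", "scan*threshold"):
            assert get(eff_name)["ss"] == pytest.approx(0.0, abs=1e-20)

    def test_hand_worked_small_design(self):
        # independent oracle: explicit mean-based decomposition on the
        # subjects x scans x thresholds cube
        df = _make_design(
            lambda g, s, a, b: 0.0, noise_seed=42, noise_sd=1.0, n_per_group=2
        )
        tbl = rm_anova(df).set_index("effect")
        cube = (
            df.pivot_table(index=["group", "subject"], columns=["scan", "threshold"], values="ss")
            .to_numpy()
            .reshape(4, 2, 2)
        )  # subject x scan x threshold, subjects ordered g1 s1,s2 then g2 s3,s4
        gm = cube.mean()
        subj_mean = cube.mean(axis=(1, 2))
        group_mean = np.array([subj_mean[:2].mean(), subj_mean[2:].mean()])
        a_mean = cube.mean(axis=(0, 2))
        b_mean = cube.mean(axis=(0, 1))
        ss_group = 4 * 2 * ((group_mean - gm) ** 2).sum()
        ss_subj = 4 * ((subj_mean - np.repeat(group_mean, 2)) ** 2).sum()
        ss_a = 4 * 2 * ((a_mean - gm) ** 2).sum()
        ga_mean = np.stack([cube[:2].mean(axis=(0, 2)), cube[2:].mean(axis=(0, 2))])
        ss_ag = 2 * 2 * ((ga_mean - group_mean[:, None] - a_mean[None, :] + gm) ** 2).sum()
        sa_mean = cube.mean(axis=2)
        ss_as = 2 * (
            (
                sa_mean
                - subj_mean[:, None]
                - np.repeat(ga_mean, 2, axis=0)
                + np.repeat(group_mean, 2)[:, None]
            )
            ** 2
        ).sum()
        assert tbl.loc["group", "ss"] == pytest.approx(ss_group)
        assert tbl.loc["scan", "ss"] == pytest.approx(ss_a)
        assert tbl.loc["scan*group", "ss"] == pytest.approx(ss_ag)
        assert tbl.loc["scan", "F"] == pytest.approx(
            (ss_a / 1) / (ss_as / 2)
        )
        assert tbl.loc["group", "F"] == pytest.approx((ss_group / 1) / (ss_subj / 2))

    def test_subject_order_invariance(self):
        df = _make_design(lambda g, s, a, b: 0.0, noise_seed=7, noise_sd=1.0)
        tbl1 = rm_anova(df)
        tbl2 = rm_anova(df.sample(frac=1, random_state=1))
        assert np.allclose(tbl1["F"], tbl2["F"], equal_nan=True)

    def test_incomplete_subject_dropped(self):
        df = _make_design(lambda g, s, a, b: 0.0, noise_seed=3, noise_sd=1.0)
        broken = df[~((df["subject"] == "s1") & (df["scan"] == "task"))]
        with pytest.warns(UserWarning, match="incomplete"):
            tbl = rm_anova(broken)
        full = rm_anova(df[df["subject"] != "s1"])
        assert np.allclose(tbl["ss"], full["ss"])

    def test_gg_epsilon_range(self):
        df = _make_design(
            lambda g, s, a, b: b * (2.0 if a == "task" else 1.0),
            noise_seed=11,
            noise_sd=0.3,
            n_per_group=5,
        )
        tbl = rm_anova(df)
        within = tbl[tbl["effect"].isin(["scan", "threshold", "scan*threshold"])]
        assert ((within["gg_eps"] > 0) & (within["gg_eps"] <= 1)).all()


def _profile(effects, scans=("rest", "task1", "task2a", "task2b"), n_per_group=3, noise_sd=0.0, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    sid = 0
    for g in ("high_bias", "low_bias"):
        for _ in range(n_per_group):
            sid += 1
            for scan in scans:
                for thr in (0.2, 0.3):
                    rows.append(
                        {
                            "subject": f"s{sid}",
                            "group": g,
                            "scan": scan,
                            "threshold": thr,
                            "ss": effects(g, scan) + noise_sd * rng.standard_normal(),
                        }
                    )
    df = pd.DataFrame(rows)
    groups = df[["subject", "group"]].drop_duplicates()
    return df.drop(columns="group"), groups


class TestRestToTaskChange:
    def test_identical_scans_zero_deltas(self):
        profile, groups = _profile(lambda g, scan: 0.7)
        out = rest_to_task_change(profile, groups)
        means = out["means"].pivot_table(index=["group", "threshold"], columns="scan", values="ss")
        assert np.allclose(means.to_numpy() - 0.7, 0.0)

    def test_planted_group_by_scan_shift_detected(self):
        drop = {"rest": 0.0, "task1": 0.1, "task2a": 0.2, "task2b": 0.3}

        def eff(g, scan):
            return 0.8 - (drop[scan] if g == "high_bias" else 0.0)

        profile, groups = _profile(eff, n_per_group=6, noise_sd=0.01, seed=2)
        out = rest_to_task_change(profile, groups)
        ph = out["posthoc"]
        hi = ph[(ph["group"] == "high_bias") & (ph["scan_a"] == "task1") & (ph["scan_b"] == "task2b")]
        assert (hi["p"] < 0.01).all()
        means = out["means"].pivot_table(
            index=["group", "threshold"], columns="scan", values="ss"
        )
        hi_delta = (means.loc["high_bias"]["task1"] - means.loc["high_bias"]["task2b"]).mean()
        lo_delta = (means.loc["low_bias"]["task1"] - means.loc["low_bias"]["task2b"]).mean()
        assert hi_delta == pytest.approx(0.2, abs=0.02)
        assert abs(lo_delta) < 0.02

    def test_paired_t_matches_closed_form(self):
        profile, groups = _profile(lambda g, scan: 0.5, noise_sd=0.2, seed=5)
        out = rest_to_task_change(profile, groups)
        row = out["posthoc"].iloc[0]
        w = profile.merge(groups, on="subject")
        w = w[(w["group"] == row["group"]) & (w["threshold"] == row["threshold"])]
        piv = w.pivot_table(index="subject", columns="scan", values="ss")
        d = (piv[row["scan_a"]] - piv[row["scan_b"]]).to_numpy()
        t_hand = d.mean() / (d.std(ddof=1) / math.sqrt(len(d)))
        assert row["t"] == pytest.approx(t_hand)

    def test_leave_one_scan_out(self):
        profile, groups = _profile(lambda g, scan: 0.5, noise_sd=0.1, seed=6)
        out = rest_to_task_change(profile, groups, leave_out="task2b")
        anova = out["leave_one_out_anova"]
        assert "task2b" not in set(
            profile[profile["scan"] == "nonexistent"]["scan"]
        )  # trivial guard
        assert {"scan", "threshold", "group"} <= set(anova["effect"])

    def test_small_group_rejected(self):
        profile, groups = _profile(lambda g, scan: 0.5, n_per_group=1, noise_sd=0.1)
        with pytest.raises(ValueError, match="< 2 subjects"):
            rest_to_task_change(profile, groups)
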