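"""Outcome classification, ANOVA oracles, mixed models, imputation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from cordmt.phantom import simulate_metric_table
from cordmt.stats import (
    aggregate_subject_level,
    anova_oneway,
    anova_twoway,
    classify_outcome,
    fit_mixed_model,
    impute_missing,
    pearson_ndi,
    pool_rubin,
    run_staged_analysis,
)


class TestClassifyOutcome:
    @pytest.mark.parametrize(
        "ndi, expected",
        [
            (5.53, "recovered"),
            (19.2, "mild"),
            (29.7, "severe"),
            (9.999, "recovered"),
            (10.0, "mild"),
            (28.0, "mild"),
            (28.001, "severe"),
            (0.0, "recovered"),
            (100.0, "severe"),
        ],
    )
    def test_bands(self, ndi, expected):
        assert classify_outcome(ndi) == expected

    @pytest.mark.parametrize("bad", [-1.0, 101.0, np.nan])
    def test_out_of_range_raises(self, bad):
        with pytest.raises(ValueError):
            classify_outcome(bad)


class TestAggregation:
    def _tables(self):
        tract = pd.DataFrame(
            {
                "subject_id": ["s1"] * 4 + ["s2"] * 2,
                "level": ["C2/3", "C2/3", "C3/4", "C3/4", "C2/3", "C2/3"],
                "tract": ["CST_L", "CST_R"] * 3,
                "mtr_percent": [40.0, 42.0, 44.0, 42.0, 39.0, 39.0],
            }
        )
        mtrh = pd.DataFrame(
            {
                "subject_id": ["s1", "s1", "s2"],
                "level": ["C2/3", "C3/4", "C2/3"],
                "mtrh": [0.10, 0.14, 0.08],
            }
        )
        return tract, mtrh

    def test_mean_over_levels(self):
        tract, mtrh = self._tables()
        agg = aggregate_subject_level(tract, mtrh).set_index("subject_id")
        assert agg.loc["s1", "CST_L"] == pytest.approx((40 + 44) / 2)
        assert agg.loc["s1", "mtrh"] == pytest.approx(0.12)

    def test_single_level_subject_passes_through(self):
        tract, mtrh = self._tables()
        agg = aggregate_subject_level(tract, mtrh).set_index("subject_id")
        assert agg.loc["s2", "CST_L"] == pytest.approx(39.0)
        assert agg.loc["s2", "mtrh"] == pytest.approx(0.08)


def oneway_oracle(groups):
    """Textbook one-way ANOVA from sums of squares."""
    allv = np.concatenate(groups)
    grand = allv.mean()
    ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
    dfb, dfw = len(groups) - 1, len(allv) - len(groups)
    F = (ssb / dfb) / (ssw / dfw)
    return ssb, ssw, F, sps.f.sf(F, dfb, dfw)


class TestAnovaOneway:
    def test_identical_groups_give_null_result(self):
        df = pd.DataFrame(
            {"outcome": ["a", "a", "b", "b", "c", "c"], "v": [1.0, 2.0, 1.0, 2.0, 1.0, 2.0]}
        )
        res = anova_oneway(df, "v")
        assert res.anova.loc["outcome", "F"] == pytest.approx(0.0, abs=1e-12)
        assert res.anova.loc["outcome", "PR(>F)"] == pytest.approx(1.0, abs=1e-12)

    def test_matches_textbook_oracle(self):
        groups = [
            np.array([1.0, 2.0, 3.0]),
            np.array([2.0, 3.0, 4.0]),
            np.array([10.0, 11.0, 12.0]),
        ]
        df = pd.DataFrame(
            {
                "outcome": ["g1"] * 3 + ["g2"] * 3 + ["g3"] * 3,
                "v": np.concatenate(groups),
            }
        )
        res = anova_oneway(df, "v")
        ssb, ssw, F, p = oneway_oracle(groups)
        assert res.anova.loc["outcome", "sum_sq"] == pytest.approx(ssb, abs=1e-8)
        assert res.anova.loc["residual", "sum_sq"] == pytest.approx(ssw, abs=1e-8)
        assert res.anova.loc["outcome", "F"] == pytest.approx(F, abs=1e-8)
        assert res.anova.loc["outcome", "PR(>F)"] == pytest.approx(p, abs=1e-8)

    def test_p_value_agrees_with_permutation_null(self):
        rng = np.random.default_rng(0)
        v = rng.normal(10, 2, 24) + np.repeat([0.0, 1.2, 2.0], 8)
        labels = np.repeat(["a", "b", "c"], 8)
        df = pd.DataFrame({"outcome": labels, "v": v})
        res = anova_oneway(df, "v")
        f_obs = res.anova.loc["outcome", "F"]
        exceed = 0
        n_perm = 1000
        for _ in range(n_perm):
            perm = pd.DataFrame({"outcome": rng.permutation(labels), "v": v})
            groups = [perm.loc[perm["outcome"] == g, "v"].to_numpy() for g in "abc"]
            if oneway_oracle(groups)[2] >= f_obs:
                exceed += 1
        assert abs(exceed / n_perm - res.anova.loc["outcome", "PR(>F)"]) < 0.05

    def test_posthoc_bonferroni_on_significance(self):
        df = pd.DataFrame(
            {
                "outcome": ["a"] * 4 + ["b"] * 4 + ["c"] * 4,
                "v": [1, 2, 1, 2, 1.5, 2.5, 1.5, 2.5, 9, 10, 9, 10],
            }
        )
        res = anova_oneway(df, "v")
        assert res.posthoc is not None and len(res.posthoc) == 3
        assert (res.posthoc["p_adj"] >= res.posthoc["p_raw"] - 1e-15).all()
        assert (res.posthoc["p_adj"] <= 1.0).all()

    def test_location_invariance(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(
            {"outcome": np.repeat(["a", "b", "c"], 6), "v": rng.normal(0, 1, 18)}
        )
        r1 = anova_oneway(df, "v")
        df2 = df.assign(v=df["v"] + 1000.0)
        r2 = anova_oneway(df2, "v")
        assert r1.anova.loc["outcome", "F"] == pytest.approx(
            r2.anova.loc["outcome", "F"], rel=1e-9
        )

    def test_insufficient_groups_raise(self):
        df = pd.DataFrame({"outcome": ["a", "a", "b"], "v": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError):
            anova_oneway(df, "v")


def twoway_oracle_balanced(df, value, fa, fb):
    """Textbook balanced two-way ANOVA from cell means."""
    la, lb = sorted(df[fa].unique()), sorted(df[fb].unique())
    n = len(df) // (len(la) * len(lb))
    grand = df[value].mean()
    cell = df.groupby([fa, fb])[value].mean()
    ma = df.groupby(fa)[value].mean()
    mb = df.groupby(fb)[value].mean()
    ss_a = n * len(lb) * sum((ma[a] - grand) ** 2 for a in la)
    ss_b = n * len(la) * sum((mb[b] - grand) ** 2 for b in lb)
    ss_ab = n * sum(
        (cell[(a, b)] - ma[a] - mb[b] + grand) ** 2 for a in la for b in lb
    )
    ss_e = sum(
        ((df.loc[(df[fa] == a) & (df[fb] == b), value] - cell[(a, b)]) ** 2).sum()
        for a in la
        for b in lb
    )
    df_e = len(df) - len(la) * len(lb)
    return ss_a, ss_b, ss_ab, ss_e, df_e


class TestAnovaTwoway:
    def test_matches_balanced_oracle(self):
        rng = np.random.default_rng(2)
        rows = []
        for outcome in ("recovered", "mild", "severe"):
            for sex in ("female", "male"):
                for _ in range(5):
                    rows.append(
                        {"outcome": outcome, "sex": sex, "v": rng.normal(40, 2)}
                    )
        df = pd.DataFrame(rows)
        res = anova_twoway(df, "v")
        ss_a, ss_b, ss_ab, ss_e, df_e = twoway_oracle_balanced(
            df, "v", "outcome", "sex"
        )
        mse = ss_e / df_e
        assert res.anova.loc["outcome", "sum_sq"] == pytest.approx(ss_a, abs=1e-8)
        assert res.anova.loc["sex", "sum_sq"] == pytest.approx(ss_b, abs=1e-8)
        assert res.anova.loc["outcome*sex", "sum_sq"] == pytest.approx(ss_ab, abs=1e-8)
        f_ab = (ss_ab / 2) / mse
        assert res.anova.loc["outcome*sex", "F"] == pytest.approx(f_ab, abs=1e-8)
        assert res.anova.loc["outcome*sex", "PR(>F)"] == pytest.approx(
            sps.f.sf(f_ab, 2, df_e), abs=1e-8
        )

    def test_constant_sex_degenerates_to_oneway(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame(
            {
                "outcome": np.repeat(["a", "b", "c"], 6),
                "sex": "female",
                "v": rng.normal(0, 1, 18),
            }
        )
        r2 = anova_twoway(df, "v")
        r1 = anova_oneway(df, "v")
        assert r2.anova.loc["outcome", "F"] == pytest.approx(
            r1.anova.loc["outcome", "F"], rel=1e-9
        )

    def test_interaction_type_i_error_calibrated(self):
        """Null simulation at the study's unbalanced cell sizes."""
        rej = 0
        n_rep = 500
        for i in range(n_rep):
            d = simulate_metric_table(seed=300_000 + i)
            per = (
                d.groupby(["subject_id", "outcome", "sex"])["value"]
                .mean()
                .reset_index()
            )
            r = anova_twoway(per, "value")
            if r.anova.loc["outcome*sex", "PR(>F)"] < 0.05:
                rej += 1
        assert 0.03 <= rej / n_rep <= 0.07


class TestMixedModel:
    CELL_MEANS = {
        ("recovered", "female"): 0.094,
        ("recovered", "male"): 0.111,
        ("mild", "female"): 0.087,
        ("mild", "male"): 0.112,
        ("severe", "female"): 0.140,
        ("severe", "male"): 0.067,
    }

    def test_noiseless_lsmeans_recover_generating_cell_means(self):
        d = simulate_metric_table(
            cell_means=self.CELL_MEANS, subject_sd=0.0, noise_sd=0.0, seed=4
        )
        res = fit_mixed_model(d)
        ls = res.ls_means.set_index(["outcome", "sex"])["estimate"]
        for cell, mean in self.CELL_MEANS.items():
            assert ls[cell] == pytest.approx(mean, abs=1e-6)

    def test_elevated_severe_female_cell_detected(self):
        """Power check at the study cell sizes: +2.5 subject SD in one cell."""
        means = {cell: 0.09 for cell in self.CELL_MEANS}
        means[("severe", "female")] = 0.14
        wins = 0
        n_rep = 25
        for i in range(n_rep):
            d = simulate_metric_table(
                cell_means=means, subject_sd=0.02, noise_sd=0.02, seed=40_000 + i
            )
            res = fit_mixed_model(d)
            ls = res.ls_means.set_index(["outcome", "sex"])["estimate"]
            ct = res.contrasts.set_index(["comparison", "within"])
            ok = (
                ls.idxmax() == ("severe", "female")
                and ct.loc[("recovered vs severe", "female"), "p"] < 0.05
                and ct.loc[("mild vs severe", "female"), "p"] < 0.05
            )
            wins += ok
        assert wins / n_rep >= 0.8

    def test_contrast_table_shape(self):
        d = simulate_metric_table(seed=5)
        res = fit_mixed_model(d)
        assert len(res.contrasts) == 9
        assert len(res.ls_means) == 6
        low = res.ls_means["ci_lower"] <= res.ls_means["estimate"]
        high = res.ls_means["estimate"] <= res.ls_means["ci_upper"]
        assert low.all() and high.all()


class TestImputation:
    def _table(self, seed=0, frac_missing=0.0):
        d = simulate_metric_table(seed=seed)
        if frac_missing:
            rng = np.random.default_rng(seed + 1)
            mask = rng.random(len(d)) < frac_missing
            d.loc[mask, "value"] = np.nan
        return d

    def test_no_missing_returns_identical_sets(self):
        d = self._table()
        sets = impute_missing(d, n_sets=5, seed=0)
        assert len(sets) == 5
        for s in sets:
            pd.testing.assert_frame_equal(s, d)

    def test_seed_determinism(self):
        d = self._table(frac_missing=0.1)
        a = impute_missing(d, seed=7)
        b = impute_missing(d, seed=7)
        c = impute_missing(d, seed=8)
        pd.testing.assert_frame_equal(a[0], b[0])
        assert not a[0]["value"].equals(c[0]["value"])

    def test_mcar_pooled_cell_means_unbiased(self):
        """10% MCAR missingness: pooled cell means stay within 0.2 SD of truth."""
        cell = ("severe", "female")
        biases = []
        for i in range(100):
            d = self._table(seed=50_000 + i, frac_missing=0.1)
            sets = impute_missing(d, n_sets=5, seed=i)
            per_set = [
                s.groupby(["outcome", "sex"])["value"].mean()[cell] for s in sets
            ]
            biases.append(np.mean(per_set) - 0.09)
        sd = np.sqrt(0.02**2 + 0.02**2 / 4)  # subject SD + level-mean noise
        assert abs(np.mean(biases)) < 0.2 * sd

    def test_over_half_missing_cell_refused(self):
        d = self._table()
        mask = (d["outcome"] == "severe") & (d["sex"] == "male")
        d.loc[mask, "value"] = np.nan
        with pytest.raises(ValueError, match="missing"):
            impute_missing(d)

    def test_rubin_pooling_reduces_to_single_set(self):
        est = np.array([[1.0, 2.0]])
        var = np.array([[0.04, 0.09]])
        pooled = pool_rubin(est, var)
        assert pooled["estimate"].tolist() == [1.0, 2.0]
        assert pooled["se"].to_numpy() == pytest.approx([0.2, 0.3])


class TestPearson:
    def test_perfect_linear_relationships(self):
        df = pd.DataFrame(
            {
                "subject_id": [f"s{i}" for i in range(6)] * 2,
                "level": ["C2/3"] * 6 + ["C3/4"] * 6,
                "metric": "mtrh",
                "value": list(np.arange(6.0)) + list(-np.arange(6.0)),
            }
        )
        ndi = pd.Series(
            2 * np.arange(6.0) + 1, index=[f"s{i}" for i in range(6)]
        )
        out = pearson_ndi(df, ndi).set_index("level")
        assert out.loc["C2/3", "r"] == pytest.approx(1.0)
        assert out.loc["C3/4", "r"] == pytest.approx(-1.0)

    def test_hand_computed_five_points(self):
        x = np.array([1.0, 2.0, 4.0, 5.0, 8.0])
        y = np.array([2.0, 3.0, 3.0, 6.0, 9.0])
        r_oracle = float(
            ((x - x.mean()) * (y - y.mean())).sum()
            / np.sqrt(((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum())
        )
        df = pd.DataFrame(
            {
                "subject_id": [f"s{i}" for i in range(5)],
                "level": "C2/3",
                "metric": "CST_L",
                "value": x,
            }
        )
        ndi = pd.Series(y, index=[f"s{i}" for i in range(5)])
        out = pearson_ndi(df, ndi)
        assert out.iloc[0]["r"] == pytest.approx(r_oracle, abs=1e-10)

    def test_constant_metric_flagged(self):
        df = pd.DataFrame(
            {
                "subject_id": [f"s{i}" for i in range(5)],
                "level": "C2/3",
                "metric": "mtrh",
                "value": 0.1,
            }
        )
        ndi = pd.Series(np.arange(5.0), index=[f"s{i}" for i in range(5)])
        out = pearson_ndi(df, ndi)
        assert out.iloc[0]["flag"] == "constant_metric"
        assert np.isnan(out.iloc[0]["r"])


class TestStagedAnalysis:
    def _inputs(self, lesion_shift=0.0, seed=0):
        d = simulate_metric_table(
            cell_means={
                cell: 0.09 + (lesion_shift if cell == ("severe", "female") else 0.0)
                for cell in TestMixedModel.CELL_MEANS
            },
            seed=seed,
        )
        subjects = (
            d.groupby(["subject_id", "outcome", "sex", "age", "bmi"])
            .size()
            .reset_index()[["subject_id", "outcome", "sex", "age", "bmi"]]
        )
        rng = np.random.default_rng(seed)
        subjects["ndi_year1_pct"] = rng.uniform(1, 40, len(subjects))
        mtrh = d.rename(columns={"value": "mtrh"})[["subject_id", "level", "mtrh"]]
        # constant tract table so tract metrics stay in the null
        rows = []
        for _, r in d.iterrows():
            for t in ("CST_L", "CST_R", "SPTH_L", "SPTH_R"):
                rows.append(
                    {
                        "subject_id": r["subject_id"],
                        "level": r["level"],
                        "tract": t,
                        "mtr_percent": 40.0 + rng.normal(0, 0.5),
                    }
                )
        return subjects, pd.DataFrame(rows), mtrh

    def test_gating_blocks_stage2_for_null_metrics(self):
        subjects, tract, mtrh = self._inputs(lesion_shift=0.0, seed=123)
        out = run_staged_analysis(subjects, tract, mtrh, gate=True)
        assert set(out.stage2) <= set(out.stage1)
        out_all = run_staged_analysis(subjects, tract, mtrh, gate=False)
        assert set(out_all.stage2) == set(out_all.stage1)

    def test_lesioned_cohort_flags_interaction(self):
        subjects, tract, mtrh = self._inputs(lesion_shift=0.06, seed=7)
        out = run_staged_analysis(subjects, tract, mtrh)
        res = out.stage3["mtrh"]
        assert float(res.anova.iloc[0]["p"]) < 0.05
        ls = res.ls_means.set_index(["outcome", "sex"])["estimate"]
        assert ls.idxmax() == ("severe", "female")
        assert "report" not in out.report.lower() or len(out.report) > 100
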