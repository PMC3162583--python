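"""Background adjustment, quantile normalization, family LMM and the selection rule."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from ginipipe import simulate
from ginipipe.nmd import (
    background_adjust,
    build_logratio_matrix,
    filter_region,
    fit_all_genes,
    fit_family_lmm,
    log_ratio,
    quantile_normalize,
    run_nmd_de,
    select_de_genes,
)


class TestBackgroundAdjust:
    def test_plain_subtraction(self):
        assert background_adjust(100.0, 20.0) == 80.0

    def test_floor_applies_when_background_dominates(self):
        assert background_adjust(10.0, 50.0) == 1.0
        assert background_adjust(10.0, 50.0, floor=0.5) == 0.5

    def test_rejects_negative_intensities(self):
        with pytest.raises(ValueError):
            background_adjust(-1.0, 0.0)

    def test_generator_round_trip_recovers_planted_ratio(self):
        # with vanishing noise the planted ln-ratio survives adjustment exactly
        design = simulate.StudyDesign(n_families=2, seed=1)
        cfg = simulate.NmdSimConfig(
            n_probes=50, n_true_genes=5, n_stress_genes=0,
            effect_log_ratio=0.7, noise_sd=1e-12, in_region_fraction=1.0,
        )
        samples, truth = simulate.simulate_nmd_arrays(design, cfg)
        affected = next(s for s in samples if s.affected)
        rec = affected.records
        r = background_adjust(rec["rMeanSignal"], rec["rBGMedianSignal"])
        g = background_adjust(rec["gMeanSignal"], rec["gBGMedianSignal"])
        ratios = pd.Series(log_ratio(r, g), index=truth["class"].to_numpy())
        assert ratios["true"].to_numpy() == pytest.approx(0.7, abs=1e-6)
        assert ratios["null"].to_numpy() == pytest.approx(0.0, abs=1e-6)


class TestLogRatio:
    @pytest.mark.parametrize(
        "r,g,expected", [(5.0, 5.0, 0.0), (np.e * 4, 4.0, 1.0), (80.0, 40.0, np.log(2))]
    )
    def test_values(self, r, g, expected):
        assert log_ratio(r, g) == pytest.approx(expected)


class TestQuantileNormalize:
    def test_two_column_toy(self):
        out = quantile_normalize(np.array([[1.0, 4.0], [2.0, 5.0], [3.0, 6.0]]))
        assert out[:, 0] == pytest.approx([2.5, 3.5, 4.5])
        assert out[:, 1] == pytest.approx([2.5, 3.5, 4.5])

    def test_identical_columns_are_fixed_point(self, rng):
        col = rng.normal(size=40)
        x = np.column_stack([col, col, col])
        assert quantile_normalize(x) == pytest.approx(x)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_sorted_columns_identical_and_ranks_preserved(self, seed):
        # continuous draws: tie-free almost surely (ties have their own test)
        x = np.random.default_rng(seed).normal(size=(10, 4))
        out = quantile_normalize(x)
        sorted_cols = np.sort(out, axis=0)
        for j in range(1, out.shape[1]):
            assert sorted_cols[:, j] == pytest.approx(sorted_cols[:, 0], abs=1e-9)
        # rank order within each column is preserved
        for j in range(out.shape[1]):
            a = np.argsort(np.argsort(x[:, j], kind="stable"), kind="stable")
            b = np.argsort(np.argsort(out[:, j], kind="stable"), kind="stable")
            assert (a == b).all()

    def test_ties_get_mean_reference_value(self):
        x = np.array([[1.0, 10.0], [1.0, 20.0], [5.0, 30.0]])
        out = quantile_normalize(x)
        ref = np.mean(np.sort(x, axis=0), axis=1)
        assert out[0, 0] == out[1, 0] == pytest.approx(ref[:2].mean())

    def test_rejects_missing_values(self):
        with pytest.raises(ValueError):
            quantile_normalize(np.array([[1.0, np.nan], [2.0, 3.0]]))


class TestFilterRegion:
    def _matrix(self, bands):
        n = len(bands)
        values = pd.DataFrame(
            np.zeros((n, 4)), index=[f"p{i}" for i in range(n)], columns=list("abcd")
        )
        meta = pd.DataFrame(
            {"family_id": ["f1", "f1", "f2", "f2"], "affected": [True, False, True, False]},
            index=list("abcd"),
        )
        gene_meta = pd.DataFrame(
            {"gene_id": [f"g{i}" for i in range(n)], "band": bands},
            index=values.index,
        )
        from ginipipe.nmd import LogRatioMatrix

        return LogRatioMatrix(values=values, sample_meta=meta, gene_meta=gene_meta)

    def test_prefix_matching_is_case_insensitive(self):
        m = self._matrix(["Xq27.1", "Xq28", "7q21", "xq27.3"])
        out = filter_region(m, ["Xq27", "Xq28"])
        assert list(out.gene_meta["band"]) == ["Xq27.1", "Xq28", "xq27.3"]

    def test_empty_whitelist_disables_filter(self):
        m = self._matrix(["Xq27.1", "7q21"])
        assert filter_region(m, []).values.shape == m.values.shape

    def test_empty_result_warns(self):
        m = self._matrix(["7q21", "1p36"])
        with pytest.warns(UserWarning):
            filter_region(m, ["Xq27"])


class TestFamilyLmm:
    def test_constant_response_is_null(self):
        meta = pd.DataFrame(
            {
                "family_id": ["f1", "f1", "f2", "f2", "f3", "f3"],
                "affected": [True, False] * 3,
            },
            index=[f"s{i}" for i in range(6)],
        )
        fit = fit_family_lmm(np.full(6, 2.0), meta)
        assert fit.beta_hat == pytest.approx(0.0, abs=1e-12)
        assert fit.p_value == 1.0

    def test_matches_paired_t_on_balanced_design(self):
        values, meta = simulate.simulate_logratio_genes(
            50, 6, beta=1.0, sd_family=0.5, sd_resid=0.2, seed=21
        )
        aff = meta["affected"].to_numpy()
        for _, y in values.iterrows():
            fit = fit_family_lmm(y.to_numpy(), meta)
            d = y.to_numpy()[aff] - y.to_numpy()[~aff]
            tt = stats.ttest_rel(y.to_numpy()[aff], y.to_numpy()[~aff])
            assert fit.beta_hat == pytest.approx(d.mean(), abs=1e-8)
            assert fit.p_value == pytest.approx(tt.pvalue, abs=1e-8)
            assert fit.df == 5

    def test_parameter_recovery_of_fixed_effect(self):
        values, meta = simulate.simulate_logratio_genes(
            200, 6, beta=1.0, sd_family=0.5, sd_resid=0.2, seed=33
        )
        betas = [fit_family_lmm(y.to_numpy(), meta).beta_hat for _, y in values.iterrows()]
        assert abs(np.mean(betas) - 1.0) <= 0.05

    def test_unbalanced_families_match_statsmodels_estimate(self):
        # independent mixed-model route as a cross-check on beta
        import statsmodels.formula.api as smf

        rng = np.random.default_rng(5)
        fam = np.repeat(["f1", "f2", "f3", "f4"], [3, 2, 4, 3])
        aff = np.array([1, 0, 0, 1, 0, 1, 1, 0, 0, 1, 0, 0], dtype=bool)
        y = 0.5 * aff + rng.normal(0, 0.3, size=12) + np.repeat(rng.normal(0, 0.4, 4), [3, 2, 4, 3])
        meta = pd.DataFrame({"family_id": fam, "affected": aff},
                            index=[f"s{i}" for i in range(12)])
        fit = fit_family_lmm(y, meta)
        df = pd.DataFrame({"y": y, "aff": aff.astype(float), "fam": fam})
        sm_fit = smf.mixedlm("y ~ aff", df, groups=df["fam"]).fit(reml=True)
        assert fit.beta_hat == pytest.approx(sm_fit.params["aff"], rel=1e-2)
        assert fit.se_beta == pytest.approx(sm_fit.bse["aff"], rel=1e-2)

    def test_singular_status_rejected(self):
        meta = pd.DataFrame(
            {"family_id": ["f1", "f1", "f2", "f2"], "affected": [True] * 4},
            index=list("abcd"),
        )
        with pytest.raises(ValueError):
            fit_family_lmm(np.arange(4.0), meta)


class TestSelection:
    def _fits(self, rows):
        return pd.DataFrame(
            rows,
            columns=["gene_id", "beta_hat", "p_value", "fold_change"],
            index=[f"p{i}" for i in range(len(rows))],
        )

    def test_direction_and_threshold_rules(self):
        fits = self._fits(
            [
                ("gA", -2.0, 0.001, 3.0),  # wrong direction
                ("gB", 1.0, 0.030, 2.0),  # p above cut-off
                ("gC", 1.0, 0.010, 2.0),  # selected
            ]
        )
        out = select_de_genes(fits, alpha=0.025)
        assert list(out["selected"]) == [False, False, True]
        assert out.loc[out["gene_id"] == "gC", "reason"].iloc[0] == "p_only"

    def test_fold_change_threshold_and_location_pick(self):
        fits = self._fits(
            [
                ("gA", 1.0, 0.01, 1.2),  # fails FC
                ("gB", 1.0, 0.01, 2.0),  # passes both
                ("gC", -0.5, 0.80, 1.0),  # picked on location alone
            ]
        )
        out = select_de_genes(fits, alpha=0.025, fc_threshold=1.5, location_include=["gC"])
        assert list(out["selected"]) == [False, True, True]
        assert list(out["reason"]) == ["not_selected", "p_and_fc", "location"]

    def test_stress_exclusion_beats_significance(self):
        fits = self._fits([("gS", 3.0, 1e-6, 5.0)])
        out = select_de_genes(fits, exclusion_list=["gS"])
        assert not out["selected"].iloc[0]
        assert out["reason"].iloc[0] == "excluded_stress"

    def test_selection_monotone_in_alpha(self, rng):
        fits = self._fits(
            [(f"g{i}", rng.normal(), rng.uniform(), 1.0) for i in range(50)]
        )
        loose = set(select_de_genes(fits, alpha=0.05).query("selected")["gene_id"])
        strict = set(select_de_genes(fits, alpha=0.01).query("selected")["gene_id"])
        assert strict <= loose


class TestEndToEnd:
    def test_recovers_planted_genes_and_excludes_stress(self):
        design = simulate.StudyDesign(n_families=6, seed=42)
        cfg = simulate.NmdSimConfig(
            n_probes=400, n_true_genes=5, n_stress_genes=10,
            effect_log_ratio=1.0, noise_sd=0.1, in_region_fraction=0.5,
        )
        samples, truth = simulate.simulate_nmd_arrays(design, cfg)
        stress = truth.loc[truth["class"] == "stress", "gene_id"]
        calls = run_nmd_de(samples, exclusion_list=stress)
        merged = calls.merge(truth[["gene_id", "class"]], on="gene_id")
        selected = merged[merged["selected"]]
        assert (selected["class"] == "true").sum() >= 4
        assert (selected["class"] == "stress").sum() == 0
        assert set(merged.loc[merged["class"] == "stress", "reason"]) == {"excluded_stress"}

    def test_sample_order_invariance(self):
        design = simulate.StudyDesign(n_families=3, seed=9)
        cfg = simulate.NmdSimConfig(
            n_probes=60, n_true_genes=2, n_stress_genes=2,
            effect_log_ratio=1.0, noise_sd=0.2, in_region_fraction=1.0,
        )
        samples, _ = simulate.simulate_nmd_arrays(design, cfg)
        fwd = run_nmd_de(samples)
        rev = run_nmd_de(samples[::-1])
        pd.testing.assert_frame_equal(
            fwd.sort_index(), rev.sort_index(), check_exact=False, rtol=1e-6, atol=1e-9
        )
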