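"""Kendall-tau decomposition, directional family statistics, permutation tests, Ward."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from ginipipe.famtau import (
    RankedProfileSet,
    exact_enumeration_pvalues,
    family_directional_distance,
    filter_expression,
    kendall_pair_distance,
    overall_directional_distance,
    pairwise_distance_matrix,
    permutation_pvalues,
    ward_cluster,
)
from .conftest import make_profiles
from .oracles import kendall_decomposition_enumeration, naive_ward_linkage


class TestKendallPairDistance:
    def test_worked_four_feature_example(self):
        res = kendall_pair_distance([1, 2, 3, 4], [1, 3, 2, 4])
        assert res.tau == pytest.approx(2 / 3)
        assert res.distance == pytest.approx(1 / 6)
        assert res.contributions == pytest.approx([0, 1 / 12, 1 / 12, 0])

    def test_identity_and_monotone_transform(self, rng):
        x = rng.normal(size=30)
        for y in (x, np.exp(x), 3 * x + 2):
            res = kendall_pair_distance(x, y)
            assert res.tau == pytest.approx(1.0)
            assert res.distance == pytest.approx(0.0, abs=1e-15)
            assert np.allclose(res.contributions, 0.0)

    def test_antitone_profile(self, rng):
        x = rng.normal(size=25)
        res = kendall_pair_distance(x, -x)
        assert res.tau == pytest.approx(-1.0)
        assert res.distance == pytest.approx(1.0)
        assert res.contributions.sum() == pytest.approx(1.0)

    def test_matches_enumeration_oracle_and_scipy(self, rng):
        for m in (5, 8, 13):
            x, y = rng.normal(size=m), rng.normal(size=m)
            res = kendall_pair_distance(x, y)
            dist_oracle, contrib_oracle = kendall_decomposition_enumeration(x, y)
            assert res.distance == pytest.approx(dist_oracle, abs=1e-14)
            assert res.contributions == pytest.approx(contrib_oracle, abs=1e-14)
            # tie-free data: tau-a agrees with scipy's tau-b
            assert res.tau == pytest.approx(sps.kendalltau(x, y).statistic)

    def test_decomposition_conserves_distance(self, rng):
        for m in rng.integers(5, 80, size=40):
            x, y = rng.normal(size=m), rng.normal(size=m)
            res = kendall_pair_distance(x, y)
            assert abs(res.contributions.sum() - res.distance) <= 1e-12
            assert (res.contributions >= 0).all()

    def test_rejects_degenerate_input(self):
        with pytest.raises(ValueError):
            kendall_pair_distance([1.0], [2.0])


class TestFamilyDirectionalDistance:
    def _pair_profiles(self, patient, healthy):
        values = pd.DataFrame(
            {"p": patient, "h": healthy},
            index=[f"m{i}" for i in range(len(patient))],
        )
        meta = pd.DataFrame(
            {"family_id": ["f1", "f1"], "is_patient": [True, False]},
            index=["p", "h"],
        )
        return RankedProfileSet(values=values, sample_meta=meta)

    def test_hand_enumerated_four_feature_family(self):
        prof = self._pair_profiles([1, 2, 3, 4], [1, 3, 2, 4])
        d = family_directional_distance(prof, "f1")
        # feature 2: patient rank 2 vs healthy rank 3 -> negative component
        assert d == pytest.approx([0, -1 / 12, 1 / 12, 0])

    def test_identical_profiles_contribute_nothing(self):
        prof = self._pair_profiles([3, 1, 2, 5], [3, 1, 2, 5])
        assert np.allclose(family_directional_distance(prof, "f1"), 0.0)

    def test_label_swap_flips_every_sign(self, rng):
        x, y = rng.normal(size=12), rng.normal(size=12)
        fwd = family_directional_distance(self._pair_profiles(x, y), "f1")
        rev = family_directional_distance(self._pair_profiles(y, x), "f1")
        assert fwd == pytest.approx(-rev)

    def test_requires_both_statuses(self):
        values = pd.DataFrame({"a": [1, 2], "b": [2, 1]}, index=["m0", "m1"])
        meta = pd.DataFrame(
            {"family_id": ["f1", "f1"], "is_patient": [True, True]}, index=["a", "b"]
        )
        with pytest.raises(ValueError):
            RankedProfileSet(values=values, sample_meta=meta)


class TestOverallDirectionalDistance:
    def test_single_family_equals_family_component(self, rng):
        profiles, _ = make_profiles(1, 10, seed=4)
        res = overall_directional_distance(profiles)
        d = family_directional_distance(profiles, profiles.families[0])
        assert res.overall.to_numpy() == pytest.approx(d)

    def test_mirror_families_cancel(self, rng):
        x, y = rng.normal(size=8), rng.normal(size=8)
        values = pd.DataFrame(
            {"p1": x, "h1": y, "p2": y, "h2": x}, index=[f"m{i}" for i in range(8)]
        )
        meta = pd.DataFrame(
            {
                "family_id": ["f1", "f1", "f2", "f2"],
                "is_patient": [True, False, True, False],
            },
            index=["p1", "h1", "p2", "h2"],
        )
        res = overall_directional_distance(RankedProfileSet(values, meta))
        assert np.allclose(res.overall.to_numpy(), 0.0, atol=1e-14)

    def test_planted_shift_attains_maximum(self):
        profiles, truth = make_profiles(9, 100, seed=7, shift=2.0, n_up=1)
        res = overall_directional_distance(profiles)
        planted = truth.loc[truth["direction"] == "up", "mirna_id"].iloc[0]
        assert res.overall.idxmax() == planted

    def test_monotone_per_individual_transform_invariance(self):
        profiles, _ = make_profiles(3, 15, seed=9)
        base = overall_directional_distance(profiles)
        warped = profiles.values.copy()
        rng = np.random.default_rng(1)
        for i, c in enumerate(warped.columns):  # different transform per individual
            scale = 1.0 + rng.uniform(0.1, 2.0)
            warped[c] = np.exp(scale * warped[c] / warped[c].abs().max())
        warped_prof = RankedProfileSet(values=warped, sample_meta=profiles.sample_meta)
        res = overall_directional_distance(warped_prof)
        assert res.overall.to_numpy() == pytest.approx(base.overall.to_numpy())


class TestPermutationPvalues:
    def test_global_label_swap_exchanges_tails(self):
        profiles, _ = make_profiles(4, 12, seed=3)
        fwd = permutation_pvalues(profiles, 500, seed=8)
        flipped_meta = profiles.sample_meta.copy()
        flipped_meta["is_patient"] = ~flipped_meta["is_patient"].astype(bool)
        flipped = RankedProfileSet(values=profiles.values, sample_meta=flipped_meta)
        rev = permutation_pvalues(flipped, 500, seed=8)
        assert rev.observed.to_numpy() == pytest.approx(-fwd.observed.to_numpy())
        assert rev.p_up.to_numpy() == pytest.approx(fwd.p_down.to_numpy())
        assert rev.p_down.to_numpy() == pytest.approx(fwd.p_up.to_numpy())

    def test_agrees_with_exact_enumeration_small_design(self):
        profiles, _ = make_profiles(3, 10, seed=5)
        exact = exact_enumeration_pvalues(profiles)
        assert exact.n_permutations == 8  # 2^3 labelings
        mc = permutation_pvalues(profiles, 20_000, seed=2)
        se = np.sqrt(exact.p_up * (1 - exact.p_up) / 20_000)
        assert (np.abs(mc.p_up - exact.p_up) <= 3 * se + 1e-3).all()

    def test_multi_member_families_agree_with_enumeration(self):
        # families with >2 members force the generic resampling path
        profiles, _ = make_profiles(3, 10, seed=5, sizes=[(1, 2), (2, 1), (1, 1)])
        exact = exact_enumeration_pvalues(profiles)
        assert exact.n_permutations == 3 * 3 * 2
        mc = permutation_pvalues(profiles, 20_000, seed=3)
        se = np.sqrt(exact.p_up * (1 - exact.p_up) / 20_000)
        assert (np.abs(mc.p_up - exact.p_up) <= 3 * se + 1e-3).all()

    def test_add_one_estimator_never_zero(self):
        profiles, _ = make_profiles(2, 6, seed=1)
        res = permutation_pvalues(profiles, 50, seed=0)
        assert (res.p_up > 0).all() and (res.p_down > 0).all()
        assert (res.p_up <= 1).all() and (res.p_down <= 1).all()

    def test_requires_permutations(self):
        profiles, _ = make_profiles(2, 6, seed=1)
        with pytest.raises(ValueError):
            permutation_pvalues(profiles, 0)


class TestExactEnumeration:
    def test_single_pair_family_support(self, rng):
        x, y = rng.normal(size=6), rng.normal(size=6)
        values = pd.DataFrame({"p": x, "h": y}, index=[f"m{i}" for i in range(6)])
        meta = pd.DataFrame(
            {"family_id": ["f1", "f1"], "is_patient": [True, False]}, index=["p", "h"]
        )
        res = exact_enumeration_pvalues(RankedProfileSet(values, meta))
        assert set(np.unique(res.p_up)) <= {0.5, 1.0}

    def test_constant_data_gives_unit_pvalues(self):
        values = pd.DataFrame(
            {s: [1.0, 2.0, 3.0] for s in ["p1", "h1", "p2", "h2"]},
            index=["m0", "m1", "m2"],
        )
        meta = pd.DataFrame(
            {
                "family_id": ["f1", "f1", "f2", "f2"],
                "is_patient": [True, False, True, False],
            },
            index=values.columns,
        )
        res = exact_enumeration_pvalues(RankedProfileSet(values, meta))
        assert (res.p_up == 1.0).all() and (res.p_down == 1.0).all()

    def test_combinatorial_bound_enforced(self):
        profiles, _ = make_profiles(3, 5, seed=5)
        with pytest.raises(ValueError, match="labelings"):
            exact_enumeration_pvalues(profiles, max_labelings=4)


class TestWardCluster:
    def test_two_individuals_single_merge(self):
        tree = ward_cluster(np.array([[0.0, 0.3], [0.3, 0.0]]), labels=["a", "b"])
        assert tree.merges.shape == (1, 4)
        assert tree.heights[0] == pytest.approx(0.3)

    def test_coincident_pair_merges_first(self):
        d = np.array([[0.0, 0.0, 1.0], [0.0, 0.0, 1.0], [1.0, 1.0, 0.0]])
        tree = ward_cluster(d)
        assert set(tree.merges[0, :2].astype(int)) == {0, 1}
        assert tree.heights[0] == pytest.approx(0.0)

    def test_matches_naive_lance_williams_oracle(self, rng):
        for trial in range(5):
            x = rng.normal(size=(6, 4))
            d = np.abs(x[:, None, :] - x[None, :, :]).sum(axis=2)
            np.fill_diagonal(d, 0.0)
            tree = ward_cluster(d)
            oracle = naive_ward_linkage(d)
            for got, want in zip(tree.merges, oracle):
                assert {int(got[0]), int(got[1])} == {want[0], want[1]}
                assert got[2] == pytest.approx(want[2])

    def test_heights_non_decreasing_and_newick_wellformed(self, rng):
        profiles, _ = make_profiles(4, 20, seed=6)
        tree = ward_cluster(pairwise_distance_matrix(profiles))
        assert (np.diff(tree.heights) >= -1e-12).all()
        nwk = tree.to_newick()
        assert nwk.endswith(";") and nwk.count("(") == len(tree.merges)


class TestFilterExpression:
    def test_drops_undetected_features_then_poor_samples(self):
        values = pd.DataFrame(
            {
                "s1": [5.0, 0.0, 5.0, 5.0],
                "s2": [5.0, 0.0, 5.0, 0.0],
                "s3": [0.0, 0.0, 0.0, 0.0],
            },
            index=["m1", "m2", "m3", "m4"],
        )
        out = filter_expression(values, detect_floor=0.0,
                                min_feature_fraction=0.5, min_sample_fraction=0.5)
        assert list(out.index) == ["m1", "m3"]
        assert "s3" not in out.columns
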