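import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats
from statsmodels.stats.multitest import multipletests

from rtomics.differential import (
    bh_adjust,
    call_differential,
    choose_test,
    compare_clinical,
    compare_contingency,
    compare_feature,
    detect_group_exclusive,
    effect_magnitude,
    fold_change,
    hedges_g,
    rank_biserial,
)
from rtomics.tables import CohortMetadata, FeatureTable


class TestChooseTest:
    def test_normal_equal_variance_routes_to_t(self):
        rng = np.random.default_rng(5)  # seed chosen so both gates pass
        a, b = rng.normal(0, 1, 12), rng.normal(0, 1, 12)
        assert stats.shapiro(a).pvalue > 0.05 and stats.shapiro(b).pvalue > 0.05
        assert choose_test(a, b) == "t"

    def test_unequal_variance_routes_to_welch(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(0, 1, 50), rng.normal(0, 5, 50)
        assert choose_test(a, b) == "welch"

    def test_nonnormal_routes_to_mann_whitney(self):
        rng = np.random.default_rng(0)
        a, b = rng.exponential(1, 50), rng.normal(0, 1, 50)
        assert choose_test(a, b) == "mann-whitney"

    def test_too_few_observations_raises(self):
        with pytest.raises(ValueError, match=">=3"):
            choose_test([1.0, 2.0], [1.0, 2.0, 3.0])


class TestCompareFeature:
    def test_identical_groups_give_p_one(self):
        assert compare_feature([1.0, 1.0, 1.0], [1.0, 1.0, 1.0], "t") == 1.0

    def test_separated_groups_give_tiny_p(self):
        p = compare_feature([1, 2, 3], [101, 102, 103], "t")
        assert p < 1e-6

    def test_mann_whitney_exact_small_n(self):
        # U_a = 0; 2 of 6 orderings as or more extreme two-sided
        assert compare_feature([1, 2], [3, 4], "mann-whitney") == pytest.approx(1 / 3)


class TestBhAdjust:
    def test_hand_example(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.037])[0] == pytest.approx(0.037)

    def test_capped_at_one(self):
        np.testing.assert_allclose(bh_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_matches_bruteforce_and_statsmodels(self):
        """Step-up equivalence: q_(i) = min_{j>=i} p_(j) m/j on small random vectors."""
        rng = np.random.default_rng(42)
        for _ in range(50):
            m = rng.integers(1, 11)
            p = rng.random(m)
            q = bh_adjust(p)
            order = np.argsort(p)
            expected = np.empty(m)
            for rank_pos, idx in enumerate(order):
                expected[idx] = min(
                    min(p[order[j]] * m / (j + 1) for j in range(rank_pos, m)), 1.0)
            np.testing.assert_allclose(q, expected, rtol=1e-12)
            np.testing.assert_allclose(q, multipletests(p, method="fdr_bh")[1], rtol=1e-12)

    def test_rejections_monotone_in_sorted_order(self):
        rng = np.random.default_rng(7)
        p = rng.random(40)
        q = bh_adjust(p)
        assert (np.diff(q[np.argsort(p)]) >= -1e-15).all()

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=30))
    @settings(deadline=None, derandomize=True)
    def test_bh_invariants_hold_for_arbitrary_inputs(self, p):
        """q >= p elementwise, q in [0,1], and order-preserving on sorted p."""
        q = bh_adjust(p)
        p = np.asarray(p)
        assert (q >= p - 1e-15).all()
        assert (q >= 0).all() and (q <= 1).all()
        order = np.argsort(p, kind="stable")
        assert (np.diff(q[order]) >= -1e-15).all()


class TestEffectSizes:
    def test_hedges_g_hand_example(self):
        assert hedges_g([1, 2, 3], [3, 4, 5]) == pytest.approx(-1.6)

    def test_hedges_g_zero_for_identical_means(self):
        assert hedges_g([1, 2, 3], [2, 1, 3]) == pytest.approx(0.0)

    def test_hedges_g_antisymmetric(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(0, 1, 10), rng.normal(1, 1, 10)
        assert hedges_g(a, b) == pytest.approx(-hedges_g(b, a))

    def test_rank_biserial_extremes_and_ties(self):
        assert rank_biserial([1, 2], [3, 4]) == pytest.approx(-1.0)
        assert rank_biserial([3, 4], [1, 2]) == pytest.approx(1.0)
        assert rank_biserial([1, 2, 3], [1, 2, 3]) == pytest.approx(0.0)

    def test_magnitude_bands_per_effect_type(self):
        assert effect_magnitude(0.85, "hedges_g") == "high"
        assert effect_magnitude(-0.6, "hedges_g") == "medium"
        assert effect_magnitude(0.45, "rank_biserial") == "medium"
        assert effect_magnitude(0.45, "hedges_g") == "small"


class TestFoldChange:
    def test_hodges_lehmann_hand_example(self):
        # pairwise ratios {2, 1, 4, 2} -> median 2
        assert fold_change([2, 4], [1, 2], "hodges-lehmann") == pytest.approx(2.0)

    def test_identity(self):
        assert fold_change([1, 2, 3], [1, 2, 3], "classical") == pytest.approx(1.0)

    def test_homogeneity(self):
        rng = np.random.default_rng(3)
        a, b = rng.lognormal(size=8), rng.lognormal(size=8)
        for est in ("classical", "hodges-lehmann"):
            assert fold_change(3 * a, b, est) == pytest.approx(3 * fold_change(a, b, est))

    def test_hl_matches_explicit_pairwise_median(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            a = rng.lognormal(size=rng.integers(2, 7))
            b = rng.lognormal(size=rng.integers(2, 7))
            explicit = np.median([x / y for x in a for y in b])
            assert fold_change(a, b, "hodges-lehmann") == pytest.approx(explicit)


class TestGroupExclusive:
    def _table(self, row, meta):
        df = pd.DataFrame([row], index=["f"], columns=meta.sample_ids)
        return FeatureTable(df)

    def _meta(self, n=12):
        idx = [f"g{i}" for i in range(n)] + [f"p{i}" for i in range(n)]
        return CohortMetadata(pd.DataFrame({"group": ["GR"] * n + ["PR"] * n}, index=idx))

    def test_exclusive_detection(self):
        meta = self._meta()
        row = [np.nan] * 12 + [1.0] * 8 + [np.nan] * 4
        flags = detect_group_exclusive(self._table(row, meta), meta)
        assert flags["f"] == "PR"

    def test_detected_in_both_groups_is_none(self):
        meta = self._meta()
        row = [1.0] + [np.nan] * 11 + [1.0] + [np.nan] * 11
        flags = detect_group_exclusive(self._table(row, meta), meta)
        assert flags["f"] == "none"

    def test_below_detection_floor_is_none(self):
        meta = self._meta()
        row = [np.nan] * 12 + [1.0, 1.0] + [np.nan] * 10
        flags = detect_group_exclusive(self._table(row, meta), meta, min_detected=6)
        assert flags["f"] == "none"


class TestCallDifferential:
    def test_exclusives_and_directions_in_summary(self, small_cohort):
        _, (prot, met, meta, truth) = small_cohort
        rec, summary = call_differential(prot, meta)
        n_excl_truth = sum(1 for f in truth.exclusive_feature_ids if f.startswith("PROT"))
        assert summary["n_exclusive_GR"] + summary["n_exclusive_PR"] == n_excl_truth
        for fid, owner in truth.exclusive_feature_ids.items():
            if fid.startswith("PROT"):
                assert rec.loc[fid, "exclusive_group"] == owner
        # effect type paired to the test branch
        tested = rec[rec["test_used"].notna()]
        assert (tested.loc[tested["test_used"] == "mann-whitney", "effect_type"]
                == "rank_biserial").all()
        assert (tested.loc[tested["test_used"].isin(["t", "welch"]), "effect_type"]
                == "hedges_g").all()
        assert (tested["p_adjusted"] >= tested["p_value"] - 1e-15).all()

    def test_label_permutation_destroys_significance(self, small_cohort):
        _, (prot, _, meta, _) = small_cohort
        rng = np.random.default_rng(0)
        perm = meta.table.copy()
        perm["group"] = rng.permutation(perm["group"].to_numpy())
        rec, summary = call_differential(prot, CohortMetadata(perm))
        assert summary["n_significant_fdr"] <= 2

    def test_direction_matches_planted_truth(self, small_cohort):
        _, (prot, _, meta, truth) = small_cohort
        rec, _ = call_differential(prot, meta)
        sig = rec[(rec["p_adjusted"] < 0.05)]
        planted = [f for f in sig.index if f in truth.direction_per_feature]
        agree = np.mean([rec.loc[f, "direction"] == truth.direction_per_feature[f]
                         for f in planted])
        assert agree == 1.0


class TestClinicalComparisons:
    def test_contingency_router(self):
        name, _, _ = compare_contingency(np.array([[5, 6], [7, 6]]))
        assert name == "fisher-exact"
        name, _, _ = compare_contingency(np.array([[4, 5], [8, 6], [0, 1]]))
        assert name == "chi-square"

    def test_continuous_and_categorical_covariates(self):
        rng = np.random.default_rng(8)
        df = pd.DataFrame({
            "group": ["GR"] * 12 + ["PR"] * 12,
            "age": rng.normal(65, 10, 24).round(),
            "sex": rng.choice(["F", "M"], 24).tolist(),
        }, index=[f"s{i}" for i in range(24)])
        out = {c.covariate: c for c in compare_clinical(CohortMetadata(df))}
        assert out["age"].test in ("t", "welch", "mann-whitney")
        assert out["sex"].test == "fisher-exact"
        assert 0 <= out["sex"].p_value <= 1

    def test_single_level_covariate_skipped(self):
        df = pd.DataFrame({
            "group": ["GR"] * 3 + ["PR"] * 3,
            "site": ["A"] * 6,
        }, index=[f"s{i}" for i in range(6)])
        out = compare_clinical(CohortMetadata(df))
        assert all(c.covariate != "site" for c in out)
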