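"""Effect sizes, heterogeneity, z-scoring and Ward clustering."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.cluster.hierarchy import fcluster

from omiflim import (
    coefficient_of_variation,
    cohens_d,
    effect_size_table,
    heterogeneity_table,
    sample_feature_table,
    ward_cluster,
    zscore_features,
)
from omiflim.simulate import effect_pair
from omiflim.stats import categorize_d, linkage_to_newick


class TestCohensD:
    def test_identical_groups_give_zero(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        es = cohens_d(x, x, warn_small_n=False)
        assert es.d == 0.0 and es.category == "none" and es.direction == "none"

    def test_hand_value(self):
        rng = np.random.default_rng(0)
        # construct exact moments: mean 2 vs 1, both sample SDs exactly 1
        def with_moments(mean, n=200):
            z = rng.normal(size=n)
            z = (z - z.mean()) / z.std(ddof=1)
            return mean + z

        es = cohens_d(with_moments(2.0), with_moments(1.0))
        assert es.d == pytest.approx(1.0, abs=1e-12)
        assert es.category == "large" and es.direction == "increase"

    @pytest.mark.parametrize(
        "d,category",
        [
            (0.1, "none"),
            (0.2, "small"),
            (0.49, "small"),
            (0.5, "medium"),
            (0.6, "medium"),
            (0.79, "medium"),
            (0.8, "large"),
            (2.0, "large"),
            (-0.6, "medium"),
        ],
    )
    def test_category_boundaries_half_open(self, d, category):
        assert categorize_d(d) == category

    def test_antisymmetry_exact(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(0, 1, 150), rng.normal(0.5, 2, 150)
        assert cohens_d(a, b).d == -cohens_d(b, a).d

    @given(
        shift=st.floats(-100, 100),
        scale=st.floats(0.01, 100),
        seed=st.integers(0, 2**16),
    )
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_location_scale_invariance(self, shift, scale, seed):
        rng = np.random.default_rng(seed)
        a, b = rng.normal(0, 1, 120), rng.normal(1, 1, 120)
        d0 = cohens_d(a, b).d
        d1 = cohens_d(scale * (a + shift), scale * (b + shift)).d
        assert d1 == pytest.approx(d0, rel=1e-9)

    def test_zero_variance_flagged_undefined(self):
        es = cohens_d([1.0, 1.0, 1.0], [2.0, 2.0, 2.0], warn_small_n=False)
        assert np.isnan(es.d) and es.category == "undefined"

    def test_small_groups_warn_not_error(self):
        with pytest.warns(UserWarning, match="guideline"):
            cohens_d([1.0, 2.0, 3.0], [2.0, 3.0, 4.0])

    @pytest.mark.parametrize("target", [0.2, 0.5, 0.8, 2.0])
    def test_monte_carlo_recovery(self, target):
        t = sample_feature_table(effect_pair(target), 1000, rng_seed=7)
        a = t[t.cell_type == "group_a"]["nadph_tau_m"]
        b = t[t.cell_type == "group_b"]["nadph_tau_m"]
        es = cohens_d(b, a, warn_small_n=False)
        assert es.d == pytest.approx(target, abs=0.1)


class TestCov:
    def test_constant_values(self):
        assert coefficient_of_variation([5.0, 5.0, 5.0]) == 0.0

    def test_hand_value(self):
        assert coefficient_of_variation([1.0, 3.0]) == pytest.approx(
            np.sqrt(2) / 2, abs=1e-12
        )

    @given(k=st.floats(1e-6, 1e6), seed=st.integers(0, 2**16))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_scale_invariance(self, k, seed):
        rng = np.random.default_rng(seed)
        x = rng.uniform(1, 10, 50)
        assert coefficient_of_variation(k * x) == pytest.approx(
            coefficient_of_variation(x), rel=1e-12
        )

    def test_nonpositive_mean_flagged(self):
        with pytest.warns(UserWarning):
            assert np.isnan(coefficient_of_variation([-1.0, -3.0]))

    def test_single_value_rejected(self):
        with pytest.raises(ValueError):
            coefficient_of_variation([1.0])


class TestZscore:
    def _table(self, n=50, seed=0):
        rng = np.random.default_rng(seed)
        return pd.DataFrame(
            {"a": rng.normal(5, 2, n), "b": rng.uniform(0, 100, n)}
        )

    def test_columns_standardized(self):
        z, _ = zscore_features(self._table(), ["a", "b"])
        assert np.allclose(z.mean(), 0, atol=1e-9)
        assert np.allclose(z.std(ddof=1), 1, atol=1e-9)

    def test_two_row_symmetry(self):
        z, _ = zscore_features(pd.DataFrame({"a": [1.0, 3.0]}), ["a"])
        assert z["a"].tolist() == pytest.approx([-np.sqrt(0.5), np.sqrt(0.5)])

    def test_round_trip_inverse(self):
        t = self._table()
        z, scale = zscore_features(t, ["a", "b"])
        back = z * scale["sd"] + scale["mean"]
        assert np.allclose(back, t[["a", "b"]], atol=1e-10)

    def test_zero_variance_column_dropped_with_warning(self):
        t = self._table()
        t["c"] = 7.0
        with pytest.warns(UserWarning, match="zero-variance"):
            z, _ = zscore_features(t, ["a", "c"])
        assert "c" not in z.columns

    def test_missing_values_rejected(self):
        t = self._table()
        t.loc[0, "a"] = np.nan
        with pytest.raises(ValueError, match="QC"):
            zscore_features(t, ["a"])


class TestWardCluster:
    def test_separated_blobs_recovered_exactly(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0, 1, size=(40, 3))
        b = rng.normal(10, 1, size=(40, 3))  # 10 SDs apart
        z = pd.DataFrame(np.vstack([a, b]))
        res = ward_cluster(z, n_clusters=2)
        labels = res["clusters"]
        assert len(set(labels[:40])) == 1 and len(set(labels[40:])) == 1
        assert labels[0] != labels[40]

    def test_duplicate_rows_merge_first_at_zero_height(self):
        x = pd.DataFrame([[0.0, 0.0], [5.0, 5.0], [0.0, 0.0]])
        res = ward_cluster(x)
        lm = res["linkage"]
        assert lm[0, 2] == 0.0
        assert {int(lm[0, 0]), int(lm[0, 1])} == {0, 2}

    def test_three_point_merge_order_matches_exhaustive_ward(self):
        # brute-force the Ward criterion: merge cost = sqrt(2 * increase in
        # within-cluster sum of squares); compare order and heights
        pts = np.array([[0.0, 0.0], [1.0, 0.5], [6.0, 2.0]])

        def ess(ix):
            p = pts[list(ix)]
            return ((p - p.mean(axis=0)) ** 2).sum()

        pairs = list(itertools.combinations(range(3), 2))
        costs = {pair: np.sqrt(2 * ess(pair)) for pair in pairs}
        first = min(costs, key=costs.get)
        final_height = np.sqrt(2 * (ess((0, 1, 2)) - ess(first)))

        res = ward_cluster(pd.DataFrame(pts))
        lm = res["linkage"]
        assert {int(lm[0, 0]), int(lm[0, 1])} == set(first)
        assert lm[0, 2] == pytest.approx(costs[first], rel=1e-12)
        assert lm[1, 2] == pytest.approx(final_height, rel=1e-12)

    def test_annotations_never_affect_dendrogram(self):
        rng = np.random.default_rng(3)
        z = pd.DataFrame(rng.normal(size=(30, 4)))
        ann1 = pd.DataFrame({"cond": ["q"] * 15 + ["a"] * 15})
        ann2 = pd.DataFrame({"cond": rng.permutation(ann1["cond"])})
        r1 = ward_cluster(z, annotations=ann1)
        r2 = ward_cluster(z, annotations=ann2)
        assert np.array_equal(r1["linkage"], r2["linkage"])

    def test_newick_rendering_has_all_leaves(self):
        rng = np.random.default_rng(4)
        res = ward_cluster(pd.DataFrame(rng.normal(size=(6, 2))))
        nwk = res["newick"]
        assert nwk.endswith(";")
        for leaf in range(6):
            assert str(leaf) in nwk

    def test_missing_values_rejected(self):
        x = pd.DataFrame([[0.0, np.nan], [1.0, 2.0]])
        with pytest.raises(ValueError, match="QC"):
            ward_cluster(x)


class TestTables:
    def _two_condition_table(self):
        q = sample_feature_table(effect_pair(1.0), 200, rng_seed=0, condition="quiescent")
        a = sample_feature_table(effect_pair(1.0), 200, rng_seed=1, condition="activated")
        a["nadph_tau_m"] += 30.0
        return pd.concat([q, a], ignore_index=True)

    def test_effect_size_table_pooled_and_stratified(self):
        t = self._two_condition_table()
        pooled = effect_size_table(t, ["nadph_tau_m"], by=None)
        assert len(pooled) == 1
        assert pooled["nadph_tau_m_direction"][0] == "increase"
        strat = effect_size_table(t, ["nadph_tau_m"], by=["cell_type"])
        assert set(strat["cell_type"]) == {"group_a", "group_b"}

    def test_heterogeneity_table_matches_direct_cov(self):
        t = self._two_condition_table()
        het = heterogeneity_table(t, ["nadph_tau_m"], by=("cell_type", "condition"))
        row = het[(het.cell_type == "group_a") & (het.condition == "quiescent")]
        sub = t[(t.cell_type == "group_a") & (t.condition == "quiescent")]["nadph_tau_m"]
        assert row["cov"].iloc[0] == pytest.approx(sub.std(ddof=1) / sub.mean())
        assert row["n"].iloc[0] == len(sub)
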