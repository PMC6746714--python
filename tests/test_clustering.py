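"""Fuzzy c-means, k selection, and the cluster comparison tests."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from embryomics.clustering import (
    compare_clusterings,
    fisher_enrichment,
    fuzzy_cmeans,
    meta_overlap_test,
    select_k,
    zscore_profiles,
)
from embryomics.datatypes import CognateMap


class TestZScore:
    def test_two_point_oracle(self):
        z = zscore_profiles(pd.DataFrame({"a": [0.0], "b": [2.0]}))
        assert z.iloc[0].to_numpy() == pytest.approx([-1 / math.sqrt(2), 1 / math.sqrt(2)])

    def test_constant_profile_maps_to_zeros(self):
        z = zscore_profiles(pd.DataFrame({"a": [3.0], "b": [3.0], "c": [3.0]}))
        assert np.allclose(z.iloc[0], 0.0)

    def test_rows_standardized(self):
        rng = np.random.default_rng(0)
        z = zscore_profiles(pd.DataFrame(rng.normal(size=(20, 6))))
        assert np.allclose(z.mean(axis=1), 0.0, atol=1e-12)
        assert np.allclose(z.std(axis=1, ddof=1), 1.0)


class TestFCM:
    def test_k1_is_the_mean(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame(rng.normal(size=(15, 3)))
        cl = fuzzy_cmeans(X, 1)
        assert np.allclose(cl.membership, 1.0)
        assert np.allclose(cl.centroids.iloc[0], X.mean(axis=0))

    def test_two_blob_recovery(self):
        rng = np.random.default_rng(2)
        a = rng.normal(0, 0.1, (30, 4))
        b = rng.normal(3, 0.1, (30, 4))
        X = pd.DataFrame(np.vstack([a, b]))
        cl = fuzzy_cmeans(X, 2, seed=0)
        labels = cl.hard.to_numpy()
        assert len(set(labels[:30])) == 1 and len(set(labels[30:])) == 1
        assert labels[0] != labels[-1]

    def test_membership_rows_sum_to_one(self):
        rng = np.random.default_rng(3)
        X = pd.DataFrame(rng.normal(size=(40, 5)))
        cl = fuzzy_cmeans(X, 4, seed=1)
        assert np.abs(cl.membership.sum(axis=1) - 1.0).max() < 1e-9

    def test_objective_nonincreasing_in_iterations(self):
        rng = np.random.default_rng(4)
        X = pd.DataFrame(rng.normal(size=(50, 4)))
        objs = [
            fuzzy_cmeans(X, 3, seed=2, n_restarts=1, max_iter=i).objective
            for i in (1, 2, 4, 8, 32)
        ]
        assert all(b <= a + 1e-9 for a, b in zip(objs, objs[1:]))

    def test_k_larger_than_n_rejected(self):
        X = pd.DataFrame(np.ones((3, 2)))
        with pytest.raises(ValueError):
            fuzzy_cmeans(X, 5)


class TestSelectK:
    def test_singleton_range(self):
        X = pd.DataFrame(np.random.default_rng(0).normal(size=(10, 3)))
        assert select_k(X, k_range=[2]).k == 2

    def test_planted_archetype_count(self):
        rng = np.random.default_rng(5)
        centers = np.array(
            [[2, 0, 0, 0], [-2, 0, 0, 0], [0, 2, 0, 0], [0, -2, 0, 0]]
        )
        X = pd.DataFrame(
            np.vstack([c + rng.normal(0, 0.15, (40, 4)) for c in centers])
        )
        sel = select_k(X, k_range=range(2, 8), seed=0)
        assert sel.k == 4


class TestFisher:
    def test_hypergeometric_hand_value(self):
        # universe 8, margins 4/4, overlap 3 -> one-sided p = 17/70
        _, p = fisher_enrichment(3, 4, 4, 8)
        assert p == pytest.approx(17 / 70)

    def test_empty_overlap_is_depleted(self):
        _, p = fisher_enrichment(0, 4, 4, 8)
        assert p >= 0.5


class TestComparison:
    def _clusterings(self):
        rng = np.random.default_rng(6)
        genes = [f"g{i}" for i in range(60)]
        profiles = pd.DataFrame(
            np.vstack(
                [
                    np.linspace(0, 2, 6) + rng.normal(0, 0.05, 6)
                    if i < 30
                    else np.linspace(2, 0, 6) + rng.normal(0, 0.05, 6)
                    for i in range(60)
                ]
            ),
            index=genes,
            columns=["1cell", "2cell", "4cell", "8cell", "morula", "blastocyst"],
        )
        cl = fuzzy_cmeans(zscore_profiles(profiles), 2, seed=0)
        return cl, profiles

    def test_self_comparison_diagonal(self):
        cl, profiles = self._clusterings()
        tfc = profiles.copy()
        tfc.columns = ["1cell", "2cell_late", "4cell", "8cell", "morula", "blastocyst"]
        cmap = CognateMap.identity(profiles.index)
        comp = compare_clusterings(cl, cl, cmap, profiles, tfc)
        # align diagonal by hard-assignment identity
        for c in range(cl.k):
            assert comp.r.loc[c, c] == pytest.approx(1.0, abs=0.02)
            assert comp.overlap.loc[c, c] == len(cl.members(c))
        assert comp.universe == 60

    def test_meta_overlap_table_and_oracle(self):
        from embryomics.clustering import ClusterComparison, MetaOverlapResult

        r = pd.DataFrame([[0.9] * 4, [0.2] * 4])
        p = pd.DataFrame([[0.01, 0.01, 0.01, 0.2], [0.01, 0.2, 0.2, 0.2]])
        comp = ClusterComparison(
            r=r, overlap=r * 0, pvalues=p, universe=10,
            protein_members={}, transcript_members={},
        )
        res = meta_overlap_test(comp, r_min=0.5, p_max=0.05)
        assert res.table.tolist() == [[3, 1], [1, 3]]
        assert res.pvalue == pytest.approx(17 / 70)

    def test_degenerate_all_significant_gives_infinite_or(self):
        from embryomics.clustering import ClusterComparison

        r = pd.DataFrame([[0.9, 0.9], [0.2, 0.3]])
        p = pd.DataFrame([[0.01, 0.01], [0.5, 0.9]])
        comp = ClusterComparison(
            r=r, overlap=r * 0, pvalues=p, universe=10,
            protein_members={}, transcript_members={},
        )
        res = meta_overlap_test(comp)
        assert res.table.tolist() == [[2, 0], [0, 2]]
        assert np.isinf(res.sample_odds_ratio) or np.isinf(res.odds_ratio)


def test_fisher_matches_exhaustive_hypergeometric_small():
    rng = np.random.default_rng(7)
    for _ in range(50):
        n = int(rng.integers(2, 20))
        a = int(rng.integers(0, n + 1))
        b = int(rng.integers(0, n - a + 1))
        c = int(rng.integers(0, n - a - b + 1))
        size_a, size_b = a + b, a + c
        _, p = fisher_enrichment(a, size_a, size_b, n)
        lo = max(0, size_a + size_b - n)
        hi = min(size_a, size_b)
        denom = math.comb(n, size_b)
        oracle = sum(
            math.comb(size_a, k) * math.comb(n - size_a, size_b - k) / denom
            for k in range(a, hi + 1)
        )
        assert p == pytest.approx(oracle, rel=1e-9)
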