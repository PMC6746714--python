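"""Shrinkage LDA, LOOCV AUC, marker ranking and enrichment."""

import numpy as np
import pandas as pd
import pytest

import embryomics as em
from embryomics.datatypes import DesignError, StageDesign
from embryomics.markers import (
    discover_markers,
    enrichment_test,
    fit_lda,
    label_stages,
    loocv_auc,
    rank_auc,
    rank_markers,
)

EARLY = ("oocyte", "1cell", "2cell")
LATE = ("4cell", "8cell", "morula", "blastocyst")


def _design():
    samples = [f"{s}_rep{r}" for s in EARLY + LATE for r in (1, 2, 3)]
    return StageDesign.from_sample_names(samples, reference="oocyte")


def _labels(design):
    return label_stages(design, EARLY, LATE)


class TestLabels:
    def test_partition(self):
        labels = _labels(_design())
        assert labels["oocyte_rep1"] == "early"
        assert labels["4cell_rep2"] == "late"

    def test_overlap_and_incompleteness_rejected(self):
        d = _design()
        with pytest.raises(DesignError):
            label_stages(d, EARLY + ("4cell",), LATE)
        with pytest.raises(DesignError):
            label_stages(d, EARLY, LATE[:-1])


def _separable_matrix(design, rng, n_noise=30, gap=10.0):
    labels = _labels(design)
    rows = {"signal": [gap if labels[s] == "late" else 0.0 for s in design.samples]}
    for i in range(n_noise):
        rows[f"noise{i}"] = rng.normal(0, 1, len(design.samples))
    return pd.DataFrame.from_dict(rows, orient="index", columns=design.samples)


class TestLDA:
    def test_separable_training_accuracy(self):
        design = _design()
        m = _separable_matrix(design, np.random.default_rng(0))
        labels = _labels(design)
        model = fit_lda(m, labels)
        assert (model.predict(m) == labels).all()

    def test_duplicated_feature_gets_equal_weight_at_diagonal(self):
        design = _design()
        rng = np.random.default_rng(1)
        m = _separable_matrix(design, rng, n_noise=5, gap=2.0)
        m.loc["signal_copy"] = m.loc["signal"]
        model = fit_lda(m, _labels(design), shrinkage=1.0)
        assert model.weights["signal"] == pytest.approx(model.weights["signal_copy"])

    def test_small_class_rejected(self):
        design = StageDesign.from_sample_names(
            ["oocyte_rep1", "4cell_rep1", "4cell_rep2", "8cell_rep1"],
            reference="oocyte",
        )
        labels = label_stages(design, ("oocyte",), ("4cell", "8cell"))
        m = pd.DataFrame(np.ones((3, 4)), columns=design.samples)
        with pytest.raises(ValueError):
            fit_lda(m, labels)

    def test_woodbury_matches_direct_solve(self):
        rng = np.random.default_rng(2)
        design = _design()
        m = pd.DataFrame(
            rng.normal(size=(60, len(design.samples))), columns=design.samples
        )
        labels = _labels(design)
        model = fit_lda(m, labels, shrinkage=0.5)
        # direct dense solve for comparison
        X0 = m[labels.index[labels == "early"]].to_numpy().T
        X1 = m[labels.index[labels == "late"]].to_numpy().T
        mu0, mu1 = X0.mean(0), X1.mean(0)
        Xc = np.vstack([X0 - mu0, X1 - mu1])
        S = Xc.T @ Xc / (len(X0) + len(X1) - 2)
        Sreg = 0.5 * S + 0.5 * np.diag(np.diag(S))
        w = np.linalg.solve(Sreg, mu1 - mu0)
        assert np.allclose(model.weights.to_numpy(), w, atol=1e-8)


class TestLOOCV:
    def test_perfectly_separated_auc_one(self):
        design = _design()
        m = _separable_matrix(design, np.random.default_rng(3))
        auc, scores = loocv_auc(m, _labels(design))
        assert auc == 1.0

    def test_null_auc_near_half(self):
        rng = np.random.default_rng(4)
        design = _design()
        aucs = []
        for _ in range(5):
            m = pd.DataFrame(
                rng.normal(size=(25, len(design.samples))), columns=design.samples
            )
            aucs.append(loocv_auc(m, _labels(design))[0])
        assert 0.2 < np.mean(aucs) < 0.8

    def test_flipped_sample_breaks_perfection(self):
        design = _design()
        m = _separable_matrix(design, np.random.default_rng(5), n_noise=2)
        m.loc["signal", "blastocyst_rep1"] = -5.0  # one late sample looks early
        auc, _ = loocv_auc(m, _labels(design))
        assert auc < 1.0


class TestRanking:
    def test_dominant_feature_ranked_first(self):
        design = _design()
        m = _separable_matrix(design, np.random.default_rng(6))
        model = fit_lda(m, _labels(design))
        res = rank_markers(model, m, top_n=1)
        assert res.top == ["signal"]

    def test_scale_invariance(self):
        design = _design()
        m = _separable_matrix(design, np.random.default_rng(7))
        model = fit_lda(m, _labels(design))
        r1 = rank_markers(model, m, top_n=5)
        m2 = m.copy()
        m2.loc["noise0"] *= 100.0
        model2 = fit_lda(m2, _labels(design))
        r2 = rank_markers(model2, m2, top_n=5)
        assert r2.relevance["noise0"] == pytest.approx(r1.relevance["noise0"], rel=1e-6)

    def test_top_n_bounds(self):
        design = _design()
        m = _separable_matrix(design, np.random.default_rng(8), n_noise=3)
        model = fit_lda(m, _labels(design))
        with pytest.raises(ValueError):
            rank_markers(model, m, top_n=100)


class TestEnrichment:
    def test_hypergeometric_oracle(self):
        universe = [f"g{i}" for i in range(8)]
        _, p = enrichment_test(universe[:4], universe[2:6], universe)
        # margins 4/4, overlap 2 in universe 8: sum of k>=2 tail
        import math

        oracle = sum(
            math.comb(4, k) * math.comb(4, 4 - k) / math.comb(8, 4) for k in (2, 3, 4)
        )
        assert p == pytest.approx(oracle)

    def test_identical_sets_minimal_p(self):
        universe = [f"g{i}" for i in range(10)]
        _, p_match = enrichment_test(universe[:4], universe[:4], universe)
        _, p_partial = enrichment_test(universe[:4], universe[2:6], universe)
        assert p_match < p_partial

    def test_subset_and_empty_universe_errors(self):
        with pytest.raises(ValueError):
            enrichment_test(["x"], ["x"], [])
        with pytest.raises(ValueError):
            enrichment_test(["x"], ["y"], ["y"])


def test_four_cell_sits_nearest_the_boundary_when_only_markers_ramp():
    """With the marker ramp as the only planted signal, held-out LDA scores
    place the 4-cell samples closest to the early/late boundary."""
    hits = 0
    for seed in range(5):
        cfg = em.SimulationConfig(
            n_genes=600, seed=seed, profile_scale=0.0,
            frac_correlated=0.0, frac_anticorrelated=0.0,
            background_coupling=(0.0, 0.0), batch_sd=0.0,
        )
        ds = em.simulate_dataset(cfg)
        from embryomics.proteome import batch_correct, filter_detected, quantile_normalize

        corrected = quantile_normalize(
            filter_detected(ds.protein_matrix, ds.protein_design)
        ).dropna()
        res = discover_markers(corrected, ds.protein_design, EARLY, LATE)
        sc = res.loocv_scores
        stage_of = ds.protein_design.stage_of
        late = [s for s in sc.index if stage_of[s] in LATE]
        four = [s for s in late if stage_of[s] == "4cell"]
        others = [s for s in late if stage_of[s] != "4cell"]
        if np.abs(sc[four]).mean() < np.abs(sc[others]).mean():
            hits += 1
    assert hits >= 4
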