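"""Proteome processing: detection filter, quantile normalization, batch
correction and the stage ANOVA, against hand-computed oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from embryomics.datatypes import DesignError, StageDesign
from embryomics.proteome import (
    NormalizationError,
    anova_stage_test,
    batch_correct,
    call_de_proteins,
    filter_detected,
    fold_changes,
    protein_de,
    quantile_normalize,
    stage_means,
)


def _design(samples):
    return StageDesign.from_sample_names(samples, reference=samples[0].rsplit("_", 1)[0])


def _matrix(rows, samples):
    return pd.DataFrame(rows, index=[f"p{i}" for i in range(len(rows))], columns=samples)


class TestFilterDetected:
    samples = [f"{s}_rep{r}" for s in ("oocyte", "2cell", "4cell") for r in (1, 2)]

    def test_two_reps_of_one_stage_kept(self):
        m = _matrix([[1.0, 2.0, np.nan, np.nan, np.nan, np.nan]], self.samples)
        out = filter_detected(m, _design(self.samples), min_reps=2, min_stages=1)
        assert list(out.index) == ["p0"]

    def test_single_rep_everywhere_dropped(self):
        m = _matrix([[1.0, np.nan, 2.0, np.nan, 3.0, np.nan]], self.samples)
        out = filter_detected(m, _design(self.samples), min_reps=2, min_stages=1)
        assert out.empty

    def test_two_stages_two_reps_variant(self):
        m = _matrix([[1.0, 2.0, 3.0, 4.0, np.nan, np.nan]], self.samples)
        out = filter_detected(m, _design(self.samples), min_reps=2, min_stages=2)
        assert list(out.index) == ["p0"]
        strict = filter_detected(m, _design(self.samples), min_reps=2, min_stages=3)
        assert strict.empty

    def test_unknown_sample_rejected(self):
        m = _matrix([[1.0]], ["8cell_rep1"])
        with pytest.raises(DesignError):
            filter_detected(m, _design(self.samples))


class TestQuantileNormalize:
    def test_rank_mean_oracle(self):
        m = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [2.0, 4.0, 6.0]})
        out = quantile_normalize(m)
        expected = pd.DataFrame({"a": [1.5, 3.0, 4.5], "b": [1.5, 3.0, 4.5]})
        pd.testing.assert_frame_equal(out, expected)

    def test_identical_columns_are_a_fixed_point(self):
        m = pd.DataFrame({"a": [3.0, 1.0, 2.0], "b": [3.0, 1.0, 2.0]})
        pd.testing.assert_frame_equal(quantile_normalize(m), m)

    def test_idempotent_on_complete_matrices(self):
        rng = np.random.default_rng(1)
        m = pd.DataFrame(rng.normal(size=(40, 5)))
        once = quantile_normalize(m)
        twice = quantile_normalize(once)
        pd.testing.assert_frame_equal(once, twice)

    def test_missing_entries_stay_missing(self):
        m = pd.DataFrame({"a": [1.0, np.nan, 3.0], "b": [2.0, 4.0, 6.0]})
        out = quantile_normalize(m)
        assert np.isnan(out.loc[1, "a"])
        assert out.notna().sum().sum() == 5

    def test_sample_with_single_value_is_an_error(self):
        m = pd.DataFrame({"a": [1.0, np.nan, np.nan], "b": [2.0, 4.0, 6.0]})
        with pytest.raises(NormalizationError, match="a"):
            quantile_normalize(m)


class TestBatchCorrect:
    def test_hand_anova_residual_oracle(self):
        # one feature: stageA (2,1,0), stageB (4,3,2) by replicate
        samples = ["A_rep1", "A_rep2", "A_rep3", "B_rep1", "B_rep2", "B_rep3"]
        design = _design(samples)
        m = _matrix([[2.0, 1.0, 0.0, 4.0, 3.0, 2.0]], samples)
        out = batch_correct(m, design)
        expected = [1.0, 1.0, 1.0, 3.0, 3.0, 3.0]
        assert np.allclose(out.iloc[0].to_numpy(), expected)

    def test_zero_batch_effect_is_identity(self):
        samples = ["A_rep1", "A_rep2", "B_rep1", "B_rep2"]
        m = _matrix([[1.0, 2.0, 3.0, 4.0]], samples)  # rep means equal (2,3)... not
        m = _matrix([[1.0, 1.0, 3.0, 3.0]], samples)
        out = batch_correct(m, _design(samples))
        pd.testing.assert_frame_equal(out, m)

    def test_within_replicate_contrasts_unchanged(self):
        rng = np.random.default_rng(2)
        samples = [f"{s}_rep{r}" for s in ("A", "B", "C") for r in (1, 2)]
        m = _matrix(rng.normal(size=(8, 6)), samples)
        out = batch_correct(m, _design(samples))
        for rep in ("rep1", "rep2"):
            cols = [s for s in samples if s.endswith(rep)]
            before = m[cols[0]] - m[cols[1]]
            after = out[cols[0]] - out[cols[1]]
            assert np.allclose(before, after)

    def test_post_correction_replicate_means_equal(self):
        rng = np.random.default_rng(3)
        samples = [f"{s}_rep{r}" for s in ("A", "B") for r in (1, 2, 3)]
        design = _design(samples)
        m = _matrix(rng.normal(size=(10, 6)), samples)
        out = batch_correct(m, design)
        reps = design.replicate_series(list(out.columns))
        means = {
            r: out[[c for c in out.columns if reps[c] == r]].mean(axis=1)
            for r in ("rep1", "rep2", "rep3")
        }
        assert np.allclose(means["rep1"], means["rep2"])
        assert np.allclose(means["rep2"], means["rep3"])


class TestAnova:
    samples = ["A_rep1", "A_rep2", "A_rep3", "B_rep1", "B_rep2", "B_rep3"]

    def test_closed_form_f_oracle(self):
        m = _matrix([[1.0, 2.0, 3.0, 2.0, 3.0, 4.0]], self.samples)
        p = anova_stage_test(m, _design(self.samples))
        # F = 1.5 on (1, 4) df
        assert p.iloc[0] == pytest.approx(stats.f.sf(1.5, 1, 4))
        assert p.iloc[0] == pytest.approx(0.288, abs=1e-3)

    def test_constant_feature_gives_p_one(self):
        m = _matrix([[2.0] * 6], self.samples)
        assert anova_stage_test(m, _design(self.samples)).iloc[0] == 1.0

    def test_single_stage_feature_is_na(self):
        m = _matrix([[1.0, 2.0, 3.0, np.nan, np.nan, np.nan]], self.samples)
        assert np.isnan(anova_stage_test(m, _design(self.samples)).iloc[0])


class TestFoldChanges:
    samples = ["oocyte_rep1", "oocyte_rep2", "2cell_rep1", "2cell_rep2"]

    def test_definition_and_reference_zero(self):
        design = _design(self.samples)
        m = _matrix([[1.0, 1.0, 3.0, 3.0]], self.samples)
        fc = fold_changes(m, design)
        assert fc.loc["p0", "2cell"] == pytest.approx(2.0)
        assert "oocyte" not in fc.columns
        means = stage_means(m, design)
        assert means.loc["p0", "oocyte"] == pytest.approx(1.0)

    def test_undetected_reference_gives_na(self):
        m = _matrix([[np.nan, np.nan, 3.0, 3.0]], self.samples)
        fc = fold_changes(m, _design(self.samples))
        assert np.isnan(fc.loc["p0", "2cell"])

    def test_missing_reference_stage_is_error(self):
        m = _matrix([[1.0, 1.0, 3.0, 3.0]], self.samples)
        with pytest.raises(DesignError):
            fold_changes(m, _design(self.samples), reference="morula")


class TestCallDE:
    samples = [f"{s}_rep{r}" for s in ("oocyte", "2cell", "4cell") for r in (1, 2)]

    def _de(self, rows):
        return protein_de(_matrix(rows, self.samples), _design(self.samples))

    def test_thresholds_applied(self):
        # p small, fold change 2^1.2 between oocyte and 4cell
        de = self._de([[0.0, 0.01, 0.6, 0.61, 1.2, 1.21]])
        sel, _ = call_de_proteins(de, p_max=0.05, min_fc=2.0, scope="any_pair")
        assert list(sel) == ["p0"]

    def test_large_p_excluded_regardless_of_fold_change(self):
        de = self._de([[0.0, 4.0, 1.0, 5.0, 2.0, 6.0]])
        assert de.pvalues.iloc[0] > 0.05
        sel, _ = call_de_proteins(de, scope="any_pair")
        assert len(sel) == 0

    def test_transition_sets_localized(self):
        # change only between 2cell and 4cell
        de = self._de([[0.0, 0.02, 0.0, 0.02, 1.5, 1.52]])
        sel, transitions = call_de_proteins(de, scope="consecutive")
        assert list(sel) == ["p0"]
        assert list(transitions["2cell->4cell"]) == ["p0"]
        assert len(transitions["oocyte->2cell"]) == 0

    def test_invalid_scope_rejected(self):
        de = self._de([[0.0, 0.0, 0.0, 0.0, 0.0, 0.0]])
        with pytest.raises(ValueError):
            call_de_proteins(de, scope="bogus")
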