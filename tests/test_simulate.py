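"""Generator contracts: determinism, planted structure, noise-free limits."""

import numpy as np
import pandas as pd
import pytest

import embryomics as em
from embryomics.simulate import (
    ConfigError,
    MARKER_RAMP,
    SimulationConfig,
    simulate_annotations,
    simulate_external_measurements,
)
from scipy import stats


def test_coupling_class_counts_match_rounded_fractions():
    cfg = SimulationConfig(n_genes=1000, frac_correlated=0.07, frac_anticorrelated=0.03)
    truth = em.generate_truth(cfg)
    counts = truth.coupling_class.value_counts()
    assert counts["correlated"] == 70
    assert counts["anticorrelated"] == 30


def test_same_seed_gives_identical_outputs():
    cfg = SimulationConfig(n_genes=120, seed=5)
    a, b = em.simulate_dataset(cfg), em.simulate_dataset(cfg)
    pd.testing.assert_frame_equal(a.protein_matrix, b.protein_matrix)
    pd.testing.assert_frame_equal(a.count_matrix, b.count_matrix)
    pd.testing.assert_series_equal(a.truth.coupling_class, b.truth.coupling_class)
    assert [m.values.tolist() for m in a.measurements] == [
        m.values.tolist() for m in b.measurements
    ]


@pytest.mark.parametrize(
    "kwargs",
    [
        dict(frac_correlated=0.9, frac_anticorrelated=0.2),
        dict(protein_stages=()),
        dict(noise_sd=-1.0),
        dict(archetype_purity=(0.8, 0.2)),
        dict(delay_profile=(1.0, 1.0)),
    ],
)
def test_invalid_configs_rejected(kwargs):
    with pytest.raises(ConfigError):
        SimulationConfig(n_genes=50, **kwargs).validate()


def test_noise_free_proteome_columns_identical_within_stage():
    cfg = SimulationConfig(
        n_genes=60,
        seed=1,
        batch_sd=0.0,
        noise_sd=0.0,
        detect_midpoint=-np.inf,
        detect_prob_overall=1.0,
    )
    truth = em.generate_truth(cfg)
    matrix, design = em.simulate_proteome(truth, cfg)
    assert matrix.notna().all().all()
    for stage in design.stages:
        cols = design.samples_of_stage(stage)
        block = matrix[cols]
        assert np.allclose(block.sub(block.iloc[:, 0], axis=0), 0.0)
    # and the fold-change of each gene equals the planted profile exactly
    fc = matrix["morula_rep1"] - matrix["oocyte_rep1"]
    planted = truth.protein_fc.loc[matrix.index, "morula"]
    assert np.allclose(fc, planted)


def test_full_detection_limit_has_no_missing_values():
    cfg = SimulationConfig(n_genes=80, seed=2, detect_midpoint=-np.inf)
    truth = em.generate_truth(cfg)
    matrix, _ = em.simulate_proteome(truth, cfg)
    assert matrix.notna().all().all()


def test_replicate_means_recover_planted_batch_offsets():
    cfg = SimulationConfig(
        n_genes=3000,
        seed=3,
        batch_sd=1.0,
        profile_scale=0.0,
        frac_correlated=0.0,
        frac_anticorrelated=0.0,
        n_markers=0,
        detect_midpoint=-np.inf,
        detect_prob_overall=1.0,
        drop_blastocyst_rep=False,
    )
    truth = em.generate_truth(cfg)
    matrix, design = em.simulate_proteome(truth, cfg)
    grand = matrix.to_numpy().mean()
    for rep, planted in truth.batch_offsets.items():
        cols = design.samples_of_replicate(rep)
        est = matrix[cols].to_numpy().mean() - grand
        centered = planted - np.mean(list(truth.batch_offsets.values()))
        n = matrix[cols].size
        se = cfg.noise_sd / np.sqrt(n) + cfg.baseline_sd / np.sqrt(cfg.n_genes)
        assert abs(est - centered) < 3 * 3 * se  # generous 3x(3 SE)


def test_transcriptome_poisson_limit_and_moment_recovery():
    cfg = SimulationConfig(
        n_genes=2000,
        seed=4,
        nb_dispersion=0.0,
        size_factor_range=(1.0, 1.0),
        profile_scale=0.0,
        frac_correlated=0.0,
        frac_anticorrelated=0.0,
        n_markers=0,
    )
    truth = em.generate_truth(cfg)
    counts, design = em.simulate_transcriptome(truth, cfg)
    # Poisson: variance ~ mean across genes
    mu = truth.count_baseline.to_numpy()
    sample = counts.to_numpy()[:, 0]
    big = mu > 100
    assert np.corrcoef(sample[big], mu[big])[0, 1] > 0.95
    # planted fold change recovered in the group means at large baselines
    cfg2 = SimulationConfig(n_genes=4000, seed=5, nb_dispersion=0.01,
                            size_factor_range=(1.0, 1.0))
    truth2 = em.generate_truth(cfg2)
    counts2, design2 = em.simulate_transcriptome(truth2, cfg2)
    sel = (truth2.count_baseline > 500) & truth2.transcript_fc["morula"].abs().between(1, 3)
    mor = counts2[design2.samples_of_stage("morula")].mean(axis=1)
    ooc = counts2[design2.samples_of_stage("oocyte")].mean(axis=1)
    est_lfc = np.log2(mor[sel] / ooc[sel])
    err = est_lfc - truth2.transcript_fc.loc[sel, "morula"]
    assert err.abs().median() < 0.25


def test_annotations_emit_233_complexes_with_bounded_sizes(small_dataset):
    complexes, pathways = simulate_annotations(small_dataset.truth, small_dataset.config)
    assert len(complexes) == 233
    sizes = [len(m) for m in complexes.values()]
    assert min(sizes) >= 2 and max(sizes) <= 20
    planted = set(small_dataset.truth.markers) & set(pathways["marker_pathway"])
    assert len(planted) >= 5


def test_marker_profiles_follow_the_ramp(small_dataset):
    truth = small_dataset.truth
    g = truth.markers[0]
    sign = truth.marker_sign[g]
    expected = sign * small_dataset.config.marker_effect * MARKER_RAMP
    assert np.allclose(truth.protein_fc.loc[g].to_numpy(), expected)


def test_external_measurements_rank_match_at_zero_noise():
    cfg = SimulationConfig(
        n_genes=100, seed=6, measurement_noise_sd=0.0, n_high_fidelity=37
    )
    truth = em.generate_truth(cfg)
    sets = simulate_external_measurements(truth, cfg)
    assert len(sets) == 37
    for ms in sets[:5]:
        profile = np.concatenate([[0.0], truth.protein_fc.loc[ms.protein].to_numpy()])
        rho = stats.spearmanr(ms.values.to_numpy(), profile).statistic
        assert rho == pytest.approx(1.0)


def test_too_many_measurement_sets_rejected():
    cfg = SimulationConfig(n_genes=60, seed=7, n_markers=5)
    truth = em.generate_truth(cfg)
    with pytest.raises(ConfigError):
        simulate_external_measurements(truth, cfg, n_sets=1000)


def test_planted_fraction_recovery_within_two_points():
    """Full-pipeline per-gene profile correlations recover the 7%/3% tails."""
    from embryomics.proteome import (
        batch_correct,
        filter_detected,
        fold_changes,
        quantile_normalize,
    )
    from embryomics.transcriptome import transcript_de
    from embryomics.datatypes import DEFAULT_STAGE_MAP

    corr, anti = [], []
    for seed in (11, 12):
        ds = em.simulate_dataset(SimulationConfig(n_genes=2000, seed=seed))
        pm, pdes = ds.protein_matrix, ds.protein_design
        corrected = batch_correct(quantile_normalize(filter_detected(pm, pdes)), pdes)
        pfc = fold_changes(corrected, pdes)
        tres = transcript_de(ds.count_matrix, ds.transcript_design)
        pairs = [
            (ts, ps)
            for ps in pfc.columns
            for ts in DEFAULT_STAGE_MAP.get(ps, ())
            if ts in tres.lfc.columns
        ]
        common = pfc.dropna().index.intersection(tres.lfc.index)
        X = pfc.loc[common, [ps for _, ps in pairs]].to_numpy()
        Y = tres.lfc.loc[common, [ts for ts, _ in pairs]].to_numpy()
        rhos = np.array(
            [stats.spearmanr(x, y).statistic for x, y in zip(X, Y)]
        )
        corr.append(100 * (rhos >= 0.8).mean())
        anti.append(100 * (rhos <= -0.8).mean())
    assert abs(np.mean(corr) - 7.0) <= 2.0
    assert abs(np.mean(anti) - 3.0) <= 2.0
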