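"""Synthetic matched proteome/transcriptome datasets with known ground truth.

The generator emulates the *processed* outputs of a SILAC + RNA-seq study of
mouse preimplantation development: a proteome of log2 L/H ratios over
7 stages x 3 replicates (with one blastocyst replicate dropped for quality
control, 20 samples), and a transcriptome of negative-binomial read counts
over 8 stages x 2 replicates (the 2-cell stage split into early/late).

Ground truth is planted at the level of fold-change profiles relative to the
oocyte.  A configurable fraction of genes is *coupled*: the protein profile
follows (or, for anticorrelated genes, mirrors) the transcript profile with a
developmental delay and with coupling weights that ramp up toward the
blastocyst -- the mechanism by which transcript->protein concordance increases
as free ribosomes replace cytoplasmic lattices at the morula stage.
Uncoupled genes draw independent protein and transcript profiles from small
archetype libraries (monotone drift, blastocyst surge/drop, early peak, ...).

Everything is deterministic given ``SimulationConfig.seed``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .datatypes import (
    DEFAULT_STAGE_MAP,
    PROTEIN_STAGES,
    TRANSCRIPT_STAGES,
    CognateMap,
    StageDesign,
)


class ConfigError(ValueError):
    """Raised for inconsistent simulation configurations."""


# ---------------------------------------------------------------------------
# archetype libraries (fold-change shapes over the non-reference stages)
# ---------------------------------------------------------------------------

#: Protein fold-change shapes over (1cell, 2cell, 4cell, 8cell, morula,
#: blastocyst): steady increase/decrease, an early-mid peak/dip, and a mild
#: drift ending in a sharp morula->blastocyst crash/surge -- the cluster
#: morphologies seen in preimplantation proteomes, chosen mutually separated
#: after z-scoring so profile clusters are well defined.
PROTEIN_ARCHETYPES = np.array(
    [
        [0.17, 0.33, 0.50, 0.67, 0.83, 1.00],
        [-0.17, -0.33, -0.50, -0.67, -0.83, -1.00],
        [0.30, 0.90, 1.00, 0.65, 0.10, -0.30],
        [-0.30, -0.90, -1.00, -0.65, -0.10, 0.30],
        [0.05, 0.15, 0.20, 0.25, 0.30, -1.00],
        [-0.05, -0.15, -0.20, -0.25, -0.30, 1.00],
    ]
)

#: Transcript fold-change shapes over (1cell, 2cell_early, 2cell_late, 4cell,
#: 8cell, morula, blastocyst): maternal decay (early/late), genome activation
#: (early/late), a transient 2-cell wave, a blastocyst surge and a mid peak.
#: Plateaus keep a slight slope so that stage ranks stay well defined.
TRANSCRIPT_ARCHETYPES = np.array(
    [
        [-0.10, -0.60, -0.85, -0.92, -0.96, -0.98, -1.00],
        [0.00, -0.05, -0.20, -0.50, -0.80, -0.95, -1.00],
        [0.10, 0.60, 0.85, 0.92, 0.96, 0.98, 1.00],
        [0.00, 0.05, 0.15, 0.45, 0.75, 0.95, 1.00],
        [0.30, 1.00, 0.60, 0.15, 0.00, -0.20, -0.30],
        [0.00, 0.02, 0.05, 0.12, 0.25, 0.55, 1.00],
        [0.00, 0.10, 0.40, 1.00, 0.60, 0.10, -0.05],
        [-0.30, -1.00, -0.60, -0.15, 0.00, 0.20, 0.30],
        [0.00, -0.10, -0.40, -1.00, -0.60, -0.10, 0.05],
    ]
)

#: Draw probabilities for the transcript archetypes: transient waves (the
#: 2-cell genome-activation burst / transient repression and the 8-cell
#: 4-cell peak/dip) dominate the early and mid differential calls, as around EGA
#: and compaction.
TRANSCRIPT_ARCHETYPE_WEIGHTS = (0.10, 0.10, 0.10, 0.10, 0.16, 0.10, 0.09, 0.16, 0.09)

#: Archetypes of genes under sustained transcriptional programs (gradual
#: maternal decay and genome activation); the planted coupled genes are drawn
#: from these smooth shapes, whose stage ranks survive the coupling delay.
COUPLED_TRANSCRIPT_ARCHETYPES = (0, 1, 2, 3)

#: Early/late marker shape: flat through the 2-cell stage, partial effect at
#: the 4-cell stage (the transitional stage), full effect afterwards.
MARKER_RAMP = np.array([0.0, 0.0, 0.7, 1.0, 1.0, 1.0])


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic dataset.

    Defaults mirror the design of the emulated study: 7 proteome stages in
    triplicate minus one dropped blastocyst replicate (20 samples), 8
    transcriptome stages in duplicate, 7%/3% planted positive/negative
    transcript-protein coupling, 233 protein complexes and 37 external
    validation measurement sets.
    """

    n_genes: int = 2000
    protein_stages: tuple[str, ...] = PROTEIN_STAGES
    transcript_stages: tuple[str, ...] = TRANSCRIPT_STAGES
    protein_reps: int = 3
    transcript_reps: int = 2
    drop_blastocyst_rep: bool = True
    # log2 L/H baseline distribution and noise
    baseline_mean: float = 0.0
    baseline_sd: float = 1.5
    batch_sd: float = 0.3
    noise_sd: float = 0.25
    # abundance-dependent missingness: P(detect) = logistic(slope * (x - midpoint))
    detect_midpoint: float = -3.5
    detect_slope: float = 1.0
    # study-wide per-protein detectability (proteome depth)
    detect_prob_overall: float = 0.8
    # transcript counts
    nb_dispersion: float = 0.02
    count_log_mean: float = math.log(300.0)
    count_log_sd: float = 1.2
    size_factor_range: tuple[float, float] = (2.0 / 3.0, 1.5)
    # planted coupling
    frac_correlated: float = 0.07
    frac_anticorrelated: float = 0.03
    coupling_delay: int = 1
    delay_profile: tuple[float, ...] = (0.70, 0.78, 0.85, 0.90, 0.95, 1.00)
    coupling_noise_sd: float = 0.10
    # weak pervasive transcript->protein coupling of the remaining genes
    # (per-gene strength drawn uniformly from this range); the correlated /
    # anticorrelated classes are the strong tails on top of this background
    background_coupling: tuple[float, float] = (0.0, 0.45)
    # fold-change amplitudes (log2 units), lognormal across genes; protein
    # changes are damped relative to transcript changes (maternal stores and
    # steady basal translation buffer the proteome)
    amplitude_log_mean: float = math.log(2.5)
    amplitude_log_sd: float = 0.6
    protein_amplitude_log_mean: float = math.log(1.4)
    protein_amplitude_log_sd: float = 0.5
    profile_scale: float = 1.0
    # uncoupled profiles mix an archetype with idiosyncratic per-stage shape
    # noise; purity is drawn per gene from this range (1 = pure archetype)
    archetype_purity: tuple[float, float] = (0.0, 0.6)
    shape_noise_sd: float = 0.55
    # serial correlation (AR(1)) of the idiosyncratic shape component along
    # the stage axis: transcriptional programs drift gradually, while protein
    # turnover buffers stage-to-stage persistence
    transcript_shape_phi: float = 0.55
    protein_shape_phi: float = 0.10
    # planted early/late markers
    n_markers: int = 40
    marker_effect: float = 3.5
    marker_baseline_mean: float = 3.0
    marker_baseline_sd: float = 0.4
    # annotations
    n_complexes: int = 233
    complex_size_range: tuple[int, int] = (2, 20)
    n_pathways: int = 20
    pathway_size_range: tuple[int, int] = (10, 60)
    # external validation measurements
    n_measurement_sets: int = 37
    n_high_fidelity: int = 14
    measurement_noise_sd: float = 0.25
    measurement_noise_sd_low: float = 2.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes <= 0:
            raise ConfigError("n_genes must be positive")
        for name in ("protein_stages", "transcript_stages"):
            stages = getattr(self, name)
            if len(stages) == 0:
                raise ConfigError(f"{name} is empty")
            if len(set(stages)) != len(stages):
                raise ConfigError(f"{name} contains duplicates")
        if self.frac_correlated < 0 or self.frac_anticorrelated < 0:
            raise ConfigError("coupling fractions must be nonnegative")
        if self.frac_correlated + self.frac_anticorrelated > 1:
            raise ConfigError("frac_correlated + frac_anticorrelated must be <= 1")
        for name in ("batch_sd", "noise_sd", "nb_dispersion", "coupling_noise_sd",
                     "measurement_noise_sd", "measurement_noise_sd_low"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if not 0 <= self.detect_prob_overall <= 1:
            raise ConfigError("detect_prob_overall must be in [0, 1]")
        if self.protein_reps < 1 or self.transcript_reps < 1:
            raise ConfigError("replicate counts must be >= 1")
        if len(self.delay_profile) != len(self.protein_stages) - 1:
            raise ConfigError("delay_profile needs one weight per non-reference protein stage")
        if self.coupling_delay < 0:
            raise ConfigError("coupling_delay must be >= 0")
        lo, hi = self.archetype_purity
        if not (0 <= lo <= hi <= 1):
            raise ConfigError("archetype_purity must satisfy 0 <= lo <= hi <= 1")
        if self.n_markers < 0:
            raise ConfigError("n_markers must be >= 0")

    def with_(self, **kwargs) -> "SimulationConfig":
        return replace(self, **kwargs)


@dataclass
class SyntheticTruth:
    """Planted ground truth for one simulated dataset."""

    genes: pd.Index
    coupling_class: pd.Series  # 'correlated' | 'anticorrelated' | 'uncoupled'
    transcript_fc: pd.DataFrame  # genes x non-reference transcript stages (log2)
    protein_fc: pd.DataFrame  # genes x non-reference protein stages (log2)
    protein_archetype: pd.Series  # archetype id; -1 for coupled genes
    transcript_archetype: pd.Series
    baseline_log2_lh: pd.Series
    count_baseline: pd.Series
    batch_offsets: dict[str, float]
    markers: pd.Index
    marker_sign: pd.Series
    detection_prob: pd.Series  # per-protein study-wide detectability
    detected_overall: pd.Index  # proteins detected anywhere in the study
    complexes: dict[str, list[str]]

    def marker_set(self) -> set[str]:
        return set(self.markers)


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stream])


def _ar1_noise(
    rng: np.random.Generator, n: int, n_stages: int, sd: float, phi: float
) -> np.ndarray:
    """Stationary-scale AR(1) drift along the stage axis (per-stage sd ~ ``sd``)."""
    innov_sd = sd * math.sqrt(max(1.0 - phi**2, 1e-12)) if abs(phi) < 1 else sd
    x = np.empty((n, n_stages))
    prev = rng.normal(0.0, sd, n)
    for s in range(n_stages):
        prev = phi * prev + rng.normal(0.0, innov_sd, n)
        x[:, s] = prev
    return x


def _protein_to_transcript_index(config: SimulationConfig) -> list[int]:
    """Index of the primary cognate transcript stage for each protein stage."""
    tstages = list(config.transcript_stages)
    idx = []
    for ps in config.protein_stages:
        mapped = DEFAULT_STAGE_MAP.get(ps, (ps,))
        primary = mapped[-1] if mapped[-1] in tstages else ps
        if primary not in tstages:
            raise ConfigError(f"protein stage {ps!r} has no transcript counterpart")
        idx.append(tstages.index(primary))
    return idx


def generate_truth(config: SimulationConfig) -> SyntheticTruth:
    """Draw the planted ground truth for one dataset.

    Coupling-class counts equal the rounded planted fractions exactly; the
    protein profile of a coupled gene is ``sign * delay_profile[j] *
    transcript_fc[delayed stage]`` plus independent Gaussian noise.
    """
    config.validate()
    n = config.n_genes
    genes = pd.Index([f"g{i:05d}" for i in range(n)], name="gene")

    rng = _rng(config, 0)

    # coupling classes with exact rounded counts
    n_corr = round(config.frac_correlated * n)
    n_anti = round(config.frac_anticorrelated * n)
    classes = np.array(["uncoupled"] * n, dtype=object)
    order = rng.permutation(n)
    classes[order[:n_corr]] = "correlated"
    classes[order[n_corr : n_corr + n_anti]] = "anticorrelated"
    coupling = pd.Series(classes, index=genes, name="coupling_class")

    # amplitudes, archetypes and per-gene shape purity
    coupled = coupling != "uncoupled"
    t_amp = rng.lognormal(config.amplitude_log_mean, config.amplitude_log_sd, n)
    p_amp = rng.lognormal(
        config.protein_amplitude_log_mean, config.protein_amplitude_log_sd, n
    )
    t_arch = rng.choice(
        TRANSCRIPT_ARCHETYPES.shape[0], size=n, p=TRANSCRIPT_ARCHETYPE_WEIGHTS
    )
    t_arch[coupled.values] = rng.choice(
        COUPLED_TRANSCRIPT_ARCHETYPES, size=int(coupled.sum())
    )
    p_arch = rng.integers(0, PROTEIN_ARCHETYPES.shape[0], n)
    lo_pur, hi_pur = config.archetype_purity
    t_purity = rng.uniform(lo_pur, hi_pur, n)
    p_purity = rng.uniform(lo_pur, hi_pur, n)
    # coupled transcripts follow their archetype exactly (sustained programs)
    t_purity[coupled.values] = 1.0

    t_cols = [s for s in config.transcript_stages if s != config.transcript_stages[0]]
    p_cols = [s for s in config.protein_stages if s != config.protein_stages[0]]

    t_shape = t_purity[:, None] * TRANSCRIPT_ARCHETYPES[t_arch] + (
        1.0 - t_purity[:, None]
    ) * _ar1_noise(rng, n, len(t_cols), config.shape_noise_sd, config.transcript_shape_phi)
    transcript_fc = t_shape * t_amp[:, None] * config.profile_scale

    # protein profiles: uncoupled genes draw from the protein archetype
    # library (with the same purity mixing); coupled genes track the
    # (delayed, ramp-weighted) transcript profile with the class sign.
    p_shape = p_purity[:, None] * PROTEIN_ARCHETYPES[p_arch] + (
        1.0 - p_purity[:, None]
    ) * _ar1_noise(rng, n, len(p_cols), config.shape_noise_sd, config.protein_shape_phi)
    own = p_shape * p_amp[:, None] * config.profile_scale
    p2t = _protein_to_transcript_index(config)  # per protein stage incl. reference
    weights = np.asarray(config.delay_profile)
    sign = np.where(coupling == "anticorrelated", -1.0, 1.0)
    # transcript fold change indexed by transcript stage position (0 = reference -> 0)
    full_t = np.concatenate([np.zeros((n, 1)), transcript_fc], axis=1)
    tracked = np.empty((n, len(p_cols)))
    for j, _stage in enumerate(p_cols):
        src = max(p2t[j + 1] - config.coupling_delay, 0)
        tracked[:, j] = weights[j] * full_t[:, src]
    # uncoupled genes: independent profile blended with a weak tracked
    # component; coupled genes: fully tracked with the class sign.
    bg = rng.uniform(*config.background_coupling, n)
    protein_fc = np.sqrt(1.0 - bg[:, None] ** 2) * own + bg[:, None] * tracked
    protein_fc[coupled.values] = (sign[:, None] * tracked)[coupled.values]
    if config.coupling_noise_sd > 0 and coupled.any():
        cn = _rng(config, 1).normal(
            0.0, config.coupling_noise_sd, (int(coupled.sum()), len(p_cols))
        )
        protein_fc[coupled.values] += cn
    p_arch_series = pd.Series(np.where(coupled, -1, p_arch), index=genes, name="protein_archetype")

    # baselines
    rng2 = _rng(config, 2)
    baseline = rng2.normal(config.baseline_mean, config.baseline_sd, n)
    count_base = rng2.lognormal(config.count_log_mean, config.count_log_sd, n)

    # batch offsets per proteome replicate
    batch = {
        f"rep{r + 1}": float(off)
        for r, off in enumerate(rng2.normal(0.0, config.batch_sd, config.protein_reps))
    }

    # planted early/late markers: abundant, otherwise-flat uncoupled genes
    uncoupled_idx = np.flatnonzero(~coupled.values)
    if config.n_markers > len(uncoupled_idx):
        raise ConfigError("n_markers exceeds the number of uncoupled genes")
    marker_pos = rng2.choice(uncoupled_idx, size=config.n_markers, replace=False)
    marker_sign = rng2.choice([-1.0, 1.0], size=config.n_markers)
    baseline[marker_pos] = rng2.normal(
        config.marker_baseline_mean, config.marker_baseline_sd, config.n_markers
    )
    protein_fc[marker_pos] = (
        marker_sign[:, None] * config.marker_effect * MARKER_RAMP[None, : len(p_cols)]
    )
    p_arch_series.iloc[marker_pos] = -2  # markers are their own archetype
    markers = genes[np.sort(marker_pos)]
    sign_series = pd.Series(
        marker_sign[np.argsort(marker_pos)], index=markers, name="marker_sign"
    )

    # study-wide detectability and the realized detected proteome
    detection_prob = pd.Series(config.detect_prob_overall, index=genes, name="detection_prob")
    detection_prob.loc[markers] = max(config.detect_prob_overall, 0.99)
    detected = rng2.random(n) < detection_prob.values
    detected_overall = genes[detected]

    # protein complexes over the gene universe
    rng3 = _rng(config, 3)
    lo, hi = config.complex_size_range
    complexes: dict[str, list[str]] = {}
    for c in range(config.n_complexes):
        size = int(rng3.integers(lo, hi + 1))
        members = rng3.choice(n, size=size, replace=False)
        complexes[f"complex{c + 1:04d}"] = [genes[i] for i in sorted(members)]

    return SyntheticTruth(
        genes=genes,
        coupling_class=coupling,
        transcript_fc=pd.DataFrame(transcript_fc, index=genes, columns=t_cols),
        protein_fc=pd.DataFrame(protein_fc, index=genes, columns=p_cols),
        protein_archetype=p_arch_series,
        transcript_archetype=pd.Series(t_arch, index=genes, name="transcript_archetype"),
        baseline_log2_lh=pd.Series(baseline, index=genes, name="baseline_log2_lh"),
        count_baseline=pd.Series(count_base, index=genes, name="count_baseline"),
        batch_offsets=batch,
        markers=markers,
        marker_sign=sign_series,
        detection_prob=detection_prob,
        detected_overall=detected_overall,
        complexes=complexes,
    )


def proteome_design(config: SimulationConfig) -> StageDesign:
    samples: list[str] = []
    for stage in config.protein_stages:
        for r in range(1, config.protein_reps + 1):
            if (
                config.drop_blastocyst_rep
                and stage == config.protein_stages[-1]
                and r == config.protein_reps
            ):
                continue  # QC-dropped blastocyst replicate
            samples.append(f"{stage}_rep{r}")
    return StageDesign.from_sample_names(
        samples, stage_order=config.protein_stages, reference=config.protein_stages[0]
    )


def transcriptome_design(config: SimulationConfig) -> StageDesign:
    samples = [
        f"{stage}_rep{r}"
        for stage in config.transcript_stages
        for r in range(1, config.transcript_reps + 1)
    ]
    return StageDesign.from_sample_names(
        samples, stage_order=config.transcript_stages, reference=config.transcript_stages[0]
    )


def simulate_proteome(
    truth: SyntheticTruth, config: SimulationConfig
) -> tuple[pd.DataFrame, StageDesign]:
    """Simulate the log2 L/H matrix (proteins x samples) with missingness.

    log2 L/H of gene g in sample (stage, rep) = baseline_g + FC_g(stage) +
    batch_rep + noise; the value is then censored with probability
    ``1 - logistic(detect_slope * (value - detect_midpoint))``, emulating the
    abundance-dependent detection limit of MS.  Only proteins detected
    study-wide (``truth.detected_overall``) appear in the matrix.
    """
    design = proteome_design(config)
    rng = _rng(config, 4)
    genes = truth.detected_overall
    fc = pd.concat(
        [
            pd.Series(0.0, index=truth.genes, name=config.protein_stages[0]),
            truth.protein_fc,
        ],
        axis=1,
    ).loc[genes]
    values = {}
    for sample in design.samples:
        stage = design.stage_of[sample]
        rep = design.replicate_of[sample]
        x = (
            truth.baseline_log2_lh.loc[genes].values
            + fc[stage].values
            + truth.batch_offsets[rep]
            + rng.normal(0.0, config.noise_sd, len(genes))
        )
        with np.errstate(over="ignore"):
            p_detect = 1.0 / (1.0 + np.exp(-config.detect_slope * (x - config.detect_midpoint)))
        miss = rng.random(len(genes)) >= p_detect
        x = x.astype(float)
        x[miss] = np.nan
        values[sample] = x
    matrix = pd.DataFrame(values, index=genes)
    return matrix, design


def simulate_transcriptome(
    truth: SyntheticTruth, config: SimulationConfig
) -> tuple[pd.DataFrame, StageDesign]:
    """Simulate NB counts: mean = sf_sample * baseline_g * 2^FC_g(stage)."""
    design = transcriptome_design(config)
    rng = _rng(config, 5)
    lo, hi = config.size_factor_range
    sf = np.exp(rng.uniform(math.log(lo), math.log(hi), len(design.samples)))
    fc = pd.concat(
        [
            pd.Series(0.0, index=truth.genes, name=config.transcript_stages[0]),
            truth.transcript_fc,
        ],
        axis=1,
    )
    alpha = config.nb_dispersion
    counts = {}
    for j, sample in enumerate(design.samples):
        stage = design.stage_of[sample]
        mu = sf[j] * truth.count_baseline.values * np.exp2(fc[stage].values)
        if alpha == 0:
            c = rng.poisson(mu)
        else:
            shape = 1.0 / alpha
            lam = rng.gamma(shape, alpha * mu)
            c = rng.poisson(lam)
        counts[sample] = c
    return pd.DataFrame(counts, index=truth.genes), design


def simulate_annotations(
    truth: SyntheticTruth, config: SimulationConfig
) -> tuple[dict[str, list[str]], dict[str, list[str]]]:
    """Protein-complex catalog and pathway gene sets.

    One pathway (``marker_pathway``) is enriched in the planted marker set by
    construction; the remaining pathways are random draws from the gene
    universe.
    """
    rng = _rng(config, 6)
    n = len(truth.genes)
    pathways: dict[str, list[str]] = {}
    n_marker_members = min(20, len(truth.markers))
    picked = rng.choice(len(truth.markers), size=n_marker_members, replace=False)
    members = {truth.markers[i] for i in picked}
    n_bg = int(rng.integers(*config.pathway_size_range))
    members |= {truth.genes[i] for i in rng.choice(n, size=n_bg, replace=False)}
    pathways["marker_pathway"] = sorted(members)
    for k in range(config.n_pathways - 1):
        size = int(rng.integers(*config.pathway_size_range))
        idx = rng.choice(n, size=size, replace=False)
        pathways[f"pathway{k + 1:03d}"] = [truth.genes[i] for i in sorted(idx)]
    return dict(truth.complexes), pathways


@dataclass
class MeasurementSet:
    """One external (enzymatic/immunofluorescence-style) stage profile."""

    name: str
    protein: str
    values: pd.Series  # indexed by stage, arbitrary monotone scale
    noise_sd: float
    high_fidelity: bool


def simulate_external_measurements(
    truth: SyntheticTruth, config: SimulationConfig, n_sets: int | None = None
) -> list[MeasurementSet]:
    """Draw external measurement sets for validation.

    Each set is a protein's true stage profile plus Gaussian noise, pushed
    through a random increasing transform (scale/shift/exp) to mimic an
    arbitrary assay scale.  ``n_high_fidelity`` sets use low noise.
    """
    n_sets = config.n_measurement_sets if n_sets is None else n_sets
    pool = truth.detected_overall
    if n_sets > len(pool):
        raise ConfigError("n_sets exceeds the number of detected proteins")
    rng = _rng(config, 7)
    chosen = rng.choice(len(pool), size=n_sets, replace=False)
    stages = list(config.protein_stages)
    sets: list[MeasurementSet] = []
    for i, gi in enumerate(chosen):
        gene = pool[gi]
        profile = np.concatenate(
            [[0.0], truth.protein_fc.loc[gene].values]
        ) + truth.baseline_log2_lh.loc[gene]
        hi_fi = i < config.n_high_fidelity
        sd = config.measurement_noise_sd if hi_fi else config.measurement_noise_sd_low
        noisy = profile + rng.normal(0.0, sd, len(stages))
        a = rng.uniform(0.5, 2.0)
        b = rng.normal(0.0, 1.0)
        transformed = np.exp(a * (noisy - noisy.mean()) / max(noisy.std(), 1e-9)) + b
        sets.append(
            MeasurementSet(
                name=f"set{i + 1:02d}",
                protein=gene,
                values=pd.Series(transformed, index=stages),
                noise_sd=sd,
                high_fidelity=hi_fi,
            )
        )
    return sets


@dataclass
class SyntheticDataset:
    """Bundle of everything one simulation run produces."""

    config: SimulationConfig
    truth: SyntheticTruth
    protein_matrix: pd.DataFrame
    protein_design: StageDesign
    count_matrix: pd.DataFrame
    transcript_design: StageDesign
    cognate_map: CognateMap
    complexes: dict[str, list[str]]
    pathways: dict[str, list[str]]
    measurements: list[MeasurementSet]


def simulate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Run the full generator: truth, both matrices, annotations, validation sets."""
    truth = generate_truth(config)
    protein_matrix, protein_design = simulate_proteome(truth, config)
    count_matrix, transcript_design = simulate_transcriptome(truth, config)
    complexes, pathways = simulate_annotations(truth, config)
    measurements = simulate_external_measurements(truth, config)
    return SyntheticDataset(
        config=config,
        truth=truth,
        protein_matrix=protein_matrix,
        protein_design=protein_design,
        count_matrix=count_matrix,
        transcript_design=transcript_design,
        cognate_map=CognateMap.identity(truth.genes),
        complexes=complexes,
        pathways=pathways,
        measurements=measurements,
    )
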