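"""Seeded generators for every input the pipeline consumes.

The generators emulate the statistical structure of the study designs the
pipeline targets, with planted ground truth exposed for tests:

* bulk tumor cohorts where latent factors (stemness, neural infiltration,
  CRE activity, ...) co-vary with a configurable correlation matrix, drive
  planted gene programs and (optionally) survival;
* paired sphere/adherent expression datasets with TF target programs
  up-shifted in spheres of chosen datasets;
* single-cell negative-binomial counts with a CSC subpopulation that
  co-activates pluripotency and mitochondrial programs through a shared
  per-cell latent intensity;
* limiting-dilution plates (see :func:`tmescreen.dilution.simulate_assay`).

Every generator is a pure function of its spec plus seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import ExpressionMatrix, GeneSetCollection, SurvivalTable

DEFAULT_NOISE_SD = 1.0
DEFAULT_BASELINE_MEAN = 7.0  # log2-scale expression baseline
DEFAULT_CENSORING_RATE = 0.3


def gene_universe(n_genes: int, prefix: str = "G") -> list[str]:
    width = max(4, len(str(n_genes)))
    return [f"{prefix}{i:0{width}d}" for i in range(n_genes)]


@dataclass
class PlantedProgram:
    """A gene program driven by a latent factor or a binary carrier group.

    Exactly one of ``factor`` (continuous loading on a named latent factor)
    or ``carrier_fraction`` (that fraction of samples carries a flat
    ``amplitude`` up-shift) must be set. Amplitudes are in noise-SD units.
    """

    name: str
    genes: list[str]
    amplitude: float
    factor: str | None = None
    carrier_fraction: float | None = None

    def __post_init__(self) -> None:
        if (self.factor is None) == (self.carrier_fraction is None):
            raise ValueError("set exactly one of factor / carrier_fraction")
        if self.carrier_fraction is not None and not 0 < self.carrier_fraction < 1:
            raise ValueError("carrier_fraction must lie in (0, 1)")
        if not np.isfinite(self.amplitude):
            raise ValueError("amplitude must be finite")


@dataclass
class GeneratorSpec:
    n_genes: int = 1000
    n_samples: int = 200
    factor_names: list[str] = field(default_factory=lambda: ["stemness"])
    factor_correlation: np.ndarray | None = None  # defaults to identity
    programs: list[PlantedProgram] = field(default_factory=list)
    noise_sd: float = DEFAULT_NOISE_SD
    baseline_mean: float = DEFAULT_BASELINE_MEAN
    survival_betas: dict[str, float] = field(default_factory=dict)
    survival_scale: float = 1.0
    censoring_rate: float = DEFAULT_CENSORING_RATE
    seed: int = 0

    def correlation(self) -> np.ndarray:
        k = len(self.factor_names)
        if self.factor_correlation is None:
            return np.eye(k)
        c = np.asarray(self.factor_correlation, dtype=float)
        if c.shape != (k, k) or not np.allclose(c, c.T):
            raise ValueError("factor correlation must be a symmetric k x k matrix")
        eigvals = np.linalg.eigvalsh(c)
        if eigvals.min() < -1e-10:
            raise ValueError("factor correlation matrix is not positive semi-definite")
        return c


@dataclass
class SyntheticCohort:
    matrix: ExpressionMatrix
    factors: pd.DataFrame  # samples x latent factors (the planted truth)
    carriers: dict[str, np.ndarray]  # program -> boolean carrier mask
    survival: SurvivalTable | None = None


def make_cohort(spec: GeneratorSpec) -> SyntheticCohort:
    """Draw one bulk cohort from a generator spec; fully seed-reproducible."""
    rng = np.random.default_rng(spec.seed)
    genes = gene_universe(spec.n_genes)
    samples = [f"S{i:04d}" for i in range(spec.n_samples)]
    corr = spec.correlation()
    chol = np.linalg.cholesky(corr + 1e-12 * np.eye(len(corr)))
    factors = rng.standard_normal((spec.n_samples, len(spec.factor_names))) @ chol.T
    factors_df = pd.DataFrame(factors, index=samples, columns=spec.factor_names)

    baseline = spec.baseline_mean + rng.standard_normal(spec.n_genes)
    values = baseline[:, None] + spec.noise_sd * rng.standard_normal(
        (spec.n_genes, spec.n_samples)
    )
    gene_index = {g: i for i, g in enumerate(genes)}
    carriers: dict[str, np.ndarray] = {}
    for prog in spec.programs:
        rows = [gene_index[g] for g in prog.genes if g in gene_index]
        if not rows:
            raise ValueError(f"program {prog.name!r} has no genes in the universe")
        if prog.factor is not None:
            if prog.factor not in spec.factor_names:
                raise ValueError(f"unknown factor {prog.factor!r}")
            signal = prog.amplitude * factors_df[prog.factor].to_numpy()
        else:
            mask = rng.random(spec.n_samples) < prog.carrier_fraction
            carriers[prog.name] = mask
            signal = prog.amplitude * mask.astype(float)
        values[np.ix_(rows, range(spec.n_samples))] += signal[None, :]

    survival = None
    if spec.survival_betas:
        log_hazard = np.zeros(spec.n_samples)
        for fname, beta in spec.survival_betas.items():
            log_hazard += beta * factors_df[fname].to_numpy()
        rate = np.exp(log_hazard) / spec.survival_scale
        t_event = rng.exponential(1.0 / rate)
        censored = rng.random(spec.n_samples) < spec.censoring_rate
        # censored subjects are observed a uniform fraction of the way to
        # their event, giving the requested marginal censoring rate exactly
        t_obs = np.where(censored, rng.random(spec.n_samples) * t_event, t_event)
        survival = SurvivalTable(
            patient_ids=samples, time=t_obs, event=(~censored).astype(int)
        )

    matrix = ExpressionMatrix(gene_ids=genes, sample_ids=samples, values=values)
    return SyntheticCohort(matrix=matrix, factors=factors_df, carriers=carriers, survival=survival)


# ---------------------------------------------------------------------------
# TF target collections and paired sphere/adherent datasets


def make_tf_targets(
    universe: list[str],
    n_factors: int = 50,
    targets_per_factor: int = 40,
    seed: int = 0,
    planted: dict[str, list[str]] | None = None,
) -> GeneSetCollection:
    """Random TF -> target-set collection over a gene universe.

    ``planted`` pins chosen factors to fixed target lists (the planted
    programs); the remaining factors draw targets uniformly at random.
    """
    rng = np.random.default_rng(seed)
    planted = planted or {}
    sets: dict[str, list[str]] = {}
    for name, genes in planted.items():
        sets[name] = list(genes)
    i = 0
    while len(sets) < n_factors:
        name = f"TF{i:02d}"
        i += 1
        if name in sets:
            continue
        sets[name] = list(rng.choice(universe, size=targets_per_factor, replace=False))
    return GeneSetCollection(sets=sets, category="tf_targets")


@dataclass
class PairedDatasets:
    datasets: list[tuple[ExpressionMatrix, list[str]]]
    truth: dict[str, list[int]]  # TF -> dataset indices where its targets are up


def make_pairs(
    n_datasets: int,
    tf_targets: GeneSetCollection,
    planted: dict[str, list[int]],
    amplitude: float = 1.5,
    n_genes: int = 1000,
    replicates: int = 1,
    noise_sd: float = 1.0,
    baseline_mean: float = DEFAULT_BASELINE_MEAN,
    seed: int = 0,
) -> PairedDatasets:
    """Paired sphere/adherent profiles with planted TF-target up-regulation.

    ``planted`` maps TF names (keys of ``tf_targets``) to the dataset
    indices whose sphere samples up-shift that TF's targets by
    ``amplitude`` noise-SD units.
    """
    for tf in planted:
        if tf not in tf_targets.sets:
            raise ValueError(f"unknown TF {tf!r}")
    rng = np.random.default_rng(seed)
    genes = gene_universe(n_genes)
    gene_index = {g: i for i, g in enumerate(genes)}
    datasets = []
    for d in range(n_datasets):
        n = 2 * replicates
        samples = [f"D{d:02d}_{k}" for k in range(n)]
        labels = ["sphere"] * replicates + ["adherent"] * replicates
        baseline = baseline_mean + rng.standard_normal(n_genes)
        values = baseline[:, None] + noise_sd * rng.standard_normal((n_genes, n))
        for tf, active_in in planted.items():
            if d not in active_in:
                continue
            rows = [gene_index[g] for g in tf_targets[tf] if g in gene_index]
            values[np.ix_(rows, range(replicates))] += amplitude
        datasets.append(
            (ExpressionMatrix(gene_ids=genes, sample_ids=samples, values=values), labels)
        )
    return PairedDatasets(datasets=datasets, truth={tf: list(ds) for tf, ds in planted.items()})


# ---------------------------------------------------------------------------
# Ready-made two-arm screen scenario


@dataclass
class ScreenScenario:
    cohort: SyntheticCohort
    pairs: PairedDatasets
    tf_targets: GeneSetCollection
    stemness_signature: list[str]
    planted_tfs: list[str]


def make_screen_scenario(
    n_genes: int = 1500,
    n_samples: int = 120,
    n_tfs: int = 50,
    n_planted: int = 5,
    targets_per_tf: int = 40,
    n_datasets: int = 17,
    n_active_datasets: int = 10,
    cohort_amplitude: float = 0.8,
    sphere_amplitude: float = 1.5,
    null: bool = False,
    seed: int = 0,
) -> ScreenScenario:
    """Full synthetic two-arm screen with planted TME-responsive TFs.

    The planted TFs' target genes load on the cohort's stemness factor
    (arm A signal) and are up-shifted in spheres of ``n_active_datasets``
    datasets (arm B signal). ``null=True`` removes all planted structure
    while keeping sizes, for empirical false-positive-rate checks.
    """
    rng = np.random.default_rng(seed)
    genes = gene_universe(n_genes)
    planted_tfs = [f"TF{i:02d}" for i in range(n_planted)]
    # disjoint target blocks for planted TFs, then the stemness signature
    blocks = rng.choice(n_genes, size=n_planted * targets_per_tf + 50, replace=False)
    planted_sets = {
        tf: [genes[j] for j in blocks[i * targets_per_tf : (i + 1) * targets_per_tf]]
        for i, tf in enumerate(planted_tfs)
    }
    signature = [genes[j] for j in blocks[n_planted * targets_per_tf :]]
    tf_targets = make_tf_targets(
        genes, n_factors=n_tfs, targets_per_factor=targets_per_tf,
        seed=int(rng.integers(2**31 - 1)), planted=planted_sets,
    )

    amp = 0.0 if null else cohort_amplitude
    programs = [
        PlantedProgram("stemness_signature", signature, 0.0 if null else 1.0, factor="stemness")
    ] + [
        PlantedProgram(f"targets_{tf}", planted_sets[tf], amp, factor="stemness")
        for tf in planted_tfs
    ]
    cohort = make_cohort(
        GeneratorSpec(
            n_genes=n_genes,
            n_samples=n_samples,
            factor_names=["stemness"],
            programs=programs,
            seed=int(rng.integers(2**31 - 1)),
        )
    )
    active: dict[str, list[int]] = {}
    if not null:
        for tf in planted_tfs:
            active[tf] = list(
                rng.choice(n_datasets, size=n_active_datasets, replace=False)
            )
    pairs = make_pairs(
        n_datasets,
        tf_targets,
        planted=active,
        amplitude=sphere_amplitude,
        n_genes=n_genes,
        seed=int(rng.integers(2**31 - 1)),
    )
    return ScreenScenario(
        cohort=cohort,
        pairs=pairs,
        tf_targets=tf_targets,
        stemness_signature=signature,
        planted_tfs=[] if null else planted_tfs,
    )


# ---------------------------------------------------------------------------
# Multi-cohort compendium for the correlation landscape


@dataclass
class Compendium:
    cohorts: list[SyntheticCohort]
    markers: GeneSetCollection
    positive_cohorts: list[int]  # indices with the planted neural-CRE correlation
    positive_stem_cohorts: list[int]  # indices with the planted CRE-stemness correlation
    rho: float


def make_compendium(
    n_cohorts: int = 32,
    n_positive: int = 24,
    rho: float = 0.45,
    n_samples: int = 300,
    n_genes: int = 2000,
    marker_size: int = 30,
    amplitude: float = 2.0,
    n_positive_stem: int = 0,
    rho_stem: float | None = None,
    seed: int = 0,
) -> Compendium:
    """Multi-cohort bulk compendium with latent signal correlations.

    The first ``n_positive`` cohorts plant a neural-CRE factor correlation
    of ``rho``; the first ``n_positive_stem`` cohorts additionally plant a
    CRE-stemness correlation of ``rho_stem`` (default: same as ``rho``).
    Remaining cohorts are null for the respective pair. Marker genes load
    on their factor at ``amplitude`` noise-SD units, the specificity
    expected of curated cell-type markers.
    """
    rng = np.random.default_rng(seed)
    if rho_stem is None:
        rho_stem = rho
    genes = gene_universe(n_genes)
    picks = rng.choice(n_genes, size=3 * marker_size, replace=False)
    marker_sets = {
        "neural": [genes[i] for i in picks[:marker_size]],
        "cre": [genes[i] for i in picks[marker_size : 2 * marker_size]],
        "stemness": [genes[i] for i in picks[2 * marker_size :]],
    }
    markers = GeneSetCollection(sets=marker_sets, category="cell_markers")
    cohorts = []
    for c in range(n_cohorts):
        r = rho if c < n_positive else 0.0
        rs = rho_stem if c < n_positive_stem else 0.0
        corr = np.array([[1.0, r, 0.0], [r, 1.0, rs], [0.0, rs, 1.0]])
        spec = GeneratorSpec(
            n_genes=n_genes,
            n_samples=n_samples,
            factor_names=["neural", "cre", "stemness"],
            factor_correlation=corr,
            programs=[
                PlantedProgram("neural", marker_sets["neural"], amplitude, factor="neural"),
                PlantedProgram("cre", marker_sets["cre"], amplitude, factor="cre"),
                PlantedProgram("stemness", marker_sets["stemness"], amplitude, factor="stemness"),
            ],
            seed=int(rng.integers(2**31 - 1)),
        )
        cohorts.append(make_cohort(spec))
    return Compendium(
        cohorts=cohorts,
        markers=markers,
        positive_cohorts=list(range(n_positive)),
        positive_stem_cohorts=list(range(n_positive_stem)),
        rho=rho,
    )


# ---------------------------------------------------------------------------
# Single-cell counts with a coordinated CSC subpopulation


@dataclass
class SingleCellTruth:
    matrix: ExpressionMatrix
    labels: pd.Series  # planted CSC / non-CSC truth
    programs: GeneSetCollection  # esc / pluripotency / mitochondrial sets
    marker_genes: list[str]


def make_single_cells(
    n_cells: int = 1000,
    csc_fraction: float = 0.2,
    coupling: float = 0.7,
    shift: float = 1.0,
    n_genes: int = 600,
    program_size: int = 40,
    dispersion: float = 0.5,
    library_sd: float = 0.3,
    seed: int = 0,
) -> SingleCellTruth:
    """Negative-binomial single-cell counts with a planted CSC population.

    CSC cells up-shift the ESC program by ``shift`` log-units and share a
    per-cell latent intensity u ~ N(0,1) that multiplies both the
    pluripotency and mitochondrial program means by exp(coupling * u),
    creating the coordinated activation the scoring stage should recover.
    Marker genes are strongly expressed in CSCs and near-silent elsewhere.
    """
    if not 0 < csc_fraction < 1:
        raise ValueError("csc_fraction must lie in (0, 1)")
    if 3 * program_size + 2 > n_genes:
        raise ValueError("n_genes too small for three disjoint programs plus markers")
    rng = np.random.default_rng(seed)
    genes = gene_universe(n_genes, prefix="SG")
    marker_genes = ["MARKER1", "MARKER2"]
    genes = marker_genes + genes[: n_genes - len(marker_genes)]
    cells = [f"C{i:04d}" for i in range(n_cells)]

    picks = rng.choice(
        np.arange(len(marker_genes), n_genes), size=3 * program_size, replace=False
    )
    programs = GeneSetCollection(
        sets={
            "esc": [genes[i] for i in picks[:program_size]],
            "pluripotency": [genes[i] for i in picks[program_size : 2 * program_size]],
            "mitochondrial": [genes[i] for i in picks[2 * program_size :]],
        },
        category="signature",
    )

    n_csc = int(round(csc_fraction * n_cells))
    is_csc = np.zeros(n_cells, dtype=bool)
    is_csc[rng.choice(n_cells, size=n_csc, replace=False)] = True

    base_log_mean = rng.normal(0.5, 1.0, size=n_genes)
    log_mu = np.tile(base_log_mean[:, None], (1, n_cells))
    gene_index = {g: i for i, g in enumerate(genes)}
    u = rng.standard_normal(n_cells)  # shared CSC coordination intensity
    csc_cols = np.where(is_csc)[0]
    for name, coupled in (("esc", False), ("pluripotency", True), ("mitochondrial", True)):
        rows = [gene_index[g] for g in programs[name]]
        eff = shift + (coupling * u[is_csc] if coupled else 0.0)
        log_mu[np.ix_(rows, csc_cols)] += eff
    for g in marker_genes:
        log_mu[gene_index[g]] = np.where(is_csc, np.log(6.0), np.log(0.05))

    libsize = rng.lognormal(0.0, library_sd, size=n_cells)
    mu = np.exp(log_mu) * libsize[None, :]
    r = 1.0 / dispersion
    counts = rng.negative_binomial(r, r / (r + mu))
    matrix = ExpressionMatrix(
        gene_ids=genes, sample_ids=cells, values=counts.astype(float), modality="single_cell"
    )
    labels = pd.Series(np.where(is_csc, "CSC", "non-CSC"), index=cells, name="truth")
    return SingleCellTruth(
        matrix=matrix, labels=labels, programs=programs, marker_genes=marker_genes
    )
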