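"""Forward-in-time simulation of linkage disequilibrium panels.

A chromosomal segment of dense biallelic loci evolves under neutral
Wright–Fisher random mating with recombination and symmetric mutation:
an initial population in Hardy–Weinberg and linkage equilibrium (every
allele a fair coin) is mated at random for 1000 generations at effective
size 500, then for 50 generations at size 100, approaching mutation–drift
equilibrium while building up LD over short map distances.

The segment is organised into bins of 10 consecutive loci; the last locus
of each bin is a (normally hidden) QTL, the other nine are candidate SNP
markers.  From the final generation one marker per bin is selected (allele
frequency closest to 0.5) and one QTL is selected the same way, and a 1 cM
analysis window is laid out so that the QTL sits exactly 0.3 cM to the
right of the window's first marker.  Study individuals are drawn from the
final population by one additional meiosis per gamete, and phenotypes are
simulated as an additive biallelic QTL effect plus Gaussian noise with a
prescribed fraction of phenotypic variance explained by the QTL.

Analysis coordinates are the nominal bin grid: marker j of the window sits
at j × spacing cM and the QTL at 0.3 cM.  Physical locus positions drive
recombination during the simulation; the bin grid is what the mapping
methods (and the precision measure) see.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Optional, Union

import numpy as np

__all__ = [
    "DEFAULT_MUTATION_RATE",
    "LocusMap",
    "PopulationHaplotypes",
    "DemographyConfig",
    "MarkerPanel",
    "StudyData",
    "SimulationError",
    "PanelConstructionError",
    "DegenerateQTLError",
    "init_population",
    "advance_generation",
    "run_history",
    "select_markers_and_qtl",
    "sample_study_population",
    "simulate_phenotypes",
    "simulate_study",
    "synthesize_ld_study",
]

logger = logging.getLogger(__name__)

#: per-locus, per-transmitted-gamete allele flip probability
DEFAULT_MUTATION_RATE = 2.5e-5

#: loci per bin; the last locus of each bin is a QTL
BIN_SIZE = 10


class SimulationError(RuntimeError):
    """Base class for simulator failures."""


class PanelConstructionError(SimulationError):
    """A required bin holds no segregating marker; caller should resimulate."""


class DegenerateQTLError(PanelConstructionError):
    """No eligible segregating QTL locus; caller should resimulate."""


RngLike = Union[int, np.random.Generator, None]


def _as_rng(rng: RngLike) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


@dataclass(frozen=True)
class LocusMap:
    """Uniformly spaced biallelic loci; every ``BIN_SIZE``-th locus is a QTL.

    Parameters
    ----------
    n_loci
        Total loci on the segment (markers + hidden QTL).
    spacing_cM
        Distance between adjacent loci in centimorgan (0.01, 0.005 or
        0.002 for marker spacings of 0.1, 0.05, 0.02 cM after bin-wise
        selection).
    """

    n_loci: int
    spacing_cM: float

    def __post_init__(self) -> None:
        if self.n_loci < 1:
            raise ValueError("n_loci must be positive")
        if self.spacing_cM <= 0:
            raise ValueError("spacing_cM must be positive")

    @property
    def positions_cM(self) -> np.ndarray:
        return np.arange(self.n_loci) * self.spacing_cM

    @property
    def is_qtl(self) -> np.ndarray:
        """Boolean flag per locus; the last locus of each 10-locus bin."""
        return np.arange(self.n_loci) % BIN_SIZE == BIN_SIZE - 1

    @property
    def qtl_indices(self) -> np.ndarray:
        return np.flatnonzero(self.is_qtl)

    @property
    def n_bins(self) -> int:
        return self.n_loci // BIN_SIZE

    @property
    def marker_spacing_cM(self) -> float:
        """Spacing of the bin grid, i.e. of the selected marker panel."""
        return BIN_SIZE * self.spacing_cM


@dataclass
class PopulationHaplotypes:
    """A diploid population as a (2 × size, n_loci) {0,1} haplotype matrix.

    Rows 2i and 2i+1 are the maternal and paternal haplotypes of
    individual i.
    """

    haplotypes: np.ndarray
    generation: int
    population_size: int

    def __post_init__(self) -> None:
        self.haplotypes = np.ascontiguousarray(self.haplotypes, dtype=np.uint8)
        if self.haplotypes.ndim != 2:
            raise ValueError("haplotypes must be 2-dimensional")
        if self.haplotypes.shape[0] != 2 * self.population_size:
            raise ValueError("row count must equal 2 x population_size")
        if self.haplotypes.size and self.haplotypes.max() > 1:
            raise ValueError("haplotype entries must be 0 or 1")

    @property
    def n_loci(self) -> int:
        return self.haplotypes.shape[1]

    def allele_frequencies(self) -> np.ndarray:
        """Frequency of allele 1 at every locus."""
        return self.haplotypes.mean(axis=0)


@dataclass(frozen=True)
class DemographyConfig:
    """Two-phase random-mating history with per-gamete mutation."""

    phase1_size: int = 500
    phase1_generations: int = 1000
    phase2_size: int = 100
    phase2_generations: int = 50
    mutation_rate: float = DEFAULT_MUTATION_RATE
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.phase1_size <= 0 or self.phase2_size <= 0:
            raise ValueError("population sizes must be positive")
        if self.phase1_generations < 0 or self.phase2_generations < 0:
            raise ValueError("generation counts must be non-negative")
        if not 0 <= self.mutation_rate < 1:
            raise ValueError("mutation_rate must be in [0, 1)")


@dataclass(frozen=True)
class MarkerPanel:
    """Selected marker/QTL loci and the 1 cM analysis window.

    ``marker_indices`` holds, per bin, the locus index of the selected
    marker (−1 where a bin is monomorphic and no selection was possible).
    ``window_positions_cM`` is the nominal analysis grid: marker j at
    j × marker_spacing_cM, QTL at ``qtl_position_cM`` (0.3 cM from the
    first window marker).
    """

    marker_indices: np.ndarray
    qtl_index: int
    qtl_bin: int
    window_marker_indices: np.ndarray
    window_positions_cM: np.ndarray
    qtl_position_cM: float
    marker_spacing_cM: float

    @property
    def n_window_markers(self) -> int:
        return len(self.window_marker_indices)


@dataclass
class StudyData:
    """Phased window haplotypes, phenotypes and design for a study sample.

    The QTL genotype is carried along as simulation truth but is hidden
    from the mapping methods, which see only the window markers.
    """

    maternal_haplotypes: np.ndarray
    paternal_haplotypes: np.ndarray
    positions_cM: np.ndarray
    qtl_genotype: Optional[np.ndarray] = None
    y: Optional[np.ndarray] = None
    X: Optional[np.ndarray] = None
    qtl_position_cM: float = 0.3
    qtl_variance_fraction: Optional[float] = None
    qtl_pool_freq: Optional[float] = None
    mu_true: Optional[float] = None

    def __post_init__(self) -> None:
        self.maternal_haplotypes = np.ascontiguousarray(
            self.maternal_haplotypes, dtype=np.uint8
        )
        self.paternal_haplotypes = np.ascontiguousarray(
            self.paternal_haplotypes, dtype=np.uint8
        )
        if self.maternal_haplotypes.shape != self.paternal_haplotypes.shape:
            raise ValueError("maternal/paternal haplotype shapes differ")
        if self.maternal_haplotypes.shape[1] != len(self.positions_cM):
            raise ValueError("haplotype columns must match marker positions")
        if self.X is None:
            self.X = np.ones((self.n_individuals, 1))
        self.X = np.asarray(self.X, dtype=float)
        if self.y is not None:
            self.y = np.asarray(self.y, dtype=float)
            if len(self.y) != self.n_individuals:
                raise ValueError("phenotype length must match individuals")

    @property
    def n_individuals(self) -> int:
        return self.maternal_haplotypes.shape[0]

    @property
    def n_markers(self) -> int:
        return self.maternal_haplotypes.shape[1]


# ---------------------------------------------------------------------------
# Core Wright-Fisher machinery
# ---------------------------------------------------------------------------


def init_population(locus_map: LocusMap, size: int, seed: RngLike = None) -> PopulationHaplotypes:
    """Generation-0 population with every allele an independent fair coin.

    This puts the segment in Hardy-Weinberg and linkage equilibrium with
    all allele frequencies centred on 0.5.
    """
    if size <= 0:
        raise ValueError("population size must be positive")
    rng = _as_rng(seed)
    haps = (rng.random((2 * size, locus_map.n_loci)) < 0.5).astype(np.uint8)
    return PopulationHaplotypes(haps, generation=0, population_size=size)


def _sparse_hits(rng: np.random.Generator, n_cells: int, p: float) -> np.ndarray:
    """Flat indices of successes of an i.i.d. Bernoulli(p) field of n_cells.

    Exact: the success count is Binomial(n_cells, p) and, given the count,
    positions are uniform without replacement.  Avoids materialising the
    dense field, which dominates runtime at mutation/crossover rates of
    1e-4 and below.
    """
    if n_cells == 0 or p == 0.0:
        return np.empty(0, dtype=np.int64)
    k = rng.binomial(n_cells, p)
    if k == 0:
        return np.empty(0, dtype=np.int64)
    return rng.choice(n_cells, size=k, replace=False)


def _meiosis(
    haplotypes: np.ndarray,
    parent_idx: np.ndarray,
    locus_map: LocusMap,
    mutation_rate: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """One recombinant, mutated gamete per entry of ``parent_idx``.

    Crossovers: one Bernoulli(d/100) phase switch per adjacent-locus
    interval of length d cM (no interference; at d <= 0.01 cM this is
    indistinguishable from Poisson crossover counts).  Mutation: each
    transmitted allele flips with probability ``mutation_rate``.
    """
    n_gametes = len(parent_idx)
    n_loci = locus_map.n_loci
    start = rng.integers(0, 2, size=n_gametes)
    # bulk copy: the whole haplotype chosen by the starting phase
    gametes = haplotypes[2 * parent_idx + start].copy()

    if n_loci > 1:
        p_switch = locus_map.spacing_cM / 100.0
        hits = _sparse_hits(rng, n_gametes * (n_loci - 1), p_switch)
        if len(hits):
            rows, cols = np.divmod(hits, n_loci - 1)
            order = np.argsort(rows, kind="stable")
            rows, cols = rows[order], cols[order]
            boundaries = np.flatnonzero(np.diff(rows)) + 1
            for r_cols, r in zip(
                np.split(cols, boundaries), rows[np.r_[0, boundaries]]
            ):
                hap_a = haplotypes[2 * parent_idx[r] + start[r]]
                hap_b = haplotypes[2 * parent_idx[r] + 1 - start[r]]
                ind = np.zeros(n_loci, dtype=bool)
                ind[r_cols + 1] = True
                phase = np.logical_xor.accumulate(ind)
                gametes[r] = np.where(phase, hap_b, hap_a)

    if mutation_rate > 0:
        hits = _sparse_hits(rng, n_gametes * n_loci, mutation_rate)
        if len(hits):
            rows, cols = np.divmod(hits, n_loci)
            gametes[rows, cols] ^= 1

    return gametes


def advance_generation(
    pop: PopulationHaplotypes,
    locus_map: LocusMap,
    next_size: int,
    mutation_rate: float,
    rng: RngLike,
) -> PopulationHaplotypes:
    """One discrete generation of random mating.

    Each of ``next_size`` offspring takes two parents drawn uniformly with
    replacement (selfing allowed); each parent transmits one recombinant,
    mutated gamete.
    """
    if next_size <= 0:
        raise ValueError("next_size must be positive")
    if pop.population_size <= 0:
        raise ValueError("parent population is empty")
    rng = _as_rng(rng)
    parents = rng.integers(0, pop.population_size, size=(next_size, 2))
    gametes = _meiosis(pop.haplotypes, parents.ravel(), locus_map, mutation_rate, rng)
    return PopulationHaplotypes(gametes, pop.generation + 1, next_size)


def run_history(locus_map: LocusMap, demo: DemographyConfig) -> PopulationHaplotypes:
    """Run the full two-phase LD-generating history and return the final generation."""
    rng = np.random.default_rng(demo.rng_seed)
    pop = init_population(locus_map, demo.phase1_size, rng)
    for phase_size, phase_gens in (
        (demo.phase1_size, demo.phase1_generations),
        (demo.phase2_size, demo.phase2_generations),
    ):
        for _ in range(phase_gens):
            pop = advance_generation(pop, locus_map, phase_size, demo.mutation_rate, rng)
        logger.info(
            "history at generation %d (size %d): %.1f%% loci segregating",
            pop.generation,
            phase_size,
            100.0 * np.mean((pop.allele_frequencies() > 0) & (pop.allele_frequencies() < 1)),
        )
    return pop


# ---------------------------------------------------------------------------
# Panel construction and study sampling
# ---------------------------------------------------------------------------


def select_markers_and_qtl(
    pop: PopulationHaplotypes,
    locus_map: LocusMap,
    window_cM: float = 1.0,
    qtl_offset_cM: float = 0.3,
) -> MarkerPanel:
    """Bin-wise marker selection and QTL/window placement.

    Per 10-locus bin the segregating marker with allele frequency closest
    to 0.5 is selected (ties broken toward the lower locus index).  Among
    QTL loci whose bin admits the window geometry, the one closest to
    frequency 0.5 is chosen, and the window of consecutive bins is placed
    so the QTL lies ``qtl_offset_cM`` right of the first window marker on
    the nominal grid.

    Raises
    ------
    DegenerateQTLError
        If no eligible QTL locus segregates.
    PanelConstructionError
        If a window bin holds no segregating marker.
    """
    freqs = pop.allele_frequencies()
    n_bins = locus_map.n_bins
    ms = locus_map.marker_spacing_cM
    n_window = int(round(window_cM / ms)) + 1  # fence-post: 11/21/51 markers
    offset_bins = int(round(qtl_offset_cM / ms))
    if n_window > n_bins:
        raise PanelConstructionError("segment too short for the analysis window")

    selected = np.full(n_bins, -1, dtype=np.int64)
    for b in range(n_bins):
        lo = b * BIN_SIZE
        marker_loci = np.arange(lo, lo + BIN_SIZE - 1)  # last locus is the QTL
        f = freqs[marker_loci]
        seg = (f > 0) & (f < 1)
        if seg.any():
            cand = marker_loci[seg]
            selected[b] = cand[np.argmin(np.abs(freqs[cand] - 0.5))]

    qtl_loci = locus_map.qtl_indices
    bins = np.arange(n_bins)
    eligible = (bins >= offset_bins) & (bins <= n_bins - (n_window - offset_bins))
    qf = freqs[qtl_loci]
    eligible &= (qf > 0) & (qf < 1)
    if not eligible.any():
        raise DegenerateQTLError("no segregating QTL locus admits the window geometry")
    cand_bins = bins[eligible]
    qtl_bin = int(cand_bins[np.argmin(np.abs(qf[eligible] - 0.5))])
    qtl_index = int(qtl_loci[qtl_bin])

    first_bin = qtl_bin - offset_bins
    window_bins = np.arange(first_bin, first_bin + n_window)
    window_markers = selected[window_bins]
    if (window_markers < 0).any():
        raise PanelConstructionError(
            f"window bins {window_bins[window_markers < 0].tolist()} hold no "
            "segregating marker"
        )

    return MarkerPanel(
        marker_indices=selected,
        qtl_index=qtl_index,
        qtl_bin=qtl_bin,
        window_marker_indices=window_markers,
        window_positions_cM=np.arange(n_window) * ms,
        qtl_position_cM=qtl_offset_cM,
        marker_spacing_cM=ms,
    )


def sample_study_population(
    pop: PopulationHaplotypes,
    locus_map: LocusMap,
    panel: MarkerPanel,
    n: int,
    rng: RngLike,
    mutation_rate: float = DEFAULT_MUTATION_RATE,
) -> StudyData:
    """Draw n unrelated study individuals from the final population.

    Each individual receives two gametes; each gamete is produced by one
    additional meiosis from a uniformly drawn final-generation individual,
    so the sample size may exceed the final census while preserving the
    population's haplotype-frequency distribution.
    """
    if n <= 0:
        raise ValueError("sample size must be positive")
    rng = _as_rng(rng)
    parent_idx = rng.integers(0, pop.population_size, size=2 * n)
    gametes = _meiosis(pop.haplotypes, parent_idx, locus_map, mutation_rate, rng)
    mat, pat = gametes[0::2], gametes[1::2]
    qtl_genotype = (
        mat[:, panel.qtl_index].astype(np.int64) + pat[:, panel.qtl_index]
    )
    return StudyData(
        maternal_haplotypes=mat[:, panel.window_marker_indices],
        paternal_haplotypes=pat[:, panel.window_marker_indices],
        positions_cM=panel.window_positions_cM.copy(),
        qtl_genotype=qtl_genotype,
        qtl_position_cM=panel.qtl_position_cM,
        qtl_pool_freq=float(pop.allele_frequencies()[panel.qtl_index]),
    )


def simulate_phenotypes(
    study: StudyData,
    qtl_variance_fraction: float,
    rng: RngLike,
    pool_freq: Optional[float] = None,
) -> StudyData:
    """Additive-QTL phenotypes with a fixed fraction of variance explained.

    y_i = g_i * mu_true + e_i with e_i ~ N(0, 1 - fraction) and
    mu_true = sqrt(fraction / (2 p (1-p))) at the sampling-pool QTL allele
    frequency p, so total phenotypic variance is ~1.  fraction = 0 gives
    pure unit-variance noise (the null used for calibration).
    """
    if not 0 <= qtl_variance_fraction < 1:
        raise ValueError("qtl_variance_fraction must be in [0, 1)")
    rng = _as_rng(rng)
    n = study.n_individuals
    if qtl_variance_fraction == 0.0:
        y = rng.normal(0.0, 1.0, size=n)
        mu_true = 0.0
    else:
        p = pool_freq if pool_freq is not None else study.qtl_pool_freq
        if p is None:
            raise ValueError("pool QTL frequency unknown; pass pool_freq")
        if not 0 < p < 1:
            raise DegenerateQTLError(f"QTL monomorphic in pool (p={p})")
        if study.qtl_genotype is None:
            raise ValueError("study lacks QTL genotypes")
        mu_true = float(np.sqrt(qtl_variance_fraction / (2 * p * (1 - p))))
        e = rng.normal(0.0, np.sqrt(1 - qtl_variance_fraction), size=n)
        y = study.qtl_genotype * mu_true + e
    out = replace(study)
    out.y = np.asarray(y, dtype=float)
    out.qtl_variance_fraction = qtl_variance_fraction
    out.mu_true = mu_true
    return out


def simulate_study(
    marker_spacing_cM: float,
    n: int,
    qtl_variance_fraction: float,
    seed: int,
    n_loci: int = 2000,
    demography: Optional[DemographyConfig] = None,
    history: Optional[PopulationHaplotypes] = None,
    locus_map: Optional[LocusMap] = None,
    max_tries: int = 20,
):
    """Full pipeline: history -> panel -> sample -> phenotypes.

    Monomorphic panels trigger resimulation of the whole history with a
    fresh seed (up to ``max_tries``).  A pre-computed ``history`` (with its
    ``locus_map``) can be reused across study replicates; then only the
    sampling and phenotypes are redrawn.

    Returns (locus_map, history, panel, study).
    """
    rng = np.random.default_rng(seed)
    if history is not None:
        if locus_map is None:
            raise ValueError("reusing a history requires its locus_map")
        panel = select_markers_and_qtl(history, locus_map)
        study = sample_study_population(history, locus_map, panel, n, rng)
        study = simulate_phenotypes(study, qtl_variance_fraction, rng)
        return locus_map, history, panel, study

    locus_map = LocusMap(n_loci=n_loci, spacing_cM=marker_spacing_cM / BIN_SIZE)
    base = demography if demography is not None else DemographyConfig()
    last_err: Optional[Exception] = None
    for attempt in range(max_tries):
        demo = replace(base, rng_seed=int(rng.integers(0, 2**31 - 1)))
        pop = run_history(locus_map, demo)
        try:
            panel = select_markers_and_qtl(pop, locus_map)
        except PanelConstructionError as err:
            last_err = err
            logger.info("panel construction failed (attempt %d): %s", attempt + 1, err)
            continue
        study = sample_study_population(pop, locus_map, panel, n, rng)
        study = simulate_phenotypes(study, qtl_variance_fraction, rng)
        return locus_map, pop, panel, study
    raise PanelConstructionError(
        f"no usable panel after {max_tries} histories"
    ) from last_err


# ---------------------------------------------------------------------------
# Direct (synthetic) LD generator for fast experiments
# ---------------------------------------------------------------------------


def synthesize_ld_study(
    n: int,
    pi_true: tuple[float, float],
    qtl_variance_fraction: float,
    rng: RngLike,
    n_markers: int = 11,
    marker_spacing_cM: float = 0.1,
    qtl_marker: int = 3,
    neighbour_ld: float = 0.8,
) -> StudyData:
    """Synthetic study with a prescribed marker-QTL disequilibrium.

    A shortcut that skips the Wright-Fisher history: each gamete carries a
    focal-marker allele a ~ Bernoulli(0.5), a QTL allele Q2 with
    probability ``pi_true[a]`` (so pi_true are the conditional QTL allele
    frequencies on the two focal-marker haplotypes), and flanking markers
    forming a Markov chain that copies its neighbour with probability
    ``neighbour_ld``.  Phenotypes are then simulated exactly as for
    simulator output.  Used for fast parameter-recovery experiments where
    the LD parameters must be known exactly.
    """
    rng = _as_rng(rng)
    if not 0 <= qtl_marker < n_markers:
        raise ValueError("qtl_marker outside the window")

    def gametes(count: int) -> tuple[np.ndarray, np.ndarray]:
        haps = np.zeros((count, n_markers), dtype=np.uint8)
        focal = (rng.random(count) < 0.5).astype(np.uint8)
        haps[:, qtl_marker] = focal
        for j in range(qtl_marker + 1, n_markers):
            copy = rng.random(count) < neighbour_ld
            haps[:, j] = np.where(copy, haps[:, j - 1], rng.integers(0, 2, count))
        for j in range(qtl_marker - 1, -1, -1):
            copy = rng.random(count) < neighbour_ld
            haps[:, j] = np.where(copy, haps[:, j + 1], rng.integers(0, 2, count))
        p_q2 = np.where(focal == 1, pi_true[1], pi_true[0])
        qtl = (rng.random(count) < p_q2).astype(np.int64)
        return haps, qtl

    mat, qtl_m = gametes(n)
    pat, qtl_p = gametes(n)
    pool_freq = 0.5 * (pi_true[0] + pi_true[1])
    study = StudyData(
        maternal_haplotypes=mat,
        paternal_haplotypes=pat,
        positions_cM=np.arange(n_markers) * marker_spacing_cM,
        qtl_genotype=qtl_m + qtl_p,
        qtl_position_cM=qtl_marker * marker_spacing_cM,
        qtl_pool_freq=pool_freq,
    )
    return simulate_phenotypes(study, qtl_variance_fraction, rng, pool_freq=pool_freq)
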