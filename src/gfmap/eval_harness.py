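"""Power and precision experiments for the mapping methods.

The protocol mirrors the simulation study design: for every replicate an
LD history is simulated (or drawn from a shared pool), a marker panel and
study sample are built, phenotypes are generated under the null (no QTL)
or the alternative (QTL explaining 2% or 5% of phenotypic variance), and
one of four methods is run:

* ``LSR1`` / ``LSR2`` — least-squares scan; statistic = F at the min-p
  position.
* ``BGF1`` / ``BGF2`` — Bayesian gene-frequency chain; statistic =
  posterior mean of the QTL-variance functional.

The critical value is the empirical upper 10% quantile of the statistic
over the null replicates; power is the fraction of alternative-replicate
statistics strictly exceeding it; precision is the mean absolute error
(cM) of the estimated location over alternative replicates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from . import bgf_sampler, lsr_scan
from .bgf_sampler import ChainConfig, PriorConfig, ProposalConfig
from .ld_simulator import (
    BIN_SIZE,
    DemographyConfig,
    LocusMap,
    PanelConstructionError,
    PopulationHaplotypes,
    run_history,
    sample_study_population,
    select_markers_and_qtl,
    simulate_phenotypes,
)

__all__ = [
    "METHODS",
    "ExperimentConfig",
    "ExperimentResult",
    "critical_value",
    "power",
    "mae",
    "panel_with_typed_qtl",
    "run_method",
    "run_experiment",
    "run_paired_experiment",
]

logger = logging.getLogger(__name__)

METHODS = ("BGF1", "BGF2", "LSR1", "LSR2")

#: chain length used per replicate inside experiments (short chains)
DEFAULT_EXPERIMENT_CHAIN = ChainConfig(n_iterations=6_000, burn_in=1_500, thinning=5)


@dataclass(frozen=True)
class ExperimentConfig:
    """One cell of the power/precision study.

    ``n_histories`` = None simulates a fresh LD history per replicate (the
    most conservative protocol); an integer reuses a round-robin pool of
    that many histories, trading some replicate independence for speed.
    ``n_loci`` scales the simulated segment (2000 at full scale).
    """

    method: str = "LSR1"
    qtl_variance_fraction: float = 0.05
    marker_spacing_cM: float = 0.1
    n: int = 500
    n_null_reps: int = 1500
    n_power_reps: Optional[int] = None  # default: same as n_null_reps
    master_seed: int = 0
    n_loci: int = 2000
    demography: DemographyConfig = field(default_factory=DemographyConfig)
    n_histories: Optional[int] = None
    chain: ChainConfig = DEFAULT_EXPERIMENT_CHAIN
    prior: PriorConfig = field(default_factory=PriorConfig)
    proposal: ProposalConfig = field(default_factory=ProposalConfig)
    level: float = 0.10
    max_panel_tries: int = 20

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"method must be one of {METHODS}")
        if not 0 <= self.qtl_variance_fraction < 1:
            raise ValueError("qtl_variance_fraction must be in [0, 1)")
        if self.n_null_reps < 0 or (self.n_power_reps or 0) < 0:
            raise ValueError("replicate counts must be non-negative")

    @property
    def k(self) -> int:
        return int(self.method[-1])

    @property
    def is_bgf(self) -> bool:
        return self.method.startswith("BGF")


@dataclass
class ExperimentResult:
    critical_value: float
    power: float
    mae_cM: float
    se_mae: float
    records: pd.DataFrame
    config: ExperimentConfig


def critical_value(null_stats, level: float = 0.10) -> float:
    """Empirical upper quantile: the ceil((1-level) R)-th order statistic."""
    stats = np.sort(np.asarray(null_stats, dtype=float))
    if len(stats) < 10:
        raise ValueError("need at least 10 null statistics")
    rank = int(np.ceil((1.0 - level) * len(stats)))  # 1-based order statistic
    return float(stats[rank - 1])


def power(alt_stats, critical: float) -> float:
    """Fraction of alternative statistics strictly above the critical value."""
    alt_stats = np.asarray(alt_stats, dtype=float)
    if alt_stats.size == 0:
        raise ValueError("no alternative statistics")
    return float(np.mean(alt_stats > critical))


def mae(estimated_positions_cM, true_position_cM: float):
    """Mean absolute error of location estimates and its standard error."""
    est = np.asarray(estimated_positions_cM, dtype=float)
    if est.size == 0:
        raise ValueError("no estimates")
    err = np.abs(est - true_position_cM)
    se = float(err.std(ddof=1) / np.sqrt(len(err))) if len(err) > 1 else 0.0
    return float(err.mean()), se


def panel_with_typed_qtl(panel):
    """Replace the QTL bin's selected marker with the QTL locus itself.

    The causal variant then sits on the typed panel at its own nominal
    position — complete LD between "marker" and QTL.
    """
    import dataclasses

    first_bin = int(panel.window_marker_indices[0]) // BIN_SIZE
    idx = panel.qtl_bin - first_bin
    if not 0 <= idx < panel.n_window_markers:
        raise ValueError("QTL bin lies outside the analysis window")
    markers = panel.window_marker_indices.copy()
    markers[idx] = panel.qtl_index
    return dataclasses.replace(panel, window_marker_indices=markers)


def run_method(study, cfg: ExperimentConfig, chain_seed: int):
    """Run the configured mapping method; returns (statistic, estimated cM)."""
    if cfg.is_bgf:
        chain = bgf_sampler.run_chain(
            study,
            k=cfg.k,
            prior=cfg.prior,
            proposal=cfg.proposal,
            chain=replace(cfg.chain, seed=chain_seed),
        )
        s = bgf_sampler.summarize(chain)
        return s.statistic, s.estimated_position_cM
    res = lsr_scan.scan(study, k=cfg.k)
    return res.statistic, res.estimated_position_cM


def _new_history(locus_map: LocusMap, cfg: ExperimentConfig, rng: np.random.Generator):
    """Simulate histories until one admits a panel; returns (pop, panel)."""
    last: Optional[Exception] = None
    for _ in range(cfg.max_panel_tries):
        demo = replace(cfg.demography, rng_seed=int(rng.integers(0, 2**31 - 1)))
        pop = run_history(locus_map, demo)
        try:
            return pop, select_markers_and_qtl(pop, locus_map)
        except PanelConstructionError as err:
            last = err
    raise PanelConstructionError(
        f"no usable panel in {cfg.max_panel_tries} histories"
    ) from last


def run_paired_experiment(
    methods, cfg: ExperimentConfig, typed_qtl: bool = False
) -> dict[str, ExperimentResult]:
    """Run several methods on identical replicate datasets (paired design).

    Every method sees exactly the same simulated histories, panels, samples
    and phenotypes, so per-replicate records can be compared method against
    method.  ``typed_qtl`` replaces the selected marker of the QTL's bin
    with the QTL locus itself, putting the causal variant on the typed
    panel (complete LD; the regime where the Bayesian and least-squares
    analyses coincide).
    """
    for m in methods:
        if m not in METHODS:
            raise ValueError(f"unknown method {m!r}")
    locus_map = LocusMap(cfg.n_loci, cfg.marker_spacing_cM / BIN_SIZE)
    n_power_reps = cfg.n_null_reps if cfg.n_power_reps is None else cfg.n_power_reps
    master = np.random.SeedSequence(cfg.master_seed)
    hist_rng = np.random.default_rng(master.spawn(1)[0])

    pool: list[tuple[PopulationHaplotypes, object]] = []
    if cfg.n_histories is not None:
        for _ in range(cfg.n_histories):
            pool.append(_new_history(locus_map, cfg, hist_rng))

    records: dict[str, list] = {m: [] for m in methods}
    rep_seeds = master.spawn(cfg.n_null_reps + n_power_reps)
    for rep, seed_seq in enumerate(rep_seeds):
        is_null = rep < cfg.n_null_reps
        rng = np.random.default_rng(seed_seq)
        if pool:
            pop, panel = pool[rep % len(pool)]
        else:
            pop, panel = _new_history(locus_map, cfg, rng)
        if typed_qtl:
            panel = panel_with_typed_qtl(panel)
        fraction = 0.0 if is_null else cfg.qtl_variance_fraction
        study = sample_study_population(
            pop, locus_map, panel, cfg.n, rng, cfg.demography.mutation_rate
        )
        study = simulate_phenotypes(study, fraction, rng)
        chain_seed = int(rng.integers(0, 2**31 - 1))
        for m in methods:
            stat, est = run_method(study, replace(cfg, method=m), chain_seed)
            records[m].append(
                {
                    "replicate": rep,
                    "phase": "null" if is_null else "power",
                    "statistic": stat,
                    "estimated_position_cM": est,
                    "abs_error_cM": np.nan
                    if is_null
                    else abs(est - panel.qtl_position_cM),
                }
            )
        if (rep + 1) % 50 == 0:
            logger.info("replicate %d/%d done", rep + 1, len(rep_seeds))

    out = {}
    for m in methods:
        df = pd.DataFrame(records[m])
        null_stats = df.loc[df.phase == "null", "statistic"].to_numpy()
        crit = (
            critical_value(null_stats, cfg.level) if len(null_stats) >= 10 else np.nan
        )
        if n_power_reps > 0:
            alt = df[df.phase == "power"]
            pw = (
                power(alt["statistic"].to_numpy(), crit)
                if np.isfinite(crit)
                else np.nan
            )
            mae_cM, se = mae(alt["estimated_position_cM"].to_numpy(), 0.3)
        else:
            pw, mae_cM, se = np.nan, np.nan, np.nan
        out[m] = ExperimentResult(
            critical_value=crit,
            power=pw,
            mae_cM=mae_cM,
            se_mae=se,
            records=df,
            config=replace(cfg, method=m),
        )
    return out


def run_experiment(cfg: ExperimentConfig) -> ExperimentResult:
    """Null calibration plus power/precision for one study cell."""
    return run_paired_experiment((cfg.method,), cfg)[cfg.method]
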