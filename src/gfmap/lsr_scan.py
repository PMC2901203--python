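"""Least-squares regression scan: the frequentist comparator for QTL fine mapping.

At each candidate position the phenotype is regressed on the copy numbers
g_ij of the 2^k marker haplotypes at that position (k = 1 SNP or k = 2
flanking SNPs with known phase), and an F-test of equality of all
haplotype effects against the covariate-only model is performed.  The
estimated QTL location is the candidate with the smallest p-value; when
several candidates have p-values numerically equal to zero the middle one
of those is taken (the lower of the two middles for an even count).

Because haplotype copy numbers sum to 2, one observed haplotype column is
dropped against the intercept for identifiability; haplotypes unobserved
in the sample are dropped as well, with the numerator degrees of freedom
reduced accordingly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import f as f_dist

from .gf_model import candidate_positions, haplotype_codes, n_candidates
from .ld_simulator import StudyData

__all__ = ["ZERO_P", "MonomorphicPositionError", "LSRResult", "fit_position", "scan"]

#: p-values below this are treated as numerically zero (double underflow region)
ZERO_P = 1e-15


class MonomorphicPositionError(ValueError):
    """Fewer than two marker haplotypes observed; no test possible."""


@dataclass
class LSRResult:
    """Per-position F tests and the location decision of a scan."""

    table: pd.DataFrame
    estimated_location: int
    estimated_position_cM: float
    model_k: int

    @property
    def statistic(self) -> float:
        """Detection statistic: the F value at the estimated location."""
        return float(self.table.loc[self.estimated_location, "F"])

    @property
    def min_p(self) -> float:
        return float(self.table.loc[self.estimated_location, "p"])


def _copy_numbers(study: StudyData, location: int, k: int) -> np.ndarray:
    """n x 2^k matrix of haplotype copy numbers at a candidate position."""
    m, p = haplotype_codes(study, location, k)
    n, h = study.n_individuals, 2**k
    g = np.zeros((n, h))
    np.add.at(g, (np.arange(n), m), 1.0)
    np.add.at(g, (np.arange(n), p), 1.0)
    return g


def fit_position(study: StudyData, location: int, k: int):
    """F-test of haplotype effects at one candidate position.

    Returns (F, df1, df2, p) with df1 = observed haplotypes - 1 and
    df2 = n - (covariates + df1).

    Raises
    ------
    MonomorphicPositionError
        If fewer than two haplotypes are observed at the position.
    """
    if study.y is None:
        raise ValueError("study has no phenotypes")
    g = _copy_numbers(study, location, k)
    observed = np.flatnonzero(g.sum(axis=0) > 0)
    if len(observed) < 2:
        raise MonomorphicPositionError(
            f"position {location}: only {len(observed)} haplotype(s) observed"
        )
    X0 = study.X
    # drop the first observed haplotype column against the intercept
    X1 = np.column_stack([X0, g[:, observed[1:]]])
    y = study.y

    beta0, *_ = np.linalg.lstsq(X0, y, rcond=None)
    rss0 = float(np.sum((y - X0 @ beta0) ** 2))
    beta1, _, rank1, _ = np.linalg.lstsq(X1, y, rcond=None)
    rss1 = float(np.sum((y - X1 @ beta1) ** 2))

    df1 = rank1 - X0.shape[1]  # collinear haplotype columns shed df
    if df1 < 1:
        raise MonomorphicPositionError(
            f"position {location}: haplotype columns carry no rank"
        )
    df2 = study.n_individuals - rank1
    if df2 < 1:
        raise ValueError("too few individuals for the model")
    F = max((rss0 - rss1) / df1 / (rss1 / df2), 0.0)
    p = float(f_dist.sf(F, df1, df2))
    return F, df1, df2, p


def scan(study: StudyData, k: int = 1) -> LSRResult:
    """Fit every candidate position and apply the minimum-p location rule.

    Monomorphic positions are skipped and recorded with missing statistics.
    """
    L = n_candidates(study.n_markers, k)
    positions = candidate_positions(study.positions_cM, k)
    rows = []
    for l in range(L):
        try:
            F, df1, df2, p = fit_position(study, l, k)
            rows.append((l, positions[l], F, df1, df2, p, True))
        except MonomorphicPositionError:
            rows.append((l, positions[l], np.nan, np.nan, np.nan, np.nan, False))
    table = pd.DataFrame(
        rows, columns=["location", "position_cM", "F", "df1", "df2", "p", "tested"]
    )
    if not table["tested"].any():
        raise MonomorphicPositionError("no testable position in the window")

    p_vals = table["p"].to_numpy()
    zero = np.flatnonzero(p_vals < ZERO_P)  # NaN compares False
    if len(zero) > 0:
        est = int(zero[(len(zero) - 1) // 2])  # middle; lower of two middles
    else:
        est = int(np.nanargmin(p_vals))  # first minimum on exact ties
    return LSRResult(
        table=table,
        estimated_location=est,
        estimated_position_cM=float(positions[est]),
        model_k=k,
    )
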