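"""Relative evolutionary rates of gene families and their dispersion.

For each gene family in a group of related genomes, the family's pairwise
sequence distances are regressed (zero intercept) on the pairwise distances
of the group's phylogenetic tree; the slope is the family's evolutionary
rate relative to the group average.  Families whose relationship is poorly
linear (R^2 < 0.9, typically rare gene-replacement cases) are discarded.
Dividing each slope by the family's mean slope across groups removes
family-specific rate effects; measuring against the group's own tree removes
group-level effects.  The standard deviation of the doubly-corrected
relative rates within a group quantifies rate over-dispersion, and — under
the barrier model — equals the coefficient of variation of the times over
which the group's genes have actually been diverging, making it an
observable fingerprint of asynchronous barrier crossing.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "RateRecord",
    "DispersionResult",
    "family_rate",
    "relative_rates_table",
    "dispersion",
    "delay_rate_association",
    "pair_vectors",
]

R2_THRESHOLD = 0.9


@dataclass
class RateRecord:
    group: str
    family: str
    slope: float
    r2: float
    relative_rate: Optional[float] = None


@dataclass
class DispersionResult:
    group: str
    std: float
    n_families: int


def pair_vectors(gene_matrix: pd.DataFrame, tree_matrix: pd.DataFrame
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Matched upper-triangle vectors of two square distance matrices."""
    if list(gene_matrix.index) != list(gene_matrix.columns):
        raise ValueError("gene distance matrix must be square with matching labels")
    common = [g for g in tree_matrix.index if g in set(gene_matrix.index)]
    if len(common) < 3:
        raise ValueError("need at least three shared genomes")
    g = gene_matrix.loc[common, common].to_numpy(dtype=float)
    t = tree_matrix.loc[common, common].to_numpy(dtype=float)
    iu = np.triu_indices(len(common), k=1)
    return g[iu], t[iu]


def family_rate(gene_distances, tree_distances) -> tuple[float, float]:
    """Zero-intercept regression of gene on tree distances: (slope, R^2).

    Accepts matched 1-D pair vectors or square labeled DataFrames.  The slope
    is sum(xy)/sum(x^2); R^2 is the uncentered coefficient of determination
    of the through-origin model, clamped to [0, 1].
    """
    if isinstance(gene_distances, pd.DataFrame):
        y, x = pair_vectors(gene_distances, tree_distances)
    else:
        y = np.asarray(gene_distances, dtype=float)
        x = np.asarray(tree_distances, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need at least three matched pairs")
    sxx = float(x @ x)
    if sxx == 0:
        raise ValueError("all tree distances are zero: rate undefined")
    slope = float(x @ y) / sxx
    syy = float(y @ y)
    if syy == 0:
        return slope, 1.0 if slope == 0 else 0.0
    rss = float(np.sum((y - slope * x) ** 2))
    r2 = 1.0 - rss / syy
    return slope, min(max(r2, 0.0), 1.0)


def relative_rates_table(records: Sequence[RateRecord],
                         r2_min: float = R2_THRESHOLD) -> list[RateRecord]:
    """Fill in family-mean-normalized relative rates across groups.

    Records with R^2 below ``r2_min`` are dropped first; each surviving
    record's relative rate is its slope divided by the mean slope of the same
    family across groups (group-level correction is already inherent in the
    slopes, which are measured against each group's own tree).  Families
    whose across-group mean slope is zero are excluded with a warning.
    """
    kept = [r for r in records if r.r2 >= r2_min]
    by_family: dict = {}
    for r in kept:
        by_family.setdefault(r.family, []).append(r.slope)
    means = {fam: float(np.mean(slopes)) for fam, slopes in by_family.items()}
    out = []
    dropped = []
    for r in kept:
        m = means[r.family]
        if m == 0:
            dropped.append(r.family)
            continue
        out.append(RateRecord(group=r.group, family=r.family, slope=r.slope,
                              r2=r.r2, relative_rate=r.slope / m))
    if dropped:
        warnings.warn(f"excluded families with zero mean slope: {sorted(set(dropped))}",
                      RuntimeWarning)
    return out


def dispersion(records: Sequence[RateRecord]) -> DispersionResult:
    """Sample standard deviation of one group's relative rates."""
    groups = {r.group for r in records}
    if len(groups) != 1:
        raise ValueError("dispersion is computed per group; mixed groups supplied")
    rates = np.array([r.relative_rate for r in records], dtype=float)
    if rates.size < 2:
        raise ValueError("need at least two retained families")
    return DispersionResult(group=groups.pop(), std=float(np.std(rates, ddof=1)),
                            n_families=rates.size)


def delay_rate_association(dispersions: Sequence[float], delays: Sequence[float],
                           turnover_ratios: Optional[Sequence[float]] = None,
                           tree_depths: Optional[Sequence[float]] = None,
                           short_delay_factor: float = 0.5) -> dict:
    """Association tests between rate dispersion, clock delay and gene turnover.

    Returns Pearson correlation of dispersion vs delay, Spearman rank
    correlation of delay vs relative gene-turnover rate (if supplied), and a
    two-sample t-test of dispersions between strongly delayed groups
    (tau_inf > tree depth) and nearly linearly diverging ones (tau_inf <
    ``short_delay_factor`` x tree depth), when tree depths are supplied.
    Constant input vectors make a correlation undefined; it is reported as
    NaN."""
    d = np.asarray(dispersions, dtype=float)
    tau = np.asarray(delays, dtype=float)
    if d.size != tau.size or d.size < 4:
        raise ValueError("need matched dispersion/delay vectors of length >= 4")
    out: dict = {"n_groups": int(d.size)}
    if np.ptp(d) == 0 or np.ptp(tau) == 0:
        out["pearson_r"] = math.nan
        out["pearson_p"] = math.nan
    else:
        r, p = stats.pearsonr(d, tau)
        out["pearson_r"] = float(r)
        out["pearson_p"] = float(p)
    if turnover_ratios is not None:
        tr = np.asarray(turnover_ratios, dtype=float)
        if np.ptp(tr) == 0 or np.ptp(tau) == 0:
            out["spearman_rho"] = math.nan
            out["spearman_p"] = math.nan
        else:
            rho, p = stats.spearmanr(tau, tr)
            out["spearman_rho"] = float(rho)
            out["spearman_p"] = float(p)
    if tree_depths is not None:
        depth = np.asarray(tree_depths, dtype=float)
        long_mask = tau > depth
        short_mask = tau < short_delay_factor * depth
        out["n_long_delay"] = int(long_mask.sum())
        out["n_short_delay"] = int(short_mask.sum())
        if long_mask.sum() >= 2 and short_mask.sum() >= 2:
            t, p = stats.ttest_ind(d[long_mask], d[short_mask])
            out["ttest_t"] = float(t)
            out["ttest_p"] = float(p)
        else:
            out["ttest_t"] = math.nan
            out["ttest_p"] = math.nan
    return out
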