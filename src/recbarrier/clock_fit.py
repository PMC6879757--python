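"""Fit barrier-crossing scenarios to sequence-vs-gene-content tree distances.

For every unordered pair of leaves, the sequence-based tree gives an observed
divergence ``x`` (substitutions per site) and the gene-content tree gives a
distance ``y`` (gain+loss events per family) proportional to true time.  If
two genomes split ``t`` ago, the barrier process predicts ``x = 2 G(t)`` and
``y = 2 a t`` where ``a`` is the gene-turnover events per substitution-time
unit, so the fitted model is::

    y = a * 2 * G_theta^{-1}(x / 2)

with the barrier parameters ``theta`` and amplitude ``a`` estimated by
nonlinear least squares (sequence distance as the independent variable).
Scenarios are compared by AIC = 2k + n (ln(2 pi RSS / n) + 1), and the 95%
confidence interval for the long-term delay ``tau_inf`` is obtained by
profiling the RSS: the bounds are where RSS(tau_inf) crosses
``RSS* (1 + 1.96^2 / (n - 1))``.  When that threshold is never crossed below
10x the largest observed distance the upper bound is reported as unbounded
(the regime where most genomes are still strongly bound by recombination).

A heuristic power law ``y = b x^alpha`` is fitted alongside as a
model-free reference, on the original scale so its RSS/AIC are comparable.

Pairwise points share tree branches and are therefore statistically
dependent; as is conventional for this analysis, the dependence is ignored
and ``n`` is the raw pair count (see the methods note for the consequences
for CI calibration).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import dendropy
import numpy as np
from scipy import optimize

from .barrier_model import BarrierParams, DivergenceMap

__all__ = [
    "DistanceScatter",
    "FitResult",
    "PowerLawFit",
    "pairwise_scatter",
    "fit_barrier",
    "aic",
    "tau_confidence_interval",
    "fit_power_law",
    "select_scenario",
    "FIT_SCENARIOS",
]

#: scenarios fitted by default: constant hazard, linearly increasing hazard,
#: linear-plus-constant hazard, and autocatalytic (fraction-dependent) hazard
FIT_SCENARIOS = ("constant", "linear", "linear_plus_constant", "autocatalytic")

_PHI_BOUNDS = (0.1, 50.0)


@dataclass
class DistanceScatter:
    """Matched pairwise leaf distances from the two trees."""

    x: np.ndarray  # sequence-tree distances (substitutions/site)
    y: np.ndarray  # gene-content-tree distances (events per family)
    pair_ids: list

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.shape != self.y.shape or self.x.ndim != 1:
            raise ValueError("x and y must be 1-D arrays of equal length")
        if self.x.size < 8:
            raise ValueError("need at least 8 leaf pairs")
        if np.any(self.x < 0) or np.any(self.y < 0):
            raise ValueError("distances must be non-negative")

    @property
    def n(self) -> int:
        return self.x.size


def _clade_sets(tree: dendropy.Tree) -> set:
    out = set()
    for node in tree.postorder_internal_node_iter():
        leaves = frozenset(lf.taxon.label for lf in node.leaf_iter())
        out.add(leaves)
    return out


def _pairwise_distances(tree: dendropy.Tree) -> dict:
    pdm = tree.phylogenetic_distance_matrix()
    taxa = sorted(tree.taxon_namespace, key=lambda t: t.label)
    out = {}
    for i, t1 in enumerate(taxa):
        for t2 in taxa[i + 1:]:
            out[(t1.label, t2.label)] = pdm.distance(t1, t2)
    return out


def pairwise_scatter(seq_tree: dendropy.Tree, gc_tree: dendropy.Tree) -> DistanceScatter:
    """All unordered leaf pairs' distances in the two trees, matched by label.

    The trees must have identical leaf sets and topologies (they are meant to
    be the same tree with branch lengths from the two clocks)."""
    seq_leaves = {lf.taxon.label for lf in seq_tree.leaf_node_iter()}
    gc_leaves = {lf.taxon.label for lf in gc_tree.leaf_node_iter()}
    if seq_leaves != gc_leaves:
        raise ValueError(
            f"leaf sets differ: {sorted(seq_leaves ^ gc_leaves)} not shared")
    if _clade_sets(seq_tree) != _clade_sets(gc_tree):
        raise ValueError("tree topologies differ")
    d_seq = _pairwise_distances(seq_tree)
    d_gc = _pairwise_distances(gc_tree)
    pairs = sorted(d_seq)
    x = np.array([d_seq[p] for p in pairs])
    y = np.array([d_gc[p] for p in pairs])
    return DistanceScatter(x=x, y=y, pair_ids=pairs)


@dataclass
class FitResult:
    """One scenario's least-squares fit to a distance scatter."""

    scenario: str
    params: Optional[BarrierParams]
    a: float
    rss: float
    n_obs: int
    n_params: int
    aic: float
    tau_inf: float
    tau_ci: Optional[tuple] = None  # (lower, upper or None for unbounded)
    delta_aic: Optional[float] = None

    def to_dict(self) -> dict:
        return {
            "scenario": self.scenario,
            "params": None if self.params is None else self.params.to_dict(),
            "a": self.a,
            "rss": self.rss,
            "n_obs": self.n_obs,
            "n_params": self.n_params,
            "aic": self.aic,
            "tau_inf": self.tau_inf,
            "tau_ci": None if self.tau_ci is None else list(self.tau_ci),
            "delta_aic": self.delta_aic,
        }


@dataclass
class PowerLawFit:
    """Heuristic power law y = b x^alpha fitted on the original scale."""

    b: float
    alpha: float
    rss: float
    n_obs: int
    aic: float


def aic(rss: float, n: int, k: int) -> float:
    """AIC = 2k + n (ln(2 pi RSS / n) + 1); -inf (with a warning) when RSS = 0."""
    if n <= 0:
        raise ValueError("n must be positive")
    if rss < 0:
        raise ValueError("RSS must be non-negative")
    if rss == 0:
        warnings.warn("RSS = 0: AIC is -inf", RuntimeWarning)
        return -math.inf
    return 2 * k + n * (math.log(2 * math.pi * rss / n) + 1.0)


def _predicted_times(scenario: str, theta: Sequence[float], x_unique: np.ndarray) -> np.ndarray:
    """g(x) = 2 G^{-1}(x/2) on unique x values for the given scenario parameters.

    theta holds the barrier parameters only (the amplitude a is profiled out):
    constant/linear: (tau_inf,); linear_plus_constant: (lambda0, lambda1);
    autocatalytic: (tau_inf, phi).
    """
    if scenario == "constant":
        (ti,) = theta
        params = None if ti <= 0 else BarrierParams.constant(1.0 / ti)
    elif scenario == "linear":
        (ti,) = theta
        params = None if ti <= 0 else BarrierParams.linear(math.pi / (2.0 * ti * ti))
    elif scenario == "linear_plus_constant":
        l0, l1 = theta
        params = None if (l0 <= 0 and l1 <= 0) else BarrierParams.linear_plus_constant(l0, l1)
    elif scenario == "autocatalytic":
        ti, phi = theta
        params = None if ti <= 0 else BarrierParams.autocatalytic(ti, phi)
    else:
        raise ValueError(f"unknown fit scenario {scenario!r}")
    if params is None:  # degenerate tau_inf -> 0 limit: identity map
        return x_unique.copy()
    return np.asarray(DivergenceMap(params).inverse_pairwise(x_unique))


def _profiled_rss(scenario: str, theta, x_unique, inv, y) -> tuple[float, float]:
    """RSS minimized over the amplitude a in closed form; returns (rss, a)."""
    g = _predicted_times(scenario, theta, x_unique)[inv]
    gg = float(g @ g)
    if gg == 0.0:
        return float(y @ y), 0.0
    a = float(g @ y) / gg
    a = max(a, 0.0)
    r = y - a * g
    return float(r @ r), a


def _scenario_params(scenario: str, theta) -> Optional[BarrierParams]:
    if scenario == "constant":
        return BarrierParams.constant(1.0 / theta[0]) if theta[0] > 0 else None
    if scenario == "linear":
        return BarrierParams.linear(math.pi / (2.0 * theta[0] ** 2)) if theta[0] > 0 else None
    if scenario == "linear_plus_constant":
        return BarrierParams.linear_plus_constant(theta[0], theta[1])
    if scenario == "autocatalytic":
        return BarrierParams.autocatalytic(theta[0], theta[1]) if theta[0] > 0 else None
    raise ValueError(scenario)


def _n_params(scenario: str) -> int:
    # amplitude a counts as a parameter in every scenario
    return {"constant": 2, "linear": 2, "linear_plus_constant": 3, "autocatalytic": 3}[scenario]


def _theta_from_z(scenario: str, z, x_max: float) -> tuple:
    """Map scaled optimizer coordinates to native barrier parameters.

    The optimizer works in O(1)-scaled coordinates so a single Nelder-Mead
    tolerance is meaningful across scenarios: tau in units of x_max, phi and
    the two linear_plus_constant component delays on a log scale.
    """
    if scenario in ("constant", "linear"):
        return (z[0] * x_max,)
    if scenario == "autocatalytic":
        return (z[0] * x_max, math.exp(z[1]))
    # linear_plus_constant: components parametrized by their delays
    tau_c = math.exp(z[0]) * x_max
    tau_l = math.exp(z[1]) * x_max
    return (1.0 / tau_c, math.pi / (2.0 * tau_l * tau_l))


def _starts(scenario: str) -> list:
    """Start grid in scaled coordinates (tau in units of max observed x)."""
    taus = (0.1, 0.5, 1.0, 2.0)
    if scenario in ("constant", "linear"):
        return [(t,) for t in taus] + [(1e-3,)]
    if scenario == "linear_plus_constant":
        return [(math.log(t1), math.log(t2)) for t1 in taus for t2 in taus]
    return [(t, math.log(phi)) for t in taus for phi in (1.0, 5.0, 20.0)]


def _z_bounds(scenario: str) -> list:
    if scenario in ("constant", "linear"):
        return [(0.0, 10.0)]
    if scenario == "linear_plus_constant":
        return [(-12.0, 7.0), (-12.0, 7.0)]
    return [(0.0, 10.0), (math.log(_PHI_BOUNDS[0]), math.log(_PHI_BOUNDS[1]))]


def fit_barrier(scatter: DistanceScatter, scenario: str,
                fixed_tau: Optional[float] = None) -> FitResult:
    """Least-squares fit of one barrier scenario to a distance scatter.

    Multi-start bounded optimization over the barrier parameters, with the
    amplitude ``a`` profiled out in closed form at every step.  With
    ``fixed_tau`` set (used for RSS profiling), ``tau_inf`` is pinned and
    only the remaining parameters are optimized.
    """
    x, y = scatter.x, scatter.y
    x_unique, inv = np.unique(x, return_inverse=True)
    x_max = float(x.max())
    if x_max <= 0:
        raise ValueError("all sequence distances are zero")

    def objective(theta):
        try:
            rss, _ = _profiled_rss(scenario, theta, x_unique, inv, y)
        except (ValueError, FloatingPointError):
            return np.inf
        return rss

    yss = float(y @ y)
    best = None
    if fixed_tau is not None:
        if scenario == "autocatalytic":
            res = optimize.minimize_scalar(
                lambda phi: objective((fixed_tau, phi)),
                bounds=_PHI_BOUNDS, method="bounded",
                options={"xatol": 1e-8})
            best = ((fixed_tau, float(res.x)), float(res.fun))
        elif scenario in ("constant", "linear"):
            best = ((fixed_tau,), objective((fixed_tau,)))
        else:
            raise ValueError("fixed_tau profiling supported for constant, linear "
                             "and autocatalytic scenarios")
    else:
        bounds = _z_bounds(scenario)
        starts = _starts(scenario)
        if len(bounds) == 1:
            res = optimize.minimize_scalar(
                lambda t: objective((t * x_max,)), bounds=bounds[0], method="bounded",
                options={"xatol": 1e-10})
            best = ((float(res.x) * x_max,), float(res.fun))
        else:
            zobj = lambda z: objective(_theta_from_z(scenario, z, x_max))
            # coarse pass from every start, full optimization from the best few
            ranked_starts = sorted(starts, key=zobj)[:4]
            z_best, f_best = None, np.inf
            for z0 in ranked_starts:
                res = optimize.minimize(
                    zobj, np.asarray(z0, dtype=float), method="Nelder-Mead",
                    bounds=bounds,
                    options={"xatol": 1e-6, "fatol": 1e-10 * max(yss, 1e-30),
                             "maxiter": 400})
                if res.fun < f_best:
                    z_best, f_best = res.x, float(res.fun)
            # polish
            res = optimize.minimize(
                zobj, z_best, method="Nelder-Mead", bounds=bounds,
                options={"xatol": 1e-9, "fatol": 1e-14 * max(yss, 1e-30),
                         "maxiter": 600})
            if res.fun < f_best:
                z_best, f_best = res.x, float(res.fun)
            best = (_theta_from_z(scenario, z_best, x_max), f_best)
    if best is None or not np.isfinite(best[1]):
        raise RuntimeError(f"fit failed for scenario {scenario!r}: no converged start")
    theta, rss = best
    rss, a = _profiled_rss(scenario, theta, x_unique, inv, y)
    params = _scenario_params(scenario, theta)
    if scenario == "linear_plus_constant":
        from .barrier_model import tau_infinity
        ti = tau_infinity(params) if params is not None else 0.0
        if not np.isfinite(ti):
            ti = 0.0
    else:
        ti = float(theta[0])
    k = _n_params(scenario)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        a_val = aic(rss, scatter.n, k)
    return FitResult(scenario=scenario, params=params, a=a, rss=rss,
                     n_obs=scatter.n, n_params=k, aic=a_val, tau_inf=ti)


def tau_confidence_interval(scatter: DistanceScatter, scenario: str,
                            best: FitResult) -> tuple[float, Optional[float]]:
    """95% CI for tau_inf from the RSS profile.

    Bounds solve RSS(tau) = RSS* (1 + 1.96^2/(n-1)) with all other
    parameters re-optimized at each fixed tau; the upper bound is ``None``
    (unbounded) when the threshold is not crossed below 10x the largest
    observed sequence distance."""
    n = scatter.n
    x_max = float(scatter.x.max())
    tau_hat = best.tau_inf
    # anchor the threshold to the profile's own value at tau_hat so the
    # crossing is always bracketed even when RSS* is at numerical zero
    rss_star = max(best.rss, fit_barrier(scatter, scenario, fixed_tau=tau_hat).rss)
    threshold = rss_star * (1.0 + 1.96**2 / (n - 1))

    def excess(tau):
        return fit_barrier(scatter, scenario, fixed_tau=tau).rss - threshold

    # lower bound
    if tau_hat <= 0 or excess(max(tau_hat * 1e-9, 0.0)) <= 0:
        lower = 0.0
    else:
        lower = float(optimize.brentq(excess, max(tau_hat * 1e-9, 0.0), tau_hat,
                                      xtol=1e-12, rtol=1e-10))
    # upper bound
    tau_cap = 10.0 * x_max
    if excess(tau_cap) <= 0:
        upper: Optional[float] = None
    elif tau_hat >= tau_cap:
        upper = None
    else:
        upper = float(optimize.brentq(excess, max(tau_hat, 1e-12), tau_cap,
                                      xtol=1e-12, rtol=1e-10))
    return (lower, upper)


def fit_power_law(scatter: DistanceScatter) -> PowerLawFit:
    """Nonlinear least squares for y = b x^alpha on the original scale.

    Zero-x points are excluded (with a warning) since x^alpha is undefined
    there for alpha < 0 and uninformative for the prefactor."""
    x, y = scatter.x, scatter.y
    keep = x > 0
    if not keep.all():
        warnings.warn(f"excluding {int((~keep).sum())} points with x = 0 "
                      "from the power-law fit", RuntimeWarning)
    x, y = x[keep], y[keep]
    if x.size < 3:
        raise ValueError("too few positive-x points for a power-law fit")
    # log-log regression for the starting point (positive y only)
    pos = y > 0
    if pos.sum() >= 2:
        coef = np.polyfit(np.log(x[pos]), np.log(y[pos]), 1)
        alpha0, logb0 = float(coef[0]), float(coef[1])
    else:
        alpha0, logb0 = 1.0, 0.0

    def resid(p):
        logb, alpha = p
        return np.exp(logb + alpha * np.log(x)) - y

    res = optimize.least_squares(resid, x0=[logb0, alpha0], method="lm", xtol=1e-14,
                                 ftol=1e-14, gtol=1e-14)
    rss = float(res.fun @ res.fun)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        a_val = aic(rss, scatter.n, 2)
    return PowerLawFit(b=float(np.exp(res.x[0])), alpha=float(res.x[1]),
                       rss=rss, n_obs=scatter.n, aic=a_val)


def select_scenario(scatter: DistanceScatter,
                    scenarios: Sequence[str] = FIT_SCENARIOS,
                    with_power_law: bool = True,
                    with_ci: bool = False) -> list:
    """Fit every scenario (plus the heuristic power law) and rank by AIC.

    Individual fit failures are recorded as warnings; the ranking covers the
    successful fits.  Each returned FitResult carries its delta-AIC relative
    to the best model."""
    results: list = []
    for scenario in scenarios:
        try:
            results.append(fit_barrier(scatter, scenario))
        except Exception as exc:  # ranking proceeds over successes
            warnings.warn(f"fit failed for {scenario}: {exc}", RuntimeWarning)
    if with_power_law:
        try:
            pl = fit_power_law(scatter)
            results.append(FitResult(
                scenario="power_law_heuristic", params=None, a=pl.b, rss=pl.rss,
                n_obs=pl.n_obs, n_params=2, aic=pl.aic, tau_inf=math.nan))
        except Exception as exc:
            warnings.warn(f"power-law fit failed: {exc}", RuntimeWarning)
    if not results:
        raise RuntimeError("all scenario fits failed")
    results.sort(key=lambda r: (r.aic, r.n_params))
    best_aic = results[0].aic
    for r in results:
        r.delta_aic = r.aic - best_aic
    if with_ci:
        for r in results:
            if r.scenario in ("constant", "linear", "autocatalytic"):
                r.tau_ci = tau_confidence_interval(scatter, r.scenario, r)
    return results
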