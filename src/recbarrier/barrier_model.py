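"""Phenomenological model of recombination-barrier spread along a genome.

During the early divergence of two prokaryotic lineages, homologous
recombination (gene conversion) keeps most loci close to the population
consensus, so substitutions at those loci do not contribute to long-term
sequence divergence.  A locus starts diverging freely only once it has
crossed the *recombination barrier*.  The model tracks the fraction of the
genome still subject to recombination, ``f(t)``, which decays from 1 at the
time of the common ancestor according to a scenario-specific hazard
``R(f, t)``::

    df/dt = -R(f, t) * f,    f(0) = 1

Four hazard scenarios are supported:

* ``power_law``            R(t) = lambda0 * t**gamma  (gamma = 0: constant)
* ``linear``               R(t) = lambda1 * t
* ``linear_plus_constant`` R(t) = lambda0 + lambda1 * t
* ``autocatalytic``        R(f) = lambda0 - lambda1 * f  (barrier spread
  accelerates as more of the genome becomes isolated)

The accumulated delay of the molecular clock is ``tau(t) = int_0^t f(u) du``,
a concave saturating function with long-time limit ``tau_inf``.  The
observable per-lineage divergence is ``G(t) = mu * (t - tau(t))`` and the
pairwise divergence of two genomes that split ``t`` ago is ``2 mu (t -
tau(t))``.  All quantities are carried in substitutions-per-site units with
``mu = 1`` unless stated otherwise.

The autocatalytic scenario is also parametrized by ``(tau_inf, phi)``, in
which the observable divergence has the closed form::

    G(t) = t - tau_inf * (1 - ln(1 + e^{phi (1 - xi t / tau_inf)})
                              / ln(1 + e^phi))

with the normalizer ``xi = (1 + e^-phi) ln(1 + e^phi) / phi`` chosen so that
G(0) = 0 and G'(0) = 0.  The mapping between the two parametrizations follows
from the logistic solution of the ODE and is exposed here as conversion
utilities.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import integrate, optimize, special

__all__ = [
    "SCENARIOS",
    "BarrierParams",
    "DivergenceMap",
    "recombining_fraction",
    "crossing_density",
    "delay",
    "tau_infinity",
    "forward_divergence",
    "inverse_divergence",
    "xi_from_phi",
    "autocatalytic_rates_from_shape",
    "autocatalytic_shape_from_rates",
    "recombining_fraction_ode",
    "delay_quadrature",
    "sample_crossing_times",
]

SCENARIOS = ("power_law", "linear", "linear_plus_constant", "autocatalytic")

_ODE_RTOL = 1e-9
_QUAD_RTOL = 1e-9


def xi_from_phi(phi: float) -> float:
    """Normalizer xi ensuring G(0) = 0 and G'(0) = 0 for given sharpness phi."""
    if phi <= 0:
        raise ValueError("phi must be positive")
    # (1 + e^-phi) * ln(1 + e^phi) / phi, stable for large phi
    return (1.0 + math.exp(-phi)) * float(np.logaddexp(0.0, phi)) / phi


def autocatalytic_rates_from_shape(tau_inf: float, phi: float) -> tuple[float, float]:
    """Map (tau_inf, phi) to the hazard rates (lambda0, lambda1).

    Derived from the logistic solution of df/dt = -(lambda0 - lambda1 f) f:
    lambda0 = phi * xi / tau_inf and lambda1 = lambda0 / (1 + e^-phi).
    """
    if tau_inf <= 0:
        raise ValueError("tau_inf must be positive")
    xi = xi_from_phi(phi)
    lambda0 = phi * xi / tau_inf
    lambda1 = lambda0 / (1.0 + math.exp(-phi))
    return lambda0, lambda1


def autocatalytic_shape_from_rates(lambda0: float, lambda1: float) -> tuple[float, float]:
    """Map hazard rates (lambda0, lambda1), lambda0 > lambda1 > 0, to (tau_inf, phi)."""
    if not (lambda0 > lambda1 > 0):
        raise ValueError("autocatalytic scenario requires lambda0 > lambda1 > 0")
    r = lambda1 / lambda0
    phi = math.log(r / (1.0 - r))  # logit
    tau_inf = float(np.logaddexp(0.0, phi)) / (r * lambda0)
    return tau_inf, phi


@dataclass(frozen=True)
class BarrierParams:
    """Scenario identifier plus the rate/shape parameters of barrier crossing.

    Only the fields relevant to the chosen scenario are used; the rest stay
    ``None``.  ``xi`` is always derived from ``phi`` and never set directly.
    """

    scenario: str
    lambda0: Optional[float] = None
    lambda1: Optional[float] = None
    gamma: Optional[float] = None
    tau_inf: Optional[float] = None
    phi: Optional[float] = None

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if self.scenario == "power_law":
            if self.lambda0 is None or self.lambda0 < 0:
                raise ValueError("power_law requires lambda0 >= 0")
            g = 0.0 if self.gamma is None else self.gamma
            if g <= -1:
                raise ValueError("power_law requires gamma > -1")
            object.__setattr__(self, "gamma", g)
        elif self.scenario == "linear":
            if self.lambda1 is None or self.lambda1 < 0:
                raise ValueError("linear requires lambda1 >= 0")
        elif self.scenario == "linear_plus_constant":
            if self.lambda0 is None or self.lambda1 is None:
                raise ValueError("linear_plus_constant requires lambda0 and lambda1")
            if self.lambda0 < 0 or self.lambda1 < 0:
                raise ValueError("rates must be >= 0")
        else:  # autocatalytic
            if self.tau_inf is not None and self.phi is not None:
                if self.tau_inf <= 0 or self.phi <= 0:
                    raise ValueError("autocatalytic requires tau_inf > 0 and phi > 0")
                l0, l1 = autocatalytic_rates_from_shape(self.tau_inf, self.phi)
                object.__setattr__(self, "lambda0", l0)
                object.__setattr__(self, "lambda1", l1)
            elif self.lambda0 is not None and self.lambda1 is not None:
                ti, phi = autocatalytic_shape_from_rates(self.lambda0, self.lambda1)
                object.__setattr__(self, "tau_inf", ti)
                object.__setattr__(self, "phi", phi)
            else:
                raise ValueError(
                    "autocatalytic requires (tau_inf, phi) or (lambda0, lambda1)"
                )

    # -- convenience constructors -------------------------------------------------
    @classmethod
    def power_law(cls, lambda0: float, gamma: float = 0.0) -> "BarrierParams":
        return cls("power_law", lambda0=lambda0, gamma=gamma)

    @classmethod
    def constant(cls, rate: float) -> "BarrierParams":
        """Constant crossing hazard (power law with gamma = 0)."""
        return cls("power_law", lambda0=rate, gamma=0.0)

    @classmethod
    def linear(cls, lambda1: float) -> "BarrierParams":
        return cls("linear", lambda1=lambda1)

    @classmethod
    def linear_plus_constant(cls, lambda0: float, lambda1: float) -> "BarrierParams":
        return cls("linear_plus_constant", lambda0=lambda0, lambda1=lambda1)

    @classmethod
    def autocatalytic(cls, tau_inf: float, phi: float) -> "BarrierParams":
        return cls("autocatalytic", tau_inf=tau_inf, phi=phi)

    @property
    def xi(self) -> float:
        if self.scenario != "autocatalytic":
            raise AttributeError("xi is defined only for the autocatalytic scenario")
        return xi_from_phi(self.phi)

    # -- serialization ------------------------------------------------------------
    def to_dict(self) -> dict:
        out = {"scenario": self.scenario}
        for name in ("lambda0", "lambda1", "gamma", "tau_inf", "phi"):
            value = getattr(self, name)
            if value is not None:
                out[name] = float(value)
        return out

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_dict(cls, d: dict) -> "BarrierParams":
        d = dict(d)
        scenario = d.pop("scenario")
        if scenario == "autocatalytic" and "tau_inf" in d and "phi" in d:
            return cls.autocatalytic(d["tau_inf"], d["phi"])
        allowed = {k: d[k] for k in ("lambda0", "lambda1", "gamma", "tau_inf", "phi") if k in d}
        return cls(scenario, **allowed)

    @classmethod
    def from_json(cls, text: str) -> "BarrierParams":
        return cls.from_dict(json.loads(text))


def _check_time(t) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be non-negative")
    return t


def recombining_fraction(params: BarrierParams, t) -> np.ndarray | float:
    """Fraction f(t) of the genome still subject to gene conversion at time t.

    Closed forms are used for every scenario; f(0) = 1 and f is
    non-increasing.
    """
    t = _check_time(t)
    s = params.scenario
    if s == "power_law":
        beta = params.gamma + 1.0
        out = np.exp(-params.lambda0 * np.power(t, beta) / beta)
    elif s == "linear":
        out = np.exp(-0.5 * params.lambda1 * t * t)
    elif s == "linear_plus_constant":
        out = np.exp(-params.lambda0 * t - 0.5 * params.lambda1 * t * t)
    else:  # autocatalytic: f = (1 + e^-phi) * sigmoid(phi (1 - xi t / tau_inf))
        phi, ti = params.phi, params.tau_inf
        z = phi * (1.0 - xi_from_phi(phi) * t / ti)
        out = (1.0 + np.exp(-phi)) * special.expit(z)
    return out if out.ndim else float(out)


def crossing_density(params: BarrierParams, t) -> np.ndarray | float:
    """Probability density P(t) = -df/dt that a locus crosses the barrier at t."""
    t = _check_time(t)
    f = np.asarray(recombining_fraction(params, t), dtype=float)
    s = params.scenario
    if s == "power_law":
        # guard 0**negative for gamma < 0 at t = 0
        with np.errstate(divide="ignore"):
            hazard = params.lambda0 * np.power(t, params.gamma)
        hazard = np.where(np.isfinite(hazard), hazard, np.inf)
    elif s == "linear":
        hazard = params.lambda1 * t
    elif s == "linear_plus_constant":
        hazard = params.lambda0 + params.lambda1 * t
    else:
        hazard = params.lambda0 - params.lambda1 * f
    out = hazard * f
    return out if out.ndim else float(out)


def tau_infinity(params: BarrierParams) -> float:
    """Long-term delay tau_inf = int_0^inf f(u) du (substitutions per site)."""
    s = params.scenario
    if s == "power_law":
        if params.lambda0 == 0:
            return math.inf
        beta = params.gamma + 1.0
        c = params.lambda0 / beta
        return special.gamma(1.0 + 1.0 / beta) / c ** (1.0 / beta)
    if s == "linear":
        if params.lambda1 == 0:
            return math.inf
        return math.sqrt(math.pi / (2.0 * params.lambda1))
    if s == "linear_plus_constant":
        l0, l1 = params.lambda0, params.lambda1
        if l1 == 0:
            return math.inf if l0 == 0 else 1.0 / l0
        a = l0 / math.sqrt(2.0 * l1)
        return math.sqrt(math.pi / (2.0 * l1)) * special.erfcx(a)
    return params.tau_inf


def delay(params: BarrierParams, t) -> np.ndarray | float:
    """Recombination-driven clock delay tau(t) = int_0^t f(u) du.

    Concave, non-decreasing, tau(0) = 0, tau(t) -> tau_inf.
    """
    t = _check_time(t)
    s = params.scenario
    if s == "power_law":
        l0, beta = params.lambda0, params.gamma + 1.0
        if l0 == 0:
            out = t.copy()
        else:
            c = l0 / beta
            a = 1.0 / beta
            # int_0^t exp(-c u^beta) du via the regularized lower incomplete gamma
            out = special.gamma(a) / (beta * c**a) * special.gammainc(a, c * np.power(t, beta))
    elif s == "linear":
        l1 = params.lambda1
        if l1 == 0:
            out = t.copy()
        else:
            out = math.sqrt(math.pi / (2.0 * l1)) * special.erf(np.sqrt(0.5 * l1) * t)
    elif s == "linear_plus_constant":
        l0, l1 = params.lambda0, params.lambda1
        if l1 == 0:
            out = t.copy() if l0 == 0 else (1.0 - np.exp(-l0 * t)) / l0
        else:
            # tau(t) = sqrt(pi/(2 l1)) * [erfcx(a) - f(t) erfcx(a + s)],  a = l0/sqrt(2 l1)
            a = l0 / math.sqrt(2.0 * l1)
            sgrid = np.sqrt(0.5 * l1) * t
            f = np.exp(-l0 * t - 0.5 * l1 * t * t)
            out = math.sqrt(math.pi / (2.0 * l1)) * (special.erfcx(a) - f * special.erfcx(a + sgrid))
    else:  # autocatalytic: tau = tau_inf * ln(1 + e^z) / ln(1 + e^phi)
        phi, ti = params.phi, params.tau_inf
        z = phi * (1.0 - xi_from_phi(phi) * t / ti)
        out = ti * (1.0 - np.logaddexp(0.0, z) / np.logaddexp(0.0, phi))
    out = np.asarray(out)
    return out if out.ndim else float(out)


def recombining_fraction_ode(params: BarrierParams, t_grid) -> np.ndarray:
    """Numeric oracle: solve df/dt = -R(f, t) f with a stiff-capable integrator.

    Used to cross-check the closed forms; the closed forms are the production
    path.  For the autocatalytic scenario the equivalent linear equation for
    g = 1/f (dg/dt = lambda0 g - lambda1, the Bernoulli transform) is
    integrated instead: the nonlinear form has an exponentially unstable
    plateau for sharp sigmoids that no forward integrator can track in double
    precision, while the relative error of the linear form stays controlled.
    """
    t_grid = np.atleast_1d(np.asarray(t_grid, dtype=float))
    if np.any(np.diff(t_grid) < 0):
        raise ValueError("t_grid must be non-decreasing")

    auto = params.scenario == "autocatalytic"

    def rhs(t, y):
        if auto:
            return [params.lambda0 * y[0] - params.lambda1]
        f = y[0]
        s = params.scenario
        if s == "power_law":
            hz = params.lambda0 * t ** params.gamma if t > 0 else (
                params.lambda0 if params.gamma == 0 else 0.0)
        elif s == "linear":
            hz = params.lambda1 * t
        else:
            hz = params.lambda0 + params.lambda1 * t
        return [-hz * f]

    t_end = float(t_grid[-1]) if t_grid[-1] > 0 else 1.0
    sol = integrate.solve_ivp(
        rhs, (0.0, t_end), [1.0], method="LSODA", t_eval=np.clip(t_grid, 0, t_end),
        rtol=_ODE_RTOL, atol=1e-14,
    )
    if not sol.success:
        raise RuntimeError(f"ODE integration failed: {sol.message}")
    return 1.0 / sol.y[0] if auto else sol.y[0]


def delay_quadrature(params: BarrierParams, t: float) -> float:
    """Numeric oracle for tau(t) by adaptive quadrature of f."""
    t = float(t)
    if t < 0:
        raise ValueError("time must be non-negative")
    if t == 0:
        return 0.0
    val, err = integrate.quad(
        lambda u: recombining_fraction(params, u), 0.0, t,
        epsrel=_QUAD_RTOL, epsabs=1e-12, limit=200,
    )
    if not np.isfinite(val) or err > max(1e-8, 1e-6 * abs(val)):
        raise RuntimeError(f"quadrature did not converge (value={val}, err={err})")
    return val


@dataclass(frozen=True)
class DivergenceMap:
    """Map between true time and observed sequence divergence.

    ``forward(t) = mu (t - tau(t))`` is the per-lineage map used for tree
    heights; ``pairwise(t) = 2 mu (t - tau(t))`` is the divergence of two
    genomes that split ``t`` ago.  ``mu`` defaults to 1 so all times are in
    substitutions-per-site units.
    """

    params: BarrierParams
    mu: float = 1.0

    def __post_init__(self) -> None:
        if self.mu <= 0:
            raise ValueError("mu must be positive")

    @property
    def tau_inf(self) -> float:
        return tau_infinity(self.params)

    def forward(self, t) -> np.ndarray | float:
        t = _check_time(t)
        out = self.mu * (t - np.asarray(delay(self.params, t)))
        # clip tiny negative round-off near t = 0
        out = np.maximum(out, 0.0)
        return out if out.ndim else float(out)

    def pairwise(self, t) -> np.ndarray | float:
        out = 2.0 * np.asarray(self.forward(t))
        return out if out.ndim else float(out)

    def inverse(self, d) -> np.ndarray | float:
        """Invert the per-lineage map: find t with forward(t) = d.

        Vectorized bracketed bisection on [d/mu, d/mu + tau_inf]; the forward
        map G satisfies t - tau_inf <= G(t) <= t, so the root is bracketed.
        """
        d = np.asarray(d, dtype=float)
        if np.any(d < 0):
            raise ValueError("observed divergence must be non-negative")
        ti = self.tau_inf
        if not np.isfinite(ti):
            raise ValueError("divergence map is not invertible (infinite delay)")
        scalar = d.ndim == 0
        d = np.atleast_1d(d)
        lo = d / self.mu
        hi = lo + ti * (1.0 + 1e-12) + 1e-15
        # 70 bisection steps: bracket width reduced by 2^-70, below 1e-10 relative
        for _ in range(70):
            mid = 0.5 * (lo + hi)
            too_low = np.asarray(self.forward(mid)) < d
            lo = np.where(too_low, mid, lo)
            hi = np.where(too_low, hi, mid)
        out = 0.5 * (lo + hi)
        out[d == 0.0] = 0.0
        return float(out[0]) if scalar else out

    def inverse_pairwise(self, d) -> np.ndarray | float:
        """Total path time 2t for a pair with observed pairwise divergence d."""
        d = np.asarray(d, dtype=float)
        out = 2.0 * np.asarray(self.inverse(d / 2.0))
        return out if out.ndim else float(out)


def forward_divergence(dmap: DivergenceMap, t, pairwise: bool = False):
    """Observed divergence after time t (per-lineage, or pairwise with factor 2)."""
    return dmap.pairwise(t) if pairwise else dmap.forward(t)


def inverse_divergence(dmap: DivergenceMap, d, pairwise: bool = False):
    """True time recovering observed divergence d under the barrier process."""
    return dmap.inverse_pairwise(d) if pairwise else dmap.inverse(d)


def sample_crossing_times(params: BarrierParams, size: int, rng: np.random.Generator,
                          t_max: float | None = None) -> np.ndarray:
    """Draw barrier-crossing times from the density P(t) = -df/dt.

    Inverse-CDF sampling: the CDF is 1 - f(t), inverted by bisection.  With
    ``t_max`` set, draws are right-censored at ``t_max`` (loci that have not
    crossed by then are reported as ``t_max``), which is how crossing times
    enter finite-depth simulations.
    """
    ti = tau_infinity(params)
    if not np.isfinite(ti):
        raise ValueError("crossing density is improper (f does not decay)")
    u = rng.uniform(size=size)
    # solve f(t) = 1 - u on a bracket [0, T] with f(T) < min(1 - u)
    target = 1.0 - u
    hi = max(10.0 * ti, 1e-6)
    while recombining_fraction(params, hi) > target.min() and hi < 1e12:
        hi *= 2.0
    lo = np.zeros(size)
    hi = np.full(size, hi)
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        fmid = np.asarray(recombining_fraction(params, mid))
        above = fmid > target
        lo = np.where(above, mid, lo)
        hi = np.where(above, hi, mid)
    out = 0.5 * (lo + hi)
    if t_max is not None:
        out = np.minimum(out, t_max)
    return out
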