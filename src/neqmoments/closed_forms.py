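"""Closed-form moment trajectories for the four named demographies.

All expressions describe the equilibration of a single derived allele
that starts as a delta function at frequency ``p0`` and evolves under
strong additive purifying selection (validity roughly ``2 N s' >= 5``),
mutation, back mutation, and drift.  Constant-size forms are the direct
vectorized transcriptions of the perturbative results; the exponential
and bottleneck forms are given at their lowest vertex order, with the
longest expressions (exponential kappa_4, bottleneck kappa_3) produced by
the exact exponential-polynomial evaluation of the same diagram
integrals rather than transcribed term by term.  Bottleneck kappa_4 and
oscillating kappa_3/kappa_4 have no closed form here and are computed by
the numerical diagram engine (see :mod:`neqmoments.diagrams`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from . import demography as dem
from .diagrams import evaluate_diagram_exact
from .params import PopGenParams
from .trajectory import MomentTrajectory

logger = logging.getLogger("neqmoments")

__all__ = [
    "ExpDerived", "BottleneckDerived", "CumulantSet",
    "mean_constant", "variance_constant", "kappa3_constant", "kappa4_constant",
    "noncentral_moments_constant", "noncentral_from_cumulants",
    "kappas_exponential", "kappa2_bottleneck", "kappa3_bottleneck",
    "kappa2_oscillating", "kappa2_oscillating_asymptotic",
    "standardized_set", "asymptotic_standardized", "analytic_cumulants",
    "three_vertex_variance_asymptote", "variance_signflip_gamma",
]


@dataclass(frozen=True)
class ExpDerived:
    """Combined parameters of the exponentially growing demography."""
    gamma_prime_exp: float      # 2 N0 (s' - Gamma)
    Gamma: float


@dataclass(frozen=True)
class BottleneckDerived:
    gamma_prime_0: float        # 2 N0 s'
    gamma_prime_b: float        # 2 Nb s'


@dataclass
class CumulantSet:
    """Aligned kappa_1..kappa_4 with the standardized shape statistics."""
    kappa1: np.ndarray
    kappa2: np.ndarray
    kappa3: np.ndarray
    kappa4: np.ndarray

    @property
    def K3(self):
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(self.kappa2 > 0, self.kappa3 / self.kappa2 ** 1.5, np.nan)

    @property
    def K4(self):
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(self.kappa2 > 0, self.kappa4 / self.kappa2 ** 2, np.nan)

    @property
    def xi(self):
        """Equilibrium index (2/3) K4 / K3^2; exactly 1 at strong-selection
        mutation-selection-drift balance in a constant-size population."""
        k3 = self.K3
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(np.abs(k3) > 0, (2.0 / 3.0) * self.K4 / k3 ** 2, np.nan)


def _traj(times, values, quantity, order) -> MomentTrajectory:
    return MomentTrajectory(np.asarray(times, float), values, quantity,
                            "closed_form", order)


# ----------------------------------------------------------------------
# constant population size
# ----------------------------------------------------------------------

def mean_constant(params: PopGenParams, times, vertex_level: str = "lowest",
                  N: float | None = None) -> MomentTrajectory:
    """Mean frequency; the one-vertex form is the deterministic trajectory
    ``p0 e^{-s't} + lambda'(1 - e^{-s't})`` shared by all demographies."""
    t = np.asarray(times, dtype=float)
    sp, lp, p0, s = params.s_prime, params.lambda_prime, params.p0, params.s
    x = np.exp(-sp * t)
    vals = p0 * x + lp * (1.0 - x)
    if vertex_level == "lowest":
        return _traj(t, vals, "kappa1", 1)
    if N is None:
        raise ValueError("three-vertex mean needs the population size N")
    g = params.gamma_prime(N)
    st = sp * t
    vals = vals + (s * p0 ** 2 / sp) * (x - x ** 2) \
        + (2.0 * s * lp * p0 / sp) * ((st - 1.0) * x + x ** 2) \
        + (s * lp ** 2 / sp) * (1.0 - 2.0 * st * x - x ** 2) \
        + (s * p0 / (g * sp)) * ((st - 1.0) * x + x ** 2) \
        + (s * lp / (2.0 * g * sp)) * (1.0 - 2.0 * st * x - x ** 2)
    return _traj(t, vals, "kappa1", 3)


def variance_constant(params: PopGenParams, N: float, times,
                      vertex_level: str = "lowest") -> MomentTrajectory:
    t = np.asarray(times, dtype=float)
    sp, lp, p0 = params.s_prime, params.lambda_prime, params.p0
    g = params.gamma_prime(N)
    x = np.exp(-sp * t)
    vals = (p0 / g) * x * (1.0 - x) + (lp / (2.0 * g)) * (1.0 - x) ** 2
    if vertex_level == "lowest":
        return _traj(t, vals, "kappa2", 2)
    st = sp * t
    # three-vertex tree terms (high-frequency drift fed by p0/mutation)
    d5 = -(p0 ** 2 / g) * st * x ** 2 \
        - (2.0 * p0 * lp / g) * (x - (st + 1.0) * x ** 2) \
        - (lp ** 2 / (2.0 * g)) * (1.0 - 4.0 * x + (2.0 * st + 3.0) * x ** 2)
    # one-loop drift self-interaction terms
    d6 = -(p0 / g ** 2) * (x - (st + 1.0) * x ** 2) \
        - (lp / (4.0 * g ** 2)) * (1.0 - 4.0 * x + (2.0 * st + 3.0) * x ** 2)
    return _traj(t, vals + d5 + d6, "kappa2", 3)


def kappa3_constant(params: PopGenParams, N: float, times) -> MomentTrajectory:
    t = np.asarray(times, dtype=float)
    sp, lp, p0 = params.s_prime, params.lambda_prime, params.p0
    g = params.gamma_prime(N)
    x = np.exp(-sp * t)
    vals = (3.0 * p0 / (2.0 * g ** 2)) * x * (1.0 - x) ** 2 \
        + (lp / (2.0 * g ** 2)) * (1.0 - x) ** 3
    return _traj(t, vals, "kappa3", 3)


def kappa4_constant(params: PopGenParams, N: float, times) -> MomentTrajectory:
    t = np.asarray(times, dtype=float)
    sp, lp, p0 = params.s_prime, params.lambda_prime, params.p0
    g = params.gamma_prime(N)
    x = np.exp(-sp * t)
    vals = (3.0 * p0 / g ** 3) * x * (1.0 - x) ** 3 \
        + (3.0 * lp / (4.0 * g ** 3)) * (1.0 - x) ** 4
    return _traj(t, vals, "kappa4", 4)


def three_vertex_variance_asymptote(params: PopGenParams, N: float) -> float:
    """t -> infinity limit of the three-vertex variance,
    lambda'(2 gamma'(1 - lambda') - 1) / (4 gamma'^2); negative once
    gamma' drops below the sign-flip threshold."""
    lp = params.lambda_prime
    g = params.gamma_prime(N)
    return lp * (2.0 * g * (1.0 - lp) - 1.0) / (4.0 * g ** 2)


def variance_signflip_gamma(params: PopGenParams) -> float:
    """gamma' at which the late-time three-vertex variance changes sign:
    1 / (2 (1 - lambda')), approaching 1/2 in the weak-mutation limit."""
    return 1.0 / (2.0 * (1.0 - params.lambda_prime))


def noncentral_from_cumulants(k1, k2, k3, k4, order: int):
    """Assemble E[p^n] from cumulants (moment-cumulant relations)."""
    if order == 1:
        return k1
    if order == 2:
        return k2 + k1 ** 2
    if order == 3:
        return k3 + 3.0 * k2 * k1 + k1 ** 3
    if order == 4:
        return k4 + 4.0 * k3 * k1 + 3.0 * k2 ** 2 + 6.0 * k2 * k1 ** 2 + k1 ** 4
    raise ValueError("order must be 1..4")


def noncentral_moments_constant(params: PopGenParams, N: float, times,
                                order: int) -> MomentTrajectory:
    t = np.asarray(times, dtype=float)
    k1 = mean_constant(params, t).values
    k2 = variance_constant(params, N, t).values
    k3 = kappa3_constant(params, N, t).values
    k4 = kappa4_constant(params, N, t).values
    vals = noncentral_from_cumulants(k1, k2, k3, k4, order)
    return _traj(t, vals, f"m{order}", None)


# ----------------------------------------------------------------------
# exponential growth N(t) = N0 exp(Gamma t)
# ----------------------------------------------------------------------

_POLE_REL = 1e-9
_POLE_EPS = 1e-6


def _exp_pole_distance(sp: float, Gamma: float) -> float:
    return min(abs(sp - Gamma), abs(2.0 * sp - Gamma),
               abs(3.0 * sp - 2.0 * Gamma), abs(4.0 * sp - 3.0 * Gamma))


def kappas_exponential(params: PopGenParams, N0: float, Gamma: float, times,
                       order: int) -> MomentTrajectory:
    """kappa_2..kappa_4 at lowest vertex order in an exponentially growing
    population; kappa_1 keeps the deterministic constant-size form.

    Near the denominators' poles (Gamma close to s', 2s', 3s'/2, 4s'/3)
    the trajectory is evaluated as the centred average at Gamma +/- eps,
    which approximates the analytic limit with O(eps^2) error.
    """
    if order == 1:
        return mean_constant(params, times)
    if order not in (2, 3, 4):
        raise ValueError("order must be 1..4")
    sp = params.s_prime
    if _exp_pole_distance(sp, Gamma) < _POLE_REL * sp and Gamma != 0.0:
        eps = _POLE_EPS * sp
        logger.warning("growth rate within pole guard of s'; using centred "
                       "limit evaluation at Gamma +/- %.3g", eps)
        lo = kappas_exponential(params, N0, Gamma - eps, times, order)
        hi = kappas_exponential(params, N0, Gamma + eps, times, order)
        return _traj(lo.times, 0.5 * (lo.values + hi.values),
                     f"kappa{order}", lo.vertex_order)

    t = np.asarray(times, dtype=float)
    lp, p0 = params.lambda_prime, params.p0
    gx = 2.0 * N0 * (sp - Gamma)            # gamma'_exp
    if order == 2:
        e = np.exp
        vals = p0 * (e(-(sp + Gamma) * t) - e(-2 * sp * t)) / gx \
            + lp * (sp * e(-2 * sp * t) + (sp - Gamma) * e(-Gamma * t)
                    + (Gamma - 2 * sp) * e(-(Gamma + sp) * t)) \
            / (gx * (2 * sp - Gamma))
        return _traj(t, vals, "kappa2", 2)
    if order == 3:
        e = np.exp
        vals = 3.0 * p0 * e(-sp * t) * (e(-Gamma * t) - e(-sp * t)) ** 2 \
            / (2.0 * gx ** 2) \
            + (3.0 * lp / (2.0 * gx ** 2)) * (
                e(-2 * Gamma * t) * (1.0 - e(-sp * t))
                - 2 * sp * e(-Gamma * t) * (e(-Gamma * t) - e(-2 * sp * t))
                / (2 * sp - Gamma)
                + sp * (e(-2 * Gamma * t) - e(-3 * sp * t)) / (3 * sp - 2 * Gamma))
        return _traj(t, vals, "kappa3", 3)
    # kappa_4: sum of the chain and fan drift diagrams, evaluated exactly.
    d = dem.exponential(N0, Gamma)
    total = np.zeros_like(t)
    for did in ("D8L", "D8R", "D9L", "D9R"):
        total = total + evaluate_diagram_exact(did, params, d, t).values
    return _traj(t, total, "kappa4", 4)


# ----------------------------------------------------------------------
# square bottleneck
# ----------------------------------------------------------------------

def kappa2_bottleneck(params: PopGenParams, N0: float, Nb: float,
                      Ti: float, Tb: float, times) -> MomentTrajectory:
    """Lowest-order variance through a square bottleneck.

    The trajectory splits into three temporal slices: the persistent
    constant-N0 piece, a transient switched on at the bottleneck onset
    Ti, and a second transient switched on at re-expansion Ti + Tb; the
    persistent piece equilibrates back to lambda'/(2 gamma'_0).
    """
    t = np.asarray(times, dtype=float)
    sp, lp, p0 = params.s_prime, params.lambda_prime, params.p0
    g0 = 2.0 * N0 * sp
    gb = 2.0 * Nb * sp
    e = np.exp
    x = e(-sp * t)
    theta_i = (t > Ti).astype(float)
    theta_ib = (t > Ti + Tb).astype(float)
    base = (p0 / g0 + (lp / (2.0 * g0)) * (e(sp * t) - 1.0)) * (x - x ** 2)
    jump = (1.0 / (2.0 * gb) - 1.0 / (2.0 * g0))
    during = theta_i * (2.0 * p0 + lp * (e(sp * t) + e(sp * Ti) - 2.0)) \
        * (x - e(-2.0 * sp * t + sp * Ti))
    after = theta_ib * (2.0 * p0 + lp * (e(sp * t) + e(sp * (Ti + Tb)) - 2.0)) \
        * (e(-2.0 * sp * t + sp * (Ti + Tb)) - x)
    return _traj(t, base + jump * (during + after), "kappa2", 2)


def kappa3_bottleneck(params: PopGenParams, N0: float, Nb: float,
                      Ti: float, Tb: float, times) -> MomentTrajectory:
    """Lowest-order third cumulant through a square bottleneck, from the
    exact piecewise evaluation of the two drift-chain diagrams (the
    printed form of this trajectory is long; the exact algebra gives the
    identical piecewise-exponential expression)."""
    t = np.asarray(times, dtype=float)
    d = dem.bottleneck(N0, Nb, Ti, Tb)
    vals = (evaluate_diagram_exact("D7L", params, d, t).values
            + evaluate_diagram_exact("D7R", params, d, t).values)
    return _traj(t, vals, "kappa3", 3)


# ----------------------------------------------------------------------
# oscillating (cyclical) population size
# ----------------------------------------------------------------------

def kappa2_oscillating(params: PopGenParams, Nmax: float, Nmin: float,
                       tau: float, times) -> MomentTrajectory:
    """Lowest-order variance in the reciprocal-cosine cyclical demography."""
    t = np.asarray(times, dtype=float)
    sp, lp, p0 = params.s_prime, params.lambda_prime, params.p0
    a = sp * tau
    pi = np.pi
    phi = 2.0 * pi * t / tau
    np_, nm = Nmax + Nmin, Nmax - Nmin
    x = np.exp(-sp * t)
    part1 = (p0 / (4.0 * Nmax * Nmin * sp * (4.0 * pi ** 2 + a ** 2))) * (
        4.0 * pi ** 2 * np_ * x * (1.0 - x)
        + a ** 2 * (np_ - 2.0 * Nmin * x) * x
        - nm * a * (a * np.cos(phi) + 2.0 * pi * np.sin(phi)) * x)
    denom = 4.0 * pi ** 4 + 5.0 * pi ** 2 * a ** 2 + a ** 4
    part2 = (lp / (8.0 * Nmax * Nmin * sp * denom)) * (
        np_ * ((4.0 * pi ** 4 + 3.0 * pi ** 2 * a ** 2) * (1.0 - x) ** 2
               + (2.0 * pi ** 2 * a ** 2 + a ** 4) * (1.0 - 2.0 * x))
        + (4.0 * pi ** 2 * Nmax * a ** 2 + 2.0 * Nmin * a ** 4) * x ** 2
        - nm * a * (2.0 * a * (a ** 2 + pi ** 2) * np.cos(phi) * x
                    + (3.0 * pi ** 2 + (a ** 2 + pi ** 2) * (1.0 - 4.0 * x))
                    * (pi * np.sin(phi) + a * np.cos(phi))))
    return _traj(t, part1 + part2, "kappa2", 2)


def kappa2_oscillating_asymptotic(params: PopGenParams, Nmax: float, Nmin: float,
                                  tau: float, times) -> MomentTrajectory:
    """Late-time variance: oscillation around lambda'/(2 * 2 Nbar_osc s'),
    the mutation-selection-drift variance of a constant population at the
    harmonic-mean effective size, with a selection-dependent phase lag."""
    t = np.asarray(times, dtype=float)
    sp, lp = params.s_prime, params.lambda_prime
    a = sp * tau
    pi = np.pi
    phi = 2.0 * pi * t / tau
    np_, nm = Nmax + Nmin, Nmax - Nmin
    denom = 4.0 * pi ** 4 + 5.0 * pi ** 2 * a ** 2 + a ** 4
    vals = (lp * np_ / (8.0 * Nmax * Nmin * sp)) * (
        1.0 - (4.0 * pi ** 2 * a + a ** 3) / denom * (nm / np_)
        * (pi * np.sin(phi) + a * np.cos(phi)))
    return _traj(t, vals, "kappa2", 2)


# ----------------------------------------------------------------------
# standardized statistics
# ----------------------------------------------------------------------

def standardized_set(k1: MomentTrajectory, k2: MomentTrajectory,
                     k3: MomentTrajectory, k4: MomentTrajectory) -> CumulantSet:
    """Combine aligned cumulant trajectories into a :class:`CumulantSet`.

    K3, K4 and xi are NaN wherever kappa_2 (or kappa_3, for xi) vanishes,
    e.g. at t = 0 where the distribution is a delta function.
    """
    for other in (k2, k3, k4):
        if other.times.shape != k1.times.shape or \
                not np.allclose(other.times, k1.times):
            raise ValueError("cumulant trajectories are on different grids")
    return CumulantSet(k1.values, k2.values, k3.values, k4.values)


def analytic_cumulants(params: PopGenParams, demog, times,
                       n_steps: int | None = None) -> dict[int, MomentTrajectory]:
    """kappa_1..kappa_4 for a named demography, routed to the closed forms
    where one exists and to the numerical diagram engine otherwise
    (bottleneck kappa_4, oscillating kappa_3 and kappa_4)."""
    from .diagrams import cumulant_via_diagrams
    times = np.asarray(times, dtype=float)
    p = demog.params
    out = {1: mean_constant(params, times)}
    if demog.kind == "constant":
        out[2] = variance_constant(params, p["N"], times)
        out[3] = kappa3_constant(params, p["N"], times)
        out[4] = kappa4_constant(params, p["N"], times)
    elif demog.kind == "exponential":
        for o in (2, 3, 4):
            out[o] = kappas_exponential(params, p["N0"], p["Gamma"], times, o)
    elif demog.kind == "bottleneck":
        out[2] = kappa2_bottleneck(params, p["N0"], p["Nb"], p["Ti"], p["Tb"], times)
        out[3] = kappa3_bottleneck(params, p["N0"], p["Nb"], p["Ti"], p["Tb"], times)
        out[4] = cumulant_via_diagrams(4, params, demog, times, n_steps=n_steps)
    elif demog.kind == "oscillating":
        out[2] = kappa2_oscillating(params, p["Nmax"], p["Nmin"], p["tau"], times)
        for o in (3, 4):
            out[o] = cumulant_via_diagrams(o, params, demog, times, n_steps=n_steps)
    else:
        for o in (2, 3, 4):
            out[o] = cumulant_via_diagrams(o, params, demog, times, n_steps=n_steps)
    return out


def asymptotic_standardized(params: PopGenParams, N: float) -> dict:
    """t -> infinity strong-selection values at constant size: K3 and K4
    depend only on the population-scaled mutation rate, and xi = 1."""
    lp = params.lambda_prime
    g = params.gamma_prime(N)
    k2 = lp / (2.0 * g)
    k3 = lp / (2.0 * g ** 2)
    k4 = 3.0 * lp / (4.0 * g ** 3)
    K3 = k3 / k2 ** 1.5
    K4 = k4 / k2 ** 2
    return {"K3": K3, "K4": K4, "xi": (2.0 / 3.0) * K4 / K3 ** 2}
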