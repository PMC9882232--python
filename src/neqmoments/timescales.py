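"""Equilibration timescales and the time of maximal transient variance.

The equilibration time of a moment is defined by the "factor of ten"
construction: the time at which the decaying part of the trajectory has
fallen to one tenth of the asymptotic value.  For the n-th cumulant at
constant population size this gives

    t_eq(kappa_n) ~ (1/s') * ln(10 n |p0 - lambda'| / lambda'),

where the factor n comes from the linear expansion of (1 - e^{-s't})^n
in the mutation term.  These are order-of-magnitude constructions, not
sharp thresholds; they are reported as real numbers, with an integer
floor provided for convenience.

The standardized skew and excess kurtosis equilibrate at half the rate
(their leading deviation is O(e^{-2s't}) because the first-order terms of
kappa_n and the normalizing power of kappa_2 cancel):

    K3(t) ~ K3_inf * (1 - (3/2) (p0/lambda')^2 e^{-2s't})
    K4(t) ~ K4_inf * (1 - 4     (p0/lambda')^2 e^{-2s't})

so t_eq(K3) = ln(15 (p0/lambda')^2)/(2s') and
t_eq(K4) = ln(40 (p0/lambda')^2)/(2s'), a fixed gap of ln(8/3)/(2s').
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .closed_forms import kappas_exponential, variance_constant
from .params import ParameterError, PopGenParams

__all__ = [
    "EquilibrationTime", "t_eq_mean", "t_eq_cumulant", "t_eq_standardized",
    "t_var_max", "t_var_max_numeric", "burnin_recommendation",
    "floor_generations",
]


@dataclass(frozen=True)
class EquilibrationTime:
    quantity: str
    t_eq: float                 # generations, real-valued
    formula_valid: bool         # False at poles / outside the derivation's regime


def floor_generations(t: float) -> int:
    """Integer part of an equilibration time, in generations.

    The times come from logarithms of round parameter ratios and are
    order-of-magnitude constructions, so the value is rounded to two
    decimals before flooring; this keeps a time sitting within numerical
    noise of an integer (e.g. 17.9977) from dropping a whole generation.
    """
    return int(math.floor(round(t, 2)))


def _t_eq(params: PopGenParams, factor: float, quantity: str,
          rate_half: bool = False) -> EquilibrationTime:
    sp, lp, p0 = params.s_prime, params.lambda_prime, params.p0
    if lp == 0.0:
        raise ParameterError("equilibration times need a nonzero mutation rate")
    if p0 == lp:
        raise ParameterError("equilibration time is singular at p0 = lambda'")
    arg = factor * abs(p0 - lp) / lp
    rate = 2.0 * sp if rate_half else sp
    t = math.log(arg) / rate
    valid = t >= 0.0
    return EquilibrationTime(quantity, t, valid)


def t_eq_mean(params: PopGenParams) -> EquilibrationTime:
    """Equilibration time of the mean frequency, ln(10 |p0-l'|/l')/s'."""
    return _t_eq(params, 10.0, "kappa1")


def t_eq_cumulant(params: PopGenParams, n: int) -> EquilibrationTime:
    """Equilibration time of kappa_n, ln(10 n |p0-l'|/l')/s'.

    The derivation of the n >= 2 times assumes p0 > lambda'; outside that
    regime the value is still returned but flagged (formula_valid=False),
    since the slowest surviving exponential is then not guaranteed to
    dominate.  The n >= 5 extension follows the same ln(10 n) pattern but
    is unverified beyond the fourth cumulant.
    """
    if n < 1:
        raise ValueError("cumulant order must be >= 1")
    res = _t_eq(params, 10.0 * n, f"kappa{n}")
    if n >= 2 and params.p0 <= params.lambda_prime:
        res = EquilibrationTime(res.quantity, res.t_eq, False)
    return res


def t_eq_standardized(params: PopGenParams, N: float, which: str) -> EquilibrationTime:
    """Equilibration time of the standardized skew (K3) or excess
    kurtosis (K4); both scale as 1/(2 s')."""
    sp, lp, p0 = params.s_prime, params.lambda_prime, params.p0
    if which not in ("K3", "K4"):
        raise ValueError("which must be 'K3' or 'K4'")
    if p0 <= 0.0 or lp == 0.0:
        return EquilibrationTime(which, float("-inf"), False)
    coef = 1.5 if which == "K3" else 4.0
    arg = 10.0 * coef * (p0 / lp) ** 2
    t = math.log(arg) / (2.0 * sp)
    valid = t >= 0.0 and params.gamma_prime(N) >= 1.0
    return EquilibrationTime(which, t, valid)


def t_var_max(params: PopGenParams, Gamma: float = 0.0) -> float:
    """Approximate time of the transient variance maximum,
    ln(2s'/(s'+Gamma))/(s'-Gamma); ln(2)/s' at constant size.  Valid in
    the new-mutation regime mu << p0.  At the removable point s' = Gamma
    the limit 1/(2 s') is returned.
    """
    sp = params.s_prime
    d = sp - Gamma
    if abs(d) < 1e-9 * sp:
        return 1.0 / (2.0 * sp)
    return math.log(2.0 * sp / (sp + Gamma)) / d


def t_var_max_numeric(params: PopGenParams, N: float, Gamma: float = 0.0,
                      t_hi: float | None = None) -> float:
    """Time of maximal variance from the root of d(kappa_2)/dt, found by
    bracketing and bisecting the centred finite difference of the
    closed-form trajectory (constant size, or exponential growth)."""
    sp = params.s_prime

    def kappa2(t):
        t = np.atleast_1d(np.asarray(t, dtype=float))
        if Gamma == 0.0:
            return variance_constant(params, N, t).values
        return kappas_exponential(params, N, Gamma, t, 2).values

    def dk2(t):
        h = max(1e-4 / sp, 1e-6 * t)
        lo = max(t - h, 0.0)
        return ((kappa2(t + h) - kappa2(lo)) / (t + h - lo)).item()

    if t_hi is None:
        t_hi = 50.0 / sp if Gamma <= sp else 50.0 / Gamma
    ts = np.geomspace(1e-3 / sp, t_hi, 400)
    vals = kappa2(ts)
    i = int(np.argmax(vals))
    if i == 0 or i == len(ts) - 1:
        raise ValueError("variance maximum not bracketed in (0, t_hi)")
    return brentq(dk2, ts[i - 1], ts[i + 1], xtol=1e-6 / sp)


def burnin_recommendation(params: PopGenParams, N: float, max_order: int = 4) -> float:
    """Suggested simulation burn-in: ten times the slowest requested
    cumulant's equilibration time, capped at the neutral coalescent-bound
    8N generations."""
    t = max(t_eq_cumulant(params, n).t_eq for n in range(1, max_order + 1))
    return min(10.0 * max(t, 0.0), 8.0 * N)
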