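"""Deterministic diploid population-size histories N(t).

Four named demographies are provided, matching the parameterizations used
throughout the analytics:

* ``constant``: N(t) = N.
* ``exponential``: N(t) = N0 * exp(Gamma * t).
* ``bottleneck``: a square bottleneck -- size N0 until generation Ti,
  size Nb for the following Tb generations, then N0 again.  The switch
  uses the left-continuous Heaviside convention (Theta(0) = 0): the size
  at exactly t = Ti is still N0, and at exactly t = Ti + Tb is still Nb.
* ``oscillating``: N(t) = 2*Nmax*Nmin / ((Nmax+Nmin) + (Nmin-Nmax)*cos(2*pi*t/tau)),
  a tau-periodic population that starts at Nmax and reaches Nmin at every
  half period.  Its harmonic-mean effective size over one period is
  exactly 2*Nmax*Nmin/(Nmax+Nmin).

``size_at`` returns real (un-rounded) sizes; integer rounding is applied
only inside the Wright-Fisher simulator.  An arbitrary callable N(t) is
also accepted for use with the numerical diagram engine.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
from scipy.optimize import minimize_scalar

from .params import ParameterError


@dataclass(frozen=True)
class Demography:
    kind: str                      # constant | exponential | bottleneck | oscillating | callable
    params: dict = field(default_factory=dict)
    func: Optional[Callable[[np.ndarray], np.ndarray]] = None

    # -- size evaluation ------------------------------------------------

    def size_at(self, t):
        """Real-valued diploid size N(t); t may be a scalar or array, t >= 0."""
        t_arr = np.asarray(t, dtype=float)
        if np.any(t_arr < 0):
            raise ValueError("demography is defined for t >= 0 only")
        p = self.params
        if self.kind == "constant":
            out = np.full_like(t_arr, float(p["N"]))
        elif self.kind == "exponential":
            out = p["N0"] * np.exp(p["Gamma"] * t_arr)
        elif self.kind == "bottleneck":
            inside = (t_arr > p["Ti"]) & (t_arr <= p["Ti"] + p["Tb"])
            out = np.where(inside, float(p["Nb"]), float(p["N0"]))
        elif self.kind == "oscillating":
            out = _osc_size(t_arr, p["Nmax"], p["Nmin"], p["tau"], p.get("phase", 0.0))
        elif self.kind == "callable":
            out = np.asarray(self.func(t_arr), dtype=float)
        else:  # pragma: no cover
            raise ValueError(f"unknown demography kind {self.kind!r}")
        return out if out.ndim else float(out)

    def drift_coupling_at(self, t):
        """Time-dependent drift-vertex coupling 1 / (4 N(t))."""
        return 1.0 / (4.0 * np.asarray(self.size_at(t), dtype=float))

    # -- structure hints used by the integrators ------------------------

    def breakpoints(self, t_max: float) -> list[float]:
        """Interior discontinuity times of N(t) within (0, t_max)."""
        if self.kind != "bottleneck":
            return []
        p = self.params
        return [b for b in (p["Ti"], p["Ti"] + p["Tb"]) if 0.0 < b < t_max]

    def min_size(self, t_max: float) -> float:
        """Minimum of N(t) over [0, t_max] (used by the validity check)."""
        p = self.params
        if self.kind == "constant":
            return float(p["N"])
        if self.kind == "exponential":
            return float(p["N0"] * math.exp(min(0.0, p["Gamma"]) * t_max)
                         if p["Gamma"] < 0 else p["N0"])
        if self.kind == "bottleneck":
            return float(p["Nb"] if p["Ti"] < t_max else p["N0"])
        if self.kind == "oscillating":
            return float(p["Nmin"] if t_max >= p["tau"] / 2.0
                         else np.min(self.size_at(np.linspace(0.0, t_max, 2049))))
        res = minimize_scalar(lambda u: float(self.size_at(u)),
                              bounds=(0.0, t_max), method="bounded")
        return float(min(res.fun, self.size_at(0.0), self.size_at(t_max)))


def _osc_size(t, nmax, nmin, tau, phase):
    denom = (nmax + nmin) + (nmin - nmax) * np.cos(2.0 * np.pi * t / tau + phase)
    return 2.0 * nmax * nmin / denom


# -- constructors --------------------------------------------------------

def constant(N: float) -> Demography:
    if N <= 0:
        raise ParameterError("N must be positive")
    return Demography("constant", {"N": float(N)})


def exponential(N0: float, Gamma: float) -> Demography:
    if N0 <= 0:
        raise ParameterError("N0 must be positive")
    return Demography("exponential", {"N0": float(N0), "Gamma": float(Gamma)})


def bottleneck(N0: float, Nb: float, Ti: float, Tb: float) -> Demography:
    if N0 <= 0 or Nb <= 0:
        raise ParameterError("population sizes must be positive")
    if Ti <= 0 or Tb <= 0:
        raise ParameterError("Ti and Tb must be positive")
    return Demography("bottleneck", {"N0": float(N0), "Nb": float(Nb),
                                     "Ti": float(Ti), "Tb": float(Tb)})


def oscillating(Nmax: float, Nmin: float, tau: float, phase: float = 0.0) -> Demography:
    if Nmin <= 0 or Nmax < Nmin:
        raise ParameterError("require Nmax >= Nmin > 0")
    if tau <= 0:
        raise ParameterError("period tau must be positive")
    return Demography("oscillating", {"Nmax": float(Nmax), "Nmin": float(Nmin),
                                      "tau": float(tau), "phase": float(phase)})


def from_callable(func: Callable[[np.ndarray], np.ndarray]) -> Demography:
    return Demography("callable", {}, func=func)


def effective_size_osc(Nmax: float, Nmin: float) -> float:
    """Harmonic-mean effective size of the oscillating demography.

    For the reciprocal-cosine parameterization the harmonic mean of N(t)
    over one period is exactly the harmonic mean of Nmax and Nmin.
    """
    if Nmin <= 0 or Nmax < Nmin:
        raise ParameterError("require Nmax >= Nmin > 0")
    return 2.0 * Nmax * Nmin / (Nmax + Nmin)
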