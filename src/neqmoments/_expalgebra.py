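"""Exact algebra on piecewise exponential-polynomial functions.

The time-ordered integrals behind every moment trajectory are nested
convolutions of exponentials against the drift coupling 1/(4 N(t)).  For
the named demographies that coupling is itself a sum of (complex)
exponentials -- a constant, ``exp(-Gamma t)``, a piecewise constant, or
``a + b cos(w t)`` -- so every intermediate stage stays inside the ring of
functions of the form::

    f(xi) = sum_j  c_j * xi**m_j * exp(r_j * xi)        (per segment)

with complex rates ``r_j`` and integer powers ``m_j``.  This module
implements that ring (sum, product, antiderivative, and the causal
convolution against a decaying propagator) exactly, which turns the
diagram integrals for the exponential, bottleneck, and oscillating
demographies into closed forms evaluated to machine precision, with no
quadrature.  Polynomial factors appear automatically whenever two rates
collide (the "pole" cases such as Gamma = 2 s').

Segments use local coordinates ``xi = t - T_j`` so that carried boundary
values never require exponentially large coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

# Rates closer than this (relative to the dominant decay scale) are merged;
# exact pole cases then promote a polynomial factor instead of dividing by
# a vanishing rate difference.
_RATE_TOL = 1e-12


class ExpPoly:
    """A finite sum of terms c * x**m * exp(r*x) on a single interval."""

    __slots__ = ("terms", "scale")

    def __init__(self, terms=None, scale=1.0):
        # terms: dict {(r, m): c} with complex r, int m >= 0, complex c
        self.terms = dict(terms) if terms else {}
        self.scale = scale  # characteristic rate magnitude for zero tests

    # -- construction ---------------------------------------------------

    @classmethod
    def exponential(cls, coeff, rate, scale=1.0):
        return cls({(complex(rate), 0): complex(coeff)}, scale=scale)

    @classmethod
    def const(cls, coeff, scale=1.0):
        return cls({(0j, 0): complex(coeff)}, scale=scale)

    def _zero_rate(self, r) -> bool:
        return abs(r) <= _RATE_TOL * max(self.scale, 1e-300)

    # -- ring operations ------------------------------------------------

    def __add__(self, other: "ExpPoly") -> "ExpPoly":
        out = dict(self.terms)
        for key, c in other.terms.items():
            out[key] = out.get(key, 0j) + c
        return ExpPoly(out, scale=max(self.scale, other.scale))

    def scaled(self, a) -> "ExpPoly":
        return ExpPoly({k: a * c for k, c in self.terms.items()}, scale=self.scale)

    def __mul__(self, other: "ExpPoly") -> "ExpPoly":
        out: dict = {}
        for (r1, m1), c1 in self.terms.items():
            for (r2, m2), c2 in other.terms.items():
                key = (r1 + r2, m1 + m2)
                out[key] = out.get(key, 0j) + c1 * c2
        return ExpPoly(out, scale=max(self.scale, other.scale))

    def shift_rate(self, dr) -> "ExpPoly":
        """Multiply by exp(dr * x)."""
        return ExpPoly({(r + dr, m): c for (r, m), c in self.terms.items()},
                       scale=self.scale)

    # -- calculus -------------------------------------------------------

    def antiderivative(self) -> "ExpPoly":
        """An antiderivative, term by term (integration constant 0-ish).

        For r != 0 uses the by-parts recursion
        ``int x^m e^{rx} = x^m e^{rx}/r - (m/r) int x^{m-1} e^{rx}``.
        """
        out: dict = {}

        def _acc(key, c):
            out[key] = out.get(key, 0j) + c

        for (r, m), c in self.terms.items():
            if self._zero_rate(r):
                _acc((0j, m + 1), c / (m + 1))
                continue
            coef = c
            mm = m
            while mm > 0:
                _acc((r, mm), coef / r)
                coef = -coef * mm / r
                mm -= 1
            _acc((r, 0), coef / r)
        return ExpPoly(out, scale=self.scale)

    def eval_at(self, x):
        x = np.asarray(x, dtype=float)
        total = np.zeros(x.shape, dtype=complex)
        for (r, m), c in self.terms.items():
            if c == 0:
                continue
            # combine the (possibly huge/tiny) coefficient with the
            # exponential in the exponent to avoid overflow at large x
            term = np.exp(r * x + np.log(complex(c)))
            if m:
                term = term * x ** m
            total += term
        return total

    def value0(self) -> complex:
        """Value at x = 0 (only m == 0 terms contribute)."""
        return sum(c for (r, m), c in self.terms.items() if m == 0)

    def convolve_decay(self, k: float, y0=0j) -> "ExpPoly":
        """g(x) = e^{-kx} y0 + int_0^x e^{-k(x-u)} f(u) du, exactly."""
        shifted = self.shift_rate(complex(k))
        H = shifted.antiderivative()
        g = H.shift_rate(-complex(k))
        boundary = y0 - H.value0()
        g = g + ExpPoly.exponential(boundary, -k, scale=self.scale)
        return ExpPoly(g.terms, scale=max(self.scale, abs(k)))


@dataclass
class PiecewiseExpPoly:
    """ExpPoly functions on consecutive segments [T_j, T_{j+1})."""

    boundaries: Sequence[float]       # T_0 = 0 < T_1 < ... < T_{k-1}; last open-ended
    pieces: list                      # list of ExpPoly in local coords t - T_j

    def __post_init__(self):
        assert len(self.pieces) == len(self.boundaries)
        assert self.boundaries[0] == 0.0

    # -- construction ---------------------------------------------------

    @classmethod
    def from_global_exponentials(cls, terms, boundaries, scale=1.0):
        """terms: iterable of (coeff, rate) meaning sum c*exp(r*t) globally."""
        pieces = []
        for T in boundaries:
            seg = {}
            for c, r in terms:
                key = (complex(r), 0)
                seg[key] = seg.get(key, 0j) + complex(c) * np.exp(complex(r) * T)
            pieces.append(ExpPoly(seg, scale=scale))
        return cls(list(boundaries), pieces)

    @classmethod
    def piecewise_const(cls, values, boundaries, scale=1.0):
        return cls(list(boundaries),
                   [ExpPoly.const(v, scale=scale) for v in values])

    # -- operations -----------------------------------------------------

    def _check(self, other):
        if list(other.boundaries) != list(self.boundaries):
            raise ValueError("segmentations differ")

    def __add__(self, other):
        self._check(other)
        return PiecewiseExpPoly(self.boundaries,
                                [a + b for a, b in zip(self.pieces, other.pieces)])

    def __mul__(self, other):
        self._check(other)
        return PiecewiseExpPoly(self.boundaries,
                                [a * b for a, b in zip(self.pieces, other.pieces)])

    def scaled(self, a):
        return PiecewiseExpPoly(self.boundaries, [p.scaled(a) for p in self.pieces])

    def convolve_decay(self, k: float) -> "PiecewiseExpPoly":
        """Causal convolution with e^{-k dt}, carrying values across segments."""
        out = []
        y0 = 0j
        bounds = list(self.boundaries) + [None]
        for j, piece in enumerate(self.pieces):
            g = piece.convolve_decay(k, y0=y0)
            out.append(g)
            if bounds[j + 1] is not None:
                seg_len = bounds[j + 1] - bounds[j]
                y0 = complex(g.eval_at(seg_len))
        return PiecewiseExpPoly(self.boundaries, out)

    def eval_at(self, t):
        t = np.atleast_1d(np.asarray(t, dtype=float))
        idx = np.searchsorted(self.boundaries, t, side="right") - 1
        out = np.zeros(t.shape, dtype=complex)
        for j, piece in enumerate(self.pieces):
            mask = idx == j
            if np.any(mask):
                out[mask] = piece.eval_at(t[mask] - self.boundaries[j])
        return out

    def eval_real(self, t):
        return self.eval_at(t).real
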