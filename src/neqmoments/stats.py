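"""Cumulant estimation from per-site allele frequencies, with Monte-Carlo
standard errors.

Estimators use population (divide-by-n) moment formulas, matching the
simulator's own recording; with the 10^4--10^5 sites typically averaged,
the O(1/L) bias of these estimators is negligible relative to their
sampling noise.  Monomorphic sites are always included in the averages.
Standard errors come from site-level bootstrap resampling (the sites are
independent by construction).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import ParameterError

__all__ = ["MomentEstimate", "cumulants_from_freqs", "mean_stderr",
           "bootstrap_cumulants", "cumulants_from_noncentral",
           "block_cumulant_se"]


@dataclass(frozen=True)
class MomentEstimate:
    value: float
    stderr: float
    n_sites: int


def _kappas(p: np.ndarray, max_order: int) -> dict:
    out = {"kappa1": float(np.mean(p))}
    d = p - out["kappa1"]
    c = {k: float(np.mean(d ** k)) for k in range(2, max_order + 1)}
    if max_order >= 2:
        out["kappa2"] = c[2]
    if max_order >= 3:
        out["kappa3"] = c[3]
    if max_order >= 4:
        out["kappa4"] = c[4] - 3.0 * c[2] ** 2
    if out.get("kappa2", 0.0) > 0.0:
        k2 = out["kappa2"]
        if max_order >= 3:
            out["K3"] = out["kappa3"] / k2 ** 1.5
        if max_order >= 4:
            out["K4"] = out["kappa4"] / k2 ** 2
            if out.get("K3"):
                out["xi"] = (2.0 / 3.0) * out["K4"] / out["K3"] ** 2
    return out


def cumulants_from_freqs(freqs, max_order: int = 4) -> dict:
    """Cumulants kappa_1..kappa_max_order of the site-frequency sample,
    plus the standardized K3, K4 and the equilibrium index xi where the
    variance (and skew, for xi) is nonzero."""
    p = np.asarray(freqs, dtype=float)
    if p.size < 2:
        raise ParameterError("need at least two sites")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("frequencies must lie in [0, 1]")
    if not 2 <= max_order <= 4:
        raise ValueError("max_order must be 2..4")
    out = _kappas(p, max_order)
    out["n_sites"] = p.size
    return out


def cumulants_from_noncentral(m: np.ndarray) -> np.ndarray:
    """k1..k4 (last axis) from non-central moments m1..m4 (last axis)."""
    m1, m2, m3, m4 = (m[..., i] for i in range(4))
    k1 = m1
    k2 = m2 - m1 ** 2
    k3 = m3 - 3 * m2 * m1 + 2 * m1 ** 3
    c4 = m4 - 4 * m3 * m1 + 6 * m2 * m1 ** 2 - 3 * m1 ** 4
    k4 = c4 - 3 * k2 ** 2
    return np.stack([k1, k2, k3, k4], axis=-1)


def mean_stderr(freqs) -> MomentEstimate:
    """Standard error of the mean frequency, sqrt(kappa_2 / L).

    This is the sampling noise of the per-generation mean over L sites;
    it inflates whenever the allele-frequency variance does (e.g. during
    a bottleneck).
    """
    p = np.asarray(freqs, dtype=float)
    if p.size < 2:
        raise ParameterError("standard error of the mean needs >= 2 sites")
    k2 = float(np.var(p))
    return MomentEstimate(float(np.mean(p)), np.sqrt(k2 / p.size), p.size)


def bootstrap_cumulants(freqs, max_order: int = 4, n_boot: int = 200,
                        seed: int = 0) -> dict:
    """Site-level bootstrap estimates (value +/- stderr) of the cumulants
    and standardized statistics."""
    p = np.asarray(freqs, dtype=float)
    point = cumulants_from_freqs(p, max_order)
    rng = np.random.default_rng(seed)
    keys = [k for k in point if k != "n_sites"]
    samples = {k: [] for k in keys}
    for _ in range(n_boot):
        rep = _kappas(p[rng.integers(0, p.size, p.size)], max_order)
        for k in keys:
            samples[k].append(rep.get(k, np.nan))
    out = {}
    for k in keys:
        arr = np.asarray(samples[k], dtype=float)
        out[k] = MomentEstimate(point[k], float(np.nanstd(arr)), p.size)
    return out


def block_cumulant_se(block_noncentral: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Cumulant estimates and standard errors from per-block moments.

    ``block_noncentral`` has shape (T, B, 4) -- non-central moments
    m1..m4 of B disjoint site blocks at T time points (as recorded by the
    simulator).  Returns ``(kappas, se)`` of shape (T, 4): the pooled
    estimate and the standard error of the across-block mean.
    """
    kb = cumulants_from_noncentral(block_noncentral)     # (T, B, 4)
    B = kb.shape[1]
    est = cumulants_from_noncentral(block_noncentral.mean(axis=1))
    se = kb.std(axis=1, ddof=1) / np.sqrt(B)
    return est, se
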