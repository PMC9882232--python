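"""Population-genetic parameters and derived combined constants.

Every analytic result in this package is driven by three numbers derived
from the raw inputs:

* ``s_prime = s + mu + mu_b`` -- the effective selection coefficient, the
  total per-generation rate at which deterministic forces pull the derived
  allele frequency down (purifying selection, saturation of the mutational
  target, and back mutation).
* ``lambda_prime = mu / s_prime`` -- the mutation-selection balance
  frequency, the asymptote of the mean frequency.
* ``gamma_prime = 2 N s_prime`` -- the population-scaled selection
  strength; ``1 / gamma_prime`` is the small parameter of the perturbative
  expansion, and the approximations are trustworthy for
  ``gamma_prime >= ~5``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

logger = logging.getLogger("neqmoments")

#: Default population-scaled selection cutoff below which the perturbative
#: approximations degrade (a ~20% correction from the next order).
GAMMA_PRIME_THRESHOLD = 5.0


class ParameterError(ValueError):
    """Raised for population-genetic parameters outside their domain."""


@dataclass(frozen=True)
class PopGenParams:
    """Parameters of a single biallelic site under additive selection.

    ``s`` is the heterozygote selection coefficient, stored positive for
    deleterious selection; the simulator maps it to signed fitness
    internally.  ``t0`` is fixed at zero by convention: all times are
    generations since the initial condition ``p(0) = p0``.
    """

    s: float
    mu: float
    mu_b: float
    p0: float
    t0: float = 0.0

    @property
    def s_prime(self) -> float:
        return self.s + self.mu + self.mu_b

    @property
    def lambda_prime(self) -> float:
        return self.mu / self.s_prime

    def gamma_prime(self, n_diploid: float) -> float:
        """Population-scaled effective selection 2*N*s' for diploid size N."""
        return 2.0 * n_diploid * self.s_prime


@dataclass(frozen=True)
class EfficacyReport:
    """Outcome of the strong-selection validity check over a time window."""

    gamma_prime_min: float
    threshold: float
    in_regime: bool


def make_params(s: float, mu: float = 0.0, mu_b: float = 0.0,
                p0: float = 0.0) -> PopGenParams:
    """Validate raw parameters and return a :class:`PopGenParams`.

    Raises
    ------
    ParameterError
        If ``s <= 0``, a mutation rate is negative, or ``p0`` is outside
        ``[0, 1)``.
    """
    if not (s > 0.0) or not math.isfinite(s):
        raise ParameterError(f"selection coefficient must be positive, got {s}")
    if mu < 0.0 or mu_b < 0.0:
        raise ParameterError(f"mutation rates must be non-negative, got {mu}, {mu_b}")
    if not (0.0 <= p0 < 1.0):
        raise ParameterError(f"initial frequency must be in [0, 1), got {p0}")
    return PopGenParams(s=float(s), mu=float(mu), mu_b=float(mu_b), p0=float(p0))


def efficacy_check(params: PopGenParams, demography, t_max: float,
                   threshold: float = GAMMA_PRIME_THRESHOLD) -> EfficacyReport:
    """Check 2*N(t)*s' >= threshold over the evaluation window [0, t_max].

    Being out of regime is a warning condition, not an error: evaluation
    proceeds, but the perturbative trajectories should be interpreted with
    care (and compared against simulation).
    """
    if not t_max > 0:
        raise ParameterError(f"t_max must be positive, got {t_max}")
    n_min = demography.min_size(t_max)
    gmin = 2.0 * n_min * params.s_prime
    ok = gmin >= threshold
    if not ok:
        logger.warning(
            "out of strong-selection regime: min 2*N(t)*s' = %.3g < %.3g",
            gmin, threshold)
    return EfficacyReport(gamma_prime_min=gmin, threshold=threshold, in_regime=ok)
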