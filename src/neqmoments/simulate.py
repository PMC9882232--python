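"""Forward Wright-Fisher simulation of independently evolving sites.

L biallelic sites evolve independently (the infinite-recombination
limit) under diploid selection, binomial drift, Poisson mutation and
back mutation, and a deterministic demography N(t).  Each generation:

1. selection acts on the expected frequency through the standard diploid
   post-selection formula (fitnesses 1+s_hom, 1+s_het, 1 for the three
   genotypes, assuming Hardy-Weinberg proportions);
2. drift draws the new count from Binomial(2 N_{t+1}, p_bar), where
   N_{t+1} is the (rounded) demography size at the offspring generation;
3. mutation adds Poisson(mu * (2 N_{t+1} - n)) new copies and back
   mutation removes Poisson(mu_b * n), so fixed alleles can "un-fix";
4. counts are clamped to [0, 2 N_{t+1}] (excess -> fixation, deficit ->
   extinction).

The population mean of the first five non-central moments, central
moments, and cumulants across sites is recorded for each of the first
ten generations and every ``printgen`` generations thereafter.  The CLI
accepts a positive deleterious coefficient ``s`` and maps it to additive
fitness effects s_het = -s, s_hom = -2s; raw signed overrides are
allowed for dominance experiments (no analytic counterpart is provided
for those).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .demography import Demography
from .params import ParameterError, PopGenParams

__all__ = ["SimConfig", "SimResult", "expected_freq_after_selection",
           "step", "run"]


def expected_freq_after_selection(p, s_hom: float, s_het: float):
    """Deterministic post-selection frequency for a diploid population.

    ``s_hom`` and ``s_het`` are signed fitness effects (> -1); for a
    deleterious additive allele of strength s they are -2s and -s.  The
    boundaries p = 0, 1 are fixed points, and a deleterious allele never
    increases in expected frequency.
    """
    if s_hom <= -1.0 or s_het <= -1.0:
        raise ParameterError("fitness effects must exceed -1")
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("frequencies must lie in [0, 1]")
    q = 1.0 - p
    num = (1.0 + s_hom) * p * p + (1.0 + s_het) * p * q
    den = (1.0 + s_hom) * p * p + 2.0 * (1.0 + s_het) * p * q + q * q
    out = num / den
    return out if out.ndim else float(out)


@dataclass
class SimConfig:
    L: int
    generations: int
    params: PopGenParams
    demography: Demography
    init_count: int = 1
    printgen: int = 10
    burnin: int = 0
    seed: int = 0
    s_het: Optional[float] = None       # signed override; default -params.s
    s_hom: Optional[float] = None       # signed override; default -2*params.s
    record: Sequence[str] = ("noncentral", "central", "cumulants")
    n_blocks: int = 0                   # per-block moments for resampling SEs

    def fitness_effects(self) -> tuple[float, float]:
        sh = -self.params.s if self.s_het is None else self.s_het
        sH = 2.0 * sh if self.s_hom is None else self.s_hom
        return sH, sh

    def validate(self) -> None:
        if self.L < 1:
            raise ParameterError("need at least one site")
        n0 = _round_size(self.demography.size_at(0.0))
        if not (0 <= self.init_count <= 2 * n0):
            raise ParameterError("init_count must be within [0, 2 N(0)]")
        if self.printgen < 1:
            raise ParameterError("printgen must be >= 1")


@dataclass
class SimResult:
    times: np.ndarray                   # recorded generations
    pop_size: np.ndarray                # diploid N at each recorded generation
    noncentral: np.ndarray              # (T, 5): mean of p^1..p^5 over sites
    central: np.ndarray                 # (T, 4): central moments c2..c5
    cumulants: np.ndarray               # (T, 5): k1..k5
    block_noncentral: Optional[np.ndarray] = None   # (T, n_blocks, 4)
    metadata: dict = field(default_factory=dict)

    def freqs_at(self, index: int):  # pragma: no cover - convenience only
        raise NotImplementedError("per-site frequencies are not stored; "
                                  "use run(..., return_freqs=True)")


def _round_size(n: float) -> int:
    """Half-up rounding of the demography to whole diploid individuals."""
    n_int = int(np.floor(n + 0.5))
    if n_int < 1:
        raise ParameterError(f"demography fell below one diploid individual ({n})")
    return n_int


def step(counts: np.ndarray, n_next: int, mu: float, mu_b: float,
         s_hom: float, s_het: float, n_curr: int,
         rng: np.random.Generator) -> np.ndarray:
    """Advance all sites by one generation; returns the new counts."""
    p = counts / (2.0 * n_curr)
    p_bar = expected_freq_after_selection(p, s_hom, s_het)
    n = rng.binomial(2 * n_next, p_bar)
    n = n + rng.poisson(mu * (2 * n_next - n)) - rng.poisson(mu_b * n)
    return np.clip(n, 0, 2 * n_next)


def _moments(p: np.ndarray):
    m = np.array([np.mean(p ** k) for k in range(1, 6)])
    d = p - m[0]
    c = np.array([np.mean(d ** k) for k in range(2, 6)])
    k = np.array([m[0], c[0], c[1],
                  c[2] - 3.0 * c[0] ** 2,
                  c[3] - 10.0 * c[1] * c[0]])
    return m, c, k


def run(config: SimConfig, return_freqs: bool = False) -> SimResult:
    """Run the simulation; deterministic given ``config.seed``."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    s_hom, s_het = config.fitness_effects()
    mu, mu_b = config.params.mu, config.params.mu_b
    n0 = _round_size(config.demography.size_at(0.0))
    counts = np.full(config.L, config.init_count, dtype=np.int64)

    for _ in range(config.burnin):
        counts = step(counts, n0, mu, mu_b, s_hom, s_het, n0, rng)

    record_times = sorted(set(range(min(10, config.generations + 1)))
                          | set(range(0, config.generations + 1, config.printgen))
                          | {config.generations})
    rec_set = set(record_times)

    times, sizes, m_rows, c_rows, k_rows, b_rows = [], [], [], [], [], []
    blocks = None
    if config.n_blocks:
        edges = np.linspace(0, config.L, config.n_blocks + 1).astype(int)
        blocks = list(zip(edges[:-1], edges[1:]))

    def record(t, n_curr):
        p = counts / (2.0 * n_curr)
        m, c, k = _moments(p)
        times.append(t)
        sizes.append(n_curr)
        m_rows.append(m)
        c_rows.append(c)
        k_rows.append(k)
        if blocks:
            b_rows.append(np.array([[np.mean(p[a:b] ** j) for j in range(1, 5)]
                                    for a, b in blocks]))

    n_curr = n0
    if 0 in rec_set:
        record(0, n_curr)
    for t in range(config.generations):
        n_next = _round_size(config.demography.size_at(float(t + 1)))
        counts = step(counts, n_next, mu, mu_b, s_hom, s_het, n_curr, rng)
        n_curr = n_next
        if (t + 1) in rec_set:
            record(t + 1, n_curr)

    result = SimResult(
        times=np.array(times, dtype=float),
        pop_size=np.array(sizes, dtype=float),
        noncentral=np.array(m_rows),
        central=np.array(c_rows),
        cumulants=np.array(k_rows),
        block_noncentral=np.array(b_rows) if b_rows else None,
        metadata={
            "L": config.L, "generations": config.generations,
            "seed": config.seed, "init_count": config.init_count,
            "printgen": config.printgen, "burnin": config.burnin,
            "s": config.params.s, "mu": mu, "mu_b": mu_b,
            "s_hom": s_hom, "s_het": s_het,
            "demography": {"kind": config.demography.kind,
                           **config.demography.params},
            "record": list(config.record),
        },
    )
    if return_freqs:
        return result, counts / (2.0 * n_curr)
    return result
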