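# Methods

## Model and assumptions

A single biallelic site carries a derived allele at frequency p(t) in a
diploid population of deterministic size N(t).  The allele is
deleterious and additive (heterozygote coefficient s > 0, homozygote
2s), gains copies by recurrent mutation at rate μ per individual per
generation, loses them by back mutation at rate μ_b, and fluctuates by
binomial drift.  All analytics linearize the dynamics around the
low-frequency regime maintained by strong selection: the trajectories
are perturbative expansions whose small parameter is 1/γ'(t) with
γ'(t) = 2N(t)s' and s' = s + μ + μ_b.  The working validity cutoff is
γ' ≥ 5 everywhere on the evaluation window (a ~20% next-order
correction at the boundary); `efficacy_check` reports the minimum of
2N(t)s' and warns — rather than refuses — outside the regime, because
the approach to breakdown is itself informative.

Time is measured in generations from the initial condition
p(0) = p₀ ∈ [0, 1), a delta-function start representing, e.g., a new
mutation at p₀ = 1/2N(0).  Sites are completely unlinked, so L-site
summaries are averages of i.i.d. trajectories.

## Trajectories and the two evaluation routes

Every cumulant contribution is a time-ordered integral: products of
propagators G(t₂,t₁) = Θ(t₂−t₁)e^{−s'(t₂−t₁)} (left-continuous Θ, so
G(t,t) = 0) connected at interaction vertices whose couplings are p₀
(pinned at t = 0), μ (integrated over its occurrence time), s, and
±1/(4N(t_v)) for the two drift vertices.  Because every propagator
factorizes over the vertex times, a bundle of k parallel edges crossing
an inter-vertex interval decays at k·s', and each registered diagram
reduces to a chain (or a small tree) of one-dimensional causal
convolutions.  The registry in `diagrams.py` stores, per diagram, the
vertex sequence, the effective bundle multiplicities, and the
combinatorial counting factor.  All counting factors were re-derived
by direct integration and are locked by tests against the printed
constant-size trajectories; they are never free parameters.

Two independent evaluation routes exist:

1. **Numerical engine** (`evaluate_diagram`): each convolution is
   advanced with an exact exponential integrator (the source linearly
   interpolated per step, recursion evaluated by `scipy.signal.lfilter`)
   on a mesh that is graded dyadically toward t = 0 — the cumulants
   vanish polynomially there and a uniform mesh loses all relative
   accuracy — and split at demography discontinuities so no step
   straddles a bottleneck edge.  Output values are sampled with a
   monotone cubic (PCHIP) interpolant.  Default resolution is
   ~400 steps per 1/s' (at least 20 000 overall, and ≥200 steps per
   oscillation period), giving relative errors ≲10⁻⁵ against the exact
   route.  The "maximally connected" fourth-cumulant topology, whose
   two drift branches are mutually unordered, is evaluated per output
   time with a backward pass for the shared branch factor followed by a
   Simpson quadrature.  A direct simplex-quadrature fallback exists for
   the one- and two-vertex diagrams purely as a cross-check.

2. **Exact algebra** (`evaluate_diagram_exact`): for the four named
   demographies the drift coupling 1/4N(t) is a sum of (complex)
   exponentials — constant, e^{−Γt}, piecewise constant, or
   a + b·cos(2πt/τ) — so every intermediate stage stays in the ring of
   piecewise c·ξ^m·e^{rξ} functions.  Sums, products, antiderivatives
   and causal convolutions are closed-form in that ring, making this
   route a machine-precision closed form.  Rate collisions (the poles
   Γ ∈ {s', 2s', 3s'/2, 4s'/3} of the printed exponential-demography
   formulas) automatically promote polynomial factors instead of
   dividing by zero; *near*-collisions are handled one level up by
   evaluating at Γ ± ε (ε = 10⁻⁶ s') and averaging, an O(ε²)
   approximation of the analytic limit.  Segments use local time
   coordinates so carried boundary values never need exponentially
   large coefficients, and evaluation combines coefficients and
   exponentials in the exponent to avoid overflow.  Two stability
   limits are respected: the branch-factor construction for the
   maximally connected fourth-cumulant diagrams cancels catastrophically
   beyond s't ≈ 18 for the oscillatory coupling, so that combination is
   delegated to the numerical engine (as are all piecewise fan cases).

`closed_forms.py` exposes the literal vectorized transcriptions where
the printed expressions are reliable (all constant-size forms, the
exponential variance and third cumulant, the bottleneck variance, the
oscillating variance and its late-time form) and uses the exact algebra
where the source rendering is corrupted (exponential fourth cumulant,
bottleneck third cumulant); the two are cross-locked in the tests, and
both are compared against the numerical engine.  The bottleneck fourth
cumulant and the oscillating third and fourth cumulants are
engine-only by design.

## Timescales

Equilibration times use the "factor of ten" construction: the time at
which the slowest-decaying exponential has fallen to a tenth of the
asymptote, giving t_eq(κ_n) = ln(10·n·|p₀−λ'|/λ')/s'.  These are
order-of-magnitude quantities; `floor_generations` reports the integer
part after rounding to two decimals so that values within numerical
noise of an integer (17.9977 at s = 10^{-1/2}) do not lose a whole
generation to the floor discontinuity.  The derivation of the n ≥ 2
times presumes p₀ > λ'; outside that regime the value is returned but
flagged.  For the standardized K₃ and K₄ the leading O(e^{−s't})
deviations cancel between numerator and normalization, leaving

    K₃(t) ≈ K₃∞ (1 − (3/2)(p₀/λ')² e^{−2s't})
    K₄(t) ≈ K₄∞ (1 − 4(p₀/λ')² e^{−2s't}),

so t_eq(K₃) = ln(15(p₀/λ')²)/2s' and t_eq(K₄) = ln(40(p₀/λ')²)/2s',
separated by ln(8/3)/2s'.  These two were re-derived here from the
second-order expansion (the residuals at t_eq, checked numerically, are
5–6%, inside the ≤10% the construction promises); the expansion is
asymptotic, so treat them as scale estimates when (p₀/λ')e^{−s't} ~ 1.
The transient variance maximum is ln(2s'/(s'+Γ))/(s'−Γ) (ln 2/s' for
constant size), with a bracketed-bisection numerical root of dκ₂/dt as
the exact counterpart.  The suggested simulation burn-in is ten times
the slowest requested cumulant's t_eq, capped at the neutral 8N bound.

## Wright–Fisher simulator

L sites evolve independently.  Per generation: diploid selection on the
expected frequency with fitnesses (1+s_hom, 1+s_het, 1) — the positive
CLI coefficient s maps to s_het = −s, s_hom = −2s — then a binomial
draw of 2N_{t+1} copies, then Poisson mutation with target 2N_{t+1}−n
and Poisson back mutation with target n, then clamping to [0, 2N_{t+1}]
(so fixation and extinction are absorbing only until the next mutation
event; fixed alleles can un-fix).  The demography is evaluated at the
offspring generation index and rounded half-up to whole individuals.
The first ten generations and every `printgen`-th thereafter are
recorded as site-averages of the first five non-central moments,
central moments, and cumulants; optional disjoint site blocks provide
resampling standard errors for any derived statistic.  Runs are exactly
reproducible from the seed (single `numpy` Generator).

Two systematic gaps between the simulator and the continuous-time
analytics are expected and documented rather than corrected away:

* **Discrete generations.**  The stationary variance of the
  per-generation recursion is μ/(4Ns'²)·(1−s'/2)⁻¹ — a +5.3% offset at
  s' = 0.1 (observed +4.9% in simulation).  Tests that resolve the
  stationary level at this selection strength compare against the
  corrected value.
* **First-generations moments.**  One binomial generation from a delta
  start yields κ₄ ≈ p₀/(2N)³ where the diffusion-limit trajectory gives
  3p₀/(2N)³; the gap fades after a few generations as integrated
  contributions dominate.  The densely recorded generations t = 1…9
  therefore deviate in κ₃/κ₄ by O(1) with very small sampling errors.

## What the synthetic runs do and do not show

The simulator *is* the package's data generator: delta-function starts,
unlinked sites, constant rates, deterministic demographies.  Agreement
between it and the analytics validates the perturbative machinery under
exactly the model's assumptions; it says nothing about linkage,
dominance, fluctuating selection, or sampling noise of real cohorts
(finite-sample binomial downsampling corrections are out of scope).
The comparison statistic is a per-time-point z-score using block
(site-level) resampling standard errors, with a ±5 SE band.  For the
mean and variance this is well calibrated and ≥95% of reported points
agree in all four demographies at L = 2·10⁴.  For κ₃ and especially κ₄
the band is intrinsically anti-conservative at this number of sites:
the estimators are dominated by a handful of high-frequency sites, so
realizations that happen to lack them undershoot the estimate and its
resampling SE *jointly*.  Drawing L = 2·10⁴ i.i.d. frequencies from the
exact equilibrium Gamma(4Nμ, 2Ns') distribution — no simulator
involved — reproduces the effect (coverage ≈0.95 for κ₃ and ≈0.83 for
κ₄ at 5 SE).  The corresponding κ₃/κ₄ agreement assertions are kept at
the stringent nominal level and fail by these calibration margins;
widening the band or substituting a temporal-scatter SE (which was
tested) would mask the genuine breakdown signature below γ' ≈ 5 — at
2Ns' = 3 the simulated late-time variance sits 51% above the analytic
curve, at 2Ns' = 5 21%, at 2Ns' = 200 only the discrete-generation 5% —
and is not done.

## Default study conditions

Simulation validation runs use the four demographies at their
reference parameterizations — constant N = 10³; exponential N₀ = 10³,
Γ = 10⁻³ (2 000 generations); bottleneck N₀ = 10⁴ → N_b = 10³ at
T_i = 10³ for T_b = 10³ (4 000 generations); oscillating
N_max = 10⁴, N_min = 10³, τ = 10³ (5 000 generations) — with
s = 10⁻¹, μ = 10⁻⁶, μ_b = μ/100, one copy per site at t = 0, and
L = 2·10⁴ sites (10⁵ for the scalar ξ check), recording every 10
generations.  These sizes keep the full validation suite to a few
minutes on one core while leaving every comparison inside its
Monte-Carlo resolution.
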