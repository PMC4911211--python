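# Methods

## Model

A complex genetic disorder is represented by N functional modules of the
biological interaction network. Disease requires every module to be in
its disease-permissive state simultaneously. Each module evolves
independently as a three-state continuous-time Markov chain:

- **naive → mature** at rate 1/τ (exponential maturation, mean τ years);
  the mature state is permissive with probability F (the module disease
  propensity, MDP) and protective with probability 1 − F;
- **mature protective → permissive** at the slow failure rate 1/T
  (T ≫ τ), following the reliability-theory view of aging as the failure
  of redundant non-aging components.

With modules naive-protective at birth the permissive state is
absorbing, so the probability that a module is permissive by age x is a
phase-type hitting CDF and equals the bracket

    B(x) = (1 − w)(1 − e^(−x/τ)) + w(1 − e^(−x/T)),  w = (1 − F)/(1 − τ/T).

The onset CDF is the product of the brackets over modules; under the
mean-field homogenization (geometric means τ, T, Φ across modules) it is
B(x)^N, and the age-specific incidence is I(x) = N B′(x) B(x)^(N−1).
A naive-*permissive* module type is also provided for the general model;
its permissive-state occupancy P(x) = e^(−x/τ) + F(e^(−x/T) −
e^(−x/τ))/(1 − τ/T) is derived from the corresponding transition matrix
(it is an occupancy, not a CDF, because the permissive state is not
absorbing there). The product over modules is then a joint occupancy; it
reduces to the onset CDF in the all-protective default. Onset
simulation is restricted to naive-protective networks, where onset age
is exactly the maximum of the per-module permissive-entry times.

**Scale convention.** Registry rates (per 100,000 person-years) are
compared with I(x)·10⁵, i.e. the unconditional onset density stands in
for the hazard. With lifetime risk Φ^N ≲ 0.4% the two differ by less
than half a percent, far below registry noise.

**Numerics.** The T → ∞ limit is an explicit branch (w → 1 − Φ; used
whenever T/τ > 10¹²) to avoid cancellation; `expm1` is used at small
ages. Binned evaluation defaults to the bin midpoint (published curves
are plotted at bin centres); a 5-point Gauss–Legendre bin average is
available and differs from the midpoint by < 1% on 5-year bins.

## Fitting

`IncidenceModel.fit` minimizes Σ_bins (10⁵·I(midpoint) − rate)² over
(τ, T, Φ) for each candidate integer N, using box-constrained L-BFGS-B
on (τ, log₁₀T, Φ) — T is optimized on a log scale because its profile is
a long, flat ridge. Multi-start (default 32 seeded draws: τ ~ U[1,40],
Φ ~ U[0.05,0.95], log₁₀T ~ U over [50, 10⁵] y) guards against the ridge;
the seed is recorded in the result so fits are bitwise reproducible. N
is profiled over an integer grid and never relaxed to a continuous
value: the exponent is structurally a module count. An optional
Poisson-variance weighting (`loss="poisson_weighted_ls"`) is available
when person-years are known; unweighted least squares is the default
because it is the conventional registry-fitting choice. R² is reported
against the table mean; it is NaN for a zero-variance table and may be
negative for models worse than the mean. Identifiability, measured on
noiseless synthetic registries: τ and Φ recover to ≤ 2%, T only to
~25% (documented ridge); the profile over N is shallow, with many N
fitting nearly equally well — `profile_N` exposes this rather than
hiding it.

## Environmental-transition simulation

The published account of this sub-model is unavailable; the
implementation is this package's reconstruction, built from three named,
swappable ingredients and constrained by the published phenomenology
(rising young-adult peak between ages 20–30 stabilizing a few decades
after t₅₀; annual incidence below a quarter of its eventual maximum at
t₅₀; annual incidence peaking about four decades after t₅₀ with a small
decline after).

1. **Rollout**: the exposed population fraction is logistic in calendar
   time with scale `transition_width` (default 10 y), reaching ½ at t₅₀.
2. **Propensity coupling**: a module stabilizing at calendar time t is
   permissive with probability Φ₁ + (Φ₂ − Φ₁)ε(t) — exposure status is
   drawn at stabilization time (mean-field across modules).
3. **Transient destabilization**: during a fixed calendar era (default
   [t₅₀, t₅₀ + 40 y]) mature protective modules fail at 1/T* instead of
   1/T. The era is anchored on decade-by-decade registry fits during the
   North-American outbreak, where the fitted failure time dropped to
   ~350 y around the transition and returned to ~1000 y three to four
   decades later; it is deliberately *not* tied to the rollout width.
   An alternative `destabilize="legacy"` strategy restricts the fast
   failure to modules that stabilized before their carrier's exposure.

For a cohort born in year b the per-module permissive CDF is an
integral over the stabilization age with the piecewise-constant failure
rate integrated in closed form; it is evaluated by Gauss–Legendre
quadrature segmented at the era boundaries (192 nodes; era-edge kinks
would otherwise cost ~10⁻³ relative accuracy, segmented panels reach
~10⁻⁷). The onset CDF is the N-th power, and cross-sectional curves are
assembled cohort-wise: the incidence at age x and calendar time t is the
onset density at age x of the cohort born in t − x, because the
secular phenomenology is inherently a cohort effect. The annual
population series averages the cross-sectional curve over a population
age structure (default uniform 0–90 y; configurable weights). A
Monte-Carlo cohort simulator mirrors the same model (per-module
exposure Bernoulli at stabilization; failure times drawn by analytic
inversion of the piecewise-linear cumulative rate) and is required to
agree with the quadrature within binomial error.

What the reconstruction does **not** reproduce: the transient second
incidence peak in the oldest age groups reported around four decades
after t₅₀. Within this model family (exchangeable modules,
age-independent exposure) the old-age incidence N·r·prot(x)·B(x)^(N−1)
is monotone in age — the growth of B^(N−1) with age dominates the decay
of the protective pool — so no interior old-age maximum can form.
Reproducing it likely requires an ingredient we cannot recover from the
published description, such as age-dependent exposure adoption. The
peak-detection utility (3-point moving-average smoothing, strict
interior maxima) is provided and tested on constructed curves.
Robustness: the reported conclusions (annual peak decade, quarter bound
at t₅₀, post-transition peak ages) are invariant to the rollout width
across 5–40 y, although absolute curve heights at fixed decades are not
(the exposed fraction at a given decade necessarily depends on the
width).

## Genetics layer

A locus with risk-allele frequency p affects one module; F denotes that
module's MDP among carriers (dominant coding: carriers versus
protective-allele homozygotes). For a rare disease

    OR = (1 − p)² F / (Φ − (1 − (1 − p)²) F),

with fixed point OR = 1 ⇔ F = Φ, strictly increasing in F, and the
algebraic inverse F = OR·Φ/((1−p)² + OR(2p − p²)). The density g of
carrier MDPs implied by an OR distribution ν and a RAF distribution ρ is
computed by a change of variables; the integration uses u = OR as the
variable, where the Jacobians combine into the smooth integrand
ν(u)·Φ·√q·ρ(1 − √q)/(2x|Φ − x|) with q = u(Φ−x)/(x(1−u)). The reachable
odds ratios at MDP value x are [x/Φ, ∞) above Φ and (0, x/Φ] below, so
finite ν supports are integrated exactly (per-histogram-bin
Gauss–Legendre panels) and never missed. g has an integrable
logarithmic singularity at x = Φ whenever ν's support touches OR = 1
(every locus with p → 1 maps to F → Φ); since genome-wide-significant
risk alleles have ORs bounded away from 1, analyses use a left-truncated
log-normal ν (mode 1.1, σ = 0.15, truncated at 1.02 — mode and spread
chosen to emulate the published susceptibility-locus catalogue) and
histogram comparisons are made bin-averaged, which is also what a
sampled catalogue estimates.

The detection-power correction reweights an observed OR histogram by
the inverse power of a carrier-contrast two-proportion z-test at
genome-wide significance (α = 5×10⁻⁸; default 20,000 cases / 30,000
controls, configurable), either at a representative RAF or marginalized
over ρ by quadrature. The exact published correction is unknown; this
reconstruction is a named, swappable strategy.

## Synthetic data

All generators are pure functions of (config, seed), drawing each
module from its own spawned substream so cohorts are bitwise
reproducible. The registry generator uses 5-year bins to age 90 and
5×10⁶ person-years per bin by default — a plausibility choice giving
Poisson scatter comparable to the visual scatter of national registries,
not a published value. Censoring at `max_age` (default 90 y) mirrors
registry truncation; censored individuals appear as `inf` onset ages.
Passing tests on these data demonstrate internal consistency of model,
simulator and fitter under exchangeable-module, stationary-exposure
assumptions; they do not validate the model against real registries,
which carry diagnostic drift, age-structure change and mortality that
the generator deliberately omits.

## Problem sizes

The test suite uses 10⁶-individual cohorts for closed-form/simulation
equivalence, 50 replicate registries for the noise study, 10⁶ draws for
distributional oracles, and 4×10⁵–10⁶ draws for quadrature/Monte-Carlo
agreement in the transition model; the full suite runs in well under a
minute on one CPU.
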