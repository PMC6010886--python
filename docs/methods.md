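# Methods

## Model and conditioning

`treerates` models each phylogeny as a reconstructed constant-rate
birth–death process started from the two crown lineages, with
per-lineage speciation rate λ, extinction rate μ (both per unit time,
≥ 0), and a known sampling fraction ρ ∈ (0, 1] under which each extant
species enters the tree independently (missing-at-random). The
likelihood of a tree is conditioned on its crown age *t*₁ and on both
crown lineages leaving sampled descendants; it is a function only of
the tip count *N* and the *N* − 1 internal-node ages, so topology never
enters beyond the `(N−1)!` labelling factor. Crown-age conditioning is
the only conditioning implemented; stem-age or survival-only variants
would need different normalizing terms.

The joint likelihood of *m* trees is the product of per-tree
likelihoods. Rate-sharing hypotheses are expressed as constraint maps
(partitions of trees into λ-classes and μ-classes); nestedness is
checked structurally — the alternative's partitions must refine the
null's, and a pure-birth null (μ ≡ 0) sits on the boundary of any model
with free μ. Tests refer 2ΔlogL to χ² with df equal to the difference
in free-parameter counts: 2m−2 (free vs equal), m−1 (shared-μ or
shared-λ variants, and the pure-birth pair), 2g−2 (g groups vs equal).
The χ² reference is asymptotic and can be slightly anticonservative
when μ̂ sits at its zero boundary, which is why a parametric-bootstrap
null is provided (below) and why marginal p-values deserve caution.

Assumptions worth restating: rates are constant in time and across
lineages within a tree; sampling fractions are known, not estimated;
missing taxa are missing at random; trees are ultrametric, binary, and
calibrated in common time units. Trees of unknown mutual relationship
may be compared, since the likelihood never uses between-tree structure.

## Numerics

All computation is on the log scale. With *r* = λ − μ, *x* = *rt* and
*a* = ρλ/*r*, the shared denominator is handled through
Q(t) = e^{−x} + a(1 − e^{−x}), which is strictly positive for every
real *r* (μ > λ is allowed and needs no special casing), and:

* 1 − p₀ = ρ/Q (algebraic form — no subtractive cancellation as
  p₀ → 1); p₁ = ρ e^{−x}/Q².
* For r > 0, log Q = log(e^{−x} − a·expm1(−x)): both terms positive,
  no overflow. For r < 0, log Q = −x + log1p(a·expm1(x)): the large
  exponent stays on the log scale, so extreme μ cannot overflow the
  objective (an unguarded evaluation here is what an optimizer will
  find and exploit).
* |λ − μ| < 10⁻⁹·max(λ, 1) switches to the analytic λ→μ limit
  (Q = 1 + ρλt), letting the optimizer cross the critical ridge
  smoothly; the limit agrees with the full expression to ≥ 6
  significant digits at |λ−μ| = 10⁻¹².
* log((N−1)!) uses the log-gamma function (safe for trees with
  thousands of tips).
* λ = 0 with N > 2 returns −∞ (not an exception); zero-age internal
  nodes are rejected at input, as the ordered-branching-time model has
  no density there. Polytomies are a hard input error rather than being
  silently resolved: zero-length resolution would create zero ages and
  change the meaning of the (N−1)-node product.

A note on shapes: p₀ is non-decreasing and p₁ non-increasing in age
only under complete sampling. With ρ < 1 both curves can initially move
the other way (an older lineage has more descendants, hence a better
chance of having at least/exactly one sampled); the property tests
encode the ρ = 1 monotonicity and the weaker ρ < 1 facts. At extreme
|λ−μ|·t the true values of p₁ and 1−p₀ fall below double-precision
resolution and round to 0/1; tests assert strict bounds only inside the
representable range.

## Optimization

Rates are optimized as (log λ, log μ) per class — positivity for free —
with box bounds (log 10⁻¹⁰, 12) and μ ≤ 10⁻¹⁰ reported as exactly 0.
Local search is L-BFGS-B (finite-difference gradients) with convergence
tolerance 10⁻⁸ on the log-likelihood, from a moment-matched start
(λ₀ = max(ln(N̄/2)/T̄, 10⁻⁶) per class, inverting the crown expectation
E(N) = 2e^{λT}; μ₀ = λ₀/4). Up to `n_restarts` (default 5) starts are
tried — the plain start, any caller-supplied warm starts, then
multiplicative jitters e^{U(−1,1)} from a seeded generator — stopping
early once two independent starts agree within 10⁻⁶ log-units, since
the surface is in practice unimodal (a dedicated stability test checks
default fits against many differently-seeded restarts). Ties between
restarts break toward fewer iterations.

Because μ̂ frequently belongs on its μ = 0 boundary (the source of the
extinction estimator's slight upward mean bias — values that "want" to
be negative pile up at zero), every non-pure-birth fit also evaluates
the μ ≡ 0 profile — closed form when all ρ = 1, where the class MLE is
λ̂ = Σ(Nᵢ−2)/Σ(2t₁ᵢ + Σⱼ≥₂ tⱼᵢ) — and keeps the better of the two.
When a nested null has already been fitted, the alternative is
additionally warm-started at the null's optimum projected into its
parameterization, which guarantees logL(alt) ≥ logL(null) and hence a
non-negative LRT statistic by construction; residual negative 2ΔlogL
within 10⁻⁴ (possible only between independently run fits) is clamped
to 0, anything larger is reported as an optimization failure.

Sampling fractions are fixed data, never estimated, defaulting to 1.

## Simulators

`simulate_crown_bd` grows a tree forward (Gillespie) from two crown
lineages for a fixed duration *T*: with *n* lineages alive the waiting
time is exponential at rate n(λ+μ) and the event is a speciation with
probability λ/(λ+μ), applied to a uniformly chosen lineage. Two
acceptance schemes are offered:

* `condition="crown-survival"` (the default) keeps a run only if both
  crown lineages leave (sampled) descendants, so the reconstructed
  crown age equals *T* deterministically — the scheme that matches the
  likelihood's crown-age conditioning, and the one the parametric
  bootstrap uses when matching an observed crown age.
* `condition="survival"` keeps any run with enough extant tips; if one
  crown lineage died out, the reconstructed crown (the extant tips'
  MRCA) is younger than *T*. This is the acceptance rule under which
  the crown richness expectation E(N) = 2e^{(λ−μ)T} describes the
  simulated grid designs and under which the scripted studies'
  reference operating characteristics hold; crown-survival acceptance
  enriches for older, larger trees and visibly raises measured power
  (e.g. from ≈0.86 to ≈0.97 at the largest speciation contrast). The
  experiment drivers therefore use `"survival"`.

In both schemes the extant count must reach `min_tips`; extinct
lineages are then pruned, and under ρ < 1 extant tips are dropped
independently with the run redrawn if fewer than 2 tips survive (or,
under crown-survival, if a crown lineage loses all sampled
descendants). 10⁶ consecutive rejections abort with an error.
`min_tips` defaults to 5 and is applied in every scripted experiment
(the power designs require it; the null grids adopt it for internal
consistency, and the choice is recorded in each experiment's metadata);
it can be lowered to 2.

`simulate_yule_NT` conditions a pure-birth tree jointly on tip count
and crown age: given the process has *n* tips at crown age *T*, the
*n*−2 non-crown node ages are i.i.d. with CDF
F(t) = (1−e^{−λt})/(1−e^{−λT}), drawn by analytic inversion; topology
follows by splitting a uniformly chosen open lineage at each age,
oldest first. A distribution test checks it against brute-force
rejection (forward simulation accepted only when N = n). Joint (N, T)
conditioning with μ > 0 has no comparable closed form and is done by
rejection only where needed (bootstrap nulls conditioned on N), with a
capped redraw count.

The parametric bootstrap refits the null, simulates replicate tree
sets under the null's ML rates with each replicate matching the
observed crown ages — and, under `conditioning="depth-rates-N"`, each
observed tip count — and reports the add-one estimator
p = (1 + #{boot ≥ observed})/(n_boot + 1), which cannot return 0.
Whether bootstrap replicates should fix N as well as (T, λ, μ) is a
genuinely open question, so both schemes are exposed behind a flag with
`depth-rates` as the default.

Randomness: every simulation stream derives from integer seed tuples
fed to numpy's PCG64 (`default_rng([seed, condition, replicate])`), so
experiments are bit-for-bit reproducible and trivially parallelizable.

## Scripted experiments and their scales

The experiment drivers reproduce the method's operating
characteristics; all rejection rates are at α = 0.05, summaries carry
exact one-sided binomial tests against the nominal level, KS uniformity
tests of the p-value distribution, Monte-Carlo standard errors, and
estimate means/SDs.

* `null-grid` — type-I error: triples of trees at shared rates chosen
  so E(N) ∈ {20, 50, 100, 200, 500} after T = 100 at extinction
  fraction μ/λ = 0.25 (λ = ln(E(N)/2)/(0.75·T)).
* `unequal-depth` — type-I error for pairs at λ = 0.052, μ = 0.013 and
  depths 100 vs 141.14 (expected sizes ≈ 100 and 500).
* `power-speciation` — pairs at T = 100, shared μ = 0.013, λ₁ = 0.052,
  λ₂ ∈ {0.045, 0.052, 0.059, 0.068, 0.075}; also the parameter-recovery
  readout.
* `power-extinction` — the mirror sweep. The shared λ is set to 0.075,
  the smallest value among the sweep designs' rates for which every
  tree-2 richness target up to E(N) = 1000 is reachable with μ ≥ 0
  (λ = 0.052 would demand μ < 0); μ₂ = λ − ln(E(N₂)/2)/T.
* `power-both` — both rates differ, richness targets crossing
  {50…1000} against {1000…50} with extinction fractions interpolating
  linearly 0.35→0.15 and 0.15→0.35.
* `multitree` — one tree at λ = 0.067 vs 1–10 companions at λ = 0.056,
  μ = 0.017 shared.
* `yule-small` — pure-birth pairs at λ = 0.04 vs 0.08, each tree
  conditioned to exactly N ∈ {5, 10, 20, 40, 80} tips with
  Tᵢ = ln(N/2)/λᵢ.

Default replicate count is 500 per condition. The acceptance script
runs the designs it reports at 500 replicates (200 per tree-count for
the multi-tree design); the test suite exercises the same designs at
200–500 replicates per condition, sized so the whole suite completes in
minutes while keeping Monte-Carlo standard errors of a rejection rate
near 0.01–0.035.

## What the simulations do and do not show

The generator emulates exactly the process the likelihood assumes:
constant rates, missing-at-random sampling, known crown age, binary
ultrametric trees without measurement error. Passing calibration and
power checks therefore validate the estimator and test machinery, not
their robustness to real-data pathologies: rate variation in time or
among lineages, underestimated deep edges, coalescent inflation of
terminal branches, or phylogenetically clumped missing taxa (all of
which tend to bias extinction estimates downward in empirical trees)
are outside what these simulations can certify.

## Known limitations

* Extinction estimates from single small trees are noisy and often sit
  exactly at 0; only their cross-replicate mean behavior is
  characterized here.
* At the smallest-tree null condition (richness expectation 50) the
  full df=2 test runs mildly conservative (~0.03 rejection at nominal
  0.05 over >1000 replicates) — a boundary effect of μ̂ = 0 on the χ²
  asymptotics. Cross-checks against an independent implementation of
  the same likelihood reproduce the conservatism, so it is a property
  of the method at that tree size, not of this implementation.
* The bootstrap with exact-N conditioning under μ > 0 uses rejection
  and may fail (with a clear error) when the observed N is far from
  its expectation under the null rates.
* No standard errors or profile confidence intervals on rate
  estimates, no AIC/BIC ranking (derivable from reported logL and k),
  no multiple-testing correction across alternatives, no NEXUS input,
  and no trait-dependent, time-varying, diversity-dependent, or
  protracted-speciation models.
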