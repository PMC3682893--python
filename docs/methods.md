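# Methods

## The model

During exposure to a bactericidal antibiotic a population is treated as a
mixture of two phenotypes. Normal cells die at rate *m* (h⁻¹) and switch into
a protected persister state at rate *a*; persister cells neither die nor grow
and switch back at rate *b*:

```
n'(t) = -(m + a) n(t) + b p(t)
p'(t) =        a n(t) - b p(t)
```

This is the stochastic-switching ("type II") picture of persistence: persisters
are generated continuously during growth, not triggered by stationary phase.
The total viable concentration N(t) = n(t) + p(t) is a biexponential

N(t) = c₁ e^{λ₁ t} + c₂ e^{λ₂ t},  λ₁ < λ₂ ≤ 0,

with λ₁, λ₂ the roots of λ² + (m+a+b)λ + mb = 0 and amplitudes fixed by
N(0) = N₀ and N′(0) = −m(1−f_p)N₀, where f_p is the persister fraction at drug
addition. On a log scale this is the familiar biphasic kill curve: a steep
initial kill of normal cells and a slowly decaying persister tail.

Trajectories are evaluated through the Lagrange form of the 2×2 matrix
exponential, which is uniform in a, b ≥ 0; the measure-zero repeated-eigenvalue
boundary ((m+a+b)² = 4mb, detected at relative discriminant < 1e−12) uses the
limiting (w₀ + w₁t)e^{λt} form in trajectory evaluation and is excluded from
the fitted parameter space, keeping the likelihood parameterization
4-dimensional.

## Identifiability

CFU data determine only (c₁, c₂, λ₁, λ₂); the five mechanistic quantities
(m, a, b, N₀, f_p) are constrained to a one-parameter family. Writing
u = 1 − f_p and D = −N′(0)/N(0) = −(c₁λ₁ + c₂λ₂)/(c₁ + c₂), the inverse map is

m = D/u,  b = λ₁λ₂/m,  a = −(λ₁+λ₂) − m − b,

and requiring a ≥ 0 confines u to [D/|λ₁|, min(1, D/|λ₂|)]. For a fitted curve
(c₁, c₂ ≥ 0) D is a convex combination of |λ₁| and |λ₂|, so the persister
fraction is only bounded above: f_p ∈ [0, 1 − D/|λ₁|]. The point estimate is
the interval midpoint; the slow-amplitude fraction c₂/(c₁+c₂) is reported
alongside as a model-free alternative. Outputs also carry the equivalent
normal-cell-fraction convention F₀ = 1 − f_p (whose near-one intervals are how
this degeneracy is often quoted), so either convention can be read off without
ambiguity.

The container type admits c₁ < 0 (reached when back-switching is fast relative
to killing, so the slow amplitude exceeds N₀) as long as N(t) stays positive
and nonincreasing; the *fitted* space restricts to c₁ > 0, matching the
visibly biphasic curves the method is applied to. In that regime D < |λ₂| and
the fraction interval acquires a positive lower bound as well.

## Likelihood and fitting

Counts are modelled as Poisson: x_t ~ Poisson(N(t)·δ_t), with δ_t the
*effective plated volume* (plated volume × serial-dilution factor, ml). The
log-likelihood is Σ_t [x_t ln(N δ_t) − N δ_t − ln x_t!]; a zero count
contributes −N δ_t, and a zero predicted mean against a positive count yields
−∞ (flagged, not raised).

Optimization works in unconstrained coordinates c₁ = e^{θ₁}, c₂ = e^{θ₂},
λ₂ = −e^{θ₃}, λ₁ = λ₂ − e^{θ₄}, which enforce positivity and eigenvalue
ordering. Starting values come from a two-phase split of the data (late-phase
log-linear slope → λ₂ and c₂, early-phase slope → λ₁ and c₁) perturbed
log-uniformly (seeded); from each start a Nelder–Mead simplex search and a
BFGS quasi-Newton search with the analytic gradient are run, the best optimum
is kept, and a final tight simplex polish confirms it as a fixed point
(refitting from the optimum improves the log-likelihood by < 1e−6). A
stochastic dual-annealing pass is available behind `use_annealing` but off by
default: on the test grid the two deterministic optimizers from 10 starts
always reach the same optimum. Default `FitConfig` uses 10 starts; the
large study sweeps in the validation suite use a 3-start BFGS-only profile,
which reproduces the default protocol's recovery rates on the recovery grid
at a fraction of the cost.

Confidence intervals are 95% normal-approximation intervals from the
numerically differentiated observed information at the MLE in θ-coordinates
(where the approximation is symmetric), mapped back through the monotone
transforms. A singular information matrix flags the intervals unavailable
without discarding the fit. These per-replicate (Hessian) intervals are
distinct from the across-replicate standard errors of the strain summaries;
both are produced and labelled.

**Detection limit.** When every late-phase count (t ≥ 8 h) is zero the
persister tail is unobserved and the slow amplitude is unstable; the fraction
is then reported as a rule-of-three upper bound 3/(V_late · Ĉ₀), with V_late
the summed late effective volumes and Ĉ₀ the observed initial concentration,
and the replicate is flagged `detection_limit`. Flagged replicates contribute
their bound to strain summaries.

**Model comparison.** Biphasicity is called by refitting the nested
single-exponential model N = c e^{λt} under the same likelihood and requiring
the biexponential to win by ΔAIC > 4 (the conventional "considerably less
support" cut; the reduced optimum is injected as a boundary start of the full
fit so the nesting inequality holds numerically).

## Synthetic data

The generator emulates a standard persister assay: growth to exponential
phase, drug addition at t = 0, sampling at {0,1,2,3,4,20,24,28,48} h, 6
biological replicates. Early samples are 5 µl spots after serial 10-fold
dilution; late samples plate 100–500 µl directly. Dilutions are chosen
deterministically to bring the expected count under 300 colonies per plate
(targets 10–300); when even the largest late volume undershoots, that volume
is used and the curve enters the detection-limit regime. Counts are pure
Poisson around the deterministic mean — exactly the error model the
likelihood assumes, so generator/fitter closure tests measure estimation
error, not model misspecification. Real plates add overdispersion
(plating efficiency, colony overlap, pipetting), so recovery rates here are
an upper bound on what field data would give.

Study scenarios draw, per strain × antibiotic, log-uniform
f_p ∈ [1e−5, 0.1] (spanning the <0.001%–>10% range such assays report),
m ∈ [0.5, 5] h⁻¹, b ∈ [1e−4, 0.1] h⁻¹, N₀ ∈ [1e7, 1e8] CFU/ml. The entry
rate is not drawn independently: a = f_p(g + b)/(1 − f_p) with growth rate
g = 2 h⁻¹, the quasi-stationary balance that sustains the fraction f_p during
pre-treatment exponential growth. This makes the fraction a monotone function
of the entry rate across strains — the mechanistic structure behind the
determinant analysis. The `shared` scenario reuses one strain-level fraction
across antibiotics (a single multidrug-tolerance mechanism); `independent`
draws each strain × antibiotic fraction separately.

Combination treatments are generated from the pair's hypothesis: exclusive
f_AB = 0, independent f_AB = f_A·f_B, coincident f_AB = min(f_A, f_B); the
kill rate is the max of the single-drug kill rates and the exit rate follows
the more lethal drug (simulation conventions, recorded in the truth table).

An exact event-driven (Gillespie) simulator of the jump process (propensities
m·n, a·n, b·p) is included as an independent stochastic oracle for the
closed-form mean. All randomness descends from a single scenario seed via
`numpy.random.SeedSequence` spawning; identical seeds give byte-identical
datasets.

## Study-level statistics

Fractions span four orders of magnitude, so replicate aggregation is on the
log₁₀ scale (means and standard errors of log₁₀ f_p); natural-scale means
would be dominated by single replicates. Cross-antibiotic association uses
Spearman's rank correlation (average ranks on ties) with permutation
p-values: exhaustive enumeration of all n! orderings for n ≤ 7, otherwise
10,000 seeded Monte-Carlo permutations with the add-one estimator
(1 + #extreme)/(1 + B), two-sided. Raw p-values are reported per pair; with
three antibiotic pairs no multiplicity correction is applied and the number
of tests is noted in the outputs.

Combination calls compare log₁₀ f_AB against the two non-trivial hypotheses
and label the nearer one when within τ = 0.5 log₁₀ (half an order of
magnitude separates the hypotheses cleanly at these fraction ranges);
a below-detection f_AB (default bound 1e−7) is exclusive regardless; anything
else is ambiguous, and both distances are always reported. The classifier's
validation triples draw single-drug fractions from [1e−3, 0.1] — the
well-measured range in which combination assays are actually run, and the
range in which an independent-hypothesis product stays above detection.

The determinant analysis pools strain × treatment records and correlates
log₁₀ f_p against log₁₀ a, log₁₀ b and log₁₀ m (Spearman, as above).

## Validation problem sizes

The validation suite (`persisterfit.validation`, asserted in
`tests/test_acceptance.py` and reported by `scripts/acceptance.py`) uses:
1,000 random parameter draws for closed-form/ODE agreement (LSODA,
rtol 1e−11, atol ≈ 0 — absolute tolerance must be effectively off to track
ten decades of decay) and for identifiability coverage; 1,000 exact-event
runs of 10⁴ cells for the stochastic oracle; 50 seeded curves per
f_p ∈ {1e−4, 1e−3, 1e−2, 1e−1} for fraction recovery; 50 runs per regime for
model selection; 300 triples per hypothesis (0.15 log₁₀ noise) for the
combination classifier; and 2 × 20 twelve-strain studies (the 3-start BFGS
profile) for study-level discrimination. For the independent design the
headline metric is the fraction of individual pairwise correlations inside
the n = 12 null band (|ρ| < 0.58, the two-sided 5% critical value); the
stricter per-study all-three-inside rate is also computed, but with ~5% of
null correlations expected outside the band by construction it carries no
designed-in margin at 20 studies.

## Limitations

- The Poisson error model ignores plating overdispersion and differential
  colony-forming propensity of persisters.
- Pre-treatment growth enters only through the initial condition (N₀, f_p);
  stationary-phase-triggered (type I) persistence, drug pharmacokinetics and
  resistance emergence are out of scope.
- The identifiability interval, not a point, is the honest estimate of f_p;
  the midpoint is a reporting convention, and for very wide intervals
  (slow-tail curves barely above detection) the midpoint can sit well away
  from the generating value.
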