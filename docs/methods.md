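# Methods

## The model family

`lvcompete` models a two-member co-culture of drug-sensitive cells S(t) and
drug-resistant cells R(t) (fluorescence a.u., identified with population
size) growing in a shared well. Three growth laws are implemented as
two-population extensions with frequency-dependent competition:

* **logistic** — dS/dt = ρ₁ (1 − (S + α_SR R)/K₁) g(t) S,
  dR/dt = ρ₂ (1 − (α_RS S + R)/K₂) R
* **Gompertz** — dS/dt = ρ₁ ln(K₁/(S + α_SR R)) g(t) S, analogously for R
* **von Bertalanffy** — dS/dt = ρ₁ (1 − ((S + α_SR R)/K₁)^{1/3}) g(t) S^{2/3},
  with the classic 1/3 exponent

where g(t) carries the drug effect. Three drug-efficacy terms act on the
sensitive equation only: the Norton–Simon multiplier g = (1 − λC(t)) (kill
proportional to growth), a density-independent subtractive term −λC(t), and
a ratio-dependent subtractive term −λC(t)S. C(t) is a right-continuous unit
step: 0 before the dosing time (default 20 h), a constant dose (default 1)
afterwards; λ absorbs the dose magnitude.

Parameters and units: ρ₁, ρ₂ (h⁻¹) intrinsic growth rates; K₁, K₂ (a.u.)
carrying capacities; α_SR, α_RS (dimensionless) competition coefficients
(effect of resistant on sensitive and vice versa); λ (h⁻¹ per unit dose for
the subtractive terms, dimensionless for Norton–Simon). All rates and
capacities must be positive; α and λ nonnegative.

For model comparison the seven parameters are tied stepwise into five
variants per growth law (15 models total): variant 1 shares ρ and K across
populations with α ≡ 1 (2 free parameters, 3 with drug); variant 2 frees
ρ₁ ≠ ρ₂; variants 3 and 4 free one competition coefficient each; variant 5
frees both. No variant frees more than five parameters.

### Numerical conventions

* **von Bertalanffy radical.** The cube root is applied to the full density
  quotient (S + α_SR R)/K₁ so that S = K₁ (with R = 0) remains the
  carrying-capacity equilibrium, consistent with K's role in the other laws.
* **Gompertz floor.** The log argument is floored at 10⁻¹² K to keep the RHS
  finite near extinction; the factor S in front sends the product to zero
  anyway.
* **Nonnegativity.** The linear kill term can formally drive S below zero;
  populations are floored at zero in the RHS and extinction is absorbing
  (a nonpositive population with negative derivative is held at zero).
* **Norton–Simon literalism.** For λC > 1 the multiplier inverts the growth
  term for all three laws; this is implemented literally, including the
  resulting finite-time blow-up above carrying capacity, which the
  integrator cuts off at a state magnitude of 10¹² and reports as a
  divergence.

## Integration

Trajectories are computed with `scipy.integrate.solve_ivp` (LSODA,
stiffness-switching). Integration is split at the dose onset so the adaptive
stepper never straddles the discontinuity in C(t); each segment sees a
constant drug level. Default tolerances are rtol = atol = 10⁻⁸ for plain
trajectory evaluation; the fitting loop uses rtol = 10⁻⁷, which changes
fitted parameters well below their statistical uncertainty while roughly
halving runtime.

## The synthetic plate generator

The generator emulates a competition assay between GFP-labeled sensitive
and mCherry-labeled resistant NSCLC cells: four environments (DMSO control,
CAF co-culture, drug, CAF+drug), eight seeding ratios of sensitive to total
(0, 0.1, 0.2, 0.4, 0.6, 0.8, 0.9, 1), six replicates, fluorescence every
4 h from 0 to 120 h, a single constant drug dose at 20 h — 192 wells in the
full design.

Per well, the initial total population is drawn lognormally with mean 500
a.u. and CV 0.2 (wells show real dispersion in seeding density), split by
the seeding ratio, integrated under the environment's ground-truth model,
scaled by per-channel gain (default 1), and multiplied by lognormal
measurement noise exp(σZ) with σ = 0.05; an optional additive noise floor
(default 0) can mimic background fluorescence. Everything is reproducible
from the design seed.

**Default ground truth.** Logistic growth with the ratio-dependent kill term
in every environment. The competition coefficients are the drug-stratified
co-culture medians reported for this assay — α_SR = 0.519 / 0.961 and
α_RS = 0.576 / 2.144 without / with drug. Growth rates, capacities and drug
efficacies are not printed for the original data; the defaults are chosen
once as realistic values for these cell lines: ρ₁ = 0.05 h⁻¹,
ρ₂ = 0.055 h⁻¹ (doubling times near 14 h and 13 h), K₁ = 6000, K₂ = 9000 a.u.
(resistant cells carry the larger capacity), λ = 0.09 h⁻¹ (drug) and
0.06 h⁻¹ (CAF+drug), so that λ exceeds ρ₁ — drug wells decline within the
120 h window — and CAFs attenuate drug efficacy. Under these defaults the
phase-plane outcome is coexistence in the drug-free environments and
competitive exclusion of the sensitive type under drug, the qualitative
pattern the pipeline is meant to expose.

**What the generator does not emulate:** spatial structure within wells,
CAF population dynamics (CAF presence is a binary label that switches
parameter values), fluorescence calibration drift, pipetting outliers, or
evolving resistance. Passing recovery tests therefore demonstrates that the
estimation machinery is correct and well-conditioned under the assay's
design, not that the selected model is true of any particular real dataset.

## Fitting

Each well is fit independently by minimizing the weighted cost

J_w = Σ_{i∈{S,R}} Σ_{t=12,16,…,116} ((d_it^meas − d_it^model)/max_t d_i^meas)²

— 27 time points per channel, each channel normalized by its own measured
maximum so the minority population is not swamped. The first 12 h are
excluded (cells settling); the ODE initial state is pinned to the measured
values at 12 h. A channel whose measured maximum is zero (the unseeded
channel of a monoculture) is excluded from the sum and from the data-point
count N. The chi-square error is identified with J_w (a `sqrt` convention
is available for comparison), and AIC = N ln(χ²/N) + 2 N_varys.

Optimization is bounded multi-start local least squares
(`scipy.optimize.least_squares`, TRF, Jacobian-based scaling). Starts are
drawn log-uniformly within the bounds from a seeded generator; zero lower
bounds are floored at 10⁻³ for start sampling only. Default bounds:
ρ ∈ [10⁻³, 2] h⁻¹, K ∈ [10, 10⁶] a.u., α ∈ [0, 10], λ ∈ [0, 10] — generous
and covering competition coefficients above 2. `fit_well` defaults to 20
starts; the staged protocol and the comparison tables default to 5, because
their sub-problems leave at most two parameters free at a time and the cost
surfaces are smooth — in seeded checks 3–5 starts reproduce the 20-start
optima to well below the replicate-to-replicate spread. Failed integrations
during a line search are penalized with large constant residuals. All
results are deterministic given the seed.

### The staged protocol

1. **Monoculture growth.** The one-population logistic models (the sensitive
   one with the ratio-dependent kill term, the resistant one with no drug
   term) are fit to every drug-free monoculture well; the medians of
   (ρ₁, K₁, ρ₂, K₂) are pooled across DMSO and CAF environments.
2. **Drug efficacy.** With those medians fixed, λ is fit per drug-treated
   sensitive monoculture well; medians are taken separately by CAF status,
   since CAFs modulate drug efficacy.
3. **Competition.** With growth and drug parameters fixed, the competition
   coefficients (α_SR, α_RS) are the only free parameters fit per co-culture
   well.

Median (not mean) aggregation is used at every step. The stage-3 table of
per-well coefficients feeds the statistical layer.

## Statistics

* **Two-way ANOVA** of a fitted parameter on drug × CAF with interaction,
  Type II sums of squares (identical to the classical decomposition for
  balanced designs; main effects adjusted for each other when unbalanced).
  An empty or singleton design cell drops the interaction with a warning.
  On the full co-culture design (144 wells) the residual df is 140.
* **Paired t-test** of α_RS vs α_SR within wells; 72 drug-treated co-culture
  wells give df 71.
* **ANCOVA nonlinearity probe.** Per-capita growth is estimated at interior
  grid points by centered log-differences r_t = (ln N_{t+4} − ln N_{t−4})/8 h⁻¹
  (points whose stencil touches a nonpositive value are dropped), pooled
  across replicates per environment × cell type, and regressed on N and N².
  Logistic growth predicts a vanishing quadratic coefficient; Gompertz and
  von Bertalanffy a positive one. The centered-difference estimator carries
  an O((ρΔt)²) curvature bias, negligible against measurement noise at the
  default design but visible on noiseless fine-grid data; it is a pragmatic
  stand-in for whatever estimator a particular lab pipeline uses.

Significance is reported against α = 0.05 throughout; no multiple-testing
correction is applied across the battery.

## Phase plane

For the selected model (logistic + ratio-dependent) in the post-onset
constant-dose regime, the kill term folds into an effective sensitive
capacity K₁' = K₁(1 − λC/ρ₁). Equilibria are closed-form: the origin, the
boundary points (K₁', 0) (when K₁' > 0) and (0, K₂), and the interior
solution of the linear nullcline system S + α_SR R = K₁',
α_RS S + R = K₂. Stability comes from the analytic Jacobian; eigenvalue
real parts within 10⁻⁹ of zero are declared marginal and the report labeled
degenerate rather than silently classified (this includes the transcritical
bifurcation at λC = ρ₁ and the degenerate nullcline determinant
α_SR α_RS = 1). Outcomes: stable interior ⇒ coexistence; a single stable
boundary ⇒ exclusion of the other type; both boundaries stable ⇒
bistability. Classification is cross-checked by long-run integration
(blocks of 100 h until the relative change per block falls below 10⁻⁸, cap
10⁵ h). Pre-onset transients are ignored for classification. Gompertz and
von Bertalanffy co-culture equilibria are out of scope.

## Problem sizes in the test and acceptance runs

Chosen to keep the suites responsive while preserving the design structure:
the degrees-of-freedom and noiseless-recovery checks run the full 192-well
design; the 20-seed noisy-recovery sweep uses 2 replicates and 4 interior
seeding ratios per plate (the recovered medians' error distribution, not
the per-plate well count, is what those checks measure); the drug-efficacy
comparison uses 3 replicates per seed; the growth-law comparison uses a
36-well cohort — the DMSO co-cultures (6 interior ratios × 6 replicates),
matching the original comparison's cohort size. Staged fits use 3 starts.

## Interpreting the growth-law comparison

On synthetic plates the two-parameter variant-1 models carry median
chi-square errors an order of magnitude above the variant-5 models, while
variants 2–5 differ from one another by only a few percent *of the
variant-1 error scale*. The spread is measured against that scale because
it is the scale on which "the flexible variants fit almost equally well" is
a meaningful claim: variants 2–5 are non-nested four-to-five-parameter
structures with different systematic misfits to any fixed asymmetric ground
truth, so their errors cannot coincide to within a few percent of each
other on data where the truth is known and fixed — the informative contrast
is that their differences are negligible next to the under-parameterized
model's error.

## Known limitations

* Equilibrium analysis covers only the selected logistic/ratio-dependent
  model; other laws would need numeric root finding (a non-goal).
* The per-capita growth estimator in the ANCOVA is one defensible choice
  among several; its quadratic bias term is documented above.
* The Norton–Simon multiplier's behavior for λC > 1 is implemented exactly
  as written, pathologies included; it is the comparison's point that this
  regime is biologically implausible.
* No pharmacokinetics: the dose is a step function, λ absorbs magnitude.
* Identifiability of (α_SR, α_RS) degrades in wells where one population
  collapses quickly (drug environments at extreme seeding ratios); the
  staged protocol mitigates this by freeing only the two coefficients, and
  medians across the ratio ladder absorb the remaining per-well noise.
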