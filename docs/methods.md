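# Methods

## Model and conventions

The package implements the six-gene *Arabidopsis* flowering network (AP1,
LFY, SOC1, FD, AGL24, FT; inputs SVP and FLC in meristem and leaves) as a
system of delay differential equations with Hill kinetics, its three-gene
reduction (FD, AGL24 and FT held at quasi-steady values), and the two-gene
AP1–LFY motif with lumped FT / FT–FD action constants F₁ (on LFY) and F₂
(on AP1), each inhibiting below 1 and activating above 1.

Units are nM for concentrations and **minutes** for time throughout the
numerics; the FT transport delay is stated in days at the registry surface
(default 0.5 day) and converted at the model boundary.  Keeping a single
internal time unit avoids the mixed-unit errors invited by rate constants
in min⁻¹ alongside horizons in days.  The Hill cooperativity of the
LFY→AP1 activation is n = 3; all cubic-root analysis assumes that value.

### Parameters and inputs

The 34 kinetic constants (β₁…β₁₂ in nM/min, K₁…K₁₆ in nM, d₁…d₆ in
min⁻¹), the delay and n ship as a machine-readable registry
(`data/parameters.yaml`), with the admissible ranges β ∈ [0.001, 200],
K ∈ [0.001, 2000], d ∈ [0.001, 1], Δ ∈ [0, 1] day attached for validation
and random draws.

The four constant external input levels are **synthetic reconstructions**
(`data/inputs_synthetic.yaml`).  The experimental SVP/FLC series behind
the original analysis are not redistributable, and the equilibrium
equations only constrain the two products κ₁₁(x₇)κ₁₂(x₈) and
κ₁₅(x₉)κ₁₆(x₁₀).  Those products are back-solved from the published
positive equilibrium (SOC1 and FT balances), and within each product the
two levels are set equal: x₇ = x₈ ≈ 1.529 nM, x₉ = x₁₀ ≈ 137.75 nM.  With
these levels the model's recomputed equilibrium agrees with the published
one to ~2×10⁻⁵ relative, so every downstream quantity is reproduced while
no claim is made that the individual levels match the unpublished
measurements.

## Steady states

At constant inputs the FT level is fixed directly (x̄₆ = u), FD and AGL24
are slaved to LFY and SOC1, and the remaining coupling is reduced to a
scalar problem in the SOC1 level: for trial x̄₃ the LFY balance is solved
by Brent's method on [0, (β₄+β₅+β₆)/d₂ + 1] (the net flux is negative at 0
and positive there, so a root always exists, with AP1 explicit in LFY),
and the SOC1 production–degradation residual is bracketed on 2000
log-spaced points over (10⁻⁶, 10⁶) nM and polished to 10⁻¹² absolute.  The
symbolic elimination to a 17th-degree polynomial is deliberately not
reproduced: the numeric route yields the same solution set and every
candidate is verified against the full right-hand side (relative residual
< 10⁻⁸ required).  The log grid cannot represent roots below 10⁻⁶ nM or
above 10⁶ nM; none arise for the registry parameters, and for random draws
any missed root is caught by the residual oracle returning nothing rather
than something wrong.

Motif equilibria come from the closed-form cubic.  The discriminant
Δ₃ = ω₄(4(ω₃F₁F₂)³ − 27(ω₁+ω₂F₂)²ω₄) is non-negative exactly when two
positive equilibria exist.  A configuration is reported as a saddle-node
double root when |Δ₃| falls below 10⁻⁶ of the *sum* of the discriminant's
two terms — its natural magnitude; an absolute band (e.g. relative to ω₄²)
would be meaningless because the two terms are ~10³ times larger than ω₄²
at criticality.

## Stability

The delayed FT channel enters the equilibrium problem at its steady value
and the linearised system's stability is delay-independent, so verdicts
come from the ordinary 6×6 analytic Jacobian.  Its characteristic
polynomial factors as (λ+d₆)·P(λ); the quintic coefficients a₁…a₅ are
obtained numerically by polynomial deflation of the root λ = −d₆
(remainder checked below 10⁻⁹ relative) rather than from closed-form
coefficient expressions, and passed to the Routh–Hurwitz predicate
(aᵢ > 0; a₁a₂a₃ + a₁a₅ > a₃² + a₁²a₄; (a₁a₄−a₅)(a₁a₂a₃+a₁a₅−a₃²−a₁²a₄) >
a₅(a₁a₂−a₃)²).  Every verdict is cross-checked against the eigenvalues of
the Jacobian; any Routh–Hurwitz expression within 10⁻⁹ (relative to its
own scale) of zero is reported `marginal` instead of being forced to a
side.  The motif uses the explicit criterion
x̄₂ⁿ⁻¹ > n d₁d₂K₁ⁿK₄/(β₁β₄F₁F₂) together with the existence bound
x̄₂ < β₄F₁/d₂; equality is the saddle-node and coincides with Δ₃ = 0.

## Integration

The delay model is integrated by the method of steps: classical
Runge–Kutta (RK4) with a fixed step (default 1 min) inside each segment,
the delayed FT value read from the stored uniform grid by linear
interpolation in O(1), and a constant pre-history equal to the initial
state (no biological information about pre-germination history exists).
The step must not exceed the delay so stage look-backs stay inside the
computed grid; with zero delay the scheme is plain RK4 and the two paths
agree to roundoff.  Linear interpolation of the delayed channel caps the
observed convergence order near 2 when the delay is active (RK4's order 4
is recovered at Δ = 0); with the default 1-min step endpoint errors are
far below every tolerance used.  States above 10⁹ nM or non-finite abort
with a divergence error naming the time.  The fastest registry timescale
is 1/d₁ ≈ 1.2 min, so steps above ~3 min are outside RK4's stability
region for this model — the default keeps a threefold margin.

Motif event computations (flowering times, basin classification) use
scipy's LSODA with rtol 10⁻⁸/atol 10⁻¹⁰ and a terminal event, since they
need dense event location rather than a fixed grid.

## Bifurcation and flowering

Critical action constants solve Δ₃ = 0 by bisection on (10⁻⁴, 10) to
10⁻⁷ absolute in F, in three scenarios: F₁ = 1 (action on AP1 only),
F₂ = 1 (action on LFY only), F₁ = F₂ (equal action).

"Flowering time" is operationally defined as the first time AP1 reaches
50% of the upper stable equilibrium; the source analysis never states its
convention.  Because sub-threshold trajectories collapse to the trivial
state while supra-threshold ones commit fully, the initial-LFY flowering
threshold (1.25 nM on a 0.01 nM grid at initial AP1 = 0.24 nM, horizon
100 days) is insensitive to that fraction — verified in the tests for
25–95%.  Basin classification requires the endpoint to land within 1%
(relative, 0.01 nM floor) of a stable state and otherwise returns
`unresolved` rather than guessing.

## Stochastic motifs

Sample paths use Euler–Maruyama with a fixed step (default 0.5 min) and
independent N(0, Δt) increments per component.  The "5% constant noise"
condition of the switching experiments is taken literally as σᵢ = 0.05 in
the additive model's units (nM·min^−1/2).  States are clamped at zero
after each step — additive noise otherwise drives concentrations negative,
where Hill terms are meaningless — and clamp activations are counted and
reported, since the clamp acts as a reflecting boundary that slightly
biases near-zero dynamics upward.  Randomness uses one master seed with
one spawned child stream per trajectory (`numpy.random.SeedSequence`), so
ensembles are reproducible across machines and ensemble size.

Ensemble endpoints are classified by deterministic continuation (the
endpoint is handed to the basin classifier), so a path counts as switched
only if the noise actually carried it into the flowering basin.  The
default ensemble horizon is 50 days.  Under the stated switching
conditions (start (0.2, 1.2) nM, just below the saddle at ≈(0.247, 1.246))
the switching fraction at that horizon is high (~0.95–1.0 across seeds)
because additive noise keeps acting for the whole horizon; both basins
remain populated, but the split is seed-dependent at 100 paths.

The Lyapunov certificate evaluates the bounds σᵢ < √(2dᵢ), the infimum of
admissible quadratic-form weights θ > (β₄F₁/K₄)²/((2d₁−σ₁²)(2d₂−σ₂²)),
and the admissible Young's-inequality window for ε at θ twice the infimum.
Empirical corroboration of mean-square decay/growth is done over a *short*
horizon (~50 min, 500–2000 paths) on the slow LFY component: above the
bound, second-moment growth is carried by rare large excursions of an
asymptotically lognormal field, so over long horizons a finite ensemble
mean cannot track the true (growing) moment, and the fast AP1 component at
large σ√Δt is dominated by clamp absorption.  Within the chosen window the
empirical ratio separates cleanly (≈0.5–0.8 at 80% of the bounds versus
≈1.3–4 at 120% of the LFY bound, across seeds).

## Sensitivity

Normalised local sensitivities S_q = (q/y)·∂y/∂q are estimated by central
differences at 1% relative perturbation (0.5–2% give the same leading
ranks; smoothness under step doubling is tested).  Flowering has two
scalar signatures responding to disjoint parameter groups: the equilibrium
AP1 level is controlled by d₁ and β₁ (the LFY→AP1 Hill term is saturated
at equilibrium, hiding K₁), while the onset time — AP1 first reaching half
its equilibrium, integrated delay-free since the delay shifts onsets by a
parameter-independent constant — is controlled by K₁, β₅, K₅, β₄, K₄ (d₁
cancels from the timing because it rescales trajectory and target alike).
`local_sensitivity` ranks a single functional (equilibrium AP1 by
default); `flowering_sensitivity` ranks by the largest |S| across the two
signatures, and its top seven are exactly {β₁, β₄, β₅, K₁, K₄, K₅, d₁} —
all parameters of the AP1 and LFY balance equations.

## Synthetic data

The generator emulates the study's inputs: constant levels, or
piecewise-linear non-negative signals with values drawn uniformly at
equally spaced knots (linear interpolation keeps them inside their ranges
everywhere), defaulting to ranges of (0, 2×) the reconstructed fixture
levels.  Parameter draws are log-uniform across the admissible ranges —
they span up to five decades, which a uniform draw would concentrate in
the top decade — with the delay drawn uniformly (its range contains zero)
and n fixed at 3.  Constant mode is the default for all equilibrium work.
The generator makes no attempt to reproduce the actual expression time
courses quantitatively; passing tests therefore demonstrate correctness of
the dynamics and analysis machinery under the study's parameter regime,
not agreement with any particular experimental series.

## Problem sizes used in the shipped checks

The acceptance script runs entirely at desk scale (< 1 s): bisections,
cubic roots, one full steady-state solve and an 11-point threshold scan.
The test suite integrates the full delay model for 100 days at a 1-min
step once, uses 100-path ensembles at the 50-day default for switching
and 500-path short-horizon ensembles for the moment checks, and verifies
the Routh–Hurwitz predicates on 1000 random polynomials.

## Known limitations

* Stability is delay-independent for this model class; no quasi-polynomial
  (delay-dependent) spectrum computation is provided, and no bifurcation
  continuation is attempted in the full six-dimensional system.
* The steady-state solver's bracketing grid bounds the representable SOC1
  roots to (10⁻⁶, 10⁶) nM.
* Euler–Maruyama is first-order weak/half-order strong; no Milstein or
  higher-order scheme is implemented.  Multiplicative-noise runs with
  σ√Δt ≳ 1 on the fast component are dominated by the zero clamp.
* The stochastic treatment covers the two-gene motif only; the full model
  is deterministic here.
* Parameter values are taken as shipped; no re-fitting to expression data
  is provided.
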