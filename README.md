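# floranet

Deterministic and stochastic dynamics of the *Arabidopsis thaliana*
flowering gene regulatory network.

The transition from vegetative growth to flowering in *Arabidopsis* is
committed by the floral meristem identity genes **AP1** and **LFY**.  Their
regulation is embedded in a six-gene network — AP1, LFY, SOC1, FD, AGL24
and FT, driven by SVP and FLC expression in the meristem and the leaves —
in which FT is produced in the leaves and acts on the meristem after a
transport delay.  `floranet` implements this network as a delay
differential equation model with Hill kinetics, together with the chain of
reductions that makes its behaviour analysable: a three-gene
(AP1/LFY/SOC1) model obtained by quasi-steady decoupling, and a two-gene
AP1–LFY motif whose bistability explains the flowering switch.

The package is aimed at systems biologists and applied dynamicists who
want to reproduce, probe or extend this analysis: equilibria and
Routh–Hurwitz stability of the full model, saddle-node bifurcation of the
motif, flowering thresholds, noise-driven switching, and a stochastic
Lyapunov stability certificate.

## The model

The full network, with protein concentrations x₁…x₆ (nM) for AP1, LFY,
SOC1, FD, AGL24, FT and external inputs x₇…x₁₀ (SVPₘ, FLCₘ, SVPₗ, FLCₗ):

```
ẋ₁ = β₁ γ₁ⁿ(x₂) + β₂ γ₂(x₄) + β₃ γ₃(x₆(t−Δ)) − d₁x₁
ẋ₂ = β₄ γ₄(x₁) + β₅ γ₅(x₃) + β₆ γ₆(x₅) − d₂x₂
ẋ₃ = [β₇ γ₇(x₃) + β₈ γ₈(x₅) + β₉ γ₉(x₄)γ₁₀(x₆(t−Δ))] κ₁₁(x₇)κ₁₂(x₈) − d₃x₃
ẋ₄ = β₁₀ γ₁₃(x₂) − d₄x₄
ẋ₅ = β₁₁ γ₁₄(x₃) − d₅x₅
ẋ₆ = β₁₂ κ₁₅(x₉)κ₁₆(x₁₀) − d₆x₆
```

with Hill activation γⱼⁿ(x) = xⁿ/(xⁿ+Kⱼⁿ), inhibition κⱼ(x) = Kⱼ/(x+Kⱼ),
and an FT transport delay Δ (0.5 day).  The two-gene motif keeps only the
mutual AP1–LFY activation, with the FT and FT–FD actions lumped into
constants F₂ and F₁:

```
ẋ₁ = β₁ F₂ x₂³/(x₂³+K₁³) − d₁x₁        (AP1)
ẋ₂ = β₄ F₁ x₁/(x₁+K₄) − d₂x₂           (LFY)
```

Positive motif equilibria are roots of
(ω₁+ω₂F₂)x₂³ − ω₃F₁F₂x₂² + ω₄ = 0 with ω₁ = d₁d₂K₄, ω₂ = d₂β₁,
ω₃ = β₁β₄, ω₄ = d₁d₂K₁³K₄; its discriminant locates the saddle-node at
which the flowering switch is born.  Stochastic variants add additive
(σᵢ dWᵢ) or multiplicative (σᵢ(xᵢ−x̄ᵢ) dWᵢ) white noise; the origin is
stable in probability whenever σᵢ < √(2dᵢ).

All kinetic constants ship with the package
(`src/floranet/data/parameters.yaml`).  The four external input levels are
a synthetic reconstruction back-solved from the published equilibrium (the
experimental series are not redistributable); see
`src/floranet/data/inputs_synthetic.yaml`.

## Worked example

```python
import floranet as fn

p = fn.ParameterSet.default()
inputs = fn.InputSignals.default()

# unique positive equilibrium of the full model and its stability
state = fn.solve_full_steady_state(p, inputs)[0]
print(state.x.round(3))
# [   121.567    452.395    827.835   1113.882  86881.254      2.037]
print(fn.full_model_stability(state, p, inputs).verdict)
# stable

# saddle-node of the AP1-LFY motif under equal FT / FT-FD action
mp = fn.MotifParams.from_parameters(p)
print(round(fn.find_critical_F("subsystem3", mp).critical_F, 5))
# 0.21156

# flowering threshold on the initial LFY concentration
mp_best = mp.with_F(F1=1.3445, F2=1.0476)
threshold, _ = fn.flowering_threshold(mp_best, ap1_init=0.24)
print(threshold)
# 1.25
```

The equilibrium says that a committed (flowering) plant settles at
~121.6 nM AP1 and ~452.4 nM LFY; the verdict confirms this state attracts
the post-germination trajectory.  The critical action constant 0.21156
means no flowering state exists at all until the joint FT/FT–FD drive
reaches about a fifth of its reference strength, and the 1.25 nM threshold
is the minimum initial LFY (at 0.24 nM AP1) from which the motif commits
to flowering rather than decaying back to the vegetative state.

A command-line interface mirrors the library
(`floranet steady-state`, `floranet motif-bifurcation --scenario subsystem3`,
`floranet flowering-time`, `floranet sde-ensemble`, `floranet sensitivity`,
`floranet simulate-full`, `floranet generate-data`); every run writes its
artifacts plus a manifest with the configuration and seed.

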