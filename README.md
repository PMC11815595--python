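# violakin

Kinetic modelling toolkit for dual-substrate plant cell suspension
cultures, built around *Viola odorata* batch and fed-batch cultivation:
growth kernels with Luong-type substrate inhibition, fixed-step RK4
simulation, weighted least-squares parameter estimation with a Rosenbrock
rotating-directions optimizer, F-test model discrimination, local
parameter sensitivity ranking, exhaustive in-silico fed-batch feed
design, and a seeded synthetic-data generator with known ground truth.

## Who this is for

Bioprocess engineers and modellers who need to (i) fit mechanistic
growth/uptake models to time-course data of biomass and two limiting
substrates (a carbon and a nitrogen source), (ii) choose between rival
kernel forms statistically, and (iii) design a feeding strategy that
raises biomass productivity without tipping the broth into substrate
inhibition.

## The model

Biomass `X` (g DW L⁻¹) grows on sucrose `S₁` and potassium nitrate `S₂`
(g L⁻¹) in broth volume `V` (L); time is in days:

```
dX/dt  = μX − (F/V)·X
dS₁/dt = −(μ/Y_X/S₁ + m_S₁)·X + (F/V)·(S₀₁ − S₁)
dS₂/dt = −(μ/Y_X/S₂ + m_S₂)·X + (F/V)·(S₀₂ − S₂)
dV/dt  = F
```

with feed flow `F = 0` in batch operation. The specific growth rate is a
product of a limitation and an inhibition term per substrate:

```
μ = μmax · lim₁(S₁) · lim₂(S₂) · [1 − (S₁/S_m₁)^n₃] · [1 − (S₂/S_m₂)^n₄]
```

where each `lim` is Monod `S/(S+K_S)` or sigmoid (Hill)
`Sⁿ/(Sⁿ+K_Sⁿ)` depending on the model type (Monod/Monod, Monod/sigmoid,
or sigmoid/sigmoid), and the Luong-type bracket drives growth to zero at
the ceiling concentration `S_m`. Parameters are estimated by minimizing
the weighted sum of squared residuals `Σᵢⱼ ((c_ij − ĉ_ij)/W_j)²` over
all measured species under box bounds, and rival fitted models are
compared with variance-ratio and nested-SSE F tests.

## Worked example

```python
import violakin as vk

p = vk.BATCH_FIT_MONOD_SIGMOID          # published batch fit
m = vk.ModelType.MONOD_SIGMOID

# growth rate in the optimized starting medium
mu = vk.specific_growth_rate(p, m, s1=45.6, s2=2.1)
print(f"mu at start: {mu:.3f} /d")

# the experimentally validated feeding strategy
feed = vk.FeedStrategy(v0=1.2, t_feed_start=10, t_end=17,
                       flow=0.072, feed_s1=250, feed_s2=15)
traj = vk.simulate_fedbatch(p, m, feed)
print(f"day-17 biomass: {traj.biomass[-1]:.2f} g DW/L")
print(f"productivity:   {traj.biomass[-1] / 17:.2f} g DW/L/d")

# is the extra 13th parameter of the all-sigmoid model worth it?
res = vk.f_test_nested(2.053, 2.037, 12, 13, 34)
print(f"nested F = {res.f_statistic:.3f} "
      f"(critical {res.critical_value:.3f})")
```

Output:

```
mu at start: 0.140 /d
day-17 biomass: 42.00 g DW/L
productivity:   2.47 g DW/L/d
nested F = 0.165 (critical 4.325)
```

The culture starts at 0.140 d⁻¹ (inhibition already costs ~45% of the
uninhibited rate at 45.6 g L⁻¹ sucrose), the validated feed roughly
doubles the ~22 g DW L⁻¹ batch plateau by day 17, and the nested F test
says the 13-parameter all-sigmoid kernel buys no significant SSE
improvement over the 12-parameter Monod/sigmoid combination.

A `violakin` command-line tool exposes the same pipeline
(`synth`, `fit`, `discriminate`, `sensitivity`, `simulate-batch`,
`simulate-fedbatch`, `design-feed`); see `violakin --help`.

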