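# areavar

Small-area variation analysis for nested two-level health geographies:
classical variation statistics plus a hierarchical Bayesian spatio-temporal
Poisson model, with variance partitioning, calibration checking, and a
synthetic-data generator that emulates a national hospital system (203
health-care areas nested in 17 regions observed over 12 years).

It is written for health-services and disease-mapping researchers who want
to ask: *how much of the variation in hospitalization risks happens at the
area level, how much at the region level, how much is a common time trend,
and which regions follow trajectories of their own?*

## The model

Observed admissions `o_it` in area `i` (belonging to region `j`) and year
`t`, with expected counts `e_it` from internal age/sex standardization, are
modelled as

```
o_it ~ Poisson(e_it · r_it)
log r_it = β + u_i(j) + v_j + γ_t + δ_jt
```

- `u_i(j)` — exchangeable Gaussian area effects (ICAR spatial variant
  available),
- `v_j` — exchangeable Gaussian region effects,
- `γ_t` — random walk of order 1 (each year neighbours the adjacent years),
- `δ_jt` — exchangeable region×year interaction: each region's own
  trajectory around the common trend,
- `log τ ~ logGamma(1, 0.0005)` on each precision.

Inference is Hamiltonian Monte Carlo over the latent surface interleaved
with exact conjugate updates of the precisions (see `docs/methods.md`),
with split-R̂/ESS convergence gates. The headline outputs are per-cell
relative risks, the fractions of variance attributable to the four
components, the yearly variance of spatial risks, leave-one-out PIT
calibration histograms, and an exclude-and-refit sensitivity analysis for
regions with singular trajectories.

The descriptive layer provides age/sex-standardized rates per 10,000
person-years, standardized hospitalization ratios, the extremal quotient
EQ5–95 and McPherson's systematic coefficient of variation (SCV).

## Worked example

```python
import areavar as av

geo, pop, panel, truth = av.preset_scenario(
    "PCI_like", seed=5, J=8, areas_per_region=14, T=12)
summary = av.fit(panel, geo, chains=2, warmup=400, draws=300, seed=6,
                 max_leapfrog=64)
dec = av.fractions_of_variance(summary)
for k, f in dec.fractions.items():
    print(f"{k:12s} {f:6.1%}")
```

prints (seed-exact)

```
HA            55.2%
AC            24.6%
temporal       1.0%
interaction   19.2%
```

meaning: in this PCI-like scenario just over half of the spatio-temporal
variation in log risks is attributable to area-level phenomena, about a
quarter to stable region-level differences, almost nothing to the common
national trend, and nearly a fifth to regions moving on trajectories of
their own — the signature of unevenly adopted innovations. The
`examples/` directory has one short script per capability: simulating and
writing datasets, the descriptive variation table, fitting and
decomposition, PIT calibration and exchangeable-vs-ICAR agreement, and the
singular-region sensitivity analysis.

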