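# Methods

## The problem

Hospitalization risks in a decentralized health system vary at two nested
geographic levels: health-care areas (HAs, the catchment population of one
hospital) and the regions (autonomous communities, ACs) that group them and
set policy. The questions this package answers are (i) how much areas vary
around the system average in a given year (classical small-area variation
statistics), and (ii) how the total spatio-temporal variation in risks
splits between area-level phenomena, region-level phenomena, a common
temporal trend, and region-specific departures from that trend.

## Descriptive layer

For counts `c_s` and person-years `n_s` per age×sex stratum,
the directly standardized rate is `Σ_s w_s (c_s/n_s) / Σ_s w_s × 10⁴`,
with the pooled study population as the standard (no external standard is
assumed). Expected counts use internal indirect standardization: stratum
rates pooled over *all* areas and years applied to each cell's stratified
person-years, which forces `Σe = Σo`. The standardized hospitalization
ratio is `o/e` (undefined, flagged, at zero exposure).

The extremal quotient EQ5–95 drops areas strictly outside the 5th–95th
empirical percentiles of the rate distribution and returns max/min of the
survivors. The percentile convention is Hazen plotting positions
(configurable via any numpy quantile method): in large samples this trims a
5% tail on each side, while in very small samples the extreme observations
survive, which keeps the statistic defined for toy inputs. The systematic
coefficient of variation is McPherson's estimator
`SCV = (1/k) Σ_i [(o_i−e_i)²/e_i² − 1/e_i]`, the between-area variance of
O/E ratios in excess of the Poisson noise floor; small-sample negative
values are truncated to zero and flagged.

## The spatio-temporal model

Counts are conditionally Poisson with offset expected counts,

    o_it ~ Poisson(e_it · r_it),
    log r_it = β + u_i(j) + v_j + γ_t + δ_jt ,

with exchangeable Gaussian area effects `u` (an intrinsic CAR variant on
the area adjacency graph is available), exchangeable Gaussian region
effects `v`, an intrinsic first-order random-walk prior on the temporal
effect `γ` (each year's neighbours are the adjacent years), and an
exchangeable region×year interaction `δ` that lets every region carry its
own trajectory around the common trend. Precisions get
`log τ ~ logGamma(1, 0.0005)` hyperpriors, read — as is standard in this
literature — as `τ ~ Gamma(shape 1, rate 0.0005)` on the precision scale.
`β` has a flat prior.

### Identifiability

Intrinsic priors and the nesting of effects leave the level of each block
unidentified. Every random-effect block is parameterized directly in the
orthonormal sum-to-zero (Helmert) subspace of its index set, so
`mean(u) = mean(v) = mean(γ) = mean(δ) = 0` holds exactly in every reported
draw and the overall level lives in `β`. For the intrinsic RW1/ICAR priors
that subspace is exactly their proper support; for exchangeable blocks it
is the iid Gaussian law conditioned on a zero mean.

### Inference

Inference is MCMC, exact in the limit and self-diagnosing, rather than a
deterministic approximation: the posterior contract (draws, relative-risk
summaries, diagnostics) is engine-agnostic. The sampler alternates

1. one Hamiltonian trajectory on the latent surface (`β` and all blocks),
   with dual-averaging step-size adaptation, windowed diagonal mass
   estimation, and trajectory lengths jittered over the upper half of
   `[1, max_leapfrog]`;
2. exact conjugate Gibbs draws of the four precisions
   (`τ | block ~ Gamma(shape + df/2, rate + qf/2)`);
3. exact Gaussian "re-splitting" Gibbs updates along the
   likelihood-invariant overlaps between nested blocks (region patterns can
   sit in `v`, in within-region means of `u`, or in time-means of `δ`;
   common yearly shifts in `γ` or year-means of `δ`). The linear predictor
   is unchanged to machine precision by these moves; without them the
   variance split between nested components mixes extremely slowly;
4. interweaving scale moves: Metropolis proposals that rescale a block and
   its precision jointly while holding the standardized (non-centered)
   coordinates fixed, which traverses the `(σ, effect)` ridge.

Cycle (2)–(4) is run three times per trajectory; it costs a few grid
evaluations against ~100 gradient evaluations per trajectory. Defaults:
2 chains, 600 warmup + 500 kept draws, `max_leapfrog = 128`, target
acceptance 0.9. Convergence gates are split-R̂ ≤ 1.05 and bulk ESS ≥ 100 on
`β` and the log precisions (via arviz); a violating fit is *flagged*
(`converged=False`, a `ConvergenceWarning`), never silently accepted.
Chains are deterministic given the seed.

Relative-risk summaries report both posterior means and medians per cell
(which of the two the original analyses reported is not documented).

### A note on the hyperprior at small scale

`Gamma(1, 0.0005)` on a precision is extremely diffuse, and its marginal
likelihood has a large (integrable) spike as a variance component
approaches zero — the gain grows like `((J−1)/2)·log(qf/rate)`. When the
number of regions is small and the area effects can absorb region-level
structure, the posterior legitimately hedges toward `σ_v ≈ 0`: with ~5–6
regions of ~4–8 areas the estimated region share of variance can be
substantially smaller than the generative one even though the *total*
region surface is tracked accurately. The effect disappears at the study's
real dimensions (203 areas), where absorbing region structure into the area
term is far too expensive. Desk-scale analyses of the region share should
therefore use at least ~8 regions × ~14 areas; this is the scale the
scenario-comparison tests use. This is a property of the stated prior, not
of the sampler: long independent chains agree on the hedged posterior.

## Variance decomposition

Components live on different index sets, so each is expanded to the common
(area, year) grid: `u` repeated over years, `v` and `δ` broadcast to member
areas, `γ` broadcast to areas. Per posterior draw the empirical variance of
each expanded surface is computed over all cells, averaged over draws, and
normalized to fractions (the exact estimator behind the published
decompositions is not documented, so outputs are tagged with the weighting
and source). Default weighting is per-cell (regions implicitly weighted by
their area counts); per-unit weighting (variance over the native index set)
is available and coincides with per-cell weighting on balanced designs.
The yearly risk-variance series is the variance across areas of the
posterior-mean log relative risk, per year (a risk-scale basis is
available; the basis is tagged in the output since the published magnitudes
do not pin it down).

The singular-region flagger scores each region by the mean over years of
`|posterior mean δ_jt|` standardized by the posterior SD of `δ_jt` —
advisory only, ordering candidates for the exclude-and-refit sensitivity
analysis, which drops all areas of the named regions and reports both
decompositions side by side.

## Calibration and agreement

PIT calibration uses the non-randomized mean-PIT for counts
(`u = (F(o−1) + F(o))/2` with the predictive CDF averaged over draws,
10 bins, and a chi-square uniformity statistic). By default the predictive
CDF per cell is the importance-weighted leave-one-out predictive (draw
weights ∝ reciprocal of that cell's likelihood): the plain in-sample
posterior predictive conditions on the very observation being checked and
produces a spurious central hump even for a well-specified model, while the
LOO correction restores near-uniformity; the in-sample variant remains
available (`leave_one_out=False`).

Agreement between the exchangeable-area and ICAR-area fits is quantified by
the one-way random-effects intraclass correlation ICC(1,1) on paired
per-cell risk estimates (the ICC flavor is configurable in principle; the
one-way single-measurement form is the default since the comparison treats
the two models as anonymous raters).

## Synthetic-data generator

The generator is the stand-in for the real hospitalization registry and
defines the study conditions:

- **Geography** — Voronoi cells of uniform points on the unit square;
  adjacency from shared borders (the Delaunay dual, always connected);
  regions are contiguous strips of areas sorted by first coordinate, which
  honours exact per-region size specifications. Default: 203 areas in 17
  regions.
- **Population** — per-area totals log-normal with median 159,000 and IQR
  (80,000–263,000) (median pins μ; σ fitted to the quartile ratio); a fixed
  adult age pyramid over 5-year bands from 20 to 85+ by sex; slow per-area
  annual drift (mean +0.2%, SD 0.4%). Stratum reference rates follow a
  log-linear age gradient (+5.5%/year of age) with a 1.4× male excess,
  scaled so the pooled crude rate matches the requested baseline.
- **Components** — `u`, `v` iid centered Gaussians; `γ` either a
  deterministic shape (linear up/down, inverted-V with the peak at ~65% of
  the window, i.e. 2009 for 2002–2013) rescaled to the requested SD, or a
  genuine RW1 draw (increment SD as given) for recovery studies; `δ` iid
  centered, optionally amplitude-modulated (below). Counts are drawn per
  stratum, `o_its ~ Poisson(n_its·rate_s·exp(η_it))`, so stratified
  observed counts are available for internal standardization.
- **Presets** — three archetypes whose component SDs are set from the
  published variance-decomposition profiles (PCI 51.6/28.6/2.1/17.7%,
  CCC 54.7/26.6/9.1/9.6%, COPD 56.9/37.0/3.0/3.1%, normalized), whose
  year-one crude rates are calibrated exactly to the published starting
  rates (7.7, 4.2, 21 per 10,000 person-years) via the intercept, and whose
  common trends match the published shapes (up / inverted-V / down). Total
  log-risk variance per condition (0.09, 0.03, 0.20) is set from the
  published yearly risk-variance magnitudes. The published sources are
  internally tense here — the PCI rate rise implies a far larger temporal
  component than its 2.1% variance share — and the presets resolve this in
  favour of the variance profile, since every trend check downstream is a
  sign test.
- **Interaction modulation** — a stationary iid `δ` cannot produce the
  reported *rising* (PCI-like) or *collapsing* (COPD-like) spread of
  regional risks over time. Presets therefore tie a fraction
  (`interaction_mix`: PCI 0.6, CCC 0, COPD 1) of `δ`'s variance to the
  region pattern with a linearly growing or shrinking amplitude,
  `δ_jt ∝ g̃_t·ṽ_j`, exactly centered in both margins so nothing leaks into
  `γ` or `v`. The fitted region×year interaction can represent this surface
  exactly.
- Every drawn component is centered over its own index set so generative
  fractions of variance are well defined. Components are *not* rescaled to
  their nominal SDs: realized variances carry natural sampling noise, and
  recovery checks therefore compare against the realized (not nominal)
  fractions and precisions — the likelihood only ever sees the
  realization. For the RW1 trend the recorded precision is that of the
  realized increments.

What the generator does **not** emulate: real administrative boundaries or
demography, migration, within-year seasonality, coding or allocation
artefacts, covariate-driven confounding. Passing tests show the method
recovers the structures in its own generative class at desk scale, not that
the substantive published conclusions transfer to other data.

## Problem sizes used in the test suite

Test and script problem sizes are the package's own scaling choices:
recovery studies use 5 regions × 8 areas × 10 years with short chains (2 ×
400–500 draws); scenario-archetype comparisons use 8 regions × 14 areas ×
12 years; calibration studies 4 × 4 × 8. The full 203-area geometry is
exercised by the generator tests and the dataset-writing example.

## Known limitations

- Interaction types with structured time or space dependence (beyond
  exchangeable region×year) are out of scope, as are covariates.
- The ICAR variant replaces only the area-level exchangeable term; it keeps
  the region level, and no convolution (BYM) variant is provided.
- The fraction-of-variance estimator includes posterior spread, which
  slightly inflates small components in weakly informed fits.
- At few-region desk scales the region-variance share inherits the
  hyperprior hedging described above.
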