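# Methods

## Scope and data model

The package analyzes a replicated two-treatment (Control vs. NPK+)
grassland nutrient-addition design: per site, K (default 3) permanent 1 m²
subplots per treatment, sampled annually for species percent cover and
clipped aboveground live biomass (g m⁻²), over 4–9 post-treatment years.
Each subplot is one "community"; the K subplots jointly are the larger
scale.  The unit of computation is the `CommunityTensor`: a dense
`(species, subplot, year)` cover array plus a `(subplot, year)` biomass
array for one site × treatment × duration window covering post-treatment
years 1..d.

Data-preparation conventions:

- Sites sampled twice a year are collapsed to annual records by the
  seasonal **maximum**, for cover per species and for biomass per subplot.
  For biomass the choice between maximum and the seasonal sum is a genuine
  judgment call; maximum is the default (symmetric with cover, avoids
  double-counting standing tissue through regrowth), `how="sum"` is
  available.
- Taxa inconsistently identified over time are aggregated (typically to
  genus) by summing cover within subplot-years, which conserves total
  summed cover.
- Species not recorded in a subplot-year within a window are true zeros,
  not missing values.  Summed cover may exceed 100% (multilayer canopies)
  and is never renormalized.
- Biomass is the completeness authority: every subplot-year in a window
  must carry a biomass record, otherwise the window is rejected with the
  list of gaps.

## Stability and asynchrony partition

Stability at any scale is invariability: temporal mean over temporal
standard deviation.  Species-level statistics (species stability, species
asynchrony) are computed on cover; community-level statistics (alpha,
gamma stability, spatial asynchrony) on biomass.  Covariances use the
sample denominator n−1.  The two asynchrony indices are variance-weighted
incoherence ratios, ≥ 1 by Cauchy–Schwarz, equal to 1 under perfect
synchrony, and they link the scales exactly:

- alpha stability × spatial asynchrony = gamma stability,
- species stability × species asynchrony = alpha stability computed on
  cover.

The species-asynchrony denominator is read as Σ_k √(Σ_ij w_ij,kk) — the
within-subplot variance of total community cover, summed over subplots
after taking square roots.  The subscripts of this term are often printed
ambiguously; this is the only reading under which the multiplicative chain
above holds, and the chain is enforced in tests to 1e−10.

Zero denominators (e.g. perfectly compensating species) yield flagged
infinities rather than exceptions; the log-transform step converts
non-positive/non-finite values to missing with a counted warning, and the
pipeline excludes such windows from inference, reporting the count.

**Detrending** (optional, off by default): each species-subplot cover
series and each subplot biomass series is replaced by the residuals of an
ordinary least-squares regression on the year index *inside the
covariance computations only*; the means in the numerators stay raw.
Detrending requires ≥ 3 years.

## Diversity indices

Local indices are computed per subplot and averaged: richness is the
annual count of species with positive cover averaged over subplot-years;
Shannon H (nats) and inverse Simpson D are computed, by default, on each
subplot's species-wise temporal mean cover over the window
(`TIME_MEAN_COVER`), which yields the design's "one value per site,
treatment and duration".  Computing indices per year and then averaging
(`ANNUAL_THEN_AVERAGE`) is available because the averaging order is a
genuinely open choice; richness always uses annual counts.  Evenness is
Pielou J = mean H / ln(mean richness), undefined (missing, warned) at mean
richness 1.  Gamma diversity is the inverse Simpson of subplot-summed
cover; multiplicative beta = gamma / mean local D.

Caveat: with an *arithmetic* mean of local inverse Simpson in the
denominator, beta is not mathematically confined to [1, K] — unequal
subplot evenness or totals can push it slightly below 1 (values around
0.95 occur on noisy windows).  The definition is kept as stated because it
is the one directly comparable to metacommunity theory; the [1, K] bound
is exact when subplots share an abundance spectrum, and is tested there.

## Inference

- **Path model** (per duration window and treatment, sites as replicates):
  every variable z-scored, each endogenous variable regressed on its
  parents by OLS.  Default structure: richness → species stability;
  richness → species asynchrony; species stability + species asynchrony →
  alpha stability; beta diversity → spatial asynchrony; alpha stability +
  spatial asynchrony → gamma stability.  The richness–beta association is
  exogenous and reported as a Pearson correlation, not a directed path.
  Stability/asynchrony variables enter on the natural-log scale.
  Coefficient SEs are the least-squares SEs on z-scored variables; no
  small-sample correction.  No d-separation/global-fit test is computed.
- **Meta-analysis** across durations: fixed-effect inverse-variance
  pooling (weights 1/SE²) with the Cochrane heterogeneity Q;
  DerSimonian–Laird random-effects estimates are reported alongside.
  Duration windows are nested (years 1..4 ⊂ 1..5 ⊂ …), so the pooled
  estimates treat correlated inputs as independent; this follows the
  standard protocol for this design and is the main reason pooled SEs
  should be read as descriptive rather than strictly calibrated.  With a
  single duration window the lone estimate stands in for the pool.
- **Treatment contrast** per path: two-group Q = (θc − θf)² / (SEc² +
  SEf²), df = 1, p from χ²₁.
- **Bivariate slopes** with AR(1) errors across nested duration windows
  per site: iterated Cochrane–Orcutt — estimate ρ from within-series lag-1
  residual autocorrelation, quasi-difference (dropping each series' first
  observation), refit, iterate to |Δρ| < 1e−8 (max 100 iterations;
  non-convergence returns the last iterate, flagged).  ρ may be fixed
  (ρ = 0 reproduces OLS exactly).
- **ANOVA**: two-way (treatment, duration), type-II sums of squares.
- **Climate adjustment**: residuals of a site-level OLS on the CVs of
  annual precipitation and temperature; near-collinear covariates
  (|r| > 0.999) drop one with a warning.
- **Log response ratios**: ln(fertilized/control) per site and duration
  for positive-valued metrics.

## Synthetic experiment generator

The generator emulates the study's *structure*, not any particular
dataset.  Per site: a species pool of size P ~ uniform on
`richness_range` (default 8–28) with lognormal mean covers (meanlog 1.3,
sdlog 1.0, in percent; subplot totals ~60–120%); each subplot community is
a weighted sample of local richness 0.75·P — a shared core (fraction ω of
species, ω ~ uniform on (0.3, 0.95) per site) plus subplot-specific
extras.  Because abundance-based beta responds to turnover of *dominants*,
ω also governs a per-subplot permutation of abundance ranks among a
(1−ω) fraction of species: every subplot carries the same abundance
spectrum (so the variance-weighted asynchrony indices respond to
correlation, not scale imbalance) but different species in the dominant
roles.

Log cover of a present species is

    ln cover[i,k,t] = ln mean[i,k] − V/2 + e[k,t] + τ·η[i,t] + σ·z[i,k,t]

with e[k,t] the subplot-year environment (sd `env_sd` = 0.15, equicorrelated
across subplots at `rho_space` = 0.25), η[i,t] a species-specific response
to the year shared across subplots (weight τ = `tau_b` = 0.8), z independent
noise (σ = 0.15), and V the total log-variance so the expectation is exactly
`mean[i,k]`.  The species-specific response must be *additive* in this way:
scaling one shared environmental series per species would leave all
log-series perfectly correlated and produce no asynchrony at any τ.  Species
response heterogeneity is what makes richer communities more asynchronous
and compositionally distinct subplots fluctuate out of phase.  Subplot
biomass is `mass_per_cover` (4 g m⁻² per percent) times summed cover with
5–10% multiplicative noise.

The variance budget (env_sd, rho_space, tau_b, σ) was set so that the
built-in insurance effects are detectable at the study's scale (42 sites,
4–9 years) while metric levels stay realistic (alpha stability ≈ 1–5,
species stability ≈ 0.7–1.5, species asynchrony ≈ 1.3–4.5, beta ≈ 1–2).

Fertilization effects apply to the NPK arm only: each fertilized subplot
drops its rarest species with expected count `richness_loss` (default 1.8,
Poisson; random loss available), species means are multiplied by
`biomass_multiplier` (1.3), response heterogeneity τ shrinks by
`homogenization` (0.8), and the shared environmental response is amplified
by `1 + fert_destabilization·rich_norm` (destabilization 1.0, rich_norm the
site's position on the richness gradient).  The amplification is of
*common* variance deliberately: it lowers species stability most at
species-rich fertilized sites (the built-in treatment × richness
interaction) while also synchronizing species there, producing the
attenuated diversity–asynchrony relationships under fertilization.  An
earlier design that inflated independent noise instead was discarded
because it *raised* species asynchrony with richness — the opposite
phenomenology.

Environmental series are drawn independently for the two arms.  Sharing
site-year fluctuations across arms would correlate the per-arm coefficient
estimates and make the treatment-Q contrast conservative; independent
draws keep it calibrated, at the cost of understating the spatial pairing
of real treatment plots.  The species pool, compositions, and niche
assignment are shared between arms.

Determinism: each site consumes an independent child stream of the seed
(`SeedSequence.spawn`), with a fixed documented draw order, so outputs are
byte-identical given a config and seed.  Climate covariates (CVs of
precipitation and temperature) are drawn uniform per site and written to a
separate table; they are covariates for residualization only, not drivers
of the simulated dynamics.

Presets: `control_like` (no fertilization effects in either arm — the NPK
arm is a statistical replicate; diversity stabilizes), `fertilized_like`
(all fertilization effects on), `null_world` (τ = 0, ω = 1, no
fertilization effects: no diversity–stability relationship, null
treatment contrast).

**What passing tests do and do not show.**  The generator reproduces the
experiment's dimensions, the lognormal abundance structure, shared
interannual fluctuation with species-specific responses, compositional
turnover, and the direction of fertilization effects.  It does not
reproduce observation error in visual cover estimation, temporal
occupancy turnover (community membership is fixed over a window),
demographic autocorrelation (years are exchangeable given the
environment), climate-driven dynamics, or any real dataset's parameter
values.  Recovery results therefore validate the estimators and pipeline
under a known truth, not any empirical claim about real grasslands.

## Problem sizes and numerical choices

- Identity and bound checks run on 1,000 random tensors (2–10 species,
  2–3 subplots, 4–9 years) at relative tolerance 1e−10; agreement with a
  brute-force covariance-expansion oracle on 200 small tensors at 1e−10.
- Parameter-recovery checks run the full pipeline on 20 paired seeds of
  the 42-site worlds; the null calibration uses 200 seeds of a reduced
  30-site, 4-year null world (a single duration window, where the
  two-group Q contrast is exact; at 20 sites the normal approximation to
  the standardized-coefficient distribution is visibly heavy-tailed).
- ANOVA type-I calibration uses 1,000 pure-noise replicates of a balanced
  2 × 3 design (36 rows).
- Covariance sums are clipped at −1e−12 before square roots (an assertion
  fails loudly below that); tiny negative round-off becomes 0.
- CSV outputs are written with `%.12g` floats; determinism is exact bytes.

## Known limitations

- Homogenization in the generator removes species-specific variance
  outright, so fertilized communities can be *more* stable in absolute
  terms even while every diversity–stability relationship attenuates; the
  fertilization effects of interest here are on the relationships, not on
  absolute stability levels.

- Pooled meta-analytic SEs across nested durations ignore the correlation
  between windows (see above).
- Beta diversity can dip slightly below 1 (see above).
- Because log gamma stability is an exact function of log alpha stability
  and log spatial asynchrony (the multiplicative identity), the gamma
  regression of the path model is deterministic: its R² is 1 and its
  coefficient SEs are numerically ~0, so pooled CIs for those two paths
  collapse and their treatment-Q values are not interpretable.
- The AR(1) slope assumes a common ρ across series and drops each
  series' first observation (Cochrane–Orcutt rather than Prais–Winsten).
- `fixed_rho` aside, ρ estimation on very short series (3–4 windows) is
  noisy and occasionally non-convergent; the last iterate is returned
  flagged.
- The CLI's `analyze` subcommand expects metric tables produced by
  `metrics` in the same output directory.
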