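# Methods

## The problem

A single-season camera-trap survey observes a mammal community
imperfectly: rare or shy species can go entirely undetected, so the
count of species photographed is a biased floor on true species
richness. `camtrap_msom` implements the standard remedy — a
hierarchical multi-species occupancy model (MSOM) with parameter-
expanded data augmentation in the Dorazio–Royle tradition — together
with the data preparation and downstream summaries that a camera-trap
richness analysis needs.

## Data preparation

**Independence filtering.** Consecutive images of the same species at
the same station are serially dependent (an animal lingering in front
of the camera). Within each (site, species) stream — (site, kind) for
humans and livestock — records are processed in time order and a record
is retained iff at least `window_minutes` (default 60) have elapsed
since the previously *retained* record. This greedy-from-first rule is
the common camera-trap convention; a gap of exactly the window counts
as independent. Filtering is idempotent, and cross-camera deduplication
is deliberately out of scope: deciding whether two nearby cameras
photographed the same individual requires human judgment (movement
direction, distances), not a timestamp rule.

**Detection histories.** The deployment window of site *i* (inclusive
dates) yields `n_i` whole occasions; the default occasion is one day,
which for 74–107-day deployments gives effort in the 74–107 range. A
trailing partial occasion is dropped when `occasion_days > 1`. The
response for species *k* is `y_ik`, the number of occasions with at
least one independent detection; multiple independent records on one
day still count one occasion. Only `kind = wildlife` records
contribute; only species with at least one detection appear.

**Covariates.** Four per-site covariates: mean elevation and mean
terrain ruggedness within a buffer (default 100 m) of the station, mean
canopy cover in the same buffer, and the count of independent
human/livestock images (disturbance). TRI follows the
root-sum-of-squares definition: `sqrt(sum over 8 neighbours
(e_nbr − e_ctr)^2)`, border cells using the neighbours that exist.
Buffer means average all cells whose *center* falls inside the circle —
the simplest reproducible partial-cell rule. Rasters are plain planar
grids (metre units) serialized as ESRI ASCII text; projected inputs are
the caller's responsibility. All base covariates are standardized to
mean 0, sample sd 1 (the n−1 denominator), and the quadratic elevation
term is the square of the *standardized* elevation, not re-standardized,
so all five design columns live on comparable scales. Disturbance
enters raw (then standardized); no log transform.

## The model

For species `k = 1..M` (observed `K` plus `M−K` all-zero augmented
rows; default augmentation size `n_aug = K`) and site `i = 1..I`:

    w_k  ~ Bernoulli(Omega)                      community membership
    z_ik ~ Bernoulli(psi_ik)                     latent occupancy
    y_ik ~ Binomial(n_i, p_k · z_ik · w_k)       observation
    logit(psi_ik) = beta_0k + Σ_m beta_mk X_mi
    beta_mk   ~ Normal(mu_m, sigma_m^2)          community pooling
    logit p_k ~ Normal(mu_p, sigma_p^2)

Detection is constant per species across sites and occasions. Community
richness is the derived quantity `N = Σ_k w_k`, and site richness
`N_i = Σ_k w_k z_ik`. Hyperpriors are weakly informative:
`mu ~ Normal(0, 10^2)`, `sigma ~ Uniform(0, 5)`, `Omega ~ Beta(1, 1)`.
The detection hierarchy mirrors the occupancy hierarchy — standard MSOM
practice. Hyperparameters are shared across species (they must be, for
pooling to happen); `w_k = 1` is forced for observed species.

Writing the observation kernel as `Binomial(n, p·z·w)` (rather than
putting `w` inside the occupancy kernel) makes the `z` conditional for
an excluded species its prior `Bernoulli(psi)`; the two
parameterizations are marginally identical.

## The sampler

A purpose-built Metropolis-within-Gibbs sampler; one sweep updates:

1. **z** — exact Bernoulli conditional. Detection forces presence;
   otherwise `P(z=1) = psi(1−p)^n / (psi(1−p)^n + 1−psi)` for members,
   prior `psi` for non-members.
2. **w** (augmented species only) — the species' own `z` row is
   marginalized out, giving `P(w=1) = Ω·L1 / (Ω·L1 + 1−Ω)` with
   `L1 = Π_i [psi_ik(1−p_k)^{n_i} + 1−psi_ik]`; the `z` row is then
   redrawn under the new `w`. Collapsing avoids the absorbing state a
   naive joint (z, w) update would create.
3. **Omega** — conjugate `Beta(1+Σw, 1+M−Σw)`.
4. **Species parameters** — random-walk Metropolis, vectorized across
   species: a Gaussian block proposal on `beta_k` scored by the
   Bernoulli z-likelihood plus its normal prior, then a scalar proposal
   on `logit p_k` scored by the binomial likelihood on occupied sites.
   Species with `w = 0` have a flat likelihood and draw both directly
   from the community priors (a valid partially collapsed move: their
   stale `z` row is not consumed before the next z-update).
5. **Hyperparameters** — conjugate normal draws for the means;
   random-walk on `log sigma` with the Jacobian term and the
   Uniform(0, 5) support enforced.

Proposal scales adapt toward ~35% acceptance during burn-in only
(multiplicative Robbins–Monro steps every 50 iterations) and are frozen
afterwards, preserving detailed balance for all retained draws. Chains
are initialized at the presence matrix plus Bernoulli(0.5) fill for
`z`, `w = 1` everywhere, and hypermeans jittered per chain
(chain-indexed child seeds) for overdispersed starts. Default run
settings are three chains of 100 000 iterations, 5 000 burn-in,
thinning by 60; every run is bit-reproducible from its seed.

Convergence is summarized with the classic Gelman–Rubin statistic
(`R̂ = sqrt(((n−1)/n·W + B/n)/W)`), reported per parameter; 1.1 is used
as a warning threshold, never as an automatic stop. Numerics: all
Bernoulli/binomial terms are evaluated through `log1p`/`logaddexp`
forms, so extreme `psi` or `p` cannot overflow; a zero within-chain
variance yields an undefined (NaN) `R̂` flag rather than an exception.

### Validation strategy

Three independent oracles back the sampler, all in the test suite:
exhaustive enumeration of the joint posterior over all `(z, w)`
configurations on instances with `M ≤ 3`, `I ≤ 3`, `n_i ≤ 2` (full
conditionals agree to 1e-10); deterministic 2-D grid integration of a
one-species model with fixed hyperparameters (Kolmogorov–Smirnov
distance of the sampled marginals < 0.05 at 20k draws); and replicated
recovery on synthetic data at the survey regime described below.

## Downstream summaries

**Richness regression.** Posterior-mean site richness `E[N_i]` is
regressed on the five standardized design columns by OLS with
intercept (statsmodels under the hood; tests verify the closed-form
normal-equations solution to 1e-10). We report `beta`, `se`, the 95%
t-interval, `t`, two-sided `p`, and state the residual df explicitly
(`I − 6` for the full design). Using the posterior mean as response is
a pragmatic default — it ignores posterior uncertainty in `N_i` — and a
draw-wise regression is possible with the stored `N_i` draws.

**Accumulation curve.** Distinct species detected pooled across sites
by survey day, with the posterior mean of `N` (± 1 posterior sd) as a
reference line; the curve is non-decreasing and ends at `K`.

**Activity overlap.** The overlap coefficient `Δ̂₁ = ∫ min(f̂, ĝ)`
between two diel densities, each a von Mises kernel density on the
24-h circle with the plug-in concentration of Taylor's circular
bandwidth rule (evaluated with exponentially scaled Bessel functions
for stability), integrated by the trapezoid rule on a 512-point grid
and clipped to [0, 1]. `Δ̂₁` is the conventional estimator for modest
sample sizes. Bootstrap intervals for `Δ̂` are out of scope.

## The synthetic-data generator

The generator is the forward model, and its defaults pin the regime
this package targets: `I = 45` stations active 74–107 days, a true
community of `N_true = 26` species, community mean occupancy 0.28 and
per-occasion detection 0.02 on the logit scale, covariate-driven
occupancy (community slope means −0.3 elevation, −0.4 elevation²,
+0.1 ruggedness, +0.4 canopy, +0.2 disturbance; between-species sd
0.5). The between-species sds (1.5 occupancy intercept, 2.0 detection)
were chosen so that a survey of this size typically detects ~20–26 of
the 26 species — the heavy low-`p` tail is what makes whole species go
unseen, which is the phenomenon the model exists to correct.

`simulate_camera_records` expands detection days into timestamped
bursts (base image plus Poisson follow-ups within 40 minutes), places
human/livestock traffic on distinct two-hourly slots so the independent
disturbance count per site equals the covariate table exactly, and
sprinkles blank triggers. All timestamps stay within 02:00–23:00 so
that bursts can never straddle the one-hour independence window across
midnight: by construction the ingest pipeline recovers the generating
detection matrix *exactly*, and the round trip is asserted in the
tests. This timestamp restriction is also the generator's main
unrealism: real wildlife activity is strongly nocturnal/crepuscular, so
the record-level generator should not be used to study diel activity
(use `simulate_activity_times`, which produces proper circular midday
vs crepuscular mixtures, for that).

What passing recovery tests show — and what they do not: they show the
sampler inverts its own forward model at the stated regime (95% CRI for
`N` covering truth in ≥85% of replicates, community occupancy/detection
posterior means unbiased within 0.05). They do not certify performance
on real surveys, where occupancy is spatially autocorrelated, detection
varies with occasion and weather, cameras fail mid-deployment, and
species identity can be misassigned — none of which the generator
emulates.

## Problem sizes used in routine checks

The replicated calibration runs 50 synthetic surveys at the full study
dimensions (45 sites, 26 species, 52 augmented rows) but with a single
chain of 6 000 iterations (2 000 burn-in, thin 2) per replicate; the
grid-oracle and enumeration checks use deliberately tiny instances.
These reduced chain lengths are a deliberate package choice so the
whole suite runs routinely; the pipeline default remains 3 × 100 000.
Acceptance reporting (`scripts/acceptance.py`) uses two chains of
15 000 for the single showcase fit and ten replicates for the coverage
check.

## Known limitations

- Single season, closed community; no multi-season dynamics.
- Detection constant within species: no occasion- or site-level
  detection covariates.
- No spatial autocorrelation in occupancy; sites are exchangeable given
  covariates.
- Cross-camera dependence of detections is not modelled or filtered.
- The augmentation ceiling `M` caps the richness posterior; if the
  posterior for `N` piles up near `M`, `n_aug` must be raised.
- Community means are summarized as `logit^{-1}(mu)` (the median
  species), not the mean of species-level probabilities; with the
  heavy-tailed spreads used here the two can differ noticeably.
- GeoTIFF rasters are not read directly; convert to ESRI ASCII grids or
  supply a per-site covariate table.
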