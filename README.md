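# camtrap-msom

Multi-species occupancy modelling and species-richness estimation for
camera-trap surveys.

Camera traps detect wildlife imperfectly: a species can occupy a
surveyed landscape yet never trigger a camera, so the raw species list
undercounts true richness and naïve occupancy (fraction of stations
with a detection) understates true occupancy. This package implements
the standard hierarchical fix for single-season surveys — a Bayesian
multi-species occupancy model (MSOM) with data augmentation — plus
everything around it: building detection histories from raw image
records, deriving standardized site covariates, a purpose-built MCMC
sampler, and downstream summaries (richness regression, species
accumulation, diel activity overlap). It is aimed at wildlife
ecologists analyzing community camera-trap data and at methodologists
who want a transparent, fully tested reference implementation of the
augmented MSOM.

## The model

For species `k` (observed `K` plus `M−K` all-zero augmented rows) and
site `i` with `n_i` daily occasions:

```
w_k  ~ Bernoulli(Ω)                        is k part of the community?
z_ik ~ Bernoulli(ψ_ik)                     latent occupancy
y_ik ~ Binomial(n_i, p_k · z_ik · w_k)     detections
logit(ψ_ik) = β_0k + Σ_m β_mk X_mi         covariate model
β_mk ~ N(μ_m, σ_m²),  logit(p_k) ~ N(μ_p, σ_p²)
```

Species richness is the derived posterior `N = Σ_k w_k`, so the model
estimates how many species the survey *missed*. The sampler is
Metropolis-within-Gibbs with exact conditionals for `z`, `w` (collapsed
over the species' latent occupancy) and `Ω`, adaptive random-walk steps
for species and hyper parameters, and classic Gelman–Rubin diagnostics.
See `docs/methods.md` for the full account and validation strategy.

## Worked example

Simulate a survey at the package's default regime (45 stations active
74–107 days, a 26-species community with mean occupancy 0.28 and
per-occasion detection 0.02), push the raw records through the ingest
pipeline, and fit the model:

```python
import camtrap_msom as cm

history, truth = cm.simulate_community(seed=11)
records, deployments = cm.simulate_camera_records(truth, seed=11)
independent = cm.filter_independent(records, window_minutes=60)
history2 = cm.build_detection_history(independent, deployments)
print("species x sites:", history2.y.shape, " trap nights:", history2.n.sum())

data = cm.augment(history2, design=truth.design)
cfg = cm.MCMCConfig(n_chains=3, n_iter=20_000, burn_in=4_000, thin=8, seed=11)
samples = cm.run_mcmc(data, cfg)
print(samples.summary().loc[["N", "psi_community", "p_community"]].round(3))

sr = cm.site_richness(samples)
reg = cm.richness_regression(sr.mean, truth.design)
print(reg[["term", "beta", "se", "p"]].round(3).to_string(index=False))
```

Output:

```
species x sites: (22, 45)  trap nights: 3974
                 mean     sd    q2.5  median   q97.5   rhat
N              26.454  4.443  22.000  25.000  39.000  1.000
psi_community   0.428  0.095   0.232   0.429   0.608  1.047
p_community     0.017  0.013   0.001   0.015   0.048  1.004
        term   beta    se     p
       const 11.844 0.247 0.000
   elevation  0.211 0.177 0.238
elevation_sq -1.637 0.180 0.000
         tri  0.003 0.198 0.986
      canopy  1.613 0.177 0.000
 disturbance  0.772 0.192 0.000
```

Reading this: 22 of the 26 simulated species were actually detected;
the posterior for `N` (mean 26.5, 95% CRI 22–39) recovers the truth the
survey could not see directly. `psi_community` and `p_community` are
the community mean occupancy and per-day detection probability
(`logit⁻¹` of the hypermeans). The regression of posterior-mean site
richness on the standardized covariates recovers the generator's
quadratic elevation profile (negative `elevation_sq`) and positive
canopy and disturbance effects; `se` here reflects only the spread of
posterior-mean richness across the 45 sites.

The same pipeline is scriptable from the shell:

```bash
msom simulate --sites 45 --richness 26 --seed 1 --out synth/
msom ingest --records synth/records.csv --deployments synth/deployments.csv --out ingested/
msom fit --history ingested/detection_history.csv --effort ingested/effort.csv \
         --covariates synth/covariates.csv --chains 3 --iters 20000 --out posterior/
msom run --config run.yaml        # or the whole thing from one YAML config
msom overlap --records synth/records.csv --group-a disturbance --group-b wildlife
```

Real surveys enter through the same two CSVs (`records`: site, kind,
species, timestamp; `deployments`: site, x, y, start, end) plus either
a per-site covariate table or elevation/canopy rasters as ESRI ASCII
grids.

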