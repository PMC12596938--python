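# avian-itv

Hierarchical Bayesian estimation of **within-population phenotypic
variation** in bird morphology, and of what drives it — across each
species' range and among species.

Large banding programs measure body mass and wing chord for hundreds of
thousands of individual birds at stations across a continent. The amount of
trait variation *within* a single population (one species at one station)
is itself a biological quantity: it fuels selection, buffers environmental
change, and varies systematically with geography and life history. This
package provides the full analysis chain for such data, for ecologists and
evolutionary biologists working with capture–recapture morphology records:

1. **Filtering** (`avian_itv.filters`) — adult males only, first capture per
   season, 5-MAD outlier exclusion per station × species, and sample-size /
   spatial-coverage inclusion rules iterated to a fixed point.
2. **CV estimation** (`avian_itv.cv_model`) — a hierarchical normal model of
   log traits: `y_ijk ~ N(mu_jk, sigma_jk)` with species-level and global
   layers; the coefficient of variation `CV_jk = sigma_jk / mu_jk` is derived
   per posterior draw, so every downstream step carries its full
   sample-size-aware uncertainty (`cv_hat ± tau_hat`).
3. **Covariates** (`avian_itv.covariates`) — latitude; distance to the range
   edge with 10-km gap closing; spatial and temporal CV of a productivity
   raster in a 10-km buffer; species-level generation time, hand-wing index,
   range size and migratory status.
4. **Within-species regression** (`avian_itv.within_model`) — measurement-error
   model `cv_hat ~ N(theta, tau_hat)`, `theta ~ N(alpha_k + x'beta_k,
   sigma_theta)`, with correlated species-specific coefficient vectors
   `(alpha_k, beta_k) ~ MVN(mu, Sigma)`.
5. **Among-species regression** (`avian_itv.among_model`) — species-average
   CVs on life-history covariates with phylogenetically correlated
   intercepts `eta ~ MVN(0, sigma_phylo^2 P)`, `P` the Brownian-motion
   correlation from the tree's patristic distances.
6. **Synthetic data** (`avian_itv.synth`) — a generative inverse of the whole
   chain (captures, raster, range polygons, traits, Yule phylogeny, injected
   contaminants) with every ground-truth value recorded, used by the test
   suite for recovery and calibration experiments.

All models are fitted with blocked Gibbs samplers written for this package
(conjugate updates, vectorised slice sampling, analytic marginalisation of
latent layers); convergence is gated on rank-normalised split R-hat and bulk
ESS, and effects are reported as posterior mean, equal-tailed 89% credible
interval and p(>0). See `docs/methods.md` for the full model and sampler
documentation.

## Worked example

```python
from avian_itv import synth, pipeline

# a synthetic study with known truth: 5 species x 6 stations
cfg = synth.SimConfig(n_species=5, n_locations_per_species=6, seed=42)
ds = synth.simulate_captures(cfg)
ds.to_dir("demo_data")

conf = pipeline.default_config("demo_data", "demo_out", seed=1)
conf["mcmc_cv"] = {"chains": 4, "iterations": 4000, "warmup": 1000}
report = pipeline.run_pipeline(conf)

eff = report["traits"]["mass"]["stages"]["within_model"]["effects"]
for row in eff:
    print(f"{row['parameter']:9s} {row['mean']:+7.3f} "
          f"[{row['ci_low89']:+7.3f}, {row['ci_high89']:+7.3f}]  p>0={row['p_gt0']:.2f}")
```

prints (numbers from this exact run):

```
mu_alpha  +24.096 [+22.379, +25.819]  p>0=1.00
mu_beta1   -0.142 [ -0.518,  +0.231]  p>0=0.26
mu_beta2   -0.238 [ -1.508,  +0.985]  p>0=0.38
mu_beta3   +0.588 [ -1.809,  +2.944]  p>0=0.65
mu_beta4   +0.134 [ -1.951,  +2.225]  p>0=0.54
```

`mu_alpha` is the cross-species mean CV × 1000 of log body mass (a CV of
0.025); the generator's true value is 25. `mu_beta1..4` are the
cross-species effects of latitude, log distance-to-edge, log spatial and
log temporal environmental variability on CV × 1000 (generating values
−0.15, 0.15, 0.28, 0.07): at this deliberately small study size (30 groups)
all four intervals are wide and cover their generating values — the point of
the example is that the 89% intervals state that uncertainty honestly rather
than manufacturing precision. The report also carries the among-species effects
and, for every stage, the convergence gate (R-hat, ESS, divergences).

The same stages are scriptable from the shell:

```sh
avian-itv simulate --n-species 5 --n-locations 6 --seed 42 demo_data
avian-itv run-all config.yaml      # or: filter / fit-cv / covariates / fit-within / fit-among
```

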