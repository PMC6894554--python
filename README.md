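# denshab — density-dependent habitat selection for territorial animals

When a territorial species recolonizes a landscape, what is *available* to
each settling group is not the whole landscape but the part not already
held by conspecifics.  Habitat-selection models that ignore this produce
coefficients that drift with population density for reasons that have
nothing to do with changing preference.  `denshab` implements, end to end,
a workflow that takes territoriality seriously — built for spatial
ecologists studying recovering carnivore populations (its model system is a
multi-decade grey-wolf recolonization), and for methodologists who want a
fully synthetic, truth-known testbed for availability-dependent selection
models.

The core model is a resource selection probability function (RSPF): a
binomial GLMM on used (1) / unused (0) points,

    logit P(y=1) = x'β + (x∘d)'γ + u_year + Σ_j b_{pack,j} x_j

with habitat covariates `x`, standardized regional wolf density `d`,
covariate-by-density interactions `γ` (the habitat functional response:
the effective slope of covariate `j` is `β_j + γ_j d`, switching sign at
`d = −β_j/γ_j`), iid year intercepts and per-pack random coefficients.
Because unused points are drawn from space known to be unoccupied, the
inverse-logit is a genuine probability of use, not just a relative index.

Around that model the package provides every stage of the workflow:

| stage | module |
| --- | --- |
| synthetic landscapes, IPD recolonization, telemetry + track surveys | `denshab.synthetic_world` |
| territory estimation (plug-in KDE, 95% isopleths, MCP, A/B/C cascade) | `denshab.territory` |
| pack-year matrix, midpoint gap filling, dispersal-smoothed density | `denshab.density` |
| Monte-Carlo boundary uncertainty → occupancy-probability rasters | `denshab.occupancy` |
| focal means, distance decay, standardization | `denshab.covariates` |
| dynamic availability domains and used/unused sampling | `denshab.sampling` |
| hierarchical RSPF, diagnostics, response curves, post-hoc tests | `denshab.rspf` |
| selection-ratio theory simulations | `denshab.scenarios` |

The numbered scripts under `analysis/` run the stages as a narrative
(`01_simulate_world.py` → `07_selection_ratios.py`), exchanging plain-text
products (CSV, GeoJSON, ASCII grids) under `results/`.

## Worked example

```sh
python analysis/01_simulate_world.py --seed 1 --out results
python analysis/02_estimate_territories.py --out results
```

prints

```
simulated 25 years on a 200 km square landscape
final year: 60 packs, 238 wolves
telemetry: 29000 fixes; track points: 8892
estimated 843 pack-year territories (0 unresolved)
methods used: {'A-yearly': 690, 'B': 152, 'C': 1}
mean territory area 276.9 km^2
```

— a population growing logistically to ~60 packs (mean pack size 4), with
most pack-years resolvable by a yearly kernel isopleth and the rest falling
back to pooled (B) or track-only (C) estimates; the mean estimated
territory (277 km²) sits close to the generative mean of 283 km².
Continuing with `03`–`06` builds density surfaces (38.12 km smoothing
radius — the median of a 55-km-mean exponential dispersal kernel),
occupancy-probability rasters, the used/unused design (about five used
points per average territory, unused points at one per 1000 km² of each
pack's 165-km availability disc), and the fitted RSPF with its posterior
summary table, in which the three true-signal covariates out-rank both
pure-noise covariates by |mean/s.e.| and the prey-by-density interaction
comes out negative — the generative pre-emptive settlement produces exactly
the declining prey response the theory predicts.  `07` adds the four
used-vs-available theory scenarios and the empirical used:available ratio
by density.

In code, the same end-to-end run is one call:

```python
from denshab.pipeline import PipelineConfig, run_pipeline

result = run_pipeline(PipelineConfig(), seed=1)
print(result.fit.summary().round(3))   # mean, s.e., percentiles, mode
```

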