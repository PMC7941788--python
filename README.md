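# wildfire-excess

Spatiotemporal analysis of excess respiratory hospitalizations during
wildfire-smoke events: a within-community matched design producing per-unit
daily excess counts, Moran's I clustering inference with permutation tests,
a spatial Bayesian hierarchical model with spherical Gaussian-process
covariance, and multilevel B-spline surface interpolation. Written for
environmental epidemiologists who have a daily count panel per spatial unit
(e.g. respiratory admissions per ZIP code), unit centroids in projected
kilometers, and a set of exposure dates.

## The method

For unit *i* and exposed day *d*, the **excess count** is

```
excess(i,d) = Y(i,d) − median{ Y(i, d±7k) : k = 1..w }
```

— the unit's own count minus the median of its weekday-matched control days
in the *w* = 2 weeks before and after. Per-unit maps of mean excess are
tested for spatial structure with **Global and Local (Anselin) Moran's I**
under permutation inference; re-running the design on no-event periods is
the **falsification test** (expected verdict: spatially random). The 5-day
aggregated excess is then smoothed with a two-stage hierarchical model

```
Y = β₀·1 + W + ε,   W ~ N(0, σ²H(φ)),   ε ~ N(0, τ²I)
```

with spherical correlation `H`, semivariogram-derived priors, and
Metropolis-within-Gibbs MCMC, yielding per-unit posterior means, SDs, the
signal-to-noise map `SNR_i = mean_i / SD_i`, and a 300×300 multilevel
B-spline surface.

Hospital-discharge data are confidential, so the package ships a
synthetic-data module (`wildfire_excess.synthetic`) generating Poisson count
panels with weekday structure and a wind-driven anisotropic smoke plume, with
known ground truth; all tests run against it. See `docs/methods.md` for
model details, defaults, and limitations.

## Worked example

The numbered drivers under `analysis/` run the full study on synthetic data
(outputs under `results/`):

```
$ python analysis/01_simulate.py
wrote 9828 count records for 108 units
county daily mean/unit: 0.476 (exposed days: 0.791); max daily count 5
expected excess (truth) total over 5 days: 149.4

$ python analysis/02_matched_excess.py
[fire] total excess +247.5 of 427 admissions = 58.0% (reported 58%)
[nofire] total excess +80.5 of 292 admissions = 27.6% (reported 28%)

$ python analysis/03_spatial_clustering.py
[fire] Moran I = +0.208 (E[I] = -0.0093), p = 0.001 -> clustered
[nofire] Moran I = +0.051 (E[I] = -0.0093), p = 0.169 -> random
significant HH clusters: 13 units (13 downwind, 0 upwind of the fire)

$ python analysis/04_bhm_surface.py
retained 2500 draws; phi acceptance 0.69
SNR: median 3.29, max 6.59 (top units: Z004, Z017, Z101)
highest-precision units sit downwind of the fire at (35.0, 35.0)
surface: 300x300 raster, data RMS residual 0.0015
```

Reading: the smoke period shows strongly positive county excess and a
spatially *clustered* excess map, with every significant high-high cluster
downwind of the fire; the no-fire panel shows the small positive excess
expected from the median contrast's skewness bias but a spatially *random*
map. The hierarchical model's most precise estimates (highest SNR) sit in
the plume footprint, and the fitted field is rasterized for mapping.
(The no-event map's positive total is systematic at low counts — see the
median-bias note in `docs/methods.md`.)

A single call runs everything with one seed and a manifest:

```python
from wildfire_excess import PipelineConfig, run_report
run_report(PipelineConfig(out_dir="results/report", seed=42))
```

## Library layout

| module | contents |
|---|---|
| `wildfire_excess.synthetic` | geometry, plume kernel, count panels, GP fields |
| `wildfire_excess.matched` | control days, excess counts, period summaries |
| `wildfire_excess.moran` | k-NN weights, global/local Moran, falsification report |
| `wildfire_excess.variogram` | spherical model, Matheron estimator, WLS fit |
| `wildfire_excess.bhm` | Metropolis-within-Gibbs sampler, SNR map |
| `wildfire_excess.surface` | multilevel B-spline 300×300 rasterization |
| `wildfire_excess.io` / `.pipeline` | CSV/JSON/ASCII-grid formats, report runs |

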