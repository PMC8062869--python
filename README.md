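# lithospat

Spatial statistics for microbial biofilms on mineral surfaces.

Subsurface microbes colonise rock unevenly: on polished rock coupons imaged
by coupled SEM/XEDS, cell densities peak over iron-, sulfur- and
titanium-rich mineral grains rather than over the silicate matrix. This
package provides the full analysis chain needed to quantify that kind of
mineral selectivity from element-map rasters and curated cell masks, and a
synthetic-scene generator with known ground truth so every stage can be
verified without microscope data.

**Who it is for:** geomicrobiologists and microscopists with per-element
signal rasters (XEDS maps), painted cell/fungal feature masks or centroid
tables, and optionally 16S community tables with bulk chemistry.

## The model

Cell centroids are treated as an inhomogeneous Poisson point process over
the scanned window W with log-linear intensity in the element rasters
Z_i(u):

    lambda(u) = exp(beta0 + sum_i beta_i * Z_i(u)),   u in W

The log-likelihood `sum_k log lambda(x_k) - int_W lambda(u) du` is
maximised via the Berman–Turner quadrature device (the integral is
discretised over data + dummy points whose weights sum to |W|, turning the
fit into a weighted Poisson regression solved by IRLS). A null (homogeneous)
model and covariate models are compared with the likelihood-ratio test,
`stat = deviance(null) - deviance(alt) ~ chi-square(df)`; an exhaustive
search over element subsets (up to 5 covariates) reports every model and
selects the best by lowest p-value, then highest deviance, then fewest
covariates. Goodness-of-fit is checked with the inhomogeneous Besag
L-function, `L(r) = sqrt(K(r)/pi)`, against pointwise Monte-Carlo envelopes
of patterns simulated from the fitted intensity.

Around this core: tile stitching into panoramic element maps, per-feature
morphology (circularity `4*pi*A/P^2` classifying filament <= 0.1 < rod
<= 0.7 < cocci), Gaussian-kernel 2-D density hotspots, and community
statistics (abundance/prevalence taxa filtering, taxa-chemistry
correlation matrices, Bray–Curtis, SIMPER).

## Worked example

```python
import lithospat as ls

# a synthetic transect: Fe/S-rich grain in a Si/Al/O matrix
scene = ls.GrainScene(seed=1)
emap = ls.make_element_map(scene)

# plant sulfur selectivity (standardized scale) targeting ~400 cells
truth = ls.calibrate_beta0(emap, {"S": 1.5}, 400)
cells = ls.simulate_selective_cells(emap, truth, seed=2)
print(cells.n)                        # 399

# refit: the planted coefficient is recovered
fit = ls.fit_ppm(cells, emap, covariate_names=["S"])
print(fit.beta.round(3))              # [-2.364  1.523]

# exhaustive model selection over five channels
sub = emap.subset(["S", "Si", "Al", "Fe", "Ti"])
report = ls.model_search(cells, sub, max_covariates=5)
print(report.best)                    # ('S',)

# goodness-of-fit: L-function inside the 99-sim envelope
res = ls.envelope(cells, fit.fitted_intensity, n_sim=99, rng=3)
print(res.inside_envelope)            # True
```

The fitted vector is `[beta0, beta_S]` on the standardized covariate
scale: `beta_S ~ 1.52` against the planted 1.5 means one standard
deviation of sulfur signal multiplies the local cell intensity by
`exp(1.52) ~ 4.6`. `report.best == ('S',)` shows the search isolates the
driving element among correlated channels, and the envelope verdict means
the observed clustering is fully explained by the fitted intensity.

The same stages run from the shell:

```sh
lithospat synth --seed 1 --beta S=1.5 --target-n 400 --out demo/
lithospat ppm-search --cells demo/cells.csv --elements demo/element_map.tif \
    --out demo/search.json
lithospat run config.yaml --out demo_run/
```

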