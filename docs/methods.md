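# Methods

This note records the statistical model, the conventions and defaults, what
the synthetic generator does and does not emulate, and the numerically
delicate choices. Nothing here states an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Coordinates, windows and rasters

All continuous coordinates are micrometres, origin at the top-left of the
panorama, x rightward, y downward (image convention). Pixel `(i, j)` covers
the half-open square `[j*s, (j+1)*s) x [i*s, (i+1)*s)`; centroids use pixel
centres. The analysis window is the *scanned* region: pixels covered by no
tile (or carrying NaN) are excluded from `|W|`, from quadrature and from
all integrals, so a panorama's bounding box never inflates the window area.
Tile overlap during stitching is resolved by a configurable rule
(last-wins by default, `mean`/`first` available) because manual photo
stitching does not document its blending.

## Morphology

Area is pixel count times pixel area. Raw pixel-edge perimeter counting
overestimates smooth boundaries badly enough that a digital circle scores
`c = 4*pi*A/P^2 ~ 0.8`, so perimeters use the Crofton formula with 4
projection directions (`skimage.measure.perimeter_crofton`). Numerical
comparison across estimators showed the 2-direction Crofton variant
underestimates axis-aligned rectangles (pushing rods above the cocci
threshold) and the weighted pixel-configuration estimator fails thin
1-px-wide shapes; the 4-direction variant satisfies the analytic identities
(disk r >= 6 px within [0.95, 1.05]; rectangles within a few percent).
Features below ~6 px radius can overshoot c = 1 by ~6% from digitisation —
at the default 0.05 um/px that is sub-0.3-um detail, below reliable
segmentation anyway.

Class boundaries: filament `c <= 0.1`, rod `0.1 < c <= 0.7`, cocci
`c > 0.7` (boundary values resolve down: 0.1 is filament, 0.7 is rod).
Reported sizes are minima — critical-point drying shrinks cells and no
correction is applied. Touching features with distinct labels are never
merged; 8-connectivity is used when labelling binary input.

## Kernel density hotspots

The KDE is an exact separable Gaussian product-kernel sum on a regular
grid (no binning). Bandwidths default to the per-axis normal-reference
rule in the MASS convention, `h = 4 * 1.06 * min(sd, IQR/1.34) * n^(-1/5)`,
with kernel standard deviation `h/4` — the default of the R plotting stack
commonly used for such figures, so surfaces are comparable. No edge
correction is applied; density is biased low within about one bandwidth of
the window border, which matches how such hotspot figures are usually
drawn and is irrelevant to inference (the point-process model, not the
KDE, carries the statistical claim). Contour levels are equally spaced in
density (not quantiles), 10 by default; the surface integrates to n unless
`normalized=True`, and the flag is recorded in output metadata.

## Poisson point-process fitting

The Berman–Turner scheme tiles the window at the dummy spacing, places one
dummy point per tile (at the valid pixel nearest the tile centre, so
partially scanned windows work), and splits each tile's valid area equally
among the data + dummy points it contains; weights sum to |W| exactly
(checked to 1e-6 relative). Data points are assigned to tiles through
their pixel's centre so point and area bookkeeping can never disagree at
tile boundaries. Default spacing gives at least 4x as many dummies as data
points and at least a 64x64 grid.

The weighted Poisson regression is maximised by IRLS with step-halving,
convergence at relative log-likelihood change < 1e-8, at most 100
iterations; non-convergence is flagged on the fit, not raised. Covariates
are standardized to zero mean / unit variance over valid pixels before
fitting (detector units are arbitrary and raw scales destabilise IRLS);
coefficients are reported on both scales, and the likelihood-ratio
statistic is invariant to the affine rescaling. Constant channels are
dropped with a note; collinear channels are dropped by an incremental rank
check. Wald standard errors come from the observed information on the
quadrature.

Model comparison uses `stat = 2*(ll_alt - ll_null)` on the chi-square
upper tail. The subset search is exhaustive over all combinations of up to
5 covariates — greedy search can miss saturated winners — with a
configurable cap (default 1e6 fits) guarding rasters with many trace
elements. The best-model rule (lowest p, highest deviance, fewest
covariates) is made total by ranking p-values in *log space*
(`chi2.logsf`): under strong effects double-precision p-values underflow
to 0 for every superset of the true model, and a naive tie-break on
deviance would then always return saturated models; log-space ranking
preserves "lowest p-value" exactly while keeping the chain deterministic
(final ties break on fewer covariates, then names). No multiple-testing
correction is applied across the family — the report carries `n_models`
so users can apply their own. Searches on patterns with fewer than 70
cells are flagged (`min_cells_ok=False`): below that, covariate models
rarely beat the null.

## L-function and envelopes

The inhomogeneous K weights ordered pairs by `1/(lambda_i * lambda_j)`.
Default edge correction is the border (reduced-sample) estimator — points
within r of the boundary (computed by distance transform when the window
has invalid regions) are excluded as pair sources, with the retained
`1/lambda` mass as normaliser; translation correction is available for
fully valid rectangular windows. Simulation uses exact thinning of a
homogeneous Poisson at the raster maximum (intensity is piecewise constant
per pixel, so thinning is exact).

Envelopes are pointwise min/max of 99 simulations from the fitted
intensity (pointwise exceedance 2/100 per r under the truth); observed and
simulated curves are evaluated under the same plug-in intensity, which is
known to be mildly conservative because the intensity is not re-estimated
per simulation. The default r grid is 128 points from 0 to one quarter of
the shorter window side. `L(r) = sqrt(K(r)/pi)` is concave in K, so at r
where the expected pair count is only a handful the mean of L-hat sits a
few percent below r purely from discreteness; calibration studies
therefore use r grids whose first nonzero point expects >= 10 pairs.

## Community statistics

Taxa filtering keeps taxa reaching >= 1% in at least one sample *and*
present in at least half of the samples; abundances are not renormalised
afterwards so retained values stay interpretable against the whole
community (recorded in output metadata). Correlations default to Pearson
on raw abundances (Spearman and transforms by flag); zero-variance rows
give NaN, explicitly distinct from 0. Heatmap ordering uses
complete-linkage clustering of correlation distance. Bray–Curtis comes
from `scipy.spatial.distance`; SIMPER is computed directly from its
defining average over between-group pairs, so the per-taxon contributions
sum to the mean between-group dissimilarity to machine precision (the test
suite cross-checks against `vegan::simper`). The selected set is the
smallest descending prefix reaching 75% cumulative contribution.

## Synthetic scenes

A scene is one elliptical grain (Fe/S-rich by default; an Fe/Ti preset
mirrors ilmenite-type grains) in a Si/Al/O matrix. Element signals are
arbitrary detector-like counts: two-level means plus Gaussian noise
truncated at zero and lightly blurred (sigma = 1.5 px) to emulate the beam
interaction volume spanning neighbouring pixels — which also keeps
covariates smooth at the quadrature scale. Planted selectivity
coefficients live on the standardized channel scale, the same scale the
fitter reports, so truth and estimate are directly comparable;
`calibrate_beta0` solves the intercept for a target expected count.
Default working scene: 500 x 768 px at 0.05 um/px (a portion of a
transect; simulations finish in seconds); `full_transect_scene()` gives
the full-scale 1024 x 1536 px, ~0.025 mm^2 tile. Target counts follow the
observed per-transect range (~70–1500 cells; stamped-mask fixtures use
counts giving ~1–4.5% coverage).

What the generator does *not* emulate: real XEDS spectra and detector
artefacts, SEM texture, spatially correlated mineralogy beyond one grain,
centroid artefacts of very large or merged cells, and cell-cell
interaction (the truth is exactly Poisson). Passing tests therefore show
the estimators are correct and calibrated *under the model*, not that real
biofilms lack interaction structure — on real data the envelope diagnostic
is the guard against that.

## Calibration study sizes

The verification studies (tests and `scripts/acceptance.py`) use: 200
scenes for coefficient recovery/coverage at ~500 cells each; 500
simulations for type-I calibration at ~200 cells; 100 searches for
planted-model selection; 100 simulations for L calibration (64-point r
grid, first nonzero r expecting ~12 pairs, see above); 120 meta-runs of
99-simulation envelopes (the exceedance average is heavy-tailed, so
smaller meta-samples are unstable around the 2% theory value); 100 random
tables for the SIMPER identity. These sizes are the package's choice of
precision/runtime trade-off; the whole script runs in a few minutes on one
CPU.

## Known limitations

- Quadrature resolution trades accuracy for time; deviances from other
  implementations with different internal resolutions will differ by small
  amounts even on identical data.
- Plug-in envelopes are conservative; global rank envelopes are out of
  scope.
- The KDE has no boundary correction.
- Circularity of features below ~6 px radius is unreliable (see above).
- SIMPER is reported without the permutation significance test some
  packages add; only the decomposition itself is computed.
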