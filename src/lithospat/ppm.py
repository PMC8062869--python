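"""Inhomogeneous Poisson point-process models with element-map covariates.

The intensity is log-linear in the covariates,

    lambda(u) = exp(beta0 + sum_i beta_i * Z_i(u)),

where Z_i are element rasters (standardized to zero mean / unit variance
over the valid window before fitting; coefficients are reported on both
scales). The log-likelihood

    log L(beta) = sum_data log lambda(x_k)  -  integral_W lambda(u) du

is discretised with the Berman-Turner device: data points and a regular
grid of dummy points are pooled into a quadrature scheme with weights
w_j summing to |W|, and the likelihood becomes that of a weighted Poisson
regression with response y_j = 1/w_j at data points and 0 at dummies,
maximised here by iteratively reweighted least squares.

Nested models are compared by the likelihood-ratio (analysis-of-deviance)
test: stat = 2*(loglik_alt - loglik_null) = deviance(null) - deviance(alt),
referred to a chi-square upper tail with df equal to the difference in
parameter count. The covariate-subset search fits every subset of up to
``max_covariates`` channels and selects the best model by the rule
(lowest p-value, highest deviance, fewest covariates), made total by a
deterministic lexicographic tie-break.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .geometry import CellPattern, ElementMap, ObservationWindow

WEIGHT_SUM_RTOL = 1e-6


@dataclass
class QuadratureScheme:
    """Berman-Turner quadrature: pooled data + dummy points with weights.

    Weights are counting weights: the window is tiled at the dummy spacing,
    each tile's valid area is split equally among the data and dummy points
    it contains, so ``sum(weights) == |W|`` exactly.
    """

    x: np.ndarray  # (m,) um
    y: np.ndarray  # (m,) um
    is_data: np.ndarray  # (m,) bool
    weights: np.ndarray  # (m,) um^2, > 0
    window: ObservationWindow
    dummy_spacing_um: float

    @property
    def m(self) -> int:
        return len(self.x)

    @property
    def n_data(self) -> int:
        return int(self.is_data.sum())


def default_dummy_spacing(pattern: CellPattern, window: ObservationWindow) -> float:
    """Spacing giving >= 4x as many dummies as data, at least a 96x96 grid.

    The 96x96 floor keeps the midpoint-sampling error of the intensity
    integral well below 0.5% even for pixel-scale covariate noise.
    """
    short = min(window.width_um, window.height_um)
    area = window.width_um * window.height_um
    n_dummy = max(4 * max(pattern.n, 1), 96 * 96)
    spacing = math.sqrt(area / n_dummy)
    return min(spacing, short / 96)


def build_quadrature(
    pattern: CellPattern,
    window: ObservationWindow | None = None,
    dummy_spacing_um: float | None = None,
) -> QuadratureScheme:
    """Berman-Turner quadrature scheme for a pattern over its window.

    Dummy points sit on a regular grid at ``dummy_spacing_um`` (one per
    tile, at the valid pixel nearest the tile centre, so partially scanned
    windows are handled). Each tile's valid area is split equally among
    the data + dummy points inside it; total weight equals |W|.
    """
    if window is None:
        window = pattern.window
    s = window.pixel_size_um
    if dummy_spacing_um is None:
        dummy_spacing_um = default_dummy_spacing(pattern, window)
    if dummy_spacing_um <= 0:
        raise ValueError("dummy_spacing_um must be positive")
    if dummy_spacing_um > max(window.width_um, window.height_um):
        raise ValueError("dummy_spacing_um exceeds the window extent")

    ok = window.contains(pattern.x, pattern.y)
    if not ok.all():
        raise ValueError(
            f"pattern points on invalid pixels: indices "
            f"{np.flatnonzero(~ok).tolist()}"
        )

    nty = max(1, math.ceil(window.height_um / dummy_spacing_um))
    ntx = max(1, math.ceil(window.width_um / dummy_spacing_um))

    # tile index of every pixel (by pixel centre), valid-area per tile
    px_x, px_y = window.pixel_centers()
    tile_col_of_px = np.minimum((px_x / dummy_spacing_um).astype(int), ntx - 1)
    tile_row_of_px = np.minimum((px_y / dummy_spacing_um).astype(int), nty - 1)
    valid = window.full_mask()
    tile_of_pixel = (tile_row_of_px[:, None] * ntx + tile_col_of_px[None, :])
    tile_ids_valid = tile_of_pixel[valid]
    tile_area = np.bincount(tile_ids_valid, minlength=nty * ntx) * s * s

    # one dummy per tile with valid area: valid pixel nearest the tile centre
    rows_v, cols_v = np.nonzero(valid)
    tid_v = tile_ids_valid
    cx = (tid_v % ntx + 0.5) * dummy_spacing_um
    cy = (tid_v // ntx + 0.5) * dummy_spacing_um
    d2 = (px_x[cols_v] - cx) ** 2 + (px_y[rows_v] - cy) ** 2
    order = np.lexsort((d2, tid_v))
    tid_sorted = tid_v[order]
    first = np.ones(len(tid_sorted), dtype=bool)
    first[1:] = tid_sorted[1:] != tid_sorted[:-1]
    pick = order[first]
    dummy_x = px_x[cols_v[pick]]
    dummy_y = px_y[rows_v[pick]]
    dummy_tile = tid_v[pick]

    # data points assigned to tiles via their pixel's centre (consistency
    # with the tile areas even when spacing is not pixel-aligned)
    if pattern.n:
        drow, dcol = window.pixel_of(pattern.x, pattern.y)
        data_tile = tile_of_pixel[drow, dcol]
    else:
        data_tile = np.zeros(0, dtype=int)

    all_tile = np.concatenate([data_tile, dummy_tile])
    counts = np.bincount(all_tile, minlength=nty * ntx)
    w = tile_area[all_tile] / counts[all_tile]

    x = np.concatenate([pattern.x, dummy_x])
    y = np.concatenate([pattern.y, dummy_y])
    is_data = np.zeros(len(x), dtype=bool)
    is_data[: pattern.n] = True

    total = w.sum()
    if not math.isclose(total, window.area_um2, rel_tol=WEIGHT_SUM_RTOL):
        raise AssertionError(
            f"quadrature weights sum {total} != window area {window.area_um2}"
        )
    return QuadratureScheme(x, y, is_data, w, window, dummy_spacing_um)


@dataclass
class PPMFit:
    """Fitted log-linear Poisson intensity model."""

    covariate_names: list[str]
    beta: np.ndarray  # intercept + coefficients, standardized covariate scale
    beta_raw: np.ndarray  # same, on the original covariate scale
    se: np.ndarray  # Wald standard errors, standardized scale
    loglik: float
    n_data: int
    converged: bool
    window: ObservationWindow
    quad: QuadratureScheme
    fitted_intensity: np.ndarray | None = None  # (h, w) raster, NaN off-window
    dropped: list[str] = field(default_factory=list)
    n_iter: int = 0

    @property
    def df(self) -> int:
        return len(self.beta)

    @property
    def deviance(self) -> float:
        """-2 * loglik (additive constant cancels in nested differences)."""
        return -2.0 * self.loglik

    def intensity_at(self, x_um, y_um) -> np.ndarray:
        if self.fitted_intensity is None:
            raise ValueError("fit has no intensity raster")
        row, col = self.window.pixel_of(x_um, y_um)
        return self.fitted_intensity[row, col]

    def to_dict(self) -> dict:
        return {
            "covariates": self.covariate_names,
            "beta_standardized": [float(b) for b in self.beta],
            "beta_raw": [float(b) for b in self.beta_raw],
            "se_standardized": [float(v) for v in self.se],
            "loglik": float(self.loglik),
            "deviance": float(self.deviance),
            "n_data": self.n_data,
            "converged": self.converged,
            "dropped": self.dropped,
        }


@dataclass
class LRTResult:
    """Likelihood-ratio (analysis-of-deviance) comparison of nested fits."""

    stat: float  # deviance(null) - deviance(alt) = 2 * (ll_alt - ll_null)
    df: int
    p_value: float
    log_p: float  # natural-log p-value (ranking scale; avoids underflow)


def _design_matrix(quad: QuadratureScheme, covariates: ElementMap | None,
                   names: list[str]):
    """Standardized design at quadrature points + raw-scale transform info."""
    m = quad.m
    cols = [np.ones(m)]
    means, sds = [0.0], [1.0]
    kept = []
    dropped = []
    if names:
        stats = covariates.channel_stats()
        row, col = quad.window.pixel_of(quad.x, quad.y)
        for name in names:
            mu = float(stats.loc[name, "mean"])
            sd = float(stats.loc[name, "sd"])
            if sd <= 0:
                dropped.append(name)
                continue
            z = (covariates.channel(name)[row, col] - mu) / sd
            cols.append(z)
            means.append(mu)
            sds.append(sd)
            kept.append(name)
    X = np.column_stack(cols)
    # drop columns that are collinear with earlier ones
    keep_idx = [0]
    for k in range(1, X.shape[1]):
        trial = X[:, keep_idx + [k]]
        if np.linalg.matrix_rank(trial) == len(keep_idx) + 1:
            keep_idx.append(k)
        else:
            dropped.append(kept[k - 1])
    if len(keep_idx) < X.shape[1]:
        kept = [kept[k - 1] for k in keep_idx[1:]]
        means = [means[k] for k in keep_idx]
        sds = [sds[k] for k in keep_idx]
        X = X[:, keep_idx]
    return X, kept, dropped, np.array(means), np.array(sds)


def fit_ppm(
    pattern: CellPattern,
    covariates: ElementMap | None = None,
    quad: QuadratureScheme | None = None,
    covariate_names: list[str] | None = None,
    max_iter: int = 100,
    tol: float = 1e-8,
    with_intensity: bool = True,
) -> PPMFit:
    """Maximum-likelihood fit of the log-linear Poisson intensity.

    ``covariates=None`` (or an empty name list) fits the homogeneous null
    model, whose MLE is ``lambda = n / |W|``. Constant or collinear
    covariates are dropped with a note in ``fit.dropped`` rather than
    raising. Non-convergence after ``max_iter`` IRLS iterations is flagged
    via ``fit.converged``, not raised.
    """
    if pattern.n < 1:
        raise ValueError("need at least one data point")
    if quad is None:
        quad = build_quadrature(pattern)
    names = list(covariate_names) if covariate_names is not None else (
        list(covariates.channels) if covariates is not None else [])
    if names and covariates is None:
        raise ValueError("covariate names given without an element map")

    X, kept, dropped, means, sds = _design_matrix(quad, covariates, names)
    w = quad.weights
    y = np.where(quad.is_data, 1.0 / w, 0.0)
    area = quad.window.area_um2

    beta = np.zeros(X.shape[1])
    beta[0] = math.log(quad.n_data / area)

    def loglik_of(eta):
        lam = np.exp(eta)
        ll = float(np.sum(np.where(quad.is_data, eta, 0.0)) - np.sum(w * lam))
        return ll, lam

    eta = X @ beta
    ll, lam = loglik_of(eta)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        z = eta + (y - lam) / lam
        ww = w * lam
        sw = np.sqrt(ww)
        beta_new, *_ = np.linalg.lstsq(X * sw[:, None], z * sw, rcond=None)
        eta_new = np.clip(X @ beta_new, -700, 700)
        ll_new, lam_new = loglik_of(eta_new)
        # step-halving if the Newton step overshoots
        step = 1.0
        while ll_new < ll - 1e-12 and step > 1e-4:
            step /= 2
            beta_new = beta + step * (beta_new - beta)
            eta_new = np.clip(X @ beta_new, -700, 700)
            ll_new, lam_new = loglik_of(eta_new)
        rel = abs(ll_new - ll) / (abs(ll) + 1e-12)
        beta, eta, lam = beta_new, eta_new, lam_new
        if rel < tol:
            ll = ll_new
            converged = True
            break
        ll = ll_new

    # Wald SEs from the observed information X' diag(w lam) X
    info = X.T @ (X * (w * lam)[:, None])
    try:
        cov = np.linalg.inv(info)
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        se = np.full(len(beta), np.nan)

    # raw-scale coefficients: beta_raw_i = beta_i / sd_i,
    # intercept_raw = beta0 - sum beta_i mu_i / sd_i
    beta_raw = beta.copy()
    if len(beta) > 1:
        beta_raw[1:] = beta[1:] / sds[1:]
        beta_raw[0] = beta[0] - float(np.sum(beta[1:] * means[1:] / sds[1:]))

    intensity = None
    if with_intensity:
        h, wd = quad.window.shape
        if kept:
            z_stack = np.stack([
                (covariates.channel(nm) - means[k + 1]) / sds[k + 1]
                for k, nm in enumerate(kept)
            ])
            eta_map = beta[0] + np.tensordot(beta[1:], z_stack, axes=1)
        else:
            eta_map = np.full((h, wd), beta[0])
        intensity = np.exp(np.clip(eta_map, -700, 700))
        mmask = quad.window.full_mask()
        intensity = np.where(mmask, intensity, np.nan)

    return PPMFit(
        covariate_names=kept, beta=beta, beta_raw=beta_raw, se=se,
        loglik=ll, n_data=quad.n_data, converged=converged,
        window=quad.window, quad=quad, fitted_intensity=intensity,
        dropped=dropped, n_iter=it,
    )


def likelihood_ratio_test(null_fit: PPMFit, alt_fit: PPMFit) -> LRTResult:
    """ANOVA likelihood-ratio test of nested Poisson point-process fits.

    ``stat = 2*(loglik_alt - loglik_null) = deviance(null) - deviance(alt)``
    referred to the chi-square upper tail with df = parameter difference.
    The log p-value is also returned: it ranks extremely significant
    models without floating-point underflow.
    """
    if not set(null_fit.covariate_names) <= set(alt_fit.covariate_names):
        raise ValueError("models are not nested (null covariates not a subset)")
    if null_fit.n_data != alt_fit.n_data or null_fit.quad is not alt_fit.quad:
        if null_fit.quad.m != alt_fit.quad.m or not np.array_equal(
                null_fit.quad.weights, alt_fit.quad.weights):
            raise ValueError("fits must share the same quadrature scheme")
    df = alt_fit.df - null_fit.df
    if df < 1:
        raise ValueError("alternative model must have more parameters")
    stat = 2.0 * (alt_fit.loglik - null_fit.loglik)
    if stat < -1e-6:
        raise ValueError(
            f"negative LRT statistic {stat}: quadrature mismatch between fits"
        )
    stat = max(stat, 0.0)
    return LRTResult(
        stat=stat, df=df,
        p_value=float(chi2.sf(stat, df)),
        log_p=float(chi2.logsf(stat, df)),
    )


@dataclass
class ModelSearchReport:
    """All covariate subsets with their LRT results, plus the best model.

    ``best`` is None iff no subset reaches ``p <= alpha``. ``rows`` carries
    one entry per subset: (covariates, p_value, deviance-difference, df,
    log_p). No multiple-testing correction is applied across the family;
    ``n_models`` is reported so users can apply their own.
    """

    rows: list[dict]
    best: tuple[str, ...] | None
    min_cells_ok: bool
    n_data: int
    n_models: int
    alpha: float

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.rows)
        df["covariates"] = df["covariates"].map(lambda c: "+".join(c))
        return df

    def table2_rows(self, coupon: str = "", substrate: str = "") -> pd.DataFrame:
        """Flat report in the published table schema."""
        df = self.to_dataframe()[["covariates", "p_value", "deviance"]]
        df.insert(0, "substrate", substrate)
        df.insert(0, "coupon", coupon)
        df = df.rename(columns={"covariates": "model"})
        return df


def model_search(
    pattern: CellPattern,
    elements: ElementMap,
    max_covariates: int = 5,
    alpha: float = 0.05,
    min_cells: int = 70,
    quad: QuadratureScheme | None = None,
    max_models: int = 10**6,
) -> ModelSearchReport:
    """Exhaustive covariate-subset search against the null random model.

    Fits every subset of 1..``max_covariates`` channels, tests each against
    the homogeneous null by the likelihood-ratio test, and selects the best
    model by (lowest p, highest deviance, fewest covariates, then names) —
    among subsets with p <= alpha only. Patterns with fewer than
    ``min_cells`` points are still searched but flagged
    (``min_cells_ok=False``): sparse transects rarely support covariate
    models over the null.
    """
    channels = list(elements.channels)
    n_models = sum(
        math.comb(len(channels), k)
        for k in range(1, min(max_covariates, len(channels)) + 1)
    )
    if n_models > max_models:
        raise ValueError(
            f"{n_models} candidate models exceed the cap {max_models}; "
            "pre-select channels or lower max_covariates"
        )
    if quad is None:
        quad = build_quadrature(pattern)
    null_fit = fit_ppm(pattern, quad=quad, with_intensity=False)

    rows = []
    for k in range(1, min(max_covariates, len(channels)) + 1):
        for combo in itertools.combinations(channels, k):
            alt = fit_ppm(pattern, elements, quad=quad,
                          covariate_names=list(combo), with_intensity=False)
            lrt = likelihood_ratio_test(null_fit, alt)
            rows.append({
                "covariates": combo,
                "p_value": lrt.p_value,
                "deviance": lrt.stat,
                "df": lrt.df,
                "log_p": lrt.log_p,
                "converged": alt.converged,
            })

    sig = [r for r in rows if r["p_value"] <= alpha]
    best = None
    if sig:
        best_row = min(
            sig,
            key=lambda r: (r["log_p"], -r["deviance"], len(r["covariates"]),
                           r["covariates"]),
        )
        best = best_row["covariates"]
    rows.sort(key=lambda r: (r["log_p"], -r["deviance"], len(r["covariates"]),
                             r["covariates"]))
    return ModelSearchReport(
        rows=rows, best=best, min_cells_ok=pattern.n >= min_cells,
        n_data=pattern.n, n_models=n_models, alpha=alpha,
    )
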