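"""Synthetic element maps, cell patterns, masks and community fixtures.

The generator emulates the statistical structure of high-magnification
SEM/XEDS transects across a mineral grain boundary: a single Fe/S-rich
(or Fe/Ti-rich) grain embedded in a Si/Al/O silicate matrix, with cells
drawn from a log-linear inhomogeneous Poisson intensity over the element
channels. Defaults mirror the study conditions: a full transect covers
~0.025 mm^2 on a 1024 x 1536-pixel canvas (``full_transect_scene``);
the default working scene is a 500 x 768-px portion at 0.05 um/px so a
simulation completes in seconds; observed cell counts per transect span
roughly 70-1500 and cell coverage ~1-4.5% of the transect area.

Element signals are arbitrary detector-like counts: per-pixel Gaussian
noise truncated at zero, lightly blurred (sigma = 1.5 px) to emulate the
beam interaction volume spanning neighbouring pixels. Planted selectivity
coefficients are expressed on the standardized channel scale — the same
scale on which the model module fits — so ground truth and estimates are
directly comparable.

All generators are pure functions of (parameters, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .community import BulkChemistry, CommunityTable
from .geometry import CellPattern, ElementMap, FeatureMask, ObservationWindow
from .lfunction import simulate_ipp

#: matrix/grain element means (arbitrary detector counts) for an Fe/S grain
#: in a silicate (Si/Al/O) matrix; Ti present only as background.
MATRIX_COMPOSITION = {"Si": 30.0, "Al": 10.0, "O": 40.0,
                      "Fe": 2.0, "S": 1.0, "Ti": 0.5}
FE_S_GRAIN = {"Si": 5.0, "Al": 2.0, "O": 30.0,
              "Fe": 30.0, "S": 18.0, "Ti": 0.5}
FE_TI_GRAIN = {"Si": 5.0, "Al": 2.0, "O": 30.0,
               "Fe": 30.0, "S": 1.0, "Ti": 15.0}


@dataclass
class GrainScene:
    """Parameters of a synthetic grain-in-matrix transect.

    The grain is an ellipse (centre/semi-axes in fractions of the window,
    rotation in radians) strictly inside the window.
    """

    width_px: int = 768
    height_px: int = 500
    pixel_size_um: float = 0.05
    grain_center: tuple[float, float] = (0.4, 0.5)  # fractions of (w, h)
    grain_axes: tuple[float, float] = (0.22, 0.30)  # fractions of (w, h)
    grain_angle: float = 0.3
    matrix_composition: dict[str, float] = field(
        default_factory=lambda: dict(MATRIX_COMPOSITION))
    grain_composition: dict[str, float] = field(
        default_factory=lambda: dict(FE_S_GRAIN))
    noise_sd: float | dict[str, float] = 1.0
    blur_px: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if set(self.grain_composition) != set(self.matrix_composition):
            raise ValueError("grain and matrix must list the same elements")
        for comp in (self.matrix_composition, self.grain_composition):
            if any(v < 0 for v in comp.values()):
                raise ValueError("compositions must be non-negative")
        cx, cy = self.grain_center
        ax, ay = self.grain_axes
        if not (0 < cx - ax and cx + ax < 1 and 0 < cy - ay and cy + ay < 1):
            raise ValueError("grain must lie strictly inside the window")

    @property
    def window(self) -> ObservationWindow:
        return ObservationWindow(self.width_px, self.height_px,
                                 self.pixel_size_um)

    def grain_mask(self) -> np.ndarray:
        """Boolean raster of pixels whose centre falls inside the ellipse."""
        w = self.window
        gx, gy = w.pixel_centers()
        X, Y = np.meshgrid(gx, gy)
        cx = self.grain_center[0] * w.width_um
        cy = self.grain_center[1] * w.height_um
        ax = self.grain_axes[0] * w.width_um
        ay = self.grain_axes[1] * w.height_um
        ca, sa = math.cos(self.grain_angle), math.sin(self.grain_angle)
        u = (X - cx) * ca + (Y - cy) * sa
        v = -(X - cx) * sa + (Y - cy) * ca
        return (u / ax) ** 2 + (v / ay) ** 2 <= 1.0


def full_transect_scene(**kwargs) -> GrainScene:
    """Full-scale transect preset: 1024 x 1536 px covering ~0.025 mm^2."""
    # 0.025 mm^2 = 25,000 um^2 over 1024*1536 px -> ~0.126 um/px
    defaults = dict(width_px=1536, height_px=1024, pixel_size_um=0.126)
    defaults.update(kwargs)
    return GrainScene(**defaults)


def make_element_map(scene: GrainScene) -> ElementMap:
    """Element raster stack for a grain scene (seeded, deterministic)."""
    rng = np.random.default_rng(scene.seed)
    w = scene.window
    inside = scene.grain_mask()
    channels = sorted(scene.matrix_composition)
    stack = np.empty((len(channels),) + w.shape)
    for k, el in enumerate(channels):
        base = np.where(inside, scene.grain_composition[el],
                        scene.matrix_composition[el]).astype(float)
        sd = (scene.noise_sd.get(el, 0.0)
              if isinstance(scene.noise_sd, dict) else scene.noise_sd)
        if sd > 0:
            noise = rng.normal(0.0, sd, size=w.shape)
            if scene.blur_px > 0:
                # keep per-pixel sd after smoothing
                noise = gaussian_filter(noise, scene.blur_px)
                noise *= sd / max(noise.std(), 1e-12)
            base = base + noise
        stack[k] = np.clip(base, 0.0, None)
    return ElementMap(w, channels, stack,
                      provenance=f"synthetic grain scene seed={scene.seed}")


@dataclass
class SelectivityTruth:
    """Planted log-linear selectivity (standardized covariate scale)."""

    beta0: float
    beta: dict[str, float] = field(default_factory=dict)

    def intensity(self, emap: ElementMap) -> np.ndarray:
        """lambda(u) raster implied by the truth on this element map."""
        missing = set(self.beta) - set(emap.channels)
        if missing:
            raise ValueError(f"truth elements not in map: {missing}")
        std = emap.standardized()
        eta = np.full(emap.window.shape, self.beta0)
        for el, b in self.beta.items():
            eta = eta + b * std.channel(el)
        lam = np.exp(np.clip(eta, -700, 700))
        return np.where(emap.window.full_mask(), lam, np.nan)

    def expected_n(self, emap: ElementMap) -> float:
        lam = self.intensity(emap)
        m = emap.window.full_mask()
        return float(np.nansum(lam[m]) * emap.window.pixel_size_um**2)


def calibrate_beta0(emap: ElementMap, beta: dict[str, float],
                    target_n: float) -> SelectivityTruth:
    """Choose beta0 so the expected count equals ``target_n``."""
    probe = SelectivityTruth(0.0, dict(beta))
    en = probe.expected_n(emap)
    return SelectivityTruth(math.log(target_n / en), dict(beta))


def simulate_selective_cells(
    emap: ElementMap,
    truth: SelectivityTruth,
    seed: int | np.random.Generator | None = None,
) -> CellPattern:
    """Inhomogeneous Poisson cell pattern from the planted intensity."""
    en = truth.expected_n(emap)
    if en > 1e6:
        raise ValueError(f"expected count {en:.3g} exceeds 1e6: runaway intensity")
    lam = truth.intensity(emap)
    lam = np.nan_to_num(lam, nan=0.0)
    return simulate_ipp(lam, emap.window, rng=seed)


# ---------------------------------------------------------------------
# Feature-mask stamping
# ---------------------------------------------------------------------

def _stamp_cocci(rng) -> np.ndarray:
    r = int(rng.integers(6, 10))
    d = 2 * r + 1
    yy, xx = np.mgrid[:d, :d] - r
    return (xx**2 + yy**2) <= (r + 0.5) ** 2


def _stamp_rod(rng) -> np.ndarray:
    a = int(rng.integers(3, 6))            # semi-minor
    b = int(round(a * rng.uniform(3.3, 4.5)))  # semi-major, elongation > 3

    ang = rng.uniform(0, np.pi)
    d = 2 * b + 3
    yy, xx = np.mgrid[:d, :d] - (d // 2)
    ca, sa = np.cos(ang), np.sin(ang)
    u = xx * ca + yy * sa
    v = -xx * sa + yy * ca
    return (u / b) ** 2 + (v / a) ** 2 <= 1.0


def _stamp_filament(rng, bifurcate: bool = False) -> np.ndarray:
    """Thin dilated polyline; optionally with a branch (fungal-like)."""
    L = int(rng.integers(80, 120))
    ang = rng.uniform(0, np.pi)
    d = L + 8
    img = np.zeros((d, d), bool)
    c = d // 2
    t = np.linspace(-L / 2, L / 2, 4 * L)
    wiggle = 6 * np.sin(t / L * np.pi * rng.uniform(0.5, 1.5))
    xs = (c + t * np.cos(ang) - wiggle * np.sin(ang)).astype(int)
    ys = (c + t * np.sin(ang) + wiggle * np.cos(ang)).astype(int)
    ok = (xs >= 0) & (xs < d) & (ys >= 0) & (ys < d)
    img[ys[ok], xs[ok]] = True
    if bifurcate:
        t2 = np.linspace(0, L / 3, L)
        ang2 = ang + rng.uniform(0.5, 1.0)
        xs2 = (c + t2 * np.cos(ang2)).astype(int)
        ys2 = (c + t2 * np.sin(ang2)).astype(int)
        ok2 = (xs2 >= 0) & (xs2 < d) & (ys2 >= 0) & (ys2 < d)
        img[ys2[ok2], xs2[ok2]] = True
    from scipy.ndimage import binary_dilation

    return binary_dilation(img, np.ones((2, 2), bool))


def make_feature_mask(
    pattern: CellPattern,
    morphology_mix: dict[str, float] | None = None,
    seed: int | np.random.Generator | None = None,
    fungal_fraction: float = 0.0,
    max_tries: int = 100,
) -> tuple[FeatureMask, list[str]]:
    """Stamp a shaped feature at each pattern point; returns mask + truth.

    ``morphology_mix`` gives fractions over {"cocci", "rod", "filament"}
    (must sum to 1); each point independently draws a class. Overlapping
    stamps are relocated (up to ``max_tries`` uniform draws) rather than
    merged; if no free spot is found the stamp is placed anyway with a
    warning. ``fungal_fraction`` of points instead receive a bifurcating
    fungal filament (class "fungal").

    Returns the mask and the per-feature ground-truth class list (indexed
    by feature id - 1).
    """
    import warnings as _warnings

    if morphology_mix is None:
        morphology_mix = {"rod": 1.0}
    if abs(sum(morphology_mix.values()) - 1.0) > 1e-9:
        raise ValueError("morphology_mix fractions must sum to 1")
    rng = np.random.default_rng(seed)
    w = pattern.window
    labels = np.zeros(w.shape, dtype=np.int32)
    classes: dict[int, str] = {}
    truth: list[str] = []
    kinds = list(morphology_mix)
    probs = np.array([morphology_mix[k] for k in kinds])
    s = w.pixel_size_um

    for k in range(pattern.n):
        fungal = rng.random() < fungal_fraction
        if fungal:
            kind = "fungal"
            stamp = _stamp_filament(rng, bifurcate=True)
        else:
            kind = kinds[rng.choice(len(kinds), p=probs)]
            stamp = {"cocci": _stamp_cocci, "rod": _stamp_rod,
                     "filament": _stamp_filament}[kind](rng)
        sh, sw = stamp.shape
        row = int(pattern.y[k] / s) - sh // 2
        col = int(pattern.x[k] / s) - sw // 2
        placed = False
        for attempt in range(max_tries):
            r0 = min(max(row, 0), w.height_px - sh)
            c0 = min(max(col, 0), w.width_px - sw)
            if r0 < 0 or c0 < 0:
                break  # stamp larger than window; place clipped below
            region = labels[r0:r0 + sh, c0:c0 + sw]
            if not (region[stamp] != 0).any():
                region[stamp] = k + 1
                placed = True
                break
            row = int(rng.integers(0, max(w.height_px - sh, 1)))
            col = int(rng.integers(0, max(w.width_px - sw, 1)))
        if not placed:
            _warnings.warn(f"feature {k + 1}: no free spot after "
                           f"{max_tries} tries; overlapping placement")
            r0 = min(max(row, 0), max(w.height_px - sh, 0))
            c0 = min(max(col, 0), max(w.width_px - sw, 0))
            sub = stamp[:w.height_px - r0, :w.width_px - c0]
            labels[r0:r0 + sub.shape[0], c0:c0 + sub.shape[1]][sub] = k + 1
        classes[k + 1] = "fungal" if fungal else "cell"
        truth.append(kind)

    mask = FeatureMask(labels, classes, w)
    return mask, truth


def make_community_fixture(
    n_samples: int = 16,
    n_taxa: int = 20,
    chem: BulkChemistry | None = None,
    linked_taxa: dict[str, tuple[str, float]] | None = None,
    seed: int | np.random.Generator | None = None,
    base_concentration: float = 5.0,
) -> CommunityTable:
    """Dirichlet community table with planted taxon-element correlations.

    Each sample is assigned a substrate (cycling through ``chem``'s rows)
    and a group label alternating rock/control. For a linked taxon
    ``t -> (element, effect)`` the Dirichlet concentration is scaled by
    ``exp(effect * z)`` where z is the substrate's standardized element
    weight-%, so the taxon's realised abundance correlates positively with
    that element across samples.
    """
    rng = np.random.default_rng(seed)
    if chem is None:
        chem = default_bulk_chemistry()
    linked_taxa = linked_taxa or {}
    substrates = list(chem.weight_pct.index)
    taxa = [f"taxon_{k:02d}" for k in range(n_taxa)]
    for t, (el, _) in linked_taxa.items():
        if el not in chem.weight_pct.columns:
            raise ValueError(f"linked element {el} not in chemistry table")
        if t not in taxa:
            raise ValueError(f"linked taxon {t} outside generated taxa")
    z = (chem.weight_pct - chem.weight_pct.mean()) / chem.weight_pct.std(ddof=0)
    rows = []
    sample_ids = [f"sample_{k:02d}" for k in range(n_samples)]
    subs, groups = [], []
    for k in range(n_samples):
        sub = substrates[k % len(substrates)]
        subs.append(sub)
        groups.append("rock" if k % 2 == 0 else "control")
        alpha = np.full(n_taxa, base_concentration)
        for t, (el, effect) in linked_taxa.items():
            alpha[taxa.index(t)] *= math.exp(effect * float(z.loc[sub, el]))
        rows.append(rng.dirichlet(alpha))
    ab = pd.DataFrame(rows, index=sample_ids, columns=taxa)
    meta = {"substrate": dict(zip(sample_ids, subs)),
            "linked_taxa": {t: [el, eff] for t, (el, eff) in linked_taxa.items()}}
    return CommunityTable(ab, groups=pd.Series(groups, index=sample_ids),
                          metadata=meta)


def default_bulk_chemistry() -> BulkChemistry:
    """Four silicate substrates spanning Fe/S/Ti-rich to felsic-poor."""
    data = pd.DataFrame(
        {
            "Si": [25.0, 28.0, 30.0, 26.0],
            "Al": [8.0, 9.0, 10.0, 8.5],
            "O": [45.0, 46.0, 47.0, 45.5],
            "Fe": [12.0, 6.0, 3.0, 10.0],
            "S": [4.0, 1.5, 0.3, 0.1],
            "Ti": [0.5, 0.4, 0.3, 3.0],
            "Ca": [3.0, 2.0, 1.5, 3.5],
        },
        index=["poorman", "homestake", "ellison", "yates"],
    )
    return BulkChemistry(data)
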