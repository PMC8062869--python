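"""Core spatial types: observation windows, element-map rasters, point patterns.

Coordinate convention (used everywhere in this package): origin at the
panorama top-left, x increases rightward, y increases downward (image
convention). Continuous coordinates are in micrometres. Pixel ``(i, j)``
(row i, column j) covers the half-open square
``[j*s, (j+1)*s) x [i*s, (i+1)*s)`` where ``s`` is the pixel edge in um;
its centre is ``((j + 0.5) * s, (i + 0.5) * s)``.

Rasters are numpy arrays indexed ``[row, col]`` (i.e. ``[y, x]``); element
stacks are ``(channel, row, col)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile


@dataclass(frozen=True)
class ObservationWindow:
    """Rectangular scan window, possibly with unscanned (invalid) pixels.

    The analysis window is the *scanned* region: pixels outside
    ``valid_mask`` are excluded from areas, integrals and quadrature.

    Parameters
    ----------
    width_px, height_px : int
        Raster dimensions.
    pixel_size_um : float
        Edge length of a pixel in micrometres.
    valid_mask : ndarray of bool, optional
        ``(height_px, width_px)`` mask of scanned pixels. ``None`` means
        fully scanned.
    """

    width_px: int
    height_px: int
    pixel_size_um: float
    valid_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.width_px <= 0 or self.height_px <= 0:
            raise ValueError("window dimensions must be positive")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if self.valid_mask is not None:
            m = np.asarray(self.valid_mask, dtype=bool)
            if m.shape != (self.height_px, self.width_px):
                raise ValueError(
                    f"valid_mask shape {m.shape} does not match window "
                    f"({self.height_px}, {self.width_px})"
                )
            if not m.any():
                raise ValueError("window has no valid pixels")
            object.__setattr__(self, "valid_mask", m)

    # -- geometry -----------------------------------------------------

    @property
    def shape(self) -> tuple[int, int]:
        return (self.height_px, self.width_px)

    @property
    def width_um(self) -> float:
        return self.width_px * self.pixel_size_um

    @property
    def height_um(self) -> float:
        return self.height_px * self.pixel_size_um

    @property
    def n_valid(self) -> int:
        if self.valid_mask is None:
            return self.width_px * self.height_px
        return int(self.valid_mask.sum())

    @property
    def area_um2(self) -> float:
        """Area of the scanned region |W| in um^2."""
        return self.n_valid * self.pixel_size_um**2

    def full_mask(self) -> np.ndarray:
        if self.valid_mask is None:
            return np.ones(self.shape, dtype=bool)
        return self.valid_mask

    def pixel_of(self, x_um, y_um) -> tuple[np.ndarray, np.ndarray]:
        """Row/col indices of the pixels containing the given points."""
        s = self.pixel_size_um
        col = np.floor(np.asarray(x_um, dtype=float) / s).astype(int)
        row = np.floor(np.asarray(y_um, dtype=float) / s).astype(int)
        return row, col

    def pixel_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """1-D arrays of x (per column) and y (per row) pixel centres, um."""
        s = self.pixel_size_um
        x = (np.arange(self.width_px) + 0.5) * s
        y = (np.arange(self.height_px) + 0.5) * s
        return x, y

    def contains(self, x_um, y_um) -> np.ndarray:
        """True where points fall on valid pixels of the window."""
        x = np.atleast_1d(np.asarray(x_um, dtype=float))
        y = np.atleast_1d(np.asarray(y_um, dtype=float))
        inside = (x >= 0) & (x < self.width_um) & (y >= 0) & (y < self.height_um)
        if self.valid_mask is not None:
            ok = inside.copy()
            if ok.any():
                row, col = self.pixel_of(x[ok], y[ok])
                ok_vals = self.valid_mask[row, col]
                ok[np.flatnonzero(inside)] = ok_vals
            inside = ok
        return inside


@dataclass
class RasterTile:
    """A single scan tile placed on a panorama canvas by pixel offsets."""

    values: np.ndarray  # (h, w) or (c, h, w)
    offset_x_px: int
    offset_y_px: int
    name: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim == 2:
            v = v[None, :, :]
        if v.ndim != 3:
            raise ValueError("tile values must be 2-D or 3-D (c, h, w)")
        self.values = v

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape[1:]


@dataclass
class ElementMap:
    """Multi-channel element-signal raster over an observation window.

    ``values[k]`` is the raster for element ``channels[k]`` (arbitrary
    detector units or weight-%). Values on invalid pixels are undefined
    (typically NaN) and excluded from all statistics.
    """

    window: ObservationWindow
    channels: list[str]
    values: np.ndarray  # (n_channels, h, w)
    provenance: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("values must be (n_channels, h, w)")
        if self.values.shape[0] != len(self.channels):
            raise ValueError("channel count mismatch")
        if self.values.shape[1:] != self.window.shape:
            raise ValueError("raster dimensions do not match window")
        if len(set(self.channels)) != len(self.channels):
            raise ValueError("channel symbols must be unique")
        m = self.window.full_mask()
        if not np.isfinite(self.values[:, m]).all():
            raise ValueError("non-finite element values on valid pixels")

    def channel(self, name: str) -> np.ndarray:
        return self.values[self.channels.index(name)]

    def subset(self, names: list[str]) -> "ElementMap":
        idx = [self.channels.index(n) for n in names]
        return ElementMap(self.window, list(names), self.values[idx],
                          provenance=self.provenance)

    def channel_stats(self) -> pd.DataFrame:
        """Mean and sd per channel over valid pixels (used to standardize)."""
        m = self.window.full_mask()
        rows = []
        for k, name in enumerate(self.channels):
            v = self.values[k][m]
            rows.append({"channel": name, "mean": float(v.mean()),
                         "sd": float(v.std())})
        return pd.DataFrame(rows).set_index("channel")

    def standardized(self) -> "ElementMap":
        """Zero-mean/unit-sd channels over valid pixels (sd-0 left centred)."""
        stats = self.channel_stats()
        out = self.values.copy()
        for k, name in enumerate(self.channels):
            mu, sd = stats.loc[name, "mean"], stats.loc[name, "sd"]
            out[k] = (out[k] - mu) / (sd if sd > 0 else 1.0)
        return ElementMap(self.window, list(self.channels), out,
                          provenance=self.provenance + " [standardized]")

    # -- I/O ----------------------------------------------------------

    def to_tiff(self, path: str | Path) -> None:
        """Multi-page TIFF, one page per element, plus a JSON sidecar."""
        path = Path(path)
        tifffile.imwrite(path, self.values.astype(np.float32))
        meta = {
            "channels": self.channels,
            "pixel_size_um": self.window.pixel_size_um,
            "provenance": self.provenance,
        }
        path.with_suffix(".json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def from_tiff(cls, path: str | Path) -> "ElementMap":
        path = Path(path)
        values = np.asarray(tifffile.imread(path), dtype=float)
        if values.ndim == 2:
            values = values[None]
        meta = json.loads(path.with_suffix(".json").read_text())
        valid = np.isfinite(values).all(axis=0)
        window = ObservationWindow(
            width_px=values.shape[2], height_px=values.shape[1],
            pixel_size_um=float(meta["pixel_size_um"]),
            valid_mask=None if valid.all() else valid,
        )
        return cls(window, list(meta["channels"]), values,
                   provenance=meta.get("provenance", ""))


@dataclass
class CellPattern:
    """Planar point pattern of cell centroids (um) with optional marks."""

    points: np.ndarray  # (n, 2) columns x_um, y_um
    window: ObservationWindow
    marks: np.ndarray | None = None  # per-point morphology/class labels

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float).reshape(-1, 2)
        self.points = pts
        if self.marks is not None:
            self.marks = np.asarray(self.marks)
            if len(self.marks) != len(pts):
                raise ValueError("marks length must equal point count")
        ok = self.window.contains(pts[:, 0], pts[:, 1])
        if not ok.all():
            bad = np.flatnonzero(~ok)[:5]
            raise ValueError(
                f"{(~ok).sum()} point(s) outside the valid window, e.g. "
                f"indices {bad.tolist()}"
            )

    @property
    def n(self) -> int:
        return len(self.points)

    @property
    def x(self) -> np.ndarray:
        return self.points[:, 0]

    @property
    def y(self) -> np.ndarray:
        return self.points[:, 1]

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame({"x_um": self.x, "y_um": self.y})
        df["class"] = self.marks if self.marks is not None else ""
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, window: ObservationWindow) -> "CellPattern":
        df = pd.read_csv(path)
        marks = df["class"].to_numpy() if "class" in df else None
        return cls(df[["x_um", "y_um"]].to_numpy(), window, marks=marks)


@dataclass
class FeatureMask:
    """Labelled raster of curated biofilm features.

    ``labels`` is an integer raster (0 = background, k > 0 = feature id);
    ``classes`` maps each feature id to ``"cell"`` or ``"fungal"``.
    """

    labels: np.ndarray
    classes: dict[int, str]
    window: ObservationWindow

    VALID_CLASSES = ("cell", "fungal")

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.shape != self.window.shape:
            raise ValueError("label raster dimensions must equal window's")
        for fid, cls in self.classes.items():
            if cls not in self.VALID_CLASSES:
                raise ValueError(f"feature {fid}: unknown class {cls!r}")

    def feature_ids(self, class_filter: str | None = None) -> list[int]:
        ids = sorted(int(i) for i in np.unique(self.labels) if i > 0)
        if class_filter is not None:
            ids = [i for i in ids if self.classes.get(i) == class_filter]
        return ids

    def to_files(self, tiff_path: str | Path, csv_path: str | Path) -> None:
        tifffile.imwrite(tiff_path, self.labels.astype(np.int32))
        pd.DataFrame(
            {"feature_id": list(self.classes), "class": list(self.classes.values())}
        ).to_csv(csv_path, index=False)

    @classmethod
    def from_files(cls, tiff_path: str | Path, csv_path: str | Path,
                   pixel_size_um: float) -> "FeatureMask":
        labels = np.asarray(tifffile.imread(tiff_path))
        df = pd.read_csv(csv_path)
        classes = dict(zip(df["feature_id"].astype(int), df["class"]))
        window = ObservationWindow(labels.shape[1], labels.shape[0], pixel_size_um)
        return cls(labels, classes, window)


# ---------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------

def stitch_tiles(
    tiles: list[RasterTile],
    canvas: ObservationWindow,
    channels: list[str],
    overlap_rule: str = "last",
) -> ElementMap:
    """Compose scan tiles into a panoramic element map.

    Tiles are written onto the canvas at their pixel offsets. Pixels covered
    by no tile are marked invalid in the panorama window's ``valid_mask``.

    Parameters
    ----------
    overlap_rule : {"last", "first", "mean"}
        How pixels covered by several tiles are resolved. ``"last"``
        (default): tiles written in list order, later tiles win.
    """
    if overlap_rule not in ("last", "first", "mean"):
        raise ValueError(f"unknown overlap_rule {overlap_rule!r}")
    if not tiles:
        raise ValueError("no tiles to stitch")
    n_ch = len(channels)
    for t in tiles:
        if t.n_channels != n_ch:
            raise ValueError(
                f"tile {t.name or '?'} has {t.n_channels} channels, "
                f"expected {n_ch}"
            )
        h, w = t.shape
        if (t.offset_x_px < 0 or t.offset_y_px < 0
                or t.offset_x_px + w > canvas.width_px
                or t.offset_y_px + h > canvas.height_px):
            raise ValueError(
                f"tile {t.name or '?'} at offset "
                f"({t.offset_x_px}, {t.offset_y_px}) size ({h}, {w}) "
                f"exceeds canvas ({canvas.height_px}, {canvas.width_px})"
            )

    out = np.full((n_ch,) + canvas.shape, np.nan)
    count = np.zeros(canvas.shape, dtype=int)
    if overlap_rule == "mean":
        acc = np.zeros_like(out)
    for t in tiles:
        h, w = t.shape
        sl = (slice(t.offset_y_px, t.offset_y_px + h),
              slice(t.offset_x_px, t.offset_x_px + w))
        if overlap_rule == "last":
            out[(slice(None),) + sl] = t.values
        elif overlap_rule == "first":
            fresh = count[sl] == 0
            region = out[(slice(None),) + sl]
            region[:, fresh] = t.values[:, fresh]
            out[(slice(None),) + sl] = region
        else:  # mean
            acc[(slice(None),) + sl] += t.values
        count[sl] += 1
    if overlap_rule == "mean":
        covered = count > 0
        out[:, covered] = acc[:, covered] / count[covered]

    covered = count > 0
    finite = np.isfinite(out).all(axis=0)
    valid = covered & finite
    if canvas.valid_mask is not None:
        valid &= canvas.valid_mask
    window = ObservationWindow(
        canvas.width_px, canvas.height_px, canvas.pixel_size_um,
        valid_mask=None if valid.all() else valid,
    )
    return ElementMap(window, list(channels), out,
                      provenance=f"stitched from {len(tiles)} tile(s)")


def mask_to_centroids(mask: FeatureMask, class_filter: str | None = None) -> CellPattern:
    """One point per feature at the mean of its pixel centres, in um.

    ``class_filter`` restricts to ``"cell"`` or ``"fungal"`` features;
    ``None`` keeps all. Zero features yield an empty pattern.
    """
    s = mask.window.pixel_size_um
    ids = mask.feature_ids(class_filter)
    pts, marks = [], []
    for fid in ids:
        rows, cols = np.nonzero(mask.labels == fid)
        if rows.size == 0:
            continue
        pts.append(((cols.mean() + 0.5) * s, (rows.mean() + 0.5) * s))
        marks.append(mask.classes.get(fid, "cell"))
    pts_arr = np.asarray(pts, dtype=float).reshape(-1, 2)
    return CellPattern(pts_arr, mask.window,
                       marks=np.asarray(marks) if marks else None)


def rasterize_points(pattern: CellPattern, window: ObservationWindow | None = None) -> np.ndarray:
    """Integer raster of point counts per pixel; sums to ``pattern.n``."""
    if window is None:
        window = pattern.window
    ok = window.contains(pattern.x, pattern.y)
    if not ok.all():
        raise ValueError(
            f"points outside window at indices {np.flatnonzero(~ok).tolist()}"
        )
    counts = np.zeros(window.shape, dtype=int)
    if pattern.n:
        row, col = window.pixel_of(pattern.x, pattern.y)
        np.add.at(counts, (row, col), 1)
    return counts


def read_tile_offsets(path: str | Path) -> pd.DataFrame:
    """Tile-offset table ``tile,offset_x_px,offset_y_px`` (editor export)."""
    df = pd.read_csv(path)
    required = {"tile", "offset_x_px", "offset_y_px"}
    if not required.issubset(df.columns):
        raise ValueError(f"offset table must have columns {sorted(required)}")
    return df
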