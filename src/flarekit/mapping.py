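"""Per-pixel activity maps and line-ROI kymographs.

A FRET map is a per-pixel -R (or heterotransfer ratio) raster with a validity
mask: channel backgrounds are subtracted, dim pixels are masked by an
intensity floor, the channel intensities are Gaussian-smoothed, and the
anisotropy equation applied pixelwise.  Kymographs stack a bilinear line
profile over time (rows = frames, columns = positions along the line).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from matplotlib import colormaps
from scipy import ndimage

from .anisotropy import BackgroundModel, anisotropy, estimate_background, fret_ratio

__all__ = ["FretMap", "Kymograph", "fret_map", "fret_ratio_map",
           "render_map", "sample_line", "kymograph", "intensity_floor_from_background"]


@dataclass
class FretMap:
    """Per-pixel activity raster (-R by default) with validity mask."""

    values: np.ndarray
    validity: np.ndarray
    display_range: tuple[float, float] = (-0.35, -0.25)
    colormap: str = "inferno"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.validity = np.asarray(self.validity, dtype=bool)
        if self.values.shape != self.validity.shape:
            raise ValueError("values and validity shapes differ")
        if not np.all(np.isfinite(self.values[self.validity])):
            raise ValueError("non-finite values inside the validity mask")


@dataclass
class Kymograph:
    """Time-versus-position raster: row i = line profile at frame i."""

    values: np.ndarray                    # (T, L), NaN where invalid
    t: np.ndarray                         # minutes per row
    s: np.ndarray                         # pixels along the line per column
    meta: dict = field(default_factory=dict)


def intensity_floor_from_background(raster: np.ndarray, background_mask: np.ndarray,
                                    k: float = 3.0) -> float:
    """Threshold separating cells from background for map masking:
    background mean + k * background sd."""
    vals = np.asarray(raster, dtype=float)[np.asarray(background_mask, dtype=bool)]
    if vals.size == 0:
        raise ValueError("empty background mask")
    return float(vals.mean() + k * vals.std())


def _prepare_channels(A: np.ndarray, B: np.ndarray, background: BackgroundModel,
                      background_roi, smooth_sigma: float):
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    if A.shape != B.shape:
        raise ValueError("channel shapes differ")
    A = A - estimate_background(A, background, background_roi)
    B = B - estimate_background(B, background, background_roi)
    if smooth_sigma > 0:
        A_s = ndimage.gaussian_filter(A, smooth_sigma)
        B_s = ndimage.gaussian_filter(B, smooth_sigma)
    else:
        A_s, B_s = A, B
    return A, B, A_s, B_s


def fret_map(P: np.ndarray, S: np.ndarray, g: float = 1.0,
             background: BackgroundModel | None = None, background_roi=None,
             smooth_sigma: float = 1.0, intensity_floor: float = 0.0,
             display_range: tuple[float, float] = (-0.35, -0.25),
             colormap: str = "inferno") -> FretMap:
    """Per-pixel -R map.

    Order of operations: subtract each channel's background, mask pixels with
    total background-corrected intensity P + 2 g S below ``intensity_floor``,
    Gaussian-smooth the channel intensities (smoothing before the ratio keeps
    small-denominator pixels from amplifying noise), apply the anisotropy
    equation, negate.
    """
    background = background or BackgroundModel(method="percentile")
    P0, S0, P_s, S_s = _prepare_channels(P, S, background, background_roi, smooth_sigma)
    bright = (P0 + 2.0 * g * S0) >= intensity_floor
    r = anisotropy(P_s, S_s, g)
    validity = bright & ~np.ma.getmaskarray(r)
    values = np.where(validity, -np.ma.filled(r, 0.0), np.nan)
    return FretMap(values, validity, display_range, colormap)


def fret_ratio_map(C: np.ndarray, Y: np.ndarray, b: float = 0.0,
                   background: BackgroundModel | None = None, background_roi=None,
                   smooth_sigma: float = 1.0, intensity_floor: float = 0.0,
                   display_range: tuple[float, float] = (0.0, 2.0),
                   colormap: str = "inferno") -> FretMap:
    """Heterotransfer counterpart: per-pixel (Y - b C)/C map (not negated)."""
    background = background or BackgroundModel(method="percentile")
    C0, Y0, C_s, Y_s = _prepare_channels(C, Y, background, background_roi, smooth_sigma)
    bright = (C0 + Y0) >= intensity_floor
    ratio = fret_ratio(Y_s, C_s, b)
    validity = bright & ~np.ma.getmaskarray(ratio)
    values = np.where(validity, np.ma.filled(ratio, 0.0), np.nan)
    return FretMap(values, validity, display_range, colormap)


def render_map(fmap: FretMap, colormap: str | None = None,
               display_range: tuple[float, float] | None = None) -> np.ndarray:
    """Pseudo-color a map into an 8-bit RGB image.

    Values are mapped linearly over ``display_range`` onto the named
    perceptually-uniform colormap (default inferno); invalid pixels render
    black.  Deterministic.
    """
    name = colormap or fmap.colormap
    lo, hi = display_range or fmap.display_range
    if not (lo < hi):
        raise ValueError("display_range low must be < high")
    try:
        cmap = colormaps[name]
    except KeyError as exc:
        raise ValueError(
            f"unknown colormap {name!r}; available e.g. "
            f"{sorted(n for n in colormaps if not n.endswith('_r'))[:12]} ..."
        ) from exc
    norm = np.clip((np.nan_to_num(fmap.values, nan=lo) - lo) / (hi - lo), 0.0, 1.0)
    rgb = (cmap(norm)[..., :3] * 255).astype(np.uint8)
    rgb[~fmap.validity] = 0
    return rgb


def sample_line(raster: np.ndarray, line, width: int = 1, spacing: float = 1.0,
                validity: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Bilinear profile along a line segment.

    ``line`` is ((y0, x0), (y1, x1)); samples are placed every ``spacing``
    pixels from the start point, endpoints included.  For width > 1 the value
    at each position is the mean over ``width`` samples along the
    perpendicular.  Invalid pixels are excluded from the average; a position
    with no valid samples returns NaN.  Returns (profile, s) with s the
    distance along the line in pixels.
    """
    raster = np.asarray(raster, dtype=float)
    if width < 1:
        raise ValueError("width must be >= 1")
    (y0, x0), (y1, x1) = line
    length = float(np.hypot(y1 - y0, x1 - x0))
    if length == 0:
        raise ValueError("zero-length line")
    n = int(np.floor(length / spacing)) + 1
    s = np.arange(n) * spacing
    uy, ux = (y1 - y0) / length, (x1 - x0) / length     # along-line unit vector
    py, px = -ux, uy                                     # perpendicular
    offsets = (np.arange(width) - (width - 1) / 2.0)
    ys = y0 + s[:, None] * uy + offsets[None, :] * py    # (n, width)
    xs = x0 + s[:, None] * ux + offsets[None, :] * px
    vals = ndimage.map_coordinates(raster, [ys.ravel(), xs.ravel()],
                                   order=1, mode="nearest").reshape(n, width)
    if validity is not None:
        ok = ndimage.map_coordinates(np.asarray(validity, dtype=float),
                                     [ys.ravel(), xs.ravel()],
                                     order=1, mode="nearest").reshape(n, width) > 0.999
        vals = np.where(ok, vals, np.nan)
        n_ok = np.sum(ok, axis=1)
        with np.errstate(invalid="ignore"):
            profile = np.where(n_ok > 0, np.nansum(vals, axis=1) / np.maximum(n_ok, 1),
                               np.nan)
    else:
        profile = vals.mean(axis=1)
    return profile, s


def kymograph(maps, line, width: int = 1, t: np.ndarray | None = None,
              spacing: float = 1.0) -> Kymograph:
    """Stack per-frame line profiles into a time-versus-position raster.

    ``maps`` may be FretMap objects (validity respected) or plain rasters.
    Row order is time order.
    """
    if len(maps) == 0:
        raise ValueError("need at least one frame")
    rows, s_axis = [], None
    shape = None
    for m in maps:
        raster = m.values if isinstance(m, FretMap) else np.asarray(m, dtype=float)
        validity = m.validity if isinstance(m, FretMap) else None
        if shape is None:
            shape = raster.shape
        elif raster.shape != shape:
            raise ValueError("all maps must share one shape")
        profile, s_axis = sample_line(raster, line, width, spacing, validity)
        rows.append(profile)
    t = np.asarray(t, dtype=float) if t is not None else np.arange(len(rows), dtype=float)
    return Kymograph(np.vstack(rows), t, s_axis, meta={"line": line, "width": width})
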