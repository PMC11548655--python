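"""Anisotropy and FRET-ratio quantification.

Fluorescence anisotropy of a pixel or region is

    R = (P - g S) / (P + 2 g S)

with P and S the background-corrected parallel and perpendicular intensities
and g the instrument's correction for unequal detection sensitivity of the
two polarization states.  R lies in [-0.5, 1]; energy migration between like
fluorophores (homotransfer FRET) depolarizes emission and lowers R, so sensor
activation is conventionally presented as -R.

The two-color (heterotransfer) counterpart is the bleedthrough-corrected
ratio (Y - b C) / C, where b is the fraction of donor emission detected in
the acceptor channel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .stackio import ChannelStack, polygon_mask
from .traces import RegionTrace

__all__ = [
    "CalibrationParams",
    "BackgroundModel",
    "estimate_background",
    "anisotropy",
    "estimate_g",
    "fret_ratio",
    "estimate_bleedthrough",
    "roi_anisotropy",
    "roi_fret_ratio",
    "EPS_DENOM",
]

#: validity floor for denominators, counts
EPS_DENOM = 1e-9


@dataclass(frozen=True)
class CalibrationParams:
    """Instrument calibration: g (perpendicular-channel sensitivity) and b
    (donor bleedthrough fraction)."""

    g: float = 1.0
    b: float = 0.0
    source: str = "provided"          # "provided" | "estimated"
    reference_r: float | None = None  # anisotropy of the g reference, if estimated

    def __post_init__(self) -> None:
        if self.g <= 0:
            raise ValueError("g must be > 0")
        if not (0.0 <= self.b < 1.0):
            raise ValueError("b must be in [0, 1)")
        if self.source not in ("provided", "estimated"):
            raise ValueError("source must be 'provided' or 'estimated'")


@dataclass(frozen=True)
class BackgroundModel:
    """How per-channel, per-frame background is estimated: the mean of a
    hand-drawn background ROI, or a low percentile of the whole frame."""

    method: str = "roi_mean"
    percentile: float = 5.0

    def __post_init__(self) -> None:
        if self.method not in ("roi_mean", "percentile"):
            raise ValueError("method must be 'roi_mean' or 'percentile'")
        if not (0 <= self.percentile <= 100):
            raise ValueError("percentile must be in [0, 100]")


def estimate_background(raster: np.ndarray, model: BackgroundModel,
                        background_roi=None) -> float:
    """Scalar background level of one frame for one channel."""
    raster = np.asarray(raster, dtype=float)
    if model.method == "roi_mean":
        if background_roi is None:
            raise ValueError("roi_mean background requires a background ROI")
        mask = polygon_mask(background_roi, raster.shape)
        if not mask.any():
            raise ValueError("background ROI rasterizes to zero pixels")
        return float(raster[mask].mean())
    return float(np.percentile(raster, model.percentile))


def anisotropy(P, S, g=1.0):
    """R = (P - g S) / (P + 2 g S), elementwise.

    ``g`` may be a scalar or an array broadcastable against P and S.  Array
    inputs return a masked array with pixels masked where the denominator
    falls at or below the validity floor; scalar inputs return a float (or
    ``np.ma.masked`` for an invalid denominator).
    """
    g = np.asarray(g, dtype=float)
    if np.any(g <= 0):
        raise ValueError("g must be > 0")
    P = np.asarray(P, dtype=float)
    S = np.asarray(S, dtype=float)
    denom = P + 2.0 * g * S
    invalid = denom <= EPS_DENOM
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (P - g * S) / denom
    out = np.ma.masked_array(r, mask=invalid)
    if out.ndim == 0:
        return np.ma.masked if invalid else float(out)
    return out


def estimate_g(P_ref, S_ref, r_ref: float) -> float:
    """g of a reference specimen with known anisotropy, from the algebraic
    inverse of the anisotropy equation:

        g = P (1 - r_ref) / (S (1 + 2 r_ref))

    Raster inputs yield the median of per-pixel estimates over valid pixels.
    """
    if not (-0.5 < r_ref < 1.0):
        raise ValueError("r_ref must lie strictly inside (-0.5, 1)")
    P = np.asarray(P_ref, dtype=float)
    S = np.asarray(S_ref, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        g = P * (1.0 - r_ref) / (S * (1.0 + 2.0 * r_ref))
    if g.ndim == 0:
        if S <= EPS_DENOM:
            raise ValueError("S_ref must be > 0")
        return float(g)
    valid = (S > EPS_DENOM) & np.isfinite(g) & (g > 0)
    if not valid.any():
        raise ValueError("no valid pixels for g estimation")
    return float(np.median(g[valid]))


def fret_ratio(Y, C, b: float = 0.0):
    """Bleedthrough-corrected heterotransfer ratio (Y - b C) / C."""
    if not (0.0 <= b < 1.0):
        raise ValueError("b must be in [0, 1)")
    Y = np.asarray(Y, dtype=float)
    C = np.asarray(C, dtype=float)
    invalid = C <= EPS_DENOM
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = (Y - b * C) / C
    out = np.ma.masked_array(ratio, mask=invalid)
    if out.ndim == 0:
        return np.ma.masked if invalid else float(out)
    return out


def estimate_bleedthrough(C_donor_only, Y_donor_only, mask) -> float:
    """b from a donor-only specimen: the median of per-pixel Y/C over the
    validity mask (median for robustness to stray bright pixels)."""
    C = np.asarray(C_donor_only, dtype=float)
    Y = np.asarray(Y_donor_only, dtype=float)
    mask = np.asarray(mask, dtype=bool) & (C > EPS_DENOM)
    if not mask.any():
        raise ValueError("empty validity mask")
    b = float(np.median(Y[mask] / C[mask]))
    if not (0.0 <= b < 1.0):
        raise ValueError(f"estimated b {b:.4f} outside [0, 1)")
    return b


def _roi_channel_sums(stack: ChannelStack, cell_roi, background: BackgroundModel,
                      background_roi=None):
    """Per-frame background-corrected (sum_a, sum_b) over the ROI's valid
    pixels.  Background is estimated per channel per frame; negative residual
    pixels are retained in the sums (unbiased)."""
    shape = stack.channel_a.shape[1:]
    mask = polygon_mask(cell_roi, shape)
    if stack.validity_b is not None:
        mask = mask & stack.validity_b
    if not mask.any():
        raise ValueError("cell ROI has zero valid pixels")
    sums_a = np.empty(len(stack))
    sums_b = np.empty(len(stack))
    for i in range(len(stack)):
        bg_a = estimate_background(stack.channel_a[i], background, background_roi)
        bg_b = estimate_background(stack.channel_b[i], background, background_roi)
        sums_a[i] = (stack.channel_a[i][mask] - bg_a).sum()
        sums_b[i] = (stack.channel_b[i][mask] - bg_b).sum()
    return sums_a, sums_b


def roi_anisotropy(stack: ChannelStack, cell_roi, background: BackgroundModel,
                   g: float = 1.0, background_roi=None,
                   cell_id: int | str = 1, per_pixel_mean: bool = False) -> RegionTrace:
    """Per-cell anisotropy time course from a registered channel stack.

    Default estimator: sum background-corrected P and S over the ROI, then
    apply the anisotropy equation to the two sums (intensity-weighted, the
    noise-optimal order).  ``per_pixel_mean=True`` instead averages per-pixel
    R over the ROI, for comparison.  The trace carries the presented -R.
    """
    if per_pixel_mean:
        shape = stack.channel_a.shape[1:]
        mask = polygon_mask(cell_roi, shape)
        if stack.validity_b is not None:
            mask = mask & stack.validity_b
        values = np.empty(len(stack))
        for i in range(len(stack)):
            bg_a = estimate_background(stack.channel_a[i], background, background_roi)
            bg_b = estimate_background(stack.channel_b[i], background, background_roi)
            r = anisotropy(stack.channel_a[i] - bg_a, stack.channel_b[i] - bg_b, g)
            sel = mask & ~np.ma.getmaskarray(r)
            if not sel.any():
                raise ValueError(f"frame {i}: ROI has zero valid pixels")
            values[i] = float(np.ma.mean(r[sel]))
    else:
        sums_a, sums_b = _roi_channel_sums(stack, cell_roi, background, background_roi)
        values = np.empty(len(stack))
        for i, (pa, sb) in enumerate(zip(sums_a, sums_b)):
            r = anisotropy(pa, sb, g)
            if r is np.ma.masked:
                raise ValueError(f"frame {i}: ROI intensity at or below the validity floor")
            values[i] = r
    return RegionTrace(cell_id, stack.timebase.copy(), -values, "negR",
                       meta={"g": g, "estimator": "per_pixel_mean" if per_pixel_mean else "summed"})


def roi_fret_ratio(stack: ChannelStack, cell_roi, background: BackgroundModel,
                   b: float = 0.0, background_roi=None,
                   cell_id: int | str = 1) -> RegionTrace:
    """Per-cell heterotransfer FRET-ratio time course: channel sums over the
    ROI, then (Y - b C)/C on the sums.  channel_a is the donor C, channel_b
    the acceptor Y."""
    sums_c, sums_y = _roi_channel_sums(stack, cell_roi, background, background_roi)
    values = np.empty(len(stack))
    for i, (c, y) in enumerate(zip(sums_c, sums_y)):
        ratio = fret_ratio(y, c, b)
        if ratio is np.ma.masked:
            raise ValueError(f"frame {i}: donor ROI intensity at or below the validity floor")
        values[i] = ratio
    return RegionTrace(cell_id, stack.timebase.copy(), values, "ratio", meta={"b": b})
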