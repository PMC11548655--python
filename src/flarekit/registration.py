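"""Sub-pixel alignment of the two split channels.

The dual-view optics impose a fixed translation between the half-views, so a
single translation (no rotation/scaling) is estimated from a reference frame
pair via phase correlation and applied to every perpendicular/acceptor frame.

Shift convention: ``ChannelShift(dy, dx)`` means the moving image's content is
displaced by (+dy, +dx) relative to the reference, i.e.
``moving(y, x) = reference(y - dy, x - dx)``.  ``apply_shift`` with the
negated shift therefore restores alignment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.registration import phase_cross_correlation

from .stackio import ChannelStack

__all__ = ["ChannelShift", "estimate_shift", "apply_shift", "register_stack"]

MAX_SHIFT_PX = 20.0


@dataclass(frozen=True)
class ChannelShift:
    dy: float
    dx: float
    score: float = 0.0  # normalized cross-correlation at the estimated shift

    def __post_init__(self) -> None:
        if abs(self.dy) > MAX_SHIFT_PX or abs(self.dx) > MAX_SHIFT_PX:
            raise ValueError(
                f"shift ({self.dy}, {self.dx}) exceeds the {MAX_SHIFT_PX}-px bound"
            )

    @property
    def negated(self) -> "ChannelShift":
        return ChannelShift(-self.dy, -self.dx, self.score)


def _ncc(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a * a).sum() * (b * b).sum())
    if denom == 0:
        return 0.0
    return float(np.clip((a * b).sum() / denom, -1.0, 1.0))


def estimate_shift(reference: np.ndarray, moving: np.ndarray, upsample: int = 20) -> ChannelShift:
    """Estimate the translation of ``moving`` relative to ``reference`` by
    phase correlation, refined to 1/``upsample`` pixel."""
    reference = np.asarray(reference, dtype=float)
    moving = np.asarray(moving, dtype=float)
    if reference.shape != moving.shape:
        raise ValueError("reference and moving must have the same shape")
    if np.ptp(reference) == 0 or np.ptp(moving) == 0:
        raise ValueError("no structure to register: constant image")
    # Hann window after mean subtraction suppresses the spectral leakage that
    # biases sub-pixel estimates on smooth, non-periodic images.
    win = np.outer(np.hanning(reference.shape[0]), np.hanning(reference.shape[1]))
    ref_w = (reference - reference.mean()) * win
    mov_w = (moving - moving.mean()) * win
    # phase_cross_correlation returns the shift to apply to `moving` to match
    # `reference`; our convention stores the displacement of `moving`, i.e.
    # its negation.
    shift, _, _ = phase_cross_correlation(
        ref_w, mov_w, upsample_factor=max(1, int(upsample)), normalization=None
    )
    dy, dx = float(-shift[0]), float(-shift[1])
    aligned, _ = apply_shift(moving, ChannelShift(dy, dx).negated)
    return ChannelShift(dy, dx, score=max(0.0, _ncc(reference, aligned)))


def apply_shift(raster: np.ndarray, shift: ChannelShift) -> tuple[np.ndarray, np.ndarray]:
    """Translate a raster by (shift.dy, shift.dx) with bilinear interpolation.

    Returns (shifted, validity): pixels whose value required data from
    outside the field are filled with the image's background estimate (5th
    percentile) and marked invalid.
    """
    raster = np.asarray(raster, dtype=float)
    if not (np.isfinite(shift.dy) and np.isfinite(shift.dx)):
        raise ValueError("shift must be finite")
    if shift.dy == 0.0 and shift.dx == 0.0:
        return raster.copy(), np.ones(raster.shape, dtype=bool)
    bg = float(np.percentile(raster, 5))
    out = ndimage.shift(raster, (shift.dy, shift.dx), order=1, mode="constant", cval=bg)
    support = ndimage.shift(
        np.ones(raster.shape), (shift.dy, shift.dx), order=1, mode="constant", cval=0.0
    )
    return out, support > 0.999


def register_stack(stack: ChannelStack, mode: str = "first_frame", upsample: int = 20) -> ChannelStack:
    """Register channel_b onto channel_a with one stack-wide translation.

    The shift is estimated from the first frame pair or from the time-mean
    frame pair; the dual-view geometry is fixed over a time course, so one
    transform serves all frames.
    """
    if mode not in ("first_frame", "mean_frame"):
        raise ValueError(f"unknown registration mode {mode!r}")
    if mode == "first_frame":
        ref, mov = stack.channel_a[0], stack.channel_b[0]
    else:
        ref, mov = stack.channel_a.mean(axis=0), stack.channel_b.mean(axis=0)
    shift = estimate_shift(ref, mov, upsample=upsample)
    inv = shift.negated
    shifted = np.empty_like(stack.channel_b)
    validity = None
    for i in range(len(stack)):
        shifted[i], validity = apply_shift(stack.channel_b[i], inv)
    meta = dict(stack.meta)
    meta["registration"] = {"dy": shift.dy, "dx": shift.dx, "score": shift.score, "mode": mode}
    return ChannelStack(
        stack.channel_a.copy(), shifted, stack.timebase.copy(),
        registered=True, validity_b=validity, meta=meta,
    )
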