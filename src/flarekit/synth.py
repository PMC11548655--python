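"""Synthetic polarization-microscopy data generator.

Renders dual-view time-lapse stacks (parallel/perpendicular polarization
channels, or donor/acceptor channels in heterotransfer mode) from a fully
parameterized ground truth, so that every analysis stage can be validated by
recovery of known values.

Image-formation model
---------------------
For a pixel with total emitted intensity ``I`` (photons) and true anisotropy
``r``, the ideal channel intensities are::

    P      = I * (1 + 2 r) / 3        (parallel)
    S_true = I * (1 - r) / 3          (perpendicular)

so that ``P + 2 S_true = I`` and ``(P - S_true) / (P + 2 S_true) = r``.  The
instrument's unequal sensitivity to the two polarization states is modeled as
an attenuation of the detected perpendicular channel, ``S_det = S_true / g``,
which the analysis-side g-factor correction exactly cancels.  With noise
enabled, each channel's photon signal is Poisson sampled, Gaussian read noise
is added, and a constant camera offset applied.  The second half-view is
translated by a fixed sub-pixel misalignment before composition into a single
side-by-side frame, emulating a dual-view beam splitter.

Drug-response kinetics are exponential-saturation with a Hill-function dose
dependence of the amplitude; cell-to-cell variability is a multiplicative
Normal(1, cell_sd) factor on the amplitude.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .stackio import DualViewStack
from .traces import RegionTrace

__all__ = [
    "KineticsSpec",
    "NoiseSpec",
    "AcquisitionSpec",
    "GroundTruthScene",
    "TruthSidecar",
    "make_cells",
    "make_scene",
    "hill_amplitude",
    "anisotropy_kinetics",
    "render_polarization_frame",
    "simulate_timecourse",
    "render_heterotransfer_timecourse",
    "simulate_roi_traces",
    "inscribed_square_roi",
    "moving_band_maps",
]

R_MIN, R_MAX = -0.5, 1.0


@dataclass(frozen=True)
class KineticsSpec:
    """Drug-response kinetics of the true anisotropy signal.

    ``r_base`` is the pre-drug anisotropy; ``delta_r_max`` the saturating
    amplitude (negative for sensor activation, since activation lowers R and
    raises the presented -R); ``tau`` the exponential time constant in
    minutes; ``ec50``/``hill_slope`` shape the dose dependence of the
    amplitude; ``cell_sd`` is the s.d. of the per-cell multiplicative
    amplitude factor.
    """

    r_base: float = 0.30
    delta_r_max: float = -0.02
    tau: float = 2.0
    t_drug: float = 0.0
    ec50: float = 3.0
    hill_slope: float = 1.0
    cell_sd: float = 0.1

    def __post_init__(self) -> None:
        if not (R_MIN <= self.r_base <= R_MAX):
            raise ValueError(f"r_base {self.r_base} outside [{R_MIN}, {R_MAX}]")
        if not (R_MIN <= self.r_base + self.delta_r_max <= R_MAX):
            raise ValueError("r_base + delta_r_max outside anisotropy bounds")
        if self.tau <= 0:
            raise ValueError("tau must be > 0")
        if self.ec50 <= 0:
            raise ValueError("ec50 must be > 0")
        if self.hill_slope <= 0:
            raise ValueError("hill_slope must be > 0")
        if self.cell_sd < 0:
            raise ValueError("cell_sd must be >= 0")


@dataclass(frozen=True)
class NoiseSpec:
    """Camera/photon noise model: Poisson shot noise on the expected photon
    signal, Gaussian read noise (counts), constant offset (counts) and a
    uniform background photon level."""

    photons_per_cell_pixel: float = 1000.0
    read_sd: float = 2.0
    offset: float = 100.0
    background_photons: float = 20.0

    def __post_init__(self) -> None:
        for name in ("photons_per_cell_pixel", "read_sd", "offset", "background_photons"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class AcquisitionSpec:
    """Acquisition geometry and calibration constants.

    30-s frame cadence with 6 pre-drug frames (a 3-minute baseline) by
    default.  ``channel_shift`` is the fixed (dy, dx) sub-pixel misalignment
    of the second half-view; ``g`` the perpendicular-channel detection
    sensitivity; ``b`` the donor bleedthrough fraction (heterotransfer only).
    """

    frame_interval: float = 30.0
    n_frames_pre: int = 6
    n_frames_post: int = 20
    half_view_shape: tuple[int, int] = (256, 256)
    channel_shift: tuple[float, float] = (0.0, 0.0)
    g: float = 1.0
    b: float = 0.0

    def __post_init__(self) -> None:
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be > 0")
        if self.n_frames_pre < 0 or self.n_frames_post < 0:
            raise ValueError("frame counts must be >= 0")
        if self.g <= 0:
            raise ValueError("g must be > 0")
        if not (0.0 <= self.b < 1.0):
            raise ValueError("b must be in [0, 1)")

    @property
    def n_frames(self) -> int:
        return self.n_frames_pre + self.n_frames_post

    def times_min(self) -> np.ndarray:
        """Frame times in minutes relative to drug addition (frame
        ``n_frames_pre`` is T = 0)."""
        idx = np.arange(self.n_frames)
        return (idx - self.n_frames_pre) * self.frame_interval / 60.0


@dataclass
class GroundTruthScene:
    """The simulator's ground truth: labeled cell masks, per-cell emitted
    intensity I (photons per pixel; I = P + 2S), kinetics/noise/acquisition
    specs and the root RNG seed."""

    cell_masks: np.ndarray
    intensity: dict[int, float]
    kinetics: KineticsSpec
    noise: NoiseSpec
    acquisition: AcquisitionSpec
    seed: int = 0
    anisotropy_truth: dict[tuple[int, int], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        labels = self.cell_labels
        missing = [k for k in labels if k not in self.intensity]
        if missing:
            raise ValueError(f"no intensity for cell labels {missing}")

    @property
    def cell_labels(self) -> list[int]:
        return sorted(int(k) for k in np.unique(self.cell_masks) if k != 0)


@dataclass
class TruthSidecar:
    """Per-cell, per-frame truth accompanying a simulated stack."""

    t_min: np.ndarray
    r_true: dict[int, np.ndarray]          # cell label -> per-frame truth
    cell_factor: dict[int, float]          # per-cell amplitude factor
    dose: float
    params: dict

    def to_frame(self):
        import pandas as pd

        rows = []
        for cell, r in sorted(self.r_true.items()):
            for i, t in enumerate(self.t_min):
                rows.append((cell, i, float(t), float(r[i])))
        return pd.DataFrame(rows, columns=["cell_id", "frame", "t_min", "r_true"])

    def to_json_dict(self) -> dict:
        return {
            "params": self.params,
            "dose": self.dose,
            "t_min": [float(t) for t in self.t_min],
            "cell_factor": {str(k): float(v) for k, v in self.cell_factor.items()},
            "r_true": {str(k): [float(x) for x in v] for k, v in self.r_true.items()},
        }


# ---------------------------------------------------------------------------
# RNG discipline: one root seed; fixed-offset child streams per purpose so
# partial re-rendering is reproducible.

_STREAM_CELLS = 0
_STREAM_FACTORS = 1
_STREAM_FRAME_BASE = 1000


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(stream)]))


def make_cells(
    n_cells: int, half_view_shape: tuple[int, int], seed: int, min_area: int = 50
) -> np.ndarray:
    """Place ``n_cells`` disjoint elliptical cells on a dark field.

    Rejection-samples ellipse centers/axes/orientations; each placed cell must
    not touch an existing one and must cover at least ``min_area`` pixels.
    Raises ``RuntimeError('field too crowded')`` after 200 failed attempts
    per cell.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    h, w = half_view_shape
    rng = _rng(seed, _STREAM_CELLS)
    masks = np.zeros((h, w), dtype=np.int32)
    yy, xx = np.mgrid[0:h, 0:w]
    for label in range(1, n_cells + 1):
        for _ in range(200):
            a = rng.uniform(0.05, 0.14) * min(h, w)   # semi-axes, pixels
            b = rng.uniform(0.6, 1.0) * a
            cy = rng.uniform(a + 1, h - a - 1)
            cx = rng.uniform(a + 1, w - a - 1)
            theta = rng.uniform(0, math.pi)
            c, s = math.cos(theta), math.sin(theta)
            u = (xx - cx) * c + (yy - cy) * s
            v = -(xx - cx) * s + (yy - cy) * c
            ell = (u / a) ** 2 + (v / b) ** 2 <= 1.0
            if ell.sum() < min_area:
                continue
            # require a 2-px moat around existing cells
            if (masks[ndimage.binary_dilation(ell, iterations=2)] != 0).any():
                continue
            masks[ell] = label
            break
        else:
            raise RuntimeError("field too crowded: could not place all cells")
    return masks


def make_scene(
    n_cells: int = 5,
    kinetics: KineticsSpec | None = None,
    noise: NoiseSpec | None = None,
    acquisition: AcquisitionSpec | None = None,
    seed: int = 0,
) -> GroundTruthScene:
    """Convenience factory: cells plus uniform per-cell intensity equal to the
    noise spec's photon budget."""
    kinetics = kinetics or KineticsSpec()
    noise = noise or NoiseSpec()
    acquisition = acquisition or AcquisitionSpec()
    masks = make_cells(n_cells, acquisition.half_view_shape, seed)
    # photons_per_cell_pixel is the brighter-channel (P) budget at baseline;
    # convert to total I so P = I(1+2r)/3 matches it.
    I = noise.photons_per_cell_pixel * 3.0 / (1.0 + 2.0 * kinetics.r_base)
    intensity = {int(k): float(I) for k in np.unique(masks) if k != 0}
    return GroundTruthScene(masks, intensity, kinetics, noise, acquisition, seed)


def hill_amplitude(spec: KineticsSpec, dose: float) -> float:
    """Saturating amplitude A(dose) = delta_r_max * d^h / (ec50^h + d^h)."""
    if dose < 0:
        raise ValueError("dose must be >= 0")
    if dose == 0:
        return 0.0
    dh = dose ** spec.hill_slope
    return spec.delta_r_max * dh / (spec.ec50 ** spec.hill_slope + dh)


def anisotropy_kinetics(spec: KineticsSpec, dose: float, t: float) -> float:
    """True anisotropy at time ``t`` (minutes relative to drug addition).

    r(t) = r_base for t < 0, and r_base + A(dose) (1 - exp(-t/tau)) after,
    clipped to the physical range [-0.5, 1].
    """
    a = hill_amplitude(spec, dose)
    tt = t - spec.t_drug
    if tt < 0:
        r = spec.r_base
    else:
        r = spec.r_base + a * (1.0 - math.exp(-tt / spec.tau))
    return float(min(max(r, R_MIN), R_MAX))


def _truth_table(
    scene: GroundTruthScene, dose: float, clip_hi: float = R_MAX, lo: float = R_MIN
) -> TruthSidecar:
    acq = scene.acquisition
    t_min = acq.times_min()
    rng = _rng(scene.seed, _STREAM_FACTORS)
    labels = scene.cell_labels
    factors = {k: float(rng.normal(1.0, scene.kinetics.cell_sd)) for k in labels}
    r_true: dict[int, np.ndarray] = {}
    a = hill_amplitude(scene.kinetics, dose)
    for k in labels:
        amp = a * factors[k]
        r = np.full(t_min.shape, scene.kinetics.r_base)
        post = t_min >= scene.kinetics.t_drug
        r[post] = scene.kinetics.r_base + amp * (
            1.0 - np.exp(-(t_min[post] - scene.kinetics.t_drug) / scene.kinetics.tau)
        )
        r_true[k] = np.clip(r, lo, clip_hi)
    params = {
        "kinetics": dataclasses.asdict(scene.kinetics),
        "noise": dataclasses.asdict(scene.noise),
        "acquisition": dataclasses.asdict(scene.acquisition),
        "seed": scene.seed,
    }
    return TruthSidecar(t_min, r_true, factors, float(dose), params)


def _r_field(scene: GroundTruthScene, sidecar: TruthSidecar, frame: int) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel (I, r) fields for one frame (background pixels have I = 0)."""
    masks = scene.cell_masks
    I = np.zeros(masks.shape, dtype=float)
    r = np.zeros(masks.shape, dtype=float)
    for k in scene.cell_labels:
        sel = masks == k
        I[sel] = scene.intensity[k]
        r[sel] = sidecar.r_true[k][frame]
    return I, r


def _compose_dual_view(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    return np.concatenate([a, b], axis=1)


def _detect(
    signal: np.ndarray, noise: NoiseSpec, noise_on: bool, rng: np.random.Generator | None
) -> np.ndarray:
    if noise_on:
        assert rng is not None
        out = rng.poisson(signal).astype(float)
        out += rng.normal(0.0, noise.read_sd, size=signal.shape)
    else:
        out = signal.astype(float)
    return out + noise.offset


def render_polarization_frame(
    scene: GroundTruthScene,
    frame_index: int,
    sidecar: TruthSidecar,
    noise_on: bool = True,
    seed: int | None = None,
) -> np.ndarray:
    """Render one side-by-side P|S frame from the truth table.

    The perpendicular channel is attenuated by 1/g and translated by the
    acquisition's channel_shift (bilinear) before composition.
    """
    acq = scene.acquisition
    if not (0 <= frame_index < acq.n_frames):
        raise IndexError(f"frame_index {frame_index} outside acquisition range")
    I, r = _r_field(scene, sidecar, frame_index)
    if np.any((r < R_MIN) | (r > R_MAX)):
        raise ValueError("true anisotropy outside [-0.5, 1]")
    P = I * (1.0 + 2.0 * r) / 3.0 + scene.noise.background_photons
    S = (I * (1.0 - r) / 3.0 + scene.noise.background_photons) / acq.g
    rng = None
    if noise_on:
        rng = _rng(scene.seed if seed is None else seed, _STREAM_FRAME_BASE + frame_index)
    P_det = _detect(P, scene.noise, noise_on, rng)
    S_det = _detect(S, scene.noise, noise_on, rng)
    dy, dx = acq.channel_shift
    if dy != 0.0 or dx != 0.0:
        S_det = ndimage.shift(S_det, (dy, dx), order=1, mode="nearest")
    return _compose_dual_view(P_det, S_det)


def simulate_timecourse(
    scene: GroundTruthScene, dose: float, noise_on: bool = True
) -> tuple[DualViewStack, TruthSidecar]:
    """Simulate a drug-addition time course; returns the raw dual-view stack
    and the truth sidecar (per-cell per-frame anisotropy, amplitude factors,
    all scene parameters)."""
    sidecar = _truth_table(scene, dose)
    acq = scene.acquisition
    frames = np.stack(
        [
            render_polarization_frame(scene, i, sidecar, noise_on=noise_on)
            for i in range(acq.n_frames)
        ]
    )
    stack = DualViewStack(
        frames=frames,
        frame_interval=acq.frame_interval,
        t_drug_index=acq.n_frames_pre,
        layout="horizontal",
    )
    return stack, sidecar


def render_heterotransfer_timecourse(
    scene: GroundTruthScene, dose: float, noise_on: bool = True
) -> tuple[DualViewStack, TruthSidecar]:
    """Simulate a two-color donor|acceptor (C|Y) time course.

    A FRET fraction f(t) follows the same kinetics law as r (the kinetics
    spec's r_base is the baseline fraction, constrained to [0, 1)); per pixel
    C = I (1 - f), Y_true = I f, and the detected acceptor channel is
    Y = Y_true + b C.  The sidecar's r_true holds f.
    """
    sidecar = _truth_table(scene, dose, clip_hi=1.0, lo=0.0)
    for k, f in sidecar.r_true.items():
        if np.any((f < 0) | (f >= 1.0)):
            raise ValueError(f"FRET fraction for cell {k} outside [0, 1)")
    acq = scene.acquisition
    frames = []
    for i in range(acq.n_frames):
        I, f = _r_field(scene, sidecar, i)
        C = I * (1.0 - f) + scene.noise.background_photons
        Y = I * f + acq.b * (I * (1.0 - f)) + scene.noise.background_photons
        rng = _rng(scene.seed, _STREAM_FRAME_BASE + i) if noise_on else None
        C_det = _detect(C, scene.noise, noise_on, rng)
        Y_det = _detect(Y, scene.noise, noise_on, rng)
        dy, dx = acq.channel_shift
        if dy != 0.0 or dx != 0.0:
            Y_det = ndimage.shift(Y_det, (dy, dx), order=1, mode="nearest")
        frames.append(_compose_dual_view(C_det, Y_det))
    stack = DualViewStack(
        frames=np.stack(frames),
        frame_interval=acq.frame_interval,
        t_drug_index=acq.n_frames_pre,
        layout="horizontal",
    )
    return stack, sidecar


def simulate_roi_traces(
    kinetics: KineticsSpec,
    n_cells: int,
    dose: float,
    noise_sd: float,
    acquisition: AcquisitionSpec | None = None,
    seed: int = 0,
    treatment: str = "",
) -> list[RegionTrace]:
    """Trace-level simulator: per-cell anisotropy time courses with i.i.d.
    Gaussian measurement noise of s.d. ``noise_sd`` per frame, bypassing image
    formation.  Used for statistical-power and dose-response studies where
    rendering full stacks would add nothing.

    Traces carry the presented -R (value_kind ``negR``).
    """
    acq = acquisition or AcquisitionSpec()
    t_min = acq.times_min()
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 77]))
    a = hill_amplitude(kinetics, dose)
    traces = []
    for c in range(n_cells):
        amp = a * rng.normal(1.0, kinetics.cell_sd)
        r = np.full(t_min.shape, kinetics.r_base)
        post = t_min >= 0
        r[post] = kinetics.r_base + amp * (1.0 - np.exp(-t_min[post] / kinetics.tau))
        r = np.clip(r, R_MIN, R_MAX) + rng.normal(0.0, noise_sd, size=t_min.shape)
        traces.append(
            RegionTrace(
                cell_id=c + 1,
                t=t_min.copy(),
                value=-r,
                value_kind="negR",
                meta={"treatment": treatment, "dose": float(dose)},
            )
        )
    return traces


def inscribed_square_roi(masks: np.ndarray, label: int) -> list:
    """Rectangle ROI polygon fully inside a labeled cell region: the largest
    axis-aligned square of pixels around the region centroid whose pixels all
    carry the label.  Edges sit at pixel-center +-0.5 so the rasterized mask
    is exactly the square."""
    ys, xs = np.nonzero(masks == label)
    if ys.size == 0:
        raise ValueError(f"label {label} not present")
    cy, cx = int(round(ys.mean())), int(round(xs.mean()))
    half = 0
    while True:
        nxt = half + 1
        y0, y1, x0, x1 = cy - nxt, cy + nxt, cx - nxt, cx + nxt
        block = masks[max(0, y0):y1 + 1, max(0, x0):x1 + 1]
        if block.shape != (2 * nxt + 1, 2 * nxt + 1) or not np.all(block == label):
            break
        half = nxt
    y0, y1, x0, x1 = cy - half, cy + half, cx - half, cx + half
    return [[y0 - 0.5, x0 - 0.5], [y0 - 0.5, x1 + 0.5],
            [y1 + 0.5, x1 + 0.5], [y1 + 0.5, x0 - 0.5]]


def moving_band_maps(
    shape: tuple[int, int],
    n_frames: int,
    start_col: float,
    speed_px_per_frame: float,
    band_sigma: float = 2.0,
    base: float = -0.30,
    amplitude: float = 0.02,
) -> tuple[list[np.ndarray], np.ndarray]:
    """Scripted membrane-protrusion analogue: a Gaussian band of elevated
    activity translating along the column axis at a known speed.

    Returns per-frame activity rasters (value_kind -R) and the true band
    center column per frame.  Not a motility model; used to validate
    kymograph geometry.
    """
    h, w = shape
    cols = np.arange(w, dtype=float)
    truth = start_col + speed_px_per_frame * np.arange(n_frames)
    maps = []
    for c in truth:
        profile = base + amplitude * np.exp(-0.5 * ((cols - c) / band_sigma) ** 2)
        maps.append(np.tile(profile, (h, 1)))
    return maps, truth
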