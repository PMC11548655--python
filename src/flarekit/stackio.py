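"""Stack, ROI and trace I/O: multi-page TIFF in/out, dual-view splitting,
polygon rasterization and the long-format trace CSV schema.

Coordinate convention: 0-based (row, col); pixel centers at integer
coordinates; polygons live in the same continuous frame.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from matplotlib.path import Path as MplPath

from .traces import VALUE_KINDS, RegionTrace

log = logging.getLogger(__name__)

__all__ = [
    "DualViewStack",
    "ChannelStack",
    "RoiSet",
    "read_stack",
    "write_stack",
    "split_dual_view",
    "polygon_mask",
    "read_roi_json",
    "write_roi_json",
    "write_trace_csv",
    "read_trace_csv",
]


@dataclass
class DualViewStack:
    """Time-ordered raw frames, each a side-by-side pair of channel
    half-images (horizontal layout: [A | B]; vertical: A above B)."""

    frames: np.ndarray                      # (T, H, W) counts
    frame_interval: float = 30.0            # seconds
    t_drug_index: int | None = None
    layout: str = "horizontal"

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (T, H, W) array")
        if self.layout not in ("horizontal", "vertical"):
            raise ValueError(f"unknown layout {self.layout!r}")
        axis_len = self.frames.shape[2] if self.layout == "horizontal" else self.frames.shape[1]
        if axis_len % 2 != 0:
            warnings.warn(
                f"split axis length {axis_len} is odd; split_dual_view will fail",
                stacklevel=2,
            )

    def __len__(self) -> int:
        return int(self.frames.shape[0])


@dataclass
class ChannelStack:
    """Split (and possibly registered) two-channel image series.

    channel_a holds P (or donor C), channel_b holds S (or acceptor Y).
    ``validity_b`` marks channel_b pixels invalidated by registration edge
    fill; ``timebase`` is minutes relative to drug addition.
    """

    channel_a: np.ndarray
    channel_b: np.ndarray
    timebase: np.ndarray
    registered: bool = False
    validity_b: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.channel_a = np.asarray(self.channel_a, dtype=float)
        self.channel_b = np.asarray(self.channel_b, dtype=float)
        self.timebase = np.asarray(self.timebase, dtype=float)
        if self.channel_a.shape != self.channel_b.shape:
            raise ValueError("channel shapes differ")
        if self.timebase.size != self.channel_a.shape[0]:
            raise ValueError("timebase length differs from frame count")
        if self.timebase.size > 1 and not np.all(np.diff(self.timebase) > 0):
            raise ValueError("timebase must be strictly increasing")

    def __len__(self) -> int:
        return int(self.channel_a.shape[0])


@dataclass
class RoiSet:
    """Named polygon regions (role 'cell' or 'background') and line segments
    (for kymographs), in pixel coordinates."""

    regions: dict = field(default_factory=dict)  # name -> {"polygon": [[y,x],...], "role": str}
    lines: dict = field(default_factory=dict)    # name -> {"p0": [y,x], "p1": [y,x], "width": int}

    def __post_init__(self) -> None:
        for name, reg in self.regions.items():
            if reg.get("role") not in ("cell", "background"):
                raise ValueError(f"region {name!r}: role must be 'cell' or 'background'")
            if len(reg.get("polygon", [])) < 3:
                raise ValueError(f"region {name!r}: polygon needs >= 3 vertices")
        for name, line in self.lines.items():
            if line.get("width", 1) < 1:
                raise ValueError(f"line {name!r}: width must be >= 1")

    def cells(self) -> dict:
        return {n: r for n, r in self.regions.items() if r["role"] == "cell"}

    def background(self) -> dict:
        return {n: r for n, r in self.regions.items() if r["role"] == "background"}


# ---------------------------------------------------------------------------
# TIFF stack I/O.  Pixel data are stored as 16-bit unsigned counts; metadata
# travels in a JSON sidecar next to the TIFF.


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_stack(stack: DualViewStack, path: str | Path) -> Path:
    """Write a multi-page 16-bit TIFF plus a metadata JSON sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    data = np.clip(np.rint(stack.frames), 0, 65535).astype(np.uint16)
    tifffile.imwrite(path, data, photometric="minisblack")
    meta = {
        "frame_interval": stack.frame_interval,
        "t_drug_index": stack.t_drug_index,
        "layout": stack.layout,
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))
    return path


def read_stack(path: str | Path) -> DualViewStack:
    """Read a multi-page TIFF stack; metadata from the JSON sidecar when
    present, else documented defaults (30-s cadence, horizontal layout) with a
    logged warning."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        frames = tifffile.imread(path)
    except Exception as exc:  # noqa: BLE001 - surface as a format error
        raise ValueError(f"unreadable TIFF {path}: {exc}") from exc
    frames = np.asarray(frames)
    if frames.ndim == 2:
        frames = frames[None]
    if frames.ndim != 3:
        raise ValueError(f"{path}: expected 2-D pages, got array of ndim {frames.ndim}")
    meta = {"frame_interval": 30.0, "t_drug_index": None, "layout": "horizontal"}
    sc = _sidecar_path(path)
    if sc.exists():
        meta.update(json.loads(sc.read_text()))
    else:
        log.warning("%s: no metadata sidecar; assuming %s", path, meta)
    return DualViewStack(frames.astype(float), meta["frame_interval"],
                         meta["t_drug_index"], meta["layout"])


def split_dual_view(stack: DualViewStack) -> ChannelStack:
    """Split each side-by-side frame into its two channel halves.

    The first half along the layout axis becomes channel_a (P or C), the
    second channel_b (S or Y).  The timebase puts T = 0 at ``t_drug_index``
    (first frame if absent).
    """
    frames = stack.frames
    axis = 2 if stack.layout == "horizontal" else 1
    n = frames.shape[axis]
    if n % 2 != 0:
        raise ValueError(f"split axis length {n} is odd")
    half = n // 2
    if stack.layout == "horizontal":
        a, b = frames[:, :, :half], frames[:, :, half:]
    else:
        a, b = frames[:, :half, :], frames[:, half:, :]
    t0 = stack.t_drug_index if stack.t_drug_index is not None else 0
    timebase = (np.arange(len(stack)) - t0) * stack.frame_interval / 60.0
    return ChannelStack(a.copy(), b.copy(), timebase, registered=False)


def recompose_dual_view(cstack: ChannelStack, layout: str = "horizontal") -> np.ndarray:
    """Inverse of split_dual_view (for round-trip checks and export)."""
    axis = 2 if layout == "horizontal" else 1
    return np.concatenate([cstack.channel_a, cstack.channel_b], axis=axis)


# ---------------------------------------------------------------------------
# Polygons and ROI serialization


def polygon_mask(polygon, shape: tuple[int, int]) -> np.ndarray:
    """Rasterize a polygon: a pixel is included iff its center (integer
    coordinates) lies inside the polygon, even-odd rule."""
    verts = np.asarray(polygon, dtype=float)
    if verts.ndim != 2 or verts.shape[0] < 3 or verts.shape[1] != 2:
        raise ValueError("polygon needs >= 3 (y, x) vertices")
    h, w = shape
    if h <= 0 or w <= 0:
        raise ValueError("shape must be positive")
    yy, xx = np.mgrid[0:h, 0:w]
    pts = np.column_stack([xx.ravel(), yy.ravel()])
    # MplPath works in (x, y); simple polygons: winding == even-odd
    path = MplPath(verts[:, ::-1])
    inside = path.contains_points(pts, radius=0.0)
    return inside.reshape(h, w)


def write_roi_json(rois: RoiSet, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps({"regions": rois.regions, "lines": rois.lines}, indent=1))
    return path


def read_roi_json(path: str | Path) -> RoiSet:
    data = json.loads(Path(path).read_text())
    return RoiSet(regions=data.get("regions", {}), lines=data.get("lines", {}))


# ---------------------------------------------------------------------------
# Trace CSV schema: long format, columns cell_id, t_min, value, value_kind


def write_trace_csv(traces, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    rows = []
    for tr in traces:
        for t, v in zip(tr.t, tr.value):
            rows.append((tr.cell_id, float(t), float(v), tr.value_kind))
    df = pd.DataFrame(rows, columns=["cell_id", "t_min", "value", "value_kind"])
    df.to_csv(path, index=False)
    return path


def read_trace_csv(path: str | Path) -> list[RegionTrace]:
    df = pd.read_csv(Path(path))
    expected = ["cell_id", "t_min", "value", "value_kind"]
    if list(df.columns) != expected:
        raise ValueError(f"trace CSV must have columns {expected}, got {list(df.columns)}")
    bad = set(df["value_kind"].unique()) - set(VALUE_KINDS)
    if bad:
        raise ValueError(f"unknown value_kind {sorted(bad)}")
    traces = []
    for (cell, kind), grp in df.groupby(["cell_id", "value_kind"], sort=False):
        grp = grp.sort_values("t_min")
        traces.append(RegionTrace(cell, grp["t_min"].to_numpy(),
                                  grp["value"].to_numpy(), str(kind)))
    return traces
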