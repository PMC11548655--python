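"""Per-region quantified time series."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Recognized trace value kinds: raw anisotropy (R), presented -R, baseline
#: changes, heterotransfer ratio, and the T=0-normalized ratio.
VALUE_KINDS = ("R", "negR", "dR", "negdR", "ratio", "R_over_R0")


@dataclass
class RegionTrace:
    """One cell's quantified time series.

    ``t`` is in minutes relative to drug addition (negative = pre-drug);
    ``value`` is interpreted according to ``value_kind``; ``meta`` carries the
    treatment label, dose and any derived quantities (e.g. the subtracted
    baseline).
    """

    cell_id: int | str
    t: np.ndarray
    value: np.ndarray
    value_kind: str = "R"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.value = np.asarray(self.value, dtype=float)
        if self.t.shape != self.value.shape:
            raise ValueError("t and value must have the same length")
        if self.t.size > 1 and not np.all(np.diff(self.t) > 0):
            raise ValueError("t must be strictly increasing")
        if self.value_kind not in VALUE_KINDS:
            raise ValueError(f"unknown value_kind {self.value_kind!r}")

    def as_neg_r(self) -> "RegionTrace":
        """Return the trace in the presented -R convention."""
        if self.value_kind == "negR":
            return self
        if self.value_kind == "R":
            return RegionTrace(self.cell_id, self.t, -self.value, "negR", dict(self.meta))
        raise ValueError(f"cannot convert value_kind {self.value_kind!r} to negR")

    def __len__(self) -> int:
        return int(self.t.size)
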