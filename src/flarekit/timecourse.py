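"""Time-course summaries and dose-response statistics.

Converts per-cell anisotropy traces into the standard reporting quantities:
smoothed traces, change over the pre-drug baseline (-dR), the T=0-normalized
ratio R/R0, peak and integrated responses, unpaired two-group t-tests and the
normalized (0-100) Hill dose-response fit.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy import optimize, stats

from .traces import RegionTrace

__all__ = [
    "RegionTrace",
    "DoseResponseResult",
    "GroupComparison",
    "smooth_trace",
    "delta_over_baseline",
    "ratio_over_t0",
    "peak_response",
    "integrate_response",
    "compare_groups",
    "normalize_dose_response",
    "fit_hill",
    "summarize_mean_response",
]

EPS = 1e-12


def smooth_trace(trace: RegionTrace, window: int = 3) -> RegionTrace:
    """Centered moving average with windows shrinking at the trace ends
    (every output point averages the samples within +-(window-1)/2 frames
    that exist).  window=1 is the identity."""
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be odd and >= 1")
    n = len(trace)
    if window > n:
        raise ValueError("window longer than trace")
    half = window // 2
    v = trace.value
    out = np.empty(n)
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        out[i] = v[lo:hi].mean()
    meta = dict(trace.meta)
    meta["smooth_window"] = window
    return RegionTrace(trace.cell_id, trace.t.copy(), out, trace.value_kind, meta)


def delta_over_baseline(trace: RegionTrace, baseline_minutes: float = 3.0) -> RegionTrace:
    """Change in anisotropy over the pre-drug baseline, presented as -dR.

    The baseline is the mean over samples with t in [-baseline_minutes, 0)
    (drug addition at T = 0 excluded); the output is -(R(t) - baseline), so
    a drop in R (sensor activation) appears as positive -dR.  Accepts traces
    in R or -R convention.
    """
    neg = trace.as_neg_r()
    sel = (neg.t >= -baseline_minutes) & (neg.t < 0)
    if not sel.any():
        raise ValueError("no pre-drug samples in the baseline window")
    baseline = float(neg.value[sel].mean())
    meta = dict(neg.meta)
    meta["baseline_negR"] = baseline
    meta["baseline_minutes"] = baseline_minutes
    return RegionTrace(neg.cell_id, neg.t.copy(), neg.value - baseline, "negdR", meta)


def ratio_over_t0(trace: RegionTrace, tol_frames: float = 0.5) -> RegionTrace:
    """Normalize a -R trace to its value at drug addition: R/R0(t) =
    (-R(t)) / (-R(0)).  The T=0 sample is the nearest sample within half a
    frame interval."""
    neg = trace.as_neg_r()
    i0 = int(np.argmin(np.abs(neg.t)))
    dt = np.median(np.diff(neg.t)) if len(neg) > 1 else np.inf
    if abs(neg.t[i0]) > tol_frames * dt:
        raise ValueError("no sample within half a frame interval of T = 0")
    r0 = neg.value[i0]
    if abs(r0) <= EPS:
        raise ValueError("-R at T = 0 is below the validity floor")
    meta = dict(neg.meta)
    meta["negR_t0"] = float(r0)
    return RegionTrace(neg.cell_id, neg.t.copy(), neg.value / r0, "R_over_R0", meta)


def peak_response(trace: RegionTrace, search_window: tuple[float, float]) -> dict:
    """Peak trace value over t in ``search_window`` (inclusive).

    For most value kinds this is the window maximum.  For R/R0 traces the
    peak is the sample deviating most from 1 (activation moves the ratio away
    from 1, and which side depends on the sign convention of the stored
    trace); the result then also carries ``percent_change`` =
    (peak - 1) * 100, the sensor's dynamic-range statistic.
    """
    lo, hi = search_window
    sel = (trace.t >= lo) & (trace.t <= hi)
    if not sel.any():
        raise ValueError("search window contains no samples")
    if trace.value_kind == "R_over_R0":
        score = np.where(sel, np.abs(trace.value - 1.0), -np.inf)
    else:
        score = np.where(sel, trace.value, -np.inf)
    i = int(np.argmax(score))
    out = {"peak": float(trace.value[i]), "t_peak": float(trace.t[i])}
    if trace.value_kind == "R_over_R0":
        out["percent_change"] = (out["peak"] - 1.0) * 100.0
    return out


def integrate_response(trace: RegionTrace, window: tuple[float, float] = (5.0, 10.0)) -> float:
    """Trapezoidal integral of a -dR trace over t in ``window`` (minutes),
    in units of -dR x min.  Endpoints falling between samples are linearly
    interpolated; the samples must cover the window."""
    lo, hi = window
    if hi <= lo:
        raise ValueError("window must have positive length")
    if trace.t[0] > lo or trace.t[-1] < hi:
        raise ValueError("trace does not cover the integration window")
    inside = (trace.t > lo) & (trace.t < hi)
    t = np.concatenate([[lo], trace.t[inside], [hi]])
    v = np.concatenate([
        [np.interp(lo, trace.t, trace.value)],
        trace.value[inside],
        [np.interp(hi, trace.t, trace.value)],
    ])
    return float(np.trapezoid(v, t))


def summarize_mean_response(trace: RegionTrace, window: tuple[float, float] = (2.0, 10.0)) -> float:
    """Per-cell scalar for group comparisons: mean trace value over a
    post-drug window (default 2-10 min)."""
    sel = (trace.t >= window[0]) & (trace.t <= window[1])
    if not sel.any():
        raise ValueError("summary window contains no samples")
    return float(trace.value[sel].mean())


@dataclass(frozen=True)
class GroupComparison:
    t_stat: float
    p_value: float
    mean_a: float
    mean_b: float
    n_a: int
    n_b: int
    test: str


def compare_groups(a, b, test: str = "student") -> GroupComparison:
    """Two-sided unpaired t-test on per-cell scalar summaries.

    ``student`` pools the variances (the conventional default); ``welch``
    drops the equal-variance assumption.  No multiplicity correction: each
    comparison is a single pairwise test.  Two zero-variance groups with
    equal means return p = 1 by convention.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    if test not in ("student", "welch"):
        raise ValueError("test must be 'student' or 'welch'")
    if np.var(a) == 0 and np.var(b) == 0 and a.mean() == b.mean():
        return GroupComparison(0.0, 1.0, float(a.mean()), float(b.mean()),
                               a.size, b.size, test)
    res = stats.ttest_ind(a, b, equal_var=(test == "student"))
    return GroupComparison(float(res.statistic), float(res.pvalue),
                           float(a.mean()), float(b.mean()), a.size, b.size, test)


def normalize_dose_response(doses, responses):
    """Rescale raw responses to the 0-100 convention.

    Per-dose means are computed first; the lowest and highest group means
    anchor 0 and 100, so the group means span exactly [0, 100].  Returns
    (normalized_responses, (lo_mean, hi_mean)).
    """
    doses = np.asarray(doses, dtype=float)
    responses = np.asarray(responses, dtype=float)
    if doses.shape != responses.shape:
        raise ValueError("doses and responses must align")
    uniq = np.unique(doses)
    if uniq.size < 3:
        raise ValueError("need >= 3 distinct doses")
    means = np.array([responses[doses == d].mean() for d in uniq])
    lo, hi = means.min(), means.max()
    if hi - lo <= EPS:
        raise ValueError("degenerate dose-response: max group mean equals min")
    return 100.0 * (responses - lo) / (hi - lo), (float(lo), float(hi))


@dataclass
class DoseResponseResult:
    """Hill fit on the 0-100 scale: response = 100 d^h / (EC50^h + d^h)."""

    ec50: float
    hill_slope: float
    r2: float
    bottom: float = 0.0
    top: float = 100.0

    def fitted_curve(self) -> Callable:
        ec50, h = self.ec50, self.hill_slope
        def curve(d):
            d = np.asarray(d, dtype=float)
            return 100.0 * d ** h / (ec50 ** h + d ** h)
        return curve


def _hill(logd, log_ec50, h):
    # response in logarithmic dose; numerically stable logistic form
    return 100.0 / (1.0 + 10.0 ** (h * (log_ec50 - logd)))


def fit_hill(doses, normalized_responses, n_starts: int = 5) -> DoseResponseResult:
    """Least-squares Hill fit with bottom fixed at 0 and top at 100,
    optimizing log10(EC50) and the slope h, multi-started over a log-spaced
    EC50 grid to avoid local minima."""
    doses = np.asarray(doses, dtype=float)
    y = np.asarray(normalized_responses, dtype=float)
    if doses.shape != y.shape:
        raise ValueError("doses and responses must align")
    if np.any(doses <= 0):
        raise ValueError("doses must be positive")
    if np.unique(doses).size < 3:
        raise ValueError("need >= 3 distinct doses")
    logd = np.log10(doses)

    def resid(params):
        return _hill(logd, params[0], params[1]) - y

    best = None
    starts = np.linspace(logd.min(), logd.max(), n_starts)
    for s in starts:
        try:
            sol = optimize.least_squares(
                resid, x0=[s, 1.0],
                bounds=([logd.min() - 3.0, 1e-3], [logd.max() + 3.0, 20.0]),
            )
        except Exception:  # noqa: BLE001
            continue
        if sol.success and (best is None or sol.cost < best.cost):
            best = sol
    if best is None:
        raise RuntimeError("Hill fit failed to converge from all starts")
    ss_res = float(2.0 * best.cost)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return DoseResponseResult(ec50=float(10.0 ** best.x[0]),
                              hill_slope=float(best.x[1]),
                              r2=float(min(max(r2, 0.0), 1.0)))
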