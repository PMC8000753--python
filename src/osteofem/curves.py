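"""Embedding force-distance curve analysis.

Quasi-static press-fit of the spike array into trabecular bone produces
force-distance traces with three characteristic regions: an initial phase in
which spikes penetrate the intertrabecular space and gradually engage the
trabeculae (region I), a linear phase of elastic load transfer from spikes to
trabeculae (region II), and a post-yield phase of trabecular destruction and
densification with irregular force drops (region III).  This module splits a
trace into those regions, averages replicate traces into a mean line with an
SD band, and fits the region-II line by ordinary least squares.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class ForceCurve:
    """A single embedding trace: force (N) on a strictly increasing
    displacement grid (mm)."""

    displacement: np.ndarray
    force: np.ndarray
    replicate_id: int = 0

    def __post_init__(self) -> None:
        d = np.asarray(self.displacement, dtype=float)
        f = np.asarray(self.force, dtype=float)
        if d.shape != f.shape or d.ndim != 1:
            raise ValueError("displacement and force must be equal-length 1-D arrays")
        if not np.all(np.diff(d) > 0):
            raise ValueError("displacement grid must be strictly increasing")
        if not np.all(np.isfinite(f)):
            raise ValueError("forces must be finite")
        object.__setattr__(self, "displacement", d)
        object.__setattr__(self, "force", f)


@dataclass(frozen=True)
class RegionSegmentation:
    """Displacement values splitting the trace into regions I / II / III."""

    boundary_1: float
    boundary_2: float

    def __post_init__(self) -> None:
        if not (0.0 < self.boundary_1 < self.boundary_2):
            raise ValueError("require 0 < boundary_1 < boundary_2")


@dataclass(frozen=True)
class RegionFit:
    """Region-II ordinary-least-squares line: force = a*displacement + b."""

    a: float
    b: float
    r_squared: float


def _rolling_slopes(x: np.ndarray, y: np.ndarray, half: int) -> np.ndarray:
    """Centred local slope over +-`half` samples (least-squares per window)."""
    n = len(x)
    slopes = np.empty(n)
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        xs, ys = x[lo:hi], y[lo:hi]
        slopes[i] = np.polyfit(xs, ys, 1)[0] if len(xs) > 1 else np.nan
    return slopes


def detect_regions(curve: ForceCurve, window: float = 0.2,
                   slope_tol: float = 0.15) -> RegionSegmentation:
    """Locate the linear region II of an embedding trace.

    A coarse pass finds the longest contiguous span whose rolling-window local
    slope stays within ``+-slope_tol`` (relative) of the span's median slope;
    a refinement pass then fits a line to the core of that span and moves each
    boundary to the first sample whose residual from the line exceeds three
    core residual standard deviations (with a small absolute floor, so that
    noiseless breakpoints are caught at the first off-line sample).

    Parameters
    ----------
    window:
        Rolling-slope window width in mm (default 0.2).
    slope_tol:
        Relative slope stability tolerance (default 0.15).
    """
    x, y = curve.displacement, curve.force
    step = np.median(np.diff(x))
    half = max(int(round(window / step / 2)), 1)
    if len(x) < 3 * (2 * half + 1):
        raise ValueError("curve shorter than 3 rolling windows")

    slopes = _rolling_slopes(x, y, half)

    # Coarse pass: longest run of slope-stable samples around the median
    # slope of the middle third (one re-estimation on the found run).
    mid = slice(len(x) // 3, 2 * len(x) // 3)
    med = np.median(slopes[mid])
    best = _longest_true_run(np.abs(slopes - med) <= slope_tol * abs(med))
    if best is not None:
        med = np.median(slopes[best[0]:best[1]])
        best = _longest_true_run(np.abs(slopes - med) <= slope_tol * abs(med))
    if best is None:
        raise ValueError("no slope-stable span found")
    i0, i1 = best

    # Refinement: line fit on the inner 60% of the coarse span, then walk the
    # boundaries out/in to the first sample off that line.
    span = i1 - i0
    core = slice(i0 + int(0.2 * span), i1 - int(0.2 * span))
    a, b = np.polyfit(x[core], y[core], 1)
    resid = y - (a * x + b)
    sd = float(np.std(resid[core]))
    tol = max(3.0 * sd, 1e-9 * max(1.0, float(np.max(np.abs(y)))))
    ok = np.abs(resid) <= tol
    lo = i0
    while lo > 0 and ok[lo - 1]:
        lo -= 1
    while lo < len(x) - 1 and not ok[lo]:
        lo += 1
    hi = i1 - 1
    while hi < len(x) - 1 and ok[hi + 1]:
        hi += 1
    while hi > 0 and not ok[hi]:
        hi -= 1
    if hi - lo < 2:
        raise ValueError("degenerate region II after refinement")

    b1 = float(x[lo]) if lo > 0 else float(x[0] + 0.5 * step)
    b2 = float(x[hi]) if hi < len(x) - 1 else float(x[-1])
    if not b1 < b2:
        b1, b2 = float(x[lo]), float(x[min(hi + 1, len(x) - 1)])
    return RegionSegmentation(boundary_1=b1, boundary_2=b2)


def _longest_true_run(mask: np.ndarray) -> tuple[int, int] | None:
    best, start, n = None, None, len(mask)
    for i in range(n + 1):
        if i < n and mask[i]:
            if start is None:
                start = i
        else:
            if start is not None:
                if best is None or i - start > best[1] - best[0]:
                    best = (start, i)
                start = None
    return best


def mean_curve(curves: list[ForceCurve] | tuple[ForceCurve, ...],
               grid: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pointwise mean line and sample-SD band of replicate traces.

    Each trace is linearly interpolated onto ``grid``; the SD uses the n-1
    (sample) denominator.  The grid must lie within every trace's span.
    """
    if len(curves) < 2:
        raise ValueError("need at least 2 replicate curves")
    grid = np.asarray(grid, dtype=float)
    for c in curves:
        if grid[0] < c.displacement[0] - 1e-12 or grid[-1] > c.displacement[-1] + 1e-12:
            raise ValueError("grid outside the span of a replicate curve")
    stack = np.vstack([np.interp(grid, c.displacement, c.force) for c in curves])
    return stack.mean(axis=0), stack.std(axis=0, ddof=1)


def fit_region2(grid: np.ndarray, mean_force: np.ndarray,
                segmentation: RegionSegmentation) -> RegionFit:
    """OLS fit of the mean line over region II; R^2 = 1 - RSS/TSS."""
    grid = np.asarray(grid, dtype=float)
    mean_force = np.asarray(mean_force, dtype=float)
    sel = (grid >= segmentation.boundary_1) & (grid <= segmentation.boundary_2)
    xs, ys = grid[sel], mean_force[sel]
    if len(xs) < 3:
        raise ValueError("region II contains fewer than 3 grid points")
    if np.ptp(xs) == 0:
        raise ValueError("degenerate constant-displacement input")
    res = stats.linregress(xs, ys)
    tss = float(np.sum((ys - ys.mean()) ** 2))
    if tss == 0.0:
        warnings.warn("zero total sum of squares in region II; reporting R^2 = 0")
        r2 = 0.0
    else:
        rss = float(np.sum((ys - (res.slope * xs + res.intercept)) ** 2))
        r2 = 1.0 - rss / tss
    return RegionFit(a=float(res.slope), b=float(res.intercept), r_squared=r2)
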