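"""Area-under-the-curve and peak-fold statistics for induction time-courses.

After a stimulus (here LPS), immediate-early transcripts rise and fall over
hours; the area under the mean expression curve summarizes total induction
and areas are compared between genes as percent ratios.  AUC is the
composite trapezoid of the mean curve (no baseline subtraction by default),
restricted to a window whose endpoints are linearly interpolated when they
fall between samples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["InductionCurve", "trapezoid_auc", "auc_ratio", "peak_fold_change"]


@dataclass
class InductionCurve:
    """Mean +/- SD induction time-course for one gene.

    ``times`` must be strictly increasing; units (hours or minutes) are
    declared by the caller and carried through unchanged.
    """

    gene_id: str
    times: np.ndarray
    means: np.ndarray
    sds: np.ndarray | None = None
    n: int = 1
    time_unit: str = "h"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.means = np.asarray(self.means, dtype=float)
        if self.sds is not None:
            self.sds = np.asarray(self.sds, dtype=float)
        if len(self.times) != len(self.means):
            raise ValueError("times and means must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.n < 1:
            raise ValueError("n must be >= 1")

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, gene_id: str, time_unit: str = "h") -> "InductionCurve":
        """Build from a long table with columns time, mean, sd, n for one gene."""
        sub = frame[frame["gene_id"] == gene_id].sort_values("time")
        if sub.empty:
            raise ValueError(f"gene {gene_id!r} absent from curve table")
        return cls(
            gene_id=gene_id,
            times=sub["time"].to_numpy(float),
            means=sub["mean"].to_numpy(float),
            sds=sub["sd"].to_numpy(float) if "sd" in sub else None,
            n=int(sub["n"].iloc[0]) if "n" in sub else 1,
            time_unit=time_unit,
        )


def trapezoid_auc(curve: InductionCurve, window: tuple[float, float] | None = None) -> float:
    """Composite trapezoid area of the mean curve over ``window``.

    Window endpoints between samples are interpolated linearly, which makes
    the area exactly additive over adjacent windows.
    """
    t, y = curve.times, curve.means
    if window is None:
        window = (float(t[0]), float(t[-1]))
    lo, hi = window
    if lo < t[0] or hi > t[-1] or lo >= hi:
        raise ValueError(f"window {window} outside observed span [{t[0]}, {t[-1]}]")
    inner = (t > lo) & (t < hi)
    tt = np.concatenate([[lo], t[inner], [hi]])
    yy = np.concatenate([[np.interp(lo, t, y)], y[inner], [np.interp(hi, t, y)]])
    return float(np.trapezoid(yy, tt))


def auc_ratio(
    curve_a: InductionCurve, curve_b: InductionCurve, window: tuple[float, float] | None = None
) -> float:
    """100 * AUC(A) / AUC(B)."""
    denom = trapezoid_auc(curve_b, window)
    if denom == 0:
        raise ValueError("auc_ratio: reference curve has zero area")
    return 100.0 * trapezoid_auc(curve_a, window) / denom


def peak_fold_change(curve: InductionCurve) -> tuple[float, float]:
    """Peak time and fold change of the mean curve versus its t = 0 value.

    Ties pick the earliest peak; a monotone-decreasing curve peaks at t0
    with fold 1.
    """
    if curve.times[0] != 0:
        raise ValueError("peak_fold_change requires a t = 0 sample")
    baseline = curve.means[0]
    if baseline <= 0:
        raise ValueError("peak_fold_change: zero or negative baseline")
    i = int(np.argmax(curve.means))
    return float(curve.times[i]), float(curve.means[i] / baseline)
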