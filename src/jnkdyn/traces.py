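"""Quantification of single-cell kinase-translocation-reporter (KTR) traces.

A KTR trace is the cytoplasmic-to-nuclear (C/N) fluorescence ratio of a
JNK activity reporter, sampled at a fixed frame interval (10 min by
default) with a few pre-treatment frames establishing a per-cell baseline.
Activity metrics follow the standard imaging workflow: the baseline is the
mean of the frames immediately preceding treatment, pulses are local
maxima exceeding 50% above baseline (a height threshold chosen to reject
noise), and the duration of activity is the time spent above that same
threshold, optionally restricted to an early window such as the first 3 h.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

__all__ = [
    "CellTrace",
    "PulseSummary",
    "compute_baseline",
    "detect_pulses",
    "activity_duration",
    "activity_auc",
    "summarize_population",
]

DEFAULT_FRAME_INTERVAL = 1.0 / 6.0  # h (10 min)
DEFAULT_BASELINE_FRAMES = 4


@dataclass
class CellTrace:
    """Single-cell C/N ratio series on a uniform frame grid.

    ``treatment_time`` (h) splits the trace into pre-treatment baseline
    frames and the post-treatment response; at least
    ``n_baseline_frames`` frames must precede it.
    """

    cell_id: str
    frame_times: np.ndarray
    cn_ratio: np.ndarray
    n_baseline_frames: int = DEFAULT_BASELINE_FRAMES
    treatment_time: float = 0.0

    def __post_init__(self) -> None:
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        self.cn_ratio = np.asarray(self.cn_ratio, dtype=float)
        if self.frame_times.shape != self.cn_ratio.shape:
            raise ValueError("frame_times and cn_ratio must have equal length")
        steps = np.diff(self.frame_times)
        if steps.size == 0 or np.any(steps <= 0):
            raise ValueError("frame_times must be strictly increasing")
        if np.max(np.abs(steps - steps[0])) > 1e-6:
            raise ValueError("frame spacing must be uniform (within 1e-6 h)")
        if np.any(self.cn_ratio <= 0):
            raise ValueError("C/N ratios must be positive")
        n_pre = int(np.sum(self.frame_times < self.treatment_time))
        if n_pre < self.n_baseline_frames:
            raise ValueError(
                f"cell {self.cell_id}: {self.n_baseline_frames} pre-treatment frames "
                f"required for the baseline, found {n_pre}"
            )

    @property
    def frame_interval(self) -> float:
        return float(self.frame_times[1] - self.frame_times[0])

    @property
    def post_mask(self) -> np.ndarray:
        return self.frame_times >= self.treatment_time


@dataclass
class PulseSummary:
    """Per-cell pulse and duration metrics derived from one trace."""

    cell_id: str
    baseline: float
    threshold: float
    n_pulses: int
    peak_times: tuple[float, ...]
    total_duration: float
    windowed_duration: float
    auc: float = 0.0

    def __post_init__(self) -> None:
        if self.n_pulses != len(self.peak_times):
            raise ValueError("n_pulses must equal len(peak_times)")


def compute_baseline(trace: CellTrace) -> float:
    """Mean C/N over the last ``n_baseline_frames`` pre-treatment frames."""
    pre = np.flatnonzero(trace.frame_times < trace.treatment_time)
    return float(np.mean(trace.cn_ratio[pre[-trace.n_baseline_frames :]]))


def detect_pulses(
    trace: CellTrace,
    baseline: float | None = None,
    threshold_frac: float = 0.5,
    min_distance_frames: int | None = None,
):
    """Count pulses: post-treatment local maxima at least 50% above baseline.

    A pulse is a strict local maximum of the post-treatment series whose
    value is ≥ (1 + threshold_frac)·baseline; plateaus of equal values
    count once at their leftmost frame, and the series endpoints are never
    peaks.  ``min_distance_frames`` optionally enforces a minimum inter-peak
    spacing (off by default — the height rule is the only criterion).

    Returns ``(n_pulses, peak_times)``.
    """
    if baseline is None:
        baseline = compute_baseline(trace)
    if baseline <= 0:
        raise ValueError("baseline must be positive")
    threshold = (1.0 + threshold_frac) * baseline
    post = trace.post_mask
    x = trace.cn_ratio[post]
    t = trace.frame_times[post]
    idx, props = find_peaks(
        x, height=threshold, plateau_size=1, distance=min_distance_frames
    )
    left = props["left_edges"]  # plateau collapse: leftmost frame
    return int(left.size), tuple(float(v) for v in t[left])


def activity_duration(
    trace: CellTrace,
    baseline: float | None = None,
    threshold_frac: float = 0.5,
    window: tuple[float, float] | None = None,
) -> float:
    """Time (h) spent at or above the activity threshold.

    Counts post-treatment frames with C/N ≥ (1 + threshold_frac)·baseline,
    optionally restricted to ``window`` = (start, end) in hours, times the
    frame interval.
    """
    if baseline is None:
        baseline = compute_baseline(trace)
    threshold = (1.0 + threshold_frac) * baseline
    mask = trace.post_mask.copy()
    if window is not None:
        lo, hi = window
        if lo < trace.frame_times[0] - 1e-9 or hi > trace.frame_times[-1] + 1e-9:
            raise ValueError(
                f"window ({lo}, {hi}) outside trace span "
                f"[{trace.frame_times[0]}, {trace.frame_times[-1]}]"
            )
        mask &= (trace.frame_times >= lo) & (trace.frame_times < hi)
    n_above = int(np.sum(trace.cn_ratio[mask] >= threshold))
    return n_above * trace.frame_interval


def activity_auc(
    trace: CellTrace,
    baseline: float | None = None,
    threshold_frac: float = 0.5,
    window: tuple[float, float] | None = None,
) -> float:
    """Area above the activity threshold (C/N·h), a secondary metric."""
    if baseline is None:
        baseline = compute_baseline(trace)
    threshold = (1.0 + threshold_frac) * baseline
    mask = trace.post_mask.copy()
    if window is not None:
        lo, hi = window
        mask &= (trace.frame_times >= lo) & (trace.frame_times < hi)
    excess = np.clip(trace.cn_ratio[mask] - threshold, 0.0, None)
    return float(excess.sum() * trace.frame_interval)


def summarize_trace(
    trace: CellTrace,
    threshold_frac: float = 0.5,
    window: tuple[float, float] = (0.0, 3.0),
    baseline: float | None = None,
) -> PulseSummary:
    """All per-cell metrics for one trace (per-cell baseline by default)."""
    if baseline is None:
        baseline = compute_baseline(trace)
    n, peaks = detect_pulses(trace, baseline, threshold_frac)
    return PulseSummary(
        cell_id=trace.cell_id,
        baseline=baseline,
        threshold=(1.0 + threshold_frac) * baseline,
        n_pulses=n,
        peak_times=peaks,
        total_duration=activity_duration(trace, baseline, threshold_frac),
        windowed_duration=activity_duration(trace, baseline, threshold_frac, window),
        auc=activity_auc(trace, baseline, threshold_frac),
    )


def summarize_population(
    traces: list[CellTrace],
    threshold_frac: float = 0.5,
    window: tuple[float, float] = (0.0, 3.0),
    shared_baseline: bool = False,
):
    """Population summary: frame-aligned mean ± SD plus a per-cell table.

    All traces must share the frame grid.  With ``shared_baseline`` the
    condition-wide mean baseline is applied to every cell instead of the
    per-cell baseline.

    Returns ``(per_frame, per_cell)`` DataFrames.
    """
    if not traces:
        raise ValueError("need at least one trace")
    grid = traces[0].frame_times
    for tr in traces[1:]:
        if tr.frame_times.shape != grid.shape or np.max(np.abs(tr.frame_times - grid)) > 1e-9:
            raise ValueError(f"cell {tr.cell_id}: frame grid differs from the first trace")
    values = np.vstack([tr.cn_ratio for tr in traces])
    per_frame = pd.DataFrame(
        {
            "time_h": grid,
            "mean_cn": values.mean(axis=0),
            "sd_cn": values.std(axis=0, ddof=0),
        }
    )
    base = None
    if shared_baseline:
        base = float(np.mean([compute_baseline(tr) for tr in traces]))
    rows = [
        summarize_trace(tr, threshold_frac, window, baseline=base).__dict__
        for tr in traces
    ]
    per_cell = pd.DataFrame(rows)
    per_cell["peak_times"] = per_cell["peak_times"].map(
        lambda p: ";".join(f"{v:.6g}" for v in p)
    )
    return per_frame, per_cell
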