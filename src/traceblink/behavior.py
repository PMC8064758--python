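"""Conditioned-response scoring from eye-area traces.

The eye trace is the segmented eye area per frame normalized by the
session-average area (≈1 when open).  A session-wide "standard eye area"
line is fit by least squares to the frames whose area lies in the central
95% band (2.5th-97.5th percentile), so blinks and closures do not bias
the fit.  The conditioned-response threshold is 2% below that line, as a
fraction of the line itself, which makes classification invariant to
uniform rescaling of the trace.  A trial is a conditioned response (CR)
when the area falls below threshold within the half-open tone-puff
window [tone onset, puff onset).  Spontaneous closures are counted the
same way in 600 ms sliding windows over the non-stimulus periods.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .synthetic import TrialSchedule

__all__ = ["EyeTrace", "CRThreshold", "TrialOutcome", "area_from_mask_stack",
           "fit_cr_threshold", "classify_cr", "cr_percentage",
           "spontaneous_closure_rate"]

log = logging.getLogger(__name__)


@dataclass
class EyeTrace:
    area: np.ndarray  # per-frame eye area / session mean area
    frame_rate: float = 20.0

    def __post_init__(self) -> None:
        self.area = np.asarray(self.area, dtype=float)
        if self.area.ndim != 1 or len(self.area) == 0:
            raise ValueError("eye trace must be a non-empty 1-D array")

    @classmethod
    def from_raw_area(cls, raw: np.ndarray, frame_rate: float = 20.0) -> "EyeTrace":
        raw = np.asarray(raw, dtype=float)
        return cls(raw / raw.mean(), frame_rate)


@dataclass(frozen=True)
class CRThreshold:
    """Standard-eye-area line and the relative CR deviation below it."""

    slope: float  # per frame
    intercept: float
    deviation: float = 0.02  # fraction of the standard area

    def line(self, frames: np.ndarray) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(frames, dtype=float)

    def threshold(self, frames: np.ndarray) -> np.ndarray:
        return self.line(frames) * (1.0 - self.deviation)


@dataclass(frozen=True)
class TrialOutcome:
    trial_id: int
    cr: bool
    min_area_in_window: float


def area_from_mask_stack(path) -> np.ndarray:
    """Reduce a binary eye-mask TIFF stack to a normalized area trace:
    foreground pixels per frame divided by the stack-mean area."""
    import tifffile

    stack = tifffile.imread(path)
    if stack.ndim == 2:
        stack = stack[None]
    counts = (stack > 0).reshape(stack.shape[0], -1).sum(axis=1).astype(float)
    return counts / counts.mean()


def fit_cr_threshold(eye: EyeTrace, deviation: float = 0.02,
                     central_band: tuple[float, float] = (2.5, 97.5)) -> CRThreshold:
    """Least-squares line through the central 95% of the open-eye frames.

    The fit is two-pass: an initial line through the value-percentile
    band, then a refit keeping the frames whose residuals lie within the
    central 95% of the residual noise distribution (|r - median| within
    1.96 robust SDs).  The second pass is what makes the standard-area
    line insensitive to eye closures, which are deep, one-sided, and can
    occupy well over the 2.5% a plain percentile trim could remove.

    A constant trace degenerates to a horizontal line at that constant.
    """
    a = eye.area
    frames_all = np.arange(len(a), dtype=float)
    lo, hi = np.percentile(a, central_band)
    keep = (a >= lo) & (a <= hi)
    if np.ptp(a[keep]) == 0 or keep.sum() < 2:
        return CRThreshold(slope=0.0, intercept=float(a[keep].mean()
                                                      if keep.any() else a.mean()),
                           deviation=deviation)
    slope, intercept = np.polyfit(frames_all[keep], a[keep], 1)
    resid = a - (intercept + slope * frames_all)
    med = np.median(resid)
    mad_sd = 1.4826 * np.median(np.abs(resid - med))
    if mad_sd > 0:
        keep = np.abs(resid - med) <= 1.96 * mad_sd
        if keep.sum() >= 2 and np.ptp(frames_all[keep]) > 0:
            slope, intercept = np.polyfit(frames_all[keep], a[keep], 1)
    return CRThreshold(slope=float(slope), intercept=float(intercept),
                       deviation=deviation)


def classify_cr(eye: EyeTrace, threshold: CRThreshold,
                schedule: TrialSchedule) -> list[TrialOutcome]:
    """Per-trial CR flags: area below threshold anywhere in the half-open
    window [tone onset, puff onset).  Trials whose window extends past the
    trace are skipped with a log entry."""
    a = eye.area
    outcomes = []
    for trial in range(schedule.n_trials):
        t0, t1 = schedule.tone_puff_window(trial)
        if t1 > len(a):
            log.warning("trial %d window [%d, %d) outside eye trace of %d "
                        "frames; skipped", trial, t0, t1, len(a))
            continue
        frames = np.arange(t0, t1)
        below = a[t0:t1] < threshold.threshold(frames)
        outcomes.append(TrialOutcome(trial_id=trial, cr=bool(below.any()),
                                     min_area_in_window=float(a[t0:t1].min())))
    return outcomes


def cr_percentage(outcomes: list[TrialOutcome]) -> float:
    if not outcomes:
        raise ValueError("no scored trials")
    return 100.0 * sum(o.cr for o in outcomes) / len(outcomes)


def spontaneous_closure_rate(eye: EyeTrace, mask: np.ndarray,
                             threshold: CRThreshold,
                             window_frames: int = 12) -> float:
    """Fraction of 600 ms (12-frame) sliding windows in the non-stimulus
    periods that contain a below-threshold frame (step one frame; windows
    must lie entirely within a contiguous masked stretch)."""
    a = eye.area
    mask = np.asarray(mask, dtype=bool)
    if len(mask) != len(a):
        raise ValueError("mask length must match the eye trace")
    frames = np.arange(len(a))
    below = a < threshold.threshold(frames)
    # windows fully inside the mask
    cm = np.concatenate([[0], np.cumsum(mask)])
    in_mask = cm[window_frames:] - cm[:-window_frames] == window_frames
    cb = np.concatenate([[0], np.cumsum(below)])
    has_closure = cb[window_frames:] - cb[:-window_frames] > 0
    n_windows = int(in_mask.sum())
    if n_windows == 0:
        raise ValueError("non-stimulus mask shorter than one window")
    return float((in_mask & has_closure).sum() / n_windows)
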