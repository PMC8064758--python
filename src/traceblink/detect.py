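"""Calcium event detection from normalized fluorescence traces.

An event onset coincides with a rise in low-frequency spectral power, so
detection proceeds in three stages:

1. A sliding multitaper spectrogram (1 s window, 50 ms step, NW = 2 with
   3 DPSS tapers) is computed for each trace and the power at frequencies
   in (0, 2] Hz is averaged, giving one low-frequency power value per
   window position.
2. The first difference of that power series (``power_diff``) is screened
   for outliers more than three scaled median absolute deviations from
   its median; each run of consecutive outliers is collapsed to its first
   member with positive ``power_diff``, which marks a candidate onset.
3. Candidates are gated by amplitude: the event peak is the first local
   maximum after the onset (prominence above the trace's robust noise
   SD), the onset is refined backward from the peak to the first point
   of the rise, and the event is kept only if peak minus onset is at
   least seven standard deviations of the trace over the 10 s preceding
   the onset.  The gate's SD defaults to a first-difference noise
   estimate (scaled MAD of the differenced window divided by sqrt(2)),
   which measures the noise floor even when slow calcium transients fall
   inside the preceding window; a value-based robust SD and the plain
   standard deviation are available as options.

Rising phases (onset through peak) of the surviving events are set to 1
in the binarized trace used by all downstream ensemble statistics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.fft import rfft, rfftfreq
from scipy.signal import find_peaks
from scipy.signal.windows import dpss

__all__ = ["SpectrogramParams", "CalciumEvent", "EventTrain", "PowerSeries",
           "lowfreq_power_series", "detect_onsets", "amplitude_filter",
           "detect_events", "event_rate", "MAD_SCALE"]

log = logging.getLogger(__name__)

#: consistency constant making the MAD an unbiased SD estimate for Gaussians
MAD_SCALE = 1.4826


@dataclass(frozen=True)
class SpectrogramParams:
    """Multitaper spectrogram settings (time-bandwidth 2, 3 tapers,
    1 s window sliding in 50 ms steps, power averaged below 2 Hz)."""

    time_bandwidth: float = 2.0
    n_tapers: int = 3
    window_s: float = 1.0
    step_s: float = 0.05
    max_freq: float = 2.0

    def __post_init__(self) -> None:
        if self.n_tapers > 2 * self.time_bandwidth - 1:
            raise ValueError("n_tapers must be <= 2*time_bandwidth - 1")
        if self.step_s > self.window_s:
            raise ValueError("step must not exceed the window length")


@dataclass(frozen=True)
class CalciumEvent:
    onset_frame: int
    peak_frame: int
    amplitude: float  # signal difference between the peak and the onset

    def __post_init__(self) -> None:
        if self.peak_frame <= self.onset_frame:
            raise ValueError("peak must follow onset")
        if self.amplitude <= 0:
            raise ValueError("amplitude must be positive")


@dataclass
class PowerSeries:
    values: np.ndarray  # mean low-frequency power, one per window position
    window_starts: np.ndarray  # frame index of each window's first sample
    window_frames: int
    step_frames: int


@dataclass
class EventTrain:
    events: list[CalciumEvent]
    binary: np.ndarray  # uint8, ones on rising phases [onset, peak]
    power_diff: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def onsets(self) -> np.ndarray:
        return np.array([e.onset_frame for e in self.events], dtype=int)


def lowfreq_power_series(
    trace: np.ndarray, frame_rate: float,
    params: SpectrogramParams = SpectrogramParams(),
) -> PowerSeries:
    """Mean multitaper power in (0, max_freq] Hz over sliding windows.

    Each window is demeaned, tapered with the DPSS family, and its power
    spectrum averaged across tapers and across the in-band frequency bins
    (DC excluded).
    """
    x = np.asarray(trace, dtype=float)
    win = int(round(params.window_s * frame_rate))
    step = max(int(round(params.step_s * frame_rate)), 1)
    if len(x) < win:
        raise ValueError(f"trace of {len(x)} frames shorter than the "
                         f"{win}-frame spectrogram window")
    segs = sliding_window_view(x, win)[::step]  # (n_win, win)
    segs = segs - segs.mean(axis=1, keepdims=True)
    tapers = dpss(win, params.time_bandwidth, Kmax=params.n_tapers)  # (K, win)
    spec = rfft(segs[None, :, :] * tapers[:, None, :], axis=-1)
    power = (spec.real**2 + spec.imag**2).mean(axis=0)  # (n_win, n_freq)
    freqs = rfftfreq(win, d=1.0 / frame_rate)
    band = (freqs > 0) & (freqs <= params.max_freq)
    if not band.any():
        raise ValueError("no frequency bins below max_freq; window too short")
    starts = np.arange(0, len(x) - win + 1, step)
    return PowerSeries(values=power[:, band].mean(axis=1),
                       window_starts=starts, window_frames=win,
                       step_frames=step)


def detect_onsets(
    power: PowerSeries, n_frames: int,
    n_mad: float = 3.0, scaled_mad: bool = True, onset_ref: str = "end",
) -> tuple[np.ndarray, np.ndarray]:
    """Candidate onset frames from outliers of the power first difference.

    ``power_diff[i]`` is the change from window i to window i+1; outliers
    beyond ``n_mad`` (scaled) MADs from the global median are grouped
    into consecutive runs, and each run contributes the first member with
    positive change.  The onset frame is taken at the start, center, or
    end of that window (``onset_ref``); the end is the default because
    the power first jumps when the event enters the window's trailing
    edge, placing the window end at the true onset.

    Returns (onset_frames, power_diff).
    """
    pd_ = np.diff(power.values)
    if len(pd_) == 0:
        return np.empty(0, dtype=int), pd_
    med = np.median(pd_)
    mad = np.median(np.abs(pd_ - med))
    scale = MAD_SCALE if scaled_mad else 1.0
    thresh = n_mad * scale * mad
    # a noiseless trace has MAD 0; any deviation from the median is then
    # an outlier, which keeps isolated transients detectable
    outlier = np.abs(pd_ - med) > thresh
    idx = np.flatnonzero(outlier)
    onsets = []
    if len(idx):
        run_breaks = np.flatnonzero(np.diff(idx) > 1) + 1
        for run in np.split(idx, run_breaks):
            # first outlier of each positive stretch: a run that spans two
            # overlapping transients (rise, fall, rise again without the
            # outliers ever pausing) contributes one onset per rise
            pos = pd_[run] > 0
            starts = pos & ~np.concatenate([[False], pos[:-1]])
            onsets.extend(run[starts])
    offset = {"start": 0, "center": power.window_frames // 2,
              "end": power.window_frames - 1}[onset_ref]
    frames = np.array(
        [power.window_starts[i + 1] + offset for i in onsets], dtype=int)
    frames = np.unique(np.clip(frames, 0, n_frames - 1))
    return frames, pd_


def _robust_sd(x: np.ndarray) -> float:
    return MAD_SCALE * float(np.median(np.abs(x - np.median(x))))


def _noise_sd(x: np.ndarray) -> float:
    """Noise SD from robust first differences; insensitive to the slow
    calcium transients themselves (their frame-to-frame slope is well
    below the noise), so it estimates the noise floor even in windows
    that contain events."""
    d = np.diff(x)
    if len(d) == 0:
        return 0.0
    return _robust_sd(d) / np.sqrt(2.0)


_GATE_SD = {"noise_diff": _noise_sd, "robust": _robust_sd,
            "plain": lambda x: float(np.std(x))}


def _refine_onset(x: np.ndarray, candidate: int, peak: int,
                  sigma: float, lookback: int) -> int:
    """Walk back from the peak to the first point of the rise.

    The spectrogram places a candidate within a frame or two of the true
    onset, but by then the trace has already begun to rise, which would
    undermeasure peak-minus-onset amplitude.  The onset is moved to the
    last frame at or below a level a small fraction of the way up the
    transient (at least two noise SDs above the local pre-event median).
    """
    lo = max(0, min(candidate, peak) - lookback)
    pre_med = float(np.median(x[lo:candidate + 1])) if candidate > lo \
        else float(x[lo])
    level = pre_med + max(0.2 * (x[peak] - pre_med), 2.0 * sigma)
    for m in range(peak - 1, lo - 1, -1):
        if x[m] <= level:
            return m
    return int(min(candidate, peak - 1))


def amplitude_filter(
    candidates: np.ndarray, trace: np.ndarray, frame_rate: float,
    n_sd: float = 7.0, sd_window_s: float = 10.0, min_sd_window_s: float = 1.0,
    sd_estimator: str = "noise_diff",
) -> EventTrain:
    """Keep candidates whose peak-minus-onset amplitude reaches ``n_sd``
    standard deviations of the trace over the ``sd_window_s`` seconds
    preceding the onset.

    The peak is the first local maximum after the candidate with
    prominence above the trace's robust (MAD-based) noise SD; candidates
    sharing a peak are merged into one event, and the onset is refined
    backward from the peak to the first point of the rise.
    ``sd_estimator`` selects the gate's SD over the preceding window:
    ``"noise_diff"`` (default) estimates the noise floor from robust
    first differences and so is unaffected by calcium transients inside
    the window; ``"robust"`` is a scaled-MAD SD of the values; ``"plain"``
    is the ordinary standard deviation.  Onsets too close to the start of
    the recording fall back to the first ``min_sd_window_s`` seconds of
    the trace for the SD estimate (logged).
    """
    if sd_estimator not in _GATE_SD:
        raise ValueError(f"sd_estimator must be one of {sorted(_GATE_SD)}")
    x = np.asarray(trace, dtype=float)
    n = len(x)
    sigma = _robust_sd(x)
    peaks, _ = find_peaks(x, prominence=max(sigma, np.finfo(float).tiny))
    sd_win = int(round(sd_window_s * frame_rate))
    min_win = int(round(min_sd_window_s * frame_rate))
    lookback = int(round(frame_rate))  # one spectrogram window
    events: list[CalciumEvent] = []
    binary = np.zeros(n, dtype=np.uint8)
    used_peaks: set[int] = set()
    for cand in np.sort(np.asarray(candidates, dtype=int)):
        nxt = peaks[peaks > cand]
        if len(nxt) == 0:
            continue
        peak = int(nxt[0])
        if peak in used_peaks:
            continue  # a later candidate of the same transient
        onset = _refine_onset(x, int(cand), peak, sigma, lookback)
        amplitude = x[peak] - x[onset]
        if amplitude <= 0:
            continue
        pre = x[max(0, onset - sd_win):onset]
        if len(pre) < min_win:
            log.warning("onset at frame %d has only %d preceding frames; "
                        "using the first %d frames for the SD gate",
                        onset, len(pre), min_win)
            pre = x[:min_win]
        gate_sd = _GATE_SD[sd_estimator](pre)
        if amplitude < n_sd * gate_sd:
            continue
        used_peaks.add(peak)
        events.append(CalciumEvent(int(onset), peak, float(amplitude)))
        binary[onset:peak + 1] = 1
    return EventTrain(events=events, binary=binary)


def detect_events(
    trace: np.ndarray, frame_rate: float,
    params: SpectrogramParams = SpectrogramParams(),
    n_mad: float = 3.0, scaled_mad: bool = True, onset_ref: str = "end",
    n_sd: float = 7.0, sd_window_s: float = 10.0, sd_estimator: str = "noise_diff",
) -> EventTrain:
    """Full detection chain for one baseline-normalized trace."""
    power = lowfreq_power_series(trace, frame_rate, params)
    candidates, pd_ = detect_onsets(power, len(trace), n_mad=n_mad,
                                    scaled_mad=scaled_mad, onset_ref=onset_ref)
    train = amplitude_filter(candidates, trace, frame_rate, n_sd=n_sd,
                             sd_window_s=sd_window_s, sd_estimator=sd_estimator)
    train.power_diff = pd_
    return train


def event_rate(train: EventTrain, mask: np.ndarray, frame_rate: float) -> float:
    """Event onsets per minute restricted to the masked (non-stimulus) frames."""
    mask = np.asarray(mask, dtype=bool)
    masked_minutes = mask.sum() / frame_rate / 60.0
    if masked_minutes == 0:
        raise ValueError("empty non-stimulus mask; rate undefined")
    onsets = train.onsets
    in_mask = mask[onsets].sum() if len(onsets) else 0
    return float(in_mask / masked_minutes)
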