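"""Seeded synthetic trace-conditioning sessions.

Generates everything the downstream analysis consumes — trial schedules,
ground-truth calcium event trains, rendered fluorescence traces, eye-area
traces with conditioned and spontaneous closures, and ROI geometry — with
the statistical structure of a wide-field CA1 recording during trace
eye-blink conditioning: 20 Hz sampling, 350 ms tone / 250 ms trace /
100 ms puff trials at 35 +/- 5 s inter-trial intervals, sparse calcium
events (~1.7/min at rest), and tone-locked conditioned (CO) and
extinction (EX) sub-populations with controllable overlap.

Randomness is organised around a single master seed that fans out into
independent per-purpose and per-cell substreams, so enlarging the
population does not perturb the cells already generated.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SimConfig",
    "TrialSchedule",
    "GroundTruth",
    "generate_trial_schedule",
    "generate_experiment_schedule",
    "assign_populations",
    "generate_event_trains",
    "calcium_kernel",
    "render_fluorescence",
    "truth_binary",
    "generate_eye_trace",
    "generate_roi_centroids",
    "simulate_session",
    "write_session",
]

# durations of the within-trial epochs, in seconds
TONE_S = 0.35
TRACE_S = 0.25
TONE_PUFF_S = 0.60  # tone onset -> puff onset
RESPONSE_S = 1.0  # post-tone response window
PRE_EXCLUDE_S = 2.0  # trial period starts 2 s before the tone ...
POST_EXCLUDE_S = 8.0  # ... and ends 8 s after it


@dataclass(frozen=True)
class SimConfig:
    """Generator parameters; defaults reproduce the recording conditions.

    Rates are per minute, durations in seconds, geometry in pixels.
    ``noise_sd`` is the white-noise standard deviation expressed as a
    fraction of the unit event amplitude; its default (0.1, peak SNR 10)
    keeps single events above the detector's 7-SD amplitude gate, as is
    the case for somatic GCaMP6f transients in wide-field recordings.
    """

    n_cells: int = 200
    n_trials: int = 20
    frame_rate: float = 20.0
    iti_mean: float = 35.0
    iti_jitter: float = 5.0
    basal_rate: float = 1.7
    resp_fraction_co: float = 0.15
    resp_fraction_ex: float = 0.11
    overlap_jaccard: float = 0.10
    resp_prob_co: float = 0.13
    resp_prob_ex: float = 0.07
    kernel_rise: float = 0.1
    kernel_decay: float = 0.6
    noise_sd: float = 0.1
    fov_px: int = 1024
    px_um: float = 1.312
    cr_prob: float = 0.65
    spont_closure_rate: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("resp_fraction_co", "resp_fraction_ex", "overlap_jaccard",
                     "resp_prob_co", "resp_prob_ex", "cr_prob",
                     "spont_closure_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if self.iti_jitter >= self.iti_mean:
            raise ValueError("iti_jitter must be smaller than iti_mean")
        if self.basal_rate < 0 or self.noise_sd < 0:
            raise ValueError("rates and noise must be non-negative")

    def replace(self, **kwargs) -> "SimConfig":
        return replace(self, **kwargs)


@dataclass
class TrialSchedule:
    """Tone/puff onset frames and per-trial block labels for one session."""

    tone_onsets: np.ndarray  # frame index of each tone onset
    puff_onsets: np.ndarray  # frame index of each puff onset (NaN-free; -1 = no puff)
    frame_rate: float
    n_frames: int
    blocks: np.ndarray  # per-trial string label, e.g. "cond" / "ext"

    @property
    def n_trials(self) -> int:
        return len(self.tone_onsets)

    @property
    def tone_puff_frames(self) -> int:
        """Length of the tone-puff window: 600 ms, 12 frames at 20 Hz."""
        return int(round(TONE_PUFF_S * self.frame_rate))

    @property
    def response_frames(self) -> int:
        """Length of the post-tone response window: 1 s, 20 frames at 20 Hz."""
        return int(round(RESPONSE_S * self.frame_rate))

    def response_window(self, trial: int) -> tuple[int, int]:
        """Half-open frame window [tone, tone + 1 s) for one trial."""
        t = int(self.tone_onsets[trial])
        return t, t + self.response_frames

    def tone_puff_window(self, trial: int) -> tuple[int, int]:
        t = int(self.tone_onsets[trial])
        return t, t + self.tone_puff_frames

    def trials_in_block(self, block: str) -> np.ndarray:
        return np.flatnonzero(self.blocks == block)

    def subset(self, trials: Sequence[int]) -> "TrialSchedule":
        trials = np.asarray(trials, dtype=int)
        puffs = self.puff_onsets[trials] if len(self.puff_onsets) == self.n_trials \
            else self.puff_onsets
        return TrialSchedule(self.tone_onsets[trials], puffs, self.frame_rate,
                             self.n_frames, self.blocks[trials])


@dataclass
class GroundTruth:
    """Latent state of a simulated session, for validation of the analysis."""

    co_cells: set[int] = field(default_factory=set)
    ex_cells: set[int] = field(default_factory=set)
    event_onsets_true: list[np.ndarray] = field(default_factory=list)
    cr_trials_true: set[int] = field(default_factory=set)
    centroids: np.ndarray | None = None  # (n_cells, 2) pixels
    roi_radii: np.ndarray | None = None  # (n_cells,) pixels


def _stream(seed: int, *key: int) -> np.random.Generator:
    """Independent substream of the master seed keyed by small integers."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=tuple(key)))


# substream purpose keys
_K_SCHEDULE, _K_POP, _K_EVENTS, _K_RENDER, _K_EYE, _K_ROI, _K_CR = range(7)


def generate_trial_schedule(
    config: SimConfig,
    with_puff: bool = True,
    n_trials: int | None = None,
    duration_s: float | None = None,
    start_s: float | None = None,
    block: str = "cond",
    rng: np.random.Generator | None = None,
) -> TrialSchedule:
    """Draw tone onsets with inter-trial intervals uniform on iti_mean ± jitter.

    The puff onset, when present, is 600 ms (tone + trace interval) after
    each tone onset.  The session extends one mean ITI before the first
    and after the last tone unless ``duration_s`` is given, in which case
    the schedule must fit or a ``ValueError`` is raised.
    """
    fr = config.frame_rate
    n = config.n_trials if n_trials is None else int(n_trials)
    if rng is None:
        rng = _stream(config.seed, _K_SCHEDULE)
    lead = config.iti_mean if start_s is None else float(start_s)
    gaps = rng.uniform(config.iti_mean - config.iti_jitter,
                       config.iti_mean + config.iti_jitter, size=max(n - 1, 0))
    tone_s = lead + np.concatenate([[0.0], np.cumsum(gaps)])
    end_s = tone_s[-1] + config.iti_mean if n else lead
    if duration_s is not None:
        if end_s > duration_s:
            raise ValueError(
                f"session of {duration_s:.0f} s too short for {n} trials at "
                f"ITI {config.iti_mean}±{config.iti_jitter} s "
                f"(needs ≥ {end_s:.0f} s)")
        end_s = duration_s
    tones = np.round(tone_s * fr).astype(int)
    puffs = tones + int(round(TONE_PUFF_S * fr)) if with_puff \
        else np.empty(0, dtype=int)
    return TrialSchedule(
        tone_onsets=tones,
        puff_onsets=puffs,
        frame_rate=fr,
        n_frames=int(round(end_s * fr)),
        blocks=np.array([block] * n, dtype=object),
    )


def generate_experiment_schedule(
    config: SimConfig,
    blocks: Sequence[tuple[str, int, bool]] = (("cond", 20, True), ("ext", 20, False)),
) -> TrialSchedule:
    """Concatenate trial blocks (label, n_trials, with_puff) into one session.

    The default emulates the final imaging day: a conditioning block of
    CS-US trials followed immediately by CS-only extinction trials.
    """
    rng = _stream(config.seed, _K_SCHEDULE)
    tone_list, puff_list, label_list = [], [], []
    offset = 0
    for label, n, with_puff in blocks:
        sched = generate_trial_schedule(config, with_puff=with_puff,
                                        n_trials=n, block=label, rng=rng)
        tone_list.append(sched.tone_onsets + offset)
        if with_puff:
            puff_list.append(sched.puff_onsets + offset)
        label_list.extend([label] * n)
        offset += sched.n_frames
    return TrialSchedule(
        tone_onsets=np.concatenate(tone_list),
        puff_onsets=(np.concatenate(puff_list) if puff_list
                     else np.empty(0, dtype=int)),
        frame_rate=config.frame_rate,
        n_frames=offset,
        blocks=np.array(label_list, dtype=object),
    )


def assign_populations(config: SimConfig) -> GroundTruth:
    """Draw CO and EX cell identities with the configured Jaccard overlap.

    The intersection size c solves J = c / (a + b - c) for the configured
    set sizes a = round(n·f_co), b = round(n·f_ex).
    """
    rng = _stream(config.seed, _K_POP)
    n = config.n_cells
    a = int(round(n * config.resp_fraction_co))
    b = int(round(n * config.resp_fraction_ex))
    j = config.overlap_jaccard
    c = int(round(j * (a + b) / (1.0 + j)))
    c = min(c, a, b)
    if a + b - c > n:
        raise ValueError("responsive fractions exceed the population")
    cells = rng.permutation(n)
    common = cells[:c]
    co_only = cells[c:a]
    ex_only = cells[a:a + b - c]
    return GroundTruth(
        co_cells=set(int(i) for i in np.concatenate([common, co_only])),
        ex_cells=set(int(i) for i in np.concatenate([common, ex_only])),
    )


def _active_blocks(schedule: TrialSchedule, population: str) -> np.ndarray:
    """Trials on which a population is tone-locked: CO on CS-US blocks,
    EX on CS-only (extinction) blocks."""
    has_puff = np.zeros(schedule.n_trials, dtype=bool)
    if len(schedule.puff_onsets) == schedule.n_trials:
        has_puff[:] = True
    elif len(schedule.puff_onsets):
        # blocks built by generate_experiment_schedule: puffed trials are
        # exactly those whose tone has a matching puff 600 ms later
        puffed = set(schedule.puff_onsets - schedule.tone_puff_frames)
        has_puff = np.array([t in puffed for t in schedule.tone_onsets])
    return np.flatnonzero(has_puff if population == "co" else ~has_puff)


def generate_event_trains(
    config: SimConfig,
    schedule: TrialSchedule,
    truth: GroundTruth,
) -> GroundTruth:
    """Fill ``event_onsets_true``: Poisson background everywhere plus one
    tone-locked event per active trial with the population's per-trial
    response probability, placed uniformly in the 1 s post-tone window."""
    fr = config.frame_rate
    p_frame = config.basal_rate / 60.0 / fr
    resp_win = schedule.response_frames
    co_trials = _active_blocks(schedule, "co")
    ex_trials = _active_blocks(schedule, "ex")
    onsets: list[np.ndarray] = []
    for cell in range(config.n_cells):
        rng = _stream(config.seed, _K_EVENTS, cell)
        ev = np.flatnonzero(rng.random(schedule.n_frames) < p_frame)
        extra = []
        for pop, trials, p in (("co", co_trials, config.resp_prob_co),
                               ("ex", ex_trials, config.resp_prob_ex)):
            members = truth.co_cells if pop == "co" else truth.ex_cells
            if cell not in members:
                continue
            fire = rng.random(len(trials)) < p
            for trial in trials[fire]:
                t0, _ = schedule.response_window(int(trial))
                extra.append(t0 + rng.integers(0, resp_win))
        if extra:
            ev = np.union1d(ev, np.array(extra, dtype=int))
        onsets.append(ev.astype(int))
    truth.event_onsets_true = onsets
    return truth


def calcium_kernel(config: SimConfig, n_frames: int | None = None) -> np.ndarray:
    """Difference-of-exponentials indicator kernel with unit peak.

    K(t) = exp(-t/tau_d) - exp(-t/tau_r), sampled at the frame rate and
    truncated at 8 decay constants.
    """
    fr = config.frame_rate
    if n_frames is None:
        n_frames = int(round(8 * config.kernel_decay * fr)) + 1
    t = np.arange(n_frames) / fr
    k = np.exp(-t / config.kernel_decay) - np.exp(-t / config.kernel_rise)
    peak = k.max()
    if peak <= 0:
        raise ValueError("kernel_decay must exceed kernel_rise")
    return k / peak


def kernel_peak_frames(config: SimConfig) -> int:
    """Frames from event onset to the kernel peak (the rising-phase length)."""
    return int(np.argmax(calcium_kernel(config)))


def render_fluorescence(
    config: SimConfig,
    schedule: TrialSchedule,
    truth: GroundTruth,
    baseline_range: tuple[float, float] = (50.0, 150.0),
) -> np.ndarray:
    """Forward model for the detector: (n_cells, n_frames) raw traces.

    Each trace is the superposition of unit-peak kernels at the true event
    onsets, plus a constant per-cell baseline and white Gaussian noise of
    SD ``noise_sd`` (in units of the event amplitude).
    """
    n_frames = schedule.n_frames
    kernel = calcium_kernel(config)
    traces = np.empty((config.n_cells, n_frames))
    for cell in range(config.n_cells):
        rng = _stream(config.seed, _K_RENDER, cell)
        baseline = rng.uniform(*baseline_range)
        deltas = np.zeros(n_frames)
        ev = truth.event_onsets_true[cell]
        np.add.at(deltas, ev, 1.0)
        clean = np.convolve(deltas, kernel)[:n_frames]
        noise = rng.normal(0.0, config.noise_sd, size=n_frames) \
            if config.noise_sd > 0 else 0.0
        traces[cell] = baseline + clean + noise
    return traces


def truth_binary(
    config: SimConfig, schedule: TrialSchedule, truth: GroundTruth
) -> np.ndarray:
    """Ground-truth binarized traces: ones on each event's rising phase
    (onset through the kernel peak), as the responsive-cell analysis uses."""
    rise = kernel_peak_frames(config)
    out = np.zeros((config.n_cells, schedule.n_frames), dtype=np.uint8)
    for cell, ev in enumerate(truth.event_onsets_true):
        for o in ev:
            out[cell, o:min(o + rise + 1, schedule.n_frames)] = 1
    return out


# ---------------------------------------------------------------------------
# eye behavior


def _dip_profile(rng: np.random.Generator, fr: float,
                 depth_range=(0.03, 0.08),
                 dur_range_s=(0.15, 0.40)) -> np.ndarray:
    """One trapezoidal eye closure: linear fall, flat bottom, linear rise."""
    depth = rng.uniform(*depth_range)
    dur = int(round(rng.uniform(*dur_range_s) * fr))
    dur = max(dur, 3)
    fall = max(1, dur // 3)
    rise = max(1, dur // 3)
    flat = dur - fall - rise
    prof = np.concatenate([
        np.linspace(0, depth, fall, endpoint=False),
        np.full(max(flat, 0), depth),
        np.linspace(depth, 0, rise + 1),
    ])
    return prof


def _expected_subthreshold_span(config: SimConfig, n_mc: int = 1000) -> float:
    """Mean number of frames a spontaneous dip spends below the 2% CR
    threshold, estimated from the dip-shape distribution itself."""
    rng = _stream(config.seed, _K_EYE, 999)
    spans = [np.count_nonzero(_dip_profile(rng, config.frame_rate) > 0.02)
             for _ in range(n_mc)]
    return float(np.mean(spans))


def generate_eye_trace(
    config: SimConfig,
    schedule: TrialSchedule,
    truth: GroundTruth,
    noise_sd: float = 0.005,
    puff_depth: float = 0.45,
    puff_dur_s: float = 1.0,
) -> np.ndarray:
    """Normalized eye-area trace: ~1.0 open, trapezoidal conditioned dips
    on CR trials inside the tone-puff window, a deep sustained closure
    after each puff, and spontaneous dips in non-stimulus periods placed
    so that the expected fraction of 600 ms windows containing a closure
    equals ``spont_closure_rate``."""
    fr = config.frame_rate
    n = schedule.n_frames
    rng = _stream(config.seed, _K_EYE)
    area = np.ones(n)

    # conditioned responses
    cr_rng = _stream(config.seed, _K_CR)
    cr_trials = set(np.flatnonzero(
        cr_rng.random(schedule.n_trials) < config.cr_prob).tolist())
    truth.cr_trials_true = cr_trials
    tp = schedule.tone_puff_frames
    for trial in sorted(cr_trials):
        tone = int(schedule.tone_onsets[trial])
        prof = _dip_profile(rng, fr)
        # start early enough that the threshold crossing happens pre-puff
        start = tone + int(rng.integers(1, max(tp // 2, 2)))
        end = min(start + len(prof), n)
        area[start:end] -= prof[: end - start]

    # puff-evoked closures (always deeper and longer than any CR dip)
    for puff in schedule.puff_onsets:
        dur = int(round(puff_dur_s * fr))
        edge = max(1, dur // 6)
        prof = np.concatenate([
            np.linspace(0, puff_depth, edge, endpoint=False),
            np.full(dur - 2 * edge, puff_depth),
            np.linspace(puff_depth, 0, edge + 1),
        ])
        end = min(puff + len(prof), n)
        area[puff:end] -= prof[: end - puff]

    # spontaneous closures in the non-stimulus periods, Poisson placement
    # calibrated so P(600 ms window contains a closure) = spont_closure_rate
    if config.spont_closure_rate > 0:
        win = tp  # 12 frames
        span = _expected_subthreshold_span(config)
        lam = -np.log(1.0 - config.spont_closure_rate) / (span + win - 1)
        mask = np.ones(n, dtype=bool)
        pre = int(round(PRE_EXCLUDE_S * fr))
        post = int(round(POST_EXCLUDE_S * fr))
        for tone in schedule.tone_onsets:
            mask[max(tone - pre, 0): tone + post + 1] = False
        starts = np.flatnonzero((rng.random(n) < lam) & mask)
        for s in starts:
            prof = _dip_profile(rng, fr)
            end = min(s + len(prof), n)
            area[s:end] -= prof[: end - s]

    if noise_sd > 0:
        area = area + rng.normal(0.0, noise_sd, size=n)
    return area


def generate_roi_centroids(
    config: SimConfig, margin_px: int = 20, min_sep_px: float = 8.0,
    radius_range: tuple[float, float] = (4.0, 6.0),
) -> tuple[np.ndarray, np.ndarray]:
    """Uniform ROI centroids on the imaging field with a minimum separation,
    plus per-cell disc radii. Returns (centroids (n,2) float, radii (n,))."""
    rng = _stream(config.seed, _K_ROI)
    pts: list[np.ndarray] = []
    lo, hi = margin_px, config.fov_px - margin_px
    attempts = 0
    while len(pts) < config.n_cells:
        cand = rng.uniform(lo, hi, size=2)
        if not pts or np.min(np.linalg.norm(np.array(pts) - cand, axis=1)) >= min_sep_px:
            pts.append(cand)
        attempts += 1
        if attempts > 1000 * config.n_cells:
            raise RuntimeError("could not place ROIs; lower min_sep_px")
    radii = rng.uniform(*radius_range, size=config.n_cells)
    return np.array(pts), radii


@dataclass
class Session:
    """Bundle of one simulated session's observables and latent truth."""

    config: SimConfig
    schedule: TrialSchedule
    truth: GroundTruth
    traces: np.ndarray  # (n_cells, n_frames) raw fluorescence
    eye: np.ndarray  # (n_frames,) normalized eye area


def simulate_session(
    config: SimConfig,
    blocks: Sequence[tuple[str, int, bool]] | None = None,
    render: bool = True,
) -> Session:
    """Full forward simulation: schedule, identities, events, traces, eye, ROIs."""
    if blocks is None:
        schedule = generate_experiment_schedule(config)
    else:
        schedule = generate_experiment_schedule(config, blocks)
    truth = assign_populations(config)
    generate_event_trains(config, schedule, truth)
    truth.centroids, truth.roi_radii = generate_roi_centroids(config)
    traces = render_fluorescence(config, schedule, truth) if render \
        else np.zeros((config.n_cells, 0))
    eye = generate_eye_trace(config, schedule, truth)
    return Session(config, schedule, truth, traces, eye)


# ---------------------------------------------------------------------------
# on-disk layout


def write_session(session: Session, outdir: str | Path, hdf5: bool = True) -> None:
    """Write a session in the pipeline's exchange formats: traces as CSV
    (cells x frames) and optionally HDF5, the schedule and ROI centroids
    as CSV, and the ground truth as JSON."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    n_cells = session.config.n_cells
    pd.DataFrame(session.traces,
                 index=pd.Index(range(n_cells), name="cell_id")
                 ).to_csv(out / "traces.csv")
    pd.DataFrame({"frame": np.arange(len(session.eye)), "area": session.eye}
                 ).to_csv(out / "eye_trace.csv", index=False)
    sched = session.schedule
    puffs = np.full(sched.n_trials, -1, dtype=int)
    if len(sched.puff_onsets):
        lookup = {t: p for t, p in zip(
            sched.puff_onsets - sched.tone_puff_frames, sched.puff_onsets)}
        puffs = np.array([lookup.get(t, -1) for t in sched.tone_onsets])
    pd.DataFrame({
        "trial": np.arange(sched.n_trials),
        "tone_frame": sched.tone_onsets,
        "puff_frame": puffs,
        "block": sched.blocks,
    }).to_csv(out / "schedule.csv", index=False)
    if session.truth.centroids is not None:
        pd.DataFrame({
            "cell_id": np.arange(n_cells),
            "x_px": session.truth.centroids[:, 0],
            "y_px": session.truth.centroids[:, 1],
            "radius_px": session.truth.roi_radii,
        }).to_csv(out / "roi_centroids.csv", index=False)
    truth_json = {
        "co_cells": sorted(session.truth.co_cells),
        "ex_cells": sorted(session.truth.ex_cells),
        "cr_trials_true": sorted(session.truth.cr_trials_true),
        "event_onsets_true": [o.tolist() for o in session.truth.event_onsets_true],
        "config": asdict(session.config),
        "n_frames": sched.n_frames,
    }
    (out / "ground_truth.json").write_text(json.dumps(truth_json))
    if hdf5:
        import h5py

        with h5py.File(out / "session.h5", "w") as f:
            f.create_dataset("traces", data=session.traces)
            f.create_dataset("eye_area", data=session.eye)
            f.create_dataset("tone_onsets", data=sched.tone_onsets)
            f.create_dataset("puff_onsets", data=sched.puff_onsets)
            f.attrs["frame_rate"] = sched.frame_rate
            f.attrs["seed"] = session.config.seed
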