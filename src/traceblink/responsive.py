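"""Tone-responsive cell identification against a per-cell shuffle null.

A cell's tone response is the mean of its binarized calcium trace over
the 20 one-second windows following tone onsets.  The null for that
statistic is built by repeatedly (1000x) drawing 20 non-overlapping
one-second segments from the cell's own non-stimulus periods (frames more
than 2 s before or 8 s after every tone onset) and averaging the binary
trace over them.  The cell is "responsive" when the tone response
strictly exceeds the 95th percentile of its null distribution.

Session overlap is summarized by the common-cell percentage
100*|S1 n S2| / |S1 u S2|, a Jaccard index in percent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .synthetic import PRE_EXCLUDE_S, POST_EXCLUDE_S, TrialSchedule

__all__ = ["ShuffleNull", "ResponsiveLabel", "PopulationOverlap",
           "non_stimulus_mask", "build_shuffle_null", "tone_amplitude",
           "classify_responsive", "classify_population", "response_latency",
           "population_overlap", "responsive_fraction"]

log = logging.getLogger(__name__)


@dataclass
class ShuffleNull:
    """Null distribution of mean binarized amplitude over random segments."""

    distribution: np.ndarray  # one mean per shuffle
    n_shuffles: int = 1000
    n_segments: int = 20
    segment_len: int = 20  # frames (1 s at 20 Hz)
    seed: int | None = None

    @property
    def p95(self) -> float:
        return float(np.percentile(self.distribution, 95))


@dataclass
class ResponsiveLabel:
    cell_id: int
    tone_amplitude: float
    null_p95: float
    responsive: bool
    latency_ms: float = float("nan")  # mean first-event latency, NaN if no events


@dataclass
class PopulationOverlap:
    set1_ids: set[int]
    set2_ids: set[int]
    common_ids: set[int] = field(init=False)
    jaccard_pct: float = field(init=False)

    def __post_init__(self) -> None:
        if not self.set1_ids and not self.set2_ids:
            raise ValueError("overlap of two empty sets is undefined")
        self.common_ids = self.set1_ids & self.set2_ids
        cs, r1, r2 = len(self.common_ids), len(self.set1_ids), len(self.set2_ids)
        self.jaccard_pct = 100.0 * cs / (r1 + r2 - cs)


def non_stimulus_mask(schedule: TrialSchedule,
                      n_frames: int | None = None) -> np.ndarray:
    """Boolean mask of non-stimulus frames: True outside the union of
    [tone - 2 s, tone + 8 s] windows around every tone onset."""
    if n_frames is None:
        n_frames = schedule.n_frames
    fr = schedule.frame_rate
    pre = int(round(PRE_EXCLUDE_S * fr))
    post = int(round(POST_EXCLUDE_S * fr))
    mask = np.ones(n_frames, dtype=bool)
    for tone in schedule.tone_onsets:
        mask[max(int(tone) - pre, 0): int(tone) + post + 1] = False
    return mask


def _valid_segment_starts(mask: np.ndarray, seg_len: int) -> np.ndarray:
    """Start frames whose whole segment lies inside the mask."""
    m = np.asarray(mask, dtype=bool)
    c = np.concatenate([[0], np.cumsum(m)])
    full = c[seg_len:] - c[:-seg_len] == seg_len
    return np.flatnonzero(full)


def _max_disjoint(starts: np.ndarray, seg_len: int) -> int:
    """Greedy count of pairwise non-overlapping segments available."""
    count, last_end = 0, -1
    for s in starts:
        if s > last_end:
            count += 1
            last_end = s + seg_len - 1
    return count


def build_shuffle_null(
    binary: np.ndarray, mask: np.ndarray,
    n_shuffles: int = 1000, n_segments: int = 20, segment_len: int = 20,
    seed: int | np.random.Generator = 0, max_reject_rounds: int = 200,
) -> ShuffleNull:
    """Per-shuffle mean of the binary trace over ``n_segments`` disjoint
    segments drawn uniformly from the non-stimulus mask.

    Segments are drawn by vectorised rejection sampling (redraw shuffles
    whose sorted starts come closer than one segment length), with a
    seeded greedy fallback for shuffles still unresolved after
    ``max_reject_rounds`` rounds.  Raises if the mask cannot host
    ``n_segments`` disjoint segments.
    """
    binary = np.asarray(binary)
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    starts_pool = _valid_segment_starts(mask, segment_len)
    if _max_disjoint(starts_pool, segment_len) < n_segments:
        raise ValueError(
            f"non-stimulus mask supports fewer than {n_segments} disjoint "
            f"{segment_len}-frame segments")
    c = np.concatenate([[0], np.cumsum(binary)])

    draws = np.empty((n_shuffles, n_segments), dtype=int)
    pending = np.arange(n_shuffles)
    for _ in range(max_reject_rounds):
        if len(pending) == 0:
            break
        cand = rng.choice(starts_pool, size=(len(pending), n_segments))
        cand.sort(axis=1)
        ok = (np.diff(cand, axis=1) >= segment_len).all(axis=1)
        draws[pending[ok]] = cand[ok]
        pending = pending[~ok]
    for i in pending:  # greedy fallback, still uniform enough for a null
        perm = rng.permutation(starts_pool)
        chosen: list[int] = []
        for s in perm:
            if all(abs(s - t) >= segment_len for t in chosen):
                chosen.append(int(s))
                if len(chosen) == n_segments:
                    break
        else:
            raise ValueError("greedy fallback could not place all segments")
        draws[i] = np.sort(chosen)

    seg_sums = c[draws + segment_len] - c[draws]  # (n_shuffles, n_segments)
    dist = seg_sums.sum(axis=1) / (n_segments * segment_len)
    return ShuffleNull(distribution=dist.astype(float), n_shuffles=n_shuffles,
                       n_segments=n_segments, segment_len=segment_len)


def tone_amplitude(binary: np.ndarray, schedule: TrialSchedule) -> float:
    """Mean of the binary trace over the post-tone 1 s response windows."""
    win = schedule.response_frames
    total = 0.0
    for trial in range(schedule.n_trials):
        a, b = schedule.response_window(trial)
        total += binary[a:b].sum()
    return float(total / (schedule.n_trials * win))


def response_latency(onsets: np.ndarray, schedule: TrialSchedule) -> float:
    """Mean latency (ms) of the first event onset inside the 1 s post-tone
    window, over trials that have one; NaN if no trial does."""
    onsets = np.asarray(onsets, dtype=int)
    lats = []
    for trial in range(schedule.n_trials):
        a, b = schedule.response_window(trial)
        inside = onsets[(onsets >= a) & (onsets < b)]
        if len(inside):
            lats.append((inside.min() - a) / schedule.frame_rate * 1000.0)
    return float(np.mean(lats)) if lats else float("nan")


def classify_responsive(
    binary: np.ndarray, schedule: TrialSchedule, null: ShuffleNull,
    cell_id: int = 0, onsets: np.ndarray | None = None,
) -> ResponsiveLabel:
    """Label one cell: responsive iff its tone amplitude strictly exceeds
    the 95th percentile of its shuffle null (ties are not responsive)."""
    amp = tone_amplitude(binary, schedule)
    p95 = null.p95
    lat = response_latency(onsets, schedule) if onsets is not None \
        else float("nan")
    return ResponsiveLabel(cell_id=cell_id, tone_amplitude=amp, null_p95=p95,
                           responsive=bool(amp > p95), latency_ms=lat)


def classify_population(
    binaries: np.ndarray, schedule: TrialSchedule, mask: np.ndarray,
    onsets: list[np.ndarray] | None = None,
    n_shuffles: int = 1000, seed: int = 0,
) -> list[ResponsiveLabel]:
    """Shuffle-test every cell of a (n_cells, n_frames) binary matrix.

    Segments are drawn per cell, per shuffle, from an independent
    substream of ``seed`` so cell order does not couple the nulls.
    """
    labels = []
    for cell in range(binaries.shape[0]):
        rng = np.random.default_rng(
            np.random.SeedSequence(seed, spawn_key=(cell,)))
        null = build_shuffle_null(binaries[cell], mask,
                                  n_shuffles=n_shuffles, seed=rng)
        labels.append(classify_responsive(
            binaries[cell], schedule, null, cell_id=cell,
            onsets=None if onsets is None else onsets[cell]))
    return labels


def population_overlap(s1: set[int], s2: set[int]) -> PopulationOverlap:
    """Common-cell percentage 100*|S1 n S2|/|S1 u S2| between two sessions."""
    return PopulationOverlap(set(s1), set(s2))


def responsive_fraction(labels_or_count, total: int | None = None) -> float:
    """Percentage of cells flagged responsive.

    Accepts either a list of :class:`ResponsiveLabel` or an explicit
    (count, total) pair.
    """
    if total is None:
        labels = list(labels_or_count)
        if not labels:
            raise ValueError("no labels")
        count = sum(1 for l in labels if l.responsive)
        total = len(labels)
    else:
        count = int(labels_or_count)
        if count > total:
            raise ValueError("count exceeds total")
    if total == 0:
        raise ValueError("total must be positive")
    return 100.0 * count / total
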