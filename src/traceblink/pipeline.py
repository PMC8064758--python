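"""End-to-end session analysis.

Chains the stages of the trace-conditioning analysis — simulate (or
load), normalize, detect events, score eye behavior, identify responsive
cells per trial block, build co-occurrence networks, and test spatial
organisation — and collects the headline quantities (CR%, responsive
fractions, cell- and edge-level Jaccard overlaps, network density and
degree) into one summary that is bit-reproducible for a given config and
seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import behavior as beh
from . import detect as det
from . import network as net
from . import responsive as resp
from . import spatial as spa
from . import synthetic as syn

__all__ = ["SessionAnalysis", "run_pipeline", "sort_trial_average",
           "analyze_session", "default_config"]

log = logging.getLogger(__name__)


def default_config(seed: int = 0) -> dict:
    """Demo configuration: a final imaging day (20 CS-US then 20 CS-only
    trials) at the generator defaults."""
    return {
        "simulate": {"seed": seed},
        "blocks": [["cond", 20, True], ["ext", 20, False]],
        "detection": {},
        "responsive": {"n_shuffles": 1000},
    }


@dataclass
class SessionAnalysis:
    """Per-stage outputs plus a JSON-ready summary with provenance."""

    config: dict
    session: syn.Session
    trains: list[det.EventTrain]
    outcomes: dict[str, list[beh.TrialOutcome]]
    labels: dict[str, list[resp.ResponsiveLabel]]
    networks: dict[str, net.NetworkMap]
    summary: dict[str, Any]


def _config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True).encode()).hexdigest()[:16]


def sort_trial_average(
    traces: np.ndarray, schedule: syn.TrialSchedule,
    trials: np.ndarray | None = None,
    external_order: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Trial-averaged responses sorted by tone-puff window fluorescence.

    Each cell's trace is averaged over trials on the aligned window
    [tone - 2 s, tone + 8 s], the mean of the 12 frames before the tone
    is subtracted, and cells are ordered by descending mean fluorescence
    in the 12-frame tone-puff window (stable, so ties keep cell-id
    order).  ``external_order`` instead applies a fixed permutation, to
    compare spatially matched cells across sessions.

    Returns (order, trial_averaged_matrix[order]).
    """
    fr = schedule.frame_rate
    pre = int(round(syn.PRE_EXCLUDE_S * fr))
    post = int(round(syn.POST_EXCLUDE_S * fr))
    tp = schedule.tone_puff_frames
    if trials is None:
        trials = np.arange(schedule.n_trials)
    if len(trials) == 0:
        raise ValueError("need at least one trial")
    windows = []
    for trial in trials:
        t = int(schedule.tone_onsets[trial])
        if t - pre < 0 or t + post + 1 > traces.shape[1]:
            log.warning("trial %d window outside traces; skipped", trial)
            continue
        windows.append(traces[:, t - pre:t + post + 1])
    if not windows:
        raise ValueError("no trial fits inside the traces")
    avg = np.mean(windows, axis=0)  # (n_cells, pre+post+1)
    avg = avg - avg[:, pre - tp:pre].mean(axis=1, keepdims=True)
    if external_order is not None:
        order = np.asarray(external_order, dtype=int)
    else:
        score = avg[:, pre:pre + tp].mean(axis=1)
        order = np.argsort(-score, kind="stable")
    return order, avg[order]


def analyze_session(config: dict) -> SessionAnalysis:
    """Run the full analysis on a freshly simulated session."""
    sim_kwargs = dict(config.get("simulate", {}))
    sim = syn.SimConfig(**sim_kwargs)
    blocks = [tuple(b) for b in config.get(
        "blocks", [("cond", sim.n_trials, True), ("ext", sim.n_trials, False)])]
    session = syn.simulate_session(sim, blocks=blocks)
    schedule = session.schedule
    fr = schedule.frame_rate

    from .preprocess import normalize_traces

    norm = normalize_traces(session.traces)
    det_kwargs = config.get("detection", {})
    trains = [det.detect_events(norm[c], fr, **det_kwargs)
              for c in range(sim.n_cells)]
    mask = resp.non_stimulus_mask(schedule)

    # behavior
    eye = beh.EyeTrace(session.eye, fr)
    thr = beh.fit_cr_threshold(eye)
    outcomes: dict[str, list[beh.TrialOutcome]] = {}
    cr_pct: dict[str, float] = {}
    for label in dict.fromkeys(schedule.blocks):
        sub = schedule.subset(schedule.trials_in_block(label))
        outcomes[label] = beh.classify_cr(eye, thr, sub)
        cr_pct[label] = beh.cr_percentage(outcomes[label])
    spont = beh.spontaneous_closure_rate(eye, mask, thr)

    # responsive cells per block
    resp_kwargs = config.get("responsive", {})
    binaries = np.stack([t.binary for t in trains])
    onsets = [t.onsets for t in trains]
    labels: dict[str, list[resp.ResponsiveLabel]] = {}
    resp_sets: dict[str, set[int]] = {}
    for label in dict.fromkeys(schedule.blocks):
        sub = schedule.subset(schedule.trials_in_block(label))
        labels[label] = resp.classify_population(
            binaries, sub, mask, onsets=onsets,
            n_shuffles=resp_kwargs.get("n_shuffles", 1000),
            seed=sim.seed)
        resp_sets[label] = {l.cell_id for l in labels[label] if l.responsive}

    block_names = list(dict.fromkeys(schedule.blocks))
    summary: dict[str, Any] = {
        "seed": sim.seed,
        "config_hash": _config_hash(config),
        "n_cells": sim.n_cells,
        "cr_pct": cr_pct,
        "spontaneous_closure_rate": spont,
        "basal_event_rate_per_min": float(np.mean(
            [det.event_rate(t, mask, fr) for t in trains])),
        "responsive_fraction_pct": {
            b: resp.responsive_fraction(labels[b]) for b in block_names},
    }

    # overlaps and networks for every pair of blocks
    networks: dict[str, net.NetworkMap] = {}
    if len(block_names) >= 2:
        b1, b2 = block_names[0], block_names[1]
        s1, s2 = resp_sets[b1], resp_sets[b2]
        if s1 or s2:
            summary["cell_jaccard_pct"] = resp.population_overlap(s1, s2).jaccard_pct
        union = s1 | s2
        centroids = session.truth.centroids
        for b in (b1, b2):
            sub = schedule.subset(schedule.trials_in_block(b))
            vecs = [net.trial_response_vector(trains, schedule, int(t))
                    for t in schedule.trials_in_block(b)]
            mat = net.cooccurrence(vecs, schedule.trials_in_block(b))
            networks[b] = net.build_network(mat, union, centroids)
        nets = list(networks.values())
        summary["network"] = {
            "density": {b: (net.network_density(networks[b])
                            if networks[b].n >= 2 else float("nan"))
                        for b in networks},
            "degree": {b: net.network_degree(networks[b]) if networks[b].n
                       else float("nan") for b in networks},
        }
        try:
            summary["edge_jaccard_pct"] = net.edge_overlap(*nets).jaccard_pct
        except ValueError:
            summary["edge_jaccard_pct"] = float("nan")

    # spatial organisation of the responsive identities
    if session.truth.centroids is not None and len(block_names) >= 2:
        roi_map = spa.discs_to_roi_map(session.truth.centroids,
                                       session.truth.roi_radii,
                                       px_um=sim.px_um, fov_px=sim.fov_px)
        spatial_summary = {}
        for name, cells in (("co", resp_sets[block_names[0]]),
                            ("ex", resp_sets[block_names[1]])):
            if len(cells) >= 2:
                obs, _, p = spa.bootstrap_identity(
                    roi_map, cells, n_boot=config.get("spatial_boot", 200),
                    seed=sim.seed)
                spatial_summary[name] = {"observed_pct": obs, "p_two_tailed": p}
        summary["spatial"] = spatial_summary

    return SessionAnalysis(config=config, session=session, trains=trains,
                           outcomes=outcomes, labels=labels,
                           networks=networks, summary=summary)


def _write_outputs(analysis: SessionAnalysis, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    syn.write_session(analysis.session, outdir / "session")
    rows = []
    for cell, train in enumerate(analysis.trains):
        for e in train.events:
            rows.append((cell, e.onset_frame, e.peak_frame, e.amplitude))
    pd.DataFrame(rows, columns=["cell_id", "onset_frame", "peak_frame",
                                "amplitude"]).to_csv(
        outdir / "events.csv", index=False)
    for block, labels in analysis.labels.items():
        pd.DataFrame([asdict(l) for l in labels]).to_csv(
            outdir / f"responsive_{block}.csv", index=False)
    for block, outs in analysis.outcomes.items():
        pd.DataFrame([asdict(o) for o in outs]).to_csv(
            outdir / f"behavior_{block}.csv", index=False)
    import networkx as nx

    for block, netmap in analysis.networks.items():
        g = netmap.graph.copy()
        for _, data in g.nodes(data=True):  # GraphML cannot store tuples
            p = data.pop("pos", None)
            if p is not None:
                data["x"], data["y"] = float(p[0]), float(p[1])
        nx.write_graphml(g, outdir / f"network_{block}.graphml")
        pd.DataFrame([(u, v, d["count"]) for u, v, d in
                      netmap.graph.edges(data=True)],
                     columns=["cell_i", "cell_j", "count"]).to_csv(
            outdir / f"edges_{block}.csv", index=False)
    (outdir / "summary.json").write_text(
        json.dumps(analysis.summary, indent=2, sort_keys=True))


def run_pipeline(config: dict | str | Path,
                 outdir: str | Path | None = None) -> SessionAnalysis:
    """Validate the config, run every stage, and optionally write a run
    directory (session files, per-stage CSVs, GraphML networks, and
    ``summary.json``)."""
    if not isinstance(config, dict):
        import yaml

        config = yaml.safe_load(Path(config).read_text())
    if not isinstance(config, dict):
        raise ValueError("config must be a mapping")
    unknown = set(config) - {"simulate", "blocks", "detection", "responsive",
                             "spatial_boot"}
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    analysis = analyze_session(config)
    if outdir is not None:
        _write_outputs(analysis, Path(outdir))
    return analysis
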