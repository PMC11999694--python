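"""Migration-regime labelling, behaviour classification and motility metrics.

Per assigned frame a track receives exactly one regime label: ``probing``
(staying within ~two cell sizes, 20 µm, of its interaction point while
interacting with the monolayer), ``crawling_above`` / ``crawling_below``
(continuous locomotion above or below the endothelial monolayer),
``accelerated`` (flow-driven jumps), or ``unassigned``.  The above/below
state follows the transmigration coefficient tc with hysteresis: a diapedesis
event takes minutes, so a completed transmigration requires tc to stay high
over several frames, while a brief excursion that retreats is logged as an
uncompleted transmigration attempt.

Per-track motility is reported over the scopes used for cohort comparison:
probing before transmigration, crawling before transmigration, all crawling
above, all crawling below, the whole track excluding accelerated movement
(and under-segmented / gap regions), and the whole track.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .imaging import AcquisitionClock
from .tracking import Track

__all__ = [
    "REGIMES",
    "BEHAVIOR_CATEGORIES",
    "RegimeParams",
    "TransmigrationEvent",
    "MotilityEntry",
    "select_tracks",
    "filter_debris",
    "probing_mask",
    "label_regimes",
    "classify_behavior",
    "compute_motility",
    "compute_am_metrics",
    "MOTILITY_SCOPES",
    "analyze_tracks",
]

REGIMES = ("probing", "crawling_above", "crawling_below", "transmigrating",
           "accelerated", "unassigned")

BEHAVIOR_CATEGORIES = (
    "detached", "out_of_fov", "crawling", "probing",
    "crawling_full_transmigration", "probing_full_transmigration",
    "crawling_uncompleted_transmigration", "probing_uncompleted_transmigration",
)

MOTILITY_SCOPES = (
    "probing_before_transmigration", "crawling_before_transmigration",
    "all_crawling_above", "all_crawling_below", "whole_excl_am", "whole_track",
)


@dataclass(frozen=True)
class RegimeParams:
    """Thresholds of the per-frame regime labelling."""

    window_frames: int = 36          # probing window (36 × 10 s = 6 min)
    probing_radius_um: float = 20.0  # ~two cell sizes
    tc_enter: float = 0.25           # start of a transmigration attempt
    tc_full: float = 0.95            # fully below the monolayer
    tc_exit: float = 0.1             # retreat back above
    full_sustain_frames: int = 3
    attempt_min_frames: int = 2


@dataclass(frozen=True)
class TransmigrationEvent:
    frame: int
    kind: str        # "full" or "attempt"


@dataclass
class MotilityEntry:
    """Motility metrics over one regime scope of one track."""

    scope: str
    n_frames: int = 0
    duration_s: float = 0.0
    vector_displacement_um: tuple = (0.0, 0.0)
    absolute_displacement_um: float = 0.0
    path_length_um: float = 0.0
    migration_speed_um_min: float = 0.0    # displacement / time
    crawling_speed_um_min: float = 0.0     # path / time
    instantaneous_speed_mean_um_min: float = 0.0
    instantaneous_speed_std_um_min: float = 0.0
    meandering_index: float = 0.0
    empty: bool = True


# ---------------------------------------------------------------------------
# track selection
# ---------------------------------------------------------------------------

def _touching_pairs(instances, max_gap_px: float = 1.0):
    """Labels of instances whose masks lie within ``max_gap_px`` pixels."""
    touching = set()
    for i in range(len(instances)):
        for j in range(i + 1, len(instances)):
            a, b = instances[i], instances[j]
            if a.bbox and b.bbox:
                ay0, ax0, ay1, ax1 = a.bbox
                by0, bx0, by1, bx1 = b.bbox
                if (ay0 > by1 + max_gap_px or by0 > ay1 + max_gap_px or
                        ax0 > bx1 + max_gap_px or bx0 > ax1 + max_gap_px):
                    continue
            da = a.pixels[:, None, :] - b.pixels[None, :, :]
            if (np.abs(da).max(axis=2) <= max_gap_px).any():
                touching.add(i)
                touching.add(j)
    return touching


def select_tracks(tracks: list[Track], clock: AcquisitionClock,
                  bounding_box_um, fiducial_margin_um: float = 25.0,
                  min_flow_frames: int = 6, min_assigned_frac: float = 0.75,
                  final_instances=None, nodes=None) -> list[Track]:
    """Keep only tracks that can be analysed reliably.

    A track is kept iff (a) every assigned position lies at least
    ``fiducial_margin_um`` inside the bounding box enclosing all detections,
    (b) it is assigned in at least ``min_flow_frames`` frames of the
    physiological-flow phase, (c) it is assigned in at least
    ``min_assigned_frac`` of the frames along its span, and (d) the cell is
    not touching another cell at the final acquisition frame
    (mask adjacency within 1 px, checked when final-frame instances are
    supplied).
    """
    xmin, ymin, xmax, ymax = bounding_box_um
    touching_final = set()
    if final_instances:
        idx = _touching_pairs(final_instances)
        touching_final = {id(final_instances[i]) for i in idx}
    kept = []
    for t in tracks:
        pos = t.positions[t.flags != "gap"]
        pos = pos[np.isfinite(pos).all(axis=1)]
        if len(pos) == 0:
            continue
        inside = ((pos[:, 0] >= xmin + fiducial_margin_um) &
                  (pos[:, 0] <= xmax - fiducial_margin_um) &
                  (pos[:, 1] >= ymin + fiducial_margin_um) &
                  (pos[:, 1] <= ymax - fiducial_margin_um))
        if not inside.all():
            continue
        flow_assigned = np.sum((t.flags != "gap") &
                               (t.frames >= clock.accumulation_end_frame))
        if flow_assigned < min_flow_frames:
            continue
        if t.assigned_fraction < min_assigned_frac:
            continue
        if final_instances and nodes is not None and len(t.node_ids):
            last_nid = next((nid for nid in t.node_ids[::-1] if nid >= 0), -1)
            if last_nid >= 0 and nodes[last_nid].instance is not None and \
                    id(nodes[last_nid].instance) in touching_final:
                continue
        kept.append(t)
    return kept


def filter_debris(tracks: list[Track], nodes,
                  median_single_area_px: float,
                  min_p_cell: float = 0.6, min_area_frac: float = 0.3,
                  eps_debris: float = 5.0,
                  min_total_move_um: float = 1.0) -> list[Track]:
    """Rule-based removal of non-cell tracks (debris).

    A track is dropped when its median cell probability is below
    ``min_p_cell``, its median area is below ``min_area_frac`` of the single
    cell area, or it never moves (< ``min_total_move_um`` total) while being
    extremely elongated (ε > ``eps_debris``).  Boundary values are kept
    (comparisons are strict drops).
    """
    kept = []
    for t in tracks:
        nids = t.node_ids[t.node_ids >= 0]
        if len(nids) == 0:
            continue
        pcell = np.median([nodes[i].p_cell_mean for i in nids])
        area = np.median([nodes[i].area_px for i in nids])
        elong = np.median([nodes[i].elongation for i in nids])
        pos = t.positions[t.flags == "assigned"]
        move = float(np.nansum(np.linalg.norm(np.diff(pos, axis=0), axis=1))) \
            if len(pos) > 1 else 0.0
        if pcell < min_p_cell:
            continue
        if area < min_area_frac * median_single_area_px:
            continue
        if move < min_total_move_um and elong > eps_debris:
            continue
        kept.append(t)
    return kept


# ---------------------------------------------------------------------------
# regime labelling
# ---------------------------------------------------------------------------

def probing_mask(positions: np.ndarray, assigned: np.ndarray,
                 window_frames: int, probing_radius_um: float) -> np.ndarray:
    """Frames belonging to a probing interval.

    A frame is probing when some sliding window of ``window_frames``
    consecutive assigned frames covering it keeps every position within
    ``probing_radius_um`` of the window's anchor (its first position).
    Tracks shorter than the window are classified as a single window.
    """
    n = len(positions)
    out = np.zeros(n, dtype=bool)
    idx = np.nonzero(np.asarray(assigned, bool))[0]
    win = min(window_frames, max(len(idx), 1))
    for s in range(len(idx)):
        w_idx = idx[s:s + win]
        if len(w_idx) < 2:
            continue
        anchor = positions[w_idx[0]]
        d = np.linalg.norm(positions[w_idx] - anchor, axis=1)
        if np.all(d <= probing_radius_um):
            out[w_idx] = True
    return out


def _tc_state_machine(tc: np.ndarray, prm: RegimeParams):
    """Hysteresis walk over the tc sequence.

    Returns ``(below, events)`` where ``below[i]`` says the cell is under the
    monolayer at frame i, and events list full transmigrations (first frame
    of the sustained high-tc run) and uncompleted attempts (excursions above
    ``tc_enter`` for ≥ attempt_min_frames that fall back below ``tc_exit``
    without achieving the sustained full level).
    """
    n = len(tc)
    below = np.zeros(n, dtype=bool)
    events: list[TransmigrationEvent] = []
    state_below = False
    exc_start = None          # index where tc first rose above tc_enter
    exc_len = 0
    i = 0
    while i < n:
        v = tc[i]
        if not state_below:
            # check for a sustained full-transmigration run starting here
            if v >= prm.tc_full:
                run = 0
                while i + run < n and tc[i + run] >= prm.tc_full:
                    run += 1
                if run >= prm.full_sustain_frames:
                    events.append(TransmigrationEvent(i, "full"))
                    state_below = True
                    exc_start, exc_len = None, 0
                    below[i:i + run] = True
                    i += run
                    continue
            if v >= prm.tc_enter:
                if exc_start is None:
                    exc_start = i
                exc_len += 1
            elif v < prm.tc_exit and exc_start is not None:
                if exc_len >= prm.attempt_min_frames:
                    events.append(TransmigrationEvent(exc_start, "attempt"))
                exc_start, exc_len = None, 0
        else:
            below[i] = True
            if v < prm.tc_exit:   # reverse transmigration: back above
                state_below = False
                below[i] = False
        i += 1
    return below, events


def label_regimes(track: Track, tc_per_frame: np.ndarray,
                  prm: RegimeParams | None = None,
                  frame_interval_s: float = 10.0):
    """Label each frame of a track with its migration regime.

    Frames reached by a jump link are ``accelerated``.  The above/below
    state comes from the tc hysteresis (see :func:`_tc_state_machine`).
    Above-monolayer non-accelerated frames are ``probing`` when some sliding
    window of ``window_frames`` anchored at its first position keeps every
    position within ``probing_radius_um`` of the anchor, else
    ``crawling_above``; below-monolayer locomotion is ``crawling_below``.
    Gap frames are ``unassigned``.
    """
    prm = prm or RegimeParams()
    n = len(track.frames)
    labels = np.array(["unassigned"] * n, dtype=object)
    assigned = track.flags != "gap"
    tc = np.asarray(tc_per_frame, dtype=float)
    below, events = _tc_state_machine(np.where(assigned, tc, 0.0), prm)

    jump_frames = {f for (f, _, _) in track.jumps}
    is_jump = np.array([f in jump_frames for f in track.frames])

    # probing: any qualifying window covering the frame
    probing = probing_mask(track.positions, assigned, prm.window_frames,
                           prm.probing_radius_um)

    for i in range(n):
        if not assigned[i]:
            continue
        if is_jump[i]:
            labels[i] = "accelerated"
        elif below[i]:
            labels[i] = "crawling_below"
        elif probing[i]:
            labels[i] = "probing"
        else:
            labels[i] = "crawling_above"
    return labels, events


# ---------------------------------------------------------------------------
# behaviour classification
# ---------------------------------------------------------------------------

def _majority_pre_regime(labels, frames, cut_frame) -> str:
    """'probing' or 'crawling' by majority of above-monolayer labels before
    the cut frame (whole track if the cut precedes everything)."""
    mask = frames < cut_frame
    pre = [l for l, m in zip(labels, mask)
           if m and l in ("probing", "crawling_above")]
    if not pre:
        pre = [l for l in labels if l in ("probing", "crawling_above")]
    n_prob = sum(1 for l in pre if l == "probing")
    return "probing" if n_prob * 2 >= len(pre) and pre else \
        ("crawling" if pre else "probing")


def classify_behavior(track: Track, labels, events, clock: AcquisitionClock,
                      fov_bounds_um, boundary_margin_um: float = 25.0) -> str:
    """Assign the track its behaviour category.

    Decision order: (1) a track that ends before the last acquisition frame
    with a terminal accelerated step (or disappearance) away from the
    boundary detached; (2) one that exits through the fiducial boundary left
    the FoV; (3) a full transmigration event makes it crawling- or
    probing-full-transmigration by the majority pre-event regime; (4) an
    attempt without completion likewise with 'uncompleted'; (5) otherwise
    probing or crawling by overall majority.
    """
    last_frame = clock.n_frames - 1
    ends_early = track.end_frame < last_frame
    end_pos = track.positions[-1]
    near_boundary = False
    if fov_bounds_um is not None and np.isfinite(end_pos).all():
        xmin, ymin, xmax, ymax = fov_bounds_um
        d = min(end_pos[0] - xmin, xmax - end_pos[0],
                end_pos[1] - ymin, ymax - end_pos[1])
        near_boundary = d < boundary_margin_um
    if ends_early:
        terminal_am = (len(labels) and labels[-1] == "accelerated") or \
            track.end_reason == "detached"
        if terminal_am and not near_boundary:
            return "detached"
        if near_boundary or track.end_reason == "out_of_fov":
            return "out_of_fov"
    fulls = [e for e in events if e.kind == "full"]
    if fulls:
        cut = track.frames[min(fulls[0].frame, len(track.frames) - 1)]
        return f"{_majority_pre_regime(labels, track.frames, cut)}_full_transmigration"
    attempts = [e for e in events if e.kind == "attempt"]
    if attempts:
        cut = track.frames[min(attempts[0].frame, len(track.frames) - 1)]
        return (f"{_majority_pre_regime(labels, track.frames, cut)}"
                "_uncompleted_transmigration")
    return _majority_pre_regime(labels, track.frames,
                                track.frames[-1] + 1)


# ---------------------------------------------------------------------------
# motility
# ---------------------------------------------------------------------------

def _scope_mask(labels, frames, events, scope: str):
    labels = np.asarray(labels, dtype=object)
    first_full = None
    for e in events:
        if e.kind == "full":
            first_full = frames[min(e.frame, len(frames) - 1)]
            break
    cut = first_full if first_full is not None else frames[-1] + 1
    if scope == "probing_before_transmigration":
        return (labels == "probing") & (frames < cut)
    if scope == "crawling_before_transmigration":
        return (labels == "crawling_above") & (frames < cut)
    if scope == "all_crawling_above":
        return labels == "crawling_above"
    if scope == "all_crawling_below":
        return labels == "crawling_below"
    if scope == "whole_excl_am":
        return np.isin(labels, ("probing", "crawling_above", "crawling_below"))
    if scope == "whole_track":
        return labels != "unassigned"
    raise ValueError(f"unknown scope {scope!r}")


def compute_motility(track: Track, labels, scope: str,
                     events=(), frame_interval_s: float = 10.0,
                     gap_max: int = 3) -> MotilityEntry:
    """Motility metrics of one track over one regime scope.

    The path is the sum of step lengths over successive in-scope frames no
    more than ``gap_max`` frames apart (gaps bridged by straight segments);
    speeds are in µm/min; the meandering index is absolute displacement over
    path length (0 when the path is 0).  Fewer than 2 frames in scope yields
    an empty entry.
    """
    entry = MotilityEntry(scope=scope)
    mask = _scope_mask(labels, track.frames, events, scope)
    idx = np.nonzero(mask & np.isfinite(track.positions).all(axis=1))[0]
    if len(idx) < 2:
        return entry
    frames = track.frames[idx]
    pos = track.positions[idx]
    am_frames = set(track.frames[np.asarray(labels, object) == "accelerated"])
    include_am = scope == "whole_track"
    steps, dts = [], []
    for a, b in zip(range(len(idx) - 1), range(1, len(idx))):
        dframe = frames[b] - frames[a]
        if dframe <= 0 or dframe > gap_max:
            continue
        if not include_am and any(f in am_frames
                                  for f in range(frames[a] + 1, frames[b] + 1)):
            continue  # step would bridge across an accelerated displacement
        steps.append(float(np.linalg.norm(pos[b] - pos[a])))
        dts.append(dframe * frame_interval_s)
    if not steps:
        return entry
    path = float(np.sum(steps))
    duration = float(np.sum(dts))
    disp_vec = pos[-1] - pos[0]
    disp = float(np.linalg.norm(disp_vec))
    inst = np.array(steps) / np.array(dts) * 60.0
    entry.n_frames = int(len(idx))
    entry.duration_s = duration
    entry.vector_displacement_um = (float(disp_vec[0]), float(disp_vec[1]))
    entry.absolute_displacement_um = disp
    entry.path_length_um = path
    entry.migration_speed_um_min = disp / duration * 60.0
    entry.crawling_speed_um_min = path / duration * 60.0
    entry.instantaneous_speed_mean_um_min = float(inst.mean())
    entry.instantaneous_speed_std_um_min = float(inst.std())
    entry.meandering_index = disp / path if path > 0 else 0.0
    entry.empty = False
    return entry


def compute_am_metrics(track: Track):
    """Aggregate accelerated-movement time, displacement and speed.

    The AM speed is the displacement-weighted mean of per-jump speeds, a
    proxy for how strongly the cell adheres to the endothelium.
    """
    if not track.jumps:
        return 0.0, 0.0, 0.0
    disps = np.array([d for (_, d, _) in track.jumps])
    speeds = np.array([s for (_, _, s) in track.jumps])
    times = disps / speeds * 60.0
    am_time_s = float(times.sum())
    am_disp = float(disps.sum())
    am_speed = float((disps * speeds).sum() / disps.sum())
    return am_time_s, am_disp, am_speed


# ---------------------------------------------------------------------------
# cohort-level convenience
# ---------------------------------------------------------------------------

def analyze_tracks(tracks: list[Track], nodes, clock: AcquisitionClock,
                   fov_bounds_um, prm: RegimeParams | None = None,
                   frame_interval_s: float = 10.0,
                   gap_max: int = 3) -> pd.DataFrame:
    """Per-track behaviour category and flattened motility scopes."""
    prm = prm or RegimeParams()
    rows = []
    for t in tracks:
        tc = np.array([nodes[nid].tc if nid >= 0 else 0.0
                       for nid in t.node_ids])
        labels, events = label_regimes(t, tc, prm, frame_interval_s)
        cat = classify_behavior(t, labels, events, clock, fov_bounds_um)
        row = {"track_id": t.track_id, "category": cat,
               "start_frame": t.start_frame, "end_frame": t.end_frame,
               "end_reason": t.end_reason,
               "n_full_transmigration": sum(e.kind == "full" for e in events),
               "n_attempts": sum(e.kind == "attempt" for e in events)}
        for scope in MOTILITY_SCOPES:
            m = compute_motility(t, labels, scope, events,
                                 frame_interval_s, gap_max)
            for k in ("duration_s", "absolute_displacement_um",
                      "path_length_um", "migration_speed_um_min",
                      "crawling_speed_um_min",
                      "instantaneous_speed_mean_um_min",
                      "instantaneous_speed_std_um_min", "meandering_index"):
                row[f"{scope}.{k}"] = getattr(m, k) if not m.empty else np.nan
        am_t, am_d, am_s = compute_am_metrics(t)
        row.update({"am_time_s": am_t, "am_displacement_um": am_d,
                    "am_speed_um_min": am_s})
        rows.append(row)
    return pd.DataFrame(rows)
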