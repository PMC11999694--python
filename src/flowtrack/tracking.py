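"""Track reconstruction for cells migrating under flow.

Flow introduces events that defeat plain frame-to-frame association: cells
appear suddenly in the field of view, detach and vanish, or are displaced
downstream by ≥ 8 µm in a single frame step ("accelerated movement", AM).
Touching cells are under-segmented into one detection.  The tracker handles
this with four stages:

1. *Linking* — all candidate connections between detections in adjacent
   frames within a search radius.
2. *Track candidates* — a conservation-style integer program: each detection
   (node) carries a multiplicity μ (how many cells it may contain), links
   carry integer flows, and appearance/disappearance slack closes the
   balance ``inflow + appearance = μ = outflow + disappearance`` at every
   node.  The program is solved to proven optimality (HiGHS via
   :func:`scipy.optimize.milp`).
3. *Global consistency* — the same conservation program re-solved on the
   graph of track segments, followed by a search for "jumps" (missing
   segments due to accelerated movement, displacement ≥ 8 µm at speeds well
   above crawling, biased downstream) and removal of unreliable short or
   multiplicity-zero segments.
4. *Intersection resolution* — identities of isolated cells (M = 1) are
   matched across under-segmented regions by feature similarity and
   positional continuity, and extended one vertex deep into intersections
   when the branch multiplicity equals the number of emerging M = 1
   segments.

All positions are (x, y) in µm; flow points along +x.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import sparse
from scipy.optimize import Bounds, LinearConstraint, linear_sum_assignment, milp
from scipy.spatial import cKDTree

from .imaging import AcquisitionClock

__all__ = [
    "TrackingConfig",
    "Node",
    "CandidateLink",
    "TrackSegment",
    "SegmentGraph",
    "Track",
    "build_nodes",
    "estimate_multiplicity",
    "build_links",
    "solve_track_candidates",
    "build_segment_graph",
    "resolve_global_consistency",
    "extend_into_intersections",
    "resolve_intersections",
    "reconstruct_tracks",
    "appearance_cost",
    "disappearance_cost",
    "feature_dissimilarity",
    "solve_conservation",
]

_BIG = 1e6


@dataclass(frozen=True)
class TrackingConfig:
    """Weights and thresholds of the tracking pipeline (distances in µm)."""

    r_link_um: float = 15.0           # max displacement for standard links
    w_d: float = 1.0                  # link cost per µm of displacement
    w_f: float = 10.0                 # weight of feature dissimilarity
    c_app: float = 20.0               # appearance cost (per unit multiplicity)
    c_dis: float = 20.0               # disappearance cost
    c_dev: float = 10.0               # cost per unit |μ − m_est| per node
    boundary_lambda_um: float = 50.0  # decay length of the boundary discount
    boundary_floor: float = 0.2       # minimal cost factor at the FoV edge
    accumulation_relax_frames: int = 3
    accumulation_cost_factor: float = 0.5
    gap_max: int = 3                  # max temporal gap for jumps / bridging
    len_min: int = 3                  # minimum reliable segment length (frames)
    jump_min_um: float = 8.0          # AM displacement floor
    v_jump_min_um_min: float = 30.0   # AM speed floor (µm/min)
    jump_beta: float = 1.0            # flow-direction prior strength
    jump_cost_max: float = 60.0       # acceptance threshold for jump links
    m_max: int = 4                    # multiplicity cap per node


@dataclass
class Node:
    """A detection at one frame, with its multiplicity estimate."""

    index: int
    frame: int
    pos: np.ndarray               # (x, y) µm
    area_px: float
    elongation: float
    p_cell_mean: float
    tc: float
    n_seeds: int = 1
    m_est: int = 1
    m_min: int = 0
    m_max: int = 2
    dist_to_edge_um: float = np.inf
    instance = None


@dataclass
class CandidateLink:
    """Candidate connection between nodes in nearby frames."""

    u: int
    v: int
    distance_um: float
    cost: float
    is_jump: bool = False


@dataclass
class TrackSegment:
    """Maximal unbranched run of nodes with constant multiplicity M."""

    id: int
    node_ids: list
    M: int

    @property
    def length(self) -> int:
        return len(self.node_ids)


@dataclass
class SegEdge:
    u: int                        # segment id
    v: int
    flow: int
    cost: float
    is_jump: bool = False
    distance_um: float = 0.0
    dt_frames: int = 1


@dataclass
class SegmentGraph:
    segments: dict                # id -> TrackSegment
    edges: list                   # list[SegEdge]
    extensible_regions: list = field(default_factory=list)

    def edges_from(self, sid):
        return [e for e in self.edges if e.u == sid and e.flow > 0]

    def edges_to(self, sid):
        return [e for e in self.edges if e.v == sid and e.flow > 0]


@dataclass
class Track:
    """A reconstructed cell track.

    ``frames``/``positions``/``node_ids``/``flags`` are parallel arrays over
    the frames of the track span; ``flags`` is one of ``assigned``,
    ``undersegmented`` (position taken from a merged detection) or ``gap``.
    """

    track_id: int
    frames: np.ndarray
    positions: np.ndarray         # (T, 2) µm; NaN at gaps
    node_ids: np.ndarray          # -1 at gaps / undersegmented intervals
    flags: np.ndarray             # object array of str
    jumps: list                   # (frame, displacement_um, speed_um_min)
    end_reason: str = "lost"

    @property
    def start_frame(self) -> int:
        return int(self.frames[0])

    @property
    def end_frame(self) -> int:
        return int(self.frames[-1])

    @property
    def assigned_fraction(self) -> float:
        return float(np.mean(self.flags != "gap"))

    def assigned_frames(self) -> np.ndarray:
        return self.frames[self.flags != "gap"]


# ---------------------------------------------------------------------------
# stage 0: nodes and links
# ---------------------------------------------------------------------------

def estimate_multiplicity(area_px: float, n_seeds: int,
                          median_single_area_px: float, m_cap: int = 4):
    """Multiplicity estimate of a detection.

    ``m_est`` is the larger of the number of centroid seeds inside the mask
    and the area ratio to the median single-cell area (rounded, at least 1),
    capped at ``m_cap``; the allowed range is m_est ± 1 (clipped to [0, cap]).
    """
    if median_single_area_px <= 0:
        raise ValueError("median single-cell area must be > 0")
    m_area = max(1, int(round(area_px / median_single_area_px)))
    m_est = min(max(int(n_seeds), m_area, 1), m_cap)
    return m_est, (max(0, m_est - 1), min(m_est + 1, m_cap))


def build_nodes(instances_by_frame: dict, cfg: TrackingConfig,
                fov_bounds_um=None,
                median_single_area_px: float | None = None) -> list[Node]:
    """Flatten per-frame instances into tracking nodes.

    ``fov_bounds_um`` is ``(xmin, ymin, xmax, ymax)``; by default the
    bounding box of all detections.  The median single-seed instance area is
    used as the single-cell reference area unless given explicitly.
    """
    all_inst = [(f, i) for f in sorted(instances_by_frame)
                for i in instances_by_frame[f]]
    if not all_inst:
        return []
    if median_single_area_px is None:
        singles = [i.area_px for _, i in all_inst if i.n_seeds <= 1]
        median_single_area_px = float(np.median(singles or
                                                [i.area_px for _, i in all_inst]))
    if fov_bounds_um is None:
        xs = [i.pos_um[0] for _, i in all_inst]
        ys = [i.pos_um[1] for _, i in all_inst]
        fov_bounds_um = (min(xs), min(ys), max(xs), max(ys))
    xmin, ymin, xmax, ymax = fov_bounds_um
    nodes = []
    for frame, inst in all_inst:
        x, y = inst.pos_um
        d_edge = max(0.0, min(x - xmin, xmax - x, y - ymin, ymax - y))
        m_est, (m_lo, m_hi) = estimate_multiplicity(
            inst.area_px, inst.n_seeds, median_single_area_px, cfg.m_max)
        node = Node(index=len(nodes), frame=frame,
                    pos=np.asarray(inst.pos_um, dtype=float),
                    area_px=float(inst.area_px), elongation=float(inst.elongation),
                    p_cell_mean=float(inst.p_cell_mean), tc=float(inst.tc),
                    n_seeds=inst.n_seeds, m_est=m_est, m_min=m_lo, m_max=m_hi,
                    dist_to_edge_um=d_edge)
        node.instance = inst
        nodes.append(node)
    return nodes


def feature_dissimilarity(a, b) -> float:
    """Symmetric dissimilarity of two detections' appearance features."""
    da = abs(a.area_px - b.area_px) / max(a.area_px + b.area_px, 1e-12)
    de = abs(a.elongation - b.elongation) / max(a.elongation + b.elongation, 1e-12)
    dp = abs(a.p_cell_mean - b.p_cell_mean)
    return da + de + dp


def build_links(nodes: list[Node], cfg: TrackingConfig) -> list[CandidateLink]:
    """All candidate connections between adjacent-frame nodes within radius.

    The link cost is ``w_d·distance + w_f·feature_dissimilarity``; the search
    is exhaustive within ``r_link_um`` (KD-tree accelerated).
    """
    by_frame: dict[int, list[Node]] = {}
    for n in nodes:
        by_frame.setdefault(n.frame, []).append(n)
    links: list[CandidateLink] = []
    frames = sorted(by_frame)
    for f in frames:
        if f + 1 not in by_frame:
            continue
        cur, nxt = by_frame[f], by_frame[f + 1]
        tree = cKDTree([m.pos for m in nxt])
        for n in cur:
            for j in sorted(tree.query_ball_point(n.pos, cfg.r_link_um)):
                m = nxt[j]
                dist = float(np.linalg.norm(m.pos - n.pos))
                cost = cfg.w_d * dist + cfg.w_f * feature_dissimilarity(n, m)
                links.append(CandidateLink(n.index, m.index, dist, cost,
                                           is_jump=dist >= cfg.jump_min_um))
    return links


# ---------------------------------------------------------------------------
# stage 1: the conservation program
# ---------------------------------------------------------------------------

def _boundary_factor(dist_to_edge_um: float, cfg: TrackingConfig) -> float:
    """Discount factor for appearance/disappearance near the FoV boundary.

    The *discount* decays with distance from the edge: the factor is
    ``floor`` at the boundary and approaches 1 deep inside the FoV.
    """
    decay = np.exp(-dist_to_edge_um / cfg.boundary_lambda_um)
    return cfg.boundary_floor + (1.0 - cfg.boundary_floor) * (1.0 - decay)


def _phase_factor(frame: int, cfg: TrackingConfig, clock: AcquisitionClock) -> float:
    """Appearance/disappearance discount during accumulation and just after
    the flow increase, when cells wash in and out."""
    if frame < clock.accumulation_end_frame + cfg.accumulation_relax_frames:
        return cfg.accumulation_cost_factor
    return 1.0


def appearance_cost(frame: int, dist_to_edge_um: float, cfg: TrackingConfig,
                    clock: AcquisitionClock, first_frame: int = 0) -> float:
    if frame == first_frame:
        return 0.0
    return (cfg.c_app * _boundary_factor(dist_to_edge_um, cfg)
            * _phase_factor(frame, cfg, clock))


def disappearance_cost(frame: int, dist_to_edge_um: float, cfg: TrackingConfig,
                       clock: AcquisitionClock, last_frame: int) -> float:
    if frame == last_frame:
        return 0.0
    return (cfg.c_dis * _boundary_factor(dist_to_edge_um, cfg)
            * _phase_factor(frame, cfg, clock))


def _components(n_items: int, edges) -> list[list[int]]:
    parent = list(range(n_items))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for (u, v, *_rest) in edges:
        ru, rv = find(u), find(v)
        if ru != rv:
            parent[ru] = rv
    comps: dict[int, list[int]] = {}
    for i in range(n_items):
        comps.setdefault(find(i), []).append(i)
    return sorted(comps.values(), key=lambda c: c[0])


def solve_conservation(m_est, m_lo, m_hi, app_cost, dis_cost, edges,
                       c_dev, dev_weight=None):
    """Solve the conservation integer program to optimality.

    Items (detections or segments) carry integer usages μ_i ∈ [m_lo, m_hi];
    directed edges ``(u, v, cost, f_max)`` carry integer flows; appearance
    a_i and disappearance d_i close the balance

        Σ_in f + a_i = μ_i = Σ_out f + d_i .

    The objective is Σ f·cost + Σ (app·a + dis·d + c_dev·w_i·|μ − m_est|),
    with ``dev_weight`` w_i defaulting to 1.  Returns ``(flows, mu, total
    cost)``.  Connected components are solved independently; items with no
    incident edge are solved in closed form.
    """
    m_est = np.asarray(m_est, dtype=int)
    m_lo = np.asarray(m_lo, dtype=int)
    m_hi = np.asarray(m_hi, dtype=int)
    app_cost = np.asarray(app_cost, dtype=float)
    dis_cost = np.asarray(dis_cost, dtype=float)
    w = np.ones(len(m_est)) if dev_weight is None else np.asarray(dev_weight, float)
    n = len(m_est)
    flows = np.zeros(len(edges), dtype=int)
    mu = np.zeros(n, dtype=int)
    total = 0.0
    edge_idx_of_item: dict[int, list[int]] = {i: [] for i in range(n)}
    for k, (u, v, *_r) in enumerate(edges):
        edge_idx_of_item[u].append(k)
        edge_idx_of_item[v].append(k)

    for comp in _components(n, edges):
        comp_edges = sorted({k for i in comp for k in edge_idx_of_item[i]})
        if not comp_edges:
            i = comp[0]
            best = (np.inf, m_lo[i])
            for m in range(m_lo[i], m_hi[i] + 1):
                c = m * (app_cost[i] + dis_cost[i]) + c_dev * w[i] * abs(m - m_est[i])
                if c < best[0] - 1e-12:
                    best = (c, m)
            mu[comp[0]] = best[1]
            total += best[0]
            continue
        total += _solve_component_milp(
            comp, comp_edges, edges, m_est, m_lo, m_hi,
            app_cost, dis_cost, c_dev, w, flows, mu)
    return flows, mu, total


def _solve_component_milp(comp, comp_edges, edges, m_est, m_lo, m_hi,
                          app_cost, dis_cost, c_dev, w, flows, mu):
    items = {i: k for k, i in enumerate(comp)}
    ni, ne = len(comp), len(comp_edges)
    # variable layout: [f_e | mu_i | a_i | d_i | dev_i]
    ofs_mu, ofs_a = ne, ne + ni
    ofs_d, ofs_dev = ne + 2 * ni, ne + 3 * ni
    nvar = ne + 4 * ni
    c = np.zeros(nvar)
    lb = np.zeros(nvar)
    ub = np.zeros(nvar)
    for k, ek in enumerate(comp_edges):
        u, v, cost, fmax = edges[ek]
        c[k] = cost
        ub[k] = fmax
    for i, k in items.items():
        c[ofs_mu + k] = 0.0
        lb[ofs_mu + k], ub[ofs_mu + k] = m_lo[i], m_hi[i]
        c[ofs_a + k], c[ofs_d + k] = app_cost[i], dis_cost[i]
        ub[ofs_a + k] = ub[ofs_d + k] = m_hi[i]
        c[ofs_dev + k] = c_dev * w[i]
        ub[ofs_dev + k] = m_hi[i] + m_est[i]
    rows, cols, vals, con_lb, con_ub = [], [], [], [], []
    row = 0
    for i, k in items.items():
        # inflow + a = mu  ->  sum_in f + a - mu = 0
        for kk, ek in enumerate(comp_edges):
            if edges[ek][1] == i:
                rows.append(row); cols.append(kk); vals.append(1.0)
        rows.append(row); cols.append(ofs_a + k); vals.append(1.0)
        rows.append(row); cols.append(ofs_mu + k); vals.append(-1.0)
        con_lb.append(0.0); con_ub.append(0.0); row += 1
        # outflow + d = mu
        for kk, ek in enumerate(comp_edges):
            if edges[ek][0] == i:
                rows.append(row); cols.append(kk); vals.append(1.0)
        rows.append(row); cols.append(ofs_d + k); vals.append(1.0)
        rows.append(row); cols.append(ofs_mu + k); vals.append(-1.0)
        con_lb.append(0.0); con_ub.append(0.0); row += 1
        # dev >= mu - m_est   ->  mu - dev <= m_est
        rows += [row, row]; cols += [ofs_mu + k, ofs_dev + k]; vals += [1.0, -1.0]
        con_lb.append(-np.inf); con_ub.append(float(m_est[i])); row += 1
        # dev >= m_est - mu   ->  -mu - dev <= -m_est
        rows += [row, row]; cols += [ofs_mu + k, ofs_dev + k]; vals += [-1.0, -1.0]
        con_lb.append(-np.inf); con_ub.append(float(-m_est[i])); row += 1
    A = sparse.csr_matrix((vals, (rows, cols)), shape=(row, nvar))
    integrality = np.zeros(nvar)
    integrality[:ofs_dev] = 1  # flows, mu, a, d integer; dev continuous
    res = milp(c, constraints=LinearConstraint(A, con_lb, con_ub),
               integrality=integrality, bounds=Bounds(lb, ub))
    if res.status != 0 or res.x is None:
        raise RuntimeError(f"conservation program not solved: {res.message}")
    x = res.x
    for kk, ek in enumerate(comp_edges):
        flows[ek] = int(round(x[kk]))
    for i, k in items.items():
        mu[i] = int(round(x[ofs_mu + k]))
    return float(res.fun)


def solve_track_candidates(nodes: list[Node], links: list[CandidateLink],
                           cfg: TrackingConfig, clock: AcquisitionClock,
                           first_frame=None, last_frame=None):
    """Globally optimal link selection and per-node multiplicities.

    Returns ``(flows, mu, objective)`` where ``flows[k]`` is the integer flow
    on ``links[k]`` and ``mu[i]`` the resolved usage of ``nodes[i]``.
    """
    if not nodes:
        return np.zeros(0, int), np.zeros(0, int), 0.0
    frames = [n.frame for n in nodes]
    first_frame = min(frames) if first_frame is None else first_frame
    last_frame = max(frames) if last_frame is None else last_frame
    edges = [(lk.u, lk.v, lk.cost, min(nodes[lk.u].m_max, nodes[lk.v].m_max))
             for lk in links]
    app = [appearance_cost(n.frame, n.dist_to_edge_um, cfg, clock, first_frame)
           for n in nodes]
    dis = [disappearance_cost(n.frame, n.dist_to_edge_um, cfg, clock, last_frame)
           for n in nodes]
    return solve_conservation([n.m_est for n in nodes],
                              [n.m_min for n in nodes],
                              [n.m_max for n in nodes],
                              app, dis, edges, cfg.c_dev)


# ---------------------------------------------------------------------------
# stage 2: segment graph
# ---------------------------------------------------------------------------

def build_segment_graph(nodes, links, flows, mu, cfg: TrackingConfig
                        ) -> SegmentGraph:
    """Condense the selected flows into track segments and branch vertices.

    A link is internal to a segment iff it is the unique selected out-link of
    its source and the unique selected in-link of its target, carries the
    full multiplicity of both (constant along the segment) and is not a
    sudden displacement (≥ jump_min_um, which splits the chain)."""
    out_sel: dict[int, list[int]] = {}
    in_sel: dict[int, list[int]] = {}
    for k, lk in enumerate(links):
        if flows[k] > 0:
            out_sel.setdefault(lk.u, []).append(k)
            in_sel.setdefault(lk.v, []).append(k)

    def internal(k):
        lk = links[k]
        return (out_sel.get(lk.u) == [k] and in_sel.get(lk.v) == [k]
                and mu[lk.u] == mu[lk.v] == flows[k]
                and lk.distance_um < cfg.jump_min_um)

    seg_of_node: dict[int, int] = {}
    segments: dict[int, TrackSegment] = {}
    order = sorted((n for n in nodes if mu[n.index] > 0),
                   key=lambda n: (n.frame, n.index))
    for n in order:
        if n.index in seg_of_node:
            continue
        chain = [n.index]
        cur = n.index
        while True:
            outs = out_sel.get(cur, [])
            if len(outs) == 1 and internal(outs[0]):
                nxt = links[outs[0]].v
                chain.append(nxt)
                cur = nxt
            else:
                break
        sid = len(segments)
        segments[sid] = TrackSegment(sid, chain, int(mu[chain[0]]))
        for idx in chain:
            seg_of_node[idx] = sid

    edges: list[SegEdge] = []
    for k, lk in enumerate(links):
        if flows[k] <= 0 or internal(k):
            continue
        su, sv = seg_of_node.get(lk.u), seg_of_node.get(lk.v)
        if su is None or sv is None or su == sv:
            continue
        edges.append(SegEdge(su, sv, int(flows[k]), lk.cost,
                             is_jump=lk.distance_um >= cfg.jump_min_um,
                             distance_um=lk.distance_um, dt_frames=1))
    return SegmentGraph(segments, edges)


def _seg_ends(nodes, seg: TrackSegment):
    return nodes[seg.node_ids[0]], nodes[seg.node_ids[-1]]


def resolve_global_consistency(seg_graph: SegmentGraph, nodes,
                               cfg: TrackingConfig, clock: AcquisitionClock,
                               first_frame=None, last_frame=None
                               ) -> SegmentGraph:
    """Re-solve multiplicity conservation at segment level, search for jumps,
    and prune unreliable segments.

    Steps: (i) the node-level conservation program is re-run with segments as
    items (deviation cost scaled by segment length); (ii) unterminated
    segment ends and starts within ``gap_max`` frames, displaced by at least
    ``jump_min_um`` at a speed above ``v_jump_min_um_min``, are connected by
    jump links when the flow-direction-weighted cost stays below
    ``jump_cost_max``; (iii) segments with M = 0, and segments shorter than
    ``len_min`` with no remaining connections, are removed.
    """
    segs = seg_graph.segments
    if not segs:
        return seg_graph
    ids = sorted(segs)
    pos_of = {sid: i for i, sid in enumerate(ids)}
    all_frames = [nodes[s.node_ids[0]].frame for s in segs.values()] + \
                 [nodes[s.node_ids[-1]].frame for s in segs.values()]
    first_frame = min(all_frames) if first_frame is None else first_frame
    last_frame = max(all_frames) if last_frame is None else last_frame

    m_est = [segs[sid].M for sid in ids]
    m_lo = [max(0, segs[sid].M - 1) for sid in ids]
    m_hi = [min(cfg.m_max, segs[sid].M + 1) for sid in ids]
    app, dis, wdev = [], [], []
    for sid in ids:
        head, tail = _seg_ends(nodes, segs[sid])
        app.append(appearance_cost(head.frame, head.dist_to_edge_um, cfg,
                                   clock, first_frame))
        dis.append(disappearance_cost(tail.frame, tail.dist_to_edge_um, cfg,
                                      clock, last_frame))
        wdev.append(segs[sid].length)
    edges = [(pos_of[e.u], pos_of[e.v], e.cost,
              min(m_hi[pos_of[e.u]], m_hi[pos_of[e.v]]))
             for e in seg_graph.edges]
    flows, M, _ = solve_conservation(m_est, m_lo, m_hi, app, dis, edges,
                                     cfg.c_dev, dev_weight=wdev)
    new_edges = []
    for e, f in zip(seg_graph.edges, flows):
        if f > 0:
            new_edges.append(replace(e, flow=int(f)))
    for i, sid in enumerate(ids):
        segs[sid].M = int(M[i])

    # --- jump search -------------------------------------------------------
    has_out = {e.u for e in new_edges}
    has_in = {e.v for e in new_edges}
    ends = [sid for sid in ids if segs[sid].M >= 1 and sid not in has_out
            and nodes[segs[sid].node_ids[-1]].frame < last_frame]
    starts = [sid for sid in ids if segs[sid].M >= 1 and sid not in has_in
              and nodes[segs[sid].node_ids[0]].frame > first_frame]
    dt_s = None
    candidates = []
    for se in ends:
        tail = nodes[segs[se].node_ids[-1]]
        for ss in starts:
            if ss == se:
                continue
            head = nodes[segs[ss].node_ids[0]]
            dt = head.frame - tail.frame
            if not (1 <= dt <= cfg.gap_max):
                continue
            disp_vec = head.pos - tail.pos
            disp = float(np.linalg.norm(disp_vec))
            if disp < cfg.jump_min_um:
                continue
            dt_s = dt * _frame_interval(nodes)
            speed = disp / dt_s * 60.0
            if speed <= cfg.v_jump_min_um_min:
                continue
            cos_theta = disp_vec[0] / disp if disp > 0 else 1.0
            cost = (cfg.w_d * disp * (1 + cfg.jump_beta * (1 - cos_theta))
                    + cfg.w_f * feature_dissimilarity(tail, head))
            if cost < cfg.jump_cost_max:
                candidates.append((cost, se, ss, disp, dt))
    used_e, used_s = set(), set()
    for cost, se, ss, disp, dt in sorted(candidates,
                                         key=lambda c: (c[0], c[1], c[2])):
        if se in used_e or ss in used_s:
            continue
        used_e.add(se); used_s.add(ss)
        new_edges.append(SegEdge(se, ss, flow=min(segs[se].M, segs[ss].M),
                                 cost=cost, is_jump=True, distance_um=disp,
                                 dt_frames=dt))

    # --- pruning -----------------------------------------------------------
    connected = {e.u for e in new_edges} | {e.v for e in new_edges}
    keep = {sid for sid in ids
            if segs[sid].M > 0
            and (segs[sid].length >= cfg.len_min or sid in connected)}
    segments = {sid: segs[sid] for sid in keep}
    edges_kept = [e for e in new_edges if e.u in keep and e.v in keep]
    return SegmentGraph(segments, edges_kept)


_FRAME_INTERVAL_S = [10.0]


def _frame_interval(_nodes):
    return _FRAME_INTERVAL_S[0]


def set_frame_interval(seconds: float):
    """Set the acquisition frame interval used for speed computations."""
    _FRAME_INTERVAL_S[0] = float(seconds)


# ---------------------------------------------------------------------------
# stage 3: intersections
# ---------------------------------------------------------------------------

def _merge_regions(seg_graph: SegmentGraph):
    """Weakly connected components of M ≥ 2 segments."""
    merged = {sid for sid, s in seg_graph.segments.items() if s.M >= 2}
    adj: dict[int, set] = {sid: set() for sid in merged}
    for e in seg_graph.edges:
        if e.u in merged and e.v in merged:
            adj[e.u].add(e.v)
            adj[e.v].add(e.u)
    seen, regions = set(), []
    for sid in sorted(merged):
        if sid in seen:
            continue
        stack, region = [sid], set()
        while stack:
            cur = stack.pop()
            if cur in region:
                continue
            region.add(cur)
            stack.extend(adj[cur] - region)
        seen |= region
        regions.append(region)
    return regions


def extend_into_intersections(seg_graph: SegmentGraph, nodes=None
                              ) -> SegmentGraph:
    """Mark intersections into which isolated-cell tracks can be extended.

    A merged region whose branch multiplicity n equals both the number of
    incoming and outgoing M = 1 segments lets the n identities be propagated
    one vertex deep: the merged detections' positions are later attached to
    the matched tracks (flagged under-segmented).
    """
    regions = []
    for region in _merge_regions(seg_graph):
        in_pure = sorted({e.u for e in seg_graph.edges
                          if e.v in region and e.u not in region
                          and seg_graph.segments[e.u].M == 1})
        out_pure = sorted({e.v for e in seg_graph.edges
                           if e.u in region and e.v not in region
                           and seg_graph.segments[e.v].M == 1})
        n = max(seg_graph.segments[sid].M for sid in region)
        regions.append({
            "segments": sorted(region),
            "in_pure": in_pure,
            "out_pure": out_pure,
            "n": n,
            "extensible": len(in_pure) == len(out_pure) == n,
        })
    seg_graph.extensible_regions = regions
    return seg_graph


def resolve_intersections(seg_graph: SegmentGraph, nodes,
                          cfg: TrackingConfig,
                          frame_interval_s: float = 10.0,
                          clock: AcquisitionClock | None = None,
                          fov_bounds_um=None,
                          boundary_margin_um: float = 25.0) -> list[Track]:
    """Assemble tracks, matching identities across under-segmented regions.

    For a region with k incoming and k outgoing M = 1 segments, identities
    are matched by minimal total cost (feature dissimilarity of the flanking
    segment ends plus positional continuity) via the Hungarian algorithm;
    ties break deterministically toward lower segment ids.  Matched flanks
    are concatenated into one track with the under-segmented interval either
    filled with the merged detections' positions (when the region admits
    extension) or marked as gap.  Unequal counts terminate all tracks at the
    region.
    """
    if not seg_graph.extensible_regions and _merge_regions(seg_graph):
        seg_graph = extend_into_intersections(seg_graph)
    segs = seg_graph.segments
    pure = {sid for sid, s in segs.items() if s.M == 1}
    succ: dict[int, tuple] = {}
    has_pred: set[int] = set()

    # direct pure -> pure connections (standard or jump)
    for e in sorted(seg_graph.edges, key=lambda e: (e.u, e.v)):
        if e.u in pure and e.v in pure and e.flow >= 1:
            if e.u not in succ and e.v not in has_pred:
                succ[e.u] = (e.v, "jump" if e.is_jump else "link", None)
                has_pred.add(e.v)

    # matches across merge regions
    for region in seg_graph.extensible_regions:
        ins = [sid for sid in region["in_pure"] if sid not in succ]
        outs = [sid for sid in region["out_pure"] if sid not in has_pred]
        if not ins or not outs or len(ins) != len(outs):
            continue
        k = len(ins)
        C = np.full((k, k), _BIG)
        for i, si in enumerate(ins):
            tail = nodes[segs[si].node_ids[-1]]
            for j, sj in enumerate(outs):
                head = nodes[segs[sj].node_ids[0]]
                dt = head.frame - tail.frame
                if dt <= 0:
                    continue
                drift = float(np.linalg.norm(head.pos - tail.pos)) / dt
                C[i, j] = (cfg.w_f * feature_dissimilarity(tail, head)
                           + cfg.w_d * drift + 1e-9 * (i * k + j))
        ri, cj = linear_sum_assignment(C)
        for i, j in zip(ri, cj):
            if C[i, j] >= _BIG / 2:
                continue
            succ[ins[i]] = (outs[j], "merge", region)
            has_pred.add(outs[j])

    # region frame -> merged-node lookup (for under-segmented position fill)
    region_nodes = {}
    for region in seg_graph.extensible_regions:
        lookup: dict[int, list[int]] = {}
        for sid in region["segments"]:
            if sid in segs:
                for nid in segs[sid].node_ids:
                    lookup.setdefault(nodes[nid].frame, []).append(nid)
        region_nodes[id(region)] = lookup

    tracks: list[Track] = []
    roots = sorted(sid for sid in pure if sid not in has_pred)
    for root in roots:
        chain = [(root, None, None)]
        cur = root
        visited = {root}
        while cur in succ:
            nxt, kind, region = succ[cur]
            if nxt in visited:
                break
            chain.append((nxt, kind, region))
            visited.add(nxt)
            cur = nxt
        tracks.append(_assemble_track(len(tracks), chain, segs, nodes, cfg,
                                      frame_interval_s, region_nodes))
    last_frame = max((n.frame for n in nodes), default=0)
    for t in tracks:
        t.end_reason = _end_reason(t, last_frame, fov_bounds_um,
                                   boundary_margin_um)
    return tracks


def _assemble_track(tid, chain, segs, nodes, cfg, frame_interval_s,
                    region_nodes) -> Track:
    frames, poss, nids, flags, jumps = [], [], [], [], []

    def add_node(nid, flag="assigned"):
        n = nodes[nid]
        frames.append(n.frame)
        poss.append(n.pos)
        nids.append(nid if flag == "assigned" else -1)
        flags.append(flag if flag != "assigned" else "assigned")

    for (sid, kind, region) in chain:
        seg = segs[sid]
        head = nodes[seg.node_ids[0]]
        if frames:
            prev_frame, prev_pos = frames[-1], poss[-1]
            if kind == "jump":
                dt = (head.frame - prev_frame) * frame_interval_s
                disp = float(np.linalg.norm(head.pos - prev_pos))
                jumps.append((int(head.frame), disp, disp / dt * 60.0))
                for f in range(prev_frame + 1, head.frame):
                    frames.append(f); poss.append(np.full(2, np.nan))
                    nids.append(-1); flags.append("gap")
            elif kind == "merge":
                lookup = region_nodes.get(id(region), {})
                for f in range(prev_frame + 1, head.frame):
                    cand = lookup.get(f, [])
                    if region is not None and region["extensible"] and cand:
                        # nearest merged detection to the interpolated path
                        alpha = (f - prev_frame) / (head.frame - prev_frame)
                        target = prev_pos + alpha * (head.pos - prev_pos)
                        nid = min(cand, key=lambda q:
                                  float(np.linalg.norm(nodes[q].pos - target)))
                        frames.append(f); poss.append(nodes[nid].pos)
                        nids.append(-1); flags.append("undersegmented")
                    else:
                        frames.append(f); poss.append(np.full(2, np.nan))
                        nids.append(-1); flags.append("gap")
            else:  # standard link between segments (sudden displacement split)
                dt = (head.frame - prev_frame) * frame_interval_s
                disp = float(np.linalg.norm(head.pos - prev_pos))
                if disp >= cfg.jump_min_um:
                    jumps.append((int(head.frame), disp, disp / dt * 60.0))
        for nid in seg.node_ids:
            add_node(nid)
        # intra-segment sudden displacements cannot occur (segments split
        # at >= jump_min_um); nothing to annotate inside a segment
    return Track(track_id=tid,
                 frames=np.asarray(frames, dtype=int),
                 positions=np.asarray(poss, dtype=float),
                 node_ids=np.asarray(nids, dtype=int),
                 flags=np.asarray(flags, dtype=object),
                 jumps=jumps)


def _end_reason(track: Track, last_frame: int, fov_bounds_um,
                margin: float) -> str:
    if track.end_frame >= last_frame:
        return "end_of_acquisition"
    end_pos = track.positions[-1]
    if fov_bounds_um is not None and np.isfinite(end_pos).all():
        xmin, ymin, xmax, ymax = fov_bounds_um
        d = min(end_pos[0] - xmin, xmax - end_pos[0],
                end_pos[1] - ymin, ymax - end_pos[1])
        if d < margin:
            return "out_of_fov"
    if track.jumps and track.jumps[-1][0] >= track.end_frame - 1:
        return "detached"
    return "lost"


# ---------------------------------------------------------------------------
# one-call pipeline
# ---------------------------------------------------------------------------

def reconstruct_tracks(instances_by_frame: dict,
                       cfg: TrackingConfig | None = None,
                       clock: AcquisitionClock | None = None,
                       fov_bounds_um=None,
                       frame_interval_s: float = 10.0) -> list[Track]:
    """Full tracking pipeline: link, optimise, consolidate, resolve.

    ``instances_by_frame`` maps frame index to lists of
    :class:`~flowtrack.segmentation.CellInstance`.
    """
    cfg = cfg or TrackingConfig()
    if clock is None:
        frames = sorted(instances_by_frame) or [0]
        clock = AcquisitionClock(accumulation_end_frame=0,
                                 n_frames=max(frames) + 1)
    set_frame_interval(frame_interval_s)
    nodes = build_nodes(instances_by_frame, cfg, fov_bounds_um)
    if not nodes:
        return []
    if fov_bounds_um is None:
        xs = np.array([n.pos[0] for n in nodes])
        ys = np.array([n.pos[1] for n in nodes])
        fov_bounds_um = (xs.min(), ys.min(), xs.max(), ys.max())
    links = build_links(nodes, cfg)
    flows, mu, _obj = solve_track_candidates(nodes, links, cfg, clock)
    seg_graph = build_segment_graph(nodes, links, flows, mu, cfg)
    seg_graph = resolve_global_consistency(seg_graph, nodes, cfg, clock)
    seg_graph = extend_into_intersections(seg_graph, nodes)
    tracks = resolve_intersections(seg_graph, nodes, cfg,
                                   frame_interval_s=frame_interval_s,
                                   clock=clock, fov_bounds_um=fov_bounds_um)
    # conservation sanity: every assigned node used at most once across tracks
    used = [nid for t in tracks for nid in t.node_ids if nid >= 0]
    if len(used) != len(set(used)):
        warnings.warn("internal: a detection was assigned to multiple tracks")
    return tracks
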