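"""End-to-end orchestration: config schema, run directory, manifest."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .analysis import RegimeParams, analyze_tracks, filter_debris, select_tracks
from .imaging import AcquisitionClock, read_stack
from .segmentation import (SegmentationThresholds, extract_instances,
                           instances_to_frame_table)
from .stats import aggregate_behavior
from .tracking import TrackingConfig, build_nodes, reconstruct_tracks

log = logging.getLogger("flowtrack")

__all__ = ["RunConfig", "run_pipeline", "tracks_to_table"]

_MODALITIES = ("probability_maps", "fluorescence")


@dataclass
class RunConfig:
    """Validated configuration of a pipeline run.

    Unknown keys in a config file are rejected; a serialized copy is stored
    with every run for reproducibility.
    """

    modality: str = "probability_maps"
    seed: int = 0
    pixel_size_um: float = 0.629
    frame_interval_s: float = 10.0
    accumulation_end_frame: int = 33
    cell_prob_path: str | None = None
    centroid_path: str | None = None
    transmigration_path: str | None = None
    fluorescence_path: str | None = None
    segmentation: dict = field(default_factory=dict)
    tracking: dict = field(default_factory=dict)
    regimes: dict = field(default_factory=dict)
    selection: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.modality not in _MODALITIES:
            raise ValueError(f"modality must be one of {_MODALITIES}")
        for name, cls in (("segmentation", SegmentationThresholds),
                          ("tracking", TrackingConfig),
                          ("regimes", RegimeParams)):
            d = getattr(self, name)
            allowed = {f.name for f in dataclasses.fields(cls)}
            unknown = set(d) - allowed
            if unknown:
                raise ValueError(f"unknown {name} keys: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        allowed = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - allowed
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @property
    def hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:16]


def tracks_to_table(tracks, nodes) -> pd.DataFrame:
    """Flatten tracks into the standard per-frame track table."""
    rows = []
    for t in tracks:
        jump_frames = {f for (f, _, _) in t.jumps}
        for k, frame in enumerate(t.frames):
            nid = int(t.node_ids[k])
            rows.append({
                "track_id": t.track_id, "frame": int(frame),
                "x_um": float(t.positions[k, 0]),
                "y_um": float(t.positions[k, 1]),
                "area_px": nodes[nid].area_px if nid >= 0 else np.nan,
                "tc": nodes[nid].tc if nid >= 0 else np.nan,
                "is_jump": bool(frame in jump_frames),
                "flag": str(t.flags[k]),
            })
    return pd.DataFrame(rows, columns=["track_id", "frame", "x_um", "y_um",
                                       "area_px", "tc", "is_jump", "flag"])


def _load_stacks(cfg: RunConfig):
    common = dict(pixel_size_um=cfg.pixel_size_um,
                  frame_interval_s=cfg.frame_interval_s)
    if cfg.modality == "fluorescence":
        from .imaging import preprocess_fluorescence
        raw = read_stack(cfg.fluorescence_path, "fluorescence", **common)
        pre = preprocess_fluorescence(raw)
        # tracker-ready: intensity rescaled to [0, 1] stands in for the cell
        # probability; the same map supplies centroid peaks; no
        # transmigration detection without a second compartment
        cell = pre.frames / 255.0
        zeros = np.zeros_like(cell)
        return cell, cell, zeros
    cell = read_stack(cfg.cell_prob_path, "cell_prob", **common).frames
    cent = read_stack(cfg.centroid_path, "centroid", **common).frames
    trp = read_stack(cfg.transmigration_path, "transmigration_prob",
                     **common).frames
    return cell, cent, trp


def run_pipeline(cfg: RunConfig, out_dir) -> dict:
    """Execute preprocess → extract → track → analyze → summarize.

    Writes instances.csv, tracks.csv, analysis.csv, summary.json and a
    manifest (config copy + hash) into ``out_dir``; returns the summary.
    In the fluorescence modality the preprocessed intensity stands in for
    the cell probability and transmigration detection is skipped.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    seg_thr = SegmentationThresholds(**cfg.segmentation)
    trk_cfg = TrackingConfig(**cfg.tracking)
    prm = RegimeParams(**cfg.regimes)

    cell, cent, trp = _load_stacks(cfg)
    clock = AcquisitionClock(
        accumulation_end_frame=min(cfg.accumulation_end_frame, len(cell)),
        n_frames=len(cell))
    log.info("segmenting %d frames", len(cell))
    instances_by_frame = {
        t: extract_instances(cell[t], cent[t], trp[t], seg_thr, frame=t,
                             pixel_size_um=cfg.pixel_size_um)
        for t in range(len(cell))
    }
    instances_to_frame_table(instances_by_frame).to_csv(
        out / "instances.csv", index=False)

    log.info("tracking")
    tracks = reconstruct_tracks(instances_by_frame, trk_cfg, clock,
                                frame_interval_s=cfg.frame_interval_s)
    nodes = build_nodes(instances_by_frame, trk_cfg)
    tracks_to_table(tracks, nodes).to_csv(out / "tracks.csv", index=False)

    log.info("analyzing %d tracks", len(tracks))
    all_pos = np.array([n.pos for n in nodes]) if nodes else np.zeros((0, 2))
    bbox = (all_pos[:, 0].min(), all_pos[:, 1].min(),
            all_pos[:, 0].max(), all_pos[:, 1].max()) if len(all_pos) else \
        (0, 0, 0, 0)
    selected = select_tracks(tracks, clock, bbox, **cfg.selection)
    singles = [n.area_px for n in nodes if n.n_seeds <= 1] or [400.0]
    selected = filter_debris(selected, nodes, float(np.median(singles)))
    table = analyze_tracks(selected, nodes, clock, bbox, prm,
                           frame_interval_s=cfg.frame_interval_s,
                           gap_max=trk_cfg.gap_max)
    table.to_csv(out / "analysis.csv", index=False)

    summary = {
        "n_frames": len(cell),
        "n_instances": int(sum(len(v) for v in instances_by_frame.values())),
        "n_tracks": len(tracks),
        "n_selected_tracks": len(selected),
        "n_transmigration_events": int(table["n_full_transmigration"].sum())
        if len(table) else 0,
        "elapsed_s": round(time.time() - t0, 2),
    }
    if len(table):
        summary["behavior_fractions"] = \
            aggregate_behavior(table["category"]).fractions
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    with open(out / "manifest.json", "w") as fh:
        json.dump({"config": cfg.to_dict(), "config_hash": cfg.hash},
                  fh, indent=2, sort_keys=True)
    return summary
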