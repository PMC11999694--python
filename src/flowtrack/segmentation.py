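"""Per-frame cell instance extraction from probability / centroid maps.

The segmentation post-processing stage: threshold the cell-probability map,
seed a watershed with peaks of the centroid map to split touching cells,
drop small objects, and compute per-cell shape and transmigration features.

Feature conventions
-------------------
elongation
    ε = sqrt(Σ x'ᵢ² / Σ y'ᵢ²), where x' and y' are mask-pixel coordinates
    projected on the long and short principal axes (second central moments);
    axes are ordered so ε ≥ 1.
transmigration coefficient
    tc = (1/n_pix) Σ min(p_tr,i, p_cell,i) / p_cell,i over mask pixels; ~0 for
    a cell above the endothelial monolayer and ~1 once fully below it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.feature import peak_local_max
from skimage.segmentation import watershed

__all__ = [
    "CellInstance",
    "SegmentationThresholds",
    "extract_instances",
    "compute_elongation",
    "compute_transmigration_features",
    "calibrate_threshold",
    "calibrate_thresholds",
    "instances_to_frame_table",
]

ELONGATION_MAX = 100.0


@dataclass(frozen=True)
class SegmentationThresholds:
    """Thresholds of the segmentation post-processing.

    Defaults are used when no calibration reference is available; with
    reference masks they are selected by pixel-F1 grid search.
    """

    t_cell_mask: float = 0.5
    t_transmigration: float = 0.5
    t_centroid_peak: float = 0.3
    min_area_px: int = 30
    seed_min_distance_px: int = 4

    def __post_init__(self):
        for name in ("t_cell_mask", "t_transmigration", "t_centroid_peak"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValueError(f"{name} must be in (0, 1), got {v}")


@dataclass
class CellInstance:
    """One segmented cell in one frame."""

    frame: int
    pixels: np.ndarray          # (N, 2) int (y, x) coordinates, 8-connected
    centroid_px: tuple          # (y, x) arithmetic centroid in pixels
    centroid_um: tuple          # (x, y) in µm
    area_px: int
    angle_rad: float
    elongation: float
    p_cell_mean: float
    p_tr_mean: float
    tc: float
    label: int = 0
    n_seeds: int = 1
    bbox: tuple = field(default=None)  # type: ignore[assignment]

    @property
    def pos_um(self) -> np.ndarray:
        """Centroid as an (x, y) µm vector."""
        return np.asarray(self.centroid_um, dtype=float)


def compute_elongation(pixels: np.ndarray) -> tuple[float, float]:
    """Elongation ε and long-axis angle of a pixel mask.

    Principal axes are obtained from the second central moments of the pixel
    coordinates; ε = sqrt(larger/smaller axis moment) ≥ 1.  A degenerate
    short axis (e.g. a 1-px-wide line) caps ε at ``ELONGATION_MAX``; a single
    pixel has no orientation and returns (1, 0) with a warning.
    """
    pts = np.asarray(pixels, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 1:
        raise ValueError("pixels must be a non-empty (N, 2) array")
    if pts.shape[0] == 1:
        warnings.warn("single-pixel mask: orientation undefined")
        return 1.0, 0.0
    d = pts - pts.mean(axis=0)
    syy = float(np.sum(d[:, 0] ** 2))
    sxx = float(np.sum(d[:, 1] ** 2))
    sxy = float(np.sum(d[:, 0] * d[:, 1]))
    # eigenvalues of [[sxx, sxy], [sxy, syy]] (x first: angle measured from +x)
    tr, det = sxx + syy, sxx * syy - sxy**2
    disc = max(tr * tr / 4 - det, 0.0) ** 0.5
    lam1, lam2 = tr / 2 + disc, tr / 2 - disc
    if lam2 <= max(lam1, 1.0) * 1e-12:
        angle = 0.5 * np.arctan2(2 * sxy, sxx - syy)
        return ELONGATION_MAX, float(angle)
    eps = float(np.sqrt(lam1 / lam2))
    angle = 0.5 * np.arctan2(2 * sxy, sxx - syy)
    return eps, float(angle)


def compute_transmigration_features(pixels, cell_prob, tr_prob):
    """Mean probabilities and the transmigration coefficient over a mask.

    Pixels with p_cell = 0 inside the mask indicate a mask/probability
    inconsistency: they are excluded from the tc sum with a warning.
    """
    ys, xs = np.asarray(pixels)[:, 0], np.asarray(pixels)[:, 1]
    pc = np.asarray(cell_prob, dtype=float)[ys, xs]
    pt = np.asarray(tr_prob, dtype=float)[ys, xs]
    p_cell_mean = float(pc.mean())
    p_tr_mean = float(pt.mean())
    ok = pc > 0
    if not ok.all():
        warnings.warn(f"{(~ok).sum()} mask pixel(s) with p_cell=0 excluded from tc")
    if not ok.any():
        return p_cell_mean, p_tr_mean, 0.0
    tc = float(np.mean(np.minimum(pt[ok], pc[ok]) / pc[ok]))
    return p_cell_mean, p_tr_mean, min(max(tc, 0.0), 1.0)


def extract_instances(cell_prob, centroid_map, tr_prob,
                      thr: SegmentationThresholds | None = None,
                      frame: int = 0,
                      pixel_size_um: float = 0.629) -> list[CellInstance]:
    """Extract cell instances from one frame of the three map channels.

    Foreground = ``cell_prob ≥ t_cell_mask``.  Seeds are local maxima of the
    centroid map (3×3 non-max suppression, minimum separation
    ``seed_min_distance_px``) above ``t_centroid_peak``.  Connected foreground
    components holding ≥ 2 seeds are split by a watershed of the inverted
    cell probability; components without a seed are kept whole.  Objects
    below ``min_area_px`` (default 30 px; a typical cell covers ~400 px) are
    discarded as noise.
    """
    thr = thr or SegmentationThresholds()
    cell_prob = np.asarray(cell_prob, dtype=np.float32)
    tr_prob = np.asarray(tr_prob, dtype=np.float32)
    fg = cell_prob >= thr.t_cell_mask
    if not fg.any():
        return []
    peaks = peak_local_max(
        np.asarray(centroid_map, dtype=np.float32),
        min_distance=thr.seed_min_distance_px,
        threshold_abs=thr.t_centroid_peak,
        exclude_border=False,
    )
    seed_img = np.zeros(fg.shape, dtype=np.int32)
    peaks = peaks[fg[peaks[:, 0], peaks[:, 1]]] if len(peaks) else peaks
    for i, (py, px) in enumerate(peaks, start=1):
        seed_img[py, px] = i

    comp, n_comp = ndimage.label(fg, structure=np.ones((3, 3), dtype=int))
    objects = ndimage.find_objects(comp)
    regions = []  # (pixels (N,2) in frame coords, n_seeds)
    for ci in range(1, n_comp + 1):
        sl = objects[ci - 1]
        oy, ox = sl[0].start, sl[1].start
        sub_mask = comp[sl] == ci
        sub_seeds = np.where(sub_mask, seed_img[sl], 0)
        seed_ids = np.unique(sub_seeds)
        seed_ids = seed_ids[seed_ids > 0]
        if len(seed_ids) >= 2:
            markers, _ = ndimage.label(sub_seeds > 0)
            ws = watershed(-cell_prob[sl], markers, mask=sub_mask)
            for w in range(1, int(ws.max()) + 1):
                ys, xs = np.nonzero(ws == w)
                if len(ys):
                    regions.append((np.column_stack([ys + oy, xs + ox]), 1))
            ys, xs = np.nonzero(sub_mask & (ws == 0))
            if len(ys):
                regions.append((np.column_stack([ys + oy, xs + ox]), 0))
        else:
            ys, xs = np.nonzero(sub_mask)
            regions.append((np.column_stack([ys + oy, xs + ox]),
                            int(len(seed_ids))))

    instances: list[CellInstance] = []
    for pixels, n_seeds in regions:
        if len(pixels) < thr.min_area_px:
            continue
        ys, xs = pixels[:, 0], pixels[:, 1]
        cy, cx = float(ys.mean()), float(xs.mean())
        eps, ang = compute_elongation(pixels)
        pcm, ptm, tc = compute_transmigration_features(pixels, cell_prob, tr_prob)
        instances.append(CellInstance(
            frame=frame,
            pixels=pixels,
            centroid_px=(cy, cx),
            centroid_um=(cx * pixel_size_um, cy * pixel_size_um),
            area_px=len(ys),
            angle_rad=ang,
            elongation=eps,
            p_cell_mean=pcm,
            p_tr_mean=ptm,
            tc=tc,
            label=len(instances) + 1,
            n_seeds=max(n_seeds, 1),
            bbox=(int(ys.min()), int(xs.min()), int(ys.max()) + 1, int(xs.max()) + 1),
        ))
    return instances


def _pixel_f1(pred: np.ndarray, ref: np.ndarray) -> float:
    tp = np.count_nonzero(pred & ref)
    fp = np.count_nonzero(pred & ~ref)
    fn = np.count_nonzero(~pred & ref)
    denom = 2 * tp + fp + fn
    return 2 * tp / denom if denom else 1.0


def calibrate_threshold(prob, reference_mask, grid=None):
    """Pick the probability threshold maximising pixel F1 vs a reference mask.

    The grid runs over (0, 1) in steps of 0.01; ties resolve to the lowest
    threshold.  Returns ``(threshold, best_f1)``.
    """
    prob = np.asarray(prob, dtype=float)
    ref = np.asarray(reference_mask).astype(bool)
    grid = np.round(np.arange(0.01, 1.0, 0.01), 2) if grid is None else grid
    best_t, best_f1 = float(grid[0]), -1.0
    for t in grid:
        f1 = _pixel_f1(prob >= t, ref)
        if f1 > best_f1 + 1e-12:
            best_t, best_f1 = float(t), f1
    return best_t, best_f1


def calibrate_thresholds(prob_stacks: dict, reference_masks: dict,
                         defaults: SegmentationThresholds | None = None
                         ) -> SegmentationThresholds:
    """Grid-search cell/transmigration thresholds against reference masks.

    ``prob_stacks`` and ``reference_masks`` map kind names (``cell_prob``,
    ``transmigration_prob``) to arrays.  Missing or empty references leave
    the corresponding default unchanged (with a warning); a best F1 below 0.5
    is flagged as a probable inverted or mismatched map.
    """
    defaults = defaults or SegmentationThresholds()
    values = {"t_cell_mask": defaults.t_cell_mask,
              "t_transmigration": defaults.t_transmigration}
    for kind, attr in (("cell_prob", "t_cell_mask"),
                       ("transmigration_prob", "t_transmigration")):
        ref = reference_masks.get(kind)
        prob = prob_stacks.get(kind)
        if ref is None or prob is None or np.asarray(ref).size == 0:
            warnings.warn(f"no reference for {kind}; keeping default {attr}")
            continue
        t, f1 = calibrate_threshold(np.asarray(prob), np.asarray(ref))
        if f1 < 0.5:
            warnings.warn(f"{kind}: best F1 {f1:.2f} < 0.5 — check the input maps")
        values[attr] = t
    return SegmentationThresholds(
        t_cell_mask=values["t_cell_mask"],
        t_transmigration=values["t_transmigration"],
        t_centroid_peak=defaults.t_centroid_peak,
        min_area_px=defaults.min_area_px,
        seed_min_distance_px=defaults.seed_min_distance_px,
    )


def instances_to_frame_table(instances_by_frame: dict) -> pd.DataFrame:
    """Flatten per-frame instance lists into the standard instance table."""
    rows = []
    for frame, instances in sorted(instances_by_frame.items()):
        for inst in instances:
            rows.append({
                "frame": frame, "id": inst.label,
                "x_um": inst.centroid_um[0], "y_um": inst.centroid_um[1],
                "area_px": inst.area_px, "angle_rad": inst.angle_rad,
                "elongation": inst.elongation, "p_cell_mean": inst.p_cell_mean,
                "p_tr_mean": inst.p_tr_mean, "tc": inst.tc,
            })
    cols = ["frame", "id", "x_um", "y_um", "area_px", "angle_rad",
            "elongation", "p_cell_mean", "p_tr_mean", "tc"]
    return pd.DataFrame(rows, columns=cols)
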