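"""Image-stack I/O, frame alignment, tile stitching and fluorescence preprocessing.

All stacks are held as :class:`MapStack`: a ``(T, H, W)`` float32 array plus
acquisition metadata.  Coordinates follow the ``(y, x)`` = (row, col)
convention with *y* increasing downward; the flow direction is +x.  Physical
distances are expressed in micrometres via ``pixel_size_um``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import tifffile
from scipy import ndimage
from skimage import exposure, filters
from skimage.registration import phase_cross_correlation

__all__ = [
    "MapStack",
    "AcquisitionClock",
    "StackFormatError",
    "read_stack",
    "write_stack",
    "align_frames",
    "stitch_tiles",
    "preprocess_fluorescence",
    "normalize_histogram",
]

#: value ranges accepted per stack kind
_KIND_RANGES = {
    "cell_prob": (0.0, 1.0),
    "centroid": (0.0, 1.0),
    "transmigration_prob": (0.0, 1.0),
    "fluorescence": (0.0, 255.0),
    "phase": (0.0, 255.0),
}

PROB_KINDS = ("cell_prob", "centroid", "transmigration_prob")

DEFAULT_PIXEL_SIZE_UM = 0.629
DEFAULT_FRAME_INTERVAL_S = 10.0


class StackFormatError(ValueError):
    """Raised when input frames are inconsistent or out of range."""


@dataclass
class MapStack:
    """A time-lapse stack of single-channel scalar maps.

    Parameters
    ----------
    frames
        ``(T, H, W)`` float32 array.  Probability kinds live in [0, 1],
        fluorescence/phase in [0, 255].
    pixel_size_um
        Lateral pixel size in µm/px (> 0).
    frame_interval_s
        Time between consecutive frames in seconds (> 0).
    kind
        One of ``cell_prob``, ``centroid``, ``transmigration_prob``,
        ``fluorescence``, ``phase``.
    origin_offset_px
        Per-frame ``(dy, dx)`` integer alignment shifts relative to frame 0.
    """

    frames: np.ndarray
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    frame_interval_s: float = DEFAULT_FRAME_INTERVAL_S
    kind: str = "cell_prob"
    origin_offset_px: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=np.float32)
        if self.frames.ndim != 3 or self.frames.shape[0] < 1:
            raise StackFormatError("frames must be a non-empty (T, H, W) array")
        if self.pixel_size_um <= 0 or self.frame_interval_s <= 0:
            raise StackFormatError("pixel_size_um and frame_interval_s must be > 0")
        if self.kind not in _KIND_RANGES:
            raise StackFormatError(f"unknown stack kind {self.kind!r}")
        lo, hi = _KIND_RANGES[self.kind]
        vmin, vmax = float(self.frames.min()), float(self.frames.max())
        if vmin < lo - 1e-6 or vmax > hi + 1e-6:
            raise StackFormatError(
                f"{self.kind} values [{vmin:.3g}, {vmax:.3g}] outside [{lo}, {hi}]"
            )
        if self.origin_offset_px is None:
            self.origin_offset_px = np.zeros((len(self.frames), 2), dtype=int)
        else:
            self.origin_offset_px = np.asarray(self.origin_offset_px, dtype=int)

    def __len__(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self):
        return self.frames.shape

    @property
    def fov_um(self):
        """(width, height) of the field of view in µm."""
        _, h, w = self.frames.shape
        return (w * self.pixel_size_um, h * self.pixel_size_um)


@dataclass(frozen=True)
class AcquisitionClock:
    """Phase boundaries of the assay.

    ``accumulation_end_frame`` is the first frame analysed under physiological
    flow (the cells arrested by then define the cohort); frames before it
    belong to the low-shear accumulation phase.
    """

    accumulation_end_frame: int = 33
    n_frames: int = 160

    def __post_init__(self):
        if not (0 <= self.accumulation_end_frame <= self.n_frames):
            raise ValueError("require 0 <= accumulation_end_frame <= n_frames")

    def is_flow_frame(self, frame: int) -> bool:
        return frame >= self.accumulation_end_frame


def read_stack(paths, kind, pixel_size_um=DEFAULT_PIXEL_SIZE_UM,
               frame_interval_s=DEFAULT_FRAME_INTERVAL_S) -> MapStack:
    """Read a multipage TIFF (or an ordered list of TIFFs) into a MapStack.

    Frames are stacked in temporal order; shapes must agree and values must
    lie in the range dictated by ``kind``.
    """
    if isinstance(paths, (str, bytes)) or hasattr(paths, "__fspath__"):
        paths = [paths]
    paths = list(paths)
    if not paths:
        raise StackFormatError("empty input: no stack files given")
    frames = []
    for p in paths:
        arr = tifffile.imread(p)
        if arr.ndim == 2:
            arr = arr[None]
        elif arr.ndim != 3:
            raise StackFormatError(f"{p}: expected 2D or 3D TIFF, got ndim={arr.ndim}")
        frames.append(np.asarray(arr, dtype=np.float32))
    shapes = {f.shape[1:] for f in frames}
    if len(shapes) != 1:
        raise StackFormatError(f"mismatched frame shapes: {sorted(shapes)}")
    data = np.concatenate(frames, axis=0)
    return MapStack(data, pixel_size_um=pixel_size_um,
                    frame_interval_s=frame_interval_s, kind=kind)


def write_stack(stack: MapStack, path, sidecar: bool = True) -> None:
    """Write a MapStack to a multipage float32 TIFF.

    With ``sidecar=True`` a JSON file next to the TIFF records pixel size,
    frame interval, kind and the per-frame alignment offsets so a read
    round-trips losslessly.
    """
    tifffile.imwrite(path, stack.frames.astype(np.float32),
                     photometric="minisblack")
    if sidecar:
        meta = {
            "pixel_size_um": stack.pixel_size_um,
            "frame_interval_s": stack.frame_interval_s,
            "kind": stack.kind,
            "origin_offset_px": stack.origin_offset_px.tolist(),
        }
        with open(str(path) + ".json", "w") as fh:
            json.dump(meta, fh)


def _shift_int(frame: np.ndarray, dy: int, dx: int) -> np.ndarray:
    """Translate by whole pixels, zero-filling uncovered borders."""
    out = np.zeros_like(frame)
    h, w = frame.shape
    ys = slice(max(0, dy), min(h, h + dy))
    xs = slice(max(0, dx), min(w, w + dx))
    ys_src = slice(max(0, -dy), min(h, h - dy))
    xs_src = slice(max(0, -dx), min(w, w - dx))
    out[ys, xs] = frame[ys_src, xs_src]
    return out


def _norm_corr_at(a: np.ndarray, b: np.ndarray, dy: int, dx: int) -> float:
    """Normalised correlation of a and b after shifting b by (dy, dx)."""
    bs = _shift_int(b, dy, dx)
    am = a - a.mean()
    bm = bs - bs.mean()
    denom = np.linalg.norm(am) * np.linalg.norm(bm)
    if denom == 0:
        return 0.0
    return float(np.vdot(am, bm) / denom)


def align_frames(stack: MapStack, reference_masks: MapStack | None = None,
                 min_confidence: float = 0.2, max_shift_px: int = 10) -> MapStack:
    """Estimate per-frame integer translation offsets and resample frames.

    Shifts are estimated by phase correlation between consecutive frames (of
    ``reference_masks`` when given, otherwise of the stack itself) and
    accumulated relative to frame 0.  Shifts are rounded to whole pixels.  If
    the normalised correlation at the estimated shift falls below
    ``min_confidence`` the frame keeps a zero incremental offset and a warning
    is emitted.
    """
    if len(stack) < 2:
        raise ValueError("alignment needs at least 2 frames")
    src = reference_masks.frames if reference_masks is not None else stack.frames
    offsets = np.zeros((len(stack), 2), dtype=int)
    cum = np.zeros(2, dtype=int)
    for t in range(1, len(stack)):
        shift, _, _ = phase_cross_correlation(src[t - 1], src[t], normalization=None)
        dy, dx = int(round(shift[0])), int(round(shift[1]))
        if abs(dy) > max_shift_px or abs(dx) > max_shift_px:
            dy = dx = 0
        conf = _norm_corr_at(src[t - 1], src[t], dy, dx)
        if conf < min_confidence:
            warnings.warn(
                f"frame {t}: alignment confidence {conf:.2f} < {min_confidence}; "
                "keeping zero offset")
            dy = dx = 0
        cum = cum + (dy, dx)
        offsets[t] = cum
    aligned = np.stack([
        _shift_int(stack.frames[t], offsets[t, 0], offsets[t, 1])
        for t in range(len(stack))
    ])
    out = replace(stack, frames=aligned)
    out.origin_offset_px = offsets
    return out


def _feather_weights(h: int, w: int, ramp: int) -> np.ndarray:
    """Weight map ramping linearly from 0 at the tile border to 1 inside."""
    wy = np.minimum(np.arange(h) + 1, np.arange(h)[::-1] + 1)
    wx = np.minimum(np.arange(w) + 1, np.arange(w)[::-1] + 1)
    wy = np.clip(wy / max(ramp, 1), 0, 1)
    wx = np.clip(wx / max(ramp, 1), 0, 1)
    return np.outer(wy, wx).astype(np.float32)


def stitch_tiles(tiles, layout, overlap_um: float = 100.0,
                 search_margin_px: int = 8, match_threshold: float = 0.5) -> MapStack:
    """Stitch a grid of tile stacks into one stack.

    Parameters
    ----------
    tiles
        List of MapStacks sharing kind, pixel size and frame count.
    layout
        ``(n_rows, n_cols)``; tiles are listed row-major.
    overlap_um
        Nominal overlap between adjacent tiles (default 100 µm, matching a
        tiled acquisition of 870×650 µm tiles on a ~3170×1220 µm canvas).

    Offsets between adjacent tiles are refined by maximising normalised
    correlation of the shared overlap strip (first frame) within
    ``±search_margin_px`` of the nominal offset; a match score below
    ``match_threshold`` falls back to the nominal layout offset with a
    warning.  Overlap pixels are blended with feathered averaging.
    """
    n_rows, n_cols = layout
    if len(tiles) != n_rows * n_cols:
        raise ValueError("layout does not match the number of tiles")
    if len(tiles) == 1:
        return tiles[0]
    base = tiles[0]
    if any(t.kind != base.kind or len(t) != len(base) for t in tiles):
        raise StackFormatError("tiles must share kind and frame count")
    px = base.pixel_size_um
    ov = int(round(overlap_um / px))
    th, tw = base.frames.shape[1:]

    # nominal tile origins
    origins = {}
    for r in range(n_rows):
        for c in range(n_cols):
            origins[(r, c)] = np.array([r * (th - ov), c * (tw - ov)], dtype=int)

    # refine each tile against its left/top neighbour on frame 0
    for r in range(n_rows):
        for c in range(n_cols):
            if r == 0 and c == 0:
                continue
            nb = (r, c - 1) if c > 0 else (r - 1, c)
            a = tiles[nb[0] * n_cols + nb[1]].frames[0]
            b = tiles[r * n_cols + c].frames[0]
            nominal = origins[(r, c)] - origins[nb]
            best = (nominal, -np.inf)
            for dy in range(-search_margin_px, search_margin_px + 1):
                for dx in range(-search_margin_px, search_margin_px + 1):
                    off = nominal + (dy, dx)
                    score = _overlap_score(a, b, off)
                    if score > best[1]:
                        best = (off, score)
            if best[1] < match_threshold:
                warnings.warn(
                    f"tile {(r, c)}: overlap match score {best[1]:.2f} below "
                    f"{match_threshold}; using nominal offset")
                best = (nominal, best[1])
            origins[(r, c)] = origins[nb] + best[0]

    oy = np.array([o[0] for o in origins.values()])
    ox = np.array([o[1] for o in origins.values()])
    H = int(oy.max()) + th
    W = int(ox.max()) + tw
    weights = _feather_weights(th, tw, ramp=max(ov, 1))
    out = np.zeros((len(base), H, W), dtype=np.float32)
    wsum = np.zeros((H, W), dtype=np.float32)
    for (r, c), o in origins.items():
        tile = tiles[r * n_cols + c].frames
        out[:, o[0]:o[0] + th, o[1]:o[1] + tw] += tile * weights
        wsum[o[0]:o[0] + th, o[1]:o[1] + tw] += weights
    out /= np.maximum(wsum, 1e-12)
    lo, hi = _KIND_RANGES[base.kind]
    np.clip(out, lo, hi, out=out)
    return MapStack(out, pixel_size_um=px, frame_interval_s=base.frame_interval_s,
                    kind=base.kind)


def _overlap_score(a: np.ndarray, b: np.ndarray, offset) -> float:
    """Normalised correlation of the region where tile b (at offset) overlaps a."""
    dy, dx = int(offset[0]), int(offset[1])
    h, w = a.shape
    y0, y1 = max(0, dy), min(h, dy + b.shape[0])
    x0, x1 = max(0, dx), min(w, dx + b.shape[1])
    if y1 - y0 < 4 or x1 - x0 < 4:
        return -np.inf
    ra = a[y0:y1, x0:x1]
    rb = b[y0 - dy:y1 - dy, x0 - dx:x1 - dx]
    ra = ra - ra.mean()
    rb = rb - rb.mean()
    denom = np.linalg.norm(ra) * np.linalg.norm(rb)
    if denom == 0:
        return 0.0
    return float(np.vdot(ra, rb) / denom)


def preprocess_fluorescence(stack: MapStack, sigma: float = 0.75,
                            clip_abundance: float = 0.003,
                            background_threshold=None) -> MapStack:
    """Turn a raw fluorescence stack into tracker-ready 0–255 intensity maps.

    Per frame: Gaussian blur (σ = 0.75 px), background-threshold subtraction
    (Otsu on the blurred frame unless ``background_threshold`` is given),
    clipping of rare bright values — intensities whose histogram abundance is
    below ``clip_abundance`` (0.3%) of the abundance at the background
    threshold — and a linear rescale to [0, 255].
    """
    if stack.kind != "fluorescence":
        raise ValueError("preprocess_fluorescence expects kind='fluorescence'")
    out = np.zeros_like(stack.frames)
    for t, frame in enumerate(stack.frames):
        blurred = ndimage.gaussian_filter(frame, sigma=sigma)
        if np.ptp(blurred) == 0:
            warnings.warn(f"frame {t}: constant intensity; output zeroed")
            continue
        thr = (background_threshold if background_threshold is not None
               else filters.threshold_otsu(blurred))
        sub = np.clip(blurred - thr, 0, None)
        counts, edges = np.histogram(blurred, bins=256)
        thr_bin = min(np.searchsorted(edges, thr, side="right") - 1, 255)
        fg_bins = np.nonzero(counts[thr_bin + 1:])[0] + thr_bin + 1
        if len(fg_bins) == 0:
            clip_val = max(sub.max(), 1e-12)
        else:
            # the "threshold abundance" is the histogram count just above the
            # background threshold; brightness bins rarer than 0.3% of it are
            # the outlier tail and get clipped
            ref_abundance = counts[fg_bins[0]]
            abundant = fg_bins[counts[fg_bins] >= clip_abundance * ref_abundance]
            clip_val = edges[abundant.max() + 1] - thr if len(abundant) \
                else max(sub.max(), 1e-12)
        if clip_val <= 0:
            clip_val = max(sub.max(), 1e-12)
        sub = np.minimum(sub, clip_val)
        out[t] = sub / clip_val * 255.0
    return MapStack(out, pixel_size_um=stack.pixel_size_um,
                    frame_interval_s=stack.frame_interval_s, kind="fluorescence")


def normalize_histogram(stack: MapStack, reference: np.ndarray | None = None,
                        nbins: int = 256) -> MapStack:
    """Monotone per-frame intensity remap matching cumulative histograms.

    ``reference`` may be a 2D reference frame; by default the first frame of
    the stack is used.  The remap is the standard CDF-matching construction
    (via :func:`skimage.exposure.match_histograms`), hence monotone and
    idempotent on frames that already match the reference.
    """
    ref = stack.frames[0] if reference is None else np.asarray(reference)
    out = np.stack([
        exposure.match_histograms(frame, ref).astype(np.float32)
        for frame in stack.frames
    ])
    lo, hi = _KIND_RANGES[stack.kind]
    np.clip(out, lo, hi, out=out)
    return replace(stack, frames=out)
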