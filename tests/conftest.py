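"""Shared fixtures and factories for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from flowtrack.segmentation import CellInstance
from flowtrack.tracking import Track


def make_instance(frame, x_um, y_um, area_px=400, elongation=1.5,
                  p_cell_mean=0.9, tc=0.0, n_seeds=1,
                  pixel_size_um=0.629) -> CellInstance:
    """Minimal CellInstance for tracking/analysis tests (synthetic mask)."""
    area_px = int(round(area_px))
    side = max(int(round(np.sqrt(area_px))), 2)
    cy, cx = int(round(y_um / pixel_size_um)), int(round(x_um / pixel_size_um))
    ys, xs = np.mgrid[cy:cy + side, cx:cx + side]
    pixels = np.column_stack([ys.ravel(), xs.ravel()])[:area_px]
    return CellInstance(
        frame=frame, pixels=pixels, centroid_px=(y_um / pixel_size_um,
                                                 x_um / pixel_size_um),
        centroid_um=(x_um, y_um), area_px=area_px, angle_rad=0.0,
        elongation=elongation, p_cell_mean=p_cell_mean, p_tr_mean=tc,
        tc=tc, n_seeds=n_seeds,
        bbox=(int(pixels[:, 0].min()), int(pixels[:, 1].min()),
              int(pixels[:, 0].max()) + 1, int(pixels[:, 1].max()) + 1))


def make_track(track_id, frames, xy, flags=None, jumps=None,
               node_ids=None) -> Track:
    """Construct a Track directly from per-frame positions."""
    frames = np.asarray(frames, dtype=int)
    xy = np.asarray(xy, dtype=float)
    if flags is None:
        flags = np.array(["assigned"] * len(frames), dtype=object)
    else:
        flags = np.asarray(flags, dtype=object)
    if node_ids is None:
        node_ids = np.where(flags == "assigned",
                            np.arange(len(frames)), -1)
    return Track(track_id=track_id, frames=frames, positions=xy,
                 node_ids=np.asarray(node_ids, dtype=int), flags=flags,
                 jumps=list(jumps or []))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def selection_fixture():
    """20 constructed tracks with hand-audited keep/drop decisions.

    Bounding box (0,0)-(1000,800) µm, flow phase from frame 33 of 160.
    Returns ``(tracks, expected_keep)``.
    """
    def base(tid, start=33, n=40, x0=500.0, y0=400.0, step=1.0, gap_every=0):
        frames = np.arange(start, start + n)
        xy = np.column_stack([x0 + step * np.arange(n), np.full(n, y0)])
        flags = np.array(["assigned"] * n, dtype=object)
        if gap_every:
            flags[::gap_every] = "gap"
            xy[flags == "gap"] = np.nan
        return make_track(tid, frames, xy, flags)

    tracks, expected = [], []
    for i in range(10):                      # clean mid-field: keep
        tracks.append(base(i, y0=100.0 + 50 * i))
        expected.append(True)
    t = base(10)                             # 10 µm from the x edge: drop
    t.positions[5] = (10.0, 400.0)
    tracks.append(t); expected.append(False)
    t = base(11)                             # 10 µm from the y edge: drop
    t.positions[-1] = (500.0, 790.0)
    tracks.append(t); expected.append(False)
    t = base(12)                             # exactly on the margin: keep
    t.positions[0] = (25.0, 400.0)
    tracks.append(t); expected.append(True)
    tracks.append(base(13, start=28, n=10))  # 5 flow frames: drop
    expected.append(False)
    tracks.append(base(14, start=27, n=12))  # exactly 6 flow frames: keep
    expected.append(True)
    tracks.append(base(15, gap_every=2))     # 50% assigned: drop
    expected.append(False)
    tracks.append(base(16, gap_every=5))     # 80% assigned: keep
    expected.append(True)
    tracks.append(base(17, start=0, n=30))   # accumulation only: drop
    expected.append(False)
    tracks.append(base(18, n=100))           # long clean: keep
    expected.append(True)
    tracks.append(base(19, n=6))             # minimal flow support: keep
    expected.append(True)
    return tracks, expected
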