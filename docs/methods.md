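# Methods

This note documents the models, parameters and design choices behind
`flowtrack`: what each stage computes, why the defaults are what they are,
and what the synthetic benchmark does and does not establish about real
data.

## Setting and conventions

The pipeline targets time-lapse assays of immune cells interacting with an
endothelial monolayer in a flow chamber. The default geometry is
0.629 µm/pixel and 10 s/frame; a low-shear accumulation phase is followed by
physiological flow, and analysis of arrested cells starts at the first flow
frame (`AcquisitionClock.accumulation_end_frame`, default 33 for the
standard acquisition protocol). Coordinates are (x, y) in µm with flow along
+x; pixel indices are 0-based (row, col) with half-open boxes. All distances
are reported in µm, speeds in µm/min.

## Instance extraction

Foreground is `p_cell ≥ t_cell_mask` (default 0.5). Seeds are local maxima
of the centroid map above `t_centroid_peak` (default 0.3) with 3×3 non-max
suppression and a 4 px minimum separation — the centroid channel is peaked
and smooth, so a small suppression radius suffices. Foreground components
holding ≥ 2 seeds are split by a watershed of the *inverted* cell
probability restricted to the component (flooding from the seeds); a
component without seeds is kept whole rather than discarded, since a missed
centroid peak should not delete a cell. Objects under `min_area_px = 30` are
treated as noise (a typical cell covers ~400 px). Components are
8-connected: elongated cells often touch diagonally through thin
protrusions.

Per-cell features: the centroid is the arithmetic mean of mask pixel
coordinates; the orientation and elongation come from the second central
moments, with axes ordered so that ε = sqrt(larger/smaller) ≥ 1, capped at
100 for degenerate (1-px-wide) masks. The transmigration coefficient
`t_c = mean(min(p_tr, p_cell)/p_cell)` is bounded in [0, 1] by construction;
mask pixels with `p_cell = 0` indicate a mask/probability inconsistency and
are excluded with a warning rather than propagating NaNs.

When reference masks are available, `t_cell_mask` and `t_transmigration`
are calibrated by maximizing pixel F1 on a 0.01-step grid over (0, 1), ties
resolving to the lowest threshold (the most inclusive of equally good
choices).

## Tracking

### Candidate links

All detection pairs in adjacent frames within `r_link_um = 15` µm are
candidate links — generous relative to crawling (≤ 10 µm/min ≈ 1.7 µm/frame)
so that moderate flow displacement stays linkable, while jumps beyond it are
handled separately. Link cost is `w_d·distance + w_f·dissimilarity` with
`w_d = 1 /µm`, `w_f = 10` and dissimilarity the sum of relative area
difference, relative elongation difference and |Δp̄_cell| (each in [0, 1]).

### The conservation program

Under-segmentation is modelled by an integer node multiplicity: the estimate
`m_est` is the larger of the number of centroid seeds inside the mask and
the area divided by the median single-cell area (rounded, ≥ 1), capped at
`m_max = 4`; larger clumps are declared unresolvable. The allowed range is
`m_est ± 1` (clipped to [0, cap]), so a spurious detection can resolve to
multiplicity 0 and a slightly under-estimated clump can grow by one.

The program selects integer link flows `f_e`, node usages `μ_i`, and
appearance/disappearance slack `a_i, d_i ≥ 0` minimizing

```
Σ_e f_e·cost_e + Σ_i [ c_app,i·a_i + c_dis,i·d_i + c_dev·|μ_i − m_est,i| ]
s.t.  Σ_in f + a_i = μ_i = Σ_out f + d_i ,   μ_i ∈ [m_min,i, m_max,i]
```

with `c_app = c_dis = 20` (an appearance must be "worth" about a 20 µm link)
and `c_dev = 10` per node. Appearance in the first frame and disappearance
in the last are free. Near the field-of-view boundary the costs are
discounted by `floor + (1−floor)(1 − exp(−d/λ))` with `λ = 50 µm` and
`floor = 0.2` — the *discount* decays with distance to the edge, so washing
in/out at the boundary is cheap while mid-field appearance stays expensive.
During accumulation and the first 3 frames after the flow increase the
costs are halved (cells genuinely wash in and out then). The program
decomposes over connected components of the link graph and each component is
solved to proven optimality with HiGHS (`scipy.optimize.milp`); isolated
nodes are solved in closed form. HiGHS is deterministic for a fixed model,
which, together with sorted link construction and index-based tie-breaking,
makes the whole tracker reproducible bit-for-bit.

### Segments, consistency, jumps

Selected flows are condensed into *segments* — maximal unbranched node runs
with constant multiplicity, additionally split where a selected link spans
≥ 8 µm (a sudden displacement is an ambiguous point, not an interior of a
segment). The same conservation program is re-solved with segments as items
(deviation cost scaled by segment length, so a long segment is not zeroed
out to save one appearance). Then unterminated segment ends and starts are
candidate *jumps*: temporal gap ≤ `gap_max = 3` frames, displacement
≥ 8 µm, implied speed > 30 µm/min (well above crawling), cost
`w_d·disp·(1 + β(1 − cos θ)) + w_f·dissimilarity` with β = 1 penalizing
against-flow directions, accepted below `jump_cost_max = 60` (roughly the
cost of the disappearance + appearance pair a jump replaces), matched
greedily by ascending cost. Finally segments with multiplicity 0 and
unconnected segments shorter than `len_min = 3` frames are removed as
unreliable.

### Intersections

Regions of multiplicity ≥ 2 segments are under-segmented intersections.
When a region with branch multiplicity n has exactly n incoming and n
outgoing multiplicity-1 segments, the identities are extended one vertex
deep into the region and matched one-to-one by the Hungarian algorithm on
feature dissimilarity of the flanking segment ends plus positional drift;
ties break deterministically toward lower segment ids. Matched flanks
become one track whose intersection interval carries the merged detections'
positions flagged `undersegmented` (excluded from motility but usable for
identity scoring); non-extensible matched regions leave a gap; unequal
counts terminate all tracks at the region.

## Migration analysis

Track selection mirrors the standard analysis filters: every assigned
position ≥ 25 µm inside the bounding box of all detections, ≥ 6 assigned
frames in the flow phase, ≥ 75 % of the span assigned, and no mask
adjacency (within 1 px) to another cell at the final frame. Debris is
removed by a rule-based filter (median p̄_cell < 0.6, or median area < 30 %
of the single-cell area, or immobile with ε > 5); these thresholds are
configuration, standing in for a learned artifact classifier.

Above/below-monolayer state follows `t_c` with hysteresis: a *full
transmigration* requires `t_c ≥ 0.95` sustained for ≥ 3 frames (diapedesis
takes minutes, so a single high frame is noise); an excursion above 0.25
for ≥ 2 frames that falls back below 0.1 without completing is an
*uncompleted attempt*; a completed cell whose `t_c` later drops below 0.1
is flagged as reverse transmigration and returns to the above state.

Probing vs crawling uses a sliding-window geometric test: a frame is
probing when some window of `window_frames` consecutive assigned frames
covering it stays within 20 µm (≈ two cell sizes) of the window's first
position. The window default is 36 frames (6 min): crawling spans
3–10 µm/min, and only a window long enough for a crawler to traverse the
20 µm radius discriminates the two regimes — a 2-minute window cannot, since
even the fastest crawler covers at most ~20 µm in it. Frames reached by a
jump are `accelerated`; below-monolayer locomotion is `crawling_below`.

Behaviour categories are decided in order: terminal accelerated
movement/disappearance away from the boundary → *detached*; exit through
the fiducial boundary → *out of FoV*; full transmigration →
*crawling/probing full transmigration* by the majority pre-event regime;
attempts only → the *uncompleted* variants; otherwise *probing* or
*crawling* by overall majority.

Motility is computed per scope (probing before transmigration, crawling
before transmigration, all crawling above, all crawling below, whole track
excluding accelerated movement, whole track): path length sums steps
between successive in-scope frames at most `gap_max` frames apart (gaps
bridged straight; steps that would bridge across an accelerated frame are
excluded from all scopes except the whole track); migration speed is
displacement over time, crawling speed path over time, and the meandering
index displacement over path (0 for a closed loop, defined as 0 when the
path is 0). Accelerated-movement metrics aggregate per-jump displacement,
time and the displacement-weighted mean speed — a proxy for adhesion
strength.

## Cohort statistics

Behaviour fractions are reported over the selected ("arrested = 100 %")
cohort with the binomial standard error `sqrt(p(1−p)/N)`. Distribution
comparisons use the two-sided Mann–Whitney U test: exact null for
min(n) ≤ 20 without ties, normal approximation with tie/continuity
correction otherwise, with the conventional ns/*/**/***/**** tiers at
0.05/0.01/0.001/0.0001. Cross-tile duplicate removal uses the fin/fout
identity criterion evaluated over the first track's assigned frames
(frames where the other track is absent count as "far"); the printed
inequality `f_in > 0.5·f_out − 0.8` alone is satisfied almost everywhere on
[0,1]², so the default adds the guard `f_in ≥ 0.5`; both the coefficients
and guard are configurable, including the literal form.

## Synthetic benchmark

The generator emulates: seeding at 50–80 cells/mm² (Poisson), cell areas
~N(400, 60²) px clipped to [150, 900], elongations U(1.1, 2.5); crawling as
a persistent random walk (speed U(3, 10) µm/min, heading diffusion 0.35
rad/frame); probing as a mean-reverting walk confined within 8 µm of an
anchor (safely inside the 20 µm definition); transmigration as a linear
`t_c` ramp over U(18, 30) frames (3–5 min) followed by crawling below;
jumps of U(8, 30) µm downstream (rate 0.05 /cell/min) that move the probing
anchor with the cell; detachment (0.01 /cell/min) ending the track;
appearances (0.3 /mm²/min); and touching cells — a companion placed ~7 µm
from a host, moving with it for 10–30 frames before separating — producing
genuine under-segmentation. Above-monolayer truth *labels* are assigned by
the same windowed geometric probing definition applied to the true
trajectory: the simulator's motion states set the dynamics, but the label a
perfect observer would assign follows the operative definition, so the
benchmark's regime-accuracy figure measures pipeline degradation rather
than a definitional mismatch.

Rendering draws each cell as an anisotropic Gaussian whose 0.5-contour
matches its area and elongation (cell probability = clipped sum + Gaussian
noise, σ = 0.05 by default), 1.5 px centroid peaks, and the footprint
scaled by `t_c` for the transmigration channel — so the `t_c` formula
round-trips exactly in the noiseless case.

Scoring: a truth track (with ≥ 6 assigned frames, the analyzable-track
floor) is matched to a reconstruction when the fin/fout criterion holds;
matching is greedy one-to-one by descending f_in. Track reconstruction
efficiency is the matched fraction of truth tracks; detection efficiency is
the per-frame fraction of truth positions with an instance centroid within
17 µm.

What passing does **not** show: the renderer contains no phase-contrast
texture, no endothelial background, no illumination drift, and its
probability maps are better calibrated than any segmentation network's
output; real-data efficiency therefore depends on upstream segmentation
quality in a way the benchmark cannot probe. Cell division is not modelled
(and not handled by the tracker).

## Problem sizes and numerical choices

The shipped benchmark figures (`scripts/acceptance.py`) use 20 scenes of
600×420 µm × 160 frames with densities spanning 50–80 cells/mm² — about
16 cells per scene, chosen so the full recomputation takes minutes on a
single CPU while every event type (jumps, detachments, touching cells,
transmigrations) occurs many times per run. The test suite uses the same
conditions at 2–3 scenes plus noiseless round-trip scenes.

Numerical conventions: sub-pixel alignment shifts are rounded to integers
(tracking thresholds are in µm, ≫ 1 px); the deviation variable in the ILP
is continuous (its optimum is integral given integer μ); solver input
ordering is sorted and all tie-breaks are index-based, making outputs
bit-reproducible across runs; degenerate inputs (empty frames, single-pixel
masks, constant fluorescence frames, empty scopes) return defined empty
values with warnings rather than raising.

## Known limitations

- Multiplicity is capped at 4; larger clumps terminate tracks.
- Jump search considers temporal gaps up to 3 frames; longer occlusions
  split tracks.
- The debris filter is a fixed rule set, not a learned classifier.
- Reverse transmigration is flagged but not analysed statistically.
- Tile stitching assumes translation-only offsets.
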