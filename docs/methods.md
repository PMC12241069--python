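# Methods

## Scope and coordinate conventions

`hemidia` operates on temporally ordered binary lung-field masks (one per
DCR frame); segmentation of raw radiographs is upstream and out of scope.
All geometry is in 0-based `(row, col)` image coordinates with rows growing
downward; equations use `x ≡ col`, `y ≡ row`.  All distances are in pixels
with no sub-pixel interpolation; physical units come only from the detector
pitch (`pixel_spacing_um`, default 417 μm/px).

## Lung-field identification

Connected components are labeled with 4-connectivity (a one-pixel diagonal
bridge must not merge the lungs).  The two largest components of at least
`min_component_area` (default 100 px) are kept.  Area alone cannot tell left
from right, so sides are assigned positionally: in a postero-anterior view
the patient's right lung appears on the image's left, hence the component
with the smaller centroid column is the right lung.  Fewer than two
lung-sized components is a per-frame detection error; the sequence continues
with that frame marked failed.

## Edge extraction and contour tracing

The edge is the mask minus its morphological erosion with the 3×3 cross
template, with raster border pixels treated as eroded.  Equivalently: a
foreground pixel is an edge pixel iff it touches background through a
4-neighbor or lies on the image border.  This keeps contours closed where a
lung touches the frame and makes the edge exactly one pixel thick
(the 4-boundary, which is 8-connected as a curve).

Tracing: one-pixel spurs (pixels with fewer than two 8-neighbors in the
edge set, iteratively) are pruned; the remaining set must form one
8-connected cycle.  A Moore-neighbor walk with Jacob's stopping criterion
orders the cycle; the orientation is normalized to clockwise in image
coordinates (positive shoelace sum).  Well-formed curves yield a cycle
visiting each pixel exactly once.  A curve that touches itself diagonally
(a pinch, which can occur when the cardiophrenic notch closes to within one
pixel) is accepted if the walk covers every pixel with at most a few
duplicate visits; incomplete coverage is an error.

## Landmark definitions

The upstream literature leaves the chord endpoints unspecified, so they are
fixed here as deterministic extremes of the contour:

* costophrenic angle `A` — inferior-most edge pixel, ties broken laterally
  (minimum column on the right lung, maximum on the left);
* apex anchor `B` — superior-most edge pixel, ties broken medially.

The cardiophrenic angle is the argmax of the point-to-line distance to the
chord `A–B` over the edge pixels strictly on the medial side of the chord
(greater column for the right lung, lesser for the left).  Ties are broken
by contour order along the inferior arc starting from `A`, which makes the
result independent of pixel discovery order.

The left corner search is additionally restricted to rows at or below the
auxiliary point: the medial-most intersection of the left edge with the
horizontal line `Δy` pixels **above** the right corner's row.  The row
direction of `Δy` is a convention choice (the sign is configurable); placing
the auxiliary row superior to `C1` is the reading under which the
restriction excludes the cardiac-border bulge, which otherwise beats the
true corner.  If no edge pixel sits exactly on the auxiliary row, the
nearest row within ±2 rows is used (nearer wins; tie goes to the superior
row).

## Hemi-diaphragm length

The hemi-diaphragm is the contour arc from `A` to `C` that does not contain
the apex anchor.  Its length is the chamfer arc length (axial step 1,
diagonal step √2); the straight chord `A–C` is also computed and selectable
via `length_mode="chord"` because the measurement convention of prior work
is ambiguous.  Note the chamfer length of a digitized smooth curve
overestimates the true curve length — up to ~8% at slopes near 22.5°, ~3–5%
on the phantom dome — so arc lengths should be compared between frames
(where the bias cancels), not against analytic curve lengths.

## Abnormality classification and correction

Baseline `l_base` is the minimum left hemi-diaphragm length over non-failed
frames; frame `i` is abnormal iff `l_i − l_base ≥ Δl` with the inclusive
threshold as specified (default `Δl` = 20 px).  The baseline frame is normal
by construction.

Correction of an abnormal frame `k` uses the nearest normal frame as
reference (ties toward the earlier frame, for determinism).  The vertical
displacement is taken from the *right* cardiophrenic angles,
`d = y_C1,k − y_C1,ref`: the printed left-side form of the displacement is
degenerate after the reference initialization (it is identically zero), and
the right corner is the reliable one by assumption.  The corrected row is
`y_C2,ref + d`; the corrected column is the medial-most intersection of the
frame's own left edge with that horizontal line.

Numerical guard: if the corrected row lands one pixel below the notch
corner, the scan line misses the medial boundary branch entirely and the
nearest intersection is the far lateral dome wall.  The intersection search
therefore scans the ±2-row window, identifies the most medial column
reached anywhere in the window, and picks the row nearest the target whose
own medial intersection is within 10 columns of it (same-branch test).  The
10-column tolerance only needs to separate the medial branch from the
lateral wall (~100 px away) while tolerating the medial border's slope over
two rows (~2 px); any value in between behaves identically.

If no normal frame exists the correction is impossible by design (the
method's stated limitation); the library raises and the CLI exits non-zero.
Re-running the optimization on corrected output changes nothing: corrected
lengths fall below threshold, so no frame is re-flagged.

## Evaluation metrics

Per frame: Euclidean errors of `B1, C1, B2, C2` against ground truth and
signed length errors of both hemi-diaphragms.  Aggregates per case are
mean ± SD (min–max) with the sample (n−1) SD — the convention for reported
± SD on samples; configurable in principle but not exposed.  Absolute
values are applied to length errors before aggregation so positive and
negative errors cannot cancel.  Two pooled columns follow the published
table layout: the mean of the four landmark-error means and the mean of the
two length-error means.  Display rounding is half-away-from-zero at the
printed precision, computed after snapping to 12 significant digits so that
decimal-looking values stored as binary floats round as their decimal
counterparts would.

## The breathing phantom

The phantom states a world in which every stage is testable without
clinical data:

* 30 frames at 15 frames/s on a 512×512 raster at 417 μm/px — the imaging
  regime of the target system; one breath per sequence
  (`breath_period` = 30 frames ⇒ a 2 s cycle, brisk quiet breathing);
* two lung silhouettes from smooth parametric boundaries (quadratic Bézier
  apex with a deliberate kink so the topmost pixel is unambiguous, straight
  chest walls, parabolic diaphragm dome);
* the dome's base row follows `y0 − A·sin(2π(k−1)/T)` with
  `excursion_amplitude` A = 30 px ≈ 12.5 mm of diaphragm travel, within the
  quiet-breathing range reported for DCR;
* a cardiac silhouette carved from the medial-inferior left lung: the
  boundary leaves the dome at the cardiophrenic corner and arcs (laterally
  bulging Bézier) up to the medial chest wall.  The geometry is arranged so
  that, as in real masks, the *global* max-distance pixel is on the cardiac
  border — only the auxiliary restriction recovers the true corner;
* obscured frames emulate the segmentation failure: the notch is filled by
  a fillet — a near-vertical rise off the corner, a medial shelf at
  `notch_width − obscure_radius` columns, and a climb to the wall.  This
  moves the apparent corner up and ~40 px medially and lengthens the
  apparent left hemi-diaphragm by more than `Δl`, while preserving the dome
  below the true corner's row so the temporal correction can land on it.
  Ground truth stores the pre-obscuring corner.

Rasterization is polygon scan conversion (even-odd) united with the
rasterized polygon outline; without the outline, thin corner tips (the
cardiophrenic notch) lose their apex pixel.  The union dilates shapes by
about half a pixel (a radius-50 disc gains ~2.3% area).  Self-intersecting
polygons are rejected.  Identical configs produce bit-identical output; the
optional boundary jitter (off by default) is a smooth low-frequency
sinusoidal displacement driven by the seed — white vertex noise would
self-intersect the polygon.

What a green phantom test does **not** establish: robustness to real
segmentation noise (ragged edges, holes, under-segmentation), to pathology
that reshapes the lung field, to breath cycles that drift in amplitude, or
to failure modes other than the modeled notch fill.  The phantom's motion
is a pure vertical translation of the inferior border, so the consistency
criterion holds exactly by construction; clinical sequences satisfy it only
approximately.

## Known limitations

* The correction requires at least one normal frame; an all-abnormal
  sequence cannot be repaired.
* A temporally distant reference weakens the consistency assumption; the
  gap is not bounded by default (`max_reference_gap` is deliberately not
  imposed — the nearest normal frame is always used).
* Corner localization is pixel-integer; sub-pixel accuracy is out of scope.
* Only the left cardiophrenic angle is corrected; right-side failures,
  observed to be rare, pass through unchanged.
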