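# hemidia

Hemi-diaphragm measurement and temporal correction for dynamic chest
radiography (DCR) lung-field masks.

## The problem

DCR records the thorax at ~15 frames/s over a breathing cycle.  Given a
binary lung-field mask per frame (from any upstream segmentation), the
motion of each hemi-diaphragm can be quantified from the inferior border of
the lung field, delimited by two anatomical corners per lung:

* the **costophrenic angle** `A` — the inferolateral corner where the
  diaphragm meets the chest wall;
* the **cardiophrenic angle** `C` — the inferomedial corner where the
  diaphragm meets the cardiac silhouette.

During breathing the lung field deforms; at some time points the left
cardiophrenic notch becomes inconspicuous on the mask.  The detected corner
then slides up the cardiac border, the measured left hemi-diaphragm becomes
spuriously long, and per-frame errors of tens of pixels appear.  `hemidia`
detects these corners, flags the failing frames, and repairs them using the
temporal structure of the sequence.

## Method

Per frame (image coordinates, row = y growing downward, col = x):

1. **Edge extraction.**  The lung edge is the mask minus its morphological
   erosion (border pixels count as eroded), i.e. every foreground pixel with
   a background 4-neighbor; it is ordered into a closed 8-connected contour.
2. **Corner detection by maximum point-to-chord distance.**  With the chord
   `a·x + b·y + c = 0` through `A` (inferior-most edge pixel) and the apex
   anchor `B` (superior-most edge pixel), the cardiophrenic angle is the
   medial-side edge pixel maximizing `|a·x + b·y + c| / √(a²+b²)`.
3. **Auxiliary restriction (left lung).**  The left corner is *not* the
   global maximum — the cardiac border bulge beats it.  The horizontal line
   `Δy` (default 20 px) above the right corner `C1` crosses the left edge at
   the auxiliary point `C2′`; left-corner candidates are restricted to rows
   at or below `C2′`.
4. **Abnormality flagging.**  Each hemi-diaphragm is the edge arc from `A`
   to `C` (length: axial step 1, diagonal step √2).  With the sequence
   baseline `l_base = min_i l_i` (shortest left hemi-diaphragm), frame `i`
   is abnormal iff `l_i − l_base ≥ Δl` (default 20 px).
5. **Consistency-criterion correction.**  Left and right cardiophrenic
   angles displace vertically in concert: `d_k ≈ y_C1,k − y_C1,k±n`.  For an
   abnormal frame `k`, take the nearest normal frame `k±n` as reference, set
   the corrected row to `y_C2,k±n + d_k`, and re-read the corrected column
   off frame `k`'s own left edge at that row.  Right-lung landmarks are
   never altered.

Errors against ground-truth annotations are Euclidean pixel distances per
landmark and signed hemi-diaphragm length differences, aggregated as
mean ± SD (min–max), with absolute values taken of length errors before
aggregation.  Pixel errors convert to micrometres via the detector pitch
(417 μm/px by default).

## Worked example

The built-in breathing phantom generates 30 frames (512×512) of two lung
silhouettes whose parabolic diaphragm dome follows a sinusoidal excursion,
with a cardiac notch carved from the left lung.  Obscuring frames 2–26
fills the notch, reproducing the detection failure:

```sh
hemidia phantom --out ph --obscure
hemidia correct ph --out run
hemidia evaluate run/landmarks_corrected.csv ph/ground_truth.csv
```

prints (corrected landmarks vs. analytic ground truth):

```
dB1: 0.000 ± 0.000 (0.000–0.000)
dC1: 0.000 ± 0.000 (0.000–0.000)
dB2: 0.000 ± 0.000 (0.000–0.000)
dC2: 0.505 ± 0.679 (0.000–1.414)
mean_error_angles: 0.126
```

On the 25 obscured frames the initial left-corner error averages 41.23 px;
after correction it is 0.57 px — the apex and costophrenic anchors are exact
and the repaired cardiophrenic angle sits within ~1 px of the true carved
corner.  `run/qc_report.csv` lists, per frame, the status, length excess
over baseline, reference frame, and vertical displacement used.

The same pipeline is scriptable:

```python
import hemidia as h

cfg = h.PhantomConfig(obscured_frames=h.case3_obscured_frames())
frames, truth = h.generate_sequence(cfg)
results = h.detect_sequence(frames)
optimized, labels, records = h.optimize_sequence(results)
```

## Acceptance script

`python scripts/acceptance.py --seed 1 --out results/acceptance.json`
regenerates the obscured phantom from scratch, runs detection and the
consistency-criterion correction on all 30 frames, evaluates corner errors
against the analytic ground truth, and writes the results JSON (a summary
also goes to stderr).

## Layout

* `hemidia.mask_io` — mask sequence IO, lung-field labeling, landmark CSVs
* `hemidia.edge_geometry` — edge extraction, contour tracing, chord geometry
* `hemidia.landmarks` — corner detection, hemi-diaphragm assembly
* `hemidia.temporal_qc` — baseline classification and temporal correction
* `hemidia.metrics` — error metrics and table-style aggregation
* `hemidia.phantom` — synthetic breathing phantom with analytic ground truth
* `hemidia.cli` — `hemidia phantom | detect | correct | evaluate`

See `docs/methods.md` for modeling assumptions, parameter defaults, and
numerical choices.
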