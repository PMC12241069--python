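"""Per-frame cardiophrenic-angle detection and hemi-diaphragm assembly.

Detection order per frame (postero-anterior view):

1. right lung: chord from costophrenic angle A1 to apex anchor B1; the right
   cardiophrenic angle C1 is the medial-side edge pixel farthest from the
   chord (maximum point-to-line distance);
2. an auxiliary point C2' is placed at the medial ("left") intersection of
   the horizontal line ``delta_y`` pixels above C1's row with the left lung
   edge — it caps how far up the left-corner search may reach, excluding the
   cardiac-border bulge;
3. left lung: C2 is the farthest medial-side pixel from the chord A2-B2,
   restricted to rows at or below the auxiliary point;
4. each hemi-diaphragm is the edge arc from the costophrenic angle A to the
   cardiophrenic angle C that avoids the apex.

All distances are in pixels; no sub-pixel interpolation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .edge_geometry import (
    Chord,
    ContourError,
    EdgeContour,
    GeometryError,
    extract_edge,
    find_apex_anchor,
    find_costophrenic_angle,
    make_chord,
    medial_side_pixels,
    signed_point_line_distance,
    trace_contour,
)
from .mask_io import DetectionError, MaskFrame, SequenceConfig, identify_lung_fields

__all__ = [
    "LandmarkSet",
    "HemiDiaphragm",
    "FrameResult",
    "AuxiliaryPointError",
    "detect_right_cardiophrenic",
    "compute_auxiliary_point",
    "detect_left_cardiophrenic",
    "extract_hemidiaphragm",
    "detect_frame",
    "detect_sequence",
]

Point = tuple[int, int]

SQRT2 = math.sqrt(2.0)


class AuxiliaryPointError(DetectionError):
    """The horizontal auxiliary line misses the left lung edge."""


@dataclass(frozen=True)
class LandmarkSet:
    """Named landmark points of one frame, pixel (row, col) coordinates.

    A1/A2 costophrenic angles, B1/B2 apex anchors, C1/C2 cardiophrenic
    angles (1 = right lung, 2 = left lung).  ``C2_aux`` is the auxiliary
    restriction point; ``C2_corrected`` is set by the temporal correction.
    """

    frame_index: int
    A1: Point
    B1: Point
    C1: Point
    A2: Point
    B2: Point
    C2: Point
    C2_aux: Point | None = None
    C2_corrected: Point | None = None

    @property
    def C2_final(self) -> Point:
        """Corrected left cardiophrenic angle when available, else initial."""
        return self.C2_corrected if self.C2_corrected is not None else self.C2

    def as_records(self) -> list[dict]:
        recs = []
        for name in ("A1", "B1", "C1", "A2", "B2", "C2"):
            r, c = getattr(self, name)
            if name == "C2" and self.C2_corrected is not None:
                r, c = self.C2_corrected
                corrected = True
            else:
                corrected = False
            recs.append({"frame": self.frame_index, "landmark_name": name,
                         "row": int(r), "col": int(c),
                         "corrected_flag": corrected})
        return recs


@dataclass(frozen=True)
class HemiDiaphragm:
    """Edge sub-path from costophrenic angle A to cardiophrenic angle C."""

    side: str
    frame_index: int
    path: np.ndarray = field(repr=False)  # ordered (n, 2), path[0]=A, path[-1]=C

    @property
    def arc_length(self) -> float:
        steps = np.abs(np.diff(self.path, axis=0))
        diag = (steps.max(axis=1) == 1) & (steps.min(axis=1) == 1)
        return float(np.where(diag, SQRT2, 1.0).sum())

    @property
    def chord_length(self) -> float:
        d = self.path[-1] - self.path[0]
        return float(math.hypot(d[0], d[1]))

    def length(self, mode: str = "arc") -> float:
        return self.arc_length if mode == "arc" else self.chord_length


@dataclass(frozen=True)
class FrameResult:
    """Outcome of landmark detection on one frame."""

    frame_index: int
    landmarks: LandmarkSet | None
    right_hemi: HemiDiaphragm | None
    left_hemi: HemiDiaphragm | None
    right_contour: EdgeContour | None
    left_contour: EdgeContour | None
    error: str | None = None

    @property
    def ok(self) -> bool:
        return self.error is None


def _argmax_distance(candidates: np.ndarray, chord: Chord) -> Point:
    """Candidate with maximum |distance| to the chord; ties -> first in order."""
    d = np.abs(signed_point_line_distance(candidates, chord))
    i = int(np.argmax(d))  # np.argmax returns the first maximum
    return int(candidates[i, 0]), int(candidates[i, 1])


def detect_right_cardiophrenic(contour_right: EdgeContour) -> tuple[Point, Chord]:
    """Right cardiophrenic angle: farthest medial-side pixel from chord A1-B1."""
    a = find_costophrenic_angle(contour_right)
    b = find_apex_anchor(contour_right)
    chord = make_chord(a, b)
    cands = medial_side_pixels(contour_right, chord)
    return _argmax_distance(cands, chord), chord


def _horizontal_intersection(contour: EdgeContour, target_row: int,
                             tolerance: int = 2) -> Point:
    """Medial-most ("left") contour pixel on the horizontal line at target_row.

    If no contour pixel sits exactly on the target row, the nearest row with
    intersections within ±tolerance is used (nearer row wins; tie -> smaller
    row, i.e. the superior one).
    """
    p = contour.path
    for delta in range(tolerance + 1):
        for row in ((target_row,) if delta == 0
                    else (target_row - delta, target_row + delta)):
            hits = p[p[:, 0] == row]
            if hits.size:
                return int(row), int(hits[:, 1].min())
    raise AuxiliaryPointError(
        f"left edge has no pixel within ±{tolerance} rows of row {target_row}"
    )


def compute_auxiliary_point(contour_left: EdgeContour, C1: Point,
                            delta_y: int = 20) -> Point:
    """Auxiliary point: medial intersection of the line delta_y above C1."""
    return _horizontal_intersection(contour_left, C1[0] - delta_y)


def detect_left_cardiophrenic(contour_left: EdgeContour,
                              C2_aux: Point) -> tuple[Point, Chord]:
    """Left cardiophrenic angle under the auxiliary row restriction.

    Candidates are the medial-side pixels of chord A2-B2 at or below the
    auxiliary point's row (row >= row(C2_aux)); C2 is the farthest from the
    chord, ties broken by candidate order from A2 along the inferior arc.
    """
    a = find_costophrenic_angle(contour_left)
    b = find_apex_anchor(contour_left)
    chord = make_chord(a, b)
    cands = medial_side_pixels(contour_left, chord)
    cands = cands[cands[:, 0] >= C2_aux[0]]
    if cands.size == 0:
        raise DetectionError(
            "no left-corner candidates at or below the auxiliary row"
        )
    return _argmax_distance(cands, chord), chord


def extract_hemidiaphragm(contour: EdgeContour, A: Point, C: Point,
                          side: str) -> HemiDiaphragm:
    """Edge arc from A to C avoiding the apex anchor (the inferior border)."""
    if tuple(A) == tuple(C):
        raise GeometryError("degenerate hemi-diaphragm: A coincides with C")
    p = contour.path
    n = len(p)
    def index_of(pt: Point) -> int:
        hits = np.where((p[:, 0] == pt[0]) & (p[:, 1] == pt[1]))[0]
        if hits.size == 0:
            raise GeometryError(f"point {pt} does not lie on the contour")
        return int(hits[0])
    ia, ic = index_of(A), index_of(C)
    ib = index_of(find_apex_anchor(contour))
    # the cyclic range (ia -> ic) walking forward; apex must not be inside
    def in_fwd_range(i: int) -> bool:
        return (i - ia) % n <= (ic - ia) % n
    if not in_fwd_range(ib):
        idx = [(ia + t) % n for t in range((ic - ia) % n + 1)]
    else:
        idx = [(ia - t) % n for t in range((ia - ic) % n + 1)]
    return HemiDiaphragm(side=side, frame_index=contour.frame_index,
                         path=p[idx])


def detect_frame(frame: MaskFrame,
                 config: SequenceConfig | None = None) -> FrameResult:
    """Run the full landmark chain on one frame; errors become a marker."""
    config = config or SequenceConfig()
    k = frame.frame_index
    try:
        right, left = identify_lung_fields(frame, config)
        rc = trace_contour(extract_edge(right.to_mask(frame.shape)),
                           "right", k)
        lc = trace_contour(extract_edge(left.to_mask(frame.shape)),
                           "left", k)
        C1, _ = detect_right_cardiophrenic(rc)
        aux = compute_auxiliary_point(lc, C1, config.delta_y)
        C2, _ = detect_left_cardiophrenic(lc, aux)
        lm = LandmarkSet(
            frame_index=k,
            A1=find_costophrenic_angle(rc), B1=find_apex_anchor(rc), C1=C1,
            A2=find_costophrenic_angle(lc), B2=find_apex_anchor(lc), C2=C2,
            C2_aux=aux,
        )
        rh = extract_hemidiaphragm(rc, lm.A1, lm.C1, "right")
        lh = extract_hemidiaphragm(lc, lm.A2, lm.C2, "left")
        return FrameResult(k, lm, rh, lh, rc, lc)
    except (DetectionError, ContourError, GeometryError) as exc:
        return FrameResult(k, None, None, None, None, None, error=str(exc))


def detect_sequence(frames: list[MaskFrame],
                    config: SequenceConfig | None = None) -> list[FrameResult]:
    """Detect landmarks on every frame; per-frame failures do not abort."""
    if len(frames) == 0:
        raise ValueError("empty frame sequence")
    return [detect_frame(f, config) for f in frames]
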