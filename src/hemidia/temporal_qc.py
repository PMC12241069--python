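"""Abnormal hemi-diaphragm identification and temporal correction.

Lung-field deformation during breathing can blunt the left cardiophrenic
notch, sliding the detected corner up the cardiac border and lengthening the
apparent left hemi-diaphragm.  Two-stage quality control:

* classification — the shortest left hemi-diaphragm across the sequence is
  the baseline; a frame whose length exceeds the baseline by at least
  ``delta_l`` pixels is abnormal;
* correction — assuming both hemi-diaphragms move vertically in concert
  (diaphragm-motion consistency), the abnormal frame's left corner row is
  rebuilt from the nearest normal frame's left corner shifted by the
  right corner's displacement, and its column is re-read off the frame's
  own left edge at that row.

Right-lung landmarks are never modified.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .edge_geometry import EdgeContour
from .landmarks import (
    AuxiliaryPointError,
    FrameResult,
    HemiDiaphragm,
    LandmarkSet,
    extract_hemidiaphragm,
)
from .mask_io import SequenceConfig

__all__ = [
    "FrameLabel",
    "CorrectionRecord",
    "CorrectionImpossibleError",
    "baseline_length",
    "classify_frames",
    "nearest_normal_frame",
    "vertical_displacement",
    "correct_left_cardiophrenic",
    "optimize_sequence",
    "qc_report",
]

Point = tuple[int, int]


class CorrectionImpossibleError(RuntimeError):
    """No normal reference frame exists; the correction cannot run."""


@dataclass(frozen=True)
class FrameLabel:
    frame_index: int
    status: str  # "normal", "abnormal", or "failed"
    left_length: float | None
    excess: float | None  # l_i - l_base, >= 0 for non-failed frames


@dataclass(frozen=True)
class CorrectionRecord:
    frame_index: int
    reference_index: int
    displacement: float  # vertical, signed; positive = inferior
    corrected: Point | None
    applied: bool
    note: str = ""


def baseline_length(lengths: list[float | None]) -> float:
    """Shortest left hemi-diaphragm length over all non-failed frames."""
    valid = [l for l in lengths if l is not None]
    if not valid:
        raise CorrectionImpossibleError("all frames failed; no baseline length")
    return min(valid)


def classify_frames(lengths: list[float | None],
                    delta_l: float = 20.0,
                    frame_indices: list[int] | None = None) -> list[FrameLabel]:
    """Label each frame normal/abnormal against the sequence baseline.

    Abnormal iff ``l_i - l_base >= delta_l`` (inclusive threshold); a frame
    with no length is labeled failed.  The baseline frame has excess 0 and is
    always normal.
    """
    base = baseline_length(lengths)
    if frame_indices is None:
        frame_indices = list(range(1, len(lengths) + 1))
    labels = []
    for k, l in zip(frame_indices, lengths):
        if l is None:
            labels.append(FrameLabel(k, "failed", None, None))
        else:
            excess = l - base
            status = "abnormal" if excess >= delta_l else "normal"
            labels.append(FrameLabel(k, status, l, excess))
    return labels


def nearest_normal_frame(k: int, labels: list[FrameLabel]) -> int:
    """Index of the normal frame closest in time to k; ties -> earlier frame."""
    normal = [lab.frame_index for lab in labels if lab.status == "normal"]
    if not normal:
        raise CorrectionImpossibleError(
            "no normal frame in the sequence; every hemi-diaphragm is "
            "abnormal, so the consistency-based correction cannot be applied"
        )
    return min(normal, key=lambda j: (abs(k - j), j))


def vertical_displacement(C1_k: Point, C1_ref: Point) -> int:
    """Signed vertical displacement of the right cardiophrenic angle.

    Positive values point inferiorly (rows grow downward).
    """
    return int(C1_k[0]) - int(C1_ref[0])


def _medial_branch_intersection(contour: EdgeContour, target_row: int,
                                row_tolerance: int = 2,
                                branch_tolerance: int = 10) -> Point:
    """Medial-most edge intersection near ``target_row``, branch-aware.

    A horizontal line one pixel below the cardiophrenic corner misses the
    medial boundary branch entirely and would latch onto the lung's lateral
    wall far away.  Guard: find the most medial column any row in the
    ±``row_tolerance`` window reaches, then take the row nearest the target
    whose own medial-most intersection stays within ``branch_tolerance``
    columns of it (i.e. lies on the same medial branch); ties prefer the
    superior row.
    """
    p = contour.path
    window = p[np.abs(p[:, 0] - target_row) <= row_tolerance]
    if window.size == 0:
        raise AuxiliaryPointError(
            f"left edge has no pixel within ±{row_tolerance} rows of "
            f"row {target_row}"
        )
    branch_col = int(window[:, 1].min())
    for delta in range(row_tolerance + 1):
        for row in ((target_row,) if delta == 0
                    else (target_row - delta, target_row + delta)):
            hits = window[window[:, 0] == row]
            if hits.size == 0:
                continue
            col = int(hits[:, 1].min())
            if col <= branch_col + branch_tolerance:
                return int(row), col
    # no row stays on the medial branch: fall back to the most medial pixel
    rows_at_min = window[window[:, 1] == branch_col][:, 0]
    return int(rows_at_min.min()), branch_col


def correct_left_cardiophrenic(
    left_contour: EdgeContour,
    landmarks_k: LandmarkSet,
    reference: LandmarkSet,
    d: int,
    row_tolerance: int = 2,
) -> tuple[Point, HemiDiaphragm]:
    """Rebuild the left cardiophrenic angle of an abnormal frame.

    The corrected row is the reference frame's left-corner row shifted by the
    right-corner displacement ``d``; the corrected column is the medial-most
    intersection of that horizontal line with the frame's own left edge
    (nearest-row fallback within ±``row_tolerance``, kept on the medial
    boundary branch).  The left hemi-diaphragm is re-extracted to end at the
    corrected point.
    """
    target_row = int(reference.C2_final[0]) + int(d)
    corrected = _medial_branch_intersection(left_contour, target_row,
                                            row_tolerance=row_tolerance)
    hemi = extract_hemidiaphragm(left_contour, landmarks_k.A2, corrected,
                                 "left")
    return corrected, hemi


def optimize_sequence(
    results: list[FrameResult],
    config: SequenceConfig | None = None,
) -> tuple[list[FrameResult], list[FrameLabel], list[CorrectionRecord]]:
    """Classify the sequence and correct every abnormal left hemi-diaphragm.

    Normal and failed frames pass through untouched; right-lung landmarks are
    never modified.  Raises :class:`CorrectionImpossibleError` when abnormal
    frames exist but no normal reference does.
    """
    config = config or SequenceConfig()
    lengths = [r.left_hemi.length(config.length_mode) if r.ok else None
               for r in results]
    labels = classify_frames(lengths, config.delta_l,
                             [r.frame_index for r in results])
    by_index = {r.frame_index: r for r in results}
    records: list[CorrectionRecord] = []
    out: list[FrameResult] = []
    for r, lab in zip(results, labels):
        if lab.status != "abnormal":
            out.append(r)
            continue
        ref_idx = nearest_normal_frame(r.frame_index, labels)
        ref = by_index[ref_idx].landmarks
        d = vertical_displacement(r.landmarks.C1, ref.C1)
        try:
            corrected, hemi = correct_left_cardiophrenic(
                r.left_contour, r.landmarks, ref, d)
        except AuxiliaryPointError as exc:
            records.append(CorrectionRecord(r.frame_index, ref_idx, d,
                                            None, False, note=str(exc)))
            out.append(r)
            continue
        lm = replace(r.landmarks, C2_corrected=corrected)
        out.append(replace(r, landmarks=lm, left_hemi=hemi))
        records.append(CorrectionRecord(r.frame_index, ref_idx, d,
                                        corrected, True))
    return out, labels, records


def qc_report(labels: list[FrameLabel],
              records: list[CorrectionRecord]) -> pd.DataFrame:
    """Tabular QC summary: one row per frame, correction columns where applied."""
    rec_by_frame = {rec.frame_index: rec for rec in records}
    rows = []
    for lab in labels:
        rec = rec_by_frame.get(lab.frame_index)
        rows.append({
            "frame": lab.frame_index,
            "status": lab.status,
            "left_length": lab.left_length,
            "excess": lab.excess,
            "reference_index": rec.reference_index if rec else pd.NA,
            "displacement": rec.displacement if rec else pd.NA,
            "corrected_row": rec.corrected[0] if rec and rec.corrected else pd.NA,
            "corrected_col": rec.corrected[1] if rec and rec.corrected else pd.NA,
        })
    return pd.DataFrame(rows)
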