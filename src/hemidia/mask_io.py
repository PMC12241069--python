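"""Reading and validation of lung-field mask sequences and landmark tables.

A dynamic chest radiography (DCR) run yields one binary lung-field mask per
frame (both lungs foreground).  This module loads such a sequence, labels the
two lung fields, assigns anatomical sides (postero-anterior view: the
patient's right lung appears on the image's left), and reads/writes the
landmark CSV schema shared with ground-truth annotation files.

Coordinate convention, project-wide: 0-based ``(row, col)``, row increasing
downward; ``x ≡ col`` and ``y ≡ row``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "SequenceConfig",
    "MaskFrame",
    "LungField",
    "MaskIOError",
    "ValidationError",
    "DetectionError",
    "read_mask_sequence",
    "frames_from_arrays",
    "identify_lung_fields",
    "write_landmarks",
    "read_landmarks",
]

LANDMARK_COLUMNS = ["frame", "landmark_name", "row", "col", "corrected_flag"]


class MaskIOError(IOError):
    """Unreadable or unwritable mask/landmark file."""


class ValidationError(ValueError):
    """Input violates a sequence invariant (e.g. mismatched frame shapes)."""


class DetectionError(RuntimeError):
    """A per-frame detection step failed (e.g. merged lung fields)."""


@dataclass(frozen=True)
class SequenceConfig:
    """Tunable parameters of the measurement pipeline.

    delta_y
        Vertical offset (pixels) of the auxiliary point above the right
        cardiophrenic angle; restricts the left-corner candidate set.
    delta_l
        Length excess (pixels) over the sequence baseline beyond which a
        left hemi-diaphragm is flagged abnormal.
    pixel_spacing_um
        Detector pitch, micrometres per pixel (417 for the target system).
    min_component_area
        Connected components smaller than this are discarded as specks.
    length_mode
        Hemi-diaphragm length convention: "arc" (along the mask edge,
        axial step 1 / diagonal step sqrt(2)) or "chord" (Euclidean A-C).
    """

    delta_y: int = 20
    delta_l: float = 20.0
    pixel_spacing_um: float = 417.0
    min_component_area: int = 100
    length_mode: str = "arc"

    def __post_init__(self) -> None:
        if self.delta_l <= 0:
            raise ValidationError("delta_l must be positive")
        if self.pixel_spacing_um <= 0:
            raise ValidationError("pixel_spacing_um must be positive")
        if self.length_mode not in ("arc", "chord"):
            raise ValidationError(f"unknown length_mode {self.length_mode!r}")


@dataclass(frozen=True)
class MaskFrame:
    """One binary lung-field raster with its 1-based time index."""

    frame_index: int
    grid: np.ndarray
    pixel_spacing_um: float = 417.0

    def __post_init__(self) -> None:
        g = np.asarray(self.grid)
        if g.ndim != 2:
            raise ValidationError(
                f"frame {self.frame_index}: mask must be 2-D, got {g.ndim}-D"
            )
        vals = np.unique(g)
        if not np.isin(vals, (0, 1)).all():
            raise ValidationError(
                f"frame {self.frame_index}: mask values must be exactly {{0,1}}"
            )
        object.__setattr__(self, "grid", g.astype(np.uint8))

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape


@dataclass(frozen=True)
class LungField:
    """One connected lung-field component with its anatomical side label."""

    side: str  # "right" or "left", patient-relative
    pixel_rows: np.ndarray = field(repr=False)
    pixel_cols: np.ndarray = field(repr=False)

    @property
    def area(self) -> int:
        return int(self.pixel_rows.size)

    @property
    def centroid(self) -> tuple[float, float]:
        return float(self.pixel_rows.mean()), float(self.pixel_cols.mean())

    def to_mask(self, shape: tuple[int, int]) -> np.ndarray:
        m = np.zeros(shape, dtype=np.uint8)
        m[self.pixel_rows, self.pixel_cols] = 1
        return m


def _binarize(arr: np.ndarray, path: str | Path) -> np.ndarray:
    if arr.ndim == 3:
        # single-channel images saved with a trailing channel axis
        if arr.shape[2] == 1:
            arr = arr[:, :, 0]
        else:
            raise ValidationError(f"{path}: expected a single-channel raster")
    if arr.ndim != 2:
        raise ValidationError(f"{path}: expected a 2-D raster, got {arr.ndim}-D")
    return (arr != 0).astype(np.uint8)


def read_mask_sequence(
    paths: Sequence[str | Path], config: SequenceConfig | None = None
) -> list[MaskFrame]:
    """Load an ordered mask sequence; any nonzero pixel binarizes to 1.

    Frame indices are 1-based positions in ``paths``.  All frames must share
    one raster shape.
    """
    config = config or SequenceConfig()
    if len(paths) == 0:
        raise ValidationError("empty mask sequence")
    frames: list[MaskFrame] = []
    for k, p in enumerate(paths, start=1):
        try:
            arr = np.asarray(iio.imread(p))
        except (OSError, ValueError) as exc:
            raise MaskIOError(f"cannot read mask file {p}: {exc}") from exc
        grid = _binarize(arr, p)
        if frames and grid.shape != frames[0].shape:
            raise ValidationError(
                f"frame {k} ({p}) has shape {grid.shape}, but frame 1 has "
                f"shape {frames[0].shape}"
            )
        frames.append(
            MaskFrame(frame_index=k, grid=grid,
                      pixel_spacing_um=config.pixel_spacing_um)
        )
    return frames


def frames_from_arrays(
    grids: Sequence[np.ndarray], pixel_spacing_um: float = 417.0
) -> list[MaskFrame]:
    """Wrap in-memory binary arrays as a validated MaskFrame sequence."""
    if len(grids) == 0:
        raise ValidationError("empty mask sequence")
    frames = []
    for k, g in enumerate(grids, start=1):
        g = (np.asarray(g) != 0).astype(np.uint8)
        if frames and g.shape != frames[0].shape:
            raise ValidationError(
                f"frame {k} has shape {g.shape}, but frame 1 has shape "
                f"{frames[0].shape}"
            )
        frames.append(MaskFrame(k, g, pixel_spacing_um))
    return frames


_STRUCT4 = ndimage.generate_binary_structure(2, 1)  # 4-connectivity


def identify_lung_fields(
    frame: MaskFrame, config: SequenceConfig | None = None
) -> tuple[LungField, LungField]:
    """Split a mask into (right, left) lung fields.

    The two largest 4-connected components at least ``min_component_area``
    pixels are kept; the one whose centroid column is smaller is the
    anatomical right lung (PA view).  Pure function of the raster.
    """
    config = config or SequenceConfig()
    labeled, n = ndimage.label(frame.grid, structure=_STRUCT4)
    if n == 0:
        raise DetectionError(f"frame {frame.frame_index}: no foreground")
    areas = ndimage.sum_labels(np.ones_like(labeled), labeled,
                               index=np.arange(1, n + 1))
    keep = [(a, lab) for lab, a in zip(range(1, n + 1), areas)
            if a >= config.min_component_area]
    if len(keep) < 2:
        raise DetectionError(
            f"frame {frame.frame_index}: found {len(keep)} lung-sized "
            f"component(s); need two (merged or missing lung fields?)"
        )
    keep.sort(key=lambda t: (-t[0], t[1]))
    fields = []
    for _, lab in keep[:2]:
        rows, cols = np.nonzero(labeled == lab)
        fields.append((float(cols.mean()), rows, cols))
    fields.sort(key=lambda t: t[0])
    right = LungField("right", fields[0][1], fields[0][2])
    left = LungField("left", fields[1][1], fields[1][2])
    return right, left


def write_landmarks(records: pd.DataFrame | Sequence[dict], path: str | Path) -> None:
    """Write a landmark table (detected or ground truth) as CSV.

    Schema: frame, landmark_name, row, col, corrected_flag — integer
    coordinates, bit-exact on round-trip.
    """
    df = pd.DataFrame(records)
    if df.empty:
        raise ValidationError("no landmark records to write")
    missing = [c for c in LANDMARK_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"landmark records missing columns {missing}")
    out = df[LANDMARK_COLUMNS].copy()
    out["frame"] = out["frame"].astype(int)
    out["row"] = out["row"].astype(int)
    out["col"] = out["col"].astype(int)
    out["corrected_flag"] = out["corrected_flag"].astype(bool)
    try:
        out.to_csv(path, index=False)
    except OSError as exc:
        raise MaskIOError(f"cannot write landmark file {path}: {exc}") from exc


def read_landmarks(path: str | Path) -> pd.DataFrame:
    """Read a landmark CSV written by :func:`write_landmarks` (or ground truth)."""
    try:
        df = pd.read_csv(path)
    except OSError as exc:
        raise MaskIOError(f"cannot read landmark file {path}: {exc}") from exc
    missing = [c for c in LANDMARK_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")
    df["frame"] = df["frame"].astype(int)
    df["row"] = df["row"].astype(int)
    df["col"] = df["col"].astype(int)
    df["corrected_flag"] = df["corrected_flag"].astype(bool)
    return df[LANDMARK_COLUMNS]
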