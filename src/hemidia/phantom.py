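"""Synthetic breathing-phantom mask sequences with analytic ground truth.

Each frame holds two lung-field silhouettes built from smooth parametric
contours: near-vertical chest walls, a kinked apex (so the topmost pixel is
unambiguous), and an inferior border shaped as a downward-opening parabolic
dome whose base row follows a sinusoid across frames (quiet-breathing
excursion).  The left lung carries a cardiac silhouette carved from its
medial-inferior corner: the boundary leaves the dome at the cardiophrenic
corner and arcs up the cardiac border to the medial chest wall.

Selected frames emulate the segmentation failure mode: the cardiophrenic
notch is filled by a fillet (the mask bleeds over the cardiac border), which
moves the apparent corner up and medially and lengthens the apparent left
hemi-diaphragm — while the dome below the true corner's row is preserved, so
the temporal correction can recover the true corner from a normal reference
frame.  Ground truth is recorded analytically before obscuring.

Geometry is defined in a 512×512 reference frame and scaled to the requested
image size.  Identical config ⇒ bit-identical output (no randomness unless
``jitter`` is enabled).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from shapely.geometry import Polygon as _ShapelyPolygon
from skimage.draw import polygon as _draw_polygon
from skimage.draw import polygon_perimeter as _draw_perimeter

from .mask_io import MaskFrame

__all__ = [
    "PhantomConfig",
    "PhantomGroundTruth",
    "PhantomConfigError",
    "generate_sequence",
    "rasterize_contour",
    "case3_obscured_frames",
    "case4_obscured_frames",
]


class PhantomConfigError(ValueError):
    """Geometrically impossible phantom configuration."""


def case3_obscured_frames(n_frames: int = 30) -> frozenset[int]:
    """Obscuring pattern of a sequence abnormal at times 2–26."""
    return frozenset(range(2, min(27, n_frames + 1)))


def case4_obscured_frames(n_frames: int = 30) -> frozenset[int]:
    """Obscuring pattern abnormal at times 1–5 and 11–30."""
    return frozenset(range(1, 6)) | frozenset(range(11, n_frames + 1))


@dataclass(frozen=True)
class PhantomConfig:
    """Stated world of the phantom.

    Defaults mirror the imaging regime of the target DCR system (30 frames
    at 15 frames/s — one two-second quiet breath per sequence) on a 512×512
    raster at 417 μm/pixel.  ``excursion_amplitude`` of 30 px ≈ 12.5 mm
    diaphragm travel, within the reported quiet-breathing range.
    """

    image_size: tuple[int, int] = (512, 512)
    n_frames: int = 30
    frame_rate: float = 15.0
    excursion_amplitude: float = 30.0
    breath_period: float = 30.0
    notch_depth: float = 70.0
    notch_width: float = 50.0
    obscured_frames: frozenset[int] = frozenset()
    obscure_radius: float = 40.0
    jitter: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        rows, cols = self.image_size
        if rows < 128 or cols < 128:
            raise PhantomConfigError("image_size must be at least 128×128")
        if self.n_frames < 1:
            raise PhantomConfigError("n_frames must be >= 1")
        if self.excursion_amplitude < 0:
            raise PhantomConfigError("excursion_amplitude must be >= 0")
        if self.breath_period <= 0:
            raise PhantomConfigError("breath_period must be positive")
        bad = set(self.obscured_frames) - set(range(1, self.n_frames + 1))
        if bad:
            raise PhantomConfigError(f"obscured_frames outside 1..n: {sorted(bad)}")
        if not (10 <= self.notch_width <= 80):
            raise PhantomConfigError("notch_width must be in [10, 80] px")
        if not (30 <= self.notch_depth <= 150):
            raise PhantomConfigError("notch_depth must be in [30, 150] px")
        if self.obscure_radius >= self.notch_width + 35:
            raise PhantomConfigError("obscure_radius too large for the notch")
        object.__setattr__(self, "obscured_frames",
                           frozenset(self.obscured_frames))


@dataclass(frozen=True)
class PhantomGroundTruth:
    """Analytic per-frame landmarks (pre-obscuring) and true left arc length."""

    landmarks: list[dict]  # per frame: name -> (row, col), rounded to pixel
    left_arc_length: list[float]  # analytic smooth dome length, pixels
    right_arc_length: list[float]
    obscured: list[bool]

    def landmark_records(self) -> list[dict]:
        recs = []
        for k, lm in enumerate(self.landmarks, start=1):
            for name in ("A1", "B1", "C1", "A2", "B2", "C2"):
                r, c = lm[name]
                recs.append({"frame": k, "landmark_name": name,
                             "row": int(r), "col": int(c),
                             "corrected_flag": False})
        return recs


# ---------------------------------------------------------------------------
# reference geometry (512×512 frame; x = col, y = row, y down)

_REF = 512.0

# right lung (image left)
_R_XLAT, _R_XMED = 60.0, 235.0
_R_APEX = (165.0, 85.0)
_R_WALL_TOP_LAT, _R_WALL_TOP_MED = 220.0, 240.0
_R_XDOME = 160.0
_R_CDOME = 0.006  # parabola coefficient, row = y_d + c (x - x_dome)^2

# left lung (image right)
_L_XLAT, _L_XMED = 450.0, 285.0
_L_APEX = (355.0, 90.0)
_L_WALL_TOP_LAT, _L_WALL_TOP_MED = 230.0, 240.0
_L_XDOME = 380.0
_L_CDOME = 0.011

_Y0 = 370.0  # dome base row at mid-breath


def _bezier(p0, p1, p2, n: int = 160) -> np.ndarray:
    """Quadratic Bezier samples as an (n, 2) array of (x, y)."""
    t = np.linspace(0.0, 1.0, n)[:, None]
    p0, p1, p2 = (np.asarray(p, dtype=float) for p in (p0, p1, p2))
    return (1 - t) ** 2 * p0 + 2 * t * (1 - t) * p1 + t**2 * p2


def _parabola_arc_length(c: float, u0: float, u1: float) -> float:
    """Arc length of row = c u² between u0 and u1 (u = x offset from dome)."""
    a = 2.0 * c

    def F(u: float) -> float:
        return 0.5 * (u * math.sqrt(1 + a * a * u * u) + math.asinh(a * u) / a)

    return abs(F(u1) - F(u0))


def rasterize_contour(vertices_xy: np.ndarray,
                      shape: tuple[int, int]) -> np.ndarray:
    """Scan-convert a closed simple polygon to a binary component.

    ``vertices_xy`` is an (n, 2) array of (x, y) points.  Self-intersecting
    polygons are rejected.
    """
    v = np.asarray(vertices_xy, dtype=float)
    if v.ndim != 2 or v.shape[1] != 2 or len(v) < 3:
        raise PhantomConfigError("polygon needs at least 3 (x, y) vertices")
    if not _ShapelyPolygon(v).is_valid:
        raise PhantomConfigError("polygon contour is self-intersecting")
    mask = np.zeros(shape, dtype=np.uint8)
    rr, cc = _draw_polygon(v[:, 1], v[:, 0], shape=shape)
    mask[rr, cc] = 1
    # fill alone drops boundary pixels whose centers fall just outside (it
    # shaves thin corner tips such as the cardiophrenic notch); union with
    # the rasterized perimeter keeps every boundary vertex on the mask
    rr, cc = _draw_perimeter(np.round(v[:, 1]).astype(int),
                             np.round(v[:, 0]).astype(int), shape=shape)
    mask[rr, cc] = 1
    return mask


def _dedup(parts: list[np.ndarray]) -> np.ndarray:
    """Concatenate boundary parts, dropping duplicated seam vertices."""
    v = np.vstack(parts)
    keep = np.ones(len(v), dtype=bool)
    keep[1:] = np.abs(np.diff(v, axis=0)).max(axis=1) > 1e-9
    if np.abs(v[0] - v[-1]).max() <= 1e-9:
        keep[-1] = False
    return v[keep]


def _right_lung_polygon(y_d: float) -> np.ndarray:
    xs = np.arange(_R_XMED, _R_XLAT - 0.5, -1.0)
    dome = np.column_stack([xs, y_d + _R_CDOME * (xs - _R_XDOME) ** 2])
    parts = [
        _bezier((_R_XLAT, _R_WALL_TOP_LAT), (100.0, 130.0), _R_APEX),
        _bezier(_R_APEX, (220.0, 130.0), (_R_XMED, _R_WALL_TOP_MED)),
        np.array([[_R_XMED, _R_WALL_TOP_MED],
                  [_R_XMED, y_d + _R_CDOME * (_R_XMED - _R_XDOME) ** 2]]),
        dome,
        np.array([[_R_XLAT, y_d + _R_CDOME * (_R_XLAT - _R_XDOME) ** 2],
                  [_R_XLAT, _R_WALL_TOP_LAT]]),
    ]
    return _dedup(parts)


def _left_lung_polygon(cfg: PhantomConfig, y_d: float,
                       obscured: bool) -> np.ndarray:
    x_c2 = _L_XDOME - cfg.notch_width
    row_t = y_d + _L_CDOME * cfg.notch_width**2
    h = (_L_XMED, _Y0 - cfg.notch_depth)
    xs = np.arange(_L_XLAT, x_c2 - 0.5, -1.0)
    dome = np.column_stack([xs, y_d + _L_CDOME * (xs - _L_XDOME) ** 2])
    if obscured:
        # fillet filling the notch: near-vertical rise off the corner, then a
        # medial shelf, then up the cardiac region to the medial wall
        m0 = (x_c2 - 6.0, row_t - cfg.obscure_radius / 4.0)
        m1 = (x_c2 - cfg.obscure_radius, row_t - cfg.obscure_radius / 4.0)
        medial = np.array([[x_c2, row_t], m0, m1, h])
    else:
        ctrl = (x_c2 + 5.0, 0.5 * (h[1] + row_t))
        medial = _bezier((x_c2, row_t), ctrl, h)
    parts = [
        _bezier(_L_APEX, (400.0, 140.0), (_L_XLAT, _L_WALL_TOP_LAT)),
        np.array([[_L_XLAT, _L_WALL_TOP_LAT],
                  [_L_XLAT, y_d + _L_CDOME * (_L_XLAT - _L_XDOME) ** 2]]),
        dome,
        medial,
        np.array([[_L_XMED, h[1]], [_L_XMED, _L_WALL_TOP_MED]]),
        _bezier((_L_XMED, _L_WALL_TOP_MED), (300.0, 140.0), _L_APEX),
    ]
    return _dedup(parts)


def _scale_xy(pts: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    rows, cols = shape
    out = pts.astype(float).copy()
    out[:, 0] *= cols / _REF
    out[:, 1] *= rows / _REF
    return out


def _scaled_point(x: float, y: float, shape: tuple[int, int]) -> tuple[int, int]:
    rows, cols = shape
    return int(round(y * rows / _REF)), int(round(x * cols / _REF))


def generate_sequence(
    config: PhantomConfig | None = None,
) -> tuple[list[MaskFrame], PhantomGroundTruth]:
    """Generate the phantom mask sequence and its analytic ground truth."""
    cfg = config or PhantomConfig()
    shape = tuple(cfg.image_size)
    rng = np.random.default_rng(cfg.seed) if cfg.jitter > 0 else None
    frames: list[MaskFrame] = []
    truths: list[dict] = []
    left_lens: list[float] = []
    right_lens: list[float] = []
    obscured_flags: list[bool] = []
    x_c2 = _L_XDOME - cfg.notch_width
    for k in range(1, cfg.n_frames + 1):
        phase = math.sin(2.0 * math.pi * (k - 1) / cfg.breath_period)
        y_d = _Y0 - cfg.excursion_amplitude * phase
        obscured = k in cfg.obscured_frames
        polys = [_right_lung_polygon(y_d),
                 _left_lung_polygon(cfg, y_d, obscured)]
        grid = np.zeros(shape, dtype=np.uint8)
        for poly in polys:
            if rng is not None:
                # smooth low-frequency boundary jitter: white noise on dense
                # vertices would self-intersect the polygon
                i = np.arange(len(poly))
                wavelength = rng.uniform(80.0, 160.0)
                phase = rng.uniform(0.0, 2.0 * np.pi)
                dy = cfg.jitter * np.sin(2 * np.pi * i / wavelength + phase)
                poly = poly + np.column_stack([np.zeros_like(dy), dy])
            grid |= rasterize_contour(_scale_xy(poly, shape), shape)
        frames.append(MaskFrame(k, grid))
        truths.append({
            "A1": _scaled_point(_R_XLAT,
                                y_d + _R_CDOME * (_R_XLAT - _R_XDOME) ** 2,
                                shape),
            "B1": _scaled_point(*_R_APEX, shape),
            "C1": _scaled_point(_R_XMED,
                                y_d + _R_CDOME * (_R_XMED - _R_XDOME) ** 2,
                                shape),
            "A2": _scaled_point(_L_XLAT,
                                y_d + _L_CDOME * (_L_XLAT - _L_XDOME) ** 2,
                                shape),
            "B2": _scaled_point(*_L_APEX, shape),
            "C2": _scaled_point(x_c2,
                                y_d + _L_CDOME * cfg.notch_width**2, shape),
        })
        scale = shape[1] / _REF
        left_lens.append(scale * _parabola_arc_length(
            _L_CDOME, x_c2 - _L_XDOME, _L_XLAT - _L_XDOME))
        right_lens.append(scale * _parabola_arc_length(
            _R_CDOME, _R_XLAT - _R_XDOME, _R_XMED - _R_XDOME))
        obscured_flags.append(obscured)
    return frames, PhantomGroundTruth(truths, left_lens, right_lens,
                                      obscured_flags)
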