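"""Lung-field edge extraction and chord geometry.

The lung edge is the mask minus its morphological erosion (cross template,
raster border treated as eroded), i.e. every foreground pixel with a
background 4-neighbor or on the image border.  The edge is ordered into a
closed 8-connected contour, on which the chord endpoints are located:

* A — the costophrenic angle, inferior-most edge pixel (lateral tie-break);
* B — the apex anchor, superior-most edge pixel (medial tie-break).

The cardiophrenic corner is then found downstream as the medial-side pixel
farthest from the chord A-B (maximum point-to-line distance).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "EdgeContour",
    "Chord",
    "GeometryError",
    "ContourError",
    "extract_edge",
    "trace_contour",
    "find_costophrenic_angle",
    "find_apex_anchor",
    "make_chord",
    "signed_point_line_distance",
    "medial_side_pixels",
]

Point = tuple[int, int]  # (row, col)


class GeometryError(ValueError):
    """Degenerate geometric input (coincident chord points, tiny field)."""


class ContourError(RuntimeError):
    """Edge pixels do not form a single traceable closed contour."""


@dataclass(frozen=True)
class EdgeContour:
    """Closed 8-connected edge path of one lung, clockwise in image coords."""

    side: str  # "right" or "left"
    path: np.ndarray = field(repr=False)  # (n, 2) int array of (row, col)
    frame_index: int = 0

    def __post_init__(self) -> None:
        p = np.asarray(self.path, dtype=np.int64)
        if p.ndim != 2 or p.shape[1] != 2 or p.shape[0] < 4:
            raise ContourError("contour path must be an (n>=4, 2) array")
        steps = np.abs(np.diff(np.vstack([p, p[:1]]), axis=0)).max(axis=1)
        if not (steps == 1).all():
            raise ContourError("consecutive contour pixels must be 8-adjacent")
        object.__setattr__(self, "path", p)

    def __len__(self) -> int:
        return len(self.path)

    @property
    def pixel_set(self) -> set[Point]:
        return {(int(r), int(c)) for r, c in self.path}


@dataclass(frozen=True)
class Chord:
    """Directed straight line a→b with unit-normalized coefficients.

    Satisfies a_coef*x + b_coef*y + c_coef = 0 with x = col, y = row;
    positive evaluation lies to the visual left of travel a→b.
    """

    a: Point
    b: Point
    coefficients: tuple[float, float, float]


_STRUCT4 = ndimage.generate_binary_structure(2, 1)
_STRUCT8 = ndimage.generate_binary_structure(2, 2)


def extract_edge(field_mask: np.ndarray) -> np.ndarray:
    """Edge layer of a binary component: mask minus its erosion.

    Border pixels of the raster count as eroded, so component pixels touching
    the image border are edge pixels and contours stay closed there.
    Returns a binary uint8 array of the same shape.
    """
    m = np.asarray(field_mask).astype(bool)
    if m.sum() == 0:
        raise GeometryError("empty lung field")
    rows, cols = np.nonzero(m)
    # a thin line is legitimately all edge; reject only blobs smaller than
    # the erosion template in both dimensions
    if np.ptp(rows) + 1 < 3 and np.ptp(cols) + 1 < 3:
        raise GeometryError("lung field smaller than its 3x3 template")
    eroded = ndimage.binary_erosion(m, structure=_STRUCT4, border_value=0)
    return (m & ~eroded).astype(np.uint8)


def _prune_spurs(edge: np.ndarray) -> np.ndarray:
    """Iteratively drop pixels with fewer than two 8-neighbors in the edge."""
    e = edge.astype(bool).copy()
    kernel = np.ones((3, 3), dtype=np.uint8)
    kernel[1, 1] = 0
    while True:
        nb = ndimage.convolve(e.astype(np.uint8), kernel, mode="constant")
        spurs = e & (nb < 2)
        if not spurs.any():
            return e
        e &= ~spurs


# Clockwise ring of the 8 neighbor offsets, starting East, in image
# coordinates (row down): E, SE, S, SW, W, NW, N, NE.
_RING_CW = [(0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1), (-1, 0), (-1, 1)]
_RING_CCW = _RING_CW[::-1]


def _moore_walk(edge: np.ndarray, start: Point, ring: list) -> list[Point]:
    """Walk the closed edge curve hugging one side (scan order = ``ring``)."""
    h, w = edge.shape
    ring_index = {d: i for i, d in enumerate(ring)}
    npix = int(edge.sum())
    path = [start]
    # start is the lexicographic (row, col) minimum: nothing above it and
    # nothing to its left in the same row, so the backtrack direction is West.
    prev_dir = (0, -1)
    cur = start
    first_move: tuple[int, int] | None = None
    for _ in range(2 * npix + 4):
        back = ring_index[(-prev_dir[0], -prev_dir[1])]
        for step in range(1, 9):
            d = ring[(back + step) % 8]
            r, c = cur[0] + d[0], cur[1] + d[1]
            if 0 <= r < h and 0 <= c < w and edge[r, c]:
                nxt = (r, c)
                break
        else:  # isolated pixel: cannot happen after spur pruning
            raise ContourError("contour walk stranded at an isolated pixel")
        if first_move is None:
            first_move = d
        elif cur == start and d == first_move:
            # Jacob's stopping criterion: back at the start pixel and about
            # to repeat the initial move — the cycle is complete.
            return path[:-1] if path[-1] == start else path
        path.append(nxt)
        prev_dir = d
        cur = nxt
    raise ContourError("contour walk failed to close")


def trace_contour(edge_pixels: np.ndarray | set, side: str,
                  frame_index: int = 0,
                  shape: tuple[int, int] | None = None) -> EdgeContour:
    """Order an edge-pixel set into one closed clockwise contour.

    One-pixel spurs are pruned first; a disconnected remainder raises
    :class:`ContourError` naming the fragment count.
    """
    if isinstance(edge_pixels, set):
        if shape is None:
            raise ValueError("shape is required when passing a pixel set")
        edge = np.zeros(shape, dtype=np.uint8)
        for r, c in edge_pixels:
            edge[r, c] = 1
    else:
        edge = np.asarray(edge_pixels).astype(np.uint8)
    pruned = _prune_spurs(edge)
    if not pruned.any():
        raise ContourError("edge set fully pruned; no closed contour present")
    _, n = ndimage.label(pruned, structure=_STRUCT8)
    if n != 1:
        raise ContourError(f"edge set splits into {n} fragments; expected 1")
    rows, cols = np.nonzero(pruned)
    start = (int(rows[0]), int(cols[0]))  # np.nonzero is row-major: lex min
    npix = int(pruned.sum())
    path = None
    fallback = None
    for ring in (_RING_CW, _RING_CCW):
        cand = _moore_walk(pruned, start, ring)
        covered = len({tuple(p) for p in cand})
        if len(cand) == npix and covered == npix:
            path = cand  # exact cycle: every pixel visited once
            break
        if covered == npix and len(cand) <= npix + 8 and fallback is None:
            # pinched curve: the walk crosses a self-touching pixel twice;
            # accept full coverage with a handful of duplicates
            fallback = cand
    if path is None:
        path = fallback
    if path is None:
        raise ContourError(
            f"contour walk covered {covered}/{npix} edge pixels; "
            f"edge curve is pinched or self-touching"
        )
    arr = np.array(path, dtype=np.int64)
    # canonical orientation: clockwise in image coordinates (positive
    # shoelace sum with x=col, y=row, row increasing downward)
    x, y = arr[:, 1], arr[:, 0]
    shoelace = float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))
    if shoelace < 0:
        arr = np.vstack([arr[:1], arr[1:][::-1]])
    return EdgeContour(side=side, path=arr, frame_index=frame_index)


def find_costophrenic_angle(contour: EdgeContour) -> Point:
    """Inferior-most edge pixel; ties broken toward the lateral side.

    Lateral means the minimum column for the right lung (image left) and the
    maximum column for the left lung.
    """
    p = contour.path
    bottom = p[p[:, 0] == p[:, 0].max()]
    if contour.side == "right":
        c = bottom[:, 1].min()
    else:
        c = bottom[:, 1].max()
    return int(bottom[0, 0]), int(c)


def find_apex_anchor(contour: EdgeContour) -> Point:
    """Superior-most edge pixel; ties broken toward the medial side.

    Medial means the maximum column for the right lung and the minimum
    column for the left lung.
    """
    p = contour.path
    top = p[p[:, 0] == p[:, 0].min()]
    if contour.side == "right":
        c = top[:, 1].max()
    else:
        c = top[:, 1].min()
    return int(top[0, 0]), int(c)


def make_chord(a: Point, b: Point) -> Chord:
    """Unit-normalized line through a and b (x = col, y = row)."""
    if tuple(a) == tuple(b):
        raise GeometryError(f"degenerate chord: endpoints coincide at {a}")
    (ra, ca), (rb, cb) = a, b
    dx, dy = cb - ca, rb - ra
    norm = math.hypot(dx, dy)
    a_coef, b_coef = dy / norm, -dx / norm
    c_coef = -(a_coef * ca + b_coef * ra)
    return Chord(a=(int(ra), int(ca)), b=(int(rb), int(cb)),
                 coefficients=(a_coef, b_coef, c_coef))


def signed_point_line_distance(p: Point | np.ndarray, chord: Chord):
    """Signed distance of (row, col) point(s) to the chord line.

    Magnitude is the Euclidean point-to-line distance (Eq. of a normalized
    line); the sign is positive to the visual left of travel a→b.
    Accepts a single point or an (n, 2) array.
    """
    a_coef, b_coef, c_coef = chord.coefficients
    arr = np.asarray(p, dtype=float)
    if arr.ndim == 1:
        return float(a_coef * arr[1] + b_coef * arr[0] + c_coef)
    return a_coef * arr[:, 1] + b_coef * arr[:, 0] + c_coef


def _medial_sign(side: str, chord: Chord) -> float:
    """Sign of the signed distance on the medial side of the chord.

    Medial = greater column for the right lung, lesser column for the left.
    Probe with a point displaced by +1 column from the chord midpoint.
    """
    a_coef, _, _ = chord.coefficients
    # moving +1 in column changes the signed value by a_coef
    probe = a_coef if side == "right" else -a_coef
    if probe == 0:
        raise GeometryError("chord is vertical in columns; no medial side")
    return math.copysign(1.0, probe)


def medial_side_pixels(contour: EdgeContour, chord: Chord) -> np.ndarray:
    """Contour pixels strictly on the medial side of the chord, ordered
    along the arc from A through the inferior border to B.

    The returned (n, 2) array preserves contour order starting at the chord's
    A endpoint walking in the direction that traverses the medial/inferior
    arc first.  Raises :class:`ContourError` if no pixel lies medially.
    """
    p = contour.path
    sgn = _medial_sign(contour.side, chord)
    d = signed_point_line_distance(p, chord) * sgn
    medial = d > 1e-12
    if not medial.any():
        raise ContourError("no contour pixels on the medial side of the chord")
    ia = np.where((p[:, 0] == chord.a[0]) & (p[:, 1] == chord.a[1]))[0]
    if ia.size == 0:
        raise GeometryError("chord endpoint A does not lie on the contour")
    rolled = np.roll(np.arange(len(p)), -int(ia[0]))
    # walk forward or backward from A, whichever reaches a medial pixel first
    fwd = rolled
    bwd = rolled[::-1]
    bwd = np.roll(bwd, 1)  # keep A itself first
    def first_medial(order):
        hits = np.nonzero(medial[order])[0]
        return hits[0] if hits.size else len(p)
    order = fwd if first_medial(fwd) <= first_medial(bwd) else bwd
    return p[order][medial[order]]
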