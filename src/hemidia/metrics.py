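"""Evaluation metrics against ground-truth landmark annotations.

Per frame: Euclidean pixel errors of the four chord landmarks (B1, C1 on the
right lung; B2, C2 on the left) and signed length errors of both
hemi-diaphragms.  Per case: mean ± sample SD (min–max) per column, plus two
pooled columns — the mean of the four angle-error means and the mean of the
two length-error means.  Absolute values are taken of the signed length
errors before aggregation so positive and negative errors cannot cancel.
"""

from __future__ import annotations

import math
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

__all__ = [
    "landmark_error",
    "length_error",
    "frame_errors",
    "aggregate_case",
    "mean_error_of_means",
    "paper_summary",
    "round_half_up",
]

ANGLE_COLUMNS = ["dB1", "dC1", "dB2", "dC2"]
LENGTH_COLUMNS = ["len_err_right", "len_err_left"]


def round_half_up(value: float, decimals: int = 3) -> float:
    """Round half away from zero to the printed precision (display only).

    The value is first snapped to 12 significant digits so that decimal
    arithmetic carried out in binary floats (e.g. 13.214/4 = 3.3035, stored
    as 3.30349999...) still rounds the way the exact decimal would.
    """
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(f"{value:.12g}").quantize(q, rounding=ROUND_HALF_UP))


def landmark_error(p, p_gt) -> float:
    """Euclidean pixel distance between a detected point and its ground truth."""
    return math.hypot(p[0] - p_gt[0], p[1] - p_gt[1])


def length_error(l: float, l_gt: float) -> float:
    """Signed hemi-diaphragm length difference; aggregates use |.|."""
    if l < 0 or l_gt < 0:
        raise ValueError("hemi-diaphragm lengths must be non-negative")
    return l - l_gt


def frame_errors(detected: dict, truth: dict,
                 lengths: dict | None = None,
                 truth_lengths: dict | None = None) -> dict:
    """Error row for one frame.

    ``detected``/``truth`` map landmark names (B1, C1, B2, C2; C2 is the
    corrected point when a correction was applied) to (row, col).
    ``lengths``/``truth_lengths`` map "right"/"left" to hemi-diaphragm
    lengths.  Missing ground-truth entries yield NaN (recorded gaps).
    """
    row: dict = {}
    for name, col in zip(("B1", "C1", "B2", "C2"), ANGLE_COLUMNS):
        if name in detected and name in truth:
            row[col] = landmark_error(detected[name], truth[name])
        else:
            row[col] = np.nan
    for side, col in zip(("right", "left"), LENGTH_COLUMNS):
        if lengths and truth_lengths and side in lengths and side in truth_lengths:
            row[col] = length_error(lengths[side], truth_lengths[side])
        else:
            row[col] = np.nan
    return row


def _column_stats(values: pd.Series, absolute: bool) -> dict:
    v = values.dropna().astype(float)
    if absolute:
        v = v.abs()
    if v.empty:
        return {"mean": np.nan, "sd": np.nan, "min": np.nan, "max": np.nan,
                "n": 0}
    return {
        "mean": float(v.mean()),
        "sd": float(v.std(ddof=1)) if len(v) > 1 else 0.0,
        "min": float(v.min()),
        "max": float(v.max()),
        "n": int(len(v)),
    }


def aggregate_case(rows: pd.DataFrame | list[dict]) -> dict:
    """Per-case aggregates in the layout of the error tables.

    Returns ``{column: {mean, sd, min, max, n}}`` for the four angle columns
    and the two length columns (absolute values applied to length errors
    first), plus ``mean_error_angles`` and ``mean_error_lengths``.
    """
    df = pd.DataFrame(rows)
    if df.empty:
        raise ValueError("no error rows to aggregate")
    agg: dict = {}
    for col in ANGLE_COLUMNS:
        agg[col] = _column_stats(df[col], absolute=False)
    for col in LENGTH_COLUMNS:
        agg[col] = _column_stats(df[col], absolute=True)
    agg["mean_error_angles"] = mean_error_of_means(
        [agg[c]["mean"] for c in ANGLE_COLUMNS])
    agg["mean_error_lengths"] = mean_error_of_means(
        [agg[c]["mean"] for c in LENGTH_COLUMNS])
    return agg


def mean_error_of_means(column_means: list[float]) -> float:
    """Mean of per-column mean errors (the tables' "Mean error" cell)."""
    vals = [m for m in column_means if not (m is None or np.isnan(m))]
    if not vals:
        return float("nan")
    return float(np.mean(vals))


def paper_summary(case_means_before: list[float],
                  case_means_after: list[float],
                  pixel_spacing_um: float = 417.0) -> dict:
    """Pool per-case means and convert the error reduction to micrometres.

    Pooled values are arithmetic means of per-case means; the reduction is
    pooled_before − pooled_after, also expressed in micrometres via the
    detector pixel spacing.
    """
    before = float(np.mean(case_means_before))
    after = float(np.mean(case_means_after))
    reduction = before - after
    return {
        "pooled_before": before,
        "pooled_after": after,
        "reduction_px": reduction,
        "reduction_um": reduction * pixel_spacing_um,
    }


def format_cell(stats: dict, decimals: int = 3) -> str:
    """Render one aggregate as ``mean ± SD (min–max)`` at printed precision."""
    f = lambda v: f"{round_half_up(v, decimals):.{decimals}f}"
    return (f"{f(stats['mean'])} ± {f(stats['sd'])} "
            f"({f(stats['min'])}–{f(stats['max'])})")
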