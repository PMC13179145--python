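"""Shared anterior–posterior axis helpers.

The AP axis of a disc (or the analogous axis of any structure) is the
chord through its anterior-most and posterior-most points, where the
extremes are taken by projection onto the anterior direction supplied by
the image orientation metadata.  Ties are broken to the smallest row,
then smallest column, so that symmetric shapes get an axis-aligned chord.

All functions work in mm coordinates as (row_mm, col_mm) point arrays.
"""

from __future__ import annotations

import numpy as np


def to_mm(points_px: np.ndarray, spacing_mm: tuple[float, float]) -> np.ndarray:
    """(row, col) pixel coordinates -> (row_mm, col_mm)."""
    pts = np.asarray(points_px, dtype=float)
    return pts * np.asarray(spacing_mm, dtype=float)


def extreme_points(
    points_mm: np.ndarray, anterior: tuple[float, float]
) -> tuple[np.ndarray, np.ndarray]:
    """Anterior-most and posterior-most points of a point set.

    Projection onto the anterior unit vector, ties broken by smallest
    row then smallest column.
    """
    pts = np.asarray(points_mm, dtype=float)
    d = np.asarray(anterior, dtype=float)
    d = d / np.linalg.norm(d)
    proj = pts @ d
    tol = 1e-9 * max(1.0, float(np.abs(proj).max()))

    def pick(candidates: np.ndarray) -> np.ndarray:
        order = np.lexsort((candidates[:, 1], candidates[:, 0]))
        return candidates[order[0]].copy()

    p_ant = pick(pts[proj >= proj.max() - tol])
    p_post = pick(pts[proj <= proj.min() + tol])
    return p_ant, p_post


def ap_axis(
    points_mm: np.ndarray, anterior: tuple[float, float]
) -> tuple[np.ndarray, np.ndarray, float]:
    """AP chord of a point set: (posterior point, unit vector posterior->
    anterior, chord length mm)."""
    p_ant, p_post = extreme_points(points_mm, anterior)
    vec = p_ant - p_post
    length = float(np.linalg.norm(vec))
    if length == 0.0:
        raise ValueError("degenerate AP axis: all points coincide")
    return p_post, vec / length, length
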