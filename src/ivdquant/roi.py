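"""Point-guided region-of-interest handling.

A tracer places an ordered series of points around a disc or vertebral-body
boundary; the software closes them into a polygon, which is rasterized onto
the image grid and propagated unchanged across all echo times.  Manual
post-generation adjustment is modelled as supplying an edited point list.

Conventions: points are ``(row, col)`` in pixel units (sub-pixel allowed),
pixel centers sit at integer coordinates, point connection is linear
(polyline, not spline), and a pixel belongs to a mask iff its center lies
inside the polygon — centers exactly on an edge count as inside.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import shapely
from shapely.geometry import Polygon
from shapely.geometry.polygon import orient

from .stack import LEVELS, VERTEBRAE, EchoStack

__all__ = [
    "BoundaryTrace",
    "PixelMask",
    "TraceError",
    "close_boundary",
    "rasterize",
    "select_slices",
    "propagate",
    "read_traces",
    "write_traces",
]


class TraceError(ValueError):
    """A boundary trace violates its invariants (too few points,
    collinear, self-intersecting, unknown level, outside the grid)."""


@dataclass
class BoundaryTrace:
    """An ordered 2-D point list on one slice for one structure.

    ``points`` has shape (n, 2) as (row, col) pixel coordinates.
    """

    structure: str  # "disc" | "vertebra"
    level: str
    slice_index: int
    points: np.ndarray
    provenance: str = "manual"  # "manual" | "phantom-truth"

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise TraceError("trace points must be an (n, 2) array")
        if self.points.shape[0] < 3:
            raise TraceError(
                f"trace for {self.level} slice {self.slice_index}: "
                f"need >= 3 points, got {self.points.shape[0]}"
            )
        if self.structure not in ("disc", "vertebra"):
            raise TraceError(f"unknown structure kind {self.structure!r}")
        labels = LEVELS if self.structure == "disc" else VERTEBRAE
        if self.level not in labels:
            raise TraceError(
                f"unknown {self.structure} label {self.level!r}; "
                f"expected one of {labels}"
            )
        if self.slice_index < 0:
            raise TraceError("slice index must be >= 0")


@dataclass
class PixelMask:
    """Boolean mask congruent with one image slice."""

    slice_index: int
    mask: np.ndarray
    spacing_mm: tuple[float, float]

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())

    @property
    def pixel_area_mm2(self) -> float:
        return float(self.spacing_mm[0] * self.spacing_mm[1])

    @property
    def area_mm2(self) -> float:
        """Mask area: pixel count x pixel area."""
        return self.n_pixels * self.pixel_area_mm2

    def indices(self) -> tuple[np.ndarray, np.ndarray]:
        """(rows, cols) of included pixels, row-major order."""
        return np.nonzero(self.mask)


def _segments_intersect(p1, p2, p3, p4) -> bool:
    """Proper intersection of open segments p1p2 and p3p4."""

    def cross(o, a, b):
        return (a[0] - o[0]) * (b[1] - o[1]) - (a[1] - o[1]) * (b[0] - o[0])

    d1 = cross(p3, p4, p1)
    d2 = cross(p3, p4, p2)
    d3 = cross(p1, p2, p3)
    d4 = cross(p1, p2, p4)
    return ((d1 > 0) != (d2 > 0)) and ((d3 > 0) != (d4 > 0))


def _offending_segments(pts: np.ndarray) -> tuple[int, int] | None:
    """Brute-force search for a pair of properly crossing edges."""
    n = len(pts)
    edges = [(pts[i], pts[(i + 1) % n]) for i in range(n)]
    for i in range(n):
        for j in range(i + 2, n):
            if i == 0 and j == n - 1:  # adjacent around the wrap
                continue
            if _segments_intersect(*edges[i], *edges[j]):
                return i, j
    return None


def close_boundary(trace: BoundaryTrace) -> Polygon:
    """Connect traced points linearly into a simple closed polygon.

    The returned polygon lives in (x=col, y=row) pixel coordinates with
    counter-clockwise exterior orientation.  A duplicated closing point is
    dropped; collinear or self-intersecting traces are rejected, the
    latter naming the offending segment pair.
    """
    pts = trace.points
    if np.allclose(pts[0], pts[-1]):
        pts = pts[:-1]
    if pts.shape[0] < 3:
        raise TraceError("fewer than 3 distinct points after closing")
    xy = pts[:, ::-1]  # (row, col) -> (x=col, y=row)
    poly = Polygon(xy)
    if poly.is_valid and poly.is_simple and poly.area > 0.0:
        return orient(poly, sign=1.0)
    pair = _offending_segments(xy)
    if pair is not None:
        raise TraceError(
            f"trace for {trace.level} slice {trace.slice_index} "
            f"self-intersects (segments {pair[0]} and {pair[1]})"
        )
    if poly.area == 0.0:
        raise TraceError(
            f"trace for {trace.level} slice {trace.slice_index}: "
            "points are collinear (zero enclosed area)"
        )
    raise TraceError(
        f"trace for {trace.level} slice {trace.slice_index} is not a "
        "simple closed polygon"
    )


def rasterize(
    polygon: Polygon,
    grid_shape: tuple[int, int],
    spacing_mm: tuple[float, float],
    slice_index: int = 0,
) -> PixelMask:
    """Rasterize a polygon (pixel coordinates) onto the image grid.

    A pixel is included iff its center lies inside the polygon; centers
    exactly on an edge are counted inside.  The polygon must lie within
    the grid (pixel extent [-0.5, n-0.5] per axis).
    """
    n_rows, n_cols = grid_shape
    minx, miny, maxx, maxy = polygon.bounds
    if minx < -0.5 or miny < -0.5 or maxx > n_cols - 0.5 or maxy > n_rows - 0.5:
        raise TraceError(
            f"polygon bounds ({miny:.1f},{minx:.1f})-({maxy:.1f},{maxx:.1f}) "
            f"exceed grid {grid_shape}"
        )
    r0, r1 = int(np.ceil(miny)), int(np.floor(maxy))
    c0, c1 = int(np.ceil(minx)), int(np.floor(maxx))
    mask = np.zeros(grid_shape, dtype=bool)
    if r1 >= r0 and c1 >= c0:
        rows = np.arange(r0, r1 + 1)
        cols = np.arange(c0, c1 + 1)
        cc, rr = np.meshgrid(cols, rows)
        # intersects == interior or boundary hit at the pixel center
        inside = shapely.intersects_xy(polygon, cc.ravel(), rr.ravel())
        mask[r0 : r1 + 1, c0 : c1 + 1] = inside.reshape(rr.shape)
    return PixelMask(slice_index=slice_index, mask=mask, spacing_mm=spacing_mm)


def select_slices(
    traces: list[BoundaryTrace],
    n_slices: int,
) -> tuple[dict[str, list[int]], list[dict]]:
    """Determine which slices carry a valid closed trace for each level.

    Slices at the start or end of the stack where the boundary was not
    visible simply have no trace and are excluded.  Invalid traces
    (self-intersecting, collinear, out-of-stack slice index) are logged
    with a reason and excluded; a level with zero valid slices is marked
    missing in the log rather than raising.

    Returns ``(included, log)`` where ``included`` maps level -> sorted
    slice indices and ``log`` is a list of per-event dicts.
    """
    included: dict[str, list[int]] = {}
    log: list[dict] = []
    by_level: dict[str, list[BoundaryTrace]] = {}
    for tr in traces:
        by_level.setdefault(tr.level, []).append(tr)
    for level, level_traces in by_level.items():
        ok_slices: set[int] = set()
        for tr in level_traces:
            if tr.slice_index >= n_slices:
                log.append({
                    "level": level, "slice": tr.slice_index,
                    "event": "excluded", "reason": "slice_outside_stack",
                })
                continue
            try:
                close_boundary(tr)
            except TraceError as exc:
                log.append({
                    "level": level, "slice": tr.slice_index,
                    "event": "excluded", "reason": f"invalid_trace: {exc}",
                })
                continue
            ok_slices.add(tr.slice_index)
        if ok_slices:
            included[level] = sorted(ok_slices)
            log.append({
                "level": level, "event": "included",
                "slices": sorted(ok_slices),
            })
        else:
            log.append({
                "level": level, "event": "level_missing",
                "reason": "no_valid_slices",
            })
    return included, log


def propagate(trace: BoundaryTrace, stack: EchoStack) -> np.ndarray:
    """Extract the traced pixel values across all echo times.

    The identical pixel index set (from rasterizing the closed trace on
    its slice) is used at every echo.  Returns an array of shape
    ``(n_mask_pixels, n_echoes)`` with echoes ordered by ascending TE.
    """
    if trace.slice_index >= stack.n_slices:
        raise TraceError(
            f"slice {trace.slice_index} outside stack of {stack.n_slices}"
        )
    stack = stack.sorted_by_echo_time()
    poly = close_boundary(trace)
    mask = rasterize(
        poly, stack.grid_shape, stack.spacing_mm, trace.slice_index
    )
    rows, cols = mask.indices()
    return stack.data[trace.slice_index, rows, cols, :]


# ---------------------------------------------------------------------------
# ROI JSON interchange format: one object per trace, array per file:
#   {"level": ..., "structure": ..., "slice": ..., "points": [[r, c], ...],
#    "spacing_mm": [dr, dc], "provenance": ...}
# ---------------------------------------------------------------------------

def write_traces(
    traces: list[BoundaryTrace],
    path: str | Path,
    spacing_mm: tuple[float, float],
) -> None:
    """Write traces to the ROI JSON interchange format."""
    records = [
        {
            "level": tr.level,
            "structure": tr.structure,
            "slice": int(tr.slice_index),
            "points": np.asarray(tr.points, dtype=float).tolist(),
            "spacing_mm": [float(spacing_mm[0]), float(spacing_mm[1])],
            "provenance": tr.provenance,
        }
        for tr in traces
    ]
    Path(path).write_text(json.dumps(records, indent=1))


def read_traces(path: str | Path) -> tuple[list[BoundaryTrace], tuple[float, float]]:
    """Read and validate traces from the ROI JSON format."""
    records = json.loads(Path(path).read_text())
    if not isinstance(records, list):
        raise TraceError("ROI JSON must be an array of trace objects")
    traces: list[BoundaryTrace] = []
    spacing: tuple[float, float] | None = None
    for rec in records:
        tr = BoundaryTrace(
            structure=rec["structure"],
            level=rec["level"],
            slice_index=int(rec["slice"]),
            points=np.asarray(rec["points"], dtype=float),
            provenance=rec.get("provenance", "manual"),
        )
        sp = tuple(float(v) for v in rec["spacing_mm"])
        if spacing is None:
            spacing = sp  # type: ignore[assignment]
        elif sp != spacing:
            raise TraceError("inconsistent spacing_mm across traces in file")
        traces.append(tr)
    if spacing is None:
        raise TraceError("ROI JSON file holds no traces")
    return traces, spacing
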