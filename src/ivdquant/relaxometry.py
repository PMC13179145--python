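"""T2 relaxometry: log-linear fitting and anterior–posterior partitioning.

Transverse relaxation is modelled as mono-exponential,
``S(TE) = S0 * exp(-TE / T2)``, so a straight-line fit of ln S against
echo time gives ``T2 = -1/slope`` and ``S0 = exp(intercept)``.  All
echoes are used by default, with no explicit stimulated-echo
suppression; an echo subset (e.g. dropping the first echo) can be
selected upstream.

Each disc is divided into five equidistant anterior–posterior bands along
its width: 1 = anterior annulus, 2 = anterior nucleus, 3 = central
nucleus, 4 = posterior nucleus, 5 = posterior annulus.  Regional T2 fits
the region-mean signal per echo by default (average, log, fit); a
per-voxel mode (fit every voxel, average the T2s) is available for
sensitivity checks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._geom import ap_axis, to_mm
from .roi import PixelMask
from .stack import ANTERIOR_DEFAULT, EchoStack

__all__ = [
    "T2Fit",
    "PartitionError",
    "REGION_NAMES",
    "fit_t2",
    "partition_ap",
    "region_t2",
    "aggregate_level",
]

REGION_NAMES: dict[int, str] = {
    1: "anterior annulus",
    2: "anterior nucleus",
    3: "central nucleus",
    4: "posterior nucleus",
    5: "posterior annulus",
}

#: Minimum AP extent (pixels) for a partitionable mask.
MIN_PARTITION_WIDTH_PX = 5


class PartitionError(ValueError):
    """Mask too degenerate to partition into five AP bands."""


@dataclass
class T2Fit:
    """Result of one log-linear T2 fit."""

    t2_ms: float
    s0: float
    r2: float
    n_echoes: int
    ok: bool = True
    reason: str | None = None

    @classmethod
    def failed(cls, reason: str, n_echoes: int = 0) -> "T2Fit":
        return cls(
            t2_ms=np.nan, s0=np.nan, r2=np.nan,
            n_echoes=n_echoes, ok=False, reason=reason,
        )


def fit_t2(signal: np.ndarray, echo_times_ms: np.ndarray) -> T2Fit:
    """Fit T2 by ordinary least squares of ln(signal) on echo time.

    Echoes with non-positive signal are dropped (they have no logarithm);
    fewer than 3 usable echoes, or a non-negative slope (non-decaying
    signal), yield a failed fit carrying a reason code instead of a value.
    """
    s = np.asarray(signal, dtype=float)
    te = np.asarray(echo_times_ms, dtype=float)
    if s.shape != te.shape:
        raise ValueError("signal and echo_times_ms must have the same shape")
    keep = s > 0
    s, te = s[keep], te[keep]
    n = s.size
    if n < 3:
        return T2Fit.failed("insufficient_positive_echoes", n_echoes=n)
    y = np.log(s)
    te_c = te - te.mean()
    y_c = y - y.mean()
    sxx = float(te_c @ te_c)
    slope = float(te_c @ y_c) / sxx
    if slope >= 0.0:
        return T2Fit.failed("non_decaying_signal", n_echoes=n)
    intercept = float(y.mean() - slope * te.mean())
    ss_tot = float(y_c @ y_c)
    ss_res = float(np.sum((y - (intercept + slope * te)) ** 2))
    r2 = 1.0 if ss_tot == 0.0 else 1.0 - ss_res / ss_tot
    return T2Fit(
        t2_ms=-1.0 / slope,
        s0=float(np.exp(intercept)),
        r2=float(np.clip(r2, 0.0, 1.0)),
        n_echoes=n,
    )


def partition_ap(
    mask: PixelMask,
    anterior: tuple[float, float] = ANTERIOR_DEFAULT,
) -> np.ndarray:
    """Label every mask pixel with its anterior–posterior region (1–5).

    The AP axis is the chord through the anterior-most and posterior-most
    mask pixel centers (projection onto the anterior direction, ties to
    the smallest row then column).  Pixel centers are projected onto this
    chord and binned into five equal-length intervals; band boundaries
    are half-open so that a center exactly on a boundary falls in the
    lower-index (more anterior) band; region 1 is the anterior band.

    Returns an integer grid congruent with the mask: 0 outside, 1–5
    inside.  Raises :class:`PartitionError` for masks narrower than
    five pixels along the axis.
    """
    rows, cols = mask.indices()
    if rows.size == 0:
        raise PartitionError("empty mask")
    pts_px = np.column_stack([rows, cols]).astype(float)
    pts_mm = to_mm(pts_px, mask.spacing_mm)
    p_post, u, length = ap_axis(pts_mm, anterior)
    mean_spacing = float(np.mean(mask.spacing_mm))
    if length / mean_spacing < MIN_PARTITION_WIDTH_PX - 1:
        raise PartitionError(
            f"AP extent {length:.2f} mm (< {MIN_PARTITION_WIDTH_PX} px) "
            "too narrow to partition"
        )
    # t runs 0 at the posterior-most point to 1 at the anterior-most;
    # pixels projecting beyond the chord ends fall into the end bands.
    t = np.clip(((pts_mm - p_post) @ u) / length, 0.0, 1.0)
    band_from_posterior = np.minimum(np.floor(5.0 * t).astype(int), 4)
    labels_flat = 5 - band_from_posterior
    labels = np.zeros(mask.mask.shape, dtype=np.int8)
    labels[rows, cols] = labels_flat
    return labels


def region_t2(
    stack: EchoStack,
    mask: PixelMask,
    partition: np.ndarray,
    mode: str = "mean",
) -> dict[int, T2Fit]:
    """Fit T2 per AP region (keys 1–5) and for the whole disc (key 0).

    ``mode="mean"`` (default): average the signal over region pixels at
    each echo, then fit once.  ``mode="voxel"``: fit every voxel and
    average the successful T2 estimates (sensitivity mode).
    """
    if mode not in ("mean", "voxel"):
        raise ValueError(f"unknown fit mode {mode!r}")
    stack = stack.sorted_by_echo_time()
    te = stack.echo_times_ms
    img = stack.data[mask.slice_index]  # (row, col, echo)
    out: dict[int, T2Fit] = {}
    for region in (0, 1, 2, 3, 4, 5):
        sel = mask.mask if region == 0 else (partition == region)
        if not sel.any():
            out[region] = T2Fit.failed("empty_region")
            continue
        values = img[sel, :]  # (n_pixels, n_echoes)
        if mode == "mean":
            out[region] = fit_t2(values.mean(axis=0), te)
        else:
            fits = [fit_t2(v, te) for v in values]
            t2s = [f.t2_ms for f in fits if f.ok]
            if not t2s:
                out[region] = T2Fit.failed("all_voxel_fits_failed")
            else:
                r2s = [f.r2 for f in fits if f.ok]
                out[region] = T2Fit(
                    t2_ms=float(np.mean(t2s)), s0=np.nan,
                    r2=float(np.mean(r2s)), n_echoes=int(te.size),
                )
    return out


def aggregate_level(per_slice_values) -> tuple[float, int]:
    """Unweighted mean over included slices.

    Missing slices (NaN or None) are excluded; returns ``(mean, n)`` with
    the count of contributing slices, or ``(nan, 0)`` if none remain.
    """
    vals = np.asarray(
        [np.nan if v is None else float(v) for v in per_slice_values]
    )
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        return float("nan"), 0
    return float(vals.mean()), int(vals.size)
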