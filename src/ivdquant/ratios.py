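"""Nucleus-to-annulus signal-intensity ratio from T2-weighted images.

The hydrated nucleus pulposus is bright on T2-weighted images while the
annulus fibrosus is dark, so the ratio of the mean signal of the three
central anterior–posterior regions (2, 3, 4 — the nucleus) to the mean
of the two outer regions (1, 5 — the annulus) indexes disc hydration
contrast.  Regions are averaged across slices first and the ratio is
formed once per level (ratio of averaged regions, not an average of
per-slice ratios); both region means enter the ratio unweighted by pixel
count.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .roi import PixelMask

__all__ = [
    "RegionIntensity",
    "region_intensities",
    "nucleus_annulus_ratio",
    "level_ratio",
]

NUCLEUS_REGIONS = (2, 3, 4)
ANNULUS_REGIONS = (1, 5)


@dataclass
class RegionIntensity:
    """Mean signal and pixel count per AP region on one slice."""

    level: str
    slice_index: int
    means: np.ndarray  # shape (5,), regions 1..5
    counts: np.ndarray  # shape (5,)

    @property
    def valid(self) -> bool:
        return bool(np.all(self.counts >= 1))


def region_intensities(
    image_slice: np.ndarray,
    mask: PixelMask,
    partition: np.ndarray,
    level: str = "",
) -> RegionIntensity:
    """Mean signal per AP region on one single-echo slice."""
    means = np.full(5, np.nan)
    counts = np.zeros(5, dtype=int)
    for region in range(1, 6):
        sel = partition == region
        counts[region - 1] = int(sel.sum())
        if counts[region - 1]:
            means[region - 1] = float(image_slice[sel].mean())
    return RegionIntensity(
        level=level, slice_index=mask.slice_index, means=means, counts=counts
    )


def nucleus_annulus_ratio(region_means) -> float:
    """Ratio of mean nucleus (regions 2,3,4) to mean annulus (1,5) signal.

    Unweighted means of the five region means.  Returns NaN (missing) if
    any region mean is absent or the annulus mean is not positive.
    """
    m = np.asarray(region_means, dtype=float)
    if m.shape != (5,):
        raise ValueError("expected exactly 5 region means")
    if not np.all(np.isfinite(m)):
        return float("nan")
    nucleus = m[[r - 1 for r in NUCLEUS_REGIONS]].mean()
    annulus = m[[r - 1 for r in ANNULUS_REGIONS]].mean()
    if annulus <= 0.0:
        return float("nan")
    return float(nucleus / annulus)


def level_ratio(
    per_slice_region_means,
    mode: str = "ratio_of_averages",
) -> tuple[float, int]:
    """Level nucleus-to-annulus ratio from per-slice region means.

    ``per_slice_region_means`` is an (n_slices, 5) array.  The default
    order of operations averages each region over slices first, then
    forms one ratio per level.  ``mode="average_of_ratios"`` (sensitivity
    alternative) forms per-slice ratios and averages them instead.

    Returns ``(ratio, n_slices_used)``; slices with any missing region
    are excluded.
    """
    arr = np.asarray(per_slice_region_means, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 5:
        raise ValueError("expected an (n_slices, 5) array of region means")
    complete = np.all(np.isfinite(arr), axis=1)
    arr = arr[complete]
    n = int(arr.shape[0])
    if n == 0:
        return float("nan"), 0
    if mode == "ratio_of_averages":
        return nucleus_annulus_ratio(arr.mean(axis=0)), n
    if mode == "average_of_ratios":
        ratios = np.asarray([nucleus_annulus_ratio(row) for row in arr])
        ratios = ratios[np.isfinite(ratios)]
        if ratios.size == 0:
            return float("nan"), 0
        return float(ratios.mean()), int(ratios.size)
    raise ValueError(f"unknown aggregation mode {mode!r}")
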