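"""In-memory image stack containers shared across the pipeline.

Conventions (used everywhere in the package):

* voxel array axes are ``(slice, row, col)`` for single-echo stacks and
  ``(slice, row, col, echo)`` for multi-echo stacks;
* pixel coordinates are 0-based ``(row, col)`` with pixel centers at
  integer coordinates; sub-pixel positions are allowed in traces;
* in-plane spacing is per-axis ``(mm/row-step, mm/col-step)``;
* the anterior anatomical direction defaults to increasing column index
  (phantom convention); real data must carry orientation metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Disc levels, superior to inferior.
LEVELS: tuple[str, ...] = (
    "T11/T12", "T12/L1", "L1/L2", "L2/L3", "L3/L4", "L4/L5", "L5/S1",
)

#: Vertebral bodies spanning the disc levels above.
VERTEBRAE: tuple[str, ...] = ("T11", "T12", "L1", "L2", "L3", "L4", "L5", "S1")

#: Vertebral body used to normalise each disc level (the vertebra inferior
#: to the disc's upper vertebra, i.e. the lower vertebra of the pair).
DISC_TO_VERTEBRA: dict[str, str] = {
    "T11/T12": "T12", "T12/L1": "L1", "L1/L2": "L2", "L2/L3": "L3",
    "L3/L4": "L4", "L4/L5": "L5", "L5/S1": "S1",
}

#: Default anterior direction as a (row, col) unit vector.
ANTERIOR_DEFAULT: tuple[float, float] = (0.0, 1.0)


@dataclass
class EchoStack:
    """A multi-echo image stack with its acquisition geometry.

    Parameters
    ----------
    data
        Voxel values, shape ``(n_slices, n_rows, n_cols, n_echoes)``.
    echo_times_ms
        Echo time of each echo, ms, strictly increasing.
    spacing_mm
        In-plane pixel spacing ``(row, col)`` in mm.
    slice_thickness_mm, slice_gap_mm
        Through-plane geometry; their sum is the effective slice spacing
        used for volume integration.
    anterior
        Anatomical anterior direction as a (row, col) unit vector.
    """

    data: np.ndarray
    echo_times_ms: np.ndarray
    spacing_mm: tuple[float, float]
    slice_thickness_mm: float
    slice_gap_mm: float
    anterior: tuple[float, float] = ANTERIOR_DEFAULT
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.echo_times_ms = np.asarray(self.echo_times_ms, dtype=float)
        if self.data.ndim == 3:  # single-echo convenience
            self.data = self.data[..., np.newaxis]
        if self.data.ndim != 4:
            raise ValueError("EchoStack data must be (slice, row, col, echo)")
        if self.data.shape[-1] != self.echo_times_ms.size:
            raise ValueError(
                f"{self.data.shape[-1]} echo volumes but "
                f"{self.echo_times_ms.size} echo times"
            )
        if self.echo_times_ms.size and (
            np.any(self.echo_times_ms <= 0)
            or np.unique(self.echo_times_ms).size != self.echo_times_ms.size
        ):
            raise ValueError("echo times must be distinct and > 0")

    @property
    def n_slices(self) -> int:
        return self.data.shape[0]

    @property
    def n_echoes(self) -> int:
        return self.data.shape[-1]

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.data.shape[1], self.data.shape[2]

    @property
    def effective_slice_spacing_mm(self) -> float:
        """Slice thickness + interslice gap, mm (volume integration step)."""
        return self.slice_thickness_mm + self.slice_gap_mm

    def sorted_by_echo_time(self) -> "EchoStack":
        """Return a copy with echoes sorted by ascending echo time."""
        order = np.argsort(self.echo_times_ms, kind="stable")
        return EchoStack(
            data=self.data[..., order],
            echo_times_ms=self.echo_times_ms[order],
            spacing_mm=self.spacing_mm,
            slice_thickness_mm=self.slice_thickness_mm,
            slice_gap_mm=self.slice_gap_mm,
            anterior=self.anterior,
            meta=dict(self.meta),
        )
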