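"""Synthetic lumbar-spine phantoms and synthetic cohorts.

Every downstream stage of the pipeline is exercised on data generated
here, so no image download is ever required.  The phantom emulates a
sagittal multi-echo spin-echo acquisition: discs are superellipse
cross-sections stacked over a slice extent, voxel signal decays
mono-exponentially with echo time (``S = S0 * exp(-TE/T2)``) with a
distinct true T2 per anterior–posterior region, and optional additive
Gaussian or Rician noise.  Companion single-echo T2-weighted and
vertebral-body (mDIXON-analog) stacks support the nucleus-to-annulus
ratio and the height-to-vertebral-body ratio.

The cohort generator draws per-participant exposures (lifetime
physical-loading scores), covariates, and disc outcomes with *planted*
linear effects ``y = alpha + beta_true * BPAQ + sum gamma_k cov_k + eps``
so that the statistics module can be tested by parameter recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import gamma as gamma_fn
from scipy.stats import truncnorm
from shapely.geometry import Polygon

from .relaxometry import partition_ap
from .roi import BoundaryTrace, PixelMask, rasterize
from .stack import DISC_TO_VERTEBRA, LEVELS, VERTEBRAE, EchoStack

__all__ = [
    "SequenceGeometry",
    "MULTIECHO_SEQUENCE",
    "T2W_SEQUENCE",
    "MDIXON_SEQUENCE",
    "DiscSpec",
    "PhantomSpec",
    "CohortSpec",
    "SexParams",
    "GroundTruth",
    "ConfigurationError",
    "default_phantom_spec",
    "make_disc_geometry",
    "simulate_multiecho",
    "simulate_t2w",
    "simulate_vertebral",
    "generate_cohort",
    "assign_pfirrmann",
    "spec_from_truth",
    "superellipse_area_mm2",
]


class ConfigurationError(ValueError):
    """A phantom or cohort specification is internally inconsistent."""


# ---------------------------------------------------------------------------
# Acquisition geometry of the three emulated sequences
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SequenceGeometry:
    """Acquisition geometry of one sagittal sequence."""

    name: str
    fov_mm: tuple[float, float]  # (row extent, col extent)
    matrix: tuple[int, int]  # (rows, cols)
    n_slices: int
    slice_thickness_mm: float
    slice_gap_mm: float
    echo_times_ms: tuple[float, ...]

    @property
    def pixel_spacing_mm(self) -> tuple[float, float]:
        return (
            self.fov_mm[0] / self.matrix[0],
            self.fov_mm[1] / self.matrix[1],
        )

    @property
    def pixel_area_mm2(self) -> float:
        dr, dc = self.pixel_spacing_mm
        return dr * dc

    @property
    def effective_slice_spacing_mm(self) -> float:
        return self.slice_thickness_mm + self.slice_gap_mm


#: Eight-echo sagittal spin-echo sequence used for T2, height and volume.
MULTIECHO_SEQUENCE = SequenceGeometry(
    name="sagittal spin-echo multi-echo",
    fov_mm=(634.0, 669.0),
    matrix=(704, 704),
    n_slices=12,
    slice_thickness_mm=3.5,
    slice_gap_mm=1.0,
    echo_times_ms=(15.75, 36.75, 57.75, 78.75, 99.75, 120.75, 141.75, 162.75),
)

#: Single-echo T2-weighted sequence used for the nucleus-to-annulus ratio.
T2W_SEQUENCE = SequenceGeometry(
    name="T2 sagittal spin-echo",
    fov_mm=(400.0, 400.0),
    matrix=(768, 768),
    n_slices=15,
    slice_thickness_mm=3.5,
    slice_gap_mm=1.0,
    echo_times_ms=(70.0,),
)

#: Two-echo mDIXON sequence used for vertebral-body height.
MDIXON_SEQUENCE = SequenceGeometry(
    name="mDIXON sagittal TE",
    fov_mm=(400.0, 400.0),
    matrix=(512, 512),
    n_slices=80,
    slice_thickness_mm=3.0,
    slice_gap_mm=0.0,
    echo_times_ms=(1.186, 2.372),
)

DEFAULT_ECHO_TIMES_MS = MULTIECHO_SEQUENCE.echo_times_ms


# ---------------------------------------------------------------------------
# Phantom specification
# ---------------------------------------------------------------------------

#: Superellipse exponent for disc cross-sections (rounded, simple shape).
DISC_EXPONENT = 2.5
#: Superellipse exponent for vertebral bodies (near-rectangular).
VERTEBRA_EXPONENT = 6.0


def superellipse_area_mm2(width_mm: float, height_mm: float,
                          exponent: float) -> float:
    """Analytic area of ``|x/a|^n + |y/b|^n = 1`` with a=w/2, b=h/2."""
    a, b = width_mm / 2.0, height_mm / 2.0
    n = exponent
    return 4.0 * a * b * gamma_fn(1 + 1 / n) ** 2 / gamma_fn(1 + 2 / n)


def superellipse_chord_mean_factor(
    exponent: float, k: int = 50, tail_fraction: float = 0.05
) -> float:
    """Ratio of the station-mean perpendicular chord to the nominal
    (maximal) height of a superellipse.

    The morphometric height convention averages perpendicular chords at
    ``k`` stations along the AP axis excluding ``tail_fraction`` at each
    end, so the measured height of a superellipse of nominal height h is
    ``factor * h`` with this analytic factor.
    """
    u = np.linspace(2 * tail_fraction - 1.0, 1.0 - 2 * tail_fraction, k)
    return float(np.mean((1.0 - np.abs(u) ** exponent) ** (1.0 / exponent)))


@dataclass
class DiscSpec:
    """Geometry of one disc level in the phantom."""

    center_px: tuple[float, float]  # (row, col)
    width_mm: float
    height_mm: float
    slice_first: int
    slice_last: int  # inclusive
    exponent: float = DISC_EXPONENT

    @property
    def slices(self) -> list[int]:
        return list(range(self.slice_first, self.slice_last + 1))


@dataclass
class PhantomSpec:
    """Full specification of a multi-echo lumbar-spine phantom."""

    n_slices: int = 12
    grid_shape: tuple[int, int] = (384, 160)
    spacing_mm: tuple[float, float] = (0.90, 0.95)
    slice_thickness_mm: float = 3.5
    slice_gap_mm: float = 1.0
    echo_times_ms: tuple[float, ...] = DEFAULT_ECHO_TIMES_MS
    s0_disc: float = 1000.0
    s0_background: float = 300.0
    t2_background_ms: float = 50.0
    discs: dict[str, DiscSpec] = field(default_factory=dict)
    region_t2_ms: dict[str, tuple[float, ...]] = field(default_factory=dict)
    vertebra_heights_mm: dict[str, float] = field(default_factory=dict)
    vertebra_centers_px: dict[str, tuple[float, float]] = field(
        default_factory=dict
    )
    vertebra_width_mm: float = 34.0
    nucleus_intensity: dict[str, float] | float = 200.0
    annulus_intensity: dict[str, float] | float = 100.0
    t2w_background: float = 40.0
    vertebral_intensity: float = 180.0
    noise_model: str = "none"  # none | gaussian | rician
    noise_sigma: float = 0.0
    seed: int = 0

    def nucleus_intensity_at(self, level: str) -> float:
        v = self.nucleus_intensity
        return float(v[level] if isinstance(v, dict) else v)

    def annulus_intensity_at(self, level: str) -> float:
        v = self.annulus_intensity
        return float(v[level] if isinstance(v, dict) else v)

    def validate(self) -> None:
        te = np.asarray(self.echo_times_ms, dtype=float)
        if np.any(te <= 0) or np.any(np.diff(te) <= 0):
            raise ConfigurationError(
                "echo times must be strictly increasing and > 0"
            )
        if self.noise_model not in ("none", "gaussian", "rician"):
            raise ConfigurationError(
                f"unknown noise model {self.noise_model!r}"
            )
        if self.noise_sigma < 0:
            raise ConfigurationError("noise sigma must be >= 0")
        if self.t2_background_ms <= 0:
            raise ConfigurationError("background T2 must be > 0")
        for level, disc in self.discs.items():
            if disc.width_mm <= 0 or disc.height_mm <= 0:
                raise ConfigurationError(
                    f"{level}: disc width/height must be > 0"
                )
            if disc.slice_last < disc.slice_first:
                raise ConfigurationError(
                    f"{level}: empty slice extent "
                    f"[{disc.slice_first}, {disc.slice_last}]"
                )
            if disc.slice_first < 0 or disc.slice_last >= self.n_slices:
                raise ConfigurationError(
                    f"{level}: slice extent outside the {self.n_slices}-slice"
                    " stack"
                )
            t2s = self.region_t2_ms.get(level)
            if t2s is None or len(t2s) != 5:
                raise ConfigurationError(
                    f"{level}: need exactly 5 region T2 values"
                )
            if np.any(np.asarray(t2s, dtype=float) <= 0):
                raise ConfigurationError(f"{level}: region T2 must be > 0")
            if self.annulus_intensity_at(level) < 0 or \
                    self.nucleus_intensity_at(level) < 0:
                raise ConfigurationError(
                    f"{level}: T2-weighted intensities must be >= 0"
                )
        for vert, h in self.vertebra_heights_mm.items():
            if h <= 0:
                raise ConfigurationError(f"{vert}: vertebral height must be > 0")


#: Default per-level disc geometry (height, width in mm) and region T2 (ms).
_DEFAULT_DISC_DIMS: dict[str, tuple[float, float]] = {
    # level: (height_mm, width_mm)
    "T11/T12": (8.0, 32.0),
    "T12/L1": (8.5, 33.0),
    "L1/L2": (9.0, 34.0),
    "L2/L3": (9.5, 35.0),
    "L3/L4": (10.0, 36.0),
    "L4/L5": (11.0, 37.0),
    "L5/S1": (10.0, 36.0),
}

_DEFAULT_REGION_T2: dict[str, tuple[float, ...]] = {
    "T11/T12": (70.0, 105.0, 112.0, 105.0, 66.0),
    "T12/L1": (71.0, 107.0, 114.0, 107.0, 67.0),
    "L1/L2": (72.0, 109.0, 116.0, 109.0, 68.0),
    "L2/L3": (73.0, 111.0, 118.0, 111.0, 69.0),
    "L3/L4": (74.0, 113.0, 120.0, 113.0, 70.0),
    "L4/L5": (73.0, 112.0, 119.0, 112.0, 69.0),
    "L5/S1": (71.0, 108.0, 115.0, 108.0, 67.0),
}

DEFAULT_VB_HEIGHT_MM = 27.0


def default_phantom_spec(seed: int = 0, **overrides) -> PhantomSpec:
    """Seven-level default phantom mirroring the emulated acquisition:
    12 slices of 3.5 mm with a 1.0 mm gap, eight echo times, discs traced
    on slices 2–9."""
    spec = PhantomSpec(seed=seed, **overrides)
    dr, dc = spec.spacing_mm
    n_rows, n_cols = spec.grid_shape
    col_center = (n_cols - 1) / 2.0
    row_mm = 22.0  # superior margin
    vb_heights = {v: DEFAULT_VB_HEIGHT_MM for v in VERTEBRAE}
    gap_mm = 1.0  # cortical gap between disc and endplate
    discs: dict[str, DiscSpec] = {}
    centers: dict[str, tuple[float, float]] = {}
    for i, vert in enumerate(VERTEBRAE):
        vb_h = vb_heights[vert]
        centers[vert] = ((row_mm + vb_h / 2.0) / dr, col_center)
        row_mm += vb_h + gap_mm
        if i < len(LEVELS):
            level = LEVELS[i]
            h, w = _DEFAULT_DISC_DIMS[level]
            discs[level] = DiscSpec(
                center_px=((row_mm + h / 2.0) / dr, col_center),
                width_mm=w,
                height_mm=h,
                slice_first=2,
                slice_last=9,
            )
            row_mm += h + gap_mm
    spec.discs = discs
    spec.region_t2_ms = dict(_DEFAULT_REGION_T2)
    spec.vertebra_heights_mm = vb_heights
    spec.vertebra_centers_px = centers
    spec.validate()
    return spec


# ---------------------------------------------------------------------------
# Geometry
# ---------------------------------------------------------------------------

def _superellipse_polygon(
    center_px: tuple[float, float],
    width_mm: float,
    height_mm: float,
    exponent: float,
    spacing_mm: tuple[float, float],
    n_vertices: int = 128,
) -> Polygon:
    """Superellipse boundary polygon in (x=col, y=row) pixel coordinates."""
    dr, dc = spacing_mm
    a_px = width_mm / 2.0 / dc
    b_px = height_mm / 2.0 / dr
    t = np.linspace(0.0, 2.0 * np.pi, n_vertices, endpoint=False)
    e = 2.0 / exponent
    x = center_px[1] + a_px * np.sign(np.cos(t)) * np.abs(np.cos(t)) ** e
    y = center_px[0] + b_px * np.sign(np.sin(t)) * np.abs(np.sin(t)) ** e
    return Polygon(np.column_stack([x, y]))


@dataclass
class DiscGeometry:
    """Rasterized phantom disc geometry (shared across echoes)."""

    polygons: dict[str, Polygon]  # per level, identical across its slices
    slices: dict[str, list[int]]
    masks: dict[str, PixelMask]
    partitions: dict[str, np.ndarray]  # 1..5 region labels per level
    analytic_area_mm2: dict[str, float]


def make_disc_geometry(spec: PhantomSpec) -> DiscGeometry:
    """Build per-level disc polygons, masks and AP region labels.

    Each disc is a superellipse cross-section replicated over its slice
    extent.  Raises :class:`ConfigurationError` (naming the level) if a
    disc exceeds the grid.
    """
    spec.validate()
    polygons: dict[str, Polygon] = {}
    slices: dict[str, list[int]] = {}
    masks: dict[str, PixelMask] = {}
    partitions: dict[str, np.ndarray] = {}
    areas: dict[str, float] = {}
    for level, disc in spec.discs.items():
        poly = _superellipse_polygon(
            disc.center_px, disc.width_mm, disc.height_mm,
            disc.exponent, spec.spacing_mm,
        )
        minx, miny, maxx, maxy = poly.bounds
        n_rows, n_cols = spec.grid_shape
        if minx < -0.5 or miny < -0.5 or maxx > n_cols - 0.5 \
                or maxy > n_rows - 0.5:
            raise ConfigurationError(
                f"{level}: disc geometry exceeds the "
                f"{n_rows}x{n_cols} grid"
            )
        mask = rasterize(poly, spec.grid_shape, spec.spacing_mm)
        polygons[level] = poly
        slices[level] = disc.slices
        masks[level] = mask
        partitions[level] = partition_ap(mask)
        areas[level] = superellipse_area_mm2(
            disc.width_mm, disc.height_mm, disc.exponent
        )
    return DiscGeometry(
        polygons=polygons, slices=slices, masks=masks,
        partitions=partitions, analytic_area_mm2=areas,
    )


def _disc_traces(spec: PhantomSpec, geometry: DiscGeometry) -> list[BoundaryTrace]:
    traces = []
    for level, poly in geometry.polygons.items():
        pts = np.asarray(poly.exterior.coords[:-1])[:, ::-1]  # (row, col)
        for s in geometry.slices[level]:
            traces.append(BoundaryTrace(
                structure="disc", level=level, slice_index=s,
                points=pts.copy(), provenance="phantom-truth",
            ))
    return traces


# ---------------------------------------------------------------------------
# Ground truth ledger
# ---------------------------------------------------------------------------

@dataclass
class LevelTruth:
    """True per-level quantities of one phantom."""

    region_t2_ms: tuple[float, ...]
    height_mm: float
    width_mm: float
    slice_areas_mm2: list[float]
    volume_cm3: float
    vb_height_mm: float
    nucleus_intensity: float
    annulus_intensity: float
    pfirrmann: int
    slices: list[int]


@dataclass
class GroundTruth:
    """Truth ledger written alongside every simulated phantom."""

    levels: dict[str, LevelTruth]
    disc_traces: list[BoundaryTrace]
    vertebra_traces: list[BoundaryTrace] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for level, lt in self.levels.items():
            rows.append({
                "level": level,
                **{f"t2_r{i+1}": lt.region_t2_ms[i] for i in range(5)},
                "height_mm": lt.height_mm,
                "width_mm": lt.width_mm,
                "volume_cm3": lt.volume_cm3,
                "vb_height_mm": lt.vb_height_mm,
                "height_ratio": lt.height_mm / lt.vb_height_mm,
                "na_ratio": (
                    lt.nucleus_intensity / lt.annulus_intensity
                    if lt.annulus_intensity > 0 else np.nan
                ),
                "pfirrmann": lt.pfirrmann,
                "n_slices": len(lt.slices),
            })
        return pd.DataFrame(rows)


def _ground_truth(spec: PhantomSpec, geometry: DiscGeometry) -> GroundTruth:
    levels: dict[str, LevelTruth] = {}
    spacing = spec.slice_thickness_mm + spec.slice_gap_mm
    for level, disc in spec.discs.items():
        area = geometry.analytic_area_mm2[level]
        n_sl = len(geometry.slices[level])
        vert = DISC_TO_VERTEBRA[level]
        t2s = tuple(float(v) for v in spec.region_t2_ms[level])
        levels[level] = LevelTruth(
            region_t2_ms=t2s,
            height_mm=disc.height_mm,
            width_mm=disc.width_mm,
            slice_areas_mm2=[area] * n_sl,
            volume_cm3=area * n_sl * spacing / 1000.0,
            vb_height_mm=float(
                spec.vertebra_heights_mm.get(vert, np.nan)
            ),
            nucleus_intensity=spec.nucleus_intensity_at(level),
            annulus_intensity=spec.annulus_intensity_at(level),
            pfirrmann=int(assign_pfirrmann(t2s[2])),
            slices=list(geometry.slices[level]),
        )
    return GroundTruth(levels=levels, disc_traces=_disc_traces(spec, geometry))


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------

def _apply_noise(data: np.ndarray, spec: PhantomSpec, stream: int) -> np.ndarray:
    if spec.noise_model == "none" or spec.noise_sigma == 0.0:
        return data
    rng = np.random.default_rng([abs(int(spec.seed)) % (2**31), stream])
    if spec.noise_model == "gaussian":
        return data + rng.normal(0.0, spec.noise_sigma, size=data.shape)
    # Rician: magnitude of the complex signal with i.i.d. Gaussian channels
    re = data + rng.normal(0.0, spec.noise_sigma, size=data.shape)
    im = rng.normal(0.0, spec.noise_sigma, size=data.shape)
    return np.sqrt(re**2 + im**2)


def _label_volume(spec: PhantomSpec, geometry: DiscGeometry) -> np.ndarray:
    """Integer label per voxel: 0 background, level_index*5 + region."""
    labels = np.zeros((spec.n_slices, *spec.grid_shape), dtype=np.int16)
    for li, level in enumerate(spec.discs):
        part = geometry.partitions[level]
        sel = part > 0
        for s in geometry.slices[level]:
            labels[s][sel] = li * 5 + part[sel]
    return labels


def simulate_multiecho(
    spec: PhantomSpec,
    geometry: DiscGeometry | None = None,
) -> tuple[EchoStack, GroundTruth]:
    """Simulate the multi-echo stack with per-region exponential decay.

    Before noise, a voxel in region ``r`` holds exactly
    ``S0_disc * exp(-TE_i / T2_r)`` at echo ``i``; background tissue uses
    its own S0/T2.  A fixed seed gives byte-identical output.
    """
    spec.validate()
    if len(spec.echo_times_ms) < 3:
        raise ConfigurationError("need at least 3 echo times")
    if geometry is None:
        geometry = make_disc_geometry(spec)
    labels = _label_volume(spec, geometry)
    te = np.asarray(spec.echo_times_ms, dtype=float)
    n_labels = 1 + 5 * len(spec.discs)
    t2_lut = np.full(n_labels, spec.t2_background_ms)
    s0_lut = np.full(n_labels, spec.s0_background)
    for li, level in enumerate(spec.discs):
        for r in range(5):
            t2_lut[li * 5 + r + 1] = spec.region_t2_ms[level][r]
            s0_lut[li * 5 + r + 1] = spec.s0_disc
    decay = s0_lut[:, None] * np.exp(-te[None, :] / t2_lut[:, None])
    data = decay[labels]  # (slice, row, col, echo)
    data = _apply_noise(data, spec, stream=1)
    stack = EchoStack(
        data=data,
        echo_times_ms=te,
        spacing_mm=spec.spacing_mm,
        slice_thickness_mm=spec.slice_thickness_mm,
        slice_gap_mm=spec.slice_gap_mm,
        meta={"sequence": "multiecho", "seed": spec.seed},
    )
    return stack, _ground_truth(spec, geometry)


def simulate_t2w(
    spec: PhantomSpec,
    geometry: DiscGeometry | None = None,
    echo_time_ms: float = 70.0,
) -> EchoStack:
    """Simulate the single-echo T2-weighted stack.

    Nucleus regions (2, 3, 4) take the nucleus intensity, annulus regions
    (1, 5) the annulus intensity, per level.
    """
    spec.validate()
    if geometry is None:
        geometry = make_disc_geometry(spec)
    labels = _label_volume(spec, geometry)
    n_labels = 1 + 5 * len(spec.discs)
    lut = np.full(n_labels, spec.t2w_background)
    for li, level in enumerate(spec.discs):
        i_n = spec.nucleus_intensity_at(level)
        i_a = spec.annulus_intensity_at(level)
        for r in range(5):
            lut[li * 5 + r + 1] = i_n if (r + 1) in (2, 3, 4) else i_a
    data = lut[labels][..., None]
    data = _apply_noise(data, spec, stream=2)
    return EchoStack(
        data=data,
        echo_times_ms=np.asarray([echo_time_ms]),
        spacing_mm=spec.spacing_mm,
        slice_thickness_mm=spec.slice_thickness_mm,
        slice_gap_mm=spec.slice_gap_mm,
        meta={"sequence": "t2w", "seed": spec.seed},
    )


def simulate_vertebral(
    spec: PhantomSpec,
    geometry: DiscGeometry | None = None,
) -> tuple[EchoStack, list[BoundaryTrace], dict[str, float]]:
    """Simulate the vertebral-body stack (mDIXON analog) with traces.

    Vertebral bodies are near-rectangular superellipses of the specified
    heights; returns the stack, truth boundary traces, and the true
    height per vertebra.
    """
    spec.validate()
    if geometry is None:
        geometry = make_disc_geometry(spec)
    data = np.full(
        (spec.n_slices, *spec.grid_shape), spec.t2w_background, dtype=float
    )
    traces: list[BoundaryTrace] = []
    heights: dict[str, float] = {}
    slice_extents = [s for sl in geometry.slices.values() for s in sl]
    lo = min(slice_extents) if slice_extents else 0
    hi = max(slice_extents) if slice_extents else spec.n_slices - 1
    for vert in VERTEBRAE:
        if vert not in spec.vertebra_centers_px:
            continue
        h = spec.vertebra_heights_mm[vert]
        poly = _superellipse_polygon(
            spec.vertebra_centers_px[vert], spec.vertebra_width_mm, h,
            VERTEBRA_EXPONENT, spec.spacing_mm,
        )
        minx, miny, maxx, maxy = poly.bounds
        n_rows, n_cols = spec.grid_shape
        if minx < -0.5 or miny < -0.5 or maxx > n_cols - 0.5 \
                or maxy > n_rows - 0.5:
            raise ConfigurationError(
                f"{vert}: vertebral geometry exceeds the grid"
            )
        mask = rasterize(poly, spec.grid_shape, spec.spacing_mm)
        pts = np.asarray(poly.exterior.coords[:-1])[:, ::-1]
        for s in range(lo, hi + 1):
            data[s][mask.mask] = spec.vertebral_intensity
            traces.append(BoundaryTrace(
                structure="vertebra", level=vert, slice_index=s,
                points=pts.copy(), provenance="phantom-truth",
            ))
        heights[vert] = float(h)
    data = _apply_noise(data[..., None], spec, stream=3)
    stack = EchoStack(
        data=data,
        echo_times_ms=np.asarray([MDIXON_SEQUENCE.echo_times_ms[1]]),
        spacing_mm=spec.spacing_mm,
        slice_thickness_mm=spec.slice_thickness_mm,
        slice_gap_mm=spec.slice_gap_mm,
        meta={"sequence": "vertebral", "seed": spec.seed},
    )
    return stack, traces, heights


# ---------------------------------------------------------------------------
# Degeneration grading surrogate
# ---------------------------------------------------------------------------

#: Nucleus-T2 thresholds (ms) separating grades 5|4|3|2|1.
PFIRRMANN_T2_THRESHOLDS_MS = (60.0, 80.0, 95.0, 110.0)


def assign_pfirrmann(nucleus_t2_ms, thresholds=PFIRRMANN_T2_THRESHOLDS_MS):
    """Map nucleus T2 (ms) to an ordinal degeneration grade 1–5.

    Visual grading is out of scope; this surrogate sends a hydrated
    (high-T2) nucleus to grade 1 and a desiccated one to grade 5 through
    ordered thresholds, so lower nucleus T2 never yields a lower grade.
    """
    th = np.asarray(thresholds, dtype=float)
    if th.size != 4 or np.any(np.diff(th) <= 0):
        raise ConfigurationError("need 4 strictly increasing T2 thresholds")
    t2 = np.asarray(nucleus_t2_ms, dtype=float)
    grade = 5 - np.digitize(t2, th, right=False)
    if grade.ndim == 0:
        return int(grade)
    return grade.astype(int)


# ---------------------------------------------------------------------------
# Synthetic cohorts with planted effects
# ---------------------------------------------------------------------------

@dataclass
class SexParams:
    """Per-sex distribution parameters (location, scale) of exposures and
    covariates; all loading/occupational scores are truncated at zero."""

    n: int = 20
    bpaq: tuple[float, float] = (16.97, 17.66)
    age: tuple[float, float] = (35.15, 5.85)
    bmi: tuple[float, float] = (28.67, 4.33)
    occ_sit_current: tuple[float, float] = (30.0, 30.65)
    occ_labour_current: tuple[float, float] = (31.19, 63.36)
    occ_sit_past: tuple[float, float] = (105.81, 136.0)
    occ_labour_past: tuple[float, float] = (71.49, 87.0)


_FEMALE_DEFAULTS = SexParams(
    n=20,
    bpaq=(12.00, 13.39),
    age=(30.55, 5.43),
    bmi=(29.90, 8.95),
    occ_sit_current=(23.64, 30.65),
    occ_labour_current=(17.14, 24.31),
    occ_sit_past=(47.76, 83.53),
    occ_labour_past=(5.53, 12.66),
)

COVARIATES = (
    "age", "bmi",
    "occ_sit_current", "occ_labour_current",
    "occ_sit_past", "occ_labour_past",
)


@dataclass
class CohortSpec:
    """Specification of a synthetic cohort with planted effects.

    ``beta`` maps ``(outcome, level)`` to the planted coefficient of the
    exposure (BPAQ total score) on that outcome; ``level`` may be
    ``"all"``.  Outcomes: ``t2`` (applied to every AP region unless a
    region-specific ``t2_r<k>`` key overrides it), ``height_ratio``,
    ``volume_cm3``, ``na_ratio``; clinical outcomes (``vas_avg``,
    ``vas_current``, ``vas_worst``, ``odi``) use level ``"clinical"``.
    """

    male: SexParams = field(default_factory=SexParams)
    female: SexParams = field(default_factory=lambda: replace(_FEMALE_DEFAULTS))
    beta: dict[tuple[str, str], float] = field(default_factory=lambda: {
        ("t2", "L5/S1"): -0.30,
        ("na_ratio", "L5/S1"): -0.02,
    })
    covariate_effects: dict[tuple[str, str], float] = field(
        default_factory=lambda: {("t2", "age"): -0.3}
    )
    residual_sd: dict[str, float] = field(default_factory=lambda: {
        "t2_level": 10.0,   # shared disc-level T2 noise (ms)
        "t2_region": 6.0,   # additional independent per-region noise (ms)
        "height_ratio": 0.033,
        "volume_cm3": 1.2,
        "na_ratio": 0.45,
        "vb_height_mm": 1.5,
        "vas": 20.0,
        "odi": 9.0,
    })
    baseline_vas: float = 40.0
    baseline_odi: float = 22.0
    seed: int = 0

    def validate(self) -> None:
        if self.male.n <= 0 or self.female.n <= 0:
            raise ConfigurationError("cohort n must be > 0 per sex")
        if any(v < 0 for v in self.residual_sd.values()):
            raise ConfigurationError("residual SDs must be >= 0")


def _truncated_normal(rng, loc, scale, size, lower=0.0):
    if scale == 0.0:
        return np.full(size, loc)
    a = (lower - loc) / scale
    return truncnorm.rvs(
        a, np.inf, loc=loc, scale=scale, size=size, random_state=rng
    )


def _beta_for(cspec: CohortSpec, outcome: str, level: str) -> float:
    return cspec.beta.get(
        (outcome, level), cspec.beta.get((outcome, "all"), 0.0)
    )


def _default_baselines() -> dict[str, dict[str, float]]:
    """Per-level outcome baselines derived from the default phantom."""
    base: dict[str, dict[str, float]] = {}
    spacing = 4.5
    n_slices = 8
    for level in LEVELS:
        h, w = _DEFAULT_DISC_DIMS[level]
        area = superellipse_area_mm2(w, h, DISC_EXPONENT)
        base[level] = {
            **{f"t2_r{i+1}": _DEFAULT_REGION_T2[level][i] for i in range(5)},
            "height_ratio": h / DEFAULT_VB_HEIGHT_MM,
            "volume_cm3": area * n_slices * spacing / 1000.0,
            "na_ratio": 2.0,
            "vb_height_mm": DEFAULT_VB_HEIGHT_MM,
        }
    return base


def generate_cohort(
    cspec: CohortSpec,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a synthetic cohort and its per-level outcome truths.

    Returns ``(cohort, level_truth)``: ``cohort`` holds one row per
    participant (sex, BPAQ scores, covariates, pain and disability);
    ``level_truth`` holds one row per participant x disc level with the
    planted disc outcomes (region and whole-disc T2, height ratio,
    volume, nucleus-to-annulus ratio, degeneration grade).
    """
    cspec.validate()
    rng = np.random.default_rng([abs(int(cspec.seed)) % (2**31), 101])
    baselines = _default_baselines()
    rows = []
    pid = 0
    for sex, params in (("male", cspec.male), ("female", cspec.female)):
        n = params.n
        bpaq = _truncated_normal(rng, *params.bpaq, n)
        past_share = rng.uniform(0.5, 0.9, size=n)
        age = np.clip(rng.normal(*params.age, size=n), 18.0, None)
        bmi = np.clip(rng.normal(*params.bmi, size=n), 15.0, None)
        occ = {
            "occ_sit_current": _truncated_normal(
                rng, *params.occ_sit_current, n),
            "occ_labour_current": _truncated_normal(
                rng, *params.occ_labour_current, n),
            "occ_sit_past": _truncated_normal(rng, *params.occ_sit_past, n),
            "occ_labour_past": _truncated_normal(
                rng, *params.occ_labour_past, n),
        }
        for i in range(n):
            rows.append({
                "participant": f"P{pid:03d}",
                "sex": sex,
                "bpaq_total": float(bpaq[i]),
                "bpaq_past": float(bpaq[i] * past_share[i]),
                "bpaq_current": float(bpaq[i] * (1 - past_share[i])),
                "age": float(age[i]),
                "bmi": float(bmi[i]),
                **{k: float(v[i]) for k, v in occ.items()},
            })
            pid += 1
    cohort = pd.DataFrame(rows)

    # covariate contributions are centred at the pooled male/female location
    cov_center = {
        "age": (cspec.male.age[0] + cspec.female.age[0]) / 2,
        "bmi": (cspec.male.bmi[0] + cspec.female.bmi[0]) / 2,
        "occ_sit_current": (cspec.male.occ_sit_current[0]
                            + cspec.female.occ_sit_current[0]) / 2,
        "occ_labour_current": (cspec.male.occ_labour_current[0]
                               + cspec.female.occ_labour_current[0]) / 2,
        "occ_sit_past": (cspec.male.occ_sit_past[0]
                         + cspec.female.occ_sit_past[0]) / 2,
        "occ_labour_past": (cspec.male.occ_labour_past[0]
                            + cspec.female.occ_labour_past[0]) / 2,
    }

    def cov_term(outcome: str) -> np.ndarray:
        term = np.zeros(len(cohort))
        for (out, cov), g in cspec.covariate_effects.items():
            if out == outcome:
                term = term + g * (cohort[cov].to_numpy() - cov_center[cov])
        return term

    sd = cspec.residual_sd
    x = cohort["bpaq_total"].to_numpy()
    n_all = len(cohort)
    truth_rows = []
    for level in LEVELS:
        base = baselines[level]
        eps_level = rng.normal(0.0, sd.get("t2_level", 0.0), size=n_all)
        t2_regions = {}
        for r in range(1, 6):
            beta_r = cspec.beta.get(
                (f"t2_r{r}", level),
                _beta_for(cspec, "t2", level),
            )
            eps_r = rng.normal(0.0, sd.get("t2_region", 0.0), size=n_all)
            t2_regions[r] = np.clip(
                base[f"t2_r{r}"] + beta_r * x + cov_term("t2")
                + eps_level + eps_r,
                5.0, None,
            )
        vb = np.clip(
            base["vb_height_mm"]
            + rng.normal(0.0, sd.get("vb_height_mm", 0.0), size=n_all),
            15.0, None,
        )
        ratio = np.clip(
            base["height_ratio"] + _beta_for(cspec, "height_ratio", level) * x
            + cov_term("height_ratio")
            + rng.normal(0.0, sd.get("height_ratio", 0.0), size=n_all),
            0.1, None,
        )
        vol = np.clip(
            base["volume_cm3"] + _beta_for(cspec, "volume_cm3", level) * x
            + cov_term("volume_cm3")
            + rng.normal(0.0, sd.get("volume_cm3", 0.0), size=n_all),
            1.0, None,
        )
        na = np.clip(
            base["na_ratio"] + _beta_for(cspec, "na_ratio", level) * x
            + cov_term("na_ratio")
            + rng.normal(0.0, sd.get("na_ratio", 0.0), size=n_all),
            0.2, None,
        )
        t2_whole = np.mean([t2_regions[r] for r in range(1, 6)], axis=0)
        grades = assign_pfirrmann(t2_regions[3])
        for i in range(n_all):
            truth_rows.append({
                "participant": cohort["participant"].iloc[i],
                "level": level,
                "t2_ms": float(t2_whole[i]),
                **{f"t2_r{r}": float(t2_regions[r][i]) for r in range(1, 6)},
                "height_ratio": float(ratio[i]),
                "vb_height_mm": float(vb[i]),
                "height_mm": float(ratio[i] * vb[i]),
                "volume_cm3": float(vol[i]),
                "na_ratio": float(na[i]),
                "pfirrmann": int(grades[i]),
            })
    level_truth = pd.DataFrame(truth_rows)

    for name, key in (
        ("vas_avg", "vas"), ("vas_current", "vas"), ("vas_worst", "vas"),
    ):
        b = _beta_for(cspec, name, "clinical")
        cohort[name] = np.clip(
            cspec.baseline_vas + b * x
            + rng.normal(0.0, sd.get(key, 0.0), size=n_all),
            0.0, 100.0,
        )
    cohort["odi"] = np.clip(
        cspec.baseline_odi + _beta_for(cspec, "odi", "clinical") * x
        + rng.normal(0.0, sd.get("odi", 0.0), size=n_all),
        0.0, 100.0,
    )
    return cohort, level_truth


def spec_from_truth(
    base_spec: PhantomSpec,
    participant_truth: pd.DataFrame,
    seed: int,
) -> PhantomSpec:
    """Build a per-participant phantom whose geometry and T2s realise that
    participant's planted outcome truths.

    Region T2s are taken directly; disc height comes from the planted
    height ratio times the vertebral-body height; disc width is chosen so
    the superellipse slice area integrates to the planted volume; the
    T2-weighted nucleus intensity realises the planted nucleus-to-annulus
    ratio against a fixed annulus intensity.

    Planted heights refer to the *measured* (chord-mean) convention, so
    nominal superellipse heights are inflated by the analytic chord
    factor to make the quantified values center on the planted truths.
    """
    spec = replace(
        base_spec,
        discs=dict(base_spec.discs),
        region_t2_ms=dict(base_spec.region_t2_ms),
        vertebra_heights_mm=dict(base_spec.vertebra_heights_mm),
        vertebra_centers_px=dict(base_spec.vertebra_centers_px),
        nucleus_intensity={},
        annulus_intensity={},
        seed=seed,
    )
    shape_factor = superellipse_area_mm2(1.0, 1.0, DISC_EXPONENT)
    disc_chord = superellipse_chord_mean_factor(DISC_EXPONENT)
    vb_chord = superellipse_chord_mean_factor(VERTEBRA_EXPONENT)
    spacing = spec.slice_thickness_mm + spec.slice_gap_mm
    for _, row in participant_truth.iterrows():
        level = row["level"]
        disc = base_spec.discs[level]
        height = float(row["height_mm"]) / disc_chord
        n_sl = disc.slice_last - disc.slice_first + 1
        area = float(row["volume_cm3"]) * 1000.0 / (n_sl * spacing)
        width = area / (shape_factor * height)
        spec.discs[level] = replace(disc, width_mm=width, height_mm=height)
        spec.region_t2_ms[level] = tuple(
            float(row[f"t2_r{r}"]) for r in range(1, 6)
        )
        vert = DISC_TO_VERTEBRA[level]
        spec.vertebra_heights_mm[vert] = float(row["vb_height_mm"]) / vb_chord
        spec.annulus_intensity[level] = 100.0
        spec.nucleus_intensity[level] = 100.0 * float(row["na_ratio"])
    spec.validate()
    return spec
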