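"""Digital phantoms: porous sponge mimetic and 2D axial thorax slice.

The sponge phantom mirrors the physical water-doped sponge used to validate
the lung-water sequence: a porous binary texture whose mean water content is
set by a fill fraction. The thorax phantom is an analytic-ellipse axial
slice (chest wall, two lungs, heart, optional posterior-basal pleural
effusion) whose lung tissue parameters follow the lung tissue model, so
lung water content can be dialled without changing geometry. Because every
region is an ellipse, the slice has an exact closed-form Fourier transform,
which the acquisition module uses as an inverse-crime-free forward model.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter

from .signal import TissueParams, lung_tissue_model

__all__ = [
    "SpongePhantom",
    "Ellipse",
    "ThoraxSlice",
    "MotionModel",
    "make_sponge",
    "make_thorax",
    "displace",
    "LABELS",
]

# Region labels of the thorax slice.
LABELS = {
    "background": 0,
    "chest_wall": 1,
    "left_lung": 2,
    "right_lung": 3,
    "heart": 4,
    "effusion": 5,
}


@dataclass
class SpongePhantom:
    """Binary porous water-fraction map (1 inside pores, 0 in the matrix)."""

    grid: np.ndarray
    pore_scale_px: float
    fill_fraction: float
    seed: int
    pixel_size_mm: float = 1.0

    @property
    def size_px(self) -> int:
        return self.grid.shape[0]

    @property
    def fov_mm(self) -> float:
        return self.size_px * self.pixel_size_mm


@dataclass(frozen=True)
class Ellipse:
    """Axis-aligned ellipse: center (mm), semi-axes (mm), region label."""

    cx_mm: float
    cy_mm: float
    a_mm: float
    b_mm: float
    label: int

    def contains(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        return ((x - self.cx_mm) / self.a_mm) ** 2 + (
            (y - self.cy_mm) / self.b_mm
        ) ** 2 <= 1.0


@dataclass
class ThoraxSlice:
    """Axial thorax slice at the level of the pulmonary arteries.

    label_map is the rasterised region map; ellipses (painted in order, each
    over the previous) carry the exact geometry for analytic k-space
    evaluation. shift_mm records any rigid in-plane displacement applied.
    """

    label_map: np.ndarray
    tissue_table: dict[int, TissueParams]
    lung_water_fraction: float
    pixel_size_mm: float
    ellipses: tuple[Ellipse, ...]
    seed: int = 0
    shift_mm: tuple[float, float] = (0.0, 0.0)

    @property
    def size_px(self) -> int:
        return self.label_map.shape[0]

    @property
    def fov_mm(self) -> float:
        return self.size_px * self.pixel_size_mm

    def coords_mm(self) -> tuple[np.ndarray, np.ndarray]:
        """Pixel-center coordinates (x, y) in mm, image row = y."""
        n = self.size_px
        ax = (np.arange(n) - n // 2) * self.pixel_size_mm
        x, y = np.meshgrid(ax, ax, indexing="xy")
        return x, y


@dataclass(frozen=True)
class MotionModel:
    """Rigid-body exercise motion for an axial slice.

    The breathing term is a smooth sinusoidal superior-inferior excursion
    whose in-plane projection translates the slice along y. Jitter bursts
    occur independently per sampling event with jitter_burst_probability and
    add a random offset of magnitude up to jitter_amplitude_mm. Because
    superior-inferior motion is largely through-plane for an axial slice, a
    displacement of s mm also modulates the slice's total signal by
    (1 + through_plane_per_mm * s) and — motion through the slice-select
    gradient — imparts a spoke-wide phase of phase_per_mm_rad * s radians;
    these are what make motion-corrupted spokes detectable at the k-space
    center.
    """

    breathing_amplitude_mm: float = 0.0
    breathing_period_s: float = 4.0
    jitter_amplitude_mm: float = 0.0
    jitter_burst_probability: float = 0.0
    seed: int = 0
    through_plane_per_mm: float = 0.02
    phase_per_mm_rad: float = 0.3

    def __post_init__(self) -> None:
        if self.breathing_amplitude_mm < 0 or self.jitter_amplitude_mm < 0:
            raise ValueError("motion amplitudes must be >= 0")
        if not 0.0 <= self.jitter_burst_probability <= 1.0:
            raise ValueError("jitter_burst_probability must be in [0, 1]")
        if self.breathing_period_s <= 0:
            raise ValueError("breathing_period_s must be positive")

    def displacement_at(
        self, t: float, event_index: int | None = None
    ) -> tuple[float, float, complex]:
        """(dx, dy, modulation) at time t seconds.

        dx/dy are the in-plane translation in mm; modulation is the complex
        through-plane factor scale * exp(i * phase). Jitter randomness is
        keyed on (seed, event_index) when an event index is given, else on
        the microsecond-quantised time, so repeated queries are
        reproducible.
        """
        si = self.breathing_amplitude_mm * np.sin(2.0 * np.pi * t / self.breathing_period_s)
        dx, dy = 0.0, float(si)
        si_burst = 0.0
        if self.jitter_amplitude_mm > 0 and self.jitter_burst_probability > 0:
            key = event_index if event_index is not None else int(round(t * 1e6))
            rng = np.random.default_rng([self.seed, key & 0x7FFFFFFF])
            if rng.random() < self.jitter_burst_probability:
                mag = rng.uniform(0.0, self.jitter_amplitude_mm)
                ang = rng.uniform(0.0, 2.0 * np.pi)
                dx += mag * np.cos(ang)
                dy += mag * np.sin(ang)
                si_burst = mag * np.sin(ang)
        scale = max(1.0 + self.through_plane_per_mm * (si + si_burst), 0.0)
        phase = self.phase_per_mm_rad * (si + si_burst)
        return float(dx), float(dy), complex(scale * np.exp(1j * phase))


def make_sponge(
    size_px: int = 128,
    pore_scale_px: float = 4.0,
    fill_fraction: float = 0.3,
    seed: int = 0,
    pixel_size_mm: float = 1.0,
) -> SpongePhantom:
    """Generate a porous sponge phantom.

    A white-noise field is smoothed to a correlation length of
    pore_scale_px and thresholded at the (1 - fill_fraction) quantile, so
    the pore (water = 1) area fraction equals fill_fraction up to pixel
    rounding.
    """
    if size_px < 64:
        raise ValueError("size_px must be >= 64")
    if not 0.0 <= fill_fraction <= 1.0:
        raise ValueError(f"fill_fraction must be in [0, 1], got {fill_fraction}")
    rng = np.random.default_rng(seed)
    field_ = gaussian_filter(rng.standard_normal((size_px, size_px)), pore_scale_px)
    if fill_fraction == 0.0:
        grid = np.zeros((size_px, size_px))
    elif fill_fraction == 1.0:
        grid = np.ones((size_px, size_px))
    else:
        thr = np.quantile(field_, 1.0 - fill_fraction)
        grid = (field_ > thr).astype(float)
    return SpongePhantom(
        grid=grid,
        pore_scale_px=pore_scale_px,
        fill_fraction=fill_fraction,
        seed=seed,
        pixel_size_mm=pixel_size_mm,
    )


def _thorax_ellipses(effusion_present: bool, rng: np.random.Generator) -> tuple[Ellipse, ...]:
    # small seed-dependent anatomical variation; containment margins are
    # generous enough for the +/-2 mm, +/-3 % jitter below
    jc = lambda: float(rng.uniform(-2.0, 2.0))
    js = lambda: float(rng.uniform(0.97, 1.03))
    body = Ellipse(jc(), jc(), 170.0 * js(), 110.0 * js(), LABELS["chest_wall"])
    left = Ellipse(-82.0 + jc(), jc(), 50.0 * js(), 80.0 * js(), LABELS["left_lung"])
    right = Ellipse(82.0 + jc(), jc(), 50.0 * js(), 80.0 * js(), LABELS["right_lung"])
    heart = Ellipse(jc() * 0.5, 30.0 + jc(), 28.0 * js(), 34.0 * js(), LABELS["heart"])
    ells = [body, left, right, heart]
    if effusion_present:
        # dependent posterior-basal collection inside the right lung
        ells.append(
            Ellipse(right.cx_mm + 2.0, right.cy_mm - 56.0, 24.0, 13.0, LABELS["effusion"])
        )
    return tuple(ells)


def make_thorax(
    lung_water_fraction: float = 0.2,
    effusion_present: bool = False,
    pixel_size_mm: float = 3.0,
    size_px: int = 128,
    seed: int = 0,
) -> ThoraxSlice:
    """Build the axial thorax slice phantom.

    Geometry depends only on the seed (and the effusion flag); the lung
    water fraction sets lung tissue parameters via lung_tissue_model without
    touching the geometry, so rest/stress pairs share identical label maps.
    """
    if not 0.05 <= lung_water_fraction <= 0.6:
        raise ValueError(
            f"lung_water_fraction must be in [0.05, 0.6], got {lung_water_fraction}"
        )
    rng = np.random.default_rng(seed)
    ellipses = _thorax_ellipses(effusion_present, rng)

    n = size_px
    ax = (np.arange(n) - n // 2) * pixel_size_mm
    x, y = np.meshgrid(ax, ax, indexing="xy")
    label_map = np.zeros((n, n), dtype=np.int8)
    for e in ellipses:  # paint in order
        label_map[e.contains(x, y)] = e.label

    lung = lung_tissue_model(lung_water_fraction)
    tissue_table = {
        LABELS["background"]: TissueParams(0.0, 1000.0, 1.0),
        LABELS["chest_wall"]: TissueParams(0.75, 900.0, 30.0),
        LABELS["left_lung"]: lung,
        LABELS["right_lung"]: lung,
        LABELS["heart"]: TissueParams(0.85, 1400.0, 35.0),
        LABELS["effusion"]: TissueParams(0.97, 2800.0, 60.0),
    }
    return ThoraxSlice(
        label_map=label_map,
        tissue_table=tissue_table,
        lung_water_fraction=lung_water_fraction,
        pixel_size_mm=pixel_size_mm,
        ellipses=ellipses,
        seed=seed,
    )


def displace(slice_: ThoraxSlice, motion: MotionModel, t: float) -> ThoraxSlice:
    """Rigidly translate the slice to its position at time t.

    The analytic ellipses carry the exact continuous shift; the rasterised
    label map is rolled by the nearest whole number of pixels with periodic
    wrap, which conserves total proton density exactly. A zero-amplitude
    model returns the input unchanged.
    """
    if t < 0:
        raise ValueError("t must be >= 0")
    dx, dy, _scale = motion.displacement_at(t)
    if dx == 0.0 and dy == 0.0:
        return slice_
    ells = tuple(
        replace(e, cx_mm=e.cx_mm + dx, cy_mm=e.cy_mm + dy) for e in slice_.ellipses
    )
    px = slice_.pixel_size_mm
    rolled = np.roll(
        slice_.label_map, (int(round(dy / px)), int(round(dx / px))), axis=(0, 1)
    )
    return replace(
        slice_,
        label_map=rolled,
        ellipses=ells,
        shift_mm=(slice_.shift_mm[0] + dx, slice_.shift_mm[1] + dy),
    )
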