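"""Synthetic gastric peristalsis and emptying phantoms with known ground truth.

Real-time sagittal MRI of the antrum yields, per slice, a time series of
bright-lumen cross-sectional areas modulated by three processes: a
traveling contraction wave in the 1.8-4.2 cpm band, respiratory motion in
the 0.15-0.30 Hz band, and measurement noise.  The generators here emulate
exactly that structure with every kinematic parameter known:

    area_i(t) = A0 * (1 - d * w(t - tau_i)) * (1 + b * sin(2*pi*f_b*t)) + eps

where ``w`` is a raised-cosine contraction pulse train with unit peak
(so the occlusion depth ``d`` is exactly the peak relative area
reduction), ``tau_i`` the per-slice wave arrival delay (slice-center
separation divided by wave speed), ``b`` the breathing amplitude and
``eps`` white Gaussian area noise.  Image phantoms render the same areas
as a bright quasi-elliptical lumen on a dark background; static 3-D
phantoms provide spheres of known volume for volumetry; emptying series
follow first- or zero-order kinetics.

All generators draw from a single explicitly seeded random stream and are
bit-reproducible for identical specifications.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .exceptions import InvalidSpecError
from .motility import AreaTimeSeries, SliceGeometry
from .volumetry import VolumeSeries

__all__ = [
    "PhantomSpec",
    "EmptyingSpec",
    "DynamicPhantom",
    "contraction_waveform",
    "generate_area_signals",
    "generate_dynamic_phantom",
    "generate_static_volume_phantom",
    "generate_emptying_series",
    "compute_mn_dose",
    "MOLAR_MASS_MN",
]

# conventional atomic masses (g/mol)
MOLAR_MASS_MN = 54.938
_MASS_C = 12.011
_MASS_H = 1.008
_MASS_O = 15.999
#: gluconate anion C6H11O7
_MASS_GLUCONATE = 6 * _MASS_C + 11 * _MASS_H + 7 * _MASS_O
_MASS_WATER = 2 * _MASS_H + _MASS_O

#: rendered lumen intensity in image phantoms (arbitrary units)
BRIGHT_INTENSITY = 1000.0
#: antral lumen elongation (major/minor semi-axis) in rendered frames
LUMEN_ASPECT_RATIO = 1.6


@dataclass(frozen=True)
class PhantomSpec:
    """Ground-truth kinematics of a synthetic peristalsis recording.

    Defaults emulate a healthy postprandial antrum recorded with the
    three-slice sagittal real-time protocol: 3 cpm contractions at
    occlusion depth 0.5, a 20 mm relaxed lumen, quiet breathing at
    0.25 Hz, 180 s at 6.24 frames/s.
    """

    true_frequency: float = 3.0        # contraction rate, cpm
    wave_speed: float = 1.7            # aboral propagation speed, mm/s
    occlusion_depth: float = 0.5       # peak relative area reduction, [0, 1]
    baseline_diameter: float = 20.0    # relaxed lumen diameter, mm
    breathing_frequency: float = 0.25  # Hz
    breathing_amplitude: float = 0.05  # fraction of baseline area
    noise_sd: float = 0.02             # fraction of baseline area
    duration: float = 180.0            # s
    seed: int = 0
    geometry: SliceGeometry = field(default_factory=SliceGeometry)
    pulse_sharpness: int = 3           # exponent of the raised-cosine pulse

    def __post_init__(self) -> None:
        if self.true_frequency <= 0:
            raise InvalidSpecError("true_frequency must be > 0")
        if self.wave_speed <= 0:
            raise InvalidSpecError("wave_speed must be > 0")
        if not (0.0 <= self.occlusion_depth <= 1.0):
            raise InvalidSpecError("occlusion_depth must be in [0, 1]")
        if self.baseline_diameter <= 0:
            raise InvalidSpecError("baseline_diameter must be > 0")
        if self.breathing_frequency < 0 or self.breathing_amplitude < 0:
            raise InvalidSpecError("breathing parameters must be >= 0")
        if self.noise_sd < 0:
            raise InvalidSpecError("noise_sd must be >= 0")
        if self.duration <= 0:
            raise InvalidSpecError("duration must be > 0")
        if self.pulse_sharpness < 1:
            raise InvalidSpecError("pulse_sharpness must be >= 1")

    @property
    def baseline_area(self) -> float:
        """Relaxed lumen cross-sectional area in mm^2."""
        return np.pi * (self.baseline_diameter / 2.0) ** 2


@dataclass(frozen=True)
class EmptyingSpec:
    """Ground truth of a synthetic gastric-content-volume decay.

    ``rate_constant`` is per-min for first-order and mL/min for
    zero-order kinetics; ``sample_times`` are in min and must be strictly
    increasing; generated volumes are clipped at zero.
    """

    model_order: str = "first"
    rate_constant: float = 0.0469
    initial_volume: float = 290.0
    sample_times: tuple = tuple(range(0, 65, 8))
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model_order not in ("first", "zero"):
            raise InvalidSpecError(f"unknown model order {self.model_order!r}")
        if self.rate_constant < 0:
            raise InvalidSpecError("rate_constant must be >= 0")
        if self.initial_volume < 0:
            raise InvalidSpecError("initial_volume must be >= 0")
        times = np.asarray(self.sample_times, dtype=float)
        if times.size < 1 or (times.size > 1 and not np.all(np.diff(times) > 0)):
            raise InvalidSpecError("sample_times must be non-empty, strictly increasing")
        if self.noise_sd < 0:
            raise InvalidSpecError("noise_sd must be >= 0")


@dataclass
class DynamicPhantom:
    """Rendered 2D+t phantom: per-slice images, ground-truth masks, areas."""

    images: list          # list of (ny, nx, nt) float32 arrays
    masks: list           # list of (ny, nx, nt) uint8 arrays
    area_signals: list    # list of AreaTimeSeries (analytic ground truth)
    spec: PhantomSpec


def contraction_waveform(t: np.ndarray, frequency_cpm: float, sharpness: int = 3) -> np.ndarray:
    """Raised-cosine contraction pulse train, nonnegative with unit peak.

    ``w(t) = ((1 + cos(2 pi f t)) / 2) ** sharpness`` with ``f`` in Hz.
    Higher sharpness narrows the contraction pulse within each cycle,
    emulating a localized lumen indentation rather than a sinusoidal
    squeeze; the fundamental at ``f`` stays the strongest spectral line.
    """
    f_hz = frequency_cpm / 60.0
    return ((1.0 + np.cos(2.0 * np.pi * f_hz * np.asarray(t))) / 2.0) ** sharpness


def _slice_delays(spec: PhantomSpec) -> np.ndarray:
    sep = spec.geometry.slice_center_separation
    return np.arange(spec.geometry.n_slices) * sep / spec.wave_speed


def generate_area_signals(spec: PhantomSpec) -> list[AreaTimeSeries]:
    """Generate one antral area-time series per slice.

    Slice ``i + 1`` lags slice ``i`` by the slice-center separation
    divided by the wave speed; breathing and noise are common-parameter
    but independently drawn per slice.  Areas are clipped at zero.
    """
    geom = spec.geometry
    n_frames = int(round(geom.frame_rate * spec.duration))
    if n_frames < 2:
        raise InvalidSpecError("duration x frame_rate must give at least 2 frames")
    t = np.arange(n_frames) / geom.frame_rate
    rng = np.random.default_rng(spec.seed)
    a0 = spec.baseline_area

    out = []
    for i, tau in enumerate(_slice_delays(spec)):
        w = contraction_waveform(t - tau, spec.true_frequency, spec.pulse_sharpness)
        areas = a0 * (1.0 - spec.occlusion_depth * w)
        if spec.breathing_amplitude > 0:
            areas = areas * (
                1.0 + spec.breathing_amplitude
                * np.sin(2.0 * np.pi * spec.breathing_frequency * t)
            )
        if spec.noise_sd > 0:
            areas = areas + rng.normal(0.0, spec.noise_sd * a0, size=n_frames)
        out.append(
            AreaTimeSeries(
                areas=np.clip(areas, 0.0, None),
                frame_rate=geom.frame_rate,
                slice_index=i,
            )
        )
    return out


def _render_lumen_frame(
    area_mm2: float,
    grid_shape: tuple[int, int],
    pixel_spacing: float,
    aspect_ratio: float = LUMEN_ASPECT_RATIO,
) -> np.ndarray:
    """Rasterize a centered ellipse of the given area (voxel-center rule)."""
    ny, nx = grid_shape
    if area_mm2 <= 0:
        return np.zeros(grid_shape, dtype=np.uint8)
    semi_minor = np.sqrt(area_mm2 / (np.pi * aspect_ratio))
    semi_major = aspect_ratio * semi_minor
    y = (np.arange(ny) - (ny - 1) / 2.0) * pixel_spacing
    x = (np.arange(nx) - (nx - 1) / 2.0) * pixel_spacing
    yy, xx = np.meshgrid(y, x, indexing="ij")
    inside = (xx / semi_major) ** 2 + (yy / semi_minor) ** 2 <= 1.0
    return inside.astype(np.uint8)


def generate_dynamic_phantom(
    spec: PhantomSpec, grid_shape: tuple[int, int] = (140, 140)
) -> DynamicPhantom:
    """Render per-slice 2D+t image stacks with ground-truth lumen masks.

    Each frame shows a bright elliptical lumen (T1-bright manganese-labeled
    content) on a dark background; the rendered lumen area follows the
    analytic area signal of that slice up to pixel-boundary discretization.
    Per-voxel Gaussian intensity noise is scaled by ``spec.noise_sd`` times
    the lumen intensity, and the analytic area signal is generated without
    area noise (noise enters the images, not the geometry).
    """
    geom = spec.geometry
    signal_spec = replace(spec, noise_sd=0.0)
    signals = generate_area_signals(signal_spec)

    # largest possible lumen must fit the field of view
    max_area = spec.baseline_area * (1.0 + spec.breathing_amplitude)
    semi_major = LUMEN_ASPECT_RATIO * np.sqrt(max_area / (np.pi * LUMEN_ASPECT_RATIO))
    fov_half = min(grid_shape) * geom.pixel_spacing / 2.0
    if semi_major >= fov_half:
        raise InvalidSpecError(
            f"lumen semi-major axis {semi_major:.1f} mm exceeds half field of view "
            f"{fov_half:.1f} mm; enlarge the grid or shrink the lumen"
        )

    rng = np.random.default_rng(spec.seed)
    images, masks = [], []
    for series in signals:
        nt = len(series)
        mask = np.empty((*grid_shape, nt), dtype=np.uint8)
        for k in range(nt):
            mask[..., k] = _render_lumen_frame(
                series.areas[k], grid_shape, geom.pixel_spacing
            )
        image = mask.astype(np.float32) * BRIGHT_INTENSITY
        if spec.noise_sd > 0:
            image = image + rng.normal(
                0.0, spec.noise_sd * BRIGHT_INTENSITY, size=image.shape
            ).astype(np.float32)
        images.append(image)
        masks.append(mask)
    return DynamicPhantom(images=images, masks=masks, area_signals=signals, spec=spec)


def generate_static_volume_phantom(
    volume_ml: float,
    voxel_spacing: Sequence[float] = (1.0, 1.0, 1.0),
    seed: int = 0,
    grid_shape: Optional[tuple[int, int, int]] = None,
    noise_sd: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Render a 3-D spherical content phantom of known volume.

    Returns ``(image, mask)``; the mask is a voxel-center rasterized
    sphere whose analytic volume is ``volume_ml``, the image is bright
    inside with optional Gaussian noise (sd as a fraction of the bright
    intensity).  With ``grid_shape=None`` the grid is sized to fit.
    """
    if volume_ml < 0:
        raise InvalidSpecError("volume_ml must be >= 0")
    spacing = np.asarray(voxel_spacing, dtype=float)
    if spacing.shape != (3,) or np.any(spacing <= 0):
        raise InvalidSpecError("voxel_spacing must be 3 positive values (mm)")

    radius = (3.0 * volume_ml * 1000.0 / (4.0 * np.pi)) ** (1.0 / 3.0)  # mm
    if grid_shape is None:
        grid_shape = tuple(int(np.ceil(2.0 * radius / s)) + 4 for s in spacing)
        grid_shape = tuple(max(g, 4) for g in grid_shape)
    else:
        half_extent = np.array([(g - 1) / 2.0 * s for g, s in zip(grid_shape, spacing)])
        if np.any(radius > half_extent):
            raise InvalidSpecError(
                f"sphere radius {radius:.1f} mm exceeds grid half-extent "
                f"{half_extent.min():.1f} mm"
            )

    coords = [
        (np.arange(g) - (g - 1) / 2.0) * s for g, s in zip(grid_shape, spacing)
    ]
    zz, yy, xx = np.meshgrid(*coords, indexing="ij")
    mask = (zz**2 + yy**2 + xx**2 <= radius**2).astype(np.uint8)
    rng = np.random.default_rng(seed)
    image = mask.astype(np.float32) * BRIGHT_INTENSITY
    if noise_sd > 0:
        image = image + rng.normal(0.0, noise_sd * BRIGHT_INTENSITY, size=image.shape).astype(
            np.float32
        )
    return image, mask


def generate_emptying_series(spec: EmptyingSpec) -> VolumeSeries:
    """Generate a gastric-content-volume decay of known kinetics.

    First order: ``V(t) = c0 exp(-k t)``; zero order: ``V(t) = c0 - k t``;
    Gaussian noise added per sample and the result clipped at zero.
    """
    t = np.asarray(spec.sample_times, dtype=float)
    if spec.model_order == "first":
        v = spec.initial_volume * np.exp(-spec.rate_constant * t)
    else:
        v = spec.initial_volume - spec.rate_constant * t
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        v = v + rng.normal(0.0, spec.noise_sd, size=t.size)
    label = f"{spec.model_order}-order phantom"
    return VolumeSeries(times=t, volumes=np.clip(v, 0.0, None), label=label)


def compute_mn_dose(
    concentration_g_per_l: float, volume_l: float, hydrate_waters: int = 2
) -> float:
    """Elemental Mn2+ dose (mg) of a manganese(II) gluconate solution.

    ``concentration_g_per_l`` is grams of the (optionally hydrated) salt
    Mn(C6H11O7)2 * n H2O per litre; the dose is the dissolved salt mass
    times the manganese mass fraction.  The protocol solution of 0.73 g/L
    dihydrate, 290 mL, delivers 24.2 mg Mn2+.
    """
    if concentration_g_per_l < 0 or volume_l < 0 or hydrate_waters < 0:
        raise InvalidSpecError("concentration, volume and hydrate_waters must be >= 0")
    molar_mass = MOLAR_MASS_MN + 2 * _MASS_GLUCONATE + hydrate_waters * _MASS_WATER
    return concentration_g_per_l * volume_l * (MOLAR_MASS_MN / molar_mass) * 1000.0
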