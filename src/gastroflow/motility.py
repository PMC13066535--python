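"""Quantification of gastric peristalsis from antral area-time curves.

Peristaltic contractions of the distal stomach (antrum) show up in dynamic
MRI as a rhythmic modulation of the antral cross-sectional area.  Given
per-slice area-time series sampled at a uniform frame rate, this module
computes

* the dominant contraction frequency in the physiological band
  0.03-0.07 Hz (1.8-4.2 cycles per minute, cpm), gated by a spectral
  *dominance factor*,
* the per-frame *occlusion* — the relative lumen narrowing versus the
  relaxed reference area,
* the wave *propagation distance* spanned by a three-slice sagittal stack,
* an *apparent propagation speed* derived from frequency and distance, and
* an independent cross-correlation speed estimate from the inter-slice
  time delay of the band-passed signals.

Frequencies are reported in cpm, areas in mm^2, speeds in mm/s.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import signal as sp_signal

from .exceptions import (
    BandResolutionError,
    DegenerateReferenceError,
    InsufficientDataError,
    UnsupportedGeometryError,
)

logger = logging.getLogger(__name__)

#: Physiological antral contraction band (Hz): 1.8-4.2 cpm.
DEFAULT_BAND_HZ = (0.03, 0.07)
#: Respiratory interference band (Hz), used for diagnostics/plots only.
BREATHING_BAND_HZ = (0.15, 0.30)
#: Minimum record length accepted for spectral analysis (s).
MIN_RECORD_SECONDS = 30.0

__all__ = [
    "SliceGeometry",
    "FrequencyBand",
    "AreaTimeSeries",
    "FrequencyResult",
    "OcclusionResult",
    "CrossCorrResult",
    "MotilityTimepointReport",
    "hz_to_cpm",
    "cpm_to_hz",
    "smooth_for_display",
    "amplitude_spectrum",
    "dominant_frequency",
    "bandpass",
    "occlusion",
    "propagation_distance",
    "apparent_speed",
    "crosscorr_speed",
    "analyze_timepoint",
]


def hz_to_cpm(freq_hz: float) -> float:
    """Convert a frequency from Hz to cycles per minute."""
    return freq_hz * 60.0


def cpm_to_hz(freq_cpm: float) -> float:
    """Convert a frequency from cycles per minute to Hz."""
    return freq_cpm / 60.0


@dataclass(frozen=True)
class SliceGeometry:
    """Multi-slice real-time acquisition geometry.

    Parameters
    ----------
    slice_thickness : float
        Slice thickness in mm.
    distance_factor : float
        Scanner distance factor (DF); the edge-to-edge inter-slice gap is
        ``distance_factor * slice_thickness``.
    n_slices : int
        Number of interleaved slices (three in the sagittal protocol).
    pixel_spacing : float
        In-plane pixel size in mm (isotropic).
    frame_rate : float
        Effective temporal sampling rate in frames/s.
    """

    slice_thickness: float = 5.0
    distance_factor: float = 1.5
    n_slices: int = 3
    pixel_spacing: float = 200.0 / 140.0
    frame_rate: float = 6.24

    def __post_init__(self) -> None:
        if self.slice_thickness <= 0:
            raise ValueError("slice_thickness must be > 0")
        if self.distance_factor < 0:
            raise ValueError("distance_factor must be >= 0")
        if self.n_slices < 1:
            raise ValueError("n_slices must be >= 1")
        if self.pixel_spacing <= 0:
            raise ValueError("pixel_spacing must be > 0")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be > 0")

    @property
    def inter_slice_gap(self) -> float:
        """Edge-to-edge gap between adjacent slices in mm (DF x thickness)."""
        return self.distance_factor * self.slice_thickness

    @property
    def slice_center_separation(self) -> float:
        """Center-to-center distance of adjacent slices in mm."""
        return self.slice_thickness + self.inter_slice_gap

    @property
    def frame_interval(self) -> float:
        """Temporal sampling interval in s."""
        return 1.0 / self.frame_rate


@dataclass(frozen=True)
class FrequencyBand:
    """Closed frequency interval [low, high] in Hz."""

    low: float = DEFAULT_BAND_HZ[0]
    high: float = DEFAULT_BAND_HZ[1]

    def __post_init__(self) -> None:
        if not (0.0 < self.low < self.high):
            raise ValueError(f"require 0 < low < high, got [{self.low}, {self.high}]")

    @property
    def low_cpm(self) -> float:
        return hz_to_cpm(self.low)

    @property
    def high_cpm(self) -> float:
        return hz_to_cpm(self.high)

    def contains(self, freq_hz: np.ndarray | float) -> np.ndarray | bool:
        return (np.asarray(freq_hz) >= self.low) & (np.asarray(freq_hz) <= self.high)


@dataclass
class AreaTimeSeries:
    """Uniformly sampled antral cross-sectional area signal for one slice.

    ``areas`` are in mm^2 and sampled at ``frame_rate`` frames/s.  Slice
    indices are 0-based internally (slice 0 is the paper-facing "slice 1",
    nearest the pylorus).
    """

    areas: np.ndarray
    frame_rate: float
    slice_index: int = 0
    timepoint_id: str = ""

    def __post_init__(self) -> None:
        self.areas = np.asarray(self.areas, dtype=float)
        if self.areas.ndim != 1:
            raise ValueError("areas must be a 1-D sequence")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be > 0")
        if np.any(self.areas < 0):
            raise ValueError("areas must be non-negative")

    def __len__(self) -> int:
        return self.areas.size

    @property
    def duration(self) -> float:
        """Record length in s."""
        return self.areas.size / self.frame_rate

    @property
    def times(self) -> np.ndarray:
        """Sample times in s (first frame at t = 0)."""
        return np.arange(self.areas.size) / self.frame_rate


@dataclass
class FrequencyResult:
    """Outcome of dominant-frequency detection on one slice.

    ``valid`` is true iff the dominance factor — ratio of the in-band peak
    amplitude to the mean in-band amplitude (peak included) — reaches the
    threshold.  ``dominant_frequency_cpm`` is None when invalid.
    """

    frequencies_hz: np.ndarray
    amplitudes: np.ndarray
    peak_frequency_cpm: float
    dominance_factor: float
    valid: bool

    @property
    def dominant_frequency_cpm(self) -> Optional[float]:
        return self.peak_frequency_cpm if self.valid else None


@dataclass
class OcclusionResult:
    """Per-frame occlusion (%) of one slice against its relaxed reference."""

    reference_area: float
    occlusion_pct: np.ndarray
    mean_occlusion_pct: float

    @property
    def max_occlusion_pct(self) -> float:
        return float(np.max(self.occlusion_pct))


@dataclass
class CrossCorrResult:
    """Inter-slice delay estimate from normalized cross-correlation.

    ``optimal_lag_s`` is the unrestricted argmax over +/- one dominant
    period (sign convention: positive when the far slice lags the pyloric
    slice).  ``delay_s`` is the forward-propagation delay used for the
    speed — the best strictly positive lag — reflecting the anatomical
    prior that the wave travels along increasing slice index.
    """

    optimal_lag_s: float
    delay_s: Optional[float]
    speed_mm_s: Optional[float]
    reason: str = ""


@dataclass
class MotilityTimepointReport:
    """Per-timepoint aggregation across sagittal slices.

    ``mean_frequency_cpm`` is present iff at least two slices have a valid
    dominant frequency (the two-of-three rule); ``apparent_speed_mm_s``
    is derived from it and is present under the same condition.
    """

    timepoint_id: str
    frequency: list  # list[FrequencyResult]
    occlusion: list  # list[OcclusionResult]
    mean_frequency_cpm: Optional[float]
    propagation_distance_mm: Optional[float]
    apparent_speed_mm_s: Optional[float]
    crosscorr: Optional[CrossCorrResult]
    n_valid_slices: int = 0


# ---------------------------------------------------------------------------
# signal conditioning
# ---------------------------------------------------------------------------

def smooth_for_display(
    series: AreaTimeSeries, window: int = 59, order: int = 1
) -> np.ndarray:
    """Savitzky-Golay smoothing of an area-time curve, for display only.

    The default window of 59 frames (~9.5 s at 6.24 fps) with a first-order
    local fit removes frame-to-frame segmentation jitter while preserving
    the slow contraction envelope.  Spectral analysis always uses the raw
    signal; this smoothing must never feed the FFT.

    If the series is shorter than ``window`` the window is reduced to the
    largest odd length not exceeding the series, with a logged warning.
    """
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if order >= window:
        raise ValueError("order must be < window")
    n = len(series)
    if n < window:
        reduced = n if n % 2 == 1 else n - 1
        logger.warning(
            "series length %d < smoothing window %d; reducing window to %d",
            n, window, reduced,
        )
        window = reduced
    if window <= order:
        return series.areas.copy()
    return sp_signal.savgol_filter(series.areas, window, order)


def _one_sided_amplitudes(x: np.ndarray) -> np.ndarray:
    """Amplitude normalization such that a sinusoid of amplitude A yields A
    at its bin; Parseval: var(x) = sum(a[k]^2)/2 over interior bins plus
    a[nyq]^2 for even length."""
    n = x.size
    amps = np.abs(np.fft.rfft(x)) / n
    amps[1:] *= 2.0
    if n % 2 == 0:
        amps[-1] /= 2.0  # Nyquist bin is not duplicated
    return amps


def amplitude_spectrum(series: AreaTimeSeries) -> tuple[np.ndarray, np.ndarray]:
    """One-sided amplitude spectrum of the mean-removed raw area signal.

    Returns ``(frequencies_hz, amplitudes)``; the frequency resolution is
    ``frame_rate / len(series)``.  A pure sinusoid at a grid frequency
    appears as a single bin whose amplitude equals the sinusoid amplitude.
    """
    n = len(series)
    if n < 16:
        raise InsufficientDataError(f"need >= 16 frames for a spectrum, got {n}")
    x = series.areas
    if not np.all(np.isfinite(x)):
        raise ValueError("areas contain non-finite values")
    x = x - x.mean()
    freqs = np.fft.rfftfreq(n, d=1.0 / series.frame_rate)
    return freqs, _one_sided_amplitudes(x)


def dominant_frequency(
    frequencies_hz: np.ndarray,
    amplitudes: np.ndarray,
    band: FrequencyBand = FrequencyBand(),
    dominance_threshold: float = 2.0,
) -> FrequencyResult:
    """Locate the in-band spectral peak and gate it by dominance factor.

    The dominance factor is the ratio of the peak amplitude to the mean
    amplitude over all in-band bins, peak included; peaks with a factor
    below ``dominance_threshold`` (default 2.0) are flagged invalid.  At
    equal peak amplitudes the lowest frequency wins.
    """
    frequencies_hz = np.asarray(frequencies_hz, dtype=float)
    amplitudes = np.asarray(amplitudes, dtype=float)
    in_band = band.contains(frequencies_hz)
    if not np.any(in_band):
        resolution = float(frequencies_hz[1] - frequencies_hz[0])
        raise BandResolutionError(resolution, band.high - band.low)
    band_freqs = frequencies_hz[in_band]
    band_amps = amplitudes[in_band]
    peak_idx = int(np.argmax(band_amps))  # first max -> lowest frequency
    peak_amp = float(band_amps[peak_idx])
    mean_amp = float(band_amps.mean())
    factor = peak_amp / mean_amp if mean_amp > 0 else (1.0 if peak_amp == 0 else np.inf)
    valid = bool(factor >= dominance_threshold)
    return FrequencyResult(
        frequencies_hz=frequencies_hz,
        amplitudes=amplitudes,
        peak_frequency_cpm=hz_to_cpm(float(band_freqs[peak_idx])),
        dominance_factor=factor,
        valid=valid,
    )


def bandpass(series: AreaTimeSeries, band: FrequencyBand = FrequencyBand()) -> np.ndarray:
    """Ideal spectral band-pass of the mean-removed area signal.

    Discrete Fourier bins outside ``band`` (the DC bin included) are zeroed
    and the signal inverse-transformed, i.e. the band is applied literally
    as a spectral mask.  The output has (numerically) zero mean.
    """
    n = len(series)
    if n < 16:
        raise InsufficientDataError(f"need >= 16 frames to bandpass, got {n}")
    x = series.areas - series.areas.mean()
    spec = np.fft.rfft(x)
    freqs = np.fft.rfftfreq(n, d=1.0 / series.frame_rate)
    spec[~band.contains(freqs)] = 0.0
    return np.fft.irfft(spec, n=n)


# ---------------------------------------------------------------------------
# occlusion
# ---------------------------------------------------------------------------

def occlusion(series: AreaTimeSeries, top_fraction: float = 0.10) -> OcclusionResult:
    """Per-frame antral occlusion (%) against the relaxed reference area.

    The reference is the median of the ``ceil(top_fraction * N)`` largest
    areas of the record — a robust stand-in for the fully relaxed lumen.
    Occlusion is ``100 * (1 - area / reference)`` with negative values
    clipped to 0 (the lumen cannot be more open than relaxed); complete
    antral closure corresponds to 100%.
    """
    n = len(series)
    if n < 10:
        raise InsufficientDataError(f"need >= 10 frames for occlusion, got {n}")
    if not (0.0 < top_fraction <= 1.0):
        raise ValueError("top_fraction must be in (0, 1]")
    areas = series.areas
    k = math.ceil(top_fraction * n)
    top = np.sort(areas)[-k:]
    reference = float(np.median(top))
    if reference <= 0.0:
        raise DegenerateReferenceError(
            "reference area is zero; the series contains no open-lumen frames"
        )
    occ = 100.0 * (1.0 - areas / reference)
    occ = np.clip(occ, 0.0, None)
    return OcclusionResult(
        reference_area=reference,
        occlusion_pct=occ,
        mean_occlusion_pct=float(occ.mean()),
    )


# ---------------------------------------------------------------------------
# propagation
# ---------------------------------------------------------------------------

def propagation_distance(geometry: SliceGeometry) -> float:
    """Effective sampling distance (mm) spanned by a three-slice stack.

    Defined as ``3 * thickness + 2 * gap`` — the outer-edge span from the
    first to the third slice.  Only the three-slice sagittal layout is
    supported.
    """
    if geometry.n_slices != 3:
        raise UnsupportedGeometryError(
            f"propagation distance is defined for 3 slices, got {geometry.n_slices}"
        )
    return 3.0 * geometry.slice_thickness + 2.0 * geometry.inter_slice_gap


def apparent_speed(frequency_cpm: float, distance_mm: float) -> float:
    """Apparent propagation speed (mm/s) from frequency and slice span.

    ``speed = (frequency / 60) * distance``: one wave per contraction cycle
    is assumed to traverse the sampled span.  This is an apparent, not a
    true phase, speed — the contraction wave spans multiple slices.
    """
    if frequency_cpm < 0:
        raise ValueError("frequency must be >= 0")
    if distance_mm < 0:
        raise ValueError("distance must be >= 0")
    return frequency_cpm / 60.0 * distance_mm


def _normalized_xcorr(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Full cross-correlation of unit-norm signals; lags in frames.

    Positive lag means ``a`` lags ``b`` (a is b delayed).
    """
    na = np.linalg.norm(a)
    nb = np.linalg.norm(b)
    if na == 0 or nb == 0:
        return np.zeros(a.size + b.size - 1), np.arange(-(b.size - 1), a.size)
    corr = sp_signal.correlate(a / na, b / nb, mode="full")
    lags = sp_signal.correlation_lags(a.size, b.size, mode="full")
    return corr, lags


def crosscorr_speed(
    series_list: Sequence[AreaTimeSeries],
    geometry: SliceGeometry,
    band: FrequencyBand = FrequencyBand(),
    dominance_threshold: float = 2.0,
) -> CrossCorrResult:
    """Wave speed from the time delay between the outer slices.

    The band-passed, mean-removed signals of slice 1 (pyloric, index 0)
    and slice 3 (index 2) are cross-correlated; the delay of slice 3
    behind slice 1 divided into the propagation distance gives the speed.
    The lag search covers +/- one dominant period (the delay of a periodic
    wave is only defined modulo its period).  Because the contraction wave
    travels along increasing slice index by anatomy, the speed uses the
    best strictly positive lag; the unrestricted optimum is reported too,
    and a result with no measurable forward delay is absent, not an error.

    Both outer slices must be at least 30 s long and carry a valid
    dominant frequency.
    """
    if len(series_list) < 3:
        raise InsufficientDataError(
            f"cross-correlation needs slices 1 and 3; got {len(series_list)} series"
        )
    s1, s3 = series_list[0], series_list[2]
    for s in (s1, s3):
        if s.duration < MIN_RECORD_SECONDS:
            raise InsufficientDataError(
                f"slice {s.slice_index}: record of {s.duration:.1f} s is shorter "
                f"than the {MIN_RECORD_SECONDS:.0f} s minimum"
            )
    results = []
    for s in (s1, s3):
        freqs, amps = amplitude_spectrum(s)
        results.append(dominant_frequency(freqs, amps, band, dominance_threshold))
    if not all(r.valid for r in results):
        raise InsufficientDataError(
            "dominant frequency invalid on an outer slice; delay is undefined"
        )

    mean_cpm = float(np.mean([r.peak_frequency_cpm for r in results]))
    period_s = 60.0 / mean_cpm
    max_lag = int(round(period_s * s1.frame_rate))

    x1 = bandpass(s1, band)
    x3 = bandpass(s3, band)
    corr, lags = _normalized_xcorr(x3, x1)
    window = np.abs(lags) <= max_lag
    corr_w, lags_w = corr[window], lags[window]

    optimal_lag = int(lags_w[np.argmax(corr_w)])
    optimal_lag_s = optimal_lag / s1.frame_rate

    positive = lags_w > 0
    distance = propagation_distance(geometry)
    frame_interval = 1.0 / s1.frame_rate
    if not np.any(positive):
        logger.info("no positive lags in search window; crosscorr speed absent")
        return CrossCorrResult(optimal_lag_s, None, None, "no positive lag in window")
    delay_frames = int(lags_w[positive][np.argmax(corr_w[positive])])
    delay_s = delay_frames / s1.frame_rate
    if delay_s <= frame_interval:
        logger.info(
            "forward delay %.3f s not above one frame interval; speed absent", delay_s
        )
        return CrossCorrResult(
            optimal_lag_s, None, None, "delay within one frame interval"
        )
    return CrossCorrResult(optimal_lag_s, delay_s, distance / delay_s, "")


# ---------------------------------------------------------------------------
# per-timepoint aggregation
# ---------------------------------------------------------------------------

def analyze_timepoint(
    series_list: Sequence[AreaTimeSeries],
    geometry: SliceGeometry,
    band: FrequencyBand = FrequencyBand(),
    dominance_threshold: float = 2.0,
    top_fraction: float = 0.10,
    timepoint_id: str = "",
) -> MotilityTimepointReport:
    """Full motility quantification of one measurement timepoint.

    Per-slice frequency and occlusion are always computed.  The timepoint
    mean frequency is the unweighted mean of the dominant frequencies over
    valid slices and is reported only when at least two slices are valid;
    the apparent speed derives from that mean and inherits its presence.
    The cross-correlation speed is attempted when both outer slices carry
    a valid frequency.
    """
    if len(series_list) == 0:
        raise InsufficientDataError("no slice series supplied")

    freq_results = []
    occ_results = []
    for s in series_list:
        freqs, amps = amplitude_spectrum(s)
        freq_results.append(dominant_frequency(freqs, amps, band, dominance_threshold))
        occ_results.append(occlusion(s, top_fraction))

    valid = [r for r in freq_results if r.valid]
    mean_freq = float(np.mean([r.peak_frequency_cpm for r in valid])) if len(valid) >= 2 else None

    dist = None
    speed = None
    if geometry.n_slices == 3:
        dist = propagation_distance(geometry)
        if mean_freq is not None:
            speed = apparent_speed(mean_freq, dist)

    xc = None
    if len(series_list) >= 3 and freq_results[0].valid and freq_results[2].valid:
        try:
            xc = crosscorr_speed(series_list, geometry, band, dominance_threshold)
        except InsufficientDataError as exc:
            logger.info("cross-correlation skipped: %s", exc)

    return MotilityTimepointReport(
        timepoint_id=timepoint_id,
        frequency=freq_results,
        occlusion=occ_results,
        mean_frequency_cpm=mean_freq,
        propagation_distance_mm=dist,
        apparent_speed_mm_s=speed,
        crosscorr=xc,
        n_valid_slices=len(valid),
    )
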