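import numpy as np
import pytest

from gastroflow.motility import AreaTimeSeries, SliceGeometry


@pytest.fixture
def geometry():
    """Default three-slice sagittal geometry (5 mm slices, DF 1.5, 6.24 fps)."""
    return SliceGeometry()


def make_sinusoid_series(
    freq_hz: float,
    amplitude: float = 10.0,
    offset: float = 100.0,
    n: int = 1123,
    frame_rate: float = 6.24,
    on_grid: bool = True,
) -> AreaTimeSeries:
    """Area series with a single sinusoidal component.

    With ``on_grid`` the frequency snaps to the nearest DFT grid point so
    the component occupies exactly one bin.
    """
    if on_grid:
        k = round(freq_hz * n / frame_rate)
        freq_hz = k * frame_rate / n
    t = np.arange(n) / frame_rate
    areas = offset + amplitude * np.sin(2 * np.pi * freq_hz * t)
    return AreaTimeSeries(areas=areas, frame_rate=frame_rate)


@pytest.fixture
def sinusoid_3cpm():
    return make_sinusoid_series(0.05)
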