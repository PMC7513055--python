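import numpy as np
import pytest
from hypothesis import settings as _hyp_settings

_hyp_settings.register_profile("deterministic", derandomize=True)
_hyp_settings.load_profile("deterministic")

from tremorspiral import (
    Recording,
    SpiralGeometry,
    TremorParams,
    generate_spiral,
)

#: compact geometry used throughout the tests: ~3 s, ~630 samples
SMALL_GEOMETRY = SpiralGeometry(turns=2.0, angular_rate=4.0)


@pytest.fixture(scope="session")
def tremor_recording() -> Recording:
    """An essential-tremor-like drawing: 6 Hz radial tremor, pen lifts."""
    return generate_spiral(
        TremorParams(amplitude=60.0, frequency_hz=6.0, pen_lift_rate=2.0),
        seed=42,
        label="ET",
        subject_id="ET01",
    )


@pytest.fixture(scope="session")
def quiet_recording() -> Recording:
    """A control-like drawing with no injected tremor."""
    return generate_spiral(
        TremorParams(amplitude=0.0, pen_lift_rate=1.0),
        seed=7,
        label="CR",
        subject_id="CR01",
    )


@pytest.fixture(scope="session")
def all_down_recording() -> Recording:
    """A drawing that never leaves the surface."""
    return generate_spiral(
        TremorParams(amplitude=10.0, pen_lift_rate=0.0),
        geometry=SMALL_GEOMETRY,
        seed=3,
        label="CR",
        subject_id="CR02",
    )


def colored_noise(rng: np.random.Generator, n: int, beta: float) -> np.ndarray:
    """Gaussian 1/f^beta noise via spectral shaping.

    beta controls roughness: beta = 0 is white noise (rough, FD -> 2),
    large beta is smooth (FD -> 1); theoretical FD = (5 - beta) / 2 for
    beta in [1, 3].
    """
    white = rng.standard_normal(n)
    f = np.fft.rfftfreq(n)
    f[0] = f[1]  # avoid division by zero at DC
    shaped = np.fft.rfft(white) * f ** (-beta / 2.0)
    out = np.fft.irfft(shaped, n)
    return out / out.std()


def make_recording(
    t: np.ndarray,
    x: np.ndarray,
    y: np.ndarray,
    pen_down: np.ndarray | None = None,
    pressure: float | np.ndarray = 512.0,
) -> Recording:
    """Hand-built recording with valid defaults for the other channels."""
    n = len(t)
    if pen_down is None:
        pen_down = np.ones(n, dtype=bool)
    p = np.broadcast_to(np.asarray(pressure, dtype=float), (n,)).copy()
    p[~pen_down] = 0.0
    p[pen_down & (p <= 0)] = 1.0
    return Recording(
        t=t,
        x=x,
        y=y,
        pressure=p,
        azimuth=np.full(n, 180.0),
        altitude=np.full(n, 60.0),
        pen_down=pen_down,
    )
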