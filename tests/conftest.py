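import numpy as np
import pytest

from vesselastica import (VesselPhantomSpec, generate_phantom,
                          load_printed_degradation)


@pytest.fixture(scope="session")
def printed_strength():
    strength, _ = load_printed_degradation()
    return strength


@pytest.fixture(scope="session")
def printed_mw():
    _, mw = load_printed_degradation()
    return mw


@pytest.fixture(scope="session")
def exact_phantom():
    """Noiseless zero-lag phantom whose frame grid hits the pressure extrema.

    81 frames at 40 Hz over a 1 s cycle put frames exactly at the pressure
    minimum (t = 0.75 s) and maximum (t = 0.25 s), so the analytic modulus is
    recoverable to machine precision.
    """
    spec = VesselPhantomSpec(
        elastic_modulus_true=50.0, n_frames=81, frame_rate=40.0,
        cycle_period=1.0, pressure_mean=8.0, pressure_amplitude=2.0, seed=11,
    )
    contours, pressure, truth = generate_phantom(spec)
    return spec, contours, pressure, truth


def circle_contour(radius: float, n: int = 64, center=(0.0, 0.0)) -> np.ndarray:
    theta = 2.0 * np.pi * np.arange(n) / n
    return np.column_stack([center[0] + radius * np.cos(theta),
                            center[1] + radius * np.sin(theta)])
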