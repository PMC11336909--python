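import numpy as np
import pytest

from fuspa.synth import ClutterSpec, IQMovie, VesselSpec, simulate_iq_movie

# Doppler-path acquisition constants shared across tests: 15 MHz transducer,
# 525 us compounded-frame period, 1540 m/s sound speed.
F0_HZ = 15e6
PRF_C_HZ = 1e6 / 525.0
C_M_S = 1540.0


def tone_movie(f_hz, n_frames=150, shape=(2, 2), prf_c_hz=PRF_C_HZ, amplitude=1.0):
    """Single complex slow-time phasor replicated over a small frame."""
    t = np.arange(n_frames) / prf_c_hz
    x = amplitude * np.exp(2j * np.pi * f_hz * t)
    data = np.broadcast_to(x, (*shape, n_frames)).copy()
    return IQMovie(data, prf_c_hz=prf_c_hz, f0_hz=F0_HZ, c_m_s=C_M_S)


@pytest.fixture
def descending_vessel_scene():
    """One descending 10 mm/s plug-flow tube under 30 dB rank-10 clutter."""
    vessel = VesselSpec(center_mm=(4.8, 3.2), radius_mm=0.3, axial_velocity_mm_s=10.0)
    movie, truth = simulate_iq_movie(
        [vessel],
        ClutterSpec(),
        (96, 64, 150),
        noise_sigma=1e-3,
        seed=7,
    )
    return movie, truth
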