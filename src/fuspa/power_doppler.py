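"""Power-Doppler intensity mapping (the CBV proxy).

After clutter rejection the residual slow-time signal is dominated by moving
red blood cells, so the per-pixel mean squared magnitude is taken as directly
proportional to the fractional moving blood volume.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .synth import IQMovie

__all__ = ["CBVMap", "power_doppler_map"]


@dataclass
class CBVMap:
    """Per-pixel power-Doppler intensity: linear units plus a dB view
    referenced to the map maximum."""

    intensity: np.ndarray
    intensity_db: np.ndarray
    n_frames_used: int


def power_doppler_map(filtered: IQMovie, smooth_sigma_px: float | None = None) -> CBVMap:
    """Mean squared magnitude over slow time, per pixel.

    ``intensity(z, x) = mean_t |IQ(z, x, t)|^2``. The dB view is
    ``10 log10(I / max I)`` with a -120 dB floor for empty pixels. Optional
    Gaussian smoothing (``smooth_sigma_px``) is off by default. The input is
    expected to be clutter-filtered already; this is not enforced.
    """
    if filtered.n_frames == 0:
        raise ValueError("cannot compute power Doppler of zero frames")
    intensity = np.mean(np.abs(filtered.data) ** 2, axis=2)
    if smooth_sigma_px is not None and smooth_sigma_px > 0:
        intensity = ndimage.gaussian_filter(intensity, smooth_sigma_px)
    peak = intensity.max()
    if peak > 0:
        db = 10.0 * np.log10(np.maximum(intensity, peak * 1e-12) / peak)
    else:
        db = np.full_like(intensity, -120.0)
    return CBVMap(intensity=intensity, intensity_db=db, n_frames_used=filtered.n_frames)
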