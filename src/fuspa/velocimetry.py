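"""Directional autocorrelation velocimetry (the CBF proxy).

The clutter-filtered, wall-filtered slow-time signal of each pixel is split
into positive- and negative-frequency components. Each component's axial
velocity follows from the phase of the lag-1 temporal autocorrelation (the
Kasai estimator): ``f_d = prf_c * arg(R(1)) / 2pi`` and
``v_z = c * f_d / (2 f0)``, bounded by the Nyquist velocity
``c * prf_c / (4 f0)`` by construction of arg().

Sign convention (fixed package-wide): the transducer sits above the tissue,
depth increases downward, and **descending** flow (away from the transducer)
produces a negative Doppler shift — so the descending map is read from the
negative-frequency component and the ascending map from the positive one.
A component is only trusted where it holds a sufficient fraction of the total
spectral power (0.2 positive / 0.25 negative) and where its normalized lag-1
autocorrelation magnitude exceeds 0.2; everything else is masked.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .clutter import FilterConfig, slow_time_highpass, svd_clutter_filter
from .synth import IQMovie

__all__ = [
    "VelocimetryConfig",
    "VelocityMap",
    "directional_split",
    "axial_velocity",
    "axial_velocity_multilag",
    "validity_masks",
    "assemble_cbf_map",
    "cbf_pipeline",
    "nyquist_velocity_mm_s",
]


@dataclass(frozen=True)
class VelocimetryConfig:
    """Validity thresholds and the CBF-path filter settings."""

    pos_power_fraction_min: float = 0.2
    neg_power_fraction_min: float = 0.25
    autocorr_min: float = 0.2
    svd_n_reject: int = 10
    highpass_cutoff_hz: float = 70.0
    highpass_order: int = 4

    def __post_init__(self) -> None:
        for name in ("pos_power_fraction_min", "neg_power_fraction_min", "autocorr_min"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")


@dataclass
class VelocityMap:
    """Signed axial-velocity maps with their validity masks.

    ``v_descending`` / ``v_ascending`` are non-negative speeds (mm/s) of flow
    away from / toward the transducer, zero where the corresponding mask is
    false. ``v_signed`` combines them (+ descending, - ascending); pixels
    valid in both directions keep the larger-magnitude component there while
    both per-direction maps retain their values for overlay display.
    """

    v_descending: np.ndarray
    v_ascending: np.ndarray
    valid_pos: np.ndarray
    valid_neg: np.ndarray
    v_signed: np.ndarray


def nyquist_velocity_mm_s(f0_hz: float, prf_c_hz: float, c_m_s: float) -> float:
    """Largest unambiguous axial speed: c * prf_c / (4 f0), in mm/s."""
    return c_m_s * prf_c_hz / (4.0 * f0_hz) * 1e3


def directional_split(movie: IQMovie):
    """Split each pixel's slow-time spectrum at 0 Hz.

    Returns ``(pos_movie, neg_movie, frac_pos, frac_neg)`` where the
    components are inverse transforms of the positive-/negative-frequency
    halves and the fractions are each component's share of the total spectral
    power, so ``frac_pos + frac_neg <= 1`` with equality when the excluded
    bins are empty. The DC bin is excluded from both components (a
    clutter-filtered signal should be DC-free); for even lengths the Nyquist
    bin is excluded too, since its rotation sign is ambiguous and assigning
    it to either side would break the symmetry between descending and
    ascending flow.
    """
    nt = movie.n_frames
    if nt < 2:
        raise ValueError("directional split requires at least 2 frames")
    spec = np.fft.fft(movie.data, axis=2)
    freqs = np.fft.fftfreq(nt)
    nyquist = np.abs(freqs) == 0.5
    pos_mask = (freqs > 0) & ~nyquist
    neg_mask = (freqs < 0) & ~nyquist
    power = np.abs(spec) ** 2
    total = power.sum(axis=2)
    safe_total = np.where(total > 0, total, 1.0)
    frac_pos = np.where(total > 0, power[:, :, pos_mask].sum(axis=2) / safe_total, 0.0)
    frac_neg = np.where(total > 0, power[:, :, neg_mask].sum(axis=2) / safe_total, 0.0)
    pos = np.fft.ifft(np.where(pos_mask[None, None, :], spec, 0.0), axis=2)
    neg = np.fft.ifft(np.where(neg_mask[None, None, :], spec, 0.0), axis=2)
    return movie.with_data(pos), movie.with_data(neg), frac_pos, frac_neg


def axial_velocity(component: IQMovie, f0_hz=None, prf_c_hz=None, c_m_s=None):
    """Kasai lag-1 autocorrelation velocity per pixel.

    ``R(1) = sum_t IQ*(t) IQ(t+1)``; the Doppler shift is
    ``prf_c * arg(R(1)) / 2pi`` and the velocity ``c f_d / (2 f0)`` (mm/s,
    signed like the Doppler shift). Also returns ``|R(1)| / R(0)`` for the
    noise mask; pixels with ``R(0) = 0`` get velocity 0 and autocorrelation 0.
    """
    f0 = f0_hz if f0_hz is not None else component.f0_hz
    prf = prf_c_hz if prf_c_hz is not None else component.prf_c_hz
    c = c_m_s if c_m_s is not None else component.c_m_s
    x = component.data if isinstance(component, IQMovie) else np.asarray(component)
    r1 = np.sum(np.conj(x[..., :-1]) * x[..., 1:], axis=-1)
    r0 = np.sum(np.abs(x) ** 2, axis=-1)
    f_d = prf * np.angle(r1) / (2.0 * np.pi)
    v_mm_s = c * f_d / (2.0 * f0) * 1e3
    autocorr = np.where(r0 > 0, np.abs(r1) / np.where(r0 > 0, r0, 1.0), 0.0)
    v_mm_s = np.where(r0 > 0, v_mm_s, 0.0)
    return v_mm_s, autocorr


def axial_velocity_multilag(component: IQMovie, n_lags: int = 4):
    """Multi-lag variant: weighted linear fit of the unwrapped phase of
    R(tau), tau = 1..n_lags, weighted by |R(tau)|.

    Agrees with the lag-1 estimator on noiseless phasors; averages down phase
    noise on broadband signals at the cost of a tighter aliasing limit
    (phase must stay unwrappable across lags). Returns (v_mm_s, lag-1
    normalized autocorrelation).
    """
    x = component.data
    nt = x.shape[-1]
    if n_lags < 1 or n_lags >= nt:
        raise ValueError("n_lags must be in [1, n_frames)")
    prf, f0, c = component.prf_c_hz, component.f0_hz, component.c_m_s
    phases = []
    weights = []
    r0 = np.sum(np.abs(x) ** 2, axis=-1)
    r1_abs = None
    prev = np.zeros(x.shape[:-1])
    for lag in range(1, n_lags + 1):
        r = np.sum(np.conj(x[..., :-lag]) * x[..., lag:], axis=-1)
        ang = np.angle(r)
        # unwrap against the extrapolated previous phase
        ang = prev + np.angle(np.exp(1j * (ang - prev)))
        phases.append(ang)
        weights.append(np.abs(r))
        if lag == 1:
            r1_abs = np.abs(r)
        prev = ang * (lag + 1) / lag
    taus = np.arange(1, n_lags + 1, dtype=float)
    ph = np.stack(phases, axis=-1)
    w = np.stack(weights, axis=-1)
    wsum = w.sum(axis=-1)
    wsum = np.where(wsum > 0, wsum, 1.0)
    # weighted least squares slope through the origin: sum w tau phi / sum w tau^2
    num = (w * taus * ph).sum(axis=-1)
    den = (w * taus**2).sum(axis=-1)
    slope = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    f_d = prf * slope / (2.0 * np.pi)
    v_mm_s = c * f_d / (2.0 * f0) * 1e3
    autocorr = np.where(r0 > 0, r1_abs / np.where(r0 > 0, r0, 1.0), 0.0)
    return v_mm_s, autocorr


def validity_masks(frac_pos, frac_neg, autocorr_pos, autocorr_neg,
                   config: VelocimetryConfig = VelocimetryConfig()):
    """Threshold rule: a direction is valid where its power fraction exceeds
    its floor (0.2 positive, 0.25 negative) AND its normalized lag-1
    autocorrelation exceeds 0.2."""
    valid_pos = (frac_pos > config.pos_power_fraction_min) & (
        autocorr_pos > config.autocorr_min
    )
    valid_neg = (frac_neg > config.neg_power_fraction_min) & (
        autocorr_neg > config.autocorr_min
    )
    return valid_pos, valid_neg


def assemble_cbf_map(v_pos, v_neg, valid_pos, valid_neg) -> VelocityMap:
    """Combine per-direction velocities into a signed CBF map.

    The negative-frequency component carries descending flow, so its
    (negative) velocity is negated into a non-negative descending speed;
    the positive component carries ascending flow. Where both directions are
    valid the signed map takes the larger-magnitude component.
    """
    v_pos = np.asarray(v_pos)
    v_neg = np.asarray(v_neg)
    v_desc = np.where(valid_neg, np.maximum(-v_neg, 0.0), 0.0)
    v_asc = np.where(valid_pos, np.maximum(v_pos, 0.0), 0.0)
    v_signed = np.where(v_desc >= v_asc, v_desc, -v_asc)
    v_signed = np.where(valid_pos | valid_neg, v_signed, 0.0)
    return VelocityMap(
        v_descending=v_desc,
        v_ascending=v_asc,
        valid_pos=np.asarray(valid_pos, dtype=bool),
        valid_neg=np.asarray(valid_neg, dtype=bool),
        v_signed=v_signed,
    )


def cbf_pipeline(movie: IQMovie, config: VelocimetryConfig = VelocimetryConfig(),
                 estimator: str = "lag1") -> VelocityMap:
    """The full CBF path in the fixed stage order:
    SVD rejection -> 70 Hz zero-phase high-pass -> directional split ->
    per-component autocorrelation velocity -> validity masking -> assembly.
    """
    filt_cfg = FilterConfig(
        n_reject=config.svd_n_reject,
        highpass_cutoff_hz=config.highpass_cutoff_hz,
        highpass_order=config.highpass_order,
        apply_highpass=True,
    )
    filtered, _ = svd_clutter_filter(movie, filt_cfg)
    filtered = slow_time_highpass(filtered, filt_cfg)
    pos, neg, frac_pos, frac_neg = directional_split(filtered)
    if estimator == "lag1":
        v_pos, ac_pos = axial_velocity(pos)
        v_neg, ac_neg = axial_velocity(neg)
    elif estimator == "multilag":
        v_pos, ac_pos = axial_velocity_multilag(pos)
        v_neg, ac_neg = axial_velocity_multilag(neg)
    else:
        raise ValueError(f"unknown estimator {estimator!r}")
    valid_pos, valid_neg = validity_masks(frac_pos, frac_neg, ac_pos, ac_neg, config)
    return assemble_cbf_map(v_pos, v_neg, valid_pos, valid_neg)
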