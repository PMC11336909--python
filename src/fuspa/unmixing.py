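"""Multispectral photoacoustic unmixing: HbO / HbD / ICG maps, SO2 and ICG
time activity.

Per pixel, the measured amplitudes across wavelengths are modeled as a
non-negative combination of chromophore spectra scaled by the per-wavelength
laser pulse energy; non-negative least squares (NNLS) inverts the model.
Oxygen saturation is then SO2 = HbO / (HbO + HbD) wherever hemoglobin signal
exists, and unmixed ICG maps are reduced to ROI time-activity curves.

No fluence correction is applied: concentrations carry a depth-dependent bias
wherever light attenuates, which is documented rather than corrected.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.optimize import nnls

from .synth import PAStack

__all__ = [
    "ExtinctionTable",
    "default_extinction_table",
    "ConcentrationMaps",
    "SO2Map",
    "average_wavelength_sets",
    "split_frame_block",
    "build_system_matrix",
    "unmix_stack",
    "compute_so2",
    "icg_time_activity",
    "CHROMOPHORES",
]

CHROMOPHORES = ("HbO", "HbD", "ICG")

# Molar extinction coefficients (cm^-1 / M) at the three imaging wavelengths,
# frozen as versioned package constants so results are reproducible:
# hemoglobin values from the standard compiled whole-blood tables, ICG from
# compiled ICG-in-plasma spectra (absorption peak near 800 nm in plasma).
_DEFAULT_EXTINCTION = {
    "HbO": {750.0: 518.0, 800.0: 816.0, 850.0: 1058.0},
    "HbD": {750.0: 1405.24, 800.0: 761.72, 850.0: 691.32},
    "ICG": {750.0: 78000.0, 800.0: 192000.0, 850.0: 24000.0},
}


@dataclass(frozen=True)
class ExtinctionTable:
    """Molar extinction per chromophore per wavelength, all values >= 0."""

    values: dict = field(default_factory=lambda: _DEFAULT_EXTINCTION)
    source: str = "compiled-tables-v1"

    def __post_init__(self) -> None:
        for chromo, spectrum in self.values.items():
            if any(eps < 0 for eps in spectrum.values()):
                raise ValueError(f"negative extinction for {chromo}")

    def epsilon(self, chromophore: str, wavelength_nm: float) -> float:
        try:
            spectrum = self.values[chromophore]
        except KeyError:
            raise KeyError(f"unknown chromophore {chromophore!r}") from None
        try:
            return spectrum[float(wavelength_nm)]
        except KeyError:
            raise KeyError(
                f"no extinction value for {chromophore} at {wavelength_nm} nm"
            ) from None

    @property
    def chromophores(self) -> tuple:
        return tuple(self.values.keys())


def default_extinction_table() -> ExtinctionTable:
    return ExtinctionTable()


@dataclass
class ConcentrationMaps:
    """Non-negative per-pixel chromophore amounts plus the NNLS residual norm."""

    HbO: np.ndarray
    HbD: np.ndarray
    ICG: np.ndarray
    residual: np.ndarray

    def __getitem__(self, name: str) -> np.ndarray:
        return getattr(self, name)


@dataclass
class SO2Map:
    """Oxygen saturation in [0, 1] on its support; masked pixels are NaN."""

    so2: np.ndarray
    support_mask: np.ndarray


def split_frame_block(frames, n_wavelengths: int = 3):
    """Group a flat frame block into complete wavelength sets.

    A 16-frame block at 3 wavelengths yields 5 complete sets; the spare
    frame(s) at the tail are discarded. Returns an array of shape
    (n_sets, n_wavelengths, z, x).
    """
    frames = np.asarray(frames, dtype=float)
    n_sets = frames.shape[0] // n_wavelengths
    if n_sets == 0:
        raise ValueError("no complete wavelength set in the frame block")
    return frames[: n_sets * n_wavelengths].reshape(
        n_sets, n_wavelengths, *frames.shape[1:]
    )


def average_wavelength_sets(stack: PAStack) -> np.ndarray:
    """Average the repeated sets per wavelength (the SNR step).

    Zero-mean noise of std sigma drops to sigma / sqrt(n_sets). Returns an
    array of shape (n_wavelengths, z, x).
    """
    if stack.n_sets < 1:
        raise ValueError("need at least one complete wavelength set")
    return stack.images.mean(axis=0)


def build_system_matrix(
    table: ExtinctionTable,
    wavelengths_nm,
    pulse_energies_mj,
    chromophores=CHROMOPHORES,
    energy_ref_mj: float = 1.0,
) -> np.ndarray:
    """Energy-normalized unmixing matrix E (wavelengths x chromophores).

    Row lambda is the extinction spectrum scaled by that wavelength's pulse
    energy relative to ``energy_ref_mj`` (a fixed unit reference), matching
    the forward model amplitude ~ E_lambda * sum eps c. Scaling all energies
    and all images together therefore leaves the solution unchanged.
    """
    if len(pulse_energies_mj) != len(wavelengths_nm):
        raise ValueError("one pulse energy per wavelength required")
    if any(e <= 0 for e in pulse_energies_mj):
        raise ValueError("pulse energies must be > 0")
    rows = []
    for wl, energy in zip(wavelengths_nm, pulse_energies_mj):
        rows.append(
            [(energy / energy_ref_mj) * table.epsilon(ch, wl) for ch in chromophores]
        )
    return np.asarray(rows, dtype=float)


def unmix_stack(averaged_frames: np.ndarray, system_matrix: np.ndarray) -> ConcentrationMaps:
    """Per-pixel NNLS: c = argmin ||E c - p||_2 subject to c >= 0.

    ``averaged_frames`` has shape (n_wavelengths, z, x); the system matrix
    must have at least as many rows (wavelengths) as columns (chromophores).
    """
    p = np.asarray(averaged_frames, dtype=float)
    e = np.asarray(system_matrix, dtype=float)
    if p.shape[0] != e.shape[0]:
        raise ValueError("frame count must match the system-matrix rows")
    if e.shape[0] < e.shape[1]:
        raise ValueError("need at least as many wavelengths as chromophores")
    n_wl, nz, nx = p.shape
    flat = p.reshape(n_wl, -1)
    conc = np.empty((e.shape[1], flat.shape[1]))
    resid = np.empty(flat.shape[1])
    for i in range(flat.shape[1]):
        conc[:, i], resid[i] = nnls(e, flat[:, i])
    maps = conc.reshape(e.shape[1], nz, nx)
    return ConcentrationMaps(
        HbO=maps[0], HbD=maps[1], ICG=maps[2], residual=resid.reshape(nz, nx)
    )


def compute_so2(maps: ConcentrationMaps, floor: float | None = None) -> SO2Map:
    """SO2 = HbO / (HbO + HbD) where total hemoglobin exceeds ``floor``.

    ``floor`` defaults to 1% of the map's maximum HbO + HbD; below it the
    ratio is noise-dominated and the pixel is masked (NaN) and excluded from
    any downstream ROI statistics.
    """
    thb = maps.HbO + maps.HbD
    if floor is None:
        floor = 0.01 * thb.max() if thb.max() > 0 else 0.0
    support = thb > floor
    so2 = np.full(thb.shape, np.nan)
    so2[support] = maps.HbO[support] / thb[support]
    return SO2Map(so2=so2, support_mask=support)


def icg_time_activity(concentration_maps, roi_masks, smooth_window: int = 5):
    """ROI-mean ICG per frame, raw plus moving-average smoothed overlay.

    ``concentration_maps`` is a time-ordered sequence of
    :class:`ConcentrationMaps`; ``roi_masks`` a dict of boolean masks.
    Returns ``{roi: {"raw": ..., "smoothed": ...}}``; a window of 1 leaves
    the curve untouched.
    """
    maps = list(concentration_maps)
    if len(maps) < 2:
        raise ValueError("need at least 2 time points for a time-activity curve")
    if smooth_window < 1:
        raise ValueError("smooth_window must be >= 1")
    out = {}
    for name, mask in roi_masks.items():
        mask = np.asarray(mask, dtype=bool)
        if not mask.any():
            raise ValueError(f"ROI {name!r} is empty")
        raw = np.array([m.ICG[mask].mean() for m in maps])
        smoothed = ndimage.uniform_filter1d(raw, smooth_window, mode="nearest")
        out[name] = {"raw": raw, "smoothed": smoothed}
    return out
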