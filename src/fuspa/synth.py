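"""Physics-informed synthetic data with known ground truth.

Three generators emulate the acquisitions consumed by the processing chain:

* :func:`simulate_iq_movie` — beamformed, angle-compounded complex IQ
  ensembles containing moving blood scatterers (slow-time phasors at the
  pulse-echo Doppler frequency), a low-rank tissue-clutter term, and thermal
  noise. Simulation starts at the compounded-IQ level; beamforming is a
  vendor-side step upstream of everything this package does.
* :func:`simulate_mb_movie` — sparse microbubble point-spread functions moving
  along prescribed tracks, for localization-microscopy testing.
* :func:`simulate_mspa_stack` — multispectral photoacoustic image sets built
  from ground-truth chromophore concentration maps with per-wavelength pulse
  energies and exponential fluence decay.

Axis convention everywhere: (depth z, lateral x, slow-time t), depth
increasing away from the transducer. Descending flow (positive axial
velocity, away from the transducer) produces a **negative** Doppler shift of
the IQ phasor, f_d = -2 f0 v_z / c, as in pulse-echo physics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "IQMovie",
    "VesselSpec",
    "ClutterSpec",
    "ChromophorePhantom",
    "PAStack",
    "doppler_frequency_hz",
    "simulate_iq_movie",
    "simulate_mb_movie",
    "straight_track",
    "simulate_mspa_stack",
    "make_tube_phantom_scene",
]


@dataclass
class IQMovie:
    """Complex beamformed frame stack with its acquisition metadata.

    ``data`` has shape (depth, lateral, slow-time). ``prf_c_hz`` is the
    compounded frame rate, ``f0_hz`` the transducer center frequency,
    ``c_m_s`` the sound speed and ``pixel_pitch_mm`` the (isotropic) pixel
    spacing. The metadata travels with the array so that downstream stages
    cannot silently mix units.
    """

    data: np.ndarray
    pixel_pitch_mm: float = 0.1
    f0_hz: float = 15e6
    c_m_s: float = 1540.0
    prf_c_hz: float = 1e6 / 525.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise ValueError("IQ data must be 3-D (depth, lateral, slow-time)")
        if self.prf_c_hz <= 0 or self.f0_hz <= 0 or self.c_m_s <= 0:
            raise ValueError("prf_c_hz, f0_hz and c_m_s must be > 0")
        if self.pixel_pitch_mm <= 0:
            raise ValueError("pixel_pitch_mm must be > 0")

    @property
    def n_frames(self) -> int:
        return self.data.shape[2]

    @property
    def frame_shape(self) -> tuple:
        return self.data.shape[:2]

    def with_data(self, data: np.ndarray) -> "IQMovie":
        """Same acquisition metadata, new array."""
        return IQMovie(
            data=data,
            pixel_pitch_mm=self.pixel_pitch_mm,
            f0_hz=self.f0_hz,
            c_m_s=self.c_m_s,
            prf_c_hz=self.prf_c_hz,
        )


@dataclass(frozen=True)
class VesselSpec:
    """A straight tube of moving blood.

    ``axial_velocity_mm_s`` is signed, positive = descending (away from the
    transducer). ``orientation`` is the tube axis: ``"axial"`` (vertical tube,
    flow along depth), ``"lateral"`` (horizontal tube, flow along x, zero
    Doppler), or a float angle in degrees from the depth axis. ``radius_mm``
    is the tube half-width in the imaging plane.
    """

    center_mm: tuple
    radius_mm: float
    axial_velocity_mm_s: float
    scatterer_density_per_mm2: float = 20.0
    orientation: object = "axial"
    length_mm: float | None = None
    profile: str = "plug"

    def __post_init__(self) -> None:
        if self.radius_mm <= 0:
            raise ValueError("radius_mm must be > 0")
        if self.scatterer_density_per_mm2 <= 0:
            raise ValueError("scatterer_density_per_mm2 must be > 0")
        if self.profile not in ("plug", "parabolic"):
            raise ValueError("profile must be 'plug' or 'parabolic'")

    @property
    def axis_angle_deg(self) -> float:
        """Tube-axis angle from the depth axis, degrees."""
        if self.orientation == "axial":
            return 0.0
        if self.orientation == "lateral":
            return 90.0
        return float(self.orientation)


@dataclass(frozen=True)
class ClutterSpec:
    """Low-rank tissue-clutter model.

    ``amplitude_ratio`` is the linear clutter-to-blood RMS amplitude ratio
    (use :meth:`from_db` for dB), ``n_modes`` the number of spatial/temporal
    mode pairs (the clutter rank before noise), ``mode_bandwidth_hz`` the
    one-sided bandwidth of the temporal envelopes.
    """

    amplitude_ratio: float = 10 ** (30 / 20)
    n_modes: int = 10
    mode_bandwidth_hz: float = 65.0

    def __post_init__(self) -> None:
        if self.amplitude_ratio < 0:
            raise ValueError("amplitude_ratio must be >= 0")
        if self.n_modes < 1:
            raise ValueError("n_modes must be >= 1")

    @classmethod
    def from_db(cls, db: float, **kwargs) -> "ClutterSpec":
        return cls(amplitude_ratio=10 ** (db / 20), **kwargs)


@dataclass
class ChromophorePhantom:
    """Ground-truth chromophore concentration maps (arbitrary units).

    ``maps`` holds 2-D non-negative arrays keyed by chromophore name
    ('HbO', 'HbD', 'ICG'). ``fluence_decay_per_mm`` is the effective
    exponential attenuation of the optical fluence with depth (wavelength
    independent, mirroring the absence of fluence correction downstream).
    """

    maps: dict
    fluence_decay_per_mm: float = 0.0
    noise_sigma: float = 0.0
    pixel_pitch_mm: float = 0.1

    def __post_init__(self) -> None:
        shapes = {np.asarray(m).shape for m in self.maps.values()}
        if len(shapes) != 1:
            raise ValueError("all concentration maps must share one shape")
        if any(np.any(np.asarray(m) < 0) for m in self.maps.values()):
            raise ValueError("concentrations must be non-negative")
        if self.fluence_decay_per_mm < 0:
            raise ValueError("fluence_decay_per_mm must be >= 0")

    @property
    def shape(self) -> tuple:
        return next(iter(self.maps.values())).shape

    def fluence(self) -> np.ndarray:
        """Depth-dependent fluence factor exp(-mu_eff * depth), per pixel."""
        nz, nx = self.shape
        depth_mm = np.arange(nz)[:, None] * self.pixel_pitch_mm
        return np.exp(-self.fluence_decay_per_mm * depth_mm) * np.ones((nz, nx))


@dataclass
class PAStack:
    """Per-wavelength photoacoustic amplitude images, repeated over sets.

    ``images`` has shape (n_sets, n_wavelengths, depth, lateral);
    ``pulse_energies_mj`` is one energy per wavelength.
    """

    images: np.ndarray
    wavelengths_nm: tuple
    pulse_energies_mj: tuple
    pixel_pitch_mm: float = 0.1

    def __post_init__(self) -> None:
        self.images = np.asarray(self.images, dtype=float)
        if self.images.ndim != 4:
            raise ValueError("images must be (n_sets, n_wavelengths, z, x)")
        if self.images.shape[1] != len(self.wavelengths_nm):
            raise ValueError("one image per wavelength per set required")
        if len(self.pulse_energies_mj) != len(self.wavelengths_nm):
            raise ValueError("one pulse energy per wavelength required")
        if any(e <= 0 for e in self.pulse_energies_mj):
            raise ValueError("pulse energies must be > 0")

    @property
    def n_sets(self) -> int:
        return self.images.shape[0]


def doppler_frequency_hz(v_mm_s, f0_hz: float, c_m_s: float):
    """Signed pulse-echo Doppler shift of the IQ phasor.

    Positive axial velocity (descending, away from the transducer) lengthens
    the echo path every frame, so the phasor rotates negatively:
    f_d = -2 f0 v_z / c.
    """
    return -2.0 * f0_hz * (np.asarray(v_mm_s, dtype=float) * 1e-3) / c_m_s


def _deposit_gaussians(frame, pos_z, pos_x, amplitudes, sigma_px):
    """Add Gaussian blobs at continuous positions onto ``frame`` in place."""
    nz, nx = frame.shape
    r = max(1, int(np.ceil(3 * sigma_px)))
    offs = np.arange(-r, r + 1)
    dz, dx = np.meshgrid(offs, offs, indexing="ij")
    for z0, x0, a in zip(pos_z, pos_x, amplitudes):
        iz = int(round(z0))
        ix = int(round(x0))
        zz = iz + dz
        xx = ix + dx
        w = np.exp(-(((zz - z0) ** 2 + (xx - x0) ** 2) / (2 * sigma_px**2)))
        ok = (zz >= 0) & (zz < nz) & (xx >= 0) & (xx < nx)
        np.add.at(frame, (zz[ok], xx[ok]), a * w[ok])


def _vessel_support(vessel: VesselSpec, shape, pitch_mm: float) -> np.ndarray:
    """Boolean in-plane support of a tube: a band of half-width radius around
    the axis line through ``center_mm``, clipped to ``length_mm`` if given."""
    nz, nx = shape
    z = np.arange(nz)[:, None] * pitch_mm
    x = np.arange(nx)[None, :] * pitch_mm
    z0, x0 = vessel.center_mm
    theta = np.deg2rad(vessel.axis_angle_deg)
    axis = np.array([np.cos(theta), np.sin(theta)])  # (dz, dx) unit vector
    dz = z - z0
    dx = x - x0
    along = dz * axis[0] + dx * axis[1]
    across = -dz * axis[1] + dx * axis[0]
    support = np.abs(across) <= vessel.radius_mm
    if vessel.length_mm is not None:
        support &= np.abs(along) <= vessel.length_mm / 2.0
    return support


def simulate_iq_movie(
    vessels,
    clutter: ClutterSpec | None,
    movie_shape,
    *,
    pixel_pitch_mm: float = 0.1,
    f0_hz: float = 15e6,
    c_m_s: float = 1540.0,
    prf_c_hz: float = 1e6 / 525.0,
    noise_sigma: float = 0.0,
    blood_amplitude: float = 1.0,
    psf_sigma_px: float = 1.0,
    seed=None,
):
    """Simulate a compounded IQ ensemble with known ground truth.

    Blood is realized as discrete scatterers with circular complex Gaussian
    amplitudes, advected along the tube axis (wrapping at the ends) and
    deposited through a Gaussian point-spread function; every scatterer's
    phasor advances by the pulse-echo Doppler shift of its vessel each frame,
    so in-vessel pixels carry slow-time phasors at f_d = -2 f0 v_z / c with
    natural transit-time broadening. Clutter is an exact sum of ``n_modes``
    smooth spatial patterns times band-limited temporal envelopes (rank <=
    n_modes before noise), scaled so its FOV RMS amplitude is
    ``amplitude_ratio`` times the in-vessel blood RMS. Thermal noise is
    circular complex Gaussian with total std ``noise_sigma``.

    Returns
    -------
    (IQMovie, dict)
        The movie and a ground-truth dict with keys ``velocity_map`` (signed
        mm/s, + descending), ``doppler_hz`` (signed shift), ``support``
        (blood mask), ``aliased`` (True if any |f_d| > prf_c/2), and the
        separate ``blood`` / ``clutter`` component arrays.
    """
    rng = np.random.default_rng(seed)
    nz, nx, nt = movie_shape
    shape2d = (nz, nx)
    fov_z = nz * pixel_pitch_mm
    fov_x = nx * pixel_pitch_mm

    blood = np.zeros((nz, nx, nt), dtype=complex)
    velocity_map = np.zeros(shape2d)
    support = np.zeros(shape2d, dtype=bool)
    aliased = False

    for vessel in vessels:
        z0, x0 = vessel.center_mm
        if not (0 <= z0 <= fov_z and 0 <= x0 <= fov_x):
            raise ValueError(f"vessel center {vessel.center_mm} outside field of view")
        theta = np.deg2rad(vessel.axis_angle_deg)
        axis = np.array([np.cos(theta), np.sin(theta)])
        # axis extent: clip the tube to the FOV along its axis
        if vessel.length_mm is not None:
            half_len = vessel.length_mm / 2.0
        else:
            half_len = 0.5 * np.hypot(fov_z, fov_x)
        sup = _vessel_support(vessel, shape2d, pixel_pitch_mm)
        support |= sup
        v_axis = vessel.axial_velocity_mm_s  # centerline speed along the tube axis

        # per-pixel ground truth: axial (depth) velocity component
        z_grid = np.arange(nz)[:, None] * pixel_pitch_mm
        x_grid = np.arange(nx)[None, :] * pixel_pitch_mm
        across_px = -(z_grid - z0) * axis[1] + (x_grid - x0) * axis[0]
        if vessel.profile == "parabolic":
            v_profile = v_axis * (1.0 - (across_px / vessel.radius_mm) ** 2)
        else:
            v_profile = np.full((nz, nx), v_axis)
        velocity_map[sup] = (v_profile * axis[0])[sup]
        f_d_peak = doppler_frequency_hz(v_axis * axis[0], f0_hz, c_m_s)
        if abs(f_d_peak) > prf_c_hz / 2.0:
            aliased = True

        area = 2 * vessel.radius_mm * 2 * half_len
        n_scatt = max(1, int(round(vessel.scatterer_density_per_mm2 * area)))
        along = rng.uniform(-half_len, half_len, n_scatt)
        across = rng.uniform(-vessel.radius_mm, vessel.radius_mm, n_scatt)
        if vessel.profile == "parabolic":
            speeds = v_axis * (1.0 - (across / vessel.radius_mm) ** 2)
        else:
            speeds = np.full(n_scatt, v_axis)
        amp = (rng.normal(size=n_scatt) + 1j * rng.normal(size=n_scatt)) / np.sqrt(2)
        dt = 1.0 / prf_c_hz
        f_d_s = doppler_frequency_hz(speeds * axis[0], f0_hz, c_m_s)
        phase_step = np.exp(2j * np.pi * f_d_s * dt)
        vessel_block = np.zeros((nz, nx, nt), dtype=complex)
        for t in range(nt):
            pos_along = ((along + speeds * t * dt + half_len) % (2 * half_len)) - half_len
            z_mm = z0 + pos_along * axis[0] - across * axis[1]
            x_mm = x0 + pos_along * axis[1] + across * axis[0]
            _deposit_gaussians(
                vessel_block[:, :, t],
                z_mm / pixel_pitch_mm,
                x_mm / pixel_pitch_mm,
                amp * (phase_step**t),
                psf_sigma_px,
            )
        # normalize so a vessel at the reference density (20 / mm^2) has
        # in-vessel RMS amplitude = blood_amplitude; power then scales
        # linearly with scatterer density, as for incoherent blood speckle
        rms = np.sqrt(np.mean(np.abs(vessel_block[sup]) ** 2))
        if rms > 0:
            target = blood_amplitude * np.sqrt(vessel.scatterer_density_per_mm2 / 20.0)
            vessel_block *= target / rms
        blood += vessel_block

    blood_ref = blood_amplitude

    clutter_arr = np.zeros((nz, nx, nt), dtype=complex)
    if clutter is not None and clutter.amplitude_ratio > 0:
        freqs = np.fft.fftfreq(nt, d=1.0 / prf_c_hz)
        keep = np.abs(freqs) <= clutter.mode_bandwidth_hz
        # Mode energies decay geometrically but stay clustered, mirroring the
        # in vivo situation where every tissue-motion component sits far above
        # blood (that is what makes a fixed rejection count work); a steeper
        # decay or random mode energies would let the weakest clutter modes
        # approach the blood singular values, and the rejected subspace would
        # then mix measurably with the blood.
        weights = 0.9 ** np.arange(clutter.n_modes)
        weights /= np.sqrt(np.sum(weights**2))
        for k in range(clutter.n_modes):
            spatial = ndimage.gaussian_filter(
                rng.normal(size=shape2d), 6.0
            ) + 1j * ndimage.gaussian_filter(rng.normal(size=shape2d), 6.0)
            spec = np.zeros(nt, dtype=complex)
            coeffs = rng.normal(size=keep.sum()) + 1j * rng.normal(size=keep.sum())
            spec[keep] = coeffs
            spec[0] += 3.0 * np.sqrt(max(keep.sum(), 1))  # strong quasi-DC part
            envelope = np.fft.ifft(spec) * nt
            mode = spatial[:, :, None] * envelope[None, None, :]
            norm = np.linalg.norm(mode)
            if norm > 0:
                clutter_arr += (weights[k] / norm) * mode
        rms = np.sqrt(np.mean(np.abs(clutter_arr) ** 2))
        if rms > 0:
            clutter_arr *= clutter.amplitude_ratio * blood_ref / rms

    movie = blood + clutter_arr
    if noise_sigma > 0:
        movie = movie + (
            rng.normal(scale=noise_sigma / np.sqrt(2), size=movie.shape)
            + 1j * rng.normal(scale=noise_sigma / np.sqrt(2), size=movie.shape)
        )

    truth = {
        "velocity_map": velocity_map,
        "doppler_hz": doppler_frequency_hz(velocity_map, f0_hz, c_m_s),
        "support": support,
        "aliased": aliased,
        "blood": blood,
        "clutter": clutter_arr,
    }
    iq = IQMovie(
        data=movie,
        pixel_pitch_mm=pixel_pitch_mm,
        f0_hz=f0_hz,
        c_m_s=c_m_s,
        prf_c_hz=prf_c_hz,
    )
    return iq, truth


def straight_track(start_zx, velocity_px_per_frame, n_frames, start_frame=0):
    """Ground-truth track: (n_frames, 3) array of (frame, z, x), constant step."""
    t = np.arange(n_frames)
    z = start_zx[0] + velocity_px_per_frame[0] * t
    x = start_zx[1] + velocity_px_per_frame[1] * t
    return np.column_stack([t + start_frame, z, x]).astype(float)


def simulate_mb_movie(
    tracks,
    psf_sigma_px: float,
    frame_shape,
    n_frames: int,
    *,
    noise_sigma: float = 0.0,
    amplitude: float = 1.0,
    seed=None,
):
    """Render microbubble tracks into an amplitude movie.

    ``tracks`` is a list of (n, 3) arrays of (frame index, z, x) in continuous
    pixel units. Each frame is the sum of isotropic Gaussian PSFs at the
    tracks' positions plus white Gaussian noise.

    Returns (frames, truth_tracks) where ``frames`` has shape
    (n_frames, depth, lateral).
    """
    if psf_sigma_px <= 0:
        raise ValueError("psf_sigma_px must be > 0")
    nz, nx = frame_shape
    rng = np.random.default_rng(seed)
    frames = np.zeros((n_frames, nz, nx))
    for track in tracks:
        track = np.asarray(track, dtype=float)
        for f, z, x in track:
            fi = int(round(f))
            if not (0 <= fi < n_frames):
                continue
            if not (0 <= z < nz and 0 <= x < nx):
                raise ValueError(f"track position ({z}, {x}) outside frame bounds")
            _deposit_gaussians(frames[fi], [z], [x], [amplitude], psf_sigma_px)
    if noise_sigma > 0:
        frames = frames + rng.normal(scale=noise_sigma, size=frames.shape)
    return frames, [np.asarray(t, dtype=float).copy() for t in tracks]


def simulate_mspa_stack(
    phantom: ChromophorePhantom,
    wavelengths_nm=(750.0, 800.0, 850.0),
    pulse_energies_mj=(1.0, 1.0, 1.0),
    n_sets: int = 5,
    seed=None,
    extinction_table=None,
) -> PAStack:
    """Forward photoacoustic model: amplitude = E_lambda * fluence(z) * sum_k
    eps_k(lambda) c_k, replicated over ``n_sets`` with independent noise."""
    from .unmixing import default_extinction_table

    table = extinction_table if extinction_table is not None else default_extinction_table()
    rng = np.random.default_rng(seed)
    fluence = phantom.fluence()
    clean = []
    for wl, energy in zip(wavelengths_nm, pulse_energies_mj):
        img = np.zeros(phantom.shape)
        for name, conc in phantom.maps.items():
            img += table.epsilon(name, wl) * np.asarray(conc, dtype=float)
        clean.append(energy * fluence * img)
    clean = np.stack(clean)  # (n_wl, z, x)
    images = np.stack(
        [
            clean + rng.normal(scale=phantom.noise_sigma, size=clean.shape)
            if phantom.noise_sigma > 0
            else clean.copy()
            for _ in range(n_sets)
        ]
    )
    return PAStack(
        images=images,
        wavelengths_nm=tuple(wavelengths_nm),
        pulse_energies_mj=tuple(pulse_energies_mj),
        pixel_pitch_mm=phantom.pixel_pitch_mm,
    )


def make_tube_phantom_scene(
    so2_level: float,
    icg_concentration: float = 1.0,
    flow_speed_mm_s: float = 10.0,
    *,
    shape=(128, 128),
    pixel_pitch_mm: float = 0.1,
    tube_radius_mm: float = 0.785,
    total_hb: float = 1.0,
    fluence_decay_per_mm: float = 0.0,
    noise_sigma: float = 0.0,
):
    """Two-tube validation scene: flowing blood on the left, static ICG on the
    right (tube inner radius 0.785 mm as in the physical phantom).

    The left tube carries blood with HbO/HbD split by ``so2_level`` and flows
    at ``flow_speed_mm_s`` (positive = descending); the right tube holds a
    static ICG solution. Returns (vessel list, ChromophorePhantom) on a
    shared geometry so the UFUS and MSPA chains see a consistent scene.
    """
    if not 0.0 <= so2_level <= 1.0:
        raise ValueError("so2_level must be in [0, 1]")
    nz, nx = shape
    fov_z = nz * pixel_pitch_mm
    fov_x = nx * pixel_pitch_mm
    left_x = fov_x / 3.0
    right_x = 2.0 * fov_x / 3.0
    center_z = fov_z / 2.0

    blood_tube = VesselSpec(
        center_mm=(center_z, left_x),
        radius_mm=tube_radius_mm,
        axial_velocity_mm_s=flow_speed_mm_s,
        orientation="axial",
    )
    sup_left = _vessel_support(blood_tube, shape, pixel_pitch_mm)
    icg_tube = VesselSpec(
        center_mm=(center_z, right_x),
        radius_mm=tube_radius_mm,
        axial_velocity_mm_s=0.0,
        orientation="axial",
    )
    sup_right = _vessel_support(icg_tube, shape, pixel_pitch_mm)

    hbo = np.where(sup_left, so2_level * total_hb, 0.0)
    hbd = np.where(sup_left, (1.0 - so2_level) * total_hb, 0.0)
    icg = np.where(sup_right, icg_concentration, 0.0)
    phantom = ChromophorePhantom(
        maps={"HbO": hbo, "HbD": hbd, "ICG": icg},
        fluence_decay_per_mm=fluence_decay_per_mm,
        noise_sigma=noise_sigma,
        pixel_pitch_mm=pixel_pitch_mm,
    )
    return [blood_tube], phantom
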