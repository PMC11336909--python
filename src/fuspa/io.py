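"""HDF5 dataset container, map export, configuration, and pipeline driver.

One container format carries every stage's data so the acquisition metadata
(f0, compounded PRF, pixel pitch) always travels with the arrays: groups
``/iq`` (complex movie + metadata), ``/pa`` (stack + wavelengths + energies),
``/maps`` (named 2-D outputs), ``/truth`` (simulation ground truth) and
``/meta`` (config snapshot, seed, package version). Axis order is
(depth, lateral, slow-time) for movies and (depth, lateral) for maps.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import tifffile
import yaml

__all__ = [
    "SchemaError",
    "DatasetContainer",
    "write_container",
    "read_container",
    "export_map",
    "load_config",
    "run_pipeline",
]

_IQ_REQUIRED_ATTRS = ("f0_hz", "prf_c_hz", "pixel_pitch_mm", "c_m_s")


class SchemaError(ValueError):
    """A container is missing required structure or metadata."""


@dataclass
class DatasetContainer:
    """In-memory view of one dataset container."""

    iq: object = None  # IQMovie or None
    pa: object = None  # PAStack or None
    maps: dict = field(default_factory=dict)
    truth: dict = field(default_factory=dict)
    meta: dict = field(default_factory=dict)


def _package_version() -> str:
    from . import __version__

    return __version__


def write_container(container: DatasetContainer, path) -> None:
    """Write a container; arrays round-trip losslessly and every write is
    stamped with the package version."""
    from .synth import IQMovie, PAStack

    path = Path(path)
    with h5py.File(path, "w") as f:
        f.attrs["fuspa_version"] = _package_version()
        if container.iq is not None:
            iq: IQMovie = container.iq
            g = f.create_group("iq")
            d = g.create_dataset("data", data=iq.data)
            d.attrs["axes"] = "depth,lateral,slow_time"
            d.attrs["units"] = "arbitrary complex amplitude"
            g.attrs["f0_hz"] = iq.f0_hz
            g.attrs["prf_c_hz"] = iq.prf_c_hz
            g.attrs["pixel_pitch_mm"] = iq.pixel_pitch_mm
            g.attrs["c_m_s"] = iq.c_m_s
        if container.pa is not None:
            pa: PAStack = container.pa
            g = f.create_group("pa")
            d = g.create_dataset("images", data=pa.images)
            d.attrs["axes"] = "set,wavelength,depth,lateral"
            d.attrs["units"] = "arbitrary PA amplitude"
            g.create_dataset("wavelengths_nm", data=np.asarray(pa.wavelengths_nm))
            g.create_dataset("pulse_energies_mj", data=np.asarray(pa.pulse_energies_mj))
            g.attrs["pixel_pitch_mm"] = pa.pixel_pitch_mm
        for group_name, payload in (("maps", container.maps), ("truth", container.truth)):
            g = f.create_group(group_name)
            for name, arr in payload.items():
                arr = np.asarray(arr)
                d = g.create_dataset(name, data=arr)
                d.attrs["axes"] = "depth,lateral" if arr.ndim == 2 else "unspecified"
        g = f.create_group("meta")
        for key, value in container.meta.items():
            g.attrs[key] = json.dumps(value) if isinstance(value, (dict, list)) else value


def read_container(path) -> DatasetContainer:
    """Read a container back; missing required IQ metadata raises
    :class:`SchemaError` naming the field."""
    from .synth import IQMovie, PAStack

    out = DatasetContainer()
    with h5py.File(path, "r") as f:
        if "iq" in f:
            g = f["iq"]
            for attr in _IQ_REQUIRED_ATTRS:
                if attr not in g.attrs:
                    raise SchemaError(f"/iq is missing required metadata {attr!r}")
            out.iq = IQMovie(
                data=g["data"][()],
                f0_hz=float(g.attrs["f0_hz"]),
                prf_c_hz=float(g.attrs["prf_c_hz"]),
                pixel_pitch_mm=float(g.attrs["pixel_pitch_mm"]),
                c_m_s=float(g.attrs["c_m_s"]),
            )
        if "pa" in f:
            g = f["pa"]
            out.pa = PAStack(
                images=g["images"][()],
                wavelengths_nm=tuple(g["wavelengths_nm"][()]),
                pulse_energies_mj=tuple(g["pulse_energies_mj"][()]),
                pixel_pitch_mm=float(g.attrs.get("pixel_pitch_mm", 0.1)),
            )
        for group_name, target in (("maps", out.maps), ("truth", out.truth)):
            if group_name in f:
                for name, ds in f[group_name].items():
                    target[name] = ds[()]
        if "meta" in f:
            for key, value in f["meta"].attrs.items():
                if isinstance(value, str) and value[:1] in "[{":
                    try:
                        value = json.loads(value)
                    except json.JSONDecodeError:
                        pass
                out.meta[key] = value
        out.meta.setdefault("fuspa_version", f.attrs.get("fuspa_version"))
    return out


def export_map(map2d: np.ndarray, path, fmt: str = "tiff",
               db_floor: float = -60.0) -> None:
    """Export a 2-D map.

    ``fmt`` is one of ``tiff`` (32-bit float, lossless), ``png`` (8-bit after
    dB compression referenced to the map maximum, clipped at ``db_floor``),
    or ``csv`` (one row per pixel with z/x indices).
    """
    import imageio.v3 as iio

    arr = np.asarray(map2d, dtype=float)
    if arr.ndim != 2:
        raise ValueError("export_map requires a 2-D map")
    if np.all(np.isnan(arr)):
        raise ValueError("map contains only NaN")
    path = Path(path)
    if fmt == "tiff":
        tifffile.imwrite(path, arr.astype(np.float32))
    elif fmt == "png":
        mags = np.abs(np.nan_to_num(arr))
        peak = mags.max()
        if peak <= 0:
            db = np.full(arr.shape, db_floor)
        else:
            db = 10.0 * np.log10(np.maximum(mags, peak * 10 ** (db_floor / 10.0)) / peak)
        scaled = (np.clip((db - db_floor) / -db_floor, 0, 1) * 255).astype(np.uint8)
        iio.imwrite(path, scaled)
    elif fmt == "csv":
        nz, nx = arr.shape
        zz, xx = np.meshgrid(np.arange(nz), np.arange(nx), indexing="ij")
        pd.DataFrame(
            {"z": zz.ravel(), "x": xx.ravel(), "value": arr.ravel()}
        ).to_csv(path, index=False)
    else:
        raise ValueError(f"unknown export format {fmt!r}")


DEFAULT_CONFIG = {
    "seed": 0,
    "scene": {
        "kind": "tube_phantom",
        "so2_level": 0.9,
        "icg_concentration": 1.0,
        "flow_speed_mm_s": 10.0,
        "shape": [96, 96],
        "pixel_pitch_mm": 0.1,
        "noise_sigma": 0.001,
    },
    "acquisition": {
        "n_compound_frames": 150,
        "inter_angle_interval_us": 75,
        "n_angles": 7,
        "f0_hz": 15.0e6,
        "c_m_s": 1540.0,
    },
    "clutter": {"db_above_blood": 30.0, "n_modes": 10, "mode_bandwidth_hz": 15.0},
    "cbv": {"n_reject": 9},
    "cbf": {"svd_n_reject": 10, "highpass_cutoff_hz": 70.0},
    "mspa": {
        "wavelengths_nm": [750.0, 800.0, 850.0],
        "pulse_energies_mj": [1.0, 1.0, 1.0],
        "n_sets": 5,
        "pa_noise_sigma": 0.0,
    },
}


def load_config(path=None) -> dict:
    """Load a YAML config, filling unspecified sections from the defaults."""
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    if path is not None:
        with open(path) as f:
            user = yaml.safe_load(f) or {}
        for key, value in user.items():
            if isinstance(value, dict) and isinstance(cfg.get(key), dict):
                cfg[key].update(value)
            else:
                cfg[key] = value
    return cfg


def run_pipeline(config: dict | None = None, out_dir=None, seed=None) -> DatasetContainer:
    """End-to-end demo pipeline on the bundled tube-phantom scene:
    simulate -> clutter filter -> CBV -> CBF -> MSPA unmix -> SO2.

    Validates the stage parameters against the scene before running (e.g. a
    rejection count not smaller than the ensemble length fails early). With a
    fixed seed the output maps are deterministic. If ``out_dir`` is given the
    container and TIFF maps are written there.
    """
    from .clutter import FilterConfig, svd_clutter_filter
    from .power_doppler import power_doppler_map
    from .synth import ClutterSpec, make_tube_phantom_scene, simulate_iq_movie, simulate_mspa_stack
    from .unmixing import (
        average_wavelength_sets,
        build_system_matrix,
        compute_so2,
        default_extinction_table,
        unmix_stack,
    )
    from .velocimetry import VelocimetryConfig, cbf_pipeline

    cfg = json.loads(json.dumps(config if config is not None else DEFAULT_CONFIG))
    if seed is not None:
        cfg["seed"] = int(seed)
    acq = cfg["acquisition"]
    n_frames = int(acq["n_compound_frames"])
    for key in ("n_reject",):
        if int(cfg["cbv"][key]) >= n_frames:
            raise SchemaError(
                f"cbv.{key}={cfg['cbv'][key]} must be smaller than the "
                f"{n_frames}-frame ensemble"
            )
    if int(cfg["cbf"]["svd_n_reject"]) >= n_frames:
        raise SchemaError("cbf.svd_n_reject must be smaller than the ensemble length")

    scene = cfg["scene"]
    if scene["kind"] != "tube_phantom":
        raise SchemaError(f"unknown scene kind {scene['kind']!r}")
    vessels, phantom = make_tube_phantom_scene(
        so2_level=float(scene["so2_level"]),
        icg_concentration=float(scene["icg_concentration"]),
        flow_speed_mm_s=float(scene["flow_speed_mm_s"]),
        shape=tuple(scene["shape"]),
        pixel_pitch_mm=float(scene["pixel_pitch_mm"]),
        noise_sigma=float(cfg["mspa"]["pa_noise_sigma"]),
    )
    prf_c = 1e6 / (int(acq["n_angles"]) * int(acq["inter_angle_interval_us"]))
    base_seed = int(cfg["seed"])
    movie, truth = simulate_iq_movie(
        vessels,
        ClutterSpec.from_db(
            float(cfg["clutter"]["db_above_blood"]),
            n_modes=int(cfg["clutter"]["n_modes"]),
            mode_bandwidth_hz=float(cfg["clutter"]["mode_bandwidth_hz"]),
        ),
        (*scene["shape"], n_frames),
        pixel_pitch_mm=float(scene["pixel_pitch_mm"]),
        f0_hz=float(acq["f0_hz"]),
        c_m_s=float(acq["c_m_s"]),
        prf_c_hz=prf_c,
        noise_sigma=float(scene["noise_sigma"]),
        seed=base_seed,
    )

    filtered, _ = svd_clutter_filter(movie, FilterConfig(n_reject=int(cfg["cbv"]["n_reject"])))
    cbv = power_doppler_map(filtered)
    vmap = cbf_pipeline(
        movie,
        VelocimetryConfig(
            svd_n_reject=int(cfg["cbf"]["svd_n_reject"]),
            highpass_cutoff_hz=float(cfg["cbf"]["highpass_cutoff_hz"]),
        ),
    )

    mspa = cfg["mspa"]
    stack = simulate_mspa_stack(
        phantom,
        wavelengths_nm=tuple(mspa["wavelengths_nm"]),
        pulse_energies_mj=tuple(mspa["pulse_energies_mj"]),
        n_sets=int(mspa["n_sets"]),
        seed=base_seed + 1,
    )
    averaged = average_wavelength_sets(stack)
    e = build_system_matrix(
        default_extinction_table(), stack.wavelengths_nm, stack.pulse_energies_mj
    )
    conc = unmix_stack(averaged, e)
    so2 = compute_so2(conc)

    container = DatasetContainer(
        iq=movie,
        pa=stack,
        maps={
            "cbv_intensity": cbv.intensity,
            "cbv_db": cbv.intensity_db,
            "cbf_signed_mm_s": vmap.v_signed,
            "cbf_descending_mm_s": vmap.v_descending,
            "cbf_ascending_mm_s": vmap.v_ascending,
            "so2": so2.so2,
            "hbo": conc.HbO,
            "hbd": conc.HbD,
            "icg": conc.ICG,
        },
        truth={
            "velocity_map": truth["velocity_map"],
            "support": truth["support"].astype(np.uint8),
            "so2_level": np.asarray(float(scene["so2_level"])),
        },
        meta={"config": cfg, "seed": base_seed, "fuspa_version": _package_version()},
    )
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_container(container, out_dir / "dataset.h5")
        for name in ("cbv_intensity", "cbf_signed_mm_s", "so2"):
            export_map(container.maps[name], out_dir / f"{name}.tiff", "tiff")
    return container
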