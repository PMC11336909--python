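# fuspa

Processing chain for combined ultrafast-ultrasound (UFUS) and multispectral
photoacoustic (MSPA) brain hemodynamics imaging — the software side of a
head-mounted imaging platform that interleaves plane-wave Doppler ensembles
with multi-wavelength photoacoustic frames to map cerebral blood volume
(CBV), cerebral blood flow (CBF), and oxygen saturation (SO₂) at
single-vessel resolution, plus contrast-agent imaging (ICG perfusion,
microbubble super-resolution).

It is written for researchers who have beamformed, angle-compounded complex
IQ movies and per-wavelength photoacoustic stacks and need the downstream
functional maps and analyses, and it ships a physics-informed synthetic-data
generator so the entire chain is testable with known ground truth.

## What it computes

* **Clutter filtering** — the IQ movie is reshaped to a Casorati matrix
  (space × slow time) and the leading singular components are rejected
  (9 for the CBV path, 10 for the CBF path), followed by a zero-phase
  4th-order 70 Hz Butterworth wall filter along slow time.
* **CBV (power Doppler)** — I(z,x) = (1/N) Σ_t |IQ(z,x,t)|², proportional to
  the moving blood volume fraction.
* **CBF (directional velocimetry)** — the slow-time spectrum is split at
  0 Hz; each component's axial velocity follows from the lag-1
  autocorrelation phase (Kasai): f_d = PRF_c·arg R(1)/2π and
  v_z = c·f_d/(2 f₀). A component is valid where it holds > 0.2 (positive) /
  > 0.25 (negative) of the spectral power and |R(1)|/R(0) > 0.2. Descending
  flow (away from the transducer) carries the negative Doppler shift and is
  rendered red by convention.
* **SO₂ and ICG (spectral unmixing)** — per pixel, non-negative least
  squares on the energy-normalized extinction matrix of {HbO, HbD, ICG} at
  750/800/850 nm; SO₂ = HbO/(HbO + HbD) where hemoglobin signal exists;
  ICG maps reduce to ROI time-activity curves.
* **ULM (localization microscopy)** — sub-pixel microbubble localization
  (weighted log-quadratic fit), minimum-cost frame-to-frame linking
  (Hungarian algorithm), and accumulation of tracks into 10 µm density,
  direction, and mean-speed maps.
* **Hemodynamic analysis** — relative changes
  r(t) = (x(t) − mean of first 10 frames)/mean × 100% (the same formula for
  rCBV, rCBF, rSO₂), ROI statistics under a baseline/stimulus/post paradigm,
  and lagged Pearson cross-correlation between a reference region and
  voxels or a second ROI (e.g. cortex vs. draining vein).
* **Acquisition timing** — exact integer-microsecond schedules of the
  interleaved sequences (525 µs compounded frames, 78.75 ms ensembles,
  1.6 s MSPA blocks, ≈3.3 s combined frames, 560 ms ULM sequences).

See `docs/methods.md` for models, assumptions, and numerical choices.

## Worked example

Run the bundled tube-phantom scene (flowing blood at a prescribed SO₂ on the
left, static ICG on the right) end to end — simulate, clutter-filter,
CBV, CBF, unmix:

```python
import numpy as np
from fuspa.io import load_config, run_pipeline

cfg = load_config()
cfg["scene"].update({"shape": [64, 64], "so2_level": 0.8, "flow_speed_mm_s": 10.0})
c = run_pipeline(cfg, seed=1)

sup = c.truth["support"].astype(bool)  # blood-tube pixels
print(f"SO2 in blood tube: {np.nanmean(c.maps['so2'][sup]):.3f} (truth 0.800)")
print(f"median axial velocity in tube: "
      f"{np.median(c.maps['cbf_signed_mm_s'][sup]):+.2f} mm/s (truth +10.00)")
print(f"CBV contrast tube/background: "
      f"{c.maps['cbv_intensity'][sup].mean()/c.maps['cbv_intensity'][~sup].mean():.0f}x")
```

prints

```
SO2 in blood tube: 0.800 (truth 0.800)
median axial velocity in tube: +10.65 mm/s (truth +10.00)
CBV contrast tube/background: 164x
```

i.e. the unmixer recovers the tube oxygenation exactly at this noise level,
the velocimeter recovers the descending 10 mm/s flow with the correct sign
(the per-pixel median carries a few percent of broadening-induced spread),
and the power-Doppler map isolates the vessel from the static background by
over two orders of magnitude.

The same stages are available from the shell and compose through an HDF5
container that carries the acquisition metadata (f₀, PRF_c, pixel pitch)
with the data:

```bash
fuspa simulate --seed 1 --out scene.h5
fuspa filter --input scene.h5 --output filtered.h5 --n-reject 9
fuspa cbv --input filtered.h5 --out-tiff cbv.tiff --n-reject 0
fuspa cbf --input scene.h5 --out-tiff cbf.tiff
fuspa unmix --input scene.h5 --out-dir maps/
```

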