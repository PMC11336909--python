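# Methods

This note documents the models, estimators, numerical choices, and known
limitations behind the `fuspa` package: a processing chain for interleaved
ultrafast-ultrasound (UFUS) and multispectral photoacoustic (MSPA) brain
imaging, together with the synthetic-data generators used to validate it.

## Conventions

All image arrays are ordered (depth z, lateral x) with depth increasing away
from the transducer; IQ movies add slow time as the last axis, map stacks put
time first. Descending flow (positive axial velocity, away from the
transducer, i.e. into the cortex when imaging through a cranial window)
produces a **negative** Doppler shift of the IQ phasor, f_d = −2 f₀ v_z / c,
as in pulse-echo physics; descending flow is therefore read from the
negative-frequency component of the directional split. Sequence timing is
held in integer microseconds so quantities like the 525 µs compounded-frame
period and the 78.75 ms ensemble window are exact.

## Acquisition timing model

`fuspa.acquisition` plans three deterministic schedules:

* UFUS block: a pass over the plane-wave angle list (default 7 angles,
  75 µs apart) yields one compounded frame per 525 µs (PRF_c ≈ 1904.76 Hz);
  150 frames form one 78.75 ms Doppler ensemble, followed by a configurable
  host-transfer dead time (default 1.1 s — the hardware-bound transfer is
  only known approximately, so it is a parameter rather than a constant).
* MSPA block: frames fire at the laser pulse-repetition rate (10 Hz) while
  the wavelength cycles 750→800→850 nm; 5 sets plus 1 spare frame give
  16 frames in 1.6 s.
* Combined frame: MSPA block + UFUS block + a configurable
  trigger-synchronization slack (default 0.2 s), ≈3.28 s total.
* ULM session: the UFUS sequence with 200 µs inter-angle time and 400 frames
  per sequence (560 ms); accumulation time counts live acquisition only,
  session time adds the ≈2 s inter-sequence transfers.

## Synthetic scenes

The generators produce data at the beamformed, angle-compounded IQ level:
beamforming is vendor-side and upstream of every algorithm here.

**Blood.** Each vessel is a straight tube (band of half-width `radius_mm`
around its axis). Scatterers with circular complex Gaussian amplitudes are
advected along the axis (plug or parabolic/Poiseuille profile, wrapping at
the tube ends) and deposited through an isotropic Gaussian PSF; each
scatterer's phasor advances by its pulse-echo Doppler shift per frame. This
reproduces the Doppler spectrum — including transit-time broadening as
scatterers cross the PSF — without a wave simulation. Per vessel, amplitudes
are normalized so a tube at the reference density (20 scatterers/mm²) has
unit in-vessel RMS; power then scales linearly with scatterer density, as for
incoherent speckle.

**Clutter.** Tissue clutter is an exact sum of `n_modes` smooth random
spatial patterns × band-limited temporal envelopes, so its rank before noise
is exactly `n_modes`. Two choices matter and are deliberate:

* *Envelope bandwidth* (default 65 Hz): a 150-frame ensemble resolves
  12.7 Hz per DFT bin, so a clutter band must span ≈±65 Hz to support ten
  independent temporal modes. A much narrower band silently collapses the
  clutter rank — and a rejection count larger than the actual clutter rank
  consumes blood instead. The default sits just below the 70 Hz wall-filter
  cutoff, which is self-consistent: that cutoff exists to remove the clutter
  band.
* *Mode energies* decay geometrically (0.9^k) rather than randomly, keeping
  every clutter mode far above blood (the weakest mode's singular value is
  still ~17× the largest blood component at the default 30 dB ratio). This
  mirrors the in vivo situation that makes a *fixed* rejection count
  workable at all; a steep or random energy profile lets the weakest clutter
  modes approach the blood singular values, and the rejected subspace then
  mixes measurably with the blood (a seed-dependent velocity bias).

The clutter-to-blood ratio is an RMS amplitude ratio (30 dB default).
Thermal noise is circular complex Gaussian. For estimator-recovery scenes the
noise floor is set 60 dB below blood (the flow-phantom validation regime):
the quantity under test there is estimator bias, and for slow flows the wall
filter attenuates the signal by tens of dB, so a higher floor would measure
the noise rather than the estimator. Threshold/masking behavior under noise
is exercised separately.

**Microbubbles.** Frames are sums of isotropic Gaussian PSFs at the tracks'
continuous positions plus white noise. **MSPA stacks** follow the linear
forward model p_λ = E_λ · e^(−μ_eff·z) · Σ_k ε_k(λ) c_k + noise, replicated
over sets with independent noise. The **tube-phantom scene** builds the
two-tube geometry (flowing blood with a prescribed SO₂ split on the left,
static ICG on the right, 0.785 mm inner radius) on a shared grid for the
UFUS and MSPA chains.

What the generators do *not* emulate: aberration and reverberation clutter,
depth-dependent beam width, nonlinearities, skull effects, wavelength-
dependent fluence, bubble disruption, physiological motion beyond the
low-rank model. Passing recovery tests therefore demonstrates correctness of
the estimators under the stated signal model, not in vivo performance.

## Clutter filtering

The movie is reshaped to a Casorati matrix (space × time) and the leading
`n_reject` singular components are subtracted (9 on the CBV path, 10 on the
CBF path). Subtracting the rank-truncation rather than re-summing kept
components makes the residual energy equal Σ_{i>r} σ_i² to machine precision.
The SVD is economy-size on the thin time dimension (150–400 ≪ space).

A note on rejection counts: over rank-r clutter, n_reject > r necessarily
consumes the strongest (n_reject − r) blood components. For temporally
coherent flow (plug profile — essentially a rank-1 tone) this can erase the
vessel entirely. The filter is validated in two regimes: rejection matched to
the clutter rank (blood preserved within 1%), and the published operating
point (n_reject = 10 over rank-10 clutter) inside the full CBF chain.

The 70 Hz wall filter is a 4th-order Butterworth high-pass applied zero-phase
along slow time. It is implemented as the exact forward-backward magnitude
response |H(f)|² applied in the slow-time frequency domain: on a short
ensemble, time-domain `filtfilt` reflection padding injects mirrored
(conjugate-rotation) edge content that measurably biases the downstream
autocorrelation phase (~3–5% at 10 mm/s), while the spectral form is
transient-free and identical in steady state. A tone exactly at the cutoff
keeps 1/4 of its power (two −3 dB passes).

## Velocimetry

After SVD(10) and the wall filter, each pixel's slow-time spectrum is split
at 0 Hz. The DC bin is excluded from both components (the filtered signal
should be DC-free); the Nyquist bin of even-length records is excluded too,
since its rotation sign is ambiguous and assigning it to one side breaks the
exact symmetry between descending and ascending flow. Power fractions are
measured against the total including the excluded bins.

Axial velocity uses the lag-1 autocorrelation (Kasai) phase:
R(1) = Σ_t IQ*(t) IQ(t+1), f_d = PRF_c·arg R(1)/2π, v_z = c·f_d/(2 f₀),
bounded by the Nyquist velocity c·PRF_c/(4 f₀) ≈ 48.9 mm/s at the default
operating point. A multi-lag variant (weighted linear phase fit over lags
1…L) is provided; it matches the lag-1 estimator on pure tones and is not
the default because the literature fit it stands in for is not fully
specified. Validity masks follow the published thresholds: power fraction
> 0.2 (positive side) / > 0.25 (negative side) AND normalized lag-1
autocorrelation |R(1)|/R(0) > 0.2. The signed map takes the larger-magnitude
component where both directions are valid.

**Physical floor.** At f₀ = 15 MHz, 2 mm/s corresponds to a 39 Hz Doppler
shift — inside the wall-filter stopband. The filtered tone retains ~8×10⁻⁵
of its power while its finite-record leakage above 70 Hz retains ~1%, so
leakage dominates by ~100× and both magnitude and direction of sub-cutoff
flow are unrecoverable by construction. Recovery is accurate (<5% median
error, correct signs) from 5 mm/s upward; the 2 mm/s case is reported as a
documented limitation, not an estimator property.

## Power Doppler (CBV)

Per-pixel mean squared magnitude over slow time of the clutter-filtered
movie, with a dB view referenced to the map maximum (−120 dB floor for empty
pixels). No spatial smoothing by default; a Gaussian option exists.

## Spectral unmixing (SO₂, ICG)

The five repeated wavelength sets are averaged (noise ↓ √5), spare frames
dropped. The system matrix holds the molar extinction spectra of HbO, HbD
and ICG at 750/800/850 nm — frozen package constants from the standard
compiled tables (ICG: in-plasma spectrum peaking near 800 nm) — with row λ
scaled by that wavelength's pulse energy against a fixed unit reference.
Absolute (not mutually relative) energy scaling is used so that scaling all
energies and all images together leaves concentrations unchanged; the
per-row behavior (doubling one energy doubles that row) is the same either
way. Per pixel, concentrations solve the non-negative least-squares problem
min‖Ec − p‖₂, c ≥ 0. SO₂ = HbO/(HbO+HbD) where total hemoglobin exceeds a
floor (default 1% of the map maximum; below it the ratio is noise). No
fluence correction is applied; with nonzero μ_eff, concentrations carry a
depth-dependent multiplicative bias that cancels in SO₂ (both chromophores
attenuate together) but not in ICG amplitudes. ICG time-activity curves are
ROI means per frame with a moving-average overlay.

## Ultrasound localization microscopy

Microbubbles are detected as regional maxima above an absolute threshold
(exposed in config; a noise-floor multiple is the sensible setting) and
refined by an intensity-weighted log-quadratic surface fit over a 5×5
neighborhood — exact for a Gaussian PSF in the noiseless limit, ~0.13 px
mean error at 20 dB peak SNR. Frame-to-frame linking minimizes total
Euclidean distance via `scipy.optimize.linear_sum_assignment`; pairs beyond
`max_link_distance` are rejected, unmatched detections seed new tracks, no
gap closing. The minimum track length defaults to 20 frames (the published
minimum-duration figure is not physically realizable within a 560 ms
sequence and is treated as a misprint; the parameter is prominent in
config). Tracks accumulate onto a 10 µm grid: density counts localizations,
direction signs each track by its net depth displacement, and per-bin mean
speed averages the step speeds (displacement × frame rate) touching each
bin.

## Hemodynamic analysis

Relative change r(t) = (x(t) − m)/m × 100% with m the mean of the first 10
frames; the window length is exposed because 10 frames spans ≈33 s at the
combined-frame rate but ≈7 s at the continuous-UFUS rate, while the formula
is the same in both regimes. ROI curves average per-pixel relative changes
(relative change first, then ROI average) and report the across-pixel
population std per frame as the shaded band. Cross-correlation is the
Pearson coefficient at integer frame lags over the truncated overlap window,
both series mean-removed over that window — normalized correlation is used
because reported coefficients lie in [−1, 1], and truncation avoids the
artificial decay of zero padding. Voxels with near-zero variance are masked.
The stimulation paradigm (2 min baseline / 3 min stimulus / 3 min post) is
summarized by window means and the post-onset peak time.

## Problem sizes

Validation scenes are sized for speed while retaining the structure that
matters: velocimetry scenes are 96×64 px × 150 frames (the full published
ensemble length, which sets the spectral resolution that the clutter-rank
and wall-filter effects depend on); unmixing phantoms 32×32 px × 5 sets ×
3 wavelengths; ULM scenes 40×40 px with 30–60 frames per track. Recovery
statistics pool 2–3 seeds per condition.

## Known limitations

* Axial velocity only; no lateral velocity, angle correction, or spectral
  Doppler.
* Sub-cutoff flow (< ≈3.6 mm/s at the default operating point) is removed by
  the wall filter (see above).
* Concentrations are relative (arbitrary units); no fluence inversion, so
  ICG amplitude comparisons across depths are biased when μ_eff > 0.
* The clutter model is a stand-in chosen for controlled rank and band; the
  acquisition hardware chain (beamforming, compounding) is not simulated.
* Vein/artery separation by flow direction is meaningful only where vessels
  run roughly axially (cortical vessels under a cranial window).
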