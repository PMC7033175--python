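# Methods

## Equivalent-circuit forward model

The sensor is modelled as two ideally polarizable gold electrodes (no
charge-transfer resistance) in series with the buffer:
`Z(f) = 2/(jωC_dl) + R_s + Z_p(f)`, where the particle branch is
`Z_p = ΔR ∥ (2/(jωC_m) + R_c)`. The factor 2 on both capacitive terms
reflects the two electrode interfaces and the two membrane crossings in
series. Because the baseline terms cancel in `|Z_with − Z_without|`, the
impedance *change* a transit produces is exactly `|Z_p(f)|`:

* **bead** — membrane branch open (insulating polymer/magnetite), so
  `|ΔZ| = ΔR`, flat in frequency;
* **cell** — `|ΔZ|` falls monotonically from `ΔR` toward `ΔR ∥ R_c` as the
  membrane capacitance shorts; with the defaults below the decline begins
  near 1 MHz and reaches 0.794× the 300 kHz value at 20 MHz;
* **aggregate** — a cell plus n bead volumes: ΔR grows by the volume law,
  membrane parameters stay the cell's.

The occlusion resistance is taken proportional to particle volume
(`ΔR(k·r) = k³·ΔR(r)`), the small-particle Coulter regime.

### Default parameters

No instrument-calibrated values are available for this geometry, so the
defaults are chosen once to be physiologically plausible and to reproduce
the qualitative bead/cell frequency response; they are configuration, not
claims:

| parameter | default | why |
|---|---|---|
| C_dl | 1 nF | µm-scale gold electrodes in PBS |
| R_s | 10 kΩ | PBS conductivity across a 20 µm pore |
| bead ΔR | 100 Ω at r = 1.4 µm | reference occlusion |
| cell ΔR | 800 Ω (2× radius → 8× volume) | volume law |
| C_m | 10 pF | lumped membrane of a ~6 µm cell in series twice |
| R_c | 2 kΩ | cytoplasm resistance of the occluded path |
| grid | 300 kHz, 500 kHz, 1 MHz, 5 MHz, 20 MHz | measurement band |

`R_c` is deliberately of the same order as ΔR: the cytoplasm replaces the
occluded electrolyte path when the membrane shorts, so a value far above ΔR
would make the cell's high-frequency decline invisible (50 kΩ would give a
1.6 % drop), contradicting the observed marked decline and the
lower-than-unity high/low SNR slope of cells. With 2 kΩ the 20 MHz response
is ~79 % of the low-frequency value.

## Synthetic traces

The generator emulates what the lock-in delivers: per-frequency demodulated
amplitude in µV, sampled at 100 kHz for 20 s. Measured peak height is
parameterised *directly* in µV at the 500 kHz reference frequency (the
drive-voltage → µV conversion of the real instrument chain is not
modelled); the circuit model contributes only the relative scaling
`|ΔZ(f)|/|ΔZ(500 kHz)|` per particle kind, so cross-frequency behaviour is
physical while absolute amplitudes match the reported population means.

* **Pulse**: Gaussian bump, σ = pulse_width/4, pulse_width = 1 ms —
  a smooth unimodal transit much shorter than drift timescales. Event times
  are uniform with a 3-pulse-width minimum separation (dilute suspension,
  one particle in the pore at a time) and snapped to the sample grid so
  every channel peaks at the same index.
* **Drift**: 5 µV sinusoid, 30 s period (plus optional linear ramp) —
  a slow baseline wander far below pulse bandwidth.
* **Noise**: additive white Gaussian, σ = 0.3 µV per channel, independent
  across channels (bead SNR ≈ 6.7).
* **Populations** (reference amplitudes, truncated-normal > 0):
  beads 2 µV (CV 0.05 — monodisperse 2.8 µm beads vary by a few % in
  diameter, ≲10 % in volume), doublets 10 µV (CV 0.1), cells 15 µV
  (CV 0.2, biological size spread), aggregates 25 µV (CV 0.3, variable
  bead load), essentially all above the 10 µV rule.
* **Presets**: pure beads = 300 events, 90 % bead / 10 % doublet;
  pure cells = 300 events; mixture = 200 events, 75 % bead / 25 %
  aggregate (capture uses an overabundance of beads, so bare beads
  dominate).

What the generator does **not** emulate: amplitude dependence on the
particle's trajectory through the non-uniform field, pulse-shape asymmetry,
coincidence events, electrode fouling/step drifts, 1/f and mains
interference, or channel-to-channel demodulator delays. Passing tests
therefore validate the *pipeline logic and statistics*, not performance on
any particular instrument's artefacts.

## Signal chain

All filtering uses sym8. The decomposition level is chosen so the coarsest
approximation scale exceeds 50 pulse widths (level 13 at 100 kHz / 1 ms):
the approximation then carries drift (cut-off ≈ 6 Hz) and essentially no
pulse energy, and detrending = zeroing it before reconstruction.

Denoising estimates σ from the finest detail coefficients (MAD/0.6745) and
applies the universal threshold σ√(2 ln N) with **hard** thresholding to
the **four finest detail levels** only. Two deliberate choices:

* *hard, not soft*: soft thresholding shrinks every retained coefficient by
  the threshold (≈ 1.6 µV here) and biased 2 µV pulse amplitudes low by
  tens of percent in calibration on synthetic traces;
* *fine levels only*: white noise puts 94 % of its variance in the four
  finest levels, while the transit-scale coefficients that set pulse height
  live at coarser levels; thresholding everything clipped small-pulse
  amplitudes by 6–13 %, thresholding the fine levels keeps the mean
  amplitude error ≈ 0.3 % at default noise while still removing ~94 % of
  the noise power.

Detection runs on the filtered 500 kHz reference channel:
`scipy.signal.find_peaks` with height k·σ (σ = post-detrend, *pre*-denoise
estimate — the instrument's actual noise, independent of filter settings —
which is also the SNR denominator), minimum separation one pulse width, and
a minimum peak width of 0.2 ms at half prominence. The width requirement
rejects the rare single-coefficient noise blips that survive hard
thresholding (a real transit is ~0.6 ms FWHM). k defaults to 3.5: because
detection operates on the denoised trace, whose residual noise floor is
~0.075 µV, the absolute threshold (≈ 1.05 µV) is still ≈ 14 residual
standard deviations — false positives stay negligible — while the smallest
bead pulses clear it with margin despite the ≈ 11 % per-event amplitude
jitter the filter chain leaves on 2 µV pulses. Amplitudes on the other
channels are read as the filtered-signal maximum within ±2 samples of the
reference peak.

## Gating

* **Amplitude mixtures**: `sklearn` Gaussian mixtures (full covariance,
  k-means++ init under a fixed seed, components reported by ascending
  mean); bimodality is decided by BIC(2) < BIC(1).
* **Ellipse gates**: sample mean and full covariance of
  (SNR @ 500 kHz, SNR @ 20 MHz); the gate boundary is the Mahalanobis
  ellipse at `scale` standard deviations (default 1). Covariance-oriented
  ellipses generalise axis-aligned SD boxes and cost nothing.
* **Classification**: events inside the bead ellipse are beads (bead
  precedence — bare beads dominate the mixture); otherwise the
  smallest-Mahalanobis gate among containing ellipses, with nearest-gate
  fallback for events outside all ellipses so the labelling is a total
  partition. The aggregate gate for a mixture run is fitted to mixture
  events farther than 3 bead-gate SDs from the bead centre.
* **Threshold rule**: the 1-D alternative labels any event above 10 µV at
  500 kHz an aggregate.
* **Sample comparison**: Welch (unequal-variance) two-sample t-test on
  reference amplitudes.

## Numerical and degenerate-input choices

* All randomness flows through `numpy` Generators seeded explicitly;
  identical config + seed reproduces traces and CSVs byte-for-byte.
  Pipeline stages derive child seeds (< 2³¹) from one master seed via
  `SeedSequence`.
* Zero-variance amplitude draws (CV = 0) return the mean exactly;
  non-positive normal draws are resampled, not clipped.
* `estimate_noise_sigma` of an all-zero series is 0; detection on a
  zero-noise flat trace returns an empty event table.
* Mixture fits use `reg_covar = 1e-8`, so identical-valued inputs yield a
  single near-zero-width component instead of a singular fit.
* Gate construction raises on singular covariance (e.g. collinear points)
  with advice rather than regularising silently.
* Event placement raises a `GenerationError` naming the separation
  constraint when the requested density is infeasible.

## Problem sizes

Preset traces are 20 s at 100 kHz × 5 channels (2 × 10⁶ samples/channel),
with 300/300/200 events — enough pure-noise span for stable σ estimates and
several hundred peaks per sample, while a full simulate-and-process run
takes ~1 s. Recovery claims (counts, aggregate recovery within 10 %) are
exercised over 10 independent replicates per preset.

## Known limitations

* Absolute µV amplitudes are configuration, not predictions: without the
  instrument's transimpedance/demodulation calibration the circuit model
  cannot convert |ΔZ| to volts, so only cross-frequency ratios are
  model-derived.
* The aggregate population model (single mean/CV, cell membrane parameters,
  +n bead volumes) is a plausible stand-in; real aggregate amplitude
  distributions depend on bead load and geometry.
* The detector assumes non-overlapping pulses; coincidence handling and
  pulse-shape fitting are out of scope.
* Gates assume roughly elliptical (Gaussian) clusters in SNR space; heavy
  tails or curved manifolds would need different boundaries.
* The forward model is not fitted to measured spectra; parameter inference
  from data is out of scope.
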