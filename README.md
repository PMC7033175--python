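# impedcyto

Analysis toolkit for **multi-frequency microfluidic impedance cytometry**
with immuno-magnetic capture: it models, simulates and analyses the
demodulated lock-in traces produced when single particles — bare magnetic
beads, cancer cells, and antibody-mediated bead–cell aggregates — transit a
two-electrode sensing pore. The readout of interest is the number of
bead–cell aggregate events in an immuno-magnetically separated sample, a
label-free proxy for surface-marker (e.g. activated matriptase) expression
on captured cells.

It is written for groups building or analysing Coulter-type impedance
cytometers who need a tested, reproducible pipeline from raw demodulated
traces to gated event counts, plus a ground-truthed simulator for validating
detector settings.

## Model

A transit event perturbs the inter-electrode impedance

```
Z(f) = 2/(jωC_dl) + R_s + ΔR ∥ (2/(jωC_m) + R_c),   ω = 2πf
```

with `C_dl` the per-electrode double-layer capacitance, `R_s` the solution
resistance, `ΔR` the occlusion resistance (proportional to particle
*volume*: ΔR ∝ r³), and `C_m`, `R_c` the membrane capacitance and cytoplasm
resistance of a cell. For a rigid bead the membrane branch is open, so its
impedance change |ΔZ(f)| is flat in frequency; for a cell the membrane
shorts above ~1 MHz and |ΔZ| declines. A cell of twice the bead radius
produces an 8× larger low-frequency impedance change. These two signatures —
volume at low frequency, membrane at high frequency — separate beads, cells
and aggregates in (SNR @ 500 kHz, SNR @ 20 MHz) space.

The analysis chain is:

1. **simulate** (`impedcyto.synth`) — seeded multi-frequency traces
   (300 kHz, 500 kHz, 1 MHz, 5 MHz, 20 MHz) with Gaussian transit pulses,
   sinusoidal baseline drift and white noise, plus a ground-truth event log;
2. **process** (`impedcyto.sigproc`) — sym8 wavelet detrending (coarse
   approximation zeroed) and denoising (universal hard threshold on the
   fine detail levels), then peak detection on the 500 kHz reference
   channel with per-channel amplitude/SNR readout;
3. **analyze** (`impedcyto.gating`) — Gaussian-mixture fits of the
   amplitude distributions, Welch test between samples, and
   mean/covariance ellipse gates that count mixture aggregates.

## Worked example

```
impedcyto run-all --seed 1 --out-dir runs/demo
```

simulates the three study samples (pure beads, pure cells, separated
mixture), filters and detects events, builds gates and prints

```
aggregate count (ellipse gate): 53
```

The mixture trace for this seed contains 200 events of which 53 are true
aggregates: the ellipse gate and the 10 µV amplitude threshold both recover
exactly 53. `runs/demo/analysis/report.json` holds the rest of the run:
300/300/200 events detected on the three samples; bead amplitude components
at 1.96 ± 0.12 µV (91 %) and 9.90 ± 0.85 µV (9 %, non-specific doublets);
cell component at 14.41 ± 2.83 µV; mixture components at 1.96 µV (73 %) and
23.3 µV (27 %); bead-vs-cell Welch t = −55.8, p ≈ 1e-233. `impedcyto report
--analysis-dir runs/demo/analysis` renders a Markdown summary, and
`--figures` adds the amplitude histogram and SNR scatter with 1-SD ellipses.

The same stages are available as `impedcyto simulate / process / analyze`
for individual files (HDF5 or CSV traces, CSV event tables), and as plain
library calls (`preset_sample`, `process_trace`, `build_gate`, …).

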