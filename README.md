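# mesomux

Temporal demultiplexing, crosstalk unmixing, image reconstruction and
fluorescence-lifetime analysis for multiplexed two-photon mesoscopy.

## The problem

Large field-of-view two-photon microscopes trade field size against frame
rate: the laser visits one point at a time. A standard way to recover speed
is **temporal multiplexing**: each pulse of an 80 MHz excitation laser
(12.5 ns inter-pulse interval) is split into four copies, delayed by 0,
3.125, 6.25 and 9.375 ns through optical delay loops, and sent to four
different focal points (two lateral positions × two depths). A single PMT
detects all four fluorescence streams; a fast digitizer (3.2 GS/s, 40
samples per laser period) separates them again by arrival time, assigning
four per-pulse time gates to four channels — an effective 320 MHz pulse
rate at the specimen. The same digitizer, read at full rate, resolves the
fluorescence **decay** within each 12.5 ns period, turning the instrument
into a wide-field fluorescence-lifetime (FLIM) microscope.

`mesomux` implements the complete host-side computation of such a system,
plus a synthetic scope that replaces the instrument, so every stage can be
validated against ground truth:

* **timing** — closed-form multiplexing design: pulse delays, delay-line
  lengths (c·6.25 ns ≈ 1.88 m), the two-wave-plate power split
  `1 : xy : y : x` over (path1D, path1I, path2D, path2I), arrival windows,
  and the air-to-water focus correction Δfocus = 1.35 × Δstage.
* **synthetic** — a digital twin: Poisson photon statistics,
  negative-going single-photon pulses with a damped ringing tail, two
  free-running 8 kHz resonant scanners, mono-exponential decays with a
  spatially varying lifetime, circulant inter-channel leakage.
* **gating** — the FPGA's computation in software: 48-sample (15 ns)
  per-pulse records on interleaved odd/even loops, four user-defined gate
  integrals clipped to 16 bits, 1/2/4-pulse accumulation, single-photon
  event detection and statistics.
* **crosstalk** — leakage coefficients (a, b, c) estimated from a
  single-beam 40-bin calibration profile and removed pulse-by-pulse via
  the circulant model `J = W I`, `W = circ(1, a, b, c)`.
* **reconstruction** — sync-driven frame assembly (per-scanner H-sync,
  V-sync), bidirectional phase estimation, resonant-scanner desinusoiding
  (cosinusoidal sweep, central fill fraction), 16-bit TIFF export.
* **flim** — lifetime estimation from 40-bin decay stacks: IRF-convolved
  least squares `ŷ = A·(ū∗e^{-t/τ}) + B`, Poisson maximum likelihood
  `min Σ(λ_k − y_k log λ_k)`, phasor analysis
  `τ = tan(φ)/ω` with IRF correction `C = C1/C0`, the four-gate rapid
  lifetime determination, and a genetic algorithm that picks the four
  gate windows (population 100, 100 generations, 20 elites, ±1-bin
  mutations, fitness = Pearson correlation with full-fit lifetimes over
  120 pixels).
* **traces** — ROI post-processing: neuropil subtraction within a 60 µm
  annulus and ΔF baselines (rolling 8th percentile over 15 s, Gaussian
  smoothed with σ = 30 s).

## Worked example

```python
import numpy as np
import mesomux as mx

# multiplexing plan
scheme = mx.mux_pulse_delays(80e6, 4)
print(scheme.path_delays)        # (0.0, 3.125, 6.25, 9.375) ns
print(scheme.effective_rate)     # 320 MHz at the specimen

split = mx.split_powers(100.0, x=0.9, y=1.1)
print([round(p, 2) for p in split.powers])
# [25.06, 24.81, 27.57, 22.56] mW for (p1D, p1I, p2D, p2I); sums to 100

# FLIM on a synthetic two-lifetime specimen
irf = mx.IRFTrace(mx.make_irf_trace())           # ringing IRF, peak at bin 19
tau_map = np.random.default_rng(0).choice([1.5, 3.0], size=(12, 12))
stack = mx.simulate_decay_stack(tau_map, irf.u, 200.0, 50, "poisson", seed=1)
tau_hat = mx.fit_stack(stack, irf, method="ls", brightness_percentile=0.0)
print(np.median(tau_hat[tau_map == 1.5]))   # 1.500 ns
print(np.median(tau_hat[tau_map == 3.0]))   # 2.993 ns
print(np.median(np.abs(tau_hat - tau_map))) # 0.016 ns median error
```

The fitted lifetime map separates the two classes to within a few tens of
picoseconds at 50 averaged images — the accuracy regime in which lifetime
contrast distinguishes fluorophore environments.

The command line mirrors the library for shell use:

```sh
mesomux plan                      # delays, path lengths, powers, data rates
mesomux simulate --out s.h5 --seed 1
mesomux demux --stream s.h5 --out c.h5 --accumulate 4
mesomux reconstruct --counts c.h5 --channel 0 --out ch0.tif
mesomux flim-fit --stack stack.tif --irf irf.tif --method ls --out tau.tif
mesomux ga-gates --stack stack.tif --irf irf.tif --out gates.json
```

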