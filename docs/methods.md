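# Methods

This note documents the models, conventions, parameter choices and known
limitations behind `mesomux`. It is written for users who need to judge
what the package's validation does — and does not — demonstrate about
real instruments.

## Multiplexing model

An 80 MHz pulse train (period 12.5 ns) is split four ways with delays
`k · period / n_paths` (3.125 ns steps for four paths), giving an
effective 320 MHz excitation rate. Delay-line lengths use
`length = c · delay` with c rounded to 3.0×10⁸ m/s — the convention under
which the 6.25 ns loop comes out at the commonly quoted 1.88 m; the exact
CODATA value is available via `SPEED_OF_LIGHT_EXACT`. The power split
through two half-wave-plate/PBS stages is the lossless ideal
`(p1D, p1I, p2D, p2I) = M · (1, xy, y, x) / ((1+x)(1+y))`; transmission
losses of the loop optics (ETL, relay lenses) are not modeled. The
air-to-water focus correction is the fixed factor 1.35.

## Synthetic scope

The simulator emulates the acquisition chain at the digitizer level:

* **Scanner kinematics.** Each resonant scanner's position follows
  `cos(π t / T_sweep)` with one line per half period (8 kHz → 62.5 µs
  sweeps) and only the central `fill_fraction` imaged. The functional
  form is the standard resonant model; the two scanners are given
  independent, configurable phases because the hardware cannot
  synchronize them — the property that makes per-scanner H-sync
  assembly, and the ghost-image negative control, meaningful.
* **Photon statistics.** Per pulse and per path, a Poisson count with
  mean equal to the phantom brightness at the currently addressed pixel;
  each photon's delay is an exponential draw from the local lifetime,
  quantized to the 0.3125 ns grid (sub-sample jitter is an option,
  default off, so gate-level oracles stay exact).
* **Single-photon response.** A negative Gaussian lobe of configurable
  FWHM (default 1.875 ns) followed by an exponentially damped sinusoid
  whose first positive peak lags the trough by a configurable delay
  (default 2.5 ns). Ring amplitude, frequency and damping are free
  fixture parameters: the real detection chain's ringing is known only
  graphically, so no calibrated values are claimed. The kernel lead-in
  before the trough is short (1.2 × FWHM), standing in for the cable-delay
  trimming that keeps all four fluorescence windows inside one 15 ns
  record. Photons superpose linearly; PMT saturation and afterpulsing are
  not modeled.
* **Leakage.** Inter-channel leakage is injected by adding copies of the
  photon impulse train shifted by one, two and three 3.125 ns steps,
  scaled by (a, b, c). Gate integration then reproduces `J = W I` exactly
  for in-gate signal, which is what makes the unmixing round trip a sharp
  test. Real leakage additionally includes the decay tail of the
  fluorophore itself spilling into later gates; channel-purity fixtures
  therefore use sub-nanosecond lifetimes and a narrow kernel, and the
  measured purity (≥99 %) should not be read as a claim about arbitrary
  fluorophores on the real instrument.

Default test-scale streams are a few lines of 64 or fewer pixels —
full-rate simulation of one 16-line frame is ~3.4 M samples — so the whole
suite runs on a laptop-class machine.

## Gating conventions

* Records are 48 samples (15 ns) per pulse: the last path's fluorescence
  window extends past the 12.5 ns period, so consecutive records overlap
  by 8 samples, handled by interleaved odd/even loops exactly as the
  hardware does.
* PMT pulses are negative-going; gate sums are `Σ (baseline − sample)`
  so stored counts are non-negative, then saturate at 65535 (no
  wraparound). The baseline offset is a parameter (default 0) because
  whether the hardware subtracts one on-chip is not specified.
* Gate endpoints are inclusive on both ends ("time points 5 to 7" = 3
  samples). Default gates are 10 samples per path starting 2 samples
  after the path delay; the offset absorbs the kernel lead-in.
* Event detection aligns at the downward threshold crossing, holds off
  until the waveform re-crosses baseline, and measures the negative
  lobe's FWHM by linear interpolation at half-trough.

## Crosstalk ordering convention

The mixing matrix is kept verbatim as `W = circ(1, a, b, c)` with rows
`[1 a b c; c 1 a b; b c 1 a; a b c 1]`. In that form, row r receives
coefficient `a` from column r+1 — i.e. the canonical matrix applies to
channel vectors whose index runs opposite to gate firing order. For
vectors in acquisition-time order (gate 0 earliest; decay tails leak
*forward* into the gates 1, 2, 3 steps later, wrapping cyclically across
the 12.5 ns period), the physical matrix is the transpose, exposed as
`MixingModel.W_acquisition` and used by `unmix` and the simulator. The
orientation is validated end-to-end by the ghost-removal experiment:
with the wrong orientation the residual ghost is ~70 % of the uncorrected
power, with the correct one ~0.1 %. Unmixing is applied per pulse before
image reconstruction (the two scanners' pixels do not correspond in the
raw stream) and the result stays in floating point to avoid requantization
bias. Coefficients are estimated as gate-**sum** ratios of the 40-bin
calibration profile at +10/+20/+30 bins (cyclic); peak ratios would be a
defensible alternative but do not match how signals are actually
integrated.

## Reconstruction

A line is the interval between consecutive H-sync events (H-sync treated
as sweep start; the sync phase is configurable because hardware
conventions vary). Counts are binned by time within the line using exact
integer arithmetic; backward sweeps are stored column-mirrored so all
lines share one spatial orientation. The bidirectional offset is the
argmax of the forward/backward mean-line cross-correlation with parabolic
sub-sample refinement; positive shift means backward lines displaced to
the right. Desinusoiding resamples each line by linear interpolation from
uniform-in-time bins to pixel centers uniform in the spatial coordinate
`ρ(t) = (1 − cos(π t/T))/2`, cropped to the central fill fraction —
linear interpolation is invertible and preserves flat fields exactly;
line-integral conservation holds to ~1 % on smooth images. TIFF export
clamps negative (unmixed) values at zero with a logged count and
saturates at the 16-bit ceiling with a warning.

## Lifetime estimation

The per-pixel model is `ŷ_k = A · (ū ∗ e^{−t/τ})_k + B` on the 40-bin
grid (Δt = 0.3125 ns): the unit-sum IRF is tripled (`ū = [u u u]`), the
exponential is sampled over three periods, and the middle period of the
linear convolution is kept so decay tails wrap correctly across the
12.5 ns boundary. The offset is not convolved — a DC background passed
through a unit-sum kernel is itself. The least-squares objective uses
squared residuals; τ is found by a coarse log-grid scan plus a bounded
1-D refinement (the residual can be multimodal in τ), with (A, B) in
closed form, clamped non-negative, at every candidate. Search bounds
default to [0.3125, 12.5] ns — one bin width to one period — and are
exposed as parameters. The Poisson estimator minimizes
`Σ(λ_k − y_k log λ_k)` by L-BFGS-B on (A, B, τ) with λ floored at 1e-10,
initialized from the least-squares fit; the image-averaging factor
cancels from the argmin. Pixels below a configurable brightness
percentile (default 50th of the summed trace) are skipped.

Phasor analysis follows the min–max normalization procedure for both
trace and IRF, corrects by the complex ratio `C = C1/C0`, and converts
phase to lifetime by `τ = tan(φ)/ω`. Min–max normalization shifts the DC
component, so phasor lifetimes carry a small systematic offset relative
to fitted ones; the validation therefore checks *rank* agreement
(Spearman ≥ 0.99 on noiseless stacks), not equality.

### Four-gate method and GA

A gate gene is eight ordered bins `b1 ≤ b2 < … < b7 ≤ b8` forming four
inclusive windows; observed and model gate values are the **mean** over
each window's bins (averaging only the two endpoint bins is a switchable
alternative). Preprocessing circularly shifts traces so the reference
bin lands at bin 0 (the shift is a parameter, default 19; the synthetic
IRF places its reference at bin 19 accordingly) and subtracts the trace
minimum as the constant baseline. The model curve is baseline-subtracted
the same way at every candidate τ, which makes the fit exactly invariant
to the trace offset; a per-pixel scalar amplitude is profiled out in
closed form because the four-gate model as written has no amplitude
parameter and would otherwise depend on pixel brightness. τ then
minimizes the four-point residual by a bounded search with tolerance
1e-4 after a coarse grid bracket.

The GA evolves 100 genes for 100 generations: the 20 best are kept as
elites, 80 offspring are single ±1-bin mutations of random elites
(invalid mutations retried), and duplicates are removed. Fitness is the
Pearson correlation between four-gate and full-fit lifetimes over 120
pixels drawn once per run (seeded) from the brighter half of the image —
fixed rather than resampled per generation so fitness values are
comparable across generations. Fitness evaluation batches the same 1-D
search over a 240-point log-τ grid with parabolic refinement, vectorized
across pixels; the public `four_gate_lifetime` keeps the scalar bounded
search. Elitism makes the best fitness non-decreasing by construction,
and that property is asserted, not assumed.

### Noise study

The error-vs-averaging study simulates, for each image count n, an
independent decay stack over a two-lifetime map (1.5/3.0 ns) and fits it
with the estimator matched to its noise model: additive Gaussian noise at
the per-pixel shot-noise scale fitted by least squares, or Poisson counts
fitted by maximum likelihood. The lifetime map from n = 200 averaged
images defines ground truth, so its own error is zero by construction.
Study conditions: a 20×20 map, per-pixel brightness uniform in
[0.2, 3.0] (a bright-specimen regime with ~15× dynamic range, as in
standard FLIM test slides), 100 photons per unit decay amplitude per
image, n ∈ {12, 50, 200}. Under these conditions the brightest-decile
MAE sits well below the all-pixel MAE at every n, and the Poisson
likelihood buys no significant accuracy over least squares — the
agreement between the two estimators is a statement about this
moderate-to-high count regime, not about photon-starved imaging, where
the Poisson model does matter.

## Numerical choices and degenerate inputs

* Demultiplexing oracle equality is asserted bit-exactly on
  integer-valued records (digitizer codes); float records are compared to
  1e-9 because summation order differs between the vectorized and scalar
  paths.
* Constant traces: least squares returns A ≈ 0 flagged unidentifiable;
  phasor returns NaN flagged invalid; the four-gate search flags the
  bound.
* The mixing matrix is rejected above a condition-number cap (default
  1e6); a = b = c = 1 is singular.
* `solve_split` requires the product constraint `p1D·p1I = p2D·p2I`
  within tolerance; violating targets have no wave-plate solution.
* All stochastic operations take explicit seeds and reproduce
  bit-identically.

## Known limitations

* The optical layer (PSFs, ETL dynamics, aberrations) is out of scope;
  brightness maps are the ground truth, not a rendered specimen.
* Only mono-exponential decays are modeled; multi-exponential mixtures,
  TCSPC import and FRET efficiency are not.
* The synthetic scanner has no turnaround dead time or phase drift within
  a run; bidirectional offsets are injected, not emergent.
* TDMS containers are not read; HDF5 is the native format.
* Channel purity and ghost-removal figures are established with
  sub-nanosecond-lifetime fixtures and a narrow detector kernel; slower
  fluorophores leak more by physics, which is exactly what the crosstalk
  correction is for.
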