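"""Synthetic mesoscope: generates every input the analysis chain consumes.

The simulator is a digital twin of a temporally multiplexed two-photon
acquisition: an 80 MHz excitation train split into four paths spaced
3.125 ns apart, fluorescence detected by a single PMT whose single-photon
response is a negative-going pulse followed by a damped oscillation, a
3.2 GS/s digitizer (40 samples per laser period), and two free-running
8 kHz resonant scanners whose phases are not synchronized.  It produces

* raw digitizer streams (waveform + laser clock + two H-syncs + V-sync),
* 40-bin per-pixel decay stacks with Gaussian or Poisson noise,
* ground-truth phantoms (brightness per path, lifetime map, object labels),
* calcium-indicator ROI traces with a known baseline.

Scanner kinematics follow the standard resonant model: the spatial
position along a line is ``cos(pi * t / T_sweep)`` with one line per half
oscillation period, and only the central ``fill_fraction`` of the sweep is
imaged.  Photon arrival times are quantized to the digitizer grid before
kernel placement so that time-gate oracles are exact; sub-sample jitter is
available as an option.  PMT pulses superpose linearly (no saturation).

Inter-channel leakage follows the circulant mixing model: signal gated in
one channel leaks into the channels gated one, two and three 3.125 ns
steps later with coefficients (a, b, c), wrapping cyclically across the
12.5 ns period.  The simulator realises this by adding delayed scaled
copies of the photon impulse train, so gate integration recovers J = W I
exactly for in-gate signal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import fftconvolve

__all__ = [
    "ScopeConfig",
    "Phantom",
    "RawStream",
    "SinglePhotonIRF",
    "DecayStack",
    "make_photon_kernel",
    "make_irf_trace",
    "simulate_pmt_stream",
    "simulate_decay_stack",
    "make_phantom",
    "simulate_calcium_traces",
]

#: Acquisition-time channel order and the scanner each path uses.
#: Paths are gated in the order (path1 direct, path2 direct, path1 indirect,
#: path2 indirect), at 0, 3.125, 6.25 and 9.375 ns after the laser trigger;
#: path-1 channels ride scanner 0 (H-sync 1), path-2 channels scanner 1.
CHANNEL_ORDER = ("path1D", "path2D", "path1I", "path2I")
CHANNEL_SCANNER = (0, 1, 0, 1)


@dataclass(frozen=True)
class ScopeConfig:
    """Geometry and rates of the simulated acquisition."""

    sample_rate: float = 3.2e9
    rep_rate: float = 80e6
    n_paths: int = 4
    resonant_freq: float = 8e3
    fill_fraction: float = 0.5
    lines_per_frame: int = 16
    pixels_per_line: int = 64
    scanner_phases: tuple[float, float] = (0.0, 0.0)
    noise_sd: float = 1.0
    photon_amplitude: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        spp = self.sample_rate / self.rep_rate
        if abs(spp - round(spp)) > 1e-9:
            raise ValueError(
                f"sample_rate/rep_rate must be an integer number of samples "
                f"per laser period, got {spp}"
            )
        if not (0.0 < self.fill_fraction <= 1.0):
            raise ValueError(f"fill_fraction must be in (0, 1], got {self.fill_fraction}")

    @property
    def samples_per_period(self) -> int:
        """Digitizer samples per laser period (40 at defaults)."""
        return round(self.sample_rate / self.rep_rate)

    @property
    def bins_per_path_step(self) -> int:
        """Digitizer samples per inter-path delay (10 at defaults)."""
        return self.samples_per_period // self.n_paths

    @property
    def samples_per_sweep(self) -> int:
        """Digitizer samples per resonant half period (one line)."""
        return round(self.sample_rate / (2.0 * self.resonant_freq))

    @property
    def dt_ns(self) -> float:
        return 1e9 / self.sample_rate


@dataclass
class Phantom:
    """Ground-truth specimen: per-path brightness, lifetimes, object masks.

    ``brightness_maps`` has shape (n_paths, lines, pixels) in mean photons
    per laser pulse per pixel, indexed in acquisition-time channel order.
    ``tau_map`` holds fluorescence lifetimes in ns; ``labels`` integer
    object masks (0 = background).
    """

    brightness_maps: np.ndarray
    tau_map: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.brightness_maps < 0):
            raise ValueError("brightness must be non-negative")
        bright = self.brightness_maps.sum(axis=0) > 0
        if np.any(self.tau_map[bright] <= 0):
            raise ValueError("tau must be positive wherever brightness is positive")


@dataclass
class RawStream:
    """Simulated digitizer record: waveform plus event streams.

    Event times are sample indices into ``waveform``.  The laser clock is
    strictly periodic with ``sample_rate / rep_rate`` samples between
    events; each H-sync stream has one event per resonant half period with
    its scanner's phase offset.
    """

    waveform: np.ndarray
    laser_clock: np.ndarray
    hsync1: np.ndarray
    hsync2: np.ndarray
    vsync: np.ndarray
    config: ScopeConfig | None = None

    def hsync(self, scanner: int) -> np.ndarray:
        if scanner == 0:
            return self.hsync1
        if scanner == 1:
            return self.hsync2
        raise ValueError(f"scanner must be 0 or 1, got {scanner}")


@dataclass
class SinglePhotonIRF:
    """Sampled single-photon PMT response, peak-normalized to -1.

    The main lobe is a negative-going Gaussian of the configured FWHM; a
    damped sinusoidal tail follows, its first positive peak lagging the
    trough by ``trough_peak_delay_ns``.
    """

    kernel: np.ndarray
    fwhm_ns: float
    ring_frequency: float
    ring_damping: float
    trough_peak_delay_ns: float
    sample_rate: float

    @property
    def trough_index(self) -> int:
        return int(np.argmin(self.kernel))


def make_photon_kernel(
    fwhm_ns: float = 1.875,
    ring_frequency: float = 400e6,
    ring_damping: float = 0.5,
    sample_rate: float = 3.2e9,
    ring_amplitude: float = 0.3,
    trough_peak_delay_ns: float = 2.5,
    duration_ns: float = 15.0,
) -> SinglePhotonIRF:
    """Build the single-photon impulse response of the detection chain.

    Parameters
    ----------
    fwhm_ns : float
        Full width at half maximum of the negative main lobe (ns).
    ring_frequency : float
        Frequency of the damped oscillatory tail (Hz).
    ring_damping : float
        Exponential damping rate of the tail (1/ns).
    ring_amplitude : float
        Tail amplitude relative to the (unit) trough depth; 0 disables it.
    trough_peak_delay_ns : float
        Lag of the tail's first positive peak behind the trough (ns).
    """
    dt = 1e9 / sample_rate
    if fwhm_ns <= 0:
        raise ValueError(f"fwhm must be positive, got {fwhm_ns}")
    if fwhm_ns < 2 * dt:
        raise ValueError(
            f"fwhm {fwhm_ns} ns is below two sample intervals ({2 * dt} ns) "
            "and cannot be resolved"
        )
    n = round(duration_ns / dt)
    t = np.arange(n) * dt
    # short lead-in before the trough: the hardware trims cable delays so
    # fluorescence arrives just after the trigger, keeping all four paths
    # inside one record
    t_trough = max(1.2 * fwhm_ns, 3.0 * dt)
    sigma = fwhm_ns / (2.0 * math.sqrt(2.0 * math.log(2.0)))
    kernel = -np.exp(-0.5 * ((t - t_trough) / sigma) ** 2)

    if ring_amplitude > 0:
        omega = 2.0 * math.pi * ring_frequency * 1e-9  # rad/ns
        # the damped sinusoid A e^{-g s} sin(w s) peaks at s* = atan(w/g)/w
        s_star = math.atan2(omega, ring_damping) / omega
        t_start = t_trough + trough_peak_delay_ns - s_star
        s = t - t_start
        ring = np.where(
            s >= 0,
            ring_amplitude * np.exp(-ring_damping * np.maximum(s, 0.0))
            * np.sin(omega * np.maximum(s, 0.0)),
            0.0,
        )
        kernel = kernel + ring

    kernel = kernel / abs(kernel.min())  # trough at exactly -1
    return SinglePhotonIRF(
        kernel=kernel,
        fwhm_ns=fwhm_ns,
        ring_frequency=ring_frequency,
        ring_damping=ring_damping,
        trough_peak_delay_ns=trough_peak_delay_ns,
        sample_rate=sample_rate,
    )


def _hsync_events(config: ScopeConfig, scanner: int, n_samples: int) -> np.ndarray:
    period_samples = config.sample_rate / config.resonant_freq
    offset = config.scanner_phases[scanner] / (2.0 * math.pi) * period_samples
    first = offset % config.samples_per_sweep
    events = np.arange(first, n_samples, config.samples_per_sweep)
    return np.round(events).astype(np.int64)


def scanner_pixel_positions(
    sample_indices: np.ndarray, config: ScopeConfig, scanner: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Map sample times to (line, column, inside-fill) for one scanner.

    The line is the resonant half period (sweep) containing the sample,
    counted from the scanner's first sweep start; the column follows the
    cosinusoidal sweep cropped to the central ``fill_fraction``, in spatial
    order (backward sweeps are mirrored so columns always run the same
    spatial direction).
    """
    period_samples = config.sample_rate / config.resonant_freq
    offset = (config.scanner_phases[scanner] / (2.0 * math.pi) * period_samples) % (
        config.samples_per_sweep
    )
    rel = (np.asarray(sample_indices, dtype=np.float64) - offset) / config.samples_per_sweep
    sweep = np.floor(rel).astype(np.int64)
    u = rel - sweep  # phase within the sweep, [0, 1)
    # forward sweep: position cos(pi u) runs +1 -> -1; rho in [0, 1] is the
    # spatial coordinate left -> right along the line
    rho = 0.5 * (1.0 - np.cos(np.pi * u))
    backward = (sweep % 2) == 1
    rho = np.where(backward, 1.0 - rho, rho)
    ff = config.fill_fraction
    lo = 0.5 * (1.0 - ff)
    inside = (rho >= lo) & (rho < lo + ff) & (sweep >= 0)
    col = np.floor((rho - lo) / ff * config.pixels_per_line).astype(np.int64)
    col = np.clip(col, 0, config.pixels_per_line - 1)
    return sweep, col, inside


def make_irf_trace(
    kernel: SinglePhotonIRF | None = None, reference_bin: int = 19
) -> np.ndarray:
    """40-bin IRF trace derived from the single-photon kernel.

    The negative-going kernel is inverted and rectified, cropped to one
    laser period, and circularly rolled so its peak (the reference bin)
    sits at ``reference_bin`` — the position the four-gate preprocessing
    shift later moves back to bin 0.
    """
    if kernel is None:
        kernel = make_photon_kernel()
    u = np.maximum(-kernel.kernel[:40], 0.0)
    if len(u) < 40:
        u = np.pad(u, (0, 40 - len(u)))
    return np.roll(u, reference_bin - int(np.argmax(u)))


def simulate_pmt_stream(
    phantom: Phantom,
    config: ScopeConfig,
    mixing=None,
    seed: int = 0,
    kernel: SinglePhotonIRF | None = None,
    subsample_jitter: bool = False,
) -> RawStream:
    """Simulate the full-rate digitizer record of one multiplexed frame.

    For every laser pulse and every path, a Poisson photon count is drawn
    with mean equal to the phantom brightness at the pixel the path's
    scanner currently addresses; each photon is placed at the path's delay
    plus an exponential lifetime draw, quantized to the sample grid, and
    the impulse train is convolved with the single-photon kernel.  Leakage
    (``mixing``: a :class:`~mesomux.crosstalk.MixingModel` or None) adds
    delayed scaled copies of the train.  Gaussian baseline noise of sd
    ``config.noise_sd`` is added last.
    """
    n_paths, n_lines, n_cols = phantom.brightness_maps.shape
    if n_paths != config.n_paths:
        raise ValueError(
            f"phantom has {n_paths} brightness maps but config.n_paths is "
            f"{config.n_paths}"
        )
    if n_lines < config.lines_per_frame or n_cols != config.pixels_per_line:
        raise ValueError(
            f"phantom geometry {(n_lines, n_cols)} does not match config "
            f"({config.lines_per_frame} lines x {config.pixels_per_line} pixels)"
        )
    rng = np.random.default_rng(seed)
    if kernel is None:
        kernel = make_photon_kernel(sample_rate=config.sample_rate)

    margin = config.samples_per_sweep  # room for phase offsets + kernel tails
    n_samples = config.lines_per_frame * config.samples_per_sweep + margin
    spp = config.samples_per_period
    laser_clock = np.arange(0, n_samples - 2 * spp, spp, dtype=np.int64)

    train = np.zeros(n_samples, dtype=np.float64)
    dt_ns = config.dt_ns
    for q in range(config.n_paths):
        scanner = CHANNEL_SCANNER[q] if config.n_paths == 4 else 0
        t_exc = laser_clock + q * config.bins_per_path_step
        line, col, inside = scanner_pixel_positions(t_exc, config, scanner)
        valid = inside & (line >= 0) & (line < n_lines)
        mean = np.zeros(len(t_exc))
        mean[valid] = phantom.brightness_maps[q, line[valid], col[valid]]
        counts = rng.poisson(mean)
        hit = counts > 0
        if not np.any(hit):
            continue
        starts = np.repeat(t_exc[hit], counts[hit]).astype(np.float64)
        taus = np.zeros(len(t_exc))
        taus[valid] = phantom.tau_map[line[valid], col[valid]]
        tau_per_photon = np.repeat(taus[hit], counts[hit])
        delays_ns = rng.exponential(tau_per_photon)
        if subsample_jitter:
            arrival = starts + delays_ns / dt_ns
        else:
            arrival = starts + np.round(delays_ns / dt_ns)
        idx = np.round(arrival).astype(np.int64)
        ok = idx < n_samples
        np.add.at(train, idx[ok], 1.0)

    if mixing is not None:
        step = config.bins_per_path_step
        leaked = train.copy()
        for coeff, shift in zip((mixing.a, mixing.b, mixing.c), (step, 2 * step, 3 * step)):
            if coeff != 0.0 and shift < n_samples:
                leaked[shift:] += coeff * train[:-shift]
        train = leaked

    waveform = fftconvolve(train * config.photon_amplitude, kernel.kernel)[:n_samples]
    if config.noise_sd > 0:
        waveform = waveform + rng.normal(0.0, config.noise_sd, size=n_samples)

    return RawStream(
        waveform=waveform.astype(np.float64),
        laser_clock=laser_clock,
        hsync1=_hsync_events(config, 0, n_samples),
        hsync2=_hsync_events(config, 1, n_samples),
        vsync=np.array([0], dtype=np.int64),
        config=config,
    )


@dataclass
class DecayStack:
    """Per-pixel 40-bin fluorescence decay cube (mean counts per bin)."""

    cube: np.ndarray  # (lines, pixels, 40)
    dt_ns: float = 0.3125
    n_images_averaged: int | None = None

    def __post_init__(self) -> None:
        if self.cube.shape[-1] != 40:
            raise ValueError(f"decay cube must have 40 bins, got {self.cube.shape[-1]}")


def simulate_decay_stack(
    tau_map: np.ndarray,
    irf: np.ndarray,
    photons_per_pixel: float,
    n_images: int | None,
    noise_model: str = "poisson",
    seed: int = 0,
    offset: float = 0.5,
    brightness_map: np.ndarray | None = None,
    gaussian_sd: float = 1.0,
) -> DecayStack:
    """Simulate an averaged 40-bin decay stack over a lifetime map.

    The per-pixel expected trace is the IRF-convolved mono-exponential with
    amplitude ``photons_per_pixel`` (optionally modulated per pixel by
    ``brightness_map``), offset ``offset``, and lifetime from ``tau_map``.
    Observed bins are drawn per ``noise_model`` ('poisson' or 'gaussian')
    and averaged over ``n_images`` acquisitions; ``n_images=None`` returns
    the noiseless expectation.
    """
    from .flim import IRFTrace, convolve_model

    tau_map = np.asarray(tau_map, dtype=np.float64)
    if np.any(tau_map <= 0):
        raise ValueError("tau_map must be positive everywhere")
    if noise_model not in ("poisson", "gaussian"):
        raise ValueError(f"unknown noise_model {noise_model!r}")
    u = IRFTrace(np.asarray(irf, dtype=np.float64))
    rng = np.random.default_rng(seed)

    taus, inverse = np.unique(tau_map, return_inverse=True)
    curves = np.stack(
        [convolve_model(u, A=1.0, B=0.0, tau=t) for t in taus]
    )  # (n_tau, 40), unit amplitude
    amp = np.full(tau_map.shape, float(photons_per_pixel))
    if brightness_map is not None:
        amp = amp * np.asarray(brightness_map, dtype=np.float64)
    lam = amp[..., None] * curves[inverse.reshape(tau_map.shape)] + offset

    if n_images is None:
        cube = lam
    elif noise_model == "poisson":
        cube = rng.poisson(lam * n_images).astype(np.float64) / n_images
    else:
        cube = lam + rng.normal(0.0, gaussian_sd / math.sqrt(n_images), size=lam.shape)
    return DecayStack(cube=cube, n_images_averaged=n_images)


def make_phantom(
    kind: str,
    shape: tuple[int, int],
    n_objects: int,
    seed: int = 0,
    n_paths: int = 4,
    background: float = 0.0,
    brightness: float = 2.0,
    tau_classes: tuple[float, ...] = (1.5, 3.0),
) -> Phantom:
    """Build a reproducible labeled phantom.

    ``kind`` selects object shapes: 'beads' (small disks), 'cells' (larger
    disks with dim centers), 'vessels' (thick line segments).  Objects are
    disjoint, assigned round-robin to paths, and alternate between the
    lifetime classes.  ``n_objects = 0`` gives a uniform background.
    """
    if kind not in ("beads", "cells", "vessels"):
        raise ValueError(f"unknown phantom kind {kind!r}")
    h, w = shape
    if h <= 0 or w <= 0:
        raise ValueError(f"shape must be positive, got {shape}")
    rng = np.random.default_rng(seed)
    labels = np.zeros((h, w), dtype=np.int32)
    bright = np.full((n_paths, h, w), background, dtype=np.float64)
    tau = np.full((h, w), 2.0, dtype=np.float64)
    yy, xx = np.mgrid[0:h, 0:w]

    placed = 0
    attempts = 0
    while placed < n_objects and attempts < 200 * max(n_objects, 1):
        attempts += 1
        if kind == "vessels":
            r = max(1, min(h, w) // 16)
            cy = rng.integers(r, max(r + 1, h - r))
            cx = rng.integers(r, max(r + 1, w - r))
            length = rng.integers(min(h, w) // 4, min(h, w) // 2)
            angle = rng.uniform(0, math.pi)
            t = np.linspace(-length / 2, length / 2, 2 * int(length) + 1)
            py = np.clip(np.round(cy + t * math.sin(angle)).astype(int), 0, h - 1)
            px = np.clip(np.round(cx + t * math.cos(angle)).astype(int), 0, w - 1)
            mask = np.zeros((h, w), dtype=bool)
            mask[py, px] = True
            mask = (np.abs(yy[..., None] - py) + np.abs(xx[..., None] - px)).min(-1) <= r
        else:
            r = max(1, min(h, w) // (20 if kind == "beads" else 10))
            cy = rng.integers(r, max(r + 1, h - r))
            cx = rng.integers(r, max(r + 1, w - r))
            mask = (yy - cy) ** 2 + (xx - cx) ** 2 <= r * r
        if np.any(labels[mask] != 0):
            continue
        placed += 1
        labels[mask] = placed
        path = (placed - 1) % n_paths
        obj_bright = brightness * rng.uniform(0.5, 1.5)
        if kind == "cells":
            core = (yy - cy) ** 2 + (xx - cx) ** 2 <= (r // 2) ** 2
            bright[path][mask] += obj_bright
            bright[path][core] *= 0.4
        else:
            bright[path][mask] += obj_bright
        tau[mask] = tau_classes[(placed - 1) % len(tau_classes)]
    return Phantom(brightness_maps=bright, tau_map=tau, labels=labels)


def simulate_calcium_traces(
    n_rois: int,
    duration_s: float,
    fs: float,
    transient_rate: float,
    seed: int = 0,
    noise_sd: float = 0.05,
    decay_tau_s: float = 0.6,
    rise_tau_s: float = 0.05,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate ROI fluorescence traces with a known drifting baseline.

    Each trace is ``baseline + transients + noise``: the baseline is a slow
    random drift (low-frequency sinusoids plus a linear trend), transients
    are sparse non-negative double-exponential events at ``transient_rate``
    Hz, and the noise is white Gaussian.  Returns ``(traces, baselines)``,
    both of shape (n_rois, n_samples).
    """
    if fs <= 0:
        raise ValueError(f"fs must be positive, got {fs}")
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    traces = np.empty((n_rois, n))
    baselines = np.empty((n_rois, n))
    kernel_t = np.arange(0, 6 * decay_tau_s, 1 / fs)
    kern = np.exp(-kernel_t / decay_tau_s) - np.exp(-kernel_t / rise_tau_s)
    if kern.max() > 0:
        kern /= kern.max()
    for i in range(n_rois):
        base = (
            1.0
            + 0.2 * rng.standard_normal() * t / max(duration_s, 1e-9)
            + 0.1 * np.sin(2 * math.pi * rng.uniform(0.002, 0.008) * t + rng.uniform(0, 2 * math.pi))
        )
        events = np.zeros(n)
        n_ev = rng.poisson(transient_rate * duration_s)
        if n_ev > 0:
            idx = rng.integers(0, n, size=n_ev)
            amps = rng.uniform(0.5, 2.0, size=n_ev)
            np.add.at(events, idx, amps)
        transients = np.convolve(events, kern)[:n]
        baselines[i] = base
        traces[i] = base + transients + rng.normal(0.0, noise_sd, size=n)
    return traces, baselines
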