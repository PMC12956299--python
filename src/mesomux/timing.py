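"""Closed-form timing, delay-geometry and power-split calculations.

Temporal multiplexing splits each pulse of an 80 MHz excitation laser into
four copies spaced by a quarter of the 12.5 ns inter-pulse interval
(3.125 ns), so that fluorescence excited by each copy can be assigned to its
originating beam path purely by arrival time at a single detector.  The
functions here describe that scheme analytically: pulse delays and the
optical path lengths that realise them, the power distribution produced by
two half-wave-plate / polarizing-beam-splitter stages, the arrival windows
used for time gating, and the air-to-water focus correction applied during
axial stage scans.

All times are in nanoseconds, lengths in metres or micrometres as labelled;
no implicit unit conversion is performed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Rounded vacuum light speed (m/s).  The conventional delay-line figure
#: "6.25 ns = 1.88 m" is only reproduced with this rounding; pass
#: ``light_speed=SPEED_OF_LIGHT_EXACT`` for the CODATA value.
SPEED_OF_LIGHT = 3.0e8
SPEED_OF_LIGHT_EXACT = 299_792_458.0

#: Axial focus displacement per unit stage displacement when focusing
#: through a water-like specimen with an air-immersion objective.
FOCUS_SCALING = 1.35


@dataclass(frozen=True)
class MuxScheme:
    """Temporal-multiplexing scheme of an ``n_paths``-way split pulse train.

    Attributes
    ----------
    rep_rate : float
        Laser repetition rate in Hz.
    n_paths : int
        Number of interleaved excitation paths.
    period : float
        Inter-pulse interval ``1/rep_rate`` in ns.
    spacing : float
        Delay between consecutive paths, ``period / n_paths`` in ns.
    path_delays : tuple of float
        Delay of each path relative to the undelayed path, ns.
    effective_rate : float
        Pulse rate seen by the specimen, ``rep_rate * n_paths`` in Hz.
    """

    rep_rate: float
    n_paths: int
    period: float = field(init=False)
    spacing: float = field(init=False)
    path_delays: tuple[float, ...] = field(init=False)
    effective_rate: float = field(init=False)

    def __post_init__(self) -> None:
        if self.rep_rate <= 0:
            raise ValueError(f"rep_rate must be positive, got {self.rep_rate}")
        if int(self.n_paths) != self.n_paths or self.n_paths < 1:
            raise ValueError(f"n_paths must be an integer >= 1, got {self.n_paths}")
        period = 1.0 / self.rep_rate * 1e9  # ns
        spacing = period / self.n_paths
        object.__setattr__(self, "period", period)
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(
            self, "path_delays", tuple(k * spacing for k in range(self.n_paths))
        )
        object.__setattr__(self, "effective_rate", self.rep_rate * self.n_paths)


@dataclass(frozen=True)
class PowerSplit:
    """Power distribution over the four excitation paths.

    ``x`` is the direct-to-indirect split ratio and ``y`` the ratio between
    the two direct beams; the four output powers are then in ratio
    ``1 : xy : y : x`` in the order (path1 direct, path1 indirect,
    path2 direct, path2 indirect) and sum to the input power ``M``.
    """

    M: float
    x: float
    y: float
    powers: tuple[float, float, float, float]

    @property
    def path1_direct(self) -> float:
        return self.powers[0]

    @property
    def path1_indirect(self) -> float:
        return self.powers[1]

    @property
    def path2_direct(self) -> float:
        return self.powers[2]

    @property
    def path2_indirect(self) -> float:
        return self.powers[3]


def mux_pulse_delays(rep_rate: float, n_paths: int) -> MuxScheme:
    """Compute the delay scheme for an ``n_paths``-way temporal multiplex.

    Parameters
    ----------
    rep_rate : float
        Laser repetition rate in Hz (e.g. ``80e6``).
    n_paths : int
        Number of equally spaced interleaved paths.

    Returns
    -------
    MuxScheme

    Examples
    --------
    >>> s = mux_pulse_delays(80e6, 4)
    >>> s.path_delays
    (0.0, 3.125, 6.25, 9.375)
    >>> s.effective_rate
    320000000.0
    """
    if int(n_paths) != n_paths:
        raise ValueError(f"n_paths must be an integer, got {n_paths}")
    return MuxScheme(rep_rate=rep_rate, n_paths=int(n_paths))


def delay_to_path_length(delay_ns: float, light_speed: float = SPEED_OF_LIGHT) -> float:
    """Free-space path length (m) realising a given optical delay (ns)."""
    if delay_ns < 0:
        raise ValueError(f"delay must be non-negative, got {delay_ns}")
    return light_speed * delay_ns * 1e-9


def split_powers(M: float, x: float, y: float) -> PowerSplit:
    """Distribute input power ``M`` over the four paths of the delay module.

    Two half-wave-plate/PBS stages set the direct-to-indirect ratio ``1:x``
    and the direct-to-direct ratio ``1:y``; the indirect beams are then in
    the inverse ratio ``y:1``.  The resulting powers are::

        path1D = M / ((1+x)(1+y))      path1I = M x y / ((1+x)(1+y))
        path2D = M y / ((1+x)(1+y))    path2I = M x   / ((1+x)(1+y))

    so (path1D : path1I : path2D : path2I) = 1 : xy : y : x, conserving M.
    """
    if M < 0 or x < 0 or y < 0:
        raise ValueError(f"M, x, y must be non-negative, got {(M, x, y)}")
    denom = (1.0 + x) * (1.0 + y)
    powers = (M / denom, M * x * y / denom, M * y / denom, M * x / denom)
    return PowerSplit(M=M, x=x, y=y, powers=powers)


def solve_split(
    target_powers: tuple[float, float, float, float], rtol: float = 1e-9
) -> tuple[float, float, float]:
    """Invert :func:`split_powers`: recover ``(M, x, y)`` from four powers.

    The four powers must be consistent with the ``1 : xy : y : x`` structure,
    i.e. satisfy ``p1D * p1I == p2D * p2I`` (the product constraint) within
    ``rtol``; otherwise no wave-plate setting can produce them and a
    ``ValueError`` is raised.
    """
    p = np.asarray(target_powers, dtype=float)
    if p.shape != (4,) or np.any(p < 0):
        raise ValueError("target_powers must be four non-negative powers")
    p1d, p1i, p2d, p2i = p
    if p1d <= 0:
        raise ValueError("path1-direct power must be positive to define the ratios")
    lhs, rhs = p1d * p1i, p2d * p2i
    scale = max(lhs, rhs, 1e-300)
    if abs(lhs - rhs) / scale > rtol * 10 + 1e-15:
        raise ValueError(
            "target powers violate the product constraint p1D*p1I = p2D*p2I; "
            "no (M, x, y) setting reproduces them"
        )
    M = float(p.sum())
    x = p2i / p1d
    y = p2d / p1d
    return M, float(x), float(y)


def stage_to_focus(delta_stage_um: float) -> float:
    """Focal displacement (μm) inside an aqueous specimen per stage step.

    With an air objective focusing into a water-like medium, the focal plane
    moves ``1.35x`` further than the mechanical stage because of the
    refractive-index mismatch at the specimen surface.
    """
    return FOCUS_SCALING * delta_stage_um


def arrival_window(
    path_index: int, spacing_ns: float, first_window: tuple[float, float]
) -> tuple[float, float]:
    """Fluorescence arrival window of a path, shifted from the first path's.

    If fluorescence from the undelayed path arrives in ``first_window``
    (ns after the laser trigger), path ``k`` arrives ``k * spacing`` later.
    """
    lo, hi = first_window
    if lo >= hi:
        raise ValueError(f"first_window must satisfy lo < hi, got {first_window}")
    if path_index < 0:
        raise ValueError(f"path_index must be non-negative, got {path_index}")
    shift = path_index * spacing_ns
    return (lo + shift, hi + shift)


def stream_data_rate(
    rep_rate: float = 80e6, n_channels: int = 4, bytes_per_value: int = 2
) -> float:
    """Raw output data rate (bytes/s) of per-pulse gated acquisition.

    Four 16-bit gate sums per laser pulse at 80 MHz give 640 MB/s.
    """
    if rep_rate <= 0 or n_channels < 1 or bytes_per_value < 1:
        raise ValueError("rep_rate, n_channels and bytes_per_value must be positive")
    return rep_rate * n_channels * bytes_per_value
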