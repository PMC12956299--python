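"""Inter-channel leakage estimation and circulant unmixing.

When four excitation paths are separated by only 3.125 ns, the fluorescence
tail excited by one path spills into the gates integrated one, two and
three steps later.  With leakage coefficients (a, b, c) for those three
delays, the measured per-pulse channel vector J relates to the true vector
I through the circulant mixing model::

    J = W I,   W = circ(1, a, b, c) = [[1, a, b, c],
                                       [c, 1, a, b],
                                       [b, c, 1, a],
                                       [a, b, c, 1]]

The channel vector is in acquisition-time order (the order in which the
gates fire: path1D, path2D, path1I, path2I), so row r says: the channel
gated r steps after the source receives its tail with coefficient a, b, c
cyclically.  Leakage is removed pulse by pulse via I = W^-1 J — before
image reconstruction, never on reconstructed images, because the two
resonant scanners are unsynchronized and pixels of different paths do not
correspond in the raw stream.

Coefficients are estimated from a single-beam calibration: the 40-bin
time-resolved fluorescence profile of one active path, where (a, b, c)
are the ratios of the main gate's sum re-integrated +10, +20 and +30 bins
later (cyclic over the 40-bin period) to the main-gate sum itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .gating import ChannelCounts, GateSet

__all__ = [
    "MixingModel",
    "CalibrationProfile",
    "IllConditionedError",
    "mixing_matrix",
    "circulant_eigenvalues",
    "estimate_leakage",
    "unmix",
]


class IllConditionedError(ValueError):
    """The mixing matrix is singular or too ill-conditioned to invert."""


@dataclass(frozen=True)
class MixingModel:
    """Circulant leakage model circ(1, a, b, c)."""

    a: float
    b: float
    c: float
    W: np.ndarray = field(init=False, repr=False)
    condition_number: float = field(init=False)

    def __post_init__(self) -> None:
        if self.a < 0 or self.b < 0 or self.c < 0:
            raise ValueError(f"leakage coefficients must be non-negative, got "
                             f"{(self.a, self.b, self.c)}")
        v = np.array([1.0, self.a, self.b, self.c])
        idx = (np.arange(4)[None, :] - np.arange(4)[:, None]) % 4
        W = v[idx]  # W[i, j] = v[(j - i) mod 4]
        object.__setattr__(self, "W", W)
        object.__setattr__(self, "condition_number", float(np.linalg.cond(W)))

    @property
    def W_acquisition(self) -> np.ndarray:
        """Mixing matrix for channel vectors in acquisition-time order.

        The canonical circ(1, a, b, c) above multiplies channel vectors
        whose index runs opposite to gate firing order (row r receives
        coefficient a from index r+1, the channel gated one step earlier
        in that convention).  For vectors ordered as the gates fire —
        where the tail of channel q leaks *forward* into channels q+1,
        q+2, q+3 (cyclically) with coefficients a, b, c — the matrix is
        the transpose: W_acq[r, q] = v[(r - q) mod 4].  Both share the
        circulant eigenvalues.
        """
        return self.W.T


def mixing_matrix(a: float, b: float, c: float, cond_cap: float = 1e6) -> MixingModel:
    """Build and validate the circulant mixing model.

    Raises :class:`IllConditionedError` when the matrix cannot be inverted
    reliably (e.g. a = b = c = 1, where the row-sum eigenvector is the only
    non-null direction).
    """
    model = MixingModel(a=a, b=b, c=c)
    if not np.isfinite(model.condition_number) or model.condition_number > cond_cap:
        raise IllConditionedError(
            f"mixing matrix circ(1, {a}, {b}, {c}) has condition number "
            f"{model.condition_number:.3g} (cap {cond_cap:.3g})"
        )
    return model


def circulant_eigenvalues(a: float, b: float, c: float) -> np.ndarray:
    """Closed-form eigenvalues of circ(1, a, b, c).

    For W[i, j] = v[(j - i) mod 4] with v = (1, a, b, c) these are
    ``sum_j v_j i^(m j)`` for m = 0..3:
    {1+a+b+c, 1+ai-b-ci, 1-a+b-c, 1-ai-b+ci}.
    """
    v = np.array([1.0, a, b, c], dtype=complex)
    m = np.arange(4)
    return (v[None, :] * (1j ** (m[:, None] * np.arange(4)[None, :]))).sum(axis=1)


@dataclass
class CalibrationProfile:
    """40-bin mean-intensity trace of a single-beam acquisition.

    ``profile`` samples the fluorescence every 0.3125 ns across the
    12.5 ns laser period (baseline-subtracted, so non-negative up to
    noise); ``main_gate`` is the inclusive bin range containing the
    profile's peak, on the same 40-bin grid.
    """

    profile: np.ndarray
    main_gate: tuple[int, int]

    def __post_init__(self) -> None:
        self.profile = np.asarray(self.profile, dtype=np.float64)
        if self.profile.shape != (40,):
            raise ValueError(f"profile must have 40 bins, got {self.profile.shape}")
        lo, hi = self.main_gate
        if not (0 <= lo <= hi < 40):
            raise ValueError(f"main_gate {self.main_gate} outside the 40-bin grid")


def _cyclic_gate_sum(profile: np.ndarray, gate: tuple[int, int], shift: int) -> float:
    lo, hi = gate
    bins = (np.arange(lo, hi + 1) + shift) % 40
    return float(profile[bins].sum())


def estimate_leakage(calibration: CalibrationProfile, step_bins: int = 10
                     ) -> tuple[float, float, float]:
    """Estimate (a, b, c) from a single-beam time-resolved profile.

    Each coefficient is the main-gate sum re-evaluated ``step_bins`` (one
    3.125 ns channel step), 2x and 3x later — cyclically over the 40-bin
    period — divided by the main-gate sum.  The main gate must contain the
    profile's peak and have a positive sum.
    """
    prof = calibration.profile
    lo, hi = calibration.main_gate
    peak = int(np.argmax(prof))
    if not (lo <= peak <= hi):
        raise ValueError(
            f"main gate {calibration.main_gate} does not contain the profile "
            f"peak at bin {peak}"
        )
    s0 = _cyclic_gate_sum(prof, calibration.main_gate, 0)
    if s0 <= 0:
        raise ValueError(f"main-gate sum must be positive, got {s0}")
    return tuple(
        _cyclic_gate_sum(prof, calibration.main_gate, k * step_bins) / s0
        for k in (1, 2, 3)
    )


def unmix(counts: ChannelCounts, model: MixingModel, cond_cap: float = 1e6
          ) -> ChannelCounts:
    """Remove inter-channel leakage pulse by pulse: I = W^-1 J.

    ``counts`` must be in acquisition-time channel order (the order the
    mixing model is defined in).  Output values are kept in floating point
    (not re-clipped to 16 bits) to avoid quantization bias; the correction
    is meant to be applied before image reconstruction.
    """
    if counts.channel_order != "acquisition":
        raise ValueError(
            f"counts are in {counts.channel_order!r} order; unmixing requires "
            "acquisition-time order"
        )
    if not np.isfinite(model.condition_number) or model.condition_number > cond_cap:
        raise IllConditionedError(
            f"mixing model condition number {model.condition_number:.3g} "
            f"exceeds cap {cond_cap:.3g}"
        )
    unmixed = np.linalg.solve(model.W_acquisition, counts.values.T).T
    return ChannelCounts(
        values=unmixed,
        pulse_samples=counts.pulse_samples,
        channel_order=counts.channel_order,
        accumulation=counts.accumulation,
    )
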