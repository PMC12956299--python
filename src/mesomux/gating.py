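"""Per-pulse gating: the FPGA's real-time computation, re-expressed offline.

The acquisition hardware slices the 3.2 GS/s PMT waveform into one record
per laser pulse (48 samples = 15 ns, so fluorescence extending past the
12.5 ns period is captured; consecutive records overlap by 8 samples and
are handled by interleaved odd/even loops), integrates four user-defined
time gates into four 16-bit channels, and optionally sums 1, 2 or 4
consecutive pulses before streaming.  Single-photon events can also be
detected and characterized directly on the raw waveform.

Sign convention: PMT pulses are negative-going; gate integration negates
the samples (after subtracting a configurable baseline) so that stored
counts are non-negative, then saturates to the 16-bit range.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from .synthetic import RawStream

__all__ = [
    "GateSet",
    "ChannelCounts",
    "PhotonEvent",
    "default_gates",
    "slice_pulse_records",
    "integrate_gates",
    "accumulate_pulses",
    "detect_photon_events",
    "photon_event_stats",
]

UINT16_MAX = 65535.0


@dataclass(frozen=True)
class GateSet:
    """Four inclusive (start, end) sample-index gates within a pulse record."""

    gates: tuple[tuple[int, int], ...]
    record_len: int = 48

    def __post_init__(self) -> None:
        if len(self.gates) != 4:
            raise ValueError(f"exactly four gates required, got {len(self.gates)}")
        for lo, hi in self.gates:
            if not (0 <= lo <= hi < self.record_len):
                raise ValueError(
                    f"gate ({lo}, {hi}) outside record of length {self.record_len}"
                )
        spans = [set(range(lo, hi + 1)) for lo, hi in self.gates]
        for i in range(4):
            for j in range(i + 1, 4):
                if spans[i] & spans[j]:
                    warnings.warn(
                        f"gates {i} and {j} overlap; integrated counts will "
                        "share samples",
                        stacklevel=2,
                    )


def default_gates(
    samples_per_period: int = 40,
    n_paths: int = 4,
    width: int = 10,
    record_len: int = 48,
    offset: int = 2,
) -> GateSet:
    """One gate per path: ``width`` samples starting ``offset`` after the
    path's delay (the offset absorbs the detection chain's pulse lead-in)."""
    step = samples_per_period // n_paths
    return GateSet(
        gates=tuple(
            (q * step + offset, q * step + offset + width - 1) for q in range(n_paths)
        ),
        record_len=record_len,
    )


@dataclass
class ChannelCounts:
    """Per-pulse 4-channel gate-integrated values.

    ``values`` has shape (n_pulses, 4) in acquisition-time channel order
    (path1D, path2D, path1I, path2I by default); ``pulse_samples`` holds
    the laser-clock sample index of each pulse for image assembly, and
    ``accumulation`` how many raw pulses each row sums.
    """

    values: np.ndarray
    pulse_samples: np.ndarray
    channel_order: str = "acquisition"
    accumulation: int = 1

    def __post_init__(self) -> None:
        if self.values.ndim != 2 or self.values.shape[1] != 4:
            raise ValueError(f"values must be (n_pulses, 4), got {self.values.shape}")
        if len(self.pulse_samples) != len(self.values):
            raise ValueError("pulse_samples length must match values")


def slice_pulse_records(
    stream: RawStream, record_len: int = 48
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Slice the waveform into one ``record_len``-sample record per pulse.

    Records start at each laser-clock event; when ``record_len`` exceeds
    the inter-pulse spacing, consecutive records overlap (the hardware's
    interleaved odd/even measurement loops).  Pulses whose record would
    run past the end of the waveform are dropped with a warning.

    Returns ``(records, pulse_samples, parity)`` where ``parity`` tags odd
    and even pulses (0/1).
    """
    clock = np.asarray(stream.laser_clock, dtype=np.int64)
    if len(clock) == 0:
        raise ValueError("stream has no laser-clock events")
    spacing = np.diff(clock)
    if len(spacing) and record_len < spacing.min():
        raise ValueError(
            f"record_len {record_len} is shorter than the pulse period "
            f"({spacing.min()} samples)"
        )
    n = len(stream.waveform)
    keep = clock + record_len <= n
    if not np.all(keep):
        warnings.warn(
            f"dropping {np.count_nonzero(~keep)} trailing pulse(s) whose "
            "record extends past the waveform end",
            stacklevel=2,
        )
    clock = clock[keep]
    records = stream.waveform[clock[:, None] + np.arange(record_len)[None, :]]
    parity = (np.arange(len(clock)) % 2).astype(np.int8)
    return records, clock, parity


def integrate_gates(
    records: np.ndarray,
    gate_set: GateSet,
    polarity: str = "negative",
    baseline: float = 0.0,
    pulse_samples: np.ndarray | None = None,
    clip: bool = True,
) -> ChannelCounts:
    """Integrate the four time gates of each pulse record into channels.

    Channel ``c`` is the sum over gate ``c`` of the polarity-corrected,
    baseline-offset samples: ``baseline - sample`` for negative-going PMT
    pulses, ``sample - baseline`` for positive.  Values saturate to the
    16-bit range unless ``clip`` is False (floating-point output either way).
    """
    records = np.asarray(records, dtype=np.float64)
    if records.shape[1] != gate_set.record_len:
        raise ValueError(
            f"records have {records.shape[1]} samples but gate_set.record_len "
            f"is {gate_set.record_len}"
        )
    if polarity not in ("negative", "positive"):
        raise ValueError(f"polarity must be 'negative' or 'positive', got {polarity!r}")
    corrected = (baseline - records) if polarity == "negative" else (records - baseline)
    values = np.stack(
        [corrected[:, lo : hi + 1].sum(axis=1) for lo, hi in gate_set.gates], axis=1
    )
    if clip:
        values = np.clip(values, 0.0, UINT16_MAX)
    if pulse_samples is None:
        pulse_samples = np.arange(len(records), dtype=np.int64)
    return ChannelCounts(values=values, pulse_samples=np.asarray(pulse_samples))


def accumulate_pulses(counts: ChannelCounts, n: int) -> ChannelCounts:
    """Sum every ``n`` consecutive pulses per channel (n in {1, 2, 4}).

    The output rate is ``rep_rate / n``; a trailing remainder that does not
    fill a group is dropped with a warning.  Total counts are conserved up
    to the dropped remainder.
    """
    if n not in (1, 2, 4):
        raise ValueError(f"accumulation factor must be 1, 2 or 4, got {n}")
    if n == 1:
        return counts
    m = len(counts.values)
    groups = m // n
    if m % n:
        warnings.warn(
            f"dropping {m % n} trailing pulse(s) not filling an accumulation "
            "group",
            stacklevel=2,
        )
    values = counts.values[: groups * n].reshape(groups, n, 4).sum(axis=1)
    samples = counts.pulse_samples[: groups * n : n]
    return ChannelCounts(
        values=values,
        pulse_samples=samples,
        channel_order=counts.channel_order,
        accumulation=counts.accumulation * n,
    )


@dataclass
class PhotonEvent:
    """One detected (negative-going) photon pulse on the raw waveform."""

    crossing_index: int
    trough_index: int
    trough_amplitude: float
    second_peak_index: int
    second_peak_amplitude: float
    fwhm_ns: float


def _fwhm_interp(w: np.ndarray, trough: int, dt_ns: float) -> float:
    """FWHM of the negative lobe by linear interpolation at half-trough."""
    half = w[trough] / 2.0  # negative
    left = trough
    while left > 0 and w[left] < half:
        left -= 1
    if w[left] < half:  # never re-crossed: clip at edge
        t_left = float(left)
    else:
        t_left = left + (half - w[left]) / (w[left + 1] - w[left])
    right = trough
    while right < len(w) - 1 and w[right] < half:
        right += 1
    if w[right] < half:
        t_right = float(right)
    else:
        t_right = right - (half - w[right]) / (w[right - 1] - w[right])
    return (t_right - t_left) * dt_ns


def detect_photon_events(
    waveform: np.ndarray,
    threshold: float,
    dt_ns: float = 0.3125,
    search_window_ns: float = 10.0,
) -> list[PhotonEvent]:
    """Detect negative-going photon pulses by threshold crossing.

    One event is registered per downward crossing of ``threshold`` (which
    must be below the baseline of 0); a refractory hold-off suppresses
    further crossings until the waveform returns above baseline.  For each
    event the trough, the following (second) positive peak of the ringing
    tail and the FWHM of the negative lobe are measured.
    """
    w = np.asarray(waveform, dtype=np.float64)
    if threshold >= 0:
        raise ValueError(f"threshold must be below baseline (negative), got {threshold}")
    below = w < threshold
    crossings = np.flatnonzero(~below[:-1] & below[1:]) + 1
    win = int(round(search_window_ns / dt_ns))
    events: list[PhotonEvent] = []
    hold_until = -1
    for c in crossings:
        if c <= hold_until:
            continue
        # trough: minimum until the waveform re-crosses baseline (0)
        end = c
        while end < len(w) - 1 and w[end] < 0:
            end += 1
        trough = c + int(np.argmin(w[c:end + 1]))
        hold_until = end
        peak_stop = min(len(w), end + win)
        if peak_stop > end:
            second_peak = end + int(np.argmax(w[end:peak_stop]))
        else:
            second_peak = end
        events.append(
            PhotonEvent(
                crossing_index=int(c),
                trough_index=int(trough),
                trough_amplitude=float(w[trough]),
                second_peak_index=int(second_peak),
                second_peak_amplitude=float(w[second_peak]),
                fwhm_ns=_fwhm_interp(w, trough, dt_ns),
            )
        )
    return events


def photon_event_stats(
    events: list[PhotonEvent],
    waveform: np.ndarray | None = None,
    snippet_ns: tuple[float, float] = (2.0, 10.0),
    dt_ns: float = 0.3125,
) -> dict:
    """Summary statistics over detected photon events.

    Returns median FWHM, the Pearson correlation between trough and
    second-peak sample indices (the ringing-phase consistency check; None
    with fewer than two events), the FWHM values, and — when the waveform
    is supplied — a matrix of per-event snippets aligned at the threshold
    crossing and sorted by second-peak amplitude.
    """
    fwhms = np.array([e.fwhm_ns for e in events])
    out: dict = {
        "n_events": len(events),
        "median_fwhm_ns": float(np.median(fwhms)) if len(events) else None,
        "fwhm_ns": fwhms,
    }
    if len(events) >= 2:
        troughs = np.array([e.trough_index for e in events], dtype=float)
        peaks = np.array([e.second_peak_index for e in events], dtype=float)
        if np.ptp(troughs) > 0 and np.ptp(peaks) > 0:
            out["trough_peak_correlation"] = float(np.corrcoef(troughs, peaks)[0, 1])
        else:
            out["trough_peak_correlation"] = None
        out["median_peak_trough_gap_ns"] = float(np.median(peaks - troughs) * dt_ns)
    else:
        out["trough_peak_correlation"] = None
    if waveform is not None and events:
        pre = int(round(snippet_ns[0] / dt_ns))
        post = int(round(snippet_ns[1] / dt_ns))
        order = np.argsort([e.second_peak_amplitude for e in events])[::-1]
        rows = []
        for i in order:
            c = events[i].crossing_index
            if c - pre < 0 or c + post > len(waveform):
                continue
            rows.append(waveform[c - pre : c + post])
        out["aligned_matrix"] = np.array(rows) if rows else np.empty((0, pre + post))
    return out
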