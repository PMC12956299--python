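"""Image assembly from per-pulse counts, phase and sine-wave correction.

Per-pulse channel counts carry no position; images are assembled from the
synchronization streams: the V-sync marks a frame start, each H-sync marks
the start of one resonant-scanner sweep (one line), and pulses are placed
along the line by their time within the sweep.  Because the two resonant
scanners free-run with a random relative phase, a channel must be
assembled against the H-sync of its own scanner (path-1 channels against
H-sync 1, path-2 channels against H-sync 2); using the wrong sync
scrambles lines into a decorrelated image — the negative control for the
two-scanner design.

Bidirectional (forward/backward) lines are stored time-reversed on
backward sweeps so that columns always run the same spatial direction;
a residual bidirectional phase offset is estimated by cross-correlating
mean forward and backward lines and removed by sub-pixel shifting.
Finally, resonant-scanner sinusoidal distortion is corrected by resampling
each line from uniform-in-time bins to uniform-in-space pixels using the
cosinusoidal sweep model, cropped to the central fill fraction
("desinusoiding"), and frames are exported as 16-bit multi-page TIFF.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import tifffile

from .gating import ChannelCounts
from .synthetic import CHANNEL_SCANNER

__all__ = [
    "FrameGeometry",
    "RawImage",
    "assemble_frame",
    "estimate_bidirectional_offset",
    "apply_bidirectional_offset",
    "desinusoid",
    "export_tiff16",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FrameGeometry:
    """Geometry of one reconstructed frame.

    ``pulses_per_line`` sets the width of the raw (time-ordered) image:
    counts between consecutive H-syncs are binned into that many equal
    time bins.  ``pixels_per_line`` is the output width after
    desinusoiding; ``fill_fraction`` the imaged central portion of the
    sweep.  With ``bidirectional`` scanning every other line is a
    backward sweep; ``first_line_forward`` fixes the direction of line 0.
    """

    lines_per_frame: int
    pulses_per_line: int
    pixels_per_line: int
    fill_fraction: float = 0.5
    bidirectional: bool = True
    first_line_forward: bool = True

    def __post_init__(self) -> None:
        if not (0.0 < self.fill_fraction <= 1.0):
            raise ValueError(f"fill_fraction must be in (0, 1], got {self.fill_fraction}")
        if self.pixels_per_line > self.pulses_per_line:
            raise ValueError(
                f"pixels_per_line ({self.pixels_per_line}) cannot exceed "
                f"pulses_per_line ({self.pulses_per_line})"
            )
        if self.lines_per_frame < 1 or self.pulses_per_line < 1:
            raise ValueError("geometry counts must be positive")


@dataclass
class RawImage:
    """Time-ordered image before desinusoiding.

    ``pixels`` is (lines, pulses_per_line); ``line_directions`` is +1 for
    forward sweeps, -1 for backward (whose columns are already reversed to
    spatial order).  Provenance records the channel, sync source and frame.
    """

    pixels: np.ndarray
    line_directions: np.ndarray
    channel: int
    sync_source: int
    frame_index: int = 0


def assemble_frame(
    counts: ChannelCounts,
    hsync: np.ndarray,
    vsync: np.ndarray,
    geometry: FrameGeometry,
    channel: int,
    frame_index: int = 0,
    sync_source: int | None = None,
) -> RawImage:
    """Assemble one channel's frame from pulse counts and sync events.

    Pulses between consecutive H-sync events form one line; each line is
    divided into ``pulses_per_line`` equal time bins and pulse counts
    falling in a bin are averaged.  H-sync must come from the scanner that
    carries the channel (``CHANNEL_SCANNER``); passing the other stream is
    permitted (it is the ghost-image negative control) but the provenance
    records which was used.
    """
    if not (0 <= channel <= 3):
        raise ValueError(f"channel must be in 0..3, got {channel}")
    if sync_source is None:
        sync_source = CHANNEL_SCANNER[channel]
    hsync = np.asarray(hsync, dtype=np.int64)
    vsync = np.asarray(vsync, dtype=np.int64)
    if len(vsync) <= frame_index:
        raise ValueError(f"no V-sync event for frame {frame_index}")
    start = vsync[frame_index]
    lines_sync = hsync[hsync >= start]
    if len(lines_sync) < geometry.lines_per_frame + 1:
        raise ValueError(
            f"insufficient H-sync events for a full frame: need "
            f"{geometry.lines_per_frame + 1}, have {len(lines_sync)}"
        )
    samples = counts.pulse_samples
    values = counts.values[:, channel]
    img = np.zeros((geometry.lines_per_frame, geometry.pulses_per_line))
    directions = np.empty(geometry.lines_per_frame, dtype=np.int8)
    for i in range(geometry.lines_per_frame):
        lo, hi = lines_sync[i], lines_sync[i + 1]
        sel = (samples >= lo) & (samples < hi)
        forward = (i % 2 == 0) == geometry.first_line_forward or not geometry.bidirectional
        directions[i] = 1 if forward else -1
        if not np.any(sel):
            continue
        rel = (samples[sel] - lo).astype(np.int64)
        bins = np.minimum(
            rel * geometry.pulses_per_line // int(hi - lo),
            geometry.pulses_per_line - 1,
        )
        acc = np.bincount(bins, weights=values[sel], minlength=geometry.pulses_per_line)
        npx = np.bincount(bins, minlength=geometry.pulses_per_line)
        line = np.divide(acc, npx, out=np.zeros_like(acc), where=npx > 0)
        if not forward:
            line = line[::-1]  # store backward sweeps in spatial order
        img[i] = line
    return RawImage(
        pixels=img,
        line_directions=directions,
        channel=channel,
        sync_source=sync_source,
        frame_index=frame_index,
    )


def estimate_bidirectional_offset(img: RawImage) -> tuple[float, bool]:
    """Estimate the forward/backward line misalignment in raw columns.

    Cross-correlates the mean forward line against the mean backward line
    (already column-mirrored at assembly) and refines the peak with a
    parabolic fit.  Returns ``(shift, confident)``; a featureless image
    yields shift 0 with ``confident=False``.
    """
    fwd = img.pixels[img.line_directions > 0]
    bwd = img.pixels[img.line_directions < 0]
    if len(fwd) == 0 or len(bwd) == 0:
        raise ValueError("bidirectional offset needs both forward and backward lines")
    a = fwd.mean(axis=0)
    b = bwd.mean(axis=0)
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a**2).sum() * (b**2).sum())
    if denom <= 0:
        return 0.0, False
    corr = np.correlate(a, b, mode="full") / denom
    lags = np.arange(-len(b) + 1, len(a))
    k = int(np.argmax(corr))
    shift = float(lags[k])
    if 0 < k < len(corr) - 1:  # parabolic sub-pixel refinement
        y0, y1, y2 = corr[k - 1], corr[k], corr[k + 1]
        d = y0 - 2 * y1 + y2
        if d < 0:
            shift += 0.5 * (y0 - y2) / d
    confident = float(corr[k]) > 0.2
    # sign convention: positive shift = backward lines displaced to the
    # right relative to forward lines
    return -shift, confident


def apply_bidirectional_offset(img: RawImage, shift: float) -> RawImage:
    """Shift backward lines by ``-shift`` columns (linear interpolation)."""
    out = img.pixels.copy()
    cols = np.arange(img.pixels.shape[1], dtype=float)
    for i in np.flatnonzero(img.line_directions < 0):
        out[i] = np.interp(cols + shift, cols, img.pixels[i])
    return RawImage(
        pixels=out,
        line_directions=img.line_directions,
        channel=img.channel,
        sync_source=img.sync_source,
        frame_index=img.frame_index,
    )


def desinusoid(img: RawImage, geometry: FrameGeometry) -> np.ndarray:
    """Resample each line from uniform-in-time to uniform-in-space pixels.

    The resonant scanner position follows ``cos(pi t / T_sweep)``; the
    spatial coordinate rho(t) = (1 - cos(pi t/T)) / 2 runs 0..1 over a
    sweep, and only the central ``fill_fraction`` is imaged.  Output pixel
    centers are uniform in rho and sampled from the time-ordered line by
    linear interpolation, so column ordering is preserved (the sweep is
    monotone) and a flat field stays flat.
    """
    ff = geometry.fill_fraction
    if ff <= 0:
        raise ValueError("fill_fraction must be positive")
    n_raw = img.pixels.shape[1]
    w = geometry.pixels_per_line
    # spatial centers of output pixels within the cropped sweep
    rho = 0.5 * (1.0 - ff) + ff * (np.arange(w) + 0.5) / w
    u = np.arccos(1.0 - 2.0 * rho) / np.pi  # time fraction within the sweep
    # raw column m covers time fraction [m/n, (m+1)/n]; its center:
    u_raw = (np.arange(n_raw) + 0.5) / n_raw
    out = np.empty((img.pixels.shape[0], w))
    for i, dirn in enumerate(img.line_directions):
        line = img.pixels[i]
        # backward lines were stored spatially mirrored; their stored
        # column m maps to time fraction 1-(m+.5)/n, which by cosine
        # symmetry gives the same rho-vs-index mapping as a forward line.
        out[i] = np.interp(u, u_raw, line)
    return out


def export_tiff16(imgs: np.ndarray, path, scale: float = 1.0) -> None:
    """Write frames as a multi-page 16-bit TIFF (lossless round trip).

    ``imgs`` is (frames, h, w) or (h, w).  Values are multiplied by
    ``scale``; negatives (e.g. from unmixing) are clamped to 0 with a
    logged count, and values above 65535 saturate with a warning.
    """
    imgs = np.asarray(imgs, dtype=np.float64) * scale
    n_neg = int(np.count_nonzero(imgs < 0))
    if n_neg:
        logger.info("clamping %d negative pixel(s) to 0 in %s", n_neg, path)
        imgs = np.maximum(imgs, 0.0)
    if np.any(imgs > 65535):
        warnings.warn(
            f"{np.count_nonzero(imgs > 65535)} pixel(s) exceed the 16-bit "
            "range and will saturate",
            stacklevel=2,
        )
        imgs = np.minimum(imgs, 65535.0)
    tifffile.imwrite(path, np.round(imgs).astype(np.uint16),
                     photometric="minisblack")
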