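"""ROI time-series processing: neuropil subtraction and baseline removal.

Calcium-indicator fluorescence rides on a slowly drifting baseline (photo-
bleaching, focus drift) plus local neuropil contamination.  The background
of an ROI is taken as the per-frame mean of pixels within a 60 um radius
of the ROI, excluding every detected ROI, and subtracted frame by frame.
The activity baseline is then a rolling low percentile (8th over a 15 s
window) smoothed with a wide Gaussian (sigma 30 s); subtracting it sets
quiescent stretches to zero.  The default output is delta-F (baseline
subtracted); delta-F/F is available as an option.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import distance_transform_edt, gaussian_filter1d, percentile_filter

__all__ = ["background_subtract", "percentile_baseline"]


def background_subtract(
    roi_trace: np.ndarray,
    movie: np.ndarray,
    roi_masks: np.ndarray,
    roi_index: int,
    radius_um: float = 60.0,
    um_per_px: float = 1.0,
) -> np.ndarray:
    """Subtract the local background (neuropil) trace from an ROI trace.

    ``movie`` is (frames, h, w); ``roi_masks`` an integer label image
    (0 = background, k = ROI k).  The background annulus contains the
    pixels within ``radius_um`` of ROI ``roi_index`` that belong to no ROI
    at all; its per-frame mean is subtracted from ``roi_trace``.
    """
    if um_per_px <= 0:
        raise ValueError(f"um_per_px must be positive, got {um_per_px}")
    roi = roi_masks == roi_index
    if not np.any(roi):
        raise ValueError(f"ROI {roi_index} not present in the label image")
    radius_px = radius_um / um_per_px
    dist = distance_transform_edt(~roi)
    annulus = (dist <= radius_px) & (roi_masks == 0)
    if not np.any(annulus):
        raise ValueError(
            f"background annulus of ROI {roi_index} is empty "
            f"(radius {radius_um} um = {radius_px:.1f} px)"
        )
    background = movie[:, annulus].mean(axis=1)
    return np.asarray(roi_trace, dtype=np.float64) - background


def percentile_baseline(
    trace: np.ndarray,
    fs: float,
    pct: float = 8.0,
    window_s: float = 15.0,
    sigma_s: float = 30.0,
    mode: str = "rolling",
    dff: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Slow-baseline estimate by rolling percentile + Gaussian smoothing.

    A centered ``window_s``-second window's ``pct``-th percentile is
    computed at every sample (``mode='rolling'``) or once per
    non-overlapping tile (``mode='tiled'``, then held constant over the
    tile), and the result is smoothed with a Gaussian of ``sigma_s``
    seconds (reflect-padded edges).  Returns ``(baseline, corrected)``
    where ``corrected`` is ``trace - baseline`` (delta-F) or, with
    ``dff=True``, ``(trace - baseline) / baseline``.
    """
    if fs <= 0:
        raise ValueError(f"fs must be positive, got {fs}")
    trace = np.asarray(trace, dtype=np.float64)
    win = max(int(round(window_s * fs)), 1)
    if trace.shape[-1] <= win:
        raise ValueError(
            f"trace length {trace.shape[-1]} must exceed the window "
            f"({win} samples)"
        )
    if mode == "rolling":
        size = (1,) * (trace.ndim - 1) + (win,)
        raw = percentile_filter(trace, percentile=pct, size=size, mode="reflect")
    elif mode == "tiled":
        n = trace.shape[-1]
        raw = np.empty_like(trace)
        for start in range(0, n, win):
            seg = slice(start, min(start + win, n))
            raw[..., seg] = np.percentile(trace[..., seg], pct, axis=-1, keepdims=True)
    else:
        raise ValueError(f"mode must be 'rolling' or 'tiled', got {mode!r}")
    baseline = gaussian_filter1d(raw, sigma=sigma_s * fs, mode="reflect")
    corrected = trace - baseline
    if dff:
        corrected = corrected / baseline
    return baseline, corrected
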