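"""Ratiometric measures: Fura Red calcium ratio and generalized polarization.

The Fura Red ratio FRr(t) = I_bound(t) / I_unbound(t) cancels
photobleaching and focus drift common to both indicator forms; the
baseline is the mean ratio over the pre-stimulus frames and the
amplitude is the ratio at the first post-stimulus maximum minus the
baseline.

Generalized polarization GP = (I_ordered - I_disordered) /
(I_ordered + I_disordered) is evaluated at the membrane position of a
line profile crossing the cell edge — the position of maximum summed
intensity — and averaged over several positions per cell.  Lower GP
means a more fluid (less cholesterol-ordered) membrane.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "RatioTrace",
    "GpMeasurement",
    "compute_frr",
    "compute_gp",
    "extract_line_profile",
    "per_cell_gp",
]


@dataclass
class RatioTrace:
    """Fura Red ratio trace with baseline/amplitude extraction."""

    frr: np.ndarray
    stim_frame: int
    baseline: float
    amplitude: float
    normalized_amplitude: float
    peak_frame: int
    peak_is_local_max: bool = True
    excluded_frames: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))


def compute_frr(bound, unbound, stim_frame: int = 4, n_baseline: int = 4,
                smooth: bool = True) -> RatioTrace:
    """Fura Red ratio with baseline and first-maximum amplitude.

    The baseline is the mean FRr over frames [0, n_baseline); the peak
    is the first frame at/after ``stim_frame`` whose (optionally
    3-frame-median-smoothed) FRr exceeds both neighbors, and the
    amplitude is the raw FRr there minus the baseline.  If no local
    maximum exists before the series ends, the global post-stimulus
    maximum is used and ``peak_is_local_max`` is False.  Frames with
    non-positive unbound intensity are excluded with a warning.
    """
    bound = np.asarray(bound, dtype=float)
    unbound = np.asarray(unbound, dtype=float)
    if bound.shape != unbound.shape:
        raise ValueError("channel series must have equal length")
    if stim_frame < n_baseline:
        raise ValueError("stim_frame must be >= n_baseline")

    bad = unbound <= 0
    if bad.any():
        warnings.warn(f"{bad.sum()} frame(s) with non-positive unbound "
                      "intensity excluded")
    frr = np.where(bad, np.nan, bound / np.where(bad, 1.0, unbound))
    baseline = float(np.nanmean(frr[:n_baseline]))

    s = frr.copy()
    if smooth and len(frr) >= 3:
        finite = np.isfinite(frr)
        tmp = frr.copy()
        if (~finite).any():
            tmp[~finite] = np.interp(np.flatnonzero(~finite),
                                     np.flatnonzero(finite), frr[finite])
        # edge-replicated 3-frame median; zero padding would fabricate
        # a spurious plateau at the ends of the series
        padded = np.pad(tmp, 1, mode="edge")
        s = np.median(np.lib.stride_tricks.sliding_window_view(padded, 3), axis=1)

    peak_frame, is_local = None, True
    for i in range(max(stim_frame, 1), len(s) - 1):
        # median smoothing can flatten a sharp peak into a plateau, so the
        # right-hand comparison tolerates equality
        if s[i] > s[i - 1] and s[i] >= s[i + 1]:
            peak_frame = i
            break
    if peak_frame is None:
        is_local = False
        post = np.nan_to_num(frr[stim_frame:], nan=-np.inf)
        peak_frame = stim_frame + int(np.argmax(post))

    amplitude = float(frr[peak_frame] - baseline) if np.isfinite(frr[peak_frame]) \
        else float(np.nanmax(frr[stim_frame:]) - baseline)
    return RatioTrace(
        frr=frr, stim_frame=stim_frame, baseline=baseline,
        amplitude=amplitude, normalized_amplitude=amplitude / baseline,
        peak_frame=int(peak_frame), peak_is_local_max=is_local,
        excluded_frames=np.flatnonzero(bad),
    )


@dataclass
class GpMeasurement:
    """Per-cell GP: mean over per-position membrane GP values."""

    gp_values: np.ndarray
    gp_mean: float
    n_positions: int


class UndefinedGpError(ValueError):
    """Summed channel intensity is zero at the membrane position."""


def compute_gp(profile_ch1, profile_ch2) -> float:
    """GP at the membrane position of a two-channel line profile.

    The membrane is localized jointly as the maximum of the summed
    channels so both intensities are read at the same point;
    GP = (I1 - I2)/(I1 + I2) there.
    """
    p1 = np.asarray(profile_ch1, dtype=float)
    p2 = np.asarray(profile_ch2, dtype=float)
    if p1.shape != p2.shape:
        raise ValueError("profiles must have equal length")
    idx = int(np.argmax(p1 + p2))
    total = p1[idx] + p2[idx]
    if total == 0:
        raise UndefinedGpError("zero summed intensity at membrane position")
    return float((p1[idx] - p2[idx]) / total)


def extract_line_profile(image_ch1, image_ch2, start, end):
    """Bilinear line profiles at unit-pixel spacing, both channels.

    ``start``/``end`` are (row, col) pixel coordinates inside the
    images; the two channels are sampled at identical positions.
    """
    img1 = np.asarray(image_ch1, dtype=float)
    img2 = np.asarray(image_ch2, dtype=float)
    if img1.shape != img2.shape:
        raise ValueError("channel images must have equal shape")
    start = np.asarray(start, dtype=float)
    end = np.asarray(end, dtype=float)
    length = np.hypot(*(end - start))
    if length == 0:
        raise ValueError("zero-length profile segment")
    for p in (start, end):
        if np.any(p < 0) or np.any(p > np.array(img1.shape) - 1):
            raise ValueError("endpoints must lie inside the image")
    n = int(np.ceil(length)) + 1
    t = np.linspace(0.0, 1.0, n)
    coords = np.outer(1 - t, start) + np.outer(t, end)
    p1 = ndimage.map_coordinates(img1, coords.T, order=1)
    p2 = ndimage.map_coordinates(img2, coords.T, order=1)
    return p1, p2


def per_cell_gp(profiles) -> GpMeasurement:
    """Per-cell GP: arithmetic mean of per-position GPs.

    ``profiles`` is a sequence of (profile_ch1, profile_ch2) pairs,
    conventionally 4–10 positions per cell.
    """
    values = np.array([compute_gp(p1, p2) for p1, p2 in profiles])
    if len(values) == 0:
        raise ValueError("need at least one profile")
    if not 4 <= len(values) <= 10:
        warnings.warn("per-cell GP conventionally averages 4-10 positions")
    return GpMeasurement(gp_values=values, gp_mean=float(values.mean()),
                         n_positions=len(values))
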