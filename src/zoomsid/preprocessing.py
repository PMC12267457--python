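"""Spectral preprocessing: baseline correction, smoothing, noise, peak picking.

The chain mirrors the processing applied to the site's MALDI fingerprints:
baseline correction (Precision = 15 segments, Relative offset = 25%),
Savitzky-Golay smoothing (window 0.3 Da, 2 cycles, order 2), and peak
picking at S/N >= 3 with centroids read at 75% of apex height.  The order
baseline -> smooth -> noise -> pick is fixed.

The baseline algorithm is a segment-anchor realization of the mMass-style
"Precision / Relative offset" parameters: the m/z axis is split into
``precision`` equal-width segments; each contributes an anchor at the
segment minimum lifted by ``relative_offset`` percent of the segment's local
intensity spread (measured robustly as median - minimum, so narrow peaks do
not inflate it); the anchors are joined piecewise-linearly, subtracted, and
negatives clipped to zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks, savgol_filter

from .spectral_io import Peak, PeakList, Spectrum

logger = logging.getLogger(__name__)

__all__ = [
    "PreprocessConfig",
    "correct_baseline",
    "smooth",
    "estimate_noise",
    "pick_peaks",
    "preprocess",
]

_MAD_SCALE = 1.4826  # MAD -> sigma for Gaussian noise


@dataclass(frozen=True)
class PreprocessConfig:
    """Knobs of the processing chain, with the site study's defaults."""

    baseline_precision: int = 15
    baseline_relative_offset: float = 25.0
    smooth_window: float = 0.3  # Da
    smooth_cycles: int = 2
    snr_threshold: float = 3.0
    picking_height: float = 0.75
    noise_window: float = 100.0  # Da

    def __post_init__(self):
        if self.baseline_precision < 2:
            raise ValueError("baseline_precision must be >= 2")
        if not 0.0 < self.picking_height < 1.0:
            raise ValueError("picking_height must be in (0, 1)")
        if self.snr_threshold <= 0:
            raise ValueError("snr_threshold must be > 0")
        if self.smooth_window <= 0:
            raise ValueError("smooth_window must be > 0")
        if self.smooth_cycles < 1:
            raise ValueError("smooth_cycles must be >= 1")


def correct_baseline(s: Spectrum, cfg: PreprocessConfig = PreprocessConfig()) -> Spectrum:
    """Subtract a piecewise-linear baseline through segment anchors."""
    n_seg = cfg.baseline_precision
    if len(s) < 2 * n_seg:
        logger.warning(
            "spectrum of %d points shorter than %d baseline segments; using constant baseline",
            len(s), n_seg,
        )
        n_seg = 1
    edges = np.linspace(s.mz[0], s.mz[-1], n_seg + 1)
    anchor_x, anchor_y = [], []
    for lo, hi in zip(edges[:-1], edges[1:]):
        mask = (s.mz >= lo) & (s.mz <= hi)
        if not mask.any():
            continue
        seg = s.intensity[mask]
        i_min = int(np.argmin(seg))
        seg_min = float(seg[i_min])
        spread = float(np.median(seg)) - seg_min  # robust to narrow tall peaks
        # anchor at the minimum's own position so sloping baselines are
        # reproduced exactly by the piecewise-linear interpolation
        anchor_x.append(float(s.mz[mask][i_min]))
        anchor_y.append(seg_min + cfg.baseline_relative_offset / 100.0 * spread)
    ax, ay = np.array(anchor_x), np.array(anchor_y)
    baseline = np.interp(s.mz, ax, ay)
    if ax.size >= 2:
        # extrapolate the end slopes instead of clamping, so ramps keep
        # being removed outside the outermost anchors
        left = s.mz < ax[0]
        right = s.mz > ax[-1]
        baseline[left] = ay[0] + (s.mz[left] - ax[0]) * (ay[1] - ay[0]) / (ax[1] - ax[0])
        baseline[right] = ay[-1] + (s.mz[right] - ax[-1]) * (ay[-1] - ay[-2]) / (
            ax[-1] - ax[-2]
        )
    corrected = np.clip(s.intensity - baseline, 0.0, None)
    return s.with_intensity(corrected, "baseline")


def _window_points(mz: np.ndarray, window_da: float) -> int:
    spacing = float(np.median(np.diff(mz)))
    n = int(round(window_da / spacing))
    if n % 2 == 0:
        n += 1
    return n


def smooth(s: Spectrum, cfg: PreprocessConfig = PreprocessConfig()) -> Spectrum:
    """Savitzky-Golay smoothing, window given in Da, polynomial order 2."""
    n = _window_points(s.mz, cfg.smooth_window)
    if n < 3 or n > len(s):
        logger.warning("smoothing window of %d points too small/large; skipping", n)
        return s.with_intensity(s.intensity.copy(), "smooth")
    window = max(n, 5)  # order-2 fit needs > 3 points to do anything
    y = s.intensity
    for _ in range(cfg.smooth_cycles):
        y = savgol_filter(y, window_length=window, polyorder=2)
    return s.with_intensity(np.clip(y, 0.0, None), "smooth")


def _windowed_stats(s: Spectrum, window_da: float) -> tuple[np.ndarray, np.ndarray]:
    """Per-point (noise sigma, background) via windowed median/MAD."""
    span = s.mz[-1] - s.mz[0]
    n_win = max(1, int(round(span / window_da)))
    edges = np.linspace(s.mz[0], s.mz[-1], n_win + 1)
    centers, levels, medians = [], [], []
    for lo, hi in zip(edges[:-1], edges[1:]):
        mask = (s.mz >= lo) & (s.mz <= hi)
        if not mask.any():
            continue
        seg = s.intensity[mask]
        med = float(np.median(seg))
        mad = float(np.median(np.abs(seg - med)))
        centers.append(0.5 * (lo + hi))
        levels.append(_MAD_SCALE * mad)
        medians.append(med)
    noise = np.interp(s.mz, centers, levels)
    background = np.interp(s.mz, centers, medians)
    floor = max(float(np.max(s.intensity)), 1.0) * np.finfo(float).eps * 10
    return np.maximum(noise, floor), background


def estimate_noise(s: Spectrum, window_da: float = 100.0) -> np.ndarray:
    """Per-point robust noise level: windowed MAD * 1.4826, interpolated.

    Computed on (baseline-corrected) intensities in windows of ``window_da``
    Da; strictly positive (floored at machine-epsilon scale) so S/N ratios
    are always defined.
    """
    return _windowed_stats(s, window_da)[0]


def _cross_at(mz: np.ndarray, y: np.ndarray, i_from: int, i_to_dir: int, level: float) -> float:
    """m/z where y crosses ``level`` walking from i_from in direction ±1."""
    i = i_from
    while 0 < i < len(y) - 1:
        j = i + i_to_dir
        if y[j] < level <= y[i]:
            # linear interpolation between the bracketing samples
            frac = (y[i] - level) / (y[i] - y[j])
            return float(mz[i] + frac * (mz[j] - mz[i]))
        if y[j] > y[i] and y[j] >= level and j != i_from:
            break  # climbing into a neighbouring peak before crossing
        i = j
    return float(mz[i_from])


def pick_peaks(
    s: Spectrum,
    cfg: PreprocessConfig = PreprocessConfig(),
    noise: np.ndarray | None = None,
) -> PeakList:
    """S/N-thresholded local maxima with centroids at fractional peak height.

    A local maximum is reported when its height above the local background
    (windowed median) reaches ``snr_threshold`` times the local noise sigma.
    ``noise`` may be supplied externally (the full chain estimates it before
    smoothing, since smoothing deflates the apparent noise and would inflate
    every S/N ratio).  The centroid m/z is the midpoint of the two linearly
    interpolated crossings of the profile at ``picking_height`` x apex; the
    reported intensity is the apex.
    """
    if "baseline" not in s.history or "smooth" not in s.history:
        logger.warning(
            "pick_peaks called on a spectrum without baseline/smooth preprocessing"
        )
    est_noise, background = _windowed_stats(s, cfg.noise_window)
    if noise is None:
        noise = est_noise
    idx, _ = find_peaks(s.intensity)
    peaks = []
    for i in idx:
        snr = (s.intensity[i] - background[i]) / noise[i]
        if snr < cfg.snr_threshold:
            continue
        level = cfg.picking_height * s.intensity[i]
        left = _cross_at(s.mz, s.intensity, i, -1, level)
        right = _cross_at(s.mz, s.intensity, i, +1, level)
        peaks.append(Peak(0.5 * (left + right), float(s.intensity[i]), float(snr)))
    return PeakList(sample_id=s.sample_id, replicate_index=s.replicate_index, peaks=peaks)


def preprocess(s: Spectrum, cfg: PreprocessConfig = PreprocessConfig()) -> PeakList:
    """Full chain: baseline -> noise estimate -> smooth -> pick.

    The noise level is taken from the baseline-corrected, *unsmoothed*
    profile so that "S/N = 3" keeps its meaning relative to the raw noise.
    """
    corrected = correct_baseline(s, cfg)
    noise = estimate_noise(corrected, cfg.noise_window)
    return pick_peaks(smooth(corrected, cfg), cfg, noise=noise)
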