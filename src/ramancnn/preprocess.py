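"""Spectral pre-processing: the manual four-step pipeline, the multi-method
baseline-correction channel bank, and per-feature standardisation.

The manual pipeline applies, in order: (i) iterative 5th-order polynomial
background subtraction, (ii) rubberband (lower convex hull) subtraction,
(iii) wavelet soft-threshold denoising, (iv) vector normalisation.

The channel bank stacks the raw spectrum (channel 0) with the raw spectrum
minus each registered baseline estimate — eight channels with the default
seven-method registry — producing the multi-channel CNN input.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pywt

from .baselines import DEFAULT_CHANNEL_METHODS, get_baseline_method
from .dataset import DegenerateInputError, FormatError, Spectrum

logger = logging.getLogger(__name__)

SD_FLOOR = 1e-8


# ---------------------------------------------------------------------------
# manual pipeline steps
# ---------------------------------------------------------------------------

def polynomial_baseline_subtract(
    intensities: np.ndarray,
    order: int = 5,
    *,
    iterative: bool = True,
    max_iter: int = 50,
) -> np.ndarray:
    """Subtract a least-squares polynomial background of the given degree.

    By default the fit is re-estimated iteratively on the points at or below
    the current fit, so peaks do not drag the polynomial upward.  With
    ``iterative=False`` a single plain least-squares fit is subtracted.
    """
    if order < 0:
        raise ValueError(f"polynomial order must be >= 0, got {order}")
    y = np.asarray(intensities, dtype=float)
    n = y.size
    if n <= order:
        raise ValueError(f"need more than order={order} points, got {n}")
    x = np.linspace(-1.0, 1.0, n)
    scale = max(np.max(np.abs(y)), 1e-300)
    tol = 1e-10 * scale
    support = np.ones(n, dtype=bool)
    coef = np.polynomial.polynomial.polyfit(x[support], y[support], order)
    fit = np.polynomial.polynomial.polyval(x, coef)
    if iterative:
        for _ in range(max_iter):
            new_support = y <= fit + tol
            if new_support.sum() <= order + 1:
                break
            if np.array_equal(new_support, support):
                break
            support = new_support
            coef = np.polynomial.polynomial.polyfit(x[support], y[support], order)
            fit = np.polynomial.polynomial.polyval(x, coef)
    return y - fit


def _lower_hull_indices(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Andrew's monotone chain, lower hull only; x must be increasing."""
    hull: list[int] = []
    for i in range(x.size):
        while len(hull) >= 2:
            j, k = hull[-2], hull[-1]
            # keep turn strictly clockwise: (k - j) x (i - j) >= 0 means k is
            # on or above the chord from j to i -> drop k
            cross = (x[k] - x[j]) * (y[i] - y[j]) - (y[k] - y[j]) * (x[i] - x[j])
            if cross <= 0:
                hull.pop()
            else:
                break
        hull.append(i)
    return np.asarray(hull, dtype=int)


def rubberband_subtract(wavenumbers: np.ndarray, intensities: np.ndarray) -> np.ndarray:
    """Subtract the lower convex hull of the spectrum (rubberband baseline).

    The output is non-negative everywhere and exactly zero at every hull
    vertex, in particular at both endpoints.
    """
    x = np.asarray(wavenumbers, dtype=float)
    y = np.asarray(intensities, dtype=float)
    if x.size != y.size or x.size < 2:
        raise ValueError("need >= 2 points with matching shapes")
    if not np.all(np.diff(x) > 0):
        raise ValueError("wavenumbers must be strictly increasing")
    idx = _lower_hull_indices(x, y)
    baseline = np.interp(x, x[idx], y[idx])
    out = y - baseline
    out[idx] = 0.0  # exact zeros at hull vertices
    return np.maximum(out, 0.0)


def wavelet_denoise(
    intensities: np.ndarray,
    level: int = 3,
    threshold_rule: str = "soft",
    *,
    wavelet: str = "sym4",
) -> np.ndarray:
    """Multi-level wavelet shrinkage with the universal threshold.

    The noise scale is the median absolute deviation of the finest detail
    coefficients; details are thresholded (soft by default) and the signal is
    reconstructed to the original length.
    """
    y = np.asarray(intensities, dtype=float)
    n = y.size
    if level < 1:
        raise ValueError("level must be >= 1")
    if n < 2**level:
        raise ValueError(f"signal of length {n} too short for level {level}")
    if threshold_rule not in ("soft", "hard"):
        raise ValueError("threshold_rule must be 'soft' or 'hard'")
    max_level = pywt.dwt_max_level(n, pywt.Wavelet(wavelet).dec_len)
    if level > max_level:
        raise ValueError(f"level {level} exceeds maximum {max_level} for length {n}")
    coeffs = pywt.wavedec(y, wavelet, level=level)
    finest = coeffs[-1]
    sigma = np.median(np.abs(finest - np.median(finest))) / 0.6745
    thresh = sigma * np.sqrt(2.0 * np.log(max(n, 2)))
    if thresh > 0:
        coeffs[1:] = [pywt.threshold(c, thresh, mode=threshold_rule) for c in coeffs[1:]]
    out = pywt.waverec(coeffs, wavelet)
    return out[:n]


def vector_normalize(intensities: np.ndarray) -> np.ndarray:
    """Scale to unit Euclidean norm."""
    y = np.asarray(intensities, dtype=float)
    norm = float(np.linalg.norm(y))
    if norm == 0.0:
        raise DegenerateInputError("cannot vector-normalise the all-zero spectrum")
    return y / norm


def manual_pipeline(spectrum: Spectrum, *, poly_order: int = 5,
                    wavelet_level: int = 3) -> Spectrum:
    """The four-step manual pre-processing pipeline; metadata preserved."""
    y = polynomial_baseline_subtract(spectrum.intensities, poly_order)
    y = rubberband_subtract(spectrum.wavenumbers, y)
    y = wavelet_denoise(y, wavelet_level)
    y = vector_normalize(y)
    return spectrum.with_intensities(y)


# ---------------------------------------------------------------------------
# channel bank
# ---------------------------------------------------------------------------

@dataclass
class MultiChannelSpectrum:
    """The C x W stack fed to the CNN: raw plus baseline-corrected variants."""

    channels: np.ndarray  # (C, W)
    channel_names: tuple[str, ...]
    metadata: dict

    def __post_init__(self) -> None:
        self.channels = np.asarray(self.channels, dtype=float)
        if self.channels.ndim != 2 or self.channels.shape[0] != len(self.channel_names):
            raise FormatError("channels must be (C, W) with C == len(channel_names)")
        if not np.all(np.isfinite(self.channels)):
            raise FormatError("channel values must be finite")

    @property
    def n_channels(self) -> int:
        return self.channels.shape[0]


def channel_bank(
    spectrum: Spectrum,
    method_names: Sequence[str] = DEFAULT_CHANNEL_METHODS,
) -> MultiChannelSpectrum:
    """Stack the raw spectrum with one baseline-corrected channel per method.

    Channel 0 is always the unmodified raw intensities.  A method returning
    non-finite values is flagged and its channel falls back to the raw
    spectrum with a logged warning.
    """
    raw = spectrum.intensities
    chans = [raw.copy()]
    names = ["raw"]
    for name in method_names:
        fn = get_baseline_method(name)
        baseline = fn(spectrum.wavenumbers, raw)
        corrected = raw - np.asarray(baseline, dtype=float)
        if not np.all(np.isfinite(corrected)):
            logger.warning(
                "baseline method %r produced non-finite values; channel replaced by raw", name
            )
            corrected = raw.copy()
        chans.append(corrected)
        names.append(name)
    return MultiChannelSpectrum(np.stack(chans), tuple(names), spectrum.metadata)


def stack_dataset(spectra: Iterable[Spectrum],
                  method_names: Sequence[str] = DEFAULT_CHANNEL_METHODS) -> np.ndarray:
    """(N, C, W) channel-bank stack for a whole collection of spectra."""
    return np.stack([channel_bank(s, method_names).channels for s in spectra])


# ---------------------------------------------------------------------------
# standardisation
# ---------------------------------------------------------------------------

@dataclass
class StandardizationStats:
    """Per-(channel, wavenumber) mean and sd fitted on a training fold."""

    mean: np.ndarray  # (C, W)
    sd: np.ndarray  # (C, W), floored
    n_fitted: int

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.sd = np.asarray(self.sd, dtype=float)
        if self.mean.shape != self.sd.shape:
            raise FormatError("mean and sd shapes differ")
        if np.any(self.sd < SD_FLOOR):
            raise FormatError(f"sd must be floored at {SD_FLOOR}")


def fit_standardizer(stack: np.ndarray) -> StandardizationStats:
    """Fit per-feature mean/sd (population convention) on training spectra.

    ``stack`` is (N, C, W) — or (N, W), treated as single-channel.
    """
    x = np.asarray(stack, dtype=float)
    if x.ndim == 2:
        x = x[:, None, :]
    if x.ndim != 3:
        raise ValueError("expected (N, C, W) or (N, W) input")
    if x.shape[0] < 2:
        raise ValueError("need at least 2 spectra to fit a standardizer")
    mean = x.mean(axis=0)
    sd = np.maximum(x.std(axis=0), SD_FLOOR)
    return StandardizationStats(mean=mean, sd=sd, n_fitted=x.shape[0])


def standardize(stack: np.ndarray, stats: StandardizationStats) -> np.ndarray:
    """(x - mean) / sd per (channel, wavenumber); shape preserved."""
    x = np.asarray(stack, dtype=float)
    squeeze = False
    if x.ndim == 2 and stats.mean.shape[0] == 1:
        x = x[:, None, :]
        squeeze = True
    if x.shape[-2:] != stats.mean.shape:
        raise ValueError(f"shape {x.shape} does not match stats {stats.mean.shape}")
    out = (x - stats.mean) / stats.sd
    return out[:, 0, :] if squeeze else out
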