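"""The 11 heart-rate-variability parameters of one 5-minute window.

Conventions (fixed here because they make the Poincare identities exact
and are applied consistently):

* SDNN and SD1 use the population standard deviation (divide by n).
* SD1 is computed around zero successive difference, i.e.
  ``sd1 = rmssd / sqrt(2)`` exactly, and
  ``sd2 = sqrt(2*sdnn**2 - sd1**2)``, so ``sd1^2 + sd2^2 = 2*sdnn^2``.
* pNN50 uses a strict inequality (> 50 ms).
* Band powers are reported in s^2.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from scipy.interpolate import CubicSpline

from .rr_preprocess import NNSeries

__all__ = [
    "SpectralBands",
    "Tachogram",
    "TACHOGRAM_FS",
    "time_domain",
    "resample_tachogram",
    "detrend_highpass",
    "welch_psd",
    "welch_band_powers",
    "poincare",
    "hrv_vector",
]

TACHOGRAM_FS = 7.0
PNN_THRESHOLD_S = 0.050


@dataclass(frozen=True)
class SpectralBands:
    """Frequency-band edges (Hz) for tachogram spectral powers."""

    vlf: tuple[float, float] = (0.0, 0.04)
    lf: tuple[float, float] = (0.04, 0.15)
    hf: tuple[float, float] = (0.15, 0.40)


@dataclass(frozen=True)
class Tachogram:
    """NN intervals resampled to a uniform signal at 7 Hz."""

    values: np.ndarray
    fs: float = TACHOGRAM_FS
    detrended: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))


def time_domain(nn: NNSeries | np.ndarray) -> tuple[float, float, float, float]:
    """Return ``(mean_nn, sdnn, rmssd, pnn50)``.

    ``sdnn`` is the population SD; ``rmssd`` the root mean square of
    successive differences; ``pnn50`` the proportion of successive
    differences strictly exceeding 50 ms.
    """
    x = nn.nn if isinstance(nn, NNSeries) else np.asarray(nn, dtype=float)
    if len(x) < 2:
        raise ValueError("need at least 2 NN intervals")
    diffs = np.diff(x)
    mean_nn = float(np.mean(x))
    sdnn = float(np.std(x))
    rmssd = float(np.sqrt(np.mean(diffs**2)))
    pnn50 = float(np.mean(np.abs(diffs) > PNN_THRESHOLD_S))
    return mean_nn, sdnn, rmssd, pnn50


def resample_tachogram(nn: NNSeries | np.ndarray,
                       beat_times: np.ndarray | None = None,
                       fs: float = TACHOGRAM_FS) -> Tachogram:
    """Cubic-spline resample the NN sequence onto a uniform grid.

    Each interval's value is attached to the time of the beat that ends
    it; the spline is sampled at ``fs`` over the interior span.
    """
    if isinstance(nn, NNSeries):
        values = nn.nn
        if beat_times is None:
            beat_times = nn.beat_times
    else:
        values = np.asarray(nn, dtype=float)
    if beat_times is None:
        raise ValueError("beat_times required when nn is a bare array")
    beat_times = np.asarray(beat_times, dtype=float)
    if len(values) < 4:
        raise ValueError("need at least 4 NN intervals for cubic-spline resampling")
    if len(beat_times) != len(values) + 1:
        raise ValueError("beat_times must have len(nn) + 1 entries")
    anchor = beat_times[1:]
    spline = CubicSpline(anchor, values)
    n = int(math.floor((anchor[-1] - anchor[0]) * fs)) + 1
    grid = anchor[0] + np.arange(n) / fs
    return Tachogram(values=spline(grid), fs=fs, detrended=False)


def _lowpass_trend(x: np.ndarray, fs: float, cutoff: float) -> np.ndarray:
    """Zero-phase FIR low-pass via symmetric kernel + odd-reflect padding.

    Odd reflection continues linear trends exactly, so constants and
    ramps are reproduced (and thus removed exactly by the high-pass
    complement).
    """
    numtaps = int(round(90.0 * fs))
    numtaps |= 1
    max_taps = 2 * len(x) - 1
    if numtaps > max_taps:
        numtaps = max_taps if max_taps % 2 == 1 else max_taps - 1
    kernel = sps.firwin(numtaps, cutoff, fs=fs)
    pad = numtaps // 2
    padded = np.pad(x, pad, mode="reflect", reflect_type="odd")
    return sps.fftconvolve(padded, kernel, mode="same")[pad:-pad]


def detrend_highpass(t: Tachogram, cutoff: float = 0.035) -> Tachogram:
    """Remove the mean and slow trend (< ~0.035 Hz) from a tachogram.

    Realized as the complement of a zero-phase FIR low-pass: DC and
    linear ramps are removed to numerical precision, while a 0.3 Hz
    oscillation passes essentially unchanged.
    """
    x = t.values
    trend = _lowpass_trend(x, t.fs, cutoff)
    return Tachogram(values=x - trend, fs=t.fs, detrended=True)


def welch_psd(x: np.ndarray, fs: float, nperseg: int | None = None,
              window: str = "hann") -> tuple[np.ndarray, np.ndarray]:
    """One-sided Welch PSD (density scaling, 50% overlap, no detrending).

    Default segmentation is 512-sample Hann windows; shorter signals fall
    back to the largest power of two that fits (with a warning).
    """
    x = np.asarray(x, dtype=float)
    if nperseg is None:
        nperseg = 512
    if nperseg > len(x):
        nperseg = 2 ** int(math.floor(math.log2(len(x))))
        warnings.warn(
            f"signal shorter than a full Welch segment; using nperseg={nperseg}",
            stacklevel=2,
        )
    freqs, psd = sps.welch(x, fs=fs, window=window, nperseg=nperseg,
                           noverlap=nperseg // 2, detrend=False,
                           scaling="density")
    return freqs, psd


def _band_power(freqs: np.ndarray, psd: np.ndarray, band: tuple[float, float]) -> float:
    """Trapezoidal integral of the PSD over ``band``, with edge interpolation."""
    lo, hi = band
    lo = max(lo, freqs[0])
    hi = min(hi, freqs[-1])
    if hi <= lo:
        return 0.0
    inner = freqs[(freqs > lo) & (freqs < hi)]
    grid = np.concatenate(([lo], inner, [hi]))
    vals = np.interp(grid, freqs, psd)
    return float(np.trapezoid(vals, grid))


def welch_band_powers(t: Tachogram, bands: SpectralBands | None = None,
                      ) -> tuple[float, float, float, float]:
    """Return ``(vlf, lf, hf, lf_hf)`` band powers in s^2.

    Powers are trapezoidal integrals of the Welch PSD (512-point Hann
    segments, 50% overlap, density normalization) over each band;
    ``lf_hf`` is NaN when the HF power vanishes.
    """
    bands = bands or SpectralBands()
    freqs, psd = welch_psd(t.values, t.fs)
    vlf = _band_power(freqs, psd, bands.vlf)
    lf = _band_power(freqs, psd, bands.lf)
    hf = _band_power(freqs, psd, bands.hf)
    lf_hf = lf / hf if hf > 0 else float("nan")
    return vlf, lf, hf, lf_hf


def poincare(nn: NNSeries | np.ndarray) -> tuple[float, float, float]:
    """Return ``(sd1, sd2, sd1_sd2)`` of the lag-1 Poincare plot.

    SD1 is the dispersion perpendicular to the identity line, taken
    around zero difference (``rmssd/sqrt(2)``); SD2 follows from
    ``sd2 = sqrt(2*sdnn^2 - sd1^2)``.  The ratio is NaN when SD2 = 0.
    """
    x = nn.nn if isinstance(nn, NNSeries) else np.asarray(nn, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 NN intervals for Poincare analysis")
    diffs = np.diff(x)
    sd1 = float(np.sqrt(np.mean(diffs**2) / 2.0))
    sdnn = float(np.std(x))
    sd2 = float(np.sqrt(max(0.0, 2.0 * sdnn**2 - sd1**2)))
    ratio = sd1 / sd2 if sd2 > 0 else float("nan")
    return sd1, sd2, ratio


def hrv_vector(nn: NNSeries, beat_times: np.ndarray | None = None) -> dict[str, float]:
    """All 11 HRV parameters as a name->value dict (table order)."""
    mean_nn, sdnn, rmssd, pnn50 = time_domain(nn)
    tach = detrend_highpass(resample_tachogram(nn, beat_times))
    vlf, lf, hf, lf_hf = welch_band_powers(tach)
    sd1, sd2, sd1_sd2 = poincare(nn)
    return {
        "mean_nn": mean_nn, "sdnn": sdnn, "rmssd": rmssd, "pnn50": pnn50,
        "vlf": vlf, "lf": lf, "hf": hf, "lf_hf": lf_hf,
        "sd1": sd1, "sd2": sd2, "sd1_sd2": sd1_sd2,
    }
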