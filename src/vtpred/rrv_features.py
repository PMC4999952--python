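"""The 3 respiratory-rate-variability parameters.

Respiration is band-passed to 0.1-0.5 Hz, positive peaks are located
with the delta detector, and the breath-to-breath period statistics
RPdM / RPdSD / RPdV are computed.  RPdSD uses the sample SD (n-1):
breath counts per window are small.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import signal as sps

from .peak_detection import detect_peaks_delta
from .signal_io import WaveformRecord

__all__ = ["BreathSeries", "bandpass_resp", "breath_series", "rrv_stats",
           "rrv_vector", "InsufficientBreathsError"]

logger = logging.getLogger(__name__)

RESP_BAND = (0.1, 0.5)
PLAUSIBLE_PERIOD_S = (1.0, 10.0)


class InsufficientBreathsError(ValueError):
    """Fewer than 3 breath peaks available."""


@lru_cache(maxsize=32)
def _design_bandpass(order: int, lo: float, hi: float, fs: float) -> np.ndarray:
    nyq = fs / 2.0
    return sps.butter(order, [lo / nyq, hi / nyq], btype="band", output="sos")


@dataclass(frozen=True)
class BreathSeries:
    """Positive-peak times (s) and breath periods (s)."""

    peak_times: np.ndarray
    periods: np.ndarray

    def __post_init__(self) -> None:
        pt = np.asarray(self.peak_times, dtype=float)
        object.__setattr__(self, "peak_times", pt)
        object.__setattr__(self, "periods", np.diff(pt))
        if np.any(self.periods <= 0):
            raise ValueError("breath periods must be positive")
        lo, hi = PLAUSIBLE_PERIOD_S
        if np.any((self.periods < lo) | (self.periods > hi)):
            logger.info("breath periods outside the plausible %s-%s s range", lo, hi)


def bandpass_resp(resp: WaveformRecord, band: tuple[float, float] = RESP_BAND,
                  order: int = 4) -> WaveformRecord:
    """Zero-phase Butterworth band-pass (0.1-0.5 Hz by default)."""
    if resp.fs <= 2 * band[1]:
        raise ValueError(
            f"sampling rate {resp.fs} Hz too low for a {band[0]}-{band[1]} Hz passband"
        )
    sos = _design_bandpass(order, band[0], band[1], resp.fs)
    filtered = sps.sosfiltfilt(sos, resp.samples - np.mean(resp.samples))
    return WaveformRecord(samples=filtered, fs=resp.fs, channel=resp.channel, t0=resp.t0)


def breath_series(resp: WaveformRecord, delta: float | None = None) -> BreathSeries:
    """Band-pass then locate positive peaks.

    ``delta`` defaults to 0.2 x the interquartile range of the filtered
    signal (scale-adaptive: respiration amplitude units are arbitrary).
    """
    filtered = bandpass_resp(resp)
    if delta is None:
        q75, q25 = np.percentile(filtered.samples, [75, 25])
        delta = 0.2 * (q75 - q25)
        if delta <= 0:
            raise InsufficientBreathsError("insufficient breaths (flat signal)")
    peaks = detect_peaks_delta(filtered, delta)
    # keep only positive peaks
    positive = peaks.indices[filtered.samples[peaks.indices] > 0]
    if len(positive) < 3:
        raise InsufficientBreathsError("insufficient breaths")
    return BreathSeries(peak_times=filtered.t0 + positive / filtered.fs,
                        periods=np.empty(0))


def rrv_stats(periods: np.ndarray) -> dict[str, float]:
    """Period statistics: mean, sample SD, and their ratio as a percent."""
    periods = np.asarray(periods, dtype=float)
    rpdm = float(np.mean(periods))
    rpdsd = float(np.std(periods, ddof=1)) if len(periods) > 1 else 0.0
    rpdv = 100.0 * rpdsd / rpdm if rpdm > 0 else float("nan")
    return {"rpdm": rpdm, "rpdsd": rpdsd, "rpdv": rpdv}


def rrv_vector(resp: WaveformRecord, delta: float | None = None) -> dict[str, float]:
    """Return ``{"rpdm", "rpdsd", "rpdv"}`` from a respiration window.

    rpdm = mean breath period (s); rpdsd = sample SD of the periods (s);
    rpdv = 100 * rpdsd / rpdm (percent).
    """
    return rrv_stats(breath_series(resp, delta=delta).periods)
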