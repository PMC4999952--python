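"""R-peak detection in ECG and delta-prominence peak detection.

Two detectors live here:

* :func:`detect_r_peaks` — a filter/transform/threshold QRS detector
  (band-pass, differentiate, square, moving-window integrate, adaptive
  threshold, 200 ms refractory) followed by refinement to the raw-signal
  local maximum.
* :func:`detect_peaks_delta` — the classic alternating max/min scan that
  reports a local maximum once the signal has dropped by at least
  ``delta`` below it.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import signal as sps

from .signal_io import Channel, WaveformRecord

__all__ = [
    "BeatSeries",
    "PeakList",
    "RPeakConfig",
    "detect_r_peaks",
    "detect_peaks_delta",
    "InsufficientBeatsError",
]


class InsufficientBeatsError(ValueError):
    """Raised when fewer than two beats can be located."""


@dataclass(frozen=True)
class BeatSeries:
    """R-peak times (s) and the successive RR intervals (s)."""

    peak_times: np.ndarray
    rr: np.ndarray

    def __post_init__(self) -> None:
        pt = np.asarray(self.peak_times, dtype=float)
        if pt.ndim != 1 or len(pt) < 2:
            raise InsufficientBeatsError("insufficient beats")
        if np.any(np.diff(pt) <= 0):
            raise ValueError("peak times must be strictly increasing")
        object.__setattr__(self, "peak_times", pt)
        object.__setattr__(self, "rr", np.diff(pt))

    @classmethod
    def from_times(cls, peak_times: np.ndarray) -> "BeatSeries":
        peak_times = np.asarray(peak_times, dtype=float)
        return cls(peak_times=peak_times, rr=np.diff(peak_times))

    def __len__(self) -> int:
        return len(self.peak_times)


@dataclass(frozen=True)
class PeakList:
    """Local-maximum sample indices and their times."""

    indices: np.ndarray
    times: np.ndarray

    def __post_init__(self) -> None:
        idx = np.asarray(self.indices, dtype=int)
        if idx.ndim != 1:
            raise ValueError("indices must be 1-D")
        if len(idx) > 1 and np.any(np.diff(idx) <= 0):
            raise ValueError("indices must be strictly increasing")
        object.__setattr__(self, "indices", idx)
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))

    def __len__(self) -> int:
        return len(self.indices)


@dataclass(frozen=True)
class RPeakConfig:
    """Settings for :func:`detect_r_peaks`."""

    band: tuple[float, float] = (5.0, 15.0)     # QRS energy band, Hz
    integration_window_s: float = 0.150
    refractory_s: float = 0.200
    threshold_fraction: float = 0.25            # of the robust envelope peak
    refine_halfwidth_s: float = 0.050
    edge_margin_s: float = 0.25


@lru_cache(maxsize=32)
def _design_qrs_band(lo: float, hi: float, fs: float) -> np.ndarray:
    nyq = fs / 2.0
    return sps.butter(3, [lo / nyq, hi / nyq], btype="band", output="sos")


def _moving_integrate(x: np.ndarray, width: int) -> np.ndarray:
    kernel = np.ones(width) / width
    return np.convolve(x, kernel, mode="same")


def detect_r_peaks(ecg: WaveformRecord, cfg: RPeakConfig | None = None) -> BeatSeries:
    """Locate R-peaks in a lead-II ECG window.

    The fiducial points come from an adaptive threshold on the
    band-passed/differentiated/squared/integrated transform; each is then
    refined to the local maximum of the *raw* signal within +-50 ms.  A
    200 ms refractory period is enforced and peaks within 0.25 s of the
    window edges are discarded (incomplete morphology).

    Raises
    ------
    InsufficientBeatsError
        If fewer than two beats are found.
    """
    cfg = cfg or RPeakConfig()
    if ecg.channel is not Channel.ECG_II:
        raise ValueError("R-peak detection expects an ECG_II record")
    if ecg.duration < 10.0:
        raise ValueError("window too short for R-peak detection (< 10 s)")
    fs = ecg.fs
    x = ecg.samples - np.mean(ecg.samples)

    nyq = fs / 2.0
    hi = min(cfg.band[1], 0.95 * nyq)
    filtered = sps.sosfiltfilt(_design_qrs_band(cfg.band[0], hi, fs), x)
    transformed = np.gradient(filtered) ** 2
    width = max(1, int(round(cfg.integration_window_s * fs)))
    envelope = _moving_integrate(transformed, width)

    # robust envelope scale: 98th percentile tolerates a few huge artifacts
    scale = np.percentile(envelope, 98)
    if scale <= 0:
        raise InsufficientBeatsError("insufficient beats")
    threshold = cfg.threshold_fraction * scale
    distance = max(1, int(round(cfg.refractory_s * fs)))
    fiducials, _ = sps.find_peaks(envelope, height=threshold, distance=distance)

    # refine each fiducial to the raw-signal maximum within +-50 ms
    half = max(1, int(round(cfg.refine_halfwidth_s * fs)))
    refined = []
    for f in fiducials:
        lo, hi_i = max(0, f - half), min(len(x), f + half + 1)
        refined.append(lo + int(np.argmax(ecg.samples[lo:hi_i])))
    refined = np.unique(refined)

    # drop peaks near the window edges
    margin = cfg.edge_margin_s * fs
    refined = refined[(refined >= margin) & (refined <= len(x) - 1 - margin)]

    # enforce refractory on refined peaks: keep the larger of close pairs
    keep: list[int] = []
    for idx in refined:
        if keep and (idx - keep[-1]) < distance:
            if ecg.samples[idx] > ecg.samples[keep[-1]]:
                keep[-1] = int(idx)
        else:
            keep.append(int(idx))
    if len(keep) < 2:
        raise InsufficientBeatsError("insufficient beats")
    times = ecg.t0 + np.asarray(keep) / fs
    return BeatSeries.from_times(times)


def detect_peaks_delta(signal: WaveformRecord | np.ndarray, delta: float,
                       fs: float | None = None) -> PeakList:
    """Alternating max/min peak detection.

    A local maximum is reported once the signal subsequently drops by at
    least ``delta`` below it; the search then looks for a minimum, and so
    on.  Equivalent to a brute-force prominence scan on small inputs.

    Parameters
    ----------
    signal:
        Waveform record, or a bare sample array (then ``fs`` is needed to
        produce times; defaults to 1 Hz).
    delta:
        Required drop in signal units; must be > 0.
    """
    if delta <= 0 or not np.isfinite(delta):
        raise ValueError(f"delta must be positive, got {delta}")
    if isinstance(signal, WaveformRecord):
        x = signal.samples
        fs = signal.fs
        t0 = signal.t0
    else:
        x = np.asarray(signal, dtype=float)
        fs = fs or 1.0
        t0 = 0.0

    peaks: list[int] = []
    mn, mx = np.inf, -np.inf
    mx_pos = 0
    looking_for_max = True
    for i, v in enumerate(x):
        if v > mx:
            mx, mx_pos = v, i
        if v < mn:
            mn = v
        if looking_for_max:
            if v < mx - delta:
                peaks.append(mx_pos)
                mn = v
                looking_for_max = False
        else:
            if v > mn + delta:
                mx, mx_pos = v, i
                looking_for_max = True
    indices = np.asarray(peaks, dtype=int)
    return PeakList(indices=indices, times=t0 + indices / fs)
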