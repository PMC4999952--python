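"""Ectopic-beat handling on RR interval series.

Ectopic beats (premature beat + compensatory pause) corrupt the RR
sequence with a short/long interval pair.  They are first *flagged* by a
running-median rule on the intervals, then *corrected* under the
integrated pulse frequency modulation (IPFM) view of beat generation:
the k-th beat time t_k satisfies  integral_0^{t_k} (1 + m(t)) dt = k*T,
so the cumulative beat index is a smooth, monotone function of time.
Flagged beat times are re-estimated by monotone-cubic interpolation of
that index-vs-time function through the clean beats.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import PchipInterpolator

from .peak_detection import BeatSeries

__all__ = ["NNSeries", "flag_ectopic", "correct_ectopic_ipfm", "preprocess_rr"]

DEFAULT_TOL = 0.2


@dataclass(frozen=True)
class NNSeries:
    """Ectopic-corrected normal-to-normal intervals.

    Attributes
    ----------
    nn:
        Corrected intervals in seconds, all > 0.
    beat_times:
        Corrected beat times; ``len(beat_times) == len(nn) + 1``.
    ectopic_mask:
        Flags on the *original* beats (True = treated as ectopic).
    n_corrected:
        Number of beats whose time was modified or dropped.
    """

    nn: np.ndarray
    beat_times: np.ndarray
    ectopic_mask: np.ndarray
    n_corrected: int = 0

    def __post_init__(self) -> None:
        nn = np.asarray(self.nn, dtype=float)
        if len(nn) < 2:
            raise ValueError("NN series needs at least 2 intervals")
        if np.any(nn <= 0):
            raise ValueError("NN intervals must be positive")
        object.__setattr__(self, "nn", nn)
        object.__setattr__(self, "beat_times", np.asarray(self.beat_times, dtype=float))
        object.__setattr__(self, "ectopic_mask", np.asarray(self.ectopic_mask, dtype=bool))

    def __len__(self) -> int:
        return len(self.nn)


def _interval_reference(rr: np.ndarray, i: int, flagged: np.ndarray, k: int = 5) -> float:
    """Median of the ~k nearest intervals around i, skipping flagged ones.

    Left neighbours use the flags decided so far (left-to-right pass);
    right neighbours are taken as-is since they are still unclassified.
    """
    left = [rr[j] for j in range(i - 1, -1, -1) if not flagged[j]]
    right = [rr[j] for j in range(i + 1, len(rr))]
    half = k // 2
    window = left[:half][::-1] + right[: k - min(half, len(left))]
    # top up from the left if the right side ran short
    need = k - len(window)
    if need > 0:
        window = left[half : half + need][::-1] + window
    if not window:
        return float(np.median(rr))
    return float(np.median(window))


def _references_no_flags(rr: np.ndarray) -> np.ndarray:
    """Vectorized :func:`_interval_reference` for an all-clear flag state.

    Interior intervals (2 left and 3 right neighbours available) use a
    sliding-window median; the few edge intervals fall back to the scalar
    routine.
    """
    n = len(rr)
    refs = np.empty(n)
    no_flags = np.zeros(n, dtype=bool)
    if n >= 6:
        # window for interval i: [i-2, i-1, i+1, i+2, i+3]
        windows = np.lib.stride_tricks.sliding_window_view(rr, 6)[:, [0, 1, 3, 4, 5]]
        refs[2:n - 3] = np.median(windows, axis=1)
    for i in (*range(min(2, n)), *range(max(0, n - 3), n)):
        refs[i] = _interval_reference(rr, i, no_flags)
    return refs


def flag_ectopic(beats: BeatSeries, tol: float = DEFAULT_TOL,
                 nsigma: float = 4.5) -> np.ndarray:
    """Flag beats adjacent to anomalous RR intervals.

    An interval is anomalous when it deviates from the running median of
    the 5 surrounding unflagged intervals by more than
    ``max(tol * reference, nsigma * sigma_short)``, where ``sigma_short``
    is a MAD-based estimate of the series' own short-range variability
    (deviation from a centred 5-point median filter).  The robust floor
    keeps genuinely variable sinus rhythm from being flagged wholesale;
    a premature beat + compensatory pause still stands far outside both
    terms.  A beat is flagged when either of its bounding intervals is
    anomalous.  Deterministic single left-to-right pass.

    Returns a boolean mask over the beats (length ``len(beats)``).
    """
    rr = beats.rr
    if len(rr) < 5:
        raise ValueError("too-short series for ectopic flagging (need >= 5 intervals)")
    n = len(rr)
    interval_flag = np.zeros(n, dtype=bool)
    if np.isfinite(tol):
        from scipy.signal import medfilt

        # interior-only MAD (medfilt zero-pads the edges); the floor is
        # meaningless on short series where one ectopic dominates it
        if n >= 20:
            core = (rr - medfilt(rr, 5))[2:-2]
            sigma_short = 1.4826 * float(np.median(np.abs(core)))
        else:
            sigma_short = 0.0
        refs0 = _references_no_flags(rr)
        for i in range(n):
            # the precomputed no-flag reference is exact unless a flag
            # was raised in the 5-interval left lookback
            if interval_flag[max(0, i - 6):i].any():
                ref = _interval_reference(rr, i, interval_flag)
            else:
                ref = refs0[i]
            if ref > 0 and abs(rr[i] - ref) > max(tol * ref, nsigma * sigma_short):
                interval_flag[i] = True
    mask = np.zeros(len(beats), dtype=bool)
    mask[:-1] |= interval_flag   # beat starting the interval
    mask[1:] |= interval_flag    # beat ending the interval
    return mask


def correct_ectopic_ipfm(beats: BeatSeries, ectopic_mask: np.ndarray) -> NNSeries:
    """Re-estimate flagged beat times via the IPFM index function.

    Clean beats keep their times and integer indices; each flagged beat's
    time is re-read off a monotone cubic (PCHIP) fit of time vs beat
    index through the clean beats.  Flagged beats at the series edges
    have no two-sided support and are dropped.  With an all-false mask
    the input is returned unchanged.
    """
    ectopic_mask = np.asarray(ectopic_mask, dtype=bool)
    if ectopic_mask.shape != (len(beats),):
        raise ValueError("ectopic_mask length must match number of beats")
    times = beats.peak_times
    clean_idx = np.flatnonzero(~ectopic_mask)
    if len(clean_idx) < 4:
        raise ValueError("fewer than 4 clean beats; cannot correct")

    if not ectopic_mask.any():
        return NNSeries(nn=beats.rr.copy(), beat_times=times.copy(),
                        ectopic_mask=ectopic_mask, n_corrected=0)

    # interior flagged beats: interpolate time as a function of index
    lo, hi = clean_idx[0], clean_idx[-1]
    index_to_time = PchipInterpolator(clean_idx, times[clean_idx])
    new_times = times.copy().astype(float)
    interior_flagged = np.flatnonzero(ectopic_mask & (np.arange(len(beats)) > lo)
                                      & (np.arange(len(beats)) < hi))
    new_times[interior_flagged] = index_to_time(interior_flagged)

    # edge-flagged beats are dropped entirely
    keep = np.ones(len(beats), dtype=bool)
    keep[np.flatnonzero(ectopic_mask & ((np.arange(len(beats)) <= lo)
                                        | (np.arange(len(beats)) >= hi)))] = False
    kept_times = new_times[keep]
    n_corrected = int(len(interior_flagged) + (~keep).sum())
    return NNSeries(nn=np.diff(kept_times), beat_times=kept_times,
                    ectopic_mask=ectopic_mask, n_corrected=n_corrected)


def preprocess_rr(beats: BeatSeries, tol: float = DEFAULT_TOL,
                  max_passes: int = 5) -> NNSeries:
    """Flag then correct, iterated to a fixpoint.

    Correcting beats slightly lowers the series' robust variability
    estimate, which can expose borderline intervals on a re-scan; the
    loop repeats flag + correct until a pass flags nothing (idempotence
    by construction) or ``max_passes`` is reached.
    """
    mask0 = flag_ectopic(beats, tol=tol)
    out = correct_ectopic_ipfm(beats, mask0)
    for _ in range(max_passes - 1):
        current = BeatSeries.from_times(out.beat_times)
        mask = flag_ectopic(current, tol=tol)
        if not mask.any():
            break
        corrected = correct_ectopic_ipfm(current, mask)
        out = NNSeries(nn=corrected.nn, beat_times=corrected.beat_times,
                       ectopic_mask=out.ectopic_mask,
                       n_corrected=out.n_corrected + corrected.n_corrected)
    return out
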