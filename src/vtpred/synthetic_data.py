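"""Synthetic ECG + respiration cohorts with controllable HRV/RRV statistics.

The study's CCU recordings are not public, so this module emulates them:

* RR series come from an integrated pulse frequency modulation (IPFM)
  forward model — a beat fires whenever the integral of ``(1 + m(t))/T``
  crosses the next integer — with ``m(t)`` a sum of an LF tone, an HF
  tone and band-limited noise scaled to a target SDNN.
* ECG is rendered as stereotyped P-QRS-T Gaussian templates at the beat
  times; ectopic beats are injected as premature beats with preserved
  compensatory pauses.
* Respiration is a phase-continuous cosine whose successive peak-to-peak
  periods follow a truncated normal with target mean / SD.

Two cohort generators are provided: waveform-level (`gen_cohort`,
exercising the whole extraction pipeline) and feature-level
(`gen_feature_cohort`, drawing the 14 parameters directly from the
group statistics for fast classifier fixtures).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy.integrate import cumulative_trapezoid

from .signal_io import Channel, FEATURE_NAMES, WaveformRecord, LabeledWindow

__all__ = [
    "GroupStats",
    "SimConfig",
    "default_group_stats",
    "gen_rr_series",
    "gen_ecg_from_rr",
    "inject_ectopics",
    "gen_resp",
    "gen_cohort",
    "gen_feature_cohort",
]

LF_TONE_HZ = 0.095
HF_TONE_HZ = 0.275

#: Reference per-group feature statistics (mean, SD), in seconds / s^2 / %.
_CONTROL_STATS: dict[str, tuple[float, float]] = {
    "mean_nn": (0.709, 0.149),
    "sdnn": (0.061, 0.042),
    "rmssd": (0.068, 0.053),
    "pnn50": (0.209, 0.224),
    "vlf": (4.1e-05, 6.54e-05),
    "lf": (7.61e-04, 1.16e-03),
    "hf": (1.53e-03, 2.02e-03),
    "lf_hf": (0.498, 0.372),
    "sd1": (0.039, 0.029),
    "sd2": (0.081, 0.057),
    "sd1_sd2": (0.466, 0.169),
    "rpdm": (2.73, 0.817),
    "rpdsd": (0.721, 0.578),
    "rpdv": (28.4, 5.31),
}

_VT_STATS: dict[str, tuple[float, float]] = {
    "mean_nn": (0.718, 0.158),
    "sdnn": (0.073, 0.045),
    "rmssd": (0.081, 0.057),
    "pnn50": (0.239, 0.205),
    "vlf": (6.23e-05, 9.81e-05),
    "lf": (1.04e-03, 1.15e-03),
    "hf": (1.96e-03, 2.16e-03),
    "lf_hf": (0.533, 0.435),
    "sd1": (0.047, 0.032),
    "sd2": (0.098, 0.060),
    "sd1_sd2": (0.469, 0.164),
    "rpdm": (2.95, 0.871),
    "rpdsd": (0.915, 0.868),
    "rpdv": (25.4, 3.56),
}


@dataclass(frozen=True)
class GroupStats:
    """Per-parameter (mean, SD) for the control and pre-VT groups."""

    control: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(_CONTROL_STATS))
    vt: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(_VT_STATS))

    def __post_init__(self) -> None:
        for group in (self.control, self.vt):
            missing = set(FEATURE_NAMES) - set(group)
            if missing:
                raise ValueError(f"missing parameters in group stats: {sorted(missing)}")
            for name, (_, sd) in group.items():
                if sd < 0:
                    raise ValueError(f"negative SD for {name}")

    def for_label(self, label: int) -> dict[str, tuple[float, float]]:
        return self.vt if label > 0 else self.control


def default_group_stats() -> GroupStats:
    """Built-in reference statistics for the two groups."""
    return GroupStats()


@dataclass(frozen=True)
class SimConfig:
    """Cohort simulation settings; ``seed`` is mandatory."""

    seed: int
    n_per_group: int = 52
    duration_s: float = 300.0
    ecg_fs: float = 250.0
    resp_fs: float = 62.5
    ectopic_rate_per_min: float = 1.0
    ecg_noise_sd: float = 0.03
    resp_noise_sd: float = 0.02

    def __post_init__(self) -> None:
        if self.duration_s < 60:
            raise ValueError("window duration must be at least 60 s")
        if self.n_per_group < 1:
            raise ValueError("n_per_group must be >= 1")


def _trunc_normal(rng: np.random.Generator, mean: float, sd: float,
                  lo: float, hi: float, size: int | None = None) -> np.ndarray | float:
    """Normal draw truncated to [lo, hi] by resampling (clip fallback)."""
    n = size or 1
    out = rng.normal(mean, sd, size=n)
    for _ in range(100):
        bad = (out < lo) | (out > hi)
        if not bad.any():
            break
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
    out = np.clip(out, lo, hi)
    return out if size is not None else float(out[0])


def gen_rr_series(mean_nn: float, sdnn_target: float, lf_frac: float,
                  hf_frac: float, duration: float, seed: int,
                  lf_freq: float = LF_TONE_HZ, hf_freq: float = HF_TONE_HZ,
                  ) -> tuple[np.ndarray, np.ndarray]:
    """IPFM-generated beat times and RR intervals.

    The modulation ``m(t)`` mixes an LF tone, an HF tone and band-limited
    noise; their variances are split per ``lf_frac`` / ``hf_frac`` (the
    remainder goes to noise) and scaled so the realized SDNN approximates
    ``sdnn_target``.  Tone amplitudes are pre-compensated for the
    low-pass effect of integrating the modulation over each beat.

    Returns ``(beat_times, rr)``.
    """
    if not 0.3 <= mean_nn <= 2.0:
        raise ValueError(f"mean_nn {mean_nn} outside the supported 0.3-2.0 s range")
    if sdnn_target < 0 or sdnn_target > 0.5 * mean_nn:
        raise ValueError("infeasible sdnn target (must be in [0, 0.5*mean_nn])")
    if not (0 <= lf_frac <= 1 and 0 <= hf_frac <= 1 and lf_frac + hf_frac <= 1):
        raise ValueError("lf_frac and hf_frac must be in [0,1] and sum to <= 1")

    rng = np.random.default_rng(seed)
    grid_fs = 8.0
    t = np.arange(0.0, duration + 1.0 / grid_fs, 1.0 / grid_fs)
    sigma_m = sdnn_target / mean_nn

    m = np.zeros_like(t)
    if sigma_m > 0:
        phi1, phi2 = rng.uniform(0, 2 * np.pi, size=2)
        a_lf = sigma_m * np.sqrt(2.0 * lf_frac) / np.sinc(lf_freq * mean_nn)
        a_hf = sigma_m * np.sqrt(2.0 * hf_frac) / np.sinc(hf_freq * mean_nn)
        m = (a_lf * np.cos(2 * np.pi * lf_freq * t + phi1)
             + a_hf * np.cos(2 * np.pi * hf_freq * t + phi2))
        noise_var = sigma_m**2 * (1.0 - lf_frac - hf_frac)
        if noise_var > 0:
            white = rng.standard_normal(len(t))
            sos = sps.butter(4, [0.035 / (grid_fs / 2), 0.40 / (grid_fs / 2)],
                             btype="band", output="sos")
            colored = sps.sosfiltfilt(sos, white)
            colored -= colored.mean()
            scale = np.std(colored)
            if scale > 0:
                # ~0.95: average integration loss over the noise band
                m = m + colored * (np.sqrt(noise_var) / scale) / 0.95
        m = np.clip(m, -0.9, 0.9)

    rate = (1.0 + m) / mean_nn
    integ = np.concatenate(([0.0], cumulative_trapezoid(rate, t)))
    n_beats = int(np.floor(integ[-1]))
    if n_beats < 2:
        raise ValueError("window too short to generate beats")
    beat_times = np.interp(np.arange(1, n_beats + 1, dtype=float), integ, t)
    return beat_times, np.diff(beat_times)


# ECG template: (amplitude, center offset s, Gaussian width s) per wave
_ECG_TEMPLATE = (
    (0.12, -0.220, 0.030),   # P
    (-0.12, -0.028, 0.011),  # Q
    (1.00, 0.000, 0.012),    # R
    (-0.18, 0.030, 0.012),   # S
    (0.35, 0.250, 0.055),    # T
)


def gen_ecg_from_rr(beat_times: np.ndarray, fs: float = 250.0,
                    noise_sd: float = 0.0, seed: int = 0,
                    duration: float | None = None) -> WaveformRecord:
    """Render beats as P-QRS-T Gaussian templates plus white noise.

    The R apex falls within one sample of each beat time.  Beat pairs
    closer than 0.25 s are rejected (overlapping morphology).
    """
    beat_times = np.asarray(beat_times, dtype=float)
    if beat_times.size == 0:
        raise ValueError("empty beat list")
    if fs < 100:
        raise ValueError("ECG sampling rate must be >= 100 Hz")
    if len(beat_times) > 1 and np.min(np.diff(beat_times)) < 0.25:
        raise ValueError("beats closer than 0.25 s cannot be rendered")
    if duration is None:
        duration = beat_times[-1] + 0.5
    n = int(round(duration * fs))
    x = np.zeros(n)
    for amp, offset, width in _ECG_TEMPLATE:
        centers = beat_times + offset
        seg = int(np.ceil(4.0 * width * fs))
        start = np.ceil((centers - 4.0 * width) * fs).astype(int)
        idx = start[:, None] + np.arange(2 * seg + 1)[None, :]
        vals = amp * np.exp(-0.5 * ((idx / fs - centers[:, None]) / width) ** 2)
        valid = (idx >= 0) & (idx < n)
        x += np.bincount(idx[valid].ravel(), weights=vals[valid].ravel(), minlength=n)
    if noise_sd > 0:
        x = x + np.random.default_rng(seed).normal(0.0, noise_sd, size=n)
    return WaveformRecord(samples=x, fs=fs, channel=Channel.ECG_II)


class EctopicInjection(NamedTuple):
    beat_times: np.ndarray
    ectopic_indices: np.ndarray


def inject_ectopics(beat_times: np.ndarray, rate_per_min: float,
                    seed: int = 0) -> EctopicInjection:
    """Advance randomly chosen beats by 40% of the local RR interval.

    The following sinus beat is left unchanged (compensatory pause), so
    each ectopic produces one short + one long interval.  The number of
    ectopics is Poisson(rate * duration / 60).  Returns the perturbed
    times and the indices of the perturbed beats.
    """
    beat_times = np.asarray(beat_times, dtype=float)
    if rate_per_min < 0:
        raise ValueError("rate must be >= 0")
    rng = np.random.default_rng(seed)
    duration = beat_times[-1] - beat_times[0] if len(beat_times) > 1 else 0.0
    n_ect = rng.poisson(rate_per_min * duration / 60.0) if rate_per_min > 0 else 0
    if n_ect == 0 or len(beat_times) < 7:
        return EctopicInjection(beat_times.copy(), np.empty(0, dtype=int))

    candidates = np.arange(2, len(beat_times) - 2)
    chosen = rng.choice(candidates, size=min(n_ect, len(candidates)), replace=False)
    chosen.sort()
    # keep selections >= 3 beats apart so short/long pairs stay isolated
    kept: list[int] = []
    for idx in chosen:
        if not kept or idx - kept[-1] >= 3:
            kept.append(int(idx))
    new_times = beat_times.copy()
    final = []
    for idx in kept:
        rr_local = beat_times[idx] - beat_times[idx - 1]
        if 0.6 * rr_local >= 0.25:  # renderable after the advance
            new_times[idx] -= 0.4 * rr_local
            final.append(idx)
    return EctopicInjection(new_times, np.asarray(final, dtype=int))


def gen_resp(rpdm_target: float, rpdsd_target: float, duration: float,
             fs: float = 62.5, seed: int = 0,
             noise_sd: float = 0.0) -> WaveformRecord:
    """Respiration as a cosine with per-breath periods of target mean/SD.

    Periods are drawn from a truncated normal and affine-adjusted so
    their sample mean and SD match the targets; the waveform phase is
    piecewise linear between successive peaks, so the rendered
    peak-to-peak intervals equal the drawn periods.
    """
    if not 1.0 <= rpdm_target <= 10.0:
        raise ValueError("rpdm target must be within 1-10 s")
    if rpdsd_target < 0 or rpdsd_target >= rpdm_target:
        raise ValueError("rpdsd target must be in [0, rpdm)")
    rng = np.random.default_rng(seed)
    n_breaths = int(np.ceil(duration / rpdm_target)) + 3
    lo, hi = 1.6, 9.8
    if rpdsd_target > 0:
        periods = rng.normal(rpdm_target, rpdsd_target, size=n_breaths)
        periods = _affine_to(np.clip(periods, lo, hi), rpdm_target, rpdsd_target)
        periods = np.clip(periods, lo, hi)
        # the 0.1-0.5 Hz analysis band-pass smooths breath-to-breath
        # period variability, so the statistics extracted downstream
        # shrink relative to the drawn ones; close the loop by measuring
        # the extracted stats and re-scaling the drawn periods
        for _ in range(4):
            record = _render_resp(periods, duration, fs)
            got = _measure_periods(record)
            if got is None:
                break
            got_m, got_s = got
            if (abs(got_m - rpdm_target) < 0.01 * rpdm_target
                    and abs(got_s - rpdsd_target) < 0.02 * rpdsd_target):
                break
            gain = np.clip(rpdsd_target / got_s, 0.6, 1.8) if got_s > 0 else 1.5
            new_mean = rpdm_target + np.clip(rpdm_target - got_m,
                                             -0.2 * rpdm_target, 0.2 * rpdm_target)
            periods = np.clip((periods - periods.mean()) * gain + new_mean, lo, hi)
    else:
        periods = np.full(n_breaths, rpdm_target)

    record = _render_resp(periods, duration, fs)
    if noise_sd > 0:
        x = record.samples + rng.normal(0.0, noise_sd, size=len(record.samples))
        record = WaveformRecord(samples=x, fs=fs, channel=Channel.RESP)
    return record


def _affine_to(values: np.ndarray, mean: float, sd: float) -> np.ndarray:
    got_sd = np.std(values, ddof=1)
    if got_sd > 0:
        values = (values - values.mean()) * (sd / got_sd) + mean
    return values


def _render_resp(periods: np.ndarray, duration: float, fs: float) -> WaveformRecord:
    """Cosine with piecewise-linear phase: peaks exactly at the cumsum."""
    peaks = np.concatenate(([periods[0] / 2.0], periods[:-1])).cumsum()
    peaks = peaks[peaks < duration + float(np.mean(periods))]
    t = np.arange(int(round(duration * fs))) / fs
    phase = np.interp(t, peaks, np.arange(len(peaks), dtype=float))
    before = t < peaks[0]
    phase[before] = (t[before] - peaks[0]) / periods[0]
    after = t > peaks[-1]
    phase[after] = (len(peaks) - 1) + (t[after] - peaks[-1]) / periods[-1]
    return WaveformRecord(samples=np.cos(2 * np.pi * phase), fs=fs,
                          channel=Channel.RESP)


def _measure_periods(record: WaveformRecord) -> tuple[float, float] | None:
    """Extracted (mean, sample SD) of the breath periods, or None."""
    from .rrv_features import InsufficientBreathsError, breath_series

    try:
        periods = breath_series(record).periods
    except InsufficientBreathsError:
        return None
    if len(periods) < 3:
        return None
    return float(np.mean(periods)), float(np.std(periods, ddof=1))


def _draw_record_params(rng: np.random.Generator,
                        stats: dict[str, tuple[float, float]]) -> dict[str, float]:
    """Per-record generator parameters drawn from the group statistics."""
    mean_nn = _trunc_normal(rng, *stats["mean_nn"], 0.4, 1.4)
    sdnn = _trunc_normal(rng, *stats["sdnn"], 0.01, 0.30 * mean_nn)
    lf = _trunc_normal(rng, *stats["lf"], 1e-06, 0.05)
    hf = _trunc_normal(rng, *stats["hf"], 1e-06, 0.05)
    lf_frac = lf / sdnn**2
    hf_frac = hf / sdnn**2
    total = lf_frac + hf_frac
    if total > 0.85:
        lf_frac *= 0.85 / total
        hf_frac *= 0.85 / total
    rpdm = _trunc_normal(rng, *stats["rpdm"], 1.3, 6.0)
    rpdv = _trunc_normal(rng, *stats["rpdv"], 8.0, 55.0)
    return {
        "mean_nn": mean_nn, "sdnn": sdnn,
        "lf_frac": lf_frac, "hf_frac": hf_frac,
        "rpdm": rpdm, "rpdsd": rpdm * rpdv / 100.0, "rpdv": rpdv,
    }


def gen_cohort(stats: GroupStats, cfg: SimConfig,
               return_truth: bool = False
               ) -> list[LabeledWindow] | tuple[list[LabeledWindow], pd.DataFrame]:
    """Generate a full waveform cohort (pre-VT labeled +1, control -1).

    Each record draws its generator parameters from the group-level
    distributions, then synthesizes paired ECG + respiration waveforms.
    Deterministic given ``cfg.seed``; infeasible draws are resampled.
    """
    ss = np.random.SeedSequence(cfg.seed)
    windows: list[LabeledWindow] = []
    truth_rows = []
    groups = (("vt", 1, stats.vt), ("control", -1, stats.control))
    children = ss.spawn(2 * cfg.n_per_group)
    k = 0
    for group_name, label, group_stats in groups:
        for i in range(cfg.n_per_group):
            child = children[k]
            k += 1
            rng = np.random.default_rng(child)
            for attempt in range(100):
                int_seeds = rng.integers(0, 2**31 - 1, size=4)
                params = _draw_record_params(rng, group_stats)
                try:
                    beat_times, _ = gen_rr_series(
                        params["mean_nn"], params["sdnn"], params["lf_frac"],
                        params["hf_frac"], cfg.duration_s, seed=int(int_seeds[0]))
                    injected = inject_ectopics(beat_times, cfg.ectopic_rate_per_min,
                                               seed=int(int_seeds[1]))
                    ecg = gen_ecg_from_rr(injected.beat_times, fs=cfg.ecg_fs,
                                          noise_sd=cfg.ecg_noise_sd,
                                          seed=int(int_seeds[2]),
                                          duration=cfg.duration_s)
                except ValueError:
                    continue  # infeasible draw (e.g. RR too short to render)
                break
            else:
                raise RuntimeError("could not draw feasible record parameters")
            resp = gen_resp(params["rpdm"], params["rpdsd"], cfg.duration_s,
                            fs=cfg.resp_fs, seed=int(int_seeds[3]),
                            noise_sd=cfg.resp_noise_sd)
            source_id = f"{group_name}_{i:03d}"
            windows.append(LabeledWindow(ecg=ecg, resp=resp, label=label,
                                         source_id=source_id))
            truth_rows.append({"source_id": source_id, "label": label,
                               "n_ectopics": len(injected.ectopic_indices),
                               **params})
    if return_truth:
        return windows, pd.DataFrame(truth_rows).set_index("source_id")
    return windows


def gen_feature_cohort(stats: GroupStats, n_per_group: int,
                       seed: int = 0) -> pd.DataFrame:
    """Draw feature vectors directly from the group statistics.

    Independent truncated normals per parameter; the three ratio fields
    (``lf_hf``, ``sd1_sd2``, ``rpdsd``) are recomputed from the drawn
    parents for internal consistency (``rpdsd = rpdm * rpdv / 100``).
    Returns a DataFrame with the 14 features, ``label`` and a
    ``source_id`` index.
    """
    rng = np.random.default_rng(seed)
    bounds = {
        "mean_nn": (0.3, 2.0), "sdnn": (1e-8, np.inf), "rmssd": (1e-8, np.inf),
        "pnn50": (0.0, 1.0), "vlf": (0.0, np.inf), "lf": (1e-12, np.inf),
        "hf": (1e-12, np.inf), "sd1": (1e-8, np.inf), "sd2": (1e-8, np.inf),
        "rpdm": (0.5, 10.0), "rpdv": (0.0, 100.0),
    }
    frames = []
    for group_name, label, group_stats in (("vt", 1, stats.vt),
                                           ("control", -1, stats.control)):
        cols = {}
        for name, (lo, hi) in bounds.items():
            mean, sd = group_stats[name]
            cols[name] = np.asarray(
                _trunc_normal(rng, mean, sd, lo, hi, size=n_per_group))
        cols["lf_hf"] = cols["lf"] / cols["hf"]
        cols["sd1_sd2"] = cols["sd1"] / cols["sd2"]
        cols["rpdsd"] = cols["rpdm"] * cols["rpdv"] / 100.0
        df = pd.DataFrame({n: cols[n] for n in FEATURE_NAMES})
        df["label"] = label
        df.index = [f"{group_name}_{i:03d}" for i in range(n_per_group)]
        frames.append(df)
    out = pd.concat(frames)
    out.index.name = "source_id"
    return out
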