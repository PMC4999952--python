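import numpy as np
import pytest

from vtpred.peak_detection import BeatSeries
from vtpred.signal_io import Channel, WaveformRecord
from vtpred.synthetic_data import gen_ecg_from_rr, gen_rr_series


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def clean_beats():
    """IPFM beat series with typical sinus statistics, no ectopics."""
    beat_times, rr = gen_rr_series(0.8, 0.05, 0.3, 0.3, 300, seed=7)
    return BeatSeries.from_times(beat_times)


@pytest.fixture
def clean_ecg():
    """Noise-free rendered ECG with known ground-truth beat times."""
    beat_times, _ = gen_rr_series(0.8, 0.04, 0.3, 0.3, 300, seed=11)
    ecg = gen_ecg_from_rr(beat_times, fs=250, noise_sd=0.0, duration=300)
    return ecg, beat_times


def make_record(samples, fs=62.5, channel=Channel.RESP):
    return WaveformRecord(samples=np.asarray(samples, dtype=float), fs=fs,
                          channel=channel)
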