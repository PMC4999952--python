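import numpy as np
import pytest

from vtpred.hrv_features import (detrend_highpass, resample_tachogram,
                                 welch_band_powers)
from vtpred.peak_detection import detect_r_peaks
from vtpred.rr_preprocess import NNSeries
from vtpred.signal_io import FEATURE_NAMES, Channel
from vtpred.synthetic_data import (GroupStats, SimConfig, default_group_stats,
                                   gen_cohort, gen_ecg_from_rr,
                                   gen_feature_cohort, gen_resp, gen_rr_series,
                                   inject_ectopics)


class TestGenRrSeries:
    def test_zero_sdnn_constant_rr(self):
        _, rr = gen_rr_series(0.8, 0.0, 0.0, 0.0, 300, seed=0)
        np.testing.assert_allclose(rr, 0.8, atol=1e-6)

    def test_reference_targets_recovered(self):
        means, sds = [], []
        for seed in range(5):
            _, rr = gen_rr_series(0.709, 0.061, 0.2, 0.4, 300, seed=seed)
            means.append(rr.mean())
            sds.append(np.std(rr))
        assert np.mean(means) == pytest.approx(0.709, rel=0.02)
        assert np.mean(sds) == pytest.approx(0.061, rel=0.15)

    def test_hf_only_spectral_ratio(self):
        beat_times, rr = gen_rr_series(0.8, 0.05, 0.0, 1.0, 300, seed=1)
        nn = NNSeries(nn=rr, beat_times=beat_times,
                      ectopic_mask=np.zeros(len(beat_times), dtype=bool))
        _, lf, hf, _ = welch_band_powers(detrend_highpass(resample_tachogram(nn)))
        assert hf > 10 * lf

    def test_infeasible_target_rejected(self):
        with pytest.raises(ValueError, match="infeasible"):
            gen_rr_series(0.8, 0.5, 0.2, 0.2, 300, seed=0)
        with pytest.raises(ValueError, match="mean_nn"):
            gen_rr_series(0.1, 0.0, 0.0, 0.0, 300, seed=0)
        with pytest.raises(ValueError, match="frac"):
            gen_rr_series(0.8, 0.05, 0.8, 0.8, 300, seed=0)

    def test_deterministic(self):
        a = gen_rr_series(0.8, 0.05, 0.3, 0.3, 300, seed=5)
        b = gen_rr_series(0.8, 0.05, 0.3, 0.3, 300, seed=5)
        np.testing.assert_array_equal(a[0], b[0])


class TestGenEcg:
    def test_noise_free_beats_recovered_exactly(self):
        beat_times, _ = gen_rr_series(0.8, 0.04, 0.3, 0.3, 300, seed=2)
        ecg = gen_ecg_from_rr(beat_times, fs=250, noise_sd=0.0, duration=300)
        det = detect_r_peaks(ecg)
        interior = beat_times[(beat_times > 0.3) & (beat_times < 299.7)]
        dist = np.abs(det.peak_times[:, None] - interior[None, :]).min(axis=0)
        assert np.all(dist <= 1.0 / 250 + 1e-9)

    def test_r_apex_within_one_sample(self):
        beat_times = np.array([1.0, 1.8, 2.6, 3.4, 4.2])
        ecg = gen_ecg_from_rr(beat_times, fs=250, noise_sd=0.0)
        for t in beat_times:
            window = ecg.samples[int((t - 0.1) * 250):int((t + 0.1) * 250)]
            apex = int((t - 0.1) * 250) + np.argmax(window)
            assert abs(apex / 250 - t) <= 1.0 / 250

    def test_empty_beat_list_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            gen_ecg_from_rr(np.array([]), fs=250)

    def test_overlapping_beats_rejected(self):
        with pytest.raises(ValueError, match="0.25"):
            gen_ecg_from_rr(np.array([1.0, 1.1]), fs=250)

    def test_channel_and_fs(self):
        ecg = gen_ecg_from_rr(np.array([1.0, 2.0]), fs=125)
        assert ecg.channel is Channel.ECG_II
        assert ecg.fs == 125


class TestInjectEctopics:
    def test_zero_rate_identity(self):
        beat_times = np.arange(0, 300, 0.8)
        out = inject_ectopics(beat_times, 0.0, seed=0)
        np.testing.assert_array_equal(out.beat_times, beat_times)
        assert len(out.ectopic_indices) == 0

    def test_rate_two_per_minute(self):
        beat_times = np.arange(0, 300, 0.8)
        counts = [len(inject_ectopics(beat_times, 2.0, seed=s).ectopic_indices)
                  for s in range(20)]
        assert 5 <= np.mean(counts) <= 15  # Poisson mean 10

    def test_short_long_pair_structure(self):
        beat_times = np.arange(0, 300, 0.8)
        out = inject_ectopics(beat_times, 2.0, seed=3)
        rr = np.diff(out.beat_times)
        for idx in out.ectopic_indices:
            assert rr[idx - 1] == pytest.approx(0.48, abs=1e-9)   # short
            assert rr[idx] == pytest.approx(1.12, abs=1e-9)       # long pause
        # sinus beats after the ectopic are unchanged
        assert np.all(np.isin(np.round(out.beat_times[~np.isin(
            np.arange(len(beat_times)), out.ectopic_indices)], 9),
            np.round(beat_times, 9)))

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            inject_ectopics(np.arange(10.0), -1.0)


class TestGenResp:
    def test_zero_sd_gives_zero_rpdv(self):
        from vtpred.rrv_features import rrv_vector
        out = rrv_vector(gen_resp(3.0, 0.0, 300, seed=0))
        assert out["rpdv"] < 1.0

    def test_reference_targets(self):
        from vtpred.rrv_features import rrv_vector
        outs = [rrv_vector(gen_resp(2.95, 0.915, 300, seed=s)) for s in range(4)]
        assert np.mean([o["rpdm"] for o in outs]) == pytest.approx(2.95, rel=0.05)
        assert np.mean([o["rpdsd"] for o in outs]) == pytest.approx(0.915, rel=0.20)

    def test_doubling_targets(self):
        from vtpred.rrv_features import rrv_vector
        a = rrv_vector(gen_resp(2.1, 0.45, 300, seed=7))
        b = rrv_vector(gen_resp(4.2, 0.90, 300, seed=7))
        assert b["rpdm"] == pytest.approx(2 * a["rpdm"], rel=0.10)
        assert b["rpdsd"] == pytest.approx(2 * a["rpdsd"], rel=0.30)

    def test_degenerate_rejected(self):
        with pytest.raises(ValueError, match="rpdsd"):
            gen_resp(3.0, 3.0, 300, seed=0)
        with pytest.raises(ValueError, match="rpdm"):
            gen_resp(0.5, 0.1, 300, seed=0)


class TestGroupStats:
    def test_defaults_complete(self):
        stats = default_group_stats()
        assert set(stats.control) == set(FEATURE_NAMES)
        assert set(stats.vt) == set(FEATURE_NAMES)
        assert stats.control["mean_nn"] == (0.709, 0.149)
        assert stats.vt["rpdv"] == (25.4, 3.56)

    def test_missing_param_rejected(self):
        bad = {k: v for k, v in default_group_stats().control.items()
               if k != "sdnn"}
        with pytest.raises(ValueError, match="missing"):
            GroupStats(control=bad)

    def test_negative_sd_rejected(self):
        bad = dict(default_group_stats().control)
        bad["sdnn"] = (0.06, -0.01)
        with pytest.raises(ValueError, match="negative SD"):
            GroupStats(control=bad)


class TestGenCohort:
    def test_structure_and_labels(self):
        cfg = SimConfig(seed=1, n_per_group=3, duration_s=60.0,
                        ecg_fs=125.0, resp_fs=12.0)
        windows = gen_cohort(default_group_stats(), cfg)
        assert len(windows) == 6
        assert sum(w.label == 1 for w in windows) == 3
        assert sum(w.label == -1 for w in windows) == 3
        for w in windows:
            assert w.ecg.duration == pytest.approx(60.0, abs=0.1)
            assert w.resp.channel is Channel.RESP

    def test_seed_reproducibility(self):
        cfg = SimConfig(seed=2, n_per_group=2, duration_s=60.0,
                        ecg_fs=125.0, resp_fs=12.0)
        a = gen_cohort(default_group_stats(), cfg)
        b = gen_cohort(default_group_stats(), cfg)
        for wa, wb in zip(a, b):
            np.testing.assert_array_equal(wa.ecg.samples, wb.ecg.samples)
            np.testing.assert_array_equal(wa.resp.samples, wb.resp.samples)
            assert wa.source_id == wb.source_id

    def test_truth_frame(self):
        cfg = SimConfig(seed=3, n_per_group=2, duration_s=60.0,
                        ecg_fs=125.0, resp_fs=12.0)
        windows, truth = gen_cohort(default_group_stats(), cfg, return_truth=True)
        assert len(truth) == 4
        assert {"mean_nn", "sdnn", "rpdm", "rpdv", "n_ectopics"} <= set(truth.columns)

    def test_bad_config(self):
        with pytest.raises(ValueError, match="duration"):
            SimConfig(seed=0, duration_s=30.0)


class TestGenFeatureCohort:
    def test_large_sample_means_match_low_truncation_params(self):
        stats = default_group_stats()
        df = gen_feature_cohort(stats, 10_000, seed=0)
        for label, group in ((1, stats.vt), (-1, stats.control)):
            sub = df[df.label == label]
            # parameters whose truncation probability is negligible
            for name in ("mean_nn", "rpdm", "rpdv"):
                assert sub[name].mean() == pytest.approx(group[name][0], rel=0.02), name

    def test_ratios_consistent(self):
        df = gen_feature_cohort(default_group_stats(), 100, seed=1)
        np.testing.assert_allclose(df["lf_hf"], df["lf"] / df["hf"], rtol=1e-12)
        np.testing.assert_allclose(df["sd1_sd2"], df["sd1"] / df["sd2"], rtol=1e-12)
        np.testing.assert_allclose(df["rpdv"], 100 * df["rpdsd"] / df["rpdm"],
                                   rtol=1e-12)

    def test_bounds_respected(self):
        df = gen_feature_cohort(default_group_stats(), 2000, seed=2)
        assert df["pnn50"].between(0, 1).all()
        for name in ("sdnn", "rmssd", "vlf", "lf", "hf", "sd1", "sd2", "rpdsd"):
            assert (df[name] >= 0).all()

    def test_zero_sd_point_clouds_separable(self):
        stats = default_group_stats()
        degenerate = GroupStats(
            control={k: (m, 0.0) for k, (m, s) in stats.control.items()},
            vt={k: (m, 0.0) for k, (m, s) in stats.vt.items()})
        df = gen_feature_cohort(degenerate, 20, seed=3)
        vt = df[df.label == 1][list(FEATURE_NAMES)].drop_duplicates()
        ctl = df[df.label == -1][list(FEATURE_NAMES)].drop_duplicates()
        assert len(vt) == 1 and len(ctl) == 1
        assert not vt.iloc[0].equals(ctl.iloc[0])

    def test_deterministic(self):
        a = gen_feature_cohort(default_group_stats(), 50, seed=9)
        b = gen_feature_cohort(default_group_stats(), 50, seed=9)
        assert a.equals(b)
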