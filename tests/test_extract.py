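"""Event-extraction chain: decimation, baseline, threshold, morphology."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import entosense as es
from entosense.errors import ConfigError, DataError
from entosense.extract import BELOW_MEDIAN_SD_FACTOR, _mask_runs


# --------------------------------------------------------------------------
# independent oracles
# --------------------------------------------------------------------------

def oracle_erode(mask, k):
    """From-definition flat erosion, centred element (left-biased when
    even), false border."""
    mask = np.asarray(mask, bool)
    if k <= 1:
        return mask.copy()
    n, c = mask.size, k // 2
    padded = np.zeros(n + k, bool)
    padded[c:c + n] = mask
    return np.array([padded[i:i + k].all() for i in range(n)])


def oracle_dilate(mask, m):
    mask = np.asarray(mask, bool)
    if m <= 1:
        return mask.copy()
    n, c = mask.size, (m - 1) // 2
    padded = np.zeros(n + m, bool)
    padded[c:c + n] = mask
    return np.array([padded[i:i + m].any() for i in range(n)])


def oracle_refine(mask, k, m):
    return oracle_dilate(oracle_erode(mask, k), m)


# --------------------------------------------------------------------------
# decimation
# --------------------------------------------------------------------------

class TestDecimate:
    @pytest.mark.parametrize("factor", [1, 3, 10])
    def test_constant_preserved(self, factor):
        out = es.decimate(np.ones(100), factor)
        np.testing.assert_allclose(out, 1.0)
        assert out.size == 100 // factor

    def test_zero_mean_blocks_cancel(self):
        stream = np.tile([1.0, -1.0], 10)
        np.testing.assert_allclose(es.decimate(stream, 10), [0.0, 0.0])

    def test_sine_attenuation_matches_closed_form(self):
        # block-mean of N samples attenuates a tone at f by
        # sin(pi f N / fs) / (N sin(pi f / fs))
        fs, f, n_blk = 20000.0, 100.0, 10
        t = np.arange(40000) / fs
        dec = es.decimate(np.sin(2 * np.pi * f * t), n_blk)
        amp = np.sqrt(2) * dec.std()
        expected = np.sin(np.pi * f * n_blk / fs) / (
            n_blk * np.sin(np.pi * f / fs))
        assert expected > 0.99  # < 1 % attenuation at 100 Hz
        assert amp == pytest.approx(expected, abs=1e-3)

    def test_short_stream_warns_and_returns_empty(self):
        with pytest.warns(UserWarning):
            out = es.decimate(np.ones(5), 10)
        assert out.size == 0

    def test_bad_factor(self):
        with pytest.raises(ConfigError):
            es.decimate(np.ones(10), 0)


# --------------------------------------------------------------------------
# rolling baseline
# --------------------------------------------------------------------------

class TestRollingBaseline:
    def test_constant_stream(self):
        with pytest.warns(UserWarning):
            track = es.rolling_baseline(np.full(8000, 3.5), 2.0, 0.5, 2000.0)
        np.testing.assert_allclose(track.median, 3.5)
        np.testing.assert_allclose(track.sd, 0.0)
        assert track.n_degenerate_windows == track.median.size

    def test_below_median_sd_closed_form(self, rng):
        # SD of the below-median half of a Gaussian is sigma*sqrt(1 - 2/pi)
        sigma = 2.0
        stream = rng.normal(10.0, sigma, 40000)
        track = es.rolling_baseline(stream, 2.0, 0.5, 2000.0)
        assert np.median(track.median) == pytest.approx(10.0, abs=0.05)
        # the estimator (median across windows) hits the closed form within
        # 3 %; individual 4000-sample windows carry a little sampling noise
        assert np.median(track.sd) == pytest.approx(
            sigma * BELOW_MEDIAN_SD_FACTOR, rel=0.03
        )
        np.testing.assert_allclose(
            track.sd, sigma * BELOW_MEDIAN_SD_FACTOR, rtol=0.10
        )

    def test_robust_to_rare_positive_spikes(self, rng):
        clean = rng.normal(0.0, 1.0, 20000)
        spiky = clean.copy()
        idx = rng.choice(clean.size, size=clean.size // 20, replace=False)
        spiky[idx] += 50.0
        t_clean = es.rolling_baseline(clean)
        t_spiky = es.rolling_baseline(spiky)
        # 5 % contamination at +50 sigma moves the median by well under 2 %
        # of the spike amplitude and the below-median SD by a few per cent
        assert np.abs(t_spiky.median - t_clean.median).max() < 0.02 * 50
        np.testing.assert_allclose(t_spiky.sd, t_clean.sd, rtol=0.03)

    def test_interpolation_holds_edges(self):
        track = es.rolling_baseline(np.arange(8000.0), 2.0, 0.5, 2000.0)
        t = np.array([0.0, track.centers_s[0], track.centers_s[-1], 4.0])
        med, _ = track.interp(t)
        assert med[0] == med[1] and med[2] == med[3]

    def test_too_short_stream_raises(self):
        with pytest.raises(DataError):
            es.rolling_baseline(np.ones(100), 2.0, 0.5, 2000.0)


# --------------------------------------------------------------------------
# thresholding
# --------------------------------------------------------------------------

class TestDetectMask:
    def test_threshold_boundary(self):
        sd = np.ones(2)
        med = np.zeros(2)
        mask = es.detect_mask(np.array([10.1, 9.9]), med, sd, snr_factor=10)
        assert mask.tolist() == [True, False]

    def test_negative_excursions_ignored(self):
        mask = es.detect_mask(np.array([-20.0]), np.zeros(1), np.ones(1), 10)
        assert not mask[0]

    def test_zero_residual_all_false(self):
        mask = es.detect_mask(np.zeros(100), np.zeros(100), np.ones(100), 10)
        assert not mask.any()

    def test_zero_sd_floored_at_epsilon(self):
        mask = es.detect_mask(np.array([1e-3]), np.zeros(1), np.zeros(1), 10)
        assert mask[0]

    def test_length_mismatch(self):
        with pytest.raises(DataError):
            es.detect_mask(np.zeros(3), np.zeros(2), np.zeros(3), 10)


# --------------------------------------------------------------------------
# morphology
# --------------------------------------------------------------------------

class TestRefineMask:
    FS = 20000.0

    def test_sub_500us_spike_removed(self):
        mask = np.zeros(100, bool)
        mask[40:48] = True  # 8 samples = 400 us at 20 kHz
        out = es.refine_mask(mask, 500e-6, 30e-3, self.FS)
        assert not out.any()

    def test_run_length_arithmetic(self):
        # 2000-sample run, erode 10, dilate 600 -> 2000 - 10 + 600 = 2590
        mask = np.zeros(5000, bool)
        mask[1500:3500] = True
        out = es.refine_mask(mask, 10 / self.FS, 600 / self.FS, self.FS)
        assert out.sum() == 2590
        runs = _mask_runs(out)
        assert len(runs) == 1

    def test_zero_elements_are_identity(self):
        mask = np.zeros(50, bool)
        mask[10:13] = True
        out = es.refine_mask(mask, 0.0, 0.0, self.FS)
        np.testing.assert_array_equal(out, mask)

    def test_matches_oracle_on_fixed_patterns(self):
        patterns = [
            np.array([0, 1, 1, 1, 0, 1, 0, 1, 1, 0, 0, 1, 1, 1, 1], bool),
            np.ones(12, bool),
            np.zeros(12, bool),
        ]
        for mask in patterns:
            for k, m in [(2, 3), (3, 5), (1, 4), (4, 1)]:
                got = es.refine_mask(mask, k / self.FS, m / self.FS, self.FS)
                np.testing.assert_array_equal(
                    got, oracle_refine(mask, k, m), err_msg=f"k={k} m={m}"
                )

    @given(
        mask=st.lists(st.booleans(), min_size=1, max_size=64),
        k=st.integers(0, 6),
        m=st.integers(0, 10),
    )
    def test_matches_oracle_property(self, mask, k, m):
        mask = np.array(mask, bool)
        got = es.refine_mask(mask, k / self.FS, m / self.FS, self.FS)
        np.testing.assert_array_equal(got, oracle_refine(mask, k, m))


# --------------------------------------------------------------------------
# full extraction
# --------------------------------------------------------------------------

def _pulse_recording(spans_per_channel, duration=3.0, fs=20000.0, seed=0,
                     amp=50.0):
    """Noise recording with rectangular pulses injected on chosen channels."""
    rng = np.random.default_rng(seed)
    n = int(duration * fs)
    data = 100.0 + rng.normal(0, 1.0, (8, n))
    for chan, (a, b) in spans_per_channel:
        data[es.CHANNELS.index(chan), a:b] += amp
    return es.RawRecording(data=data, sample_rate=fs)


class TestExtractEvents:
    def test_or_union_of_overlapping_runs_is_one_event(self):
        rec = _pulse_recording(
            [("Q1_808", (20000, 24000)), ("Q2_980", (23000, 28000))]
        )
        events, _ = es.extract_events(rec)
        assert len(events) == 1
        ev = events[0]
        assert ev.start <= 20000 and ev.end >= 28000

    def test_noise_only_recording_yields_no_events(self):
        scene = es.SceneConfig(
            duration=3.0, noise_sd=1.0,
            baseline=es.synthgen.BaselineDrift(offset=100.0, drift_amp=0.0),
            seed=9,
        )
        rec, _ = es.synth_recording(scene)
        events, model = es.extract_events(rec)
        assert events == []
        # noise metadata still reported, near the true below-median SD
        # the track is expressed on the full-resolution noise scale, so the
        # reported level approximates sigma * sqrt(1 - 2/pi) of the raw noise
        level = model.noise_level()
        assert all(
            v == pytest.approx(BELOW_MEDIAN_SD_FACTOR, rel=0.05)
            for v in level.values()
        )

    def test_injected_transits_recovered_one_to_one(self):
        insects = [es.demo_preset(t0=1.0 + 0.8 * i) for i in range(10)]
        scene = es.SceneConfig(duration=10.0, noise_sd=1.0, insects=insects,
                               seed=10)
        rec, truth = es.synth_recording(scene)
        events, _ = es.extract_events(rec)
        assert len(events) == 10
        mids = [ins["t0"] for ins in truth.insects]
        for ev, mid in zip(events, mids):
            assert ev.start_time_s < mid < ev.end_time_s

    def test_event_invariants(self):
        scene = es.SceneConfig(duration=3.0, noise_sd=1.0,
                               insects=[es.demo_preset(t0=1.5)], seed=11)
        rec, _ = es.synth_recording(scene)
        events, _ = es.extract_events(rec)
        ev = events[0]
        assert ev.end > ev.start
        assert ev.snippet.shape == (8, ev.end - ev.start)
        assert max(ev.peak_snr.values()) >= 10.0

    def test_idempotence(self):
        scene = es.SceneConfig(duration=3.0, noise_sd=1.0,
                               insects=[es.demo_preset(t0=1.5)], seed=12)
        rec, _ = es.synth_recording(scene)
        ev1, _ = es.extract_events(rec)
        ev2, _ = es.extract_events(rec)
        assert [(e.start, e.end) for e in ev1] == \
            [(e.start, e.end) for e in ev2]
        for a, b in zip(ev1, ev2):
            np.testing.assert_array_equal(a.snippet, b.snippet)

    def test_raising_snr_factor_never_adds_events(self):
        weak = es.InsectSpec(t0=1.5, body_amp_808=2, body_amp_980=2,
                             wing_amp_808=5, wing_amp_980=5)
        scene = es.SceneConfig(duration=3.0, noise_sd=1.0, insects=[weak],
                               seed=13)
        rec, _ = es.synth_recording(scene)
        counts = []
        for snr in (5.0, 10.0, 20.0, 50.0):
            params = es.DetectionParams(snr_factor=snr)
            counts.append(len(es.extract_events(rec, params)[0]))
        assert counts == sorted(counts, reverse=True)

    def test_linear_drift_produces_no_events(self):
        # 10 below-median-SD units per minute of drift on a noise-only scene
        drift = es.synthgen.BaselineDrift(
            offset=100.0, drift_amp=0.0,
            drift_slope=10.0 * BELOW_MEDIAN_SD_FACTOR / 60.0,
        )
        scene = es.SceneConfig(duration=6.0, noise_sd=1.0, baseline=drift,
                               seed=14)
        rec, _ = es.synth_recording(scene)
        events, _ = es.extract_events(rec)
        assert events == []

    def test_spikes_are_not_reported_as_events(self):
        scene = es.SceneConfig(duration=4.0, noise_sd=1.0, spike_rate=5.0,
                               spike_amp=100.0, seed=15)
        rec, truth = es.synth_recording(scene)
        assert len(truth.spikes) > 0
        events, _ = es.extract_events(rec)
        assert events == []
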