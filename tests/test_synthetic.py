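"""Generator contracts: background spectrum, ictal waveform shape,
cohort count statistics and dialysis tables."""

import numpy as np
import pandas as pd
import pytest
import scipy.signal

import sonictal as s
from sonictal.synthetic import MIN_ICTAL_DURATION_S, plan_cohort_truth


class TestBackground:
    def test_length_and_rms_contract(self):
        rec = s.generate_background(10, 500, 50, seed=1)
        assert rec.n_samples == 5000
        rms = np.sqrt(np.mean(rec.samples**2))
        assert 47.5 <= rms <= 52.5

    def test_zero_scale_gives_zero_trace(self):
        rec = s.generate_background(10, 500, 0, seed=9)
        assert np.all(rec.samples == 0)

    def test_pink_spectral_slope(self):
        # Welch-periodogram fit: log-log PSD slope over 1-50 Hz near -1
        rec = s.generate_background(60, 500, 50, seed=7)
        f, p = scipy.signal.welch(rec.samples, fs=500, nperseg=4096)
        band = (f >= 1) & (f <= 50)
        slope = np.polyfit(np.log10(f[band]), np.log10(p[band]), 1)[0]
        assert -1.3 <= slope <= -0.7

    def test_deterministic_under_seed(self):
        a = s.generate_background(5, 500, 50, seed=3).samples
        b = s.generate_background(5, 500, 50, seed=3).samples
        np.testing.assert_array_equal(a, b)

    @pytest.mark.parametrize("duration,fs", [(0, 500), (-1, 500), (5, -10)])
    def test_invalid_arguments_rejected(self, duration, fs):
        with pytest.raises(ValueError):
            s.generate_background(duration, fs, 50, seed=1)


class TestIctalWaveform:
    def test_sample_count_transients_and_spectral_peak(self):
        x = s.synth_ictal_waveform(5, 10, 400, 500)
        assert x.size == 2500
        assert np.max(np.abs(x)) == pytest.approx(400)
        peaks, _ = scipy.signal.find_peaks(x, height=100)
        # ~50 transients at 10 Hz over 5 s; the onset/offset ramps suppress
        # a couple of edge transients below the counting height
        assert 44 <= peaks.size <= 52
        spec = np.abs(np.fft.rfft(x - x.mean())) ** 2
        freqs = np.fft.rfftfreq(x.size, 1 / 500)
        usable = freqs > 0.5
        assert abs(freqs[usable][np.argmax(spec[usable])] - 10) <= 1

    def test_minimum_duration_train_has_six_transients(self):
        # 3 s at 2 Hz: exactly the minimum ictal duration, 6 transients
        x = s.synth_ictal_waveform(3, 2, 300, 500)
        assert x.size == 1500
        peaks, _ = scipy.signal.find_peaks(x, height=100)
        assert peaks.size == 6

    def test_zero_amplitude_gives_zero_vector(self):
        assert np.all(s.synth_ictal_waveform(5, 10, 0, 500) == 0)

    @pytest.mark.parametrize("freq", [1.5, 25.0])
    def test_rep_freq_outside_band_rejected(self, freq):
        with pytest.raises(ValueError):
            s.synth_ictal_waveform(5, freq, 100, 500)


def _count_table(truth: pd.DataFrame) -> pd.DataFrame:
    ictal = truth[~truth.is_subthreshold]
    return ictal.groupby(["animal_id", "period"]).size().unstack(fill_value=0)


class TestCohortCounts:
    def test_null_effect_centres_post_pre_ratio_on_one(self):
        cfg = s.CohortConfig(
            groups=("A",),
            n_per_group=40,
            event_rate_mean={"A": 100.0},
            effects={"A": s.InterventionEffect()},
            seed=5,
        )
        counts = _count_table(plan_cohort_truth(cfg))
        pooled = counts["post"].sum() / counts["pre"].sum()
        assert 0.9 <= pooled <= 1.1

    def test_mean_ratio_recovers_configured_multiplier(self):
        # generator self-consistency: mean per-animal post/pre ratio within
        # 2 standard errors of the configured rate multiplier
        cfg = s.CohortConfig(
            groups=("PHT+FUS",), n_per_group=60, seed=17, session_hours=1.0
        )
        counts = _count_table(plan_cohort_truth(cfg))
        ratio = counts["post"] / counts["pre"]
        m = cfg.effect("PHT+FUS").rate_multiplier
        se = ratio.std(ddof=1) / np.sqrt(len(ratio))
        assert abs(ratio.mean() - m) <= 2 * se

    def test_pre_counts_strongly_overdispersed(self):
        cfg = s.CohortConfig(groups=("PHT+FUS",), n_per_group=200, seed=23)
        pre = _count_table(plan_cohort_truth(cfg))["pre"]
        assert pre.std(ddof=1) / pre.mean() >= 0.8

    def test_truth_is_deterministic_and_events_disjoint(self, tiny_cohort_config):
        t1 = plan_cohort_truth(tiny_cohort_config)
        t2 = plan_cohort_truth(tiny_cohort_config)
        pd.testing.assert_frame_equal(t1, t2)
        for _, grp in t1.groupby(["animal_id", "period", "session"]):
            g = grp.sort_values("start_s")
            assert (g.start_s.to_numpy()[1:] >= (g.start_s + g.duration_s).to_numpy()[:-1]).all()

    def test_ictal_durations_at_least_minimum(self, tiny_cohort_config):
        truth = plan_cohort_truth(tiny_cohort_config)
        ictal = truth[~truth.is_subthreshold]
        arts = truth[truth.is_subthreshold]
        assert (ictal.duration_s >= MIN_ICTAL_DURATION_S).all()
        assert (arts.duration_s < MIN_ICTAL_DURATION_S).all()

    def test_rendered_records_deterministic(self, tiny_cohort_config):
        r1, _ = s.generate_cohort(tiny_cohort_config)
        r2, _ = s.generate_cohort(tiny_cohort_config)
        np.testing.assert_array_equal(r1[0].samples, r2[0].samples)
        np.testing.assert_array_equal(r1[-1].samples, r2[-1].samples)

    def test_oversized_event_raises_generation_error(self):
        cfg = s.CohortConfig(
            groups=("A",),
            n_per_group=1,
            sessions_per_period=1,
            session_hours=0.002,  # 7.2 s sessions
            event_rate_mean={"A": 20.0},
            effects={"A": s.InterventionEffect()},
            duration_lognorm=(2.6, 0.1),  # ~13.5 s events
            seed=1,
        )
        with pytest.raises(s.synthetic.GenerationError):
            plan_cohort_truth(cfg)


class TestDialysis:
    def test_law_of_large_numbers_on_ff_set4(self):
        cfg = s.DialysisConfig(n_paired_runs=10_000, seed=1)
        samples = s.generate_dialysis_samples(cfg)
        m = samples.loc[samples.condition == "FF_set4", "concentration_ug_ml"].mean()
        assert 0.64 <= m <= 0.66

    def test_zero_noise_returns_exact_means(self):
        cfg = s.DialysisConfig(
            condition_sds={c: 0.0 for c in s.synthetic.DEFAULT_DIALYSIS_MEANS},
            run_effect_sd=0.0,
            seed=4,
        )
        samples = s.generate_dialysis_samples(cfg)
        for cond, mean in s.synthetic.DEFAULT_DIALYSIS_MEANS.items():
            vals = samples.loc[samples.condition == cond, "concentration_ug_ml"]
            assert np.allclose(vals, mean)

    def test_paired_ff_minus_ctrl_positive_in_most_replicates(self):
        # Monte-Carlo: FF_set4 - Ctrl paired differences have positive mean
        # in >= 95% of seeded n = 8 replicates
        positive = 0
        for seed in range(1000):
            cfg = s.DialysisConfig(seed=seed)
            samples = s.generate_dialysis_samples(cfg)
            wide = samples.pivot(
                index="run", columns="condition", values="concentration_ug_ml"
            )
            positive += (wide["FF_set4"] - wide["Ctrl"]).mean() > 0
        assert positive >= 950

    def test_determinism(self):
        a = s.generate_dialysis_samples(s.DialysisConfig(seed=7))
        b = s.generate_dialysis_samples(s.DialysisConfig(seed=7))
        pd.testing.assert_frame_equal(a, b)
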