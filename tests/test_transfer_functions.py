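"""Spectra, TF ratios, smoothing, cohort averaging, and spectral features."""

import numpy as np
import pytest
from scipy import stats as sps

from tiltpress import transfer_functions as tfm


def _analytic_first_order_ctf(fc=1.0, lo=100.0, hi=1000.0, n=900,
                              log_spaced=False):
    if log_spaced:
        freq = np.logspace(np.log10(lo * fc), np.log10(hi * fc), n)
    else:
        freq = np.linspace(lo * fc, hi * fc, n)
    mag = -10.0 * np.log10(1.0 + (freq / fc) ** 2)
    return tfm.CohortTF("ICP", "0_1", freq, mag, mag, mag, n_subjects=1)


def _tfe(freq, mag, **kw):
    base = dict(subject_id="S1", output_channel="ICP", step_label="0_1",
                mask=np.ones(len(freq), dtype=bool))
    base.update(kw)
    return tfm.TransferFunctionEstimate(freq=freq, magnitude_db=mag, **base)


class TestWindowSpectrum:
    def test_frequency_resolution_is_inverse_duration(self):
        x = np.zeros(600 * 1000)
        freq, _ = tfm.window_spectrum(x, 1000.0, 600.0)
        assert freq[1] - freq[0] == pytest.approx(1.0 / 600.0)

    def test_exact_bin_sinusoid_concentrates_energy(self):
        fs, dur = 200.0, 30.0
        t = np.arange(int(dur * fs)) / fs
        x = np.sin(2 * np.pi * 2.0 * t)  # 2 Hz = bin 60 exactly
        freq, spec = tfm.window_spectrum(x, fs, dur)
        k = int(2.0 * dur)
        power = np.abs(spec) ** 2
        assert power[k] / power.sum() > 1 - 1e-9

    def test_parseval_energy_identity(self):
        rng = np.random.default_rng(5)
        fs, dur = 100.0, 20.0
        x = rng.standard_normal(int(dur * fs))
        freq, spec = tfm.window_spectrum(x, fs, dur)
        n = int(dur * fs)
        seg = x[:n] - x[:n].mean()
        # one-sided Parseval: double the interior bins
        w = np.full(spec.size, 2.0)
        w[0] = 1.0
        if n % 2 == 0:
            w[-1] = 1.0
        lhs = np.sum(w * np.abs(spec) ** 2) / n
        rhs = np.sum(seg**2)
        assert abs(lhs - rhs) / rhs < 1e-9

    def test_short_series_rejected_without_padding(self):
        with pytest.raises(ValueError, match="shorter"):
            tfm.window_spectrum(np.zeros(100), 100.0, 10.0)


class TestTfRatio:
    def test_self_ratio_is_zero_db(self):
        rng = np.random.default_rng(0)
        fs, dur = 200.0, 30.0
        x = rng.standard_normal(int(dur * fs))
        freq, spec = tfm.window_spectrum(x, fs, dur)
        tf = tfm.tf_ratio(spec, spec, freq)
        np.testing.assert_allclose(tf.magnitude_db[tf.mask], 0.0, atol=1e-9)

    def test_scalar_gain_of_two_is_6_02_db(self):
        rng = np.random.default_rng(1)
        fs, dur = 200.0, 30.0
        x = rng.standard_normal(int(dur * fs))
        freq, spec = tfm.window_spectrum(x, fs, dur)
        tf = tfm.tf_ratio(2.0 * spec, spec, freq)
        np.testing.assert_allclose(tf.magnitude_db[tf.mask],
                                   20 * np.log10(2), atol=1e-9)

    def test_known_second_order_section_recovered(self):
        # pass white noise through an analytic resonant section in the
        # frequency domain; the ratio must match the analytic response
        from tiltpress.synthetic_data import SimChannelSpec, compartment_response

        spec_ch = SimChannelSpec(name="ICP", baseline_mean=0.0,
                                 pulse_amplitude=1.0, hydro_slope=0.0,
                                 resonances=((4.2, 0.1, 10.0),))
        h = compartment_response(spec_ch)
        rng = np.random.default_rng(2)
        fs, dur = 200.0, 60.0
        x = rng.standard_normal(int(dur * fs))
        freq, in_spec = tfm.window_spectrum(x, fs, dur)
        out = np.fft.irfft(np.fft.rfft(x - x.mean()) * h(
            np.fft.rfftfreq(x.size, 1 / fs)), n=x.size)
        _, out_spec = tfm.window_spectrum(out, fs, dur)
        tf = tfm.tf_ratio(out_spec, in_spec, freq)
        expect = 20 * np.log10(np.abs(h(freq[tf.mask])))
        err = np.abs(tf.magnitude_db[tf.mask] - expect)
        assert np.max(err) < 0.5

    def test_all_bins_below_floor_rejected(self):
        freq = np.arange(10.0)
        in_spec = np.full(10, 1e-9, dtype=complex)
        in_spec[0] = 1.0  # only the (excluded) DC bin clears the floor
        with pytest.raises(ValueError, match="floor"):
            tfm.tf_ratio(np.ones(10, dtype=complex), in_spec, freq, floor=0.5)


class TestSmoothTf:
    def test_constant_preserved_including_edges(self):
        freq = np.exp2(np.arange(200) / 48.0)
        tf = _tfe(freq, np.zeros(200))
        out = tfm.smooth_tf(tf)
        np.testing.assert_allclose(out.magnitude_db, 0.0, atol=1e-9)

    def test_impulse_spread_symmetric_area_preserved(self):
        freq = np.exp2(np.arange(201) / 48.0)
        mag = np.zeros(201)
        mag[100] = 10.0
        out = tfm.smooth_tf(_tfe(freq, mag))
        assert abs(out.magnitude_db.sum() - 10.0) < 0.1  # 1% of the area
        k = int(np.argmin(np.abs(out.freq - freq[100])))
        left = out.magnitude_db[k - 10 : k]
        right = out.magnitude_db[k + 1 : k + 11][::-1]
        np.testing.assert_allclose(left, right, atol=0.05)

    def test_sharp_resonance_survives_default_bandwidth(self):
        from tiltpress.synthetic_data import SimChannelSpec, compartment_response

        h = compartment_response(SimChannelSpec(
            name="ICP", baseline_mean=0.0, pulse_amplitude=1.0,
            hydro_slope=0.0, resonances=((4.2, 0.05, 10.0),),
        ))
        freq = np.arange(1, 1800) / 60.0  # the 60 s window grid
        mag = 20 * np.log10(np.abs(h(freq)))
        out = tfm.smooth_tf(_tfe(freq, mag))
        assert mag.max() - out.magnitude_db.max() < 1.0

    def test_masked_bins_remasked_after_smoothing(self):
        freq = np.exp2(np.arange(200) / 48.0)
        mask = np.ones(200, dtype=bool)
        mask[80:120] = False
        out = tfm.smooth_tf(_tfe(freq, np.zeros(200), mask=mask))
        assert not out.mask.all()
        assert out.mask.sum() >= 140


class TestCohortAverage:
    def test_identical_subjects_zero_ci_width(self):
        freq = np.exp2(np.arange(100) / 48.0)
        tfs = [_tfe(freq, np.full(100, -3.0), subject_id=f"S{i}")
               for i in range(4)]
        ctf = tfm.cohort_average(tfs)
        np.testing.assert_allclose(ctf.mean_db, -3.0)
        np.testing.assert_allclose(ctf.ci_high_db - ctf.ci_low_db, 0.0,
                                   atol=1e-12)

    def test_db_mean_of_0_and_6_is_3(self):
        freq = np.exp2(np.arange(50) / 48.0)
        g = 20 * np.log10(2)
        ctf = tfm.cohort_average([
            _tfe(freq, np.zeros(50), subject_id="S1"),
            _tfe(freq, np.full(50, g), subject_id="S2"),
        ])
        np.testing.assert_allclose(ctf.mean_db, g / 2)

    def test_single_subject_ci_flagged_undefined(self):
        freq = np.exp2(np.arange(50) / 48.0)
        ctf = tfm.cohort_average([_tfe(freq, np.zeros(50))])
        assert ctf.n_subjects == 1
        assert np.all(np.isnan(ctf.ci_low_db))

    def test_ci_coverage_calibrated(self):
        # n=6 subjects with sigma=2 dB Gaussian perturbation around a flat
        # truth: pooled pointwise coverage of the 95% CI over 1000 cohorts
        rng = np.random.default_rng(99)
        freq = np.exp2(np.arange(40) / 48.0)
        reps, n = 1000, 6
        covered = 0
        total = 0
        for _ in range(reps):
            tfs = [_tfe(freq, rng.normal(0.0, 2.0, freq.size),
                        subject_id=f"S{i}") for i in range(n)]
            ctf = tfm.cohort_average(tfs)
            covered += int(np.sum((ctf.ci_low_db <= 0) & (0 <= ctf.ci_high_db)))
            total += freq.size
        assert abs(covered / total - 0.95) < 0.02


class TestFeatures:
    def test_monotone_decay_has_no_features(self):
        ctf = _analytic_first_order_ctf(fc=1.0, lo=0.5, hi=30, n=500)
        feats = tfm.find_peaks_and_notches(ctf, band=(0.5, 30.0))
        assert feats.peaks == [] and feats.notches == []

    def test_notch_detected_near_8hz(self, tf_cohort):
        import dataclasses

        from tiltpress import synthetic_data as sd

        cfg, _, _ = tf_cohort
        specs = tuple(
            dataclasses.replace(s, notches=((8.0, 0.15, 12.0),))
            if s.name == "IAPds" else s
            for s in cfg.channel_specs
        )
        cfg2 = dataclasses.replace(cfg, channel_specs=specs, n_subjects=3)
        recs, _ = sd.generate_cohort(cfg2)
        ctfs = tfm.cohort_transfer_functions(recs, steps=("0_1",))
        feats = tfm.find_peaks_and_notches(ctfs[("IAPds", "0_1")])
        assert feats.notches, "no notch found"
        f_notch = min(feats.notches, key=lambda fn: abs(fn[0] - 8.0))[0]
        assert abs(f_notch - 8.0) <= 2 * 8.0 * (2 ** (1 / 48) - 1)

    def test_first_order_asymptote_minus_20(self):
        ctf = _analytic_first_order_ctf()
        feats = tfm.fit_rolloff(ctf, fit_band=(100.0, 1000.0))
        assert feats.rolloff_db_per_decade == pytest.approx(-20.0, abs=0.1)

    def test_second_order_asymptote_minus_40(self):
        freq = np.linspace(100, 1000, 900)
        mag = -20.0 * np.log10(1.0 + freq**2) / 1.0
        ctf = tfm.CohortTF("ICP", "0_1", freq, mag, mag, mag, 1)
        feats = tfm.fit_rolloff(ctf, fit_band=(100.0, 1000.0))
        assert feats.rolloff_db_per_decade == pytest.approx(-40.0, abs=0.2)

    def test_flat_response_zero_slope(self):
        freq = np.linspace(1, 30, 300)
        ctf = tfm.CohortTF("ICP", "0_1", freq, np.zeros(300), np.zeros(300),
                           np.zeros(300), 1)
        feats = tfm.fit_rolloff(ctf, fit_band=(2.0, 25.0))
        assert feats.rolloff_db_per_decade == pytest.approx(0.0, abs=1e-9)

    def test_narrow_band_rejected_with_required_span(self):
        ctf = _analytic_first_order_ctf()
        with pytest.raises(ValueError, match="decade"):
            tfm.fit_rolloff(ctf, fit_band=(100.0, 150.0))


class TestPipelineRecovery:
    def test_noise_free_pipeline_within_1_db(self):
        import dataclasses

        from tiltpress import synthetic_data as sd

        cfg = sd.tf_validation_config(seed=11)
        specs = tuple(dataclasses.replace(s, noise_sd=0.0)
                      for s in cfg.channel_specs)
        cfg = dataclasses.replace(cfg, channel_specs=specs)
        recs, truth = sd.generate_cohort(cfg)
        ctfs = tfm.cohort_transfer_functions(recs, steps=("0_1",))
        ctf = ctfs[("ICP", "0_1")]
        sel = (ctf.freq >= 0.5) & (ctf.freq <= 20.0)
        expect = truth.tf_magnitude_db(0, "ICP", ctf.freq[sel])
        assert np.nanmax(np.abs(ctf.mean_db[sel] - expect)) < 1.0

    def test_noise_free_cohort_has_exactly_two_peaks(self):
        import dataclasses

        from tiltpress import synthetic_data as sd

        cfg = sd.tf_validation_config(seed=4)
        specs = tuple(dataclasses.replace(s, noise_sd=0.0)
                      for s in cfg.channel_specs)
        cfg = dataclasses.replace(cfg, channel_specs=specs, n_subjects=2)
        recs, truth = sd.generate_cohort(cfg)
        ctfs = tfm.cohort_transfer_functions(recs, steps=("0_1",))
        feats = tfm.find_peaks_and_notches(ctfs[("ITP", "0_1")])
        assert len(feats.peaks) == 2
        got = sorted(f for f, _ in feats.peaks)
        for f_est, f_true in zip(got, (4.2, 11.5)):
            assert abs(f_est - f_true) <= 2 * f_true * (2 ** (1 / 48) - 1) + 0.05

    def test_features_stable_when_duration_doubles(self):
        # same cohort, 60 s vs 120 s windows (steps regenerated at 120 s):
        # peak locations agree within one coarse-grid bin
        import dataclasses

        from tiltpress import synthetic_data as sd

        peaks = {}
        for dur in (60.0, 120.0):
            cfg = sd.tf_validation_config(seed=6, step_duration=dur,
                                          n_subjects=3)
            specs = tuple(dataclasses.replace(s, noise_sd=0.0)
                          for s in cfg.channel_specs)
            cfg = dataclasses.replace(cfg, channel_specs=specs)
            recs, _ = sd.generate_cohort(cfg)
            ctfs = tfm.cohort_transfer_functions(recs, steps=("0_1",))
            feats = tfm.find_peaks_and_notches(ctfs[("ICP", "0_1")])
            peaks[dur] = sorted(f for f, _ in feats.peaks)[:2]
        for a, b in zip(peaks[60.0], peaks[120.0]):
            assert abs(a - b) <= a * (2 ** (1 / 48) - 1) + 1e-9
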