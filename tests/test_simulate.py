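import numpy as np
import pytest

from conftest import quiet_config
from ospipe import design, erp, montage, simulate
from ospipe.simulate import ConfigError, EpochSet, SimulationConfig


class TestKernels:
    def test_hann_bump_peak_and_support(self):
        t = np.arange(-200.0, 301.0)
        k = simulate.hann_bump(t, 109.0, 25.0)
        assert k[t == 109.0] == 1.0
        assert np.all(k[(t < 84.0) | (t > 134.0)] == 0.0)
        assert np.all(k >= 0.0)

    def test_tapered_boxcar_plateau(self):
        t = np.arange(0.0, 200.0)
        k = simulate.tapered_boxcar(t, (50.0, 90.0), 5.0)
        assert np.all(k[(t >= 55.0) & (t <= 85.0)] == 1.0)
        assert np.all(k[(t < 50.0) | (t > 90.0)] == 0.0)

    def test_boxcar_no_ramp(self):
        t = np.arange(0.0, 200.0)
        k = simulate.tapered_boxcar(t, (50.0, 90.0), 0.0)
        assert np.all(k[(t >= 50.0) & (t <= 90.0)] == 1.0)
        assert k.sum() == 41.0


class TestSimulateParticipant:
    def test_noiseless_roi_peak_equals_amplitude(self, small_schedule):
        cfg = quiet_config(oN1_mean={"familiar": -2.0, "unfamiliar": -2.0})
        eps, _ = simulate.simulate_participant(small_schedule, cfg, 0)
        wave = erp.average_epochs(eps["familiar"])
        roi = erp.roi_mean(wave)
        val = roi[wave.time_axis == 109.0][0]
        assert val == pytest.approx(-2.0, abs=1e-9)

    def test_all_zero_when_everything_off(self, small_schedule):
        cfg = quiet_config(oN1_mean={"familiar": 0.0, "unfamiliar": 0.0})
        eps, _ = simulate.simulate_participant(small_schedule, cfg, 0)
        assert np.all(eps["familiar"].data == 0.0)
        assert np.all(eps["unfamiliar"].data == 0.0)

    def test_artifact_count_matches_fraction(self, default_schedule):
        cfg = SimulationConfig(noise_sd=3.0, artifact_fraction=0.1,
                               dtype="float32")
        eps, gt = simulate.simulate_participant(default_schedule, cfg, 1)
        idx = gt.artifact_indices["familiar"]
        assert len(idx) == 25  # 0.1 * 250
        peaks = np.abs(eps["familiar"].data).max(axis=(1, 2))
        assert np.all(peaks[idx] > 80.0)
        clean = np.delete(peaks, idx)
        assert np.all(clean < 80.0)

    def test_epoch_counts_and_labels_follow_schedule(self, small_schedule):
        cfg = quiet_config()
        eps, _ = simulate.simulate_participant(small_schedule, cfg, 0)
        for cond in ("familiar", "unfamiliar"):
            scheduled = small_schedule.scheduled_counts(cond)
            assert eps[cond].n_epochs == sum(scheduled.values())
            labels, counts = np.unique(eps[cond].labels, return_counts=True)
            assert dict(zip(labels, counts)) == scheduled

    def test_linearity_of_note_pattern_component(self, small_schedule):
        base = dict(noise_sd=2.0, oN1_within_sd=0.0, artifact_fraction=0.0)
        cfg_on = SimulationConfig(
            note_pattern_amp={"familiar": 1.5, "unfamiliar": 0.0},
            note_pattern_ramp_ms=0.0, **base)
        cfg_off = SimulationConfig(
            note_pattern_amp={"familiar": 0.0, "unfamiliar": 0.0},
            note_pattern_ramp_ms=0.0, **base)
        eps_on, gt = simulate.simulate_participant(small_schedule, cfg_on, 3)
        eps_off, _ = simulate.simulate_participant(small_schedule, cfg_off, 3)
        diff = eps_on["familiar"].data - eps_off["familiar"].data
        t = eps_on["familiar"].time_axis
        k = simulate.tapered_boxcar(t, (50.0, 90.0), 0.0)
        for i, note in enumerate(eps_on["familiar"].labels):
            expected = 1.5 * gt.note_patterns[note][:, None] * k[None, :]
            assert np.allclose(diff[i], expected, atol=1e-9)

    def test_noise_spectrum_slope(self, small_schedule):
        cfg = SimulationConfig(noise_sd=5.0, noise_spectrum_exponent=1.0,
                               oN1_mean={"familiar": 0.0, "unfamiliar": 0.0},
                               oN1_within_sd=0.0,
                               note_pattern_amp=0.0)
        eps, _ = simulate.simulate_participant(small_schedule, cfg, 9)
        data = eps["familiar"].data
        spec = np.abs(np.fft.rfft(data, axis=2)) ** 2
        freqs = np.fft.rfftfreq(data.shape[2], d=1e-3)
        mean_spec = spec.mean(axis=(0, 1))
        sel = (freqs >= 4.0) & (freqs <= 100.0)
        slope = np.polyfit(np.log(freqs[sel]), np.log(mean_spec[sel]), 1)[0]
        assert slope == pytest.approx(-1.0, abs=0.3)

    def test_noise_sd_calibration(self, small_schedule):
        cfg = SimulationConfig(noise_sd=5.0,
                               oN1_mean={"familiar": 0.0, "unfamiliar": 0.0},
                               oN1_within_sd=0.0, note_pattern_amp=0.0)
        eps, _ = simulate.simulate_participant(small_schedule, cfg, 2)
        sd = eps["familiar"].data.std()
        assert sd == pytest.approx(5.0, rel=0.05)

    def test_recovery_hook_matches_noiseless_average(self, small_schedule):
        cfg = quiet_config(note_pattern_amp={"familiar": 1.2,
                                             "unfamiliar": 0.0})
        eps, gt = simulate.simulate_participant(small_schedule, cfg, 0)
        for cond in ("familiar", "unfamiliar"):
            avg = erp.average_epochs(eps[cond])
            expected = gt.expected_average(cond, avg.time_axis)
            assert np.allclose(avg.data, expected, atol=1e-6)


class TestCohort:
    def test_zero_between_sd_gives_population_means(self, small_schedule):
        cfg = quiet_config(n_participants=3)
        _, truth = simulate.simulate_cohort(cfg, small_schedule)
        for gt in truth.participants:
            assert gt.oN1_amplitude["familiar"] == pytest.approx(-1.95)
            assert gt.oN1_amplitude["unfamiliar"] == pytest.approx(-1.37)

    def test_determinism_bitwise(self, small_schedule):
        cfg = quiet_config(noise_sd=2.0, seed=123)
        a, _ = simulate.simulate_cohort(cfg, small_schedule)
        b, _ = simulate.simulate_cohort(cfg, small_schedule)
        assert np.array_equal(a[0]["familiar"].data, b[0]["familiar"].data)

    def test_between_participant_sd_recovered(self, small_schedule):
        # cheap cohort: low sampling rate, no noise; checks the amplitude draws
        cfg = quiet_config(
            n_participants=100, fs=250.0, epoch_span=(-200.0, 300.0),
            oN1_between_sd={"familiar": 1.17, "unfamiliar": 0.98}, seed=5)
        _, truth = simulate.simulate_cohort(cfg, small_schedule)
        amps = truth.amplitude_table()
        fam = amps.query("condition == 'familiar'")["amplitude_uV"]
        assert fam.std() == pytest.approx(1.17, rel=0.2)
        assert fam.mean() == pytest.approx(-1.95, abs=3 * 1.17 / 10)

    def test_condition_correlation_shrinks_difference_sd(self, small_schedule):
        cfg = quiet_config(
            n_participants=150, fs=250.0, epoch_span=(-200.0, 300.0),
            oN1_between_sd={"familiar": 1.17, "unfamiliar": 0.98},
            condition_correlation=0.75, seed=6)
        _, truth = simulate.simulate_cohort(cfg, small_schedule)
        amps = truth.amplitude_table().pivot(index="participant",
                                             columns="condition",
                                             values="amplitude_uV")
        diff_sd = (amps["familiar"] - amps["unfamiliar"]).std()
        expected = np.sqrt(1.17 ** 2 + 0.98 ** 2
                           - 2 * 0.75 * 1.17 * 0.98)
        assert diff_sd == pytest.approx(expected, rel=0.25)


class TestValidation:
    def test_config_errors(self):
        with pytest.raises(ConfigError):
            SimulationConfig(fs=0.0)
        with pytest.raises(ConfigError):
            SimulationConfig(epoch_span=(-100.0, 400.0))
        with pytest.raises(ConfigError):
            SimulationConfig(noise_sd=-1.0)
        with pytest.raises(ConfigError):
            SimulationConfig(artifact_fraction=0.1, artifact_amp=50.0)
        with pytest.raises(ConfigError):
            SimulationConfig(oN1_topography={"NotAChannel": 1.0})
        with pytest.raises(ConfigError):
            SimulationConfig(oN1_mean={"familiar": -1.0})

    def test_epochset_invariants(self):
        n_ch = len(montage.CHANNELS)
        t = np.arange(-200.0, 301.0)
        good = dict(data=np.zeros((2, n_ch, len(t))), time_axis=t,
                    labels=np.array(["E", "F"]), retained=np.ones(2, bool),
                    fs=1000.0, condition="familiar", participant_id="p")
        EpochSet(**good)
        with pytest.raises(ValueError):
            EpochSet(**{**good, "labels": np.array(["E", "X"])})
        with pytest.raises(ValueError):
            EpochSet(**{**good, "time_axis": t[::-1]})
        with pytest.raises(ValueError):
            EpochSet(**{**good, "fs": 500.0})

    def test_topography_roi_normalization(self):
        w = SimulationConfig().topography_vector()
        roi_idx = montage.channel_indices(montage.CHANNELS, montage.ROI)
        assert w[roi_idx].mean() == pytest.approx(1.0, abs=1e-12)
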