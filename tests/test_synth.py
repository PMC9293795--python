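import numpy as np
import pytest

from alphalat.lateralization import hemisphere
from alphalat.synth import (
    PowerStudyConfig,
    StudyConfig,
    TrialParams,
    coupling_slope_for_r,
    generate_study,
    generate_trial_signal,
    simulate_trial_power,
    study_ground_truth,
)
from alphalat.timefreq import build_wavelet_family, tf_power


def _small_config(**kw):
    base = dict(n_subjects=2, n_trials_per_session=4, seed=7)
    base.update(kw)
    return StudyConfig(**base)


PAIR_CHANNELS = {lab: hemisphere(lab)
                 for lab in ("P7", "P8", "P3", "P4", "CP5", "CP6")}


def _trial_params(**kw):
    base = dict(
        fs=250.0, n_samples=1000, cue_sample=250, cue_side="L",
        channels=("P7", "P8"), pair_channels=PAIR_CHANNELS,
        alpha_freq=10.0, alpha_amplitude=8.0, noise_amplitude=0.0,
        noise_exponent=1.0, li_profile=np.zeros(1000), amp_jitter_sd=0.0,
    )
    base.update(kw)
    return TrialParams(**base)


class TestConfigValidation:
    def test_defaults_valid(self):
        StudyConfig().validate()

    @pytest.mark.parametrize("kw", [
        {"n_subjects": 1},
        {"catch_fraction": 0.0},
        {"catch_fraction": 1.0},
        {"epoch_window": (-400.0, 4000.0)},
        {"li_amplitude_stress": np.nan},
        {"channels": ("Fz", "Cz", "P7", "P8")},
    ])
    def test_invalid_configs_rejected(self, kw):
        with pytest.raises(ValueError):
            _small_config(**kw).validate()


class TestTrialSignal:
    def test_equal_gains_give_identical_envelopes(self):
        """Zero noise + symmetric gains: both hemispheres carry the same
        alpha envelope (phases differ, power does not)."""
        rng = np.random.default_rng(0)
        sig = generate_trial_signal(_trial_params(), rng)
        assert np.std(sig[0]) == pytest.approx(np.std(sig[1]), rel=1e-3)

    def test_symmetric_before_cue(self):
        li = np.zeros(1000)
        li[250:] = 0.6
        rng = np.random.default_rng(1)
        sig = generate_trial_signal(_trial_params(li_profile=li), rng)
        pre = slice(50, 240)
        assert np.std(sig[0, pre]) == pytest.approx(np.std(sig[1, pre]),
                                                    rel=1e-2)
        # after the cue the contra (P8 for cue L) envelope is reduced
        post = slice(300, 950)
        assert np.std(sig[1, post]) < np.std(sig[0, post])

    def test_full_suppression_yields_li_plus_one(self):
        """g_contra = 0 with no noise: decomposed LI hits the +1 boundary."""
        rng = np.random.default_rng(2)
        sig = generate_trial_signal(
            _trial_params(li_profile=np.ones(1000)), rng)
        fam = build_wavelet_family(250.0, n=10, f_range=(5.0, 15.0),
                                   fwhm_range=(300.0, 150.0))
        tf = tf_power(sig[None], np.arange(1000) * 4.0, 250.0, fam,
                      ch_names=["P7", "P8"])
        fi = np.argmin(np.abs(fam.center_freqs - 10.0))
        ipsi = tf.power[0, 0, fi, 300:700]   # P7, cue L
        contra = tf.power[0, 1, fi, 300:700]
        li = (ipsi - contra) / (ipsi + contra)
        assert np.all(li > 0.99)

    def test_injected_li_recovered_across_trials(self):
        """Law of large numbers: many noisy trials average to LI 0.2."""
        rng = np.random.default_rng(3)
        fam = build_wavelet_family(250.0, n=5, f_range=(8.0, 12.0),
                                   fwhm_range=(300.0, 200.0))
        params = _trial_params(li_profile=np.full(1000, 0.2),
                               noise_amplitude=2.0, amp_jitter_sd=0.2)
        p_ipsi = np.zeros(0)
        acc_i = acc_c = 0.0
        for _ in range(120):
            sig = generate_trial_signal(params, rng)
            tf = tf_power(sig[None], np.arange(1000) * 4.0, 250.0, fam,
                          ch_names=["P7", "P8"])
            fi = np.argmin(np.abs(fam.center_freqs - 10.0))
            acc_i += tf.power[0, 0, fi, 300:700].mean()
            acc_c += tf.power[0, 1, fi, 300:700].mean()
        li = (acc_i - acc_c) / (acc_i + acc_c)
        assert li == pytest.approx(0.2, abs=0.02)

    @pytest.mark.parametrize("kw", [
        {"alpha_freq": 1.0},
        {"alpha_freq": 25.0},
        {"cue_side": "X"},
        {"li_profile": np.full(1000, 1.5)},
    ])
    def test_invalid_params_rejected(self, kw):
        with pytest.raises(ValueError):
            generate_trial_signal(_trial_params(**kw),
                                  np.random.default_rng(0))


class TestStudyGeneration:
    def test_bit_identical_under_same_seed(self):
        s1 = generate_study(_small_config())
        s2 = generate_study(_small_config())
        for key in s1.recordings:
            assert np.array_equal(s1.recordings[key].data,
                                  s2.recordings[key].data)
            assert s1.recordings[key].events == s2.recordings[key].events
            assert np.array_equal(s1.cortisol[key].concentrations,
                                  s2.cortisol[key].concentrations)
        assert s1.ground_truth.to_json() == s2.ground_truth.to_json()

    def test_different_seed_differs(self):
        s1 = generate_study(_small_config())
        s2 = generate_study(_small_config(seed=8))
        key = ("S01", 1)
        assert not np.array_equal(s1.recordings[key].data,
                                  s2.recordings[key].data)

    def test_marker_count_and_balance(self):
        study = generate_study(_small_config(n_trials_per_session=8))
        for rec in study.recordings.values():
            labels = [lab for _, lab in rec.events]
            assert len(labels) == 8
            assert labels.count("cueL") == 4

    def test_sessions_counterbalanced(self):
        study = generate_study(_small_config())
        assert study.conditions[("S01", 1)] == "stress"
        assert study.conditions[("S01", 2)] == "control"
        assert study.conditions[("S02", 1)] == "control"
        assert study.conditions[("S02", 2)] == "stress"

    def test_ground_truth_reproducible_without_eeg(self):
        cfg = _small_config()
        gt = study_ground_truth(cfg)
        study = generate_study(cfg)
        assert gt.to_json() == study.ground_truth.to_json()


class TestTrialPowerStudy:
    def test_deterministic(self):
        cfg = PowerStudyConfig(n_subjects=3, n_trials=10, seed=5)
        s1 = simulate_trial_power(cfg)
        s2 = simulate_trial_power(cfg)
        assert np.array_equal(s1.pow_contra, s2.pow_contra)
        assert np.array_equal(s1.delta_auci, s2.delta_auci)

    def test_null_study_has_no_mean_lateralization(self):
        """With all effects at zero the grand-average LI is within noise."""
        cfg = PowerStudyConfig(
            n_subjects=8, n_trials=80, li_amplitude_control=0.0,
            li_amplitude_stress=0.0, subject_sd=0.0, coupling_slope=0.0,
            coupling_noise_sd=0.0, window_boost_stress=0.0, seed=11,
        )
        st = simulate_trial_power(cfg)
        maps = st.subject_li_maps()
        grand = np.mean([maps["stress"], maps["control"]], axis=0)
        per_subject = grand.mean(axis=(1, 2))
        se = per_subject.std(ddof=1) / np.sqrt(len(per_subject))
        assert abs(per_subject.mean()) < 3.0 * se

    def test_injected_li_appears_in_band_and_interval(self):
        cfg = PowerStudyConfig(n_subjects=6, n_trials=120, subject_sd=0.0,
                               coupling_noise_sd=0.0, seed=2)
        st = simulate_trial_power(cfg)
        maps = st.subject_li_maps()
        f, t = st.freqs, st.times
        band = (f >= 8) & (f <= 14)
        inside = maps["stress"][:, band][:, :, (t >= 100) & (t <= 800)].mean()
        outside = maps["stress"][:, ~band].mean()
        assert inside > 0.08
        assert abs(outside) < 0.03

    def test_measured_li_increases_with_amplitude(self):
        """Monotonicity: larger injected amplitude, larger measured LI."""
        means = []
        for amp in (0.05, 0.15, 0.30):
            vals = []
            for rep in range(20):
                cfg = PowerStudyConfig(
                    n_subjects=4, n_trials=40, subject_sd=0.0,
                    li_amplitude_control=amp, li_amplitude_stress=amp,
                    li_profile_control=(1.0, 1.0, 1.0),
                    coupling_noise_sd=0.0, seed=1000 * rep + 17,
                )
                st = simulate_trial_power(cfg)
                maps = st.subject_li_maps()
                f, t = st.freqs, st.times
                sel = maps["control"][:, (f >= 8) & (f <= 14)]
                sel = sel[:, :, (t >= 0) & (t <= 2610)]
                vals.append(float(sel.mean()))
            means.append(np.mean(vals))
        assert means[0] < means[1] < means[2]

    def test_coupling_calibration_reaches_target_r(self):
        """The calibrated slope produces roughly the requested latent r."""
        cfg = PowerStudyConfig(n_subjects=2000, n_trials=1, seed=3)
        slope = coupling_slope_for_r(cfg, 0.6)
        rng = np.random.default_rng(0)
        dauc = cfg.delta_auci_mean + cfg.delta_auci_sd * rng.standard_normal(
            2000)
        p_s = cfg.li_profile_stress[1]
        p_c = cfg.li_profile_control[1]
        dli = (slope * dauc
               + rng.normal(0.0, cfg.coupling_noise_sd, 2000)
               + rng.normal(0.0, cfg.subject_sd * p_s, 2000)
               - rng.normal(0.0, cfg.subject_sd * p_c, 2000))
        r = np.corrcoef(dauc, dli)[0, 1]
        assert r == pytest.approx(0.6, abs=0.05)

    def test_invalid_target_r_rejected(self):
        with pytest.raises(ValueError):
            coupling_slope_for_r(PowerStudyConfig(), 1.5)
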