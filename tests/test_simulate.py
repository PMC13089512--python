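"""Synthetic cohort generators: determinism, protocol rules, planted recovery."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

import remfrag.simulate as sim
from remfrag.autonomic import hrd
from remfrag.hypnogram import transition_matrix
from remfrag.sdt import counts_from_table, dprime
from remfrag.timefreq import band_topography, baseline_db, morlet_ersp


class TestConfigValidation:
    def test_defaults_valid(self):
        sim.CohortConfig()

    def test_non_stochastic_rows_rejected(self):
        bad = sim._default_transitions()
        bad["CTR"] = bad["CTR"] * 1.01
        with pytest.raises(ValueError, match="sum to 1"):
            sim.CohortConfig(transitions=bad)

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError):
            sim.CohortConfig(n_subjects=1)

    def test_negative_dprime_rejected(self):
        with pytest.raises(ValueError):
            sim.CohortConfig(memory=sim.MemoryParams(
                dprime={"T0": -1.0, "T1": 1.0, "T2": 1.0}))

    def test_nonpositive_hr_rejected(self):
        with pytest.raises(ValueError):
            sim.CohortConfig(autonomic=sim.AutonomicParams(baseline_hr_bpm=0.0))

    def test_negative_scr_rejected(self):
        with pytest.raises(ValueError):
            sim.CohortConfig(autonomic=sim.AutonomicParams(
                scr_amp_us={"negative": -0.1, "neutral": 0.1}))

    def test_invalid_condition_label(self, config):
        with pytest.raises(ValueError):
            sim.generate_hypnogram(config, 0, "XXX")


class TestHypnogramGeneration:
    def test_control_night_has_no_stimulations(self, config):
        _, ev = sim.generate_hypnogram(config, 0, "CTR")
        assert (ev["type"] == "stim_on").sum() == 0

    def test_certain_arousal_makes_single_stim_trains(self):
        cfg = sim.CohortConfig(
            n_subjects=2, seed=3,
            stim=sim.StimProtocolParams(arousal_prob=(1.0,) * 7, stray_stims=0))
        _, ev = sim.generate_hypnogram(cfg, 0, "FRG")
        stims = ev[ev["type"] == "stim_on"]
        assert len(stims) > 0
        assert stims.groupby("train_id").size().max() == 1

    def test_intensity_escalates_within_train(self):
        cfg = sim.CohortConfig(
            n_subjects=2, seed=4,
            stim=sim.StimProtocolParams(arousal_prob=(0.0,) * 6 + (1.0,),
                                        stray_stims=0))
        _, ev = sim.generate_hypnogram(cfg, 0, "FRG")
        stims = ev[ev["type"] == "stim_on"]
        for _, tr in stims.groupby("train_id"):
            steps = tr.sort_values("onset_s")["intensity_step"].tolist()
            assert steps == sorted(steps)

    def test_deterministic_under_fixed_seed(self, config):
        h1, e1 = sim.generate_hypnogram(config, 1, "FRG")
        h2, e2 = sim.generate_hypnogram(config, 1, "FRG")
        assert h1.stages == h2.stages
        pd.testing.assert_frame_equal(e1, e2)

    def test_empirical_transitions_match_generator_matrix(self):
        cfg = sim.CohortConfig(n_subjects=2, seed=9, n_epochs=10_000)
        h, _ = sim.generate_hypnogram(cfg, 0, "CTR")
        tm = transition_matrix(h)
        P = cfg.transitions["CTR"]
        for i in range(5):
            n_row = tm.counts[i].sum()
            if n_row < 50:
                continue
            se = np.sqrt(P[i] * (1 - P[i]) / n_row)
            assert np.all(np.abs(tm.P[i] - P[i]) <= 3 * se + 1e-12)


class TestEegGeneration:
    def test_byte_identical_under_fixed_seed(self, config):
        a, _ = sim.generate_eeg_epochs(config, 0, 3)
        b, _ = sim.generate_eeg_epochs(config, 0, 3)
        np.testing.assert_array_equal(a, b)

    def test_zero_effect_epochs_are_null(self):
        cfg = sim.CohortConfig(n_subjects=2, seed=6,
                               eeg=sim.EegParams(bursts=(), ch_names=("Cz", "Pz")))
        eps, truth = sim.generate_eeg_epochs(cfg, 0, 50)
        db = baseline_db(morlet_ersp(eps, cfg.eeg.sfreq))
        sel = db.time_mask((0, 6000))
        post = np.nanmean(db.values[:, :, sel])
        assert abs(post) < 0.2
        assert truth.channel_db == {}

    def test_planted_alpha_burst_recovered(self):
        burst = sim.BandBurst("alpha", 3.0, 6.0, 8.0, 11.8, (1.0, 1.0, 1.0))
        cfg = sim.CohortConfig(
            n_subjects=2, seed=8,
            eeg=sim.EegParams(bursts=(burst,), ch_names=("P3", "Pz", "P4"),
                              alpha_subject_sd_db=0.0,
                              alpha_dev_weights=(0.0, 0.0, 0.0)))
        eps, truth = sim.generate_eeg_epochs(cfg, 0, 50)
        db = baseline_db(morlet_ersp(eps, cfg.eeg.sfreq))
        topo = band_topography(db, "alpha")
        assert truth.channel_db["alpha"] == pytest.approx(3.0)
        np.testing.assert_allclose(topo.values, 3.0, atol=0.5)

    def test_burst_longer_than_window_rejected(self):
        with pytest.raises(ValueError, match="window shorter"):
            sim.CohortConfig(eeg=sim.EegParams(
                bursts=(sim.BandBurst("alpha", 3.0, 20.0, 8.0, 11.8,
                                      sim._weights(1, 1, 1)),)))


class TestAutonomicGeneration:
    def test_zero_amplitude_yields_near_zero_hrd(self):
        cfg = sim.CohortConfig(
            n_subjects=2, seed=5,
            autonomic=replace(sim.AutonomicParams(),
                              hrd_amp_bpm={"CTR": (0., 0., 0.), "FRG": (0., 0., 0.)},
                              trial_noise_sd_bpm=0.0, subject_sd_bpm=0.0,
                              session_dev_sd_bpm=0.0, stimulus_sd_bpm=0.0))
        trials = sim.generate_autonomic_trials(cfg, 0, "CTR", "T0")
        vals = [hrd(t) for t in trials]
        assert np.allclose(vals, 0.0, atol=0.3)

    def test_planted_amplitude_recovered_within_se(self):
        cfg = sim.CohortConfig(
            n_subjects=2, seed=15,
            autonomic=replace(sim.AutonomicParams(),
                              hrd_amp_bpm={"CTR": (5., 5., 5.), "FRG": (5., 5., 5.)},
                              neutral_scale=1.0, trial_noise_sd_bpm=1.0,
                              subject_sd_bpm=0.0, session_dev_sd_bpm=0.0,
                              stimulus_sd_bpm=0.0))
        trials = sim.generate_autonomic_trials(cfg, 0, "CTR", "T0")
        vals = [hrd(t) for t in trials]
        assert np.mean(vals) == pytest.approx(5.0, abs=1.0)

    def test_habituation_pattern_planted(self, config):
        a = config.autonomic
        assert a.hrd_amp_bpm["CTR"][0] > a.hrd_amp_bpm["CTR"][1]
        assert a.hrd_amp_bpm["FRG"][0] == a.hrd_amp_bpm["FRG"][1]

    def test_invalid_session_rejected(self, config):
        with pytest.raises(ValueError):
            sim.generate_autonomic_trials(config, 0, "CTR", "T9")


class TestRecognitionGeneration:
    def test_chance_model_rates_near_half(self):
        cfg = sim.CohortConfig(
            n_subjects=2, seed=21,
            memory=sim.MemoryParams(dprime={"T0": 0., "T1": 0., "T2": 0.},
                                    criterion=0.0, subject_sd=0.0,
                                    n_old=200, n_new=200))
        t = sim.generate_recognition(cfg, 0, "CTR", "T0")
        c = counts_from_table(t)
        assert c.hits / c.n_old == pytest.approx(0.5, abs=0.12)
        assert c.false_alarms / c.n_new == pytest.approx(0.5, abs=0.12)

    def test_extreme_criterion_silences_old_responses(self):
        cfg = sim.CohortConfig(n_subjects=2, seed=22,
                               memory=sim.MemoryParams(criterion=50.0))
        t = sim.generate_recognition(cfg, 0, "CTR", "T0")
        assert (t["response"] == "NEW").all()

    def test_planted_dprime_recovered_across_subjects(self):
        cfg = sim.CohortConfig(
            n_subjects=200, seed=23,
            memory=sim.MemoryParams(dprime={"T0": 2.0, "T1": 2.0, "T2": 2.0},
                                    subject_sd=0.0))
        ds = [dprime(counts_from_table(sim.generate_recognition(cfg, s, "CTR", "T0")))
              for s in range(200)]
        assert np.mean(ds) == pytest.approx(2.0, abs=0.35)


class TestCoupling:
    def test_subject_truth_is_pure(self, config):
        assert sim.subject_truth(config, 3) == sim.subject_truth(config, 3)

    def test_planted_coupling_magnitude(self):
        cfg = sim.CohortConfig(n_subjects=400, seed=31)
        alpha = np.array([sim.subject_truth(cfg, s).alpha_dev_db for s in range(400)])
        delta = np.array([sim.subject_truth(cfg, s).delta_hrd_dev_bpm
                          for s in range(400)])
        r = np.corrcoef(alpha, delta)[0, 1]
        assert r == pytest.approx(cfg.coupling.r, abs=0.1)

    def test_topography_cohort_shapes_and_determinism(self, config):
        m1, d1 = sim.generate_band_topography_cohort(config)
        m2, d2 = sim.generate_band_topography_cohort(config)
        assert m1.shape == (config.n_subjects, 19)
        np.testing.assert_array_equal(m1, m2)
        np.testing.assert_array_equal(d1, d2)
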