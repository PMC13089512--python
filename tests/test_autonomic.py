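"""IBI correction, heart-rate deceleration, EDA chain and SCR deconvolution."""

import numpy as np
import pandas as pd
import pytest

from remfrag.autonomic import (
    IbiRejectError,
    TrialPhysio,
    bateman,
    cda_scr,
    correct_ibi,
    hrd,
    ibi_artifact_criterion,
    preprocess_eda,
    resting_hrv,
    screen_nonresponders,
)


def make_trial(beat_times_ms, ibi_ms, onset=5.0, eda=None, eda_fs=None):
    return TrialPhysio(beat_times_ms=np.asarray(beat_times_ms, float),
                       ibi_ms=np.asarray(ibi_ms, float), eda=eda, eda_fs=eda_fs,
                       stim_onset_s=onset)


class TestIbiCorrection:
    def test_clean_series_untouched(self):
        res = correct_ibi(np.full(60, 1000.0))
        assert res.flagged.size == 0
        np.testing.assert_array_equal(res.corrected_ms, np.full(60, 1000.0))

    def test_single_spurious_beat_interpolated(self):
        ibi = np.full(40, 1000.0)
        ibi[20] = 400.0
        res = correct_ibi(ibi)
        assert res.flagged.tolist() == [20]
        assert res.corrected_ms[20] == pytest.approx(1000.0, abs=1.0)

    def test_three_artifacts_match_criterion_oracle(self):
        rng = np.random.default_rng(11)
        ibi = 1000.0 + rng.normal(0, 15, size=80)
        for i in (10, 40, 66):
            ibi[i] = 520.0
        res = correct_ibi(ibi)
        # brute-force oracle: same moving-median criterion evaluated by loops
        crit = ibi_artifact_criterion(ibi)
        expected = []
        for i in range(len(ibi)):
            lo, hi = max(0, i - 2), min(len(ibi), i + 3)
            if abs(ibi[i] - np.median(ibi[lo:hi])) > crit:
                expected.append(i)
        assert res.flagged.tolist() == expected == [10, 40, 66]

    def test_flagged_fraction_guard_rejects(self):
        ibi = np.full(40, 1000.0)
        ibi[[5, 15, 25]] = 400.0
        with pytest.raises(IbiRejectError):
            correct_ibi(ibi, max_flagged_fraction=0.05)

    def test_too_few_beats_rejected(self):
        with pytest.raises(ValueError):
            correct_ibi(np.array([900.0, 910, 905]))


class TestHrd:
    def test_constant_hr_gives_zero(self):
        beats = np.arange(1000, 16000, 1000.0)
        assert hrd(make_trial(beats, np.full(beats.size, 1000.0))) == pytest.approx(0.0)

    def test_formula_pre_mean_minus_post_min(self):
        beats = np.arange(1000, 13000, 1000.0)
        ibi = np.full(beats.size, 1000.0)      # HR 60 everywhere...
        ibi[7] = 60000.0 / 55.0                # ...except 55 bpm at t = 8 s
        assert hrd(make_trial(beats, ibi)) == pytest.approx(5.0, abs=1e-9)

    def test_insufficient_coverage_raises(self):
        beats = np.arange(1000, 8000, 1000.0)  # ends before onset + 6 s
        with pytest.raises(ValueError):
            hrd(make_trial(beats, np.full(beats.size, 1000.0)))

    def test_translation_and_offset_invariance(self):
        rng = np.random.default_rng(5)
        ibi = 900 + rng.normal(0, 30, 16).cumsum() * 0  # base rhythm
        ibi = 900 + rng.normal(0, 25, 16)
        beats = np.cumsum(ibi)
        base = hrd(make_trial(beats, ibi, onset=5.0))
        # time translation: shift beats and onset together
        shifted = hrd(make_trial(beats + 2000.0, ibi, onset=7.0))
        assert shifted == pytest.approx(base, abs=1e-9)
        # uniform HR offset: +k bpm everywhere leaves HRD unchanged
        hr = 60000.0 / ibi + 10.0
        ibi2 = 60000.0 / hr
        offset = hrd(make_trial(beats, ibi2, onset=5.0))
        assert offset == pytest.approx(base, abs=0.3)


class TestEda:
    def test_constant_trace_unchanged(self):
        out = preprocess_eda(np.full(3000, 2.5), fs=100.0)
        assert out.size == 300
        np.testing.assert_allclose(out, 2.5, atol=1e-9)

    def test_5hz_component_suppressed(self):
        t = np.arange(0, 30, 0.01)
        x = np.sin(2 * np.pi * 5 * t)
        out = preprocess_eda(x, fs=100.0)
        assert np.abs(out[20:-20]).max() < 0.05

    def test_step_smoothed_without_overshoot(self):
        x = np.r_[np.zeros(1500), np.ones(1500)]
        out = preprocess_eda(x, fs=100.0)
        assert out.max() <= 1.05 and out.min() >= -0.05
        # ramp through the step (10% to 90% crossings) is monotone
        lo = np.argmax(out > 0.1)
        hi = np.argmax(out > 0.9)
        assert np.all(np.diff(out[lo:hi]) > 0)

    def test_low_rate_rejected(self):
        with pytest.raises(ValueError):
            preprocess_eda(np.zeros(100), fs=5.0)


class TestCdaScr:
    def test_flat_trace_no_response(self):
        tr = make_trial(np.arange(1000, 16000, 1000.0), np.full(15, 1000.0),
                        eda=np.full(150, 2.0), eda_fs=10.0)
        res = cda_scr(tr)
        assert res.value == pytest.approx(0.0, abs=1e-6)
        assert not res.responded

    @pytest.mark.parametrize("mass", [0.5, 1.0, 2.0])
    def test_planted_driver_mass_recovered(self, mass):
        fs = 10.0
        t = np.arange(0, 15, 1 / fs)
        eda = 2.0 + mass * bateman(t - 5.0 - 2.0)   # driver mass at onset + 2 s
        tr = make_trial(np.arange(1000, 16000, 1000.0), np.full(15, 1000.0),
                        eda=eda, eda_fs=fs)
        res = cda_scr(tr)
        assert res.value == pytest.approx(mass / 5.0, rel=0.10)

    def test_linearity_in_driver_amplitude(self):
        fs = 10.0
        t = np.arange(0, 15, 1 / fs)
        vals = []
        for mass in (0.5, 2.0):                 # 4x range
            eda = 2.0 + mass * bateman(t - 7.0)
            tr = make_trial(np.arange(1000, 16000, 1000.0), np.full(15, 1000.0),
                            eda=eda, eda_fs=fs)
            vals.append(cda_scr(tr).value)
        assert vals[1] == pytest.approx(4 * vals[0], rel=0.10)

    def test_subthreshold_amplitude_not_a_response(self):
        fs = 10.0
        t = np.arange(0, 15, 1 / fs)
        peak = bateman(np.array([1.177]))[0]
        eda = 2.0 + (0.04 / peak) * bateman(t - 7.0)   # 0.04 uS peak
        tr = make_trial(np.arange(1000, 16000, 1000.0), np.full(15, 1000.0),
                        eda=eda, eda_fs=fs)
        assert not cda_scr(tr).responded

    def test_missing_eda_rejected(self):
        tr = make_trial(np.arange(1000, 16000, 1000.0), np.full(15, 1000.0))
        with pytest.raises(ValueError):
            cda_scr(tr)


class TestScreening:
    @staticmethod
    def _table(frac_by_subject):
        rows = []
        for subj, fracs in frac_by_subject.items():
            for cond, frac in fracs.items():
                n_resp = int(round(frac * 14))
                for k in range(14):
                    rows.append({"subject": subj, "condition": cond,
                                 "session": "T0", "stimulus_type": "negative",
                                 "responded": k < n_resp})
        return pd.DataFrame(rows)

    def test_two_of_fourteen_excluded(self):
        t = self._table({"a": {"CTR": 2 / 14, "FRG": 10 / 14}})
        assert not screen_nonresponders(t)["keep"].iloc[0]

    def test_three_of_fourteen_retained(self):
        t = self._table({"a": {"CTR": 3 / 14, "FRG": 3 / 14}})
        assert screen_nonresponders(t)["keep"].iloc[0]

    def test_cohort_matches_rule_oracle(self):
        rng = np.random.default_rng(2)
        fracs = {s: {"CTR": rng.integers(0, 15) / 14,
                     "FRG": rng.integers(0, 15) / 14} for s in range(12)}
        out = screen_nonresponders(self._table(fracs)).set_index("subject")
        for s, f in fracs.items():
            assert out.at[s, "keep"] == (f["CTR"] >= 0.2 and f["FRG"] >= 0.2)


class TestRestingHrv:
    def test_constant_ibis(self):
        out = resting_hrv(np.full(150, 1000.0))
        assert out["SDNN"] == 0.0 and out["RMSSD"] == 0.0
        assert out["mean_hr"] == pytest.approx(60.0)

    def test_alternating_ibis_closed_form(self):
        ibi = np.tile([990.0, 1010.0], 80)
        assert resting_hrv(ibi)["RMSSD"] == pytest.approx(20.0)

    def test_matches_loop_oracle(self, rng):
        ibi = 950 + rng.normal(0, 40, 200)
        out = resting_hrv(ibi)
        sdnn = np.sqrt(sum((x - ibi.mean()) ** 2 for x in ibi) / (len(ibi) - 1))
        rmssd = np.sqrt(np.mean([(a - b) ** 2 for a, b in zip(ibi[1:], ibi[:-1])]))
        assert out["SDNN"] == pytest.approx(sdnn)
        assert out["RMSSD"] == pytest.approx(rmssd)

    def test_short_segment_rejected(self):
        with pytest.raises(ValueError):
            resting_hrv(np.full(30, 1000.0))
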