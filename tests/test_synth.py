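"""Trial-sequence structure, diffusion observer, staircase and trace synthesis."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from histbias.ddm import DDMParams
from histbias.synth import (
    CohortSpec,
    ObserverSpec,
    TaskDesign,
    WeibullPsychometric,
    generate_cohort,
    generate_trial_sequence,
    run_quest_staircase,
    simulate_first_passages,
    simulate_fixed_block,
    simulate_observer,
    synthesize_ecg,
    synthesize_pupil,
)


class TestTrialSequence:
    def test_exact_within_block_counterbalancing(self, design):
        df = generate_trial_sequence(design, 3, seed=0)
        for _, block in df.groupby("block"):
            assert (block["stimulus_side"] == 1).sum() == design.trials_per_block // 2
            assert (block["stimulus_side"] == -1).sum() == design.trials_per_block // 2

    def test_first_trials_flagged_unavailable(self, design):
        df = generate_trial_sequence(design, 1, seed=0)
        flagged = df.loc[~df["prev_choice_available"], "trial_in_block"].tolist()
        assert flagged == [0, 40, 80, 120]

    def test_itis_within_range(self, design):
        df = generate_trial_sequence(design, 1, seed=3)
        assert df["iti"].between(*design.iti_range).all()

    def test_deterministic_given_seed(self, design):
        a = generate_trial_sequence(design, 2, seed=7)
        b = generate_trial_sequence(design, 2, seed=7)
        pd.testing.assert_frame_equal(a, b)

    def test_zero_blocks_rejected(self, design):
        with pytest.raises(ValueError):
            generate_trial_sequence(design, 0, seed=0)

    def test_indivisible_block_structure_rejected(self):
        with pytest.raises(ValueError, match="divisible"):
            TaskDesign(trials_per_block=150, minibreak_every=40).validate()

    def test_balanced_length4_blocks_match_enumeration(self):
        # exhaustive result: for 2/2-balanced blocks of length 4 the expected
        # adjacent-repeat fraction is 1/3 (sampling without replacement)
        design = TaskDesign(trials_per_block=4, minibreak_every=4)
        reps = []
        for seed in range(600):
            df = generate_trial_sequence(design, 1, seed=seed)
            s = df["stimulus_side"].to_numpy()
            reps.append(np.mean(s[1:] == s[:-1]))
        assert np.mean(reps) == pytest.approx(1.0 / 3.0, abs=0.02)


class TestDiffusionObserver:
    def test_strong_drift_gives_near_perfect_accuracy(self, design):
        params = DDMParams(a=1.4, v_weak=5.0, v_strong=5.0, t0=0.3)
        spec = ObserverSpec(ddm_placebo=params)
        seq = generate_trial_sequence(design, 1, seed=1)
        sim = simulate_observer(seq, spec, seed=2)
        assert sim["correct"].mean() > 0.98

    def test_zero_drift_symmetric_choices(self):
        choices, _ = simulate_first_passages(a=1.4, z=0.5, mu=0.0, n=10_000, seed=3)
        assert abs(np.mean(choices == 1) - 0.5) < 0.02

    def test_absorption_probability_matches_closed_form(self):
        # P(upper) = (1 - exp(-2 mu x0)) / (1 - exp(-2 mu a)) = 0.731 here
        choices, _ = simulate_first_passages(a=2.0, z=0.5, mu=0.5, n=100_000,
                                             dt=0.0005, seed=4)
        assert np.mean(choices == 1) == pytest.approx(0.7311, abs=0.006)

    def test_absorption_matches_closed_form_many_parameter_sets(self):
        rng = np.random.default_rng(0)
        for i in range(10):
            a = rng.uniform(0.8, 2.5)
            z = rng.uniform(0.3, 0.7)
            mu = rng.uniform(-1.5, 1.5)
            choices, _ = simulate_first_passages(a, z, mu, n=20_000, seed=100 + i)
            if abs(mu) < 1e-12:
                expect = z
            else:
                expect = -np.expm1(-2 * mu * z * a) / -np.expm1(-2 * mu * a)
            assert np.mean(choices == 1) == pytest.approx(expect, abs=0.015)

    def test_invalid_dt_rejected(self, design, biased_observer):
        seq = generate_trial_sequence(design, 1, seed=0)
        with pytest.raises(ValueError):
            simulate_observer(seq, biased_observer, dt=-0.001)
        with pytest.raises(ValueError):
            simulate_observer(seq, biased_observer, dt=0.01)

    def test_rt_bounds_and_correct_consistency(self, session_trials, design):
        resp = session_trials.dropna(subset=["rt"])
        assert (resp["rt"] > 0).all() and (resp["rt"] <= design.max_rt).all()
        assert (resp["correct"] == (resp["choice"] == resp["stimulus_side"])).all()

    def test_drug_shrinkage_reduces_vbias_shift_only(self, biased_observer):
        import dataclasses
        spec = dataclasses.replace(biased_observer, drug_bias_shrinkage=0.8)
        drug = spec.ddm_truth("atomoxetine")
        assert drug.vbias_prev_right - drug.vbias_prev_left == pytest.approx(0.3 * 0.2)
        assert drug.z_prev_right - drug.z_prev_left == pytest.approx(
            spec.ddm_placebo.z_prev_right - spec.ddm_placebo.z_prev_left
        )


class TestQuestStaircase:
    def test_converged_level_near_analytic(self):
        w = WeibullPsychometric(threshold=0.1, slope=3.5, lapse=0.0)
        level = run_quest_staircase(w, 0.70, n_trials=400, seed=5)
        assert level == pytest.approx(w.level_for(0.70), rel=0.15)

    @pytest.mark.parametrize("target", [0.70, 0.85])
    def test_accuracy_near_target(self, target):
        w = WeibullPsychometric()
        level = run_quest_staircase(w, target, n_trials=200, seed=6)
        acc = simulate_fixed_block(w, level, 1000, seed=7)
        assert acc == pytest.approx(target, abs=0.05)

    def test_invalid_target_rejected(self):
        with pytest.raises(ValueError):
            run_quest_staircase(WeibullPsychometric(), 0.45, 200, seed=0)


class TestTraces:
    def test_pupil_nan_only_inside_blinks(self, pupil_session):
        bad = np.flatnonzero(~np.isfinite(pupil_session.samples)) / pupil_session.fs
        for t in bad:
            assert any(s - 0.02 <= t <= e + 0.02 for s, e in pupil_session.blink_intervals)

    def test_zero_blink_rate_gives_no_dropout(self, session_trials, biased_observer):
        tr = synthesize_pupil(session_trials, biased_observer, seed=8, blink_rate=0.0)
        assert np.isfinite(tr.samples).all()

    def test_low_sampling_rate_rejected(self, session_trials, biased_observer):
        with pytest.raises(ValueError):
            synthesize_pupil(session_trials, biased_observer, fs=10.0, seed=0)

    def test_ecg_beat_count_matches_rate(self):
        ecg = synthesize_ecg(60.0, 60.0, seed=9)
        assert len(ecg.true_rpeak_times) == pytest.approx(60, abs=3)

    def test_ecg_zero_jitter_periodic(self):
        ecg = synthesize_ecg(60.0, 60.0, seed=10, ibi_jitter_sd=0.0)
        ibis = np.diff(ecg.true_rpeak_times)
        assert np.allclose(ibis, 1.0, atol=1e-9)

    def test_ecg_rate_bounds(self):
        with pytest.raises(ValueError):
            synthesize_ecg(60.0, 150.0, seed=0)


class TestCohort:
    def test_shape_and_trial_totals(self):
        coh = generate_cohort(2, seed=42)
        per = coh.trials.groupby("participant_id").size()
        assert len(per) == 2
        # 4 sessions x 6 blocks x 160 trials, within the reported 3,520-4,320
        assert (per == 4 * 6 * 160).all()
        sessions = coh.trials.groupby(["participant_id", "session_id"])["drug"].first()
        for pid in per.index:
            assert sorted(sessions[pid].tolist()) == ["atomoxetine", "atomoxetine",
                                                      "placebo", "placebo"]

    def test_deterministic_given_seed(self):
        a = generate_cohort(2, seed=43).trials
        b = generate_cohort(2, seed=43).trials
        pd.testing.assert_frame_equal(a, b)

    def test_ground_truth_ledger_complete(self):
        coh = generate_cohort(2, seed=44)
        truth = coh.ground_truth
        assert set(truth) == {"p00", "p01"}
        for v in truth.values():
            assert "ddm_placebo" in v and "ddm_atomoxetine" in v

    def test_too_few_participants_rejected(self):
        with pytest.raises(ValueError):
            generate_cohort(1, seed=0)


@settings(max_examples=20, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=10_000))
def test_sequence_determinism_property(seed):
    d = TaskDesign(trials_per_block=8, minibreak_every=4, n_blocks_per_session=1)
    a = generate_trial_sequence(d, 1, seed=seed)
    b = generate_trial_sequence(d, 1, seed=seed)
    assert (a["stimulus_side"] == b["stimulus_side"]).all()
    assert (a["strength"] == b["strength"]).all()


class TestTraceSerialization:
    def test_pupil_csv_round_trip(self, pupil_session, tmp_path):
        f = tmp_path / "pupil.csv"
        pupil_session.to_csv(f)
        from histbias.synth import PupilTrace
        back = PupilTrace.from_csv(f)
        assert back.fs == pupil_session.fs
        assert np.allclose(back.samples, pupil_session.samples,
                           atol=1e-9, equal_nan=True)
        assert back.blink_intervals == pupil_session.blink_intervals
        assert np.allclose(back.choice_times, pupil_session.choice_times,
                           atol=1e-9, equal_nan=True)
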