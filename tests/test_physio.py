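"""Pupil preprocessing chain, tpr quantification, R-peak detection, binning."""

import numpy as np
import pandas as pd
import pytest

from histbias import physio
from histbias.synth import (
    EcgTrace,
    PupilTrace,
    pupil_irf,
    synthesize_ecg,
)


def _trace(samples, fs=100.0, blinks=(), saccades=(), blocks=()):
    n = len(samples)
    return PupilTrace(
        fs=fs, samples=np.asarray(samples, dtype=float),
        blink_intervals=list(blinks), saccade_times=list(saccades),
        trial_onsets=np.array([]), choice_times=np.array([]),
        feedback_times=np.array([]), block_bounds=list(blocks),
    )


class TestInterpolation:
    def test_identity_without_gaps(self):
        x = np.sin(np.arange(500) / 40)
        out = physio.interpolate_missing(_trace(x))
        assert np.array_equal(out.samples, x)

    def test_linear_ramp_restored_exactly(self):
        x = np.linspace(0, 10, 1000)
        y = x.copy()
        y[400:450] = np.nan
        out = physio.interpolate_missing(_trace(y))
        assert np.allclose(out.samples, x, atol=1e-9)

    def test_gap_replaced_by_chord_between_padded_endpoints(self):
        fs = 100.0
        t = np.arange(2000) / fs
        x = np.sin(2 * np.pi * 0.5 * t)
        y = x.copy()
        y[1000:1050] = np.nan
        out = physio.interpolate_missing(_trace(y, fs=fs))
        i0, i1 = 1000 - 15, 1049 + 15  # 150 ms pad
        expect = np.interp(np.arange(i0, i1 + 1), [i0 - 1, i1 + 1], [x[i0 - 1], x[i1 + 1]])
        assert np.allclose(out.samples[i0: i1 + 1], expect, atol=1e-9)

    def test_fully_missing_rejected(self):
        with pytest.raises(ValueError):
            physio.interpolate_missing(_trace(np.full(100, np.nan)))

    def test_idempotent(self):
        y = np.sin(np.arange(1000) / 50)
        y[300:330] = np.nan
        once = physio.interpolate_missing(_trace(y))
        twice = physio.interpolate_missing(once)
        assert np.array_equal(once.samples, twice.samples)


class TestLowpass:
    def test_dc_gain_is_unity(self):
        out = physio.lowpass(_trace(np.full(2000, 7.0)))
        assert np.allclose(out.samples, 7.0, atol=1e-9)

    def test_stopband_attenuation(self):
        # 20 Hz at a 6 Hz third-order cut-off: |H|^2 (zero-phase) ~ 7e-4
        t = np.arange(4000) / 100.0
        out = physio.lowpass(_trace(np.sin(2 * np.pi * 20 * t)))
        mid = out.samples[500:-500]
        assert np.max(np.abs(mid)) < 0.05

    def test_passband_preserved(self):
        t = np.arange(30000) / 100.0
        out = physio.lowpass(_trace(np.sin(2 * np.pi * 0.1 * t)))
        mid = out.samples[2000:-2000]
        assert np.max(np.abs(mid)) == pytest.approx(1.0, abs=0.01)

    def test_cutoff_above_nyquist_rejected(self):
        with pytest.raises(ValueError):
            physio.lowpass(_trace(np.zeros(100), fs=10.0), cutoff=6.0)


class TestDeconvolution:
    def _planted(self, seed=0, n_events=40, noise=0.3, fs=50.0, dur=400.0):
        rng = np.random.default_rng(seed)
        n = int(dur * fs)
        kt = np.arange(int(4.0 * fs)) / fs
        kernel = pupil_irf(kt) - 0.4 * pupil_irf(kt, shape=5, t_max=2.0)
        times = np.sort(rng.uniform(5, dur - 10, n_events))
        x = noise * rng.standard_normal(n)
        for ti in times:
            i0 = int(round(ti * fs))
            x[i0: i0 + len(kernel)] += kernel[: n - i0]
        return _trace(x, fs=fs), {"blink": times}, kernel

    def test_white_noise_round_trip(self):
        trace, events, kernel = self._planted()
        est = physio.estimate_event_irfs(trace, events, window=4.0)
        r = np.corrcoef(est.kernels["blink"], kernel)[0, 1]
        assert r > 0.95

    def test_zero_events_gives_zero_kernel_with_flag(self):
        trace, events, _ = self._planted()
        events["saccade"] = []
        est = physio.estimate_event_irfs(trace, events, window=4.0)
        assert not np.any(est.kernels["saccade"])
        assert any("saccade" in f for f in est.flags)

    def test_joint_equals_separate_for_disjoint_events(self):
        trace, events, _ = self._planted(n_events=20)
        # second event type far from the first half's events
        events2 = {"blink": events["blink"][:10], "other": events["blink"][10:] + 0.0}
        joint = physio.estimate_event_irfs(trace, events2, window=2.0)
        sep_b = physio.estimate_event_irfs(trace, {"blink": events2["blink"]}, window=2.0)
        # disjoint, non-overlapping designs: joint estimate matches marginal
        assert np.corrcoef(joint.kernels["blink"], sep_b.kernels["blink"])[0, 1] > 0.99

    def test_removal_of_pure_artifact_leaves_nothing(self):
        trace, events, kernel = self._planted(noise=0.0)
        est = physio.estimate_event_irfs(trace, events, window=4.0)
        out = physio.remove_event_responses(trace, est, events)
        assert np.max(np.abs(out.samples)) < 0.05 * np.max(np.abs(kernel))

    def test_removal_without_events_is_identity(self):
        trace, _, _ = self._planted()
        est = physio.IrfEstimate(kernels={}, fs=trace.fs, window=4.0)
        out = physio.remove_event_responses(trace, est, {})
        assert np.array_equal(out.samples, trace.samples)

    def test_residual_uncorrelated_with_planted_artifact(self):
        trace, events, kernel = self._planted(noise=0.5, n_events=60)
        est = physio.estimate_event_irfs(trace, events, window=4.0)
        out = physio.remove_event_responses(trace, est, events)
        artifact = trace.samples - 0.5 * 0  # reconstruct planted component
        planted = np.zeros_like(trace.samples)
        for ti in events["blink"]:
            i0 = int(ti * trace.fs)
            planted[i0: i0 + len(kernel)] += kernel[: len(planted) - i0]
        r = np.corrcoef(out.samples, planted)[0, 1]
        assert abs(r) < 0.1


class TestPsc:
    def test_constant_trace_maps_to_zero(self):
        out = physio.to_psc(_trace(np.full(100, 1234.0)))
        assert np.allclose(out.samples, 0.0)

    def test_scale_invariance_exact(self):
        x = 1000 + 50 * np.sin(np.arange(1000) / 30)
        a = physio.to_psc(_trace(x)).samples
        b = physio.to_psc(_trace(2 * x)).samples
        assert np.allclose(a, b, atol=1e-10)

    def test_arithmetic(self):
        x = np.full(10, 1000.0)
        x[0] = 1010.0
        x = x - (x.mean() - 1000.0)  # keep mean exactly 1000
        out = physio.to_psc(_trace(np.concatenate([[1010.0], np.full(1000, 1000.0)])))
        # sample 1010 around a mean of ~1000 -> ~1 PSC
        assert out.samples[0] == pytest.approx(1.0, abs=0.02)

    def test_nonpositive_mean_rejected(self):
        with pytest.raises(ValueError):
            physio.to_psc(_trace(np.full(100, -5.0)))


class TestTaskEvokedResponse:
    def test_flat_trace_gives_zero(self):
        clean = physio.CleanPupil(fs=100.0, samples=np.zeros(5000))
        tpr = physio.task_evoked_response(clean, np.array([20.0]), np.array([19.0]))
        assert tpr[0] == 0.0

    def test_unit_step_at_choice(self):
        x = np.zeros(5000)
        x[2000:] = 1.0  # step exactly at the choice report
        clean = physio.CleanPupil(fs=100.0, samples=x)
        tpr = physio.task_evoked_response(clean, np.array([20.0]), np.array([19.0]))
        assert tpr[0] == pytest.approx(1.0)

    def test_invariant_to_constant_offset(self):
        rng = np.random.default_rng(4)
        x = rng.standard_normal(5000)
        clean1 = physio.CleanPupil(fs=100.0, samples=x)
        clean2 = physio.CleanPupil(fs=100.0, samples=x + 37.5)
        ct, ot = np.array([20.0, 30.0]), np.array([19.0, 29.0])
        assert np.allclose(
            physio.task_evoked_response(clean1, ct, ot),
            physio.task_evoked_response(clean2, ct, ot),
            atol=1e-10,
        )

    def test_window_outside_trace_flagged_missing(self):
        clean = physio.CleanPupil(fs=100.0, samples=np.zeros(100))
        tpr = physio.task_evoked_response(clean, np.array([50.0]), np.array([49.0]))
        assert np.isnan(tpr[0])


class TestBlockwise:
    def test_constant_trace_block_means(self):
        tr = _trace(np.full(6000, 3.0), blocks=[(0, 30), (30, 60)])
        assert np.allclose(physio.blockwise_pupil(tr), 3.0)

    def test_heart_rate_arithmetic(self):
        ecg = EcgTrace(fs=250.0, samples=np.zeros(250 * 60),
                       true_rpeak_times=np.arange(72) / 72 * 60,
                       block_bounds=[(0.0, 60.0)])
        hr = physio.blockwise_heart_rate(ecg, peak_times=ecg.true_rpeak_times)
        assert hr[0] == pytest.approx(72.0)


class TestRpeakDetection:
    def test_noiseless_train_fully_recovered(self):
        ecg = synthesize_ecg(120.0, 70.0, seed=1, noise_sd=0.0)
        peaks = physio.detect_rpeaks(ecg)
        assert len(peaks) == len(ecg.true_rpeak_times)

    def test_high_sensitivity_with_noise(self):
        ecg = synthesize_ecg(300.0, 65.0, seed=2, noise_sd=0.1)  # SNR 10
        peaks = physio.detect_rpeaks(ecg)
        hits = np.mean([np.min(np.abs(peaks - t)) < 0.05 for t in ecg.true_rpeak_times])
        assert hits >= 0.99

    def test_refractory_period_prevents_double_counting(self):
        fs = 250.0
        t = np.arange(int(5 * fs)) / fs
        x = np.exp(-0.5 * ((t - 2.5) / 0.05) ** 2)  # one wide peak
        ecg = EcgTrace(fs=fs, samples=x + 0.01 * np.random.default_rng(0).standard_normal(len(t)),
                       true_rpeak_times=np.array([2.5]))
        peaks = physio.detect_rpeaks(ecg)
        assert len(peaks) == 1


class TestBinning:
    def _trials(self, n=400, seed=0):
        rng = np.random.default_rng(seed)
        return pd.DataFrame(
            {
                "participant_id": "p00",
                "tpr": rng.standard_normal(n),
                "repeat": rng.random(n) < 0.55,
                "correct": rng.random(n) < 0.75,
                "rt": rng.uniform(0.3, 1.5, n),
            }
        )

    def test_single_bin_equals_overall(self):
        df = self._trials()
        binned = physio.bin_trials_by_tpr(df, n_bins=1)
        assert binned["repeat"].iloc[0] == pytest.approx(df["repeat"].mean())

    def test_equal_counts(self):
        binned = physio.bin_trials_by_tpr(self._trials(n=401), n_bins=8)
        counts = binned["n_trials"]
        assert counts.max() - counts.min() <= 1

    def test_demeaned_bin_index(self):
        binned = physio.bin_trials_by_tpr(self._trials(), n_bins=8)
        assert binned["P"].mean() == pytest.approx(0.0)

    def test_too_many_bins_rejected(self):
        with pytest.raises(ValueError):
            physio.bin_trials_by_tpr(self._trials(n=50), n_bins=8)
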