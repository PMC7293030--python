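"""TPM analysis: drift removal, QC, rolling sigma, state and transition calls."""
import numpy as np
import pytest

from loopfold import tpm
from loopfold.synthgen import TPMSimSpec, TPMState, simulate_tpm_trace


def make_trace(x, y=None, label="0uM", length=105.0):
    n = len(x)
    if y is None:
        y = np.array(x, dtype=float)
    return tpm.BeadTrace(np.arange(n) * 0.2, x, y, np.repeat(label, n), length)


def make_rs(sigma, window=50):
    sigma = np.asarray(sigma, dtype=float)
    return tpm.RollingSigma(np.arange(len(sigma)) * 0.2, sigma, window)


class TestRemoveDrift:
    def test_linear_trend_removed(self, rng):
        t = np.arange(1000) * 0.2
        trace = make_trace(3.0 * t + rng.normal(0, 5, 1000))
        out = tpm.remove_drift(trace)
        coeff, cov = np.polyfit(t, out.x_nm, 1, cov=True)
        assert abs(coeff[0]) < np.sqrt(cov[0, 0])

    def test_pure_line_maps_to_zero(self):
        t = np.arange(100) * 0.2
        out = tpm.remove_drift(make_trace(5.0 * t - 2.0))
        assert np.abs(out.x_nm).max() < 1e-9

    def test_idempotent(self, rng):
        trace = make_trace(rng.normal(0, 59, 500) + 0.4 * np.arange(500))
        once = tpm.remove_drift(trace)
        twice = tpm.remove_drift(once)
        assert np.allclose(once.x_nm, twice.x_nm, atol=1e-9)

    def test_per_segment_removal(self, rng):
        x = np.concatenate([2.0 * np.arange(200.0), -1.5 * np.arange(300.0)])
        labels = np.repeat(["a", "b"], [200, 300])
        trace = tpm.BeadTrace(np.arange(500) * 0.2, x, x, labels)
        out = tpm.remove_drift(trace)
        for _, sl in out.segments():
            assert np.abs(out.x_nm[sl]).max() < 1e-6

    def test_short_segment_warns_and_passes_through(self):
        labels = np.repeat(["a", "b"], [495, 5])
        x = np.arange(500.0)
        trace = tpm.BeadTrace(np.arange(500) * 0.2, x, x, labels)
        with pytest.warns(UserWarning, match="drift not removed"):
            out = tpm.remove_drift(trace)
        assert np.array_equal(out.x_nm[495:], x[495:])


class TestQC:
    def test_isotropic_bead_has_zero_eccentricity(self, rng):
        x = rng.normal(0, 59, 2000)
        trace = make_trace(x, np.array(x))
        qc = tpm.qc_tether(trace)
        assert qc.eccentricity == 0.0 and qc.pass_eccentricity

    def test_eccentricity_cut_is_strict(self, rng):
        y = rng.normal(0, 59, 2000)
        x = 0.7975 * y  # sigma ratio exactly 0.7975 -> e = 0.45
        qc = tpm.qc_tether(make_trace(x, y))
        assert qc.eccentricity == pytest.approx(0.45, abs=1e-12)
        assert not qc.pass_eccentricity

    def test_whole_trace_sigma_cutoff(self, rng):
        x = rng.normal(0, 1, 2000)
        x *= 39.0 / np.std(x, ddof=1)  # exactly 39 nm, below the 40-nm cutoff
        qc = tpm.qc_tether(make_trace(x, np.array(x), length=105.0))
        assert qc.sigma_cutoff_nm == 40.0 and not qc.pass_sigma
        assert not qc.passed

    def test_zero_sigma_y_fails_with_reason(self):
        trace = make_trace(np.arange(100.0), np.zeros(100))
        qc = tpm.qc_tether(trace, sigma_cutoff_nm=40.0)
        assert not qc.passed and "sigma_y" in qc.reason


class TestRollingSigma:
    def test_constant_trace_gives_zero(self):
        rs = tpm.rolling_sigma(make_trace(np.full(200, 7.0)))
        assert np.allclose(rs.sigma_nm, 0.0)
        assert len(rs.sigma_nm) == 200 - 50 + 1

    def test_alternating_trace_closed_form(self):
        x = 3.0 * (-1.0) ** np.arange(200)
        rs = tpm.rolling_sigma(make_trace(x))
        assert np.allclose(rs.sigma_nm, 3.0 * np.sqrt(50 / 49), atol=1e-9)

    def test_single_state_mean_level(self):
        trace, _ = simulate_tpm_trace(TPMSimSpec([TPMState(59, 59, 400.0)],
                                                 seed=2))
        rs = tpm.rolling_sigma(trace)
        assert np.mean(rs.sigma_nm) == pytest.approx(59, abs=2)

    def test_drift_invariance_after_removal(self):
        plain, _ = simulate_tpm_trace(TPMSimSpec([TPMState(59, 59, 400.0)],
                                                 seed=6))
        drifted, _ = simulate_tpm_trace(TPMSimSpec(
            [TPMState(59, 59, 400.0)], drift_nm_per_s=(1.0, 0.5), seed=6))
        drifted.tether_length_nm = plain.tether_length_nm = 105.0
        a = tpm.rolling_sigma(tpm.remove_drift(plain))
        b = tpm.rolling_sigma(tpm.remove_drift(drifted))
        assert np.abs(a.sigma_nm - b.sigma_nm).max() < 0.5


class TestDetectStates:
    def test_single_gaussian_gives_one_peak(self, rng):
        rs = make_rs(rng.normal(59, 2, 2000))
        model = tpm.detect_states(rs)
        assert len(model.peaks) == 1
        assert model.peaks[0].sigma_nm == pytest.approx(59, abs=1)

    def test_two_clusters_give_two_peaks(self, rng):
        rs = make_rs(np.concatenate([rng.normal(20, 2, 500),
                                     rng.normal(59, 2, 500)]))
        model = tpm.detect_states(rs)
        assert len(model.peaks) == 2
        assert model.peaks[0].sigma_nm == pytest.approx(20, abs=1)
        assert model.peaks[1].sigma_nm == pytest.approx(59, abs=1)

    def test_low_count_histogram_has_no_peaks(self, rng):
        # every bin stays at or below the window size -> no qualifying peak
        rs = make_rs(rng.uniform(0, 100, 500))
        assert tpm.detect_states(rs).peaks == []

    def test_peaks_below_detection_limit_flagged(self, rng):
        rs = make_rs(np.abs(rng.normal(4, 0.8, 1000)))
        model = tpm.detect_states(rs)
        assert model.peaks and not model.peaks[0].reliable

    def test_reported_peaks_satisfy_count_rule(self):
        trace, _ = simulate_tpm_trace(TPMSimSpec(
            [TPMState(59, 59, 150.0), TPMState(20, 20, 150.0)], seed=4))
        rs = tpm.rolling_sigma(trace)
        model = tpm.detect_states(rs)
        for peak in model.peaks:
            assert peak.count > rs.window
            # a qualifying histogram bin backs every reported peak
            centres = 0.5 * (model.bin_edges[:-1] + model.bin_edges[1:])
            near = np.abs(centres - peak.sigma_nm) < 8
            assert model.counts[near].max() > rs.window

    def test_state_ladder_recovery(self):
        """Three-state ladders (dwell >= 100 s, separations >= 5 nm within
        resolution) are recovered in >= 95% of seeds, locations within 3 nm."""
        hits = 0
        for seed in range(20):
            trace, _ = simulate_tpm_trace(TPMSimSpec(
                [TPMState(59, 59, 150.0), TPMState(35, 35, 150.0),
                 TPMState(20, 20, 150.0)], seed=seed))
            model = tpm.detect_states(tpm.rolling_sigma(trace))
            locs = model.peak_locations
            if len(locs) == 3 and np.allclose(locs, [20, 35, 59], atol=3):
                hits += 1
        assert hits >= 19


class TestTransitions:
    def test_instant_step_is_one_discrete_forward(self):
        rs = make_rs(np.concatenate([np.full(500, 59.0), np.full(500, 20.0)]))
        model = tpm.detect_states(rs)
        trans = tpm.detect_transitions(rs, model)
        assert len(trans) == 1
        assert trans[0].direction == "forward"
        assert trans[0].transition_class == "discrete"

    def test_fold_and_unfold_cycle(self):
        trace, _ = simulate_tpm_trace(TPMSimSpec(
            [TPMState(59, 59, 200.0), TPMState(20, 20, 200.0),
             TPMState(59, 59, 200.0)], seed=3))
        rs = tpm.rolling_sigma(trace)
        trans = tpm.detect_transitions(rs, tpm.detect_states(rs))
        directions = [t.direction for t in trans]
        assert directions == ["forward", "reverse"]

    def test_slow_ramp_classified_gradual(self):
        ramp = np.linspace(59.0, 20.0, 75)  # 15 s at 5 Hz
        rs = make_rs(np.concatenate([np.full(500, 59.0), ramp,
                                     np.full(500, 20.0)]))
        trans = tpm.detect_transitions(rs, tpm.detect_states(rs))
        assert len(trans) == 1
        assert trans[0].transition_class == "gradual"

    def test_transition_count_conservation(self):
        """Transitions chain: signed index jumps telescope to the net
        state-index displacement, and the forward/reverse balance has the
        same sign as that displacement."""
        ladders = [
            [59, 35, 20], [59, 20, 59], [20, 59, 35, 20], [59, 35, 59, 20],
        ]
        for seed, sigmas in enumerate(ladders):
            trace, _ = simulate_tpm_trace(TPMSimSpec(
                [TPMState(s, s, 150.0) for s in sigmas], seed=seed))
            rs = tpm.rolling_sigma(trace)
            model = tpm.detect_states(rs)
            trans = tpm.detect_transitions(rs, model)
            locs = model.peak_locations

            def idx(value):
                return int(np.argmin(np.abs(locs - value)))

            jumps = sum(idx(t.start_peak_nm) - idx(t.end_peak_nm)
                        for t in trans)
            start = int(np.argmin(np.abs(locs - sigmas[0])))
            end = int(np.argmin(np.abs(locs - sigmas[-1])))
            assert jumps == start - end
            fwd = sum(1 for t in trans if t.direction == "forward")
            rev = len(trans) - fwd
            if start != end:
                assert np.sign(fwd - rev) == np.sign(start - end)


class TestPoolPeaks:
    def test_identical_peaks_stack_in_one_bin(self, rng):
        models = [tpm.detect_states(make_rs(rng.normal(59, 2, 1000)))
                  for _ in range(10)]
        pooled = tpm.pool_peaks(models)
        occupied = pooled[pooled["count"] > 0]
        assert len(occupied) == 1 and occupied["count"].iloc[0] == 10

    def test_detection_limit_flags(self, rng):
        models = [tpm.detect_states(make_rs(np.abs(rng.normal(m, 0.5, 1000))))
                  for m in (5.0, 7.5)]
        pooled = tpm.pool_peaks(models)
        low = pooled[(pooled.bin_left == 3.0)].iloc[0]
        high = pooled[(pooled.bin_left == 6.0)].iloc[0]
        assert low["below_detection_limit"] and not high["below_detection_limit"]

    def test_empty_model_list(self):
        assert tpm.pool_peaks([]).empty

    def test_detection_limit_value(self):
        assert tpm.detection_limit(3.0) == 6.0
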