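"""Generators: step discipline, analytic decay laws, rasterization round trips."""
import numpy as np
import pytest

from loopfold import afm, geometry, polymer, synthgen, tpm
from loopfold.synthgen import (AFMImageSpec, ContourSpec, PlacedMolecule,
                               TPMSimSpec, TPMState, rasterize_afm_image,
                               simulate_contour, simulate_tpm_trace,
                               simulate_wlc_contour)

from conftest import render_molecule

KIND_PARAMS = [
    ("wlc", dict(persistence_nm=60.0)),
    ("arc_c", dict(radius_nm=18.0)),
    ("arc_s", dict(radius_nm=13.0)),
    ("loop", dict(radius_nm=10.0)),
    ("pseudo_loop", dict(radius_nm=5.5)),
]


# ---------------------------------------------------------------------------
# TPM traces
# ---------------------------------------------------------------------------

class TestTPMTraces:
    def test_single_state_sample_std(self):
        """Seed-averaged sample std of a sigma=59 state is 59 +/- 3 nm."""
        stds = []
        for seed in range(5):
            trace, _ = simulate_tpm_trace(
                TPMSimSpec([TPMState(59, 59, 400.0)], seed=seed))
            stds.append(np.std(trace.x_nm, ddof=1))
        assert abs(np.mean(stds) - 59) < 3

    def test_drift_adds_to_line_fit_slope(self):
        base, _ = simulate_tpm_trace(TPMSimSpec([TPMState(59, 59, 400.0)],
                                                seed=5))
        drifted, _ = simulate_tpm_trace(TPMSimSpec(
            [TPMState(59, 59, 400.0)], drift_nm_per_s=(0.5, 0.0), seed=5))
        slope = np.polyfit(base.time_s, drifted.x_nm - base.x_nm, 1)[0]
        assert slope == pytest.approx(0.5, abs=1e-9)

    def test_two_state_track_has_one_transition_frame(self):
        _, track = simulate_tpm_trace(TPMSimSpec(
            [TPMState(59, 59, 200.0), TPMState(20, 20, 200.0)], seed=0))
        assert np.count_nonzero(np.diff(track)) == 1

    def test_subframe_dwell_rejected(self):
        with pytest.raises(ValueError, match="dwell"):
            TPMSimSpec([TPMState(59, 59, 0.1)])

    def test_ramp_interpolates_sigma(self):
        trace, track = simulate_tpm_trace(TPMSimSpec(
            [TPMState(50, 50, 100.0), TPMState(10, 10, 100.0)],
            ramp_s=20.0, seed=1))
        # during the ramp the realized |x| envelope shrinks gradually: the
        # windowed std midway through the ramp sits between the two states
        b = 500  # transition frame
        mid = np.std(trace.x_nm[b + 30:b + 70], ddof=1)
        assert 15 < mid < 45

    def test_ou_mode_preserves_stationary_sigma(self):
        trace, _ = simulate_tpm_trace(TPMSimSpec(
            [TPMState(59, 59, 2000.0)], ou_tau_s=2.0, seed=3))
        assert np.std(trace.x_nm, ddof=1) == pytest.approx(59, rel=0.1)

    def test_determinism(self):
        a, ta = simulate_tpm_trace(TPMSimSpec([TPMState(59, 59, 200.0)], seed=9))
        b, tb = simulate_tpm_trace(TPMSimSpec([TPMState(59, 59, 200.0)], seed=9))
        assert np.array_equal(a.x_nm, b.x_nm) and np.array_equal(ta, tb)


# ---------------------------------------------------------------------------
# contours
# ---------------------------------------------------------------------------

class TestContours:
    @pytest.mark.parametrize("kind,kw", KIND_PARAMS)
    def test_equal_segments_and_total_length(self, kind, kw):
        spec = ContourSpec(kind, 105.0, step_nm=4.0, seed=1, **kw)
        poly = simulate_contour(spec)
        seg = geometry.segment_lengths(poly)
        assert np.allclose(seg, spec.effective_step_nm, atol=1e-9)
        assert geometry.polyline_length(poly) == pytest.approx(105.0, abs=1e-6)

    def test_stiff_limit_is_straight(self):
        poly = simulate_wlc_contour(ContourSpec("wlc", 105.0,
                                                persistence_nm=1e9, seed=0))
        end_to_end = np.hypot(*(poly[-1] - poly[0]))
        assert end_to_end == pytest.approx(105.0, abs=1e-5)

    def test_wlc_tangent_decay_matches_2d_law(self, rng):
        """Pooled <cos theta> follows exp(-l/(2 Lp)): 0.819 at l=24, and the
        fitted decay extrapolates to e^-1 = 0.368 at l = 2 Lp = 120 nm."""
        chains = [simulate_wlc_contour(
            ContourSpec("wlc", 105.0, persistence_nm=60.0, step_nm=4.0), rng)
            for _ in range(2000)]
        tc = polymer.tangent_correlation(chains)
        at24 = tc.mean_cos[np.argmin(np.abs(tc.ell_nm - 24.0))]
        assert at24 == pytest.approx(np.exp(-0.2), abs=0.01)
        fit = polymer.fit_wlc_correlation(tc, s=2)
        assert np.exp(-120.0 / (2 * fit.persistence_nm)) == \
            pytest.approx(np.exp(-1.0), abs=0.02)

    def test_wlc_msd_matches_flexible_polymer_model(self, rng):
        chains = [simulate_wlc_contour(
            ContourSpec("wlc", 105.0, persistence_nm=60.0, step_nm=4.0), rng)
            for _ in range(2000)]
        msd = polymer.msd_profile(chains)
        model = polymer.wlc_msd_model(msd.ell_nm, 60.0, s=2)
        sel = msd.ell_nm <= 80  # beyond that few pairs remain
        assert np.allclose(msd.msd_nm2[sel], model[sel], rtol=0.05)

    def test_arc_chord_formula(self):
        length = np.pi * 18.0 / 2
        poly = simulate_contour(ContourSpec("arc_c", length, radius_nm=18.0,
                                            step_nm=1.0))
        chord = np.hypot(*(poly[-1] - poly[0]))
        assert chord == pytest.approx(2 * 18 * np.sin(np.pi / 4), abs=0.1)

    def test_s_shape_curvature_integrates_to_zero(self):
        poly = simulate_contour(ContourSpec("arc_s", 105.0, radius_nm=18.0,
                                            step_nm=2.0))
        kappa = geometry.signed_curvature(poly)
        assert abs(kappa.sum()) < 1e-9

    def test_pseudo_loop_crosses_itself(self):
        poly = simulate_contour(ContourSpec("pseudo_loop", 105.0,
                                            radius_nm=5.5, step_nm=2.0))
        assert geometry.self_intersects(poly)

    def test_loop_too_short_rejected(self):
        with pytest.raises(ValueError, match="loop"):
            ContourSpec("loop", 50.0, radius_nm=10.0)

    def test_loop_rasterized_diameter_round_trip(self):
        """The d-formula recovers the centerline diameter 2R of a loop."""
        rec = render_molecule("loop", radius_nm=10.0)
        d = afm.measure_loop_diameter(rec)
        assert d == pytest.approx(20.0, abs=synthgen.DEFAULT_PIXEL_NM)

    @pytest.mark.parametrize("lp", [10.0, 30.0, 60.0])
    def test_persistence_length_recovery(self, lp):
        """Pooled correlation of >=2000 chains recovers Lp within 5%."""
        rng = np.random.default_rng(17)
        chains = [simulate_wlc_contour(
            ContourSpec("wlc", 105.0, persistence_nm=lp, step_nm=4.0), rng)
            for _ in range(2000)]
        fit = polymer.fit_wlc_correlation(polymer.tangent_correlation(chains))
        assert fit.persistence_nm == pytest.approx(lp, rel=0.05)

    def test_step_size_invariance(self):
        """Halving the step changes the recovered Lp by < 3%.

        The two ensembles are driven by the same Gaussian increments (a
        coarse-step turn is the sum of two fine-step turns), so the
        comparison isolates the systematic step effect from Monte Carlo
        noise.
        """
        rng = np.random.default_rng(4)
        lp, length = 60.0, 104.0
        h2 = 2.0
        fine, coarse = [], []
        for _ in range(1000):
            z = rng.normal(0.0, np.sqrt(h2 / lp), 51)
            psi_fine = np.concatenate([[0.0], np.cumsum(z)])
            fine.append(np.vstack([[0, 0], np.cumsum(
                h2 * np.column_stack([np.cos(psi_fine), np.sin(psi_fine)]),
                axis=0)]))
            z4 = z[:50].reshape(-1, 2).sum(axis=1)  # variance h4/Lp exactly
            psi_c = np.concatenate([[0.0], np.cumsum(z4)])
            coarse.append(np.vstack([[0, 0], np.cumsum(
                4.0 * np.column_stack([np.cos(psi_c), np.sin(psi_c)]),
                axis=0)]))
        lp_fine = polymer.fit_wlc_correlation(
            polymer.tangent_correlation(fine)).persistence_nm
        lp_coarse = polymer.fit_wlc_correlation(
            polymer.tangent_correlation(coarse)).persistence_nm
        assert abs(lp_fine - lp_coarse) / lp < 0.03


# ---------------------------------------------------------------------------
# rasterization
# ---------------------------------------------------------------------------

class TestRasterization:
    def test_empty_spec_gives_zero_image(self):
        img, truth = rasterize_afm_image(AFMImageSpec())
        assert not truth and not img.heights.any()

    def test_straight_contour_round_trip_length(self):
        rec = render_molecule("arc_c", 105.0, radius_nm=1e9)
        assert rec.contour_length_nm == pytest.approx(
            105.0, abs=2 * synthgen.DEFAULT_PIXEL_NM)

    def test_mask_width_matches_nominal(self):
        """At the half-height threshold the mask is ~ridge_width wide."""
        spec = AFMImageSpec(molecules=[PlacedMolecule(
            ContourSpec("arc_c", 105.0, radius_nm=1e9, step_nm=2.0),
            (500.0, 500.0), 0.0)])
        img, _ = rasterize_afm_image(spec)
        mask = img.heights > 0.25
        widths = mask.sum(axis=0)
        widths = widths[widths > 0]
        assert 2.0 <= widths.mean() <= 3.0

    def test_row_offsets_are_removed_by_leveling(self, rng):
        coeffs = rng.normal(0, 1.0, (256, 6))
        spec = AFMImageSpec(molecules=[PlacedMolecule(
            ContourSpec("arc_c", 105.0, radius_nm=1e9, step_nm=2.0),
            (500.0, 500.0), 0.7)], row_offsets=coeffs,
            noise_sigma_nm=0.05, seed=2)
        img, _ = rasterize_afm_image(spec)
        leveled = afm.level_rows(img)
        background = np.abs(np.median(leveled.heights, axis=1))
        assert np.median(background) < 0.05

    def test_overlapping_molecules_flagged(self):
        near = [PlacedMolecule(ContourSpec("arc_c", 105.0, radius_nm=1e9,
                                           step_nm=2.0), (500.0, 500.0), 0.0),
                PlacedMolecule(ContourSpec("arc_c", 105.0, radius_nm=1e9,
                                           step_nm=2.0), (505.0, 503.0), 0.1)]
        _, truth = rasterize_afm_image(AFMImageSpec(molecules=near))
        assert truth[0]["overlaps"] and truth[1]["overlaps"]

    def test_out_of_field_placement_rejected(self):
        spec = AFMImageSpec(molecules=[PlacedMolecule(
            ContourSpec("arc_c", 105.0, radius_nm=1e9, step_nm=2.0),
            (990.0, 500.0), 0.0)])
        with pytest.raises(ValueError, match="field of view"):
            rasterize_afm_image(spec)

    def test_determinism(self):
        spec = AFMImageSpec(molecules=[PlacedMolecule(
            ContourSpec("wlc", 105.0, persistence_nm=60.0, seed=3),
            (500.0, 500.0), 1.0)], noise_sigma_nm=0.05, seed=11)
        a, _ = rasterize_afm_image(spec)
        b, _ = rasterize_afm_image(spec)
        assert np.array_equal(a.heights, b.heights)
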