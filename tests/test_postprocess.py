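"""The five-step cleanup chain: toy fixtures, round trips, recoveries."""

import numpy as np
import pandas as pd
import pytest

from smlmpipe import io, postprocess as pp, synthetic as syn
from smlmpipe.geometry import Region
from smlmpipe.transforms import ChannelWarp, PolynomialTransform


@pytest.fixture
def params():
    return pp.FilterParams()


class TestRemoveDuplicates:
    def test_same_frame_pair_keeps_most_precise(self, params):
        # 5 nm apart, uncertainties 10 and 15 -> pair radius max(10,15)=15,
        # 5 < 15 so they group; the 10 nm member survives
        t = io.make_table(x=[0.0, 5.0], y=[0.0, 0.0], frame=0, uncertainty=[10.0, 15.0])
        out = pp.remove_duplicates(t, params)
        assert len(out) == 1
        assert out["uncertainty"].iloc[0] == 10.0

    def test_different_frames_untouched(self, params):
        t = io.make_table(x=[0.0, 0.0], y=[0.0, 0.0], frame=[0, 1], uncertainty=10.0)
        out = pp.remove_duplicates(t, params)
        assert len(out) == 2

    def test_transitive_grouping(self, params):
        # chain 0-8-16 nm with uncertainty 10: pairs (0,8) and (8,16) are
        # close, (0,16) is not; transitivity collapses all three
        t = io.make_table(
            x=[0.0, 8.0, 16.0], y=[0.0, 0.0, 0.0], frame=0, uncertainty=[10.0, 9.0, 10.0]
        )
        out = pp.remove_duplicates(t, params)
        assert len(out) == 1
        assert out["uncertainty"].iloc[0] == 9.0

    def test_empty_table(self, params):
        assert len(pp.remove_duplicates(io.empty_table(), params)) == 0


class TestFilterUncertainty:
    def test_strict_threshold_keeps_boundary(self, params):
        t = io.make_table(x=[0.0, 1.0, 2.0], y=0.0, uncertainty=[15.0, 20.0, 25.0])
        out = pp.filter_uncertainty(t, params)
        assert sorted(out["uncertainty"]) == [15.0, 20.0]

    def test_all_below_unchanged(self, params):
        t = io.make_table(x=[0.0, 1.0], y=0.0, uncertainty=5.0)
        assert len(pp.filter_uncertainty(t, params)) == 2

    def test_all_above_empties(self, params):
        t = io.make_table(x=[0.0, 1.0], y=0.0, uncertainty=25.0)
        assert len(pp.filter_uncertainty(t, params)) == 0


class TestDensityFilter:
    def test_mutual_triangle_kept(self, params):
        # equilateral 30 nm triangle: each point has exactly 2 neighbors
        t = io.make_table(x=[0.0, 30.0, 15.0], y=[0.0, 0.0, 25.98], uncertainty=5.0)
        assert len(pp.density_filter(t, params)) == 3

    def test_isolated_point_removed(self, params):
        t = io.make_table(
            x=[0.0, 30.0, 15.0, 500.0], y=[0.0, 0.0, 25.98, 500.0], uncertainty=5.0
        )
        out = pp.density_filter(t, params)
        assert len(out) == 3
        assert 500.0 not in out["x"].values

    def test_lone_pair_removed(self, params):
        # each member of a 30 nm pair has only 1 neighbor < min 2
        t = io.make_table(x=[0.0, 30.0], y=0.0, uncertainty=5.0)
        assert len(pp.density_filter(t, params)) == 0

    def test_single_pass_no_cascade(self, params):
        # colinear chain spaced 40 nm: ends have 1 neighbor within 50 nm,
        # interior points 2.  A cascading filter would also strip the new
        # ends after removing the old ones; the single pass must not.
        x = np.arange(6) * 40.0
        t = io.make_table(x=x, y=0.0, uncertainty=5.0)
        out = pp.density_filter(t, params)
        assert sorted(out["x"]) == [40.0, 80.0, 120.0, 160.0]


class TestMergeBlinks:
    def test_consecutive_blinks_merge_to_one(self, params):
        t = io.make_table(
            x=[0.0, 5.0, 8.0], y=0.0, frame=[3, 4, 5], uncertainty=10.0
        )
        out = pp.merge_blinks(t, params)
        assert len(out) == 1
        assert out["frame"].iloc[0] == 3

    def test_distant_molecules_stay_separate(self, params):
        t = io.make_table(
            x=[0.0, 100.0, 0.0, 100.0], y=0.0, frame=[0, 0, 1, 1], uncertainty=10.0
        )
        assert len(pp.merge_blinks(t, params)) == 2

    def test_equal_weight_pair_averages_symmetrically(self, params):
        t = io.make_table(x=[0.0, 10.0], y=0.0, frame=[0, 1], uncertainty=10.0)
        out = pp.merge_blinks(t, params)
        assert len(out) == 1
        assert out["x"].iloc[0] == pytest.approx(5.0)
        assert out["uncertainty"].iloc[0] == pytest.approx(10.0 / np.sqrt(2))

    def test_frame_gap_breaks_chain_by_default(self, params):
        t = io.make_table(x=[0.0, 2.0], y=0.0, frame=[0, 2], uncertainty=10.0)
        assert len(pp.merge_blinks(t, params)) == 2
        relaxed = pp.FilterParams(merge_max_gap_frames=1)
        assert len(pp.merge_blinks(t, relaxed)) == 1

    def test_precision_budget_conserved(self, params, rng):
        # merging preserves the total 1/sigma^2 within each chain
        t = io.make_table(
            x=rng.normal(0, 3, 5),
            y=rng.normal(0, 3, 5),
            frame=np.arange(5),
            uncertainty=rng.uniform(5, 15, 5),
        )
        out = pp.merge_blinks(t, params)
        assert len(out) == 1
        assert (1.0 / out["uncertainty"] ** 2).sum() == pytest.approx(
            (1.0 / t["uncertainty"] ** 2).sum()
        )


class TestDrift:
    def test_static_fiducials_give_zero_path(self, roi):
        t = syn.add_fiducials(
            io.empty_table(), roi, 2, 0.0, 1, n_frames=100, channels=("647",)
        )
        est = pp.estimate_drift(t)
        np.testing.assert_allclose(est.offsets, 0.0, atol=1e-9)

    def test_linear_drift_recovered_below_one_nanometre(self, roi):
        rmss = []
        for s in range(5):
            t = syn.add_fiducials(
                io.empty_table(), roi, 2, 2.0, s, n_frames=500, channels=("647",)
            )
            drift = syn.DriftPath.linear(500, 0.5, 0.2)
            est = pp.estimate_drift(syn.apply_drift(t, drift), smoothing_window=10)
            err = est.offsets - drift.offsets
            rmss.append(np.sqrt(np.mean(np.sum(err**2, axis=1))))
        assert np.mean(rmss) < 1.0

    def test_two_beads_beat_one_bead(self, roi):
        def rms_for(n_beads, s):
            t = syn.add_fiducials(
                io.empty_table(), roi, n_beads, 3.0, s, n_frames=300, channels=("647",)
            )
            drift = syn.DriftPath.linear(300, 0.4, -0.1)
            est = pp.estimate_drift(syn.apply_drift(t, drift))
            err = est.offsets - drift.offsets
            return np.mean(np.sum(err**2, axis=1))

        one = np.mean([rms_for(1, s) for s in range(8)])
        two = np.mean([rms_for(2, s) for s in range(8)])
        assert two < one

    def test_correction_round_trip(self, roi):
        mol = syn.generate_csr(roi, 100, 2)
        loc = syn.simulate_localizations(mol, syn.BlinkModel(3, 5, 0, 300), 3)
        full = syn.add_fiducials(loc, roi, 3, 2.0, 1, channels=("647",))
        drift = syn.DriftPath.random_walk(300, 0.4, 9)
        drifted = syn.apply_drift(full, drift)
        corrected = pp.apply_drift_correction(drifted, pp.estimate_drift(drifted))
        err = corrected[["x", "y"]].to_numpy() - full[["x", "y"]].to_numpy()
        assert np.sqrt(np.mean(np.sum(err**2, axis=1))) < 2.5

    def test_exact_round_trip_with_known_path(self, roi):
        t = io.make_table(x=[10.0, 20.0], y=[5.0, 5.0], frame=[0, 50], uncertainty=7.0)
        d = syn.DriftPath.linear(100, 0.3, -0.2)
        back = pp.apply_drift_correction(syn.apply_drift(t, d), d)
        np.testing.assert_allclose(back[["x", "y"]], t[["x", "y"]], atol=1e-9)
        assert (back["uncertainty"] == t["uncertainty"]).all()
        assert (back["frame"] == t["frame"]).all()

    def test_no_fiducials_is_an_error(self):
        t = io.make_table(x=[0.0], y=[0.0])
        with pytest.raises(ValueError, match="fiducial"):
            pp.estimate_drift(t)


class TestRegistration:
    @staticmethod
    def _bead_tables(warp, seed, n_beads=12, n_frames=500, loc_sigma=2.0):
        region = Region(0, 0, 20000, 20000)
        fixed = syn.add_fiducials(
            io.empty_table(), region, n_beads, loc_sigma, seed,
            n_frames=n_frames, channels=("647",),
        )
        moving = fixed.copy()
        moving["channel"] = "488"
        moving = syn.apply_channel_warp(moving, warp, "488")
        return moving, fixed

    def test_identity_for_identical_beads(self):
        moving, fixed = self._bead_tables(ChannelWarp.identity(), 1, loc_sigma=0.0)
        t = pp.fit_registration(moving, fixed, degree=1)
        np.testing.assert_allclose(t.coef_x, [0.0, 1.0, 0.0], atol=1e-9)
        np.testing.assert_allclose(t.coef_y, [0.0, 0.0, 1.0], atol=1e-9)
        assert t.rms_residual < 1e-9

    def test_translation_recovered(self):
        moving, fixed = self._bead_tables(ChannelWarp.translation(30.0, -10.0), 2)
        t = pp.fit_registration(moving, fixed, degree=1)
        assert t.coef_x[0] == pytest.approx(-30.0, abs=0.5)
        assert t.coef_y[0] == pytest.approx(10.0, abs=0.5)

    def test_degree2_coefficients_recovered_within_one_percent(self):
        warp = PolynomialTransform.identity(2)
        warp.coef_x[:] = [30.0, 1.002, 2e-3, 3e-7, -2e-7, 1e-7]
        warp.coef_y[:] = [-10.0, -2e-3, 0.998, -1e-7, 2e-7, -3e-7]
        moving, fixed = self._bead_tables(warp, 3)
        t = pp.fit_registration(moving, fixed, degree=2)
        # the fitted registration approximates the warp's inverse; compare
        # by round trip through the true warp instead of coefficients
        grid = Region(0, 0, 20000, 20000).sample_uniform(
            200, np.random.default_rng(0)
        )
        restored = t.apply(warp.apply(grid))
        np.testing.assert_allclose(restored, grid, atol=1.0)
        # and the forward map refit on true positions matches within 1%
        centroids = pp.fiducial_centroids(fixed)
        forward = PolynomialTransform.fit(centroids, warp.apply(centroids), degree=2)
        np.testing.assert_allclose(forward.coef_x, warp.coef_x, rtol=0.01, atol=5e-8)
        np.testing.assert_allclose(forward.coef_y, warp.coef_y, rtol=0.01, atol=5e-8)

    def test_warp_then_registration_round_trip(self, roi):
        warp = PolynomialTransform.identity(2)
        warp.coef_x[:] = [30.0, 1.001, 1e-3, 2e-7, -1e-7, 1e-7]
        warp.coef_y[:] = [-10.0, -1e-3, 0.999, -1e-7, 1e-7, -2e-7]
        moving, fixed = self._bead_tables(warp, 4)
        t = pp.fit_registration(moving, fixed, degree=2)
        restored = pp.apply_registration(moving, t, "488")
        err = restored[["x", "y"]].to_numpy() - fixed[["x", "y"]].to_numpy()
        resid = np.sqrt(np.mean(np.sum(err**2, axis=1)))
        # per-blink noise (sigma=2 per axis in both channels) dominates
        assert resid < np.sqrt(2 * 2 * 2.0**2) + 2 * t.rms_residual

    def test_identity_registration_is_identity(self):
        t = io.make_table(x=[1.0, 2.0], y=[3.0, 4.0], channel="488")
        out = pp.apply_registration(t, PolynomialTransform.identity(), "488")
        pd.testing.assert_frame_equal(out, t)

    def test_too_few_beads_error_states_count(self):
        pts = np.array([[0.0, 0.0], [100.0, 0.0], [0.0, 100.0]])
        with pytest.raises(ValueError, match="6"):
            PolynomialTransform.fit(pts, pts, degree=2)


class TestRunPostprocess:
    def test_clean_table_passes_steps_1_to_3_unchanged(self, roi, params):
        # one blink per molecule in its own frame (no duplicates), all
        # uncertainties below 20 nm, and every point in a tight triplet so
        # the density filter is satisfied everywhere
        centers = np.stack(
            np.meshgrid(np.arange(5) * 500.0 + 250, np.arange(5) * 500.0 + 250), -1
        ).reshape(-1, 2)
        offsets = np.array([[0.0, 0.0], [30.0, 0.0], [15.0, 26.0]])
        pts = (centers[:, None, :] + offsets[None, :, :]).reshape(-1, 2)
        t = io.make_table(
            x=pts[:, 0], y=pts[:, 1], frame=np.arange(len(pts)), uncertainty=5.0
        )
        step123 = pp.density_filter(
            pp.filter_uncertainty(pp.remove_duplicates(t, params), params), params
        )
        assert len(step123) == len(t)

    def test_molecule_count_recovery_within_5_percent(self, params):
        # sparse field so chains never collide: 600 molecules in 8x8 um
        region = Region(0, 0, 8000, 8000)
        field = syn.generate_csr(region, 600, 3)
        t = syn.simulate_localizations(field, syn.BlinkModel(3.0, 5.0, 0.0, 400), 4)
        # the density filter would strip sparse singles; bypass it here so
        # the audit isolates duplicate removal + merging against ground truth
        step = pp.remove_duplicates(t, params)
        step = pp.filter_uncertainty(step, params)
        merged = pp.merge_blinks(step, params)
        assert abs(len(merged) - field.n) / field.n < 0.05

    def test_printed_step_order_is_used(self, params):
        # two molecules, each blinking in frames 0 and 1 with the second
        # blink at 25 nm uncertainty.  The printed order filters those away
        # (step 2) before merging (step 5), so each survivor keeps its
        # frame-0 position exactly; merging first would move the outputs to
        # uncertainty-weighted means.
        t = io.make_table(
            x=[0.0, 10.0, 1000.0, 1010.0],
            y=0.0,
            frame=[0, 1, 0, 1],
            uncertainty=[10.0, 25.0, 10.0, 25.0],
        )
        loose = pp.FilterParams(density_min_neighbors=1, density_radius=1e6)
        out = pp.run_postprocess(t, loose)
        assert sorted(out["x"]) == [0.0, 1000.0]

    def test_pure_function_determinism(self, roi, params):
        field = syn.generate_cluster_field(roi, syn.ClusterFieldParams(5, 30, 50, 0.1), 7)
        t = syn.simulate_localizations(field, syn.BlinkModel(3, 8, 3, 200), 8)
        t = syn.add_fiducials(t, roi, 2, 2.0, 9)
        a = pp.run_postprocess(t, params)
        b = pp.run_postprocess(t, params)
        pd.testing.assert_frame_equal(a, b)

    def test_filters_are_contractive(self, roi, params):
        field = syn.generate_cluster_field(roi, syn.ClusterFieldParams(5, 30, 50, 0.2), 1)
        t = syn.simulate_localizations(field, syn.BlinkModel(2, 12, 6, 100), 2)
        f1 = pp.filter_uncertainty(t, params)
        f2 = pp.density_filter(f1, params)
        assert len(f1) <= len(t)
        assert len(f2) <= len(f1)
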