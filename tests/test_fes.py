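"""Histogram reweighting, FES projection, state finding and convergence."""

import numpy as np
import pytest

import unbindkin as uk
from unbindkin import fes
from unbindkin.dynamics import Trajectory
from unbindkin.metad import BiasState, Hill, WellTemperedParams

KBT = 0.59616


def flat_trajectory(x, dt=1.0):
    x = np.asarray(x, dtype=float)
    return Trajectory(times=dt * np.arange(1, x.size + 1), coords=x)


class TestReweight:
    def test_unbiased_gives_equal_weights(self):
        tr = flat_trajectory(np.linspace(3, 20, 200))
        s = fes.reweight(tr, BiasState(params=WellTemperedParams()), kbt=KBT)
        assert np.allclose(s.weights, 1.0)

    def test_static_bias_weights_proportional_to_boltzmann_factor(self):
        """All hills deposited before the first frame: w ∝ exp(V(s)/kBT)."""
        bias = BiasState(params=WellTemperedParams())
        bias.append(Hill(time=0.5, center=(10.0,), width=(1.0,), height=1.2))
        x = np.linspace(5, 15, 100)
        tr = flat_trajectory(x)
        s = fes.reweight(tr, bias, kbt=KBT)
        v = 1.2 * np.exp(-0.5 * ((x - 10.0) / 1.0) ** 2)
        expect = np.exp(v / KBT)
        expect *= s.weights.mean() / expect.mean()
        assert np.allclose(s.weights, expect, rtol=1e-3)

    def test_unbiased_fes_equals_plain_histogram(self):
        rng = np.random.default_rng(0)
        x = rng.normal(10.0, 1.0, 4000)
        tr = flat_trajectory(x)
        s = fes.reweight(tr, BiasState(params=WellTemperedParams()), kbt=KBT)
        f = fes.project_fes(s, bin_width=0.2)
        hist, edges = np.histogram(x, bins=np.arange(x.min() - 1e-9,
                                                     x.max() + 0.2, 0.2))
        m = hist > 0
        F = -KBT * np.log(hist[m].astype(float))
        F -= F.min()
        assert np.allclose(f.F[np.isfinite(f.F)], F, atol=1e-9)

    def test_well_tempered_run_recovers_potential(self, doublewell,
                                                  dw_wt_fes):
        """Reweighted FES matches the known double-well within 0.3 kcal/mol
        RMSE over the visited region."""
        _, _, _, surface = dw_wt_fes
        m = (np.isfinite(surface.F) & (surface.centers > 3)
             & (surface.centers < 20))
        U = doublewell.potential(surface.centers[m])
        U -= U.min()
        F = surface.F[m] - surface.F[m].min()
        assert np.sqrt(np.mean((F - U) ** 2)) < 0.3


class TestProjection:
    def test_uniform_weights_uniform_samples_flat(self):
        rng = np.random.default_rng(1)
        s = fes.WeightedSamples(values=rng.uniform(0, 10, 100_000),
                                weights=np.ones(100_000), kbt=KBT)
        f = fes.project_fes(s, bin_width=0.5)
        assert np.nanmax(f.F[np.isfinite(f.F)]) < 0.1

    def test_harmonic_curvature_recovered(self):
        """Boltzmann samples of a quadratic potential: F = 0.5 k x²."""
        k = 2.0
        rng = np.random.default_rng(2)
        x = rng.normal(0.0, np.sqrt(KBT / k), 200_000)
        s = fes.WeightedSamples(values=x, weights=np.ones(x.size), kbt=KBT)
        f = fes.project_fes(s, bin_width=0.05, range_=(-1.0, 1.0))
        m = np.isfinite(f.F) & (np.abs(f.centers) < 0.5)
        coef = np.polyfit(f.centers[m], f.F[m], 2)
        assert coef[0] == pytest.approx(0.5 * k, rel=0.05)

    def test_min_shift_exact_zero(self):
        s = fes.WeightedSamples(values=np.array([1.0, 2.0, 2.1]),
                                weights=np.ones(3), kbt=KBT)
        f = fes.project_fes(s, bin_width=0.5)
        assert np.min(f.F[np.isfinite(f.F)]) == 0.0

    def test_mismatched_series_rejected(self):
        s = fes.WeightedSamples(values=np.ones(5), weights=np.ones(5),
                                kbt=KBT)
        with pytest.raises(ValueError):
            fes.project_fes(s, cv_series=np.ones(4))


class TestStates:
    def exact_surface(self, landscape):
        x = np.arange(3.0, 22.0, 0.05)
        F = landscape.potential(x)
        F -= F.min()
        return fes.FreeEnergySurface(centers=x, F=F, bin_width=0.05, kbt=KBT)

    def test_one_barrier_preset(self, presets):
        st = fes.find_states_and_barriers(self.exact_surface(
            presets["dhaa31like"]))
        assert len(st.barriers) == 1
        x0, ts, x1, h = st.barriers[0]
        assert h == pytest.approx(4.81, abs=0.05)
        assert x0 == pytest.approx(5.94, abs=0.1)
        assert x1 == pytest.approx(12.14, abs=0.1)
        assert st.maxima[0][0] == "TS1"

    def test_two_barrier_preset(self, presets):
        st = fes.find_states_and_barriers(self.exact_surface(
            presets["dhaawtlike"]))
        heights = [b[3] for b in st.barriers]
        assert heights == pytest.approx([2.26, 1.46], abs=0.05)
        assert [m[0] for m in st.maxima] == ["TS1", "TS2"]

    def test_monotone_surface_has_no_ts(self):
        x = np.linspace(0, 10, 100)
        f = fes.FreeEnergySurface(centers=x, F=0.5 * x, bin_width=0.1,
                                  kbt=KBT)
        st = fes.find_states_and_barriers(f)
        assert st.barriers == [] and st.maxima == []

    def test_global_min_label_is_lowest(self, presets):
        st = fes.find_states_and_barriers(self.exact_surface(
            presets["dhaawtlike"]))
        vals = {lab: f for lab, _, f in st.minima}
        assert vals["global_min"] == min(vals.values())


class TestConvergence:
    def test_final_dg_matches_boltzmann_integration(self, doublewell,
                                                    dw_wt_fes):
        """Converged well-tempered run: basin free-energy difference within
        0.2 kcal/mol of direct Boltzmann integration of the potential."""
        traj, bias, _, _ = dw_wt_fes
        basin_a, basin_b = (6.0, 10.0), (14.0, 18.0)
        out = fes.convergence_curves(traj, bias, basin_a, basin_b,
                                     checkpoints=[traj.times[-1]], kbt=KBT)
        x = np.arange(2.5, 25, 0.001)
        U = doublewell.potential(x)
        U -= U.min()
        w = np.exp(-U / KBT)
        ma = (x >= 6.0) & (x <= 10.0)
        mb = (x >= 14.0) & (x <= 18.0)
        exact = -KBT * np.log(w[ma].sum() / w[mb].sum())
        assert out["dG"][-1] == pytest.approx(exact, abs=0.2)

    def test_antisymmetry_under_basin_swap(self, dw_wt_fes):
        traj, bias, _, _ = dw_wt_fes
        tc = [traj.times[-1]]
        ab = fes.convergence_curves(traj, bias, (6.0, 10.0), (14.0, 18.0),
                                    tc, kbt=KBT)
        ba = fes.convergence_curves(traj, bias, (14.0, 18.0), (6.0, 10.0),
                                    tc, kbt=KBT)
        assert ab["dG"][-1] == pytest.approx(-ba["dG"][-1], abs=1e-9)

    def test_unvisited_basin_gives_missing_value(self, dw_wt_fes):
        traj, bias, _, _ = dw_wt_fes
        out = fes.convergence_curves(traj, bias, (6.0, 10.0), (14.0, 18.0),
                                     checkpoints=[traj.times[0] * 1.5],
                                     kbt=KBT)
        # at the very start basin B (the far well) has not been reached
        assert np.isnan(out["dG"][0])

    def test_overlapping_basins_rejected(self, dw_wt_fes):
        traj, bias, _, _ = dw_wt_fes
        with pytest.raises(ValueError):
            fes.convergence_curves(traj, bias, (6.0, 12.0), (10.0, 18.0),
                                   [100.0], kbt=KBT)


class TestExtractFrames:
    def test_window_covering_everything(self):
        tr = flat_trajectory(np.linspace(0, 1, 50))
        idx = fes.extract_state_frames(tr, center=0.5, tolerance=10.0)
        assert idx.size == 50

    def test_center_outside_range_empty_with_warning(self):
        tr = flat_trajectory(np.linspace(0, 1, 50))
        with pytest.warns(RuntimeWarning):
            idx = fes.extract_state_frames(tr, center=99.0, tolerance=0.01)
        assert idx.size == 0

    def test_count_matches_linear_scan(self):
        rng = np.random.default_rng(3)
        x = rng.uniform(0, 20, 5000)
        tr = flat_trajectory(x)
        idx = fes.extract_state_frames(tr, center=10.0, tolerance=0.5)
        brute = sum(1 for v in x if abs(v - 10.0) <= 0.5)
        assert idx.size == brute
        assert np.all(np.abs(x[idx] - 10.0) <= 0.5)
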