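"""Preset landscape construction, Boltzmann sampling, MFPT oracles and the
synthetic residue-energy generator."""

import numpy as np
import pytest
from scipy.integrate import trapezoid

import unbindkin as uk
from unbindkin.landscapes import ConfigurationError, alternating_extrema

KBT = 0.59616


class TestPresets:
    def test_dhaa31like_single_barrier(self, presets):
        L = presets["dhaa31like"]
        barriers = L.measured_barriers()
        assert len(barriers) == 1
        x_min, x_ts, _, height = barriers[0]
        assert height == pytest.approx(4.81, abs=0.05)
        assert x_min == pytest.approx(5.94, abs=0.1)
        mins = [(p, v) for kind, p, v in L.measured_features() if kind == "min"]
        assert mins[0][1] == pytest.approx(0.0, abs=1e-6)  # global min at 0
        assert mins[1][0] == pytest.approx(12.14, abs=0.1)  # mouth minimum

    def test_dhaawtlike_two_barriers(self, presets):
        L = presets["dhaawtlike"]
        barriers = L.measured_barriers()
        assert len(barriers) == 2
        assert barriers[0][3] == pytest.approx(2.26, abs=0.05)
        assert barriers[1][3] == pytest.approx(1.46, abs=0.05)

    def test_flat_is_zero_inside_domain(self, presets):
        L = presets["flat"]
        x = np.linspace(1.0, 24.0, 100)
        assert np.allclose(L.potential(x), 0.0)

    def test_unknown_preset_rejected(self):
        with pytest.raises(ConfigurationError):
            uk.build_preset_landscape("nosuchpreset")

    def test_doublewell_barrier_is_5_kbt(self, doublewell):
        (_, _, _, height), = doublewell.measured_barriers()
        assert height == pytest.approx(5 * KBT, abs=0.05)

    def test_force_is_minus_gradient(self, presets):
        L = presets["dhaawtlike"]
        x = np.linspace(3.0, 24.0, 50)
        eps = 1e-6
        num = -(L.potential(x + eps) - L.potential(x - eps)) / (2 * eps)
        assert np.allclose(L.force(x), num, atol=1e-5)


class TestSampling:
    def test_zero_temperature_stays_at_start(self, presets):
        p = uk.LangevinParams(temperature=1e-12, seed=1)
        tr = uk.simulate_langevin(presets["flat"], p, 2000, x0=12.0)
        assert np.allclose(tr.coords, 12.0)

    def test_seed_determinism(self, doublewell):
        p = uk.LangevinParams(seed=11)
        a = uk.simulate_langevin(doublewell, p, 20_000)
        b = uk.simulate_langevin(doublewell, p, 20_000)
        assert np.array_equal(a.coords, b.coords)

    def test_boltzmann_occupancy_and_fes_recovery(self, doublewell):
        """Long unbiased run: well occupancies match the Boltzmann integral
        and -kBT ln(hist) reproduces the potential (RMSE < 0.3 kcal/mol)."""
        tr = uk.simulate_langevin(doublewell, uk.LangevinParams(seed=7),
                                  8_000_000, save_stride=20)
        x = tr.coords
        xs = np.linspace(2.5, 25.0, 4001)
        w = np.exp(-doublewell.potential(xs) / KBT)
        exact = (trapezoid(w[xs < 12], xs[xs < 12])
                 / trapezoid(w[xs >= 12], xs[xs >= 12]))
        ratio = np.mean(x < 12) / np.mean(x >= 12)
        assert ratio == pytest.approx(exact, rel=0.15)
        h, edges = np.histogram(x, bins=np.arange(2.5, 25, 0.1))
        c = 0.5 * (edges[1:] + edges[:-1])
        m = h >= 100
        F = -KBT * np.log(h[m])
        F -= F.min()
        U = doublewell.potential(c[m])
        U -= U.min()
        assert np.sqrt(np.mean((F - U) ** 2)) < 0.3

    def test_integration_error_reports_step(self, doublewell):
        with pytest.raises(ValueError):
            uk.simulate_langevin(doublewell, uk.LangevinParams(seed=1), 0)


class TestMfptOracle:
    def test_flat_matches_diffusive_scaling(self):
        """Free diffusion with reflecting wall: MFPT = (L² - l²)/2D."""
        L = uk.build_preset_landscape("flat")
        p = uk.LangevinParams()
        got = uk.mfpt_oracle_1d(L, 10.0, 20.0, friction=p.friction)
        # hard-wall closed form with reflection at the wall onset (x=0)
        exact = (20.0**2 - 10.0**2) / (2 * p.diffusion)
        assert got == pytest.approx(exact, rel=0.05)

    def test_source_equals_absorbing_is_zero(self, doublewell):
        assert uk.mfpt_oracle_1d(doublewell, 8.0, 8.0) == 0.0

    def test_absorbing_outside_domain_rejected(self, doublewell):
        with pytest.raises(ConfigurationError):
            uk.mfpt_oracle_1d(doublewell, 8.0, 40.0)

    def test_quadrature_vs_brute_force(self, doublewell):
        """Closed-form double integral vs 500 stochastic first passages."""
        mq = uk.mfpt_oracle_1d(doublewell, 8.0, 20.0)
        mb, times = uk.mfpt_brute_force(doublewell, 8.0, 20.0, n_runs=500,
                                        seed=4)
        assert len(times) == 500
        assert mb == pytest.approx(mq, rel=0.15)

    def test_mirrored_direction(self, doublewell):
        """Downhill-to-the-left first passage uses the mirrored solution."""
        m = uk.mfpt_oracle_1d(doublewell, 16.0, 6.0)
        mb, _ = uk.mfpt_brute_force(doublewell, 16.0, 6.0, n_runs=300, seed=5)
        assert m > 0
        assert mb == pytest.approx(m, rel=0.2)


class TestResidueTables:
    LABELS = ["F152", "F168", "F149", "F245", "F144"]

    def test_zero_noise_reproduces_spec_exactly(self):
        spec = [("F152", -3.0), ("F149", -2.0)]
        mins, ts1 = uk.generate_residue_energy_tables(
            5, 10, spec, noise_sd=0.0, seed=0, labels=self.LABELS)
        diff = mins.mean() - ts1.mean()
        assert diff["F152"] == pytest.approx(-3.0)
        assert diff["F149"] == pytest.approx(-2.0)
        assert diff["F168"] == pytest.approx(0.0)

    def test_noisy_recovery_within_standard_error(self):
        mins, ts1 = uk.generate_residue_energy_tables(
            5, 100, [("F152", -2.0)], noise_sd=0.5, seed=3,
            labels=self.LABELS)
        diff = (mins.mean() - ts1.mean())["F152"]
        assert diff == pytest.approx(-2.0, abs=0.3)  # ~4 SE of the difference

    def test_empty_spec_gives_null_differences(self):
        mins, ts1 = uk.generate_residue_energy_tables(
            5, 200, [], noise_sd=0.2, seed=1, labels=self.LABELS)
        assert np.all(np.abs(mins.mean() - ts1.mean()) < 0.15)

    def test_too_few_frames_rejected(self):
        with pytest.raises(ValueError):
            uk.generate_residue_energy_tables(3, 1, [], seed=0)


def test_alternating_extrema_ignores_plateau_noise():
    x = np.linspace(0, 4 * np.pi, 500)
    u = np.cos(x) + 1e-12 * np.sin(40 * x)
    ext = alternating_extrema(u, tol=1e-3)
    kinds = [k for k, _ in ext]
    assert kinds == ["min", "max", "min", "max"] or \
        kinds == ["min", "max", "min"]
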