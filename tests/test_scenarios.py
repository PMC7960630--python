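"""Benchmark scenario construction, the attractant pulse, and config I/O."""

import numpy as np
import pytest
from scipy.integrate import quad

import kinetax as kx
from kinetax import (
    ScenarioSpec,
    Variant,
    gaussian_pulse,
    hill_threshold,
    make_agar_plate,
    make_linear_gradient,
    make_transient_source,
)


class TestGaussianPulse:
    def test_total_content_is_conserved(self):
        for T in (0.05, 0.3):
            total, _ = quad(
                lambda R: 2 * np.pi * R * gaussian_pulse(R, T, 0.5, 0.5),
                0.0, np.inf,
            )
            assert total == pytest.approx(0.5, rel=1e-6)

    def test_peak_value(self):
        assert gaussian_pulse(0.0, 0.01, 0.5, 0.5) == pytest.approx(
            0.5 / (4 * np.pi * 0.5 * 0.01)
        )

    def test_shape_is_gaussian(self):
        T, N = 0.05, 0.5
        R = 2 * np.sqrt(N * T)
        ratio = gaussian_pulse(R, T, 0.5, N) / gaussian_pulse(0.0, T, 0.5, N)
        assert ratio == pytest.approx(np.exp(-1.0), rel=1e-12)

    def test_invalid_time_rejected(self):
        with pytest.raises(ValueError):
            gaussian_pulse(1.0, 0.0, 0.5, 0.5)

    def test_rate_matches_finite_difference(self):
        h = 1e-7
        fd = (gaussian_pulse(0.7, 0.1 + h, 0.5, 0.5)
              - gaussian_pulse(0.7, 0.1 - h, 0.5, 0.5)) / (2 * h)
        assert kx.gaussian_pulse_rate(0.7, 0.1, 0.5, 0.5) == pytest.approx(
            fd, rel=1e-6
        )


class TestLinearGradient:
    def test_benchmark_parameters_stored_verbatim(self):
        p = make_linear_gradient().params
        assert (p.H, p.N, p.K_chi, p.delta0, p.eta, p.omega, p.n_hill) == (
            0.0, 0.0, 0.53, 50.0, 2.0, 0.2, 5.0
        )
        assert p.growth_on is False

    def test_dominance_threshold_of_default_set(self):
        assert hill_threshold(make_linear_gradient().params) == pytest.approx(
            39.78, abs=0.01
        )

    def test_critical_concentration_lies_inside_domain(self):
        spec = make_linear_gradient()
        state = spec.build_initial_state()
        # the cell where C crosses omega exists strictly inside the domain
        idx = int(np.argmin(np.abs(state.C - spec.params.omega)))
        assert 0 < idx < spec.grid.n_cells - 1
        assert state.C[idx] == pytest.approx(spec.params.omega, abs=spec.grid.dx)

    def test_variants_cover_controls_and_hill_sweep(self):
        spec = make_linear_gradient()
        by_label = {v.label: v for v in spec.variants}
        assert by_label["pure_chemotaxis"].overrides == {"eta": 0.0}
        sweep = {by_label[f"n_{n}"].overrides.get("n_hill") for n in (1, 5, 10, 40)}
        assert sweep == {1.0, 5.0, 10.0, 40.0}

    def test_initial_population_mean_density(self):
        spec = make_linear_gradient()
        state = spec.build_initial_state()
        w = spec.grid.cell_volumes
        assert np.sum(state.B * w) / np.sum(w) == pytest.approx(0.2)

    def test_pure_chemotaxis_variant_reaches_exponential_steady_state(self):
        spec = make_linear_gradient(n_cells=200)
        spec.t_snapshots = [17.0]
        traj = kx.run_variant(spec, "pure_chemotaxis")
        p = spec.variant_params("pure_chemotaxis")
        state = traj.final
        ana = kx.steady_state_ratio(state.C, 0, p)
        w = spec.grid.cell_volumes
        num = state.B / np.sum(state.B * w)
        ref = ana / np.sum(ana * w)
        assert np.sum(np.abs(num - ref) * w) < 1e-3


class TestAgarPlate:
    def test_benchmark_parameters_stored_verbatim(self):
        p = make_agar_plate().params
        assert (p.H, p.K_S, p.N, p.K_chi, p.delta0, p.eta, p.omega, p.n_hill) == (
            3.5, 1.0, 0.5, 0.53, 105.0, 0.5, 0.5, 5.0
        )
        assert p.growth_on is True and p.zeta == 0.0

    def test_uniform_attractant_carries_no_initial_drift(self):
        spec = make_agar_plate()
        state = spec.build_initial_state()
        assert np.all(state.C == 1.0)
        dCdT = np.zeros_like(state.C)
        out = kx.divergence_of_flux(
            np.full_like(state.C, 0.3), state.C, dCdT, spec.grid, spec.params
        )
        np.testing.assert_allclose(out, 0.0, atol=1e-13)

    def test_constant_speed_controls(self):
        spec = make_agar_plate()
        low = spec.variant_params("const_speed_base")
        high = spec.variant_params("const_speed_high")
        assert low.mode == high.mode == "constant_speed"
        assert low.speed_factor == 1.0
        assert high.speed_factor == pytest.approx(1.0 + spec.params.eta)


class TestTransientSource:
    def test_benchmark_parameters_stored_verbatim(self):
        p = make_transient_source().params
        assert (p.H, p.K_S, p.N, p.K_chi, p.delta0, p.eta, p.omega, p.n_hill) == (
            3.5, 1.0, 0.5, 0.53, 50.0, 2.0, 0.2, 1.0
        )
        assert p.zeta == pytest.approx(8.164e-3)
        assert p.growth_on is False

    def test_initial_state_is_kernel_over_uniform_population(self):
        spec = make_transient_source()
        state = spec.build_initial_state()
        assert state.T == 0.01
        np.testing.assert_allclose(state.B, 0.2)
        np.testing.assert_allclose(
            state.C,
            gaussian_pulse(spec.grid.cell_centers, 0.01, 0.5, 0.5),
            rtol=1e-12,
        )

    def test_four_response_variants(self):
        spec = make_transient_source()
        ov = {v.label: v.overrides for v in spec.variants}
        assert ov["ck_zeta"] == {}
        assert ov["ck_nozeta"] == {"zeta": 0.0}
        assert ov["chemo_zeta"] == {"eta": 0.0}
        assert ov["chemo_nozeta"] == {"eta": 0.0, "zeta": 0.0}

    def test_evolved_attractant_follows_kernel_without_consumption(self):
        # with consumption off the evolved C is the freely diffusing pulse
        spec = make_transient_source({"H": 0.0})
        spec.t_snapshots = [0.3, 0.64]
        traj = kx.run_variant(spec)
        for s in traj.states:
            ref = gaussian_pulse(spec.grid.cell_centers, s.T, 0.5, 0.5)
            assert np.max(np.abs(s.C - ref)) < 1e-3

    def test_analytic_attractant_mode(self):
        spec = make_transient_source(c_analytic=True, n_cells=200)
        spec.t_snapshots = [0.05]
        traj = kx.run_variant(spec)
        ref = gaussian_pulse(spec.grid.cell_centers, 0.05, 0.5, 0.5)
        np.testing.assert_allclose(traj.final.C, ref, rtol=1e-12)


class TestConfigRoundTrip:
    @pytest.mark.parametrize(
        "factory", [make_linear_gradient, make_agar_plate, make_transient_source]
    )
    def test_lossless(self, factory, tmp_path):
        spec = factory()
        path = tmp_path / "scenario.toml"
        spec.to_toml(path)
        back = ScenarioSpec.from_toml(path)
        assert back.name == spec.name
        assert back.grid == spec.grid
        assert back.params == spec.params
        assert back.c_mode == spec.c_mode
        assert back.c_analytic == spec.c_analytic
        assert back.t_snapshots == spec.t_snapshots
        assert back.initial == spec.initial
        assert back.variants == spec.variants

    def test_unknown_keys_rejected(self, tmp_path):
        spec = make_linear_gradient()
        path = tmp_path / "scenario.toml"
        spec.to_toml(path)
        text = path.read_text().replace("[params]", "[params]\nwarp_drive = 1.0")
        path.write_text(text)
        with pytest.raises(ValueError, match="warp_drive"):
            ScenarioSpec.from_toml(path)

    def test_unknown_section_rejected(self, tmp_path):
        path = tmp_path / "scenario.toml"
        make_linear_gradient().to_toml(path)
        path.write_text(path.read_text() + "\n[telemetry]\nenabled = true\n")
        with pytest.raises(ValueError, match="telemetry"):
            ScenarioSpec.from_toml(path)


def test_boundary_sensitivity_of_transient_source():
    spec = make_transient_source(n_cells=150)
    spec.t_snapshots = [0.1]
    out = kx.boundary_sensitivity(spec, "ck_zeta")
    assert out["peak_rel_change"] < 5e-3
    assert out["total_rel_change"] < 5e-3
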