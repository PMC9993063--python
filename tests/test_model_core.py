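"""Core dynamics: feedback, right-hand side and the simulator."""

import numpy as np
import pytest

from odna_retention import (Encoding, ModelParameters, PeriodicEnvironment,
                            StaticEnvironment, Trajectory, equilibrium,
                            feedback, generate_red, generate_white, rhs,
                            simulate)

from _oracles import rk4_reference, sinusoid


class TestFeedback:
    @pytest.mark.parametrize("E, x_m, expected", [
        (1.0, 0.4, 0.6),   # deficit branch
        (1.0, 1.2, 0.0),   # supply exceeds demand: expression off
        (0.0, 0.0, 0.0),   # boundary of both branches
        (2.0, 2.0, 0.0),   # exact matching
    ])
    def test_values(self, E, x_m, expected):
        assert feedback(E, x_m) == pytest.approx(expected)

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            feedback(-0.1, 0.0)
        with pytest.raises(ValueError):
            feedback(1.0, -0.1)

    def test_continuity_at_the_kink(self):
        eps = 1e-12
        assert feedback(1.0, 1.0 - eps) == pytest.approx(eps, abs=1e-15)
        assert feedback(1.0, 1.0 + eps) == 0.0


class TestRHS:
    def test_origin_organelle_encoding(self, unit_static):
        params = ModelParameters(1.0, 0.1, 0.5, 0.1, 0.75,
                                 Encoding.ORGANELLE)
        dxm, dxc = rhs(0.0, (0.0, 0.0), params, unit_static)
        assert dxm == pytest.approx(0.75)
        assert dxc == 0.0

    def test_origin_nuclear_encoding(self, unit_static):
        params = ModelParameters(1.0, 0.1, 0.0, 0.0, 1.0, Encoding.NUCLEUS)
        dxm, dxc = rhs(0.0, (0.0, 0.0), params, unit_static)
        assert dxm == 0.0
        assert dxc == pytest.approx(1.0)

    def test_vanishes_at_closed_form_equilibrium(self, unit_static):
        # x_m* = lambda p a / (lambda p + nu_m) = 0.6
        params = ModelParameters(1.0, 0.1, 0.5, 0.1, 0.75,
                                 Encoding.ORGANELLE)
        dxm, dxc = rhs(10.0, (0.6, 0.0), params, unit_static)
        assert dxm == pytest.approx(0.0, abs=1e-14)
        assert dxc == 0.0

    def test_negative_state_rejected(self, unit_static):
        params = ModelParameters()
        with pytest.raises(ValueError):
            rhs(0.0, (-0.1, 0.0), params, unit_static)


class TestParameters:
    @pytest.mark.parametrize("field, value", [
        ("synthesis_rate", -1.0),
        ("transport_rate", -0.5),
        ("degradation_organelle", float("nan")),
        ("wildtype_fraction", 1.5),
        ("wildtype_fraction", -0.1),
        ("encoding", 0.5),
    ])
    def test_invalid_values_rejected(self, field, value):
        with pytest.raises(ValueError):
            ModelParameters(**{field: value})

    def test_encoding_is_exact_enum(self):
        params = ModelParameters(encoding=1)
        assert params.encoding is Encoding.NUCLEUS
        assert params.with_encoding(0).encoding is Encoding.ORGANELLE


class TestSimulate:
    def test_perfect_adaptation_without_organelle_turnover(self):
        # nu_m = 0: supply converges to demand exactly
        params = ModelParameters(1.0, 1.0, 0.0, 0.1, 0.75)
        traj = simulate(params, StaticEnvironment(1.0))
        assert abs(traj.x_m[-1] - 1.0) < 1e-6
        # and stays there over the whole second half
        second_day = traj.x_m[traj.time >= 144.0]
        assert np.all(np.abs(second_day - 1.0) < 1e-6)

    def test_static_equilibrium_value(self, reference_params):
        traj = simulate(reference_params, StaticEnvironment(1.0))
        assert traj.x_m[-1] == pytest.approx(0.6, abs=1e-7)

    def test_no_synthesis_means_no_product(self):
        params = ModelParameters(synthesis_rate=0.0)
        for env in (StaticEnvironment(1.0),
                    PeriodicEnvironment(1.0, 1.0, 4.0),
                    generate_white(1.0, 1.0, 288.0, seed=0)):
            traj = simulate(params, env)
            assert np.all(traj.x_m == 0.0)
            assert np.all(traj.x_c == 0.0)

    @pytest.mark.parametrize("alpha", [Encoding.ORGANELLE, Encoding.NUCLEUS])
    def test_random_static_equilibria_match_closed_form(self, alpha):
        """Simulated static steady states hit the closed forms to 1e-6.

        Parameter sets are drawn across decades of rates; the window is
        extended beyond the default two days where the slowest relaxation
        rate would not have decayed yet.
        """
        rng = np.random.default_rng(2024)
        for _ in range(20):
            params = ModelParameters(
                synthesis_rate=10 ** rng.uniform(-2, 1),
                transport_rate=10 ** rng.uniform(-2, 1),
                degradation_organelle=rng.uniform(0.0, 1.0),
                degradation_cytosol=rng.uniform(0.0, 1.0),
                wildtype_fraction=rng.uniform(0.25, 1.0),
                encoding=alpha)
            try:
                eq = equilibrium(params, a=1.0)
            except ValueError:
                continue
            rate = _slowest_rate(params)
            t_end = max(288.0, 40.0 / rate)
            traj = simulate(params, StaticEnvironment(1.0),
                            window=(0.0, t_end), sampling_step=t_end / 2880)
            assert abs(traj.x_m[-1] - eq.x_m_star) < 1e-6, params
            assert abs(traj.x_c[-1] - eq.x_c_star) < 1e-6, params

    def test_nonnegativity_across_environment_classes(self, reference_params):
        envs = [StaticEnvironment(1.0),
                PeriodicEnvironment(1.0, 1.0, 10.0),
                generate_white(1.0, 1.0, 288.0, seed=1),
                generate_red(1.0, 1.0, 288.0, seed=1)]
        for env in envs:
            for enc in Encoding:
                traj = simulate(reference_params.with_encoding(enc), env)
                assert np.all(traj.x_m >= 0.0)
                assert np.all(traj.x_c >= 0.0)
                assert traj.clip_magnitude < 1e-7

    def test_organelle_encoding_never_feeds_cytosol(self, reference_params):
        traj = simulate(reference_params, PeriodicEnvironment(1.0, 1.0, 4.0))
        assert np.all(traj.x_c == 0.0)

    def test_fast_transport_makes_cytosol_transparent(self):
        """With nu_c = 0 and near-instantaneous import, nuclear encoding
        approaches the undamaged organelle-encoded dynamics pointwise."""
        nuclear = ModelParameters(1.0, 1e4, 0.5, 0.0, 0.75,
                                  Encoding.NUCLEUS)
        organelle = ModelParameters(1.0, 1e4, 0.5, 0.0, 1.0,
                                    Encoding.ORGANELLE)
        env = PeriodicEnvironment(1.0, 1.0, 2.0)
        tn = simulate(nuclear, env)
        to = simulate(organelle, env)
        assert np.max(np.abs(tn.x_m - to.x_m)) < 1e-3

    @pytest.mark.parametrize("alpha", [Encoding.ORGANELLE, Encoding.NUCLEUS])
    @pytest.mark.parametrize("k", [1.0, 10.0])
    def test_bounded_by_peak_demand_under_periodic_forcing(self, alpha, k):
        a, b = 1.0, 1.0
        params = ModelParameters(1.0, 0.5, 0.3, 0.1, 0.9, alpha)
        traj = simulate(params, PeriodicEnvironment(a, b, k))
        after = traj.x_m[traj.time >= 144.0]
        assert np.all(after <= a * (1 + b) + 1e-6)

    def test_agrees_with_rk4_oracle_on_periodic_forcing(self):
        params = ModelParameters(1.0, 0.1, 0.5, 0.0, 0.75, Encoding.NUCLEUS)
        traj = simulate(params, PeriodicEnvironment(1.0, 1.0, 4.0),
                        window=(0.0, 30.0))
        _, ref_m, ref_c = rk4_reference(params, sinusoid(1.0, 1.0, 4.0),
                                        t_end=30.0)
        assert np.max(np.abs(traj.x_m - ref_m)) < 1e-5
        assert np.max(np.abs(traj.x_c - ref_c)) < 1e-5

    def test_uniform_grid_covers_window(self, reference_params, unit_static):
        traj = simulate(reference_params, unit_static, window=(0.0, 10.0),
                        sampling_step=0.1)
        assert traj.time[0] == 0.0 and traj.time[-1] == 10.0
        assert np.allclose(np.diff(traj.time), 0.1)

    def test_invalid_windows_rejected(self, reference_params, unit_static):
        with pytest.raises(ValueError):
            simulate(reference_params, unit_static, window=(10.0, 0.0))
        with pytest.raises(ValueError):
            simulate(reference_params, unit_static, sampling_step=0.0)
        with pytest.raises(ValueError):
            simulate(reference_params, unit_static,
                     initial_state=(-1.0, 0.0))


def _slowest_rate(params):
    """Smallest decay rate of the deficit-branch linear system."""
    if params.encoding == Encoding.ORGANELLE:
        return max(params.synthesis_rate * params.wildtype_fraction
                   + params.degradation_organelle, 1e-4)
    jac = np.array([
        [-params.degradation_organelle, params.transport_rate],
        [-params.synthesis_rate,
         -(params.transport_rate + params.degradation_cytosol)],
    ])
    rates = -np.real(np.linalg.eigvals(jac))
    return max(min(rates), 1e-4)


class TestTrajectory:
    def test_csv_export_columns(self, reference_params, unit_static,
                                tmp_path):
        traj = simulate(reference_params, unit_static, window=(0.0, 5.0))
        path = tmp_path / "traj.csv"
        traj.to_csv(path)
        import pandas as pd
        df = pd.read_csv(path)
        assert list(df.columns) == ["time", "x_m", "x_c", "E", "alpha"]
        assert len(df) == len(traj.time)
        assert set(df["alpha"]) == {0}

    def test_slice_outside_span_rejected(self, reference_params,
                                         unit_static):
        traj = simulate(reference_params, unit_static, window=(0.0, 5.0))
        with pytest.raises(ValueError):
            traj.slice(10.0, 20.0)

    def test_time_grid_must_increase(self, reference_params, unit_static):
        with pytest.raises(ValueError):
            Trajectory(time=np.array([0.0, 1.0, 0.5]),
                       x_m=np.zeros(3), x_c=np.zeros(3),
                       demand=np.ones(3), params=reference_params,
                       environment=unit_static)
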