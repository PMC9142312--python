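import math

import numpy as np
import pytest

from fractumor import (
    DivergenceError,
    FractionalOrders,
    ModelParams,
    SolverSettings,
    Trajectory,
    integrate,
    integrate_integer_reference,
    integrate_system,
)
from tests.conftest import STUDY_IC


def mittag_leffler(q: float, z: float) -> float:
    """Series evaluation of E_q(z) in arbitrary precision (solver oracle)."""
    import mpmath

    return float(
        mpmath.nsum(lambda k: mpmath.mpf(z) ** k / mpmath.gamma(q * k + 1),
                    [0, mpmath.inf])
    )


class TestScalarOracles:
    def test_zero_right_hand_side_keeps_constant_solution(self):
        _, u = integrate_system(lambda s: np.zeros(1), [0.63], [0.7],
                                SolverSettings(h=0.05, t_end=5.0))
        assert np.allclose(u, 0.7, atol=1e-14)

    @pytest.mark.parametrize("q", [0.7, 0.9, 0.995])
    def test_constant_forcing_matches_power_law_solution(self, q):
        # D^q u = 1, u(0) = 0  ->  u(t) = t^q / Gamma(q+1); the piecewise-
        # linear product quadrature is exact for constant f
        t, u = integrate_system(lambda s: np.ones(1), [q], [0.0],
                                SolverSettings(h=0.01, t_end=10.0))
        exact = t ** q / math.gamma(q + 1.0)
        assert np.max(np.abs(u[:, 0] - exact)) < 1e-10

    @pytest.mark.parametrize("q", [0.8, 0.95])
    def test_linear_decay_matches_mittag_leffler(self, q):
        # D^q u = -u, u(0) = 1  ->  u(t) = E_q(-t^q)
        t, u = integrate_system(lambda s: -s, [q], [1.0],
                                SolverSettings(h=1e-3, t_end=5.0))
        idx = np.linspace(1, t.size - 1, 25).astype(int)
        err = max(abs(u[i, 0] - mittag_leffler(q, -(t[i] ** q))) for i in idx)
        assert err < 1e-3

    def test_quadratic_blowup_reports_failing_step(self):
        # du/dt = u^2, u(0) = 2 blows up at t = 0.5
        with pytest.raises(DivergenceError) as exc:
            integrate_system(lambda s: s ** 2, [1.0], [2.0],
                             SolverSettings(h=0.01, t_end=2.0))
        assert 0 < exc.value.step <= 200
        assert exc.value.states.shape[0] == exc.value.step


class TestModelIntegration:
    def test_integer_limit_matches_adaptive_reference(self, params):
        s = SolverSettings(h=2e-3, t_end=20.0)
        pece = integrate(params, FractionalOrders(1, 1, 1), STUDY_IC, s)
        ref = integrate_integer_reference(params, STUDY_IC, s)
        assert np.max(np.abs(pece.states - ref.states)) < 1e-3

    def test_reference_trajectory_remains_bounded(self, params):
        # the orbit stays on the small attracting set for tens of time units,
        # then migrates to a larger (still bounded) periodic orbit
        traj = integrate_integer_reference(
            params, STUDY_IC, SolverSettings(h=0.05, t_end=500.0)
        )
        assert np.all(np.isfinite(traj.states))
        assert np.max(np.abs(traj.states)) < 15.0
        first40 = traj.states[traj.times <= 40.0]
        assert np.all(np.abs(first40) <= 2.5)

    def test_equilibrium_initial_condition_is_invariant(self, params, e4):
        traj = integrate_integer_reference(
            params, e4, SolverSettings(h=0.01, t_end=1.0)
        )
        assert np.max(np.abs(traj.states - e4)) < 1e-6

    def test_bitwise_determinism(self, params):
        s = SolverSettings(h=0.01, t_end=10.0)
        orders = FractionalOrders.commensurate_order(0.9)
        t1 = integrate(params, orders, STUDY_IC, s)
        t2 = integrate(params, orders, STUDY_IC, s)
        assert np.array_equal(t1.states, t2.states)

    def test_cyclic_equivariance_of_commensurate_trajectories(self, params):
        s = SolverSettings(h=0.01, t_end=10.0)
        orders = FractionalOrders.commensurate_order(0.9)
        base = integrate(params, orders, (0.4, 0.5, 0.5), s)
        rolled = integrate(params.cycled(), orders, (0.5, 0.5, 0.4), s)
        assert np.allclose(np.roll(base.states, -1, axis=1), rolled.states,
                           atol=1e-10)

    def test_truncated_memory_converges_to_full_history(self, params):
        orders = FractionalOrders.commensurate_order(0.9)
        full = integrate(params, orders, STUDY_IC,
                         SolverSettings(h=0.01, t_end=20.0))
        errs = []
        for L in (200, 1000, 2000):
            trunc = integrate(params, orders, STUDY_IC,
                              SolverSettings(h=0.01, t_end=20.0, memory=L))
            errs.append(np.max(np.abs(trunc.states - full.states)))
        assert errs[-1] == 0.0  # window >= N is exactly the full scheme
        assert errs[1] < errs[0]

    def test_runaway_state_aborts_with_step_index(self, params):
        with pytest.raises(DivergenceError) as exc:
            integrate(params, FractionalOrders(1, 1, 1), (5.0, 5.0, 5.0),
                      SolverSettings(h=0.01, t_end=50.0))
        assert exc.value.step > 0


class TestTrajectoryContainer:
    def test_validates_aligned_lengths(self):
        with pytest.raises(ValueError):
            Trajectory(times=np.arange(3.0), states=np.zeros((4, 3)))

    def test_csv_round_trip_preserves_full_precision(self, tmp_path, params):
        import pandas as pd

        traj = integrate(params, FractionalOrders.commensurate_order(0.9),
                         STUDY_IC, SolverSettings(h=0.01, t_end=2.0))
        out = tmp_path / "traj.csv"
        traj.write_csv(out)
        frame = pd.read_csv(out, float_precision="round_trip")
        assert list(frame.columns) == ["t", "x", "y", "z"]
        assert np.allclose(frame[["x", "y", "z"]].to_numpy(), traj.states,
                           rtol=0, atol=0)
        sidecar = out.with_suffix(".csv.json")
        assert sidecar.exists()

    def test_settings_validation(self):
        with pytest.raises(ValueError):
            SolverSettings(h=0.0, t_end=1.0)
        with pytest.raises(ValueError):
            SolverSettings(h=0.3, t_end=1.0)  # not an integer step count
        with pytest.raises(ValueError):
            FractionalOrders(1.2, 1.0, 1.0)
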