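import numpy as np
import pytest

from fractumor import (
    FractionalOrders,
    LyapunovSettings,
    RegimeThresholds,
    ScanSpec,
    SolverSettings,
    Trajectory,
    bifurcation_scan,
    classify_regime,
    converges_to,
    extrema_series,
    largest_lyapunov_system,
)
from tests.conftest import STUDY_IC, STUDY_PARAMS


def _traj_from_series(series, h=0.01):
    s = np.asarray(series, dtype=float)
    return Trajectory(times=h * np.arange(s.size),
                      states=np.column_stack([s, s, s]))


class TestExtremaSeries:
    def test_constant_series_has_no_peaks(self):
        peaks = extrema_series(_traj_from_series(np.ones(200)), "x", 0.0)
        assert peaks.size == 0

    def test_sampled_sine_peaks_at_unit_amplitude(self):
        h = 0.01
        t = h * np.arange(5000)
        peaks = extrema_series(_traj_from_series(np.sin(t), h), "x", 0.0)
        assert peaks.size == 8  # one per 2*pi on [0, 50)
        assert np.allclose(peaks, 1.0, atol=h ** 2)

    def test_short_post_transient_window_rejected(self):
        with pytest.raises(ValueError, match="50"):
            extrema_series(_traj_from_series(np.ones(60)), "x", 0.5)


class TestClassifyRegime:
    def test_empty_extrema_is_stable(self):
        assert classify_regime(np.array([])) == "stable"

    def test_two_cluster_peaks_without_stretching_is_periodic(self):
        peaks = np.tile([1.20, 0.80], 25) + 1e-5
        assert classify_regime(peaks, lle=-0.01) == "periodic"

    def test_many_clusters_with_positive_lle_is_chaotic(self):
        rng = np.random.default_rng(3)
        peaks = rng.uniform(0.5, 2.0, size=200)
        assert classify_regime(peaks, lle=0.02) == "chaotic"

    def test_many_clusters_without_lle_is_ambiguous(self):
        rng = np.random.default_rng(3)
        peaks = rng.uniform(0.5, 2.0, size=200)
        assert classify_regime(peaks, lle=None) == "periodic-or-chaotic"

    def test_decaying_tail_overrides_peak_spread(self):
        # slow algebraic relaxation: peaks still spread, amplitude shrinking
        t = np.arange(2000, dtype=float)
        tail = 1e-3 * np.cos(0.3 * t) / (1.0 + 0.01 * t)
        peaks = extrema_series(_traj_from_series(tail), "x", 0.0)
        assert classify_regime(peaks, series_tail=tail) == "stable"

    def test_period_one_cycle_not_mistaken_for_stable(self):
        # peaks agree to ~1e-5, but the oscillation amplitude is large
        t = 0.01 * np.arange(20000)
        tail = 1.5 * np.cos(0.3 * t)
        peaks = extrema_series(_traj_from_series(tail), "x", 0.0)
        assert np.ptp(peaks) < 1e-4
        assert classify_regime(peaks, series_tail=tail) == "periodic"

    def test_raising_lle_threshold_never_creates_chaos(self):
        rng = np.random.default_rng(5)
        peaks = rng.uniform(0.5, 2.0, size=100)
        order = {"stable": 0, "periodic": 1, "periodic-or-chaotic": 2,
                 "chaotic": 3}
        labels = [
            classify_regime(peaks, lle=0.02,
                            thresholds=RegimeThresholds(eps_lyap=eps))
            for eps in (0.001, 0.01, 0.05)
        ]
        assert order[labels[0]] >= order[labels[1]] >= order[labels[2]]


class TestLyapunov:
    def test_linear_contraction_has_unit_negative_exponent(self):
        # horizon kept short: exponential contraction of the tangent flow
        # is representable in the nonlocal scheme only while |lambda| t < ~30
        r = largest_lyapunov_system(
            lambda u: -u, [1.0], [1.0],
            SolverSettings(h=0.01, t_end=30.0),
            LyapunovSettings(),
        )
        assert r.lle == pytest.approx(-1.0, rel=0.1)

    def test_stable_regime_has_negative_exponent(self):
        from fractumor import largest_lyapunov

        r = largest_lyapunov(
            STUDY_PARAMS, FractionalOrders.commensurate_order(0.90), STUDY_IC,
            SolverSettings(h=0.02, t_end=150.0), LyapunovSettings(),
        )
        assert r.lle < 0.0

    def test_estimate_is_seed_deterministic(self):
        s = SolverSettings(h=0.01, t_end=60.0)
        kw = dict(rhs=lambda u: -u, orders=[0.9], ic=[1.0], settings=s)
        a = largest_lyapunov_system(**kw, lyap=LyapunovSettings(seed=11))
        b = largest_lyapunov_system(**kw, lyap=LyapunovSettings(seed=11))
        assert a.lle == b.lle


class TestConvergenceCheck:
    def test_detects_convergence_and_rejects_orbit(self):
        t = 0.01 * np.arange(2000)
        target = np.array([1.0, 1.0, 1.0])
        decaying = Trajectory(t, 1.0 + np.exp(-t)[:, None] * np.ones(3))
        orbiting = Trajectory(t, 1.0 + 0.5 * np.cos(t)[:, None] * np.ones(3))
        assert converges_to(decaying, target)
        assert not converges_to(orbiting, target)


@pytest.fixture(scope="module")
def tiny_spec():
    return ScanSpec(
        swept="q",
        grid=np.array([0.90, 0.97]),
        params=STUDY_PARAMS,
        orders=FractionalOrders(1, 1, 1),
        ic=STUDY_IC,
        settings=SolverSettings(h=0.02, t_end=150.0),
        lyapunov="never",
    )


class TestBifurcationScan:
    def test_separates_stable_from_oscillating_orders(self, tiny_spec):
        result = bifurcation_scan(tiny_spec)
        assert result.regimes() == ["stable", "periodic"]

    def test_scan_is_repeatable(self, tiny_spec):
        r1 = bifurcation_scan(tiny_spec)
        r2 = bifurcation_scan(tiny_spec)
        for p1, p2 in zip(r1.points, r2.points):
            assert p1.regime == p2.regime
            assert np.array_equal(p1.extrema, p2.extrema)

    def test_tidy_output_one_row_per_peak(self, tiny_spec, tmp_path):
        result = bifurcation_scan(tiny_spec)
        frame = result.to_dataframe()
        n_peaks = sum(max(1, p.extrema.size) for p in result.points)
        assert len(frame) == n_peaks
        result.write(tmp_path / "scan.csv", tmp_path / "scan.json")
        assert (tmp_path / "scan.csv").exists()
        assert (tmp_path / "scan.json").exists()

    def test_rejects_malformed_grid(self):
        with pytest.raises(ValueError):
            ScanSpec(swept="q", grid=np.array([0.9, 0.8]),
                     params=STUDY_PARAMS, orders=FractionalOrders(1, 1, 1))
        with pytest.raises(ValueError):
            ScanSpec(swept="growth", grid=np.array([0.1, 0.2]),
                     params=STUDY_PARAMS, orders=FractionalOrders(1, 1, 1))
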