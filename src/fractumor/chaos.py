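"""Regime quantification: Lyapunov exponents, bifurcation extrema, scans.

Three stable/periodic/chaotic diagnostics are combined:

* the largest Lyapunov exponent (LLE), estimated with a two-trajectory
  Benettin method run inside the fractional solver itself;
* post-transient local maxima of one state variable (the vertical axis of a
  bifurcation diagram);
* a rule-based regime classifier over those two.

Benettin renormalization under a Caputo scheme needs care: the ABM update
reconstructs ``u_{n+1}`` from ``u_0`` and the whole right-hand-side history,
so rescaling only a perturbed trajectory's *current* state would not change
its future at all, while rescaling its entire history difference amplifies
the stored initial-time separation without bound whenever the dynamics
contract (the rescale factor exceeds 1).  The separation is therefore
propagated through the variational (tangent-linear) system
``D^q delta = J(x(t)) delta`` along the fiducial trajectory, discretized with
the same predictor--corrector weights.  Because that system is linear in
``delta``, rescaling its complete history at renormalization times is exact
-- purely a floating-point-range device -- and the classic Benettin
log-stretch bookkeeping carries over unchanged.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Optional, Sequence

import numpy as np

from .model import ModelParams
from .solver import (
    CaputoABM,
    DivergenceError,
    FractionalOrders,
    SolverSettings,
    Trajectory,
    integrate,
)

__all__ = [
    "LyapunovSettings",
    "LyapunovResult",
    "RegimeThresholds",
    "ScanSpec",
    "ScanPoint",
    "ScanResult",
    "largest_lyapunov",
    "largest_lyapunov_system",
    "extrema_series",
    "classify_regime",
    "converges_to",
    "bifurcation_scan",
]


@dataclass(frozen=True)
class LyapunovSettings:
    """Benettin-method knobs.

    perturbation : amplitude of the initial tangent vector (the exponent is
        invariant to it by linearity; kept away from float range limits).
    renorm_interval : time between renormalizations (in model time units).
    discard_fraction : leading fraction of renormalization intervals dropped
        as transient before averaging log stretch factors.
    seed : seeds the random initial perturbation direction (the only source
        of randomness in the whole package).
    """

    perturbation: float = 1e-8
    renorm_interval: float = 1.0
    discard_fraction: float = 0.4
    seed: int = 0

    def to_dict(self) -> dict:
        return {
            "perturbation": self.perturbation,
            "renorm_interval": self.renorm_interval,
            "discard_fraction": self.discard_fraction,
            "seed": self.seed,
        }


@dataclass
class LyapunovResult:
    """Largest Lyapunov exponent (1/time) with its convergence trace.

    ``trace_times``/``trace`` hold the running post-transient estimate after
    each renormalization; ``converged`` flags whether the final 20% of the
    trace stays within 20% relative spread.
    """

    lle: float
    trace_times: np.ndarray
    trace: np.ndarray
    settings: LyapunovSettings
    converged: bool

    def to_dict(self) -> dict:
        return {
            "lle": float(self.lle),
            "converged": bool(self.converged),
            "settings": self.settings.to_dict(),
            "n_renormalizations": int(self.trace.size),
        }


def _benettin(
    rhs: Callable[[np.ndarray], np.ndarray],
    jac: Callable[[np.ndarray], np.ndarray],
    orders: np.ndarray,
    ic: np.ndarray,
    settings: SolverSettings,
    lyap: LyapunovSettings,
) -> LyapunovResult:
    h, n_steps = settings.h, settings.n_steps
    m = int(round(lyap.renorm_interval / h))
    if m < 1 or abs(m * h - lyap.renorm_interval) > 1e-9:
        raise ValueError(
            f"renorm_interval {lyap.renorm_interval} is not a multiple of h={h}"
        )
    n_renorm = n_steps // m
    if n_renorm < 2:
        raise ValueError("integration horizon too short for any renormalization")

    ic = np.asarray(ic, dtype=float)
    dim = ic.size
    rng = np.random.default_rng(lyap.seed)
    direction = rng.normal(size=dim)
    direction /= np.linalg.norm(direction)
    d0 = lyap.perturbation

    fid = CaputoABM(rhs, orders, ic, h, n_steps, settings.memory)
    N, q = fid.N, fid.q
    # tangent vector history, same reversed f-storage layout as the stepper
    dstates = np.empty((N + 1, dim))
    dfrev = np.empty((N + 1, dim))
    dstates[0] = d0 * direction
    dfrev[N] = jac(ic) @ dstates[0]

    stretches = np.empty(n_renorm)
    for k in range(n_renorm):
        for _ in range(m):
            n = fid.n
            j0 = 0 if fid.memory is None else max(0, n + 1 - fid.memory)
            nh = n - j0 + 1
            x_next = fid.step()
            J_next = jac(x_next)

            hist = dfrev[N - n : N - n + nh]
            pred = dstates[0] + fid._pf * np.array(
                [np.dot(fid._B[:nh, i], hist[:, i]) for i in range(dim)]
            )
            acc = (J_next @ pred).astype(float)
            j1 = max(1, j0)
            nc = n - j1 + 1
            if nc > 0:
                ch = dfrev[N - n : N - n + nc]
                acc += np.array(
                    [np.dot(fid._A[:nc, i], ch[:, i]) for i in range(dim)]
                )
            if j0 == 0:
                eta0 = n ** (q + 1.0) - (n - q) * (n + 1.0) ** q
                acc += eta0 * dfrev[N]
            new = dstates[0] + fid._cf * acc
            if not np.all(np.isfinite(new)):
                t = h * np.arange(n + 2)
                raise DivergenceError(n + 1, t[: n + 1], dstates[: n + 1].copy())
            dstates[n + 1] = new
            dfrev[N - (n + 1)] = J_next @ new

        n = fid.n
        d1 = float(np.linalg.norm(dstates[n]))
        if d1 == 0.0:
            d1 = 1e-300  # tangent vector collapsed to exactly zero
        stretches[k] = math.log(d1 / d0)
        # exact for the linear variational system: rescale the whole history
        s = d0 / d1
        dstates[: n + 1] *= s
        dfrev[N - n :] *= s

    k0 = int(math.floor(lyap.discard_fraction * n_renorm))
    kept = stretches[k0:]
    tau = m * h
    cum = np.cumsum(kept)
    trace = cum / (tau * np.arange(1, kept.size + 1))
    trace_times = tau * (k0 + np.arange(1, kept.size + 1))
    lle = float(trace[-1])

    tail = trace[int(math.floor(0.8 * trace.size)) :]
    scale = max(abs(lle), 1e-12)
    converged = bool((tail.max() - tail.min()) / scale < 0.2)
    return LyapunovResult(lle, trace_times, trace, lyap, converged)


def largest_lyapunov_system(
    rhs: Callable[[np.ndarray], np.ndarray],
    orders,
    ic,
    settings: SolverSettings,
    lyap: LyapunovSettings = LyapunovSettings(),
    jac: Optional[Callable[[np.ndarray], np.ndarray]] = None,
) -> LyapunovResult:
    """Benettin LLE for a generic Caputo system (validation entry point).

    ``jac`` is the Jacobian of ``rhs``; when omitted it is approximated with
    central finite differences (step 1e-7).
    """
    orders = np.atleast_1d(np.asarray(orders, dtype=float))
    ic = np.atleast_1d(np.asarray(ic, dtype=float))
    if jac is None:
        dim = ic.size
        eye = np.eye(dim)
        fd = 1e-7

        def jac(state: np.ndarray) -> np.ndarray:
            return np.column_stack(
                [
                    (np.atleast_1d(rhs(state + fd * eye[k]))
                     - np.atleast_1d(rhs(state - fd * eye[k]))) / (2 * fd)
                    for k in range(dim)
                ]
            )

    return _benettin(rhs, jac, orders, ic, settings, lyap)


def largest_lyapunov(
    params: ModelParams,
    orders: FractionalOrders,
    ic,
    settings: SolverSettings,
    lyap: LyapunovSettings = LyapunovSettings(),
) -> LyapunovResult:
    """Largest Lyapunov exponent of the tumor--host--effector model."""
    from .model import jacobian

    a, b, c = params.a, params.b, params.c

    def rhs(s: np.ndarray) -> np.ndarray:
        x, y, z = s
        return np.array(
            [
                a * x * (1.0 - y) * (1.0 + z) - x * x * y,
                b * y * (1.0 - z) * (1.0 + x) - y * y * z,
                c * z * (1.0 - x) * (1.0 + y) - z * z * x,
            ]
        )

    return _benettin(rhs, lambda s: jacobian(s, params), orders.as_array(),
                     np.asarray(ic, float), settings, lyap)


def extrema_series(
    traj: Trajectory,
    variable: str = "x",
    transient_fraction: float = 0.6,
) -> np.ndarray:
    """Strict local maxima of one state variable after the transient.

    Sample ``k`` is a peak iff ``s[k-1] < s[k] > s[k+1]``; values are returned
    in time order.  Possibly empty (monotone convergence).
    """
    if not (0.0 <= transient_fraction < 1.0):
        raise ValueError(f"transient_fraction must lie in [0,1), got {transient_fraction}")
    s = traj.component(variable)
    start = int(math.floor(transient_fraction * s.size))
    tail = s[start:]
    if tail.size < 50:
        raise ValueError(
            f"post-transient window holds only {tail.size} samples (< 50); "
            "integrate longer or reduce transient_fraction"
        )
    inner = tail[1:-1]
    mask = (inner > tail[:-2]) & (inner > tail[2:])
    return inner[mask]


@dataclass(frozen=True)
class RegimeThresholds:
    """Classifier thresholds (artifact choices, see the methods note).

    eps_stable : max peak spread still called a point attractor.
    cluster_tol : peaks closer than this merge into one cluster.
    max_periodic_clusters : cluster count above which a positive-LLE check is
        required to call the point chaotic.
    eps_lyap : minimum LLE to diagnose chaos.
    amp_tol : max post-transient oscillation amplitude still called stable
        (used only when the series tail is supplied).
    """

    eps_stable: float = 1e-4
    cluster_tol: float = 1e-3
    max_periodic_clusters: int = 16
    eps_lyap: float = 0.005
    amp_tol: float = 1e-2


def _cluster_count(peaks: np.ndarray, tol: float) -> int:
    v = np.sort(peaks)
    return 1 + int(np.count_nonzero(np.diff(v) > tol))


def classify_regime(
    extrema: np.ndarray,
    lle: Optional[float] = None,
    series_tail: Optional[np.ndarray] = None,
    thresholds: RegimeThresholds = RegimeThresholds(),
) -> str:
    """Label a run ``stable``, ``periodic``, ``chaotic`` or ambiguous.

    Fractional trajectories relax at an algebraic (not exponential) rate, so
    a converging run can still carry a slowly decaying peak train; when the
    post-transient ``series_tail`` is supplied, stability is therefore judged
    by the oscillation amplitude of its last quarter (small and not growing),
    which also keeps genuine small-spread period-1 cycles out of the stable
    bin.  Otherwise the peak-spread rule alone is used.  Chaos requires a
    positive LLE; many peak clusters without an LLE give the honest
    ``periodic-or-chaotic``.
    """
    th = thresholds
    extrema = np.asarray(extrema, dtype=float)
    if series_tail is not None:
        tail = np.asarray(series_tail, dtype=float)
        q = tail.size // 4
        if q >= 2:
            amp_last = float(np.ptp(tail[-q:]))
            amp_prev = float(np.ptp(tail[-2 * q : -q]))
            if amp_last < th.amp_tol and amp_last <= amp_prev * 1.05:
                return "stable"
    if extrema.size == 0:
        return "stable"
    if series_tail is None and float(np.ptp(extrema)) < th.eps_stable:
        return "stable"
    if lle is not None and lle > th.eps_lyap:
        return "chaotic"
    n_clusters = _cluster_count(extrema, th.cluster_tol)
    if n_clusters <= th.max_periodic_clusters:
        return "periodic"
    return "periodic-or-chaotic"


def converges_to(
    traj: Trajectory, point, tol: float = 1e-2, floor: float = 1e-3
) -> bool:
    """True if the trajectory has converged to ``point``.

    Converged means the final distance is below ``tol`` and either still
    shrinking (compared with the distance at 80% of the run) or already at
    the ``floor`` — the latter so that a run sitting on the solver's own
    discretization bias near the equilibrium is not mistaken for a
    non-converging one.
    """
    point = np.asarray(point, dtype=float)
    d_end = float(np.linalg.norm(traj.final_state - point))
    d_80 = float(
        np.linalg.norm(traj.states[int(0.8 * traj.states.shape[0])] - point)
    )
    return d_end < tol and (d_end < d_80 or d_end < floor)


@dataclass(frozen=True)
class ScanSpec:
    """One-parameter sweep specification.

    ``swept`` is one of ``q`` (commensurate order), ``q1``/``q2``/``q3``
    (single-equation order) or ``a``/``b``/``c`` (growth rate); ``grid`` must
    be strictly increasing.  ``lyapunov`` controls when the LLE is computed
    per point: ``"never"``, ``"always"`` or ``"auto"`` (only when the peak
    structure alone cannot separate periodic from chaotic).

    With ``track_equilibrium`` (the default) each point first checks
    convergence to that point's own coexistence equilibrium — the physically
    meaningful notion of stability here, and far more reliable than peak
    statistics under the slow algebraic relaxation of fractional dynamics.
    """

    swept: str
    grid: np.ndarray
    params: ModelParams
    orders: FractionalOrders
    ic: tuple[float, float, float] = (0.4, 0.5, 0.5)
    settings: SolverSettings = SolverSettings(h=0.01, t_end=300.0)
    transient_fraction: float = 0.6
    variable: str = "x"
    lyapunov: str = "auto"
    lyap_settings: LyapunovSettings = LyapunovSettings()
    thresholds: RegimeThresholds = RegimeThresholds()
    track_equilibrium: bool = True
    conv_tol: float = 1e-2
    conv_floor: float = 1e-3

    def __post_init__(self) -> None:
        if self.swept not in {"q", "q1", "q2", "q3", "a", "b", "c"}:
            raise ValueError(f"unknown sweep parameter {self.swept!r}")
        g = np.asarray(self.grid, dtype=float)
        if g.ndim != 1 or g.size < 1 or np.any(np.diff(g) <= 0):
            raise ValueError("grid must be a strictly increasing 1-D array")
        object.__setattr__(self, "grid", g)
        if self.lyapunov not in {"never", "auto", "always"}:
            raise ValueError(f"lyapunov must be never/auto/always, got {self.lyapunov!r}")

    def point_inputs(self, value: float) -> tuple[ModelParams, FractionalOrders]:
        """Parameters and orders with the swept quantity set to ``value``."""
        if self.swept in {"a", "b", "c"}:
            return self.params.replace(**{self.swept: value}), self.orders
        if self.swept == "q":
            return self.params, FractionalOrders.commensurate_order(value)
        return self.params, self.orders.replace(**{self.swept: value})


@dataclass
class ScanPoint:
    value: float
    regime: str
    extrema: Optional[np.ndarray] = None
    lle: Optional[float] = None
    final_state: Optional[np.ndarray] = None
    error: Optional[str] = None


@dataclass
class ScanResult:
    """Per-grid-point regimes, extrema and (optional) Lyapunov exponents."""

    spec: ScanSpec
    points: list[ScanPoint]

    def regimes(self) -> list[str]:
        return [p.regime for p in self.points]

    def to_dataframe(self):
        """Tidy frame: one row per (grid point, peak); peakless points keep NaN."""
        import pandas as pd

        rows = []
        for p in self.points:
            peaks = p.extrema if p.extrema is not None and p.extrema.size else [np.nan]
            for pk in np.atleast_1d(peaks):
                rows.append(
                    {
                        self.spec.swept: p.value,
                        "peak": pk,
                        "lle": np.nan if p.lle is None else p.lle,
                        "regime": p.regime,
                    }
                )
        return pd.DataFrame(rows)

    def summary(self) -> list[dict]:
        return [
            {
                self.spec.swept: float(p.value),
                "regime": p.regime,
                "n_peaks": 0 if p.extrema is None else int(p.extrema.size),
                "lle": None if p.lle is None else float(p.lle),
                "error": p.error,
            }
            for p in self.points
        ]

    def write(self, csv_path, json_path=None) -> None:
        self.to_dataframe().to_csv(csv_path, index=False)
        if json_path is not None:
            Path(json_path).write_text(json.dumps(self.summary(), indent=2) + "\n")


def _scan_one(spec: ScanSpec, value: float) -> ScanPoint:
    params, orders = spec.point_inputs(value)
    try:
        traj = integrate(params, orders, spec.ic, spec.settings)
    except DivergenceError as exc:
        return ScanPoint(value, "diverged", error=str(exc))
    if spec.track_equilibrium:
        from .equilibria import find_coexistence_equilibrium

        eq = find_coexistence_equilibrium(params)
        if eq.converged and converges_to(traj, eq.coords, spec.conv_tol, spec.conv_floor):
            peaks = extrema_series(traj, spec.variable, spec.transient_fraction)
            return ScanPoint(value, "stable", extrema=peaks,
                             final_state=traj.final_state.copy())
    series = traj.component(spec.variable)
    start = int(math.floor(spec.transient_fraction * series.size))
    tail = series[start:]
    peaks = extrema_series(traj, spec.variable, spec.transient_fraction)

    lle = None
    need_lle = spec.lyapunov == "always"
    if spec.lyapunov == "auto" and peaks.size:
        provisional = classify_regime(peaks, None, tail, spec.thresholds)
        need_lle = provisional == "periodic-or-chaotic"
    if need_lle:
        try:
            lle = largest_lyapunov(
                params, orders, spec.ic, spec.settings, spec.lyap_settings
            ).lle
        except DivergenceError as exc:
            return ScanPoint(value, "diverged", extrema=peaks, error=str(exc))
    regime = classify_regime(peaks, lle, tail, spec.thresholds)
    return ScanPoint(value, regime, extrema=peaks, lle=lle,
                     final_state=traj.final_state.copy())


def bifurcation_scan(spec: ScanSpec) -> ScanResult:
    """Sweep ``spec.grid``, one integration (plus optional LLE) per point.

    Points are mutually independent — the result does not depend on
    evaluation order — and per-point failures are recorded in the row rather
    than aborting the scan.
    """
    points = []
    for v in spec.grid:
        try:
            points.append(_scan_one(spec, float(v)))
        except Exception as exc:  # pragma: no cover - defensive per-row guard
            points.append(ScanPoint(float(v), "error", error=repr(exc)))
    return ScanResult(spec, points)
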