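"""Caputo fractional Adams--Bashforth--Moulton (ABM) predictor--corrector.

Implements the classic PECE scheme for systems of Caputo fractional
differential equations ``D^{q_i} u_i = f_i(u)`` with per-component orders
``q_i`` in ``(0, 1]`` on a uniform grid ``t_n = n h``:

predictor (fractional rectangle rule)::

    u^P_{n+1,i} = u_{0,i} + 1/Gamma(q_i) * sum_{j=0..n} omega_{j,n+1} f_i(u_j)
    omega_{j,n+1} = (h^q / q) * ((n-j+1)^q - (n-j)^q)

corrector (fractional trapezoid rule, one pass)::

    u_{n+1,i} = u_{0,i} + h^q/Gamma(q+2) * ( f_i(u^P_{n+1})
                + sum_{j=0..n} eta_{j,n+1} f_i(u_j) )
    eta_{0,n+1}   = n^{q+1} - (n-q)(n+1)^q
    eta_{j,n+1}   = (n-j+2)^{q+1} + (n-j)^{q+1} - 2(n-j+1)^{q+1},  1<=j<=n
    eta_{n+1,n+1} = 1

At ``q = 1`` the weights collapse exactly to the rectangle / trapezoid rules
and the scheme is the ordinary one-step Adams--Bashforth--Moulton method.
The history convolutions make every step cost O(n), the whole run O(N^2);
an optional truncated-memory window trades accuracy for speed on long scans.

The incommensurate case shares one time grid; each component keeps its own
weight tables keyed by its order.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional

import numpy as np

from .model import ModelParams, vector_field

__all__ = [
    "FractionalOrders",
    "SolverSettings",
    "Trajectory",
    "DivergenceError",
    "corrector_weights",
    "predictor_weights",
    "CaputoABM",
    "integrate_system",
    "integrate",
    "integrate_integer_reference",
]

#: states whose max-norm exceeds this are treated as numerically divergent
DIVERGENCE_THRESHOLD = 1.0e6


def _check_order(q: float) -> float:
    q = float(q)
    if not (0.0 < q <= 1.0) or not math.isfinite(q):
        raise ValueError(f"fractional order must lie in (0, 1], got {q!r}")
    return q


@dataclass(frozen=True)
class FractionalOrders:
    """Caputo derivative orders of the x, y and z equations, each in (0, 1]."""

    q1: float
    q2: float
    q3: float

    def __post_init__(self) -> None:
        for name in ("q1", "q2", "q3"):
            _check_order(getattr(self, name))

    @classmethod
    def commensurate_order(cls, q: float) -> "FractionalOrders":
        return cls(q, q, q)

    @property
    def commensurate(self) -> bool:
        return self.q1 == self.q2 == self.q3

    def as_array(self) -> np.ndarray:
        return np.array([self.q1, self.q2, self.q3], dtype=float)

    def cycled(self) -> "FractionalOrders":
        return FractionalOrders(self.q2, self.q3, self.q1)

    def replace(self, **kw: float) -> "FractionalOrders":
        d = {"q1": self.q1, "q2": self.q2, "q3": self.q3}
        d.update(kw)
        return FractionalOrders(**d)


INTEGER_ORDERS = FractionalOrders(1.0, 1.0, 1.0)


@dataclass(frozen=True)
class SolverSettings:
    """Uniform-grid integration settings.

    ``memory=None`` keeps the full O(N^2) history (the scheme as defined);
    ``memory=L`` truncates both convolutions to the most recent ``L`` steps
    (short-memory principle) -- an approximation, clearly labelled as such,
    for long parameter sweeps.
    """

    h: float = 0.01
    t_end: float = 500.0
    memory: Optional[int] = None

    def __post_init__(self) -> None:
        if not (self.h > 0) or not math.isfinite(self.h):
            raise ValueError(f"step size h must be positive, got {self.h!r}")
        if not (self.t_end > 0) or not math.isfinite(self.t_end):
            raise ValueError(f"t_end must be positive, got {self.t_end!r}")
        n = self.t_end / self.h
        if abs(n - round(n)) > 1e-8 * max(1.0, n):
            raise ValueError(
                f"t_end/h = {n} is not an integer number of steps "
                f"(h={self.h}, t_end={self.t_end})"
            )
        if round(n) < 1:
            raise ValueError("need at least one step")
        if self.memory is not None and self.memory < 1:
            raise ValueError(f"memory window must be >= 1 steps, got {self.memory}")

    @property
    def n_steps(self) -> int:
        return int(round(self.t_end / self.h))

    def to_dict(self) -> dict:
        return {"h": self.h, "t_end": self.t_end, "memory": self.memory}


class DivergenceError(RuntimeError):
    """Raised when the integration produces a non-finite or runaway state.

    Attributes
    ----------
    step : int
        Index of the first failing step.
    times, states : ndarray
        The valid part of the trajectory computed before the failure.
    """

    def __init__(self, step: int, times: np.ndarray, states: np.ndarray):
        super().__init__(f"trajectory diverged at step {step} (t = {times[-1]:g})")
        self.step = step
        self.times = times
        self.states = states


def corrector_weights(q: float, n: int) -> np.ndarray:
    """Corrector (fractional trapezoid) weights eta_{j,n+1}, j = 0..n+1.

    With the prefactor ``h^q / Gamma(q+2)`` these integrate the Caputo kernel
    against a piecewise-linear interpolant of f exactly; at ``q = 1`` they
    reduce to the trapezoid pattern ``(1, 2, ..., 2, 1)``.
    """
    q = _check_order(q)
    if n < 0:
        raise ValueError(f"step index n must be >= 0, got {n}")
    w = np.empty(n + 2)
    w[0] = n ** (q + 1.0) - (n - q) * (n + 1.0) ** q
    if n >= 1:
        k = np.arange(n, dtype=float)  # ages n-j for j = n..1
        ages = (k + 2.0) ** (q + 1.0) + k ** (q + 1.0) - 2.0 * (k + 1.0) ** (q + 1.0)
        w[1 : n + 1] = ages[::-1]
    w[n + 1] = 1.0
    return w


def predictor_weights(q: float, h: float, n: int) -> np.ndarray:
    """Predictor (fractional rectangle) weights omega_{j,n+1}, j = 0..n.

    ``omega_{j,n+1} = (h^q/q) * ((n-j+1)^q - (n-j)^q)``; the sum telescopes to
    ``(h^q/q)(n+1)^q``.  At ``q = 1`` every weight equals ``h``.
    """
    q = _check_order(q)
    if h <= 0:
        raise ValueError(f"step size h must be positive, got {h!r}")
    if n < 0:
        raise ValueError(f"step index n must be >= 0, got {n}")
    k = np.arange(n + 1, dtype=float)  # ages n-j for j = n..0
    b = (k + 1.0) ** q - k ** q
    return (h ** q / q) * b[::-1]


class CaputoABM:
    """Stepping engine for the fractional ABM scheme on a generic system.

    Holds the state history and, reversed, the right-hand-side history (row
    ``N - j`` stores ``f(u_j)``) so that every convolution is a contiguous
    dot product.  :func:`integrate_system` drives it to completion; the
    Lyapunov machinery in :mod:`fractumor.chaos` steps two engines in
    lockstep and rescales their history difference at renormalization times.
    """

    def __init__(
        self,
        rhs: Callable[[np.ndarray], np.ndarray],
        orders: np.ndarray,
        ic: np.ndarray,
        h: float,
        n_steps: int,
        memory: Optional[int] = None,
    ):
        self.rhs = rhs
        self.q = np.asarray(orders, dtype=float)
        self.dim = self.q.size
        self.h = float(h)
        self.N = int(n_steps)
        self.memory = memory
        ic = np.asarray(ic, dtype=float)
        if ic.shape != (self.dim,) or not np.all(np.isfinite(ic)):
            raise ValueError(f"initial condition must be a finite {self.dim}-vector")

        k = np.arange(self.N + 1, dtype=float)[:, None]
        qr = self.q[None, :]
        # per-component weight tables indexed by age k = n - j
        self._B = (k + 1.0) ** qr - k ** qr                       # (N+1, dim)
        self._A = (
            (k + 2.0) ** (qr + 1.0) + k ** (qr + 1.0) - 2.0 * (k + 1.0) ** (qr + 1.0)
        )
        g = np.array([math.gamma(qi + 2.0) for qi in self.q])
        self._cf = self.h ** self.q / g                           # corrector prefactor
        self._pf = self.h ** self.q / np.array(
            [math.gamma(qi + 1.0) for qi in self.q]
        )                                                         # (h^q/q)/Gamma(q)

        self.states = np.empty((self.N + 1, self.dim))
        self.frev = np.empty((self.N + 1, self.dim))
        self.states[0] = ic
        self.frev[self.N] = rhs(ic)
        self.n = 0  # last completed step index

    def step(self) -> np.ndarray:
        """Advance one step; returns the new state or raises DivergenceError."""
        n, N, q = self.n, self.N, self.q
        j0 = 0 if self.memory is None else max(0, n + 1 - self.memory)
        nh = n - j0 + 1  # history terms j0..n
        hist = self.frev[N - n : N - n + nh]  # rows j = n .. j0, age-ascending

        pred = self.states[0] + self._pf * np.array(
            [np.dot(self._B[:nh, i], hist[:, i]) for i in range(self.dim)]
        )
        fp = self.rhs(pred)

        acc = fp.astype(float).copy()
        j1 = max(1, j0)
        nc = n - j1 + 1
        if nc > 0:
            ch = self.frev[N - n : N - n + nc]  # rows j = n .. j1
            acc += np.array(
                [np.dot(self._A[:nc, i], ch[:, i]) for i in range(self.dim)]
            )
        if j0 == 0:
            eta0 = n ** (q + 1.0) - (n - q) * (n + 1.0) ** q
            acc += eta0 * self.frev[N]
        new = self.states[0] + self._cf * acc

        if not np.all(np.isfinite(new)) or np.max(np.abs(new)) > DIVERGENCE_THRESHOLD:
            t = self.h * np.arange(n + 2)
            self.states[n + 1] = new
            raise DivergenceError(n + 1, t[: n + 1], self.states[: n + 1].copy())
        self.states[n + 1] = new
        self.frev[N - (n + 1)] = self.rhs(new)
        self.n = n + 1
        return new

    def run(self) -> np.ndarray:
        while self.n < self.N:
            self.step()
        return self.states


@dataclass
class Trajectory:
    """Discretized solution on the uniform grid ``t_j = j h``.

    Carries full provenance: the model parameters, the per-equation Caputo
    orders and the solver settings that produced it.
    """

    times: np.ndarray
    states: np.ndarray
    params: Optional[ModelParams] = None
    orders: Optional[FractionalOrders] = None
    settings: Optional[SolverSettings] = None
    method: str = "caputo_abm_pece"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.states = np.asarray(self.states, dtype=float)
        if self.states.shape[0] != self.times.shape[0]:
            raise ValueError("times and states lengths differ")

    @property
    def x(self) -> np.ndarray:
        return self.states[:, 0]

    @property
    def y(self) -> np.ndarray:
        return self.states[:, 1]

    @property
    def z(self) -> np.ndarray:
        return self.states[:, 2]

    @property
    def final_state(self) -> np.ndarray:
        return self.states[-1]

    def component(self, variable: str) -> np.ndarray:
        idx = {"x": 0, "y": 1, "z": 2}
        try:
            return self.states[:, idx[variable]]
        except KeyError:
            raise ValueError(f"variable must be one of x, y, z, got {variable!r}")

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {"t": self.times, "x": self.x, "y": self.y, "z": self.z}
        )

    def write_csv(self, path, sidecar: bool = True) -> None:
        """Write ``t,x,y,z`` CSV (full precision) plus a JSON provenance sidecar."""
        path = Path(path)
        self.to_dataframe().to_csv(path, index=False, float_format="%.17g")
        if sidecar:
            meta = {
                "method": self.method,
                "params": None
                if self.params is None
                else {"a": self.params.a, "b": self.params.b, "c": self.params.c},
                "orders": None
                if self.orders is None
                else {"q1": self.orders.q1, "q2": self.orders.q2, "q3": self.orders.q3},
                "settings": None if self.settings is None else self.settings.to_dict(),
                "n_samples": int(self.times.size),
            }
            path.with_suffix(path.suffix + ".json").write_text(
                json.dumps(meta, indent=2) + "\n"
            )


def integrate_system(
    rhs: Callable[[np.ndarray], np.ndarray],
    orders,
    ic,
    settings: SolverSettings,
) -> tuple[np.ndarray, np.ndarray]:
    """Integrate a generic Caputo system ``D^{q_i} u_i = f_i(u)``.

    Returns ``(times, states)``.  Raises :class:`DivergenceError` (carrying
    the partial trajectory) if the state leaves the finite range.
    """
    orders = np.atleast_1d(np.asarray(orders, dtype=float))
    ic = np.atleast_1d(np.asarray(ic, dtype=float))
    eng = CaputoABM(rhs, orders, ic, settings.h, settings.n_steps, settings.memory)
    states = eng.run()
    times = settings.h * np.arange(settings.n_steps + 1)
    return times, states


def integrate(
    params: ModelParams,
    orders: FractionalOrders,
    ic,
    settings: SolverSettings,
) -> Trajectory:
    """Fractional-order trajectory of the tumor--host--effector model.

    One corrector pass per step (PECE), full memory unless the settings say
    otherwise.  Deterministic: identical inputs give bit-identical output.
    """
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

    times, states = integrate_system(rhs, orders.as_array(), ic, settings)
    return Trajectory(times, states, params, orders, settings)


def integrate_integer_reference(
    params: ModelParams,
    ic,
    settings: SolverSettings,
    rtol: float = 1e-10,
    atol: float = 1e-12,
) -> Trajectory:
    """High-accuracy classical (q = 1) trajectory on the same grid.

    Validation oracle for the ``q -> 1`` limit of the fractional scheme; uses
    an adaptive integrator sampled on the solver grid.
    """
    from scipy.integrate import solve_ivp

    times = settings.h * np.arange(settings.n_steps + 1)
    sol = solve_ivp(
        lambda t, s: vector_field(s, params),
        (0.0, settings.t_end),
        np.asarray(ic, dtype=float),
        method="LSODA",
        t_eval=times,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise DivergenceError(len(sol.t), sol.t, sol.y.T)
    return Trajectory(
        times, sol.y.T, params, INTEGER_ORDERS, settings, method="lsoda_reference"
    )
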