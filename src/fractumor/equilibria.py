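"""Equilibria, Jacobian spectra and Matignon fractional stability.

The model has five equilibria: the extinction state ``E0 = (0,0,0)``, three
closed-form boundary states

    E1 = (0, -1, b/(b-1))        (defined for b != 1)
    E2 = (c/(c-1), 0, -1)        (defined for c != 1)
    E3 = (-1, a/(a-1), 0)        (defined for a != 1)

and an interior coexistence state ``E4`` with all coordinates nonzero, which
has no closed form and is found by damped Newton iteration on the
stationarity system.

For a commensurate Caputo system of order ``q`` an equilibrium is
asymptotically stable iff every Jacobian eigenvalue satisfies
``|arg(lambda)| > q*pi/2`` (Matignon condition).  Its first failure as ``q``
grows defines the chaos-threshold order

    q* = (2/pi) * min_i |arg(lambda_i)|,

a necessary condition for chaos around the equilibrium being ``q > q*``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .model import ModelParams, jacobian, vector_field
from .solver import FractionalOrders

__all__ = [
    "Equilibrium",
    "StabilityReport",
    "closed_form_equilibria",
    "find_coexistence_equilibrium",
    "stability_report",
    "chaos_threshold",
    "write_stability_json",
]


@dataclass(frozen=True)
class Equilibrium:
    coords: np.ndarray
    label: str  # E0..E4
    method: str  # closed_form | root_refined
    residual: float = 0.0
    converged: bool = True

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "coords": [float(v) for v in self.coords],
            "method": self.method,
            "residual": float(self.residual),
            "converged": bool(self.converged),
        }


def closed_form_equilibria(params: ModelParams) -> list[Equilibrium]:
    """The four analytically known equilibria E0--E3.

    A boundary equilibrium whose defining growth rate equals 1 exactly is
    undefined (division by zero) and is omitted with a warning.
    """
    a, b, c = params.a, params.b, params.c
    out = [Equilibrium(np.zeros(3), "E0", "closed_form")]
    defs = [
        ("E1", b, lambda: np.array([0.0, -1.0, b / (b - 1.0)])),
        ("E2", c, lambda: np.array([c / (c - 1.0), 0.0, -1.0])),
        ("E3", a, lambda: np.array([-1.0, a / (a - 1.0), 0.0])),
    ]
    for label, rate, build in defs:
        if rate == 1.0:
            warnings.warn(
                f"{label} is undefined when its growth rate equals 1; omitted",
                stacklevel=2,
            )
            continue
        coords = build()
        res = float(np.max(np.abs(vector_field(coords, params))))
        out.append(Equilibrium(coords, label, "closed_form", residual=res))
    return out


def find_coexistence_equilibrium(
    params: ModelParams,
    guess: Sequence[float] = (0.5, 0.5, 0.5),
    tol: float = 1e-12,
    max_iter: int = 100,
) -> Equilibrium:
    """Interior coexistence equilibrium E4 by damped Newton iteration.

    Uses the analytic Jacobian with backtracking line search on the residual
    max-norm.  The result is flagged non-converged (never silently replaced)
    if the iteration stalls or a coordinate collapses to zero.
    """
    x = np.asarray(guess, dtype=float)
    res = vector_field(x, params)
    for _ in range(max_iter):
        rn = np.max(np.abs(res))
        if rn < tol:
            break
        try:
            delta = np.linalg.solve(jacobian(x, params), -res)
        except np.linalg.LinAlgError:
            return Equilibrium(x, "E4", "root_refined", rn, converged=False)
        lam, ok = 1.0, False
        for _ in range(40):
            trial = x + lam * delta
            tres = vector_field(trial, params)
            if np.max(np.abs(tres)) < rn:
                x, res, ok = trial, tres, True
                break
            lam *= 0.5
        if not ok:
            return Equilibrium(x, "E4", "root_refined",
                               float(np.max(np.abs(res))), converged=False)
    rn = float(np.max(np.abs(res)))
    converged = rn < 1e-10 and bool(np.all(np.abs(x) > 1e-8))
    return Equilibrium(x, "E4", "root_refined", rn, converged=converged)


def chaos_threshold(eigenvalues: Sequence[complex]) -> Optional[float]:
    """Chaos-threshold order ``q* = (2/pi) min |arg(lambda)|``.

    Returns ``None`` for a (numerically) zero eigenvalue, where the argument
    is undefined.  All eigenvalues strictly negative real give the capped
    value 2.0 ("never unstable by this criterion"); a positive real
    eigenvalue gives 0.0 (unstable at every order).  Scale-invariant:
    multiplying all eigenvalues by a positive real leaves q* unchanged.
    """
    lams = np.asarray(eigenvalues, dtype=complex)
    if np.any(np.abs(lams) < 1e-14):
        return None
    qs = (2.0 / np.pi) * np.min(np.abs(np.angle(lams)))
    return float(min(qs, 2.0))


@dataclass(frozen=True)
class StabilityReport:
    """Matignon stability assessment of one equilibrium.

    ``matignon_margins[i] = |arg(lambda_i)| - q_eff*pi/2``; the equilibrium is
    asymptotically stable iff every margin is positive.  For incommensurate
    orders the condition is evaluated at ``q_eff = max(q1, q2, q3)`` — a
    conservative heuristic, flagged as such, since the theorem covers only
    the commensurate case.
    """

    equilibrium: Equilibrium
    eigenvalues: np.ndarray
    orders: FractionalOrders
    matignon_margins: np.ndarray
    stable: bool
    q_star: Optional[float]
    heuristic_incommensurate: bool = False

    def to_dict(self) -> dict:
        return {
            "equilibrium": self.equilibrium.to_dict(),
            "eigenvalues": [
                {"re": float(l.real), "im": float(l.imag)} for l in self.eigenvalues
            ],
            "orders": {"q1": self.orders.q1, "q2": self.orders.q2,
                       "q3": self.orders.q3},
            "matignon_margins": [float(m) for m in self.matignon_margins],
            "stable": bool(self.stable),
            "q_star": None if self.q_star is None else float(self.q_star),
            "heuristic_incommensurate": bool(self.heuristic_incommensurate),
        }


def stability_report(
    eq: Equilibrium,
    params: ModelParams,
    orders: FractionalOrders = FractionalOrders(1.0, 1.0, 1.0),
) -> StabilityReport:
    """Eigenvalues, Matignon margins, stability verdict and q* for ``eq``."""
    lams = np.linalg.eigvals(jacobian(eq.coords, params))
    lams = lams[np.lexsort((lams.imag, lams.real))]
    q_eff = max(orders.q1, orders.q2, orders.q3)
    margins = np.abs(np.angle(lams)) - q_eff * np.pi / 2.0
    return StabilityReport(
        equilibrium=eq,
        eigenvalues=lams,
        orders=orders,
        matignon_margins=margins,
        stable=bool(np.all(margins > 0.0)),
        q_star=chaos_threshold(lams),
        heuristic_incommensurate=not orders.commensurate,
    )


def write_stability_json(
    reports: Sequence[StabilityReport], path, extra: Optional[dict] = None
) -> None:
    payload = {"reports": [r.to_dict() for r in reports]}
    if extra:
        payload.update(extra)
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")
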