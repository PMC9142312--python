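"""Three-species tumor--host--effector competition model.

The state ``(x, y, z)`` collects the (dimensionless) sizes of the tumor-cell,
healthy-host-cell and effector-immune-cell populations in a single tumor-site
compartment.  Each population grows at its own rate (``a``, ``b``, ``c``) while
being inhibited and promoted by the other two in a cyclic pattern:

    dx/dt = a*x*(1 - y)*(1 + z) - x**2 * y
    dy/dt = b*y*(1 - z)*(1 + x) - y**2 * z
    dz/dt = c*z*(1 - x)*(1 + y) - z**2 * x

The system is equivariant under the cyclic relabelling
``(x, y, z) -> (y, z, x)`` combined with ``(a, b, c) -> (b, c, a)``.  In the
fractional-order variant the left-hand sides become Caputo derivatives of
orders ``q1, q2, q3`` in ``(0, 1]`` (see :mod:`fractumor.solver`); the
right-hand side, and hence everything in this module, is unchanged.

No positivity clipping is applied: three of the five equilibria have negative
coordinates and must be reachable by the analysis code, even though negative
populations carry no biological meaning.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ModelParams", "vector_field", "jacobian"]


@dataclass(frozen=True)
class ModelParams:
    """Growth rates of the three cell populations (units 1/time).

    Parameters
    ----------
    a : float
        Growth rate of the tumor-cell population ``x``.
    b : float
        Growth rate of the healthy-host-cell population ``y``.
    c : float
        Growth rate of the effector-immune-cell population ``z``.

    All three must be positive, finite reals.
    """

    a: float
    b: float
    c: float

    def __post_init__(self) -> None:
        for name in ("a", "b", "c"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(
                    f"growth rate {name} must be a positive finite real, got {v!r}"
                )

    def as_array(self) -> np.ndarray:
        return np.array([self.a, self.b, self.c], dtype=float)

    def cycled(self) -> "ModelParams":
        """Parameters for the cyclically relabelled system (a,b,c)->(b,c,a)."""
        return ModelParams(self.b, self.c, self.a)

    def replace(self, **kw: float) -> "ModelParams":
        d = {"a": self.a, "b": self.b, "c": self.c}
        d.update(kw)
        return ModelParams(**d)


def _as_state(state) -> np.ndarray:
    s = np.asarray(state, dtype=float)
    if s.shape != (3,):
        raise ValueError(f"state must have exactly 3 components, got shape {s.shape}")
    if not np.all(np.isfinite(s)):
        raise ValueError(f"state must be finite, got {s}")
    return s


def vector_field(state, params: ModelParams) -> np.ndarray:
    """Population growth rates ``(dx/dt, dy/dt, dz/dt)`` at ``state``.

    Cyclically equivariant: permuting the state ``(x,y,z) -> (y,z,x)``
    together with ``params.cycled()`` permutes the output the same way.
    """
    x, y, z = _as_state(state)
    return np.array(
        [
            params.a * x * (1.0 - y) * (1.0 + z) - x * x * y,
            params.b * y * (1.0 - z) * (1.0 + x) - y * y * z,
            params.c * z * (1.0 - x) * (1.0 + y) - z * z * x,
        ]
    )


def jacobian(state, params: ModelParams) -> np.ndarray:
    """Analytic Jacobian of :func:`vector_field` at ``state``.

    At the origin the matrix is ``diag(a, b, c)``, so the extinction
    equilibrium is unstable for any admissible (positive) growth rates.
    """
    x, y, z = _as_state(state)
    a, b, c = params.a, params.b, params.c
    return np.array(
        [
            [
                a * (1.0 - y) * (1.0 + z) - 2.0 * x * y,
                -a * x * (1.0 + z) - x * x,
                a * x * (1.0 - y),
            ],
            [
                b * y * (1.0 - z),
                b * (1.0 - z) * (1.0 + x) - 2.0 * y * z,
                -b * y * (1.0 + x) - y * y,
            ],
            [
                -c * z * (1.0 + y) - z * z,
                c * z * (1.0 - x),
                c * (1.0 - x) * (1.0 + y) - 2.0 * z * x,
            ],
        ]
    )
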