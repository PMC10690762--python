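"""The NDES map on the 3-simplex: single steps, trajectories, fixed points.

The model advances the abundance triple (pine, fir, broadleaf) of a forest
plot by one survey interval (5 years).  Written as normalized exponential
weights it is

    w1 = 1
    w2 = t1 * exp(t3*y1 + t4*y2)
    w3 = t2 * exp(t5*y1 + t6*y2)
    F(y)_i = w_i / (w1 + w2 + w3)

which is algebraically identical to the three reciprocal expressions of the
published system (see :func:`step_literal`).  Outputs are strictly interior
to the simplex, so trajectories can never leave it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "NDESParameters",
    "FixedPointResult",
    "step",
    "step_literal",
    "trajectory",
    "fixed_point",
    "validate_simplex",
]

#: Abundance triples must sum to 1 within this tolerance to be accepted.
SIMPLEX_TOL = 1e-9


@dataclass(frozen=True)
class NDESParameters:
    """The six parameters (t1..t6) of the difference equation system.

    t1 and t2 are positive multiplicative scales on the fir and broadleaf
    weights relative to pine; t3..t6 are exponents per unit abundance.
    """

    t1: float
    t2: float
    t3: float
    t4: float
    t5: float
    t6: float

    def __post_init__(self) -> None:
        if not (self.t1 > 0 and self.t2 > 0):
            raise ValueError(
                f"t1 and t2 must be positive (weight scales; the literal "
                f"form divides by them); got t1={self.t1}, t2={self.t2}"
            )
        for name in ("t1", "t2", "t3", "t4", "t5", "t6"):
            v = getattr(self, name)
            if not np.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v}")

    @classmethod
    def from_sequence(cls, t: Sequence[float]) -> "NDESParameters":
        t = np.asarray(t, dtype=float)
        if t.shape != (6,):
            raise ValueError(f"expected 6 parameters, got shape {t.shape}")
        return cls(*t)

    def to_array(self) -> np.ndarray:
        return np.array([self.t1, self.t2, self.t3, self.t4, self.t5, self.t6])


@dataclass(frozen=True)
class FixedPointResult:
    """Equilibrium Y* = F(Y*) with convergence diagnostics."""

    y_star: np.ndarray
    iterations: int
    residual: float          # max component of |F(Y*) - Y*|
    starts_agreeing: int     # multi-start runs that reached the same point
    n_starts: int


def validate_simplex(y, tol: float = SIMPLEX_TOL) -> np.ndarray:
    """Check that ``y`` is a valid abundance triple; return it as an array."""
    y = np.asarray(y, dtype=float)
    if y.shape != (3,):
        raise ValueError(f"abundance must be a triple, got shape {y.shape}")
    if np.any(y < -tol) or np.any(y > 1 + tol):
        raise ValueError(f"abundance components must lie in [0, 1]: {y}")
    if abs(y.sum() - 1.0) > tol:
        raise ValueError(f"abundance must sum to 1 (got {y.sum()!r}): {y}")
    return y


def _log_weights(y: np.ndarray, T: NDESParameters) -> np.ndarray:
    return np.array([
        0.0,
        np.log(T.t1) + T.t3 * y[0] + T.t4 * y[1],
        np.log(T.t2) + T.t5 * y[0] + T.t6 * y[1],
    ])


def step(y0, T: NDESParameters) -> np.ndarray:
    """Advance an abundance triple by one survey interval (5 years).

    Computed as a shifted softmax of the log-weights so that extreme
    parameter values (e.g. wild Monte Carlo draws) cannot overflow; the
    shift cancels in the normalization, so this is exactly the published
    system.
    """
    y0 = validate_simplex(y0)
    a = _log_weights(y0, T)
    a -= a.max()
    w = np.exp(a)
    return w / w.sum()


def step_literal(y0, T: NDESParameters) -> np.ndarray:
    """Term-by-term transcription of the three reciprocal expressions.

    Serves as the independent oracle for :func:`step`; the two must agree
    to machine precision for any valid input.  Unlike :func:`step` it has
    no overflow guard, so it is suitable only for moderate parameters.
    """
    y0 = validate_simplex(y0)
    t1, t2, t3, t4, t5, t6 = T.to_array()
    u, v = y0[0], y0[1]
    f1 = 1.0 / (1.0
                + t1 * np.exp(t3 * u + t4 * v)
                + t2 * np.exp(t5 * u + t6 * v))
    f2 = 1.0 / ((1.0 / t1) * np.exp(-t3 * u - t4 * v)
                + 1.0
                + (t2 / t1) * np.exp((t5 - t3) * u + (t6 - t4) * v))
    f3 = 1.0 / ((1.0 / t2) * np.exp(-t5 * u - t6 * v)
                + (t1 / t2) * np.exp((t3 - t5) * u + (t4 - t6) * v)
                + 1.0)
    return np.array([f1, f2, f3])


def trajectory(y0, T: NDESParameters, k: int) -> np.ndarray:
    """Iterate the map ``k`` times; returns a (k+1, 3) array.

    Row 0 is the initial triple; row j is the state 5*j years later.
    """
    if k < 0:
        raise ValueError(f"step count must be >= 0, got {k}")
    y0 = validate_simplex(y0)
    out = np.empty((k + 1, 3))
    out[0] = y0
    for j in range(k):
        out[j + 1] = step(out[j], T)
    return out


def _iterate_to_fixed_point(
    y: np.ndarray,
    T: NDESParameters,
    tol: float,
    max_iter: int,
) -> tuple[np.ndarray, int, float]:
    """Picard iteration Y <- F(Y) with damped fallback on oscillation.

    Damping switches to Y <- (Y + F(Y))/2 if the residual fails to be
    monotone non-increasing over a 100-iteration window; the fixed points
    of the damped map coincide with those of F.
    """
    damped = False
    window_worst = np.inf
    since_check = 0
    prev_res = np.inf
    for it in range(1, max_iter + 1):
        fy = step(y, T)
        res = np.max(np.abs(fy - y))
        if res <= tol:
            return fy, it, res
        if not damped:
            since_check += 1
            if res > prev_res:
                if since_check >= 100 and res > window_worst:
                    damped = True
            window_worst = min(window_worst, res)
            if since_check >= 100:
                since_check = 0
                window_worst = res
        prev_res = res
        y = (y + fy) / 2.0 if damped else fy
    raise RuntimeError(
        f"fixed-point iteration did not converge within {max_iter} "
        f"iterations (last residual {res:.3e})"
    )


def fixed_point(
    T: NDESParameters,
    tol: float = 1e-12,
    n_starts: int = 16,
    max_iter: int = 1_000_000,
    seed: int | None = 0,
) -> FixedPointResult:
    """Solve Y* = F(Y*) by iteration from multiple starting points.

    The equilibrium is asserted (not proven) to be unique and stable for
    fitted parameter values, so uniqueness is verified empirically per
    call: iteration is run from the three simplex vertices, the
    barycenter, and ``n_starts - 4`` seeded random interior points, and
    all limits must agree within ``10 * tol``.

    Raises
    ------
    RuntimeError
        If any start fails to converge, or if distinct limits are found.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")
    # vertices are nudged inward: the map is defined on the closed simplex
    # but interior starts converge faster and match field usage
    eps = 1e-9
    vertex = (1 - 2 * eps) * np.eye(3) + eps
    starts = [vertex[0], vertex[1], vertex[2], np.full(3, 1 / 3)][:n_starts]
    if n_starts > 4:
        rng = np.random.default_rng(seed)
        starts.extend(rng.dirichlet(np.ones(3), size=n_starts - 4))

    limits = []
    total_iters = 0
    final_res = np.inf
    for y in starts:
        y_lim, its, res = _iterate_to_fixed_point(np.asarray(y), T, tol, max_iter)
        limits.append(y_lim)
        total_iters = max(total_iters, its)
        final_res = min(final_res, res)

    ref = limits[0]
    agree = sum(1 for y in limits if np.max(np.abs(y - ref)) <= 10 * tol)
    if agree != len(limits):
        distinct = {tuple(np.round(y, 8)) for y in limits}
        raise RuntimeError(
            f"multi-start fixed-point iteration found {len(distinct)} "
            f"distinct limits: {sorted(distinct)}"
        )
    return FixedPointResult(
        y_star=ref,
        iterations=total_iters,
        residual=final_res,
        starts_agreeing=agree,
        n_starts=len(limits),
    )
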