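"""Fit the NDES parameters to paired plot observations.

The loss is ordinary least squares over all three predicted abundance
components; positivity of t1 and t2 is enforced by optimizing log t1 and
log t2.  Because both observed and predicted triples sum to one, per-plot
residuals sum to zero and carry only two independent components — so the
parameter covariance is built from the first two components only
(Gauss-Newton, sigma^2 * (J'J)^-1, delta-method back to the t scale),
mirroring the rank-2 structure of the limit covariance downstream.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

from .abundance import PairedObservation
from .core import NDESParameters

__all__ = [
    "NDESFit",
    "init_params_logratio",
    "fit_ndes",
    "r_squared",
    "param_covariance",
]

#: Floor applied to latter components in the log-ratio initializer only;
#: the NLS loss keeps observed zeros as-is.
LOGRATIO_FLOOR = 1e-6


@dataclass(frozen=True)
class NDESFit:
    """Fitted parameters with covariance and fit diagnostics."""

    T: NDESParameters
    cov: np.ndarray                 # 6x6, on the t scale
    r2: tuple[float, float, float]  # per group; NaN where observed variance is 0
    n_pairs: int
    objective: float                # residual sum of squares, all 3 components
    converged: bool

    @property
    def standard_errors(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov))

    def to_dict(self) -> dict:
        """JSON-shaped report with fixed field names for downstream tools."""
        return {
            "parameters": dict(zip(
                ("t1", "t2", "t3", "t4", "t5", "t6"), self.T.to_array().tolist()
            )),
            "standard_errors": self.standard_errors.tolist(),
            "covariance": self.cov.tolist(),
            "r_squared": {
                "pine": self.r2[0], "fir": self.r2[1], "broadleaf": self.r2[2],
            },
            "n_pairs": self.n_pairs,
            "objective": self.objective,
            "converged": self.converged,
        }


def _stack(pairs: Sequence[PairedObservation]) -> tuple[np.ndarray, np.ndarray]:
    y0 = np.array([p.y0 for p in pairs])
    y1 = np.array([p.y1 for p in pairs])
    return y0, y1


def _theta_to_params(theta: np.ndarray) -> NDESParameters:
    return NDESParameters(
        np.exp(theta[0]), np.exp(theta[1]), theta[2], theta[3], theta[4], theta[5]
    )


def _predict(theta: np.ndarray, y0: np.ndarray) -> np.ndarray:
    """Vectorized one-step prediction for all plots; (n, 3)."""
    a = np.zeros((y0.shape[0], 3))
    a[:, 1] = theta[0] + theta[2] * y0[:, 0] + theta[3] * y0[:, 1]
    a[:, 2] = theta[1] + theta[4] * y0[:, 0] + theta[5] * y0[:, 1]
    a -= a.max(axis=1, keepdims=True)
    w = np.exp(a)
    return w / w.sum(axis=1, keepdims=True)


def _jacobian(theta: np.ndarray, y0: np.ndarray) -> np.ndarray:
    """d predicted / d theta, shape (n, 3, 6).

    Softmax derivative: dp_i/da_j = p_i (delta_ij - p_j), with
    a2 = theta1 + t3 y1 + t4 y2 and a3 = theta2 + t5 y1 + t6 y2.
    """
    p = _predict(theta, y0)
    n = y0.shape[0]
    da = np.zeros((n, 3, 6))
    da[:, 1, 0] = 1.0
    da[:, 1, 2] = y0[:, 0]
    da[:, 1, 3] = y0[:, 1]
    da[:, 2, 1] = 1.0
    da[:, 2, 4] = y0[:, 0]
    da[:, 2, 5] = y0[:, 1]
    dp_da = p[:, :, None] * (np.eye(3)[None] - p[:, None, :])
    return np.einsum("nij,njk->nik", dp_da, da)


def init_params_logratio(pairs: Sequence[PairedObservation]) -> NDESParameters:
    """Starting values from the exact log-ratio identity of the map.

    The map implies log(y21/y11) = log t1 + t3*y10 + t4*y20 and
    log(y31/y11) = log t2 + t5*y10 + t6*y20, so on noiseless data two
    ordinary linear regressions recover the parameters exactly.  Latter
    components are floored at 1e-6 before taking ratios.
    """
    if len(pairs) < 6:
        raise ValueError(f"need at least 6 pairs to initialize, got {len(pairs)}")
    y0, y1 = _stack(pairs)
    y1 = np.maximum(y1, LOGRATIO_FLOOR)
    X = np.column_stack([np.ones(len(pairs)), y0[:, 0], y0[:, 1]])
    if np.linalg.matrix_rank(X) < 3:
        raise ValueError(
            "rank-deficient design: former abundances do not vary enough "
            "to identify the parameters"
        )
    b_fir, *_ = np.linalg.lstsq(X, np.log(y1[:, 1] / y1[:, 0]), rcond=None)
    b_brd, *_ = np.linalg.lstsq(X, np.log(y1[:, 2] / y1[:, 0]), rcond=None)
    return NDESParameters(
        t1=float(np.exp(b_fir[0])), t2=float(np.exp(b_brd[0])),
        t3=float(b_fir[1]), t4=float(b_fir[2]),
        t5=float(b_brd[1]), t6=float(b_brd[2]),
    )


def r_squared(observed: np.ndarray, predicted: np.ndarray) -> tuple[float, float, float]:
    """Per-group coefficient of determination, 1 - SSE/SST.

    SST is about the observed per-group mean.  A group whose observed
    values do not vary has no defined R^2 and is reported as NaN, never
    silently as 0 or 1.
    """
    observed = np.asarray(observed, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if observed.shape != predicted.shape or observed.ndim != 2 or observed.shape[1] != 3:
        raise ValueError("observed and predicted must both be (n, 3)")
    if observed.shape[0] < 2:
        raise ValueError("need at least 2 observations per group")
    out = []
    for i in range(3):
        col = observed[:, i]
        # identical observed values (ptp == 0) leave SST as pure rounding
        # noise, so R^2 is undefined rather than 0/0-driven garbage
        sst = np.sum((col - col.mean()) ** 2)
        if sst == 0 or np.ptp(col) == 0:
            out.append(float("nan"))
            continue
        sse = np.sum((observed[:, i] - predicted[:, i]) ** 2)
        out.append(float(1.0 - sse / sst))
    return tuple(out)  # type: ignore[return-value]


def param_covariance(
    pairs: Sequence[PairedObservation],
    T: NDESParameters,
    dof_per_plot: int = 2,
) -> np.ndarray:
    """Gauss-Newton covariance of the fitted parameters, on the t scale.

    Only the first two predicted components enter the Jacobian and the
    residual variance (the third is linearly dependent and would make the
    information matrix singular):  sigma^2 = RSS_2 / (dof_per_plot*n - 6),
    cov_theta = sigma^2 (J'J)^-1 on (log t1, log t2, t3..t6), then the
    delta method maps log-scale entries back to t1, t2.
    """
    y0, y1 = _stack(pairs)
    n = len(pairs)
    theta = np.array([np.log(T.t1), np.log(T.t2), T.t3, T.t4, T.t5, T.t6])
    pred = _predict(theta, y0)
    J = _jacobian(theta, y0)[:, :2, :].reshape(2 * n, 6)
    rss2 = float(np.sum((y1[:, :2] - pred[:, :2]) ** 2))
    dof = dof_per_plot * n - 6
    if dof <= 0:
        raise ValueError(f"not enough pairs ({n}) for a covariance estimate")
    jtj = J.T @ J
    try:
        cov_theta = np.linalg.solve(jtj, np.eye(6)) * (rss2 / dof)
    except np.linalg.LinAlgError:
        raise np.linalg.LinAlgError(
            "singular information matrix J'J; the initial abundances are "
            "not varied enough — fit on plots with more diverse composition"
        ) from None
    scale = np.array([T.t1, T.t2, 1.0, 1.0, 1.0, 1.0])
    cov_t = cov_theta * np.outer(scale, scale)
    return (cov_t + cov_t.T) / 2.0


def fit_ndes(
    pairs: Sequence[PairedObservation],
    init: NDESParameters | None = None,
    max_restarts: int = 5,
    seed: int = 0,
) -> NDESFit:
    """Least-squares fit of the six parameters to paired observations.

    Minimizes the squared prediction error over all three abundance
    components; restarts from jittered initial values (10% scale, seeded)
    if the optimizer reports failure.
    """
    if len(pairs) < 6:
        raise ValueError(f"need at least 6 pairs to fit, got {len(pairs)}")
    y0, y1 = _stack(pairs)
    if init is None:
        init = init_params_logratio(pairs)
    theta0 = np.array([np.log(init.t1), np.log(init.t2),
                       init.t3, init.t4, init.t5, init.t6])

    def residuals(theta: np.ndarray) -> np.ndarray:
        return (_predict(theta, y0) - y1).ravel()

    def jac(theta: np.ndarray) -> np.ndarray:
        return _jacobian(theta, y0).reshape(-1, 6)

    rng = np.random.default_rng(seed)
    last_exc: Exception | None = None
    sol = None
    for attempt in range(max_restarts + 1):
        start = theta0 if attempt == 0 else theta0 * (1 + 0.1 * rng.standard_normal(6))
        try:
            res = least_squares(residuals, start, jac=jac, method="lm", xtol=1e-14, ftol=1e-14)
        except Exception as exc:  # numerical failure inside the solver
            last_exc = exc
            continue
        if res.status > 0:
            sol = res
            break
        last_exc = RuntimeError(f"optimizer status {res.status}: {res.message}")
    if sol is None:
        raise RuntimeError(
            f"NDES fit failed after {max_restarts} restarts"
        ) from last_exc

    T_hat = _theta_to_params(sol.x)
    pred = _predict(sol.x, y0)
    grad_norm = float(np.linalg.norm(sol.grad)) if sol.grad is not None else np.inf
    return NDESFit(
        T=T_hat,
        cov=param_covariance(pairs, T_hat),
        r2=r_squared(y1, pred),
        n_pairs=len(pairs),
        objective=float(np.sum((pred - y1) ** 2)),
        converged=bool(sol.status > 0 and grad_norm < 1e-6),
    )
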