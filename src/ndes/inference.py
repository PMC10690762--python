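"""Uncertainty of the abundance limit Y* = F(Y*).

Three pieces:

* a Monte Carlo estimate of the 3x3 limit covariance — one multivariate
  normal parameter draw per plot, each iterated to its limit from that
  plot's latter observed abundance;
* equal-tail confidence intervals for a single limit component from the
  normal distribution truncated to [0, 1] (abundances cannot leave the
  unit interval);
* a Hotelling-style F-test of hypotheses about the limit vector.  The
  three components sum to one, so the limit covariance has rank 2 and the
  test is run on the first two (pine, fir) components only.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import brentq
from scipy.stats import f as f_dist
from scipy.stats import truncnorm

from .core import NDESParameters, _iterate_to_fixed_point, fixed_point
from .estimation import NDESFit

__all__ = [
    "LimitEstimate",
    "TruncatedNormalInterval",
    "FTestResult",
    "mc_limit_covariance",
    "truncnorm_interval",
    "calibrate_sigma_from_interval",
    "limit_f_test",
    "extinction_test_battery",
]


@dataclass(frozen=True)
class LimitEstimate:
    """Point estimate of the limit plus its Monte Carlo covariance."""

    y_star: np.ndarray      # fixed point at the fitted parameters
    sigma_star: np.ndarray  # 3x3 sample covariance of simulated limits
    n: int                  # plot count = number of retained draws
    draws: int
    redraws: int            # invalid draws (t1 or t2 <= 0) that were replaced
    seed: int | None

    def to_dict(self) -> dict:
        return {
            "y_star": self.y_star.tolist(),
            "sigma_star": self.sigma_star.tolist(),
            "n": self.n,
            "draws": self.draws,
            "redraws": self.redraws,
        }


@dataclass(frozen=True)
class TruncatedNormalInterval:
    point: float
    sigma: float
    level: float
    lower: float
    upper: float


@dataclass(frozen=True)
class FTestResult:
    F: float
    df1: int
    df2: int
    p_value: float
    hypothesis: tuple[float, float]

    def to_dict(self) -> dict:
        return {
            "F": self.F, "df1": self.df1, "df2": self.df2,
            # 6 decimals to match conventional inventory reporting
            "p_value": float(f"{self.p_value:.6f}"),
            "hypothesis_pine_fir": list(self.hypothesis),
        }


def mc_limit_covariance(
    fit: NDESFit,
    initial_abundances: Sequence[np.ndarray],
    seed: int | None = 0,
    draws_per_plot: int = 1,
    max_redraws: int = 100,
    tol: float = 1e-10,
    max_iter: int = 200_000,
) -> LimitEstimate:
    """Monte Carlo covariance of the limit under parameter uncertainty.

    For each plot, draw a parameter vector T0 ~ MVN(T, cov) (Cholesky,
    seeded) and iterate the map with T0 from that plot's latter observed
    abundance until it converges; the sample covariance of the simulated
    limits estimates D(Y*).  Because the limit is a global attractor, the
    per-plot initial values do not move the limit — the spread comes
    entirely from the parameter draws.

    Draws with t1 <= 0 or t2 <= 0 (where the map is undefined), or whose
    iteration fails to converge, are redrawn up to ``max_redraws`` times;
    the total redraw count is reported.  If more than 10% of draws need
    redraws the parameter covariance is too wide for the positivity
    constraint and an error is raised.
    """
    inits = [np.asarray(y, dtype=float) for y in initial_abundances]
    if not inits:
        raise ValueError("need at least one per-plot initial abundance")
    n = len(inits) * draws_per_plot
    mean = fit.T.to_array()
    cov = np.asarray(fit.cov, dtype=float)
    if cov.shape != (6, 6):
        raise ValueError(f"fit covariance must be 6x6, got {cov.shape}")
    # Cholesky of a PSD (possibly singular) covariance via jitter fallback
    if np.allclose(cov, 0):
        chol = np.zeros((6, 6))
    else:
        try:
            chol = np.linalg.cholesky(cov)
        except np.linalg.LinAlgError:
            w, V = np.linalg.eigh(cov)
            chol = V @ np.diag(np.sqrt(np.clip(w, 0, None)))

    rng = np.random.default_rng(seed)
    limits = np.empty((n, 3))
    redraws = 0
    k = 0
    for y_init in inits:
        for _ in range(draws_per_plot):
            for attempt in range(max_redraws + 1):
                T0 = mean + chol @ rng.standard_normal(6)
                if T0[0] <= 0 or T0[1] <= 0:
                    redraws += 1
                    continue
                try:
                    y_lim, _, _ = _iterate_to_fixed_point(
                        y_init.copy(), NDESParameters.from_sequence(T0), tol, max_iter
                    )
                except RuntimeError:
                    redraws += 1
                    continue
                limits[k] = y_lim
                break
            else:
                raise RuntimeError(
                    f"draw for plot {k} still invalid after {max_redraws} redraws"
                )
            k += 1
    if redraws > 0.10 * n:
        raise RuntimeError(
            f"{redraws} of {n} parameter draws were invalid (>10%); the "
            "parameter covariance is too wide for the t1,t2 > 0 constraint"
        )

    sigma_star = np.cov(limits, rowvar=False, ddof=1) if n > 1 else np.zeros((3, 3))
    y_star = fixed_point(fit.T, tol=tol).y_star
    return LimitEstimate(
        y_star=y_star, sigma_star=sigma_star,
        n=len(inits), draws=n, redraws=redraws, seed=seed,
    )


def _trunc(point: float, sigma: float):
    a, b = (0.0 - point) / sigma, (1.0 - point) / sigma
    return truncnorm(a, b, loc=point, scale=sigma)


def truncnorm_interval(
    point: float, sigma: float, level: float = 0.95
) -> TruncatedNormalInterval:
    """Equal-tail interval under the normal truncated to [0, 1].

    Tail mass (1-level)/2 on each side; quantiles from the truncated CDF.
    """
    if sigma <= 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    if not 0.0 <= point <= 1.0:
        raise ValueError(f"point estimate must lie in [0, 1], got {point}")
    if not 0.0 < level < 1.0:
        raise ValueError(f"confidence level must lie in (0, 1), got {level}")
    dist = _trunc(point, sigma)
    q = (1.0 - level) / 2.0
    return TruncatedNormalInterval(
        point=point, sigma=sigma, level=level,
        lower=float(dist.ppf(q)), upper=float(dist.ppf(1.0 - q)),
    )


def calibrate_sigma_from_interval(
    point: float, lower: float, upper: float, level: float = 0.95
) -> float:
    """Back out sigma from a published equal-tail truncated-normal interval.

    One sigma cannot in general match both endpoints exactly (truncation
    skews the interval), so sigma is chosen to match the interval WIDTH,
    which is strictly increasing in sigma and root-found to 1e-14.
    """
    width = upper - lower
    if width <= 0:
        raise ValueError("interval must have positive width")

    def gap(s: float) -> float:
        iv = truncnorm_interval(point, s, level)
        return (iv.upper - iv.lower) - width

    return float(brentq(gap, 1e-12, 10.0, xtol=1e-14))


def limit_f_test(
    y_star_2: Sequence[float],
    y0_2: Sequence[float],
    sigma_2: np.ndarray,
    n: int,
) -> FTestResult:
    """Hotelling-style F-test of the first two limit components.

    F = (n-p)/((n-1)p) * d' S^-1 d with d the (pine, fir) difference,
    S the top-left 2x2 block of the limit covariance, p = 2; the p-value
    is the upper tail of F(p, n-p).
    """
    p = 2
    if n <= p:
        raise ValueError(f"need n > {p} plots, got {n}")
    d = np.asarray(y_star_2, dtype=float) - np.asarray(y0_2, dtype=float)
    S = np.asarray(sigma_2, dtype=float)
    if S.shape != (2, 2):
        raise ValueError(f"sigma_2 must be 2x2, got {S.shape}")
    try:
        quad = float(d @ np.linalg.solve(S, d))
    except np.linalg.LinAlgError:
        raise np.linalg.LinAlgError(
            "singular 2x2 limit covariance; the F-test is undefined"
        ) from None
    F = (n - p) / ((n - 1) * p) * quad
    return FTestResult(
        F=float(F), df1=p, df2=n - p,
        p_value=float(f_dist.sf(F, p, n - p)),
        hypothesis=(float(y0_2[0]), float(y0_2[1])),
    )


def extinction_test_battery(limit: LimitEstimate) -> dict[str, FTestResult]:
    """The three extinction hypotheses on the limit vector.

    pine_extinct:  pine -> 0, fir unchanged; fir_extinct: fir -> 0, pine
    unchanged; both_extinct: both -> 0 (broadleaf -> 1).
    """
    y1, y2 = limit.y_star[0], limit.y_star[1]
    S2 = limit.sigma_star[:2, :2]
    n = limit.n
    return {
        "pine_extinct": limit_f_test((y1, y2), (0.0, y2), S2, n),
        "fir_extinct": limit_f_test((y1, y2), (y1, 0.0), S2, n),
        "both_extinct": limit_f_test((y1, y2), (0.0, 0.0), S2, n),
    }
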