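"""Long-term projection of province-wide species composition.

Each plot's trajectory is iterated individually under the fitted map and
the province-wide series is the per-step average over plots
(iterate-then-average — the map is nonlinear, so averaging first would
give a different, wrong, series).  One step is one 5-year survey
interval; the conventional default horizon is the year 2119.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .core import NDESParameters, trajectory
from .estimation import NDESFit

__all__ = ["ProjectionSeries", "predict_average_trajectory", "relative_error"]

STEP_YEARS = 5
DEFAULT_HORIZON_YEAR = 2119


@dataclass(frozen=True)
class ProjectionSeries:
    """Mean projected abundance per 5-year step, optionally with the
    per-plot trajectories retained."""

    start_year: int
    horizon_year: int
    mean_abundance: np.ndarray          # (n_steps+1, 3)
    per_plot: np.ndarray | None = None  # (n_plots, n_steps+1, 3)

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.start_year, self.horizon_year + 1, STEP_YEARS)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.mean_abundance, columns=["pine", "fir", "broadleaf"]
        ).assign(year=self.years)[["year", "pine", "fir", "broadleaf"]]


def predict_average_trajectory(
    fit: NDESFit | NDESParameters,
    initial: Sequence[np.ndarray],
    start_year: int,
    horizon_year: int = DEFAULT_HORIZON_YEAR,
    keep_per_plot: bool = False,
) -> ProjectionSeries:
    """Project every plot forward and average per step.

    ``initial`` holds one abundance triple per plot (the latter observed
    abundance of the modelling period); ``horizon_year - start_year``
    must be a multiple of the 5-year step.
    """
    T = fit.T if isinstance(fit, NDESFit) else fit
    if not initial:
        raise ValueError("need at least one initial plot abundance")
    span = horizon_year - start_year
    if span < 0 or span % STEP_YEARS:
        raise ValueError(
            f"horizon {horizon_year} must be start_year plus a multiple of "
            f"{STEP_YEARS} years"
        )
    k = span // STEP_YEARS
    per_plot = np.stack([trajectory(y, T, k) for y in initial])
    return ProjectionSeries(
        start_year=start_year,
        horizon_year=horizon_year,
        mean_abundance=per_plot.mean(axis=0),
        per_plot=per_plot if keep_per_plot else None,
    )


def relative_error(predicted, actual) -> np.ndarray:
    """Signed relative error in percent, 100*(pred - actual)/actual.

    Positive means the prediction overshoots.  Components with a zero
    actual value are undefined and returned as NaN, never as 0.
    """
    predicted = np.asarray(predicted, dtype=float)
    actual = np.asarray(actual, dtype=float)
    if predicted.shape != actual.shape:
        raise ValueError("predicted and actual must have the same shape")
    out = np.full(actual.shape, np.nan)
    ok = actual != 0
    out[ok] = 100.0 * (predicted[ok] - actual[ok]) / actual[ok]
    return out
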