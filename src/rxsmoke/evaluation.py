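"""Model-vs-observation performance statistics.

Community-standard definitions over paired model (M) and observed (O)
values:

    NMB = 100 * sum(M - O) / sum(O)
    NME = 100 * sum|M - O| / sum(O)
    R   = sample Pearson correlation

plus an ordinary least-squares regression of model on observation with
t-based 95% confidence intervals on slope and intercept.  Pairs with a
missing member are dropped listwise (count logged).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = ["PairedSeries", "nmb", "nme", "pearson_r", "regression_line", "RegressionResult"]


@dataclass(frozen=True)
class PairedSeries:
    """Aligned model/observation vectors with optional labels."""

    model: np.ndarray
    obs: np.ndarray
    labels: tuple = ()

    def __post_init__(self) -> None:
        m = np.asarray(self.model, dtype=float)
        o = np.asarray(self.obs, dtype=float)
        if m.shape != o.shape or m.ndim != 1:
            raise ValueError("model and obs must be equal-length 1D vectors")
        keep = np.isfinite(m) & np.isfinite(o)
        dropped = int((~keep).sum())
        if dropped:
            logger.info("dropped %d pairs with missing values", dropped)
            m, o = m[keep], o[keep]
        if len(m) < 2:
            raise ValueError("need at least 2 complete pairs")
        object.__setattr__(self, "model", m)
        object.__setattr__(self, "obs", o)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, model_col: str = "model", obs_col: str = "obs"):
        return cls(frame[model_col].to_numpy(), frame[obs_col].to_numpy())

    def __len__(self) -> int:
        return len(self.model)


def nmb(pairs: PairedSeries) -> float:
    """Normalized mean bias in percent."""
    denom = pairs.obs.sum()
    if denom == 0:
        raise ValueError("NMB undefined: observations sum to zero")
    return float(100.0 * (pairs.model - pairs.obs).sum() / denom)


def nme(pairs: PairedSeries) -> float:
    """Normalized mean error in percent."""
    denom = pairs.obs.sum()
    if denom == 0:
        raise ValueError("NME undefined: observations sum to zero")
    return float(100.0 * np.abs(pairs.model - pairs.obs).sum() / denom)


def pearson_r(pairs: PairedSeries) -> float:
    """Sample Pearson correlation coefficient."""
    if np.std(pairs.model) == 0 or np.std(pairs.obs) == 0:
        raise ValueError("Pearson R undefined for a zero-variance vector")
    return float(stats.pearsonr(pairs.model, pairs.obs).statistic)


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    slope_ci: tuple
    intercept_ci: tuple
    n: int
    ci_defined: bool


def regression_line(pairs: PairedSeries, alpha: float = 0.05) -> RegressionResult:
    """OLS of model on observation with standard-error-based CIs.

    With n = 2 the fit is exact and the CI is flagged undefined rather
    than reported as zero-width.
    """
    res = stats.linregress(pairs.obs, pairs.model)
    n = len(pairs)
    if n <= 2:
        return RegressionResult(
            float(res.slope), float(res.intercept), float(res.rvalue**2),
            (np.nan, np.nan), (np.nan, np.nan), n, ci_defined=False,
        )
    tcrit = stats.t.ppf(1 - alpha / 2, df=n - 2)
    return RegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        slope_ci=(float(res.slope - tcrit * res.stderr), float(res.slope + tcrit * res.stderr)),
        intercept_ci=(
            float(res.intercept - tcrit * res.intercept_stderr),
            float(res.intercept + tcrit * res.intercept_stderr),
        ),
        n=n,
        ci_defined=True,
    )
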