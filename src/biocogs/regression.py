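"""Linear sensitivity meta-model of CoG/g.

An ordinary-least-squares fit of CoG/g on the three sampled inputs (titer,
target output, material-cost deviation) summarizes the Monte Carlo cloud in
four numbers per scenario.  The meta-model is deliberately first-order: its
point is not prediction but screening — which inputs still move the cost at
all (two-sided t-tests against zero, alpha-level screen) and which dominates
once each coefficient is weighted by the span its input actually varies over.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import ConfigurationError, DegenerateDesignError
from .uncertainty import MCResult

__all__ = [
    "LinearFit",
    "ShiftReport",
    "fit_ols",
    "significance_screen",
    "strategy_shift_report",
]

DEFAULT_PREDICTORS = ("titer", "target_output", "material_cost_deviation")


@dataclass(frozen=True)
class LinearFit:
    terms: tuple[str, ...]  # "intercept" first, then predictors
    coefficients: Mapping[str, float]
    standard_errors: Mapping[str, float]
    t_statistics: Mapping[str, float]
    p_values: Mapping[str, float]
    residual_variance: float
    n: int

    def __post_init__(self):
        for name in ("coefficients", "standard_errors", "t_statistics", "p_values"):
            object.__setattr__(self, name, dict(getattr(self, name)))
        if not self.n > len(self.terms):
            raise ConfigurationError("need n > number of coefficients")

    @property
    def df_resid(self) -> int:
        return self.n - len(self.terms)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "coefficient": self.coefficients,
                "standard_error": self.standard_errors,
                "t": self.t_statistics,
                "p_value": self.p_values,
            }
        )


def fit_ols(
    samples: "MCResult | pd.DataFrame",
    *,
    response: str = "cog_per_g",
    predictors: Sequence[str] = DEFAULT_PREDICTORS,
) -> LinearFit:
    """OLS of ``response`` on ``predictors`` with an intercept.

    Standard errors use the unbiased residual variance; p-values are
    two-sided from the t distribution with n - p degrees of freedom.
    A constant predictor column (e.g. from a degenerate sampling
    distribution) raises :class:`DegenerateDesignError` naming the column.
    """
    data = samples.samples if isinstance(samples, MCResult) else samples
    if len(data) < 5:
        raise ConfigurationError(f"need at least 5 samples, got {len(data)}")
    missing = [c for c in (response, *predictors) if c not in data.columns]
    if missing:
        raise ConfigurationError(f"samples lack column(s): {missing}")

    X = data.loc[:, list(predictors)].to_numpy(dtype=float)
    for j, name in enumerate(predictors):
        if np.ptp(X[:, j]) == 0.0:
            raise DegenerateDesignError(name)
    y = data[response].to_numpy(dtype=float)

    res = sm.OLS(y, sm.add_constant(X, has_constant="add")).fit()
    terms = ("intercept", *predictors)
    return LinearFit(
        terms=terms,
        coefficients=dict(zip(terms, map(float, res.params))),
        standard_errors=dict(zip(terms, map(float, res.bse))),
        t_statistics=dict(zip(terms, map(float, res.tvalues))),
        p_values=dict(zip(terms, map(float, res.pvalues))),
        residual_variance=float(res.mse_resid),
        n=int(res.nobs),
    )


def significance_screen(fit: LinearFit, alpha: float) -> dict[str, bool]:
    """Per-term indicator: significant iff p < alpha."""
    if not 0 < alpha < 1:
        raise ConfigurationError(f"alpha must be in (0, 1), got {alpha}")
    return {term: fit.p_values[term] < alpha for term in fit.terms}


def _ranking(fit: LinearFit, spans: Mapping[str, float]) -> list[str]:
    drivers = [t for t in fit.terms if t != "intercept"]
    missing = [t for t in drivers if t not in spans]
    if missing:
        raise ConfigurationError(f"no span provided for driver(s): {missing}")
    return sorted(drivers, key=lambda t: (-abs(fit.coefficients[t] * spans[t]), t))


@dataclass(frozen=True)
class ShiftReport:
    """Driver rankings before and after an optimization, and what moved."""

    ranking_before: tuple[str, ...]
    ranking_after: tuple[str, ...]
    rank_changes: Mapping[str, tuple[int, int]]  # term -> (rank before, after), 1-based
    lost_significance: tuple[str, ...]
    gained_significance: tuple[str, ...]
    alpha: float

    @property
    def shifted(self) -> bool:
        return self.ranking_before != self.ranking_after or bool(
            self.lost_significance or self.gained_significance
        )


def strategy_shift_report(
    before: LinearFit,
    after: LinearFit,
    spans: Mapping[str, float],
    *,
    spans_after: Mapping[str, float] | None = None,
    alpha: float = 0.01,
) -> ShiftReport:
    """Rank drivers by |coefficient x parameter span| in each scenario and
    report rank changes and terms whose significance flipped at ``alpha``.

    ``spans`` gives each driver the width of the range it varies over, so
    coefficients in different units become comparable dollar impacts.  When
    the optimization changes a parameter's range (the titer range widens
    after optimization), pass the after-scenario widths as ``spans_after``.
    """
    if before.terms != after.terms:
        raise ConfigurationError("fits must share one parameterization")
    rb = _ranking(before, spans)
    ra = _ranking(after, spans if spans_after is None else spans_after)
    sig_b = significance_screen(before, alpha)
    sig_a = significance_screen(after, alpha)
    drivers = rb  # same member set as ra
    changes = {
        t: (rb.index(t) + 1, ra.index(t) + 1) for t in drivers
    }
    lost = tuple(t for t in drivers if sig_b[t] and not sig_a[t])
    gained = tuple(t for t in drivers if not sig_b[t] and sig_a[t])
    return ShiftReport(
        ranking_before=tuple(rb),
        ranking_after=tuple(ra),
        rank_changes=dict(changes),
        lost_significance=lost,
        gained_significance=gained,
        alpha=alpha,
    )
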