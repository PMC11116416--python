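"""Univariate OLS of leachate toxicity against pellet weathering metrics.

Each regression relates one weathering predictor (the weathering
percentage, the fraction of pellets scoring >= 2, or the sample %YI) to
the mean larval growth in undiluted leachate expressed as % of control
(higher = less toxic).  Significance bands follow conventional annotation
levels (p < 0.1, p < 0.05, p < 0.01).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["RegressionResult", "fit_weathering_toxicity", "regression_table",
           "plot_regression"]


@dataclass(frozen=True)
class RegressionResult:
    predictor_name: str
    n: int
    slope: float
    intercept: float
    r_squared: float
    p_slope: float
    significance_band: str


def _band(p: float) -> str:
    if p < 0.01:
        return "p<0.01"
    if p < 0.05:
        return "p<0.05"
    if p < 0.1:
        return "p<0.1"
    return "ns"


def fit_weathering_toxicity(
    x: Sequence[float],
    y: Sequence[float],
    predictor_name: str = "weathering_pct",
) -> RegressionResult:
    """Simple OLS of toxicity response on one weathering predictor.

    ``x``: weathering metric values (% scale).  ``y``: mean larval growth
    as % of control in the undiluted leachate.  Requires n >= 3 and a
    non-constant predictor; the slope p-value is the two-sided t test.
    Small-sample fits are legitimate here (field studies have few
    stations) but warrant caution in interpretation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError(
            f"regression needs n >= 3 observations, got n={x.size}; "
            "too few points to estimate a slope and its uncertainty"
        )
    if np.ptp(x) == 0:
        raise ValueError("predictor is constant; slope undefined")
    res = stats.linregress(x, y)
    p = float(res.pvalue)
    return RegressionResult(
        predictor_name=predictor_name,
        n=int(x.size),
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        p_slope=p,
        significance_band=_band(p),
    )


def regression_table(
    df: pd.DataFrame,
    predictors: Sequence[str] = ("weathering_pct", "pct_ge2", "sample_yi"),
    response: str = "growth_pct_control",
) -> pd.DataFrame:
    """One univariate regression row per available predictor column."""
    if response not in df.columns:
        raise ValueError(f"response column {response!r} missing")
    rows = []
    for pred in predictors:
        if pred not in df.columns:
            continue
        sub = df[[pred, response]].dropna()
        r = fit_weathering_toxicity(sub[pred], sub[response], predictor_name=pred)
        rows.append(
            dict(
                predictor=r.predictor_name,
                n=r.n,
                slope=r.slope,
                intercept=r.intercept,
                r_squared=r.r_squared,
                p_slope=r.p_slope,
                band=r.significance_band,
            )
        )
    return pd.DataFrame(rows)


def plot_regression(x, y, result: RegressionResult, path) -> None:
    """Scatter + fitted line saved to ``path`` (PNG)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    fig, ax = plt.subplots(figsize=(4.5, 3.5))
    ax.scatter(x, y, color="tab:blue")
    xs = np.linspace(x.min(), x.max(), 50)
    ax.plot(xs, result.intercept + result.slope * xs, color="tab:red")
    ax.set_xlabel(result.predictor_name)
    ax.set_ylabel("growth (% of control)")
    ax.set_title(
        f"r²={result.r_squared:.2f}, {result.significance_band}"
    )
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
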