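"""Content-on-color regressions: predict flavonoid content from CIELAB color.

Each analyte's content (mg/g) is modelled as an ordinary least-squares
linear function of the peel color axes, by default a* and b*:

    y = c_a * a + c_b * b + intercept

with the usual summaries R = sqrt(R^2) and
F = (R^2 / k) / ((1 - R^2) / (n - k - 1)).
Coefficients are in raw CIELAB units (no standardization), so the fitted
equation can be applied directly to a colorimeter reading.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .pathcoef import ols
from .sample_io import ColorTriple, SampleTable

__all__ = ["RegressionModel", "fit_color_regression", "predict_content",
           "regression_table"]


@dataclass
class RegressionModel:
    response: str
    coefficients: dict[str, float]
    intercept: float
    R: float
    R2: float
    F: float
    n: int
    k: int

    def equation(self) -> str:
        terms = []
        for axis, c in self.coefficients.items():
            terms.append(f"{c:+.3f}{axis}*")
        return f"y = {' '.join(terms)} {self.intercept:+.3f}".replace("= +", "= ")


def _f_statistic(r2: float, n: int, k: int) -> float:
    if r2 >= 1.0:
        return float("inf")
    return (r2 / k) / ((1.0 - r2) / (n - k - 1))


def fit_color_regression(table: SampleTable | pd.DataFrame, response: str,
                         predictors: Sequence[str] = ("a", "b"),
                         ) -> RegressionModel:
    """OLS fit of one analyte's content on the chosen color axes."""
    frame = table.to_frame() if isinstance(table, SampleTable) else table
    for col in (response, *predictors):
        if col not in frame.columns:
            raise KeyError(f"column {col!r} absent from table")
    sub = frame[[response, *predictors]].astype(float).dropna()
    n, k = len(sub), len(predictors)
    if n <= k + 1:
        raise ValueError(f"need n > k + 1 rows (n={n}, k={k})")
    y = sub[response].to_numpy()
    X = sub[list(predictors)].to_numpy()
    if np.linalg.matrix_rank(np.column_stack([np.ones(n), X])) < k + 1:
        raise np.linalg.LinAlgError(
            f"collinear color predictors {list(predictors)}")
    if np.ptp(y) == 0:
        return RegressionModel(
            response=response,
            coefficients={ax: 0.0 for ax in predictors},
            intercept=float(y[0]), R=0.0, R2=0.0, F=0.0, n=n, k=k)
    fit = ols(X, y)
    r2 = max(0.0, fit.r2)
    return RegressionModel(
        response=response,
        coefficients={ax: float(c) for ax, c in zip(predictors, fit.coef)},
        intercept=fit.intercept,
        R=float(np.sqrt(r2)), R2=r2, F=_f_statistic(r2, n, k), n=n, k=k)


def predict_content(model: RegressionModel, color: ColorTriple) -> float:
    """Evaluate the fitted equation at a color reading. Predictions are not
    clipped; a negative content triggers a warning."""
    value = model.intercept
    for axis, coef in model.coefficients.items():
        value += coef * getattr(color, axis)
    if value < 0:
        warnings.warn(
            f"negative predicted content {value:.3f} mg/g for {model.response}")
    return float(value)


def regression_table(table: SampleTable | pd.DataFrame,
                     responses: Sequence[str],
                     predictors: Sequence[str] = ("a", "b"),
                     r2_threshold: float = 0.0) -> pd.DataFrame:
    """One fitted model per response, as a summary table; rows under the
    reporting threshold are kept but flagged."""
    frame = table.to_frame() if isinstance(table, SampleTable) else table
    missing = [ax for ax in predictors if ax not in frame.columns]
    if missing:
        raise KeyError(f"color column(s) absent: {missing}")
    rows = []
    for resp in responses:
        m = fit_color_regression(frame, resp, predictors)
        rows.append({
            "response": resp,
            "equation": m.equation(),
            **{f"coef_{ax}": c for ax, c in m.coefficients.items()},
            "intercept": m.intercept,
            "R": m.R, "R2": m.R2, "F": m.F, "n": m.n,
            "below_threshold": m.R2 < r2_threshold,
        })
    return pd.DataFrame(rows)
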