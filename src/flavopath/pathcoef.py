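"""Path analysis: stepwise screening, direct/indirect decomposition and
decision coefficients.

For a standardized response y and standardized predictors x_1..x_k, the
direct path coefficients P solve R_xx P = r_xy, i.e. they are the
standardized multiple-regression coefficients. Each predictor's simple
correlation with the response then decomposes exactly as

    r_i = P_i + sum_{j != i} r_ij P_j

where r_ij P_j is predictor i's indirect effect routed through its
correlated co-predictor j. The decision coefficient

    D_i = 2 P_i r_i - P_i^2

ranks the predictors' net contribution: positive D marks a promoting
factor, negative D an inhibiting one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .sample_io import SampleTable

__all__ = [
    "StepwiseTrace", "PathAnalysisResult", "CollinearityError",
    "stepwise_select", "path_decompose", "decision_coefficient",
    "rank_factors", "ols",
]


class CollinearityError(ValueError):
    """Predictor correlation matrix is singular."""


@dataclass
class OLSFit:
    """Minimal OLS fit (intercept included) with coefficient t-test p-values."""
    coef: np.ndarray       # without intercept
    intercept: float
    p_values: np.ndarray   # per coefficient, two-sided
    r2: float
    n: int
    k: int
    resid: np.ndarray


def ols(X: np.ndarray, y: np.ndarray) -> OLSFit:
    """OLS via normal equations with intercept; p-values from the t test."""
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    n, k = X.shape
    if n <= k + 1:
        raise ValueError(f"need n > k + 1 (n={n}, k={k})")
    Xd = np.column_stack([np.ones(n), X])
    XtX = Xd.T @ Xd
    try:
        beta = np.linalg.solve(XtX, Xd.T @ y)
    except np.linalg.LinAlgError as exc:
        raise CollinearityError(str(exc)) from exc
    resid = y - Xd @ beta
    dof = n - k - 1
    sigma2 = float(resid @ resid) / dof
    cov = sigma2 * np.linalg.inv(XtX)
    se = np.sqrt(np.diag(cov))
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = beta / se
    p = 2.0 * stats.t.sf(np.abs(tvals), df=dof)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - float(resid @ resid) / ss_tot if ss_tot > 0 else 0.0
    return OLSFit(coef=beta[1:], intercept=float(beta[0]),
                  p_values=p[1:], r2=r2, n=n, k=k, resid=resid)


# ------------------------------------------------------------- stepwise

@dataclass
class StepwiseTrace:
    steps: list[tuple[str, str, float]]  # (action, variable, p at action)
    final_set: list[str]


def stepwise_select(table: SampleTable | pd.DataFrame, response: str,
                    candidates: Sequence[str], p_enter: float = 0.05,
                    p_remove: float = 0.10) -> StepwiseTrace:
    """Forward-stepwise screening with backward checks.

    At each step the excluded candidate with the smallest coefficient
    p-value (equivalently the partial-F p) is considered for entry. The
    entry decision compares the Sidak-adjusted minimum, 1 - (1 - p)^m over
    the m candidates screened that step, against ``p_enter`` so the
    familywise false-entry rate per step equals ``p_enter`` under the
    global null; with ten pure-noise candidates the raw smallest-p rule
    would admit a spurious variable in roughly 40% of datasets. Any
    included variable whose (raw) coefficient p-value exceeds ``p_remove``
    is then dropped. Ties break by candidate list order; ``p_enter <=
    p_remove`` is required to rule out enter/remove cycles.
    """
    if p_enter > p_remove:
        raise ValueError("p_enter must be <= p_remove (cycling risk)")
    frame = table.to_frame() if isinstance(table, SampleTable) else table
    data = frame[[response, *candidates]].astype(float).dropna()
    y = data[response].to_numpy()
    n = len(data)
    included: list[str] = []
    steps: list[tuple[str, str, float]] = []
    while True:
        changed = False
        # forward: best candidate by p-value of its coefficient when added
        best: tuple[float, int, str] | None = None
        for pos, cand in enumerate(candidates):
            if cand in included:
                continue
            if n <= len(included) + 2:
                raise ValueError(
                    f"too few rows (n={n}) to extend a {len(included)}-"
                    "predictor model")
            X = data[[*included, cand]].to_numpy()
            p_cand = float(ols(X, y).p_values[-1])
            if best is None or p_cand < best[0]:
                best = (p_cand, pos, cand)
        if best is not None:
            m = len([c for c in candidates if c not in included])
            p_adj = 1.0 - (1.0 - best[0]) ** m
            if p_adj < p_enter:
                included.append(best[2])
                steps.append(("enter", best[2], p_adj))
                changed = True
        # backward: drop anything that no longer earns its place
        while included:
            fit = ols(data[included].to_numpy(), y)
            worst = int(np.argmax(fit.p_values))
            p_worst = float(fit.p_values[worst])
            if p_worst > p_remove:
                name = included.pop(worst)
                steps.append(("remove", name, p_worst))
                changed = True
            else:
                break
        if not changed:
            break
    return StepwiseTrace(steps=steps, final_set=list(included))


# ------------------------------------------------------ decomposition

@dataclass
class PathAnalysisResult:
    response: str
    predictors: tuple[str, ...]
    r_xy: pd.Series            # predictor-response correlations
    direct: pd.Series          # path coefficients P_i
    indirect: pd.DataFrame     # (i, j): effect of i routed via j
    indirect_total: pd.Series
    decision: pd.Series
    significance: pd.Series = field(default=None)  # type: ignore[assignment]

    def to_frame(self) -> pd.DataFrame:
        """Tabular layout: r, direct, per-mediator indirects, total, D, p."""
        out = pd.DataFrame({
            "response": self.response,
            "r": self.r_xy,
            "direct": self.direct,
        })
        for j in self.predictors:
            out[f"via_{j}"] = self.indirect[j]
        out["indirect_total"] = self.indirect_total
        out["decision"] = self.decision
        if self.significance is not None:
            out["p"] = self.significance
        return out


def decision_coefficient(direct: float, r_xy: float) -> float:
    """D = 2 P r - P^2, the path-analysis ranking index."""
    return 2.0 * direct * r_xy - direct**2


def path_decompose(
    data: SampleTable | pd.DataFrame | None,
    response: str,
    predictors: Sequence[str],
    r_xy: Sequence[float] | None = None,
    R_xx: np.ndarray | pd.DataFrame | None = None,
) -> PathAnalysisResult:
    """Decompose predictor-response correlations into direct and indirect
    path coefficients.

    Either raw ``data`` (a table with the response and predictor columns)
    or correlation-level inputs (``r_xy`` plus the predictor
    intercorrelation matrix ``R_xx``) must be supplied; the latter allows
    published coefficient blocks to be checked without raw data.
    """
    predictors = tuple(predictors)
    if len(predictors) < 1:
        raise ValueError("at least one predictor required")
    significance = None
    if data is not None:
        frame = data.to_frame() if isinstance(data, SampleTable) else data
        sub = frame[[response, *predictors]].astype(float).dropna()
        corr = sub.corr()
        r_vec = corr.loc[list(predictors), response].to_numpy()
        R = corr.loc[list(predictors), list(predictors)].to_numpy()
        fit = ols(sub[list(predictors)].to_numpy(), sub[response].to_numpy())
        significance = pd.Series(fit.p_values, index=list(predictors))
    else:
        if r_xy is None or R_xx is None:
            raise ValueError("supply either data or (r_xy, R_xx)")
        r_vec = np.asarray(r_xy, float)
        R = np.asarray(R_xx, float) if not isinstance(R_xx, pd.DataFrame) \
            else R_xx.loc[list(predictors), list(predictors)].to_numpy()

    # positive definiteness check doubles as the collinearity guard
    try:
        np.linalg.cholesky(R)
    except np.linalg.LinAlgError:
        raise CollinearityError(
            f"predictor correlation matrix for {list(predictors)} is "
            "singular or indefinite") from None

    P = np.linalg.solve(R, r_vec)
    if np.any(np.abs(P) > 1):
        big = [predictors[i] for i in np.flatnonzero(np.abs(P) > 1)]
        warnings.warn(
            f"direct path coefficient(s) of magnitude > 1 for {big}: "
            "strong predictor collinearity")
    k = len(predictors)
    indirect = np.zeros((k, k))
    for i in range(k):
        for j in range(k):
            if i != j:
                indirect[i, j] = R[i, j] * P[j]
    idx = list(predictors)
    return PathAnalysisResult(
        response=response,
        predictors=predictors,
        r_xy=pd.Series(r_vec, index=idx),
        direct=pd.Series(P, index=idx),
        indirect=pd.DataFrame(indirect, index=idx, columns=idx),
        indirect_total=pd.Series(indirect.sum(axis=1), index=idx),
        decision=pd.Series(
            [decision_coefficient(P[i], r_vec[i]) for i in range(k)], index=idx),
        significance=significance,
    )


def rank_factors(result: PathAnalysisResult
                 ) -> list[tuple[str, float, str]]:
    """Predictors sorted by decision coefficient (descending, stable),
    labelled promoting / inhibiting / neutral."""
    def label(d: float) -> str:
        if d > 0:
            return "promoting"
        if d < 0:
            return "inhibiting"
        return "neutral"

    items = [(code, float(result.decision[code])) for code in result.predictors]
    items.sort(key=lambda kv: -kv[1])
    return [(code, d, label(d)) for code, d in items]
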