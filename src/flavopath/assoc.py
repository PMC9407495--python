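"""Pearson correlation matrices with two-sided significance flags.

Correlations are computed on pairwise-complete observations; p-values use
the exact t reference distribution, t = r * sqrt((n-2)/(1-r^2)) with n-2
degrees of freedom, appropriate for the small cohort sizes this pipeline
targets. Flags follow the conventional star notation: "**" for p < 0.01,
"*" for 0.01 <= p < 0.05 (strict inequalities at the boundaries).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .sample_io import SampleTable

__all__ = ["CorrelationResult", "pearson_matrix", "flag_significance",
           "pearson_p_value"]


@dataclass
class CorrelationResult:
    variables: tuple[str, ...]
    r: pd.DataFrame
    p: pd.DataFrame
    n: pd.DataFrame
    flags: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def to_long_frame(self) -> pd.DataFrame:
        """Long format (var1, var2, r, p, n, flag), upper triangle only."""
        rows = []
        for i, v1 in enumerate(self.variables):
            for v2 in self.variables[i + 1:]:
                rows.append({
                    "var1": v1, "var2": v2,
                    "r": self.r.loc[v1, v2],
                    "p": self.p.loc[v1, v2],
                    "n": self.n.loc[v1, v2],
                    "flag": "" if self.flags is None else self.flags.loc[v1, v2],
                })
        return pd.DataFrame(rows)

    def write_csv(self, long_path: str | Path, square_path: str | Path) -> None:
        self.to_long_frame().to_csv(long_path, index=False)
        square = self.r.round(3).astype(str)
        if self.flags is not None:
            square = square + self.flags.where(self.flags == "", " " + self.flags)
        square.to_csv(square_path)


def pearson_p_value(r: float, n: int) -> float:
    """Two-sided p for a sample Pearson r at n pairwise-complete rows."""
    if n < 3:
        return float("nan")
    if abs(r) >= 1.0:
        return 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    return float(2.0 * stats.t.sf(abs(t), df=n - 2))


def pearson_matrix(table: SampleTable | pd.DataFrame,
                   variables: Sequence[str]) -> CorrelationResult:
    """Pairwise-complete Pearson correlation over the requested variables.

    Constant columns yield undefined correlations: those cells are reported
    as NaN with a warning, never coerced to zero.
    """
    frame = table.matrix(variables) if isinstance(table, SampleTable) else \
        table[list(variables)].astype(float)
    k = len(variables)
    r = np.full((k, k), np.nan)
    p = np.full((k, k), np.nan)
    n = np.zeros((k, k), dtype=int)
    cols = [frame[v].to_numpy(float) for v in variables]
    for i in range(k):
        for j in range(i, k):
            mask = ~np.isnan(cols[i]) & ~np.isnan(cols[j])
            m = int(mask.sum())
            n[i, j] = n[j, i] = m
            if m < 3:
                raise ValueError(
                    f"fewer than 3 pairwise-complete rows for "
                    f"({variables[i]}, {variables[j]})")
            x, y = cols[i][mask], cols[j][mask]
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                if i == j and np.ptp(x) == 0:
                    warnings.warn(
                        f"constant column {variables[i]}: correlation undefined")
                elif i != j:
                    warnings.warn(
                        f"constant column in pair ({variables[i]}, "
                        f"{variables[j]}): correlation undefined")
                continue
            if i == j:
                r[i, i], p[i, i] = 1.0, 0.0
                continue
            rij = float(np.corrcoef(x, y)[0, 1])
            rij = max(-1.0, min(1.0, rij))
            r[i, j] = r[j, i] = rij
            p[i, j] = p[j, i] = pearson_p_value(rij, m)
    variables = tuple(variables)
    result = CorrelationResult(
        variables=variables,
        r=pd.DataFrame(r, index=variables, columns=variables),
        p=pd.DataFrame(p, index=variables, columns=variables),
        n=pd.DataFrame(n, index=variables, columns=variables),
    )
    return flag_significance(result)


def flag_significance(result: CorrelationResult,
                      alphas: tuple[float, float] = (0.05, 0.01)
                      ) -> CorrelationResult:
    """Fill the star flags: "**" below the stricter level, "*" below the
    looser one; a p exactly equal to an alpha is not significant."""
    loose, strict = max(alphas), min(alphas)
    p = result.p
    flags = pd.DataFrame("", index=p.index, columns=p.columns)
    flags = flags.mask(p.lt(loose) & p.ge(strict), "*")
    flags = flags.mask(p.lt(strict), "**")
    result.flags = flags.fillna("")
    return result
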