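"""Covariance-based structural equation modelling over observed variables.

A model is a directed acyclic set of regressions among measured variables
plus free covariances between exogenous variables and free residual
variances for every endogenous variable. With A the coefficient matrix
(A[t, s] is the edge s -> t) and Psi the covariance of exogenous terms and
residuals, the model-implied covariance is

    Sigma(theta) = (I - A)^-1 Psi (I - A)^-T

Free parameters are estimated by minimizing the normal-theory maximum-
likelihood discrepancy

    F(theta) = ln|Sigma| + tr(S Sigma^-1) - ln|S| - p

against the sample covariance S; chi2 = (n - 1) F at the optimum (the
Wishart-likelihood convention). Fit is summarized by CMIN/DF, RMSEA, GFI
and AGFI, and models pass selection only under CMIN/DF < 1, RMSEA < 0.08
and AGFI > 0.9 (strict inequalities; a just-identified model, df = 0, has
no defined CMIN/DF or RMSEA and always fails selection).

Standardization multiplies each coefficient by sd(source)/sd(target) under
the implied covariance; total effects over the acyclic graph factor as
(I - B)^-1 Gamma, and the indirect part is enumerated path by path so each
mediator's contribution is reported as the product of its edge
coefficients.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .sample_io import SampleTable

__all__ = [
    "SemSpec", "SemFit", "EffectsTable", "FitIndices",
    "parse_spec", "fit_sem", "fit_indices", "standardize",
    "effects_decomposition", "effects_from_edges", "select_models",
    "implied_covariance",
]


# ---------------------------------------------------------------- spec

@dataclass(frozen=True)
class SemSpec:
    variables: tuple[str, ...]
    regressions: tuple[tuple[str, str], ...]          # (source, target)
    exogenous_covariances: tuple[tuple[str, str], ...] = ()

    def __post_init__(self) -> None:
        declared = set(self.variables)
        for s, t in list(self.regressions) + list(self.exogenous_covariances):
            if s not in declared or t not in declared:
                raise ValueError(f"edge ({s}, {t}) uses undeclared variable")
        self.topological_order()  # raises on cycles

    def endogenous(self) -> tuple[str, ...]:
        targets = {t for _, t in self.regressions}
        return tuple(v for v in self.variables if v in targets)

    def exogenous(self) -> tuple[str, ...]:
        endo = set(self.endogenous())
        return tuple(v for v in self.variables if v not in endo)

    def parents(self, var: str) -> tuple[str, ...]:
        return tuple(s for s, t in self.regressions if t == var)

    def topological_order(self) -> tuple[str, ...]:
        indeg = {v: 0 for v in self.variables}
        for _, t in self.regressions:
            indeg[t] += 1
        queue = [v for v in self.variables if indeg[v] == 0]
        order: list[str] = []
        children = {v: [] for v in self.variables}
        for s, t in self.regressions:
            children[s].append(t)
        while queue:
            v = queue.pop(0)
            order.append(v)
            for c in children[v]:
                indeg[c] -= 1
                if indeg[c] == 0:
                    queue.append(c)
        if len(order) != len(self.variables):
            raise ValueError("regression graph contains a cycle")
        return tuple(order)

    def parameter_names(self) -> list[str]:
        names = [f"{s}->{t}" for s, t in self.regressions]
        names += [f"{v}~~{v}" for v in self.exogenous()]
        names += [f"{a}~~{b}" for a, b in self.exogenous_covariances]
        names += [f"{v}~~{v}" for v in self.endogenous()]
        return names

    @property
    def n_free(self) -> int:
        return (len(self.regressions) + len(self.exogenous())
                + len(self.exogenous_covariances) + len(self.endogenous()))

    def degrees_of_freedom(self) -> int:
        p = len(self.variables)
        return p * (p + 1) // 2 - self.n_free


def parse_spec(text: str, variables: Sequence[str] | None = None) -> SemSpec:
    """Parse the one-edge-per-line grammar: ``SRC -> DST`` for a regression,
    ``SRC ~~ DST`` for a free exogenous covariance; ``#`` starts a comment."""
    regressions: list[tuple[str, str]] = []
    covariances: list[tuple[str, str]] = []
    seen: list[str] = []

    def note(v: str) -> None:
        if v not in seen:
            seen.append(v)

    for lineno, line in enumerate(text.splitlines(), 1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "->" in line:
            src, dst = (part.strip() for part in line.split("->", 1))
            regressions.append((src, dst))
        elif "~~" in line:
            a, b = (part.strip() for part in line.split("~~", 1))
            covariances.append((a, b))
        else:
            raise ValueError(f"unparseable model line {lineno}: {line!r}")
        for v in (regressions[-1] if "->" in line else covariances[-1]):
            note(v)
    return SemSpec(
        variables=tuple(variables) if variables is not None else tuple(seen),
        regressions=tuple(regressions),
        exogenous_covariances=tuple(covariances),
    )


# ----------------------------------------------------- implied moments

def _unpack(spec: SemSpec, theta: np.ndarray):
    p = len(spec.variables)
    idx = {v: i for i, v in enumerate(spec.variables)}
    expected = spec.n_free
    if len(theta) != expected:
        raise ValueError(f"theta has length {len(theta)}, expected {expected}")
    A = np.zeros((p, p))
    Psi = np.zeros((p, p))
    pos = 0
    for s, t in spec.regressions:
        A[idx[t], idx[s]] = theta[pos]
        pos += 1
    for v in spec.exogenous():
        Psi[idx[v], idx[v]] = theta[pos]
        pos += 1
    for a, b in spec.exogenous_covariances:
        Psi[idx[a], idx[b]] = Psi[idx[b], idx[a]] = theta[pos]
        pos += 1
    for v in spec.endogenous():
        Psi[idx[v], idx[v]] = theta[pos]
        pos += 1
    return A, Psi


def implied_covariance(spec: SemSpec, theta: Sequence[float]) -> np.ndarray:
    """Sigma(theta) from the reduced form of the structural equations."""
    A, Psi = _unpack(spec, np.asarray(theta, float))
    inv = np.linalg.inv(np.eye(len(spec.variables)) - A)
    sigma = inv @ Psi @ inv.T
    return (sigma + sigma.T) / 2.0


# ---------------------------------------------------------------- fit

@dataclass
class FitIndices:
    cmin_df: float
    rmsea: float
    gfi: float
    agfi: float


@dataclass
class SemFit:
    spec: SemSpec
    estimates: dict[str, float]
    standardized: dict[str, float]
    implied_cov: pd.DataFrame
    sample_cov: pd.DataFrame
    n: int
    chi2: float
    df: int
    cmin_df: float
    rmsea: float
    gfi: float
    agfi: float
    r2: dict[str, float]
    converged: bool
    f_min: float
    theta: np.ndarray = field(repr=False, default=None)  # type: ignore

    def standardized_edge(self, source: str, target: str) -> float:
        return self.standardized[f"{source}->{target}"]

    def wald_tests(self) -> pd.DataFrame:
        """Standard errors from the inverse numerical Hessian of the fit
        function, with two-sided Wald p-values and star annotations.

        The Hessian is evaluated on the correlation scale (all observed
        variances 1), where finite differences are well conditioned, and
        the standard errors are mapped back to raw units."""
        names = self.spec.parameter_names()
        S = self.sample_cov.to_numpy()
        d = 1.0 / np.sqrt(np.diag(S))
        S_corr = S * np.outer(d, d)
        factor = _scale_factors(self.spec, np.sqrt(np.diag(S)))
        theta_corr = self.theta / factor

        def h(th: np.ndarray) -> float:
            return 0.5 * (self.n - 1) * _discrepancy(self.spec, th, S_corr)

        H = _numeric_hessian(h, theta_corr)
        try:
            acov = np.linalg.inv(H)
            se = np.sqrt(np.clip(np.diag(acov), 0.0, None)) * np.abs(factor)
        except np.linalg.LinAlgError:
            se = np.full(len(names), np.nan)
        est = np.array([self.estimates[nm] for nm in names])
        with np.errstate(divide="ignore", invalid="ignore"):
            z = est / se
        pvals = 2.0 * stats.norm.sf(np.abs(z))
        stars = np.where(pvals < 0.01, "**", np.where(pvals < 0.05, "*", "ns"))
        return pd.DataFrame({
            "parameter": names, "estimate": est,
            "standardized": [self.standardized[nm] for nm in names],
            "se": se, "z": z, "p": pvals, "stars": stars,
        }).set_index("parameter")

    def edge_frame(self) -> pd.DataFrame:
        """Edge list (source, target, standardized coefficient, p, stars)."""
        wald = self.wald_tests()
        rows = []
        for s, t in self.spec.regressions:
            name = f"{s}->{t}"
            rows.append({
                "source": s, "target": t,
                "estimate": self.estimates[name],
                "standardized": self.standardized[name],
                "p": wald.loc[name, "p"],
                "stars": wald.loc[name, "stars"],
            })
        return pd.DataFrame(rows)


def _discrepancy(spec: SemSpec, theta: np.ndarray, S: np.ndarray) -> float:
    try:
        sigma = implied_covariance(spec, theta)
        chol = np.linalg.cholesky(sigma)
    except np.linalg.LinAlgError:
        return 1e10
    p = S.shape[0]
    logdet_sigma = 2.0 * float(np.log(np.diag(chol)).sum())
    sign, logdet_s = np.linalg.slogdet(S)
    inv = np.linalg.inv(sigma)
    return logdet_sigma + float(np.trace(S @ inv)) - logdet_s - p


def _numeric_hessian(fun, x: np.ndarray, eps: float = 1e-4) -> np.ndarray:
    m = len(x)
    H = np.zeros((m, m))
    f0 = fun(x)
    for i in range(m):
        for j in range(i, m):
            ei = np.zeros(m); ei[i] = eps
            ej = np.zeros(m); ej[j] = eps
            fpp = fun(x + ei + ej)
            fpm = fun(x + ei - ej)
            fmp = fun(x - ei + ej)
            fmm = fun(x - ei - ej)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * eps * eps)
    return H


def _scale_factors(spec: SemSpec, sd: np.ndarray) -> np.ndarray:
    """Per-parameter factors mapping correlation-scale estimates to raw
    units: theta_raw = factor * theta_corr."""
    lookup = dict(zip(spec.variables, sd))
    factors = []
    for s, t in spec.regressions:
        factors.append(lookup[t] / lookup[s])
    for v in spec.exogenous():
        factors.append(lookup[v] ** 2)
    for a, b in spec.exogenous_covariances:
        factors.append(lookup[a] * lookup[b])
    for v in spec.endogenous():
        factors.append(lookup[v] ** 2)
    return np.asarray(factors)


def _start_values(spec: SemSpec, S: pd.DataFrame) -> np.ndarray:
    """Least-squares start: per-equation regression coefficients read off
    the sample covariance (exact MLE for recursive models with all
    exogenous covariances free)."""
    betas: dict[tuple[str, str], float] = {}
    resid: dict[str, float] = {}
    for var in spec.endogenous():
        parents = list(spec.parents(var))
        Spp = S.loc[parents, parents].to_numpy()
        Spy = S.loc[parents, var].to_numpy()
        coef = np.linalg.solve(Spp, Spy)
        for par, b in zip(parents, coef):
            betas[(par, var)] = float(b)
        rv = float(S.loc[var, var] - Spy @ coef)
        resid[var] = max(rv, 0.05 * float(S.loc[var, var]))
    theta = [betas[edge] for edge in spec.regressions]
    theta += [float(S.loc[v, v]) for v in spec.exogenous()]
    theta += [float(S.loc[a, b]) for a, b in spec.exogenous_covariances]
    theta += [resid[v] for v in spec.endogenous()]
    return np.asarray(theta, float)


def fit_sem(data: SampleTable | pd.DataFrame | tuple, spec: SemSpec,
            n: int | None = None, max_restarts: int = 5,
            seed: int = 0) -> SemFit:
    """Fit a path model by maximum likelihood.

    ``data`` is a sample table / data frame with the spec's variables as
    columns, or a tuple ``(sample_cov, n)`` where ``sample_cov`` is a
    DataFrame (or array over ``spec.variables``). A small-sample warning is
    issued when n < 5 x free parameters; non-convergence returns a fit with
    ``converged = False`` rather than raising.
    """
    variables = list(spec.variables)
    if isinstance(data, tuple):
        cov, n = data
        S = cov if isinstance(cov, pd.DataFrame) else \
            pd.DataFrame(np.asarray(cov, float), index=variables, columns=variables)
        S = S.loc[variables, variables]
    else:
        frame = data.to_frame() if isinstance(data, SampleTable) else data
        sub = frame[variables].astype(float).dropna()
        n = len(sub)
        S = sub.cov()  # ddof=1
    if n is None or n <= len(variables):
        raise ValueError("need n greater than the number of variables")
    try:
        np.linalg.cholesky(S.to_numpy())
    except np.linalg.LinAlgError:
        raise ValueError("sample covariance is not positive definite") from None
    if n < 5 * spec.n_free:
        warnings.warn(
            f"small sample: n={n} < 5 x {spec.n_free} free parameters; "
            "interpret fit indices cautiously")

    # optimize on the correlation scale: F is invariant to rescaling of
    # the observed variables, and finite differences are well conditioned
    # when every variance is 1
    Smat = S.to_numpy()
    sd = np.sqrt(np.diag(Smat))
    S_corr = Smat / np.outer(sd, sd)
    S_corr_df = pd.DataFrame(S_corr, index=variables, columns=variables)
    factor = _scale_factors(spec, sd)
    fun = lambda th: _discrepancy(spec, th, S_corr)
    start = _start_values(spec, S_corr_df)
    rng = np.random.default_rng(seed)
    best = None
    for attempt in range(max_restarts + 1):
        x0 = start if attempt == 0 else \
            start * (1.0 + 0.1 * rng.standard_normal(len(start)))
        res = optimize.minimize(
            fun, x0, method="L-BFGS-B",
            options={"maxiter": 2000, "ftol": 1e-14, "gtol": 1e-9})
        grad_norm = float(np.max(np.abs(res.jac)))
        # F >= 0 with equality only at a perfect fit, so res.fun ~ 0 is
        # itself proof of convergence; the gradient test allows for the
        # noise floor of 2-point finite differences (~1e-5 on this scale)
        converged = (bool(res.success) and grad_norm < 1e-4) \
            or res.fun < 1e-9
        if best is None or res.fun < best[0].fun:
            best = (res, converged)
        if converged:
            break
    res, converged = best
    if not converged:
        warnings.warn("SEM optimization did not converge; inspect the fit")

    theta = res.x * factor
    f_min = max(float(res.fun), 0.0)
    sigma = implied_covariance(spec, theta)
    chi2 = max((n - 1) * f_min, 0.0)
    df = spec.degrees_of_freedom()
    idx = fit_indices(chi2, df, n, Smat, sigma, spec.n_free)
    names = spec.parameter_names()
    estimates = {nm: float(v) for nm, v in zip(names, theta)}

    fit = SemFit(
        spec=spec,
        estimates=estimates,
        standardized={},
        implied_cov=pd.DataFrame(sigma, index=variables, columns=variables),
        sample_cov=S,
        n=int(n),
        chi2=chi2, df=df,
        cmin_df=idx.cmin_df, rmsea=idx.rmsea, gfi=idx.gfi, agfi=idx.agfi,
        r2={}, converged=converged, f_min=f_min, theta=theta,
    )
    return standardize(fit)


def fit_indices(chi2: float, df: int, n: int,
                sample_cov: np.ndarray, implied_cov: np.ndarray,
                free_params: int) -> FitIndices:
    """CMIN/DF, RMSEA, GFI and AGFI. For df = 0 the first two are undefined
    and returned as NaN (and such models never pass selection)."""
    if df < 0:
        raise ValueError("negative degrees of freedom")
    if n < 2:
        raise ValueError("need n >= 2")
    S = np.asarray(sample_cov, float)
    sigma = np.asarray(implied_cov, float)
    p = S.shape[0]
    inv = np.linalg.inv(sigma)
    resid = inv @ (S - sigma)
    gfi = 1.0 - float(np.trace(resid @ resid)) / float(
        np.trace((inv @ S) @ (inv @ S)))
    if df > 0:
        cmin_df = chi2 / df
        rmsea = math.sqrt(max(chi2 - df, 0.0) / (df * (n - 1)))
        agfi = 1.0 - (p * (p + 1) / (2.0 * df)) * (1.0 - gfi)
    else:
        cmin_df = float("nan")
        rmsea = float("nan")
        agfi = float("nan")
    return FitIndices(cmin_df=cmin_df, rmsea=rmsea, gfi=gfi, agfi=agfi)


def standardize(fit: SemFit) -> SemFit:
    """Fill the standardized coefficients and endogenous R^2 from the
    model-implied variances."""
    sigma = fit.implied_cov
    sd = {v: math.sqrt(float(sigma.loc[v, v])) for v in fit.spec.variables}
    if any(s == 0 for s in sd.values()):
        degenerate = [v for v, s in sd.items() if s == 0]
        raise ValueError(f"zero implied variance for {degenerate}")
    std: dict[str, float] = {}
    for s, t in fit.spec.regressions:
        name = f"{s}->{t}"
        std[name] = fit.estimates[name] * sd[s] / sd[t]
    for v in fit.spec.exogenous():
        std[f"{v}~~{v}"] = 1.0
    for a, b in fit.spec.exogenous_covariances:
        std[f"{a}~~{b}"] = fit.estimates[f"{a}~~{b}"] / (sd[a] * sd[b])
    r2 = {}
    # endogenous names may repeat exogenous ~~ pattern; residual variance
    # entries are the trailing block of parameter_names
    for v in fit.spec.endogenous():
        resid_std = fit.estimates[f"{v}~~{v}"] / (sd[v] ** 2)
        std[f"{v}~~{v}"] = resid_std
        r2[v] = 1.0 - resid_std
    fit.standardized = std
    fit.r2 = r2
    return fit


# ------------------------------------------------------------- effects

@dataclass
class EffectsTable:
    entries: dict[tuple[str, str], dict]

    def effect(self, source: str, target: str) -> tuple[float, float, float]:
        e = self.entries.get((source, target))
        if e is None:
            return (0.0, 0.0, 0.0)
        return (e["direct"], e["indirect"], e["total"])

    def mediator_contribution(self, source: str, target: str,
                              mediator: str) -> float:
        e = self.entries.get((source, target), {})
        return e.get("mediators", {}).get(mediator, 0.0)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (s, t), e in sorted(self.entries.items()):
            rows.append({"source": s, "target": t, "direct": e["direct"],
                         "indirect": e["indirect"], "total": e["total"]})
        return pd.DataFrame(rows)


def effects_from_edges(edges: Mapping[tuple[str, str], float]) -> EffectsTable:
    """Direct / indirect / total effect decomposition from a bare dict of
    standardized edge coefficients over an acyclic graph.

    Indirect effects are enumerated as sums of edge-coefficient products
    over all directed paths of length >= 2; each path's product is
    attributed to its first intermediate node, so a single-mediator chain
    reports exactly the product of its two edges for that mediator.
    """
    nodes = sorted({v for edge in edges for v in edge})
    children: dict[str, list[str]] = {v: [] for v in nodes}
    for (s, t) in edges:
        children[s].append(t)
    # cycle guard
    color: dict[str, int] = {}

    def check(v: str) -> None:
        color[v] = 1
        for c in children[v]:
            if color.get(c) == 1:
                raise ValueError("effect decomposition needs an acyclic graph")
            if color.get(c, 0) == 0:
                check(c)
        color[v] = 2

    for v in nodes:
        if color.get(v, 0) == 0:
            check(v)

    entries: dict[tuple[str, str], dict] = {}

    def paths_from(source: str):
        stack = [(source, [source], 1.0)]
        while stack:
            node, chain, prod = stack.pop()
            for nxt in children[node]:
                value = prod * edges[(node, nxt)]
                yield chain + [nxt], value
                stack.append((nxt, chain + [nxt], value))

    for source in nodes:
        for chain, prod in paths_from(source):
            target = chain[-1]
            entry = entries.setdefault(
                (source, target),
                {"direct": 0.0, "indirect": 0.0, "total": 0.0, "mediators": {}})
            if len(chain) == 2:
                entry["direct"] += prod
            else:
                entry["indirect"] += prod
                med = chain[1]
                entry["mediators"][med] = entry["mediators"].get(med, 0.0) + prod
    for entry in entries.values():
        entry["total"] = entry["direct"] + entry["indirect"]
    return EffectsTable(entries=entries)


def effects_decomposition(fit: SemFit) -> EffectsTable:
    """Standardized effect decomposition of a fitted model; totals agree
    with the reduced-form (I - B)^-1 Gamma factorization."""
    if not fit.standardized:
        raise ValueError("standardize the fit first")
    edges = {(s, t): fit.standardized[f"{s}->{t}"]
             for s, t in fit.spec.regressions}
    table = effects_from_edges(edges)
    # cross-check totals against the matrix form
    endo = list(fit.spec.endogenous())
    exo = list(fit.spec.exogenous())
    B = np.zeros((len(endo), len(endo)))
    G = np.zeros((len(endo), len(exo)))
    for (s, t), value in edges.items():
        if s in endo:
            B[endo.index(t), endo.index(s)] = value
        else:
            G[endo.index(t), exo.index(s)] = value
    try:
        total_exo = np.linalg.solve(np.eye(len(endo)) - B, G)
    except np.linalg.LinAlgError:
        raise ValueError("(I - B) singular: cyclic or unidentified model") \
            from None
    for j, x in enumerate(exo):
        for i, y in enumerate(endo):
            expected = float(total_exo[i, j])
            got = table.entries.get((x, y), {"total": 0.0})["total"]
            if abs(expected - got) > 1e-9:
                raise AssertionError(
                    f"effect bookkeeping mismatch for {x}->{y}")
    return table


def select_models(fits: Sequence[SemFit],
                  max_cmin_df: float = 1.0, max_rmsea: float = 0.08,
                  min_agfi: float = 0.9) -> list[SemFit]:
    """Threshold-based selection with strict inequalities; undefined indices
    (just-identified models) fail. Input order is preserved."""
    accepted = []
    for fit in fits:
        if not fit.converged:
            raise ValueError("select_models expects converged fits")
        ok = (fit.cmin_df < max_cmin_df and fit.rmsea < max_rmsea
              and fit.agfi > min_agfi)
        if math.isnan(fit.cmin_df) or math.isnan(fit.rmsea) or math.isnan(fit.agfi):
            ok = False
        if ok:
            accepted.append(fit)
    return accepted
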