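"""Multivariate chemotyping: PCA, hierarchical clustering, OPLS-DA.

All three operate on the samples x variables matrix of a
:class:`~flavopath.sample_io.SampleTable`. Unit-variance scaling is the
default throughout because the analytes span two orders of magnitude in
mg/g; covariance-scale (center-only) PCA is available as a fallback.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .sample_io import SampleTable

__all__ = [
    "PCAResult", "HCAResult", "OPLSDAResult",
    "run_pca", "run_hca", "export_newick", "run_oplsda",
    "altitude_split_labels",
]


def _matrix(table: SampleTable | pd.DataFrame,
            variables: Sequence[str]) -> pd.DataFrame:
    frame = table.matrix(variables) if isinstance(table, SampleTable) else \
        table[list(variables)].astype(float)
    if frame.isna().any().any():
        bad = [v for v in variables if frame[v].isna().any()]
        raise ValueError(
            f"missing cells in {bad}; impute or subset before multivariate "
            "analysis")
    return frame


def _scale(X: np.ndarray, scaling: str) -> np.ndarray:
    X = X - X.mean(axis=0)
    if scaling == "unit_variance":
        sd = X.std(axis=0, ddof=1)
        if np.any(sd == 0):
            raise ValueError("constant column under unit-variance scaling")
        X = X / sd
    elif scaling != "center_only":
        raise ValueError(f"unknown scaling {scaling!r}")
    return X


# ---------------------------------------------------------------- PCA

@dataclass
class PCAResult:
    loadings: pd.DataFrame      # variables x components
    scores: pd.DataFrame        # samples x components
    explained_pct: np.ndarray   # % of total variance per component
    cumulative_pct: np.ndarray


def run_pca(table: SampleTable | pd.DataFrame, variables: Sequence[str],
            scaling: str = "unit_variance") -> PCAResult:
    """PCA by SVD of the scaled, centered matrix.

    Component signs are fixed so that the largest-magnitude entry of every
    loading column is positive, making scores reproducible across BLAS
    implementations.
    """
    frame = _matrix(table, variables)
    if frame.shape[0] < 2 or frame.shape[1] < 2:
        raise ValueError("PCA needs at least 2 samples and 2 variables")
    Z = _scale(frame.to_numpy(float), scaling)
    U, s, Vt = np.linalg.svd(Z, full_matrices=False)
    # deterministic sign: dominant loading entry positive
    for k in range(Vt.shape[0]):
        pivot = np.argmax(np.abs(Vt[k]))
        if Vt[k, pivot] < 0:
            Vt[k] *= -1
            U[:, k] *= -1
    var = s**2
    pct = 100.0 * var / var.sum()
    comps = [f"PC{k + 1}" for k in range(len(s))]
    return PCAResult(
        loadings=pd.DataFrame(Vt.T, index=list(variables), columns=comps),
        scores=pd.DataFrame(U * s, index=frame.index, columns=comps),
        explained_pct=pct,
        cumulative_pct=np.cumsum(pct),
    )


# ---------------------------------------------------------------- HCA

@dataclass
class HCAResult:
    merge_tree: np.ndarray      # scipy linkage matrix
    order: list[str]            # leaf ordering
    labels: list[str]
    scaled_matrix: pd.DataFrame
    linkage: str
    metric: str

    def leaf_sets(self) -> list[frozenset[str]]:
        """The sample set of every internal node (clade partition)."""
        tree = hierarchy.to_tree(self.merge_tree)
        out: list[frozenset[str]] = []

        def collect(node) -> frozenset[str]:
            if node.is_leaf():
                return frozenset({self.labels[node.id]})
            members = collect(node.left) | collect(node.right)
            out.append(members)
            return members

        collect(tree)
        return out


def run_hca(table: SampleTable | pd.DataFrame, variables: Sequence[str],
            metric: str = "euclidean", linkage: str = "complete") -> HCAResult:
    """Agglomerative clustering of samples on unit-variance-scaled variables.

    Ties between equal-distance pairs are broken deterministically by
    scipy's smallest-index convention.
    """
    if linkage not in ("complete", "ward", "average", "single"):
        raise ValueError(f"unsupported linkage {linkage!r}")
    if metric != "euclidean":
        raise ValueError(f"unsupported metric {metric!r}")
    frame = _matrix(table, variables)
    if frame.shape[0] < 2:
        raise ValueError("clustering needs at least 2 samples")
    Z = _scale(frame.to_numpy(float), "unit_variance")
    merge = hierarchy.linkage(pdist(Z, metric=metric), method=linkage)
    labels = list(frame.index)
    order = [labels[i] for i in hierarchy.leaves_list(merge)]
    return HCAResult(
        merge_tree=merge, order=order, labels=labels,
        scaled_matrix=pd.DataFrame(Z, index=frame.index, columns=list(variables)),
        linkage=linkage, metric=metric,
    )


def export_newick(result: HCAResult) -> str:
    """Serialize the dendrogram as an ultrametric newick string.

    Node depth is merge height / 2, so a two-leaf tree merged at height h
    reads ``(A:h/2,B:h/2);``.
    """
    tree = hierarchy.to_tree(result.merge_tree)

    def esc(name: str) -> str:
        return name.replace(" ", "_").replace(",", "_").replace("(", "_") \
                   .replace(")", "_").replace(":", "_").replace(";", "_")

    def render(node, parent_depth: float) -> str:
        depth = node.dist / 2.0
        branch = parent_depth - depth
        if node.is_leaf():
            return f"{esc(result.labels[node.id])}:{branch:.10g}"
        left = render(node.left, depth)
        right = render(node.right, depth)
        return f"({left},{right}):{branch:.10g}"

    root_depth = tree.dist / 2.0
    if tree.is_leaf():
        return f"{esc(result.labels[tree.id])}:0;"
    left = render(tree.left, root_depth)
    right = render(tree.right, root_depth)
    return f"({left},{right});"


# ---------------------------------------------------------------- OPLS-DA

@dataclass
class OPLSDAResult:
    predictive_scores: pd.Series
    predictive_loadings: pd.Series
    orthogonal_scores: pd.DataFrame
    orthogonal_loadings: pd.DataFrame
    r2x: float
    r2y: float
    q2: float
    classes: pd.Series


def altitude_split_labels(table: SampleTable,
                          high_groups: Sequence[str] = ("A", "B")) -> pd.Series:
    """Default two-class chemotype labels: high-altitude groups vs rest."""
    frame = table.to_frame()
    return pd.Series(
        np.where(frame["group"].isin(list(high_groups)), "high", "low"),
        index=frame.index, name="class")


def _opls_components(X: np.ndarray, y: np.ndarray, n_orth: int):
    """Orthogonal-projection deflation; returns deflated X and components."""
    T_orth, P_orth = [], []
    for _ in range(n_orth):
        w = X.T @ y
        w = w / np.linalg.norm(w)
        t = X @ w
        p = X.T @ t / (t @ t)
        w_orth = p - (w @ p) * w
        norm = np.linalg.norm(w_orth)
        if norm < 1e-12:
            raise ValueError("no orthogonal variation left to remove")
        w_orth = w_orth / norm
        t_orth = X @ w_orth
        p_orth = X.T @ t_orth / (t_orth @ t_orth)
        X = X - np.outer(t_orth, p_orth)
        T_orth.append(t_orth)
        P_orth.append(p_orth)
    return X, T_orth, P_orth


def run_oplsda(table: SampleTable | pd.DataFrame, variables: Sequence[str],
               classes: Sequence[str] | pd.Series, n_orth: int = 1,
               scaling: str = "unit_variance", n_folds: int = 7,
               seed: int = 0) -> OPLSDAResult:
    """Two-class OPLS-DA with one predictive component.

    The class vector is coded +/-1 and centered; each orthogonal component
    removes the part of the X variation uncorrelated with class before the
    single predictive component is fitted. Q2 comes from seeded, stratified
    7-fold cross-validation.
    """
    frame = _matrix(table, variables)
    cls = pd.Series(list(classes), index=frame.index)
    levels = sorted(cls.unique())
    if len(levels) != 2:
        raise ValueError(f"OPLS-DA needs exactly 2 classes, got {levels}")
    if min((cls == lv).sum() for lv in levels) < 2:
        raise ValueError("each class needs at least 2 members")
    X0 = _scale(frame.to_numpy(float), scaling)
    if n_orth < 0:
        raise ValueError("n_orth must be >= 0")
    rank = np.linalg.matrix_rank(X0)
    if n_orth >= rank:
        raise ValueError(f"n_orth={n_orth} >= rank(X)={rank}")
    y_raw = np.where(cls.to_numpy() == levels[1], 1.0, -1.0)
    y = y_raw - y_raw.mean()

    X, T_orth, _P_orth = _opls_components(X0.copy(), y, n_orth)
    w = X.T @ y
    w = w / np.linalg.norm(w)
    t = X @ w
    p = X.T @ t / (t @ t)
    q = (y @ t) / (t @ t)

    modeled = np.outer(t, p)
    for t_o, p_o in zip(T_orth, _P_orth):
        modeled = modeled + np.outer(t_o, p_o)
    r2x = 1.0 - float(((X0 - modeled) ** 2).sum() / (X0 ** 2).sum())
    r2y = 1.0 - float(((y - t * q) ** 2).sum() / (y ** 2).sum())
    q2 = _cross_validated_q2(X0, y, n_orth, n_folds, seed)

    comps = [f"ortho{k + 1}" for k in range(n_orth)]
    return OPLSDAResult(
        predictive_scores=pd.Series(t, index=frame.index, name="t_pred"),
        predictive_loadings=pd.Series(p, index=list(variables), name="p_pred"),
        orthogonal_scores=pd.DataFrame(
            np.column_stack(T_orth) if T_orth else np.empty((len(frame), 0)),
            index=frame.index, columns=comps),
        orthogonal_loadings=pd.DataFrame(
            np.column_stack(_P_orth) if _P_orth else np.empty((len(variables), 0)),
            index=list(variables), columns=comps),
        r2x=r2x, r2y=r2y, q2=q2, classes=cls,
    )


def _stratified_folds(y: np.ndarray, n_folds: int, seed: int) -> list[np.ndarray]:
    rng = np.random.default_rng(seed)
    folds: list[list[int]] = [[] for _ in range(n_folds)]
    for sign in (-1, 1):
        idx = np.flatnonzero((y > 0) == (sign > 0))
        rng.shuffle(idx)
        for k, i in enumerate(idx):
            folds[k % n_folds].append(int(i))
    return [np.array(sorted(f)) for f in folds if f]


def _cross_validated_q2(X0: np.ndarray, y: np.ndarray, n_orth: int,
                        n_folds: int, seed: int) -> float:
    press = 0.0
    total = 0.0
    for test in _stratified_folds(y, n_folds, seed):
        train = np.setdiff1d(np.arange(len(y)), test)
        Xtr, ytr = X0[train], y[train]
        Xte = X0[test]
        ytr_c = ytr - ytr.mean()
        try:
            Xd, _, P_orth = _opls_components(Xtr.copy(), ytr_c, n_orth)
        except ValueError:
            continue
        w = Xd.T @ ytr_c
        w = w / np.linalg.norm(w)
        t = Xd @ w
        q = (ytr_c @ t) / (t @ t)
        # apply the same orthogonal filter to the held-out rows
        Xte_d = Xte.copy()
        Xtr_d = Xtr.copy()
        for p_o in P_orth:
            wt = Xtr_d.T @ ytr_c
            wt = wt / np.linalg.norm(wt)
            tt = Xtr_d @ wt
            pp = Xtr_d.T @ tt / (tt @ tt)
            w_orth = pp - (wt @ pp) * wt
            w_orth = w_orth / np.linalg.norm(w_orth)
            t_o_te = Xte_d @ w_orth
            t_o_tr = Xtr_d @ w_orth
            p_o_tr = Xtr_d.T @ t_o_tr / (t_o_tr @ t_o_tr)
            Xte_d = Xte_d - np.outer(t_o_te, p_o_tr)
            Xtr_d = Xtr_d - np.outer(t_o_tr, p_o_tr)
        pred = (Xte_d @ w) * q + ytr.mean()
        press += float(((y[test] - pred) ** 2).sum())
        total += float(((y[test] - ytr.mean()) ** 2).sum())
    return 1.0 - press / total if total > 0 else float("nan")
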