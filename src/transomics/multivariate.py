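"""Multivariate profiling: scaling, HCA, PCA, PLS-DA and OPLS-DA.

Estimators follow the scikit-learn protocol (``fit`` / ``transform``,
``get_params``/``set_params``, fitted attributes with a trailing
underscore) so they compose with sklearn pipelines. The latent-variable
math (PCA by SVD, PLS-DA by NIPALS, OPLS-DA by orthogonal signal
correction) is implemented here; hierarchical clustering delegates the
merge-tree construction to :mod:`scipy.cluster.hierarchy`.

Sign conventions are fixed for reproducibility: every component's
loading/weight vector is flipped so its largest-magnitude entry is
positive.

Discriminant analyses encode classes as centered indicator columns
(two classes: a single centered +/-1 vector). Scaling is the caller's
choice; :func:`autoscale` (unit variance) is the conventional default
for metabolite ROI intensities, ``log2(x+1)`` + autoscaling for RPKM.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from sklearn.base import BaseEstimator, TransformerMixin


def _as_matrix(X) -> np.ndarray:
    A = np.asarray(X.values if hasattr(X, "values") else X, dtype=float)
    if A.ndim != 2 or A.shape[0] < 1 or A.shape[1] < 1:
        raise ValueError("expected a 2-D matrix with at least one row and column")
    if not np.isfinite(A).all():
        raise ValueError("matrix contains non-finite values")
    return A


def _fix_sign(vectors: np.ndarray, companions: list[np.ndarray]) -> None:
    """Flip each column of ``vectors`` (and companions) so max-|entry| > 0."""
    for k in range(vectors.shape[1]):
        j = int(np.argmax(np.abs(vectors[:, k])))
        if vectors[j, k] < 0:
            vectors[:, k] *= -1
            for c in companions:
                c[:, k] *= -1


def zscore_features(matrix: pd.DataFrame) -> pd.DataFrame:
    """Scale each feature row to mean 0, sd 1 (population sd).

    Constant rows become all zeros, with a warning.
    """
    df = matrix.astype(float)
    mu = df.mean(axis=1)
    sd = df.std(axis=1, ddof=0)
    constant = sd == 0
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant feature row(s) z-scored to zeros", stacklevel=2
        )
    sd = sd.replace(0, 1.0)
    return df.sub(mu, axis=0).div(sd, axis=0)


def autoscale(X: np.ndarray) -> np.ndarray:
    """Column-wise unit-variance scaling of a samples x features matrix."""
    A = _as_matrix(X)
    sd = A.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    return (A - A.mean(axis=0)) / sd


def encode_classes(classes) -> tuple[np.ndarray, list]:
    """Centered class indicator matrix (single +/-1 column for two classes)."""
    labels = sorted(set(classes))
    if len(labels) < 2:
        raise ValueError("need at least two classes")
    y = np.asarray(classes)
    if len(labels) == 2:
        Y = np.where(y == labels[1], 1.0, -1.0)[:, None]
    else:
        Y = np.stack([(y == lab).astype(float) for lab in labels], axis=1)
    return Y - Y.mean(axis=0), labels


# ---------------------------------------------------------------------------
# PCA


class PCA(TransformerMixin, BaseEstimator):
    """Principal component analysis by SVD of the column-centered matrix.

    Fitted attributes: ``scores_`` (samples x k), ``loadings_``
    (features x k, orthonormal columns), ``explained_variance_ratio_``,
    ``mean_``.
    """

    def __init__(self, n_components: int | None = None):
        self.n_components = n_components

    def fit(self, X, y=None):
        A = _as_matrix(X)
        n, p = A.shape
        self.mean_ = A.mean(axis=0)
        U, s, Vt = np.linalg.svd(A - self.mean_, full_matrices=False)
        k_max = min(n, p)
        k = k_max if self.n_components is None else min(self.n_components, k_max)
        if not (isinstance(k, (int, np.integer)) and k >= 1):
            raise ValueError(f"n_components must be a positive integer, got {self.n_components!r}")
        loadings = Vt.T[:, :k].copy()
        scores = (U[:, :k] * s[:k]).copy()
        _fix_sign(loadings, [scores])
        self.loadings_ = loadings
        self.scores_ = scores
        var = s**2
        total = var.sum()
        self.explained_variance_ratio_ = var[:k] / total if total > 0 else np.zeros(k)
        self.singular_values_ = s[:k].copy()
        return self

    def transform(self, X):
        return (_as_matrix(X) - self.mean_) @ self.loadings_

    def inverse_transform(self, scores):
        return np.asarray(scores) @ self.loadings_.T + self.mean_


# ---------------------------------------------------------------------------
# PLS-DA (NIPALS)


class PLSDA(BaseEstimator):
    """Partial least squares discriminant analysis via NIPALS.

    X is column-centered and regressed onto a centered class-indicator Y;
    components are extracted iteratively with deflation of both blocks.
    Fitted attributes: ``x_scores_``, ``x_weights_``, ``x_loadings_``,
    ``y_loadings_``, ``classes_``.
    """

    def __init__(self, n_components: int = 2, max_iter: int = 500, tol: float = 1e-10):
        self.n_components = n_components
        self.max_iter = max_iter
        self.tol = tol

    def fit(self, X, y):
        A = _as_matrix(X)
        Y, self.classes_ = encode_classes(y)
        if A.shape[0] != Y.shape[0]:
            raise ValueError("X and y have different numbers of samples")
        counts = pd.Series(list(y)).value_counts()
        if (counts < 2).any():
            raise ValueError("every class needs at least two samples")
        self.x_mean_ = A.mean(axis=0)
        Xc = A - self.x_mean_
        Yc = Y.copy()
        n, p = Xc.shape
        k = min(self.n_components, n - 1, p)
        W, T, P, Q = [], [], [], []
        for _ in range(k):
            u = Yc[:, int(np.argmax(Yc.var(axis=0)))].copy()
            w = np.zeros(p)
            for _ in range(self.max_iter):
                w_new = Xc.T @ u
                norm = np.linalg.norm(w_new)
                if norm == 0:
                    break
                w_new /= norm
                t = Xc @ w_new
                q = Yc.T @ t / (t @ t)
                qn = np.linalg.norm(q)
                u = (Yc @ q / (q @ q)) if qn > 0 else u
                if np.linalg.norm(w_new - w) < self.tol:
                    w = w_new
                    break
                w = w_new
            t = Xc @ w
            tt = t @ t
            if tt == 0:
                break
            pvec = Xc.T @ t / tt
            q = Yc.T @ t / tt
            Xc = Xc - np.outer(t, pvec)
            Yc = Yc - np.outer(t, q)
            W.append(w)
            T.append(t)
            P.append(pvec)
            Q.append(q)
        self.x_weights_ = np.array(W).T
        self.x_scores_ = np.array(T).T
        self.x_loadings_ = np.array(P).T
        self.y_loadings_ = np.array(Q).T
        # sign flips propagate through t = Xc w, p = Xc't/t't and q = Yc't/t't
        _fix_sign(self.x_weights_, [self.x_scores_, self.x_loadings_, self.y_loadings_])
        return self

    def transform(self, X):
        Xc = _as_matrix(X) - self.x_mean_
        T = np.zeros((Xc.shape[0], self.x_weights_.shape[1]))
        for a in range(self.x_weights_.shape[1]):
            t = Xc @ self.x_weights_[:, a]
            T[:, a] = t
            Xc = Xc - np.outer(t, self.x_loadings_[:, a])
        return T

    def predict(self, X):
        T = self.transform(X)
        Yhat = T @ self.y_loadings_.T
        if len(self.classes_) == 2:
            return np.array([self.classes_[1] if v > 0 else self.classes_[0] for v in Yhat[:, 0]])
        return np.array([self.classes_[int(i)] for i in np.argmax(Yhat, axis=1)])


# ---------------------------------------------------------------------------
# OPLS-DA (orthogonal signal correction, two classes)


class OPLSDA(BaseEstimator):
    """Orthogonal PLS-DA: split X into class-predictive and class-orthogonal parts.

    Two-class only. ``n_ortho`` orthogonal components are stripped by
    orthogonal signal correction; one predictive component (the T score)
    is then extracted from the filtered matrix. With ``n_ortho=0`` the
    predictive component coincides with PLS-DA component 1.

    Fitted attributes: ``t_scores_`` (predictive), ``p_pred_``, ``w_pred_``,
    ``ortho_scores_`` (samples x n_ortho), ``ortho_loadings_``,
    ``ortho_weights_``, ``classes_``.
    """

    def __init__(self, n_ortho: int = 1):
        self.n_ortho = n_ortho

    def fit(self, X, y):
        if self.n_ortho < 0:
            raise ValueError("n_ortho must be >= 0")
        A = _as_matrix(X)
        Y, self.classes_ = encode_classes(y)
        if Y.shape[1] != 1:
            raise ValueError("OPLS-DA supports exactly two classes")
        yv = Y[:, 0]
        self.x_mean_ = A.mean(axis=0)
        Xc = A - self.x_mean_
        T_o, P_o, W_o = [], [], []
        for _ in range(self.n_ortho):
            w = Xc.T @ yv / (yv @ yv)
            w /= np.linalg.norm(w)
            t = Xc @ w
            p = Xc.T @ t / (t @ t)
            w_o = p - (w @ p) * w
            norm = np.linalg.norm(w_o)
            if norm < 1e-12:
                break
            w_o /= norm
            t_o = Xc @ w_o
            p_o = Xc.T @ t_o / (t_o @ t_o)
            Xc = Xc - np.outer(t_o, p_o)
            T_o.append(t_o)
            P_o.append(p_o)
            W_o.append(w_o)
        w = Xc.T @ yv / (yv @ yv)
        w /= np.linalg.norm(w)
        w_mat = w[:, None]
        t_mat = (Xc @ w)[:, None]
        _fix_sign(w_mat, [t_mat])
        self.w_pred_ = w_mat[:, 0]
        self.t_scores_ = t_mat[:, 0]
        self.p_pred_ = Xc.T @ self.t_scores_ / (self.t_scores_ @ self.t_scores_)
        self.ortho_scores_ = np.array(T_o).T if T_o else np.zeros((A.shape[0], 0))
        self.ortho_loadings_ = np.array(P_o).T if P_o else np.zeros((A.shape[1], 0))
        self.ortho_weights_ = np.array(W_o).T if W_o else np.zeros((A.shape[1], 0))
        self.y_ = yv
        return self

    def transform(self, X):
        Xc = _as_matrix(X) - self.x_mean_
        for a in range(self.ortho_weights_.shape[1]):
            t_o = Xc @ self.ortho_weights_[:, a]
            Xc = Xc - np.outer(t_o, self.ortho_loadings_[:, a])
        return (Xc @ self.w_pred_)[:, None]


# ---------------------------------------------------------------------------
# Hierarchical clustering


class HierarchicalClustering(BaseEstimator):
    """Agglomerative clustering (default: Euclidean distance, complete linkage).

    Fitted attributes: ``linkage_`` (scipy merge-tree, heights
    non-decreasing), ``leaf_order_`` (dendrogram leaf permutation),
    ``labels_`` after :meth:`cut`.
    """

    def __init__(self, metric: str = "euclidean", linkage: str = "complete"):
        self.metric = metric
        self.linkage = linkage

    def fit(self, X, y=None):
        A = _as_matrix(X)
        if A.shape[0] < 2:
            raise ValueError("clustering needs at least two rows")
        self.linkage_ = hierarchy.linkage(A, method=self.linkage, metric=self.metric)
        self.leaf_order_ = hierarchy.leaves_list(self.linkage_)
        self.n_leaves_ = A.shape[0]
        return self

    def cut(self, k: int) -> np.ndarray:
        if not 1 <= k <= self.n_leaves_:
            raise ValueError(f"k must be in [1, {self.n_leaves_}]")
        self.labels_ = hierarchy.cut_tree(self.linkage_, n_clusters=k)[:, 0]
        return self.labels_

    def to_newick(self, leaf_names=None) -> str:
        """Dendrogram as a Newick string with merge heights as branch lengths."""
        tree = hierarchy.to_tree(self.linkage_)
        names = (
            [str(x) for x in leaf_names]
            if leaf_names is not None
            else [f"leaf{i}" for i in range(self.n_leaves_)]
        )

        def rec(node, parent_height):
            length = parent_height - node.dist
            if node.is_leaf():
                return f"{names[node.id]}:{length:.10g}"
            left = rec(node.left, node.dist)
            right = rec(node.right, node.dist)
            return f"({left},{right}):{length:.10g}"

        return f"({rec(tree.left, tree.dist)},{rec(tree.right, tree.dist)});"


@dataclass
class ClusterResult:
    """Merge tree + leaf order, the exportable clustering summary."""

    linkage: np.ndarray
    leaf_order: np.ndarray
    model: HierarchicalClustering

    def cut(self, k: int) -> np.ndarray:
        return self.model.cut(k)

    def to_newick(self, leaf_names=None) -> str:
        return self.model.to_newick(leaf_names)


# ---------------------------------------------------------------------------
# Thin functional wrappers


def pca(matrix, n_components: int | None = None) -> PCA:
    """Fit :class:`PCA` on a samples x features matrix."""
    return PCA(n_components=n_components).fit(matrix)


def plsda(matrix, classes, n_components: int = 2) -> PLSDA:
    return PLSDA(n_components=n_components).fit(matrix, classes)


def oplsda(matrix, classes, n_ortho: int = 1) -> OPLSDA:
    return OPLSDA(n_ortho=n_ortho).fit(matrix, classes)


def hca(matrix, metric: str = "euclidean", linkage: str = "complete") -> ClusterResult:
    model = HierarchicalClustering(metric=metric, linkage=linkage).fit(matrix)
    return ClusterResult(linkage=model.linkage_, leaf_order=model.leaf_order_, model=model)
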