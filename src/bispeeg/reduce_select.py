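"""Locality sensitive discriminant analysis (LSDA) and t-test feature selection.

LSDA is a supervised linear reduction that preserves *local* class
structure: a k-nearest-neighbour graph is split, per neighbourhood, into
same-label and different-label edges (weight matrices Ww and Wb), and the
projection maximises the locally-weighted between-class margin against
within-class compactness through the generalized eigenproblem

    X (alpha Lb + (1 - alpha) Ww) X^T a  =  lambda X Dw X^T a,

with Lb = Db - Wb and X the centred data matrix (features x samples).
The top-d eigenvectors form the projection basis; reduced columns are named
LSDA1..LSDAd in decreasing-eigenvalue order.

Selection afterwards is a per-component two-sample Welch t-test (unequal
variances, Welch-Satterthwaite degrees of freedom); components with
p >= 0.05 are discarded and the survivors ranked by ascending p.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

__all__ = [
    "FeatureMatrix",
    "LSDAModel",
    "TTestResult",
    "lsda_fit",
    "lsda_transform",
    "welch_t_from_summary",
    "ttest_rank",
    "select_features",
]


@dataclass
class FeatureMatrix:
    """Stacked per-sample feature matrix with class labels."""

    X: np.ndarray  # (n_samples, n_features)
    labels: np.ndarray  # (n_samples,) class label per sample
    sample_ids: list[str] | None = None
    feature_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-D (samples x features)")
        if len(self.labels) != self.X.shape[0]:
            raise ValueError("one label per sample required")
        if not np.isfinite(self.X).all():
            raise ValueError("feature matrix contains non-finite values")
        if self.X.shape[0] < 4 or len(np.unique(self.labels)) < 2:
            raise ValueError("need >= 4 samples with both classes present")


@dataclass
class LSDAModel:
    """Fitted LSDA projection basis (columns ordered by decreasing eigenvalue)."""

    projection: np.ndarray  # (n_features, d)
    mean: np.ndarray  # (n_features,) training mean subtracted before projecting
    eigenvalues: np.ndarray  # (d,) decreasing
    k: int
    alpha: float
    Ww: np.ndarray
    Wb: np.ndarray

    @property
    def d(self) -> int:
        return self.projection.shape[1]


def _knn_indices(X: np.ndarray, k: int) -> np.ndarray:
    """Indices of the k nearest neighbours (excluding self) per row.

    Euclidean distances; ties broken by sample index for determinism.
    """
    d2 = np.sum((X[:, None, :] - X[None, :, :]) ** 2, axis=2)
    np.fill_diagonal(d2, np.inf)
    order = np.argsort(d2, axis=1, kind="stable")
    return order[:, :k]


def lsda_fit(
    data: FeatureMatrix | np.ndarray,
    labels: np.ndarray | None = None,
    k: int = 5,
    alpha: float = 0.5,
    d: int = 30,
    ridge: float = 1e-8,
) -> LSDAModel:
    """Fit the LSDA projection on labelled samples.

    ``d`` must not exceed min(n_features, n_samples - 1); callers that want
    "as many components as possible" should clamp before calling.  A
    singular constraint matrix triggers automatic ridge regularization
    (logged), never a silent failure.
    """
    if isinstance(data, FeatureMatrix):
        X, y = data.X, data.labels
    else:
        X = np.asarray(data, dtype=float)
        y = np.asarray(labels)
    n, D = X.shape
    if len(np.unique(y)) < 2:
        raise ValueError("LSDA needs samples from both classes")
    if not 1 <= k < n:
        raise ValueError(f"k={k} must satisfy 1 <= k < n_samples={n}")
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    d_max = min(D, n - 1)
    if d > d_max:
        raise ValueError(f"d={d} exceeds min(n_features, n_samples - 1) = {d_max}")

    mean = X.mean(axis=0)
    Xc = X - mean

    nbrs = _knn_indices(Xc, k)
    Ww = np.zeros((n, n))
    Wb = np.zeros((n, n))
    for i in range(n):
        for j in nbrs[i]:
            if y[i] == y[j]:
                Ww[i, j] = Ww[j, i] = 1.0
            else:
                Wb[i, j] = Wb[j, i] = 1.0

    Dw = np.diag(Ww.sum(axis=1))
    Db = np.diag(Wb.sum(axis=1))
    Lb = Db - Wb

    M = alpha * Lb + (1.0 - alpha) * Ww
    A = Xc.T @ M @ Xc
    B = Xc.T @ Dw @ Xc
    A = (A + A.T) / 2.0
    B = (B + B.T) / 2.0

    from scipy.linalg import eigh as geigh

    scale = np.trace(B) / D if np.trace(B) > 0 else 1.0
    reg = ridge * scale
    for attempt in range(12):
        try:
            w, V = geigh(A, B + reg * np.eye(D))
            break
        except np.linalg.LinAlgError:
            log.warning("singular constraint matrix in LSDA; raising ridge to %.3g", reg * 100)
            reg *= 100.0
    else:
        raise np.linalg.LinAlgError("LSDA constraint matrix singular despite regularization")
    if reg > ridge * scale:
        log.info("LSDA used ridge regularization %.3g on the constraint matrix", reg)

    idx = np.argsort(w, kind="stable")[::-1][:d]
    eigvals = w[idx]
    basis = V[:, idx]
    # deterministic sign: largest-magnitude coefficient of each direction positive
    for c in range(basis.shape[1]):
        j = np.argmax(np.abs(basis[:, c]))
        if basis[j, c] < 0:
            basis[:, c] = -basis[:, c]
    return LSDAModel(projection=basis, mean=mean, eigenvalues=eigvals,
                     k=k, alpha=alpha, Ww=Ww, Wb=Wb)


def lsda_transform(model: LSDAModel, X: np.ndarray) -> pd.DataFrame:
    """Project samples onto the fitted basis; columns named LSDA1..LSDAd."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != model.projection.shape[0]:
        raise ValueError(
            f"X has {X.shape[1] if X.ndim == 2 else '?'} features; "
            f"model expects {model.projection.shape[0]}"
        )
    Z = (X - model.mean) @ model.projection
    return pd.DataFrame(Z, columns=[f"LSDA{j + 1}" for j in range(model.d)])


def welch_t_from_summary(
    mean1: float, sd1: float, n1: int,
    mean2: float, sd2: float, n2: int,
) -> tuple[float, float, float]:
    """Welch two-sample t from group summaries: (|t|, two-sided p, df).

    t = |mean2 - mean1| / sqrt(sd1^2/n1 + sd2^2/n2) with Welch-Satterthwaite
    degrees of freedom.  Degenerate groups (both sd = 0, equal means) give
    t = 0, p = 1.
    """
    if sd1 < 0 or sd2 < 0:
        raise ValueError("standard deviations must be >= 0")
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    v1 = sd1**2 / n1
    v2 = sd2**2 / n2
    se2 = v1 + v2
    if se2 == 0.0:
        if mean1 == mean2:
            return 0.0, 1.0, float(n1 + n2 - 2)
        return float("inf"), 0.0, float(n1 + n2 - 2)
    t = abs(mean2 - mean1) / np.sqrt(se2)
    df = se2**2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    p = 2.0 * stats.t.sf(t, df)
    return float(t), float(p), float(df)


@dataclass
class TTestResult:
    """Per-feature Welch t-test summary over two classes."""

    feature_names: list[str]
    class_names: tuple[str, str]
    mean1: np.ndarray
    sd1: np.ndarray
    mean2: np.ndarray
    sd2: np.ndarray
    t: np.ndarray
    p: np.ndarray
    df: np.ndarray
    constant_features: list[str] = field(default_factory=list)

    @property
    def rank(self) -> np.ndarray:
        """Feature indices sorted by ascending p (stable for ties)."""
        return np.argsort(self.p, kind="stable")

    def to_frame(self) -> pd.DataFrame:
        c1, c2 = self.class_names
        return pd.DataFrame({
            "feature": self.feature_names,
            f"mean_{c1}": self.mean1, f"sd_{c1}": self.sd1,
            f"mean_{c2}": self.mean2, f"sd_{c2}": self.sd2,
            "p_value": self.p, "t_value": self.t, "df": self.df,
        })


def ttest_rank(
    Z: pd.DataFrame | np.ndarray,
    labels: np.ndarray,
    class_order: tuple[str, str] | None = None,
) -> TTestResult:
    """Column-wise Welch t-test of a (reduced) feature matrix.

    Exactly consistent with :func:`welch_t_from_summary` applied to each
    column's own summary statistics (ddof-1 standard deviations).
    """
    if isinstance(Z, pd.DataFrame):
        names = [str(c) for c in Z.columns]
        X = Z.to_numpy(dtype=float)
    else:
        X = np.asarray(Z, dtype=float)
        names = [f"LSDA{j + 1}" for j in range(X.shape[1])]
    labels = np.asarray(labels)
    uniq = list(dict.fromkeys(labels.tolist()))
    if class_order is not None:
        uniq = list(class_order)
    if len(uniq) != 2:
        raise ValueError(f"need exactly two classes, got {uniq}")
    g1 = X[labels == uniq[0]]
    g2 = X[labels == uniq[1]]
    if len(g1) < 2 or len(g2) < 2:
        raise ValueError("each class needs at least 2 samples")

    n_feat = X.shape[1]
    m1 = np.empty(n_feat); s1 = np.empty(n_feat)
    m2 = np.empty(n_feat); s2 = np.empty(n_feat)
    t = np.empty(n_feat)
    p = np.empty(n_feat)
    df = np.empty(n_feat)
    constant = []
    for j in range(n_feat):
        # column-wise summaries so the result is bit-identical to calling
        # welch_t_from_summary on that column's own statistics
        m1[j], s1[j] = g1[:, j].mean(), g1[:, j].std(ddof=1)
        m2[j], s2[j] = g2[:, j].mean(), g2[:, j].std(ddof=1)
        t[j], p[j], df[j] = welch_t_from_summary(
            m1[j], s1[j], len(g1), m2[j], s2[j], len(g2)
        )
        if s1[j] == 0.0 and s2[j] == 0.0 and m1[j] == m2[j]:
            constant.append(names[j])
    if constant:
        log.info("constant features (t=0, p=1): %s", constant)
    return TTestResult(
        feature_names=names, class_names=(str(uniq[0]), str(uniq[1])),
        mean1=m1, sd1=s1, mean2=m2, sd2=s2, t=t, p=p, df=df,
        constant_features=constant,
    )


def select_features(result: TTestResult, p_threshold: float = 0.05) -> list[int]:
    """Indices of features with p < threshold, ordered by ascending p."""
    order = result.rank
    return [int(j) for j in order if result.p[j] < p_threshold]
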