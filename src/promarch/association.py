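"""Correlation machinery linking promoter architecture to expression.

Covers plain correlations with their t-form test statistics, Spearman
partial correlations via the precision matrix of rank-transformed columns,
the promoter-shuffle permutation null (the correlation's t-statistic against
datasets with randomized promoter/transcript assignments), hierarchical
clustering with 1 - r as the distance, and the radial-kernel support-vector
predictor of breadth/PEM with its scrambled (negative) and retained
(positive) controls.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from sklearn.metrics import roc_auc_score
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC, SVR

__all__ = [
    "CorrelationResult",
    "NullDistribution",
    "PredictorReport",
    "ClusterResult",
    "correlate",
    "partial_correlation",
    "shuffle_null",
    "cluster_by_correlation",
    "fit_predictor",
]

_METHODS = ("pearson", "spearman", "kendall")


@dataclass(frozen=True)
class CorrelationResult:
    method: str
    r: float
    t: float
    df: int
    p: float
    n: int
    constant_input: bool = False  # r undefined: one vector was constant


@dataclass(frozen=True)
class NullDistribution:
    observed_stat: float
    replicates: np.ndarray
    n_reps: int
    seed: int | None
    empirical_p: float


@dataclass(frozen=True)
class PredictorReport:
    mode: str
    r_prediction: float
    r_scrambled: float
    r_retained: float
    auc: float | None
    split_seed: int | None
    hyperparameters: dict = field(default_factory=dict)


@dataclass(frozen=True)
class ClusterResult:
    linkage: np.ndarray
    labels: tuple[str, ...]
    leaf_order: tuple[str, ...]
    distance: pd.DataFrame

    def to_newick(self) -> str:
        tree = hierarchy.to_tree(self.linkage)

        def rec(node) -> str:
            if node.is_leaf():
                return self.labels[node.id]
            left, right = rec(node.left), rec(node.right)
            dl = node.dist - node.left.dist
            dr = node.dist - node.right.dist
            return f"({left}:{dl:.6g},{right}:{dr:.6g})"

        return rec(tree) + ";"


def _safe_corr(x: np.ndarray, y: np.ndarray, method: str) -> float:
    if method == "pearson":
        return float(stats.pearsonr(x, y).statistic)
    if method == "spearman":
        return float(stats.spearmanr(x, y).statistic)
    return float(stats.kendalltau(x, y).statistic)


def correlate(
    x: Sequence[float] | np.ndarray,
    y: Sequence[float] | np.ndarray,
    method: str = "pearson",
) -> CorrelationResult:
    """Correlation with the t-form test (pearson/spearman) or the normal
    approximation (kendall).

    For pearson and spearman, t = r * sqrt((n-2)/(1-r^2)) on n-2 degrees of
    freedom.  A constant input vector leaves the coefficient undefined and is
    flagged rather than raising.
    """
    if method not in _METHODS:
        raise ValueError(f"method must be one of {_METHODS}")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 paired non-missing observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return CorrelationResult(method, float("nan"), float("nan"), n - 2, float("nan"), n, True)

    if method == "kendall":
        res = stats.kendalltau(x, y)
        return CorrelationResult(method, float(res.statistic), float("nan"), n - 2, float(res.pvalue), n)
    r = _safe_corr(x, y, method)
    if abs(r) >= 1.0:
        t = math.copysign(float("inf"), r)
        p = 0.0
    else:
        t = r * math.sqrt((n - 2) / (1 - r * r))
        p = 2 * stats.t.sf(abs(t), df=n - 2)
    return CorrelationResult(method, r, t, n - 2, float(p), n)


def partial_correlation(
    table: pd.DataFrame,
    target_col: str,
    other_col: str,
    control_cols: Sequence[str] = (),
) -> float:
    """Spearman partial correlation of two columns given a control set.

    All columns are rank-transformed, the correlation matrix of
    [target, other, controls] is inverted, and the partial correlation is
    read off the precision matrix.  With an empty control set this equals
    the plain Spearman correlation.
    """
    cols = [target_col, other_col, *control_cols]
    sub = table[cols].dropna()
    if len(sub) < len(control_cols) + 3:
        raise ValueError("too few complete rows for the requested control set")
    ranks = sub.rank().to_numpy()
    corr = np.corrcoef(ranks, rowvar=False)
    try:
        prec = np.linalg.inv(corr)
    except np.linalg.LinAlgError:
        sing = _collinear_columns(sub)
        raise ValueError(f"singular correlation matrix; collinear columns: {sing}") from None
    return float(-prec[0, 1] / math.sqrt(prec[0, 0] * prec[1, 1]))


def _collinear_columns(sub: pd.DataFrame) -> list[str]:
    bad = [c for c in sub.columns if sub[c].nunique() == 1]
    if bad:
        return bad
    cm = sub.rank().corr().to_numpy()
    names = list(sub.columns)
    out = set()
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            if abs(cm[i, j]) > 1 - 1e-12:
                out.update((names[i], names[j]))
    return sorted(out)


def shuffle_null(
    tfbs_counts: Sequence[float] | np.ndarray,
    boe: Sequence[float] | np.ndarray,
    n_reps: int = 1000,
    seed: int | None = None,
    method: str = "pearson",
) -> NullDistribution:
    """Permutation null for the architecture-breadth correlation.

    Each replicate permutes the promoter count vector (a random reassignment
    of promoters to transcripts, sampling without replacement) and records
    the correlation's t-statistic.  The empirical two-sided p-value carries
    the +1 pseudocount: p = (1 + #{|t_rep| >= |t_obs|}) / (1 + n_reps).
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    x = np.asarray(tfbs_counts, dtype=float)
    y = np.asarray(boe, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")
    rng = np.random.default_rng(seed)
    observed = correlate(x, y, method).t
    reps = np.empty(n_reps)
    for i in range(n_reps):
        reps[i] = correlate(rng.permutation(x), y, method).t
    emp_p = (1 + int(np.sum(np.abs(reps) >= abs(observed)))) / (1 + n_reps)
    return NullDistribution(float(observed), reps, n_reps, seed, float(emp_p))


def cluster_by_correlation(matrix: pd.DataFrame, method: str = "pearson") -> ClusterResult:
    """Average-linkage agglomerative clustering of columns at distance 1 - r.

    Columns are ordered by name first so leaf order is deterministic under
    ties; a constant column (undefined correlation) raises.
    """
    if method not in _METHODS:
        raise ValueError(f"method must be one of {_METHODS}")
    if matrix.shape[1] < 2:
        raise ValueError("need at least 2 columns")
    df = matrix[sorted(matrix.columns)]
    const = [c for c in df.columns if df[c].nunique() <= 1]
    if const:
        raise ValueError(f"constant column(s): {const}")
    corr = df.corr(method=method)
    dist = 1.0 - corr
    cond = hierarchy.distance.squareform(dist.to_numpy(), checks=False)
    Z = hierarchy.linkage(cond, method="average")
    leaves = hierarchy.leaves_list(Z)
    labels = tuple(df.columns)
    return ClusterResult(Z, labels, tuple(labels[i] for i in leaves), dist)


def _pearson_or_zero(a: np.ndarray, b: np.ndarray) -> float:
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def fit_predictor(
    features: pd.DataFrame | np.ndarray,
    response: Sequence[float] | np.ndarray,
    mode: str = "regression",
    hyperparams: Mapping[str, float] | None = None,
    split_seed: int | None = None,
) -> PredictorReport:
    """Radial-kernel SVM predictor of breadth (or PEM) from TF count vectors.

    The data are split in half at random; features are scaled/centred on the
    training half.  In regression mode accuracy is the Pearson correlation
    between predicted and observed response on the held-out half (the
    response is standardized internally for the fit and back-transformed).
    In binary mode the response is dichotomized at BoE 0.33 (narrow vs not)
    and accuracy is the ROC AUC averaged over 10 random half splits.

    Two controls reuse the same split: *scrambled* permutes the training
    response (negative control, expect r near 0) and *retained* adds the
    response itself as a feature (positive control, expect r near 1).
    """
    hp = {"cost": 1.0, "gamma": 0.01, "epsilon": 0.1}
    if hyperparams:
        hp.update(hyperparams)
    X = features.to_numpy(dtype=float) if isinstance(features, pd.DataFrame) else np.asarray(features, dtype=float)
    y = np.asarray(response, dtype=float)
    n = len(y)
    if n < 50:
        raise ValueError("fewer than 50 rows: the half/half split is too small")
    if mode not in ("regression", "binary"):
        raise ValueError("mode must be 'regression' or 'binary'")
    rng = np.random.default_rng(split_seed)

    def half_split(r):
        idx = r.permutation(n)
        half = n // 2
        return idx[:half], idx[half:]

    def run_regression(Xf: np.ndarray, yv: np.ndarray, train, test, scramble=False) -> float:
        ytr = yv[train].copy()
        if scramble:
            ytr = rng.permutation(ytr)
        xscaler = StandardScaler().fit(Xf[train])
        ym, ys = ytr.mean(), ytr.std()
        ys = ys if ys > 0 else 1.0
        model = SVR(kernel="rbf", C=hp["cost"], gamma=hp["gamma"], epsilon=hp["epsilon"])
        model.fit(xscaler.transform(Xf[train]), (ytr - ym) / ys)
        pred = model.predict(xscaler.transform(Xf[test])) * ys + ym
        return _pearson_or_zero(pred, yv[test])

    train, test = half_split(rng)
    if mode == "regression":
        r_pred = run_regression(X, y, train, test)
        r_scram = run_regression(X, y, train, test, scramble=True)
        X_ret = np.column_stack([X, y])
        r_ret = run_regression(X_ret, y, train, test)
        return PredictorReport("regression", r_pred, r_scram, r_ret, None, split_seed, dict(hp))

    # binary: narrow (BoE <= 0.33) vs not
    lab = (y > 0.33).astype(int)
    if lab.min() == lab.max():
        raise ValueError("binary response is constant at the 0.33 cutoff")

    def run_binary(Xf: np.ndarray, lv: np.ndarray, train, test, scramble=False) -> float:
        ltr = lv[train].copy()
        if scramble:
            ltr = rng.permutation(ltr)
        if ltr.min() == ltr.max():
            return 0.5
        xscaler = StandardScaler().fit(Xf[train])
        model = SVC(kernel="rbf", C=hp["cost"], gamma=hp["gamma"])
        model.fit(xscaler.transform(Xf[train]), ltr)
        score = model.decision_function(xscaler.transform(Xf[test]))
        return float(roc_auc_score(lv[test], score))

    aucs, aucs_scram, aucs_ret = [], [], []
    for _ in range(10):
        tr, te = half_split(rng)
        aucs.append(run_binary(X, lab, tr, te))
        aucs_scram.append(run_binary(X, lab, tr, te, scramble=True))
        aucs_ret.append(run_binary(np.column_stack([X, lab]), lab, tr, te))
    return PredictorReport(
        "binary",
        r_prediction=float(np.mean(aucs)),
        r_scrambled=float(np.mean(aucs_scram)),
        r_retained=float(np.mean(aucs_ret)),
        auc=float(np.mean(aucs)),
        split_seed=split_seed,
        hyperparameters=dict(hp),
    )
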