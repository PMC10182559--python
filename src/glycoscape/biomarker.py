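"""Supervised biomarker scoring: PLS-DA with VIP selection and ROC analysis.

The discriminant route follows the common metabolomics recipe: log10 +
autoscale normalization, NIPALS PLS1 against a +/-1-coded response, VIP
(variable importance in projection) feature selection at a threshold of
1.5, univariate rank-based AUC, and a cross-validated multivariate AUC
using an L2-regularized linear margin classifier with weight-based feature
ranking.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.svm import LinearSVC

__all__ = [
    "log_autoscale",
    "plsda",
    "vip_scores",
    "roc_univariate",
    "roc_multivariate",
    "PLSDAResult",
]


def log_autoscale(X, pseudo_count: float | None = None):
    """log10(x + pseudo) then per-feature centering and unit-variance scaling.

    The pseudo-count defaults to half the smallest nonzero matrix entry.
    Zero-variance features (after log) are dropped; the returned mask marks
    survivors.  Output columns have mean 0 and variance 1.
    """
    X = np.asarray(X, dtype=np.float64)
    if (X < 0).any():
        raise ValueError("intensities must be nonnegative")
    if pseudo_count is None:
        nz = X[X > 0]
        pseudo_count = float(nz.min()) / 2.0 if nz.size else 1.0
    L = np.log10(X + pseudo_count)
    # exact-range test: std of a constant column is ~1e-16, not 0
    keep = np.ptp(L, axis=0) > 0
    L = L[:, keep]
    Z = (L - L.mean(axis=0)) / L.std(axis=0, ddof=1)
    return Z, keep


@dataclass
class PLSDAResult:
    scores: np.ndarray               # samples x components
    loadings: np.ndarray             # features x components
    weights: np.ndarray              # features x components
    y_variance: np.ndarray           # per-component explained y-variance
    vip: np.ndarray
    selected: np.ndarray             # feature indices with VIP > threshold
    vip_threshold: float
    ellipses: dict = field(default_factory=dict)


def _nipals_pls1(X: np.ndarray, y: np.ndarray, n_components: int):
    """NIPALS PLS1: deterministic deflation-based fit for a single response."""
    Xk = X.copy()
    yk = y.astype(np.float64).copy()
    n, p = X.shape
    W = np.zeros((p, n_components))
    P = np.zeros((p, n_components))
    T = np.zeros((n, n_components))
    ss_y = np.zeros(n_components)
    for a in range(n_components):
        w = Xk.T @ yk
        norm = np.linalg.norm(w)
        if norm < 1e-12:
            W, P, T, ss_y = W[:, :a], P[:, :a], T[:, :a], ss_y[:a]
            break
        w /= norm
        t = Xk @ w
        tt = t @ t
        if tt < 1e-12:
            W, P, T, ss_y = W[:, :a], P[:, :a], T[:, :a], ss_y[:a]
            break
        p_load = Xk.T @ t / tt
        q = yk @ t / tt
        Xk = Xk - np.outer(t, p_load)
        yk = yk - q * t
        W[:, a], P[:, a], T[:, a] = w, p_load, t
        ss_y[a] = (q * q) * tt  # y sum of squares explained by component a
    return W, P, T, ss_y


def vip_scores(W: np.ndarray, ss_y: np.ndarray) -> np.ndarray:
    """VIP_j = sqrt(p * sum_a ssy_a (w_ja/||w_a||)^2 / sum_a ssy_a).

    The mean of squared VIPs is exactly 1 for any fit.
    """
    p, A = W.shape
    wnorm2 = (W**2).sum(axis=0)
    wnorm2[wnorm2 == 0] = 1.0
    contrib = (W**2) / wnorm2
    total = ss_y.sum()
    if total <= 0:
        return np.ones(p)
    return np.sqrt(p * (contrib @ ss_y) / total)


def plsda(
    X,
    y,
    n_components: int = 2,
    vip_threshold: float = 1.5,
) -> PLSDAResult:
    """PLS-DA on a normalized matrix against binary labels.

    ``y`` may hold any two distinct values; they are coded -1/+1 in sorted
    order.  95% confidence ellipses of the 2-D scores are computed per class
    from the score covariance at the chi-squared (2 df) quantile.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError(f"plsda needs exactly 2 classes, got {len(classes)}")
    if n_components >= min(X.shape):
        raise ValueError("n_components must be below matrix rank bound")
    yc = np.where(y == classes[0], -1.0, 1.0)
    yc = yc - yc.mean()

    W, P, T, ss_y = _nipals_pls1(X, yc, n_components)
    vip = vip_scores(W, ss_y)
    selected = np.flatnonzero(vip > vip_threshold)

    ellipses = {}
    if T.shape[1] >= 2:
        q = stats.chi2.ppf(0.95, df=2)
        for cls in classes:
            S = T[y == cls, :2]
            if len(S) >= 3:
                cov = np.cov(S, rowvar=False)
                evals, evecs = np.linalg.eigh(cov)
                ellipses[cls] = {
                    "center": S.mean(axis=0),
                    "axes": np.sqrt(np.clip(evals, 0, None) * q),
                    "rotation": evecs,
                }
    return PLSDAResult(
        scores=T,
        loadings=P,
        weights=W,
        y_variance=ss_y,
        vip=vip,
        selected=selected,
        vip_threshold=vip_threshold,
        ellipses=ellipses,
    )


def roc_univariate(values, y) -> tuple[float, np.ndarray]:
    """Rank-based AUC and ROC points for one feature against binary labels.

    AUC = Mann-Whitney U / (n_pos * n_neg) with midrank tie handling; the
    ROC curve is the tie-aware step function from (0,0) to (1,1).  The
    positive class is the larger label value.
    """
    values = np.asarray(values, dtype=np.float64)
    y = np.asarray(y)
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError("roc_univariate needs exactly 2 classes")
    pos = y == classes[1]
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("one class is empty")

    ranks = stats.rankdata(values)
    u = ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0
    auc = u / (n_pos * n_neg)

    # tie-aware ROC: sweep unique thresholds from high to low
    order = np.argsort(-values, kind="stable")
    sv, sy = values[order], pos[order]
    tps = np.cumsum(sy)
    fps = np.cumsum(~sy)
    distinct = np.r_[np.flatnonzero(np.diff(sv)), len(sv) - 1]
    tpr = np.r_[0.0, tps[distinct] / n_pos]
    fpr = np.r_[0.0, fps[distinct] / n_neg]
    points = np.column_stack([fpr, tpr])
    return float(auc), points


def roc_multivariate(
    X,
    y,
    top_k: int = 10,
    n_repeats: int = 50,
    holdout_fraction: float = 1 / 3,
    seed: int = 0,
    C: float = 1.0,
) -> dict:
    """Cross-validated multivariate AUC with SVM-style feature ranking.

    Repeated stratified Monte-Carlo splits: per repeat, a linear margin
    classifier (squared-hinge LinearSVC) is trained on all features of the
    training split, features are ranked by |weight|, the classifier is
    retrained on the top_k, and the held-out samples are scored.  AUCs are
    pooled over repeats (mean + percentile 95% CI).
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError("roc_multivariate needs exactly 2 classes")
    n = len(y)
    if n < 8:
        raise ValueError("need at least 8 samples")
    counts = {c: int((y == c).sum()) for c in classes}
    if min(counts.values()) < 2:
        raise ValueError("each class needs at least 2 samples")
    top_k = min(top_k, X.shape[1])

    rng = np.random.default_rng(seed)
    pos_idx = np.flatnonzero(y == classes[1])
    neg_idx = np.flatnonzero(y == classes[0])
    n_pos_test = max(1, round(len(pos_idx) * holdout_fraction))
    n_neg_test = max(1, round(len(neg_idx) * holdout_fraction))
    if n_pos_test >= len(pos_idx) or n_neg_test >= len(neg_idx):
        raise ValueError("holdout fraction leaves a class empty in training")

    aucs = []
    for _ in range(n_repeats):
        test = np.concatenate(
            [
                rng.choice(pos_idx, size=n_pos_test, replace=False),
                rng.choice(neg_idx, size=n_neg_test, replace=False),
            ]
        )
        train = np.setdiff1d(np.arange(n), test)
        clf = LinearSVC(C=C, loss="squared_hinge", dual=False, tol=1e-6)
        clf.fit(X[train], y[train])
        ranking = np.argsort(-np.abs(clf.coef_[0]), kind="stable")
        feats = np.sort(ranking[:top_k])
        clf2 = LinearSVC(C=C, loss="squared_hinge", dual=False, tol=1e-6)
        clf2.fit(X[train][:, feats], y[train])
        scores = clf2.decision_function(X[test][:, feats])
        auc, _ = roc_univariate(scores, y[test])
        aucs.append(auc)
    aucs = np.asarray(aucs)
    lo, hi = np.percentile(aucs, [2.5, 97.5])
    return {
        "auc_mean": float(aucs.mean()),
        "auc_ci": (float(lo), float(hi)),
        "aucs": aucs,
        "n_repeats": n_repeats,
        "top_k": top_k,
        "holdout_fraction": holdout_fraction,
        "classifier": "LinearSVC(squared_hinge, l2)",
    }
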