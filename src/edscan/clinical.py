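"""Clinical association: hub-hormone correlation, cis correlation, ROC/AUC.

Correlations are plain Pearson with two-sided t-based p-values (n − 2 df) on
complete cases.  ROC analysis is empirical over all score thresholds; the
AUC is computed with the Mann–Whitney U convention (ties get half credit),
which equals the trapezoidal integral of the ROC points.  Multi-marker
combination fits an unpenalized logistic regression of the group label on
the marker levels and scores samples by the fitted linear predictor; exact
duplicate markers are dropped before the fit and perfect separation falls
back to a ridge-stabilized fit flagged in the result.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.metrics import roc_curve

__all__ = [
    "AssociationResult", "ROCResult",
    "pearson_assoc", "hub_clinical_correlation", "cis_correlation",
    "roc_single", "roc_combined",
]


@dataclass
class AssociationResult:
    event_id: str
    feature: str
    r: float
    p: float
    n: int
    testable: bool = True


@dataclass
class ROCResult:
    markers: list[str]
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float
    coefficients: dict[str, float] | None = None
    ridge_stabilized: bool = False
    dropped_duplicates: list[str] = field(default_factory=list)


def pearson_assoc(x: np.ndarray, y: np.ndarray, event_id: str = "",
                  feature: str = "") -> AssociationResult:
    """Pearson r with two-sided t p-value on complete cases (needs n >= 3)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    n = int(ok.sum())
    if (n < 3 or np.all(x[ok] == x[ok][0] if n else True)
            or np.all(y[ok] == y[ok][0] if n else True)):
        return AssociationResult(event_id, feature, np.nan, np.nan, n,
                                 testable=False)
    r, p = stats.pearsonr(x[ok], y[ok])
    return AssociationResult(event_id, feature, float(r), float(p), n)


def hub_clinical_correlation(levels: pd.DataFrame, hub_ids: list[str],
                             traits: pd.DataFrame,
                             features: list[str] | None = None,
                             ) -> pd.DataFrame:
    """Full hub x clinical-feature Pearson grid.

    ``levels`` is events x samples; ``traits`` is samples x features (any
    non-numeric columns are ignored).  Pairs with a constant editing vector
    or fewer than 3 complete cases are emitted with ``testable = False``.
    """
    if features is None:
        features = [c for c in traits.columns if c != "group"
                    and pd.api.types.is_numeric_dtype(traits[c])]
    samples = [s for s in levels.columns if s in traits.index]
    rows = []
    for eid in hub_ids:
        lev = levels.loc[eid, samples].to_numpy(dtype=float)
        for feat in features:
            res = pearson_assoc(lev,
                                traits.loc[samples, feat].to_numpy(float),
                                event_id=eid, feature=feat)
            rows.append(res.__dict__)
    return pd.DataFrame(rows)


def cis_correlation(event_levels: pd.Series,
                    gene_expression: pd.Series,
                    event_id: str = "", gene_id: str = "",
                    ) -> AssociationResult:
    """Correlation between an event's editing level and host-gene expression."""
    common = [s for s in event_levels.index if s in gene_expression.index]
    return pearson_assoc(event_levels.loc[common].to_numpy(float),
                         gene_expression.loc[common].to_numpy(float),
                         event_id=event_id, feature=gene_id)


def _auc_mann_whitney(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC = U/(n1*n0) with half credit for ties (all-pairs convention)."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    ranks = stats.rankdata(np.concatenate([pos, neg]))
    u = ranks[: pos.size].sum() - pos.size * (pos.size + 1) / 2.0
    return float(u / (pos.size * neg.size))


def _prepare(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=float)
    ok = ~(np.isnan(scores) | np.isnan(labels))
    scores, labels = scores[ok], labels[ok]
    if not ((labels == 1).any() and (labels == 0).any()):
        raise ValueError("both classes must be present for ROC analysis")
    return scores, labels.astype(int)


def roc_single(levels, labels, marker: str = "marker") -> ROCResult:
    """Empirical ROC and AUC for one marker (higher score = case-like)."""
    scores, y = _prepare(levels, labels)
    fpr, tpr, thr = roc_curve(y, scores)
    return ROCResult(markers=[marker], fpr=fpr, tpr=tpr, thresholds=thr,
                     auc=_auc_mann_whitney(scores, y))


def _logistic_nll(beta: np.ndarray, X: np.ndarray, y: np.ndarray,
                  ridge: float) -> tuple[float, np.ndarray]:
    eta = X @ beta
    # stable log(1 + exp(eta)) and sigmoid
    nll = float(np.sum(np.logaddexp(0.0, eta) - y * eta))
    p = 1.0 / (1.0 + np.exp(-eta))
    grad = X.T @ (p - y)
    if ridge > 0:
        pen = np.r_[0.0, beta[1:]]          # intercept unpenalized
        nll += 0.5 * ridge * float(pen @ pen)
        grad = grad + ridge * pen
    return nll, grad


def _fit_logistic(X: np.ndarray, y: np.ndarray,
                  ridge: float = 0.0) -> tuple[np.ndarray, float]:
    beta0 = np.zeros(X.shape[1])
    res = optimize.minimize(_logistic_nll, beta0, args=(X, y, ridge),
                            jac=True, method="L-BFGS-B",
                            options={"maxiter": 2000, "ftol": 1e-14,
                                     "gtol": 1e-10})
    nll = _logistic_nll(res.x, X, y, 0.0)[0]
    return res.x, float(nll)


def roc_combined(level_matrix: pd.DataFrame, labels,
                 ridge: float = 1.0) -> ROCResult:
    """Logistic-regression combination of several markers into one score.

    ``level_matrix`` is samples x markers.  Complete cases only; exact
    duplicate marker columns are dropped before the fit.  If the unpenalized
    fit shows perfect separation (unbounded coefficients), the fit is
    re-run with a small ridge penalty and flagged ``ridge_stabilized``.
    """
    if level_matrix.shape[1] < 2:
        raise ValueError("combined ROC needs >= 2 markers")
    y_all = pd.Series(np.asarray(labels, dtype=float),
                      index=level_matrix.index)
    data = level_matrix.astype(float).copy()
    data["__y__"] = y_all
    data = data.dropna()
    if len(data) < 6:
        raise ValueError("need >= 6 complete-case samples")
    y = data.pop("__y__").to_numpy()
    if not ((y == 1).any() and (y == 0).any()):
        raise ValueError("both classes must be present for ROC analysis")

    dropped: list[str] = []
    cols: list[str] = []
    seen: list[np.ndarray] = []
    for c in data.columns:
        v = data[c].to_numpy()
        if any(np.array_equal(v, w) for w in seen):
            dropped.append(str(c))
        else:
            seen.append(v)
            cols.append(str(c))
    Xraw = data[cols].to_numpy()
    # standardize for optimizer conditioning; coefficients mapped back
    mu, sd = Xraw.mean(axis=0), Xraw.std(axis=0)
    sd[sd == 0] = 1.0
    Xs = (Xraw - mu) / sd
    X = np.column_stack([np.ones(len(Xs)), Xs])

    beta, nll = _fit_logistic(X, y, ridge=0.0)
    # separation signature: the unpenalized likelihood can be driven to a
    # perfect fit (deviance -> 0) or the coefficients diverge
    ridge_used = nll < 0.05 or np.max(np.abs(beta[1:])) > 30.0
    if ridge_used:
        beta, _ = _fit_logistic(X, y, ridge=ridge)
    scores = X @ beta
    fpr, tpr, thr = roc_curve(y.astype(int), scores)
    coef_scale = beta[1:] / sd
    coefficients = {"intercept": float(beta[0] - np.sum(coef_scale * mu))}
    coefficients.update({c: float(b) for c, b in zip(cols, coef_scale)})
    return ROCResult(markers=cols, fpr=fpr, tpr=tpr, thresholds=thr,
                     auc=_auc_mann_whitney(scores, y.astype(int)),
                     coefficients=coefficients,
                     ridge_stabilized=ridge_used,
                     dropped_duplicates=dropped)
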