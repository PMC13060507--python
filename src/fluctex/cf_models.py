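"""Classification layer: covariate-adjusted per-feature logistic models,
correlation pruning, elastic-net logistic regression, forward-AIC model
selection, and ROC/AUC reporting.

The outcome throughout is a binary group label (case = the CF-like group).
Odds ratios are per 1 unit of the raw feature (Hz or percentage point);
the elastic net standardizes features internally for penalization but the
per-feature adjusted models are fit on the raw scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler

from .cohort_stats import bh_fdr
from .errors import InputError
from .spectral_features import FeatureTable

ADJUSTMENT_COVARIATES = ("age", "sex", "moca")


def _binary_outcome(ft: FeatureTable, case: str | None) -> tuple[np.ndarray, str]:
    groups = ft.groups
    if len(groups) != 2:
        raise InputError(f"binary outcome requires exactly two groups, got {groups}")
    if case is None:
        case = groups[0]
    if case not in groups:
        raise InputError(f"case group {case!r} not in {groups}")
    return (ft.data["group"] == case).to_numpy(int), case


def _design(ft: FeatureTable, columns: list[str]) -> np.ndarray:
    """Numeric design matrix; sex is coded 0/1 by sorted level."""
    cols = []
    for c in columns:
        x = ft.data[c]
        if x.dtype == object or str(x.dtype) == "category":
            levels = sorted(x.unique())
            if len(levels) > 2:
                raise InputError(f"covariate {c} has >2 levels: {levels}")
            x = x.map({lvl: i for i, lvl in enumerate(levels)})
        cols.append(x.to_numpy(float))
    out = np.column_stack(cols)
    if np.isnan(out).any():
        raise InputError(f"missing values in columns {columns}")
    return out


@dataclass
class AdjustedModelResult:
    """One covariate-adjusted logistic fit for a single EEG feature."""

    feature: str
    odds_ratio: float
    ci_low: float
    ci_high: float
    p: float
    q: float | None = None
    separation: bool = False
    n: int = 0

    def as_dict(self) -> dict:
        return {
            "feature": self.feature, "odds_ratio": self.odds_ratio,
            "ci_low": self.ci_low, "ci_high": self.ci_high,
            "p": self.p, "q": self.q, "separation": self.separation, "n": self.n,
        }


def fit_adjusted_logistic(ft: FeatureTable, feature: str,
                          covariates: tuple[str, ...] = ADJUSTMENT_COVARIATES,
                          case: str | None = None) -> AdjustedModelResult:
    """Logistic regression of group on one feature, adjusted for covariates.

    Fits ``case ~ feature + age + sex + MoCA`` by maximum likelihood and
    reports the feature's odds ratio per raw unit with a Wald 95% CI.
    Complete or quasi-complete separation triggers a small-ridge refit,
    flagged via ``separation=True``.
    """
    y, _ = _binary_outcome(ft, case)
    x_feat = ft.data[feature].to_numpy(float)
    if np.ptp(x_feat) == 0:
        raise InputError(f"feature {feature} has zero variance")
    X = sm.add_constant(_design(ft, [feature, *covariates]))

    beta = se = None
    separation = False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, X).fit(disp=0, maxiter=200)
            beta = res.params
            se = res.bse
            if (not res.mle_retvals.get("converged", False)
                    or np.abs(beta).max() > 50 or not np.all(np.isfinite(se))):
                separation = True
        except Exception:
            separation = True

    if separation:
        # small-ridge fallback: penalized MLE with Wald SEs from the
        # penalized Fisher information
        alpha = 1e-2
        clf = LogisticRegression(C=1.0 / alpha, solver="lbfgs",
                                 fit_intercept=False, max_iter=2000)
        clf.fit(X, y)
        beta = clf.coef_.ravel()
        eta = X @ beta
        w = 1.0 / (np.cosh(eta / 2.0) ** 2) / 4.0  # p(1-p)
        info = X.T @ (X * w[:, None]) + alpha * np.eye(X.shape[1])
        cov = np.linalg.inv(info)
        se = np.sqrt(np.diag(cov))

    b, s = float(beta[1]), float(se[1])
    z = b / s if s > 0 else 0.0
    p = float(2 * sps.norm.sf(abs(z)))
    half = 1.959963984540054 * s
    return AdjustedModelResult(
        feature=feature, odds_ratio=float(np.exp(b)),
        ci_low=float(np.exp(b - half)), ci_high=float(np.exp(b + half)),
        p=p, separation=separation, n=len(y))


def fit_adjusted_logistic_all(ft: FeatureTable, features: list[str] | None = None,
                              covariates: tuple[str, ...] = ADJUSTMENT_COVARIATES,
                              case: str | None = None) -> list[AdjustedModelResult]:
    """Adjusted logistic model per feature, with BH-FDR q over the set."""
    if features is None:
        features = list(ft.candidate_features)
    results = [fit_adjusted_logistic(ft, f, covariates, case) for f in features]
    qs = bh_fdr([r.p for r in results])
    for r, q in zip(results, qs):
        r.q = float(q)
    return results


def prune_correlated(ft: FeatureTable, threshold: float = 0.9,
                     features: list[str] | None = None) -> list[str]:
    """Greedy removal of highly correlated features (absolute Spearman).

    While any remaining pair exceeds ``threshold``, the member of the
    most-correlated pair with the higher mean absolute correlation to all
    remaining features is dropped; exact ties drop the later column.
    """
    if not (0 < threshold <= 1):
        raise InputError(f"threshold must be in (0, 1], got {threshold}")
    if features is None:
        features = list(ft.candidate_features)
    if len(features) < 2:
        raise InputError("need >= 2 candidate features to prune")
    corr = ft.data[features].corr(method="spearman").abs().to_numpy()
    np.fill_diagonal(corr, 0.0)
    keep = list(range(len(features)))
    while len(keep) > 1:
        sub = corr[np.ix_(keep, keep)]
        i, j = np.unravel_index(np.argmax(sub), sub.shape)
        if sub[i, j] <= threshold or np.isnan(sub[i, j]):
            break
        mean_i = sub[i].sum() / (len(keep) - 1)
        mean_j = sub[j].sum() / (len(keep) - 1)
        # drop the more globally correlated member; ties drop the later column
        drop_local = j if (mean_j > mean_i or
                           (mean_j == mean_i and keep[j] > keep[i])) else i
        del keep[drop_local]
    return [features[k] for k in keep]


@dataclass
class ClassifierReport:
    """Fitted multivariate classifier with apparent and cross-validated AUC."""

    method: str
    selected: dict[str, float]
    intercept: float
    apparent_auc: float
    cv_auc: float | None
    roc_fpr: np.ndarray
    roc_tpr: np.ndarray
    metadata: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "method": self.method, "selected": self.selected,
            "intercept": self.intercept, "apparent_auc": self.apparent_auc,
            "cv_auc": self.cv_auc,
            "roc": {"fpr": self.roc_fpr.tolist(), "tpr": self.roc_tpr.tolist()},
            "metadata": self.metadata,
        }


def roc_auc(scores, labels) -> tuple[float, tuple[np.ndarray, np.ndarray]]:
    """AUC and ROC curve; ties contribute 1/2 (trapezoidal integration)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) != 2:
        raise InputError("both classes must be present for ROC analysis")
    auc = float(roc_auc_score(labels, scores))
    fpr, tpr, _ = roc_curve(labels, scores)
    return auc, (fpr, tpr)


def _cv_auc(X: np.ndarray, y: np.ndarray, make_clf, n_folds: int, seed: int) -> float:
    """Mean out-of-fold AUC over a stratified k-fold split."""
    n_folds = min(n_folds, int(np.bincount(y).min()))
    if n_folds < 2:
        return float("nan")
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    aucs = []
    for tr, te in skf.split(X, y):
        if len(np.unique(y[te])) < 2:
            continue
        clf = make_clf()
        clf.fit(X[tr], y[tr])
        aucs.append(roc_auc_score(y[te], clf.decision_function(X[te])))
    return float(np.mean(aucs)) if aucs else float("nan")


def fit_elastic_net(ft: FeatureTable, features: list[str] | None = None,
                    l1_ratio: float = 0.5, n_folds: int = 10, seed: int = 0,
                    case: str | None = None, C: float | None = None,
                    c_grid: np.ndarray | None = None) -> ClassifierReport:
    """Elastic-net penalized logistic regression with CV-selected penalty.

    Features are standardized (mean 0, SD 1); the L1/L2 mix is fixed at
    ``l1_ratio`` (default 0.5) and the overall penalty strength is chosen
    on a logarithmic grid by stratified k-fold CV maximizing out-of-fold
    AUC. ``C`` (inverse penalty) may be forced to bypass the search.
    Reported coefficients are on the standardized scale.
    """
    if features is None:
        features = list(ft.candidate_features)
    if len(features) < 2:
        raise InputError("elastic net needs >= 2 features")
    y, case = _binary_outcome(ft, case)
    if len(y) < 10:
        raise InputError("elastic net needs n >= 10 subjects")
    scaler = StandardScaler()
    X = scaler.fit_transform(_design(ft, features))

    def make_clf(c):
        return lambda: LogisticRegression(
            solver="saga", l1_ratio=l1_ratio, C=c, max_iter=20000)

    if c_grid is None:
        c_grid = np.logspace(-2, 1, 10)
    if C is None:
        cv_by_c = {c: _cv_auc(X, y, make_clf(c), n_folds, seed) for c in c_grid}
        # ties in CV AUC resolve toward the stronger penalty (sparser model)
        C = max(cv_by_c, key=lambda c: (cv_by_c[c], -c))
        cv_auc_val = cv_by_c[C]
    else:
        cv_auc_val = _cv_auc(X, y, make_clf(C), n_folds, seed)

    clf = make_clf(C)()
    clf.fit(X, y)
    coefs = clf.coef_.ravel()
    selected = {f: float(c) for f, c in zip(features, coefs) if c != 0.0}
    scores = clf.decision_function(X)
    if np.ptp(scores) == 0:
        apparent, (fpr, tpr) = 0.5, (np.array([0.0, 1.0]), np.array([0.0, 1.0]))
    else:
        apparent, (fpr, tpr) = roc_auc(scores, y)
    return ClassifierReport(
        method="elastic_net", selected=selected, intercept=float(clf.intercept_[0]),
        apparent_auc=apparent, cv_auc=cv_auc_val, roc_fpr=fpr, roc_tpr=tpr,
        metadata={"l1_ratio": l1_ratio, "C": float(C),
                  "c_grid": [float(c) for c in np.atleast_1d(c_grid)],
                  "n_folds": n_folds, "seed": seed, "case": case,
                  "features": list(features)})


def forward_aic(ft: FeatureTable, features: list[str] | None = None,
                n_folds: int = 10, seed: int = 0,
                case: str | None = None) -> ClassifierReport:
    """Forward stepwise logistic regression under the AIC criterion.

    Starts from the intercept-only model and repeatedly adds the feature
    yielding the largest AIC decrease, stopping when no addition improves
    AIC. Candidates whose fit fails (e.g. separation) are skipped.
    """
    if features is None:
        features = list(ft.candidate_features)
    y, case = _binary_outcome(ft, case)
    Xall = _design(ft, list(features)) if features else np.empty((len(y), 0))

    def fit_aic(cols: list[int]) -> tuple[float, object] | None:
        X = sm.add_constant(Xall[:, cols]) if cols else np.ones((len(y), 1))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                res = sm.Logit(y, X).fit(disp=0, maxiter=200)
            except Exception:
                return None
            if not res.mle_retvals.get("converged", False) or \
                    np.abs(res.params).max() > 50:
                return None
        return float(res.aic), res

    current: list[int] = []
    best_aic, best_res = fit_aic([])
    improved = True
    while improved and len(current) < len(features):
        improved = False
        candidates = []
        for j in range(len(features)):
            if j in current:
                continue
            fit = fit_aic(current + [j])
            if fit is not None:
                candidates.append((fit[0], j, fit[1]))
        if candidates:
            aic, j, res = min(candidates, key=lambda t: (t[0], t[1]))
            if aic < best_aic:
                current.append(j)
                best_aic, best_res = aic, res
                improved = True

    sel_names = [features[j] for j in current]
    params = np.asarray(best_res.params, dtype=float)
    intercept = float(params[0])
    selected = {name: float(b) for name, b in zip(sel_names, params[1:])}
    scores = (np.ones((len(y), 1)) if not current
              else sm.add_constant(Xall[:, current])) @ params
    if np.ptp(scores) == 0:
        apparent, (fpr, tpr) = 0.5, (np.array([0.0, 1.0]), np.array([0.0, 1.0]))
        cv = None
    else:
        apparent, (fpr, tpr) = roc_auc(scores, y)
        Xsel = Xall[:, current]
        cv = _cv_auc(Xsel, y,
                     lambda: LogisticRegression(C=np.inf, max_iter=2000),
                     n_folds, seed)
    return ClassifierReport(
        method="forward_aic", selected=selected, intercept=intercept,
        apparent_auc=apparent, cv_auc=cv, roc_fpr=fpr, roc_tpr=tpr,
        metadata={"aic": best_aic, "n_folds": n_folds, "seed": seed,
                  "case": case, "features": list(features)})
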