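"""Combined-model construction: VIF multicollinearity screening with a
univariable-|beta| representative rule, Gini-importance feature selection,
and a grid-searched random-forest fitted under fivefold cross-validation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import GridSearchCV, StratifiedKFold

from .errors import DegenerateInputError, DomainError
from .evalstats import ScoredCohort, youden_cutoff

log = logging.getLogger(__name__)

__all__ = [
    "VifReport",
    "CombinedModel",
    "DEFAULT_GRID",
    "compute_vif",
    "resolve_collinearity",
    "univariable_beta",
    "select_features_gini",
    "fit_combined",
    "predict_combined",
]

DEFAULT_GRID = {
    "n_estimators": [100, 300, 500],
    "max_depth": [3, 5, None],
    "min_samples_leaf": [1, 5],
}

CORR_GROUP_THRESHOLD = 0.7  # |r| linking flagged features into one group


@dataclass
class VifReport:
    vif: dict[str, float]
    flagged: list[str] = field(default_factory=list)
    dropped: list[str] = field(default_factory=list)
    kept_representative: dict[str, float] = field(default_factory=dict)
    actions: list[str] = field(default_factory=list)


@dataclass
class CombinedModel:
    models: list[RandomForestClassifier]
    selected_features: list[str]
    importances: list[pd.Series]  # per fold, sums to 1
    best_hyperparams: list[dict]  # per fold grid cell
    training_cutoff: float
    oof_probs: pd.Series  # indexed by case id / row index
    fold_val_ids: list[list] = field(default_factory=list)


def _check_matrix(X: pd.DataFrame) -> None:
    if X.isna().any().any():
        raise DomainError("feature matrix contains missing values")
    if X.columns.duplicated().any():
        raise DomainError("feature matrix has duplicate column names")


def compute_vif(X: pd.DataFrame) -> VifReport:
    """VIF_j = 1 / (1 - R^2_j), with R^2_j from least-squares regression of
    column j (with intercept) on the remaining columns.  Exact linear
    dependence is reported as +inf."""
    _check_matrix(X)
    if X.shape[1] < 2:
        raise DomainError("VIF requires at least 2 features")
    if X.shape[0] <= X.shape[1]:
        raise DomainError("VIF requires n > p")
    vals = X.to_numpy(dtype=float)
    vif: dict[str, float] = {}
    for j, name in enumerate(X.columns):
        yj = vals[:, j]
        others = np.delete(vals, j, axis=1)
        A = np.column_stack([np.ones(len(yj)), others])
        coef, *_ = np.linalg.lstsq(A, yj, rcond=None)
        resid = yj - A @ coef
        ss_tot = np.sum((yj - yj.mean()) ** 2)
        if ss_tot <= 0:
            vif[name] = float("inf")  # constant column
            continue
        r2 = 1.0 - np.sum(resid**2) / ss_tot
        vif[name] = float("inf") if r2 >= 1.0 - 1e-12 else float(1.0 / (1.0 - r2))
    flagged = [k for k, v in vif.items() if v > 5.0 or np.isinf(v)]
    return VifReport(vif=vif, flagged=flagged)


def univariable_beta(x: np.ndarray, y: np.ndarray) -> float:
    """|beta| from a univariable logistic fit on the z-scored feature.

    Perfect separation returns +inf; a degenerate (constant) feature raises.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=int)
    sd = x.std()
    if sd == 0:
        raise DegenerateInputError("constant feature has no univariable effect")
    xz = (x - x.mean()) / sd
    if xz[y == 1].min() > xz[y == 0].max() or xz[y == 1].max() < xz[y == 0].min():
        return float("inf")
    lr = LogisticRegression(penalty=None, solver="lbfgs", max_iter=2000)
    lr.fit(xz.reshape(-1, 1), y)
    return float(abs(lr.coef_[0, 0]))


def _correlation_groups(X: pd.DataFrame, flagged: list[str]) -> list[list[str]]:
    """Connected components among flagged features linked by |r| >= 0.7."""
    if len(flagged) < 2:
        return [[f] for f in flagged]
    sub = X[flagged].to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(sub, rowvar=False)
    corr = np.nan_to_num(corr, nan=1.0)  # constant columns: treat as linked
    n = len(flagged)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if abs(corr[i, j]) >= CORR_GROUP_THRESHOLD:
                parent[find(i)] = find(j)
    groups: dict[int, list[str]] = {}
    for i, f in enumerate(flagged):
        groups.setdefault(find(i), []).append(f)
    return list(groups.values())


def resolve_collinearity(X: pd.DataFrame, labels, threshold: float = 5.0
                         ) -> tuple[pd.DataFrame, VifReport]:
    """Iteratively drop collinear features: within each flagged group
    (|r| >= 0.7), keep the feature with the largest standardized univariable
    logistic |beta|; recompute VIF until nothing exceeds the threshold.
    Idempotent; every action is recorded in the report."""
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise DegenerateInputError("labels must contain both classes")
    X = X.copy()
    dropped: list[str] = []
    kept: dict[str, float] = {}
    actions: list[str] = []
    while X.shape[1] >= 2:
        report = compute_vif(X)
        flagged = [f for f in report.flagged if report.vif[f] > threshold
                   or np.isinf(report.vif[f])]
        if not flagged:
            break
        any_drop = False
        for group in _correlation_groups(X, flagged):
            if len(group) < 2:
                continue
            betas = {}
            for f in group:
                try:
                    betas[f] = univariable_beta(X[f].to_numpy(), labels)
                except DegenerateInputError:
                    warnings.warn(f"feature {f!r} degenerate; dropped from group")
                    betas[f] = -np.inf
            keep = max(group, key=lambda f: (betas[f], -group.index(f)))
            kept[keep] = betas[keep]
            for f in group:
                if f != keep:
                    dropped.append(f)
                    actions.append(f"dropped {f} (|beta|={betas[f]:.4g}) in favor of "
                                   f"{keep} (|beta|={betas[keep]:.4g})")
                    any_drop = True
            X = X.drop(columns=[f for f in group if f != keep])
        if not any_drop:
            warnings.warn("flagged features form no resolvable group; stopping")
            break
    final = compute_vif(X) if X.shape[1] >= 2 else VifReport(vif={X.columns[0]: 1.0})
    final.dropped = dropped
    final.kept_representative = kept
    final.actions = actions
    return X, final


def select_features_gini(X: pd.DataFrame, labels, seed: int = 0,
                         n_estimators: int = 500) -> tuple[list[str], pd.Series]:
    """Select-from-model with a random-forest estimator: keep features whose
    Gini (mean-decrease-impurity) importance exceeds the mean importance."""
    _check_matrix(X)
    labels = np.asarray(labels, dtype=int)
    rf = RandomForestClassifier(n_estimators=n_estimators, random_state=seed, n_jobs=1)
    rf.fit(X.to_numpy(dtype=float), labels)
    imp = pd.Series(rf.feature_importances_, index=X.columns)
    selected = list(imp.index[imp > imp.mean()])
    if not selected:
        warnings.warn("all importances tied at the mean; retaining all features")
        selected = list(X.columns)
    return selected, imp


def fit_combined(X: pd.DataFrame, labels, grid: dict | None = None, folds: int = 5,
                 seed: int = 0, inner_folds: int = 3) -> CombinedModel:
    """Stratified fivefold CV; per fold an inner-CV AUC grid search picks the
    forest hyperparameters and the fold model is fitted on the fold-train
    split.  The operating cutoff is the Youden threshold on the pooled
    out-of-fold probabilities."""
    _check_matrix(X)
    labels = np.asarray(labels, dtype=int)
    if grid is None:
        grid = DEFAULT_GRID
    if not grid:
        raise DomainError("hyperparameter grid must be nonempty")
    vals = X.to_numpy(dtype=float)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    models, importances, best_params, fold_val_ids = [], [], [], []
    oof = pd.Series(index=X.index, dtype=float)
    for tr, va in skf.split(vals, labels):
        y_tr = labels[tr]
        if len(np.unique(y_tr)) < 2 or len(np.unique(labels[va])) < 2:
            raise DegenerateInputError("single-class fold; reduce folds or rebalance")
        inner = StratifiedKFold(n_splits=inner_folds, shuffle=True, random_state=seed)
        gs = GridSearchCV(RandomForestClassifier(random_state=seed, n_jobs=1),
                          grid, scoring="roc_auc", cv=inner, refit=True)
        gs.fit(vals[tr], y_tr)
        model = gs.best_estimator_
        models.append(model)
        best_params.append(gs.best_params_)
        importances.append(pd.Series(model.feature_importances_, index=X.columns))
        oof.iloc[va] = model.predict_proba(vals[va])[:, 1]
        fold_val_ids.append(list(X.index[va]))
    cutoff = youden_cutoff(ScoredCohort(oof.to_numpy(), labels))
    return CombinedModel(models=models, selected_features=list(X.columns),
                         importances=importances, best_hyperparams=best_params,
                         training_cutoff=float(cutoff), oof_probs=oof,
                         fold_val_ids=fold_val_ids)


def predict_combined(model: CombinedModel, X: pd.DataFrame) -> np.ndarray:
    """Mean of the five fold-forests' probabilities."""
    vals = X[model.selected_features].to_numpy(dtype=float)
    return np.mean([m.predict_proba(vals)[:, 1] for m in model.models], axis=0)
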