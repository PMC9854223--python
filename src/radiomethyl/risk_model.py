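"""Stenosis-radiophenotype prediction: logistic modelling stack.

Maximum-likelihood logistic regression (Wald 95% CIs and p-values),
backward-elimination variable selection, performance metrics with the
cohort's class convention — sensitivity is the correct-classification
rate of the minority *no-stenosis* class and specificity that of the
majority *stenosis* class, named explicitly to prevent silent swaps —
and a stratified 70/30 split with fivefold cross-validation that drives
selection-stability-weighted 0-100 importance scores.

AUC uses the rank (Mann-Whitney) formulation with midranks for ties,
scoring the stenosis class as positive.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.model_selection import StratifiedKFold, train_test_split

#: absolute coefficient beyond which a fit is flagged as separated
_SEPARATION_COEF = 50.0


def encode_features(df: pd.DataFrame, variables: list[str]) -> pd.DataFrame:
    """Numeric design matrix: yes/no columns become 1/0."""
    out = {}
    for var in variables:
        col = df[var]
        if pd.api.types.is_numeric_dtype(col):
            out[var] = col.to_numpy(dtype=float)
        else:
            vals = set(col.unique()) - {"yes", "no"}
            if vals:
                raise ValueError(f"column {var} is neither numeric nor yes/no: {vals}")
            out[var] = (col == "yes").to_numpy(dtype=float)
    return pd.DataFrame(out, index=df.index)


@dataclass
class LogisticModel:
    """Fitted logistic regression with Wald inference.

    ``params`` is indexed by variable name (plus ``intercept``) with
    columns ``coef``, ``ci_low``, ``ci_high``, ``p_value``, ``z``.
    """

    params: pd.DataFrame
    variables: list[str]
    converged: bool
    separated: bool
    dropped: list[str] = field(default_factory=list)
    llf: float = math.nan

    @property
    def intercept(self) -> float:
        return float(self.params.loc["intercept", "coef"])

    def coef(self, variable: str) -> float:
        return float(self.params.loc[variable, "coef"])

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        """Fitted probability of the positive (stenosis) class."""
        eta = np.full(len(X), self.intercept)
        for var in self.variables:
            eta = eta + self.coef(var) * X[var].to_numpy(dtype=float)
        return 1.0 / (1.0 + np.exp(-eta))


def fit_logistic(X: pd.DataFrame, y, maxiter: int = 100, tol: float = 1e-8) -> LogisticModel:
    """Maximum-likelihood fit with Wald 95% CIs and p-values.

    Constant columns are dropped (a zero-variance predictor carries no
    information; with none left the intercept equals the logit of the
    prevalence). Complete separation is detected — via the optimizer's
    own warning or runaway coefficients — and flagged rather than
    silently returning divergent estimates.
    """
    y = np.asarray(y, dtype=float)
    classes = np.unique(y)
    if not np.array_equal(classes, [0.0, 1.0]):
        raise ValueError("labels must be binary with both classes present")
    keep = [c for c in X.columns if np.std(X[c].to_numpy(dtype=float)) > 0]
    dropped = [c for c in X.columns if c not in keep]
    design = sm.add_constant(X[keep].astype(float), has_constant="add")
    separated = False
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        model = sm.Logit(y, design)
        try:
            res = model.fit(disp=0, maxiter=maxiter, tol=tol)
        except np.linalg.LinAlgError:
            # Newton's Hessian can go singular on badly scaled or nearly
            # separated designs; BFGS still reaches the MLE and the Wald
            # covariance is taken from the analytic Hessian at the optimum
            res = model.fit(disp=0, maxiter=10 * maxiter, method="bfgs", gtol=tol)
        for w in caught:
            if "separation" in str(w.message).lower():
                separated = True
    conf = res.conf_int(alpha=0.05)
    tab = pd.DataFrame(
        {
            "coef": res.params,
            "ci_low": conf[0],
            "ci_high": conf[1],
            "p_value": res.pvalues,
            "z": res.tvalues,
        }
    ).rename(index={"const": "intercept"})
    slopes = res.params.drop(labels=["const"], errors="ignore").to_numpy()
    if slopes.size and np.nanmax(np.abs(slopes)) > _SEPARATION_COEF:
        separated = True
    return LogisticModel(
        params=tab,
        variables=keep,
        converged=bool(res.mle_retvals.get("converged", True)),
        separated=separated,
        dropped=dropped,
        llf=float(res.llf),
    )


def select_variables(
    X: pd.DataFrame,
    y,
    retention_p: float = 0.1,
    direction: str = "backward",
) -> tuple[list[str], LogisticModel]:
    """Stepwise variable selection at the retention threshold.

    backward (default): fit all candidates, repeatedly drop the
    largest-p variable until every retained p < retention_p; on an
    exact p tie the later-listed variable is dropped. forward: add the
    best candidate while its p in the grown model stays below
    retention_p. keep_all: no selection. An empty final set
    (intercept-only) is allowed.
    """
    candidates = list(X.columns)
    if not candidates:
        raise ValueError("candidate set is empty")
    if direction == "keep_all":
        model = fit_logistic(X, y)
        return model.variables, model
    if direction == "forward":
        current: list[str] = []
        model = _intercept_only(y)
        while True:
            best = None
            for var in candidates:
                if var in current:
                    continue
                m = fit_logistic(X[current + [var]], y)
                if var not in m.params.index:
                    continue
                p = float(m.params.loc[var, "p_value"])
                if not math.isnan(p) and (best is None or p < best[1]):
                    best = (var, p, m)
            if best is None or best[1] >= retention_p:
                return current, model
            current.append(best[0])
            model = best[2]
    if direction != "backward":
        raise ValueError("direction must be backward, forward or keep_all")

    current = list(candidates)
    model = fit_logistic(X[current], y)
    while True:
        current = list(model.variables)
        if not current:
            return [], _intercept_only(y)
        pvals = model.params.loc[current, "p_value"]
        worst_p = np.nanmax(pvals.to_numpy()) if not pvals.isna().all() else math.nan
        if not math.isnan(worst_p) and worst_p < retention_p:
            return current, model
        # among exact ties (or all-NaN), drop the later-listed variable
        if math.isnan(worst_p):
            drop = current[-1]
        else:
            tied = [v for v in current if pvals[v] == worst_p or math.isnan(pvals[v])]
            drop = tied[-1]
        current = [v for v in current if v != drop]
        if not current:
            return [], _intercept_only(y)
        model = fit_logistic(X[current], y)


def _intercept_only(y) -> LogisticModel:
    y = np.asarray(y, dtype=float)
    prev = y.mean()
    coef = math.log(prev / (1 - prev))
    tab = pd.DataFrame(
        {"coef": [coef], "ci_low": [math.nan], "ci_high": [math.nan],
         "p_value": [math.nan], "z": [math.nan]},
        index=["intercept"],
    )
    return LogisticModel(tab, [], converged=True, separated=False)


# ---------------------------------------------------------------------------
# performance
# ---------------------------------------------------------------------------


@dataclass
class PerformanceReport:
    """Accuracy, class-specific rates and AUC.

    ``sensitivity_no_stenosis``: correct-classification rate of the
    no-stenosis (label 0) class. ``specificity_stenosis``: rate of the
    stenosis (label 1) class. Accuracy is their prevalence-weighted mean.
    """

    accuracy: float
    sensitivity_no_stenosis: float
    specificity_stenosis: float
    auc: float
    n_no_stenosis: int
    n_stenosis: int


def auc_mann_whitney(scores, labels) -> float:
    """AUC via the rank formulation with midranks for ties.

    The stenosis class (label 1) is the positive score direction; a
    constant score gives 0.5 by the midrank convention.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n1 = int(labels.sum())
    n0 = len(labels) - n1
    if n0 == 0 or n1 == 0:
        return math.nan
    ranks = stats.rankdata(scores, method="average")
    u = ranks[labels == 1].sum() - n1 * (n1 + 1) / 2
    return float(u / (n0 * n1))


def evaluate(
    model: LogisticModel, X: pd.DataFrame, y, threshold: float = 0.5
) -> PerformanceReport:
    """Classify at ``threshold`` and score against labels.

    Predicted class is stenosis when the fitted probability is >= the
    threshold. A class absent from the data leaves its rate (and AUC)
    undefined (NaN) rather than raising.
    """
    y = np.asarray(y, dtype=int)
    proba = model.predict_proba(X)
    pred = (proba >= threshold).astype(int)
    n1 = int(y.sum())
    n0 = len(y) - n1
    sens = float((pred[y == 0] == 0).mean()) if n0 else math.nan
    spec = float((pred[y == 1] == 1).mean()) if n1 else math.nan
    acc = float((pred == y).mean()) if len(y) else math.nan
    return PerformanceReport(
        accuracy=acc,
        sensitivity_no_stenosis=sens,
        specificity_stenosis=spec,
        auc=auc_mann_whitney(proba, y),
        n_no_stenosis=n0,
        n_stenosis=n1,
    )


# ---------------------------------------------------------------------------
# cross-validated pipeline
# ---------------------------------------------------------------------------


@dataclass
class SplitPlan:
    """Train/test split and cross-validation layout."""

    train_fraction: float = 0.70
    folds: int = 5
    stratified: bool = True
    seed: int = 0

    def validate(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must lie in (0, 1)")
        if self.folds < 2:
            raise ValueError("folds must be >= 2")


def importance_scores(
    fold_models: list[LogisticModel], candidates: list[str]
) -> pd.DataFrame:
    """0-100 importance from per-fold Wald statistics.

    Raw importance of a variable is its mean |Wald z| over folds, with a
    variable contributing zero in folds whose model does not retain it —
    so unstable borderline variables score low even when occasionally
    significant. Scores are linearly rescaled so the maximum is 100.
    Returns a DataFrame (variable, score) in descending order.
    """
    if not fold_models:
        raise ValueError("at least one fold model required")
    raw = {}
    for var in candidates:
        zs = []
        for m in fold_models:
            if var in m.variables and var in m.params.index:
                z = m.params.loc[var, "z"]
                zs.append(abs(z) if not math.isnan(z) else 0.0)
            else:
                zs.append(0.0)
        raw[var] = float(np.mean(zs))
    top = max(raw.values())
    scale = 100.0 / top if top > 0 else 0.0
    out = pd.DataFrame(
        {"variable": list(raw), "score": [v * scale for v in raw.values()]}
    ).sort_values("score", ascending=False, kind="stable").reset_index(drop=True)
    return out


@dataclass
class CrossValReport:
    importance: pd.DataFrame
    performance: PerformanceReport
    selected: list[str]
    final_model: LogisticModel
    fold_models: list[LogisticModel]
    fold_selected: list[list[str]]
    train_index: np.ndarray
    test_index: np.ndarray


def split_and_crossvalidate(
    features: pd.DataFrame,
    labels,
    candidates: list[str] | None = None,
    plan: SplitPlan | None = None,
    retention_p: float = 0.1,
    threshold: float = 0.5,
    direction: str = "backward",
) -> CrossValReport:
    """Stratified 70/30 split with fivefold CV on the training part.

    Per fold, variable selection is rerun on the fold's training
    portion; those per-fold models drive the selection-stability
    importance scores. The final model is selected and refit on the
    full training part and scored exactly once on the untouched test
    part. Fully reproducible from ``plan.seed``.
    """
    plan = plan or SplitPlan()
    plan.validate()
    candidates = candidates or list(features.columns)
    X = encode_features(features, candidates)
    y = np.asarray(labels, dtype=int)
    idx = np.arange(len(X))
    train_idx, test_idx = train_test_split(
        idx,
        train_size=plan.train_fraction,
        stratify=y if plan.stratified else None,
        random_state=plan.seed % (2**32),
        shuffle=True,
    )
    X_train, y_train = X.iloc[train_idx], y[train_idx]
    X_test, y_test = X.iloc[test_idx], y[test_idx]

    skf = StratifiedKFold(
        n_splits=plan.folds, shuffle=True, random_state=(plan.seed + 1) % (2**32)
    )
    fold_models, fold_selected = [], []
    for tr, va in skf.split(X_train, y_train):
        if len(np.unique(y_train[tr])) < 2 or len(np.unique(y_train[va])) < 2:
            raise ValueError("a CV fold lost a class; cohort too small for plan")
        sel, model = select_variables(
            X_train.iloc[tr], y_train[tr], retention_p=retention_p, direction=direction
        )
        fold_models.append(model)
        fold_selected.append(sel)

    importance = importance_scores(fold_models, candidates)
    selected, final_model = select_variables(
        X_train, y_train, retention_p=retention_p, direction=direction
    )
    performance = evaluate(final_model, X_test, y_test, threshold=threshold)
    return CrossValReport(
        importance=importance,
        performance=performance,
        selected=selected,
        final_model=final_model,
        fold_models=fold_models,
        fold_selected=fold_selected,
        train_index=train_idx,
        test_index=test_idx,
    )
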