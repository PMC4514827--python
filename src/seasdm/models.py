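"""The five presence-background model forms and cross-validation.

Every form exposes the same contract: fit on a labeled pixel table
(presence=1, background=0) and predict a suitability in [0, 1] for any
covariate vector.  The forms:

GLM     logistic regression by maximum likelihood on linear + quadratic
        terms per covariate (ridge fallback on separation).
MARS    multivariate adaptive regression splines: greedy forward
        selection of hinge-function pairs, backward pruning by
        generalized cross-validation, and a final binomial refit of the
        surviving basis.  Implemented here from scratch.
BRT     stochastic gradient boosting of shallow regression trees on the
        binomial deviance (scikit-learn's gradient boosting machine).
RF      random forest of fully grown classification trees; suitability
        is the fraction of trees voting presence.
MAXENT  maximum-entropy presence-background model, estimated in its
        penalized-logistic-regression formulation over linear,
        quadratic, and hinge feature expansions, with the output
        logistic transform calibrated at prevalence 0.5.

Model runs are deterministic under a fixed seed, including fold
assignment in 10-fold cross-validation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit, logit
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from .evaluation import (
    compute_auc,
    confusion_at_threshold,
    minimum_training_presence_threshold,
)
from .grids import RasterLayer
from .predictors import PredictorStack, TrainingTable

MODEL_FORM_NAMES = ("GLM", "MARS", "BRT", "RF", "MAXENT")

#: Community-standard defaults for presence-background SDM fitting; all
#: overridable per run.
DEFAULT_HYPERPARAMETERS: dict[str, dict] = {
    "GLM": {"quadratic": True},
    # GCV cost-per-knot of 4 compensates for the selection bias of the
    # exhaustive knot search; smaller penalties retain spurious hinge
    # terms on pure-noise covariates.
    "MARS": {"max_terms": 21, "degree": 1, "gcv_penalty": 4.0, "n_knots": 25},
    "BRT": {
        "max_depth": 3,
        "learning_rate": 0.01,
        "subsample": 0.75,
        "n_estimators": 5000,
        "n_iter_no_change": 20,
        "validation_fraction": 0.1,
        "tol": 1e-4,
    },
    "RF": {"n_estimators": 1000, "max_features": "sqrt", "min_samples_leaf": 1},
    "MAXENT": {
        "penalty_multiplier": 1.0,
        "features": ("linear", "quadratic", "hinge"),
        "n_hinge_knots": 5,
    },
}


@dataclass
class FittedModel:
    """A fitted suitability model with an opaque predictor."""

    form: str
    covariate_names: list[str]
    _predict: callable = field(repr=False)
    metadata: dict = field(default_factory=dict)

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Suitability in [0, 1] for raw covariate rows (training order)."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != len(self.covariate_names):
            raise ValueError(
                f"expected {len(self.covariate_names)} covariates, got {X.shape[1]}"
            )
        out = np.asarray(self._predict(X), dtype=float)
        return np.clip(out, 0.0, 1.0)


def _merge_hp(form: str, hp: dict | None) -> dict:
    merged = dict(DEFAULT_HYPERPARAMETERS[form])
    if hp:
        merged.update(hp)
    return merged


class _Standardizer:
    """Column-wise centering/scaling; constant columns scale to zero."""

    def __init__(self, X: np.ndarray) -> None:
        self.mean = X.mean(axis=0)
        sd = X.std(axis=0)
        self.sd = np.where(sd > 0, sd, 1.0)
        self.constant = sd == 0

    def __call__(self, X: np.ndarray) -> np.ndarray:
        Z = (X - self.mean) / self.sd
        Z[:, self.constant] = 0.0
        return Z


def _fit_logistic_with_fallback(F: np.ndarray, y: np.ndarray):
    """Unpenalized logistic fit; ridge fallback on separation/divergence."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        clf = LogisticRegression(C=np.inf, solver="lbfgs", max_iter=1000)
        clf.fit(F, y)
    fallback = (clf.n_iter_[0] >= 1000) or (np.abs(clf.coef_).max() > 30)
    if fallback:
        clf = LogisticRegression(C=1.0, solver="lbfgs", max_iter=1000)
        clf.fit(F, y)
    return clf, fallback



class _ProbaPredictor:
    """predict_proba[:, 1] of a fitted classifier (picklable)."""

    def __init__(self, clf, transform=None):
        self.clf = clf
        self.transform = transform

    def __call__(self, X):
        F = self.transform(X) if self.transform is not None else X
        return self.clf.predict_proba(F)[:, 1]


class _ConstantPredictor:
    def __init__(self, value: float):
        self.value = float(value)

    def __call__(self, X):
        return np.full(X.shape[0], self.value)


class _QuadraticExpansion:
    def __init__(self, std: _Standardizer, quadratic: bool):
        self.std = std
        self.quadratic = quadratic

    def __call__(self, X):
        Z = self.std(X)
        return np.hstack([Z, Z**2]) if self.quadratic else Z


class _MarsBasis:
    """Hinge basis over standardized covariates (without intercept)."""

    def __init__(self, std: _Standardizer, terms, kept_cols):
        self.std = std
        self.terms = terms
        self.kept_cols = kept_cols

    def __call__(self, X):
        Z = self.std(X)
        cols = []
        for k in self.kept_cols:
            j, t = self.terms[k // 2]
            h1, h2 = _hinge_pair(Z[:, j], t)
            cols.append(h1 if k % 2 == 0 else h2)
        return np.column_stack(cols)


class _MaxentFeatures:
    def __init__(self, std: _Standardizer, feats, knots):
        self.std = std
        self.feats = feats
        self.knots = knots

    def __call__(self, X):
        Z = self.std(X)
        cols = []
        if "linear" in self.feats:
            cols.append(Z)
        if "quadratic" in self.feats:
            cols.append(Z**2)
        if "hinge" in self.feats:
            for j in range(Z.shape[1]):
                for t in self.knots[j]:
                    h1, h2 = _hinge_pair(Z[:, j], t)
                    cols.append(np.column_stack([h1, h2]))
        return np.hstack(cols)


class _MaxentPredictor:
    def __init__(self, clf, features: _MaxentFeatures, prevalence_shift: float):
        self.clf = clf
        self.features = features
        self.prevalence_shift = float(prevalence_shift)

    def __call__(self, X):
        eta = self.clf.decision_function(self.features(X))
        return expit(eta - self.prevalence_shift)


# --------------------------------------------------------------------------
# GLM

def fit_glm(table: TrainingTable, hp: dict | None = None, seed: int = 0) -> FittedModel:
    """Logistic regression with linear and quadratic terms per covariate."""
    hp = _merge_hp("GLM", hp)
    X, y = table.X, table.y
    expand = _QuadraticExpansion(_Standardizer(X), hp["quadratic"])
    clf, fallback = _fit_logistic_with_fallback(expand(X), y)
    return FittedModel(
        "GLM",
        list(table.covariate_names),
        _ProbaPredictor(clf, expand),
        {"ridge_fallback": fallback, "coef": clf.coef_[0].copy(),
         "intercept": float(clf.intercept_[0])},
    )


# --------------------------------------------------------------------------
# MARS

def _hinge_pair(x: np.ndarray, knot: float) -> tuple[np.ndarray, np.ndarray]:
    return np.maximum(x - knot, 0.0), np.maximum(knot - x, 0.0)


def _lstsq_sse(B: np.ndarray, y: np.ndarray) -> float:
    coef, res, rank, _ = np.linalg.lstsq(B, y, rcond=None)
    if res.size:
        return float(res[0])
    return float(np.sum((y - B @ coef) ** 2))


def fit_mars(table: TrainingTable, hp: dict | None = None, seed: int = 0) -> FittedModel:
    """Additive MARS: forward hinge-pair selection, GCV pruning, binomial refit.

    The forward pass greedily adds mirrored hinge pairs max(x-t, 0) /
    max(t-x, 0) at quantile candidate knots, minimizing squared error on
    the 0/1 response, up to ``max_terms`` basis columns.  The backward
    pass greedily deletes terms to minimize the generalized
    cross-validation score GCV = (RSS/n) / (1 - C/n)^2 with effective
    parameter count C = M + penalty*(M-1)/2.  The surviving basis is
    refit as a binomial linear model and predictions pass through the
    inverse logit.  Constant covariates are never candidates.
    """
    hp = _merge_hp("MARS", hp)
    if hp["degree"] != 1:
        raise ValueError("only additive MARS (degree=1) is implemented")
    X, y = table.X, table.y.astype(float)
    n, p = X.shape
    std = _Standardizer(X)
    Z = std(X)

    # Candidate knots per covariate at interior quantiles.
    qs = np.linspace(0.05, 0.95, hp["n_knots"])
    candidates: list[tuple[int, float]] = []
    for j in range(p):
        if std.constant[j]:
            continue
        knots = np.unique(np.quantile(Z[:, j], qs))
        candidates.extend((j, float(t)) for t in knots)

    terms: list[tuple[int, float]] = []  # (covariate index, knot) pairs
    B = np.ones((n, 1))
    sse = _lstsq_sse(B, y)
    used: set[tuple[int, float]] = set()
    while B.shape[1] + 2 <= hp["max_terms"]:
        best = None
        for cand in candidates:
            if cand in used:
                continue
            h1, h2 = _hinge_pair(Z[:, cand[0]], cand[1])
            s = _lstsq_sse(np.column_stack([B, h1, h2]), y)
            if best is None or s < best[0]:
                best = (s, cand)
        if best is None or best[0] >= sse * (1 - 1e-4):
            break
        sse = best[0]
        cand = best[1]
        used.add(cand)
        terms.append(cand)
        h1, h2 = _hinge_pair(Z[:, cand[0]], cand[1])
        B = np.column_stack([B, h1, h2])

    def build_basis(Zr: np.ndarray, keep: list[int]) -> np.ndarray:
        cols = [np.ones(Zr.shape[0])]
        for k in keep:
            j, t = terms[k // 2]
            h1, h2 = _hinge_pair(Zr[:, j], t)
            cols.append(h1 if k % 2 == 0 else h2)
        return np.column_stack(cols)

    def gcv(keep: list[int]) -> float:
        m = 1 + len(keep)
        c = m + hp["gcv_penalty"] * (m - 1) / 2.0
        if c >= n:
            return np.inf
        rss = _lstsq_sse(build_basis(Z, keep), y)
        return (rss / n) / (1 - c / n) ** 2

    # Backward pruning: greedy single-column deletion, best subset by GCV.
    keep = list(range(2 * len(terms)))
    best_keep, best_gcv = list(keep), gcv(keep)
    while keep:
        scores = [(gcv([k for k in keep if k != drop]), drop) for drop in keep]
        g, drop = min(scores)
        keep = [k for k in keep if k != drop]
        if g <= best_gcv:
            best_gcv, best_keep = g, list(keep)

    F = build_basis(Z, best_keep)[:, 1:]  # refit adds its own intercept
    if F.shape[1] == 0:
        predict = _ConstantPredictor(float(np.clip(y.mean(), 1e-12, 1 - 1e-12)))
        meta = {"n_terms": 0, "knots": []}
    else:
        clf, fallback = _fit_logistic_with_fallback(F, y.astype(int))
        predict = _ProbaPredictor(clf, _MarsBasis(std, list(terms), list(best_keep)))
        meta = {
            "n_terms": len(best_keep),
            "knots": [
                (table.covariate_names[terms[k // 2][0]],
                 float(terms[k // 2][1] * std.sd[terms[k // 2][0]]
                       + std.mean[terms[k // 2][0]]))
                for k in best_keep
            ],
            "ridge_fallback": fallback,
        }
    return FittedModel("MARS", list(table.covariate_names), predict, meta)


# --------------------------------------------------------------------------
# BRT

def fit_brt(table: TrainingTable, hp: dict | None = None, seed: int = 0) -> FittedModel:
    """Stochastic gradient boosting on the binomial deviance."""
    hp = _merge_hp("BRT", hp)
    if hp["learning_rate"] <= 0:
        raise ValueError("BRT learning rate (shrinkage) must be positive")
    n_no_change = hp["n_iter_no_change"]
    clf = GradientBoostingClassifier(
        loss="log_loss",
        max_depth=hp["max_depth"],
        learning_rate=hp["learning_rate"],
        subsample=hp["subsample"],
        n_estimators=hp["n_estimators"],
        n_iter_no_change=n_no_change,
        validation_fraction=hp["validation_fraction"],
        tol=hp["tol"],
        random_state=seed,
    )
    clf.fit(table.X, table.y)
    return FittedModel(
        "BRT",
        list(table.covariate_names),
        _ProbaPredictor(clf),
        {"n_trees": clf.n_estimators_, "train_score": clf.train_score_.copy()},
    )


# --------------------------------------------------------------------------
# RF

def fit_rf(table: TrainingTable, hp: dict | None = None, seed: int = 0) -> FittedModel:
    """Random forest; suitability = fraction of trees voting presence."""
    hp = _merge_hp("RF", hp)
    if hp["n_estimators"] < 1:
        raise ValueError("RF needs at least one tree")
    clf = RandomForestClassifier(
        n_estimators=hp["n_estimators"],
        max_features=hp["max_features"],
        min_samples_leaf=hp["min_samples_leaf"],
        random_state=seed,
        n_jobs=1,
        oob_score=False,
    )
    clf.fit(table.X, table.y)
    return FittedModel(
        "RF",
        list(table.covariate_names),
        _ProbaPredictor(clf),
        {"n_trees": hp["n_estimators"]},
    )


# --------------------------------------------------------------------------
# Maxent

def fit_maxent(table: TrainingTable, hp: dict | None = None, seed: int = 0) -> FittedModel:
    """Presence-background maximum entropy as L1-penalized logistic regression.

    Features are linear, quadratic, and hinge expansions (both
    orientations, knots at interior quantiles) of the standardized
    covariates.  The exponential presence-density model is estimated via
    its logistic-regression formulation with an L1 penalty controlled by
    ``penalty_multiplier`` (larger = stronger shrinkage; infinity shrinks
    all features out, giving a uniform map).  The fitted linear predictor
    is re-centered by the training prevalence so the output logistic
    transform is calibrated at prevalence 0.5.
    """
    hp = _merge_hp("MAXENT", hp)
    if hp["penalty_multiplier"] < 0:
        raise ValueError("penalty multiplier must be non-negative")
    X, y = table.X, table.y
    std = _Standardizer(X)
    feats = tuple(hp["features"])
    qs = np.linspace(0.1, 0.9, hp["n_hinge_knots"])
    knots = [
        np.unique(np.quantile(std(X)[:, j], qs)) if not std.constant[j] else np.array([])
        for j in range(X.shape[1])
    ]
    expand = _MaxentFeatures(std, feats, knots)
    F = expand(X)
    # C is the inverse regularization strength of the L1 problem.
    pm = hp["penalty_multiplier"]
    C = np.inf if pm == 0 else 1.0 / pm
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        if np.isinf(C):
            clf = LogisticRegression(C=np.inf, solver="lbfgs", max_iter=2000)
        else:
            clf = LogisticRegression(
                C=C, l1_ratio=1, solver="liblinear", max_iter=2000,
                random_state=seed,
            )
        clf.fit(F, y)
    prevalence_shift = logit(np.clip(y.mean(), 1e-12, 1 - 1e-12))
    return FittedModel(
        "MAXENT",
        list(table.covariate_names),
        _MaxentPredictor(clf, expand, prevalence_shift),
        {"n_features": F.shape[1],
         "n_active": int(np.sum(clf.coef_ != 0))},
    )


_FITTERS = {
    "GLM": fit_glm,
    "MARS": fit_mars,
    "BRT": fit_brt,
    "RF": fit_rf,
    "MAXENT": fit_maxent,
}


def fit_model(
    form: str, table: TrainingTable, hp: dict | None = None, seed: int = 0
) -> FittedModel:
    """Fit one of the five registered model forms."""
    if form not in _FITTERS:
        raise ValueError(f"unknown model form {form!r}; choose from {MODEL_FORM_NAMES}")
    return _FITTERS[form](table, hp=hp, seed=seed)


# --------------------------------------------------------------------------
# Cross-validation

@dataclass
class CVResult:
    form: str
    folds: list[dict]  # auc, sensitivity, specificity, threshold per fold
    mean_auc: float
    mean_sensitivity: float
    mean_specificity: float


def cross_validate(
    form: str,
    table: TrainingTable,
    k: int = 10,
    seed: int = 0,
    hp: dict | None = None,
) -> CVResult:
    """k-fold cross-validation, stratified on the presence label.

    Each fold fits on the other k-1 folds, takes the minimum-training-
    presence threshold from the training partition, and scores AUC,
    sensitivity, and specificity on the held-out fold.  Reported values
    are arithmetic means over folds.
    """
    if table.n_presence < k:
        raise ValueError(
            f"only {table.n_presence} presence rows for {k} folds; "
            "reduce k or supply more presences"
        )
    X, y = table.X, table.y
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = []
    for fold_id, (tr, te) in enumerate(skf.split(X, y)):
        sub = TrainingTable(
            table.frame.iloc[tr].reset_index(drop=True),
            table.covariate_names,
            table.subset,
        )
        model = fit_model(form, sub, hp=hp, seed=seed + fold_id)
        thr = minimum_training_presence_threshold(model, sub.presence_X())
        scores = model.predict(X[te])
        yt = y[te]
        auc = compute_auc(scores[yt == 1], scores[yt == 0])
        sens, spec = confusion_at_threshold(scores[yt == 1], scores[yt == 0], thr)
        folds.append({
            "fold": fold_id, "auc": auc, "sensitivity": sens,
            "specificity": spec, "threshold": thr,
        })
    return CVResult(
        form=form,
        folds=folds,
        mean_auc=float(np.mean([f["auc"] for f in folds])),
        mean_sensitivity=float(np.mean([f["sensitivity"] for f in folds])),
        mean_specificity=float(np.mean([f["specificity"] for f in folds])),
    )


def predict_surface(model: FittedModel, stack: PredictorStack) -> RasterLayer:
    """Per-pixel suitability surface; nodata pixels stay nodata."""
    stack_names = stack.names
    if stack_names != model.covariate_names:
        missing = set(model.covariate_names) - set(stack_names)
        extra = set(stack_names) - set(model.covariate_names)
        if missing or extra:
            raise ValueError(
                f"stack/model covariate mismatch: missing {sorted(missing)}, "
                f"unexpected {sorted(extra)}"
            )
        # Same names, different order: align to training order.
        stack = stack.subset(model.covariate_names)
    valid = stack.valid_mask()
    rows, cols = np.nonzero(valid)
    out = np.full(stack.grid.shape, np.nan)
    if rows.size:
        X = np.column_stack([
            stack.layers[n].values[rows, cols] for n in model.covariate_names
        ])
        out[rows, cols] = model.predict(X)
    return RasterLayer(stack.grid, f"suitability_{model.form.lower()}", out)
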