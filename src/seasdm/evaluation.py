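"""Model evaluation: AUC, minimum-training-presence thresholding,
sensitivity/specificity, and permutation variable importance.

AUC is the rank-based (Mann–Whitney) probability that a random presence
outscores a random background pixel, with ties counted one half.  The
classification threshold is the minimum training presence (MTP): the
lowest suitability predicted for any training presence, with the rule
"predicted >= threshold => presence", which by construction classifies
every training presence correctly.  Variable importance is the drop in
AUC when one covariate column is randomly permuted while the others are
left intact (ΔAUC), averaged over repeats and over model forms, and
ranked.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


def compute_auc(presence_scores, background_scores) -> float:
    """Rank-based AUC: P(random presence score > random background score).

    Ties contribute 1/2.  Equivalent to the Mann–Whitney U statistic
    normalized by ``n_presence * n_background`` and to the trapezoidal
    area under the empirical ROC curve.
    """
    p = np.asarray(presence_scores, dtype=float)
    b = np.asarray(background_scores, dtype=float)
    if p.size == 0 or b.size == 0:
        raise ValueError("presence and background score lists must be non-empty")
    ranks = stats.rankdata(np.concatenate([p, b]))
    r1 = ranks[: p.size].sum()
    u = r1 - p.size * (p.size + 1) / 2.0
    return float(u / (p.size * b.size))


def minimum_training_presence_threshold(model, training_presence_X) -> float:
    """MTP threshold: minimum predicted suitability over training presences."""
    X = np.asarray(training_presence_X, dtype=float)
    if X.shape[0] == 0:
        raise ValueError("need at least one training presence")
    return float(np.min(model.predict(X)))


def confusion_at_threshold(
    presence_scores, background_scores, threshold: float
) -> tuple[float, float]:
    """(sensitivity, specificity) at a threshold with the >= presence rule."""
    p = np.asarray(presence_scores, dtype=float)
    b = np.asarray(background_scores, dtype=float)
    if p.size == 0 or b.size == 0:
        raise ValueError("presence and background score lists must be non-empty")
    sensitivity = float(np.mean(p >= threshold))
    specificity = float(np.mean(b < threshold))
    return sensitivity, specificity


def permutation_importance(
    model,
    X: np.ndarray,
    y: np.ndarray,
    covariate_names: list[str],
    variable: str,
    n_repeats: int = 10,
    seed: int = 0,
) -> float:
    """ΔAUC of one covariate: baseline AUC minus mean permuted AUC.

    Each repeat independently shuffles the variable's column, leaving
    the rest of the evaluation table intact.  Values near zero (possibly
    slightly negative) indicate a covariate the model does not rely on.
    """
    if variable not in covariate_names:
        raise ValueError(f"variable {variable!r} not among {covariate_names}")
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    col = covariate_names.index(variable)
    scores = model.predict(X)
    base = compute_auc(scores[y == 1], scores[y == 0])
    rng = np.random.default_rng(seed)
    perm_aucs = []
    Xp = X.copy()
    for _ in range(n_repeats):
        Xp[:, col] = rng.permutation(X[:, col])
        s = model.predict(Xp)
        perm_aucs.append(compute_auc(s[y == 1], s[y == 0]))
    return float(base - np.mean(perm_aucs))


@dataclass
class VariableImportance:
    variable: str
    per_form: dict[str, float]  # form name -> ΔAUC
    mean_delta_auc: float
    rank: int


def rank_importance(per_form_table: pd.DataFrame) -> list[VariableImportance]:
    """Rank covariates by mean ΔAUC across model forms (descending).

    ``per_form_table`` has one row per variable and one column per form.
    Every form must score the same variable set.  Ties in the mean are
    broken by variable name so the ranking is deterministic.
    """
    if per_form_table.isna().any().any():
        raise ValueError("inconsistent variable sets across forms (missing ΔAUC)")
    means = per_form_table.mean(axis=1)
    order = sorted(per_form_table.index, key=lambda v: (-means[v], v))
    return [
        VariableImportance(
            variable=v,
            per_form=per_form_table.loc[v].to_dict(),
            mean_delta_auc=float(means[v]),
            rank=i + 1,
        )
        for i, v in enumerate(order)
    ]
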