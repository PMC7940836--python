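"""Performance measures: MAE, R^2, Dice overlap, and cross-validation.

"Full" support refers to the concatenation of the per-modality supports
(indices ``k*p + j`` for modality ``k``), "joint" support to the voxels
selected in *both* modalities.  Dice(A, B) = 2|A n B| / (|A| + |B|);
pairwise Dice across fits from different training sets measures support
stability.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd

from . import models, tuning

__all__ = [
    "dice",
    "joint_support",
    "full_support",
    "mae",
    "r_squared",
    "pairwise_dice",
    "kfold_cv",
]


def dice(set_a, set_b) -> float:
    """Dice overlap 2|A n B| / (|A|+|B|) of two index sets.

    Both empty -> 1.0 (perfect agreement on "nothing selected"); exactly one
    empty -> 0.0.
    """
    a = np.unique(np.asarray(list(set_a), dtype=np.int64))
    b = np.unique(np.asarray(list(set_b), dtype=np.int64))
    if a.size == 0 and b.size == 0:
        return 1.0
    inter = np.intersect1d(a, b, assume_unique=True).size
    return 2.0 * inter / (a.size + b.size)


def joint_support(fit_or_pair) -> np.ndarray:
    """Voxels selected in every modality (intersection of supports)."""
    if isinstance(fit_or_pair, (tuple, list)):
        s = fit_or_pair[0].support(0)
        for f in fit_or_pair[1:]:
            s = np.intersect1d(s, f.support(0), assume_unique=True)
        return s
    return fit_or_pair.joint_support


def full_support(fit) -> np.ndarray:
    return fit.full_support


def mae(y, yhat) -> float:
    """Mean absolute prediction error."""
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape:
        raise ValueError("y and yhat must have the same shape")
    return float(np.mean(np.abs(y - yhat)))


def r_squared(y, yhat, center: str = "test_mean") -> float:
    """Coefficient of determination ``1 - SS_res / SS_tot``.

    ``center='test_mean'`` (default) takes SS_tot about the mean of the
    evaluated ``y`` itself, so the null predictor ``yhat = mean(y)`` scores
    exactly 0; ``center='zero'`` uses uncentered SS_tot.
    """
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    ss_res = float(np.sum((y - yhat) ** 2))
    ref = y.mean() if center == "test_mean" else 0.0
    ss_tot = float(np.sum((y - ref) ** 2))
    if ss_tot == 0.0:
        return 1.0 if ss_res == 0.0 else -np.inf
    return 1.0 - ss_res / ss_tot


def pairwise_dice(supports) -> tuple[float, float]:
    """Mean and SD of Dice over all unordered pairs of support sets.

    With a single pair the SD is reported as 0.0 (no spread estimate).
    """
    supports = list(supports)
    if len(supports) < 2:
        raise ValueError("need at least two supports for pairwise comparison")
    vals = [dice(a, b) for a, b in itertools.combinations(supports, 2)]
    sd = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
    return float(np.mean(vals)), sd


def _fit_metrics(fit, design, y_train, test=None):
    row = dict(
        train_mae=mae(y_train, models.predict(fit, design)),
        df=int(fit.full_support.size),
    )
    if test is not None:
        X_test, y_test = test
        yhat = models.predict(fit, design, X_test)
        row["test_mae"] = mae(y_test, yhat)
        row["test_r2"] = r_squared(y_test, yhat)
    return row


def kfold_cv(
    raw_X_list,
    y,
    model_kind: str,
    k: int = 23,
    grid=None,
    settings=None,
    seed: int = 0,
    space=None,
    criterion: str = "bic",
):
    """K-fold cross-validation with per-fold tuning and support stability.

    Folds are a seeded random partition of the subjects into ``k`` near-equal
    parts.  Each fold's model is tuned by BIC on its training portion (raw
    data re-standardized per fold, so no leakage), evaluated on the held-out
    part, and the pairwise Dice of the ``k`` tuned supports summarizes
    stability.  Returns ``(summary_row: dict, per_fold: DataFrame)``.
    """
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    if k > n:
        raise ValueError(f"k={k} exceeds the number of subjects n={n}")
    if k < 2:
        raise ValueError("need at least 2 folds")
    rng = np.random.default_rng(seed)
    fold_of = np.empty(n, dtype=int)
    perm = rng.permutation(n)
    for f, chunk in enumerate(np.array_split(perm, k)):
        fold_of[chunk] = f

    raw_X_list = [np.asarray(X, dtype=float) for X in raw_X_list]
    rows, fulls, joints = [], [], []
    for f in range(k):
        hold = fold_of == f
        X_tr = [X[~hold] for X in raw_X_list]
        X_te = [X[hold] for X in raw_X_list]
        design = models.standardize(X_tr, y[~hold], space=space)
        fit, _ = tuning.grid_search(model_kind, design, grid, settings, criterion)
        row = dict(fold=f, **_fit_metrics(fit, design, y[~hold], (X_te, y[hold])))
        rows.append(row)
        fulls.append(fit.full_support)
        joints.append(fit.joint_support)
    per_fold = pd.DataFrame(rows)
    pw_full = pairwise_dice(fulls)
    pw_joint = pairwise_dice(joints)
    summary = dict(
        model=model_kind,
        train_mae_mean=per_fold.train_mae.mean(),
        train_mae_sd=per_fold.train_mae.std(ddof=1),
        test_mae_mean=per_fold.test_mae.mean(),
        test_mae_sd=per_fold.test_mae.std(ddof=1),
        test_r2_mean=per_fold.test_r2.mean(),
        test_r2_sd=per_fold.test_r2.std(ddof=1),
        pairwise_dice_full_mean=pw_full[0],
        pairwise_dice_full_sd=pw_full[1],
        pairwise_dice_joint_mean=pw_joint[0],
        pairwise_dice_joint_sd=pw_joint[1],
    )
    return summary, per_fold
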