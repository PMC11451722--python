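"""Cross-validated mapping from latent subject scores to a behavioral target.

Subject-mode factor scores (or any subject x feature matrix) are mapped to
the target (e.g. age in months) with k-fold cross-validated ensemble
regression. When the factorization itself is supervised it must be refit
inside each training fold — test subjects receive scores by projection onto
the training fold's non-subject factors, never through their own target —
so the pooled out-of-fold correlation is leakage-free.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.ensemble import GradientBoostingRegressor, RandomForestRegressor
from sklearn.linear_model import LinearRegression
from sklearn.model_selection import KFold

from .tensor import (FeatureTensor, SupervisionSpec, cp_decompose,
                     project_subjects, supervised_cp)

#: Documented default hyperparameters for the regressor families.
REGRESSOR_DEFAULTS = {
    "random_forest": {"n_estimators": 200},
    "gradient_boost": {"n_estimators": 200},
    "linear": {},
}


def make_regressor(name: str, seed: int | None = 0, **overrides):
    params = dict(REGRESSOR_DEFAULTS.get(name, {}), **overrides)
    if name == "random_forest":
        return RandomForestRegressor(random_state=seed, **params)
    if name == "gradient_boost":
        return GradientBoostingRegressor(random_state=seed, **params)
    if name == "linear":
        return LinearRegression(**params)
    raise ValueError(f"unknown regressor: {name!r}")


@dataclass
class PredictionResult:
    """Pooled out-of-fold predictions plus summary metrics."""

    predictions: np.ndarray
    target: np.ndarray
    fold_assignment: np.ndarray
    r: float
    p_value: float
    mae: float
    per_fold_r: list[float]
    regressor: str
    seed: int
    extra: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {"r": self.r, "p_value": self.p_value, "mae": self.mae,
                "per_fold_r": self.per_fold_r, "regressor": self.regressor,
                "seed": self.seed, **self.extra}


def eval_metrics(pred: np.ndarray, target: np.ndarray
                 ) -> tuple[float, float, float]:
    """Pearson r (two-sided p) and mean absolute error in target units."""
    pred = np.asarray(pred, dtype=float)
    target = np.asarray(target, dtype=float)
    if pred.size != target.size or pred.size < 3:
        raise ValueError("need equal-length vectors of length >= 3")
    if pred.std() == 0 or target.std() == 0:
        raise ValueError("zero variance in predictions or target")
    r, p = stats.pearsonr(pred, target)
    mae = float(np.mean(np.abs(pred - target)))
    return float(r), float(p), mae


def cv_regress(scores: np.ndarray, target: np.ndarray, k: int = 5,
               regressor: str = "random_forest", seed: int = 0
               ) -> PredictionResult:
    """k-fold cross-validated regression of the target on fixed scores.

    Folds are disjoint and exhaustive; each subject is predicted exactly
    once, by a model that never saw its target.
    """
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    if scores.shape[0] != np.asarray(target).size:
        scores = scores.T
    target = np.asarray(target, dtype=float).ravel()
    n = target.size
    if k < 2:
        raise ValueError("k must be >= 2")
    if n < 2 * k:
        raise ValueError(f"need at least {2 * k} subjects for k={k}")
    if target.std() == 0:
        raise ValueError("constant target")
    preds = np.empty(n)
    fold_assign = np.empty(n, dtype=int)
    per_fold_r = []
    kf = KFold(n_splits=k, shuffle=True, random_state=seed)
    for fold, (tr, te) in enumerate(kf.split(scores)):
        model = make_regressor(regressor, seed=seed)
        model.fit(scores[tr], target[tr])
        preds[te] = model.predict(scores[te])
        fold_assign[te] = fold
        if preds[te].std() > 0 and target[te].std() > 0:
            per_fold_r.append(float(stats.pearsonr(preds[te], target[te])[0]))
        else:
            per_fold_r.append(0.0)
    r, p, mae = eval_metrics(preds, target)
    return PredictionResult(predictions=preds, target=target,
                            fold_assignment=fold_assign, r=r, p_value=p,
                            mae=mae, per_fold_r=per_fold_r,
                            regressor=regressor, seed=seed)


def crossval_factor_correlation(T: FeatureTensor, target: np.ndarray,
                                rank: int = 3, k: int = 5,
                                supervised: bool = True,
                                gamma: float | str = "auto",
                                seed: int = 0, n_starts: int = 2,
                                tol: float = 1e-7, max_iter: int = 200
                                ) -> float:
    """Pooled held-out correlation between one latent factor and the target.

    Per fold the tensor is factorized on training subjects only; the factor
    whose training scores correlate most with the target is selected (sign
    and standardization also fixed on training data), held-out subjects are
    scored by projection, and the standardized held-out scores are pooled
    across folds. This is the direct factor-target correlation protocol: it
    asks whether a single latent component is a target axis, without any
    downstream regressor.
    """
    target = np.asarray(target, dtype=float).ravel()
    n = T.shape[0]
    pooled = np.empty(n)
    kf = KFold(n_splits=k, shuffle=True, random_state=seed)
    for tr, te in kf.split(np.arange(n)):
        if supervised:
            sup = SupervisionSpec(target=target[tr], gamma=gamma)
            F = supervised_cp(T.values[tr], rank, sup, seed=seed, tol=tol,
                              max_iter=max_iter, n_starts=n_starts,
                              mask=T.mask[tr])
        else:
            F = cp_decompose(T.values[tr], rank, seed=seed, tol=tol,
                             max_iter=max_iter, n_starts=n_starts,
                             mask=T.mask[tr])
        st = project_subjects(F, T.values[tr], mask=T.mask[tr])
        se = project_subjects(F, T.values[te], mask=T.mask[te])
        cors = [np.corrcoef(st[:, r], target[tr])[0, 1]
                for r in range(rank)]
        best = int(np.argmax(np.abs(cors)))
        sign = np.sign(cors[best]) or 1.0
        sd = st[:, best].std()
        pooled[te] = sign * (se[:, best] - st[:, best].mean()) / max(sd, 1e-12)
    return float(stats.pearsonr(pooled, target)[0])


def crossval_factor_regression(T: FeatureTensor, target: np.ndarray,
                               rank: int = 3, k: int = 5,
                               supervised: bool = True,
                               gamma: float | str = "auto",
                               covariates: np.ndarray | None = None,
                               regressor: str = "random_forest",
                               seed: int = 0, n_starts: int = 2,
                               tol: float = 1e-7, max_iter: int = 200
                               ) -> PredictionResult:
    """Per-fold factorization + regression, the full biomarker protocol.

    For every fold: factorize the training subjects' subtensor (supervised
    on training targets only when ``supervised``), project the held-out
    subjects onto the resulting non-subject factors, train the regressor on
    training scores, and predict the held-out targets. Pooled predictions
    give the headline r / MAE; per-fold correlations are also reported.
    """
    target = np.asarray(target, dtype=float).ravel()
    n = T.shape[0]
    if target.size != n:
        raise ValueError("target length must match tensor subject mode")
    preds = np.empty(n)
    fold_assign = np.empty(n, dtype=int)
    per_fold_r = []
    kf = KFold(n_splits=k, shuffle=True, random_state=seed)
    for fold, (tr, te) in enumerate(kf.split(np.arange(n))):
        sub_values = T.values[tr]
        sub_mask = T.mask[tr]
        if supervised:
            sup = SupervisionSpec(
                target=target[tr],
                covariates=None if covariates is None else covariates[tr],
                gamma=gamma)
            F = supervised_cp(sub_values, rank, sup, seed=seed, tol=tol,
                              max_iter=max_iter, n_starts=n_starts,
                              mask=sub_mask)
        else:
            F = cp_decompose(sub_values, rank, seed=seed, tol=tol,
                             max_iter=max_iter, n_starts=n_starts,
                             mask=sub_mask)
        # score train and test subjects with the SAME operator (least-squares
        # projection onto the non-subject factors): supervision shapes the
        # subspace, but features fed to the regressor are computed
        # identically on both sides, so there is no train/test shift and no
        # target leakage into test scores
        train_scores = project_subjects(F, T.values[tr], mask=T.mask[tr])
        train_scores = train_scores * F.weights
        test_scores = project_subjects(F, T.values[te], mask=T.mask[te])
        test_scores = test_scores * F.weights
        model = make_regressor(regressor, seed=seed)
        model.fit(train_scores, target[tr])
        preds[te] = model.predict(test_scores)
        fold_assign[te] = fold
        if preds[te].std() > 0 and target[te].std() > 0:
            per_fold_r.append(float(stats.pearsonr(preds[te], target[te])[0]))
        else:
            per_fold_r.append(0.0)
    r, p, mae = eval_metrics(preds, target)
    return PredictionResult(
        predictions=preds, target=target, fold_assignment=fold_assign,
        r=r, p_value=p, mae=mae, per_fold_r=per_fold_r, regressor=regressor,
        seed=seed,
        extra={"supervised": supervised, "rank": rank, "k": k})
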