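"""Cross-validated microbial biomarker discovery.

The pipeline runs N repeats of stratified K-fold cross-validation on logCPM
abundances. Within each training fold a sparse classifier (L1-penalized
logistic regression, or a random forest) is tuned by an inner 3-fold grid
search and its surviving features become that fold's *candidate* set. A
feature's **importance score** is the fraction of folds whose candidate set
contains it; features scoring at or above the cutoff ``P`` form the final
biomarker panel. Panel performance is then measured by a fresh repeated CV
(seed-offset, same K and N) that refits the model per fold on the fixed panel
— feature selection never sees the evaluation fold's held-out samples — and
reports per-fold ROC curves, their vertical average on a fixed 101-point FPR
grid, and the mean of the per-fold trapezoidal AUCs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import auc, roc_curve
from sklearn.model_selection import GridSearchCV, StratifiedKFold

from .core import MicrobiomeExperiment
from .errors import AnalysisError, ValidationError
from .transform import counts_to_logcpm, upsample_counts

#: Inverse-penalty grid for the L1 logistic path.
LOGISTIC_C_GRID = np.logspace(-3, 3, 8)

#: FPR grid for vertical ROC averaging.
FPR_GRID = np.linspace(0.0, 1.0, 101)

#: Seed offset separating the evaluation CV stream from the selection CV.
EVAL_SEED_OFFSET = 1000

SMALL_SAMPLE_WARNING_N = 30


@dataclass(frozen=True)
class BiomarkerConfig:
    """Parameters of the biomarker search."""

    target: str
    level: str | None = None
    model: str = "logistic"
    K: int = 3
    N: int = 3
    importance_cutoff: float = 0.20
    candidate_fraction: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.model not in ("logistic", "random_forest"):
            raise ValidationError(f"unknown model {self.model!r}")
        if self.K < 2:
            raise ValidationError("K must be >= 2")
        if self.N < 1:
            raise ValidationError("N must be >= 1")
        if not 0 <= self.importance_cutoff <= 1:
            raise ValidationError("importance_cutoff must be in [0, 1]")
        if not 0 < self.candidate_fraction <= 1:
            raise ValidationError("candidate_fraction must be in (0, 1]")


@dataclass(frozen=True)
class BiomarkerResult:
    """Selected panel, per-feature importance scores, and CV performance."""

    selected: tuple[str, ...]
    importance_scores: pd.Series
    fold_aucs: tuple[float, ...]
    mean_auc: float
    roc_fpr: np.ndarray
    roc_mean_tpr: np.ndarray
    n_folds: int
    skipped_folds: int


def cv_splits(labels: pd.Series, K: int, N: int, seed: int):
    """Repeated stratified K-fold splits as (repeat, fold, train_ids, test_ids).

    Stratification keeps each fold's class ratio within one sample of the
    global ratio; the same seed always yields the same splits.
    """
    labels = pd.Series(labels)
    counts = labels.value_counts()
    if len(counts) != 2:
        raise ValidationError(f"target must have exactly 2 classes, got {len(counts)}")
    if counts.min() < K:
        raise ValidationError(
            f"K={K} exceeds the minority class size {counts.min()}"
        )
    ids = labels.index.to_numpy()
    y = labels.to_numpy()
    out = []
    for rep in range(N):
        skf = StratifiedKFold(n_splits=K, shuffle=True, random_state=seed + rep)
        for fold, (tr, te) in enumerate(skf.split(ids, y)):
            out.append((rep, fold, list(ids[tr]), list(ids[te])))
    return out


def _grid_model(model: str, n_features: int, seed: int):
    inner = StratifiedKFold(n_splits=3, shuffle=True, random_state=seed)
    if model == "logistic":
        est = LogisticRegression(penalty="l1", solver="liblinear",
                                 max_iter=2000, random_state=seed)
        grid = {"C": list(LOGISTIC_C_GRID)}
    else:
        p = max(n_features, 1)
        mf = sorted({max(1, int(np.sqrt(p))), max(1, p // 3), max(1, p // 5)})
        est = RandomForestClassifier(n_estimators=200, random_state=seed)
        grid = {"max_features": mf}
    return GridSearchCV(est, grid, cv=inner, scoring="roc_auc", n_jobs=1)


def fold_candidates(
    train_X: pd.DataFrame,
    train_y: pd.Series,
    model: str = "logistic",
    candidate_fraction: float = 1.0,
    seed: int = 0,
):
    """Tune a classifier on one training fold; return its candidate features
    and the fitted scorer.

    Logistic candidates are the features with nonzero L1 coefficients; forest
    candidates are the features with positive impurity importance, truncated
    to the top ``candidate_fraction`` fraction when configured.
    """
    classes = pd.unique(train_y)
    if len(classes) < 2 or min((train_y == c).sum() for c in classes) < 2:
        raise AnalysisError("degenerate training fold: needs >= 2 samples per class")
    search = _grid_model(model, train_X.shape[1], seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        search.fit(train_X.to_numpy(dtype=float), train_y.to_numpy())
    best = search.best_estimator_
    if model == "logistic":
        weight = np.abs(best.coef_.ravel())
        mask = weight > 0
    else:
        weight = best.feature_importances_
        mask = weight > 0
    candidates = list(train_X.columns[mask])
    if candidate_fraction < 1.0 and candidates:
        n_keep = max(1, int(round(candidate_fraction * train_X.shape[1])))
        order = np.argsort(weight)[::-1]
        top = [train_X.columns[i] for i in order[:n_keep] if weight[i] > 0]
        candidates = top
    return candidates, best


def importance_scores(
    candidate_sets: list[list[str]], all_features: pd.Index
) -> pd.Series:
    """Fraction of non-skipped folds whose candidate set contains each feature."""
    if not candidate_sets:
        raise AnalysisError("all folds were skipped; no candidate sets")
    score = pd.Series(0.0, index=all_features)
    for cset in candidate_sets:
        score[list(cset)] += 1.0
    return score / len(candidate_sets)


def _select(scores: pd.Series, cutoff: float) -> list[str]:
    # threshold semantics: score >= P, except P == 0 means "seen in any fold"
    if cutoff == 0:
        mask = scores > 0
    else:
        mask = scores >= cutoff
    return list(scores.index[mask])


def find_biomarker(exp: MicrobiomeExperiment, config: BiomarkerConfig) -> BiomarkerResult:
    """Full biomarker pipeline: select by CV importance, then evaluate the
    fixed panel with a fresh repeated CV."""
    if config.level is not None:
        exp = upsample_counts(exp, config.level)
    if config.target not in exp.sample_metadata.columns:
        raise ValidationError(f"unknown target covariate {config.target!r}")
    y = exp.sample_metadata[config.target]
    if exp.n_samples < SMALL_SAMPLE_WARNING_N:
        warnings.warn(
            f"n={exp.n_samples} samples: biomarker selection on small datasets "
            "is prone to overfitting; interpret with caution",
            stacklevel=2,
        )
    X = counts_to_logcpm(exp.counts).T  # samples x features

    splits = cv_splits(y, config.K, config.N, config.seed)
    candidate_sets: list[list[str]] = []
    skipped = 0
    for rep, fold, train_ids, _ in splits:
        try:
            cands, _model = fold_candidates(
                X.loc[train_ids], y.loc[train_ids],
                model=config.model,
                candidate_fraction=config.candidate_fraction,
                seed=config.seed + 100 * rep + fold,
            )
        except AnalysisError:
            warnings.warn(f"skipping degenerate fold (repeat {rep}, fold {fold})",
                          stacklevel=2)
            skipped += 1
            continue
        candidate_sets.append(cands)
    scores = importance_scores(candidate_sets, X.columns)
    selected = _select(scores, config.importance_cutoff)
    if not selected:
        raise AnalysisError(
            f"no feature reaches importance cutoff P={config.importance_cutoff}; "
            "lower P or use candidate_fraction"
        )

    # evaluation: fresh CV stream, fixed panel, per-fold refit
    pos_label = pd.unique(y)[1]
    eval_splits = cv_splits(y, config.K, config.N, config.seed + EVAL_SEED_OFFSET)
    Xsel = X[selected]
    fold_aucs = []
    tprs = []
    for rep, fold, train_ids, test_ids in eval_splits:
        try:
            _, model = fold_candidates(
                Xsel.loc[train_ids], y.loc[train_ids],
                model=config.model, candidate_fraction=1.0,
                seed=config.seed + EVAL_SEED_OFFSET + 100 * rep + fold,
            )
        except AnalysisError:
            continue
        prob = model.predict_proba(Xsel.loc[test_ids].to_numpy(dtype=float))
        pos_col = list(model.classes_).index(pos_label)
        y_true = (y.loc[test_ids] == pos_label).to_numpy(dtype=int)
        if y_true.min() == y_true.max():
            continue  # held-out fold has a single class; AUC undefined
        fpr, tpr, _ = roc_curve(y_true, prob[:, pos_col])
        fold_aucs.append(float(auc(fpr, tpr)))
        tprs.append(np.interp(FPR_GRID, fpr, tpr))
    if not fold_aucs:
        raise AnalysisError("no evaluation fold produced a defined ROC")
    mean_tpr = np.mean(tprs, axis=0)
    mean_tpr[0] = 0.0
    mean_tpr[-1] = 1.0
    return BiomarkerResult(
        selected=tuple(selected),
        importance_scores=scores,
        fold_aucs=tuple(fold_aucs),
        mean_auc=float(np.mean(fold_aucs)),
        roc_fpr=FPR_GRID.copy(),
        roc_mean_tpr=mean_tpr,
        n_folds=len(candidate_sets),
        skipped_folds=skipped,
    )
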