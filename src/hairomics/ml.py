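"""Family-aware Random-Forest prediction from hair-protein profiles.

Three tasks: classify mothers vs children, classify sex, and predict age
in months, always with log1p spectral counts as features and subjects as
samples.  Cross-validation is *family-aware*: all members of a family
share a fold, so familial similarity in the proteome can never leak from
the training set into the test set.  The study design is 10-fold CV
repeated 100 times; classification is scored by AUC plus a
Wilcoxon-Mann-Whitney test on the two score distributions, regression by
the R^2 and slope p-value of a linear fit of observed on predicted
values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor
from sklearn.metrics import roc_auc_score

from .data import SpectralCountMatrix, SubjectMetadata
from .diffexpr import rank_sum_group_comparison
from scipy import stats

__all__ = [
    "TASKS",
    "CVResult",
    "family_folds",
    "run_cv",
    "evaluate_classification",
    "evaluate_regression",
]

TASKS = ("sex_classification", "person_classification", "age_regression")


def family_folds(
    metadata: SubjectMetadata, k: int, rng: np.random.Generator
) -> dict[str, int]:
    """Randomly partition families into ``k`` folds of near-equal subject counts.

    Families are shuffled, then assigned largest-first to the currently
    smallest fold, so no family ever straddles folds and fold sizes
    differ by at most the largest family size.  Unrelated children are
    singleton families.  Deterministic given the generator state.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    sizes = metadata.table.groupby("family_id").size()
    fams = list(sizes.index)
    order = [fams[i] for i in rng.permutation(len(fams))]
    order.sort(key=lambda f: -sizes[f])  # stable: ties keep shuffled order
    fold_load = np.zeros(k, dtype=int)
    assignment: dict[str, int] = {}
    for fam in order:
        fold = int(np.argmin(fold_load))
        assignment[fam] = fold
        fold_load[fold] += sizes[fam]
    return assignment


@dataclass
class CVResult:
    """Out-of-fold predictions and metrics of a repeated family-aware CV.

    ``predictions`` holds one column per repeat (probability of female /
    probability of mother / predicted age in months); every subject is
    predicted exactly once per repeat.  ``eval_p`` is computed on the
    per-subject mean prediction across repeats: a Wilcoxon-Mann-Whitney
    p for classification, the linear-model slope p for regression.
    """

    task: str
    predictions: pd.DataFrame
    per_repeat_metric: np.ndarray
    mean_metric: float
    metric_name: str
    eval_statistic: float
    eval_p: float
    n_excluded_repeats: int
    fold_log: list[dict[str, int]] = field(repr=False, default_factory=list)
    seed: Optional[int] = None


def _task_target(task: str, metadata: SubjectMetadata) -> np.ndarray:
    t = metadata.table
    if task == "person_classification":
        return (t["role"] == "mother").to_numpy()
    if task == "sex_classification":
        return (t["sex"] == "F").to_numpy()
    if task == "age_regression":
        return t["age_months"].to_numpy(dtype=float)
    raise ValueError(f"unknown task {task!r}; expected one of {TASKS}")


def run_cv(
    matrix: SpectralCountMatrix,
    metadata: SubjectMetadata,
    task: str,
    k: int = 10,
    n_repeats: int = 100,
    seed: Optional[int] = None,
    n_estimators: int = 500,
    shuffle_labels: bool = False,
    log_transform: bool = True,
) -> CVResult:
    """Repeated k-fold family-aware CV with a Random Forest.

    Each repeat draws a fresh family-fold partition, trains on k-1 folds
    and predicts the held-out fold, covering every subject once.  A
    train/test family overlap is asserted impossible on every fold.
    ``shuffle_labels`` permutes the target anew each repeat — the
    permutation null for the whole pipeline, under which classification
    AUC is centred on 0.5.

    Repeats whose pooled out-of-fold predictions cannot be scored (a
    class absent) are excluded from the mean and counted.
    """
    if task not in TASKS:
        raise ValueError(f"unknown task {task!r}; expected one of {TASKS}")
    subjects = list(matrix.counts.columns)
    if set(subjects) != set(metadata.subject_ids):
        raise ValueError("matrix subjects and metadata subjects differ")
    meta = metadata.subset(subjects)

    x = matrix.counts.T.to_numpy(dtype=float)
    if log_transform:
        x = np.log1p(x)
    y = _task_target(task, meta)
    classification = task != "age_regression"
    if classification and len(np.unique(y)) < 2:
        raise ValueError("classification target has a single class")

    families = meta.table["family_id"].to_numpy()
    ss = np.random.SeedSequence(seed)
    repeat_seeds = ss.generate_state(2 * n_repeats) % (2**31)

    preds = pd.DataFrame(
        np.nan, index=subjects, columns=[f"repeat_{r + 1}" for r in range(n_repeats)]
    )
    metrics, fold_log = [], []
    n_excluded = 0
    for r in range(n_repeats):
        rng = np.random.default_rng(int(repeat_seeds[2 * r]))
        rf_seed = int(repeat_seeds[2 * r + 1])
        assignment = family_folds(meta, k, rng)
        fold_log.append(assignment)
        folds = np.array([assignment[f] for f in families])
        y_rep = rng.permutation(y) if shuffle_labels else y

        col = np.full(len(subjects), np.nan)
        for fold in range(k):
            test = folds == fold
            if not test.any():
                continue
            train = ~test
            train_fams = set(families[train])
            test_fams = set(families[test])
            assert not (train_fams & test_fams), "family leak between train and test"
            if classification:
                if len(np.unique(y_rep[train])) < 2:
                    continue  # untrainable fold; its subjects stay unpredicted
                model = RandomForestClassifier(
                    n_estimators=n_estimators, random_state=rf_seed
                )
                model.fit(x[train], y_rep[train])
                pos = list(model.classes_).index(True)
                col[test] = model.predict_proba(x[test])[:, pos]
            else:
                model = RandomForestRegressor(
                    n_estimators=n_estimators, random_state=rf_seed
                )
                model.fit(x[train], y_rep[train])
                col[test] = model.predict(x[test])
        preds.iloc[:, r] = col

        scored = ~np.isnan(col)
        try:
            if classification:
                metric, _ = evaluate_classification(col[scored], y_rep[scored])
            else:
                metric, _ = evaluate_regression(col[scored], y_rep[scored])
            metrics.append(metric)
        except ValueError:
            n_excluded += 1
            metrics.append(np.nan)
    if n_excluded:
        warnings.warn(f"{n_excluded} repeat(s) had undefined metrics", stacklevel=2)

    per_repeat = np.array(metrics, dtype=float)
    mean_metric = float(np.nanmean(per_repeat))
    mean_pred = preds.mean(axis=1).to_numpy()
    if classification:
        eval_stat, eval_p = evaluate_classification(mean_pred, y)
        metric_name = "auc"
    else:
        eval_stat, eval_p = evaluate_regression(mean_pred, y)
        metric_name = "r_squared"
    return CVResult(
        task=task,
        predictions=preds,
        per_repeat_metric=per_repeat,
        mean_metric=mean_metric,
        metric_name=metric_name,
        eval_statistic=eval_stat,
        eval_p=eval_p,
        n_excluded_repeats=n_excluded,
        fold_log=fold_log,
        seed=seed,
    )


def evaluate_classification(scores: Sequence[float], labels: Sequence[bool]) -> tuple[float, float]:
    """AUC and Wilcoxon-Mann-Whitney p for scores of a binary label.

    AUC is the rank-based probability that a positive's score exceeds a
    negative's (ties count 1/2); it equals U/(n1*n2), an identity
    asserted internally against the U statistic.  The p-value is the
    two-sided rank-sum test between the two score distributions.
    """
    s = np.asarray(scores, dtype=float)
    lab = np.asarray(labels, dtype=bool)
    pos, neg = s[lab], s[~lab]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes must be present to compute AUC")
    auc = float(roc_auc_score(lab, s))
    u, p = rank_sum_group_comparison(pos, neg)
    assert abs(auc - u / (len(pos) * len(neg))) < 1e-9, "AUC != U/(n1*n2)"
    return auc, p


def evaluate_regression(predicted: Sequence[float], observed: Sequence[float]) -> tuple[float, float]:
    """R^2 and slope p of the linear fit of observed on predicted values.

    Zero variance in the predictions gives (0, 1) by convention.
    """
    pred = np.asarray(predicted, dtype=float)
    obs = np.asarray(observed, dtype=float)
    if len(pred) < 3:
        raise ValueError("need at least 3 pairs")
    if np.var(pred) == 0:
        return 0.0, 1.0
    fit = stats.linregress(pred, obs)
    return float(fit.rvalue**2), float(fit.pvalue)
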