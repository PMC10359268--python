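"""Slide-level morphometric moments and elastic-net classification.

Each slide is summarized by the mean and unbiased variance of every
morphometric feature over its cells — 42 red-cell and 53 white-cell
features give a 190-long moment vector — optionally extended with the
three blood counts (WBCC, Hb, Plt). Four binary diagnostic contrasts are
fit with cross-validated elastic-net logistic regression; a variance
decomposition of the linear predictor attributes prediction to feature
groups.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold

from .io_core import TASKS, SlideBag
from .morphometry import cell_feature_names, wbc_feature_names

BLOOD_COUNTS = ("wbcc", "hb", "plt")


@dataclass
class TaskSpec:
    """One of the four binary diagnostic contrasts.

    Eligibility is encoded in the slide labels themselves: a slide takes
    part in a task iff its label for that task is 0 or 1.
    """

    task: str

    def __post_init__(self) -> None:
        if self.task not in TASKS:
            raise ValueError(f"unknown task {self.task!r}; expected one of {TASKS}")

    def eligible(self, bag_or_labels) -> bool:
        labels = getattr(bag_or_labels, "labels", bag_or_labels)
        return labels.get(self.task) is not None

    def label(self, bag_or_labels) -> int:
        labels = getattr(bag_or_labels, "labels", bag_or_labels)
        return int(labels[self.task])


def moment_names() -> list[str]:
    names = []
    for feat in cell_feature_names():
        names += [f"rbc_{feat}_mean", f"rbc_{feat}_var"]
    for feat in wbc_feature_names():
        names += [f"wbc_{feat}_mean", f"wbc_{feat}_var"]
    return names


@dataclass
class SlideSummary:
    """Per-slide moment vector plus blood counts and cell counts."""

    slide_id: str
    moments: pd.Series  # indexed by moment_names()
    blood_counts: dict[str, float | None]
    n_rbc: int
    n_wbc: int
    labels: dict[str, int | None] = field(default_factory=dict)
    condition: str | None = None


def compute_moments(bag: SlideBag) -> SlideSummary:
    """Mean and unbiased (n-1) variance of each feature for each cell type.

    Moments of a cell type with fewer than two cells are flagged missing
    (NaN); an entirely empty bag is an error.
    """
    if bag.n_cells("rbc") == 0 and bag.n_cells("wbc") == 0:
        raise ValueError(f"slide {bag.slide_id}: empty bag")
    values: dict[str, float] = {}
    for ct, canonical in (("rbc", cell_feature_names()), ("wbc", wbc_feature_names())):
        mat = bag.rbc_features if ct == "rbc" else bag.wbc_features
        n = bag.n_cells(ct)
        d = mat.shape[1] if (mat.ndim == 2 and mat.shape[1] > 0) else len(canonical)
        # canonical names when the bag carries the full schema, positional
        # names for reduced-dimension (e.g. simulated) feature spaces
        names = canonical if d == len(canonical) else [f"f{j}" for j in range(d)]
        for j, feat in enumerate(names):
            if n >= 2:
                col = mat[:, j]
                values[f"{ct}_{feat}_mean"] = float(col.mean())
                values[f"{ct}_{feat}_var"] = float(col.var(ddof=1))
            elif n == 1:
                values[f"{ct}_{feat}_mean"] = float(mat[0, j])
                values[f"{ct}_{feat}_var"] = np.nan
            else:
                values[f"{ct}_{feat}_mean"] = np.nan
                values[f"{ct}_{feat}_var"] = np.nan
    moments = pd.Series(values)
    return SlideSummary(
        slide_id=bag.slide_id, moments=moments, blood_counts=dict(bag.blood_counts),
        n_rbc=bag.n_cells("rbc"), n_wbc=bag.n_cells("wbc"),
        labels=dict(bag.labels), condition=bag.condition,
    )


def summaries_to_frame(summaries: Sequence[SlideSummary],
                       use_blood_counts: bool = False) -> pd.DataFrame:
    """Stack summaries into a design matrix (rows = slides)."""
    rows = []
    for s in summaries:
        row = s.moments.copy()
        if use_blood_counts:
            for bc in BLOOD_COUNTS:
                val = s.blood_counts.get(bc)
                row[f"bc_{bc}"] = np.nan if val is None else float(val)
        row.name = s.slide_id
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Elastic-net model
# ---------------------------------------------------------------------------

@dataclass
class FoldModel:
    classifier: LogisticRegression
    feat_mean: np.ndarray
    feat_scale: np.ndarray
    impute_median: np.ndarray
    columns: list[str]


@dataclass
class ElasticNetResult:
    task: str
    fold_models: list[FoldModel]
    fold_assignments: np.ndarray  # fold index per eligible slide
    oof_probs: np.ndarray
    labels: np.ndarray
    slide_ids: list[str]
    cv_auc: float
    roc: tuple[np.ndarray, np.ndarray]  # (fpr, tpr) on pooled out-of-fold scores
    best_fold: int


def _fit_fold(X_tr, y_tr, columns, C_grid, l1_ratio, seed, inner_folds=3):
    """Impute/standardize on the training fold, pick C by inner-CV deviance."""
    med = np.nanmedian(X_tr, axis=0)
    med = np.where(np.isnan(med), 0.0, med)
    X_tr = np.where(np.isnan(X_tr), med, X_tr)
    mean = X_tr.mean(axis=0)
    scale = X_tr.std(axis=0)
    scale[scale < 1e-12] = 1.0
    Xs = (X_tr - mean) / scale

    best_C, best_dev = C_grid[0], np.inf
    if len(C_grid) > 1 and np.bincount(y_tr).min() >= inner_folds:
        inner = StratifiedKFold(n_splits=inner_folds, shuffle=True, random_state=seed)
        for C in C_grid:
            dev = 0.0
            for tr, te in inner.split(Xs, y_tr):
                clf = LogisticRegression(
                    l1_ratio=l1_ratio, C=C,
                    solver="saga", max_iter=5000, random_state=seed,
                )
                clf.fit(Xs[tr], y_tr[tr])
                p = np.clip(clf.predict_proba(Xs[te])[:, 1], 1e-12, 1 - 1e-12)
                dev += -np.sum(y_tr[te] * np.log(p) + (1 - y_tr[te]) * np.log(1 - p))
            if dev < best_dev:
                best_dev, best_C = dev, C
    clf = LogisticRegression(
        l1_ratio=l1_ratio, C=best_C,
        solver="saga", max_iter=20000, random_state=seed,
    )
    clf.fit(Xs, y_tr)
    return FoldModel(clf, mean, scale, med, list(columns))


def _apply_fold(model: FoldModel, X):
    X = np.where(np.isnan(X), model.impute_median, X)
    Xs = (X - model.feat_mean) / model.feat_scale
    return model.classifier.predict_proba(Xs)[:, 1]


def fit_elastic_net_cv(
    frame: pd.DataFrame,
    labels: Sequence[int | None] | dict[str, dict],
    task: TaskSpec | str,
    folds: int = 5,
    seed: int = 0,
    l1_ratio: float = 0.5,
    C_grid: Sequence[float] = (0.01, 0.1, 1.0, 10.0),
) -> ElasticNetResult:
    """Cross-validated elastic-net logistic regression for one task.

    Features are z-scored (and missing values median-imputed) with
    training-fold statistics only; folds are stratified on the task label.
    Returns per-fold models and the pooled out-of-fold AUC.
    """
    if isinstance(task, str):
        task = TaskSpec(task)
    if isinstance(labels, dict):
        y_all = [labels[sid].get(task.task) for sid in frame.index]
    else:
        y_all = list(labels)
    eligible = [i for i, y in enumerate(y_all) if y is not None]
    if not eligible:
        raise ValueError(f"no slides eligible for task {task.task}")
    X = frame.to_numpy(dtype=float)[eligible]
    y = np.array([y_all[i] for i in eligible], dtype=int)
    slide_ids = [str(frame.index[i]) for i in eligible]
    if np.bincount(y, minlength=2).min() < folds:
        raise ValueError(
            f"task {task.task}: need >= {folds} slides per class for stratification"
        )

    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    oof = np.full(len(y), np.nan)
    assign = np.full(len(y), -1)
    fold_models = []
    fold_aucs = []
    for fold_idx, (tr, te) in enumerate(skf.split(X, y)):
        model = _fit_fold(X[tr], y[tr], frame.columns, list(C_grid), l1_ratio, seed)
        fold_models.append(model)
        oof[te] = _apply_fold(model, X[te])
        assign[te] = fold_idx
        fold_aucs.append(
            roc_auc_score(y[te], oof[te]) if len(np.unique(y[te])) > 1 else np.nan
        )
    cv_auc = float(roc_auc_score(y, oof))
    fpr, tpr, _ = roc_curve(y, oof)
    best_fold = int(np.nanargmax(fold_aucs))
    return ElasticNetResult(
        task=task.task, fold_models=fold_models, fold_assignments=assign,
        oof_probs=oof, labels=y, slide_ids=slide_ids, cv_auc=cv_auc,
        roc=(fpr, tpr), best_fold=best_fold,
    )


def predict_slide(model: FoldModel, row: pd.Series | np.ndarray) -> float:
    """Probability for one slide summary under a fitted fold model."""
    if isinstance(row, pd.Series):
        missing = [c for c in model.columns if c not in row.index]
        if missing:
            raise ValueError(f"summary missing features: {missing[:5]}")
        x = row[model.columns].to_numpy(dtype=float)
    else:
        x = np.asarray(row, dtype=float)
    return float(_apply_fold(model, x[None, :])[0])


# ---------------------------------------------------------------------------
# Feature-group attribution
# ---------------------------------------------------------------------------

def default_groups(columns: Sequence[str]) -> dict[str, list[str]]:
    """Partition moment/blood-count columns into the five standard groups."""
    groups: dict[str, list[str]] = {
        "rbc_mean": [], "rbc_var": [], "wbc_mean": [], "wbc_var": [], "blood_counts": [],
    }
    for col in columns:
        if col.startswith("bc_"):
            groups["blood_counts"].append(col)
        elif col.startswith("rbc_"):
            groups["rbc_mean" if col.endswith("_mean") else "rbc_var"].append(col)
        elif col.startswith("wbc_"):
            groups["wbc_mean" if col.endswith("_mean") else "wbc_var"].append(col)
    return {g: cols for g, cols in groups.items() if cols}


def feature_group_contribution(
    model: FoldModel,
    frame: pd.DataFrame,
    groups: dict[str, Sequence[str]] | None = None,
) -> dict[str, float]:
    """Share of linear-predictor variance attributable to each feature group.

    With eta = sum_g eta_g (eta_g the group's partial linear predictor on
    the standardized data), the share of group g is
    [Var(eta_g) + sum_{h != g} Cov(eta_g, eta_h)] / Var(eta): covariance
    cross-terms are split equally between the two groups involved, so the
    shares sum to 1 and are invariant to feature order.
    """
    if groups is None:
        groups = default_groups(model.columns)
    X = frame[model.columns].to_numpy(dtype=float)
    X = np.where(np.isnan(X), model.impute_median, X)
    Xs = (X - model.feat_mean) / model.feat_scale
    beta = model.classifier.coef_.ravel()
    if np.allclose(beta, 0):
        raise ValueError("all coefficients are zero: contribution undefined")
    col_idx = {c: i for i, c in enumerate(model.columns)}
    etas = {}
    for g, cols in groups.items():
        idx = [col_idx[c] for c in cols]
        etas[g] = Xs[:, idx] @ beta[idx]
    eta = np.sum(list(etas.values()), axis=0)
    total_var = float(np.var(eta))
    if total_var <= 0:
        raise ValueError("linear predictor has zero variance")
    names = list(etas)
    cov = np.cov(np.stack([etas[g] for g in names]), ddof=0)
    cov = np.atleast_2d(cov)
    shares = {}
    for i, g in enumerate(names):
        shares[g] = float((cov[i, i] + np.sum(np.delete(cov[i], i))) / total_var)
    return shares
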