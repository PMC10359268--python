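"""Morphotype analysis: prototype-based multiple-instance learning.

The model learns K soft cell prototypes ("computational morphotypes") per
cell type jointly with slide-level linear classifiers over morphotype
proportions. Each cell i is softly assigned to prototypes by

    a_ik = softmax_k( -tau * ||x_i - m_k||^2 )

in standardized feature space, with a learnable assignment temperature
tau > 0. A slide's proportion vector is the mean of its cells' assignment
rows; white- and red-cell proportions (optionally with standardized blood
counts) feed one linear head per diagnostic task. Training minimizes the
sum over tasks of the mean binary cross-entropy over task-eligible slides
(slides without a label for a task are masked out of that task's term),
by full-batch Adam with analytic gradients.

Morphotypes that recur across cross-validation folds — matched one-to-one
by maximal total cosine similarity and exceeding a similarity threshold in
every fold — are labeled *stable* and can be used alone at prediction
time, guarding against fold-specific solutions.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist
from sklearn.cluster import KMeans
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import KFold, StratifiedKFold

from .io_core import TASKS, SlideBag

CELL_TYPES = ("wbc", "rbc")
VALID_K = (10, 25, 50)


class TaskError(ValueError):
    pass


def _sigmoid(z):
    return 1.0 / (1.0 + np.exp(-np.clip(z, -500, 500)))


# ---------------------------------------------------------------------------
# Model container
# ---------------------------------------------------------------------------

@dataclass
class MorphotypeModel:
    prototypes: dict[str, np.ndarray]        # cell type -> (K, d), standardized space
    log_tau: dict[str, float]                # temperature, tau = exp(log_tau)
    heads: dict[str, tuple[np.ndarray, float]]  # task -> (weights, intercept)
    feat_stats: dict[str, tuple[np.ndarray, np.ndarray]]  # cell type -> (mean, scale)
    bc_stats: tuple[np.ndarray, np.ndarray] | None = None
    use_blood_counts: bool = False
    tasks: tuple[str, ...] = TASKS

    def tau(self, ct: str) -> float:
        return float(np.exp(self.log_tau[ct]))

    @property
    def k(self) -> dict[str, int]:
        return {ct: self.prototypes[ct].shape[0] for ct in self.prototypes}

    def head_dim(self) -> int:
        d = sum(self.prototypes[ct].shape[0] for ct in CELL_TYPES)
        return d + (3 if self.use_blood_counts else 0)

    def morphotype_ids(self) -> list[str]:
        return [f"{ct}_{k}" for ct in CELL_TYPES
                for k in range(self.prototypes[ct].shape[0])]

    def copy(self) -> "MorphotypeModel":
        return copy.deepcopy(self)


def _standardize_cells(model: MorphotypeModel, ct: str, X: np.ndarray) -> np.ndarray:
    mean, scale = model.feat_stats[ct]
    return (np.atleast_2d(X) - mean) / scale


def _blood_vector(model: MorphotypeModel, bag: SlideBag) -> np.ndarray:
    mean, scale = model.bc_stats
    raw = np.array([
        bag.blood_counts.get(k) if bag.blood_counts.get(k) is not None else mean[i]
        for i, k in enumerate(("wbcc", "hb", "plt"))
    ], dtype=float)
    return (raw - mean) / scale


def init_model(
    bags: Sequence[SlideBag],
    k: int | dict[str, int],
    tasks: Sequence[str] = TASKS,
    use_blood_counts: bool = False,
    seed: int = 0,
    max_kmeans_cells: int = 20000,
) -> MorphotypeModel:
    """Initialize prototypes by k-means on a pooled training subsample.

    Features are standardized with pooled per-cell-type statistics; heads
    start at zero and tau at 1. Deterministic given ``seed``.
    """
    if isinstance(k, int):
        k = {ct: k for ct in CELL_TYPES}
    for ct, kk in k.items():
        if kk < 2:
            raise ValueError("K must be >= 2")
    rng = np.random.default_rng(seed)
    prototypes, log_tau, feat_stats = {}, {}, {}
    for ct in CELL_TYPES:
        mats = [b.wbc_features if ct == "wbc" else b.rbc_features
                for b in bags if b.n_cells(ct) > 0]
        if not mats:
            raise ValueError(f"no {ct} cells in training bags")
        X = np.concatenate(mats)
        if k[ct] > X.shape[0]:
            raise ValueError(f"K={k[ct]} exceeds number of {ct} training cells")
        mean = X.mean(axis=0)
        scale = X.std(axis=0)
        scale[scale < 1e-12] = 1.0
        Xs = (X - mean) / scale
        if Xs.shape[0] > max_kmeans_cells:
            idx = rng.choice(Xs.shape[0], size=max_kmeans_cells, replace=False)
            Xs = Xs[idx]
        km = KMeans(n_clusters=k[ct], n_init=5,
                    random_state=int(rng.integers(2**31 - 1)))
        km.fit(Xs)
        prototypes[ct] = km.cluster_centers_.copy()
        log_tau[ct] = 0.0
        feat_stats[ct] = (mean, scale)

    bc_stats = None
    if use_blood_counts:
        raw = np.array([
            [b.blood_counts.get(key) for key in ("wbcc", "hb", "plt")]
            for b in bags
        ], dtype=float)
        mean = np.nanmean(raw, axis=0)
        mean = np.where(np.isnan(mean), 0.0, mean)
        scale = np.nanstd(raw, axis=0)
        scale = np.where((scale < 1e-12) | np.isnan(scale), 1.0, scale)
        bc_stats = (mean, scale)

    heads = {
        t: (np.zeros(sum(k[ct] for ct in CELL_TYPES)
                     + (3 if use_blood_counts else 0)), 0.0)
        for t in tasks
    }
    return MorphotypeModel(
        prototypes=prototypes, log_tau=log_tau, heads=heads,
        feat_stats=feat_stats, bc_stats=bc_stats,
        use_blood_counts=use_blood_counts, tasks=tuple(tasks),
    )


# ---------------------------------------------------------------------------
# Forward pass
# ---------------------------------------------------------------------------

def soft_assign(model: MorphotypeModel, cell_type: str, features: np.ndarray,
                standardized: bool = False) -> np.ndarray:
    """Soft assignment matrix (n, K); each row lies on the simplex."""
    X = np.atleast_2d(np.asarray(features, dtype=float))
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite cell features")
    if not standardized:
        X = _standardize_cells(model, cell_type, X)
    D = cdist(X, model.prototypes[cell_type], metric="sqeuclidean")
    Z = -model.tau(cell_type) * D
    Z -= Z.max(axis=1, keepdims=True)
    A = np.exp(Z)
    A /= A.sum(axis=1, keepdims=True)
    return A


def slide_proportions(assignments: np.ndarray) -> np.ndarray:
    """Per-slide morphotype proportion vector: the mean assignment row."""
    A = np.atleast_2d(assignments)
    if A.shape[0] == 0:
        raise ValueError("slide has no cells")
    return A.mean(axis=0)


def bag_proportions(model: MorphotypeModel, bag: SlideBag) -> np.ndarray:
    """Concatenated [p_wbc ; p_rbc] for one bag; a missing cell type
    contributes a zero block."""
    parts = []
    for ct in CELL_TYPES:
        X = bag.wbc_features if ct == "wbc" else bag.rbc_features
        if bag.n_cells(ct) == 0:
            parts.append(np.zeros(model.prototypes[ct].shape[0]))
        else:
            parts.append(slide_proportions(soft_assign(model, ct, X)))
    return np.concatenate(parts)


def mil_forward(model: MorphotypeModel, bag: SlideBag) -> dict[str, float]:
    """Per-task logits for one slide bag."""
    feats = bag_proportions(model, bag)
    if model.use_blood_counts:
        feats = np.concatenate([feats, _blood_vector(model, bag)])
    logits = {}
    for task, (w, b) in model.heads.items():
        if w.shape[0] != feats.shape[0]:
            raise ValueError(
                f"head for {task} expects {w.shape[0]} inputs, got {feats.shape[0]}"
            )
        logits[task] = float(feats @ w + b)
    return logits


def predict_proba(model: MorphotypeModel, bag: SlideBag) -> dict[str, float]:
    return {t: float(_sigmoid(z)) for t, z in mil_forward(model, bag).items()}


# ---------------------------------------------------------------------------
# Training (full-batch Adam, analytic gradients)
# ---------------------------------------------------------------------------

@dataclass
class TrainConfig:
    """Full-batch Adam settings.

    Prototypes and the assignment temperature use a 10x smaller step than
    the linear heads: the k-means initialization already places prototypes
    at the cell-density optima, and the slide-level objective alone would
    otherwise drag them to fold-specific decision-optimal positions,
    destroying cross-fold stability.

    ``cluster_weight`` scales a soft k-means density-attachment term
    (the expected squared cell-to-prototype distance under the soft
    assignments) that anchors prototypes to the cell density. Without it,
    surplus prototypes fragment each density mode along directions chosen
    by sampling noise — a rotational degeneracy that makes morphotypes
    irreproducible across folds. The attachment gradient treats the
    assignments as fixed (EM-style), so it pulls each prototype toward
    its softly assigned cell mean; the classification loss is unaffected
    and is what the reported loss trajectory tracks.
    """

    learning_rate: float = 1e-2
    prototype_lr: float = 1e-3
    epochs: int = 500
    patience: int = 50          # early stop when smoothed loss plateaus
    min_delta: float = 1e-5
    cluster_weight: float = 0.1  # density-attachment strength, see below
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8


@dataclass
class _BagCache:
    """Standardized features and squared distances reused every epoch."""

    X: dict[str, np.ndarray]
    blood: np.ndarray | None
    labels: dict[str, int | None]


def _prepare(model, bags):
    cache = []
    for bag in bags:
        X = {}
        for ct in CELL_TYPES:
            raw = bag.wbc_features if ct == "wbc" else bag.rbc_features
            X[ct] = _standardize_cells(model, ct, raw) if bag.n_cells(ct) else None
        blood = _blood_vector(model, bag) if model.use_blood_counts else None
        cache.append(_BagCache(X=X, blood=blood, labels=bag.labels))
    return cache


def multi_objective_loss(model: MorphotypeModel, bags: Sequence[SlideBag],
                         objectives: Sequence[str] | None = None) -> float:
    """Sum over tasks of mean binary cross-entropy over eligible slides."""
    objectives = list(objectives or model.tasks)
    per_task: dict[str, list[float]] = {t: [] for t in objectives}
    for bag in bags:
        logits = mil_forward(model, bag)
        for t in objectives:
            y = bag.labels.get(t)
            if y is None:
                continue
            p = _sigmoid(logits[t])
            per_task[t].append(-(y * np.log(p + 1e-12)
                                 + (1 - y) * np.log(1 - p + 1e-12)))
    total = 0.0
    for t in objectives:
        if per_task[t]:
            total += float(np.mean(per_task[t]))
    return total


def _params_from_model(model: MorphotypeModel, objectives):
    params = {}
    for ct in CELL_TYPES:
        params[f"M_{ct}"] = model.prototypes[ct].copy()
        params[f"logtau_{ct}"] = np.array([model.log_tau[ct]])
    for t in objectives:
        w, b = model.heads[t]
        params[f"w_{t}"] = w.copy()
        params[f"b_{t}"] = np.array([b])
    return params


def _epoch_loss_grads(params, cache, objectives, n_eligible, k, offsets, head_dim,
                      cluster_weight: float = 0.0):
    """Full-batch classification loss and analytic gradients.

    With ``cluster_weight`` > 0, prototype gradients additionally include
    the density-attachment pull toward each prototype's softly assigned
    cell mean (assignments treated as constants); the returned loss value
    is the classification term only.
    """
    grads = {key: np.zeros_like(v) for key, v in params.items()}
    attach = {ct: np.zeros_like(params[f"M_{ct}"]) for ct in CELL_TYPES}
    n_cells_total = {ct: 0 for ct in CELL_TYPES}
    total_loss = 0.0
    for c in cache:
        # forward
        A, D, p = {}, {}, {}
        for ct in CELL_TYPES:
            if c.X[ct] is None:
                A[ct] = D[ct] = None
                p[ct] = np.zeros(k[ct])
                continue
            tau = float(np.exp(params[f"logtau_{ct}"][0]))
            Dct = cdist(c.X[ct], params[f"M_{ct}"], metric="sqeuclidean")
            Z = -tau * Dct
            Z -= Z.max(axis=1, keepdims=True)
            Act = np.exp(Z)
            Act /= Act.sum(axis=1, keepdims=True)
            A[ct], D[ct] = Act, Dct
            p[ct] = Act.mean(axis=0)
            if cluster_weight > 0:
                col = Act.sum(axis=0)
                attach[ct] += 2.0 * (col[:, None] * params[f"M_{ct}"]
                                     - Act.T @ c.X[ct])
                n_cells_total[ct] += Act.shape[0]
        feat = np.concatenate([p["wbc"], p["rbc"]] +
                              ([c.blood] if c.blood is not None else []))
        # per-task loss and upstream gradient on the proportion vector
        dfeat = np.zeros(head_dim)
        for t in objectives:
            y = c.labels.get(t)
            if y is None:
                continue
            w = params[f"w_{t}"]
            logit = float(feat @ w + params[f"b_{t}"][0])
            prob = _sigmoid(logit)
            total_loss += (-(y * np.log(prob + 1e-12)
                             + (1 - y) * np.log(1 - prob + 1e-12))
                           / n_eligible[t])
            dlogit = (prob - y) / n_eligible[t]
            grads[f"w_{t}"] += dlogit * feat
            grads[f"b_{t}"][0] += dlogit
            dfeat += dlogit * w
        # backprop through proportions into prototypes and temperature
        for ct in CELL_TYPES:
            if A[ct] is None:
                continue
            tau = float(np.exp(params[f"logtau_{ct}"][0]))
            n_cells = A[ct].shape[0]
            u = dfeat[offsets[ct] : offsets[ct] + k[ct]] / n_cells
            s = A[ct] @ u  # (n,)
            G = A[ct] * (u[None, :] - s[:, None])  # dL/dZ, Z = -tau * D
            # dL/dM_k = -tau * sum_i G_ik * 2 (m_k - x_i)
            col = G.sum(axis=0)
            grads[f"M_{ct}"] += -tau * 2.0 * (
                col[:, None] * params[f"M_{ct}"] - G.T @ c.X[ct]
            )
            grads[f"logtau_{ct}"][0] += float(-(G * D[ct]).sum() * tau)
    if cluster_weight > 0:
        for ct in CELL_TYPES:
            if n_cells_total[ct]:
                grads[f"M_{ct}"] += cluster_weight * attach[ct] / n_cells_total[ct]
    return total_loss, grads


def _training_setup(model, bags, objectives):
    cache = _prepare(model, bags)
    n_eligible = {t: sum(1 for c in cache if c.labels.get(t) is not None)
                  for t in objectives}
    k = model.k
    offsets, off = {}, 0
    for ct in CELL_TYPES:
        offsets[ct] = off
        off += k[ct]
    return cache, n_eligible, k, offsets


def loss_and_gradients(model: MorphotypeModel, bags: Sequence[SlideBag],
                       objectives: Sequence[str] | None = None):
    """Loss and analytic parameter gradients at the model's current state."""
    objectives = list(objectives or model.tasks)
    cache, n_eligible, k, offsets = _training_setup(model, bags, objectives)
    params = _params_from_model(model, objectives)
    return _epoch_loss_grads(params, cache, objectives, n_eligible, k,
                             offsets, model.head_dim())


def train(
    model: MorphotypeModel,
    bags: Sequence[SlideBag],
    objectives: Sequence[str] | None = None,
    config: TrainConfig | None = None,
    seed: int = 0,
) -> tuple[MorphotypeModel, list[float]]:
    """Train prototypes, temperatures and heads jointly by full-batch Adam.

    Returns the trained model and the loss trajectory. Deterministic given
    the model initialization and ``seed`` (the optimizer itself is
    deterministic; ``seed`` is reserved for stochastic batching variants).
    """
    model = model.copy()
    objectives = list(objectives or model.tasks)
    for t in objectives:
        labels = [b.labels.get(t) for b in bags]
        pos = sum(1 for v in labels if v == 1)
        neg = sum(1 for v in labels if v == 0)
        if pos == 0 or neg == 0:
            raise TaskError(f"task {t!r} needs at least one slide of each class")
    if config is None:
        config = TrainConfig()

    # slides ineligible for every selected objective carry no training
    # signal; dropping them keeps the loss and gradients (including the
    # density attachment) invariant to their presence
    bags = [b for b in bags
            if any(b.labels.get(t) is not None for t in objectives)]

    cache, n_eligible, k, offsets = _training_setup(model, bags, objectives)
    params = _params_from_model(model, objectives)
    m_state = {key: np.zeros_like(v) for key, v in params.items()}
    v_state = {key: np.zeros_like(v) for key, v in params.items()}

    losses: list[float] = []
    best_loss, best_epoch = np.inf, 0
    head_dim = model.head_dim()

    for epoch in range(config.epochs):
        total_loss, grads = _epoch_loss_grads(
            params, cache, objectives, n_eligible, k, offsets, head_dim,
            cluster_weight=config.cluster_weight,
        )
        losses.append(total_loss)

        # Adam step
        tstep = epoch + 1
        for key in params:
            g = grads[key]
            m_state[key] = config.beta1 * m_state[key] + (1 - config.beta1) * g
            v_state[key] = config.beta2 * v_state[key] + (1 - config.beta2) * g**2
            m_hat = m_state[key] / (1 - config.beta1**tstep)
            v_hat = v_state[key] / (1 - config.beta2**tstep)
            lr = (config.prototype_lr
                  if key.startswith(("M_", "logtau_")) else config.learning_rate)
            params[key] -= lr * m_hat / (np.sqrt(v_hat) + config.eps)

        if total_loss < best_loss - config.min_delta:
            best_loss, best_epoch = total_loss, epoch
        elif epoch - best_epoch >= config.patience:
            break

    for ct in CELL_TYPES:
        model.prototypes[ct] = params[f"M_{ct}"]
        model.log_tau[ct] = float(params[f"logtau_{ct}"][0])
    for t in objectives:
        model.heads[t] = (params[f"w_{t}"], float(params[f"b_{t}"][0]))
    return model, losses


# ---------------------------------------------------------------------------
# Cross-validation
# ---------------------------------------------------------------------------

@dataclass
class CVResult:
    fold_models: list[MorphotypeModel]
    fold_of_slide: dict[str, int]
    auc: dict[str, float]              # pooled out-of-fold AUC per task
    fold_mean_auc: list[float]
    best_fold: int
    oof_probs: dict[str, dict[str, float]]  # task -> slide_id -> prob


def crossvalidate(
    bags: Sequence[SlideBag],
    k: int | dict[str, int],
    objectives: Sequence[str] | None = None,
    folds: int = 5,
    seed: int = 0,
    use_blood_counts: bool = False,
    config: TrainConfig | None = None,
) -> CVResult:
    """Stratified k-fold cross-validation of the morphotype model.

    Folds are stratified on the first objective (slides without that label
    are spread round-robin); each fold trains on the remainder and is
    evaluated out-of-fold. The best fold maximizes the mean per-task AUC
    on its held-out slides.
    """
    objectives = list(objectives or TASKS)
    primary = objectives[0]
    labeled = [i for i, b in enumerate(bags) if b.labels.get(primary) is not None]
    unlabeled = [i for i, b in enumerate(bags) if b.labels.get(primary) is None]
    y = np.array([bags[i].labels[primary] for i in labeled])
    if np.bincount(y, minlength=2).min() < folds:
        raise ValueError(
            f"stratification failure: fewer than {folds} slides in a class "
            f"of task {primary}"
        )
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    fold_of = {}
    for f, (_, te) in enumerate(skf.split(np.zeros(len(labeled)), y)):
        for j in te:
            fold_of[bags[labeled[j]].slide_id] = f
    for j, i in enumerate(unlabeled):
        fold_of[bags[i].slide_id] = j % folds

    fold_models = []
    oof: dict[str, dict[str, float]] = {t: {} for t in objectives}
    fold_mean_auc = []
    for f in range(folds):
        train_bags = [b for b in bags if fold_of[b.slide_id] != f]
        test_bags = [b for b in bags if fold_of[b.slide_id] == f]
        model = init_model(train_bags, k, tasks=objectives,
                           use_blood_counts=use_blood_counts,
                           seed=seed * 1000 + f)
        model, _ = train(model, train_bags, objectives=objectives, config=config)
        fold_models.append(model)
        aucs = []
        for t in objectives:
            ys, ps = [], []
            for b in test_bags:
                if b.labels.get(t) is None:
                    continue
                prob = predict_proba(model, b)[t]
                oof[t][b.slide_id] = prob
                ys.append(b.labels[t])
                ps.append(prob)
            if len(set(ys)) > 1:
                aucs.append(roc_auc_score(ys, ps))
        fold_mean_auc.append(float(np.mean(aucs)) if aucs else np.nan)

    auc = {}
    for t in objectives:
        ys = [b.labels[t] for b in bags
              if b.slide_id in oof[t] and b.labels.get(t) is not None]
        ps = [oof[t][b.slide_id] for b in bags
              if b.slide_id in oof[t] and b.labels.get(t) is not None]
        auc[t] = float(roc_auc_score(ys, ps)) if len(set(ys)) > 1 else float("nan")
    best_fold = int(np.nanargmax(fold_mean_auc))
    return CVResult(fold_models=fold_models, fold_of_slide=fold_of, auc=auc,
                    fold_mean_auc=fold_mean_auc, best_fold=best_fold,
                    oof_probs=oof)


# ---------------------------------------------------------------------------
# Cross-fold stability selection
# ---------------------------------------------------------------------------

@dataclass
class StabilityReport:
    """Matching of reference-fold morphotypes across all other folds."""

    reference_fold: int
    match_table: dict[str, list[tuple[int, float]]]  # morphotype id -> (matched idx, cos)
    stable: dict[str, list[int]]                     # cell type -> stable prototype rows
    threshold: float

    def stable_ids(self) -> list[str]:
        return [f"{ct}_{i}" for ct in CELL_TYPES for i in self.stable.get(ct, [])]

    def n_stable(self) -> int:
        return sum(len(v) for v in self.stable.values())


def _cosine_matrix(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    An = A / np.maximum(np.linalg.norm(A, axis=1, keepdims=True), 1e-12)
    Bn = B / np.maximum(np.linalg.norm(B, axis=1, keepdims=True), 1e-12)
    return An @ Bn.T


def stability_select(
    fold_models: Sequence[MorphotypeModel],
    threshold: float = 0.8,
    reference_fold: int = 0,
) -> StabilityReport:
    """Find morphotypes recurring across every cross-validation fold.

    Prototypes are compared in standardized feature space. For each
    non-reference fold, an assignment-problem optimum maximizes total
    cosine similarity between reference and fold prototypes; a reference
    morphotype is stable iff its matched similarity is >= ``threshold`` in
    every fold.
    """
    if len(fold_models) < 2:
        raise ValueError("stability selection needs at least two fold models")
    ref = fold_models[reference_fold]
    match_table: dict[str, list[tuple[int, float]]] = {}
    stable: dict[str, list[int]] = {}
    for ct in CELL_TYPES:
        K, d = ref.prototypes[ct].shape
        for m in fold_models:
            if m.prototypes[ct].shape != (K, d):
                raise ValueError(f"fold prototype shape mismatch for {ct}")
        sims = np.full((len(fold_models), K), 1.0)
        matches = np.tile(np.arange(K), (len(fold_models), 1))
        for fi, m in enumerate(fold_models):
            if fi == reference_fold:
                continue
            C = _cosine_matrix(ref.prototypes[ct], m.prototypes[ct])
            rows, cols = linear_sum_assignment(-C)
            sims[fi, rows] = C[rows, cols]
            matches[fi, rows] = cols
        for ki in range(K):
            match_table[f"{ct}_{ki}"] = [
                (int(matches[fi, ki]), float(sims[fi, ki]))
                for fi in range(len(fold_models))
            ]
        stable[ct] = [ki for ki in range(K) if sims[:, ki].min() >= threshold]
    return StabilityReport(reference_fold=reference_fold, match_table=match_table,
                           stable=stable, threshold=threshold)


def predict_stable(
    model: MorphotypeModel, report: StabilityReport, bag: SlideBag
) -> dict[str, float]:
    """Predict using only stable morphotypes.

    Proportions are restricted to the stable set and renormalized to sum
    to 1 within each cell-type block (matching the full forward pass,
    where each block is a simplex vector); head weights are restricted
    correspondingly and blood-count weights are kept. With every
    morphotype stable this reduces exactly to :func:`mil_forward`.
    """
    if report.n_stable() == 0:
        raise ValueError("stable set is empty")
    full = bag_proportions(model, bag)
    k = model.k
    keep = []
    restricted_parts = []
    off = 0
    for ct in CELL_TYPES:
        idx = [off + i for i in report.stable.get(ct, [])]
        block = full[idx]
        total = block.sum()
        if total > 0:
            block = block / total
        restricted_parts.append(block)
        keep += idx
        off += k[ct]
    keep = np.array(keep, dtype=int)
    restricted = np.concatenate(restricted_parts)
    out = {}
    n_prop = sum(k.values())
    for task, (w, b) in model.heads.items():
        w_prop = w[:n_prop][keep]
        w_rest = w[n_prop:]
        logit = float(restricted @ w_prop + b)
        if model.use_blood_counts:
            logit += float(_blood_vector(model, bag) @ w_rest)
        out[task] = float(_sigmoid(logit))
    return out


def match_to_centroids(model: MorphotypeModel, cell_type: str,
                       centroids: np.ndarray) -> np.ndarray:
    """Best cosine similarity of each planted centroid to a model prototype,
    after standardizing the centroids into model space (diagnostic helper
    for parameter-recovery checks)."""
    mean, scale = model.feat_stats[cell_type]
    C = (np.atleast_2d(centroids) - mean) / scale
    sims = _cosine_matrix(C, model.prototypes[cell_type])
    return sims.max(axis=1)
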