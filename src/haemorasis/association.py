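"""Post-hoc statistics linking morphotypes to expert annotations and
clinical conditions.

* :func:`enrichment` — how over-represented each expert-annotated cell
  type is within each computational morphotype:
  enrichment(c, t) = P(type t | morphotype c) / P(type t), with a
  chi-squared test (with continuity correction) on the 2x2 table
  {in c vs not} x {type t vs not} and Benjamini–Hochberg control across
  the grid.
* :func:`proportion_ratio` — condition-contrast heatmap values: the ratio
  of median slide proportions between two conditions, with top-k
  morphotype selection by absolute difference of medians.
* :func:`density_ratio` — local class purity in a 2-D embedding: the
  kernel density of the predominant class over the summed class densities.
* :func:`external_validate` — AUC with standard error 1/sqrt(n) and the
  interval clamped to [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency
from sklearn.metrics import roc_auc_score
from sklearn.neighbors import KernelDensity
from statsmodels.stats.multitest import multipletests


@dataclass
class EnrichmentTable:
    """Morphotype x annotated-type enrichment ratios with test statistics."""

    ratio: pd.DataFrame      # CM x type
    counts: pd.DataFrame     # CM x type cell counts
    chi2: pd.DataFrame
    p_value: pd.DataFrame
    significant: pd.DataFrame  # BH-adjusted at alpha
    alpha: float


def enrichment(
    assignments: Sequence, annotations: Sequence, alpha: float = 0.05
) -> EnrichmentTable:
    """Enrichment of annotated cell types within hard morphotype labels.

    ``assignments`` holds one morphotype label per annotated cell (hard
    labels, e.g. the argmax of a soft assignment); ``annotations`` the
    expert type per cell. Empty morphotypes are excluded. The identity
    sum_c P(c) * enrichment(c, t) = 1 holds for every type t.
    """
    assignments = np.asarray(assignments)
    annotations = np.asarray(annotations)
    if assignments.shape != annotations.shape:
        raise ValueError("assignments and annotations must align")
    N = len(assignments)
    if N == 0:
        raise ValueError("no annotated cells")
    cms = [c for c in pd.unique(assignments)]
    types = [t for t in pd.unique(annotations)]
    counts = pd.DataFrame(0, index=cms, columns=types, dtype=int)
    for c, t in zip(assignments, annotations):
        counts.loc[c, t] += 1
    cm_totals = counts.sum(axis=1)
    type_totals = counts.sum(axis=0)

    ratio = pd.DataFrame(index=cms, columns=types, dtype=float)
    chi2 = pd.DataFrame(index=cms, columns=types, dtype=float)
    pval = pd.DataFrame(index=cms, columns=types, dtype=float)
    for c in cms:
        for t in types:
            in_c_t = counts.loc[c, t]
            ratio.loc[c, t] = (in_c_t / cm_totals[c]) / (type_totals[t] / N)
            table = np.array([
                [in_c_t, cm_totals[c] - in_c_t],
                [type_totals[t] - in_c_t, N - cm_totals[c] - type_totals[t] + in_c_t],
            ])
            if table.sum(axis=0).min() == 0 or table.sum(axis=1).min() == 0:
                chi2.loc[c, t], pval.loc[c, t] = 0.0, 1.0
            else:
                stat, p, _, _ = chi2_contingency(table, correction=True)
                chi2.loc[c, t], pval.loc[c, t] = float(stat), float(p)

    rejected, _, _, _ = multipletests(pval.to_numpy().ravel(), alpha=alpha,
                                      method="fdr_bh")
    significant = pd.DataFrame(
        rejected.reshape(pval.shape), index=cms, columns=types
    )
    return EnrichmentTable(ratio=ratio, counts=counts, chi2=chi2,
                           p_value=pval, significant=significant, alpha=alpha)


def hard_assignments(soft: np.ndarray) -> np.ndarray:
    """Hard morphotype label per cell: argmax of the soft assignment row
    (ties broken toward the lowest index)."""
    return np.argmax(np.atleast_2d(soft), axis=1)


# ---------------------------------------------------------------------------
# Condition proportion ratios
# ---------------------------------------------------------------------------

@dataclass
class ProportionRatioResult:
    ratio: np.ndarray               # median_A / median_B per morphotype
    median_diff: np.ndarray         # median_A - median_B
    selected: np.ndarray            # top-k morphotype indices
    infinite: np.ndarray            # flags where median_B == 0


def proportion_ratio(
    proportions: np.ndarray,
    conditions: Sequence[str],
    contrast: tuple[str, str],
    top_k: int = 5,
    effect: str = "median_difference",
) -> ProportionRatioResult:
    """Morphotype proportion ratios between two conditions.

    ``proportions`` is (n_slides, K); ``contrast`` = (A, B) compares
    median_A / median_B per morphotype. Selection takes the ``top_k``
    morphotypes by absolute difference in median proportion (the default
    reading of "median effect size"); ``effect="standardized"`` divides
    that difference by the pooled median absolute deviation instead.
    """
    P = np.atleast_2d(np.asarray(proportions, dtype=float))
    conditions = np.asarray(conditions)
    a, b = contrast
    in_a, in_b = conditions == a, conditions == b
    if not in_a.any() or not in_b.any():
        raise ValueError(f"need at least one slide in each of {a!r} and {b!r}")
    med_a = np.median(P[in_a], axis=0)
    med_b = np.median(P[in_b], axis=0)
    infinite = med_b == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(infinite, np.inf, med_a / np.where(infinite, 1.0, med_b))
    diff = med_a - med_b
    if effect == "standardized":
        pooled = np.concatenate([P[in_a], P[in_b]])
        mad = np.median(np.abs(pooled - np.median(pooled, axis=0)), axis=0)
        score = np.abs(diff) / np.maximum(mad, 1e-12)
    else:
        score = np.abs(diff)
    selected = np.argsort(-score)[: min(top_k, P.shape[1])]
    return ProportionRatioResult(ratio=ratio, median_diff=diff,
                                 selected=selected, infinite=infinite)


# ---------------------------------------------------------------------------
# Embedding density ratios
# ---------------------------------------------------------------------------

def density_ratio(points: np.ndarray, labels: Sequence, bandwidth: float
                  ) -> np.ndarray:
    """Per-point local purity in a 2-D embedding.

    For each point, Gaussian kernel densities are evaluated per class and
    the ratio of the predominant (maximal) class density to the summed
    densities is returned. With a single class the ratio is 1 everywhere.
    """
    if bandwidth <= 0:
        raise ValueError("bandwidth must be > 0")
    X = np.atleast_2d(np.asarray(points, dtype=float))
    labels = np.asarray(labels)
    classes = pd.unique(labels)
    if len(classes) == 1:
        return np.ones(X.shape[0])
    dens = np.zeros((len(classes), X.shape[0]))
    for i, cls in enumerate(classes):
        sub = X[labels == cls]
        kde = KernelDensity(bandwidth=bandwidth).fit(sub)
        # weight by class size so densities are comparable across classes
        dens[i] = np.exp(kde.score_samples(X)) * len(sub)
    return dens.max(axis=0) / dens.sum(axis=0)


# ---------------------------------------------------------------------------
# External validation
# ---------------------------------------------------------------------------

@dataclass
class ValidationResult:
    auc: float
    se: float
    interval: tuple[float, float]
    n: int


def external_validate(scores: Sequence[float], labels: Sequence[int]
                      ) -> ValidationResult:
    """Rank-statistic AUC with standard error 1/sqrt(n).

    The reported interval [max(AUC - se, 0), min(AUC + se, 1)] is clamped
    to the unit interval.
    """
    labels = np.asarray(labels, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if len(np.unique(labels)) < 2:
        raise ValueError("external validation needs both classes")
    auc = float(roc_auc_score(labels, scores))
    n = len(labels)
    se = 1.0 / np.sqrt(n)
    return ValidationResult(auc=auc, se=float(se),
                            interval=(max(auc - se, 0.0), min(auc + se, 1.0)), n=n)
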