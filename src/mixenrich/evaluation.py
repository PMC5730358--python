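"""Reproducibility metrics for enrichment result lists.

Compares a candidate term ranking (p-values / odds ratios from one
analysis, e.g. a single-subject replicate) against a reference term list
(e.g. a cohort analysis, or simulation ground truth): ROC/AUC,
precision-recall, Spearman rank correlation of odds ratios, and
cross-replicate overlap summaries.  Terms are matched by exact
identifier only; no semantic-similarity credit is given.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import spearmanr
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve as _sk_roc_curve


@dataclass
class ReferenceComparison:
    """A candidate ranking against binary reference labels.

    The evaluation domain is the terms present in both analyses; the
    reference-significant set is restricted to it on construction.
    """

    candidate: dict[str, tuple[float, float]]  # term -> (p_value, odds_ratio)
    reference_significant: set[str]
    common_terms: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not self.common_terms:
            self.common_terms = set(self.candidate)
        self.common_terms = self.common_terms & set(self.candidate)
        self.reference_significant = self.reference_significant & self.common_terms

    def _arrays(self) -> tuple[np.ndarray, np.ndarray]:
        terms = sorted(self.common_terms)
        y = np.array([t in self.reference_significant for t in terms], dtype=int)
        p = np.array([self.candidate[t][0] for t in terms])
        return y, p


@dataclass
class OverlapSummary:
    per_replicate_sizes: list[int]
    intersection_all: int
    intersection_all_and_reference: int | None
    union_all: int
    frac_of_each_replicate: list[float]
    frac_of_smallest: float


def roc_curve(cmp: ReferenceComparison) -> tuple[np.ndarray, np.ndarray, float]:
    """ROC of the candidate p-value ranking against the reference labels.

    Terms are ranked by ascending p (smaller p = stronger call); tied
    p-values are grouped into a single ROC vertex, so the trapezoid AUC
    equals the tie-corrected Mann-Whitney probability that a random
    reference-positive term outranks a random negative one.
    """
    y, p = cmp._arrays()
    n_pos = int(y.sum())
    if n_pos == 0 or n_pos == y.size:
        raise ValueError("AUC undefined: reference needs at least one positive and one negative")
    fpr, tpr, _ = _sk_roc_curve(y, -p)
    return fpr, tpr, float(_trapezoid_auc(fpr, tpr))


def precision_recall(
    cmp: ReferenceComparison, threshold_grid: Sequence[float] | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Precision and recall of thresholded candidate calls.

    A term is called positive when its candidate p <= threshold.  At a
    threshold yielding zero calls, precision is 1 by convention.
    """
    y, p = cmp._arrays()
    n_pos = int(y.sum())
    if n_pos == 0 or n_pos == y.size:
        raise ValueError("undefined: reference needs at least one positive and one negative")
    if threshold_grid is None:
        threshold_grid = np.unique(p)
    prec, rec = [], []
    for thr in threshold_grid:
        called = p <= thr
        tp = int((called & (y == 1)).sum())
        fp = int((called & (y == 0)).sum())
        prec.append(tp / (tp + fp) if (tp + fp) else 1.0)
        rec.append(tp / n_pos)
    return np.array(prec), np.array(rec)


def rank_correlation(
    candidate_or: Mapping[str, float], reference_or: Mapping[str, float]
) -> tuple[float, float]:
    """Spearman rho (average-rank ties, t-approximation p) on shared terms.

    Odds ratios should be made finite upstream (Haldane-corrected tables)
    so every term has a well-defined rank.
    """
    common = sorted(set(candidate_or) & set(reference_or))
    if len(common) < 3:
        raise ValueError(f"need at least 3 common terms, got {len(common)}")
    a = np.array([candidate_or[t] for t in common])
    b = np.array([reference_or[t] for t in common])
    rho, p = spearmanr(a, b)
    return float(rho), float(p)


def overlap_summary(
    replicate_results: Sequence[set[str]], reference: set[str] | None = None
) -> OverlapSummary:
    """Set-overlap counts across replicate significant-term lists.

    Reports the all-replicate intersection as a fraction of each
    replicate's own list and of the smallest list (the two denominator
    conventions in use for such comparisons, side by side).
    """
    if len(replicate_results) < 2:
        raise ValueError("need at least two replicate sets")
    sets = [set(s) for s in replicate_results]
    inter = set.intersection(*sets)
    union = set.union(*sets)
    sizes = [len(s) for s in sets]
    smallest = min(sizes)
    return OverlapSummary(
        per_replicate_sizes=sizes,
        intersection_all=len(inter),
        intersection_all_and_reference=(len(inter & reference) if reference is not None else None),
        union_all=len(union),
        frac_of_each_replicate=[len(inter) / n if n else 0.0 for n in sizes],
        frac_of_smallest=len(inter) / smallest if smallest else 0.0,
    )
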