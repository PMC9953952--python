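"""Answer-set construction, chromosome-disjoint cross-validation, metrics.

Variants of the same gene share properties, so random CV splits leak: a model
can look good by memorizing genes.  Folds are therefore cut along
chromosomes — every variant of a chromosome lands in the same fold — and a
hard error is raised if a train and test split ever share a chromosome.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from sklearn.metrics import (
    accuracy_score,
    f1_score,
    precision_score,
    recall_score,
    roc_auc_score,
    roc_curve,
)

from .annotations import ClinVarRecord
from .kg import parse_variant_key

__all__ = [
    "LabeledVariant",
    "FoldAssignment",
    "MetricReport",
    "CVReport",
    "LeakageError",
    "build_estimation_answer_set",
    "build_explanation_answer_set",
    "balance_classes",
    "chromosome_folds",
    "compute_metrics",
    "cross_validate",
    "parameter_sweep",
]


class LeakageError(RuntimeError):
    """Train and test splits share a chromosome."""


@dataclass(frozen=True)
class LabeledVariant:
    key: str
    gene: str
    chrom: str
    consequence: str
    label: str  # 'pathogenic' | 'benign'
    stars: int


def build_estimation_answer_set(
    clinvar: Sequence[ClinVarRecord],
    consequence: str = "missense_variant",
) -> list[LabeledVariant]:
    """High-confidence answer set for measuring estimation performance.

    Keeps missense records with review status >= 2 stars whose significance
    is exactly Pathogenic or Benign; Likely_* and VUS are excluded.
    """
    out = []
    for r in clinvar:
        if r.review_stars < 2 or r.consequence != consequence:
            continue
        if r.clinical_significance == "Pathogenic":
            label = "pathogenic"
        elif r.clinical_significance == "Benign":
            label = "benign"
        else:
            continue
        out.append(
            LabeledVariant(r.key, r.gene, r.chrom, r.consequence, label, r.review_stars)
        )
    return out


def build_explanation_answer_set(
    clinvar: Sequence[ClinVarRecord], seed: int = 0
) -> list[LabeledVariant]:
    """Larger, looser answer set for training the explanation model.

    Likely_pathogenic / Likely_benign map to their parent label, every
    single-nucleotide consequence is admitted, and the majority class is
    downsampled to parity.
    """
    mapping = {
        "Pathogenic": "pathogenic",
        "Likely_pathogenic": "pathogenic",
        "Benign": "benign",
        "Likely_benign": "benign",
    }
    out = []
    for r in clinvar:
        label = mapping.get(r.clinical_significance)
        if label is None:
            continue
        if len(r.ref) != 1 or len(r.alt) != 1:  # SNVs only
            continue
        out.append(
            LabeledVariant(r.key, r.gene, r.chrom, r.consequence, label, r.review_stars)
        )
    return balance_classes(out, seed)


def balance_classes(
    variants: Sequence[LabeledVariant], seed: int
) -> list[LabeledVariant]:
    """Downsample the majority class uniformly to the minority count.

    Every minority-class variant is preserved; input order is kept.
    """
    path = [v for v in variants if v.label == "pathogenic"]
    ben = [v for v in variants if v.label == "benign"]
    if not path or not ben:
        raise ValueError("both classes must be present to balance")
    minority, majority = (path, ben) if len(path) <= len(ben) else (ben, path)
    rng = np.random.default_rng(seed)
    keep_idx = set(
        rng.choice(len(majority), size=len(minority), replace=False).tolist()
    )
    kept_majority = {majority[i].key for i in keep_idx}
    keep = {v.key for v in minority} | kept_majority
    return [v for v in variants if v.key in keep]


@dataclass
class FoldAssignment:
    assignment: dict[str, int]  # variant key -> fold
    chrom_fold: dict[str, int]
    k: int
    seed: int

    def fold_of(self, key: str) -> int:
        return self.assignment[key]

    def test_keys(self, fold: int) -> set[str]:
        return {k for k, f in self.assignment.items() if f == fold}


def chromosome_folds(
    variants: Sequence[LabeledVariant], k: int = 5, seed: int = 0
) -> FoldAssignment:
    """Partition chromosomes into ``k`` folds by greedy size balancing.

    Chromosomes are packed largest-first into the currently lightest fold, so
    no chromosome is ever split; ``seed`` shuffles equal-sized chromosomes
    before packing.
    """
    counts: dict[str, int] = {}
    for v in variants:
        counts[v.chrom] = counts.get(v.chrom, 0) + 1
    if len(counts) < k:
        raise ValueError(f"need at least {k} chromosomes, got {len(counts)}")
    rng = np.random.default_rng(seed)
    chroms = sorted(counts)
    order = sorted(
        rng.permutation(len(chroms)).tolist(), key=lambda i: -counts[chroms[i]]
    )
    loads = [0] * k
    chrom_fold: dict[str, int] = {}
    for i in order:
        fold = int(np.argmin(loads))
        chrom_fold[chroms[i]] = fold
        loads[fold] += counts[chroms[i]]
    return FoldAssignment(
        {v.key: chrom_fold[v.chrom] for v in variants}, chrom_fold, k, seed
    )


@dataclass
class MetricReport:
    accuracy: float
    precision: float
    recall: float
    f1: float
    auc: float
    roc: Optional[list[tuple[float, float]]] = None
    n: int = 0


@dataclass
class CVReport:
    folds: list[MetricReport]
    mean: MetricReport


def compute_metrics(
    scores: Sequence[float], labels: Sequence[str], threshold: float = 0.5
) -> MetricReport:
    """Accuracy / precision / recall / F1 at ``threshold`` plus rank AUC.

    'pathogenic' is the positive class.  AUC uses the Mann-Whitney rank
    statistic (tie-corrected); both classes must be present.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.array([1 if lab == "pathogenic" else 0 for lab in labels])
    if len(scores) != len(y) or len(y) < 2:
        raise ValueError("need matching scores and labels, n >= 2")
    if len(set(y.tolist())) < 2:
        raise ValueError("AUC is undefined with a single class")
    pred = (scores >= threshold).astype(int)
    fpr, tpr, _ = roc_curve(y, scores)
    return MetricReport(
        accuracy=float(accuracy_score(y, pred)),
        precision=float(precision_score(y, pred, zero_division=0)),
        recall=float(recall_score(y, pred, zero_division=0)),
        f1=float(f1_score(y, pred, zero_division=0)),
        auc=float(roc_auc_score(y, scores)),
        roc=list(zip(fpr.tolist(), tpr.tolist())),
        n=len(y),
    )


def cross_validate(
    fit: Callable[[list[LabeledVariant]], object],
    score: Callable[[object, list[LabeledVariant]], Sequence[float]],
    variants: Sequence[LabeledVariant],
    folds: FoldAssignment,
    threshold: float = 0.5,
) -> CVReport:
    """k-fold CV respecting the fold assignment; mean of per-fold metrics.

    Raises :class:`LeakageError` if any fold's train and test sets share a
    chromosome.
    """
    reports = []
    for f in range(folds.k):
        test = [v for v in variants if folds.fold_of(v.key) == f]
        train = [v for v in variants if folds.fold_of(v.key) != f]
        if not test or not train:
            continue
        shared = {v.chrom for v in train} & {v.chrom for v in test}
        if shared:
            raise LeakageError(
                f"fold {f}: chromosomes {sorted(shared)} appear in both train and test"
            )
        model = fit(train)
        reports.append(compute_metrics(score(model, test), [v.label for v in test], threshold))
    mean = MetricReport(
        accuracy=float(np.mean([r.accuracy for r in reports])),
        precision=float(np.mean([r.precision for r in reports])),
        recall=float(np.mean([r.recall for r in reports])),
        f1=float(np.mean([r.f1 for r in reports])),
        auc=float(np.mean([r.auc for r in reports])),
        n=sum(r.n for r in reports),
    )
    return CVReport(reports, mean)


def parameter_sweep(
    make_pipeline: Callable[[int], tuple[Callable, Callable]],
    params: Sequence[int],
    variants: Sequence[LabeledVariant],
    folds: FoldAssignment,
) -> tuple[list[tuple[int, float]], int]:
    """Mean CV accuracy per parameter value; the best value is the method's
    reported performance (accuracy-vs-parameter curve protocol)."""
    curve = []
    for p in params:
        fit, score = make_pipeline(p)
        curve.append((p, cross_validate(fit, score, variants, folds).mean.accuracy))
    best = max(curve, key=lambda t: (t[1], -t[0]))[0]
    return curve, best
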