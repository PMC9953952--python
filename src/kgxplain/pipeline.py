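"""End-to-end wiring: tables -> knowledge graph -> models -> CV reports.

Thin composition layer used by the command-line interface, the examples and
the test harness.  Nothing here adds behavior; it only sequences the modules.
"""

from __future__ import annotations

from typing import Callable, Optional, Sequence

from . import annotations as ann
from . import baselines, classifier, evaluation
from .classifier import ClassifierConfig, GraphHashModel
from .evaluation import CVReport, FoldAssignment, LabeledVariant
from .features import VariantIndex, build_feature_graph, make_mask_plan
from .kg import KnowledgeGraph
from .simulate import SimulatedDataset

__all__ = [
    "dataset_to_kg",
    "graph_pipeline",
    "vector_pipeline",
    "train_estimation_model",
    "train_explanation_model",
    "run_synthetic_cv",
]


def dataset_to_kg(ds: SimulatedDataset) -> tuple[KnowledgeGraph, VariantIndex, list]:
    """(knowledge graph, variant index, clinvar records) from one dataset."""
    clinvar, cosmic, dbnsfp, dbscsnv = ds.load_records()
    for name, res in (
        ("clinvar", clinvar), ("cosmic", cosmic),
        ("dbnsfp", dbnsfp), ("dbscsnv", dbscsnv),
    ):
        if res.n_rejected:
            raise ValueError(f"{name} loader rejected {res.n_rejected} generated rows")
    kg = ann.records_to_kg(
        clinvar.records, cosmic.records, dbnsfp.records, dbscsnv.records
    )
    return kg, ds.variant_index(), clinvar.records


def graph_pipeline(
    kg: KnowledgeGraph,
    index: VariantIndex,
    config: Optional[ClassifierConfig] = None,
) -> tuple[Callable, Callable]:
    """(fit, score) pair over estimation-mode feature graphs, for CV."""
    config = config or ClassifierConfig()
    cache: dict[str, object] = {}

    def fg_of(key: str):
        if key not in cache:
            cache[key] = build_feature_graph(key, kg, "estimation", index)
        return cache[key]

    def fit(train: list[LabeledVariant]):
        return classifier.train(
            [fg_of(v.key) for v in train], [v.label for v in train], config
        )

    def score(model, test: list[LabeledVariant]):
        return [classifier.predict(model, fg_of(v.key)) for v in test]

    return fit, score


def vector_pipeline(
    kg: KnowledgeGraph,
    index: VariantIndex,
    family: str = "forest",
    max_depth: Optional[int] = None,
    seed: int = 0,
) -> tuple[Callable, Callable]:
    """(fit, score) pair over flattened vectors for the tree baselines."""
    cache: dict[str, baselines.FeatureVector] = {}

    def vec_of(key: str):
        if key not in cache:
            cache[key] = baselines.flatten(
                build_feature_graph(key, kg, "estimation", index)
            )
        return cache[key]

    def fit(train: list[LabeledVariant]):
        vectors = [vec_of(v.key) for v in train]
        labels = [v.label for v in train]
        if family == "tree":
            return baselines.fit_tree(vectors, labels, max_depth or 9, seed)
        if family == "forest":
            return baselines.fit_forest(vectors, labels, max_depth, seed)
        raise ValueError(f"unknown baseline family {family!r}")

    def score(model, test: list[LabeledVariant]):
        return baselines.predict_proba(model, [vec_of(v.key) for v in test]).tolist()

    return fit, score


def train_estimation_model(
    ds: SimulatedDataset,
    config: Optional[ClassifierConfig] = None,
    seed: int = 0,
) -> tuple[GraphHashModel, list[LabeledVariant]]:
    """Train the ClinVar-free estimation model on the full answer set."""
    kg, index, clinvar = dataset_to_kg(ds)
    answers = evaluation.balance_classes(
        evaluation.build_estimation_answer_set(clinvar), seed
    )
    fit, _ = graph_pipeline(kg, index, config)
    return fit(answers), answers


def train_explanation_model(
    ds: SimulatedDataset,
    config: Optional[ClassifierConfig] = None,
    seed: int = 0,
) -> tuple[GraphHashModel, list[LabeledVariant]]:
    """Train the explanation model with ClinVar half-masking.

    The explanation answer set admits Likely_* labels and all SNVs; half of
    the training variants (per the mask plan) are built without their own
    ClinVar record so the model cannot rely on ClinVar alone.
    """
    config = config or ClassifierConfig()
    kg, index, clinvar = dataset_to_kg(ds)
    answers = evaluation.build_explanation_answer_set(clinvar, seed)
    plan = make_mask_plan([v.key for v in answers], seed)
    graphs = [
        build_feature_graph(
            v.key, kg, "explanation", index, drop_target_clinvar=plan.drop(v.key)
        )
        for v in answers
    ]
    model = classifier.train(graphs, [v.label for v in answers], config)
    return model, answers


def run_synthetic_cv(
    ds: SimulatedDataset,
    model: str = "graph",
    k: int = 5,
    seed: int = 0,
    config: Optional[ClassifierConfig] = None,
    max_depth: Optional[int] = None,
) -> CVReport:
    """Chromosome-disjoint k-fold CV of one method on one dataset."""
    kg, index, clinvar = dataset_to_kg(ds)
    answers = evaluation.balance_classes(
        evaluation.build_estimation_answer_set(clinvar), seed
    )
    folds = evaluation.chromosome_folds(answers, k, seed)
    if model == "graph":
        fit, score = graph_pipeline(kg, index, config)
    else:
        fit, score = vector_pipeline(kg, index, model, max_depth, seed)
    return evaluation.cross_validate(fit, score, answers, folds)
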