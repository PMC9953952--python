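"""Fixed-length feature vectors and tree-based baseline classifiers.

Decision trees and random forests cannot consume graphs, so each estimation
feature graph is flattened into a fixed-schema vector: variable-cardinality
structure (neighbors, publications) is aggregated into counts, COSMIC sample
counts are compressed to a log10 bin, and only two categorical crosses are
materialized (consequence x significance, and consequence x review-status
band x significance), both tallied within coarse neighbor-distance bins.
Missing numeric scores use a -1 sentinel, which tree splits isolate
naturally.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.tree import DecisionTreeClassifier

from .annotations import (
    DEFAULT_PUBLISHERS,
    ESTIMATION_ALGORITHMS,
    SIGNIFICANCE_LEVELS,
)
from .features import FeatureGraph

__all__ = [
    "FeatureVector",
    "FlattenSchema",
    "bin_sample_count",
    "aggregate_publications",
    "aggregate_neighbors",
    "flatten",
    "fit_tree",
    "fit_forest",
    "predict_proba",
    "DEFAULT_DISTANCE_BIN_EDGES",
    "DEFAULT_CONSEQUENCES",
]

#: Inclusive upper edges (bases) of the neighbor-distance bins.
DEFAULT_DISTANCE_BIN_EDGES = (10, 25, 50, 100)

DEFAULT_CONSEQUENCES = ("missense_variant", "synonymous_variant", "stop_gained")

MISSING = -1.0


def bin_sample_count(n: int) -> int:
    """log10-style aggregation of a COSMIC sample count into bins 0..5.

    1 -> 0; (1, 10] -> 1; (10, 100] -> 2; (100, 1000] -> 3;
    (1000, 10000] -> 4; everything above 10000 -> 5.
    """
    if not isinstance(n, (int, np.integer)) or isinstance(n, bool) or n < 1:
        raise ValueError(f"sample count must be an integer >= 1, got {n!r}")
    for b, upper in enumerate((1, 10, 100, 1000, 10000)):
        if n <= upper:
            return b
    return 5


def _bin_label(d: int, edges: Sequence[int]) -> str:
    lo = 1
    for upper in edges:
        if d <= upper:
            return f"{lo}_{upper}"
        lo = upper + 1
    raise ValueError(f"distance {d} outside [1, {edges[-1]}]")


def aggregate_publications(
    clinvar_pubs: Sequence[tuple[str, str]],
    cosmic_pubs: Sequence[str],
    publishers: Sequence[str] = DEFAULT_PUBLISHERS,
) -> dict[str, float]:
    """Reference counts: per-publisher for ClinVar, one total for COSMIC."""
    out = {f"clinvar_pubs_{p}": 0.0 for p in publishers}
    for _, publisher in clinvar_pubs:
        name = f"clinvar_pubs_{publisher}"
        if name in out:
            out[name] += 1.0
        else:
            out.setdefault("clinvar_pubs_other", 0.0)
            out["clinvar_pubs_other"] += 1.0
    out.setdefault("clinvar_pubs_other", 0.0)
    out["cosmic_pubs_total"] = float(len(cosmic_pubs))
    return out


@dataclass
class NeighborInfo:
    """What flattening needs to know about one neighbor."""

    distance: int
    consequence: Optional[str] = None  # from its ClinVar record
    significance: Optional[str] = None
    review_stars: Optional[int] = None
    clinvar_pubs: tuple[tuple[str, str], ...] = ()
    cosmic_registered: bool = False
    cosmic_sample_count: Optional[int] = None
    cosmic_pubs: tuple[str, ...] = ()


def _stars_band(stars: Optional[int]) -> str:
    return "ge2" if (stars or 0) >= 2 else "lt2"


def aggregate_neighbors(
    neighbors: Sequence[NeighborInfo],
    bin_edges: Sequence[int] = DEFAULT_DISTANCE_BIN_EDGES,
    consequences: Sequence[str] = DEFAULT_CONSEQUENCES,
    publishers: Sequence[str] = DEFAULT_PUBLISHERS,
) -> dict[str, float]:
    """Tally neighbor annotations within distance bins (fixed key set)."""
    bins = [_bin_label(e, bin_edges) for e in bin_edges]
    out: dict[str, float] = {}
    for b in bins:
        out[f"nb_{b}_count"] = 0.0
        for sig in SIGNIFICANCE_LEVELS:
            out[f"nb_{b}_clinvar_{sig}"] = 0.0
        for cons in consequences:
            for sig in SIGNIFICANCE_LEVELS:
                out[f"nb_{b}_x_{cons}_{sig}"] = 0.0
                for band in ("lt2", "ge2"):
                    out[f"nb_{b}_x_{cons}_{band}_{sig}"] = 0.0
        for p in publishers:
            out[f"nb_{b}_clinvar_pubs_{p}"] = 0.0
        out[f"nb_{b}_cosmic_registered"] = 0.0
        out[f"nb_{b}_cosmic_pubs_total"] = 0.0
    for nb in neighbors:
        b = _bin_label(nb.distance, bin_edges)  # raises if out of range
        out[f"nb_{b}_count"] += 1.0
        if nb.significance is not None:
            key = f"nb_{b}_clinvar_{nb.significance}"
            if key in out:
                out[key] += 1.0
            if nb.consequence in consequences:
                cross1 = f"nb_{b}_x_{nb.consequence}_{nb.significance}"
                if cross1 in out:
                    out[cross1] += 1.0
                cross2 = (
                    f"nb_{b}_x_{nb.consequence}_{_stars_band(nb.review_stars)}"
                    f"_{nb.significance}"
                )
                if cross2 in out:
                    out[cross2] += 1.0
        for _, publisher in nb.clinvar_pubs:
            key = f"nb_{b}_clinvar_pubs_{publisher}"
            if key in out:
                out[key] += 1.0
        if nb.cosmic_registered:
            out[f"nb_{b}_cosmic_registered"] += 1.0
        out[f"nb_{b}_cosmic_pubs_total"] += float(len(nb.cosmic_pubs))
    return out


@dataclass
class FlattenSchema:
    bin_edges: tuple[int, ...] = DEFAULT_DISTANCE_BIN_EDGES
    consequences: tuple[str, ...] = DEFAULT_CONSEQUENCES
    publishers: tuple[str, ...] = DEFAULT_PUBLISHERS
    algorithms: tuple[str, ...] = ESTIMATION_ALGORITHMS


@dataclass
class FeatureVector:
    """Ordered (name, value) pairs; identical schema across a dataset."""

    names: tuple[str, ...]
    values: np.ndarray

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.names, self.values.tolist()))


def _neighbors_from_graph(fg: FeatureGraph) -> list[NeighborInfo]:
    out = []
    for nkey, dist in fg.neighbor_links:
        hub = fg.hub_id(nkey)
        recs = fg.records_of(hub)
        info = NeighborInfo(distance=dist)
        cv = recs.get("clinvar_record")
        if cv is not None:
            f = fg.record_fields(cv)
            info.consequence = f.get("consequence")
            info.significance = f.get("clinical_significance")
            info.review_stars = f.get("review_stars")
            info.clinvar_pubs = tuple(
                (pmid, pub or "") for pmid, pub, _ in fg.record_publications(cv)
            )
        cm = recs.get("cosmic_record")
        if cm is not None:
            info.cosmic_registered = True
            info.cosmic_sample_count = fg.record_fields(cm).get("sample_count")
            info.cosmic_pubs = tuple(p for p, _, _ in fg.record_publications(cm))
        out.append(info)
    return out


def flatten(fg: FeatureGraph, schema: Optional[FlattenSchema] = None) -> FeatureVector:
    """Estimation feature graph -> fixed-length vector.

    Composes the target's scalar features (six dbNSFP scores, COSMIC
    registration / sample bin / publication total) with the neighbor and
    publication aggregations.  The vector length depends only on the schema,
    never on neighbor, record or publication counts, and record order does
    not matter.
    """
    if fg.mode != "estimation":
        raise ValueError("flatten expects an estimation-mode feature graph")
    schema = schema or FlattenSchema()
    feat: dict[str, float] = {}

    target_recs = fg.records_of(fg.target_hub_id)
    dbn = target_recs.get("dbnsfp_record")
    scores = fg.record_fields(dbn) if dbn else {}
    for alg in schema.algorithms:
        feat[f"dbnsfp_{alg}"] = float(scores.get(alg, MISSING))

    cm = target_recs.get("cosmic_record")
    if cm is not None:
        f = fg.record_fields(cm)
        feat["cosmic_registered"] = 1.0
        feat["cosmic_sample_bin"] = float(bin_sample_count(int(f["sample_count"])))
        cosmic_pubs = [p for p, _, _ in fg.record_publications(cm)]
    else:
        feat["cosmic_registered"] = 0.0
        feat["cosmic_sample_bin"] = MISSING
        cosmic_pubs = []
    feat.update(aggregate_publications([], cosmic_pubs, schema.publishers))
    feat.update(
        aggregate_neighbors(
            _neighbors_from_graph(fg),
            schema.bin_edges,
            schema.consequences,
            schema.publishers,
        )
    )
    names = tuple(sorted(feat))
    return FeatureVector(names, np.array([feat[n] for n in names]))


def _check_classes(labels: Sequence[str]) -> np.ndarray:
    y = np.array([1 if lab == "pathogenic" else 0 for lab in labels])
    if len(set(y.tolist())) < 2:
        raise ValueError("training needs both classes present")
    return y


def fit_tree(
    vectors: Sequence[FeatureVector],
    labels: Sequence[str],
    max_depth: int = 9,
    seed: int = 0,
) -> DecisionTreeClassifier:
    y = _check_classes(labels)
    X = np.stack([v.values for v in vectors])
    model = DecisionTreeClassifier(max_depth=max_depth, random_state=seed)
    model.fit(X, y)
    return model


def fit_forest(
    vectors: Sequence[FeatureVector],
    labels: Sequence[str],
    max_depth: Optional[int] = None,
    seed: int = 0,
    n_estimators: int = 200,
) -> RandomForestClassifier:
    y = _check_classes(labels)
    X = np.stack([v.values for v in vectors])
    model = RandomForestClassifier(
        n_estimators=n_estimators, max_depth=max_depth, random_state=seed
    )
    model.fit(X, y)
    return model


def predict_proba(model, vectors: Sequence[FeatureVector]) -> np.ndarray:
    """Pathogenic-class probability for each vector."""
    X = np.stack([v.values for v in vectors])
    return model.predict_proba(X)[:, 1]
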