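"""Graph classifier with pathogenicity scores and edge attribution.

The scoring backend is a deterministic graph-feature-hashing model: every
edge of a feature graph is mapped to a token describing what it asserts
(e.g. "the target's SIFT score", "a neighbor's ClinVar significance is
Pathogenic"), tokens are hashed into a fixed-dimension signed feature vector,
and a regularized logistic regression is fitted on the hashed vectors.  The
model is linear in edge presence, scores in [0, 1], and trains in seconds on
a CPU.

Explanations need per-edge attributions.  ``edge_contributions`` fits a
LIME-style local linear surrogate over random edge-masking perturbations of
one graph: edges are switched off at random, the masked graphs are re-scored,
and a linear fit of score against the mask indicators yields one signed
contribution per edge (positive pushes toward pathogenic).  When the mask
space is small enough it is enumerated exhaustively and the fit is the exact
unpenalized least-squares surrogate.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import asdict, dataclass, field
from typing import IO, Optional, Sequence, Union

import numpy as np
from sklearn.linear_model import LogisticRegression, Ridge

from .features import NEIGHBOR_PREDICATE_PREFIX, FeatureGraph
from .kg import KGEdge

__all__ = [
    "ClassifierConfig",
    "GraphHashModel",
    "EdgeContribution",
    "NodeContribution",
    "train",
    "predict",
    "classify",
    "edge_contributions",
    "node_contributions",
    "distance_bin",
    "DEFAULT_DISTANCE_BINS",
]

#: Distance bins (inclusive upper edges, bases) for neighbor links.
DEFAULT_DISTANCE_BINS = (10, 25, 50, 100)

LABELS = ("benign", "pathogenic")


def distance_bin(d: int, bins: Sequence[int] = DEFAULT_DISTANCE_BINS) -> int:
    if not 1 <= d <= bins[-1]:
        raise ValueError(f"distance {d} outside [1, {bins[-1]}]")
    for i, edge in enumerate(bins):
        if d <= edge:
            return i
    raise AssertionError("unreachable")


@dataclass
class ClassifierConfig:
    backend: str = "graph_kernel_logistic"
    epochs: int = 10
    seed: int = 0
    decision_threshold: float = 0.5
    hash_dim: int = 4096
    C: float = 1.0
    node_aggregation: str = "max"  # 'max' | 'sum' | 'mean'
    lime_samples: int = 256
    lime_ridge: float = 1e-3

    def __post_init__(self) -> None:
        if self.backend == "gnn":
            raise NotImplementedError(
                "no GNN backend is available in this build; "
                "use backend='graph_kernel_logistic'"
            )
        if self.backend != "graph_kernel_logistic":
            raise ValueError(f"unknown backend {self.backend!r}")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


# -- edge tokenization --------------------------------------------------------

_NUMERIC_SCALING = {
    "review_stars": lambda v: float(v) / 4.0,
    "last_update_year": lambda v: (float(v) - 2000.0) / 25.0,
    "n_submissions": lambda v: math.log1p(float(v)) / 3.0,
    "sample_count": lambda v: math.log10(float(v)) / 5.0,
}

_CATEGORICAL_FIELDS = {"clinical_significance", "consequence"}


def edge_token(fg: FeatureGraph, edge: KGEdge) -> Optional[tuple[str, float]]:
    """(token, value) describing one edge, or None for inert plumbing edges."""
    g = fg.graph
    role = fg.edge_roles.get(edge, "target")
    prefix = "t" if role == "target" else "n"
    pred = edge.predicate
    obj = g.nodes[edge.object]
    subj = g.nodes[edge.subject]
    if pred.startswith(NEIGHBOR_PREDICATE_PREFIX):
        d = int(pred[len(NEIGHBOR_PREDICATE_PREFIX):])
        return (f"nblink:bin{distance_bin(d)}", 1.0)
    if pred == "in_gene":
        return None
    if pred == "about_variant":
        return (f"{prefix}:{subj.node_type}:present", 1.0)
    if obj.node_type in ("dbnsfp_score", "dbscsnv_score"):
        return (f"{prefix}:{subj.node_type}:{pred}", float(obj.value))
    if pred == "has_publication":
        return (f"{prefix}:{subj.node_type}:pub", 1.0)
    if pred == "publisher":
        return (f"{prefix}:pub:publisher={obj.value}", 1.0)
    if pred in _CATEGORICAL_FIELDS:
        return (f"{prefix}:{subj.node_type}:{pred}={obj.value}", 1.0)
    if pred in _NUMERIC_SCALING:
        return (f"{prefix}:{subj.node_type}:{pred}", _NUMERIC_SCALING[pred](obj.value))
    if pred == "protein_change":
        return (f"{prefix}:{subj.node_type}:protein_change", 1.0)
    return (f"{prefix}:{subj.node_type}:{pred}", 1.0)


def _hash_token(token: str, dim: int) -> tuple[int, float]:
    h = int.from_bytes(hashlib.blake2b(token.encode(), digest_size=8).digest(), "big")
    return h % dim, (1.0 if (h >> 62) & 1 else -1.0)


def sorted_edges(fg: FeatureGraph) -> list[KGEdge]:
    return sorted(fg.graph.edges, key=lambda e: (e.subject, e.predicate, e.object))


def _edge_feature_matrix(fg: FeatureGraph, dim: int) -> tuple[list[KGEdge], np.ndarray]:
    """Rows: per-edge hashed feature vectors (graph vector = column sum)."""
    edges = sorted_edges(fg)
    phi = np.zeros((len(edges), dim))
    for i, e in enumerate(edges):
        tok = edge_token(fg, e)
        if tok is None:
            continue
        idx, sign = _hash_token(tok[0], dim)
        phi[i, idx] += sign * tok[1]
    return edges, phi


def graph_vector(fg: FeatureGraph, dim: int) -> np.ndarray:
    _, phi = _edge_feature_matrix(fg, dim)
    if phi.shape[0] == 0:
        return np.zeros(dim)
    return phi.sum(axis=0)


# -- model ---------------------------------------------------------------------


@dataclass
class GraphHashModel:
    """Trained feature-hashing logistic model, tagged with its feature mode."""

    config: ClassifierConfig
    mode: str
    coef: np.ndarray
    intercept: float

    def decision(self, x: np.ndarray) -> float:
        return float(x @ self.coef + self.intercept)

    def score_vector(self, x: np.ndarray) -> float:
        return 1.0 / (1.0 + math.exp(-self.decision(x)))

    # -- serialization ("single archive file": JSON) ----

    def to_json(self, sink: Union[str, IO[str]]) -> None:
        blob = {
            "backend": self.config.backend,
            "config": asdict(self.config),
            "mode": self.mode,
            "coef": self.coef.tolist(),
            "intercept": self.intercept,
        }
        if hasattr(sink, "write"):
            json.dump(blob, sink)
        else:
            with open(sink, "w", encoding="utf-8") as fh:
                json.dump(blob, fh)

    @classmethod
    def from_json(cls, source: Union[str, IO[str]]) -> "GraphHashModel":
        if hasattr(source, "read"):
            blob = json.load(source)
        else:
            with open(source, encoding="utf-8") as fh:
                blob = json.load(fh)
        return cls(
            ClassifierConfig(**blob["config"]),
            blob["mode"],
            np.asarray(blob["coef"]),
            float(blob["intercept"]),
        )


EdgeContribution = dict  # KGEdge -> signed float
NodeContribution = dict  # node_id -> signed float


def train(
    graphs: Sequence[FeatureGraph],
    labels: Sequence[str],
    config: Optional[ClassifierConfig] = None,
) -> GraphHashModel:
    """Fit the hashing backend on labelled feature graphs.

    Deterministic for a fixed seed/config.  All graphs must share one feature
    mode; both classes must be present.
    """
    config = config or ClassifierConfig()
    if len(graphs) != len(labels) or len(graphs) < 2:
        raise ValueError("need >= 2 graphs with one label each")
    for lab in labels:
        if lab not in LABELS:
            raise ValueError(f"label must be one of {LABELS}, got {lab!r}")
    y = np.array([1 if lab == "pathogenic" else 0 for lab in labels])
    if len(set(y.tolist())) < 2:
        raise ValueError("training needs both classes present")
    modes = {g.mode for g in graphs}
    if len(modes) != 1:
        raise ValueError(f"mixed feature modes in training set: {modes}")
    X = np.stack([graph_vector(g, config.hash_dim) for g in graphs])
    lr = LogisticRegression(
        C=config.C,
        max_iter=100 * config.epochs,
        random_state=config.seed,
        solver="lbfgs",
    )
    lr.fit(X, y)
    return GraphHashModel(config, modes.pop(), lr.coef_[0].copy(), float(lr.intercept_[0]))


def predict(model: GraphHashModel, fg: FeatureGraph) -> float:
    """Pathogenicity score in [0, 1] for one feature graph."""
    if fg.mode != model.mode:
        raise ValueError(
            f"feature mode mismatch: model trained in {model.mode!r} mode, "
            f"graph built in {fg.mode!r} mode"
        )
    return model.score_vector(graph_vector(fg, model.config.hash_dim))


def classify(score: float, threshold: float = 0.5) -> str:
    """'pathogenic' iff score >= threshold (default 0.5), else 'benign'."""
    if not 0.0 <= score <= 1.0:
        raise ValueError(f"score {score} outside [0, 1]")
    return "pathogenic" if score >= threshold else "benign"


def edge_contributions(
    model: GraphHashModel,
    fg: FeatureGraph,
    n_perturbations: Optional[int] = None,
    seed: int = 0,
) -> EdgeContribution:
    """LIME-style per-edge attribution for one graph's score.

    Random subsets of edges are switched off, the masked graphs re-scored,
    and a local linear surrogate fitted: the returned value for edge *e* is
    its coefficient (positive = pushes toward pathogenic).  If the full mask
    space (2^E) fits within the perturbation budget it is enumerated and the
    surrogate is the exact unpenalized least-squares fit; otherwise
    ``n_perturbations`` uniform masks and a small ridge penalty are used.
    """
    if fg.mode != model.mode:
        raise ValueError("feature mode mismatch between model and graph")
    n_perturbations = n_perturbations or model.config.lime_samples
    edges, phi = _edge_feature_matrix(fg, model.config.hash_dim)
    E = len(edges)
    if E == 0:
        return {}
    z = phi @ model.coef  # per-edge decision-value increments
    b = model.intercept

    if 2**E <= max(n_perturbations, 2):
        masks = ((np.arange(2**E)[:, None] >> np.arange(E)) & 1).astype(float)
    else:
        rng = np.random.default_rng(seed)
        masks = rng.integers(0, 2, size=(n_perturbations, E)).astype(float)
        masks[0, :] = 1.0  # anchor at the unperturbed graph
    scores = 1.0 / (1.0 + np.exp(-(b + masks @ z)))

    if masks.shape[0] == 2**E:
        design = np.hstack([np.ones((masks.shape[0], 1)), masks])
        coef, *_ = np.linalg.lstsq(design, scores, rcond=None)
        weights = coef[1:]
    else:
        ridge = Ridge(alpha=model.config.lime_ridge, fit_intercept=True)
        ridge.fit(masks, scores)
        weights = ridge.coef_
    return {e: float(w) for e, w in zip(edges, weights)}


def node_contributions(
    edge_contribs: EdgeContribution,
    fg: FeatureGraph,
    aggregation: str = "max",
) -> NodeContribution:
    """Fold per-edge contributions onto nodes.

    Default aggregation is signed max-magnitude over incident edges, which
    reduces to plain equality for a single incident edge and avoids
    double-counting; 'sum' and 'mean' are selectable.
    """
    incident: dict[str, list[float]] = {nid: [] for nid in fg.graph.nodes}
    for e in sorted(edge_contribs, key=lambda e: (e.subject, e.predicate, e.object)):
        c = edge_contribs[e]
        incident[e.subject].append(c)
        incident[e.object].append(c)
    out: NodeContribution = {}
    for nid, vals in incident.items():
        if not vals:
            out[nid] = 0.0
        elif aggregation == "max":
            out[nid] = max(vals, key=lambda v: (abs(v), v))
        elif aggregation == "sum":
            out[nid] = float(sum(vals))
        elif aggregation == "mean":
            out[nid] = float(sum(vals) / len(vals))
        else:
            raise ValueError(f"unknown aggregation {aggregation!r}")
    return out
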