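"""Per-variant feature subgraphs in estimation or explanation mode.

The classifier never sees the whole knowledge graph: for each target variant
a *feature graph* is cut out of it, containing

* the target's own permitted annotation records — in **estimation** mode the
  target's ClinVar record is excluded (it encodes the training label) and
  only the six non-ensemble dbNSFP algorithms are kept (circularity guard);
  in **explanation** mode everything is permitted;
* for every other variant within 100 bases on the same chromosome
  (a *neighbor*), its ClinVar and COSMIC records in both modes, linked from
  the target hub with the base-pair distance on the link.

Explanation-model training additionally masks the target ClinVar record on a
random half of the variants (:func:`make_mask_plan`), so the model does not
learn to parrot ClinVar alone.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .annotations import ESTIMATION_ALGORITHMS
from .kg import KGEdge, KGError, KnowledgeGraph, canonical_variant_key, parse_variant_key

__all__ = [
    "Variant",
    "VariantIndex",
    "FeatureGraph",
    "MaskPlan",
    "neighbors_within",
    "build_feature_graph",
    "make_mask_plan",
    "NEIGHBOR_PREDICATE_PREFIX",
    "DEFAULT_WINDOW",
]

DEFAULT_WINDOW = 100
NEIGHBOR_PREDICATE_PREFIX = "neighbor_within:"


@dataclass(frozen=True)
class Variant:
    """One entry of the variant list (the universe of known variants)."""

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    consequence: str

    @property
    def key(self) -> str:
        return canonical_variant_key(self.chrom, self.pos, self.ref, self.alt)


class VariantIndex:
    """Position index over all known variants, sorted per chromosome."""

    def __init__(self, variants: Iterable[Variant]):
        self.by_key: dict[str, Variant] = {}
        self._per_chrom: dict[str, list[tuple[int, str]]] = {}
        for v in variants:
            self.by_key[v.key] = v
        for v in self.by_key.values():
            self._per_chrom.setdefault(v.chrom, []).append((v.pos, v.key))
        for entries in self._per_chrom.values():
            entries.sort()

    def __contains__(self, key: str) -> bool:
        return key in self.by_key

    def __len__(self) -> int:
        return len(self.by_key)

    def variant(self, key: str) -> Variant:
        try:
            return self.by_key[key]
        except KeyError:
            raise KGError(f"variant {key!r} not in index") from None

    def keys(self):
        return self.by_key.keys()


def neighbors_within(
    target: str, index: VariantIndex, window: int = DEFAULT_WINDOW
) -> list[tuple[str, int]]:
    """Variants on the target's chromosome within ``window`` bases.

    Distance is the absolute difference of (leftmost reference) positions,
    inclusive at the window bound; the target itself is excluded.  Returned
    ascending by distance, ties by position then key.
    """
    tv = index.variant(target)
    entries = index._per_chrom.get(tv.chrom, [])
    lo = bisect.bisect_left(entries, (tv.pos - window, ""))
    hi = bisect.bisect_right(entries, (tv.pos + window, "\xff"))
    out = []
    for pos, key in entries[lo:hi]:
        if key == target:
            continue
        d = abs(pos - tv.pos)
        if d <= window:
            out.append((key, d, pos))
    out.sort(key=lambda t: (t[1], t[2], t[0]))
    return [(key, d) for key, d, _ in out]


class FeatureGraph:
    """The per-variant subgraph handed to the classifier."""

    def __init__(self, target: str, mode: str):
        if mode not in ("estimation", "explanation"):
            raise ValueError(f"mode must be 'estimation' or 'explanation', got {mode!r}")
        self.target = target
        self.mode = mode
        self.graph = KnowledgeGraph()
        self.neighbor_links: list[tuple[str, int]] = []  # (neighbor key, distance)
        self.edge_roles: dict[KGEdge, str] = {}  # 'target' | 'neighbor'

    # -- structure accessors --------------------------------------------------

    @property
    def target_hub_id(self) -> str:
        return self.graph.hub_index[self.target]

    def hub_id(self, key: str) -> str:
        return self.graph.hub_index[key]

    def records_of(self, hub_id: str) -> dict[str, str]:
        """node_type -> record node id for records attached to a hub."""
        out = {}
        for e in self.graph.in_edges(hub_id):
            n = self.graph.nodes[e.subject]
            if n.node_type.endswith("_record"):
                out[n.node_type] = n.node_id
        return out

    def record_fields(self, record_id: str) -> dict[str, object]:
        """predicate -> payload for literal/score children of a record."""
        out = {}
        for e in self.graph.out_edges(record_id):
            n = self.graph.nodes[e.object]
            if n.node_type in ("literal_value", "dbnsfp_score", "dbscsnv_score"):
                out[e.predicate] = n.value
        return out

    def field_node(self, record_id: str, predicate: str) -> Optional[str]:
        for e in self.graph.out_edges(record_id):
            if e.predicate == predicate:
                return e.object
        return None

    def record_publications(self, record_id: str) -> list[tuple[str, Optional[str], str]]:
        """(pmid, publisher or None, publication node id) for a record."""
        out = []
        for e in self.graph.out_edges(record_id):
            if e.predicate != "has_publication":
                continue
            pub = self.graph.nodes[e.object]
            publisher = None
            for pe in self.graph.out_edges(pub.node_id):
                if pe.predicate == "publisher":
                    publisher = self.graph.nodes[pe.object].value
            out.append((str(pub.value), publisher, pub.node_id))
        out.sort()
        return out

    def _assert_invariants(self) -> None:
        if self.mode != "estimation":
            return
        target_records = self.records_of(self.target_hub_id)
        if "clinvar_record" in target_records:
            raise KGError("estimation feature graph contains a target ClinVar record")
        dbn = target_records.get("dbnsfp_record")
        if dbn is not None:
            extra = set(self.record_fields(dbn)) - set(ESTIMATION_ALGORITHMS)
            if extra:
                raise KGError(
                    f"estimation feature graph carries non-whitelisted dbNSFP "
                    f"algorithms on the target: {sorted(extra)}"
                )


def _copy_node(fg: FeatureGraph, kg: KnowledgeGraph, node_id: str) -> None:
    fg.graph.add_node(kg.nodes[node_id])


def _copy_subtree(
    fg: FeatureGraph,
    kg: KnowledgeGraph,
    record_id: str,
    hub_id: str,
    role: str,
    allowed_predicates: Optional[set[str]] = None,
) -> None:
    """Copy a record node, its attach edge and its out-closure into ``fg``."""
    _copy_node(fg, kg, record_id)
    _copy_node(fg, kg, hub_id)
    e = fg.graph.add_edge(record_id, "about_variant", hub_id)
    fg.edge_roles[e] = role
    frontier = [(record_id, True)]
    seen = {record_id}
    while frontier:
        nid, is_root = frontier.pop()
        for edge in kg.out_edges(nid):
            if edge.object == hub_id:
                continue
            if is_root and allowed_predicates is not None:
                if edge.predicate not in allowed_predicates:
                    continue
            _copy_node(fg, kg, edge.object)
            fe = fg.graph.add_edge(edge.subject, edge.predicate, edge.object)
            fg.edge_roles[fe] = role
            if edge.object not in seen:
                seen.add(edge.object)
                frontier.append((edge.object, False))


def build_feature_graph(
    target: str,
    kg: KnowledgeGraph,
    mode: str,
    index: VariantIndex,
    window: int = DEFAULT_WINDOW,
    drop_target_clinvar: bool = False,
) -> FeatureGraph:
    """Cut the target variant's feature subgraph out of the knowledge graph.

    ``drop_target_clinvar`` implements the explanation-training mask plan; it
    has no effect in estimation mode, where the target's ClinVar record is
    always excluded.
    """
    if target not in index:
        raise KGError(f"unknown target variant {target!r}")
    fg = FeatureGraph(target, mode)
    hub_id = fg.graph.get_or_create_hub(target, "variant")

    target_records = {}
    if target in kg.hub_index:
        kg_hub = kg.hub_index[target]
        for e in kg.in_edges(kg_hub):
            n = kg.nodes[e.subject]
            if n.node_type.endswith("_record"):
                target_records[n.node_type] = n.node_id
        # gene link travels with the target
        for e in kg.out_edges(kg_hub):
            if e.predicate == "in_gene":
                _copy_node(fg, kg, e.object)
                fe = fg.graph.add_edge(hub_id, "in_gene", e.object)
                fg.edge_roles[fe] = "target"

    if mode == "estimation":
        permitted = {
            "cosmic_record": None,
            "dbnsfp_record": set(ESTIMATION_ALGORITHMS),
        }
    else:
        permitted = {
            "cosmic_record": None,
            "dbnsfp_record": None,
            "dbscsnv_record": None,
        }
        if not drop_target_clinvar:
            permitted["clinvar_record"] = None
    for rtype, allowed in permitted.items():
        rid = target_records.get(rtype)
        if rid is not None:
            _copy_subtree(fg, kg, rid, hub_id, "target", allowed)

    for nkey, dist in neighbors_within(target, index, window):
        nhub = fg.graph.get_or_create_hub(nkey, "variant")
        le = fg.graph.add_edge(hub_id, f"{NEIGHBOR_PREDICATE_PREFIX}{dist}", nhub)
        fg.edge_roles[le] = "neighbor"
        fg.neighbor_links.append((nkey, dist))
        if nkey not in kg.hub_index:
            continue
        for e in kg.in_edges(kg.hub_index[nkey]):
            n = kg.nodes[e.subject]
            if n.node_type in ("clinvar_record", "cosmic_record"):
                _copy_subtree(fg, kg, n.node_id, nhub, "neighbor", None)

    fg._assert_invariants()
    return fg


@dataclass
class MaskPlan:
    """Which variants train the explanation model *without* their ClinVar."""

    plan: dict[str, str]  # key -> 'keep_clinvar' | 'drop_clinvar'
    seed: int

    def drop(self, key: str) -> bool:
        return self.plan[key] == "drop_clinvar"

    @property
    def n_dropped(self) -> int:
        return sum(1 for v in self.plan.values() if v == "drop_clinvar")


def make_mask_plan(variants: Sequence[str], seed: int) -> MaskPlan:
    """Mark floor(n/2) variants, chosen uniformly under ``seed``, as masked."""
    keys = list(variants)
    if len(keys) < 2:
        raise ValueError("mask plan needs at least 2 variants")
    rng = np.random.default_rng(seed)
    dropped = set(rng.choice(len(keys), size=len(keys) // 2, replace=False).tolist())
    plan = {
        k: ("drop_clinvar" if i in dropped else "keep_clinvar")
        for i, k in enumerate(keys)
    }
    return MaskPlan(plan, seed)
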