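"""Typed knowledge-graph store with hub nodes and N-Triples serialization.

The graph integrates per-database annotation records (ClinVar-, COSMIC-,
dbNSFP- and dbscSNV-style) around canonical *hub* nodes: one hub per variant
and one per gene.  Every annotation record attaches to exactly one hub, and
gene hubs are linked from the variant hubs they contain, so records from
different databases that describe the same variant are joined through a
shared hub.

Edges are (subject, predicate, object) triples with set semantics: adding the
same triple twice is a no-op, and the triple count is the unit of size.
"""

from __future__ import annotations

import re
import urllib.parse
from dataclasses import dataclass, field
from typing import IO, Iterable, Iterator, Optional, Union

import rdflib
from rdflib import Literal, URIRef

__all__ = [
    "KGNode",
    "KGEdge",
    "KnowledgeGraph",
    "KGError",
    "IntegrityError",
    "NTriplesParseError",
    "NODE_TYPES",
    "SOURCE_DBS",
    "canonical_variant_key",
    "parse_variant_key",
    "variant_hub_id",
    "gene_hub_id",
]

#: Closed registry of ontology class labels for nodes.
NODE_TYPES = frozenset(
    {
        "variant_hub",
        "gene_hub",
        "clinvar_record",
        "cosmic_record",
        "dbnsfp_record",
        "dbnsfp_score",
        "dbscsnv_record",
        "dbscsnv_score",
        "publication",
        "literal_value",
    }
)

SOURCE_DBS = frozenset({"clinvar", "cosmic", "dbnsfp", "dbscsnv", "hub", "none"})

_ALLELE_RE = re.compile(r"^[ACGT]+$")

#: Project namespace under which node and predicate IRIs are synthesized.
NS = "https://kgxplain.example.org/"


class KGError(Exception):
    """Base error for knowledge-graph operations."""


class IntegrityError(KGError):
    """A graph invariant would be violated (e.g. record on two hubs)."""


class NTriplesParseError(KGError):
    """Malformed N-Triples input."""


def canonical_variant_key(chrom: str, pos: int, ref: str, alt: str) -> str:
    """Canonical cross-database identity of a variant: ``"chrom:pos:ref>alt"``.

    Coordinates are 1-based fully-closed (VCF/ClinVar convention); alleles are
    normalized to uppercase and the chromosome label is stored without a
    ``chr`` prefix.
    """
    chrom = str(chrom)
    if chrom.lower().startswith("chr"):
        chrom = chrom[3:]
    if not isinstance(pos, int) or isinstance(pos, bool) or pos < 1:
        raise ValueError(f"position must be a positive 1-based integer, got {pos!r}")
    ref, alt = str(ref).upper(), str(alt).upper()
    for name, allele in (("ref", ref), ("alt", alt)):
        if not _ALLELE_RE.match(allele):
            raise ValueError(f"{name} allele {allele!r} is not a nonempty ACGT string")
    return f"{chrom}:{pos}:{ref}>{alt}"


def parse_variant_key(key: str) -> tuple[str, int, str, str]:
    """Inverse of :func:`canonical_variant_key`."""
    chrom, pos, alleles = key.split(":")
    ref, alt = alleles.split(">")
    return chrom, int(pos), ref, alt


def variant_hub_id(key: str) -> str:
    return f"hub:variant:{key}"


def gene_hub_id(symbol: str) -> str:
    return f"hub:gene:{symbol}"


Scalar = Union[str, int, float]


@dataclass(frozen=True)
class KGNode:
    """A typed node; hub nodes carry their canonical key as ``value``."""

    node_id: str
    node_type: str
    value: Optional[Scalar] = None
    source_db: str = "none"

    def __post_init__(self) -> None:
        if self.node_type not in NODE_TYPES:
            raise ValueError(f"unknown node_type {self.node_type!r}")
        if self.source_db not in SOURCE_DBS:
            raise ValueError(f"unknown source_db {self.source_db!r}")
        if self.node_type.endswith("_hub") and self.source_db != "hub":
            raise ValueError("hub nodes must have source_db='hub'")

    @property
    def is_hub(self) -> bool:
        return self.source_db == "hub"


@dataclass(frozen=True)
class KGEdge:
    """A (subject, predicate, object) triple between node ids."""

    subject: str
    predicate: str
    object: str


class KnowledgeGraph:
    """Directed multigraph of :class:`KGNode`/:class:`KGEdge` with set semantics.

    ``hub_index`` maps a canonical variant key or gene symbol to the node id
    of its hub, bijectively onto the hub nodes.
    """

    def __init__(self) -> None:
        self.nodes: dict[str, KGNode] = {}
        self.edges: set[KGEdge] = set()
        self.hub_index: dict[str, str] = {}
        self._out: dict[str, set[KGEdge]] = {}
        self._in: dict[str, set[KGEdge]] = {}

    # -- basic mutation -----------------------------------------------------

    def add_node(self, node: KGNode) -> KGNode:
        existing = self.nodes.get(node.node_id)
        if existing is not None:
            if existing != node:
                raise IntegrityError(
                    f"node id {node.node_id!r} already present with different payload"
                )
            return existing
        self.nodes[node.node_id] = node
        if node.is_hub:
            self.hub_index[str(node.value)] = node.node_id
        return node

    def add_edge(self, subject: str, predicate: str, obj: str) -> KGEdge:
        for endpoint in (subject, obj):
            if endpoint not in self.nodes:
                raise KGError(f"edge endpoint {endpoint!r} not in graph")
        edge = KGEdge(subject, predicate, obj)
        if edge not in self.edges:
            self.edges.add(edge)
            self._out.setdefault(subject, set()).add(edge)
            self._in.setdefault(obj, set()).add(edge)
        return edge

    # -- queries ------------------------------------------------------------

    def out_edges(self, node_id: str) -> set[KGEdge]:
        return self._out.get(node_id, set())

    def in_edges(self, node_id: str) -> set[KGEdge]:
        return self._in.get(node_id, set())

    def node(self, node_id: str) -> KGNode:
        try:
            return self.nodes[node_id]
        except KeyError:
            raise KGError(f"unknown node {node_id!r}") from None

    def __contains__(self, node_id: str) -> bool:
        return node_id in self.nodes

    def __len__(self) -> int:
        return len(self.nodes)

    @property
    def n_triples(self) -> int:
        return len(self.edges)

    # -- hubs ---------------------------------------------------------------

    def get_or_create_hub(self, key: str, kind: str) -> str:
        """Return the hub node id for ``key``, creating the hub if absent.

        Idempotent: repeated calls with the same key return the same id and
        add nothing.
        """
        if kind not in ("variant", "gene"):
            raise ValueError(f"hub kind must be 'variant' or 'gene', got {kind!r}")
        if key in self.hub_index:
            return self.hub_index[key]
        node_id = variant_hub_id(key) if kind == "variant" else gene_hub_id(key)
        node = KGNode(node_id, f"{kind}_hub", value=key, source_db="hub")
        self.add_node(node)
        return node_id

    def attach_record(self, record_node: KGNode, hub: str, predicate: str) -> None:
        """Attach an annotation record node to its (single) hub.

        Re-attaching to the same hub is a no-op; attaching a record that is
        already on a *different* hub raises :class:`IntegrityError`.
        """
        if hub not in self.nodes or not self.nodes[hub].is_hub:
            raise KGError(f"{hub!r} is not a hub node in this graph")
        self.add_node(record_node)
        for e in self.out_edges(record_node.node_id):
            if self.nodes[e.object].is_hub and e.object != hub:
                raise IntegrityError(
                    f"record {record_node.node_id!r} already attached to hub {e.object!r}"
                )
        self.add_edge(record_node.node_id, predicate, hub)

    # -- traversal ----------------------------------------------------------

    def reachable_subgraph(self, start: str) -> "KnowledgeGraph":
        """Closure of nodes reachable from ``start``.

        Edges are followed in their stored direction everywhere; at a hub
        node, incoming edges are additionally crossed in reverse
        (record -> hub -> record), so that annotation records attached to a
        hub are reachable from it.
        """
        if start not in self.nodes:
            raise KGError(f"unknown start node {start!r}")
        seen = {start}
        frontier = [start]
        keep_edges: set[KGEdge] = set()
        while frontier:
            nid = frontier.pop()
            neighbors: list[tuple[str, KGEdge]] = [
                (e.object, e) for e in self.out_edges(nid)
            ]
            if self.nodes[nid].is_hub:
                neighbors += [(e.subject, e) for e in self.in_edges(nid)]
            for nxt, edge in neighbors:
                keep_edges.add(edge)
                if nxt not in seen:
                    seen.add(nxt)
                    frontier.append(nxt)
        sub = KnowledgeGraph()
        for nid in seen:
            sub.add_node(self.nodes[nid])
        for e in keep_edges:
            if e.subject in seen and e.object in seen:
                sub.add_edge(e.subject, e.predicate, e.object)
        return sub

    # -- N-Triples serialization ---------------------------------------------

    def _node_iri(self, node: KGNode) -> URIRef:
        quoted = urllib.parse.quote(node.node_id, safe="")
        iri = f"{NS}n/{node.node_type}/{node.source_db}/{quoted}"
        if node.value is not None:
            vt = {int: "i", float: "f"}.get(type(node.value), "s")
            iri += f"?v={urllib.parse.quote(str(node.value), safe='')}&t={vt}"
        return URIRef(iri)

    @staticmethod
    def _iri_node(iri: str) -> KGNode:
        if not iri.startswith(NS + "n/"):
            raise NTriplesParseError(f"IRI outside project namespace: {iri}")
        rest = iri[len(NS) + 2 :]
        value: Optional[Scalar] = None
        if "?" in rest:
            rest, query = rest.split("?", 1)
            params = urllib.parse.parse_qs(query)
            raw = params["v"][0]
            vt = params.get("t", ["s"])[0]
            value = {"i": int, "f": float, "s": str}[vt](raw)
        node_type, source_db, quoted = rest.split("/", 2)
        return KGNode(urllib.parse.unquote(quoted), node_type, value, source_db)

    def _predicate_iri(self, predicate: str) -> URIRef:
        return URIRef(f"{NS}p/{urllib.parse.quote(predicate, safe='')}")

    def write_ntriples(self, sink: Union[str, IO[str]]) -> int:
        """Serialize edges as N-Triples; returns the triple (edge) count.

        Each KG edge becomes exactly one triple.  Node type, source and
        payload are encoded in the synthesized IRIs; ``literal_value`` object
        nodes serialize as typed RDF literals.  Isolated nodes are not
        representable and are dropped.
        """
        g = rdflib.Graph()
        for e in sorted(self.edges, key=lambda e: (e.subject, e.predicate, e.object)):
            subj = self._node_iri(self.nodes[e.subject])
            pred = self._predicate_iri(e.predicate)
            onode = self.nodes[e.object]
            if onode.node_type == "literal_value":
                obj: Union[URIRef, Literal] = Literal(onode.value)
            else:
                obj = self._node_iri(onode)
            g.add((subj, pred, obj))
        data = g.serialize(format="nt")
        if hasattr(sink, "write"):
            sink.write(data)
        else:
            with open(sink, "w", encoding="utf-8") as fh:
                fh.write(data)
        return len(g)

    @classmethod
    def read_ntriples(cls, source: Union[str, IO[str]]) -> "KnowledgeGraph":
        """Parse an N-Triples file written by :meth:`write_ntriples`.

        Literal objects become fresh ``literal_value`` nodes scoped to their
        (subject, predicate, value) triple.
        """
        g = rdflib.Graph()
        try:
            if hasattr(source, "read"):
                g.parse(data=source.read(), format="nt")
            else:
                g.parse(source, format="nt")
        except Exception as exc:  # rdflib reports the offending line
            raise NTriplesParseError(str(exc)) from exc
        kg = cls()
        for s, p, o in g:
            snode = cls._iri_node(str(s))
            kg.add_node(snode)
            if not str(p).startswith(NS + "p/"):
                raise NTriplesParseError(f"predicate outside project namespace: {p}")
            predicate = urllib.parse.unquote(str(p)[len(NS) + 2 :])
            if isinstance(o, Literal):
                value = o.toPython()
                onode = KGNode(
                    f"lit:{snode.node_id}:{predicate}:{value}",
                    "literal_value",
                    value,
                    snode.source_db,
                )
            else:
                onode = cls._iri_node(str(o))
            kg.add_node(onode)
            kg.add_edge(snode.node_id, predicate, onode.node_id)
        return kg

    # -- TSV dialect ----------------------------------------------------------

    def to_tsv(self, nodes_sink: IO[str], edges_sink: IO[str]) -> None:
        nodes_sink.write("node_id\tnode_type\tvalue\tsource_db\n")
        for nid in sorted(self.nodes):
            n = self.nodes[nid]
            v = "" if n.value is None else str(n.value)
            nodes_sink.write(f"{n.node_id}\t{n.node_type}\t{v}\t{n.source_db}\n")
        edges_sink.write("subject\tpredicate\tobject\n")
        for e in sorted(self.edges, key=lambda e: (e.subject, e.predicate, e.object)):
            edges_sink.write(f"{e.subject}\t{e.predicate}\t{e.object}\n")

    # -- equality up to payload-preserving isomorphism -------------------------

    def signature(self) -> tuple:
        """Canonical content signature, invariant to literal node renaming."""

        def nsig(nid: str) -> tuple:
            n = self.nodes[nid]
            if n.node_type == "literal_value":
                return ("literal_value", n.value, n.source_db)
            return (n.node_type, n.node_id, n.value, n.source_db)

        esigs = sorted(
            (nsig(e.subject), e.predicate, nsig(e.object)) for e in self.edges
        )
        isolated = sorted(
            nsig(nid)
            for nid in self.nodes
            if not self._out.get(nid) and not self._in.get(nid)
        )
        return (tuple(esigs), tuple(isolated))
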