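"""Simplified annotation-table schemas and their conversion into the graph.

Four tab-separated tables emulate the public variant databases a clinical
annotation pipeline integrates:

``clinvar.tsv``
    chrom, pos, ref, alt, gene, consequence, clinical_significance,
    review_stars (0-4), last_update_year, n_submissions (>=1),
    publications ("pmid:publisher;pmid:publisher", may be empty)
``cosmic.tsv``
    chrom, pos, ref, alt, gene, protein_change (HGVS-p-like, may be empty),
    sample_count (>=1), publications ("pmid;pmid", may be empty)
``dbnsfp.tsv``
    chrom, pos, ref, alt, then one column per algorithm; cells are rank-style
    scores in [0, 1] (higher = more damaging) or empty for missing
``dbscsnv.tsv``
    chrom, pos, ref, alt, ada_score, rf_score (both in [0, 1])

Every row loads into exactly one record or is rejected with a reason;
loaders never silently drop data.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import IO, Optional, Sequence, Union

import pandas as pd

from .kg import KGNode, KnowledgeGraph, canonical_variant_key

__all__ = [
    "ClinVarRecord",
    "CosmicRecord",
    "DbnsfpRecord",
    "DbscsnvRecord",
    "LoadResult",
    "SchemaError",
    "load_clinvar",
    "load_cosmic",
    "load_dbnsfp",
    "load_dbscsnv",
    "records_to_kg",
    "SIGNIFICANCE_LEVELS",
    "ESTIMATION_ALGORITHMS",
    "EXPLANATION_ONLY_ALGORITHMS",
    "CONSERVATION_ALGORITHMS",
    "ALL_ALGORITHMS",
    "algorithm_class",
    "DEFAULT_PUBLISHERS",
]

SIGNIFICANCE_LEVELS = (
    "Pathogenic",
    "Likely_pathogenic",
    "Benign",
    "Likely_benign",
    "VUS",
)

#: dbNSFP algorithms permitted as *estimation* features for the target
#: variant.  Ensemble scores trained on ClinVar (CADD, REVEL, MetaLR, ...)
#: are excluded here to avoid type-1 circularity: they encode the label.
ESTIMATION_ALGORITHMS = (
    "SIFT",
    "LRT",
    "PROVEAN",
    "phyloP100way_vertebrate",
    "GERP++_RS",
    "SiPhy_29way_logOdds",
)

#: Additional algorithms available only to the explanation-mode model.
EXPLANATION_ONLY_ALGORITHMS = (
    "CADD",
    "DANN",
    "FATHMM",
    "M-CAP",
    "MetaLR",
    "MetaSVM",
    "MutPred",
    "MutationTaster",
    "Polyphen2_HDIV",
    "Polyphen2_HVAR",
    "REVEL",
    "fathmm-MKL_coding",
    "phastCons100way_vertebrate",
)

ALL_ALGORITHMS = ESTIMATION_ALGORITHMS + EXPLANATION_ONLY_ALGORITHMS

#: Conservation-based (as opposed to functional-prediction) algorithms.
CONSERVATION_ALGORITHMS = frozenset(
    {
        "phyloP100way_vertebrate",
        "GERP++_RS",
        "SiPhy_29way_logOdds",
        "phastCons100way_vertebrate",
    }
)

#: Closed vocabulary of ClinVar publication publishers (configurable at the
#: loader level); drives the per-publisher tabulation in baseline flattening.
DEFAULT_PUBLISHERS = ("Elsevier", "Springer", "Wiley", "NEJM")


def algorithm_class(name: str) -> str:
    """'conservation' or 'prediction' class of a dbNSFP algorithm."""
    return "conservation" if name in CONSERVATION_ALGORITHMS else "prediction"


class SchemaError(ValueError):
    """Input table does not match the documented schema."""


@dataclass(frozen=True)
class ClinVarRecord:
    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    consequence: str
    clinical_significance: str
    review_stars: int
    last_update_year: int
    n_submissions: int
    publications: tuple[tuple[str, str], ...] = ()  # (pmid, publisher)

    @property
    def key(self) -> str:
        return canonical_variant_key(self.chrom, self.pos, self.ref, self.alt)


@dataclass(frozen=True)
class CosmicRecord:
    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    protein_change: Optional[str]
    sample_count: int
    publications: tuple[str, ...] = ()

    @property
    def key(self) -> str:
        return canonical_variant_key(self.chrom, self.pos, self.ref, self.alt)


@dataclass(frozen=True)
class DbnsfpRecord:
    chrom: str
    pos: int
    ref: str
    alt: str
    scores: tuple[tuple[str, float], ...]  # (algorithm, score in [0,1])

    @property
    def key(self) -> str:
        return canonical_variant_key(self.chrom, self.pos, self.ref, self.alt)

    def score_map(self) -> dict[str, float]:
        return dict(self.scores)


@dataclass(frozen=True)
class DbscsnvRecord:
    chrom: str
    pos: int
    ref: str
    alt: str
    ada_score: float
    rf_score: float

    @property
    def key(self) -> str:
        return canonical_variant_key(self.chrom, self.pos, self.ref, self.alt)


@dataclass
class LoadResult:
    """Loaded records plus per-row rejections (row index, reason)."""

    records: list
    rejections: list[tuple[int, str]] = field(default_factory=list)

    @property
    def n_loaded(self) -> int:
        return len(self.records)

    @property
    def n_rejected(self) -> int:
        return len(self.rejections)


def _read_table(source: Union[str, IO[str]], required: Sequence[str]) -> pd.DataFrame:
    df = pd.read_csv(source, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    return df


def _key_fields(row) -> tuple[str, int, str, str]:
    chrom, pos, ref, alt = row["chrom"], int(row["pos"]), row["ref"], row["alt"]
    canonical_variant_key(chrom, pos, ref, alt)  # validates
    if chrom.lower().startswith("chr"):
        chrom = chrom[3:]
    return chrom, pos, ref.upper(), alt.upper()


def load_clinvar(source: Union[str, IO[str]]) -> LoadResult:
    cols = [
        "chrom", "pos", "ref", "alt", "gene", "consequence",
        "clinical_significance", "review_stars", "last_update_year",
        "n_submissions", "publications",
    ]
    df = _read_table(source, cols)
    out = LoadResult([])
    for i, row in df.iterrows():
        try:
            chrom, pos, ref, alt = _key_fields(row)
            sig = row["clinical_significance"]
            if sig not in SIGNIFICANCE_LEVELS:
                raise ValueError(f"unknown clinical_significance {sig!r}")
            stars = int(row["review_stars"])
            if not 0 <= stars <= 4:
                raise ValueError(f"review_stars {stars} outside [0, 4]")
            nsub = int(row["n_submissions"])
            if nsub < 1:
                raise ValueError(f"n_submissions {nsub} < 1")
            pubs = []
            if row["publications"]:
                for item in row["publications"].split(";"):
                    pmid, _, publisher = item.partition(":")
                    if not pmid or not publisher:
                        raise ValueError(f"malformed publication entry {item!r}")
                    pubs.append((pmid, publisher))
            out.records.append(
                ClinVarRecord(
                    chrom, pos, ref, alt, row["gene"], row["consequence"],
                    sig, stars, int(row["last_update_year"]), nsub, tuple(pubs),
                )
            )
        except (ValueError, KeyError) as exc:
            out.rejections.append((int(i), str(exc)))
    return out


def load_cosmic(source: Union[str, IO[str]]) -> LoadResult:
    cols = ["chrom", "pos", "ref", "alt", "gene", "protein_change",
            "sample_count", "publications"]
    df = _read_table(source, cols)
    out = LoadResult([])
    for i, row in df.iterrows():
        try:
            chrom, pos, ref, alt = _key_fields(row)
            n = int(row["sample_count"])
            if n < 1:
                raise ValueError(f"sample_count {n} < 1")
            pubs = tuple(p for p in row["publications"].split(";") if p)
            pchange = row["protein_change"] or None
            out.records.append(
                CosmicRecord(chrom, pos, ref, alt, row["gene"], pchange, n, pubs)
            )
        except (ValueError, KeyError) as exc:
            out.rejections.append((int(i), str(exc)))
    return out


def load_dbnsfp(source: Union[str, IO[str]]) -> LoadResult:
    df = _read_table(source, ["chrom", "pos", "ref", "alt"])
    algs = [c for c in df.columns if c not in ("chrom", "pos", "ref", "alt")]
    out = LoadResult([])
    for i, row in df.iterrows():
        try:
            chrom, pos, ref, alt = _key_fields(row)
            scores = []
            for alg in algs:
                cell = row[alg]
                if cell == "":
                    continue
                s = float(cell)
                if not 0.0 <= s <= 1.0:
                    raise ValueError(f"{alg} score {s} outside [0, 1]")
                scores.append((alg, s))
            out.records.append(DbnsfpRecord(chrom, pos, ref, alt, tuple(scores)))
        except (ValueError, KeyError) as exc:
            out.rejections.append((int(i), str(exc)))
    return out


def load_dbscsnv(source: Union[str, IO[str]]) -> LoadResult:
    cols = ["chrom", "pos", "ref", "alt", "ada_score", "rf_score"]
    df = _read_table(source, cols)
    out = LoadResult([])
    for i, row in df.iterrows():
        try:
            chrom, pos, ref, alt = _key_fields(row)
            ada, rf = float(row["ada_score"]), float(row["rf_score"])
            for name, s in (("ada_score", ada), ("rf_score", rf)):
                if not 0.0 <= s <= 1.0:
                    raise ValueError(f"{name} {s} outside [0, 1]")
            out.records.append(DbscsnvRecord(chrom, pos, ref, alt, ada, rf))
        except (ValueError, KeyError) as exc:
            out.rejections.append((int(i), str(exc)))
    return out


# -- graph construction ------------------------------------------------------


def _lit(kg: KnowledgeGraph, parent: str, predicate: str, value, source: str) -> None:
    node = KGNode(f"lit:{parent}:{predicate}:{value}", "literal_value", value, source)
    kg.add_node(node)
    kg.add_edge(parent, predicate, node.node_id)


def _pub(kg: KnowledgeGraph, parent: str, pmid: str, publisher: Optional[str]) -> None:
    pub = KGNode(f"pub:{pmid}", "publication", pmid, "none")
    kg.add_node(pub)
    kg.add_edge(parent, "has_publication", pub.node_id)
    if publisher is not None:
        _lit(kg, pub.node_id, "publisher", publisher, "none")


def _link_gene(kg: KnowledgeGraph, variant_hub: str, gene: str) -> None:
    gene_hub = kg.get_or_create_hub(gene, "gene")
    kg.add_edge(variant_hub, "in_gene", gene_hub)


def records_to_kg(
    clinvar: Sequence[ClinVarRecord] = (),
    cosmic: Sequence[CosmicRecord] = (),
    dbnsfp: Sequence[DbnsfpRecord] = (),
    dbscsnv: Sequence[DbscsnvRecord] = (),
) -> KnowledgeGraph:
    """Assemble validated records into one hub-joined knowledge graph.

    One record node per input record, with a literal (or score/publication)
    child node per field; each record attaches to its variant hub, and the
    variant hub links to the gene hub, so same-variant records from different
    sources share a single hub.  Deterministic for a fixed input order.
    """
    kg = KnowledgeGraph()
    for r in clinvar:
        hub = kg.get_or_create_hub(r.key, "variant")
        _link_gene(kg, hub, r.gene)
        rid = f"clinvar:{r.key}"
        node = KGNode(rid, "clinvar_record", None, "clinvar")
        kg.attach_record(node, hub, "about_variant")
        _lit(kg, rid, "clinical_significance", r.clinical_significance, "clinvar")
        _lit(kg, rid, "consequence", r.consequence, "clinvar")
        _lit(kg, rid, "review_stars", r.review_stars, "clinvar")
        _lit(kg, rid, "last_update_year", r.last_update_year, "clinvar")
        _lit(kg, rid, "n_submissions", r.n_submissions, "clinvar")
        for pmid, publisher in r.publications:
            _pub(kg, rid, pmid, publisher)
    for r in cosmic:
        hub = kg.get_or_create_hub(r.key, "variant")
        _link_gene(kg, hub, r.gene)
        rid = f"cosmic:{r.key}"
        node = KGNode(rid, "cosmic_record", None, "cosmic")
        kg.attach_record(node, hub, "about_variant")
        if r.protein_change is not None:
            _lit(kg, rid, "protein_change", r.protein_change, "cosmic")
        _lit(kg, rid, "sample_count", r.sample_count, "cosmic")
        for pmid in r.publications:
            _pub(kg, rid, pmid, None)
    for r in dbnsfp:
        hub = kg.get_or_create_hub(r.key, "variant")
        rid = f"dbnsfp:{r.key}"
        node = KGNode(rid, "dbnsfp_record", None, "dbnsfp")
        kg.attach_record(node, hub, "about_variant")
        for alg, score in r.scores:
            snode = KGNode(f"dbnsfp:{r.key}:{alg}", "dbnsfp_score", score, "dbnsfp")
            kg.add_node(snode)
            kg.add_edge(rid, alg, snode.node_id)
    for r in dbscsnv:
        hub = kg.get_or_create_hub(r.key, "variant")
        rid = f"dbscsnv:{r.key}"
        node = KGNode(rid, "dbscsnv_record", None, "dbscsnv")
        kg.attach_record(node, hub, "about_variant")
        for name, score in (("ada_score", r.ada_score), ("rf_score", r.rf_score)):
            snode = KGNode(f"dbscsnv:{r.key}:{name}", "dbscsnv_score", score, "dbscsnv")
            kg.add_node(snode)
            kg.add_edge(rid, name, snode.node_id)
    return kg
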