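"""Shared builders: tiny hand-made annotation worlds for graph/explainer tests."""

from __future__ import annotations

import pytest

from kgxplain.annotations import (
    ClinVarRecord,
    CosmicRecord,
    DbnsfpRecord,
    DbscsnvRecord,
    records_to_kg,
)
from kgxplain.features import Variant, VariantIndex, build_feature_graph


def make_variant(chrom="17", pos=1000, ref="G", alt="C", gene="MYO7A",
                 consequence="missense_variant") -> Variant:
    return Variant(str(chrom), pos, ref, alt, gene, consequence)


def clinvar_for(v: Variant, significance="Pathogenic", stars=3, year=2019,
                n_submissions=3, publications=()) -> ClinVarRecord:
    return ClinVarRecord(v.chrom, v.pos, v.ref, v.alt, v.gene, v.consequence,
                         significance, stars, year, n_submissions,
                         tuple(publications))


def cosmic_for(v: Variant, protein_change=None, sample_count=10,
               publications=()) -> CosmicRecord:
    return CosmicRecord(v.chrom, v.pos, v.ref, v.alt, v.gene, protein_change,
                        sample_count, tuple(publications))


def dbnsfp_for(v: Variant, scores: dict) -> DbnsfpRecord:
    return DbnsfpRecord(v.chrom, v.pos, v.ref, v.alt, tuple(scores.items()))


def dbscsnv_for(v: Variant, ada=0.5, rf=0.5) -> DbscsnvRecord:
    return DbscsnvRecord(v.chrom, v.pos, v.ref, v.alt, ada, rf)


def toy_world(variants, clinvar=(), cosmic=(), dbnsfp=(), dbscsnv=()):
    """(knowledge graph, variant index) for a hand-made annotation set."""
    kg = records_to_kg(list(clinvar), list(cosmic), list(dbnsfp), list(dbscsnv))
    return kg, VariantIndex(variants)


def explanation_graph(target: Variant, variants, **records):
    kg, index = toy_world(variants, **records)
    return build_feature_graph(target.key, kg, "explanation", index), kg, index


@pytest.fixture
def lone_variant():
    v = make_variant()
    return v, *toy_world([v])
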