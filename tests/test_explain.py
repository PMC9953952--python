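"""X-Factor math, rule matching, golden sentences, ranked explanations."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kgxplain.annotations import CONSERVATION_ALGORITHMS, ALL_ALGORITHMS
from kgxplain.classifier import ClassifierConfig, train
from kgxplain.explain import (
    DEFAULT_IMPACT,
    DEFAULT_RULES,
    XImpactTable,
    explain,
    match_rule,
    number_word,
    render_sentence,
    sentence_contribution,
    x_factor,
)
from kgxplain.features import build_feature_graph

from .conftest import (
    clinvar_for,
    cosmic_for,
    dbnsfp_for,
    explanation_graph,
    make_variant,
)

RULES = {r.name: r for r in DEFAULT_RULES}


class TestXFactor:
    def test_zero_contribution_is_half(self):
        for impact in (0.0, 0.5, 2.0, 100.0):
            assert x_factor(0.0, impact) == 0.5

    def test_zero_impact_is_half(self):
        for c in (-5.0, -0.1, 0.3, 7.0):
            assert x_factor(c, 0.0) == 0.5

    def test_closed_form_value(self):
        assert x_factor(2.0, 3.0) == pytest.approx(1 / (1 + math.exp(-6)), abs=1e-12)

    def test_negative_impact_rejected(self):
        with pytest.raises(ValueError):
            x_factor(0.3, -1.0)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        c=st.floats(-50, 50, allow_nan=False),
        i=st.floats(0, 50, allow_nan=False),
    )
    def test_symmetry_and_range(self, c, i):
        f = x_factor(c, i)
        assert 0.0 < f < 1.0
        assert f + x_factor(-c, i) == pytest.approx(1.0, abs=1e-12)

    def test_strictly_increasing_in_contribution(self):
        grid = np.linspace(-3, 3, 25)
        vals = [x_factor(c, 1.7) for c in grid]
        assert all(a < b for a, b in zip(vals, vals[1:]))


def test_number_words():
    assert number_word(3) == "three"
    assert number_word(14) == "fourteen"
    assert number_word(26) == "twenty-six"
    assert number_word(40) == "forty"


def _single(rule, fg, params=None):
    matches = match_rule(RULES[rule], fg, params)
    assert len(matches) >= 1
    return matches[0]


def golden_fixture(rule_name):
    """Per-rule fixture whose slot values reproduce the printed sample."""
    t = make_variant(chrom="17", pos=5000, gene="MYO7A")
    prediction = [a for a in ALL_ALGORITHMS if a not in CONSERVATION_ALGORITHMS]

    if rule_name == "Neighboring variants in ClinVar":
        nbs = [make_variant(pos=5001 + i, gene="MYO7A") for i in range(14)]
        sigs = ["Pathogenic"] * 3 + ["VUS"] * 11
        cl = [clinvar_for(n, s) for n, s in zip(nbs, sigs)]
        fg, *_ = explanation_graph(t, [t] + nbs, clinvar=cl)
        return fg, (
            "Fourteen neighboring variants are “missense variant”, three of "
            "which are registered as “Pathogenic” in ClinVar."
        )
    if rule_name == "Outstanding algorithms in dbNSFP":
        scores = {
            "phyloP100way_vertebrate": 0.97, "SiPhy_29way_logOdds": 0.88,
            "SIFT": 0.72, "PROVEAN": 0.71, "LRT": 0.63, "GERP++_RS": 0.20,
        }
        fg, *_ = explanation_graph(t, [t], dbnsfp=[dbnsfp_for(t, scores)])
        return fg, (
            "This variant has dbNSFP algorithms: phyloP100way_vertebrate is "
            "high (0.97), SiPhy_29way_logOdds is high (0.88), SIFT is high "
            "(0.72), PROVEAN is high (0.71), and LRT is moderate (0.63)."
        )
    if rule_name == "Average of algorithms in dbNSFP":
        scores = {a: 0.84 for a in prediction[:14]}
        scores.update({a: 0.79 for a in CONSERVATION_ALGORITHMS})
        fg, *_ = explanation_graph(t, [t], dbnsfp=[dbnsfp_for(t, scores)])
        return fg, (
            "This variant has an average score of 0.84 for 14 prediction "
            "algorithms, and 0.79 for 4 conservation algorithms from dbNSFP."
        )
    if rule_name == "Same amino acid variants":
        nb = make_variant(pos=5002, gene="MYO7A", alt="T")
        fg, *_ = explanation_graph(
            t, [t, nb],
            cosmic=[cosmic_for(t, "p.R100L"), cosmic_for(nb, "p.G100V")],
            clinvar=[clinvar_for(nb, "VUS")],
        )
        return fg, (
            'Neighboring variants in the same base are registered as "VUS" in ClinVar.'
        )
    if rule_name == "Neighboring variant papers":
        nbs = [make_variant(pos=5001 + i, gene="MYO7A") for i in range(8)]
        counts = [3, 3, 3, 3, 3, 3, 4, 4]  # 26 distinct papers
        pmid = 900
        cl = []
        for n, c in zip(nbs, counts):
            pubs = [(str(pmid + j), "Elsevier") for j in range(c)]
            pmid += c
            cl.append(clinvar_for(n, publications=pubs))
        fg, *_ = explanation_graph(t, [t] + nbs, clinvar=cl)
        return fg, "Eight neighboring variants are reported in twenty-six papers."
    if rule_name == "Variants in COSMIC":
        nb = make_variant(pos=5050, gene="MYO7A")
        fg, *_ = explanation_graph(t, [t, nb], cosmic=[cosmic_for(nb, "p.R1861*")])
        return fg, "A neighboring variant, p.R1861*, is registered in COSMIC."
    if rule_name == "Variants in dbNSFP":
        fg, *_ = explanation_graph(t, [t], dbnsfp=[dbnsfp_for(t, {"SIFT": 0.88})])
        return fg, (
            "This variant has a score of 0.88 according to the SIFT algorithm "
            "of dbNSFP."
        )
    if rule_name == "Variants reference":
        fg, *_ = explanation_graph(
            t, [t], clinvar=[clinvar_for(t, publications=[("28492532", "Elsevier")])]
        )
        return fg, (
            "This variant is explained in https://pubmed.ncbi.nlm.nih.gov/28492532/ "
            "(accessed on 2 December 2022)."
        )
    if rule_name == "Variants in ClinVar":
        fg, *_ = explanation_graph(
            t, [t], clinvar=[clinvar_for(t, "Pathogenic", stars=3, n_submissions=3)]
        )
        return fg, (
            "This variant is considered pathogenic with 3 stars in ClinVar, "
            "and the report has 3 submissions."
        )
    if rule_name == "Variants type":
        fg, *_ = explanation_graph(t, [t])
        return fg, "This variant is a missense variant."
    raise AssertionError(rule_name)


@pytest.mark.parametrize("rule_name", sorted(RULES))
def test_golden_sentences_match_reference_byte_for_byte(rule_name):
    fg, expected = golden_fixture(rule_name)
    params = {"target_consequence": "missense_variant"}
    match = _single(rule_name, fg, params)
    assert render_sentence(RULES[rule_name], match) == expected
    assert match.support <= set(fg.graph.nodes)  # evidence exists in the subgraph


class TestMatching:
    def test_no_clinvar_no_match(self):
        t = make_variant()
        fg, *_ = explanation_graph(t, [t])
        assert match_rule(RULES["Variants in ClinVar"], fg) == []
        assert match_rule(RULES["Neighboring variants in ClinVar"], fg) == []

    def test_estimation_graph_rejected(self):
        from .conftest import toy_world

        t = make_variant()
        kg, index = toy_world([t])
        fg = build_feature_graph(t.key, kg, "estimation", index)
        with pytest.raises(ValueError):
            match_rule(RULES["Variants type"], fg)

    def test_case_study_rule_coverage(self):
        # high dbNSFP scores + pathogenic neighbors in ClinVar and COSMIC +
        # a same-codon VUS: five rule families must all fire.
        t = make_variant(chrom="11", pos=9000, gene="MYO7A")
        n1 = make_variant(chrom="11", pos=9010, gene="MYO7A")
        n2 = make_variant(chrom="11", pos=9002, gene="MYO7A", alt="T")
        scores = {a: 0.9 for a in ("SIFT", "PROVEAN", "CADD")}
        scores.update({a: 0.8 for a in CONSERVATION_ALGORITHMS})
        fg, *_ = explanation_graph(
            t, [t, n1, n2],
            dbnsfp=[dbnsfp_for(t, scores)],
            cosmic=[cosmic_for(t, "p.R1861Q"), cosmic_for(n1, "p.R1861*"),
                    cosmic_for(n2, "p.G1861V")],
            clinvar=[clinvar_for(n1, "Pathogenic"), clinvar_for(n2, "VUS")],
        )
        fired = {name for name, r in RULES.items() if match_rule(r, fg)}
        assert fired >= {
            "Outstanding algorithms in dbNSFP",
            "Average of algorithms in dbNSFP",
            "Same amino acid variants",
            "Neighboring variants in ClinVar",
            "Variants in COSMIC",
        }

    def test_unbound_slot_is_rendering_error(self):
        t = make_variant()
        fg, *_ = explanation_graph(t, [t], clinvar=[clinvar_for(t)])
        match = _single("Variants in ClinVar", fg)
        match.slots.pop("stars")
        with pytest.raises(ValueError):
            render_sentence(RULES["Variants in ClinVar"], match)


class TestSentenceContribution:
    def test_singleton(self):
        assert sentence_contribution(["n"], {"n": 0.4}) == 0.4

    def test_max_magnitude(self):
        assert sentence_contribution(["a", "b"], {"a": 0.1, "b": -0.7}) == -0.7

    def test_empty_and_all_zero(self):
        assert sentence_contribution([], {}) == 0.0
        assert sentence_contribution(["a", "b"], {"a": 0.0, "b": 0.0}) == 0.0


def _explanation_model(seed=0, n=40):
    """Explanation-mode model on variants with planted dbNSFP signal."""
    from .conftest import toy_world

    rng = np.random.default_rng(seed)
    variants, dbn, cl, labels = [], [], [], []
    for i in range(n):
        v = make_variant(chrom=str(i % 8 + 1), pos=10_000 * (i + 1), gene=f"G{i}")
        label = i % 2
        s = rng.uniform(0.6, 0.95) if label else rng.uniform(0.05, 0.4)
        variants.append(v)
        dbn.append(dbnsfp_for(v, {"SIFT": round(float(s), 6)}))
        cl.append(clinvar_for(v, "Pathogenic" if label else "Benign"))
        labels.append("pathogenic" if label else "benign")
    kg, index = toy_world(variants, clinvar=cl, dbnsfp=dbn)
    graphs = [build_feature_graph(v.key, kg, "explanation", index) for v in variants]
    model = train(graphs, labels, ClassifierConfig(seed=seed))
    return model, kg, index, variants


class TestExplain:
    def test_output_sorted_and_bounded(self):
        model, kg, index, variants = _explanation_model()
        sents = explain(model, variants[1].key, kg, index, top_n=3, seed=0)
        assert 1 <= len(sents) <= 3
        xs = [s.x_factor for s in sents]
        assert xs == sorted(xs, reverse=True)

    def test_support_nodes_exist(self):
        model, kg, index, variants = _explanation_model()
        fg = build_feature_graph(variants[1].key, kg, "explanation", index)
        for s in explain(model, variants[1].key, kg, index, top_n=20, seed=0):
            assert s.support <= set(fg.graph.nodes)

    def test_estimation_model_refused(self):
        from .test_classifier import planted_graphs

        graphs, labels = planted_graphs(10, seed=1)
        est_model = train(graphs, labels)
        _, kg, index, variants = _explanation_model()
        with pytest.raises(ValueError):
            explain(est_model, variants[0].key, kg, index)

    def test_top_n_validation(self):
        model, kg, index, variants = _explanation_model()
        with pytest.raises(ValueError):
            explain(model, variants[0].key, kg, index, top_n=0)

    def test_rank_monotone_in_impact(self):
        # boosting the impact of the node type behind a positively-contributing
        # sentence must not push that sentence down the ranking
        model, kg, index, variants = _explanation_model()
        target = variants[1].key  # pathogenic with a high planted score
        base = explain(model, target, kg, index, top_n=50, seed=0)
        positive = [s for s in base if s.contribution > 0 and s.rule == "Variants in dbNSFP"]
        assert positive, "fixture must yield a positive dbNSFP sentence"
        text = positive[0].text
        rank_before = [s.text for s in base].index(text)
        boosted = XImpactTable({**DEFAULT_IMPACT.weights, "dbnsfp_score": 50.0})
        after = explain(model, target, kg, index, impact_table=boosted, top_n=50, seed=0)
        rank_after = [s.text for s in after].index(text)
        assert rank_after <= rank_before
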