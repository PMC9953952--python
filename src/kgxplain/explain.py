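"""Template-based explanation sentences ranked by X-Factor.

Each explanation rule (*X-Rule*) pairs a pattern over the explanation-mode
feature subgraph with a sentence template.  Matching a rule yields a *node
set* (the supporting evidence) plus slot values; rendering fills the template
from node payloads.  The relevance of a sentence (*X-Factor*) combines the
classifier's attribution for its supporting nodes (*X-Contribution*, signed,
positive = pathogenic) with a physician-assigned importance weight per node
type (*X-Impact*):

    X-Factor = sigmoid(X-Contribution x X-Impact)

Sentences are returned sorted by descending X-Factor, truncated to the top N.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import yaml

from .annotations import algorithm_class
from .classifier import (
    GraphHashModel,
    edge_contributions,
    node_contributions,
    predict,
)
from .features import FeatureGraph, VariantIndex, build_feature_graph
from .kg import KnowledgeGraph

__all__ = [
    "XRule",
    "XImpactTable",
    "ExplanationSentence",
    "DEFAULT_RULES",
    "DEFAULT_IMPACT",
    "x_factor",
    "match_rule",
    "render_sentence",
    "sentence_contribution",
    "explain",
    "load_explainer_config",
    "number_word",
]

# -- small English number-word helper (counts in rendered sentences) ----------

_UNITS = (
    "zero one two three four five six seven eight nine ten eleven twelve "
    "thirteen fourteen fifteen sixteen seventeen eighteen nineteen"
).split()
_TENS = "zero ten twenty thirty forty fifty sixty seventy eighty ninety".split()


def number_word(n: int) -> str:
    """English word for a nonnegative count below 1000 ('twenty-six')."""
    if n < 0 or n >= 1000:
        raise ValueError(f"count {n} out of supported range")
    if n < 20:
        return _UNITS[n]
    if n < 100:
        tens, unit = divmod(n, 10)
        return _TENS[tens] + (f"-{_UNITS[unit]}" if unit else "")
    hundreds, rest = divmod(n, 100)
    word = f"{_UNITS[hundreds]} hundred"
    return word + (f" {number_word(rest)}" if rest else "")


def _word_cap(n: int) -> str:
    w = number_word(n)
    return w[0].upper() + w[1:]


# -- X-Factor ------------------------------------------------------------------


def x_factor(contribution: float, impact: float) -> float:
    """sigmoid(contribution x impact); 0.5 at zero contribution or impact.

    Computed with the overflow-safe branch and clamped to the open unit
    interval so extreme products still yield a usable rank weight.
    """
    if impact < 0:
        raise ValueError(f"impact must be nonnegative, got {impact}")
    x = contribution * impact
    if x >= 0:
        f = 1.0 / (1.0 + math.exp(-x))
    else:
        e = math.exp(x)
        f = e / (1.0 + e)
    tiny = math.ulp(0.0)
    return min(max(f, tiny), 1.0 - math.ulp(1.0) / 2)


class XImpactTable:
    """Importance weight per node type, with a baseline for unlisted types."""

    def __init__(self, weights: dict[str, float], baseline: float = 0.5):
        for t, w in weights.items():
            if w < 0:
                raise ValueError(f"impact for {t!r} must be nonnegative")
        if baseline < 0:
            raise ValueError("baseline impact must be nonnegative")
        self.weights = dict(weights)
        self.baseline = baseline

    def get(self, node_type: str) -> float:
        return self.weights.get(node_type, self.baseline)


#: Default importance weights: database listing is what physicians check
#: first, so record nodes outrank raw scores and publications.
DEFAULT_IMPACT = XImpactTable(
    {
        "clinvar_record": 2.0,
        "cosmic_record": 1.5,
        "dbnsfp_score": 1.0,
        "publication": 1.0,
    },
    baseline=0.5,
)


@dataclass
class Match:
    slots: dict  # raw slot values
    support: frozenset  # node ids used as evidence


@dataclass
class XRule:
    """Declarative pattern + template for one explanation sentence family."""

    name: str
    template: str
    matcher: Callable[[FeatureGraph, dict], list[Match]]
    cardinality: str = "one_per_variant"  # or 'one_per_match'
    params: dict = field(default_factory=dict)


def match_rule(rule: XRule, fg: FeatureGraph, params: Optional[dict] = None) -> list[Match]:
    """All (maximal) matches of a rule's pattern on an explanation subgraph."""
    if fg.mode != "explanation":
        raise ValueError("explanation rules match on explanation-mode subgraphs")
    merged = dict(rule.params)
    if params:
        merged.update(params)
    return rule.matcher(fg, merged)


def render_sentence(rule: XRule, match: Match) -> str:
    """Fill the rule's template from a match's slot values."""
    try:
        return rule.template.format(**match.slots)
    except (KeyError, IndexError) as exc:
        raise ValueError(f"unbound template slot in rule {rule.name!r}: {exc}") from exc


def sentence_contribution(node_set: Sequence[str], node_contribs: dict) -> float:
    """Signed max-magnitude contribution over a matched node set (0 if empty)."""
    vals = [node_contribs.get(n, 0.0) for n in node_set]
    if not vals:
        return 0.0
    return max(vals, key=lambda v: (abs(v), v))


# -- the ten rules --------------------------------------------------------------

_SIG_PRIORITY = ("Pathogenic", "Likely_pathogenic", "Benign", "Likely_benign", "VUS")


def _sig_text(sig: str) -> str:
    return sig.replace("_", " ")


def _neighbor_views(fg: FeatureGraph) -> list[dict]:
    """Structured view of every neighbor: its records, fields and node ids."""
    out = []
    for nkey, dist in fg.neighbor_links:
        hub = fg.hub_id(nkey)
        recs = fg.records_of(hub)
        view = {"key": nkey, "distance": dist, "hub": hub}
        for rtype in ("clinvar_record", "cosmic_record"):
            rid = recs.get(rtype)
            if rid is None:
                view[rtype] = None
            else:
                view[rtype] = {
                    "id": rid,
                    "fields": fg.record_fields(rid),
                    "pubs": fg.record_publications(rid),
                }
        out.append(view)
    return out


def _target_records(fg: FeatureGraph) -> dict[str, str]:
    return fg.records_of(fg.target_hub_id)


def _residue(protein_change: Optional[str]) -> Optional[int]:
    """Residue number from an HGVS-p-like string ('p.R1861*' -> 1861)."""
    if not protein_change:
        return None
    digits = "".join(ch for ch in protein_change if ch.isdigit())
    return int(digits) if digits else None


def _match_neighbors_clinvar(fg: FeatureGraph, params: dict) -> list[Match]:
    views = [v for v in _neighbor_views(fg) if v["clinvar_record"]]
    if not views:
        return []
    consequences = Counter(
        v["clinvar_record"]["fields"].get("consequence") for v in views
    )
    modal, _ = max(consequences.items(), key=lambda kv: (kv[1], str(kv[0])))
    subset = [v for v in views if v["clinvar_record"]["fields"].get("consequence") == modal]
    sigs = {v["clinvar_record"]["fields"].get("clinical_significance") for v in subset}
    sig = next((s for s in _SIG_PRIORITY if s in sigs), None)
    if sig is None:
        return []
    n_sig = sum(
        1
        for v in subset
        if v["clinvar_record"]["fields"].get("clinical_significance") == sig
    )
    support = frozenset(v["clinvar_record"]["id"] for v in subset)
    slots = {
        "n_total": _word_cap(len(subset)),
        "consequence": str(modal).replace("_", " "),
        "n_sig": number_word(n_sig),
        "significance": sig,
    }
    return [Match(slots, support)]


def _match_outstanding(fg: FeatureGraph, params: dict) -> list[Match]:
    high = params.get("high_threshold", 0.70)
    moderate = params.get("moderate_threshold", 0.50)
    rid = _target_records(fg).get("dbnsfp_record")
    if rid is None:
        return []
    scores = fg.record_fields(rid)
    kept = sorted(
        ((alg, float(s)) for alg, s in scores.items() if float(s) >= moderate),
        key=lambda kv: (-kv[1], kv[0]),
    )
    if not kept:
        return []
    items = [
        f"{alg} is {'high' if s >= high else 'moderate'} ({s:.2f})" for alg, s in kept
    ]
    if len(items) == 1:
        listed = items[0]
    else:
        listed = ", ".join(items[:-1]) + ", and " + items[-1]
    support = frozenset(fg.field_node(rid, alg) for alg, _ in kept)
    return [Match({"listed": listed}, support)]


def _match_average(fg: FeatureGraph, params: dict) -> list[Match]:
    rid = _target_records(fg).get("dbnsfp_record")
    if rid is None:
        return []
    scores = fg.record_fields(rid)
    groups: dict[str, list[float]] = {"prediction": [], "conservation": []}
    for alg, s in scores.items():
        groups[algorithm_class(alg)].append(float(s))
    if not groups["prediction"] or not groups["conservation"]:
        return []
    slots = {
        "pred_avg": f"{sum(groups['prediction']) / len(groups['prediction']):.2f}",
        "n_pred": len(groups["prediction"]),
        "cons_avg": f"{sum(groups['conservation']) / len(groups['conservation']):.2f}",
        "n_cons": len(groups["conservation"]),
    }
    support = frozenset(fg.field_node(rid, alg) for alg in scores)
    return [Match(slots, support)]


def _match_same_residue(fg: FeatureGraph, params: dict) -> list[Match]:
    target_cosmic = _target_records(fg).get("cosmic_record")
    if target_cosmic is None:
        return []
    res = _residue(fg.record_fields(target_cosmic).get("protein_change"))
    if res is None:
        return []
    hits = []
    for v in _neighbor_views(fg):
        if not v["clinvar_record"] or not v["cosmic_record"]:
            continue
        if _residue(v["cosmic_record"]["fields"].get("protein_change")) == res:
            hits.append(v)
    if not hits:
        return []
    sigs = {v["clinvar_record"]["fields"].get("clinical_significance") for v in hits}
    sig = next(s for s in _SIG_PRIORITY if s in sigs)
    support = frozenset(
        nid
        for v in hits
        for nid in (v["clinvar_record"]["id"], v["cosmic_record"]["id"])
    )
    return [Match({"significance": sig}, support)]


def _match_neighbor_papers(fg: FeatureGraph, params: dict) -> list[Match]:
    reported, pmids, support = [], set(), set()
    for v in _neighbor_views(fg):
        pubs = []
        for rtype in ("clinvar_record", "cosmic_record"):
            if v[rtype]:
                pubs.extend(v[rtype]["pubs"])
        if pubs:
            reported.append(v)
            for pmid, _, pub_node in pubs:
                pmids.add(pmid)
                support.add(pub_node)
            support.update(v[rt]["id"] for rt in ("clinvar_record", "cosmic_record") if v[rt])
    if not reported:
        return []
    slots = {"n_variants": _word_cap(len(reported)), "n_papers": number_word(len(pmids))}
    return [Match(slots, frozenset(support))]


def _match_neighbor_cosmic(fg: FeatureGraph, params: dict) -> list[Match]:
    out = []
    for v in _neighbor_views(fg):
        rec = v["cosmic_record"]
        if rec is None:
            continue
        pc = rec["fields"].get("protein_change")
        if pc is None:
            continue
        support = frozenset({rec["id"], fg.field_node(rec["id"], "protein_change")})
        out.append(Match({"protein_change": pc}, support))
    return out


def _match_target_dbnsfp(fg: FeatureGraph, params: dict) -> list[Match]:
    rid = _target_records(fg).get("dbnsfp_record")
    if rid is None:
        return []
    out = []
    for alg, s in sorted(fg.record_fields(rid).items()):
        out.append(
            Match(
                {"score": f"{float(s):.2f}", "algorithm": alg},
                frozenset({fg.field_node(rid, alg)}),
            )
        )
    return out


def _match_target_reference(fg: FeatureGraph, params: dict) -> list[Match]:
    accessed = params.get("accessed_on", "2 December 2022")
    out = []
    recs = _target_records(fg)
    for rtype in ("clinvar_record", "cosmic_record"):
        rid = recs.get(rtype)
        if rid is None:
            continue
        for pmid, _, pub_node in fg.record_publications(rid):
            url = f"https://pubmed.ncbi.nlm.nih.gov/{pmid}/"
            out.append(Match({"url": url, "accessed": accessed}, frozenset({pub_node})))
    return out


def _match_target_clinvar(fg: FeatureGraph, params: dict) -> list[Match]:
    rid = _target_records(fg).get("clinvar_record")
    if rid is None:
        return []
    f = fg.record_fields(rid)
    sig = str(f.get("clinical_significance"))
    sig_text = "of uncertain significance" if sig == "VUS" else _sig_text(sig).lower()
    slots = {
        "significance": sig_text,
        "stars": int(f.get("review_stars", 0)),
        "n_submissions": int(f.get("n_submissions", 0)),
    }
    support = frozenset(
        {rid}
        | {
            fg.field_node(rid, p)
            for p in ("clinical_significance", "review_stars", "n_submissions")
            if fg.field_node(rid, p)
        }
    )
    return [Match(slots, support)]


def _match_variant_type(fg: FeatureGraph, params: dict) -> list[Match]:
    consequence = params.get("target_consequence")
    if consequence is None:
        rid = _target_records(fg).get("clinvar_record")
        if rid is not None:
            consequence = fg.record_fields(rid).get("consequence")
    if consequence is None:
        return []
    slots = {"consequence": str(consequence).replace("_", " ")}
    return [Match(slots, frozenset({fg.target_hub_id}))]


#: The ten rules, in table order (used for deterministic tie-breaking).
DEFAULT_RULES: tuple[XRule, ...] = (
    XRule(
        "Neighboring variants in ClinVar",
        "{n_total} neighboring variants are “{consequence}”, {n_sig} of "
        "which are registered as “{significance}” in ClinVar.",
        _match_neighbors_clinvar,
    ),
    XRule(
        "Outstanding algorithms in dbNSFP",
        "This variant has dbNSFP algorithms: {listed}.",
        _match_outstanding,
    ),
    XRule(
        "Average of algorithms in dbNSFP",
        "This variant has an average score of {pred_avg} for {n_pred} prediction "
        "algorithms, and {cons_avg} for {n_cons} conservation algorithms from dbNSFP.",
        _match_average,
    ),
    XRule(
        "Same amino acid variants",
        'Neighboring variants in the same base are registered as "{significance}" '
        "in ClinVar.",
        _match_same_residue,
    ),
    XRule(
        "Neighboring variant papers",
        "{n_variants} neighboring variants are reported in {n_papers} papers.",
        _match_neighbor_papers,
    ),
    XRule(
        "Variants in COSMIC",
        "A neighboring variant, {protein_change}, is registered in COSMIC.",
        _match_neighbor_cosmic,
        cardinality="one_per_match",
    ),
    XRule(
        "Variants in dbNSFP",
        "This variant has a score of {score} according to the {algorithm} "
        "algorithm of dbNSFP.",
        _match_target_dbnsfp,
        cardinality="one_per_match",
    ),
    XRule(
        "Variants reference",
        "This variant is explained in {url} (accessed on {accessed}).",
        _match_target_reference,
        cardinality="one_per_match",
    ),
    XRule(
        "Variants in ClinVar",
        "This variant is considered {significance} with {stars} stars in ClinVar, "
        "and the report has {n_submissions} submissions.",
        _match_target_clinvar,
    ),
    XRule(
        "Variants type",
        "This variant is a {consequence}.",
        _match_variant_type,
    ),
)

_RULE_ORDER = {r.name: i for i, r in enumerate(DEFAULT_RULES)}


@dataclass
class ExplanationSentence:
    text: str
    x_factor: float
    rule: str
    support: frozenset
    contribution: float = 0.0
    impact: float = 0.0


def explain(
    model: GraphHashModel,
    target: str,
    kg: KnowledgeGraph,
    index: VariantIndex,
    rules: Sequence[XRule] = DEFAULT_RULES,
    impact_table: XImpactTable = DEFAULT_IMPACT,
    top_n: int = 10,
    seed: int = 0,
    n_perturbations: Optional[int] = None,
) -> list[ExplanationSentence]:
    """Ranked explanation sentences for one variant.

    Builds the explanation-mode feature subgraph, scores it, attributes the
    score to edges and nodes, applies every rule to the subgraph, and returns
    the top ``top_n`` sentences sorted by descending X-Factor (ties broken by
    rule table order, then text).  Requires an explanation-mode model.
    """
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    if model.mode != "explanation":
        raise ValueError(
            "explanations require a model trained in explanation mode; "
            f"this model was trained in {model.mode!r} mode"
        )
    fg = build_feature_graph(target, kg, "explanation", index)
    econ = edge_contributions(model, fg, n_perturbations=n_perturbations, seed=seed)
    ncon = node_contributions(econ, fg, model.config.node_aggregation)

    tv = index.variant(target)
    sentences = []
    for rule in rules:
        params = {"target_consequence": tv.consequence}
        for m in match_rule(rule, fg, params):
            support = sorted(m.support)
            contrib = sentence_contribution(support, ncon)
            anchor = (
                max(support, key=lambda nid: (abs(ncon.get(nid, 0.0)), nid))
                if support
                else None
            )
            impact = (
                impact_table.get(fg.graph.nodes[anchor].node_type)
                if anchor is not None
                else impact_table.baseline
            )
            sentences.append(
                ExplanationSentence(
                    render_sentence(rule, m),
                    x_factor(contrib, impact),
                    rule.name,
                    m.support,
                    contrib,
                    impact,
                )
            )
    sentences.sort(key=lambda s: (-s.x_factor, _RULE_ORDER.get(s.rule, 99), s.text))
    return sentences[:top_n]


def load_explainer_config(path: str) -> tuple[tuple[XRule, ...], XImpactTable]:
    """Load impact weights and rule overrides from one YAML config file.

    Schema::

        impact:
          clinvar_record: 2.0
          baseline: 0.5
        rules:
          "Outstanding algorithms in dbNSFP":
            enabled: true
            template: "..."
            params: {high_threshold: 0.7}
    """
    with open(path, encoding="utf-8") as fh:
        blob = yaml.safe_load(fh) or {}
    impact_cfg = dict(blob.get("impact", {}))
    baseline = float(impact_cfg.pop("baseline", DEFAULT_IMPACT.baseline))
    weights = dict(DEFAULT_IMPACT.weights)
    weights.update({k: float(v) for k, v in impact_cfg.items()})
    impact = XImpactTable(weights, baseline)

    rules = []
    overrides = blob.get("rules", {})
    for rule in DEFAULT_RULES:
        o = overrides.get(rule.name, {})
        if not o.get("enabled", True):
            continue
        rules.append(
            XRule(
                rule.name,
                o.get("template", rule.template),
                rule.matcher,
                rule.cardinality,
                {**rule.params, **o.get("params", {})},
            )
        )
    return tuple(rules), impact
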