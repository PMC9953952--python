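"""Synthetic variant sets and annotation tables with a planted signal.

The generator emulates the statistical structure the classifier's features
assume, without any real genome data:

* variants are placed per gene with near-exponential gaps, so a realistic
  fraction has neighbors within the 100-base window;
* pathogenicity clusters along the sequence ("hotspots"): with probability
  ``hotspot_clustering`` a variant copies the label of its predecessor when
  that predecessor lies within 100 bases;
* dbNSFP rank scores are Beta-distributed with a class-dependent mean
  (pathogenic mean = benign mean + ``score_separation``);
* COSMIC sample counts are log-uniform, shifted up by
  ``cosmic_count_shift`` decades for pathogenic variants;
* ClinVar significance reflects the true label with a small noise rate, plus
  Likely_*/VUS records and a review-star distribution.

Setting ``score_separation``, ``hotspot_clustering`` and
``cosmic_count_shift`` to zero (``SimulationConfig.null``) removes every
planted signal: a classifier's chromosome-disjoint CV AUC should then be
indistinguishable from 0.5.
"""

from __future__ import annotations

import io
import json
import os
from dataclasses import asdict, dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from . import annotations as ann
from .features import Variant, VariantIndex
from .kg import canonical_variant_key

__all__ = ["SimulationConfig", "SimulatedDataset", "simulate", "planted_signal_report"]

_BASES = ("A", "C", "G", "T")
_AA = "ARNDCQEGHILKMFPSTWYV"
_CONSEQUENCES = ("missense_variant", "synonymous_variant", "stop_gained")
_CONSEQ_P = (0.7, 0.2, 0.1)
_STAR_P = (0.08, 0.12, 0.40, 0.30, 0.10)


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic dataset (all rates per variant)."""

    n_chromosomes: int = 10
    genes_per_chromosome: int = 5
    variants_per_gene: int = 40
    pathogenic_fraction: float = 0.5
    hotspot_clustering: float = 0.5
    score_separation: float = 0.3
    benign_score_mean: float = 0.35
    score_concentration: float = 10.0
    cosmic_count_shift: float = 1.0  # decades added to pathogenic counts
    clinvar_coverage: float = 0.9
    cosmic_coverage: float = 0.6
    dbnsfp_coverage: float = 0.95
    dbscsnv_coverage: float = 0.3
    significance_noise: float = 0.02
    exact_significance_prob: float = 0.7
    vus_prob: float = 0.1
    mean_gap: float = 60.0  # bases between consecutive variants in a gene
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "pathogenic_fraction", "hotspot_clustering", "clinvar_coverage",
            "cosmic_coverage", "dbnsfp_coverage", "dbscsnv_coverage",
            "significance_noise", "exact_significance_prob", "vus_prob",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if not 0.0 < self.pathogenic_fraction < 1.0:
            raise ValueError("pathogenic_fraction must be in (0, 1)")
        if self.score_separation < 0 or self.cosmic_count_shift < 0:
            raise ValueError("signal parameters must be nonnegative")
        if not 0 < self.benign_score_mean + self.score_separation < 1:
            raise ValueError("class score means must stay inside (0, 1)")
        if self.mean_gap < 1.0:
            raise ValueError("mean_gap < 1 base: variants denser than coordinates")

    @property
    def n_variants(self) -> int:
        return self.n_chromosomes * self.genes_per_chromosome * self.variants_per_gene

    @classmethod
    def null(cls, seed: int = 0, **overrides) -> "SimulationConfig":
        """A configuration with every planted signal removed."""
        return cls(
            score_separation=0.0,
            hotspot_clustering=0.0,
            cosmic_count_shift=0.0,
            seed=seed,
            **overrides,
        )


@dataclass
class SimulatedDataset:
    config: SimulationConfig
    variants: pd.DataFrame  # chrom pos ref alt gene consequence
    truth: pd.DataFrame  # key, label
    clinvar: pd.DataFrame
    cosmic: pd.DataFrame
    dbnsfp: pd.DataFrame
    dbscsnv: pd.DataFrame

    def variant_index(self) -> VariantIndex:
        return VariantIndex(
            Variant(r.chrom, int(r.pos), r.ref, r.alt, r.gene, r.consequence)
            for r in self.variants.itertuples()
        )

    def truth_labels(self) -> dict[str, str]:
        return dict(zip(self.truth["key"], self.truth["label"]))

    def load_records(self):
        """Round the tables through the documented TSV loaders."""
        def through(df, loader):
            buf = io.StringIO()
            df.to_csv(buf, sep="\t", index=False)
            buf.seek(0)
            return loader(buf)

        return (
            through(self.clinvar, ann.load_clinvar),
            through(self.cosmic, ann.load_cosmic),
            through(self.dbnsfp, ann.load_dbnsfp),
            through(self.dbscsnv, ann.load_dbscsnv),
        )

    def write(self, outdir: str) -> None:
        os.makedirs(outdir, exist_ok=True)
        for name in ("variants", "truth", "clinvar", "cosmic", "dbnsfp", "dbscsnv"):
            getattr(self, name).to_csv(
                os.path.join(outdir, f"{name}.tsv"), sep="\t", index=False
            )
        with open(os.path.join(outdir, "provenance.json"), "w", encoding="utf-8") as fh:
            json.dump({"config": asdict(self.config)}, fh, indent=2, sort_keys=True)

    @classmethod
    def read(cls, indir: str) -> "SimulatedDataset":
        with open(os.path.join(indir, "provenance.json"), encoding="utf-8") as fh:
            config = SimulationConfig(**json.load(fh)["config"])
        frames = {
            name: pd.read_csv(
                os.path.join(indir, f"{name}.tsv"), sep="\t", dtype=str,
                keep_default_na=False,
            )
            for name in ("variants", "truth", "clinvar", "cosmic", "dbnsfp", "dbscsnv")
        }
        return cls(config, **frames)


def _beta_score(rng, mean: float, concentration: float) -> float:
    a = mean * concentration
    b = (1.0 - mean) * concentration
    return float(rng.beta(a, b))


def simulate(config: SimulationConfig) -> SimulatedDataset:
    """Generate one dataset; byte-identical TSVs for a fixed config."""
    rng = np.random.default_rng(config.seed)
    rows, truth_rows = [], []
    clinvar_rows, cosmic_rows, dbnsfp_rows, dbscsnv_rows = [], [], [], []
    pmid_counter = 8_000_000
    p_mean = config.benign_score_mean + config.score_separation
    b_mean = config.benign_score_mean

    for ci in range(config.n_chromosomes):
        chrom = str(ci + 1)
        for gi in range(config.genes_per_chromosome):
            gene = f"GENE{ci + 1}_{gi + 1}"
            gene_start = 1_000_000 * (gi + 1)
            pos = gene_start
            prev_pos: Optional[int] = None
            prev_label: Optional[int] = None
            for _ in range(config.variants_per_gene):
                pos += 1 + int(rng.exponential(config.mean_gap))
                if (
                    prev_pos is not None
                    and pos - prev_pos <= 100
                    and rng.random() < config.hotspot_clustering
                ):
                    label = prev_label
                else:
                    label = int(rng.random() < config.pathogenic_fraction)
                prev_pos, prev_label = pos, label

                ref, alt = rng.choice(len(_BASES), size=2, replace=False)
                ref, alt = _BASES[ref], _BASES[alt]
                consequence = _CONSEQUENCES[
                    int(rng.choice(len(_CONSEQUENCES), p=_CONSEQ_P))
                ]
                key = canonical_variant_key(chrom, pos, ref, alt)
                rows.append((chrom, pos, ref, alt, gene, consequence))
                truth_rows.append((key, "pathogenic" if label else "benign"))

                if rng.random() < config.clinvar_coverage:
                    reported = label
                    if rng.random() < config.significance_noise:
                        reported = 1 - reported
                    u = rng.random()
                    if u < config.exact_significance_prob:
                        sig = "Pathogenic" if reported else "Benign"
                    elif u < config.exact_significance_prob + config.vus_prob:
                        sig = "VUS"
                    else:
                        sig = "Likely_pathogenic" if reported else "Likely_benign"
                    stars = int(rng.choice(5, p=_STAR_P))
                    pubs = []
                    for _ in range(int(rng.poisson(0.8))):
                        pmid_counter += 1
                        publisher = ann.DEFAULT_PUBLISHERS[
                            int(rng.choice(len(ann.DEFAULT_PUBLISHERS)))
                        ]
                        pubs.append(f"{pmid_counter}:{publisher}")
                    clinvar_rows.append(
                        (
                            chrom, pos, ref, alt, gene, consequence, sig, stars,
                            int(rng.integers(2005, 2021)),
                            int(rng.integers(1, 11)),
                            ";".join(pubs),
                        )
                    )

                if rng.random() < config.cosmic_coverage:
                    residue = (pos - gene_start) // 3 + 1
                    aa_from = _AA[int(rng.choice(len(_AA)))]
                    aa_to = "*" if rng.random() < 0.05 else _AA[int(rng.choice(len(_AA)))]
                    exponent = rng.uniform(0, 2) + label * config.cosmic_count_shift
                    sample_count = max(1, int(round(10**exponent)))
                    pubs = []
                    for _ in range(int(rng.poisson(0.5))):
                        pmid_counter += 1
                        pubs.append(str(pmid_counter))
                    cosmic_rows.append(
                        (
                            chrom, pos, ref, alt, gene,
                            f"p.{aa_from}{residue}{aa_to}",
                            sample_count, ";".join(pubs),
                        )
                    )

                if rng.random() < config.dbnsfp_coverage:
                    mean = p_mean if label else b_mean
                    scores = [
                        f"{_beta_score(rng, mean, config.score_concentration):.6f}"
                        for _ in ann.ALL_ALGORITHMS
                    ]
                    dbnsfp_rows.append((chrom, pos, ref, alt, *scores))

                if rng.random() < config.dbscsnv_coverage:
                    mean = p_mean if label else b_mean
                    dbscsnv_rows.append(
                        (
                            chrom, pos, ref, alt,
                            f"{_beta_score(rng, mean, config.score_concentration):.6f}",
                            f"{_beta_score(rng, mean, config.score_concentration):.6f}",
                        )
                    )

    variants = pd.DataFrame(
        rows, columns=["chrom", "pos", "ref", "alt", "gene", "consequence"]
    )
    truth = pd.DataFrame(truth_rows, columns=["key", "label"])
    clinvar = pd.DataFrame(
        clinvar_rows,
        columns=[
            "chrom", "pos", "ref", "alt", "gene", "consequence",
            "clinical_significance", "review_stars", "last_update_year",
            "n_submissions", "publications",
        ],
    )
    cosmic = pd.DataFrame(
        cosmic_rows,
        columns=["chrom", "pos", "ref", "alt", "gene", "protein_change",
                 "sample_count", "publications"],
    )
    dbnsfp = pd.DataFrame(
        dbnsfp_rows, columns=["chrom", "pos", "ref", "alt", *ann.ALL_ALGORITHMS]
    )
    dbscsnv = pd.DataFrame(
        dbscsnv_rows, columns=["chrom", "pos", "ref", "alt", "ada_score", "rf_score"]
    )
    return SimulatedDataset(config, variants, truth, clinvar, cosmic, dbnsfp, dbscsnv)


def planted_signal_report(dataset: SimulatedDataset) -> dict:
    """Realized class separation per feature family.

    Reports the mean dbNSFP score gap between classes, the nearest-neighbor
    label concordance (against the no-clustering base rate), and per-source
    annotation coverage — the quantities downstream signal-recovery checks
    condition on.
    """
    truth = dataset.truth_labels()
    cfg = dataset.config

    dbn = dataset.dbnsfp
    gaps = None
    if len(dbn):
        keys = [
            canonical_variant_key(r.chrom, int(r.pos), r.ref, r.alt)
            for r in dbn.itertuples()
        ]
        labels = np.array([truth[k] == "pathogenic" for k in keys])
        means = dbn[list(ann.ALL_ALGORITHMS)].astype(float).to_numpy().mean(axis=1)
        if labels.any() and (~labels).any():
            gaps = float(means[labels].mean() - means[~labels].mean())

    index = dataset.variant_index()
    from .features import neighbors_within

    same = total = 0
    for key, label in truth.items():
        nbs = neighbors_within(key, index)
        if not nbs:
            continue
        total += 1
        if truth[nbs[0][0]] == label:
            same += 1
    p = cfg.pathogenic_fraction
    report = {
        "n_variants": len(truth),
        "realized_score_gap": gaps,
        "neighbor_label_concordance": (same / total) if total else None,
        "concordance_base_rate": p * p + (1 - p) * (1 - p),
        "fraction_with_neighbor": total / len(truth) if truth else 0.0,
        "coverage": {
            "clinvar": len(dataset.clinvar) / len(truth),
            "cosmic": len(dataset.cosmic) / len(truth),
            "dbnsfp": len(dataset.dbnsfp) / len(truth),
            "dbscsnv": len(dataset.dbscsnv) / len(truth),
        },
    }
    return report
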