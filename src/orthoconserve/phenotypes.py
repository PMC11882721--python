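"""Phenotype enrichment of worm orthologs against the worm genome.

Each phenotype term yields a 2x2 table comparing the annotation rate in
a worm gene set against the protein-coding genome, tested through the
expected-count dispatch rule (Fisher below the cutoff, Yates-corrected
chi-squared otherwise).  By default the genome row *includes* the gene
set (overlapping comparison, so the genome proportion is the same across
sensitivity reruns); ``disjoint=True`` gives the cleaner disjoint
comparison.  The reference-first orientation means an odds ratio below 1
indicates enrichment in the gene set.

``exclusion_sensitivity`` reruns the analysis with a gene family removed
from the set (the universe is unchanged) and reports the terms whose
significance status flips — the divergent chemoreceptor-family check.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .contingency import select_test
from .exceptions import ValidationError

__all__ = [
    "PhenotypeAnnotation",
    "PhenotypePanel",
    "annotation_index",
    "phenotype_contingency",
    "enrich",
    "exclusion_sensitivity",
]

SOCIAL_TERMS = (
    "social feeding",
    "solitary feeding",
    "bordering",
    "non-bordering",
    "pheromone production",
    "pheromone sensation",
    "pheromone behavioral response",
)
ESSENTIAL_TERMS = (
    "lethal",
    "embryonic lethal",
    "larval lethal",
    "sterile",
    "sterile progeny",
)


@dataclass(frozen=True)
class PhenotypeAnnotation:
    worm_gene: str
    phenotype: str
    evidence: str


@dataclass(frozen=True)
class PhenotypePanel:
    """Term lists analysed per block: social behaviour and fitness."""

    social: tuple[str, ...] = SOCIAL_TERMS
    essential: tuple[str, ...] = ESSENTIAL_TERMS

    def __post_init__(self):
        if set(self.social) & set(self.essential):
            raise ValidationError("social and essential term lists must be disjoint")

    @property
    def vocabulary(self) -> tuple[str, ...]:
        return self.social + self.essential

    @classmethod
    def from_yaml(cls, path) -> "PhenotypePanel":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(
            social=tuple(data.get("social", SOCIAL_TERMS)),
            essential=tuple(data.get("essential", ESSENTIAL_TERMS)),
        )


def annotation_index(annotations: Iterable[PhenotypeAnnotation]) -> dict[str, frozenset[str]]:
    """Map phenotype term -> set of annotated genes (evidence-agnostic)."""
    idx: dict[str, set[str]] = {}
    for a in annotations:
        idx.setdefault(a.phenotype, set()).add(a.worm_gene)
    return {term: frozenset(genes) for term, genes in idx.items()}


def phenotype_contingency(
    gene_set: Iterable[str],
    phenotype: str,
    universe: Iterable[str],
    annotations,
    disjoint: bool = False,
) -> np.ndarray:
    """Build the 2x2 table (genome row first, gene set second).

    ``annotations`` may be raw annotations or an :func:`annotation_index`.
    A gene is annotated if it carries the term under any evidence type.
    """
    genes = frozenset(gene_set)
    uni = frozenset(universe)
    if not genes:
        raise ValidationError("gene set is empty")
    if not genes <= uni:
        raise ValidationError("gene set is not contained in the universe")
    idx = annotations if isinstance(annotations, dict) else annotation_index(annotations)
    annotated = idx.get(phenotype, frozenset()) & uni
    genome = uni - genes if disjoint else uni
    a = len(annotated & genome)
    c = len(annotated & genes)
    return np.array([[a, len(genome) - a], [c, len(genes) - c]])


def enrich(
    gene_set: Iterable[str],
    terms: Sequence[str],
    universe: Iterable[str],
    annotations,
    threshold: float = 10.0,
    disjoint: bool = False,
    block: Optional[str] = None,
) -> pd.DataFrame:
    """Per-term contingency tests for a list of phenotype terms.

    Returns a frame with the genome and set proportions, odds ratio with
    95% interval (Fisher path), p-value and the method dispatched to.
    """
    genes = frozenset(gene_set)
    uni = frozenset(universe)
    idx = annotations if isinstance(annotations, dict) else annotation_index(annotations)
    rows = []
    for term in terms:
        table = phenotype_contingency(genes, term, uni, idx, disjoint=disjoint)
        res = select_test(table, threshold=threshold)
        (a, b), (c, d) = table
        rows.append(
            {
                "block": block,
                "term": term,
                "n_genome": int(a + b),
                "k_genome": int(a),
                "prop_genome": a / (a + b),
                "n_set": int(c + d),
                "k_set": int(c),
                "prop_set": c / (c + d),
                "odds_ratio": res.odds_ratio,
                "ci_low": res.ci_low,
                "ci_high": res.ci_high,
                "p_value": res.p_value,
                "method": res.method,
                "expected_min": res.expected_min,
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "block",
            "term",
            "n_genome",
            "k_genome",
            "prop_genome",
            "n_set",
            "k_set",
            "prop_set",
            "odds_ratio",
            "ci_low",
            "ci_high",
            "p_value",
            "method",
            "expected_min",
        ],
    )
    if block is None:
        df = df.drop(columns=["block"])
    return df


def exclusion_sensitivity(
    gene_set: Iterable[str],
    family: Iterable[str],
    terms: Sequence[str],
    universe: Iterable[str],
    annotations,
    threshold: float = 10.0,
    alpha: float = 0.05,
    disjoint: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame, list[str]]:
    """Rerun enrichment with a gene family removed from the set.

    Returns (including-family table, excluding-family table, list of terms
    whose significance status at ``alpha`` changed).  The universe is left
    unchanged; removing the whole analysis set is an error.
    """
    genes = frozenset(gene_set)
    fam = frozenset(family)
    reduced = genes - fam
    if not reduced:
        raise ValidationError("family removal leaves an empty analysis set")
    with_fam = enrich(genes, terms, universe, annotations, threshold=threshold, disjoint=disjoint)
    without_fam = enrich(
        reduced, terms, universe, annotations, threshold=threshold, disjoint=disjoint
    )
    flipped = [
        term
        for term, p1, p2 in zip(with_fam["term"], with_fam["p_value"], without_fam["p_value"])
        if (p1 < alpha) != (p2 < alpha)
    ]
    return with_fam, without_fam, flipped
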