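"""Stepwise human -> C. elegans ortholog resolution.

Resolution proceeds through three evidence tiers per human gene:
curated assertions from an Ensembl-Compara-style export, then a
WormBase-style export, then BLASTP hits of the gene's largest protein
product filtered through a four-part counterpart rule:

1. query and subject protein lengths differ by at most 100 residues;
2. the best hit E-value is below 1e-4 (strict);
3. at least one HSP shows >= 20% identity over >= 50 aligned residues;
4. the same worm gene is also hit by the established orthologs of at
   least three other species (corroboration).

A human gene is *conserved* iff at least one tier yields an assertion;
higher tiers shadow lower ones.  Worm orthologs are subsequently grouped
per source human gene, merging groups that share a worm gene (so genes
with a common ortholog form a single group), which is the unit used by
the cross-species interaction analysis.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from .exceptions import ValidationError

__all__ = [
    "GeneRecord",
    "OrthologAssertion",
    "BlastHit",
    "CounterpartCriteria",
    "CounterpartDecision",
    "OrthologyMap",
    "OrthologGroup",
    "evaluate_counterpart",
    "hits_for_largest_transcript",
    "resolve_orthologs",
    "filter_protein_coding",
    "build_groups",
]

BIOTYPES = ("protein_coding", "pseudogene", "other")
SOURCES = ("ensembl", "wormbase", "blastp")


@dataclass(frozen=True)
class GeneRecord:
    gene_id: str
    symbol: str
    biotype: str
    species: str

    def __post_init__(self):
        if self.biotype not in BIOTYPES:
            raise ValidationError(f"unknown biotype {self.biotype!r}")


@dataclass(frozen=True)
class OrthologAssertion:
    human_gene: str
    worm_gene: str
    source: str

    def __post_init__(self):
        if self.source not in SOURCES:
            raise ValidationError(f"unknown assertion source {self.source!r}")


@dataclass(frozen=True)
class BlastHit:
    """One tabular BLASTP HSP (outfmt-6 dialect plus qlen/slen)."""

    query_id: str
    subject_id: str
    percent_identity: float
    alignment_length: int
    mismatches: int
    gap_opens: int
    qstart: int
    qend: int
    sstart: int
    send: int
    e_value: float
    bit_score: float
    query_length: int
    subject_length: int

    def __post_init__(self):
        if not 0 <= self.percent_identity <= 100:
            raise ValidationError("percent_identity outside [0, 100]")
        if self.alignment_length < 1:
            raise ValidationError("alignment_length must be >= 1")
        if self.e_value < 0:
            raise ValidationError("e_value must be >= 0")
        if self.query_length < 1 or self.subject_length < 1:
            raise ValidationError("sequence lengths must be >= 1")


@dataclass(frozen=True)
class CounterpartCriteria:
    """Thresholds of the four-part BLASTP counterpart rule."""

    max_length_diff: float = 100.0
    max_e_value: float = 1e-4
    min_identity_pct: float = 20.0
    min_segment_length: float = 50.0
    min_corroborating_species: int = 3

    def __post_init__(self):
        for name in (
            "max_length_diff",
            "max_e_value",
            "min_identity_pct",
            "min_segment_length",
            "min_corroborating_species",
        ):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be strictly positive")


@dataclass(frozen=True)
class CounterpartDecision:
    worm_gene: str
    accepted: bool
    failed_criteria: tuple[int, ...] = ()


class OrthologyMap:
    """Many-to-many human/worm mapping with per-assertion provenance."""

    def __init__(self, assertions: Iterable[OrthologAssertion], step_counts: Optional[dict] = None):
        self.assertions: tuple[OrthologAssertion, ...] = tuple(
            dict.fromkeys(assertions)  # dedupe, keep order
        )
        self.step_counts = dict(step_counts or {})
        self._by_human: dict[str, list[OrthologAssertion]] = defaultdict(list)
        for a in self.assertions:
            self._by_human[a.human_gene].append(a)

    @property
    def conserved_human_genes(self) -> frozenset[str]:
        return frozenset(self._by_human)

    @property
    def worm_orthologs(self) -> frozenset[str]:
        return frozenset(a.worm_gene for a in self.assertions)

    def orthologs_of(self, human_gene: str) -> frozenset[str]:
        return frozenset(a.worm_gene for a in self._by_human.get(human_gene, ()))

    def __len__(self) -> int:
        return len(self.assertions)

    def __iter__(self):
        return iter(self.assertions)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            [(a.human_gene, a.worm_gene, a.source) for a in self.assertions],
            columns=["human_gene", "worm_gene", "source"],
        )


@dataclass(frozen=True)
class OrthologGroup:
    group_id: str
    human_genes: frozenset[str]
    worm_genes: frozenset[str]


def hits_for_largest_transcript(hits: Sequence[BlastHit]) -> list[BlastHit]:
    """Restrict hits to the query with the longest protein product.

    When a human gene was queried with several products, the longest one
    is the relevant BLAST query; ties break to the lexicographically
    smallest query id so the choice is deterministic.
    """
    if not hits:
        return []
    best = min(hits, key=lambda h: (-h.query_length, h.query_id))
    return [h for h in hits if h.query_id == best.query_id]


def evaluate_counterpart(
    hits: Sequence[BlastHit],
    corroboration: Mapping[str, frozenset[str] | set[str]],
    criteria: CounterpartCriteria = CounterpartCriteria(),
) -> dict[str, CounterpartDecision]:
    """Apply the four counterpart criteria per candidate worm gene.

    ``hits`` are the HSPs of one human gene's largest-transcript product;
    ``corroboration`` maps species tag -> worm genes hit by that species'
    established ortholog of the same human gene.  A candidate is accepted
    iff all four criteria hold; rejections list the 1-based indices of the
    failed criteria.
    """
    if not hits:
        raise ValidationError("evaluate_counterpart requires at least one hit")
    by_subject: dict[str, list[BlastHit]] = defaultdict(list)
    for h in hits:
        by_subject[h.subject_id].append(h)

    decisions: dict[str, CounterpartDecision] = {}
    for subject, shits in by_subject.items():
        failed: list[int] = []
        if not any(
            abs(h.query_length - h.subject_length) <= criteria.max_length_diff for h in shits
        ):
            failed.append(1)
        if not min(h.e_value for h in shits) < criteria.max_e_value:
            failed.append(2)
        # per-HSP conjunction: one HSP must satisfy both identity and length
        if not any(
            h.percent_identity >= criteria.min_identity_pct
            and h.alignment_length >= criteria.min_segment_length
            for h in shits
        ):
            failed.append(3)
        n_species = sum(1 for genes in corroboration.values() if subject in genes)
        if n_species < criteria.min_corroborating_species:
            failed.append(4)
        decisions[subject] = CounterpartDecision(
            worm_gene=subject, accepted=not failed, failed_criteria=tuple(failed)
        )
    return decisions


def resolve_orthologs(
    focal_genes: Sequence[str],
    ensembl: Iterable[OrthologAssertion],
    wormbase: Iterable[OrthologAssertion],
    blast_accepted: Iterable[OrthologAssertion] = (),
    human_universe: Optional[Iterable[str] | frozenset[str]] = None,
) -> OrthologyMap:
    """Stepwise resolution: ensembl, else wormbase, else accepted BLASTP.

    Returns an :class:`OrthologyMap` restricted to ``focal_genes`` whose
    ``step_counts`` record how many genes each tier resolved (and how many
    remained non-conserved).
    """
    if human_universe is not None:
        universe = frozenset(human_universe)
        missing = [g for g in focal_genes if g not in universe]
        if missing:
            raise ValidationError(
                f"focal genes absent from human universe: {sorted(missing)[:5]}"
            )
    if len(set(focal_genes)) != len(focal_genes):
        raise ValidationError("focal gene list contains duplicates")

    tiers = {
        "ensembl": defaultdict(list),
        "wormbase": defaultdict(list),
        "blastp": defaultdict(list),
    }
    for name, source in (("ensembl", ensembl), ("wormbase", wormbase), ("blastp", blast_accepted)):
        for a in source:
            tiers[name][a.human_gene].append(a)

    assertions: list[OrthologAssertion] = []
    counts = {"ensembl": 0, "wormbase": 0, "blastp": 0, "non_conserved": 0}
    for gene in focal_genes:
        for tier in ("ensembl", "wormbase", "blastp"):
            if tiers[tier].get(gene):
                assertions.extend(
                    OrthologAssertion(gene, a.worm_gene, tier) for a in tiers[tier][gene]
                )
                counts[tier] += 1
                break
        else:
            counts["non_conserved"] += 1
    counts["conserved"] = len(focal_genes) - counts["non_conserved"]
    counts["focal_size"] = len(focal_genes)
    return OrthologyMap(assertions, step_counts=counts)


def filter_protein_coding(
    omap: OrthologyMap, worm_universe: Iterable[GeneRecord]
) -> tuple[frozenset[str], frozenset[str]]:
    """Drop pseudogene orthologs from the worm-side analysis set.

    Returns (retained protein-coding orthologs, excluded pseudogenes).
    Human conservation status is unaffected: a gene whose only orthologs
    are pseudogenes still counts as conserved.
    """
    biotype = {g.gene_id: g.biotype for g in worm_universe}
    orthologs = omap.worm_orthologs
    missing = [w for w in orthologs if w not in biotype]
    if missing:
        raise ValidationError(f"worm orthologs absent from worm universe: {sorted(missing)[:5]}")
    pseudo = frozenset(w for w in orthologs if biotype[w] == "pseudogene")
    return orthologs - pseudo, pseudo


def build_groups(
    omap: OrthologyMap, symbols: Optional[Mapping[str, str]] = None
) -> list[OrthologGroup]:
    """Group worm orthologs per source human gene, merging shared orthologs.

    Starts from one group per conserved human gene and merges any two
    groups sharing a worm gene, to a fixed point (union-find), so the
    result partitions the worm ortholog set.  Group ids join the sorted
    human symbols (gene ids when no symbol map is given) with "+".
    """
    parent: dict[str, str] = {}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x: str, y: str) -> None:
        rx, ry = find(x), find(y)
        if rx != ry:
            parent[max(rx, ry)] = min(rx, ry)

    humans = sorted(omap.conserved_human_genes)
    for h in humans:
        parent[h] = h
    worm_owner: dict[str, str] = {}
    for h in humans:
        for w in sorted(omap.orthologs_of(h)):
            if w in worm_owner:
                union(h, worm_owner[w])
            else:
                worm_owner[w] = h

    members: dict[str, list[str]] = defaultdict(list)
    for h in humans:
        members[find(h)].append(h)

    groups = []
    for root, hs in members.items():
        worm = frozenset().union(*(omap.orthologs_of(h) for h in hs))
        names = sorted(symbols.get(h, h) if symbols else h for h in hs)
        groups.append(
            OrthologGroup(
                group_id="+".join(names),
                human_genes=frozenset(hs),
                worm_genes=worm,
            )
        )
    groups.sort(key=lambda g: g.group_id)
    return groups
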