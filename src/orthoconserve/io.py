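"""Readers and writers for the plain-text exchange formats.

All inputs are TSV: gene universes (gene_id, symbol, biotype), ortholog
assertion exports (human_gene, worm_gene), BLASTP tabular output
(outfmt-6 columns plus qlen and slen), corroboration tables
(species, worm_gene), phenotype annotations (worm_gene, phenotype,
evidence) and undirected edge lists (gene_a, gene_b[, interaction_type]).
"""

from __future__ import annotations

import logging
from typing import Iterable, Optional, Sequence

import pandas as pd

from .exceptions import FormatError, ValidationError
from .orthology import BIOTYPES, BlastHit, GeneRecord, OrthologAssertion

logger = logging.getLogger("orthoconserve")

__all__ = [
    "parse_gene_table",
    "parse_ortholog_table",
    "parse_blast_tabular",
    "parse_corroboration",
    "load_annotations",
    "write_orthology_map",
    "write_groups",
]

BLAST_COLUMNS = [
    "query_id",
    "subject_id",
    "percent_identity",
    "alignment_length",
    "mismatches",
    "gap_opens",
    "qstart",
    "qend",
    "sstart",
    "send",
    "e_value",
    "bit_score",
    "query_length",
    "subject_length",
]


def _read_tsv(path, required: Sequence[str]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: file is empty (expected a header line)")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    return df


def parse_gene_table(path, species: str) -> list[GeneRecord]:
    """Read a gene universe TSV (gene_id, symbol, biotype).

    Unknown biotypes are mapped to "other" with a logged warning;
    duplicate gene ids are a validation error.
    """
    df = _read_tsv(path, ["gene_id", "symbol", "biotype"])
    dup = df["gene_id"].duplicated()
    if dup.any():
        raise ValidationError(
            f"{path}: duplicate gene_id(s) {sorted(df.loc[dup, 'gene_id'].unique())[:5]}"
        )
    unknown = ~df["biotype"].isin(BIOTYPES)
    if unknown.any():
        logger.warning(
            "%s: %d record(s) with unknown biotype mapped to 'other'", path, int(unknown.sum())
        )
        df.loc[unknown, "biotype"] = "other"
    return [
        GeneRecord(gene_id=r.gene_id, symbol=r.symbol, biotype=r.biotype, species=species)
        for r in df.itertuples(index=False)
    ]


def parse_ortholog_table(
    path,
    source: str,
    human_universe: Optional[frozenset[str] | set[str]] = None,
    worm_universe: Optional[frozenset[str] | set[str]] = None,
) -> list[OrthologAssertion]:
    """Read an ortholog assertion TSV (human_gene, worm_gene).

    Every row is stamped with ``source``; duplicated (human, worm) pairs
    collapse to one assertion.  When universes are supplied, ids appearing
    in the wrong column (cross-contamination) raise a validation error.
    """
    df = _read_tsv(path, ["human_gene", "worm_gene"])
    if (df["human_gene"] == df["worm_gene"]).any():
        raise ValidationError(f"{path}: self-referential ortholog row")
    if human_universe is not None:
        bad = df["worm_gene"].isin(human_universe)
        if bad.any():
            raise ValidationError(
                f"{path}: human id(s) in worm column: {sorted(df.loc[bad, 'worm_gene'])[:5]}"
            )
    if worm_universe is not None:
        bad = df["human_gene"].isin(worm_universe)
        if bad.any():
            raise ValidationError(
                f"{path}: worm id(s) in human column: {sorted(df.loc[bad, 'human_gene'])[:5]}"
            )
    seen: dict[tuple[str, str], None] = {}
    for r in df.itertuples(index=False):
        seen.setdefault((r.human_gene, r.worm_gene))
    return [OrthologAssertion(h, w, source) for h, w in seen]


def parse_blast_tabular(path) -> list[BlastHit]:
    """Read BLASTP tabular output: 12 outfmt-6 columns plus qlen, slen."""
    hits: list[BlastHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != len(BLAST_COLUMNS):
                raise FormatError(
                    f"{path}: line {lineno}: expected {len(BLAST_COLUMNS)} columns, got {len(parts)}"
                )
            try:
                hits.append(
                    BlastHit(
                        query_id=parts[0],
                        subject_id=parts[1],
                        percent_identity=float(parts[2]),
                        alignment_length=int(parts[3]),
                        mismatches=int(parts[4]),
                        gap_opens=int(parts[5]),
                        qstart=int(parts[6]),
                        qend=int(parts[7]),
                        sstart=int(parts[8]),
                        send=int(parts[9]),
                        e_value=float(parts[10]),
                        bit_score=float(parts[11]),
                        query_length=int(parts[12]),
                        subject_length=int(parts[13]),
                    )
                )
            except ValueError as exc:
                raise FormatError(f"{path}: line {lineno}: {exc}") from exc
    return hits


def parse_corroboration(path) -> dict[str, frozenset[str]]:
    """Read a corroboration TSV (species, worm_gene) into species -> genes."""
    df = _read_tsv(path, ["species", "worm_gene"])
    return {
        species: frozenset(sub["worm_gene"])
        for species, sub in df.groupby("species", sort=True)
    }


def load_annotations(path, vocabulary: Iterable[str]):
    """Read phenotype annotations, dropping rows outside ``vocabulary``.

    Returns a list of :class:`~orthoconserve.phenotypes.PhenotypeAnnotation`;
    the number of dropped out-of-vocabulary rows is logged.
    """
    from .phenotypes import PhenotypeAnnotation

    vocab = frozenset(vocabulary)
    df = _read_tsv(path, ["worm_gene", "phenotype", "evidence"])
    keep = df["phenotype"].isin(vocab)
    dropped = int((~keep).sum())
    if dropped:
        logger.info("%s: dropped %d annotation(s) outside vocabulary", path, dropped)
    seen: dict[tuple[str, str, str], None] = {}
    for r in df.loc[keep].itertuples(index=False):
        seen.setdefault((r.worm_gene, r.phenotype, r.evidence))
    return [PhenotypeAnnotation(g, p, e) for g, p, e in seen]


def write_orthology_map(omap, path) -> None:
    omap.to_frame().to_csv(path, sep="\t", index=False)


def write_groups(groups, path) -> None:
    pd.DataFrame(
        [
            (g.group_id, ",".join(sorted(g.human_genes)), ",".join(sorted(g.worm_genes)))
            for g in groups
        ],
        columns=["group_id", "human_genes", "worm_genes"],
    ).to_csv(path, sep="\t", index=False)
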