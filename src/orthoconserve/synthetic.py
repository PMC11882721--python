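"""Synthetic paired-species worlds with known ground truth.

The generator emulates every input the pipeline consumes — two gene
universes, tiered ortholog evidence (curated assertions plus BLASTP
tabular hits with corroboration), phenotype annotations and interaction
networks — with planted parameters (conservation rates, one-to-many
ortholog counts, phenotype risk ratios, edge densities and a
cross-species edge-conservation rate) so each stage can be checked
against the truth without any external download.

Two entry points:

* :func:`generate_world` draws a world at the configured rates,
  reproducibly for a fixed seed.  BLAST decoy hits are constructed to
  violate exactly one counterpart criterion each, so the filter's
  per-criterion diagnostics are testable.
* :func:`benchmark_fixture` builds one deterministic world calibrated to the
  benchmark study conditions: a 69-gene focal set with 50 conserved
  (35 curated-primary, 13 curated-secondary, 2 via BLASTP), 70 worm
  orthologs of which 4 are pseudogenes, 49 ortholog groups, ten
  pre-baked random sets with conservation counts
  (44, 51, 53, 47, 41, 49, 50, 51, 44, 50), a human network with 133
  within-set interactions of which exactly 9 are mirrored among 44 worm
  group-pair interactions, and phenotype annotations whose enrichment
  reproduces the benchmark odds ratios.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .interactions import InteractionNetwork
from .orthology import (
    BlastHit,
    CounterpartCriteria,
    GeneRecord,
    OrthologAssertion,
    OrthologyMap,
    evaluate_counterpart,
    hits_for_largest_transcript,
    resolve_orthologs,
)
from .phenotypes import PhenotypeAnnotation

__all__ = ["SyntheticWorldConfig", "SyntheticWorld", "generate_world", "benchmark_fixture"]

SPECIES_POOL = (
    "M. musculus",
    "R. norvegicus",
    "D. rerio",
    "D. melanogaster",
    "X. tropicalis",
    "S. cerevisiae",
)

DEFAULT_BASE_RATES = {
    "lethal": 0.09,
    "embryonic lethal": 0.15,
    "larval lethal": 0.04,
    "sterile": 0.12,
    "sterile progeny": 0.04,
}
# observed set-to-genome rate ratios of the benchmark study conditions
DEFAULT_RISK_RATIOS = {
    "lethal": 1.9,
    "embryonic lethal": 1.4,
    "larval lethal": 1.1,
    "sterile": 1.5,
    "sterile progeny": 0.5,
}


@dataclass(frozen=True)
class SyntheticWorldConfig:
    seed: int = 0
    n_human: int = 20310
    n_worm: int = 19985  # protein-coding worm genes; pseudogenes are extra
    worm_pseudogene_rate: float = 0.08
    focal_size: int = 69
    conservation_rate_focal: float = 0.72
    conservation_rate_background: float = 0.70
    one_to_many_mean: float = 1.4
    phenotype_base_rates: dict = field(default_factory=lambda: dict(DEFAULT_BASE_RATES))
    phenotype_risk_ratio_focal: dict = field(default_factory=lambda: dict(DEFAULT_RISK_RATIOS))
    edge_density: float = 0.002
    within_set_edge_multiplier: float = 50.0
    edge_conservation_rate: float = 0.07
    blast_decoy_count: int = 4
    source_split: tuple[int, int, int] = (35, 13, 2)  # ensembl : wormbase : blastp

    def __post_init__(self):
        for name in (
            "worm_pseudogene_rate",
            "conservation_rate_focal",
            "conservation_rate_background",
            "edge_conservation_rate",
        ):
            if not 0 <= getattr(self, name) <= 1:
                raise ValidationError(f"{name} must lie in [0, 1]")
        if self.focal_size > self.n_human:
            raise ValidationError("focal_size exceeds the human universe")
        if self.within_set_edge_multiplier <= 0 or self.one_to_many_mean < 1:
            raise ValidationError("multipliers must be positive (one_to_many_mean >= 1)")
        for r, v in self.phenotype_base_rates.items():
            if not 0 <= v <= 1:
                raise ValidationError(f"base rate for {r!r} outside [0, 1]")


@dataclass
class SyntheticWorld:
    config: SyntheticWorldConfig
    human_universe: list
    worm_universe: list
    focal_genes: tuple
    truth_orthology: dict  # human gene -> frozenset of planted worm orthologs
    truth_tiers: dict  # human gene -> "ensembl" | "wormbase" | "blastp"
    ensembl: list
    wormbase: list
    blast_hits: dict  # human gene -> list[BlastHit]
    corroboration: dict  # species -> frozenset of worm genes
    blast_decoys: dict  # human gene -> frozenset of decoy subject ids
    annotations: list
    human_network: InteractionNetwork
    worm_network: InteractionNetwork
    random_sets: tuple = ()
    random_sets_worm: tuple = ()
    human_symbols: dict = field(default_factory=dict)

    # -- convenience views -------------------------------------------------
    @property
    def human_ids(self) -> list[str]:
        return [g.gene_id for g in self.human_universe]

    @property
    def worm_coding_ids(self) -> list[str]:
        return [g.gene_id for g in self.worm_universe if g.biotype == "protein_coding"]

    def accepted_blast_assertions(
        self, criteria: CounterpartCriteria = CounterpartCriteria()
    ) -> list[OrthologAssertion]:
        accepted = []
        for gene, hits in self.blast_hits.items():
            decisions = evaluate_counterpart(
                hits_for_largest_transcript(hits), self.corroboration, criteria
            )
            accepted.extend(
                OrthologAssertion(gene, d.worm_gene, "blastp")
                for d in decisions.values()
                if d.accepted
            )
        return accepted

    def resolve(self, criteria: CounterpartCriteria = CounterpartCriteria()) -> OrthologyMap:
        return resolve_orthologs(
            list(self.focal_genes),
            self.ensembl,
            self.wormbase,
            self.accepted_blast_assertions(criteria),
            human_universe=self.human_ids,
        )

    def conserved_count(self, gene_set) -> int:
        """Number of genes in ``gene_set`` with any ortholog assertion."""
        known = {a.human_gene for a in self.ensembl} | {a.human_gene for a in self.wormbase}
        known |= {a.human_gene for a in self.accepted_blast_assertions()}
        return len(frozenset(gene_set) & known)

    def write(self, outdir) -> None:
        """Write every input table in the formats the pipeline reads."""
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)

        def genes_frame(records):
            return pd.DataFrame(
                [(g.gene_id, g.symbol, g.biotype) for g in records],
                columns=["gene_id", "symbol", "biotype"],
            )

        genes_frame(self.human_universe).to_csv(out / "human_genes.tsv", sep="\t", index=False)
        genes_frame(self.worm_universe).to_csv(out / "worm_genes.tsv", sep="\t", index=False)
        for name, assertions in (("ensembl", self.ensembl), ("wormbase", self.wormbase)):
            pd.DataFrame(
                [(a.human_gene, a.worm_gene) for a in assertions],
                columns=["human_gene", "worm_gene"],
            ).to_csv(out / f"{name}.tsv", sep="\t", index=False)
        with open(out / "blast.tsv", "w") as fh:
            for gene in sorted(self.blast_hits):
                for h in self.blast_hits[gene]:
                    fh.write(
                        "\t".join(
                            str(x)
                            for x in (
                                h.query_id,
                                h.subject_id,
                                h.percent_identity,
                                h.alignment_length,
                                h.mismatches,
                                h.gap_opens,
                                h.qstart,
                                h.qend,
                                h.sstart,
                                h.send,
                                h.e_value,
                                h.bit_score,
                                h.query_length,
                                h.subject_length,
                            )
                        )
                        + "\n"
                    )
        pd.DataFrame(
            [(sp, w) for sp in sorted(self.corroboration) for w in sorted(self.corroboration[sp])],
            columns=["species", "worm_gene"],
        ).to_csv(out / "corroboration.tsv", sep="\t", index=False)
        pd.DataFrame(
            [(a.worm_gene, a.phenotype, a.evidence) for a in self.annotations],
            columns=["worm_gene", "phenotype", "evidence"],
        ).to_csv(out / "annotations.tsv", sep="\t", index=False)
        for name, net in (("human_network", self.human_network), ("worm_network", self.worm_network)):
            pd.DataFrame(sorted(net.edges()), columns=["gene_a", "gene_b"]).to_csv(
                out / f"{name}.tsv", sep="\t", index=False
            )
        (out / "focal.txt").write_text("\n".join(self.focal_genes) + "\n")
        if self.random_sets:
            pd.DataFrame(
                [(i + 1, g) for i, s in enumerate(self.random_sets) for g in sorted(s)],
                columns=["set", "gene_id"],
            ).to_csv(out / "random_sets.tsv", sep="\t", index=False)


# ---------------------------------------------------------------------------
# BLAST hit construction


def _passing_hit(rng, query: str, subject: str) -> BlastHit:
    qlen = int(rng.integers(300, 800))
    slen = qlen + int(rng.integers(-100, 101))
    alen = int(rng.integers(60, 260))
    return BlastHit(
        query_id=query,
        subject_id=subject,
        percent_identity=float(np.round(rng.uniform(25, 90), 1)),
        alignment_length=alen,
        mismatches=int(alen * 0.3),
        gap_opens=int(rng.integers(0, 5)),
        qstart=1,
        qend=alen,
        sstart=1,
        send=alen,
        e_value=float(10.0 ** rng.uniform(-50, -4.5)),
        bit_score=float(np.round(rng.uniform(80, 400), 1)),
        query_length=qlen,
        subject_length=max(slen, 60),
    )


def _decoy_hit(rng, query: str, subject: str, violation: int) -> BlastHit:
    """A hit violating exactly the given criterion (1-3; 4 is corroboration)."""
    h = _passing_hit(rng, query, subject)
    if violation == 1:
        sign = 1 if rng.random() < 0.5 else -1
        slen = h.query_length + sign * int(rng.integers(101, 301))
        h = replace(h, subject_length=max(slen, h.query_length + 101))
    elif violation == 2:
        h = replace(h, e_value=float(10.0 ** rng.uniform(-3, -1)))
    elif violation == 3:
        # identity too low; keep a long segment so only criterion 3 fails
        h = replace(h, percent_identity=float(np.round(rng.uniform(5, 19), 1)))
    return h


# ---------------------------------------------------------------------------
# generate_world


def generate_world(config: SyntheticWorldConfig) -> SyntheticWorld:
    """Draw a complete world at the configured rates (seed-reproducible)."""
    ss = np.random.SeedSequence(config.seed)
    (
        rng_orth,
        rng_blast,
        rng_pheno,
        rng_hnet,
        rng_wnet,
    ) = (np.random.default_rng(s) for s in ss.spawn(5))

    n_pseudo = int(round(config.n_worm * config.worm_pseudogene_rate))
    human = [
        GeneRecord(f"HSA{i:05d}", f"HGN{i}", "protein_coding", "human")
        for i in range(1, config.n_human + 1)
    ]
    worm = [
        GeneRecord(f"WBG{i:08d}", f"wrm-{i}", "protein_coding", "worm")
        for i in range(1, config.n_worm + 1)
    ] + [
        GeneRecord(f"WBGP{i:08d}", f"psg-{i}", "pseudogene", "worm") for i in range(1, n_pseudo + 1)
    ]
    human_ids = np.array([g.gene_id for g in human])
    coding_ids = np.array([g.gene_id for g in worm if g.biotype == "protein_coding"])
    pseudo_ids = np.array([g.gene_id for g in worm if g.biotype == "pseudogene"])

    focal = tuple(sorted(rng_orth.choice(human_ids, size=config.focal_size, replace=False)))
    focal_set = frozenset(focal)

    # --- planted orthology for the focal set --------------------------------
    conserved_mask = rng_orth.random(config.focal_size) < config.conservation_rate_focal
    conserved = [g for g, m in zip(focal, conserved_mask) if m]
    split = np.asarray(config.source_split, dtype=float)
    tier_of = {
        g: ("ensembl", "wormbase", "blastp")[int(t)]
        for g, t in zip(conserved, rng_orth.choice(3, size=len(conserved), p=split / split.sum()))
    }

    coding_pool = list(rng_orth.permutation(coding_ids))
    pseudo_pool = list(rng_orth.permutation(pseudo_ids))

    def draw_orthologs(k: int) -> list[str]:
        picks = []
        for _ in range(k):
            use_pseudo = pseudo_pool and rng_orth.random() < config.worm_pseudogene_rate
            picks.append(pseudo_pool.pop() if use_pseudo else coding_pool.pop())
        return picks

    truth: dict[str, frozenset[str]] = {}
    for g in conserved:
        k = 1 + min(int(rng_orth.poisson(config.one_to_many_mean - 1)), 12)
        truth[g] = frozenset(draw_orthologs(k))

    ensembl = [
        OrthologAssertion(g, w, "ensembl")
        for g in conserved
        if tier_of[g] == "ensembl"
        for w in sorted(truth[g])
    ]
    wormbase = [
        OrthologAssertion(g, w, "wormbase")
        for g in conserved
        if tier_of[g] == "wormbase"
        for w in sorted(truth[g])
    ]

    # background conservation: curated 1:1 assertions outside the focal set
    background = [g for g in human_ids if g not in focal_set]
    bg_mask = rng_orth.random(len(background)) < config.conservation_rate_background
    bg_conserved = [g for g, m in zip(background, bg_mask) if m]
    bg_partners = rng_orth.choice(coding_ids, size=len(bg_conserved), replace=False)
    ensembl.extend(
        OrthologAssertion(g, w, "ensembl") for g, w in zip(bg_conserved, bg_partners)
    )

    # --- BLAST evidence ------------------------------------------------------
    blast_hits: dict[str, list[BlastHit]] = {}
    corroboration: dict[str, set[str]] = {sp: set() for sp in SPECIES_POOL}
    decoys: dict[str, frozenset[str]] = {}
    blast_queried = [g for g in conserved if tier_of[g] == "blastp"] + [
        g for g in focal if g not in truth
    ]
    for g in blast_queried:
        query = f"{g}_P1"
        hits: list[BlastHit] = []
        for w in sorted(truth.get(g, ())):
            hits.append(_passing_hit(rng_blast, query, w))
            n_sp = int(rng_blast.integers(3, len(SPECIES_POOL) + 1))
            for sp in rng_blast.choice(SPECIES_POOL, size=n_sp, replace=False):
                corroboration[sp].add(w)
        gene_decoys = []
        for _ in range(config.blast_decoy_count):
            violation = int(rng_blast.integers(1, 5))
            subject = coding_pool.pop()
            hits.append(_decoy_hit(rng_blast, query, subject, violation))
            if violation == 4:
                n_sp = int(rng_blast.integers(0, 3))  # corroborated by <= 2 species
                for sp in rng_blast.choice(SPECIES_POOL, size=n_sp, replace=False):
                    corroboration[sp].add(subject)
            else:
                for sp in rng_blast.choice(SPECIES_POOL, size=3, replace=False):
                    corroboration[sp].add(subject)
            gene_decoys.append(subject)
        decoys[g] = frozenset(gene_decoys)
        blast_hits[g] = hits

    # --- phenotype annotations ----------------------------------------------
    focal_orthologs = frozenset().union(*truth.values()) if truth else frozenset()
    annotations: list[PhenotypeAnnotation] = []
    coding_arr = coding_ids
    is_focal_orth = np.isin(coding_arr, sorted(focal_orthologs))
    for term, base in config.phenotype_base_rates.items():
        rr = config.phenotype_risk_ratio_focal.get(term, 1.0)
        p_vec = np.where(is_focal_orth, min(base * rr, 1.0), base)
        chosen = coding_arr[rng_pheno.random(coding_arr.size) < p_vec]
        evid = rng_pheno.choice(["rnai", "allele"], size=chosen.size)
        annotations.extend(
            PhenotypeAnnotation(g, term, e) for g, e in zip(chosen.tolist(), evid.tolist())
        )

    # --- interaction networks -------------------------------------------------
    def er_edges(ids: np.ndarray, p: float, rng) -> list[tuple[str, str]]:
        n = ids.size
        m = rng.binomial(n * (n - 1) // 2, p)
        a = rng.integers(0, n, size=int(m * 1.2) + 8)
        b = rng.integers(0, n, size=a.size)
        keep = a != b
        pairs = {(min(x, y), max(x, y)) for x, y in zip(a[keep], b[keep])}
        pairs = list(itertools.islice(pairs, m))
        return [(str(ids[i]), str(ids[j])) for i, j in pairs]

    h_edges = er_edges(human_ids, config.edge_density, rng_hnet)
    p_within = min(config.edge_density * config.within_set_edge_multiplier, 0.5)
    conserved_sorted = sorted(truth)
    within_edges = [
        (a, b)
        for a, b in itertools.combinations(conserved_sorted, 2)
        if rng_hnet.random() < p_within
    ]
    human_network = InteractionNetwork("human", h_edges + within_edges)

    w_edges = er_edges(coding_ids, config.edge_density, rng_wnet)
    mirrored = []
    for a, b in human_network.graph.subgraph(conserved_sorted).edges():
        if truth[a] & truth[b]:
            continue  # shared ortholog: same group, not mirrorable
        if rng_wnet.random() < config.edge_conservation_rate:
            wa = sorted(truth[a])[int(rng_wnet.integers(len(truth[a])))]
            wb = sorted(truth[b])[int(rng_wnet.integers(len(truth[b])))]
            mirrored.append((wa, wb))
    worm_network = InteractionNetwork("worm", w_edges + mirrored)

    return SyntheticWorld(
        config=config,
        human_universe=human,
        worm_universe=worm,
        focal_genes=focal,
        truth_orthology=truth,
        truth_tiers=tier_of,
        ensembl=ensembl,
        wormbase=wormbase,
        blast_hits=blast_hits,
        corroboration={sp: frozenset(v) for sp, v in corroboration.items()},
        blast_decoys=decoys,
        annotations=annotations,
        human_network=human_network,
        worm_network=worm_network,
        human_symbols={g.gene_id: g.symbol for g in human},
    )


# ---------------------------------------------------------------------------
# benchmark_fixture

TABLE1_RANDOM_COUNTS = (44, 51, 53, 47, 41, 49, 50, 51, 44, 50)

# interologs planted in the fixture: (human a, human b, worm a, worm b)
FIXTURE_CONSERVED_PAIRS = (
    ("ACVR2A", "GBE1", "daf-1", "T04A8.7"),
    ("APLNR", "DRD2", "npr-33", "ser-5"),
    ("ARNTL", "SIM1", "aha-1", "hif-1"),
    ("ARNTL", "SIPA1L1", "aha-1", "F53A10.2"),
    ("FBXL17", "UBE3B", "fbxl-1", "oxi-1"),
    ("GRIK2", "NRXN1", "glr-1", "nrx-1"),
    ("ISL1", "LPXN", "lim-7", "pxl-1"),
    ("PARVA", "SMNTL", "pat-6", "T15B12.1"),
    ("PHF2", "SSRP1", "jmjd-1.2", "athp-1"),
)

# genome-wide annotated counts (of 19,985 coding genes) and counts among the
# 57 non-chemoreceptor-family coding orthologs; calibrated so the enrichment
# odds ratios and p-values reproduce the benchmark values
FIXTURE_PHENOTYPE_COUNTS = {
    "lethal": (1838, 11),
    "embryonic lethal": (3003, 14),
    "larval lethal": (821, 3),
    "sterile": (2408, 12),
    "sterile progeny": (717, 1),
}

FIXTURE_HUMAN_EDGE_TOTAL = 133
FIXTURE_WORM_GROUP_PAIR_TOTAL = 44


def benchmark_fixture() -> SyntheticWorld:
    """Deterministic world reproducing the benchmark study conditions."""
    rng = np.random.default_rng(20250221)
    config = SyntheticWorldConfig(seed=20250221)

    # --- universes ------------------------------------------------------------
    named_worm = [
        "daf-1",
        "sma-6",
        "T04A8.7",
        "npr-33",
        "ser-5",
        "aha-1",
        "hif-1",
        "F53A10.2",
        "fbxl-1",
        "oxi-1",
        "glr-1",
        "nrx-1",
        "lim-7",
        "pxl-1",
        "pat-6",
        "T15B12.1",
        "jmjd-1.1",
        "jmjd-1.2",
        "athp-1",
        "ztf-11",
    ] + [f"srsx-3{i}" for i in range(1, 10)]
    n_tail = config.n_worm - len(named_worm)
    worm = (
        [GeneRecord(g, g, "protein_coding", "worm") for g in named_worm]
        + [
            GeneRecord(f"wbg-{i:05d}", f"wbg-{i:05d}", "protein_coding", "worm")
            for i in range(1, n_tail + 1)
        ]
        + [GeneRecord(f"srsx-p{i}", f"srsx-p{i}", "pseudogene", "worm") for i in range(1, 5)]
    )
    coding_ids = [g.gene_id for g in worm if g.biotype == "protein_coding"]
    assert len(coding_ids) == config.n_worm

    named_human = [
        "ACVR2A",
        "GBE1",
        "APLNR",
        "DRD2",
        "ARNTL",
        "SIM1",
        "SIPA1L1",
        "FBXL17",
        "UBE3B",
        "GRIK2",
        "NRXN1",
        "ISL1",
        "LPXN",
        "PARVA",
        "SMNTL",
        "PHF2",
        "SSRP1",
        "OR5B17",
    ]
    soc = [f"SOC{i}" for i in range(19, 51)]  # SOC19..SOC50: 32 further conserved
    nonconserved = [f"SOCN{i}" for i in range(1, 20)]  # 19 non-conserved
    focal = tuple(named_human + soc + nonconserved)
    n_tail_h = config.n_human - len(focal)
    human = [GeneRecord(g, g, "protein_coding", "human") for g in focal] + [
        GeneRecord(f"hsa-{i:05d}", f"hsa-{i:05d}", "protein_coding", "human")
        for i in range(1, n_tail_h + 1)
    ]

    # --- planted orthology: 50 conserved genes, 70 worm orthologs -------------
    truth: dict[str, frozenset[str]] = {
        "ACVR2A": frozenset({"daf-1", "sma-6"}),
        "GBE1": frozenset({"T04A8.7"}),
        "APLNR": frozenset({"npr-33"}),
        "DRD2": frozenset({"ser-5"}),
        "ARNTL": frozenset({"aha-1"}),
        "SIM1": frozenset({"hif-1"}),
        "SIPA1L1": frozenset({"F53A10.2"}),
        "FBXL17": frozenset({"fbxl-1"}),
        "UBE3B": frozenset({"oxi-1"}),
        "GRIK2": frozenset({"glr-1"}),
        "NRXN1": frozenset({"nrx-1"}),
        "ISL1": frozenset({"lim-7"}),
        "LPXN": frozenset({"pxl-1"}),
        "PARVA": frozenset({"pat-6"}),
        "SMNTL": frozenset({"T15B12.1"}),
        "SSRP1": frozenset({"athp-1"}),
        "PHF2": frozenset({"jmjd-1.1", "jmjd-1.2"}),
        "OR5B17": frozenset({f"srsx-3{i}" for i in range(1, 10)} | {f"srsx-p{i}" for i in range(1, 5)}),
        # two human genes sharing one worm ortholog -> 49 groups
        "SOC19": frozenset({"ztf-11"}),
        "SOC20": frozenset({"ztf-11"}),
    }
    # SOC21..SOC27 get two orthologs each, SOC28..SOC50 one each -> 70 total
    tail_iter = iter(f"wbg-{i:05d}" for i in range(1, 200))
    for i in range(21, 28):
        truth[f"SOC{i}"] = frozenset({next(tail_iter), next(tail_iter)})
    for i in range(28, 51):
        truth[f"SOC{i}"] = frozenset({next(tail_iter)})
    conserved = sorted(truth)
    assert len(conserved) == 50
    all_orthologs = frozenset().union(*truth.values())
    assert len(all_orthologs) == 70

    # tiers: 2 via BLASTP, 13 via the secondary curated source, 35 primary
    blast_tier = ["SOC48", "SOC49"]
    wormbase_tier = [f"SOC{i}" for i in range(35, 48)]
    tier_of = {
        g: ("blastp" if g in blast_tier else "wormbase" if g in wormbase_tier else "ensembl")
        for g in conserved
    }
    ensembl = [
        OrthologAssertion(g, w, "ensembl")
        for g in conserved
        if tier_of[g] == "ensembl"
        for w in sorted(truth[g])
    ]
    wormbase = [
        OrthologAssertion(g, w, "wormbase")
        for g in conserved
        if tier_of[g] == "wormbase"
        for w in sorted(truth[g])
    ]

    # background assertions give the ten pre-baked random sets their
    # conservation counts; sets are disjoint slices of the background pool
    background = [g.gene_id for g in human if g.gene_id not in focal]
    random_sets = []
    offset = 0
    for k in TABLE1_RANDOM_COUNTS:
        members = background[offset : offset + 69]
        offset += 69
        ensembl.extend(
            OrthologAssertion(g, coding_ids[-(offset - 69 + j + 1)], "ensembl")
            for j, g in enumerate(members[:k])
        )
        random_sets.append(frozenset(members))

    # --- BLAST evidence for the two BLASTP-tier genes + decoys ----------------
    blast_hits: dict[str, list[BlastHit]] = {}
    corroboration: dict[str, set[str]] = {sp: set() for sp in SPECIES_POOL}
    decoys: dict[str, frozenset[str]] = {}
    decoy_iter = iter(f"wbg-{i:05d}" for i in range(300, 1000))
    for g in blast_tier + nonconserved:
        query = f"{g}_P1"
        hits = [_passing_hit(rng, query, w) for w in sorted(truth.get(g, ()))]
        for w in sorted(truth.get(g, ())):
            for sp in SPECIES_POOL[:4]:
                corroboration[sp].add(w)
        gene_decoys = []
        for violation in (1, 2, 3, 4):
            subject = next(decoy_iter)
            hits.append(_decoy_hit(rng, query, subject, violation))
            n_sp = 3 if violation != 4 else 2
            for sp in SPECIES_POOL[:n_sp]:
                corroboration[sp].add(subject)
            gene_decoys.append(subject)
        decoys[g] = frozenset(gene_decoys)
        blast_hits[g] = hits

    # --- phenotype annotations -------------------------------------------------
    coding_orthologs = sorted(all_orthologs & set(coding_ids))
    srsx_family = sorted(g for g in all_orthologs if g.startswith("srsx"))
    non_srsx = [g for g in coding_orthologs if not g.startswith("srsx")]
    assert len(non_srsx) == 57 and len(srsx_family) == 13
    fill_pool = [g for g in coding_ids if g not in all_orthologs]
    annotations: list[PhenotypeAnnotation] = []
    fill_offset = 5000  # keep genome fill away from ortholog/decoy ids
    for term, (genome_count, set_count) in FIXTURE_PHENOTYPE_COUNTS.items():
        carriers = non_srsx[:set_count]
        n_fill = genome_count - set_count
        carriers += fill_pool[fill_offset : fill_offset + n_fill]
        fill_offset += n_fill
        annotations.extend(PhenotypeAnnotation(g, term, "rnai") for g in carriers)
    annotations.append(PhenotypeAnnotation("daf-1", "social feeding", "allele"))

    # --- human network: 133 within-set edges, 9 of them mirrored ---------------
    human_edges = {(min(a, b), max(a, b)) for a, b, _, _ in FIXTURE_CONSERVED_PAIRS}
    # the most interactive gene touches 16 of the other conserved genes
    hub_partners = [f"SOC{i}" for i in range(21, 36)]
    for p in hub_partners:
        human_edges.add(tuple(sorted(("ACVR2A", p))))
    degree: dict[str, int] = {}
    for a, b in human_edges:
        degree[a] = degree.get(a, 0) + 1
        degree[b] = degree.get(b, 0) + 1
    candidates = [
        (a, b)
        for a, b in itertools.combinations(conserved, 2)
        if (a, b) not in human_edges
        and "ACVR2A" not in (a, b)
        and not (a == "SOC19" and b == "SOC20")  # same group: keep totals unambiguous
    ]
    for idx in rng.permutation(len(candidates)):
        if len(human_edges) == FIXTURE_HUMAN_EDGE_TOTAL:
            break
        a, b = candidates[idx]
        if degree.get(a, 0) >= 15 or degree.get(b, 0) >= 15:
            continue
        human_edges.add((a, b))
        degree[a] = degree.get(a, 0) + 1
        degree[b] = degree.get(b, 0) + 1
    assert len(human_edges) == FIXTURE_HUMAN_EDGE_TOTAL

    # a handful of interactions among the non-conserved genes, plus modest
    # within-set edges for each random split set (a per-query-set export)
    extra_human = [
        ("SOCN1", "SOCN2"),
        ("SOCN1", "SOCN3"),
        ("SOCN4", "SOCN5"),
        ("SOCN6", "SOCN7"),
        ("SOCN2", "SOCN8"),
    ]
    for s in random_sets:
        members = sorted(s)
        extra_human.append((members[0], members[1]))
        extra_human.append((members[50], members[51]))
        for a, b in itertools.combinations(members[:50], 2):
            if rng.random() < 0.004:
                extra_human.append((a, b))
        for a, b in itertools.combinations(members[50:], 2):
            if rng.random() < 0.03:
                extra_human.append((a, b))
    human_network = InteractionNetwork("human", sorted(human_edges) + extra_human)

    # --- worm network -----------------------------------------------------------
    worm_edges = {(min(wa, wb), max(wa, wb)) for _, _, wa, wb in FIXTURE_CONSERVED_PAIRS}
    assert len(worm_edges) == 9
    # co-orthologs of one human gene are highly interactive among themselves
    within_group = [("daf-1", "sma-6"), ("jmjd-1.1", "jmjd-1.2")] + [
        (srsx_family[i], srsx_family[i + 1]) for i in range(len(srsx_family) - 2)
    ]
    # 35 further group-pair edges whose human counterparts do NOT interact
    group_of = {w: h for h, ws in truth.items() for w in ws}
    group_of.update({w: "SOC19+SOC20" for w in truth["SOC19"]})
    rep = {h: sorted(ws)[0] for h, ws in truth.items()}
    human_edge_groups = set()
    for a, b in human_edges:
        ga = "SOC19+SOC20" if a in ("SOC19", "SOC20") else a
        gb = "SOC19+SOC20" if b in ("SOC19", "SOC20") else b
        human_edge_groups.add((min(ga, gb), max(ga, gb)))
    extra_pairs = 0
    for a, b in itertools.combinations(sorted(rep), 2):
        if extra_pairs == FIXTURE_WORM_GROUP_PAIR_TOTAL - 9:
            break
        ga = "SOC19+SOC20" if a in ("SOC19", "SOC20") else a
        gb = "SOC19+SOC20" if b in ("SOC19", "SOC20") else b
        if ga == gb or (min(ga, gb), max(ga, gb)) in human_edge_groups:
            continue
        key = (min(rep[a], rep[b]), max(rep[a], rep[b]))
        if key in worm_edges:
            continue
        worm_edges.add(key)
        human_edge_groups.add((min(ga, gb), max(ga, gb)))  # avoid double-counting a pair
        extra_pairs += 1
    assert extra_pairs == FIXTURE_WORM_GROUP_PAIR_TOTAL - 9

    # ten random worm gene sets of 49, with modest internal connectivity
    worm_pool = [g for g in coding_ids if g not in all_orthologs][:490]
    random_sets_worm = [frozenset(worm_pool[i * 49 : (i + 1) * 49]) for i in range(10)]
    extra_worm = []
    for s in random_sets_worm:
        members = sorted(s)
        extra_worm.append((members[0], members[1]))
        for a, b in itertools.combinations(members, 2):
            if rng.random() < 0.004:
                extra_worm.append((a, b))
    worm_network = InteractionNetwork(
        "worm", sorted(worm_edges) + within_group + extra_worm
    )

    return SyntheticWorld(
        config=config,
        human_universe=human,
        worm_universe=worm,
        focal_genes=focal,
        truth_orthology=truth,
        truth_tiers=tier_of,
        ensembl=ensembl,
        wormbase=wormbase,
        blast_hits=blast_hits,
        corroboration={sp: frozenset(v) for sp, v in corroboration.items()},
        blast_decoys=decoys,
        annotations=annotations,
        human_network=human_network,
        worm_network=worm_network,
        random_sets=tuple(random_sets),
        random_sets_worm=tuple(random_sets_worm),
        human_symbols={g.gene_id: g.symbol for g in human},
    )
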