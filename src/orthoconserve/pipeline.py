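"""End-to-end orchestration of the four analysis stages.

``run_pipeline`` executes orthology resolution, conservation testing,
phenotype enrichment and the interaction analyses in order, from either
a :class:`~orthoconserve.synthetic.SyntheticWorld` (in-memory) or a YAML
config pointing at input TSVs.  Every stochastic step derives its stream
from the single root seed, so a rerun with the same config is
byte-identical.  Stages degrade gracefully: missing network inputs skip
the interaction stage with a log entry rather than aborting the report.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import io as oio
from .conservation import (
    RandomSetConfig,
    pairwise_set_comparison,
    reference_comparison,
    sample_random_sets,
    zscore_outlier,
)
from .contingency import ContingencyResult
from .exceptions import ValidationError
from .interactions import (
    InteractionNetwork,
    conserved_edges,
    group_interactions,
    levene_test,
    load_edge_list,
    overdispersion_test,
    profile_set,
    quasipoisson_compare,
)
from .orthology import (
    CounterpartCriteria,
    build_groups,
    evaluate_counterpart,
    filter_protein_coding,
    hits_for_largest_transcript,
    resolve_orthologs,
    OrthologAssertion,
)
from .phenotypes import PhenotypePanel, annotation_index, exclusion_sensitivity
from .synthetic import SyntheticWorld

logger = logging.getLogger("orthoconserve")

__all__ = ["PipelineConfig", "RunReport", "run_pipeline", "run_pipeline_from_world"]

REFERENCE_CONSERVED = 10678
REFERENCE_TOTAL = 20310


@dataclass
class PipelineConfig:
    """Paths and parameters of a full pipeline run (YAML-loadable)."""

    human_genes: str
    worm_genes: str
    focal: str
    ensembl: str
    wormbase: str
    blast: Optional[str] = None
    corroboration: Optional[str] = None
    annotations: Optional[str] = None
    human_network: Optional[str] = None
    worm_network: Optional[str] = None
    exclude_family_prefix: Optional[str] = None
    seed: int = 0
    n_random: int = 10
    reference_conserved: int = REFERENCE_CONSERVED
    reference_total: int = REFERENCE_TOTAL
    expected_count_cutoff: float = 10.0
    alpha: float = 0.05
    max_extra: int = 0
    criteria: CounterpartCriteria = field(default_factory=CounterpartCriteria)
    outdir: Optional[str] = None

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise ValidationError("alpha must lie in (0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh)
        crit = data.pop("criteria", None)
        cfg = cls(**data)
        if crit:
            cfg.criteria = CounterpartCriteria(**crit)
        return cfg


@dataclass
class RunReport:
    resolution: dict
    table1: pd.DataFrame
    zscore: float
    reference: ContingencyResult
    enrichment_including: Optional[pd.DataFrame] = None
    enrichment_excluding: Optional[pd.DataFrame] = None
    flipped_terms: list = field(default_factory=list)
    social: Optional[pd.DataFrame] = None
    interactivity: Optional[dict] = None
    conserved_interactions: Optional[pd.DataFrame] = None
    interaction_counts: Optional[dict] = None
    groups: list = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def to_json_dict(self) -> dict:
        def cres(r: Optional[ContingencyResult]):
            if r is None:
                return None
            return {
                "method": r.method,
                "statistic": r.statistic,
                "p_value": r.p_value,
                "odds_ratio": r.odds_ratio,
                "ci": [r.ci_low, r.ci_high],
                "expected_min": r.expected_min,
            }

        return {
            "resolution": self.resolution,
            "table1": self.table1.to_dict(orient="records"),
            "zscore": self.zscore,
            "reference": cres(self.reference),
            "enrichment_including": None
            if self.enrichment_including is None
            else self.enrichment_including.to_dict(orient="records"),
            "enrichment_excluding": None
            if self.enrichment_excluding is None
            else self.enrichment_excluding.to_dict(orient="records"),
            "flipped_terms": self.flipped_terms,
            "interactivity": self.interactivity,
            "interaction_counts": self.interaction_counts,
            "n_groups": len(self.groups),
            "provenance": self.provenance,
        }

    def write(self, outdir) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "report.json", "w") as fh:
            json.dump(self.to_json_dict(), fh, indent=2, default=_jsonable)
        self.table1.to_csv(out / "table1.tsv", sep="\t", index=False)
        if self.enrichment_including is not None:
            pd.concat(
                [
                    self.enrichment_including.assign(block="including_family"),
                    self.enrichment_excluding.assign(block="excluding_family"),
                ]
            ).to_csv(out / "table2.tsv", sep="\t", index=False)
        if self.conserved_interactions is not None:
            self.conserved_interactions.to_csv(out / "table3.tsv", sep="\t", index=False)


def _jsonable(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, (frozenset, set, tuple)):
        return sorted(o) if isinstance(o, (frozenset, set)) else list(o)
    if isinstance(o, float) and np.isnan(o):
        return None
    raise TypeError(f"not JSON-serialisable: {type(o)}")


def _qp_row(label: str, focal_counts, other_counts) -> dict:
    try:
        r = quasipoisson_compare(focal_counts, other_counts)
        return {
            "comparison": label,
            "rate_ratio": r.rate_ratio,
            "std_error": r.std_error,
            "p_value": r.p_value,
            "dispersion": r.dispersion,
        }
    except ValidationError as exc:
        logger.warning("quasipoisson comparison %s skipped: %s", label, exc)
        return {
            "comparison": label,
            "rate_ratio": None,
            "std_error": None,
            "p_value": None,
            "dispersion": None,
        }


def run_pipeline_from_world(
    world: SyntheticWorld,
    seed: Optional[int] = None,
    n_random: int = 10,
    reference: tuple[int, int] = (REFERENCE_CONSERVED, REFERENCE_TOTAL),
    expected_count_cutoff: float = 10.0,
    alpha: float = 0.05,
    max_extra: int = 0,
    criteria: CounterpartCriteria = CounterpartCriteria(),
    panel: PhenotypePanel = PhenotypePanel(),
) -> RunReport:
    """Run every stage on an in-memory world and assemble the report.

    When the world carries pre-baked random sets those are used; otherwise
    ``n_random`` sets of the focal size are sampled from the human
    universe (excluding the focal genes) at the given seed.
    """
    seed = world.config.seed if seed is None else seed

    # --- stage 1: orthology ---------------------------------------------------
    omap = world.resolve(criteria)
    symbols = world.human_symbols or None
    groups = build_groups(omap, symbols=symbols)
    coding, pseudo = filter_protein_coding(omap, world.worm_universe)
    resolution = dict(omap.step_counts)
    resolution.update(
        worm_orthologs=len(omap.worm_orthologs),
        worm_protein_coding=len(coding),
        worm_pseudogenes=len(pseudo),
        n_groups=len(groups),
    )
    focal = list(world.focal_genes)
    n_focal = len(focal)
    k_focal = resolution["conserved"]

    # --- stage 2: conservation --------------------------------------------------
    if world.random_sets:
        random_sets = list(world.random_sets)
    else:
        random_sets = sample_random_sets(
            RandomSetConfig(
                universe=tuple(world.human_ids),
                seed=seed,
                n_sets=n_random,
                set_size=n_focal,
                exclude=frozenset(focal),
            )
        )
    random_counts = [(world.conserved_count(s), len(s)) for s in random_sets]
    results = pairwise_set_comparison(
        (k_focal, n_focal), random_counts, threshold=expected_count_cutoff
    )
    table1 = pd.DataFrame(
        {
            "set": [f"random_{i + 1}" for i in range(len(random_sets))] + ["focal"],
            "conserved": [k for k, _ in random_counts] + [k_focal],
            "total": [n for _, n in random_counts] + [n_focal],
            "pct": [100 * k / n for k, n in random_counts] + [100 * k_focal / n_focal],
            "method": [r.method for r in results] + [None],
            "statistic": [r.statistic for r in results] + [None],
            "p_value": [r.p_value for r in results] + [None],
        }
    )
    for r in results:
        logger.info("conservation dispatch: %s (min expected %.1f)", r.method, r.expected_min)
    z = zscore_outlier([k for k, _ in random_counts] + [k_focal], k_focal)
    ref_res = reference_comparison(
        (k_focal, n_focal), reference, remove_overlap=True, threshold=expected_count_cutoff
    )

    report = RunReport(
        resolution=resolution,
        table1=table1,
        zscore=z,
        reference=ref_res,
        groups=groups,
        provenance={"seed": seed, "package": "orthoconserve 0.1.0"},
    )

    # --- stage 3: phenotype enrichment ------------------------------------------
    if world.annotations:
        universe = world.worm_coding_ids
        idx = annotation_index(world.annotations)
        family = frozenset(
            g for g in omap.worm_orthologs if g.startswith("srsx")
        )
        gene_set = coding
        from .phenotypes import enrich

        if family & gene_set:
            incl, excl, flipped = exclusion_sensitivity(
                gene_set,
                family,
                panel.essential,
                universe,
                idx,
                threshold=expected_count_cutoff,
                alpha=alpha,
            )
        else:
            incl = enrich(gene_set, panel.essential, universe, idx, threshold=expected_count_cutoff)
            excl, flipped = incl, []
        report.enrichment_including = incl
        report.enrichment_excluding = excl
        report.flipped_terms = flipped
        # social block is reported descriptively (annotation counts only)
        social_rows = [
            {
                "term": t,
                "annotated_in_set": len(idx.get(t, frozenset()) & gene_set),
                "annotated_in_genome": len(idx.get(t, frozenset()) & frozenset(universe)),
            }
            for t in panel.social
        ]
        report.social = pd.DataFrame(social_rows)
    else:
        logger.info("no phenotype annotations supplied; enrichment stage skipped")

    # --- stage 4: interactions -----------------------------------------------
    if world.human_network is not None and world.human_network.n_edges > 0:
        hnet = world.human_network
        conserved_set = frozenset(omap.conserved_human_genes)
        nonconserved_set = frozenset(focal) - conserved_set
        n_c, n_nc = len(conserved_set), len(nonconserved_set)

        from .interactions import expand_neighbors

        def set_profile(s, label, net):
            base = frozenset(s)
            if max_extra:
                expanded = expand_neighbors(base, net, max_extra)
                prof_all = profile_set(expanded, net, label)
                # degrees reported for original members only
                per_gene = {g: prof_all.per_gene.get(g, 0) for g in base}
                return prof_all, per_gene
            prof = profile_set(base, net, label)
            return prof, prof.per_gene

        prof_c, deg_c = set_profile(conserved_set, "conserved", hnet)
        prof_nc, deg_nc = (
            set_profile(nonconserved_set, "non_conserved", hnet)
            if nonconserved_set
            else (None, None)
        )
        rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
        profiles_c, profiles_nc = [], []
        for i, s in enumerate(random_sets):
            members = sorted(s)
            split_a, split_b = members[:n_c], members[n_c : n_c + n_nc]
            pa, da = set_profile(frozenset(split_a), f"random_{i + 1}_a", hnet)
            profiles_c.append((pa, da))
            if split_b:
                pb, db = set_profile(frozenset(split_b), f"random_{i + 1}_b", hnet)
                profiles_nc.append((pb, db))

        def degree_vec(d):
            return np.array([d[g] for g in sorted(d)], dtype=float)

        groups_c = [degree_vec(deg_c)] + [degree_vec(d) for _, d in profiles_c]
        labels_c = ["conserved"] + [f"r{i}" for i in range(len(profiles_c))]
        lev_c = levene_test(groups_c)
        disp_c = overdispersion_test(
            np.concatenate(groups_c),
            np.concatenate([[lbl] * len(g) for lbl, g in zip(labels_c, groups_c)]),
        )
        qp_c = [
            _qp_row(f"conserved_vs_random_{i + 1}", degree_vec(deg_c), degree_vec(d))
            for i, (_, d) in enumerate(profiles_c)
        ]

        interactivity = {
            "conserved_total_edges": prof_c.total_edges,
            "random_total_edges_50": [p.total_edges for p, _ in profiles_c],
            "levene_conserved": {"F": lev_c[0], "p": lev_c[1]},
            "dispersion_conserved": {"dispersion": disp_c.dispersion, "p": disp_c.p_value},
            "quasipoisson_conserved": qp_c,
        }
        if prof_nc is not None and profiles_nc:
            groups_nc = [degree_vec(deg_nc)] + [degree_vec(d) for _, d in profiles_nc]
            lev_nc = levene_test(groups_nc)
            disp_nc = overdispersion_test(
                np.concatenate(groups_nc),
                np.concatenate(
                    [
                        [lbl] * len(g)
                        for lbl, g in zip(
                            ["non_conserved"] + [f"r{i}" for i in range(len(profiles_nc))], groups_nc
                        )
                    ]
                ),
            )
            interactivity.update(
                non_conserved_total_edges=prof_nc.total_edges,
                random_total_edges_19=[p.total_edges for p, _ in profiles_nc],
                levene_non_conserved={"F": lev_nc[0], "p": lev_nc[1]},
                dispersion_non_conserved={"dispersion": disp_nc.dispersion, "p": disp_nc.p_value},
                quasipoisson_non_conserved=[
                    _qp_row(f"non_conserved_vs_random_{i + 1}", degree_vec(deg_nc), degree_vec(d))
                    for i, (_, d) in enumerate(profiles_nc)
                ],
            )

        if world.worm_network is not None and world.worm_network.n_edges > 0:
            wnet = world.worm_network
            gprof = group_interactions(wnet, groups)
            interactivity["worm_group_interactions"] = gprof.total_edges
            worm_randoms = list(world.random_sets_worm) or [
                frozenset(
                    rng.choice(
                        np.array(sorted(frozenset(world.worm_coding_ids) - omap.worm_orthologs)),
                        size=len(groups),
                        replace=False,
                    )
                )
                for _ in range(len(random_sets))
            ]
            group_degrees = degree_vec(gprof.per_gene)
            qp_w = []
            worm_rand_edges = []
            for i, s in enumerate(worm_randoms):
                p = profile_set(s, wnet, f"worm_random_{i + 1}")
                worm_rand_edges.append(p.total_edges)
                qp_w.append(
                    _qp_row(f"worm_groups_vs_random_{i + 1}", group_degrees, degree_vec(p.per_gene))
                )
            interactivity["worm_random_total_edges"] = worm_rand_edges
            interactivity["quasipoisson_worm"] = qp_w

            edges, (h_cons, h_tot), (w_cons, w_tot) = conserved_edges(hnet, wnet, groups)
            report.conserved_interactions = pd.DataFrame(
                [
                    {
                        "human_gene_1": e.human_pair[0],
                        "human_gene_2": e.human_pair[1],
                        "worm_gene_1": e.worm_pair[0],
                        "worm_gene_2": e.worm_pair[1],
                        "group_1": e.groups[0],
                        "group_2": e.groups[1],
                    }
                    for e in edges
                ]
            )
            report.interaction_counts = {
                "human_conserved": h_cons,
                "human_total": h_tot,
                "worm_conserved": w_cons,
                "worm_total": w_tot,
            }
        report.interactivity = interactivity
    else:
        logger.info("no interaction networks supplied; interaction stage skipped")

    return report


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Load inputs from the config's paths and run every stage."""
    human = oio.parse_gene_table(config.human_genes, species="human")
    worm = oio.parse_gene_table(config.worm_genes, species="worm")
    focal = [
        line.strip() for line in Path(config.focal).read_text().splitlines() if line.strip()
    ]
    human_ids = frozenset(g.gene_id for g in human)
    worm_ids = frozenset(g.gene_id for g in worm)
    ensembl = oio.parse_ortholog_table(config.ensembl, "ensembl", human_ids, worm_ids)
    wormbase = oio.parse_ortholog_table(config.wormbase, "wormbase", human_ids, worm_ids)
    blast_hits: dict[str, list] = {}
    corroboration: dict[str, frozenset] = {}
    if config.blast and Path(config.blast).exists():
        for h in oio.parse_blast_tabular(config.blast):
            gene = h.query_id.rsplit("_", 1)[0]
            blast_hits.setdefault(gene, []).append(h)
        if config.corroboration and Path(config.corroboration).exists():
            corroboration = oio.parse_corroboration(config.corroboration)
    annotations = []
    if config.annotations and Path(config.annotations).exists():
        annotations = oio.load_annotations(config.annotations, PhenotypePanel().vocabulary)
    hnet = (
        load_edge_list(config.human_network, "human")
        if config.human_network and Path(config.human_network).exists()
        else InteractionNetwork("human")
    )
    wnet = (
        load_edge_list(config.worm_network, "worm")
        if config.worm_network and Path(config.worm_network).exists()
        else InteractionNetwork("worm")
    )
    from .synthetic import SyntheticWorldConfig

    world = SyntheticWorld(
        config=SyntheticWorldConfig(seed=config.seed),
        human_universe=human,
        worm_universe=worm,
        focal_genes=tuple(focal),
        truth_orthology={},
        truth_tiers={},
        ensembl=ensembl,
        wormbase=wormbase,
        blast_hits=blast_hits,
        corroboration=corroboration,
        blast_decoys={},
        annotations=annotations,
        human_network=hnet,
        worm_network=wnet,
        human_symbols={g.gene_id: g.symbol for g in human},
    )
    report = run_pipeline_from_world(
        world,
        seed=config.seed,
        n_random=config.n_random,
        reference=(config.reference_conserved, config.reference_total),
        expected_count_cutoff=config.expected_count_cutoff,
        alpha=config.alpha,
        max_extra=config.max_extra,
        criteria=config.criteria,
    )
    if config.outdir:
        report.write(config.outdir)
    return report
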