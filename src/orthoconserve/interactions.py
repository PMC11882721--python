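"""Within-set interactivity, count-model comparisons and interologs.

Networks are simple undirected graphs over gene ids.  A set's
interactivity profile counts edges with both endpoints inside the set
and each member's within-set degree.  Per-gene degree distributions are
compared across sets with Levene's variance test, a Poisson-regression
overdispersion diagnostic, and two-group quasi-Poisson rate-ratio tests
(variance a free multiple of the mean, t-based inference), matching the
standard treatment of overdispersed interaction counts.

For the cross-species step, worm networks are collapsed onto ortholog
groups (within-group edges discarded — co-orthologs of one human gene
are trivially interactive among themselves) and an interaction is
*conserved* when a human within-set edge joins two groups that are also
joined by at least one worm edge (an interolog, generalized over
many-to-many orthology).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ValidationError
from .orthology import OrthologGroup

logger = logging.getLogger("orthoconserve")

__all__ = [
    "InteractionNetwork",
    "InteractivityProfile",
    "DispersionResult",
    "QuasiPoissonResult",
    "ConservedEdge",
    "load_edge_list",
    "profile_set",
    "expand_neighbors",
    "levene_test",
    "overdispersion_test",
    "quasipoisson_compare",
    "group_interactions",
    "conserved_edges",
]


class InteractionNetwork:
    """Simple undirected graph over one species' gene ids."""

    def __init__(self, species: str, edges: Iterable[tuple[str, str]] = ()):
        self.species = species
        self.graph = nx.Graph()
        dropped = 0
        for a, b in edges:
            if a == b:
                dropped += 1
                continue
            self.graph.add_edge(a, b)
        if dropped:
            logger.info("%s network: dropped %d self-loop(s)", species, dropped)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edges(self) -> Iterable[tuple[str, str]]:
        return self.graph.edges()

    def has_edge(self, a: str, b: str) -> bool:
        return self.graph.has_edge(a, b)


def load_edge_list(path, species: str) -> InteractionNetwork:
    """Read an edge-list TSV (gene_a, gene_b[, interaction_type]).

    Duplicate pairs (in either orientation, or differing only in
    interaction type) collapse to one edge; self-loops are dropped.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("gene_a", "gene_b"):
        if col not in df.columns:
            from .exceptions import FormatError

            raise FormatError(f"{path}: missing required column {col!r}")
    return InteractionNetwork(species, zip(df["gene_a"], df["gene_b"]))


@dataclass(frozen=True)
class InteractivityProfile:
    set_label: str
    total_edges: int
    per_gene: dict[str, int]

    def __post_init__(self):
        if sum(self.per_gene.values()) != 2 * self.total_edges:
            raise ValidationError("degree sum does not equal twice the edge count")

    @property
    def degrees(self) -> np.ndarray:
        return np.array([self.per_gene[g] for g in sorted(self.per_gene)])


def profile_set(
    gene_set: Iterable[str], network: InteractionNetwork, label: str = "set"
) -> InteractivityProfile:
    """Count within-set edges and per-gene within-set degrees.

    Genes with no within-set partner are kept with degree 0, so profiles
    of equally sized sets are directly comparable.
    """
    genes = frozenset(gene_set)
    if not genes:
        raise ValidationError("gene set is empty")
    sub = network.graph.subgraph(genes)
    per_gene = {g: (sub.degree(g) if g in sub else 0) for g in genes}
    return InteractivityProfile(
        set_label=label, total_edges=sub.number_of_edges(), per_gene=per_gene
    )


def expand_neighbors(
    gene_set: Iterable[str], network: InteractionNetwork, max_extra: int = 20
) -> frozenset[str]:
    """Add the outside genes best connected into the set.

    Emulates a "max resultant genes" neighbourhood expansion by ranking
    outside genes on their number of edges into the set (ties break to the
    lexicographically smaller gene id).  ``max_extra=0`` is the identity.
    """
    if max_extra < 0:
        raise ValidationError("max_extra must be >= 0")
    genes = frozenset(gene_set)
    if max_extra == 0:
        return genes
    degree_into: dict[str, int] = {}
    for g in genes:
        if g not in network.graph:
            continue
        for nb in network.graph.neighbors(g):
            if nb not in genes:
                degree_into[nb] = degree_into.get(nb, 0) + 1
    ranked = sorted(degree_into, key=lambda x: (-degree_into[x], x))
    return genes | frozenset(ranked[:max_extra])


def levene_test(
    groups: Sequence[Sequence[float]], centering: str = "mean"
) -> tuple[float, float]:
    """Levene's test for equality of variances across groups.

    ``centering="mean"`` is the classical test (one-way ANOVA on absolute
    deviations from the group mean); ``"median"`` is the Brown-Forsythe
    variant, better calibrated on skewed counts.
    """
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValidationError("levene_test needs >= 2 groups with >= 2 values each")
    if centering not in ("mean", "median"):
        raise ValidationError(f"unknown centering {centering!r}")
    f, p = stats.levene(*groups, center=centering)
    return float(f), float(p)


@dataclass(frozen=True)
class DispersionResult:
    dispersion: float  # Pearson X^2 / residual df
    p_value: float  # one-sided auxiliary test of over-dispersion


def _poisson_irls(y: np.ndarray, X: np.ndarray):
    """Poisson regression via statsmodels GLM (IRLS)."""
    import statsmodels.api as sm

    return sm.GLM(y, X, family=sm.families.Poisson()).fit()


def overdispersion_test(
    counts: Sequence[float], groups: Sequence[str]
) -> DispersionResult:
    """Test for over-dispersion in grouped counts.

    Fits a Poisson log-linear model with an intercept plus group
    indicators, reports dispersion = Pearson X^2 / (n - p), and tests
    H0: Var = mu against Var = (1 + alpha) mu one-sidedly through the
    auxiliary regression of ((y - mu)^2 - y) / mu on a constant
    (squared-residual form).
    """
    y = np.asarray(counts, dtype=float)
    labels = np.asarray(groups)
    if y.shape != labels.shape:
        raise ValidationError("counts and groups must have equal length")
    X = pd.get_dummies(pd.Series(labels), drop_first=True, dtype=float)
    X.insert(0, "const", 1.0)
    res = _poisson_irls(y, X.to_numpy())
    mu = res.fittedvalues
    df_resid = len(y) - X.shape[1]
    if df_resid <= 1:
        raise ValidationError("not enough residual degrees of freedom")
    dispersion = float(((y - mu) ** 2 / mu).sum() / df_resid)
    z = ((y - mu) ** 2 - y) / mu
    alpha_hat = z.mean()
    se = z.std(ddof=1) / np.sqrt(len(z))
    if se == 0:
        return DispersionResult(dispersion=dispersion, p_value=1.0)
    t_stat = alpha_hat / se
    p = float(stats.t.sf(t_stat, df=len(z) - 1))
    return DispersionResult(dispersion=dispersion, p_value=p)


@dataclass(frozen=True)
class QuasiPoissonResult:
    rate_ratio: float  # mean(other) / mean(focal)
    std_error: float  # SE of log rate ratio, scaled by sqrt(dispersion)
    p_value: float  # two-sided, t distribution with residual df
    dispersion: float
    df_resid: int


def quasipoisson_compare(
    focal: Sequence[float], other: Sequence[float]
) -> QuasiPoissonResult:
    """Two-group quasi-Poisson comparison of per-gene counts.

    Fits the log-linear model log mu = b0 + b1 * [other] by Poisson IRLS;
    in this saturated two-group design exp(b1) equals the ratio of group
    means exactly.  The Wald standard error is scaled by the square root
    of the Pearson dispersion and the two-sided p-value uses the t
    distribution with n - 2 degrees of freedom.
    """
    y1 = np.asarray(focal, dtype=float)
    y2 = np.asarray(other, dtype=float)
    if y1.size == 0 or y2.size == 0:
        raise ValidationError("both groups must be nonempty")
    if y1.sum() == 0 or y2.sum() == 0:
        raise ValidationError("a group with all-zero counts has an infinite log-rate")
    y = np.concatenate([y1, y2])
    X = np.column_stack([np.ones(y.size), np.r_[np.zeros(y1.size), np.ones(y2.size)]])
    res = _poisson_irls(y, X)
    df_resid = y.size - 2
    mu = res.fittedvalues
    dispersion = float(((y - mu) ** 2 / mu).sum() / df_resid)
    se = float(res.bse[1]) * np.sqrt(dispersion)
    beta1 = float(res.params[1])
    t_stat = beta1 / se if se > 0 else np.inf * np.sign(beta1)
    p = float(2 * stats.t.sf(abs(t_stat), df=df_resid))
    return QuasiPoissonResult(
        rate_ratio=float(np.exp(beta1)),
        std_error=se,
        p_value=p,
        dispersion=dispersion,
        df_resid=df_resid,
    )


@dataclass(frozen=True)
class ConservedEdge:
    human_pair: tuple[str, str]
    worm_pair: tuple[str, str]
    groups: tuple[str, str]


def _gene_to_group(groups: Sequence[OrthologGroup]) -> tuple[dict[str, str], dict[str, str]]:
    """Map human genes and worm genes to their group id (partition check)."""
    human_of: dict[str, str] = {}
    worm_of: dict[str, str] = {}
    for g in groups:
        for h in g.human_genes:
            human_of[h] = g.group_id
        for w in g.worm_genes:
            if w in worm_of:
                raise ValidationError(f"worm gene {w} appears in two groups")
            worm_of[w] = g.group_id
    return human_of, worm_of


def group_interactions(
    worm_network: InteractionNetwork, groups: Sequence[OrthologGroup]
) -> InteractivityProfile:
    """Collapse the worm network onto ortholog groups.

    Within-group edges are discarded; an unordered group pair counts one
    interaction when at least one worm edge joins their members.  The
    per-"gene" map carries per-group degrees in the collapsed graph.
    """
    _, worm_of = _gene_to_group(groups)
    pairs: set[tuple[str, str]] = set()
    for a, b in worm_network.edges():
        ga, gb = worm_of.get(a), worm_of.get(b)
        if ga is None or gb is None or ga == gb:
            continue
        pairs.add((min(ga, gb), max(ga, gb)))
    per_group = {g.group_id: 0 for g in groups}
    for ga, gb in pairs:
        per_group[ga] += 1
        per_group[gb] += 1
    return InteractivityProfile(
        set_label="ortholog_groups", total_edges=len(pairs), per_gene=per_group
    )


def conserved_edges(
    human_network: InteractionNetwork,
    worm_network: InteractionNetwork,
    groups: Sequence[OrthologGroup],
) -> tuple[list[ConservedEdge], tuple[int, int], tuple[int, int]]:
    """Detect interactions present in both species (interologs).

    A human within-set edge (H1, H2) is conserved iff H1 and H2 belong to
    distinct ortholog groups and at least one worm edge joins a member of
    group(H1) to a member of group(H2); the reported worm witness pair is
    the lexicographically smallest.  Symmetrically, a worm group-pair
    interaction is conserved iff some human edge joins the two groups.
    Returns (edges, (human conserved, human total), (worm conserved,
    worm total)).
    """
    human_of, _ = _gene_to_group(groups)
    members = {g.group_id: sorted(g.worm_genes) for g in groups}

    worm_pairs: dict[tuple[str, str], list[tuple[str, str]]] = {}
    _, worm_of = _gene_to_group(groups)
    for a, b in worm_network.edges():
        ga, gb = worm_of.get(a), worm_of.get(b)
        if ga is None or gb is None or ga == gb:
            continue
        key = (min(ga, gb), max(ga, gb))
        worm_pairs.setdefault(key, []).append((a, b) if ga <= gb else (b, a))

    human_edges = [
        (a, b)
        for a, b in human_network.edges()
        if a in human_of and b in human_of
    ]
    human_total = len(human_edges)

    found: list[ConservedEdge] = []
    conserved_group_pairs: set[tuple[str, str]] = set()
    for a, b in sorted(human_edges):
        ga, gb = human_of[a], human_of[b]
        if ga == gb:
            continue
        key = (min(ga, gb), max(ga, gb))
        witnesses = worm_pairs.get(key)
        if not witnesses:
            continue
        wa, wb = min(witnesses)
        if ga > gb:
            wa, wb = wb, wa
        found.append(ConservedEdge(human_pair=(a, b), worm_pair=(wa, wb), groups=(ga, gb)))
        conserved_group_pairs.add(key)

    human_pair_keys = {
        (min(human_of[a], human_of[b]), max(human_of[a], human_of[b]))
        for a, b in human_edges
        if human_of[a] != human_of[b]
    }
    worm_total = len(worm_pairs)
    worm_conserved = len(set(worm_pairs) & human_pair_keys)
    return found, (len(found), human_total), (worm_conserved, worm_total)
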