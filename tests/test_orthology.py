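import dataclasses

import pytest
from hypothesis import given, settings, strategies as st

from orthoconserve import (
    BlastHit,
    CounterpartCriteria,
    FormatError,
    OrthologAssertion,
    ValidationError,
    build_groups,
    evaluate_counterpart,
    filter_protein_coding,
    hits_for_largest_transcript,
    parse_blast_tabular,
    parse_gene_table,
    parse_ortholog_table,
    resolve_orthologs,
)
from orthoconserve.orthology import GeneRecord, OrthologyMap


def make_hit(subject="w1", qlen=500, slen=460, evalue=1e-5, pident=25.0, length=60, query="H1_P1"):
    return BlastHit(
        query_id=query,
        subject_id=subject,
        percent_identity=pident,
        alignment_length=length,
        mismatches=10,
        gap_opens=0,
        qstart=1,
        qend=length,
        sstart=1,
        send=length,
        e_value=evalue,
        bit_score=100.0,
        query_length=qlen,
        subject_length=slen,
    )


CORROBORATED = {f"sp{i}": {"w1"} for i in range(3)}


class TestParsers:
    def test_gene_table_roundtrip(self, tmp_path):
        p = tmp_path / "genes.tsv"
        p.write_text(
            "gene_id\tsymbol\tbiotype\n"
            "g1\tA\tprotein_coding\ng2\tB\tpseudogene\ng3\tC\tprotein_coding\n"
        )
        records = parse_gene_table(p, species="worm")
        assert len(records) == 3
        assert sum(r.biotype == "pseudogene" for r in records) == 1

    def test_gene_table_header_only(self, tmp_path):
        p = tmp_path / "genes.tsv"
        p.write_text("gene_id\tsymbol\tbiotype\n")
        assert parse_gene_table(p, species="worm") == []

    def test_gene_table_unknown_biotype_maps_to_other(self, tmp_path, caplog):
        p = tmp_path / "genes.tsv"
        p.write_text("gene_id\tsymbol\tbiotype\ng1\tA\tlincRNA\n")
        with caplog.at_level("WARNING", logger="orthoconserve"):
            (rec,) = parse_gene_table(p, species="human")
        assert rec.biotype == "other"
        assert "unknown biotype" in caplog.text

    def test_gene_table_duplicate_id_rejected(self, tmp_path):
        p = tmp_path / "genes.tsv"
        p.write_text("gene_id\tsymbol\tbiotype\ng1\tA\tprotein_coding\ng1\tB\tother\n")
        with pytest.raises(ValidationError):
            parse_gene_table(p, species="human")

    def test_gene_table_missing_column(self, tmp_path):
        p = tmp_path / "genes.tsv"
        p.write_text("gene_id\tsymbol\ng1\tA\n")
        with pytest.raises(FormatError):
            parse_gene_table(p, species="human")

    def test_ortholog_table_dedupes(self, tmp_path):
        p = tmp_path / "orth.tsv"
        p.write_text("human_gene\tworm_gene\nH1\tw1\nH1\tw2\nH1\tw1\n")
        assertions = parse_ortholog_table(p, "ensembl")
        assert len(assertions) == 2
        assert len({a.human_gene for a in assertions}) == 1

    def test_ortholog_table_cross_contamination(self, tmp_path):
        p = tmp_path / "orth.tsv"
        p.write_text("human_gene\tworm_gene\nH1\tH2\n")
        with pytest.raises(ValidationError):
            parse_ortholog_table(p, "ensembl", human_universe={"H1", "H2"})

    def test_blast_tabular_parses_fields(self, tmp_path):
        p = tmp_path / "b.tsv"
        p.write_text("H1_P1\tw1\t25.0\t60\t10\t0\t1\t60\t1\t60\t1e-30\t100.0\t500\t460\n")
        (hit,) = parse_blast_tabular(p)
        assert hit.e_value == 1e-30
        assert hit.subject_length == 460

    def test_blast_tabular_reports_bad_line(self, tmp_path):
        p = tmp_path / "b.tsv"
        p.write_text("H1_P1\tw1\tnot_a_number\t60\t10\t0\t1\t60\t1\t60\t1e-30\t100\t500\t460\n")
        with pytest.raises(FormatError, match="line 1"):
            parse_blast_tabular(p)


class TestCounterpartCriteria:
    def test_all_criteria_met_is_accepted(self):
        decisions = evaluate_counterpart([make_hit()], CORROBORATED)
        assert decisions["w1"].accepted

    def test_evalue_boundary_is_strict(self):
        decisions = evaluate_counterpart([make_hit(evalue=1e-3)], CORROBORATED)
        assert decisions["w1"].failed_criteria == (2,)
        # exactly at the threshold is still a rejection ("below" is strict)
        decisions = evaluate_counterpart([make_hit(evalue=1e-4)], CORROBORATED)
        assert 2 in decisions["w1"].failed_criteria

    def test_identity_and_segment_must_hold_in_one_hsp(self):
        # 25% over 40 aa and 19% over 80 aa: neither HSP satisfies both
        hits = [make_hit(pident=25, length=40), make_hit(pident=19, length=80)]
        decisions = evaluate_counterpart(hits, CORROBORATED)
        assert decisions["w1"].failed_criteria == (3,)

    def test_corroboration_counts_distinct_species(self):
        two_species = {"sp0": {"w1"}, "sp1": {"w1"}, "sp2": set()}
        decisions = evaluate_counterpart([make_hit()], two_species)
        assert decisions["w1"].failed_criteria == (4,)

    def test_length_difference_over_100_rejected(self):
        decisions = evaluate_counterpart([make_hit(qlen=500, slen=399)], CORROBORATED)
        assert decisions["w1"].failed_criteria == (1,)
        assert evaluate_counterpart([make_hit(qlen=500, slen=400)], CORROBORATED)["w1"].accepted

    def test_empty_hits_rejected(self):
        with pytest.raises(ValidationError):
            evaluate_counterpart([], CORROBORATED)

    @given(
        relax=st.sampled_from(
            ["max_length_diff", "max_e_value", "min_identity_pct", "min_segment_length", "min_corroborating_species"]
        ),
        qlen=st.integers(60, 800),
        slen=st.integers(60, 800),
        evalue=st.floats(1e-40, 1e-1),
        pident=st.floats(1, 99),
        length=st.integers(1, 400),
        n_species=st.integers(0, 3),
    )
    @settings(max_examples=150, derandomize=True)
    def test_relaxing_a_threshold_never_shrinks_the_accepted_set(
        self, relax, qlen, slen, evalue, pident, length, n_species
    ):
        hit = make_hit(qlen=qlen, slen=slen, evalue=evalue, pident=pident, length=length)
        corr = {f"sp{i}": {"w1"} for i in range(n_species)}
        strict = CounterpartCriteria()
        relaxed_values = {
            "max_length_diff": 200.0,
            "max_e_value": 1e-2,
            "min_identity_pct": 10.0,
            "min_segment_length": 20.0,
            "min_corroborating_species": 1,
        }
        loose = dataclasses.replace(strict, **{relax: relaxed_values[relax]})
        if evaluate_counterpart([hit], corr, strict)["w1"].accepted:
            assert evaluate_counterpart([hit], corr, loose)["w1"].accepted

    def test_largest_transcript_selection(self):
        hits = [make_hit(query="H1_P2", qlen=300), make_hit(query="H1_P1", qlen=500)]
        assert {h.query_id for h in hits_for_largest_transcript(hits)} == {"H1_P1"}
        # tie breaks to the lexicographically smaller id
        hits = [make_hit(query="H1_P2", qlen=500), make_hit(query="H1_P1", qlen=500)]
        assert {h.query_id for h in hits_for_largest_transcript(hits)} == {"H1_P1"}


class TestResolve:
    def test_stepwise_dominance(self):
        ensembl = [OrthologAssertion("H1", "w1", "ensembl")]
        wormbase = [OrthologAssertion("H1", "w2", "wormbase")]
        omap = resolve_orthologs(["H1"], ensembl, wormbase)
        assert omap.orthologs_of("H1") == {"w1"}
        # adding lower-tier evidence never changes the resolved set
        omap2 = resolve_orthologs(
            ["H1"], ensembl, wormbase + [OrthologAssertion("H1", "w3", "wormbase")]
        )
        assert omap2.orthologs_of("H1") == {"w1"}

    def test_step_counts(self):
        ensembl = [OrthologAssertion("H1", "w1", "ensembl")]
        wormbase = [OrthologAssertion("H2", "w2", "wormbase")]
        blast = [OrthologAssertion("H3", "w3", "blastp")]
        omap = resolve_orthologs(["H1", "H2", "H3", "H4"], ensembl, wormbase, blast)
        assert omap.step_counts["ensembl"] == 1
        assert omap.step_counts["wormbase"] == 1
        assert omap.step_counts["blastp"] == 1
        assert omap.step_counts["non_conserved"] == 1
        assert omap.conserved_human_genes == {"H1", "H2", "H3"}

    def test_no_evidence_means_nothing_conserved(self):
        omap = resolve_orthologs(["H1", "H2"], [], [])
        assert omap.step_counts["conserved"] == 0

    def test_unknown_focal_gene_rejected(self):
        with pytest.raises(ValidationError):
            resolve_orthologs(["H9"], [], [], human_universe=["H1"])


class TestFilterAndGroups:
    def worm_universe(self, pseudo=()):
        records = []
        for g in ("w1", "w2", "w3", "w4"):
            bt = "pseudogene" if g in pseudo else "protein_coding"
            records.append(GeneRecord(g, g, bt, "worm"))
        return records

    def test_pseudogenes_removed_from_worm_side_only(self):
        omap = OrthologyMap(
            [OrthologAssertion("H1", "w1", "ensembl"), OrthologAssertion("H1", "w2", "ensembl")]
        )
        coding, pseudo = filter_protein_coding(omap, self.worm_universe(pseudo=("w2",)))
        assert coding == {"w1"} and pseudo == {"w2"}
        assert omap.conserved_human_genes == {"H1"}

    def test_all_pseudogenes_is_not_an_error(self):
        omap = OrthologyMap([OrthologAssertion("H1", "w1", "ensembl")])
        coding, pseudo = filter_protein_coding(omap, self.worm_universe(pseudo=("w1",)))
        assert coding == frozenset() and pseudo == {"w1"}

    def test_transitive_chain_merges_to_single_group(self):
        omap = OrthologyMap(
            [
                OrthologAssertion("H1", "w1", "ensembl"),
                OrthologAssertion("H1", "w2", "ensembl"),
                OrthologAssertion("H2", "w2", "ensembl"),
                OrthologAssertion("H2", "w3", "ensembl"),
                OrthologAssertion("H3", "w3", "ensembl"),
            ]
        )
        (group,) = build_groups(omap)
        assert group.group_id == "H1+H2+H3"
        assert group.worm_genes == {"w1", "w2", "w3"}

    def test_disjoint_map_gives_one_group_per_gene(self):
        omap = OrthologyMap(
            [OrthologAssertion(f"H{i}", f"w{i}", "ensembl") for i in range(12)]
        )
        assert len(build_groups(omap)) == 12

    @given(st.permutations(list(range(8))))
    @settings(max_examples=30, derandomize=True)
    def test_groups_partition_worm_set_invariant_to_order(self, order):
        pairs = [
            ("H1", "w1"), ("H2", "w1"), ("H3", "w2"), ("H3", "w3"),
            ("H4", "w3"), ("H5", "w4"), ("H6", "w5"), ("H6", "w6"),
        ]
        permuted = [pairs[i] for i in order]
        omap = OrthologyMap([OrthologAssertion(h, w, "ensembl") for h, w in permuted])
        groups = build_groups(omap)
        covered = [w for g in groups for w in g.worm_genes]
        assert sorted(covered) == sorted(set(covered))  # pairwise disjoint
        assert set(covered) == set(omap.worm_orthologs)
        assert [g.group_id for g in groups] == ["H1+H2", "H3+H4", "H5", "H6"]
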