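"""Ortholog filter chain, metaexon collapse, and gene-level filters."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from orthostage import (
    AlignmentHit,
    ExonRecord,
    GenomicInterval,
    Metaexon,
    apply_gene_level_filters,
    build_metaexon_table,
    collapse_metaexons,
    filter_orthologous_exons,
    read_metaexon_table,
    write_metaexon_table,
)
from orthostage.align import rank_hits
from orthostage.types import LOW_IDENTITY, MULTI_CHROM, MULTI_GENE, NO_RECIPROCAL, SECOND_HIT, UNANNOTATED


def exon(exon_id="e1", gene="G1", start=1000, end=1150, chrom="chrA1", strand="+"):
    return ExonRecord(exon_id, gene, chrom, start, end, strand, "A")


def hit(exon_id="e1", identity=1.0, species="B", chrom=None, start=5000, strand="+", length=150):
    chrom = chrom or ("chrB1" if species == "B" else "chrA1")
    return AlignmentHit(exon_id, species, chrom, start, start + length, strand, identity, length)


def self_hit(ex, identity=1.0):
    """A self hit at the exon's own annotated locus."""
    return AlignmentHit(
        ex.exon_id, "A", ex.chrom, ex.start, ex.end, ex.strand, identity, ex.end - ex.start
    )


def run_filter(ex, cross, own, **kw):
    retained, best, report = filter_orthologous_exons(
        [ex], {ex.exon_id: rank_hits(cross)}, {ex.exon_id: rank_hits(own)}, **kw
    )
    return retained, report


class TestOrthologFilters:
    @pytest.mark.parametrize(
        "cross_idents, self_extra, expect_retained, expect_reason",
        [
            # all criteria clearly satisfied
            ((0.95, 0.85, 0.80), [], True, None),
            # "at least 92%": boundary inclusive
            ((0.92,), [], True, None),
            ((0.9199,), [], False, LOW_IDENTITY),
            ((0.91,), [], False, LOW_IDENTITY),
            ((), [], False, LOW_IDENTITY),  # no cross hits at all
            # second match > 0.90 in the target genome removes
            ((0.95, 0.905), [], False, SECOND_HIT),
            # exactly 0.90 is tolerated (strict inequality)
            ((0.95, 0.90), [], True, None),
            # second match in the exon's own genome also removes
            ((0.95,), [0.905], False, SECOND_HIT),
            ((0.95,), [0.90], True, None),
        ],
    )
    def test_identity_and_second_hit_boundaries(
        self, cross_idents, self_extra, expect_retained, expect_reason
    ):
        ex = exon()
        cross = [hit(identity=i, start=5000 + 1000 * k) for k, i in enumerate(cross_idents)]
        own = [self_hit(ex)] + [
            hit(species="A", identity=i, start=20_000 + 1000 * k)
            for k, i in enumerate(self_extra)
        ]
        retained, report = run_filter(ex, cross, own)
        assert bool(retained) == expect_retained
        if expect_reason:
            assert report.removed_with_reason(expect_reason) == [ex.exon_id]

    def test_reciprocal_mapping_required(self):
        ex = exon()
        # Best self hit elsewhere on the chromosome: does not map back.
        own = [hit(species="A", identity=1.0, start=30_000)]
        retained, report = run_filter(ex, [hit(identity=0.95)], own)
        assert not retained
        assert report.removed_with_reason(NO_RECIPROCAL) == [ex.exon_id]

    def test_reciprocal_requires_same_strand(self):
        ex = exon(strand="+")
        own = [
            AlignmentHit(ex.exon_id, "A", ex.chrom, ex.start, ex.end, "-", 1.0, 150)
        ]
        retained, report = run_filter(ex, [hit(identity=0.95)], own)
        assert report.removed_with_reason(NO_RECIPROCAL) == [ex.exon_id]

    def test_exact_duplicate_decoy_reports_second_hit_not_reciprocity(self):
        """Two identity-1.0 self hits: cause is the duplication, whichever copy
        wins the rank-1 tie-break."""
        ex = exon(start=50_000, end=50_150)
        own = rank_hits([self_hit(ex), hit(species="A", identity=1.0, start=1000)])
        assert own[0].target_start == 1000  # leftmost wins the tie -> decoy is rank 1
        retained, report = run_filter(ex, [hit(identity=0.98)], list(own))
        assert report.removed_with_reason(SECOND_HIT) == [ex.exon_id]

    def test_missing_self_hit_list_is_an_input_error(self):
        ex = exon()
        with pytest.raises(KeyError, match="same-species hit list"):
            filter_orthologous_exons([ex], {ex.exon_id: [hit()]}, {})

    def test_report_conservation(self):
        exons = [exon(f"e{i}", start=1000 * (i + 1), end=1000 * (i + 1) + 150) for i in range(4)]
        cross = {
            "e0": [hit("e0", 0.95)],
            "e1": [hit("e1", 0.91)],
            "e2": [hit("e2", 0.95), hit("e2", 0.93, start=9000)],
            "e3": [],
        }
        own = {ex.exon_id: [self_hit(ex)] for ex in exons}
        retained, _, report = filter_orthologous_exons(exons, cross, own)
        stage = report.stages[0]
        assert stage.n_input == 4
        assert stage.n_retained == len(retained) == 1
        assert stage.n_removed == 3
        stage.check_conservation()


def brute_force_merge(intervals):
    """Pairwise merge-until-fixpoint oracle over (start, end) tuples.

    Merges overlapping or bookended pairs in arbitrary order until stable.
    """
    ivs = [list(t) for t in intervals]
    changed = True
    while changed:
        changed = False
        for i in range(len(ivs)):
            for j in range(i + 1, len(ivs)):
                a, b = ivs[i], ivs[j]
                if a and b and max(a[0], b[0]) <= min(a[1], b[1]):
                    a[0], a[1] = min(a[0], b[0]), max(a[1], b[1])
                    ivs[j] = []
                    changed = True
        ivs = [iv for iv in ivs if iv]
    return sorted(map(tuple, ivs))


class TestCollapse:
    def collapse_spans(self, intervals, gene="G1"):
        exons = [
            exon(f"e{i}", gene=gene, start=s, end=e) for i, (s, e) in enumerate(intervals)
        ]
        mes = collapse_metaexons(exons)
        return sorted((m.span_a.start, m.span_a.end) for m in mes)

    def test_overlapping_same_gene_intervals_merge(self):
        assert self.collapse_spans([(100, 200), (150, 250)]) == [(100, 250)]

    def test_disjoint_intervals_stay_separate(self):
        assert self.collapse_spans([(100, 200), (300, 400)]) == [(100, 200), (300, 400)]

    def test_bookended_intervals_merge(self):
        assert self.collapse_spans([(100, 200), (200, 300)]) == [(100, 300)]

    def test_different_genes_never_merge(self):
        exons = [exon("e1", gene="G1", start=100, end=200), exon("e2", gene="G2", start=150, end=250)]
        assert len(collapse_metaexons(exons)) == 2

    def test_constituents_and_ordering(self):
        exons = [
            exon("e2", start=500, end=600),
            exon("e1", start=100, end=260),
            exon("e0", start=200, end=300),
        ]
        mes = collapse_metaexons(exons)
        assert [m.span_a.start for m in mes] == [100, 500]
        assert sorted(mes[0].constituent_exons) == ["e0", "e1"]

    @settings(max_examples=100, deadline=None)
    @given(
        st.lists(
            st.tuples(st.integers(0, 500), st.integers(1, 80)).map(
                lambda t: (t[0], t[0] + t[1])
            ),
            min_size=1,
            max_size=20,
        )
    )
    def test_collapse_matches_brute_force_oracle(self, intervals):
        assert self.collapse_spans(intervals) == brute_force_merge(intervals)

    def test_b_coordinates_are_merged_hit_targets(self):
        exons = [exon("e1", start=100, end=200), exon("e2", start=150, end=260)]
        best = {
            "e1": hit("e1", 0.95, start=5000, length=100),
            "e2": hit("e2", 0.95, start=5050, length=110),
        }
        (me,) = collapse_metaexons(exons, best)
        assert me.intervals_b == [GenomicInterval("chrB1", 5000, 5160, "+")]


def metaexon(me_id, gene, a_span, b_span, chrom_a="chrA1", chrom_b="chrB1"):
    return Metaexon(
        metaexon_id=me_id,
        gene_id=gene,
        intervals_a=[GenomicInterval(chrom_a, *a_span)],
        intervals_b=[GenomicInterval(chrom_b, *b_span)],
        constituent_exons=[f"{me_id}.x"],
    )


def annotation_for(metaexons):
    """One annotated exon per metaexon, at its own locus."""
    return [
        ExonRecord(f"{m.metaexon_id}.x", m.gene_id, m.span_a.chrom,
                   m.span_a.start, m.span_a.end, "+", "A")
        for m in metaexons
    ]


class TestGeneLevelFilters:
    def test_overlap_with_second_gene_removes(self):
        m1 = metaexon("m1", "G1", (100, 200), (100, 200))
        anno = annotation_for([m1]) + [
            ExonRecord("other", "G2", "chrA1", 150, 250, "+", "A")
        ]
        kept, report = apply_gene_level_filters([m1], anno, anno)
        assert kept == []
        assert report.removed_with_reason(MULTI_GENE) == ["m1"]

    def test_gene_on_two_chromosomes_in_either_species_removes_all(self):
        m1 = metaexon("m1", "G1", (100, 200), (100, 200))
        m2 = metaexon("m2", "G1", (5000, 5100), (5000, 5100))
        anno_a = annotation_for([m1, m2])
        # In species B the gene is annotated on two chromosomes.
        anno_b = [
            ExonRecord("b1", "G1", "chrB1", 100, 200, "+", "B"),
            ExonRecord("b2", "G1", "chrB2", 100, 200, "+", "B"),
        ]
        kept, report = apply_gene_level_filters([m1, m2], anno_a, anno_b)
        assert kept == []
        assert sorted(report.removed_with_reason(MULTI_CHROM)) == ["m1", "m2"]

    def test_gene_absent_from_other_species_annotation(self):
        m1 = metaexon("m1", "G1", (100, 200), (100, 200))
        kept, report = apply_gene_level_filters([m1], annotation_for([m1]), [])
        assert kept == []
        assert report.removed_with_reason(UNANNOTATED) == ["m1"]

    @pytest.mark.parametrize(
        "intron_b, removed",
        [
            (11_999, False),  # diff 9,999 -> kept
            (12_000, True),   # diff 10,000 -> boundary inclusive, removed
            (13_000, True),
        ],
    )
    def test_intron_difference_boundary(self, intron_b, removed):
        # Species A intron: 2,000 bp; species B intron: intron_b.
        m1 = metaexon("m1", "G1", (100, 200), (100, 200))
        m2 = metaexon("m2", "G1", (2200, 2300), (200 + intron_b, 300 + intron_b))
        anno = annotation_for([m1, m2])
        kept, report = apply_gene_level_filters([m1, m2], anno, anno)
        if removed:
            assert kept == []
            assert sorted(report.removed_with_reason("intron_diff")) == ["m1", "m2"]
        else:
            assert len(kept) == 2

    def test_single_metaexon_gene_passes_intron_filter_vacuously(self):
        m1 = metaexon("m1", "G1", (100, 200), (100, 200))
        anno = annotation_for([m1])
        kept, _ = apply_gene_level_filters([m1], anno, anno)
        assert len(kept) == 1

    def test_intron_side_configurable(self):
        m1 = metaexon("m1", "G1", (100, 200), (100, 200))
        m2 = metaexon("m2", "G1", (2200, 2300), (15_000, 15_100))
        anno = annotation_for([m1, m2])
        kept_up, _ = apply_gene_level_filters([m1, m2], anno, anno, intron_side="upstream")
        assert [m.metaexon_id for m in kept_up] == ["m1"]
        kept_dn, _ = apply_gene_level_filters([m1, m2], anno, anno, intron_side="downstream")
        assert [m.metaexon_id for m in kept_dn] == ["m2"]


class TestTableIO:
    def test_round_trip(self, tmp_path, tiny_genomes):
        sim = tiny_genomes
        table, _ = build_metaexon_table(
            sim.exons_a, sim.exons_b, sim.genome_a, sim.genome_b
        )
        paths = write_metaexon_table(table, tmp_path)
        back = read_metaexon_table(paths["tsv"])
        assert len(back) == len(table)
        for orig, rt in zip(table, back):
            assert orig.metaexon_id == rt.metaexon_id
            assert orig.gene_id == rt.gene_id
            assert orig.span_a == rt.span_a
            assert orig.intervals_b == rt.intervals_b
            assert orig.constituent_exons == rt.constituent_exons

    def test_empty_table_writes_header_only(self, tmp_path):
        paths = write_metaexon_table([], tmp_path)
        assert read_metaexon_table(paths["tsv"]) == []
        assert paths["bed_a"].read_text() == ""


class TestPlantedTruth:
    def test_clean_orthologs_survive_and_faults_get_correct_reasons(self, tiny_genomes):
        sim = tiny_genomes
        table, report = build_metaexon_table(
            sim.exons_a, sim.exons_b, sim.genome_a, sim.genome_b
        )
        retained = {e for m in table for e in m.constituent_exons}
        truth = sim.truth
        clean = truth[truth.expected_retained]
        assert clean.exon_id.isin(retained).all()
        # decoy parents out via second_hit (exon ids in the pre-collapse stage)
        decoys = set(truth.loc[truth.expected_reason == "second_hit", "exon_id"])
        assert decoys == set(report.removed_with_reason("second_hit"))
        # intron-shift flanks out via intron_diff (metaexon ids post-collapse)
        shift_exons = set(truth.loc[truth.expected_reason == "intron_diff", "exon_id"])
        assert not (shift_exons & retained)
        removed_me = report.removed_with_reason("intron_diff")
        assert len(removed_me) == len(shift_exons)

    def test_filter_order_stability(self, tiny_genomes):
        """Second-hit before vs after reciprocity: same retained set on data
        where the two filters flag disjoint exon sets is guaranteed; here we
        assert the full chain is deterministic across repeated runs."""
        sim = tiny_genomes
        t1, r1 = build_metaexon_table(sim.exons_a, sim.exons_b, sim.genome_a, sim.genome_b)
        t2, r2 = build_metaexon_table(sim.exons_a, sim.exons_b, sim.genome_a, sim.genome_b)
        assert [m.metaexon_id for m in t1] == [m.metaexon_id for m in t2]
        assert r1.summary_counts() == r2.summary_counts()
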