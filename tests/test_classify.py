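import pytest

from cucirc.classify import (
    GeneIndex,
    classify_all,
    classify_origin,
    exon_architecture,
    origin_percentages,
    summarize,
)
from cucirc.io_formats import CircRecord, GeneModel


@pytest.fixture
def five_exon_gene():
    # plus strand, exons of 100 nt separated by 200 nt introns
    exons = [(1000 + i * 300, 1099 + i * 300) for i in range(5)]
    return GeneModel.from_genomic_exons("gA", "Chr1", "+", exons)


@pytest.fixture
def index(five_exon_gene):
    return GeneIndex([five_exon_gene])


class TestOriginPrecedence:
    def test_both_ends_in_exons_is_exonic(self, index):
        call = classify_origin(CircRecord("Chr1", 1300, 1699), index)
        assert call.origin == "exonic" and call.parent_gene == "gA"

    def test_span_inside_single_intron_is_intronic(self, index):
        call = classify_origin(CircRecord("Chr1", 1120, 1280), index)
        assert call.origin == "intronic" and call.parent_gene == "gA"

    def test_no_gene_overlap_is_intergenic(self, index):
        call = classify_origin(CircRecord("Chr1", 5000, 5400), index)
        assert call.origin == "intergenic" and call.parent_gene is None

    def test_span_crossing_gene_boundary_is_intergenic(self, index):
        # start before the gene, end inside an exon: neither rule matches
        call = classify_origin(CircRecord("Chr1", 500, 1650), index)
        assert call.origin == "intergenic"

    def test_nested_gene_tie_breaks_by_overlap_then_id(self):
        outer = GeneModel.from_genomic_exons("gOuter", "Chr1", "+", [(100, 1000)])
        inner = GeneModel.from_genomic_exons("gInner", "Chr1", "+", [(300, 600)])
        idx = GeneIndex([outer, inner])
        call = classify_origin(CircRecord("Chr1", 300, 600), idx)
        assert call.origin == "exonic" and call.parent_gene == "gOuter"

    def test_origin_partition_is_exhaustive(self, paper_mix_sim):
        calls = classify_all(paper_mix_sim.circs, paper_mix_sim.genes)
        counts = {"exonic": 0, "intronic": 0, "intergenic": 0}
        for c in calls.values():
            counts[c.origin] += 1
        assert sum(counts.values()) == len(paper_mix_sim.circs)

    def test_origin_calls_recover_simulator_truth(self, tiny_sim):
        calls = classify_all(tiny_sim.circs, tiny_sim.genes)
        for cid in tiny_sim.truth.index:
            assert calls[cid].origin == tiny_sim.truth.loc[cid, "origin"]


class TestExonArchitecture:
    def test_middle_exons(self, five_exon_gene):
        arch = exon_architecture(CircRecord("Chr1", 1300, 2199), five_exon_gene)
        assert (arch.position_class, arch.exon_count) == ("middle", 3)
        assert arch.spliced_length == sum(arch.exon_lengths) == 300

    def test_last_exon_alone(self, five_exon_gene):
        arch = exon_architecture(CircRecord("Chr1", 2200, 2299), five_exon_gene)
        assert (arch.position_class, arch.exon_count) == ("last", 1)

    def test_minus_strand_flips_first_and_last(self):
        exons = [(1000 + i * 300, 1099 + i * 300) for i in range(5)]
        minus = GeneModel.from_genomic_exons("gB", "Chr1", "-", exons)
        # genomically last exon is the transcript's first on the minus strand
        arch = exon_architecture(CircRecord("Chr1", 2200, 2299), minus)
        assert arch.position_class == "first"

    def test_whole_gene_is_first_and_last(self, five_exon_gene):
        arch = exon_architecture(CircRecord("Chr1", 1000, 2299), five_exon_gene)
        assert arch.position_class == "first_and_last"
        assert arch.exon_count == 5

    def test_no_exon_intersection_is_a_contract_violation(self, five_exon_gene):
        with pytest.raises(ValueError, match="no exon"):
            exon_architecture(CircRecord("Chr1", 1120, 1280), five_exon_gene)

    def test_strand_flip_swaps_first_last_and_keeps_middle(self, tiny_sim):
        calls = classify_all(tiny_sim.circs, tiny_sim.genes)
        genes = {g.gene_id: g for g in tiny_sim.genes}
        flipped = {
            gid: GeneModel.from_genomic_exons(
                gid, g.chrom, "-" if g.strand == "+" else "+", g.exons_genomic
            )
            for gid, g in genes.items()
        }
        swap = {"first": "last", "last": "first"}
        for c in tiny_sim.circs:
            call = calls[c.circ_id]
            if call.origin != "exonic":
                continue
            a = exon_architecture(c, genes[call.parent_gene])
            b = exon_architecture(c, flipped[call.parent_gene])
            assert b.position_class == swap.get(a.position_class, a.position_class)
            assert b.exon_count == a.exon_count


class TestSummaries:
    def test_cohort_percentages_from_published_counts(self):
        pct = origin_percentages({"exonic": 2216, "intergenic": 434, "intronic": 137})
        assert pct == {"exonic": 79.51, "intergenic": 15.57, "intronic": 4.92}

    def test_single_exonic_circ_is_all_exonic(self, five_exon_gene):
        circ = CircRecord("Chr1", 1300, 1699)
        calls = classify_all([circ], [five_exon_gene])
        arch = {circ.circ_id: exon_architecture(circ, five_exon_gene)}
        report = summarize(calls, arch, [circ])
        assert report.origin_percent["exonic"] == 100.00
        assert report.median_length == arch[circ.circ_id].spliced_length

    def test_percentages_sum_to_one_hundred(self, paper_mix_sim):
        calls = classify_all(paper_mix_sim.circs, paper_mix_sim.genes)
        report = summarize(calls, {}, paper_mix_sim.circs)
        assert sum(report.origin_percent.values()) == pytest.approx(100.0, abs=0.02)

    def test_empty_input_reports_zero_totals(self):
        report = summarize({}, {}, [])
        assert report.total == 0
        assert report.origin_percent == {}
        assert report.median_length is None

    def test_length_uses_spliced_length_for_exonic(self, five_exon_gene):
        circ = CircRecord("Chr1", 1300, 1999)  # genomic span 700, spliced 300
        calls = classify_all([circ], [five_exon_gene])
        arch = {circ.circ_id: exon_architecture(circ, five_exon_gene)}
        report = summarize(calls, arch, [circ], bin_width=200)
        assert report.lengths[circ.circ_id] == 300
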