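import numpy as np
import pytest

from cucirc.altcirc import (
    LocusGroup,
    dominance_table,
    dominant_isoform,
    group_loci,
    isoform_histogram,
)
from cucirc.classify import OriginCall
from cucirc.io_formats import CircRecord


def _exonic(chrom, start, end, gene):
    return CircRecord(chrom, start, end), OriginCall(
        CircRecord(chrom, start, end).circ_id, "exonic", gene
    )


class TestGrouping:
    def test_same_parent_gene_forms_one_locus(self):
        c1, o1 = _exonic("Chr1", 100, 500, "gA")
        c2, o2 = _exonic("Chr1", 100, 800, "gA")
        groups = group_loci([c1, c2], {o1.circ_id: o1, o2.circ_id: o2})
        assert len(groups) == 1 and groups[0].isoform_count == 2
        assert groups[0].locus_class == "exon"

    def test_overlapping_intergenic_spans_form_one_locus(self):
        c1 = CircRecord("Chr1", 100, 500)
        c2 = CircRecord("Chr1", 400, 900)
        calls = {
            c.circ_id: OriginCall(c.circ_id, "intergenic", None) for c in (c1, c2)
        }
        groups = group_loci([c1, c2], calls)
        assert len(groups) == 1
        assert groups[0].locus_class == "intergenic_region"

    def test_touching_but_disjoint_intergenic_spans_split(self):
        c1 = CircRecord("Chr1", 100, 500)
        c2 = CircRecord("Chr1", 501, 900)
        calls = {
            c.circ_id: OriginCall(c.circ_id, "intergenic", None) for c in (c1, c2)
        }
        assert len(group_loci([c1, c2], calls)) == 2

    def test_different_chromosomes_are_different_loci(self):
        c1 = CircRecord("Chr1", 100, 500)
        c2 = CircRecord("Chr2", 100, 500)
        calls = {
            c.circ_id: OriginCall(c.circ_id, "intergenic", None) for c in (c1, c2)
        }
        assert len(group_loci([c1, c2], calls)) == 2

    def test_mixed_origins_in_one_gene_are_a_mixture_locus(self):
        c1, o1 = _exonic("Chr1", 100, 500, "gA")
        c2 = CircRecord("Chr1", 520, 560)
        o2 = OriginCall(c2.circ_id, "intronic", "gA")
        groups = group_loci([c1, c2], {o1.circ_id: o1, c2.circ_id: o2})
        assert len(groups) == 1 and groups[0].locus_class == "mixture"

    def test_every_circ_lands_in_exactly_one_group(self, paper_mix_sim):
        from cucirc.classify import classify_all

        calls = classify_all(paper_mix_sim.circs, paper_mix_sim.genes)
        groups = group_loci(paper_mix_sim.circs, calls)
        members = [m for g in groups for m in g.members]
        assert sorted(members) == sorted(c.circ_id for c in paper_mix_sim.circs)


class TestIsoformHistogram:
    def test_counts_by_isoform_number(self):
        groups = [
            LocusGroup("l1", ["a", "b"], "exon"),
            LocusGroup("l2", ["c", "d"], "exon"),
            LocusGroup("l3", ["e", "f", "g"], "exon"),
        ]
        assert isoform_histogram(groups) == {2: 2, 3: 1}

    def test_singletons_are_excluded(self):
        groups = [LocusGroup("l1", ["a"], "exon"), LocusGroup("l2", ["b"], "intron")]
        assert isoform_histogram(groups) == {}

    def test_histogram_conserves_multi_isoform_circs(self, paper_mix_sim):
        from cucirc.classify import classify_all

        calls = classify_all(paper_mix_sim.circs, paper_mix_sim.genes)
        groups = group_loci(paper_mix_sim.circs, calls)
        hist = isoform_histogram(groups)
        assert sum(k * v for k, v in hist.items()) == sum(
            g.isoform_count for g in groups if g.isoform_count >= 2
        )


class TestDominance:
    def group(self, *ids):
        return LocusGroup("l", list(ids), "exon")

    def test_clear_dominant(self):
        g = self.group("a", "b", "c")
        assert dominant_isoform(g, {"a": 10, "b": 4, "c": 1}) == "a"

    def test_below_twofold_is_not_dominant(self):
        g = self.group("a", "b")
        assert dominant_isoform(g, {"a": 10, "b": 6}) is None

    def test_exactly_twofold_qualifies(self):
        g = self.group("a", "b")
        assert dominant_isoform(g, {"a": 8, "b": 4}) == "a"

    def test_all_zero_expression_has_no_dominant(self):
        g = self.group("a", "b")
        assert dominant_isoform(g, {"a": 0.0, "b": 0.0}) is None

    def test_zero_competitor_counts_as_satisfied(self):
        g = self.group("a", "b")
        assert dominant_isoform(g, {"a": 0.5, "b": 0.0}) == "a"

    def test_at_most_one_dominant(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            ids = [f"m{i}" for i in range(rng.integers(2, 6))]
            expr = {i: float(rng.lognormal(0, 1.5)) for i in ids}
            g = self.group(*ids)
            dom = dominant_isoform(g, expr)
            if dom is not None:
                others = [expr[i] for i in ids if i != dom]
                assert all(expr[dom] >= 2 * v for v in others)

    def test_planted_fourfold_dominants_are_recovered(self):
        # loci with one 4x isoform over low multiplicative noise
        rng = np.random.default_rng(123)
        recovered = 0
        n_loci = 100
        for k in range(n_loci):
            ids = [f"l{k}_m{i}" for i in range(3)]
            base = rng.lognormal(1.0, 0.3)
            expr = {ids[0]: 4.0 * base * rng.lognormal(0, 0.1)}
            for other in ids[1:]:
                expr[other] = base * rng.lognormal(0, 0.1)
            if dominant_isoform(self.group(*ids), expr) == ids[0]:
                recovered += 1
        assert recovered / n_loci >= 0.95

    def test_dominance_table_reports_na_and_ratio(self):
        groups = [
            LocusGroup("l1", ["a", "b"], "exon"),
            LocusGroup("l2", ["c", "d"], "exon"),
            LocusGroup("l3", ["e"], "exon"),  # singleton: excluded
        ]
        df = dominance_table(groups, {"a": 8, "b": 4, "c": 5, "d": 4, "e": 1})
        assert list(df["locus_id"]) == ["l1", "l2"]
        assert list(df["dominant"]) == ["a", "NA"]
        assert df.loc[0, "dominance_ratio"] == pytest.approx(2.0)
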