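import numpy as np
import pandas as pd
import pytest

from cucirc.io_formats import reverse_complement
from cucirc.target_scan import (
    build_network,
    circ_sequence,
    scan_many,
    scan_target,
    score_site,
)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _rand_seq(rng, n):
    return _BASES[rng.integers(0, 4, n)].tobytes().decode()


@pytest.fixture
def mirna():
    rng = np.random.default_rng(100)
    return _rand_seq(rng, 21)


class TestScoreSite:
    def test_perfect_complement_scores_zero(self, mirna):
        score, sym = score_site(mirna, reverse_complement(mirna))
        assert score == 0.0
        assert sym == "|" * 21

    def test_single_mismatch_outside_seed_costs_one(self, mirna):
        window = list(reverse_complement(mirna))
        # miRNA position 15 pairs window position 21 - 15 = index 6
        idx = 21 - 15
        window[idx] = {"A": "C", "C": "A", "G": "T", "T": "G"}[window[idx]]
        score, _ = score_site(mirna, "".join(window))
        assert score == pytest.approx(1.0)

    def test_wobble_in_seed_costs_doubled_half(self):
        mirna = "A" + "G" + "A" * 19  # G at position 2.. use position 3
        mirna = "AAG" + "A" * 18  # G at position 3
        window = list(reverse_complement(mirna))
        # make target base U(T) opposite miRNA position 3: window index 21-3=18
        window[18] = "T"
        score, sym = score_site(mirna, "".join(window))
        assert score == pytest.approx(1.0)  # 0.5 wobble x2 seed weighting
        assert sym[2] == "o"

    def test_non_nucleotide_symbol_is_an_error(self, mirna):
        with pytest.raises(ValueError, match="non-nucleotide"):
            score_site(mirna, "X" * 21)

    def test_u_and_t_are_equivalent(self, mirna):
        rna = reverse_complement(mirna).replace("T", "U")
        score, _ = score_site(mirna, rna)
        assert score == 0.0

    def test_length_difference_beyond_four_is_an_error(self, mirna):
        with pytest.raises(ValueError, match="within"):
            score_site(mirna, "A" * 30)

    def test_gap_absorbs_length_difference(self, mirna):
        # one extra target base: best alignment needs one gap (>= 2.0)
        window = reverse_complement(mirna) + "A"
        score, _ = score_site(mirna, window)
        assert score >= 2.0


class TestScanTarget:
    def test_planted_perfect_site_found_once(self, mirna):
        rng = np.random.default_rng(1)
        target = _rand_seq(rng, 80) + reverse_complement(mirna) + _rand_seq(rng, 80)
        hits = scan_target(mirna, target, cutoff=4.0)
        assert len(hits) == 1
        assert hits[0].score == 0.0
        assert hits[0].target_start == 81 and hits[0].target_end == 101

    def test_random_target_at_cutoff_zero_is_empty(self, mirna):
        rng = np.random.default_rng(2)
        assert scan_target(mirna, _rand_seq(rng, 2000), cutoff=0.0) == []

    def test_two_distant_sites_give_two_hits(self, mirna):
        rng = np.random.default_rng(3)
        site = reverse_complement(mirna)
        target = site + _rand_seq(rng, 100) + site
        hits = scan_target(mirna, target, cutoff=4.0)
        assert len(hits) == 2

    def test_target_shorter_than_mirna_is_empty(self, mirna):
        assert scan_target(mirna, "ACGT") == []

    def test_lowering_cutoff_never_adds_hits(self, mirna):
        rng = np.random.default_rng(4)
        target = _rand_seq(rng, 500) + reverse_complement(mirna) + _rand_seq(rng, 500)
        loose = {(h.target_start, h.target_end) for h in scan_target(mirna, target, 6.0)}
        tight = {(h.target_start, h.target_end) for h in scan_target(mirna, target, 2.0)}
        assert tight <= loose

    def test_mismatch_positions_preserved_on_opposite_strand_reading(self):
        # reading the site from the opposite strand swaps the roles of the
        # two sequences; Watson-Crick pairs stay paired and a non-wobble
        # mismatch stays a mismatch at the same alignment index
        mirna = ("ACGT" * 6)[:21]  # position 16 (index 15) is 'T'
        window = list(reverse_complement(mirna))
        window[21 - 1 - 15] = "C"  # pairs miRNA index 15 as (T, G): mismatch
        target = "".join(window)
        (hit,) = scan_target(mirna, target, cutoff=10.0)
        (mhit,) = scan_target(
            reverse_complement(target), reverse_complement(mirna), cutoff=10.0,
        )
        assert hit.alignment.count(".") == 1 and hit.alignment[15] == "."
        assert mhit.alignment == hit.alignment
        assert mhit.score == hit.score

    def test_planted_sites_in_simulated_circs_recovered(self, tiny_sim):
        planted = tiny_sim.truth[tiny_sim.truth["planted_mirna"] != ""]
        assert len(planted) > 0
        genes = {g.gene_id: g for g in tiny_sim.genes}
        for cid, row in planted.iterrows():
            circ = next(c for c in tiny_sim.circs if c.circ_id == cid)
            seq = circ_sequence(
                circ, tiny_sim.genome, genes[row["parent_gene"]], wrap=20
            )
            hits = scan_target(tiny_sim.mirnas[row["planted_mirna"]], seq, cutoff=4.0)
            assert any(h.score == 0.0 for h in hits)


class TestNetwork:
    def test_edge_counts(self):
        circ_hits = pd.DataFrame(
            {"mirna": ["m1", "m2"], "target_id": ["circA", "circA"]}
        )
        mrna_hits = pd.DataFrame({"mirna": ["m1", "m2"], "target_id": ["r1", "r2"]})
        edges = build_network(circ_hits, mrna_hits, {"circA"})
        assert len(edges) == 4
        types = [e.edge_type for e in edges]
        assert types.count("circ-miRNA") == 2 and types.count("miRNA-mRNA") == 2

    def test_no_de_circs_gives_empty_network(self):
        circ_hits = pd.DataFrame({"mirna": ["m1"], "target_id": ["circA"]})
        mrna_hits = pd.DataFrame({"mirna": ["m1"], "target_id": ["r1"]})
        assert build_network(circ_hits, mrna_hits, set()) == []

    def test_mrna_edges_require_a_retained_mirna(self):
        circ_hits = pd.DataFrame({"mirna": ["m1"], "target_id": ["circA"]})
        mrna_hits = pd.DataFrame({"mirna": ["m2"], "target_id": ["r1"]})
        edges = build_network(circ_hits, mrna_hits, {"circA"})
        assert [e.edge_type for e in edges] == ["circ-miRNA"]

    def test_wrap_makes_junction_spanning_sites_visible(self, tiny_sim, mirna):
        circ = tiny_sim.circs[0]
        seq = circ_sequence(circ, tiny_sim.genome, None, wrap=20)
        plain = circ_sequence(circ, tiny_sim.genome, None, wrap=0)
        assert seq == plain + plain[:20]
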