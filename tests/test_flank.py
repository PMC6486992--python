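import numpy as np
import pytest

from oracles import brute_force_matches

from cucirc.flank import find_complementary, mite_overlap, scan_flanks
from cucirc.io_formats import CircRecord, reverse_complement

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _rand_seq(rng, n):
    return _BASES[rng.integers(0, 4, n)].tobytes().decode()


class TestFindComplementary:
    def test_planted_repeat_found_once(self):
        rng = np.random.default_rng(0)
        s = _rand_seq(rng, 18)
        up = _rand_seq(rng, 60) + s + _rand_seq(rng, 60)
        down = _rand_seq(rng, 40) + reverse_complement(s) + _rand_seq(rng, 40)
        matches = find_complementary(up, down, min_len=18)
        assert len(matches) == 1
        m = matches[0]
        assert up[m.up_start - 1 : m.up_end] == reverse_complement(
            down[m.down_start - 1 : m.down_end]
        )
        assert m.length >= 18

    def test_seventeen_bases_below_threshold_is_no_match(self):
        rng = np.random.default_rng(1)
        s = _rand_seq(rng, 17)
        up = _rand_seq(rng, 50) + s + _rand_seq(rng, 50)
        down = _rand_seq(rng, 50) + reverse_complement(s) + _rand_seq(rng, 50)
        assert find_complementary(up, down, min_len=18) == []

    def test_n_never_matches(self):
        up = "N" * 30
        down = "N" * 30
        assert find_complementary(up, down, min_len=4) == []

    @pytest.mark.parametrize("min_len", [4, 10, 18])
    def test_equals_brute_force_oracle(self, min_len):
        rng = np.random.default_rng(min_len)
        for _ in range(40):
            up = _rand_seq(rng, 200)
            down = _rand_seq(rng, 200)
            got = {
                (m.up_start, m.up_end, m.down_start, m.down_end)
                for m in find_complementary(up, down, min_len)
            }
            assert got == brute_force_matches(up, down, min_len)

    def test_symmetry_of_arguments(self):
        rng = np.random.default_rng(9)
        s = _rand_seq(rng, 20)
        up = _rand_seq(rng, 30) + s + _rand_seq(rng, 30)
        down = _rand_seq(rng, 30) + reverse_complement(s) + _rand_seq(rng, 30)
        fwd = find_complementary(up, down, 18)
        rev = find_complementary(down, up, 18)
        assert len(fwd) == len(rev)
        assert sorted(m.length for m in fwd) == sorted(m.length for m in rev)

    def test_every_reported_match_verifies(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            up = _rand_seq(rng, 150)
            down = _rand_seq(rng, 150)
            for m in find_complementary(up, down, min_len=5):
                assert up[m.up_start - 1 : m.up_end] == reverse_complement(
                    down[m.down_start - 1 : m.down_end]
                )


class TestScanFlanks:
    def test_planted_flank_circs_are_exactly_the_detected_set(self, tiny_sim):
        table, summary = scan_flanks(
            tiny_sim.circs, tiny_sim.genome,
            window=tiny_sim.config.flank_window, min_len=18,
        )
        detected = set(table.loc[table["has_complementary_flanks"], "circ_id"])
        planted = set(tiny_sim.truth.index[tiny_sim.truth["planted_flank"]])
        assert detected == planted
        assert summary["n_with_complementary_flanks"] == len(planted)

    def test_circ_at_chromosome_start_has_empty_upstream_window(self):
        genome = {"Chr1": "ACGT" * 300}
        table, _ = scan_flanks([CircRecord("Chr1", 1, 40)], genome, window=100)
        assert not table["has_complementary_flanks"].iloc[0]

    def test_wider_window_never_loses_detections(self, tiny_sim):
        t1, _ = scan_flanks(tiny_sim.circs, tiny_sim.genome, window=500, min_len=18)
        t2, _ = scan_flanks(tiny_sim.circs, tiny_sim.genome, window=1000, min_len=18)
        a = t1.set_index("circ_id")["has_complementary_flanks"]
        b = t2.set_index("circ_id")["has_complementary_flanks"]
        assert (b | ~a).all()  # a implies b


class TestMiteOverlap:
    def test_both_windows_covered_is_true(self):
        circ = CircRecord("Chr1", 2000, 3000)
        mites = {"Chr1": [(1500, 1600), (3200, 3300)]}
        table, count = mite_overlap([circ], mites, window=1000)
        assert bool(table["mite_both_flanks"].iloc[0]) and count == 1

    def test_single_window_only_is_false(self):
        circ = CircRecord("Chr1", 2000, 3000)
        mites = {"Chr1": [(1500, 1600)]}
        table, count = mite_overlap([circ], mites, window=1000)
        assert not table["mite_both_flanks"].iloc[0] and count == 0

    def test_empty_mite_set_is_all_false(self, tiny_sim):
        table, count = mite_overlap(tiny_sim.circs, {}, window=1000)
        assert count == 0 and not table["mite_both_flanks"].any()

    def test_unknown_chromosome_warns_and_is_ignored(self):
        circ = CircRecord("Chr1", 2000, 3000)
        mites = {"ChrX": [(1500, 1600)]}
        with pytest.warns(UserWarning, match="ChrX"):
            table, count = mite_overlap(
                [circ], mites, window=1000, known_chroms={"Chr1"}
            )
        assert count == 0

    def test_matches_simulator_truth(self, tiny_sim):
        table, _ = mite_overlap(
            tiny_sim.circs, tiny_sim.mites, window=tiny_sim.config.flank_window
        )
        flags = table.set_index("circ_id")["mite_both_flanks"]
        for cid in tiny_sim.truth.index:
            assert bool(flags[cid]) == bool(tiny_sim.truth.loc[cid, "mite_both"])
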