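"""Bundled reference statistics from a published cucumber salt-stress
circRNA-seq experiment (two tissues x two conditions x two replicates).

These printed per-sample library statistics and headline cohort counts are
shipped as example inputs for the report arithmetic: mapped and junction
percentages, origin percentages, the dominant-isoform fraction and the
canonical splice-signal fraction are all recomputed from these integers by
the package, never stored as percentages.
"""

from __future__ import annotations

from typing import Dict, List, Tuple

from .io_formats import SampleStats

# sample_id -> (total_reads, mapped_reads, junction_reads, n_circRNA)
EXAMPLE_LIBRARY_TABLE: Dict[str, Tuple[int, int, int, int]] = {
    "CK-L1": (64_941_534, 59_683_975, 4_115, 337),
    "CK-L2": (47_247_952, 43_533_334, 3_223, 344),
    "Na-L1": (52_711_124, 48_504_173, 2_814, 277),
    "Na-L2": (56_139_180, 51_545_903, 3_610, 288),
    "CK-R1": (55_226_326, 37_769_894, 28_936, 807),
    "CK-R2": (48_243_900, 33_538_249, 29_102, 924),
    "Na-R1": (55_918_188, 23_369_033, 45_248, 819),
    "Na-R2": (65_369_878, 36_585_168, 37_162, 909),
}

EXAMPLE_READ_LENGTH = 150


def example_sample_stats() -> List[SampleStats]:
    return [
        SampleStats(sid, total, mapped, EXAMPLE_READ_LENGTH)
        for sid, (total, mapped, _, _) in EXAMPLE_LIBRARY_TABLE.items()
    ]


def example_junction_reads() -> Dict[str, int]:
    return {sid: j for sid, (_, _, j, _) in EXAMPLE_LIBRARY_TABLE.items()}


def example_circ_counts() -> Dict[str, int]:
    return {sid: c for sid, (_, _, _, c) in EXAMPLE_LIBRARY_TABLE.items()}


# cohort-level worked-example integers
EXAMPLE_ORIGIN_COUNTS: Dict[str, int] = {
    "exonic": 2216,
    "intergenic": 434,
    "intronic": 137,
}
EXAMPLE_DOMINANT = (845, 1131)  # loci with a dominant isoform / events
EXAMPLE_CANONICAL = (325, 2787)  # canonical-signal circs / all circs
EXAMPLE_DE_COUNTS: Dict[str, Tuple[int, int]] = {  # tissue -> (up, down)
    "root": (991, 943),
    "leaf": (19, 25),
}
EXAMPLE_TISSUE_SETS = {"leaf": 827, "root": 2420, "shared": 460}
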