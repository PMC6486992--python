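"""Back-splice boundary splice signals.

The donor dinucleotide is read on the plus strand immediately 3' of the
junction end, the acceptor immediately 5' of the start, and the pair is
labelled ``donor/acceptor`` in that fixed genomic order.  GT/AG is the
canonical U2 spliceosome signal; CT/AC is its minus-strand equivalent and is
also counted as canonical.  No strand inference is attempted: labels report
exactly what the plus strand reads, matching the reporting convention of the
field (non-canonical labels such as CT/AT or GA/AG are kept as-is).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd

from .io_formats import CircRecord

__all__ = [
    "SpliceSignalPair",
    "CANONICAL_PAIRS",
    "extract_signal",
    "tally_signals",
    "SignalTally",
    "boundary_pfm",
]

CANONICAL_PAIRS = {"GT/AG", "CT/AC"}
_BASES = "ACGT"


@dataclass
class SpliceSignalPair:
    circ_id: str
    donor: str
    acceptor: str

    @property
    def pair_label(self) -> str:
        return f"{self.donor}/{self.acceptor}"

    @property
    def canonical(self) -> bool:
        return self.pair_label in CANONICAL_PAIRS


def _base_at(seq: str, pos: int) -> str:
    """1-based lookup degrading to N outside the chromosome."""
    if 1 <= pos <= len(seq):
        b = seq[pos - 1].upper()
        return b if b in _BASES else "N"
    return "N"


def extract_signal(circ: CircRecord, genome: Mapping[str, str]) -> SpliceSignalPair:
    seq = genome[circ.chrom]
    donor = _base_at(seq, circ.end + 1) + _base_at(seq, circ.end + 2)
    acceptor = _base_at(seq, circ.start - 2) + _base_at(seq, circ.start - 1)
    return SpliceSignalPair(circ.circ_id, donor, acceptor)


@dataclass
class SignalTally:
    table: pd.DataFrame  # pair_label, count, percent, canonical
    top_table: pd.DataFrame  # top-k labels individually, remainder as Others
    total: int
    canonical_count: int
    canonical_percent: float  # one decimal place


def tally_signals(pairs: Sequence[SpliceSignalPair], top_k: int = 10) -> SignalTally:
    """Count signal pairs, canonical fraction, and a top-k + Others table.

    N-containing dinucleotides are never canonical and are folded into the
    "Others" row of the top table.
    """
    counts: Dict[str, int] = {}
    for p in pairs:
        counts[p.pair_label] = counts.get(p.pair_label, 0) + 1
    total = len(pairs)
    labels = sorted(counts, key=lambda k: (-counts[k], k))
    table = pd.DataFrame(
        {
            "pair_label": labels,
            "count": [counts[l] for l in labels],
            "percent": [round(100.0 * counts[l] / total, 2) if total else 0.0 for l in labels],
            "canonical": [l in CANONICAL_PAIRS for l in labels],
        }
    )
    canonical_count = sum(counts.get(l, 0) for l in CANONICAL_PAIRS)
    canonical_percent = round(100.0 * canonical_count / total, 1) if total else 0.0

    clean = [l for l in labels if "N" not in l]
    top = clean[:top_k]
    others = total - sum(counts[l] for l in top)
    rows = [
        {"pair_label": l, "count": counts[l], "canonical": l in CANONICAL_PAIRS}
        for l in top
    ]
    if others > 0 or len(clean) > top_k or len(clean) < len(labels):
        rows.append({"pair_label": "Others", "count": others, "canonical": False})
    top_table = pd.DataFrame(rows, columns=["pair_label", "count", "canonical"])
    return SignalTally(table, top_table, total, canonical_count, canonical_percent)


def boundary_pfm(
    circs: Sequence[CircRecord],
    genome: Mapping[str, str],
    half_window: int = 5,
) -> pd.DataFrame:
    """Position-frequency matrix around both back-splice boundaries.

    Columns cover [start-half_window .. start+half_window-1] (labelled
    ``acceptor_<offset>``) and [end-half_window+1 .. end+half_window]
    (``donor_<offset>``); each column holds base frequencies over all circs,
    normalised over counted (non-N) bases, rows in A/C/G/T order.  This is
    the matrix a consensus sequence logo is rendered from.
    """
    if half_window < 1:
        raise ValueError("half_window must be >= 1")
    acceptor_offsets = list(range(-half_window, half_window))
    donor_offsets = list(range(-half_window + 1, half_window + 1))
    columns = [f"acceptor_{o:+d}" for o in acceptor_offsets] + [
        f"donor_{o:+d}" for o in donor_offsets
    ]
    counts = np.zeros((4, len(columns)), dtype=float)
    base_idx = {b: i for i, b in enumerate(_BASES)}
    for c in circs:
        seq = genome[c.chrom]
        positions = [c.start + o for o in acceptor_offsets] + [
            c.end + o for o in donor_offsets
        ]
        for j, pos in enumerate(positions):
            b = _base_at(seq, pos)
            if b in base_idx:
                counts[base_idx[b], j] += 1
    sums = counts.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        freqs = np.where(sums > 0, counts / np.where(sums > 0, sums, 1), 0.0)
    return pd.DataFrame(freqs, index=list(_BASES), columns=columns)
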