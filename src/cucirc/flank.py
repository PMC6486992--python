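"""Reverse-complementary flanking sequences and MITE overlap.

Paired inverted repeats in the sequences flanking a back-splice junction can
base-pair and bring the two splice sites together, so the fraction of
circRNAs with sufficiently long complementary flanks (and with miniature
inverted-repeat transposable elements, MITEs, on both sides) measures how
much pairing-driven circularization can explain the cohort.

Matching is exact and ungapped: a hit is a maximal substring of the upstream
window equal to the reverse complement of a substring of the downstream
window, at least ``min_len`` bases long (default 18).  The search is
seed-and-extend over a k-mer index of the reverse-complemented downstream
window (k = min(min_len, 12)), which is deterministic and directly checkable
against a brute-force substring scan.  N never matches anything.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

import pandas as pd
from intervaltree import IntervalTree

from .io_formats import CircRecord, reverse_complement

__all__ = [
    "FlankMatch",
    "find_complementary",
    "scan_flanks",
    "mite_overlap",
]


@dataclass(frozen=True)
class FlankMatch:
    """An exact reverse-complement match between flank windows (1-based)."""

    up_start: int
    up_end: int
    down_start: int
    down_end: int

    @property
    def length(self) -> int:
        return self.up_end - self.up_start + 1


def find_complementary(
    up_seq: str, down_seq: str, min_len: int = 18
) -> List[FlankMatch]:
    """All maximal exact reverse-complement matches of length >= min_len.

    Positions are 1-based within each input sequence.  Contained
    (non-maximal) matches are suppressed.
    """
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    up = up_seq.upper()
    rc = reverse_complement(down_seq.upper())
    n_up, n_rc = len(up), len(rc)
    if n_up < min_len or n_rc < min_len:
        return []

    k = min(min_len, 12)
    index: Dict[str, List[int]] = {}
    for j in range(n_rc - k + 1):
        kmer = rc[j : j + k]
        if "N" not in kmer:
            index.setdefault(kmer, []).append(j)

    # per-diagonal (i - j) intervals already covered by a reported extension
    covered: Dict[int, Set[int]] = {}
    raw: Set[Tuple[int, int, int]] = set()
    for i in range(n_up - k + 1):
        kmer = up[i : i + k]
        if "N" in kmer:
            continue
        for j in index.get(kmer, ()):
            d = i - j
            if i in covered.get(d, ()):
                continue
            # extend left
            i0, j0 = i, j
            while i0 > 0 and j0 > 0 and up[i0 - 1] == rc[j0 - 1] and up[i0 - 1] != "N":
                i0 -= 1
                j0 -= 1
            # extend right
            i1, j1 = i + k - 1, j + k - 1
            while (
                i1 + 1 < n_up
                and j1 + 1 < n_rc
                and up[i1 + 1] == rc[j1 + 1]
                and up[i1 + 1] != "N"
            ):
                i1 += 1
                j1 += 1
            covered.setdefault(d, set()).update(range(i0, i1 + 1))
            length = i1 - i0 + 1
            if length >= min_len:
                raw.add((i0, j0, length))

    matches = []
    for i0, j0, length in raw:
        j1 = j0 + length - 1
        down_start0 = n_rc - 1 - j1  # 0-based in down_seq
        matches.append(
            FlankMatch(
                up_start=i0 + 1,
                up_end=i0 + length,
                down_start=down_start0 + 1,
                down_end=down_start0 + length,
            )
        )
    matches.sort(key=lambda m: (m.up_start, m.down_start, m.length))
    return matches


def _windows(
    circ: CircRecord, chrom_len: int, window: int
) -> Tuple[Tuple[int, int], Tuple[int, int]]:
    """Clamped upstream/downstream flank windows; (1, 0) style when empty."""
    up = (max(1, circ.start - window), circ.start - 1)
    down = (circ.end + 1, min(chrom_len, circ.end + window))
    return up, down


def scan_flanks(
    circs: Sequence[CircRecord],
    genome: Mapping[str, str],
    window: int = 1000,
    min_len: int = 18,
) -> Tuple[pd.DataFrame, Dict[str, float]]:
    """Search every circRNA's flank windows for complementary pairs.

    Upstream window = [start-window, start-1], downstream = [end+1,
    end+window], clamped at chromosome edges; ChrUn spacer Ns can never
    participate in a match.  Returns a per-circ table and a cohort summary
    (count and percentage with complementary flanks).
    """
    rows = []
    for c in circs:
        seq = genome[c.chrom]
        (u0, u1), (d0, d1) = _windows(c, len(seq), window)
        up = seq[u0 - 1 : u1] if u1 >= u0 else ""
        down = seq[d0 - 1 : d1] if d1 >= d0 else ""
        matches = find_complementary(up, down, min_len) if up and down else []
        rows.append(
            {
                "circ_id": c.circ_id,
                "n_matches": len(matches),
                "max_match_len": max((m.length for m in matches), default=0),
                "has_complementary_flanks": bool(matches),
            }
        )
    table = pd.DataFrame(
        rows,
        columns=["circ_id", "n_matches", "max_match_len", "has_complementary_flanks"],
    )
    n = len(table)
    count = int(table["has_complementary_flanks"].sum()) if n else 0
    summary = {
        "n_circs": float(n),
        "n_with_complementary_flanks": float(count),
        "percent_with_complementary_flanks": round(100.0 * count / n, 2) if n else 0.0,
    }
    return table, summary


def mite_overlap(
    circs: Sequence[CircRecord],
    mites: Mapping[str, Sequence[Tuple[int, int]]],
    window: int = 1000,
    known_chroms: Optional[Set[str]] = None,
) -> Tuple[pd.DataFrame, int]:
    """Flag circRNAs whose upstream AND downstream windows each overlap a MITE.

    MITE intervals are 1-based inclusive per chromosome; intervals on
    chromosomes absent from ``known_chroms`` (when given) are ignored with a
    warning.  Returns the per-circ table and the cohort count of circs with
    MITEs on both sides.
    """
    trees: Dict[str, IntervalTree] = {}
    for chrom, ivals in mites.items():
        if known_chroms is not None and chrom not in known_chroms:
            warnings.warn(f"MITE intervals on unknown chromosome {chrom!r} ignored")
            continue
        tree = trees.setdefault(chrom, IntervalTree())
        for s, e in ivals:
            tree.addi(s, e + 1)

    rows = []
    for c in circs:
        (u0, u1), (d0, d1) = _windows(c, 10**12, window)
        tree = trees.get(c.chrom)
        up_hit = bool(tree is not None and u1 >= u0 and tree.overlap(u0, u1 + 1))
        down_hit = bool(tree is not None and d1 >= d0 and tree.overlap(d0, d1 + 1))
        rows.append(
            {
                "circ_id": c.circ_id,
                "mite_upstream": up_hit,
                "mite_downstream": down_hit,
                "mite_both_flanks": up_hit and down_hit,
            }
        )
    table = pd.DataFrame(
        rows, columns=["circ_id", "mite_upstream", "mite_downstream", "mite_both_flanks"]
    )
    return table, int(table["mite_both_flanks"].sum()) if len(table) else 0
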