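"""Genomic origin calls, exon architecture, and cohort summaries.

Origin precedence: a junction whose two back-splice coordinates both fall
inside exon intervals of one gene is exonic; otherwise a junction whose whole
span lies inside a single intron of one gene is intronic; everything else
(including spans crossing gene boundaries or several genes) is intergenic.
On nested/ambiguous genes the parent is the gene with the largest span
overlap, ties broken lexicographically.  Exon position classes (first /
middle / last) are assigned in transcript orientation, so the biologically
first exon of a minus-strand gene is the genomically last one.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .io_formats import CircRecord, GeneModel

__all__ = [
    "OriginCall",
    "ExonArchitecture",
    "GeneIndex",
    "classify_origin",
    "classify_all",
    "exon_architecture",
    "SummaryReport",
    "summarize",
]

ORIGINS = ("exonic", "intronic", "intergenic")


@dataclass
class OriginCall:
    circ_id: str
    origin: str
    parent_gene: Optional[str] = None

    def __post_init__(self) -> None:
        if self.origin not in ORIGINS:
            raise ValueError(f"invalid origin {self.origin!r}")
        if (self.parent_gene is not None) != (self.origin in {"exonic", "intronic"}):
            raise ValueError("parent_gene present iff origin is exonic/intronic")


@dataclass
class ExonArchitecture:
    circ_id: str
    position_class: str  # first | middle | last | first_and_last
    exon_count: int
    exon_lengths: List[int]
    spliced_length: int

    def __post_init__(self) -> None:
        if self.exon_count != len(self.exon_lengths):
            raise ValueError("exon_count must equal len(exon_lengths)")
        if self.spliced_length != sum(self.exon_lengths):
            raise ValueError("spliced_length must equal sum(exon_lengths)")


class GeneIndex:
    """Interval index over gene models for fast origin lookups."""

    def __init__(self, genes: Sequence[GeneModel]):
        self.genes: Dict[str, GeneModel] = {g.gene_id: g for g in genes}
        self._trees: Dict[str, IntervalTree] = {}
        for g in genes:
            tree = self._trees.setdefault(g.chrom, IntervalTree())
            tree.addi(g.start, g.end + 1, g.gene_id)

    def overlapping(self, chrom: str, start: int, end: int) -> List[GeneModel]:
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        hits = sorted(iv.data for iv in tree.overlap(start, end + 1))
        return [self.genes[gid] for gid in hits]


def _overlap(a: Tuple[int, int], b: Tuple[int, int]) -> int:
    return max(0, min(a[1], b[1]) - max(a[0], b[0]) + 1)


def classify_origin(circ: CircRecord, index: GeneIndex) -> OriginCall:
    candidates = index.overlapping(circ.chrom, circ.start, circ.end)

    def pick(genes: List[GeneModel]) -> GeneModel:
        return max(
            genes,
            key=lambda g: (_overlap((circ.start, circ.end), (g.start, g.end)), g.gene_id),
        ) if len(genes) > 1 else genes[0]

    exonic = [
        g
        for g in candidates
        if any(s <= circ.start <= e for s, e in g.exons_genomic)
        and any(s <= circ.end <= e for s, e in g.exons_genomic)
    ]
    if exonic:
        return OriginCall(circ.circ_id, "exonic", pick(exonic).gene_id)

    intronic = [
        g
        for g in candidates
        if any(s <= circ.start and circ.end <= e for s, e in g.introns_genomic)
    ]
    if intronic:
        return OriginCall(circ.circ_id, "intronic", pick(intronic).gene_id)

    return OriginCall(circ.circ_id, "intergenic", None)


def classify_all(
    circs: Sequence[CircRecord], genes: Sequence[GeneModel]
) -> Dict[str, OriginCall]:
    index = GeneIndex(genes)
    return {c.circ_id: classify_origin(c, index) for c in circs}


def exon_architecture(circ: CircRecord, gene: GeneModel) -> ExonArchitecture:
    """Exon-level architecture of an exonic circRNA within its parent gene.

    Exon counts/lengths come from parent exons intersected with the circ
    span; the position class comes from the transcript-orientation indices of
    the covered exons.
    """
    n = len(gene.exons)
    covered: List[Tuple[int, Tuple[int, int]]] = []  # (transcript index, clipped span)
    for idx, (s, e) in enumerate(gene.exons, start=1):
        cs, ce = max(s, circ.start), min(e, circ.end)
        if cs <= ce:
            covered.append((idx, (cs, ce)))
    if not covered:
        raise ValueError(
            f"{circ.circ_id}: intersects no exon of {gene.gene_id} "
            "(should not have been called exonic)"
        )
    indices = {idx for idx, _ in covered}
    has_first, has_last = 1 in indices, n in indices
    if has_first and has_last:
        position_class = "first_and_last"
    elif has_first:
        position_class = "first"
    elif has_last:
        position_class = "last"
    else:
        position_class = "middle"
    lengths = [e - s + 1 for _, (s, e) in covered]
    return ExonArchitecture(circ.circ_id, position_class, len(covered), lengths, sum(lengths))


@dataclass
class SummaryReport:
    total: int
    origin_counts: Dict[str, int]
    origin_percent: Dict[str, float]
    chromosome_counts: Dict[str, int]
    position_class_counts: Dict[str, int]
    exon_count_hist: Dict[int, int]
    lengths: pd.Series
    length_hist: pd.DataFrame  # columns bin_start, bin_end, count
    median_length: Optional[float]

    def to_frames(self) -> Dict[str, pd.DataFrame]:
        return {
            "origin": pd.DataFrame(
                {
                    "origin": list(self.origin_counts),
                    "count": list(self.origin_counts.values()),
                    "percent": [self.origin_percent[o] for o in self.origin_counts],
                }
            ),
            "chromosome": pd.DataFrame(
                {
                    "chrom": list(self.chromosome_counts),
                    "count": list(self.chromosome_counts.values()),
                }
            ),
            "length_hist": self.length_hist,
        }


def origin_percentages(counts: Mapping[str, int]) -> Dict[str, float]:
    total = sum(counts.values())
    if total == 0:
        return {}
    return {k: round(100.0 * v / total, 2) for k, v in counts.items()}


def summarize(
    calls: Mapping[str, OriginCall],
    architectures: Mapping[str, ExonArchitecture],
    circs: Sequence[CircRecord],
    bin_width: int = 200,
) -> SummaryReport:
    """Cohort summary: origin counts/percentages, chromosome distribution,
    length histogram (spliced length where exon structure is known, genomic
    span otherwise) and the median length."""
    origin_counts = {o: 0 for o in ORIGINS}
    chrom_counts: Dict[str, int] = {}
    pos_counts: Dict[str, int] = {}
    exon_hist: Dict[int, int] = {}
    lengths: Dict[str, int] = {}
    for c in circs:
        call = calls[c.circ_id]
        origin_counts[call.origin] += 1
        chrom_counts[c.chrom] = chrom_counts.get(c.chrom, 0) + 1
        arch = architectures.get(c.circ_id)
        if call.origin == "exonic" and arch is not None:
            lengths[c.circ_id] = arch.spliced_length
            pos_counts[arch.position_class] = pos_counts.get(arch.position_class, 0) + 1
            exon_hist[arch.exon_count] = exon_hist.get(arch.exon_count, 0) + 1
        else:
            lengths[c.circ_id] = c.span

    total = len(circs)
    length_series = pd.Series(lengths, dtype=float)
    if total:
        max_len = int(length_series.max())
        edges = np.arange(0, max_len + bin_width, bin_width)
        counts, _ = np.histogram(length_series.values, bins=np.append(edges, edges[-1] + bin_width))
        hist = pd.DataFrame(
            {
                "bin_start": edges,
                "bin_end": edges + bin_width - 1,
                "count": counts.astype(int),
            }
        )
        hist = hist[hist["count"] > 0].reset_index(drop=True)
        median = float(length_series.median())
    else:
        hist = pd.DataFrame(columns=["bin_start", "bin_end", "count"])
        median = None

    return SummaryReport(
        total=total,
        origin_counts=origin_counts,
        origin_percent=origin_percentages(origin_counts),
        chromosome_counts=dict(sorted(chrom_counts.items())),
        position_class_counts=dict(sorted(pos_counts.items())),
        exon_count_hist=dict(sorted(exon_hist.items())),
        lengths=length_series,
        length_hist=hist,
        median_length=median,
    )
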