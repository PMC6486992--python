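"""Alternative-circularization loci and dominant isoforms.

Distinct back-splice junctions arising from one locus are alternative
circularization isoforms.  Genic circRNAs (exonic or intronic) are grouped
by parent gene; intergenic circRNAs are grouped by connected components of
genomic-span overlap (>= 1 bp).  A locus with >= 2 isoforms is an
alternative-circularization locus, and its dominant isoform (if any) is the
member whose mean abundance is at least twofold that of every other member.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import pandas as pd

from .classify import OriginCall
from .io_formats import CircRecord

__all__ = [
    "LocusGroup",
    "group_loci",
    "isoform_histogram",
    "dominant_isoform",
    "dominance_table",
]

_CLASS_BY_ORIGIN = {
    "exonic": "exon",
    "intronic": "intron",
    "intergenic": "intergenic_region",
}


@dataclass
class LocusGroup:
    locus_id: str
    members: List[str]
    locus_class: str  # exon | intron | intergenic_region | mixture

    @property
    def isoform_count(self) -> int:
        return len(self.members)


def _locus_class(origins: Sequence[str]) -> str:
    unique = set(origins)
    if len(unique) == 1:
        return _CLASS_BY_ORIGIN[unique.pop()]
    return "mixture"


def group_loci(
    circs: Sequence[CircRecord], calls: Mapping[str, OriginCall]
) -> List[LocusGroup]:
    by_gene: Dict[str, List[CircRecord]] = {}
    intergenic: List[CircRecord] = []
    for c in circs:
        call = calls[c.circ_id]
        if call.parent_gene is not None:
            by_gene.setdefault(call.parent_gene, []).append(c)
        else:
            intergenic.append(c)

    groups: List[LocusGroup] = []
    for gene_id in sorted(by_gene):
        members = sorted(by_gene[gene_id], key=lambda c: (c.start, c.end))
        groups.append(
            LocusGroup(
                f"locus:{gene_id}",
                [c.circ_id for c in members],
                _locus_class([calls[c.circ_id].origin for c in members]),
            )
        )

    # connected components of >=1 bp span overlap, per chromosome
    by_chrom: Dict[str, List[CircRecord]] = {}
    for c in intergenic:
        by_chrom.setdefault(c.chrom, []).append(c)
    for chrom in sorted(by_chrom):
        chunk = sorted(by_chrom[chrom], key=lambda c: (c.start, c.end))
        component: List[CircRecord] = []
        comp_end = -1
        k = 0
        for c in chunk:
            if component and c.start > comp_end:
                k += 1
                groups.append(_intergenic_group(chrom, k, component, calls))
                component = []
                comp_end = -1
            component.append(c)
            comp_end = max(comp_end, c.end)
        if component:
            k += 1
            groups.append(_intergenic_group(chrom, k, component, calls))
    return groups


def _intergenic_group(
    chrom: str, k: int, members: List[CircRecord], calls: Mapping[str, OriginCall]
) -> LocusGroup:
    return LocusGroup(
        f"locus:{chrom}:ig{k}",
        [c.circ_id for c in members],
        _locus_class([calls[c.circ_id].origin for c in members]),
    )


def isoform_histogram(groups: Sequence[LocusGroup]) -> Dict[int, int]:
    """Number of loci per isoform count, restricted to multi-isoform loci."""
    hist: Dict[int, int] = {}
    for g in groups:
        if g.isoform_count >= 2:
            hist[g.isoform_count] = hist.get(g.isoform_count, 0) + 1
    return dict(sorted(hist.items()))


def dominant_isoform(
    group: LocusGroup, expression: Mapping[str, float]
) -> Optional[str]:
    """The member at least twofold higher expressed than every other member.

    ``expression`` maps circ_id to mean SRPBM over all samples.  Returns None
    when no member qualifies (including the all-zero case); a twofold margin
    over a zero-expressed competitor counts as satisfied.
    """
    if group.isoform_count < 2:
        raise ValueError("dominance is defined for multi-isoform loci only")
    values = {m: float(expression.get(m, 0.0)) for m in group.members}
    best = max(sorted(values), key=lambda m: values[m])
    if values[best] <= 0.0:
        return None
    ok = all(values[best] >= 2.0 * v for m, v in values.items() if m != best)
    return best if ok else None


def dominance_table(
    groups: Sequence[LocusGroup], expression: Mapping[str, float]
) -> pd.DataFrame:
    """Per multi-isoform locus: class, members, dominant member and ratio."""
    rows = []
    for g in groups:
        if g.isoform_count < 2:
            continue
        dom = dominant_isoform(g, expression)
        values = sorted(
            (float(expression.get(m, 0.0)) for m in g.members), reverse=True
        )
        ratio = values[0] / values[1] if values[1] > 0 else float("inf") if values[0] > 0 else float("nan")
        rows.append(
            {
                "locus_id": g.locus_id,
                "locus_class": g.locus_class,
                "isoform_count": g.isoform_count,
                "members": ",".join(g.members),
                "dominant": dom if dom is not None else "NA",
                "dominance_ratio": ratio,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "locus_id",
            "locus_class",
            "isoform_count",
            "members",
            "dominant",
            "dominance_ratio",
        ],
    )
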