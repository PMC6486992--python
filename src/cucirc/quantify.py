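"""SRPBM normalization and the multi-sample expression matrix.

SRPBM (spliced reads per billion mapped) divides the junction-read count by
the mapped library size expressed in billions and by the read length, giving
an abundance unit comparable across libraries of different depth:

    SRPBM = junction_reads / (mapped_reads / 1e9) / read_length
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io_formats import CircRecord, SampleStats

__all__ = ["srpbm", "ExpressionMatrix", "build_matrix", "correlate_with_parents"]


def srpbm(junction_reads: float, mapped_reads: float, read_length: float) -> float:
    if mapped_reads <= 0:
        raise ValueError("mapped_reads must be > 0 (undefined denominator)")
    if read_length <= 0:
        raise ValueError("read_length must be > 0")
    return junction_reads / (mapped_reads / 1e9) / read_length


@dataclass
class ExpressionMatrix:
    """Raw junction-read counts and SRPBM values, circs x samples."""

    raw: pd.DataFrame
    srpbm: pd.DataFrame
    stats: List[SampleStats]

    @property
    def circ_ids(self) -> List[str]:
        return list(self.raw.index)

    @property
    def sample_ids(self) -> List[str]:
        return list(self.raw.columns)

    def mean_srpbm(self, samples: Sequence[str] | None = None) -> pd.Series:
        cols = list(samples) if samples is not None else self.sample_ids
        return self.srpbm[cols].mean(axis=1)

    def write(self, raw_path, srpbm_path) -> None:
        self.raw.to_csv(raw_path, sep="\t", index_label="circ_id")
        self.srpbm.to_csv(srpbm_path, sep="\t", index_label="circ_id", float_format="%.6g")


def build_matrix(
    tables: Mapping[str, Sequence[CircRecord]],
    stats: Sequence[SampleStats],
) -> ExpressionMatrix:
    """Assemble per-sample junction tables into one matrix keyed on circ_id.

    The row set is the union of circs over samples; a circ absent from a
    sample gets raw count 0 and SRPBM 0.  Column order follows ``stats``.
    """
    stat_ids = [s.sample_id for s in stats]
    unknown = set(tables) - set(stat_ids)
    if unknown:
        raise KeyError(f"samples without library stats: {sorted(unknown)}")

    keys = sorted(
        {(r.chrom, r.start, r.end) for recs in tables.values() for r in recs}
    )
    index = [CircRecord(*k).circ_id for k in keys]
    raw = pd.DataFrame(0, index=index, columns=stat_ids, dtype=np.int64)
    for sample_id, recs in tables.items():
        for r in recs:
            raw.loc[r.circ_id, sample_id] = r.junction_reads

    srpbm_df = raw.astype(float).copy()
    for s in stats:
        srpbm_df[s.sample_id] = [
            srpbm(v, s.mapped_reads, s.read_length) for v in raw[s.sample_id]
        ]
    return ExpressionMatrix(raw, srpbm_df, list(stats))


@dataclass
class CorrelationResult:
    r: float
    p_value: float
    n: int


def correlate_with_parents(
    circ_abundance: Mapping[str, float],
    gene_abundance: Mapping[str, float],
    parent_map: Mapping[str, str],
) -> CorrelationResult:
    """Pearson correlation of circRNA vs parental-gene abundance.

    Both abundances are log2(x + 1)-transformed before correlating; entries
    are paired through ``parent_map`` (circ_id -> gene_id), restricted to
    genic circs with an abundance on both sides.
    """
    xs: List[float] = []
    ys: List[float] = []
    for circ_id, gene_id in parent_map.items():
        if circ_id in circ_abundance and gene_id in gene_abundance:
            xs.append(np.log2(circ_abundance[circ_id] + 1.0))
            ys.append(np.log2(gene_abundance[gene_id] + 1.0))
    if len(xs) < 3:
        raise ValueError(f"need >= 3 circ/parent pairs, got {len(xs)}")
    r, p = sps.pearsonr(xs, ys)
    return CorrelationResult(float(r), float(p), len(xs))
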