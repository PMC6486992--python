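"""Pipeline orchestration and run reports.

``run_pipeline`` executes the full characterization over one dataset:
origin classification and exon architecture, alternative circularization,
splice signals, flanking complementary sequences and MITEs, SRPBM
quantification and parental-gene correlation, per-tissue differential
expression with the global abundance-shift comparison, term enrichment on
parents of differential circs, and the circRNA-miRNA-mRNA network.  The
report bundle also carries a per-sample library summary (total reads,
mapped reads with percentage, junction reads with percentage, circRNA
count, plus an All row of column sums) and tissue overlap counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Dict, FrozenSet, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from . import altcirc, classify, diffexpr, enrich, flank, quantify, splicesig, target_scan
from .enrich import read_gene_terms
from .io_formats import (
    CircRecord,
    GeneModel,
    SampleStats,
    read_genome_fasta,
    read_gff3,
    read_junction_table,
    read_mite_bed,
    read_sample_stats,
)
from .quantify import ExpressionMatrix
from .simulate import SimResult

logger = logging.getLogger("cucirc")

__all__ = ["PipelineInputs", "PipelineReport", "run_pipeline", "table1_summary", "tissue_overlap"]


@dataclass
class PipelineInputs:
    genome: Dict[str, str]
    genes: List[GeneModel]
    tables: Dict[str, List[CircRecord]]
    stats: List[SampleStats]
    mites: Dict[str, List[Tuple[int, int]]] = field(default_factory=dict)
    gene_abundance: Optional[pd.DataFrame] = None
    mirnas: Dict[str, str] = field(default_factory=dict)
    mrnas: Dict[str, str] = field(default_factory=dict)
    gene_terms: Dict[str, Set[str]] = field(default_factory=dict)
    tissues: Tuple[str, ...] = ("L", "R")
    conditions: Tuple[str, ...] = ("CK", "Na")

    @classmethod
    def from_sim(cls, sim: SimResult) -> "PipelineInputs":
        return cls(
            genome=sim.genome,
            genes=sim.genes,
            tables=sim.tables,
            stats=sim.stats,
            mites=sim.mites,
            gene_abundance=sim.gene_abundance,
            mirnas=sim.mirnas,
            mrnas=sim.mrnas,
            gene_terms=sim.gene_terms,
            tissues=sim.config.tissues,
            conditions=sim.config.conditions,
        )

    @classmethod
    def from_dir(cls, path, **kwargs) -> "PipelineInputs":
        path = Path(path)
        tables = {
            p.stem: read_junction_table(p)
            for p in sorted((path / "junctions").glob("*.tsv"))
        }
        mites_path = path / "mites.bed"
        terms_path = path / "gene_terms.tsv"
        abundance_path = path / "gene_abundance.tsv"
        mirnas = {}
        mrnas = {}
        for attr, fname in (("mirnas", "mirnas.fa"), ("mrnas", "mrnas.fa")):
            p = path / fname
            if p.exists():
                seqs = read_genome_fasta(p)
                if attr == "mirnas":
                    mirnas = seqs
                else:
                    mrnas = seqs
        return cls(
            genome=read_genome_fasta(path / "genome.fa"),
            genes=read_gff3(path / "genes.gff3"),
            tables=tables,
            stats=read_sample_stats(path / "sample_stats.tsv"),
            mites=read_mite_bed(mites_path) if mites_path.exists() else {},
            gene_abundance=(
                pd.read_csv(abundance_path, sep="\t", index_col=0)
                if abundance_path.exists()
                else None
            ),
            mirnas=mirnas,
            mrnas=mrnas,
            gene_terms=read_gene_terms(terms_path) if terms_path.exists() else {},
            **kwargs,
        )

    def samples_of(self, tissue: str, condition: str) -> List[str]:
        return [
            s.sample_id
            for s in self.stats
            if s.sample_id.startswith(f"{condition}-{tissue}")
        ]


def _union_circs(tables: Mapping[str, Sequence[CircRecord]]) -> List[CircRecord]:
    best: Dict[Tuple[str, int, int], CircRecord] = {}
    for recs in tables.values():
        for r in recs:
            key = (r.chrom, r.start, r.end)
            if key not in best:
                best[key] = CircRecord(
                    r.chrom, r.start, r.end, r.strand, 0, r.reported_type, r.gene_id
                )
    return [best[k] for k in sorted(best)]


@dataclass
class PipelineReport:
    circs: List[CircRecord]
    calls: Dict[str, classify.OriginCall]
    architectures: Dict[str, classify.ExonArchitecture]
    summary: classify.SummaryReport
    loci: List[altcirc.LocusGroup]
    isoform_hist: Dict[int, int]
    dominance: pd.DataFrame
    signals: splicesig.SignalTally
    pfm: pd.DataFrame
    flank_table: pd.DataFrame
    flank_summary: Dict[str, float]
    mite_table: pd.DataFrame
    mite_count: int
    matrix: ExpressionMatrix
    correlation: Optional[quantify.CorrelationResult]
    de_tables: Dict[str, pd.DataFrame]
    de_summary: pd.DataFrame
    global_shift: Dict[str, Tuple[float, float]]
    enrichment: pd.DataFrame
    network: List[target_scan.NetworkEdge]
    table1: pd.DataFrame
    overlap: Dict[FrozenSet[str], int]

    def write(self, outdir) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        frames = self.summary.to_frames()
        frames["origin"].to_csv(out / "origin_summary.tsv", sep="\t", index=False)
        frames["chromosome"].to_csv(out / "chromosome_counts.tsv", sep="\t", index=False)
        frames["length_hist"].to_csv(out / "length_hist.tsv", sep="\t", index=False)
        pd.DataFrame(
            [
                {
                    "circ_id": cid,
                    "origin": call.origin,
                    "parent_gene": call.parent_gene or "NA",
                }
                for cid, call in self.calls.items()
            ]
        ).to_csv(out / "origin_calls.tsv", sep="\t", index=False)
        pd.DataFrame(
            [
                {
                    "circ_id": a.circ_id,
                    "position_class": a.position_class,
                    "exon_count": a.exon_count,
                    "spliced_length": a.spliced_length,
                }
                for a in self.architectures.values()
            ]
        ).to_csv(out / "exon_architecture.tsv", sep="\t", index=False)
        self.dominance.to_csv(out / "altcirc_loci.tsv", sep="\t", index=False, float_format="%.4g")
        self.signals.table.to_csv(out / "splice_signals.tsv", sep="\t", index=False)
        self.signals.top_table.to_csv(out / "splice_signals_top.tsv", sep="\t", index=False)
        self.pfm.to_csv(out / "boundary_pfm.tsv", sep="\t", index_label="base", float_format="%.5f")
        self.flank_table.to_csv(out / "flank_matches.tsv", sep="\t", index=False)
        self.mite_table.to_csv(out / "mite_overlap.tsv", sep="\t", index=False)
        self.matrix.write(out / "counts.tsv", out / "srpbm.tsv")
        for tissue, df in self.de_tables.items():
            df.to_csv(out / f"de_{tissue}.tsv", sep="\t", index_label="circ_id", float_format="%.6g")
        self.de_summary.to_csv(out / "de_summary.tsv", sep="\t", index=False)
        self.enrichment.to_csv(out / "enrichment.tsv", sep="\t", index=False, float_format="%.6g")
        pd.DataFrame(
            [
                {"source": e.source, "target": e.target, "edge_type": e.edge_type}
                for e in self.network
            ],
            columns=["source", "target", "edge_type"],
        ).to_csv(out / "network_edges.tsv", sep="\t", index=False)
        self.table1.to_csv(out / "library_summary.tsv", sep="\t", index=False)
        with open(out / "tissue_overlap.tsv", "w") as fh:
            fh.write("region\tcount\n")
            for region in sorted(self.overlap, key=lambda r: sorted(r)):
                fh.write("+".join(sorted(region)) + f"\t{self.overlap[region]}\n")


def table1_summary(
    stats: Sequence[SampleStats],
    junction_reads: Mapping[str, int],
    circ_counts: Mapping[str, int],
) -> pd.DataFrame:
    """Per-sample library summary with an All row of column sums.

    Mapped percentage = mapped/total (2 decimals); junction percentage =
    junction reads/total reads (3 decimals); both recomputed from the row's
    own integers, including the All row.
    """
    rows = []
    for s in stats:
        j = int(junction_reads.get(s.sample_id, 0))
        rows.append(
            {
                "sample": s.sample_id,
                "total_reads": s.total_reads,
                "mapped_reads": s.mapped_reads,
                "mapped_percent": round(100.0 * s.mapped_reads / s.total_reads, 2),
                "junction_reads": j,
                "junction_percent": round(100.0 * j / s.total_reads, 3),
                "n_circRNA": int(circ_counts.get(s.sample_id, 0)),
            }
        )
    total = sum(r["total_reads"] for r in rows)
    mapped = sum(r["mapped_reads"] for r in rows)
    junction = sum(r["junction_reads"] for r in rows)
    rows.append(
        {
            "sample": "All",
            "total_reads": total,
            "mapped_reads": mapped,
            "mapped_percent": round(100.0 * mapped / total, 2) if total else 0.0,
            "junction_reads": junction,
            "junction_percent": round(100.0 * junction / total, 3) if total else 0.0,
            "n_circRNA": sum(r["n_circRNA"] for r in rows),
        }
    )
    df = pd.DataFrame(rows)
    # self-consistency: every percentage recomputes from its own row
    for _, row in df.iterrows():
        assert row["mapped_percent"] == round(
            100.0 * row["mapped_reads"] / row["total_reads"], 2
        )
        assert row["junction_percent"] == round(
            100.0 * row["junction_reads"] / row["total_reads"], 3
        )
    return df


def tissue_overlap(sets: Mapping[str, Set[str]]) -> Dict[FrozenSet[str], int]:
    """Exact Venn-region counts over two or more named sets.

    Each element is counted once, under the frozenset of set names that
    contain it; |A-only| + |A-shared regions| = |A| by construction.
    """
    if len(sets) < 2:
        raise ValueError("need at least two named sets")
    regions: Dict[FrozenSet[str], int] = {}
    universe = set().union(*sets.values())
    for element in universe:
        membership = frozenset(name for name, s in sets.items() if element in s)
        regions[membership] = regions.get(membership, 0) + 1
    return regions


def run_pipeline(
    inputs: PipelineInputs,
    flank_window: int = 1000,
    flank_min_len: int = 18,
    length_bin_width: int = 200,
    lfc_cutoff: float = diffexpr.DEFAULT_LFC_CUTOFF,
    fdr_cutoff: float = diffexpr.DEFAULT_FDR_CUTOFF,
    target_cutoff: float = target_scan.DEFAULT_CUTOFF,
    enrich_tissue: Optional[str] = None,
) -> PipelineReport:
    """Execute classify -> altcirc -> splicesig -> flank -> quantify ->
    diffexpr -> enrich -> target_scan over one dataset."""
    circs = _union_circs(inputs.tables)
    logger.info("pipeline start: %d circs, %d samples", len(circs), len(inputs.stats))

    calls = classify.classify_all(circs, inputs.genes)
    genes_by_id = {g.gene_id: g for g in inputs.genes}
    architectures = {
        c.circ_id: classify.exon_architecture(c, genes_by_id[calls[c.circ_id].parent_gene])
        for c in circs
        if calls[c.circ_id].origin == "exonic"
    }
    summary = classify.summarize(calls, architectures, circs, bin_width=length_bin_width)
    logger.info("origin counts: %s", summary.origin_counts)

    matrix = quantify.build_matrix(inputs.tables, inputs.stats)
    mean_expr = matrix.mean_srpbm()

    loci = altcirc.group_loci(circs, calls)
    iso_hist = altcirc.isoform_histogram(loci)
    dominance = altcirc.dominance_table(loci, mean_expr)

    sigs = [splicesig.extract_signal(c, inputs.genome) for c in circs]
    tally = splicesig.tally_signals(sigs)
    pfm = splicesig.boundary_pfm(circs, inputs.genome)
    logger.info("canonical signals: %d (%.1f%%)", tally.canonical_count, tally.canonical_percent)

    flank_table, flank_summary = flank.scan_flanks(
        circs, inputs.genome, window=flank_window, min_len=flank_min_len
    )
    mite_table, mite_count = flank.mite_overlap(
        circs, inputs.mites, window=flank_window, known_chroms=set(inputs.genome)
    )

    correlation = None
    if inputs.gene_abundance is not None:
        parent_map = {
            cid: call.parent_gene
            for cid, call in calls.items()
            if call.parent_gene is not None
        }
        gene_mean = inputs.gene_abundance.mean(axis=1)
        try:
            correlation = quantify.correlate_with_parents(
                mean_expr.to_dict(), gene_mean.to_dict(), parent_map
            )
        except ValueError:
            correlation = None

    de_tables: Dict[str, pd.DataFrame] = {}
    shifts: Dict[str, Tuple[float, float]] = {}
    lib_sizes = {s.sample_id: s.mapped_reads for s in inputs.stats}
    control, treated_cond = inputs.conditions[0], inputs.conditions[-1]
    for tissue in inputs.tissues:
        treated = inputs.samples_of(tissue, treated_cond)
        ctrl = inputs.samples_of(tissue, control)
        if not treated or not ctrl:
            continue
        res = diffexpr.de_test(matrix.raw, matrix.srpbm, lib_sizes, treated, ctrl)
        de_tables[tissue] = diffexpr.call_de(res, lfc_cutoff, fdr_cutoff)
        x = np.log2(matrix.srpbm[treated].mean(axis=1) + 1.0)
        y = np.log2(matrix.srpbm[ctrl].mean(axis=1) + 1.0)
        shifts[tissue] = diffexpr.global_shift(x, y)
        logger.info(
            "%s: %d up, %d down; rank-sum p=%.3g",
            tissue,
            int((de_tables[tissue]["call"] == "up").sum()),
            int((de_tables[tissue]["call"] == "down").sum()),
            shifts[tissue][1],
        )
    de_summary = diffexpr.de_report(de_tables) if de_tables else pd.DataFrame(
        columns=["tissue", "up", "down", "total"]
    )

    enrichment = pd.DataFrame()
    if inputs.gene_terms and de_tables:
        tissue = enrich_tissue or list(de_tables)[-1]
        df = de_tables[tissue]
        de_ids = set(df.index[df["call"] != "ns"])
        de_genes = {
            calls[cid].parent_gene
            for cid in de_ids
            if cid in calls and calls[cid].parent_gene is not None
        }
        background = {
            call.parent_gene for call in calls.values() if call.parent_gene is not None
        }
        if de_genes:
            enrichment = enrich.enrich_terms(de_genes, background, inputs.gene_terms)

    network: List[target_scan.NetworkEdge] = []
    if inputs.mirnas and de_tables:
        de_ids = set()
        for df in de_tables.values():
            de_ids |= set(df.index[df["call"] != "ns"])
        wrap = max(len(s) for s in inputs.mirnas.values()) - 1
        circ_seqs = {
            c.circ_id: target_scan.circ_sequence(
                c,
                inputs.genome,
                genes_by_id.get(calls[c.circ_id].parent_gene)
                if calls[c.circ_id].origin == "exonic"
                else None,
                wrap=wrap,
            )
            for c in circs
            if c.circ_id in de_ids
        }
        circ_hits = target_scan.scan_many(inputs.mirnas, circ_seqs, target_cutoff)
        mrna_hits = target_scan.scan_many(inputs.mirnas, inputs.mrnas, target_cutoff)
        network = target_scan.build_network(circ_hits, mrna_hits, de_ids)

    junction_totals = {
        s.sample_id: sum(r.junction_reads for r in inputs.tables.get(s.sample_id, []))
        for s in inputs.stats
    }
    circ_counts = {
        s.sample_id: len(inputs.tables.get(s.sample_id, [])) for s in inputs.stats
    }
    table1 = table1_summary(inputs.stats, junction_totals, circ_counts)

    per_tissue_sets: Dict[str, Set[str]] = {}
    for tissue in inputs.tissues:
        ids: Set[str] = set()
        for s in inputs.stats:
            if f"-{tissue}" in s.sample_id:
                ids |= {r.circ_id for r in inputs.tables.get(s.sample_id, [])}
        per_tissue_sets[tissue] = ids
    overlap = (
        tissue_overlap(per_tissue_sets) if len(per_tissue_sets) >= 2 else {}
    )

    return PipelineReport(
        circs=circs,
        calls=calls,
        architectures=architectures,
        summary=summary,
        loci=loci,
        isoform_hist=iso_hist,
        dominance=dominance,
        signals=tally,
        pfm=pfm,
        flank_table=flank_table,
        flank_summary=flank_summary,
        mite_table=mite_table,
        mite_count=mite_count,
        matrix=matrix,
        correlation=correlation,
        de_tables=de_tables,
        de_summary=de_summary,
        global_shift=shifts,
        enrichment=enrichment,
        network=network,
        table1=table1,
        overlap=overlap,
    )
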