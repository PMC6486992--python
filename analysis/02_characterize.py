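"""Characterize the circRNA cohort: genomic origin, exon architecture,
chromosome/length distributions, alternative circularization, splice
signals, and flanking complementary sequences / MITEs.

Reads results/sim_data/ (run 01_simulate.py first) and writes the
characterization tables to results/characterization/.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

import pandas as pd

from cucirc import altcirc, classify, flank, quantify, splicesig
from cucirc.report import PipelineInputs

DATA = Path("results/sim_data")
OUT = Path("results/characterization")


def main() -> None:
    if not DATA.exists():
        sys.exit(f"{DATA} not found -- run analysis/01_simulate.py first")
    OUT.mkdir(parents=True, exist_ok=True)
    inputs = PipelineInputs.from_dir(DATA)
    circs = sorted(
        {r.circ_id: r for recs in inputs.tables.values() for r in recs}.values(),
        key=lambda c: (c.chrom, c.start, c.end),
    )

    calls = classify.classify_all(circs, inputs.genes)
    genes = {g.gene_id: g for g in inputs.genes}
    archs = {
        c.circ_id: classify.exon_architecture(c, genes[calls[c.circ_id].parent_gene])
        for c in circs
        if calls[c.circ_id].origin == "exonic"
    }
    summary = classify.summarize(calls, archs, circs)
    frames = summary.to_frames()
    frames["origin"].to_csv(OUT / "origin_summary.tsv", sep="\t", index=False)
    frames["chromosome"].to_csv(OUT / "chromosome_counts.tsv", sep="\t", index=False)
    frames["length_hist"].to_csv(OUT / "length_hist.tsv", sep="\t", index=False)
    print("origin percentages:", summary.origin_percent)
    print("exon position classes:", summary.position_class_counts)
    print(f"median length: {summary.median_length:.0f} nt")

    mat = quantify.build_matrix(inputs.tables, inputs.stats)
    groups = altcirc.group_loci(circs, calls)
    hist = altcirc.isoform_histogram(groups)
    dom = altcirc.dominance_table(groups, mat.mean_srpbm().to_dict())
    dom.to_csv(OUT / "altcirc_loci.tsv", sep="\t", index=False, float_format="%.4g")
    with_dom = int((dom["dominant"] != "NA").sum())
    print(f"alternative circularization: {len(dom)} multi-isoform loci, "
          f"isoform histogram {hist}, dominant isoform in {with_dom} "
          f"({100 * with_dom / max(1, len(dom)):.1f}%)")

    pairs = [splicesig.extract_signal(c, inputs.genome) for c in circs]
    tally = splicesig.tally_signals(pairs)
    tally.table.to_csv(OUT / "splice_signals.tsv", sep="\t", index=False)
    splicesig.boundary_pfm(circs, inputs.genome).to_csv(
        OUT / "boundary_pfm.tsv", sep="\t", index_label="base", float_format="%.5f"
    )
    print(f"canonical GT/AG (incl. CT/AC) signals: {tally.canonical_count} "
          f"({tally.canonical_percent}%)")
    print("top signals:", dict(zip(tally.top_table['pair_label'][:5],
                                   tally.top_table['count'][:5])))

    ftable, fsummary = flank.scan_flanks(circs, inputs.genome, window=1000, min_len=18)
    ftable.to_csv(OUT / "flank_matches.tsv", sep="\t", index=False)
    mtable, mcount = flank.mite_overlap(
        circs, inputs.mites, window=1000, known_chroms=set(inputs.genome)
    )
    mtable.to_csv(OUT / "mite_overlap.tsv", sep="\t", index=False)
    print(f"circs with >=18 bp complementary flanks within 1 kb: "
          f"{int(fsummary['n_with_complementary_flanks'])} "
          f"({fsummary['percent_with_complementary_flanks']}%)")
    print(f"circs with MITEs on both flanks: {mcount}")


if __name__ == "__main__":
    main()
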