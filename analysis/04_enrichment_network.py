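"""Term enrichment among parent genes of differential circRNAs, and the
circRNA-miRNA-mRNA regulatory network.

Reads results/sim_data/ and results/diffexpr/ and writes results/network/.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

import pandas as pd

from cucirc import classify, enrich, target_scan
from cucirc.report import PipelineInputs

DATA = Path("results/sim_data")
DE = Path("results/diffexpr")
OUT = Path("results/network")


def main() -> None:
    if not DATA.exists() or not DE.exists():
        sys.exit("run analysis/01_simulate.py and 03_differential_expression.py first")
    OUT.mkdir(parents=True, exist_ok=True)
    inputs = PipelineInputs.from_dir(DATA)

    circs = sorted(
        {r.circ_id: r for recs in inputs.tables.values() for r in recs}.values(),
        key=lambda c: (c.chrom, c.start, c.end),
    )
    calls = classify.classify_all(circs, inputs.genes)
    genes = {g.gene_id: g for g in inputs.genes}

    de_ids = set()
    for p in sorted(DE.glob("de_*.tsv")):
        if p.name == "de_summary.tsv":
            continue
        df = pd.read_csv(p, sep="\t", index_col=0)
        de_ids |= set(df.index[df["call"] != "ns"])
    print(f"{len(de_ids)} differential circRNAs across tissues")

    de_genes = {
        calls[cid].parent_gene for cid in de_ids
        if cid in calls and calls[cid].parent_gene is not None
    }
    background = {c.parent_gene for c in calls.values() if c.parent_gene is not None}
    enrichment = enrich.enrich_terms(de_genes, background, inputs.gene_terms)
    enrichment.to_csv(OUT / "enrichment.tsv", sep="\t", index=False,
                      float_format="%.6g")
    top = enrichment.head(3)
    print(f"enrichment over {len(background)} background parent genes, "
          f"{len(de_genes)} differential parents; top terms:")
    for _, row in top.iterrows():
        print(f"  {row['term_id']}: k={row['k']}/{row['K']} p={row['p_value']:.3g} "
              f"fdr={row['fdr']:.3g}")

    wrap = max(len(s) for s in inputs.mirnas.values()) - 1
    circ_seqs = {
        c.circ_id: target_scan.circ_sequence(
            c, inputs.genome,
            genes.get(calls[c.circ_id].parent_gene)
            if calls[c.circ_id].origin == "exonic" else None,
            wrap=wrap,
        )
        for c in circs if c.circ_id in de_ids
    }
    circ_hits = target_scan.scan_many(inputs.mirnas, circ_seqs)
    mrna_hits = target_scan.scan_many(inputs.mirnas, inputs.mrnas)
    circ_hits.to_csv(OUT / "circ_mirna_hits.tsv", sep="\t", index=False)
    mrna_hits.to_csv(OUT / "mirna_mrna_hits.tsv", sep="\t", index=False)
    edges = target_scan.build_network(circ_hits, mrna_hits, de_ids)
    pd.DataFrame(
        [{"source": e.source, "target": e.target, "edge_type": e.edge_type}
         for e in edges],
        columns=["source", "target", "edge_type"],
    ).to_csv(OUT / "network_edges.tsv", sep="\t", index=False)
    n_cm = sum(e.edge_type == "circ-miRNA" for e in edges)
    n_mm = sum(e.edge_type == "miRNA-mRNA" for e in edges)
    print(f"network: {n_cm} circ-miRNA edges, {n_mm} miRNA-mRNA edges")


if __name__ == "__main__":
    main()
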