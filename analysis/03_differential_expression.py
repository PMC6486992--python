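"""SRPBM quantification, salt-stress differential expression per tissue,
the global abundance-shift comparison, and circRNA vs parental-gene
correlation.

Reads results/sim_data/ and writes results/diffexpr/.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

import numpy as np

from cucirc import classify, diffexpr, quantify
from cucirc.report import PipelineInputs

DATA = Path("results/sim_data")
OUT = Path("results/diffexpr")


def main() -> None:
    if not DATA.exists():
        sys.exit(f"{DATA} not found -- run analysis/01_simulate.py first")
    OUT.mkdir(parents=True, exist_ok=True)
    inputs = PipelineInputs.from_dir(DATA)

    mat = quantify.build_matrix(inputs.tables, inputs.stats)
    mat.write(OUT / "counts.tsv", OUT / "srpbm.tsv")
    libs = {s.sample_id: s.mapped_reads for s in inputs.stats}

    de_tables = {}
    for tissue in inputs.tissues:
        treated = inputs.samples_of(tissue, "Na")
        ctrl = inputs.samples_of(tissue, "CK")
        res = diffexpr.de_test(mat.raw, mat.srpbm, libs, treated, ctrl)
        called = diffexpr.call_de(res)
        de_tables[tissue] = called
        called.to_csv(OUT / f"de_{tissue}.tsv", sep="\t", index_label="circ_id",
                      float_format="%.6g")
        up = int((called["call"] == "up").sum())
        down = int((called["call"] == "down").sum())
        x = np.log2(mat.srpbm[treated].mean(axis=1) + 1.0)
        y = np.log2(mat.srpbm[ctrl].mean(axis=1) + 1.0)
        _, p = diffexpr.global_shift(x, y)
        print(f"tissue {tissue}: {up} up, {down} down "
              f"(|log2FC| > 1, FDR <= 0.05); global shift rank-sum p = {p:.3g}")
    report = diffexpr.de_report(de_tables)
    report.to_csv(OUT / "de_summary.tsv", sep="\t", index=False)
    print(report.to_string(index=False))

    if inputs.gene_abundance is not None:
        circs = [r for recs in inputs.tables.values() for r in recs]
        calls = classify.classify_all(
            sorted({c.circ_id: c for c in circs}.values(),
                   key=lambda c: (c.chrom, c.start, c.end)),
            inputs.genes,
        )
        parent_map = {
            cid: call.parent_gene for cid, call in calls.items()
            if call.parent_gene is not None
        }
        corr = quantify.correlate_with_parents(
            mat.mean_srpbm().to_dict(),
            inputs.gene_abundance.mean(axis=1).to_dict(),
            parent_map,
        )
        print(f"circRNA vs parental-gene abundance: r = {corr.r:.3f} "
              f"(p = {corr.p_value:.2g}, n = {corr.n} genic circs)")


if __name__ == "__main__":
    main()
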