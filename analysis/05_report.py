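"""Aggregate run report: per-sample library summary (with percentages and
an All row), tissue overlap of detected circRNAs, and the full stage-by-
stage report bundle.

Reads results/sim_data/ and writes results/report/.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from cucirc.report import PipelineInputs, run_pipeline

DATA = Path("results/sim_data")
OUT = Path("results/report")


def main() -> None:
    if not DATA.exists():
        sys.exit(f"{DATA} not found -- run analysis/01_simulate.py first")
    inputs = PipelineInputs.from_dir(DATA)
    report = run_pipeline(inputs)
    report.write(OUT)
    print(report.table1.to_string(index=False))
    print("tissue overlap:")
    for region in sorted(report.overlap, key=lambda r: sorted(r)):
        print(f"  {'+'.join(sorted(region))}: {report.overlap[region]}")
    print(f"full report bundle written to {OUT}/")


if __name__ == "__main__":
    main()
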