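#!/usr/bin/env python
"""Scan the focal genome for pseudogenes against the panel.

Applies the degradation criteria — premature stops, frameshifts, lost
canonical stops, large deletions, short inversions — plus the supporting
panel-based checks (length anomalies, hydrophobicity outside the panel's
t-based confidence interval), and writes the per-gene evidence report.
"""

import argparse
from pathlib import Path

import pandas as pd

from pseudoplast.io import read_genbank, write_report
from pseudoplast.scan import scan_genome


def main(indir: Path, outdir: Path):
    focal = read_genbank(indir / "focal.gb")
    panel = [read_genbank(p) for p in sorted(indir.glob("panel_*.gb"))]
    report = scan_genome(focal, panel)
    outdir.mkdir(parents=True, exist_ok=True)
    jp, tp = write_report(report, outdir / "degradation_report")

    hydro = [{"gene": g, "focal": s.hydrophobicity.focal_fraction,
              "ci_low": s.hydrophobicity.ci[0], "ci_high": s.hydrophobicity.ci[1],
              "outside": not (s.hydrophobicity.ci[0] <= s.hydrophobicity.focal_fraction
                              <= s.hydrophobicity.ci[1])}
             for g, s in sorted(report.per_gene.items()) if s.hydrophobicity]
    pd.DataFrame(hydro).to_csv(outdir / "hydrophobicity.tsv", sep="\t", index=False)

    print(f"pseudogene verdicts: {', '.join(report.flagged())}")
    for gene in report.flagged():
        kinds = sorted({e.kind for e in report.per_gene[gene].events})
        print(f"  {gene}: {', '.join(kinds)}")
    print(f"report -> {jp}, {tp}")


if __name__ == "__main__":
    ap = argparse.ArgumentParser()
    ap.add_argument("--in", dest="indir", type=Path,
                    default=Path("results/synthetic"))
    ap.add_argument("--out", type=Path, default=Path("results/tables"))
    args = ap.parse_args()
    main(args.indir, args.out)
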