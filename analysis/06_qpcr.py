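"""qPCR-style validation of the candidate genes.

Computes per-sample 2^-ΔΔCt fold changes from the synthetic Ct table and
compares case vs control per gene with the normality-driven test rule
(Welch t when both groups look normal, Mann-Whitney otherwise).
"""

import argparse
from pathlib import Path

import pandas as pd

from methexpress.io import write_tsv
from methexpress.qpcr import analyze_qpcr


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--datadir", type=Path, default=Path("results/data"))
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    args = ap.parse_args()

    ct = pd.read_csv(args.datadir / "ct.tsv", sep="\t")
    folds, summary = analyze_qpcr(ct)
    print("per-gene relative expression (case vs control):")
    print(summary.to_string(index=False))
    write_tsv(folds, args.outdir / "qpcr_fold_changes.tsv")
    write_tsv(summary, args.outdir / "qpcr_summary.tsv")


if __name__ == "__main__":
    main()
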