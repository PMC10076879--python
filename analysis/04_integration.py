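"""Integrate differential methylation with differential expression.

Gene-level join of significant DM loci and DE results, region-stratified
Pearson correlation between Δβ and log2FC, promoter/enhancer DMG
classification with quadrant counts, and the two Δβ-ranked candidate
tables (hypermethylated-downregulated and hypomethylated-upregulated).
"""

import argparse
from pathlib import Path

import pandas as pd

from methexpress.annotation import read_manifest
from methexpress.integration import (
    classify_dmgs,
    direction_counts,
    join_dm_de,
    rank_candidates,
    region_correlation,
)
from methexpress.io import write_tsv


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--datadir", type=Path, default=Path("results/data"))
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    ap.add_argument("--top", type=int, default=15)
    args = ap.parse_args()

    sig = pd.read_csv(args.outdir / "dml_significant.tsv", sep="\t")
    de = pd.read_csv(args.outdir / "de_results.tsv", sep="\t")
    manifest = read_manifest(args.datadir / "manifest.tsv")

    records = join_dm_de(sig, manifest, de)
    print(f"{len(records)} gene-level records "
          f"({records.attrs['dropped_no_expression']} DM genes lacked expression)")

    corr = region_correlation(records)
    print("methylation-expression correlation by region group:")
    print(corr.to_string(index=False))

    quad = classify_dmgs(records)
    prom4 = quad[(quad.partition == "promoter_related") & (quad.quadrant == "part4")]
    print(f"promoter-related DMGs in part 4 (hyper-down): "
          f"{int(prom4['count'].iloc[0])}/{int(prom4['total'].iloc[0])} "
          f"({prom4['percent'].iloc[0]:.1f}%)")

    hyper_down, hypo_up = rank_candidates(records, k=args.top)
    print(f"candidate tables: {len(hyper_down)} hyper-down, {len(hypo_up)} hypo-up "
          f"(top {args.top} by |d-beta|)")

    write_tsv(records, args.outdir / "integrated_records.tsv")
    write_tsv(corr, args.outdir / "region_correlation.tsv")
    write_tsv(quad, args.outdir / "dmg_quadrant_counts.tsv")
    write_tsv(direction_counts(records), args.outdir / "dmg_direction_counts.tsv")
    write_tsv(hyper_down, args.outdir / "candidates_hyper_down.tsv")
    write_tsv(hypo_up, args.outdir / "candidates_hypo_up.tsv")


if __name__ == "__main__":
    main()
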