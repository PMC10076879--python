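"""Over-representation analysis of the DEG lists.

Tests the up- and downregulated DEG lists against the synthetic GMT
collection (which contains one set spiked with planted-effect genes)
using the hypergeometric upper tail with the count-matrix genes as
universe.
"""

import argparse
from pathlib import Path

import pandas as pd

from methexpress.enrichment import enrich, read_gmt
from methexpress.io import read_gene_list, write_tsv


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--datadir", type=Path, default=Path("results/data"))
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    args = ap.parse_args()

    collection = read_gmt(args.datadir / "sets.gmt")
    universe = list(
        pd.read_csv(args.datadir / "counts.tsv", sep="\t", index_col=0).index
    )
    for name in ("up", "down"):
        genes = read_gene_list(args.outdir / f"degs_{name}.txt")
        if not genes:
            print(f"{name}: no DEGs, skipped")
            continue
        res = enrich(genes, universe, collection)
        top = res.iloc[0]
        print(f"{name}regulated ({len(genes)} genes): top term "
              f"{top['term']} (k={top['k']}/{top['K']}, p={top['p_value']:.3g}, "
              f"fdr={top['fdr']:.3g})")
        write_tsv(res, args.outdir / f"enrichment_{name}.tsv")


if __name__ == "__main__":
    main()
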