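"""Gene-level integration of differential methylation and expression.

Significant DM loci are joined to the DE table by gene symbol; a gene with
several significant loci is represented by the locus of maximal |Δβ| (ties
broken by lower p, then lexicographic probe id). Records are stratified by
the representative probe's region group for methylation-expression
correlation, split into promoter-related vs enhancer-related DMGs (promoter
= TSS1500/TSS200; "enhancer-related" simply means not in a promoter), and
partitioned into quadrants by the signs of Δβ and log2FC:

    part1 = hypomethylated & upregulated     (Δβ < 0, lfc > 0)
    part2 = hypermethylated & upregulated    (Δβ > 0, lfc > 0)
    part3 = hypomethylated & downregulated   (Δβ < 0, lfc < 0)
    part4 = hypermethylated & downregulated  (Δβ > 0, lfc < 0)

Parts 1 and 4 are the anti-correlated quadrants expected when promoter
methylation represses transcription.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import PROMOTER_CLASSES, REGION_GROUPS

QUADRANTS = ("part1", "part2", "part3", "part4")
CORRELATION_GROUPS = tuple(g for g in REGION_GROUPS if g != "Intergenic")

CANDIDATE_COLUMNS = [
    "Probe_ID",
    "Gene",
    "beta_case_avg",
    "beta_control_avg",
    "beta_change",
    "RELATION_TO_CPG_ISLAND",
    "log2FoldChange",
    "padj",
]


def assign_quadrant(delta_beta: float, log2fc: float) -> str:
    """Quadrant of the (Δβ, log2FC) plane; exact zeros fall on 'boundary'."""
    if not (math.isfinite(delta_beta) and math.isfinite(log2fc)):
        raise ValueError("delta_beta and log2fc must be finite")
    if delta_beta == 0 or log2fc == 0:
        return "boundary"
    if delta_beta < 0:
        return "part1" if log2fc > 0 else "part3"
    return "part2" if log2fc > 0 else "part4"


def join_dm_de(
    dml: pd.DataFrame, manifest: pd.DataFrame, de: pd.DataFrame
) -> pd.DataFrame:
    """Join significant DM loci with DE results at gene level.

    ``dml`` is the significant subset of a call_dml table; ``de`` is a full
    nb_wald_test table. One record is produced per (gene, DM direction); a
    gene's representative locus is the one with maximal |Δβ|. Genes without
    an expression measurement are dropped and counted in
    ``attrs['dropped_no_expression']``.
    """
    if dml.empty:
        warnings.warn("empty DML list; no integrated records")
        out = pd.DataFrame(
            columns=["gene", "probe_id", "delta_beta", "abs_delta_beta",
                     "region_group", "island_relation", "promoter_related",
                     "log2fc", "padj", "quadrant"]
        )
        out.attrs["dropped_no_expression"] = 0
        return out

    rows = []
    for _, locus in dml.iterrows():
        probe = locus["probe_id"]
        if probe not in manifest.index:
            raise KeyError(f"probe {probe} absent from manifest")
        m = manifest.loc[probe]
        for gene in dict.fromkeys(g for g, _ in m["annotations"]):
            promoter = any(
                g == gene and cls in PROMOTER_CLASSES for g, cls in m["annotations"]
            )
            rows.append(
                {
                    "gene": gene,
                    "probe_id": probe,
                    "beta_case_avg": locus["beta_case_avg"],
                    "beta_control_avg": locus["beta_control_avg"],
                    "delta_beta": locus["delta_beta"],
                    "abs_delta_beta": locus["abs_delta_beta"],
                    "dm_p": locus["p_value"],
                    "direction": locus["direction"],
                    "region_group": m["region_group"],
                    "island_relation": m["island_relation"],
                    "promoter_related": promoter,
                }
            )
    per_locus = pd.DataFrame(rows)
    # representative locus per (gene, direction): max |Δβ|, then lower p, then probe id
    per_locus = per_locus.sort_values(
        ["abs_delta_beta", "dm_p", "probe_id"], ascending=[False, True, True]
    )
    rep = per_locus.drop_duplicates(subset=["gene", "direction"], keep="first")

    de_idx = de.set_index("gene") if "gene" in de.columns else de
    have = rep["gene"].isin(de_idx.index)
    dropped = int((~have).sum())
    rep = rep.loc[have].copy()
    rep["log2fc"] = de_idx.loc[rep["gene"], "log2fc"].to_numpy()
    rep["padj"] = de_idx.loc[rep["gene"], "padj"].to_numpy()
    rep["quadrant"] = [
        assign_quadrant(d, l) for d, l in zip(rep["delta_beta"], rep["log2fc"])
    ]
    rep = rep.reset_index(drop=True)
    rep.attrs["dropped_no_expression"] = dropped
    return rep


def region_correlation(records: pd.DataFrame) -> pd.DataFrame:
    """Pearson r between signed Δβ and log2FC within each region group.

    Two-sided p from the t reference on n-2 df. Groups with fewer than
    three genes, or zero variance in either variable, are reported with
    NaN r/p and flagged.
    """
    out = []
    for group in CORRELATION_GROUPS:
        sub = records.loc[records["region_group"] == group]
        n = len(sub)
        r = p = float("nan")
        flag = ""
        if n < 3:
            flag = "n<3"
        elif sub["delta_beta"].nunique() == 1 or sub["log2fc"].nunique() == 1:
            flag = "zero-variance"
        else:
            r, p = stats.pearsonr(sub["delta_beta"], sub["log2fc"])
        out.append(
            {"region_group": group, "pearson_r": r, "p_value": p,
             "n_genes": n, "flag": flag}
        )
    return pd.DataFrame(out)


def classify_dmgs(records: pd.DataFrame) -> pd.DataFrame:
    """Promoter-related vs enhancer-related DMG counts per quadrant.

    Percentages use the partition total (promoter-related or
    enhancer-related record count) as denominator, rounded half-even to one
    decimal. Quadrant counts plus boundary sum to the partition total.
    """
    rows = []
    for name, sub in (
        ("promoter_related", records.loc[records["promoter_related"]]),
        ("enhancer_related", records.loc[~records["promoter_related"]]),
    ):
        total = len(sub)
        for quad in QUADRANTS + ("boundary",):
            k = int((sub["quadrant"] == quad).sum())
            pct = float(np.round(100.0 * k / total, 1)) if total else float("nan")
            rows.append(
                {"partition": name, "quadrant": quad, "count": k,
                 "total": total, "percent": pct}
            )
    return pd.DataFrame(rows)


def direction_counts(records: pd.DataFrame) -> pd.DataFrame:
    """Up/down expression counts per partition (direction-based tally).

    Complements the quadrant-based tally: a record counts as upregulated if
    log2fc > 0, downregulated if log2fc < 0, regardless of Δβ sign.
    """
    rows = []
    for name, sub in (
        ("promoter_related", records.loc[records["promoter_related"]]),
        ("enhancer_related", records.loc[~records["promoter_related"]]),
    ):
        rows.append(
            {
                "partition": name,
                "upregulated": int((sub["log2fc"] > 0).sum()),
                "downregulated": int((sub["log2fc"] < 0).sum()),
            }
        )
    return pd.DataFrame(rows)


def _candidate_schema(sub: pd.DataFrame) -> pd.DataFrame:
    out = pd.DataFrame(
        {
            "Probe_ID": sub["probe_id"].to_numpy(),
            "Gene": sub["gene"].to_numpy(),
            "beta_case_avg": sub["beta_case_avg"].to_numpy(),
            "beta_control_avg": sub["beta_control_avg"].to_numpy(),
            "beta_change": sub["abs_delta_beta"].to_numpy(),
            "RELATION_TO_CPG_ISLAND": [
                "" if rel == "OpenSea" else rel for rel in sub["island_relation"]
            ],
            "log2FoldChange": sub["log2fc"].to_numpy(),
            "padj": sub["padj"].to_numpy(),
        }
    )
    return out[CANDIDATE_COLUMNS].reset_index(drop=True)


def rank_candidates(
    records: pd.DataFrame,
    k: int = 15,
    lfc_threshold: float = 1.0,
    padj_threshold: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Top-k candidate tables ranked by |Δβ| descending.

    Table A: hypermethylated-downregulated (Δβ > 0, log2FC < 0); table B:
    hypomethylated-upregulated (Δβ < 0, log2FC > 0). Both additionally gate
    on the expression side (padj < threshold, |log2FC| >= threshold); the DM
    gate is inherited from the significant-DML input. One row per gene;
    ties broken by lower padj, then gene symbol.
    """
    if records.empty:
        empty = pd.DataFrame(columns=CANDIDATE_COLUMNS)
        return empty, empty.copy()
    gated = records.loc[
        (records["padj"] < padj_threshold)
        & (records["log2fc"].abs() >= lfc_threshold)
    ]
    ranked = gated.sort_values(
        ["abs_delta_beta", "padj", "gene"], ascending=[False, True, True]
    ).drop_duplicates(subset="gene", keep="first")
    hyper_down = ranked.loc[(ranked["delta_beta"] > 0) & (ranked["log2fc"] < 0)].head(k)
    hypo_up = ranked.loc[(ranked["delta_beta"] < 0) & (ranked["log2fc"] > 0)].head(k)
    return _candidate_schema(hyper_down), _candidate_schema(hypo_up)


def filter_reported(table: pd.DataFrame, exclusion_list) -> pd.DataFrame:
    """Drop candidate rows whose gene appears in a user-supplied exclusion list.

    Removed gene symbols are recorded in ``attrs['removed']``.
    """
    excl = set(exclusion_list)
    gene_col = "Gene" if "Gene" in table.columns else "gene"
    keep = ~table[gene_col].isin(excl)
    out = table.loc[keep].reset_index(drop=True)
    out.attrs["removed"] = sorted(set(table.loc[~keep, gene_col]))
    return out
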