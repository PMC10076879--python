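"""Probe-level genomic annotation for 450K-style methylation arrays.

Every probe is assigned (i) zero or more (gene, region class) annotations,
(ii) a single six-way region group used for region-stratified integration,
and (iii) a CpG-island relation (Island / Shore / Shelf / OpenSea, with the
N_/S_ prefix marking the lower-/higher-coordinate flank).

Coordinates are 1-based inclusive throughout, matching array-manifest
convention; BED export converts to 0-based half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

#: Region classes a probe may carry per annotated gene.
REGION_CLASSES = ("TSS1500", "TSS200", "5UTR", "1stExon", "Body", "3UTR")

#: Classes counted as promoter (standard 450K convention: TSS1500 U TSS200).
PROMOTER_CLASSES = frozenset({"TSS1500", "TSS200"})

#: CpG-island relations, N_ = lower-coordinate side, S_ = higher-coordinate.
ISLAND_RELATIONS = ("Island", "N_Shore", "S_Shore", "N_Shelf", "S_Shelf", "OpenSea")

#: Six-way region groups plus Intergenic for unannotated probes.
REGION_GROUPS = (
    "1stExon",
    "3UTR",
    "5UTR",
    "GeneBody",
    "MultipleLocations",
    "Promoter",
    "Intergenic",
)

SHORE_BP = 2000
SHELF_BP = 2000  # shelves extend a further 2 kb beyond the shores


@dataclass
class ProbeRecord:
    """One array probe with genomic position and annotation."""

    probe_id: str
    chrom: str
    pos: int  # 1-based
    strand: str = "+"
    gene_annotations: list[tuple[str, str]] = field(default_factory=list)
    island_relation: str = "OpenSea"

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"probe {self.probe_id}: position must be >= 1")
        if self.island_relation not in ISLAND_RELATIONS:
            raise ValueError(f"unknown island relation {self.island_relation!r}")
        for _, cls in self.gene_annotations:
            if cls not in REGION_CLASSES:
                raise ValueError(f"unknown region class {cls!r}")


def _classify_single(pos: int, start: int, end: int) -> str:
    if start > end:
        raise ValueError(f"invalid island interval ({start}, {end})")
    if start <= pos <= end:
        return "Island"
    if start - SHORE_BP <= pos < start:
        return "N_Shore"
    if end < pos <= end + SHORE_BP:
        return "S_Shore"
    if start - SHORE_BP - SHELF_BP <= pos < start - SHORE_BP:
        return "N_Shelf"
    if end + SHORE_BP < pos <= end + SHORE_BP + SHELF_BP:
        return "S_Shelf"
    return "OpenSea"


def classify_island_relation(
    pos: int, islands: tuple[int, int] | Sequence[tuple[int, int]]
) -> str:
    """Relation of a probe position to one or more CpG islands.

    Island if inside; shores are the 2 kb flanks; shelves the next 2 kb;
    OpenSea beyond. With multiple islands the nearest island decides
    (distance zero inside), ties broken toward the lower-coordinate island.
    """
    if pos < 1:
        raise ValueError("position must be >= 1")
    if isinstance(islands, tuple) and len(islands) == 2 and isinstance(islands[0], int):
        return _classify_single(pos, *islands)
    islands = list(islands)
    if not islands:
        return "OpenSea"
    best = None
    for start, end in sorted(islands):
        if start > end:
            raise ValueError(f"invalid island interval ({start}, {end})")
        dist = 0 if start <= pos <= end else min(abs(pos - start), abs(pos - end))
        if best is None or dist < best[0]:
            best = (dist, start, end)
    return _classify_single(pos, best[1], best[2])


def assign_region_group(probe: ProbeRecord | Iterable[tuple[str, str]]) -> str:
    """Collapse a probe's gene annotations to one six-way region group.

    No annotation -> Intergenic; promoter classes only -> Promoter; exactly
    one distinct non-promoter class -> that class (Body reported as
    GeneBody); two or more distinct classes -> MultipleLocations.
    """
    anns = probe.gene_annotations if isinstance(probe, ProbeRecord) else list(probe)
    classes = {cls for _, cls in anns}
    if not classes:
        return "Intergenic"
    if classes <= PROMOTER_CLASSES:
        return "Promoter"
    if len(classes) == 1:
        (cls,) = classes
        return "GeneBody" if cls == "Body" else cls
    return "MultipleLocations"


def parse_annotations(genes: str, groups: str) -> list[tuple[str, str]]:
    """Parse semicolon-delimited manifest gene/region columns.

    450K manifests repeat (gene, class) per transcript; duplicates are
    collapsed while preserving first-seen order.
    """
    if not genes or pd.isna(genes):
        return []
    gene_list = str(genes).split(";")
    group_list = str(groups).split(";")
    if len(gene_list) != len(group_list):
        raise ValueError("gene and region-class annotation counts differ")
    seen: list[tuple[str, str]] = []
    for g, c in zip(gene_list, group_list):
        g, c = g.strip(), c.strip()
        if not g:
            continue
        if c not in REGION_CLASSES:
            raise ValueError(f"unknown region class {c!r}")
        if (g, c) not in seen:
            seen.append((g, c))
    return seen


def read_manifest(path) -> pd.DataFrame:
    """Read a probe manifest TSV into a probe-indexed DataFrame.

    Expected columns: probe_id, chrom, pos, strand, UCSC_RefGene_Name,
    UCSC_RefGene_Group, Relation_to_UCSC_CpG_Island (blank = OpenSea).
    Adds parsed ``annotations`` and derived ``region_group`` columns.
    """
    df = pd.read_csv(path, sep="\t", dtype={"probe_id": str, "chrom": str}, keep_default_na=False)
    required = {"probe_id", "chrom", "pos", "UCSC_RefGene_Name", "UCSC_RefGene_Group"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    if "Relation_to_UCSC_CpG_Island" not in df.columns:
        df["Relation_to_UCSC_CpG_Island"] = ""
    df["island_relation"] = df["Relation_to_UCSC_CpG_Island"].replace("", "OpenSea")
    df["annotations"] = [
        parse_annotations(g, c)
        for g, c in zip(df["UCSC_RefGene_Name"], df["UCSC_RefGene_Group"])
    ]
    df["region_group"] = [assign_region_group(a) for a in df["annotations"]]
    return df.set_index("probe_id", drop=False)


def manifest_from_records(records: Iterable[ProbeRecord]) -> pd.DataFrame:
    """Build the manifest DataFrame surface from ProbeRecord objects."""
    rows = []
    for r in records:
        rows.append(
            {
                "probe_id": r.probe_id,
                "chrom": r.chrom,
                "pos": r.pos,
                "strand": r.strand,
                "UCSC_RefGene_Name": ";".join(g for g, _ in r.gene_annotations),
                "UCSC_RefGene_Group": ";".join(c for _, c in r.gene_annotations),
                "Relation_to_UCSC_CpG_Island": (
                    "" if r.island_relation == "OpenSea" else r.island_relation
                ),
                "island_relation": r.island_relation,
                "annotations": list(r.gene_annotations),
                "region_group": assign_region_group(r),
            }
        )
    return pd.DataFrame(rows).set_index("probe_id", drop=False)


def dml_region_distribution(
    dml: pd.DataFrame, manifest: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-direction proportions of DM loci over region groups and island relations.

    ``dml`` must carry ``probe_id`` and ``direction`` (hyper/hypo) columns;
    every probe must exist in the manifest. Returns two DataFrames indexed
    by category with one proportion column per direction, each summing to 1.
    """
    unknown = set(dml["probe_id"]) - set(manifest.index)
    if unknown:
        raise KeyError(f"probes absent from manifest: {sorted(unknown)[:5]}")
    sub = manifest.loc[dml["probe_id"], ["region_group", "island_relation"]].copy()
    sub["direction"] = dml["direction"].to_numpy()

    def _props(col: str, cats: Sequence[str]) -> pd.DataFrame:
        out = {}
        for direction, grp in sub.groupby("direction"):
            counts = grp[col].value_counts()
            out[direction] = counts.reindex(cats, fill_value=0) / len(grp)
        return pd.DataFrame(out)

    return _props("region_group", REGION_GROUPS), _props("island_relation", ISLAND_RELATIONS)


def dml_to_bed(dml: pd.DataFrame, manifest: pd.DataFrame, path) -> None:
    """Write significant loci as BED (0-based half-open) sorted by position."""
    sub = manifest.loc[dml["probe_id"]]
    bed = pd.DataFrame(
        {
            "chrom": sub["chrom"].to_numpy(),
            "start": sub["pos"].to_numpy() - 1,
            "end": sub["pos"].to_numpy(),
            "name": dml["probe_id"].to_numpy(),
            "score": dml["delta_beta"].to_numpy(),
            "strand": sub.get("strand", pd.Series("+", index=sub.index)).to_numpy(),
        }
    ).sort_values(["chrom", "start"])
    bed.to_csv(path, sep="\t", header=False, index=False)
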