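"""End-to-end orchestration: DM -> annotate -> DE -> integrate -> enrich -> rank -> qPCR.

A single :class:`PipelineConfig` names the input files and thresholds; all
outputs are written to one directory together with a JSON provenance record
(config hash, seed, package version). Stage failures raise
:class:`StageError` naming the stage. Optional inputs (GMT collections, Ct
table, exclusion list) simply skip their stage when absent.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field, asdict
from importlib import resources
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .annotation import dml_region_distribution, dml_to_bed, read_manifest
from .enrichment import enrich, read_gmt
from .expression import call_degs, nb_wald_test, pca_qc
from .integration import (
    classify_dmgs,
    direction_counts,
    filter_reported,
    join_dm_de,
    rank_candidates,
    region_correlation,
)
from .io import read_gene_list, read_matrix, read_samples, write_json, write_tsv
from .methylation import call_dml, quantile_normalize, sample_correlation_qc, significant_dml
from .qpcr import analyze_qpcr

_FIXTURE_SHA256 = {
    "table_hyper_down.tsv": "bfc14dddeefaa8b45b55538c6c0116e8c251ff71ef3851aef3f001f51926c85b",
    "table_hypo_up.tsv": "bf33d6a36c6ff051a49e4fac2dcb892bb597ad88c68d49c6f5673fb5d8540f78",
}


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    beta: str | None = None
    counts: str | None = None
    manifest: str | None = None
    samples: str | None = None
    samples_rna: str | None = None  # defaults to `samples`
    gmt: str | None = None
    ct: str | None = None
    exclusion_list: str | None = None
    delta_beta: float = 0.2
    dm_p: float = 0.05
    lfc: float = 1.0
    padj: float = 0.05
    top_k: int = 15
    paired: bool = False
    normalize: bool = False
    enrichment_background: str = "platform"  # or "expressed"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("delta_beta", "dm_p", "lfc", "padj"):
            if getattr(self, name) <= 0:
                raise ValueError(f"threshold {name} must be positive")
        if self.top_k < 1:
            raise ValueError("top_k must be positive")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:16]


def _require(config: PipelineConfig, names: list[str], stage: str) -> None:
    for name in names:
        value = getattr(config, name)
        if value is None:
            raise StageError(f"[{stage}] config field '{name}' is required")
        if not Path(value).exists():
            raise StageError(f"[{stage}] input file not found: {value}")


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Run every configured stage and write the result bundle to ``outdir``.

    Returns a dict of in-memory results keyed by stage name; files are
    written with diff-stable formatting plus a ``provenance.json`` record.
    """
    _require(config, ["beta", "manifest", "samples", "counts"], "configuration")
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict = {}

    try:
        manifest = read_manifest(config.manifest)
    except Exception as e:  # noqa: BLE001 - stage-named rethrow
        raise StageError(f"[annotate] {e}") from e

    try:
        beta = read_matrix(config.beta)
        samples = read_samples(config.samples)
        if config.normalize:
            beta = quantile_normalize(beta)
        results["qc_correlation"] = sample_correlation_qc(beta)
        dml = call_dml(beta, samples, config.delta_beta, config.dm_p,
                       paired=config.paired)
        results["dml"] = dml
        sig = significant_dml(dml)
        results["dml_significant"] = sig
        if len(sig):
            region_dist, island_dist = dml_region_distribution(sig, manifest)
            results["dml_region_distribution"] = region_dist
            results["dml_island_distribution"] = island_dist
            dml_to_bed(sig, manifest, out / "dml_significant.bed")
        else:
            warnings.warn("no significant DM loci")
    except StageError:
        raise
    except Exception as e:
        raise StageError(f"[differential-methylation] {e}") from e

    try:
        counts = read_matrix(config.counts)
        samples_rna = read_samples(config.samples_rna or config.samples)
        de = nb_wald_test(counts, samples_rna)
        results["de"] = de
        up, down = call_degs(de, config.lfc, config.padj)
        results["degs"] = {"up": up, "down": down}
        coords, var_frac = pca_qc(counts)
        results["pca"] = {"coordinates": coords, "variance_fraction": list(var_frac)}
    except Exception as e:
        raise StageError(f"[differential-expression] {e}") from e

    try:
        records = join_dm_de(results["dml_significant"], manifest, de)
        results["integrated"] = records
        results["region_correlation"] = region_correlation(records)
        results["dmg_quadrants"] = classify_dmgs(records)
        results["dmg_directions"] = direction_counts(records)
        hyper_down, hypo_up = rank_candidates(
            records, config.top_k, config.lfc, config.padj
        )
        if config.exclusion_list:
            excl = read_gene_list(config.exclusion_list)
            hyper_down = filter_reported(hyper_down, excl)
            hypo_up = filter_reported(hypo_up, excl)
        results["candidates_hyper_down"] = hyper_down
        results["candidates_hypo_up"] = hypo_up
    except Exception as e:
        raise StageError(f"[integration] {e}") from e

    if config.gmt:
        try:
            collection = read_gmt(config.gmt)
            if config.enrichment_background == "expressed":
                universe = list(de["gene"])
            else:
                universe = sorted(
                    {g for anns in manifest["annotations"] for g, _ in anns}
                    | set(de["gene"])
                )
            tables = {}
            for name, genes in (("up", up), ("down", down)):
                if genes:
                    tables[name] = enrich(
                        [g for g in genes if g in set(universe)], universe, collection
                    )
            results["enrichment"] = tables
        except Exception as e:
            raise StageError(f"[enrichment] {e}") from e

    if config.ct:
        try:
            ct = pd.read_csv(config.ct, sep="\t")
            folds, summary = analyze_qpcr(ct)
            results["qpcr_folds"] = folds
            results["qpcr_summary"] = summary
        except Exception as e:
            raise StageError(f"[qpcr] {e}") from e

    _write_bundle(results, out)
    write_json(
        {
            "config": asdict(config),
            "config_sha256_16": config.digest(),
            "seed": config.seed,
            "package": "methexpress",
            "version": __version__,
        },
        out / "provenance.json",
    )
    return results


def _write_bundle(results: dict, out: Path) -> None:
    tables = {
        "qc_correlation": ("qc_sample_correlation.tsv", True),
        "dml": ("dml_all.tsv", False),
        "dml_significant": ("dml_significant.tsv", False),
        "dml_region_distribution": ("dml_region_distribution.tsv", True),
        "dml_island_distribution": ("dml_island_distribution.tsv", True),
        "de": ("de_results.tsv", False),
        "integrated": ("integrated_records.tsv", False),
        "region_correlation": ("region_correlation.tsv", False),
        "dmg_quadrants": ("dmg_quadrant_counts.tsv", False),
        "dmg_directions": ("dmg_direction_counts.tsv", False),
        "candidates_hyper_down": ("candidates_hyper_down.tsv", False),
        "candidates_hypo_up": ("candidates_hypo_up.tsv", False),
        "qpcr_folds": ("qpcr_fold_changes.tsv", False),
        "qpcr_summary": ("qpcr_summary.tsv", False),
    }
    for key, (fname, keep_index) in tables.items():
        if key in results:
            df = results[key]
            if key == "integrated" and "annotations" in df.columns:
                df = df.drop(columns=["annotations"])
            write_tsv(df, out / fname, index=keep_index)
    if "degs" in results:
        from .io import write_gene_list

        write_gene_list(results["degs"]["up"], out / "degs_up.txt")
        write_gene_list(results["degs"]["down"], out / "degs_down.txt")
    if "pca" in results:
        write_tsv(results["pca"]["coordinates"].rename_axis("sample_id"),
                  out / "pca_coordinates.tsv", index=True)
    for name, table in results.get("enrichment", {}).items():
        write_tsv(table, out / f"enrichment_{name}.tsv")


def load_fixture_tables(verify: bool = True) -> tuple[pd.DataFrame, pd.DataFrame]:
    """The two 15-row in-package candidate tables (worked-example fixtures).

    Table A: hypermethylated-downregulated genes; table B:
    hypomethylated-upregulated genes. ``beta_change`` is the absolute
    group-mean difference and is re-derivable from the two mean columns;
    signed ``delta_beta`` and ``abs_delta_beta`` helper columns are added.
    A SHA-256 mismatch on either file raises an integrity error.
    """
    out = []
    for fname in ("table_hyper_down.tsv", "table_hypo_up.tsv"):
        ref = resources.files("methexpress.data").joinpath(fname)
        raw = ref.read_bytes()
        if verify and hashlib.sha256(raw).hexdigest() != _FIXTURE_SHA256[fname]:
            raise RuntimeError(f"fixture integrity error: {fname}")
        df = pd.read_csv(ref.open("r"), sep="\t", keep_default_na=False)
        df["padj"] = df["padj"].astype(float)
        df["delta_beta"] = df["beta_case_avg"] - df["beta_control_avg"]
        df["abs_delta_beta"] = df["delta_beta"].abs()
        out.append(df)
    return out[0], out[1]
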