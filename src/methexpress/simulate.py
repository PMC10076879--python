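"""Synthetic matched case/control methylation + expression datasets.

The generator emulates the study design the pipeline targets: matched
ectopic/eutopic-style sample pairs measured on a 450K-style methylation
array (Beta-distributed β values with planted |Δβ| effects on a subset of
probes) and by RNA-seq-style gene counts (negative-binomial with log-normal
library-size factors and planted log2 fold changes). A configurable
negative coupling ties promoter-probe methylation shifts to the annotated
gene's expression, so the promoter-methylation/expression integration has
a planted, recoverable signal.

All randomness flows from ``SimulationConfig.seed`` through independent
SeedSequence children per stage; identical configs give bit-identical
outputs.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .annotation import classify_island_relation, manifest_from_records, ProbeRecord

_BETA_EPS = 1e-6
_MEAN_MARGIN = 0.03  # planted group means kept inside (margin, 1 - margin)


@dataclass
class SimulationConfig:
    """Study-design parameters for one synthetic dataset.

    Defaults mirror a small matched-pair tissue study: 6 case/control pairs,
    Beta-precision 40 methylation noise, |Δβ| = 0.3 planted effects on 5% of
    probes, |log2FC| = 2 on 5% of genes with NB dispersion 0.05, and full
    negative promoter coupling.
    """

    n_pairs: int = 6
    n_probes: int = 5000
    n_genes: int = 800
    frac_dml: float = 0.05
    delta_beta_effect: float = 0.3
    frac_deg: float = 0.05
    lfc_effect: float = 2.0
    nb_dispersion: float = 0.05
    coupling_strength: float = -1.0
    base_depth: float = 400_000.0
    beta_precision: float = 40.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pairs < 2:
            raise ValueError("need at least two matched pairs")
        if self.n_probes < 1 or self.n_genes < 1:
            raise ValueError("n_probes and n_genes must be positive")
        if self.n_probes < self.n_genes:
            raise ValueError("need n_probes >= n_genes")
        for name in ("frac_dml", "frac_deg"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if not 0 <= self.delta_beta_effect <= 1:
            raise ValueError("delta_beta_effect must lie in [0, 1]")
        if self.lfc_effect < 0:
            raise ValueError("lfc_effect must be non-negative")
        if self.nb_dispersion <= 0 or self.beta_precision <= 0 or self.base_depth <= 0:
            raise ValueError("dispersion, precision and depth must be positive")
        if not -1 <= self.coupling_strength <= 0:
            raise ValueError("coupling_strength must lie in [-1, 0]")


@dataclass
class SyntheticTruth:
    """Planted-effect bookkeeping for recovery tests.

    ``dml_effects`` maps planted probe -> signed Δβ; ``deg_effects`` maps
    planted gene -> signed log2FC (independent of methylation);
    ``coupled_genes`` maps gene -> (promoter probe id, realized log2FC
    induced by the coupling).
    """

    dml_effects: dict = field(default_factory=dict)
    deg_effects: dict = field(default_factory=dict)
    coupled_genes: dict = field(default_factory=dict)

    @property
    def dml_probes(self) -> set:
        return set(self.dml_effects)

    @property
    def deg_genes(self) -> set:
        return set(self.deg_effects)

    def to_json(self, path) -> None:
        payload = {
            "dml_effects": self.dml_effects,
            "deg_effects": self.deg_effects,
            "coupled_genes": {g: list(v) for g, v in self.coupled_genes.items()},
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        d = json.loads(Path(path).read_text())
        return cls(
            dml_effects=d["dml_effects"],
            deg_effects=d["deg_effects"],
            coupled_genes={g: tuple(v) for g, v in d["coupled_genes"].items()},
        )


def _rng_children(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.Generator(np.random.PCG64(s))
            for s in np.random.SeedSequence(seed).spawn(n)]


def generate_manifest(n_probes: int, n_genes: int, seed: int, n_chroms: int = 5):
    """Synthetic probe manifest, gene models and CpG-island intervals.

    Returns ``(manifest, genes, islands)``: a probe-indexed manifest
    DataFrame, a gene-model DataFrame (chrom, tss, length, strand) and a
    per-chromosome dict of 1-based inclusive island intervals. Probe
    positions are drawn relative to gene models (promoter / 5'UTR /
    1st exon / body / 3'UTR) with intergenic and multi-annotation probes
    mixed in; each probe's island relation is derived geometrically from
    the island intervals (shores = 2 kb flanks, shelves the next 2 kb).
    """
    if n_probes < 1 or n_genes < 1:
        raise ValueError("n_probes and n_genes must be positive")
    if n_probes < n_genes:
        raise ValueError("need n_probes >= n_genes")
    rng = _rng_children(seed, 1)[0]
    n_chroms = max(1, min(n_chroms, n_genes))
    chrom_len = 20_000_000

    genes = pd.DataFrame(
        {
            "gene": [f"GENE{i:04d}" for i in range(n_genes)],
            "chrom": [f"chr{(i % n_chroms) + 1}" for i in range(n_genes)],
            "tss": rng.integers(100_000, chrom_len - 100_000, size=n_genes),
            "length": rng.integers(3_000, 60_000, size=n_genes),
            "strand": rng.choice(["+", "-"], size=n_genes),
        }
    ).set_index("gene", drop=False)

    # islands: over TSSs of about half the genes, plus free-standing ones
    islands: dict[str, list[tuple[int, int]]] = {f"chr{c + 1}": [] for c in range(n_chroms)}
    for _, g in genes.iterrows():
        if rng.random() < 0.5:
            length = int(rng.integers(300, 2001))
            start = int(g["tss"] - rng.integers(100, 1000))
            islands[g["chrom"]].append((max(1, start), max(1, start) + length - 1))
    for _ in range(max(1, n_genes // 2)):
        chrom = f"chr{int(rng.integers(n_chroms)) + 1}"
        length = int(rng.integers(300, 2001))
        start = int(rng.integers(1, chrom_len - length))
        islands[chrom].append((start, start + length - 1))
    islands = {c: sorted(iv) for c, iv in islands.items()}

    classes_genic = ["5UTR", "1stExon", "Body", "3UTR"]
    records: list[ProbeRecord] = []
    for i in range(n_probes):
        pid = f"cg{i:08d}"
        kind = rng.choice(
            ["promoter", "genic", "multi", "intergenic"], p=[0.25, 0.40, 0.05, 0.30]
        )
        if kind == "intergenic":
            chrom = f"chr{int(rng.integers(n_chroms)) + 1}"
            pos = int(rng.integers(1, chrom_len))
            anns: list[tuple[str, str]] = []
        else:
            g = genes.iloc[int(rng.integers(n_genes))]
            chrom, tss, glen = g["chrom"], int(g["tss"]), int(g["length"])
            if kind == "promoter":
                off = int(rng.integers(1, 1501))
                pos = tss - off
                anns = [(g["gene"], "TSS200" if off <= 200 else "TSS1500")]
            else:
                cls = classes_genic[int(rng.integers(4))]
                if cls == "5UTR":
                    pos = tss + int(rng.integers(0, 300))
                elif cls == "1stExon":
                    pos = tss + int(rng.integers(300, 800))
                elif cls == "Body":
                    pos = tss + int(rng.integers(800, max(801, glen - 500)))
                else:
                    pos = tss + glen - int(rng.integers(0, 500))
                anns = [(g["gene"], cls)]
                if kind == "multi":
                    other = classes_genic[int(rng.integers(4))]
                    if other == cls:
                        other = "Body" if cls != "Body" else "3UTR"
                    anns.append((g["gene"], other))
        pos = max(1, pos)
        rel = classify_island_relation(pos, islands.get(chrom, []))
        records.append(
            ProbeRecord(pid, chrom, pos, str(rng.choice(["+", "-"])), anns, rel)
        )
    return manifest_from_records(records), genes, islands


def _sample_sheet(n_pairs: int) -> pd.DataFrame:
    rows = []
    for i in range(1, n_pairs + 1):
        rows.append({"sample_id": f"case_{i}", "group": "case", "pair_id": f"P{i}"})
    for i in range(1, n_pairs + 1):
        rows.append({"sample_id": f"control_{i}", "group": "control", "pair_id": f"P{i}"})
    return pd.DataFrame(rows)


def generate_methylation(manifest: pd.DataFrame, config: SimulationConfig):
    """β matrix with planted group-mean shifts on a random probe subset.

    Each probe's β values are Beta(μφ, (1-μ)φ) draws; planted probes'
    case-group mean is shifted by a signed ``delta_beta_effect`` (clamped
    into (0, 1) with a warning when necessary). Returns
    ``(beta, samples, truth)``.
    """
    rng = _rng_children(config.seed, 3)[1]
    n_probes = len(manifest)
    phi = config.beta_precision
    delta = config.delta_beta_effect

    mu0 = rng.uniform(0.05, 0.95, size=n_probes)
    n_dml = int(round(config.frac_dml * n_probes))
    planted_idx = rng.choice(n_probes, size=n_dml, replace=False)
    signs = rng.choice([-1.0, 1.0], size=n_dml)

    lo, hi = _MEAN_MARGIN, 1.0 - _MEAN_MARGIN
    mu_case = mu0.copy()
    clamped = 0
    for j, (idx, s) in enumerate(zip(planted_idx, signs)):
        # re-draw the base mean so the shifted mean stays inside (0, 1)
        if s > 0:
            if hi - delta > lo:
                mu0[idx] = rng.uniform(lo, hi - delta)
            else:
                mu0[idx] = lo
        else:
            if lo + delta < hi:
                mu0[idx] = rng.uniform(lo + delta, hi)
            else:
                mu0[idx] = hi
        shifted = mu0[idx] + s * delta
        if not lo <= shifted <= hi:
            shifted = min(max(shifted, _BETA_EPS), 1 - _BETA_EPS)
            clamped += 1
        mu_case[idx] = shifted
    mu_case[np.setdiff1d(np.arange(n_probes), planted_idx)] = mu0[
        np.setdiff1d(np.arange(n_probes), planted_idx)
    ]
    if clamped:
        warnings.warn(f"{clamped} planted probes clamped to keep means inside (0, 1)")

    samples = _sample_sheet(config.n_pairs)
    n = config.n_pairs
    case = rng.beta(mu_case[:, None] * phi, (1 - mu_case[:, None]) * phi, size=(n_probes, n))
    ctrl = rng.beta(mu0[:, None] * phi, (1 - mu0[:, None]) * phi, size=(n_probes, n))
    mat = np.clip(np.hstack([case, ctrl]), _BETA_EPS, 1 - _BETA_EPS)
    beta = pd.DataFrame(mat, index=manifest.index, columns=samples["sample_id"])

    probe_ids = manifest.index.to_numpy()
    truth = SyntheticTruth(
        dml_effects={
            str(probe_ids[idx]): float(s * delta) for idx, s in zip(planted_idx, signs)
        }
    )
    return beta, samples, truth


def _promoter_couples(manifest: pd.DataFrame, truth: SyntheticTruth) -> dict[str, str]:
    """Gene -> planted promoter probe (first probe id wins per gene)."""
    couples: dict[str, str] = {}
    for probe in sorted(truth.dml_effects):
        for gene, cls in manifest.loc[probe, "annotations"]:
            if cls in ("TSS1500", "TSS200") and gene not in couples:
                couples[gene] = probe
    return couples


def generate_counts(
    genes: pd.DataFrame,
    config: SimulationConfig,
    truth: SyntheticTruth,
    manifest: pd.DataFrame | None = None,
):
    """NB count matrix with planted DEGs and promoter-coupled genes.

    Planted DEGs receive signed ``lfc_effect`` on well-expressed genes
    (normalized base mean >= 100). When a manifest is supplied, every gene
    carrying a planted promoter DML becomes a coupled gene whose log2FC is
    ``coupling_strength * (Δβ / delta_beta_effect) * lfc_effect`` — with
    negative coupling, hypermethylated promoters depress expression.
    Returns ``(counts, samples, truth)`` with the truth updated in place.
    """
    rng = _rng_children(config.seed, 3)[2]
    gene_ids = list(genes["gene"])
    n_genes = len(gene_ids)
    base = rng.lognormal(np.log(config.base_depth / max(n_genes, 1)), 1.0, size=n_genes)

    lfc = np.zeros(n_genes)
    gene_pos = {g: i for i, g in enumerate(gene_ids)}

    couples = _promoter_couples(manifest, truth) if manifest is not None else {}
    for gene, probe in couples.items():
        if gene not in gene_pos:
            continue
        d = truth.dml_effects[probe]
        scale = d / config.delta_beta_effect if config.delta_beta_effect > 0 else 0.0
        val = config.coupling_strength * scale * config.lfc_effect
        lfc[gene_pos[gene]] = val
        truth.coupled_genes[gene] = (probe, float(val))

    n_deg = int(round(config.frac_deg * n_genes))
    free = [g for g in gene_ids if g not in truth.coupled_genes]
    chosen = rng.choice(len(free), size=min(n_deg, len(free)), replace=False)
    for j in chosen:
        g = free[j]
        s = float(rng.choice([-1.0, 1.0]))
        lfc[gene_pos[g]] = s * config.lfc_effect
        truth.deg_effects[g] = s * config.lfc_effect
    # planted and coupled effects sit on adequately expressed genes
    for g in list(truth.deg_effects) + list(truth.coupled_genes):
        i = gene_pos.get(g)
        if i is not None and base[i] < 100:
            base[i] = rng.uniform(100, 1000)

    samples = _sample_sheet(config.n_pairs)
    sf = rng.lognormal(0.0, 0.2, size=len(samples))
    is_case = (samples["group"] == "case").to_numpy().astype(float)
    mean = base[:, None] * np.power(2.0, lfc[:, None] * is_case[None, :]) * sf[None, :]
    r = 1.0 / config.nb_dispersion
    counts = rng.negative_binomial(r, r / (r + mean))
    counts = pd.DataFrame(counts, index=pd.Index(gene_ids, name="gene"),
                          columns=samples["sample_id"])
    return counts, samples, truth


def generate_qpcr(
    config: SimulationConfig,
    truth: SyntheticTruth,
    n_patients: int = 7,
    n_assay_genes: int = 5,
) -> pd.DataFrame:
    """Synthetic Ct table for a handful of planted genes (β-actin-style reference).

    Case samples' ΔCt is lowered by each gene's true log2FC (one PCR cycle
    per doubling), so the 2^-ΔΔCt readout recovers the planted folds.
    """
    rng = _rng_children(config.seed, 4)[3]
    effects = dict(truth.deg_effects)
    effects.update({g: v for g, (_, v) in truth.coupled_genes.items()})
    assay = sorted(effects, key=lambda g: -abs(effects[g]))[:n_assay_genes]
    if not assay:
        raise ValueError("no planted genes available for qPCR simulation")
    rows = []
    for gene in assay:
        base_dct = rng.normal(8.0, 0.5)
        for i in range(1, n_patients + 1):
            for group in ("case", "control"):
                ref = rng.normal(15.0, 0.2)
                dct = base_dct + rng.normal(0.0, 0.3)
                if group == "case":
                    dct -= effects[gene]
                rows.append(
                    {"sample_id": f"{group}_{i}", "group": group, "gene": gene,
                     "ct_target": ref + dct, "ct_reference": ref}
                )
    return pd.DataFrame(rows)


def generate_gmt(genes: pd.DataFrame, truth: SyntheticTruth, seed: int,
                 n_sets: int = 10) -> list[tuple[str, str, list[str]]]:
    """Synthetic gene-set collection: random sets plus one planted-DEG set."""
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence([seed, 91])))
    universe = list(genes["gene"])
    sets = []
    for i in range(n_sets):
        size = int(rng.integers(20, 51))
        members = list(rng.choice(universe, size=min(size, len(universe)), replace=False))
        sets.append((f"RANDOM_SET_{i:02d}", "synthetic random set", members))
    planted = sorted(set(truth.deg_effects) | set(truth.coupled_genes))
    if planted:
        spike = planted[: min(30, len(planted))]
        pad = list(rng.choice(universe, size=10, replace=False))
        sets.append(("PLANTED_EFFECT_SET", "synthetic set enriched in planted genes",
                     sorted(set(spike + pad))))
    return sets


def simulate_dataset(config: SimulationConfig) -> dict:
    """Full synthetic bundle: manifest, β, counts, sample sheet, truth, GMT, Ct."""
    manifest, genes, islands = generate_manifest(
        config.n_probes, config.n_genes, config.seed
    )
    beta, samples, truth = generate_methylation(manifest, config)
    counts, _, truth = generate_counts(genes, config, truth, manifest)
    bundle = {
        "config": config,
        "manifest": manifest,
        "genes": genes,
        "islands": islands,
        "beta": beta,
        "counts": counts,
        "samples": samples,
        "truth": truth,
        "gmt": generate_gmt(genes, truth, config.seed),
    }
    try:
        bundle["ct"] = generate_qpcr(config, truth)
    except ValueError:
        bundle["ct"] = None
    return bundle


def write_dataset(bundle: dict, outdir) -> dict[str, Path]:
    """Write a simulated bundle as plain-text files; returns the path map."""
    from .io import write_tsv
    from .enrichment import write_gmt

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = bundle["manifest"].drop(columns=["annotations", "region_group",
                                                "island_relation"])
    paths = {
        "manifest": out / "manifest.tsv",
        "beta": out / "beta.tsv",
        "counts": out / "counts.tsv",
        "samples": out / "samples.tsv",
        "genes": out / "genes.tsv",
        "truth": out / "truth.json",
        "gmt": out / "sets.gmt",
    }
    write_tsv(manifest, paths["manifest"], index=False)
    write_tsv(bundle["beta"].rename_axis("probe_id"), paths["beta"], index=True)
    write_tsv(bundle["counts"].rename_axis("gene"), paths["counts"], index=True)
    write_tsv(bundle["samples"], paths["samples"], index=False)
    write_tsv(bundle["genes"].reset_index(drop=True), paths["genes"], index=False)
    bundle["truth"].to_json(paths["truth"])
    write_gmt(bundle["gmt"], paths["gmt"])
    if bundle.get("ct") is not None:
        paths["ct"] = out / "ct.tsv"
        write_tsv(bundle["ct"], paths["ct"], index=False)
    return paths
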