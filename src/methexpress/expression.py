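"""Count-based differential expression: size factors, NB Wald test, PCA QC.

This is a deliberately simplified negative-binomial Wald stage, not a DESeq2
reimplementation: per-gene method-of-moments dispersion without shrinkage
across genes, no outlier refitting. Normalization is median-of-ratios;
fold changes use a pseudo-mean of 0.5 for stability at low counts; p-values
come from a two-sided t reference on the Wald statistic with n1 + n2 - 2
degrees of freedom (the dispersion and group means are estimated from few
replicates, and the normal reference is markedly anti-conservative there)
and are BH-adjusted. DEG gates follow padj < 0.05 and |log2FC| >= 1.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .methylation import bh_adjust

PSEUDO_MEAN = 0.5
DISPERSION_FLOOR = 1e-8


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios normalization factors, one per sample column.

    factor_j = median over genes (with positive geometric mean across
    samples) of counts[g, j] / geomean_g.
    """
    mat = pd.DataFrame(counts).to_numpy(dtype=float)
    if np.any(mat < 0):
        raise ValueError("counts must be non-negative")
    with np.errstate(divide="ignore"):
        log_mat = np.log(mat)
    finite = np.all(np.isfinite(log_mat), axis=1)
    if not finite.any():
        raise ValueError("no gene has nonzero counts in every sample")
    geomean = np.exp(log_mat[finite].mean(axis=1))
    factors = np.median(mat[finite] / geomean[:, None], axis=0)
    if np.any(factors <= 0) or np.any(~np.isfinite(factors)):
        raise ValueError("degenerate size factors")
    return pd.Series(factors, index=pd.DataFrame(counts).columns, name="size_factor")


def _moments_dispersion(Y: np.ndarray, Z: np.ndarray) -> np.ndarray:
    """Pooled per-gene method-of-moments NB dispersion from two groups.

    alpha_g = max(floor, df-weighted mean over groups of (s^2 - mu) / mu^2)
    under the NB variance mu + alpha * mu^2.
    """
    def group_alpha(M: np.ndarray) -> np.ndarray:
        mu = M.mean(axis=1)
        s2 = M.var(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            a = (s2 - mu) / mu**2
        return np.where(mu > 0, a, 0.0)

    w1, w2 = Y.shape[1] - 1, Z.shape[1] - 1
    alpha = (w1 * group_alpha(Y) + w2 * group_alpha(Z)) / (w1 + w2)
    return np.maximum(alpha, DISPERSION_FLOOR)


def nb_wald_test(counts: pd.DataFrame, samples: pd.DataFrame) -> pd.DataFrame:
    """Per-gene NB Wald test of case vs control on a genes x samples matrix.

    Genes with zero counts in every sample are excluded (their ids are kept
    in the result's ``attrs['excluded']``). Returns gene, base_mean, group
    means, log2fc = log2((mu_case + 0.5) / (mu_control + 0.5)), Wald
    p-value, BH padj and direction.
    """
    counts = pd.DataFrame(counts)
    if not np.allclose(counts.to_numpy(), np.round(counts.to_numpy())):
        raise ValueError("counts must be integer-valued")
    case_ids = list(samples.loc[samples["group"] == "case", "sample_id"])
    control_ids = list(samples.loc[samples["group"] == "control", "sample_id"])
    if len(case_ids) < 2 or len(control_ids) < 2:
        raise ValueError("each group needs at least two samples")

    sf = size_factors(counts)
    norm = counts.to_numpy(dtype=float) / sf.to_numpy()[None, :]
    norm = pd.DataFrame(norm, index=counts.index, columns=counts.columns)

    nonzero = counts.sum(axis=1) > 0
    excluded = list(counts.index[~nonzero])
    norm = norm.loc[nonzero]

    Y = norm[case_ids].to_numpy()
    Z = norm[control_ids].to_numpy()
    mu1, mu2 = Y.mean(axis=1), Z.mean(axis=1)
    log2fc = np.log2((mu1 + PSEUDO_MEAN) / (mu2 + PSEUDO_MEAN))

    alpha = _moments_dispersion(Y, Z)
    ln2sq = np.log(2.0) ** 2
    # delta method on log2(mu + c): Var(mu_hat) = (mu + alpha mu^2)/n
    var_l2 = (
        (mu1 + alpha * mu1**2) / (Y.shape[1] * (mu1 + PSEUDO_MEAN) ** 2)
        + (mu2 + alpha * mu2**2) / (Z.shape[1] * (mu2 + PSEUDO_MEAN) ** 2)
    ) / ln2sq
    se = np.sqrt(np.maximum(var_l2, 1e-300))
    wald = log2fc / se
    df = Y.shape[1] + Z.shape[1] - 2
    pvals = 2.0 * stats.t.sf(np.abs(wald), df)
    pvals = np.minimum(pvals, 1.0)

    res = pd.DataFrame(
        {
            "gene": norm.index.astype(str),
            "base_mean": norm.to_numpy().mean(axis=1),
            "mean_case": mu1,
            "mean_control": mu2,
            "log2fc": log2fc,
            "se": se,
            "stat": wald,
            "p_value": pvals,
            "padj": bh_adjust(pvals),
        },
        index=norm.index,
    )
    res["direction"] = np.where(res["log2fc"] >= 0, "up", "down")
    res.attrs["excluded"] = excluded
    res.attrs["size_factors"] = sf.to_dict()
    return res


def call_degs(
    results: pd.DataFrame, lfc_threshold: float = 1.0, padj_threshold: float = 0.05
) -> tuple[list[str], list[str]]:
    """Up/down differentially expressed gene lists at the stated gates."""
    if results.empty:
        raise ValueError("empty DE results")
    sig = results["padj"] < padj_threshold
    up = list(results.loc[sig & (results["log2fc"] >= lfc_threshold), "gene"])
    down = list(results.loc[sig & (results["log2fc"] <= -lfc_threshold), "gene"])
    return up, down


def pca_qc(counts: pd.DataFrame, n_components: int = 2) -> tuple[pd.DataFrame, np.ndarray]:
    """Sample PCA on log2(normalized count + 1), gene-centered, via SVD.

    Returns per-sample coordinates on the leading components and the
    variance-explained fractions. Component signs are fixed so the
    largest-magnitude gene loading is positive.
    """
    counts = pd.DataFrame(counts)
    if counts.shape[1] < 3:
        raise ValueError("PCA QC needs at least three samples")
    sf = size_factors(counts)
    X = np.log2(counts.to_numpy(dtype=float) / sf.to_numpy()[None, :] + 1.0)
    X = X - X.mean(axis=1, keepdims=True)  # center genes
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    k = min(n_components, Vt.shape[0])
    for i in range(k):
        j = np.argmax(np.abs(U[:, i]))
        if U[j, i] < 0:
            U[:, i] *= -1
            Vt[i] *= -1
    total = (S**2).sum()
    var_frac = (S[:k] ** 2) / total if total > 0 else np.zeros(k)
    coords = pd.DataFrame(
        (Vt[:k].T * S[:k]),
        index=counts.columns,
        columns=[f"PC{i + 1}" for i in range(k)],
    )
    return coords, var_frac


def set_overlap(list_a, list_b) -> dict:
    """Overlap of two identifier lists, with the shared share of list A.

    Mirrors a two-set Venn readout: |A∩B|, |A\\B|, |B\\A| and
    100 * |A∩B| / |A|.
    """
    A, B = set(list_a), set(list_b)
    if not A:
        raise ValueError("list_a is empty; overlap percentage undefined")
    inter = A & B
    return {
        "intersection": len(inter),
        "a_only": len(A - B),
        "b_only": len(B - A),
        "pct_a_shared": 100.0 * len(inter) / len(A),
    }


def top_table(results: pd.DataFrame, n: int = 10, by: str = "padj") -> pd.DataFrame:
    """Top up- and downregulated genes, ranked by padj then |log2fc|.

    ``by='lfc'`` ranks by |log2fc| first instead.
    """
    if by == "padj":
        keys, asc = ["padj", "abs_lfc"], [True, False]
    elif by == "lfc":
        keys, asc = ["abs_lfc", "padj"], [False, True]
    else:
        raise ValueError("by must be 'padj' or 'lfc'")
    df = results.assign(abs_lfc=results["log2fc"].abs())
    up = df[df["log2fc"] > 0].sort_values(keys, ascending=asc).head(n)
    down = df[df["log2fc"] < 0].sort_values(keys, ascending=asc).head(n)
    return pd.concat([up, down]).drop(columns="abs_lfc")
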