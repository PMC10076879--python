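"""β-value computation, normalization, QC and differential-methylation calling.

The differential test is the two-sided Wilcoxon rank-sum (Mann-Whitney) test
by default — exact for small designs without ties, otherwise the normal
approximation with midrank tie correction. No continuity correction is
applied in the approximation: the exact null distribution is discrete, and
at typical group sizes the correction stacks on that discreteness to make
null p-values visibly conservative (non-uniform); the plain approximation
is the better-calibrated choice. A probe is called differentially
methylated when the raw p-value
is below ``p_threshold`` AND the group-mean difference |Δβ| meets
``delta_threshold`` (default 0.2). BH false-discovery-rate values are
computed and reported alongside but do not gate the call.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

DEFAULT_BETA_OFFSET = 100.0
DEFAULT_EXACT_THRESHOLD = 12


def compute_beta(M, U, offset: float = DEFAULT_BETA_OFFSET):
    """β = M / (M + U + offset), elementwise.

    The offset (default 100) regularizes low-intensity probes, bounding β
    in [0, M/(M+offset)) strictly below 1.
    """
    M = np.asarray(M, dtype=float)
    U = np.asarray(U, dtype=float)
    if offset <= 0:
        raise ValueError("offset must be positive")
    if np.any(M < 0) or np.any(U < 0):
        raise ValueError("intensities must be non-negative")
    return M / (M + U + offset)


def quantile_normalize(matrix: pd.DataFrame, impute_missing: bool = False) -> pd.DataFrame:
    """Quantile-normalize columns to a common (row-mean of sorted) distribution.

    After normalization every column holds the same multiset of values — the
    row-wise mean of the per-column sorted values — placed in each column's
    original rank order. Tied entries within a column receive the mean of the
    reference values their positions span.
    """
    df = pd.DataFrame(matrix).astype(float)
    if df.isna().any().any():
        if not impute_missing:
            raise ValueError("matrix has missing values; set impute_missing=True")
        row_means = df.mean(axis=1)
        df = df.apply(lambda col: col.fillna(row_means))
    if df.shape[1] < 2:
        warnings.warn("single-column matrix: quantile normalization is the identity")
        return df.copy()
    ref = np.sort(df.to_numpy(), axis=0).mean(axis=1)
    out = np.empty_like(df.to_numpy())
    for j, col in enumerate(df.to_numpy().T):
        order = np.argsort(col, kind="stable")
        mapped = np.empty_like(ref)
        mapped[order] = ref
        # ties: average the reference values assigned across the tie run
        sorted_vals = col[order]
        i = 0
        while i < len(sorted_vals):
            k = i
            while k + 1 < len(sorted_vals) and sorted_vals[k + 1] == sorted_vals[i]:
                k += 1
            if k > i:
                mapped[order[i : k + 1]] = ref[i : k + 1].mean()
            i = k + 1
        out[:, j] = mapped
    return pd.DataFrame(out, index=df.index, columns=df.columns)


def sample_correlation_qc(matrix: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Pearson correlation between sample columns.

    Standard profile-reproducibility QC: matched case/control methylomes are
    expected to correlate highly. Zero-variance samples yield NaN against
    every partner and a warning.
    """
    df = pd.DataFrame(matrix).astype(float)
    if df.shape[1] < 2:
        raise ValueError("need at least two samples")
    degenerate = df.columns[df.std(axis=0, ddof=0) == 0]
    if len(degenerate):
        warnings.warn(f"zero-variance samples flagged: {list(degenerate)}")
    corr = df.corr(method="pearson")
    np.fill_diagonal(corr.values, 1.0)
    return corr


def wilcoxon_rank_sum(
    x, y, exact_threshold: int = DEFAULT_EXACT_THRESHOLD, paired: bool = False
) -> float:
    """Two-sided Wilcoxon p-value for two samples.

    Unpaired (rank-sum/Mann-Whitney) by default. The exact null distribution
    is used when the pooled size is at most ``exact_threshold`` and the data
    carry no ties; otherwise the normal approximation with midrank tie
    correction. ``paired=True`` switches to the signed-rank test on x - y.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs at least two observations")
    if paired:
        if x.size != y.size:
            raise ValueError("paired test requires equal sizes")
        d = x - y
        if np.all(d == 0):
            return 1.0
        method = "exact" if x.size <= exact_threshold else "approx"
        return float(stats.wilcoxon(x, y, method=method).pvalue)
    pooled = np.concatenate([x, y])
    no_ties = len(np.unique(pooled)) == pooled.size
    if x.size + y.size <= exact_threshold and no_ties:
        method = "exact"
    else:
        method = "asymptotic"
    p = stats.mannwhitneyu(x, y, alternative="two-sided", method=method,
                           use_continuity=False).pvalue
    return float(min(p, 1.0))


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _group_columns(samples: pd.DataFrame) -> tuple[list, list]:
    if not {"sample_id", "group"} <= set(samples.columns):
        raise ValueError("sample sheet needs sample_id and group columns")
    bad = set(samples["group"]) - {"case", "control"}
    if bad:
        raise ValueError(f"unknown group labels: {sorted(bad)}")
    case = list(samples.loc[samples["group"] == "case", "sample_id"])
    control = list(samples.loc[samples["group"] == "control", "sample_id"])
    return case, control


def call_dml(
    beta: pd.DataFrame,
    samples: pd.DataFrame,
    delta_threshold: float = 0.2,
    p_threshold: float = 0.05,
    paired: bool = False,
    exact_threshold: int = DEFAULT_EXACT_THRESHOLD,
) -> pd.DataFrame:
    """Differential-methylation calling on a probes x samples β matrix.

    Returns one row per probe with group means, signed Δβ (case - control),
    raw Wilcoxon p, BH fdr, direction (hyper = higher in case) and the
    ``significant`` flag: raw p < ``p_threshold`` and |Δβ| >= ``delta_threshold``.
    """
    beta = pd.DataFrame(beta).astype(float)
    if ((beta < 0) | (beta > 1)).any().any():
        raise ValueError("β values must lie in [0, 1]")
    case_ids, control_ids = _group_columns(samples)
    if len(case_ids) < 2 or len(control_ids) < 2:
        raise ValueError("each group needs at least two samples")
    X = beta[case_ids].to_numpy()
    Y = beta[control_ids].to_numpy()

    mean_case = X.mean(axis=1)
    mean_control = Y.mean(axis=1)
    delta = mean_case - mean_control

    n_tot = X.shape[1] + Y.shape[1]
    if paired:
        pair_map = samples.set_index("sample_id")["pair_id"]
        order = np.argsort([pair_map[s] for s in control_ids])
        case_sorted = [case_ids[i] for i in np.argsort([pair_map[s] for s in case_ids])]
        ctrl_sorted = [control_ids[i] for i in order]
        Xp = beta[case_sorted].to_numpy()
        Yp = beta[ctrl_sorted].to_numpy()
        pvals = np.array(
            [wilcoxon_rank_sum(Xp[i], Yp[i], exact_threshold, paired=True)
             for i in range(len(beta))]
        )
    elif n_tot <= exact_threshold:
        pvals = np.array(
            [wilcoxon_rank_sum(X[i], Y[i], exact_threshold) for i in range(len(beta))]
        )
    else:
        res = stats.mannwhitneyu(X, Y, axis=1, alternative="two-sided",
                                 method="asymptotic", use_continuity=False)
        pvals = np.minimum(res.pvalue, 1.0)

    out = pd.DataFrame(
        {
            "probe_id": beta.index.astype(str),
            "beta_case_avg": mean_case,
            "beta_control_avg": mean_control,
            "delta_beta": delta,
            "abs_delta_beta": np.abs(delta),
            "p_value": pvals,
            "fdr": bh_adjust(pvals),
            "direction": np.where(delta >= 0, "hyper", "hypo"),
        },
        index=beta.index,
    )
    out["significant"] = (out["p_value"] < p_threshold) & (
        out["abs_delta_beta"] >= delta_threshold
    )
    return out


def significant_dml(dml: pd.DataFrame) -> pd.DataFrame:
    """The called subset of a call_dml table."""
    return dml.loc[dml["significant"]].copy()
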