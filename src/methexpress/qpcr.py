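"""Relative qPCR quantification (2^-ΔΔCt) and group comparison.

Each target gene is normalized to a reference gene (β-actin role):
ΔCt_s = Ct_target,s - Ct_reference,s, ΔΔCt_s = ΔCt_s - mean(control ΔCt),
fold_s = 2^(-ΔΔCt_s). Per-sample folds are reported; the control group's
geometric-mean fold is 1 by construction. Group comparison follows the
normality-driven rule: Welch t-test when both groups pass a
Lilliefors-style Kolmogorov-Smirnov normality check, Mann-Whitney
otherwise, with significance stars *** p<0.001, ** p<0.01, * p<0.05, ns.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.diagnostic import lilliefors

CT_COLUMNS = ("sample_id", "group", "gene", "ct_target", "ct_reference")


def stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def ddct_fold_change(records: pd.DataFrame) -> pd.DataFrame:
    """Per-sample 2^-ΔΔCt fold changes for one gene's Ct records.

    Rows missing a reference Ct are skipped with a warning. Requires at
    least one case and one control record after skipping.
    """
    df = pd.DataFrame(records)
    missing = set(CT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"Ct table missing columns: {sorted(missing)}")
    bad = df["ct_reference"].isna() | df["ct_target"].isna()
    if bad.any():
        warnings.warn(f"{int(bad.sum())} records skipped (missing Ct)")
        df = df.loc[~bad]
    if not np.isfinite(df[["ct_target", "ct_reference"]].to_numpy()).all() or (
        (df[["ct_target", "ct_reference"]] <= 0).any().any()
    ):
        raise ValueError("Ct values must be positive and finite")
    if df["gene"].nunique() > 1:
        raise ValueError("ddct_fold_change handles one gene at a time")
    n_case = (df["group"] == "case").sum()
    n_ctrl = (df["group"] == "control").sum()
    if n_case < 1 or n_ctrl < 1:
        raise ValueError("need at least one case and one control record")
    dct = df["ct_target"] - df["ct_reference"]
    baseline = dct[df["group"] == "control"].mean()
    ddct = dct - baseline
    out = df[["sample_id", "group", "gene"]].copy()
    out["delta_ct"] = dct.to_numpy()
    out["delta_delta_ct"] = ddct.to_numpy()
    out["fold_change"] = np.power(2.0, -ddct.to_numpy())
    return out.reset_index(drop=True)


def normality_check(values) -> tuple[float, bool]:
    """Lilliefors-style KS normality test (mean/SD estimated from the data).

    Returns (p_value, verdict); verdict is True ("normal") iff p >= 0.05.
    Zero-variance input is flagged non-normal.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValueError("normality check needs n >= 3")
    if np.ptp(x) == 0:
        warnings.warn("zero-variance sample: non-normal verdict")
        return 0.0, False
    if x.size >= 4:
        _, p = lilliefors(x, dist="norm")
    else:
        # n = 3: below the tabulated range; Monte-Carlo null of D (seeded)
        d_obs = ks_normality_statistic(x)
        null_rng = np.random.default_rng(0)
        null = [
            ks_normality_statistic(null_rng.standard_normal(x.size))
            for _ in range(2000)
        ]
        p = float(np.mean(np.asarray(null) >= d_obs))
    return float(p), bool(p >= 0.05)


def ks_normality_statistic(values) -> float:
    """Sup-distance D between the empirical CDF and the fitted normal CDF."""
    x = np.sort(np.asarray(values, dtype=float))
    n = x.size
    z = (x - x.mean()) / x.std(ddof=1)
    cdf = stats.norm.cdf(z)
    d_plus = np.max(np.arange(1, n + 1) / n - cdf)
    d_minus = np.max(cdf - np.arange(0, n) / n)
    return float(max(d_plus, d_minus))


def group_compare(case_values, control_values) -> dict:
    """Compare fold changes (or any readout) between case and control.

    Welch t-test when both groups pass the normality check, Mann-Whitney
    otherwise. Returns test name, statistic, two-sided p and stars.
    """
    x = np.asarray(case_values, dtype=float)
    y = np.asarray(control_values, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs at least two values")
    try:
        normal = normality_check(x)[1] and normality_check(y)[1]
    except ValueError:  # n < 3 in a group: fall back to the rank test
        normal = False
    if normal:
        test = "welch_t"
        stat, p = stats.ttest_ind(x, y, equal_var=False)
    else:
        test = "mann_whitney"
        res = stats.mannwhitneyu(x, y, alternative="two-sided")
        stat, p = res.statistic, res.pvalue
    p = float(min(p, 1.0))
    return {"test": test, "statistic": float(stat), "p_value": p, "stars": stars(p)}


def analyze_qpcr(ct_table: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full qPCR analysis: per-sample folds and per-gene group comparison."""
    df = pd.DataFrame(ct_table)
    folds = []
    summary = []
    for gene, sub in df.groupby("gene", sort=True):
        f = ddct_fold_change(sub)
        folds.append(f)
        case = f.loc[f["group"] == "case", "fold_change"]
        ctrl = f.loc[f["group"] == "control", "fold_change"]
        row = {"gene": gene, "n_case": len(case), "n_control": len(ctrl),
               "mean_fold_case": float(case.mean()),
               "mean_fold_control": float(ctrl.mean())}
        if len(case) >= 2 and len(ctrl) >= 2:
            row.update(group_compare(case, ctrl))
        summary.append(row)
    return pd.concat(folds, ignore_index=True), pd.DataFrame(summary)
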