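"""Relative gene-expression (comparative Ct) and group-comparison statistics.

Relative quantities follow the comparative threshold-cycle method:
replicate Ct values are averaged, normalized to the 18S endogenous
control (dCt = Ct_target - Ct_18S), referenced to a calibrator cohort
(ddCt = dCt - mean dCt of the calibrator), and expressed as
RQ = 2^(-ddCt). Group comparisons use a normality-gated cascade
(Shapiro-Wilk on residuals; ANOVA + Tukey HSD when normal, otherwise
Kruskal-Wallis + pairwise rank-sum), with Benjamini-Hochberg FDR control
across each analysis family. Taxon-wise case/control differences use
two-sided Student t-tests on log10 abundances, and abundance-expression
associations use Spearman rank correlation, both BH-adjusted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests
from statsmodels.stats.multicomp import pairwise_tukeyhsd

CONTROL_GENE = "18S"
LOG_EPS = 1e-6


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order-preserving)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def relative_quantity(
    ct_table: pd.DataFrame,
    calibrator: str = "HC",
    control_gene: str = CONTROL_GENE,
    sd_flag_cutoff: float = 0.5,
) -> pd.DataFrame:
    """Comparative-Ct relative expression per sample x gene.

    ``ct_table`` is long format with columns sample_id, group, gene,
    replicate, ct. ``calibrator`` names the cohort whose mean dCt per
    gene is the ddCt reference. Returns one row per sample x target gene
    with mean_ct, ct_sd, delta_ct, delta_delta_ct, rq and a
    ``high_replicate_sd`` flag (replicate SD above ``sd_flag_cutoff``
    cycles).
    """
    required = {"sample_id", "group", "gene", "replicate", "ct"}
    missing = required - set(ct_table.columns)
    if missing:
        raise ValueError(f"ct table missing columns: {sorted(missing)}")
    summary = (
        ct_table.groupby(["sample_id", "group", "gene"])["ct"]
        .agg(mean_ct="mean", ct_sd="std", n_replicates="count")
        .reset_index()
    )
    control = summary[summary["gene"] == control_gene].set_index("sample_id")["mean_ct"]
    if control.empty:
        raise ValueError(f"endogenous control gene {control_gene!r} absent from table")
    targets = summary[summary["gene"] != control_gene].copy()
    missing_ctrl = set(targets["sample_id"]) - set(control.index)
    if missing_ctrl:
        raise ValueError(f"samples lacking {control_gene}: {sorted(missing_ctrl)}")
    targets["delta_ct"] = targets["mean_ct"] - targets["sample_id"].map(control).to_numpy()

    cal = targets[targets["group"] == calibrator]
    if cal.empty:
        raise ValueError(f"calibrator cohort {calibrator!r} has no samples")
    cal_dct = cal.groupby("gene")["delta_ct"].mean()
    targets["delta_delta_ct"] = targets["delta_ct"] - targets["gene"].map(cal_dct).to_numpy()
    targets["rq"] = 2.0 ** (-targets["delta_delta_ct"])
    targets["high_replicate_sd"] = targets["ct_sd"] > sd_flag_cutoff
    return targets.reset_index(drop=True)


def rq_ratio(rq_table: pd.DataFrame, numerator: str, denominator: str) -> pd.Series:
    """Per-sample ratio of two genes' relative quantities (e.g. IL-10/IFN-g)."""
    wide = rq_table.pivot(index="sample_id", columns="gene", values="rq")
    for gene in (numerator, denominator):
        if gene not in wide.columns:
            raise KeyError(f"gene {gene!r} absent from RQ table")
    return wide[numerator] / wide[denominator]


@dataclass(frozen=True)
class GroupTestResult:
    gene: str
    test_used: str  # "anova_tukey" | "kruskal_ranksum"
    shapiro_p: float
    omnibus_p: float
    pairwise: pd.DataFrame  # columns: group_a, group_b, p, p_adj, significant


def gated_group_test(
    values: pd.Series,
    groups: pd.Series,
    gene: str = "",
    alpha: float = 0.05,
) -> GroupTestResult:
    """Normality-gated omnibus + post-hoc comparison across cohorts.

    Residuals from the group-mean model are tested with Shapiro-Wilk at
    alpha; the parametric branch runs one-way ANOVA with Tukey HSD
    pairwise p-values, the nonparametric branch Kruskal-Wallis with
    pairwise two-sided rank-sum tests. Pairwise p-values are BH-adjusted
    within the family and flagged at adjusted p < alpha.
    """
    values = pd.Series(values).astype(float)
    groups = pd.Series(groups).loc[values.index]
    levels = sorted(groups.unique())
    if len(levels) < 2:
        raise ValueError("need at least two groups")
    blocks = [values[groups == g].to_numpy() for g in levels]
    if any(len(b) < 3 for b in blocks):
        raise ValueError("need at least 3 values per group")
    residuals = np.concatenate([b - b.mean() for b in blocks])
    if np.allclose(residuals, 0.0):
        raise ValueError("values constant within every group")
    shapiro_p = float(stats.shapiro(residuals).pvalue)

    pairs = [(a, b) for i, a in enumerate(levels) for b in levels[i + 1:]]
    if shapiro_p >= alpha:
        test_used = "anova_tukey"
        omnibus_p = float(stats.f_oneway(*blocks).pvalue)
        tukey = pairwise_tukeyhsd(values.to_numpy(), groups.to_numpy(), alpha=alpha)
        frame = pd.DataFrame(tukey.summary().data[1:], columns=tukey.summary().data[0])
        lookup = {
            tuple(sorted((row["group1"], row["group2"]))): float(row["p-adj"])
            for _, row in frame.iterrows()
        }
        raw = [lookup[tuple(sorted(p))] for p in pairs]
    else:
        test_used = "kruskal_ranksum"
        omnibus_p = float(stats.kruskal(*blocks).pvalue)
        raw = [
            float(stats.mannwhitneyu(
                values[groups == a], values[groups == b], alternative="two-sided"
            ).pvalue)
            for a, b in pairs
        ]
    adj = bh_adjust(raw)
    pairwise = pd.DataFrame(
        {
            "group_a": [a for a, _ in pairs],
            "group_b": [b for _, b in pairs],
            "p": raw,
            "p_adj": adj,
            "significant": adj < alpha,
        }
    )
    return GroupTestResult(gene, test_used, shapiro_p, omnibus_p, pairwise)


def genus_ttests(rel_abund: pd.DataFrame, metadata: pd.DataFrame) -> pd.DataFrame:
    """Per-taxon two-sided Student t-test (log10 abundances) with BH-FDR.

    Returns a taxa-indexed frame with ``p`` and ``p_adj`` columns.
    """
    y = metadata.loc[list(rel_abund.columns), "group"].to_numpy()
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError("taxon-wise t-tests need exactly two cohorts")
    X = np.log10(rel_abund.to_numpy(dtype=float) + LOG_EPS)
    a, b = X[:, y == classes[0]], X[:, y == classes[1]]
    with np.errstate(invalid="ignore", divide="ignore"):
        _, p = stats.ttest_ind(a, b, axis=1, equal_var=True)
    p = np.where(np.isnan(p), 1.0, p)
    return pd.DataFrame({"p": p, "p_adj": bh_adjust(p)}, index=rel_abund.index)


def spearman_matrix(
    X: pd.DataFrame, Y: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Spearman rho between every X column and every Y column (paired rows).

    Returns ``(rho, p, p_adj)`` frames indexed by X columns; constant
    columns yield NaN and are excluded from the BH family.
    """
    common = X.index.intersection(Y.index)
    if len(common) < 4:
        raise ValueError("need at least 4 paired samples")
    Xc, Yc = X.loc[common], Y.loc[common]
    rho = pd.DataFrame(index=X.columns, columns=Y.columns, dtype=float)
    pval = rho.copy()
    for xc in X.columns:
        for yc in Y.columns:
            if Xc[xc].nunique() < 2 or Yc[yc].nunique() < 2:
                continue
            r, p = stats.spearmanr(Xc[xc], Yc[yc])
            rho.loc[xc, yc], pval.loc[xc, yc] = r, p
    flat = pval.to_numpy().ravel()
    mask = np.isfinite(flat)
    adj = np.full_like(flat, np.nan)
    if mask.any():
        adj[mask] = bh_adjust(flat[mask])
    p_adj = pd.DataFrame(adj.reshape(pval.shape), index=pval.index, columns=pval.columns)
    return rho, pval, p_adj


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    p_value: float
    r_squared: float


def simple_regression(x, y) -> RegressionResult:
    """Ordinary least squares y ~ x with a two-sided slope test."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 points")
    if np.allclose(x, x[0]):
        raise ValueError("zero variance in x")
    fit = stats.linregress(x, y)
    return RegressionResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        p_value=float(fit.pvalue),
        r_squared=float(fit.rvalue**2),
    )
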