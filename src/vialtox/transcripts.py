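"""Post-differential-expression transcriptomic summaries.

Operates on the two tables an upstream targeted-transcriptomics
workflow produces: a raw gene x sample counts matrix and a long
differential-expression table (gene, chemical, log2FC, adjusted p).
Provides upper-quartile count normalization, the frequent-DEG tally,
and per-gene Spearman correlation of log2FC with morphological potency
(BMC50, with 50 uM imputed for chemicals that had no estimable BMC).
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .stats import holm_adjust, spearman_exact

__all__ = [
    "upper_quartile_normalize",
    "de_flags",
    "tally_frequent_degs",
    "correlate_potency",
]


def upper_quartile_normalize(counts: pd.DataFrame):
    """Scale each sample so its upper quartile matches a common target.

    The per-sample scaling reference is the 75th percentile of counts
    over the genes with nonzero counts in that sample; the common
    target is the geometric mean of those percentiles, so factors
    multiply to 1 in the balanced case and depth differences cancel.
    Returns (normalized DataFrame, factor Series).
    """
    mat = counts.to_numpy(dtype=float)
    if np.any(mat < 0):
        raise ValueError("counts must be nonnegative")
    q75 = np.empty(mat.shape[1])
    for j in range(mat.shape[1]):
        nz = mat[:, j][mat[:, j] > 0]
        if nz.size == 0:
            raise ValueError(f"sample {counts.columns[j]!r} is all zero")
        q75[j] = np.percentile(nz, 75)
    target = math.exp(float(np.mean(np.log(q75))))
    factors = target / q75
    normed = counts.astype(float) * factors
    return normed, pd.Series(factors, index=counts.columns, name="factor")


def de_flags(de: pd.DataFrame, p_threshold: float = 0.05,
             lfc_threshold: float = 1.0) -> pd.Series:
    """Boolean DE flag per row: adjusted p <= 0.05 and |log2FC| >= 1."""
    return (de["padj"] <= p_threshold) & (de["log2fc"].abs() >= lfc_threshold)


def tally_frequent_degs(de: pd.DataFrame, min_fraction: float = 0.25,
                        top_k: int = 5, p_threshold: float = 0.05,
                        lfc_threshold: float = 1.0) -> pd.DataFrame:
    """Most frequently differentially expressed genes.

    Counts, per gene, the chemicals in which it is differentially
    expressed; keeps genes DE in at least ``min_fraction`` of the
    chemicals present in the table (count >= ceil(fraction x n)), and
    returns the ``top_k`` by count with the mean log2FC over their DE
    instances.  Ties at the cut rank are all retained; ordering is by
    descending count then gene name.
    """
    n_chem = de["chemical"].nunique()
    flagged = de[de_flags(de, p_threshold, lfc_threshold)]
    if flagged.empty:
        return pd.DataFrame(columns=["gene", "n_de", "mean_log2fc"])
    tally = (flagged.groupby("gene")
             .agg(n_de=("chemical", "nunique"), mean_log2fc=("log2fc", "mean"))
             .reset_index())
    tally = tally[tally.n_de >= math.ceil(min_fraction * n_chem)]
    tally = tally.sort_values(["n_de", "gene"], ascending=[False, True],
                              ignore_index=True)
    if len(tally) > top_k:
        cutoff = tally.n_de.iloc[top_k - 1]
        tally = tally[tally.n_de >= cutoff].reset_index(drop=True)
    return tally


def correlate_potency(de: pd.DataFrame, bmc: pd.DataFrame, genes,
                      impute_bmc: float = 50.0, alpha: float = 0.05,
                      min_abs_rho: float = 0.5) -> pd.DataFrame:
    """Per-gene Spearman correlation of log2FC with BMC50 across chemicals.

    Chemicals with no estimable BMC50 are assigned ``impute_bmc``
    (50 uM), which creates tied ranks, so the t-approximation p-value
    path is used there.  The gene family is Holm-adjusted; a gene is
    significant iff adjusted p <= ``alpha`` and |rho| >= ``min_abs_rho``
    (the magnitude criterion, since BMC is inverse potency and either
    sign may be reported).
    """
    chems = sorted(de["chemical"].unique())
    if len(chems) < 4:
        raise ValueError("need >= 4 chemicals")
    bmc_map = dict(zip(bmc["chemical"], bmc["bmc"]))
    y = np.array([bmc_map.get(c, np.nan) for c in chems])
    y = np.where(np.isfinite(y), y, impute_bmc)
    rows = []
    for gene in genes:
        sub = de[de.gene == gene].set_index("chemical")["log2fc"]
        x = sub.reindex(chems).to_numpy(dtype=float)
        ok = np.isfinite(x)
        if ok.sum() < 4 or np.ptp(x[ok]) == 0:
            rows.append((gene, np.nan, np.nan))
            continue
        res = spearman_exact(x[ok], y[ok])
        rows.append((gene, res.estimate, res.p_value))
    out = pd.DataFrame(rows, columns=["gene", "rho", "p_value"])
    finite = out.p_value.notna()
    padj = np.full(len(out), np.nan)
    if finite.any():
        padj[finite.to_numpy()] = holm_adjust(out.loc[finite, "p_value"])
    out["p_adjusted"] = padj
    out["significant"] = (out.p_adjusted <= alpha) & \
        (out.rho.abs() >= min_abs_rho)
    out["significant"] = out["significant"].fillna(False)
    return out
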