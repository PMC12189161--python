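"""FPKM quantification, threshold differential expression, and 2^-ddCt.

The differential-expression stage is a deliberately simple stand-in for an
NB-GLM engine: median-of-ratios size factors, log2 fold change of normalized
group means with pseudocount 1, a Welch t-test on log2 normalized counts, and
BH adjustment.  Output metadata labels it "threshold DE (stand-in)".  The
flagging thresholds are adjusted p < 0.05 and |log2FC| > 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from ripsplice.core_io import CountMatrix, GeneModel
from ripsplice.splicing import bh_fdr

DE_METHOD_LABEL = "threshold DE (stand-in)"
PADJ_CUT = 0.05
LFC_CUT = 1.0


def compute_fpkm(matrix: CountMatrix, models: list[GeneModel]) -> pd.DataFrame:
    """FPKM per gene and sample: counts * 1e9 / (library_size * exonic_length)."""
    lengths = {m.gene_id: m.exonic_length for m in models}
    missing = [g for g in matrix.df.index if g not in lengths]
    if missing:
        raise ValueError(f"genes missing from the annotation: {missing[:5]}")
    zero_len = [g for g, ln in lengths.items() if ln <= 0 and g in matrix.df.index]
    if zero_len:
        raise ValueError(f"genes with zero exonic length: {zero_len[:5]}")
    lib = matrix.library_sizes()
    if (lib <= 0).any():
        raise ValueError("zero library size")
    len_vec = np.array([lengths[g] for g in matrix.df.index], dtype=float)
    fpkm = matrix.df.values * 1e9 / (lib.values[None, :] * len_vec[:, None])
    return pd.DataFrame(fpkm, index=matrix.df.index, columns=matrix.df.columns)


def size_factors(df: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors over genes with all-positive counts."""
    log_counts = np.log(df.where(df > 0))
    log_geomean = log_counts.mean(axis=1)
    usable = np.isfinite(log_geomean) & (df > 0).all(axis=1)
    if not usable.any():
        raise ValueError("no gene has positive counts in every sample")
    ratios = log_counts.loc[usable].sub(log_geomean[usable], axis=0)
    return np.exp(ratios.median(axis=0))


def differential_expression(
    matrix: CountMatrix,
    padj_cut: float = PADJ_CUT,
    lfc_cut: float = LFC_CUT,
) -> pd.DataFrame:
    """Threshold DE stand-in; returns one row per gene.

    Columns: baseMean, log2fc (group2 vs group1, alphabetical group order),
    t, p_value, padj, de_flag in {up, down, none}.
    """
    groups = matrix.groups
    names = sorted(set(groups.values()))
    if len(names) != 2:
        raise ValueError(f"need exactly two groups, got {names}")
    g1, g2 = names
    s1 = [s for s in matrix.samples if groups[s] == g1]
    s2 = [s for s in matrix.samples if groups[s] == g2]
    if len(s1) < 2 or len(s2) < 2:
        raise ValueError("need >= 2 samples per group")

    sf = size_factors(matrix.df)
    norm = matrix.df / sf
    log_norm = np.log2(norm + 1.0)

    mean1 = norm[s1].mean(axis=1)
    mean2 = norm[s2].mean(axis=1)
    log2fc = np.log2(mean2 + 1.0) - np.log2(mean1 + 1.0)

    a = log_norm[s1].values
    b = log_norm[s2].values
    tstat = np.full(len(matrix.df), 0.0)
    pval = np.ones(len(matrix.df))
    var_a, var_b = a.var(axis=1, ddof=1), b.var(axis=1, ddof=1)
    testable = (var_a > 0) | (var_b > 0)
    if testable.any():
        res = sps.ttest_ind(a[testable], b[testable], axis=1, equal_var=False)
        tstat[testable] = res.statistic
        pval[testable] = res.pvalue
    # zero variance in both groups but different means: maximally significant
    degenerate = ~testable & (a.mean(axis=1) != b.mean(axis=1))
    pval[degenerate] = 0.0

    padj = bh_fdr(pval)
    flag = np.where(
        (padj < padj_cut) & (log2fc > lfc_cut), "up",
        np.where((padj < padj_cut) & (log2fc < -lfc_cut), "down", "none"),
    )
    out = pd.DataFrame(
        {
            "baseMean": norm.mean(axis=1),
            f"mean_{g1}": mean1,
            f"mean_{g2}": mean2,
            "log2fc": log2fc,
            "t": tstat,
            "p_value": pval,
            "padj": padj,
            "de_flag": flag,
        },
        index=matrix.df.index,
    )
    out.attrs["method"] = DE_METHOD_LABEL
    out.attrs["thresholds"] = {"padj": padj_cut, "abs_log2fc": lfc_cut}
    return out


def deg_gene_set(de_table: pd.DataFrame) -> set[str]:
    return set(de_table.index[de_table["de_flag"] != "none"])


# ---------------------------------------------------------------------------
# Relative qPCR quantification
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DdCtRecord:
    ct_target_treated: float
    ct_reference_treated: float
    ct_target_control: float
    ct_reference_control: float

    def __post_init__(self) -> None:
        for value in (
            self.ct_target_treated, self.ct_reference_treated,
            self.ct_target_control, self.ct_reference_control,
        ):
            if not np.isfinite(value):
                raise ValueError("Ct values must be finite")


def ddct(record: DdCtRecord) -> float:
    """Relative expression by the 2^-ddCt method."""
    dct_treated = record.ct_target_treated - record.ct_reference_treated
    dct_control = record.ct_target_control - record.ct_reference_control
    ddct_value = dct_treated - dct_control
    return float(2.0 ** (-ddct_value))


def ddct_table(df: pd.DataFrame) -> pd.DataFrame:
    """Apply :func:`ddct` row-wise to a Ct table.

    Expects columns ct_target_treated / ct_reference_treated /
    ct_target_control / ct_reference_control (extra columns pass through).
    """
    required = [
        "ct_target_treated", "ct_reference_treated",
        "ct_target_control", "ct_reference_control",
    ]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"Ct table missing columns: {missing}")
    out = df.copy()
    out["relative_expression"] = [
        ddct(DdCtRecord(*row)) for row in df[required].itertuples(index=False)
    ]
    return out
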