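"""Normalization, replicate aggregation, fold-change, and a two-group
differential-expression gate.

All thresholded filters downstream (marker census, enrichment versus a
reference, blood-meal regulation, cross-species censorship) run through the
operations here.  The differential test is a Welch two-sample test on
log2(TPM+1) with Benjamini–Hochberg adjustment; it preserves the padj<0.05
significance gate that count-model tools provide, and externally computed
adjusted p-values can be substituted via :meth:`DEResult.with_padj`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import (
    TPM_TOTAL,
    ConditionProfile,
    ExpressionMatrix,
    SampleSheet,
)

#: Pseudocount (TPM) added wherever an expression ratio is formed.  Keeps a
#: 100-TPM/0-TPM marker at a ratio of ~10⁴, safely above any fold threshold,
#: while leaving ratios of well-expressed genes essentially untouched.
DEFAULT_PSEUDOCOUNT = 0.01


def to_tpm(matrix: ExpressionMatrix, gene_lengths_kb: pd.Series) -> ExpressionMatrix:
    """Convert raw counts to TPM given per-gene lengths in kilobases.

    Per column: rate = count / length; value = rate / sum(rate) × 1e6.
    """
    if matrix.unit != "counts":
        raise ValueError("to_tpm expects a counts matrix")
    missing = matrix.genes.difference(gene_lengths_kb.index)
    if len(missing):
        raise ValueError(f"missing gene length for {missing[0]!r}")
    lengths = gene_lengths_kb.reindex(matrix.genes).astype(float)
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be positive")
    rate = matrix.data.div(lengths, axis=0)
    tpm = rate.div(rate.sum(axis=0), axis=1) * TPM_TOTAL
    return ExpressionMatrix(tpm, "TPM")


def renormalize_tpm(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Rescale each column to sum 1e6 (e.g. after subsetting to orthologs)."""
    sums = matrix.data.sum(axis=0)
    zero = sums[sums <= 0]
    if len(zero):
        raise ValueError(f"cannot renormalize all-zero column {zero.index[0]!r}")
    data = matrix.data.div(sums, axis=1) * TPM_TOTAL
    return ExpressionMatrix(data, "TPM")


def aggregate_replicates(
    matrix: ExpressionMatrix,
    sheet: SampleSheet,
    group_keys: tuple[str, ...] = ("compartment", "condition", "timepoint_h"),
) -> dict[tuple, ConditionProfile]:
    """Arithmetic per-gene mean of TPM across replicate columns per group.

    Returns a dict keyed by the tuple of group values (in ``group_keys``
    order).  Samples in the sheet but not the matrix are ignored; an empty
    group raises.
    """
    for key in group_keys:
        if key not in sheet.data.columns:
            raise ValueError(f"unknown group key {key!r}")
    sheet.check_matrix(matrix)
    sub = sheet.data[sheet.data["sample_id"].isin(matrix.samples)]
    profiles: dict[tuple, ConditionProfile] = {}
    for key, grp in sub.groupby(list(group_keys), dropna=False, sort=True):
        key = key if isinstance(key, tuple) else (key,)
        cols = grp["sample_id"].tolist()
        if not cols:
            raise ValueError(f"empty replicate group {key}")
        mean = matrix.data[cols].mean(axis=1)
        info = dict(zip(group_keys, key))
        tp = info.get("timepoint_h")
        profiles[key] = ConditionProfile(
            values=mean,
            compartment=str(info.get("compartment", "")),
            condition=(None if "condition" not in info else info["condition"]),
            timepoint_h=(None if tp is None or pd.isna(tp) else float(tp)),
            n_replicates=len(cols),
        )
    return profiles


def fold_change(
    profile_a: pd.Series,
    profile_b: pd.Series,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> pd.Series:
    """Gene-wise ratio (a + ε) / (b + ε); finite and positive for ε > 0."""
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    a, b = profile_a.align(profile_b, join="inner")
    return (a + pseudocount) / (b + pseudocount)


@dataclass
class DEResult:
    """Per-gene two-group comparison: means, log2 fold-change (B vs A), p, padj."""

    table: pd.DataFrame  # columns: mean_a, mean_b, fc, log2fc, p, padj
    group_a: str = "A"
    group_b: str = "B"

    def __post_init__(self) -> None:
        required = {"mean_a", "mean_b", "fc", "log2fc", "p", "padj"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"DEResult table missing columns: {sorted(missing)}")
        padj = self.table["padj"]
        if ((padj < 0) | (padj > 1)).any():
            raise ValueError("padj must lie in [0, 1]")

    def with_padj(self, padj: pd.Series) -> "DEResult":
        """Substitute externally computed adjusted p-values (e.g. a count model's)."""
        table = self.table.copy()
        table["padj"] = padj.reindex(table.index)
        return DEResult(table, self.group_a, self.group_b)


def _welch(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Vectorized Welch two-sample p-values across rows of a and b.

    Rows with zero variance in both groups get p=1 when means are equal and
    p=0 when they differ (the limit of the statistic).
    """
    na, nb = a.shape[1], b.shape[1]
    ma, mb = a.mean(axis=1), b.mean(axis=1)
    va, vb = a.var(axis=1, ddof=1), b.var(axis=1, ddof=1)
    se2 = va / na + vb / nb
    p = np.ones(a.shape[0])
    degenerate = se2 == 0
    p[degenerate & (ma != mb)] = 0.0
    ok = ~degenerate
    t = (mb[ok] - ma[ok]) / np.sqrt(se2[ok])
    df = se2[ok] ** 2 / (
        (va[ok] / na) ** 2 / (na - 1) + (vb[ok] / nb) ** 2 / (nb - 1)
    )
    p[ok] = 2.0 * stats.t.sf(np.abs(t), df)
    return p


def differential_test(
    matrix: ExpressionMatrix,
    sheet: SampleSheet,
    group_a,
    group_b,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> DEResult:
    """Welch test on log2(TPM+1) per gene, BH step-up across all tested genes.

    ``group_a`` / ``group_b`` are either explicit sample-id lists or dicts of
    sample-sheet filters (e.g. ``{"compartment": "gut", "timepoint_h": 6}``).
    Fold-changes are formed on replicate-mean TPM with the shared pseudocount;
    the test itself runs on per-replicate values.
    """
    cols_a = group_a if isinstance(group_a, (list, tuple)) else sheet.select(**group_a)
    cols_b = group_b if isinstance(group_b, (list, tuple)) else sheet.select(**group_b)
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise ValueError(
            "differential_test needs >=2 replicates per group; "
            "use fold_change for single-replicate contrasts"
        )
    a = matrix.data[list(cols_a)].to_numpy(dtype=float)
    b = matrix.data[list(cols_b)].to_numpy(dtype=float)
    p = _welch(np.log2(a + 1.0), np.log2(b + 1.0))
    padj = multipletests(p, method="fdr_bh")[1]
    mean_a, mean_b = a.mean(axis=1), b.mean(axis=1)
    fc = (mean_b + pseudocount) / (mean_a + pseudocount)
    table = pd.DataFrame(
        {
            "mean_a": mean_a,
            "mean_b": mean_b,
            "fc": fc,
            "log2fc": np.log2(fc),
            "p": p,
            "padj": padj,
        },
        index=matrix.genes,
    )
    return DEResult(table)


def filter_regulated(
    de: DEResult, min_fold: float = 2.0, alpha: float = 0.05
) -> tuple[set[str], set[str]]:
    """Split significant genes into up- and down-regulated sets.

    up: padj < alpha and FC >= min_fold; down: padj < alpha and
    FC <= 1/min_fold.  Disjoint for min_fold > 1.
    """
    if min_fold < 1:
        raise ValueError("min_fold must be >= 1")
    t = de.table
    sig = t["padj"] < alpha
    up = set(t.index[sig & (t["fc"] >= min_fold)])
    down = set(t.index[sig & (t["fc"] <= 1.0 / min_fold)])
    return up, down
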