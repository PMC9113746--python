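"""Categorical transcriptome accounting.

*Investment* is the cumulative TPM a compartment devotes to a curated gene
category — the fraction of its own transcriptome spent on that function.
*Yield* is the RNA mass recovered per dissected organ.  *Output* weights
investment by yield, converting relative commitments into each
compartment's absolute share of a category's transcripts.  Percent-of-max
scaling and top-N census views, plus a flat one-sided over-representation
test, round out the accounting toolkit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import (
    TPM_TOTAL,
    CategoryMap,
    ConditionProfile,
    YieldMeasurement,
)
from .markers import _profile_frame


@dataclass
class InvestmentTable:
    """Compartment × category cumulative TPM with derived percentage views."""

    table: pd.DataFrame  # index: compartment/condition label; columns: category
    missing_genes: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        v = self.table.to_numpy()
        if (v < 0).any() or (v > TPM_TOTAL * (1 + 1e-9)).any():
            raise ValueError("cumulative TPM must lie in [0, 1e6]")

    def percent_of_transcriptome(self) -> pd.DataFrame:
        return self.table / TPM_TOTAL * 100.0

    def percent_of_max(self) -> tuple[pd.DataFrame, list[str]]:
        """Scale each category so the top compartment scores 100.

        Returns the scaled frame and the list of all-zero categories (left
        as zeros and flagged rather than divided).
        """
        scaled = self.table.copy()
        zero_cats = []
        for cat in scaled.columns:
            col = scaled[cat]
            m = col.max()
            if m <= 0:
                zero_cats.append(cat)
            else:
                scaled[cat] = col / m * 100.0
        return scaled, zero_cats


@dataclass
class YieldTable:
    """Per-compartment mean RNA per organ (ng) with per-replicate values."""

    mean_ng: pd.Series
    replicates: pd.DataFrame  # columns: compartment, replicate, yield_ng

    def __post_init__(self) -> None:
        if (self.mean_ng <= 0).any():
            raise ValueError("yields must be positive")


@dataclass
class OutputTable:
    """Yield-weighted investment and each compartment's percentage share."""

    output: pd.DataFrame  # compartment × category, investment × yield
    shares: pd.DataFrame  # same shape; columns sum to 100

    def __post_init__(self) -> None:
        sums = self.shares.sum(axis=0)
        if not np.allclose(sums, 100.0, atol=1e-9):
            raise ValueError("output shares must sum to 100 per category")


def cumulative_investment(
    profiles: dict[str, ConditionProfile],
    category_map: CategoryMap,
) -> InvestmentTable:
    """Sum each category's genes (TPM) within every compartment/condition.

    Category genes absent from the expression universe are counted as zero
    and reported in ``missing_genes``.
    """
    frame = _profile_frame(profiles)
    universe = set(frame.index)
    rows = {}
    missing: dict[str, list[str]] = {}
    for cat in sorted(category_map.categories):
        genes = category_map.categories[cat]
        present = sorted(genes & universe)
        absent = sorted(genes - universe)
        if absent:
            missing[cat] = absent
        rows[cat] = (
            frame.loc[present].sum(axis=0) if present
            else pd.Series(0.0, index=frame.columns)
        )
    table = pd.DataFrame(rows).reindex(index=frame.columns)  # compartment × category
    return InvestmentTable(table=table, missing_genes=missing)


def scale_to_max(values: pd.Series) -> tuple[pd.Series, str | None]:
    """Scale non-negative values so the maximum is 100.

    Returns ``(scaled, flag)`` where flag is ``"all_zero"`` for an all-zero
    vector (returned unscaled) or ``"low_expression"`` when the maximum is
    below 1 TPM — such rows are suppressed to zeros rather than scaled, as a
    percent-of-max display of sub-1-TPM noise would be misleading.
    """
    if (values < 0).any():
        raise ValueError("scale_to_max requires non-negative values")
    m = values.max()
    if m == 0:
        return values.astype(float), "all_zero"
    if m < 1.0:
        return pd.Series(0.0, index=values.index), "low_expression"
    return values / m * 100.0, None


def rna_yield(measurements: list[YieldMeasurement]) -> YieldTable:
    """Per-organ yield = concentration [ng/µl] × volume [µl] / organs pooled."""
    if not measurements:
        raise ValueError("no yield measurements supplied")
    records = [
        {
            "compartment": m.compartment,
            "replicate": m.replicate,
            "yield_ng": m.concentration_ng_ul * m.volume_ul / m.n_organs,
        }
        for m in measurements
    ]
    reps = pd.DataFrame(records).sort_values(["compartment", "replicate"])
    mean = reps.groupby("compartment")["yield_ng"].mean()
    return YieldTable(mean_ng=mean, replicates=reps.reset_index(drop=True))


def weight_by_yield(investment: InvestmentTable, yields: YieldTable) -> OutputTable:
    """Convert investments to outputs: cell × compartment yield, then shares."""
    missing = [c for c in investment.table.index if c not in yields.mean_ng.index]
    if missing:
        raise ValueError(f"no RNA yield for compartment(s) {missing}")
    w = yields.mean_ng.reindex(investment.table.index)
    output = investment.table.mul(w, axis=0)
    totals = output.sum(axis=0)
    shares = output.copy()
    nonzero = totals > 0
    shares.loc[:, nonzero] = output.loc[:, nonzero].div(totals[nonzero], axis=1) * 100.0
    if (~nonzero).any():
        # an all-zero category has no transcripts to apportion; give equal shares
        shares.loc[:, ~nonzero] = 100.0 / len(output.index)
    return OutputTable(output=output, shares=shares)


def top_expressed(
    profile: ConditionProfile,
    n: int = 20,
    category_map: CategoryMap | None = None,
) -> pd.DataFrame:
    """Top-n genes by TPM (ties broken by gene id) with transcriptome shares.

    Columns: gene_id, tpm, percent, cumulative_percent and, when a category
    map is given, a semicolon-joined category column.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    s = profile.values.sort_values(ascending=False, kind="mergesort")
    order = sorted(zip(-s.to_numpy(), s.index))  # descending TPM, lexicographic ties
    genes = [g for _, g in order][:n]
    tpm = profile.values.reindex(genes)
    percent = tpm / TPM_TOTAL * 100.0
    frame = pd.DataFrame(
        {
            "gene_id": genes,
            "tpm": tpm.to_numpy(),
            "percent": percent.to_numpy(),
            "cumulative_percent": percent.cumsum().to_numpy(),
        }
    )
    if category_map is not None:
        lookup: dict[str, list[str]] = {}
        for cat, members in category_map.categories.items():
            for g in members:
                lookup.setdefault(g, []).append(cat)
        frame["category"] = [
            ";".join(sorted(lookup.get(g, []))) for g in frame["gene_id"]
        ]
    return frame


def category_enrichment(
    selected: set[str],
    universe: set[str],
    category_map: CategoryMap,
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation per category, BH-adjusted.

    p is the upper-tail probability of drawing at least the observed overlap
    when ``len(selected)`` genes are sampled from the universe without
    replacement.  Categories are clipped to the universe before testing.
    """
    stray = selected - universe
    if stray:
        raise ValueError(f"selected genes outside universe: {sorted(stray)[:10]}")
    m = len(universe)
    n_sel = len(selected)
    records = []
    for cat in sorted(category_map.categories):
        members = category_map.categories[cat] & universe
        k = len(members & selected)
        p = float(stats.hypergeom.sf(k - 1, m, len(members), n_sel))
        records.append(
            {"category": cat, "size": len(members), "overlap": k, "p": min(p, 1.0)}
        )
    frame = pd.DataFrame(records)
    frame["padj"] = multipletests(frame["p"], method="fdr_bh")[1]
    return frame
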