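"""Cross-species ortholog correlation and sequential signature censorship.

Matched compartments of two species are compared over their one-to-one
orthologs: both profiles are subset to the pairs, rescaled to TPM, and
regressed in log10(x+1) space.  A small set of highly, disparately
expressed pairs — the 'species signature' — can depress the correlation;
censoring them one at a time (most disparate significant pair first,
renormalizing the survivors after each removal) traces how slope and R²
recover and identifies the signature genes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import TPM_TOTAL, ExpressionMatrix, OrthologTable, SampleSheet
from .core import DEResult, _welch
from .deconv import RegressionReport
from statsmodels.stats.multitest import multipletests


@dataclass
class CensorshipTrajectory:
    """Ordered censorship steps with the fit after each removal.

    ``steps`` columns: step, gene_a, gene_b, score, padj, slope, r2.  Step 0
    is the uncensored fit (no pair attached).
    """

    steps: pd.DataFrame

    def __post_init__(self) -> None:
        pairs = self.steps.loc[self.steps["step"] > 0, ["gene_a", "gene_b"]]
        if pairs.duplicated().any():
            raise ValueError("a pair was censored twice")

    @property
    def n_censored(self) -> int:
        return int((self.steps["step"] > 0).sum())

    def final_fit(self) -> tuple[float, float]:
        last = self.steps.iloc[-1]
        return float(last["slope"]), float(last["r2"])


def select_one_to_one(table: OrthologTable) -> list[tuple[str, str]]:
    """The (gene_a, gene_b) pairs with a 1-to-1 relation, in table order."""
    sub = table.data[table.data["relation"] == "1-to-1"]
    pairs = list(zip(sub["gene_a"], sub["gene_b"]))
    if not pairs:
        warnings.warn("ortholog table contains no 1-to-1 pairs", stacklevel=2)
    return pairs


def _paired_profiles(
    profile_a: pd.Series,
    profile_b: pd.Series,
    pairs: list[tuple[str, str]],
) -> pd.DataFrame:
    """Subset both profiles to the pairs and rescale each side to TPM sums."""
    genes_a = [a for a, _ in pairs]
    genes_b = [b for _, b in pairs]
    a = profile_a.reindex(genes_a)
    b = profile_b.reindex(genes_b)
    if a.isna().any() or b.isna().any():
        missing = [g for g, v in zip(genes_a + genes_b, list(a) + list(b)) if pd.isna(v)]
        raise ValueError(f"pair gene(s) missing from profiles: {missing[:10]}")
    frame = pd.DataFrame(
        {
            "gene_a": genes_a,
            "gene_b": genes_b,
            "a": a.to_numpy(dtype=float),
            "b": b.to_numpy(dtype=float),
        }
    )
    for col in ("a", "b"):
        total = frame[col].sum()
        if total <= 0:
            raise ValueError(f"all-zero profile for species {col!r} after subsetting")
        frame[col] *= TPM_TOTAL / total
    return frame


def _fit(frame: pd.DataFrame, log_space: bool) -> tuple[float, float, float]:
    x = np.log10(frame["a"] + 1.0) if log_space else frame["a"]
    y = np.log10(frame["b"] + 1.0) if log_space else frame["b"]
    res = stats.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue**2)


def ortholog_correlation(
    profile_a: pd.Series,
    profile_b: pd.Series,
    pairs: list[tuple[str, str]],
    log_space: bool = True,
) -> RegressionReport:
    """OLS of species-B on species-A expression over rescaled 1-to-1 pairs."""
    if len(pairs) < 3:
        raise ValueError("need at least 3 ortholog pairs to fit")
    frame = _paired_profiles(profile_a, profile_b, pairs)
    slope, intercept, r2 = _fit(frame, log_space)
    return RegressionReport(
        slope=slope, intercept=intercept, r_squared=r2, n_points=len(frame)
    )


def paired_differential_test(
    matrix_a: ExpressionMatrix,
    matrix_b: ExpressionMatrix,
    pairs: list[tuple[str, str]],
) -> DEResult:
    """Between-species Welch test on the renormalized 1-to-1 subset.

    Replicate columns of each species are subset to its side of the pairs
    and rescaled to TPM before testing; the result is indexed by pair
    (species-A gene id).
    """
    genes_a = [a for a, _ in pairs]
    genes_b = [b for _, b in pairs]
    a = matrix_a.data.reindex(genes_a)
    b = matrix_b.data.reindex(genes_b)
    if a.isna().any().any() or b.isna().any().any():
        raise ValueError("some pair genes are missing from the matrices")
    a = a / a.sum(axis=0) * TPM_TOTAL
    b = b / b.sum(axis=0) * TPM_TOTAL
    if a.shape[1] < 2 or b.shape[1] < 2:
        raise ValueError("paired differential test needs >=2 replicates per species")
    av, bv = a.to_numpy(dtype=float), b.to_numpy(dtype=float)
    p = _welch(np.log2(av + 1.0), np.log2(bv + 1.0))
    padj = multipletests(p, method="fdr_bh")[1]
    mean_a, mean_b = av.mean(axis=1), bv.mean(axis=1)
    fc = (mean_b + 0.01) / (mean_a + 0.01)
    table = pd.DataFrame(
        {
            "mean_a": mean_a,
            "mean_b": mean_b,
            "fc": fc,
            "log2fc": np.log2(fc),
            "p": p,
            "padj": padj,
        },
        index=pd.Index(genes_a, name="gene_a"),
    )
    return DEResult(table, group_a="species_a", group_b="species_b")


def sequential_censorship(
    profile_a: pd.Series,
    profile_b: pd.Series,
    pairs: list[tuple[str, str]],
    de: DEResult,
    max_steps: int,
    alpha: float = 0.05,
    log_space: bool = True,
) -> CensorshipTrajectory:
    """Censor the most disparate significant pair, renormalize, refit, repeat.

    Candidates are pairs with padj < alpha in the between-species test.  The
    disparity score |log10(a+1) − log10(b+1)| is recomputed on the current
    renormalization at every step; ties break by pair id.  Stops after
    ``max_steps`` removals or when candidates are exhausted.
    """
    if max_steps < 0:
        raise ValueError("max_steps must be non-negative")
    frame = _paired_profiles(profile_a, profile_b, pairs)
    padj = de.table["padj"].reindex(frame["gene_a"]).to_numpy()
    if np.isnan(padj).any():
        raise ValueError("DE result does not cover every ortholog pair")
    frame["padj"] = padj
    slope, _, r2 = _fit(frame, log_space)
    records = [
        {
            "step": 0, "gene_a": "", "gene_b": "", "score": np.nan,
            "padj": np.nan, "slope": slope, "r2": r2,
        }
    ]
    for step in range(1, max_steps + 1):
        live = frame[frame["padj"] < alpha].copy()
        if live.empty or len(frame) <= 3:
            break
        live["score"] = (
            np.log10(live["a"] + 1.0) - np.log10(live["b"] + 1.0)
        ).abs()
        live = live.sort_values(
            ["score", "gene_a", "gene_b"], ascending=[False, True, True]
        )
        victim = live.iloc[0]
        frame = frame[frame["gene_a"] != victim["gene_a"]]
        for col in ("a", "b"):
            frame[col] = frame[col] / frame[col].sum() * TPM_TOTAL
        slope, _, r2 = _fit(frame, log_space)
        records.append(
            {
                "step": step,
                "gene_a": victim["gene_a"],
                "gene_b": victim["gene_b"],
                "score": float(victim["score"]),
                "padj": float(victim["padj"]),
                "slope": slope,
                "r2": r2,
            }
        )
    return CensorshipTrajectory(pd.DataFrame(records))


def species_signature(trajectory: CensorshipTrajectory, k: int) -> pd.DataFrame:
    """The first k censored pairs, in censorship order, with their scores."""
    steps = trajectory.steps[trajectory.steps["step"] > 0]
    if k > len(steps):
        raise ValueError(f"k={k} exceeds the {len(steps)} censorship steps taken")
    return steps.head(k)[["step", "gene_a", "gene_b", "score", "padj"]].reset_index(
        drop=True
    )
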