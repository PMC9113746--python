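"""Whole-body transcriptome deconvolution from compartment-exclusive markers.

Writing X_c(g) for the mean TPM of gene g in body part c and w_c for the
fraction of whole-body transcripts contributed by that part,

    sum_c X_c(g) * w_c  ≈  X_wholebody(g)          for every gene g,

with the fractions summing to 1 when the dissected parts tile the body.
For a marker gene of part c the other terms vanish, so each marker yields a
direct estimate  ŵ_g = X_wholebody(g) / X_c(g);  the part's scaling factor
is the arithmetic mean of its markers' estimates.  The estimate is
validated by predicting the whole-body profile from the parts and
regressing prediction on observation in log space.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.outliers_influence import OLSInfluence

from .containers import ConditionProfile
from .markers import MarkerSet, _profile_frame


@dataclass
class ScalingFactors:
    """Per-compartment fractional contribution to the whole-body transcriptome."""

    fractions: pd.Series  # compartment -> fraction
    n_markers: pd.Series
    sd: pd.Series  # sd of per-marker estimates (ddof=1; NaN for 1 marker)
    per_marker: pd.DataFrame  # columns: compartment, gene_id, estimate

    def __post_init__(self) -> None:
        if (self.fractions < 0).any():
            raise ValueError("scaling factors cannot be negative")
        if (self.n_markers < 1).any():
            raise ValueError("every reported compartment needs >= 1 marker")

    @property
    def total(self) -> float:
        """Sum of fractions, deliberately not forced to 1."""
        return float(self.fractions.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "fraction": self.fractions,
                "percent": self.fractions * 100.0,
                "n_markers": self.n_markers,
                "sd": self.sd,
            }
        ).rename_axis("compartment")


@dataclass
class RegressionReport:
    """OLS fit summary with the identities of iteratively removed outliers."""

    slope: float
    intercept: float
    r_squared: float
    n_points: int
    removed_outliers: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (-1e-12 <= self.r_squared <= 1 + 1e-12):
            raise ValueError("R² must lie in [0, 1]")


def estimate_scaling_factors(
    markers: MarkerSet,
    part_profiles: dict[str, ConditionProfile],
    whole_body: ConditionProfile,
) -> ScalingFactors:
    """Average per-marker ratios X_wholebody/X_part into per-part fractions."""
    frame = _profile_frame(part_profiles)
    wb = whole_body.values.reindex(frame.index)
    if wb.isna().any():
        raise ValueError("whole-body profile does not share the gene universe")
    records = []
    for comp in frame.columns:
        genes = markers.genes_for(comp)
        if not genes:
            raise ValueError(f"compartment {comp!r} has no markers")
        for g in genes:
            focal = frame.at[g, comp]
            if focal <= 0:
                raise ValueError(f"marker {g!r} has zero expression in {comp!r}")
            records.append(
                {"compartment": comp, "gene_id": g, "estimate": wb[g] / focal}
            )
    per_marker = pd.DataFrame(records)
    grouped = per_marker.groupby("compartment")["estimate"]
    fractions = grouped.mean().reindex(frame.columns)
    return ScalingFactors(
        fractions=fractions,
        n_markers=grouped.size().reindex(frame.columns),
        sd=grouped.std(ddof=1).reindex(frame.columns),
        per_marker=per_marker,
    )


def sum_check(
    factors: ScalingFactors, low: float = 90.0, high: float = 110.0
) -> tuple[float, bool]:
    """Total percentage and a warning flag when it leaves [low, high].

    Parts that tile the body should sum near 100%; a clean dissection with a
    deliberately excised section will fall a few points short.
    """
    if len(factors.fractions) == 0:
        raise ValueError("no scaling factors to sum")
    total = factors.total * 100.0
    eps = 1e-9  # boundary totals pass despite float summation error
    return total, not (low - eps <= total <= high + eps)


def predict_whole_body(
    part_profiles: dict[str, ConditionProfile],
    factors: ScalingFactors,
) -> ConditionProfile:
    """Mixture prediction: per gene, sum_c X_c(g) * w_c."""
    frame = _profile_frame(part_profiles)
    missing = [c for c in frame.columns if c not in factors.fractions.index]
    if missing:
        raise ValueError(f"no scaling factor for compartment(s) {missing}")
    w = factors.fractions.reindex(frame.columns).to_numpy()
    predicted = pd.Series(frame.to_numpy() @ w, index=frame.index)
    return ConditionProfile(
        values=predicted, compartment="whole_body_predicted",
        n_replicates=max(1, min(p.n_replicates for p in part_profiles.values())),
    )


def validate_prediction(
    predicted: ConditionProfile,
    observed: ConditionProfile,
    min_tpm: float = 1.0,
    max_outliers: int = 5,
    resid_threshold: float = 4.0,
) -> RegressionReport:
    """Regress log10(predicted+1) on log10(observed+1), shedding gross outliers.

    Genes with observed TPM below ``min_tpm`` are excluded.  While the
    largest absolute externally studentized residual exceeds
    ``resid_threshold`` and fewer than ``max_outliers`` points have been
    removed, the offending gene is dropped (one at a time) and the model
    refit; removal order is reported.
    """
    pred, obs = predicted.values.align(observed.values, join="inner")
    keep = obs >= min_tpm
    if keep.sum() < 10:
        raise ValueError("fewer than 10 genes above the observed-TPM floor")
    x = np.log10(obs[keep] + 1.0)
    y = np.log10(pred[keep] + 1.0)
    removed: list[str] = []
    while True:
        if x.nunique() < 2:
            raise ValueError("degenerate regressor: observed values have no spread")
        model = sm.OLS(y, sm.add_constant(x)).fit()
        if len(removed) >= max_outliers:
            break
        if model.ssr <= 1e-24:  # perfect fit; studentized residuals undefined
            break
        resid = OLSInfluence(model).resid_studentized_external
        worst = resid.abs().idxmax()
        if abs(resid[worst]) <= resid_threshold:
            break
        removed.append(worst)
        x = x.drop(worst)
        y = y.drop(worst)
    return RegressionReport(
        slope=float(model.params.iloc[1]),
        intercept=float(model.params.iloc[0]),
        r_squared=float(model.rsquared),
        n_points=int(model.nobs),
        removed_outliers=removed,
    )
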