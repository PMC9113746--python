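"""Wave clustering of blood-meal time-course expression.

Blood feeding triggers successive transcriptional waves: cohorts of genes
induced (or repressed) rapidly (peak at 6 h post blood meal), with
sustained intermediate deviation (6–24 h), or delayed (peak at 24 h),
typically returning toward baseline by 48 h.  The procedure: censor genes
below a TPM floor, z-score each gene's profile across timepoints,
hierarchically cluster the z rows, and label each cluster's centroid by the
timing and sign of its extremal deviation from the pre-meal baseline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .containers import ConditionProfile

CANONICAL_TIMEPOINTS = (0.0, 6.0, 24.0, 48.0)

WAVE_LABELS = (
    "rapid-induced",
    "intermediate-induced",
    "delayed-induced",
    "rapid-repressed",
    "intermediate-repressed",
    "delayed-repressed",
)


@dataclass
class WaveAssignment:
    """Gene-level wave labels with the cluster centroids that induced them.

    ``table`` columns: gene_id, cluster, cohort, peak_h; ``centroids`` is a
    cluster × timepoint z matrix.
    """

    table: pd.DataFrame
    centroids: pd.DataFrame

    def counts(self) -> pd.Series:
        return self.table.groupby("cohort").size()


def timepoint_frame(
    profiles: dict[tuple, ConditionProfile] | dict[float, ConditionProfile]
) -> pd.DataFrame:
    """Arrange per-timepoint profiles into a gene × timepoint frame.

    Accepts either ``{timepoint: profile}`` or the tuple-keyed dict from
    :func:`atlasdecon.core.aggregate_replicates`, reading the timepoint from
    the profile itself in the latter case.
    """
    cols = {}
    for key, prof in profiles.items():
        tp = prof.timepoint_h if prof.timepoint_h is not None else float(key)
        cols[float(tp)] = prof.values
    frame = pd.DataFrame(cols)
    return frame[sorted(frame.columns)]


def zscore_profiles(frame: pd.DataFrame, min_tpm: float = 2.0) -> pd.DataFrame:
    """Row-wise z-scores over timepoints after censoring low-expressed genes.

    Genes whose maximum mean TPM across the compared conditions is below
    ``min_tpm`` are dropped; so are zero-variance rows (with a warning).
    z uses the n−1 standard deviation, matching row scaling in heatmap
    clustering tools.
    """
    if frame.shape[1] < 2:
        raise ValueError("need at least two timepoints to z-score")
    kept = frame[frame.max(axis=1) >= min_tpm]
    sd = kept.std(axis=1, ddof=1)
    flat = sd == 0
    if flat.any():
        warnings.warn(
            f"dropping {int(flat.sum())} zero-variance gene(s) before clustering",
            stacklevel=2,
        )
        kept, sd = kept[~flat], sd[~flat]
    return kept.sub(kept.mean(axis=1), axis=0).div(sd, axis=0)


def cluster_rows(
    z: pd.DataFrame,
    k: int,
    metric: str = "euclidean",
    linkage: str = "complete",
) -> tuple[pd.Series, list[str]]:
    """Agglomerative clustering of z rows cut into k clusters.

    Returns (labels, dendrogram leaf order).  Deterministic given the input
    row order.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > len(z):
        raise ValueError(f"k={k} exceeds the {len(z)} available rows")
    tree = hierarchy.linkage(pdist(z.to_numpy(), metric=metric), method=linkage)
    labels = hierarchy.fcluster(tree, t=k, criterion="maxclust")
    order = [z.index[i] for i in hierarchy.leaves_list(tree)]
    return pd.Series(labels, index=z.index, name="cluster"), order


def classify_centroid(
    centroid: pd.Series,
    intermediate_tol: float = 0.5,
) -> tuple[str, float]:
    """Label one cluster centroid and report its extremum timepoint.

    Deviations are measured from the t0 (pre-meal) baseline.  Induced vs
    repressed follows the sign of the larger |deviation| at 6 or 24 h;
    'intermediate' requires sustained deviation (|z6 − z24| below
    ``intermediate_tol`` with both excursions on the same side of baseline),
    otherwise the extremum timepoint decides rapid (6 h) vs delayed (24 h).
    """
    tps = sorted(centroid.index)
    if 6.0 not in tps or 24.0 not in tps or 0.0 not in tps:
        raise ValueError("wave labels need the 0, 6 and 24 h timepoints")
    base = centroid[0.0]
    d6, d24 = centroid[6.0] - base, centroid[24.0] - base
    extreme = d6 if abs(d6) >= abs(d24) else d24
    direction = "induced" if extreme > 0 else "repressed"
    sustained = (
        abs(centroid[6.0] - centroid[24.0]) < intermediate_tol
        and d6 * d24 > 0
    )
    if sustained:
        return f"intermediate-{direction}", (6.0 + 24.0) / 2
    if abs(d6) >= abs(d24):
        return f"rapid-{direction}", 6.0
    return f"delayed-{direction}", 24.0


def wave_pipeline(
    frame: pd.DataFrame,
    k: int = 6,
    min_tpm: float = 2.0,
    log_expression: bool = True,
    linkage: str = "ward",
    metric: str = "euclidean",
    intermediate_tol: float = 0.5,
) -> "WaveAssignment":
    """Censor, z-score, cluster and wave-label a gene × timepoint TPM frame.

    This is the package's standard wave workflow.  The TPM censor is
    applied on the raw scale; by default expression is then log10(x+1)
    transformed before z-scoring and Ward linkage is used for the cut —
    TPM is heavy-tailed, and on the raw scale the multiplicative noise of
    a cohort's high-amplitude timepoint dominates its z profile, blurring
    cohorts together (see the methods note).  Pass
    ``log_expression=False, linkage="complete"`` for raw-scale z rows and
    the classic heatmap-tool defaults.
    """
    kept = frame[frame.max(axis=1) >= min_tpm]
    x = np.log10(kept + 1.0) if log_expression else kept
    z = zscore_profiles(x, min_tpm=0.0)
    clusters, _ = cluster_rows(z, k=k, metric=metric, linkage=linkage)
    return assign_waves(z, clusters, intermediate_tol=intermediate_tol)


def assign_waves(
    z: pd.DataFrame,
    clusters: pd.Series,
    intermediate_tol: float = 0.5,
) -> WaveAssignment:
    """Label every clustered gene with its cluster centroid's wave cohort."""
    centroids = z.groupby(clusters).mean()
    records = []
    for cid, centroid in centroids.iterrows():
        cohort, peak = classify_centroid(centroid, intermediate_tol)
        for gene in clusters.index[clusters == cid]:
            records.append(
                {"gene_id": gene, "cluster": int(cid), "cohort": cohort, "peak_h": peak}
            )
    table = (
        pd.DataFrame(records, columns=["gene_id", "cluster", "cohort", "peak_h"])
        .sort_values("gene_id")
        .reset_index(drop=True)
    )
    return WaveAssignment(table=table, centroids=centroids)
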