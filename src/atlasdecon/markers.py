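"""Compartment-exclusive marker census and reference-relative enrichment.

A marker of compartment c is a gene expressed at ``min_tpm`` or more there
(replicate-mean TPM) and at least ``min_fold`` higher than in every other
compartment individually.  Because the fold criterion exceeds 1, no gene can
be a marker of two compartments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import ConditionProfile
from .core import DEFAULT_PSEUDOCOUNT, DEResult


@dataclass
class MarkerSet:
    """Census of compartment-exclusive markers.

    ``table`` columns: compartment, gene_id, focal_tpm, max_other_tpm,
    min_ratio; sorted within each compartment by focal TPM descending, ties
    by gene id.
    """

    table: pd.DataFrame
    min_tpm: float
    min_fold: float

    def genes_for(self, compartment: str) -> list[str]:
        sub = self.table[self.table["compartment"] == compartment]
        return sub["gene_id"].tolist()

    @property
    def compartments(self) -> list[str]:
        return sorted(self.table["compartment"].unique())

    def counts(self) -> pd.Series:
        return self.table.groupby("compartment").size()


def _profile_frame(profiles: dict[str, ConditionProfile] | dict[str, pd.Series]) -> pd.DataFrame:
    """Stack per-compartment profiles into a gene × compartment frame."""
    cols = {}
    for name, prof in profiles.items():
        cols[name] = prof.values if isinstance(prof, ConditionProfile) else prof
    frame = pd.DataFrame(cols)
    if frame.isna().any().any():
        raise ValueError("profiles do not share a common gene universe")
    return frame


def find_markers(
    profiles: dict[str, ConditionProfile],
    min_tpm: float = 5.0,
    min_fold: float = 50.0,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> MarkerSet:
    """Census genes exclusive to one compartment.

    Gene g is a marker of compartment c iff X_c(g) >= min_tpm and
    (X_c(g)+ε)/(X_d(g)+ε) >= min_fold for every other compartment d.
    """
    if min_fold <= 1:
        raise ValueError("min_fold must exceed 1")
    if len(profiles) < 2:
        raise ValueError("need at least two compartment profiles")
    frame = _profile_frame(profiles)
    values = frame.to_numpy(dtype=float)
    n_comp = values.shape[1]
    records = []
    for j, comp in enumerate(frame.columns):
        others = values[:, [k for k in range(n_comp) if k != j]]
        max_other = others.max(axis=1)
        min_ratio = (values[:, j] + pseudocount) / (max_other + pseudocount)
        is_marker = (values[:, j] >= min_tpm) & (min_ratio >= min_fold)
        for i in np.nonzero(is_marker)[0]:
            records.append(
                {
                    "compartment": comp,
                    "gene_id": frame.index[i],
                    "focal_tpm": values[i, j],
                    "max_other_tpm": max_other[i],
                    "min_ratio": min_ratio[i],
                }
            )
    table = pd.DataFrame(
        records,
        columns=["compartment", "gene_id", "focal_tpm", "max_other_tpm", "min_ratio"],
    )
    if len(table):
        table = table.sort_values(
            ["compartment", "focal_tpm", "gene_id"],
            ascending=[True, False, True],
        ).reset_index(drop=True)
        # min_fold > 1 makes double assignment impossible; assert the invariant
        assert not table["gene_id"].duplicated().any()
    return MarkerSet(table, min_tpm=min_tpm, min_fold=min_fold)


def enriched_vs_reference(
    profile: ConditionProfile,
    reference: ConditionProfile,
    min_fold: float,
    de: DEResult,
    alpha: float = 0.05,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> set[str]:
    """Genes fold-enriched over a reference profile and significant in ``de``.

    The reference may be an aggregate profile (e.g. the pooled remainder of
    an organ); ``de`` must cover the same contrast over the same genes.
    """
    focal, ref = profile.values.align(reference.values, join="outer")
    if focal.isna().any() or ref.isna().any():
        raise ValueError("profile and reference do not share a gene universe")
    ratio = (focal + pseudocount) / (ref + pseudocount)
    padj = de.table["padj"].reindex(focal.index)
    if padj.isna().any():
        raise ValueError("DE result does not cover the profile's gene universe")
    return set(focal.index[(ratio >= min_fold) & (padj < alpha)])
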