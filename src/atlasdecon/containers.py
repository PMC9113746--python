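"""Typed containers for expression data and study metadata.

The pipeline's canonical in-memory objects are thin wrappers around pandas
structures that validate their invariants on construction.  Expression is
carried gene-by-sample; TPM-flagged matrices must have columns summing to
10⁶ within a relative tolerance of 1e-6.  Validation is total: any schema
violation raises before a computation stage can run on bad data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

TPM_TOTAL = 1.0e6
TPM_RTOL = 1.0e-6

SAMPLE_SHEET_COLUMNS = (
    "sample_id",
    "compartment",
    "condition",
    "timepoint_h",
    "replicate",
    "species",
)

ORTHOLOG_RELATIONS = frozenset(
    {"1-to-1", "1-to-many", "many-to-1", "many-to-many"}
)


class SchemaError(ValueError):
    """A table violates its declared schema (duplicates, bad columns...)."""


class ConsistencyError(ValueError):
    """Two otherwise valid tables disagree (e.g. sample missing from sheet)."""


class UnitError(ValueError):
    """Expression values are inconsistent with the declared unit."""


def _check_unique(values, what: str) -> None:
    idx = pd.Index(values)
    if idx.has_duplicates:
        dups = idx[idx.duplicated()].unique().tolist()
        raise SchemaError(f"duplicate {what}: {dups[:10]}")


@dataclass
class ExpressionMatrix:
    """Gene-by-sample non-negative expression values with a unit flag.

    Parameters
    ----------
    data
        DataFrame with gene ids as index and sample ids as columns.
    unit
        Either ``"counts"`` or ``"TPM"``.  TPM columns must sum to 1e6
        within relative tolerance 1e-6.
    """

    data: pd.DataFrame
    unit: str

    def __post_init__(self) -> None:
        if self.unit not in ("counts", "TPM"):
            raise UnitError(f"unknown unit {self.unit!r}; expected counts or TPM")
        _check_unique(self.data.index, "gene id")
        _check_unique(self.data.columns, "sample id")
        values = self.data.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise SchemaError("expression values must be numeric")
        if np.isnan(values).any():
            rows, cols = np.nonzero(np.isnan(values))
            raise SchemaError(
                "missing value at gene "
                f"{self.data.index[rows[0]]!r}, sample {self.data.columns[cols[0]]!r}"
            )
        if (values < 0).any():
            rows, cols = np.nonzero(values < 0)
            raise SchemaError(
                "negative value at gene "
                f"{self.data.index[rows[0]]!r}, sample {self.data.columns[cols[0]]!r}"
            )
        if self.unit == "TPM":
            sums = values.sum(axis=0)
            bad = np.abs(sums - TPM_TOTAL) > TPM_RTOL * TPM_TOTAL
            if bad.any():
                j = int(np.nonzero(bad)[0][0])
                raise UnitError(
                    f"TPM column {self.data.columns[j]!r} sums to {sums[j]:.6g}, "
                    f"expected {TPM_TOTAL:g}"
                )

    @property
    def genes(self) -> pd.Index:
        return self.data.index

    @property
    def samples(self) -> pd.Index:
        return self.data.columns

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        missing = [s for s in sample_ids if s not in self.data.columns]
        if missing:
            raise ConsistencyError(f"samples not in matrix: {missing}")
        return ExpressionMatrix(self.data.loc[:, list(sample_ids)], self.unit)


@dataclass
class SampleSheet:
    """Per-sample metadata: compartment, condition, timepoint, replicate, species."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in SAMPLE_SHEET_COLUMNS if c not in self.data.columns]
        if missing:
            raise SchemaError(f"sample sheet missing columns: {missing}")
        _check_unique(self.data["sample_id"], "sample_id")
        key = self.data[list(SAMPLE_SHEET_COLUMNS[1:])]
        if key.duplicated().any():
            raise SchemaError(
                "duplicate (compartment, condition, timepoint_h, replicate, species) "
                "combination in sample sheet"
            )
        reps = self.data["replicate"]
        if (reps.astype(float) < 1).any():
            raise SchemaError("replicate numbers must be positive integers")
        tp = self.data["timepoint_h"]
        if (tp.dropna().astype(float) < 0).any():
            raise SchemaError("timepoint_h must be non-negative")
        self.data = self.data.reset_index(drop=True)

    @property
    def sample_ids(self) -> pd.Index:
        return pd.Index(self.data["sample_id"])

    def select(self, **filters) -> list[str]:
        """Sample ids matching every ``column=value`` filter."""
        mask = pd.Series(True, index=self.data.index)
        for col, value in filters.items():
            if col not in self.data.columns:
                raise SchemaError(f"unknown sample sheet column {col!r}")
            mask &= self.data[col] == value
        return self.data.loc[mask, "sample_id"].tolist()

    def check_matrix(self, matrix: ExpressionMatrix) -> None:
        """Every matrix column must appear exactly once in the sheet."""
        sheet_ids = set(self.sample_ids)
        orphans = [s for s in matrix.samples if s not in sheet_ids]
        if orphans:
            raise ConsistencyError(
                f"samples in matrix absent from sample sheet: {orphans[:10]}"
            )


@dataclass
class CategoryMap:
    """Mapping of category name to gene-id set, with optional category groups.

    Genes may belong to several categories; :meth:`overlapping_genes` lists
    them so pipelines can flag the double counting in their reports.
    """

    categories: dict[str, set[str]]
    groups: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, genes in self.categories.items():
            if not genes:
                raise SchemaError(f"category {name!r} has an empty gene set")

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "CategoryMap":
        if not {"gene_id", "category"} <= set(frame.columns):
            raise SchemaError("category map needs gene_id and category columns")
        cats: dict[str, set[str]] = {}
        for cat, sub in frame.groupby("category"):
            cats[str(cat)] = set(sub["gene_id"])
        groups = {}
        if "group" in frame.columns:
            for cat, sub in frame.groupby("category"):
                g = sub["group"].dropna().unique()
                if len(g):
                    groups[str(cat)] = str(g[0])
        return cls(cats, groups)

    def overlapping_genes(self) -> dict[str, list[str]]:
        seen: dict[str, list[str]] = {}
        for cat, genes in self.categories.items():
            for g in genes:
                seen.setdefault(g, []).append(cat)
        return {g: sorted(cats) for g, cats in seen.items() if len(cats) > 1}


@dataclass
class OrthologTable:
    """OrthoFinder-style relations between two species' gene ids."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"gene_a", "gene_b", "orthogroup_id", "relation"}
        missing = required - set(self.data.columns)
        if missing:
            raise SchemaError(f"ortholog table missing columns: {sorted(missing)}")
        bad = set(self.data["relation"]) - ORTHOLOG_RELATIONS
        if bad:
            raise SchemaError(f"unknown ortholog relation labels: {sorted(bad)}")
        one = self.data[self.data["relation"] == "1-to-1"]
        for col in ("gene_a", "gene_b"):
            dup = one[col][one[col].duplicated()]
            if len(dup):
                raise SchemaError(
                    f"gene {dup.iloc[0]!r} occurs more than once in the 1-to-1 subset"
                )
        self.data = self.data.reset_index(drop=True)


@dataclass
class YieldMeasurement:
    """One RNA-yield measurement: concentration [ng/µl], volume [µl], organs pooled."""

    compartment: str
    concentration_ng_ul: float
    volume_ul: float
    n_organs: int
    replicate: int

    def __post_init__(self) -> None:
        if self.concentration_ng_ul <= 0 or self.volume_ul <= 0:
            raise ValueError("concentration and volume must be positive")
        if self.n_organs < 1:
            raise ValueError("n_organs must be a positive integer")
        if self.replicate < 1:
            raise ValueError("replicate must be a positive integer")


@dataclass
class ConditionProfile:
    """Per-gene mean TPM for one compartment/condition after replicate averaging."""

    values: pd.Series
    compartment: str
    condition: str | None = None
    timepoint_h: float | None = None
    n_replicates: int = 1

    def __post_init__(self) -> None:
        if (self.values < 0).any():
            raise ValueError("profile values must be non-negative")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        self.values = self.values.astype(float)
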