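"""Reading and writing the pipeline's tab-separated interchange formats.

Canonical dialect: tab-separated, UTF-8, ``#`` comment lines allowed,
expression matrices keyed by a first ``gene_id`` column.  Reports are
written with deterministic row/column order and floats rendered to six
significant digits, so identical runs produce byte-identical files.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import is_dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import (
    CategoryMap,
    ConsistencyError,
    ExpressionMatrix,
    OrthologTable,
    SampleSheet,
    SchemaError,
    YieldMeasurement,
)

logger = logging.getLogger("atlasdecon")
if not logger.handlers:
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)

FLOAT_FORMAT = "%.6g"


def _read_tsv(path: str | Path, **kwargs) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    digest = hashlib.sha256(path.read_bytes()).hexdigest()[:12]
    logger.info("reading %s (sha256 %s)", path, digest)
    return pd.read_csv(path, sep="\t", comment="#", **kwargs)


def read_expression_matrix(path: str | Path, unit: str) -> ExpressionMatrix:
    frame = _read_tsv(path)
    if frame.columns[0] != "gene_id":
        raise SchemaError(
            f"expression matrix must start with a gene_id column, got {frame.columns[0]!r}"
        )
    frame = frame.set_index("gene_id")
    try:
        frame = frame.astype(float)
    except (TypeError, ValueError) as exc:
        raise SchemaError(f"non-numeric expression values: {exc}") from exc
    return ExpressionMatrix(frame, unit)


def read_sample_sheet(path: str | Path) -> SampleSheet:
    return SampleSheet(_read_tsv(path))


def read_category_map(path: str | Path) -> CategoryMap:
    cmap = CategoryMap.from_frame(_read_tsv(path))
    overlaps = cmap.overlapping_genes()
    if overlaps:
        logger.info("%d gene(s) belong to multiple categories", len(overlaps))
    return cmap


def read_ortholog_table(path: str | Path) -> OrthologTable:
    return OrthologTable(_read_tsv(path))


def read_yields(path: str | Path) -> list[YieldMeasurement]:
    frame = _read_tsv(path)
    required = {"compartment", "concentration_ng_ul", "volume_ul", "n_organs", "replicate"}
    missing = required - set(frame.columns)
    if missing:
        raise SchemaError(f"yield table missing columns: {sorted(missing)}")
    return [
        YieldMeasurement(
            compartment=str(r.compartment),
            concentration_ng_ul=float(r.concentration_ng_ul),
            volume_ul=float(r.volume_ul),
            n_organs=int(r.n_organs),
            replicate=int(r.replicate),
        )
        for r in frame.itertuples()
    ]


def read_inputs(paths: dict[str, str | Path], unit: str):
    """Read and cross-validate a full input bundle.

    ``paths`` maps roles (``matrix``, ``samples`` and optionally
    ``categories``, ``orthologs``, ``yields``) to files.  Matrix columns
    must all appear in the sample sheet.
    """
    if "matrix" not in paths or "samples" not in paths:
        raise ValueError("paths must include at least 'matrix' and 'samples'")
    matrix = read_expression_matrix(paths["matrix"], unit)
    sheet = read_sample_sheet(paths["samples"])
    sheet.check_matrix(matrix)
    categories = read_category_map(paths["categories"]) if "categories" in paths else None
    orthologs = read_ortholog_table(paths["orthologs"]) if "orthologs" in paths else None
    yields = read_yields(paths["yields"]) if "yields" in paths else None
    return matrix, sheet, categories, orthologs, yields


def write_expression_matrix(matrix: ExpressionMatrix, path: str | Path) -> None:
    frame = matrix.data.sort_index().rename_axis("gene_id")
    frame.to_csv(path, sep="\t", float_format=FLOAT_FORMAT)


def _as_frame(result) -> pd.DataFrame:
    if isinstance(result, pd.DataFrame):
        return result
    if isinstance(result, pd.Series):
        return result.to_frame()
    for attr in ("to_frame",):
        if hasattr(result, attr):
            return getattr(result, attr)()
    for attr in ("table", "steps"):
        if hasattr(result, attr):
            return getattr(result, attr)
    if is_dataclass(result):
        return pd.DataFrame([vars(result)])
    raise TypeError(f"cannot render {type(result).__name__} as a report")


def write_report(
    result,
    path: str | Path,
    format: str = "tsv",
    config: dict | None = None,
    seed: int | None = None,
    sort: bool = True,
) -> None:
    """Write a typed pipeline output deterministically.

    TSV reports sort rows by their primary key unless the row order is the
    payload (pass ``sort=False`` for ranked lists or trajectories); floats
    use six significant digits.  JSON reports embed the run config and seed.
    """
    frame = _as_frame(result)
    if sort and len(frame):
        if frame.index.name is not None:
            frame = frame.sort_index()
        else:
            frame = frame.sort_values(list(frame.columns), kind="mergesort")
    path = Path(path)
    if format == "tsv":
        frame.to_csv(
            path, sep="\t", float_format=FLOAT_FORMAT,
            index=frame.index.name is not None,
        )
    elif format == "json":
        def _default(o):
            if isinstance(o, (np.integer,)):
                return int(o)
            if isinstance(o, (np.floating,)):
                return float(o)
            raise TypeError(type(o))

        payload = {
            "config": config or {},
            "seed": seed,
            "rows": json.loads(frame.to_json(orient="records", double_precision=6)),
        }
        path.write_text(json.dumps(payload, indent=1, sort_keys=True, default=_default))
    else:
        raise ValueError(f"unknown report format {format!r}; use tsv or json")
    logger.info("wrote %s (%s)", path, format)
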