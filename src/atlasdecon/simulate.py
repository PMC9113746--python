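"""Ground-truthed synthetic expression datasets.

Each generator emulates the statistical structure one analysis stage
assumes, and returns the planted truth alongside the data so recovery can
be scored exactly:

* :func:`generate_atlas` — multi-compartment TPM profiles with planted
  compartment-exclusive markers and a whole-body sample that is a known
  weighted mixture of the compartments.
* :func:`generate_time_course` — a 0/6/24/48 h blood-meal course built
  from rapid/intermediate/delayed induction and repression templates.
* :func:`generate_two_species` — paired species profiles linked by a
  one-to-one ortholog table with a few planted, highly/disparately
  expressed signature pairs.
* :func:`generate_two_group` — a two-group design with planted log2
  fold-changes for calibrating the differential-expression gate.

Noise is multiplicative log-normal on TPM: every replicate column is the
mean profile times exp(N(0, noise_sd_log²)) gene-wise, renormalized to sum
1e6.  Generators are pure functions of their parameters and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import (
    TPM_TOTAL,
    ExpressionMatrix,
    OrthologTable,
    SampleSheet,
    SchemaError,
)

DEFAULT_COMPARTMENTS = (
    "head",
    "thorax",
    "abdomen",
    "gut",
    "malpighian_tubules",
    "ovaries",
)

#: Between-compartment spread (log10) of each gene's expression around a
#: shared baseline.  Real body parts share a housekeeping backbone, so
#: per-gene levels are correlated across compartments; 0.3 log10 units of
#: compartment-specific deviation leaves the marginal per-compartment
#: distribution at the stated log-normal(1, 1) while keeping chance 50-fold
#: enrichments (≈1.7 log10 units over the max of five correlated profiles)
#: vanishingly rare, as they are in real atlases.
COMPARTMENT_EFFECT_SD_LOG10 = 0.3

#: TPM multipliers per timepoint (0, 6, 24, 48 h) for each wave template.
WAVE_TEMPLATES: dict[str, tuple[float, float, float, float]] = {
    "rapid-induced": (1.0, 6.0, 1.0, 1.0),
    "intermediate-induced": (1.0, 4.0, 4.0, 1.0),
    "delayed-induced": (1.0, 1.0, 6.0, 1.0),
    "rapid-repressed": (1.0, 1 / 6, 1.0, 1.0),
    "intermediate-repressed": (1.0, 1 / 4, 1 / 4, 1.0),
    "delayed-repressed": (1.0, 1.0, 1 / 6, 1.0),
    "flat": (1.0, 1.0, 1.0, 1.0),
}


@dataclass
class SyntheticTruth:
    """Planted ground truth recorded by the generators."""

    true_weights: dict[str, float] = field(default_factory=dict)
    marker_genes: dict[str, set[str]] = field(default_factory=dict)
    wave_template: dict[str, str] = field(default_factory=dict)
    template_multipliers: dict[str, tuple[float, ...]] = field(default_factory=dict)
    signature_pairs: list[tuple[str, str]] = field(default_factory=list)
    signature_log10_ratios: dict[tuple[str, str], float] = field(default_factory=dict)
    de_genes: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.true_weights:
            total = sum(self.true_weights.values())
            if abs(total - 1.0) > 1e-12:
                raise ValueError(f"true weights sum to {total}, not 1")
        sets = list(self.marker_genes.values())
        for i, s in enumerate(sets):
            for t in sets[i + 1:]:
                if s & t:
                    raise ValueError("marker sets must be disjoint across compartments")


def _gene_ids(n: int, prefix: str = "g") -> list[str]:
    width = max(5, len(str(n - 1)))
    return [f"{prefix}{i:0{width}d}" for i in range(n)]


def _replicates(
    mean: np.ndarray, n_replicates: int, noise_sd_log: float, rng: np.random.Generator
) -> np.ndarray:
    """Mean profile × gene-wise log-normal noise, renormalized to TPM."""
    noise = np.exp(rng.normal(0.0, noise_sd_log, size=(mean.shape[0], n_replicates)))
    cols = mean[:, None] * noise
    return cols / cols.sum(axis=0) * TPM_TOTAL


def _sheet_rows(sample_ids, compartment, condition, timepoint_h, species):
    return [
        {
            "sample_id": sid,
            "compartment": compartment,
            "condition": condition,
            "timepoint_h": timepoint_h,
            "replicate": r + 1,
            "species": species,
        }
        for r, sid in enumerate(sample_ids)
    ]


def generate_atlas(
    n_genes: int = 20_000,
    compartments: tuple[str, ...] = DEFAULT_COMPARTMENTS,
    markers_per_compartment: int = 12,
    weights: dict[str, float] | None = None,
    noise_sd_log: float = 0.2,
    n_replicates: int = 3,
    seed: int = 0,
) -> tuple[ExpressionMatrix, SampleSheet, SyntheticTruth]:
    """Simulate a body-part atlas with a known whole-body mixture.

    Per-compartment mean profiles are log-normal with log10 mean 1 and sd 1
    (a shared baseline plus compartment-specific deviation).  Each
    compartment's planted markers are set high (≥100 TPM pre-normalization)
    there and to 0 everywhere else.  The whole-body mean is the
    weight-mixed sum of the compartment means; noise is applied after
    mixing, so at ``noise_sd_log=0`` the whole-body column equals the
    mixture exactly.
    """
    k = len(compartments)
    if markers_per_compartment < 1:
        raise ValueError("markers_per_compartment must be >= 1")
    if noise_sd_log < 0:
        raise ValueError("noise_sd_log must be non-negative")
    rng = np.random.default_rng(seed)
    if weights is None:
        w = rng.dirichlet(np.full(k, 2.0))
        weights = dict(zip(compartments, w))
    else:
        w = np.array([weights[c] for c in compartments], dtype=float)
        if abs(w.sum() - 1.0) > 1e-9:
            raise ValueError(f"weights sum to {w.sum()}, not 1")
    genes = _gene_ids(n_genes)

    base_sd = np.sqrt(1.0 - COMPARTMENT_EFFECT_SD_LOG10**2)
    base = rng.normal(1.0, base_sd, size=n_genes)
    effects = rng.normal(0.0, COMPARTMENT_EFFECT_SD_LOG10, size=(n_genes, k))
    means = 10.0 ** (base[:, None] + effects)

    marker_idx = rng.choice(n_genes, size=k * markers_per_compartment, replace=False)
    marker_genes: dict[str, set[str]] = {}
    for j, comp in enumerate(compartments):
        idx = marker_idx[j * markers_per_compartment:(j + 1) * markers_per_compartment]
        means[idx, :] = 0.0
        means[idx, j] = 10.0 ** rng.uniform(2.0, 3.0, size=len(idx))
        marker_genes[comp] = {genes[i] for i in idx}

    means = means / means.sum(axis=0) * TPM_TOTAL
    wb_mean = means @ w

    columns: dict[str, np.ndarray] = {}
    sheet_rows = []
    for j, comp in enumerate(compartments):
        reps = _replicates(means[:, j], n_replicates, noise_sd_log, rng)
        ids = [f"{comp}_r{r + 1}" for r in range(n_replicates)]
        for r, sid in enumerate(ids):
            columns[sid] = reps[:, r]
        sheet_rows += _sheet_rows(ids, comp, "sugar_fed", np.nan, "synthetic")
    reps = _replicates(wb_mean, n_replicates, noise_sd_log, rng)
    ids = [f"whole_body_r{r + 1}" for r in range(n_replicates)]
    for r, sid in enumerate(ids):
        columns[sid] = reps[:, r]
    sheet_rows += _sheet_rows(ids, "whole_body", "sugar_fed", np.nan, "synthetic")

    matrix = ExpressionMatrix(pd.DataFrame(columns, index=genes), "TPM")
    sheet = SampleSheet(pd.DataFrame(sheet_rows))
    truth = SyntheticTruth(
        true_weights={c: float(x) for c, x in zip(compartments, w)},
        marker_genes=marker_genes,
    )
    return matrix, sheet, truth


def generate_time_course(
    n_genes: int = 600,
    timepoints: tuple[float, ...] = (0.0, 6.0, 24.0, 48.0),
    genes_per_template: int = 100,
    noise_sd_log: float = 0.3,
    n_replicates: int = 3,
    seed: int = 0,
    templates: tuple[str, ...] = tuple(t for t in WAVE_TEMPLATES if t != "flat"),
) -> tuple[ExpressionMatrix, SampleSheet, SyntheticTruth]:
    """Simulate a blood-meal time course from wave templates.

    The first ``genes_per_template`` genes follow the first template and so
    on; any remainder is flat.  Each timepoint column is renormalized to
    TPM, so observed fold-changes equal the template multipliers up to the
    per-column renormalization factor (recorded multipliers in the truth
    let tests back that factor out).
    """
    if len(timepoints) < 2:
        raise ValueError("need at least two timepoints")
    for t in templates:
        if len(WAVE_TEMPLATES[t]) != len(timepoints):
            raise ValueError(f"template {t!r} not defined at the supplied timepoints")
    if n_genes < genes_per_template * len(templates):
        raise ValueError("n_genes too small for the requested templates")
    rng = np.random.default_rng(seed)
    genes = _gene_ids(n_genes)
    labels = []
    for t in templates:
        labels += [t] * genes_per_template
    labels += ["flat"] * (n_genes - len(labels))

    baseline = 10.0 ** rng.normal(1.3, 0.4, size=n_genes)
    mult = np.array([WAVE_TEMPLATES[lab] for lab in labels])
    means = baseline[:, None] * mult  # genes × timepoints, pre-normalization

    columns: dict[str, np.ndarray] = {}
    sheet_rows = []
    for ti, tp in enumerate(timepoints):
        mean_t = means[:, ti] / means[:, ti].sum() * TPM_TOTAL
        reps = _replicates(mean_t, n_replicates, noise_sd_log, rng)
        ids = [f"gut_t{int(tp)}_r{r + 1}" for r in range(n_replicates)]
        for r, sid in enumerate(ids):
            columns[sid] = reps[:, r]
        condition = "sugar_fed" if tp == 0 else "blood_fed"
        sheet_rows += _sheet_rows(ids, "gut", condition, float(tp), "synthetic")

    matrix = ExpressionMatrix(pd.DataFrame(columns, index=genes), "TPM")
    sheet = SampleSheet(pd.DataFrame(sheet_rows))
    truth = SyntheticTruth(
        wave_template=dict(zip(genes, labels)),
        template_multipliers={t: WAVE_TEMPLATES[t] for t in set(labels)},
    )
    return matrix, sheet, truth


def generate_two_species(
    n_orthologs: int = 2_000,
    n_signature: int = 5,
    signature_log10_gap: float = 2.0,
    noise_sd_log: float = 0.1,
    n_replicates: int = 4,
    seed: int = 0,
    n_decoy: int = 0,
) -> tuple[
    ExpressionMatrix, ExpressionMatrix, SampleSheet, SampleSheet,
    OrthologTable, SyntheticTruth,
]:
    """Simulate paired species profiles with planted signature pairs.

    Non-signature orthologs share the same mean expression in both species.
    Signature pairs are planted among the highest-expressed genes (log10
    TPM ~4.5–5, i.e. several percent of the transcriptome each, as real
    species-signature genes are) in one species, alternating sides, with a
    ``signature_log10_gap`` deficit in the other — the few highly and
    disparately expressed genes that depress cross-species correlation.
    ``n_decoy`` adds many-to-many rows (ids outside both matrices) to
    exercise relation filtering.
    """
    if n_signature >= n_orthologs:
        raise ValueError("n_signature must be smaller than n_orthologs")
    if n_signature and signature_log10_gap <= 0:
        raise ValueError("signature_log10_gap must be positive")
    rng = np.random.default_rng(seed)
    genes_a = _gene_ids(n_orthologs, prefix="spa")
    genes_b = _gene_ids(n_orthologs, prefix="spb")
    if set(genes_a) & set(genes_b):
        raise SchemaError("species gene id prefixes collide")

    base = 10.0 ** rng.normal(1.0, 1.0, size=n_orthologs)
    mean_a = base.copy()
    mean_b = base.copy()
    sig_idx = np.sort(rng.choice(n_orthologs, size=n_signature, replace=False))
    signature_pairs: list[tuple[str, str]] = []
    sig_ratios: dict[tuple[str, str], float] = {}
    for j, idx in enumerate(sig_idx):
        high = 10.0 ** rng.uniform(4.5, 5.0)
        low = high / 10.0**signature_log10_gap
        if j % 2 == 0:
            mean_a[idx], mean_b[idx] = high, low
            ratio = -signature_log10_gap  # log10(b/a)
        else:
            mean_a[idx], mean_b[idx] = low, high
            ratio = signature_log10_gap
        pair = (genes_a[idx], genes_b[idx])
        signature_pairs.append(pair)
        sig_ratios[pair] = ratio

    mean_a = mean_a / mean_a.sum() * TPM_TOTAL
    mean_b = mean_b / mean_b.sum() * TPM_TOTAL

    def _species(genes, mean, tag):
        reps = _replicates(mean, n_replicates, noise_sd_log, rng)
        ids = [f"{tag}_gut_r{r + 1}" for r in range(n_replicates)]
        matrix = ExpressionMatrix(
            pd.DataFrame({sid: reps[:, r] for r, sid in enumerate(ids)}, index=genes),
            "TPM",
        )
        sheet = SampleSheet(
            pd.DataFrame(_sheet_rows(ids, "gut", "sugar_fed", np.nan, tag))
        )
        return matrix, sheet

    matrix_a, sheet_a = _species(genes_a, mean_a, "species_a")
    matrix_b, sheet_b = _species(genes_b, mean_b, "species_b")

    rows = [
        {
            "gene_a": ga,
            "gene_b": gb,
            "orthogroup_id": f"OG{i:06d}",
            "relation": "1-to-1",
        }
        for i, (ga, gb) in enumerate(zip(genes_a, genes_b))
    ]
    for d in range(n_decoy):
        rows.append(
            {
                "gene_a": f"spa_decoy{d:04d}",
                "gene_b": f"spb_decoy{d:04d}",
                "orthogroup_id": f"OGD{d:05d}",
                "relation": "many-to-many",
            }
        )
    table = OrthologTable(pd.DataFrame(rows))
    truth = SyntheticTruth(
        signature_pairs=signature_pairs, signature_log10_ratios=sig_ratios
    )
    return matrix_a, matrix_b, sheet_a, sheet_b, table, truth


def generate_two_group(
    n_genes: int = 5_000,
    n_de: int = 0,
    log2fc: float = 2.0,
    noise_sd_log: float = 0.2,
    n_replicates: int = 5,
    seed: int = 0,
) -> tuple[ExpressionMatrix, SampleSheet, SyntheticTruth]:
    """Two-group design with ``n_de`` genes planted at a log2 fold-change.

    Group A and B share a log-normal mean profile; the first ``n_de`` genes
    (chosen at random) are multiplied by 2**log2fc in group B before
    renormalization.  Used to calibrate the differential-expression gate
    (null false-positive rate and sensitivity on planted effects).
    """
    if n_de > n_genes:
        raise ValueError("n_de cannot exceed n_genes")
    rng = np.random.default_rng(seed)
    genes = _gene_ids(n_genes)
    mean = 10.0 ** rng.normal(1.0, 1.0, size=n_genes)
    mean_b = mean.copy()
    de_idx = np.sort(rng.choice(n_genes, size=n_de, replace=False)) if n_de else []
    mean_b[de_idx] *= 2.0**log2fc
    mean_a = mean / mean.sum() * TPM_TOTAL
    mean_b = mean_b / mean_b.sum() * TPM_TOTAL

    columns: dict[str, np.ndarray] = {}
    sheet_rows = []
    for tag, m in (("a", mean_a), ("b", mean_b)):
        reps = _replicates(m, n_replicates, noise_sd_log, rng)
        ids = [f"group_{tag}_r{r + 1}" for r in range(n_replicates)]
        for r, sid in enumerate(ids):
            columns[sid] = reps[:, r]
        sheet_rows += _sheet_rows(ids, "whole_body", f"group_{tag}", np.nan, "synthetic")
    matrix = ExpressionMatrix(pd.DataFrame(columns, index=genes), "TPM")
    sheet = SampleSheet(pd.DataFrame(sheet_rows))
    truth = SyntheticTruth(de_genes={genes[i]: log2fc for i in de_idx})
    return matrix, sheet, truth
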