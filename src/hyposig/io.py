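"""Readers and writers for the pipeline's plain-text formats.

Formats
-------
* expression: gene-by-sample TSV; first column the gene id, header row
  the sample ids.
* gene sets: GMT — one set per line: name, description, then member
  gene ids, tab-separated.
* clinical: TSV with columns sample_id, os_time, os_event, pfs_time,
  pfs_event, stage, grade, residual, gender (+ optional annotations).
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .datatypes import (
    CLINICAL_COLUMNS,
    ClinicalTable,
    ExpressionMatrix,
    FormatError,
    GeneSet,
)

logger = logging.getLogger(__name__)

__all__ = [
    "read_expression",
    "write_expression",
    "read_gmt",
    "write_gmt",
    "read_clinical",
    "write_clinical",
    "align_samples",
]


def read_expression(path: str | Path, log_transform_input: bool = False) -> ExpressionMatrix:
    """Read a gene-by-sample TSV into a validated :class:`ExpressionMatrix`.

    With ``log_transform_input`` the raw values ``x`` are replaced by
    ``log2(x + 1)``, the usual transform for RSEM-style abundance
    estimates delivered on the linear scale.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except Exception as exc:  # ragged rows, empty file, ...
        raise FormatError(f"{path}: cannot parse as gene-by-sample TSV: {exc}") from exc
    non_numeric = df.columns[[not pd.api.types.is_numeric_dtype(df[c]) for c in df.columns]]
    if len(non_numeric):
        for col in non_numeric:
            bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()].tolist()
            if bad:
                raise FormatError(f"{path}: non-numeric value for gene {bad[0]!r} in column {col!r}")
        df = df.apply(pd.to_numeric)
    if df.isna().any().any():
        gene = df.index[df.isna().any(axis=1)][0]
        raise FormatError(f"{path}: missing value in row for gene {gene!r}")
    if log_transform_input:
        if (df.to_numpy() < 0).any():
            raise FormatError(f"{path}: negative values cannot be log2(x+1)-transformed")
        df = np.log2(df + 1.0)
    return ExpressionMatrix(df)


def write_expression(matrix: ExpressionMatrix, path: str | Path) -> None:
    matrix.values.to_csv(path, sep="\t", index_label="gene_id")


def read_gmt(path: str | Path) -> list[GeneSet]:
    """Parse a GMT file into a list of gene sets.

    Duplicate genes within a line are dropped (first occurrence kept)
    with a logged warning; a line with fewer than three fields is a
    format error; an empty file yields an empty list.
    """
    path = Path(path)
    sets: list[GeneSet] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line needs name, description and >=1 gene")
            name, _desc, *genes = fields
            genes = [g for g in genes if g]
            seen: dict[str, None] = {}
            for g in genes:
                if g in seen:
                    continue
                seen[g] = None
            if len(seen) < len(genes):
                logger.warning(
                    "%s:%d: gene set %r contains %d duplicate gene ids; deduplicated",
                    path, lineno, name, len(genes) - len(seen),
                )
            sets.append(GeneSet(name=name, genes=tuple(seen)))
    return sets


def write_gmt(gene_sets: Sequence[GeneSet], path: str | Path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for gs in gene_sets:
            fh.write("\t".join([gs.name, description, *gs.genes]) + "\n")


def read_clinical(path: str | Path) -> ClinicalTable:
    """Read and validate a clinical TSV.

    Rows with a missing survival time or event indicator (either
    endpoint) are dropped with a logged count; a missing mandatory
    column is a format error.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t")
    except Exception as exc:
        raise FormatError(f"{path}: cannot parse as TSV: {exc}") from exc
    missing_cols = [c for c in CLINICAL_COLUMNS if c not in df.columns]
    if missing_cols:
        raise FormatError(f"{path}: missing mandatory columns: {missing_cols}")
    survival_cols = ["os_time", "os_event", "pfs_time", "pfs_event"]
    incomplete = df[survival_cols].isna().any(axis=1)
    if incomplete.any():
        logger.warning(
            "%s: dropped %d row(s) with missing survival time/event", path, int(incomplete.sum())
        )
        df = df.loc[~incomplete]
    return ClinicalTable(df)


def write_clinical(clinical: ClinicalTable, path: str | Path) -> None:
    clinical.table.to_csv(path, sep="\t", index_label="sample_id")


def align_samples(matrix: ExpressionMatrix, clinical: ClinicalTable) -> tuple[ExpressionMatrix, ClinicalTable]:
    """Restrict both inputs to their common samples (expression order).

    Samples present on one side only are dropped, never imputed; the
    discarded count is logged.
    """
    common = [s for s in matrix.sample_ids if s in set(clinical.sample_ids)]
    if not common:
        raise ValueError("expression and clinical tables share no samples")
    dropped = (len(matrix.sample_ids) - len(common)) + (len(clinical) - len(common))
    if dropped:
        logger.warning("sample alignment dropped %d unmatched sample(s)", dropped)
    return (
        ExpressionMatrix(matrix.values[common]),
        clinical.subset(common),
    )
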