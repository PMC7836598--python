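"""Shared domain containers for the hypoxia-signature pipeline.

The pipeline moves three validated objects between stages:

* :class:`ExpressionMatrix` — a log-scale gene-by-sample matrix,
* :class:`GeneSet` — a named collection of gene identifiers (hallmark
  sets and derived signatures),
* :class:`ClinicalTable` — per-sample survival endpoints plus ordinal
  and binary covariates.

Tabular intermediate results (differential-expression tables, score
tables) are plain :class:`pandas.DataFrame` objects with documented
column schemas; see :mod:`hyposig.signature` and :mod:`hyposig.scoring`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "GeneSet",
    "ExpressionMatrix",
    "ClinicalTable",
    "PipelineConfig",
    "STAGE_LEVELS",
    "GRADE_LEVELS",
]

#: Ordinal pathologic-stage levels, upper categories collapsed as in
#: standard clinical reporting for pancreatic cohorts.
STAGE_LEVELS: tuple[str, ...] = ("I", "II", "III/IV")

#: Ordinal histologic-grade levels, G3 and G4 collapsed.
GRADE_LEVELS: tuple[str, ...] = ("G1", "G2", "G3/G4")


class FormatError(ValueError):
    """Raised when an input file or table violates its declared format."""


@dataclass(frozen=True)
class GeneSet:
    """A named, duplicate-free, order-preserving collection of gene ids."""

    name: str
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"gene set {self.name!r} is empty")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"gene set {self.name!r} contains duplicate ids")
        object.__setattr__(self, "genes", tuple(str(g) for g in self.genes))

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self) -> Iterator[str]:
        return iter(self.genes)

    def __contains__(self, gene: object) -> bool:
        return gene in set(self.genes)

    def intersection(self, other: "GeneSet | Iterable[str]", name: str | None = None) -> "GeneSet":
        """Intersect with another set; result is sorted by gene id."""
        other_genes = set(other.genes if isinstance(other, GeneSet) else other)
        common = sorted(set(self.genes) & other_genes)
        if not common:
            raise ValueError("intersection is empty")
        return GeneSet(name=name or self.name, genes=tuple(common))


class ExpressionMatrix:
    """Log-scale expression values, genes in rows, samples in columns.

    Parameters
    ----------
    values
        Numeric DataFrame indexed by gene id with sample ids as columns.
        Identifiers must be unique, every value finite, and at least two
        samples present.
    """

    def __init__(self, values: pd.DataFrame) -> None:
        if not isinstance(values, pd.DataFrame):
            raise TypeError("expression values must be a pandas DataFrame")
        if values.index.has_duplicates:
            dupes = values.index[values.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate gene identifiers: {dupes[:5]}")
        if values.columns.has_duplicates:
            dupes = values.columns[values.columns.duplicated()].unique().tolist()
            raise FormatError(f"duplicate sample identifiers: {dupes[:5]}")
        if values.shape[1] < 2:
            raise FormatError("an expression matrix needs at least 2 samples")
        arr = values.to_numpy(dtype=float, copy=False)
        if not np.isfinite(arr).all():
            raise FormatError("expression matrix contains non-finite values")
        self._values = values.astype(float)
        self._values.index = self._values.index.astype(str).rename("gene_id")
        self._values.columns = self._values.columns.astype(str).rename(None)

    # -- accessors -----------------------------------------------------
    @property
    def values(self) -> pd.DataFrame:
        """The underlying gene-by-sample DataFrame."""
        return self._values

    @property
    def gene_ids(self) -> list[str]:
        return self._values.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self._values.columns.tolist()

    @property
    def shape(self) -> tuple[int, int]:
        return self._values.shape

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        """Restrict to the given genes (order preserved, all must exist)."""
        missing = [g for g in genes if g not in self._values.index]
        if missing:
            raise KeyError(f"genes absent from matrix: {missing[:5]}")
        return ExpressionMatrix(self._values.loc[list(genes)])

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        g, s = self.shape
        return f"ExpressionMatrix({g} genes x {s} samples)"


#: Mandatory clinical columns, in canonical order.
CLINICAL_COLUMNS: tuple[str, ...] = (
    "sample_id",
    "os_time",
    "os_event",
    "pfs_time",
    "pfs_event",
    "stage",
    "grade",
    "residual",
    "gender",
)


class ClinicalTable:
    """Per-sample survival endpoints and clinical covariates.

    Wraps a DataFrame indexed by ``sample_id`` with columns ``os_time``,
    ``os_event``, ``pfs_time``, ``pfs_event`` (times non-negative, events
    coded 0/1), ordinal ``stage`` / ``grade`` strings, binary
    ``residual`` / ``gender``, plus any extra categorical annotation
    columns (e.g. molecular subtype labels), which are carried through
    untouched.
    """

    def __init__(self, table: pd.DataFrame) -> None:
        df = table.copy()
        if df.index.name != "sample_id":
            if "sample_id" not in df.columns:
                raise FormatError("clinical table lacks a sample_id column")
            df = df.set_index("sample_id")
        df.index = df.index.astype(str)
        if df.index.has_duplicates:
            dupes = df.index[df.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate sample ids in clinical table: {dupes[:5]}")
        required = [c for c in CLINICAL_COLUMNS if c != "sample_id"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise FormatError(f"clinical table missing mandatory columns: {missing}")
        for col in ("os_time", "pfs_time"):
            df[col] = pd.to_numeric(df[col])
            if (df[col] < 0).any():
                bad = df.index[df[col] < 0][0]
                raise FormatError(f"negative {col} for sample {bad!r}")
        for col in ("os_event", "pfs_event", "residual", "gender"):
            df[col] = pd.to_numeric(df[col], downcast=None).astype(int)
            if not df[col].isin((0, 1)).all():
                raise FormatError(f"column {col} must be coded 0/1")
        for col, levels in (("stage", STAGE_LEVELS), ("grade", GRADE_LEVELS)):
            df[col] = df[col].astype(str)
            bad = sorted(set(df[col]) - set(levels))
            if bad:
                raise FormatError(f"unknown {col} levels {bad}; expected {levels}")
        self._table = df

    @property
    def table(self) -> pd.DataFrame:
        return self._table

    @property
    def sample_ids(self) -> list[str]:
        return self._table.index.tolist()

    def __len__(self) -> int:
        return len(self._table)

    def subset(self, sample_ids: Sequence[str]) -> "ClinicalTable":
        return ClinicalTable(self._table.loc[list(sample_ids)].reset_index())

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"ClinicalTable({len(self)} samples)"


@dataclass
class PipelineConfig:
    """Tunable thresholds of the analysis pipeline.

    Defaults follow the derivation protocol: upregulated genes must show
    fold-change > 2 at BH-adjusted p < 0.05; the gene-vs-score
    correlation screen keeps genes with r >= 0.05 at p < 0.05; forward
    covariate selection enters at likelihood-ratio p < 0.05; high/low
    groups split at the cohort median score.
    """

    fold_change_threshold: float = 2.0
    adjusted_p_threshold: float = 0.05
    gene_corr_r_threshold: float = 0.05
    gene_corr_p_threshold: float = 0.05
    forward_entry_p: float = 0.05
    score_split: str = "median"
    log_transform_input: bool = False
    seed: int = 20210126

    def __post_init__(self) -> None:
        if self.fold_change_threshold <= 0:
            raise ValueError("fold_change_threshold must be positive")
        for name in ("adjusted_p_threshold", "gene_corr_p_threshold", "forward_entry_p"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must lie in (0, 1)")
        if self.score_split != "median":
            raise ValueError("only the median score split is supported")
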