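"""Median-dichotomized per-sample signature scoring.

For every signature gene, each sample receives +1 if its expression is
in the top half of the cohort for that gene and -1 otherwise; the
sample's score is the sum of these contributions over all signature
genes present in the matrix. The score is a raw integer sum (never
rescaled by the number of genes used) and depends only on within-gene
ranks, so it is invariant under any strictly increasing per-gene
transformation of the expression values.

Score tables are DataFrames indexed by sample id with integer columns
``score`` and ``n_genes_used`` and a categorical ``group`` column
("high" iff the score is strictly above the cohort median score).
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import ExpressionMatrix, GeneSet

logger = logging.getLogger(__name__)

__all__ = [
    "binarize_gene",
    "signature_score",
    "assign_groups",
    "correlate_genes_with_score",
]


def binarize_gene(values: Sequence[float]) -> np.ndarray:
    """Map per-sample expression of one gene to +1 / -1 by the median.

    +1 iff the value is strictly greater than the median of the vector,
    else -1. With an even number of distinct values this yields exactly
    half of each sign; ties at the median fall to -1. A constant vector
    is uninformative: every sample gets -1 and a warning is logged.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or v.size < 2:
        raise ValueError("need a 1-d vector of >=2 values")
    if np.all(v == v[0]):
        logger.warning("constant expression vector; gene contributes -1 to every sample")
        return -np.ones(v.size, dtype=int)
    return np.where(v > np.median(v), 1, -1).astype(int)


def assign_groups(scores: Sequence[int]) -> pd.Series | np.ndarray:
    """Label each sample "high" iff its score strictly exceeds the median."""
    s = pd.Series(scores)
    if s.size < 2:
        raise ValueError("need >=2 samples to split")
    if s.nunique() == 1:
        raise ValueError("all scores identical; high/low stratification impossible")
    labels = np.where(s.to_numpy() > s.median(), "high", "low")
    if isinstance(scores, pd.Series):
        return pd.Series(labels, index=scores.index, name="group")
    return labels


def signature_score(matrix: ExpressionMatrix, signature: GeneSet) -> pd.DataFrame:
    """Per-sample signature score over the genes present in the matrix.

    Signature genes absent from the matrix are dropped with a logged
    warning; if none is present the score is undefined and a ValueError
    is raised. The returned table carries ``score``, ``n_genes_used``
    and the median-split ``group`` label for every sample.
    """
    present = [g for g in signature.genes if g in matrix.values.index]
    missing = len(signature) - len(present)
    if not present:
        raise ValueError(f"no gene of signature {signature.name!r} is present in the matrix")
    if missing:
        logger.warning("signature %r: %d gene(s) absent from the matrix; scoring on %d",
                       signature.name, missing, len(present))
    sub = matrix.values.loc[present].to_numpy()
    contributions = np.vstack([binarize_gene(row) for row in sub])
    scores = contributions.sum(axis=0)
    table = pd.DataFrame(
        {"score": scores, "n_genes_used": len(present)},
        index=pd.Index(matrix.sample_ids, name="sample_id"),
    )
    if table["score"].nunique() > 1:
        table["group"] = assign_groups(table["score"])
    else:
        # scores can legitimately all coincide (e.g. perfectly
        # anti-correlated genes); the score is still defined, only the
        # high/low stratification is not
        logger.warning("all scores identical; high/low group left unassigned")
        table["group"] = pd.NA
    return table


def correlate_genes_with_score(
    matrix: ExpressionMatrix,
    scores: pd.DataFrame | Sequence[float],
    r_threshold: float = 0.05,
    p_threshold: float = 0.05,
) -> pd.DataFrame:
    """Screen all genes for positive Pearson correlation with the score.

    Computes each gene's Pearson r against the per-sample score with a
    two-sided p from the t transform, and keeps genes with
    ``r >= r_threshold`` and ``p < p_threshold`` (a one-sided screen for
    positively associated genes), sorted by descending r. Zero-variance
    genes have an undefined correlation and are excluded with a warning.
    """
    if isinstance(scores, pd.DataFrame):
        score = scores["score"].reindex(matrix.sample_ids)
        if score.isna().any():
            raise ValueError("score table does not cover every expression sample")
        score = score.to_numpy(dtype=float)
    else:
        score = np.asarray(scores, dtype=float)
        if score.size != len(matrix.sample_ids):
            raise ValueError("scores length does not match the sample count")
    n = score.size
    if n < 3:
        raise ValueError("need >=3 samples for a correlation p-value")
    if np.std(score) == 0:
        raise ValueError("score vector has zero variance")

    x = matrix.values.to_numpy()
    xc = x - x.mean(axis=1, keepdims=True)
    sc = score - score.mean()
    x_ss = (xc ** 2).sum(axis=1)
    zero_var = x_ss == 0
    if zero_var.any():
        logger.warning("%d zero-variance gene(s) excluded from the correlation screen",
                       int(zero_var.sum()))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (xc @ sc) / np.sqrt(x_ss * (sc ** 2).sum())
        r = np.clip(r, -1.0, 1.0)
        t = r * np.sqrt((n - 2) / (1.0 - r ** 2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p[np.isclose(np.abs(r), 1.0)] = 0.0

    table = pd.DataFrame(
        {"r": r, "p": p}, index=pd.Index(matrix.gene_ids, name="gene_id")
    ).loc[~zero_var]
    keep = (table["r"] >= r_threshold) & (table["p"] < p_threshold)
    return table.loc[keep].sort_values("r", ascending=False)
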