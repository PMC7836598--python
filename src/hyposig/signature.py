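"""Derivation of the hypoxia signature from tumor-vs-normal screens.

The signature is the set of genes that (a) pass an upregulation screen
(fold-change and BH-adjusted p thresholds) in *every* supplied
tumor/normal study and (b) belong to the hypoxia hallmark set.

The differential-expression table is a DataFrame with one row per gene
and columns ``log2_fold_change`` (tumor mean minus normal mean of the
log2 values), ``fold_change`` (= 2**log2_fold_change, i.e. a ratio of
geometric means), ``p_value`` (two-sided Welch t-test) and
``adjusted_p`` (Benjamini-Hochberg across all tested genes).
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
    "benjamini_hochberg",
    "differential_expression",
    "filter_upregulated",
    "intersect_signature",
]


def benjamini_hochberg(p_values: np.ndarray) -> np.ndarray:
    """BH step-up adjusted p-values.

    For p-values sorted ascending, the adjusted value at rank i is
    ``min_{j >= i} p_(j) * m / j`` capped at 1; results are returned in
    the original order.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty_like(adjusted)
    out[order] = adjusted
    return out


def differential_expression(matrix: ExpressionMatrix, groups: Sequence) -> pd.DataFrame:
    """Per-gene Welch t-test of tumor vs normal on log2 expression.

    Parameters
    ----------
    matrix
        Log2-scale expression, genes x samples.
    groups
        Per-sample labels aligned with ``matrix.sample_ids``: either the
        strings ``"tumor"`` / ``"normal"`` or booleans (True = tumor).

    Genes whose values are constant within *both* groups have an
    undefined t statistic and receive ``p_value = 1`` regardless of the
    mean difference, so they can never pass a significance filter.
    """
    labels = pd.Series(list(groups), index=matrix.sample_ids)
    if labels.dtype == bool:
        tumor_mask = labels.to_numpy()
    else:
        allowed = {"tumor", "normal"}
        bad = set(labels.astype(str)) - allowed
        if bad:
            raise ValueError(f"unknown group labels {sorted(bad)}; expected {sorted(allowed)}")
        tumor_mask = (labels.astype(str) == "tumor").to_numpy()
    n_tumor, n_normal = int(tumor_mask.sum()), int((~tumor_mask).sum())
    if n_tumor < 2 or n_normal < 2:
        raise ValueError(f"each group needs >=2 samples (tumor={n_tumor}, normal={n_normal})")

    x = matrix.values.to_numpy()
    tumor, normal = x[:, tumor_mask], x[:, ~tumor_mask]
    log2fc = tumor.mean(axis=1) - normal.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        result = stats.ttest_ind(tumor, normal, axis=1, equal_var=False)
        p = np.asarray(result.pvalue, dtype=float)
    both_constant = (tumor.var(axis=1) == 0) & (normal.var(axis=1) == 0)
    p[both_constant] = 1.0
    if np.isnan(p).any():  # pragma: no cover - defensive
        p[np.isnan(p)] = 1.0
    return pd.DataFrame(
        {
            "log2_fold_change": log2fc,
            "fold_change": np.exp2(log2fc),
            "p_value": p,
            "adjusted_p": benjamini_hochberg(p),
        },
        index=pd.Index(matrix.gene_ids, name="gene_id"),
    )


def filter_upregulated(
    de_table: pd.DataFrame,
    fc_threshold: float = 2.0,
    adj_p_threshold: float = 0.05,
    name: str = "upregulated",
) -> GeneSet | None:
    """Genes with fold_change > threshold AND adjusted_p < threshold.

    Both inequalities are strict: a gene at exactly the fold-change
    threshold is excluded. Returns ``None`` for an empty result (a
    :class:`GeneSet` cannot be empty).
    """
    if fc_threshold <= 0 or not 0 < adj_p_threshold < 1:
        raise ValueError("invalid thresholds")
    keep = (de_table["fold_change"] > fc_threshold) & (de_table["adjusted_p"] < adj_p_threshold)
    genes = tuple(sorted(de_table.index[keep]))
    if not genes:
        logger.warning("no genes pass fold_change > %g and adjusted_p < %g", fc_threshold, adj_p_threshold)
        return None
    return GeneSet(name=name, genes=genes)


def intersect_signature(
    upregulated_sets: Sequence[GeneSet | None],
    hallmark: GeneSet,
    name: str = "HYPOXIA_SIGNATURE",
) -> tuple[str, ...]:
    """Intersection of all upregulated sets with the hallmark set.

    Order-independent and idempotent; the result is sorted by gene id.
    An empty intersection is allowed (logged) and returned as an empty
    tuple rather than an error, since a too-stringent screen is a valid
    outcome the caller should see.
    """
    if len(upregulated_sets) == 0:
        raise ValueError("need at least one upregulated gene set")
    common = set(hallmark.genes)
    for gs in upregulated_sets:
        common &= set(gs.genes) if gs is not None else set()
    if not common:
        logger.warning("signature %r is empty after intersection", name)
    return tuple(sorted(common))


def signature_gene_set(genes: Sequence[str], name: str = "HYPOXIA_SIGNATURE") -> GeneSet:
    """Wrap a non-empty derived signature as a named gene set."""
    return GeneSet(name=name, genes=tuple(genes))
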