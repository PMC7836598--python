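"""End-to-end orchestration of the hypoxia-signature analysis.

``run_all`` chains the full pipeline on synthetic inputs: simulate two
tumor/normal studies and a survival cohort, derive the signature by
DE screening + hallmark intersection, score every cohort sample for
hypoxia and EMT, and run the survival / correlation / contingency
analyses. Real inputs follow the same path through the individual
module functions (see examples/ and the CLI).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import association, io as hio, scoring, signature, simulate
from .datatypes import GeneSet, PipelineConfig

logger = logging.getLogger(__name__)

__all__ = ["PipelineResult", "derive_signature_from_studies", "run_all"]


@dataclass
class PipelineResult:
    """Everything the full pipeline computes on one cohort."""

    signature: tuple[str, ...]
    de_tables: list[pd.DataFrame]
    hypoxia_scores: pd.DataFrame
    emt_scores: pd.DataFrame
    logrank: dict[str, association.LogRankResult]
    cox_univariate: dict[str, association.CoxResult]
    cox_multivariate: dict[str, association.CoxResult]
    correlation: association.CorrelationResult
    contingency: dict[str, association.ContingencyResult]
    truth: dict = field(default_factory=dict)


def derive_signature_from_studies(
    studies: list[tuple], hallmark: GeneSet, config: PipelineConfig
) -> tuple[tuple[str, ...], list[pd.DataFrame]]:
    """DE-screen each study and intersect the upregulated sets with the hallmark."""
    de_tables = [signature.differential_expression(m, g) for m, g in studies]
    upregulated = [
        signature.filter_upregulated(
            t, config.fold_change_threshold, config.adjusted_p_threshold
        )
        for t in de_tables
    ]
    sig = signature.intersect_signature(upregulated, hallmark)
    return sig, de_tables


def run_all(
    sim_config: simulate.SyntheticConfig,
    config: PipelineConfig | None = None,
    outdir: str | Path | None = None,
) -> PipelineResult:
    """Run simulate -> derive-signature -> score -> associate.

    When ``outdir`` is given, every tabular result is also written
    there as a TSV.
    """
    config = config or PipelineConfig()

    hypoxia_set, emt_set = simulate.generate_gene_sets(sim_config)
    studies = simulate.generate_de_studies(sim_config, hypoxia_set)
    cohort = simulate.generate_survival_cohort(sim_config, hypoxia_set, emt_set)

    sig_genes, de_tables = derive_signature_from_studies(studies, hypoxia_set, config)
    if not sig_genes:
        raise RuntimeError("derived signature is empty; nothing to score")
    sig = signature.signature_gene_set(sig_genes)
    logger.info("derived signature of %d genes", len(sig_genes))

    hypoxia_scores = scoring.signature_score(cohort.expression, sig)
    emt_scores = scoring.signature_score(cohort.expression, emt_set)
    groups = hypoxia_scores["group"]

    logrank = {ep: association.km_logrank(cohort.clinical, groups, ep) for ep in ("os", "pfs")}
    cox_uni = {
        ep: association.cox_univariate(cohort.clinical, "hypoxia_score", ep, groups=groups)
        for ep in ("os", "pfs")
    }
    candidates = ["hypoxia_score", "stage", "grade", "residual", "gender"]
    cox_multi = {
        ep: association.cox_multivariate_forward(
            cohort.clinical, candidates, ep, entry_p=config.forward_entry_p, groups=groups
        )
        for ep in ("os", "pfs")
    }
    controls = association.ordinal_codes(cohort.clinical)
    correlation = association.correlation_analysis(
        hypoxia_scores["score"], emt_scores["score"], controls
    )
    contingency = {
        col: association.group_contingency(groups, cohort.clinical.table[col])
        for col in ("stage", "grade", "subtype")
        if col in cohort.clinical.table.columns
    }

    result = PipelineResult(
        signature=sig_genes,
        de_tables=de_tables,
        hypoxia_scores=hypoxia_scores,
        emt_scores=emt_scores,
        logrank=logrank,
        cox_univariate=cox_uni,
        cox_multivariate=cox_multi,
        correlation=correlation,
        contingency=contingency,
        truth=cohort.truth,
    )
    if outdir is not None:
        write_results(result, outdir)
    return result


def write_results(result: PipelineResult, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    hio.write_gmt([signature.signature_gene_set(result.signature)], outdir / "signature.gmt")
    for i, de in enumerate(result.de_tables, start=1):
        de.to_csv(outdir / f"de_study{i}.tsv", sep="\t")
    scores = result.hypoxia_scores.rename(
        columns={"score": "hypoxia_score", "n_genes_used": "hypoxia_n_genes", "group": "hypoxia_group"}
    ).join(
        result.emt_scores.rename(
            columns={"score": "emt_score", "n_genes_used": "emt_n_genes", "group": "emt_group"}
        )
    )
    scores.to_csv(outdir / "scores.tsv", sep="\t")

    rows = []
    for ep, lr in result.logrank.items():
        rows.append({"endpoint": ep, "chi_square": lr.chi_square, "p_value": lr.p_value,
                     **{f"n_{k}": v for k, v in lr.group_sizes.items()},
                     **{f"median_{k}": v for k, v in lr.median_survival.items()}})
    pd.DataFrame(rows).to_csv(outdir / "logrank.tsv", sep="\t", index=False)
    pd.concat(
        [lr.km_curves.assign(endpoint=ep) for ep, lr in result.logrank.items()],
        ignore_index=True,
    ).to_csv(outdir / "km_curves.tsv", sep="\t", index=False)

    for kind, results in (("univariate", result.cox_univariate), ("multivariate", result.cox_multivariate)):
        tables = []
        for ep, cox in results.items():
            t = cox.table.copy()
            t.insert(0, "endpoint", ep)
            t["flag"] = cox.flag or ""
            tables.append(t)
        pd.concat(tables).to_csv(outdir / f"cox_{kind}.tsv", sep="\t")

    corr = result.correlation
    pd.DataFrame([{
        "pearson_r": corr.pearson_r, "pearson_p": corr.pearson_p,
        "partial_r": corr.partial_r, "partial_p": corr.partial_p,
        "controls": ",".join(corr.controls),
    }]).to_csv(outdir / "correlation.tsv", sep="\t", index=False)

    cont_rows = []
    for name, cont in result.contingency.items():
        for group in cont.counts.index:
            for level in cont.counts.columns:
                cont_rows.append({
                    "variable": name, "group": group, "level": level,
                    "count": int(cont.counts.loc[group, level]),
                    "proportion": float(cont.proportions.loc[group, level]),
                    "chi_square": cont.chi_square, "p_value": cont.p_value,
                })
    pd.DataFrame(cont_rows).to_csv(outdir / "contingency.tsv", sep="\t", index=False)
    logger.info("wrote pipeline results to %s", outdir)
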