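"""Synthetic tumor/normal studies and survival cohorts with planted truth.

The generator emulates the statistical structure the pipeline is built
for, with every effect planted and recoverable:

* two tumor-vs-normal expression studies in which a fixed subset of the
  hypoxia hallmark genes is upregulated in tumors by ``effect_log2fc``
  on the log2 scale;
* a survival cohort driven by a latent per-sample hypoxia level
  ``z ~ N(0, 1)`` that jointly raises signature-gene expression
  (loading ``factor_loading``), EMT-gene expression (``emt_loading``),
  event hazard (``log_hr``), and the odds of higher stage/grade.

Expression noise is Gaussian on the log2 scale; survival times are
exponential (constant baseline hazard, so proportional hazards holds
exactly) with independent exponential censoring.

All randomness flows from ``SyntheticConfig.seed``; identical configs
give bit-identical outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit

from .datatypes import ClinicalTable, ExpressionMatrix, GeneSet
from . import io as hio

logger = logging.getLogger(__name__)

__all__ = [
    "SyntheticConfig",
    "LatentCohort",
    "generate_gene_sets",
    "generate_de_studies",
    "generate_survival_cohort",
    "write_de_study",
    "write_cohort",
]

# Distinct stream tags so each operation draws from its own child
# generator while remaining a pure function of the config seed.
_TAG_GENE_SETS = 1
_TAG_PLANTED = 2
_TAG_STUDY_BASE = 10  # + study index
_TAG_COHORT = 20


@dataclass(frozen=True)
class SyntheticConfig:
    """Planted parameters of the simulated study conditions.

    Defaults mirror the cohorts the pipeline targets: two microarray
    studies of 39 tumor / 39 normal samples, a 177-sample survival
    cohort, 200-gene hallmark sets with 30 truly hypoxia-responsive
    genes, a 2-fold planted tumor shift, and a latent hypoxia effect
    sized to give a high-vs-low group hazard ratio near 1.8 and a
    hypoxia-EMT score correlation near 0.5.
    """

    seed: int = 20210126
    n_genes: int = 10_000
    hallmark_size: int = 200
    emt_size: int = 200
    n_planted: int = 30
    n_tumor: int = 39
    n_normal: int = 39
    cohort_size: int = 177
    effect_log2fc: float = 2.0
    factor_loading: float = 1.0
    emt_loading: float = 0.03
    log_hr: float = 0.38
    noise_sd: float = 0.5
    censor_rate: float = 0.018
    #: constant baseline hazards (per time unit) for the two endpoints
    baseline_hazard_os: float = 0.035
    baseline_hazard_pfs: float = 0.058
    #: "latent": hazard = h0*exp(log_hr*z); "dichotomized": hazard =
    #: h0*exp(log_hr*1[z>0]), which plants an exact group hazard ratio.
    hazard_form: str = "latent"

    def __post_init__(self) -> None:
        counts = dict(
            n_genes=self.n_genes, hallmark_size=self.hallmark_size,
            emt_size=self.emt_size, n_planted=self.n_planted,
            n_tumor=self.n_tumor, n_normal=self.n_normal,
            cohort_size=self.cohort_size,
        )
        for name, v in counts.items():
            if v <= 0:
                raise ValueError(f"{name} must be positive, got {v}")
        if self.n_planted > self.hallmark_size:
            raise ValueError("n_planted cannot exceed hallmark_size")
        if self.hallmark_size + self.emt_size > self.n_genes:
            raise ValueError("hallmark_size + emt_size cannot exceed n_genes")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.effect_log2fc < 0 or self.factor_loading < 0 or self.emt_loading < 0:
            raise ValueError("effect sizes must be non-negative")
        if self.censor_rate < 0:
            raise ValueError("censor_rate must be non-negative")
        if self.hazard_form not in ("latent", "dichotomized"):
            raise ValueError("hazard_form must be 'latent' or 'dichotomized'")


@dataclass
class LatentCohort:
    """A survival cohort together with its hidden generating state."""

    expression: ExpressionMatrix
    clinical: ClinicalTable
    latent_factor: pd.Series
    truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.expression.sample_ids != self.clinical.sample_ids:
            raise ValueError("expression and clinical sample sets differ")
        if list(self.latent_factor.index) != self.expression.sample_ids:
            raise ValueError("latent factor must cover the identical sample set")


def _rng(config: SyntheticConfig, tag: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=config.seed, spawn_key=(tag,)))


def _gene_ids(n_genes: int) -> list[str]:
    width = max(5, len(str(n_genes)))
    return [f"G{i:0{width}d}" for i in range(1, n_genes + 1)]


def generate_gene_sets(config: SyntheticConfig) -> tuple[GeneSet, GeneSet]:
    """Draw disjoint hypoxia-hallmark and EMT-hallmark gene sets."""
    rng = _rng(config, _TAG_GENE_SETS)
    genes = _gene_ids(config.n_genes)
    picked = rng.choice(config.n_genes, size=config.hallmark_size + config.emt_size, replace=False)
    hypoxia = GeneSet("HALLMARK_HYPOXIA", tuple(sorted(genes[i] for i in picked[: config.hallmark_size])))
    emt = GeneSet(
        "HALLMARK_EPITHELIAL_MESENCHYMAL_TRANSITION",
        tuple(sorted(genes[i] for i in picked[config.hallmark_size:])),
    )
    return hypoxia, emt


def planted_genes(config: SyntheticConfig, hallmark: GeneSet) -> list[str]:
    """The hallmark genes carrying true tumor/hypoxia effects.

    Deterministic given the config seed, and shared by the DE studies
    and the survival cohort so the downstream signature has a single
    ground truth.
    """
    if config.n_planted > len(hallmark):
        raise ValueError("n_planted exceeds the hallmark set size")
    rng = _rng(config, _TAG_PLANTED)
    idx = rng.choice(len(hallmark), size=config.n_planted, replace=False)
    return sorted(hallmark.genes[i] for i in idx)


def _baseline_means(rng: np.random.Generator, n_genes: int) -> np.ndarray:
    # log2-scale abundances roughly spanning the microarray dynamic range
    return rng.uniform(4.0, 10.0, size=n_genes)


def generate_de_studies(
    config: SyntheticConfig, hallmark: GeneSet
) -> list[tuple[ExpressionMatrix, pd.Series]]:
    """Two tumor/normal studies sharing one planted upregulated gene list.

    Returns ``[(matrix, groups), ...]`` where ``groups`` is a Series of
    ``"tumor"`` / ``"normal"`` labels indexed by sample id.
    """
    planted = planted_genes(config, hallmark)
    genes = _gene_ids(config.n_genes)
    planted_mask = np.isin(genes, planted)
    studies: list[tuple[ExpressionMatrix, pd.Series]] = []
    for s in range(2):
        rng = _rng(config, _TAG_STUDY_BASE + s)
        n = config.n_tumor + config.n_normal
        base = _baseline_means(rng, config.n_genes)
        values = base[:, None] + rng.normal(0.0, config.noise_sd, size=(config.n_genes, n))
        values[np.ix_(planted_mask, np.arange(config.n_tumor))] += config.effect_log2fc
        samples = [f"S{s + 1}_T{i + 1:03d}" for i in range(config.n_tumor)] + [
            f"S{s + 1}_N{i + 1:03d}" for i in range(config.n_normal)
        ]
        matrix = ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples))
        groups = pd.Series(
            ["tumor"] * config.n_tumor + ["normal"] * config.n_normal, index=samples, name="group"
        )
        studies.append((matrix, groups))
    return studies


def _ordinal(rng: np.random.Generator, z: np.ndarray, cut1: float, cut2: float,
             slope: float, levels: tuple[str, ...]) -> list[str]:
    """Draw a 3-level ordinal with P(higher category) increasing in z.

    ``p_ge2 = expit(cut1 + slope*z)`` and ``p_ge3 = expit(cut2 + slope*z)``
    with cut2 < cut1 so the categories nest; a single uniform per sample
    keeps the draw monotone in z.
    """
    p_ge2 = expit(cut1 + slope * z)
    p_ge3 = expit(cut2 + slope * z)
    u = rng.uniform(size=z.shape)
    level = (u < p_ge2).astype(int) + (u < p_ge3).astype(int)
    return [levels[k] for k in level]


def generate_survival_cohort(
    config: SyntheticConfig, hallmark: GeneSet, emt: GeneSet
) -> LatentCohort:
    """Simulate the expression + clinical cohort driven by latent hypoxia."""
    rng = _rng(config, _TAG_COHORT)
    n = config.cohort_size
    genes = _gene_ids(config.n_genes)
    planted = planted_genes(config, hallmark)
    samples = [f"P{i + 1:04d}" for i in range(n)]

    z = rng.standard_normal(n)

    base = _baseline_means(rng, config.n_genes)
    values = base[:, None] + rng.normal(0.0, config.noise_sd, size=(config.n_genes, n))
    values[np.isin(genes, planted)] += config.factor_loading * z
    values[np.isin(genes, list(emt.genes))] += config.emt_loading * z
    expression = ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples))

    eta = config.log_hr * (z > 0).astype(float) if config.hazard_form == "dichotomized" else config.log_hr * z
    risk = np.exp(eta)

    def _endpoint(h0: float) -> tuple[np.ndarray, np.ndarray]:
        event_time = rng.exponential(1.0 / (h0 * risk))
        if config.censor_rate > 0:
            censor_time = rng.exponential(1.0 / config.censor_rate, size=n)
        else:
            censor_time = np.full(n, np.inf)
        time = np.minimum(event_time, censor_time)
        event = (event_time <= censor_time).astype(int)
        return time, event

    os_time, os_event = _endpoint(config.baseline_hazard_os)
    pfs_time, pfs_event = _endpoint(config.baseline_hazard_pfs)

    stage = _ordinal(rng, z, cut1=1.9, cut2=-2.6, slope=0.8, levels=("I", "II", "III/IV"))
    grade = _ordinal(rng, z, cut1=1.7, cut2=-0.7, slope=0.8, levels=("G1", "G2", "G3/G4"))
    residual = rng.binomial(1, 0.35, size=n)
    gender = rng.binomial(1, 0.5, size=n)
    # a two-group molecular-subtype label, mildly enriched at high z,
    # consumed downstream only as a given categorical annotation
    subtype = np.where(rng.uniform(size=n) < expit(-0.4 + 0.6 * z), "basal-like", "classical")

    clinical = ClinicalTable(pd.DataFrame({
        "sample_id": samples,
        "os_time": os_time,
        "os_event": os_event,
        "pfs_time": pfs_time,
        "pfs_event": pfs_event,
        "stage": stage,
        "grade": grade,
        "residual": residual,
        "gender": gender,
        "subtype": subtype,
    }))

    truth = {
        "planted_genes": planted,
        "log_hr": config.log_hr,
        "hazard_form": config.hazard_form,
        "factor_loading": config.factor_loading,
        "emt_loading": config.emt_loading,
    }
    return LatentCohort(
        expression=expression,
        clinical=clinical,
        latent_factor=pd.Series(z, index=samples, name="latent_hypoxia"),
        truth=truth,
    )


# ---------------------------------------------------------------- output


def write_de_study(study: tuple[ExpressionMatrix, pd.Series], outdir: str | Path, name: str) -> None:
    outdir = Path(outdir)
    matrix, groups = study
    hio.write_expression(matrix, outdir / f"{name}.tsv")
    groups.rename("group").to_frame().to_csv(outdir / f"{name}.groups.tsv", sep="\t", index_label="sample_id")


def write_cohort(config: SyntheticConfig, outdir: str | Path) -> None:
    """Generate and write every pipeline input plus the truth file."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    hypoxia, emt = generate_gene_sets(config)
    studies = generate_de_studies(config, hypoxia)
    cohort = generate_survival_cohort(config, hypoxia, emt)

    for i, study in enumerate(studies, start=1):
        write_de_study(study, outdir, f"study{i}")
    hio.write_gmt([hypoxia, emt], outdir / "gene_sets.gmt", description="synthetic")
    hio.write_expression(cohort.expression, outdir / "cohort_expression.tsv")
    hio.write_clinical(cohort.clinical, outdir / "cohort_clinical.tsv")
    with open(outdir / "truth.txt", "w") as fh:
        for key, value in asdict(config).items():
            fh.write(f"{key}\t{value}\n")
        fh.write("planted_genes\t" + ",".join(cohort.truth["planted_genes"]) + "\n")
    logger.info("wrote synthetic inputs to %s", outdir)
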