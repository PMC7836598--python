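"""Clinical associations of the signature score.

Covers the downstream statistics of the pipeline: Kaplan-Meier /
log-rank comparison of the high and low score groups, univariate and
forward likelihood-ratio (LR) multivariate Cox proportional-hazards
models, Pearson and partial correlation between per-sample scores, and
chi-square contingency analysis of categorical annotations against the
score group.

Covariate coding follows clinical-table convention: the score enters as
the binary high/low indicator (low = reference); grade is coded with G2
and G3/G4 indicators against a G1 reference, stage with II and III/IV
indicators against stage I; residual tumor and gender are already 0/1.
Cox models are fit by partial-likelihood maximization with Efron tie
handling; confidence intervals are Wald at 95% throughout.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import logrank_test
from lifelines.utils import ConvergenceWarning

from .datatypes import ClinicalTable, GRADE_LEVELS, STAGE_LEVELS

logger = logging.getLogger(__name__)

__all__ = [
    "CoxResult",
    "LogRankResult",
    "CorrelationResult",
    "ContingencyResult",
    "km_logrank",
    "cox_univariate",
    "cox_multivariate_forward",
    "pearson",
    "partial_correlation",
    "correlation_analysis",
    "group_contingency",
    "cox_design",
]

_ENDPOINTS = {"os": ("os_time", "os_event"), "pfs": ("pfs_time", "pfs_event")}


# ------------------------------------------------------------- results


@dataclass
class CoxResult:
    """Hazard ratios with Wald 95% CIs and p-values.

    ``table`` has one row per model term with columns ``hazard_ratio``,
    ``ci_low``, ``ci_high``, ``p_value``. ``retained`` lists the
    covariates present in the model (for forward selection, those that
    entered). A non-empty ``flag`` marks an unreliable fit
    (non-convergence, monotone likelihood / separation, or too few
    events); flagged estimates should not be interpreted.
    """

    table: pd.DataFrame
    log_likelihood: float
    retained: list[str] = field(default_factory=list)
    flag: str | None = None
    endpoint: str = "os"

    @property
    def converged(self) -> bool:
        return self.flag is None


@dataclass
class LogRankResult:
    chi_square: float
    p_value: float
    group_sizes: dict[str, int]
    median_survival: dict[str, float]
    km_curves: pd.DataFrame
    endpoint: str = "os"


@dataclass
class CorrelationResult:
    pearson_r: float
    pearson_p: float
    partial_r: float
    partial_p: float
    controls: list[str] = field(default_factory=list)


@dataclass
class ContingencyResult:
    counts: pd.DataFrame
    proportions: pd.DataFrame
    chi_square: float
    p_value: float
    dropped_levels: list[str] = field(default_factory=list)


def _endpoint_columns(endpoint: str) -> tuple[str, str]:
    try:
        return _ENDPOINTS[endpoint.lower()]
    except KeyError:
        raise ValueError(f"unknown endpoint {endpoint!r}; expected one of {sorted(_ENDPOINTS)}")


# ---------------------------------------------------------- KM/log-rank


def km_logrank(
    clinical: ClinicalTable,
    groups: pd.Series,
    endpoint: str = "os",
) -> LogRankResult:
    """Two-group log-rank test plus Kaplan-Meier curves.

    ``groups`` is a high/low Series indexed by sample id; samples absent
    from either input are dropped by identifier intersection. The
    statistic is the classic observed-minus-expected sum over event
    times normalized by the hypergeometric variance, chi-square with
    1 df.
    """
    time_col, event_col = _endpoint_columns(endpoint)
    df = clinical.table
    common = df.index.intersection(groups.index)
    if len(common) < len(df) or len(common) < len(groups):
        logger.warning("km_logrank: %d sample(s) dropped by identifier intersection",
                       (len(df) - len(common)) + (len(groups) - len(common)))
    df = df.loc[common]
    g = groups.loc[common].astype(str)
    levels = sorted(g.unique())
    if len(levels) != 2:
        raise ValueError(f"need exactly two non-empty groups, got {levels}")
    if df[event_col].sum() == 0:
        raise ValueError("no events in either group; log-rank test undefined")

    masks = {lev: (g == lev).to_numpy() for lev in levels}
    res = logrank_test(
        df[time_col][masks[levels[0]]], df[time_col][masks[levels[1]]],
        event_observed_A=df[event_col][masks[levels[0]]],
        event_observed_B=df[event_col][masks[levels[1]]],
    )

    curves = []
    medians: dict[str, float] = {}
    for lev in levels:
        kmf = KaplanMeierFitter()
        kmf.fit(df[time_col][masks[lev]], df[event_col][masks[lev]], label=lev)
        medians[lev] = float(kmf.median_survival_time_)
        c = kmf.survival_function_.reset_index()
        c.columns = ["time", "survival"]
        c.insert(0, "group", lev)
        curves.append(c)

    return LogRankResult(
        chi_square=float(res.test_statistic),
        p_value=float(res.p_value),
        group_sizes={lev: int(masks[lev].sum()) for lev in levels},
        median_survival=medians,
        km_curves=pd.concat(curves, ignore_index=True),
        endpoint=endpoint,
    )


# ----------------------------------------------------------------- Cox


def cox_design(
    clinical: ClinicalTable,
    covariates: Sequence[str],
    groups: pd.Series | None = None,
) -> pd.DataFrame:
    """Design-matrix columns for the requested covariates.

    ``hypoxia_score`` (alias ``group``) requires ``groups`` and is coded
    1 for the high group; ``stage`` and ``grade`` expand to two
    indicator columns each against their lowest reference level; binary
    and numeric clinical columns pass through unchanged.
    """
    df = clinical.table
    cols: dict[str, pd.Series] = {}
    for cov in covariates:
        if cov in ("hypoxia_score", "group"):
            if groups is None:
                raise ValueError("a groups Series is required for the hypoxia_score covariate")
            aligned = groups.reindex(df.index)
            if aligned.isna().any():
                raise ValueError("groups do not cover every clinical sample")
            cols["hypoxia_score"] = (aligned.astype(str) == "high").astype(float)
        elif cov == "stage":
            for lev in STAGE_LEVELS[1:]:
                cols[f"stage_{lev}"] = (df["stage"] == lev).astype(float)
        elif cov == "grade":
            for lev in GRADE_LEVELS[1:]:
                cols[f"grade_{lev}"] = (df["grade"] == lev).astype(float)
        elif cov in df.columns and pd.api.types.is_numeric_dtype(df[cov]):
            cols[cov] = df[cov].astype(float)
        else:
            raise ValueError(f"cannot code covariate {cov!r}")
    return pd.DataFrame(cols, index=df.index)


def _term_to_columns(clinical: ClinicalTable, term: str) -> list[str]:
    if term == "stage":
        return [f"stage_{lev}" for lev in STAGE_LEVELS[1:]]
    if term == "grade":
        return [f"grade_{lev}" for lev in GRADE_LEVELS[1:]]
    if term == "group":
        return ["hypoxia_score"]
    return [term]


def _fit_cox(design: pd.DataFrame, time: pd.Series, event: pd.Series) -> tuple[CoxPHFitter | None, str | None]:
    """Fit a Cox model, returning the fitter and a reliability flag."""
    data = design.copy()
    data["_time"], data["_event"] = time, event
    cph = CoxPHFitter()
    flag: str | None = None
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            cph.fit(data, duration_col="_time", event_col="_event")
        except (ConvergenceError, np.linalg.LinAlgError, ValueError) as exc:
            return None, f"non_converged: {exc}"
    for w in caught:
        if issubclass(w.category, ConvergenceWarning):
            flag = f"unreliable: {w.message}"
            break
    if flag is None:
        se = cph.standard_errors_
        if not np.isfinite(se).all() or (se > 50).any():
            flag = "unreliable: effectively infinite standard error (separation)"
    n_events = int(event.sum())
    if flag is None and n_events < 2 * design.shape[1]:
        flag = f"unreliable: only {n_events} event(s) for {design.shape[1]} parameter(s)"
    return cph, flag


def _cox_table(cph: CoxPHFitter) -> pd.DataFrame:
    s = cph.summary
    table = pd.DataFrame({
        "hazard_ratio": s["exp(coef)"],
        "ci_low": s["exp(coef) lower 95%"],
        "ci_high": s["exp(coef) upper 95%"],
        "se": s["se(coef)"],
        "p_value": s["p"],
    })
    table.index.name = "term"
    return table


def cox_univariate(
    clinical: ClinicalTable,
    covariate: str,
    endpoint: str = "os",
    groups: pd.Series | None = None,
) -> CoxResult:
    """Single-covariate Cox proportional-hazards fit.

    A multi-level covariate (stage, grade) contributes one hazard-ratio
    row per non-reference level. Non-convergence or monotone likelihood
    yields a flagged result rather than silent numbers.
    """
    time_col, event_col = _endpoint_columns(endpoint)
    design = cox_design(clinical, [covariate], groups=groups)
    cph, flag = _fit_cox(design, clinical.table[time_col], clinical.table[event_col])
    if cph is None:
        empty = pd.DataFrame(columns=["hazard_ratio", "ci_low", "ci_high", "p_value"])
        return CoxResult(table=empty, log_likelihood=np.nan, retained=[], flag=flag, endpoint=endpoint)
    return CoxResult(
        table=_cox_table(cph),
        log_likelihood=float(cph.log_likelihood_),
        retained=[covariate],
        flag=flag,
        endpoint=endpoint,
    )


def cox_multivariate_forward(
    clinical: ClinicalTable,
    candidates: Sequence[str],
    endpoint: str = "os",
    entry_p: float = 0.05,
    groups: pd.Series | None = None,
) -> CoxResult:
    """Forward likelihood-ratio covariate selection for a Cox model.

    At each step the candidate whose LR test (twice the gain in partial
    log-likelihood over the current model, chi-square with df equal to
    the number of added parameters) has the smallest p-value enters,
    provided that p < ``entry_p``; selection stops when no candidate
    qualifies. An empty model (no candidate enters at step one) is a
    legitimate outcome and is returned as such.
    """
    if not 0 < entry_p <= 1:
        raise ValueError("entry_p must lie in (0, 1]")
    time_col, event_col = _endpoint_columns(endpoint)
    time, event = clinical.table[time_col], clinical.table[event_col]
    full_design = cox_design(clinical, list(candidates), groups=groups)

    remaining = list(candidates)
    selected: list[str] = []
    current_cols: list[str] = []
    current_ll: float | None = None  # None while the model is empty
    current_fit: CoxPHFitter | None = None
    flag: str | None = None

    while remaining:
        best: tuple[float, str, CoxPHFitter, float] | None = None  # (p, term, fit, ll)
        for term in remaining:
            cols = current_cols + _term_to_columns(clinical, term)
            cph, term_flag = _fit_cox(full_design[cols], time, event)
            if cph is None:
                logger.warning("forward selection: candidate %r failed to fit (%s)", term, term_flag)
                continue
            ll = float(cph.log_likelihood_)
            df_added = len(_term_to_columns(clinical, term))
            if current_ll is None:
                # vs the null model: lifelines' LR test of the fit itself
                lr = cph.log_likelihood_ratio_test()
                p = float(stats.chi2.sf(float(lr.test_statistic), df_added))
            else:
                p = float(stats.chi2.sf(2.0 * (ll - current_ll), df_added))
            if best is None or p < best[0]:
                best = (p, term, cph, ll)
        if best is None or best[0] >= entry_p:
            break
        p, term, cph, ll = best
        selected.append(term)
        remaining.remove(term)
        current_cols += _term_to_columns(clinical, term)
        current_ll, current_fit = ll, cph
        logger.info("forward selection (%s): entered %r at LR p = %.4g", endpoint, term, p)

    if current_fit is None:
        empty = pd.DataFrame(columns=["hazard_ratio", "ci_low", "ci_high", "p_value"])
        return CoxResult(table=empty, log_likelihood=np.nan, retained=[], flag=None, endpoint=endpoint)
    _, flag = _fit_cox(full_design[current_cols], time, event)
    return CoxResult(
        table=_cox_table(current_fit),
        log_likelihood=float(current_ll),
        retained=selected,
        flag=flag,
        endpoint=endpoint,
    )


# -------------------------------------------------------- correlations


def pearson(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Sample Pearson correlation with its two-sided t-transform p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d vectors of equal length")
    if x.size < 3:
        raise ValueError("need n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero-variance input; correlation undefined")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def _residualize(v: np.ndarray, controls: np.ndarray) -> np.ndarray:
    design = np.column_stack([np.ones(v.size), controls])
    coef, *_ = np.linalg.lstsq(design, v, rcond=None)
    return v - design @ coef


def partial_correlation(
    x: Sequence[float],
    y: Sequence[float],
    controls: Sequence[Sequence[float]] | np.ndarray | pd.DataFrame | None = None,
) -> tuple[float, float]:
    """Pearson correlation of x and y after removing linear control effects.

    Both variables are residualized on the controls (least squares with
    an intercept; ordinal controls should be coded as consecutive
    integers); the p-value uses the t transform with
    ``df = n - 2 - k`` for k controls. With no controls this reduces to
    :func:`pearson`. Collinear controls raise a ValueError naming the
    dependency.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if controls is None or (hasattr(controls, "__len__") and len(controls) == 0):
        return pearson(x, y)
    if isinstance(controls, pd.DataFrame):
        names = list(controls.columns)
        z = controls.to_numpy(dtype=float)
    else:
        z = np.asarray(controls, dtype=float)
        if z.ndim == 1:
            z = z[:, None]
        elif z.shape[0] != x.size and z.shape[1] == x.size:
            z = z.T  # accept a list of control vectors
        names = [f"control_{i}" for i in range(z.shape[1])]
    if z.shape[0] != x.size:
        raise ValueError("controls must have one row per sample")
    k = z.shape[1]
    n = x.size
    if n <= k + 2:
        raise ValueError(f"need n > {k + 2} samples for {k} controls")
    design = np.column_stack([np.ones(n), z])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError(f"collinear controls (including intercept): {names}")
    rx = _residualize(x, z)
    ry = _residualize(y, z)
    if np.allclose(rx, 0) or np.allclose(ry, 0):
        raise ValueError("a variable is fully explained by the controls; partial correlation undefined")
    r = float(np.corrcoef(rx, ry)[0, 1])
    df = n - 2 - k
    t = r * np.sqrt(df / max(1.0 - r ** 2, np.finfo(float).tiny))
    p = float(2.0 * stats.t.sf(abs(t), df=df))
    return r, p


def correlation_analysis(
    x: Sequence[float],
    y: Sequence[float],
    controls: pd.DataFrame | None = None,
) -> CorrelationResult:
    """Pearson plus partial correlation between two score vectors."""
    r, p = pearson(x, y)
    if controls is None or controls.shape[1] == 0:
        pr, pp = r, p
        names: list[str] = []
    else:
        pr, pp = partial_correlation(x, y, controls)
        names = list(controls.columns)
    return CorrelationResult(pearson_r=r, pearson_p=p, partial_r=pr, partial_p=pp, controls=names)


def ordinal_codes(clinical: ClinicalTable, columns: Sequence[str] = ("stage", "grade", "residual")) -> pd.DataFrame:
    """Integer-coded control variables (stage I=1..III/IV=3 etc.)."""
    df = clinical.table
    out: dict[str, pd.Series] = {}
    for col in columns:
        if col == "stage":
            out[col] = df["stage"].map({lev: i + 1 for i, lev in enumerate(STAGE_LEVELS)}).astype(float)
        elif col == "grade":
            out[col] = df["grade"].map({lev: i + 1 for i, lev in enumerate(GRADE_LEVELS)}).astype(float)
        else:
            out[col] = df[col].astype(float)
    return pd.DataFrame(out, index=df.index)


# -------------------------------------------------------- contingency


def group_contingency(groups: pd.Series, category: pd.Series) -> ContingencyResult:
    """Counts, within-group proportions and a chi-square independence test.

    Category levels with zero total count are dropped with a warning;
    the Pearson chi-square uses no continuity correction.
    """
    groups = groups.astype(str)
    category = category.reindex(groups.index)
    if category.isna().any():
        raise ValueError("category does not cover every grouped sample")
    counts = pd.crosstab(groups, category.astype(str))
    dropped = [lev for lev in counts.columns if counts[lev].sum() == 0]
    if dropped:
        logger.warning("dropping empty category level(s): %s", dropped)
        counts = counts.drop(columns=dropped)
    if counts.shape[1] < 2:
        raise ValueError("need at least two category levels with non-zero counts")
    chi2, p, _, _ = stats.chi2_contingency(counts.to_numpy(), correction=False)
    proportions = counts.div(counts.sum(axis=1), axis=0)
    return ContingencyResult(
        counts=counts,
        proportions=proportions,
        chi_square=float(chi2),
        p_value=float(p),
        dropped_levels=dropped,
    )
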