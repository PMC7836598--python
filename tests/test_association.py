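"""Survival and correlation statistics against independent oracles."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_clinical
from hyposig.datatypes import ClinicalTable
from hyposig.association import (
    cox_multivariate_forward,
    cox_univariate,
    correlation_analysis,
    group_contingency,
    km_logrank,
    ordinal_codes,
    partial_correlation,
    pearson,
)
from hyposig.simulate import SyntheticConfig, generate_gene_sets, generate_survival_cohort


# ------------------------------------------------------------ oracles


def logrank_oracle(times1, events1, times2, events2) -> float:
    """Hand-style log-rank chi-square: observed-minus-expected events in
    group 1 summed over event times, squared over the hypergeometric
    variance sum."""
    t1, e1 = np.asarray(times1, float), np.asarray(events1, int)
    t2, e2 = np.asarray(times2, float), np.asarray(events2, int)
    event_times = np.unique(np.concatenate([t1[e1 == 1], t2[e2 == 1]]))
    u, var = 0.0, 0.0
    for t in event_times:
        n1, n2 = (t1 >= t).sum(), (t2 >= t).sum()
        d1 = ((t1 == t) & (e1 == 1)).sum()
        d2 = ((t2 == t) & (e2 == 1)).sum()
        n, d = n1 + n2, d1 + d2
        u += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (n2 / n) * (n - d) / (n - 1)
    return u * u / var


def partial_r_oracle(x, y, z) -> float:
    """Partial correlation from the inverse of the full correlation matrix."""
    data = np.column_stack([x, y, np.asarray(z)])
    omega = np.linalg.inv(np.corrcoef(data, rowvar=False))
    return -omega[0, 1] / np.sqrt(omega[0, 0] * omega[1, 1])


def _clinical_from_survival(times, events) -> ClinicalTable:
    n = len(times)
    return ClinicalTable(pd.DataFrame({
        "sample_id": [f"P{i}" for i in range(n)],
        "os_time": times, "os_event": events,
        "pfs_time": times, "pfs_event": events,
        "stage": ["II"] * n, "grade": ["G2"] * n,
        "residual": [0] * n, "gender": [0] * n,
    }))


def _series(values, clinical):
    return pd.Series(values, index=clinical.table.index)


# ----------------------------------------------------------- log-rank


def test_logrank_identical_groups_zero():
    times = [1.0, 2.0, 3.0, 1.0, 2.0, 3.0]
    clin = _clinical_from_survival(times, [1] * 6)
    groups = _series(["high"] * 3 + ["low"] * 3, clin)
    res = km_logrank(clin, groups, "os")
    assert res.chi_square == pytest.approx(0.0, abs=1e-12)


def test_logrank_separated_groups_hand_value():
    """A {1,2,3} vs B {4,5,6}, all events: chi-square = 1.85^2 / 0.6775."""
    clin = _clinical_from_survival([1, 2, 3, 4, 5, 6], [1] * 6)
    groups = _series(["A"] * 3 + ["B"] * 3, clin)
    res = km_logrank(clin, groups, "os")
    assert res.chi_square == pytest.approx(1.85 ** 2 / 0.6775, rel=1e-10)
    assert res.chi_square == pytest.approx(
        logrank_oracle([1, 2, 3], [1] * 3, [4, 5, 6], [1] * 3), rel=1e-10)


@pytest.mark.parametrize("seed", range(8))
def test_logrank_matches_oracle_on_tiny_instances(seed):
    """On <=8 samples with ties and censoring the statistic equals the
    exhaustive observed-vs-expected computation."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(4, 9))
    times = rng.integers(1, 5, size=n).astype(float)
    events = rng.integers(0, 2, size=n)
    labels = rng.permutation(["high"] * (n // 2) + ["low"] * (n - n // 2))
    if events[labels == "high"].sum() == 0 and events[labels == "low"].sum() == 0:
        events[0] = 1
    clin = _clinical_from_survival(times, events)
    groups = _series(labels, clin)
    expected = logrank_oracle(times[labels == "high"], events[labels == "high"],
                              times[labels == "low"], events[labels == "low"])
    assert km_logrank(clin, groups, "os").chi_square == pytest.approx(expected, rel=1e-8)


def test_logrank_no_events_anywhere_is_error():
    clin = _clinical_from_survival([1, 2, 3, 4], [0, 0, 0, 0])
    with pytest.raises(ValueError, match="no events"):
        km_logrank(clin, _series(["high", "high", "low", "low"], clin), "os")


def test_km_curves_and_group_sizes(rng):
    clin = make_clinical(40, rng)
    groups = _series(["high"] * 20 + ["low"] * 20, clin)
    res = km_logrank(clin, groups, "pfs")
    assert res.group_sizes == {"high": 20, "low": 20}
    assert set(res.km_curves["group"]) == {"high", "low"}
    surv = res.km_curves.groupby("group")["survival"]
    assert (surv.first() == 1.0).all() and (res.km_curves["survival"].diff().dropna() <= 1.0).all()


# ---------------------------------------------------------------- Cox


def test_cox_degenerate_two_samples_flagged():
    clin = _clinical_from_survival([1.0, 2.0], [1, 0])
    res = cox_univariate(clin, "hypoxia_score", "os",
                         groups=_series(["high", "low"], clin))
    assert res.flag is not None


def test_cox_univariate_matches_lifelines_direct(rng):
    """The module's coding of the binary score group reproduces a direct
    lifelines fit on the 0/1 indicator."""
    from lifelines import CoxPHFitter
    clin = make_clinical(120, rng)
    groups = _series(rng.permutation(["high"] * 60 + ["low"] * 60), clin)
    res = cox_univariate(clin, "hypoxia_score", "os", groups=groups)
    df = clin.table.assign(ind=(groups == "high").astype(float))
    cph = CoxPHFitter().fit(df[["os_time", "os_event", "ind"]], "os_time", "os_event")
    assert res.table["hazard_ratio"].iloc[0] == pytest.approx(
        float(cph.summary["exp(coef)"].iloc[0]))


def test_forward_selection_keeps_planted_drops_noise():
    """With one prognostic candidate and one pure-noise candidate, forward
    LR selection retains the planted one in the clear majority of seeds."""
    kept_planted = kept_noise = 0
    n_seeds = 7
    for seed in range(n_seeds):
        cfg = SyntheticConfig(n_genes=80, hallmark_size=30, emt_size=30, n_planted=30,
                              cohort_size=500, log_hr=np.log(2), hazard_form="dichotomized",
                              seed=seed)
        h, e = generate_gene_sets(cfg)
        c = generate_survival_cohort(cfg, h, e)
        groups = pd.Series(np.where(c.latent_factor > 0, "high", "low"),
                           index=c.clinical.table.index)
        res = cox_multivariate_forward(c.clinical, ["hypoxia_score", "gender"], "os",
                                       entry_p=0.05, groups=groups)
        kept_planted += "hypoxia_score" in res.retained
        kept_noise += "gender" in res.retained
    assert kept_planted >= n_seeds - 1
    assert kept_noise <= 2


def test_forward_selection_entry_p_one_enters_all(rng):
    clin = make_clinical(100, rng)
    groups = _series(rng.permutation(["high"] * 50 + ["low"] * 50), clin)
    res = cox_multivariate_forward(clin, ["hypoxia_score", "gender", "residual"], "os",
                                  entry_p=0.999999, groups=groups)
    assert set(res.retained) == {"hypoxia_score", "gender", "residual"}


def test_forward_selection_empty_model_reported():
    """Covariates unrelated to a deterministic hazard should not enter."""
    rng = np.random.default_rng(0)
    clin = make_clinical(100, rng, os_time=rng.exponential(10, 100).tolist(),
                         os_event=[1] * 100)
    res = cox_multivariate_forward(clin, ["gender"], "os", entry_p=0.001)
    assert res.retained == [] and res.table.empty


def test_multi_level_covariate_rows():
    """Grade expands to G2 and G3/G4 hazard ratios against a G1 reference."""
    rng = np.random.default_rng(5)
    clin = make_clinical(150, rng)
    res = cox_univariate(clin, "grade", "os")
    assert list(res.table.index) == ["grade_G2", "grade_G3/G4"]


# -------------------------------------------------------- correlation


def test_pearson_hand_example():
    r, p = pearson([1, 2, 3, 4], [1, 3, 2, 4])
    assert r == pytest.approx(0.8)


def test_pearson_exact_linear_and_orthogonal():
    x = np.arange(10, dtype=float)
    r, _ = pearson(x, 2 * x + 1)
    assert r == pytest.approx(1.0)
    r0, _ = pearson([1, 2, 3, 4], [1, -1, -1, 1])  # exactly orthogonal to the trend
    assert r0 == pytest.approx(0.0, abs=1e-12)


def test_pearson_zero_variance_error():
    with pytest.raises(ValueError, match="zero-variance"):
        pearson([1, 1, 1, 1], [1, 2, 3, 4])


def test_partial_no_controls_reduces_to_pearson(rng):
    x, y = rng.normal(size=50), rng.normal(size=50)
    assert partial_correlation(x, y, None) == pearson(x, y)
    assert partial_correlation(x, y, []) == pearson(x, y)


@pytest.mark.parametrize("seed", range(6))
def test_partial_matches_inverse_correlation_oracle(seed):
    rng = np.random.default_rng(seed)
    k = int(rng.integers(1, 5))
    n = 60
    z = rng.normal(size=(n, k))
    x = z @ rng.normal(size=k) + rng.normal(size=n)
    y = z @ rng.normal(size=k) + rng.normal(size=n)
    r, _ = partial_correlation(x, y, z)
    assert r == pytest.approx(partial_r_oracle(x, y, z), abs=1e-8)


def test_partial_matches_pingouin():
    import pingouin as pg
    rng = np.random.default_rng(11)
    df = pd.DataFrame(rng.normal(size=(80, 3)), columns=["x", "y", "z"])
    df["y"] += 0.5 * df["z"]
    r, p = partial_correlation(df["x"], df["y"], df[["z"]])
    ref = pg.partial_corr(df, x="x", y="y", covar="z")
    assert r == pytest.approx(float(ref["r"].iloc[0]), abs=1e-10)
    assert p == pytest.approx(float(ref["p_val"].iloc[0]), abs=1e-10)


def test_partial_collinear_controls_error(rng):
    z = rng.normal(size=40)
    controls = np.column_stack([z, 2 * z])
    with pytest.raises(ValueError, match="collinear"):
        partial_correlation(rng.normal(size=40), rng.normal(size=40), controls)


def test_partial_y_equals_control_error(rng):
    z = rng.normal(size=40)
    with pytest.raises(ValueError, match="fully explained"):
        partial_correlation(rng.normal(size=40), z, z)


def test_correlation_analysis_bundles_both(rng):
    x, y = rng.normal(size=60), rng.normal(size=60)
    controls = pd.DataFrame({"c": rng.normal(size=60)})
    res = correlation_analysis(x, y + 0.5 * x, controls)
    assert -1 <= res.pearson_r <= 1 and -1 <= res.partial_r <= 1
    assert res.controls == ["c"]


# -------------------------------------------------------- contingency


def test_contingency_identical_distributions_zero():
    groups = pd.Series(["high"] * 10 + ["low"] * 10)
    cat = pd.Series((["A"] * 5 + ["B"] * 5) * 2)
    res = group_contingency(groups, cat)
    assert res.chi_square == pytest.approx(0.0)


def test_contingency_perfect_separation_hand_value():
    """2x2 table [[10,0],[0,10]]: every expected count is 5, so the
    chi-square is 4 * (5^2/5) = 20."""
    groups = pd.Series(["high"] * 10 + ["low"] * 10)
    cat = pd.Series(["A"] * 10 + ["B"] * 10)
    res = group_contingency(groups, cat)
    assert res.chi_square == pytest.approx(20.0)


def test_contingency_single_level_error():
    groups = pd.Series(["high", "low"])
    with pytest.raises(ValueError):
        group_contingency(groups, pd.Series(["A", "A"]))


def test_high_group_enriched_for_upper_grade():
    """The latent factor raises both the score and the odds of G3/G4, so
    the high-score group shows the larger upper-grade proportion."""
    from hyposig.scoring import signature_score
    cfg = SyntheticConfig(n_genes=200, hallmark_size=30, emt_size=30, n_planted=30,
                          cohort_size=400, seed=1)
    h, e = generate_gene_sets(cfg)
    c = generate_survival_cohort(cfg, h, e)
    groups = signature_score(c.expression, h)["group"]
    res = group_contingency(groups, c.clinical.table["grade"])
    assert res.proportions.loc["high", "G3/G4"] > res.proportions.loc["low", "G3/G4"]


def test_ordinal_codes_integer_coding(rng):
    clin = make_clinical(20, rng)
    codes = ordinal_codes(clin)
    assert set(codes["stage"]).issubset({1.0, 2.0, 3.0})
    assert set(codes["grade"]).issubset({1.0, 2.0, 3.0})
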