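"""Count/volume model correctness, contrasts, FDR, diagnostics."""

import numpy as np
import pandas as pd
import pytest
from statsmodels.stats.multitest import multipletests

from pvspatial.stat_models import (
    ModelSpec,
    apply_fdr,
    breusch_pagan,
    effect_size_label,
    fdr_adjust,
    fit_count_model,
    fit_log_volume_model,
    interaction_model,
    sequential_contrasts,
)
from pvspatial.synthetic import simulate_counts


def _covfree(outcome="count", family="NB", **kw):
    return ModelSpec(outcome, family, group="group", reference="A", covariates=(), **kw)


def test_nb_saturated_two_group_fit_reproduces_sample_mean_ratio():
    """With a saturated two-group NB model the fitted group means equal the
    sample means, so beta_exp is the raw ratio of means (here 4/2 = 2)."""
    df = pd.DataFrame({"count": [1, 2, 3] * 4 + [2, 4, 6] * 4, "group": ["A"] * 12 + ["B"] * 12})
    (res,) = fit_count_model(df, _covfree())
    assert res.term == "group[B]"
    assert res.beta_exp == pytest.approx(2.0, abs=1e-3)
    assert res.dispersion_alpha is not None and res.dispersion_alpha >= 0


def test_nb_null_effect_small_coefficient():
    df = simulate_counts(seed=5, n_per_group=300, rate_ratio=1.0)
    results = fit_count_model(
        df, ModelSpec("count", "NB", group="group", reference="A", covariates=("age", "sex"))
    )
    group = next(r for r in results if r.term == "group[B]")
    se = abs(group.coefficient - np.log(group.ci_low)) / 1.96 if group.ci_low > 0 else 1.0
    assert abs(group.coefficient) < 3 * max(se, 1e-6)
    assert group.ci_low <= group.beta_exp <= group.ci_high


def test_nb_rejects_noninteger_and_all_zero():
    df = pd.DataFrame({"count": [0.5, 1.2, 2.0, 1.0], "group": ["A", "A", "B", "B"]})
    with pytest.raises(ValueError, match="integer"):
        fit_count_model(df, _covfree())
    dfz = pd.DataFrame({"count": [0] * 10, "group": ["A", "B"] * 5})
    with pytest.raises(ValueError, match="all-zero"):
        fit_count_model(dfz, _covfree())
    (res,) = fit_count_model(dfz, _covfree(family="ZINB"))
    assert res.zero_inflation_pi == 1.0 and not res.converged


def test_zinb_recovers_rate_ratio_and_zero_share():
    rng = np.random.default_rng(42)
    n = 800
    g = np.repeat(["A", "B"], n // 2)
    mu = np.exp(1.6 + np.log(1.5) * (g == "B"))
    lam = rng.gamma(2.0, mu / 2.0)
    y = rng.poisson(lam)
    y[rng.random(n) < 0.6] = 0
    df = pd.DataFrame({"count": y, "group": g})
    results = fit_count_model(df, _covfree(family="ZINB"))
    group = next(r for r in results if r.term == "group[B]")
    assert group.converged
    assert group.beta_exp == pytest.approx(1.5, rel=0.25)
    assert group.zero_inflation_pi == pytest.approx(0.6, abs=0.07)


def test_log_volume_model_recovers_standardized_shift():
    rng = np.random.default_rng(7)
    n = 2000
    g = np.repeat(["A", "B"], n // 2)
    vol = np.exp(rng.normal(0, 1, n) + 0.5 * (g == "B"))
    df = pd.DataFrame({"vol": vol, "group": g})
    results, n_excl = fit_log_volume_model(
        df, ModelSpec("vol", "GAUSSIAN_LOG_OUTCOME", group="group", reference="A", covariates=())
    )
    assert n_excl == 0
    beta = next(r for r in results if r.term == "group[B]").std_beta
    # true standardized shift: 0.5 / sd(log outcome) with pooled sd ~ sqrt(1 + 0.25/4)
    assert beta == pytest.approx(0.5 / np.sqrt(1 + 0.0625), abs=0.1)


def test_log_volume_zero_handling():
    df = pd.DataFrame({"vol": [0.0, 1.0, 2.0, 3.0, 1.5, 0.8], "group": list("AABABB")})
    results, n_excl = fit_log_volume_model(
        df, ModelSpec("vol", "GAUSSIAN_LOG_OUTCOME", group="group", reference="A", covariates=())
    )
    assert n_excl == 1
    assert all(r.n_obs == 5 for r in results)


def test_interaction_requires_two_groups():
    df = pd.DataFrame({"count": [1, 2, 3, 4], "group": ["A"] * 4, "wml_log_volume": [1.0, 2, 3, 4]})
    with pytest.raises(ValueError, match="single group"):
        interaction_model(df, ModelSpec("count", "NB", group="group", reference="A",
                                        covariates=(), wml_log_volume="wml_log_volume"))


def test_interaction_recovers_slope_ratio():
    rng = np.random.default_rng(11)
    n = 3000
    g = np.repeat(["A", "B"], n // 2)
    w = rng.normal(0, 1, n)
    slope = np.where(g == "A", 0.2, 0.2 + np.log(1.5))
    mu = np.exp(2.0 + slope * w)
    y = rng.poisson(rng.gamma(4.0, mu / 4.0))
    df = pd.DataFrame({"count": y, "group": g, "wml_log_volume": w})
    results = interaction_model(
        df, ModelSpec("count", "NB", group="group", reference="A", covariates=(),
                      wml_log_volume="wml_log_volume")
    )
    inter = next(r for r in results if "wml_log_volume:" in r.term)
    assert inter.beta_exp == pytest.approx(1.5, rel=0.15)


def test_sequential_contrasts_identity_and_antisymmetry():
    df = simulate_counts(seed=9, n_per_group=200, rate_ratio=1.3).copy()
    df["group"] = np.where(df["group"] == "A", "CU", "MCI")
    ad = simulate_counts(seed=10, n_per_group=100, rate_ratio=1.6).query("group == 'B'").copy()
    ad["group"] = "AD"
    df = pd.concat([df, ad], ignore_index=True)
    spec = ModelSpec("count", "NB", group="group", reference="CU", covariates=("age", "sex"))
    contrasts = sequential_contrasts(df, spec, ["CU", "MCI", "AD"])
    assert [c.term for c in contrasts] == ["MCI vs CU", "AD vs MCI"]
    # pair including the reference equals the raw coefficient
    fit = fit_count_model(df, spec)
    raw = next(r for r in fit if r.term == "group[MCI]")
    assert contrasts[0].coefficient == pytest.approx(raw.coefficient, abs=1e-6)
    # antisymmetry
    rev = sequential_contrasts(df, spec, ["MCI", "CU"])
    assert rev[0].coefficient == pytest.approx(-contrasts[0].coefficient, abs=1e-5)
    with pytest.raises(ValueError, match="absent"):
        sequential_contrasts(df, spec, ["CU", "MCI", "XX"])


def test_fdr_stepup_hand_case_and_edge_cases():
    assert fdr_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04, 0.04, 0.04, 0.04])
    assert fdr_adjust([0.2, 0.2, 0.2]) == pytest.approx([0.2, 0.2, 0.2])
    assert fdr_adjust([0.7]) == pytest.approx([0.7])
    with pytest.raises(ValueError):
        fdr_adjust([0.5, 1.5])


def test_fdr_matches_statsmodels_on_random_vectors(rng):
    """Cross-check the step-up implementation against the reference
    implementation on many random p-vectors."""
    for _ in range(300):
        p = rng.random(rng.integers(1, 25))
        ours = fdr_adjust(p)
        theirs = multipletests(p, method="fdr_bh")[1]
        assert ours == pytest.approx(theirs, abs=1e-12)


def test_apply_fdr_within_family():
    from pvspatial.stat_models import GroupModelResult

    results = [
        GroupModelResult("a", 0, 0, 0, 0.01, family_id="f1"),
        GroupModelResult("b", 0, 0, 0, 0.04, family_id="f1"),
        GroupModelResult("c", 0, 0, 0, 0.04, family_id="f2"),
    ]
    adj = apply_fdr(results)
    assert adj[0].p_fdr == pytest.approx(0.02)
    assert adj[1].p_fdr == pytest.approx(0.04)
    assert adj[2].p_fdr == pytest.approx(0.04)  # alone in its family
    assert all(r.p_fdr >= r.p_value for r in adj)


def test_breusch_pagan_null_and_power(rng):
    n = 500
    x = rng.normal(size=n)
    X = np.column_stack([np.ones(n), x])
    # homoscedastic: p uniform-ish, statistic small
    resid = rng.normal(size=n)
    lm, p = breusch_pagan(resid, X)
    assert p > 0.001
    # variance proportional to predictor: p -> 0
    resid_het = rng.normal(size=n) * np.sqrt(np.exp(x))
    _, p_het = breusch_pagan(resid_het, X)
    assert p_het < 1e-4
    # constant squared residuals
    assert breusch_pagan(np.ones(20), np.column_stack([np.ones(20), np.arange(20.0)])) == (0.0, 1.0)
    with pytest.raises(ValueError, match="n > k"):
        breusch_pagan(np.ones(3), np.ones((3, 3)))


@pytest.mark.parametrize(
    "value, scale, label",
    [
        (0.54, "std_beta", "large"),
        (-0.05, "std_beta", "small"),
        (0.2, "std_beta", "medium"),
        (0.4, "std_beta", "medium-large"),
        (1.0, "beta_exp", "no change"),
        (0.8, "beta_exp", "decrease"),
        (1.3, "beta_exp", "increase"),
    ],
)
def test_effect_size_labels(value, scale, label):
    assert effect_size_label(value, scale) == label
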