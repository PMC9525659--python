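"""Quasi-Bayesian causal mediation: identities, calibration, determinism."""

import numpy as np
import pandas as pd
import pytest

from epimediate import cma, synthdata
from epimediate.cma import (
    fit_mediation_models,
    proportion_mediated,
    quasi_bayesian_cma,
    validate_at_second_timepoint,
)
from epimediate.dataio import DEFAULT_COVARIATES, ValidationError


def _series(x, name=None):
    return pd.Series(np.asarray(x, dtype=float), name=name)


def test_noiseless_chain_recovers_slopes_exactly(rng):
    # m = 2e + d with d orthogonal to [1, e] so a = 2 exactly and the
    # mediator-outcome design stays full rank; o = 3m exactly gives b = 3
    n = 50
    e = rng.normal(size=n)
    d = rng.normal(size=n)
    Z = np.column_stack([np.ones(n), e])
    d = d - Z @ np.linalg.lstsq(Z, d, rcond=None)[0]
    m = 2.0 * e + d
    o = 3.0 * m
    models = fit_mediation_models(_series(m), _series(o), _series(e))
    assert models.a == pytest.approx(2.0, abs=1e-10)
    assert models.b == pytest.approx(3.0, abs=1e-10)
    assert models.c_prime == pytest.approx(0.0, abs=1e-9)


def test_unrelated_mediator_gives_null_paths(rng):
    n = 4000
    e = _series(rng.normal(size=n))
    m = _series(rng.normal(size=n))
    o = _series(rng.normal(size=n))
    models = fit_mediation_models(m, o, e)
    assert abs(models.a) < 0.05 and abs(models.b) < 0.05
    est = quasi_bayesian_cma(models, nsims=1000, seed=4)
    assert abs(est.acme.estimate) < 0.01
    assert est.acme.p > 0.2


def test_sample_order_invariance(rng):
    n = 80
    e = rng.normal(size=n)
    m = 0.5 * e + rng.normal(size=n)
    o = -2.0 * m + rng.normal(size=n)
    m1 = fit_mediation_models(_series(m), _series(o), _series(e))
    perm = rng.permutation(n)
    m2 = fit_mediation_models(_series(m[perm]), _series(o[perm]), _series(e[perm]))
    np.testing.assert_allclose(m1.em_params, m2.em_params, rtol=1e-9)
    np.testing.assert_allclose(m1.mo_params, m2.mo_params, rtol=1e-9)


def test_te_equals_acme_plus_ade_and_pm_identity(rng):
    n = 300
    e = rng.integers(0, 2, n).astype(float)
    m = 0.5 + 0.03 * e + rng.normal(size=n) * 0.05
    o = 100 - 40 * m - 5 * e + rng.normal(size=n) * 5
    models = fit_mediation_models(_series(m), _series(o), _series(e))
    est = quasi_bayesian_cma(models, nsims=500, seed=1)
    assert est.te.estimate == pytest.approx(
        est.acme.estimate + est.ade.estimate, abs=1e-12
    )
    assert est.pm.estimate == pytest.approx(
        est.acme.estimate / est.te.estimate, abs=1e-12
    )
    for eff in (est.acme, est.ade, est.te):
        assert eff.ci_low <= eff.estimate <= eff.ci_high


def test_monte_carlo_mean_matches_product_of_normals(rng):
    # with independent model draws, E[a_s b_s] = a*b; check within 3 MC SE
    n = 500
    e = rng.normal(size=n)
    m = 0.4 * e + rng.normal(size=n)
    o = 1.5 * m + 0.5 * e + rng.normal(size=n)
    models = fit_mediation_models(_series(m), _series(o), _series(e))
    nsims = 20_000
    est_rng = np.random.default_rng(2)
    a_s = est_rng.multivariate_normal(
        models.em_params.to_numpy(), models.em_cov.to_numpy(), nsims
    )[:, models.em_params.index.get_loc("__exposure")]
    b_s = est_rng.multivariate_normal(
        models.mo_params.to_numpy(), models.mo_cov.to_numpy(), nsims
    )[:, models.mo_params.index.get_loc("__mediator")]
    prod = a_s * b_s
    se = prod.std() / np.sqrt(nsims)
    assert abs(prod.mean() - models.a * models.b) < 3 * se


def test_null_b_path_gives_null_acme():
    rng = np.random.default_rng(8)
    n = 20_000
    e = rng.integers(0, 2, n).astype(float)
    m = 0.5 + 0.05 * e + rng.normal(size=n) * 0.01
    o = 100.0 + rng.normal(size=n) * 0.1  # mediator unrelated to outcome
    models = fit_mediation_models(_series(m), _series(o), _series(e))
    est = quasi_bayesian_cma(models, nsims=1000, seed=3)
    assert abs(est.acme.estimate) < 0.005
    assert est.acme.p > 0.5


def test_fixed_seed_reproduces_cis_exactly(rng):
    n = 120
    e = rng.normal(size=n)
    m = 0.3 * e + rng.normal(size=n)
    o = -1.0 * m + rng.normal(size=n)
    models = fit_mediation_models(_series(m), _series(o), _series(e))
    e1 = quasi_bayesian_cma(models, nsims=800, seed=99)
    e2 = quasi_bayesian_cma(models, nsims=800, seed=99)
    assert e1 == e2
    with pytest.raises(ValidationError, match="nsims"):
        quasi_bayesian_cma(models, nsims=50, seed=0)


def test_acme_p_calibrated_under_exposure_permutation():
    # null a-path via exposure permutation, strong b-path: the ACME test
    # then inherits the a-test's size; p<0.05 rate within [0.03, 0.07]
    rng = np.random.default_rng(12)
    n, reps = 150, 1000
    m0 = 0.5 + rng.normal(size=n) * 0.05
    o0 = 100.0 - 60.0 * m0 + rng.normal(size=n) * 0.5
    rej = 0
    for rep in range(reps):
        e = rng.permutation(np.r_[np.ones(40), np.zeros(n - 40)])
        models = fit_mediation_models(_series(m0), _series(o0), _series(e))
        est = quasi_bayesian_cma(models, nsims=300, seed=rep)
        rej += est.acme.p < 0.05
    assert 0.03 <= rej / reps <= 0.07


@pytest.mark.parametrize(
    "acme, te, expected",
    [(5.0, 5.0, 1.0), (0.0, -3.0, 0.0), (-2.0, -10.0, 0.20)],
)
def test_proportion_mediated_values(acme, te, expected):
    assert proportion_mediated(acme, te) == pytest.approx(expected)


def test_proportion_mediated_undefined_at_zero_te():
    assert np.isnan(proportion_mediated(1.0, 0.0))


def test_bootstrap_engine_agrees_on_point_estimates(rng):
    n = 200
    e = rng.integers(0, 2, n).astype(float)
    m = 0.5 + 0.04 * e + rng.normal(size=n) * 0.05
    o = 100 - 30 * m - 4 * e + rng.normal(size=n) * 5
    models = fit_mediation_models(_series(m), _series(o), _series(e))
    qb = quasi_bayesian_cma(models, nsims=400, seed=5)
    bs = cma.bootstrap_cma(_series(m), _series(o), _series(e), nsims=200, seed=5)
    assert bs.acme.estimate == pytest.approx(qb.acme.estimate, abs=1e-12)
    assert bs.acme.ci_low < qb.acme.estimate < bs.acme.ci_high


def _two_timepoint_cohort(effect_t2, seed):
    cfg = synthdata.SimConfig(
        n_samples=600, n_probes=12, n_cmrs=1, cmr_size_range=(2, 2),
        n_true_mediators=1, n_em_only=0, effect_em=0.05, effect_mo=-60.0,
        effect_mo_t2=effect_t2, noise_sd_m=0.05, noise_sd_y=5.0,
        outcome_sd=7.0, frac_outcome_t1=1.0, frac_outcome_t2=1.0, seed=seed,
    )
    return cfg, *synthdata.simulate_cohort(cfg)


def test_validation_confirms_persistent_mediator():
    cfg, beta, pheno, truth = _two_timepoint_cohort(effect_t2=-60.0, seed=77)
    probe = truth.loc[truth["is_mediator"], "probe_id"].iloc[0]
    covs = list(DEFAULT_COVARIATES) + ["cotinine_ngml"]
    out = validate_at_second_timepoint(
        [probe], beta, pheno, "alcohol", "motor", covariates=covs, seed=1
    )
    assert out.loc[probe, "significant"]


def test_validation_rejects_timepoint1_only_effect():
    # planted at 6 months only: should rarely validate at 24 months
    hits = 0
    covs = list(DEFAULT_COVARIATES) + ["cotinine_ngml"]
    for seed in range(20):
        cfg, beta, pheno, truth = _two_timepoint_cohort(effect_t2=0.0, seed=200 + seed)
        probe = truth.loc[truth["is_mediator"], "probe_id"].iloc[0]
        out = validate_at_second_timepoint(
            [probe], beta, pheno, "alcohol", "motor", covariates=covs, seed=seed
        )
        hits += bool(out.loc[probe, "significant"])
    assert hits <= 2  # >=90% non-significant


def test_validation_empty_input_gives_empty_output(default_cohort):
    _, beta, pheno, _ = default_cohort
    out = validate_at_second_timepoint([], beta, pheno, "alcohol", "motor")
    assert out.empty
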