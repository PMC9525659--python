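"""Causal mediation analysis for a single mediator (linear–linear case).

Two OLS models — mediator ~ exposure + covariates and
outcome ~ mediator + exposure + covariates — define the average causal
mediation effect ACME = a·b, the average direct effect ADE = c', the total
effect TE = ACME + ADE, and the proportion mediated PM = ACME/TE (no
exposure–mediator interaction). Uncertainty comes from quasi-Bayesian
Monte-Carlo draws of the coefficient vectors from each model's asymptotic
multivariate normal; a nonparametric bootstrap engine (resample rows,
refit) is available as an alternative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .dataio import PhenotypeTable, BetaMatrix, ValidationError, outcome_column

__all__ = [
    "MediationModels",
    "Effect",
    "CmaEstimates",
    "fit_mediation_models",
    "quasi_bayesian_cma",
    "bootstrap_cma",
    "proportion_mediated",
    "validate_at_second_timepoint",
]


@dataclass
class MediationModels:
    """Fitted coefficient vectors and covariances of the two linear models."""

    em_params: pd.Series
    em_cov: pd.DataFrame
    mo_params: pd.Series
    mo_cov: pd.DataFrame
    n: int
    exposure_term: str = "__exposure"
    mediator_term: str = "__mediator"

    def __post_init__(self) -> None:
        for cov in (self.em_cov, self.mo_cov):
            c = cov.to_numpy()
            if not np.allclose(c, c.T, atol=1e-10):
                raise ValidationError("coefficient covariance is not symmetric")
            if np.linalg.eigvalsh((c + c.T) / 2).min() < -1e-8:
                raise ValidationError(
                    "coefficient covariance is not positive semidefinite"
                )

    @property
    def a(self) -> float:
        """Exposure slope of the E-M model."""
        return float(self.em_params[self.exposure_term])

    @property
    def b(self) -> float:
        """Mediator slope of the M-O model."""
        return float(self.mo_params[self.mediator_term])

    @property
    def c_prime(self) -> float:
        """Exposure slope of the M-O model (the direct effect)."""
        return float(self.mo_params[self.exposure_term])


def _ols(y: pd.Series, X: pd.DataFrame):
    arr = X.to_numpy()
    if np.linalg.matrix_rank(arr) < arr.shape[1]:
        raise ValidationError("rank-deficient mediation design")
    return sm.OLS(y, X).fit()


def fit_mediation_models(
    mediator: pd.Series,
    outcome: pd.Series,
    exposure: pd.Series,
    covariates: pd.DataFrame | None = None,
) -> MediationModels:
    """Fit the E-M and M-O OLS models on complete cases."""
    df = pd.DataFrame(
        {
            "__mediator": mediator.astype(float),
            "__outcome": outcome.astype(float),
            "__exposure": exposure.astype(float),
        }
    )
    if covariates is not None and covariates.shape[1] > 0:
        df = df.join(covariates.astype(float))
    df = df.dropna()
    k = 2 + (0 if covariates is None else covariates.shape[1])
    if len(df) < k + 2:
        raise ValidationError(f"only {len(df)} complete cases for {k} parameters")
    covs = df.drop(columns=["__mediator", "__outcome", "__exposure"])
    Xem = sm.add_constant(
        pd.concat([df[["__exposure"]], covs], axis=1), has_constant="add"
    )
    em = _ols(df["__mediator"], Xem)
    Xmo = sm.add_constant(
        pd.concat([df[["__mediator", "__exposure"]], covs], axis=1),
        has_constant="add",
    )
    mo = _ols(df["__outcome"], Xmo)
    return MediationModels(
        em_params=em.params,
        em_cov=em.cov_params(),
        mo_params=mo.params,
        mo_cov=mo.cov_params(),
        n=len(df),
    )


@dataclass(frozen=True)
class Effect:
    """Point estimate with a 95% Monte-Carlo interval and two-sided p."""

    estimate: float
    ci_low: float
    ci_high: float
    p: float


@dataclass
class CmaEstimates:
    """ACME, ADE, TE and PM with Monte-Carlo intervals and p-values."""

    acme: Effect
    ade: Effect
    te: Effect
    pm: Effect
    nsims: int
    seed: int
    pm_discarded_frac: float = 0.0
    pm_unstable: bool = False

    @property
    def significant_mediation(self) -> bool:
        """The reporting criterion: ACME p < 0.05 and TE p < 0.05."""
        return self.acme.p < 0.05 and self.te.p < 0.05

    def to_row(self) -> dict:
        row: dict = {}
        for name, eff in (
            ("acme", self.acme),
            ("ade", self.ade),
            ("te", self.te),
            ("pm", self.pm),
        ):
            row[name] = eff.estimate
            row[f"{name}_ci_low"] = eff.ci_low
            row[f"{name}_ci_high"] = eff.ci_high
            row[f"{name}_p"] = eff.p
        row["nsims"] = self.nsims
        row["seed"] = self.seed
        return row


def _mc_p(draws: np.ndarray) -> float:
    n = draws.size
    lo = np.mean(draws <= 0)
    hi = np.mean(draws >= 0)
    return float(max(2.0 * min(lo, hi), 2.0 / n))


def _summarize(
    acme_s: np.ndarray,
    ade_s: np.ndarray,
    acme_pt: float,
    ade_pt: float,
    nsims: int,
    seed: int,
) -> CmaEstimates:
    te_s = acme_s + ade_s
    te_pt = acme_pt + ade_pt
    q = (2.5, 97.5)

    def eff(draws: np.ndarray, point: float) -> Effect:
        lo, hi = np.percentile(draws, q)
        return Effect(point, float(lo), float(hi), _mc_p(draws))

    pm_pt = proportion_mediated(acme_pt, te_pt)
    sign = np.sign(te_pt) if te_pt != 0 else 1.0
    keep = np.sign(te_s) == sign
    discarded = 1.0 - keep.mean() if te_s.size else 1.0
    if keep.sum() >= 2:
        pm_draws = acme_s[keep] / te_s[keep]
        lo, hi = np.percentile(pm_draws, q)
        pm = Effect(pm_pt, float(lo), float(hi), _mc_p(pm_draws))
    else:
        pm = Effect(pm_pt, np.nan, np.nan, np.nan)
    return CmaEstimates(
        acme=eff(acme_s, acme_pt),
        ade=eff(ade_s, ade_pt),
        te=eff(te_s, te_pt),
        pm=pm,
        nsims=nsims,
        seed=seed,
        pm_discarded_frac=float(discarded),
        pm_unstable=discarded > 0.10,
    )


def quasi_bayesian_cma(
    models: MediationModels, nsims: int = 1000, seed: int = 0
) -> CmaEstimates:
    """Quasi-Bayesian Monte-Carlo mediation inference.

    Draws ``nsims`` coefficient vectors from each model's asymptotic
    multivariate normal; per draw ACME_s = a_s·b_s, ADE_s = c'_s,
    TE_s = ACME_s + ADE_s. Point estimates use the fitted coefficients; CIs
    are the 2.5/97.5 percentiles; p-values are two-sided Monte-Carlo tail
    probabilities floored at 2/nsims. PM draws are restricted to draws whose
    TE sign matches the TE point estimate (flagged when >10% are discarded).
    """
    if nsims < 100:
        raise ValidationError("nsims < 100 gives unstable percentile intervals")
    rng = np.random.default_rng(seed)
    em_draws = rng.multivariate_normal(
        models.em_params.to_numpy(), models.em_cov.to_numpy(), size=nsims,
        method="svd",
    )
    mo_draws = rng.multivariate_normal(
        models.mo_params.to_numpy(), models.mo_cov.to_numpy(), size=nsims,
        method="svd",
    )
    ia = models.em_params.index.get_loc(models.exposure_term)
    ib = models.mo_params.index.get_loc(models.mediator_term)
    ic = models.mo_params.index.get_loc(models.exposure_term)
    acme_s = em_draws[:, ia] * mo_draws[:, ib]
    ade_s = mo_draws[:, ic]
    return _summarize(
        acme_s, ade_s, models.a * models.b, models.c_prime, nsims, seed
    )


def bootstrap_cma(
    mediator: pd.Series,
    outcome: pd.Series,
    exposure: pd.Series,
    covariates: pd.DataFrame | None = None,
    nsims: int = 1000,
    seed: int = 0,
) -> CmaEstimates:
    """Nonparametric bootstrap engine: resample rows, refit, percentile CIs."""
    if nsims < 100:
        raise ValidationError("nsims < 100 gives unstable percentile intervals")
    models = fit_mediation_models(mediator, outcome, exposure, covariates)
    df = pd.DataFrame(
        {"m": mediator.astype(float), "y": outcome.astype(float),
         "e": exposure.astype(float)}
    )
    if covariates is not None and covariates.shape[1] > 0:
        df = df.join(covariates.astype(float))
    df = df.dropna().reset_index(drop=True)
    rng = np.random.default_rng(seed)
    n = len(df)
    acme_s = np.empty(nsims)
    ade_s = np.empty(nsims)
    cov_cols = [c for c in df.columns if c not in ("m", "y", "e")]
    for s in range(nsims):
        idx = rng.integers(0, n, n)
        boot = df.iloc[idx]
        try:
            m = fit_mediation_models(
                boot["m"], boot["y"], boot["e"],
                boot[cov_cols] if cov_cols else None,
            )
        except ValidationError:
            acme_s[s], ade_s[s] = np.nan, np.nan
            continue
        acme_s[s] = m.a * m.b
        ade_s[s] = m.c_prime
    ok = np.isfinite(acme_s) & np.isfinite(ade_s)
    return _summarize(
        acme_s[ok], ade_s[ok], models.a * models.b, models.c_prime, nsims, seed
    )


def proportion_mediated(acme: float, te: float) -> float:
    """PM = ACME/TE at the point-estimate level; NaN when TE = 0."""
    if te == 0:
        return float("nan")
    return acme / te


def validate_at_second_timepoint(
    significant_probes: list[str],
    beta: BetaMatrix,
    phenotypes: PhenotypeTable,
    exposure: str,
    domain: str,
    covariates: list[str] | None = None,
    timepoint: str = "24mo",
    nsims: int = 1000,
    seed: int = 0,
    min_n: int = 30,
) -> pd.DataFrame:
    """Re-test 6-month mediators against the 24-month outcome.

    Reruns the two-model fit and quasi-Bayesian inference per probe on the
    second-timepoint outcome; a probe validates when ACME p < 0.05 and
    TE p < 0.05. Returns one row per probe (empty input, empty output).
    """
    rows = []
    if not significant_probes:
        return pd.DataFrame(
            columns=["probe_id", "acme", "acme_p", "te", "te_p", "significant"]
        ).set_index("probe_id")
    pdata = phenotypes.data
    common = pdata.index.intersection(beta.sample_ids)
    y = pdata.loc[common, outcome_column(domain, timepoint)]
    n_avail = int(y.notna().sum())
    if n_avail == 0:
        raise ValidationError("no overlapping samples with second-timepoint outcome")
    if n_avail < min_n:
        raise ValidationError(
            f"only {n_avail} samples with {timepoint} outcome (< {min_n})"
        )
    e = pdata.loc[common, exposure]
    covs = pdata.loc[common, list(covariates)] if covariates else None
    ss = np.random.SeedSequence(seed)
    for probe, child in zip(
        significant_probes, ss.spawn(len(significant_probes))
    ):
        m = beta.values.loc[common, probe]
        models = fit_mediation_models(m, y, e, covs)
        est = quasi_bayesian_cma(
            models, nsims=nsims, seed=int(child.generate_state(1)[0] % 2**31)
        )
        rows.append(
            {
                "probe_id": probe,
                "acme": est.acme.estimate,
                "acme_p": est.acme.p,
                "te": est.te.estimate,
                "te_p": est.te.p,
                "significant": est.significant_mediation,
            }
        )
    return pd.DataFrame(rows).set_index("probe_id")
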