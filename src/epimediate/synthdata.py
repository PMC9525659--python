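"""Synthetic birth-cohort generator for methylation mediation analyses.

Emulates the statistical structure the downstream pipeline assumes: a
samples × probes beta matrix with co-methylated region (CMR) block
correlation, a phenotype table with a cotinine-defined smoking gradient, a
binary alcohol exposure, maternal/perinatal covariates, compositional
cell-type proportions, genetic PCs and Bayley-scale outcomes at two
timepoints, plus a ground-truth ledger of the planted
exposure → methylation → outcome paths so parameter recovery is testable.

The default configuration reproduces the study conditions the package is
designed around: n = 262 samples, an active-smoker prevalence of 29.77%
(cotinine ≥ 500 ng/ml), an alcohol-exposure prevalence of 17.18%, Bayley
composites centred near 100 (SD ≈ 15) with outcomes observed for 112/262
samples at 6 months and 184/262 at 24 months, and negative planted indirect
paths (a > 0 on the beta scale, b < 0 on the Bayley scale) on the motor
domain with per-mediator indirect effects of a·b = −1.5 score units.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .dataio import (
    BAYLEY_DOMAINS,
    CELL_TYPES,
    GENETIC_PCS,
    TIMEPOINTS,
    BetaMatrix,
    EwasWeights,
    PhenotypeTable,
    outcome_column,
)

__all__ = ["SimConfig", "ConfigError", "simulate_cohort", "simulate_ewas_weights"]


class ConfigError(ValueError):
    """The simulation configuration is internally inconsistent."""


#: Dirichlet concentrations for the 7 cord-blood cell types; granulocytes
#: dominate, as in cord-blood reference panels.
_CELL_ALPHA = np.array([6.0, 4.0, 2.0, 3.0, 3.0, 27.0, 4.0])

#: Location shifts (relative to outcome_mean) per timepoint/domain, matching
#: the ordering of median Bayley composites by domain and age: scores are
#: higher at 6 months than at 24 months except the socioemotional domain.
_DOMAIN_SHIFT = {
    "6mo": {
        "cognitive": 3.0,
        "language": 1.0,
        "motor": 9.0,
        "adaptive": 1.0,
        "socioemotional": 13.0,
    },
    "24mo": {
        "cognitive": -15.0,
        "language": -17.0,
        "motor": -8.0,
        "adaptive": -16.0,
        "socioemotional": 16.0,
    },
}

#: Within-CMR and between-feature genomic gaps (bp); the between gap is far
#: larger than any reasonable CMR max-gap so blocks are unambiguous.
_WITHIN_CMR_GAP = 200
_BETWEEN_GAP = 10_000


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic cohort.

    Effect sizes follow the linear mediation model: ``effect_em`` is the
    exposure → methylation slope in beta units per exposure unit (the *a*
    path), ``effect_mo`` the methylation → outcome slope in Bayley score
    units per beta unit (the *b* path), so each planted mediator carries an
    indirect effect a·b.
    """

    n_samples: int = 262
    n_probes: int = 1000
    n_cmrs: int = 100
    cmr_size_range: tuple[int, int] = (2, 5)
    cmr_within_cor: float = 0.7
    prev_active_smoker: float = 0.2977
    prev_alcohol: float = 0.1718
    effect_em: float = 0.05
    effect_mo: float = -30.0
    effect_direct: float = -6.0
    n_true_mediators: int = 20
    n_em_only: int = 10
    outcome_mean: float = 100.0
    outcome_sd: float = 15.0
    noise_sd_m: float = 0.05
    noise_sd_y: float = 12.0
    seed: int = 0
    planted_exposure: Literal["alcohol", "smoking"] = "alcohol"
    target_domain: str = "motor"
    effect_mo_t2: float = 0.0
    frac_outcome_t1: float = 112 / 262
    frac_outcome_t2: float = 184 / 262

    def __post_init__(self) -> None:
        for name in ("n_samples", "n_probes", "n_cmrs"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        lo, hi = self.cmr_size_range
        if lo > hi:
            raise ConfigError("cmr_size_range min exceeds max")
        if lo < 2:
            raise ConfigError("CMRs need at least 2 probes")
        for name in (
            "prev_active_smoker",
            "prev_alcohol",
            "frac_outcome_t1",
            "frac_outcome_t2",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be a proportion in [0, 1]")
        if not 0.0 <= self.cmr_within_cor < 1.0:
            raise ConfigError("cmr_within_cor must lie in [0, 1)")
        if self.n_true_mediators < 0 or self.n_em_only < 0:
            raise ConfigError("planted probe counts must be nonnegative")
        if self.n_true_mediators > self.n_probes:
            raise ConfigError("n_true_mediators exceeds n_probes")
        if self.target_domain not in BAYLEY_DOMAINS:
            raise ConfigError(f"unknown target domain {self.target_domain!r}")
        n_block = self.n_cmrs * hi
        if self.n_cmrs * lo > self.n_probes:
            raise ConfigError("CMR blocks would exceed n_probes")
        for name in ("noise_sd_m", "noise_sd_y", "outcome_sd"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be nonnegative")


def _simulate_phenotypes(cfg: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = cfg.n_samples
    # smoking: class drawn first so the 500 ng/ml cut matches the prevalence;
    # among non-active samples the passive fraction follows the cohort split
    # (47.7% passive vs 22.5% non of the full sample).
    active = rng.random(n) < cfg.prev_active_smoker
    passive_frac = 0.4771 / (0.4771 + 0.2252)
    passive = ~active & (rng.random(n) < passive_frac)
    cot = np.empty(n)
    non = ~active & ~passive
    cot[non] = np.minimum(np.exp(rng.normal(math.log(3.0), 0.8, non.sum())), 9.9)
    cot[passive] = np.clip(
        np.exp(rng.normal(math.log(48.0), 0.9, passive.sum())), 10.0, 499.0
    )
    cot[active] = 500.0 * np.exp(np.abs(rng.normal(0.0, 0.7, active.sum())))
    alcohol = (rng.random(n) < cfg.prev_alcohol).astype(int)

    df = pd.DataFrame(
        {
            "sample_id": [f"S{i:04d}" for i in range(n)],
            "cotinine_ngml": cot,
            "alcohol": alcohol,
            "maternal_age": np.clip(np.round(rng.normal(26.5, 5.5, n)), 18, 45),
            "gestational_age": np.clip(rng.normal(39.0, 1.5, n), 30.0, 42.0),
            "hiv": (rng.random(n) < 0.244).astype(int),
            "depression": (rng.random(n) < 0.252).astype(int),
            "distress": (rng.random(n) < 0.302).astype(int),
            "ses": rng.integers(0, 4, n),
            "child_sex": (rng.random(n) < 0.557).astype(int),
        }
    )
    props = rng.dirichlet(_CELL_ALPHA, size=n)
    for j, ct in enumerate(CELL_TYPES):
        df[ct] = props[:, j]
    for pc in GENETIC_PCS:
        df[pc] = rng.normal(0.0, 1.0, n)
    return df


def _exposure_dose(cfg: SimConfig, pheno: pd.DataFrame) -> np.ndarray:
    """Exposure variable carrying the planted effects (one unit = one dose)."""
    if cfg.planted_exposure == "alcohol":
        return pheno["alcohol"].to_numpy(dtype=float)
    logc = np.log1p(pheno["cotinine_ngml"].to_numpy(dtype=float))
    sd = logc.std(ddof=0)
    return (logc - logc.mean()) / (sd if sd > 0 else 1.0)


def _covariate_component(
    cfg: SimConfig, pheno: pd.DataFrame, rng: np.random.Generator
) -> np.ndarray:
    raw = (
        0.15 * (pheno["maternal_age"].to_numpy(dtype=float) - 26.5)
        + 0.8 * (pheno["gestational_age"].to_numpy(dtype=float) - 39.0)
        - 2.0 * pheno["hiv"].to_numpy(dtype=float)
        - 2.5 * pheno["depression"].to_numpy(dtype=float)
        - 1.5 * pheno["distress"].to_numpy(dtype=float)
        + 1.8 * (pheno["ses"].to_numpy(dtype=float) - 1.5)
        + 1.0 * pheno["child_sex"].to_numpy(dtype=float)
        + 0.5 * pheno[list(GENETIC_PCS)].to_numpy(dtype=float).sum(axis=1)
    )
    # scale the systematic part so the null outcome SD approximates outcome_sd
    nominal_sd = 3.6
    target = math.sqrt(max(cfg.outcome_sd**2 - cfg.noise_sd_y**2, 0.0))
    return raw * (target / nominal_sd)


def simulate_cohort(
    config: SimConfig,
) -> tuple[BetaMatrix, PhenotypeTable, pd.DataFrame]:
    """Generate a synthetic cohort plus its ground-truth ledger.

    Returns
    -------
    beta, phenotypes, truth
        ``truth`` has one row per probe: ``probe_id``, planted slopes
        ``true_a`` and ``true_b``, ``true_acme`` = a·b, and ``is_mediator``
        (both slopes nonzero). Identical configs (same seed) produce
        bit-identical output.

    Notes
    -----
    Probes are laid on one synthetic chromosome: CMR blocks first (within-
    block gap 200 bp, equicorrelated logit-normal betas), then singleton
    probes at 10 kb gaps. Planted effect probes are singletons; their effect
    is an additive a·E shift on the beta scale so two-stage least squares
    recovers the planted slopes without transformation bias. Betas are
    clipped to [0.001, 0.999].
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    pheno = _simulate_phenotypes(cfg, rng)
    n = cfg.n_samples
    dose = _exposure_dose(cfg, pheno)

    # --- probe layout -----------------------------------------------------
    lo, hi = cfg.cmr_size_range
    sizes = []
    total = 0
    for _ in range(cfg.n_cmrs):
        k = int(rng.integers(lo, hi + 1))
        if total + k > cfg.n_probes:
            break
        sizes.append(k)
        total += k
    n_block = sum(sizes)
    n_single = cfg.n_probes - n_block
    n_planted = cfg.n_true_mediators + cfg.n_em_only
    if n_planted > n_single:
        raise ConfigError(
            f"{n_planted} planted probes need {n_planted} singleton probes, "
            f"but only {n_single} remain outside CMR blocks"
        )

    probe_ids = [f"cg{i:06d}" for i in range(cfg.n_probes)]
    pos = np.empty(cfg.n_probes, dtype=int)
    cur = 1_000
    i = 0
    for k in sizes:
        for j in range(k):
            pos[i] = cur
            cur += _WITHIN_CMR_GAP
            i += 1
        cur += _BETWEEN_GAP
    while i < cfg.n_probes:
        pos[i] = cur
        cur += _BETWEEN_GAP
        i += 1
    annot = pd.DataFrame(
        {"chrom": "chrS", "pos": pos}, index=pd.Index(probe_ids, name="probe_id")
    )

    # --- beta values ------------------------------------------------------
    beta = np.empty((n, cfg.n_probes))
    rho = cfg.cmr_within_cor
    sigma_logit = 4.0 * cfg.noise_sd_m  # d(expit)/dx = 1/4 at beta = 0.5
    i = 0
    for k in sizes:
        mu = logit(rng.uniform(0.25, 0.75))
        shared = rng.normal(0.0, 1.0, n)[:, None]
        eps = rng.normal(0.0, 1.0, (n, k))
        latent = mu + sigma_logit * (
            math.sqrt(rho) * shared + math.sqrt(1.0 - rho) * eps
        )
        beta[:, i : i + k] = expit(latent)
        i += k
    if cfg.n_probes > i:
        mu_s = logit(rng.uniform(0.35, 0.65, cfg.n_probes - i))
        latent = mu_s[None, :] + sigma_logit * rng.normal(
            0.0, 1.0, (n, cfg.n_probes - i)
        )
        beta[:, i:] = expit(latent)

    # planted probes: the first singletons after the blocks
    true_a = np.zeros(cfg.n_probes)
    true_b = np.zeros(cfg.n_probes)
    med_idx = np.arange(n_block, n_block + cfg.n_true_mediators)
    em_idx = np.arange(
        n_block + cfg.n_true_mediators, n_block + cfg.n_true_mediators + cfg.n_em_only
    )
    true_a[med_idx] = cfg.effect_em
    true_b[med_idx] = cfg.effect_mo
    true_a[em_idx] = cfg.effect_em
    planted = np.concatenate([med_idx, em_idx])
    if len(planted):
        beta[:, planted] += dose[:, None] * true_a[planted][None, :]
    np.clip(beta, 0.001, 0.999, out=beta)

    # --- outcomes ---------------------------------------------------------
    cov_comp = _covariate_component(cfg, pheno, rng)
    for tp in TIMEPOINTS:
        b_tp = cfg.effect_mo if tp == "6mo" else cfg.effect_mo_t2
        if len(med_idx):
            med = beta[:, med_idx]
            # centered so the mediated term shifts slopes, not the intercept
            mediated = (med - med.mean(axis=0)).sum(axis=1) * b_tp
        else:
            mediated = np.zeros(n)
        frac = cfg.frac_outcome_t1 if tp == "6mo" else cfg.frac_outcome_t2
        n_obs = int(round(frac * n))
        observed = np.zeros(n, dtype=bool)
        observed[rng.choice(n, size=n_obs, replace=False)] = True
        for domain in BAYLEY_DOMAINS:
            y = (
                cfg.outcome_mean
                + _DOMAIN_SHIFT[tp][domain]
                + cov_comp
                + rng.normal(0.0, cfg.noise_sd_y, n)
            )
            if domain == cfg.target_domain:
                y = y + mediated + cfg.effect_direct * dose
            y = np.clip(y, 40.0, 160.0)
            y[~observed] = np.nan
            pheno[outcome_column(domain, tp)] = y

    truth = pd.DataFrame(
        {
            "probe_id": probe_ids,
            "true_a": true_a,
            "true_b": true_b,
            "true_acme": true_a * true_b,
            "is_mediator": (true_a != 0) & (true_b != 0),
        }
    )
    bm = BetaMatrix(
        pd.DataFrame(beta, index=pd.Index(pheno["sample_id"], name="sample_id"),
                     columns=probe_ids),
        annot,
    )
    return bm, PhenotypeTable(pheno), truth


def simulate_ewas_weights(
    truth: pd.DataFrame,
    config: SimConfig,
    em_only_fraction: float = 1.0,
) -> EwasWeights:
    """Emulate external EWAS summary statistics aligned with the truth table.

    Probes with a planted exposure → methylation slope (mediators always;
    E-M-only probes with probability ``em_only_fraction``) receive effect
    sizes correlated with ``true_a`` and extreme p-values (~1e-28 to 1e-32);
    null probes receive near-zero effects and Uniform(0, 1) p-values.
    Deterministic for a given config seed.
    """
    if not 0.0 <= em_only_fraction <= 1.0:
        raise ConfigError("em_only_fraction must lie in [0, 1]")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7151]))
    a = truth["true_a"].to_numpy(dtype=float)
    b = truth["true_b"].to_numpy(dtype=float)
    m = len(truth)
    signal = a != 0
    em_only = signal & (b == 0)
    drop = em_only & (rng.random(m) >= em_only_fraction)
    signal = signal & ~drop

    effect = rng.normal(0.0, 0.002, m)
    effect[signal] = a[signal] * rng.normal(1.0, 0.15, signal.sum())
    p = rng.uniform(0.0, 1.0, m)
    p[p == 0.0] = np.nextafter(0.0, 1.0)
    p[signal] = 10.0 ** (-rng.uniform(28.0, 32.0, signal.sum()))
    se = np.abs(effect) / 12.0 + 1e-3
    return EwasWeights(
        pd.DataFrame(
            {
                "probe_id": truth["probe_id"].to_numpy(),
                "effect": effect,
                "se": se,
                "p": p,
            }
        )
    )
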