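"""High-dimensional mediation screening: DACT and a HIMA-style procedure.

Two screens over a per-probe mediation scan:

* DACT — a composite-null test. The null of no mediation decomposes into
  three cases (a=0,b≠0; a≠0,b=0; a=0,b=0). The case proportions are
  estimated from the E-M and M-O z-scores with Efron's empirical null, and
  the DACT p-value is the case-probability-weighted sum of the three
  case-specific p-values.
* HIMA-style — sure independence screening keeps the ceil(n/log n) probes
  with the largest M-O effect, the minimax concave penalty (MCP) prunes
  them in a joint outcome regression, and a joint-significance (max-p) test
  is applied to the survivors.

Both are followed by Benjamini–Hochberg FDR adjustment.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.stats.multitest import multipletests

from .assoc import MediationScan
from .dataio import BetaMatrix, PhenotypeTable, ValidationError

__all__ = [
    "NullModel",
    "DactOutput",
    "HimaOutput",
    "prefilter",
    "estimate_null_proportions",
    "dact",
    "hima_screen",
    "mcp_select",
    "joint_significance",
    "bh_adjust",
    "run_dact",
    "run_hima",
]

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# pre-filter
# ---------------------------------------------------------------------------


def prefilter(
    scan: MediationScan, alpha: float = 0.05, direction: str = "negative"
) -> pd.Index:
    """Probes with p < alpha on both sides and the requested indirect sign.

    direction="negative" keeps probes whose E-M × M-O product is negative
    (an overall negative indirect effect); "positive" the reverse; "any"
    ignores signs. Non-converged probes are dropped.
    """
    if direction not in ("negative", "positive", "any"):
        raise ValidationError("direction must be 'negative', 'positive' or 'any'")
    em, mo = scan.em, scan.mo
    ok = (
        scan.em["converged"]
        & scan.mo["converged"]
        & (em["p"] < alpha)
        & (mo["p"] < alpha)
    )
    if direction != "any":
        prod = em["estimate"] * mo["estimate"]
        ok &= prod < 0 if direction == "negative" else prod > 0
    return em.index[ok.fillna(False)]


# ---------------------------------------------------------------------------
# Efron empirical null
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class NullModel:
    """Empirical null N(delta, sigma^2) and the null proportion pi0."""

    pi0: float
    delta: float
    sigma: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.pi0 <= 1.0:
            raise ValidationError("pi0 must lie in [0, 1]")
        if self.sigma <= 0:
            raise ValidationError("sigma must be positive")


def _storey_pi0(z: np.ndarray, lam: float = 0.5) -> float:
    p = 2.0 * stats.norm.sf(np.abs(z))
    return float(min(1.0, np.mean(p > lam) / (1.0 - lam)))


def estimate_null_proportions(z: np.ndarray) -> NullModel:
    """Fit Efron's empirical null to the central z-scores.

    A normal N(delta, sigma^2) is fitted by truncated-normal maximum
    likelihood to the z-scores between the 10th and 90th percentiles; pi0 is
    the central empirical mass divided by the fitted null mass over the same
    window, capped at 1. (A narrower interquartile window leaves sigma
    nearly unidentified — the truncated likelihood is flat in sigma over the
    central 50% — so the central 80% is used.) With fewer than 200 scores
    the theoretical null N(0, 1) is used with Storey's lambda = 0.5 estimate
    of pi0 (logged).
    """
    z = np.asarray(z, dtype=float)
    z = z[np.isfinite(z)]
    if z.size == 0:
        raise ValidationError("no finite z-scores")
    if np.ptp(z) == 0:
        raise ValidationError("all z-scores identical; cannot fit a null")
    if z.size < 200:
        logger.warning(
            "only %d z-scores; falling back to the theoretical null N(0,1)",
            z.size,
        )
        return NullModel(pi0=_storey_pi0(z), delta=0.0, sigma=1.0)

    lo, hi = np.percentile(z, [10.0, 90.0])
    central = z[(z >= lo) & (z <= hi)]
    frac_central = central.size / z.size

    def nll(theta: np.ndarray) -> float:
        delta, log_sigma = theta
        sigma = math.exp(log_sigma)
        a, b = (lo - delta) / sigma, (hi - delta) / sigma
        denom = stats.norm.cdf(b) - stats.norm.cdf(a)
        if denom <= 0:
            return np.inf
        ll = stats.norm.logpdf(central, loc=delta, scale=sigma) - math.log(denom)
        return -float(ll.sum())

    sigma0 = max((hi - lo) / (2.0 * stats.norm.ppf(0.90)), 1e-3)
    res = optimize.minimize(
        nll,
        x0=np.array([float(np.median(central)), math.log(sigma0)]),
        method="Nelder-Mead",
        options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 2000},
    )
    delta, sigma = float(res.x[0]), float(math.exp(res.x[1]))
    null_mass = stats.norm.cdf((hi - delta) / sigma) - stats.norm.cdf(
        (lo - delta) / sigma
    )
    pi0 = min(1.0, frac_central / max(null_mass, 1e-12))
    return NullModel(pi0=pi0, delta=delta, sigma=sigma)


# ---------------------------------------------------------------------------
# DACT
# ---------------------------------------------------------------------------


@dataclass
class DactOutput:
    """Per-probe DACT results plus the normalized case weights used."""

    table: pd.DataFrame  # p_em, p_mo, p_dact, q
    weights: tuple[float, float, float]  # (w1, w2, w3)

    @property
    def p_dact(self) -> pd.Series:
        return self.table["p_dact"]

    @property
    def q(self) -> pd.Series:
        return self.table["q"]


def dact(
    p_em: pd.Series,
    p_mo: pd.Series,
    null_em: NullModel,
    null_mo: NullModel,
    calibrate: bool = False,
) -> DactOutput:
    """Composite-null mediation test: weighted sum of case p-values.

    With pi_a (E-M null proportion) and pi_b (M-O null proportion), the raw
    case probabilities are w1' = pi_a(1-pi_b), w2' = (1-pi_a)pi_b,
    w3' = pi_a·pi_b; normalized to sum 1. The case p-values are p_em, p_mo
    and max(p_em, p_mo)^2, and p_dact is their weighted sum. ``calibrate``
    applies an optional second-stage empirical-null correction on the
    inverse-normal transform of p_dact (off by default).
    """
    if not p_em.index.equals(p_mo.index):
        raise ValidationError("p_em and p_mo must be aligned on the same probes")
    pi_a, pi_b = null_em.pi0, null_mo.pi0
    raw = np.array([pi_a * (1 - pi_b), (1 - pi_a) * pi_b, pi_a * pi_b])
    if raw.sum() <= 0:
        raise ValidationError(
            "both null proportions are zero: no composite null case applies"
        )
    w = raw / raw.sum()
    a = p_em.to_numpy(dtype=float)
    b = p_mo.to_numpy(dtype=float)
    if np.isnan(a).any() or np.isnan(b).any():
        raise ValidationError("missing p-values in DACT input")
    p3 = np.maximum(a, b) ** 2
    p_dact = w[0] * a + w[1] * b + w[2] * p3
    p_dact = np.clip(p_dact, 0.0, 1.0)
    if calibrate:
        eps = 1e-300
        zd = stats.norm.ppf(np.clip(p_dact, eps, 1.0 - 1e-16))
        nm = estimate_null_proportions(zd)
        p_dact = stats.norm.cdf((zd - nm.delta) / nm.sigma)
    q = bh_adjust(pd.Series(p_dact, index=p_em.index))
    table = pd.DataFrame(
        {"p_em": a, "p_mo": b, "p_dact": p_dact, "q": q.to_numpy()},
        index=p_em.index,
    )
    return DactOutput(table=table, weights=(float(w[0]), float(w[1]), float(w[2])))


def run_dact(
    scan: MediationScan,
    probes: pd.Index | None = None,
    calibrate: bool = False,
) -> DactOutput:
    """Estimate both empirical nulls from the full scan, test given probes.

    The null proportions are estimated from all converged probes (the scan's
    full z-score distributions); the composite test and its BH adjustment
    are applied to ``probes`` (default: all converged probes).
    """
    keep = scan.converged()
    null_em = estimate_null_proportions(scan.em.loc[keep, "statistic"].to_numpy())
    null_mo = estimate_null_proportions(scan.mo.loc[keep, "statistic"].to_numpy())
    if probes is None:
        probes = keep
    return dact(
        scan.em.loc[probes, "p"],
        scan.mo.loc[probes, "p"],
        null_em,
        null_mo,
        calibrate=calibrate,
    )


# ---------------------------------------------------------------------------
# HIMA-style screen + MCP
# ---------------------------------------------------------------------------


def hima_screen(scan_mo: pd.DataFrame, n: int, sis_mult: float = 1.0) -> list[str]:
    """Sure independence screening: top ceil(n/log n) probes by |M-O effect|.

    Ties are broken by smaller p-value, then input order. If d reaches the
    probe pool size, all probes are returned (logged).
    """
    if n <= math.e:
        raise ValidationError("screening needs n > e so that log(n) > 1")
    d = int(math.ceil(sis_mult * n / math.log(n)))
    df = scan_mo.loc[scan_mo["converged"]].copy()
    if d >= len(df):
        logger.info("screen dimension d=%d >= %d probes; keeping all", d, len(df))
        return list(df.index)
    df["_abs"] = -df["estimate"].abs()
    df["_ord"] = np.arange(len(df))
    top = df.sort_values(["_abs", "p", "_ord"], kind="mergesort").head(d)
    return list(top.index)


def _mcp_threshold(z: float, lam: float, gamma: float) -> float:
    """Univariate MCP solution for a standardized predictor (x'x/n = 1)."""
    az = abs(z)
    if az <= lam:
        return 0.0
    if az <= gamma * lam:
        return math.copysign((az - lam) / (1.0 - 1.0 / gamma), z)
    return z


def mcp_select(
    beta_screened: pd.DataFrame,
    outcome: pd.Series,
    exposure: pd.Series,
    covariates: pd.DataFrame | None = None,
    gamma: float = 3.0,
    n_lambda: int = 100,
    lambda_min_ratio: float = 1e-3,
    max_iter: int = 500,
    tol: float = 1e-7,
) -> pd.Series:
    """Joint outcome regression with MCP on the mediators, chosen by BIC.

    All screened mediators enter one linear model together with an
    unpenalized intercept, exposure and covariates. Coordinate descent
    solves the MCP(γ) problem over a log-spaced 100-point λ path (3 decades
    down from λ_max, warm starts); the λ minimising BIC is kept. Returns the
    nonzero mediator coefficients on the original beta scale.
    """
    df = pd.DataFrame({"__y": outcome.astype(float), "__e": exposure.astype(float)})
    if covariates is not None and covariates.shape[1] > 0:
        df = df.join(covariates.astype(float))
    df = df.join(beta_screened.astype(float)).dropna()
    if beta_screened.shape[1] == 0:
        raise ValidationError("screened set is empty")
    y = df.pop("__y").to_numpy()
    n = len(y)
    med_names = list(beta_screened.columns)
    Z = np.column_stack([np.ones(n), df.drop(columns=med_names).to_numpy()])
    M = df[med_names].to_numpy()
    mu = M.mean(axis=0)
    sd = M.std(axis=0)
    if (sd == 0).any():
        dead = [m for m, s in zip(med_names, sd) if s == 0]
        raise ValidationError(f"zero-variance mediators in MCP design: {dead}")
    Ms = (M - mu) / sd  # columns satisfy x'x/n = 1

    # residualize once for lambda_max on the unpenalized fit
    coef_z, *_ = np.linalg.lstsq(Z, y, rcond=None)
    r = y - Z @ coef_z
    lam_max = np.max(np.abs(Ms.T @ r)) / n
    if lam_max <= 0:
        lam_max = 1e-6
    lambdas = np.geomspace(lam_max, lam_max * lambda_min_ratio, n_lambda)

    b = np.zeros(Ms.shape[1])
    best = None
    ZtZ_inv_Zt = np.linalg.pinv(Z)
    for lam in lambdas:
        for _ in range(max_iter):
            delta = 0.0
            # unpenalized block refit
            coef_z = ZtZ_inv_Zt @ (y - Ms @ b)
            r = y - Z @ coef_z - Ms @ b
            for j in range(Ms.shape[1]):
                zj = (Ms[:, j] @ r) / n + b[j]
                new = _mcp_threshold(zj, lam, gamma)
                if new != b[j]:
                    r -= Ms[:, j] * (new - b[j])
                    delta = max(delta, abs(new - b[j]))
                    b[j] = new
            if delta < tol:
                break
        rss = float(r @ r)
        df_model = int(np.count_nonzero(b)) + Z.shape[1]
        if rss <= 0:
            bic = -np.inf
        else:
            bic = n * math.log(rss / n) + math.log(n) * df_model
        if not np.isfinite(bic) and rss > 0:
            continue
        if best is None or bic < best[0]:
            best = (bic, b.copy())
    if best is None:
        raise ValidationError("no lambda on the path yielded a finite BIC")
    b_best = best[1] / sd  # back to original scale
    sel = pd.Series(b_best, index=med_names, name="coef")
    return sel[sel != 0.0]


def joint_significance(p_em: pd.Series, p_mo: pd.Series) -> pd.Series:
    """Joint-significance (max-p) test per probe."""
    if not p_em.index.equals(p_mo.index):
        raise ValidationError("p_em and p_mo must be aligned on the same probes")
    return pd.Series(
        np.maximum(p_em.to_numpy(dtype=float), p_mo.to_numpy(dtype=float)),
        index=p_em.index,
        name="p_joint",
    )


def bh_adjust(p: pd.Series | np.ndarray) -> pd.Series:
    """Benjamini–Hochberg step-up q-values, in input order."""
    arr = np.asarray(p, dtype=float)
    if arr.size == 0:
        return pd.Series(dtype=float)
    if np.isnan(arr).any() or (arr < 0).any() or (arr > 1).any():
        raise ValidationError("p-values must lie in [0, 1]")
    q = multipletests(arr, method="fdr_bh")[1]
    index = p.index if isinstance(p, pd.Series) else None
    return pd.Series(q, index=index, name="q")


@dataclass
class HimaOutput:
    """SIS survivors, MCP-selected probes, and their joint-significance q."""

    screened_probes: list[str]
    table: pd.DataFrame  # index: selected probes; alpha, beta, p_joint, q

    @property
    def selected_probes(self) -> list[str]:
        return list(self.table.index)


def run_hima(
    scan: MediationScan,
    beta: BetaMatrix,
    phenotypes: PhenotypeTable,
    exposure: str,
    outcome: str,
    covariates: list[str] | None = None,
    gamma: float = 3.0,
    sis_mult: float = 1.0,
) -> HimaOutput:
    """Three-step HIMA-style screen: SIS → MCP → joint significance + BH."""
    covariates = list(covariates or [])
    need = [exposure, outcome] + covariates
    sub = phenotypes.data.loc[
        phenotypes.data.index.intersection(beta.sample_ids), need
    ].astype(float).dropna()
    n = len(sub)
    screened = hima_screen(scan.mo, n, sis_mult=sis_mult)
    med = beta.values.loc[sub.index, screened]
    selected = mcp_select(
        med,
        sub[outcome],
        sub[exposure],
        sub[covariates] if covariates else None,
        gamma=gamma,
    )
    sel_index = pd.Index(selected.index)
    p_joint = joint_significance(
        scan.em.loc[sel_index, "p"], scan.mo.loc[sel_index, "p"]
    )
    q = bh_adjust(p_joint) if len(p_joint) else pd.Series(dtype=float)
    table = pd.DataFrame(
        {
            "alpha": scan.em.loc[sel_index, "estimate"],
            "beta": selected,
            "p_joint": p_joint,
            "q": q,
        }
    )
    return HimaOutput(screened_probes=screened, table=table)
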