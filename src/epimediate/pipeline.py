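"""End-to-end orchestration of the mediation analysis.

Stage order mirrors the analysis design: (1) adjusted total effects for every
exposure × Bayley domain at the primary timepoint; (2) for pairs with an
indication of a total effect, per-probe robust E-M/M-O scans, sign/p
pre-filtering and DACT (HIMA-style screening runs alongside); (3) DACT
survivors at BH-FDR ≤ fdr go to per-probe causal mediation; (4) probes with
ACME p < 0.05 and TE p < 0.05 are reported significant; (5) significant
probes are re-tested at the validation timepoint; (6) an MRS is built per
exposure and, when sufficiently predictive, tested in CMA as a single
mediator. Filter-cascade counts are logged and returned.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import assoc, cma, hdma, mrs as mrs_mod
from .dataio import (
    BAYLEY_DOMAINS,
    DEFAULT_COVARIATES,
    BetaMatrix,
    EwasWeights,
    PhenotypeTable,
    ValidationError,
    outcome_column,
    write_table,
)

__all__ = ["PipelineConfig", "Report", "run_pipeline", "write_report", "EXPOSURES"]

logger = logging.getLogger(__name__)

#: Exposure definitions: analysis column and the co-exposure adjustment.
EXPOSURES = {
    "smoking": {"column": "cotinine_ngml", "co_exposure": "alcohol"},
    "alcohol": {"column": "alcohol", "co_exposure": "cotinine_ngml"},
}


@dataclass
class PipelineConfig:
    """Knobs of the full pipeline; defaults follow the analysis design."""

    exposures: tuple[str, ...] = ("smoking", "alcohol")
    domains: tuple[str, ...] = BAYLEY_DOMAINS
    timepoint_primary: str = "6mo"
    timepoint_validation: str = "24mo"
    covariates: tuple[str, ...] = DEFAULT_COVARIATES
    alpha: float = 0.05
    fdr: float = 0.05
    gate_p: float = 0.05
    gate_include: tuple[tuple[str, str], ...] = ()
    direction: str = "negative"
    nsims: int = 1000
    seed: int = 0
    mrs_max_gap: int = 1000
    mrs_min_cor: float = 0.3
    mrs_grid: tuple[float, ...] = mrs_mod.DEFAULT_GRID
    mrs_r2_floor: float = 0.05
    dact_calibrate: bool = False
    run_hima: bool = True
    validation_min_n: int = 30

    def __post_init__(self) -> None:
        for name in ("alpha", "fdr", "gate_p"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValidationError(f"{name} must lie in (0, 1)")
        unknown = set(self.exposures) - set(EXPOSURES)
        if unknown:
            raise ValidationError(f"unknown exposures {sorted(unknown)}")


@dataclass
class Report:
    """Consolidated pipeline output: stage tables plus cascade counts."""

    total_effects: pd.DataFrame
    gated_pairs: list[tuple[str, str]]
    dact_tables: dict[tuple[str, str], pd.DataFrame] = field(default_factory=dict)
    hima_tables: dict[tuple[str, str], pd.DataFrame] = field(default_factory=dict)
    cma_table: pd.DataFrame = field(default_factory=pd.DataFrame)
    validation_table: pd.DataFrame = field(default_factory=pd.DataFrame)
    mrs_profiles: dict[str, pd.DataFrame] = field(default_factory=dict)
    mrs_cma_table: pd.DataFrame = field(default_factory=pd.DataFrame)
    counts: dict = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    def significant_probes(self, exposure: str, domain: str) -> list[str]:
        t = self.cma_table
        if t.empty:
            return []
        sel = t[(t["exposure"] == exposure) & (t["domain"] == domain) & t["significant"]]
        return list(sel["probe_id"])


def _pair_seed(base: int, tag: str) -> int:
    h = np.random.SeedSequence([base, abs(hash(tag)) % 2**31])
    return int(h.generate_state(1)[0] % 2**31)


def run_pipeline(
    beta: BetaMatrix,
    phenotypes: PhenotypeTable,
    config: PipelineConfig,
    ewas_weights: dict[str, EwasWeights] | None = None,
) -> Report:
    """Run the full analysis; see the module docstring for stage order."""
    cfg = config
    counts: dict = {}
    pdata = phenotypes.data

    # ---- stage 1: total effects -----------------------------------------
    te_rows = []
    for exp_name in cfg.exposures:
        exp_col = EXPOSURES[exp_name]["column"]
        co_col = EXPOSURES[exp_name]["co_exposure"]
        covs = [c for c in cfg.covariates if c != exp_col] + [co_col]
        for domain in cfg.domains:
            ycol = outcome_column(domain, cfg.timepoint_primary)
            res = assoc.fit_total_effect(
                pdata[ycol], pdata[exp_col], pdata[covs]
            )
            te_rows.append(
                {
                    "exposure": exp_name,
                    "domain": domain,
                    "timepoint": cfg.timepoint_primary,
                    "estimate": res.estimate,
                    "se": res.se,
                    "ci_low": res.ci_low,
                    "ci_high": res.ci_high,
                    "p": res.p,
                    "n": res.n,
                }
            )
    total_effects = pd.DataFrame(te_rows)

    # ---- stage 2 gate ----------------------------------------------------
    gated: list[tuple[str, str]] = []
    for _, row in total_effects.iterrows():
        pair = (row["exposure"], row["domain"])
        if row["p"] < cfg.gate_p or pair in cfg.gate_include:
            gated.append(pair)
    counts["pairs_tested"] = len(total_effects)
    counts["pairs_gated"] = len(gated)
    report = Report(total_effects=total_effects, gated_pairs=gated)
    report.meta = {"seed": cfg.seed, "n_probes": beta.n_probes,
                   "n_samples": beta.n_samples}
    if not gated:
        logger.info("no total effect detected; downstream stages skipped")
        report.counts = counts
        report.meta["note"] = "no total effect detected"
        return report

    # ---- stages 2-5 per gated pair ---------------------------------------
    cma_rows = []
    val_frames = []
    scan_cache: dict[str, pd.DataFrame] = {}
    for exp_name, domain in gated:
        tag = f"{exp_name}:{domain}"
        exp_col = EXPOSURES[exp_name]["column"]
        co_col = EXPOSURES[exp_name]["co_exposure"]
        covs = [c for c in cfg.covariates if c != exp_col] + [co_col]
        ycol = outcome_column(domain, cfg.timepoint_primary)

        if exp_name not in scan_cache:
            scan_cache[exp_name] = assoc.robust_scan(
                beta, phenotypes, "EM", exp_col, covariates=covs
            )
        em = scan_cache[exp_name]
        mo = assoc.robust_scan(
            beta, phenotypes, "MO", exp_col, outcome=ycol, covariates=covs
        )
        scan = assoc.MediationScan(em=em, mo=mo)
        counts[f"{tag}:probes_tested"] = int(len(scan.converged()))

        kept = hdma.prefilter(scan, alpha=cfg.alpha, direction=cfg.direction)
        counts[f"{tag}:prefiltered"] = len(kept)
        if len(kept) == 0:
            logger.info("%s: no probes survive the pre-filter", tag)
            continue
        dact_out = hdma.run_dact(scan, probes=kept, calibrate=cfg.dact_calibrate)
        report.dact_tables[(exp_name, domain)] = dact_out.table
        survivors = list(dact_out.table.index[dact_out.q <= cfg.fdr])
        counts[f"{tag}:dact_significant"] = len(survivors)

        if cfg.run_hima:
            try:
                hout = hdma.run_hima(
                    scan, beta, phenotypes, exp_col, ycol, covariates=covs
                )
                report.hima_tables[(exp_name, domain)] = hout.table
                counts[f"{tag}:hima_selected"] = len(hout.table)
            except ValidationError as exc:
                logger.warning("%s: HIMA stage skipped (%s)", tag, exc)

        # stage 3-4: per-probe CMA on DACT survivors
        common = pdata.index.intersection(beta.sample_ids)
        y = pdata.loc[common, ycol]
        e = pdata.loc[common, exp_col]
        covdf = pdata.loc[common, covs]
        n_sig = 0
        for probe in survivors:
            m = beta.values.loc[common, probe]
            models = cma.fit_mediation_models(m, y, e, covdf)
            est = cma.quasi_bayesian_cma(
                models,
                nsims=cfg.nsims,
                seed=_pair_seed(cfg.seed, f"{tag}:{probe}"),
            )
            row = {"exposure": exp_name, "domain": domain, "probe_id": probe}
            row.update(est.to_row())
            row["significant"] = est.significant_mediation
            cma_rows.append(row)
            n_sig += est.significant_mediation
        counts[f"{tag}:cma_significant"] = n_sig

        # stage 5: validation at the second timepoint
        sig_probes = [
            r["probe_id"]
            for r in cma_rows
            if r["exposure"] == exp_name and r["domain"] == domain and r["significant"]
        ]
        if sig_probes:
            try:
                val = cma.validate_at_second_timepoint(
                    sig_probes,
                    beta,
                    phenotypes,
                    exp_col,
                    domain,
                    covariates=covs,
                    timepoint=cfg.timepoint_validation,
                    nsims=cfg.nsims,
                    seed=_pair_seed(cfg.seed, f"{tag}:validation"),
                    min_n=cfg.validation_min_n,
                )
                val = val.reset_index()
                val.insert(0, "domain", domain)
                val.insert(0, "exposure", exp_name)
                val_frames.append(val)
            except ValidationError as exc:
                logger.warning("%s: validation skipped (%s)", tag, exc)

    report.cma_table = pd.DataFrame(cma_rows)
    report.validation_table = (
        pd.concat(val_frames, ignore_index=True) if val_frames else pd.DataFrame()
    )

    # ---- stage 6: MRS ----------------------------------------------------
    if ewas_weights:
        cmrs = mrs_mod.estimate_cmrs(
            beta, max_gap=cfg.mrs_max_gap, min_cor=cfg.mrs_min_cor
        )
        counts["n_cmrs"] = len(cmrs)
        mrs_rows = []
        for exp_name, weights in ewas_weights.items():
            exp_col = EXPOSURES[exp_name]["column"]
            exposure = pdata.loc[
                pdata.index.intersection(beta.sample_ids), exp_col
            ]
            profile = mrs_mod.select_threshold(
                beta, weights, cmrs, exposure, grid=cfg.mrs_grid
            )
            tab = profile.table.copy()
            tab.insert(0, "exposure", exp_name)
            report.mrs_profiles[exp_name] = tab
            counts[f"mrs:{exp_name}:best_r2"] = profile.best_r2
            if profile.best_r2 < cfg.mrs_r2_floor:
                logger.info(
                    "MRS for %s not predictive (r2=%.4f); CMA skipped",
                    exp_name,
                    profile.best_r2,
                )
                continue
            score = profile.best_scores
            co_col = EXPOSURES[exp_name]["co_exposure"]
            covs = [c for c in cfg.covariates if c != exp_col] + [co_col]
            for domain in [d for e, d in gated if e == exp_name]:
                ycol = outcome_column(domain, cfg.timepoint_primary)
                common = pdata.index.intersection(beta.sample_ids)
                models = cma.fit_mediation_models(
                    score.loc[common],
                    pdata.loc[common, ycol],
                    pdata.loc[common, exp_col],
                    pdata.loc[common, covs],
                )
                est = cma.quasi_bayesian_cma(
                    models,
                    nsims=cfg.nsims,
                    seed=_pair_seed(cfg.seed, f"mrs:{exp_name}:{domain}"),
                )
                row = {
                    "exposure": exp_name,
                    "domain": domain,
                    "mediator": "mrs",
                    "best_threshold": profile.best_threshold,
                }
                row.update(est.to_row())
                row["significant"] = est.significant_mediation
                mrs_rows.append(row)
        report.mrs_cma_table = pd.DataFrame(mrs_rows)

    report.counts = counts
    return report


def write_report(report: Report, outdir: str | Path) -> None:
    """Write the report as a directory of TSVs plus a JSON summary."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_table(report.total_effects, out / "total_effects.tsv")
    for (exp, dom), tab in report.dact_tables.items():
        write_table(tab.reset_index(), out / f"dact_{exp}_{dom}.tsv")
    for (exp, dom), tab in report.hima_tables.items():
        write_table(tab.reset_index(), out / f"hima_{exp}_{dom}.tsv")
    if not report.cma_table.empty:
        write_table(report.cma_table, out / "cma_significant_cpgs.tsv")
    if not report.validation_table.empty:
        write_table(report.validation_table, out / "validation_24mo.tsv")
    for exp, tab in report.mrs_profiles.items():
        write_table(tab, out / f"mrs_profile_{exp}.tsv")
    if not report.mrs_cma_table.empty:
        write_table(report.mrs_cma_table, out / "mrs_cma.tsv")
    summary = {
        "meta": report.meta,
        "counts": report.counts,
        "gated_pairs": [list(p) for p in report.gated_pairs],
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2, default=float))
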