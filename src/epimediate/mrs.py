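"""Methylation risk scores via CMR clumping and p-value thresholding.

An MRS is the weighted sum of beta values over probes whose external EWAS
p-value passes a threshold, after keeping at most one probe per
co-methylated region (CMR, "clumping"). The threshold is chosen from a grid
by maximising the squared correlation with the exposure ("thresholding").
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataio import BetaMatrix, EwasWeights, ValidationError

__all__ = [
    "CMRSet",
    "MrsScore",
    "MrsProfile",
    "DEFAULT_GRID",
    "estimate_cmrs",
    "clump_weights",
    "compute_mrs",
    "select_threshold",
]

logger = logging.getLogger(__name__)

#: Default p-value grid, 5e-1 down to 5e-30 in decade steps. Covers the
#: thresholds typically selected for tobacco (5e-21) and alcohol (5e-06)
#: cord-blood EWAS weights.
DEFAULT_GRID = tuple(5.0 * 10.0 ** (-k) for k in range(1, 31))


@dataclass
class CMRSet:
    """Disjoint co-methylated regions, each an ordered list of probe ids."""

    regions: list[list[str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for region in self.regions:
            if len(region) < 2:
                raise ValidationError("every CMR must contain at least 2 probes")
            for p in region:
                if p in seen:
                    raise ValidationError(f"probe {p!r} assigned to two CMRs")
                seen.add(p)

    def __len__(self) -> int:
        return len(self.regions)

    def probe_to_region(self) -> dict[str, int]:
        return {p: i for i, region in enumerate(self.regions) for p in region}


def estimate_cmrs(
    beta: BetaMatrix, max_gap: int = 1000, min_cor: float = 0.3
) -> CMRSet:
    """Detect CMRs by greedy chaining of adjacent correlated probes.

    Walk probes in genomic order per chromosome; extend the current chain
    while the next probe is at most ``max_gap`` bp away and its Pearson
    correlation with the chain's last probe is at least ``min_cor``.
    Singleton chains are discarded. A simplified stand-in for
    resampling-based CMR detection.
    """
    if beta.n_samples < 2:
        raise ValidationError("CMR estimation needs at least 2 samples")
    annot = beta.annotation
    regions: list[list[str]] = []
    vals = beta.values
    for chrom, sub in annot.groupby("chrom", sort=False):
        p = sub["pos"].to_numpy()
        if np.any(np.diff(p) < 0):
            raise ValidationError(
                f"annotation for {chrom} is not sorted by position; "
                "sort probes by (chrom, pos) first"
            )
        probes = list(sub.index)
        chain = [probes[0]]
        for prev, nxt in zip(probes, probes[1:]):
            gap = annot.at[nxt, "pos"] - annot.at[prev, "pos"]
            if gap <= max_gap:
                x = vals[chain[-1]].to_numpy()
                y = vals[nxt].to_numpy()
                sx, sy = x.std(), y.std()
                r = (
                    np.corrcoef(x, y)[0, 1]
                    if sx > 0 and sy > 0
                    else 0.0
                )
                if r >= min_cor:
                    chain.append(nxt)
                    continue
            if len(chain) >= 2:
                regions.append(chain)
            chain = [nxt]
        if len(chain) >= 2:
            regions.append(chain)
    return CMRSet(regions)


def clump_weights(weights: EwasWeights, cmrs: CMRSet) -> EwasWeights:
    """Keep, per CMR, only the probe with the smallest external p-value.

    Probes outside any CMR pass through unchanged. Ties on p are broken by
    genomic position (leftmost, i.e. first in the region's genomic order).
    """
    df = weights.data
    mapping = cmrs.probe_to_region()
    region_of = df["probe_id"].map(mapping)
    keep = np.ones(len(df), dtype=bool)
    order_in_region = {
        p: j for region in cmrs.regions for j, p in enumerate(region)
    }
    in_cmr = region_of.notna()
    sub = df.loc[in_cmr].copy()
    sub["_region"] = region_of[in_cmr].astype(int)
    sub["_order"] = sub["probe_id"].map(order_in_region)
    winners = (
        sub.sort_values(["_region", "p", "_order"], kind="mergesort")
        .groupby("_region", sort=False)
        .head(1)
        .index
    )
    keep[in_cmr.to_numpy()] = False
    keep[df.index.get_indexer(winners)] = True
    return EwasWeights(df.loc[keep].reset_index(drop=True))


@dataclass
class MrsScore:
    """Per-sample MRS at one threshold (raw weighted sum of betas)."""

    scores: pd.Series
    threshold: float
    n_probes_used: int
    degenerate: bool = False

    def standardized(self) -> pd.Series:
        """Z-scored copy for reporting (zero-variance scores pass through)."""
        sd = self.scores.std(ddof=0)
        if sd == 0:
            return self.scores - self.scores.mean()
        return (self.scores - self.scores.mean()) / sd


def compute_mrs(
    beta: BetaMatrix, weights: EwasWeights, threshold: float
) -> MrsScore:
    """Weighted sum of beta values over probes with p < threshold.

    Probes in the weights but absent from the matrix are skipped with a
    logged warning. When no probe passes, an all-zero degenerate profile is
    returned (flagged, not raised).
    """
    df = weights.data
    sel = df.loc[df["p"] < threshold]
    present = sel["probe_id"].isin(beta.probe_ids)
    if (~present).any():
        logger.warning(
            "%d weighted probes absent from the beta matrix; skipped",
            int((~present).sum()),
        )
        sel = sel.loc[present]
    if sel.empty:
        return MrsScore(
            pd.Series(0.0, index=beta.sample_ids, name="mrs"),
            threshold,
            0,
            degenerate=True,
        )
    mat = beta.values[sel["probe_id"].to_list()].to_numpy()
    raw = mat @ sel["effect"].to_numpy()
    return MrsScore(
        pd.Series(raw, index=beta.sample_ids, name="mrs"), threshold, len(sel)
    )


@dataclass
class MrsProfile:
    """Scores and prediction accuracy across a descending threshold grid."""

    table: pd.DataFrame  # threshold, n_probes_used, r2 (NaN when degenerate)
    scores: dict[float, pd.Series]
    best_threshold: float

    @property
    def best_scores(self) -> pd.Series:
        return self.scores[self.best_threshold]

    @property
    def best_r2(self) -> float:
        row = self.table.loc[self.table["threshold"] == self.best_threshold]
        return float(row["r2"].iloc[0])


def select_threshold(
    beta: BetaMatrix,
    weights: EwasWeights,
    cmrs: CMRSet,
    exposure: pd.Series,
    grid: tuple[float, ...] = DEFAULT_GRID,
) -> MrsProfile:
    """Clump, score at every grid threshold, and pick the most predictive one.

    Prediction accuracy is r², the squared Pearson correlation between the
    raw score and the exposure (continuous or binary). The best threshold is
    the argmax over non-degenerate thresholds; all-degenerate grids raise.
    """
    if len(grid) == 0:
        raise ValidationError("threshold grid is empty")
    clumped = clump_weights(weights, cmrs)
    exposure = exposure.reindex(beta.sample_ids)
    if exposure.isna().any():
        raise ValidationError("exposure missing for some samples in the matrix")
    e = exposure.to_numpy(dtype=float)
    rows = []
    scores: dict[float, pd.Series] = {}
    thresholds = sorted(set(grid), reverse=True)
    for t in thresholds:
        ms = compute_mrs(beta, clumped, t)
        scores[t] = ms.scores
        s = ms.scores.to_numpy()
        if ms.degenerate or s.std() == 0 or e.std() == 0:
            r2 = np.nan
        else:
            r2 = float(np.corrcoef(s, e)[0, 1] ** 2)
        rows.append(
            {"threshold": t, "n_probes_used": ms.n_probes_used, "r2": r2}
        )
    table = pd.DataFrame(rows)
    if table["r2"].isna().all():
        raise ValidationError("no informative threshold: all profiles degenerate")
    best = float(table.loc[table["r2"].idxmax(), "threshold"])
    return MrsProfile(table, scores, best)
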