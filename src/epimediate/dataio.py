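"""Validated tabular I/O for methylation mediation analyses.

All on-disk artifacts are delimited text (TSV canonical, CSV accepted by
extension, gzip transparent) plus a BED-like probe annotation with 0-based,
half-open coordinates. Every downstream module consumes only the validated
containers defined here: :class:`BetaMatrix`, :class:`PhenotypeTable`, and
:class:`EwasWeights`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ValidationError",
    "SchemaError",
    "BetaMatrix",
    "PhenotypeTable",
    "EwasWeights",
    "read_beta_matrix",
    "write_beta_matrix",
    "read_phenotypes",
    "write_phenotypes",
    "read_ewas_stats",
    "write_ewas_stats",
    "write_table",
    "read_table",
    "derive_smoking_class",
    "CELL_TYPES",
    "GENETIC_PCS",
    "BAYLEY_DOMAINS",
    "TIMEPOINTS",
    "outcome_column",
    "DEFAULT_COVARIATES",
    "BAYLEY_RANGE",
]


class ValidationError(ValueError):
    """A value violates the schema of one of the tabular artifacts."""


class SchemaError(ValidationError):
    """A mandatory column is missing or a header does not match."""


#: Cord-blood cell types used as compositional covariates.
CELL_TYPES = ("CD4T", "CD8T", "NK", "Bcell", "Mono", "Gran", "nRBC")
#: Genetic principal-component columns adjusting for population stratification.
GENETIC_PCS = ("PC1", "PC2", "PC3", "PC4", "PC5")
#: Bayley (BSID-III) composite domains.
BAYLEY_DOMAINS = ("cognitive", "language", "motor", "adaptive", "socioemotional")
#: Assessment ages.
TIMEPOINTS = ("6mo", "24mo")
#: Plausible BSID-III composite score range used for validation.
BAYLEY_RANGE = (40.0, 160.0)

#: Default adjustment set: maternal and perinatal covariates, cell-type
#: proportions (one dropped — they sum to 1), and five genetic PCs. The
#: co-exposure is appended per model by the caller.
DEFAULT_COVARIATES = (
    "maternal_age",
    "gestational_age",
    "hiv",
    "depression",
    "distress",
    "ses",
    "child_sex",
    *CELL_TYPES[:-1],
    *GENETIC_PCS,
)


def outcome_column(domain: str, timepoint: str) -> str:
    """Phenotype column name for a Bayley composite at a timepoint."""
    if domain not in BAYLEY_DOMAINS:
        raise SchemaError(f"unknown Bayley domain {domain!r}")
    if timepoint not in TIMEPOINTS:
        raise SchemaError(f"unknown timepoint {timepoint!r}")
    return f"bayley_{domain}_{timepoint}"


def _sep_for(path: str | Path) -> str:
    name = str(path)
    if name.endswith(".gz"):
        name = name[:-3]
    return "," if name.endswith(".csv") else "\t"


def read_table(path: str | Path) -> pd.DataFrame:
    """Read a delimited table, autodetecting TSV/CSV by extension (gzip ok)."""
    return pd.read_csv(path, sep=_sep_for(path), float_precision="round_trip")


def write_table(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    """Write a delimited table, autodetecting TSV/CSV by extension (gzip ok).

    Floats are written with 17 significant digits so write→read round-trips
    are bitwise exact.
    """
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep=_sep_for(path), index=index, float_format="%.17g")


# ---------------------------------------------------------------------------
# BetaMatrix
# ---------------------------------------------------------------------------


@dataclass
class BetaMatrix:
    """Samples × probes methylation beta values with genomic probe annotation.

    Parameters
    ----------
    values
        DataFrame indexed by sample id with one column per probe id; every
        entry must lie in [0, 1] with no missing values.
    annotation
        DataFrame indexed by probe id with ``chrom`` (label) and ``pos``
        (0-based coordinate) covering every probe in ``values``.
    """

    values: pd.DataFrame
    annotation: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.columns.duplicated().any():
            dup = self.values.columns[self.values.columns.duplicated()][0]
            raise ValidationError(f"duplicate probe id {dup!r}")
        if self.annotation.index.duplicated().any():
            dup = self.annotation.index[self.annotation.index.duplicated()][0]
            raise ValidationError(f"duplicate probe id {dup!r} in annotation")
        missing_cols = {"chrom", "pos"} - set(self.annotation.columns)
        if missing_cols:
            raise SchemaError(f"annotation lacks columns {sorted(missing_cols)}")
        unannotated = self.values.columns.difference(self.annotation.index)
        if len(unannotated):
            raise ValidationError(
                f"probes absent from annotation: {list(unannotated[:5])}"
            )
        vals = self.values.to_numpy(dtype=float)
        if np.isnan(vals).any():
            s, p = np.argwhere(np.isnan(vals))[0]
            raise ValidationError(
                f"missing beta value at sample {self.values.index[s]!r}, "
                f"probe {self.values.columns[p]!r}"
            )
        bad = (vals < 0.0) | (vals > 1.0)
        if bad.any():
            s, p = np.argwhere(bad)[0]
            raise ValidationError(
                f"beta value {vals[s, p]} outside [0, 1] at sample "
                f"{self.values.index[s]!r}, probe {self.values.columns[p]!r}"
            )
        # align annotation to probe order
        self.annotation = self.annotation.loc[self.values.columns, ["chrom", "pos"]]

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.index

    @property
    def probe_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_probes(self) -> int:
        return self.values.shape[1]

    def subset_probes(self, probes) -> "BetaMatrix":
        probes = pd.Index(probes)
        return BetaMatrix(self.values.loc[:, probes], self.annotation.loc[probes])


def read_beta_matrix(path: str | Path, annotation_path: str | Path) -> BetaMatrix:
    """Load a beta matrix (rows = samples) and its BED-like annotation.

    The matrix file must have a ``sample_id`` first column; the annotation is
    headerless BED: chrom, 0-based start, end, probe id.
    """
    df = read_table(path)
    if df.columns[0] != "sample_id":
        raise SchemaError("beta matrix must have 'sample_id' as first column")
    df = df.set_index("sample_id")
    bed = pd.read_csv(
        annotation_path,
        sep="\t",
        header=None,
        names=["chrom", "start", "end", "probe_id"],
    )
    annot = pd.DataFrame(
        {"chrom": bed["chrom"].to_numpy(), "pos": bed["start"].to_numpy()},
        index=pd.Index(bed["probe_id"], name="probe_id"),
    )
    return BetaMatrix(df, annot)


def write_beta_matrix(
    bm: BetaMatrix, path: str | Path, annotation_path: str | Path
) -> None:
    """Write the matrix as TSV and the annotation as 4-column BED."""
    out = bm.values.copy()
    out.index.name = "sample_id"
    write_table(out, path, index=True)
    bed = pd.DataFrame(
        {
            "chrom": bm.annotation["chrom"].to_numpy(),
            "start": bm.annotation["pos"].to_numpy(),
            "end": bm.annotation["pos"].to_numpy() + 2,
            "probe_id": bm.annotation.index.to_numpy(),
        }
    )
    Path(annotation_path).parent.mkdir(parents=True, exist_ok=True)
    bed.to_csv(annotation_path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# PhenotypeTable
# ---------------------------------------------------------------------------

COTININE_PASSIVE_CUT = 10.0  # ng/ml, lower bound of the passive-smoker band
COTININE_ACTIVE_CUT = 500.0  # ng/ml, inclusive active-smoker threshold


def derive_smoking_class(cotinine: pd.Series) -> pd.Series:
    """Classify urine cotinine (ng/ml): <10 non, 10–499 passive, ≥500 active."""
    c = cotinine.to_numpy(dtype=float)
    cls = np.select(
        [c >= COTININE_ACTIVE_CUT, c >= COTININE_PASSIVE_CUT],
        ["active", "passive"],
        default="non",
    )
    return pd.Series(cls, index=cotinine.index, name="smoking_class")


_PHENO_MANDATORY = (
    "sample_id",
    "cotinine_ngml",
    "alcohol",
    *DEFAULT_COVARIATES[:7],
    *CELL_TYPES,
    *GENETIC_PCS,
)


@dataclass
class PhenotypeTable:
    """Exposures, covariates, cell-type proportions, genetic PCs and outcomes.

    One row per sample, indexed by ``sample_id``. ``smoking_class`` is always
    (re-)derived from continuous cotinine. Bayley outcome columns
    (``bayley_<domain>_<timepoint>``) may be missing (NaN); samples are dropped
    per model downstream, never here.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        if df.index.name != "sample_id":
            if "sample_id" not in df.columns:
                raise SchemaError("phenotype table lacks mandatory column 'sample_id'")
            df = df.set_index("sample_id")
        missing = [c for c in _PHENO_MANDATORY if c != "sample_id" and c not in df.columns]
        if missing:
            raise SchemaError(f"phenotype table lacks mandatory columns {missing}")
        if df.index.duplicated().any():
            raise ValidationError("duplicate sample ids in phenotype table")
        cot = df["cotinine_ngml"].to_numpy(dtype=float)
        if (cot < 0).any():
            raise ValidationError("negative cotinine concentration")
        props = df[list(CELL_TYPES)].to_numpy(dtype=float)
        if (props < -1e-12).any():
            raise ValidationError("negative cell-type proportion")
        sums = props.sum(axis=1)
        off = np.abs(sums - 1.0) > 1e-6
        if off.any():
            i = int(np.argmax(off))
            raise ValidationError(
                f"cell-type proportions for sample {df.index[i]!r} sum to "
                f"{sums[i]:.6f}, expected 1"
            )
        lo, hi = BAYLEY_RANGE
        for col in df.columns:
            if col.startswith("bayley_"):
                y = df[col].to_numpy(dtype=float)
                bad = ~np.isnan(y) & ((y < lo) | (y > hi))
                if bad.any():
                    i = int(np.argmax(bad))
                    raise ValidationError(
                        f"outcome {col} = {y[i]} for sample {df.index[i]!r} "
                        f"outside plausible Bayley range [{lo}, {hi}]"
                    )
        df = df.copy()
        df["smoking_class"] = derive_smoking_class(df["cotinine_ngml"])
        self.data = df

    @property
    def sample_ids(self) -> pd.Index:
        return self.data.index

    def outcome(self, domain: str, timepoint: str) -> pd.Series:
        return self.data[outcome_column(domain, timepoint)]


def read_phenotypes(path: str | Path) -> PhenotypeTable:
    """Read and validate a phenotype/covariate table."""
    return PhenotypeTable(read_table(path))


def write_phenotypes(pheno: PhenotypeTable, path: str | Path) -> None:
    out = pheno.data.reset_index()
    write_table(out, path)


# ---------------------------------------------------------------------------
# EwasWeights
# ---------------------------------------------------------------------------


@dataclass
class EwasWeights:
    """External EWAS summary statistics used as MRS weights.

    One row per probe: signed effect size (beta-value units per exposure
    unit), its standard error, and a p-value in (0, 1].
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        missing = {"probe_id", "effect", "se", "p"} - set(df.columns)
        if missing:
            raise SchemaError(f"EWAS table lacks mandatory columns {sorted(missing)}")
        if df["probe_id"].duplicated().any():
            dup = df.loc[df["probe_id"].duplicated(), "probe_id"].iloc[0]
            raise ValidationError(f"duplicate probe id {dup!r} in EWAS weights")
        p = df["p"].to_numpy(dtype=float)
        if np.isnan(p).any() or (p <= 0).any() or (p > 1).any():
            raise ValidationError("EWAS p-values must lie in (0, 1]")
        self.data = df.reset_index(drop=True)

    @property
    def probe_ids(self) -> pd.Index:
        return pd.Index(self.data["probe_id"])

    def __len__(self) -> int:
        return len(self.data)


def read_ewas_stats(path: str | Path) -> EwasWeights:
    """Read and validate external EWAS summary statistics."""
    return EwasWeights(read_table(path))


def write_ewas_stats(weights: EwasWeights, path: str | Path) -> None:
    write_table(weights.data, path)
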