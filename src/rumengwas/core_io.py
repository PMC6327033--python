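"""Data model, file I/O, CPM normalization, prevalence filtering and phenotype derivation.

The central container is :class:`AbundanceMatrix`, a samples x features table of
non-negative abundances with a declared unit (raw ``counts``, ``cpm`` — counts per
million, each row summing to 1e6 — or ``relative`` — each row summing to 1).
Phenotypes live in :class:`PhenotypeTable`, which derives feed efficiency
(FE = milk yield / dry matter intake), residual feed intake (RFI = observed DMI
minus DMI expected from a within-population regression on production and
metabolic body weight) and the extreme-phenotype HIGH/LOW group labels used by
every downstream association stage.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("rumengwas")

CPM_TOTAL = 1e6

GROUP_HIGH = "HIGH"
GROUP_LOW = "LOW"
GROUP_UNASSIGNED = "unassigned"

#: Required columns of a phenotype CSV.
PHENOTYPE_REQUIRED = ("animal_id", "milk_yield", "dmi", "body_weight", "parity", "population")
PHENOTYPE_OPTIONAL = ("fat_pct", "protein_pct")


class DataError(ValueError):
    """Invalid input data (the user's problem, not a bug)."""


# ---------------------------------------------------------------------------
# AbundanceMatrix
# ---------------------------------------------------------------------------

@dataclass
class AbundanceMatrix:
    """Samples x features abundance matrix with a declared unit.

    Parameters
    ----------
    data
        DataFrame with sample ids as index and feature (contig/taxon) ids as
        columns.  Missing values are not allowed; absence is an explicit 0.
    unit
        One of ``counts``, ``cpm``, ``relative``.
    """

    data: pd.DataFrame
    unit: str

    def __post_init__(self) -> None:
        if self.unit not in ("counts", "cpm", "relative"):
            raise DataError(f"unknown abundance unit {self.unit!r}")
        if not self.data.index.is_unique:
            raise DataError("duplicate sample ids")
        if not self.data.columns.is_unique:
            raise DataError("duplicate feature ids")
        values = self.data.to_numpy(dtype=float)
        if np.isnan(values).any():
            raise DataError("abundance matrix contains missing values; absence must be 0")
        if (values < 0).any():
            raise DataError("abundance matrix contains negative values")
        if self.unit == "cpm" and len(self.data):
            sums = values.sum(axis=1)
            if not np.allclose(sums, CPM_TOTAL, rtol=1e-6):
                raise DataError("cpm rows must sum to 1e6")
        if self.unit == "relative" and len(self.data):
            sums = values.sum(axis=1)
            if not np.allclose(sums, 1.0, rtol=1e-9):
                raise DataError("relative rows must sum to 1")

    @property
    def sample_ids(self) -> list:
        return list(self.data.index)

    @property
    def feature_ids(self) -> list:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_features(self) -> int:
        return self.data.shape[1]

    def restrict(self, feature_ids: Sequence) -> "AbundanceMatrix":
        """Matrix restricted to the given features, preserving their order as given."""
        missing = [f for f in feature_ids if f not in self.data.columns]
        if missing:
            raise DataError(f"features not in matrix: {missing[:5]}")
        # bypass row-sum validation: a restricted CPM slice keeps original values
        out = AbundanceMatrix.__new__(AbundanceMatrix)
        out.data = self.data.loc[:, list(feature_ids)]
        out.unit = self.unit
        return out


def cpm_normalize(m: AbundanceMatrix) -> AbundanceMatrix:
    """Scale each sample's counts to counts-per-million.

    Zeros stay zero; a sample with zero total (no mapped reads) is an error.
    """
    if m.unit != "counts":
        raise DataError(f"cpm_normalize expects counts, got {m.unit}")
    totals = m.data.sum(axis=1)
    empty = totals[totals <= 0]
    if len(empty):
        raise DataError(f"sample(s) with zero total counts: {list(empty.index)}")
    out = m.data.div(totals, axis=0) * CPM_TOTAL
    return AbundanceMatrix(out, unit="cpm")


def prevalence_filter(m: AbundanceMatrix, min_count: int) -> tuple[AbundanceMatrix, list]:
    """Keep features nonzero in at least ``min_count`` samples.

    Returns the filtered matrix (column order preserved) and the dropped ids.
    """
    if min_count < 1:
        raise DataError("min_count must be >= 1")
    if min_count > m.n_samples:
        raise DataError(f"min_count {min_count} exceeds number of samples {m.n_samples}")
    prevalence = (m.data > 0).sum(axis=0)
    keep = prevalence[prevalence >= min_count].index
    dropped = [f for f in m.data.columns if f not in set(keep)]
    if dropped:
        logger.info("prevalence filter dropped %d of %d features (min_count=%d)",
                    len(dropped), m.n_features, min_count)
    out = AbundanceMatrix.__new__(AbundanceMatrix)
    out.data = m.data.loc[:, keep]
    out.unit = m.unit
    return out, dropped


# ---------------------------------------------------------------------------
# PhenotypeTable
# ---------------------------------------------------------------------------

@dataclass
class PhenotypeTable:
    """Per-animal production records plus derived FE, RFI and group labels.

    The underlying DataFrame is indexed by ``animal_id`` and carries at least
    milk_yield (kg/d), dmi (kg/d), body_weight (kg), parity
    (primiparous/multiparous) and population.  Derived columns ``fe``, ``rfi``
    and ``group`` are added by :func:`derive_fe`, :func:`derive_rfi` and
    :func:`assign_groups`.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        if df.index.name != "animal_id":
            if "animal_id" in df.columns:
                df = df.set_index("animal_id")
            else:
                raise DataError("phenotype table needs an animal_id column or index")
        if not df.index.is_unique:
            raise DataError("duplicate animal ids")
        for col in ("milk_yield", "dmi", "body_weight", "parity", "population"):
            if col not in df.columns:
                raise DataError(f"phenotype table missing required column {col!r}")
            if df[col].isna().any():
                raise DataError(f"missing values in phenotype column {col!r}")
        for col in ("milk_yield", "dmi", "body_weight"):
            df[col] = pd.to_numeric(df[col])
        if (df["dmi"] <= 0).any() or (df["body_weight"] <= 0).any():
            raise DataError("dmi and body_weight must be positive")
        if (df["milk_yield"] < 0).any():
            raise DataError("milk_yield must be non-negative")
        bad_parity = set(df["parity"].unique()) - {"primiparous", "multiparous"}
        if bad_parity:
            raise DataError(f"unknown parity levels: {sorted(bad_parity)}")
        if "group" not in df.columns:
            df = df.assign(group=GROUP_UNASSIGNED)
        self.data = df

    @property
    def animal_ids(self) -> list:
        return list(self.data.index)

    def __len__(self) -> int:
        return len(self.data)


def derive_fe(p: PhenotypeTable) -> PhenotypeTable:
    """Feed efficiency: milk yield (kg/d) divided by dry matter intake (kg/d)."""
    df = p.data.copy()
    if (df["dmi"] <= 0).any():
        raise DataError("dmi must be positive to derive FE")
    df["fe"] = df["milk_yield"] / df["dmi"]
    return PhenotypeTable(df)


def derive_rfi(p: PhenotypeTable, predictors: Sequence[str] = ("milk_yield", "metabolic_bw")) -> PhenotypeTable:
    """Residual feed intake: observed DMI minus DMI expected from regression.

    Within each population an ordinary least-squares model of DMI on the
    predictor traits (plus an intercept) is fitted; RFI is the residual, so it
    averages zero within each population.  ``metabolic_bw`` denotes
    body_weight**0.75 and is computed on the fly.
    """
    df = p.data.copy()
    df["rfi"] = np.nan
    for pop, sub in df.groupby("population", sort=False):
        if len(sub) < 3:
            raise DataError(f"population {pop!r} has fewer than 3 animals; cannot fit RFI model")
        cols = []
        for name in predictors:
            if name == "metabolic_bw":
                cols.append(sub["body_weight"].to_numpy(dtype=float) ** 0.75)
            elif name in sub.columns:
                cols.append(sub[name].to_numpy(dtype=float))
            else:
                raise DataError(f"RFI predictor {name!r} not in phenotype table")
        X = np.column_stack([np.ones(len(sub))] + cols)
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise DataError(f"collinear RFI design in population {pop!r}: predictors {list(predictors)}")
        y = sub["dmi"].to_numpy(dtype=float)
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        df.loc[sub.index, "rfi"] = y - X @ beta
    return PhenotypeTable(df)


def assign_groups(p: PhenotypeTable, trait: str, n_per_tail: int) -> PhenotypeTable:
    """Label the top ``n_per_tail`` animals by ``trait`` HIGH and the bottom LOW.

    Ties are broken by stable input order; a tie straddling either cut boundary
    is resolved that way but emits a warning.  The operation is idempotent.
    """
    df = p.data.copy()
    if trait not in df.columns:
        raise DataError(f"trait {trait!r} not present; derive it first")
    if df[trait].isna().any():
        raise DataError(f"trait {trait!r} has missing values")
    n = len(df)
    if 2 * n_per_tail > n:
        raise DataError(f"2*n_per_tail={2*n_per_tail} exceeds {n} animals")
    values = df[trait].to_numpy(dtype=float)
    # stable sort keeps input order among ties
    order = np.argsort(values, kind="stable")
    low_idx = order[:n_per_tail]
    high_idx = order[n - n_per_tail:]
    for cut_name, inside, boundary in (
        ("LOW", low_idx, n_per_tail - 1),
        ("HIGH", high_idx, n - n_per_tail),
    ):
        if 0 < n_per_tail < n:
            v_in = values[order[boundary]]
            v_out = values[order[boundary + (1 if cut_name == "LOW" else -1)]]
            if v_in == v_out:
                warnings.warn(
                    f"tie at the {cut_name} group boundary on trait {trait!r}; "
                    "resolved by stable input order", stacklevel=2)
                logger.warning("tie at %s boundary on %s", cut_name, trait)
    group = np.full(n, GROUP_UNASSIGNED, dtype=object)
    group[low_idx] = GROUP_LOW
    group[high_idx] = GROUP_HIGH
    df["group"] = group
    return PhenotypeTable(df)


def group_labels(p: PhenotypeTable, samples: Sequence) -> np.ndarray:
    """HIGH/LOW labels for the given sample ids, erroring on unassigned animals."""
    g = p.data.loc[list(samples), "group"].to_numpy()
    if (g == GROUP_UNASSIGNED).any():
        raise DataError("some animals have no HIGH/LOW group label")
    return g


# ---------------------------------------------------------------------------
# Pipeline configuration
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Central knobs of the analysis pipeline.

    Defaults follow the study design: prevalence in >=7 of 30 animals, the top
    95th percentile of information gain, per-contig significance at alpha=0.05,
    and 1,000 random-contig null replicates.
    """

    min_prevalence_count: int = 7
    ig_percentile: float = 95.0
    alpha: float = 0.05
    n_null_replicates: int = 1000
    rng_seed: int = 0
    lambda_strategy: str = "cv"
    lambda_value: float | None = None
    n_boot_per_scale: int = 1000
    boot_scales: tuple = tuple(np.round(np.arange(0.5, 1.45, 0.1), 2))

    def __post_init__(self) -> None:
        if self.min_prevalence_count < 1:
            raise DataError("min_prevalence_count must be >= 1")
        if not 0 < self.ig_percentile < 100:
            raise DataError("ig_percentile must be in (0, 100)")
        if not 0 < self.alpha <= 1:
            raise DataError("alpha must be in (0, 1]")
        if self.n_null_replicates < 1:
            raise DataError("n_null_replicates must be >= 1")
        if self.lambda_strategy not in ("cv", "fixed"):
            raise DataError("lambda_strategy must be 'cv' or 'fixed'")
        if self.lambda_strategy == "fixed" and (self.lambda_value is None or self.lambda_value <= 0):
            raise DataError("fixed lambda_strategy needs lambda_value > 0")


def prevalence_count_fraction(n_samples: int, fraction: float = 0.25) -> int:
    """ceil(fraction * n_samples) — the '25% of individuals' prevalence rule."""
    return int(np.ceil(fraction * n_samples))


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

def read_abundance_tsv(path: str | Path, unit: str) -> AbundanceMatrix:
    """Read a tab-separated abundance matrix (first column sample id, header = feature ids)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = "sample_id"
    return AbundanceMatrix(df, unit=unit)


def write_abundance_tsv(m: AbundanceMatrix, path: str | Path) -> None:
    df = m.data.copy()
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t")


def read_salmon_quants(paths: dict, count_column: str = "NumReads") -> AbundanceMatrix:
    """Assemble one counts matrix from per-sample SALMON-style quantification tables.

    ``paths`` maps sample id -> file with columns Name, Length, EffectiveLength,
    TPM, NumReads (tab-separated).  Features absent from a sample are 0.
    """
    columns_required = {"Name", count_column}
    series = {}
    for sample, path in paths.items():
        tab = pd.read_csv(path, sep="\t")
        missing = columns_required - set(tab.columns)
        if missing:
            raise DataError(f"salmon table {path} missing columns {sorted(missing)}")
        series[sample] = tab.set_index("Name")[count_column]
    df = pd.DataFrame(series).T.fillna(0.0)
    df.index.name = "sample_id"
    return AbundanceMatrix(df, unit="counts")


def read_phenotypes_csv(path: str | Path) -> PhenotypeTable:
    df = pd.read_csv(path)
    missing = set(PHENOTYPE_REQUIRED) - set(df.columns)
    if missing:
        raise DataError(f"phenotype CSV missing required columns {sorted(missing)}")
    return PhenotypeTable(df)


def write_phenotypes_csv(p: PhenotypeTable, path: str | Path) -> None:
    p.data.reset_index().to_csv(path, index=False)
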