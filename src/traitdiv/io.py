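"""Readers, writers and validation for the pipeline's tabular formats.

All tables are plain pandas DataFrames keyed by opaque string labels
(``individual_id``, ``population_id``, ``location_id``); genotypes get a thin
:class:`GenotypeTable` wrapper because a diploid multilocus layout (two allele
columns per locus, ``0`` = missing) does not map cleanly onto a flat frame.

Formats
-------
* traits / environment / locations / summaries: RFC-4180 CSV, UTF-8, ``.``
  decimal, empty cell = missing.
* genotypes: GenAlEx codominant text layout (three header lines, two columns
  per locus, allele ``0`` = missing).
* configuration: YAML, nested sections.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("traitdiv")

#: canonical functional-trait roster (column order of the trait CV table)
TRAIT_NAMES = ["RH", "AGB", "LA", "SLA", "LDMC", "FvFm", "PI", "SPS", "SPI"]

#: abiotic factors retained for the within-habitat heterogeneity index
ENV_FACTORS = [
    "altitude", "slope_exposure", "slope", "LAI", "soil_depth",
    "CEC_pot", "pH", "N", "P", "K",
]


class ValidationError(ValueError):
    """A table failed a structural or range check; the message names the row."""


# ---------------------------------------------------------------------------
# trait table
# ---------------------------------------------------------------------------

def validate_trait_table(df: pd.DataFrame) -> pd.DataFrame:
    if "population_id" not in df.columns or "individual_id" not in df.columns:
        raise ValidationError("trait table needs individual_id and population_id columns")
    if df["population_id"].isna().any():
        bad = df.index[df["population_id"].isna()][0]
        raise ValidationError(f"row {bad}: missing population_id")
    trait_cols = [c for c in df.columns if c not in ("individual_id", "population_id")]
    for c in trait_cols:
        vals = pd.to_numeric(df[c], errors="coerce")
        neg = df.index[vals < 0]
        if len(neg):
            raise ValidationError(f"row {neg[0]}: trait {c} negative ({vals[neg[0]]})")
        df[c] = vals
    if "FvFm" in df.columns:
        out = df.index[(df["FvFm"] < 0) | (df["FvFm"] > 1)]
        if len(out):
            raise ValidationError(f"row {out[0]}: FvFm={df.loc[out[0], 'FvFm']} outside [0, 1]")
    return df


def read_trait_table(path) -> pd.DataFrame:
    """Read an individual x trait CSV; unknown columns are kept as extra traits."""
    df = pd.read_csv(path, dtype={"individual_id": str, "population_id": str})
    df = validate_trait_table(df)
    logger.info("read_trait_table: %d individuals, %d populations from %s",
                len(df), df["population_id"].nunique(), path)
    return df


def write_trait_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# environmental replicates and locations
# ---------------------------------------------------------------------------

def validate_env_table(df: pd.DataFrame) -> pd.DataFrame:
    if "location_id" not in df.columns or "replicate_id" not in df.columns:
        raise ValidationError("environment table needs location_id and replicate_id columns")
    counts = df.groupby("location_id").size()
    if (counts < 1).any():
        raise ValidationError("every location needs at least one replicate")
    if "pH" in df.columns:
        bad = df.index[(df["pH"] <= 0) | (df["pH"] >= 14)]
        if len(bad):
            raise ValidationError(f"row {bad[0]}: pH={df.loc[bad[0], 'pH']} outside (0, 14)")
    factor_cols = [c for c in df.columns if c not in ("location_id", "replicate_id", "pH")]
    for c in factor_cols:
        vals = pd.to_numeric(df[c], errors="coerce")
        neg = df.index[vals < 0]
        if len(neg):
            raise ValidationError(f"row {neg[0]}: factor {c} negative")
        df[c] = vals
    return df


def read_env_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"location_id": str, "replicate_id": str})
    df = validate_env_table(df)
    logger.info("read_env_table: %d replicates, %d locations from %s",
                len(df), df["location_id"].nunique(), path)
    return df


def write_env_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_location_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"location_id": str})
    for col in ("latitude", "longitude"):
        if col not in df.columns:
            raise ValidationError(f"location table needs a {col} column")
    if (df["latitude"].abs() > 90).any() or (df["longitude"].abs() > 180).any():
        raise ValidationError("coordinates outside |lat|<=90, |lon|<=180")
    return df


def write_location_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# genotypes (GenAlEx codominant layout)
# ---------------------------------------------------------------------------

@dataclass
class GenotypeTable:
    """Diploid codominant genotypes.

    ``data`` holds one row per individual with columns ``individual_id``,
    ``population_id`` and, per locus ``L``, integer columns ``L_1``/``L_2``
    (pandas nullable Int64; both NA at a missing locus). Allele labels are
    positive integers (fragment sizes).
    """

    data: pd.DataFrame
    loci: list[str] = field(default_factory=list)

    def __post_init__(self):
        for locus in self.loci:
            a1, a2 = self.data[f"{locus}_1"], self.data[f"{locus}_2"]
            half = a1.isna() != a2.isna()
            if half.any():
                raise ValidationError(
                    f"locus {locus}: individual {self.data.loc[half.idxmax(), 'individual_id']} "
                    "has exactly one allele (diploid data must have 0 or 2)")

    @property
    def populations(self) -> list[str]:
        return list(pd.unique(self.data["population_id"]))

    def n_typed_loci(self) -> pd.Series:
        """Number of non-missing loci per individual (index: individual_id)."""
        typed = pd.DataFrame({
            locus: self.data[f"{locus}_1"].notna() for locus in self.loci
        })
        typed.index = self.data["individual_id"]
        return typed.sum(axis=1)

    def __len__(self) -> int:
        return len(self.data)


def read_genalex(path) -> GenotypeTable:
    """Parse a GenAlEx codominant file (CSV).

    Layout: line 1 ``n_loci, n_samples, n_pops, size1, size2, ...``; line 2
    title / population names; line 3 ``Sample, Pop, locus1, , locus2, , ...``;
    then one row per individual with two allele columns per locus, ``0`` for a
    missing allele. A locus typed with one zero and one nonzero allele is
    coerced to fully missing (and logged): a half-called diploid genotype is
    not interpretable.
    """
    raw = pd.read_csv(path, header=None, skip_blank_lines=False, dtype=str)
    counts = raw.iloc[0]
    n_loci = int(counts[0])
    n_samples = int(counts[1])
    header = raw.iloc[2]
    loci = [str(header[2 + 2 * i]).strip() for i in range(n_loci)]
    expected_cols = 2 + 2 * n_loci
    body = raw.iloc[3:3 + n_samples].reset_index(drop=True)
    n_allele_cols = body.iloc[:, 2:].notna().any(axis=0).sum()
    if n_allele_cols != 2 * n_loci:
        raise ValidationError(
            f"declared {n_loci} loci but found {n_allele_cols} allele columns "
            f"(expected {2 * n_loci})")
    out = pd.DataFrame({
        "individual_id": body.iloc[:, 0].astype(str).str.strip(),
        "population_id": body.iloc[:, 1].astype(str).str.strip(),
    })
    n_coerced = 0
    for i, locus in enumerate(loci):
        a1 = pd.to_numeric(body.iloc[:, 2 + 2 * i], errors="raise").fillna(0).astype(int)
        a2 = pd.to_numeric(body.iloc[:, 3 + 2 * i], errors="raise").fillna(0).astype(int)
        half = (a1 == 0) != (a2 == 0)
        if half.any():
            n_coerced += int(half.sum())
            a1 = a1.where(~half, 0)
            a2 = a2.where(~half, 0)
        out[f"{locus}_1"] = pd.array(a1, dtype="Int64")
        out[f"{locus}_2"] = pd.array(a2, dtype="Int64")
        out.loc[a1 == 0, f"{locus}_1"] = pd.NA
        out.loc[a2 == 0, f"{locus}_2"] = pd.NA
    if n_coerced:
        logger.warning("read_genalex: coerced %d half-missing locus calls to missing", n_coerced)
    logger.info("read_genalex: %d individuals, %d loci from %s", len(out), n_loci, path)
    return GenotypeTable(out, loci)


def write_genalex(g: GenotypeTable, path, title: str = "traitdiv export") -> None:
    pops = g.populations
    sizes = g.data.groupby("population_id", sort=False).size()
    ncol = 2 + 2 * len(g.loci)

    def pad(row):
        return row + [""] * (ncol - len(row))

    lines = [
        pad([str(len(g.loci)), str(len(g)), str(len(pops))] + [str(sizes[p]) for p in pops]),
        pad([title] + [""] * 2 + list(pops)),
        pad(["Sample", "Pop"] + [x for locus in g.loci for x in (locus, "")]),
    ]
    rows = []
    for _, r in g.data.iterrows():
        row = [r["individual_id"], r["population_id"]]
        for locus in g.loci:
            for k in (1, 2):
                v = r[f"{locus}_{k}"]
                row.append("0" if pd.isna(v) else str(int(v)))
        rows.append(row)
    frame = pd.DataFrame(lines + rows)
    frame.to_csv(path, header=False, index=False)


# ---------------------------------------------------------------------------
# population summaries
# ---------------------------------------------------------------------------

SUMMARY_COLUMNS = ["population_id", "iFD_CV", "iFD_CV_se", "HD", "HD_se", "GD", "GD_se"]


def write_summary(summaries: pd.DataFrame, path) -> None:
    """Write per-population summaries (iFD_CV +/- se, HD +/- se, GD +/- se)."""
    if len(summaries) == 0:
        raise ValidationError("empty summary table")
    missing = [c for c in SUMMARY_COLUMNS if c not in summaries.columns]
    if missing:
        raise ValidationError(f"summary table missing columns: {missing}")
    extra = [c for c in summaries.columns if c not in SUMMARY_COLUMNS]
    summaries[SUMMARY_COLUMNS + extra].to_csv(path, index=False)


def read_summary(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"population_id": str})
    missing = [c for c in SUMMARY_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"summary table missing columns: {missing}")
    return df


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

def read_config(path) -> dict:
    """Load a nested YAML configuration (input paths, rosters, thresholds, seeds)."""
    with open(path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValidationError(f"configuration at {path} is not a mapping")
    return cfg
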