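"""Leaf-trait derivation, quality screens and the iFD_CV index.

iFD_CV summarizes intraspecific functional trait variation of a population as
the arithmetic mean of the per-trait coefficients of variation (sample SD over
mean) of nine functional traits: releasing height (RH), aboveground biomass
(AGB), leaf area (LA), specific leaf area (SLA), leaf dry matter content
(LDMC), Fv/Fm, performance index (PI), stomatal pore surface (SPS) and
stomatal pore area index (SPI). Its standard error is the SD of the nine CVs
divided by sqrt(9).
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd
from scipy import stats

from .io import TRAIT_NAMES

logger = logging.getLogger("traitdiv")


# ---------------------------------------------------------------------------
# derived leaf traits
# ---------------------------------------------------------------------------

def derive_sla(fresh_area_mm2, dry_mass_mg):
    """Specific leaf area [mm^2/mg]: one-sided fresh leaf area over oven-dry mass."""
    fresh_area_mm2 = np.asarray(fresh_area_mm2, dtype=float)
    dry_mass_mg = np.asarray(dry_mass_mg, dtype=float)
    if np.any(dry_mass_mg <= 0):
        raise ValueError("dry mass must be positive")
    return fresh_area_mm2 / dry_mass_mg


def derive_ldmc(dry_mass_mg, fresh_mass_g):
    """Leaf dry matter content [mg/g]: oven-dry mass over water-saturated fresh mass."""
    dry_mass_mg = np.asarray(dry_mass_mg, dtype=float)
    fresh_mass_g = np.asarray(fresh_mass_g, dtype=float)
    if np.any(fresh_mass_g <= 0):
        raise ValueError("fresh mass must be positive")
    return dry_mass_mg / fresh_mass_g


def derive_sps(guard_cell_length_um, guard_cell_width_um):
    """Stomatal pore surface [um^2]: guard-cell length x width x pi/4."""
    length = np.asarray(guard_cell_length_um, dtype=float)
    width = np.asarray(guard_cell_width_um, dtype=float)
    if np.any(length <= 0) or np.any(width <= 0):
        raise ValueError("guard-cell dimensions must be positive")
    return length * width * math.pi / 4.0


def derive_spi(guard_cell_length_um, stomatal_density_per_mm2):
    """Stomatal pore area index (dimensionless): (length in mm)^2 x density [1/mm^2]."""
    length_mm = np.asarray(guard_cell_length_um, dtype=float) / 1000.0
    density = np.asarray(stomatal_density_per_mm2, dtype=float)
    if np.any(length_mm <= 0) or np.any(density < 0):
        raise ValueError("length must be positive and density non-negative")
    return length_mm ** 2 * density


def aggregate_leaves(leaf_df: pd.DataFrame, by: str = "individual_id") -> pd.DataFrame:
    """Average repeated leaf measurements to one record per individual.

    Leaf traits are measured on two leaves per individual; the individual-level
    trait value is their mean. Non-numeric columns (population labels) keep the
    first value per group.
    """
    num = leaf_df.select_dtypes("number").columns
    other = [c for c in leaf_df.columns if c not in num and c != by]
    agg = {c: "mean" for c in num} | {c: "first" for c in other}
    return leaf_df.groupby(by, sort=False).agg(agg).reset_index()


# ---------------------------------------------------------------------------
# screens
# ---------------------------------------------------------------------------

def exclude_outliers(table: pd.DataFrame, threshold: float = 4.0,
                     traits: list[str] | None = None,
                     ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Null trait records more than ``threshold`` pooled SDs from the pooled mean.

    Mean and sample SD are computed per trait over all individuals pooled
    across populations, in a single pass (the screen is not iterated). When an
    FvFm record is removed, the same individual's PI record is removed too:
    both come from one fluorescence measurement, so an erroneous FvFm entry
    discredits its paired PI value. Traits with fewer than 3 non-null values
    are skipped with a warning.

    Returns the screened table (values replaced by NaN) and an outlier report
    with one row per removed record.
    """
    table = table.copy()
    if traits is None:
        traits = [c for c in table.columns if c not in ("individual_id", "population_id")]
    reports = []
    for trait in traits:
        vals = table[trait]
        n = vals.notna().sum()
        if n < 3:
            logger.warning("exclude_outliers: trait %s has %d values, skipped", trait, n)
            continue
        mu, sd = vals.mean(), vals.std(ddof=1)
        if sd == 0:
            continue
        z = (vals - mu) / sd
        for idx in table.index[z.abs() > threshold]:
            reports.append({
                "trait": trait,
                "individual_id": table.loc[idx, "individual_id"],
                "value": vals[idx],
                "z_score": z[idx],
                "action": "removed",
            })
            table.loc[idx, trait] = np.nan
            if trait == "FvFm" and "PI" in table.columns and pd.notna(table.loc[idx, "PI"]):
                reports.append({
                    "trait": "PI",
                    "individual_id": table.loc[idx, "individual_id"],
                    "value": table.loc[idx, "PI"],
                    "z_score": np.nan,
                    "action": "removed with paired FvFm outlier",
                })
                table.loc[idx, "PI"] = np.nan
    report = pd.DataFrame(reports, columns=["trait", "individual_id", "value", "z_score", "action"])
    logger.info("exclude_outliers: removed %d records at >%g SD", len(report), threshold)
    return table, report


def trait_collinearity_screen(table: pd.DataFrame, threshold: float = 0.7,
                              traits: list[str] | None = None,
                              ) -> tuple[list[str], pd.DataFrame]:
    """Spearman collinearity screen over pooled individuals.

    Pairwise-complete Spearman rank correlations (average ranks for ties) are
    computed between all trait pairs; for each pair with ``|r| > threshold``
    the second trait (in roster order) is flagged for removal. Returns the
    retained trait list and a frame of flagged pairs.
    """
    if traits is None:
        traits = [c for c in table.columns if c not in ("individual_id", "population_id")]
    flagged, dropped = [], set()
    for i, a in enumerate(traits):
        for b in traits[i + 1:]:
            pair = table[[a, b]].dropna()
            if len(pair) < 3:
                continue
            r, p = stats.spearmanr(pair[a], pair[b])
            if abs(r) > threshold:
                flagged.append({"trait_a": a, "trait_b": b, "r_spearman": r, "p": p})
                if a not in dropped:
                    dropped.add(b)
    retained = [t for t in traits if t not in dropped]
    return retained, pd.DataFrame(flagged, columns=["trait_a", "trait_b", "r_spearman", "p"])


# ---------------------------------------------------------------------------
# coefficients of variation and iFD_CV
# ---------------------------------------------------------------------------

def cv(values, ddof: int = 1) -> float:
    """Coefficient of variation: sample SD (n-1 denominator) over the mean."""
    vals = np.asarray(pd.Series(values).dropna(), dtype=float)
    if len(vals) < 2:
        raise ValueError(f"CV needs at least 2 values, got {len(vals)}")
    mean = vals.mean()
    if mean == 0:
        raise ValueError("CV undefined for zero mean")
    return float(vals.std(ddof=ddof) / mean)


def trait_cv_table(table: pd.DataFrame, traits: list[str] | None = None) -> pd.DataFrame:
    """Per-population CV of each trait (columns ``CV_<trait>`` and ``n_<trait>``)."""
    if traits is None:
        traits = [t for t in TRAIT_NAMES if t in table.columns]
    rows = []
    for pop, grp in table.groupby("population_id", sort=False):
        row: dict = {"population_id": pop}
        for t in traits:
            vals = grp[t].dropna()
            row[f"n_{t}"] = len(vals)
            row[f"CV_{t}"] = cv(vals) if len(vals) >= 2 and vals.mean() != 0 else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def ifdcv(cv_row, impute: dict[str, float] | None = None) -> tuple[float, float]:
    """iFD_CV of one population: mean of its nine trait CVs, SE = SD/sqrt(9).

    ``cv_row`` maps trait name (or ``CV_<trait>``) to the population's CV.
    Missing trait CVs are an error unless supplied through ``impute`` (used for
    populations where a trait could not be measured and a published
    approximation stands in).
    """
    row = dict(cv_row)
    if impute:
        for k, v in impute.items():
            row[k] = v
    vals = []
    for t in TRAIT_NAMES:
        v = row.get(t, row.get(f"CV_{t}"))
        if v is None or (isinstance(v, float) and np.isnan(v)):
            raise ValueError(f"missing CV for trait {t}; impute it explicitly")
        vals.append(float(v))
    arr = np.array(vals)
    return float(arr.mean()), float(arr.std(ddof=1) / math.sqrt(len(arr)))


def ifdcv_table(cv_table: pd.DataFrame, impute: dict[str, dict[str, float]] | None = None,
                ) -> pd.DataFrame:
    """iFD_CV and SE for every population in a trait CV table.

    ``impute`` maps population_id to a trait->CV mapping for populations with
    missing trait CVs.
    """
    impute = impute or {}
    rows = []
    for _, r in cv_table.iterrows():
        pop = r["population_id"]
        mean, se = ifdcv(r, impute.get(pop))
        rows.append({"population_id": pop, "iFD_CV": mean, "iFD_CV_se": se})
    return pd.DataFrame(rows)
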