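"""Within-habitat heterogeneity (HD) from replicated environmental plots.

Each location is characterized by up to five replicate plots on which abiotic
factors (altitude, slope exposure, slope, leaf area index, soil depth and soil
chemistry) were measured. HD is the location-wise mean coefficient of
variation of the retained factors across those replicates; its SE is the SD of
the factor CVs over sqrt(number of factors).

Slope exposure is a circular quantity (degrees) but enters the CV as a plain
non-negative number; the column is flagged in output metadata because the CV
then depends on the 0-degree reference.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd
from scipy import stats

from .io import ENV_FACTORS

logger = logging.getLogger("traitdiv")

#: ordinal/circular factor summarized by the median instead of the mean
ORDINAL_FACTORS = ("slope_exposure",)


def _factor_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c not in ("location_id", "replicate_id")]


def summarize_replicates(table: pd.DataFrame) -> pd.DataFrame:
    """Per-location central values: mean for numeric factors, median for ordinal."""
    factors = _factor_columns(table)
    rows = []
    for loc, grp in table.groupby("location_id", sort=False):
        if len(grp) == 0:
            raise ValueError(f"location {loc} has no replicates")
        row: dict = {"location_id": loc}
        for f in factors:
            vals = grp[f].dropna()
            row[f] = vals.median() if f in ORDINAL_FACTORS else vals.mean()
        rows.append(row)
    return pd.DataFrame(rows)


def env_collinearity_screen(table: pd.DataFrame, threshold: float = 0.7,
                            drop_list: list[str] | None = None,
                            ) -> tuple[list[str], pd.DataFrame]:
    """Spearman screen of the factor matrix over pooled replicate records.

    Zero-variance factors are always dropped. If ``drop_list`` is given it
    overrides the automatic choice (needed to reproduce published manual
    exclusions that also removed a factor at r = .50).
    """
    factors = _factor_columns(table)
    flagged, dropped = [], set()
    for f in factors:
        if table[f].dropna().nunique() <= 1:
            dropped.add(f)
            flagged.append({"factor_a": f, "factor_b": "", "r_spearman": np.nan,
                            "reason": "zero variance"})
    if drop_list is not None:
        dropped |= set(drop_list)
    else:
        for i, a in enumerate(factors):
            for b in factors[i + 1:]:
                if a in dropped or b in dropped:
                    continue
                pair = table[[a, b]].dropna()
                if len(pair) < 3:
                    continue
                r, _ = stats.spearmanr(pair[a], pair[b])
                if abs(r) > threshold:
                    flagged.append({"factor_a": a, "factor_b": b, "r_spearman": r,
                                    "reason": f"|r|>{threshold}"})
                    dropped.add(b)
    retained = [f for f in factors if f not in dropped]
    logger.info("env_collinearity_screen: retained %d of %d factors", len(retained), len(factors))
    return retained, pd.DataFrame(flagged, columns=["factor_a", "factor_b", "r_spearman", "reason"])


def hd(table: pd.DataFrame, retained: list[str] | None = None) -> pd.DataFrame:
    """Location-wise factor CVs and HD (mean CV) with SE.

    Returns one row per location with ``CV_<factor>`` columns, ``HD`` and
    ``HD_se``. A factor with zero mean within a location makes the CV
    undefined and raises, naming the factor.
    """
    if retained is None:
        retained = [f for f in ENV_FACTORS if f in table.columns]
    rows = []
    for loc, grp in table.groupby("location_id", sort=False):
        if len(grp) < 2:
            raise ValueError(f"location {loc}: HD needs at least 2 replicates")
        row: dict = {"location_id": loc}
        cvs = []
        for f in retained:
            vals = grp[f].dropna().to_numpy(dtype=float)
            mean = vals.mean()
            if mean == 0:
                raise ValueError(f"location {loc}: factor {f} has zero mean, CV undefined")
            c = vals.std(ddof=1) / mean
            row[f"CV_{f}"] = c
            cvs.append(c)
        arr = np.array(cvs)
        row["HD"] = arr.mean()
        row["HD_se"] = arr.std(ddof=1) / math.sqrt(len(arr))
        rows.append(row)
    out = pd.DataFrame(rows)
    out.attrs["circular_factors_as_plain_cv"] = [f for f in retained if f in ORDINAL_FACTORS]
    return out
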