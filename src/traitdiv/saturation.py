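"""Resampling saturation curves: a statistic versus subsample size.

For each group (population or location) and each sample size ``n`` the engine
draws simple random subsets of the group's units without replacement,
recomputes the statistic on each subset from scratch, and records the mean and
SD over iterations. A curve that flattens before the full sample size
indicates the sampling effort was sufficient for that statistic.

``n = 1`` rows are emitted as NaN for CV-based statistics (a CV needs at least
two values); the curve still spans the full 1..N range.
"""

from __future__ import annotations

from typing import Any, Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import GenotypeTable


def saturation_curve(groups: Mapping[str, Sequence[Any]],
                     statistic: Callable[[str, Sequence[Any]], float],
                     iterations: int = 100,
                     n_max: int | None = None,
                     seed: int | None = None,
                     replace: bool = False) -> pd.DataFrame:
    """Generic curve engine.

    ``groups`` maps a group label to its resampling units (e.g. individual
    ids); ``statistic(group, units)`` returns the statistic on that subset (NaN
    where undefined). Sampling is without replacement by default, so at the
    full sample size every draw is the complete group and the SD is exactly 0.
    Deterministic under a fixed ``seed``.

    Returns a long frame: group, n, mean, sd, iterations, seed.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for group, units in groups.items():
        units = list(units)
        top = len(units) if n_max is None else n_max
        if top > len(units) and not replace:
            raise ValueError(f"group {group}: n_max={top} exceeds {len(units)} units")
        for n in range(1, top + 1):
            if not replace and n == len(units):
                # only one subset exists; the full-sample statistic, exactly
                full = statistic(group, units)
                rows.append({"group": group, "n": n, "mean": full,
                             "sd": np.nan if np.isnan(full) else 0.0,
                             "iterations": iterations, "seed": seed})
                continue
            else:
                vals = np.empty(iterations)
                for it in range(iterations):
                    sub = rng.choice(len(units), size=n, replace=replace)
                    vals[it] = statistic(group, [units[i] for i in sub])
            rows.append({"group": group, "n": n,
                         "mean": np.nan if np.isnan(vals).all() else np.nanmean(vals),
                         "sd": np.nan if np.isnan(vals).all() else np.nanstd(vals, ddof=1),
                         "iterations": iterations, "seed": seed})
    return pd.DataFrame(rows)


def saturation_onset(curve: pd.DataFrame, tolerance: float = 0.02) -> int | None:
    """Smallest n from which successive means change by < ``tolerance``.

    Changes are relative to the full-sample (largest-n) mean. Returns None when
    the curve never settles ("not saturated"). This is a labelled heuristic for
    reading a visually flattening curve, not a formal test. NaN rows (n = 1 for
    CV statistics) are ignored.
    """
    cur = curve.dropna(subset=["mean"]).sort_values("n")
    if len(cur) < 3:
        raise ValueError("saturation_onset needs a curve with at least 3 defined points")
    means = cur["mean"].to_numpy()
    ns = cur["n"].to_numpy()
    ref = abs(means[-1])
    if ref == 0:
        ref = 1.0
    steps_ok = np.abs(np.diff(means)) / ref < tolerance
    for i in range(len(steps_ok)):
        if steps_ok[i:].all():
            return int(ns[i])
    return None


# ---------------------------------------------------------------------------
# statistic-specific wrappers
# ---------------------------------------------------------------------------

def ifdcv_saturation(table: pd.DataFrame, iterations: int = 100,
                     seed: int | None = None, n_max: int | None = None) -> pd.DataFrame:
    """Saturation of iFD_CV, resampling individuals within each population.

    On subsets the index is the mean CV over traits with at least two non-null
    values (all-trait completeness cannot be demanded of a subsample).
    """
    groups = {pop: grp["individual_id"].tolist()
              for pop, grp in table.groupby("population_id", sort=False)}
    indexed = table.set_index("individual_id")
    traits = [c for c in table.columns if c not in ("individual_id", "population_id")]

    def stat(pop: str, units: Sequence[str]) -> float:
        sub = indexed.loc[list(units)]
        cvs = []
        for t in traits:
            vals = sub[t].dropna()
            if len(vals) >= 2 and vals.mean() != 0:
                cvs.append(vals.std(ddof=1) / vals.mean())
        return float(np.mean(cvs)) if cvs else np.nan

    return saturation_curve(groups, stat, iterations=iterations, seed=seed, n_max=n_max)


def hd_saturation(table: pd.DataFrame, retained: list[str] | None = None,
                  iterations: int = 100, seed: int | None = None,
                  n_max: int | None = None) -> pd.DataFrame:
    """Saturation of HD, resampling replicate plots within each location."""
    groups = {loc: grp["replicate_id"].tolist()
              for loc, grp in table.groupby("location_id", sort=False)}
    indexed = table.set_index("replicate_id")
    if retained is None:
        retained = [c for c in table.columns if c not in ("location_id", "replicate_id")]

    def stat(loc: str, units: Sequence[str]) -> float:
        if len(units) < 2:
            return np.nan
        sub = indexed.loc[list(units)]
        cvs = []
        for f in retained:
            vals = sub[f].dropna().to_numpy(dtype=float)
            if len(vals) >= 2 and vals.mean() != 0:
                cvs.append(vals.std(ddof=1) / vals.mean())
        return float(np.mean(cvs)) if cvs else np.nan

    return saturation_curve(groups, stat, iterations=iterations, seed=seed, n_max=n_max)


def he_saturation(g: GenotypeTable, iterations: int = 100,
                  seed: int | None = None, n_max: int | None = None) -> pd.DataFrame:
    """Saturation of multilocus H_e, resampling genotyped individuals.

    Allele frequencies are recomputed from each subsample (never cached from
    the full sample), so rare alleles drop out of small subsets as they would
    in a smaller field campaign.
    """
    groups = {pop: grp["individual_id"].tolist()
              for pop, grp in g.data.groupby("population_id", sort=False)}
    indexed = g.data.set_index("individual_id")

    def stat(pop: str, units: Sequence[str]) -> float:
        sub = indexed.loc[list(units)]
        hes = []
        for locus in g.loci:
            a = pd.concat([sub[f"{locus}_1"], sub[f"{locus}_2"]]).dropna()
            if len(a) == 0:
                continue
            p = a.value_counts(normalize=True).to_numpy()
            hes.append(1.0 - float((p ** 2).sum()))
        return float(np.mean(hes)) if hes else np.nan

    return saturation_curve(groups, stat, iterations=iterations, seed=seed, n_max=n_max)
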