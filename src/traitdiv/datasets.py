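"""Packaged reference tables for the 13-population *Trifolium montanum* study.

Two small CSVs ship with the package: per-population summary indices
(iFD_CV, HD, GD = multilocus expected heterozygosity, each with a standard
error, plus sampling dates and decimal-degree coordinates) and the per-trait
coefficients of variation underlying iFD_CV. Coordinates are stored as plain
decimal degrees. The KW population's CV_FvFm and CV_PI are the published
regression-approximated values (field measurements were missing there).
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

_DATA = resources.files(__name__.rsplit(".", 1)[0]) / "data"


def load_population_summary() -> pd.DataFrame:
    """Per-population iFD_CV, HD and GD (+/- SE) with coordinates and dates."""
    with resources.as_file(_DATA / "population_summary.csv") as p:
        return pd.read_csv(p, dtype={"population_id": str})


def load_trait_cv_table() -> pd.DataFrame:
    """Per-population coefficients of variation of the nine functional traits."""
    with resources.as_file(_DATA / "trait_cv.csv") as p:
        return pd.read_csv(p, dtype={"population_id": str})


def load_locations() -> pd.DataFrame:
    """Location coordinates (decimal degrees) of the 13 study populations."""
    df = load_population_summary()
    return df[["population_id", "latitude", "longitude"]].rename(
        columns={"population_id": "location_id"})


def fixture_paper_tables() -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Return (population summary, trait CV table, locations) reference tables."""
    return load_population_summary(), load_trait_cv_table(), load_locations()
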