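import numpy as np
import pandas as pd
import pytest

import traitdiv as td
from traitdiv.habitat import hd
from traitdiv.inference import backward_select, variance_partition, ztransform
from traitdiv.popgen import allele_frequencies, filter_individuals
from traitdiv.traits import ifdcv_table, trait_cv_table


@pytest.fixture(scope="session")
def paper_tables():
    """Packaged reference tables: (population summary, trait CVs, locations)."""
    return td.fixture_paper_tables()


@pytest.fixture(scope="session")
def small_sim():
    """One small deterministic synthetic study shared across read-only tests."""
    return td.simulate(td.SimulationConfig(n_populations=6), seed=42)


def multilocus_he(freqs: pd.DataFrame) -> pd.Series:
    """Pipeline H_e: per-locus 1 - sum(p^2), unweighted mean over typed loci."""
    he = freqs.groupby(["population_id", "locus"]).apply(
        lambda g: 1 - (g["freq"] ** 2).sum(), include_groups=False)
    return he.groupby("population_id").mean()


def run_recovery(seed: int, config: td.SimulationConfig | None = None):
    """Full pipeline on one synthetic study: simulate -> iFD_CV, HD, H_e ->
    z-scored backward selection. Returns the selected fit."""
    sim = td.simulate(config, seed=seed)
    ifd = ifdcv_table(trait_cv_table(sim.traits)).set_index("population_id")["iFD_CV"]
    hd_series = hd(sim.env).set_index("location_id")["HD"]
    g = filter_individuals(sim.genotypes)
    he = multilocus_he(allele_frequencies(g))
    X = pd.DataFrame({"HD": hd_series, "He": he}).loc[ifd.index]
    fit, _ = backward_select(ifd, X.apply(ztransform), standardized=True)
    return fit


@pytest.fixture(scope="session")
def recovery_counts():
    """End-to-end recovery over 100 seeds with strong coupling (a=2, b=1).

    Counts seeds whose backward-selected model keeps both HD and H_e with
    positive coefficients, and among them those ranking HD above H_e in the
    variance partition.
    """
    cfg_kw = dict(coupling_hd=2.0, coupling_he=1.0)
    both = rank = 0
    for seed in range(100):
        fit = run_recovery(seed, td.SimulationConfig(**cfg_kw))
        if set(fit.predictors) == {"HD", "He"} and (fit.params[["HD", "He"]] > 0).all():
            both += 1
            if variance_partition(fit)["HD"] > variance_partition(fit)["He"]:
                rank += 1
    return {"both_positive": both, "rank_correct": rank, "n_seeds": 100}
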