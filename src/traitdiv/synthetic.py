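"""Synthetic study generator: coupled habitat, genetic and trait variation.

The generator emulates the sampling design of the reference study — 13
populations of 20 individuals, up to five environmental replicate plots per
location, nine microsatellite loci with ~10% missing calls — with a known
causal structure so recovery can be tested end to end:

* each location gets a heterogeneity level ``h`` (log-scale SD of its
  environmental replicates), so its measured HD tracks ``h``;
* each population gets allele frequencies drawn per locus from a symmetric
  Dirichlet whose concentration is chosen to hit a target expected
  heterozygosity; genotypes are sampled under Hardy-Weinberg (an optional
  selfing rate copies the first allele with probability ``s``, depressing
  observed heterozygosity);
* individual trait values are lognormal with log-scale SD
  ``sigma = a*h + b*H_e + noise`` so that the true trait CV,
  sqrt(exp(sigma^2) - 1), is an analytic, increasing function of the coupling.
  Lognormal draws keep every trait positive, so CVs are always defined.

Target expected heterozygosities are decoupled from the heterogeneity gradient
by a seeded permutation, which keeps the two predictors identifiable in the
downstream regression.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datasets import fixture_paper_tables  # noqa: F401  (re-exported)
from .io import ENV_FACTORS, TRAIT_NAMES, GenotypeTable

_TRAIT_BASELINES = {
    "RH": 0.3,      # m
    "AGB": 2.0,     # g
    "LA": 300.0,    # mm^2
    "SLA": 20.0,    # mm^2/mg
    "LDMC": 250.0,  # mg/g
    "FvFm": 0.8,
    "PI": 3.0,
    "SPS": 150.0,   # um^2
    "SPI": 0.12,
}

# Fv/Fm varies an order of magnitude less than the other traits (a bounded
# physiological ratio); its log-scale SD is scaled down accordingly.
_TRAIT_SIGMA_SCALE = {t: 1.0 for t in TRAIT_NAMES} | {"FvFm": 0.05}

_FACTOR_BASELINES = {
    "altitude": 400.0, "slope_exposure": 180.0, "slope": 15.0, "LAI": 2.0,
    "soil_depth": 20.0, "CEC_pot": 25.0, "pH": 7.0, "N": 0.3, "P": 5.0, "K": 15.0,
}


@dataclass
class SimulationConfig:
    """Study-design parameters; defaults mirror the reference sampling design."""

    n_populations: int = 13
    n_individuals: int = 20
    n_replicates: int = 5
    n_loci: int = 9
    n_alleles: int = 6
    missing_rate: float = 0.10          # mean loci coverage ~90%
    coupling_hd: float = 1.0            # a: heterogeneity -> trait log-SD
    coupling_he: float = 0.5            # b: expected H_e -> trait log-SD
    noise_sd: float = 0.02              # residual log-SD noise
    selfing_rate: float = 0.0
    heterogeneity: np.ndarray | None = None   # h per location; default linspace(.05, .40)
    expected_he: np.ndarray | None = None     # targets; default linspace(.45, .80), permuted
    trait_baselines: dict = field(default_factory=lambda: dict(_TRAIT_BASELINES))
    trait_sigma_scale: dict = field(default_factory=lambda: dict(_TRAIT_SIGMA_SCALE))
    factor_baselines: dict = field(default_factory=lambda: dict(_FACTOR_BASELINES))

    def __post_init__(self):
        if self.n_alleles < 1 or self.n_loci < 1:
            raise ValueError("need at least one allele and one locus")
        if not 0 <= self.missing_rate <= 1 or not 0 <= self.selfing_rate <= 1:
            raise ValueError("rates must lie in [0, 1]")
        if self.heterogeneity is None:
            self.heterogeneity = np.linspace(0.05, 0.40, self.n_populations)
        self.heterogeneity = np.asarray(self.heterogeneity, dtype=float)
        if (self.heterogeneity < 0).any():
            raise ValueError("heterogeneity levels must be non-negative")
        if self.expected_he is None:
            self.expected_he = np.linspace(0.45, 0.80, self.n_populations)
        self.expected_he = np.asarray(self.expected_he, dtype=float)


@dataclass
class SimulationResult:
    traits: pd.DataFrame
    env: pd.DataFrame
    genotypes: GenotypeTable
    locations: pd.DataFrame
    truth: pd.DataFrame


def _dirichlet_concentration(target_he: float, k: int) -> float:
    """Concentration of a symmetric Dirichlet(k) with E[1 - sum p^2] = target.

    E[He] = (k-1)/k * k*alpha/(k*alpha + 1); solved for alpha.
    """
    hmax = (k - 1) / k
    if not 0 < target_he < hmax:
        raise ValueError(f"target H_e {target_he} unreachable with {k} alleles (max {hmax:.3f})")
    x = target_he / hmax
    return x / (1 - x) / k


def true_cv(sigma: float) -> float:
    """CV of a lognormal with log-scale SD sigma."""
    return math.sqrt(math.exp(sigma ** 2) - 1.0)


def simulate(config: SimulationConfig | None = None, seed: int | None = None) -> SimulationResult:
    """Generate one synthetic study; bit-for-bit reproducible under a fixed seed."""
    cfg = config or SimulationConfig()
    rng = np.random.default_rng(seed)
    npop = cfg.n_populations
    pops = [f"P{i + 1:02d}" for i in range(npop)]
    he_targets = rng.permutation(cfg.expected_he)

    # -- locations: a ~10 km grid with one distant outlier (first population)
    side = int(np.ceil(np.sqrt(max(npop - 1, 1))))
    loc_rows = [{"location_id": pops[0], "latitude": 47.40, "longitude": 10.20}]
    for i in range(1, npop):
        r, c = divmod(i - 1, side)
        loc_rows.append({"location_id": pops[i],
                         "latitude": 50.90 + 0.1 * r, "longitude": 11.00 + 0.1 * c})
    locations = pd.DataFrame(loc_rows)

    factors = [f for f in ENV_FACTORS if f in cfg.factor_baselines]
    traits = [t for t in TRAIT_NAMES if t in cfg.trait_baselines]
    env_rows, trait_rows, geno_rows, truth_rows = [], [], [], []
    allele_sizes = 100 + 2 * np.arange(cfg.n_alleles)

    for p, pop in enumerate(pops):
        h = cfg.heterogeneity[p]

        # environmental replicates: lognormal around the factor baseline
        for r in range(cfg.n_replicates):
            row = {"location_id": pop, "replicate_id": f"{pop}-R{r + 1}"}
            for f in factors:
                row[f] = cfg.factor_baselines[f] * rng.lognormal(0.0, h) if h > 0 \
                    else cfg.factor_baselines[f]
            env_rows.append(row)

        # allele frequencies and HWE genotypes
        alpha = _dirichlet_concentration(he_targets[p], cfg.n_alleles)
        pop_freqs = rng.dirichlet(np.full(cfg.n_alleles, alpha), size=cfg.n_loci)
        he_true = float(np.mean(1.0 - (pop_freqs ** 2).sum(axis=1)))
        geno = np.empty((cfg.n_individuals, cfg.n_loci, 2), dtype=int)
        for l in range(cfg.n_loci):
            draws = rng.choice(cfg.n_alleles, size=(cfg.n_individuals, 2), p=pop_freqs[l])
            if cfg.selfing_rate > 0:
                selfed = rng.random(cfg.n_individuals) < cfg.selfing_rate
                draws[selfed, 1] = draws[selfed, 0]
            geno[:, l, :] = allele_sizes[draws]
        missing = rng.random((cfg.n_individuals, cfg.n_loci)) < cfg.missing_rate
        for i in range(cfg.n_individuals):
            row = {"individual_id": f"{pop}-{i + 1:02d}", "population_id": pop}
            for l in range(cfg.n_loci):
                locus = f"L{l + 1}"
                if missing[i, l]:
                    row[f"{locus}_1"] = row[f"{locus}_2"] = pd.NA
                else:
                    row[f"{locus}_1"], row[f"{locus}_2"] = int(geno[i, l, 0]), int(geno[i, l, 1])
            geno_rows.append(row)

        # traits: lognormal with coupled log-scale SD
        sigma = cfg.coupling_hd * h + cfg.coupling_he * he_true + rng.normal(0.0, cfg.noise_sd)
        sigma = max(sigma, 0.01)
        for i in range(cfg.n_individuals):
            row = {"individual_id": f"{pop}-{i + 1:02d}", "population_id": pop}
            for t in traits:
                s = sigma * cfg.trait_sigma_scale.get(t, 1.0)
                val = cfg.trait_baselines[t] * rng.lognormal(-0.5 * s * s, s)
                if t == "FvFm":
                    val = min(val, 1.0)
                row[t] = val
            trait_rows.append(row)

        truth_rows.append({
            "population_id": pop, "h": h, "target_he": he_targets[p],
            "expected_he": he_true, "sigma": sigma,
            "true_cv": true_cv(sigma),
        })

    geno_df = pd.DataFrame(geno_rows)
    for l in range(cfg.n_loci):
        for k in (1, 2):
            geno_df[f"L{l + 1}_{k}"] = pd.array(geno_df[f"L{l + 1}_{k}"], dtype="Int64")

    return SimulationResult(
        traits=pd.DataFrame(trait_rows),
        env=pd.DataFrame(env_rows),
        genotypes=GenotypeTable(geno_df, [f"L{l + 1}" for l in range(cfg.n_loci)]),
        locations=locations,
        truth=pd.DataFrame(truth_rows),
    )
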