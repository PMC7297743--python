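"""Full pipeline on synthetic data with a known causal structure.

Simulates 13 populations whose trait variation is driven by habitat
heterogeneity (coupling a) and expected heterozygosity (coupling b), runs the
complete analysis — trait CVs, HD from replicate plots, H_e from genotypes,
z-scored backward selection — and shows that both signals are recovered.
"""

import pandas as pd

import traitdiv as td
from traitdiv.habitat import hd
from traitdiv.inference import backward_select, variance_partition, ztransform
from traitdiv.popgen import allele_frequencies, filter_individuals
from traitdiv.traits import ifdcv_table, trait_cv_table

sim = td.simulate(td.SimulationConfig(coupling_hd=2.0, coupling_he=1.0), seed=7)
print(f"simulated {sim.traits['population_id'].nunique()} populations, "
      f"{len(sim.traits)} individuals, {len(sim.env)} environmental replicates")

ifd = ifdcv_table(trait_cv_table(sim.traits)).set_index("population_id")["iFD_CV"]
hd_series = hd(sim.env).set_index("location_id")["HD"]

genotypes = filter_individuals(sim.genotypes, min_loci=4)
freqs = allele_frequencies(genotypes)
he = freqs.groupby(["population_id", "locus"]).apply(
    lambda g: 1 - (g["freq"] ** 2).sum(), include_groups=False
).groupby("population_id").mean()

X = pd.DataFrame({"HD": hd_series, "He": he}).loc[ifd.index]
fit, steps = backward_select(ifd, X.apply(ztransform), standardized=True)
print(f"backward selection kept: {fit.predictors} "
      f"(adj R2 = {fit.r2_adj:.2f}, F = {fit.fvalue:.2f})")
shares = variance_partition(fit)
print("variance shares:", {k: f"{v:.1f}%" for k, v in shares.items()})
print("truth: trait log-SD = 2.0*h + 1.0*H_e — both predictors should survive,"
      " with HD ranked first")
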