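"""Diversity indices, Nei distance and principal coordinates analysis."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import traitdiv as td
from traitdiv.io import GenotypeTable
from traitdiv.popgen import (allele_frequencies, diversity, filter_individuals,
                             individual_distance, nei_distance, nei_distance_matrix, pcoa)


def genotable(records, loci):
    """records: list of (ind, pop, {locus: (a1, a2) or None})."""
    rows = []
    for ind, pop, gen in records:
        row = {"individual_id": ind, "population_id": pop}
        for locus in loci:
            pair = gen.get(locus)
            row[f"{locus}_1"] = pd.NA if pair is None else pair[0]
            row[f"{locus}_2"] = pd.NA if pair is None else pair[1]
        rows.append(row)
    df = pd.DataFrame(rows)
    for locus in loci:
        for k in (1, 2):
            df[f"{locus}_{k}"] = pd.array(df[f"{locus}_{k}"], dtype="Int64")
    return GenotypeTable(df, loci)


class TestFiltering:
    def test_min_loci_threshold(self):
        loci = [f"L{k}" for k in range(1, 10)]
        few = {f"L{k}": (100, 102) for k in range(1, 4)}     # 3 typed loci
        enough = {f"L{k}": (100, 102) for k in range(1, 5)}  # 4 typed loci
        full = {locus: (100, 100) for locus in loci}
        g = genotable([("i1", "A", few), ("i2", "A", enough), ("i3", "A", full)], loci)
        out = filter_individuals(g, min_loci=4)
        assert out.data["individual_id"].tolist() == ["i2", "i3"]
        # fully typed table passes unchanged
        g2 = genotable([("i1", "A", full), ("i2", "A", full)], loci)
        assert len(filter_individuals(g2)) == 2

    def test_emptied_population_raises(self):
        loci = ["L1", "L2"]
        g = genotable([("i1", "A", {"L1": (100, 100)}),
                       ("i2", "B", {"L1": (100, 100), "L2": (102, 102)})], loci)
        with pytest.raises(ValueError, match="A"):
            filter_individuals(g, min_loci=2)


class TestAlleleFrequencies:
    def test_counts_of_copies(self):
        g = genotable([("i1", "A", {"L1": (100, 100)}),
                       ("i2", "A", {"L1": (100, 102)})], ["L1"])
        f = allele_frequencies(g).set_index("allele")
        assert f.loc[100, "freq"] == pytest.approx(0.75)
        assert f.loc[102, "freq"] == pytest.approx(0.25)

    def test_untyped_locus_has_no_row(self):
        g = genotable([("i1", "A", {"L1": (100, 100)})], ["L1", "L2"])
        f = allele_frequencies(g)
        assert set(f["locus"]) == {"L1"}

    def test_frequencies_sum_to_one(self, small_sim):
        f = allele_frequencies(small_sim.genotypes)
        sums = f.groupby(["population_id", "locus"])["freq"].sum()
        np.testing.assert_allclose(sums, 1.0, rtol=1e-12)


class TestDiversity:
    def test_two_equifrequent_alleles(self):
        g = genotable([("i1", "A", {"L1": (100, 102)}),
                       ("i2", "A", {"L1": (102, 100)})], ["L1"])
        d = diversity(g).iloc[0]
        assert d["H_e"] == pytest.approx(0.5)
        assert d["I"] == pytest.approx(math.log(2))
        assert d["H_o"] == 1.0

    def test_monomorphic_locus(self):
        g = genotable([("i1", "A", {"L1": (100, 100)}),
                       ("i2", "A", {"L1": (100, 100)})], ["L1"])
        d = diversity(g).iloc[0]
        assert d["H_e"] == 0.0 and d["I"] == 0.0 and d["N_A"] == 1.0

    def test_four_equifrequent_alleles(self):
        g = genotable([("i1", "A", {"L1": (100, 102)}),
                       ("i2", "A", {"L1": (104, 106)})], ["L1"])
        d = diversity(g).iloc[0]
        assert d["H_e"] == pytest.approx(0.75)
        assert d["I"] == pytest.approx(math.log(4))

    def test_unbiased_he_applies_small_sample_correction(self):
        g = genotable([("i1", "A", {"L1": (100, 102)}),
                       ("i2", "A", {"L1": (102, 100)})], ["L1"])
        d = diversity(g, unbiased_he=True).iloc[0]
        assert d["H_e"] == pytest.approx(0.5 * 4 / 3)

    def test_private_alleles_counted_against_other_populations(self):
        g = genotable([("i1", "A", {"L1": (100, 104)}),
                       ("i2", "B", {"L1": (100, 102)})], ["L1"])
        d = diversity(g).set_index("population_id")
        assert d.loc["A", "P_Ap"] == 1.0  # 104 only in A
        assert d.loc["B", "P_Ap"] == 1.0  # 102 only in B

    @settings(max_examples=40, derandomize=True)
    @given(st.lists(st.floats(0.01, 1.0), min_size=2, max_size=8))
    def test_he_bounds_and_maximum_at_equifrequency(self, weights):
        p = np.array(weights) / np.sum(weights)
        he = 1 - (p ** 2).sum()
        k = len(p)
        assert 0.0 <= he <= 1 - 1 / k + 1e-12  # maximized at equifrequent alleles

    def test_hardy_weinberg_ho_tracks_he(self):
        # under HWE sampling, observed ~ expected heterozygosity
        diffs = []
        for seed in range(20):
            cfg = td.SimulationConfig(n_populations=2, n_individuals=200, missing_rate=0.0)
            sim = td.simulate(cfg, seed=seed)
            d = diversity(sim.genotypes)
            diffs.extend((d["H_o"] - d["H_e"]).abs().tolist())
        assert np.mean(diffs) < 0.02

    def test_selfing_depresses_observed_heterozygosity(self):
        hos = []
        for s_rate in (0.0, 0.4, 0.8):
            cfg = td.SimulationConfig(n_populations=2, n_individuals=150,
                                      missing_rate=0.0, selfing_rate=s_rate)
            d = diversity(td.simulate(cfg, seed=5).genotypes)
            hos.append(d["H_o"].mean())
        assert hos[0] > hos[1] > hos[2]


class TestNeiDistance:
    def freq_frame(self, profiles):
        rows = []
        for pop, loci in profiles.items():
            for locus, freqs in loci.items():
                for allele, fr in freqs.items():
                    if fr > 0:
                        rows.append({"population_id": pop, "locus": locus,
                                     "allele": allele, "freq": fr, "n_typed": 10})
        return pd.DataFrame(rows)

    def test_identical_profiles_distance_zero(self):
        f = self.freq_frame({"A": {"L1": {1: 0.5, 2: 0.5}},
                             "B": {"L1": {1: 0.5, 2: 0.5}}})
        assert nei_distance(f, "A", "B") == pytest.approx(0.0, abs=1e-12)

    def test_half_overlapping_alleles_give_ln2(self):
        # p_A = (.5,.5,0), p_B = (0,.5,.5): I_N = 0.25/0.5 -> D = ln 2
        f = self.freq_frame({"A": {"L1": {1: 0.5, 2: 0.5}},
                             "B": {"L1": {2: 0.5, 3: 0.5}}})
        assert nei_distance(f, "A", "B") == pytest.approx(math.log(2))

    def test_disjoint_alleles_undefined(self):
        f = self.freq_frame({"A": {"L1": {1: 1.0}}, "B": {"L1": {2: 1.0}}})
        assert math.isnan(nei_distance(f, "A", "B"))

    def test_symmetry_and_monotone_divergence(self):
        base = {"L1": {1: 0.5, 2: 0.5}}
        prev = -1.0
        for eps in (0.0, 0.1, 0.2, 0.3, 0.4):
            f = self.freq_frame({"A": base, "B": {"L1": {1: 0.5 - eps, 2: 0.5 + eps}}})
            d_ab, d_ba = nei_distance(f, "A", "B"), nei_distance(f, "B", "A")
            assert d_ab == pytest.approx(d_ba)
            assert d_ab > prev
            prev = d_ab

    def test_matrix_symmetric_zero_diagonal(self, small_sim):
        f = allele_frequencies(small_sim.genotypes)
        mat = nei_distance_matrix(f)
        arr = mat.to_numpy()
        np.testing.assert_allclose(arr, arr.T)
        np.testing.assert_allclose(np.diag(arr), 0.0)


class TestPCoA:
    def test_collinear_points_recovered_on_axis_one(self):
        d = pd.DataFrame([[0, 1, 2], [1, 0, 1], [2, 1, 0]],
                         index=list("abc"), columns=list("abc"), dtype=float)
        res = pcoa(d)
        axis1 = res.coordinates["PCo1"].to_numpy()
        spacing = np.abs(np.diff(np.sort(axis1)))
        np.testing.assert_allclose(spacing, [1.0, 1.0], atol=1e-9)
        assert abs(res.eigenvalues[1]) < 1e-9

    def test_all_zero_matrix_gives_zero_eigenvalues(self):
        d = pd.DataFrame(np.zeros((4, 4)), index=list("abcd"), columns=list("abcd"))
        res = pcoa(d)
        np.testing.assert_allclose(res.eigenvalues, 0.0, atol=1e-12)

    def test_euclidean_distances_reconstructed(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(10, 2))
        d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
        labels = [f"p{k}" for k in range(10)]
        res = pcoa(pd.DataFrame(d, index=labels, columns=labels))
        emb = res.coordinates.to_numpy()
        d_emb = np.sqrt(((emb[:, None, :] - emb[None, :, :]) ** 2).sum(-1))
        np.testing.assert_allclose(d_emb, d, atol=1e-8)

    def test_eigenvalue_sum_equals_centered_trace(self):
        rng = np.random.default_rng(2)
        pts = rng.normal(size=(8, 3))
        d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
        res = pcoa(pd.DataFrame(d))
        n = 8
        j = np.eye(n) - np.ones((n, n)) / n
        b = -0.5 * j @ (d ** 2) @ j
        assert res.eigenvalues.sum() == pytest.approx(np.trace(b), abs=1e-9)

    def test_agrees_with_reference_implementation(self, small_sim):
        skbio_ordination = pytest.importorskip("skbio.stats.ordination")
        from skbio import DistanceMatrix

        f = allele_frequencies(small_sim.genotypes)
        d = nei_distance_matrix(f)
        ours = pcoa(d)
        theirs = skbio_ordination.pcoa(DistanceMatrix(d.to_numpy(), ids=list(d.index)),
                                       method="eigh")
        pos = theirs.eigvals[theirs.eigvals > 1e-10].to_numpy()
        np.testing.assert_allclose(np.sort(ours.eigenvalues[ours.eigenvalues > 1e-10]),
                                   np.sort(pos), rtol=1e-8)
        # coordinates agree up to per-axis sign
        k = min(3, ours.coordinates.shape[1])
        for ax in range(k):
            a = ours.coordinates.iloc[:, ax].to_numpy()
            b = theirs.samples.iloc[:, ax].to_numpy()
            assert min(np.abs(a - b).max(), np.abs(a + b).max()) < 1e-8

    def test_undefined_entries_rejected(self):
        d = pd.DataFrame([[0, np.nan], [np.nan, 0]], index=list("ab"), columns=list("ab"))
        with pytest.raises(ValueError, match="subset"):
            pcoa(d)


def test_individual_distance_allele_sharing():
    g = genotable([("i1", "A", {"L1": (100, 100)}),
                   ("i2", "A", {"L1": (100, 102)}),
                   ("i3", "A", {"L1": (104, 106)})], ["L1"])
    d = individual_distance(g)
    assert d.loc["i1", "i2"] == pytest.approx(0.5)   # one shared copy
    assert d.loc["i1", "i3"] == pytest.approx(1.0)   # nothing shared
    assert d.loc["i1", "i1"] == 0.0
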