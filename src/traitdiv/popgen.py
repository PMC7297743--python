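"""Microsatellite diversity indices, Nei genetic distance and PCoA.

Indices per population and locus, averaged (unweighted) over typed loci:

* ``N_A``  — allelic richness, the number of alleles observed;
* ``P_Ap`` — private allelic richness, alleles found in no other population;
* ``H_o``  — observed heterozygosity, the heterozygote fraction among typed
  individuals;
* ``H_e``  — Nei gene diversity 1 - sum(p^2); the small-sample unbiased
  variant 2N/(2N-1) * H_e is available behind ``unbiased_he=True``;
* ``I``    — Shannon's information index -sum(p ln p).

Nei's standard genetic distance D = -ln I_N accumulates the identity
numerator and the two denominator terms across loci before taking the ratio.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import GenotypeTable

logger = logging.getLogger("traitdiv")


def filter_individuals(g: GenotypeTable, min_loci: int = 4) -> GenotypeTable:
    """Drop individuals typed at fewer than ``min_loci`` loci (logged per population)."""
    typed = g.n_typed_loci().to_numpy()
    keep = typed >= min_loci
    removed = g.data.loc[~keep]
    if len(removed):
        for pop, grp in removed.groupby("population_id"):
            logger.info("filter_individuals: removed %d of population %s", len(grp), pop)
    out = g.data.loc[keep].reset_index(drop=True)
    emptied = set(g.populations) - set(out["population_id"])
    if emptied:
        raise ValueError(f"filtering at min_loci={min_loci} emptied populations: {sorted(emptied)}")
    return GenotypeTable(out, list(g.loci))


def allele_frequencies(g: GenotypeTable) -> pd.DataFrame:
    """Relative allele frequencies per population x locus.

    Returns columns ``population_id, locus, allele, freq, n_typed`` where
    ``freq`` = allele copies / (2 x individuals typed at the locus). Loci with
    no typed individual in a population have no rows (flagged in the log).
    """
    rows = []
    for pop, grp in g.data.groupby("population_id", sort=False):
        for locus in g.loci:
            a = pd.concat([grp[f"{locus}_1"], grp[f"{locus}_2"]]).dropna()
            n_typed = grp[f"{locus}_1"].notna().sum()
            if n_typed == 0:
                logger.warning("allele_frequencies: %s untyped at %s", pop, locus)
                continue
            counts = a.value_counts()
            for allele, count in counts.items():
                rows.append({"population_id": pop, "locus": locus, "allele": int(allele),
                             "freq": count / (2 * n_typed), "n_typed": int(n_typed)})
    return pd.DataFrame(rows)


def _freq_vectors(freqs: pd.DataFrame, pop: str) -> dict[str, pd.Series]:
    sub = freqs[freqs["population_id"] == pop]
    return {locus: grp.set_index("allele")["freq"] for locus, grp in sub.groupby("locus")}


def diversity(g: GenotypeTable, unbiased_he: bool = False) -> pd.DataFrame:
    """Per-population multilocus diversity indices with SEs over loci."""
    freqs = allele_frequencies(g)
    if freqs.empty:
        raise ValueError("no typed loci in any population")
    # alleles present per locus per population, for private-allele counting
    present: dict[tuple[str, str], set] = {
        (r.population_id, r.locus): set()
        for r in freqs.itertuples()
    }
    for r in freqs.itertuples():
        present[(r.population_id, r.locus)].add(r.allele)
    pops = g.populations
    rows = []
    for pop in pops:
        per_locus: dict[str, list[float]] = {k: [] for k in ("N_A", "P_Ap", "H_o", "H_e", "I")}
        for locus in g.loci:
            key = (pop, locus)
            if key not in present:
                continue
            p = freqs[(freqs["population_id"] == pop) & (freqs["locus"] == locus)]
            pv = p["freq"].to_numpy()
            n_typed = int(p["n_typed"].iloc[0])
            he = 1.0 - float((pv ** 2).sum())
            if unbiased_he:
                he *= 2 * n_typed / (2 * n_typed - 1)
            per_locus["H_e"].append(he)
            per_locus["I"].append(float(-(pv * np.log(pv)).sum()))
            per_locus["N_A"].append(float(len(pv)))
            others = set().union(*(present.get((q, locus), set()) for q in pops if q != pop))
            per_locus["P_Ap"].append(float(len(present[key] - others)))
            grp = g.data[g.data["population_id"] == pop]
            a1, a2 = grp[f"{locus}_1"], grp[f"{locus}_2"]
            typed = a1.notna()
            per_locus["H_o"].append(float((a1[typed] != a2[typed]).mean()))
        if not per_locus["H_e"]:
            raise ValueError(f"population {pop} has no typed loci")
        row: dict = {"population_id": pop, "n_loci": len(per_locus["H_e"])}
        for k, vals in per_locus.items():
            arr = np.array(vals)
            row[k] = arr.mean()
            row[f"{k}_se"] = arr.std(ddof=1) / math.sqrt(len(arr)) if len(arr) > 1 else 0.0
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Nei standard genetic distance
# ---------------------------------------------------------------------------

def nei_distance(freqs: pd.DataFrame, pop_x: str, pop_y: str) -> float:
    """Nei (standard) genetic distance D = -ln I_N between two populations.

    I_N = sum_loci sum_alleles p_x p_y / sqrt(sum_loci sum p_x^2 * sum_loci
    sum p_y^2) over loci with frequencies in both populations. Returns NaN
    when the identity is zero (no shared alleles) and raises when the
    populations share no typed locus.
    """
    fx, fy = _freq_vectors(freqs, pop_x), _freq_vectors(freqs, pop_y)
    shared = sorted(set(fx) & set(fy))
    if not shared:
        raise ValueError(f"populations {pop_x} and {pop_y} share no typed locus")
    jxy = jx = jy = 0.0
    for locus in shared:
        px, py = fx[locus], fy[locus]
        both = px.index.union(py.index)
        vx = px.reindex(both, fill_value=0.0).to_numpy()
        vy = py.reindex(both, fill_value=0.0).to_numpy()
        jxy += float((vx * vy).sum())
        jx += float((vx ** 2).sum())
        jy += float((vy ** 2).sum())
    identity = jxy / math.sqrt(jx * jy)
    if identity <= 0:
        return float("nan")
    return -math.log(min(identity, 1.0))


def nei_distance_matrix(freqs: pd.DataFrame) -> pd.DataFrame:
    """Symmetric, zero-diagonal matrix of Nei distances over all populations."""
    pops = list(pd.unique(freqs["population_id"]))
    mat = np.zeros((len(pops), len(pops)))
    for i, x in enumerate(pops):
        for j in range(i + 1, len(pops)):
            d = nei_distance(freqs, x, pops[j])
            mat[i, j] = mat[j, i] = d
    return pd.DataFrame(mat, index=pops, columns=pops)


def individual_distance(g: GenotypeTable) -> pd.DataFrame:
    """Allele-sharing dissimilarity between individuals (1 - mean shared fraction).

    Per locus typed in both individuals the similarity is the fraction of
    allele copies shared (0, 0.5 or 1); the distance is one minus the mean over
    shared loci. This is an approximation to microsatellite individual
    distances used by common GUI toolkits, adequate for ordination.
    """
    ids = g.data["individual_id"].tolist()
    n = len(ids)
    alleles = {
        locus: g.data[[f"{locus}_1", f"{locus}_2"]].to_numpy(dtype=float)
        for locus in g.loci
    }
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            sims = []
            for locus in g.loci:
                a = alleles[locus][i]
                b = alleles[locus][j]
                if np.isnan(a[0]) or np.isnan(b[0]):
                    continue
                # multiset intersection: shared allele copies (0, 1 or 2)
                shared = sum(min((a == al).sum(), (b == al).sum()) for al in set(a))
                sims.append(shared / 2.0)
            mat[i, j] = mat[j, i] = 1.0 - float(np.mean(sims)) if sims else np.nan
    return pd.DataFrame(mat, index=ids, columns=ids)


# ---------------------------------------------------------------------------
# principal coordinates analysis
# ---------------------------------------------------------------------------

@dataclass
class PCoAResult:
    coordinates: pd.DataFrame     # axes for positive eigenvalues only
    eigenvalues: np.ndarray       # all eigenvalues, descending (negatives kept)
    percent_variance: np.ndarray  # per positive axis, % of positive eigenvalue sum


def pcoa(d: pd.DataFrame) -> PCoAResult:
    """Classical scaling: Gower double-centering of -0.5 d^2, then eigh.

    Negative eigenvalues (non-Euclidean distances) are reported, never
    clipped; coordinates are returned for positive axes only. Undefined (NaN)
    entries are an error: subset the matrix first.
    """
    mat = np.asarray(d, dtype=float)
    if np.isnan(mat).any():
        raise ValueError("distance matrix has undefined entries; subset before ordination")
    if not np.allclose(mat, mat.T):
        raise ValueError("distance matrix must be symmetric")
    n = mat.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (mat ** 2) @ j
    eigval, eigvec = np.linalg.eigh((b + b.T) / 2)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    pos = eigval > 1e-12 * max(eigval.max(), 1.0)
    coords = eigvec[:, pos] * np.sqrt(eigval[pos])
    labels = list(d.index) if isinstance(d, pd.DataFrame) else list(range(n))
    pos_sum = eigval[pos].sum()
    pct = 100.0 * eigval[pos] / pos_sum if pos_sum > 0 else np.zeros(pos.sum())
    return PCoAResult(
        coordinates=pd.DataFrame(coords, index=labels,
                                 columns=[f"PCo{i + 1}" for i in range(int(pos.sum()))]),
        eigenvalues=eigval,
        percent_variance=pct,
    )
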