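"""Pairwise differentiation: AMOVA F_ST, R_ST, and empirical standardization.

F_ST is computed from a two-level AMOVA treating the 2n chromosomes of
each population as the units, with squared inter-haplotype distance
d^2 = 0/1 under allele identity (HLA) or d^2 = (size_i - size_j)^2 for
microsatellite repeat sizes (R_ST).  Negative estimates are retained as
computed.

Z_ST places an HLA F_ST in the context of a genome-wide microsatellite
background for the same population pair:

    Z_ST = (F_ST_HLA - mean(F_ST_msats)) / SD(F_ST_msats)

with an empirical p-value equal to the proportion of microsatellite loci
whose F_ST strictly exceeds the HLA value.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import Cohort, MsatPanel, PopulationSample, allele_frequencies


def _amova_fst_from_pair_sums(
    n1: int, n2: int, ssd_within_1: float, ssd_within_2: float, ssd_total: float
) -> float:
    """Two-level AMOVA variance components from sums of squared deviations."""
    n_tot = n1 + n2
    ssd_within = ssd_within_1 + ssd_within_2
    ssd_among = ssd_total - ssd_within
    df_within = n_tot - 2
    sigma_w = ssd_within / df_within if df_within > 0 else 0.0
    n_c = n_tot - (n1**2 + n2**2) / n_tot  # df_among = 1
    sigma_a = (ssd_among - sigma_w) / n_c
    denom = sigma_a + sigma_w
    if denom == 0:
        return 0.0
    return float(sigma_a / denom)


def _identity_pair_sums(counts: dict) -> tuple[int, float]:
    """(n, sum over within pairs of d^2) for allele-identity distance."""
    c = np.array(list(counts.values()), dtype=float)
    n = int(c.sum())
    same = (c * (c - 1) / 2).sum()
    return n, n * (n - 1) / 2 - same


def pairwise_fst(
    pop_a: PopulationSample, pop_b: PopulationSample, locus: str
) -> float:
    """AMOVA F_ST between two populations at one HLA locus (identity distance)."""
    fa = allele_frequencies(pop_a, locus)
    fb = allele_frequencies(pop_b, locus)
    return fst_from_counts(fa.counts, fb.counts)


def fst_from_counts(counts_a: dict, counts_b: dict) -> float:
    """AMOVA F_ST from two allele-copy count dictionaries."""
    n1, w1 = _identity_pair_sums(counts_a)
    n2, w2 = _identity_pair_sums(counts_b)
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 chromosomes in each population")
    pooled: dict = dict(counts_a)
    for a, cnt in counts_b.items():
        pooled[a] = pooled.get(a, 0) + cnt
    if len(pooled) == 1:
        return 0.0  # both populations identically monomorphic, by convention
    _, wt = _identity_pair_sums(pooled)
    n_tot = n1 + n2
    ssd_total = wt / n_tot
    return _amova_fst_from_pair_sums(n1, n2, w1 / n1, w2 / n2, ssd_total)


def _size_pair_sums(sizes: np.ndarray) -> float:
    """sum over pairs of (x_i - x_j)^2 = n * sum x^2 - (sum x)^2."""
    x = np.asarray(sizes, dtype=float)
    return float(x.size * (x**2).sum() - x.sum() ** 2)


def rst(sizes_a: np.ndarray, sizes_b: np.ndarray) -> float:
    """AMOVA R_ST between two vectors of microsatellite allele sizes."""
    a = np.asarray(sizes_a, dtype=float)
    b = np.asarray(sizes_b, dtype=float)
    n1, n2 = a.size, b.size
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 chromosomes in each population")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return 0.0
    ssd_total = _size_pair_sums(pooled) / (n1 + n2)
    return _amova_fst_from_pair_sums(
        n1, n2, _size_pair_sums(a) / n1, _size_pair_sums(b) / n2, ssd_total
    )


def msat_fst_vector(
    panel: MsatPanel, pop_a: str, pop_b: str, use_rst: bool = False
) -> np.ndarray:
    """Per-marker F_ST (or R_ST) between two populations over the whole panel.

    Markers monomorphic in the pair contribute 0.0 (not dropped), keeping
    the panel-size denominator of the empirical p-value stable.
    """
    rows_a = panel.population_rows(pop_a)
    rows_b = panel.population_rows(pop_b)
    out = np.zeros(panel.n_markers)
    for j in range(panel.n_markers):
        sa = panel.marker_sizes(rows_a, j)
        sb = panel.marker_sizes(rows_b, j)
        if sa.size < 2 or sb.size < 2:
            out[j] = 0.0
            continue
        if use_rst:
            out[j] = rst(sa, sb)
        else:
            ca = dict(zip(*np.unique(sa, return_counts=True)))
            cb = dict(zip(*np.unique(sb, return_counts=True)))
            out[j] = fst_from_counts(ca, cb)
    return out


def fst_matrix(cohort: Cohort, locus: str) -> pd.DataFrame:
    """Symmetric population-by-population F_ST matrix at one locus."""
    names = [p.name for p in cohort.populations if p.n_chromosomes(locus) >= 2]
    mat = pd.DataFrame(0.0, index=names, columns=names)
    for a, b in itertools.combinations(names, 2):
        val = pairwise_fst(cohort.population(a), cohort.population(b), locus)
        mat.loc[a, b] = mat.loc[b, a] = val
    return mat


def region_summary(
    matrices: dict[str, pd.DataFrame], region_map: dict[str, str]
) -> pd.DataFrame:
    """Mean pairwise F_ST within and between regions, per locus plus HLA mean.

    Row per region pair (within pairs have region1 == region2); columns are
    the per-locus means and ``mean_HLA`` (arithmetic mean of locus values).
    """
    loci = list(matrices)
    regions = sorted(set(region_map.values()))
    rows = []
    for i, r1 in enumerate(regions):
        for r2 in regions[i:]:
            row: dict[str, object] = {
                "region1": r1,
                "region2": r2,
                "comparison": "within" if r1 == r2 else "between",
            }
            any_pairs = False
            for locus in loci:
                mat = matrices[locus]
                pops1 = [p for p in mat.index if region_map.get(p) == r1]
                pops2 = [p for p in mat.index if region_map.get(p) == r2]
                if r1 == r2:
                    pairs = list(itertools.combinations(pops1, 2))
                else:
                    pairs = [(a, b) for a in pops1 for b in pops2]
                if not pairs:
                    row[locus] = np.nan
                    continue
                any_pairs = True
                row[locus] = float(np.mean([mat.loc[a, b] for a, b in pairs]))
            if not any_pairs:
                continue
            locus_vals = [row[l] for l in loci if not pd.isna(row[l])]
            row["mean_HLA"] = float(np.mean(locus_vals)) if locus_vals else np.nan
            rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class ZstResult:
    pair: tuple[str, str]
    locus: str
    fst_hla: float
    msat_mean: float
    msat_sd: float
    zst: float
    empirical_p: float


def zst(
    pair: tuple[str, str], locus: str, hla_fst: float, msat_fst: np.ndarray
) -> ZstResult:
    """Standardize one HLA F_ST against the pair's microsatellite background."""
    v = np.asarray(msat_fst, dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 microsatellite loci")
    mean, sd = float(v.mean()), float(v.std(ddof=1))
    if sd == 0:
        raise ValueError("zero SD in the microsatellite F_ST vector")
    return ZstResult(
        pair=pair,
        locus=locus,
        fst_hla=hla_fst,
        msat_mean=mean,
        msat_sd=sd,
        zst=(hla_fst - mean) / sd,
        empirical_p=float((v > hla_fst).mean()),
    )


def zst_region_table(
    zst_results: list[ZstResult], region_map: dict[str, str],
    significance_line: float = 3.0,
) -> pd.DataFrame:
    """Region-pair aggregation of -log(empirical p), per locus.

    The p-value resolution is one over the panel size; zeros are floored
    at half that resolution before taking logs.  ``-log(p) >= 3``
    corresponds to the 0.05 significance level for a 678-locus panel.
    """
    rows = []
    for r in zst_results:
        r1, r2 = sorted(region_map[p] for p in r.pair)
        rows.append(
            {"region_pair": f"{r1}:{r2}", "locus": r.locus,
             "zst": r.zst, "empirical_p": r.empirical_p}
        )
    df = pd.DataFrame(rows)
    floor = 0.5 * df["empirical_p"][df["empirical_p"] > 0].min() \
        if (df["empirical_p"] > 0).any() else 1e-3
    df["neg_log_p"] = -np.log(df["empirical_p"].clip(lower=floor))
    out = (
        df.groupby(["region_pair", "locus"])
        .agg(mean_zst=("zst", "mean"), mean_neg_log_p=("neg_log_p", "mean"))
        .reset_index()
    )
    out["significant"] = out["mean_neg_log_p"] >= significance_line
    return out
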