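"""Heterozygosity summaries and HLA-vs-microsatellite diversity comparisons.

Population-level: per-locus sample heterozygosity with the unbiased
n/(n-1) correction, distinct-allele counts, Pearson correlation of HLA
heterozygosity with mean microsatellite heterozygosity, and regional
contrasts (one-way ANOVA + Tukey HSD).

Individual-level: per-individual counts of homozygous HLA loci and the
proportion of homozygous microsatellite loci, per-population regressions
of one on the other, and a per-region trend test across the homozygosity
classes {0, 1, 2+}.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .data import Cohort, FrequencyTable, MsatPanel, PopulationSample, allele_frequencies


@dataclass
class DiversityStats:
    """Allele count k, unbiased sample heterozygosity H, and chromosome count n."""

    k: int
    H: float
    n: int


def heterozygosity(f: FrequencyTable, corrected: bool = True) -> DiversityStats:
    """H = (n/(n-1)) (1 - sum p_i^2); set ``corrected=False`` for the plug-in value."""
    n = f.n
    if n < 2:
        raise ValueError("need at least 2 chromosomes")
    p = np.array(list(f.frequencies.values()))
    h = 1.0 - float((p**2).sum())
    if corrected:
        h *= n / (n - 1)
    return DiversityStats(k=f.k, H=h, n=n)


def cohort_allele_count(cohort: Cohort, locus: str) -> int:
    """Number of distinct two-field alleles pooled over every population."""
    return len(cohort.allele_set(locus))


def msat_mean_heterozygosity(panel: MsatPanel, population: str,
                             corrected: bool = True) -> float:
    """Mean sample heterozygosity over all markers typed in one population."""
    rows = panel.population_rows(population)
    if rows.size == 0:
        raise ValueError(f"no individuals for population {population!r}")
    hets = []
    for j in range(panel.n_markers):
        sizes = panel.marker_sizes(rows, j)
        n = sizes.size
        if n < 2:
            continue
        _, counts = np.unique(sizes, return_counts=True)
        h = 1.0 - float(((counts / n) ** 2).sum())
        if corrected:
            h *= n / (n - 1)
        hets.append(h)
    return float(np.mean(hets))


def population_level_correlation(
    hla_h: np.ndarray | list[float], msat_h: np.ndarray | list[float]
) -> tuple[float, float]:
    """Pearson correlation (r, two-sided p) between matched diversity vectors."""
    x = np.asarray(hla_h, dtype=float)
    y = np.asarray(msat_h, dtype=float)
    if x.size < 3 or x.size != y.size:
        raise ValueError("need matched vectors of length >= 3")
    if np.allclose(x, x[0]) or np.allclose(y, y[0]):
        raise ValueError("zero variance in one of the vectors")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def regional_contrasts(
    h_by_population: dict[str, float],
    region_map: dict[str, str],
    exclude: set[str] = frozenset({"Ache"}),
) -> pd.DataFrame:
    """One-way ANOVA over regions followed by Tukey HSD pairwise contrasts.

    Populations in ``exclude`` (the Aché outlier by default) are dropped.
    Regions with fewer than two populations are skipped with a warning.
    Returns a frame with columns region1, region2, diff, p_adj.
    """
    pops = [p for p in h_by_population if p not in exclude]
    regions = pd.Series({p: region_map[p] for p in pops})
    counts = regions.value_counts()
    keep = counts[counts >= 2].index
    skipped = sorted(set(counts.index) - set(keep))
    if skipped:
        warnings.warn(f"regions with a single population skipped: {skipped}")
    pops = [p for p in pops if regions[p] in keep]
    if len(keep) < 2:
        raise ValueError("need at least two regions with >= 2 populations")
    values = np.array([h_by_population[p] for p in pops])
    labels = np.array([region_map[p] for p in pops])
    if np.allclose(values, values[0]):
        pairs = sorted(keep)
        rows = [
            {"region1": a, "region2": b, "diff": 0.0, "p_adj": 1.0}
            for i, a in enumerate(pairs)
            for b in pairs[i + 1 :]
        ]
        return pd.DataFrame(rows)
    tukey = pairwise_tukeyhsd(values, labels)
    frame = pd.DataFrame(
        tukey.summary().data[1:], columns=tukey.summary().data[0]
    )
    return pd.DataFrame(
        {
            "region1": frame["group1"],
            "region2": frame["group2"],
            "diff": frame["meandiff"].astype(float),
            "p_adj": frame["p-adj"].astype(float),
        }
    )


# ---------------------------------------------------------------------------
# Individual-level zygosity


def homozygous_hla_count(pop: PopulationSample) -> pd.Series:
    """Per individual, the number of typed HLA loci that are homozygous."""
    out = {}
    for ind in pop.individuals:
        out[ind.ident] = sum(a == b for a, b in ind.genotypes.values())
    return pd.Series(out, dtype=int)


def zygosity_table(cohort: Cohort, msat_panel: MsatPanel) -> pd.DataFrame:
    """Join per-individual HLA homozygous-locus counts with msat homozygosity.

    Columns: population, region, id, hla_hom_count, hla_class (0/1/2+),
    msat_hom_prop.
    """
    msat_prop = dict(zip(msat_panel.index, msat_panel.homozygous_proportion()))
    rows = []
    for pop in cohort.populations:
        counts = homozygous_hla_count(pop)
        for ind in pop.individuals:
            key = (pop.name, ind.ident)
            if key not in msat_prop:
                continue
            c = int(counts[ind.ident])
            rows.append(
                {
                    "population": pop.name,
                    "region": cohort.region_map[pop.name],
                    "id": ind.ident,
                    "hla_hom_count": c,
                    "hla_class": "2+" if c >= 2 else str(c),
                    "msat_hom_prop": msat_prop[key],
                }
            )
    return pd.DataFrame(rows)


def individual_level_association(
    cohort: Cohort,
    msat_panel: MsatPanel,
    alpha: float = 0.05,
    printed_threshold: float | None = None,
) -> pd.DataFrame:
    """Per population, regress msat homozygous proportion on HLA homozygous count.

    Returns slope, two-sided p, and significance flags under a Bonferroni
    threshold alpha / (number of populations tested) and optionally a fixed
    ``printed_threshold``.
    """
    table = zygosity_table(cohort, msat_panel)
    rows = []
    for name, sub in table.groupby("population"):
        x = sub["hla_hom_count"].to_numpy(dtype=float)
        y = sub["msat_hom_prop"].to_numpy(dtype=float)
        if len(x) < 3 or np.allclose(x, x[0]):
            rows.append({"population": name, "slope": np.nan, "p": np.nan})
            continue
        fit = stats.linregress(x, y)
        rows.append({"population": name, "slope": fit.slope, "p": fit.pvalue})
    out = pd.DataFrame(rows)
    n_tested = int(out["p"].notna().sum())
    bonferroni = alpha / max(n_tested, 1)
    out["bonferroni_threshold"] = bonferroni
    out["significant"] = out["p"] < bonferroni
    if printed_threshold is not None:
        out["significant_at_printed"] = out["p"] < printed_threshold
    return out


def homozygosity_class_trend(
    cohort: Cohort, msat_panel: MsatPanel, region: str
) -> tuple[float, float, pd.DataFrame]:
    """Trend of msat homozygosity across HLA classes {0, 1, 2+} in one region.

    Linear regression of the msat homozygous proportion on class score
    {0, 1, 2}; empty classes are merged upward with a warning.  Returns
    (slope, p, class-summary frame).
    """
    table = zygosity_table(cohort, msat_panel)
    sub = table[table["region"] == region]
    if sub.empty:
        raise ValueError(f"no individuals in region {region!r}")
    score = sub["hla_hom_count"].clip(upper=2).to_numpy(dtype=float)
    present = np.unique(score)
    if present.size < 2:
        warnings.warn(f"region {region}: fewer than two zygosity classes present")
        return np.nan, np.nan, pd.DataFrame()
    if present.size == 2 and set(present) != {0.0, 1.0}:
        warnings.warn(f"region {region}: empty class merged upward")
        score = np.minimum(score, 1.0)
    y = sub["msat_hom_prop"].to_numpy(dtype=float)
    fit = stats.linregress(score, y)
    summary = (
        sub.assign(cls=sub["hla_hom_count"].clip(upper=2))
        .groupby("cls")["msat_hom_prop"]
        .agg(["count", "mean"])
        .reset_index()
    )
    return float(fit.slope), float(fit.pvalue), summary


def diversity_table(cohort: Cohort, corrected: bool = True) -> pd.DataFrame:
    """Per-population per-locus chromosome counts and heterozygosities.

    The layout mirrors a sample-size/heterozygosity summary table: one row
    per population with region, then n and H per locus.
    """
    loci = sorted({locus for p in cohort.populations
                   for ind in p.individuals for locus in ind.genotypes})
    rows = []
    for pop in cohort.populations:
        row: dict[str, object] = {
            "population": pop.name,
            "region": cohort.region_map[pop.name],
        }
        for locus in loci:
            n = pop.n_chromosomes(locus)
            row[f"n_{locus}"] = n
            if n >= 2:
                row[f"H_{locus}"] = heterozygosity(
                    allele_frequencies(pop, locus), corrected=corrected
                ).H
            else:
                row[f"H_{locus}"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)
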