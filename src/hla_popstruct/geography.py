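"""Classification of alleles as endemic / LFD / other, and category summaries.

For every allele observed in the Native American cohort, the unweighted
mean frequency across Native populations is compared with the mean across
the (non-flagged) reference-panel populations:

* ``endemic`` — reference mean exactly zero (present only in the Americas);
* ``LFD`` — present elsewhere but at least 3-fold more common in the
  Americas (ratio >= 3, inclusive);
* ``other`` — everything else.

Endemic/LFD calls backed by 3 or fewer allele copies in the Americas are
flagged ``poorly_supported``; an LFD allele poorly supported in both the
primary comparison and an optional secondary (validation) comparison is
removed from the final classified list.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import AlleleName, Cohort, ReferencePanel, allele_frequencies

RATIO_THRESHOLD = 3.0
POOR_SUPPORT_COPIES = 3


@dataclass
class AlleleClassification:
    allele: AlleleName
    native_mean: float
    reference_mean: float
    ratio: float  # inf for endemic alleles
    copies: int
    category: str  # "endemic" | "LFD" | "other"
    poorly_supported: bool
    removed: bool = False  # LFD poorly supported in both datasets


def _native_means_and_copies(
    cohort: Cohort, locus: str
) -> tuple[dict[AlleleName, float], dict[AlleleName, int]]:
    pops = [p for p in cohort.native_populations() if p.n_chromosomes(locus) >= 2]
    if not pops:
        raise ValueError(f"no Native populations typed at {locus}")
    tables = [allele_frequencies(p, locus) for p in pops]
    alleles = sorted({a for t in tables for a in t.counts})
    means = {
        a: float(np.mean([t.frequency(a) for t in tables])) for a in alleles
    }
    copies = {a: int(sum(t.counts.get(a, 0) for t in tables)) for a in alleles}
    return means, copies


def classify_alleles(
    cohort: Cohort,
    panel: ReferencePanel,
    locus: str,
    secondary: "dict[AlleleName, bool] | None" = None,
) -> list[AlleleClassification]:
    """Classify every allele observed at ``locus`` in the Native cohort.

    ``secondary`` maps alleles to their poorly-supported status in an
    independent validation split; when absent, the both-datasets removal
    filter degrades to the primary-only flag (with a warning).
    """
    means, copies = _native_means_and_copies(cohort, locus)
    if secondary is None:
        warnings.warn(
            "no secondary validation split: LFD removal filter uses the "
            "primary dataset only"
        )
    out: list[AlleleClassification] = []
    for allele, native_mean in means.items():
        if copies[allele] == 0:
            raise ValueError(f"{allele}: present in cohort with zero copies")
        ref_mean = panel.mean_frequency(allele)
        if ref_mean == 0.0:
            category, ratio = "endemic", float("inf")
        else:
            ratio = native_mean / ref_mean
            category = "LFD" if ratio >= RATIO_THRESHOLD else "other"
        poor = category in ("endemic", "LFD") and copies[allele] <= POOR_SUPPORT_COPIES
        removed = False
        if category == "LFD" and poor:
            poor_secondary = secondary.get(allele, True) if secondary else True
            removed = poor_secondary
        out.append(
            AlleleClassification(
                allele=allele,
                native_mean=native_mean,
                reference_mean=ref_mean,
                ratio=ratio,
                copies=copies[allele],
                category=category,
                poorly_supported=poor,
                removed=removed,
            )
        )
    return out


def final_category_map(
    classifications: list[AlleleClassification],
) -> dict[AlleleName, str]:
    """allele -> category after applying the removal filter (removed -> other)."""
    return {
        c.allele: (c.category if not c.removed else "other")
        for c in classifications
    }


def category_frequency_sums(
    cohort: Cohort,
    classifications_by_locus: dict[str, list[AlleleClassification]],
) -> pd.DataFrame:
    """Per population and locus, the frequency sums of endemic and LFD alleles.

    Columns: population, region, locus, endemic_sum, lfd_sum, other_sum
    (the three sums partition 1 at each population x locus).
    """
    rows = []
    for locus, classifications in classifications_by_locus.items():
        cat = final_category_map(classifications)
        for pop in cohort.populations:
            if pop.n_chromosomes(locus) < 2:
                continue
            freqs = allele_frequencies(pop, locus).frequencies
            sums = {"endemic": 0.0, "LFD": 0.0, "other": 0.0}
            for allele, f in freqs.items():
                sums[cat.get(allele, "other")] += f
            rows.append(
                {
                    "population": pop.name,
                    "region": cohort.region_map[pop.name],
                    "locus": locus,
                    "endemic_sum": sums["endemic"],
                    "lfd_sum": sums["LFD"],
                    "other_sum": sums["other"],
                }
            )
    return pd.DataFrame(rows)


def region_category_means(
    sums: pd.DataFrame,
    exclude: set[str] = frozenset({"Ache"}),
    native_regions: tuple[str, ...] = ("NAM", "MEA", "SAA", "SAL"),
) -> pd.DataFrame:
    """Regional and continental means of the per-population category sums.

    The outlier populations in ``exclude`` are dropped from every cell;
    the ``all_regions`` column averages over every included Native
    population (not over regional means).
    """
    sub = sums[
        ~sums["population"].isin(exclude) & sums["region"].isin(native_regions)
    ]
    rows = []
    for locus, locus_df in sub.groupby("locus"):
        for column, label in (("endemic_sum", "endemic"), ("lfd_sum", "LFD")):
            row: dict[str, object] = {"locus": locus, "category": label}
            row["all_regions"] = float(locus_df[column].mean())
            for region in native_regions:
                cell = locus_df[locus_df["region"] == region][column]
                row[region] = float(cell.mean()) if len(cell) else np.nan
            rows.append(row)
    return pd.DataFrame(rows)


def category_msat_correlation(
    sums: pd.DataFrame, msat_h: dict[str, float]
) -> pd.DataFrame:
    """Pearson r of (endemic + LFD total frequency) vs msat heterozygosity, per locus."""
    from scipy import stats

    rows = []
    for locus, locus_df in sums.groupby("locus"):
        pops = [p for p in locus_df["population"] if p in msat_h]
        sub = locus_df.set_index("population").loc[pops]
        total = (sub["endemic_sum"] + sub["lfd_sum"]).to_numpy()
        h = np.array([msat_h[p] for p in pops])
        if len(pops) < 3 or np.allclose(total, total[0]) or np.allclose(h, h[0]):
            rows.append({"locus": locus, "r": np.nan, "p": np.nan, "n": len(pops)})
            continue
        r, p = stats.pearsonr(total, h)
        rows.append({"locus": locus, "r": float(r), "p": float(p), "n": len(pops)})
    return pd.DataFrame(rows)
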