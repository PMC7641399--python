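"""Two-locus haplotype frequencies by EM, and allele-specific heterozygosity.

The EM ("gene counting") algorithm maximizes the multinomial likelihood of
unphased two-locus genotypes over haplotype frequencies.  Only individuals
heterozygous at both loci are phase-ambiguous; the E-step splits each such
individual between its two phase resolutions in proportion to the current
haplotype frequencies, and the M-step re-normalizes expected haplotype
counts.  The log-likelihood is non-decreasing at every iteration (asserted),
and the best of several random restarts plus a linkage-equilibrium start is
returned.

Allele-specific heterozygosity (ASH) of allele a at locus L with partner
locus M is the plug-in heterozygosity of the conditional distribution of
partner alleles on haplotypes carrying a:

    ASH(a) = 1 - sum_b (h_ab / p_a)^2.

Low ASH marks alleles riding few haplotype backgrounds (young or swept
alleles); it is bounded by 1 - 1/m for m observed partner alleles.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import AlleleName, Cohort, PopulationSample


@dataclass
class HaplotypeTable:
    loci: tuple[str, str]
    frequencies: dict[tuple, float]  # (allele_A, allele_B) -> frequency
    log_likelihood: float
    iterations: int
    converged: bool

    def marginal(self, side: int) -> dict:
        out: dict = {}
        for hap, f in self.frequencies.items():
            out[hap[side]] = out.get(hap[side], 0.0) + f
        return out


def _phase_resolutions(ga: tuple, gb: tuple) -> list[tuple[tuple, tuple]]:
    """Possible (hap1, hap2) pairs for one individual's two-locus genotype."""
    a1, a2 = ga
    b1, b2 = gb
    res = [((a1, b1), (a2, b2))]
    if a1 != a2 and b1 != b2:
        res.append(((a1, b2), (a2, b1)))
    return res


def em_haplotypes(
    genotypes: list[tuple[tuple, tuple]],
    tol: float = 1e-8,
    max_iter: int = 10_000,
    restarts: int = 10,
    seed: int = 0,
    loci: tuple[str, str] = ("A", "B"),
) -> HaplotypeTable:
    """EM haplotype frequency estimation from unphased two-locus genotypes.

    ``genotypes`` is a list of ``((a1, a2), (b1, b2))`` unordered allele
    pairs, one per individual typed at both loci.
    """
    n = len(genotypes)
    if n < 2:
        raise ValueError("need at least 2 individuals")
    resolutions = [_phase_resolutions(ga, gb) for ga, gb in genotypes]
    haps = sorted({h for res in resolutions for pair in res for h in pair})
    hap_idx = {h: i for i, h in enumerate(haps)}
    m = len(haps)
    # per individual: array of (i, j) hap-index pairs
    res_idx = [
        np.array([[hap_idx[p[0]], hap_idx[p[1]]] for p in res])
        for res in resolutions
    ]

    def log_lik(f: np.ndarray) -> float:
        total = 0.0
        for pairs in res_idx:
            prob = 0.0
            for i, j in pairs:
                prob += (1 if i == j else 2) * f[i] * f[j]
            total += np.log(max(prob, 1e-300))
        return total

    def run_em(f0: np.ndarray) -> tuple[np.ndarray, float, int, bool]:
        f = f0.copy()
        ll = log_lik(f)
        for it in range(1, max_iter + 1):
            counts = np.zeros(m)
            for pairs in res_idx:
                w = np.array(
                    [(1 if i == j else 2) * f[i] * f[j] for i, j in pairs]
                )
                total = w.sum()
                if total <= 0:
                    w = np.full(len(pairs), 1.0 / len(pairs))
                else:
                    w /= total
                for wk, (i, j) in zip(w, pairs):
                    counts[i] += wk
                    counts[j] += wk
            f_new = counts / (2 * n)
            ll_new = log_lik(f_new)
            assert ll_new >= ll - 1e-9, "EM log-likelihood decreased"
            f = f_new
            if ll_new - ll < tol:
                return f, ll_new, it, True
            ll = ll_new
        return f, ll, max_iter, False

    rng = np.random.default_rng(seed)
    starts = [np.full(m, 1.0 / m)]
    # linkage-equilibrium start: product of observed allele frequencies
    freq_a: dict = {}
    freq_b: dict = {}
    for ga, gb in genotypes:
        for a in ga:
            freq_a[a] = freq_a.get(a, 0) + 1
        for b in gb:
            freq_b[b] = freq_b.get(b, 0) + 1
    le = np.array([freq_a[h[0]] * freq_b[h[1]] for h in haps], dtype=float)
    starts.append(le / le.sum())
    for _ in range(restarts):
        d = rng.dirichlet(np.ones(m))
        starts.append(d)
    best: tuple[np.ndarray, float, int, bool] | None = None
    for f0 in starts:
        result = run_em(f0)
        if best is None or result[1] > best[1]:
            best = result
    f, ll, iters, converged = best
    return HaplotypeTable(
        loci=loci,
        frequencies={h: float(f[hap_idx[h]]) for h in haps if f[hap_idx[h]] > 0},
        log_likelihood=float(ll),
        iterations=iters,
        converged=converged,
    )


@dataclass
class AshResult:
    allele: AlleleName | object
    locus: str
    partner_locus: str
    ash: float
    allele_frequency: float
    stratum: str  # "below", "0.05-0.10", ">0.10"


def _stratum(freq: float) -> str:
    if freq > 0.10:
        return ">0.10"
    if freq > 0.05:
        return "0.05-0.10"
    return "below"


def ash(haps: HaplotypeTable, allele, side: int = 0) -> AshResult:
    """Allele-specific heterozygosity of ``allele`` at the conditioned side."""
    p_a = haps.marginal(side).get(allele, 0.0)
    if p_a <= 0:
        raise ValueError(f"allele {allele} has zero frequency")
    cond = np.array(
        [f / p_a for hap, f in haps.frequencies.items() if hap[side] == allele]
    )
    value = 1.0 - float((cond**2).sum())
    return AshResult(
        allele=allele,
        locus=haps.loci[side],
        partner_locus=haps.loci[1 - side],
        ash=value,
        allele_frequency=float(p_a),
        stratum=_stratum(float(p_a)),
    )


def _two_locus_genotypes(
    pop: PopulationSample, locus_a: str, locus_b: str
) -> list[tuple[tuple, tuple]]:
    out = []
    for ind in pop.individuals:
        ga = ind.genotypes.get(locus_a)
        gb = ind.genotypes.get(locus_b)
        if ga is not None and gb is not None:
            out.append((ga, gb))
    return out


def ash_by_category(
    cohort: Cohort,
    category_map_by_locus: dict[str, dict[AlleleName, str]],
    loci: tuple[str, ...] = ("A", "B", "C", "DRB1"),
    min_individuals: int = 10,
    em_seed: int = 0,
) -> pd.DataFrame:
    """Allele-level ASH records for every population and ordered locus pair.

    EM is run per population and unordered locus pair; each allele of the
    conditioned locus then contributes one ASH record per partner locus.
    Endemic and LFD categories come from ``category_map_by_locus`` (alleles
    absent there count as "other").  Returns a long frame with columns
    population, locus, partner_locus, allele, category, frequency, stratum,
    ash — the raw material for category/stratum summaries.
    """
    rows = []
    for pop in cohort.populations:
        for la, lb in itertools.combinations(loci, 2):
            genos = _two_locus_genotypes(pop, la, lb)
            if len(genos) < min_individuals:
                continue
            haps = em_haplotypes(genos, loci=(la, lb), seed=em_seed)
            for side, (locus, partner) in enumerate(((la, lb), (lb, la))):
                cats = category_map_by_locus.get(locus, {})
                for allele in haps.marginal(side):
                    r = ash(haps, allele, side=side)
                    rows.append(
                        {
                            "population": pop.name,
                            "locus": locus,
                            "partner_locus": partner,
                            "allele": str(allele),
                            "category": cats.get(allele, "other"),
                            "frequency": r.allele_frequency,
                            "stratum": r.stratum,
                            "ash": r.ash,
                        }
                    )
    return pd.DataFrame(rows)


def ash_summary(records: pd.DataFrame) -> pd.DataFrame:
    """Category summary of allele-level ASH records.

    Per-locus rows average ASH over all allele records of that category;
    'All loci' rows pool every locus within the frequency strata.  The
    non-endemic/non-LFD category is labelled ``Non-Endemic/LFD``.
    """
    df = records.copy()
    df["summary_category"] = df["category"].map(
        {"endemic": "Endemic", "LFD": "LFD"}
    ).fillna("Non-Endemic/LFD")
    rows = []
    for (locus, cat), sub in df.groupby(["locus", "summary_category"]):
        rows.append(
            {"locus": locus, "category": cat,
             "ash": float(sub["ash"].mean()), "n_records": len(sub)}
        )
    for (cat, stratum), sub in df[df["stratum"] != "below"].groupby(
        ["summary_category", "stratum"]
    ):
        rows.append(
            {"locus": "All loci", "category": f"{cat} ({stratum})",
             "ash": float(sub["ash"].mean()), "n_records": len(sub)}
        )
    return pd.DataFrame(rows)
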