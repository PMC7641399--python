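"""Exact test of Hardy–Weinberg proportions for multiallelic loci.

The test conditions on the observed allele counts: under random union of
gametes the probability of a genotype array (f_ij) is

    P(f | c) = n! * prod_a c_a! * 2^h / ((2n)! * prod_{i<=j} f_ij!)

with n individuals, allele copy counts c_a and h heterozygotes.  The
p-value is the total probability of arrays no more probable than the one
observed.  Small array spaces are enumerated exactly; larger ones use
Monte-Carlo permutation of the 2n gametes (an i.i.d. permutation scheme,
so no burn-in is required).

Per-genotype diagnostics are standardized residuals (obs - exp)/sqrt(exp)
against the Hardy–Weinberg expectation at the sample allele frequencies,
flagged two-sided at |residual| > 1.96.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln


@dataclass
class HwpResult:
    locus: str
    p: float
    method: str  # "enumeration" | "monte_carlo" | "degenerate"
    n_individuals: int
    table: pd.DataFrame  # genotype, observed, expected, residual, flagged
    mc_se: float | None = None


def _log_table_prob(f: dict[tuple[int, int], int], c: np.ndarray) -> float:
    n = sum(f.values())
    h = sum(v for (i, j), v in f.items() if i != j)
    two_n = 2 * n
    val = (
        gammaln(n + 1)
        + gammaln(c + 1).sum()
        + h * np.log(2.0)
        - gammaln(two_n + 1)
        - sum(gammaln(v + 1) for v in f.values())
    )
    return float(val)


class _TooManyTables(Exception):
    pass


def _enumerate_tables(c: tuple[int, ...], max_tables: int):
    """Yield all genotype arrays with allele copy margins ``c`` (may raise).

    Raises ``_TooManyTables`` once more than ``max_tables`` arrays are
    produced, or once the search tree exceeds a proportional node budget
    (so that hopeless margins bail out to Monte-Carlo quickly).
    """
    k = len(c)
    rem = list(c)
    current: dict[tuple[int, int], int] = {}
    count = 0
    nodes = 0
    node_budget = 50 * max_tables + 1000

    def tick() -> None:
        nonlocal nodes
        nodes += 1
        if nodes > node_budget:
            raise _TooManyTables

    def fill_row(i: int):
        nonlocal count
        if i == k:
            if all(r == 0 for r in rem):
                count += 1
                if count > max_tables:
                    raise _TooManyTables
                yield dict(current)
            return
        for f_ii in range(rem[i] // 2 + 1):
            current[(i, i)] = f_ii
            rem[i] -= 2 * f_ii
            yield from fill_het(i, i + 1)
            rem[i] += 2 * f_ii
            del current[(i, i)]

    def fill_het(i: int, j: int):
        tick()
        if j == k:
            if rem[i] == 0:
                yield from fill_row(i + 1)
            return
        top = min(rem[i], rem[j])
        # remaining row-i mass must fit into the remaining partners
        tail = sum(rem[t] for t in range(j + 1, k))
        low = max(0, rem[i] - tail)
        for f_ij in range(low, top + 1):
            current[(i, j)] = f_ij
            rem[i] -= f_ij
            rem[j] -= f_ij
            yield from fill_het(i, j + 1)
            rem[i] += f_ij
            rem[j] += f_ij
            del current[(i, j)]

    yield from fill_row(0)


def _genotype_counts(pairs) -> tuple[dict[tuple[int, int], int], list]:
    """Map arbitrary allele labels to integer indices; return counts + labels."""
    labels = sorted({a for pair in pairs for a in pair})
    idx = {a: i for i, a in enumerate(labels)}
    counts: dict[tuple[int, int], int] = {}
    for a, b in pairs:
        key = tuple(sorted((idx[a], idx[b])))
        counts[key] = counts.get(key, 0) + 1
    return counts, labels


def _residual_table(
    f: dict[tuple[int, int], int], c: np.ndarray, labels: list
) -> pd.DataFrame:
    n = sum(f.values())
    p = c / c.sum()
    rows = []
    k = len(c)
    for i in range(k):
        for j in range(i, k):
            obs = f.get((i, j), 0)
            exp = n * (p[i] ** 2 if i == j else 2 * p[i] * p[j])
            if exp > 0:
                res = (obs - exp) / np.sqrt(exp)
                flagged = abs(res) > 1.96
            else:
                res, flagged = np.nan, False
            if obs == 0 and exp == 0:
                continue
            rows.append(
                {
                    "genotype": f"{labels[i]}+{labels[j]}",
                    "observed": obs,
                    "expected": exp,
                    "residual": res,
                    "flagged": flagged,
                }
            )
    return pd.DataFrame(rows)


def hwp_exact(
    genotype_pairs,
    mc_steps: int = 100_000,
    seed: int = 0,
    max_tables: int = 1_000_000,
    locus: str = "",
) -> HwpResult:
    """Exact (or Monte-Carlo) HWP test on a list of unordered allele pairs.

    ``genotype_pairs`` is a sequence of 2-tuples of hashable allele labels,
    one per individual.  Enumeration is used while the array space stays at
    or below ``max_tables`` arrays; otherwise ``mc_steps`` gamete
    permutations are drawn with the given seed.
    """
    pairs = list(genotype_pairs)
    if len(pairs) < 2:
        raise ValueError("need at least 2 individuals")
    f_obs, labels = _genotype_counts(pairs)
    k = len(labels)
    # each individual contributes one copy to c[i] and one to c[j] (2 if i == j)
    c = np.zeros(k, dtype=np.int64)
    for (i, j), v in f_obs.items():
        c[i] += v
        c[j] += v
    table = _residual_table(f_obs, c, labels)
    if k == 1:
        return HwpResult(
            locus=locus, p=1.0, method="degenerate",
            n_individuals=len(pairs), table=table,
        )
    tol = 1e-9
    # only the table-dependent part of the log-probability varies across
    # arrays with the same margins: h*log(2) - sum_f lgamma(f+1)
    n_ind = len(pairs)
    lgam = gammaln(np.arange(n_ind + 2, dtype=float))
    log2 = np.log(2.0)

    def log_var(f: dict[tuple[int, int], int]) -> float:
        h = sum(v for (i, j), v in f.items() if i != j)
        return h * log2 - sum(float(lgam[v + 1]) for v in f.values())

    obs_var = log_var(f_obs)
    try:
        lps = [
            log_var(f)
            for f in _enumerate_tables(tuple(int(x) for x in c), max_tables)
        ]
        lps = np.array(lps)
        probs = np.exp(lps - lps.max())
        p = float(probs[lps <= obs_var + tol].sum() / probs.sum())
        return HwpResult(
            locus=locus, p=min(p, 1.0), method="enumeration",
            n_individuals=len(pairs), table=table,
        )
    except _TooManyTables:
        pass
    rng = np.random.default_rng(seed)
    gametes = np.concatenate([np.full(int(ci), i) for i, ci in enumerate(c)])
    hits = 0
    for _ in range(mc_steps):
        rng.shuffle(gametes)
        a, b = gametes[::2], gametes[1::2]
        lo, hi = np.minimum(a, b), np.maximum(a, b)
        counts = np.bincount(lo * k + hi, minlength=k * k)
        h = int((lo != hi).sum())
        # lgamma(0+1) = 0, so empty cells contribute nothing
        var = h * np.log(2.0) - float(lgam[counts + 1].sum())
        if var <= obs_var + tol:
            hits += 1
    p = (hits + 1) / (mc_steps + 1)
    se = float(np.sqrt(p * (1 - p) / mc_steps))
    return HwpResult(
        locus=locus, p=p, method="monte_carlo",
        n_individuals=len(pairs), table=table, mc_se=se,
    )


def genotype_residuals(result: HwpResult) -> pd.DataFrame:
    """Genotype classes flagged as over/under-represented (|residual| > 1.96)."""
    return result.table[result.table["flagged"]].reset_index(drop=True)
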