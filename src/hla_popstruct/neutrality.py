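"""Neutrality tests: Ewens–Watterson homozygosity and Tajima's D.

Ewens–Watterson: the observed homozygosity F = sum p_i^2 of an allele
configuration is compared with its distribution under the Ewens sampling
formula conditional on (n, k).  Conditional on k the configuration law is
parameter-free:

    P(config | n, k) = n! / (|s(n,k)| * prod_j j^{a_j} a_j!)

with a_j the number of alleles carried by exactly j copies and |s(n,k)|
the unsigned Stirling number of the first kind.  The distribution is
enumerated exactly over partitions of n into k parts when that is cheap,
otherwise sampled by a Chinese-restaurant construction rejected on k.
The p-value is the lower tail Pr(F <= F_obs): small p points to balancing
selection (too-even frequencies), p near 1 to directional selection.

Tajima's D: D = (pi - S/a1) / sqrt(e1*S + e2*S*(S-1)) with the standard
constants; alignment columns containing any gap are excluded (complete
deletion).  The p-value is the upper tail Pr(D_sim >= D_obs) over neutral
coalescent genealogies (msprime), with mutations either fixed at the
observed S (default) or Poisson with Watterson's theta-hat, so that large
positive D (balancing selection) gives small p and negative D gives p
near one.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import msprime
import numpy as np

from .data import FrequencyTable, PopulationSample, SequenceMap, allele_frequencies
from scipy.special import gammaln

TWO_TAILED_BOUNDS = (0.025, 0.975)


# ---------------------------------------------------------------------------
# Ewens–Watterson


@dataclass
class EwResult:
    n: int
    k: int
    F_obs: float
    F_exp: float
    p: float | None
    method: str

    @property
    def significant(self) -> bool:
        lo, hi = TWO_TAILED_BOUNDS
        return self.p is not None and (self.p < lo or self.p > hi)


def _partition_count(n: int, k: int) -> int:
    """Number of partitions of n into exactly k positive parts."""

    @lru_cache(maxsize=None)
    def p(n: int, k: int) -> int:
        if k == 0:
            return 1 if n == 0 else 0
        if n < k:
            return 0
        return p(n - 1, k - 1) + p(n - k, k)

    return p(n, k)


def _partitions(n: int, k: int, max_part: int | None = None):
    """Yield partitions of n into exactly k parts, non-increasing."""
    if max_part is None:
        max_part = n
    if k == 1:
        if n <= max_part:
            yield (n,)
        return
    for first in range(min(n - k + 1, max_part), (n - 1) // k, -1):
        for rest in _partitions(n - first, k - 1, first):
            yield (first,) + rest


@lru_cache(maxsize=4096)
def ewens_conditional_distribution(n: int, k: int):
    """(F values, probabilities) of allele configurations given (n, k).

    Exact over all partitions of n into k parts.  Cached, since every
    sample with the same (n, k) shares the null.
    """
    log_ws = []
    fs = []
    for part in _partitions(n, k):
        a: dict[int, int] = {}
        for sz in part:
            a[sz] = a.get(sz, 0) + 1
        log_w = gammaln(n + 1) - sum(
            aj * np.log(j) + gammaln(aj + 1) for j, aj in a.items()
        )
        log_ws.append(log_w)
        fs.append(sum((sz / n) ** 2 for sz in part))
    log_ws = np.array(log_ws)
    probs = np.exp(log_ws - log_ws.max())
    probs /= probs.sum()
    return np.array(fs), probs


def _crp_conditional_sample(
    n: int, k: int, draws: int, rng: np.random.Generator
) -> np.ndarray:
    """F values of `draws` configurations sampled conditional on k by CRP rejection."""
    # choose theta so that E[k] matches k, for a decent acceptance rate
    i = np.arange(n)

    def mean_k(theta: float) -> float:
        return float((theta / (theta + i)).sum())

    lo, hi = 1e-3, 1e4
    for _ in range(100):
        mid = np.sqrt(lo * hi)
        if mean_k(mid) < k:
            lo = mid
        else:
            hi = mid
    theta = np.sqrt(lo * hi)
    out = np.empty(draws)
    got = 0
    while got < draws:
        counts: list[int] = []
        for j in range(n):
            if counts and rng.random() >= theta / (theta + j):
                counts[rng.choice(len(counts), p=np.array(counts) / j)] += 1
            else:
                counts.append(1)
        if len(counts) == k:
            arr = np.array(counts) / n
            out[got] = float((arr**2).sum())
            got += 1
    return out


def ewens_watterson(
    f: FrequencyTable,
    max_partitions: int = 100_000,
    mc_draws: int = 100_000,
    seed: int = 0,
) -> EwResult:
    """Ewens–Watterson homozygosity test on one allele configuration."""
    n, k = f.n, f.k
    p_vec = np.array(list(f.frequencies.values()))
    f_obs = float((p_vec**2).sum())
    if k == 1:
        return EwResult(n=n, k=1, F_obs=1.0, F_exp=1.0, p=None, method="degenerate")
    if _partition_count(n, k) <= max_partitions:
        fs, probs = ewens_conditional_distribution(n, k)
        f_exp = float((fs * probs).sum())
        p = float(probs[fs <= f_obs + 1e-12].sum())
        return EwResult(n=n, k=k, F_obs=f_obs, F_exp=f_exp, p=p, method="enumeration")
    rng = np.random.default_rng(seed)
    sims = _crp_conditional_sample(n, k, mc_draws, rng)
    f_exp = float(sims.mean())
    p = float((sims <= f_obs + 1e-12).mean())
    return EwResult(n=n, k=k, F_obs=f_obs, F_exp=f_exp, p=p, method="monte_carlo")


# ---------------------------------------------------------------------------
# Sequence recoding


class MissingSequenceError(KeyError):
    """An allele in the sample has no entry in the sequence map."""


def recode_to_sequences(
    pop: PopulationSample, locus: str, seqmap: SequenceMap
) -> list[str]:
    """One aligned sequence per chromosome (multiplicity = allele copy count)."""
    freqs = allele_frequencies(pop, locus)
    available = seqmap.sequences.get(locus, {})
    missing = sorted(str(a) for a in freqs.counts if a not in available)
    if missing:
        raise MissingSequenceError(
            f"no sequence for {len(missing)} allele(s) at {locus}: {', '.join(missing)}"
        )
    out: list[str] = []
    for allele, count in freqs.counts.items():
        out.extend([available[allele]] * count)
    return out


# ---------------------------------------------------------------------------
# Tajima's D


@dataclass
class TajimaResult:
    n: int
    S: int
    pi: float
    D: float
    p: float | None
    constants: dict[str, float]

    @property
    def significant(self) -> bool:
        lo, hi = TWO_TAILED_BOUNDS
        return self.p is not None and (self.p < lo or self.p > hi)


def tajima_constants(n: int) -> dict[str, float]:
    a1 = float(np.sum(1.0 / np.arange(1, n)))
    a2 = float(np.sum(1.0 / np.arange(1, n) ** 2))
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n**2 + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2, "c1": c1, "c2": c2,
            "e1": e1, "e2": e2}


def _complete_deletion(sequences: list[str]) -> np.ndarray:
    arr = np.array([list(s) for s in sequences])
    keep = ~(arr == "-").any(axis=0)
    return arr[:, keep]


def segregating_and_pi(sequences: list[str]) -> tuple[int, float]:
    """S and mean pairwise differences after complete deletion of gap columns."""
    arr = _complete_deletion(sequences)
    n = arr.shape[0]
    n_pairs = n * (n - 1) / 2
    s = 0
    diff_sum = 0.0
    for col in arr.T:
        _, counts = np.unique(col, return_counts=True)
        if len(counts) > 1:
            s += 1
            diff_sum += n_pairs - (counts * (counts - 1) / 2).sum()
    return int(s), float(diff_sum / n_pairs)


def _sfs_statistic_d(derived_counts: np.ndarray, n: int,
                     consts: dict[str, float]) -> float:
    s = len(derived_counts)
    pi = float((derived_counts * (n - derived_counts)).sum() / (n * (n - 1) / 2))
    denom = np.sqrt(consts["e1"] * s + consts["e2"] * s * (s - 1))
    return (pi - s / consts["a1"]) / denom


def tajimas_d(
    sequences: list[str],
    p_replicates: int = 10_000,
    seed: int = 0,
    conditioning: str = "fixed_s",
) -> TajimaResult:
    """Tajima's D with a coalescent-simulation p-value.

    ``conditioning='fixed_s'`` places exactly the observed S mutations on
    each simulated genealogy (branch-length weighted); ``'poisson'`` draws
    the mutation number as Poisson with Watterson's theta-hat.
    """
    n = len(sequences)
    if n < 4:
        raise ValueError("need at least 4 sequences")
    s, pi = segregating_and_pi(sequences)
    if s == 0:
        raise ValueError("Tajima's D undefined: no segregating sites")
    consts = tajima_constants(n)
    d_obs = (pi - s / consts["a1"]) / np.sqrt(
        consts["e1"] * s + consts["e2"] * s * (s - 1)
    )
    p = None
    if p_replicates > 0:
        rng = np.random.default_rng(seed)
        theta_w = s / consts["a1"]
        hits = 0
        used = 0
        replicates = msprime.sim_ancestry(
            samples=n,
            ploidy=1,
            population_size=1,
            num_replicates=p_replicates,
            random_seed=int(rng.integers(1, 2**31 - 1)),
        )
        for ts in replicates:
            tree = ts.first()
            nodes = [u for u in tree.nodes() if tree.parent(u) != -1]
            lengths = np.array([tree.branch_length(u) for u in nodes])
            leaf_counts = np.array([tree.num_samples(u) for u in nodes])
            if conditioning == "fixed_s":
                n_mut = s
            elif conditioning == "poisson":
                n_mut = rng.poisson(theta_w / 2 * lengths.sum())
                if n_mut == 0:
                    continue
            else:
                raise ValueError(f"unknown conditioning {conditioning!r}")
            picks = rng.choice(len(nodes), size=n_mut, p=lengths / lengths.sum())
            d_sim = _sfs_statistic_d(leaf_counts[picks], n, consts)
            used += 1
            if d_sim >= d_obs:
                hits += 1
        p = hits / used if used else None
    return TajimaResult(n=n, S=s, pi=pi, D=float(d_obs), p=p, constants=consts)
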