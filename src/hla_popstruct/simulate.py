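"""Synthetic cohorts with known ground truth.

Generates everything the analysis stages consume — an HLA genotype cohort
laid out along a serial-founder chain, a genome-wide microsatellite panel
for the same individuals, a worldwide reference allele-frequency panel,
aligned per-allele sequences, and two-locus genotype samples with known
haplotype frequencies — so that every statistic can be checked against a
planted truth without external data.

The demographic caricature: an ancestral (Asian-like) source population;
a chain of founder events (SIB → NAM → MEA → SAA → SAL by default), each a
Wright–Fisher bottleneck of ``N_b`` diploids for ``g`` generations, which
erodes heterozygosity monotonically along the chain; new ("endemic")
alleles arising after the split from the rest of the world, hence absent
from the reference panel; and "LFD" alleles that exist worldwide at low
frequency but were boosted severalfold in the Americas by drift.  Drift is
simulated on allele frequencies (multinomial resampling), not genealogies:
cheap, and adequate for heterozygosity-cline and allele-classification
behaviour.  Microsatellites mutate by a stepwise model so that allele-size
based statistics (R_ST) are meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .data import (
    AlleleName,
    Cohort,
    Individual,
    MsatPanel,
    PanelPopulation,
    PopulationSample,
    ReferencePanel,
    SequenceMap,
)

# ---------------------------------------------------------------------------
# Parameters


@dataclass
class PlantedAllele:
    """A ground-truth endemic or LFD allele planted into the American gene pool."""

    locus: str
    allele: AlleleName
    category: str  # "endemic" | "LFD"
    target_frequency: float
    regions: tuple[str, ...]


@dataclass
class SimParams:
    """Conditions for one synthetic study.

    Defaults emulate the real study's layout: 24 populations (1 Siberian,
    23 Native American across NAM/MEA/SAA/SAL), 15–25 individuals each,
    four HLA loci with locus-specific mutation parameters (HLA-B the most
    diverse), a 678-marker microsatellite panel, and a 50-population
    worldwide reference panel standing in for the published meta-analysis.
    """

    theta: dict[str, float] = field(
        default_factory=lambda: {"A": 4.0, "B": 10.0, "C": 5.0, "DRB1": 6.0}
    )
    founder_chain: tuple[tuple[str, int, int], ...] = (
        ("SIB", 300, 40),
        ("NAM", 80, 40),
        ("MEA", 80, 40),
        ("SAA", 80, 40),
        ("SAL", 60, 40),
    )
    pops_per_region: dict[str, int] = field(
        default_factory=lambda: {"SIB": 1, "NAM": 3, "MEA": 6, "SAA": 4, "SAL": 10}
    )
    pop_bottleneck: int = 50
    pop_generations: int = 10
    individuals_range: tuple[int, int] = (15, 25)
    n_msat: int = 678
    mu_msat: float = 5e-4
    n_ref_pops: int = 50
    ref_pop_size: int = 500
    ref_generations: int = 20
    planted_endemics: tuple[tuple[str, float, tuple[str, ...]], ...] = (
        ("A", 0.06, ("MEA", "SAA", "SAL")),
        ("A", 0.08, ("SAL",)),
        ("B", 0.10, ("MEA", "SAA", "SAL")),
        ("B", 0.08, ("SAL",)),
        ("C", 0.06, ("MEA", "SAA", "SAL")),
        ("DRB1", 0.06, ("SAL",)),
    )
    planted_lfd_per_locus: int = 2
    lfd_boost: float = 4.0
    ld_Dprime: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.founder_chain:
            raise ValueError("founder_chain must be non-empty")
        for region, n_b, g in self.founder_chain:
            if n_b < 1 or g < 0:
                raise ValueError(f"invalid founder event ({region}, {n_b}, {g})")


# ---------------------------------------------------------------------------
# Ewens-sampling draws


def ewens_configuration(theta: float, n: int, rng: np.random.Generator) -> np.ndarray:
    """Allele copy counts for an Ewens sample of n genes (Chinese-restaurant draw)."""
    if theta < 0:
        raise ValueError("theta must be >= 0")
    # sequential construction: gene i founds a new allele w.p. theta/(theta+i),
    # else copies a uniformly chosen earlier gene (= size-biased class choice)
    labels = np.zeros(n, dtype=np.int64)
    n_classes = 1
    u = rng.random(n)
    for i in range(1, n):
        if u[i] < theta / (theta + i):
            labels[i] = n_classes
            n_classes += 1
        else:
            labels[i] = labels[rng.integers(0, i)]
    counts = np.bincount(labels)
    return np.array(sorted(counts, reverse=True))


def _hla_name(locus: str, idx: int, endemic: bool = False) -> AlleleName:
    """Deterministic synthetic allele names; endemic names live in the 90: groups."""
    base = 90 if endemic else 1
    return AlleleName(
        locus=locus, field1=f"{base + idx // 90:02d}", field2=f"{idx % 90 + 1:02d}"
    )


def sim_neutral_population(
    theta: float, n: int, seed: int, locus: str = "A", name: str = "sim"
) -> PopulationSample:
    """A single population drawn from the Ewens sampling formula at HWP.

    Allele copy counts follow the Ewens distribution for ``n`` genes at
    scaled mutation rate ``theta``; genotypes are formed by random pairing
    of the 2n-gene pool without replacement (Hardy–Weinberg proportions).
    """
    if n < 2 or n % 2:
        raise ValueError("n must be even and >= 2")
    rng = np.random.default_rng(seed)
    config = ewens_configuration(theta, n, rng)
    gametes = np.repeat(np.arange(len(config)), config)
    rng.shuffle(gametes)
    pop = PopulationSample(name=name)
    for i in range(n // 2):
        a = _hla_name(locus, int(gametes[2 * i]))
        b = _hla_name(locus, int(gametes[2 * i + 1]))
        pair = (a, b) if a <= b else (b, a)
        pop.individuals.append(
            Individual(ident=f"{name}_{i:03d}", genotypes={locus: pair})
        )
    return pop


# ---------------------------------------------------------------------------
# Frequency-space drift


def drift_frequencies(
    freqs: np.ndarray, n_diploid: int, generations: int, rng: np.random.Generator
) -> np.ndarray:
    """Wright–Fisher multinomial drift of one or more frequency vectors.

    ``freqs`` may be 1-D (one locus) or 2-D (loci × alleles); each row is
    resampled as 2N gene copies per generation.
    """
    f = np.atleast_2d(np.asarray(freqs, dtype=float))
    f = f / f.sum(axis=1, keepdims=True)
    two_n = 2 * n_diploid
    for _ in range(generations):
        f = rng.multinomial(two_n, f) / two_n
    return f[0] if np.ndim(freqs) == 1 else f


def _stepwise_mutate(freqs: np.ndarray, mu: float) -> np.ndarray:
    """Deterministic stepwise-mutation flow: mass mu shifts one size up and down."""
    out = (1 - 2 * mu) * freqs
    out[:, 1:] += mu * freqs[:, :-1]
    out[:, :-1] += mu * freqs[:, 1:]
    # reflecting bounds keep total mass 1
    out[:, 0] += mu * freqs[:, 0]
    out[:, -1] += mu * freqs[:, -1]
    return out


def expected_heterozygosity(freqs: np.ndarray) -> float:
    f = np.asarray(freqs, dtype=float)
    return float(1.0 - (f**2).sum(axis=-1).mean())


# ---------------------------------------------------------------------------
# Two-locus construction


def two_locus_haplotypes(
    pA: Sequence[float], pB: Sequence[float], dprime: float
) -> np.ndarray:
    """Haplotype frequency matrix with disequilibrium D' between the first alleles.

    h[0,0] carries D = D' * Dmax; the remaining cells are adjusted
    proportionally so that both marginals are preserved exactly.
    """
    pA = np.asarray(pA, dtype=float)
    pB = np.asarray(pB, dtype=float)
    for p, label in ((pA, "pA"), (pB, "pB")):
        if abs(p.sum() - 1) > 1e-9 or (p < 0).any():
            raise ValueError(f"{label} is not a frequency vector")
    if not -1 <= dprime <= 1:
        raise ValueError("|D'| must be <= 1")
    if dprime >= 0:
        d_max = min(pA[0] * (1 - pB[0]), (1 - pA[0]) * pB[0])
    else:
        d_max = min(pA[0] * pB[0], (1 - pA[0]) * (1 - pB[0]))
    d = dprime * d_max
    h = np.outer(pA, pB)
    if len(pA) > 1 and len(pB) > 1 and d != 0:
        h[0, 0] += d
        h[0, 1:] -= d * pB[1:] / (1 - pB[0])
        h[1:, 0] -= d * pA[1:] / (1 - pA[0])
        h[1:, 1:] += d * np.outer(pA[1:], pB[1:]) / ((1 - pA[0]) * (1 - pB[0]))
    if (h < -1e-12).any():
        raise ValueError("infeasible D' for the given allele frequency margins")
    return np.clip(h, 0.0, None)


def sim_two_locus(
    pA: Sequence[float],
    pB: Sequence[float],
    dprime: float,
    n: int,
    seed: int,
    loci: tuple[str, str] = ("A", "B"),
):
    """Unphased two-locus genotypes by random union of gametes.

    Returns ``(genotypes, h)`` where genotypes is a list of
    ``((a1, a2), (b1, b2))`` unordered pairs and ``h`` the true haplotype
    frequency matrix.
    """
    rng = np.random.default_rng(seed)
    h = two_locus_haplotypes(pA, pB, dprime)
    flat = h.ravel() / h.sum()
    draws = rng.choice(len(flat), size=2 * n, p=flat)
    ai, bi = np.unravel_index(draws, h.shape)
    genotypes = []
    for i in range(n):
        a_pair = tuple(sorted((_hla_name(loci[0], int(ai[2 * i])),
                               _hla_name(loci[0], int(ai[2 * i + 1])))))
        b_pair = tuple(sorted((_hla_name(loci[1], int(bi[2 * i])),
                               _hla_name(loci[1], int(bi[2 * i + 1])))))
        genotypes.append((a_pair, b_pair))
    return genotypes, h


# ---------------------------------------------------------------------------
# Allele sequences


def sim_sequences(
    k: int, length: int, mode: str, seed: int, locus: str = "A"
) -> SequenceMap:
    """Aligned sequences for ``k`` alleles under two genealogical caricatures.

    ``star``: allele 0 is the unmutated ancestor and every other allele
    carries one private substitution — variation is mostly allele-private
    (negative Tajima's D regime when rare alleles abound).

    ``balanced_clades``: alleles split into two clades separated by many
    fixed differences, plus one private substitution each — shared
    intermediate-frequency variation (positive Tajima's D regime).
    """
    if k < 2 or length < k:
        raise ValueError("need k >= 2 and length >= k")
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    ancestor = rng.choice(bases, size=length)
    other = {b: [c for c in "ACGT" if c != b] for b in "ACGT"}

    def mutate(seq: np.ndarray, pos: int) -> np.ndarray:
        out = seq.copy()
        out[pos] = rng.choice(other[str(seq[pos])])
        return out

    positions = rng.permutation(length)
    seqs: dict[AlleleName, str] = {}
    if mode == "star":
        for i in range(k):
            seq = ancestor if i == 0 else mutate(ancestor, int(positions[i - 1]))
            seqs[_hla_name(locus, i)] = "".join(seq)
    elif mode == "balanced_clades":
        n_deep = max(4, length // 20)
        if n_deep + k > length:
            raise ValueError("length too short for the deep split")
        clade_b_root = ancestor
        for pos in positions[:n_deep]:
            clade_b_root = mutate(clade_b_root, int(pos))
        private = positions[n_deep : n_deep + k]
        for i in range(k):
            root = ancestor if i < (k + 1) // 2 else clade_b_root
            seqs[_hla_name(locus, i)] = "".join(mutate(root, int(private[i])))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return SequenceMap(sequences={locus: seqs})


def sim_sequence_sample(
    k: int, length: int, mode: str, n: int, seed: int, locus: str = "A"
):
    """A sample of n aligned sequences in the frequency regime matching ``mode``.

    ``star`` pairs the star genealogy with a skewed allele spectrum (one
    common ancestral allele, many rare derived ones); ``balanced_clades``
    splits the sample evenly between the two clades.  Returns
    ``(sequences, seqmap)``.
    """
    rng = np.random.default_rng(seed)
    seqmap = sim_sequences(k, length, mode, seed=seed + 1, locus=locus)
    alleles = sorted(seqmap.sequences[locus])
    if mode == "star":
        w = np.array([6.0] + [1.0] * (k - 1))
    else:
        half = (k + 1) // 2
        w = np.ones(k)
        w[:half] *= (k - half) / half if half else 1.0  # balance the two clades
    p = w / w.sum()
    draws = rng.choice(k, size=n, p=p)
    sequences = [seqmap.sequences[locus][alleles[i]] for i in draws]
    return sequences, seqmap


# ---------------------------------------------------------------------------
# Full cohort


def _sample_population(
    name: str,
    freqs_by_locus: dict[str, np.ndarray],
    alleles_by_locus: dict[str, list[AlleleName]],
    n_ind: int,
    rng: np.random.Generator,
) -> PopulationSample:
    pop = PopulationSample(name=name)
    gametes = {}
    for locus, f in freqs_by_locus.items():
        gametes[locus] = rng.choice(len(f), size=2 * n_ind, p=f / f.sum())
    for i in range(n_ind):
        ind = Individual(ident=f"{name}_{i:03d}")
        for locus in freqs_by_locus:
            a = alleles_by_locus[locus][int(gametes[locus][2 * i])]
            b = alleles_by_locus[locus][int(gametes[locus][2 * i + 1])]
            ind.genotypes[locus] = (a, b) if a <= b else (b, a)
        pop.individuals.append(ind)
    return pop


def sim_cohort(params: SimParams):
    """Simulate the full study bundle.

    Returns ``(cohort, msat_panel, reference_panel, truth)`` where truth
    records every planted allele with its category and target frequency,
    the founder-chain order, and per-region expected heterozygosities.
    """
    rng = np.random.default_rng(params.seed)
    loci = list(params.theta)

    # -- ancestral HLA frequency vectors (Ewens draw from a large pool)
    anc_freqs: dict[str, np.ndarray] = {}
    alleles: dict[str, list[AlleleName]] = {}
    for locus in loci:
        config = ewens_configuration(params.theta[locus], 2000, rng)
        anc_freqs[locus] = config / config.sum()
        alleles[locus] = [_hla_name(locus, i) for i in range(len(config))]

    # -- reference panel: mild independent drift from the ancestral pool
    panel_pops: list[PanelPopulation] = []
    for j in range(params.n_ref_pops):
        freqs = {
            locus: drift_frequencies(
                anc_freqs[locus], params.ref_pop_size, params.ref_generations, rng
            )
            for locus in loci
        }
        entry: dict[AlleleName, float] = {}
        for locus in loci:
            for a, f in zip(alleles[locus], freqs[locus]):
                if f > 0:
                    entry[a] = float(f)
        panel_pops.append(
            PanelPopulation(
                name=f"REF{j:03d}",
                frequencies=entry,
                n=100,
                migrant=j == params.n_ref_pops - 1,  # one flagged migrant population
            )
        )
    panel = ReferencePanel(populations=panel_pops)

    # -- choose LFD alleles: real worldwide alleles, rare in the panel
    planted: list[PlantedAllele] = []
    native_regions = tuple(r for r, _, _ in params.founder_chain if r != "SIB")
    for locus in loci:
        mean_f = np.array([panel.mean_frequency(a) for a in alleles[locus]])
        candidates = [
            i for i in np.argsort(mean_f) if 0.002 < mean_f[i] < 0.04
        ][: params.planted_lfd_per_locus]
        for i in candidates:
            planted.append(
                PlantedAllele(
                    locus=locus,
                    allele=alleles[locus][i],
                    category="LFD",
                    target_frequency=float(
                        min(0.5, params.lfd_boost * mean_f[i] + 0.03)
                    ),
                    regions=native_regions,
                )
            )
    for idx, (locus, target, regions) in enumerate(params.planted_endemics):
        allele = _hla_name(locus, idx, endemic=True)
        alleles[locus].append(allele)
        anc_freqs[locus] = np.append(anc_freqs[locus], 0.0)
        planted.append(
            PlantedAllele(
                locus=locus,
                allele=allele,
                category="endemic",
                target_frequency=target,
                regions=tuple(regions),
            )
        )

    # -- microsatellite ancestral frequencies on a 21-size support
    support = np.arange(10, 31)
    msat_anc = rng.dirichlet(np.full(len(support), 0.6), size=params.n_msat)

    # -- serial founder chain
    region_hla: dict[str, dict[str, np.ndarray]] = {}
    region_msat: dict[str, np.ndarray] = {}
    current_hla = {locus: anc_freqs[locus].copy() for locus in loci}
    current_msat = msat_anc.copy()
    chain_order: list[str] = []
    for region, n_b, g in params.founder_chain:
        current_hla = {
            locus: drift_frequencies(current_hla[locus], n_b, g, rng)
            for locus in loci
        }
        for _ in range(g):
            current_msat = rng.multinomial(2 * n_b, current_msat) / (2 * n_b)
            current_msat = _stepwise_mutate(current_msat, params.mu_msat)
        # plant alleles whose range includes this region
        for p in planted:
            if region in p.regions:
                f = current_hla[p.locus]
                i = alleles[p.locus].index(p.allele)
                other_mass = f.sum() - f[i]
                if p.target_frequency >= 1 or other_mass <= 0:
                    raise ValueError("planted target frequency exceeds 1")
                scale = (1 - p.target_frequency) / other_mass
                f = f * scale
                f[i] = p.target_frequency
                current_hla[p.locus] = f
        region_hla[region] = {locus: current_hla[locus].copy() for locus in loci}
        region_msat[region] = current_msat.copy()
        chain_order.append(region)

    # -- populations within regions
    populations: list[PopulationSample] = []
    region_map: dict[str, str] = {}
    ordering: dict[str, int] = {}
    msat_rows: list[np.ndarray] = []
    msat_index: list[tuple[str, str]] = []
    rank = 0
    for region in chain_order:
        for j in range(params.pops_per_region.get(region, 0)):
            name = f"{region}{j + 1}"
            pop_hla = {
                locus: drift_frequencies(
                    region_hla[region][locus],
                    params.pop_bottleneck,
                    params.pop_generations,
                    rng,
                )
                for locus in loci
            }
            pop_msat = region_msat[region]
            for _ in range(params.pop_generations):
                pop_msat = rng.multinomial(2 * params.pop_bottleneck, pop_msat) / (
                    2 * params.pop_bottleneck
                )
            n_ind = int(rng.integers(*params.individuals_range, endpoint=True))
            pop = _sample_population(name, pop_hla, alleles, n_ind, rng)
            populations.append(pop)
            region_map[name] = region
            ordering[name] = rank
            rank += 1
            # microsatellite genotypes via inverse-CDF sampling
            cdf = np.cumsum(pop_msat, axis=1)
            u = rng.random((2 * n_ind, params.n_msat))
            idx = (u[:, :, None] > cdf[None, :, :]).sum(axis=2)
            sizes = support[np.minimum(idx, len(support) - 1)]
            sizes = sizes.reshape(n_ind, 2, params.n_msat).transpose(0, 2, 1)
            msat_rows.append(sizes)
            msat_index.extend((name, ind.ident) for ind in pop.individuals)

    cohort = Cohort(populations=populations, region_map=region_map, ordering=ordering)
    msat_panel = MsatPanel(
        index=msat_index,
        markers=[f"M{j:04d}" for j in range(params.n_msat)],
        sizes=np.concatenate(msat_rows, axis=0),
    )
    truth = {
        "planted": [
            {
                "locus": p.locus,
                "allele": str(p.allele),
                "category": p.category,
                "target_frequency": p.target_frequency,
                "regions": list(p.regions),
            }
            for p in planted
        ],
        "chain_order": chain_order,
        "region_expected_het_msat": {
            r: expected_heterozygosity(region_msat[r]) for r in chain_order
        },
        "seed": params.seed,
    }
    return cohort, msat_panel, panel, truth
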