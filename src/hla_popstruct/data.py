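"""Data model and file IO for HLA cohort analyses.

In-memory containers for multilocus HLA genotype cohorts, worldwide
reference allele-frequency panels, genome-wide microsatellite panels and
aligned allele-sequence maps, together with plain-text readers/writers.

Conventions
-----------
* HLA alleles are handled at two-field ("group:protein") resolution, e.g.
  ``B*39:06``.  Deeper typing fields are dropped on parse; a trailing ``G``
  marks a g-group (alleles identical over the typed exons, reported under
  the lowest-numbered name).
* Genotype tables are TSV, one row per individual: population, individual
  id, then two columns per locus.  Untyped loci are empty cells and drop
  the individual at that locus only.
* Allele order within a genotype is non-semantic; pairs are canonicalized
  by lexicographic sort on read.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

LOCI: tuple[str, ...] = ("A", "B", "C", "DRB1")
REGIONS: tuple[str, ...] = ("SIB", "NAM", "MEA", "SAA", "SAL")

_ALLELE_RE = re.compile(
    r"^(?P<locus>[A-Z]+[0-9]*)\*(?P<f1>\d{2,3}):(?P<f2>\d{2,3})"
    r"(?P<deeper>(?::\d{2,3}[LNSQ]?)*)(?P<g>G?)$"
)


class AlleleParseError(ValueError):
    """Raised when an allele-name string does not follow LOCUS*FF:FF[:...][G]."""


@dataclass(frozen=True, order=True)
class AlleleName:
    """A two-field HLA allele name such as ``A*02:01`` or ``A*02:01G``."""

    locus: str
    field1: str
    field2: str
    g_group: bool = False

    def __str__(self) -> str:
        return f"{self.locus}*{self.field1}:{self.field2}{'G' if self.g_group else ''}"

    @property
    def name(self) -> str:
        return str(self)


def parse_allele_name(text: str) -> AlleleName:
    """Parse an HLA allele name, reducing it to two-field resolution.

    ``A*02:01:01G`` parses to ``(A, 02, 01, g_group=True)``: fields beyond
    the second are dropped (a many-to-one, idempotent reduction) and a
    trailing ``G`` sets the g-group flag.
    """
    m = _ALLELE_RE.match(text.strip())
    if m is None:
        raise AlleleParseError(f"malformed allele name: {text!r}")
    return AlleleName(
        locus=m.group("locus"),
        field1=m.group("f1"),
        field2=m.group("f2"),
        g_group=m.group("g") == "G",
    )


def format_allele_name(allele: AlleleName) -> str:
    return str(allele)


Genotype = tuple[AlleleName, AlleleName]


def _canonical_pair(a: AlleleName, b: AlleleName) -> Genotype:
    return (a, b) if a <= b else (b, a)


@dataclass
class Individual:
    """One sampled individual: an id and an unordered allele pair per typed locus."""

    ident: str
    genotypes: dict[str, Genotype] = field(default_factory=dict)

    def is_homozygous(self, locus: str) -> bool | None:
        g = self.genotypes.get(locus)
        if g is None:
            return None
        return g[0] == g[1]


@dataclass
class FrequencyTable:
    """Allele copy counts and relative frequencies at one locus of one sample."""

    locus: str
    counts: dict[AlleleName, int]

    @property
    def n(self) -> int:
        return sum(self.counts.values())

    @property
    def k(self) -> int:
        return len(self.counts)

    @property
    def frequencies(self) -> dict[AlleleName, float]:
        n = self.n
        return {a: c / n for a, c in self.counts.items()}

    def frequency(self, allele: AlleleName) -> float:
        return self.counts.get(allele, 0) / self.n


class EmptyLocusError(ValueError):
    """Raised when a population has no typed individuals at a locus."""


@dataclass
class PopulationSample:
    """All individuals of one population with their multilocus HLA genotypes."""

    name: str
    individuals: list[Individual] = field(default_factory=list)

    def genotype_pairs(self, locus: str) -> list[Genotype]:
        return [
            ind.genotypes[locus] for ind in self.individuals if locus in ind.genotypes
        ]

    def n_chromosomes(self, locus: str) -> int:
        return 2 * len(self.genotype_pairs(locus))

    def allele_set(self, locus: str) -> set[AlleleName]:
        out: set[AlleleName] = set()
        for a, b in self.genotype_pairs(locus):
            out.add(a)
            out.add(b)
        return out


def allele_frequencies(pop: PopulationSample, locus: str) -> FrequencyTable:
    """Tally allele copies at `locus` into a FrequencyTable (counts sum to n)."""
    pairs = pop.genotype_pairs(locus)
    if not pairs:
        raise EmptyLocusError(f"{pop.name}: no individuals typed at {locus}")
    counts: dict[AlleleName, int] = {}
    for a, b in pairs:
        counts[a] = counts.get(a, 0) + 1
        counts[b] = counts.get(b, 0) + 1
    return FrequencyTable(locus=locus, counts=dict(sorted(counts.items())))


@dataclass
class Cohort:
    """A set of population samples with region labels and optional route ranks.

    ``ordering`` holds a per-population rank along the colonization route
    (a least-cost-path proxy supplied externally, never computed here).
    """

    populations: list[PopulationSample]
    region_map: dict[str, str]
    ordering: dict[str, int] | None = None

    def __post_init__(self) -> None:
        for pop in self.populations:
            region = self.region_map.get(pop.name)
            if region is None:
                raise ValueError(f"population {pop.name!r} missing from region map")
            if region not in REGIONS:
                raise ValueError(
                    f"region {region!r} for {pop.name!r} not in {REGIONS}"
                )

    def population(self, name: str) -> PopulationSample:
        for pop in self.populations:
            if pop.name == name:
                return pop
        raise KeyError(name)

    @property
    def population_names(self) -> list[str]:
        return [p.name for p in self.populations]

    def native_populations(self) -> list[PopulationSample]:
        """Populations of the Americas (every region except SIB)."""
        return [p for p in self.populations if self.region_map[p.name] != "SIB"]

    def allele_set(self, locus: str) -> set[AlleleName]:
        out: set[AlleleName] = set()
        for pop in self.populations:
            out |= pop.allele_set(locus)
        return out


@dataclass
class PanelPopulation:
    """One reference-panel population: allele frequencies plus exclusion flags."""

    name: str
    frequencies: dict[AlleleName, float]
    n: int
    migrant: bool = False
    uncertain_origin: bool = False

    @property
    def excluded(self) -> bool:
        return self.migrant or self.uncertain_origin


@dataclass
class ReferencePanel:
    """Worldwide allele-frequency panel used as the non-Native comparison set.

    Mean frequencies are computed over non-flagged populations only, with
    populations lacking an allele contributing frequency zero.
    """

    populations: list[PanelPopulation]

    def included(self) -> list[PanelPopulation]:
        return [p for p in self.populations if not p.excluded]

    def mean_frequency(self, allele: AlleleName) -> float:
        pops = self.included()
        if not pops:
            raise ValueError("reference panel has no non-flagged populations")
        return float(np.mean([p.frequencies.get(allele, 0.0) for p in pops]))

    def allele_set(self, locus: str) -> set[AlleleName]:
        out: set[AlleleName] = set()
        for p in self.included():
            out |= {a for a in p.frequencies if a.locus == locus}
        return out


@dataclass
class SequenceMap:
    """Aligned DNA sequences (alphabet ACGT-) per two-field allele, per locus."""

    sequences: dict[str, dict[AlleleName, str]]

    def __post_init__(self) -> None:
        for locus, seqs in self.sequences.items():
            lengths = {len(s) for s in seqs.values()}
            if len(lengths) > 1:
                raise ValueError(f"ragged alignment for locus {locus}: lengths {sorted(lengths)}")
            for allele, s in seqs.items():
                bad = set(s) - set("ACGT-")
                if bad:
                    raise ValueError(f"{allele}: invalid characters {sorted(bad)}")

    def get(self, allele: AlleleName) -> str:
        return self.sequences[allele.locus][allele]

    def loci(self) -> list[str]:
        return list(self.sequences)


@dataclass
class MsatPanel:
    """Genome-wide microsatellite genotypes on the same individual index as a Cohort.

    ``sizes`` has shape (n_individuals, n_markers, 2) of integer repeat sizes;
    0 encodes a missing call.  ``index`` aligns rows with (population, id).
    """

    index: list[tuple[str, str]]
    markers: list[str]
    sizes: np.ndarray

    def __post_init__(self) -> None:
        self.sizes = np.asarray(self.sizes, dtype=np.int64)
        if self.sizes.shape != (len(self.index), len(self.markers), 2):
            raise ValueError("sizes array shape does not match index/markers")
        if (self.sizes < 0).any():
            raise ValueError("allele sizes must be non-negative integers")

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def population_rows(self, population: str) -> np.ndarray:
        return np.array([i for i, (p, _) in enumerate(self.index) if p == population])

    def homozygous_proportion(self) -> np.ndarray:
        """Per individual, the proportion of non-missing markers that are homozygous."""
        typed = (self.sizes > 0).all(axis=2)
        hom = (self.sizes[:, :, 0] == self.sizes[:, :, 1]) & typed
        with np.errstate(invalid="ignore"):
            return hom.sum(axis=1) / typed.sum(axis=1)

    def marker_sizes(self, population_rows: np.ndarray, marker_idx: int) -> np.ndarray:
        """Flat vector of typed allele sizes at one marker for the given rows."""
        vals = self.sizes[population_rows, marker_idx, :].ravel()
        return vals[vals > 0]


# ---------------------------------------------------------------------------
# File IO


def read_region_map(path: str | Path) -> tuple[dict[str, str], dict[str, int]]:
    """CSV with columns population, region[, ordering_rank]."""
    df = pd.read_csv(path)
    region_map = dict(zip(df["population"].astype(str), df["region"].astype(str)))
    ordering: dict[str, int] = {}
    if "ordering_rank" in df.columns:
        sub = df.dropna(subset=["ordering_rank"])
        ordering = dict(zip(sub["population"].astype(str), sub["ordering_rank"].astype(int)))
    return region_map, ordering


def write_region_map(path: str | Path, region_map: Mapping[str, str],
                     ordering: Mapping[str, int] | None = None) -> None:
    rows = []
    for pop, region in region_map.items():
        row = {"population": pop, "region": region}
        if ordering and pop in ordering:
            row["ordering_rank"] = ordering[pop]
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_cohort(path: str | Path, region_map_path: str | Path,
                loci: Sequence[str] = LOCI) -> Cohort:
    """Read a genotype TSV (population, id, then two columns per locus)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    expected = ["population", "id"] + [
        f"{locus}_{i}" for locus in loci for i in (1, 2)
    ]
    missing = [c for c in expected if c not in df.columns]
    if missing:
        raise ValueError(f"genotype table missing columns: {missing}")
    region_map, ordering = read_region_map(region_map_path)

    pops: dict[str, PopulationSample] = {}
    for _, row in df.iterrows():
        pname = row["population"]
        if pname not in region_map:
            raise ValueError(f"population {pname!r} not present in region map")
        pop = pops.setdefault(pname, PopulationSample(name=pname))
        ind = Individual(ident=row["id"])
        for locus in loci:
            a_txt, b_txt = row[f"{locus}_1"].strip(), row[f"{locus}_2"].strip()
            if not a_txt and not b_txt:
                continue
            if not a_txt or not b_txt:
                raise ValueError(
                    f"individual {ind.ident}: half-typed genotype at {locus}"
                )
            ind.genotypes[locus] = _canonical_pair(
                parse_allele_name(a_txt), parse_allele_name(b_txt)
            )
        pop.individuals.append(ind)
    return Cohort(
        populations=list(pops.values()),
        region_map=region_map,
        ordering=ordering or None,
    )


def write_cohort(cohort: Cohort, path: str | Path,
                 loci: Sequence[str] = LOCI) -> None:
    rows = []
    for pop in cohort.populations:
        for ind in pop.individuals:
            row: dict[str, str] = {"population": pop.name, "id": ind.ident}
            for locus in loci:
                g = ind.genotypes.get(locus)
                row[f"{locus}_1"] = str(g[0]) if g else ""
                row[f"{locus}_2"] = str(g[1]) if g else ""
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_reference_panel(path: str | Path) -> ReferencePanel:
    """CSV with columns population, allele, frequency, n, migrant, uncertain."""
    df = pd.read_csv(path)
    pops: dict[str, PanelPopulation] = {}
    for _, row in df.iterrows():
        name = str(row["population"])
        if name not in pops:
            pops[name] = PanelPopulation(
                name=name,
                frequencies={},
                n=int(row["n"]),
                migrant=bool(int(row.get("migrant", 0))),
                uncertain_origin=bool(int(row.get("uncertain", 0))),
            )
        allele = parse_allele_name(str(row["allele"]))
        pops[name].frequencies[allele] = float(row["frequency"])
    return ReferencePanel(populations=list(pops.values()))


def write_reference_panel(panel: ReferencePanel, path: str | Path) -> None:
    rows = []
    for pop in panel.populations:
        for allele, freq in sorted(pop.frequencies.items()):
            rows.append(
                {
                    "population": pop.name,
                    "allele": str(allele),
                    "frequency": freq,
                    "n": pop.n,
                    "migrant": int(pop.migrant),
                    "uncertain": int(pop.uncertain_origin),
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_sequence_map(fasta_path: str | Path, locus: str) -> SequenceMap:
    """Read one locus's aligned allele sequences from FASTA (headers = allele names)."""
    seqs: dict[AlleleName, str] = {}
    for record in SeqIO.parse(str(fasta_path), "fasta"):
        allele = parse_allele_name(record.id)
        if allele in seqs:
            raise ValueError(f"duplicate allele header {allele}")
        seqs[allele] = str(record.seq).upper()
    return SequenceMap(sequences={locus: seqs})


def merge_sequence_maps(maps: Iterable[SequenceMap]) -> SequenceMap:
    merged: dict[str, dict[AlleleName, str]] = {}
    for m in maps:
        for locus, seqs in m.sequences.items():
            merged.setdefault(locus, {}).update(seqs)
    return SequenceMap(sequences=merged)


def write_sequence_map(seqmap: SequenceMap, locus: str, path: str | Path) -> None:
    with open(path, "w") as fh:
        for allele, seq in sorted(seqmap.sequences[locus].items()):
            fh.write(f">{allele}\n{seq}\n")


def read_msat_panel(path: str | Path) -> MsatPanel:
    """TSV: population, id, then two columns per marker (``M0001_1`` ...)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    marker_cols = [c for c in df.columns if c not in ("population", "id")]
    markers = sorted({c.rsplit("_", 1)[0] for c in marker_cols})
    index = list(zip(df["population"], df["id"]))
    sizes = np.zeros((len(df), len(markers), 2), dtype=np.int64)
    for j, marker in enumerate(markers):
        for allele_idx in (0, 1):
            col = df[f"{marker}_{allele_idx + 1}"].replace("", "0")
            sizes[:, j, allele_idx] = col.astype(int).to_numpy()
    return MsatPanel(index=index, markers=markers, sizes=sizes)


def write_msat_panel(panel: MsatPanel, path: str | Path) -> None:
    data: dict[str, list] = {
        "population": [p for p, _ in panel.index],
        "id": [i for _, i in panel.index],
    }
    for j, marker in enumerate(panel.markers):
        data[f"{marker}_1"] = panel.sizes[:, j, 0]
        data[f"{marker}_2"] = panel.sizes[:, j, 1]
    pd.DataFrame(data).to_csv(path, sep="\t", index=False)
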