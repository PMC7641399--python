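"""Allele-name parsing, genotype-table IO, and frequency tallies."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hla_popstruct.data import (
    AlleleName,
    AlleleParseError,
    Cohort,
    EmptyLocusError,
    Individual,
    PopulationSample,
    SequenceMap,
    allele_frequencies,
    parse_allele_name,
    read_cohort,
    read_reference_panel,
    read_sequence_map,
    write_cohort,
    write_region_map,
)


class TestAlleleNames:
    @pytest.mark.parametrize(
        "text, expected",
        [
            ("A*02:01:01G", AlleleName("A", "02", "01", g_group=True)),
            ("B*39:06", AlleleName("B", "39", "06")),
            ("B*39:06:01", AlleleName("B", "39", "06")),
            ("B*39:06:02", AlleleName("B", "39", "06")),
            ("DRB1*04:05:01", AlleleName("DRB1", "04", "05")),
        ],
    )
    def test_two_field_reduction(self, text, expected):
        assert parse_allele_name(text) == expected

    def test_molecular_variants_collapse_to_one_name(self):
        assert parse_allele_name("B*39:06:01") == parse_allele_name("B*39:06:02")

    def test_format_parse_round_trip(self):
        for text in ["B*39:06", "A*02:01G", "DRB1*14:02", "C*03:05"]:
            allele = parse_allele_name(text)
            assert parse_allele_name(str(allele)) == allele
            assert str(allele) == text

    def test_reduction_is_idempotent(self):
        reduced = parse_allele_name("A*02:01:01:02G")
        assert parse_allele_name(str(reduced)) == reduced

    @pytest.mark.parametrize("bad", ["A02:01", "B*39", "X*zz:01", "", "B*39:06:"])
    def test_malformed_names_raise(self, bad):
        with pytest.raises(AlleleParseError, match="malformed"):
            parse_allele_name(bad)


def _pop(genotypes, locus="A"):
    pop = PopulationSample(name="toy")
    for i, (a, b) in enumerate(genotypes):
        pair = tuple(sorted((parse_allele_name(a), parse_allele_name(b))))
        pop.individuals.append(Individual(ident=str(i), genotypes={locus: pair}))
    return pop


class TestAlleleFrequencies:
    def test_simple_tally(self):
        pop = _pop([("A*01:01", "A*01:01"), ("A*01:01", "A*01:02")])
        ft = allele_frequencies(pop, "A")
        assert ft.n == 4
        freqs = {str(a): f for a, f in ft.frequencies.items()}
        assert freqs == {"A*01:01": 0.75, "A*01:02": 0.25}

    def test_monomorphic(self):
        ft = allele_frequencies(_pop([("A*01:01", "A*01:01")] * 3), "A")
        assert ft.k == 1 and ft.frequency(parse_allele_name("A*01:01")) == 1.0

    def test_empty_locus_error(self):
        with pytest.raises(EmptyLocusError):
            allele_frequencies(_pop([("A*01:01", "A*01:01")]), "B")

    @given(st.lists(st.tuples(st.integers(0, 5), st.integers(0, 5)),
                    min_size=1, max_size=30))
    @settings(max_examples=50, deadline=None)
    def test_counts_sum_to_n_and_frequencies_to_one(self, pairs):
        genotypes = [(f"A*01:{a+1:02d}", f"A*01:{b+1:02d}") for a, b in pairs]
        ft = allele_frequencies(_pop(genotypes), "A")
        assert sum(ft.counts.values()) == 2 * len(pairs)
        assert abs(sum(ft.frequencies.values()) - 1.0) < 1e-12
        # independent brute-force tally
        flat = [x for g in genotypes for x in g]
        assert {str(a): c for a, c in ft.counts.items()} == {
            a: flat.count(a) for a in set(flat)
        }


class TestCohortIO:
    def _write_inputs(self, tmp_path, rows, regions):
        geno = tmp_path / "cohort.tsv"
        header = "population\tid\tA_1\tA_2\tB_1\tB_2\tC_1\tC_2\tDRB1_1\tDRB1_2"
        geno.write_text("\n".join([header] + rows) + "\n")
        rmap = tmp_path / "regions.csv"
        write_region_map(rmap, regions)
        return geno, rmap

    def test_round_trip_and_locus_counts(self, tmp_path):
        rows = [
            "P1\ti1\tA*01:01\tA*01:02\tB*15:04\tB*15:04\tC*03:05\tC*04:01\tDRB1*08:02\tDRB1*08:02",
            "P1\ti2\tA*01:01\tA*01:01\tB*15:04\tB*35:19\tC*03:05\tC*03:05\t\t",
        ]
        geno, rmap = self._write_inputs(tmp_path, rows, {"P1": "NAM"})
        cohort = read_cohort(geno, rmap)
        pop = cohort.population("P1")
        assert pop.n_chromosomes("A") == 4
        # blank DRB1 cells drop the individual at that locus only
        assert pop.n_chromosomes("DRB1") == 2
        out = tmp_path / "round.tsv"
        write_cohort(cohort, out)
        again = read_cohort(out, rmap)
        for locus in ("A", "B", "C", "DRB1"):
            assert again.population("P1").genotype_pairs(locus) == pop.genotype_pairs(
                locus
            )

    def test_unknown_population_rejected(self, tmp_path):
        rows = ["P2\ti1\tA*01:01\tA*01:02\tB*15:04\tB*15:04\t"
                "C*03:05\tC*04:01\tDRB1*08:02\tDRB1*08:02"]
        geno, rmap = self._write_inputs(tmp_path, rows, {"P1": "NAM"})
        with pytest.raises(ValueError, match="region map"):
            read_cohort(geno, rmap)

    def test_invalid_region_label_rejected(self):
        with pytest.raises(ValueError, match="not in"):
            Cohort(populations=[PopulationSample("X")], region_map={"X": "EUR"})


class TestSequencesAndPanel:
    def test_fasta_round(self, tmp_path):
        path = tmp_path / "a.fasta"
        path.write_text(">A*01:01\nACGT\n>A*01:02\nACGA\n>A*01:03\nTCGA\n")
        sm = read_sequence_map(path, "A")
        assert len(sm.sequences["A"]) == 3

    def test_ragged_alignment_rejected(self, tmp_path):
        path = tmp_path / "a.fasta"
        path.write_text(">A*01:01\nACGT\n>A*01:02\nACG\n")
        with pytest.raises(ValueError, match="ragged"):
            read_sequence_map(path, "A")

    def test_gap_alphabet_allowed_others_rejected(self):
        SequenceMap(sequences={"A": {parse_allele_name("A*01:01"): "AC-T"}})
        with pytest.raises(ValueError, match="invalid"):
            SequenceMap(sequences={"A": {parse_allele_name("A*01:01"): "ACNT"}})

    def test_migrant_population_excluded_from_means(self, tmp_path):
        path = tmp_path / "panel.csv"
        path.write_text(
            "population,allele,frequency,n,migrant,uncertain\n"
            "W1,A*01:01,0.2,100,0,0\n"
            "W2,A*01:01,0.4,100,0,0\n"
            "MIG,A*01:01,1.0,100,1,0\n"
        )
        panel = read_reference_panel(path)
        assert panel.mean_frequency(parse_allele_name("A*01:01")) == pytest.approx(0.3)
        # an allele only carried by the migrant population has mean zero
        assert panel.mean_frequency(parse_allele_name("A*99:99")) == 0.0


def test_synthetic_cohort_satisfies_frequency_invariants(small_bundle):
    cohort, _, _, _ = small_bundle
    for pop in cohort.populations:
        for locus in ("A", "B", "C", "DRB1"):
            ft = allele_frequencies(pop, locus)
            assert sum(ft.counts.values()) == pop.n_chromosomes(locus)
            assert np.isclose(sum(ft.frequencies.values()), 1.0, atol=1e-12)
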