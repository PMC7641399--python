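"""Endemic / LFD classification, category sums, regional means."""

import numpy as np
import pytest

from hla_popstruct.data import (
    Cohort,
    Individual,
    PanelPopulation,
    PopulationSample,
    ReferencePanel,
    parse_allele_name,
)
from hla_popstruct.geography import (
    category_frequency_sums,
    category_msat_correlation,
    classify_alleles,
    final_category_map,
    region_category_means,
)
from hla_popstruct.published import published_category_sums
from hla_popstruct.simulate import sim_cohort

from conftest import fast_params


def _cohort_from_freqs(pop_counts):
    """pop_counts: {pop: {allele_text: copies}} with even totals -> Cohort."""
    pops = []
    for name, counts in pop_counts.items():
        gametes = [
            parse_allele_name(a) for a, c in counts.items() for _ in range(c)
        ]
        pop = PopulationSample(name=name)
        for i in range(len(gametes) // 2):
            pair = tuple(sorted((gametes[2 * i], gametes[2 * i + 1])))
            pop.individuals.append(
                Individual(ident=f"{name}{i}", genotypes={"A": pair})
            )
        pops.append(pop)
    return Cohort(populations=pops, region_map={n: "SAL" for n in pop_counts})


def _panel(freqs_by_pop):
    return ReferencePanel(
        populations=[
            PanelPopulation(
                name=name,
                frequencies={parse_allele_name(a): f for a, f in freqs.items()},
                n=100,
            )
            for name, freqs in freqs_by_pop.items()
        ]
    )


class TestClassification:
    def test_threefold_boundary_is_inclusive(self):
        # native mean 0.09 vs reference mean 0.03 -> ratio exactly 3 -> LFD
        cohort = _cohort_from_freqs(
            {"P1": {"A*01:01": 9, "A*01:02": 91}}
        )
        panel = _panel({"W1": {"A*01:01": 0.03, "A*01:02": 0.97}})
        cls = {str(c.allele): c for c in classify_alleles(cohort, panel, "A",
                                                          secondary={})}
        assert cls["A*01:01"].ratio == pytest.approx(3.0)
        assert cls["A*01:01"].category == "LFD"
        assert cls["A*01:02"].category == "other"

    def test_absent_from_reference_is_endemic(self):
        cohort = _cohort_from_freqs({"P1": {"A*90:01": 4, "A*01:02": 16}})
        panel = _panel({"W1": {"A*01:02": 1.0}})
        cls = {str(c.allele): c for c in classify_alleles(cohort, panel, "A",
                                                          secondary={})}
        assert cls["A*90:01"].category == "endemic"
        assert not cls["A*90:01"].poorly_supported  # 4 copies

    def test_poor_support_flag_and_removal_filter(self):
        cohort = _cohort_from_freqs(
            {"P1": {"A*01:01": 2, "A*01:02": 98}}
        )
        panel = _panel({"W1": {"A*01:01": 0.001, "A*01:02": 0.999}})
        # poorly supported in the primary; secondary says also poorly supported
        cls = classify_alleles(cohort, panel, "A",
                               secondary={parse_allele_name("A*01:01"): True})
        target = next(c for c in cls if str(c.allele) == "A*01:01")
        assert target.category == "LFD" and target.poorly_supported
        assert target.removed
        # well supported in the secondary dataset -> kept
        cls2 = classify_alleles(cohort, panel, "A",
                                secondary={parse_allele_name("A*01:01"): False})
        target2 = next(c for c in cls2 if str(c.allele) == "A*01:01")
        assert not target2.removed

    def test_removal_filter_only_shrinks_lfd_list(self):
        cohort = _cohort_from_freqs(
            {"P1": {"A*01:01": 2, "A*01:03": 2, "A*01:02": 96}}
        )
        panel = _panel(
            {"W1": {"A*01:01": 0.001, "A*01:03": 0.001, "A*01:02": 0.998}}
        )
        with_filter = final_category_map(
            classify_alleles(cohort, panel, "A",
                             secondary={parse_allele_name("A*01:01"): True})
        )
        without = {
            c.allele: c.category
            for c in classify_alleles(cohort, panel, "A", secondary={})
        }
        lfd_with = {a for a, c in with_filter.items() if c == "LFD"}
        lfd_without = {a for a, c in without.items() if c == "LFD"}
        assert lfd_with <= lfd_without

    def test_categories_partition_allele_set(self, small_bundle):
        cohort, _, panel, _ = small_bundle
        for locus in ("A", "B"):
            cat = final_category_map(
                classify_alleles(cohort, panel, locus, secondary={})
            )
            native_alleles = set()
            for pop in cohort.native_populations():
                native_alleles |= pop.allele_set(locus)
            assert set(cat) == native_alleles
            assert set(cat.values()) <= {"endemic", "LFD", "other"}

    def test_planted_truth_recovered(self, small_bundle):
        cohort, _, panel, truth = small_bundle
        for planted in truth["planted"]:
            cls = classify_alleles(cohort, panel, planted["locus"], secondary={})
            entry = next(
                c for c in cls if str(c.allele) == planted["allele"]
            )
            if planted["category"] == "endemic" and entry.copies >= 4:
                assert entry.category == "endemic"


class TestCategorySums:
    def test_sums_partition_unity(self, small_bundle):
        cohort, _, panel, _ = small_bundle
        cls = {
            locus: classify_alleles(cohort, panel, locus, secondary={})
            for locus in ("A", "B", "C", "DRB1")
        }
        sums = category_frequency_sums(cohort, cls)
        totals = sums["endemic_sum"] + sums["lfd_sum"] + sums["other_sum"]
        assert np.allclose(totals, 1.0, atol=1e-12)

    def test_no_endemics_gives_zero_sum(self):
        cohort = _cohort_from_freqs({"P1": {"A*01:01": 10, "A*01:02": 10}})
        panel = _panel({"W1": {"A*01:01": 0.5, "A*01:02": 0.5}})
        cls = {"A": classify_alleles(cohort, panel, "A", secondary={})}
        sums = category_frequency_sums(cohort, cls)
        assert (sums["endemic_sum"] == 0.0).all()


class TestRegionMeans:
    def test_single_population_region_mean_is_its_sum(self):
        sums = published_category_sums()
        chip = sums[(sums["population"] == "Chipewyan") & (sums["locus"] == "A")]
        out = region_category_means(
            sums[sums["population"].isin(["Chipewyan"])], exclude=set()
        )
        lfd_a = out[(out["locus"] == "A") & (out["category"] == "LFD")]
        assert lfd_a["NAM"].iloc[0] == pytest.approx(float(chip["lfd_sum"].iloc[0]))

    def test_published_regional_means_recovered(self):
        # the published regional means must equal unweighted averages of the
        # published per-population sums, with the Ache outlier excluded
        out = region_category_means(published_category_sums())
        cell = out.set_index(["locus", "category"])
        assert cell.loc[("B", "endemic"), "SAL"] == pytest.approx(0.128, abs=5e-4)
        assert cell.loc[("B", "LFD"), "SAL"] == pytest.approx(0.487, abs=5e-4)
        assert cell.loc[("DRB1", "LFD"), "all_regions"] == pytest.approx(
            0.636, abs=5e-4
        )
        assert cell.loc[("A", "endemic"), "SAA"] == pytest.approx(0.050, abs=5e-4)
        assert cell.loc[("A", "LFD"), "MEA"] == pytest.approx(0.508, abs=5e-4)

    def test_outlier_exclusion_applies_to_every_cell(self):
        incl = region_category_means(published_category_sums(), exclude=set())
        excl = region_category_means(published_category_sums())
        # the Ache has extreme LFD sums, so excluding it moves SAL values
        a = incl.set_index(["locus", "category"]).loc[("A", "LFD"), "SAL"]
        b = excl.set_index(["locus", "category"]).loc[("A", "LFD"), "SAL"]
        assert a > b


class TestMsatCorrelation:
    def test_constant_sums_reported_missing(self):
        sums = published_category_sums()
        sub = sums[sums["locus"] == "DRB1"].copy()
        sub["endemic_sum"] = 0.1
        sub["lfd_sum"] = 0.2
        out = category_msat_correlation(
            sub, {p: 0.5 + i * 0.01 for i, p in enumerate(sub["population"])}
        )
        assert np.isnan(out["r"].iloc[0])

    def test_drift_links_category_burden_to_low_msat_heterozygosity(self):
        # populations that experienced more drift carry more private/boosted
        # alleles and lower microsatellite heterozygosity: r < 0 in most runs
        from hla_popstruct.diversity import msat_mean_heterozygosity

        neg = 0
        reps = 30
        for rep in range(reps):
            cohort, msat, panel, _ = sim_cohort(
                fast_params(seed=7_000 + rep, n_msat=40, n_ref_pops=10)
            )
            cls = {"B": classify_alleles(cohort, panel, "B", secondary={})}
            sums = category_frequency_sums(cohort, cls)
            msat_h = {
                p.name: msat_mean_heterozygosity(msat, p.name)
                for p in cohort.native_populations()
            }
            out = category_msat_correlation(
                sums[sums["region"] != "SIB"], msat_h
            )
            if out["r"].iloc[0] < 0:
                neg += 1
        assert neg >= int(0.9 * reps) - 2
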