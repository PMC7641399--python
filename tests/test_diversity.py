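"""Heterozygosity summaries, correlations, regional and individual contrasts."""

import numpy as np
import pytest
from scipy import stats

from hla_popstruct.data import (
    Cohort,
    FrequencyTable,
    Individual,
    MsatPanel,
    PopulationSample,
    parse_allele_name,
)
from hla_popstruct.diversity import (
    cohort_allele_count,
    heterozygosity,
    homozygosity_class_trend,
    individual_level_association,
    population_level_correlation,
    regional_contrasts,
    zygosity_table,
)


def _ft(counts):
    return FrequencyTable(
        "A", {parse_allele_name(f"A*01:{i+1:02d}"): c for i, c in enumerate(counts)}
    )


class TestHeterozygosity:
    def test_two_alleles_counts_2_2(self):
        s = heterozygosity(_ft([2, 2]))
        assert s.H == pytest.approx(4 / 3 * 0.5)
        assert s.k == 2 and s.n == 4

    def test_monomorphic_is_zero(self):
        assert heterozygosity(_ft([10])).H == 0.0

    def test_correction_flag(self):
        assert heterozygosity(_ft([2, 2]), corrected=False).H == pytest.approx(0.5)

    def test_relabeling_invariance_and_uniform_maximum(self):
        rng = np.random.default_rng(0)
        counts = [7, 3, 5, 1]
        h = heterozygosity(_ft(counts)).H
        perm = list(rng.permutation(counts))
        assert heterozygosity(_ft(perm)).H == pytest.approx(h)
        # uniform frequencies maximize H for fixed k and n
        assert heterozygosity(_ft([4, 4, 4, 4])).H >= h


class TestAlleleCounts:
    def _cohort(self, pop_alleles):
        pops = []
        for name, alleles in pop_alleles.items():
            pop = PopulationSample(name=name)
            for i, (a, b) in enumerate(alleles):
                pop.individuals.append(
                    Individual(
                        ident=f"{name}{i}",
                        genotypes={
                            "A": tuple(sorted((parse_allele_name(a),
                                               parse_allele_name(b))))
                        },
                    )
                )
            pops.append(pop)
        return Cohort(populations=pops,
                      region_map={n: "NAM" for n in pop_alleles})

    def test_shared_plus_private(self):
        cohort = self._cohort(
            {
                "P1": [("A*01:01", "A*01:02")],
                "P2": [("A*01:01", "A*01:03")],
            }
        )
        assert cohort_allele_count(cohort, "A") == 3

    def test_union_matches_brute_force(self, small_bundle):
        cohort, _, _, _ = small_bundle
        for locus in ("A", "B"):
            brute = set()
            for pop in cohort.populations:
                for ind in pop.individuals:
                    if locus in ind.genotypes:
                        brute.update(ind.genotypes[locus])
            assert cohort_allele_count(cohort, locus) == len(brute)


class TestPopulationCorrelation:
    def test_identical_vectors(self):
        r, _ = population_level_correlation([0.1, 0.5, 0.9], [0.1, 0.5, 0.9])
        assert r == pytest.approx(1.0)

    def test_matches_hand_rolled_covariance(self):
        rng = np.random.default_rng(3)
        x = rng.random(12)
        y = 0.5 * x + rng.random(12) * 0.1
        r, _ = population_level_correlation(x, y)
        hand = ((x - x.mean()) * (y - y.mean())).sum() / np.sqrt(
            ((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum()
        )
        assert r == pytest.approx(hand, abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            population_level_correlation([1.0, 1.0, 1.0], [0.1, 0.2, 0.3])


class TestRegionalContrasts:
    REGIONS = {f"P{i}": ("NAM" if i < 4 else "SAL") for i in range(8)}

    def test_equal_values_give_p_one(self):
        h = {p: 0.5 for p in self.REGIONS}
        out = regional_contrasts(h, self.REGIONS, exclude=set())
        assert (out["p_adj"] == 1.0).all()

    def test_separated_regions_strongly_significant(self):
        rng = np.random.default_rng(1)
        h = {}
        for i, p in enumerate(self.REGIONS):
            base = 0.9 if self.REGIONS[p] == "NAM" else 0.3
            h[p] = base + rng.normal(0, 0.006)  # 10 SD separation
        out = regional_contrasts(h, self.REGIONS, exclude=set())
        assert (out["p_adj"] < 1e-4).all()

    def test_tukey_adjusted_p_not_below_unadjusted(self):
        rng = np.random.default_rng(2)
        regions = {f"P{i}": r for i, r in enumerate(
            ["NAM"] * 3 + ["MEA"] * 3 + ["SAL"] * 3)}
        h = {p: rng.random() for p in regions}
        out = regional_contrasts(h, regions, exclude=set())
        for _, row in out.iterrows():
            a = [h[p] for p in regions if regions[p] == row["region1"]]
            b = [h[p] for p in regions if regions[p] == row["region2"]]
            raw = stats.ttest_ind(a, b).pvalue
            assert row["p_adj"] >= raw - 1e-9

    def test_singleton_region_skipped_with_warning(self):
        regions = dict(self.REGIONS, P9="SIB")
        h = {p: 0.1 * i for i, p in enumerate(regions)}
        with pytest.warns(UserWarning, match="skipped"):
            out = regional_contrasts(h, regions, exclude=set())
        assert set(out["region1"]) | set(out["region2"]) == {"NAM", "SAL"}


def _independent_bundle(seed, n_pops=4, n_ind=40, n_msat=50):
    """HLA genotypes and microsatellites drawn independently (no association)."""
    rng = np.random.default_rng(seed)
    pops, index, sizes = [], [], []
    for p in range(n_pops):
        name = f"P{p}"
        pop = PopulationSample(name=name)
        for i in range(n_ind):
            ind = Individual(ident=f"{name}_{i}")
            for locus in ("A", "B", "C", "DRB1"):
                a, b = rng.integers(1, 5, size=2)
                pair = tuple(sorted((
                    parse_allele_name(f"{locus}*01:{a:02d}"),
                    parse_allele_name(f"{locus}*01:{b:02d}"),
                )))
                ind.genotypes[locus] = pair
            pop.individuals.append(ind)
            index.append((name, ind.ident))
            sizes.append(rng.integers(10, 14, size=(n_msat, 2)))
        pops.append(pop)
    cohort = Cohort(populations=pops, region_map={f"P{p}": "SAL" for p in range(n_pops)})
    panel = MsatPanel(index=index, markers=[f"M{j}" for j in range(n_msat)],
                      sizes=np.array(sizes))
    return cohort, panel


class TestIndividualLevel:
    def test_null_association_has_nominal_type_one_error(self):
        # with HLA and msat genotypes drawn independently, the fraction of
        # populations significant at raw alpha should be near alpha
        alpha, hits, total = 0.05, 0, 0
        for rep in range(50):
            cohort, panel = _independent_bundle(seed=900 + rep)
            out = individual_level_association(cohort, panel)
            hits += int((out["p"] < alpha).sum())
            total += int(out["p"].notna().sum())
        rate = hits / total
        se = np.sqrt(alpha * (1 - alpha) / total)
        assert abs(rate - alpha) < 4 * se

    def test_perfect_trend_is_detected(self):
        cohort, panel = _independent_bundle(seed=1, n_pops=1, n_ind=120)
        table = zygosity_table(cohort, panel)
        # overwrite msat homozygosity to follow the HLA class exactly
        sizes = panel.sizes.copy()
        for row, cls in enumerate(table["hla_hom_count"].clip(upper=2)):
            n_hom = int(10 + 12 * cls)
            sizes[row, :, 1] = sizes[row, :, 0] + 1
            sizes[row, :n_hom, 1] = sizes[row, :n_hom, 0]
        forced = MsatPanel(index=panel.index, markers=panel.markers, sizes=sizes)
        slope, p, summary = homozygosity_class_trend(cohort, forced, "SAL")
        assert slope > 0 and p < 0.001
        means = summary.set_index("cls")["mean"]
        assert means.is_monotonic_increasing

    def test_zygosity_classes_derived_from_counts(self, small_bundle):
        cohort, msat, _, _ = small_bundle
        table = zygosity_table(cohort, msat)
        assert set(table["hla_class"]) <= {"0", "1", "2+"}
        derived = table["hla_hom_count"].map(
            lambda c: "2+" if c >= 2 else str(c)
        )
        assert (derived == table["hla_class"]).all()
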