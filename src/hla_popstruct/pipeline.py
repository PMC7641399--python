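"""End-to-end orchestration: simulate or load inputs, run every stage, emit TSVs.

Each stage is a thin driver over the library modules; every number written
to disk is produced by a module operation.  Stages whose optional inputs
are missing (e.g. no sequence map -> no Tajima table) are skipped with a
note in the run log.  All stochastic stages take explicit seeds recorded
in the log, so a repeated run with the same config is byte-identical.
"""

from __future__ import annotations

import itertools
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import differentiation, diversity, geography, haplotypes, hwp, neutrality
from .data import (
    Cohort,
    MsatPanel,
    ReferencePanel,
    SequenceMap,
    allele_frequencies,
    merge_sequence_maps,
    read_cohort,
    read_msat_panel,
    read_reference_panel,
    read_sequence_map,
    write_cohort,
    write_msat_panel,
    write_reference_panel,
    write_region_map,
    write_sequence_map,
)
from .simulate import SimParams, sim_cohort, sim_sequences

DEFAULT_EXCLUDE = {"Ache"}


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def sequences_for_cohort(
    cohort: Cohort, length: int = 300, mode: str = "balanced_clades", seed: int = 0
) -> SequenceMap:
    """Synthetic aligned sequences covering every allele observed in the cohort."""
    maps = []
    for i, locus in enumerate(sorted({l for p in cohort.populations
                                      for ind in p.individuals
                                      for l in ind.genotypes})):
        alleles = sorted(cohort.allele_set(locus))
        if len(alleles) < 2:
            continue
        raw = sim_sequences(len(alleles), max(length, len(alleles) + 20),
                            mode, seed=seed + i, locus=locus)
        seqs = [raw.sequences[locus][a] for a in sorted(raw.sequences[locus])]
        maps.append(SequenceMap(sequences={locus: dict(zip(alleles, seqs))}))
    return merge_sequence_maps(maps)


def stage_simulate(config: dict, outdir: Path, seed: int) -> dict:
    """Generate the full synthetic bundle and write it in the standard formats."""
    overrides = dict(config.get("simulate", {}))
    overrides["seed"] = seed
    params = SimParams(**overrides)
    cohort, msat, panel, truth = sim_cohort(params)
    outdir.mkdir(parents=True, exist_ok=True)
    write_cohort(cohort, outdir / "cohort.tsv")
    write_region_map(outdir / "region_map.csv", cohort.region_map, cohort.ordering)
    write_msat_panel(msat, outdir / "msat_panel.tsv")
    write_reference_panel(panel, outdir / "reference_panel.csv")
    seqmap = sequences_for_cohort(cohort, seed=seed + 1000)
    for locus in seqmap.loci():
        write_sequence_map(seqmap, locus, outdir / f"sequences_{locus}.fasta")
    with open(outdir / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=2)
    return {
        "cohort": cohort, "msat": msat, "panel": panel,
        "seqmap": seqmap, "truth": truth,
    }


def load_inputs(config: dict) -> dict:
    paths = config.get("inputs", {})
    objs: dict = {}
    if "cohort" in paths:
        objs["cohort"] = read_cohort(paths["cohort"], paths["region_map"])
    if "msat_panel" in paths:
        objs["msat"] = read_msat_panel(paths["msat_panel"])
    if "reference_panel" in paths:
        objs["panel"] = read_reference_panel(paths["reference_panel"])
    if "sequences" in paths:
        objs["seqmap"] = merge_sequence_maps(
            read_sequence_map(p, locus) for locus, p in paths["sequences"].items()
        )
    return objs


def _loci(cohort: Cohort) -> list[str]:
    return sorted({l for p in cohort.populations
                   for ind in p.individuals for l in ind.genotypes})


def stage_diversity(objs: dict, outdir: Path, exclude: set[str]) -> dict:
    cohort: Cohort = objs["cohort"]
    table = diversity.diversity_table(cohort)
    table.to_csv(outdir / "diversity_table.tsv", sep="\t", index=False)
    out: dict = {"table": table}
    if "msat" in objs:
        msat: MsatPanel = objs["msat"]
        msat_h = {
            p.name: diversity.msat_mean_heterozygosity(msat, p.name)
            for p in cohort.populations
        }
        loci = _loci(cohort)
        hla_mean = table.set_index("population")[
            [f"H_{l}" for l in loci]
        ].mean(axis=1)
        pops = [p for p in hla_mean.index if p in msat_h]
        r, p_val = diversity.population_level_correlation(
            [hla_mean[p] for p in pops], [msat_h[p] for p in pops]
        )
        contrasts = diversity.regional_contrasts(
            msat_h, cohort.region_map, exclude=exclude
        )
        contrasts.to_csv(outdir / "regional_contrasts.tsv", sep="\t", index=False)
        assoc = diversity.individual_level_association(cohort, msat)
        assoc.to_csv(outdir / "individual_association.tsv", sep="\t", index=False)
        trend_rows = []
        for region in sorted(set(cohort.region_map.values())):
            try:
                slope, p_trend, _ = diversity.homozygosity_class_trend(
                    cohort, msat, region
                )
            except ValueError:
                continue
            trend_rows.append({"region": region, "slope": slope, "p": p_trend})
        pd.DataFrame(trend_rows).to_csv(
            outdir / "homozygosity_class_trend.tsv", sep="\t", index=False
        )
        out.update({"msat_h": msat_h, "hla_msat_r": r, "hla_msat_p": p_val,
                    "contrasts": contrasts, "association": assoc})
    return out


def stage_hwp(objs: dict, outdir: Path, seed: int, mc_steps: int = 100_000) -> pd.DataFrame:
    cohort: Cohort = objs["cohort"]
    rows, residuals = [], []
    for i, pop in enumerate(cohort.populations):
        for j, locus in enumerate(_loci(cohort)):
            pairs = pop.genotype_pairs(locus)
            if len(pairs) < 2:
                continue
            res = hwp.hwp_exact(
                pairs, mc_steps=mc_steps, seed=seed + 97 * i + j, locus=locus
            )
            rows.append(
                {"population": pop.name, "locus": locus, "p": res.p,
                 "method": res.method, "significant": res.p < 0.05}
            )
            flagged = hwp.genotype_residuals(res)
            for _, r in flagged.iterrows():
                residuals.append({"population": pop.name, "locus": locus, **r})
    report = pd.DataFrame(rows)
    report.to_csv(outdir / "hwp_tests.tsv", sep="\t", index=False)
    pd.DataFrame(residuals).to_csv(
        outdir / "hwp_flagged_genotypes.tsv", sep="\t", index=False
    )
    return report


def stage_neutrality(
    objs: dict, outdir: Path, seed: int, tajima_replicates: int = 2000
) -> dict:
    cohort: Cohort = objs["cohort"]
    ew_rows = []
    for pop in cohort.populations:
        for locus in _loci(cohort):
            if pop.n_chromosomes(locus) < 2:
                continue
            res = neutrality.ewens_watterson(
                allele_frequencies(pop, locus), seed=seed
            )
            ew_rows.append(
                {"population": pop.name, "region": cohort.region_map[pop.name],
                 "locus": locus, "n": res.n, "k": res.k,
                 "obs_F": res.F_obs, "exp_F": res.F_exp, "p": res.p,
                 "significant": res.significant}
            )
    ew_table = pd.DataFrame(ew_rows)
    ew_table.to_csv(outdir / "ewens_watterson.tsv", sep="\t", index=False)
    out = {"ew": ew_table}
    if "seqmap" in objs:
        seqmap: SequenceMap = objs["seqmap"]
        taj_rows = []
        for i, pop in enumerate(cohort.populations):
            for j, locus in enumerate(seqmap.loci()):
                if pop.n_chromosomes(locus) < 4:
                    continue
                try:
                    seqs = neutrality.recode_to_sequences(pop, locus, seqmap)
                    res = neutrality.tajimas_d(
                        seqs, p_replicates=tajima_replicates,
                        seed=seed + 131 * i + j,
                    )
                except (neutrality.MissingSequenceError, ValueError):
                    continue
                taj_rows.append(
                    {"population": pop.name, "locus": locus, "n": res.n,
                     "S": res.S, "pi": res.pi, "D": res.D, "p": res.p,
                     "significant": res.significant}
                )
        taj_table = pd.DataFrame(taj_rows)
        taj_table.to_csv(outdir / "tajimas_d.tsv", sep="\t", index=False)
        out["tajima"] = taj_table
    return out


def stage_fst(objs: dict, outdir: Path, max_zst_pairs: int | None = None) -> dict:
    cohort: Cohort = objs["cohort"]
    loci = _loci(cohort)
    matrices = {locus: differentiation.fst_matrix(cohort, locus) for locus in loci}
    for locus, mat in matrices.items():
        mat.to_csv(outdir / f"fst_matrix_{locus}.tsv", sep="\t")
    summary = differentiation.region_summary(matrices, cohort.region_map)
    summary.to_csv(outdir / "fst_region_summary.tsv", sep="\t", index=False)
    out: dict = {"matrices": matrices, "region_summary": summary}
    if "msat" in objs:
        msat: MsatPanel = objs["msat"]
        pairs = list(itertools.combinations(cohort.population_names, 2))
        if max_zst_pairs is not None:
            pairs = pairs[:max_zst_pairs]
        zst_rows, zst_results = [], []
        for a, b in pairs:
            vec = differentiation.msat_fst_vector(msat, a, b)
            for locus in loci + ["mean_HLA"]:
                if locus == "mean_HLA":
                    vals = [matrices[l].loc[a, b] for l in loci
                            if a in matrices[l].index and b in matrices[l].index]
                    if not vals:
                        continue
                    hla_fst = float(np.mean(vals))
                else:
                    mat = matrices[locus]
                    if a not in mat.index or b not in mat.index:
                        continue
                    hla_fst = float(mat.loc[a, b])
                r = differentiation.zst((a, b), locus, hla_fst, vec)
                zst_results.append(r)
                zst_rows.append(
                    {"pop1": a, "pop2": b, "locus": locus, "fst_hla": r.fst_hla,
                     "msat_mean": r.msat_mean, "msat_sd": r.msat_sd,
                     "zst": r.zst, "empirical_p": r.empirical_p}
                )
        zst_table = pd.DataFrame(zst_rows)
        zst_table.to_csv(outdir / "zst_pairs.tsv", sep="\t", index=False)
        region_table = differentiation.zst_region_table(
            zst_results, cohort.region_map
        )
        region_table.to_csv(outdir / "zst_regions.tsv", sep="\t", index=False)
        out.update({"zst": zst_table, "zst_regions": region_table})
    return out


def stage_classify(objs: dict, outdir: Path, exclude: set[str]) -> dict:
    import warnings

    cohort: Cohort = objs["cohort"]
    panel: ReferencePanel = objs["panel"]
    class_by_locus = {}
    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for locus in _loci(cohort):
            cls = geography.classify_alleles(cohort, panel, locus)
            class_by_locus[locus] = cls
            for c in cls:
                rows.append(
                    {"locus": locus, "allele": str(c.allele),
                     "native_mean": c.native_mean, "reference_mean": c.reference_mean,
                     "ratio": c.ratio, "copies": c.copies, "category": c.category,
                     "poorly_supported": c.poorly_supported, "removed": c.removed}
                )
    pd.DataFrame(rows).to_csv(outdir / "allele_classification.tsv",
                              sep="\t", index=False)
    sums = geography.category_frequency_sums(cohort, class_by_locus)
    sums.to_csv(outdir / "category_sums.tsv", sep="\t", index=False)
    means = geography.region_category_means(sums, exclude=exclude)
    means.to_csv(outdir / "category_region_means.tsv", sep="\t", index=False)
    out = {"classifications": class_by_locus, "sums": sums, "means": means}
    if "msat_h" in objs:
        corr = geography.category_msat_correlation(sums, objs["msat_h"])
        corr.to_csv(outdir / "category_msat_correlation.tsv", sep="\t", index=False)
        out["correlation"] = corr
    return out


def stage_haplo(objs: dict, outdir: Path, seed: int) -> dict:
    cohort: Cohort = objs["cohort"]
    cat_maps = {
        locus: geography.final_category_map(cls)
        for locus, cls in objs.get("classifications", {}).items()
    }
    records = haplotypes.ash_by_category(
        cohort, cat_maps, loci=tuple(_loci(cohort)), em_seed=seed
    )
    records.to_csv(outdir / "ash_records.tsv", sep="\t", index=False)
    summary = haplotypes.ash_summary(records)
    summary.to_csv(outdir / "ash_summary.tsv", sep="\t", index=False)
    return {"ash_records": records, "ash_summary": summary}


def run_all(config: dict, out: str | Path, seed: int = 0) -> dict:
    """Run every stage that its inputs allow; write a seed/timing run log."""
    outdir = Path(out)
    outdir.mkdir(parents=True, exist_ok=True)
    log: dict = {"seed": seed, "stages": {}}
    exclude = set(config.get("exclude", DEFAULT_EXCLUDE))

    def timed(name, fn, *args, **kwargs):
        t0 = time.perf_counter()
        result = fn(*args, **kwargs)
        log["stages"][name] = {"seconds": round(time.perf_counter() - t0, 3)}
        return result

    if "simulate" in config or "inputs" not in config:
        objs = timed("simulate", stage_simulate, config, outdir / "inputs", seed)
    else:
        objs = timed("load", load_inputs, config)

    results = {"inputs": objs}
    results["diversity"] = timed("diversity", stage_diversity, objs, outdir, exclude)
    if "msat_h" in results["diversity"]:
        objs["msat_h"] = results["diversity"]["msat_h"]
    results["hwp"] = timed(
        "hwp", stage_hwp, objs, outdir, seed + 1,
        config.get("hwp_mc_steps", 100_000),
    )
    results["neutrality"] = timed(
        "neutrality", stage_neutrality, objs, outdir, seed + 2,
        config.get("tajima_replicates", 2000),
    )
    if "seqmap" not in objs:
        log["stages"]["neutrality"]["note"] = "no sequence map: Tajima stage skipped"
    results["fst"] = timed(
        "fst", stage_fst, objs, outdir, config.get("max_zst_pairs")
    )
    if "panel" in objs:
        results["classify"] = timed("classify", stage_classify, objs, outdir, exclude)
        objs["classifications"] = results["classify"]["classifications"]
        results["haplo"] = timed("haplo", stage_haplo, objs, outdir, seed + 3)
    else:
        log["stages"]["classify"] = {"note": "no reference panel: stage skipped"}
    with open(outdir / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=2)
    results["log"] = log
    return results
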