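#!/usr/bin/env python
"""Heterozygosity geography: population- and individual-level summaries.

Computes per-population per-locus heterozygosity, the correlation of mean
HLA heterozygosity with mean microsatellite heterozygosity across
populations, Tukey-HSD regional contrasts of microsatellite diversity,
per-population regressions of individual microsatellite homozygosity on
the number of homozygous HLA loci, and the per-region homozygosity-class
trend.
"""

from _common import ROOT, load

from hla_popstruct.pipeline import DEFAULT_EXCLUDE, stage_diversity


def main() -> None:
    objs = load(with_sequences=False)
    out = stage_diversity(objs, ROOT, DEFAULT_EXCLUDE)
    print(f"wrote diversity tables to {ROOT}")
    print(f"  HLA vs msat heterozygosity across populations: "
          f"r = {out['hla_msat_r']:.3f} (p = {out['hla_msat_p']:.3g})")
    sig = out["contrasts"][out["contrasts"]["p_adj"] < 0.05]
    print(f"  regional msat contrasts significant at 0.05: "
          f"{len(sig)}/{len(out['contrasts'])}")
    for _, row in sig.iterrows():
        print(f"    {row['region1']}-{row['region2']}: p_adj = {row['p_adj']:.3g}")
    assoc = out["association"]
    n_sig = int(assoc["significant"].sum())
    print(f"  populations with Bonferroni-significant individual-level "
          f"HLA/msat homozygosity association: {n_sig}/{int(assoc['p'].notna().sum())}")


if __name__ == "__main__":
    main()
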