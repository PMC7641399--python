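#!/usr/bin/env python
"""EM haplotype frequencies and allele-specific heterozygosity (ASH).

Estimates two-locus haplotype frequencies per population and locus pair
by EM, computes the heterozygosity of partner alleles on haplotypes
carrying each conditioned allele, and summarizes ASH by allele category
(endemic / LFD / other) and conditioned-allele frequency stratum.
"""

from _common import ROOT, load

from hla_popstruct.pipeline import DEFAULT_EXCLUDE, stage_classify, stage_haplo


def main() -> None:
    objs = load(with_sequences=False)
    cls = stage_classify(objs, ROOT, DEFAULT_EXCLUDE)
    objs["classifications"] = cls["classifications"]
    out = stage_haplo(objs, ROOT, seed=37)
    print(f"wrote haplotype tables to {ROOT}")
    summary = out["ash_summary"]
    print("  mean allele-specific heterozygosity by category:")
    for _, row in summary.iterrows():
        print(f"    {row['locus']:8s} {row['category']:28s} "
              f"{row['ash']:.3f}  (records: {row['n_records']})")


if __name__ == "__main__":
    main()
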