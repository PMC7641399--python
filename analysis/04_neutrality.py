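#!/usr/bin/env python
"""Neutrality tests: Ewens-Watterson on allele configurations, Tajima's D
on sequence-recoded samples.

Writes a table of observed vs. expected homozygosity with conditional
p-values per population x locus, and a table of Tajima's D with
coalescent-simulation p-values for loci covered by the sequence map.
Two-tailed significance uses p < 0.025 or p > 0.975.
"""

from _common import ROOT, load

from hla_popstruct.pipeline import stage_neutrality


def main() -> None:
    objs = load()
    out = stage_neutrality(objs, ROOT, seed=23, tajima_replicates=2000)
    ew = out["ew"]
    print(f"wrote neutrality tables to {ROOT}")
    print(f"  Ewens-Watterson: {int(ew['significant'].sum())} of {len(ew)} "
          f"tests significant (two-tailed 0.05)")
    if "tajima" in out:
        taj = out["tajima"]
        pos = int((taj["D"] > 0).sum())
        print(f"  Tajima's D: {pos}/{len(taj)} positive; "
              f"{int(taj['significant'].sum())} significant")
        print(f"  mean D by locus:")
        for locus, sub in taj.groupby("locus"):
            print(f"    {locus}: {sub['D'].mean():+.2f}")


if __name__ == "__main__":
    main()
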