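"""Shared input loading for the numbered analysis drivers."""

from pathlib import Path

from hla_popstruct.pipeline import load_inputs

ROOT = Path(__file__).resolve().parent.parent / "results"
INPUTS = ROOT / "inputs"


def load(with_sequences: bool = True) -> dict:
    if not (INPUTS / "cohort.tsv").exists():
        raise SystemExit("run analysis/01_simulate.py first")
    paths = {
        "cohort": str(INPUTS / "cohort.tsv"),
        "region_map": str(INPUTS / "region_map.csv"),
        "msat_panel": str(INPUTS / "msat_panel.tsv"),
        "reference_panel": str(INPUTS / "reference_panel.csv"),
    }
    if with_sequences:
        seqs = {
            locus: str(INPUTS / f"sequences_{locus}.fasta")
            for locus in ("A", "B", "C", "DRB1")
            if (INPUTS / f"sequences_{locus}.fasta").exists()
        }
        if seqs:
            paths["sequences"] = seqs
    return load_inputs({"inputs": paths})
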