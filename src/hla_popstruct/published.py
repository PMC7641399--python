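"""Published per-population endemic/LFD frequency sums for Native American HLA data.

The values below are the published per-population sums of allele
frequencies in the endemic and LFD categories at HLA-A, -B, -C and -DRB1
for 23 Native American populations (regions: NAM = North America, MEA =
Mesoamerica, SAA = South America Andes, SAL = South America Lowlands).
They serve as a fixed input for validating the regional-mean aggregation:
the published regional means (e.g. endemic HLA-B in SAL: 0.128, LFD
HLA-B in SAL: 0.487, LFD HLA-DRB1 continental mean: 0.636, computed with
the Aché outlier excluded) must be recoverable from these sums by
unweighted averaging.
"""

from __future__ import annotations

import pandas as pd

# population, region, endemic sums (A, B, C, DRB1), LFD sums (A, B, C, DRB1)
_ROWS = [
    ("Chipewyan", "NAM", 0.000, 0.000, 0.000, 0.000, 0.160, 0.140, 0.040, 0.100),
    ("Cree", "NAM", 0.000, 0.000, 0.028, 0.000, 0.278, 0.111, 0.028, 0.361),
    ("Ojibwa", "NAM", 0.000, 0.000, 0.000, 0.000, 0.367, 0.067, 0.200, 0.469),
    ("Mixe", "MEA", 0.000, 0.000, 0.000, 0.000, 0.575, 0.675, 0.025, 0.925),
    ("Mixtec", "MEA", 0.000, 0.100, 0.025, 0.000, 0.675, 0.550, 0.025, 0.925),
    ("Zapotec", "MEA", 0.000, 0.176, 0.000, 0.000, 0.425, 0.500, 0.000, 0.723),
    ("Kaqchikel", "MEA", 0.026, 0.078, 0.026, 0.000, 0.237, 0.368, 0.026, 0.579),
    ("Cabecar", "MEA", 0.079, 0.000, 0.000, 0.000, 0.552, 0.211, 0.500, 0.763),
    ("Guaymi", "MEA", 0.000, 0.056, 0.000, 0.000, 0.583, 0.278, 0.167, 0.527),
    ("Inga", "SAA", 0.000, 0.000, 0.000, 0.000, 0.399, 0.251, 0.000, 0.666),
    ("Quechua", "SAA", 0.024, 0.191, 0.000, 0.000, 0.072, 0.334, 0.000, 0.405),
    ("Aymara", "SAA", 0.100, 0.075, 0.025, 0.000, 0.100, 0.475, 0.000, 0.625),
    ("Huilliche", "SAA", 0.075, 0.000, 0.000, 0.000, 0.375, 0.500, 0.000, 0.575),
    ("Kogi", "SAL", 0.000, 0.000, 0.000, 0.000, 0.533, 0.465, 0.214, 0.607),
    ("Arhuaco", "SAL", 0.000, 0.176, 0.000, 0.000, 0.441, 0.558, 0.235, 0.646),
    ("Wayuu", "SAL", 0.000, 0.100, 0.000, 0.000, 0.533, 0.366, 0.143, 0.667),
    ("Zenu", "SAL", 0.000, 0.187, 0.000, 0.000, 0.583, 0.438, 0.083, 0.875),
    ("Embera", "SAL", 0.000, 0.071, 0.036, 0.000, 0.428, 0.786, 0.000, 0.786),
    ("Waunana", "SAL", 0.000, 0.150, 0.000, 0.000, 0.350, 0.450, 0.000, 0.475),
    ("TicunaArara", "SAL", 0.000, 0.036, 0.000, 0.000, 0.500, 0.572, 0.036, 0.900),
    ("TicunaTarapaca", "SAL", 0.000, 0.079, 0.000, 0.000, 0.395, 0.395, 0.000, 0.947),
    ("Guarani", "SAL", 0.050, 0.350, 0.000, 0.000, 0.300, 0.350, 0.000, 0.445),
    ("Ache", "SAL", 0.000, 0.000, 0.000, 0.083, 0.884, 0.863, 0.000, 0.875),
]

LOCI = ("A", "B", "C", "DRB1")


def published_category_sums() -> pd.DataFrame:
    """The published category sums in the long layout of category_frequency_sums."""
    rows = []
    for entry in _ROWS:
        pop, region = entry[0], entry[1]
        endemic = dict(zip(LOCI, entry[2:6]))
        lfd = dict(zip(LOCI, entry[6:10]))
        for locus in LOCI:
            rows.append(
                {
                    "population": pop,
                    "region": region,
                    "locus": locus,
                    "endemic_sum": endemic[locus],
                    "lfd_sum": lfd[locus],
                    "other_sum": 1.0 - endemic[locus] - lfd[locus],
                }
            )
    return pd.DataFrame(rows)
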