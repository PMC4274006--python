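"""Published reference counts for the Amomi Fructus barcode panel.

The study system behind this package typed 29 landraces of three
*Amomum* species on six barcode regions and reported, for each single
region and multi-region combination, the total number of SNPs and the
number of SNP genotypes (STs).  Those printed counts are inputs here:
they let the correlation between marker polymorphism and typing
resolution be recomputed without re-sequencing anything.
"""

from __future__ import annotations

import pandas as pd

N_PANEL_SAMPLES = 29

# (combination, number of regions, total SNPs, STs)
_DISCRIMINATORY_POWER = [
    ("ITS", 1, 19, 15),
    ("ITS2", 1, 12, 14),
    ("LSU D1-D3", 1, 11, 8),
    ("ITS1", 1, 7, 6),
    ("rbcL", 1, 4, 2),
    ("matK", 1, 1, 3),
    ("ITS + LSU D1-D3", 2, 30, 18),
    ("ITS2 + LSU D1-D3", 2, 23, 18),
    ("ITS1 + LSU D1-D3", 2, 18, 12),
    ("rbcL + matK", 2, 5, 3),
    ("ITS + rbcL + matK", 3, 24, 16),
    ("ITS2 + rbcL + matK", 3, 17, 15),
    ("LSU D1-D3 + rbcL + matK", 3, 16, 9),
    ("ITS1 + rbcL + matK", 3, 12, 7),
    ("ITS + LSU D1-D3 + rbcL + matK", 4, 35, 19),
]

# per-region sequencing outcomes: passing traces / attempted traces
SEQUENCING_SUCCESS = {
    "LSU D1-D3": (112, 116),
    "ITS": (88, 116),
    "ITS2": (81, 116),
    "matK": (91, 116),
    "rbcL": (111, 116),
    "trnH-psbA": (40, 116),
}


def discriminatory_power_table() -> pd.DataFrame:
    """The published 15-row combination report (SNP and ST counts per
    single region and multi-region combination)."""
    return pd.DataFrame(
        _DISCRIMINATORY_POWER,
        columns=["combination", "n_regions", "n_snps", "n_sts"],
    )
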