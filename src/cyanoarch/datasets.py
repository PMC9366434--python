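"""Small bundled datasets.

Published genome summary statistics for 13 complete *Planktothrix* spp.
genomes (chromosome size, IS element content, copy numbers), used for the
chromosome-size versus IS-content regression and as realistic scale
references for the synthetic-genome generator.
"""

from __future__ import annotations

import pandas as pd

#: The planktocyclin core peptide (cyclic octapeptide of *P. rubescens*).
PLANKTOCYCLIN_PEPTIDE = "PGLVMFGV"

_GENOME_SUMMARY_ROWS = [
    # strain, lineage, chromosome_mb, is_percent_chromosome, total_is_copies, n_genes
    ("NIVA-CYA126/8", "1", 4.84, 1.6, 105, 4494),
    ("No2A", "1", 4.72, 1.3, 75, 4305),
    ("No66", "1", 4.74, 1.2, 81, 4434),
    ("No976", "1", 4.75, 0.8, 67, 4423),
    ("PCC7805", "1", 4.75, 1.3, 88, 4446),
    ("PCC7811", "1", 4.80, 1.4, 88, 4645),
    ("No365", "1A", 4.71, 1.1, 79, 4482),
    ("No82", "2", 5.45, 2.1, 137, 5043),
    ("No108", "2", 5.41, 1.9, 128, 4970),
    ("PCC7821", "2", 5.46, 2.6, 165, 5104),
    ("No758", "2A", 5.64, 2.5, 145, 4915),
    ("No713", "3", 6.60, 3.7, 282, 5696),
    ("PCC9214", "3", 6.27, 2.1, 182, 5796),
]


def planktothrix_genome_summary() -> pd.DataFrame:
    """Per-strain chromosome size (Mb) and IS content (% of nucleotides)."""
    return pd.DataFrame(
        _GENOME_SUMMARY_ROWS,
        columns=[
            "strain",
            "lineage",
            "chromosome_mb",
            "is_percent_chromosome",
            "total_is_copies",
            "n_genes",
        ],
    )
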