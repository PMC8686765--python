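"""Bundled reference datasets.

Measured specific rates (mmol/gDW/h), growth rates (1/h) and product yields
(mol/mol, gDW/g for biomass) of *E. coli* MG1655 wild type, the
ATPase-overexpression strains (low/medium/high plasmid copy number, each
with its empty-plasmid control) and the HC-ATPase overexpression variants
(pfkA, pflB, pfkA+pflB, pgk), under anaerobic growth and anaerobic growth
arrest.  Columns ending in ``_sd`` are standard deviations over three
biological replicates.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

DATA_DIR = Path(__file__).parent / "data"

_TABLES = {
    "growth": "strain_rates_growth.tsv",
    "arrest": "strain_rates_arrest.tsv",
    "variants": "strain_rates_variants.tsv",
}

RATE_COLUMNS = ["r_glc", "r_eth", "r_ace", "r_for", "r_lac", "r_suc"]
YIELD_COLUMNS = ["y_eth", "y_ace", "y_for", "y_lac", "y_suc"]


def load_rate_table(condition: str = "growth") -> pd.DataFrame:
    """Load a bundled strain rate/yield table, indexed by strain label.

    ``condition`` is one of ``growth`` (anaerobic exponential growth),
    ``arrest`` (anaerobic growth arrest) or ``variants`` (HC-ATPase
    overexpression variants, anaerobic growth).
    """
    if condition not in _TABLES:
        raise KeyError(
            f"unknown condition {condition!r}; choose from {sorted(_TABLES)}"
        )
    df = pd.read_csv(DATA_DIR / _TABLES[condition], sep="\t")
    return df.set_index("strain")
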