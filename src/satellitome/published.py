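"""Published worked-example data: the W-candidate excerpt of the
*Megaleporinus macrocephalus* satellitome.

The bundled TSV carries the printed per-library abundances (% of library
nucleotides), divergences and F/M ratios of the satellite families with the
highest female/male abundance quotients in that ZW species — the candidate
set for W-chromosome linkage. Abundances are printed to six decimals, so
only a subset of rows re-derives its printed quotient to four significant
figures from the rounded abundances; :data:`RATIO_STABLE_FAMILIES` lists
those rows, which serve as exact worked examples for the F/M calculator.
"""

from __future__ import annotations

from importlib.resources import files

import pandas as pd

#: families whose printed F/M ratio is reproducible to >=4 significant
#: figures from the 6-decimal printed abundances
RATIO_STABLE_FAMILIES = (
    "MmaSat009-53",
    "MmaSat017-72",
    "MmaSat058-71",
    "MmaSat061-33",
    "MmaSat111-33",
    "MmaSat098-37",
)


def load_w_candidates() -> pd.DataFrame:
    """The bundled W-candidate table as a DataFrame (NA = absent in male)."""
    path = files("satellitome.data").joinpath("w_candidate_table.tsv")
    with path.open() as fh:
        return pd.read_csv(fh, sep="\t", na_values=["NA"])
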