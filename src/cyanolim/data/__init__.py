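"""Bundled reference tables.

``reference_growth_rates.csv`` holds published duplicate-culture growth
rates (mu, day^-1) and generation times (Tg, days) for *Halothece* sp.
PCC 7418 across a 3x3 PO4 x Fe factorial at three NO3- regimes, and for
*Fischerella muscicola* PCC 73103 grown on N2 as sole N source.  SR
columns are the spanning range (max - min) between duplicates; empty
cells are treatments where no growth could be measured.
"""

from importlib.resources import files

import pandas as pd


def load_reference_growth_table() -> pd.DataFrame:
    """The reference 3x3 PO4 x Fe growth-rate table as a DataFrame."""
    path = files(__package__).joinpath("reference_growth_rates.csv")
    with path.open("r") as fh:
        return pd.read_csv(fh)
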