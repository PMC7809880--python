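"""Bundled reference tables.

``lipid_bilayer_summary`` ships the published summary statistics (unitary
conductance G in pS and open probability P_O at a reference voltage) for
seven viral K+ channels recorded in neutral (PC) versus anionic (PS/PG)
diphytanoyl bilayers; it is the input for the fold-change and dose-response
arithmetic in the analysis drivers.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["lipid_bilayer_summary", "po_fold_change"]


def lipid_bilayer_summary() -> pd.DataFrame:
    with resources.files("kcvgate.data").joinpath(
            "lipid_bilayer_summary.csv").open() as fh:
        return pd.read_csv(fh)


def po_fold_change(channel: str = "Kcv_S", numerator: str = "PS",
                   denominator: str = "PC",
                   column: str = "po") -> float:
    """Ratio of a summary quantity between two bilayer compositions."""
    df = lipid_bilayer_summary()
    sel = df[df.channel == channel].set_index("bilayer")[column]
    return float(sel[numerator] / sel[denominator])
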