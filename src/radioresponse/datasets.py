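"""Packaged reference data: the 38-cell-line HNSCC radiosensitivity panel.

The panel carries, per cell line, the photon surviving fractions at 2 and
3.5 Gy (SF2, SF3.5) read from fitted survival curves, the plating
efficiency, and the anatomical site of origin.  SF3.5 is the feature used
for radiosensitivity cohort clustering (see `radioresponse.clustering`).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import pandas as pd

__all__ = ["PanelEntry", "panel_fixture", "load_panel"]


@dataclass(frozen=True)
class PanelEntry:
    cell_line: str
    sf2: float
    sf35: float
    plating_efficiency: float
    site: str


def load_panel() -> pd.DataFrame:
    """The HNSCC panel as a DataFrame (38 rows)."""
    with resources.files("radioresponse.data").joinpath("hnscc_panel.csv").open() as fh:
        return pd.read_csv(fh)


def panel_fixture() -> list[PanelEntry]:
    """The HNSCC panel as typed entries."""
    return [
        PanelEntry(
            cell_line=str(r.cell_line),
            sf2=float(r.sf2),
            sf35=float(r.sf35),
            plating_efficiency=float(r.plating_efficiency),
            site=str(r.site),
        )
        for r in load_panel().itertuples()
    ]
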