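"""Packaged reference tables from the cold-storage strawberry-juice study.

Three small CSVs ship with the package:

* ``table3_enose_summary.csv`` — per-time mean ± sd (n = 20) of the
  ten E-nose channels, with the published Duncan letter column.
* ``table8_pc_scores.csv`` — per-time scores of the four retained
  fused principal components and the published composite score.
* ``table1_platecount_params.csv`` — the four fitted plate-count
  models' parameters and fit statistics.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = [
    "load_enose_summary",
    "load_pc_scores",
    "load_platecount_params",
    "PC_VARIANCE_PERCENTAGES",
]

#: Explained-variance percentages of the four retained fused components.
PC_VARIANCE_PERCENTAGES: tuple[float, float, float, float] = (60.98, 18.43, 6.99, 5.51)


def _read(name: str) -> pd.DataFrame:
    with resources.files("growthsense.data").joinpath(name).open("rb") as fh:
        return pd.read_csv(fh)


def load_enose_summary() -> pd.DataFrame:
    """E-nose channel summaries: channel, time_h, mean, sd, n, letters."""
    return _read("table3_enose_summary.csv")


def load_pc_scores() -> tuple[pd.DataFrame, tuple[float, ...]]:
    """Fused PC scores indexed by time, plus the variance percentages.

    The returned weights are percentages (sum ≈ 91.9); divide by 100
    for composite-score proportions.
    """
    df = _read("table8_pc_scores.csv").set_index("time_h")
    return df, PC_VARIANCE_PERCENTAGES


def load_platecount_params() -> pd.DataFrame:
    """Plate-count model parameters, indexed by model name."""
    return _read("table1_platecount_params.csv").set_index("model")
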