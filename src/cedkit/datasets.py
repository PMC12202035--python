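"""Bundled clinical fixture tables.

Two small CSVs transcribe the published per-patient demographics/outcome
table and the per-infusion distribution-volumetry table of the six-patient
CED trial cohort this package models (subjects anonymized S1..S6), so the
tabular analyses run with no external data.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd


def _read(name: str) -> pd.DataFrame:
    with resources.files("cedkit.data").joinpath(name).open("rb") as fh:
        return pd.read_csv(fh)


def load_cohort_table() -> pd.DataFrame:
    """Per-patient table: demographics, dose level, DLT, follow-up, status."""
    return _read("table1.csv")


def load_infusion_table() -> pd.DataFrame:
    """Per-infusion table: Vi, duration, per-treatment Vd, coverage volumes."""
    return _read("table3.csv")
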