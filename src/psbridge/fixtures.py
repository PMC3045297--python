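"""Packaged summary-level reference statistics.

These are the published group-level rates of the six-trial comparison
(adverse-event incidences per matched group, completion and response
percentages) used to validate the clamped placebo-adjusted arithmetic
bit-exactly and to calibrate the synthetic scenario suite.  Columns ending
in ``printed_diff_*`` carry the published differential cells (empty where
the published table shows NA, i.e. below the 2% reporting gate).
"""

from __future__ import annotations

import json
from importlib import resources

import pandas as pd

# fixture column -> analysis group label
FIXTURE_GROUPS = {
    "pali": "PALI_6_12",
    "placebo_pali": "PLACEBO_PALI",
    "ris_2_4": "RIS_2_4",
    "ris_4_6": "RIS_4_6",
    "placebo_ris": "PLACEBO_RIS",
}


def load_ae_incidence() -> pd.DataFrame:
    """Published AE incidence table (counts, one-decimal percentages,
    printed placebo-adjusted differential cells)."""
    with resources.files("psbridge.data").joinpath("ae_incidence.csv").open("rb") as fh:
        return pd.read_csv(fh)


def load_summary_rates() -> dict:
    """Published group sizes, completion and response percentages."""
    with resources.files("psbridge.data").joinpath("summary_rates.json").open("r") as fh:
        return json.load(fh)
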