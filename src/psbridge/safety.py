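"""Adverse-event incidence tables and clamped placebo-adjusted differentials.

Treatment-emergent AE incidence counts each subject at most once per
preferred term; percentages are rounded to one decimal, halves away from
zero.  The between-compound comparison uses the double difference

    d = clamp(active_A % - placebo_A %) - clamp(active_B % - placebo_B %)

with clamp(x) = max(x, 0): an active rate below its own program's placebo
rate is corrected to zero, never allowed to offset the other side.  The
difference is computed on the already-rounded percentages (only this order
reproduces the published cells) and the magnitude is reported when it is at
least 2.0 percentage points, for terms whose incidence reaches 5% in any
active or placebo group.  No statistical tests are applied to AE rates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import trial_data as td
from ._util import round1
from .trial_data import AdverseEventRecord

DEFAULT_INCIDENCE_THRESHOLD = 5.0   # % gate for a term to enter the table
DEFAULT_DIFFERENTIAL_THRESHOLD = 2.0  # % gate for reporting a differential

MORE_WITH_A = "more_with_side_a"
MORE_WITH_B = "more_with_side_b"


# ---------------------------------------------------------------------------
# incidence

def incidence_table(events: Sequence[AdverseEventRecord],
                    groups: Mapping[str, Sequence[str]]) -> pd.DataFrame:
    """Distinct-subject counts and one-decimal percentages per term per group.

    ``groups`` maps group label -> subject ids (the denominators).  An event
    for a subject in no group is ignored; an event for a subject id that is
    unknown entirely raises a validation error.
    """
    known: set[str] = set()
    for ids in groups.values():
        known.update(ids)
    id_groups: dict[str, list[str]] = {}
    for g, ids in groups.items():
        for i in ids:
            id_groups.setdefault(i, []).append(g)

    counted: dict[tuple[str, str], set[str]] = {}
    terms: list[str] = []
    for e in events:
        if e.subject_id not in known:
            raise td.ValidationError(
                f"event for unknown subject {e.subject_id!r}")
        if e.preferred_term not in terms:
            terms.append(e.preferred_term)
        for g in id_groups[e.subject_id]:
            counted.setdefault((e.preferred_term, g), set()).add(e.subject_id)

    rows = []
    for term in sorted(terms):
        row: dict[str, object] = {"preferred_term": term}
        for g, ids in groups.items():
            n = len(counted.get((term, g), ()))
            denom = len(ids)
            row[f"{g}_n"] = n
            row[f"{g}_pct"] = round1(100.0 * n / denom) if denom else float("nan")
        rows.append(row)
    cols = ["preferred_term"] + [f"{g}_{s}" for g in groups for s in ("n", "pct")]
    return pd.DataFrame(rows, columns=cols)


# ---------------------------------------------------------------------------
# clamped placebo-adjusted differential

@dataclass(frozen=True)
class AdjustedDifferential:
    signed: float      # clamp(a - plc_a) - clamp(b - plc_b), one decimal
    magnitude: float   # |signed|, one decimal
    direction: Optional[str]  # MORE_WITH_A / MORE_WITH_B, None when 0
    flagged: bool      # magnitude >= differential threshold


def _check_pct(name: str, value: float) -> None:
    if not (0.0 <= value <= 100.0):
        raise td.ValidationError(f"{name} percentage {value} outside [0, 100]")


def placebo_adjusted_differential(active_a_pct: float, placebo_a_pct: float,
                                  active_b_pct: float, placebo_b_pct: float,
                                  threshold: float = DEFAULT_DIFFERENTIAL_THRESHOLD,
                                  ) -> AdjustedDifferential:
    """Clamped double difference on one-decimal incidence percentages.

    Each active rate is corrected by its own program's placebo rate, with a
    negative correction set to zero; side a's corrected rate minus side b's
    gives the signed differential.  Inputs are expected on the rounded
    percentage scale; they are re-rounded defensively so raw fractions give
    the same result as pre-rounded inputs.
    """
    vals = [active_a_pct, placebo_a_pct, active_b_pct, placebo_b_pct]
    for name, v in zip(("active_a", "placebo_a", "active_b", "placebo_b"), vals):
        _check_pct(name, v)
    a, pa, b, pb = (round1(v) for v in vals)
    corrected_a = max(a - pa, 0.0)
    corrected_b = max(b - pb, 0.0)
    signed = round1(corrected_a - corrected_b)
    magnitude = abs(signed)
    if signed > 0:
        direction: Optional[str] = MORE_WITH_A
    elif signed < 0:
        direction = MORE_WITH_B
    else:
        direction = None
    return AdjustedDifferential(signed=signed, magnitude=magnitude,
                                direction=direction,
                                flagged=magnitude >= threshold)


# ---------------------------------------------------------------------------
# flagged AE table

@dataclass
class AdjustedRateTable:
    table: pd.DataFrame
    incidence_threshold: float
    differential_threshold: float


def flag_ae_table(incidence: pd.DataFrame,
                  active_a: str, placebo_a: str,
                  comparisons: Mapping[str, tuple[str, str]],
                  incidence_threshold: float = DEFAULT_INCIDENCE_THRESHOLD,
                  differential_threshold: float = DEFAULT_DIFFERENTIAL_THRESHOLD,
                  ) -> AdjustedRateTable:
    """Build the placebo-adjusted AE comparison table.

    ``incidence`` is the output of :func:`incidence_table`; ``active_a`` and
    ``placebo_a`` name side a's columns (e.g. the paliperidone ER group and
    its placebo); ``comparisons`` maps a comparison label to side b's
    (active, placebo) group pair.  A term enters the table iff any involved
    active or placebo group incidence reaches ``incidence_threshold``; each
    comparison cell reports the differential magnitude when it reaches
    ``differential_threshold``, else NA, with the direction taken from the
    sign before the magnitude.
    """
    gate_groups = {active_a, placebo_a}
    for act_b, plc_b in comparisons.values():
        gate_groups.update((act_b, plc_b))

    rows = []
    for _, rec in incidence.iterrows():
        if not any(rec[f"{g}_pct"] >= incidence_threshold for g in gate_groups):
            continue
        row: dict[str, object] = {"preferred_term": rec["preferred_term"]}
        for g in gate_groups:
            row[f"{g}_n"] = rec[f"{g}_n"]
            row[f"{g}_pct"] = rec[f"{g}_pct"]
        for label, (act_b, plc_b) in comparisons.items():
            d = placebo_adjusted_differential(
                rec[f"{active_a}_pct"], rec[f"{placebo_a}_pct"],
                rec[f"{act_b}_pct"], rec[f"{plc_b}_pct"],
                threshold=differential_threshold)
            row[f"{label}_differential"] = d.magnitude if d.flagged else np.nan
            if d.flagged:
                row[f"{label}_direction"] = (
                    "more_with_" + active_a if d.direction == MORE_WITH_A
                    else "more_with_" + act_b)
            else:
                row[f"{label}_direction"] = None
        rows.append(row)
    table = pd.DataFrame(rows)
    return AdjustedRateTable(table=table,
                             incidence_threshold=incidence_threshold,
                             differential_threshold=differential_threshold)


# ---------------------------------------------------------------------------
# weight

def weight_contrast(endpoints: pd.DataFrame,
                    groups: Mapping[str, Sequence[str]]) -> "ContrastResult":
    """Baseline-adjusted ANCOVA on weight change, same machinery as efficacy."""
    from .efficacy import ancova_contrast

    wt = endpoints[endpoints["measure"] == "weight_kg"]
    group_of: dict[str, str] = {}
    for g, ids in groups.items():
        for i in ids:
            group_of[i] = g
    sub = wt[wt["subject_id"].isin(group_of)]
    df = sub.assign(group=sub["subject_id"].map(group_of))
    return ancova_contrast(df[["group", "baseline", "change"]], measure="weight_kg")
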