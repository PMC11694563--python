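"""Per-stage removal metrics with below-detection exclusion rules.

Two metrics are computed for every treatment process of a train:

* unit removal efficiency, ``URE = (P_in - P_out) / P_initial`` — the
  fraction of the *train-influent* peak area removed by the stage, so
  stage contributions telescope along the train;
* removal efficiency, ``RE = 100 (P_in - P_out) / P_in`` — the percent of
  the stage's own input removed.

Both can be negative when a stage output exceeds its input (desorption,
deconjugation, transformation-product re-formation, or plain noise).

Below-detection (B.D.) handling per event:

* both the stage input and output B.D.            -> event excluded;
* only the output B.D.   -> output treated as 0 (removal to below
  detection) for both metrics;
* only the input B.D.    -> RE undefined (event skipped), URE computed
  with input 0 — the compound (re)appears across the stage;
* train influent B.D.    -> URE has no reference for that event, so the
  event is skipped for URE.

Averages are unweighted arithmetic means over the usable events.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .core import PeakAreaTable, TreatmentTrain


def unit_removal_efficiency(p_in: float, p_out: float, p_initial: float) -> float:
    """Fraction of the influent peak area removed by one stage."""
    if not p_initial > 0:
        raise ValueError(f"p_initial must be > 0, got {p_initial}")
    return (p_in - p_out) / p_initial


def stage_removal_efficiency(p_in: float, p_out: float) -> float:
    """Percent of a stage's input peak area removed by that stage."""
    if not p_in > 0:
        raise ValueError(f"p_in must be > 0, got {p_in}")
    return 100.0 * (p_in - p_out) / p_in


def average_stage_metric(
    per_event: Sequence[tuple], kind: str = "re"
) -> tuple[float | None, int]:
    """Average a stage metric over events under the B.D. exclusion rules.

    *per_event* holds one tuple per sampling event: ``(p_in, p_out)`` for
    ``kind="re"`` or ``(p_in, p_out, p_initial)`` for ``kind="ure"``, with
    ``None`` marking a below-detection measurement. Returns
    ``(average, n_used)``; the average is ``None`` when no event is usable.
    """
    if not per_event:
        raise ValueError("per_event must be non-empty")
    if kind not in ("re", "ure"):
        raise ValueError(f"unknown metric kind {kind!r}")
    vals: list[float] = []
    for entry in per_event:
        p_in, p_out = entry[0], entry[1]
        if p_in is None and p_out is None:
            continue  # two subsequent below-detection measurements
        if kind == "re":
            if p_in is None:
                continue  # RE undefined without a stage input
            vals.append(stage_removal_efficiency(p_in, 0.0 if p_out is None else p_out))
        else:
            p_initial = entry[2]
            if p_initial is None:
                continue  # no influent reference for this event
            vals.append(
                unit_removal_efficiency(
                    0.0 if p_in is None else p_in,
                    0.0 if p_out is None else p_out,
                    p_initial,
                )
            )
    if not vals:
        return None, 0
    return float(np.mean(vals)), len(vals)


@dataclass
class StageMetrics:
    """Averaged metrics for one compound at one treatment stage."""

    stage: str
    avg_ure: float | None
    avg_re: float | None
    n_events_ure: int
    n_events_re: int
    bd_input: bool  # stage input below detection in every event


@dataclass
class RemovalProfile:
    """Per-stage averaged URE/RE for one compound along a train."""

    compound_id: str
    stages: dict[str, StageMetrics]

    def avg_ure(self) -> dict[str, float | None]:
        return {s: m.avg_ure for s, m in self.stages.items()}

    def avg_re(self) -> dict[str, float | None]:
        return {s: m.avg_re for s, m in self.stages.items()}


def _event_values(
    table: PeakAreaTable, compound_id: str
) -> dict[str, dict[str, float | None]]:
    """Per event: stage -> value (None for B.D. or absent record)."""
    sub = table.for_compound(compound_id)
    out: dict[str, dict[str, float | None]] = {}
    for event_id, grp in sub.groupby("event_id"):
        vals: dict[str, float | None] = {}
        for _, row in grp.iterrows():
            vals[row["stage"]] = None if row["bd"] else float(row["value"])
        out[str(event_id)] = vals
    return out


def compound_profile(
    table: PeakAreaTable, train: TreatmentTrain, compound_id: str
) -> RemovalProfile:
    """Assemble the averaged removal profile of one compound.

    The input of stage *s* is the measured value at the sampling point
    immediately upstream (the previous stage), so consecutive stages
    chain; a stage or event with no record is treated as below detection.
    """
    events = _event_values(table, compound_id)
    stages: dict[str, StageMetrics] = {}
    for i, stage in enumerate(train.process_stages, start=1):
        upstream = train.stages[i - 1]
        re_rows: list[tuple] = []
        ure_rows: list[tuple] = []
        inputs_bd = []
        for vals in events.values():
            p_in = vals.get(upstream)
            p_out = vals.get(stage)
            p_initial = vals.get(train.influent)
            re_rows.append((p_in, p_out))
            ure_rows.append((p_in, p_out, p_initial))
            inputs_bd.append(p_in is None)
        avg_re, n_re = average_stage_metric(re_rows, kind="re")
        avg_ure, n_ure = average_stage_metric(ure_rows, kind="ure")
        stages[stage] = StageMetrics(
            stage=stage,
            avg_ure=avg_ure,
            avg_re=avg_re,
            n_events_ure=n_ure,
            n_events_re=n_re,
            bd_input=all(inputs_bd),
        )
    return RemovalProfile(compound_id=compound_id, stages=stages)


def all_profiles(table: PeakAreaTable, train: TreatmentTrain) -> list[RemovalProfile]:
    return [compound_profile(table, train, c) for c in table.compounds]


def profiles_to_frame(profiles: Iterable[RemovalProfile]) -> pd.DataFrame:
    """Flatten profiles to a long CSV-ready table."""
    rows = []
    for p in profiles:
        for m in p.stages.values():
            rows.append(
                {
                    "compound_id": p.compound_id,
                    "stage": m.stage,
                    "avg_URE": m.avg_ure,
                    "avg_RE": m.avg_re,
                    "n_events_ure": m.n_events_ure,
                    "n_events_re": m.n_events_re,
                    "bd_input": m.bd_input,
                }
            )
    return pd.DataFrame(rows)
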