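"""C1 clustering: group compounds by their single most effective stage.

For each compound the treatment process with the highest average unit
removal efficiency is selected; compounds sharing that process form one
cluster. Ties break toward the upstream (earlier) stage, which keeps the
assignment fully deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .core import ClusterAssignment, TreatmentTrain
from .removal import RemovalProfile


class AssignmentError(ValueError):
    """No stage of a compound's profile is eligible for best-stage selection."""


def assign_best_stage(
    profile: RemovalProfile, train: TreatmentTrain
) -> tuple[str, bool]:
    """Return ``(best_stage, tie_flag)`` for one compound.

    Eligible stages are those with at least one usable event for URE;
    among them the stage with maximal average URE wins, earliest in the
    train on exact ties. ``tie_flag`` reports that a tie occurred.
    """
    eligible = [
        (train.index(m.stage), m.stage, m.avg_ure)
        for m in profile.stages.values()
        if m.n_events_ure >= 1
    ]
    if not eligible:
        raise AssignmentError(
            f"compound {profile.compound_id!r}: no stage with a usable event"
        )
    eligible.sort(key=lambda t: t[0])  # upstream first
    best_ure = max(u for _, _, u in eligible)
    winners = [s for _, s, u in eligible if u == best_ure]
    return winners[0], len(winners) > 1


@dataclass
class C1Result:
    assignment: ClusterAssignment
    best_ure: dict[str, float]
    tie_flags: dict[str, bool]
    unassignable: tuple[str, ...]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "compound_id": c,
                "c1_label": self.assignment.labels[c],
                "best_avg_URE": self.best_ure[c],
                "tie_flag": self.tie_flags[c],
            }
            for c in self.assignment.compounds
        ]
        return pd.DataFrame(rows)


def cluster_by_best_stage(
    profiles: list[RemovalProfile], train: TreatmentTrain
) -> C1Result:
    """Cluster compounds by best stage; every retained compound is assigned.

    Compounds with no eligible stage at all are reported in
    ``unassignable`` rather than silently dropped. A compound whose best
    average URE is negative is still assigned (its ``best_avg_URE`` makes
    this visible downstream).
    """
    if not profiles:
        raise ValueError("profiles must be non-empty")
    labels: dict[str, str] = {}
    best_ure: dict[str, float] = {}
    ties: dict[str, bool] = {}
    unassignable: list[str] = []
    for p in profiles:
        try:
            stage, tie = assign_best_stage(p, train)
        except AssignmentError:
            unassignable.append(p.compound_id)
            continue
        labels[p.compound_id] = stage
        best_ure[p.compound_id] = p.stages[stage].avg_ure
        ties[p.compound_id] = tie
    return C1Result(
        assignment=ClusterAssignment(method="C1", labels=labels),
        best_ure=best_ure,
        tie_flags=ties,
        unassignable=tuple(unassignable),
    )
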