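"""C2 clustering: K-modes over stage-to-stage removal-pattern sequences.

Each compound's average removal efficiency (RE, percent) per stage is
compared with the previous stage's and transformed to one of four
categorical symbols — increase, decrease, same, B.D. — producing one
symbol per treatment process. The sequences are clustered with K-modes
(k = 3 by default) so compounds with similar removal *patterns* group
together even when their absolute efficiencies differ.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .core import ClusterAssignment, TreatmentTrain
from .kmodes import CategoricalPattern, KModesResult, kmodes_fit
from .removal import RemovalProfile

INCREASE = "increase"
DECREASE = "decrease"
SAME = "same"
BD = "B.D."
#: canonical symbol order; fixes K-modes tie-breaking for removal patterns
SYMBOLS = (INCREASE, DECREASE, SAME, BD)


class EncodingError(ValueError):
    """A profile cannot be transformed to a categorical pattern."""


def encode_pattern(
    profile: RemovalProfile, epsilon: float = 1.0
) -> CategoricalPattern:
    """Transform a removal profile into its categorical pattern.

    Stage *s* emits B.D. when its input was below detection in every
    event; otherwise the average RE is compared with the most recent
    stage that has a defined average (baseline 0% before the first
    process): a difference above *epsilon* percentage points is an
    increase, below ``-epsilon`` a decrease, and "same" otherwise.
    """
    symbols: list[str] = []
    reference = 0.0  # RE baseline ahead of the first treatment process
    for m in profile.stages.values():
        if m.bd_input:
            symbols.append(BD)
            continue
        if m.avg_re is None:
            raise EncodingError(
                f"compound {profile.compound_id!r}: stage {m.stage!r} has no "
                "average RE yet is not below detection"
            )
        diff = m.avg_re - reference
        if diff > epsilon:
            symbols.append(INCREASE)
        elif diff < -epsilon:
            symbols.append(DECREASE)
        else:
            symbols.append(SAME)
        reference = m.avg_re
    return CategoricalPattern(compound_id=profile.compound_id, symbols=tuple(symbols))


@dataclass
class C2Result:
    assignment: ClusterAssignment
    patterns: list[CategoricalPattern]
    kmodes: KModesResult
    epsilon: float

    @property
    def modes(self) -> list[tuple[str, ...]]:
        return self.kmodes.modes

    def to_frame(self) -> pd.DataFrame:
        return self.assignment.to_frame("c2_label")

    def report(self) -> dict:
        return {
            "modes": [list(m) for m in self.kmodes.modes],
            "cost": self.kmodes.cost,
            "n_iter": self.kmodes.n_iter,
            "seed": self.kmodes.seed,
            "epsilon": self.epsilon,
        }


def cluster_c2(
    profiles: list[RemovalProfile],
    k: int = 3,
    epsilon: float = 1.0,
    seed: int | None = None,
    n_init: int = 50,
    max_iter: int = 100,
) -> C2Result:
    """Encode every profile and cluster the patterns with K-modes."""
    if len(profiles) < k:
        raise ValueError(f"need at least k={k} compounds, got {len(profiles)}")
    patterns = [encode_pattern(p, epsilon=epsilon) for p in profiles]
    result = kmodes_fit(
        patterns, k=k, seed=seed, n_init=n_init, max_iter=max_iter,
        categories=SYMBOLS,
    )
    return C2Result(
        assignment=ClusterAssignment(method="C2", labels=dict(result.labels)),
        patterns=patterns,
        kmodes=result,
        epsilon=epsilon,
    )
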