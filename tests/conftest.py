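import numpy as np
import pandas as pd
import pytest

from trainfate import PeakAreaTable, TreatmentTrain
from trainfate.simulate import Archetype, SyntheticConfig


@pytest.fixture
def train3():
    """Minimal train: influent plus two processes."""
    return TreatmentTrain("mini", ("influent", "s1", "s2"))


@pytest.fixture
def train7():
    return TreatmentTrain(
        "facility_a",
        ("influent", "primary", "activated_sludge", "ozone", "BAC", "GAC", "UV"),
    )


def make_table(train, rows):
    """Build a PeakAreaTable from (compound, event, stage, value) tuples;
    value None means below detection."""
    data = pd.DataFrame(
        [
            {
                "compound_id": c,
                "event_id": e,
                "stage": s,
                "value": np.nan if v is None else float(v),
                "bd": v is None,
            }
            for c, e, s, v in rows
        ]
    )
    return PeakAreaTable(train=train, data=data)


@pytest.fixture
def make_peak_table():
    return make_table


def pattern_recovery_config(seed: int, n_compounds: int = 90) -> SyntheticConfig:
    """Three planted removal-pattern archetypes, pairwise Hamming 3 apart,
    under low measurement noise: the ground truth for C2 recovery."""
    train = TreatmentTrain("pattern_demo", ("influent", "s1", "s2", "s3", "s4"))
    archetypes = [
        Archetype("flat", (0.6, 0.6, 0.6, 0.6), 1 / 3,
                  (1.0, 1.2, 0.5, 1.2, 1.6, 6.0, 1.0)),
        Archetype("late", (0.1, 0.8, 0.1, 0.8), 1 / 3,
                  (1.5, 1.8, 0.2, 0.8, 2.0, 7.5, 2.5)),
        Archetype("early", (0.8, 0.1, 0.8, 0.1), 1 / 3,
                  (0.8, 0.9, 0.8, 1.6, 2.4, 8.5, 4.0)),
    ]
    return SyntheticConfig(
        train=train, archetypes=archetypes, n_compounds=n_compounds,
        noise_sd=0.01, detection_limit=1e-6, seed=seed,
    )
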