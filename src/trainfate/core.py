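"""Domain types, delimited-table I/O and the compound preprocessing filters.

Peak areas are relative abundances from LC-MS/MS non-target profiling;
a measurement under the instrument detection limit is carried as a
categorical *below detection* (B.D.) flag, never as the number 0, so the
downstream exclusion rules can distinguish "small" from "absent".
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

#: fixed column order for Abraham descriptors + hydrophobicity
DESCRIPTOR_COLUMNS = ("E", "S", "A", "B", "V", "L", "logKow")


class ValidationError(ValueError):
    """An input table or configuration violates a structural invariant."""


@dataclass(frozen=True)
class TreatmentTrain:
    """An ordered sequence of unit processes at one facility.

    The first stage is the facility influent sampling point; it serves as
    the normalisation reference for unit removal efficiencies and as the
    input to the first treatment process.
    """

    facility_id: str
    stages: tuple[str, ...]

    def __post_init__(self) -> None:
        stages = tuple(self.stages)
        object.__setattr__(self, "stages", stages)
        if len(stages) < 2:
            raise ValidationError(
                f"train {self.facility_id!r} needs at least 2 stages, got {len(stages)}"
            )
        dupes = {s for s in stages if list(stages).count(s) > 1}
        if dupes:
            raise ValidationError(
                f"duplicate stage name(s) in train {self.facility_id!r}: {sorted(dupes)}"
            )

    @property
    def influent(self) -> str:
        return self.stages[0]

    @property
    def process_stages(self) -> tuple[str, ...]:
        """Stages downstream of the influent (the ones with removal metrics)."""
        return self.stages[1:]

    def index(self, stage: str) -> int:
        return self.stages.index(stage)


@dataclass
class PeakAreaTable:
    """Long-format compound x event x stage peak areas bound to a train.

    ``data`` columns: ``compound_id``, ``event_id``, ``stage``, ``value``
    (float, NaN when below detection) and ``bd`` (bool flag).
    """

    train: TreatmentTrain
    data: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        required = {"compound_id", "event_id", "stage", "value", "bd"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValidationError(f"peak-area table missing column(s): {sorted(missing)}")
        unknown = set(self.data["stage"]) - set(self.train.stages)
        if unknown:
            raise ValidationError(
                f"stage name(s) not in train {self.train.facility_id!r}: {sorted(unknown)}"
            )
        numeric = self.data.loc[~self.data["bd"], "value"]
        if numeric.isna().any():
            raise ValidationError("non-flagged record with missing value")
        if (numeric <= 0).any():
            bad = self.data.loc[~self.data["bd"] & (self.data["value"] <= 0)]
            raise ValidationError(
                "peak areas must be strictly positive; offending rows: "
                f"{bad[['compound_id', 'event_id', 'stage']].to_dict('records')[:5]}"
            )
        keys = self.data[["compound_id", "event_id", "stage"]]
        if keys.duplicated().any():
            dup = keys[keys.duplicated()].iloc[0].to_dict()
            raise ValidationError(f"duplicate (compound, event, stage) key: {dup}")

    @property
    def compounds(self) -> list[str]:
        return sorted(self.data["compound_id"].unique())

    @property
    def events(self) -> list[str]:
        return sorted(self.data["event_id"].unique())

    def for_compound(self, compound_id: str) -> pd.DataFrame:
        sub = self.data[self.data["compound_id"] == compound_id]
        if sub.empty:
            raise KeyError(f"compound {compound_id!r} not in table")
        return sub

    def write(self, path: str | Path, bd_code: str = "BD") -> None:
        out = self.data.copy()
        out["value"] = [
            bd_code if bd else repr(float(v))
            for v, bd in zip(out["value"], out["bd"])
        ]
        out[["compound_id", "event_id", "stage", "value"]].to_csv(path, index=False)


@dataclass
class DescriptorTable:
    """Abraham descriptors (E, S, A, B, V, L) plus log Kow per compound.

    ``data`` is indexed by compound_id with the seven descriptor columns in
    canonical order; ``excluded`` lists compounds dropped at read time for
    incomplete descriptor rows.
    """

    data: pd.DataFrame
    excluded: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        missing = set(DESCRIPTOR_COLUMNS) - set(self.data.columns)
        if missing:
            raise ValidationError(f"descriptor table missing column(s): {sorted(missing)}")
        self.data = self.data[list(DESCRIPTOR_COLUMNS)].astype(float)
        if not np.isfinite(self.data.to_numpy()).all():
            raise ValidationError("descriptor table contains non-finite values")
        if (self.data["V"] <= 0).any():
            raise ValidationError("McGowan volume V must be positive")

    @property
    def compounds(self) -> list[str]:
        return list(self.data.index)

    def write(self, path: str | Path) -> None:
        self.data.rename_axis("compound_id").to_csv(path)


@dataclass
class ClusterAssignment:
    """A compound -> label mapping produced by one clustering method."""

    method: str  # "C1" | "C2" | "property"
    labels: dict[str, object]

    @property
    def k(self) -> int:
        return len(set(self.labels.values()))

    @property
    def compounds(self) -> list[str]:
        return sorted(self.labels)

    def sizes(self) -> dict[object, int]:
        out: dict[object, int] = {}
        for lab in self.labels.values():
            out[lab] = out.get(lab, 0) + 1
        return out

    def to_frame(self, label_col: str = "label") -> pd.DataFrame:
        return pd.DataFrame(
            {"compound_id": self.compounds,
             label_col: [self.labels[c] for c in self.compounds]}
        )


# ---------------------------------------------------------------------------
# readers


def _is_bd(cell: str, bd_code: str) -> bool:
    s = str(cell).strip()
    return s == "" or s.lower() in ("nan", bd_code.lower())


def read_peak_area_table(
    path: str | Path, train: TreatmentTrain, bd_code: str = "BD"
) -> PeakAreaTable:
    """Read a long-format peak-area CSV and bind it to *train*.

    Expected columns: ``compound_id,event_id,stage,value`` with an optional
    ``replicate`` column. Cells equal to *bd_code* (case-insensitive) or
    empty are below-detection flags. Replicates are averaged to one value
    per (compound, event, stage); B.D. replicates are ignored in the mean
    unless every replicate is B.D., in which case the record is flagged.
    """
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = {"compound_id", "event_id", "stage", "value"}
    missing = required - set(raw.columns)
    if missing:
        raise ValidationError(f"peak-area file missing column(s): {sorted(missing)}")

    values: list[float] = []
    flags: list[bool] = []
    for i, cell in enumerate(raw["value"]):
        if _is_bd(cell, bd_code):
            values.append(np.nan)
            flags.append(True)
            continue
        try:
            v = float(cell)
        except ValueError as exc:
            raise ValidationError(f"row {i}: unparseable value {cell!r}") from exc
        if v <= 0:
            raise ValidationError(
                f"row {i}: peak area must be strictly positive, got {v}"
            )
        values.append(v)
        flags.append(False)
    parsed = raw[["compound_id", "event_id", "stage"]].copy()
    parsed["value"] = values
    parsed["bd"] = flags

    if "replicate" in raw.columns:
        grouped = parsed.groupby(
            ["compound_id", "event_id", "stage"], sort=False, as_index=False
        ).agg(value=("value", "mean"), bd=("bd", "all"))
        parsed = grouped
        parsed.loc[parsed["bd"], "value"] = np.nan

    return PeakAreaTable(train=train, data=parsed.reset_index(drop=True))


def read_descriptor_table(path: str | Path) -> DescriptorTable:
    """Read a compound x descriptor CSV, excluding incomplete rows.

    Rows with any missing descriptor are dropped and reported via the
    ``excluded`` attribute of the returned table.
    """
    raw = pd.read_csv(path)
    if "compound_id" not in raw.columns:
        raise ValidationError("descriptor file missing column(s): ['compound_id']")
    missing = set(DESCRIPTOR_COLUMNS) - set(raw.columns)
    if missing:
        raise ValidationError(f"descriptor file missing column(s): {sorted(missing)}")
    raw = raw.set_index("compound_id")
    complete = raw[list(DESCRIPTOR_COLUMNS)].notna().all(axis=1)
    excluded = tuple(raw.index[~complete])
    return DescriptorTable(data=raw.loc[complete], excluded=excluded)


def read_train_config(path: str | Path) -> TreatmentTrain:
    """Read a YAML/JSON train configuration: facility_id + ordered stages."""
    text = Path(path).read_text()
    try:
        cfg = json.loads(text)
    except json.JSONDecodeError:
        cfg = yaml.safe_load(text)
    if not isinstance(cfg, Mapping) or "facility_id" not in cfg or "stages" not in cfg:
        raise ValidationError("train config needs 'facility_id' and 'stages'")
    return TreatmentTrain(facility_id=str(cfg["facility_id"]),
                          stages=tuple(str(s) for s in cfg["stages"]))


# ---------------------------------------------------------------------------
# preprocessing


@dataclass
class PreprocessResult:
    table: PeakAreaTable
    removed_all_bd: tuple[str, ...] = ()
    removed_not_shared: tuple[str, ...] = ()

    @property
    def removal_log(self) -> dict[str, list[str]]:
        return {
            "no_detection_anywhere": list(self.removed_all_bd),
            "not_shared_across_events": list(self.removed_not_shared),
        }


def preprocess_compounds(table: PeakAreaTable) -> PreprocessResult:
    """Apply the two compound filters used before clustering.

    First, compounds with no detected (numeric) value at any stage of any
    event are removed. Second, the table is restricted to the compounds
    shared among all sampling events, where a compound counts as present
    in an event if it has any record there (numeric or below-detection).
    """
    data = table.data
    events = set(data["event_id"])
    if not events:
        raise ValidationError("peak-area table has no events")

    detected = set(data.loc[~data["bd"], "compound_id"])
    all_bd = tuple(sorted(set(data["compound_id"]) - detected))

    per_event = data.groupby("compound_id")["event_id"].agg(set)
    shared = {c for c, evs in per_event.items() if evs == events}
    not_shared = tuple(sorted((detected - shared)))

    keep = detected & shared
    if not keep:
        raise ValidationError(
            "no compound survives preprocessing; inspect event coverage "
            f"(events seen: {sorted(events)})"
        )
    out = data[data["compound_id"].isin(keep)].reset_index(drop=True)
    return PreprocessResult(
        table=PeakAreaTable(train=table.train, data=out),
        removed_all_bd=all_bd,
        removed_not_shared=not_shared,
    )
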