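"""Synthetic treatment-train studies with planted removal archetypes.

The generator emulates the statistical structure the framework assumes:

* each compound belongs to one *archetype* with fixed true per-stage
  removal fractions ``r_s``; peak areas propagate multiplicatively,
  ``A_s = A_{s-1} (1 - r_s) exp(eps)`` with lognormal measurement noise
  ``eps ~ Normal(0, noise_sd^2)`` drawn independently per stage and
  event;
* influent areas are lognormal across compounds and events (instrument
  intensities are positive and heteroscedastic);
* any area under the detection limit is recorded as below detection,
  producing the B.D. runs the exclusion rules must handle;
* descriptor vectors are Gaussian per archetype, with the separation
  between archetype means scaled by an effect size Δ (Δ = 0 makes
  descriptors uninformative — a built-in null).

Ground truth per compound — the archetype and the *dominant stage*, the
stage removing the largest fraction of the influent in the noise-free
model, ``argmax_s r_s * prod_{i<s}(1 - r_i)`` — is retained so recovery
by C1/C2/classification can be scored exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import (
    DESCRIPTOR_COLUMNS,
    DescriptorTable,
    PeakAreaTable,
    TreatmentTrain,
    ValidationError,
)


@dataclass(frozen=True)
class Archetype:
    """A planted removal behaviour shared by a group of compounds."""

    label: str
    removal: tuple[float, ...]  # true removal fraction per process stage
    weight: float
    descriptor_mean: tuple[float, ...]  # 7-vector, canonical column order

    def dominant_stage_index(self) -> int:
        r = np.asarray(self.removal)
        surviving = np.concatenate([[1.0], np.cumprod(1.0 - r)[:-1]])
        return int(np.argmax(surviving * r))


@dataclass
class SyntheticConfig:
    """Full parameterisation of one synthetic study."""

    train: TreatmentTrain
    archetypes: list[Archetype]
    n_compounds: int = 120
    n_events: int = 4
    influent_log_mean: float = 13.0  # exp(13) ~ 4.4e5 peak-area units
    influent_log_sd: float = 1.0
    noise_sd: float = 0.15  # sd of log multiplicative measurement noise
    detection_limit: float = 5e3
    descriptor_sd: tuple[float, ...] = (0.3, 0.3, 0.15, 0.3, 0.3, 0.8, 0.7)
    effect_size: float = 1.0  # Δ; scales inter-archetype descriptor separation
    seed: int = 0

    def validate(self) -> None:
        n_proc = len(self.train.process_stages)
        if not self.archetypes:
            raise ValidationError("need at least one archetype")
        wsum = sum(a.weight for a in self.archetypes)
        if not np.isclose(wsum, 1.0):
            raise ValidationError(f"archetype weights must sum to 1, got {wsum}")
        for a in self.archetypes:
            if len(a.removal) != n_proc:
                raise ValidationError(
                    f"archetype {a.label!r}: {len(a.removal)} removal fractions "
                    f"for {n_proc} process stages"
                )
            if any(not (0.0 <= r < 1.0) for r in a.removal):
                raise ValidationError(
                    f"archetype {a.label!r}: removal fractions must be in [0, 1)"
                )
            if len(a.descriptor_mean) != len(DESCRIPTOR_COLUMNS):
                raise ValidationError(
                    f"archetype {a.label!r}: descriptor mean must have "
                    f"{len(DESCRIPTOR_COLUMNS)} entries"
                )
        if not self.detection_limit > 0:
            raise ValidationError("detection_limit must be positive")
        if self.n_events < 1:
            raise ValidationError("need at least one sampling event")
        if self.n_compounds < 1:
            raise ValidationError("need at least one compound")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["train"] = {"facility_id": self.train.facility_id,
                      "stages": list(self.train.stages)}
        d["archetypes"] = [
            {"label": a.label, "removal": list(a.removal), "weight": a.weight,
             "descriptor_mean": list(a.descriptor_mean)}
            for a in self.archetypes
        ]
        d["descriptor_sd"] = list(self.descriptor_sd)
        return d


@dataclass
class SyntheticStudy:
    """Generated peak areas, descriptors and per-compound ground truth."""

    peak_table: PeakAreaTable
    descriptors: DescriptorTable
    truth: pd.DataFrame  # compound_id (index), archetype, dominant_stage
    config: SyntheticConfig

    def write(self, outdir: str | Path, bd_code: str = "BD") -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.peak_table.write(outdir / "peak_areas.csv", bd_code=bd_code)
        self.descriptors.write(outdir / "descriptors.csv")
        self.truth.to_csv(outdir / "truth.csv")
        (outdir / "config.yaml").write_text(
            yaml.safe_dump(self.config.to_dict(), sort_keys=True)
        )


def generate_study(config: SyntheticConfig) -> SyntheticStudy:
    """Draw one synthetic study; deterministic given ``config.seed``."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    train = config.train
    n_arch = len(config.archetypes)
    weights = np.array([a.weight for a in config.archetypes])

    # archetype descriptor means, pulled toward the common centroid by Δ
    means = np.array([a.descriptor_mean for a in config.archetypes], dtype=float)
    center = means.mean(axis=0)
    scaled_means = center + config.effect_size * (means - center)
    sd = np.asarray(config.descriptor_sd, dtype=float)

    compound_ids = [f"cmp{idx:04d}" for idx in range(config.n_compounds)]
    arch_idx = rng.choice(n_arch, size=config.n_compounds, p=weights)

    records = []
    desc_rows = []
    truth_rows = []
    for c, ci in zip(compound_ids, arch_idx):
        arch = config.archetypes[ci]
        r = np.asarray(arch.removal)
        for e in range(config.n_events):
            event_id = f"event{e + 1}"
            area = float(rng.lognormal(config.influent_log_mean,
                                       config.influent_log_sd))
            for stage_i, stage in enumerate(train.stages):
                if stage_i > 0:
                    eps = rng.normal(0.0, config.noise_sd) if config.noise_sd > 0 else 0.0
                    area = area * (1.0 - r[stage_i - 1]) * float(np.exp(eps))
                bd = area < config.detection_limit
                records.append(
                    {"compound_id": c, "event_id": event_id, "stage": stage,
                     "value": np.nan if bd else area, "bd": bd}
                )
        desc = rng.normal(scaled_means[ci], sd)
        desc_rows.append(dict(zip(DESCRIPTOR_COLUMNS, desc), compound_id=c))
        truth_rows.append(
            {"compound_id": c, "archetype": arch.label,
             "dominant_stage": train.process_stages[arch.dominant_stage_index()]}
        )

    peak = PeakAreaTable(train=train, data=pd.DataFrame(records))
    desc_df = pd.DataFrame(desc_rows).set_index("compound_id")
    desc_df["V"] = desc_df["V"].clip(lower=0.1)  # McGowan volume is positive
    descriptors = DescriptorTable(data=desc_df)
    truth = pd.DataFrame(truth_rows).set_index("compound_id")
    return SyntheticStudy(peak_table=peak, descriptors=descriptors, truth=truth,
                          config=config)


# ---------------------------------------------------------------------------
# presets emulating the two field facilities

_POTABLE_STAGES = ("influent", "primary", "activated_sludge", "flocsed",
                   "ozone", "BAC", "GAC", "UV")
_NONPOTABLE_STAGES = ("influent", "primary", "activated_sludge",
                      "denit_filter", "chlorination")

# typical Abraham descriptor / log Kow ranges for small pharmaceuticals
_DESC_BIO = (1.0, 1.2, 0.5, 1.2, 1.6, 6.0, 1.0)
_DESC_OXID = (1.5, 1.8, 0.2, 0.8, 2.0, 7.5, 2.5)
_DESC_SORB = (0.8, 0.9, 0.8, 1.6, 2.4, 8.5, 4.0)


def preset(name: str, seed: int = 0, **overrides) -> SyntheticConfig:
    """Named study configurations mirroring the two reuse facilities.

    ``potable`` is an 8-stage advanced-reuse train (flocculation/
    sedimentation, ozone, biological and granular activated carbon, UV
    after conventional treatment); ``nonpotable`` a 5-stage train ending
    in denitrification-filtration and chlorination. Both carry 4
    sampling events, 120 compounds and three removal archetypes
    (biodegradable, oxidisable, adsorbable) with distinct dominant
    stages. Keyword overrides replace any SyntheticConfig field.
    """
    if name == "potable":
        train = TreatmentTrain("potable_reuse", _POTABLE_STAGES)
        archetypes = [
            # process stages: primary, AS, flocsed, ozone, BAC, GAC, UV
            Archetype("biodegradable", (0.10, 0.75, 0.05, 0.30, 0.20, 0.10, 0.05),
                      1 / 3, _DESC_BIO),
            Archetype("oxidizable", (0.05, 0.20, 0.05, 0.95, 0.10, 0.10, 0.05),
                      1 / 3, _DESC_OXID),
            Archetype("adsorbable", (0.05, 0.15, 0.05, 0.10, 0.30, 0.80, 0.05),
                      1 / 3, _DESC_SORB),
        ]
    elif name == "nonpotable":
        train = TreatmentTrain("nonpotable_reuse", _NONPOTABLE_STAGES)
        archetypes = [
            # process stages: primary, AS, denit_filter, chlorination
            Archetype("biodegradable", (0.10, 0.80, 0.15, 0.20), 1 / 3, _DESC_BIO),
            Archetype("oxidizable", (0.05, 0.20, 0.10, 0.90), 1 / 3, _DESC_OXID),
            Archetype("adsorbable", (0.10, 0.20, 0.80, 0.10), 1 / 3, _DESC_SORB),
        ]
    else:
        raise ValueError(f"unknown preset {name!r}; expected 'potable' or 'nonpotable'")
    cfg = SyntheticConfig(train=train, archetypes=archetypes, seed=seed)
    for key, val in overrides.items():
        if not hasattr(cfg, key):
            raise ValueError(f"unknown SyntheticConfig field {key!r}")
        setattr(cfg, key, val)
    return cfg
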