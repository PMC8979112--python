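"""Readers/writers for the shared delimited formats and run configuration.

Conventions: times in hours, retention times in minutes, volumes in
microliters; comma-delimited tables with a header row; YAML for
configuration and structured reports. Floats are serialized at full
precision — rounding happens only in human-readable summaries.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .auc import ConcentrationProfile
from .errors import ValidationError
from .pooling import (
    DEFAULT_ROUNDING_INCREMENT_UL,
    PoolingDesign,
    SamplingSchedule,
)
from .simulate import CentroidSpectrum, DEFAULT_TIMES_H, DEFAULT_TOTAL_VOLUME_UL

PEAK_TABLE_REQUIRED = ("compound_id", "species", "replicate", "area")


@dataclass(frozen=True)
class PeakAreaMatrix:
    """Long-format compounds × samples table of pooled peak areas.

    Required columns: compound_id, species, replicate, area; optional
    extras (mz, rt, name, below_lloq) are carried through untouched.
    The (compound_id, species, replicate) key is unique.
    """

    data: pd.DataFrame
    diagnostics: tuple[str, ...] = field(default=(), compare=False)

    def __post_init__(self):
        missing = [c for c in PEAK_TABLE_REQUIRED if c not in self.data.columns]
        if missing:
            raise ValidationError(f"peak table missing required column(s): {missing}")
        if (self.data["area"] < 0).any():
            raise ValidationError("peak areas must be >= 0")
        dup = self.data.duplicated(subset=["compound_id", "species", "replicate"])
        if dup.any():
            keys = self.data.loc[dup, ["compound_id", "species", "replicate"]]
            raise ValidationError(
                f"duplicate (compound, species, replicate) keys: "
                f"{keys.to_records(index=False).tolist()}"
            )

    @property
    def species(self) -> list[str]:
        return sorted(self.data["species"].unique())

    @property
    def compounds(self) -> list[str]:
        return sorted(self.data["compound_id"].unique())


def read_peak_table(path) -> PeakAreaMatrix:
    """Read a delimited peak table, rejecting malformed rows with
    line-numbered diagnostics (header is line 1)."""
    raw = pd.read_csv(path)
    missing = [c for c in PEAK_TABLE_REQUIRED if c not in raw.columns]
    if missing:
        raise ValidationError(
            f"{path}: missing required column(s): {', '.join(missing)}"
        )
    area = pd.to_numeric(raw["area"], errors="coerce")
    bad = area.isna() | (area < 0)
    diagnostics = tuple(
        f"{path}: line {i + 2}: invalid area {raw['area'].iloc[i]!r} — row rejected"
        for i in np.flatnonzero(bad.to_numpy())
    )
    clean = raw.loc[~bad].copy()
    clean["area"] = area[~bad]
    return PeakAreaMatrix(clean.reset_index(drop=True), diagnostics=diagnostics)


def write_peak_table(matrix: PeakAreaMatrix, path) -> None:
    matrix.data.to_csv(path, index=False)


def write_design(design: PoolingDesign, path) -> None:
    pd.DataFrame(
        {"time_h": design.schedule.times, "volume_uL": design.volumes}
    ).to_csv(path, index=False)


def read_design(path, total_volume: float | None = None) -> PoolingDesign:
    d = pd.read_csv(path)
    schedule = SamplingSchedule(d["time_h"].tolist())
    vols = tuple(float(v) for v in d["volume_uL"])
    return PoolingDesign(
        schedule=schedule,
        volumes=vols,
        total_volume=float(total_volume) if total_volume is not None else float(sum(vols)),
        rounding_increment=0.0 if total_volume is None else DEFAULT_ROUNDING_INCREMENT_UL,
    )


def write_profiles(profiles: Iterable[ConcentrationProfile], path) -> None:
    rows = []
    for p in profiles:
        for t, v, flag in zip(p.times, p.values, p.below_lloq):
            rows.append(
                {
                    "compound_id": p.compound_id,
                    "time_h": t,
                    "value": v,
                    "unit": p.unit_label,
                    "below_lloq": flag,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_profiles(path) -> list[ConcentrationProfile]:
    d = pd.read_csv(path)
    for col in ("compound_id", "time_h", "value"):
        if col not in d.columns:
            raise ValidationError(f"{path}: missing required column(s): {col}")
    profiles = []
    for cid, grp in d.groupby("compound_id", sort=False):
        grp = grp.sort_values("time_h")
        profiles.append(
            ConcentrationProfile(
                compound_id=str(cid),
                times=tuple(float(t) for t in grp["time_h"]),
                values=tuple(float(v) for v in grp["value"]),
                unit_label=str(grp["unit"].iloc[0]) if "unit" in grp else "value",
                below_lloq=tuple(bool(b) for b in grp["below_lloq"])
                if "below_lloq" in grp
                else (),
            )
        )
    return profiles


def write_spectra(spectra: Sequence[CentroidSpectrum], path) -> None:
    """Internal delimited spectra format: one row per centroid."""
    rows = [
        {"rt_min": s.retention_time, "mz": m, "intensity": i}
        for s in spectra
        for m, i in zip(s.mz, s.intensity)
    ]
    pd.DataFrame(rows, columns=["rt_min", "mz", "intensity"]).to_csv(path, index=False)


def read_spectra(path) -> list[CentroidSpectrum]:
    d = pd.read_csv(path)
    spectra = []
    for rt, grp in d.groupby("rt_min", sort=True):
        spectra.append(
            CentroidSpectrum(
                retention_time=float(rt),
                mz=tuple(float(m) for m in grp["mz"]),
                intensity=tuple(float(i) for i in grp["intensity"]),
            )
        )
    return spectra


@dataclass(frozen=True)
class RunConfig:
    """Configuration of a full screening run (simulated or from files)."""

    times_h: tuple[float, ...] = DEFAULT_TIMES_H
    total_volume_uL: float = DEFAULT_TOTAL_VOLUME_UL
    rounding_increment_uL: float = 0.0
    species: tuple[str, ...] = ("human", "rat", "mouse")
    reference_species: str = "human"
    reference_compounds: tuple[str, ...] = ("P1",)
    replicates: int = 3
    noise_cv: float = 0.10
    lloq: float = 0.0
    seed: int = 0
    ppm_tolerance: float = 5.0
    r_threshold: float = 0.8
    p_threshold: float = 0.001
    top_k: int = 10
    top_n: int = 10
    peak_table: str | None = None  # when set, skip simulation and load this
    out_dir: str = "aucpool_out"

    def schedule(self) -> SamplingSchedule:
        return SamplingSchedule(self.times_h)

    def to_yaml(self) -> str:
        d = asdict(self)
        d = {k: (list(v) if isinstance(v, tuple) else v) for k, v in d.items()}
        return yaml.safe_dump(d, sort_keys=True)

    def digest(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]


def read_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = set(RunConfig.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise ValidationError(f"unknown config key(s): {sorted(unknown)}")
    for key in ("times_h", "species", "reference_compounds"):
        if key in raw and isinstance(raw[key], list):
            raw[key] = tuple(raw[key])
    return RunConfig(**raw)
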