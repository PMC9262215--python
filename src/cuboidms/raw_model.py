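"""Core data model, configuration and inter-stage file I/O.

Raw detector readings are kept as pandas DataFrames with a fixed columnar
schema (one row per intensity reading in the four dimensions m/z, mobility
scan, retention time, intensity).  Pipeline stages communicate through
tables on disk -- Feather preferred, CSV accepted, chosen by file
extension.

Conventions used everywhere in this package:

* frame and scan indices are 0-based integers;
* m/z, scan and frame/RT intervals are closed on both ends;
* low scan number corresponds to high 1/K0 mobility (instrument
  convention);
* each frame id has exactly one MS level.
"""

from __future__ import annotations

import dataclasses
import math
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

#: Mass of a proton (H+) in Da, the value added to a neutral mass to obtain
#: the singly protonated m/z.
PROTON_MASS = 1.00727647

#: 13C - 12C mass difference in Da; the dominant isotope spacing for
#: peptides, divided by charge to obtain the m/z spacing of an envelope.
ISOTOPE_SPACING = 1.00335483

TABLE_SCHEMA_VERSION = 1

#: Columnar schema for raw point tables.
POINT_SCHEMA: dict[str, str] = {
    "ms_level": "int8",
    "frame_id": "int32",
    "retention_time": "float64",
    "scan": "int32",
    "mobility": "float64",
    "mz": "float64",
    "intensity": "float32",
}

#: Columnar schema for precursor isolation-window tables.
ISOLATION_WINDOW_SCHEMA: dict[str, str] = {
    "precursor_id": "int64",
    "frame_id": "int32",
    "mz_lower": "float64",
    "mz_upper": "float64",
    "scan_begin": "int32",
    "scan_end": "int32",
    "collision_energy": "float32",
}


class SchemaError(ValueError):
    """A table is missing a required column or has an unusable layout."""


@dataclass(frozen=True)
class RawPoint:
    """One detector intensity reading in 4D.

    Attributes
    ----------
    frame_id : int
        TIMS frame index (maps to retention time).
    retention_time : float
        Seconds since run start.
    scan : int
        Mobility scan index within the frame; low scan = high 1/K0.
    mobility : float
        Inverse reduced mobility 1/K0 in V*s/cm^2.
    mz : float
        Mass over charge in Th.
    intensity : float
        ADC counts (dimensionless).
    """

    frame_id: int
    retention_time: float
    scan: int
    mobility: float
    mz: float
    intensity: float

    def __post_init__(self) -> None:
        if self.intensity <= 0:
            raise ValueError("intensity must be > 0")
        if self.mz <= 0:
            raise ValueError("mz must be > 0")
        if self.retention_time < 0:
            raise ValueError("retention_time must be >= 0")
        if self.scan < 0:
            raise ValueError("scan must be >= 0")


@dataclass(frozen=True)
class IsolationWindow:
    """One quadrupole isolation event: an m/z x scan region in one frame."""

    precursor_id: int
    frame_id: int
    mz_lower: float
    mz_upper: float
    scan_begin: int
    scan_end: int
    collision_energy: float = 0.0  # eV; carried through, not used

    def __post_init__(self) -> None:
        if not self.mz_lower < self.mz_upper:
            raise ValueError("mz_lower must be < mz_upper")
        if not self.scan_begin < self.scan_end:
            raise ValueError("scan_begin must be < scan_end")


@dataclass
class PipelineConfig:
    """Tunable parameters shared across the pipeline stages.

    Defaults reflect a timsTOF-style instrument: resolution 40,000 for the
    resolution-derived peak windows, and an ADC saturation threshold of
    3000 counts.  ``base_peak_width`` is chromatography dependent and
    should be set from empirical observation of the gradient.
    """

    instrument_resolution: float = 40000.0
    saturation_threshold: float = 3000.0
    base_peak_width: float = 10.0  # seconds, chromatography-dependent
    mono_mz_extension: float = 1.0  # Th added below the isolation window
    extend_mz_both_sides: bool = False
    charge_min: int = 1
    charge_max: int = 5
    max_features_per_cuboid: int = 3
    envelope_score_threshold: float = 0.7
    min_isotopes: int = 2
    max_isotopes: int = 7
    # ratio below which a peak one isotope spacing below a candidate seed is
    # treated as noise rather than evidence the seed is not monoisotopic
    left_peak_min_ratio: float = 0.25
    ms2_charge_min: int = 1
    ms2_charge_max: int = 2
    # the envelope scorer halves the score of a two-isotope series (one
    # expected isotope missing among the first three), so an MS2 threshold
    # accepting clean fragment doublets must sit below 0.5
    ms2_envelope_score_threshold: float = 0.3
    ms2_max_fragments: int = 500
    mass_defect_window_da_min: int = 100
    mass_defect_window_da_max: int = 5000
    proton_mass: float = PROTON_MASS
    random_seed: int = 1

    def __post_init__(self) -> None:
        for name in (
            "instrument_resolution",
            "saturation_threshold",
            "base_peak_width",
            "mono_mz_extension",
            "envelope_score_threshold",
            "ms2_envelope_score_threshold",
            "proton_mass",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.charge_min > self.charge_max:
            raise ValueError("charge_min must be <= charge_max")
        if self.ms2_charge_min > self.ms2_charge_max:
            raise ValueError("ms2_charge_min must be <= ms2_charge_max")
        if self.charge_min < 1:
            raise ValueError("charge_min must be >= 1")
        if not 0 < self.mass_defect_window_da_min < self.mass_defect_window_da_max:
            raise ValueError("mass defect window range must satisfy 0 < min < max")
        if self.min_isotopes < 2:
            raise ValueError("min_isotopes must be >= 2 (charge is undefined from one peak)")

    @classmethod
    def from_file(cls, path: str | os.PathLike) -> "PipelineConfig":
        """Load a config from a TOML or YAML file mirroring the field names."""
        path = Path(path)
        if path.suffix.lower() == ".toml":
            import tomllib

            with open(path, "rb") as fh:
                data = tomllib.load(fh)
        elif path.suffix.lower() in (".yaml", ".yml"):
            import yaml

            with open(path) as fh:
                data = yaml.safe_load(fh) or {}
        else:
            raise ValueError(f"unsupported config format: {path.suffix}")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise SchemaError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def replace(self, **kwargs) -> "PipelineConfig":
        return dataclasses.replace(self, **kwargs)


@dataclass
class PointCloud:
    """Raw points partitioned by MS level, plus the frame index.

    ``frames`` has one row per frame: frame_id, ms_level, retention_time.
    """

    ms1: pd.DataFrame
    ms2: pd.DataFrame
    frames: pd.DataFrame

    def frame_rt(self) -> Mapping[int, float]:
        return dict(zip(self.frames["frame_id"], self.frames["retention_time"]))


def _empty_table(schema: Mapping[str, str]) -> pd.DataFrame:
    return pd.DataFrame({c: pd.Series(dtype=t) for c, t in schema.items()})


def _coerce(df: pd.DataFrame, schema: Mapping[str, str], where: str) -> pd.DataFrame:
    for col in schema:
        if col not in df.columns:
            raise SchemaError(f"{where}: missing required column '{col}'")
    return df[list(schema)].astype(schema, copy=True)


def write_table(rows: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write a stage table; format chosen by extension (.feather or .csv)."""
    path = Path(path)
    df = rows.reset_index(drop=True)
    if path.suffix.lower() == ".feather":
        df.to_feather(path)
    elif path.suffix.lower() == ".csv":
        df.to_csv(path, index=False)
    else:
        raise ValueError(f"unsupported table format: {path.suffix} (use .feather or .csv)")


def read_table(path: str | os.PathLike, schema: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Read a stage table written by :func:`write_table`.

    An empty file yields an empty table (with the schema's columns when a
    schema is given), not an error.
    """
    path = Path(path)
    if path.suffix.lower() == ".feather":
        df = pd.read_feather(path)
    elif path.suffix.lower() == ".csv":
        try:
            df = pd.read_csv(path)
        except pd.errors.EmptyDataError:
            df = _empty_table(schema) if schema else pd.DataFrame()
    else:
        raise ValueError(f"unsupported table format: {path.suffix} (use .feather or .csv)")
    if schema is not None:
        df = _coerce(df, schema, str(path))
    return df


def load_points(path: str | os.PathLike) -> PointCloud:
    """Load a raw point table and partition it by MS level.

    Output ordering contract: rows sorted by (frame_id, scan, mz) within
    each level.  Raises :class:`SchemaError` when a required column is
    absent or a frame id carries more than one MS level.
    """
    df = read_table(path, POINT_SCHEMA)
    return partition_points(df, where=str(path))


def partition_points(df: pd.DataFrame, where: str = "points") -> PointCloud:
    df = _coerce(df, POINT_SCHEMA, where)
    df = df.sort_values(["frame_id", "scan", "mz"], kind="stable").reset_index(drop=True)
    frames = (
        df.groupby("frame_id", sort=True)
        .agg(ms_level=("ms_level", "first"), retention_time=("retention_time", "first"))
        .reset_index()
    )
    levels_per_frame = df.groupby("frame_id")["ms_level"].nunique()
    if (levels_per_frame > 1).any():
        bad = int(levels_per_frame[levels_per_frame > 1].index[0])
        raise SchemaError(f"{where}: frame {bad} has more than one ms_level")
    ms1 = df[df["ms_level"] == 1].reset_index(drop=True)
    ms2 = df[df["ms_level"] == 2].reset_index(drop=True)
    return PointCloud(ms1=ms1, ms2=ms2, frames=frames)


def load_isolation_windows(path: str | os.PathLike) -> pd.DataFrame:
    """Load isolation windows; sorted by (precursor_id, frame_id)."""
    df = read_table(path, ISOLATION_WINDOW_SCHEMA)
    return df.sort_values(["precursor_id", "frame_id"], kind="stable").reset_index(drop=True)
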