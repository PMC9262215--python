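"""Seed precursor search cuboids from isolation windows.

During DDA acquisition the instrument selects each eluting precursor for
fragmentation several times, leaving a trail of isolation windows (small
m/z x mobility regions, one per frame).  Those windows seed the regions in
which peptide features are sought: the union of a precursor's windows is
extended

* down 1 Th in m/z (the monoisotopic peak may sit below the window),
* by the window's scan breadth on both sides in mobility (so the mobility
  apex can be determined), and
* forward and back in retention time by the user-specified base peak
  width (so the chromatographic apex can be determined),

yielding a cuboid in m/z x scan x RT.  Point extraction from a cuboid is
closed on all three axes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .raw_model import ISOLATION_WINDOW_SCHEMA, PipelineConfig

CUBOID_COLUMNS = [
    "precursor_id",
    "mz_lower",
    "mz_upper",
    "scan_lower",
    "scan_upper",
    "rt_lower",
    "rt_upper",
    "source_window_count",
]


@dataclass(frozen=True)
class PrecursorCuboid:
    """An m/z x scan x RT search region seeded from isolation windows."""

    precursor_id: int
    mz_lower: float
    mz_upper: float
    scan_lower: int
    scan_upper: int
    rt_lower: float
    rt_upper: float
    source_window_count: int

    def __post_init__(self) -> None:
        if not (
            self.mz_lower < self.mz_upper
            and self.scan_lower < self.scan_upper
            and self.rt_lower < self.rt_upper
        ):
            raise ValueError("cuboid bounds must satisfy lower < upper on every axis")


def group_windows(windows: pd.DataFrame) -> dict[int, pd.DataFrame]:
    """Group isolation windows by precursor id; every window lands in
    exactly one group."""
    if windows.empty:
        return {}
    return {
        int(pid): grp.reset_index(drop=True)
        for pid, grp in windows.groupby("precursor_id", sort=True)
    }


def build_cuboid(
    group: pd.DataFrame,
    config: PipelineConfig,
    frame_rt: Mapping[int, float],
) -> PrecursorCuboid:
    """Build the search cuboid for one precursor's window group.

    With U the union bounds of the group's windows and B its scan
    breadth: m/z extends down by ``mono_mz_extension``; scans extend by B
    on both sides (floored at 0); RT spans the windows' frame times
    +/- ``base_peak_width`` (floored at 0).
    """
    if group.empty:
        raise ValueError("cannot build a cuboid from an empty window group")
    ids = group["precursor_id"].unique()
    if len(ids) > 1:
        raise ValueError(f"window group mixes precursor ids: {sorted(ids)}")

    mz_lower = float(group["mz_lower"].min())
    mz_upper = float(group["mz_upper"].max())
    scan_lower = int(group["scan_begin"].min())
    scan_upper = int(group["scan_end"].max())
    breadth = scan_upper - scan_lower

    rts = [frame_rt[int(f)] for f in group["frame_id"]]

    mz_lo = mz_lower - config.mono_mz_extension
    mz_hi = mz_upper + (config.mono_mz_extension if config.extend_mz_both_sides else 0.0)
    return PrecursorCuboid(
        precursor_id=int(ids[0]),
        mz_lower=mz_lo,
        mz_upper=mz_hi,
        scan_lower=max(0, scan_lower - breadth),
        scan_upper=scan_upper + breadth,
        rt_lower=max(0.0, min(rts) - config.base_peak_width),
        rt_upper=max(rts) + config.base_peak_width,
        source_window_count=len(group),
    )


def seed_cuboids(
    windows: pd.DataFrame,
    config: PipelineConfig,
    frame_rt: Mapping[int, float],
) -> list[PrecursorCuboid]:
    """Build one cuboid per precursor id, ordered by precursor id."""
    return [
        build_cuboid(grp, config, frame_rt) for _, grp in sorted(group_windows(windows).items())
    ]


def cuboids_to_frame(cuboids: list[PrecursorCuboid]) -> pd.DataFrame:
    return pd.DataFrame([c.__dict__ for c in cuboids], columns=CUBOID_COLUMNS)


def cuboids_from_frame(df: pd.DataFrame) -> list[PrecursorCuboid]:
    return [
        PrecursorCuboid(
            precursor_id=int(r.precursor_id),
            mz_lower=float(r.mz_lower),
            mz_upper=float(r.mz_upper),
            scan_lower=int(r.scan_lower),
            scan_upper=int(r.scan_upper),
            rt_lower=float(r.rt_lower),
            rt_upper=float(r.rt_upper),
            source_window_count=int(r.source_window_count),
        )
        for r in df.itertuples()
    ]


def extract_cuboid_points(cuboid: PrecursorCuboid, points: pd.DataFrame) -> pd.DataFrame:
    """Points inside the cuboid; closed intervals on all three axes."""
    m = (
        (points["mz"].to_numpy() >= cuboid.mz_lower)
        & (points["mz"].to_numpy() <= cuboid.mz_upper)
        & (points["scan"].to_numpy() >= cuboid.scan_lower)
        & (points["scan"].to_numpy() <= cuboid.scan_upper)
        & (points["retention_time"].to_numpy() >= cuboid.rt_lower)
        & (points["retention_time"].to_numpy() <= cuboid.rt_upper)
    )
    return points.loc[m].reset_index(drop=True)
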