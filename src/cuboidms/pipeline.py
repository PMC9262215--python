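"""End-to-end orchestration: seed -> detect -> ms2 -> MGF.

Stages communicate in memory here; the CLI wraps each stage with the
file-based table interfaces from :mod:`cuboidms.raw_model`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cuboid_seeding import PrecursorCuboid, seed_cuboids
from .feature_resolve import Feature, detect_features
from .isotope_model import AveragineRatioModel, IsotopeRatioModel
from .ms2_pipeline import (
    FragmentIon,
    fragments_for_feature,
    generate_mass_defect_windows,
    render_mgf,
)
from .raw_model import PipelineConfig, PointCloud


@dataclass
class PipelineResult:
    cuboids: list[PrecursorCuboid]
    features: list[Feature]
    fragments: list[list[FragmentIon]]  # parallel to features
    mgf_filtered: Path | None = None
    mgf_unfiltered: Path | None = None

    def top_feature_per_precursor(self) -> dict[int, Feature]:
        """Highest-scoring feature for each precursor id."""
        best: dict[int, Feature] = {}
        for f in self.features:
            cur = best.get(f.precursor_id)
            if cur is None or f.envelope_score > cur.envelope_score:
                best[f.precursor_id] = f
        return best


def run_pipeline(
    points: PointCloud,
    isolation_windows: pd.DataFrame,
    config: PipelineConfig,
    model: IsotopeRatioModel | None = None,
    out_dir: str | Path | None = None,
    apply_saturation_correction: bool = True,
    apply_mass_defect_filter: bool = True,
) -> PipelineResult:
    """Run seeding, feature detection and MS2 processing on one run.

    When ``out_dir`` is given, filtered and unfiltered MGF files are
    written there (the filtered one only if the filter is enabled).
    """
    if model is None:
        model = AveragineRatioModel()
    frame_rt = points.frame_rt()
    cuboids = seed_cuboids(isolation_windows, config, frame_rt)
    features = detect_features(
        cuboids, points.ms1, config, model, apply_saturation_correction
    )
    windows = generate_mass_defect_windows(
        config.mass_defect_window_da_min, config.mass_defect_window_da_max
    )
    fragments = [
        fragments_for_feature(f, points.ms2, config, model, windows) for f in features
    ]
    result = PipelineResult(cuboids=cuboids, features=features, fragments=fragments)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        unfiltered = out_dir / "features.unfiltered.mgf"
        render_mgf(features, fragments, unfiltered, filtered=False)
        result.mgf_unfiltered = unfiltered
        if apply_mass_defect_filter:
            filtered = out_dir / "features.filtered.mgf"
            render_mgf(features, fragments, filtered, filtered=True)
            result.mgf_filtered = filtered
    return result
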