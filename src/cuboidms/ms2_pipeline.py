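"""MS2 extraction, fragment deconvolution, mass-defect filtering and MGF.

For each detected feature, the MS2 points inside the fragmentation
event's mobility and retention-time bounds are extracted (no m/z bounds:
a fragment may sit below or above its precursor), simplified with
intensity descent, and deconvolved with MS2-appropriate settings into
fragment neutral masses.

Tryptic-peptide masses cluster on the line ``mass ~ 1.00048 * nominal``
with narrow spread; the gaps between these mass-defect windows are
"forbidden zones" where peptide fragments cannot fall, so ions found
there are chemical or electrical noise and are removed.  The window for
nominal mass N is centred at ``N * 1.00048`` with width
``0.19 + 0.0001 * N`` (closed bounds).

Surviving fragments are written to MGF as singly protonated m/z values
(neutral mass + 1.00727647 Da).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from pyteomics import mgf as _mgf

from .feature_resolve import Feature, deconvolve_peaks
from .isotope_model import IsotopeRatioModel
from .raw_model import PipelineConfig
from .spectra_simplify import intensity_descent

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MassDefectWindow:
    """The allowed neutral-mass band around one nominal (integer) mass."""

    nominal_mass: int
    lower_mass: float
    upper_mass: float


@dataclass(frozen=True)
class FragmentIon:
    """A deconvolved MS2 ion as a neutral mass plus intensity."""

    neutral_mass: float
    singly_protonated_mz: float
    intensity: float
    kept: bool = True
    window_index: int | None = None


def extract_ms2_points(ms2_points: pd.DataFrame, feature: Feature) -> pd.DataFrame:
    """MS2 points within the feature's scan and RT extents (closed
    intervals); the full m/z range is retained."""
    m = (
        (ms2_points["scan"].to_numpy() >= feature.scan_lower)
        & (ms2_points["scan"].to_numpy() <= feature.scan_upper)
        & (ms2_points["retention_time"].to_numpy() >= feature.rt_lower)
        & (ms2_points["retention_time"].to_numpy() <= feature.rt_upper)
    )
    return ms2_points.loc[m].reset_index(drop=True)


def deconvolve_ms2(
    peaks: pd.DataFrame, config: PipelineConfig, model: IsotopeRatioModel
) -> list[FragmentIon]:
    """Deconvolve a simplified MS2 spectrum into fragment neutral masses.

    Same engine as the MS1 deconvolution, with MS2 settings (charges
    ``ms2_charge_min..ms2_charge_max``, lower score threshold).  The
    intensity of a fragment is its envelope sum.
    """
    candidates = deconvolve_peaks(
        peaks,
        config,
        model,
        charge_min=config.ms2_charge_min,
        charge_max=config.ms2_charge_max,
        score_threshold=config.ms2_envelope_score_threshold,
        max_candidates=config.ms2_max_fragments,
    )
    fragments = []
    for cand in candidates:
        neutral = cand.charge * (cand.monoisotopic_mz - config.proton_mass)
        fragments.append(
            FragmentIon(
                neutral_mass=float(neutral),
                singly_protonated_mz=float(neutral + config.proton_mass),
                intensity=float(sum(cand.isotope_intensity)),
            )
        )
    fragments.sort(key=lambda f: f.neutral_mass)
    return fragments


def generate_mass_defect_windows(da_min: int, da_max: int) -> list[MassDefectWindow]:
    """One window per nominal mass in [da_min, da_max).

    centre = nominal * 1.00048; width = 0.19 + 0.0001 * nominal.
    """
    if not 0 < da_min < da_max:
        raise ValueError("require 0 < da_min < da_max")
    windows = []
    for nominal_mass in range(int(da_min), int(da_max)):
        mass_centre = nominal_mass * 1.00048
        width = 0.19 + (0.0001 * nominal_mass)
        windows.append(
            MassDefectWindow(
                nominal_mass=nominal_mass,
                lower_mass=mass_centre - width / 2,
                upper_mass=mass_centre + width / 2,
            )
        )
    return windows


def filter_by_mass_defect(
    fragments: Sequence[FragmentIon], windows: Sequence[MassDefectWindow]
) -> tuple[list[FragmentIon], int]:
    """Mark each fragment kept iff its neutral mass sits inside a window
    (closed bounds, binary search).  Returns the fragments and the
    number removed."""
    lowers = np.array([w.lower_mass for w in windows])
    uppers = np.array([w.upper_mass for w in windows])
    out = []
    removed = 0
    for frag in fragments:
        i = int(np.searchsorted(lowers, frag.neutral_mass, side="right")) - 1
        if 0 <= i < len(windows) and frag.neutral_mass <= uppers[i]:
            out.append(replace(frag, kept=True, window_index=i))
        else:
            out.append(replace(frag, kept=False, window_index=None))
            removed += 1
    return out, removed


def fragments_for_feature(
    feature: Feature,
    ms2_points: pd.DataFrame,
    config: PipelineConfig,
    model: IsotopeRatioModel,
    windows: Sequence[MassDefectWindow] | None = None,
) -> list[FragmentIon]:
    """Extract, simplify, deconvolve and (window-)annotate one feature's
    fragment ions."""
    points = extract_ms2_points(ms2_points, feature)
    if points.empty:
        return []
    peaks = intensity_descent(points, config.instrument_resolution)
    fragments = deconvolve_ms2(peaks, config, model)
    if windows is None:
        windows = generate_mass_defect_windows(
            config.mass_defect_window_da_min, config.mass_defect_window_da_max
        )
    fragments, _ = filter_by_mass_defect(fragments, windows)
    return fragments


def render_mgf(
    features: Sequence[Feature],
    fragments_per_feature: Sequence[Sequence[FragmentIon]],
    path,
    filtered: bool,
) -> None:
    """Write one BEGIN IONS block per feature.

    PEPMASS carries the monoisotopic m/z and the feature intensity;
    CHARGE the charge state; RTINSECONDS the RT apex; TITLE encodes the
    precursor id, scan apex, 1/K0 and apex frame.  With ``filtered``
    True only fragments inside a mass-defect window are written.
    Features without a valid charge are skipped with a warning.
    """
    spectra = []
    for feature, fragments in zip(features, fragments_per_feature):
        if not feature.charge or feature.charge < 1:
            logger.warning(
                "skipping precursor %s: no charge determined", feature.precursor_id
            )
            continue
        frags = [f for f in fragments if f.kept] if filtered else list(fragments)
        frags.sort(key=lambda f: f.singly_protonated_mz)
        spectra.append(
            {
                "m/z array": np.array([f.singly_protonated_mz for f in frags]),
                "intensity array": np.array([f.intensity for f in frags]),
                "params": {
                    "title": (
                        f"precursor={feature.precursor_id} scan={feature.scan_apex} "
                        f"k0={feature.mobility_apex:.4f} frame={feature.apex_frame_id}"
                    ),
                    "pepmass": (feature.monoisotopic_mz, feature.feature_intensity),
                    "charge": f"{feature.charge}+",
                    "rtinseconds": feature.rt_apex,
                },
            }
        )
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    _mgf.write(spectra, output=str(path), file_mode="w")


def read_mgf(path) -> list[dict]:
    """Parse an MGF back into pyteomics spectrum dicts (round-trip aid)."""
    with _mgf.read(str(path)) as reader:
        return list(reader)
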