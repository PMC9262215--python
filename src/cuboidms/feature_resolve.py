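"""Resolve a cuboid's simplified spectrum into scored peptide features.

Candidate isotopic series are proposed from every simplified peak and
every charge state in range: peaks are gathered at the expected spacings
``mono_mz + i * 1.00335483 / z`` within a resolution-derived tolerance,
and the observed intensity series is scored against the theoretical
envelope for the implied mass (cosine similarity, with a 0.5 penalty per
expected-but-missing isotope among the first three).  A candidate whose
seed has a plausible isotopic neighbour one spacing *below* it is
suppressed: the seed is then unlikely to be the monoisotopic peak.

For each accepted candidate the monoisotopic peak's points (m/z within
+/- 3 sigma of the peak) are collapsed to the mobility and then the
retention-time dimension; each profile is smoothed with a Savitzky-Golay
filter and the apex and flanking valleys give the feature's extent.
Isotope intensities follow the three-point rule: the most intense point
in the apex frame plus the most intense point in the frame on either
side.  The feature's intensity is the sum of its first three isotope
intensities.  When the monoisotopic peak contains saturated readings, its
intensity is re-inferred from the nearest unsaturated isotope by chaining
theoretical peak-height ratios downward.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.signal import find_peaks, savgol_filter

from .isotope_model import (
    IsotopeModelRangeError,
    IsotopeRatioModel,
    scoring_envelope,
)
from .raw_model import ISOTOPE_SPACING, PipelineConfig
from .spectra_simplify import calculate_peak_delta
from .cuboid_seeding import PrecursorCuboid, extract_cuboid_points

UNCORRECTABLE_ALL_SATURATED = "uncorrectable: all isotopes saturated"
UNCORRECTABLE_MODEL_RANGE = "uncorrectable: outside model range"


@dataclass(frozen=True)
class EnvelopeCandidate:
    """A proposed isotopic series: charge, envelope and its fit score."""

    charge: int
    monoisotopic_mz: float
    monoisotopic_mass: float
    isotope_mz: tuple[float, ...]
    isotope_intensity: tuple[float, ...]
    peak_indices: tuple[int, ...]
    score: float


@dataclass(frozen=True)
class Extent:
    apex: float
    lower: float
    upper: float
    degenerate: bool = False


@dataclass(frozen=True)
class IsotopeMeasurement:
    """Three-point-rule intensity of one isotope plus its contributors."""

    intensity: float
    contributing: tuple[float, float, float]  # prev frame, apex frame, next frame

    def saturated(self, threshold: float) -> bool:
        return any(c >= threshold for c in self.contributing if c > 0)


@dataclass
class Feature:
    """A deconvolved peptide feature and everything the MGF header needs."""

    precursor_id: int
    charge: int
    monoisotopic_mz: float
    monoisotopic_mass: float
    envelope: list[tuple[float, float]]
    envelope_score: float
    scan_apex: int
    scan_lower: int
    scan_upper: int
    rt_apex: float
    rt_lower: float
    rt_upper: float
    isotope_intensities: list[float]
    feature_intensity: float
    mono_fit_r2: float
    saturated: bool = False
    saturation_flags: list[bool] = field(default_factory=list)
    inference_isotope_index: int | None = None
    corrected_mono_intensity: float | None = None
    correction_note: str | None = None
    apex_frame_id: int = -1
    mobility_apex: float = float("nan")
    extent_degenerate: bool = False


FEATURE_COLUMNS = [
    "precursor_id", "charge", "monoisotopic_mz", "monoisotopic_mass",
    "envelope", "envelope_score", "scan_apex", "scan_lower", "scan_upper",
    "rt_apex", "rt_lower", "rt_upper", "isotope_intensities",
    "feature_intensity", "mono_fit_r2", "saturated", "saturation_flags",
    "inference_isotope_index", "corrected_mono_intensity", "correction_note",
    "apex_frame_id", "mobility_apex", "extent_degenerate",
]


def _cosine(a: np.ndarray, b: np.ndarray) -> float:
    na = float(np.linalg.norm(a))
    nb = float(np.linalg.norm(b))
    if na == 0 or nb == 0:
        return 0.0
    return float(np.dot(a, b) / (na * nb))


def score_envelope_fit(
    observed: Sequence[float], monoisotopic_mass: float, model: IsotopeRatioModel
) -> float:
    """Cosine similarity of the observed series to the theoretical
    envelope (truncated to observed length), times 0.5 per
    expected-but-missing isotope among the first three."""
    obs = np.asarray(observed, dtype=float)
    theo = np.asarray(scoring_envelope(monoisotopic_mass, len(obs), model))
    missing = max(0, 3 - len(obs))
    return _cosine(obs, theo) * (0.5 ** missing)


def deconvolve_peaks(
    peaks: pd.DataFrame,
    config: PipelineConfig,
    model: IsotopeRatioModel,
    charge_min: int | None = None,
    charge_max: int | None = None,
    score_threshold: float | None = None,
    max_candidates: int | None = None,
) -> list[EnvelopeCandidate]:
    """Propose scored isotopic-series candidates from a simplified spectrum.

    Candidates are ranked by (score desc, mono m/z asc, charge asc);
    overlapping candidates are allowed.  Empty input yields an empty list.
    """
    charge_min = config.charge_min if charge_min is None else charge_min
    charge_max = config.charge_max if charge_max is None else charge_max
    threshold = config.envelope_score_threshold if score_threshold is None else score_threshold
    if peaks.empty:
        return []

    mz = peaks["mz_centroid"].to_numpy(dtype=float)
    inten = peaks["intensity"].to_numpy(dtype=float)
    order = np.argsort(mz, kind="stable")
    mz, inten = mz[order], inten[order]
    res = config.instrument_resolution

    def best_in_window(target: float, tol: float) -> int | None:
        lo = np.searchsorted(mz, target - tol, side="left")
        hi = np.searchsorted(mz, target + tol, side="right")
        if hi <= lo:
            return None
        return int(lo + np.argmax(inten[lo:hi]))

    candidates: list[EnvelopeCandidate] = []
    for seed in range(mz.size):
        for z in range(charge_min, charge_max + 1):
            spacing = ISOTOPE_SPACING / z
            # a credible isotopic neighbour below the seed means the seed
            # is not the monoisotopic peak of this series
            left = best_in_window(mz[seed] - spacing, calculate_peak_delta(mz[seed] - spacing, res))
            if left is not None and inten[left] >= config.left_peak_min_ratio * inten[seed]:
                continue
            members = [seed]
            for i in range(1, config.max_isotopes):
                target = mz[seed] + i * spacing
                j = best_in_window(target, calculate_peak_delta(target, res))
                if j is None:
                    break
                members.append(j)
            if len(members) < config.min_isotopes:
                continue
            mass = z * (mz[seed] - config.proton_mass)
            if mass <= 0:
                continue
            score = score_envelope_fit(inten[members], mass, model)
            if score < threshold:
                continue
            candidates.append(
                EnvelopeCandidate(
                    charge=z,
                    monoisotopic_mz=float(mz[seed]),
                    monoisotopic_mass=float(mass),
                    isotope_mz=tuple(float(m) for m in mz[members]),
                    isotope_intensity=tuple(float(v) for v in inten[members]),
                    peak_indices=tuple(members),
                    score=float(score),
                )
            )

    candidates.sort(key=lambda c: (-c.score, c.monoisotopic_mz, c.charge))
    limit = config.max_features_per_cuboid if max_candidates is None else max_candidates
    return candidates[:limit] if limit is not None else candidates


def deconvolve_ms1(
    peaks: pd.DataFrame, config: PipelineConfig, model: IsotopeRatioModel
) -> list[EnvelopeCandidate]:
    return deconvolve_peaks(peaks, config, model)


def resolve_extent(coords, intensities, center_hint: float) -> Extent:
    """Apex and flanking-valley extent of a 1D flattened profile.

    Points are summed per distinct coordinate (scan number or frame RT),
    smoothed with a Savitzky-Golay filter, and the local maximum nearest
    ``center_hint`` is taken as the apex; the nearest local minimum on
    each side (or the data boundary) bounds the extent.  Fewer than three
    distinct coordinates give a degenerate extent.
    """
    coords = np.asarray(coords, dtype=float)
    intensities = np.asarray(intensities, dtype=float)
    if coords.size == 0:
        raise ValueError("cannot resolve extent of an empty profile")
    uniq, inverse = np.unique(coords, return_inverse=True)
    sums = np.zeros(uniq.size)
    np.add.at(sums, inverse, intensities)

    if uniq.size < 3 or np.all(sums == sums[0]):
        apex = float(uniq[int(np.argmax(sums))])
        return Extent(apex=apex, lower=float(uniq[0]), upper=float(uniq[-1]), degenerate=True)

    window = min(9, uniq.size if uniq.size % 2 == 1 else uniq.size - 1)
    polyorder = min(3, window - 1)
    smoothed = savgol_filter(sums, window, polyorder)

    maxima, _ = find_peaks(smoothed)
    if maxima.size == 0:
        maxima = np.array([int(np.argmax(smoothed))])
    apex_i = int(maxima[np.argmin(np.abs(uniq[maxima] - center_hint))])

    minima, _ = find_peaks(-smoothed)
    left = minima[minima < apex_i]
    right = minima[minima > apex_i]
    lo_i = int(left.max()) if left.size else 0
    hi_i = int(right.min()) if right.size else uniq.size - 1
    return Extent(
        apex=float(uniq[apex_i]), lower=float(uniq[lo_i]), upper=float(uniq[hi_i])
    )


def isotope_intensity(
    points: pd.DataFrame,
    apex_frame: int,
    frame_order: Sequence[int] | None = None,
) -> IsotopeMeasurement:
    """Three-point-rule isotope intensity.

    Sums the most intense point in the apex frame and the most intense
    point in the frame on either side; a missing neighbour contributes 0.
    ``frame_order`` is the sorted sequence of frames at this MS level; when
    omitted, neighbours default to ``apex_frame +/- 1``.
    """
    if points.empty:
        return IsotopeMeasurement(0.0, (0.0, 0.0, 0.0))
    per_frame = points.groupby("frame_id")["intensity"].max()

    if frame_order is not None:
        frame_order = np.asarray(frame_order)
        pos = int(np.searchsorted(frame_order, apex_frame))
        prev_f = int(frame_order[pos - 1]) if pos > 0 else None
        next_f = (
            int(frame_order[pos + 1]) if pos + 1 < frame_order.size else None
        )
    else:
        prev_f, next_f = apex_frame - 1, apex_frame + 1

    def frame_max(f) -> float:
        if f is None:
            return 0.0
        return float(per_frame.get(f, 0.0))

    contributing = (frame_max(prev_f), frame_max(apex_frame), frame_max(next_f))
    return IsotopeMeasurement(float(sum(contributing)), contributing)


def feature_intensity(isotope_intensities: Sequence[float]) -> float:
    """Sum of the first (up to) three isotope intensities."""
    return float(sum(isotope_intensities[:3]))


def _gaussian(x, amplitude, mean, sigma):
    return amplitude * np.exp(-0.5 * ((x - mean) / sigma) ** 2)


def gaussian_fit_r2(mz, intensity) -> tuple[float, bool]:
    """R-squared of a Gaussian least-squares fit to a peak's m/z profile.

    Returns ``(r2, ok)``; failures (too few points, non-convergence,
    degenerate spread) give ``(0.0, False)``.  R-squared is clamped to
    [0, 1].
    """
    mz = np.asarray(mz, dtype=float)
    intensity = np.asarray(intensity, dtype=float)
    if mz.size < 4 or np.ptp(mz) == 0:
        return 0.0, False
    total = intensity.sum()
    mean0 = float(np.dot(mz, intensity) / total)
    sigma0 = float(np.sqrt(np.dot((mz - mean0) ** 2, intensity) / total)) or np.ptp(mz) / 4
    try:
        popt, _ = curve_fit(
            _gaussian,
            mz,
            intensity,
            p0=(float(intensity.max()), mean0, sigma0),
            maxfev=5000,
        )
    except (RuntimeError, ValueError):
        return 0.0, False
    residuals = intensity - _gaussian(mz, *popt)
    ss_res = float(np.sum(residuals**2))
    ss_tot = float(np.sum((intensity - intensity.mean()) ** 2))
    if ss_tot == 0:
        return 0.0, False
    return float(min(1.0, max(0.0, 1.0 - ss_res / ss_tot))), True


def correct_saturation(
    feature: Feature, model: IsotopeRatioModel, threshold: float
) -> Feature:
    """Re-infer the monoisotopic intensity when its readings are saturated.

    If the monoisotopic isotope is unsaturated the feature is returned
    unchanged.  Otherwise the nearest unsaturated isotope k anchors a
    backward chain ``I[i] = I[i+1] / ratio(mass, i)`` down to isotope 0.
    Uncorrectable states (every isotope saturated, or the mass outside
    the ratio model's valid range) are flagged, never raised.
    """
    flags = list(feature.saturation_flags)
    if not flags or not flags[0]:
        return dataclasses.replace(
            feature, saturated=False, inference_isotope_index=None,
            corrected_mono_intensity=None, correction_note=None,
        )
    unsaturated = [i for i, f in enumerate(flags) if not f]
    if not unsaturated:
        return dataclasses.replace(
            feature, saturated=True, inference_isotope_index=None,
            corrected_mono_intensity=None, correction_note=UNCORRECTABLE_ALL_SATURATED,
        )
    k = unsaturated[0]
    value = feature.isotope_intensities[k]
    try:
        for i in range(k - 1, -1, -1):
            value = value / model.ratio(feature.monoisotopic_mass, i)
    except IsotopeModelRangeError:
        return dataclasses.replace(
            feature, saturated=True, inference_isotope_index=None,
            corrected_mono_intensity=None, correction_note=UNCORRECTABLE_MODEL_RANGE,
        )
    return dataclasses.replace(
        feature, saturated=True, inference_isotope_index=k,
        corrected_mono_intensity=float(value), correction_note=None,
    )


def resolve_features(
    cuboid: PrecursorCuboid,
    ms1_points: pd.DataFrame,
    config: PipelineConfig,
    model: IsotopeRatioModel,
    ms1_frame_order: Sequence[int] | None = None,
    apply_saturation_correction: bool = True,
) -> list[Feature]:
    """Full per-cuboid feature resolution: simplify, deconvolve, extents,
    isotope intensities, Gaussian fit, saturation correction."""
    from .spectra_simplify import intensity_descent  # local to avoid cycle at import

    points = extract_cuboid_points(cuboid, ms1_points)
    if points.empty:
        return []
    peaks = intensity_descent(points, config.instrument_resolution)
    candidates = deconvolve_ms1(peaks, config, model)

    features: list[Feature] = []
    for cand in candidates:
        delta0 = calculate_peak_delta(cand.monoisotopic_mz, config.instrument_resolution)
        mono_band = points[
            (points["mz"] >= cand.monoisotopic_mz - delta0)
            & (points["mz"] <= cand.monoisotopic_mz + delta0)
        ]
        if mono_band.empty:
            continue
        scan_hint = 0.5 * (cuboid.scan_lower + cuboid.scan_upper)
        scan_ext = resolve_extent(mono_band["scan"], mono_band["intensity"], scan_hint)
        band_scan = mono_band[
            (mono_band["scan"] >= scan_ext.lower) & (mono_band["scan"] <= scan_ext.upper)
        ]
        rt_hint = 0.5 * (cuboid.rt_lower + cuboid.rt_upper)
        rt_ext = resolve_extent(
            band_scan["retention_time"], band_scan["intensity"], rt_hint
        )
        apex_rows = band_scan[band_scan["retention_time"] == rt_ext.apex]
        apex_frame = int(apex_rows["frame_id"].iloc[0]) if not apex_rows.empty else -1

        measurements: list[IsotopeMeasurement] = []
        for iso_mz in cand.isotope_mz:
            delta = calculate_peak_delta(iso_mz, config.instrument_resolution)
            band = points[
                (points["mz"] >= iso_mz - delta)
                & (points["mz"] <= iso_mz + delta)
                & (points["scan"] >= scan_ext.lower)
                & (points["scan"] <= scan_ext.upper)
                & (points["retention_time"] >= rt_ext.lower)
                & (points["retention_time"] <= rt_ext.upper)
            ]
            measurements.append(isotope_intensity(band, apex_frame, ms1_frame_order))

        iso_intensities = [m.intensity for m in measurements]
        sat_flags = [m.saturated(config.saturation_threshold) for m in measurements]
        r2, _ = gaussian_fit_r2(mono_band["mz"], mono_band["intensity"])

        scan_apex_rows = band_scan[band_scan["scan"] == int(scan_ext.apex)]
        mobility = (
            float(scan_apex_rows["mobility"].mean()) if not scan_apex_rows.empty else float("nan")
        )
        feature = Feature(
            precursor_id=cuboid.precursor_id,
            charge=cand.charge,
            monoisotopic_mz=cand.monoisotopic_mz,
            monoisotopic_mass=cand.monoisotopic_mass,
            envelope=list(zip(cand.isotope_mz, cand.isotope_intensity)),
            envelope_score=cand.score,
            scan_apex=int(scan_ext.apex),
            scan_lower=int(scan_ext.lower),
            scan_upper=int(scan_ext.upper),
            rt_apex=float(rt_ext.apex),
            rt_lower=float(rt_ext.lower),
            rt_upper=float(rt_ext.upper),
            isotope_intensities=iso_intensities,
            feature_intensity=feature_intensity(iso_intensities),
            mono_fit_r2=r2,
            saturation_flags=sat_flags,
            apex_frame_id=apex_frame,
            mobility_apex=mobility,
            extent_degenerate=scan_ext.degenerate or rt_ext.degenerate,
        )
        if apply_saturation_correction:
            feature = correct_saturation(feature, model, config.saturation_threshold)
        else:
            feature.saturated = bool(sat_flags and sat_flags[0])
        features.append(feature)
    return features


def detect_features(
    cuboids: Sequence[PrecursorCuboid],
    ms1_points: pd.DataFrame,
    config: PipelineConfig,
    model: IsotopeRatioModel,
    apply_saturation_correction: bool = True,
) -> list[Feature]:
    frame_order = np.sort(ms1_points["frame_id"].unique())
    out: list[Feature] = []
    for cuboid in cuboids:
        out.extend(
            resolve_features(
                cuboid, ms1_points, config, model, frame_order, apply_saturation_correction
            )
        )
    return out


def features_to_frame(features: Sequence[Feature]) -> pd.DataFrame:
    """Feature table for file-based stage interfaces; list-valued fields
    are JSON encoded."""
    rows = []
    for f in features:
        d = dataclasses.asdict(f)
        d["envelope"] = json.dumps(d["envelope"])
        d["isotope_intensities"] = json.dumps(d["isotope_intensities"])
        d["saturation_flags"] = json.dumps(d["saturation_flags"])
        rows.append(d)
    return pd.DataFrame(rows, columns=FEATURE_COLUMNS)


def features_from_frame(df: pd.DataFrame) -> list[Feature]:
    out = []
    for r in df.to_dict("records"):
        r["envelope"] = [tuple(p) for p in json.loads(r["envelope"])]
        r["isotope_intensities"] = json.loads(r["isotope_intensities"])
        r["saturation_flags"] = json.loads(r["saturation_flags"])
        if pd.isna(r["inference_isotope_index"]):
            r["inference_isotope_index"] = None
        else:
            r["inference_isotope_index"] = int(r["inference_isotope_index"])
        if pd.isna(r["corrected_mono_intensity"]):
            r["corrected_mono_intensity"] = None
        if r["correction_note"] is None or (
            isinstance(r["correction_note"], float) and pd.isna(r["correction_note"])
        ):
            r["correction_note"] = None
        out.append(Feature(**r))
    return out
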