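"""Synthetic timsTOF-style 4D point clouds with ground truth.

The generator emulates the statistical structure the pipeline assumes: a
DDA run is a sequence of acquisition cycles, each with one MS1 frame and
a few PASEF-style MS2 frames.  Every simulated peptide contributes, per
isotope, a cloud of raw points whose m/z values are Gaussian around the
isotope m/z with sigma = (mz / resolution) / 2.35482 and whose per-scan /
per-frame intensities follow Gaussian elution and mobility profiles.
Isotope abundances come from the shared isotope-ratio model (tests that
must be model independent inject a stub).  Detector saturation is
emulated by clipping point intensities at the saturation threshold; the
instrument's firmware extrapolation is deliberately not modelled.

MS2 fragments are b/y-type ladders of random tryptic-like sequences
(cumulative sums over the 20 monoisotopic residue masses), so fragment
masses carry the true peptide mass-defect structure.  MS2 noise is
uniform in frame, scan and m/z, with a configurable fraction forced into
the gaps between mass-defect windows, and a configurable fraction
emitted as two-isotope doublets so that some noise survives the
minimum-two-isotopes deconvolution rule and the filter's effect stays
measurable end to end.

Ground truth (peptides, per-isotope true intensities under the
three-point rule before clipping, fragment masses and their window
membership) is returned as tables sufficient to score every downstream
recovery test.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .isotope_model import AveragineRatioModel, IsotopeRatioModel, scoring_envelope
from .ms2_pipeline import generate_mass_defect_windows
from .raw_model import (
    ISOLATION_WINDOW_SCHEMA,
    ISOTOPE_SPACING,
    POINT_SCHEMA,
    PROTON_MASS,
    _empty_table,
)

#: Monoisotopic residue masses of the 20 standard amino acids.
RESIDUE_MASSES: dict[str, float] = {
    "G": 57.02146, "A": 71.03711, "S": 87.03203, "P": 97.05276,
    "V": 99.06841, "T": 101.04768, "C": 103.00919, "L": 113.08406,
    "I": 113.08406, "N": 114.04293, "D": 115.02694, "Q": 128.05858,
    "K": 128.09496, "E": 129.04259, "M": 131.04049, "H": 137.05891,
    "F": 147.06841, "R": 156.10111, "Y": 163.06333, "W": 186.07931,
}

WATER_MASS = 18.010564684


class SimulationConfigError(ValueError):
    pass


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic run.

    Peptide-level parameters mirror a short-gradient timsTOF acquisition
    at desk scale: a 240 s run of 1 s cycles (one MS1 + three MS2 frames),
    300 mobility scans per frame, chromatographic peaks of a few seconds,
    apex intensities log-uniform over ~2.5 orders of magnitude so that a
    realistic share of monoisotopic peaks saturates at the 3000-count
    threshold.  Noise rates are placeholders: the instrument's noise
    statistics are not publicly characterised.
    """

    n_peptides: int = 200
    mass_min: float = 800.0
    mass_max: float = 3200.0
    charges: tuple[int, ...] = (1, 2, 3, 4)
    charge_weights: tuple[float, ...] = (0.05, 0.55, 0.30, 0.10)
    run_duration: float = 240.0  # seconds
    cycle_time: float = 1.0  # seconds per MS1+MS2 cycle
    ms2_frames_per_cycle: int = 3
    scans_per_frame: int = 300
    mobility_low_scan: float = 1.30  # 1/K0 at scan 0
    mobility_high_scan: float = 0.85  # 1/K0 at the last scan
    rt_sigma_range: tuple[float, float] = (1.8, 3.2)  # seconds
    scan_sigma_range: tuple[float, float] = (4.0, 8.0)  # scans
    log10_apex_intensity_range: tuple[float, float] = (2.9, 5.4)
    n_isotopes: int = 6
    intensity_cv: float = 0.05  # multiplicative point-level noise
    min_point_intensity: float = 1.0
    profile_sigma_span: float = 3.0
    n_fragmentation_events: int = 4
    ms2_intensity_fraction: float = 0.3
    sequence_residues: str = "".join(RESIDUE_MASSES)  # uniform draw
    ms1_noise_per_frame: float = 30.0
    ms2_noise_per_frame: float = 60.0
    noise_intensity_scale: float = 150.0  # exponential scale, counts
    ms2_noise_outside_window_fraction: float = 0.5
    ms2_noise_doublet_fraction: float = 0.3
    clip: bool = True
    saturation_threshold: float = 3000.0
    instrument_resolution: float = 40000.0
    mz_noise_range: tuple[float, float] = (300.0, 1700.0)
    random_seed: int = 1

    def __post_init__(self) -> None:
        if self.scans_per_frame <= 0:
            raise SimulationConfigError("scans_per_frame must be > 0")
        if self.cycle_time <= 0 or self.run_duration <= 0:
            raise SimulationConfigError("run_duration and cycle_time must be > 0")
        if self.n_peptides < 0:
            raise SimulationConfigError("n_peptides must be >= 0")
        if len(self.charges) != len(self.charge_weights):
            raise SimulationConfigError("charges and charge_weights must align")
        if self.saturation_threshold <= 0:
            raise SimulationConfigError("saturation_threshold must be > 0")

    def replace(self, **kwargs) -> "SimulationConfig":
        return dataclasses.replace(self, **kwargs)


@dataclass(frozen=True)
class GroundTruthPeptide:
    monoisotopic_mass: float
    charge: int
    monoisotopic_mz: float
    rt_apex: float
    rt_sigma: float
    scan_apex: int
    scan_sigma: float
    apex_intensity: float
    envelope: tuple[float, ...]
    fragment_neutral_masses: tuple[float, ...]

    def __post_init__(self) -> None:
        expected = self.monoisotopic_mass / self.charge + PROTON_MASS
        if abs(self.monoisotopic_mz - expected) > 1e-6:
            raise ValueError("monoisotopic_mz inconsistent with mass and charge")
        if len(self.envelope) < 2 or any(a < 0 for a in self.envelope):
            raise ValueError("envelope needs >= 2 non-negative isotopes")


@dataclass
class SimulatedRun:
    """Point clouds, isolation windows and ground-truth tables."""

    ms1: pd.DataFrame
    ms2: pd.DataFrame
    isolation_windows: pd.DataFrame
    peptides: pd.DataFrame
    peptide_isotopes: pd.DataFrame
    fragments: pd.DataFrame
    config: SimulationConfig

    def all_points(self) -> pd.DataFrame:
        return pd.concat([self.ms1, self.ms2], ignore_index=True)


def clip_saturation(points: pd.DataFrame, threshold: float) -> pd.DataFrame:
    """Clip point intensities at the detector saturation threshold."""
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    out = points.copy()
    out["intensity"] = np.minimum(
        out["intensity"].to_numpy(), np.float32(threshold)
    ).astype(POINT_SCHEMA["intensity"])
    return out


def _mobility_of(scan: np.ndarray, cfg: SimulationConfig) -> np.ndarray:
    # explicit per-frame linear map scan -> 1/K0; low scan = high mobility
    span = cfg.mobility_high_scan - cfg.mobility_low_scan
    frac = scan / max(1, cfg.scans_per_frame - 1)
    return cfg.mobility_low_scan + frac * span


def _draw_sequence(rng: np.random.Generator, target_mass: float, cfg: SimulationConfig) -> str:
    residues = list(cfg.sequence_residues)
    seq: list[str] = []
    mass = WATER_MASS
    while mass < target_mass - RESIDUE_MASSES["G"]:
        aa = residues[int(rng.integers(0, len(residues)))]
        seq.append(aa)
        mass += RESIDUE_MASSES[aa]
    if len(seq) < 4:
        seq += ["A"] * (4 - len(seq))
    seq[-1] = "K" if rng.random() < 0.5 else "R"  # tryptic-like terminus
    return "".join(seq)


def _fragment_ladder(sequence: str) -> list[tuple[str, float]]:
    masses = np.array([RESIDUE_MASSES[a] for a in sequence])
    b = np.cumsum(masses)[:-1]
    y = np.cumsum(masses[::-1])[:-1] + WATER_MASS
    frags = [("b", float(m)) for m in b] + [("y", float(m)) for m in y]
    return [(t, m) for t, m in frags if m >= 120.0]


def _gauss(x: np.ndarray, mu: float, sigma: float) -> np.ndarray:
    return np.exp(-0.5 * ((x - mu) / sigma) ** 2)


def simulate_run(
    config: SimulationConfig, model: IsotopeRatioModel | None = None
) -> SimulatedRun:
    """Generate one synthetic run; byte-identical under a fixed seed."""
    cfg = config
    if model is None:
        model = AveragineRatioModel()
    rng = np.random.default_rng(cfg.random_seed)

    frames_per_cycle = 1 + cfg.ms2_frames_per_cycle
    frame_period = cfg.cycle_time / frames_per_cycle
    n_frames = int(cfg.run_duration / frame_period)
    frame_ids = np.arange(n_frames, dtype=int)
    frame_times = frame_ids * frame_period
    ms_level = np.where(frame_ids % frames_per_cycle == 0, 1, 2)
    ms1_frames = frame_ids[ms_level == 1]
    ms1_times = frame_times[ms_level == 1]
    ms2_frames = frame_ids[ms_level == 2]
    ms2_times = frame_times[ms_level == 2]

    windows_for_truth = generate_mass_defect_windows(100, 5000)
    win_lo = np.array([w.lower_mass for w in windows_for_truth])
    win_hi = np.array([w.upper_mass for w in windows_for_truth])

    def in_window(mass: float) -> bool:
        i = int(np.searchsorted(win_lo, mass, side="right")) - 1
        return 0 <= i < len(win_hi) and mass <= win_hi[i]

    ms1_parts: list[tuple] = []
    ms2_parts: list[tuple] = []
    window_rows: list[dict] = []
    peptide_rows: list[dict] = []
    isotope_rows: list[dict] = []
    fragment_rows: list[dict] = []

    rt_margin = 4 * cfg.rt_sigma_range[1]
    scan_margin = int(4 * cfg.scan_sigma_range[1])

    def emit_points(level, fids, times, scans, mzs, intensities):
        # multiplicative point-level noise, then the detection floor
        noise = np.exp(rng.normal(0.0, cfg.intensity_cv, size=intensities.size))
        inten = intensities * noise
        keep = inten >= cfg.min_point_intensity
        if not keep.any():
            return
        part = (
            np.asarray(fids)[keep],
            np.asarray(times)[keep],
            np.asarray(scans)[keep],
            np.asarray(mzs)[keep],
            inten[keep],
        )
        (ms1_parts if level == 1 else ms2_parts).append(part)

    for pid in range(cfg.n_peptides):
        target_mass = rng.uniform(cfg.mass_min, cfg.mass_max)
        sequence = _draw_sequence(rng, target_mass, cfg)
        mass = float(sum(RESIDUE_MASSES[a] for a in sequence) + WATER_MASS)
        z = int(rng.choice(cfg.charges, p=np.asarray(cfg.charge_weights) / sum(cfg.charge_weights)))
        mz0 = mass / z + PROTON_MASS
        rt_apex = float(rng.uniform(rt_margin, cfg.run_duration - rt_margin))
        rt_sigma = float(rng.uniform(*cfg.rt_sigma_range))
        scan_apex = int(rng.integers(scan_margin, cfg.scans_per_frame - scan_margin))
        scan_sigma = float(rng.uniform(*cfg.scan_sigma_range))
        apex = float(10.0 ** rng.uniform(*cfg.log10_apex_intensity_range))
        envelope = np.array(scoring_envelope(mass, cfg.n_isotopes, model))
        spacing = ISOTOPE_SPACING / z

        # --- MS1 isotope clouds -----------------------------------------
        span = cfg.profile_sigma_span
        f_sel = np.abs(ms1_times - rt_apex) <= span * rt_sigma
        pep_ms1_frames = ms1_frames[f_sel]
        pep_ms1_times = ms1_times[f_sel]
        g_rt = _gauss(pep_ms1_times, rt_apex, rt_sigma)
        scan_lo = max(0, int(np.floor(scan_apex - span * scan_sigma)))
        scan_hi = min(cfg.scans_per_frame - 1, int(np.ceil(scan_apex + span * scan_sigma)))
        pep_scans = np.arange(scan_lo, scan_hi + 1)
        g_scan = _gauss(pep_scans.astype(float), scan_apex, scan_sigma)

        # true three-point-rule intensity (noise-free, unclipped) at the
        # apex scan, for recovery scoring
        apex_pos = int(np.argmin(np.abs(ms1_times - rt_apex)))
        g_prev = _gauss(ms1_times[apex_pos - 1], rt_apex, rt_sigma) if apex_pos > 0 else 0.0
        g_here = _gauss(ms1_times[apex_pos], rt_apex, rt_sigma)
        g_next = (
            _gauss(ms1_times[apex_pos + 1], rt_apex, rt_sigma)
            if apex_pos + 1 < ms1_times.size
            else 0.0
        )
        g_scan_apex = float(_gauss(np.array([float(scan_apex)]), scan_apex, scan_sigma)[0])
        rule_factor = float(g_prev + g_here + g_next) * g_scan_apex

        for i in range(cfg.n_isotopes):
            iso_mz = mz0 + i * spacing
            cells = apex * envelope[i] * np.outer(g_rt, g_scan)
            fids = np.repeat(pep_ms1_frames, pep_scans.size)
            times = np.repeat(pep_ms1_times, pep_scans.size)
            scans = np.tile(pep_scans, pep_ms1_frames.size)
            sigma_mz = (iso_mz / cfg.instrument_resolution) / 2.35482
            mzs = rng.normal(iso_mz, sigma_mz, size=fids.size)
            emit_points(1, fids, times, scans, mzs, cells.ravel())
            isotope_rows.append(
                {
                    "peptide_id": pid,
                    "isotope": i,
                    "mz": iso_mz,
                    "relative_abundance": float(envelope[i]),
                    "true_rule_intensity": apex * float(envelope[i]) * rule_factor,
                }
            )

        # --- isolation windows / fragmentation events -------------------
        n_events = min(cfg.n_fragmentation_events, ms2_frames.size)
        event_order = np.argsort(np.abs(ms2_times - rt_apex), kind="stable")[:n_events]
        event_idx = np.sort(event_order)
        w_scan_lo = max(0, int(round(scan_apex - 2 * scan_sigma)))
        w_scan_hi = min(cfg.scans_per_frame - 1, int(round(scan_apex + 2 * scan_sigma)))
        for ei in event_idx:
            window_rows.append(
                {
                    "precursor_id": pid,
                    "frame_id": int(ms2_frames[ei]),
                    "mz_lower": mz0 - 2 * spacing,
                    "mz_upper": mz0 + 2 * spacing,
                    "scan_begin": w_scan_lo,
                    "scan_end": w_scan_hi,
                    "collision_energy": 30.0,
                }
            )

        # --- MS2 fragment points ----------------------------------------
        ladder = _fragment_ladder(sequence)
        frag_rel = rng.uniform(0.1, 1.0, size=len(ladder))
        ev_scans = np.arange(w_scan_lo, w_scan_hi + 1)
        g_ev_scan = _gauss(ev_scans.astype(float), scan_apex, scan_sigma)
        for k, ((ion_type, fmass), rel) in enumerate(zip(ladder, frag_rel)):
            frag_env = np.array(scoring_envelope(fmass, 2, model))
            frag_mz0 = fmass + PROTON_MASS  # singly charged fragments
            fragment_rows.append(
                {
                    "peptide_id": pid,
                    "fragment_index": k,
                    "ion_type": ion_type,
                    "neutral_mass": fmass,
                    "singly_protonated_mz": frag_mz0,
                    "relative_intensity": float(rel),
                    "in_mass_defect_window": in_window(fmass),
                }
            )
            for ei in event_idx:
                amp = (
                    cfg.ms2_intensity_fraction
                    * apex
                    * rel
                    * float(_gauss(np.array([ms2_times[ei]]), rt_apex, rt_sigma)[0])
                )
                if amp < cfg.min_point_intensity:
                    continue
                for iso in range(2):
                    cells = amp * frag_env[iso] * g_ev_scan
                    iso_mz = frag_mz0 + iso * ISOTOPE_SPACING
                    sigma_mz = (iso_mz / cfg.instrument_resolution) / 2.35482
                    mzs = rng.normal(iso_mz, sigma_mz, size=ev_scans.size)
                    emit_points(
                        2,
                        np.full(ev_scans.size, ms2_frames[ei]),
                        np.full(ev_scans.size, ms2_times[ei]),
                        ev_scans,
                        mzs,
                        cells,
                    )

        peptide_rows.append(
            {
                "peptide_id": pid,
                "sequence": sequence,
                "monoisotopic_mass": mass,
                "charge": z,
                "monoisotopic_mz": mz0,
                "rt_apex": rt_apex,
                "rt_sigma": rt_sigma,
                "scan_apex": scan_apex,
                "scan_sigma": scan_sigma,
                "apex_intensity": apex,
                "n_isotopes": cfg.n_isotopes,
            }
        )

    # --- noise ----------------------------------------------------------
    if cfg.ms1_noise_per_frame > 0 and ms1_frames.size:
        n_noise = int(rng.poisson(cfg.ms1_noise_per_frame * ms1_frames.size))
        pos = rng.integers(0, ms1_frames.size, size=n_noise)
        scans = rng.integers(0, cfg.scans_per_frame, size=n_noise)
        mzs = rng.uniform(*cfg.mz_noise_range, size=n_noise)
        inten = rng.exponential(cfg.noise_intensity_scale, size=n_noise) + 1.0
        emit_points(1, ms1_frames[pos], ms1_times[pos], scans, mzs, inten)

    if cfg.ms2_noise_per_frame > 0 and ms2_frames.size:
        n_noise = int(rng.poisson(cfg.ms2_noise_per_frame * ms2_frames.size))
        lo_mass, hi_mass = cfg.mz_noise_range
        pos = rng.integers(0, ms2_frames.size, size=n_noise)
        scans = rng.integers(0, cfg.scans_per_frame, size=n_noise)
        outside = rng.random(size=n_noise) < cfg.ms2_noise_outside_window_fraction
        nominal = rng.integers(int(lo_mass), int(hi_mass) - 1, size=n_noise)
        base = windows_for_truth[0].nominal_mass
        w_hi = win_hi[nominal - base]  # upper edge of own window
        w_lo = win_lo[nominal - base]
        w_next_lo = win_lo[nominal + 1 - base]
        u = rng.random(size=n_noise)
        mass = np.where(
            outside,
            (w_hi + 0.01) + u * (w_next_lo - w_hi - 0.02),  # in the gap
            w_lo + u * (w_hi - w_lo),  # inside a window
        )
        inten = rng.exponential(cfg.noise_intensity_scale, size=n_noise) + 1.0
        doublet = rng.random(size=n_noise) < cfg.ms2_noise_doublet_fraction
        for iso, sel in ((0, np.ones(n_noise, dtype=bool)), (1, doublet)):
            if not sel.any():
                continue
            iso_mz = mass[sel] + PROTON_MASS + iso * ISOTOPE_SPACING
            sigma_mz = (iso_mz / cfg.instrument_resolution) / 2.35482
            emit_points(
                2,
                ms2_frames[pos[sel]],
                ms2_times[pos[sel]],
                scans[sel],
                rng.normal(iso_mz, sigma_mz),
                inten[sel] * (0.6 if iso else 1.0),
            )

    def finalize(parts: list[tuple], level: int) -> pd.DataFrame:
        if not parts:
            return _empty_table(POINT_SCHEMA)
        fids, times, scans, mzs, intens = (
            np.concatenate([p[i] for p in parts]) for i in range(5)
        )
        df = pd.DataFrame(
            {
                "ms_level": np.full(fids.size, level, dtype=np.int8),
                "frame_id": fids,
                "retention_time": times,
                "scan": scans,
                "mobility": _mobility_of(scans.astype(float), cfg),
                "mz": mzs,
                "intensity": intens,
            }
        ).astype(POINT_SCHEMA)
        if cfg.clip:
            df = clip_saturation(df, cfg.saturation_threshold)
        return df.sort_values(["frame_id", "scan", "mz"], kind="stable").reset_index(drop=True)

    ms1 = finalize(ms1_parts, 1)
    ms2 = finalize(ms2_parts, 2)
    windows = (
        pd.DataFrame(window_rows).astype(ISOLATION_WINDOW_SCHEMA)
        if window_rows
        else _empty_table(ISOLATION_WINDOW_SCHEMA)
    )
    peptides = pd.DataFrame(peptide_rows)
    peptide_isotopes = pd.DataFrame(isotope_rows)
    fragments = pd.DataFrame(fragment_rows)
    return SimulatedRun(
        ms1=ms1,
        ms2=ms2,
        isolation_windows=windows,
        peptides=peptides,
        peptide_isotopes=peptide_isotopes,
        fragments=fragments,
        config=cfg,
    )
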