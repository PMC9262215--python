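"""Deconvolution, extents, isotope intensities and saturation correction."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from cuboidms.feature_resolve import (
    Feature,
    UNCORRECTABLE_ALL_SATURATED,
    UNCORRECTABLE_MODEL_RANGE,
    correct_saturation,
    deconvolve_peaks,
    feature_intensity,
    features_from_frame,
    features_to_frame,
    gaussian_fit_r2,
    isotope_intensity,
    resolve_extent,
)
from cuboidms.isotope_model import ConstantRatioModel, scoring_envelope
from cuboidms.raw_model import ISOTOPE_SPACING, PROTON_MASS, PipelineConfig

from oracles import deconvolution_oracle


def _peaks(pairs):
    df = pd.DataFrame(pairs, columns=["mz_centroid", "intensity"])
    df["n_points"] = 1
    df["mz_min"] = df["mz_centroid"]
    df["mz_max"] = df["mz_centroid"]
    return df


def _feature(**overrides):
    base = dict(
        precursor_id=0, charge=2, monoisotopic_mz=500.0,
        monoisotopic_mass=2 * (500.0 - PROTON_MASS), envelope=[],
        envelope_score=1.0, scan_apex=150, scan_lower=100, scan_upper=200,
        rt_apex=60.0, rt_lower=50.0, rt_upper=70.0,
        isotope_intensities=[4000.0, 3000.0, 1500.0], feature_intensity=8500.0,
        mono_fit_r2=0.9, saturation_flags=[False, False, False],
    )
    base.update(overrides)
    return Feature(**base)


class TestDeconvolve:
    def test_single_isolated_peak_yields_no_candidate(self, config, model):
        """Charge is undefined from one peak; min-two-isotopes rejects it."""
        assert deconvolve_peaks(_peaks([(500.0, 1000.0)]), config, model) == []

    def test_constructed_charge_2_series(self, config, model):
        """Peaks at the 13C spacing / 2 with model intensities resolve to
        a charge-2 candidate seeded at the mono peak."""
        mono = 500.0
        mass = 2 * (mono - PROTON_MASS)
        env = scoring_envelope(mass, 3, model)
        pairs = [
            (mono + i * ISOTOPE_SPACING / 2, 1000.0 * env[i]) for i in range(3)
        ]
        cands = deconvolve_peaks(_peaks(pairs), config, model)
        assert cands
        top = cands[0]
        assert top.charge == 2
        assert top.monoisotopic_mz == pytest.approx(mono)
        assert top.score > 0.99

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_exhaustive_enumeration(self, seed, config, model):
        """Ranked candidates equal the brute-force (seed, charge) sweep."""
        rng = np.random.default_rng(200 + seed)
        n = int(rng.integers(2, 7))
        z = int(rng.integers(1, 4))
        mono = float(rng.uniform(400, 900))
        pairs = []
        for i in range(n):
            # half constructed series, half clutter
            if i < n // 2 + 1:
                pairs.append((mono + i * ISOTOPE_SPACING / z, float(rng.uniform(100, 1000))))
            else:
                pairs.append((float(rng.uniform(400, 910)), float(rng.uniform(100, 1000))))
        peaks = _peaks(pairs)
        got = deconvolve_peaks(peaks, config, model, score_threshold=0.3, max_candidates=None)
        exp = deconvolution_oracle(
            pairs, config, model, config.charge_min, config.charge_max, 0.3
        )
        assert len(got) == len(exp)
        for g, e in zip(got, exp):
            assert g.charge == e[0]
            assert g.monoisotopic_mz == pytest.approx(e[1], abs=1e-9)
            assert g.peak_indices == e[2]
            assert g.score == pytest.approx(e[3], rel=1e-9)


class TestResolveExtent:
    def test_single_gaussian_profile(self):
        scans = np.arange(100, 131)
        profile = 1000.0 * np.exp(-0.5 * ((scans - 115) / 5.0) ** 2)
        ext = resolve_extent(scans, profile, center_hint=115)
        assert abs(ext.apex - 115) <= 1
        assert ext.lower == 100 and ext.upper == 130
        assert not ext.degenerate

    def test_two_gaussians_bounded_at_valley(self):
        scans = np.arange(100, 141)
        profile = 1000.0 * np.exp(-0.5 * ((scans - 110) / 3.0) ** 2)
        profile += 800.0 * np.exp(-0.5 * ((scans - 130) / 3.0) ** 2)
        ext = resolve_extent(scans, profile, center_hint=110)
        assert abs(ext.apex - 110) <= 1
        assert abs(ext.upper - 120) <= 1  # inter-peak valley
        assert ext.lower <= 102  # in the negligible-intensity tail

    def test_flat_profile_is_degenerate(self):
        ext = resolve_extent(np.arange(5), np.zeros(5), center_hint=2)
        assert ext.degenerate

    def test_too_few_coordinates_degenerate(self):
        ext = resolve_extent(np.array([3, 3, 4]), np.array([1.0, 2.0, 5.0]), 3)
        assert ext.degenerate
        assert ext.apex == 4 and ext.lower == 3 and ext.upper == 4


class TestIsotopeIntensity:
    def _points(self, rows):
        return pd.DataFrame(rows, columns=["frame_id", "intensity"])

    def test_three_point_rule(self):
        pts = self._points([(4, 80.0), (5, 100.0), (5, 40.0), (6, 60.0)])
        m = isotope_intensity(pts, apex_frame=5)
        assert m.intensity == 240.0
        assert m.contributing == (80.0, 100.0, 60.0)

    def test_missing_neighbours_contribute_zero(self):
        m = isotope_intensity(self._points([(5, 100.0)]), apex_frame=5)
        assert m.intensity == 100.0

    def test_frame_order_skips_other_ms_level(self):
        # MS1 frames 0, 4, 8: neighbours of 4 are 0 and 8, not 3 and 5
        pts = self._points([(0, 50.0), (4, 100.0), (8, 25.0)])
        m = isotope_intensity(pts, apex_frame=4, frame_order=[0, 4, 8])
        assert m.intensity == 175.0

    def test_saturation_ceiling_is_three_times_threshold(self):
        """All contributing points at the 3000-count threshold cap the
        rule at 9000."""
        pts = self._points([(4, 3000.0), (5, 3000.0), (6, 3000.0)])
        m = isotope_intensity(pts, apex_frame=5)
        assert m.intensity == 9000.0
        assert m.saturated(3000.0)


def test_feature_intensity_sums_first_three():
    assert feature_intensity([4000.0, 3000.0, 1500.0, 500.0]) == 8500.0
    assert feature_intensity([700.0]) == 700.0
    rng = np.random.default_rng(9)
    for _ in range(20):
        vals = rng.uniform(0, 1e4, int(rng.integers(1, 8))).tolist()
        assert feature_intensity(vals) == pytest.approx(sum(vals[: min(3, len(vals))]))


class TestGaussianFit:
    def test_noiseless_gaussian_fits_perfectly(self):
        x = np.linspace(499.95, 500.05, 25)
        y = 1000.0 * np.exp(-0.5 * ((x - 500.0) / 0.01) ** 2)
        r2, ok = gaussian_fit_r2(x, y)
        assert ok and r2 >= 0.999

    def test_uniform_noise_fits_poorly(self):
        rng = np.random.default_rng(10)
        x = np.linspace(499.95, 500.05, 50)
        y = rng.uniform(100, 200, 50)
        r2, _ = gaussian_fit_r2(x, y)
        assert r2 < 0.5

    def test_matches_independent_least_squares(self):
        """R-squared agrees with an lmfit Gaussian fit on the same data."""
        import lmfit

        rng = np.random.default_rng(12)
        x = np.linspace(499.95, 500.05, 40)
        y = 1000.0 * np.exp(-0.5 * ((x - 500.0) / 0.01) ** 2)
        y = y * (1 + 0.1 * rng.standard_normal(40))
        r2, ok = gaussian_fit_r2(x, y)
        assert ok
        gm = lmfit.models.GaussianModel()
        pars = gm.guess(y, x=x)
        out = gm.fit(y, pars, x=x)
        ref = 1 - float(np.sum(out.residual**2)) / float(np.sum((y - y.mean()) ** 2))
        assert r2 == pytest.approx(ref, abs=1e-3)

    def test_too_few_points(self):
        r2, ok = gaussian_fit_r2([1.0, 2.0, 3.0], [1.0, 2.0, 1.0])
        assert (r2, ok) == (0.0, False)


class TestCorrectSaturation:
    def test_unsaturated_mono_unchanged(self):
        stub = ConstantRatioModel(0.5)
        f = correct_saturation(_feature(), stub, 3000.0)
        assert not f.saturated
        assert f.inference_isotope_index is None
        assert f.corrected_mono_intensity is None

    def test_backward_chain_from_first_unsaturated(self):
        """Isotopes 0 and 1 saturated, isotope 2 at 900 with ratio 0.5:
        the chain gives 1800 then 3600."""
        stub = ConstantRatioModel(0.5)
        f = _feature(
            isotope_intensities=[9000.0, 9000.0, 900.0],
            saturation_flags=[True, True, False],
        )
        got = correct_saturation(f, stub, 3000.0)
        assert got.saturated
        assert got.inference_isotope_index == 2
        assert got.corrected_mono_intensity == pytest.approx(3600.0)

    def test_all_saturated_is_flagged_not_raised(self):
        stub = ConstantRatioModel(0.5)
        f = _feature(saturation_flags=[True, True, True])
        got = correct_saturation(f, stub, 3000.0)
        assert got.correction_note == UNCORRECTABLE_ALL_SATURATED
        assert got.corrected_mono_intensity is None

    def test_outside_model_range_is_flagged(self):
        narrow = ConstantRatioModel(0.5, mass_min=5000.0, mass_max=6000.0)
        f = _feature(saturation_flags=[True, False, False])
        got = correct_saturation(f, narrow, 3000.0)
        assert got.correction_note == UNCORRECTABLE_MODEL_RANGE


def test_feature_table_round_trip(tmp_path):
    feats = [
        _feature(),
        _feature(
            precursor_id=1,
            saturation_flags=[True, False, False],
            inference_isotope_index=1,
            corrected_mono_intensity=12345.6,
        ),
    ]
    df = features_to_frame(feats)
    from cuboidms.raw_model import read_table, write_table

    path = tmp_path / "features.feather"
    write_table(df, path)
    back = features_from_frame(read_table(path))
    assert back[0].inference_isotope_index is None
    assert back[1].inference_isotope_index == 1
    assert back[1].corrected_mono_intensity == pytest.approx(12345.6)
    assert back[0].isotope_intensities == feats[0].isotope_intensities


class TestRecoveryOnSyntheticData:
    def test_clean_parameter_recovery(self, clean_run, clean_result):
        """Noise-free, unclipped features: charge exact and mono m/z
        within 5 ppm for >= 95%; RT apex within one MS1 frame; scan apex
        within 2 scans."""
        best = clean_result.top_feature_per_precursor()
        truth = clean_run.peptides.set_index("peptide_id")
        n = len(truth)
        ms1_period = (
            clean_run.config.cycle_time  # one MS1 frame per cycle
        )
        ok_z = ok_ppm = ok_rt = ok_scan = 0
        for pid, t in truth.iterrows():
            f = best.get(pid)
            if f is None:
                continue
            ok_z += int(f.charge == t.charge)
            ppm = abs(f.monoisotopic_mz - t.monoisotopic_mz) / t.monoisotopic_mz * 1e6
            ok_ppm += int(ppm <= 5.0)
            ok_rt += int(abs(f.rt_apex - t.rt_apex) <= ms1_period + 1e-9)
            ok_scan += int(abs(f.scan_apex - t.scan_apex) <= 2)
        assert ok_z / n >= 0.95
        assert ok_ppm / n >= 0.95
        assert ok_rt / n >= 0.95
        assert ok_scan / n >= 0.95

    def test_saturation_correction_recovers_intensity(self, small_run, small_result):
        """On clipped features with an unsaturated anchor isotope, the
        corrected mono intensity has smaller median relative error than
        the uncorrected reading, and wider log10 dynamic range."""
        best = small_result.top_feature_per_precursor()
        iso_truth = small_run.peptide_isotopes.set_index(["peptide_id", "isotope"])
        rel_corr, rel_unc, corr_vals, unc_vals = [], [], [], []
        for pid, f in best.items():
            if not (f.saturated and f.corrected_mono_intensity):
                continue
            true0 = float(iso_truth.loc[(pid, 0)]["true_rule_intensity"])
            rel_corr.append(abs(f.corrected_mono_intensity - true0) / true0)
            rel_unc.append(abs(f.isotope_intensities[0] - true0) / true0)
            corr_vals.append(f.corrected_mono_intensity)
            unc_vals.append(f.isotope_intensities[0])
        assert len(rel_corr) >= 3  # the clipped set is non-trivial
        assert np.median(rel_corr) < np.median(rel_unc)
        dyn_corr = np.log10(max(corr_vals) / min(corr_vals))
        dyn_unc = np.log10(max(unc_vals) / min(unc_vals))
        assert dyn_corr >= dyn_unc
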