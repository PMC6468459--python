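"""Spectrum processing: smoothing, baseline, peaks, calibration, extraction, QC."""

import numpy as np
import pytest

import glycotrait as gt
from glycotrait.chem import composition_mass
from glycotrait.processing import (
    AnalyteExtraction,
    CalibrationError,
    Peak,
    QCThresholds,
    Spectrum,
    apply_calibration,
    baseline_correct,
    build_profile,
    combine_replicates,
    extract_analyte,
    pick_peaks,
    qc_analyte,
    qc_spectrum,
    recalibrate,
    smooth,
)


def gaussian_spectrum(centers, amplitudes, sigma=0.08, lo=1000.0, hi=1100.0,
                      dx=0.02, offset=0.0):
    mz = np.arange(lo, hi, dx)
    y = np.full_like(mz, offset)
    for c, a in zip(centers, amplitudes):
        y += a * np.exp(-0.5 * ((mz - c) / sigma) ** 2)
    return Spectrum(mz, y)


class TestSpectrumType:
    def test_requires_ascending_mz(self):
        with pytest.raises(ValueError, match="increasing"):
            Spectrum(np.array([1.0, 1.0, 2.0]), np.zeros(3))

    def test_requires_equal_lengths(self):
        with pytest.raises(ValueError):
            Spectrum(np.arange(3.0), np.zeros(4))


class TestSmoothing:
    def test_constant_spectrum_unchanged(self):
        s = Spectrum(np.arange(1000.0, 1010.0, 0.02), np.full(500, 7.0))
        assert smooth(s).intensity == pytest.approx(np.full(500, 7.0))

    def test_gaussian_apex_preserved_and_tic_conserved(self):
        s = gaussian_spectrum([1050.0], [1000.0])
        sm = smooth(s, cycles=4)
        assert sm.mz[np.argmax(sm.intensity)] == pytest.approx(1050.0, abs=s.dx)
        assert sm.intensity.sum() == pytest.approx(s.intensity.sum(), rel=0.01)

    def test_white_noise_variance_contracts(self, rng):
        s = Spectrum(np.arange(1000.0, 1040.0, 0.02), rng.normal(100, 10, 2000))
        assert smooth(s).intensity.var() < s.intensity.var()

    def test_too_short_spectrum_raises(self):
        s = Spectrum(np.array([1000.0, 1000.02, 1000.04]), np.zeros(3))
        with pytest.raises(ValueError, match="shorter"):
            smooth(s)


class TestBaseline:
    def test_flat_offset_removed_peaks_preserved(self):
        s = gaussian_spectrum([1050.0], [1000.0], offset=200.0)
        corrected = baseline_correct(s)
        apex = np.argmax(corrected.intensity)
        assert corrected.intensity[apex] == pytest.approx(1000.0, rel=0.02)
        edges = np.concatenate([corrected.intensity[:100], corrected.intensity[-100:]])
        assert np.abs(edges).max() < 1.0

    def test_linear_ramp_mostly_removed(self):
        mz = np.arange(1000.0, 1100.0, 0.02)
        ramp = np.linspace(0.0, 500.0, mz.size)
        peaks = 1000.0 * np.exp(-0.5 * ((mz - 1050.0) / 0.08) ** 2)
        s = Spectrum(mz, ramp + peaks)
        corrected = baseline_correct(s)
        off_peak = np.abs(mz - 1050.0) > 2.0
        assert corrected.intensity[off_peak].max() < 0.05 * 500.0

    def test_all_zero_spectrum_stays_zero(self):
        s = Spectrum(np.arange(1000.0, 1010.0, 0.02), np.zeros(500))
        assert not baseline_correct(s).intensity.any()


class TestPeakPicking:
    def test_single_peak_found_at_true_center(self, rng):
        mz = np.arange(1000.0, 1100.0, 0.02)
        noise = rng.normal(0, 10, mz.size)
        y = 100.0 * np.exp(-0.5 * ((mz - 1050.123) / 0.08) ** 2) + noise + 50.0
        spectrum = smooth(Spectrum(mz, np.clip(y, 0, None)))  # picker precondition
        strong = [p for p in pick_peaks(spectrum, sn_cutoff=5) if p.sn > 8]
        assert len(strong) == 1
        assert strong[0].mz == pytest.approx(1050.123, abs=0.02)  # ~1 grid step

    def test_resolved_doublet_gives_two_peaks(self):
        s = gaussian_spectrum([1040.0, 1045.0], [500.0, 500.0])
        peaks = [p for p in pick_peaks(s, sn_cutoff=3) if p.intensity > 100]
        assert len(peaks) == 2

    def test_noise_only_false_positive_rate(self, rng):
        """At S/N cut-off 3, pure noise yields few, weak false peaks."""
        counts = []
        for _ in range(5):
            mz = np.arange(1000.0, 1200.0, 0.02)
            s = Spectrum(mz, np.clip(rng.normal(100, 20, mz.size), 0, None))
            counts.append(len(pick_peaks(s, sn_cutoff=3)))
        # ~3300 local maxima per spectrum; one-sided >3 sigma tail is rare
        assert np.mean(counts) < 0.05 * 3300


class TestRecalibration:
    def make_peaks(self, distort=lambda m: m):
        names = list(gt.CALIBRANTS)
        return [
            Peak(mz=distort(composition_mass(c)), intensity=1000.0, area=100.0,
                 noise=10.0)
            for c in names
        ]

    def test_identity_recovered_on_calibrated_peaks(self):
        model, calibrated = recalibrate(self.make_peaks())
        for p, q in zip(calibrated, self.make_peaks()):
            assert abs(p.mz - q.mz) / q.mz * 1e6 < 0.5

    def test_known_cubic_distortion_inverted(self):
        def distort(m):
            return m + (-0.08 + 6e-5 * m - 1.2e-8 * m**2 + 2e-12 * m**3)

        model, calibrated = recalibrate(self.make_peaks(distort))
        assert model.max_abs_residual_ppm < 1.0
        for p, name in zip(calibrated, gt.CALIBRANTS):
            theo = composition_mass(name)
            assert abs(p.mz - theo) / theo * 1e6 < 1.0, name

    def test_four_matched_calibrants_is_an_error(self):
        peaks = self.make_peaks()[:4]
        with pytest.raises(CalibrationError, match="matched only 4"):
            recalibrate(peaks)

    def test_low_sn_peaks_not_used_as_calibrants(self):
        peaks = self.make_peaks()
        for p in peaks[5:]:
            p.noise = 1000.0  # S/N 1: unusable for calibration
        model, _ = recalibrate(peaks)
        assert len(model.calibrants) == 5


class TestExtraction:
    def test_noiseless_area_conservation(self, render_params):
        from glycotrait.simulate import SpectrumRenderParams, render_spectrum

        params = SpectrumRenderParams(
            mz_range=(1200.0, 1300.0), noise_sd=0.0, baseline_amp=0.0,
            baseline_offset=0.0, miscalibration=(0, 0, 0, 0), intensity_scale=1e6,
        )
        spec, _ = render_spectrum({"H5N2": 100.0}, params, seed=0)
        x = extract_analyte(spec, "H5N2")
        assert x.corrected_area == pytest.approx(1e6, rel=0.01)
        assert x.quality_score < 0.01
        assert abs(x.observed_ppm) < 2.0

    def test_absent_analyte_fails_sn(self, render_params):
        from glycotrait.simulate import render_spectrum

        spec, _ = render_spectrum({"H5N2": 100.0}, render_params, seed=1)
        x = extract_analyte(spec, "H6N5F1")  # not rendered
        assert x.sn < 6.0
        assert not qc_analyte(x)

    def test_window_outside_range_flags_absent(self):
        s = gaussian_spectrum([1050.0], [100.0])
        x = extract_analyte(s, "H7N6")  # ~2600 Da, outside 1000-1100
        assert x.absent and x.corrected_area == 0.0

    def test_three_isotope_truncation_ignores_m4_tail_of_neighbor(self):
        """A second species 5 Da up does not leak into a 3-isotope window."""
        from glycotrait.simulate import SpectrumRenderParams, render_spectrum

        params = SpectrumRenderParams(
            mz_range=(1500.0, 1700.0), noise_sd=0.0, baseline_amp=0.0,
            baseline_offset=0.0, miscalibration=(0, 0, 0, 0), intensity_scale=1e6,
        )
        solo, _ = render_spectrum({"H7N2": 100.0}, params, seed=0)
        both, _ = render_spectrum({"H7N2": 50.0, "H5N3F1": 50.0}, params, seed=0)
        # H5N3F1 (1565.55) sits ~16 Da below H7N2 (1581.53): far beyond M+4
        a = extract_analyte(solo, "H7N2").corrected_area
        b = extract_analyte(both, "H7N2").corrected_area
        assert b == pytest.approx(0.5 * a, rel=0.02)


class TestQC:
    def make_extraction(self, sn=20.0, ppm=5.0, qs=0.02, area=1e5):
        return AnalyteExtraction(
            composition="H5N2", theoretical_mz=1257.42, observed_ppm=ppm,
            raw_area=area, corrected_area=area, sn=sn, quality_score=qs,
        )

    @pytest.mark.parametrize(
        "kwargs,expected",
        [
            (dict(sn=10.0, ppm=5.0, qs=0.02), True),
            (dict(sn=5.9), False),               # S/N boundary is strict
            (dict(sn=6.0), False),
            (dict(ppm=20.0), False),             # |ppm| must be < 20
            (dict(ppm=-25.0), False),
            (dict(qs=0.10), True),               # deviation <= 0.10 passes
            (dict(qs=0.11), False),
        ],
    )
    def test_analyte_criteria_strictness(self, kwargs, expected):
        assert qc_analyte(self.make_extraction(**kwargs)) is expected

    def test_configurable_qs_direction(self):
        x = self.make_extraction(qs=0.5)
        thresholds = QCThresholds(qs_pass_below=False)
        assert qc_analyte(x, thresholds)

    def test_hand_evaluated_survivor_count(self):
        batch = [
            self.make_extraction(),                      # pass
            self.make_extraction(sn=6.1, ppm=19.9),      # pass (just inside)
            self.make_extraction(sn=5.0),                # fail S/N
            self.make_extraction(ppm=21.0),              # fail ppm
            self.make_extraction(qs=0.2),                # fail QS
            self.make_extraction(sn=3.0, ppm=30.0),      # fail both
        ]
        assert sum(qc_analyte(x) for x in batch) == 2

    def test_spectrum_qc_total_intensity(self):
        low = [self.make_extraction(area=5e4)]
        assert not qc_spectrum(low)[0]
        high = [self.make_extraction(area=1e6)]
        assert qc_spectrum(high)[0]

    def test_spectrum_qc_exactly_half_high_sn_fails(self):
        batch = [
            self.make_extraction(sn=20.0, area=5e5),
            self.make_extraction(sn=8.0, area=5e5),  # S/N <= 9: low-quality half
        ]
        passed, metrics = qc_spectrum(batch)
        assert metrics["high_sn_fraction"] == pytest.approx(0.5)
        assert not passed  # 'more than 50%' is strict


class TestProfileBuilding:
    def test_areas_rescaled_to_percentages(self):
        batch = [
            AnalyteExtraction(c, 0.0, 1.0, a, a, 20.0, 0.01)
            for c, a in [("H5N2", 2.0), ("H6N2", 3.0), ("H7N2", 5.0)]
        ]
        profile = build_profile(batch)
        assert profile.to_dict() == pytest.approx(
            {"H5N2": 20.0, "H6N2": 30.0, "H7N2": 50.0}
        )

    def test_no_passing_analytes_is_error(self):
        batch = [AnalyteExtraction("H5N2", 0.0, 1.0, 10.0, 10.0, 1.0, 0.5)]
        with pytest.raises(ValueError, match="no analytes"):
            build_profile(batch)

    def test_identical_replicates_equal_single_replicate(self, render_params):
        from glycotrait.simulate import render_spectrum

        spec, _ = render_spectrum({"H5N2": 100.0}, render_params, seed=3)
        combined = combine_replicates([spec, spec, spec])
        assert np.allclose(combined.intensity, spec.intensity)


class TestEndToEnd:
    def test_roundtrip_recovers_true_abundances(self, small_cohort, render_params):
        """simulate -> render -> process recovers the profile within 2 pp."""
        import pandas as pd

        _, profiles, truth = small_cohort
        targets = [str(c) for c in gt.default_library()]
        cohort = gt.render_cohort(profiles, render_params, replicates=2, seed=42)
        recovered = {}
        for sample, reps in cohort.items():
            profile, table, meta = gt.process_sample(reps, targets)
            assert meta["spectrum_pass"], sample
            assert meta["calibration"].max_abs_residual_ppm < 5.0
            recovered[sample] = profile
        recovered = pd.DataFrame(recovered).T.reindex(profiles.index).fillna(0.0)
        err = (recovered.reindex(columns=profiles.columns).fillna(0.0) - profiles).abs()
        assert np.median(err.to_numpy()) <= 0.5
        assert err.to_numpy().max() <= 2.0
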