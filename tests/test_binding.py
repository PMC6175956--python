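"""Vesicle-binding pipeline operations: calibration, binning, fits."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from curvsense.binding_pipeline import (DiameterCalibration, ProteinCalibration,
                                        bin_profile, calibrate_diameters,
                                        correct_bmax, density_and_coverage,
                                        filopodia_partition, fit_langmuir,
                                        footprint_from_chain_length,
                                        intensity_mode, normalized_sensitivity,
                                        proteins_per_vesicle)


class TestDiameterCalibration:
    def test_modal_intensity_maps_to_dls_mean(self, rng):
        base = rng.normal(100.0, 10.0, size=500)
        cal = DiameterCalibration(dls_mean_diameter_nm=67.0)
        d = calibrate_diameters(base, cal)
        mode = intensity_mode(base)
        idx = np.argmin(np.abs(base - mode))
        assert d[idx] == pytest.approx(67.0, rel=0.02)

    def test_area_scaling(self):
        cal = DiameterCalibration(49.0, brightness_exponent=2.0)
        x = np.concatenate([np.full(100, 100.0) + np.arange(100) * 1e-3,
                            [400.0]])
        d = calibrate_diameters(x, cal)
        # 4x the modal intensity -> twice the diameter
        assert d[-1] == pytest.approx(2 * 49.0, rel=0.02)

    def test_roundtrip_known_diameters(self, rng):
        true_d = rng.lognormal(math.log(67.0), 0.1, size=2000)
        intensity = 0.05 * true_d ** 2
        d_mode = math.exp(math.log(67.0) - 2 * 0.1 ** 2)  # mode of d^2 law
        cal = DiameterCalibration(d_mode)
        d = calibrate_diameters(intensity, cal)
        rms = np.sqrt(np.mean((d / true_d - 1) ** 2))
        assert rms < 0.05

    def test_degenerate_rejected(self):
        with pytest.raises(ValueError):
            calibrate_diameters(np.full(100, 5.0), DiameterCalibration(49.0))

    def test_too_few_puncta_rejected(self):
        with pytest.raises(ValueError):
            calibrate_diameters(np.arange(10.0), DiameterCalibration(49.0))


class TestProteinsPerVesicle:
    def test_zero_intensity(self):
        cal = ProteinCalibration(100.0)
        assert proteins_per_vesicle([0.0], cal)[0] == 0.0

    def test_linear(self):
        cal = ProteinCalibration(100.0)
        assert proteins_per_vesicle([500.0], cal)[0] == pytest.approx(5.0)

    def test_nonpositive_calibration_rejected(self):
        with pytest.raises(ValueError):
            ProteinCalibration(0.0)


class TestBinProfile:
    def test_single_bin(self):
        d = np.full(40, 100.0)
        c = np.arange(40.0)
        prof = bin_profile(d, c)
        assert len(prof) == 1
        assert prof["diameter_nm"].iloc[0] == 100.0
        assert prof["mean_count"].iloc[0] == pytest.approx(c.mean())
        sem = c.std(ddof=1) / math.sqrt(40)
        assert prof["ci95"].iloc[0] == pytest.approx(1.96 * sem)

    def test_linear_relation_preserved(self, rng):
        d = rng.uniform(15, 255, size=5000)  # covers every bin fully
        c = 3.0 * d
        prof = bin_profile(d, c)
        assert np.allclose(prof["mean_count"], 3.0 * prof["diameter_nm"],
                           rtol=0.05)

    def test_out_of_range_dropped(self):
        prof = bin_profile([10.0, 100.0, 300.0], [1.0, 2.0, 3.0])
        assert list(prof["diameter_nm"]) == [100.0]

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            bin_profile([], [])

    def test_bin_edges_half_open(self):
        # 22.49 belongs to the 20 bin, 22.5 to the 25 bin
        prof = bin_profile([22.49, 22.5], [1.0, 2.0])
        assert list(prof["diameter_nm"]) == [20.0, 25.0]
        assert list(prof["n"]) == [1, 1]


class TestDensityCoverage:
    def test_reference_coverage_arithmetic(self):
        """327 proteins on a 200 nm vesicle at 115 nm^2 is ~30% coverage."""
        prof = bin_profile(np.full(50, 200.0), np.full(50, 327.0))
        out = density_and_coverage(prof, 115.0)
        cov = out["coverage"].iloc[0]
        assert cov == pytest.approx(327 * 115 / (math.pi * 200 ** 2), rel=1e-9)
        assert cov == pytest.approx(0.30, abs=0.01)

    def test_zero_counts(self):
        prof = bin_profile(np.full(50, 100.0), np.zeros(50))
        out = density_and_coverage(prof, 115.0)
        assert out["density_per_nm2"].iloc[0] == 0.0
        assert out["coverage"].iloc[0] == 0.0

    def test_density_halves_at_sqrt2_diameter(self):
        d = np.concatenate([np.full(50, 100.0), np.full(50, 100.0 * 1.415)])
        c = np.full(100, 10.0)
        out = density_and_coverage(bin_profile(d, c), 115.0)
        dens = out.sort_values("diameter_nm")["density_per_nm2"].to_numpy()
        # bins centre at 100 and 140 nm; density scales with centre area
        assert dens[1] == pytest.approx(dens[0] * 100 ** 2 / 140 ** 2)
        assert dens[1] == pytest.approx(dens[0] / 2, rel=0.03)

    def test_nonpositive_footprint_rejected(self):
        prof = bin_profile([100.0] * 3, [1.0] * 3)
        with pytest.raises(ValueError):
            density_and_coverage(prof, 0.0)


class TestFootprint:
    def test_reference_chain(self):
        assert footprint_from_chain_length(569) == pytest.approx(115.0)

    def test_linear_scaling(self):
        # 432 residues scale to ~87 nm^2 (reported rounded to ~85)
        assert footprint_from_chain_length(432) == pytest.approx(87.3, abs=0.5)

    def test_rejects_zero(self):
        with pytest.raises(ValueError):
            footprint_from_chain_length(0)


class TestNormalizedSensitivity:
    def test_flat_profile_all_ones(self):
        d = np.repeat(np.arange(20.0, 251.0, 5.0), 30)
        counts = math.pi * d ** 2 * 1e-3  # constant density
        prof = density_and_coverage(bin_profile(d, counts), 115.0)
        out = normalized_sensitivity(prof)
        assert np.allclose(out["normalized_sensitivity"], 1.0, rtol=1e-9)

    def test_inverse_diameter_profile(self):
        d = np.repeat(np.arange(20.0, 251.0, 5.0), 30)
        counts = d  # density ~ 1/d
        prof = density_and_coverage(bin_profile(d, counts), 115.0)
        out = normalized_sensitivity(prof)
        val = out.loc[out["diameter_nm"] == 20.0,
                      "normalized_sensitivity"].iloc[0]
        assert val == pytest.approx(200.0 / 20.0, rel=0.02)

    def test_scale_invariance(self, rng):
        """Rescaling all intensities by a common factor changes nothing."""
        d = rng.uniform(30, 240, size=3000)
        c = 5e-4 * math.pi * d ** 2 * (200.0 / d)
        base = normalized_sensitivity(
            density_and_coverage(bin_profile(d, c), 115.0))
        scaled = normalized_sensitivity(
            density_and_coverage(bin_profile(d, 7.3 * c), 115.0))
        assert np.allclose(base["normalized_sensitivity"],
                           scaled["normalized_sensitivity"])

    def test_no_reference_window_rejected(self):
        prof = density_and_coverage(
            bin_profile(np.full(50, 40.0), np.full(50, 3.0)), 115.0)
        with pytest.raises(ValueError):
            normalized_sensitivity(prof)


class TestLangmuir:
    def test_noiseless_recovery(self):
        kd, bmax = 160.0, 40.0
        conc = np.array([10.0, 40.0, 160.0, 640.0, 2560.0])
        bound = bmax * conc / (kd + conc)
        fit = fit_langmuir(conc, bound)
        assert fit.kd_nM == pytest.approx(kd, rel=1e-3)
        assert fit.bmax == pytest.approx(bmax, rel=1e-3)

    def test_half_saturation_identity(self):
        fit = fit_langmuir([10.0, 50.0, 250.0],
                           [40 * c / (50 + c) for c in (10.0, 50.0, 250.0)])
        assert fit.bound(fit.kd_nM) == pytest.approx(fit.bmax / 2)

    def test_saturating_limit(self):
        fit = fit_langmuir([10.0, 100.0, 1000.0],
                           [30 * c / (70 + c) for c in (10.0, 100.0, 1000.0)])
        assert fit.bound(1e9) == pytest.approx(fit.bmax, rel=1e-4)

    def test_uncertainty_from_ci_curves(self):
        kd, bmax = 100.0, 20.0
        conc = np.array([10.0, 30.0, 100.0, 300.0, 1000.0])
        bound = bmax * conc / (kd + conc)
        fit = fit_langmuir(conc, bound, ci_series=0.1 * bound)
        assert fit.kd_sd >= 0 and fit.bmax_sd > 0

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_langmuir([1.0, 2.0], [0.1, 0.2])


class TestGeometryCorrection:
    def test_reference_values(self):
        g = correct_bmax(5.0, r_v_nm=15.0, r_p_nm=6.0)
        assert g.area_ratio == pytest.approx((21 / 15) ** 2)
        assert g.area_ratio == pytest.approx(1.96)
        assert g.bmax_corrected == pytest.approx(5.0 / 1.96)

    def test_zero_protein_radius(self):
        g = correct_bmax(5.0, r_v_nm=15.0, r_p_nm=0.0)
        assert g.area_ratio == 1.0
        assert g.bmax_corrected == 5.0

    def test_flat_membrane_limit(self):
        g = correct_bmax(5.0, r_v_nm=1e9, r_p_nm=6.0)
        assert g.area_ratio == pytest.approx(1.0, abs=1e-6)

    @given(st.floats(5.0, 500.0), st.floats(0.0, 20.0))
    @settings(max_examples=50, deadline=None)
    def test_ratio_at_least_one(self, rv, rp):
        assert correct_bmax(1.0, rv, rp).area_ratio >= 1.0

    def test_rejects_nonpositive_radius(self):
        with pytest.raises(ValueError):
            correct_bmax(1.0, 0.0)


class TestFilopodia:
    def _table(self, green_ratio, red_ratio, n=10):
        g_mem, r_mem, g_bg, r_bg = 500.0, 600.0, 50.0, 40.0
        return pd.DataFrame({
            "green_filo": green_ratio * (g_mem - g_bg) + g_bg,
            "green_mem": np.full(n, g_mem),
            "green_bg": np.full(n, g_bg),
            "red_filo": red_ratio * (r_mem - r_bg) + r_bg,
            "red_mem": np.full(n, r_mem),
            "red_bg": np.full(n, r_bg),
        })

    def test_identical_ratios_give_one(self):
        coeff, mean, ci, nexc = filopodia_partition(self._table(1.7, 1.7))
        assert mean == pytest.approx(1.0)
        assert nexc == 0

    def test_green_enrichment(self):
        coeff, mean, ci, _ = filopodia_partition(self._table(2.0, 1.0))
        assert mean == pytest.approx(2.0)

    def test_degenerate_membrane_excluded(self):
        t = self._table(2.0, 1.0, n=5)
        t.loc[0, "green_mem"] = t.loc[0, "green_bg"]  # zero after subtraction
        coeff, mean, ci, nexc = filopodia_partition(t)
        assert nexc == 1
        assert len(coeff) == 4

    def test_missing_columns_rejected(self):
        with pytest.raises(ValueError, match="columns"):
            filopodia_partition(pd.DataFrame({"green_filo": [1.0]}))
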