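"""Entropy sweeps, Boltzmann conversion and Kuhn-length calibration."""

import math

import numpy as np
import pandas as pd
import pytest

from curvsense import (EntropyEstimate, HSMCConfig, MCConfig, SAWModel,
                       Substrate, chain_stats, enumerate_saws)
from curvsense.curvature_model import (CurvatureSweep, PartitioningPrediction,
                                       calibrate_kuhn_length,
                                       entropy_vs_curvature,
                                       predict_sensitivity_profile,
                                       relative_partitioning)


def make_sweep(model, diameters, s_means, ref=200.0):
    ests = [EntropyEstimate(s + 0.1, s - 0.1, s, 0.05, 24) for s in s_means]
    return CurvatureSweep(model, 16, 16 * 0.38, list(diameters),
                          list(diameters), ests, reference_diameter_nm=ref)


class TestRelativePartitioning:
    def test_closed_forms(self, cubic_model):
        sweep = make_sweep(cubic_model, [40.0, 80.0, 200.0],
                           [10.0 + 1.0, 10.0 + math.log(2), 10.0])
        pred = relative_partitioning(sweep)
        assert pred.delta_delta_s == pytest.approx([1.0, math.log(2), 0.0])
        assert pred.k_ratio == pytest.approx([math.e, 2.0, 1.0])

    def test_single_diameter_is_identity(self, cubic_model):
        sweep = make_sweep(cubic_model, [200.0], [5.0])
        pred = relative_partitioning(sweep)
        assert pred.delta_delta_s == pytest.approx([0.0])
        assert pred.k_ratio == pytest.approx([1.0])

    def test_missing_reference_rejected(self, cubic_model):
        sweep = make_sweep(cubic_model, [40.0, 80.0], [11.0, 10.5])
        with pytest.raises(ValueError, match="reference"):
            relative_partitioning(sweep)

    def test_fold_interpolation(self, cubic_model):
        sweep = make_sweep(cubic_model, [40.0, 200.0], [10.0 + math.log(4), 10.0])
        pred = relative_partitioning(sweep)
        assert pred.fold_at(40.0) == pytest.approx(4.0)
        assert pred.fold_at(200.0) == pytest.approx(1.0)


class TestSensitivityProfile:
    def test_reference_is_one(self, cubic_model):
        sweep = make_sweep(cubic_model, [40.0, 200.0], [11.0, 10.0])
        df = predict_sensitivity_profile(relative_partitioning(sweep))
        row = df[df["diameter_nm"] == 200.0]
        assert row["predicted_sensitivity"].iloc[0] == pytest.approx(1.0)

    def test_monotone_when_entropy_monotone(self, cubic_model):
        sweep = make_sweep(cubic_model, [40.0, 80.0, 120.0, 200.0],
                           [12.0, 11.2, 10.6, 10.0])
        df = predict_sensitivity_profile(relative_partitioning(sweep))
        vals = df.sort_values("diameter_nm")["predicted_sensitivity"].to_numpy()
        assert (np.diff(vals) < 0).all()

    def test_doubling_dds_squares_ratio(self, cubic_model):
        base = make_sweep(cubic_model, [40.0, 200.0], [10.0 + 0.7, 10.0])
        doubled = make_sweep(cubic_model, [40.0, 200.0], [10.0 + 1.4, 10.0])
        r1 = relative_partitioning(base).k_ratio[0]
        r2 = relative_partitioning(doubled).k_ratio[0]
        assert r2 == pytest.approx(r1 ** 2)


class TestEntropyVsCurvature:
    def test_small_sweep_against_enumeration(self, cubic_model):
        """4-bond chain on tiny vs huge sphere: positive entropy gain."""
        hc = HSMCConfig(n_bar=50, n_bar_prime=10, n_recon=24, seed=4)
        a = cubic_model.lattice_constant_nm
        contour = 4 * 0.38
        small_d, big_d = 2 * 3 * a, 2 * 200 * a
        sweep = entropy_vs_curvature(cubic_model, contour, [small_d, big_d],
                                     hc, reference_diameter_nm=big_d)
        assert sweep.n_bonds == 4
        ref_small = math.log(enumerate_saws(
            cubic_model, 4, Substrate("sphere_exterior", radius=3)))
        ref_big = math.log(enumerate_saws(
            cubic_model, 4, Substrate("sphere_exterior", radius=200)))
        assert ref_small > ref_big  # exact oracle: convexity gains entropy
        for est, ref in zip(sweep.entropies, (ref_small, ref_big)):
            assert abs(est.s_mean - ref) < 3 * est.se
        pred = relative_partitioning(sweep)
        assert pred.k_ratio[0] > 1.0

    def test_flat_reference_included(self, cubic_model):
        hc = HSMCConfig(n_bar=50, n_bar_prime=10, n_recon=24, seed=4)
        a = cubic_model.lattice_constant_nm
        sweep = entropy_vs_curvature(cubic_model, 3 * 0.38, [2 * 300 * a], hc,
                                     include_flat=True,
                                     reference_diameter_nm=2 * 300 * a)
        ref = math.log(enumerate_saws(cubic_model, 3, Substrate("plane")))
        assert abs(sweep.flat.s_mean - ref) < 3 * sweep.flat.se
        assert abs(sweep.entropies[0].s_mean - ref) < 3 * sweep.entropies[0].se

    def test_too_small_diameter_rejected(self, cubic_model):
        hc = HSMCConfig(n_bar=10, n_recon=4)
        with pytest.raises(ValueError, match="lattice"):
            entropy_vs_curvature(cubic_model, 2.0, [0.5], hc)

    def test_realized_diameters_reported(self, cubic_model):
        hc = HSMCConfig(n_bar=20, n_bar_prime=5, n_recon=4, seed=1)
        sweep = entropy_vs_curvature(cubic_model, 2 * 0.38, [10.0], hc,
                                     reference_diameter_nm=10.0)
        r = round((10.0 / 2) / cubic_model.lattice_constant_nm)
        assert sweep.realized_diameters_nm[0] == pytest.approx(
            2 * r * cubic_model.lattice_constant_nm)


class TestCalibrateKuhnLength:
    def test_family_of_one(self, cubic_model):
        cal = calibrate_kuhn_length([cubic_model], 8 * 0.38, 1.0,
                                    MCConfig(n_steps=2000, n_traj=3, seed=2))
        assert cal.best.name == cubic_model.name

    def test_self_consistency_recovery(self, cubic_model, stiff_model):
        """A target generated by one family member selects that member."""
        cfg = MCConfig(n_steps=4000, n_traj=4, seed=6, n_equil=2000,
                       sample_every=4)
        contour = 24 * 0.38
        target = chain_stats(cubic_model, 24, cfg).rg_mean
        cal = calibrate_kuhn_length([cubic_model, stiff_model], contour,
                                    target,
                                    MCConfig(n_steps=4000, n_traj=4, seed=7,
                                             n_equil=2000, sample_every=4))
        assert cal.best.name == cubic_model.name
        assert set(cal.table["model"]) == {cubic_model.name, stiff_model.name}
        assert (cal.table["implied_lk_nm"] > 0).all()

    def test_rg_increases_with_lk(self, cubic_model, stiff_model):
        """Stiffer/swollen model has larger Rg at fixed physical contour."""
        cfg = MCConfig(n_steps=4000, n_traj=4, seed=6, n_equil=2000,
                       sample_every=4)
        cal = calibrate_kuhn_length([cubic_model, stiff_model], 24 * 0.38, 1.0,
                                    cfg)
        t = cal.table.set_index("model")
        order_rg = t["rg_sim_nm"].sort_values().index.tolist()
        order_lk = t["implied_lk_nm"].sort_values().index.tolist()
        assert order_rg == order_lk

    def test_empty_family_rejected(self):
        with pytest.raises(ValueError):
            calibrate_kuhn_length([], 10.0, 1.0, MCConfig(n_steps=100))
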