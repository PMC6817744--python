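"""CPMG R2eff extraction and two-site exchange fitting."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from riboflex import dispersion as dp
from riboflex import synthdata as sd
from riboflex.tablesio import IntensityPoint, IntensitySeries


class TestR2eff:
    def test_reference_intensity_gives_zero(self):
        assert dp.r2eff_from_intensity(100.0, 100.0, 0.05) == 0.0

    def test_hand_value(self):
        assert dp.r2eff_from_intensity(60.0, 100.0, 0.05) == pytest.approx(
            20.0 * math.log(100.0 / 60.0)
        )

    def test_error_hand_value(self):
        assert dp.r2eff_error(4.0, 60.0, 0.05) == pytest.approx(4.0 / 3.0)
        assert dp.r2eff_error(0.0, 60.0, 0.05) == 0.0

    def test_nonpositive_intensity_rejected(self):
        with pytest.raises(ValueError):
            dp.r2eff_from_intensity(-1.0, 100.0, 0.05)


class TestDispersionModel:
    def test_fast_pulsing_limit_reaches_baseline(self):
        assert dp.dispersion_model(1e6, 20.0, 5.0, 300.0) == pytest.approx(
            20.0, rel=1e-4
        )

    def test_slow_pulsing_limit_reaches_full_exchange(self):
        assert dp.dispersion_model(1e-4, 20.0, 5.0, 300.0) == pytest.approx(
            25.0, rel=1e-4
        )

    def test_hand_value_half_cycle_convention(self):
        # tau_cp = 6.25 ms at 80 Hz: bracket = 1 - 2*tanh(0.9375)/1.875
        expected = 20.0 + 5.0 * (1.0 - 2.0 * math.tanh(0.9375) / 1.875)
        assert dp.dispersion_model(80.0, 20.0, 5.0, 300.0, "half") == pytest.approx(
            expected
        )
        assert expected == pytest.approx(21.085, abs=5e-4)

    def test_reciprocal_convention_equals_half_at_doubled_kex(self):
        nu = np.array([66.67, 80.0, 320.0, 800.0])
        a = dp.dispersion_model(nu, 20.0, 5.0, 300.0, "reciprocal")
        b = dp.dispersion_model(nu, 20.0, 5.0, 600.0, "half")
        assert np.allclose(a, b)

    @given(
        kex=st.floats(10.0, 5000.0),
        rex=st.floats(0.0, 30.0),
        r2_0=st.floats(5.0, 40.0),
    )
    @settings(derandomize=True, max_examples=50)
    def test_monotone_nonincreasing_in_nu(self, kex, rex, r2_0):
        nu = np.geomspace(10.0, 5000.0, 40)
        vals = dp.dispersion_model(nu, r2_0, rex, kex)
        assert np.all(np.diff(vals) <= 1e-12)

    def test_unknown_convention_rejected(self):
        with pytest.raises(ValueError, match="convention"):
            dp.dispersion_model(80.0, 20.0, 5.0, 300.0, "quarter")


def cpmg_series(residue, field, nu_intensities, spin_label=""):
    pts = []
    seen = set()
    for nu, inten in nu_intensities:
        pts.append(IntensityPoint(nu, inten, nu in seen))
        seen.add(nu)
    return IntensitySeries(residue, spin_label, field, pts, "cpmg")


class TestBuildProfiles:
    def test_reference_replicates_and_blocks(self):
        rows = [(0.0, 100.0), (0.0, 102.0), (80.0, 60.0), (160.0, 70.0),
                (640.0, 90.0), (640.0, 88.0), (66.67, 55.0)]
        series = cpmg_series(14, 600.0, rows)
        profiles = dp.build_profiles([series])
        by_T = {p.T_relax: p for p in profiles}
        assert set(by_T) == {0.05, 0.06}
        main = by_T[0.05]
        assert main.I0 == pytest.approx(101.0)  # mean of the two references
        # R2eff at 80 Hz from the averaged reference
        r2_80 = [pt for pt in main.points if pt.nu_cpmg == 80.0][0]
        assert r2_80.R2eff == pytest.approx(-math.log(60.0 / 101.0) / 0.05)
        # replicate-based error: dI = 2 at 640 Hz
        assert r2_80.sigma == pytest.approx(2.0 / (0.05 * 60.0))

    def test_nonpositive_intensity_dropped_with_flag(self):
        rows = [(0.0, 100.0), (80.0, -5.0), (160.0, 70.0), (640.0, 90.0),
                (640.0, 88.0)]
        profiles = dp.build_profiles([cpmg_series(14, 600.0, rows)])
        (main,) = profiles
        assert all(pt.nu_cpmg != 80.0 for pt in main.points)
        assert any("nonpositive" in f for f in main.flags)

    def test_missing_replicate_uses_pooled_error(self):
        with_rep = cpmg_series(14, 600.0, [(0.0, 100.0), (80.0, 60.0),
                                           (640.0, 90.0), (640.0, 86.0)])
        without = cpmg_series(15, 600.0, [(0.0, 100.0), (80.0, 50.0),
                                          (160.0, 65.0)])
        profiles = dp.build_profiles([with_rep, without])
        other = [p for p in profiles if p.residue_id == 15][0]
        assert "pooled_replicate_error" in other.flags
        assert all(pt.sigma > 0 for pt in other.points)


def two_field_truth(kex, rex, r2_0, residues):
    return {
        "kex": kex,
        "rex": {r: rex for r in residues},
        "r2_0": {r: r2_0 for r in residues},
    }


class TestFitDispersion:
    def test_noiseless_round_trip_recovers_truth(self):
        truth = {"kex": 319.0, "rex": {1: 3.0, 2: 1.5}, "r2_0": {1: 20.0, 2: 22.0}}
        profiles = sd.gen_dispersion(truth, noise_sd=0.0, seed=0)
        fit = dp.fit_dispersion(profiles, "global", mc_iters=0)
        assert fit.kex == pytest.approx(319.0, rel=1e-4)
        assert fit.rex[(1, 600.0)] == pytest.approx(3.0, rel=1e-4)
        assert fit.rex[(1, 850.0)] == pytest.approx(3.0 * (850 / 600) ** 2, rel=1e-4)
        assert fit.r2_0[(2, 600.0)] == pytest.approx(22.0, rel=1e-4)

    def test_single_member_segmental_equals_individual(self):
        truth = two_field_truth(448.0, 3.0, 20.0, [7])
        profiles = sd.gen_dispersion(truth, noise_sd=0.3, seed=11)
        ind = dp.fit_dispersion(profiles, "individual", {7}, mc_iters=0)
        seg = dp.fit_dispersion(profiles, "segmental", {7}, mc_iters=0)
        assert seg.kex == pytest.approx(ind.kex)
        assert seg.chi2 == pytest.approx(ind.chi2)
        assert seg.rex == ind.rex

    def test_fit_matches_three_parameter_grid_oracle(self):
        """Joint fit chi2 must match a brute-force (kex, Rex, R2_0) grid."""
        truth = two_field_truth(448.0, 3.0, 20.0, [7])
        profiles = sd.gen_dispersion(truth, noise_sd=0.2, seed=11)
        for p in profiles:
            p.points = [dp.DispersionPoint(pt.nu_cpmg, pt.R2eff, 0.2) for pt in p.points]
        fit = dp.fit_dispersion(profiles, "individual", {7}, mc_iters=100, seed=11)
        assert fit.kex_ci95[0] <= 448.0 <= fit.kex_ci95[1]

        # independent scan; R2_0 shared across fields as in the generator
        nus = np.concatenate([p.nu for p in profiles])
        scales = np.concatenate(
            [np.full(len(p.points), (p.field_mhz / 600.0) ** 2) for p in profiles]
        )
        ys = np.concatenate([p.r2eff for p in profiles])
        kex_g = np.arange(350.0, 551.0, 1.0)
        rex_g = np.arange(2.0, 4.01, 0.02)
        r20_g = np.arange(19.0, 21.01, 0.02)
        best = np.inf
        for k in kex_g:
            x = k / nus
            bracket = (1.0 - 2.0 * np.tanh(0.5 * x) / x) * scales
            model = (
                r20_g[:, None, None]
                + rex_g[None, :, None] * bracket[None, None, :]
            )
            chi = (((model - ys[None, None, :]) / 0.2) ** 2).sum(axis=2)
            best = min(best, float(chi.min()))
        assert fit.chi2 <= best * 1.01
        assert fit.chi2 == pytest.approx(best, rel=0.01)

    def test_fit_beats_coarse_grid_oracle_on_many_instances(self):
        """Optimality across 20 seeded instances vs an independent 3-D scan."""
        nus = np.array([nu for nu, _ in sd.CPMG_GRID])
        kex_g = np.geomspace(10.0, 5000.0, 300)
        rex_g = np.arange(0.0, 8.01, 0.1)
        r20_g = np.arange(16.0, 26.01, 0.1)
        for seed in range(20):
            rng = np.random.default_rng(seed)
            truth = two_field_truth(rng.uniform(100, 1000), rng.uniform(1, 5),
                                    rng.uniform(18, 24), [3])
            profiles = sd.gen_dispersion(truth, fields=(600.0,), noise_sd=0.3,
                                         seed=seed)
            fit = dp.fit_dispersion(profiles, "individual", {3}, mc_iters=0)
            ys = np.concatenate([p.r2eff for p in profiles])
            best = np.inf
            for k in kex_g:
                x = k / nus
                bracket = 1.0 - 2.0 * np.tanh(0.5 * x) / x
                model = (
                    r20_g[:, None, None]
                    + rex_g[None, :, None] * bracket[None, None, :]
                )
                chi = ((model - ys[None, None, :]) ** 2).sum(axis=2) / 0.3**2
                best = min(best, float(chi.min()))
            assert fit.chi2 <= best * 1.01, f"seed {seed}"

    def test_global_fit_reduces_kex_variance_vs_individual(self):
        """Sharing kex across residues must shrink estimator scatter."""
        glob, indiv = [], []
        for seed in range(50):
            truth = {
                "kex": 319.0,
                "rex": {1: 3.0, 2: 2.0},
                "r2_0": {1: 20.0, 2: 21.5},
            }
            profiles = sd.gen_dispersion(truth, noise_sd=0.3, seed=4000 + seed)
            glob.append(dp.fit_dispersion(profiles, "global", mc_iters=0).kex)
            for res in (1, 2):
                indiv.append(
                    dp.fit_dispersion(profiles, "individual", {res}, mc_iters=0).kex
                )
        assert np.std(glob) < np.std(indiv)

    def test_segmental_chi2_at_least_sum_of_individual(self):
        truth = {"kex": 319.0, "rex": {1: 3.0, 2: 2.0}, "r2_0": {1: 20.0, 2: 21.0}}
        profiles = sd.gen_dispersion(truth, noise_sd=0.3, seed=8)
        seg = dp.fit_dispersion(profiles, "segmental", mc_iters=0)
        total_ind = sum(
            dp.fit_dispersion(profiles, "individual", {r}, mc_iters=0).chi2
            for r in (1, 2)
        )
        assert seg.chi2 >= total_ind - 1e-9

    def test_flat_profile_flagged_no_detectable_exchange(self):
        truth = {"kex": 319.0, "rex": {9: 0.0}, "r2_0": {9: 20.0}}
        profiles = sd.gen_dispersion(truth, noise_sd=0.2, seed=21)
        fit = dp.fit_dispersion(profiles, "individual", {9}, mc_iters=100, seed=3)
        assert "no_detectable_exchange" in fit.flags[9]

    def test_phi_composite_is_rex_times_kex(self):
        truth = {"kex": 319.0, "rex": {1: 3.0}, "r2_0": {1: 20.0}}
        profiles = sd.gen_dispersion(truth, noise_sd=0.0, seed=0)
        fit = dp.fit_dispersion(profiles, "individual", {1}, mc_iters=0)
        assert fit.phi[(1, 600.0)] == pytest.approx(fit.rex[(1, 600.0)] * fit.kex)

    def test_individual_scope_rejects_multiple_residues(self):
        truth = {"kex": 300.0, "rex": {1: 3.0, 2: 2.0}, "r2_0": {1: 20.0, 2: 20.0}}
        profiles = sd.gen_dispersion(truth, noise_sd=0.0, seed=0)
        with pytest.raises(ValueError, match="individual"):
            dp.fit_dispersion(profiles, "individual", mc_iters=0)
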