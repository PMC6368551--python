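"""Age inversion: parameter recovery, bootstrap behaviour, diagnostics."""

import numpy as np
import pytest

from brineage import (
    AgeEstimate,
    IdentifiabilityError,
    NoiseSpec,
    TransportParams,
    bootstrap_age_ci,
    compare_ages,
    fit_age,
    fit_free_parameter,
    make_pore_profile,
    profile_curve,
    seconds_to_years,
)
from brineage.inversion import _standardized_rss


class TestFitAge:
    def test_noise_free_self_consistency(self, heph_mg_params, core_depths):
        t_true = 1e10
        prof = profile_curve(core_depths, t_true, heph_mg_params, tracer="Mg")
        est = fit_age(prof, heph_mg_params)
        assert est.t_seconds == pytest.approx(t_true, rel=1e-3)

    def test_joint_fit_matches_single_tracer_fits(self, heph_mg_params, core_depths):
        t_true = 2.2e10
        cl_params = TransportParams(Ds=2.4e-10, Vs=9.51e-11, C0=9120.0, Cbg=630.0)
        params = {"Mg": heph_mg_params, "Cl": cl_params}
        mg = profile_curve(core_depths, t_true, heph_mg_params, tracer="Mg")
        cl = profile_curve(core_depths, t_true, cl_params, tracer="Cl")
        joint = fit_age([mg, cl], params)
        single = fit_age(mg, heph_mg_params)
        assert joint.t_seconds == pytest.approx(single.t_seconds, rel=5e-3)
        assert joint.t_seconds == pytest.approx(t_true, rel=5e-3)
        assert set(joint.per_tracer_rss) == {"Mg", "Cl"}

    def test_median_recovery_error_under_noise(self, heph_mg_params, core_depths):
        """Median relative error of t over 100 noisy replicates stays <= 5 %."""
        t_true = 2.2e10
        errors = []
        for seed in range(100):
            prof = make_pore_profile(
                heph_mg_params, t_true, core_depths,
                noise=NoiseSpec("relative-gaussian", 0.02, seed), tracer="Mg",
            )
            est = fit_age(prof, heph_mg_params)
            errors.append(abs(est.t_seconds - t_true) / t_true)
        assert np.median(errors) <= 0.05

    def test_objective_sanity_at_optimum(self, heph_mg_params, core_depths):
        prof = make_pore_profile(
            heph_mg_params, 2.2e10, core_depths,
            noise=NoiseSpec("relative-gaussian", 0.02, 3), tracer="Mg",
        )
        est = fit_age(prof, heph_mg_params)
        rss_at = lambda t: _standardized_rss([prof], heph_mg_params, t)
        assert est.rss <= rss_at(0.5 * est.t_seconds)
        assert est.rss <= rss_at(2.0 * est.t_seconds)

    def test_deterministic(self, heph_mg_params, core_depths):
        prof = make_pore_profile(
            heph_mg_params, 2.2e10, core_depths,
            noise=NoiseSpec("relative-gaussian", 0.02, 11), tracer="Mg",
        )
        a = fit_age(prof, heph_mg_params)
        b = fit_age(prof, heph_mg_params)
        assert a.t_seconds == b.t_seconds and a.rss == b.rss

    def test_rejects_empty_and_short_profiles(self, heph_mg_params):
        with pytest.raises(ValueError):
            fit_age([], heph_mg_params)
        short = profile_curve([0.0, 1.0], 1e10, heph_mg_params)
        with pytest.raises(ValueError, match=">= 3"):
            fit_age(short, heph_mg_params)

    def test_rejects_bad_bounds(self, heph_mg_params, core_depths):
        prof = profile_curve(core_depths, 1e10, heph_mg_params)
        with pytest.raises(ValueError):
            fit_age(prof, heph_mg_params, t_bounds=(1e12, 1e8))


class TestFitFreeParameter:
    def test_recovers_dd_diffusivity_noise_free(self, heph_dd_params, core_depths):
        t = 2.2e10
        prof = profile_curve(core_depths, t, heph_dd_params, tracer="dD")
        res = fit_free_parameter(
            prof, heph_dd_params.with_(Ds=1e-10), free="Ds", t=t, bounds=(1e-11, 1e-8)
        )
        assert res.value == pytest.approx(2.96e-10, rel=1e-3)

    def test_recovers_c0_exactly(self, heph_mg_params, core_depths):
        prof = profile_curve(core_depths, 2.2e10, heph_mg_params)
        res = fit_free_parameter(
            prof, heph_mg_params.with_(C0=1000.0), free="C0", t=2.2e10
        )
        assert res.value == pytest.approx(4720.0, rel=1e-12)

    def test_recovers_zero_advection_exactly(self, core_depths):
        p = TransportParams(Ds=2.4e-10, Vs=0.0, C0=4720.0, Cbg=61.0)
        prof = profile_curve(core_depths, 2.2e10, p)
        res = fit_free_parameter(
            prof, p.with_(Vs=5e-11), free="Vs", t=2.2e10, bounds=(0.0, 1e-9)
        )
        assert abs(res.value) <= 1e-12

    def test_refuses_joint_t_and_ds(self, heph_mg_params, core_depths):
        prof = profile_curve(core_depths, 2.2e10, heph_mg_params)
        with pytest.raises(IdentifiabilityError):
            fit_free_parameter(prof, heph_mg_params, free=("t", "Ds"))

    def test_unknown_parameter_rejected(self, heph_mg_params, core_depths):
        prof = profile_curve(core_depths, 2.2e10, heph_mg_params)
        with pytest.raises(ValueError):
            fit_free_parameter(prof, heph_mg_params, free="Rd", t=2.2e10, bounds=(1, 2))


class TestBootstrap:
    def test_same_seed_identical_interval(self, heph_mg_params, core_depths):
        prof = make_pore_profile(
            heph_mg_params, 2.2e10, core_depths,
            noise=NoiseSpec("relative-gaussian", 0.02, 5), tracer="Mg",
        )
        a = bootstrap_age_ci(prof, heph_mg_params, n_boot=50, seed=42)
        b = bootstrap_age_ci(prof, heph_mg_params, n_boot=50, seed=42)
        assert a == b

    def test_interval_contains_point_estimate(self, heph_mg_params, core_depths):
        prof = make_pore_profile(
            heph_mg_params, 2.2e10, core_depths,
            noise=NoiseSpec("relative-gaussian", 0.02, 6), tracer="Mg",
        )
        est = fit_age(prof, heph_mg_params)
        lo, hi = bootstrap_age_ci(prof, heph_mg_params, n_boot=100, seed=1)
        assert lo <= est.t_years <= hi

    def test_noise_free_interval_collapses(self, heph_mg_params, core_depths):
        prof = profile_curve(core_depths, 2.2e10, heph_mg_params, tracer="Mg")
        lo, hi = bootstrap_age_ci(prof, heph_mg_params, n_boot=50, seed=0)
        assert (hi - lo) <= 1e-3 * seconds_to_years(2.2e10)

    def test_tiny_n_boot_rejected(self, heph_mg_params, core_depths):
        prof = profile_curve(core_depths, 2.2e10, heph_mg_params)
        with pytest.raises(ValueError):
            bootstrap_age_ci(prof, heph_mg_params, n_boot=1)


class TestCompareAges:
    @staticmethod
    def _estimate(t_seconds):
        return AgeEstimate(t_seconds=t_seconds, rss=0.0, n_obs=10)

    def test_hephaestus_discovery_offset(self):
        a = self._estimate(700 * 3.15576e7)
        b = self._estimate(2000 * 3.15576e7)
        assert compare_ages(a, b) == pytest.approx(1300.0)

    def test_zero_for_equal_ages(self):
        a = self._estimate(1e10)
        assert compare_ages(a, a) == 0.0

    def test_caption_second_values(self):
        a = self._estimate(31.55e9)
        b = self._estimate(63.1e9)
        assert compare_ages(a, b) == pytest.approx(999.7, abs=0.1)


class TestAgeEstimateInvariants:
    def test_rejects_nonpositive_time_and_bad_ci(self):
        with pytest.raises(ValueError):
            AgeEstimate(t_seconds=0.0, rss=0.0, n_obs=1)
        with pytest.raises(ValueError):
            AgeEstimate(t_seconds=3.15576e7, rss=0.0, n_obs=1, ci_years=(2.0, 3.0))
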