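import math

import numpy as np
import pytest

from gbmwave import (
    DomainError,
    GrowthDeathModel,
    IdentifiabilityError,
    ImagingConfig,
    PatientObservation,
    consistent_death_rate,
    dimensional_width,
    estimate_single_scan,
    estimate_two_scan,
    exponential_phase_radius,
    generate_observation,
    profile_metrics,
    solve_rho_hat_from_ratio,
    volumes_to_radii,
)


class TestVolumesToRadii:
    def test_unit_sphere(self):
        R0, R1, R2 = volumes_to_radii(4 * math.pi / 3, 0.0, 0.0)
        assert R0 == pytest.approx(1.0, rel=1e-12)
        assert R1 == R0 and R2 == R0

    def test_cube_law_nesting(self):
        v = 4 * math.pi / 3
        R0, R1, R2 = volumes_to_radii(v, 7 * v, 19 * v)
        assert (R0, R1, R2) == pytest.approx((1.0, 2.0, 3.0), rel=1e-12)

    def test_all_zero(self):
        assert volumes_to_radii(0, 0, 0) == (0, 0, 0)

    def test_negative_volume(self):
        with pytest.raises(DomainError):
            volumes_to_radii(-1.0, 0.0, 0.0)


class TestObservationValidation:
    def test_ordering_enforced(self):
        with pytest.raises(DomainError):
            PatientObservation("x", 10.0, 8.0, 12.0)

    def test_widths(self):
        obs = PatientObservation("x", 5.0, 8.0, 12.0)
        assert obs.L1 == 3.0 and obs.L2 == 4.0


class TestRatioInversion:
    def test_round_trip_identity(self, reference_model):
        m = profile_metrics(2.0, reference_model)
        rh = solve_rho_hat_from_ratio(m.f_ratio, reference_model)
        assert rh == pytest.approx(2.0, rel=1e-8)

    def test_linear_value(self, linear_model):
        # f(1) ~ 0.5277 for linear shapes, a1=0.9, a2=0.1
        rh = solve_rho_hat_from_ratio(0.5277, linear_model)
        assert rh == pytest.approx(1.0, abs=2e-3)

    def test_out_of_range_reports_attainable_interval(self, reference_model):
        with pytest.raises(IdentifiabilityError) as exc:
            solve_rho_hat_from_ratio(50.0, reference_model)
        lo, hi = exc.value.attainable
        assert 0 < lo < hi < 50.0


class TestExponentialPhaseRadius:
    def test_square_difference_identity(self):
        """(R*_2)^2 - (R*_1)^2 = 4 D t* ln(a1/a2), independent of rho."""
        cfg = ImagingConfig()
        for D, rho in [(0.3, 0.2), (1.0, 0.25), (0.08, 0.17)]:
            r1 = exponential_phase_radius(D, rho, cfg.a1, cfg)
            r2 = exponential_phase_radius(D, rho, cfg.a2, cfg)
            assert r2 > r1
            assert r2**2 - r1**2 == pytest.approx(
                4 * D * cfg.t_star * math.log(cfg.a1 / cfg.a2), rel=1e-12
            )

    def test_zero_at_detectability_limit(self):
        # choose the threshold so the log term exactly equals rho * t*
        cfg = ImagingConfig()
        D, rho = 0.3, 0.2
        a_crit = cfg.p0 * math.exp(rho * cfg.t_star) / (4 * math.pi * D * cfg.t_star) ** 1.5
        r = exponential_phase_radius(D, rho, a_crit * (1 - 1e-9), cfg)
        assert r == pytest.approx(0.0, abs=1e-2)

    def test_undetectable_raises(self):
        from gbmwave import UndetectableTumorError

        cfg = ImagingConfig()
        with pytest.raises(UndetectableTumorError):
            exponential_phase_radius(5.0, 0.01, cfg.a1, cfg)


class TestTwoScanProtocol:
    @pytest.mark.parametrize("rho_hat", [0.7, 2.0, 4.5])
    def test_round_trip_exact(self, reference_model, rho_hat):
        D, rho = 0.3, 0.2
        k = rho / rho_hat
        sp = generate_observation(D, rho, k, 300.0, model=reference_model)
        est = estimate_two_scan(sp.observation, model=reference_model)
        assert est.D == pytest.approx(D, rel=1e-6)
        assert est.rho == pytest.approx(rho, rel=1e-6)
        assert est.k == pytest.approx(k, rel=1e-6)

    def test_velocity_scaling_law(self, reference_model):
        """Doubling V with widths fixed leaves rho_hat, doubles k and rho,
        and scales D as V^2 / rho (halving it overall)."""
        sp = generate_observation(0.3, 0.2, 0.06, 300.0, model=reference_model)
        o = sp.observation
        est1 = estimate_two_scan(o, model=reference_model)
        o2 = PatientObservation(o.patient_id, o.R0, o.R1, o.R2, V=2 * o.V)
        est2 = estimate_two_scan(o2, model=reference_model)
        assert est2.rho_hat == pytest.approx(est1.rho_hat, rel=1e-10)
        assert est2.k == pytest.approx(2 * est1.k, rel=1e-10)
        assert est2.rho == pytest.approx(2 * est1.rho, rel=1e-10)
        assert est2.D == pytest.approx(2 * est1.D, rel=1e-10)

    def test_missing_velocity(self, reference_model):
        obs = PatientObservation("x", 5, 8, 12)
        with pytest.raises(DomainError):
            estimate_two_scan(obs, model=reference_model)

    def test_output_contract(self, reference_model):
        sp = generate_observation(0.5, 0.22, 0.1, 280.0, model=reference_model)
        est = estimate_two_scan(sp.observation, model=reference_model)
        assert est.rho_hat == pytest.approx(est.rho / est.k, rel=1e-9)
        assert est.c == pytest.approx(2 * math.sqrt(est.rho * est.D), rel=1e-9)


class TestSingleScanProtocol:
    def test_round_trip_on_consistent_truth(self, reference_model):
        """Truths satisfying ell_2 = R*_2 - R*_1 are recovered exactly from
        the three radii alone."""
        D, rho = 0.28, 0.21
        k = consistent_death_rate(D, rho, model=reference_model)
        sp = generate_observation(D, rho, k, 300.0, model=reference_model)
        o = sp.observation
        obs = PatientObservation(o.patient_id, o.R0, o.R1, o.R2)  # drop V
        est = estimate_single_scan(obs, model=reference_model)
        assert est.D == pytest.approx(D, rel=1e-4)
        assert est.rho == pytest.approx(rho, rel=1e-4)
        assert est.k == pytest.approx(k, rel=1e-4)
        # the recovered age matches the generating age
        assert est.tumor_age == pytest.approx(300.0, rel=1e-4)

    def test_agrees_with_two_scan_at_implied_velocity(self, reference_model):
        """Feeding the single-scan estimate's wave speed back as V must
        reproduce the same parameters through the two-scan path."""
        obs = PatientObservation("p1", 14.87, 20.73, 27.77)
        est1 = estimate_single_scan(obs, model=reference_model)
        obs_v = PatientObservation("p1", obs.R0, obs.R1, obs.R2, V=est1.c)
        est2 = estimate_two_scan(obs_v, model=reference_model)
        assert est2.D == pytest.approx(est1.D, rel=1e-6)
        assert est2.rho == pytest.approx(est1.rho, rel=1e-6)
        assert est2.k == pytest.approx(est1.k, rel=1e-6)

    def test_unit_scale_consistency(self, reference_model):
        """Radii measured in cm then converted to mm give identical rates
        and the same D (mm^2/day)."""
        obs_mm = PatientObservation("p", 8.29, 15.83, 20.35)
        obs_cm_back = PatientObservation("p", 0.829 * 10, 1.583 * 10, 2.035 * 10)
        e1 = estimate_single_scan(obs_mm, model=reference_model)
        e2 = estimate_single_scan(obs_cm_back, model=reference_model)
        assert e1.rho == pytest.approx(e2.rho, rel=1e-9)
        assert e1.k == pytest.approx(e2.k, rel=1e-9)
        assert e1.D == pytest.approx(e2.D, rel=1e-9)

    def test_width_equation_switch(self, reference_model):
        obs = PatientObservation("p1", 14.87, 20.73, 27.77)
        e_l1 = estimate_single_scan(obs, ImagingConfig(width_equation="l1"), reference_model)
        e_l2 = estimate_single_scan(obs, ImagingConfig(width_equation="l2"), reference_model)
        # same rho_hat either way; the absolute scale may differ slightly
        assert e_l1.rho_hat == pytest.approx(e_l2.rho_hat, rel=1e-10)
        assert e_l1.D == pytest.approx(e_l2.D, rel=0.05)

    def test_output_contract(self, reference_model):
        est = estimate_single_scan(
            PatientObservation("p3", 6.61, 10.91, 15.24), model=reference_model
        )
        assert est.rho_hat == pytest.approx(est.rho / est.k, rel=1e-9)
        assert est.c == pytest.approx(2 * math.sqrt(est.rho * est.D), rel=1e-9)
        assert abs(est.residual) < 1e-8


class TestDimensionalWidths:
    def test_forward_widths_match_observation(self, reference_model):
        """generate_observation must place R1-R0 and R2-R1 exactly at the
        dimensional profile widths."""
        D, rho, k = 0.3, 0.2, 0.06
        m = profile_metrics(rho / k, reference_model)
        sp = generate_observation(D, rho, k, 300.0, model=reference_model)
        o = sp.observation
        assert o.L1 == pytest.approx(dimensional_width(m.I1, D, rho, k), rel=1e-12)
        assert o.L2 == pytest.approx(dimensional_width(m.I2, D, rho, k), rel=1e-12)
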