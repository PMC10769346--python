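"""Closed-form violation-rate model and its inverse."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import spikefdr as sf


class TestRefractoryConfig:
    @pytest.mark.parametrize(
        "tau, tau_c, tau_e",
        [(0.0025, 0.0, 0.0025), (0.0025, 0.00085, 0.00165), (0.002, 0.00025, 0.00175)],
    )
    def test_effective_period_is_difference(self, tau, tau_c, tau_e):
        assert sf.effective_refractory(tau, tau_c).tau_e == pytest.approx(tau_e, abs=1e-15)

    @pytest.mark.parametrize("tau, tau_c", [(0.0025, 0.0025), (0.0025, 0.003), (0.0, 0.0), (-1.0, 0.0)])
    def test_degenerate_configurations_rejected(self, tau, tau_c):
        with pytest.raises(sf.ConfigError):
            sf.effective_refractory(tau, tau_c)


class TestForwardModel:
    def test_single_contaminant_hand_value(self, cfg):
        # 2 * tau * R_FP * R_TP with no FP-FP term at N=1
        assert sf.violation_rate_homog(9.0, 1.0, cfg, 1) == pytest.approx(0.045)

    def test_no_false_positives_no_violations(self, cfg):
        assert sf.violation_rate_homog(12.0, 0.0, cfg, 5) == 0.0

    def test_infinite_contaminants_hand_value(self, cfg):
        # 2*tau_e*5*5 + tau_e*5^2 = 0.125 + 0.0625
        assert sf.violation_rate_homog(5.0, 5.0, cfg, sf.INFINITE) == pytest.approx(0.1875)

    def test_finite_n_converges_monotonically_to_infinite(self, cfg):
        rates = [sf.violation_rate_homog(5.0, 5.0, cfg, n) for n in (1, 2, 5, 50, 5000)]
        assert all(b > a for a, b in zip(rates, rates[1:]))
        assert rates[-1] == pytest.approx(sf.violation_rate_homog(5.0, 5.0, cfg, sf.INFINITE), rel=1e-3)

    def test_negative_rates_rejected(self, cfg):
        with pytest.raises(sf.DataError):
            sf.violation_rate_homog(-1.0, 1.0, cfg, 1)


class TestFdrMax:
    @pytest.mark.parametrize("n, expected", [(1, 0.5), (2, 2 / 3), (5, 5 / 6), (sf.INFINITE, 1.0), ("inf", 1.0)])
    def test_theoretical_maximum(self, n, expected):
        assert sf.fdr_max(n) == pytest.approx(expected, abs=1e-15)

    def test_averaged_convention_cap(self):
        assert (sf.fdr_max(1) + sf.fdr_max(sf.INFINITE)) / 2 == 0.75
        assert sf.FDR_MAX_AVERAGED == 0.75

    @pytest.mark.parametrize("n", [0, -1, 2.5, "three"])
    def test_invalid_counts_rejected(self, n):
        with pytest.raises(sf.ConfigError):
            sf.fdr_max(n)


class TestInverseHomogeneous:
    def test_desirable_cluster_at_20hz(self, cfg):
        # an ISIv of 0.5% at 20 Hz corresponds to ~5% contamination
        est = sf.fdr_from_isiv_homog(0.005, 20.0, cfg, 1)
        assert est.value == pytest.approx(0.5 * (1 - math.sqrt(0.8)), abs=1e-12)
        assert not est.capped

    def test_zero_isiv_gives_zero(self, cfg):
        est = sf.fdr_from_isiv_homog(0.0, 7.0, cfg, 2)
        assert est.value == 0.0 and not est.capped

    def test_same_isiv_at_low_rate_caps(self, cfg):
        # at 3 Hz an ISIv of 0.5% exceeds the N=1 ceiling -> imaginary root
        est = sf.fdr_from_isiv_homog(0.005, 3.0, cfg, 1)
        assert est.capped and est.value == sf.fdr_max(1) == 0.5

    def test_invalid_inputs_rejected(self, cfg):
        with pytest.raises(sf.DataError):
            sf.fdr_from_isiv_homog(0.005, 0.0, cfg, 1)
        with pytest.raises(sf.DataError):
            sf.fdr_from_isiv_homog(-0.001, 5.0, cfg, 1)

    def test_isiv_ceiling_at_cap(self, cfg):
        # maximum of 2*tau_e*R_t*f*(1-f) at f=1/2 for N=1
        assert sf.isiv_from_fdr_homog(0.5, 3.0, cfg, 1) == pytest.approx(0.00375)

    def test_forward_rejects_fdr_above_cap(self, cfg):
        with pytest.raises(sf.DataError):
            sf.isiv_from_fdr_homog(0.6, 10.0, cfg, 1)

    @settings(deadline=None, derandomize=True, max_examples=200)
    @given(
        x=st.floats(0.0, 0.999),
        r_t=st.floats(0.1, 50.0),
        n=st.sampled_from([1, 2, 5, 17, sf.INFINITE]),
        tau_c=st.sampled_from([0.0, 0.00085]),
    )
    def test_round_trip_to_machine_precision(self, x, r_t, n, tau_c):
        cfg = sf.effective_refractory(0.0025, tau_c)
        fdr = x * sf.fdr_max(n)
        isiv = sf.isiv_from_fdr_homog(fdr, r_t, cfg, n)
        est = sf.fdr_from_isiv_homog(isiv, r_t, cfg, n)
        assert not est.capped
        assert est.value == pytest.approx(fdr, abs=1e-10)

    def test_monotone_in_isiv_and_rate(self, cfg):
        isivs = np.linspace(0.0, 0.004, 30)
        vals = [sf.fdr_from_isiv_homog(v, 10.0, cfg, 1).value for v in isivs]
        assert all(b > a for a, b in zip(vals, vals[1:]))
        rates = np.linspace(4.0, 40.0, 30)
        vals_r = [sf.fdr_from_isiv_homog(0.002, r, cfg, 1).value for r in rates]
        assert all(b < a for a, b in zip(vals_r, vals_r[1:]))


class TestExpectedRateProduct:
    def test_hand_dot_product(self):
        a = sf.RateProfile(np.array([1.0, 3.0]), 0.05)
        b = sf.RateProfile(np.array([2.0, 0.0]), 0.05)
        assert sf.expected_rate_product(a, b) == pytest.approx(1.0)

    def test_constant_profiles_reduce_to_scalar_product(self):
        a = sf.RateProfile(np.full(10, 4.0), 0.05)
        b = sf.RateProfile(np.full(10, 2.5), 0.05)
        assert sf.expected_rate_product(a, b) == pytest.approx(10.0)

    def test_orthogonal_profiles_give_zero(self):
        a = sf.RateProfile(np.array([1.0, 0.0]), 0.05)
        b = sf.RateProfile(np.array([0.0, 2.0]), 0.05)
        assert sf.expected_rate_product(a, b) == 0.0

    def test_length_mismatch_rejected(self):
        a = sf.RateProfile(np.ones(4), 0.05)
        b = sf.RateProfile(np.ones(5), 0.05)
        with pytest.raises(sf.DataError):
            sf.expected_rate_product(a, b)


def _forward_isiv(tp_vals, fp_vals, cfg, n):
    """Independent brute-force oracle for the time-varying violation rate:
    per-bin expected pair production, summed and averaged over bins."""
    nv = float(n) if n is not sf.INFINITE else math.inf
    k = 1.0 - 1.0 / nv
    rv_bins = 2 * cfg.tau_e * tp_vals * fp_vals + 0.5 * k * 2 * cfg.tau_e * fp_vals**2
    rv_bar = rv_bins.mean()
    return rv_bar / (tp_vals + fp_vals).mean()


class TestInhomogeneous:
    def test_expected_product_matches_brute_force_oracle(self, cfg, library):
        tp = library["ramp_up"].scaled_to_mean(8.0)
        fp = library["bump_late"].scaled_to_mean(2.0)
        via_product = 2 * cfg.tau_e * sf.expected_rate_product(tp, fp) + \
            0.5 * 2 * cfg.tau_e * sf.expected_rate_product(fp, fp)
        brute = (2 * cfg.tau_e * tp.values * fp.values + cfg.tau_e * fp.values**2).mean()
        assert via_product == pytest.approx(brute, abs=1e-8)

    @pytest.mark.parametrize("n", [1, 2, 5, sf.INFINITE])
    def test_constant_profiles_match_homogeneous_path(self, cfg, n):
        prof = sf.RateProfile(np.full(40, 10.0), 0.05)
        unit = sf.RateProfile(np.ones(40), 0.05).unit
        for isiv in (0.0, 0.001, 0.004):
            homog = sf.fdr_from_isiv_homog(isiv, 10.0, cfg, n)
            inhom = sf.fdr_inhomog(prof, unit, isiv, cfg, n)
            assert inhom.value == pytest.approx(homog.value, abs=1e-10)
            assert inhom.capped == homog.capped

    @pytest.mark.parametrize("n", [1, 2, sf.INFINITE])
    @pytest.mark.parametrize("shapes", [("ramp_up", "ramp_down"), ("bump_early", "bump_early"), ("flat", "osc_sin")])
    def test_planted_fdr_recovered_algebraically(self, cfg, library, n, shapes):
        # analytic forward (no sampling), then inversion: exact round trip
        f, rt = 0.18, 11.0
        tp = library[shapes[0]].scaled_to_mean((1 - f) * rt)
        fp = library[shapes[1]].scaled_to_mean(f * rt)
        isiv = _forward_isiv(tp.values, fp.values, cfg, n)
        total = sf.RateProfile(tp.values + fp.values, tp.bin_width)
        est = sf.fdr_inhomog(total, library[shapes[1]].unit, isiv, cfg, n)
        assert est.value == pytest.approx(f, abs=1e-12)

    def test_fp_magnitude_round_trip(self, cfg):
        r_t = sf.RateProfile(np.full(2, 10.0), 0.05)
        unit = np.full(2, 1 / math.sqrt(2))
        f = 0.1
        isiv = _forward_isiv(r_t.values * (1 - f), r_t.values * f, cfg, 1)
        mag, capped = sf.fp_magnitude_inhomog(r_t, unit, isiv, cfg, 1)
        assert not capped
        recovered_fdr = mag * unit.mean() / r_t.mean_rate
        assert recovered_fdr == pytest.approx(f, abs=1e-12)

    def test_zero_isiv_zero_magnitude(self, cfg):
        r_t = sf.RateProfile(np.full(4, 5.0), 0.05)
        mag, capped = sf.fp_magnitude_inhomog(r_t, np.full(4, 0.5), 0.0, cfg, 1)
        assert mag == 0.0 and not capped

    def test_non_unit_vector_rejected(self, cfg):
        r_t = sf.RateProfile(np.full(4, 5.0), 0.05)
        with pytest.raises(sf.DataError):
            sf.fp_magnitude_inhomog(r_t, np.full(4, 1.0), 0.001, cfg, 1)

    def test_excess_isiv_signals_cap_not_exception(self, cfg):
        r_t = sf.RateProfile(np.full(4, 3.0), 0.05)
        unit = np.full(4, 0.5)
        mag, capped = sf.fp_magnitude_inhomog(r_t, unit, 0.005, cfg, 1)
        assert capped and math.isnan(mag)
        est = sf.fdr_inhomog(r_t, unit, 0.005, cfg, 1)
        assert est.capped and est.value == 0.5

    def test_positive_covariance_inflates_homogeneous_estimate(self, cfg, library):
        # TP and FP co-modulated in time produce more violations at the same
        # FDR, so the homogeneous inverse overestimates; anti-modulated
        # profiles produce fewer, so it underestimates.
        f, rt = 0.15, 10.0
        for tp_name, fp_name, over in [("osc_sin", "osc_sin", True), ("ramp_up", "ramp_up", True),
                                       ("bump_early", "bump_late", False), ("ramp_up", "ramp_down", False)]:
            tp = library[tp_name].scaled_to_mean((1 - f) * rt)
            fp = library[fp_name].scaled_to_mean(f * rt)
            isiv = _forward_isiv(tp.values, fp.values, cfg, 1)
            homog = sf.fdr_from_isiv_homog(isiv, rt, cfg, 1).value
            assert (homog > f) == over
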