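"""Rate theory: traversing speed, reactant integral, barrier-crossing rate,
Smoluchowski association, Einstein diffusion and the scheme algebra."""

import math

import numpy as np
import pytest

from pmmkinetics.constants import PS_TO_S, beta as beta_of
from pmmkinetics.free_energy import FreeEnergyProfile
from pmmkinetics.rates import (
    RateConstants,
    SpeedModel,
    ThermoParams,
    einstein_diffusion,
    hydrolysis_rate_kH,
    mean_traversing_speed,
    reactant_integral,
    scheme_ode_validate,
    smoluchowski_kA,
    transition_rate_KR,
    transition_rate_KR_via_delta,
    traversing_speed_from_trajectory,
)
from pmmkinetics.synthetic import gen_msd_tracks

THERMO = ThermoParams(temperature=300.0)
BETA = beta_of(300.0)


def flat_well_profile(width=0.05, barrier=38.8):
    """Flat reactant well of the given width with a sharp rise to the TS."""
    xi = np.array([0.0, 0.0125, 0.025, 0.0375, width, width + 5e-5, width + 0.01])
    da = np.array([0.0, 0.0, 0.0, 0.0, 0.0, barrier, barrier - 0.5])
    p = FreeEnergyProfile(xi=xi, delta_a=da)
    p.xi_R, p.xi_TS, p.barrier = 0.0, width + 5e-5, barrier
    return p


class TestTraversingSpeed:
    def test_maxwell_boltzmann_value(self):
        # sqrt(2 kB T/(pi mu)) for mu=17 amu at 300 K is 305.6 m/s
        assert mean_traversing_speed(THERMO, 17.0) == pytest.approx(0.3056, abs=2e-4)

    def test_temperature_and_mass_scaling(self):
        v = mean_traversing_speed(THERMO, 17.0)
        assert mean_traversing_speed(ThermoParams(1200.0), 17.0) == pytest.approx(2 * v)
        assert mean_traversing_speed(THERMO, 68.0) == pytest.approx(v / 2)

    def test_nonpositive_mass_rejected(self):
        with pytest.raises(ValueError):
            mean_traversing_speed(THERMO, 0.0)

    def test_trajectory_estimator(self):
        t = np.arange(5.0)
        xi = np.array([0.0, 0.1, -0.1, 0.1, 0.3])
        # |Δξ| steps: 0.1, 0.2, 0.2, 0.2 at Δt = 1 -> mean 0.175
        assert traversing_speed_from_trajectory(t, xi) == pytest.approx(0.175)


class TestReactantIntegral:
    def test_flat_well_is_its_width(self):
        p = FreeEnergyProfile(xi=np.linspace(0, 0.05, 11), delta_a=np.zeros(11))
        got = reactant_integral(p, THERMO, xi_m=0.0, xi_TS=0.05)
        assert got == pytest.approx(0.05, rel=1e-12)

    def test_high_barrier_region_is_suppressed(self):
        p = flat_well_profile(width=0.05, barrier=20.0)
        got = reactant_integral(p, THERMO)
        assert got == pytest.approx(0.05, rel=1e-3)

    def test_harmonic_well_gaussian_integral(self):
        kf = 500.0
        xi = np.linspace(0.05, 0.35, 601)  # well centre 0.2, ±4.3 sigma
        p = FreeEnergyProfile(xi=xi, delta_a=0.5 * kf * (xi - 0.2) ** 2)
        got = reactant_integral(p, THERMO, xi_m=xi[0], xi_TS=xi[-1])
        expected = math.sqrt(2 * math.pi / (BETA * kf))
        assert expected == pytest.approx(0.0866, abs=2e-4)
        assert got == pytest.approx(expected, rel=1e-3)

    def test_empty_range_rejected(self):
        p = FreeEnergyProfile(xi=[0, 1, 2], delta_a=[0, 1, 2])
        with pytest.raises(ValueError):
            reactant_integral(p, THERMO, xi_m=1.7, xi_TS=1.8)


class TestTransitionRate:
    def test_flat_well_closed_form(self):
        p = flat_well_profile()
        speed = SpeedModel(mu=17.0, mean_speed=0.3056)
        got = transition_rate_KR(p, THERMO, speed)
        oracle = math.exp(-BETA * 38.8) * 0.3056 / (2 * 0.05) * 1e12
        assert got == pytest.approx(oracle, rel=2e-3)
        assert got == pytest.approx(1.66e-16, rel=0.02)

    def test_barrierless_limit(self):
        w = 0.05
        p = FreeEnergyProfile(xi=np.linspace(0, w, 11), delta_a=np.zeros(11))
        p.xi_R, p.xi_TS, p.barrier = 0.0, w, 0.0
        speed = SpeedModel(mu=17.0, mean_speed=0.3)
        assert transition_rate_KR(p, THERMO, speed) == pytest.approx(
            0.3 / (2 * w) * 1e12, rel=1e-12
        )

    def test_extra_kcal_multiplies_by_boltzmann_factor(self):
        speed = SpeedModel(mu=17.0, mean_speed=0.3056)
        k0 = transition_rate_KR(flat_well_profile(barrier=10.0), THERMO, speed)
        k1 = transition_rate_KR(flat_well_profile(barrier=11.0), THERMO, speed)
        # the +1 kcal/mol point also shifts the (negligible) TS-edge strip
        assert k1 / k0 == pytest.approx(math.exp(-BETA), rel=1e-3)

    @pytest.mark.parametrize("delta", [1e-4, 1e-3, 1e-2])
    def test_ts_width_cancels(self, delta):
        p = flat_well_profile(barrier=12.0)
        speed = SpeedModel(mu=17.0, mean_speed=0.3056)
        direct = transition_rate_KR(p, THERMO, speed)
        via_delta = transition_rate_KR_via_delta(p, THERMO, speed, delta)
        assert via_delta == pytest.approx(direct, rel=1e-12)


class TestSmoluchowski:
    def test_published_scale(self):
        # D_sum = 6.17e-9 m²/s with r0 = 1.2 nm gives 0.056 ps⁻¹M⁻¹
        assert smoluchowski_kA(6.17e-3, 1.2) == pytest.approx(0.056, abs=5e-4)

    def test_zero_diffusion(self):
        assert smoluchowski_kA(0.0, 1.2) == 0.0

    def test_linear_in_radius_and_diffusion(self):
        base = smoluchowski_kA(1e-3, 1.0)
        assert smoluchowski_kA(1e-3, 2.0) == pytest.approx(2 * base)
        assert smoluchowski_kA(2e-3, 1.0) == pytest.approx(2 * base)

    def test_invalid_radius(self):
        with pytest.raises(ValueError):
            smoluchowski_kA(1e-3, 0.0)


class TestEinsteinDiffusion:
    def test_exact_line(self):
        t = np.linspace(0, 100, 101)
        assert einstein_diffusion(t, 6e-3 * t) == pytest.approx(1e-3, rel=1e-12)

    def test_offset_does_not_bias(self):
        t = np.linspace(0, 100, 101)
        assert einstein_diffusion(t, 6e-3 * t + 0.4) == pytest.approx(1e-3, rel=1e-12)

    def test_brownian_track_recovery(self):
        times, sq = gen_msd_tracks(D=1e-3, step=0.02, n_steps=10_000, n_tracks=100, seed=5)
        got = einstein_diffusion(times, sq.mean(axis=0))
        assert got == pytest.approx(1e-3, rel=0.10)

    def test_degenerate_input_rejected(self):
        with pytest.raises(ValueError):
            einstein_diffusion(np.zeros(20), np.zeros(20))


class TestSchemeAlgebra:
    def test_published_inputs_reproduce_overall_constant(self, published_rates):
        full, approx = hydrolysis_rate_kH(published_rates)
        assert full == pytest.approx(2.417e-15, rel=0.01)
        assert approx == pytest.approx(2.417e-15, rel=0.01)

    def test_vanishing_barrier_rate_kills_the_reaction(self, published_rates):
        r = published_rates
        small = RateConstants(kA=r.kA, k1=r.k1, k_minus1=r.k_minus1, k2=r.k2, KR=1e-25)
        smaller = RateConstants(kA=r.kA, k1=r.k1, k_minus1=r.k_minus1, k2=r.k2, KR=1e-26)
        f1, _ = hydrolysis_rate_kH(small)
        f2, _ = hydrolysis_rate_kH(smaller)
        assert f1 / f2 == pytest.approx(10.0, rel=1e-6)  # kH ∝ KR in the limit

    def test_full_and_approximate_agree_when_KR_is_negligible(self, published_rates):
        full, approx = hydrolysis_rate_kH(published_rates)
        assert abs(full - approx) / full < 1e-10

    def test_overall_rate_below_association_rate(self, rng):
        # algebraic bound kH < kA for any positive rate tuple
        for _ in range(10_000):
            k = 10.0 ** rng.uniform(-6, 0, size=4)
            kr_ps = 10.0 ** rng.uniform(-30, -1)
            rc = RateConstants(
                kA=k[0], k1=k[1], k_minus1=k[2], k2=k[3], KR=kr_ps / PS_TO_S
            )
            full, _ = hydrolysis_rate_kH(rc)
            assert full * PS_TO_S < rc.kA


class TestSchemeOde:
    def fast_rates(self):
        # KR raised to a desk-testable 1e-3 ps⁻¹; published values otherwise
        return RateConstants(
            kA=0.056, k1=0.030, k_minus1=0.0049, k2=0.007, KR=1e-3 / PS_TO_S
        )

    def test_effective_rate_matches_steady_state_algebra(self):
        rc = self.fast_rates()
        ov = scheme_ode_validate(rc, hydroxide=1e-3)
        assert ov.effective_rate == pytest.approx(ov.predicted_rate, rel=0.02)

    def test_mass_conservation(self):
        ov = scheme_ode_validate(self.fast_rates(), hydroxide=1e-3)
        assert ov.conservation_error < 1e-9

    def test_no_reaction_conserves_substrate(self):
        rc = RateConstants(kA=0.056, k1=0.030, k_minus1=0.0049, k2=0.007, KR=0.0)
        ov = scheme_ode_validate(rc, hydroxide=1e-3, horizon=1e4)
        substrate_pool = ov.concentrations[:3].sum(axis=0)
        np.testing.assert_allclose(substrate_pool, substrate_pool[0], rtol=1e-9)
        assert np.all(ov.concentrations[3] < 1e-20)

    def test_pseudo_first_order_in_hydroxide(self):
        rc = self.fast_rates()
        r1 = scheme_ode_validate(rc, hydroxide=5e-4).effective_rate
        r2 = scheme_ode_validate(rc, hydroxide=1e-3).effective_rate
        assert r2 / r1 == pytest.approx(2.0, rel=0.02)
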