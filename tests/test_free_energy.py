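"""Windowed free-energy reconstruction: exponential averaging, stitching,
bidirectional averaging and barrier location."""

import numpy as np
import pytest

from pmmkinetics.constants import beta as beta_of
from pmmkinetics.free_energy import (
    FreeEnergyProfile,
    NoBarrierError,
    StitchError,
    Window,
    average_profiles,
    locate_barrier,
    reconstruct_profile,
    zwanzig_step,
)
from pmmkinetics.synthetic import (
    WindowGeneratorSpec,
    default_target_profile,
    gen_windows,
)

T = 300.0


class TestZwanzigStep:
    def test_zero_samples_give_zero(self):
        da, ess = zwanzig_step(np.zeros(100), T)
        assert da == pytest.approx(0.0, abs=1e-14)
        assert ess == pytest.approx(100.0)

    @pytest.mark.parametrize("c", [-3.0, 0.7, 1000.0])
    def test_constant_shift_passes_through(self, c):
        # huge constants also exercise the log-sum-exp overflow guard
        da, _ = zwanzig_step(np.full(50, c), T)
        assert da == pytest.approx(c, rel=1e-12)

    def test_gaussian_closed_form(self, rng):
        # ΔA = m − βσ²/2 for Gaussian ΔU; m=2, σ²=1 at 300 K -> 1.1613
        samples = rng.normal(2.0, 1.0, size=200_000)
        da, ess = zwanzig_step(samples, T)
        assert da == pytest.approx(2.0 - beta_of(T) / 2.0, abs=0.03)
        assert 0 < ess < 200_000

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            zwanzig_step([], T)


def constant_window(index, xi, xi_ref, du, n_frames=40):
    """Window whose ΔU to every non-reference point is the constant du."""
    u = np.zeros((len(xi), n_frames))
    for i, x in enumerate(xi):
        if x != xi_ref:
            u[i] = du
    return Window(index=index, xi_ref=xi_ref, xi=np.asarray(xi, float), u=u)


class TestReconstruction:
    def test_two_constant_windows_telescope(self):
        w1 = constant_window(1, [0.0, 1.0], 0.0, 1.0)
        w2 = constant_window(2, [1.0, 2.0], 1.0, 1.0)
        profile = reconstruct_profile([w1, w2], T, "forward")
        np.testing.assert_allclose(profile.delta_a, [0.0, 1.0, 2.0], atol=1e-12)

    def test_single_window_degenerate_stitching(self, rng):
        xi = np.array([0.0, 0.1, 0.2])
        u = np.vstack([np.zeros(30), rng.normal(1.0, 0.3, 30), rng.normal(-0.5, 0.3, 30)])
        win = Window(index=1, xi_ref=0.0, xi=xi, u=u)
        profile = reconstruct_profile([win], T, "forward")
        expected = np.array([zwanzig_step(u[i] - u[0], T)[0] for i in range(3)])
        expected -= expected.min()
        np.testing.assert_allclose(profile.delta_a, expected, atol=1e-12)

    def test_five_gaussian_windows_match_analytic(self):
        target = default_target_profile(barrier=12.0)
        spec = WindowGeneratorSpec.from_profile(target, n_windows=5, frames=5000)
        windows, analytic = gen_windows(spec, seed=7)
        fwd = reconstruct_profile(windows, T, "forward")
        bwd = reconstruct_profile(windows, T, "backward")
        avg = average_profiles(fwd, bwd)
        np.testing.assert_allclose(avg.xi, analytic.xi, atol=1e-9)
        assert np.max(np.abs(avg.delta_a - analytic.delta_a)) < 0.35

    def test_split_window_reproduces_unsplit_exactly(self, rng):
        # exact when the energies beyond the split differ deterministically
        base = rng.normal(0.0, 0.5, 25)
        u = np.vstack([np.zeros(25), base, base + 0.8, base + 1.1])
        xi = np.array([0.0, 0.1, 0.2, 0.3])
        unsplit = reconstruct_profile(
            [Window(index=1, xi_ref=0.0, xi=xi, u=u)], T, "forward"
        )
        win_a = Window(index=1, xi_ref=0.0, xi=xi[:2], u=u[:2])
        win_b = Window(index=2, xi_ref=0.1, xi=xi[1:], u=u[1:])
        split = reconstruct_profile([win_a, win_b], T, "forward")
        np.testing.assert_allclose(split.delta_a, unsplit.delta_a, atol=1e-10)

    def test_gauge_invariance_under_e0_shift(self, rng):
        target = default_target_profile(barrier=5.0, n_points=21)
        spec = WindowGeneratorSpec.from_profile(target, n_windows=3, frames=200)
        windows, _ = gen_windows(spec, seed=3)
        shifted = [
            Window(index=w.index, xi_ref=w.xi_ref, xi=w.xi, u=w.u + 100.0 * (i + 1))
            for i, w in enumerate(windows)
        ]
        p0 = reconstruct_profile(windows, T, "forward")
        p1 = reconstruct_profile(shifted, T, "forward")
        np.testing.assert_allclose(p0.delta_a, p1.delta_a, atol=1e-9)

    def test_non_overlapping_windows_rejected(self):
        w1 = constant_window(1, [0.0, 1.0], 0.0, 1.0)
        w2 = constant_window(2, [1.5, 2.0], 1.5, 1.0)
        with pytest.raises(StitchError):
            reconstruct_profile([w1, w2], T, "forward")


class TestAveraging:
    def test_idempotent_on_identical_profiles(self):
        p = FreeEnergyProfile(xi=[0, 1, 2], delta_a=[0.0, 2.0, 1.0]).rezero()
        q = FreeEnergyProfile(xi=[0, 1, 2], delta_a=[0.0, 2.0, 1.0]).rezero()
        avg = average_profiles(p, q)
        np.testing.assert_allclose(avg.delta_a, p.delta_a, atol=1e-12)
        assert avg.direction == "averaged"

    def test_constant_offset_is_gauged_away(self):
        p = FreeEnergyProfile(xi=[0, 1, 2], delta_a=[0.0, 2.0, 1.0])
        q = FreeEnergyProfile(xi=[0, 1, 2], delta_a=[5.0, 7.0, 6.0])
        avg = average_profiles(p, q)
        np.testing.assert_allclose(avg.delta_a, [0.0, 2.0, 1.0], atol=1e-12)

    def test_grid_mismatch_rejected(self):
        p = FreeEnergyProfile(xi=[0, 1, 2], delta_a=[0, 1, 2])
        q = FreeEnergyProfile(xi=[0, 1, 3], delta_a=[0, 1, 2])
        with pytest.raises(ValueError, match="grid"):
            average_profiles(p, q)

    def test_average_beats_the_worse_direction(self):
        target = default_target_profile(barrier=8.0, n_points=21)
        spec = WindowGeneratorSpec.from_profile(target, n_windows=3, frames=150)
        err_avg, err_worse = [], []
        for rep in range(100):
            windows, analytic = gen_windows(spec, seed=1000 + rep)
            fwd = reconstruct_profile(windows, T, "forward")
            bwd = reconstruct_profile(windows, T, "backward")
            avg = average_profiles(fwd, bwd)
            ef = np.mean(np.abs(fwd.delta_a - analytic.delta_a))
            eb = np.mean(np.abs(bwd.delta_a - analytic.delta_a))
            err_avg.append(np.mean(np.abs(avg.delta_a - analytic.delta_a)))
            err_worse.append(max(ef, eb))
        assert np.mean(err_avg) < np.mean(err_worse)


class TestLocateBarrier:
    def test_constructed_extrema(self):
        xi = np.array([0.0, 0.2, 0.5])
        da = np.array([0.4, 0.0, 3.0])
        xi_r, xi_ts, barrier = locate_barrier(FreeEnergyProfile(xi=xi, delta_a=da))
        assert (xi_r, xi_ts) == (0.2, 0.5)
        assert barrier == pytest.approx(3.0)

    def test_equal_minima_tie_breaks_to_smallest_xi(self):
        xi = np.linspace(0, 4, 5)
        da = np.array([0.0, 2.0, 0.0, 2.0, 1.0])
        xi_r, xi_ts, _ = locate_barrier(FreeEnergyProfile(xi=xi, delta_a=da))
        assert xi_r == 0.0
        assert xi_ts == 1.0  # first of the equal maxima beyond xi_R

    def test_monotone_profile_has_no_barrier(self):
        p = FreeEnergyProfile(xi=[0, 1, 2, 3], delta_a=[0, 1, 2, 3])
        with pytest.raises(NoBarrierError):
            locate_barrier(p)

    def test_generator_barrier_recovered(self):
        target = default_target_profile(barrier=10.0)
        spec = WindowGeneratorSpec.from_profile(target, n_windows=5, frames=4000)
        windows, _ = gen_windows(spec, seed=11)
        avg = average_profiles(
            reconstruct_profile(windows, T, "forward"),
            reconstruct_profile(windows, T, "backward"),
        )
        assert avg.barrier == pytest.approx(10.0, abs=0.4)
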