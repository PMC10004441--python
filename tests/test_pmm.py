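"""Electrostatic embedding: Coulomb sums, charge-level and matrix-level
perturbed energies."""

import math

import numpy as np
import pytest

from pmmkinetics.constants import COULOMB_KCAL_NM
from pmmkinetics.pmm import (
    DegenerateGeometryError,
    EnvironmentSnapshot,
    QuantumCenterFrame,
    coulomb_potential_field,
    delta_U_series,
    perturb_ground_state,
    perturb_matrix,
)


def make_frame(charges, positions, e0=0.0, xi=0.0):
    charges = np.asarray(charges, dtype=float)
    return QuantumCenterFrame(
        xi=xi, e0=e0, elements=("X",) * charges.size,
        positions=np.asarray(positions, dtype=float), charges=charges,
    )


def snapshot(positions, charges):
    return EnvironmentSnapshot(
        positions=np.asarray(positions, dtype=float),
        charges=np.asarray(charges, dtype=float),
    )


class TestCoulombPotentialField:
    def test_unit_charge_at_unit_distance(self):
        snap = snapshot([[1.0, 0.0, 0.0]], [1.0])
        phi, field = coulomb_potential_field(snap, [0.0, 0.0, 0.0])
        assert phi == pytest.approx(COULOMB_KCAL_NM, rel=1e-12)
        # field points from the source towards the evaluation point
        np.testing.assert_allclose(field, [-COULOMB_KCAL_NM, 0.0, 0.0], rtol=1e-12)

    def test_empty_snapshot_is_zero(self):
        snap = snapshot(np.empty((0, 3)), [])
        phi, field = coulomb_potential_field(snap, [0.3, 0.1, -0.2])
        assert phi == 0.0
        np.testing.assert_array_equal(field, np.zeros(3))

    def test_symmetric_dipole_cancels_potential(self):
        snap = snapshot([[1.0, 0, 0], [-1.0, 0, 0]], [1.0, -1.0])
        phi, _ = coulomb_potential_field(snap, [0.0, 0.0, 0.0])
        assert phi == pytest.approx(0.0, abs=1e-14)

    def test_close_contact_raises(self):
        snap = snapshot([[0.01, 0, 0]], [1.0])
        with pytest.raises(DegenerateGeometryError):
            coulomb_potential_field(snap, [0.0, 0.0, 0.0])


class TestChargeLevelEmbedding:
    def test_empty_environment_returns_e0(self):
        frame = make_frame([0.4, -0.4], [[0, 0, 0], [0.1, 0, 0]], e0=-7.3)
        empty = snapshot(np.empty((0, 3)), [])
        assert perturb_ground_state(frame, empty) == -7.3

    def test_single_pair_oracle(self):
        # +1 e QC atom, +1 e source 1 nm away: U = e0 + Coulomb constant
        frame = make_frame([1.0], [[0.0, 0.0, 0.0]], e0=-10.0)
        snap = snapshot([[1.0, 0, 0]], [1.0])
        assert perturb_ground_state(frame, snap) == pytest.approx(
            -10.0 + COULOMB_KCAL_NM, rel=1e-12
        )

    def test_neutral_centre_forgets_distant_sources(self):
        frame = make_frame([1.0, -1.0], [[0, 0, 0], [0.1, 0, 0]], e0=2.0)
        shifts = []
        for dist in (10.0, 100.0):
            snap = snapshot([[dist, 0, 0]], [1.0])
            shifts.append(abs(perturb_ground_state(frame, snap) - 2.0))
        assert shifts[1] < shifts[0] / 50  # dipole coupling decays ~1/r²
        assert shifts[1] < 1e-3

    def test_additive_over_environment_charges(self, rng):
        frame = make_frame(
            rng.uniform(-0.8, 0.8, 5), rng.uniform(-0.1, 0.1, (5, 3)), e0=1.0
        )
        positions = rng.uniform(1.0, 2.0, (20, 3))
        charges = rng.uniform(-1, 1, 20)
        full = perturb_ground_state(frame, snapshot(positions, charges)) - 1.0
        singles = sum(
            perturb_ground_state(frame, snapshot(positions[i : i + 1], charges[i : i + 1]))
            - 1.0
            for i in range(20)
        )
        assert full == pytest.approx(singles, rel=1e-10)

    def test_uniform_potential_shift_scales_with_total_charge(self):
        # emulate a uniform potential by shifting phi analytically: a QC of
        # total charge q_T in potential phi gains q_T*phi at charge level
        for charges, expected in (([0.5, 0.5], 1.0), ([0.5, -0.5], 0.0)):
            frame = make_frame(charges, [[0, 0, 0], [0.05, 0, 0]])
            # one very distant charge: phi nearly constant across the QC
            snap = snapshot([[5000.0, 0, 0]], [1.0])
            phi_far = COULOMB_KCAL_NM / 5000.0
            got = perturb_ground_state(frame, snap)
            assert got == pytest.approx(expected * phi_far, abs=1e-6)


class TestMatrixLevel:
    def test_two_state_closed_form(self):
        # H = [[0, 2], [2, 10]] -> ground eigenvalue 5 - sqrt(29)
        mu = np.zeros((2, 2, 3))
        mu[0, 1, 0] = mu[1, 0, 0] = -2.0
        got = perturb_matrix([0.0, 10.0], mu, total_charge=0.0,
                             potential=0.0, efield=[1.0, 0.0, 0.0])
        assert got == pytest.approx(5.0 - math.sqrt(29.0), rel=1e-12)

    def test_unperturbed_limit_returns_lowest_state(self):
        mu = np.zeros((2, 2, 3))
        got = perturb_matrix([3.0, 7.0], mu, 1.0, 0.0, np.zeros(3))
        assert got == 3.0

    def test_single_state_reduces_to_first_order(self):
        mu = np.zeros((1, 1, 3))
        got = perturb_matrix([1.0], mu, total_charge=-2.0, potential=5.0,
                             efield=np.zeros(3))
        assert got == pytest.approx(-9.0, rel=1e-12)

    def test_asymmetric_dipole_matrix_rejected(self):
        mu = np.zeros((2, 2, 3))
        mu[0, 1, 0] = 1.0  # no mirror entry
        with pytest.raises(ValueError, match="symmetric"):
            perturb_matrix([0.0, 1.0], mu, 0.0, 0.0, np.zeros(3))

    def test_weak_field_error_is_quadratic(self):
        # ground eigenvalue approaches the first-order value as O(E²)
        mu = np.zeros((2, 2, 3))
        mu[0, 0, 0] = 0.3
        mu[1, 1, 0] = -0.1
        mu[0, 1, 0] = mu[1, 0, 0] = 0.5
        errs = []
        for e in (0.01, 0.02):
            field = np.array([e, 0.0, 0.0])
            exact = perturb_matrix([0.0, 5.0], mu, 0.0, 0.0, field)
            first_order = 0.0 - e * mu[0, 0, 0]
            errs.append(abs(exact - first_order))
        assert errs[1] / errs[0] == pytest.approx(4.0, rel=0.05)


class TestDeltaUSeries:
    def test_identity_is_zero(self, rng):
        frame = make_frame([0.3, -0.3], [[0, 0, 0], [0.1, 0, 0]], e0=1.0)
        snaps = [
            snapshot(rng.uniform(1, 2, (4, 3)), rng.uniform(-1, 1, 4))
            for _ in range(6)
        ]
        np.testing.assert_allclose(delta_U_series(frame, frame, snaps), 0.0, atol=1e-12)

    def test_pure_e0_shift(self, rng):
        a = make_frame([0.3, -0.3], [[0, 0, 0], [0.1, 0, 0]], e0=2.5)
        b = make_frame([0.3, -0.3], [[0, 0, 0], [0.1, 0, 0]], e0=1.0)
        snaps = [
            snapshot(rng.uniform(1, 2, (4, 3)), rng.uniform(-1, 1, 4))
            for _ in range(5)
        ]
        np.testing.assert_allclose(delta_U_series(a, b, snaps), 1.5, rtol=1e-12)

    def test_single_charge_difference_oracle(self):
        target = make_frame([1.0], [[0.0, 0.0, 0.0]], e0=3.0)
        reference = make_frame([0.0], [[0.0, 0.0, 0.0]], e0=1.0)
        snaps = [snapshot([[1.0, 0, 0]], [1.0])]
        got = delta_U_series(target, reference, snaps)
        assert got[0] == pytest.approx(2.0 + COULOMB_KCAL_NM, rel=1e-12)

    def test_frame_invariants(self):
        with pytest.raises(ValueError, match="charge sum"):
            make_frame_bad = QuantumCenterFrame(
                xi=0.0, e0=0.0, elements=("X",), positions=[[0, 0, 0]],
                charges=[0.5], total_charge=0.0,
            )
        with pytest.raises(ValueError, match="at least one atom"):
            QuantumCenterFrame(
                xi=0.0, e0=0.0, elements=(), positions=np.empty((0, 3)), charges=[],
            )
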