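"""Perturbed-matrix-method (PMM) electrostatic embedding of a quantum centre.

A *quantum centre* (QC) — here a phosphate-plus-hydroxide fragment held rigid
at one point ξ of the reaction coordinate — carries an unperturbed ground-state
electronic energy, ESP-fitted atomic partial charges and a permanent dipole
taken from gas-phase electronic-structure calculations.  The classical
environment (solvent, counter-ions) enters only through its point charges,
which perturb the QC electronic energy.  Two perturbation levels are offered:

* **charge level** (default): first-order embedding through the atomic
  charges, ``U = e0 + Σ_a q_a φ(r_a)`` — the natural level when only ground
  state charges are available.
* **matrix level**: diagonalisation of the perturbed Hamiltonian
  ``H̃ij = εi δij + q_T φ δij − E⃗·μ⃗ij`` built on a small basis of unperturbed
  electronic states with a transition-dipole matrix; the perturbed ground
  energy is its lowest eigenvalue.

Both are approximations that neglect short-range/higher-multipole terms;
environment charge lists are treated as finite (no periodicity, no cutoff —
truncation is the caller's responsibility).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .constants import COULOMB_KCAL_NM

__all__ = [
    "DegenerateGeometryError",
    "QuantumCenterFrame",
    "EnvironmentSnapshot",
    "PerturbedEnergySeries",
    "coulomb_potential_field",
    "perturb_ground_state",
    "perturb_matrix",
    "delta_U_series",
]

#: Default minimum source–target separation (nm) below which the Coulomb sum
#: is considered singular.
MIN_SEPARATION_NM = 0.05


class DegenerateGeometryError(ValueError):
    """An environment charge sits (numerically) on top of a target point."""


@dataclass(frozen=True)
class QuantumCenterFrame:
    """One point of the reaction profile: the rigid QC and its QM properties.

    Parameters
    ----------
    xi : float
        Reaction-coordinate value (nm).
    e0 : float
        Unperturbed ground-state electronic energy (kcal/mol).
    elements : tuple of str
        Atom element labels.
    positions : (n_atoms, 3) array
        Atom positions (nm).
    charges : (n_atoms,) array
        ESP-fitted partial charges (e).
    dipole : (3,) array
        Permanent ground-state dipole (e·nm).
    total_charge : float, optional
        Declared total charge; defaults to the charge sum.  A mismatch
        beyond 1e-6 e is rejected.
    excited_energies, dipole_matrix : optional
        Unperturbed excited-state energies (kcal/mol, ground first) and the
        full dipole/transition-dipole matrix (n_states, n_states, 3) in e·nm,
        for the matrix-level perturbation.
    """

    xi: float
    e0: float
    elements: tuple
    positions: np.ndarray
    charges: np.ndarray
    dipole: np.ndarray = field(default_factory=lambda: np.zeros(3))
    total_charge: float | None = None
    excited_energies: np.ndarray | None = None
    dipole_matrix: np.ndarray | None = None

    def __post_init__(self):
        pos = np.atleast_2d(np.asarray(self.positions, dtype=float))
        chg = np.asarray(self.charges, dtype=float).ravel()
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "charges", chg)
        object.__setattr__(self, "dipole", np.asarray(self.dipole, dtype=float).ravel())
        if pos.shape[0] < 1:
            raise ValueError("quantum centre needs at least one atom")
        if pos.shape != (chg.size, 3):
            raise ValueError(
                f"positions {pos.shape} inconsistent with {chg.size} charges"
            )
        if not np.all(np.isfinite(chg)):
            raise ValueError("non-finite atomic charge")
        total = float(chg.sum()) if self.total_charge is None else float(self.total_charge)
        if abs(chg.sum() - total) > 1e-6:
            raise ValueError(
                f"charge sum {chg.sum():.8f} != declared total {total:.8f}"
            )
        object.__setattr__(self, "total_charge", total)

    @property
    def n_atoms(self) -> int:
        return self.positions.shape[0]


@dataclass(frozen=True)
class EnvironmentSnapshot:
    """Classical point charges perturbing the QC at one MD frame."""

    positions: np.ndarray  # (m, 3) nm
    charges: np.ndarray  # (m,) e
    time: float = 0.0  # ps

    def __post_init__(self):
        pos = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        chg = np.asarray(self.charges, dtype=float).ravel()
        if pos.shape[0] != chg.size:
            raise ValueError("positions / charges length mismatch")
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "charges", chg)

    def __len__(self) -> int:
        return self.charges.size

    @property
    def net_charge(self) -> float:
        return float(self.charges.sum())


@dataclass(frozen=True)
class PerturbedEnergySeries:
    """Perturbed energies U (kcal/mol) of one ξ point, one value per frame."""

    xi: float
    values: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float).ravel())

    def __len__(self) -> int:
        return self.values.size


def coulomb_potential_field(
    snapshot: EnvironmentSnapshot,
    point: np.ndarray,
    min_separation: float = MIN_SEPARATION_NM,
) -> tuple[float, np.ndarray]:
    """Electrostatic potential and field of a charge list at one point.

    Returns ``(φ, E⃗)`` with φ in kcal/(mol·e) and E⃗ in kcal/(mol·e·nm):
    ``φ = f Σ qᵢ/rᵢ`` and ``E⃗ = f Σ qᵢ r⃗ᵢ/rᵢ³`` (r⃗ᵢ from source i to the
    point), f the Coulomb constant in internal units.

    Raises
    ------
    DegenerateGeometryError
        If any source lies closer than ``min_separation`` to the point.
    """
    point = np.asarray(point, dtype=float).ravel()
    if len(snapshot) == 0:
        return 0.0, np.zeros(3)
    rvec = point[None, :] - snapshot.positions  # source -> point
    r = np.linalg.norm(rvec, axis=1)
    if np.any(r < min_separation):
        raise DegenerateGeometryError(
            f"environment charge within {min_separation} nm of target point "
            f"(closest: {r.min():.4g} nm)"
        )
    q = snapshot.charges
    phi = COULOMB_KCAL_NM * float(np.sum(q / r))
    efield = COULOMB_KCAL_NM * (q[:, None] * rvec / r[:, None] ** 3).sum(axis=0)
    return phi, efield


def perturb_ground_state(
    frame: QuantumCenterFrame,
    snapshot: EnvironmentSnapshot,
    min_separation: float = MIN_SEPARATION_NM,
) -> float:
    """Charge-level embedding: ``U = e0 + Σ_a q_a φ(r_a)`` (kcal/mol)."""
    if len(snapshot) == 0:
        return float(frame.e0)
    u = frame.e0
    for pos, q in zip(frame.positions, frame.charges):
        phi, _ = coulomb_potential_field(snapshot, pos, min_separation)
        u += q * phi
    return float(u)


def perturb_matrix(
    energies: Sequence[float],
    dipole_matrix: np.ndarray,
    total_charge: float,
    potential: float,
    efield: np.ndarray,
) -> float:
    """Matrix-level PMM: ground eigenvalue of the perturbed Hamiltonian.

    ``H̃ij = εi δij + q_T φ δij − E⃗·μ⃗ij`` on the unperturbed electronic
    basis.  With one basis state this reduces exactly to the first-order
    expression ``ε0 + q_T φ − E⃗·μ⃗00``; with zero potential and field it
    returns ``min εi``.

    Parameters
    ----------
    energies : sequence of float
        Unperturbed state energies εi (kcal/mol).
    dipole_matrix : (n, n, 3) array
        Dipole and transition-dipole matrix elements μ⃗ij (e·nm); must be
        symmetric in (i, j).
    total_charge : float
        QC total charge q_T (e).
    potential, efield
        Environment potential (kcal/(mol·e)) and field (kcal/(mol·e·nm))
        at the QC expansion origin.
    """
    eps = np.asarray(energies, dtype=float).ravel()
    if eps.size < 1:
        raise ValueError("need at least one basis state")
    mu = np.asarray(dipole_matrix, dtype=float)
    if mu.shape != (eps.size, eps.size, 3):
        raise ValueError(
            f"dipole matrix shape {mu.shape} != ({eps.size}, {eps.size}, 3)"
        )
    if not np.allclose(mu, mu.transpose(1, 0, 2), atol=1e-12):
        raise ValueError("dipole matrix must be Hermitian-symmetric")
    efield = np.asarray(efield, dtype=float).ravel()
    h = np.diag(eps + total_charge * potential) - np.einsum("ijk,k->ij", mu, efield)
    return float(np.linalg.eigvalsh(h)[0])


def delta_U_series(
    target: QuantumCenterFrame,
    reference: QuantumCenterFrame,
    snapshots: Sequence[EnvironmentSnapshot],
    min_separation: float = MIN_SEPARATION_NM,
) -> np.ndarray:
    """Per-frame ΔU = U(ξ) − U(ξref), both perturbed by the *same* snapshot.

    The snapshots are configurations sampled in the reference-ξ ensemble;
    the target QC is evaluated in each of them (free-energy perturbation
    convention).  Returns an array of length ``len(snapshots)``.
    """
    out = np.empty(len(snapshots))
    for i, snap in enumerate(snapshots):
        out[i] = perturb_ground_state(target, snap, min_separation) - perturb_ground_state(
            reference, snap, min_separation
        )
    return out
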