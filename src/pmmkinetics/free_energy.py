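"""Landau free-energy profile reconstruction from windowed perturbed energies.

The reaction coordinate is split into N windows, each holding an MD ensemble
generated with the quantum centre fixed at a reference point ξref,n.  Within a
window, the free-energy change from ξref to any nearby grid point ξ follows
from exponential (Zwanzig) averaging of the per-frame perturbed-energy
difference ΔU = U(ξ) − U(ξref):

    ΔA(ξref → ξ) = −kB T · ln ⟨exp(−β ΔU)⟩_ξref

Window estimates are chained at shared reference grid points into a full
profile; a forward (ξref,1 → ξref,N) and a backward (ξref,N → ξref,1) pass
estimate each inter-reference sub-range in the two flanking ensembles, and
their pointwise average is the final profile.  The reactant minimum ξR, the
transition state ξTS and the barrier ΔA‡ = ΔA(ξTS) − ΔA(ξR) are located on
the assembled profile.

Exponential averaging is accurate only while the target ensemble overlaps the
sampled one; the effective sample size (ESS) of each exponential average is
reported per grid point as an overlap diagnostic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.special import logsumexp

from .constants import KB_KCAL, beta as beta_of

__all__ = [
    "Window",
    "FreeEnergyProfile",
    "NoBarrierError",
    "StitchError",
    "zwanzig_step",
    "reconstruct_profile",
    "average_profiles",
    "locate_barrier",
]

logger = logging.getLogger(__name__)

#: Grid points whose exponential average has fewer effective samples than
#: this are flagged in the log as poor-overlap estimates.
ESS_WARN_THRESHOLD = 10.0

_XI_DECIMALS = 9  # grid values compared after rounding to this precision


class NoBarrierError(ValueError):
    """Profile has no interior maximum above the reactant minimum."""


class StitchError(ValueError):
    """Adjacent windows do not share the grid point needed for chaining."""


@dataclass
class Window:
    """One sampling window: perturbed energies on a local ξ grid.

    ``u`` holds the perturbed energy U (kcal/mol) for every grid point
    (rows) and every frame of the ξref ensemble (columns); all rows refer
    to the same frames.
    """

    index: int
    xi_ref: float
    xi: np.ndarray  # (n_xi,) strictly increasing
    u: np.ndarray  # (n_xi, n_frames)

    def __post_init__(self):
        self.xi = np.asarray(self.xi, dtype=float).ravel()
        self.u = np.atleast_2d(np.asarray(self.u, dtype=float))
        if self.u.shape[0] != self.xi.size:
            raise ValueError("one energy series required per grid point")
        if np.any(np.diff(self.xi) <= 0):
            raise ValueError("window grid must be strictly increasing")
        if self._index_of(self.xi_ref) is None:
            raise ValueError(f"xi_ref={self.xi_ref} is not a window grid point")

    @classmethod
    def from_series(
        cls, index: int, xi_ref: float, series: Mapping[float, Sequence[float]]
    ) -> "Window":
        """Build from a mapping ξ → per-frame perturbed energies."""
        xis = np.array(sorted(series), dtype=float)
        u = np.vstack([np.asarray(series[x], dtype=float) for x in sorted(series)])
        return cls(index=index, xi_ref=xi_ref, xi=xis, u=u)

    @property
    def n_frames(self) -> int:
        return self.u.shape[1]

    def _index_of(self, xi: float) -> int | None:
        hit = np.flatnonzero(np.round(self.xi - xi, _XI_DECIMALS) == 0)
        return int(hit[0]) if hit.size else None

    def delta_u(self, xi: float) -> np.ndarray:
        """Per-frame ΔU = U(ξ) − U(ξref); exactly zero at ξref."""
        i = self._index_of(xi)
        if i is None:
            raise KeyError(f"xi={xi} not on window {self.index} grid")
        iref = self._index_of(self.xi_ref)
        return self.u[i] - self.u[iref]


@dataclass
class FreeEnergyProfile:
    """ΔA(ξ) relative to the reactant minimum, with located extrema.

    ``direction`` records whether the profile came from the forward pass,
    the backward pass, the forward/backward average, or an analytic
    generator ("exact").
    """

    xi: np.ndarray
    delta_a: np.ndarray
    direction: str = "forward"
    ess: np.ndarray | None = None
    xi_m: float | None = None  # lower bound of the reactant well
    xi_R: float | None = None
    xi_TS: float | None = None
    barrier: float | None = None

    def __post_init__(self):
        self.xi = np.asarray(self.xi, dtype=float).ravel()
        self.delta_a = np.asarray(self.delta_a, dtype=float).ravel()
        if self.xi.size != self.delta_a.size:
            raise ValueError("xi / delta_a length mismatch")
        if np.any(np.diff(self.xi) <= 0):
            raise ValueError("profile grid must be strictly increasing")
        if self.ess is not None:
            self.ess = np.asarray(self.ess, dtype=float).ravel()
        if self.xi_m is None:
            self.xi_m = float(self.xi[0])

    def rezero(self) -> "FreeEnergyProfile":
        """Shift so ΔA = 0 at the grid minimum and record it as ξR."""
        i = int(np.argmin(self.delta_a))
        self.delta_a = self.delta_a - self.delta_a[i]
        self.xi_R = float(self.xi[i])
        return self


def zwanzig_step(delta_u: Sequence[float], temperature: float) -> tuple[float, float]:
    """Exponential-average free-energy change and its effective sample size.

    ΔA = −kB T ln ⟨exp(−β ΔU)⟩ evaluated through a log-sum-exp, so the
    result is invariant to shifting all ΔU by a constant and immune to
    overflow.  The effective sample size ESS = (Σw)²/Σw² of the Boltzmann
    weights w = exp(−β ΔU) measures how many frames actually contribute.
    """
    du = np.asarray(delta_u, dtype=float).ravel()
    if du.size == 0:
        raise ValueError("zwanzig_step needs at least one sample")
    b = beta_of(temperature)
    log_w = -b * du
    delta_a = -KB_KCAL * temperature * (logsumexp(log_w) - np.log(du.size))
    # ESS from shifted weights (shift cancels in the ratio)
    w = np.exp(log_w - log_w.max())
    ess = float(w.sum() ** 2 / np.sum(w**2))
    return float(delta_a), ess


def _chain(
    windows: list[Window], temperature: float, reverse: bool
) -> tuple[dict[float, float], dict[float, float]]:
    """Chain window estimates into absolute ΔA values (arbitrary zero).

    Forward (reverse=False): window n estimates its grid points from its own
    ξref ensemble on the up-side segment (ξref,n, ξref,n+1]; the first window
    additionally covers everything below its reference.  The running offset is
    carried across each shared reference grid point.  ``reverse=True`` mirrors
    the procedure from the last window down.
    """
    order = list(range(len(windows)))
    if reverse:
        order = order[::-1]
    values: dict[float, float] = {}
    ess: dict[float, float] = {}
    offset = 0.0
    for k, n in enumerate(order):
        win = windows[n]
        first, last = k == 0, k == len(order) - 1
        if not reverse:
            lo = -np.inf if first else win.xi_ref
            hi = np.inf if last else windows[n + 1].xi_ref
            take = (win.xi > lo) & (win.xi <= hi) if not first else (win.xi <= hi)
        else:
            hi = np.inf if first else win.xi_ref
            lo = -np.inf if last else windows[n - 1].xi_ref
            take = (win.xi < hi) & (win.xi >= lo) if not first else (win.xi >= lo)
        local: dict[float, tuple[float, float]] = {}
        for x in win.xi[take]:
            da, e = zwanzig_step(win.delta_u(x), temperature)
            local[round(float(x), _XI_DECIMALS)] = (da, e)
            if e < ESS_WARN_THRESHOLD:
                logger.warning(
                    "window %d, xi=%.4f: effective sample size %.1f < %.0f "
                    "(poor overlap with the reference ensemble)",
                    win.index, x, e, ESS_WARN_THRESHOLD,
                )
        for x, (da, e) in local.items():
            values[x] = offset + da
            ess[x] = e
        if not last:
            nxt = windows[n + (1 if not reverse else -1)]
            boundary = round(float(nxt.xi_ref), _XI_DECIMALS)
            if win._index_of(nxt.xi_ref) is None:
                raise StitchError(
                    f"window {win.index} does not cover the neighbouring "
                    f"reference point xi={nxt.xi_ref}; windows must overlap"
                )
            da_b, _ = zwanzig_step(win.delta_u(nxt.xi_ref), temperature)
            offset = offset + da_b
    return values, ess


def reconstruct_profile(
    windows: Sequence[Window],
    temperature: float,
    direction: str = "forward",
) -> FreeEnergyProfile:
    """Assemble the full ΔA(ξ) profile from ordered windows.

    Windows must be ordered by ξref and each must cover the neighbouring
    reference grid point used for chaining.  The assembled profile is
    re-zeroed at its minimum (recorded as ξR) and, when an interior maximum
    exists, annotated with ξTS and the barrier.
    """
    if direction not in ("forward", "backward"):
        raise ValueError("direction must be 'forward' or 'backward'")
    wins = sorted(windows, key=lambda w: w.xi_ref)
    if len(wins) == 0:
        raise ValueError("at least one window required")
    refs = [w.xi_ref for w in wins]
    if np.any(np.diff(refs) <= 0):
        raise ValueError("window reference points must be strictly increasing")
    values, ess = _chain(wins, temperature, reverse=(direction == "backward"))
    xi = np.array(sorted(values))
    profile = FreeEnergyProfile(
        xi=xi,
        delta_a=np.array([values[x] for x in xi]),
        ess=np.array([ess[x] for x in xi]),
        direction=direction,
    ).rezero()
    try:
        xi_r, xi_ts, barrier = locate_barrier(profile)
    except NoBarrierError:
        pass
    else:
        profile.xi_R, profile.xi_TS, profile.barrier = xi_r, xi_ts, barrier
    return profile


def average_profiles(
    forward: FreeEnergyProfile, backward: FreeEnergyProfile
) -> FreeEnergyProfile:
    """Pointwise mean of the two direction profiles (each re-zeroed at ξR)."""
    if forward.xi.size != backward.xi.size or not np.allclose(
        forward.xi, backward.xi, atol=10.0 ** (-_XI_DECIMALS)
    ):
        raise ValueError("forward and backward profiles are on different grids")
    f = forward.delta_a - forward.delta_a.min()
    b = backward.delta_a - backward.delta_a.min()
    ess = None
    if forward.ess is not None and backward.ess is not None:
        ess = 0.5 * (forward.ess + backward.ess)
    profile = FreeEnergyProfile(
        xi=forward.xi.copy(),
        delta_a=0.5 * (f + b),
        ess=ess,
        direction="averaged",
        xi_m=forward.xi_m,
    ).rezero()
    try:
        xi_r, xi_ts, barrier = locate_barrier(profile)
    except NoBarrierError:
        pass
    else:
        profile.xi_R, profile.xi_TS, profile.barrier = xi_r, xi_ts, barrier
    return profile


def locate_barrier(
    profile: FreeEnergyProfile, search_max: float | None = None
) -> tuple[float, float, float]:
    """Locate ξR (reactant minimum), ξTS and the barrier ΔA‡.

    ξR is the argmin of ΔA over the reactant-side search range (up to
    ``search_max`` if given) and ξTS the argmax over the grid beyond ξR;
    ties break to the smallest ξ.  A profile that is monotone, or whose
    maximum beyond ξR does not rise above it, has no barrier.
    """
    da, xi = profile.delta_a, profile.xi
    if xi.size < 3:
        raise ValueError("profile needs at least three points")
    diffs = np.diff(da)
    if np.all(diffs >= 0) or np.all(diffs <= 0):
        raise NoBarrierError("profile is monotone: no interior maximum above a minimum")
    search = xi <= search_max if search_max is not None else np.ones_like(xi, bool)
    i_r = int(np.flatnonzero(search)[np.argmin(da[search])])
    after = np.arange(i_r + 1, xi.size)
    if after.size == 0:
        raise NoBarrierError("reactant minimum sits at the end of the grid")
    i_ts = int(after[np.argmax(da[after])])
    barrier = float(da[i_ts] - da[i_r])
    if barrier <= 0:
        raise NoBarrierError("no point beyond the minimum rises above it")
    return float(xi[i_r]), float(xi[i_ts]), barrier
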