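"""Plain-text readers and writers for every pipeline format.

Formats (all columnar CSV or extended XYZ, units in the headers):

* window samples: ``xi_nm,frame,U_kcal_mol`` with an ``# xi_ref_nm = <v>``
  comment line, one file per window;
* free-energy profile: ``xi_nm,delta_a_kcal_mol,ess``;
* distance trajectories: ``t_ps,r_nm`` (one file each) or one wide CSV with
  ``t_ps`` plus one column per trajectory;
* MSD tracks: ``t_ps,msd_nm2``;
* environment snapshots: concatenated extended XYZ, 5 columns
  ``element x y z charge`` (nm, e), frame comment line carrying ``t=<ps>``;
* reaction profile: CSV ``xi_nm,e0_kcal_mol,dipole_x,dipole_y,dipole_z``
  plus one companion extended-XYZ per ξ point;
* rate constants: JSON with value, unit and provenance per constant,
  floats fixed to 6 significant digits for reproducible byte output.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .free_energy import FreeEnergyProfile, Window
from .kinetics import DistanceTrajectory, SurvivalCurve
from .pmm import EnvironmentSnapshot, QuantumCenterFrame
from .rates import RateConstants

__all__ = [
    "write_window_csv", "read_window_csv",
    "write_profile_csv", "read_profile_csv",
    "write_distance_csv", "read_distance_csv",
    "write_distance_wide_csv", "read_distance_wide_csv",
    "write_msd_csv", "read_msd_csv",
    "write_survival_csv",
    "write_xyz_snapshots", "read_xyz_snapshots",
    "write_reaction_profile", "read_reaction_profile",
    "write_rates_json", "read_rates_json",
]


def write_window_csv(window: Window, path: str | Path) -> None:
    path = Path(path)
    rows = []
    for i, x in enumerate(window.xi):
        for f in range(window.n_frames):
            rows.append((x, f, window.u[i, f]))
    df = pd.DataFrame(rows, columns=["xi_nm", "frame", "U_kcal_mol"])
    with open(path, "w") as fh:
        fh.write(f"# xi_ref_nm = {window.xi_ref!r}\n")
        df.to_csv(fh, index=False)


def read_window_csv(path: str | Path, index: int = 0, xi_ref: float | None = None) -> Window:
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("#") and "xi_ref_nm" in first:
        xi_ref = float(first.split("=")[1])
    if xi_ref is None:
        raise ValueError(f"{path}: no xi_ref header comment and none supplied")
    df = pd.read_csv(path, comment="#")
    series = {
        float(x): g.sort_values("frame")["U_kcal_mol"].to_numpy()
        for x, g in df.groupby("xi_nm")
    }
    return Window.from_series(index=index, xi_ref=xi_ref, series=series)


def write_profile_csv(profile: FreeEnergyProfile, path: str | Path) -> None:
    ess = profile.ess if profile.ess is not None else np.full(profile.xi.size, np.nan)
    pd.DataFrame(
        {"xi_nm": profile.xi, "delta_a_kcal_mol": profile.delta_a, "ess": ess}
    ).to_csv(path, index=False)


def read_profile_csv(path: str | Path, direction: str = "averaged") -> FreeEnergyProfile:
    df = pd.read_csv(path)
    ess = df["ess"].to_numpy() if "ess" in df else None
    return FreeEnergyProfile(
        xi=df["xi_nm"].to_numpy(),
        delta_a=df["delta_a_kcal_mol"].to_numpy(),
        ess=None if ess is None or np.all(np.isnan(ess)) else ess,
        direction=direction,
    )


def write_distance_csv(traj: DistanceTrajectory, path: str | Path) -> None:
    pd.DataFrame({"t_ps": traj.times, "r_nm": traj.distances}).to_csv(path, index=False)


def read_distance_csv(path: str | Path, label: str = "") -> DistanceTrajectory:
    df = pd.read_csv(path)
    return DistanceTrajectory(
        times=df["t_ps"].to_numpy(), distances=df["r_nm"].to_numpy(),
        label=label or Path(path).stem,
    )


def write_distance_wide_csv(
    trajectories: Sequence[DistanceTrajectory], path: str | Path
) -> None:
    data = {"t_ps": trajectories[0].times}
    for k, tr in enumerate(trajectories):
        data[tr.label or f"r{k}_nm"] = tr.distances
    pd.DataFrame(data).to_csv(path, index=False)


def read_distance_wide_csv(path: str | Path) -> list[DistanceTrajectory]:
    df = pd.read_csv(path)
    t = df["t_ps"].to_numpy()
    return [
        DistanceTrajectory(times=t, distances=df[c].to_numpy(), label=c)
        for c in df.columns
        if c != "t_ps"
    ]


def write_msd_csv(times: np.ndarray, msd: np.ndarray, path: str | Path) -> None:
    pd.DataFrame({"t_ps": times, "msd_nm2": msd}).to_csv(path, index=False)


def read_msd_csv(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    df = pd.read_csv(path)
    return df["t_ps"].to_numpy(), df["msd_nm2"].to_numpy()


def write_survival_csv(curve: SurvivalCurve, path: str | Path) -> None:
    pd.DataFrame({"t_ps": curve.times, "survival": curve.fraction}).to_csv(
        path, index=False
    )


def write_xyz_snapshots(
    snapshots: Sequence[EnvironmentSnapshot], path: str | Path
) -> None:
    """Concatenated extended XYZ: ``element x y z charge``, nm and e."""
    with open(path, "w") as fh:
        for snap in snapshots:
            fh.write(f"{len(snap)}\n")
            fh.write(f"t={float(snap.time)!r}\n")
            for pos, q in zip(snap.positions, snap.charges):
                fh.write(
                    f"X {float(pos[0])!r} {float(pos[1])!r} "
                    f"{float(pos[2])!r} {float(q)!r}\n"
                )


def read_xyz_snapshots(path: str | Path) -> list[EnvironmentSnapshot]:
    snapshots = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        n = int(lines[i].strip())
        comment = lines[i + 1]
        time = 0.0
        for token in comment.replace(",", " ").split():
            if token.startswith("t="):
                time = float(token[2:])
        block = lines[i + 2 : i + 2 + n]
        pos = np.array([[float(v) for v in ln.split()[1:4]] for ln in block])
        chg = np.array([float(ln.split()[4]) for ln in block])
        snapshots.append(
            EnvironmentSnapshot(
                positions=pos.reshape(-1, 3), charges=chg, time=time
            )
        )
        i += 2 + n
    return snapshots


def write_reaction_profile(
    frames: Sequence[QuantumCenterFrame], csv_path: str | Path, xyz_dir: str | Path
) -> None:
    """Reaction-profile CSV plus one extended-XYZ (with charges) per ξ point."""
    csv_path, xyz_dir = Path(csv_path), Path(xyz_dir)
    xyz_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for k, fr in enumerate(frames):
        rows.append(
            (fr.xi, fr.e0, fr.dipole[0], fr.dipole[1], fr.dipole[2])
        )
        with open(xyz_dir / f"point_{k:03d}.xyz", "w") as fh:
            fh.write(f"{fr.n_atoms}\n")
            fh.write(f"xi={float(fr.xi)!r}\n")
            for el, pos, q in zip(fr.elements, fr.positions, fr.charges):
                fh.write(
                    f"{el} {float(pos[0])!r} {float(pos[1])!r} "
                    f"{float(pos[2])!r} {float(q)!r}\n"
                )
    pd.DataFrame(
        rows, columns=["xi_nm", "e0_kcal_mol", "dipole_x", "dipole_y", "dipole_z"]
    ).to_csv(csv_path, index=False)


def read_reaction_profile(
    csv_path: str | Path, xyz_dir: str | Path
) -> list[QuantumCenterFrame]:
    df = pd.read_csv(csv_path)
    xyz_dir = Path(xyz_dir)
    frames = []
    for k, row in df.iterrows():
        path = xyz_dir / f"point_{k:03d}.xyz"
        with open(path) as fh:
            lines = fh.read().splitlines()
        n = int(lines[0].strip())
        block = lines[2 : 2 + n]
        elements = tuple(ln.split()[0] for ln in block)
        pos = np.array([[float(v) for v in ln.split()[1:4]] for ln in block])
        chg = np.array([float(ln.split()[4]) for ln in block])
        frames.append(
            QuantumCenterFrame(
                xi=float(row["xi_nm"]), e0=float(row["e0_kcal_mol"]),
                elements=elements, positions=pos, charges=chg,
                dipole=np.array(
                    [row["dipole_x"], row["dipole_y"], row["dipole_z"]], dtype=float
                ),
            )
        )
    return frames


def _sig6(x):
    if isinstance(x, dict):
        return {k: _sig6(v) for k, v in x.items()}
    if isinstance(x, (list, tuple)):
        return [_sig6(v) for v in x]
    if isinstance(x, float):
        return float(f"{x:.6g}")
    return x


def write_rates_json(rates: RateConstants, path: str | Path, extra: dict | None = None) -> None:
    payload = _sig6(rates.as_dict())
    if extra:
        payload.update(_sig6(extra))
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_rates_json(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)
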