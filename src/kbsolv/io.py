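"""File interchange: coordinate/trajectory formats via MDAnalysis, curves
and tables as commented CSV.

MDAnalysis works in Angstrom; this package works in nm, so readers divide
by 10 and writers multiply.  Orthorhombic boxes only.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .rdf import RDFCurve, RunningKBI
from .thermo import BinaryThermoState
from .trajectory import Trajectory

__all__ = [
    "write_configurations",
    "read_trajectory",
    "write_curve_csv",
    "read_curve_csv",
    "write_thermo_csv",
    "read_thermo_csv",
]

_NM_TO_A = 10.0


def _universe_from(traj: Trajectory):
    import MDAnalysis as mda

    u = mda.Universe.empty(
        n_atoms=traj.n_particles,
        n_residues=traj.n_particles,
        atom_resindex=np.arange(traj.n_particles),
        trajectory=True,
    )
    names = [str(s)[:5] for s in traj.species]
    u.add_TopologyAttr("names", names)
    u.add_TopologyAttr("resnames", names)
    u.add_TopologyAttr("masses", traj.masses)
    u.load_new(
        traj.positions * _NM_TO_A,
        format="memory",
        dimensions=np.column_stack(
            [traj.box * _NM_TO_A, np.full((traj.n_frames, 3), 90.0)]
        ),
    )
    return u


def write_configurations(traj: Trajectory, path) -> None:
    """Write a trajectory as GRO (single frame), XYZ or XTC, chosen by
    file extension."""
    import MDAnalysis as mda

    path = str(path)
    if path.endswith(".gro") and traj.n_frames > 1:
        raise ValueError(
            "GRO holds a single configuration; write multi-frame "
            "trajectories as XTC (with a one-frame GRO topology)"
        )
    u = _universe_from(traj)
    with mda.Writer(path, n_atoms=traj.n_particles) as w:
        for _ in u.trajectory:
            w.write(u.atoms)


def read_trajectory(path, topology=None) -> Trajectory:
    """Read GRO/XYZ single frames or XTC/DCD trajectories (topology file
    required for formats that carry no atom records)."""
    import MDAnalysis as mda

    u = mda.Universe(str(topology), str(path)) if topology else mda.Universe(str(path))
    frames, boxes, times = [], [], []
    for ts in u.trajectory:
        frames.append(u.atoms.positions / _NM_TO_A)
        if ts.dimensions is None or not np.all(ts.dimensions[:3] > 0):
            raise ValueError(f"{path}: frames must carry an orthorhombic box")
        if not np.allclose(ts.dimensions[3:], 90.0):
            raise ValueError(f"{path}: only orthorhombic boxes are supported")
        boxes.append(ts.dimensions[:3] / _NM_TO_A)
        times.append(ts.time)
    try:
        species = u.atoms.names
    except AttributeError:
        species = np.array([f"X{i}" for i in range(len(u.atoms))])
    try:
        masses = u.atoms.masses
    except Exception:
        masses = None
    return Trajectory(
        positions=np.asarray(frames),
        species=np.asarray(species),
        box=np.asarray(boxes),
        times=np.asarray(times),
        masses=masses,
    )


def write_curve_csv(path, x, y, xlabel: str, ylabel: str, metadata: dict | None = None) -> None:
    """Two-column CSV with '#'-prefixed metadata header lines."""
    lines = [f"# {k} = {v}" for k, v in (metadata or {}).items()]
    lines.append(f"{xlabel},{ylabel}")
    for a, b in zip(np.asarray(x), np.asarray(y)):
        lines.append(f"{a:.8g},{b:.8g}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_curve_csv(path):
    """Read a two-column CSV written by :func:`write_curve_csv`; returns
    (x, y, metadata)."""
    meta = {}
    rows = []
    header_seen = False
    for line in Path(path).read_text().splitlines():
        if line.startswith("#"):
            if "=" in line:
                k, v = line[1:].split("=", 1)
                meta[k.strip()] = v.strip()
            continue
        if not header_seen:
            header_seen = True
            continue
        if line.strip():
            a, b = line.split(",")
            rows.append((float(a), float(b)))
    arr = np.asarray(rows)
    return arr[:, 0], arr[:, 1], meta


def rdf_to_csv(rdf: RDFCurve, path) -> None:
    write_curve_csv(
        path, rdf.r, rdf.g, "r_nm", "g",
        metadata={
            "pair": f"{rdf.pair[0]}|{rdf.pair[1]}",
            "n_i": rdf.n_i, "n_j": rdf.n_j, "volume_nm3": rdf.volume,
            "frames": rdf.frame_count, "dr_nm": rdf.dr,
            "corrected": rdf.corrected, "like_species": rdf.like_species,
        },
    )


def running_kbi_to_csv(run: RunningKBI, path) -> None:
    write_curve_csv(path, run.R, run.G_of_R, "R_nm", "G_nm3",
                    metadata={"quadrature": run.quadrature})


_THERMO_COLUMNS = [
    "x3", "rho_total", "rho1", "rho3", "V1", "V3", "betaT", "dmu3_dx3", "f3", "f3m", "T",
]


def write_thermo_csv(states: list[BinaryThermoState], path) -> None:
    """Binary-solution dataset as CSV: x3, molar densities (mol/L), partial
    molar volumes (cm^3/mol), betaT (1/Pa), dmu3/dx3 (J/mol), activities."""
    rows = [
        {
            "x3": s.x3, "rho_total": s.rho, "rho1": s.rho1, "rho3": s.rho3,
            "V1": s.V1, "V3": s.V3, "betaT": s.betaT, "dmu3_dx3": s.dmu3_dx3,
            "f3": s.f3, "f3m": s.f3m, "T": s.T,
        }
        for s in states
    ]
    pd.DataFrame(rows, columns=_THERMO_COLUMNS).to_csv(path, index=False)


def read_thermo_csv(path) -> list[BinaryThermoState]:
    df = pd.read_csv(path)
    missing = set(_THERMO_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"thermo CSV missing columns: {sorted(missing)}")
    return [
        BinaryThermoState(
            T=row.T, x3=row.x3, rho=row.rho_total, V1=row.V1, V3=row.V3,
            betaT=row.betaT, dmu3_dx3=row.dmu3_dx3,
            f3=None if pd.isna(row.f3) else row.f3,
            f3m=None if pd.isna(row.f3m) else row.f3m,
        )
        for row in df.itertuples()
    ]
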