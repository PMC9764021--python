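"""Reading and writing trajectories, track tables and event logs.

Three interchangeable on-disk representations are supported:

* a plain-text **track table** (TSV; columns ``frame, time_ns, particle_id,
  role, x, y, z``) — the lossless native format,
* **PDB topology + DCD/XTC coordinates** (via MDAnalysis), with the particle
  role encoded in the residue name, and
* the **ground-truth event log** as JSON lines (handled by
  :meth:`kirpore.synthetic.GroundTruthLog.to_jsonl`).

Binary coordinate output densifies the sparse per-particle frame windows:
a particle outside its active window is written at its parked position.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .pore_model import PoreGeometry, project_to_axis
from .synthetic import TrajectoryBundle

__all__ = [
    "write_track_table",
    "read_track_table",
    "write_trajectory",
    "read_trajectory",
    "with_axial",
]

_ROLE_TO_RESNAME = {
    "ion": "POT",
    "water": "WAT",
    "spm": "SPM",
    "gate": "GAT",
    "landmark": "COM",
}
_RESNAME_TO_ROLE = {v: k for k, v in _ROLE_TO_RESNAME.items()}


def with_axial(tracks: pd.DataFrame, geometry: PoreGeometry) -> pd.DataFrame:
    """Return a copy with an axial-projection column ``za`` added."""
    if "za" in tracks.columns:
        return tracks
    out = tracks.copy()
    out["za"] = project_to_axis(out[["x", "y", "z"]].to_numpy(), geometry)
    return out


def write_track_table(tracks: pd.DataFrame, path) -> None:
    """Write a track table as TSV (time stored in ns)."""
    df = tracks.copy()
    df["time_ns"] = df.pop("time") * 1e3
    cols = ["frame", "time_ns", "particle", "role", "x", "y", "z"]
    df[cols].rename(columns={"particle": "particle_id"}).to_csv(
        path, sep="\t", index=False, float_format="%.4f")


def read_track_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    df["time"] = df.pop("time_ns") * 1e-3
    df = df.rename(columns={"particle_id": "particle"})
    return df[["frame", "time", "particle", "role", "x", "y", "z"]]


def _dense_coordinates(bundle: TrajectoryBundle):
    """(n_frames, n_atoms, 3) array; inactive frames hold the edge position."""
    pids = sorted(bundle.particles)
    n_frames = bundle.n_frames
    coords = np.empty((n_frames, len(pids), 3), dtype=np.float32)
    roles = []
    for j, pid in enumerate(pids):
        pf = bundle.particles[pid]
        roles.append(pf.role)
        stop = pf.start + len(pf.xyz)
        coords[pf.start:stop, j] = pf.xyz
        if pf.start > 0:
            coords[:pf.start, j] = pf.xyz[0]
        if stop < n_frames:
            coords[stop:, j] = pf.xyz[-1]
    return pids, roles, coords


def write_trajectory(bundle: TrajectoryBundle, topology_path,
                     coordinates_path=None, track_table_path=None) -> None:
    """Write PDB topology (plus optional DCD/XTC coordinates and track table).

    The coordinate format is chosen from the file suffix.  Raises
    ``ValueError`` for an empty bundle.
    """
    if not bundle.particles:
        raise ValueError("bundle holds no particles")
    import MDAnalysis as mda
    from MDAnalysis.coordinates.memory import MemoryReader

    pids, roles, coords = _dense_coordinates(bundle)
    n_atoms = len(pids)
    u = mda.Universe.empty(
        n_atoms, n_residues=n_atoms,
        atom_resindex=np.arange(n_atoms),
        residue_segindex=np.zeros(n_atoms, dtype=int),
        trajectory=True,
    )
    u.add_TopologyAttr("names", [f"P{j:04d}" for j in range(n_atoms)])
    u.add_TopologyAttr("resnames",
                       [_ROLE_TO_RESNAME.get(r, "UNK") for r in roles])
    u.add_TopologyAttr("resids", np.arange(1, n_atoms + 1))
    u.load_new(coords, format=MemoryReader, dt=bundle.dt_ns * 1e3)  # dt in ps

    u.atoms.write(str(topology_path))
    if coordinates_path is not None:
        with mda.Writer(str(coordinates_path), n_atoms) as w:
            for _ in u.trajectory:
                w.write(u.atoms)
    if track_table_path is not None:
        write_track_table(bundle.to_track_table(), track_table_path)


def read_trajectory(topology_path, coordinates_path=None,
                    dt_ns: float | None = None) -> pd.DataFrame:
    """Read PDB(+DCD/XTC) back into a track table.

    Particle identity is the atom index (ids ``a0000`` …); the role comes
    from the residue name.  ``dt_ns`` overrides the frame interval stored
    in the file (useful for formats with unreliable time metadata).
    """
    import MDAnalysis as mda

    if coordinates_path is None:
        u = mda.Universe(str(topology_path))
    else:
        u = mda.Universe(str(topology_path), str(coordinates_path))
    n_atoms = len(u.atoms)
    pids = np.array([f"a{j:04d}" for j in range(n_atoms)])
    roles = np.array([_RESNAME_TO_ROLE.get(rn, "ion")
                      for rn in u.atoms.resnames])
    rows = []
    for i, ts in enumerate(u.trajectory):
        if dt_ns is not None:
            t_us = i * dt_ns * 1e-3
        else:
            t_us = ts.time * 1e-6  # ps -> us
        pos = ts.positions.astype(np.float64)
        rows.append(pd.DataFrame({
            "frame": i, "time": t_us, "particle": pids, "role": roles,
            "x": pos[:, 0], "y": pos[:, 1], "z": pos[:, 2],
        }))
    return pd.concat(rows, ignore_index=True)
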