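"""Gate geometry, cavity hydration and pore-closure statistics.

The activation-gate state is read from coordinates: the Cα–Cα diagonal
distance at the gate residues (I177/M181), the water count inside the
cavity cylinder, and the CTD–SF center-of-mass separation.  Pore closure
is detected from the hydration series by a water-count criterion — the
count dropping to ``threshold`` (35 by default) or less and staying there
for a persistence window — and summarized across replicates with a
Kaplan–Meier survival estimate so censored (never-closing) replicates are
handled correctly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .pore_model import PoreGeometry

__all__ = [
    "GateSeries",
    "ClosureOutcome",
    "gate_diagonal_distance",
    "cavity_hydration",
    "detect_closure",
    "closure_statistics",
    "ctd_sf_separation",
    "contact_distances",
]


@dataclass
class GateSeries:
    """Per-frame gate observables."""

    time: np.ndarray  # us
    diagonal: np.ndarray | None = None  # A
    hydration: np.ndarray | None = None  # waters
    ctd_sf: np.ndarray | None = None  # A


@dataclass(frozen=True)
class ClosureOutcome:
    closure_time: float | None  # us; None = censored
    censored_at: float | None  # us; set when censored
    threshold: int = 35
    persistence: int = 1  # frames

    @property
    def closed(self) -> bool:
        return self.closure_time is not None


def _pivot_xyz(tracks: pd.DataFrame, particles):
    """(n_frames, n_particles, 3) array for the requested particle ids."""
    sel = tracks[tracks["particle"].isin(particles)]
    if sel.empty:
        raise ValueError(f"none of {list(particles)} present in tracks")
    frames = np.sort(sel["frame"].unique())
    out = np.full((len(frames), len(particles), 3), np.nan)
    findex = {f: i for i, f in enumerate(frames)}
    for j, pid in enumerate(particles):
        grp = sel[sel["particle"] == pid]
        idx = [findex[f] for f in grp["frame"]]
        out[idx, j] = grp[["x", "y", "z"]].to_numpy()
    if np.isnan(out).any():
        raise ValueError("selected particles missing from some frames")
    times = (sel.drop_duplicates("frame").sort_values("frame")["time"]
             .to_numpy())
    return times, out


def gate_diagonal_distance(tracks: pd.DataFrame, residue: str = "I177",
                           suffixes=("A", "B", "C", "D")):
    """Mean of the two subunit-diagonal Cα–Cα distances, per frame.

    The four subunit copies are paired by topology order (A–C and B–D);
    exactly four copies are required.
    """
    ids = [f"{residue}_{s}" for s in suffixes]
    present = set(tracks["particle"].unique())
    found = [i for i in ids if i in present]
    if len(found) != 4:
        raise ValueError(
            f"gate residue {residue} must have exactly 4 subunit copies; "
            f"found {found}"
        )
    times, xyz = _pivot_xyz(tracks, ids)
    d_ac = np.linalg.norm(xyz[:, 0] - xyz[:, 2], axis=1)
    d_bd = np.linalg.norm(xyz[:, 1] - xyz[:, 3], axis=1)
    return times, 0.5 * (d_ac + d_bd)


def cavity_hydration(tracks: pd.DataFrame, geometry: PoreGeometry,
                     role: str = "water"):
    """Per-frame count of water particles inside the cavity cylinder."""
    z_lo, z_hi, radius = geometry.cavity_cylinder
    n_frames = int(tracks["frame"].max()) + 1
    waters = tracks[tracks["role"] == role]
    counts = np.zeros(n_frames, dtype=int)
    if len(waters):
        xyz = waters[["x", "y", "z"]].to_numpy()
        inside = ((xyz[:, 0] ** 2 + xyz[:, 1] ** 2 <= radius ** 2)
                  & (xyz[:, 2] >= z_lo) & (xyz[:, 2] < z_hi))
        frames = waters["frame"].to_numpy()[inside]
        np.add.at(counts, frames, 1)
    dt = np.sort(tracks["time"].unique())
    times = dt if len(dt) == n_frames else np.arange(n_frames) * (
        dt[1] - dt[0] if len(dt) > 1 else 1.0)
    return times, counts


def detect_closure(times, counts, threshold: int = 35,
                   persistence: int = 1) -> ClosureOutcome:
    """First time the hydration stays at or below ``threshold``.

    Closure is the first frame from which the count remains ≤ threshold
    for at least ``persistence`` consecutive frames; single-frame dips
    shorter than the window do not count.  A series that never satisfies
    the criterion is censored at its end.
    """
    counts = np.asarray(counts)
    times = np.asarray(times)
    if counts.size == 0:
        raise ValueError("empty hydration series")
    if persistence < 1:
        raise ValueError("persistence must be >= 1")
    below = counts <= threshold
    # run lengths of consecutive below-threshold frames ending the series
    # or lasting >= persistence
    padded = np.concatenate([[False], below, [False]])
    d = np.diff(padded.astype(int))
    starts = np.nonzero(d == 1)[0]
    stops = np.nonzero(d == -1)[0]
    for s, e in zip(starts, stops):
        if e - s >= persistence:
            return ClosureOutcome(float(times[s]), None, threshold, persistence)
    return ClosureOutcome(None, float(times[-1]), threshold, persistence)


def closure_statistics(outcomes) -> dict:
    """Median closure time and fraction-closed curve across replicates.

    Censored replicates are handled with a Kaplan–Meier survival estimate;
    when the survival curve never reaches 0.5 the median is reported as a
    lower bound (``median_is_lower_bound=True`` with the largest observed
    time).
    """
    from lifelines import KaplanMeierFitter

    outcomes = list(outcomes)
    if not outcomes:
        raise ValueError("need at least one closure outcome")
    durations = np.array([
        o.closure_time if o.closed else o.censored_at for o in outcomes
    ])
    observed = np.array([o.closed for o in outcomes])
    km = KaplanMeierFitter()
    km.fit(durations, event_observed=observed)
    median = km.median_survival_time_
    lower_bound = bool(np.isinf(median))
    if lower_bound:
        median = float(durations.max())
    curve = pd.DataFrame({
        "time": km.survival_function_.index.to_numpy(),
        "fraction_closed": 1.0 - km.survival_function_.iloc[:, 0].to_numpy(),
    })
    return {
        "median": float(median),
        "median_is_lower_bound": lower_bound,
        "n": len(outcomes),
        "n_closed": int(observed.sum()),
        "fraction_closed_curve": curve,
    }


def ctd_sf_separation(tracks: pd.DataFrame, ctd_id: str = "COM_CTD",
                      sf_id: str = "COM_SF"):
    """Euclidean CTD–SF center-of-mass distance per frame."""
    times, xyz = _pivot_xyz(tracks, [ctd_id, sf_id])
    return times, np.linalg.norm(xyz[:, 0] - xyz[:, 1], axis=1)


def contact_distances(tracks: pd.DataFrame, selection_a, selection_b):
    """Per-frame minimum distance over all cross pairs of two selections."""
    selection_a, selection_b = list(selection_a), list(selection_b)
    if not selection_a or not selection_b:
        raise ValueError("both selections must be non-empty")
    times, xyz_a = _pivot_xyz(tracks, selection_a)
    _, xyz_b = _pivot_xyz(tracks, selection_b)
    diff = xyz_a[:, :, None, :] - xyz_b[:, None, :, :]
    dist = np.sqrt((diff ** 2).sum(axis=-1))
    return times, dist.reshape(len(times), -1).min(axis=1)
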