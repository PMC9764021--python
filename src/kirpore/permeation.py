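"""Permeation analysis: event detection, currents, occupancies, densities.

All operations consume a long-format track table (columns ``frame, time,
particle, role, x, y, z``; time in µs) plus a :class:`PoreGeometry`.  Axial
positions are computed on demand and cached in a ``za`` column.

Event detection uses hysteresis (two separated thresholds): an outward
permeation is committed only when an ion that was last seen below the
inner threshold (below S6) rises above the outer threshold (above S0), so
sub-Å jitter and transient SF approaches from the extracellular side
produce no events.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .pore_model import ELEMENTARY_CHARGE, SF_SITES, PoreGeometry, assign_site
from .trajio import with_axial

__all__ = [
    "PermeationEvent",
    "CurrentResult",
    "OccupancyResult",
    "KnockOnHistogram",
    "detect_permeation_events",
    "current_and_conductance",
    "kinetic_occupancy",
    "water_ion_ratio",
    "axial_density",
    "residence_times",
    "label_configuration",
    "knockon_histogram",
]

# Site order along the axis used for configuration labels.
_LABEL_SITES = (*SF_SITES, "S_ext")


@dataclass(frozen=True)
class PermeationEvent:
    particle: str
    direction: str  # "outward" | "inward"
    t_enter: float  # us, crossed the inner boundary
    t_exit: float  # us, crossed the outer boundary


@dataclass(frozen=True)
class CurrentResult:
    n_out: int
    n_in: int
    duration: float  # us
    voltage: float  # mV
    current_pa: float
    conductance_ps: float | None  # None when voltage == 0 (undefined)


@dataclass(frozen=True)
class OccupancyResult:
    region: str
    mean: float
    se: float
    rule: str  # "all" | "intracellular_entry_only"


def _per_particle(tracks, roles):
    sel = tracks[tracks["role"].isin(roles)]
    for pid, grp in sel.groupby("particle", sort=False):
        t = grp["time"].to_numpy()
        if np.any(np.diff(t) < 0):
            raise ValueError(f"frames of particle {pid} are not time-sorted")
        yield pid, t, grp


def detect_permeation_events(tracks: pd.DataFrame, geometry: PoreGeometry,
                             hysteresis: float = 2.0,
                             roles=("ion",)) -> pd.DataFrame:
    """Two-threshold permeation detector.

    Thresholds default to ``z_lo(S6) − hysteresis`` (inner) and
    ``z_hi(S0) + hysteresis`` (outer).  Returns one row per committed event
    with columns ``particle, direction, t_enter, t_exit``.
    """
    tracks = with_axial(tracks, geometry)
    inner = geometry.z_lo("S6") - hysteresis
    outer = geometry.z_hi("S0") + hysteresis
    rows = []
    for pid, t, grp in _per_particle(tracks, roles):
        z = grp["za"].to_numpy()
        code = np.where(z < inner, 0, np.where(z > outer, 2, 1))
        keep = code != 1
        if not keep.any():
            continue
        c, tt = code[keep], t[keep]
        change = np.nonzero(np.diff(c) != 0)[0]
        for i in change:
            if c[i] == 0 and c[i + 1] == 2:
                rows.append((pid, "outward", tt[i], tt[i + 1]))
            elif c[i] == 2 and c[i + 1] == 0:
                rows.append((pid, "inward", tt[i], tt[i + 1]))
    df = pd.DataFrame(rows, columns=["particle", "direction", "t_enter", "t_exit"])
    return df.sort_values("t_exit", ignore_index=True) if len(df) else df


def current_and_conductance(events, duration: float,
                            voltage: float) -> CurrentResult:
    """Net current (pA) and conductance (pS) from permeation events.

    ``events`` is either the detector's DataFrame or a ``(n_out, n_in)``
    pair.  ``I = (N_out − N_in)·e/T``; conductance is ``I/V`` and is
    undefined (``None``) at V = 0.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if isinstance(events, tuple):
        n_out, n_in = events
    else:
        n_out = int((events["direction"] == "outward").sum()) if len(events) else 0
        n_in = int((events["direction"] == "inward").sum()) if len(events) else 0
    # e / us gives A*1e-6... current in pA: C/us = 1e6 C/s -> *1e12 pA
    current_pa = (n_out - n_in) * ELEMENTARY_CHARGE / (duration * 1e-6) * 1e12
    if voltage == 0.0:
        conductance = None
    else:
        conductance = current_pa / voltage * 1e3  # pA/mV -> pS
    return CurrentResult(n_out, n_in, duration, voltage, current_pa, conductance)


def _membership_runs(mask: np.ndarray):
    """(start, stop) index pairs of contiguous True runs (stop exclusive)."""
    if not mask.any():
        return []
    padded = np.concatenate([[False], mask, [False]])
    d = np.diff(padded.astype(int))
    starts = np.nonzero(d == 1)[0]
    stops = np.nonzero(d == -1)[0]
    return list(zip(starts, stops))


def kinetic_occupancy(tracks: pd.DataFrame, geometry: PoreGeometry,
                      region: str = "SF", rule: str = "all",
                      roles=("ion",), n_blocks: int = 5) -> OccupancyResult:
    """Time-averaged particle count in a region.

    Under ``rule="intracellular_entry_only"`` a particle's frames are
    counted only while its current visit to the region began by crossing
    the region's intracellular (lower-z) boundary — the "kinetic"
    occupancy of outwardly permeating ions, excluding ions that transiently
    approach from the extracellular side.  Visits already in progress at
    the start of a particle's record are treated as intracellular entries.
    Standard error is estimated by block averaging over ``n_blocks``
    contiguous time blocks.
    """
    if rule not in ("all", "intracellular_entry_only"):
        raise ValueError(f"unknown rule {rule!r}")
    tracks = with_axial(tracks, geometry)
    lo, hi = geometry.region_interval(region)
    n_frames = int(tracks["frame"].max()) + 1
    counts = np.zeros(n_frames)
    any_overlap = False
    for pid, t, grp in _per_particle(tracks, roles):
        z = grp["za"].to_numpy()
        frames = grp["frame"].to_numpy()
        inside = (z >= lo) & (z < hi)
        if not inside.any():
            continue
        any_overlap = True
        if rule == "all":
            counts[frames[inside]] += 1
            continue
        for start, stop in _membership_runs(inside):
            if start > 0 and z[start - 1] >= hi:
                continue  # entered from the extracellular side
            counts[frames[start:stop]] += 1
    if not any_overlap:
        warnings.warn(f"no track overlaps region {region!r}; occupancy is 0")
        return OccupancyResult(region, 0.0, 0.0, rule)
    mean = float(counts.mean())
    blocks = np.array_split(counts, max(1, n_blocks))
    block_means = np.array([b.mean() for b in blocks if len(b)])
    se = float(block_means.std(ddof=1) / np.sqrt(len(block_means))) \
        if len(block_means) > 1 else 0.0
    return OccupancyResult(region, mean, se, rule)


def water_ion_ratio(n_water, n_ion, alpha: float = 0.05):
    """Water-to-ion co-permeation ratio with a Wilson confidence interval.

    Arguments may be counts or event DataFrames.  Raises ``ValueError``
    when there are no ion events (the ratio is undefined).
    """
    from statsmodels.stats.proportion import proportion_confint

    if isinstance(n_water, pd.DataFrame):
        n_water = len(n_water)
    if isinstance(n_ion, pd.DataFrame):
        n_ion = len(n_ion)
    if n_ion <= 0:
        raise ValueError("water-to-ion ratio undefined: no ion permeations")
    ratio = n_water / n_ion
    lo, hi = proportion_confint(min(n_water, n_ion), n_ion,
                                alpha=alpha, method="wilson")
    return ratio, float(lo), float(hi)


def axial_density(tracks: pd.DataFrame, geometry: PoreGeometry,
                  bin_width: float = 0.5, normalize: bool = False,
                  roles=("ion",), z_range=None) -> pd.DataFrame:
    """Histogram of per-frame axial positions.

    Unnormalized values are mean counts per frame per Å, so the integral
    (sum × bin width) over a range equals the mean occupancy of that
    range.  ``normalize=True`` scales the peak to 1.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    tracks = with_axial(tracks, geometry)
    if z_range is None:
        z_range = (geometry.edges[0], geometry.edges[-1])
    sel = tracks[tracks["role"].isin(roles)]
    n_frames = int(tracks["frame"].max()) + 1
    bins = np.arange(z_range[0], z_range[1] + bin_width, bin_width)
    counts, edges = np.histogram(sel["za"].to_numpy(), bins=bins)
    density = counts / n_frames / bin_width
    if normalize and density.max() > 0:
        density = density / density.max()
    return pd.DataFrame({
        "z": 0.5 * (edges[:-1] + edges[1:]),
        "density": density,
    })


def residence_times(tracks: pd.DataFrame, geometry: PoreGeometry,
                    region: str, roles=("ion",)) -> pd.DataFrame:
    """Durations of maximal contiguous visits to a region.

    Returns columns ``particle, t_start, duration, censored``; a visit cut
    off by the end of a particle's record is flagged censored.
    """
    tracks = with_axial(tracks, geometry)
    lo, hi = geometry.region_interval(region)
    rows = []
    for pid, t, grp in _per_particle(tracks, roles):
        z = grp["za"].to_numpy()
        inside = (z >= lo) & (z < hi)
        for start, stop in _membership_runs(inside):
            censored = stop >= len(z)
            t_start = t[start]
            t_end = t[stop] if not censored else t[-1]
            rows.append((pid, t_start, t_end - t_start, censored))
    return pd.DataFrame(rows, columns=["particle", "t_start", "duration",
                                       "censored"])


def label_configuration(occupied) -> str:
    """Canonical knock-on configuration label.

    ``occupied`` is the set of occupied SF/S_ext sites (iterable of names,
    or a mapping site → 0/1).  Four ions give ``"A[B,C],D"`` where A is
    the lowest (incoming) site, D the highest (outgoing) and B, C the two
    between, written in descending site number (ascending z); fewer ions
    give the reduced forms ``"A[B],D"``, ``"A,D"``, ``"A"``; the empty set
    gives ``"∅"``.  A site occupied more than once is an invalid state.
    """
    if isinstance(occupied, dict):
        occupied = [s for s, n in occupied.items() if n]
    sites = list(occupied)
    for s in sites:
        if s not in _LABEL_SITES:
            raise ValueError(f"unknown SF site {s!r}")
    if len(set(sites)) != len(sites):
        raise ValueError(f"invalid state: site occupied more than once "
                         f"in {sites}")
    ordered = sorted(sites, key=_LABEL_SITES.index)  # ascending z
    n = len(ordered)
    if n == 0:
        return "∅"
    if n == 1:
        return ordered[0]
    if n == 2:
        return f"{ordered[0]},{ordered[1]}"
    middle = ",".join(ordered[1:-1])
    return f"{ordered[0]}[{middle}],{ordered[-1]}"


@dataclass
class KnockOnHistogram:
    """2-D ion-position histograms characterizing the knock-on mechanism.

    ``left`` bins (z of the lowest SF ion, centroid of the two ions
    directly above it); ``right`` bins (z of the highest, centroid of the
    two directly below).  ``dwell_fractions`` gives the fraction of
    contributing frames spent in each configuration label.
    """

    left: np.ndarray
    right: np.ndarray
    edges: np.ndarray
    dwell_fractions: pd.Series
    n_frames: int  # contributing frames (>= 3 SF ions)

    def normalized(self, which: str = "left") -> np.ndarray:
        grid = self.left if which == "left" else self.right
        total = grid.sum()
        return grid / total if total > 0 else grid

    def log_density(self, which: str = "left") -> np.ndarray:
        rho = self.normalized(which)
        with np.errstate(divide="ignore"):
            return np.where(rho > 0, np.log10(rho), np.nan)


def knockon_histogram(tracks: pd.DataFrame, geometry: PoreGeometry,
                      bin_width: float = 0.5,
                      roles=("ion",)) -> KnockOnHistogram:
    """Build the incoming/leaving-ion histograms and configuration dwells.

    "SF-bound" means axial position within ``[z_lo(S6), z_hi(S0))``;
    frames with fewer than three SF-bound ions do not contribute to the
    grids.  Configuration labels additionally include an ion in S_ext.
    """
    tracks = with_axial(tracks, geometry)
    sf_lo, sf_hi = geometry.z_lo("S6"), geometry.z_hi("S0")
    ext_hi = geometry.z_hi("S_ext")
    sel = tracks[tracks["role"].isin(roles)]
    sel = sel[(sel["za"] >= sf_lo) & (sel["za"] < ext_hi)]
    edges = np.arange(sf_lo - 2.0, sf_hi + 2.0 + bin_width, bin_width)
    nbin = len(edges) - 1
    left = np.zeros((nbin, nbin))
    right = np.zeros((nbin, nbin))
    labels = {}
    n_contrib = 0

    by_frame = sel.sort_values("frame").groupby("frame", sort=True)
    for frame, grp in by_frame:
        z_all = np.sort(grp["za"].to_numpy())
        z_sf = z_all[z_all < sf_hi]
        try:
            label = label_configuration(list(assign_site(z_all, geometry)))
        except ValueError:
            label = None
        if label is not None:
            labels[frame] = label
        if len(z_sf) < 3:
            continue
        n_contrib += 1
        ix = np.searchsorted(edges, z_sf[0], side="right") - 1
        iy = np.searchsorted(edges, 0.5 * (z_sf[1] + z_sf[2]), side="right") - 1
        if 0 <= ix < nbin and 0 <= iy < nbin:
            left[ix, iy] += 1
        jx = np.searchsorted(edges, z_sf[-1], side="right") - 1
        jy = np.searchsorted(edges, 0.5 * (z_sf[-2] + z_sf[-3]),
                             side="right") - 1
        if 0 <= jx < nbin and 0 <= jy < nbin:
            right[jx, jy] += 1
    dwell = pd.Series(labels, dtype=object).value_counts(normalize=True) \
        if labels else pd.Series(dtype=float)
    return KnockOnHistogram(left, right, edges, dwell, n_contrib)
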