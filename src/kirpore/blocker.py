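"""Polyamine (SPM) block analysis: binding/unbinding kinetics and displacement.

Binding is read from the distance between the blocker and the
rectification-controller landmark (D173 Cα center of mass), smoothed with
a 30-ns running median: bound when the smoothed distance first drops to
10 Å or less, unbound when it first exceeds 20 Å.  The two separated
thresholds act as a hysteresis band, so bind/unbind events strictly
alternate.  Waiting times across replicates are summarized by the
right-censored exponential maximum-likelihood estimator
``τ̂ = (Σ observed + Σ censored durations) / #events`` with a χ²
confidence interval.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .pore_model import PoreGeometry
from .synthetic import Z_D173

__all__ = [
    "BlockerConfig",
    "TauEstimate",
    "running_median",
    "spm_distance_series",
    "detect_binding",
    "detect_unbinding",
    "estimate_tau",
    "station_bands",
    "classify_station",
    "displaced_ions",
    "block_modulated_current",
]


@dataclass(frozen=True)
class BlockerConfig:
    """Detection thresholds; defaults follow the 10/20-Å 30-ns convention."""

    d_on: float = 10.0  # A, smoothed distance at/below which SPM is bound
    d_off: float = 20.0  # A, smoothed distance above which SPM has unbound
    window_ns: float = 30.0  # running-median window
    landmark: str = "COM_D173"

    def __post_init__(self):
        if not (self.d_off > self.d_on > 0):
            raise ValueError("need d_off > d_on > 0")
        if self.window_ns <= 0:
            raise ValueError("window must be positive")


def running_median(series, window_ns: float, dt_ns: float) -> np.ndarray:
    """Centered running median with an odd window of ``round(w/dt) | 1`` frames.

    Edges use truncated windows (no reflected or invented data).
    """
    if window_ns < dt_ns:
        raise ValueError("window must be at least one frame interval")
    wlen = int(round(window_ns / dt_ns)) | 1
    s = pd.Series(np.asarray(series, dtype=float))
    return s.rolling(wlen, center=True, min_periods=1).median().to_numpy()


def spm_distance_series(tracks: pd.DataFrame, config: BlockerConfig | None = None,
                        spm_id: str = "spm"):
    """(times, raw distance, smoothed distance) of SPM to the landmark."""
    config = config or BlockerConfig()
    spm = tracks[tracks["particle"] == spm_id].sort_values("frame")
    ref = tracks[tracks["particle"] == config.landmark].sort_values("frame")
    if spm.empty or ref.empty:
        raise ValueError("SPM bead or landmark missing from tracks")
    n = min(len(spm), len(ref))
    xyz_s = spm[["x", "y", "z"]].to_numpy()[:n]
    xyz_r = ref[["x", "y", "z"]].to_numpy()[:n]
    dist = np.linalg.norm(xyz_s - xyz_r, axis=1)
    times = spm["time"].to_numpy()[:n]
    dt_ns = (times[1] - times[0]) * 1e3 if n > 1 else config.window_ns
    smooth = running_median(dist, config.window_ns, dt_ns)
    return times, dist, smooth


def detect_binding(times, smoothed, config: BlockerConfig | None = None):
    """First time the smoothed distance is ≤ d_on, or None (censored)."""
    config = config or BlockerConfig()
    idx = np.nonzero(np.asarray(smoothed) <= config.d_on)[0]
    return float(np.asarray(times)[idx[0]]) if len(idx) else None


def detect_unbinding(times, smoothed, config: BlockerConfig | None = None,
                     block_start: float = 0.0):
    """First time after ``block_start`` the smoothed distance exceeds d_off.

    Returned time is measured **from** the block start; None if censored.
    Excursions into the (d_on, d_off] band do not count (hysteresis).
    """
    config = config or BlockerConfig()
    times = np.asarray(times)
    if block_start > times[-1]:
        raise ValueError("block start lies beyond the end of the series")
    after = times >= block_start
    idx = np.nonzero(after & (np.asarray(smoothed) > config.d_off))[0]
    return float(times[idx[0]] - block_start) if len(idx) else None


@dataclass(frozen=True)
class TauEstimate:
    tau: float | None  # us; None when no uncensored event (lower bound only)
    ci_low: float
    ci_high: float
    n_events: int
    n_censored: int
    total_time: float  # us

    @property
    def lower_bound_only(self) -> bool:
        return self.tau is None


def estimate_tau(event_times, censoring_times=(), alpha: float = 0.05
                 ) -> TauEstimate:
    """Right-censored exponential MLE of a waiting-time constant.

    ``τ̂ = (Σ observed + Σ censored)/k`` with k the number of observed
    events; the CI comes from ``2T/τ ~ χ²(2k)``.  With zero observed
    events only a lower bound (``ci_low``) is defined.
    """
    obs = np.asarray(list(event_times), dtype=float)
    cens = np.asarray(list(censoring_times), dtype=float)
    total = float(obs.sum() + cens.sum())
    k = len(obs)
    if k == 0:
        # bound: tau > T / chi2 upper quantile with 2 dof
        low = 2.0 * total / stats.chi2.ppf(1 - alpha / 2, 2)
        return TauEstimate(None, low, np.inf, 0, len(cens), total)
    tau = total / k
    ci_low = 2.0 * total / stats.chi2.ppf(1 - alpha / 2, 2 * k)
    ci_high = 2.0 * total / stats.chi2.ppf(alpha / 2, 2 * k)
    return TauEstimate(tau, ci_low, ci_high, k, len(cens), total)


def station_bands(geometry: PoreGeometry, z_d173: float = Z_D173):
    """Half-open axial bands of the SPM binding stations.

    ``above_D173`` spans from the D173 plane to the bottom of S6 — the
    deep binding region between the rectification controller and the SF.
    """
    return (
        ("bulk", -np.inf, geometry.z_lo("CTD")),
        ("CTD", geometry.z_lo("CTD"), geometry.z_hi("CTD")),
        ("G_loop", geometry.z_lo("G_loop"), geometry.z_hi("G_loop")),
        ("cavity", geometry.z_lo("cavity"), z_d173),
        ("above_D173", z_d173, geometry.z_lo("S6")),
        ("SF", geometry.z_lo("S6"), geometry.z_hi("S_ext")),
        ("translocated", geometry.z_hi("S_ext"), np.inf),
    )


def classify_station(z, geometry: PoreGeometry, z_d173: float = Z_D173):
    """Station name(s) for axial position(s), half-open band lookup."""
    bands = station_bands(geometry, z_d173)
    names = np.array([n for n, _, _ in bands])
    uppers = np.array([hi for _, _, hi in bands[:-1]])
    z_arr = np.asarray(z, dtype=float)
    idx = np.searchsorted(uppers, z_arr, side="right")
    out = names[idx]
    if np.isscalar(z) or z_arr.ndim == 0:
        return str(out)
    return out


def displaced_ions(tracks: pd.DataFrame, geometry: PoreGeometry,
                   bind_time: float, window: float = 0.5,
                   region: str = "TM_pore", roles=("ion",)) -> int:
    """Ions evicted from the TM pore (cavity+SF) by deep SPM binding.

    Counted as (ions in the region at the last frame before ``bind_time``)
    minus (ions there at the first frame at or after ``bind_time +
    window``), floored at zero.  ``bind_time`` of None (no binding) is an
    error: the count is undefined.
    """
    import warnings

    if bind_time is None:
        raise ValueError("displaced-ion count undefined: no deep binding")
    from .trajio import with_axial

    tracks = with_axial(tracks, geometry)
    lo, hi = geometry.region_interval(region)
    sel = tracks[tracks["role"].isin(roles)]
    times = np.sort(tracks["time"].unique())
    before = times[times < bind_time]
    if len(before) == 0:
        raise ValueError("no frames before the binding time")
    t_before = before[-1]
    t_target = bind_time + window
    if t_target > times[-1]:
        warnings.warn("displacement window extends past the trajectory; "
                      "using the final frame")
        t_after = times[-1]
    else:
        t_after = times[times >= t_target][0]

    def count_at(t):
        frame = sel[np.isclose(sel["time"], t)]
        inside = (frame["za"] >= lo) & (frame["za"] < hi)
        return int(inside.sum())

    return max(0, count_at(t_before) - count_at(t_after))


def block_modulated_current(events: pd.DataFrame, bound_intervals,
                            duration: float, voltage: float):
    """Currents over SPM-bound and unbound time segments separately.

    ``bound_intervals`` is a list of (start, stop) µs.  Returns a dict
    with ``current_unblocked_pa`` / ``current_blocked_pa`` (None when the
    respective total time is zero) and the event partition counts.
    """
    from .permeation import current_and_conductance

    bound_time = sum(b - a for a, b in bound_intervals)
    unbound_time = duration - bound_time

    def in_bound(t):
        return any(a <= t < b for a, b in bound_intervals)

    if len(events):
        mask = events["t_exit"].map(in_bound)
        ev_b = events[mask]
        ev_u = events[~mask]
    else:
        ev_b = ev_u = events
    out = {"n_events_blocked": len(ev_b), "n_events_unblocked": len(ev_u)}
    if bound_time > 0:
        out["current_blocked_pa"] = current_and_conductance(
            ev_b, bound_time, voltage).current_pa
    else:
        out["current_blocked_pa"] = None
    if unbound_time > 0:
        out["current_unblocked_pa"] = current_and_conductance(
            ev_u, unbound_time, voltage).current_pa
    else:
        out["current_unblocked_pa"] = None
    return out
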