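"""Stochastic kinetic trajectory generator for the extended Kir pore.

The generator stands in for millisecond-scale all-atom trajectories: a
continuous-time Markov (exact-jump / Gillespie) model of single-file,
voltage-biased ion hopping through the extended pore (bulk_in → CTD →
G-loop → cavity → SF sites S6…S0 → S_ext → bulk_out), with

* site exclusion (SF sites hold one ion; CTD/cavity hold several),
* Eyring-type voltage bias ``k(V) = k₀·exp(±z·δ·V·F/(2RT))`` where δ is the
  fraction of the membrane voltage dropped across the edge,
* stochastic water co-permeation (Bernoulli per completed outward
  permeation),
* a two-state gate with Gaussian open-state hydration and an absorbing
  closure hazard, and
* an optional tetravalent polyamine (SPM) blocker hopping over station
  regions, with voltage-dependent deep binding that can evict and block
  pore ions.

Every stochastic transition is recorded in an exact :class:`GroundTruthLog`
so analyzers can be validated event-for-event, and frames are sampled on a
regular grid with Gaussian positional jitter to mimic coordinate output.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .pore_model import (
    CHAIN_SITES,
    SF_SITES,
    PoreGeometry,
    default_geometry,
    thermal_voltage_mv,
)

__all__ = [
    "KineticModel",
    "GateModel",
    "BlockerModel",
    "Event",
    "GroundTruthLog",
    "TrajectoryBundle",
    "Scenario",
    "DeadlockError",
    "simulate",
    "calibrate_blocker_rates",
    "scenario_preset",
    "wt_base_rates",
    "wt_voltage_coupling",
]

# Axial plane of the rectification-controller (D173) Calpha ring, and the
# park positions used for particles residing in the bulk reservoirs.
Z_D173 = -8.0
PARK_IN_Z = -62.0
PARK_OUT_Z = 32.0

_BLOCKER_STATIONS = (
    ("bulk", -70.0),
    ("CTD", -42.0),
    ("G_loop", -25.0),
    ("cavity", -19.0),
    ("deep_site", -7.2),
    ("SF", 5.0),
    ("translocated", 30.0),
)


class DeadlockError(RuntimeError):
    """Raised when a reachable state has no escape despite nonzero rates."""


# ---------------------------------------------------------------------------
# model specifications
# ---------------------------------------------------------------------------


def _forward_chain_edges():
    return list(zip(CHAIN_SITES[:-1], CHAIN_SITES[1:]))


@dataclass
class KineticModel:
    """Generative specification of the voltage-biased hopping model.

    ``base_rates`` maps directed edges ``(site_i, site_j)`` between adjacent
    chain sites to zero-field rates k₀ in µs⁻¹; ``voltage_coupling`` maps the
    forward (outward) edge to the fraction δ of the total membrane voltage
    dropped across it (the same δ biases the reverse hop).  The δ values over
    the full intracellular→extracellular path must sum to 1.
    """

    geometry: PoreGeometry = field(default_factory=default_geometry)
    capacities: dict = field(default_factory=dict)
    base_rates: dict = field(default_factory=dict)
    voltage_coupling: dict = field(default_factory=dict)
    voltage: float = 0.0  # mV
    temperature: float = 310.0  # K
    water_coperm_prob: float = 0.22
    mechanism_constrained: bool = False
    # per-step rates (µs⁻¹) of the constrained knock-on cycle; None derives
    # them from the corresponding single-ion edges
    cycle_rates: dict | None = None
    ion_charge: float = 1.0
    initial_occupancy: dict | None = None
    seed: int | None = None

    def __post_init__(self):
        for edge, k in self.base_rates.items():
            if k < 0:
                raise ValueError(f"negative rate for edge {edge}: {k}")
        for site, cap in self.capacities.items():
            if cap < 1:
                raise ValueError(f"capacity of {site} must be >= 1, got {cap}")
        if not 0.0 <= self.water_coperm_prob <= 1.0:
            raise ValueError("water_coperm_prob must lie in [0, 1]")
        forward = _forward_chain_edges()
        if self.voltage_coupling and all(e in self.voltage_coupling for e in forward):
            total = sum(self.voltage_coupling[e] for e in forward)
            if abs(total - 1.0) > 1e-9:
                raise ValueError(
                    f"voltage couplings along the transmembrane path sum to "
                    f"{total}, expected 1"
                )

    def capacity(self, site: str) -> int:
        if site in ("bulk_in", "bulk_out"):
            return 10**9
        return self.capacities.get(site, 1)

    def delta(self, a: str, b: str) -> float:
        ia, ib = CHAIN_SITES.index(a), CHAIN_SITES.index(b)
        edge = (a, b) if ib > ia else (b, a)
        return self.voltage_coupling.get(edge, 0.0)

    def rate(self, a: str, b: str) -> float:
        """Voltage-biased hop rate a→b in µs⁻¹."""
        k0 = self.base_rates.get((a, b), 0.0)
        if k0 == 0.0:
            return 0.0
        sign = 1.0 if CHAIN_SITES.index(b) > CHAIN_SITES.index(a) else -1.0
        kt = thermal_voltage_mv(self.temperature)
        return k0 * math.exp(
            sign * self.ion_charge * self.delta(a, b) * self.voltage / (2.0 * kt)
        )

    def default_initial_occupancy(self) -> dict:
        if self.initial_occupancy is not None:
            return dict(self.initial_occupancy)
        if not any(k > 0 for k in self.base_rates.values()):
            return {}
        if self.mechanism_constrained:
            return {"CTD": 3, "cavity": 3, "S6": 1, "S4": 1, "S2": 1, "S1": 1}
        return {"CTD": 3, "cavity": 3}


@dataclass
class GateModel:
    """Two-state (open/closed) activation gate.

    The open→closed transition is an absorbing hazard ``closure_rate`` (µs⁻¹);
    per-frame cavity hydration and the I177 Cα–Cα diagonal are drawn from
    state-dependent Gaussians.  Defaults reflect the stably open pore:
    hydration 56 ± 8 waters, I177 diagonal 16.5 ± 0.8 Å, dropping to ∼20
    waters and ∼10 Å upon closure.
    """

    closure_rate: float = 0.0  # us^-1
    open_hydration: tuple = (56.0, 8.0)
    closed_hydration: tuple = (20.0, 5.0)
    open_gate_distance: tuple = (16.5, 0.8)  # I177 Calpha-Calpha diagonal, A
    closed_gate_distance: tuple = (10.0, 0.5)
    # secondary gate residue one helix turn below; diagonal offset vs I177
    m181_offset: float = 2.0
    ctd_sf_separation_open: float = 48.0  # A
    ctd_sf_separation_closed: float = 51.0

    def __post_init__(self):
        if self.closure_rate < 0:
            raise ValueError("closure_rate must be >= 0")
        if self.open_hydration[0] <= self.closed_hydration[0]:
            raise ValueError("open-state hydration mean must exceed closed")


@dataclass
class BlockerModel:
    """Voltage-dependent SPM blocker over ordered station regions.

    ``rates`` maps directed station pairs to ``(k₀ µs⁻¹, δ)``.  Entering
    ``deep_site`` (the region above the rectification controller D173,
    reaching into the lower SF) evicts pore ions in the direction of the
    field (``displace_on_deep_bind``) and shuts down ion transport through
    the TM pore (``block_on_deep_bind``).
    """

    stations: tuple = _BLOCKER_STATIONS
    rates: dict = field(default_factory=dict)
    displace_on_deep_bind: bool = True
    block_on_deep_bind: bool = True
    start_station: str = "bulk"
    charge: float = 4.0  # fully protonated tetra-amine

    def __post_init__(self):
        z = [anchor for _, anchor in self.stations]
        if any(b <= a for a, b in zip(z[:-1], z[1:])):
            raise ValueError("station z anchors must be strictly increasing")
        for pair, (k0, _delta) in self.rates.items():
            if k0 < 0:
                raise ValueError(f"negative blocker rate for {pair}")
        names = [n for n, _ in self.stations]
        if self.start_station not in names:
            raise ValueError(f"unknown start station {self.start_station!r}")

    @property
    def station_names(self) -> tuple:
        return tuple(n for n, _ in self.stations)

    def anchor(self, station: str) -> float:
        for name, z in self.stations:
            if name == station:
                return z
        raise KeyError(station)

    def rate(self, a: str, b: str, voltage: float, temperature: float = 310.0) -> float:
        if (a, b) not in self.rates:
            return 0.0
        k0, delta = self.rates[(a, b)]
        if k0 == 0.0:
            return 0.0
        sign = 1.0 if self.anchor(b) > self.anchor(a) else -1.0
        kt = thermal_voltage_mv(temperature)
        return k0 * math.exp(sign * self.charge * delta * voltage / (2.0 * kt))


# ---------------------------------------------------------------------------
# ground-truth log
# ---------------------------------------------------------------------------

EVENT_KINDS = (
    "hop", "permeation_out", "permeation_in", "water_coperm",
    "spm_bind", "spm_unbind", "closure",
)


@dataclass(frozen=True)
class Event:
    time: float  # us
    kind: str
    particle: str | None = None
    from_site: str | None = None
    to_site: str | None = None


@dataclass
class GroundTruthLog:
    """Exact, ordered record of every stochastic event in a simulation."""

    events: list
    duration: float  # us
    voltage: float  # mV
    seed: int | None = None
    initial_occupancy: dict = field(default_factory=dict)

    def __post_init__(self):
        times = [e.time for e in self.events]
        if any(b < a for a, b in zip(times[:-1], times[1:])):
            raise ValueError("event times must be non-decreasing")

    # -- queries -----------------------------------------------------------

    def of_kind(self, kind: str) -> list:
        return [e for e in self.events if e.kind == kind]

    def count(self, kind: str) -> int:
        return sum(1 for e in self.events if e.kind == kind)

    @property
    def n_permeations_out(self) -> int:
        return self.count("permeation_out")

    @property
    def n_permeations_in(self) -> int:
        return self.count("permeation_in")

    def closure_time(self) -> float | None:
        for e in self.events:
            if e.kind == "closure":
                return e.time
        return None

    def bind_times(self) -> list:
        return [e.time for e in self.events if e.kind == "spm_bind"]

    def unbind_times(self) -> list:
        return [e.time for e in self.events if e.kind == "spm_unbind"]

    def net_crossings_from_hops(self) -> int:
        """Net outward crossings reconstructed purely from the hop records.

        Replays a two-sided state machine over each particle's site
        sequence: the side flips to "in" in the sub-SF sites (bulk_in,
        CTD, G-loop, cavity) and to "out" in bulk_out; an in→out flip is
        +1, out→in is −1.  Initial sides come from each particle's first
        recorded location.  This reconstruction is independent of the
        permeation events in the log.
        """
        side: dict = {}
        net = 0
        for e in self.events:
            if e.kind != "hop":
                continue
            pid = e.particle
            if pid not in side:
                start = e.from_site
                side[pid] = ("in" if start in BELOW_SITES
                             else "out" if start == "bulk_out" else None)
            if e.to_site == "bulk_out":
                if side[pid] == "in":
                    net += 1
                side[pid] = "out"
            elif e.to_site in BELOW_SITES:
                if side[pid] == "out":
                    net -= 1
                side[pid] = "in"
        return net

    def occupancy_from_log(self, region: str, geometry: PoreGeometry,
                           t_max: float | None = None) -> float:
        """Time-averaged particle count in a (composite) region from hops."""
        sites = set(geometry.sites_in(region))
        t_max = self.duration if t_max is None else t_max
        count = sum(self.initial_occupancy.get(s, 0) for s in sites)
        acc = 0.0
        t_prev = 0.0
        for e in self.events:
            if e.kind != "hop":
                continue
            t = min(e.time, t_max)
            if t > t_prev:
                acc += count * (t - t_prev)
                t_prev = t
            inc = (e.to_site in sites) - (e.from_site in sites)
            count += inc
            if e.time >= t_max:
                break
        acc += count * max(0.0, t_max - t_prev)
        return acc / t_max

    def residence_intervals(self, region: str, geometry: PoreGeometry) -> pd.DataFrame:
        """Maximal contiguous visits of each particle to a region.

        Returns columns ``particle, t_start, t_end, censored`` (censored:
        the visit was cut by the end of the simulation).
        """
        sites = set(geometry.sites_in(region))
        open_visits: dict = {}
        rows = []
        # initially-placed particles are handled via their first hop; the
        # simulator logs initial placements as hops from their start site
        for e in self.events:
            if e.kind != "hop":
                continue
            inside_before = e.from_site in sites
            inside_after = e.to_site in sites
            if inside_after and not inside_before:
                open_visits[e.particle] = e.time
            elif inside_before and not inside_after and e.particle in open_visits:
                rows.append((e.particle, open_visits.pop(e.particle), e.time, False))
        for pid, t0 in open_visits.items():
            rows.append((pid, t0, self.duration, True))
        return pd.DataFrame(rows, columns=["particle", "t_start", "t_end", "censored"])

    # -- serialization -----------------------------------------------------

    def to_jsonl(self, path) -> None:
        with open(path, "w") as fh:
            meta = {
                "duration_us": self.duration,
                "voltage_mv": self.voltage,
                "seed": self.seed,
                "initial_occupancy": self.initial_occupancy,
            }
            fh.write(json.dumps({"meta": meta}) + "\n")
            for e in self.events:
                fh.write(json.dumps(dataclasses.asdict(e)) + "\n")

    @classmethod
    def from_jsonl(cls, path) -> "GroundTruthLog":
        with open(path) as fh:
            meta = json.loads(fh.readline())["meta"]
            events = [Event(**json.loads(line)) for line in fh if line.strip()]
        return cls(
            events=events,
            duration=meta["duration_us"],
            voltage=meta["voltage_mv"],
            seed=meta["seed"],
            initial_occupancy=meta["initial_occupancy"],
        )


# ---------------------------------------------------------------------------
# trajectory bundle
# ---------------------------------------------------------------------------


@dataclass
class ParticleFrames:
    role: str
    start: int  # first frame with coordinates
    xyz: np.ndarray  # (n_active_frames, 3) float32


@dataclass
class TrajectoryBundle:
    """Frames of pseudo-atom coordinates sampled from a simulation.

    Particle coordinate blocks are sparse: each particle carries positions
    only over its active frame window (bulk residency before/after is
    parked at a constant position included at the window edges).
    """

    dt_ns: float
    n_frames: int
    particles: dict  # id -> ParticleFrames
    geometry: PoreGeometry
    jitter_sd: float = 0.5
    voltage: float = 0.0

    def __post_init__(self):
        if self.n_frames < 1:
            raise ValueError("bundle must contain at least one frame")
        widths = [hi - lo for _, lo, hi in self.geometry.site_bounds]
        if self.jitter_sd >= min(widths) / 2.0:
            raise ValueError(
                "jitter sd must stay below half the narrowest site width "
                "so site assignment remains recoverable"
            )

    @property
    def times_us(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.dt_ns * 1e-3

    def to_track_table(self) -> pd.DataFrame:
        """Long-format track table: one row per particle per active frame."""
        frames, times, pids, roles, xs, ys, zs = [], [], [], [], [], [], []
        t_all = self.times_us
        for pid, pf in self.particles.items():
            n = len(pf.xyz)
            idx = np.arange(pf.start, pf.start + n)
            frames.append(idx)
            times.append(t_all[idx])
            pids.append(np.repeat(pid, n))
            roles.append(np.repeat(pf.role, n))
            xs.append(pf.xyz[:, 0])
            ys.append(pf.xyz[:, 1])
            zs.append(pf.xyz[:, 2])
        if not frames:
            raise ValueError("bundle holds no particles")
        df = pd.DataFrame({
            "frame": np.concatenate(frames).astype(np.int64),
            "time": np.concatenate(times),
            "particle": np.concatenate(pids),
            "role": np.concatenate(roles),
            "x": np.concatenate(xs).astype(np.float64),
            "y": np.concatenate(ys).astype(np.float64),
            "z": np.concatenate(zs).astype(np.float64),
        })
        return df.sort_values(["particle", "frame"], kind="stable",
                              ignore_index=True)


@dataclass
class Scenario:
    """A named study condition: kinetic model + gate + optional blocker."""

    model: KineticModel
    gate: GateModel
    blocker: BlockerModel | None = None


# ---------------------------------------------------------------------------
# simulation core
# ---------------------------------------------------------------------------


def _blocked_edges():
    """Ion edges shut while SPM occupies the deep site.

    The tetravalent blocker parked above D173 both occludes the SF and
    electrostatically excludes potassium from the cavity below it, so all
    transport into or within cavity+SF is suppressed.
    """
    blocked = set()
    tm = ("cavity", *SF_SITES, "S_ext")
    for a, b in zip(CHAIN_SITES[:-1], CHAIN_SITES[1:]):
        if a in tm or b in tm:
            blocked.add((a, b))
            blocked.add((b, a))
    # leaving toward the bulk reservoirs remains possible
    blocked.discard(("S_ext", "bulk_out"))
    blocked.discard(("cavity", "G_loop"))
    return blocked


_BLOCKED_ION_EDGES = _blocked_edges()

_SF_CYCLE = {
    # mechanism-constrained knock-on cycle; each state lists occupied sites
    "A": ("S6", "S4", "S2", "S1"),
    "B": ("S5", "S4", "S2", "S1"),
    "C": ("S5", "S3", "S2", "S0"),
    "D": ("S4", "S2", "S1", "S_ext"),
    "E": ("S4", "S2", "S1"),
}


# The two "sides" of the permeation bookkeeping.  A permeation is logged
# when an ion's side flips from intracellular to extracellular (outward)
# or vice versa — the same two-threshold semantics the coordinate-space
# detector applies, so analyzer event counts match the log exactly.
BELOW_SITES = frozenset({"bulk_in", "CTD", "G_loop", "cavity"})


class _SimState:
    def __init__(self, model, blocker, rng):
        self.model = model
        self.rng = rng
        self.site_ions = {s: [] for s in CHAIN_SITES if s not in ("bulk_in", "bulk_out")}
        self.side = {}  # particle -> "in" | "out" | None
        self.history = {}  # particle -> list[(time, site)]
        self.next_ion = 0
        self.closed = False
        self.blocked = False
        self.spm_station = blocker.start_station if blocker else None
        self.sf_state = "A" if model.mechanism_constrained else None

    def new_ion(self, origin_site):
        pid = f"ion{self.next_ion}"
        self.next_ion += 1
        self.side[pid] = ("in" if origin_site in BELOW_SITES
                          else "out" if origin_site == "bulk_out" else None)
        return pid

    def move(self, pid, a, b, t):
        if a not in ("bulk_in", "bulk_out"):
            self.site_ions[a].remove(pid)
        if b not in ("bulk_in", "bulk_out"):
            self.site_ions[b].append(pid)
        self.history.setdefault(pid, []).append((t, b))


def simulate(model: KineticModel, gate: GateModel | None = None,
             blocker: BlockerModel | None = None, duration: float = 10.0,
             seed: int | None = None, dt_ns: float = 2.0,
             jitter_sd: float = 0.5, include_gate_atoms: bool = True,
             include_hydration: bool = False,
             ) -> tuple[TrajectoryBundle, GroundTruthLog]:
    """Run an exact-jump simulation and sample frames.

    Parameters
    ----------
    model, gate, blocker
        The generative specification.  ``gate=None`` means a permanently
        open pore; ``blocker=None`` omits the SPM particle.
    duration : float
        Simulated time in µs.
    seed : int, optional
        Master seed (falls back to ``model.seed``).  All stochastic output
        is reproducible bit-exact for a given seed.
    dt_ns : float
        Frame sampling interval in ns.
    jitter_sd : float
        Gaussian positional jitter (Å) around site centers.

    Returns
    -------
    (TrajectoryBundle, GroundTruthLog)
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if seed is None:
        seed = model.seed
    rng = np.random.default_rng(seed)
    state = _SimState(model, blocker, rng)
    events: list[Event] = []
    initial = model.default_initial_occupancy()

    # place initial ions (logged only through initial_occupancy meta)
    for site, n in initial.items():
        for _ in range(n):
            pid = state.new_ion(site)
            state.site_ions[site].append(pid)
            state.history[pid] = [(0.0, site)]

    any_ion_rate = any(k > 0 for k in model.base_rates.values())
    t_close = math.inf
    if gate is not None and gate.closure_rate > 0:
        t_close = rng.exponential(1.0 / gate.closure_rate)

    water_count = 0
    spm_history = [(0.0, state.spm_station)] if blocker else None
    if blocker and state.spm_station == "deep_site":
        state.blocked = blocker.block_on_deep_bind

    # voltage is fixed per run: pre-bias all hop rates once
    constrained = model.mechanism_constrained
    sf_and_ext = set(SF_SITES) | {"S_ext"}
    ion_edges = []
    for a, b in zip(CHAIN_SITES[:-1], CHAIN_SITES[1:]):
        for x, y in ((a, b), (b, a)):
            if constrained and (x in sf_and_ext or y in sf_and_ext):
                continue
            k = model.rate(x, y)
            if k > 0.0:
                ion_edges.append((x, y, k))
    cycle_rates = model.cycle_rates or {
        "A": model.rate("S6", "S5"),
        "B": model.rate("S4", "S3"),
        "C": model.rate("S5", "S4"),
        "D": model.rate("S_ext", "bulk_out"),
        "E": model.rate("cavity", "S6"),
    }
    spm_rates = {}
    if blocker is not None:
        names = blocker.station_names
        for i, a in enumerate(names):
            for j in (i - 1, i + 1):
                if 0 <= j < len(names):
                    k = blocker.rate(a, names[j], model.voltage,
                                     model.temperature)
                    if k > 0.0:
                        spm_rates.setdefault(a, []).append((names[j], k))

    def ion_moves():
        moves = []
        if state.closed:
            return moves
        site_ions = state.site_ions
        capacity = model.capacity
        for x, y, k in ion_edges:
            if state.blocked and (x, y) in _BLOCKED_ION_EDGES:
                continue
            if x == "bulk_in" or x == "bulk_out":
                n_src = 1  # reservoir entry, pseudo-first-order
            else:
                n_src = len(site_ions[x])
                if n_src == 0:
                    continue
            if y not in ("bulk_in", "bulk_out") and \
                    len(site_ions[y]) >= capacity(y):
                continue
            moves.append((n_src * k, "ion_hop", (x, y)))
        if constrained and not state.blocked:
            sf = state.sf_state
            if sf == "E":
                n_cav = len(site_ions["cavity"])
                if n_cav:
                    moves.append((n_cav * cycle_rates["E"], "sf_cycle", "E"))
            else:
                r = cycle_rates[sf]
                if r > 0:
                    moves.append((r, "sf_cycle", sf))
        return moves

    def spm_moves():
        if blocker is None or state.closed:
            return []
        return [(k, "spm_hop", dest)
                for dest, k in spm_rates.get(state.spm_station, ())]

    def record_hop(pid, x, y, t):
        """Move an ion, log the hop and apply the permeation side-machine."""
        state.move(pid, x, y, t)
        events.append(Event(t, "hop", pid, x, y))
        side = state.side.get(pid)
        if y == "bulk_out":
            if side == "in":
                events.append(Event(t, "permeation_out", pid))
                maybe_coperm_water(t)
            state.side[pid] = "out"
        elif y in BELOW_SITES:
            if side == "out":
                events.append(Event(t, "permeation_in", pid))
            state.side[pid] = "in"

    def maybe_coperm_water(t):
        nonlocal water_count
        if rng.random() < model.water_coperm_prob:
            wid = f"w{water_count}"
            water_count += 1
            events.append(Event(t, "water_coperm", wid))

    def apply_ion_hop(edge, t):
        x, y = edge
        if x in ("bulk_in", "bulk_out"):
            pid = state.new_ion(x)
            state.history[pid] = [(t, x)]
        else:
            idx = rng.integers(len(state.site_ions[x]))
            pid = state.site_ions[x][idx]
        record_hop(pid, x, y, t)

    def apply_cycle(step, t):
        def shift(frm, to):
            pid = state.site_ions[frm][0]
            record_hop(pid, frm, to, t)
        if step == "A":
            shift("S6", "S5")
            state.sf_state = "B"
        elif step == "B":
            shift("S4", "S3")
            shift("S1", "S0")
            state.sf_state = "C"
        elif step == "C":
            shift("S0", "S_ext")
            shift("S2", "S1")
            shift("S3", "S2")
            shift("S5", "S4")
            state.sf_state = "D"
        elif step == "D":
            shift("S_ext", "bulk_out")
            state.sf_state = "E"
        elif step == "E":
            idx = rng.integers(len(state.site_ions["cavity"]))
            pid = state.site_ions["cavity"][idx]
            record_hop(pid, "cavity", "S6", t)
            state.sf_state = "A"

    def apply_spm_hop(dest, t):
        src = state.spm_station
        state.spm_station = dest
        spm_history.append((t, dest))
        if dest == "deep_site":
            events.append(Event(t, "spm_bind", "spm", src, dest))
            if blocker.displace_on_deep_bind and not model.mechanism_constrained:
                evict_sites = ["cavity", *SF_SITES, "S_ext"]
                target = "bulk_out" if model.voltage >= 0 else "bulk_in"
                for site in evict_sites:
                    for pid in list(state.site_ions[site]):
                        record_hop(pid, site, target, t)
            if blocker.block_on_deep_bind:
                state.blocked = True
        elif src == "deep_site":
            events.append(Event(t, "spm_unbind", "spm", src, dest))
            state.blocked = False

    # ------------------------------------------------------------------ loop
    t = 0.0
    while True:
        moves = ion_moves() + spm_moves()
        total = sum(m[0] for m in moves)
        if total == 0.0:
            if (not state.closed and any_ion_rate and not state.blocked
                    and not model.mechanism_constrained):
                occupied = {s: len(v) for s, v in state.site_ions.items() if v}
                raise DeadlockError(
                    f"no escape from reachable state at t={t:.4f} us; "
                    f"occupancy {occupied}, SPM at {state.spm_station}"
                )
            if not state.closed and t_close <= duration:
                events.append(Event(t_close, "closure"))
                state.closed = True
                t = t_close
                continue
            break
        t_next = t + rng.exponential(1.0 / total)
        if not state.closed and t_close < t_next:
            if t_close > duration:
                break  # t_next > t_close > duration: nothing left to do
            events.append(Event(t_close, "closure"))
            state.closed = True
            t = t_close
            continue
        if t_next > duration:
            break
        t = t_next
        u = rng.random() * total
        acc = 0.0
        for r, kind, payload in moves:
            acc += r
            if u <= acc:
                if kind == "ion_hop":
                    apply_ion_hop(payload, t)
                elif kind == "sf_cycle":
                    apply_cycle(payload, t)
                else:
                    apply_spm_hop(payload, t)
                break

    log = GroundTruthLog(
        events=events, duration=duration, voltage=model.voltage,
        seed=seed, initial_occupancy=dict(initial),
    )
    bundle = _sample_frames(
        model, gate, blocker, state, log, duration, dt_ns, jitter_sd,
        include_gate_atoms, include_hydration, rng,
        t_close if state.closed else None, spm_history,
    )
    return bundle, log


# ---------------------------------------------------------------------------
# frame sampling
# ---------------------------------------------------------------------------


def _site_position(site, geometry, rng, n):
    """n jittered positions for particles resident in `site`.

    Placement respects the permeation side-machine: cavity ions stay below
    the detector's inner threshold (z_lo(S6) − 2 Å) and vestibule (S_ext)
    ions sit low at the pore mouth, below the outer threshold, so frame
    positions and logged hops yield identical event counts.
    """
    xy_sd = 0.5
    if site == "bulk_in":
        z = np.full(n, PARK_IN_Z)
    elif site == "bulk_out":
        z = np.full(n, PARK_OUT_Z)
    elif site in ("CTD", "G_loop", "cavity"):
        lo, hi = geometry.z_lo(site), geometry.z_hi(site)
        if site == "cavity":
            hi = min(hi, geometry.z_lo("S6") - 2.4)
        z = rng.uniform(lo + 0.5, hi, n)
        xy_sd = 2.0
    elif site == "S_ext":
        z = geometry.z_lo(site) + 1.0 + rng.normal(0.0, 0.25, n)
    else:
        z = geometry.z_center(site) + rng.normal(0.0, _JITTER[0], n)
    x = rng.normal(0.0, xy_sd, n)
    y = rng.normal(0.0, xy_sd, n)
    return np.column_stack([x, y, z]).astype(np.float32)


_JITTER = [0.5]  # set per call by _sample_frames


def _piecewise_positions(history, times, geometry, rng, jitter_sd):
    """Frame positions for a particle with (time, site) history."""
    h_times = np.array([t for t, _ in history])
    h_sites = [s for _, s in history]
    idx = np.searchsorted(h_times, times, side="right") - 1
    idx = np.clip(idx, 0, len(h_sites) - 1)
    out = np.empty((len(times), 3), dtype=np.float32)
    for k, site in enumerate(h_sites):
        mask = idx == k
        n = int(mask.sum())
        if n:
            out[mask] = _site_position(site, geometry, rng, n)
    return out


def _sample_frames(model, gate, blocker, state, log, duration, dt_ns,
                   jitter_sd, include_gate_atoms, include_hydration, rng,
                   closure_time, spm_history):
    _JITTER[0] = jitter_sd
    geometry = model.geometry
    dt_us = dt_ns * 1e-3
    n_frames = int(math.floor(duration / dt_us)) + 1
    times = np.arange(n_frames) * dt_us
    pad = 3
    particles = {}

    for pid, history in state.history.items():
        t0 = history[0][0]
        t1 = history[-1][0]
        final_site = history[-1][1]
        start = max(0, int(math.floor(t0 / dt_us)) - pad)
        if final_site in ("bulk_in", "bulk_out"):
            stop = min(n_frames, int(math.ceil(t1 / dt_us)) + pad + 1)
        else:
            stop = n_frames
        if stop <= start:
            continue
        seg = times[start:stop]
        xyz = _piecewise_positions(history, seg, geometry, rng, jitter_sd)
        particles[pid] = ParticleFrames("ion", start, xyz)

    # co-permeating water markers: parked intracellular before the event,
    # extracellular after
    for e in log.of_kind("water_coperm"):
        f_event = int(math.ceil(e.time / dt_us))
        start = max(0, f_event - pad - 1)
        stop = min(n_frames, f_event + pad + 1)
        if stop <= start:
            continue
        seg = times[start:stop]
        z = np.where(seg < e.time, PARK_IN_Z, PARK_OUT_Z)
        xyz = np.column_stack([
            rng.normal(0.0, jitter_sd, len(seg)),
            rng.normal(0.0, jitter_sd, len(seg)),
            z + rng.normal(0.0, jitter_sd, len(seg)),
        ]).astype(np.float32)
        particles[e.particle] = ParticleFrames("water", start, xyz)

    open_mask = np.ones(n_frames, dtype=bool)
    if closure_time is not None:
        open_mask = times < closure_time

    if gate is not None and include_hydration:
        mean_o, sd_o = gate.open_hydration
        mean_c, sd_c = gate.closed_hydration
        counts = np.where(
            open_mask,
            np.round(rng.normal(mean_o, sd_o, n_frames)),
            np.round(rng.normal(mean_c, sd_c, n_frames)),
        ).astype(int)
        np.clip(counts, 0, None, out=counts)
        pool = int(counts.max()) if n_frames else 0
        z_lo, z_hi, radius = geometry.cavity_cylinder
        for i in range(pool):
            present = counts > i
            r = (radius - 0.2) * np.sqrt(rng.uniform(0, 1, n_frames))
            theta = rng.uniform(0, 2 * np.pi, n_frames)
            xyz = np.empty((n_frames, 3), dtype=np.float32)
            xyz[:, 0] = np.where(present, r * np.cos(theta), 25.0)
            xyz[:, 1] = np.where(present, r * np.sin(theta), 25.0)
            xyz[:, 2] = np.where(present,
                                 rng.uniform(z_lo, z_hi - 1e-6, n_frames),
                                 PARK_IN_Z)
            particles[f"hw{i}"] = ParticleFrames("water", 0, xyz)

    if gate is not None and include_gate_atoms:
        specs = {
            "I177": (gate.open_gate_distance, gate.closed_gate_distance, -10.0),
            "M181": (
                (gate.open_gate_distance[0] + gate.m181_offset,
                 gate.open_gate_distance[1]),
                (gate.closed_gate_distance[0] + gate.m181_offset,
                 gate.closed_gate_distance[1]),
                -14.0,
            ),
        }
        for res, (open_d, closed_d, zg) in specs.items():
            d = np.where(open_mask,
                         rng.normal(open_d[0], open_d[1], n_frames),
                         rng.normal(closed_d[0], closed_d[1], n_frames))
            half = d / 2.0
            zeros = np.zeros(n_frames)
            zcol = np.full(n_frames, zg)
            corners = {  # diagonal pairing by subunit order: A-C, B-D
                "A": np.column_stack([half, zeros, zcol]),
                "B": np.column_stack([zeros, half, zcol]),
                "C": np.column_stack([-half, zeros, zcol]),
                "D": np.column_stack([zeros, -half, zcol]),
            }
            for sub, xyz in corners.items():
                particles[f"{res}_{sub}"] = ParticleFrames(
                    "gate", 0, xyz.astype(np.float32))

        sep = np.where(open_mask, gate.ctd_sf_separation_open,
                       gate.ctd_sf_separation_closed)
        sf_z = 8.0
        ctd = np.column_stack([
            rng.normal(0.0, 0.15, n_frames),
            rng.normal(0.0, 0.15, n_frames),
            sf_z - sep,
        ])
        particles["COM_SF"] = ParticleFrames(
            "landmark", 0,
            np.tile(np.array([0.0, 0.0, sf_z], dtype=np.float32), (n_frames, 1)))
        particles["COM_CTD"] = ParticleFrames("landmark", 0, ctd.astype(np.float32))

    if blocker is not None:
        particles["COM_D173"] = ParticleFrames(
            "landmark", 0,
            np.tile(np.array([0.0, 0.0, Z_D173], dtype=np.float32),
                    (n_frames, 1)))
        h_times = np.array([t for t, _ in spm_history])
        h_st = [s for _, s in spm_history]
        idx = np.clip(np.searchsorted(h_times, times, side="right") - 1,
                      0, len(h_st) - 1)
        anchors = np.array([blocker.anchor(s) for s in h_st])
        z = anchors[idx] + rng.normal(0.0, jitter_sd, n_frames)
        xyz = np.column_stack([
            rng.normal(0.0, jitter_sd, n_frames),
            rng.normal(0.0, jitter_sd, n_frames), z,
        ]).astype(np.float32)
        particles["spm"] = ParticleFrames("spm", 0, xyz)

    return TrajectoryBundle(
        dt_ns=dt_ns, n_frames=n_frames, particles=particles,
        geometry=geometry, jitter_sd=jitter_sd, voltage=model.voltage,
    )


# ---------------------------------------------------------------------------
# blocker calibration and scenario presets
# ---------------------------------------------------------------------------


def calibrate_blocker_rates(anchors) -> tuple[float, float]:
    """Fit the unbinding law τ(V) = (1/k₀)·exp(−|V|/Vs) through two anchors.

    Parameters
    ----------
    anchors : two (voltage_mV, mean_unbind_time_us) pairs at distinct
        voltages with positive times.

    Returns
    -------
    (k0, Vs) : zero-voltage unbinding rate (µs⁻¹) and the voltage scale
        (mV).  Equal times at distinct voltages give ``Vs = inf``
        (voltage-independent unbinding).
    """
    (v1, tau1), (v2, tau2) = anchors
    if tau1 <= 0 or tau2 <= 0:
        raise ValueError("unbinding times must be positive")
    a1, a2 = abs(v1), abs(v2)
    if a1 == a2:
        raise ValueError("anchors must be at distinct voltages")
    if tau1 == tau2:
        return 1.0 / tau1, math.inf
    vs = (a2 - a1) / math.log(tau1 / tau2)
    tau0 = tau1 * math.exp(a1 / vs)
    return 1.0 / tau0, vs


def unbind_time_at(k0: float, vs: float, voltage: float) -> float:
    """Mean unbinding time of the calibrated law at a voltage."""
    if math.isinf(vs):
        return 1.0 / k0
    return (1.0 / k0) * math.exp(-abs(voltage) / vs)


# Two printed anchors for the WT unbinding law: 8.1 µs at −185 mV and
# 0.33 µs at −310 mV.
WT_UNBIND_ANCHORS = ((-185.0, 8.1), (-310.0, 0.33))


def wt_base_rates() -> dict:
    """Zero-field hop rates (µs⁻¹) of the WT scenario.

    Free parameters of the model, calibrated once so that the stably open
    pore at +310 mV reproduces the printed steady-state observables:
    kinetic SF occupancy ≈2.87 with the axial density peaking at S1/S2/
    S3-S4, cavity occupancy ≈2.7 and CTD ≈2.8.  The SF hops derive from a
    detailed-balance (site free-energy) parametrization with shallow
    shuttle sites S6/S5, wells at S4…S1 and a slow S1→S0 escape; the
    overall rate scale is chosen fast enough that occupancy time averages
    decorrelate within a few µs of simulated time.
    """
    r = {}

    def both(a, b, kf, kb):
        r[(a, b)] = kf
        r[(b, a)] = kb

    both("bulk_in", "CTD", 350.0, 80.0)
    both("CTD", "G_loop", 300.0, 225.0)
    both("G_loop", "cavity", 235.0, 300.0)
    both("cavity", "S6", 18.3, 82.8)
    both("S6", "S5", 577.8, 350.5)
    both("S5", "S4", 720.0, 281.3)
    both("S4", "S3", 216.7, 184.6)
    both("S3", "S2", 200.0, 200.0)
    both("S2", "S1", 192.2, 208.2)
    both("S1", "S0", 190.0, 643.6)
    both("S0", "S_ext", 155.8, 256.8)
    both("S_ext", "bulk_out", 600.0, 25.0)
    return r


def wt_voltage_coupling() -> dict:
    """Per-edge fractions of the membrane voltage; sums to 1 across the pore."""
    delta = {
        ("bulk_in", "CTD"): 0.02,
        ("CTD", "G_loop"): 0.04,
        ("G_loop", "cavity"): 0.04,
        ("cavity", "S6"): 0.10,
        ("S0", "S_ext"): 0.10,
        ("S_ext", "bulk_out"): 0.10,
    }
    sf_chain = (*SF_SITES,)
    for a, b in zip(sf_chain[:-1], sf_chain[1:]):
        delta[(a, b)] = 0.10
    return delta


def _wt_blocker() -> BlockerModel:
    k0_off, vs = calibrate_blocker_rates(WT_UNBIND_ANCHORS)
    kt = thermal_voltage_mv(310.0)
    delta_off = 2.0 * kt / (4.0 * vs)
    rates = {
        ("bulk", "CTD"): (2.0, 0.05),
        ("CTD", "bulk"): (1.0, 0.05),
        ("CTD", "G_loop"): (1.5, 0.08),
        ("G_loop", "CTD"): (8.0, 0.08),
        ("G_loop", "cavity"): (2.0, 0.08),
        ("cavity", "G_loop"): (8.0, 0.08),
        ("cavity", "deep_site"): (2.0, 0.10),
        ("deep_site", "cavity"): (k0_off, delta_off),
        # outward escape over the SF: persistent block at intermediate
        # depolarizations, transient translocation only at high voltage
        ("deep_site", "SF"): (5e-4, 0.25),
        ("SF", "deep_site"): (0.5, 0.15),
        ("SF", "translocated"): (1.0, 0.10),
        ("translocated", "SF"): (0.01, 0.10),
    }
    return BlockerModel(rates=rates)


_SCENARIOS = ("WT", "E225A_E300A", "E225A_R261Q", "ROMK_like",
              "PIP2_depleted", "D69A_D76A")

LN2 = math.log(2.0)


def scenario_preset(name: str, voltage: float = 310.0,
                    stably_open: bool = False,
                    mechanism_constrained: bool = False,
                    seed: int | None = None) -> Scenario:
    """Return the (model, gate, blocker) triple of a named study condition.

    ``stably_open`` disables the closure hazard, reproducing the condition
    of permeation-statistics runs performed on a pore that stays open for
    the full simulation.
    """
    if name not in _SCENARIOS:
        raise ValueError(f"unknown scenario {name!r}; known: {_SCENARIOS}")

    rates = wt_base_rates()
    blocker = _wt_blocker()
    closure = LN2 / 120.0  # WT, PIP2 bound: median closure >120 us

    if name == "E225A_E300A":
        # charge-neutralized CTD ring: exit-rate divisors calibrated so the
        # realized residence times are ~10x (CTD) and ~2x (cavity) the WT
        # values — site exclusion makes residence sublinear in the raw
        # divisor, so the divisors exceed the residence ratios themselves
        for edge in (("CTD", "G_loop"), ("CTD", "bulk_in")):
            rates[edge] = rates[edge] / 18.0
        for edge in (("cavity", "S6"), ("cavity", "G_loop")):
            rates[edge] = rates[edge] / 4.0
        # no SPM recruitment into the charge-neutralized CTD
        blocker.rates[("bulk", "CTD")] = (1e-6, 0.05)
    elif name == "ROMK_like":
        # no rectification controller: SPM cannot reach the deep site
        stations = tuple((n, z) for n, z in blocker.stations
                         if n != "deep_site")
        rates_b = {pair: kv for pair, kv in blocker.rates.items()
                   if "deep_site" not in pair}
        rates_b[("cavity", "SF")] = (0.0, 0.1)
        rates_b[("SF", "cavity")] = (0.0, 0.1)
        blocker = BlockerModel(stations=stations, rates=rates_b)
    elif name == "PIP2_depleted":
        closure = LN2 / 58.0  # printed median closure time 58 us
    # E225A_R261Q and D69A_D76A keep WT-like rates / WT closure hazard

    if stably_open:
        closure = 0.0

    # dedicated knock-on cycle rates: the B step (formation of the
    # S5[S3,S2],S0 intermediate) is rate limiting
    cycle_rates = {"A": 400.0, "B": 100.0, "C": 500.0, "D": 600.0,
                   "E": 800.0} if mechanism_constrained else None
    model = KineticModel(
        capacities={"CTD": 4, "G_loop": 1, "cavity": 4},
        base_rates=rates,
        voltage_coupling=wt_voltage_coupling(),
        voltage=voltage,
        water_coperm_prob=0.22,
        mechanism_constrained=mechanism_constrained,
        cycle_rates=cycle_rates,
        seed=seed,
    )
    gate = GateModel(closure_rate=closure)
    return Scenario(model=model, gate=gate, blocker=blocker)
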