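"""Generate → analyze → summarize orchestration from one configuration.

A :class:`RunConfig` names a scenario, voltages, duration, replicate count
and analysis thresholds; :func:`run_pipeline` executes the stages in
dependency order and writes machine-readable outputs, stamping every file
with the configuration hash, master seed and package version so a rerun
with an identical configuration reproduces every number bit-exact.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .synthetic import scenario_preset, simulate
from . import permeation as perm
from . import gating
from . import blocker as blk

__all__ = ["RunConfig", "run_pipeline", "summarize_iv"]


@dataclass
class RunConfig:
    scenario: str = "WT"
    voltages: tuple = (310.0,)  # mV
    duration_us: float = 5.0
    replicates: int = 1
    seed: int = 1
    dt_ns: float = 2.0
    stably_open: bool = False
    with_blocker: bool = False
    analyses: tuple = ("permeation", "gating")
    # thresholds, mirroring the standard conventions
    closure_threshold: int = 35
    persistence_us: float = 1.0
    hysteresis: float = 2.0
    d_on: float = 10.0
    d_off: float = 20.0
    window_ns: float = 30.0

    def __post_init__(self):
        if self.replicates < 1:
            raise ValueError("replicate count must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("voltages", "analyses"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _replicate_seed(master: int, voltage_index: int, replicate: int) -> int:
    # fixed arithmetic stream derivation: replicate index, not wall clock
    return (master * 1_000_003 + voltage_index * 10_007 + replicate) % (2**31)


def summarize_iv(current_results) -> pd.DataFrame:
    """i–V table from per-voltage current results (no fitting).

    ``current_results`` is an iterable of CurrentResult (several per
    voltage allowed).  Requires at least two distinct voltages; duplicate
    voltages are aggregated (mean ± se over replicates) with a warning
    when replicate counts differ.
    """
    rows = [(r.voltage, r.current_pa) for r in current_results]
    if not rows:
        raise ValueError("no current results")
    df = pd.DataFrame(rows, columns=["voltage", "current_pa"])
    if df["voltage"].nunique() < 2:
        raise ValueError("i-V summary requires at least two distinct voltages")
    counts = df.groupby("voltage").size()
    if counts.nunique() > 1:
        warnings.warn("unequal replicate counts across voltages; aggregating")
    out = df.groupby("voltage")["current_pa"].agg(["mean", "sem", "count"])
    out = out.reset_index().rename(columns={
        "mean": "current_pa", "sem": "current_se_pa", "count": "n"})
    return out


def run_pipeline(config: RunConfig, out_dir) -> dict:
    """Execute all configured stages; returns (and writes) the report."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = {
        "config_hash": config.hash(),
        "seed": config.seed,
        "version": __version__,
        "config": asdict(config),
    }
    report: dict = {"meta": meta, "voltages": {}}
    errors = []
    all_currents = []

    for vi, voltage in enumerate(config.voltages):
        vkey = f"{voltage:+.0f}mV"
        vrep: dict = {"replicates": []}
        for rep in range(config.replicates):
            seed = _replicate_seed(config.seed, vi, rep)
            sc = scenario_preset(config.scenario, voltage=voltage,
                                 stably_open=config.stably_open)
            b = sc.blocker if config.with_blocker else None
            try:
                bundle, log = simulate(
                    sc.model, sc.gate, b, duration=config.duration_us,
                    seed=seed, dt_ns=config.dt_ns,
                    include_hydration="gating" in config.analyses,
                )
                tracks = bundle.to_track_table()
                rrep: dict = {"seed": seed}
                if "permeation" in config.analyses:
                    events = perm.detect_permeation_events(
                        tracks, sc.model.geometry, config.hysteresis)
                    cur = perm.current_and_conductance(
                        events, config.duration_us, voltage)
                    occ = perm.kinetic_occupancy(
                        tracks, sc.model.geometry, "SF",
                        rule="intracellular_entry_only")
                    rrep["permeation"] = {
                        "n_out": cur.n_out, "n_in": cur.n_in,
                        "current_pa": cur.current_pa,
                        "conductance_ps": cur.conductance_ps,
                        "sf_occupancy": occ.mean, "sf_occupancy_se": occ.se,
                    }
                    all_currents.append(cur)
                    events.to_csv(out / f"events_{vkey}_r{rep}.csv",
                                  index=False)
                if "gating" in config.analyses:
                    times, counts = gating.cavity_hydration(
                        tracks, sc.model.geometry)
                    persistence = max(
                        1, int(round(config.persistence_us * 1e3 / config.dt_ns)))
                    outc = gating.detect_closure(
                        times, counts, config.closure_threshold, persistence)
                    rrep["gating"] = {
                        "closed": outc.closed,
                        "closure_time_us": outc.closure_time,
                        "censored_at_us": outc.censored_at,
                        "mean_hydration": float(np.mean(counts)),
                    }
                if config.with_blocker and "blocker" in config.analyses:
                    cfg = blk.BlockerConfig(config.d_on, config.d_off,
                                            config.window_ns)
                    t, _, smooth = blk.spm_distance_series(tracks, cfg)
                    t_on = blk.detect_binding(t, smooth, cfg)
                    t_off = None
                    if t_on is not None:
                        t_off = blk.detect_unbinding(t, smooth, cfg, t_on)
                    rrep["blocker"] = {"t_on_us": t_on, "t_off_us": t_off}
                vrep["replicates"].append(rrep)
            except Exception as exc:  # keep partial results, record failure
                errors.append({"voltage": voltage, "replicate": rep,
                               "error": f"{type(exc).__name__}: {exc}"})
        report["voltages"][vkey] = vrep

    if len(config.voltages) >= 2 and all_currents:
        iv = summarize_iv(all_currents)
        iv.to_csv(out / "iv.csv", index=False)
        report["iv"] = iv.to_dict(orient="records")
    if errors:
        report["errors"] = errors
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=float)
    return report
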