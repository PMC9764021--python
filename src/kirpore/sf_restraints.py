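"""CMAP-style backbone torsional corrections for selectivity-filter stability.

Long-timescale simulations of K⁺-channel selectivity filters are prone to
unphysical backbone rotations (notably of the filter tyrosine carbonyl)
that collapse the filter.  A standard remedy is a grid-based dihedral
correction that deepens the backbone torsional potential at the
crystallographic ϕ/ψ minima.  Here the correction takes the single-cosine
form

    ΔE(θ) = −(A/2)·(1 + cos(θ − θ₀))

which lowers the potential at θ₀ by exactly ``A`` relative to θ₀ + 180°
(A = 4.6 kcal mol⁻¹ by default), is smooth, 360°-periodic and everywhere
non-positive.  Two variants are supported: the full set (ϕ and ψ for SF
residues 143–147, ten tables) and a reduced set (ϕ only, for the two
glycines G145 and G147).

Reference angles θ₀ must be supplied by the user (e.g. measured from a
crystal structure); the package does not fetch structures.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "TorsionalCorrection",
    "correction_energy",
    "build_correction_tables",
    "full_variant",
    "reduced_variant",
    "write_charmm_stream",
    "write_csv_grid",
]

FULL_RESIDUES = (143, 144, 145, 146, 147)
REDUCED_RESIDUES = (145, 147)  # the SF glycines, phi-only


def correction_energy(theta, theta0, depth: float = 4.6):
    """ΔE(θ) in kcal mol⁻¹; ΔE(θ₀) = −depth and ΔE(θ₀ ± 180°) = 0."""
    if depth <= 0:
        raise ValueError("depth must be positive")
    theta = np.asarray(theta, dtype=float)
    return -(depth / 2.0) * (1.0 + np.cos(np.radians(theta - theta0)))


@dataclass(frozen=True)
class TorsionalCorrection:
    """Specification of a set of per-dihedral corrections.

    ``dihedrals`` maps ``(residue_id, kind)`` with kind ∈ {"phi", "psi"}
    to the reference angle θ₀ in degrees (−180 ≤ θ₀ < 180).
    """

    dihedrals: dict = field(default_factory=dict)
    depth: float = 4.6  # kcal/mol
    grid_spacing: float = 5.0  # degrees

    def __post_init__(self):
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if self.grid_spacing <= 0 or 360.0 % self.grid_spacing != 0:
            raise ValueError("grid spacing must evenly divide 360 degrees")
        for key, theta0 in self.dihedrals.items():
            resid, kind = key
            if kind not in ("phi", "psi"):
                raise ValueError(f"unknown dihedral kind {kind!r} for {resid}")
            if theta0 is not None and not -180.0 <= theta0 < 180.0:
                raise ValueError(f"theta0 for {key} outside [-180, 180)")


def full_variant(theta0: dict, depth: float = 4.6,
                 grid_spacing: float = 5.0) -> TorsionalCorrection:
    """ϕ and ψ corrections for SF residues 143–147 (ten tables)."""
    dihedrals = {(r, kind): theta0.get((r, kind))
                 for r in FULL_RESIDUES for kind in ("phi", "psi")}
    return TorsionalCorrection(dihedrals, depth, grid_spacing)


def reduced_variant(theta0: dict, depth: float = 4.6,
                    grid_spacing: float = 5.0) -> TorsionalCorrection:
    """ϕ-only corrections for the two SF glycines G145 and G147."""
    dihedrals = {(r, "phi"): theta0.get((r, "phi")) for r in REDUCED_RESIDUES}
    return TorsionalCorrection(dihedrals, depth, grid_spacing)


def build_correction_tables(spec: TorsionalCorrection) -> dict:
    """Tabulate ΔE for every dihedral on the grid [−180, 180).

    Returns ``{(resid, kind): DataFrame(theta, delta_e)}``.  Missing θ₀
    values raise a ``ValueError`` listing every gap.
    """
    missing = [key for key, theta0 in spec.dihedrals.items() if theta0 is None]
    if missing:
        raise ValueError(f"missing reference angles theta0 for: {missing}")
    grid = np.arange(-180.0, 180.0, spec.grid_spacing)
    tables = {}
    for key, theta0 in spec.dihedrals.items():
        tables[key] = pd.DataFrame({
            "theta": grid,
            "delta_e": correction_energy(grid, theta0, spec.depth),
        })
    return tables


def write_charmm_stream(tables: dict, path, depth: float = 4.6) -> None:
    """Write the correction tables as a CHARMM-stream-style patch text."""
    with open(path, "w") as fh:
        fh.write("* Backbone torsional correction tables\n")
        fh.write(f"* depth {depth:.3f} kcal/mol, single-cosine form\n*\n")
        for (resid, kind), tab in sorted(tables.items()):
            fh.write(f"\n! residue {resid} dihedral {kind}\n")
            fh.write(f"DIHEDRAL_TABLE RESID {resid} KIND {kind.upper()} "
                     f"N {len(tab)}\n")
            for theta, de in tab.itertuples(index=False):
                fh.write(f"{theta:10.2f} {de:12.6f}\n")
        fh.write("\nEND\n")


def write_csv_grid(tables: dict, path) -> None:
    """Write all tables into one long-format CSV (resid, kind, theta, delta_e)."""
    frames = []
    for (resid, kind), tab in sorted(tables.items()):
        t = tab.copy()
        t.insert(0, "kind", kind)
        t.insert(0, "resid", resid)
        frames.append(t)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
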