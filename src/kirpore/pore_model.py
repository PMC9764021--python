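"""Pore-axis coordinate conventions, site/region geometry and unit conversions.

Everything downstream — the synthetic trajectory generator and all
analyzers — measures positions as projections onto a single pore axis
oriented from the intracellular (cytoplasmic-domain, CTD) side toward the
extracellular side.  Along that axis the extended pore is partitioned into
contiguous half-open intervals: the CTD pore, the G-loop, the transmembrane
cavity, the selectivity-filter (SF) ion-binding sites S6…S0 and an
extracellular vestibule ``S_ext``.  Positions below the first interval are
``bulk_in``; above the last, ``bulk_out``.

Applied-field simulations impose a transmembrane voltage V = E · L_z · C
where E is the constant electric field in kcal mol⁻¹ Å⁻¹ e⁻¹, L_z the box
length in Å and C = 43.3641 mV (1 kcal/mol per elementary charge is
0.0433641 V).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "FIELD_TO_MV",
    "PoreGeometry",
    "VoltageProtocol",
    "ResidueMap",
    "default_geometry",
    "default_residue_map",
    "field_to_voltage",
    "project_to_axis",
    "assign_site",
    "thermal_voltage_mv",
]

#: mV produced by 1 kcal mol^-1 A^-1 e^-1 acting over 1 A.
FIELD_TO_MV = 43.3641

#: Elementary charge in coulomb (exact, SI).
ELEMENTARY_CHARGE = 1.602176634e-19

_GAS_CONSTANT = 8.31446261815324  # J mol^-1 K^-1
_FARADAY = 96485.33212  # C mol^-1

#: Sites making up the selectivity filter, cavity-side first.
SF_SITES = ("S6", "S5", "S4", "S3", "S2", "S1", "S0")

#: Canonical ordering of the single-file pathway, intracellular to
#: extracellular.  ``bulk_in``/``bulk_out`` are unbounded reservoirs.
CHAIN_SITES = (
    "bulk_in", "CTD", "G_loop", "cavity",
    *SF_SITES, "S_ext", "bulk_out",
)


def thermal_voltage_mv(temperature: float = 310.0) -> float:
    """RT/F in millivolt at the given temperature (≈26.71 mV at 310 K)."""
    return 1000.0 * _GAS_CONSTANT * temperature / _FARADAY


def field_to_voltage(e_field: float, box_length_z: float) -> float:
    """Convert a constant applied field to the transmembrane voltage it imposes.

    Parameters
    ----------
    e_field : float
        Field strength in kcal mol⁻¹ Å⁻¹ e⁻¹ (sign preserved).
    box_length_z : float
        Periodic box length along the membrane normal, Å.  Must be positive.

    Returns
    -------
    float
        Voltage in mV: ``e_field * box_length_z * 43.3641``.
    """
    if box_length_z <= 0:
        raise ValueError(f"box_length_z must be positive, got {box_length_z}")
    return e_field * box_length_z * FIELD_TO_MV


@dataclass(frozen=True)
class PoreGeometry:
    """Axial coordinate frame and site/region partition of the extended pore.

    ``site_bounds`` is an ordered sequence of ``(site, z_lo, z_hi)`` with
    contiguous half-open intervals ``[z_lo, z_hi)`` strictly increasing in z.
    ``region_map`` assigns every site to exactly one named region;
    ``composite_regions`` adds convenience groupings (``SF``, ``TM_pore``,
    ``extended_pore``) used by the analyzers.
    """

    site_bounds: tuple = ()
    region_map: Mapping[str, tuple] = field(default_factory=dict)
    axis_origin: tuple = (0.0, 0.0, 0.0)
    axis_direction: tuple = (0.0, 0.0, 1.0)
    cavity_cylinder: tuple = (-20.0, 0.0, 8.0)  # (z_lo, z_hi, radius), A
    composite_regions: Mapping[str, tuple] = field(default_factory=dict)

    def __post_init__(self):
        direction = np.asarray(self.axis_direction, dtype=float)
        if abs(np.linalg.norm(direction) - 1.0) > 1e-9:
            raise ValueError("axis_direction must have unit norm")
        if not self.site_bounds:
            raise ValueError("site_bounds must not be empty")
        prev_hi = None
        for name, lo, hi in self.site_bounds:
            if hi <= lo:
                raise ValueError(f"site {name}: empty interval [{lo}, {hi})")
            if prev_hi is not None and abs(lo - prev_hi) > 1e-9:
                raise ValueError(
                    f"site {name}: gap/overlap at z={lo} (previous ends {prev_hi})"
                )
            prev_hi = hi
        assigned = {}
        for region, sites in self.region_map.items():
            if not sites:
                raise ValueError(f"region {region} maps to no site")
            for s in sites:
                if s in assigned:
                    raise ValueError(f"site {s} assigned to both "
                                     f"{assigned[s]} and {region}")
                assigned[s] = region
        for name, _, _ in self.site_bounds:
            if name not in assigned:
                raise ValueError(f"site {name} belongs to no region")

    # -- lookups -----------------------------------------------------------

    @property
    def site_names(self) -> tuple:
        return tuple(name for name, _, _ in self.site_bounds)

    @property
    def edges(self) -> np.ndarray:
        """All interval boundaries, length ``n_sites + 1``."""
        bounds = self.site_bounds
        return np.array([bounds[0][1]] + [hi for _, _, hi in bounds])

    def z_lo(self, site: str) -> float:
        return self._interval(site)[0]

    def z_hi(self, site: str) -> float:
        return self._interval(site)[1]

    def z_center(self, site: str) -> float:
        lo, hi = self._interval(site)
        return 0.5 * (lo + hi)

    def _interval(self, site: str) -> tuple:
        for name, lo, hi in self.site_bounds:
            if name == site:
                return lo, hi
        raise KeyError(f"unknown site {site!r}")

    def region_of(self, site: str) -> str:
        if site in ("bulk_in", "bulk_out"):
            return site
        for region, sites in self.region_map.items():
            if site in sites:
                return region
        raise KeyError(f"site {site!r} has no region")

    def sites_in(self, region: str) -> tuple:
        """Sites of a named region, accepting composite names like ``SF``."""
        if region in self.composite_regions:
            return tuple(self.composite_regions[region])
        if region in self.region_map:
            return tuple(self.region_map[region])
        if region in ("bulk_in", "bulk_out"):
            return (region,)
        raise KeyError(f"unknown region {region!r}")

    def region_interval(self, region: str) -> tuple:
        """(z_lo, z_hi) spanned by a (composite) region's sites."""
        sites = self.sites_in(region)
        return min(self.z_lo(s) for s in sites), max(self.z_hi(s) for s in sites)


def project_to_axis(coords, geometry: PoreGeometry) -> np.ndarray:
    """Axial position(s) of 3-D coordinates: ``(r − origin) · axis``."""
    coords = np.asarray(coords, dtype=float)
    origin = np.asarray(geometry.axis_origin, dtype=float)
    direction = np.asarray(geometry.axis_direction, dtype=float)
    return (coords - origin) @ direction


def assign_site(z, geometry: PoreGeometry):
    """Site name(s) containing axial position(s) ``z``.

    Intervals are half-open ``[z_lo, z_hi)`` so a boundary value belongs to
    the upper site.  Positions below/above all sites map to ``bulk_in`` /
    ``bulk_out``.
    """
    z_arr = np.asarray(z, dtype=float)
    names = np.array(["bulk_in", *geometry.site_names, "bulk_out"])
    idx = np.searchsorted(geometry.edges, z_arr, side="right")
    out = names[idx]
    if np.isscalar(z) or z_arr.ndim == 0:
        return str(out)
    return out


@dataclass(frozen=True)
class VoltageProtocol:
    """Applied-field protocol; checks field/box/voltage self-consistency."""

    e_field: float | None = None  # kcal mol^-1 A^-1 e^-1
    box_length_z: float | None = None  # A
    voltage: float | None = None  # mV
    temperature: float = 310.0  # K

    def __post_init__(self):
        if self.e_field is not None and self.box_length_z is not None:
            v = field_to_voltage(self.e_field, self.box_length_z)
            if self.voltage is None:
                object.__setattr__(self, "voltage", v)
            elif abs(self.voltage - v) > 1e-6 * max(1.0, abs(v)):
                raise ValueError(
                    f"inconsistent protocol: E*L gives {v:.4f} mV, "
                    f"stated voltage is {self.voltage} mV"
                )


@dataclass(frozen=True)
class ResidueMap:
    """Named atom selections for the landmarks the analyzers use."""

    selections: Mapping[str, tuple]

    def resolve(self, label: str) -> tuple:
        try:
            return tuple(self.selections[label])
        except KeyError:
            raise KeyError(f"unknown selection label {label!r}") from None

    def validate_tetramer(self) -> None:
        """In tetramer mode every label must resolve to 4 subunit copies."""
        for label, atoms in self.selections.items():
            if len(atoms) != 4:
                raise ValueError(
                    f"selection {label!r} resolves to {len(atoms)} atoms, "
                    "expected 4 subunit copies"
                )


def default_geometry() -> PoreGeometry:
    """Synthetic default geometry.

    SF sites are 3.3-Å intervals with S4 spanning [0, 3.3) — canonical
    K⁺-channel site spacing — stacked S6 at [−6.6,−3.3) up to S0 at
    [13.2,16.5); the cavity, G-loop and CTD extend below, the ``S_ext``
    vestibule above.  All analyzers read boundaries from this object, never
    hard-code them.
    """
    spacing = 3.3
    bounds = [("CTD", -55.0, -30.0), ("G_loop", -30.0, -20.0),
              ("cavity", -20.0, -6.6)]
    lo = -6.6
    for name in SF_SITES:
        bounds.append((name, round(lo, 6), round(lo + spacing, 6)))
        lo += spacing
    bounds.append(("S_ext", 16.5, 25.0))
    region_map = {name: (name,) for name, _, _ in bounds}
    region_map["bulk_in"] = ("bulk_in",)
    region_map["bulk_out"] = ("bulk_out",)
    composite = {
        "SF": SF_SITES,
        "TM_pore": ("cavity", *SF_SITES),
        "extended_pore": ("CTD", "G_loop", "cavity", *SF_SITES, "S_ext"),
    }
    return PoreGeometry(
        site_bounds=tuple(bounds),
        region_map=region_map,
        composite_regions=composite,
    )


def default_residue_map() -> ResidueMap:
    """Landmark selections for cKir2.2 in tetramer mode (A–D subunits)."""

    def per_subunit(label):
        return tuple(f"{label}_{chain}" for chain in "ABCD")

    labels = [
        # activation gate and nearby pore-lining residues
        "I177", "M181", "S174",
        # rectification controller in the cavity
        "D173",
        # SF backbone span (represented by its center-of-mass pseudo-atom
        # per subunit when working on real trajectories)
        "SF_144_148",
        # CTD ring
        "E225", "E300", "R261", "E304",
        # interfacial-helix aspartates
        "D69", "D76",
        # R/K-rich region
        "R78", "R80", "K183", "R186", "K188", "K189",
        # CTD reference residues (secondary lipid site)
        "R219", "K220",
    ]
    return ResidueMap(selections={lab: per_subunit(lab) for lab in labels})
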