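"""Parametric geometry of DNA-origami barrels.

A barrel is a short cylinder built from three concentric layers of
circular double helices (outer, inner-middle and inner), characterised
by the mid-point diameters of the helix layers and the physical
thickness of a double helix (2.6 nm).  Both cylindrical surfaces carry
a rhombic lattice of "pixel" sites -- strand nick points spaced ~8 nm
from six nearest neighbours -- that can be functionalised with docking
handles, biotins or other guests.  Barrels stack coaxially into
polymers and discrete multimers (trimers, decamers) through orthogonal
plug/socket interfaces.

Everything downstream (the localisation simulator, the synthetic TEM
generator and the recovery tests) takes its designed dimensions and
site coordinates from this module.

Coordinate convention: the barrel axis is +z, the origin sits at the
axial centre of a monomer, lengths are in nanometres and angles in
radians.  "Upright" means the barrel axis is parallel to the optical
z axis.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml

__all__ = [
    "HELIX_THICKNESS_NM",
    "PIXEL_PITCH_NM",
    "BarrelConfigError",
    "LayerSpec",
    "BarrelSpec",
    "PixelSite",
    "StackSpec",
    "StackPosition",
    "external_diameter",
    "cavity_diameter",
    "pixel_lattice",
    "docking_ring",
    "stack_positions",
    "make_stack",
    "assembly_mass",
    "molar_concentration_from_a260",
    "list_presets",
    "get_preset",
    "load_spec_yaml",
    "export_lattice_csv",
]

#: Physical thickness of a B-form DNA double helix, nm.
HELIX_THICKNESS_NM = 2.6

#: Designed pitch of the rhombic pixel lattice, nm.
PIXEL_PITCH_NM = 8.0

_LAYER_ROLES = ("outer", "inner_middle", "inner", "connector")


class BarrelConfigError(ValueError):
    """A barrel specification is inconsistent or incomplete."""


@dataclass(frozen=True)
class LayerSpec:
    """One concentric layer of circular double helices.

    Parameters
    ----------
    role
        ``outer``, ``inner_middle``, ``inner`` or ``connector``.
    midpoint_diameter
        Diameter measured from helix mid-point, nm.
    n_helix_rings
        Number of stacked duplex rings in this layer.
    """

    role: str
    midpoint_diameter: float
    n_helix_rings: int = 1

    def __post_init__(self) -> None:
        if self.role not in _LAYER_ROLES:
            raise BarrelConfigError(f"unknown layer role {self.role!r}")
        if not self.midpoint_diameter > 0:
            raise BarrelConfigError("midpoint_diameter must be > 0")
        if self.n_helix_rings < 1:
            raise BarrelConfigError("n_helix_rings must be >= 1")


@dataclass(frozen=True)
class BarrelSpec:
    """Parametric description of one barrel class.

    ``name`` follows the diameter-height convention, e.g. ``"90-23"``
    is the ~90 nm diameter, 23 nm tall monomer.  ``monomer_height`` is
    the designed height of this monomer; ``polymer_monomer_height`` is
    the per-monomer axial repeat used when this class is polymerised
    coaxially (stored separately because the two are not derivable
    from each other).
    """

    name: str
    layers: tuple[LayerSpec, ...]
    monomer_height: float
    helix_thickness: float = HELIX_THICKNESS_NM
    pixel_pitch: float = PIXEL_PITCH_NM
    pixel_rows: int | None = None
    pixels_per_row: int | None = None
    polymer_monomer_height: float | None = None
    n_docking_handles: int = 6
    meta: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.helix_thickness >= 0:
            raise BarrelConfigError("helix_thickness must be >= 0")
        if not self.monomer_height > 0:
            raise BarrelConfigError("monomer_height must be > 0")
        roles = [l.role for l in self.layers]
        if len(set(roles)) != len(roles):
            raise BarrelConfigError("duplicate layer roles")
        d = {l.role: l.midpoint_diameter for l in self.layers}
        if {"outer", "inner_middle", "inner"} <= d.keys():
            if not d["outer"] > d["inner_middle"] > d["inner"]:
                raise BarrelConfigError(
                    "layer mid-point diameters must satisfy outer > inner_middle > inner"
                )
        if "outer" in d and "inner" in d:
            if not (d["outer"] + self.helix_thickness) > (d["inner"] - self.helix_thickness):
                raise BarrelConfigError("external diameter must exceed cavity diameter")

    def layer(self, role: str) -> LayerSpec:
        for l in self.layers:
            if l.role == role:
                return l
        raise BarrelConfigError(f"barrel {self.name!r} has no {role!r} layer")

    @property
    def diameter_class(self) -> int:
        """Nominal diameter class in nm (30, 60, 90), parsed from the name."""
        return int(self.name.split("-")[0])


@dataclass(frozen=True)
class PixelSite:
    """A single functionalisable nick point on a barrel surface."""

    surface: str  # "inner" | "outer"
    row_index: int
    azimuth_index: int
    position: tuple[float, float, float]  # nm, barrel frame
    docking_id: str | None = None

    @property
    def radius(self) -> float:
        x, y, _ = self.position
        return math.hypot(x, y)


@dataclass(frozen=True)
class StackSpec:
    """A coaxial stack of barrel monomers (polymer, trimer, decamer).

    ``monomers`` is an ordered list of ``(BarrelSpec, role)`` with role
    alternating between the two monomer species "alpha" and "beta";
    ``interfaces`` labels the orthogonal plug/socket interfaces between
    consecutive monomers (one fewer than monomers, nine for a
    decamer); ``ring_decorations`` maps monomer index to the pixel
    rows decorated with docking handles.
    """

    monomers: tuple[tuple[BarrelSpec, str], ...]
    interfaces: tuple[str, ...]
    ring_decorations: Mapping[int, tuple[int, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.monomers) < 1:
            raise BarrelConfigError("stack needs at least one monomer")
        if len(self.interfaces) != len(self.monomers) - 1:
            raise BarrelConfigError(
                f"{len(self.monomers)} monomers require "
                f"{len(self.monomers) - 1} interfaces, got {len(self.interfaces)}"
            )
        for _, role in self.monomers:
            if role not in ("alpha", "beta"):
                raise BarrelConfigError(f"monomer role must be alpha/beta, got {role!r}")

    @property
    def height(self) -> float:
        return float(sum(spec.monomer_height for spec, _ in self.monomers))


@dataclass(frozen=True)
class StackPosition:
    monomer_index: int
    axial_offset: float  # nm, base of this monomer relative to stack base
    ring_z: tuple[float, ...]  # nm, z of decorated rings, stack frame


# ---------------------------------------------------------------------------
# designed dimensions


def external_diameter(spec: BarrelSpec, rounded: bool = True) -> float:
    """External barrel diameter: outer-layer mid-point diameter plus one
    helix thickness (half a helix protrudes on each side).

    Rounded to the nearest nm by default, matching how designed
    dimensions are reported; pass ``rounded=False`` for the exact value.
    """
    d = spec.layer("outer").midpoint_diameter + spec.helix_thickness
    return float(round(d)) if rounded else float(d)


def cavity_diameter(spec: BarrelSpec, rounded: bool = True) -> float:
    """Internal cavity diameter: inner-layer mid-point diameter minus
    one helix thickness."""
    d = spec.layer("inner").midpoint_diameter - spec.helix_thickness
    return float(round(d)) if rounded else float(d)


def surface_radius(spec: BarrelSpec, surface: str) -> float:
    """Radius of the physical surface carrying pixel sites, nm."""
    if surface == "outer":
        return external_diameter(spec, rounded=False) / 2.0
    if surface == "inner":
        return cavity_diameter(spec, rounded=False) / 2.0
    raise BarrelConfigError(f"surface must be 'inner' or 'outer', got {surface!r}")


# ---------------------------------------------------------------------------
# pixel lattice


def _default_rows(spec: BarrelSpec) -> int:
    row_dz = spec.pixel_pitch * math.sqrt(3.0) / 2.0
    return max(1, int(round(spec.monomer_height / row_dz)))


def _default_sites_per_row(spec: BarrelSpec, surface: str) -> int:
    circ = 2.0 * math.pi * surface_radius(spec, surface)
    return max(3, int(round(circ / spec.pixel_pitch)))


def pixel_lattice(
    spec: BarrelSpec,
    surface: str = "outer",
    rows: int | None = None,
    sites_per_row: int | None = None,
) -> list[PixelSite]:
    """Pixel sites on one barrel surface, as a rhombic lattice.

    Rows sit at fixed z (spacing ``pitch * sqrt(3)/2``), consecutive
    rows are offset by half an azimuthal step, so every interior site
    has six nearest neighbours at approximately the pixel pitch.  Row
    z positions are centred on the barrel's axial midplane.

    Exact site counts per row are preset parameters (they cannot be
    derived without the strand routing); by default the count is the
    circumference divided by the pitch, rounded.
    """
    n_rows = rows if rows is not None else (spec.pixel_rows or _default_rows(spec))
    n_sites = (
        sites_per_row
        if sites_per_row is not None
        else (spec.pixels_per_row or _default_sites_per_row(spec, surface))
    )
    if n_rows < 1:
        raise BarrelConfigError("rows must be >= 1")
    if n_sites < 3:
        raise BarrelConfigError("sites per row must be >= 3")
    radius = surface_radius(spec, surface)
    row_dz = spec.pixel_pitch * math.sqrt(3.0) / 2.0
    dphi = 2.0 * math.pi / n_sites
    sites: list[PixelSite] = []
    for k in range(n_rows):
        z = (k - (n_rows - 1) / 2.0) * row_dz
        offset = (k % 2) * dphi / 2.0
        for j in range(n_sites):
            phi = offset + j * dphi
            sites.append(
                PixelSite(
                    surface=surface,
                    row_index=k,
                    azimuth_index=j,
                    position=(radius * math.cos(phi), radius * math.sin(phi), z),
                )
            )
    return sites


def docking_ring(
    spec: BarrelSpec,
    n_handles: int | None = None,
    z: float = 0.0,
    docking_id: str = "R1",
    surface: str = "outer",
    phase: float = 0.0,
) -> list[PixelSite]:
    """A single ring of regularly spaced docking handles on one helix.

    This is the decoration used for diameter measurements: 6, 12 or 18
    handles on one outer helix for the 30, 60, 90 nm classes.
    """
    n = n_handles if n_handles is not None else spec.n_docking_handles
    if n < 1:
        raise BarrelConfigError("need at least one docking handle")
    radius = surface_radius(spec, surface)
    dphi = 2.0 * math.pi / n
    return [
        PixelSite(
            surface=surface,
            row_index=0,
            azimuth_index=j,
            position=(
                radius * math.cos(phase + j * dphi),
                radius * math.sin(phase + j * dphi),
                z,
            ),
            docking_id=docking_id,
        )
        for j in range(n)
    ]


# ---------------------------------------------------------------------------
# stacks


def make_stack(
    spec: BarrelSpec,
    n_monomers: int,
    decorated: Sequence[int] | str = "alpha",
    decorated_rows: Sequence[int] = (0,),
    monomer_height: float | None = None,
) -> StackSpec:
    """Convenience constructor for an alternating alpha/beta stack.

    ``decorated`` selects which monomers carry docking rings: the
    string ``"alpha"`` / ``"beta"`` / ``"all"`` or an explicit list of
    monomer indices.  ``monomer_height`` defaults to the preset's
    polymer monomer height when set (the per-monomer axial repeat of
    the polymerised class), else the monomer's designed height.
    """
    h = monomer_height
    if h is None:
        h = spec.polymer_monomer_height or spec.monomer_height
    m = replace(spec, monomer_height=float(h))
    monomers = tuple((m, "alpha" if k % 2 == 0 else "beta") for k in range(n_monomers))
    interfaces = tuple(f"I{k + 1}" for k in range(n_monomers - 1))
    if decorated == "alpha":
        idx = [k for k in range(n_monomers) if k % 2 == 0]
    elif decorated == "beta":
        idx = [k for k in range(n_monomers) if k % 2 == 1]
    elif decorated == "all":
        idx = list(range(n_monomers))
    else:
        idx = list(decorated)  # type: ignore[arg-type]
    decorations = {k: tuple(decorated_rows) for k in idx}
    return StackSpec(monomers=monomers, interfaces=interfaces, ring_decorations=decorations)


def stack_positions(stack: StackSpec) -> list[StackPosition]:
    """Axial offsets of the monomers in a stack and the z positions of
    their decorated rings (stack frame, z measured from the stack base).

    All monomers must share a diameter class; the axial offset of
    monomer k is k times the monomer height, so the alpha-beta repeat
    distance is twice the monomer height.  Decorated ring z positions
    are the offsets of the decorated pixel rows within each monomer.
    """
    classes = {round(external_diameter(spec, rounded=False)) for spec, _ in stack.monomers}
    if len(classes) > 1:
        raise BarrelConfigError(f"mixed diameter classes in stack: {sorted(classes)}")
    positions: list[StackPosition] = []
    offset = 0.0
    row_dz = stack.monomers[0][0].pixel_pitch * math.sqrt(3.0) / 2.0
    for k, (spec, _) in enumerate(stack.monomers):
        rows = stack.ring_decorations.get(k, ())
        ring_z = tuple(offset + r * row_dz for r in rows)
        positions.append(StackPosition(monomer_index=k, axial_offset=offset, ring_z=ring_z))
        offset += spec.monomer_height
    return positions


# ---------------------------------------------------------------------------
# mass / concentration arithmetic


def assembly_mass(n_monomers: int, monomer_mw: float) -> float:
    """Combined molecular weight of an n-mer, in the units of
    ``monomer_mw`` (MDa for the shipped presets)."""
    if n_monomers < 1:
        raise ValueError("n_monomers must be >= 1")
    if not monomer_mw > 0:
        raise ValueError("monomer_mw must be > 0")
    return float(n_monomers * monomer_mw)


def molar_concentration_from_a260(a260: float, mw: float) -> float:
    """Molar concentration (nM) from UV absorbance at 260 nm.

    Uses the double-stranded DNA convention A260 = 1 for 50 ug/mL.
    ``mw`` is in Da (g/mol).
    """
    if a260 < 0:
        raise ValueError("a260 must be >= 0")
    if not mw > 0:
        raise ValueError("mw must be > 0")
    grams_per_litre = a260 * 50e-3  # 50 ug/mL == 50e-3 g/L
    return float(grams_per_litre / mw * 1e9)


# ---------------------------------------------------------------------------
# preset catalog


def _spec_from_dict(name: str, d: Mapping[str, object]) -> BarrelSpec:
    layers = tuple(
        LayerSpec(
            role=str(l["role"]),
            midpoint_diameter=float(l["midpoint_diameter"]),
            n_helix_rings=int(l.get("n_helix_rings", 1)),
        )
        for l in d["layers"]  # type: ignore[union-attr]
    )
    return BarrelSpec(
        name=name,
        layers=layers,
        monomer_height=float(d["monomer_height"]),
        helix_thickness=float(d.get("helix_thickness", HELIX_THICKNESS_NM)),
        pixel_pitch=float(d.get("pixel_pitch", PIXEL_PITCH_NM)),
        pixel_rows=(int(d["pixel_rows"]) if d.get("pixel_rows") is not None else None),
        pixels_per_row=(
            int(d["pixels_per_row"]) if d.get("pixels_per_row") is not None else None
        ),
        polymer_monomer_height=(
            float(d["polymer_monomer_height"])
            if d.get("polymer_monomer_height") is not None
            else None
        ),
        n_docking_handles=int(d.get("n_docking_handles", 6)),
        meta=dict(d.get("meta", {})),  # type: ignore[arg-type]
    )


def _load_catalog() -> dict[str, BarrelSpec]:
    text = resources.files("barrelpaint").joinpath("data/presets.yaml").read_text()
    raw = yaml.safe_load(text)
    return {name: _spec_from_dict(name, d) for name, d in raw["presets"].items()}


_CATALOG: dict[str, BarrelSpec] | None = None


def list_presets() -> list[str]:
    global _CATALOG
    if _CATALOG is None:
        _CATALOG = _load_catalog()
    return sorted(_CATALOG)


def get_preset(name: str) -> BarrelSpec:
    global _CATALOG
    if _CATALOG is None:
        _CATALOG = _load_catalog()
    try:
        return _CATALOG[name]
    except KeyError:
        raise BarrelConfigError(
            f"unknown preset {name!r}; available: {', '.join(sorted(_CATALOG))}"
        ) from None


def load_spec_yaml(path) -> BarrelSpec:
    """Load a custom barrel spec from a YAML file with the same schema
    as the shipped preset catalog (single top-level ``name: {...}``)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if "presets" in raw:
        raw = raw["presets"]
    if len(raw) != 1:
        raise BarrelConfigError("custom spec YAML must contain exactly one barrel")
    ((name, d),) = raw.items()
    return _spec_from_dict(name, d)


def export_lattice_csv(spec: BarrelSpec, path, surfaces: Iterable[str] = ("outer", "inner")) -> None:
    """Write pixel-site coordinates for the given surfaces as CSV with
    columns surface,row,azimuth,x,y,z,docking_id."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["surface", "row", "azimuth", "x", "y", "z", "docking_id"])
        for surface in surfaces:
            for s in pixel_lattice(spec, surface=surface):
                x, y, z = s.position
                writer.writerow(
                    [s.surface, s.row_index, s.azimuth_index,
                     f"{x:.4f}", f"{y:.4f}", f"{z:.4f}", s.docking_id or ""]
                )


def sites_to_array(sites: Sequence[PixelSite]) -> np.ndarray:
    """(n, 3) array of site positions."""
    return np.asarray([s.position for s in sites], dtype=float).reshape(-1, 3)
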