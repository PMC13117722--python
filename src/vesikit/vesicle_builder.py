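"""Whole spherical liposome construction.

Builds a two-leaflet vesicle of radially oriented coarse-grained lipids,
solvated inside (water core) and outside (box water), with every bead
assigned to one of three thermostat groups: INNER_WATER, BILAYER,
OUTER_WATER.

Geometry convention: coordinates in nm, vesicle centred at the box centre,
no periodic wrapping of the built structure.  Head-bead anchors sit on the
leaflet reference spheres; each lipid is laid out as a straight chain along
the local radial axis with template bond lengths (the two tails parallel,
offset laterally by 0.25 nm).  Residual strain and tail interdigitation are
left for downstream energy minimisation by the MD engine.

Default leaflet reference radii are tied to the reference 30 nm build:
inverting N = 4πr²/APL at the reference leaflet populations (5128 outer,
3638 inner) and APL 0.46 nm² gives r_out = 13.7009 nm, r_in = 11.5400 nm;
other diameters scale these proportionally.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
from scipy.spatial.transform import Rotation

from . import lipid_models as lm
from .errors import BuildError, CapacityError, ConsistencyError, DomainError

INNER_WATER = "INNER_WATER"
BILAYER = "BILAYER"
OUTER_WATER = "OUTER_WATER"
GROUP_ORDER = (INNER_WATER, BILAYER, OUTER_WATER)

WATER_SPECIES = "W"
TAIL_OFFSET = 0.25  # nm, lateral offset between the two parallel tails

# reference 30 nm DPPC build (leaflet counts at APL 0.46 nm^2)
REF_DIAMETER = 30.0
REF_APL = 0.46
REF_N_OUT = 5128
REF_N_IN = 3638
REF_R_OUT = math.sqrt(REF_N_OUT * REF_APL / (4.0 * math.pi))  # 13.7009 nm
REF_R_IN = math.sqrt(REF_N_IN * REF_APL / (4.0 * math.pi))  # 11.5400 nm
REF_N_WATER_IN = 67_522
REF_N_WATER_OUT = 334_358

_GOLDEN_ANGLE = math.pi * (3.0 - math.sqrt(5.0))


@dataclass(frozen=True)
class VesicleSpec:
    """Build specification.

    The no-argument spec is the packaged reference configuration: a 30 nm
    DPPC vesicle at APL 0.46 nm² in a 40 nm box with the reference water
    counts.  The water-count defaults belong to that geometry; pass
    ``n_water_in=None``/``n_water_out=None`` to fill the solvent lattice to
    capacity for other geometries.
    """

    species: str = "DPPC"
    outer_diameter: float = REF_DIAMETER  # nm
    apl: float = REF_APL  # nm^2
    box_edge: float = 40.0  # nm
    r_out_ref: Optional[float] = None  # nm; derived from diameter when None
    r_in_ref: Optional[float] = None
    n_out: Optional[int] = None  # lipid-count overrides
    n_in: Optional[int] = None
    n_water_in: Optional[int] = REF_N_WATER_IN
    n_water_out: Optional[int] = REF_N_WATER_OUT
    min_separation: float = 0.40  # nm
    water_spacing: float = 0.41  # nm, solvent lattice constant
    water_jitter: float = 0.008  # nm, full width of the per-axis jitter window
    seed: int = 0

    def __post_init__(self):
        scale = self.outer_diameter / REF_DIAMETER
        if self.r_out_ref is None:
            object.__setattr__(self, "r_out_ref", REF_R_OUT * scale)
        if self.r_in_ref is None:
            object.__setattr__(self, "r_in_ref", REF_R_IN * scale)
        if self.apl <= 0:
            raise DomainError(f"apl must be positive, got {self.apl}")
        if not 0 < self.r_in_ref < self.r_out_ref < self.box_edge / 2:
            raise DomainError(
                f"need 0 < r_in_ref < r_out_ref < box/2, got "
                f"{self.r_in_ref}, {self.r_out_ref}, box {self.box_edge}"
            )
        if self.outer_diameter > self.box_edge - 4.0:
            raise DomainError("outer diameter must leave a >= 4 nm solvent margin in the box")
        for name in ("n_out", "n_in"):
            v = getattr(self, name)
            if v is not None and (not isinstance(v, (int, np.integer)) or v <= 0):
                raise DomainError(f"{name} must be a positive integer, got {v!r}")
        for name in ("n_water_in", "n_water_out"):
            v = getattr(self, name)
            if v is not None and (not isinstance(v, (int, np.integer)) or v < 0):
                raise DomainError(f"{name} must be a non-negative integer, got {v!r}")

    def with_overrides(self, **kw) -> "VesicleSpec":
        return replace(self, **kw)

    @property
    def center(self) -> np.ndarray:
        return np.full(3, self.box_edge / 2.0)


class ParticleSystem:
    """Beads + coordinates + box: the builder's product and the analysis input.

    Struct-of-arrays layout: per-bead name/type/charge/molecule id/species/
    thermostat-group label, an (N, 3) nm coordinate array and a 3-vector box.
    """

    def __init__(self, names, types, charges, mol_ids, species, groups, coords,
                 box, provenance=None):
        self.names = np.asarray(names, dtype="U6")
        self.types = np.asarray(types, dtype="U6")
        self.charges = np.asarray(charges, dtype=float)
        self.mol_ids = np.asarray(mol_ids, dtype=np.int64)
        self.species = np.asarray(species, dtype="U6")
        self.groups = np.asarray(groups, dtype="U12")
        self.coords = np.asarray(coords, dtype=float)
        self.box = np.asarray(box, dtype=float)
        self.provenance = provenance
        n = len(self.names)
        if not all(len(a) == n for a in
                   (self.types, self.charges, self.mol_ids, self.species, self.groups)):
            raise ConsistencyError("per-bead arrays disagree in length")
        if self.coords.shape != (n, 3):
            raise ConsistencyError(f"coords shape {self.coords.shape} != ({n}, 3)")

    @property
    def n_beads(self) -> int:
        return len(self.names)

    @property
    def n_molecules(self) -> int:
        return len(np.unique(self.mol_ids))

    def net_charge(self) -> float:
        return float(self.charges.sum())

    def group_mask(self, group: str) -> np.ndarray:
        return self.groups == group

    def species_mask(self, species: str) -> np.ndarray:
        return self.species == species

    def molecule_species(self) -> np.ndarray:
        """Species of each molecule, in molecule-id order."""
        _, first = np.unique(self.mol_ids, return_index=True)
        return self.species[first]

    def with_coords(self, coords: np.ndarray) -> "ParticleSystem":
        return ParticleSystem(self.names, self.types, self.charges, self.mol_ids,
                              self.species, self.groups, coords, self.box,
                              self.provenance)

    def validate(self) -> None:
        if not np.all(np.isfinite(self.coords)):
            raise ConsistencyError("non-finite coordinates")
        if self.n_beads and (self.coords.min() < 0 or
                             np.any(self.coords > self.box[None, :])):
            raise ConsistencyError("coordinates outside the box")
        bad = ~np.isin(self.groups, GROUP_ORDER)
        if bad.any():
            raise ConsistencyError(f"unlabelled beads at indices {np.where(bad)[0][:5]}")


def leaflet_count(radius: float, apl: float) -> int:
    """Lipids on a sphere of the given radius at the given area per lipid.

    round(4πr²/APL), nearest integer with ties to even.
    """
    if radius <= 0 or apl <= 0:
        raise DomainError(f"radius and apl must be positive, got {radius}, {apl}")
    return round(4.0 * math.pi * radius * radius / apl)


def _fibonacci_sphere(n: int, rng: np.random.Generator) -> np.ndarray:
    """n near-uniform unit vectors: golden-spiral lattice + random global rotation."""
    i = np.arange(n)
    z = 1.0 - (2.0 * i + 1.0) / n
    rho = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    phi = i * _GOLDEN_ANGLE
    pts = np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])
    return pts @ Rotation.random(rng=rng).as_matrix().T


def _bead_layout(template: lm.LipidTemplate) -> tuple[np.ndarray, np.ndarray]:
    """(depth, lateral) per bead for the straight radial conformation.

    depth = distance from the head anchor along the chain axis; lateral =
    offset perpendicular to it (tail B runs parallel to tail A at
    TAIL_OFFSET).
    """
    depth = np.zeros(lm.N_BEADS)
    lateral = np.zeros(lm.N_BEADS)
    depth[1] = template.bond_length(1, 2)
    depth[2] = depth[1] + template.bond_length(2, 3)
    depth[3] = depth[2]
    lateral[3] = TAIL_OFFSET
    d = depth[2] + template.bond_length(3, 5)
    for b in lm.TAIL_A:
        depth[b - 1] = d
        if b < lm.TAIL_A[-1]:
            d += template.bond_length(b, b + 1)
    d = depth[3] + template.bond_length(4, 9)
    for b in lm.TAIL_B:
        depth[b - 1] = d
        lateral[b - 1] = TAIL_OFFSET
        if b < lm.TAIL_B[-1]:
            d += template.bond_length(b, b + 1)
    return depth, lateral


def _tangent_frame(u: np.ndarray) -> np.ndarray:
    """One deterministic unit tangent per radial unit vector (row-wise)."""
    ref = np.tile(np.array([0.0, 0.0, 1.0]), (len(u), 1))
    near_pole = np.abs(u[:, 2]) > 0.9
    ref[near_pole] = [1.0, 0.0, 0.0]
    t = np.cross(u, ref)
    return t / np.linalg.norm(t, axis=1, keepdims=True)


def place_leaflet(spec: VesicleSpec, which: str) -> tuple[np.ndarray, int]:
    """Coordinates of one leaflet's lipids, shape (n_lipids, 12, 3).

    Head beads anchor on the leaflet reference sphere; chains run radially
    inward for the outer leaflet and outward for the inner one.  The lipid
    population is leaflet_count(r_ref, apl) unless the spec overrides it.
    Deterministic for a fixed seed.
    """
    if which not in ("outer", "inner"):
        raise ValueError(f"which must be 'outer' or 'inner', got {which!r}")
    template = lm.get_template(spec.species)
    depth, lateral = _bead_layout(template)
    if depth.max() >= spec.r_in_ref:
        raise BuildError(
            f"lipid length {depth.max():.2f} nm does not fit inside the inner "
            f"leaflet radius {spec.r_in_ref:.2f} nm"
        )
    r_ref = spec.r_out_ref if which == "outer" else spec.r_in_ref
    n = (spec.n_out if which == "outer" else spec.n_in)
    if n is None:
        n = leaflet_count(r_ref, spec.apl)
    rng = np.random.default_rng([spec.seed, 0 if which == "outer" else 1])
    u = _fibonacci_sphere(n, rng)
    t1 = _tangent_frame(u)
    sign = -1.0 if which == "outer" else +1.0  # chain direction along +/- u
    radial = r_ref + sign * depth  # (12,)
    coords = (spec.center[None, None, :]
              + u[:, None, :] * radial[None, :, None]
              + t1[:, None, :] * lateral[None, :, None])
    return coords, n


def _water_lattice(spec: VesicleSpec) -> np.ndarray:
    """Jittered simple-cubic solvent lattice filling the box (site order fixed)."""
    n = max(1, round(spec.box_edge / spec.water_spacing))
    a = spec.box_edge / n
    c = (np.arange(n) + 0.5) * a
    x, y, z = np.meshgrid(c, c, c, indexing="ij")
    sites = np.column_stack([x.ravel(), y.ravel(), z.ravel()])
    rng = np.random.default_rng([spec.seed, 2])
    jitter = rng.uniform(-spec.water_jitter / 2, spec.water_jitter / 2, sites.shape)
    return sites + jitter


def _select_water(sites: np.ndarray, radii: np.ndarray, region_mask: np.ndarray,
                  target: Optional[int], region: str, inner: bool) -> np.ndarray:
    """Indices of kept water sites, honouring an exact count by trimming the
    beads closest to the exclusion shell (deterministic tie-break by index)."""
    idx = np.where(region_mask)[0]
    if target is None:
        return idx
    if len(idx) < target:
        raise CapacityError(target, len(idx), region)
    # keep the beads farthest from the shell: smallest radii for the core,
    # largest radii for the outer box
    key = radii[idx] if inner else -radii[idx]
    order = np.lexsort((idx, key))
    keep = idx[order[: target]]
    return np.sort(keep)


def solvate(system: ParticleSystem, spec: VesicleSpec) -> ParticleSystem:
    """Add INNER_WATER and OUTER_WATER beads around an assembled bilayer.

    Water occupies a jittered cubic lattice; beads within ``min_separation``
    of any lipid bead are excluded via radial exclusion shells around the
    bilayer (the lattice itself guarantees water-water separation).
    """
    lipid_mask = system.group_mask(BILAYER)
    if not lipid_mask.any():
        raise BuildError("system has no bilayer to solvate")
    center = spec.center
    lipid_r = np.linalg.norm(system.coords[lipid_mask] - center, axis=1)
    r_lo = lipid_r.min() - spec.min_separation
    r_hi = lipid_r.max() + spec.min_separation

    sites = _water_lattice(spec)
    radii = np.linalg.norm(sites - center, axis=1)
    keep_in = _select_water(sites, radii, radii <= r_lo, spec.n_water_in,
                            "inner core", inner=True)
    keep_out = _select_water(sites, radii, radii >= r_hi, spec.n_water_out,
                             "outer box", inner=False)

    n_in, n_out = len(keep_in), len(keep_out)
    n_w = n_in + n_out
    wb = lm.water_bead()
    mol_start = system.mol_ids.max() + 1 if system.n_beads else 0
    water = ParticleSystem(
        names=np.full(n_w, "W"),
        types=np.full(n_w, wb.type),
        charges=np.zeros(n_w),
        mol_ids=mol_start + np.arange(n_w),
        species=np.full(n_w, WATER_SPECIES),
        groups=np.concatenate([np.full(n_in, INNER_WATER), np.full(n_out, OUTER_WATER)]),
        coords=np.vstack([sites[keep_in], sites[keep_out]]),
        box=system.box,
    )
    prov = dict(system.provenance or {})
    prov.update(n_water_in=n_in, n_water_out=n_out)
    return _concat(system, water, provenance=prov)


def _concat(a: ParticleSystem, b: ParticleSystem, provenance=None) -> ParticleSystem:
    return ParticleSystem(
        names=np.concatenate([a.names, b.names]),
        types=np.concatenate([a.types, b.types]),
        charges=np.concatenate([a.charges, b.charges]),
        mol_ids=np.concatenate([a.mol_ids, b.mol_ids]),
        species=np.concatenate([a.species, b.species]),
        groups=np.concatenate([a.groups, b.groups]),
        coords=np.vstack([a.coords, b.coords]),
        box=a.box,
        provenance=provenance,
    )


def assemble_bilayer(spec: VesicleSpec) -> ParticleSystem:
    """Both leaflets as one BILAYER-labelled system (unsolvated)."""
    template = lm.get_template(spec.species)
    coords_out, n_out = place_leaflet(spec, "outer")
    coords_in, n_in = place_leaflet(spec, "inner")
    n_lip = n_out + n_in
    coords = np.vstack([coords_out.reshape(-1, 3), coords_in.reshape(-1, 3)])
    names = np.tile([b.name for b in template.beads], n_lip)
    types = np.tile([b.type for b in template.beads], n_lip)
    charges = np.tile([b.charge for b in template.beads], n_lip)
    mol_ids = np.repeat(np.arange(n_lip), lm.N_BEADS)
    prov = dict(spec=spec, seed=spec.seed, n_out=n_out, n_in=n_in,
                species=spec.species)
    return ParticleSystem(
        names=names, types=types, charges=charges, mol_ids=mol_ids,
        species=np.full(n_lip * lm.N_BEADS, template.name),
        groups=np.full(n_lip * lm.N_BEADS, BILAYER),
        coords=coords, box=np.full(3, spec.box_edge), provenance=prov,
    )


def build_vesicle(spec: VesicleSpec) -> ParticleSystem:
    """Full build: outer leaflet + inner leaflet + inner/outer water."""
    system = solvate(assemble_bilayer(spec), spec)
    system.validate()
    return system
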