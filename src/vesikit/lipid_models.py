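"""Coarse-grained lipid templates and force-field parameter subset.

The package ships a MARTINI 2.x style parameter file covering three
phosphatidylcholines (DPPC, DOPC, POPC) in a twelve-bead mapping plus the
four-to-one water bead.  Bead numbering is fixed as 1 = choline (+1e),
2 = phosphate (-1e), 3-4 = glycerol, 5-8 = tail A, 9-12 = tail B, so the
tail end beads are 8 and 12.  Unsaturated (cis double bond) sites sit at
the third tail bead (7 and/or 11) and are flagged by a ``D`` bead name.

Parameters load from ``data/martini_lipids.itp`` (GROMACS itp dialect) via
a registry mapping species names to moleculetype names, so a user can
substitute a force-field revision without touching code.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources

import numpy as np
import yaml

from .errors import DomainError, MissingParameterError, UnknownLipidError

KB = 0.008314462618  # Boltzmann constant, kJ/mol/K

N_BEADS = 12
HEAD_BEAD = 1
PHOSPHATE_BEAD = 2
TAIL_A = (5, 6, 7, 8)
TAIL_B = (9, 10, 11, 12)
END_BEADS = (8, 12)


@dataclass(frozen=True)
class Bead:
    index: int  # 1-based
    name: str
    type: str
    charge: float  # e


@dataclass(frozen=True)
class Bond:
    i: int
    j: int
    b0: float  # nm
    k: float  # kJ/mol/nm^2


@dataclass(frozen=True)
class Angle:
    i: int
    j: int
    k: int
    theta0: float  # degrees
    k_angle: float  # kJ/mol


@dataclass(frozen=True)
class LipidTemplate:
    """One lipid species: ordered beads, bonded terms, unsaturation flags."""

    name: str
    beads: tuple[Bead, ...]
    bonds: tuple[Bond, ...]
    angles: tuple[Angle, ...]
    unsaturated_beads: frozenset[int]

    def __post_init__(self):
        if len(self.beads) != N_BEADS:
            raise ValueError(f"{self.name}: expected {N_BEADS} beads, got {len(self.beads)}")
        charges = {b.index: b.charge for b in self.beads}
        if charges[HEAD_BEAD] != 1.0 or charges[PHOSPHATE_BEAD] != -1.0:
            raise ValueError(f"{self.name}: head/phosphate charges must be +1/-1 e")
        if any(charges[i] != 0.0 for i in range(3, N_BEADS + 1)):
            raise ValueError(f"{self.name}: beads 3-12 must be uncharged")
        if not self.unsaturated_beads <= {7, 11}:
            raise ValueError(f"{self.name}: unsaturated beads must be a subset of {{7, 11}}")

    @property
    def net_charge(self) -> float:
        return sum(b.charge for b in self.beads)

    def bond_length(self, i: int, j: int) -> float:
        for b in self.bonds:
            if {b.i, b.j} == {i, j}:
                return b.b0
        raise KeyError(f"{self.name}: no bond between beads {i} and {j}")

    def angle_for_center(self, j: int) -> Angle:
        """The angle triple whose central bead is ``j`` (tail triples are unique)."""
        for a in self.angles:
            if a.j == j:
                return a
        raise KeyError(f"{self.name}: no angle centred on bead {j}")


@dataclass(frozen=True)
class NonbondedParams:
    """Symmetric (type, type) -> (sigma nm, epsilon kJ/mol) table plus globals."""

    table: dict[tuple[str, str], tuple[float, float]] = field(repr=False)
    eps_r: float = 15.0  # relative dielectric
    r_c: float = 1.2  # cutoff, nm

    def lookup(self, a: str, b: str) -> tuple[float, float]:
        return lookup_nonbonded(a, b, self)

    @property
    def types(self) -> tuple[str, ...]:
        return tuple(sorted({t for pair in self.table for t in pair}))


@dataclass(frozen=True)
class WaterBead:
    """MARTINI water: one bead standing in for four water molecules."""

    type: str = "P4"
    charge: float = 0.0
    represented_molecules: int = 4
    v_w: float = 0.12  # nominal bead volume, nm^3

    def __post_init__(self):
        if self.charge != 0.0:
            raise ValueError("water bead must be uncharged")
        if self.represented_molecules != 4:
            raise ValueError("MARTINI water represents exactly 4 molecules per bead")


# ---------------------------------------------------------------------------
# itp dialect: parsing and serialisation


def parse_itp(text: str) -> dict:
    """Parse the subset of the GROMACS itp dialect this package uses.

    Returns a dict with ``nonbond_params`` (pair table) and ``molecules``
    (moleculetype name -> dict of atoms/bonds/angles rows).
    """
    nonbond: dict[tuple[str, str], tuple[float, float]] = {}
    molecules: dict[str, dict] = {}
    section = None
    current: dict | None = None
    for raw in text.splitlines():
        line = raw.split(";", 1)[0].strip()
        if not line:
            continue
        if line.startswith("["):
            section = line.strip("[] \t").lower()
            if section == "moleculetype":
                current = {"atoms": [], "bonds": [], "angles": []}
            continue
        tok = line.split()
        if section == "nonbond_params":
            a, b = tok[0], tok[1]
            sigma, eps = float(tok[3]), float(tok[4])
            nonbond[(a, b)] = (sigma, eps)
            nonbond[(b, a)] = (sigma, eps)
        elif section == "moleculetype":
            molecules[tok[0]] = current
        elif section == "atoms" and current is not None:
            current["atoms"].append(
                Bead(index=int(tok[0]), name=tok[4], type=tok[1], charge=float(tok[6]))
            )
        elif section == "bonds" and current is not None:
            current["bonds"].append(
                Bond(i=int(tok[0]), j=int(tok[1]), b0=float(tok[3]), k=float(tok[4]))
            )
        elif section == "angles" and current is not None:
            current["angles"].append(
                Angle(i=int(tok[0]), j=int(tok[1]), k=int(tok[2]),
                      theta0=float(tok[4]), k_angle=float(tok[5]))
            )
    return {"nonbond_params": nonbond, "molecules": molecules}


def template_to_itp(template: LipidTemplate) -> str:
    """Serialise one template to the itp dialect (round-trips via parse_itp)."""
    lines = ["[ moleculetype ]", f"  {template.name}  1", "", "[ atoms ]"]
    for b in template.beads:
        lines.append(
            f"  {b.index}  {b.type}  1  {template.name}  {b.name}  {b.index}  {b.charge}"
        )
    lines += ["", "[ bonds ]"]
    for bd in template.bonds:
        lines.append(f"  {bd.i}  {bd.j}  1  {bd.b0}  {bd.k}")
    lines += ["", "[ angles ]"]
    for a in template.angles:
        lines.append(f"  {a.i}  {a.j}  {a.k}  2  {a.theta0}  {a.k_angle}")
    return "\n".join(lines) + "\n"


def template_from_itp(text: str, name: str) -> LipidTemplate:
    parsed = parse_itp(text)
    return _template_from_rows(name, parsed["molecules"][name])


def _template_from_rows(name: str, rows: dict) -> LipidTemplate:
    beads = tuple(sorted(rows["atoms"], key=lambda b: b.index))
    unsat = frozenset(b.index for b in beads if b.name.startswith("D"))
    return LipidTemplate(
        name=name,
        beads=beads,
        bonds=tuple(rows["bonds"]),
        angles=tuple(rows["angles"]),
        unsaturated_beads=unsat,
    )


# ---------------------------------------------------------------------------
# packaged data access


def _data_text(filename: str) -> str:
    return (resources.files("vesikit") / "data" / filename).read_text()


@lru_cache(maxsize=1)
def _load_packaged() -> dict:
    parsed = parse_itp(_data_text("martini_lipids.itp"))
    registry = yaml.safe_load(_data_text("species.yaml"))
    return {"parsed": parsed, "registry": registry}


def species_registry() -> dict[str, str]:
    """Species name -> moleculetype name, from the packaged plain-text registry."""
    return dict(_load_packaged()["registry"])


def get_template(name: str) -> LipidTemplate:
    """Return the packaged template for a lipid species (case-insensitive)."""
    reg = species_registry()
    key = name.upper() if isinstance(name, str) else name
    if key not in reg:
        raise UnknownLipidError(
            f"unknown lipid species {name!r}; supported: {sorted(reg)}"
        )
    rows = _load_packaged()["parsed"]["molecules"][reg[key]]
    return _template_from_rows(reg[key], rows)


def default_nonbonded() -> NonbondedParams:
    """The packaged MARTINI 2.x pair table with eps_r = 15 and r_c = 1.2 nm."""
    return NonbondedParams(table=_load_packaged()["parsed"]["nonbond_params"])


def water_bead() -> WaterBead:
    return WaterBead()


def lookup_nonbonded(a: str, b: str, params: NonbondedParams) -> tuple[float, float]:
    """Symmetric (sigma, epsilon) lookup; raises on a missing pair."""
    try:
        return params.table[(a, b)]
    except KeyError:
        raise MissingParameterError(
            f"no nonbonded parameters for bead-type pair ({a}, {b})"
        ) from None


# ---------------------------------------------------------------------------
# angle thermodynamics


def angle_potential(theta_rad: np.ndarray, theta0_deg: float, k_angle: float) -> np.ndarray:
    """Cosine-harmonic angle potential V = (k/2)(cos θ − cos θ0)², kJ/mol."""
    c0 = math.cos(math.radians(theta0_deg))
    return 0.5 * k_angle * (np.cos(theta_rad) - c0) ** 2


def equilibrium_angle_mean(
    theta0: float, k_angle: float, temperature: float, n_grid: int = 200_001
) -> float:
    """Boltzmann-average angle ⟨θ⟩ in degrees under the cosine-harmonic potential.

    The average includes the sin θ Jacobian of the polar angle and is computed
    by deterministic trapezoidal quadrature over θ ∈ (0°, 180°).
    """
    if temperature <= 0:
        raise DomainError(f"temperature must be positive, got {temperature}")
    if k_angle <= 0:
        raise DomainError(f"angle stiffness must be positive, got {k_angle}")
    if not 0 < theta0 < 180:
        raise DomainError(f"theta0 must lie in (0, 180) degrees, got {theta0}")
    theta = np.linspace(0.0, math.pi, n_grid)
    v = angle_potential(theta, theta0, k_angle)
    # subtract the minimum before exponentiating to keep the stiff limit finite
    w = np.exp(-(v - v.min()) / (KB * temperature)) * np.sin(theta)
    num = np.trapezoid(theta * w, theta)
    den = np.trapezoid(w, theta)
    return math.degrees(num / den)
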