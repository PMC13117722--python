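"""Ground-truth-known synthetic inputs for exercising the analysis operators.

Three fixture families:

* Gaussian random-walk trajectories with known diffusion coefficient
  D = σ²/(2Δt) per axis;
* Boltzmann-sampled lipid conformers: bonds at b0, angles drawn exactly
  from the cosine-harmonic Boltzmann density (with the sin θ Jacobian),
  dihedrals uniform — statistical ground truth without nonbonded physics;
* vesicles with a spherical-cap hole punched out, as constructed truth for
  pore detection.

Everything is reproducible bit-for-bit from its seed.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import lipid_models as lm
from .errors import DomainError, SamplerFailureError
from .gmx_io import Frame, TrajectorySlice
from .vesicle_builder import BILAYER, OUTER_WATER, ParticleSystem


@dataclass(frozen=True)
class FixtureSpec:
    """Declarative description of one synthetic fixture."""

    kind: str  # random_walk | boltzmann_chains | holed_vesicle
    seed: int
    parameters: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.kind not in ("random_walk", "boltzmann_chains", "holed_vesicle"):
            raise DomainError(f"unknown fixture kind {self.kind!r}")


# ---------------------------------------------------------------------------
# Brownian trajectories


def random_walk_trajectory(n: int, frames: int, sigma2: float, dt: float,
                           seed: int, box_edge: float = 1000.0
                           ) -> TrajectorySlice:
    """Independent per-axis Gaussian increments of variance ``sigma2`` nm².

    The implied diffusion coefficient is D = sigma2/(2 dt) in nm²/ps.
    Coordinates are unwrapped (free diffusion from the box centre).
    """
    if n <= 0 or frames <= 0 or dt <= 0 or sigma2 < 0:
        raise DomainError("n, frames, dt must be positive and sigma2 >= 0")
    rng = np.random.default_rng(seed)
    steps = rng.normal(0.0, math.sqrt(sigma2), size=(frames - 1, n, 3)) \
        if frames > 1 else np.empty((0, n, 3))
    start = np.full((1, n, 3), box_edge / 2.0)
    pos = np.concatenate([start, start + np.cumsum(steps, axis=0)])
    topology = ParticleSystem(
        names=np.full(n, "PRT"), types=np.full(n, "P4"), charges=np.zeros(n),
        mol_ids=np.arange(n), species=np.full(n, "PRT"),
        groups=np.full(n, OUTER_WATER), coords=pos[0],
        box=np.full(3, box_edge),
    )
    times = np.arange(frames) * dt
    return TrajectorySlice.from_coords(topology, pos, times)


# ---------------------------------------------------------------------------
# Boltzmann-sampled chains


def sample_angles(theta0: float, k_angle: float, temperature: float, n: int,
                  rng: np.random.Generator, max_rounds: int = 10_000
                  ) -> np.ndarray:
    """Draw ``n`` angles (radians) from the cosine-harmonic Boltzmann density.

    With c = cos θ the target density is a Gaussian in c truncated to
    [-1, 1] (the sin θ Jacobian cancels), so rejection against the
    untruncated Gaussian is exact.  Persistent rejection (acceptance below
    ~1e-3) raises SamplerFailureError.
    """
    if temperature <= 0 or k_angle <= 0:
        raise DomainError("temperature and k_angle must be positive")
    c0 = math.cos(math.radians(theta0))
    sd = math.sqrt(lm.KB * temperature / k_angle)
    out = np.empty(0)
    drawn = 0
    for _ in range(max_rounds):
        need = n - len(out)
        if need <= 0:
            break
        batch = rng.normal(c0, sd, size=max(need * 2, 16))
        drawn += len(batch)
        out = np.concatenate([out, batch[(batch >= -1.0) & (batch <= 1.0)]])[:n]
        if drawn > 1000 * n and len(out) < drawn * 1e-3:
            raise SamplerFailureError(
                f"rejection acceptance below 1e-3 for theta0={theta0}, "
                f"k={k_angle}, T={temperature}")
    if len(out) < n:
        raise SamplerFailureError("rejection sampler did not converge")
    return np.arccos(out)


def _perp_basis(u: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise orthonormal pair perpendicular to unit vectors u."""
    ref = np.tile(np.array([0.0, 0.0, 1.0]), (len(u), 1))
    ref[np.abs(u[:, 2]) > 0.9] = [1.0, 0.0, 0.0]
    a = np.cross(u, ref)
    a /= np.linalg.norm(a, axis=1, keepdims=True)
    b = np.cross(u, a)
    return a, b


# tree topology of the 12-bead template: bead -> (parent, grandparent)
_CHAIN_ORDER = [(2, 1, None), (3, 2, 1), (4, 3, 2), (5, 3, 2), (6, 5, 3),
                (7, 6, 5), (8, 7, 6), (9, 4, 3), (10, 9, 4), (11, 10, 9),
                (12, 11, 10)]


def boltzmann_chain_samples(template: lm.LipidTemplate, temperature: float,
                            n: int, seed: int, spacing: float = 8.0
                            ) -> ParticleSystem:
    """``n`` independent conformers of one lipid species at equilibrium.

    Bond lengths are fixed at b0; each angle with a template potential is
    drawn from its Boltzmann density; angles without a potential and all
    dihedrals are uniform.  Conformers are laid out on a cubic grid, one
    molecule per cell, for use as a multi-molecule ParticleSystem.
    """
    if n <= 0:
        raise DomainError("n must be positive")
    rng = np.random.default_rng(seed)
    pos = np.zeros((n, lm.N_BEADS, 3))
    pos[:, 1, 2] = template.bond_length(1, 2)  # bead 2 along +z
    angle_lookup = {}
    for a in template.angles:
        angle_lookup[(a.i, a.j, a.k)] = a
        angle_lookup[(a.k, a.j, a.i)] = a
    for bead, parent, grand in _CHAIN_ORDER[1:]:
        b0 = template.bond_length(parent, bead)
        ang = angle_lookup.get((grand, parent, bead))
        if ang is not None:
            theta = sample_angles(ang.theta0, ang.k_angle, temperature, n, rng)
        else:  # no angle potential: free polar angle (uniform in cos)
            theta = np.arccos(rng.uniform(-1.0, 1.0, size=n))
        phi = rng.uniform(0.0, 2.0 * math.pi, size=n)
        u = pos[:, parent - 1] - pos[:, grand - 1]
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        a_vec, b_vec = _perp_basis(u)
        w = np.cos(phi)[:, None] * a_vec + np.sin(phi)[:, None] * b_vec
        # angle at the parent between (grand - parent) and (bead - parent)
        d = -u * np.cos(theta)[:, None] + w * np.sin(theta)[:, None]
        pos[:, bead - 1] = pos[:, parent - 1] + b0 * d

    n_side = math.ceil(n ** (1.0 / 3.0))
    cells = np.array([(i, j, k) for i in range(n_side) for j in range(n_side)
                      for k in range(n_side)][:n], dtype=float)
    offsets = (cells + 0.5) * spacing
    pos = pos - pos.mean(axis=1, keepdims=True) + offsets[:, None, :]
    box = np.full(3, n_side * spacing)

    names = np.tile([b.name for b in template.beads], n)
    types = np.tile([b.type for b in template.beads], n)
    charges = np.tile([b.charge for b in template.beads], n)
    return ParticleSystem(
        names=names, types=types, charges=charges,
        mol_ids=np.repeat(np.arange(n), lm.N_BEADS),
        species=np.full(n * lm.N_BEADS, template.name),
        groups=np.full(n * lm.N_BEADS, BILAYER),
        coords=pos.reshape(-1, 3), box=box,
        provenance=dict(fixture="boltzmann_chains", seed=seed,
                        temperature=temperature, species=template.name),
    )


# ---------------------------------------------------------------------------
# punched vesicles


def punch_hole(system: ParticleSystem, direction, half_angle: float
               ) -> ParticleSystem:
    """Remove every lipid whose head-bead direction lies inside the cone.

    Directions are measured from the vesicle centre (lipid-bead centre of
    geometry); water is untouched.  The removal count is recorded in the
    returned system's provenance as ``n_removed``.
    """
    if half_angle >= math.pi:
        raise DomainError(f"half_angle must be < pi, got {half_angle}")
    if half_angle < 0:
        raise DomainError("half_angle must be non-negative")
    direction = np.asarray(direction, dtype=float)
    nrm = np.linalg.norm(direction)
    if nrm == 0:
        raise DomainError("direction must be a nonzero vector")
    direction = direction / nrm

    lipid = system.group_mask(BILAYER)
    center = system.coords[lipid].mean(axis=0)
    head = lipid & (system.names == lm.get_template("DPPC").beads[0].name)
    # head-bead direction per lipid molecule
    head_idx = np.flatnonzero(head)
    v = system.coords[head_idx] - center
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    inside = v @ direction >= math.cos(half_angle)
    doomed_mols = set(system.mol_ids[head_idx[inside]].tolist())
    keep = ~np.isin(system.mol_ids, list(doomed_mols))
    new_ids = np.unique(system.mol_ids[keep], return_inverse=True)[1]
    prov = dict(system.provenance or {})
    prov.update(n_removed=len(doomed_mols), hole_direction=direction,
                hole_half_angle=half_angle)
    return ParticleSystem(
        names=system.names[keep], types=system.types[keep],
        charges=system.charges[keep], mol_ids=new_ids,
        species=system.species[keep], groups=system.groups[keep],
        coords=system.coords[keep], box=system.box, provenance=prov,
    )


def build_fixture(spec: FixtureSpec):
    """Dispatch a FixtureSpec to its generator."""
    p = dict(spec.parameters)
    if spec.kind == "random_walk":
        return random_walk_trajectory(seed=spec.seed, **p)
    if spec.kind == "boltzmann_chains":
        template = lm.get_template(p.pop("species", "DOPC"))
        return boltzmann_chain_samples(template, seed=spec.seed, **p)
    from .vesicle_builder import VesicleSpec, build_vesicle
    direction = p.pop("direction", (0.0, 0.0, 1.0))
    half_angle = p.pop("half_angle", 0.35)
    vspec = VesicleSpec(seed=spec.seed, **p)
    return punch_hole(build_vesicle(vspec), direction, half_angle)
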