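"""GROMACS-dialect file exchange: GRO, NDX, TOP, MDP writers and a
streaming trajectory reader (XTC/TRR/GRO via MDAnalysis).

All writers are deterministic byte-for-byte for identical inputs.  The
three thermostat groups are always emitted in the fixed order
(INNER_WATER, BILAYER, OUTER_WATER) so that per-group ``ref_t`` lines in
the run parameters are unambiguous.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterator, NamedTuple, Optional

import numpy as np

from . import lipid_models as lm
from .errors import ConsistencyError, TrajectoryMismatchError, UnknownLipidError
from .vesicle_builder import GROUP_ORDER, WATER_SPECIES, ParticleSystem

PARAMETER_FILE = "martini_lipids.itp"


# ---------------------------------------------------------------------------
# run parameters


@dataclass(frozen=True)
class ThermalProtocol:
    """One run-parameter set with three temperature-coupling groups.

    ``dt`` is in fs; temperatures in K; ``tau_p`` in ps; pressure in bar.
    """

    phase: str = "production"  # equilibration | production
    dt: float = 10.0  # fs
    n_steps: int = 23_000_000
    group_temps: dict = field(default_factory=lambda: dict.fromkeys(GROUP_ORDER, 300.0))
    thermostat: str = "v-rescale"
    barostat: str = "parrinello-rahman"
    tau_p: float = 13.0  # ps
    ref_pressure: float = 1.0  # bar
    pressure_coupling: str = "semiisotropic"
    cutoff_scheme: str = "Verlet"
    r_c: float = 1.2  # nm

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError(f"dt must be positive, got {self.dt}")
        if set(self.group_temps) != set(GROUP_ORDER):
            raise ConsistencyError(
                f"group_temps must cover exactly {GROUP_ORDER}, got "
                f"{sorted(self.group_temps)}"
            )
        if any(t <= 0 for t in self.group_temps.values()):
            raise ValueError("all group temperatures must be positive")

    @classmethod
    def equilibration(cls, length_ps: float = 300.0, temperature: float = 300.0
                      ) -> "ThermalProtocol":
        """300 ps NPT equilibration at 300 K with 10 fs steps."""
        return cls(phase="equilibration", dt=10.0,
                   n_steps=round(length_ps * 1000.0 / 10.0),
                   group_temps=dict.fromkeys(GROUP_ORDER, temperature))

    @classmethod
    def production(cls, heated_group: str, t_hot: float = 390.0,
                   t_base: float = 300.0, length_ns: float = 230.0
                   ) -> "ThermalProtocol":
        """Portion-selective heating: one thermostat group raised to t_hot."""
        if heated_group not in GROUP_ORDER:
            raise ConsistencyError(
                f"heated_group must be one of {GROUP_ORDER}, got {heated_group!r}")
        temps = dict.fromkeys(GROUP_ORDER, t_base)
        temps[heated_group] = t_hot
        return cls(phase="production", dt=10.0,
                   n_steps=round(length_ns * 1e6 / 10.0), group_temps=temps)


def write_mdp(protocol: ThermalProtocol, path, group_names=GROUP_ORDER) -> None:
    """Emit a key = value run-parameter file for the leap-frog integrator."""
    if tuple(group_names) != GROUP_ORDER:
        raise ConsistencyError(
            f"thermostat group names must be {GROUP_ORDER} (as written to the "
            f"index file), got {tuple(group_names)}")
    temps = " ".join(_num(protocol.group_temps[g]) for g in GROUP_ORDER)
    taus = " ".join(["1.0"] * len(GROUP_ORDER))
    lines = [
        f"; vesikit {protocol.phase} protocol",
        "integrator               = md",
        f"dt                       = {_num(protocol.dt / 1000.0)}",
        f"nsteps                   = {protocol.n_steps}",
        f"cutoff-scheme            = {protocol.cutoff_scheme}",
        f"rvdw                     = {_num(protocol.r_c)}",
        f"rcoulomb                 = {_num(protocol.r_c)}",
        "epsilon_r                = 15",
        f"tcoupl                   = {protocol.thermostat}",
        f"tc-grps                  = {' '.join(GROUP_ORDER)}",
        f"tau_t                    = {taus}",
        f"ref_t                    = {temps}",
        f"pcoupl                   = {protocol.barostat}",
        f"pcoupltype               = {protocol.pressure_coupling}",
        f"tau_p                    = {_num(protocol.tau_p)}",
        f"ref_p                    = {_ref_p(protocol)}",
        f"compressibility          = {_compressibility(protocol)}",
        "gen_vel                  = no",
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def _num(x: float) -> str:
    return f"{x:g}"


def _ref_p(protocol: ThermalProtocol) -> str:
    n = 2 if protocol.pressure_coupling == "semiisotropic" else 1
    return " ".join([_num(protocol.ref_pressure)] * n)


def _compressibility(protocol: ThermalProtocol) -> str:
    n = 2 if protocol.pressure_coupling == "semiisotropic" else 1
    return " ".join(["3e-4"] * n)


# ---------------------------------------------------------------------------
# structure (GRO)


def write_gro(system: ParticleSystem, path, title: str = "vesikit system") -> None:
    """Fixed-width GRO structure file, coordinates in nm to 3 decimals.

    Residue and atom numbers follow the standard modulo-100000 convention.
    """
    out = [title, f"{system.n_beads:>5d}"]
    res = (system.mol_ids + 1) % 100_000
    atom = (np.arange(system.n_beads) + 1) % 100_000
    x, y, z = system.coords.T if system.n_beads else (np.empty(0),) * 3
    for i in range(system.n_beads):
        out.append(
            f"{res[i]:>5d}{system.species[i]:<5s}{system.names[i]:>5s}"
            f"{atom[i]:>5d}{x[i]:8.3f}{y[i]:8.3f}{z[i]:8.3f}"
        )
    out.append(f"{system.box[0]:9.5f} {system.box[1]:9.5f} {system.box[2]:9.5f}")
    Path(path).write_text("\n".join(out) + "\n")


def read_gro(path, ndx_path=None) -> ParticleSystem:
    """Read a GRO file back into a ParticleSystem.

    Bead types and charges are reconstructed from the packaged templates via
    the residue name; group labels come from ``ndx_path`` when given.
    """
    lines = Path(path).read_text().splitlines()
    n = int(lines[1])
    species = np.empty(n, dtype="U6")
    names = np.empty(n, dtype="U6")
    resnums = np.empty(n, dtype=np.int64)
    coords = np.empty((n, 3))
    for i, line in enumerate(lines[2:2 + n]):
        resnums[i] = int(line[0:5])
        species[i] = line[5:10].strip()
        names[i] = line[10:15].strip()
        coords[i] = (float(line[20:28]), float(line[28:36]), float(line[36:44]))
    box = np.array([float(t) for t in lines[2 + n].split()[:3]])
    # contiguous molecule ids from residue-number change points (robust to wrap)
    if n:
        new_mol = np.empty(n, dtype=bool)
        new_mol[0] = True
        new_mol[1:] = resnums[1:] != resnums[:-1]
        mol_ids = np.cumsum(new_mol) - 1
    else:
        mol_ids = np.empty(0, dtype=np.int64)
    types = np.empty(n, dtype="U6")
    charges = np.zeros(n)
    registry = lm.species_registry()
    cache = {}
    for sp in np.unique(species):
        if sp in registry:
            cache[sp] = lm.get_template(sp)
    if n:
        _, first = np.unique(mol_ids, return_index=True)
        in_mol_index = np.arange(n) - first[mol_ids]
    else:
        in_mol_index = np.empty(0, dtype=np.int64)
    for sp in np.unique(species):
        mask = species == sp
        if sp in cache:
            t = cache[sp]
            types[mask] = np.array([b.type for b in t.beads])[in_mol_index[mask]]
            charges[mask] = np.array([b.charge for b in t.beads])[in_mol_index[mask]]
        else:
            types[mask] = lm.water_bead().type if sp == WATER_SPECIES else "X"
    groups = np.full(n, "", dtype="U12")
    if ndx_path is not None:
        for g, idx in read_ndx(ndx_path).items():
            groups[idx] = g
    sys = ParticleSystem(names, types, charges, mol_ids, species, groups,
                         coords, box)
    return sys


# ---------------------------------------------------------------------------
# index groups (NDX)


def write_ndx(system: ParticleSystem, path) -> None:
    """Three named groups of 1-based bead indices, 15 per line.

    The groups must partition the bead set; an unlabelled bead is an error.
    """
    unlabelled = ~np.isin(system.groups, GROUP_ORDER)
    if unlabelled.any():
        raise ConsistencyError(
            f"{int(unlabelled.sum())} beads carry no thermostat-group label")
    out = []
    for g in GROUP_ORDER:
        idx = np.flatnonzero(system.groups == g) + 1
        out.append(f"[ {g} ]")
        for k in range(0, len(idx), 15):
            out.append(" ".join(f"{j:d}" for j in idx[k:k + 15]))
    Path(path).write_text("\n".join(out) + "\n")


def read_ndx(path) -> dict[str, np.ndarray]:
    """Group name -> 0-based bead indices."""
    groups: dict[str, list[int]] = {}
    current = None
    for line in Path(path).read_text().splitlines():
        line = line.split(";", 1)[0].strip()
        if not line:
            continue
        if line.startswith("["):
            current = line.strip("[] ").strip()
            groups[current] = []
        elif current is not None:
            groups[current].extend(int(t) - 1 for t in line.split())
    return {g: np.asarray(v, dtype=np.int64) for g, v in groups.items()}


# ---------------------------------------------------------------------------
# topology counts (TOP)


def write_top(system: ParticleSystem, path, include: str = PARAMETER_FILE,
              system_name: str = "vesikit vesicle") -> None:
    """Topology: include the packaged parameters, list molecule counts in
    build order (adjacent runs of one species merged)."""
    if system.provenance is None:
        raise ConsistencyError(
            "system lacks build provenance; write_top requires a built system")
    registry = lm.species_registry()
    mol_species = system.molecule_species()
    out = [f'#include "{include}"', "", "[ system ]", system_name, "",
           "[ molecules ]"]
    if len(mol_species):
        change = np.r_[True, mol_species[1:] != mol_species[:-1]]
        starts = np.flatnonzero(change)
        counts = np.diff(np.r_[starts, len(mol_species)])
        for s, c in zip(mol_species[starts], counts):
            if s != WATER_SPECIES and s not in registry:
                raise UnknownLipidError(
                    f"species {s!r} has no packaged template")
            out.append(f"{s} {int(c)}")
    Path(path).write_text("\n".join(out) + "\n")


# ---------------------------------------------------------------------------
# trajectories


class Frame(NamedTuple):
    time: float  # ps
    coords: np.ndarray  # (N, 3) nm
    box: np.ndarray  # (3,) nm


class TrajectorySlice:
    """Streaming frame source bound to a per-bead topology.

    ``topology`` is a ParticleSystem whose coordinates are the reference
    frame; iteration yields Frame records with strictly increasing times.
    Selections resolve from thermostat-group labels or molecule species.
    """

    def __init__(self, topology: ParticleSystem,
                 frames: Callable[[], Iterator[Frame]] | list[Frame],
                 n_frames: Optional[int] = None):
        self.topology = topology
        self._frames = frames
        self._n_frames = n_frames if n_frames is not None else (
            len(frames) if isinstance(frames, list) else None)

    @property
    def n_frames(self) -> Optional[int]:
        return self._n_frames

    def __iter__(self) -> Iterator[Frame]:
        it = iter(self._frames) if isinstance(self._frames, list) else self._frames()
        last = None
        n = self.topology.n_beads
        for fr in it:
            if fr.coords.shape != (n, 3):
                raise TrajectoryMismatchError(
                    f"frame has {fr.coords.shape[0]} beads, topology has {n}")
            if last is not None and fr.time <= last:
                raise ConsistencyError(
                    f"frame times not strictly increasing at t = {fr.time} ps")
            last = fr.time
            yield fr

    def select(self, group: Optional[str] = None,
               species: Optional[str] = None) -> np.ndarray:
        """Boolean bead mask by thermostat group and/or molecule species."""
        mask = np.ones(self.topology.n_beads, dtype=bool)
        if group is not None:
            if group not in self.topology.groups:
                raise ConsistencyError(f"no beads labelled {group!r}")
            mask &= self.topology.group_mask(group)
        if species is not None:
            mask &= self.topology.species_mask(species)
        return mask

    @classmethod
    def from_system(cls, system: ParticleSystem, time: float = 0.0
                    ) -> "TrajectorySlice":
        return cls(system, [Frame(time, system.coords.copy(), system.box.copy())])

    @classmethod
    def from_coords(cls, system: ParticleSystem, coords: np.ndarray,
                    times: np.ndarray) -> "TrajectorySlice":
        """In-memory trajectory from an (n_frames, N, 3) array."""
        frames = [Frame(float(t), c, system.box.copy())
                  for t, c in zip(times, coords)]
        return cls(system, frames)


def open_trajectory(structure_path, trajectory_path, ndx_path=None
                    ) -> TrajectorySlice:
    """Open a structure + trajectory pair as a streaming TrajectorySlice.

    Memory use is independent of trajectory length (frames stream through
    MDAnalysis).  A bead-count mismatch raises TrajectoryMismatchError; a
    truncated trajectory ends with a partial-read warning.
    """
    import MDAnalysis as mda

    topology = read_gro(structure_path, ndx_path=ndx_path)
    try:
        u = mda.Universe(str(structure_path), str(trajectory_path))
    except (IOError, ValueError) as exc:
        raise TrajectoryMismatchError(
            f"cannot pair {structure_path} with {trajectory_path}: {exc}"
        ) from exc
    if u.trajectory.n_atoms != topology.n_beads:
        raise TrajectoryMismatchError(
            f"structure has {topology.n_beads} beads but trajectory frames "
            f"carry {u.trajectory.n_atoms}")

    def frames() -> Iterator[Frame]:
        count = 0
        try:
            for ts in u.trajectory:
                yield Frame(float(ts.time), ts.positions.astype(float) / 10.0,
                            np.asarray(ts.dimensions[:3], dtype=float) / 10.0)
                count += 1
        except (IOError, EOFError) as exc:  # truncated file mid-stream
            warnings.warn(
                f"trajectory ended early after {count} frames: {exc}",
                RuntimeWarning, stacklevel=2)

    try:
        n_frames = len(u.trajectory)
    except (IOError, TypeError):
        n_frames = None
    return TrajectorySlice(topology, frames, n_frames=n_frames)


def write_trajectory(traj: TrajectorySlice, path) -> None:
    """Write frames to an XTC/TRR/multi-frame GRO file via MDAnalysis."""
    import MDAnalysis as mda

    n = traj.topology.n_beads
    u = mda.Universe.empty(n, trajectory=True)
    with mda.Writer(str(path), n) as w:
        for fr in traj:
            u.atoms.positions = fr.coords * 10.0
            u.dimensions = [fr.box[0] * 10, fr.box[1] * 10, fr.box[2] * 10,
                            90, 90, 90]
            u.trajectory.ts.time = fr.time
            w.write(u.atoms)


def emit_build(system: ParticleSystem, protocol: ThermalProtocol, prefix) -> dict:
    """Write the .gro/.ndx/.top/.mdp set for one build; returns the paths."""
    prefix = Path(prefix)
    paths = {
        "gro": prefix.with_suffix(".gro"),
        "ndx": prefix.with_suffix(".ndx"),
        "top": prefix.with_suffix(".top"),
        "mdp": prefix.with_suffix(".mdp"),
    }
    write_gro(system, paths["gro"])
    write_ndx(system, paths["ndx"])
    write_top(system, paths["top"])
    write_mdp(protocol, paths["mdp"])
    return paths
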