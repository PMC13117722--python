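"""Measurements on coarse-grained structures and trajectories.

Implements the membrane observables the toolkit exists for: molecular
radial distributions by minimum inter-bead distance, vesicle area per
lipid, MSD and diffusion coefficients, group-group nonbonded energies,
kink angles, tail end-to-end distances and spherical pore detection.

Conventions shared by every operator:

* the vesicle centre is the centre of geometry of the lipid beads of the
  frame under analysis;
* the minimum-image convention is applied for the periodic box in all
  distance computations;
* frame-averaged operators default to the final 10 % of the trajectory
  (``last_fraction``), since structural observables are meant to describe
  the relaxed end state of a run.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from . import lipid_models as lm
from .errors import (ConsistencyError, DomainError, ResolutionError,
                     SingularGeometryError)
from .gmx_io import TrajectorySlice
from .vesicle_builder import ParticleSystem

COULOMB_CONSTANT = 138.935  # kJ nm / (mol e^2)

Selection = Union[None, str, np.ndarray]


# ---------------------------------------------------------------------------
# selection plumbing


def _as_traj(obj) -> TrajectorySlice:
    if isinstance(obj, ParticleSystem):
        return TrajectorySlice.from_system(obj)
    return obj


def _resolve_selection(topology: ParticleSystem, sel: Selection) -> np.ndarray:
    """Boolean bead mask: None = all lipid beads; str = species or group."""
    if sel is None:
        registry = lm.species_registry()
        mask = np.isin(topology.species, list(registry))
        # no lipid species present (e.g. point-particle fixtures): take all
        return mask if mask.any() else np.ones(topology.n_beads, dtype=bool)
    if isinstance(sel, str):
        if sel in lm.species_registry() or sel == "W":
            return topology.species_mask(sel)
        return topology.group_mask(sel)
    mask = np.asarray(sel)
    if mask.dtype == bool:
        return mask
    out = np.zeros(topology.n_beads, dtype=bool)
    out[mask] = True
    return out


def _frame_window(traj: TrajectorySlice, last_fraction: float):
    """Iterate the final ``last_fraction`` of frames (at least one)."""
    if last_fraction >= 1.0:
        yield from traj
        return
    if traj.n_frames is not None:
        skip = traj.n_frames - max(1, math.ceil(last_fraction * traj.n_frames))
        for i, fr in enumerate(traj):
            if i >= skip:
                yield fr
    else:
        frames = list(traj)
        keep = max(1, math.ceil(last_fraction * len(frames)))
        yield from frames[-keep:]


def _min_image(d: np.ndarray, box: np.ndarray) -> np.ndarray:
    return d - box * np.round(d / box)


def _wrap(coords: np.ndarray, box: np.ndarray) -> np.ndarray:
    return np.mod(coords, box)


# ---------------------------------------------------------------------------
# molecular radial distribution


@dataclass
class RdfResult:
    """Average neighbour count per reference lipid in 0.01 nm molecular-
    distance bins (raw counts, not a density-normalised g(r))."""

    r: np.ndarray  # bin centres, nm
    values: np.ndarray
    n_ref: int
    n_frames: int
    bin_width: float = 0.01

    @property
    def total_neighbors(self) -> float:
        return float(self.values.sum())


def molecular_rdf(traj, ref: Selection, target: Selection, r_max: float = 2.0,
                  bin_width: float = 0.01, normalized: bool = False,
                  last_fraction: float = 0.1) -> RdfResult:
    """Radial distribution of target molecules around reference lipids.

    The molecular distance between two molecules is the minimum distance
    over all of their bead pairs (minimum image).  For every reference
    molecule and frame, each target molecule contributes one count to the
    bin containing that distance; values are averaged over references and
    frames.  Self pairs are excluded.  With ``normalized=True`` the counts
    are divided by the spherical shell volume times the mean target density
    (a conventional g(r)).
    """
    if r_max <= 0:
        raise DomainError(f"r_max must be positive, got {r_max}")
    traj = _as_traj(traj)
    top = traj.topology
    ref_mask = _resolve_selection(top, ref)
    tgt_mask = _resolve_selection(top, target)
    if not ref_mask.any():
        raise ConsistencyError("reference selection is empty")
    if not tgt_mask.any():
        raise ConsistencyError("target selection is empty")

    ref_beads = np.flatnonzero(ref_mask)
    tgt_beads = np.flatnonzero(tgt_mask)
    ref_mols, ref_code = np.unique(top.mol_ids[ref_beads], return_inverse=True)
    tgt_mols, tgt_code = np.unique(top.mol_ids[tgt_beads], return_inverse=True)
    n_ref, n_tgt = len(ref_mols), len(tgt_mols)

    n_bins = int(round(r_max / bin_width))
    hist = np.zeros(n_bins)
    n_frames = 0
    for fr in _frame_window(traj, last_fraction):
        box = fr.box
        tree_r = cKDTree(_wrap(fr.coords[ref_beads], box), boxsize=box)
        tree_t = cKDTree(_wrap(fr.coords[tgt_beads], box), boxsize=box)
        coo = tree_r.sparse_distance_matrix(tree_t, r_max, output_type="coo_matrix")
        if coo.nnz:
            keys = ref_code[coo.row].astype(np.int64) * n_tgt + tgt_code[coo.col]
            # exclude bead pairs belonging to the same molecule
            same = (top.mol_ids[ref_beads][coo.row]
                    == top.mol_ids[tgt_beads][coo.col])
            keys, dists = keys[~same], coo.data[~same]
            if len(keys):
                order = np.lexsort((dists, keys))
                keys, dists = keys[order], dists[order]
                first = np.r_[True, keys[1:] != keys[:-1]]
                min_d = dists[first]  # per molecule pair, the minimum distance
                bins = np.round(min_d / bin_width).astype(int)
                ok = (bins >= 1) & (bins <= n_bins)
                np.add.at(hist, bins[ok] - 1, 1.0)
        n_frames += 1

    values = hist / (n_ref * n_frames)
    centers = bin_width * np.arange(1, n_bins + 1)
    if normalized:
        shell = 4.0 * math.pi * centers ** 2 * bin_width
        # mean target molecular density over the box
        rho = n_tgt / float(np.prod(traj.topology.box))
        values = values / (shell * rho)
    return RdfResult(r=centers, values=values, n_ref=n_ref, n_frames=n_frames,
                     bin_width=bin_width)


# ---------------------------------------------------------------------------
# leaflet assignment and area per lipid


def vesicle_center(system: ParticleSystem, lipid_mask: Optional[np.ndarray] = None
                   ) -> np.ndarray:
    """Per-frame vesicle centre: centre of geometry of the lipid beads."""
    if lipid_mask is None:
        lipid_mask = _resolve_selection(system, None)
    if not lipid_mask.any():
        raise ConsistencyError("no lipid beads to define a vesicle centre")
    return system.coords[lipid_mask].mean(axis=0)


def assign_leaflets(system: ParticleSystem, lipid_mask: Optional[np.ndarray] = None):
    """Outer/inner leaflet membership per lipid molecule.

    A lipid belongs to the outer leaflet when its head-to-tail vector points
    against the outward radial direction (tails inward).  Returns
    (mol_ids, outer_mask, center).
    """
    mask = _resolve_selection(system, lipid_mask)
    center = vesicle_center(system, mask)
    beads = np.flatnonzero(mask)
    mols, first = np.unique(system.mol_ids[beads], return_index=True)
    if len(beads) != len(mols) * lm.N_BEADS:
        raise ConsistencyError("selection does not consist of whole 12-bead lipids")
    coords = system.coords[beads].reshape(len(mols), lm.N_BEADS, 3)
    head = coords[:, lm.HEAD_BEAD - 1]
    tails = coords[:, [b - 1 for b in lm.TAIL_A + lm.TAIL_B]].mean(axis=1)
    cog = coords.mean(axis=1)
    radial = cog - center
    outer = np.einsum("ij,ij->i", tails - head, radial) < 0.0
    return mols, outer, center


@dataclass
class AplResult:
    """Area per lipid per leaflet plus the area-weighted combination."""

    outer: float  # nm^2
    inner: float
    combined: float
    r_outer: float  # leaflet radii from mean phosphate distance, nm
    r_inner: float
    n_outer: int
    n_inner: int


def vesicle_apl(system: ParticleSystem, lipid_selection: Selection = None
                ) -> AplResult:
    """Vesicle area per lipid from leaflet spheres.

    Leaflet radius is the mean radial distance of the phosphate bead from
    the vesicle centre; APL_leaflet = 4πR²/N_leaflet; the combined value is
    the area-weighted mean of the two leaflet APLs.
    """
    mask = _resolve_selection(system, lipid_selection)
    mols, outer, center = assign_leaflets(system, mask)
    if len(mols) < 20:
        raise ConsistencyError(
            f"need at least 10 lipids per leaflet, have {len(mols)} in total")
    beads = np.flatnonzero(mask)
    coords = system.coords[beads].reshape(len(mols), lm.N_BEADS, 3)
    phos_r = np.linalg.norm(coords[:, lm.PHOSPHATE_BEAD - 1] - center, axis=1)
    out = {}
    for name, sel in (("outer", outer), ("inner", ~outer)):
        n = int(sel.sum())
        if n < 10:
            raise ConsistencyError(f"{name} leaflet has {n} lipids; need >= 10")
        r = float(phos_r[sel].mean())
        out[name] = (r, n, 4.0 * math.pi * r * r / n)
    a_out = 4.0 * math.pi * out["outer"][0] ** 2
    a_in = 4.0 * math.pi * out["inner"][0] ** 2
    combined = (a_out * out["outer"][2] + a_in * out["inner"][2]) / (a_out + a_in)
    return AplResult(outer=out["outer"][2], inner=out["inner"][2],
                     combined=combined, r_outer=out["outer"][0],
                     r_inner=out["inner"][0], n_outer=out["outer"][1],
                     n_inner=out["inner"][1])


# ---------------------------------------------------------------------------
# MSD and diffusion


@dataclass
class MsdResult:
    lags: np.ndarray  # ps
    msd: np.ndarray  # nm^2
    fit_window: tuple  # (t_lo, t_hi) ps
    D: float  # 1e-5 cm^2/s
    d_fit: int
    slope: float  # nm^2/ps


def _msd_fft(pos: np.ndarray) -> np.ndarray:
    """Time-origin-averaged MSD for positions shaped (T, M, 3)."""
    T = pos.shape[0]
    nfft = 1 << (2 * T - 1).bit_length()
    fft = np.fft.rfft(pos, n=nfft, axis=0)
    acf = np.fft.irfft(fft * fft.conj(), n=nfft, axis=0)[:T].real
    sq = (pos ** 2).sum(axis=2)  # (T, M)
    s2 = acf.sum(axis=2)  # (T, M), autocorrelation of each axis, summed
    cums = np.concatenate([np.zeros((1, sq.shape[1])), np.cumsum(sq, axis=0)])
    total = cums[-1]
    k = np.arange(T)
    # sum over valid origins t of |r(t)|^2 + |r(t+k)|^2
    s1 = cums[T - k] + (total - cums[k])
    msd = (s1 - 2.0 * s2) / (T - k)[:, None]
    return msd.mean(axis=1)


def msd_and_diffusion(traj, lipid_selection: Selection = None,
                      fit_window: Optional[tuple] = None, d_fit: int = 4
                      ) -> MsdResult:
    """MSD of lipid phosphate beads and the fitted diffusion coefficient.

    Per-frame centre-of-geometry drift of the selection is removed before
    displacements are taken; the MSD is averaged over molecules and all
    time origins.  D = slope / d_fit, where d_fit = 2 x dimensionality:
    4 (lateral convention, default — motion is quasi-2-D on the vesicle
    shell) or 6 (free 3-D diffusion, recovering D = sigma^2/(2 dt) on a
    Gaussian random walk).  Units: D in 1e-5 cm^2/s.
    """
    if d_fit not in (4, 6):
        raise DomainError(f"d_fit must be 4 or 6, got {d_fit}")
    traj = _as_traj(traj)
    top = traj.topology
    mask = _resolve_selection(top, lipid_selection)
    beads = np.flatnonzero(mask)
    if not len(beads):
        raise ConsistencyError("MSD selection is empty")
    mols, first = np.unique(top.mol_ids[beads], return_index=True)
    # tracking site: phosphate bead when the molecule has one, else its first bead
    names = top.names[beads]
    track = []
    for m, f in zip(mols, first):
        mol_beads = beads[top.mol_ids[beads] == m]
        phos = mol_beads[top.names[mol_beads] == "PO4"]
        track.append(phos[0] if len(phos) else mol_beads[0])
    track = np.asarray(track)

    times, pos = [], []
    for fr in traj:
        times.append(fr.time)
        pos.append(fr.coords[track])
    times = np.asarray(times)
    if len(times) < 10:
        raise DomainError(f"need at least 10 frames, got {len(times)}")
    pos = np.asarray(pos)  # (T, M, 3)
    pos = pos - pos.mean(axis=1, keepdims=True)  # remove COG drift

    dts = np.diff(times)
    if not np.allclose(dts, dts[0], rtol=1e-6, atol=1e-9):
        raise ConsistencyError("MSD requires uniformly spaced frames")
    lags = times - times[0]
    msd = _msd_fft(pos)
    msd[0] = 0.0

    t_max = lags[-1]
    if fit_window is None:
        fit_window = (0.1 * t_max, 0.5 * t_max)
    lo, hi = fit_window
    sel = (lags >= lo) & (lags <= hi)
    if sel.sum() < 3:
        raise DomainError(
            f"fit window {fit_window} contains {int(sel.sum())} points; need >= 3")
    slope, _ = np.polyfit(lags[sel], msd[sel], 1)
    D = slope / d_fit * 1.0e3  # nm^2/ps -> 1e-5 cm^2/s
    return MsdResult(lags=lags, msd=msd, fit_window=(float(lo), float(hi)),
                     D=float(D), d_fit=d_fit, slope=float(slope))


# ---------------------------------------------------------------------------
# group-group nonbonded energies


@dataclass
class EnergyBreakdown:
    group_a: str
    group_b: str
    lj: float  # kJ/mol
    coulomb: float  # kJ/mol
    time: float = 0.0  # ps


def _pair_tables(types: np.ndarray, params: lm.NonbondedParams):
    uniq, codes = np.unique(types, return_inverse=True)
    k = len(uniq)
    sig = np.empty((k, k))
    eps = np.empty((k, k))
    for i, a in enumerate(uniq):
        for j, b in enumerate(uniq):
            sig[i, j], eps[i, j] = lm.lookup_nonbonded(a, b, params)
    return codes, sig, eps


def group_interaction_energy(system: ParticleSystem, group_a, group_b,
                             params: Optional[lm.NonbondedParams] = None,
                             time: float = 0.0) -> EnergyBreakdown:
    """Shifted-cutoff LJ and Coulomb energy between two bead groups.

    V_LJ = Σ 4ε[(σ/r)¹² − (σ/r)⁶] − V(r_c); V_coul = Σ f q_i q_j / (ε_r) ·
    (1/r − 1/r_c) with f = 138.935 kJ·nm/(mol·e²).  Pairs within one
    molecule are excluded.  Neighbour search is tree-based (periodic
    KD-tree); with equal groups each intra-group pair is counted once.
    """
    params = params or lm.default_nonbonded()
    mask_a = _resolve_selection(system, group_a)
    mask_b = _resolve_selection(system, group_b)
    name_a = group_a if isinstance(group_a, str) else "group_a"
    name_b = group_b if isinstance(group_b, str) else "group_b"
    same = bool(np.array_equal(mask_a, mask_b))
    if not same and (mask_a & mask_b).any():
        raise ConsistencyError(
            "distinct groups overlap; use identical groups for intra-group mode")
    if not same and mask_a.tobytes() > mask_b.tobytes():
        # canonical group order so the result is exactly symmetric
        mask_a, mask_b = mask_b, mask_a
    codes, sig, eps = _pair_tables(system.types, params)
    box = system.box
    ia, ib = np.flatnonzero(mask_a), np.flatnonzero(mask_b)
    rc = params.r_c
    if same:
        tree = cKDTree(_wrap(system.coords[ia], box), boxsize=box)
        pairs = tree.query_pairs(rc, output_type="ndarray")
        pi, pj = ia[pairs[:, 0]], ia[pairs[:, 1]]
    else:
        tree_a = cKDTree(_wrap(system.coords[ia], box), boxsize=box)
        tree_b = cKDTree(_wrap(system.coords[ib], box), boxsize=box)
        coo = tree_a.sparse_distance_matrix(tree_b, rc, output_type="coo_matrix")
        pi, pj = ia[coo.row], ib[coo.col]
    keep = system.mol_ids[pi] != system.mol_ids[pj]
    pi, pj = pi[keep], pj[keep]
    d = _min_image(system.coords[pi] - system.coords[pj], box)
    r = np.linalg.norm(d, axis=1)
    if np.any(r == 0.0):
        raise SingularGeometryError("coincident beads in the interaction pair list")
    s = sig[codes[pi], codes[pj]]
    e = eps[codes[pi], codes[pj]]
    sr6 = (s / r) ** 6
    src6 = (s / rc) ** 6
    lj = float(np.sum(4.0 * e * (sr6 ** 2 - sr6) - 4.0 * e * (src6 ** 2 - src6)))
    q = system.charges[pi] * system.charges[pj]
    coulomb = float(np.sum(COULOMB_CONSTANT * q / params.eps_r * (1.0 / r - 1.0 / rc)))
    return EnergyBreakdown(group_a=name_a, group_b=name_b, lj=lj,
                           coulomb=coulomb, time=time)


# ---------------------------------------------------------------------------
# chain geometry: kink angles and end-to-end distances


def _bead_angles(coords: np.ndarray, triples: Sequence[tuple[int, int, int]]
                 ) -> np.ndarray:
    """Angles in degrees for 1-based bead triples, coords shaped (M, 12, 3)."""
    out = []
    for (i, j, k) in triples:
        v1 = coords[:, i - 1] - coords[:, j - 1]
        v2 = coords[:, k - 1] - coords[:, j - 1]
        n1 = np.linalg.norm(v1, axis=1)
        n2 = np.linalg.norm(v2, axis=1)
        if np.any(n1 == 0) or np.any(n2 == 0):
            raise SingularGeometryError("zero-length bond vector in angle triple")
        c = np.einsum("ij,ij->i", v1, v2) / (n1 * n2)
        out.append(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))
    return np.concatenate(out) if out else np.empty(0)


@dataclass
class AngleStats:
    mean: float  # degrees
    std: float
    n: int
    histogram: tuple  # (counts, bin_edges in degrees)
    triples: tuple
    saturated_only: bool = False


def _tail_triples(template: lm.LipidTemplate) -> list[tuple[int, int, int]]:
    tail = set(lm.TAIL_A) | set(lm.TAIL_B)
    return [(a.i, a.j, a.k) for a in template.angles
            if {a.i, a.j, a.k} <= tail]


def kink_angles(traj, lipid_selection: Selection = None,
                last_fraction: float = 1.0, bins: int = 90) -> AngleStats:
    """Statistics of the tail angles centred on unsaturated (cis) beads.

    For a fully saturated species the saturated tail triples are analysed
    instead and the result is flagged ``saturated_only``.
    """
    traj = _as_traj(traj)
    top = traj.topology
    mask = _resolve_selection(top, lipid_selection)
    beads = np.flatnonzero(mask)
    species = np.unique(top.species[beads])
    if len(species) != 1:
        raise ConsistencyError(
            f"kink_angles needs a single-species selection, got {list(species)}")
    template = lm.get_template(str(species[0]))
    if template.unsaturated_beads:
        triples = [tuple((a.i, a.j, a.k)) for a in template.angles
                   if a.j in template.unsaturated_beads]
        saturated_only = False
    else:
        triples = _tail_triples(template)
        saturated_only = True
    n_mol = len(beads) // lm.N_BEADS
    samples = []
    for fr in _frame_window(traj, last_fraction):
        coords = fr.coords[beads].reshape(n_mol, lm.N_BEADS, 3)
        samples.append(_bead_angles(coords, triples))
    allangles = np.concatenate(samples)
    counts, edges = np.histogram(allangles, bins=bins, range=(0.0, 180.0))
    return AngleStats(mean=float(allangles.mean()), std=float(allangles.std()),
                      n=len(allangles), histogram=(counts, edges),
                      triples=tuple(triples), saturated_only=saturated_only)


@dataclass
class EndToEndResult:
    mean: float  # nm
    std: float
    n: int


def end_to_end(traj, lipid_selection: Selection = None,
               last_fraction: float = 1.0) -> EndToEndResult:
    """Mean distance between the two tail end beads (8 and 12) of each lipid."""
    traj = _as_traj(traj)
    top = traj.topology
    mask = _resolve_selection(top, lipid_selection)
    beads = np.flatnonzero(mask)
    if len(beads) % lm.N_BEADS:
        raise ConsistencyError("selection does not consist of 12-bead lipids")
    n_mol = len(beads) // lm.N_BEADS
    i8, i12 = lm.END_BEADS[0] - 1, lm.END_BEADS[1] - 1
    dists = []
    for fr in _frame_window(traj, last_fraction):
        coords = fr.coords[beads].reshape(n_mol, lm.N_BEADS, 3)
        dists.append(np.linalg.norm(coords[:, i8] - coords[:, i12], axis=1))
    d = np.concatenate(dists)
    return EndToEndResult(mean=float(d.mean()), std=float(d.std()), n=len(d))


# ---------------------------------------------------------------------------
# pore / notch detection


@dataclass
class Pore:
    direction: np.ndarray  # unit vector from the vesicle centre
    angular_radius: float  # rad
    diameter: float  # nm, 2 * R_mid * angular_radius


@dataclass
class PoreReport:
    pores: list
    resolution: float  # nm
    r_mid: float  # nm

    @property
    def n_pores(self) -> int:
        return len(self.pores)


def _sphere_grid(n_rings: int) -> np.ndarray:
    """Near-equal-area grid of unit vectors (latitude bands split in cells)."""
    centers = []
    for i in range(n_rings):
        theta = (i + 0.5) * math.pi / n_rings
        m = max(1, round(2.0 * n_rings * math.sin(theta)))
        phi = (np.arange(m) + 0.5) * 2.0 * math.pi / m
        st, ct = math.sin(theta), math.cos(theta)
        centers.append(np.column_stack([st * np.cos(phi), st * np.sin(phi),
                                        np.full(m, ct)]))
    return np.vstack(centers)


def detect_pores(system: ParticleSystem, lipid_selection: Selection = None,
                 resolution: float = 0.5, bead_radius: float = 0.235
                 ) -> PoreReport:
    """Detect lipid-depleted patches (pores/notches) on the vesicle shell.

    Lipid beads are mapped to directions on the mid-radius sphere; an
    equal-area occupancy grid at the given linear resolution is built, with
    each bead covering a disc of ``bead_radius`` (half the CG bead
    diameter).  Maximal connected empty patches are reported with diameter
    2·R_mid·α, α the patch angular radius.
    """
    mask = _resolve_selection(system, lipid_selection)
    beads = np.flatnonzero(mask)
    if not len(beads):
        raise ConsistencyError("empty lipid selection")
    center = vesicle_center(system, mask)
    vec = system.coords[beads] - center
    r = np.linalg.norm(vec, axis=1)
    if np.any(r == 0):
        raise SingularGeometryError("lipid bead exactly at the vesicle centre")
    r_mid = float(r.mean())
    n_lipids = len(np.unique(system.mol_ids[beads]))
    # per-leaflet anchor spacing (~sqrt(APL)); half the lipids per leaflet
    mean_spacing = math.sqrt(4.0 * math.pi * r_mid ** 2 / max(1, n_lipids // 2))
    if resolution > mean_spacing:
        raise ResolutionError(
            f"grid resolution {resolution} nm is coarser than the mean "
            f"inter-lipid spacing {mean_spacing:.2f} nm")
    dirs = vec / r[:, None]

    n_rings = max(4, round(math.pi * r_mid / resolution))
    grid = _sphere_grid(n_rings)
    cell_ang = math.pi / n_rings  # linear angular size of one cell
    occ_ang = 0.5 * math.sqrt(2.0) * cell_ang + bead_radius / r_mid
    tree = cKDTree(dirs)
    dist, _ = tree.query(grid, k=1)
    occupied = dist <= 2.0 * math.sin(min(occ_ang, math.pi) / 2.0)
    empty = grid[~occupied]
    pores: list[Pore] = []
    if len(empty):
        etree = cKDTree(empty)
        adj_chord = 2.0 * math.sin(min(1.5 * cell_ang, math.pi) / 2.0)
        pairs = etree.query_pairs(adj_chord, output_type="ndarray")
        from scipy.sparse import coo_matrix
        n = len(empty)
        data = np.ones(len(pairs))
        graph = coo_matrix((data, (pairs[:, 0], pairs[:, 1])), shape=(n, n))
        n_comp, labels = connected_components(graph, directed=False)
        for c in range(n_comp):
            members = empty[labels == c]
            centroid = members.mean(axis=0)
            norm = np.linalg.norm(centroid)
            if norm == 0:  # degenerate: patch wraps the whole sphere
                centroid = members[0]
                norm = 1.0
            centroid = centroid / norm
            cosang = np.clip(members @ centroid, -1.0, 1.0)
            alpha = float(np.arccos(cosang).max()) + 0.5 * cell_ang \
                + bead_radius / r_mid
            pores.append(Pore(direction=centroid, angular_radius=alpha,
                              diameter=2.0 * r_mid * alpha))
    pores.sort(key=lambda p: -p.diameter)
    return PoreReport(pores=pores, resolution=resolution, r_mid=r_mid)
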