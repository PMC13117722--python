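"""Analysis operators against brute-force oracles and closed forms."""
import math

import numpy as np
import pytest

import vesikit as vk
import vesikit.lipid_models as lm
import vesikit.traj_analysis as ta
from vesikit.errors import (ConsistencyError, DomainError, ResolutionError,
                            SingularGeometryError)
from vesikit.synthetic_fixtures import (boltzmann_chain_samples, punch_hole,
                                        random_walk_trajectory, sample_angles)


def _two_molecule_system(separation):
    """Two 2-bead DPPC-labelled stubs whose closest beads sit `separation`
    apart along x (the other bead pairs are farther)."""
    coords = np.array([[2.0, 2.0, 2.0], [1.5, 2.0, 2.0],
                       [2.0 + separation, 2.0, 2.0],
                       [2.5 + separation, 2.0, 2.0]])
    return vk.ParticleSystem(
        names=["A", "B"] * 2, types=["C1"] * 4, charges=[0.0] * 4,
        mol_ids=[0, 0, 1, 1], species=["DPPC"] * 4,
        groups=[vk.BILAYER] * 4, coords=coords, box=[20.0, 20.0, 20.0])


class TestMolecularRdf:
    def test_minimum_bead_distance_definition(self):
        res = ta.molecular_rdf(_two_molecule_system(0.50), "DPPC", "DPPC",
                               r_max=2.0)
        peak = np.flatnonzero(res.values)
        assert list(res.r[peak]) == [pytest.approx(0.50)]
        # both molecules see one neighbour at 0.50 nm
        assert res.values[peak[0]] == pytest.approx(1.0)

    def test_matches_brute_force_oracle(self, toy_molecules):
        coords, system = toy_molecules
        res = ta.molecular_rdf(system, "DPPC", "DPPC", r_max=4.0)
        box = system.box
        hist = np.zeros(len(res.r))
        for i in range(len(coords)):
            for j in range(len(coords)):
                if i == j:
                    continue
                d = coords[i][:, None, :] - coords[j][None, :, :]
                d -= box * np.round(d / box)
                md = np.sqrt((d ** 2).sum(-1)).min()
                b = int(round(md / 0.01))
                if 1 <= b <= len(hist):
                    hist[b - 1] += 1
        assert np.allclose(res.values, hist / len(coords))

    def test_lone_molecule_sees_nothing(self):
        s = _two_molecule_system(0.5)
        keep = s.mol_ids == 0
        alone = vk.ParticleSystem(s.names[keep], s.types[keep],
                                  s.charges[keep], s.mol_ids[keep],
                                  s.species[keep], s.groups[keep],
                                  s.coords[keep], s.box)
        res = ta.molecular_rdf(alone, "DPPC", "DPPC", r_max=2.0)
        assert res.values.sum() == 0.0

    def test_empty_reference_rejected(self):
        with pytest.raises(ConsistencyError):
            ta.molecular_rdf(_two_molecule_system(0.5), "W", "DPPC")


class TestVesicleApl:
    def test_scaling_law(self, mini_vesicle, mini_spec):
        base = ta.vesicle_apl(mini_vesicle)
        s = 1.3
        center = ta.vesicle_center(mini_vesicle)
        lipid = mini_vesicle.group_mask(vk.BILAYER)
        coords = mini_vesicle.coords.copy()
        coords[lipid] = center + s * (coords[lipid] - center)
        grown = mini_vesicle.with_coords(coords)
        res = ta.vesicle_apl(grown)
        assert res.combined == pytest.approx(s ** 2 * base.combined, rel=1e-9)
        assert res.outer == pytest.approx(s ** 2 * base.outer, rel=1e-9)

    def test_leaflet_assignment_matches_radial_rank_oracle(self, mini_vesicle):
        mols, outer, center = ta.assign_leaflets(mini_vesicle)
        heads = mini_vesicle.coords[mini_vesicle.names == "NC3"]
        hr = np.linalg.norm(heads - center, axis=1)
        n_out = mini_vesicle.provenance["n_out"]
        oracle = np.zeros(len(hr), dtype=bool)
        oracle[np.argsort(-hr)[:n_out]] = True
        assert np.array_equal(outer, oracle)

    def test_too_few_lipids_rejected(self):
        with pytest.raises(ConsistencyError):
            ta.vesicle_apl(_two_molecule_system(0.5))


class TestMsd:
    def test_static_trajectory_gives_zero(self):
        traj = random_walk_trajectory(50, 20, 0.0, 1.0, seed=1)
        res = ta.msd_and_diffusion(traj, np.ones(50, bool), d_fit=6)
        assert np.allclose(res.msd, 0.0, atol=1e-12)
        assert res.D == pytest.approx(0.0, abs=1e-12)

    def test_brownian_diffusion_recovered(self):
        """Gaussian random walk: fitted D equals sigma^2/(2 dt) within 5 %."""
        sigma2, dt = 0.01, 1.0
        traj = random_walk_trajectory(1000, 1000, sigma2, dt, seed=2)
        res = ta.msd_and_diffusion(traj, np.ones(1000, bool), d_fit=6)
        expected = sigma2 / (2.0 * dt) * 1.0e3  # 1e-5 cm^2/s
        assert res.D == pytest.approx(expected, rel=0.05)

    def test_time_origin_invariance(self):
        traj = random_walk_trajectory(100, 200, 0.02, 1.0, seed=3)
        shifted = vk.TrajectorySlice.from_coords(
            traj.topology,
            np.array([fr.coords for fr in traj]),
            np.array([fr.time + 500.0 for fr in traj]))
        a = ta.msd_and_diffusion(traj, np.ones(100, bool), d_fit=6)
        b = ta.msd_and_diffusion(shifted, np.ones(100, bool), d_fit=6)
        assert a.D == pytest.approx(b.D, rel=1e-12)

    def test_short_fit_window_rejected(self):
        traj = random_walk_trajectory(10, 50, 0.01, 1.0, seed=4)
        with pytest.raises(DomainError):
            ta.msd_and_diffusion(traj, np.ones(10, bool),
                                 fit_window=(10.0, 10.5))


def _random_charged_system(seed, n=50):
    rng = np.random.default_rng(seed)
    return vk.ParticleSystem(
        names=np.full(n, "X"), types=rng.choice(["P4", "C1", "Qa", "Q0"], n),
        charges=rng.choice([0.0, 0.0, 1.0, -1.0], n),
        mol_ids=np.arange(n), species=np.full(n, "W"),
        groups=rng.choice([vk.BILAYER, vk.OUTER_WATER], n),
        coords=rng.uniform(0.0, 4.0, (n, 3)), box=np.array([4.0, 4.0, 4.0]))


def _brute_energy(system, ga, gb, params):
    ia = np.flatnonzero(system.groups == ga)
    ib = np.flatnonzero(system.groups == gb)
    lj = co = 0.0
    seen = set()
    for i in ia:
        for j in ib:
            if system.mol_ids[i] == system.mol_ids[j]:
                continue
            key = (min(i, j), max(i, j))
            if ga == gb:
                if key in seen:
                    continue
                seen.add(key)
            d = system.coords[i] - system.coords[j]
            d -= system.box * np.round(d / system.box)
            r = float(np.linalg.norm(d))
            if r >= params.r_c:
                continue
            sig, eps = lm.lookup_nonbonded(system.types[i], system.types[j],
                                           params)
            v = lambda rr: 4 * eps * ((sig / rr) ** 12 - (sig / rr) ** 6)
            lj += v(r) - v(params.r_c)
            co += (ta.COULOMB_CONSTANT * system.charges[i] * system.charges[j]
                   / params.eps_r * (1 / r - 1 / params.r_c))
    return lj, co


class TestGroupEnergy:
    def test_beyond_cutoff_is_zero(self):
        params = lm.default_nonbonded()
        r = params.r_c + 0.01
        s = vk.ParticleSystem(
            names=["W", "W"], types=["C1", "C1"], charges=[0.0, 0.0],
            mol_ids=[0, 1], species=["W", "W"],
            groups=[vk.BILAYER, vk.OUTER_WATER],
            coords=[[1.0, 1.0, 1.0], [1.0 + r, 1.0, 1.0]],
            box=[10.0, 10.0, 10.0])
        e = ta.group_interaction_energy(s, vk.BILAYER, vk.OUTER_WATER, params)
        assert (e.lj, e.coulomb) == (0.0, 0.0)

    def test_matches_brute_force_cross_and_intra(self):
        params = lm.default_nonbonded()
        for seed in (0, 1):
            s = _random_charged_system(seed)
            for ga, gb in [(vk.BILAYER, vk.OUTER_WATER),
                           (vk.BILAYER, vk.BILAYER)]:
                e = ta.group_interaction_energy(s, ga, gb, params)
                blj, bco = _brute_energy(s, ga, gb, params)
                assert e.lj == pytest.approx(blj, rel=1e-9)
                assert e.coulomb == pytest.approx(bco, rel=1e-9, abs=1e-12)

    def test_symmetric_in_group_order(self):
        params = lm.default_nonbonded()
        s = _random_charged_system(7)
        a = ta.group_interaction_energy(s, vk.BILAYER, vk.OUTER_WATER, params)
        b = ta.group_interaction_energy(s, vk.OUTER_WATER, vk.BILAYER, params)
        assert (a.lj, a.coulomb) == (b.lj, b.coulomb)

    def test_lipid_water_coulomb_exactly_zero(self, mini_vesicle):
        """Water beads are uncharged, so lipid-water electrostatics vanish."""
        for water_group in (vk.INNER_WATER, vk.OUTER_WATER):
            e = ta.group_interaction_energy(mini_vesicle, vk.BILAYER,
                                            water_group)
            assert e.coulomb == 0.0
            assert e.lj != 0.0

    def test_overlapping_distinct_groups_rejected(self):
        s = _random_charged_system(3)
        mask = s.group_mask(vk.BILAYER)
        mask_b = mask.copy()
        mask_b[np.flatnonzero(~mask)[0]] = True  # superset of group A
        with pytest.raises(ConsistencyError):
            ta.group_interaction_energy(s, mask, mask_b)

    def test_coincident_beads_rejected(self):
        s = vk.ParticleSystem(
            names=["W", "W"], types=["C1", "C1"], charges=[0.0, 0.0],
            mol_ids=[0, 1], species=["W", "W"],
            groups=[vk.BILAYER, vk.OUTER_WATER],
            coords=[[1.0, 1.0, 1.0], [1.0, 1.0, 1.0]], box=[5.0, 5.0, 5.0])
        with pytest.raises(SingularGeometryError):
            ta.group_interaction_energy(s, vk.BILAYER, vk.OUTER_WATER)


def _single_lipid_system(coords, species="DOPC"):
    t = lm.get_template(species)
    return vk.ParticleSystem(
        names=[b.name for b in t.beads], types=[b.type for b in t.beads],
        charges=[b.charge for b in t.beads], mol_ids=[0] * 12,
        species=[species] * 12, groups=[vk.BILAYER] * 12,
        coords=coords, box=[50.0, 50.0, 50.0])


class TestKinkAngles:
    def test_collinear_and_equilateral_geometry(self):
        coords = np.tile(np.arange(12, dtype=float)[:, None], (1, 3)) + 10.0
        # beads 6,7,8 and 10,11,12 collinear along the diagonal -> 180 deg
        res = ta.kink_angles(_single_lipid_system(coords))
        assert res.mean == pytest.approx(180.0, abs=1e-6)
        coords2 = coords.copy()
        # make (6,7,8) and (10,11,12) equilateral triangles -> 60 deg
        for (i, j, k) in ((6, 7, 8), (10, 11, 12)):
            coords2[i - 1] = [0.0, 0.0, 0.0]
            coords2[j - 1] = [1.0, 0.0, 0.0]
            coords2[k - 1] = [0.5, math.sqrt(3) / 2, 0.0]
        coords2 += 20.0
        res2 = ta.kink_angles(_single_lipid_system(coords2))
        assert res2.mean == pytest.approx(60.0, abs=1e-6)

    def test_boltzmann_chains_match_quadrature(self):
        """Sampled kink angles agree with the Boltzmann average within 3 SE."""
        t = lm.get_template("DOPC")
        chains = boltzmann_chain_samples(t, 390.0, 3000, seed=6)
        res = ta.kink_angles(chains)
        expected = lm.equilibrium_angle_mean(120.0, 45.0, 390.0)
        se = res.std / math.sqrt(res.n)
        assert abs(res.mean - expected) < 3 * se
        assert not res.saturated_only

    def test_saturated_species_flagged(self):
        t = lm.get_template("DPPC")
        chains = boltzmann_chain_samples(t, 390.0, 200, seed=7)
        res = ta.kink_angles(chains)
        assert res.saturated_only

    def test_zero_length_bond_rejected(self):
        coords = np.full((12, 3), 5.0)
        with pytest.raises(SingularGeometryError):
            ta.kink_angles(_single_lipid_system(coords))


class TestEndToEnd:
    def test_coincident_end_beads(self):
        coords = np.tile(np.arange(12, dtype=float)[:, None], (1, 3)) + 10.0
        coords[11] = coords[7]
        res = ta.end_to_end(_single_lipid_system(coords))
        assert res.mean == 0.0

    def test_straight_build_equals_tail_offset(self, mini_vesicle):
        """Pre-minimisation chains are parallel: |r8 - r12| is the builder's
        0.25 nm lateral tail offset for every lipid."""
        res = ta.end_to_end(mini_vesicle, "DPPC")
        assert res.mean == pytest.approx(0.25, abs=1e-9)
        assert res.std == pytest.approx(0.0, abs=1e-9)

    def test_matches_direct_average_on_chains(self):
        t = lm.get_template("DOPC")
        chains = boltzmann_chain_samples(t, 390.0, 1500, seed=8)
        res = ta.end_to_end(chains)
        coords = chains.coords.reshape(-1, 12, 3)
        direct = np.linalg.norm(coords[:, 7] - coords[:, 11], axis=1)
        assert res.mean == pytest.approx(direct.mean(), rel=1e-12)
        assert abs(res.mean - direct.mean()) < 3 * direct.std() / math.sqrt(len(direct))


class TestDetectPores:
    def test_pristine_vesicle_has_none(self, mini_vesicle):
        assert ta.detect_pores(mini_vesicle).n_pores == 0

    @pytest.mark.parametrize("alpha", [0.35, 0.5, 0.7])
    def test_punched_hole_diameter(self, mini_vesicle, alpha):
        """A cap of half-angle alpha reads back as one pore of diameter
        2 R alpha within 20 %."""
        holed = punch_hole(mini_vesicle, (0.0, 0.0, 1.0), alpha)
        rep = ta.detect_pores(holed)
        assert rep.n_pores == 1
        expected = 2.0 * rep.r_mid * alpha
        assert rep.pores[0].diameter == pytest.approx(expected, rel=0.2)
        assert rep.pores[0].direction[2] > 0.95

    def test_antipodal_holes(self, mini_vesicle):
        holed = punch_hole(punch_hole(mini_vesicle, (0, 0, 1), 0.45),
                           (0, 0, -1), 0.45)
        rep = ta.detect_pores(holed)
        assert rep.n_pores == 2
        d1, d2 = rep.pores[0].direction, rep.pores[1].direction
        assert float(d1 @ d2) == pytest.approx(-1.0, abs=0.02)

    def test_coarse_resolution_rejected(self, mini_vesicle):
        with pytest.raises(ResolutionError):
            ta.detect_pores(mini_vesicle, resolution=5.0)
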