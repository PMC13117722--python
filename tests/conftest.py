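import numpy as np
import pytest

import vesikit as vk


@pytest.fixture(scope="session")
def mini_spec():
    """A 10 nm vesicle in a 16 nm box, solvent lattice filled to capacity."""
    return vk.VesicleSpec(outer_diameter=10.0, box_edge=16.0,
                          n_water_in=None, n_water_out=None, seed=1)


@pytest.fixture(scope="session")
def mini_vesicle(mini_spec):
    return vk.build_vesicle(mini_spec)


@pytest.fixture(scope="session")
def tiny_vesicle():
    """A few hundred beads, small enough for O(N^2) brute-force checks."""
    spec = vk.VesicleSpec(outer_diameter=10.0, box_edge=16.0, n_out=24,
                          n_in=16, n_water_in=30, n_water_out=80, seed=3)
    return spec, vk.build_vesicle(spec)


@pytest.fixture(scope="session")
def default_build():
    """The packaged reference configuration: 30 nm DPPC vesicle, 40 nm box."""
    spec = vk.VesicleSpec(seed=11)
    return spec, vk.build_vesicle(spec)


@pytest.fixture()
def toy_molecules():
    """Ten 3-bead molecules at random positions for RDF/energy oracles."""
    rng = np.random.default_rng(42)
    n_mol, n_b = 10, 3
    coords = rng.uniform(0.0, 6.0, (n_mol, n_b, 3))
    return coords, vk.ParticleSystem(
        names=np.tile(["A", "B", "C"], n_mol),
        types=np.full(n_mol * n_b, "C1"),
        charges=np.zeros(n_mol * n_b),
        mol_ids=np.repeat(np.arange(n_mol), n_b),
        species=np.full(n_mol * n_b, "DPPC"),
        groups=np.full(n_mol * n_b, vk.BILAYER),
        coords=coords.reshape(-1, 3),
        box=np.array([6.0, 6.0, 6.0]),
    )
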