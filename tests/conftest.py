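import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import tailgate as tg

settings.register_profile(
    "suite", deadline=None, derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")


@pytest.fixture(scope="session")
def geometry():
    return tg.GeometryParams()


@pytest.fixture(scope="session")
def forcefield():
    return tg.ForceFieldParams()


@pytest.fixture(scope="session")
def full_bundle(geometry):
    return tg.make_translocation_system(geometry, include_tail=True, seed=0)


@pytest.fixture(scope="session")
def truncated_bundle(geometry):
    return tg.make_translocation_system(geometry, include_tail=False, seed=0)


@pytest.fixture(scope="session")
def full_system(full_bundle, forcefield):
    return tg.translocation_potential(full_bundle, forcefield, 0.38)


@pytest.fixture(scope="session")
def small_experiment_config():
    """A scaled-down experiment that runs in seconds."""
    return tg.ExperimentConfig(
        geometry=tg.GeometryParams(corridor_length=2.0,
                                   bottleneck_position=1.7,
                                   pocket_depth=1.2,
                                   ligand_beads=6, tail_residues=5),
        n_events=2, max_steps=6_000, equil_steps=400, segment_steps=2_000,
        n_bootstrap=500,
    )


def random_structure(rng: np.random.Generator, n_atoms: int = 50,
                     n_chains: int = 3, box: float = 2.0) -> tg.Structure:
    """A random multi-chain bead structure for oracle tests."""
    chain_lengths = rng.multinomial(
        n_atoms - n_chains, np.full(n_chains, 1.0 / n_chains)) + 1
    chains, res_idx = [], []
    for c, ln in enumerate(chain_lengths):
        chains.extend([chr(ord("A") + c)] * ln)
        res_idx.extend(range(1, ln + 1))
    n = len(chains)
    return tg.Structure(
        atom_id=np.arange(1, n + 1),
        atom_name=np.array(["CA"] * n),
        residue_index=np.array(res_idx),
        residue_name=np.array(["GLY"] * n),
        chain_id=np.array(chains),
        coords=box * rng.random((n, 3)),
        mobile=rng.random(n) < 0.8,
    ).validate()
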