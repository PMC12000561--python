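import numpy as np
import pytest

from allodyn.io import Atom, Topology
from allodyn.network import assign_nodes
from allodyn.synth import make_toy_complex

#: five-node allosteric chain from the cofactor to the abasic base node,
#: through non-adjacent protein residues
CHAIN = ["C:1:SF4", "A:5:THR", "A:7:ALA", "A:9:SER", "B:2:DT:base"]
CHAIN_CONTACTS = tuple((CHAIN[i], CHAIN[i + 1]) for i in range(len(CHAIN) - 1))
#: decoy two-hop route between the same endpoints at background correlation
DECOY_CONTACTS = (("C:1:SF4", "A:2:GLY"), ("A:2:GLY", "B:2:DT:base"))


@pytest.fixture(scope="session")
def toy():
    """Standard 10-residue / 4-nucleotide / cofactor complex."""
    return make_toy_complex(10, 4, include_cofactor=True, seed=1)


@pytest.fixture(scope="session")
def toy_nodes(toy):
    topology, reference = toy
    return assign_nodes(topology, reference)


@pytest.fixture(scope="session")
def chain_toy():
    """Complex with the planted chain and decoy route in contact."""
    return make_toy_complex(
        10, 4, include_cofactor=True, seed=1,
        close_pairs=CHAIN_CONTACTS + DECOY_CONTACTS,
        abasic_nucleotides=(2,),
    )


def random_toy_topology(rng: np.random.Generator, n_atoms: int) -> Topology:
    """Random small topology with random charges/LJ and a random tree of
    bonds plus extra edges — for oracle comparisons."""
    atoms = []
    for i in range(n_atoms):
        atoms.append(Atom(
            atom_index=i,
            atom_name=f"X{i}",
            element="C",
            residue_index=1 + i // 3,
            residue_name="RND",
            chain_id="A",
            residue_kind="protein",
            partial_charge=float(rng.uniform(-1, 1)),
            lj_sigma=float(rng.uniform(2.5, 4.0)),
            lj_epsilon=float(rng.uniform(0.0, 0.3)),
        ))
    bonds = set()
    for i in range(1, n_atoms):
        bonds.add(frozenset((i, int(rng.integers(0, i)))))
    for _ in range(n_atoms // 3):
        i, j = rng.integers(0, n_atoms, 2)
        if i != j:
            bonds.add(frozenset((int(i), int(j))))
    return Topology(atoms=atoms, bonds=bonds)


def random_coordinates(rng: np.random.Generator, n_frames: int,
                       n_atoms: int) -> np.ndarray:
    """Random coordinates with all pairs safely separated."""
    while True:
        xyz = rng.uniform(0, 12, size=(n_frames, n_atoms, 3))
        d = xyz[:, :, None, :] - xyz[:, None, :, :]
        r = np.sqrt((d**2).sum(axis=3))
        r[:, range(n_atoms), range(n_atoms)] = np.inf
        if r.min() > 0.8:
            return xyz
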