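"""Shared fixtures: all inputs are generated programmatically at test time."""

import numpy as np
import pytest

from sranet.model_io import (Atom, RoleTable, Topology, Trajectory,
                             annotate_chemistry)
from sranet.synthetic import (HelixSpec, PlantSpec, PlantedInteraction,
                              generate_bdna, make_protein_dna_complex)


def make_atom(serial, name, resid, resname, chain="A", element=None):
    if element is None:
        element = name.lstrip("0123456789'")[0]
    return Atom(serial=serial, name=name, element=element,
                residue_index=resid, residue_name=resname, chain_id=chain)


@pytest.fixture(scope="session")
def bdna_14():
    spec = HelixSpec(sequence="ACGTACGTACGTAC")
    topology, coords = generate_bdna(spec)
    return spec, topology, coords


@pytest.fixture(scope="session")
def protein_dna():
    topology, coords = make_protein_dna_complex(n_bp=8)
    return topology, coords


@pytest.fixture(scope="session")
def planted_spec():
    """The four-occupancy plant used across contact/network tests."""
    return PlantSpec(interactions=[
        PlantedInteraction("hbond", count=1, occupancy=1.0),
        PlantedInteraction("hbond", count=2, occupancy=0.42),
        PlantedInteraction("saltbridge", count=2, occupancy=0.12),
        PlantedInteraction("saltbridge", count=1, occupancy=0.08),
    ], n_frames=100, seed=3)


@pytest.fixture(scope="session")
def random_contact_system():
    """A ~40-atom mixed system with donors, acceptors and charged groups for
    detector-vs-oracle comparisons on random coordinates."""
    atoms = []
    bonds = set()
    serial = 1
    resid = 1

    def add(name, resname, chain):
        nonlocal serial
        atoms.append(make_atom(serial, name, resid, resname, chain))
        serial += 1
        return len(atoms) - 1

    for _ in range(4):                       # serine-like donors
        i_o = add("OG", "SER", "P")
        i_h = add("HG", "SER", "P")
        bonds.add(frozenset((i_o, i_h)))
        resid += 1
    for _ in range(2):                       # arginine head groups (+)
        add("NE", "ARG", "P"); add("NH1", "ARG", "P"); add("NH2", "ARG", "P")
        resid += 1
    for _ in range(2):                       # glutamate carboxylates (-)
        add("OE1", "GLU", "P"); add("OE2", "GLU", "P")
        resid += 1
    for _ in range(2):                       # nucleotides: phosphate + O2/N4
        add("OP1", "DC", "D"); add("OP2", "DC", "D")
        add("O2", "DC", "D"); add("N3", "DC", "D")
        resid += 1
    while len(atoms) < 40:                   # apolar filler
        add("CB", "ALA", "P")
        resid += 1

    topology = Topology(atoms=atoms, bonds=bonds)
    hof = np.full(len(atoms), -1, dtype=int)
    for b in bonds:
        i, j = sorted(b)
        if atoms[j].element == "H":
            hof[j] = i
        elif atoms[i].element == "H":
            hof[i] = j
    topology.hydrogen_of = hof
    annotate_chemistry(topology, RoleTable.default())
    return topology


def random_frames(n_frames, n_atoms, box=12.0, seed=0):
    rng = np.random.default_rng(seed)
    return rng.uniform(0.0, box, size=(n_frames, n_atoms, 3))


def static_trajectory(topology, coords, n_frames=5):
    return Trajectory(topology=topology,
                      coords=np.repeat(np.asarray(coords)[None], n_frames, 0),
                      frame_times=np.arange(float(n_frames)))
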