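"""Topology loading, chemical annotation and the selection grammar."""

import numpy as np
import pytest

from sranet.model_io import (PDBParseError, SelectionError, Topology,
                             annotate_chemistry, load_topology,
                             load_trajectory, resolve_selection, write_pdb)
from sranet.model_io import _COVALENT_RADII, _DEFAULT_RADIUS

from conftest import make_atom


def build_topology(atom_specs, bonds=(), coords=None):
    atoms = [make_atom(i + 1, *spec) for i, spec in enumerate(atom_specs)]
    top = Topology(atoms=atoms, bonds={frozenset(b) for b in bonds},
                   reference_coords=None if coords is None
                   else np.asarray(coords, dtype=float))
    return top


class TestLoadTopology:
    def test_water_bonds_from_distance(self, tmp_path):
        """O with two H at 0.96 Å: the distance rule finds both O-H bonds
        and assigns each hydrogen to the oxygen."""
        pdb = tmp_path / "water.pdb"
        pdb.write_text(
            "ATOM      1  O   HOH A   1       0.000   0.000   0.000"
            "  1.00  0.00           O\n"
            "ATOM      2  H1  HOH A   1       0.960   0.000   0.000"
            "  1.00  0.00           H\n"
            "ATOM      3  H2  HOH A   1      -0.240   0.930   0.000"
            "  1.00  0.00           H\nEND\n")
        top = load_topology(pdb, bond_source="distance")
        assert len(top.bonds) == 2
        assert top.hydrogen_of[1] == 0 and top.hydrogen_of[2] == 0

    def test_conect_bonds_identical_and_roundtrip(self, tmp_path):
        """Bonds equal the CONECT set exactly; writing and reloading the
        topology reproduces atoms, residues and bonds."""
        top = build_topology(
            [("OG", 1, "SER"), ("HG", 1, "SER"), ("CB", 1, "SER")],
            bonds=[(0, 1), (0, 2)],
            coords=[[0, 0, 0], [0.96, 0, 0], [-1.4, 0, 0]])
        path = tmp_path / "frag.pdb"
        write_pdb(top, top.reference_coords, path)
        reloaded = load_topology(path, bond_source="CONECT")
        assert reloaded.bonds == top.bonds
        assert [(a.name, a.residue_index, a.residue_name, a.chain_id)
                for a in reloaded.atoms] == \
               [(a.name, a.residue_index, a.residue_name, a.chain_id)
                for a in top.atoms]
        assert np.allclose(reloaded.reference_coords, top.reference_coords,
                           atol=1e-3)

    def test_distance_rule_matches_allpairs_oracle(self, tmp_path):
        """On a random 50-atom fragment, the distance rule equals a
        brute-force all-pairs covalent-radius check."""
        rng = np.random.default_rng(42)
        elements = rng.choice(["C", "N", "O", "H", "P"], size=50)
        coords = rng.uniform(0, 8, size=(50, 3))
        specs = [(f"{el}{i + 1}", i + 1, "UNK") for i, el in enumerate(elements)]
        atoms = [make_atom(i + 1, name, resid, resname, element=elements[i])
                 for i, (name, resid, resname) in enumerate(specs)]
        # drop hydrogens that would end up orphaned (no heavy atom in range)
        keep = []
        for i, el in enumerate(elements):
            if el != "H":
                keep.append(i)
                continue
            for j, el2 in enumerate(elements):
                if el2 != "H" and np.linalg.norm(coords[i] - coords[j]) <= 1.3:
                    keep.append(i)
                    break
        atoms = [atoms[i] for i in keep]
        coords = coords[keep]
        top = Topology(atoms=atoms, reference_coords=coords)
        path = tmp_path / "rand.pdb"
        write_pdb(top, coords, path, write_conect=False)
        loaded = load_topology(path, bond_source="distance")

        oracle = set()
        for i in range(len(atoms)):
            for j in range(i + 1, len(atoms)):
                ri = _COVALENT_RADII.get(atoms[i].element.upper(), _DEFAULT_RADIUS)
                rj = _COVALENT_RADII.get(atoms[j].element.upper(), _DEFAULT_RADIUS)
                d = float(np.linalg.norm(loaded.reference_coords[i]
                                         - loaded.reference_coords[j]))
                if d < 1.2 * (ri + rj):
                    oracle.add(frozenset((i, j)))
        assert loaded.bonds == oracle

    def test_malformed_atom_record_reports_line(self, tmp_path):
        pdb = tmp_path / "bad.pdb"
        pdb.write_text("ATOM      1  O   HOH A   1  garbage\n")
        with pytest.raises(PDBParseError, match="line 1"):
            load_topology(pdb)

    def test_orphan_hydrogen_names_the_atom(self, tmp_path):
        pdb = tmp_path / "orphan.pdb"
        pdb.write_text(
            "ATOM      1  O   HOH A   1       0.000   0.000   0.000"
            "  1.00  0.00           O\n"
            "ATOM      2  H1  HOH A   1       9.000   0.000   0.000"
            "  1.00  0.00           H\nEND\n")
        from sranet.model_io import AnnotationError
        with pytest.raises(AnnotationError, match="H1"):
            load_topology(pdb, bond_source="distance")

    def test_dcd_roundtrip(self, tmp_path, protein_dna):
        """Frames written as binary DCD read back to float32 precision."""
        from sranet.model_io import Trajectory, write_dcd

        top, coords = protein_dna
        traj = Trajectory(topology=top,
                          coords=np.stack([coords, coords + 1.5]),
                          frame_times=np.arange(2.0))
        path = tmp_path / "t.dcd"
        write_dcd(traj, path)
        back = load_trajectory(top, path)
        assert back.n_frames == 2
        assert np.abs(back.coords - traj.coords).max() < 1e-4

    def test_multimodel_pdb_loads_as_trajectory(self, tmp_path, protein_dna):
        top, coords = protein_dna
        frames = np.stack([coords, coords + 1.0, coords + 2.0])
        path = tmp_path / "traj.pdb"
        write_pdb(top, frames, path)
        traj = load_trajectory(path)
        assert traj.n_frames == 3
        assert np.allclose(traj.coords[2] - traj.coords[0], 2.0, atol=1e-3)


class TestAnnotateChemistry:
    def test_lysine_single_atom_positive_group(self):
        top = build_topology(
            [("NZ", 1, "LYS"), ("HZ1", 1, "LYS"), ("CB", 1, "LYS")],
            bonds=[(0, 1)])
        annotate_chemistry(top)
        assert top.charge_group[0] == (0, +1)
        assert top.charge_group[1] is None and top.charge_group[2] is None

    def test_carboxylcytosine_groups_and_roles(self):
        """caC: negative phosphate {OP1,OP2} and carboxyl {O51,O52} groups,
        O2 acceptor, N4 donor."""
        names = ["OP1", "OP2", "O51", "O52", "O2", "N4", "H41", "N3"]
        top = build_topology([(n, 1, "DCZ") for n in names],
                             bonds=[(5, 6)])
        annotate_chemistry(top)
        groups = {}
        for i, g in enumerate(top.charge_group):
            if g is not None:
                groups.setdefault(g[0], []).append((top.atoms[i].name, g[1]))
        signed = {frozenset(n for n, _ in v): v[0][1] for v in groups.values()}
        assert signed == {frozenset({"OP1", "OP2"}): -1,
                          frozenset({"O51", "O52"}): -1}
        assert top.acceptor[4]          # O2
        assert top.donor_heavy[5]       # N4 bearing H41
        assert top.acceptor[7]          # ring N3, no H

    def test_glycine_backbone_roles_no_charge(self):
        top = build_topology(
            [("N", 1, "GLY"), ("H", 1, "GLY"), ("CA", 1, "GLY"),
             ("C", 1, "GLY"), ("O", 1, "GLY")],
            bonds=[(0, 1), (0, 2), (2, 3), (3, 4)])
        annotate_chemistry(top)
        assert all(g is None for g in top.charge_group)
        assert top.donor_heavy[0] and top.acceptor[4]
        assert not top.donor_heavy[4]

    def test_unknown_residue_goes_to_skip_report(self):
        top = build_topology([("C1", 1, "XYZ"), ("NZ", 2, "LYS"),
                              ("HZ1", 2, "LYS")], bonds=[(1, 2)])
        annotate_chemistry(top)
        assert top.skipped_residues == ["XYZ1"]
        assert top.charge_group[1] == (0, +1)

    def test_idempotent(self, random_contact_system):
        top = random_contact_system
        donor = top.donor_heavy.copy()
        acceptor = top.acceptor.copy()
        groups = list(top.charge_group)
        annotate_chemistry(top)
        assert np.array_equal(top.donor_heavy, donor)
        assert np.array_equal(top.acceptor, acceptor)
        assert top.charge_group == groups


class TestSelectionGrammar:
    @pytest.fixture(scope="class")
    def protein_155(self):
        specs = []
        for resid in range(432, 587):
            specs.append(("N", resid, "ALA"))
            specs.append(("CA", resid, "ALA"))
        return build_topology(specs)

    def test_ca_range_returns_one_atom_per_residue(self, protein_155):
        sel = resolve_selection(protein_155,
                                "protein and name CA and resid 432-586")
        assert len(sel) == 155
        assert all(protein_155.atoms[i].name == "CA" for i in sel.resolved)

    def test_empty_range_is_empty(self, protein_155):
        assert len(resolve_selection(protein_155, "resid 1-0")) == 0

    def test_not_is_complement(self, protein_155):
        a = resolve_selection(protein_155, "resid 432-441")
        b = resolve_selection(protein_155, "not (resid 432-441)")
        union = set(a.resolved) | set(b.resolved)
        assert union == set(range(protein_155.n_atoms))
        assert not set(a.resolved) & set(b.resolved)

    @pytest.mark.parametrize("expression", [
        "protein", "name CA", "resid 432-500", "element N",
        "protein and not name CA", "nucleic or chain A",
    ])
    def test_complement_partition_property(self, protein_155, expression):
        """resolve(A) and resolve(not A) partition the atom set."""
        a = set(resolve_selection(protein_155, expression).resolved)
        b = set(resolve_selection(protein_155, f"not ({expression})").resolved)
        assert a | b == set(range(protein_155.n_atoms))
        assert not a & b

    def test_order_preserved_and_deterministic(self, protein_155):
        sel = resolve_selection(protein_155, "name CA or name N")
        assert list(sel.resolved) == sorted(sel.resolved)
        again = resolve_selection(protein_155, "name CA or name N")
        assert np.array_equal(sel.resolved, again.resolved)

    def test_syntax_error_reports_position(self, protein_155):
        with pytest.raises(SelectionError) as err:
            resolve_selection(protein_155, "resid 1-2 bogus 3")
        assert err.value.position == 10
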