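"""Topology and trajectory I/O, atom selections and chemical-role annotation.

This module owns the in-memory model every downstream analysis consumes:

* :class:`Topology` — atoms, residues, covalent bonds and per-atom chemical
  annotations (hydrogen-bond donors/acceptors, formal-charge groups);
* :class:`Trajectory` — an ordered stack of coordinate frames bound to a
  topology, carrying replica identity and frame times;
* :class:`Selection` — a deterministic, order-preserving atom selection
  resolved from a small expression grammar
  (``"protein and name CA and resid 432-586"``).

PDB reading/writing handles ATOM/HETATM, CONECT and MODEL/ENDMDL records
directly so that parse errors carry line numbers and CONECT bond sets
round-trip exactly.  Binary DCD trajectories are read and written through
MDAnalysis.

Residue numbering is never rewritten on load: selections and reports use the
author numbering of the input file, so residues keep their published
identities (e.g. the reader-domain range 432-586).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "Atom",
    "Topology",
    "Trajectory",
    "Selection",
    "RoleTable",
    "PDBParseError",
    "AnnotationError",
    "SelectionError",
    "load_topology",
    "load_trajectory",
    "write_pdb",
    "write_dcd",
    "annotate_chemistry",
    "resolve_selection",
]

# ---------------------------------------------------------------------------
# residue classification and element tables
# ---------------------------------------------------------------------------

PROTEIN_RESNAMES = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "HID",
    "HIE", "HIP", "ILE", "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR",
    "TRP", "TYR", "VAL",
}

#: Standard nucleotides plus the modified-cytosine residue names this package
#: uses for 5-methyl- and 5-carboxylcytosine.  Extendable via
#: :func:`register_nucleic_resname`.
NUCLEIC_RESNAMES = {
    "DA", "DC", "DG", "DT", "DU", "A", "C", "G", "U", "T",
    "DA3", "DA5", "DC3", "DC5", "DG3", "DG5", "DT3", "DT5",
    "DCM", "DCZ", "5CM", "5CA", "CAC",
}


def register_nucleic_resname(name: str) -> None:
    """Teach the ``nucleic`` selection keyword an extra residue name."""
    NUCLEIC_RESNAMES.add(name.upper())


# covalent radii (Å) for the distance bond rule; generous default for exotics
_COVALENT_RADII = {
    "H": 0.31, "C": 0.76, "N": 0.71, "O": 0.66, "P": 1.07, "S": 1.05,
    "F": 0.57, "CL": 1.02, "BR": 1.20, "I": 1.39, "NA": 1.66, "MG": 1.41,
    "K": 2.03, "CA": 1.76, "ZN": 1.22, "FE": 1.32, "MN": 1.39,
}
_DEFAULT_RADIUS = 1.5

_TWO_LETTER_ELEMENTS = {"CL", "BR", "NA", "MG", "ZN", "FE", "MN"}


def element_from_name(name: str, resname: str = "") -> str:
    """Derive the element from a PDB atom name (standard nomenclature).

    Digits are stripped from the front (``1H5'`` → H); two-letter elements
    are only recognised for monoatomic ions, never inside residues, so DNA
    ``CA``/protein ``CA`` stay carbon/alpha-carbon.
    """
    stripped = name.strip().lstrip("0123456789'")
    if not stripped:
        raise ValueError(f"cannot derive element from atom name {name!r}")
    upper = stripped.upper()
    if upper in _TWO_LETTER_ELEMENTS and resname.strip().upper() == upper:
        return upper.capitalize()
    return upper[0]


# ---------------------------------------------------------------------------
# errors
# ---------------------------------------------------------------------------

class PDBParseError(ValueError):
    """Malformed PDB record; carries the offending 1-based line number."""

    def __init__(self, message: str, line_number: int):
        super().__init__(f"line {line_number}: {message}")
        self.line_number = line_number


class AnnotationError(ValueError):
    """Chemical-role annotation failed (e.g. orphan hydrogen)."""


class SelectionError(ValueError):
    """Selection expression is malformed; carries the token position."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at position {position})")
        self.position = position


# ---------------------------------------------------------------------------
# core types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Atom:
    """A single atom of the topology.

    ``residue_index`` is the author residue number from the source file;
    (residue_index, chain_id, name) is unique within a topology.
    """

    serial: int
    name: str
    element: str
    residue_index: int
    residue_name: str
    chain_id: str

    @property
    def residue_key(self) -> tuple[str, int]:
        return (self.chain_id, self.residue_index)


@dataclass
class Residue:
    """An ordered group of atom indices sharing one residue identity."""

    name: str
    index: int            # author numbering
    chain_id: str
    atom_indices: list[int]

    @property
    def key(self) -> tuple[str, int]:
        return (self.chain_id, self.index)

    def atom_index(self, topology: "Topology", atom_name: str) -> int | None:
        for i in self.atom_indices:
            if topology.atoms[i].name == atom_name:
                return i
        return None


@dataclass
class Topology:
    """Atoms, bonds, residues and chemical annotations.

    Annotations are filled by :func:`annotate_chemistry`:

    ``donor_heavy``
        boolean per atom — N/O heavy atom bearing at least one bonded H.
    ``acceptor``
        boolean per atom — N/O with an available lone pair per the role table.
    ``hydrogen_of``
        per atom, index of the bonded heavy atom for hydrogens, else -1.
    ``charge_group``
        per atom, (group_id, sign) or None; every group has uniform sign.
    """

    atoms: list[Atom]
    bonds: set[frozenset[int]] = field(default_factory=set)
    reference_coords: np.ndarray | None = None

    donor_heavy: np.ndarray | None = None
    acceptor: np.ndarray | None = None
    hydrogen_of: np.ndarray | None = None
    charge_group: list[tuple[int, int] | None] | None = None
    skipped_residues: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._residues: list[Residue] | None = None

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def residues(self) -> list[Residue]:
        if self._residues is None:
            groups: dict[tuple[str, int], Residue] = {}
            order: list[tuple[str, int]] = []
            for i, atom in enumerate(self.atoms):
                key = atom.residue_key
                if key not in groups:
                    groups[key] = Residue(atom.residue_name, atom.residue_index,
                                          atom.chain_id, [])
                    order.append(key)
                groups[key].atom_indices.append(i)
            self._residues = [groups[k] for k in order]
        return self._residues

    def residue_of(self, atom_index: int) -> Residue:
        atom = self.atoms[atom_index]
        for res in self.residues:
            if res.key == atom.residue_key:
                return res
        raise KeyError(atom_index)

    def bonded_to(self, atom_index: int) -> list[int]:
        out = []
        for bond in self.bonds:
            if atom_index in bond:
                (other,) = bond - {atom_index}
                out.append(other)
        return sorted(out)

    def invalidate_residue_cache(self) -> None:
        self._residues = None

    @property
    def annotated(self) -> bool:
        return self.donor_heavy is not None


@dataclass
class Trajectory:
    """Frames of Cartesian coordinates (Å) bound to a topology.

    ``frame_times`` are in ps and strictly increasing; ``replica_id`` and
    ``system_label`` identify the run the frames came from.
    """

    topology: Topology
    coords: np.ndarray                  # (n_frames, n_atoms, 3)
    frame_times: np.ndarray             # ps
    replica_id: str = "r1"
    system_label: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_frames, n_atoms, 3)")
        if self.coords.shape[1] != self.topology.n_atoms:
            raise ValueError(
                f"frame atom count {self.coords.shape[1]} does not match "
                f"topology ({self.topology.n_atoms} atoms)")
        if len(self.frame_times) != len(self.coords):
            raise ValueError("frame_times length must match frame count")
        if len(self.frame_times) > 1 and not np.all(np.diff(self.frame_times) > 0):
            raise ValueError("frame_times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    def __len__(self) -> int:
        return self.n_frames


@dataclass
class Selection:
    """A resolved atom selection: the expression plus its ordered indices."""

    expression: str
    resolved: np.ndarray               # ordered atom-index array

    def __len__(self) -> int:
        return len(self.resolved)

    def __iter__(self):
        return iter(self.resolved)


# ---------------------------------------------------------------------------
# PDB reading
# ---------------------------------------------------------------------------

def _parse_atom_line(line: str, lineno: int) -> tuple[Atom, np.ndarray]:
    try:
        serial = int(line[6:11])
        name = line[12:16].strip()
        resname = line[17:21].strip()
        chain = line[21].strip() or "A"
        resid = int(line[22:26])
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
    except (ValueError, IndexError) as exc:
        raise PDBParseError(f"malformed ATOM/HETATM record: {exc}", lineno) from None
    element = line[76:78].strip() if len(line) >= 78 else ""
    if not element:
        try:
            element = element_from_name(name, resname)
        except ValueError as exc:
            raise PDBParseError(str(exc), lineno) from None
    element = element.capitalize()
    atom = Atom(serial=serial, name=name, element=element,
                residue_index=resid, residue_name=resname, chain_id=chain)
    return atom, np.array([x, y, z])


def _read_pdb(path: str | Path) -> tuple[list[Atom], list[np.ndarray], set[frozenset[int]]]:
    """Parse ATOM/HETATM/CONECT/MODEL records into atoms, frames and bonds."""
    atoms: list[Atom] = []
    frames: list[list[np.ndarray]] = []
    current: list[np.ndarray] = []
    conect_serials: set[frozenset[int]] = set()
    in_model = False
    first_model_done = False

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            record = line[:6].strip()
            if record in ("ATOM", "HETATM"):
                atom, pos = _parse_atom_line(line, lineno)
                if not first_model_done:
                    atoms.append(atom)
                current.append(pos)
            elif record == "MODEL":
                in_model = True
                if current:
                    frames.append(current)
                    first_model_done = True
                    current = []
            elif record == "ENDMDL":
                frames.append(current)
                first_model_done = True
                current = []
            elif record == "CONECT":
                fields = line.split()[1:]
                try:
                    serials = [int(f) for f in fields]
                except ValueError:
                    raise PDBParseError("malformed CONECT record", lineno) from None
                if serials:
                    origin = serials[0]
                    for partner in serials[1:]:
                        conect_serials.add(frozenset((origin, partner)))
    if current:
        frames.append(current)
    if not atoms:
        raise PDBParseError("no ATOM/HETATM records found", 0)
    for i, frame in enumerate(frames):
        if len(frame) != len(atoms):
            raise PDBParseError(
                f"model {i + 1} has {len(frame)} atoms, expected {len(atoms)}", 0)

    serial_to_index = {}
    for i, atom in enumerate(atoms):
        serial_to_index.setdefault(atom.serial, i)
    bonds: set[frozenset[int]] = set()
    for pair in conect_serials:
        idx = [serial_to_index.get(s) for s in pair]
        if None not in idx and len(set(idx)) == 2:
            bonds.add(frozenset(idx))
    frame_arrays = [np.array(f) for f in frames]
    return atoms, frame_arrays, bonds


def _distance_bonds(atoms: Sequence[Atom], coords: np.ndarray) -> set[frozenset[int]]:
    """Bond two atoms iff their separation < 1.2 x sum of covalent radii."""
    from scipy.spatial import cKDTree

    radii = np.array([
        _COVALENT_RADII.get(a.element.upper(), _DEFAULT_RADIUS) for a in atoms
    ])
    max_cut = 1.2 * 2 * radii.max()
    tree = cKDTree(coords)
    bonds: set[frozenset[int]] = set()
    for i, j in tree.query_pairs(max_cut):
        if np.linalg.norm(coords[i] - coords[j]) < 1.2 * (radii[i] + radii[j]):
            bonds.add(frozenset((i, j)))
    return bonds


def _assign_hydrogen_of(topology: Topology) -> None:
    """Map each H to its bonded heavy atom; orphan H is an annotation error."""
    n = topology.n_atoms
    hydrogen_of = np.full(n, -1, dtype=int)
    coords = topology.reference_coords
    for i, atom in enumerate(topology.atoms):
        if atom.element.upper() != "H":
            continue
        heavy = [j for j in topology.bonded_to(i)
                 if topology.atoms[j].element.upper() != "H"]
        if not heavy and coords is not None:
            # fall back to nearest heavy atom within covalent range
            d = np.linalg.norm(coords - coords[i], axis=1)
            d[i] = np.inf
            for j in np.argsort(d):
                if topology.atoms[j].element.upper() != "H" and d[j] <= 1.3:
                    heavy = [int(j)]
                    break
        if not heavy:
            raise AnnotationError(
                f"hydrogen {atom.name} (serial {atom.serial}, residue "
                f"{atom.residue_name}{atom.residue_index}) has no heavy "
                f"neighbour within 1.3 Å")
        hydrogen_of[i] = heavy[0]
    topology.hydrogen_of = hydrogen_of


def load_topology(path: str | Path, bond_source: str = "CONECT") -> Topology:
    """Read a PDB file into a :class:`Topology`.

    Parameters
    ----------
    path
        PDB file with ATOM/HETATM records; the first MODEL supplies the
        reference coordinates.
    bond_source
        ``"CONECT"`` takes bonds verbatim from CONECT records;
        ``"distance"`` bonds every pair closer than 1.2 x the sum of the
        elements' covalent radii.
    """
    atoms, frames, conect_bonds = _read_pdb(path)
    coords = frames[0]
    if bond_source.upper() == "CONECT":
        bonds = conect_bonds
    elif bond_source == "distance":
        bonds = _distance_bonds(atoms, coords)
    else:
        raise ValueError(f"unknown bond_source {bond_source!r}")
    topology = Topology(atoms=atoms, bonds=bonds, reference_coords=coords)
    _assign_hydrogen_of(topology)
    return topology


def load_trajectory(topology_or_path, path: str | Path | None = None, *,
                    dt_ps: float = 1.0, replica_id: str = "r1",
                    system_label: str = "") -> Trajectory:
    """Load a trajectory from multi-model PDB or DCD.

    ``load_trajectory(pdb_path)`` reads topology and frames from one
    multi-model PDB; ``load_trajectory(topology, dcd_path)`` binds a DCD to an
    existing topology.  Frame times default to a uniform ``dt_ps`` grid.
    """
    if path is None:
        atoms, frames, bonds = _read_pdb(topology_or_path)
        topology = Topology(atoms=atoms, bonds=bonds, reference_coords=frames[0])
        _assign_hydrogen_of(topology)
        coords = np.stack(frames)
    else:
        topology = topology_or_path
        suffix = Path(path).suffix.lower()
        if suffix == ".dcd":
            coords = _read_dcd(path, topology.n_atoms)
        else:
            _, frames, _ = _read_pdb(path)
            coords = np.stack(frames)
        if coords.shape[1] != topology.n_atoms:
            raise ValueError(
                f"trajectory has {coords.shape[1]} atoms, topology has "
                f"{topology.n_atoms}")
    times = np.arange(len(coords), dtype=float) * dt_ps
    return Trajectory(topology=topology, coords=coords, frame_times=times,
                      replica_id=replica_id, system_label=system_label)


def _read_dcd(path: str | Path, n_atoms: int) -> np.ndarray:
    import MDAnalysis.coordinates.DCD as DCD

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        reader = DCD.DCDReader(str(path), n_atoms=n_atoms)
        frames = np.array([ts.positions.copy() for ts in reader])
        reader.close()
    return frames.astype(float)


# ---------------------------------------------------------------------------
# PDB / DCD writing
# ---------------------------------------------------------------------------

def write_pdb(topology: Topology, coords: np.ndarray, path: str | Path,
              write_conect: bool = True) -> None:
    """Write one frame (n_atoms, 3) or many (n_frames, n_atoms, 3) as PDB."""
    coords = np.asarray(coords, dtype=float)
    if coords.ndim == 2:
        coords = coords[None]
    lines: list[str] = []
    multi = coords.shape[0] > 1
    for m, frame in enumerate(coords, start=1):
        if multi:
            lines.append(f"MODEL     {m:4d}")
        for atom, pos in zip(topology.atoms, frame):
            name = atom.name if len(atom.name) == 4 else f" {atom.name:<3s}"
            lines.append(
                f"ATOM  {atom.serial:5d} {name:<4s} {atom.residue_name:<4s}"
                f"{atom.chain_id:1s}{atom.residue_index:4d}    "
                f"{pos[0]:8.3f}{pos[1]:8.3f}{pos[2]:8.3f}"
                f"{1.00:6.2f}{0.00:6.2f}          {atom.element.upper():>2s}")
        if multi:
            lines.append("ENDMDL")
    if write_conect:
        for bond in sorted(topology.bonds, key=sorted):
            i, j = sorted(bond)
            si, sj = topology.atoms[i].serial, topology.atoms[j].serial
            lines.append(f"CONECT{si:5d}{sj:5d}")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def write_dcd(trajectory: Trajectory, path: str | Path) -> None:
    """Write the trajectory frames as a binary DCD (via MDAnalysis)."""
    import MDAnalysis as mda

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        universe = mda.Universe.empty(trajectory.topology.n_atoms,
                                      trajectory=True)
        universe.load_new(trajectory.coords.astype(np.float32),
                          format="memory", order="fac")
        with mda.coordinates.DCD.DCDWriter(
                str(path), n_atoms=trajectory.topology.n_atoms) as writer:
            for _ in universe.trajectory:
                writer.write(universe.atoms)


# ---------------------------------------------------------------------------
# chemical-role annotation
# ---------------------------------------------------------------------------

@dataclass
class RoleTable:
    """Chemical-role configuration for :func:`annotate_chemistry`.

    ``charge_groups`` maps residue names to lists of (atom-name tuple, sign);
    ``acceptor_overrides`` maps residue names to sets of nitrogen atom names
    that accept despite carrying hydrogens (oxygens are always acceptors,
    hydrogen-free nitrogens accept by default).  Histidine is neutral unless
    a charge group is added.  Terminal charge groups (N-/C-termini,
    5'-phosphates) are excluded by default.
    """

    charge_groups: dict[str, list[tuple[tuple[str, ...], int]]] = field(
        default_factory=dict)
    acceptor_overrides: dict[str, set[str]] = field(default_factory=dict)
    nucleic_resnames: set[str] = field(default_factory=lambda: set(NUCLEIC_RESNAMES))
    include_terminal_groups: bool = False

    @classmethod
    def default(cls) -> "RoleTable":
        """Charged set: Arg, Lys, Glu, Asp side chains; nucleotide phosphates;
        the carboxyl oxygens (O51/O52) of carboxylcytosine."""
        groups: dict[str, list[tuple[tuple[str, ...], int]]] = {
            "ARG": [(("NE", "NH1", "NH2"), +1)],
            "LYS": [(("NZ",), +1)],
            "GLU": [(("OE1", "OE2"), -1)],
            "ASP": [(("OD1", "OD2"), -1)],
        }
        table = cls(charge_groups=groups)
        # every nucleotide carries a backbone phosphate group
        for resname in table.nucleic_resnames:
            table.charge_groups.setdefault(resname, []).append(
                (("OP1", "OP2"), -1))
        # carboxylcytosine: 5-carboxyl oxygens form a second negative group
        for resname in ("DCZ", "5CA", "CAC"):
            table.charge_groups.setdefault(resname, []).append(
                (("O51", "O52"), -1))
        return table


def annotate_chemistry(topology: Topology,
                       role_table: RoleTable | None = None) -> Topology:
    """Annotate donors, acceptors and formal-charge groups in place.

    Donors are N/O heavy atoms bearing at least one bonded hydrogen;
    acceptors are all oxygens plus nitrogens without bonded hydrogens (or
    listed in the role table's overrides).  Charge groups follow the role
    table; residues with no entry simply get no groups, and residue names
    that are neither protein, nucleic nor in the table are collected in
    ``topology.skipped_residues`` rather than failing.

    Idempotent: annotating twice yields identical annotations.
    """
    if role_table is None:
        role_table = RoleTable.default()
    if topology.hydrogen_of is None:
        _assign_hydrogen_of(topology)
    n = topology.n_atoms
    has_h = np.zeros(n, dtype=bool)
    for i, heavy in enumerate(topology.hydrogen_of):
        if heavy >= 0:
            has_h[heavy] = True

    donor = np.zeros(n, dtype=bool)
    acceptor = np.zeros(n, dtype=bool)
    for i, atom in enumerate(topology.atoms):
        el = atom.element.upper()
        if el not in ("N", "O"):
            continue
        if has_h[i]:
            donor[i] = True
        if el == "O":
            acceptor[i] = True
        else:
            overrides = role_table.acceptor_overrides.get(atom.residue_name, set())
            if not has_h[i] or atom.name in overrides:
                acceptor[i] = True

    charge_group: list[tuple[int, int] | None] = [None] * n
    skipped: list[str] = []
    known = (PROTEIN_RESNAMES | role_table.nucleic_resnames
             | set(role_table.charge_groups))
    group_id = 0
    for res in topology.residues:
        if res.name not in known:
            label = f"{res.name}{res.index}"
            if label not in skipped:
                skipped.append(label)
            continue
        for atom_names, sign in role_table.charge_groups.get(res.name, []):
            members = [i for i in res.atom_indices
                       if topology.atoms[i].name in atom_names]
            if members:
                for i in members:
                    charge_group[i] = (group_id, sign)
                group_id += 1

    topology.donor_heavy = donor
    topology.acceptor = acceptor
    topology.charge_group = charge_group
    topology.skipped_residues = skipped
    return topology


# ---------------------------------------------------------------------------
# selection grammar
# ---------------------------------------------------------------------------
# expr     := or_expr
# or_expr  := and_expr ("or" and_expr)*
# and_expr := unary ("and" unary)*
# unary    := "not" unary | "(" expr ")" | term
# term     := "all" | "none" | "protein" | "nucleic" | "hydrogen" | "heavy"
#           | "name" LIST | "resid" RANGELIST | "resname" LIST
#           | "chain" LIST | "element" LIST

_KEYWORDS = {"all", "none", "protein", "nucleic", "hydrogen", "heavy",
             "name", "resid", "resname", "chain", "element",
             "and", "or", "not", "(", ")"}


def _tokenize(expression: str) -> list[tuple[str, int]]:
    tokens: list[tuple[str, int]] = []
    i = 0
    while i < len(expression):
        ch = expression[i]
        if ch.isspace():
            i += 1
            continue
        if ch in "()":
            tokens.append((ch, i))
            i += 1
            continue
        j = i
        while j < len(expression) and not expression[j].isspace() \
                and expression[j] not in "()":
            j += 1
        tokens.append((expression[i:j], i))
        i = j
    return tokens


class _Parser:
    def __init__(self, expression: str, topology: Topology):
        self.expression = expression
        self.tokens = _tokenize(expression)
        self.pos = 0
        self.top = topology

    def peek(self) -> tuple[str, int] | None:
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def next(self) -> tuple[str, int]:
        tok = self.peek()
        if tok is None:
            raise SelectionError("unexpected end of expression",
                                 len(self.expression))
        self.pos += 1
        return tok

    def parse(self) -> np.ndarray:
        mask = self.or_expr()
        if self.peek() is not None:
            tok, at = self.peek()
            raise SelectionError(f"unexpected token {tok!r}", at)
        return mask

    def or_expr(self) -> np.ndarray:
        mask = self.and_expr()
        while self.peek() and self.peek()[0] == "or":
            self.next()
            mask = mask | self.and_expr()
        return mask

    def and_expr(self) -> np.ndarray:
        mask = self.unary()
        while self.peek() and self.peek()[0] == "and":
            self.next()
            mask = mask & self.unary()
        return mask

    def unary(self) -> np.ndarray:
        tok = self.peek()
        if tok is None:
            raise SelectionError("unexpected end of expression",
                                 len(self.expression))
        word, at = tok
        if word == "not":
            self.next()
            return ~self.unary()
        if word == "(":
            self.next()
            mask = self.or_expr()
            closing = self.peek()
            if closing is None or closing[0] != ")":
                raise SelectionError("missing closing parenthesis", at)
            self.next()
            return mask
        return self.term()

    def _values(self, keyword_at: int) -> list[tuple[str, int]]:
        values: list[tuple[str, int]] = []
        while self.peek() is not None:
            word, _ = self.peek()
            if word in _KEYWORDS:
                break
            values.append(self.next())
        if not values:
            raise SelectionError("keyword needs at least one value", keyword_at)
        out: list[tuple[str, int]] = []
        for v, at in values:
            out.extend((p, at) for p in v.split(",") if p)
        return out

    def term(self) -> np.ndarray:
        word, at = self.next()
        atoms = self.top.atoms
        n = len(atoms)
        if word == "all":
            return np.ones(n, dtype=bool)
        if word == "none":
            return np.zeros(n, dtype=bool)
        if word == "protein":
            return np.array([a.residue_name in PROTEIN_RESNAMES for a in atoms])
        if word == "nucleic":
            return np.array([a.residue_name in NUCLEIC_RESNAMES for a in atoms])
        if word == "hydrogen":
            return np.array([a.element.upper() == "H" for a in atoms])
        if word == "heavy":
            return np.array([a.element.upper() != "H" for a in atoms])
        if word == "name":
            names = {v for v, _ in self._values(at)}
            return np.array([a.name in names for a in atoms])
        if word == "resname":
            names = {v for v, _ in self._values(at)}
            return np.array([a.residue_name in names for a in atoms])
        if word == "chain":
            chains = {v for v, _ in self._values(at)}
            return np.array([a.chain_id in chains for a in atoms])
        if word == "element":
            elements = {e.upper() for e, _ in self._values(at)}
            return np.array([a.element.upper() in elements for a in atoms])
        if word == "resid":
            mask = np.zeros(n, dtype=bool)
            for value, value_at in self._values(at):
                if "-" in value and not value.startswith("-"):
                    lo_s, hi_s = value.split("-", 1)
                    try:
                        lo, hi = int(lo_s), int(hi_s)
                    except ValueError:
                        raise SelectionError(
                            f"bad residue range {value!r}", value_at) from None
                    mask |= np.array(
                        [lo <= a.residue_index <= hi for a in atoms])
                else:
                    try:
                        rid = int(value)
                    except ValueError:
                        raise SelectionError(
                            f"bad residue id {value!r}", value_at) from None
                    mask |= np.array([a.residue_index == rid for a in atoms])
            return mask
        raise SelectionError(f"unknown keyword {word!r}", at)


def resolve_selection(topology: Topology, expression: str) -> Selection:
    """Resolve a selection expression to an ordered atom-index list.

    The grammar supports ``all``, ``none``, ``protein``, ``nucleic``,
    ``hydrogen``/``heavy``, ``name``, ``resname``, ``resid`` (ranges like
    ``432-586``), ``chain``, ``element``, combined with ``and``/``or``/
    ``not`` and parentheses.  Resolution is deterministic and preserves
    topology atom order; an empty result is valid.
    """
    mask = _Parser(expression, topology).parse()
    return Selection(expression=expression, resolved=np.flatnonzero(mask))
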