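"""Synthetic fixtures: ideal B-DNA, planted-contact trajectories, harmonic
ensembles, divergent replica sets and noisy binding titrations.

Every generator is deterministic given its spec and seed, and each plants a
*known truth* the analysis modules must recover exactly:

* :func:`generate_bdna` builds a fiber-model pseudo-duplex (default rise
  3.38 Å, twist 36°/bp) whose helical symmetry makes interior groove widths
  constant, with an optional flipped-out base;
* :func:`plant_contact_trajectory` positions donor/acceptor and charged
  atoms inside the detection geometry on "on" frames (0.5 Å inside the
  cutoffs, ideal 180° angle) and well outside (cutoff + 1 Å or more) on
  "off" frames, so realized occupancies and per-frame counts equal the spec
  exactly;
* :func:`harmonic_ensemble` adds isotropic Gaussian noise of known per-atom
  σ, giving per-atom RMSF → √3·σ;
* :func:`make_replica_set` produces replicas with one or more members whose
  DNA is rigidly displaced in the tail window, the constructed truth for
  replica QC;
* :func:`simulate_binding_curve` draws a noisy 1:1 binding isotherm at a
  planted K_D.

Pseudo-residues carry only the atoms the analyses touch; fidelity to real
sugar/backbone geometry is deliberately out of scope.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model_io import (Atom, RoleTable, Topology, Trajectory,
                       annotate_chemistry)

__all__ = [
    "HelixSpec",
    "PlantSpec",
    "PlantedInteraction",
    "generate_bdna",
    "default_pair_map",
    "build_plant_scaffold",
    "plant_contact_trajectory",
    "planted_truth",
    "harmonic_ensemble",
    "make_protein_dna_complex",
    "make_replica_set",
    "simulate_binding_curve",
]

# ---------------------------------------------------------------------------
# ideal B-DNA fiber model
# ---------------------------------------------------------------------------

#: sequence letter -> (strand-1 residue name, complement letter)
_BASE_CODES = {
    "A": ("DA", "T"), "C": ("DC", "G"), "G": ("DG", "C"), "T": ("DT", "A"),
    # modified cytosines: 5-methyl (M) and 5-carboxyl (Z), pairing with G
    "M": ("DCM", "G"), "Z": ("DCZ", "G"),
}

_P_RADIUS = 8.91        # Å, phosphate distance from the helix axis
_P_PHASE = 77.0         # deg, strand phase offset of the phosphate
_RING_CENTER_RADIUS = 2.3
_RING_RADIUS = 1.4
_FLIPPED_RADIUS = 12.0  # Å, ring-center radius of a flipped-out base


@dataclass
class HelixSpec:
    """Fiber-helix parameters for :func:`generate_bdna`.

    ``sequence`` is strand 1 written 5'→3' (letters ACGT plus M/Z for
    methyl-/carboxylcytosine); ``flipped_position`` is the 1-based base-pair
    index whose strand-1 base is rotated out of the helix.
    """

    sequence: str
    rise: float = 3.38            # Å / bp
    twist: float = 36.0           # deg / bp
    flipped_position: int | None = None

    def __post_init__(self):
        if len(self.sequence) < 4:
            raise ValueError("sequence must be at least 4 bp")
        if self.rise <= 0:
            raise ValueError("rise must be positive")
        if not (0 < self.twist < 180):
            raise ValueError("twist must be in (0, 180) degrees")
        bad = set(self.sequence.upper()) - set(_BASE_CODES)
        if bad:
            raise ValueError(f"unknown sequence letters {sorted(bad)}")
        if self.flipped_position is not None and not (
                1 <= self.flipped_position <= len(self.sequence)):
            raise ValueError("flipped_position out of range")

    @property
    def n_bp(self) -> int:
        return len(self.sequence)


def _unit(angle_deg: float) -> np.ndarray:
    a = math.radians(angle_deg)
    return np.array([math.cos(a), math.sin(a), 0.0])


def _nucleotide_atoms(base_angle: float, p_angle: float, z: float,
                      resname: str, resid: int, chain: str,
                      serial_start: int, flipped: bool
                      ) -> tuple[list[Atom], list[np.ndarray],
                                 list[tuple[int, int]], int]:
    """One pseudo-nucleotide: P/OP1/OP2 backbone + 6-ring with N1/N3.

    ``base_angle`` points from the axis to the base; ``p_angle`` places the
    phosphate on the backbone circle (the two strands' phosphates sit at
    ∓77° around the base-pair direction, which makes the major groove wider
    than the minor one).  The ring points toward the axis so paired N3
    atoms sit ~1.8 Å apart.
    """
    ez = np.array([0.0, 0.0, 1.0])
    u = _unit(base_angle)                         # base direction
    p_dir = _unit(p_angle)
    p_pos = _P_RADIUS * p_dir + z * ez

    atoms: list[Atom] = []
    coords: list[np.ndarray] = []
    bonds: list[tuple[int, int]] = []
    serial = serial_start

    def add(name: str, pos: np.ndarray) -> int:
        nonlocal serial
        atoms.append(Atom(serial=serial, name=name,
                          element=name.lstrip("0123456789'")[0],
                          residue_index=resid, residue_name=resname,
                          chain_id=chain))
        coords.append(pos.copy())
        serial += 1
        return len(atoms) - 1

    i_p = add("P", p_pos)
    i_op1 = add("OP1", p_pos + 1.48 * ez)
    i_op2 = add("OP2", p_pos + 1.48 * p_dir)
    bonds += [(i_p, i_op1), (i_p, i_op2)]

    ring_center_radius = _FLIPPED_RADIUS if flipped else _RING_CENTER_RADIUS
    c = ring_center_radius * u + z * ez
    # hexagon in the (u, ez) plane; N3 points toward the axis
    ring_names = ["N3", "C2", "N1", "C6", "C5", "C4"]
    ring_idx = []
    for k, name in enumerate(ring_names):
        psi = math.radians(60.0 * k)
        pos = c + _RING_RADIUS * (math.cos(psi) * (-u) + math.sin(psi) * ez)
        ring_idx.append(add(name, pos))
    for k in range(6):
        bonds.append((ring_idx[k], ring_idx[(k + 1) % 6]))
    if resname == "DCZ":
        # 5-carboxyl oxygens hang off C5, away from the axis
        c5 = coords[ring_idx[4]]
        bonds.append((ring_idx[4], add("O51", c5 + 1.25 * u + 0.6 * ez)))
        bonds.append((ring_idx[4], add("O52", c5 + 1.25 * u - 0.6 * ez)))
    return atoms, coords, bonds, serial


def generate_bdna(spec: HelixSpec) -> tuple[Topology, np.ndarray]:
    """Build an ideal antiparallel fiber duplex.

    Strand 1 is chain A with residue ids equal to the base-pair position;
    strand 2 is chain B, antiparallel, with residue ``n+1-j`` at position
    ``j``.  Each pseudo-nucleotide carries P, OP1, OP2 and a six-membered
    ring including N1/N3 (plus O51/O52 for carboxylcytosine).  A flipped
    base keeps its backbone in place and swings only the ring outward.
    """
    n = spec.n_bp
    atoms: list[Atom] = []
    coords: list[np.ndarray] = []
    bonds: set[frozenset[int]] = set()
    serial = 1

    def append(res_atoms, res_coords, res_bonds, offset):
        for a, b in res_bonds:
            bonds.add(frozenset((a + offset, b + offset)))
        atoms.extend(res_atoms)
        coords.extend(res_coords)

    # strand 1 (chain A), 5'→3' along +z
    for j in range(1, n + 1):
        theta = (j - 1) * spec.twist
        z = (j - 1) * spec.rise
        resname = _BASE_CODES[spec.sequence[j - 1].upper()][0]
        flipped = spec.flipped_position == j
        offset = len(atoms)
        res_atoms, res_coords, res_bonds, serial = _nucleotide_atoms(
            theta, theta - _P_PHASE, z, resname, j, "A", serial, flipped)
        append(res_atoms, res_coords, res_bonds, offset)

    # strand 2 (chain B), antiparallel: residue n+1-j sits at position j
    for k in range(1, n + 1):            # chain-B residue id, 5'→3'
        j = n + 1 - k                    # base-pair position
        theta = (j - 1) * spec.twist + 180.0
        z = (j - 1) * spec.rise
        complement = _BASE_CODES[spec.sequence[j - 1].upper()][1]
        resname = _BASE_CODES[complement][0]
        offset = len(atoms)
        res_atoms, res_coords, res_bonds, serial = _nucleotide_atoms(
            theta, theta - 180.0 + _P_PHASE, z, resname, k, "B", serial, False)
        append(res_atoms, res_coords, res_bonds, offset)

    topology = Topology(atoms=atoms, bonds=bonds,
                        reference_coords=np.array(coords))
    topology.hydrogen_of = np.full(len(atoms), -1, dtype=int)
    return topology, np.array(coords)


def default_pair_map(spec: HelixSpec
                     ) -> list[tuple[tuple[str, int] | None,
                                     tuple[str, int] | None]]:
    """Pairing config for a generated duplex, numbered by strand 1.

    The flipped position keeps its strand-1 residue but loses its partner
    (the former partner position is unpaired in the duplex).
    """
    n = spec.n_bp
    pairs = []
    for j in range(1, n + 1):
        if spec.flipped_position == j:
            pairs.append((("A", j), None))
        else:
            pairs.append((("A", j), ("B", n + 1 - j)))
    return pairs


# ---------------------------------------------------------------------------
# planted-contact trajectories
# ---------------------------------------------------------------------------

@dataclass
class PlantedInteraction:
    """One interaction to plant: residue-pair node, kind, per-frame count,
    occupancy.  Counts 1–3 are supported for both kinds."""

    kind: str                     # "hbond" | "saltbridge"
    count: int = 1
    occupancy: float = 1.0

    def __post_init__(self):
        if self.kind not in ("hbond", "saltbridge"):
            raise ValueError(f"unknown kind {self.kind!r}")
        if not (1 <= self.count <= 3):
            raise ValueError("planted count must be 1..3")
        if not (0.0 <= self.occupancy <= 1.0):
            raise ValueError("occupancy must be in [0, 1]")


@dataclass
class PlantSpec:
    """Full plant specification; the seed fully determines the output."""

    interactions: list[PlantedInteraction]
    n_frames: int = 100
    seed: int = 0

    def __post_init__(self):
        if self.n_frames < 1:
            raise ValueError("need at least one frame")


_CLUSTER_SPACING = 200.0   # Å between interaction clusters
_SITE_SPACING = 30.0       # Å between sub-sites inside one cluster
_HB_ON_DISTANCE = 3.5      # Å: hbond cutoff 4.0 minus 0.5 margin
_SB_ON_DISTANCE = 4.5      # Å: salt cutoff 5.0 minus 0.5 margin
_OFF_SHIFT = 12.0          # Å applied to the mobile residue on "off" frames


def build_plant_scaffold(spec: PlantSpec) -> Topology:
    """Topology + "on"-state coordinates for :func:`plant_contact_trajectory`.

    Interaction ``k`` lives in its own cluster at ``x = k * 200 Å``: a
    hydrogen-bond cluster is a pseudo-serine (up to three O-H donors on a
    circle) aimed at the O2 acceptor of a minimal cytosine; a salt-bridge
    cluster is an arginine head group (NE/NH1/NH2) against the phosphate
    (and, for count 3, carboxyl) oxygens of a carboxylcytosine, one atom
    pair per 30 Å sub-site so cross-pairs stay far outside the cutoff.
    """
    atoms: list[Atom] = []
    coords: list[np.ndarray] = []
    bonds: set[frozenset[int]] = set()
    serial = 1

    def add(name, resname, resid, chain, pos):
        nonlocal serial
        atoms.append(Atom(serial=serial, name=name,
                          element=name.lstrip("0123456789'")[0],
                          residue_index=resid, residue_name=resname,
                          chain_id=chain))
        coords.append(np.asarray(pos, dtype=float))
        serial += 1
        return len(atoms) - 1

    for k, planted in enumerate(spec.interactions):
        origin = np.array([k * _CLUSTER_SPACING, 0.0, 0.0])
        donor_resid = 100 + k
        acceptor_resid = 200 + k
        if planted.kind == "hbond":
            i_acc = add("O2", "DC", acceptor_resid, "D", origin)
            for c in range(planted.count):
                direction = _unit(120.0 * c)
                d_pos = origin + _HB_ON_DISTANCE * direction
                h_pos = origin + (_HB_ON_DISTANCE - 1.0) * direction
                i_d = add(f"OG{c + 1}", "SER", donor_resid, "P", d_pos)
                i_h = add(f"HG{c + 1}", "SER", donor_resid, "P", h_pos)
                bonds.add(frozenset((i_d, i_h)))
        else:
            pos_names = ["NE", "NH1", "NH2"]
            neg_names = ["OP1", "OP2", "O51", "O52"]
            park = origin + np.array([0.0, 500.0, 0.0])
            pos_idx = {}
            neg_idx = {}
            for c in range(planted.count):
                site = origin + np.array([0.0, c * _SITE_SPACING, 0.0])
                pos_idx[pos_names[c]] = add(
                    pos_names[c], "ARG", donor_resid, "P", site)
                neg_idx[neg_names[c]] = add(
                    neg_names[c], "DCZ", acceptor_resid, "D",
                    site + np.array([_SB_ON_DISTANCE, 0.0, 0.0]))
            for off, name in enumerate(pos_names[planted.count:]):
                add(name, "ARG", donor_resid, "P",
                    park + np.array([off * _SITE_SPACING, 0.0, 0.0]))
            for off, name in enumerate(neg_names[planted.count:]):
                add(name, "DCZ", acceptor_resid, "D",
                    park + np.array([off * _SITE_SPACING, 100.0, 0.0]))

    topology = Topology(atoms=atoms, bonds=bonds,
                        reference_coords=np.array(coords))
    annotate_chemistry(topology, RoleTable.default())
    return topology


def plant_contact_trajectory(spec: PlantSpec,
                             scaffold: Topology | None = None) -> Trajectory:
    """Trajectory whose detected contacts equal the plant spec exactly.

    Per interaction, ``round(occupancy * n_frames)`` "on" frames are chosen
    by a seeded permutation; on "off" frames the donor-side residue is
    translated 12 Å away, putting every planted pair at least cutoff + 1 Å
    apart.  Realized occupancy therefore equals the spec occupancy exactly
    whenever ``occupancy * n_frames`` is integral.
    """
    if scaffold is None:
        scaffold = build_plant_scaffold(spec)
    base = scaffold.reference_coords
    if base is None:
        raise ValueError("scaffold topology has no reference coordinates")
    rng = np.random.default_rng(spec.seed)
    n = spec.n_frames

    # which atoms move per interaction: the chain-P (donor-side) residue
    movers: list[np.ndarray] = []
    on_masks: list[np.ndarray] = []
    for k, planted in enumerate(spec.interactions):
        resid = 100 + k
        idx = np.array([i for i, a in enumerate(scaffold.atoms)
                        if a.chain_id == "P" and a.residue_index == resid])
        if len(idx) == 0:
            raise ValueError(
                f"scaffold is missing the atoms of planted interaction {k}")
        movers.append(idx)
        n_on = int(round(planted.occupancy * n))
        mask = np.zeros(n, dtype=bool)
        mask[rng.permutation(n)[:n_on]] = True
        on_masks.append(mask)

    off_vector = np.array([0.0, 0.0, _OFF_SHIFT])
    frames = np.repeat(base[None], n, axis=0)
    for idx, mask in zip(movers, on_masks):
        off_frames = np.flatnonzero(~mask)
        for f in off_frames:
            frames[f, idx] += off_vector
    return Trajectory(topology=scaffold, coords=frames,
                      frame_times=np.arange(n, dtype=float),
                      replica_id="planted", system_label="planted")


def planted_truth(spec: PlantSpec) -> list[tuple[str, str, str, int, float]]:
    """(node_a, node_b, kind, count, occupancy) for every planted edge,
    with node labels matching the residue-level node map."""
    truth = []
    for k, planted in enumerate(spec.interactions):
        donor_res = "SER" if planted.kind == "hbond" else "ARG"
        acceptor_res = "DC" if planted.kind == "hbond" else "DCZ"
        a = f"{donor_res}{100 + k}"
        b = f"{acceptor_res}{200 + k}"
        a, b = sorted((a, b))
        occ = round(planted.occupancy * spec.n_frames) / spec.n_frames
        truth.append((a, b, planted.kind, planted.count, occ))
    return truth


# ---------------------------------------------------------------------------
# harmonic ensembles and replica sets
# ---------------------------------------------------------------------------

def harmonic_ensemble(topology: Topology, reference: np.ndarray,
                      sigmas: float | np.ndarray, n_frames: int,
                      seed: int = 0, dt_ps: float = 1.0,
                      replica_id: str = "r1") -> Trajectory:
    """Frames = reference + isotropic Gaussian noise (per-coordinate sd =
    sigma per atom); per-atom RMSF converges to √3·σ."""
    reference = np.asarray(reference, dtype=float)
    sigmas = np.broadcast_to(np.asarray(sigmas, dtype=float),
                             (reference.shape[0],))
    if np.any(sigmas < 0):
        raise ValueError("sigmas must be non-negative")
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal((n_frames, *reference.shape))
    frames = reference[None] + noise * sigmas[None, :, None]
    return Trajectory(topology=topology, coords=frames,
                      frame_times=np.arange(n_frames, dtype=float) * dt_ps,
                      replica_id=replica_id)


def make_protein_dna_complex(n_bp: int = 10, n_protein_residues: int = 6,
                             flipped_position: int | None = None
                             ) -> tuple[Topology, np.ndarray]:
    """A pseudo protein–DNA complex: fiber duplex plus a backbone-only
    protein arc (N, CA, C, O per residue, chain G) 15 Å off the helix axis.
    The protein Cα set is non-collinear, so it supports superposition fits.
    """
    helix = HelixSpec(sequence=("ACGT" * ((n_bp + 3) // 4))[:n_bp],
                      flipped_position=flipped_position)
    topology, dna_coords = generate_bdna(helix)
    atoms = list(topology.atoms)
    coords = [c for c in dna_coords]
    bonds = set(topology.bonds)
    serial = max(a.serial for a in atoms) + 1
    z_span = (n_bp - 1) * helix.rise
    for r in range(n_protein_residues):
        frac = r / max(n_protein_residues - 1, 1)
        angle = 120.0 * frac
        center = (15.0 + 2.0 * math.sin(3 * frac * math.pi)) * _unit(angle) \
            + np.array([0.0, 0.0, frac * z_span])
        offsets = {"N": np.array([-1.2, 0.0, 0.0]),
                   "CA": np.array([0.0, 0.0, 0.0]),
                   "C": np.array([1.2, 0.4, 0.0]),
                   "O": np.array([1.6, 1.4, 0.6])}
        idx = {}
        for name, off in offsets.items():
            atoms.append(Atom(serial=serial, name=name, element=name[0],
                              residue_index=500 + r, residue_name="ALA",
                              chain_id="G"))
            coords.append(center + off)
            idx[name] = len(atoms) - 1
            serial += 1
        bonds.update({frozenset((idx["N"], idx["CA"])),
                      frozenset((idx["CA"], idx["C"])),
                      frozenset((idx["C"], idx["O"]))})
    full = Topology(atoms=atoms, bonds=bonds,
                    reference_coords=np.array(coords))
    full.hydrogen_of = np.full(len(atoms), -1, dtype=int)
    return full, np.array(coords)


def make_replica_set(base: Trajectory, n: int, divergent: set[int],
                     displacement: float = 6.0, tail_fraction: float = 0.5,
                     jitter_sigma: float = 0.05, seed: int = 0,
                     dna_atom_indices: np.ndarray | None = None
                     ) -> list[Trajectory]:
    """``n`` jittered copies of ``base``; members listed in ``divergent``
    (0-based) get their DNA atoms rigidly displaced by ``displacement`` Å in
    the tail window.  ``dna_atom_indices`` defaults to all nucleic atoms."""
    if dna_atom_indices is None:
        from .model_io import resolve_selection
        dna_atom_indices = resolve_selection(base.topology, "nucleic").resolved
    rng = np.random.default_rng(seed)
    tail_start = int(round(base.n_frames * (1.0 - tail_fraction)))
    shift = np.array([displacement, 0.0, 0.0])
    replicas = []
    for r in range(n):
        coords = base.coords + jitter_sigma * rng.standard_normal(
            base.coords.shape)
        if r in divergent:
            coords[tail_start:, dna_atom_indices] += shift
        replicas.append(Trajectory(
            topology=base.topology, coords=coords,
            frame_times=base.frame_times.copy(),
            replica_id=f"r{r + 1}", system_label=base.system_label))
    return replicas


# ---------------------------------------------------------------------------
# binding titrations
# ---------------------------------------------------------------------------

def simulate_binding_curve(kd: float, concentrations,
                           amplitude: float = 1.0, baseline: float = 0.0,
                           noise_sd: float = 0.0, seed: int = 0
                           ) -> pd.DataFrame:
    """Noisy 1:1 binding isotherm: response = baseline + amplitude·c/(c+K_D)
    + N(0, noise_sd).  Concentrations and K_D are in μM."""
    concentrations = np.asarray(concentrations, dtype=float)
    if kd <= 0:
        raise ValueError("kd must be positive")
    if np.any(concentrations <= 0):
        raise ValueError("concentrations must be positive")
    rng = np.random.default_rng(seed)
    response = baseline + amplitude * concentrations / (concentrations + kd)
    if noise_sd > 0:
        response = response + rng.normal(0.0, noise_sd, len(concentrations))
    return pd.DataFrame({"concentration_um": concentrations,
                         "response": response})
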