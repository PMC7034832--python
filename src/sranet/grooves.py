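"""Minor/major groove widths of duplex DNA from cross-strand P-P distances.

The widths follow the phosphate-distance construction of El Hassan and
Calladine as read by this package: at base-pair position ``i``,

* minor groove width = distance between the P atom of the strand-1 residue
  at position ``i + 2`` and the P atom of the strand-2 residue at ``i - 2``;
* major groove width = distance between the strand-1 P at ``i - 2`` and the
  strand-2 P at ``i + 2``

(cross-strand, opposite offsets; the offset is configurable so the ±3
variant can be compared).  Raw P-P distances are reported by default; a flag
subtracts 2 x 2.9 Å of phosphate radius for comparison with tools that
report accessible widths.

Base pairing is supplied, not inferred: a flipped-out base breaks geometric
detection, so the :class:`BasePairMap` is part of the run configuration and
marks unpaired positions explicitly.  Positions whose required phosphates
fall off the ends of the map, into a gap, or onto a residue without a P atom
are undefined and reported as NaN with an explicit mask — never zero-filled.
Base-pair numbering follows the strand binding the flipped-out base.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .model_io import Topology, Trajectory

__all__ = [
    "BasePairMap",
    "GrooveProfile",
    "assign_base_pairs",
    "groove_widths",
    "PHOSPHATE_RADIUS_CORRECTION",
]

#: Subtracted from raw P-P distances when ``subtract_radius`` is enabled
#: (two phosphate van der Waals radii of 2.9 Å).
PHOSPHATE_RADIUS_CORRECTION = 5.8


@dataclass
class BasePairMap:
    """Ordered base pairs keyed by base-pair number (1-based).

    Each entry is ``(strand1_key, strand2_key)`` where a key is
    ``(chain_id, resid)``; ``None`` marks an unpaired position (e.g. the
    partner of the flipped-out base).
    """

    pairs: list[tuple[tuple[str, int] | None, tuple[str, int] | None]]

    @property
    def n_positions(self) -> int:
        return len(self.pairs)

    def strand_residue(self, position: int, strand: int
                       ) -> tuple[str, int] | None:
        """Residue key at 1-based base-pair ``position`` on strand 1 or 2."""
        if not 1 <= position <= len(self.pairs):
            return None
        return self.pairs[position - 1][strand - 1]


def assign_base_pairs(topology: Topology,
                      pairing: list[tuple[tuple[str, int] | None,
                                          tuple[str, int] | None]],
                      reference_coords: np.ndarray | None = None,
                      check_distance: float = 4.0) -> BasePairMap:
    """Validate a declared pairing against the topology.

    A residue listed twice is fatal.  With reference coordinates, declared
    pairs whose closest N1/N3-N1/N3 distance exceeds ``check_distance`` get
    a warning (sanity check only — the map is taken as authoritative).
    """
    residue_by_key = {res.key: res for res in topology.residues}
    seen: set[tuple[str, int]] = set()
    for s1, s2 in pairing:
        for key in (s1, s2):
            if key is None:
                continue
            if key not in residue_by_key:
                raise KeyError(f"residue {key} not in topology")
            if key in seen:
                raise ValueError(f"residue {key} listed twice in pairing")
            seen.add(key)
    if reference_coords is None and topology.reference_coords is not None:
        reference_coords = topology.reference_coords
    if reference_coords is not None:
        for position, (s1, s2) in enumerate(pairing, start=1):
            if s1 is None or s2 is None:
                continue
            d = _pair_atom_distance(topology, reference_coords, s1, s2)
            if d is not None and d > check_distance:
                warnings.warn(
                    f"declared pair at position {position} ({s1} / {s2}) has "
                    f"N1/N3 separation {d:.2f} Å > {check_distance} Å")
    return BasePairMap(pairs=list(pairing))


def _pair_atom_distance(topology, coords, key1, key2) -> float | None:
    def ring_nitrogens(key):
        res = next(r for r in topology.residues if r.key == key)
        return [i for i in res.atom_indices
                if topology.atoms[i].name in ("N1", "N3")]
    a = ring_nitrogens(key1)
    b = ring_nitrogens(key2)
    if not a or not b:
        return None
    return float(min(np.linalg.norm(coords[i] - coords[j])
                     for i in a for j in b))


@dataclass
class GrooveProfile:
    """Per-frame, per-position groove widths with distribution summaries.

    ``minor``/``major`` have shape (n_frames, n_positions) with NaN at
    undefined positions; ``defined_minor``/``defined_major`` are the
    corresponding masks.
    """

    positions: np.ndarray
    minor: np.ndarray
    major: np.ndarray
    defined_minor: np.ndarray
    defined_major: np.ndarray

    def summary(self) -> pd.DataFrame:
        """Mean ± sd per base-pair position (NaN where undefined)."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            rows = {
                "position": self.positions,
                "minor_mean": np.nanmean(self.minor, axis=0),
                "minor_sd": np.nanstd(self.minor, axis=0, ddof=1)
                if self.minor.shape[0] > 1 else np.full(len(self.positions), np.nan),
                "major_mean": np.nanmean(self.major, axis=0),
                "major_sd": np.nanstd(self.major, axis=0, ddof=1)
                if self.major.shape[0] > 1 else np.full(len(self.positions), np.nan),
            }
        return pd.DataFrame(rows)

    def to_table(self, path: str | Path) -> None:
        frames, positions = self.minor.shape
        lines = ["frame\tposition\tminor\tmajor"]
        for f in range(frames):
            for p in range(positions):
                minor = f"{self.minor[f, p]:.6f}" if self.defined_minor[f, p] else "NA"
                major = f"{self.major[f, p]:.6f}" if self.defined_major[f, p] else "NA"
                lines.append(f"{f}\t{self.positions[p]}\t{minor}\t{major}")
        Path(path).write_text("\n".join(lines) + "\n")


def _phosphorus_index(topology: Topology,
                      residue_by_key: dict, key) -> int | None:
    if key is None:
        return None
    res = residue_by_key.get(key)
    if res is None:
        return None
    for i in res.atom_indices:
        if topology.atoms[i].name == "P":
            return i
    return None


def groove_widths(trajectory: Trajectory, pair_map: BasePairMap,
                  offset: int = 2, subtract_radius: bool = False
                  ) -> GrooveProfile:
    """Groove widths per frame and base-pair position.

    ``offset`` is the cross-strand phosphate offset (±2 by default):
    minor(i) = |P(strand1, i+offset) − P(strand2, i−offset)|,
    major(i) = |P(strand1, i−offset) − P(strand2, i+offset)|.
    Positions lacking either phosphate are undefined (NaN + mask).
    """
    top = trajectory.topology
    residue_by_key = {res.key: res for res in top.residues}
    n_pos = pair_map.n_positions
    n_frames = trajectory.n_frames

    any_p = any(
        _phosphorus_index(top, residue_by_key, pair_map.strand_residue(i, s))
        is not None
        for i in range(1, n_pos + 1) for s in (1, 2))
    if not any_p:
        raise ValueError("no phosphorus atoms found for any mapped residue")

    minor = np.full((n_frames, n_pos), np.nan)
    major = np.full((n_frames, n_pos), np.nan)
    for col, i in enumerate(range(1, n_pos + 1)):
        p1_plus = _phosphorus_index(top, residue_by_key,
                                    pair_map.strand_residue(i + offset, 1))
        p2_minus = _phosphorus_index(top, residue_by_key,
                                     pair_map.strand_residue(i - offset, 2))
        p1_minus = _phosphorus_index(top, residue_by_key,
                                     pair_map.strand_residue(i - offset, 1))
        p2_plus = _phosphorus_index(top, residue_by_key,
                                    pair_map.strand_residue(i + offset, 2))
        if p1_plus is not None and p2_minus is not None:
            d = np.linalg.norm(trajectory.coords[:, p1_plus]
                               - trajectory.coords[:, p2_minus], axis=1)
            minor[:, col] = d
        if p1_minus is not None and p2_plus is not None:
            d = np.linalg.norm(trajectory.coords[:, p1_minus]
                               - trajectory.coords[:, p2_plus], axis=1)
            major[:, col] = d
    if subtract_radius:
        minor = minor - PHOSPHATE_RADIUS_CORRECTION
        major = major - PHOSPHATE_RADIUS_CORRECTION
    return GrooveProfile(
        positions=np.arange(1, n_pos + 1),
        minor=minor, major=major,
        defined_minor=~np.isnan(minor),
        defined_major=~np.isnan(major))
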