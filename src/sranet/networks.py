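"""Aggregate contact time series into weighted interaction networks.

Nodes are protein residues or single DNA-base atoms/atom groups (a
:class:`NodeMap` decides the granularity); edges carry two statistics:

``mean_count``
    the average number of interactions per time frame — the number printed
    next to each network edge;
``occupancy``
    the fraction of frames with at least one interaction, which drives
    pruning: edges occurring in <= the threshold fraction of simulation time
    are omitted (strictly, so an edge sitting exactly at the threshold is
    dropped).  Defaults are 0.15 for binding-pocket views and 0.10 for
    NKR-finger views.

When a node pair features both hydrogen bonds and salt bridges, the network
can keep only the salt-bridge edge (``salt_bridge_precedence``), matching how
such pairs are displayed.  Statistics are always computed per kind first, so
the alternative reading can be audited.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .contacts import ContactTimeSeries
from .model_io import Topology

__all__ = [
    "NodeMap",
    "InteractionNetwork",
    "merge_series",
    "build_network",
    "compare_networks",
    "export_network",
    "load_graphml",
    "PRUNE_BINDING_POCKET",
    "PRUNE_NKR_FINGER",
]

PRUNE_BINDING_POCKET = 0.15
PRUNE_NKR_FINGER = 0.10


@dataclass
class NodeMap:
    """Maps every atom index to exactly one node label.

    Built from ordered rules; later rules never override earlier ones.  The
    default granularity is one node per residue (label ``RESNAME<resid>``);
    atom- or atom-group-level rules carve individual atoms of a residue out
    into their own nodes, e.g. the O51/O52 carboxyl pair of a flipped
    carboxylcytosine.
    """

    labels: list[str]                       # per atom index

    @classmethod
    def residue_level(cls, topology: Topology) -> "NodeMap":
        labels = [f"{a.residue_name}{a.residue_index}" for a in topology.atoms]
        return cls(labels=labels)

    @classmethod
    def from_rules(cls, topology: Topology,
                   atom_rules: list[tuple[tuple[str, int], tuple[str, ...], str]]
                   | None = None) -> "NodeMap":
        """Residue-level map with atom-group overrides.

        ``atom_rules`` entries are ((chain_id, resid), atom_names, label):
        the named atoms of that residue become their own node.  All atoms of
        one rule must lie in a single residue by construction.
        """
        base = cls.residue_level(topology)
        if atom_rules:
            by_key: dict[tuple[str, int], dict[str, int]] = {}
            for i, atom in enumerate(topology.atoms):
                by_key.setdefault(atom.residue_key, {})[atom.name] = i
            for residue_key, atom_names, label in atom_rules:
                if residue_key not in by_key:
                    raise KeyError(f"no residue {residue_key} in topology")
                for name in atom_names:
                    idx = by_key[residue_key].get(name)
                    if idx is None:
                        raise KeyError(
                            f"residue {residue_key} has no atom {name!r}")
                    base.labels[idx] = label
        return base

    def label_of(self, atom_index: int) -> str:
        return self.labels[atom_index]


@dataclass
class InteractionNetwork:
    """Nodes and (node_a, node_b, kind)-keyed weighted edges.

    Edge attributes: ``mean_count`` (interactions/frame), ``occupancy``
    (fraction of frames present) and ``n_frames``.  Self-edges are never
    stored; every stored edge has mean_count > 0 and occupancy in (0, 1].
    """

    nodes: set[str] = field(default_factory=set)
    edges: dict[tuple[str, str, str], dict] = field(default_factory=dict)

    def add_edge(self, node_a: str, node_b: str, kind: str,
                 mean_count: float, occupancy: float, n_frames: int) -> None:
        if node_a == node_b:
            raise ValueError(f"self-edge on node {node_a!r}")
        if mean_count <= 0 or not (0 < occupancy <= 1):
            raise ValueError("stored edges need mean_count > 0 and occupancy in (0,1]")
        a, b = sorted((node_a, node_b))
        self.nodes.update((a, b))
        self.edges[(a, b, kind)] = {
            "mean_count": float(mean_count),
            "occupancy": float(occupancy),
            "n_frames": int(n_frames),
        }

    def weight(self, node_a: str, node_b: str, kind: str) -> float:
        a, b = sorted((node_a, node_b))
        edge = self.edges.get((a, b, kind))
        return edge["mean_count"] if edge else 0.0

    def summary(self) -> pd.DataFrame:
        """Edge table with mean counts rounded to 2 decimals for display."""
        rows = [
            {"node_a": a, "node_b": b, "kind": kind,
             "mean_count": round(attrs["mean_count"], 2),
             "occupancy": round(attrs["occupancy"], 4),
             "n_frames": attrs["n_frames"]}
            for (a, b, kind), attrs in sorted(self.edges.items())
        ]
        return pd.DataFrame(
            rows, columns=["node_a", "node_b", "kind", "mean_count",
                           "occupancy", "n_frames"])

    def to_networkx(self) -> nx.MultiGraph:
        g = nx.MultiGraph()
        g.add_nodes_from(sorted(self.nodes))
        for (a, b, kind), attrs in sorted(self.edges.items()):
            g.add_edge(a, b, key=kind, kind=kind, **attrs)
        return g


def merge_series(series_by_replica: list[dict[tuple, ContactTimeSeries]]
                 ) -> dict[tuple, ContactTimeSeries]:
    """Concatenate per-replica contact series into one merged series set.

    Emulates merging the (tail-sliced) replica trajectories into a single
    system-specific trajectory: counts are concatenated in replica order, a
    pair missing from one replica contributes zeros for that block, and the
    merged mean is the frame-weighted mean of the replica means.
    """
    if not series_by_replica:
        raise ValueError("no replicas to merge")
    lengths = []
    for rep in series_by_replica:
        reps = {ts.n_frames for ts in rep.values()}
        if len(reps) > 1:
            raise ValueError("inconsistent n_frames within one replica")
        lengths.append(reps.pop() if reps else 0)
    if any(n == 0 for n in lengths):
        # empty replicas: fall back to 0-length blocks only if keys elsewhere
        pass
    all_keys = sorted({k for rep in series_by_replica for k in rep})
    total = sum(lengths)
    merged: dict[tuple, ContactTimeSeries] = {}
    for key in all_keys:
        blocks = []
        for rep, n in zip(series_by_replica, lengths):
            if key in rep:
                blocks.append(rep[key].counts)
            else:
                blocks.append(np.zeros(n, dtype=int))
        counts = np.concatenate(blocks) if blocks else np.zeros(0, dtype=int)
        merged[key] = ContactTimeSeries(pair_key=key, counts=counts,
                                        n_frames=total)
    return merged


def build_network(series: dict[tuple, ContactTimeSeries], node_map: NodeMap,
                  prune_occupancy: float = PRUNE_BINDING_POCKET,
                  salt_bridge_precedence: bool = True) -> InteractionNetwork:
    """Aggregate atom-level series into a pruned node-level network.

    Atom-level counts are summed into node-level per-frame counts *before*
    statistics, so two simultaneous hydrogen bonds between one residue pair
    yield a single edge of weight 2.  Edges with occupancy <= the pruning
    threshold are omitted (strict).  With ``salt_bridge_precedence`` a node
    pair retaining both kinds keeps only the salt-bridge edge.
    """
    if not (0 <= prune_occupancy < 1):
        raise ValueError("prune_occupancy must be in [0, 1)")
    node_counts: dict[tuple[str, str, str], np.ndarray] = {}
    n_frames = None
    for (atom_a, atom_b, kind), ts in series.items():
        if atom_a >= len(node_map.labels) or atom_b >= len(node_map.labels):
            raise ValueError(
                f"node map does not cover atoms {atom_a}/{atom_b} "
                "appearing in the series")
        label_a = node_map.label_of(atom_a)
        label_b = node_map.label_of(atom_b)
        if label_a == label_b:
            continue          # intra-node contact, not an edge
        if n_frames is None:
            n_frames = ts.n_frames
        elif n_frames != ts.n_frames:
            raise ValueError("series have inconsistent n_frames")
        a, b = sorted((label_a, label_b))
        key = (a, b, kind)
        if key not in node_counts:
            node_counts[key] = np.zeros(ts.n_frames, dtype=int)
        node_counts[key] += ts.counts

    network = InteractionNetwork()
    for (a, b, kind), counts in sorted(node_counts.items()):
        occupancy = np.count_nonzero(counts) / len(counts)
        mean_count = counts.sum() / len(counts)
        if occupancy <= prune_occupancy or mean_count <= 0:
            continue
        network.add_edge(a, b, kind, mean_count, occupancy, len(counts))
    if salt_bridge_precedence:
        for (a, b, kind) in list(network.edges):
            if kind == "hbond" and (a, b, "saltbridge") in network.edges:
                del network.edges[(a, b, "hbond")]
    return network


def compare_networks(a: InteractionNetwork, b: InteractionNetwork
                     ) -> pd.DataFrame:
    """Edge-wise deltas b - a; edges missing on one side count as weight 0."""
    keys = sorted(set(a.edges) | set(b.edges))
    rows = []
    for (na, nb, kind) in keys:
        ea = a.edges.get((na, nb, kind))
        eb = b.edges.get((na, nb, kind))
        wa = ea["mean_count"] if ea else 0.0
        wb = eb["mean_count"] if eb else 0.0
        oa = ea["occupancy"] if ea else 0.0
        ob = eb["occupancy"] if eb else 0.0
        rows.append({"node_a": na, "node_b": nb, "kind": kind,
                     "weight_a": wa, "weight_b": wb,
                     "delta_mean_count": wb - wa,
                     "occupancy_a": oa, "occupancy_b": ob,
                     "delta_occupancy": ob - oa})
    return pd.DataFrame(rows, columns=[
        "node_a", "node_b", "kind", "weight_a", "weight_b",
        "delta_mean_count", "occupancy_a", "occupancy_b", "delta_occupancy"])


def export_network(network: InteractionNetwork, path: str | Path,
                   fmt: str = "graphml") -> None:
    """Write the network as GraphML (lossless), edge list or DOT."""
    path = Path(path)
    if fmt == "graphml":
        nx.write_graphml(network.to_networkx(), path)
    elif fmt == "edgelist":
        lines = ["node_a\tnode_b\tkind\tmean_count\toccupancy\tn_frames"]
        for (a, b, kind), attrs in sorted(network.edges.items()):
            lines.append(
                f"{a}\t{b}\t{kind}\t{attrs['mean_count']:.10g}\t"
                f"{attrs['occupancy']:.10g}\t{attrs['n_frames']}")
        path.write_text("\n".join(lines) + "\n")
    elif fmt == "dot":
        lines = ["graph interactions {"]
        for node in sorted(network.nodes):
            lines.append(f'    "{node}";')
        for (a, b, kind), attrs in sorted(network.edges.items()):
            color = "red" if kind == "saltbridge" else "black"
            lines.append(
                f'    "{a}" -- "{b}" [label="{attrs["mean_count"]:.2f}", '
                f'color={color}];')
        lines.append("}")
        path.write_text("\n".join(lines) + "\n")
    else:
        raise ValueError(f"unknown export format {fmt!r}")


def load_graphml(path: str | Path) -> InteractionNetwork:
    """Re-import a GraphML export; round-trips :func:`export_network`."""
    g = nx.read_graphml(str(path), force_multigraph=True)
    network = InteractionNetwork()
    network.nodes.update(g.nodes())
    for a, b, key, attrs in g.edges(keys=True, data=True):
        kind = attrs.get("kind", key)
        network.add_edge(a, b, kind, attrs["mean_count"],
                         attrs["occupancy"], int(attrs["n_frames"]))
    return network
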