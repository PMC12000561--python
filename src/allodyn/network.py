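"""Dynamic residue-nucleotide interaction networks.

Nodes: one per amino acid (anchored on the alpha-carbon), two per
nucleotide (backbone phosphorus node owning the phosphate+sugar heavy
atoms, base node anchored on a ring nitrogen owning the base heavy
atoms), one per cofactor group (anchored at the atom nearest the group
centroid).  An abasic nucleotide with no base nitrogen gets its base
node anchored at C1' and flagged — this is how an abasic (AP) site
remains addressable as a path endpoint.

Edges connect node pairs whose heavy-atom group distance stays within a
cutoff (default 4.5 A) in strictly more than a persistence fraction
(default 0.75) of frames; the edge weight is -ln|C_ij| from the motion
correlation, so strongly correlated contacts are "short".  Sequence
neighbours and the two nodes of one nucleotide are ineligible to avoid
trivial backbone shortcuts.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from allodyn.errors import IntegrityError, NodeAssignmentError
from allodyn.dynamics import CorrelationMatrix
from allodyn.io import Topology, Trajectory

logger = logging.getLogger(__name__)

DEFAULT_CUTOFF = 4.5          # Angstrom
DEFAULT_PERSISTENCE = 0.75    # strict: fraction must exceed this
CORRELATION_FLOOR = 1e-4      # |C| below this -> edge dropped

PURINES = {"A", "G", "DA", "DG", "RA", "RG", "ADE", "GUA"}
PYRIMIDINES = {"C", "T", "U", "DC", "DT", "DU", "RC", "RU", "CYT", "THY", "URA"}


@dataclass(frozen=True)
class Node:
    node_id: int
    label: str
    anchor_atom_index: int
    node_group: frozenset[int]
    residue_key: tuple[str, int]
    kind: str  # protein | backbone | base | cofactor
    flags: tuple[str, ...] = ()


@dataclass
class NodeSet:
    nodes: list[Node]

    def __post_init__(self) -> None:
        seen: set[int] = set()
        for n in self.nodes:
            if n.anchor_atom_index not in n.node_group:
                raise IntegrityError(
                    f"node {n.label}: anchor not inside its node_group"
                )
            if seen & n.node_group:
                raise IntegrityError(
                    f"node {n.label}: node_group overlaps another node"
                )
            seen |= n.node_group

    def __len__(self) -> int:
        return len(self.nodes)

    def by_label(self, label: str) -> Node:
        for n in self.nodes:
            if n.label == label:
                return n
        raise KeyError(label)

    def labels(self) -> list[str]:
        return [n.label for n in self.nodes]


@dataclass
class DynamicNetwork:
    """Persistent-contact graph weighted by -ln|correlation|."""

    nodes: NodeSet
    graph: nx.Graph
    cutoff: float
    persistence: float
    correlation_floor: float

    def edge_table(self) -> pd.DataFrame:
        rows = [
            {
                "node_i": self.nodes.nodes[i].label,
                "node_j": self.nodes.nodes[j].label,
                "contact_fraction": d["contact_fraction"],
                "correlation": d["correlation"],
                "weight": d["weight"],
            }
            for i, j, d in self.graph.edges(data=True)
        ]
        return pd.DataFrame(
            rows, columns=["node_i", "node_j", "contact_fraction",
                           "correlation", "weight"]
        )


@dataclass
class PathResult:
    """A minimum-weight path, or an explicit no-path marker."""

    nodes: list[str]
    total_weight: float
    edge_weights: list[float]
    found: bool = True

    def __post_init__(self) -> None:
        if self.found and abs(sum(self.edge_weights) - self.total_weight) > 1e-10:
            raise IntegrityError("path total != sum of edge weights")


# ---------------------------------------------------------------------------
# node assignment
# ---------------------------------------------------------------------------

def _is_heavy(element: str) -> bool:
    return element.strip().upper() not in ("H", "D")


def _base_nitrogen(residue_name: str, base_nitrogen_rule: dict | None) -> str:
    rule = base_nitrogen_rule or {}
    if residue_name in rule:
        return rule[residue_name]
    if residue_name.upper() in PURINES:
        return "N1"
    if residue_name.upper() in PYRIMIDINES:
        return "N3"
    return "N1"


_BACKBONE_SUGAR = {
    "P", "OP1", "OP2", "OP3", "O1P", "O2P",
    "O5'", "C5'", "C4'", "O4'", "C3'", "O3'", "C2'", "O2'", "C1'",
}


def assign_nodes(
    topology: Topology,
    reference: np.ndarray | None = None,
    base_nitrogen_rule: dict | None = None,
) -> NodeSet:
    """Map residues onto network nodes.

    Protein residue -> one node on CA owning all its heavy atoms.
    Nucleotide -> a phosphorus node (phosphate + sugar heavy atoms) and a
    base node (base heavy atoms, anchored on N1 for purines / N3 for
    pyrimidines, configurable via ``base_nitrogen_rule``:
    residue_name -> atom_name).  A 5'-terminal nucleotide without P gets
    only the base node, with a warning; an abasic nucleotide gets its
    base node on C1' with flag ``abasic``.  Cofactor group -> one node
    anchored at the atom nearest the group centroid (``reference``
    coordinates if given, else the first atom).
    """
    nodes: list[Node] = []
    nid = 0
    for key, atoms in topology.residues():
        kind = atoms[0].residue_kind
        chain, resi = key
        resn = atoms[0].residue_name
        heavy = [a for a in atoms if _is_heavy(a.element)]
        names = {a.atom_name: a for a in heavy}
        label_base = f"{chain}:{resi}:{resn}"
        if kind == "protein":
            if "CA" not in names:
                raise NodeAssignmentError(
                    f"protein residue {chain}/{resi} ({resn}) lacks a CA atom"
                )
            nodes.append(Node(
                nid, label_base, names["CA"].atom_index,
                frozenset(a.atom_index for a in heavy), key, "protein",
            ))
            nid += 1
        elif kind == "nucleotide":
            backbone = [a for a in heavy if a.atom_name in _BACKBONE_SUGAR]
            base = [a for a in heavy if a.atom_name not in _BACKBONE_SUGAR]
            n_name = _base_nitrogen(resn, base_nitrogen_rule)
            flags: tuple[str, ...] = ()
            if not base:
                # abasic site: base-node slot anchored at C1'
                if "C1'" not in names:
                    raise NodeAssignmentError(
                        f"nucleotide {chain}/{resi} ({resn}) has neither base "
                        f"atoms nor C1'"
                    )
                anchor = names["C1'"]
                base = [anchor]
                backbone = [a for a in backbone if a is not anchor]
                flags = ("abasic",)
                logger.warning(
                    "nucleotide %s/%s: no base atoms; base node anchored at "
                    "C1' (abasic)", chain, resi,
                )
            else:
                if n_name not in names:
                    raise NodeAssignmentError(
                        f"nucleotide {chain}/{resi} ({resn}) lacks base "
                        f"nitrogen {n_name}"
                    )
                anchor = names[n_name]
            if "P" in names:
                nodes.append(Node(
                    nid, label_base + ":P", names["P"].atom_index,
                    frozenset(a.atom_index for a in backbone), key, "backbone",
                ))
                nid += 1
            else:
                logger.warning(
                    "nucleotide %s/%s: no P atom (5'-terminal?); backbone "
                    "node skipped", chain, resi,
                )
                base = base + backbone  # keep partition covering heavy atoms
            nodes.append(Node(
                nid, label_base + ":base", anchor.atom_index,
                frozenset(a.atom_index for a in base), key, "base", flags,
            ))
            nid += 1
        elif kind == "cofactor":
            idx = [a.atom_index for a in heavy]
            if reference is not None:
                xyz = np.asarray(reference, dtype=float)[idx]
                centroid = xyz.mean(axis=0)
                anchor_idx = idx[int(np.argmin(((xyz - centroid) ** 2).sum(axis=1)))]
            else:
                anchor_idx = idx[0]
            nodes.append(Node(
                nid, label_base, anchor_idx, frozenset(idx), key, "cofactor",
            ))
            nid += 1
        # ions / solvent carry no nodes
    return NodeSet(nodes=nodes)


# ---------------------------------------------------------------------------
# contacts
# ---------------------------------------------------------------------------

def _eligible(a: Node, b: Node) -> bool:
    """Exclude covalently adjacent owners from edge formation."""
    if a.residue_key == b.residue_key:
        return False  # P node / base node of the same nucleotide
    ca, ra = a.residue_key
    cb, rb = b.residue_key
    if ca == cb and abs(ra - rb) == 1 and a.kind != "cofactor" and b.kind != "cofactor":
        return False  # sequence neighbours
    return True


def contact_map(
    trajectory: Trajectory,
    topology: Topology,
    nodes: NodeSet,
    cutoff: float = DEFAULT_CUTOFF,
    persistence: float = DEFAULT_PERSISTENCE,
) -> pd.DataFrame:
    """Per-pair persistence of heavy-atom group contact.

    For each node pair, the fraction of frames in which the minimum
    distance between the two node_groups is <= ``cutoff``.  Pairs whose
    owner residues are covalently adjacent are recorded but flagged
    ineligible.  ``eligible_edge`` applies the strict rule
    fraction > persistence.
    """
    xyz = trajectory.coordinates
    groups = [np.array(sorted(n.node_group)) for n in nodes.nodes]
    rows = []
    for i in range(len(nodes)):
        gi = groups[i]
        for j in range(i + 1, len(nodes)):
            gj = groups[j]
            d = xyz[:, gi, None, :] - xyz[:, None, gj, :]
            dmin = np.sqrt((d**2).sum(axis=3)).min(axis=(1, 2))
            frac = float((dmin <= cutoff).mean())
            elig = _eligible(nodes.nodes[i], nodes.nodes[j])
            rows.append((i, j, frac, elig, elig and frac > persistence))
    return pd.DataFrame(
        rows, columns=["i", "j", "contact_fraction", "eligible",
                       "eligible_edge"],
    )


# ---------------------------------------------------------------------------
# network construction and path analysis
# ---------------------------------------------------------------------------

def build_network(
    contacts: pd.DataFrame,
    correlations: CorrelationMatrix,
    nodes: NodeSet,
    persistence: float = DEFAULT_PERSISTENCE,
    correlation_floor: float = CORRELATION_FLOOR,
    cutoff: float = DEFAULT_CUTOFF,
) -> DynamicNetwork:
    """Assemble the weighted graph from contacts and correlations.

    An edge joins every eligible pair with contact_fraction strictly
    above ``persistence``; its weight is -ln|C_ij|.  Pairs with |C|
    below ``correlation_floor`` would carry near-infinite weight and are
    dropped with a log entry.
    """
    if correlations.n_nodes != len(nodes):
        raise IntegrityError("correlation matrix does not match the node set")
    c = correlations.matrix
    if np.any(np.abs(c) > 1 + 1e-12):
        raise IntegrityError("|correlation| > 1")
    g = nx.Graph()
    g.add_nodes_from(range(len(nodes)))
    for row in contacts.itertuples():
        if not row.eligible or not row.contact_fraction > persistence:
            continue
        cij = abs(float(c[row.i, row.j]))
        if cij < correlation_floor:
            logger.info(
                "edge %s--%s dropped: |C|=%.2e below floor %.0e",
                nodes.nodes[row.i].label, nodes.nodes[row.j].label,
                cij, correlation_floor,
            )
            continue
        w = -math.log(min(cij, 1.0))
        g.add_edge(row.i, row.j,
                   weight=max(w, 0.0),
                   contact_fraction=float(row.contact_fraction),
                   correlation=float(c[row.i, row.j]))
    return DynamicNetwork(
        nodes=nodes, graph=g, cutoff=cutoff,
        persistence=persistence, correlation_floor=correlation_floor,
    )


def edge_betweenness(network: DynamicNetwork) -> pd.DataFrame:
    """Count of shortest weighted source-target paths crossing each edge.

    Every unordered node pair contributes 1, split equally among
    co-optimal paths; disconnected pairs contribute nothing.
    """
    bc = nx.edge_betweenness_centrality(
        network.graph, normalized=False, weight="weight"
    )
    rows = [
        {
            "node_i": network.nodes.nodes[min(i, j)].label,
            "node_j": network.nodes.nodes[max(i, j)].label,
            "betweenness": val,
        }
        for (i, j), val in bc.items()
    ]
    return pd.DataFrame(
        rows, columns=["node_i", "node_j", "betweenness"]
    ).sort_values("betweenness", ascending=False, ignore_index=True)


def optimal_path(
    network: DynamicNetwork, source_node: str, target_node: str
) -> PathResult:
    """Minimum-total-weight path between two node labels.

    Dijkstra on the non-negative -ln|C| weights; among co-optimal paths
    the lexicographically smallest node-id sequence is returned.  An
    unreachable target yields a ``found=False`` result, not an
    exception.
    """
    src = network.nodes.by_label(source_node).node_id
    tgt = network.nodes.by_label(target_node).node_id
    if src == tgt:
        raise IntegrityError("source and target nodes must differ")
    g = network.graph
    try:
        paths = list(nx.all_shortest_paths(g, src, tgt, weight="weight"))
    except nx.NetworkXNoPath:
        logger.info("no path between %s and %s", source_node, target_node)
        return PathResult(nodes=[], total_weight=math.inf, edge_weights=[],
                          found=False)
    best = min(paths)  # deterministic lexicographic tie-break on node ids
    weights = [g[u][v]["weight"] for u, v in zip(best[:-1], best[1:])]
    return PathResult(
        nodes=[network.nodes.nodes[i].label for i in best],
        total_weight=float(sum(weights)),
        edge_weights=[float(w) for w in weights],
    )
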