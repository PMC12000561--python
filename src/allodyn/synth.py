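"""Synthetic complexes, trajectories and assay data with known ground truth.

Everything the analysis pipeline consumes can be generated here at toy
scale: a coarse protein-DNA-cofactor complex, Gaussian coordinate
fluctuations with a prescribed node covariance (optionally with a
planted high-correlation chain standing in for an allosteric pathway),
exactly scheduled contact persistence fractions, and simulated
glycosylase / binding / rifampicin-resistance assays.

Geometry strategy.  Node groups are compact atom blobs placed on a wide
3D grid (default 12 A spacing) so that undesignated group pairs stay
far outside the 4.5 A contact cutoff.  Each *designated* contact pair
is realized through a single "contact atom": a non-anchor atom of one
group relocated onto the axis between the two anchors, 3.5 A from the
partner anchor.  During sampling that atom is pinned relative to the
partner anchor (3.5 A in contact frames, 6.5 A in scheduled-out
frames), so contact fractions are met exactly and deterministically
while the anchor atoms — the only atoms entering correlations, RMSF and
mode analysis — carry the prescribed Gaussian displacement field,
applied rigidly to the rest of their group.

Per-axis independent application of the node covariance (the same
covariance for x, y and z) makes the generalized dot-product correlation
of the anchors equal the specified correlation matrix in expectation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from allodyn.errors import FeasibilityError, IntegrityError
from allodyn.fitting import (
    GlycosylaseDataset,
    binding_curve,
    mto_curve,
    sto_curve,
)
from allodyn.io import Atom, Topology, Trajectory
from allodyn.network import NodeSet, assign_nodes

logger = logging.getLogger(__name__)

GRID_SPACING = 12.0      # A between undesignated node anchors
CLOSE_SPACING = 10.5     # A between anchors of a designated contact pair
CONTACT_DISTANCE = 3.5   # A, pinned contact-atom distance in contact frames
APART_DISTANCE = 6.5     # A, pinned distance in scheduled-out frames
DEFAULT_NODE_VARIANCE = 0.09  # A^2 per axis (RMSF ~ 0.52 A)

# name -> (element, partial charge e, sigma A, epsilon kcal/mol)
_PARAMS = {
    "N":   ("N", -0.42, 3.25, 0.170),
    "CA":  ("C",  0.03, 3.40, 0.109),
    "C":   ("C",  0.60, 3.40, 0.086),
    "O":   ("O", -0.57, 2.96, 0.210),
    "CB":  ("C", -0.10, 3.40, 0.109),
    "P":   ("P",  1.17, 3.74, 0.200),
    "O5'": ("O", -0.51, 3.00, 0.170),
    "C5'": ("C",  0.06, 3.40, 0.109),
    "C4'": ("C",  0.11, 3.40, 0.109),
    "C3'": ("C",  0.07, 3.40, 0.109),
    "C1'": ("C",  0.04, 3.40, 0.109),
    "N1":  ("N", -0.54, 3.25, 0.170),
    "N3":  ("N", -0.55, 3.25, 0.170),
    "C2":  ("C",  0.37, 3.40, 0.086),
    "C6":  ("C",  0.20, 3.40, 0.086),
    "C4":  ("C",  0.49, 3.40, 0.086),
    "FE":  ("FE", 0.55, 2.60, 0.013),
    "S":   ("S", -0.55, 3.56, 0.250),
}

_PROTEIN_NAMES = ["ALA", "GLY", "SER", "VAL", "THR", "LEU"]
_NUC_NAMES = ["DA", "DT", "DG", "DC"]

# local offsets (A) of each atom from the node anchor, fixed per template
_PROTEIN_ATOMS = [
    ("N", (-1.2, 0.4, 0.0)),
    ("CA", (0.0, 0.0, 0.0)),
    ("C", (1.2, 0.5, 0.2)),
    ("O", (1.5, 1.4, -0.6)),
    ("CB", (-0.3, -1.3, 0.6)),
]
_BACKBONE_ATOMS = [
    ("P", (0.0, 0.0, 0.0)),
    ("O5'", (1.1, 0.8, 0.2)),
    ("C5'", (1.4, -0.7, -0.5)),
    ("C4'", (0.3, -1.4, 0.4)),
    ("C3'", (-1.1, -0.9, 0.6)),
    ("C1'", (-0.9, 1.0, -0.5)),
]
_PURINE_BASE = [("N1", (0.0, 0.0, 0.0)), ("C2", (1.3, 0.4, 0.1)),
                ("C6", (-0.7, 1.1, -0.4))]
_PYRIMIDINE_BASE = [("N3", (0.0, 0.0, 0.0)), ("C2", (1.3, 0.3, 0.2)),
                    ("C4", (-0.8, 1.0, 0.4))]
_COFACTOR_ATOMS = [
    ("FE1", "FE", (0.9, 0.9, 0.9)),
    ("FE2", "FE", (-0.9, -0.9, 0.9)),
    ("FE3", "FE", (-0.9, 0.9, -0.9)),
    ("FE4", "FE", (0.9, -0.9, -0.9)),
    ("S1", "S", (0.9, 0.9, -0.9)),
    ("S2", "S", (-0.9, -0.9, -0.9)),
    ("S3", "S", (-0.9, 0.9, 0.9)),
    ("S4", "S", (0.9, -0.9, 0.9)),
]

# preferred relocatable (non-anchor) atoms per node kind, used as contact atoms
_SPARE_NAMES = {
    "protein": ["CB", "O", "N"],
    "backbone": ["C5'", "O5'", "C3'"],
    "base": ["C2", "C6", "C4"],
    "cofactor": ["S2", "S4", "FE2"],
}


@dataclass
class CovarianceSpec:
    """Prescription for a node covariance with an optional planted chain.

    ``planted_path`` lists node indices whose mutual correlation is set
    to ``planted_correlation`` (compound-symmetric block, which keeps
    the matrix positive semi-definite for realistic levels); all other
    off-diagonal entries take ``background``.  ``node_variance`` is the
    per-axis variance in A^2 (scalar or per-node array).
    """

    n_nodes: int
    background: float = 0.0
    planted_path: tuple[int, ...] = ()
    planted_correlation: float = 0.9
    node_variance: float | np.ndarray = DEFAULT_NODE_VARIANCE
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_nodes < 1:
            raise IntegrityError("n_nodes must be >= 1")
        if not -1 < self.background < 1:
            raise IntegrityError("background correlation must lie in (-1, 1)")
        if self.planted_path and not 0 < self.planted_correlation < 1:
            raise IntegrityError("planted |C| must lie in (0, 1)")
        if any(not 0 <= i < self.n_nodes for i in self.planted_path):
            raise IntegrityError("planted path references unknown nodes")
        var = np.broadcast_to(np.asarray(self.node_variance, dtype=float),
                              (self.n_nodes,))
        if np.any(var <= 0):
            raise IntegrityError("node variances must be positive")


@dataclass
class AssaySpec:
    """True parameters + experimental design for a simulated assay.

    ``kind``: "STO", "MTO", "binding" or "rif".  ``params`` holds the
    ground-truth parameters (k2/k3/a0, kd/bmax, or f), ``design`` the
    schedule (time points, concentrations, plates...), ``noise`` the
    relative noise level.
    """

    kind: str
    params: dict
    design: dict
    noise: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("STO", "MTO", "binding", "rif"):
            raise IntegrityError(f"unknown assay kind {self.kind!r}")
        if self.noise < 0:
            raise IntegrityError("noise level must be >= 0")
        p = self.params
        if self.kind in ("STO", "MTO"):
            if not (p.get("k2", 0) > 0 and p.get("a0", 0) > 0):
                raise IntegrityError("k2 and a0 must be positive")
            if self.kind == "MTO" and not p.get("k3", 0) > 0:
                raise IntegrityError("k3 must be positive for MTO")
        elif self.kind == "binding":
            if not (p.get("kd", 0) > 0 and 0 < p.get("bmax", 0) <= 110):
                raise IntegrityError("kd > 0 and bmax in (0, 110] required")
        elif self.kind == "rif":
            if p.get("f", -1) < 0:
                raise IntegrityError("mutation frequency f must be >= 0")


# ---------------------------------------------------------------------------
# toy complex
# ---------------------------------------------------------------------------

def _grid_positions(n: int, spacing: float) -> np.ndarray:
    """n points on a cubic grid, spacing apart, deterministic order."""
    side = math.ceil(n ** (1 / 3))
    pts = []
    for i in range(n):
        pts.append((i % side, (i // side) % side, i // side**2))
    return np.array(pts, dtype=float) * spacing


def make_toy_complex(
    n_protein_residues: int,
    n_nucleotides: int,
    include_cofactor: bool = True,
    seed: int = 0,
    close_pairs: tuple[tuple[str, str], ...] = (),
    abasic_nucleotides: tuple[int, ...] = (),
) -> tuple[Topology, np.ndarray]:
    """Build a coarse protein-DNA(-cofactor) complex and its reference.

    Protein chain A (5 heavy atoms/residue incl. CA), DNA chain B
    (phosphate+sugar plus a 3-atom base with its ring nitrogen; residues
    listed in ``abasic_nucleotides`` get no base, modelling an AP site),
    optional 8-atom [4Fe-4S]-like cofactor as chain C.  Charges and
    Lennard-Jones parameters come from a small built-in table.

    ``close_pairs`` are pairs of node labels (as produced by node
    assignment, e.g. ``("A:1:ALA", "B:2:DT:base")``) to be placed in
    contact (<= 4.5 A group distance) in the reference; all other group
    pairs end up farther than 8 A apart.  Deterministic given the
    arguments; ``seed`` only perturbs nothing structural and is kept for
    interface uniformity.
    """
    if n_protein_residues < 4:
        raise IntegrityError("need >= 4 protein residues")
    if n_nucleotides < 2:
        raise IntegrityError("need >= 2 nucleotides")
    atoms: list[Atom] = []
    bonds: set[frozenset[int]] = set()
    local: list[np.ndarray] = []  # per-atom local offset
    idx = 0

    def add_atom(name, resi, resn, chain, kind, offset, element=None):
        nonlocal idx
        key = name if name in _PARAMS else name[:-1] if name[:-1] in _PARAMS else name
        el, q, sig, eps = _PARAMS.get(key, ("C", 0.0, 3.4, 0.1))
        atoms.append(Atom(idx, name, element or el, resi, resn, chain, kind,
                          q, sig, eps))
        local.append(np.asarray(offset, dtype=float))
        idx += 1
        return idx - 1

    prev_c = None
    for r in range(1, n_protein_residues + 1):
        resn = _PROTEIN_NAMES[(r - 1) % len(_PROTEIN_NAMES)]
        first = idx
        for name, off in _PROTEIN_ATOMS:
            add_atom(name, r, resn, "A", "protein", off)
        n_i, ca, c_i, o_i, cb = range(first, first + 5)
        bonds |= {frozenset(p) for p in [(n_i, ca), (ca, c_i), (c_i, o_i),
                                         (ca, cb)]}
        if prev_c is not None:
            bonds.add(frozenset((prev_c, n_i)))
        prev_c = c_i

    prev_c3 = None
    for r in range(1, n_nucleotides + 1):
        resn = _NUC_NAMES[(r - 1) % len(_NUC_NAMES)]
        first = idx
        for name, off in _BACKBONE_ATOMS:
            add_atom(name, r, resn, "B", "nucleotide", off)
        p_i, o5, c5, c4s, c3s, c1s = range(first, first + 6)
        bonds |= {frozenset(p) for p in [(p_i, o5), (o5, c5), (c5, c4s),
                                         (c4s, c3s), (c3s, c1s)]}
        if prev_c3 is not None:
            bonds.add(frozenset((prev_c3, p_i)))
        prev_c3 = c3s
        if r not in abasic_nucleotides:
            template = _PURINE_BASE if resn in ("DA", "DG") else _PYRIMIDINE_BASE
            bfirst = idx
            for name, off in template:
                # base sits ~3 A from the sugar so the two node blobs split
                add_atom(name, r, resn, "B", "nucleotide",
                         np.asarray(off) + np.array([0.0, 3.0, 0.0]))
            bonds.add(frozenset((c1s, bfirst)))
            bonds.add(frozenset((bfirst, bfirst + 1)))
            bonds.add(frozenset((bfirst + 1, bfirst + 2)))

    if include_cofactor:
        first = idx
        for name, el, off in _COFACTOR_ATOMS:
            add_atom(name, 1, "SF4", "C", "cofactor", off, element=el)
        ring = [0, 4, 1, 5, 2, 6, 3, 7]
        for a, b in zip(ring, ring[1:] + ring[:1]):
            bonds.add(frozenset((first + a, first + b)))

    topology = Topology(atoms=atoms, bonds=bonds)
    local_arr = np.array(local)
    nodes = assign_nodes(topology)

    # --- anchor layout: contact-pair graph laid out by BFS, rest on a grid
    label_to_node = {n.label: n for n in nodes.nodes}
    for a, b in close_pairs:
        for lab in (a, b):
            if lab not in label_to_node:
                raise IntegrityError(f"close_pairs references unknown node {lab!r}")
    anchor_pos = _layout_anchors(nodes, close_pairs, label_to_node)

    reference = np.empty((topology.n_atoms, 3))
    for n in nodes.nodes:
        for ai in n.node_group:
            reference[ai] = anchor_pos[n.node_id] + (
                local_arr[ai] - local_arr[n.anchor_atom_index]
            )
    # atoms outside every node group (none for the standard toy) stay local
    grouped = set().union(*(n.node_group for n in nodes.nodes))
    for ai in range(topology.n_atoms):
        if ai not in grouped:
            reference[ai] = local_arr[ai]

    # --- realize each designated contact via a relocated spare atom
    used: set[int] = set()
    for a, b in close_pairs:
        na, nb = label_to_node[a], label_to_node[b]
        donor, other = _pick_donor(topology, na, nb, used)
        spare = _pick_spare(topology, donor, used)
        used.add(spare)
        u = anchor_pos[donor.node_id] - anchor_pos[other.node_id]
        u /= np.linalg.norm(u)
        reference[spare] = anchor_pos[other.node_id] + CONTACT_DISTANCE * u
    return topology, reference


def _layout_anchors(nodes: NodeSet, close_pairs, label_to_node) -> np.ndarray:
    """Grid layout; nodes linked by close_pairs chain off their partner."""
    n = len(nodes)
    pos = np.full((n, 3), np.nan)
    adj: dict[int, list[int]] = {}
    for a, b in close_pairs:
        ia, ib = label_to_node[a].node_id, label_to_node[b].node_id
        adj.setdefault(ia, []).append(ib)
        adj.setdefault(ib, []).append(ia)
    grid = iter(_grid_positions(8 * n + 8, GRID_SPACING))
    directions = [np.array(d, dtype=float) for d in
                  [(1, 0, 0), (0, 1, 0), (0, 0, 1), (1, 1, 0), (1, 0, 1),
                   (0, 1, 1), (-1, 1, 0), (1, -1, 0)]]
    placed: list[int] = []

    def ok(p: np.ndarray, allow: set[int]) -> bool:
        return all(
            np.linalg.norm(p - pos[q]) >= GRID_SPACING - 1e-6
            for q in placed if q not in allow
        )

    for start in range(n):
        if not np.isnan(pos[start, 0]):
            continue
        # BFS over the contact-pair component
        while True:
            p = next(grid)
            if ok(p, set(adj.get(start, []))):
                break
        pos[start] = p
        placed.append(start)
        queue = [start]
        while queue:
            u = queue.pop(0)
            for v in adj.get(u, []):
                if not np.isnan(pos[v, 0]):
                    continue
                for d in directions:
                    cand = pos[u] + CLOSE_SPACING * d / np.linalg.norm(d)
                    if ok(cand, set(adj.get(v, [])) | {u}) and all(
                        np.linalg.norm(cand - pos[q]) >= CLOSE_SPACING - 1e-6
                        for q in placed
                    ):
                        pos[v] = cand
                        placed.append(v)
                        queue.append(v)
                        break
                else:
                    raise FeasibilityError(
                        "could not lay out the requested contact-pair graph"
                    )
    return pos


def _pick_donor(topology: Topology, na, nb, used: set[int]):
    """Choose which pair member donates the relocated contact atom."""
    for donor, other in ((nb, na), (na, nb)):
        if _pick_spare(topology, donor, used, required=False) is not None:
            return donor, other
    raise FeasibilityError(
        f"no spare atom available for contact pair {na.label}--{nb.label}"
    )


def _pick_spare(topology: Topology, node, used: set[int], required: bool = True):
    prefer = _SPARE_NAMES.get(node.kind, [])
    members = sorted(node.node_group)
    by_name = {topology.atoms[i].atom_name: i for i in members}
    for name in prefer:
        i = by_name.get(name)
        if i is not None and i not in used and i != node.anchor_atom_index:
            return i
    for i in members:
        if i != node.anchor_atom_index and i not in used:
            return i
    if required:
        raise FeasibilityError(f"node {node.label} has no spare atom left")
    return None


# ---------------------------------------------------------------------------
# covariance construction
# ---------------------------------------------------------------------------

def build_covariance(spec: CovarianceSpec) -> np.ndarray:
    """Node covariance (A^2 per axis) realizing the spec's correlations.

    Builds the target correlation matrix directly (background
    everywhere, a compound-symmetric block at the planted level over the
    planted path), projects to the nearest positive semi-definite matrix
    if round-off requires it, and verifies the planted entries landed
    within 0.01 of the request — otherwise raises
    :class:`FeasibilityError`.
    """
    n = spec.n_nodes
    r = np.full((n, n), float(spec.background))
    np.fill_diagonal(r, 1.0)
    chain = list(spec.planted_path)
    for i in chain:
        for j in chain:
            if i != j:
                r[i, j] = spec.planted_correlation
    evals = np.linalg.eigvalsh(r)
    if evals.min() < -1e-10:
        r_proj = _nearest_correlation(r)
        dev = float(np.abs(r_proj - r).max())
        logger.warning("covariance spec needed PSD projection; max entry "
                       "deviation %.3g", dev)
        if dev > 0.01:
            raise FeasibilityError(
                "requested correlations are incompatible with positive "
                f"semi-definiteness (projection moved entries by {dev:.3g} "
                "> 0.01)"
            )
        r = r_proj
    var = np.broadcast_to(np.asarray(spec.node_variance, dtype=float), (n,))
    sd = np.sqrt(var)
    return r * np.outer(sd, sd)


def _nearest_correlation(r: np.ndarray, iters: int = 100) -> np.ndarray:
    """Alternating projection onto PSD matrices with unit diagonal."""
    y = r.copy()
    ds = np.zeros_like(r)
    for _ in range(iters):
        rk = y - ds
        evals, evecs = np.linalg.eigh(rk)
        x = (evecs * np.clip(evals, 0, None)) @ evecs.T
        ds = x - rk
        y = x.copy()
        np.fill_diagonal(y, 1.0)
        if np.linalg.eigvalsh(y).min() > -1e-12:
            break
    return (y + y.T) / 2


# ---------------------------------------------------------------------------
# trajectory sampling
# ---------------------------------------------------------------------------

def _contact_atom(topology, reference, na, nb) -> tuple[int, "object", "object"]:
    """The designated contact atom of a pair: the non-anchor group atom
    closest to the partner anchor in the reference."""
    best = None
    for host, other in ((na, nb), (nb, na)):
        o_anchor = reference[other.anchor_atom_index]
        for ai in sorted(host.node_group):
            if ai == host.anchor_atom_index:
                continue
            d = float(np.linalg.norm(reference[ai] - o_anchor))
            if best is None or d < best[0]:
                best = (d, ai, host, other)
    if best is None:
        raise FeasibilityError("contact pair has no non-anchor atoms")
    return best[1], best[2], best[3]


def sample_trajectory(
    topology: Topology,
    reference: np.ndarray,
    covariance: np.ndarray,
    n_frames: int,
    contact_schedule: dict[tuple[str, str], float] | None = None,
    seed: int = 0,
    rigid_jitter: float = 0.0,
    cutoff: float = 4.5,
) -> Trajectory:
    """Gaussian node-fluctuation trajectory with exact contact schedules.

    Node anchors are displaced by draws from ``covariance`` applied
    independently per Cartesian axis; all atoms of a node group move
    rigidly with their anchor.  For each scheduled pair the designated
    contact atom is pinned relative to the partner anchor: within the
    contact distance in exactly ``round(fraction * n_frames)`` frames
    (the leading frames — deterministic assignment) and outside the
    cutoff in the rest.  ``rigid_jitter`` > 0 additionally applies a
    random rigid rotation/translation per frame (to exercise
    superposition); it changes no internal distances.
    """
    reference = np.asarray(reference, dtype=float)
    nodes = assign_nodes(topology, reference)
    n = len(nodes)
    covariance = np.asarray(covariance, dtype=float)
    if covariance.shape != (n, n):
        raise IntegrityError(
            f"covariance is {covariance.shape}, node set has {n} nodes"
        )
    rng = np.random.default_rng(seed)
    evals, evecs = np.linalg.eigh((covariance + covariance.T) / 2)
    if evals.min() < -1e-8:
        raise IntegrityError("covariance is not positive semi-definite")
    root = evecs * np.sqrt(np.clip(evals, 0, None))
    # (frames, axis, node) standard normals -> correlated displacements
    z = rng.standard_normal((n_frames, 3, n))
    disp = np.einsum("fan,mn->fma", z, root)  # (frames, node, axis)

    coords = np.repeat(reference[None, :, :], n_frames, axis=0)
    for node in nodes.nodes:
        members = np.array(sorted(node.node_group))
        coords[:, members, :] += disp[:, node.node_id, :][:, None, :]

    for (la, lb), frac in (contact_schedule or {}).items():
        if not 0.0 <= frac <= 1.0:
            raise IntegrityError(f"contact fraction {frac} outside [0, 1]")
        na, nb = nodes.by_label(la), nodes.by_label(lb)
        atom, host, other = _contact_atom(topology, reference, na, nb)
        k = round(frac * n_frames)
        if abs(k / n_frames - frac) > 1e-9:
            logger.warning(
                "contact fraction %.4f not exactly representable over %d "
                "frames; using %.4f", frac, n_frames, k / n_frames,
            )
        axis = coords[:, host.anchor_atom_index, :] - coords[:, other.anchor_atom_index, :]
        axis /= np.linalg.norm(axis, axis=1, keepdims=True)
        dist = np.where(np.arange(n_frames) < k, CONTACT_DISTANCE, APART_DISTANCE)
        coords[:, atom, :] = (
            coords[:, other.anchor_atom_index, :] + dist[:, None] * axis
        )

    if rigid_jitter > 0:
        from scipy.spatial.transform import Rotation

        for f in range(n_frames):
            rot = Rotation.from_rotvec(rigid_jitter * rng.standard_normal(3))
            shift = rigid_jitter * 5.0 * rng.standard_normal(3)
            centroid = coords[f].mean(axis=0)
            coords[f] = (coords[f] - centroid) @ rot.as_matrix().T + centroid + shift
    return Trajectory(coordinates=coords)


def sample_mode_trajectory(
    topology: Topology,
    reference: np.ndarray,
    eigenvalues,
    n_frames: int,
    seed: int = 0,
) -> Trajectory:
    """Trajectory whose 3N node-coordinate covariance has a given spectrum.

    Draws orthonormal mode vectors at random (seeded) over the 3N node
    Cartesian space and displaces each node group rigidly along them
    with independent N(0, eigenvalue) amplitudes — the ground truth for
    mode-contribution recovery (eigenvalue fractions of total motion).
    """
    reference = np.asarray(reference, dtype=float)
    nodes = assign_nodes(topology, reference)
    n3 = 3 * len(nodes)
    lam = np.asarray(eigenvalues, dtype=float)
    if np.any(lam < 0) or lam.size > n3:
        raise IntegrityError("eigenvalues must be >= 0 and at most 3N of them")
    rng = np.random.default_rng(seed)
    q, _ = np.linalg.qr(rng.standard_normal((n3, lam.size)))
    amps = rng.standard_normal((n_frames, lam.size)) * np.sqrt(lam)
    disp = amps @ q.T  # (frames, 3N)
    disp = disp.reshape(n_frames, len(nodes), 3)
    coords = np.repeat(reference[None, :, :], n_frames, axis=0)
    for node in nodes.nodes:
        members = np.array(sorted(node.node_group))
        coords[:, members, :] += disp[:, node.node_id, :][:, None, :]
    return Trajectory(coordinates=coords)


# ---------------------------------------------------------------------------
# assay simulation
# ---------------------------------------------------------------------------

def simulate_glycosylase(spec: AssaySpec) -> GlycosylaseDataset:
    """Exact Scheme curves plus multiplicative Gaussian noise.

    STO: P(t) = A0 (1 - e^{-k2 t}); MTO adds the linear turnover phase
    A0 k3 t.  Design keys: ``time_min`` (array), ``replicates`` (int),
    ``enzyme_nM``, ``substrate_nM``.  Noisy product is clipped into
    [0, substrate].
    """
    if spec.kind not in ("STO", "MTO"):
        raise IntegrityError("simulate_glycosylase needs an STO or MTO spec")
    rng = np.random.default_rng(spec.seed)
    t = np.asarray(spec.design["time_min"], dtype=float)
    reps = int(spec.design.get("replicates", 1))
    enzyme = float(spec.design["enzyme_nM"])
    substrate = float(spec.design["substrate_nM"])
    p = spec.params
    if spec.kind == "STO":
        clean = sto_curve(t, p["a0"], p["k2"])
    else:
        clean = mto_curve(t, p["a0"], p["k2"], p["k3"])
    times, prods, rep_ids = [], [], []
    for rep in range(reps):
        noisy = clean * (1.0 + spec.noise * rng.standard_normal(t.size))
        noisy = np.clip(noisy, 0.0, substrate)
        times.append(t)
        prods.append(noisy)
        rep_ids.append(np.full(t.size, rep))
    return GlycosylaseDataset(
        time_min=np.concatenate(times),
        product_nM=np.concatenate(prods),
        enzyme_nM=enzyme,
        substrate_nM=substrate,
        condition=spec.kind,
        replicate=np.concatenate(rep_ids),
    )


def simulate_binding(spec: AssaySpec) -> tuple[np.ndarray, np.ndarray]:
    """One-site isotherm Y = Bmax X/(KD + X) plus multiplicative noise."""
    if spec.kind != "binding":
        raise IntegrityError("simulate_binding needs a binding spec")
    rng = np.random.default_rng(spec.seed)
    x = np.asarray(spec.design["conc"], dtype=float)
    y = binding_curve(x, spec.params["bmax"], spec.params["kd"])
    y = y * (1.0 + spec.noise * rng.standard_normal(x.size))
    return x, np.clip(y, 0.0, 110.0)


def simulate_rif(spec: AssaySpec) -> tuple[np.ndarray, np.ndarray]:
    """Fluctuation-assay counts for one variant.

    Per plate: resistant ~ Poisson(f * mean viable); viable log-normal
    around the design mean with coefficient of variation
    ``viable_cv``.  Design keys: ``n_plates``, ``viable_mean``,
    ``viable_cv``.
    """
    if spec.kind != "rif":
        raise IntegrityError("simulate_rif needs a rif spec")
    rng = np.random.default_rng(spec.seed)
    n = int(spec.design.get("n_plates", 24))
    viable_mean = float(spec.design["viable_mean"])
    cv = float(spec.design.get("viable_cv", 0.2))
    f = float(spec.params["f"])
    resistant = rng.poisson(f * viable_mean, size=n)
    sigma2 = math.log(1 + cv**2)
    viable = rng.lognormal(
        mean=math.log(viable_mean) - sigma2 / 2, sigma=math.sqrt(sigma2), size=n
    )
    return resistant, viable
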