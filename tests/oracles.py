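"""Independent brute-force oracles used to cross-check the implementation.

Deliberately written with different algorithms/libraries than the
package code paths they validate: plain Python double loops, exhaustive
path enumeration, and stochastic rotation search.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


# --- non-bonded energy: plain double loop -------------------------------

def bond_graph_distance(n_atoms: int, bonds, i: int, j: int, max_depth: int = 3):
    """Bond-graph separation up to max_depth via breadth-first search."""
    adj = {k: set() for k in range(n_atoms)}
    for b in bonds:
        a, c = tuple(b)
        adj[a].add(c)
        adj[c].add(a)
    frontier, seen = {i}, {i}
    for depth in range(1, max_depth + 1):
        frontier = {v for u in frontier for v in adj[u]} - seen
        if j in frontier:
            return depth
        seen |= frontier
    return None


def brute_force_energy(frame, topology, frag_indices, scale_ee, scale_nb,
                       k_e=332.0636):
    """Fragment-environment Coulomb and LJ sums for one frame."""
    frag = set(frag_indices)
    coul = vdw = 0.0
    for i in frag:
        ai = topology.atoms[i]
        for j in range(topology.n_atoms):
            if j in frag:
                continue
            aj = topology.atoms[j]
            d = bond_graph_distance(topology.n_atoms, topology.bonds, i, j)
            if d in (1, 2):
                continue
            fee = scale_ee if d == 3 else 1.0
            fnb = scale_nb if d == 3 else 1.0
            r = math.dist(frame[i], frame[j])
            coul += fee * k_e * ai.partial_charge * aj.partial_charge / r
            sij = 0.5 * (ai.lj_sigma + aj.lj_sigma)
            eij = math.sqrt(ai.lj_epsilon * aj.lj_epsilon)
            vdw += fnb * 4 * eij * ((sij / r) ** 12 - (sij / r) ** 6)
    return coul, vdw


# --- graphs: exhaustive enumeration -------------------------------------

def all_simple_paths(edges: dict, source, target):
    """All simple paths in an undirected weighted graph given as
    {frozenset((u, v)): weight}."""
    adj: dict = {}
    for e in edges:
        u, v = tuple(e)
        adj.setdefault(u, set()).add(v)
        adj.setdefault(v, set()).add(u)
    out = []

    def dfs(node, path):
        if node == target:
            out.append(list(path))
            return
        for nxt in adj.get(node, ()):
            if nxt not in path:
                path.append(nxt)
                dfs(nxt, path)
                path.pop()

    if source in adj and target in adj:
        dfs(source, [source])
    return out


def path_weight(edges: dict, path):
    return sum(edges[frozenset((u, v))] for u, v in zip(path[:-1], path[1:]))


def enumerate_optimal_paths(edges: dict, source, target, tol=1e-12):
    """All minimum-weight simple paths between two nodes."""
    paths = all_simple_paths(edges, source, target)
    if not paths:
        return [], math.inf
    weights = [path_weight(edges, p) for p in paths]
    best = min(weights)
    return [p for p, w in zip(paths, weights) if w <= best + tol], best


def enumerate_edge_betweenness(edges: dict, nodes):
    """Edge betweenness by enumerating every pair's co-optimal paths,
    splitting ties equally."""
    bc = {e: 0.0 for e in edges}
    for s, t in itertools.combinations(nodes, 2):
        opt, best = enumerate_optimal_paths(edges, s, t)
        if not opt:
            continue
        share = 1.0 / len(opt)
        for p in opt:
            for u, v in zip(p[:-1], p[1:]):
                bc[frozenset((u, v))] += share
    return bc


# --- rotations: stochastic search + local refinement --------------------

def min_rmsd_over_rotations(mobile, target, n_samples=4000, seed=0):
    """Minimum RMSD of mobile onto target over all proper rotations,
    found by dense random sampling plus Nelder-Mead refinement."""
    from scipy.optimize import minimize
    from scipy.spatial.transform import Rotation

    mobile = mobile - mobile.mean(axis=0)
    target = target - target.mean(axis=0)

    def rmsd_of(rotvec):
        rot = Rotation.from_rotvec(rotvec).as_matrix()
        d = mobile @ rot.T - target
        return float(np.sqrt((d**2).sum(axis=1).mean()))

    rng = np.random.default_rng(seed)
    samples = Rotation.random(n_samples, rng=rng).as_rotvec()
    best = min(samples, key=rmsd_of)
    res = minimize(rmsd_of, best, method="Nelder-Mead",
                   options={"xatol": 1e-10, "fatol": 1e-14, "maxiter": 5000})
    return float(res.fun)
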