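"""Per-fragment non-bonded interaction energies.

For a reference fragment, sums Coulomb and Lennard-Jones pair energies
between every fragment atom and every atom outside the fragment, frame
by frame, and attributes each pair's energy to the partner residue.

Conventions (AMBER family):

* Coulomb constant k_e = 332.0636 kcal A mol^-1 e^-2, vacuum dielectric;
* Lennard-Jones 4*eps*[(sig/r)^12 - (sig/r)^6] with Lorentz-Berthelot
  combining (arithmetic sigma, geometric epsilon);
* 1-2 and 1-3 bonded pairs excluded; 1-4 pairs scaled by 1/1.2
  (electrostatics) and 1/2 (Lennard-Jones) — both scalings configurable;
* no distance cutoff by default (systems are small and solvent-free).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from allodyn.errors import IntegrityError, SingularityError
from allodyn.io import Fragment, Topology, Trajectory

logger = logging.getLogger(__name__)

COULOMB_CONSTANT = 332.0636  # kcal * A / (mol * e^2)
SCEE = 1.0 / 1.2  # 1-4 electrostatic scale
SCNB = 0.5       # 1-4 Lennard-Jones scale


@dataclass
class EnergyTable:
    """Fragment-vs-environment interaction energies (kcal/mol).

    ``frames``: DataFrame (frame, coulomb_kcal_mol, vdw_kcal_mol, total);
    ``per_partner``: DataFrame of frame-mean energies attributed to each
    partner residue (partner_chain, partner_resi, partner_resn,
    coulomb_kcal_mol, vdw_kcal_mol, total).
    """

    fragment_label: str
    frames: pd.DataFrame
    per_partner: pd.DataFrame

    def __post_init__(self) -> None:
        f = self.frames
        if not np.allclose(
            f["total"], f["coulomb_kcal_mol"] + f["vdw_kcal_mol"], atol=1e-10
        ):
            raise IntegrityError("total != coulomb + vdw in frame table")
        if len(self.per_partner) and abs(
            self.per_partner["total"].sum() - self.mean_total
        ) > 1e-8 * max(1.0, abs(self.mean_total)):
            raise IntegrityError("partner breakdown does not sum to the total")

    @property
    def mean_coulomb(self) -> float:
        return float(self.frames["coulomb_kcal_mol"].mean())

    @property
    def mean_vdw(self) -> float:
        return float(self.frames["vdw_kcal_mol"].mean())

    @property
    def mean_total(self) -> float:
        return float(self.frames["total"].mean())

    def standard_errors(self) -> dict[str, float]:
        n = len(self.frames)
        if n < 2:
            return {"coulomb_kcal_mol": 0.0, "vdw_kcal_mol": 0.0, "total": 0.0}
        return {
            c: float(self.frames[c].std(ddof=1) / np.sqrt(n))
            for c in ("coulomb_kcal_mol", "vdw_kcal_mol", "total")
        }


@dataclass
class DeltaEnergyTable:
    """Per-partner mutant-minus-wild-type energy differences (kcal/mol)."""

    entries: pd.DataFrame  # partner_chain, partner_resi, dE_kcal_mol, flag
    total: float = field(default=0.0)

    def __post_init__(self) -> None:
        s = float(self.entries["dE_kcal_mol"].sum()) if len(self.entries) else 0.0
        if abs(s - self.total) > 1e-10 * max(1.0, abs(s)):
            raise IntegrityError("delta-energy sum field inconsistent")


# ---------------------------------------------------------------------------
# pair bookkeeping
# ---------------------------------------------------------------------------

def _bonded_distances(topology: Topology) -> dict[frozenset[int], int]:
    """Map atom pairs to bond-graph distance 1, 2 or 3 (1-2/1-3/1-4)."""
    adj: dict[int, set[int]] = {i: set() for i in range(topology.n_atoms)}
    for b in topology.bonds:
        i, j = tuple(b)
        adj[i].add(j)
        adj[j].add(i)
    out: dict[frozenset[int], int] = {}
    for start in range(topology.n_atoms):
        seen = {start: 0}
        frontier = [start]
        for depth in (1, 2, 3):
            nxt = []
            for u in frontier:
                for v in adj[u]:
                    if v not in seen:
                        seen[v] = depth
                        nxt.append(v)
            frontier = nxt
        for v, d in seen.items():
            if v > start:
                key = frozenset((start, v))
                if key not in out or d < out[key]:
                    out[key] = d
    return out


def _pair_energies(
    trajectory: Trajectory,
    topology: Topology,
    pairs_i: np.ndarray,
    pairs_j: np.ndarray,
    scale_ee: float,
    scale_nb: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-frame, per-pair Coulomb and LJ energies with exclusions applied."""
    q = topology.charges()
    sig, eps = topology.lj_params()
    bd = _bonded_distances(topology)
    dists = np.array(
        [bd.get(frozenset((int(i), int(j))), 0) for i, j in zip(pairs_i, pairs_j)]
    )
    ee_scale = np.where(dists == 0, 1.0, np.where(dists == 3, scale_ee, 0.0))
    nb_scale = np.where(dists == 0, 1.0, np.where(dists == 3, scale_nb, 0.0))

    xyz = trajectory.coordinates
    d = xyz[:, pairs_i, :] - xyz[:, pairs_j, :]
    r = np.sqrt((d**2).sum(axis=2))  # (frames, pairs)
    close = np.argwhere(r < 1e-6)
    if close.size:
        f, p = close[0]
        raise SingularityError(
            f"atoms {int(pairs_i[p])} and {int(pairs_j[p])} overlap "
            f"(r < 1e-6 A) in frame {int(f)}"
        )
    coul = COULOMB_CONSTANT * q[pairs_i] * q[pairs_j] / r * ee_scale
    sij = 0.5 * (sig[pairs_i] + sig[pairs_j])
    eij = np.sqrt(eps[pairs_i] * eps[pairs_j])
    sr6 = (sij / r) ** 6
    vdw = 4.0 * eij * (sr6**2 - sr6) * nb_scale
    return coul, vdw


def fragment_interaction_energy(
    trajectory: Trajectory,
    topology: Topology,
    fragment: Fragment,
    scale_ee: float = SCEE,
    scale_nb: float = SCNB,
    cutoff: float | None = None,
) -> EnergyTable:
    """Non-bonded interaction energy between a fragment and the rest.

    Sums over all pairs (i in fragment, j outside), per frame, and
    attributes each pair to the residue owning atom j.  ``cutoff``
    (Angstrom), if given, zeroes pairs beyond it per frame; default is
    an exact all-pair sum.
    """
    frag_idx = fragment.sorted_indices()
    if np.any(frag_idx >= topology.n_atoms):
        raise IntegrityError("fragment references atoms outside the topology")
    env_idx = np.array(
        [i for i in range(topology.n_atoms) if i not in fragment.atom_indices],
        dtype=int,
    )
    logger.info(
        "EDA fragment %r: %d fragment atoms vs %d environment atoms; "
        "1-4 scaling ee=%.4f nb=%.4f cutoff=%s",
        fragment.label, len(frag_idx), len(env_idx), scale_ee, scale_nb, cutoff,
    )
    n_frames = trajectory.n_frames
    if env_idx.size == 0:
        frames = pd.DataFrame(
            {"frame": np.arange(n_frames), "coulomb_kcal_mol": 0.0,
             "vdw_kcal_mol": 0.0, "total": 0.0}
        )
        partners = pd.DataFrame(
            columns=["partner_chain", "partner_resi", "partner_resn",
                     "coulomb_kcal_mol", "vdw_kcal_mol", "total"]
        )
        return EnergyTable(fragment.label, frames, partners)

    pairs_i = np.repeat(frag_idx, env_idx.size)
    pairs_j = np.tile(env_idx, frag_idx.size)
    coul, vdw = _pair_energies(
        trajectory, topology, pairs_i, pairs_j, scale_ee, scale_nb
    )
    if cutoff is not None:
        xyz = trajectory.coordinates
        r = np.sqrt(
            ((xyz[:, pairs_i, :] - xyz[:, pairs_j, :]) ** 2).sum(axis=2)
        )
        mask = r <= cutoff
        coul = coul * mask
        vdw = vdw * mask

    frames = pd.DataFrame(
        {
            "frame": np.arange(n_frames),
            "coulomb_kcal_mol": coul.sum(axis=1),
            "vdw_kcal_mol": vdw.sum(axis=1),
        }
    )
    frames["total"] = frames["coulomb_kcal_mol"] + frames["vdw_kcal_mol"]

    # partner attribution: the residue owning atom j
    keys = [topology.atoms[j].residue_key for j in pairs_j]
    part = pd.DataFrame(
        {
            "partner_chain": [k[0] for k in keys],
            "partner_resi": [k[1] for k in keys],
            "partner_resn": [topology.atoms[j].residue_name for j in pairs_j],
            "coulomb_kcal_mol": coul.mean(axis=0),
            "vdw_kcal_mol": vdw.mean(axis=0),
        }
    )
    partners = (
        part.groupby(["partner_chain", "partner_resi", "partner_resn"],
                     as_index=False)
        .sum()
        .sort_values(["partner_chain", "partner_resi"], ignore_index=True)
    )
    partners["total"] = partners["coulomb_kcal_mol"] + partners["vdw_kcal_mol"]
    return EnergyTable(fragment.label, frames, partners)


def per_residue_energy_profile(
    trajectory: Trajectory,
    topology: Topology,
    fragment: Fragment,
    **kwargs,
) -> pd.DataFrame:
    """Partner-residue breakdown of the fragment interaction energy."""
    return fragment_interaction_energy(
        trajectory, topology, fragment, **kwargs
    ).per_partner


def delta_energy(
    table_mut: EnergyTable,
    table_wt: EnergyTable,
    partner_mapping: dict[tuple[str, int], tuple[str, int]] | None = None,
) -> DeltaEnergyTable:
    """Per-partner E_mutant - E_wild-type differences.

    ``partner_mapping`` maps mutant residue keys to wild-type keys;
    identity by (chain, residue index) when omitted.  Partners present
    in only one system contribute with the missing side as 0 and are
    flagged ``mutant_only`` / ``wt_only``.
    """
    def keyed(tab: EnergyTable) -> dict[tuple[str, int], float]:
        return {
            (r.partner_chain, int(r.partner_resi)): float(r.total)
            for r in tab.per_partner.itertuples()
        }

    mut = keyed(table_mut)
    wt = keyed(table_wt)
    mapping = partner_mapping or {}
    for src in mapping:
        if src not in mut:
            raise IntegrityError(
                f"partner mapping lists unknown mutant residue {src}"
            )
    rows = []
    wt_seen = set()
    for key, e_mut in mut.items():
        wt_key = mapping.get(key, key)
        if wt_key in wt:
            rows.append((key, e_mut - wt[wt_key], "both"))
            wt_seen.add(wt_key)
        else:
            rows.append((key, e_mut, "mutant_only"))
    for key, e_wt in wt.items():
        if key not in wt_seen:
            rows.append((key, -e_wt, "wt_only"))
    entries = pd.DataFrame(
        {
            "partner_chain": [k[0] for k, _, _ in rows],
            "partner_resi": [k[1] for k, _, _ in rows],
            "dE_kcal_mol": [d for _, d, _ in rows],
            "flag": [f for _, _, f in rows],
        }
    ).sort_values(["partner_chain", "partner_resi"], ignore_index=True)
    return DeltaEnergyTable(entries=entries,
                            total=float(entries["dE_kcal_mol"].sum()))
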