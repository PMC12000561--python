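"""Core data model and file formats.

A complex is described by two files:

* a **topology sidecar** (YAML) carrying per-atom metadata the PDB format
  cannot hold — partial charges (e) and Lennard-Jones parameters
  (sigma in Angstrom, epsilon in kcal/mol) — plus bonds;
* a **multi-model PDB** (MODEL/ENDMDL, fixed columns) carrying one
  coordinate frame per model, in Angstrom.

A compact whitespace-delimited frames file (``.frames``) is accepted as an
alternative trajectory container for large synthetic runs: a header line
``# allodyn-frames n_atoms=<N>`` followed by one frame per line
(``3*N`` floats, atom-major ``x y z x y z ...``).

Units are by convention, never converted implicitly: coordinates in
Angstrom, charges in elementary charge, energies in kcal/mol, times in
ps (trajectories) or min (assays). Residue numbering is 1-based as in
PDB; atom indexing is 0-based internally.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from allodyn.errors import (
    FrameError,
    IntegrityError,
    SchemaError,
    SelectionError,
)

TOPOLOGY_FORMAT_VERSION = 1

RESIDUE_KINDS = ("protein", "nucleotide", "cofactor", "ion", "solvent")

_ATOM_FIELDS = (
    "atom_index",
    "atom_name",
    "element",
    "residue_index",
    "residue_name",
    "chain_id",
    "residue_kind",
    "partial_charge",
    "lj_sigma",
    "lj_epsilon",
)


@dataclass(frozen=True)
class Atom:
    """One atom with force-field metadata.

    ``partial_charge`` in elementary charge, ``lj_sigma`` in Angstrom,
    ``lj_epsilon`` in kcal/mol.
    """

    atom_index: int
    atom_name: str
    element: str
    residue_index: int
    residue_name: str
    chain_id: str
    residue_kind: str
    partial_charge: float
    lj_sigma: float
    lj_epsilon: float

    @property
    def residue_key(self) -> tuple[str, int]:
        return (self.chain_id, self.residue_index)


@dataclass
class Topology:
    """Static description of the complex: atoms plus bonds.

    Invariants (checked by :meth:`validate`): atom indices unique and
    contiguous from 0, bond endpoints exist, lj_sigma > 0,
    lj_epsilon >= 0, residues identified uniquely by
    ``(chain_id, residue_index)``.
    """

    atoms: list[Atom]
    bonds: set[frozenset[int]] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.bonds = {frozenset(b) for b in self.bonds}
        self.validate()

    # -- invariants ----------------------------------------------------
    def validate(self) -> None:
        if not self.atoms:
            raise IntegrityError("topology must contain at least one atom")
        indices = [a.atom_index for a in self.atoms]
        if len(set(indices)) != len(indices):
            dup = sorted({i for i in indices if indices.count(i) > 1})
            raise IntegrityError(f"duplicate atom indices: {dup}")
        if sorted(indices) != list(range(len(indices))):
            raise IntegrityError(
                "atom indices must be contiguous from 0, got "
                f"min={min(indices)} max={max(indices)} n={len(indices)}"
            )
        if indices != sorted(indices):
            raise IntegrityError("atoms must be listed in index order")
        for a in self.atoms:
            if a.residue_kind not in RESIDUE_KINDS:
                raise IntegrityError(
                    f"atom {a.atom_index}: unknown residue_kind "
                    f"{a.residue_kind!r} (expected one of {RESIDUE_KINDS})"
                )
            if not a.lj_sigma > 0:
                raise IntegrityError(f"atom {a.atom_index}: lj_sigma must be > 0")
            if a.lj_epsilon < 0:
                raise IntegrityError(f"atom {a.atom_index}: lj_epsilon must be >= 0")
        for b in self.bonds:
            if len(b) != 2:
                raise IntegrityError(f"bond {sorted(b)} is not a pair")
            for i in b:
                if not 0 <= i < len(self.atoms):
                    raise IntegrityError(f"bond references missing atom {i}")
        # one residue_kind / residue_name per residue key
        kinds: dict[tuple[str, int], tuple[str, str]] = {}
        for a in self.atoms:
            seen = kinds.setdefault(a.residue_key, (a.residue_name, a.residue_kind))
            if seen != (a.residue_name, a.residue_kind):
                raise IntegrityError(
                    f"residue {a.residue_key} has inconsistent name/kind"
                )

    # -- convenience ---------------------------------------------------
    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def residues(self) -> list[tuple[tuple[str, int], list[Atom]]]:
        """Residues in order of first appearance, as (key, atoms) pairs."""
        order: dict[tuple[str, int], list[Atom]] = {}
        for a in self.atoms:
            order.setdefault(a.residue_key, []).append(a)
        return list(order.items())

    def charges(self) -> np.ndarray:
        return np.array([a.partial_charge for a in self.atoms])

    def lj_params(self) -> tuple[np.ndarray, np.ndarray]:
        return (
            np.array([a.lj_sigma for a in self.atoms]),
            np.array([a.lj_epsilon for a in self.atoms]),
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Topology):
            return NotImplemented
        return self.atoms == other.atoms and self.bonds == other.bonds


@dataclass
class Trajectory:
    """Coordinate frames (n_frames, n_atoms, 3) in Angstrom."""

    coordinates: np.ndarray
    frame_times: np.ndarray | None = None  # ps

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 3 or self.coordinates.shape[2] != 3:
            raise IntegrityError(
                f"coordinates must have shape (n_frames, n_atoms, 3), "
                f"got {self.coordinates.shape}"
            )
        if self.coordinates.shape[0] < 1:
            raise IntegrityError("trajectory needs at least one frame")
        if not np.all(np.isfinite(self.coordinates)):
            raise IntegrityError("non-finite coordinates")
        if self.frame_times is not None:
            self.frame_times = np.asarray(self.frame_times, dtype=float)
            if self.frame_times.shape != (self.coordinates.shape[0],):
                raise IntegrityError("frame_times length must match n_frames")

    @property
    def n_frames(self) -> int:
        return self.coordinates.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[1]


@dataclass(frozen=True)
class Fragment:
    """A labelled, non-empty set of atom indices within a Topology."""

    label: str
    atom_indices: frozenset[int]

    def __post_init__(self) -> None:
        object.__setattr__(self, "atom_indices", frozenset(self.atom_indices))
        if not self.atom_indices:
            raise IntegrityError(f"fragment {self.label!r} is empty")

    def sorted_indices(self) -> np.ndarray:
        return np.array(sorted(self.atom_indices), dtype=int)


# ---------------------------------------------------------------------------
# Topology sidecar (YAML)
# ---------------------------------------------------------------------------

def write_topology(topology: Topology, path: str | Path) -> None:
    """Write a Topology to its YAML sidecar; round-trips exactly."""
    doc = {
        "format_version": TOPOLOGY_FORMAT_VERSION,
        "atoms": [
            {f: getattr(a, f) for f in _ATOM_FIELDS} for a in topology.atoms
        ],
        "bonds": sorted(sorted(b) for b in topology.bonds),
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def read_topology(path: str | Path) -> Topology:
    """Read and validate a topology sidecar.

    Raises :class:`SchemaError` naming the offending field/atom on a
    malformed file and :class:`IntegrityError` on invariant violations.
    """
    path = Path(path)
    try:
        doc = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise SchemaError(f"{path}: not valid YAML: {exc}") from exc
    if not isinstance(doc, dict):
        raise SchemaError(f"{path}: topology file must be a mapping")
    for key in ("format_version", "atoms"):
        if key not in doc:
            raise SchemaError(f"{path}: missing mandatory key {key!r}")
    if doc["format_version"] != TOPOLOGY_FORMAT_VERSION:
        raise SchemaError(
            f"{path}: unsupported format_version {doc['format_version']!r}"
        )
    atoms = []
    for pos, rec in enumerate(doc["atoms"]):
        if not isinstance(rec, dict):
            raise SchemaError(f"{path}: atom entry {pos} is not a mapping")
        missing = [f for f in _ATOM_FIELDS if f not in rec]
        if missing:
            raise SchemaError(
                f"{path}: atom entry {pos} "
                f"(atom_index={rec.get('atom_index', '?')}) missing "
                f"mandatory field(s) {missing}"
            )
        unknown = [k for k in rec if k not in _ATOM_FIELDS]
        if unknown:
            raise SchemaError(
                f"{path}: atom entry {pos} has unknown field(s) {unknown}"
            )
        try:
            atoms.append(
                Atom(
                    atom_index=int(rec["atom_index"]),
                    atom_name=str(rec["atom_name"]),
                    element=str(rec["element"]),
                    residue_index=int(rec["residue_index"]),
                    residue_name=str(rec["residue_name"]),
                    chain_id=str(rec["chain_id"]),
                    residue_kind=str(rec["residue_kind"]),
                    partial_charge=float(rec["partial_charge"]),
                    lj_sigma=float(rec["lj_sigma"]),
                    lj_epsilon=float(rec["lj_epsilon"]),
                )
            )
        except (TypeError, ValueError) as exc:
            raise SchemaError(f"{path}: atom entry {pos}: {exc}") from exc
    bonds = set()
    for b in doc.get("bonds", []):
        if not isinstance(b, (list, tuple)) or len(b) != 2:
            raise SchemaError(f"{path}: bond entry {b!r} is not an index pair")
        bonds.add(frozenset(int(i) for i in b))
    return Topology(atoms=atoms, bonds=bonds)


# ---------------------------------------------------------------------------
# Trajectory (multi-model PDB and compact frames)
# ---------------------------------------------------------------------------

def _pdb_atom_line(atom: Atom, xyz: np.ndarray, serial: int) -> str:
    record = "ATOM  " if atom.residue_kind == "protein" or atom.residue_kind == "nucleotide" else "HETATM"
    name = atom.atom_name
    # PDB convention: 1-3 char names start in column 14
    name_field = f" {name:<3s}" if len(name) < 4 else f"{name:<4s}"
    return (
        f"{record}{serial:5d} {name_field} {atom.residue_name:<3.3s} "
        f"{atom.chain_id:1.1s}{atom.residue_index:4d}    "
        f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}"
        f"{1.00:6.2f}{0.00:6.2f}          {atom.element:>2.2s}"
    )


def write_trajectory(
    trajectory: Trajectory, topology: Topology, path: str | Path
) -> None:
    """Write frames as multi-model PDB (``.pdb``) or compact frames file."""
    path = Path(path)
    if trajectory.n_atoms != topology.n_atoms:
        raise FrameError(
            f"trajectory has {trajectory.n_atoms} atoms, topology "
            f"{topology.n_atoms}"
        )
    if path.suffix == ".frames":
        with path.open("w") as fh:
            fh.write(f"# allodyn-frames n_atoms={topology.n_atoms}\n")
            for frame in trajectory.coordinates:
                fh.write(" ".join(f"{v:.6f}" for v in frame.ravel()) + "\n")
        return
    lines: list[str] = []
    for m, frame in enumerate(trajectory.coordinates, start=1):
        lines.append(f"MODEL     {m:4d}")
        for a in topology.atoms:
            lines.append(_pdb_atom_line(a, frame[a.atom_index], a.atom_index + 1))
        lines.append("ENDMDL")
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")


def read_trajectory(path: str | Path, topology: Topology) -> Trajectory:
    """Read a trajectory and check every frame against the topology.

    Multi-model PDB: one frame per MODEL record; a file without MODEL
    records is treated as a single frame. Coordinates are read from the
    fixed columns at 0.001 A precision. An atom-count mismatch raises
    :class:`FrameError` citing the model number.
    """
    path = Path(path)
    if path.suffix == ".frames":
        return _read_frames_file(path, topology)
    frames: list[list[tuple[float, float, float]]] = []
    current: list[tuple[float, float, float]] | None = None
    saw_model = False
    model_number = 0
    for line in path.read_text().splitlines():
        rec = line[:6]
        if rec == "MODEL ":
            saw_model = True
            if current:
                _check_frame(current, topology, model_number)
                frames.append(current)
            model_number = int(line[6:].split()[0]) if line[6:].strip() else model_number + 1
            current = []
        elif rec in ("ATOM  ", "HETATM"):
            if current is None:
                current = []
            try:
                xyz = (float(line[30:38]), float(line[38:46]), float(line[46:54]))
            except ValueError as exc:
                raise FrameError(
                    f"{path}: unparsable coordinates in model "
                    f"{model_number or 1}: {line!r}"
                ) from exc
            current.append(xyz)
        elif rec == "ENDMDL":
            if current is not None:
                _check_frame(current, topology, model_number)
                frames.append(current)
                current = None
    if current:
        _check_frame(current, topology, model_number if saw_model else 1)
        frames.append(current)
    if not frames:
        raise FrameError(f"{path}: no coordinate records found")
    return Trajectory(coordinates=np.array(frames, dtype=float))


def _check_frame(atoms: list, topology: Topology, model_number: int) -> None:
    if len(atoms) != topology.n_atoms:
        raise FrameError(
            f"model {max(model_number, 1)}: {len(atoms)} atoms, "
            f"topology expects {topology.n_atoms}"
        )


def _read_frames_file(path: Path, topology: Topology) -> Trajectory:
    with path.open() as fh:
        header = fh.readline()
        m = re.match(r"#\s*allodyn-frames\s+n_atoms=(\d+)", header)
        if not m:
            raise SchemaError(f"{path}: missing allodyn-frames header")
        n_atoms = int(m.group(1))
        if n_atoms != topology.n_atoms:
            raise FrameError(
                f"{path}: frames file has {n_atoms} atoms, topology "
                f"{topology.n_atoms}"
            )
        data = np.loadtxt(fh, ndmin=2)
    if data.shape[1] != 3 * n_atoms:
        raise FrameError(
            f"{path}: expected {3 * n_atoms} values per frame, "
            f"got {data.shape[1]}"
        )
    return Trajectory(coordinates=data.reshape(-1, n_atoms, 3))


# ---------------------------------------------------------------------------
# Fragment selection
# ---------------------------------------------------------------------------

_SELECTOR_KEYS = ("chain", "resi", "kind", "name", "resn")


def select_fragment(topology: Topology, selector: str) -> Fragment:
    """Select atoms by a small AND-combined clause grammar.

    Grammar: whitespace-separated ``key value`` clauses, all of which an
    atom must satisfy.  Keys: ``chain <id>``, ``resi <n>`` or
    ``resi <a>-<b>`` (1-based inclusive range), ``kind <residue_kind>``,
    ``resn <residue_name>``, ``name <atom_name>``.  Values may be
    comma-separated alternatives (OR within a clause).

    Examples: ``"chain A resi 241"``, ``"kind cofactor"``,
    ``"name CA,P"``.
    """
    tokens = selector.split()
    if not tokens or len(tokens) % 2 != 0:
        raise SelectionError(
            f"malformed selector {selector!r}: expected 'key value' pairs"
        )
    clauses: list[tuple[str, str]] = []
    for key, value in zip(tokens[::2], tokens[1::2]):
        if key not in _SELECTOR_KEYS:
            raise SelectionError(
                f"malformed selector {selector!r}: unknown key {key!r} "
                f"(expected one of {_SELECTOR_KEYS})"
            )
        clauses.append((key, value))
    matched = [
        a.atom_index
        for a in topology.atoms
        if all(_clause_matches(a, k, v, selector) for k, v in clauses)
    ]
    if not matched:
        raise SelectionError(f"selector {selector!r} matched no atoms")
    return Fragment(label=selector, atom_indices=frozenset(matched))


def _clause_matches(atom: Atom, key: str, value: str, selector: str) -> bool:
    alternatives = value.split(",")
    if key == "chain":
        return atom.chain_id in alternatives
    if key == "kind":
        for alt in alternatives:
            if alt not in RESIDUE_KINDS:
                raise SelectionError(
                    f"malformed selector {selector!r}: unknown kind {alt!r}"
                )
        return atom.residue_kind in alternatives
    if key == "name":
        return atom.atom_name in alternatives
    if key == "resn":
        return atom.residue_name in alternatives
    # resi: single index or inclusive range a-b
    for alt in alternatives:
        m = re.fullmatch(r"(-?\d+)(?:-(-?\d+))?", alt)
        if not m:
            raise SelectionError(
                f"malformed selector {selector!r}: bad residue index {alt!r}"
            )
        lo = int(m.group(1))
        hi = int(m.group(2)) if m.group(2) else lo
        if lo <= atom.residue_index <= hi:
            return True
    return False


# ---------------------------------------------------------------------------
# Assay tables (CSV)
# ---------------------------------------------------------------------------

def read_assay_csv(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    """Read an assay CSV and check the documented header columns."""
    df = pd.read_csv(path)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")
    return df
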