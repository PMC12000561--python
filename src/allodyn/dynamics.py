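"""Trajectory geometry and fluctuation analysis.

Superposition (Kabsch, proper rotations only), RMSD/RMSF, node-motion
correlation matrices, and PCA of coordinate fluctuations ("essential
dynamics").  Mode contributions are reported as eigenvalue fractions of
the 3N x 3N node-coordinate covariance — the quantity usually quoted as
"mode k contributes x% of the overall motion".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from allodyn.errors import DegeneracyError, InsufficientDataError, IntegrityError
from allodyn.io import Fragment, Trajectory

logger = logging.getLogger(__name__)


@dataclass
class CorrelationMatrix:
    """Normalized node-fluctuation correlations C_ij in [-1, 1]."""

    matrix: np.ndarray
    labels: list[str]

    def __post_init__(self) -> None:
        c = np.asarray(self.matrix, dtype=float)
        n = c.shape[0]
        if c.shape != (n, n) or n != len(self.labels):
            raise IntegrityError("correlation matrix / label shape mismatch")
        if not np.allclose(c, c.T, atol=1e-10):
            raise IntegrityError("correlation matrix not symmetric")
        if not np.allclose(np.diag(c), 1.0, atol=1e-10):
            raise IntegrityError("correlation diagonal must be 1")
        if np.any(np.abs(c) > 1 + 1e-12):
            raise IntegrityError("correlation entries must lie in [-1, 1]")
        # snap round-off outside [-1, 1] and enforce exact symmetry/diagonal
        c = np.clip((c + c.T) / 2.0, -1.0, 1.0)
        np.fill_diagonal(c, 1.0)
        self.matrix = c

    @property
    def n_nodes(self) -> int:
        return self.matrix.shape[0]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.matrix, index=self.labels, columns=self.labels)


@dataclass
class ModeSpectrum:
    """Eigen-decomposition of the node-coordinate covariance.

    ``eigenvalues`` (A^2) descending and non-negative; ``fractions``
    = eigenvalue / trace; ``eigenvectors`` columns are orthonormal over
    the 3N node Cartesian coordinates.
    """

    eigenvalues: np.ndarray
    fractions: np.ndarray
    eigenvectors: np.ndarray
    labels: list[str]

    def __post_init__(self) -> None:
        ev = np.asarray(self.eigenvalues, dtype=float)
        fr = np.asarray(self.fractions, dtype=float)
        if np.any(np.diff(ev) > 1e-12):
            raise IntegrityError("eigenvalues must be sorted descending")
        if np.any(ev < 0):
            raise IntegrityError("eigenvalues must be non-negative")
        if np.any(fr < 0) or abs(fr.sum() - 1.0) > 1e-10:
            raise IntegrityError("fractions must be non-negative and sum to 1")
        gram = self.eigenvectors.T @ self.eigenvectors
        if not np.allclose(gram, np.eye(gram.shape[0]), atol=1e-8):
            raise IntegrityError("eigenvectors must be orthonormal")
        self.eigenvalues, self.fractions = ev, fr

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "mode": np.arange(1, len(self.eigenvalues) + 1),
                "eigenvalue": self.eigenvalues,
                "fraction": self.fractions,
            }
        )


# ---------------------------------------------------------------------------
# Superposition and deviation measures
# ---------------------------------------------------------------------------

def _kabsch(mobile: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Best proper rotation R and centroids aligning mobile onto target."""
    cm = mobile.mean(axis=0)
    ct = target.mean(axis=0)
    rot, _ = Rotation.align_vectors(target - ct, mobile - cm)
    return rot.as_matrix(), cm, ct


def _check_subset(subset_xyz: np.ndarray) -> None:
    if subset_xyz.shape[0] < 3:
        raise DegeneracyError(
            f"superposition needs >= 3 atoms, got {subset_xyz.shape[0]}"
        )
    centered = subset_xyz - subset_xyz.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-8) < 2:
        raise DegeneracyError("superposition subset atoms are collinear")


def superpose(
    trajectory: Trajectory, reference: np.ndarray, subset: Fragment
) -> Trajectory:
    """Rigidly fit every frame onto ``reference`` using the subset atoms.

    Least-squares rotation+translation on the subset (proper rotation,
    det +1) applied to all atoms of the frame.
    """
    reference = np.asarray(reference, dtype=float)
    idx = subset.sorted_indices()
    _check_subset(reference[idx])
    out = np.empty_like(trajectory.coordinates)
    for f in range(trajectory.n_frames):
        frame = trajectory.coordinates[f]
        R, cm, ct = _kabsch(frame[idx], reference[idx])
        out[f] = (frame - cm) @ R.T + ct
    return Trajectory(coordinates=out, frame_times=trajectory.frame_times)


def rmsd_series(
    trajectory: Trajectory,
    reference: np.ndarray,
    subset: Fragment,
    rmsd_subset: Fragment | None = None,
) -> np.ndarray:
    """Per-frame RMSD (A) after superposition on ``subset``.

    The deviation is measured over ``rmsd_subset`` (default: the
    superposition subset itself).
    """
    fitted = superpose(trajectory, reference, subset)
    idx = (rmsd_subset or subset).sorted_indices()
    diff = fitted.coordinates[:, idx, :] - np.asarray(reference, dtype=float)[idx]
    return np.sqrt((diff**2).sum(axis=2).mean(axis=1))


def rmsf(trajectory: Trajectory, subset: Fragment) -> np.ndarray:
    """Per-atom root-mean-square fluctuation about the trajectory mean.

    The trajectory is assumed already superposed; RMSF_i =
    sqrt(<|r_i - <r_i>|^2>) in Angstrom.
    """
    if trajectory.n_frames < 2:
        raise InsufficientDataError("RMSF needs >= 2 frames")
    idx = subset.sorted_indices()
    xyz = trajectory.coordinates[:, idx, :]
    dev = xyz - xyz.mean(axis=0)
    return np.sqrt((dev**2).sum(axis=2).mean(axis=0))


# ---------------------------------------------------------------------------
# Correlations and modes
# ---------------------------------------------------------------------------

def _node_displacements(trajectory: Trajectory, nodes) -> tuple[np.ndarray, list[str]]:
    """(n_frames, n_nodes, 3) anchor-atom displacements from the mean."""
    anchors = [n.anchor_atom_index for n in nodes.nodes]
    labels = [n.label for n in nodes.nodes]
    xyz = trajectory.coordinates[:, anchors, :]
    return xyz - xyz.mean(axis=0), labels


def correlation_matrix(trajectory: Trajectory, nodes) -> CorrelationMatrix:
    """Generalized (dot-product) correlation of node-anchor fluctuations.

    C_ij = <dr_i . dr_j> / sqrt(<|dr_i|^2> <|dr_j|^2>) over frames of a
    superposed trajectory.
    """
    if trajectory.n_frames < 2:
        raise InsufficientDataError("correlation needs >= 2 frames")
    disp, labels = _node_displacements(trajectory, nodes)
    # inner product over axes, averaged over frames
    cov = np.einsum("fia,fja->ij", disp, disp) / disp.shape[0]
    var = np.diag(cov)
    zero = np.where(var <= 0)[0]
    if zero.size:
        raise IntegrityError(
            "zero-fluctuation node(s), correlation undefined: "
            + ", ".join(labels[i] for i in zero)
        )
    c = cov / np.sqrt(np.outer(var, var))
    return CorrelationMatrix(matrix=c, labels=labels)


def pca_modes(trajectory: Trajectory, nodes) -> ModeSpectrum:
    """PCA of node-coordinate fluctuations (essential dynamics).

    Eigen-decomposes the 3N x 3N covariance of the node anchor
    coordinates; a mode's contribution to the overall motion is its
    eigenvalue divided by the trace.  Tiny negative eigenvalues from
    round-off are clipped to zero with a log warning.
    """
    if trajectory.n_frames < 2:
        raise InsufficientDataError("PCA needs >= 2 frames")
    disp, labels = _node_displacements(trajectory, nodes)
    n_frames, n_nodes, _ = disp.shape
    if n_frames <= 3 * n_nodes:
        logger.warning(
            "pca_modes: %d frames for %d nodes (< 3N+1); spectrum may be "
            "rank-deficient", n_frames, n_nodes,
        )
    flat = disp.reshape(n_frames, 3 * n_nodes)
    cov = flat.T @ flat / n_frames
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    if np.any(evals < -1e-10):
        raise IntegrityError("covariance has significantly negative eigenvalues")
    if np.any(evals < 0):
        logger.warning("pca_modes: clipping %d tiny negative eigenvalues to 0",
                       int((evals < 0).sum()))
        evals = np.clip(evals, 0, None)
    total = evals.sum()
    if total <= 0:
        raise IntegrityError("all-zero fluctuations; mode fractions undefined")
    return ModeSpectrum(
        eigenvalues=evals,
        fractions=evals / total,
        eigenvectors=evecs,
        labels=labels,
    )
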