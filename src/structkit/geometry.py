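"""Rigid-body geometry: Kabsch superposition, distances, axis fits, torsions.

All angles are reported in degrees and all lengths in Angstrom, following
structural-biology convention.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Union

import numpy as np
from scipy.spatial.distance import cdist

from structkit.structio import Chain, Residue, Structure

__all__ = [
    "Transform", "AxisFit", "kabsch", "apply_transform",
    "pairwise_min_distances", "fit_axis", "dihedral",
]


@dataclass
class Transform:
    """A proper rigid motion x -> R @ x + t."""

    rotation: np.ndarray   # 3x3, det = +1
    translation: np.ndarray  # 3-vector, Angstrom

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        if self.rotation.shape != (3, 3) or self.translation.shape != (3,):
            raise ValueError("rotation must be 3x3 and translation a 3-vector")
        if abs(np.linalg.det(self.rotation) - 1.0) > 1e-6:
            raise ValueError("rotation determinant must be +1 (proper rotation)")
        if not np.allclose(self.rotation @ self.rotation.T, np.eye(3), atol=1e-6):
            raise ValueError("rotation must be orthonormal")

    @classmethod
    def identity(cls) -> "Transform":
        return cls(np.eye(3), np.zeros(3))

    def inverse(self) -> "Transform":
        return Transform(self.rotation.T, -self.rotation.T @ self.translation)

    def __call__(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, dtype=float) @ self.rotation.T + self.translation


@dataclass
class AxisFit:
    """Least-squares line fit to a run of CA atoms, oriented N -> C.

    ``n_start`` / ``c_end`` are the projections of the first / last input
    point onto the fitted line; ``point`` is the centroid anchor.
    """

    point: np.ndarray
    direction: np.ndarray
    n_start: np.ndarray
    c_end: np.ndarray


def kabsch(mobile: np.ndarray, target: np.ndarray) -> tuple[Transform, float]:
    """Optimal proper rigid superposition of ``mobile`` onto ``target``.

    Solves the orthogonal Procrustes problem by SVD with reflection
    correction (smallest singular vector flipped if the determinant of the
    candidate rotation is negative), and returns the minimising Transform
    together with the minimum RMSD.
    """
    P = np.asarray(mobile, dtype=float)
    Q = np.asarray(target, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("point sets must be matching Nx3 arrays")
    n = P.shape[0]
    if n < 3:
        raise ValueError("at least 3 point pairs are required")
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    P0, Q0 = P - pc, Q - qc
    if np.linalg.matrix_rank(P0, tol=1e-8) < 2 or np.linalg.matrix_rank(Q0, tol=1e-8) < 2:
        raise ValueError("rank-deficient point set (collinear or coincident points)")
    H = P0.T @ Q0
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = qc - R @ pc
    moved = P @ R.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((moved - Q) ** 2, axis=1))))
    return Transform(R, t), rmsd


def apply_transform(t: Transform, obj: Union[Structure, Chain, Residue, np.ndarray]):
    """Apply a rigid motion to coordinates, a residue, a chain or a structure.

    Hierarchical objects are returned as new objects of the same kind with
    every atom coordinate replaced by R x + t; bare arrays come back as
    transformed arrays.
    """
    if isinstance(obj, np.ndarray) or (not hasattr(obj, "residues") and not hasattr(obj, "chains") and not hasattr(obj, "atoms")):
        return t(np.asarray(obj))
    if isinstance(obj, Structure):
        return Structure(entry_id=obj.entry_id, model_number=obj.model_number,
                         chains=[apply_transform(t, c) for c in obj.chains])
    if isinstance(obj, Chain):
        return Chain(chain_id=obj.chain_id,
                     residues=[apply_transform(t, r) for r in obj.residues])
    if isinstance(obj, Residue):
        from dataclasses import replace
        return Residue(number=obj.number, insertion_code=obj.insertion_code,
                       res_name=obj.res_name,
                       atoms=[replace(a, coords=t(a.coords)) for a in obj.atoms])
    raise TypeError(f"cannot transform object of type {type(obj)!r}")


MISSING = np.inf  # marker for residue pairs with no selectable atoms


def _select_coords(res: Residue, atom_mode: str) -> np.ndarray:
    if atom_mode == "heavy":
        atoms = res.heavy_atoms()
    elif atom_mode == "ca":
        a = res.get_atom("CA")
        atoms = [a] if a is not None else []
    elif atom_mode == "cb":
        a = res.get_atom("CB") or res.get_atom("CA")  # glycine falls back to CA
        atoms = [a] if a is not None else []
    else:
        raise ValueError(f"unknown atom_mode {atom_mode!r}")
    if not atoms:
        return np.empty((0, 3))
    return np.array([a.coords for a in atoms])


def pairwise_min_distances(a: list[Residue], b: list[Residue],
                           atom_mode: str = "heavy") -> np.ndarray:
    """Matrix of minimum inter-atomic distances between two residue sets.

    Entry (i, j) is the minimum distance over the selected atoms of residue
    i in ``a`` and residue j in ``b``.  Modes: ``heavy`` = all non-hydrogen
    atoms, ``ca`` = C-alpha only, ``cb`` = C-beta with C-alpha substituted
    for glycine.  Residues lacking every selected atom produce ``inf``
    entries, which downstream code treats as missing.
    """
    coords_a = [_select_coords(r, atom_mode) for r in a]
    coords_b = [_select_coords(r, atom_mode) for r in b]
    out = np.full((len(a), len(b)), MISSING)
    for i, ca in enumerate(coords_a):
        if ca.shape[0] == 0:
            continue
        for j, cb in enumerate(coords_b):
            if cb.shape[0] == 0:
                continue
            out[i, j] = cdist(ca, cb).min()
    return out


def fit_axis(ca_coords: np.ndarray, n_terminal_first: bool = True) -> AxisFit:
    """Fit an oriented line through CA coordinates by principal component.

    The direction is the leading principal axis of the centred coordinates,
    sign-fixed so that (last - first) . direction > 0 when
    ``n_terminal_first`` (i.e. the axis points N -> C).
    """
    X = np.asarray(ca_coords, dtype=float)
    if X.ndim != 2 or X.shape[1] != 3 or X.shape[0] < 3:
        raise ValueError("need at least 3 CA coordinates")
    centroid = X.mean(axis=0)
    X0 = X - centroid
    _, _, Vt = np.linalg.svd(X0, full_matrices=False)
    direction = Vt[0]
    span = X[-1] - X[0] if n_terminal_first else X[0] - X[-1]
    if np.dot(span, direction) < 0:
        direction = -direction
    direction = direction / np.linalg.norm(direction)
    n_start = centroid + np.dot(X[0] - centroid, direction) * direction
    c_end = centroid + np.dot(X[-1] - centroid, direction) * direction
    return AxisFit(point=centroid, direction=direction, n_start=n_start, c_end=c_end)


def dihedral(p1: np.ndarray, p2: np.ndarray, p3: np.ndarray, p4: np.ndarray) -> float:
    """Signed torsion angle p1-p2-p3-p4 in degrees, IUPAC convention, (-180, 180]."""
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < 1e-9 or np.linalg.norm(n2) < 1e-9:
        raise ValueError("collinear points: torsion undefined")
    ang = np.degrees(np.arctan2(np.dot(n1, b3) * np.linalg.norm(b2), np.dot(n1, n2)))
    if ang <= -180.0:
        ang += 360.0
    return float(ang)


def angle_between(u: np.ndarray, v: np.ndarray) -> float:
    """Unsigned angle between two vectors, degrees in [0, 180]."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    c = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))
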