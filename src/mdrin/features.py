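"""Domain-level and residue-level structural features.

Domain-level: the six inter-domain center distances R_ij
(i, j in {a, b, b', a'}), two inter-domain angles Theta_abb' and
Theta_bb'a', and the torsion Phi_abb'a' of the ordered domain centers
a-b-b'-a'.  Residue-level: pairwise Ca-Ca Euclidean distances d_ij.

Domain centers are the unweighted mean of the domain's Ca coordinates.
All features are internal coordinates and hence invariant to global
rotation/translation of a frame.  The torsion follows the IUPAC
right-handed sign convention with range (-180, 180].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import DomainPartition, Trajectory

__all__ = [
    "domain_centers",
    "domain_geometry_features",
    "residue_distance_series",
    "residue_pair_distances",
    "ResidueDistanceSeries",
    "DOMAIN_FEATURE_ORDER",
]

_CORE_DOMAINS = ("a", "b", "b'", "a'")

DOMAIN_FEATURE_ORDER = [
    "R_ab",
    "R_ab'",
    "R_aa'",
    "R_bb'",
    "R_ba'",
    "R_b'a'",
    "Theta_abb'",
    "Theta_bb'a'",
    "Phi_abb'a'",
]


def domain_centers(
    traj: Trajectory, part: DomainPartition, tags: tuple[str, ...] = _CORE_DOMAINS
) -> dict[str, np.ndarray]:
    """Per-frame unweighted mean of each domain's Ca coordinates.

    Returns a mapping tag -> (n_frames, 3) array.  Domains without any
    residue (or any Ca) are rejected.
    """
    centers: dict[str, np.ndarray] = {}
    for tag in tags:
        residues = part.residues(tag)
        if not residues:
            raise ValueError(f"domain '{tag}' has no residues")
        ca = traj.ca_coordinates(residues=residues)
        if ca.shape[1] == 0:
            raise ValueError(f"domain '{tag}' has no CA atoms")
        centers[tag] = ca.mean(axis=1)
    return centers


def _angle(p: np.ndarray, q: np.ndarray, r: np.ndarray) -> np.ndarray:
    """Angle at q formed by p and r, degrees, NaN where arms vanish."""
    u = p - q
    v = r - q
    nu = np.linalg.norm(u, axis=-1)
    nv = np.linalg.norm(v, axis=-1)
    denom = nu * nv
    with np.errstate(invalid="ignore", divide="ignore"):
        cosang = np.einsum("...i,...i", u, v) / denom
    cosang = np.clip(cosang, -1.0, 1.0)
    out = np.degrees(np.arccos(cosang))
    return np.where(denom > 0, out, np.nan)


def _dihedral(p1, p2, p3, p4) -> np.ndarray:
    """Signed dihedral of four ordered points, IUPAC convention, degrees.

    Range (-180, 180]; NaN when consecutive points coincide or the three
    bond vectors are collinear.
    """
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    nb2 = np.linalg.norm(b2, axis=-1)
    x = np.einsum("...i,...i", n1, n2)
    y = np.einsum("...i,...i", np.cross(n1, n2), b2) / np.where(nb2 > 0, nb2, np.nan)
    with np.errstate(invalid="ignore"):
        ang = np.degrees(np.arctan2(y, x))
    bad = (np.linalg.norm(n1, axis=-1) == 0) | (np.linalg.norm(n2, axis=-1) == 0)
    ang = np.where(bad, np.nan, ang)
    # atan2 returns -180 for the trans case; fold onto (-180, 180]
    return np.where(ang == -180.0, 180.0, ang)


def domain_geometry_features(centers: dict[str, np.ndarray]) -> pd.DataFrame:
    """R_ij, Theta and Phi per frame from the four domain centers.

    Undefined geometry (coincident centers in an angle or torsion) is
    propagated as NaN for that frame.
    """
    missing = [t for t in _CORE_DOMAINS if t not in centers]
    if missing:
        raise ValueError(f"missing domain centers: {missing}")
    a, b, bp, ap = (np.asarray(centers[t], dtype=float) for t in _CORE_DOMAINS)
    # explicit order keeps column names canonical
    out = {
        "R_ab": np.linalg.norm(a - b, axis=-1),
        "R_ab'": np.linalg.norm(a - bp, axis=-1),
        "R_aa'": np.linalg.norm(a - ap, axis=-1),
        "R_bb'": np.linalg.norm(b - bp, axis=-1),
        "R_ba'": np.linalg.norm(b - ap, axis=-1),
        "R_b'a'": np.linalg.norm(bp - ap, axis=-1),
        "Theta_abb'": _angle(a, b, bp),
        "Theta_bb'a'": _angle(b, bp, ap),
        "Phi_abb'a'": _dihedral(a, b, bp, ap),
    }
    return pd.DataFrame(out)


@dataclass
class ResidueDistanceSeries:
    """Per-frame symmetric Ca-Ca distance matrices for a residue subset."""

    residues: np.ndarray  # (R,) residue indices, 1-based
    distances: np.ndarray  # (n_frames, R, R), Angstrom

    def pair_series(self, res_i: int, res_j: int) -> np.ndarray:
        i = int(np.flatnonzero(self.residues == res_i)[0])
        j = int(np.flatnonzero(self.residues == res_j)[0])
        return self.distances[:, i, j]


def residue_distance_series(
    traj: Trajectory, selection=None
) -> ResidueDistanceSeries:
    """Full symmetric Ca-Ca distance matrix per frame.

    ``selection`` restricts to a residue subset (default: all residues).
    Residues lacking a Ca atom are rejected by name.
    """
    topo = traj.topology
    residues = np.asarray(
        sorted(selection) if selection is not None else topo.residue_ids, dtype=int
    )
    idx = []
    for res in residues:
        hits = np.flatnonzero((topo.residue_indices == res) & topo.ca_mask())
        if len(hits) == 0:
            raise ValueError(f"residue {res} has no CA atom")
        idx.append(hits[0])
    ca = traj.coordinates[:, idx, :]
    diff = ca[:, :, None, :] - ca[:, None, :, :]
    dist = np.linalg.norm(diff, axis=-1)
    return ResidueDistanceSeries(residues=residues, distances=dist)


def residue_pair_distances(
    traj: Trajectory, pairs: list[tuple[int, int]]
) -> pd.DataFrame:
    """Streamed Ca-Ca distances for selected residue pairs only.

    Columns are named ``d_<i>_<j>``; used e.g. for catalytic Cys pairs
    (53-56, 397-400) without materialising the full matrix.
    """
    topo = traj.topology
    cols = {}
    for i, j in pairs:
        ci = topo.ca_index_of(int(i))
        cj = topo.ca_index_of(int(j))
        cols[f"d_{i}_{j}"] = np.linalg.norm(
            traj.coordinates[:, ci, :] - traj.coordinates[:, cj, :], axis=-1
        )
    return pd.DataFrame(cols)
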