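"""Collective-motion analysis: superposition, RMSD, DCCM, PCA and FELs.

The workflow mirrors the standard essential-dynamics pipeline for a
multi-domain protein: every frame is least-squares fitted onto a reference
over a base selection (e.g. the Ca atoms of domains b and b', which act as
the base for domain motions), displacement cross-correlations and PCA are
computed on Ca Cartesian coordinates, sampling convergence is checked via
inner products of eigenvectors from data halves, and free-energy
landscapes are obtained by Gaussian-kernel density estimation on pairs of
principal components, reported as F = -ln(p / p_max) in units of k_BT so
the global minimum is exactly 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation
from sklearn.decomposition import PCA
from sklearn.neighbors import KernelDensity

from .io import Trajectory

__all__ = [
    "superpose_trajectory",
    "rmsd_series",
    "cross_correlation_matrix",
    "pca_modes",
    "eigenvector_overlap",
    "fel_projection",
    "fel_from_points",
    "PcaModel",
    "FELGrid",
]

_BACKBONE = ("N", "CA", "C", "O")


def _fit_atom_indices(traj: Trajectory, fit_residues) -> np.ndarray:
    topo = traj.topology
    mask = topo.ca_mask()
    if fit_residues is not None:
        mask &= topo.atom_mask(residues=fit_residues)
    idx = np.flatnonzero(mask)
    if len(idx) < 3:
        raise ValueError(f"need >= 3 fit atoms, got {len(idx)}")
    return idx


def superpose_trajectory(
    traj: Trajectory,
    reference: int | np.ndarray = 0,
    fit_residues=None,
) -> Trajectory:
    """Least-squares rigid-body fit of every frame onto a reference.

    The optimal rotation + translation (Kabsch) is computed over the Ca
    atoms of ``fit_residues`` (default: all residues) and applied to all
    atoms, minimising the fit-selection RMSD per frame.

    ``reference`` is a frame index or an (n_atoms, 3) coordinate array
    with the same topology.
    """
    idx = _fit_atom_indices(traj, fit_residues)
    ref = (
        traj.coordinates[reference]
        if isinstance(reference, (int, np.integer))
        else np.asarray(reference, dtype=float)
    )
    if ref.shape != (traj.n_atoms, 3):
        raise ValueError("reference has wrong shape for this topology")
    ref_sel = ref[idx]
    ref_cen = ref_sel.mean(axis=0)
    out = np.empty_like(traj.coordinates)
    for f in range(traj.n_frames):
        mob = traj.coordinates[f]
        mob_cen = mob[idx].mean(axis=0)
        rot, _ = Rotation.align_vectors(ref_sel - ref_cen, mob[idx] - mob_cen)
        out[f] = rot.apply(mob - mob_cen) + ref_cen
    return Trajectory(
        topology=traj.topology, coordinates=out, frame_labels=traj.frame_labels
    )


def rmsd_series(
    traj: Trajectory,
    reference: int | np.ndarray = 0,
    selections: dict[str, list[int] | None] | None = None,
) -> pd.DataFrame:
    """Backbone RMSD per frame for the whole protein and per selection.

    Uses N, Ca, C, O atoms where present, otherwise Ca only (coarse
    fixtures).  No fitting is performed here: align first with
    :func:`superpose_trajectory`.
    """
    if selections is None:
        selections = {"whole": None}
    ref = (
        traj.coordinates[reference]
        if isinstance(reference, (int, np.integer))
        else np.asarray(reference, dtype=float)
    )
    topo = traj.topology
    out = {}
    for name, residues in selections.items():
        mask = np.isin(topo.atom_names, _BACKBONE)
        if not mask.any():
            mask = topo.ca_mask()
        if residues is not None:
            mask &= topo.atom_mask(residues=residues)
        if not mask.any():
            raise ValueError(f"selection '{name}' is empty")
        d = traj.coordinates[:, mask, :] - ref[mask]
        out[name] = np.sqrt(np.mean(np.sum(d * d, axis=-1), axis=-1))
    return pd.DataFrame(out)


def cross_correlation_matrix(traj: Trajectory, residues=None) -> np.ndarray:
    """Normalised dynamic cross-correlation matrix of Ca displacements.

    C_ij = <dr_i . dr_j> / sqrt(<|dr_i|^2><|dr_j|^2>) with dr the
    displacement of each atom from its trajectory mean; entries lie in
    [-1, 1] with unit diagonal.  Rows/columns of zero-variance atoms are
    NaN (undefined).
    """
    ca = traj.ca_coordinates(residues=residues)
    if ca.shape[0] < 2:
        raise ValueError("need >= 2 frames for cross-correlation")
    disp = ca - ca.mean(axis=0)
    num = np.einsum("fit,fjt->ij", disp, disp) / disp.shape[0]
    var = np.diag(num).copy()
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = num / np.sqrt(np.outer(var, var))
    corr[var == 0, :] = np.nan
    corr[:, var == 0] = np.nan
    return corr


@dataclass
class PcaModel:
    """PCA of concatenated Ca Cartesian coordinates.

    ``components`` rows are orthonormal 3N-vectors; ``eigenvalues`` (A^2,
    descending) are the variances along them; ``projections`` are the
    centred frame coordinates expressed in the component basis.
    """

    mean: np.ndarray  # (3N,)
    components: np.ndarray  # (k, 3N)
    eigenvalues: np.ndarray  # (k,)
    projections: np.ndarray  # (frames, k)
    atom_indices: np.ndarray  # which atoms of the topology were used

    @property
    def variance_fractions(self) -> np.ndarray:
        total = self.eigenvalues.sum()
        if total == 0:
            return np.zeros_like(self.eigenvalues)
        return self.eigenvalues / total


def pca_modes(traj: Trajectory, residues=None) -> PcaModel:
    """Eigendecomposition of the Ca coordinate covariance.

    Works on the (frames x 3N) matrix of the selected Ca atoms; all
    min(frames, 3N) components are returned, so the eigenvalue sum equals
    the total coordinate variance.  A motionless trajectory yields all-zero
    eigenvalues rather than an error.
    """
    topo = traj.topology
    mask = topo.ca_mask()
    if residues is not None:
        mask &= topo.atom_mask(residues=residues)
    idx = np.flatnonzero(mask)
    if len(idx) == 0:
        raise ValueError("empty Ca selection")
    x = traj.coordinates[:, idx, :].reshape(traj.n_frames, -1)
    n_comp = min(x.shape)
    pca = PCA(n_components=n_comp, svd_solver="full")
    proj = pca.fit_transform(x)
    eigvals = np.clip(pca.explained_variance_, 0.0, None)
    return PcaModel(
        mean=pca.mean_,
        components=pca.components_,
        eigenvalues=eigvals,
        projections=proj,
        atom_indices=idx,
    )


def eigenvector_overlap(model_a: PcaModel, model_b: PcaModel, k: int) -> np.ndarray:
    """k x k matrix of absolute inner products of PCA eigenvectors.

    Entry (m, n) = |v_m^A . v_n^B| in [0, 1]; requires the same atom
    selection (hence coordinate ordering) in both models.
    """
    if model_a.components.shape[1] != model_b.components.shape[1]:
        raise ValueError("PCA models built on different selections")
    if k > min(len(model_a.eigenvalues), len(model_b.eigenvalues)):
        raise ValueError("k exceeds available components")
    return np.abs(model_a.components[:k] @ model_b.components[:k].T)


@dataclass
class FELGrid:
    """Free-energy surface on a regular 2-D grid, units of k_BT."""

    x: np.ndarray  # (gx,) grid coordinates, first component
    y: np.ndarray  # (gy,) grid coordinates, second component
    free_energy: np.ndarray  # (gx, gy), min exactly 0
    bandwidth: float  # A, isotropic Gaussian kernel
    components: tuple[int, int]  # 1-based PC indices

    def local_minima(self) -> list[tuple[float, float]]:
        """Interior grid points strictly below all 8 neighbours."""
        f = self.free_energy
        c = f[1:-1, 1:-1]
        is_min = np.ones_like(c, dtype=bool)
        for di in (-1, 0, 1):
            for dj in (-1, 0, 1):
                if di == dj == 0:
                    continue
                nb = f[1 + di : f.shape[0] - 1 + di, 1 + dj : f.shape[1] - 1 + dj]
                is_min &= c < nb
        out = []
        for i, j in np.argwhere(is_min):
            out.append((float(self.x[i + 1]), float(self.y[j + 1])))
        return out

    def to_frame(self) -> pd.DataFrame:
        """Long-format (x, y, F) table, one row per grid cell."""
        xx, yy = np.meshgrid(self.x, self.y, indexing="ij")
        return pd.DataFrame(
            {"x": xx.ravel(), "y": yy.ravel(), "F": self.free_energy.ravel()}
        )


def _scott_bandwidth(xy: np.ndarray) -> float:
    # Scott's rule for d=2 with an isotropic kernel: n^(-1/6) * pooled sd
    n = xy.shape[0]
    sd = np.sqrt(xy.var(axis=0, ddof=1).mean())
    return float(n ** (-1.0 / 6.0) * sd)


def fel_from_points(
    xy: np.ndarray,
    grid_size: int = 100,
    bandwidth: float | None = None,
) -> FELGrid:
    """Free-energy surface of 2-D samples via Gaussian KDE.

    F = -ln(p / p_max) so the global minimum is 0 k_BT.  Default bandwidth
    is Scott's rule on the two projected coordinates; the grid extends
    three bandwidths beyond the data range.
    """
    xy = np.asarray(xy, dtype=float)
    if xy.ndim != 2 or xy.shape[1] != 2:
        raise ValueError("xy must be (n, 2)")
    if xy.shape[0] < 100:
        warnings.warn("fewer than 100 samples: FEL will be noisy", stacklevel=2)
    if bandwidth is None:
        bandwidth = _scott_bandwidth(xy)
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive")
    pad = 3.0 * bandwidth
    gx = np.linspace(xy[:, 0].min() - pad, xy[:, 0].max() + pad, grid_size)
    gy = np.linspace(xy[:, 1].min() - pad, xy[:, 1].max() + pad, grid_size)
    kde = KernelDensity(kernel="gaussian", bandwidth=bandwidth).fit(xy)
    xx, yy = np.meshgrid(gx, gy, indexing="ij")
    logp = kde.score_samples(np.column_stack([xx.ravel(), yy.ravel()]))
    logp = logp.reshape(grid_size, grid_size)
    fes = logp.max() - logp  # global minimum exactly 0 (avoids -0.0)
    return FELGrid(
        x=gx, y=gy, free_energy=fes, bandwidth=float(bandwidth), components=(0, 0)
    )


def fel_projection(
    model: PcaModel,
    components: tuple[int, int] = (1, 2),
    grid_size: int = 100,
    bandwidth: float | None = None,
) -> FELGrid:
    """Projected free-energy landscape on a pair of principal components.

    ``components`` are 1-based PC indices (PC1 is the largest mode).
    """
    c1, c2 = components
    if min(c1, c2) < 1 or max(c1, c2) > model.projections.shape[1]:
        raise ValueError("component index out of range")
    xy = model.projections[:, [c1 - 1, c2 - 1]]
    grid = fel_from_points(xy, grid_size=grid_size, bandwidth=bandwidth)
    grid.components = (c1, c2)
    return grid
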