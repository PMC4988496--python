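"""Cartesian-covariance principal component analysis (essential dynamics).

The positional covariance of an aligned trajectory is diagonalised; the
leading eigenvectors are the collective modes that dominate the observed
conformational variability, and projections onto them yield free-energy
(PMF) surfaces via Boltzmann inversion of the occupancy histogram.
"""
from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import AtomSelection, MDFlexError, Trajectory
from .superpose import align_trajectory, average_structure

__all__ = [
    "ModeSet",
    "ProjectionSet",
    "PMFGrid",
    "covariance_matrix",
    "principal_modes",
    "fit_pca",
    "variance_fractions",
    "project",
    "pmf_2d",
    "mode_arrows",
]

_EVAL_FLOOR = -1e-8


@dataclass
class ModeSet:
    """Principal modes of the positional fluctuation covariance.

    ``eigenvectors`` has shape (3N, n_modes) with orthonormal columns sorted
    by decreasing ``eigenvalues`` (Å²). ``mean`` is the (N, 3) structure the
    fluctuations are measured about; sign convention: the largest-magnitude
    component of each eigenvector is positive.
    """

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    mean: np.ndarray | None = None
    selection: str = ""

    @property
    def n_modes(self) -> int:
        return int(self.eigenvalues.size)

    def to_frame(self) -> pd.DataFrame:
        """Tabular export: one row per (mode, atom) with x/y/z components."""
        k, n3 = self.eigenvectors.shape[1], self.eigenvectors.shape[0]
        vec = self.eigenvectors.T.reshape(k, n3 // 3, 3)
        rows = [
            (m + 1, a + 1, *vec[m, a])
            for m in range(k)
            for a in range(n3 // 3)
        ]
        return pd.DataFrame(rows, columns=["mode", "atom", "vx", "vy", "vz"])

    def to_nmd(self, path, atom_names=None) -> None:
        """Minimal NMD-style vector file for mode viewers."""
        with open(path, "w") as fh:
            if self.mean is not None:
                fh.write("coordinates " + " ".join(f"{v:.3f}" for v in self.mean.ravel()) + "\n")
            for m in range(self.n_modes):
                comps = " ".join(f"{v:.6f}" for v in self.eigenvectors[:, m])
                fh.write(f"mode {m + 1} {self.eigenvalues[m]:.6f} {comps}\n")


@dataclass
class ProjectionSet:
    """Per-frame principal-component coordinates q_i (Å)."""

    coords: np.ndarray  # (n_frames, k)
    eigenvalues: np.ndarray  # the k eigenvalues, for reference

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    def to_csv(self, path) -> None:
        k = self.coords.shape[1]
        pd.DataFrame(self.coords, columns=[f"pc{i + 1}" for i in range(k)]).to_csv(
            path, index=False
        )


@dataclass
class PMFGrid:
    """2-D potential of mean force over two PC axes, in units of k_BT."""

    x_edges: np.ndarray
    y_edges: np.ndarray
    free_energy: np.ndarray  # (nx, ny); NaN on masked (empty) bins
    counts: np.ndarray
    axes: tuple[int, int]

    @property
    def mask(self) -> np.ndarray:
        """True where a bin is empty (carries no free-energy value)."""
        return self.counts == 0

    def to_json(self, path) -> None:
        payload = {
            "axes": [int(a) for a in self.axes],
            "x_edges": self.x_edges.tolist(),
            "y_edges": self.y_edges.tolist(),
            "free_energy_kBT": [
                [None if not np.isfinite(v) else v for v in row]
                for row in self.free_energy
            ],
            "counts": self.counts.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    def to_csv(self, path) -> None:
        nx, ny = self.counts.shape
        xc = 0.5 * (self.x_edges[:-1] + self.x_edges[1:])
        yc = 0.5 * (self.y_edges[:-1] + self.y_edges[1:])
        rows = [
            (xc[i], yc[j], self.counts[i, j], self.free_energy[i, j])
            for i in range(nx)
            for j in range(ny)
        ]
        pd.DataFrame(rows, columns=["x", "y", "count", "pmf_kBT"]).to_csv(
            path, index=False
        )


def _traj_matrix(traj: Trajectory, selection: AtomSelection | None) -> np.ndarray:
    idx = selection.indices if selection is not None else np.arange(traj.n_atoms)
    if idx.size == 0:
        raise MDFlexError("empty selection")
    return traj.frames[:, idx, :].reshape(traj.n_frames, -1)


def covariance_matrix(traj: Trajectory, selection: AtomSelection | None = None) -> np.ndarray:
    """Covariance C = ⟨Δx Δxᵀ⟩ (Å²) of Cartesian coordinates about the
    trajectory mean, with the ensemble-average (1/N frames) denominator used
    by essential-dynamics tools. Frames are assumed pre-aligned."""
    x = _traj_matrix(traj, selection)
    if x.shape[0] < 2:
        raise MDFlexError("covariance needs >= 2 frames")
    xc = x - x.mean(axis=0)
    c = xc.T @ xc / x.shape[0]
    return 0.5 * (c + c.T)


def principal_modes(
    cov: np.ndarray,
    mean: np.ndarray | None = None,
    selection: str = "",
) -> ModeSet:
    """Sorted eigendecomposition of a symmetric covariance matrix.

    Eigenvalues are sorted descending with tiny negative values floored to
    zero; each eigenvector's largest-magnitude component is made positive so
    outputs are deterministic across BLAS implementations.
    """
    cov = np.asarray(cov, dtype=float)
    if cov.ndim != 2 or cov.shape[0] != cov.shape[1]:
        raise ValueError("covariance must be square")
    if not np.allclose(cov, cov.T, atol=1e-10 * max(1.0, np.abs(cov).max())):
        raise ValueError("covariance must be symmetric")
    if not np.any(cov):
        raise MDFlexError("all-zero covariance has no modes")
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    evecs = evecs[:, order]
    if evals.min() < _EVAL_FLOOR * max(1.0, evals.max()):
        raise MDFlexError("covariance is significantly non-PSD")
    evals = np.clip(evals, 0.0, None)
    # deterministic sign: largest |component| positive
    amax = np.argmax(np.abs(evecs), axis=0)
    signs = np.sign(evecs[amax, np.arange(evecs.shape[1])])
    signs[signs == 0] = 1.0
    evecs = evecs * signs
    return ModeSet(evals, evecs, mean=mean, selection=selection)


def fit_pca(
    traj: Trajectory,
    selection: AtomSelection | None = None,
    align: bool = True,
    average_max_iter: int = 10,
) -> tuple[ModeSet, Trajectory]:
    """Convenience: iterative-mean alignment, covariance, eigendecomposition.

    Returns the ModeSet (with the mean structure of the selection) and the
    aligned trajectory used to compute it.
    """
    work = traj
    if align:
        avg = average_structure(traj, selection, max_iter=average_max_iter)
        work = align_trajectory(traj, avg, selection)
    x = _traj_matrix(work, selection)
    mean = x.mean(axis=0).reshape(-1, 3)
    cov = covariance_matrix(work, selection)
    modes = principal_modes(
        cov, mean=mean, selection=selection.expression if selection else "all"
    )
    return modes, work


def variance_fractions(modes: ModeSet, k: int) -> float:
    """Cumulative fraction of total variance captured by the first k modes."""
    if k < 0 or k > modes.n_modes:
        raise ValueError(f"k={k} out of range for {modes.n_modes} modes")
    total = float(modes.eigenvalues.sum())
    if total <= 0:
        raise MDFlexError("zero total variance")
    return float(modes.eigenvalues[:k].sum() / total)


def project(
    traj: Trajectory | np.ndarray,
    modes: ModeSet,
    k: int | None = None,
    selection: AtomSelection | None = None,
) -> ProjectionSet:
    """Project frames onto the first k modes: q_i = v_iᵀ (x − x̄).

    ``traj`` may be a Trajectory (optionally restricted by ``selection``,
    which must match the one the modes were fitted on), a (F, 3N)/(F, N, 3)
    coordinate array, or a single (N, 3) conformation. Frames must already
    be aligned to the ModeSet mean.
    """
    if modes.mean is None:
        raise MDFlexError("ModeSet has no mean structure to project against")
    if k is None:
        k = modes.n_modes
    if k < 1 or k > modes.n_modes:
        raise ValueError(f"k={k} out of range")
    if isinstance(traj, Trajectory):
        x = _traj_matrix(traj, selection)
    else:
        x = np.asarray(traj, dtype=float)
        if x.ndim == 2 and x.shape[1] == 3:
            x = x.reshape(1, -1)
        elif x.ndim == 3:
            x = x.reshape(x.shape[0], -1)
    n3 = modes.eigenvectors.shape[0]
    if x.shape[1] != n3:
        raise MDFlexError(f"dimension mismatch: frames have {x.shape[1]}, modes {n3}")
    q = (x - modes.mean.reshape(1, -1)) @ modes.eigenvectors[:, :k]
    return ProjectionSet(q, modes.eigenvalues[:k].copy())


def pmf_2d(
    proj: ProjectionSet,
    axes: tuple[int, int] = (0, 1),
    bins: int = 50,
    pad_fraction: float = 0.05,
) -> PMFGrid:
    """Free-energy surface G = −ln(n/n_max) (k_BT) over two PC axes.

    Bins span the observed range padded by ``pad_fraction`` on each side;
    empty bins are masked (NaN) rather than regularised with pseudo-counts.
    The minimum over occupied bins is exactly 0.
    """
    i, j = axes
    if proj.coords.shape[0] < 1:
        raise MDFlexError("no samples to histogram")
    x = proj.coords[:, i]
    y = proj.coords[:, j]

    def _edges(v: np.ndarray) -> np.ndarray:
        lo, hi = float(v.min()), float(v.max())
        span = hi - lo
        pad = pad_fraction * span if span > 0 else max(abs(hi), 1.0) * pad_fraction
        return np.linspace(lo - pad, hi + pad, bins + 1)

    xe, ye = _edges(x), _edges(y)
    counts, _, _ = np.histogram2d(x, y, bins=[xe, ye])
    nmax = counts.max()
    if nmax == 0:
        raise MDFlexError("no occupied bins")
    with np.errstate(divide="ignore"):
        g = -np.log(counts / nmax)
    g[counts == 0] = np.nan
    return PMFGrid(xe, ye, g, counts.astype(int), (i, j))


def mode_arrows(modes: ModeSet, mode_index: int, scale: float = 1.0) -> np.ndarray:
    """Per-atom displacement vectors of one mode ('porcupine' arrows).

    Returns (N, 3) vectors equal to ``scale`` × the eigenvector components.
    """
    if mode_index < 0 or mode_index >= modes.n_modes:
        raise IndexError(f"mode index {mode_index} out of range")
    return scale * modes.eigenvectors[:, mode_index].reshape(-1, 3)
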