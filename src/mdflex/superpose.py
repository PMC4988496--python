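"""Least-squares superposition, RMSD/RMSF analysis and hinge detection.

The fit is the classic weighted Kabsch solution: the rotation that minimises
the (mass- or uniformly-weighted) RMSD between two conformations, constrained
to be proper (det = +1), obtained from the SVD of the weighted covariance of
the centred coordinate sets.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import AtomSelection, MDFlexError, Structure, Trajectory

__all__ = [
    "DegenerateGeometryError",
    "DeviationSeries",
    "FlexibilityProfile",
    "HingeRegion",
    "kabsch_superpose",
    "apply_fit",
    "align_trajectory",
    "rmsd_series",
    "average_structure",
    "rmsf_profile",
    "detect_hinges",
]


class DegenerateGeometryError(MDFlexError):
    """Superposition target is degenerate (too few or collinear atoms)."""


def kabsch_superpose(
    mobile: np.ndarray,
    reference: np.ndarray,
    weights: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal rigid superposition of ``mobile`` onto ``reference``.

    Returns ``(rotation, translation, rmsd)`` such that
    ``mobile @ rotation.T + translation`` minimises the weighted RMSD. The
    rotation is always proper (determinant +1).

    Raises
    ------
    DegenerateGeometryError
        For fewer than 3 atoms or (near-)collinear coordinates, where the
        optimal rotation is not unique.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("mobile and reference must both have shape (n, 3)")
    n = mobile.shape[0]
    if n < 3:
        raise DegenerateGeometryError("superposition requires >= 3 atoms")
    if weights is None:
        w = np.full(n, 1.0 / n)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (n,) or np.any(w < 0) or w.sum() <= 0:
            raise ValueError("weights must be non-negative with positive sum")
        w = w / w.sum()

    mob_centroid = w @ mobile
    ref_centroid = w @ reference
    mob_c = mobile - mob_centroid
    ref_c = reference - ref_centroid

    s_mob = np.linalg.svd(mob_c * np.sqrt(w)[:, None], compute_uv=False)
    if s_mob[1] <= 1e-8 * max(s_mob[0], 1.0):
        raise DegenerateGeometryError("collinear coordinates: rotation not unique")

    h = (w[:, None] * mob_c).T @ ref_c
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rotation = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    translation = ref_centroid - rotation @ mob_centroid
    fitted = mobile @ rotation.T + translation
    rmsd = float(np.sqrt(np.sum(w * np.sum((fitted - reference) ** 2, axis=1))))
    return rotation, translation, rmsd


def apply_fit(coords: np.ndarray, rotation: np.ndarray, translation: np.ndarray) -> np.ndarray:
    """Apply a rigid transform to ``(n, 3)`` or ``(f, n, 3)`` coordinates."""
    return np.asarray(coords) @ rotation.T + translation


@dataclass
class DeviationSeries:
    """Per-frame RMSD (Å) of a trajectory relative to a reference."""

    times: np.ndarray
    rmsd: np.ndarray
    selection: str
    reference: str = ""

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_ns": self.times, "rmsd_A": self.rmsd})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass(frozen=True)
class HingeRegion:
    chain: str
    start: int  # inclusive author residue numbers
    end: int


@dataclass
class FlexibilityProfile:
    """Per-atom RMSF with residue aggregation and optional hinge regions."""

    atom_indices: np.ndarray
    rmsf: np.ndarray  # Å, per selected atom
    mean_coords: np.ndarray  # (n_sel, 3) Å
    chain_ids: np.ndarray
    res_ids: np.ndarray
    atom_names: np.ndarray
    hinges: list[HingeRegion] = field(default_factory=list)

    def residue_profile(self, prefer_atom: str = "CA") -> pd.DataFrame:
        """Per-residue RMSF: the ``prefer_atom`` value if that atom is in the
        selection, otherwise the mean over the residue's selected atoms."""
        df = pd.DataFrame(
            {
                "chain": self.chain_ids.astype(str),
                "resid": self.res_ids,
                "name": self.atom_names.astype(str),
                "rmsf_A": self.rmsf,
            }
        )
        rows = []
        for (chain, resid), grp in df.groupby(["chain", "resid"], sort=False):
            ca = grp[grp["name"] == prefer_atom]
            val = float(ca["rmsf_A"].iloc[0]) if len(ca) else float(grp["rmsf_A"].mean())
            rows.append((chain, resid, val))
        out = pd.DataFrame(rows, columns=["chain", "resid", "rmsf_A"])
        return out.sort_values(["chain", "resid"], kind="stable").reset_index(drop=True)

    def to_csv(self, path) -> None:
        self.residue_profile().to_csv(path, index=False)

    def hinges_to_tsv(self, path) -> None:
        pd.DataFrame(
            [(h.chain, h.start, h.end) for h in self.hinges],
            columns=["chain", "start_resid", "end_resid"],
        ).to_csv(path, sep="\t", index=False)


def _ref_coords(reference, indices: np.ndarray) -> np.ndarray:
    if isinstance(reference, Structure):
        return reference.coords[indices]
    if isinstance(reference, Trajectory):
        return reference.frames[0][indices]
    return np.asarray(reference, dtype=float)[indices]


def rmsd_series(
    traj: Trajectory,
    reference,
    selection: AtomSelection,
    exclude: AtomSelection | None = None,
    weights: np.ndarray | None = None,
    reference_label: str = "",
) -> DeviationSeries:
    """Per-frame RMSD after optimal superposition on ``selection − exclude``.

    ``reference`` may be a Structure, a Trajectory (frame 0) or a coordinate
    array over the full topology. Atoms in ``exclude`` are removed from both
    the fit and the deviation measure (e.g. the disordered subE:123–150 loop).
    """
    eff = selection.minus(exclude)
    if eff.is_empty:
        raise MDFlexError("empty selection after applying exclusion")
    idx = eff.indices
    ref = _ref_coords(reference, idx)
    w = None if weights is None else np.asarray(weights, dtype=float)[idx]
    out = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        _, _, out[f] = kabsch_superpose(traj.frames[f, idx], ref, w)
    if not reference_label and isinstance(reference, Structure):
        reference_label = reference.label
    return DeviationSeries(traj.times.copy(), out, eff.expression, reference_label)


def average_structure(
    traj: Trajectory,
    selection: AtomSelection | None = None,
    max_iter: int = 1,
    tol: float = 1e-4,
    weights: np.ndarray | None = None,
) -> np.ndarray:
    """Mean coordinates of the selected atoms after alignment.

    The default single pass aligns every frame to the first frame and
    averages. With ``max_iter > 1`` the procedure re-aligns to the current
    mean until the mean shifts by less than ``tol`` Å (RMS); non-convergence
    is reported as a warning, not an error.
    """
    if traj.n_frames < 2:
        raise MDFlexError("average structure needs >= 2 frames")
    idx = selection.indices if selection is not None else np.arange(traj.n_atoms)
    coords = traj.frames[:, idx, :]
    w = None if weights is None else np.asarray(weights, dtype=float)[idx]

    target = coords[0]
    mean = None
    for it in range(max(1, int(max_iter))):
        aligned = np.empty_like(coords)
        for f in range(coords.shape[0]):
            rot, trans, _ = kabsch_superpose(coords[f], target, w)
            aligned[f] = apply_fit(coords[f], rot, trans)
        new_mean = aligned.mean(axis=0)
        if mean is not None:
            shift = float(np.sqrt(np.mean(np.sum((new_mean - mean) ** 2, axis=1))))
            if shift < tol:
                return new_mean
        mean = new_mean
        target = new_mean
        if max_iter == 1:
            return mean
    warnings.warn(
        f"average_structure did not converge within {max_iter} iterations",
        RuntimeWarning,
        stacklevel=2,
    )
    return mean


def align_trajectory(
    traj: Trajectory,
    reference_coords: np.ndarray,
    selection: AtomSelection | None = None,
    weights: np.ndarray | None = None,
) -> Trajectory:
    """Rigid-fit every frame onto reference coordinates of the selection.

    The fit is computed on the selected atoms and applied to all atoms.
    ``reference_coords`` has the selection's shape ``(n_sel, 3)``.
    """
    idx = selection.indices if selection is not None else np.arange(traj.n_atoms)
    ref = np.asarray(reference_coords, dtype=float)
    w = None if weights is None else np.asarray(weights, dtype=float)[idx]
    frames = np.empty_like(traj.frames)
    for f in range(traj.n_frames):
        rot, trans, _ = kabsch_superpose(traj.frames[f, idx], ref, w)
        frames[f] = apply_fit(traj.frames[f], rot, trans)
    return Trajectory(
        structure=traj.structure,
        frames=frames,
        times=traj.times.copy(),
        label=traj.label,
        duration_ns=traj.duration_ns,
    )


def rmsf_profile(
    traj: Trajectory,
    selection: AtomSelection,
    average_max_iter: int = 1,
) -> FlexibilityProfile:
    """Root-mean-square fluctuation about the average structure.

    RMSF_i = sqrt(⟨‖r_i − ⟨r_i⟩‖²⟩) computed after aligning every frame to
    the average structure over the selection.
    """
    if selection.is_empty:
        raise MDFlexError("empty selection")
    if traj.n_frames < 2:
        raise MDFlexError("RMSF needs >= 2 frames")
    idx = selection.indices
    avg = average_structure(traj, selection, max_iter=average_max_iter)
    aligned = align_trajectory(traj, avg, selection)
    coords = aligned.frames[:, idx, :]
    mean = coords.mean(axis=0)
    rmsf = np.sqrt(np.mean(np.sum((coords - mean) ** 2, axis=2), axis=0))
    s = traj.structure
    return FlexibilityProfile(
        atom_indices=idx.copy(),
        rmsf=rmsf,
        mean_coords=mean,
        chain_ids=s.chain_ids[idx],
        res_ids=s.res_ids[idx],
        atom_names=s.atom_names[idx],
    )


def _smooth(values: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return values.astype(float)
    if window > values.size:
        raise MDFlexError(
            f"smoothing window {window} larger than chain length {values.size}"
        )
    half = window // 2
    padded = np.pad(values.astype(float), half, mode="edge")
    kernel = np.ones(window) / window
    sm = np.convolve(padded, kernel, mode="valid")
    return sm[: values.size] if sm.size > values.size else sm


def detect_hinges(
    profile: FlexibilityProfile,
    smooth_window: int = 5,
    percentile: float = 25.0,
    min_len: int = 4,
    interior_only: bool = True,
) -> list[HingeRegion]:
    """Low-mobility (hinge) intervals from a residue RMSF profile.

    Per chain, the residue RMSF is smoothed with a centred moving average and
    maximal runs of at least ``min_len`` residues below the chain's given
    RMSF percentile are reported. Runs touching a chain terminus are
    suppressed by default (``interior_only``): floppy-end minima are not
    hinges in the lever-arm sense.
    """
    res = profile.residue_profile()
    hinges: list[HingeRegion] = []
    for chain, grp in res.groupby("chain", sort=False):
        grp = grp.sort_values("resid", kind="stable")
        if len(grp) < min_len:
            continue
        values = grp["rmsf_A"].to_numpy()
        resids = grp["resid"].to_numpy()
        sm = _smooth(values, smooth_window)
        thr = np.percentile(sm, percentile)
        below = sm <= thr
        i = 0
        n = len(below)
        while i < n:
            if not below[i]:
                i += 1
                continue
            j = i
            while j + 1 < n and below[j + 1]:
                j += 1
            touches_end = i == 0 or j == n - 1
            if (j - i + 1) >= min_len and not (interior_only and touches_end):
                hinges.append(HingeRegion(str(chain), int(resids[i]), int(resids[j])))
            i = j + 1
    profile.hinges = hinges
    return hinges
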