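"""Worm-like-chain persistence-length estimation for the coiled-coil tail.

For a worm-like chain of contour length L and persistence length Lp the
mean-square end-to-end distance is

    ⟨R_ee²⟩ = 2 L Lp − 2 Lp² (1 − exp(−L/Lp))

which increases strictly with Lp from 0 (fully flexible) to L² (rigid rod).
Given ⟨R_ee²⟩ measured over an ensemble (trajectory frames or independent
chains) and the contour length, Lp is recovered as the unique root of this
relation; uncertainty comes from a block bootstrap over frames.

Lengths here are nm (the reporting unit); bead trajectories, which the rest
of the package keeps in Å, are converted on entry.
"""
from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .coarse_grain import BeadTrajectory
from .core import MDFlexError

__all__ = [
    "NM_PER_ANGSTROM",
    "InfeasibleGeometryError",
    "WLCEstimate",
    "end_to_end_series",
    "contour_length",
    "wlc_msre",
    "invert_wlc",
    "estimate_lp",
]

NM_PER_ANGSTROM = 0.1


class InfeasibleGeometryError(MDFlexError):
    """⟨R_ee²⟩ outside the open interval (0, L²): no WLC solution."""


@dataclass
class WLCEstimate:
    """Persistence-length estimate with its ingredients (all nm / nm²)."""

    contour_length: float
    msre: float
    lp: float
    lp_std: float
    ci95: tuple[float, float]
    endpoints: tuple[str, str]
    n_frames: int
    block_length: int
    n_boot: int
    seed: int | None

    def to_json(self, path) -> None:
        payload = {
            "contour_length_nm": self.contour_length,
            "mean_square_ree_nm2": self.msre,
            "persistence_length_nm": self.lp,
            "persistence_length_std_nm": self.lp_std,
            "ci95_nm": list(self.ci95),
            "endpoints": list(self.endpoints),
            "n_frames": self.n_frames,
            "block_length_frames": self.block_length,
            "n_bootstrap": self.n_boot,
            "seed": self.seed,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def _bead_index(btraj: BeadTrajectory, bead: int | str) -> int:
    if isinstance(bead, str):
        try:
            return btraj.labels.index(bead)
        except ValueError:
            raise KeyError(f"no bead labelled {bead!r}") from None
    return int(bead)


def end_to_end_series(
    btraj: BeadTrajectory,
    endpoints: tuple[int | str, int | str],
    input_units: str = "angstrom",
) -> np.ndarray:
    """Per-frame end-to-end distance (nm) between two bead centers."""
    i = _bead_index(btraj, endpoints[0])
    j = _bead_index(btraj, endpoints[1])
    if i == j:
        raise ValueError("endpoints must be distinct beads")
    scale = NM_PER_ANGSTROM if input_units == "angstrom" else 1.0
    d = np.linalg.norm(btraj.centers[:, j, :] - btraj.centers[:, i, :], axis=1)
    return d * scale


def contour_length(
    btraj: BeadTrajectory,
    beads: list[int | str] | None = None,
    input_units: str = "angstrom",
) -> float:
    """Time-averaged summed consecutive bead-center distances (nm)."""
    idx = (
        [_bead_index(btraj, b) for b in beads]
        if beads is not None
        else list(range(btraj.n_beads))
    )
    if len(idx) < 2:
        raise ValueError("contour length needs >= 2 beads")
    scale = NM_PER_ANGSTROM if input_units == "angstrom" else 1.0
    path = btraj.centers[:, idx, :]
    seg = np.linalg.norm(np.diff(path, axis=1), axis=2)
    return float(seg.sum(axis=1).mean()) * scale


_SERIES_X = 1e-4  # below this L/Lp the direct formula loses precision


def wlc_msre(L: float, Lp: float) -> float:
    """Worm-like-chain ⟨R_ee²⟩ (nm²) for contour length L and persistence
    length Lp (nm). Uses a series branch for L/Lp → 0 (near-rigid rod)."""
    if L <= 0 or Lp <= 0:
        raise ValueError("L and Lp must be positive")
    x = L / Lp
    if x < _SERIES_X:
        # L² (1 − x/3 + x²/12 − x³/60 + ...)
        return float(L * L * (1.0 - x / 3.0 + x * x / 12.0 - x**3 / 60.0))
    return float(2.0 * L * Lp + 2.0 * Lp * Lp * np.expm1(-x))


def invert_wlc(msre: float, L: float, rtol: float = 1e-9) -> float:
    """Persistence length solving ⟨R_ee²⟩ = wlc_msre(L, Lp).

    The forward map is strictly increasing in Lp, so the root is unique;
    it is bracketed in log-space and solved with Brent's method.

    Raises
    ------
    InfeasibleGeometryError
        If ``msre`` ≤ 0 (no chain) or ≥ L² (straighter than a rigid rod).
    """
    if L <= 0:
        raise ValueError("L must be positive")
    if msre <= 0 or msre >= L * L:
        raise InfeasibleGeometryError(
            f"msre={msre} outside feasible interval (0, L²={L * L})"
        )

    def f(log_lp: float) -> float:
        return wlc_msre(L, float(np.exp(log_lp))) - msre

    lo, hi = np.log(1e-9 * L), np.log(1e9 * L)
    # expand in the pathological corners (msre extremely close to 0 or L²)
    while f(lo) > 0:
        lo -= 5.0
    while f(hi) < 0:
        hi += 5.0
    # xtol on log(Lp) bounds the relative error of Lp directly
    root = brentq(f, lo, hi, xtol=min(rtol, 1e-12), maxiter=200)
    return float(np.exp(root))


def estimate_lp(
    btraj: BeadTrajectory,
    endpoints: tuple[int | str, int | str],
    tail_beads: list[int | str] | None = None,
    block_length: int = 50,
    n_boot: int = 1000,
    seed: int | None = 0,
    input_units: str = "angstrom",
    use_variance: bool = False,
) -> WLCEstimate:
    """Point estimate and block-bootstrap uncertainty of Lp (nm).

    ⟨R_ee²⟩ is by default the raw second moment of the end-to-end distance
    (the quantity on the left of the WLC relation); ``use_variance=True``
    substitutes the variance about the mean instead, offered only as a
    sensitivity check. Frames are resampled in contiguous blocks of
    ``block_length`` with replacement; each replicate re-measures both the
    contour length and ⟨R_ee²⟩ and re-inverts the WLC relation.
    """
    ree = end_to_end_series(btraj, endpoints, input_units=input_units)
    idx = (
        [_bead_index(btraj, b) for b in tail_beads]
        if tail_beads is not None
        else list(range(btraj.n_beads))
    )
    scale = NM_PER_ANGSTROM if input_units == "angstrom" else 1.0
    path = btraj.centers[:, idx, :] * scale
    seg_sums = np.linalg.norm(np.diff(path, axis=1), axis=2).sum(axis=1)

    def _estimate(r: np.ndarray, segs: np.ndarray) -> float:
        msre = float(np.var(r)) if use_variance else float(np.mean(r**2))
        L = float(segs.mean())
        return invert_wlc(msre, L)

    lp = _estimate(ree, seg_sums)

    n = ree.size
    block = max(1, min(int(block_length), n))
    n_blocks = n // block
    if n_blocks < 2:
        raise MDFlexError("need >= 2 blocks of frames for the bootstrap")
    starts = np.arange(n_blocks) * block
    rng = np.random.default_rng(seed)
    reps = []
    for _ in range(int(n_boot)):
        picks = rng.integers(0, n_blocks, size=n_blocks)
        sel = np.concatenate([np.arange(s, s + block) for s in starts[picks]])
        try:
            reps.append(_estimate(ree[sel], seg_sums[sel]))
        except InfeasibleGeometryError:
            continue  # a resample straighter than a rod carries no Lp
    reps_arr = np.asarray(reps)
    if reps_arr.size >= 2:
        std = float(reps_arr.std(ddof=1))
        ci = (float(np.percentile(reps_arr, 2.5)), float(np.percentile(reps_arr, 97.5)))
    else:
        std, ci = float("nan"), (float("nan"), float("nan"))

    labels = [
        btraj.labels[_bead_index(btraj, e)] if not isinstance(e, str) else e
        for e in endpoints
    ]
    L = float(seg_sums.mean())
    msre = float(np.var(ree)) if use_variance else float(np.mean(ree**2))
    return WLCEstimate(
        contour_length=L,
        msre=msre,
        lp=lp,
        lp_std=std,
        ci95=ci,
        endpoints=(labels[0], labels[1]),
        n_frames=n,
        block_length=block,
        n_boot=int(n_boot),
        seed=seed,
    )
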