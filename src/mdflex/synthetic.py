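"""Synthetic ensembles with known ground truth for every analysis stage.

These generators stand in for molecular-dynamics trajectories: each one
plants parameters (mode variances, persistence length, spring constants)
that the corresponding analysis module must recover, which is how the
pipeline is validated without MD data.
"""
from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.optimize import brentq
from scipy.spatial.transform import Rotation

from .coarse_grain import BOLTZMANN_KCAL, BeadMap, BeadTrajectory
from .core import MDFlexError, Structure, Trajectory, write_structure, write_trajectory
from .persistence import NM_PER_ANGSTROM

__all__ = [
    "SyntheticSpec",
    "gaussian_mode_ensemble",
    "sample_wlc",
    "wlc_chains_as_beads",
    "hinged_rod_trajectory",
    "harmonic_angle_samples",
    "beads_as_calpha",
    "synthetic_stator",
    "write_fixture",
]


@dataclass
class SyntheticSpec:
    """Record of a generator invocation: kind, ground truth, sizes, seed."""

    kind: str
    params: dict
    n: int
    seed: int

    def to_json(self, path) -> None:
        def _clean(v):
            if isinstance(v, np.ndarray):
                return v.tolist()
            if isinstance(v, (np.integer, np.floating)):
                return v.item()
            return v

        with open(path, "w") as fh:
            json.dump(
                {
                    "kind": self.kind,
                    "n": self.n,
                    "seed": self.seed,
                    "params": {k: _clean(v) for k, v in self.params.items()},
                },
                fh,
                indent=1,
            )


def _random_rotations(rng: np.random.Generator, n: int) -> Rotation:
    q = rng.normal(size=(n, 4))
    return Rotation.from_quat(q / np.linalg.norm(q, axis=1, keepdims=True))


def gaussian_mode_ensemble(
    reference: Structure,
    mode_vectors: np.ndarray,
    variances: np.ndarray,
    n_frames: int,
    noise_sigma: float = 0.0,
    rigid_motions: bool = False,
    frame_spacing: float = 0.1,
    seed: int = 0,
) -> Trajectory:
    """Gaussian fluctuations about a mean structure with planted low-rank
    covariance: frames = ref + Σᵢ aᵢ vᵢ + ε, aᵢ ~ N(0, λᵢ).

    ``mode_vectors`` is (k, 3N) with orthonormal rows; ``variances`` (Å²) are
    the planted eigenvalues λᵢ; ``noise_sigma`` adds isotropic per-coordinate
    noise (Å). With ``rigid_motions`` each frame additionally receives a
    random rotation + translation, to exercise the alignment machinery.
    """
    v = np.atleast_2d(np.asarray(mode_vectors, dtype=float))
    lam = np.atleast_1d(np.asarray(variances, dtype=float))
    n3 = 3 * reference.n_atoms
    if v.shape[1] != n3 or v.shape[0] != lam.size:
        raise ValueError("mode_vectors must be (k, 3N) matching variances")
    if np.any(lam < 0):
        raise ValueError("variances must be >= 0")
    gram = v @ v.T
    if not np.allclose(gram, np.eye(v.shape[0]), atol=1e-8):
        raise MDFlexError("mode vectors must be orthonormal")

    rng = np.random.default_rng(seed)
    amps = rng.normal(size=(n_frames, lam.size)) * np.sqrt(lam)
    flat = reference.coords.reshape(1, -1) + amps @ v
    if noise_sigma > 0:
        flat = flat + rng.normal(scale=noise_sigma, size=flat.shape)
    frames = flat.reshape(n_frames, reference.n_atoms, 3)
    if rigid_motions:
        rots = _random_rotations(rng, n_frames)
        shifts = rng.uniform(-20.0, 20.0, size=(n_frames, 3))
        for f in range(n_frames):
            frames[f] = rots[f].apply(frames[f]) + shifts[f]
    times = np.arange(n_frames, dtype=float) * frame_spacing
    return Trajectory(reference, frames, times, label=f"gaussian-modes-seed{seed}")


# ---------------------------------------------------------------------------
# discrete worm-like chain
# ---------------------------------------------------------------------------

def _langevin(kappa: float) -> float:
    if kappa < 1e-6:
        return kappa / 3.0
    return 1.0 / np.tanh(kappa) - 1.0 / kappa


def _kappa_for_mean_cos(c: float) -> float:
    """Concentration κ of p(cosθ) ∝ exp(κ cosθ) with ⟨cosθ⟩ = c."""
    if not 0.0 < c < 1.0:
        raise ValueError("mean cosine must be in (0, 1)")
    return brentq(lambda k: _langevin(k) - c, 1e-9, 1e9, maxiter=500)


def _sample_cos(rng: np.random.Generator, kappa: float, size) -> np.ndarray:
    """Inverse-CDF sample of cosθ from p ∝ exp(κ cosθ) on [−1, 1]."""
    u = rng.random(size)
    if kappa < 1e-6:
        return 2.0 * u - 1.0
    # cos = 1 + log(u + (1-u) e^{-2κ}) / κ, numerically safe via logaddexp
    return 1.0 + np.logaddexp(np.log(u), np.log1p(-u) - 2.0 * kappa) / kappa


def sample_wlc(
    n_chains: int,
    n_segments: int,
    segment_length: float,
    persistence_length: float,
    seed: int = 0,
) -> np.ndarray:
    """Discrete worm-like chains with exponential tangent correlation.

    Successive segment directions satisfy ⟨cosθ⟩ = exp(−b/Lp) exactly (the
    polar deflection is drawn from p(cosθ) ∝ exp(κ cosθ) with κ matched to
    that mean, the azimuth uniform), so the planted persistence length is
    −b/ln⟨cosθ⟩ = Lp without any small-angle approximation.

    Returns chain coordinates of shape (n_chains, n_segments + 1, 3) in the
    units of ``segment_length`` (conventionally nm).
    """
    if segment_length <= 0 or persistence_length <= 0:
        raise ValueError("segment_length and persistence_length must be > 0")
    if n_segments < 2:
        raise ValueError("need >= 2 segments")
    rng = np.random.default_rng(seed)
    c = float(np.exp(-segment_length / persistence_length))
    kappa = _kappa_for_mean_cos(c)

    # random initial directions (isotropic ensemble)
    d = rng.normal(size=(n_chains, 3))
    d /= np.linalg.norm(d, axis=1, keepdims=True)
    coords = np.zeros((n_chains, n_segments + 1, 3))
    coords[:, 1] = segment_length * d
    for s in range(1, n_segments):
        cos_t = _sample_cos(rng, kappa, n_chains)
        sin_t = np.sqrt(np.clip(1.0 - cos_t**2, 0.0, None))
        psi = rng.uniform(0.0, 2.0 * np.pi, n_chains)
        # orthonormal frame around the previous direction d
        helper = np.where(
            np.abs(d[:, [0]]) < 0.9, [[1.0, 0.0, 0.0]], [[0.0, 1.0, 0.0]]
        )
        e1 = np.cross(d, helper)
        e1 /= np.linalg.norm(e1, axis=1, keepdims=True)
        e2 = np.cross(d, e1)
        d = (
            cos_t[:, None] * d
            + sin_t[:, None] * (np.cos(psi)[:, None] * e1 + np.sin(psi)[:, None] * e2)
        )
        d /= np.linalg.norm(d, axis=1, keepdims=True)
        coords[:, s + 1] = coords[:, s] + segment_length * d
    return coords


def wlc_chains_as_beads(chains_nm: np.ndarray) -> BeadTrajectory:
    """View a WLC chain ensemble (nm) as a BeadTrajectory (Å): one 'frame'
    per chain, one bead per chain vertex."""
    chains_nm = np.asarray(chains_nm, dtype=float)
    n_beads = chains_nm.shape[1]
    labels = [f"B{i + 1}" for i in range(n_beads)]
    return BeadTrajectory(chains_nm / NM_PER_ANGSTROM, labels, weighting="geometric")


# ---------------------------------------------------------------------------
# hinged rod
# ---------------------------------------------------------------------------

def _nerf_extend(p0, p1, p2, bond, theta, phi):
    """Place the next point at distance ``bond`` from p2, bending angle
    ``theta`` at p2 and torsion ``phi`` about the p1→p2 bond."""
    bc = p2 - p1
    bc /= np.linalg.norm(bc, axis=-1, keepdims=True)
    n = np.cross(p1 - p0, bc)
    n /= np.linalg.norm(n, axis=-1, keepdims=True)
    m = np.cross(n, bc)
    d = (
        -np.cos(theta)[..., None] * bc
        + np.sin(theta)[..., None]
        * (np.cos(phi)[..., None] * m + np.sin(phi)[..., None] * n)
    )
    return p2 + bond * d


def hinged_rod_trajectory(
    angle_k: np.ndarray,
    dihedral_k: np.ndarray,
    n_frames: int,
    bond_length: float = 15.0,
    theta0: np.ndarray | float = 2.6,
    phi0: np.ndarray | float = np.pi / 2,
    temperature: float = 310.0,
    seed: int = 0,
    labels: list[str] | None = None,
) -> BeadTrajectory:
    """Bead trajectory with independently Boltzmann-sampled internal
    coordinates at planted stiffnesses.

    Each bending angle i is N(θ₀ᵢ, σᵢ²) with σᵢ² = k_BT/(2 kᵢ) (resampled
    into (0, π)); dihedrals likewise about φ₀ᵢ. Beads are reconstructed with
    fixed bond lengths: bead 1 at the origin, bead 2 on +z, bead 3 in the
    xz-plane, the rest by standard internal-coordinate (NeRF) chaining.
    Units: Å and kcal mol⁻¹ rad⁻².
    """
    angle_k = np.atleast_1d(np.asarray(angle_k, dtype=float))
    dihedral_k = np.atleast_1d(np.asarray(dihedral_k, dtype=float))
    n_beads = angle_k.size + 2
    if dihedral_k.size != max(n_beads - 3, 0):
        raise ValueError("need len(dihedral_k) == len(angle_k) - 1")
    if np.any(angle_k <= 0) or np.any(dihedral_k <= 0):
        raise ValueError("spring constants must be positive")
    theta0 = np.broadcast_to(np.asarray(theta0, dtype=float), (angle_k.size,))
    phi0 = np.broadcast_to(np.asarray(phi0, dtype=float), (dihedral_k.size,))
    if np.any(theta0 <= 0) or np.any(theta0 >= np.pi):
        raise ValueError("equilibrium angles must lie strictly inside (0, π)")

    kbt = BOLTZMANN_KCAL * temperature
    sig_a = np.sqrt(kbt / (2.0 * angle_k))
    sig_d = np.sqrt(kbt / (2.0 * dihedral_k))
    rng = np.random.default_rng(seed)

    thetas = rng.normal(theta0, sig_a, size=(n_frames, angle_k.size))
    # resample the rare draws outside (0, π): reconstruction needs valid angles
    bad = (thetas <= 1e-6) | (thetas >= np.pi - 1e-6)
    while bad.any():
        thetas[bad] = rng.normal(
            np.broadcast_to(theta0, thetas.shape)[bad],
            np.broadcast_to(sig_a, thetas.shape)[bad],
        )
        bad = (thetas <= 1e-6) | (thetas >= np.pi - 1e-6)
    phis = rng.normal(phi0, sig_d, size=(n_frames, dihedral_k.size))

    centers = np.zeros((n_frames, n_beads, 3))
    centers[:, 1] = [0.0, 0.0, bond_length]
    if n_beads >= 3:
        t1 = thetas[:, 0]
        centers[:, 2] = centers[:, 1] + bond_length * np.stack(
            [np.sin(t1), np.zeros_like(t1), -np.cos(t1)], axis=1
        )
    for b in range(3, n_beads):
        centers[:, b] = _nerf_extend(
            centers[:, b - 3],
            centers[:, b - 2],
            centers[:, b - 1],
            bond_length,
            thetas[:, b - 2],
            phis[:, b - 3],
        )
    labels = labels or [f"P{i + 1}" for i in range(n_beads)]
    return BeadTrajectory(
        centers,
        labels,
        times=np.arange(n_frames, dtype=float),
        weighting="geometric",
    )


def harmonic_angle_samples(
    k_true: float,
    temperature: float = 310.0,
    n: int = 100_000,
    seed: int = 0,
    theta0: float = np.pi / 2,
    wrap: bool = False,
) -> np.ndarray:
    """Boltzmann samples of a harmonic internal coordinate: N(θ₀, σ²) with
    σ² = k_BT/(2 k_true). ``wrap=True`` folds the output into (−π, π] the
    way a dihedral is reported."""
    if k_true <= 0 or temperature <= 0:
        raise ValueError("k_true and temperature must be positive")
    rng = np.random.default_rng(seed)
    sigma = np.sqrt(BOLTZMANN_KCAL * temperature / (2.0 * k_true))
    s = rng.normal(theta0, sigma, size=n)
    if wrap:
        s = np.mod(s + np.pi, 2.0 * np.pi) - np.pi
        s[s <= -np.pi] = np.pi
    return s


# ---------------------------------------------------------------------------
# topology helpers and fixture writing
# ---------------------------------------------------------------------------

def beads_as_calpha(
    btraj: BeadTrajectory,
    residues_per_bead: int = 1,
    chain: str = "A",
    jitter: float = 0.0,
    seed: int = 0,
) -> tuple[Structure, Trajectory]:
    """Expand a bead trajectory into a Cα-trace Structure + Trajectory.

    Each bead becomes ``residues_per_bead`` consecutive residues whose CA
    atoms sit at the bead center (optionally jittered by a fixed per-atom
    offset of scale ``jitter`` Å so atoms are not exactly coincident).
    Useful to feed bead-level ground truth through the atomistic analyses.
    """
    n_beads = btraj.n_beads
    n_res = n_beads * residues_per_bead
    rng = np.random.default_rng(seed)
    offsets = (
        rng.normal(scale=jitter, size=(n_res, 3)) if jitter > 0 else np.zeros((n_res, 3))
    )
    rep = np.repeat(np.arange(n_beads), residues_per_bead)
    frames = btraj.centers[:, rep, :] + offsets[None, :, :]
    structure = Structure(
        atom_names=np.array(["CA"] * n_res, dtype=object),
        elements=np.array(["C"] * n_res, dtype=object),
        chain_ids=np.array([chain] * n_res, dtype=object),
        res_ids=np.arange(1, n_res + 1),
        res_names=np.array(["ALA"] * n_res, dtype=object),
        masses=np.full(n_res, 12.011),
        coords=frames[0],
        label="bead-calpha",
    )
    times = (
        btraj.times.copy()
        if btraj.times is not None
        else np.arange(btraj.n_frames, dtype=float)
    )
    return structure, Trajectory(structure, frames, times, label="bead-calpha")


def synthetic_stator(
    n_frames: int = 200,
    mode_variances: tuple[float, ...] = (9.0, 3.0, 1.0),
    noise_sigma: float = 0.1,
    rigid_motions: bool = False,
    frame_spacing: float = 0.5,
    seed: int = 0,
) -> tuple[Structure, Trajectory]:
    """A Cα-trace two-chain stand-in for the EG stator with planted
    low-rank Gaussian dynamics.

    Chain E spans residues 3–188 and chain G residues 21–120 (the author
    numbering the shipped bead map uses), laid out as two gently twisted
    strands, so the Table-2 bead map applies directly. The planted modes are
    smooth orthonormalised bending shapes with the given variances (Å²).
    """
    res_e = np.arange(3, 189)
    res_g = np.arange(21, 121)
    rise = 1.5  # Å per residue along the rod axis

    def strand(res: np.ndarray, phase: float, x0: float) -> np.ndarray:
        t = np.arange(res.size) * rise
        return np.stack(
            [
                x0 + 2.5 * np.cos(0.35 * t + phase),
                2.5 * np.sin(0.35 * t + phase),
                t,
            ],
            axis=1,
        )

    coords = np.vstack([strand(res_e, 0.0, 0.0), strand(res_g, np.pi, 7.0)])
    n = coords.shape[0]
    structure = Structure(
        atom_names=np.array(["CA"] * n, dtype=object),
        elements=np.array(["C"] * n, dtype=object),
        chain_ids=np.array(["E"] * res_e.size + ["G"] * res_g.size, dtype=object),
        res_ids=np.concatenate([res_e, res_g]),
        res_names=np.array(["ALA"] * n, dtype=object),
        masses=np.full(n, 12.011),
        coords=coords,
        label="synthetic-stator",
    )

    # smooth collective shapes: transverse displacements growing along z.
    # They are projected out of the rigid-body subspace (3 translations + 3
    # infinitesimal rotations about the centroid) so that superposition does
    # not absorb the planted fluctuations.
    z = coords[:, 2]
    zn = (z - z.min()) / (z.max() - z.min())
    k = len(mode_variances)
    raw = np.zeros((k, n, 3))
    for m in range(k):
        shape = np.sin((m + 1) * np.pi * zn)
        raw[m, :, m % 2] = shape  # alternate x / y bending
        if m >= 2:
            raw[m, :, 2] = 0.3 * np.cos(2 * np.pi * zn)
    centered = coords - coords.mean(axis=0)
    rigid = np.zeros((6, n, 3))
    rigid[0, :, 0] = rigid[1, :, 1] = rigid[2, :, 2] = 1.0
    for a in range(3):
        axis = np.zeros(3)
        axis[a] = 1.0
        rigid[3 + a] = np.cross(axis, centered)
    rigid_q, _ = np.linalg.qr(rigid.reshape(6, -1).T)
    flat = raw.reshape(k, -1)
    flat = flat - (flat @ rigid_q) @ rigid_q.T
    q, _ = np.linalg.qr(flat.T)
    modes = q.T[:k]

    traj = gaussian_mode_ensemble(
        structure,
        modes,
        np.asarray(mode_variances, dtype=float),
        n_frames=n_frames,
        noise_sigma=noise_sigma,
        rigid_motions=rigid_motions,
        frame_spacing=frame_spacing,
        seed=seed,
    )
    return structure, traj


def write_fixture(
    structure: Structure,
    trajectory: Trajectory,
    bead_map: BeadMap | None,
    out_dir: str | Path,
    traj_format: str = "dcd",
    spec: SyntheticSpec | None = None,
) -> dict[str, str]:
    """Write a PDB + DCD/XTC (+ bead-map TSV) fixture set with a sidecar
    JSON recording parameters, seed and file checksums.

    Coordinates are rounded to format precision before writing so that the
    same seed regenerates bit-identical files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}

    pdb_path = out / "structure.pdb"
    write_structure(structure, pdb_path)
    paths["structure"] = str(pdb_path)

    traj_path = out / f"trajectory.{traj_format}"
    rounded = Trajectory(
        structure=trajectory.structure,
        frames=np.round(trajectory.frames, 3),
        times=trajectory.times,
        label=trajectory.label,
        duration_ns=trajectory.duration_ns,
    )
    write_trajectory(rounded, traj_path, format=traj_format)
    paths["trajectory"] = str(traj_path)

    if bead_map is not None:
        bm_path = out / "beads.tsv"
        bead_map.to_tsv(bm_path)
        paths["bead_map"] = str(bm_path)

    sidecar = {
        "files": {
            key: hashlib.sha256(Path(p).read_bytes()).hexdigest()
            for key, p in paths.items()
        }
    }
    if spec is not None:
        sidecar["kind"] = spec.kind
        sidecar["n"] = spec.n
        sidecar["seed"] = spec.seed
        sidecar["params"] = {
            k: (v.tolist() if isinstance(v, np.ndarray) else v)
            for k, v in spec.params.items()
        }
    sc_path = out / "fixture.json"
    with open(sc_path, "w") as fh:
        json.dump(sidecar, fh, indent=1, sort_keys=True)
    paths["sidecar"] = str(sc_path)
    return paths
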