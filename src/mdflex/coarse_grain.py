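"""Residue→bead coarse-graining and equipartition elasticity profiles.

A bead map assigns residue intervals of each chain to an ordered series of
beads; bead centers traced over a trajectory define consecutive-bead bending
angles and dihedrals whose thermal variances are Boltzmann-inverted into
effective spring constants:

    k_i = k_B T / (2 σ_i²)

NOTE the potential convention: this k corresponds to U = k·Δx² — i.e. it is
HALF the force constant of the common U = ½k·Δx² convention. Downstream users
expecting the ½-convention must multiply by 2.
"""
from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .core import MDFlexError, Structure, Trajectory

__all__ = [
    "BOLTZMANN_KCAL",
    "BeadMapError",
    "BeadMap",
    "BeadTrajectory",
    "InternalCoordinateSeries",
    "ElasticityProfile",
    "load_bead_map",
    "eg_stator_bead_map",
    "bead_trajectory",
    "internal_coordinates",
    "spring_constants",
]

#: Boltzmann constant in kcal mol⁻¹ K⁻¹.
BOLTZMANN_KCAL = 1.9872041e-3

_DASHES = re.compile(r"[‐-―−]")  # unicode hyphens/dashes → '-'


class BeadMapError(MDFlexError):
    """Invalid bead map (overlaps, empty beads, malformed ranges)."""


@dataclass
class BeadMap:
    """Ordered bead labels with per-chain residue-interval assignments.

    ``assignments[label]`` is a list of ``(chain, first_resid, last_resid)``
    inclusive intervals; ``domains[label]`` is an optional structural-domain
    tag (e.g. head / neck / tail). Bead order defines the chain of
    consecutive-bead angles and dihedrals.
    """

    labels: list[str]
    assignments: dict[str, list[tuple[str, int, int]]]
    domains: dict[str, str | None] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: dict[tuple[str, int], str] = {}
        for label in self.labels:
            ivs = self.assignments.get(label, [])
            if not ivs:
                raise BeadMapError(f"bead {label!r} has no residues assigned")
            for chain, lo, hi in ivs:
                if hi < lo:
                    raise BeadMapError(f"descending interval {lo}-{hi} in {label!r}")
                for r in range(lo, hi + 1):
                    key = (chain, r)
                    if key in seen:
                        raise BeadMapError(
                            f"residue {chain}:{r} assigned to both "
                            f"{seen[key]!r} and {label!r}"
                        )
                    seen[key] = label
        self._residue_to_bead = seen

    @property
    def n_beads(self) -> int:
        return len(self.labels)

    @property
    def chains(self) -> list[str]:
        out: list[str] = []
        for ivs in self.assignments.values():
            for chain, _, _ in ivs:
                if chain not in out:
                    out.append(chain)
        return out

    def residues(self, chain: str) -> set[int]:
        return {r for (c, r) in self._residue_to_bead if c == chain}

    def domain(self, label: str) -> str | None:
        return self.domains.get(label)

    def unassigned_report(self) -> dict[str, list[int]]:
        """Residues inside each chain's assigned span that no bead covers."""
        report = {}
        for chain in self.chains:
            assigned = self.residues(chain)
            lo, hi = min(assigned), max(assigned)
            gaps = sorted(set(range(lo, hi + 1)) - assigned)
            if gaps:
                report[chain] = gaps
        return report

    def atom_indices(self, structure: Structure) -> list[np.ndarray]:
        """Per-bead atom index arrays into ``structure`` (map order)."""
        out = []
        for label in self.labels:
            mask = np.zeros(structure.n_atoms, dtype=bool)
            for chain, lo, hi in self.assignments[label]:
                sub = (
                    (structure.chain_ids.astype(str) == chain)
                    & (structure.res_ids >= lo)
                    & (structure.res_ids <= hi)
                )
                mask |= sub
            idx = np.flatnonzero(mask)
            if idx.size == 0:
                raise BeadMapError(
                    f"bead {label!r} maps to no atoms in the topology"
                )
            out.append(idx)
        return out

    def to_tsv(self, path) -> None:
        chains = self.chains
        rows = []
        for label in self.labels:
            row = {"bead": label}
            for chain in chains:
                parts = [
                    (f"{lo}-{hi}" if hi > lo else str(lo))
                    for c, lo, hi in self.assignments[label]
                    if c == chain
                ]
                row[chain] = ",".join(parts) if parts else "-"
            if any(self.domains.values()):
                row["domain"] = self.domains.get(label) or "-"
            rows.append(row)
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _parse_ranges(cell: str, chain: str, label: str) -> list[tuple[str, int, int]]:
    cell = _DASHES.sub("-", str(cell)).strip()
    if cell in ("", "-", "nan", "None"):
        return []
    out = []
    for part in cell.split(","):
        part = part.strip()
        if not part:
            continue
        m = re.fullmatch(r"(\d+)(?:-(\d+))?", part)
        if m is None:
            raise BeadMapError(f"malformed range {part!r} for bead {label!r}")
        lo = int(m.group(1))
        hi = int(m.group(2)) if m.group(2) else lo
        out.append((chain, lo, hi))
    return out


def load_bead_map(path) -> BeadMap:
    """Load a TSV bead map.

    Expected columns: ``bead`` (label), one column per chain holding
    comma-separated inclusive residue ranges (``-`` for none), and an
    optional ``domain`` column with a structural tag per bead.
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("-")
    cols = list(df.columns)
    if not cols or cols[0].lower() not in ("bead", "# cg bead", "cg bead"):
        raise BeadMapError("first column of a bead map must be 'bead'")
    chain_cols = [c for c in cols[1:] if c.lower() != "domain"]
    has_domain = any(c.lower() == "domain" for c in cols)
    labels, assignments, domains = [], {}, {}
    for _, row in df.iterrows():
        label = str(row[cols[0]]).strip()
        labels.append(label)
        ivs: list[tuple[str, int, int]] = []
        for chain in chain_cols:
            ivs.extend(_parse_ranges(row[chain], chain, label))
        assignments[label] = ivs
        if has_domain:
            dom = str(row["domain"]).strip()
            domains[label] = dom if dom not in ("-", "") else None
        else:
            domains[label] = None
    return BeadMap(labels, assignments, domains)


def eg_stator_bead_map() -> BeadMap:
    """The 15-bead map of the A-ATPase EG peripheral stalk shipped with the
    package (head P1–P4, neck P5, coiled-coil tail P6–P15)."""
    ref = resources.files("mdflex.data").joinpath("eg_stator_beads.tsv")
    with resources.as_file(ref) as p:
        return load_bead_map(p)


@dataclass
class BeadTrajectory:
    """Per-frame bead centers (Å) in bead-map order."""

    centers: np.ndarray  # (n_frames, n_beads, 3) Å
    labels: list[str]
    times: np.ndarray | None = None
    domains: dict[str, str | None] = field(default_factory=dict)
    weighting: str = "mass"

    def __post_init__(self) -> None:
        self.centers = np.asarray(self.centers, dtype=float)
        if self.centers.ndim != 3 or self.centers.shape[2] != 3:
            raise MDFlexError("bead centers must have shape (frames, beads, 3)")
        if not np.all(np.isfinite(self.centers)):
            raise MDFlexError("non-finite bead centers")
        if self.centers.shape[1] != len(self.labels):
            raise MDFlexError("bead count does not match labels")

    @property
    def n_frames(self) -> int:
        return self.centers.shape[0]

    @property
    def n_beads(self) -> int:
        return self.centers.shape[1]


def bead_trajectory(
    traj: Trajectory,
    bead_map: BeadMap,
    weighting: str = "mass",
) -> BeadTrajectory:
    """Map an atomistic trajectory onto bead centers.

    ``weighting='mass'`` gives centers of mass (default), ``'geometric'``
    plain coordinate means.
    """
    if weighting not in ("mass", "geometric"):
        raise ValueError("weighting must be 'mass' or 'geometric'")
    idx_per_bead = bead_map.atom_indices(traj.structure)
    centers = np.empty((traj.n_frames, bead_map.n_beads, 3))
    for b, idx in enumerate(idx_per_bead):
        if weighting == "mass":
            w = traj.structure.masses[idx]
            w = w / w.sum()
        else:
            w = np.full(idx.size, 1.0 / idx.size)
        centers[:, b, :] = np.einsum("fij,i->fj", traj.frames[:, idx, :], w)
    return BeadTrajectory(
        centers,
        list(bead_map.labels),
        times=traj.times.copy(),
        domains=dict(bead_map.domains),
        weighting=weighting,
    )


@dataclass
class InternalCoordinateSeries:
    """Per-frame value of one consecutive-bead angle or dihedral (rad).

    Angles lie in [0, π]; dihedrals are reported wrapped to (−π, π] but the
    variance is computed on the unwrapped series (cumulative ±2π correction),
    since the naive variance of wrapped angles is biased near ±π. Frames
    where the coordinate is geometrically undefined (collinear beads) are
    flagged in ``degenerate`` and excluded from the variance.
    """

    kind: str  # "angle" | "dihedral"
    index: int  # 1-based, in bead-chain order
    beads: tuple[str, ...]
    values: np.ndarray  # rad
    degenerate: np.ndarray  # bool mask per frame

    @property
    def valid_values(self) -> np.ndarray:
        return self.values[~self.degenerate]

    def unwrapped(self) -> np.ndarray:
        v = self.valid_values
        return np.unwrap(v) if self.kind == "dihedral" else v

    @property
    def variance(self) -> float:
        """Sample variance (rad², n−1 denominator) on the unwrapped series."""
        v = self.unwrapped()
        if v.size < 2:
            raise MDFlexError(f"{self.kind} #{self.index}: <2 valid frames")
        return float(np.var(v, ddof=1))

    @property
    def circular_variance(self) -> float:
        """1 − |⟨e^{iθ}⟩|, a wrap-free dispersion cross-check."""
        v = self.valid_values
        return float(1.0 - np.abs(np.exp(1j * v).mean()))


_DEGEN_SIN = 1e-8


def _angles(centers: np.ndarray) -> np.ndarray:
    """Bending angle at each interior bead: (F, B−2) in [0, π]."""
    u = centers[:, :-2, :] - centers[:, 1:-1, :]
    v = centers[:, 2:, :] - centers[:, 1:-1, :]
    un = np.linalg.norm(u, axis=2)
    vn = np.linalg.norm(v, axis=2)
    cosang = np.einsum("fbk,fbk->fb", u, v) / (un * vn)
    return np.arccos(np.clip(cosang, -1.0, 1.0))


def _dihedrals(centers: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Torsion about each interior bond: (F, B−3) in (−π, π], plus a
    degeneracy mask for frames with collinear defining beads.

    Convention: 0 for cis (eclipsed), ±π for trans."""
    b1 = centers[:, 1:-2, :] - centers[:, :-3, :]
    b2 = centers[:, 2:-1, :] - centers[:, 1:-2, :]
    b3 = centers[:, 3:, :] - centers[:, 2:-1, :]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    b2n = np.linalg.norm(b2, axis=2)
    x = np.einsum("fbk,fbk->fb", n1, n2)
    y = np.einsum("fbk,fbk->fb", np.cross(n1, n2), b2 / b2n[..., None])
    phi = np.arctan2(y, x)
    degen = (np.linalg.norm(n1, axis=2) < _DEGEN_SIN) | (
        np.linalg.norm(n2, axis=2) < _DEGEN_SIN
    )
    # wrap convention (−π, π]
    phi[phi <= -np.pi] = np.pi
    return phi, degen


def internal_coordinates(btraj: BeadTrajectory) -> list[InternalCoordinateSeries]:
    """All consecutive-bead angles and dihedrals of a bead trajectory.

    For n beads this yields exactly n−2 angle series (angle #1 over beads
    1–3, etc.) followed by n−3 dihedral series (dihedral #1 over beads 1–4).
    """
    n = btraj.n_beads
    if n < 3:
        raise MDFlexError("need >= 3 beads for angles")
    out: list[InternalCoordinateSeries] = []
    ang = _angles(btraj.centers)
    for i in range(n - 2):
        # angle undefined if either arm has zero length handled upstream
        degen = np.zeros(btraj.n_frames, dtype=bool)
        out.append(
            InternalCoordinateSeries(
                "angle",
                i + 1,
                tuple(btraj.labels[i : i + 3]),
                ang[:, i],
                degen,
            )
        )
    if n >= 4:
        dih, degen = _dihedrals(btraj.centers)
        for i in range(n - 3):
            out.append(
                InternalCoordinateSeries(
                    "dihedral",
                    i + 1,
                    tuple(btraj.labels[i : i + 4]),
                    dih[:, i],
                    degen[:, i],
                )
            )
    return out


@dataclass
class ElasticityProfile:
    """Effective spring constants k_i = k_B T / (2 σ_i²) per internal
    coordinate, ordered angle #1…#(n−2) then dihedral #1…#(n−3)."""

    table: pd.DataFrame  # kind, index, beads, variance_rad2, k, domain
    temperature: float  # K
    boltzmann: float = BOLTZMANN_KCAL  # kcal mol⁻¹ K⁻¹

    @property
    def k(self) -> np.ndarray:
        return self.table["k_kcal_mol_rad2"].to_numpy()

    def subset(self, kind: str) -> pd.DataFrame:
        return self.table[self.table["kind"] == kind].reset_index(drop=True)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    def to_json(self, path) -> None:
        payload = {
            "temperature_K": self.temperature,
            "boltzmann_kcal_mol_K": self.boltzmann,
            "convention": "U = k * dx^2 (k = kBT / (2 sigma^2))",
            "coordinates": self.table.to_dict(orient="records"),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def _domain_class(beads: tuple[str, ...], domains: dict[str, str | None]) -> str | None:
    tags = [domains.get(b) for b in beads]
    if any(t is None for t in tags):
        return None
    if "neck" in tags:
        return "neck"
    if all(t == tags[0] for t in tags):
        return tags[0]
    return "mixed"


def spring_constants(
    series: list[InternalCoordinateSeries],
    temperature: float = 310.0,
    domains: dict[str, str | None] | None = None,
) -> ElasticityProfile:
    """Boltzmann-inversion elasticity profile from internal-coordinate series.

    k_i = k_B·T / (2·σ_i²) in kcal mol⁻¹ rad⁻². A coordinate whose variance
    is exactly zero has formally infinite stiffness and raises an error
    naming the coordinate. Any coordinate involving a neck-tagged bead is
    classed 'neck'; otherwise the common tag of its beads applies.
    """
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    domains = domains or {}
    kbt = BOLTZMANN_KCAL * temperature
    rows = []
    order = {"angle": 0, "dihedral": 1}
    for s in sorted(series, key=lambda s: (order.get(s.kind, 2), s.index)):
        var = s.variance
        # roundoff floor: a constant series yields ~eps²-scale variance
        floor = 1e-24 * max(1.0, float(np.mean(s.unwrapped()) ** 2))
        if var <= floor:
            raise MDFlexError(
                f"{s.kind} #{s.index} has zero variance (infinite stiffness)"
            )
        rows.append(
            {
                "kind": s.kind,
                "index": s.index,
                "beads": "-".join(s.beads),
                "variance_rad2": var,
                "k_kcal_mol_rad2": kbt / (2.0 * var),
                "domain": _domain_class(s.beads, domains),
            }
        )
    return ElasticityProfile(pd.DataFrame(rows), temperature)
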