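#!/usr/bin/env python
"""Coarse-grain elasticity profiles: bead mapping + equipartition inversion.

Two parts: (1) the 15-bead map applied to the synthetic stator ensemble,
giving the 13-angle / 12-dihedral spring-constant profile with head/neck/
tail domain labels; (2) a hinged-rod control with planted per-coordinate
stiffnesses, showing the profile recovers the planted values and ordering.
"""
from pathlib import Path

import numpy as np

from mdflex import (
    bead_trajectory,
    hinged_rod_trajectory,
    internal_coordinates,
    load_bead_map,
    read_structure,
    read_trajectory,
    spring_constants,
)

ROOT = Path(__file__).resolve().parents[1]
FIXTURES = ROOT / "scratch" / "fixtures"
RESULTS = ROOT / "results"
SEED = 2024


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    structure = read_structure(FIXTURES / "structure.pdb")
    traj = read_trajectory(FIXTURES / "trajectory.dcd", structure, timestep=0.5)
    bm = load_bead_map(FIXTURES / "beads.tsv")

    bt = bead_trajectory(traj, bm, weighting="mass")
    prof = spring_constants(internal_coordinates(bt), temperature=310.0,
                            domains=bm.domains)
    prof.to_csv(RESULTS / "elasticity_stator.csv")
    prof.to_json(RESULTS / "elasticity_stator.json")
    t = prof.table
    for kind in ("angle", "dihedral"):
        sub = t[t["kind"] == kind]
        print(f"{kind}s: n={len(sub)}, k in "
              f"[{sub['k_kcal_mol_rad2'].min():.3g}, "
              f"{sub['k_kcal_mol_rad2'].max():.3g}] kcal/mol/rad^2")

    # control with known truth
    angle_k = np.array([6.0, 45.0, 2.5, 80.0, 18.0, 33.0])
    dihedral_k = np.array([3.0, 55.0, 9.0, 20.0, 1.8])
    rod = hinged_rod_trajectory(angle_k=angle_k, dihedral_k=dihedral_k,
                                n_frames=10_000, theta0=2.0, seed=SEED)
    rod_prof = spring_constants(internal_coordinates(rod), temperature=310.0)
    rod_prof.to_csv(RESULTS / "elasticity_hinged_rod.csv")
    got = np.concatenate([
        rod_prof.subset("angle")["k_kcal_mol_rad2"].to_numpy(),
        rod_prof.subset("dihedral")["k_kcal_mol_rad2"].to_numpy(),
    ])
    planted = np.concatenate([angle_k, dihedral_k])
    err = np.abs(got / planted - 1.0)
    print(f"hinged-rod control: max |relative error| {100 * err.max():.1f}% "
          f"over {planted.size} planted constants; "
          f"ordering preserved: {np.array_equal(np.argsort(got), np.argsort(planted))}")


if __name__ == "__main__":
    main()
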