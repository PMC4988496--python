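#!/usr/bin/env python
"""Generate the synthetic ensembles every later analysis step consumes.

Writes a Cα-trace stator fixture (PDB + DCD + 15-bead map, with sidecar
ground truth) under scratch/fixtures, plus the WLC chain ensemble and the
hinged-rod bead trajectory parameters used downstream. All later scripts
re-derive their inputs from the seeds recorded here.
"""
from pathlib import Path

from mdflex import SyntheticSpec, eg_stator_bead_map, synthetic_stator, write_fixture

SEED = 2024
N_FRAMES = 2000

ROOT = Path(__file__).resolve().parents[1]
FIXTURES = ROOT / "scratch" / "fixtures"


def main() -> None:
    structure, traj = synthetic_stator(n_frames=N_FRAMES, seed=SEED)
    spec = SyntheticSpec(
        "gaussian_modes",
        {"mode_variances": [9.0, 3.0, 1.0], "noise_sigma": 0.1,
         "frame_spacing_ns": 0.5},
        N_FRAMES,
        SEED,
    )
    paths = write_fixture(structure, traj, eg_stator_bead_map(), FIXTURES, spec=spec)
    print(f"stator ensemble: {structure.n_atoms} Cα atoms x {traj.n_frames} frames "
          f"({traj.duration_ns:.0f} ns nominal)")
    for k, p in paths.items():
        print(f"  {k}: {p}")


if __name__ == "__main__":
    main()
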