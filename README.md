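# mdflex

Flexibility analysis of molecular-dynamics trajectories of the A-ATPase EG
peripheral stalk (and rod-like protein complexes generally): least-squares
superposition with RMSD/RMSF profiles and hinge detection, Cartesian
principal component analysis with free-energy (PMF) projections,
coarse-grain bead elasticity profiles by Boltzmann inversion, and
worm-like-chain persistence-length estimation. Every analysis stage ships
with a synthetic-ensemble generator carrying known ground truth, so the
whole pipeline is validated by parameter recovery without any MD data.

## Who it is for

Structural biophysicists who have atomistic trajectories (DCD/XTC + PDB) of
an elongated complex — a coiled-coil stator, a stalk, a filament segment —
and want the standard mechanics-oriented analyses in one place with
reproducible, scriptable outputs (CSV/JSON) instead of ad-hoc tool chains.

## The quantities it computes

- **RMSD / RMSF** after optimal (Kabsch) superposition: per-frame deviation
  from a reference conformer and per-residue fluctuation about the average
  structure, with configurable atom selections and exclusions (e.g. a
  disordered loop left out of the fit and the measure).
- **Hinges**: per chain, maximal runs of residues whose smoothed RMSF falls
  below a percentile of that chain's profile — the low-mobility pivots that
  let rigid domains reorient.
- **Essential dynamics**: eigendecomposition of the Cartesian covariance
  C = ⟨Δx Δxᵀ⟩ of the aligned ensemble; variance fractions, projections
  q_i = v_iᵀ(x − x̄), and 2-D PMFs G = −ln(n/n_max) in units of k_BT.
- **Coarse-grain elasticity**: residues mapped onto beads (the shipped
  table splits the EG stator into 15 beads: head P1–P4, neck P5, coiled-coil
  tail P6–P15); every consecutive-bead angle and dihedral gets an effective
  spring constant by equipartition,

      k_i = k_B T / (2 σ_i²)      [kcal mol⁻¹ rad⁻²]

  where σ_i² is the sample variance of the internal coordinate. Note the
  convention: this k corresponds to U = k·Δx², i.e. half the force constant
  of the U = ½k·Δx² convention.
- **Persistence length**: from the mean-square end-to-end distance of the
  tail and its contour length L, L_p solves the worm-like-chain relation

      ⟨R_ee²⟩ = 2 L L_p − 2 L_p² (1 − e^(−L/L_p))

  by bracketed root finding (the map is strictly increasing in L_p), with a
  block bootstrap over frames for the uncertainty.

## Worked example

The numbered scripts under `analysis/` run the full chain on synthetic
ensembles with known ground truth:

```
python analysis/01_simulate_ensembles.py   # fixture: 286 Cα x 2000 frames
python analysis/03_pca_landscape.py
python analysis/05_persistence_length.py
```

prints (abridged):

```
first 1 mode(s): 41.0% of total variance
first 2 mode(s): 55.2% of total variance
first 3 mode(s): 60.0% of total variance
PMF grid: 629 occupied bins, max 2.64 kBT
WLC control (planted Lp 105 nm, L 30.0 nm): recovered Lp = 104.1 ± 1.5 nm
```

The generator planted three collective modes with variances 9/3/1 Å² over
an isotropic 0.1 Å noise floor spread across 858 coordinates, so the true
cumulative fractions are 41.8 / 55.7 / 60.2 % — the PCA recovers them to
within sampling error. The worm-like-chain control draws 2000 discrete
chains (segment 0.5 nm, contour 30 nm) at L_p = 105 nm and inverts the WLC
relation on their measured ⟨R_ee²⟩; the recovered 104.1 ± 1.5 nm shows the
estimator is unbiased at that stiffness.

Library use is equally direct:

```python
import mdflex

s = mdflex.read_structure("structure.pdb")
t = mdflex.read_trajectory("trajectory.dcd", s, timestep=0.5)  # ns/frame
sel = mdflex.select(s, "name CA")
excl = mdflex.select(s, "chain E and resid 123-150")
rmsd = mdflex.rmsd_series(t, s, sel, exclude=excl)
modes, aligned = mdflex.fit_pca(t, sel)
print(mdflex.variance_fractions(modes, 3))
```

A config-driven runner (`mdflex run config.yaml`) executes every stage in
order — load → window union → RMSD → RMSF/hinges → PCA/PMF → elasticity →
persistence length — writing per-stage tables plus a machine-readable
`report.json`; `mdflex simulate` and `mdflex fixtures` generate the
synthetic ensembles from the command line.

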