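# ljfit

A desk-scale toolkit for refitting Lennard-Jones force-field parameters
against solvation free energies and liquid densities. It reimplements a
complete fit–evaluate loop offline:

* **forcefield** — atom-type parameter sets (ε, σ) with pairwise (ξ, ζ)
  modifiers in the Lorentz–Berthelot combining rules
  (ε_ij = (1+ξ)·√(ε_i ε_j), σ_ij = (1+ζ)·(σ_i+σ_j)/2), plain-text parameter
  files, and a GROMACS-style `[nonbond_params]` exporter.
* **charges** — vacuum/continuum charge-set averaging (implicit polarization)
  and linear mole-fraction charge interpolation for binary mixtures.
* **toysim** — a Metropolis Monte Carlo engine for rigid LJ / point-charge
  molecules in periodic boxes: NVT and NPT (ln V volume moves), analytic tail
  corrections, block-averaged densities, and Widom test-particle insertion.
* **alchemy** — alchemical solvation free energies: a 1-1-48 softcore
  decoupling potential (α = 0.003), multi-state sampling, a from-scratch MBAR
  estimator (self-consistent + Newton, asymptotic covariance, overlap
  diagnostics), bootstrap errors, statistical-inefficiency subsampling, and
  λ-schedule redistribution toward equal per-interval uncertainties.
* **objective** — RMSD/MAE, through-origin regression slope and Pearson R,
  substance-group and temperature-bin RMSD aggregation, and the weighted
  RMSD-ratio objective `Z = w_dG·RMSD_dG/ref + w_ρ·RMSD_ρ/ref`.
* **optimizer** — Nelder–Mead downhill simplex with oriented restarts, box
  bounds by projection, and a sequential atom-type adaptation scheduler with
  prerequisite validation (including the published 21-type adaptation order).
* **solubility** — relative solubilities `ln(c_A/c_B) = −β·(ΔG_A − ΔG_B)`
  with uncertainty propagation and all-pairs enumeration.
* **synthetic** — seeded toy libraries with known ground-truth parameters,
  deterministic reference generation (cached solvent trajectories + Widom),
  and Gaussian noise models, enabling full parameter-recovery experiments.

## CLI

```bash
ljfit fixtures --out fixtures/ --seed 1 --n-types 2   # synthetic library + reference CSV
ljfit evaluate --data data.csv --out report.json --exclude-group iodine
ljfit dgsolv  --seed 1 --n-types 2 --out dg.csv       # Widom-route ΔG_solv per system
ljfit density --seed 1 --n-types 2 --out rho.csv      # NPT densities per system
ljfit relsol  --records dg_records.csv --out relsol   # all-pairs relative solubilities
ljfit fit     --seed 1 --n-types 2 --out fitdir/      # sequential parameter recovery
```

`fit` also accepts `--config config.yaml` (keys: seed, n_types, noise_sd_dg,
n_restarts, skip_water). Every output directory gets a `run_meta.json` with
the config hash, seeds and toolkit version. Exit codes: 0 success, 1 runtime
failure, 2 configuration error.

## Notes

* Units: kJ/mol, nm, e, K, bar, kg/m³; R = 8.314462618×10⁻³ kJ/(mol·K).
* The toy engine replaces production MD: only equilibrium averages matter at
  desk scale. Electrostatics are truncated-and-shifted (no Ewald); default
  test systems are neutral.
* In the alchemical workflow only solute–solvent LJ interactions are
  λ-scaled; solute charges are off (documented limitation for the neutral
  toy solutes).
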