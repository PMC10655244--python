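# ringstack

Coarse-grained simulation and analysis toolkit for concentrated solutions of
semiflexible charged ring polymers (DNA mini-ring-like models) with explicit
counterions.

The package bundles:

- **model** — reduced-unit domain types (`ForceField`, `Configuration`,
  `RingTopology`) and the interaction potentials: WCA excluded volume with
  Lorentz–Berthelot mixing, FENE bonds, harmonic-cosine bending and Coulomb
  electrostatics (Bjerrum-length parametrisation).
- **electrostatics** — smooth Ewald summation (desk-scale substitute for
  mesh methods, relative error ≤ 1e-3) and a screened Debye–Hückel solver.
- **dynamics** — Langevin velocity-Verlet integrator
  (Grønbech-Jensen–Farago discretisation), cubic-lattice ring initialisation
  with a non-concatenation guarantee, the stepwise box-compression protocol
  and full run scheduling.
- **scenes** — synthetic configurations with planted ground truth (ring
  stacks with controlled tilt/jitter, threading scenes with known crossing
  counts, counterion clouds with a planted condensed fraction) so every
  analysis stage is testable without MD.
- **conformation** — gyration tensor, radius of gyration, prolateness
  (range −1/4 … +2), ring directors, joint shape histograms, single-ring
  reference scale R_g,0 and persistence-length fits.
- **clustering** — the three pairwise stacking criteria (director alignment,
  axial and lateral separation thresholds), adjacency graph, connected-
  component stacks, W(N_s) weight fractions and the weight-averaged
  aggregation number.
- **correlations** — centre-of-mass structure factor S(k) on the box's legal
  wavevectors, radial pair correlations g(r), coherent/incoherent
  intermediate scattering functions at the cluster-peak wavenumber,
  1/e relaxation times and counterion-condensation fractions.
- **threading** — area-minimising triangulated disks spanned on each ring
  contour (fixed boundary, relaxed ghost vertices, 0.1%/240-step convergence
  rule), segment–triangle crossing detection, active/passive threading
  records with contour-cut threading depths and their joint statistics.
- **io / pipeline / cli** — extended XYZ, LAMMPS text dump and native HDF5
  trajectory formats, run manifests, and a staged analysis pipeline.

## Tests

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria, including a
scaled-down explicit-ion simulation (M = 8 rings, trivalent counterions,
ρσ³ = 0.2) that reproduces the monomer–ion contact peak of g(r); the full
suite runs in a few minutes on one CPU. One criterion (persistence length
6σ ± 1σ) fails by design: the printed bending constant implies l_per ≈ 29σ
(see the assertion's comment).

## CLI

```sh
ringstack generate --config scene.yaml --out results/ --seed 1
ringstack simulate --config run.yaml --out results/
ringstack shapes   --trajectory results/trajectory.h5 --out results/
ringstack clusters --trajectory results/trajectory.h5 --out results/
ringstack scatter  --trajectory results/trajectory.h5 --out results/
ringstack thread   --trajectory results/trajectory.h5 --out results/
ringstack pipeline --config full.yaml --out results/
```

The YAML config mirrors `ringstack.pipeline.run_pipeline`: `stages`,
`seed`, `protocol` (simulation parameters), `scene` (synthetic-scene
parameters), `criteria` (stack thresholds), `force_field` overrides.
Every run writes a `manifest.json` recording config, seeds and per-stage
provenance; fixed seeds reproduce all outputs bit for bit.

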