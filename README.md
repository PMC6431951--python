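# knotchain

Langevin dynamics and knot localization for a stretched semiflexible
bead-spring chain carrying two trefoil knots — the computational toolkit
behind an idealized optical-tweezers setup in which a tethered polymer
holds two prime knots of chosen handedness, whose sizes, separation
statistics, free-energy profiles and relative orientations are measured.

## What is in the box

| module | contents |
| --- | --- |
| `knotchain.model_core` | chain energy function (WCA + FENE + bending + smooth walls) and its analytic gradient, reduced units |
| `knotchain.langevin_md` | underdamped Langevin integrator (BAOAB splitting, velocity-Verlet core) with tethered termini and bond-overstretch topology guards |
| `knotchain.knot_analysis` | minimally interfering closure of open arcs, Alexander determinants at t = −1 and −2, shortest knotted arc search, prime-component isolation via excision, handedness from the space writhe |
| `knotchain.observables` | knot centers, the separation order parameter \|D\|, loop-normal directors, θ and θ⊥ |
| `knotchain.free_energy` | F(\|D\|) from histograms, the exact two-sliding-segment entropy model and its subtraction, barrier/minimum/onset feature extraction, the elastic knot-size model and its Q calibration |
| `knotchain.synthetic_data` | torus-trefoil templates, two-knot chain fixtures (separated or intertwined) built so their topology is known by construction, sliding-segment microstate sampler, surrogate \|D\| trajectories, capped-step T = 0 minimizer |
| `knotchain.cli_io` | XYZ / LAMMPS-dump trajectory I/O, TSV tables with config-hash headers, YAML configs, end-to-end pipeline driver |

## CLI

```sh
knotchain fixtures      --config config.yaml --out fixtures.xyz
knotchain simulate      --config config.yaml --out traj.xyz --seed 1
knotchain analyze-knots --traj traj.xyz --out knots.tsv
knotchain order-params  --traj traj.xyz --out orderparams.tsv
knotchain free-energy   --orderparams orderparams.tsv --N 300 --lk 36 --out fe
knotchain elastic-model --kappa-b 2.5,5,10,15,20 --Q 0.015
knotchain pipeline      --config config.yaml
```

A config is a flat YAML file holding the model parameters (all in
reduced units: lengths in σ, energies in ε = kBT, times in τMD), the
run protocol, and the knot fixtures; `PipelineConfig.to_yaml()` writes
a template. The production-scale system (N = 300 beads, walls at
L = 205 σ, 2×10⁷ τMD per run, 30 runs) is expressible in config but is
cluster-scale; the desk-scale default used throughout the tests is
N = 100, L = 70 σ.

## Conventions

- Bead indices are 0-based; arcs are inclusive `[s, e]` with size
  `e − s + 1` beads.
- The stretching axis is X; the walls are the planes x = 0 and x = L;
  beads 0 and N−1 are frozen on them.
- Handedness: +1 = right-handed (positive writhe), −1 = left-handed.
- With a fixed seed, simulation and pipeline output are
  bit-reproducible.
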