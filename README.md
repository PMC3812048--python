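# pmfkit

A tested, reusable implementation of a free-energy workflow for
ion-dependent transporter gating, exercised end-to-end on synthetic
multi-basin landscapes with a Brownian-dynamics engine standing in for
all-atom MD:

- **Order parameters** from structure coordinates: center-of-mass gate
  distances (thick gate between the TM1/TM8 Na2-site residue groups, the
  extracellular thin gate), ion/substrate z-displacement relative to a
  binding site, and a minimum-contact contamination diagnostic. PDB input
  via Biopython with altloc/MODEL handling and a small selection
  mini-language.
- **Model landscapes** (`pmfkit.landscape`): analytic gate x ion energy
  surfaces built from Gaussian basins with designer-known free energies,
  exact gradients, direct Boltzmann-quadrature reference PMFs (the ground
  truth for every recovery test), and an overdamped Euler-Maruyama
  propagator with optional harmonic biases and fully deterministic
  per-stream RNG.
- **String method with swarms of trajectories**
  (`pmfkit.string_method`): RMSD-steered path initialization with a
  decreasing flat-bottom ramp, arc-length subsampling into images, the
  4-step swarm iteration (swarms, drift, constrained relaxation,
  equal-spacing reparametrization), convergence metrics (RMSD to
  iteration 0 and to a lag-4 reference, plateau detection), plus a dense
  steepest-descent string as an independent MFEP oracle.
- **Umbrella sampling + WHAM** (`pmfkit.umbrella`): window grids (0.25 A
  spacing on the gate axis, 0.5 A elsewhere; force constant 5
  kcal/mol/A^2), seeding from the nearest string image, biased sampling
  with burn-in discard (60/560 by default), a self-consistent 1D/2D WHAM
  solver (bin size 0.25 A, f-constant tolerance 0.001 kcal/mol),
  3-block error estimates, and strip-integrated 1D profiles.
- **Landscape analysis** (`pmfkit.analysis`): basin/saddle location,
  Boltzmann-weighted state free-energy differences in k_BT, barrier
  heights, state classification, and a deterministic cycle report with
  aligned side-by-side 1D profiles.
- **Synthetic fixtures** (`pmfkit.fixtures`): toy PDB texts, exact draws
  from closed-form biased Gaussian distributions (the WHAM sampling
  oracle), and string histories with known convergence curves.

Energies are kcal/mol (k_B = 0.0019872041 kcal/mol/K, default
T = 298.15 K), lengths are Angstrom.

## CLI

```
pmfkit init-path   --potential cycle --start 5.5 0 --target 10 -5 --out string.txt
pmfkit relax-string --potential cycle --string string.txt --iterations 30 --out relaxed.txt
pmfkit sample      --potential cycle --bounds 4.5 11.5 -6 1 --string relaxed.txt --outdir runs/
pmfkit wham        --windows runs/windows.csv --series-dir runs/ --strip -0.5 0.5 --out pmf.txt
pmfkit gate-distance data/pdb/2JLO.pdb
pmfkit fixtures pdb --out toy.pdb
pmfkit report --config report.yaml --outdir report/
```

Built-in potential designs: `cycle` (three-basin gate x ion surface),
`apo-flat` (released-ion channel with a few-k_BT barrier), `ion-bound`
(adds the designed outward-stabilizing wells and records the designed
outward-vs-inward free-energy gap), `three-well` (string-method
benchmark). Custom designs load from YAML (`pmfkit.landscape.save_potential`
/ `load_potential`).

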