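# permawh

Membrane permeability prediction from adaptive-bias sampling, exercised
end-to-end on synthetic Langevin model systems.

Permeation of a small molecule across a stacked lipid barrier (the kind of
lamellar structure that makes skin nearly impermeable) is governed by the
inhomogeneous solubility–diffusion model: the permeation resistance of one
barrier period is

```
1/K_P = R = ∫ exp(β ΔG_rel.water(z)) / D(z) dz,
```

where ΔG_rel.water(z) is the free-energy profile (PMF) of the permeant along
the membrane normal, calibrated to the water/solvent reference, D(z) is the
local diffusion coefficient, and β = 1/k_BT.  For a stack of N effective
bilayers (N = 30 ± 6 by default, from 12 ± 0.4 lipid regions of 2.5 ± 0.5
bilayers each) the resistance scales as R_total = N·R, and the permeability
coefficient K_P = 1/R_total is reported as log₁₀K_P in cm h⁻¹.

`permawh` implements the full estimation chain on top of toy membranes with
known answers:

* **Model systems** — analytic λ-coupled free-energy landscapes (Gaussian
  barriers/wells on a solvent plateau, optional slow orientation traps
  emulating gel-phase behaviour, Beutler-style soft-core coupling with
  α = 0.5) integrated by a BAOAB velocity-Langevin integrator at 305.15 K,
  plus quadrature oracles for PMFs and solvation free energies.
* **AWH sampler** — an accelerated-weight-histogram adaptive bias on a 1D or
  2D (spatial × alchemical) grid: harmonic umbrella reference points moved
  by exact Gibbs moves every 10 steps, weighted-histogram free-energy
  updates every 10 samples, multiple communicating walkers sharing one bias,
  initial-stage covering checks (full λ traversal plus a 0.8 nm per-walker
  spatial diameter), end-state-weighted λ targets, and optional sampling
  symmetrization.
* **Friction → diffusion** — the position-dependent friction metric from the
  blocked autocovariance of the umbrella pull force, per walker, inverted via
  the Einstein relation D(z) = 1/g(z), with a rolling-median filter and
  cross-walker standard errors.
* **Permeability pipeline** — vacuum→solvent calibration via the λ axis,
  non-negativity offset, edge trimming, the trapezoid resistance integral,
  layer scaling and uncertainty propagation.

## Worked example

`examples/04_permeability_pipeline.py` runs a single 2D AWH simulation on a
compact one-barrier membrane (18 kJ/mol barrier, 8 kJ/mol well, solvent
level −5 kJ/mol), then extracts all three ingredients from that one run and
prints:

```
solvation free energy:    -4.931 kJ/mol
single-period R:        2.632e-05 h/cm
layer count:            30 bilayers
log10 K_P:                 3.103 +- 0.088 cm/h
analytic log10 K_P:        3.034 cm/h (pipeline error 0.069 log units)
```

The solvation free energy comes from the λ dimension of the same run (the
coupled−decoupled free-energy difference on the solvent plateau), the
diffusion profile from the friction metric, and the analytic value from
quadrature plus the known free diffusion coefficient kT/(mγ) — the pipeline
reproduces it to well within a factor of two.

`examples/05_2d_vs_1d_convergence.py` demonstrates why the alchemical
dimension matters on a gel-like toy whose orientation degree of freedom
relaxes far more slowly than the permeant diffuses:

```
median RMSD: 2D 0.319 vs 1D 0.542 kJ/mol
2D wins 17/21 seeds; one-sided sign test p = 0.0036
```

The other examples cover the analytic landscape oracles (`01`), a plain 2D
PMF estimation (`02`) and diffusion recovery on a flat landscape (`03`).

## Command line

A thin CLI wraps the library:

```bash
permawh simulate -c config.yml -o out --seed 7    # 2D AWH run -> pmf.xvg, diffusion.xvg
permawh solvation -o out --seed 1                 # lambda-only solvation leg
permawh pmf in.xvg -o out.xvg --symmetrize --trim-edges 2 --calibrate -4.9 --offset-nonnegative
permawh diffusion out/forces.npz -o d.xvg --blocks 128 --median-window 0.2
permawh permeability --pmf pmf.xvg --diffusion d.xvg --json result.json
permawh demo-convergence -o demo --seeds 5
```

Profiles are plain xvg-style text; run metadata (seeds, covering events,
histogram growth, stage transitions) is JSON; exit codes are 0 (success),
2 (usage), 3 (validation), 4 (numerical failure).

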