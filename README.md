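# gmmreff

Gaussian-mixture refinement of atomic models in cryo-EM density maps.

## The problem

A cryo-EM reconstruction assigns an intensity to every voxel of a 3-D grid;
an atomic model places atoms at coordinates inside that grid.  Fitting the
model to the map — and knowing *how well* each part of it fits — is hard
because real maps have spatially varying resolution: flexible loops, nucleic
acids and ligands are blurred relative to rigid cores.  `gmmreff` treats the
map as a per-atom Gaussian mixture with a uniform background term and uses
that single statistical picture for refinement, uncertainty-driven ensemble
generation, seam-free composite maps, and local quality-of-fit scores.  It is
aimed at structural biologists refining or validating models against maps in
the ~2–5 Å resolution range.

## The model

Atom *i* with position **x**ᵢ, width *B*ᵢ (the "B-factor" in the sigma sense,
Å) and atomic number *Z*ᵢ contributes intensity

    Pᵢ(v) = Zᵢ · exp(−|v − xᵢ|² / Bᵢ²)

at voxel centre **v**; the simulated map is `M_s(v) = Σᵢ Pᵢ(v) + E`, with a
uniform background *E* absorbing intensity no atom explains.  Refinement is
expectation–maximisation: the expectation step simulates `M_s` and computes
per-voxel responsibilities `γᵢ(v) = Pᵢ(v)/M_s(v)` (and `γ_err = E/M_s`); the
maximisation step re-estimates each atom's position and width from the
responsibility-weighted experimental density `Wᵢ(v) = M_e(v)·γᵢ(v)` and the
background from the error-weighted mean.  Atoms are pulled towards their
maximised positions either directly or through a biasing potential

    E_gmm = k_gmm · (1 − exp(−|xᵢ − x′ᵢ|² / 2Bᵢ³)),     k_gmm = 1e5

combined with stereochemical restraints.  Convergence is scored by the
zero-mean cross-correlation (CCC) between the experimental map and a map
simulated with a single global width equal to the map resolution; the loop
stops when the CCC has not improved for 5 iterations (or after 300).

The refined widths feed three downstream products:

* **Ensembles** — members are drawn from isotropic Gaussians whose variance
  is the (shifted) per-atom width, relaxed under an anchoring potential, a
  density-guided force and bond restraints; the voxel-wise mean of their
  simulated maps is the ensemble-average map, and per-residue RMSF summarises
  the spread.
* **Composite maps** — overlapping focused reconstructions are blended by
  per-component responsibilities `γ_c = M_c/Σ_c M_c`, removing seam
  artefacts; shared atoms count only in the component where they are best
  resolved (lowest width).
* **Local scores** — LoQFit (per-residue resolution at which the locally
  masked map-vs-model FSC crosses 0.5; lower is better) and SMOCf (sliding
  window Manders overlap between simulated and experimental density).

## Worked example

```python
import numpy as np
from gmmreff import (MapRefinement, RefinementConfig, ToySpec,
                     make_toy_model, make_ground_truth_map)

spec = ToySpec(n_residues=40, b_range=(0.5, 2.0), noise_level=0.05, seed=11)
model = make_toy_model(spec)                      # 160-atom toy chain
emap, truth = make_ground_truth_map(model, spec)  # map + generating state

start = model.copy()
start.bwidth[:] = np.clip(model.bwidth * 5, 0.25, 2.5)   # widths 5x off
fit = MapRefinement(start, emap, resolution=3.0,
                    config=RefinementConfig(residue_blend=0.0))
results = fit.fit()
print(results.summary())
err = np.abs(results.final_model.bwidth - truth.model.bwidth) / truth.model.bwidth
print(f"median width error: {100 * np.median(err):.1f}%")
```

prints (numbers from this exact script):

```
Gaussian-mixture map refinement results
===============================================
atoms                        160
mode                      direct
resolution (A)              3.00
iterations run                 8
stop reason            converged
CCC initial               0.8046
CCC final (best)          0.8087
background E              0.8938
width B min/med/max    0.326  1.294  2.500
median width error: 7.0%
```

The widths that generated the map are recovered to a few percent even from a
five-fold inflated start, and the background estimate (0.89) sits close to
the generating value (0.93).  `results.sample_ensemble()` then draws a
width-driven ensemble, and `gmmreff.loqfit` / `gmmreff.smocf` score the fit
per residue.

A command-line interface wraps the same pipeline:

```sh
gmmreff synth --n-residues 10 --seed 3 --out-prefix toy
gmmreff refine --map toy.mrc --model toy.pdb --resolution 3.0 --out refined.pdb
gmmreff score --map toy.mrc --model refined.pdb --resolution 3.0 --score loqfit
gmmreff ensemble --map toy.mrc --model refined.pdb --resolution 3.0 --n 20 --seed 1 --out-dir ens/
gmmreff compose --component a.mrc:a.pdb --component b.mrc:b.pdb --out composite.mrc
```

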