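# Methods

## Model and conventions

The map model is an unnormalised per-atom Gaussian mixture plus a uniform
background.  Atom *i* contributes `Pᵢ(v) = Zᵢ·exp(−|v−xᵢ|²/Bᵢ²)`; the
simulated map is `M_s = ΣᵢPᵢ + E`.  Three conventions matter:

* **Width convention.** `B` is the length scale of the exponent *without*
  the conventional factor ½, i.e. the per-axis standard deviation of the
  implied Gaussian is `B/√2` and the expected squared radial deviation is
  `3B²/2`.  All stored widths, caps, floors and the ensemble sampling use
  this convention.  Conversion to the crystallographic displacement
  parameter is `B_cryst = 8π²σ²` with `σ` the stored width, applied only at
  file I/O when requested.
* **Coordinates.** Real-space Å throughout; voxel `(0,0,0)`'s centre sits
  at the map origin and voxel `(i,j,k)` at `origin + (i,j,k)·voxel_size`.
  Axis permutations in MRC files are resolved at read time; internal arrays
  are always `(x, y, z)`-indexed.
* **Truncation.** Each atom's contribution is evaluated only within
  `cutoff_sigma·Bᵢ` (default 4) of its centre and is exactly zero outside.
  The same radius defines the voxel support used for the background update
  and support-restricted scores; the truncation error is bounded by
  `Z·exp(−cutoff²)`.

## The refinement loop

Expectation: simulate `M_s`, form responsibilities `γᵢ = Pᵢ/M_s`,
`γ_err = E/M_s`.  Maximisation:

* **Widths.**  The responsibility-weighted second moment
  `v = Σ W·|r−x|²/ΣW` (`W = M_e·γᵢ`) is measured over the atom's
  *signal-dominant window*: voxels within the radius where `Pᵢ ≥ 4E`
  (clamped between 1.5 voxels and the full support).  Restricting the
  window matters because the uniform background contributes to the moment
  as `r⁴`; summed over the full support of a too-wide atom it creates a
  spurious attractor in which inflated widths never deflate.  The measured
  moment is then inverted through the *discrete truncated* second-moment
  function of the atom's own Gaussian evaluated on exactly the same voxel
  set (60-step bisection on `B ∈ [0.05, 12]`).  Because measurement and
  inversion share the voxel set, discretisation and truncation cancel: a
  map simulated from the model is an exact fixed point of the update at any
  voxel size.  In the untruncated continuum limit the inversion reduces to
  `B = sqrt(2v/3)`.  Results are clamped to `[b_floor, b_cap]`
  (0.25 / 2.5 Å; 1.5 Å cap in membrane-protein mode).
* **Positions.**  The responsibility-weighted mean
  `x′ = Σ W·r / Σ W` is exposed as `maximise_positions` and is the exact
  fixed point on self-consistent data.  As a *complete* position estimator
  it has two defects on realistic grids: with ~1 Å voxels and sub-voxel
  widths the discrete centroid snaps toward lattice points, and where atoms
  overlap each atom claims part of its neighbours' density, biasing the
  equilibrium by ~0.2 Å.  The loop therefore completes the positional
  M-step by backtracking gradient descent on the squared map residual
  `Σ(M_s−M_e)²` (`polish_positions`, default 50 accepted steps, first step
  ≤ 0.25 Å), plus a weak harmonic bond penalty (strength
  `0.01·max(M_e)²` per Å², equilibrium = input bond lengths) that prevents
  tightly overlapping chain neighbours from swapping into permuted local
  minima.  The polished coordinates are the targets handed to the
  relaxation step.
* **Background.**  `E′ = mean over the support of M_e·E/M_s`, floored at
  `1e−6·max(M_e)` because the multiplicative update would otherwise make
  `E = 0` absorbing.  `E` is initialised to the mean map value outside the
  model support (10% of the map mean if the support covers the grid).
* **Width restraint.**  Per-residue blending
  `B ← (1−blend)·B + blend·mean(residue)`, default `blend = 0.5`, exposed
  over `[0, 1]`.  Parameter-recovery experiments on fixtures whose
  generating widths are drawn per atom run with `blend = 0`, since residue
  averaging is a prior about real molecules, not about those fixtures.

Relaxation: `mode="direct"` assigns the targets; `mode="relaxer"` runs a
backtracking gradient descent on the biasing potential
`k_gmm(1−exp(−d²/2B³))` (default `k_gmm = 1e5`) plus harmonic bonds and a
soft-sphere repulsion; external engines plug in as a callable
`(model, targets, config) → model`.

Convergence: each iteration is scored by the zero-mean Pearson CCC between
`M_e` and a map simulated with a single global width equal to the stated
map resolution, over that scoring model's support.  "No improvement" means
`ΔCCC ≤ 1e−6`; the loop stops after `patience = 5` consecutive
non-improvements or `max_iterations = 300`, and returns the best-CCC model.
The width-only warm-up phase (default 25 iterations) precedes positional
refinement; it also updates `E`.  Because the convergence CCC uses a global
width, it is constant while positions are fixed — the per-iteration history
therefore also records a per-atom-width CCC as the informative diagnostic
of the warm-up phase.  The warm-up exists to fix badly scaled widths before
atoms move; in experiments that perturb only positions it is turned off.

## Ensembles

Widths are shifted rigidly so their minimum is 0.25 Å; each member samples
every atom from an isotropic Gaussian with per-coordinate variance equal to
the shifted width (Å²), then minimises (L-BFGS, ≤ 2000 evaluations) the
anchoring potential `k_ens/√((2π)³B³)·(1−exp(−d²/B³))` (`k_ens = 1000`),
the density energy `−k_dens·M_e(x)` (trilinear, analytic gradient;
`k_dens = 50` by default, map-dependent over ~5–200) and bond restraints.
Ensemble size grows until the support-restricted CCC of the ensemble-average
map gains ≤ `1e−4`; a member that lowers the CCC is rejected, making the
accepted CCC sequence non-decreasing.  RMSF is computed per residue anchor
atom (Cα, C1′ for nucleotides) about the ensemble mean structure.

## Composite maps

Component maps must be pre-aligned.  Correspondence between component
models uses exact `(chain, residue, atom name)` keys; a shared atom keeps
its `Z` only in the component where its width is smallest (ties: earliest
component, deterministic).  Component weights are
`γ_c = M_c/Σ_c M_c` (zero where the denominator vanishes; those voxels are
excluded), and the composite is `Σ_c γ_c·M_{e,c}` with experimental maps
resampled to the consensus grid by trilinear interpolation.

## Local scores

*LoQFit*: soft spherical mask (raised-cosine edge over 3 voxels) of
diameter five times the global resolution, centred on each residue's
anchor atom, applied to `M_e` and to the model-simulated map (per-atom
widths); the score is the resolution at which the masked FSC first crosses
0.5 scanning low→high frequency, linearly interpolated between shells.
Residues whose FSC never drops below 0.5 are censored at the Nyquist
resolution `2·max(voxel)`, the best attainable value, and flagged.
*SMOCf*: Manders overlap `Σab/√(Σa²Σb²)` between simulated and
experimental density over the voxels within `4B` of a sliding window of
9 residues (odd, configurable; truncated at termini).  FSC shells are one
reciprocal voxel wide; non-cubic grids are zero-padded to a cube.

## Synthetic fixtures

The generators produce self-avoiding random-walk chains (bond length
1.5 Å; non-bonded contacts rejected below 2.0 Å, a conservative van der
Waals floor), widths drawn uniformly per atom, and maps simulated from the
generating state plus a uniform background equal to `noise_level` times
the peak intensity (optionally with seeded voxel noise).  Two-conformer
maps average the chain with a copy whose middle third is displaced;
component sets split the chain into overlapping windows with widths
sharpest at window centres.  Two-zone fixtures for the local scores use a
directionally biased (extended) chain so that the zones are spatially
disjoint — zone medians only measure locality when the local masks do not
straddle both zones.  Everything is bit-deterministic per seed and
returns its ground truth for recovery assertions.

What these fixtures do *not* emulate: secondary structure, side-chain
chemistry, solvent, detector/CTF effects, resolution anisotropy, or masks
applied during reconstruction.  Passing recovery tests therefore
demonstrates the estimator's correctness and conditioning, not end-to-end
performance on deposited maps.

## Problem sizes

Tests and the acceptance script use 40-residue chains (160 atoms) on
~40³–50³ grids at 1 Å voxels for recovery experiments, 20-residue chains
for ensemble experiments (20 members), 50 members for RMSF statistics and
16-residue two-zone fixtures for LoQFit.  These sizes put all estimators
well inside their asymptotic regime while keeping a full run in minutes on
one CPU core.

## Known limitations

* The width update assumes the background estimate is roughly right when
  it sizes the signal-dominant window; with `E` overestimated several-fold
  the window shrinks to its floor and width recovery degrades.
* The positional residual descent finds the nearest local minimum; initial
  displacements well beyond ~1 Å (or whole-domain motions) need the
  relaxer mode with stereochemical restraints, or rigid-body pre-fitting,
  which is out of scope here.
* Ensemble members are relaxed independently; no attempt is made to weight
  or cluster them.
* Composite-map correspondence requires consistent residue numbering
  across component models.
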