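# Methods note

This note records the model equations, the assumptions behind them, the
default parameters, what the synthetic generators can and cannot represent,
and the numerical choices made in the implementation.

## 1. Scaffold geometry

The scaffold is an array of truncated-cone spikes on concentric rings.
Defaults: spike height 5.0 mm, base diameter 0.5 mm, apex diameter 0.1 mm,
inter-spike gap 0.35 mm, maximum embedding depth of interest ≤ 3 mm.
Ring k sits at radius k·p, where the radial pitch p = base diameter + gap
= 0.85 mm; the number of spikes on a ring is the largest m whose arc
spacing 2πR/m is at least p, so bases never overlap (property-tested).
The cross-section radius at embedding depth d interpolates linearly from
apex to base; it is used both for the FE footprint and as the contact
radius in the force bookkeeping.

## 2. Densitometry chain

* Segmentation: global threshold (Otsu by default, via scikit-image) on the
  grey volume; pores are the complement, labelled with 26-connectivity.
* Noise removal: single-voxel pore components are re-assigned to bone
  (idempotent by construction).
* Pore classification: components with more than `lacuna_max_voxels`
  (default 150) voxels are canals, smaller ones lacunae. With the default
  17.5 µm voxels this cut sits between typical lacuna (~10² voxels) and
  canal (~10³–10⁴ voxels) scales.
* Marrow and soft-tissue fraction φ of a region of interest discards the
  first and last axial slice of the region (partial-volume guard) and needs
  at least three slices. Optionally, classified micro-porosity (canals,
  lacunae) is counted as bone tissue.
* Mixture rule: ρ_b = (1 − φ)·ρ_T + φ·ρ_w, ρ_T = 1.90 g/cm³,
  ρ_w = 1.00 g/cm³.
* Power law: E₂ = 315·ρ_b³ MPa (valid for ρ_b > 0, quoted for trabecular
  bone only).

**Rounding convention.** Reported densities are rounded to 2 decimals;
reported integer moduli are computed after quoting ρ_b to 3 decimals — the
precision a three-significant-figure φ supports. With φ = 0.582 and
φ = 0.491 this yields ρ_b = 1.38 and 1.46 g/cm³ and E₂ = 821 and 976 MPa.
(The unrounded chain at φ = 0.491 gives 976.5 MPa, which would round to
977; quoting ρ_b first avoids implying a fourth significant figure.)

## 3. Synthetic phantom

The trabecular phantom is a thresholded Gaussian random field: white noise
smoothed with a Gaussian kernel of σ = correlation length / (2·voxel size)
(default 200 µm at 17.5 µm voxels) and cut at the quantile that hits the
target marrow fraction (default φ* = 0.582, realised within ±0.01).
Cylindrical canals, spherical lacunae and isolated single-voxel speckles
are then carved, and two-level grey values with optional Gaussian noise
assigned. Peri-apical densification flips the soft voxels nearest to
existing bone (by Euclidean distance transform) inside a cylindrical zone
under each spike apex until the zone's φ drops by the requested amount;
requests exceeding the available soft volume raise an error.

Limitations: the phantom reproduces only first-order morphometrics
(volume fraction, correlation length, simple pore taxonomy). It has no
plate/rod architecture, anisotropy of the trabecular fabric, cortical
shell, or grey-value beam-hardening artefacts, and densification is a
volume-fraction operation, not a mechanical compaction.

## 4. Embedding-curve generator

Replicate force–displacement curves have three regions: a concave quadratic
settling region joining C¹ into a linear region F = a·x + b (defaults
a = 376.49 N/mm, b = 209.46 N) followed by a sawtooth region of stepwise
collapses. Gaussian noise (default SD 20 N) is added per replicate from a
single seeded generator. The generator encodes shape, not physics: the
region spans, the sawtooth amplitude and the noise level are descriptive
parameters.

## 5. Finite element model

* Continuum: small-strain linear elasticity; the bone is transversely
  isotropic with the symmetry axis along the spike/loading axis z
  (E₁ = 608, E₂ = 771, G₁ = 260, G₂ = 269 MPa, ν₁ = 0.17, ν₂ = 0.15,
  σ_c = 25 MPa). The compliance matrix is inverted after a
  positive-definiteness (Cholesky) check.
* Discretisation: 8-node hexahedra, 2×2×2 Gauss quadrature, uniform
  structured grid; the quarter-cylinder domain is stair-stepped (elements
  kept when their centre lies inside the radius). One element stiffness per
  material is computed and scattered with vectorised COO assembly.
* Contact simplification: the scaffold is treated as rigid and the
  frictional contact problem is replaced by a prescribed axial displacement
  of the footprint nodes — the apex-plane nodes within each spike's
  cross-section radius at the current depth. Symmetry planes carry
  zero-normal-displacement conditions; the far base is fixed.
* Solver: sparse Cholesky-backed direct solve (`scipy.sparse.linalg.spsolve`)
  up to 60 000 free DOFs, above that Jacobi-preconditioned conjugate
  gradients with relative tolerance 1e-10. Global equilibrium is asserted
  in the tests on every solve.
* Stress recovery: element stress from the mean B-matrix, nodal HMH stress
  by averaging over incident elements.
* Embedding force: the linear solution is scaled so the mean over
  footprints of the peak nodal HMH stress equals σ_c; the force is the
  scaled footprint reaction times 4 (quarter symmetry). This limit-stress
  criterion replaces an incremental elasto-plastic push-in analysis.
* Densified insert: the element layer of chosen thickness beneath the apex
  plane is re-assigned a material scaled so its longitudinal modulus equals
  the measured peri-apical E₂ (all constants scaled proportionally,
  Poisson ratios kept).
* Mesh convergence: a refinement sweep reports the footprint reaction and
  peak peri-apical HMH per element size; successive relative changes below
  5 % mark convergence, and failure to converge is reported, never
  silently accepted.

Default problem sizes (quarter domain radius 1.6 mm, height 4.05 mm,
element 0.075 mm → ≈19 000 elements) are this package's own choices to
keep a full validation loop under a minute on one CPU; they are *not*
converged production meshes. The footprint of a sharp apex is resolved by
only a handful of nodes at these sizes, so absolute forces carry a
discretisation error of several percent; the tests that assert force
monotonicity use wider, well-resolved spikes.

## 6. Validation loop

Stages: (i) generate replicates, average on the shared grid, detect
region II (rolling-slope stability followed by residual-based boundary
refinement) and fit the line; (ii) FE sweep over embedding levels, compare
against the empirical line via FVU = RSS/TSS; (iii) generate a phantom,
apply the measured densification per level, run the densitometry chain to
get peri-apical E₂ per level (constant extension beyond the measured
levels); (iv) re-run the sweep with the densified insert and recompute the
FVU. Everything is seeded and deterministic; the config digest is recorded
in the report.

The synthetic loop validates the *direction* of the re-simulation effect
(FVU decreases, force at fixed displacement increases with a stiffer
insert), not absolute force magnitudes: the default model carries a 7-spike
quarter array while the empirical curves describe a full prototype array,
so both FVU values are large and their difference is small but strictly
negative under the default seeds.

## 7. Numerical and software choices

* NumPy/SciPy for numerics, scikit-image for Otsu thresholding,
  scipy.ndimage for labelling/distance transforms, pandas for tabular
  reports, tifffile/nibabel for volume I/O, click for the CLI.
* VTK export is a small hand-written legacy-ASCII unstructured-grid writer
  (only cell type 12 with point data is needed; no suitable mesh-I/O
  library was available in the target environment).
* All stochastic steps consume a single `numpy.random.default_rng(seed)`;
  no global random state is touched.
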