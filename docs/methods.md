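# Methods

`rhizopore` quantifies the pore structure of the rhizosphere — the soil
within ~1 mm of a root — from phase-labelled 3D images, and estimates the
transport consequences of that structure by solving cell problems directly
on the voxel grid.  Because segmented synchrotron-CT volumes of this kind
are rarely published, the package ships a synthetic microcosm generator
whose ground truth is known exactly; every downstream metric is validated
against it and against independent brute-force oracles.

## Phase model

A volume is a grid of isotropic voxels (μm) labelled pore (0), mixed (1),
solid (2), root (3) or hair (4).  "Pore" is the air-filled pore space
resolvable at the imaging resolution (> 5 μm); "mixed" bundles
sub-resolution water-filled pores with silt and clay particles; "solid"
is the sand-grain skeleton.  Under saturation the fluid phase is
pore ∪ mixed.

## Synthetic microcosm generator

Default conditions emulate a barley microcosm: a 2 × 2 × 1 mm region of
interest, 5–8 μm voxels, a centred cylindrical root of 0.47 mm diameter
running the full height, bulk pore fraction 0.22, mixed fraction 0.48
(saturated fluid fraction 0.70), and ~24 hairs per mm of root length
with 8 μm hair diameter.

* **Solid phase.**  Random sequential addition of non-overlapping
  digitised balls drawn uniformly in diameter from 40–160 μm (sieved
  sandy loam scale), clipped at the domain boundary, never overlapping
  the root.  Packing beyond ~0.38 solid fraction is unreachable by
  sequential addition and raises an explicit infeasibility error.
* **Pore/mixed split.**  The remaining space is split by thresholding a
  spatial key field at the per-annulus quantile that realises the target
  pore fraction, so prescribed fractions are hit up to rounding.  The
  default key is Gaussian-correlated noise ("pockets", correlation
  length 15 μm), which produces pore bodies of realistic tens-of-μm
  local thickness.  A voxel-wise uniform split and a grain-coating mode
  are provided; the uniform mode yields single-voxel speckle with no
  resolvable pore bodies, which degenerates the pore-size and drying
  analyses — that is why pockets is the default.
* **Compaction gradient.**  With a compaction model attached, the
  per-annulus pore target follows the predicted porosity-recovery curve
  (below) instead of the bulk value.  A standalone operation can also
  impose a gradient on an existing volume by converting pore voxels to
  mixed with distance-dependent probability.
* **Hairs.**  Straight thin cylinders anchored on the root surface at
  quasi-uniform (golden-angle) axial/azimuthal positions, lying in the
  plane spanned by the outward radial normal and the root axis.  The
  obliquity cosine μ is uniform on [0.5, 1] and the axial tilt points at
  the farther axial boundary, which minimises clipping by the region of
  interest.  When a decay length r₀ is configured, the hair's *radial
  reach* is Exp(r₀)-distributed, so the expected skeleton length per
  annulus decays with exactly r₀ — the property the recovery tests
  measure.  Otherwise hair arc lengths are Normal(mean, sd).  An
  optional visibility flag labels hairs only where they cross pore
  space, mimicking their invisibility inside the fine-textured phase.

All randomness flows from a single seeded generator in documented order
(hair sub-seed, grains, key field); identical configurations are
bit-identical.

## Annuli and profiles

Distance from the root surface is the Euclidean distance transform of
the root-mask complement (distance to the nearest root voxel), scaled by
the voxel size.  Annuli are half-open 50 μm bins, `floor(d / 50)`.
Phase fractions are phase volume over annulus volume; empty annuli are
reported as missing, never zero.  Because distances are measured to
voxel centres, the innermost annulus is biased slightly low for
hair-length profiles; the decay-length estimator therefore excludes it
by default.

## Local thickness and pore-size distributions

Each pore voxel carries the diameter of the largest ball fully contained
in the pore phase (and in the image domain) that covers it.  The map is
computed as an opening transform: for each candidate radius r, the pore
mask is eroded (distance transform > r) and re-dilated (distance to the
eroded set ≤ r); a voxel's value is twice the largest r that still
covers it.  When the distance transform takes at most 200 distinct
values the transform is evaluated at every one of them and the result is
exact; otherwise radii are quantised at 0.25 voxel (diameter error
≤ 0.5 voxel).  An exhaustive sphere-fitting search is kept in the test
suite as the oracle.

PSDs are voxel-volume-weighted histograms of the map restricted to pores
wider than 5 μm, binned at one voxel-diameter, reported cumulatively at
bin right edges, absolute or normalised to the group's total pore
volume.  Two-sample comparisons use the Kolmogorov–Smirnov statistic on
the per-voxel diameters.  Voxels within one pore body share their
diameter, so per-voxel samples are correlated and the nominal p-value is
anti-conservative at full sample sizes; `compare_psd(max_samples=...)`
subsamples to decorrelate when a calibrated p-value matters.

## Connectivity and percolation

Pore clusters are labelled under 18-connectivity (faces and edges).  The
connectivity index is Γp = Σ vᵢ² / N_p², evaluated on the retained set.
Simulated drying thresholds the local-thickness map downward from the
maximum diameter in 10 μm steps; voxels wider than the threshold are
removed (large pore bodies drain first) and Γp is recomputed on each
retained subset, so the curve tracks the breakdown of connectivity.  An
alternative normalisation by the *full* pore volume is conceivable; the
retained-set convention is used because the index is defined on the
phase under consideration.  The percolation threshold d₀ is the midpoint
of a least-squares logistic fit Γp,max / (1 + e^{−a(d−d₀)}) with Γp,max
fixed to the measured full-pore-space value (it is defined as the
connectivity of the entire pore space, not a free parameter).
Initialisation: d₀ at the diameter whose Γp is nearest Γp,max/2 and
a = 4/range(d), with a > 0 enforced.  Curves that never drop below
99 % of Γp,max are flagged degenerate rather than fitted.

## Transport cell problems

Subvolume sampling: cubes (default 500 μm, n = 20) placed by rejection
sampling outside the root; two intersecting cubes may overlap at most
250 μm on every axis (disjoint cubes are unconstrained).  Each cube
carries a nested ladder of test volumes with sides L(i) = (L0³/2^i)^{1/3},
i = 0..6, rounded to even voxel counts about a common centre.

**Effective diffusion.**  Cell-centred finite-volume Laplace problem on
the fluid mask: concentration 1 and 0 on the two axis-normal faces
(half-cell Dirichlet coupling), no-flux lateral walls and solid
interfaces.  D_eff = flux · L² / (ΔC · V_fluid) — normalised per unit of
fluid content, so a fully fluid cube returns exactly 1 and the value
measures tortuous impedance, not porosity.  This convention is the one
consistent with saturated D_eff exceeding the fluid volume fraction; a
whole-domain normalisation would cap it at the fluid fraction.

**Permeability.**  Steady Stokes flow on a staggered (MAC) grid, unit
pressure difference between ghost cells half a voxel outside the two
axis-normal faces, no-slip at fluid–solid interfaces, closed no-slip
side walls by default (free-slip symmetry walls are available and are
how an infinite slit is realised in a finite domain).  A constant
gravity body force only shifts the pressure datum in this cell problem
and is absorbed into the applied gradient.  k follows from Darcy's law
with the superficial (whole-domain-averaged) velocity and the
(N+1)-cell pressure span, and scales to cm² with the voxel area.

Fluid cells not face-connected to either driven face are removed before
assembly; if no cluster spans the axis the property is 0 with a
non-percolation flag.  The velocity block is symmetric positive definite
under no-slip walls, so large systems are solved by conjugate gradients
on the pressure Schur complement with the velocity block factored once;
small systems and free-slip walls use a monolithic sparse direct solve.
Both solvers verify against closed forms: Hagen–Poiseuille tube and
plane-Poiseuille slit within 10 % at 20 voxels across the aperture
(actual errors ≈ 0.6 % and 0.5 %), free water D_eff = 1 to 1e-6, and the
tube error decreases under mesh refinement.

**REV extrapolation.**  Each (subvolume, axis, quantity) series is
fitted with a + b·e^{−cL} (L in mm); the infinite-domain property is a.
Fits are accepted only when c > 0.5 mm⁻¹ and RMSE < 0.05 (diffusion) or
< 0.5 (permeability, tabulated in 10⁻⁶ cm² so the threshold lives on the
reported scale); constant series are flagged degenerate.  Multi-start
initialisation over several decay-rate guesses guards against the
optimiser stalling in a flat region.

## Compaction model

Porosity recovery with distance x from the root surface follows the
exponential deformation model φ(x) = φ_s + (φ_b − φ_s)(1 − e^{−x/(k_D r)})
with root radius r and soil mechanical parameter k_D (dimensionless;
smaller k_D = faster recovery).  The surface porosity φ_s is fixed by
rule: the default is φ_s = 0 (full compaction at the wall), which is
well-defined for every parameter set.  A conservation rule is also
provided — φ_b − φ_s = 1/(2 k_D (1+k_D)), obtained by equating the
integrated porosity deficit around the root to the root cross-section —
but for realistic k_D ≤ 0.7 and bulk porosities ≤ 0.3 it implies a
negative surface porosity and is rejected with an explicit error; it is
usable for k_D ≳ 1.  A quadrature check of the displaced-volume balance
is part of the test suite.

## Statistics layer

Group comparisons pre-check normality per group (Shapiro–Wilk at the
same α), then run one-way ANOVA if every group is consistent with
normality and Kruskal–Wallis otherwise.  Pairwise post hoc tests are
Dunn's rank z-tests with the standard tie correction and Bonferroni
adjustment.  Pearson correlation is exposed for profile-level
associations (e.g. Γp or D_eff against pore fraction).  Under a
simulated null (3 × 5 Gaussian groups, 1000 replicates) the observed
type-I error stays at the nominal α.

## Problem sizes

Tests and the acceptance script run desk-scale configurations chosen to
exercise every code path at full fidelity: recovery studies use
2 × 2 × 0.5–1 mm volumes at 8 μm voxels (≈ 4–8 M voxels, 10 seeds),
transport campaigns use 6 subvolumes of ~190 μm with the full 7-step
ladder and 3 axes, and solver benchmarks use 20 voxels across the
aperture.  All sizes are set in one place in the tests and scripts and
scale up unchanged.

## Limitations

The generator reproduces controlled first-order features — phase
fractions with a radial gradient, grain-scale pore geometry, exponential
hair-density decay — not the full morphology of imaged soil: no
aggregate hierarchy, no anisotropy, no partial-volume or phase-contrast
artefacts, straight hairs that never branch or entangle.  Passing
recovery tests therefore demonstrates the correctness of the estimators
under known truth, not their robustness to segmentation error in real
images.  Skeleton-based hair counting cannot separate entangled hairs;
the length estimator corrects digital staircase over-counting on simple
paths but keeps raw step sums on branched components.  Transport is
computed for saturated conditions only; unsaturated behaviour is out of
scope.
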