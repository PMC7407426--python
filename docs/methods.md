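# Methods

`lungstrain` quantifies regional lung deformation from paired
end-expiration (EE) / end-inspiration (EI) CT at two study times, in two
experimental arms: spontaneous breathing after lavage injury (SB) and low
tidal-volume mechanical ventilation (MV).  This note records the models,
the numerical choices, and what the synthetic validation cohort does and
does not demonstrate.

## Aeration compartments and global metrics

Lung voxels are classified by Hounsfield value into four aeration
compartments with half-open, lower-closed intervals:
hyper-aerated [-1000, -900), normally aerated [-900, -500), poorly
aerated [-500, -100), non-aerated [-100, +100].  These are the standard
quantitative-CT ranges; the exact cut-points vary across the literature
and are configurable (`AerationThresholds`).  Voxels outside
[-1000, +100] are clamped to the nearest compartment and counted in a QC
field.  The aerated-lung mask is the union of the poor/normal/hyper
compartments; collapsed (non-aerated) tissue is excluded from all strain
computations because mask-driven registration carries no information
there.

Global metrics follow CT volumetry: EELV and EILV are aerated-mask
volumes (voxel count x voxel volume) normalised per kg body mass,
Vt = EILV − EELV, global strain = Vt/EELV, Vmin = RR x Vt.

A morphological QC step (binary opening + largest connected component)
removes speckle produced by HU noise at compartment boundaries before
registration and meshing.  It replaces the manual expert review used for
in-vivo segmentations; the removed voxel count is reported per subject.

## Mask registration

The displacement field lives on the EI grid and points backward,
x_EE = x_EI + u(x_EI), because the mesh is built at EI and needs its
expiratory reference coordinates.  Which phase is fixed versus moving is
a convention choice; it is recorded in the field metadata.

Binary masks have no interior contrast, so the built-in backend matches
*clamped signed-distance transforms*: the SDT is clipped to a +/-2-voxel
band, turning the similarity term into a surface-alignment force.  The
deformation model is a free-form deformation on a coarse control lattice
(first-order/trilinear B-spline basis, default spacing 6 working voxels)
fitted with L-BFGS-B on

    E = mean_band (SDT_EI(x) − SDT_EE(x + u))^2 + lambda * bending(u),

lambda = 1e-3 by default, with a moment-matching diagonal-affine
initialisation for capture range.  Two design facts matter:

* An *unclamped* SDT is a biased similarity for inflation: matching
  interior iso-distance shells favours a constant-offset map (zero radial
  stretch) and can fold at the centre.  The narrow band avoids this.
* Linear fields have zero bending energy and are exactly representable
  by the lattice, so uniform inflations are recovered without
  regularisation bias; the interior of the lung, where the masks carry no
  data, is filled in by bending-energy minimisation (the smooth
  interpolant of the boundary motion), which is exact for affine ground
  truth and attenuates, but preserves, smooth gradients such as a
  dorsoventral stretch ramp.

Registration runs at a capped working resolution (largest axis <= 64
voxels by default; the masks are block-averaged down) and the smooth
lattice is evaluated back on the full grid.  Cost is dominated by band
voxels, so runtime is roughly surface-area bound (~10 s for a 96^3
subject on one CPU).  The optimizer history is retained; accepted
iterates are non-increasing in energy.  The induced map's Jacobian is
checked to be positive on the fixed mask (hard failure otherwise).  The
backend is pluggable: dense fields computed by external registration
packages can be imported in the same layout.

## Mesh and volumetric strain

Every aerated EI voxel is split into 6 tetrahedra (Kuhn/Freudenthal
decomposition along a globally consistent main diagonal), giving a
conforming mesh that partitions the mask volume exactly; corner nodes are
shared.  Nodes are pushed to EE through the displacement field (trilinear
sampling; exact for affine fields).  Per tetrahedron,

    J = det F = V_EI / V_EE,   strain = J − 1,

i.e. inflation is positive.  J is computed as the volume ratio and
cross-checked against the determinant of the edge-matrix deformation
gradient; both agree to machine precision, and strain is invariant under
rigid motions applied to both configurations.  No smoothing is applied to
per-tet strains.

## ROI grid, SPI, SHI

Ten apical-basal and ten dorsal-ventral slabs of approximately equal
tetrahedral volume are intersected into a 10 x 10 grid.  Slab boundaries
come from the volume-weighted cumulative distribution of tet centroids;
equal volume holds up to the granularity of tied centroid coordinates
(Kuhn centroids take three distinct values per voxel per axis).  Tets are
binned by centroid with half-open slabs, ties to the lower slab.  Cells
with no tets are void and carry NaN, not zero.  Cell statistics are
volume-weighted: mean = sum(w e)/sum(w) and the frequency-weighted
population SD, with w the EI tet volume.

Progression and heterogeneity indices per cell:

    SPI = (1 + mean_T3) / (1 + mean_T1)
    SHI = (1 + SD) / (1 + mean)

SPI compares positionally corresponding cells (each time uses its own
equal-volume grid; cell (i, j) at T1 maps to cell (i, j) at T3).  SHI is
described in the field as a coefficient of variation on the
relative-volume scale; note the numerator is 1 + SD, not SD, so
SHI = 1 whenever SD equals the mean — the formula is implemented exactly
as defined.  Reported percentages of significant ROIs use
round-half-up to one decimal (38/87 -> 43.7 %).

## Statistical tests

* **Paired strain change (T1 vs T3)** and **SPI vs 1.0**: exact Wilcoxon
  signed-rank.  The exact null distribution is obtained by dynamic
  programming over doubled mid-ranks, equivalent to enumerating all 2^n
  sign assignments, valid with ties; zero differences are dropped.  For
  n > 25 a tie-corrected normal approximation takes over.  The test of
  SPI against 1.0 defaults to the one-sample signed-rank on SPI − 1: a
  two-sample test against the constant 1.0 is degenerate (zero-variance
  reference group); a Mann-Whitney mode against a constant-1 sample is
  provided for fidelity to the published wording.
* **Sidedness**: defaults to one-sided ("greater") for progression
  hypotheses.  With n = 5 pairs the exact two-sided floor is
  2/32 = 0.0625 > 0.05, so per-ROI calls at alpha = 0.05 are reachable
  only one-sided.  Both modes are exposed and the choice is logged.
* **SHI change**: the Feltz-Miller asymptotic chi-square test of equal
  coefficients of variation, applied to the pooled per-tet (1 + strain)
  samples of a cell across a group's subjects at T1 vs T3.  Statistic
  D = sum m_j (c_j − cbar)^2 / (cbar^2 (0.5 + cbar^2)) with
  m_j = n_j − 1, referred to chi-square(k−1).  Pooled samples are
  subsampled to 2000 tets per cell/subject/time (seeded) — the test is
  asymptotic and insensitive to this cap, which bounds memory and
  runtime.  Monte-Carlo checks: type-I error at alpha = 0.05 lies in
  [0.035, 0.065] for k = 2, n = 50 lognormal samples; power > 0.9 for a
  2:1 CV ratio at n = 100.  Two honest caveats.  First, the asymptotic
  test is mildly anti-conservative for skewed data: the measured type-I
  rate at n = 50 grows from ~0.053 (lognormal sigma 0.1) to ~0.063
  (sigma 0.3), so individual calibration runs near the upper band edge.
  Second, pooling tets across subjects treats within-subject-correlated
  registration error as independent replication; with thousands of
  pooled tets the test detects trivially small CV differences, so the
  SHI family is anti-conservative under a no-change null (null cohorts
  show seed-dependent flag rates well above alpha).  The meaningful
  readout is the contrast between groups — the amplifying group flags
  essentially everywhere, the stationary group substantially less — not
  the absolute null rate.
* No multiple-testing correction across cells by default (per-ROI calls
  at p < 0.05 as in the field's reporting convention); a
  Benjamini-Hochberg option exists.

A cell is testable only if occupied for all subjects at both times and
at least two subjects are available; untestable cells are excluded from
the reported percentages.

## Synthetic cohort: what it emulates

Phantoms are oblique superellipsoid "lungs" (DV centre drifting along the
AB axis, so corner ROI cells are genuinely void) at 100 um isotropic
voxels, with four-compartment HU texture (means −50/−300/−700/−950 HU,
Gaussian noise sd 30 HU, soft-tissue background) and a separable monotone
stretch EE -> EI whose Jacobian is a closed form (the deformation
gradient is triangular, so J is the product of the axis factors).  The
backward displacement and J are exposed as oracles; finite differences of
the displacement reproduce J to < 1e-3 relative error.

Group presets: SB stretches 1.07 -> 1.10 per axis between T1 and T3
(whole-lung strain ~23 % -> ~33 %) with a dorsally weighted stretch
gradient amplifying 0.05 -> 0.15, and ventral-anchored de-recruitment
growing 13.3 % -> 37.5 % of lung volume (between-subject SD 1.6 / 3.1
percentage points); MV uses identical presets at both times
(stretch 1.06, ~19 % strain, non-aerated 10 %), so T1/T3 differences are
pure noise.  Body mass and respiratory rate are drawn per subject
(SB 271 +/- 16 g, RR 117/129; MV 303 +/- 34 g, RR 90).  Per-subject
random effects (stretch multiplier, collapse-fraction shift, collapse
score field) are shared between the subject's two time points, making
within-subject progression monotone; all randomness flows from one
master seed through named substreams, and regeneration is bit-identical.

Not emulated: airway trees, cardiac motion, gating artifacts, scanner
noise beyond additive Gaussian, non-deforming collapsed tissue (the
analytic warp stretches the whole domain; strain ground truth is simply
not defined on non-aerated labels), and anatomically corresponding ROIs
across subjects (the grids are positional, as in the published analysis).
Passing tests therefore demonstrate correctness of the computational
chain under known smooth deformations — not registration accuracy on
real parenchymal texture.

## Problem sizes and tolerances

Default validation sizes were chosen to exercise every stage at
meaningful resolution while staying desk-scale: 96^3 phantoms
(~10^6 voxels, ~1.5 M tets per subject) for the cohort study, 128^3 for
the uniform-stretch recovery benchmark, working registration resolution
64.  Strain recovery tolerance is 5 % relative with the built-in
registration and 1e-6 with the analytic field injected (trilinear
sampling is exact on affine fields, so the only error is floating-point).
Mesh/mask volume agreement is exact by construction (asserted at 1e-12
relative); conservation of the warped mesh volume against the EE aerated
mask is reported as a QC ratio rather than asserted, since it inherits
registration error.
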