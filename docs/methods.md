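# Methods

This note documents the models, estimators and numerical choices behind
`bonespm`, what its synthetic data do and do not emulate, and the known
limitations of each stage.

## Synthetic phantoms and cohorts

A phantom is a tubular bone on an isotropic grid (default 82 µm voxels,
axis 2 axial, slice 0 distal): a dense cortical shell between a per-slice
outer-radius profile and an inner (endosteal) radius, an interior periodic
trabecular lattice, marrow at ~30 mg HA/cm³ and bone matrix near cortical
density (~886 mg HA/cm³). The image chain is `values → Gaussian blur →
additive Gaussian noise`; the blur (default σ 0.06 mm) models the point
spread / partial-volume effect and makes soft cortical membership
non-trivial, the noise (default SD 25 mg/cm³) is a simple stand-in for
quantum and reconstruction noise. No projection physics, beam hardening or
motion artifacts are simulated; motion is represented only as a per-subject
1–5 quality grade used for exclusion bookkeeping.

The default lattice is a single family of parallel plates. With one family,
BV/TV = thickness/period and Tb.N = 1/period hold exactly by construction,
which is what makes the metric estimators testable; at 82 µm a
plates+rods topology with realistic BV/TV would need struts thinner than
one voxel. Two orthogonal plate families plus axial rods remain available
(`lattice_kind="plates+rods"`). The in-plane lattice phase drifts by one
full period across the stack (`lattice_drift`): real trabeculae are not
axially invariant, and an axially invariant lattice makes any
finite-aperture BV/TV estimate hostage to the arbitrary phase of ~4
periods inside a small cross-section (phase-sampling SD ~0.03 in BV/TV at
the default geometry; with the drift it is ~0.003).

Cohorts draw per-subject parameters from group distributions. Control-group
means follow published clinical values (BV/TV 0.23, Ct.Th 1.01 mm, Tb.N
1.67 /mm, matrix/cortical BMD 886 mg/cm³; covariates age 65.3 ± 9.3 y,
height 161.2 ± 5.6 cm, weight 73.6 ± 13.8 kg, drawn independently of
group). Fracture-group means are the control means times the published
fracture/control ratios (BV/TV ×0.826, Ct.Th ×0.941, Tb.N ×0.880, BMD
×0.969). Between-subject relative SDs default to 0.10 (BV/TV), 0.04
(Ct.Th), 0.05 (matrix BMD and Tb.N). These dispersions are deliberately
narrower than a clinical population's: they are chosen by power analysis
(standardized effects d ≈ 1.4–1.7) so that desk-scale cohorts of 25 per
group retain the discriminative power the clinical study achieved with
~90 per group. Consequences for interpretation: passing group-difference
tests on these cohorts demonstrates that the measurement chain preserves
planted effects through segmentation and metric extraction — it does not
demonstrate clinical effect sizes are detectable at n=25.

Phantom geometry is scaled down (outer radius ~2.2 mm vs ~10 mm for a real
radius) so a subject fits a 64³ grid at the native voxel size; cortical
thickness and trabecular spacing are kept at their clinical values, so the
cortex-to-interior ratio is unrealistically large. Shape variation across
subjects = per-subject global scale (SD 3 %) × a smooth band-limited
sinusoidal perturbation of the radius profile, giving the shape variance
the PCA covariates need. Each subject also carries latent "BMD-like" and
"BV/TV-like" standard-normal fields on a small template grid sharing a
common factor whose weight ramps along the axis between `rho_distal` and
`rho_proximal`; these fields carry the planted location-wise correlation
(exactly ρ(v) by construction) used to validate the statistical parametric
mapping independently of the image chain.

## Segmentation

Periosteal surface: Gaussian smoothing (σ 1 voxel), thresholding
(self-calibrating default below), morphological closing with a Euclidean
ball (EDT-based), largest connected component, per-slice hole filling.
Voxels exactly at a threshold are foreground.

Thresholds default to the midpoint of the marrow/bone class means with the
classes split by Otsu's criterion. The midpoint (rather than the raw Otsu
bin value) matters: on nearly discrete histograms the Otsu threshold can
land inside the bin that holds a mode, which silently flips that whole
mode across the threshold.

Cortical/trabecular split: bone = voxels ≥ threshold inside the periosteum.
The endosteal (trabecular) volume is the morphological closing (radius 2
voxels — just enough to bridge marrow across a trabecula without rounding
the endosteal wall at plate junctions) of the union of interior marrow
components; marrow components touching the in-plane periosteal boundary
(the partial-volume ring at the outer edge) and components smaller than
`min_cortex_voxels` (intra-cortical pores) are excluded from that union,
so a small pore stays cortical and Ct.BMD is not diluted by the outer
ring. A marrow path reaching the boundary flags the segmentation
(discontinuous shell) instead of failing. The cortical mask is the shell
between the two surfaces, including intra-cortical pores — Ct.BMD is an
apparent (pore-inclusive) density, as in clinical practice.

Soft cortical membership: the fuzzy s-shaped function (0 below `a`,
quadratic rise to ½ at the midpoint, 1 above `b`), calibrated per subject
to the 10th/90th percentiles of BMD inside the cortical mask, which makes
it invariant to global intensity rescaling.

NL-FCM endosteal refinement: fuzzy c-means (c=2, fuzzifier m=2) on
z-scored features (BMD, smoothed bone indicator, periosteal distance) over
the bone voxels, with memberships relaxed toward the similarity-weighted
average of the memberships of the K=6 most similar patches (3³ patches,
7³ search window, weight λ=0.5). Patch similarities depend only on the
fixed features and are precomputed once. Cluster identity is resolved by
mean periosteal distance (cortical = smaller). Convergence is declared at
relative objective change < 1e-5; with λ>0 the plain FCM objective is not
guaranteed monotone, so the objective history is exposed and monotonicity
is asserted (in tests) at λ=0, where the alternation is standard FCM.
Degenerate inputs (constant features) return `converged=False`. The
default pipeline path uses the threshold split; NL-FCM is an optional
refinement, since the regularizer is a generic variant rather than a
published formula.

## Standard metrics

- Tb.BMD / Ct.BMD: mean calibrated intensity over the trabecular /
  cortical mask.
- Tb.BV/TV: partial-volume-compensated fraction — each trabecular voxel
  contributes `clip((I − I_marrow)/(I_tissue − I_marrow), 0, 1)` with the
  marrow level the median of non-bone trabecular voxels and the tissue
  level the mean of cortical bone. On noise-free unblurred volumes this
  equals the bone-voxel count ratio exactly; under blur it removes the
  quantization noise of counting plates only one or two voxels thick. The
  raw count ratio is also reported (`tb_bvtv_count`).
- Tb.N: 1 / (mean local thickness of the bone phase + mean local thickness
  of the marrow phase), using a sphere-fitting local-thickness transform,
  sampled away from the compartment boundary (2-voxel margin) and with a
  half-voxel interface correction per phase (EDT distances are
  center-to-center; each interface sits half a voxel beyond the last voxel
  center and is shared between the phases). For parallel plates this
  recovers 1/period; a curve-skeleton spacing estimator was rejected
  because 3D thinning reduces plates to curves and mis-measures spacing
  severalfold.
- Tb.Sp: derived as (1 − BV/TV)/Tb.N (exact identity, asserted).
- Ct.Th: cortical volume / periosteal lateral surface area (per-slice
  Crofton perimeter × slice thickness). For a hollow cylinder this is the
  annular mean (b² − a²)/2b — note this is smaller than the radial wall
  thickness; the streamline-based Surf.app.Ct.Th measures the radial one.

## Micro-finite elements

One 8-node hexahedral element per bone voxel; isotropic linear elasticity
(E = 6829 MPa, ν = 0.3; E in MPa and lengths in mm make forces N and SED
J/mm³). Elements not face-connected to both end faces of the axial extent
are pruned before meshing (each retained component must span). Boundary
conditions for the 1 % compression: distal-face nodes fixed axially,
proximal-face nodes displaced by 0.01 × axial length, lateral motion free;
the three in-plane rigid-body modes are removed by pinning one distal node
in x and y and a second same-y node in y — pins consistent with the exact
uniaxial-stress field, so a solid beam reproduces stiffness = E·A/L and
SED = ½Eε² to solver precision (the trilinear element represents the
linear exact field exactly). The assembled sparse system is solved by
Jacobi-preconditioned conjugate gradients to relative residual 1e-6
(configurable); non-convergence raises with the residual and iteration
count. Invariants checked per solve: reaction balance between end faces
and total strain energy = ½·F·δ.

Failure load: effective strain per element from the energy-equivalent
definition √(2·SED/E); the linear solution is scaled so that the critical
volume fraction (default 2 %) of tissue exceeds the critical strain
(default 0.7 %), i.e. scale = 0.007 / quantile₀.₉₈(effective strain);
FL = scale × reaction force. Both constants are configurable; by linearity
FL is invariant to the applied strain.

For cohort runs the demo-scale pipeline solves on 2× coarsened masks
(block-majority vote) to keep per-subject solves in seconds; the SED map
is upsampled back to the native grid. The coarsening factor is a config
key (`fea.coarsen`), 1 disables it.

## Parametric maps

Homogenization: uniform-weight mean over the discrete ball
{u : ‖u−v‖ ≤ r} (FFT convolution of value·mask and mask), undefined where
the kernel misses the domain. Trabecular maps are restricted to the
trabecular domain eroded by the kernel radius, so no kernel touches
cortex. Defaults r=11 for BMD/SED/BV/TV and r=5 for the inter-trabecular
distance, the working radii of this map family; desk-scale phantoms use
smaller radii via config since an r=11 erosion would consume their
interior. H.Tb.SED treats marrow as zero stored energy. H.Tb.1/N is the
local-thickness transform of the marrow phase in voxel units (bone voxels
0), matching the conventional unit and Tb.Sp-like magnitude of that map.

Cortical surface maps: the periosteal mesh is a marching-cubes isosurface
of the σ=1-smoothed mask at level 0.5 (axially padded so the tube is
watertight), vertex-clustered down to a budget (default 5000). A harmonic
potential (6-neighbor finite differences, sparse direct solve) is 0 on the
cortical voxels bordering the exterior and 1 on those bordering the
trabecular region; the maximum principle keeps interior values in (0,1).
Streamlines are integrated from each vertex along the normalized gradient
of a globally extended potential (RK2, step = half voxel); the arc length
is measured between the periosteal and endosteal 0.5-level sets of the
same smoothed indicators the mesh was extracted from, with sub-voxel
crossings by linear interpolation — this makes the half-voxel thickness
recovery independent of which voxel band carries the Dirichlet condition.
Surf.Ct.SIT is the trapezoid integral of the soft membership along the
streamline (so SIT ≤ app.Ct.Th always); Surf.Ct.BMD and Surf.Ct.SED are
arc-length-weighted means. Vertices near the axial ends of the scanned
section, stalled trajectories, and over-long trajectories are flagged
undefined and propagate as NaN.

## Spatial normalization

Registration is driven by geometry, not intensity: squared differences of
signed distance maps of the periosteal masks (clamped to ±1 mm — the far
field carries no correspondence information), because synthetic and
clinical intensity distributions differ while the analysis only needs
anatomical correspondence. Stages: center-of-mass initialization → affine
(multi-resolution regular-step gradient descent; if the optimizer ends
worse than its initialization, the initialization is kept) → symmetric-
forces demons on the affine-resampled SDFs (kept only if it improves the
metric). A registration whose final metric is worse than its
initialization raises. Maps are resampled to the template grid by
trilinear interpolation of (value × validity) and validity, keeping voxels
with ≥99 % interpolated validity — NaN-undefined regions therefore
propagate rather than bleed.

Surface correspondence maps template vertices through the
template→subject transform, projects onto the nearest subject triangle
(KD-tree over face centroids, exact point-triangle projection), and
interpolates per-vertex values barycentrically; projection distances are
QC-logged and vertices beyond 0.5 mm are undefined.

Shape covariates: generalized Procrustes over corresponded vertex sets
removing translation and rotation but *retaining scale* (bone size is
biology, not nuisance), then PCA; the first 4 scores are the default
covariates (and the components reaching 90 % variance are reported
alongside). The template is a designated reference subject of median
periosteal volume.

## Group statistics

- Adjusted group differences: OLS of the outcome on a group indicator plus
  covariates; two-sided t test on the group coefficient; collinear designs
  raise with the offending columns named.
- Partial Spearman: average ranks on ties (lattice-derived maps tie
  often), residualization of both rank vectors on the covariates, Pearson
  correlation of residuals; p from t with df = n − 2 − k. Exactly
  invariant to strictly monotone transforms.
- Fisher-Z between groups: z = (atanh ρ₁ − atanh ρ₂)/√(1/(n₁−3−k) +
  1/(n₂−3−k)). Subtracting the covariate count k from the usual n−3 is the
  standard df adjustment for partial correlations;
  `covariate_df_correction=False` restores plain n−3.
- FDR: hand-written Benjamini–Hochberg step-up (flag all p ≤ p₍ᵢ*₎ where
  i* is the largest i with p₍ᵢ₎ ≤ i·q/m), q = 0.05; NaNs excluded from m.
  Cross-checked in tests against `statsmodels.multipletests`.
- Correlation maps: the partial Spearman at every template location across
  subjects, vectorized through a single residual-maker matrix for
  locations with complete data; locations defined in fewer than 90 % of a
  group's subjects (config `stats.min_fraction`) are excluded from the map
  and from the FDR family. FDR runs over each map separately. Difference
  maps report Δρ as fracture − control with per-location effective n.
- Global (compartment-level) correlations use subject means of the
  pre-normalization maps, mirroring the convention that global analyses
  precede spatial normalization.

## Pipeline

Stages run in dependency order with content hashes (config + upstream
hash) cached in `run_manifest.json`; a re-run with unchanged config skips
completed stages. Motion grade > 3 subjects are excluded before any
analysis and counted. Volumes, masks, membership, SED and voxel maps are
NIfTI; surface maps are binary little-endian PLY with one float property
per map; tables are CSV; the report is plain text. Determinism: with a
fixed seed, repeated runs produce byte-identical CSVs (the FE solver and
registration are deterministic given inputs).

## Problem sizes

Defaults are desk-scale by design: demo cohorts of 5–12 subjects per group
on 48³–64³ grids, acceptance cohorts of 25 per group on 64³, micro-FE
closed-form checks on 32³ solids, statistics oracles at n ≤ 100 with
hundreds to thousands of Monte-Carlo replicates. The methods contain
nothing that ties them to these sizes; they are the sizes at which the
full battery runs in minutes on one CPU.

## Known limitations

- The phantom geometry is a scaled-down caricature: true radii are ~4×
  larger relative to cortical thickness, real trabecular networks are
  irregular and partially rod-like, and cortical porosity appears only
  through blur-induced partial volume, not as resolved pores.
- Tb.N's local-thickness estimator carries a voxelization bias of order a
  half voxel per phase even after the interface correction; at 82 µm and
  0.6 mm periods that is a ~5–10 % systematic, shared across subjects.
- The micro-FE model is linear elastic with axial loading only; no
  fall-configuration loading, no material nonlinearity.
- The NL-FCM regularizer is a generic non-local variant; with λ>0 its
  convergence is monitored, not proven.
- Registration accuracy is validated on translations, moderate scalings
  and smooth shape differences of the phantom family; it is not a general
  inter-subject brain-style registration benchmark.
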