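# Methods

This note documents the models, numerical choices and limitations of the
package. Units throughout: lengths in µm, forces in N, moduli in GPa,
strains dimensionless (reported in µε); array axis 0 is Z (axial), axes 1
and 2 are Y and X; physical coordinates are (x, y, z) with voxel centres at
(i + ½)·h for voxel size h.

## Segmentation

The specimen mask is a generous envelope: voxels above a low threshold
(default: 25% of the grey range) are dilated by a ball of radius 2 voxels
(configurable; the radius is not dictated by the protocol the package
mirrors, so it is exposed) and holes are filled slice-by-slice along the
axial axis first — vertebral cross-sections are closed rings, so 2D filling
makes them solid — then once in 3D. The global bone threshold defaults to
Otsu's between-class-variance maximiser computed only on masked grey values
(a reproducible stand-in for the visual threshold choice of the original
workflow; a fixed value can be supplied and every report logs the value
used). Face connectivity means the 6-neighbourhood; when component sizes
tie, the component containing the first bone voxel in (z, y, x) scan order
wins, so results are reproducible. The centred crop keeps
floor(f·N + 0.5) slices starting at floor((N − kept)/2); round-half-up is
used so the slice indices do not depend on banker's rounding.

The cortical/trabecular split is automated (the original workflow drew
manual contours): each axial slice of the bone is morphologically closed
(disk radius 5 voxels) and hole-filled to form the outer envelope; bone
within `shell_depth` voxels (default 3) of the envelope boundary is
cortical, the rest trabecular. The two labels partition bone exactly. On
phantoms with a constructed shell the split agrees with the construction
labels to ≥95% when `shell_depth` matches the constructed thickness; the
residual disagreement is a one-voxel band at the interface.

## Synthetic phantom

The generator produces what a ~39 µm microCT scan of a small vertebral body
shows: an elliptic-cylinder cortical shell (semi-axes 0.44·Lx and 0.36·Ly,
thickness 100 µm by default) around a trabecular lattice, with background
slabs above and below the body (8% of the height each) as for a potted
specimen inside the scan field of view. Those slabs are not cosmetic: a
body extruded through the whole volume leaves the axial position of the
specimen unobservable and registration can lock one lattice period off.

The lattice is a cubic rod network defined by trigonometric level sets
(rods where cos(w·a) + cos(w·b) exceeds a level, for each axis pair, with
w = 2π/period). The level maps monotonically to volume fraction, so a
60-step bisection calibrates the realised BV/TV inside the envelope to
±0.01 of the target. A sheet lattice (gyroid-type) was rejected: its
surface density forces sheets of 1–2 voxels at realistic volume fractions,
which blur and thresholding destroy (Dice ≈ 0.77 against ground truth);
the rod network at the default period of 640 µm — roughly trabecular
thickness plus separation — yields rods ~5 voxels thick and segmentation
Dice ≥ 0.98. Grey rendering: bone 190, background 60, Gaussian blur
σ = 0.8 voxels, optional additive Gaussian noise; all randomness flows from
the single integer seed in the spec, and the geometry itself is a
deterministic function of the parameters.

Analytic displacement fields (translation, affine, axial compression with
a transverse bulge, sinusoidal) are exact functions evaluable anywhere;
the dense representation samples voxel centres. The default apparent
transverse ratio of the compression field is 0.1 — the porous structure
accommodates axial compression largely without bulging, and the value
keeps the macro first principal strain below the tensile yield at 5%
nominal strain so the compressive/tensile yield ordering is meaningful.
Warping is inverse-mapping resampling, output(x) = vol(x − u(x)) with
trilinear interpolation (no holes; integer translations are exact).

## DVC

The measured field minimises
E(u) = Σ_mask [F(x − u(x)) − M(x)]² + λ‖L u‖², where u is trilinear
between nodes of a regular grid (nodal spacing NS voxels), F is the
preloaded and M the loaded image (both normalised to the masked grey range
of F), and L is the graph Laplacian of the node lattice with u in voxels.
The residual back-warps the *fixed* image with the same inverse-mapping
convention the phantom warp uses, so an imposed synthetic field is the
exact minimiser rather than the solution of an implicit equation; for the
small strains of a preload-to-load step this field coincides with the
material displacement to first order.

Minimisation is damped Gauss–Newton: normal equations assembled per grid
cell (the 24×24 corner-pair blocks are accumulated with bincounts over
cells, so assembly is vectorised and exact), sparse Cholesky-style direct
solve, step halving until the objective decreases, and a trust-region cap
of NS/4 voxels per step so ill-conditioned directions cannot jump into an
alias basin of (quasi-)periodic texture. A masked FFT cross-correlation
supplies a global integer-shift initialisation. Coarse-to-fine is a
Gaussian scale-space (σ = 2^(levels−1−l) − 1, ending at the raw images)
rather than a resampled pyramid, which keeps the grid fixed. Voxels whose
back-warped position leaves the image stay in the objective with clamped
values (so drifting out of the field of view is penalised, not rewarded)
but contribute no derivative information. The solver is deterministic; a
warning is attached only when no descent step could be taken at the finest
level.

Nodes are measurements only where the specimen provides data: the
accumulated basis weight of masked voxels is recorded per node (as a
fraction of one full cell), nodes below 0.5 are filled by harmonic
(Laplacian) extension of the measured field, and recovery errors in the
tests are evaluated at well-embedded nodes (weight ≥ 0.9) — the same
restriction grid DVC tools apply through the mask. The regularisation
default λ = 0.5 follows the repeat-scan zero-strain protocol balanced
against field fidelity: over λ ∈ {0.05, 0.2, 0.5, 1, 2} on the default
phantom, noiseless affine/compression recovery improves up to λ ≈ 0.5–1
(0.13 → 0.07 voxels RMS) while a sinusoidal field of period 4·NS degrades
beyond λ ≈ 0.5 (its Laplacian is penalised); λ = 0.5 sits at the joint
optimum. With that default and 2% grey noise, the zero-strain random
errors on the default phantom are ≈ 0.1 µm in displacement and ≈ 130 µε in
strain at NS = 16.

Grid strain treats each cell as an 8-node hexahedron of edge NS·h:
cell-centre strain from trilinear shape-function derivatives, principal
strains by symmetric eigendecomposition. Nodal spacing trades precision
for resolution exactly as in the full-scale protocol (whose NS of 48
voxels is ~3 trabecular spacings): at desk scale the tests use NS = 16 on
64³ phantoms so each cell spans at least one lattice period; fields with
wavelengths of 4·NS carry an irreducible trilinear representation bias of
~0.25 voxels at the nodes, which is why the noiseless recovery bound of
0.1 voxels is asserted for gentler fields (period 8·NS) and the 4·NS case
is asserted at 0.3 voxels.

## microFE

Every bone voxel is one cube element; nodes live on the voxel-corner
lattice, numbered lexicographically in (z, y, x), with the standard
hexahedron local corner order. All elements share one 24×24 stiffness
matrix (2×2×2 Gauss integration of the isotropic elasticity tensor;
uniform cubes, uniform material; ν = 0.5 is rejected). Boundary
conditions constrain all three components of every node on the minimum and
maximum axial node plane — one node plane per side — to the trilinearly
interpolated DVC field; interior nodes are free. Dirichlet elimination by
constraint reduction; the reduced system is solved directly (sparse LU)
below 5000 elements and by Jacobi-preconditioned CG (default relative
residual 1e-8) above; the threshold is configurable. The solved
displacement field of this Dirichlet-driven homogeneous model is
independent of E_t, and reactions are exactly proportional to it — the
package exploits both (strains computed once, forces rescaled, and the
closed-form back-calculation below).

Reactions are K·u restricted to constrained rows; AF sums the axial
components over the top-plane nodes, reported as a positive magnitude for
compression with the signed resultant retained; the vector sum of all
constrained reactions is the equilibrium check. Strains are evaluated at
element centroids; yield fractions count *elements* whose ε_p3 < −8000 µε
(compression) or ε_p1 > +7200 µε (tension), overall and as each
compartment's share of the yielded set.

Verification: the trilinear element reproduces affine fields exactly
(patch test to 1e-8 on random connected structures), a fully confined
4³ cube matches the closed form AF = E(1−ν)/((1+ν)(1−2ν))·ε·A = 215.4 N
(E = 1 GPa, ν = 0.3, ε = 1%, A = 16 mm²), CG agrees with a dense direct
oracle to 1e-8 on small meshes, and AF scales exactly with E_t.

## Validation statistics

Comparison points are DVC grid nodes inside a bone element and inside the
centred slab spanning 70% of the model height (boundary-condition
influence decays over about one cross-section width, so points near the
constrained planes would flatter the model). The predicted value is the
trilinear interpolation of the containing element's nodal solution; the
measured value is the DVC nodal estimate; the compartment label comes from
the containing voxel. Experimental values sit on the abscissa. Cook's
distances come from the simple linear regression per direction per
specimen, applied once; points with D ≥ 5·mean(D) are removed, and a
perfect (collinear) fit removes nothing — its distances are 0/0 roundoff
noise, guarded by a residual-scale test. RMSE is the prediction error
against the 1:1 line (not the regression residual), RMSE% divides by the
absolute maximum experimental value, and Lin's concordance coefficient
uses population (1/n) moments, so CC(x, x) = 1 exactly and |CC| ≤ |r|.

Back-calculation uses the exact linearity of the model in E_t: the least
squares scale between predicted and experimental forces is
s = Σ AF_pred·AF_exp / Σ AF_pred² in closed form, and E_bc = s·E_ref. On
the published four-specimen force table this gives 4.649 GPa, i.e. 4.6 at
the printed precision. One printed inconsistency is worth noting: the
published maximum force difference of 369% is not reproducible from the
published forces themselves (5256 N vs 1122 N gives 368.45%); the
recomputed value is reported as computed.

## Synthetic end-to-end experiments

Two modes exercise the chain on phantom cohorts. In *exact* mode the
loaded state is produced by the FE model itself: the truth model (at
E_true) is driven by the analytic field on its boundary planes, its
solution sampled at the grid nodes is the "measured" field (a noise-free
DVC of an FE-generated deformation), and the validation model (at the
reference modulus) is driven by that measured field. Back-calculation must
return E_true and predicted-vs-measured regressions the identity — this is
a self-consistency test of mesh, solver, interpolation and statistics,
exact up to solver tolerance when the grid node planes coincide with the
constrained model planes (NS dividing the crop-plane index; otherwise a
small BC interpolation offset of order 2% appears, which is a real
property of mid-cell boundary sampling, not an error). In *dvc* mode the
loaded image is warped, optionally noised, and registered — the full
pipeline; with 2% grey noise the cohort back-calculation lands within
~4% of E_true and the axial agreement slope within ~1%, while transverse
slopes inflate because the transverse signal (tenths of a voxel) is
comparable to the measurement noise. The default experiment sizes are 64³
phantoms in cohorts of four (exact) or two (dvc), which keep a full run in
minutes on one CPU while leaving ≥50 comparison points per specimen.

## What the phantom does and does not show

Passing on the phantom demonstrates the correctness of the machinery —
field recovery, elasticity, statistics, parameter identifiability — under
vertebra-like geometry, texture, blur and noise. It does not demonstrate
accuracy on real scans: the phantom has no beam hardening, ring artifacts,
partial-volume gradients at the 1–2 voxel scale, anatomically realistic
shape, endplates, or tissue heterogeneity, and its miniature cross-section
forces a cortical share of bone larger than in a real vertebra. Measured
BV/TV on the phantom is also systematically below the constructed value
because the mask envelope is dilated beyond the body. Conclusions about
real data rest on the workflow's design mirroring the in situ protocol,
not on the synthetic results.

## Known limitations

Linear elasticity only — beyond-yield regions are reported, not modelled;
a single homogeneous modulus; Cartesian hexahedra only; no subset-based
DVC, no rotation compensation; the matrix-free solver path for
hundred-million-DOF models is out of scope at desk scale; the figshare
image dataset of the reference study is not downloaded — a loader for its
layout is the `read_volume`/`read_force_records` pair plus the CLI
`validate` command.
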