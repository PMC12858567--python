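# Methods

This note records the models, conventions and numerical choices behind
each module, what the synthetic phantoms do and do not emulate, and the
known limitations. Units: lengths in mm (um inside voxel volumes),
forces in N, moduli and stresses in MPa, work in mJ = N·mm, mineral
density in mg HA/cm³, T2 in seconds.

## Phantoms and their ground truth

Every generator returns the synthetic measurement plus a ground-truth
record; downstream modules are validated only against these records.
Voxel membership is decided by the voxel center (a voxel is bone iff
its center lies inside the analytic solid), which is unambiguous and
convergent under refinement. Random draws come from per-operation
streams seeded by `(seed, operation tag)`, so adding a generator never
perturbs another's output.

* **Cortical tube**: annulus r_i < r_o; ground truth is the closed-form
  section property set (Ct.Ar = π(r_o²−r_i²), I_min = π/4(r_o⁴−r_i⁴),
  Ct.Th = r_o−r_i, Z = I_min/r_o). Optional single-voxel pores at a
  requested porosity.
* **Trabecular lattice**: two styles. `rods` is an orthogonal lattice of
  cylindrical rods (diameter d, pitch s) whose BV/TV is recorded as the
  exact voxel count and whose connectivity comes from the rod graph's
  first Betti number (for an n-cell grid, b1 = E − V + 1). `plates` is
  a parallel plate stack. The split exists because sphere-fitting
  separation metrics on a 3D rod lattice converge to the *diagonal*
  inter-axis gap (≈1.41·s − d), not to s − d: the plate geometry is the
  configuration for which Tb.Sp = s − d and Tb.N = 1/s are exact, so
  plates validate spacing metrics while rods validate BV/TV, Tb.Th and
  Conn.D. The rod-lattice record stores s − d and 1/s as nominal values.
* **Vertebral body**: elliptical cortical shell with flat end plates
  enclosing a rod lattice; shell and rods carry different tissue
  densities, so per-bin voxel counts under any mineral binning are
  known exactly.
* **CPMG train**: per-compartment mono-exponential decays,
  `s(t_k) = Σ_j c·v_j·exp(−t_k/T2_j)` with c the signal per microlitre;
  default acquisition 10,000 echoes at 100 us spacing. Additive
  Gaussian noise by default; Rician (magnitude) noise optional — at the
  SNR of interest (≈500) magnitude noise is indistinguishable from
  Gaussian. No diffusion, stimulated echoes or T1 effects.
* **Bending curve**: piecewise-linear — elastic ramp at stiffness k to
  the yield knee, work-hardening to ultimate, softening to the drop
  onset at knee + PYD, then a steep terminal drop; optional quadratic
  toe `f = k d²/(2·toe)` whose back-extrapolated origin is toe/2. The
  ground-truth record contains the *analytic* 0.9-secant yield point of
  the noiseless polyline (solved segment by segment), the analytic
  failure crossing, and exact trapezoid work terms, so the analyzer is
  checked against closed forms rather than against itself. Defaults
  (k = 112 N/mm, yield 14.2 N, ultimate 15.7 N) are typical healthy
  adult-mouse femur values.
* **Cohorts**: 2 (pretreatment) × 3 (glucose group) long-format tables.
  Cell locations default to end-point blood-glucose medians typical of
  non-diabetic (~175 mg/dl), untreated-diabetic (~725 mg/dl) and
  insulin-treated (~280–325 mg/dl) male STZ mice. Noise families:
  `gaussian` (location = mean), `lognormal` (location = median, scale =
  log-sd; right-skewed, triggers the non-parametric branches),
  `scaled-t` (df = 3, heavy tails).

What the phantoms do *not* emulate: scanner physics (beam hardening,
ring artifacts, partial-volume blur beyond additive noise), anatomic
geometry, machine compliance in the mechanical tests, and multi-site T2
exchange. Passing tests therefore demonstrate correctness of the
*analysis chain*, not robustness to every scanner artifact.

## Morphometry

Segmentation is a zero-phase Gaussian filter (scanner-script style
sigma/support pair, truncation at the configured support) followed by a
global threshold. Tissue mineral density is averaged after eroding two
surface-voxel layers (peel) to suppress partial-volume voxels.

Local thickness is Hildebrand-style sphere fitting, implemented as a
descending sweep over sphere-radius levels: a voxel has thickness ≥ 2r
iff it lies within r of a voxel whose Euclidean distance-map value is
≥ r (each level costs one distance transform, so the sweep is capped —
128 levels in 2D, 48 for thick 3D phases — bounding quantization error
at twice the level spacing). The sphere radius is the raw distance to
the nearest background voxel center: the extra half voxel this carries
approximately cancels the digital boundary raggedness that clips
inscribed spheres (validated against slabs, rods and the annulus).
Tb.N is the inverse mean spacing of the mid-axes, with the mid-axes
taken as the distance-transform ridge (voxels whose EDT is not exceeded
in their 26-neighborhood); a plate-model alternative 1/(Tb.Th+Tb.Sp) is
available behind a flag. Thinning-based skeletons were rejected because
3D thinning returns curve skeletons, which destroys mid-plane spacing
for plate-like structures.

Connectivity density is (1 − χ)/TV with χ the Euler characteristic of
the union of closed voxel cubes, counted exactly as V − E + F − C via
shifted boolean sums; this is the topology of the 26-connected
foreground with 6-connected background (the standard dual pair), and it
matches brute-force cell enumeration exactly on every fixture.

Cortical metrics are computed per slice in 2D and averaged over the
slab (the scanner-script convention). The periosteal envelope is a
morphological closing followed by hole filling; the medullary cavity is
the largest enclosed background component, remaining enclosed pixels
are pores (Ct.Po = pores/(bone + pores)). A slice with no enclosed
cavity, or whose cavity is only enclosed after closing, counts as a
broken ring and is excluded (all slices broken is an error). I_min is
the smaller principal second moment of the bone region about its
centroid; c_min is the largest perpendicular distance from the
I_min axis to the periosteal boundary.

## Micro-FE

One 8-node hexahedral element per bone voxel on the regular grid; a
single reference stiffness matrix (isotropic elasticity, full 2×2×2
Gauss quadrature) is scaled per element by E_t·h, which is exact for
this discretization. Tissue moduli follow the power law
E_t = 0.1127·TMD_i^1.746 evaluated at the median mineral density of
each element's bin (45–60 equal bins over 315.9–2787.3 mg HA/cm³; an
empty bin's lookup falls back to its midpoint). An analysis cylinder
(default radius 1.25 mm about the in-plane centroid) excludes posterior
elements; only the largest face-connected component spanning the
caudal-to-cranial planes is meshed, since floating islands make the
stiffness matrix singular.

Boundary conditions are high-friction axial compression: caudal nodes
fixed in x, y, z; cranial nodes fixed in x, y with prescribed
u_z = −(apparent strain)·(model height); default apparent strain 1%.
The reduced system is solved matrix-free (gather → reference-matrix
multiply → scatter) with Jacobi-preconditioned conjugate gradients,
deterministic summation order, relative-residual tolerance 1e-6 by
default. Reactions are recovered as K·u on the constrained planes;
global equilibrium holds to solver tolerance.

Equivalent strain is the energy form sqrt(2U_e/(E_t·V_e)) — the
convention of voxel-FE bone solvers — with von Mises strain behind a
flag. The failure load scales the reaction force by
0.007/ε*, where ε* is the (1 − 0.02) element-count quantile of the
equivalent-strain distribution with linear interpolation between order
statistics (elements share one volume, so count and volume quantiles
coincide). Linearity makes the estimate invariant to the apparent
strain used in the solve, which is verified to 1e-10. Mesh-consistency
caveat: the fixed end planes carry a stress singularity along their
edge ring; the percentile criterion is insensitive to it only while
that ring holds well under 2% of the volume, which sets a minimum
model aspect for refinement studies.

## Mechanical testing

The elastic stiffness is a single linear regression over the ascending
limb between 20% and 80% of the ultimate force; if that band is
contaminated (R² < 0.99, e.g. by a long toe), sliding quarter-band
windows are scanned and the stiffest well-fitting window wins. The
toe-corrected origin back-extrapolates the fit to zero force. Yield is
the first point where the secant stiffness from the corrected origin
stays below 90% of the elastic stiffness for a persistence run of
`smooth_window` samples, searched above the fit band — the persistence
and force guards exist because single noise dips at small displacement
otherwise fake yields at a few percent of ultimate. An offset-yield
criterion is selectable; results carry the criterion used, since yield
and post-yield values depend on it. Failure is the first post-ultimate
sample below 10% of ultimate; W_f and post-yield W_f are trapezoid
areas from the corrected origin and from yield. A force record whose
maximum does not exceed eight times the first-difference noise estimate
is rejected outright.

Vertebral ultimate load uses a first-failure convention (running
maximum before the first drop exceeding 20% of it); plain global
maximum is available by flag.

Notch geometry: the notch plane is the minimum-bone-area slice; the
section center is refined from the bone centroid by a Kasa circle fit
to the periosteal boundary (the centroid is biased away from the
notch); the notch half-angle is half the longest contiguous empty arc
of a 1-degree angular occupancy histogram (plus half a bin per edge for
partial blockage), and r_o/r_i are mean outer/inner radii over occupied
bins with half-pixel boundary correction. Crack-initiation toughness
treats the notched diaphysis as a thin-walled pipe with a
circumferential through-wall crack under bending:
K_c = F_b(θ/π, r_m/t)·σ·sqrt(π·r_m·θ) with σ = (F_ult·S/4)·r_o/I of the
intact annulus, and F_b = 1 + A·(4.5967(θ/π)^1.5 + 2.6422(θ/π)^4.24),
A = (0.125·r_m/t − 0.25)^0.25 for 5 ≤ r_m/t ≤ 10 and
A = (0.4·r_m/t − 3.0)^0.25 for 10 < r_m/t ≤ 20, valid for θ/π ≤ 0.611
(Takahashi's tabulation for pipe bending). Inputs outside the
tabulated range raise with the range stated; murine femora with
r_m/t below 5 therefore require a different calibration, a documented
limitation.

## Relaxometry

The echo train is inverted on a 128-point log-spaced T2 grid
(1e-5 – 10 s) by non-negative least squares with a second-difference
smoothness penalty; the penalty includes boundary rows (implicit zeros
beyond the grid), without which a linear ramp pinned at the short-T2
edge is penalty-free and unconstrained mass accumulates in bins that
decay before the first echo. The problem is solved through its normal
equations (Cholesky of A'A + λ²L'L), which collapses the
10,000-equation system to the grid dimension and makes the λ sweep
cheap.

λ is chosen by the chi-square-increase rule: the largest λ on a log
sweep (capped at the signal scale) whose data misfit stays within
1.025× the least-regularized misfit. A noise-discrepancy target was
evaluated and rejected: it lets the smoothest admissible solution spend
the entire noise budget distorting the early, mass-carrying echoes,
biasing total spectral mass by ~+17% on a single-peak reference. Total
spectral mass equals the t→0 amplitude within 2% at the study's
acquisition SNR of ≈500; at substantially lower SNR the short-T2 pool
(T2 ≈ 300 us, constrained by only the first handful of echoes) has an
irreducible mass/rate degeneracy of order 10–25% per realization, so
no λ rule restores 2% there.

Bound water is the spectral mass in the 50 us – 1 ms window (pore/free
water above 1 ms); both windows are configuration and are reported with
every result. The calibration constant is the reference volume
(21.2 ul water sphere, assumed co-acquired at the same gain; a gain
ratio is configurable) divided by the reference's free-water peak mass
integrated over 1 ms – 10 s — the peak, not the total, so spurious
sub-echo-spacing bins cannot leak into the calibration. Bone volume
comes from buoyancy: (mass in air − apparent submerged mass)/fluid
density, default 0.9982 mg/mm³ (water, 20 °C).

## Statistics

The parametric branch is the 2×3 factorial with interaction, fitted by
least squares on sum-to-zero contrasts; each effect is tested by the
SSE increase from dropping its columns from the full model, which is
Type III and safe for the mild imbalance of real cohorts (exact
agreement with statsmodels' `anova_lm(typ=3)` is asserted in the test
suite). Diagnostics gate the branch: Anderson–Darling normality on the
residuals and Spearman rank correlation of |residual| against fitted
values, both at α = 0.05 (configurable). Because two α = 0.05 gates run
on fitted residuals, well-behaved data pass both ~88–90% of the time —
slightly below the naive 0.95² — which is expected behavior, not
miscalibration of either test.

The aligned-rank-transform branch aligns the response for each effect
by subtracting every other estimated effect (unweighted cell-mean
decomposition), mid-ranks the aligned values, and refits the full
factorial, reading only the effect under test — three fits per outcome.
The defining correctness property — the two off-test effects carry
exactly zero F on each aligned response — holds to floating-point zero
and is asserted; after ranking it holds only approximately, as the ART
literature notes. Ties get mid-ranks throughout.

Post-hoc families follow the pre-declared plan: the three glucose-group
contrasts within each pretreatment level (two families) and the
pretreatment contrast within each glucose group (one family of three),
gated on a significant group or interaction effect (α = 0.05). A family
uses pooled-variance t tests with Holm–Šídák step-down adjustment
(adjusted p_(i) = 1 − (1 − p_(i))^(m−i+1), enforced monotone) when every
involved group passes Shapiro–Wilk and the Brown–Forsythe (median-
centered Levene) homogeneity test; otherwise Dunn's joint-rank z tests
with mid-rank tie correction, adjusted by the same step-down. A group
with n < 3 makes Shapiro–Wilk impossible and forces the rank branch
with a warning. Type-I error of both branches is calibrated to
[0.03, 0.07] per effect over 2000 null replicates in the acceptance
suite.

Out of scope by design: longitudinal mixed-effects models of weekly
body-mass/glucose trajectories (the factorial pipeline instead accepts
per-animal summaries such as last-four-week averages), multiplicity
control across outcomes, and Bayesian alternatives.

## Problem sizes and limitations

The default suite exercises the FE pipeline on a 24 um vertebral
phantom (~66k elements), the 6 um annulus and lattice only where the
closed-form recoveries demand that resolution, 20 seeds for
relaxometry, 100 seeds for noisy curve recovery, and 2000 Monte-Carlo
replicates for the ANOVA calibration. Known limitations: no geometric
or material nonlinearity, contact, or post-failure behavior in the FE
model; no machine-compliance correction or material-level (stress–
strain) normalization in bending; the toughness geometry factor's
r_m/t ≥ 5 validity bound excludes thick-walled murine sections; the
vendor's exact ridge-based Tb.N estimator is proprietary, so the
distance-ridge implementation is a published equivalent, not
bit-identical.
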