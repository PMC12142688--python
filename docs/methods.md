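# Methods

## Measurement model

Phase-contrast MRI encodes tissue velocity linearly into image phase:
a velocity component v maps to phase φ = π·v/VENC, with ±VENC (here
15 cm/s) at ±π. Three-directional encoding over a 3D volume, repeated over
32 temporal frames of a 3 s contraction cycle, yields a velocity vector per
voxel per frame. The analysis assumes the phase has already been
reconstructed to images (compressed-sensing or otherwise); k-space and
reconstruction are out of scope, as is phase unwrapping — velocities are
assumed below VENC.

The pipeline treats velocity frame *t* as the mean velocity over the
interval (t−1, t] and measures it at the *spatial* (Eulerian) position, as
a phase-contrast scanner does. Lagrangian displacement is recovered by
integrating trajectories through these fields.

## Preprocessing

**Phase shading.** Eddy-current-like phase offsets vary smoothly in space.
They are modelled as a 3D polynomial (order 2 by default, order ≤ 3
supported) fitted by least squares over a static mask — background voxels
at least 3 voxels away from moving tissue, whose true phase is zero — and
subtracted everywhere. The fit is exact for bias within the model class;
residual bias from higher-order shading is not removed.

**Denoising.** Each velocity component of each frame is filtered
independently with an explicit Perona–Malik scheme on the 6-neighbour
stencil:

    I ← I + δ · Σ_d c₂(|∇_d I|) · ∇_d I,   c₂(s) = 1 / (1 + (s/κ)²)

with N = 10 iterations, step δ = 3/44, and κ = 4 in the units of the
filtered image (cm/s for velocity). δ is validated against the explicit
3D stability bound δ ≤ 1/6. The update is written in flux form with zero
flux across the volume boundary, so the volume mean is conserved to
round-off. Differences are taken in index space: the filter is an
intensity-domain denoiser and deliberately ignores the physical voxel
anisotropy (1.875 × 1.875 × 5 mm); a spacing-aware variant was considered
and rejected as an unforced deviation from the classical scheme. κ is
interpreted in image units and exposed as a parameter, since velocities
around 1 cm/s against κ = 4 make the filter nearly linear inside muscle
while still attenuating sharp outliers. Filtering operates on velocity
(converted phase), not wrapped phase, to avoid wrap discontinuities.

## Tracking

Voxel trajectories are integrated by explicit forward Euler at the frame
period (93.75 ms): p(t) = p(t−1) + v(p(t−1), t)·Δt, with trilinear
interpolation of each velocity component in physical coordinates. Muscle
velocities are below a few cm/s, so a step moves well under one voxel and
the first-order scheme's error is far below the voxel scale; a midpoint
(RK2) option exists for validation and agrees with Euler to well under a
voxel on the phantom. Trajectories that leave the volume are clamped to
the boundary and flagged; the flag is sticky. The reference frame defaults
to frame 0 (rest), making the strain Lagrangian with respect to the
undeformed state. Tracking uses the denoised velocities; both choices are
recorded in the pipeline config.

## Strain

On the reference grid, the displacement gradient F_ab = ∂Δa/∂b is computed
by central differences in mm/mm (one-sided at volume edges; volumes must
span ≥ 3 voxels per axis). The strain tensor is the symmetrized gradient
L = ½(F + Fᵀ) — the small-strain (infinitesimal) form, which is the form
whose trace the incompressibility argument applies to. A Green–Lagrange
variant ½(F + Fᵀ + FᵀF) is available behind a flag for comparison but is
off by default; at 20% strain the two differ by O(ε²) ≈ 0.02, which is why
the small-strain form is also what the phantom prescribes.

Eigenvalues are sorted ascending: L_λ1 (most negative) is the compression
along the fiber at peak contraction, L_λ3 the transverse lengthening, L_λ2
the intermediate strain, near zero in muscle. Eigenvector signs are fixed
so the largest-magnitude component is non-negative — eigenvectors are
direction lines, and the colormap uses absolute components regardless. At
exactly repeated eigenvalues any orthonormal basis of the eigenspace is
acceptable; tests avoid asserting eigenvectors at degeneracies.

The invariants are computed from the tensor components prior to
diagonalization: L_max = ⅔·√(Σ_{i<j}(L_ii − L_jj)² + 6·Σ off-diagonal²),
which equals ⅔·√(Σ_{i<j}(λ_i − λ_j)²) and is rotation-invariant, and
L_vol = trace(L), the fractional volume change. A per-voxel validity mask
excludes the one-voxel volume border and any voxel whose gradient stencil
touches an out-of-field trajectory.

## Diffusion tensor fitting

The tensor is fitted per voxel to log(S_i/S0) = −b·gᵢᵀD gᵢ by weighted
least squares, with weights Sᵢ² taken from signals predicted by a
first-pass ordinary fit (one iteration). Squared-signal weights restore
the correct error weighting after the log transform; predicted rather than
observed signals keep the weights noise-free. Signals are floored at
10⁻⁶·S0 before the log and floored voxels are flagged. Eigenvalues are
sorted descending (diffusion convention, opposite to strain); the lead
eigenvector is the fiber direction; FA is the usual normalized eigenvalue
spread, clipped to [0, 1]. At b = 400 s/mm², 30 directions and SNR 50, a
*single voxel's* lead eigenvector scatters by ~4° about the true axis —
this is the physics of the acquisition, not a fitting deficiency — so
region-level fiber orientation is summarized by the lead eigenvector of the
mean dyadic tensor ⟨v vᵀ⟩ over the masked voxels, the standard
sign-invariant orientation average; it is accurate to well under 1°.
Gradient schemes are generated as a Fibonacci hemisphere (a fixed,
well-spread table); eddy-current and susceptibility correction are not
implemented (the phantom DWIs need none; externally corrected data can be
supplied).

## The phantom

The generator emulates the acquisition geometry (80 × 160 in-plane matrix
over 150 × 300 mm, ~28 slices at 5 mm, 32 frames / 3 s, VENC 15 cm/s) with
a two-region phantom: elliptic cylinders along the fiber axis z, agonist
anterior, antagonist posterior. Displacement is region-wise affine about
each region's centroid, u(x) = g(t)·A·(x − c), with the activation g(t)
following a ramp–hold–release force profile (raised-cosine ramps, ramp
fraction 0.25; the hold carries a 2% raised-cosine droop with its unique
maximum at the peak frame, mimicking imperfect force tracking — and giving
the peak-frame extraction a well-defined argmax).

The agonist matrix is A = diag(αε, (1−α)ε, −ε) with peak compressive
strain ε = 0.20 and transverse split α = 0.95: exactly traceless
(linearized incompressibility) and transversely asymmetric, giving
principal strains (−0.20, 0.01, 0.19) — a compressive and a tensile strain
of nearly equal magnitude with the intermediate one near zero, the pattern
observed in contracting muscle. The antagonist matrix is −(c/α)·A with
coactivation factor c = 0.5, which lengthens the region along the fiber,
stays traceless, and makes its compressive principal-strain magnitude
exactly c·ε — so the antagonist/agonist compressive-strain ratio is 0.5 by
construction.

Velocities are emitted as the incremental Eulerian field
v(y,t) = Δg·A(I + g_{t−1}A)⁻¹(y − c)/Δt: the velocity of the particle
currently at y, which is what phase-contrast imaging measures. This field
is linear in y inside each region, so trilinear sampling along trajectories
makes Euler tracking *machine-exact* in region interiors — the strongest
possible oracle for the kinematics and strain stages. The phase channel is
π·v/VENC plus Gaussian noise (default σ = 0.05 rad; the in-vivo level is
unknown and the parameter is swept in tests) plus an order-2 polynomial
shading bias; generation refuses to proceed if any noiseless velocity
reaches VENC. DWIs use a prolate tensor about z with
(λ∥, λ⊥1, λ⊥2) = (2.1, 1.6, 1.4)·10⁻³ mm²/s — design values for muscle —
plus Gaussian signal noise.

What the phantom does **not** emulate: partial-volume and chemical-shift
effects, fat signal, Rician magnitude statistics, intra-voxel velocity
dispersion, compressed-sensing reconstruction artifacts, gross limb motion,
through-plane fiber curvature, or spatially varying fiber orientation.
Within a ~3-voxel shell at region boundaries the piecewise-linear velocity
field is interpolated across the edge, so tracked trajectories there are
not exact; quantitative assertions use region cores or VOIs, which is also
how the in-vivo analysis places its ROIs (inside muscles, away from steep
gradients). Passing tests therefore demonstrate correctness of the
numerics and recovery under idealized deformation, not robustness to every
in-vivo artifact.

## VOIs, coactivation and statistics

A VOI is an in-plane box (nominal 9.38 × 28.13 mm → 5 × 15 voxels at
1.875 mm) replicated across adjacent slices. "Duplicated in two adjacent
slices on either side" is read as two per side (5 slices total);
`n_slices` is configurable and recorded in outputs. Indices are averaged
over valid VOI voxels at the frame of maximum force (earliest frame on
ties); a VOI with under 50% valid voxels is flagged and dropped. The
compressive strain is reported as a magnitude. Coactivation is the ratio
of the hamstrings-group mean |L_λ1| to the quadriceps-group mean, with
groups averaged by simple (unweighted) mean over muscles.

The statistics ladder, per strain index (L_λ2 excluded — its values sit at
noise level): Shapiro–Wilk per muscle × %MVC cell at α = 0.05; if all
cells pass, a two-way repeated-measures ANOVA gives the muscle and %MVC
main effects, the muscle effect Greenhouse–Geisser-corrected when
Mauchly's test fails (a standard, conservative choice); otherwise the
muscle effect is tested by Friedman per %MVC level — reported per level
plus one Bonferroni-combined decision p — and the %MVC effect by two-sided
Wilcoxon signed-rank on subject means across muscles (exact for small n
without ties; equivalent to Friedman at two conditions but with exact
small-sample p-values). A significant muscle effect triggers pairwise
Wilcoxon tests on subject values averaged over %MVC levels, Bonferroni
adjusted. Descriptives are mean ± SD under normality, median ± IQR
otherwise, matching the gate row by row.

The Friedman p-value can be computed three ways: full enumeration of the
(k!)ⁿ within-subject permutations (used automatically up to 5 × 10⁵
arrangements — e.g. a 5-subject, 3-condition table), seeded Monte-Carlo
permutation (4,000 draws), or the asymptotic χ²_{k−1}. The statistic is
the classical tie-corrected form. Calibration is verified by simulation:
on null tables (12 subjects, 4 muscles, 2 levels, σ = 0.05) the muscle and
%MVC main-effect tests reject at ~0.04–0.05; a 0.05 strain difference
between levels at σ = 0.01 is detected essentially always.

## Problem sizes and tolerances

Tests and the acceptance script use the small-grid preset
(32 × 64 × 12 voxels at full voxel spacing, 32 frames) for all
phantom-based checks — the region-wise affine model makes recovery
grid-size-independent, and the preset keeps a full pipeline run at a few
seconds. Statistical calibration uses 500 null replicates (type-I) and
200 effect replicates (power). Machine-precision assertions are placed at
1e−10–1e−14 where the computation is exact (invariant identities,
round-trips, interior tracking); recovery tolerances (±0.01 on strain,
5° on axes) reflect the discretization, not fitting slack.

## Known limitations

- The small-strain tensor is kept as the primary definition even at 20%
  strain, where finite-strain corrections are O(ε²); the flag-enabled
  Green–Lagrange variant quantifies the difference but is not the default.
- Forward Euler with per-frame fields has first-order time accuracy;
  adequate here because per-step motion is ≪ 1 voxel, but not validated
  for faster motion regimes (e.g. blood flow).
- The shading correction assumes polynomial bias and a reliable static
  mask; it cannot separate bias from true motion if the mask is
  contaminated.
- The statistics ladder implements a fixed, pre-registered-style decision
  tree; it does not model cell-level heteroscedasticity or missing data
  (unbalanced tables are rejected rather than imputed).
- Noise inflates the measured |L_λ1| slightly more in the antagonist
  (smaller eigen-gap) than in the agonist, biasing the noisy coactivation
  ratio upward by up to ~0.1 at σ = 0.05 rad; the noiseless ratio is
  exact.
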