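# Methods

This note records the models, numerical choices and limitations behind
`cochmetric`, in the spirit of a package vignette.

## Coordinate conventions

All geometry lives in a single world frame: LPS millimetres, 0-based voxel
indices, voxel-center convention; the world position of index `v` is
`origin + direction · (spacing ∘ v)`. SimpleITK performs the on-disk format
conversions (NIfTI, NRRD, MetaImage), whose native frame is already LPS.
Slicer FCSV fiducial files are RAS unless their header says otherwise and
are converted on read (negate x, y). Cropping and mirroring require
axis-aligned (signed-permutation) direction matrices — the only case in
which "the voxels whose centers lie in a world-aligned box" is itself a
grid; CT data and the phantom satisfy this.

Mirroring (for left/right laterality) reflects about the plane through the
volume's geometric center, so the mirrored atlas occupies the same world
extent as the original and both fiducial sets mirror consistently. It is an
exact involution and isometry, which is what makes the laterality symmetry
of the pipeline testable.

## Transform models

**Mapping direction.** The estimated chain maps atlas coordinates to target
coordinates, so fiducial propagation is a direct application of the chain —
no numerical inversion enters the measurement itself. Metric sampling
therefore draws points from the atlas ROI and probes the target at
transformed positions (the mirror image of sampling the target and probing
the atlas, equivalent by symmetry of NCC, chosen deliberately so that the
measured fiducials never need an inverse).

**Affine parameterisation.** translation (3) + Euler rotation (3) +
log-scale (3) + unit upper-triangular shear (3), composed as
`R · diag(exp s) · Sh` about the sample centroid. Log-scale and the explicit
rotation keep the matrix away from reflections and degeneracy during
optimisation. The rigid landmark stage is the closed-form Kabsch solution
(scipy `Rotation.align_vectors`) over the four named landmarks, with its RMS
residual reported.

**Free-form deformation.** Classic cubic-B-spline control-grid FFD:
`x → x + Σ d_ijk B3(u−i)B3(v−j)B3(w−k)`, control points acting as spline
coefficients. The default 4×4×4 grid spans the (post-affine image of the)
registration ROI: the ROI is one grid cell, giving the conventional 64
control points (192 scalar parameters). Evaluation uses
`scipy.ndimage.map_coordinates(order=3, prefilter=False)` on a coefficient
array zero-padded by the kernel support — the padding matters, because
scipy's own `constant` mode clips *values* discontinuously at the grid edge
rather than zero-extending *coefficients*; with padding the transform decays
smoothly (C²) to the identity outside the grid and matches a brute-force
tensor-product evaluation to machine precision. Fiducial propagation uses a
strict mode that raises for points beyond full cubic support.

**Invertibility.** Control displacements are capped at 0.4 × grid spacing
per component, the classic sufficient bound for an invertible cubic FFD.
Inversion (needed only to resample phantoms, never to measure) solves
`x + u(x) = y` by damped fixed-point iteration (damping 0.5, active-set);
plain Picard iteration can oscillate where the field's Jacobian norm
approaches 1 even though the map is invertible.

## Registration

**Objective.** Pearson-form NCC, undefined (an error) on constant intensity
vectors, invariant to positive linear intensity maps — the working defence
against the micro-CT vs clinical-CT intensity transfer. Optional histogram
matching of the target onto the atlas is available but off by default.

**Sampling.** Uniform without replacement over voxel centers in the ROI,
counter-based Philox generator keyed by the config seed (default 20180122),
so the 0.1 % affine sample is bitwise reproducible. The B-spline stage is
nominally dense (fraction 1.0) and additionally capped at 20 000 points by a
seeded subsample: 2×10⁴ samples over-determine 192 parameters by two orders
of magnitude, and the cap keeps dense-stage cost independent of atlas
resolution.

**Optimisation.** Monotone adaptive ascent ("regular-step" style): a
normalised gradient step that grows 1.2× on acceptance and halves on
rejection, never accepting a worse point, stopping after 5 consecutive
gains below 1e-5 or at the iteration cap (200 affine / 100 B-spline). The
affine stage uses central-difference gradients over 12 scaled parameters
(1 optimizer unit ≈ 1 mm or ≈ 1°) with a 3-level Gaussian scale-space
pyramid (smoothing at 4×, 2×, 1× the coarse voxel). The B-spline stage uses
the *analytic* NCC gradient with respect to control displacements (chain
rule through the trilinear target interpolation, with the basis-weight
matrix precomputed once): central differences over 192 parameters would
cost ~400 metric evaluations per iteration for no accuracy benefit.
Displacements are projected onto the cap each step. Per-stage NCC reported
in results is evaluated on a single common dense sample so the cascade's
values are directly comparable.

**Degenerate inputs.** Fewer than 3 or collinear landmarks, mismatched
labels, <50 % sample overlap, zero intensity variance, grids not covering
the ROI, and sub-10-point samples all raise typed errors naming the stage.
A final NCC below 0.3 does not fail the measurement but flags the result
low-confidence.

## The A-value pipeline

`AValueModel.fit()` executes landmark fit → ROI crop → affine → B-spline,
then propagates the atlas round-window/basal-turn fiducials and reports
their distance (printed to 0.01 mm). The target ROI defaults to a 10 mm
margin box around the four user-placed initialisation landmarks
(overridable; margins around the cochlea are a free choice the upstream
protocol leaves open), specified in world mm so the same box applies across
resolutions. Atlas laterality is resolved by mirroring when it differs from
the target's; laterality must be stated explicitly somewhere (flag or
fiducial-file metadata) — it is never guessed from the image.

CDL equations are configuration data, not constants: the published
coefficient sets (lateral wall, Organ of Corti) are transcription-sensitive
and are therefore supplied by the user or packager as named presets
(`[[cdl_equations]]` in the TOML config) with citation strings; the package
validates only that slopes are positive (CDL strictly increasing in A).

## The synthetic phantom

A bright tube swept along a logarithmically decaying planar spiral with
constant vertical pitch:

    r(θ) = r₀ · exp(−λ θ / 2π),  z(θ) = p · θ / 2π

Defaults: r₀ = 4.5 mm, λ = 0.5/turn, 2.5 turns, tube radius 0.6 mm, pitch
1.6 mm/turn — a human-scale cochlea with A ≈ 9.24 mm. The round-window
fiducial sits on the outer wall at θ = 0 and the basal-turn fiducial on the
outer wall at θ = π, so the A-value is closed-form:
`A = √((r(0) + r(π) + 2a)² + (p/2)²)`. Fiducials are placed on the
continuous spiral *before* voxelisation; the returned truth is exact at any
resolution. Atlas-like rendering is 0.1 mm on 128³ and clinical-like
0.6 mm on 64³ — the same two-resolution structure as micro-CT vs clinical
CT, scaled to desk runtimes. The modality gap is emulated by a different
blur (0.2 vs 0.8 mm FWHM), an affine intensity transfer, and additive
Gaussian noise; self-intersection of the tube is checked analytically.

Ground-truth deformations combine a random affine about the domain center
(defaults: per-axis scale 0.9–1.1, rotation ≤ 10°, translation ≤ 5 mm —
inter-specimen variation at the scale reported for human cochleae) with a
smoothed random FFD field rescaled to a 2 mm maximum displacement and
clipped to the invertibility cap. All draws are Philox-seeded and
reproducible.

What the phantom does *not* emulate: scala anatomy, beam hardening, metal
artifacts, partial-volume effects of surrounding temporal bone, or true
inter-subject shape variation beyond smooth low-frequency warps. Passing
the phantom suite therefore demonstrates the correctness of the machinery
(geometry, transforms, optimisation, propagation, statistics) under the
stated deformation model — not clinical accuracy on real scans, which
requires real paired data.

## Agreement statistics

Absolute percentage difference `100·|m−g|/g`; Shapiro–Wilk (scipy's
implementation, cross-checked against R) as the reported normality gate;
two-sided Wilcoxon matched-pairs with exact enumeration of all 2ⁿ sign
patterns for n ≤ 12 (ties mid-ranked) and the tie-corrected,
continuity-corrected normal approximation beyond; Spearman as Pearson on
average ranks with an exact rank-permutation p for n ≤ 8 and the
t-approximation beyond; Bland–Altman with sample (n−1) SD, 1.96·SD limits
of agreement, and the fraction of differences outside a clinical band of
±1.05 mm (the A-value error bound implied by revised CDL equations). Zero
differences are dropped by default (Wilcoxon's procedure); Pratt's method
is available. Report output labels significance at 0.05 (\*) and 0.01
(\*\*), `ns` otherwise.

## Problem sizes in the shipped experiments

The validation experiment (tests and `scripts/acceptance.py`) measures
19–20 independently deformed clinical-like targets against one study-scale
atlas. These sizes mirror the single-atlas, ~20-specimen design of the
validation literature while keeping the full suite to a few minutes on one
CPU.

## Known limitations

- Single-atlas workflow; multi-atlas fusion is out of scope.
- Landmarks are user-placed; no automatic landmark detection.
- NCC only; no mutual information (cross-modality contrast beyond a
  monotone/linear transfer is not modelled).
- Crop/mirror restricted to axis-aligned direction matrices.
- CDL presets ship empty by design: coefficients must be transcribed from
  their primary sources.
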