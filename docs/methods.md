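# Methods

`cytostretch` re-implements, as a tested pipeline, the quantitative analysis
of a cyclic-stretch experiment on mesenchymal stem cells (MSCs) encapsulated
in a 3D peptide hydrogel on a PDMS membrane: synthetic fluorescence image
generation with known ground truth, cytoskeletal orientation statistics,
intensity and nuclei-density metrics, a hyperelastic membrane model of the
stretch chamber, strain–alignment correlation, and ΔΔCt gene-expression fold
changes.  This note records the models, the defaults and why they were
chosen, and the limits of what the synthetic experiments demonstrate.

## Axial orientation statistics

Actin fibers are orientations, not directions: θ and θ+180° are the same
fiber.  All statistics therefore operate on doubled angles 2θ, where axial
data become ordinary circular data.  With R₂ the mean resultant length of
the doubled angles, the package defines

    CV_deg = (1 − R₂) · 180°,        CI = 1 − CV_deg / 180° = R₂.

A degree-valued "circular variance" is not standard (the usual circular
variance 1 − R is unitless); the definition above is the one degree-valued
spread measure that makes the coherency index hit both anchor cases —
CI = 1 for perfect alignment, CI → 0 for a random population — and be
monotone in spread.  When R₂ = 0 (e.g. equal mass at 0° and 90°) the mean
axial direction is undefined and is reported as NaN, never silently 0°.

## Synthetic micrographs

The generator emulates two-channel confocal images: an F-actin channel of
line-segment fibers with a Gaussian transverse profile, and a nuclei channel
of non-overlapping filled ellipses, both over a constant background with
additive Gaussian read noise (clipped at zero).  Fiber axial angles follow a
doubled-angle von Mises law: 2θ ~ VM(2μ, κ), whose population R₂ is the
Bessel ratio I₁(κ)/I₀(κ).  The three condition presets use concentrations
solving I₁(κ)/I₀(κ) = R for the target coherency indices:

| preset               | κ     | population CI | intensity × | nuclei × |
|----------------------|-------|---------------|-------------|----------|
| control              | 0.515 | 0.249         | 1.0         | 1.0      |
| stretch_0p5Hz_10pct  | 3.64  | 0.848         | 1.5         | 1.5      |
| stretch_2p5Hz_1pct   | 1.52  | 0.601         | 1.2         | 1.3      |

Default geometry: 1024×1024 px at 0.65 μm/px (typical 10× camera sampling),
300 fibers of 40±10 μm length and 1.5 μm width (FWHM), amplitude 1000 a.u.
over background 100 a.u., noise σ = 50 a.u. (5 % of amplitude); nuclei:
80 per frame, 160±40 μm² ellipse area, eccentricity up to 0.8, amplitude
800 over background 50, noise σ = 40.  Fiber count and photometry are
package conventions — they are not measurements — chosen so that fibers
cover a few percent of the frame and foreground/background separation
resembles well-exposed confocal data.  Stretch frequencies (0.5 vs 2.5 Hz)
enter only as preset labels; the generator models no dynamics.

What the generator does **not** emulate: point-spread-function blur,
photobleaching, Poisson shot noise (off by default), z-stacks, cell bodies
or any correlation between fiber placement and nuclei.  Consequently,
passing tests show that the measurement chain recovers known orientation
distributions and count/intensity ratios through realistic rendering and
noise — not that it is robust to every artifact of real microscopy.

## Orientation estimation

Two estimators mirror the two Fiji plugins commonly used for this analysis.

**Structure tensor (default).**  Gaussian-derivative gradients at scale
σ_g = 0.65 μm (1 px) form the tensor J = ⟨∇I ∇Iᵀ⟩ smoothed with a window
σ_w = 2.6 μm (4 px; the window must exceed the fiber width to integrate both
edges of a ridge).  The fiber angle is the minor-eigenvector orientation
(intensity varies least along a fiber); coherence = (λ₁−λ₂)/(λ₁+λ₂) ∈ [0,1]
(0 where the tensor vanishes); energy = λ₁+λ₂.  The angular histogram
weights each pixel by coherence·energy and excludes pixels below the 50th
energy percentile, the tensor-native analogue of thresholding before
extracting orientations.  This weighting carries a small positive CI bias
(~+0.02…+0.04 at the default conditions) because isolated, well-aligned
fiber cores receive more weight than crossing regions; the effect is within
the tolerances used throughout but visible when comparing image-derived CI
with ground-truth sample CI.

**Fourier directionality.**  Hann-windowed power spectrum, DC excluded,
power binned by the polar angle of the frequency coordinates and rotated by
90° (a ridge concentrates spectral energy perpendicular to itself).

Conventions: angles live in [0°, 180°) with 180° ≡ 0°; modal-bin ties
resolve to the lowest-angle bin; histogram weights are normalized to sum 1.

## Intensity and density metrics

Background is estimated by grayscale opening with a 25 μm disk (much larger
than a fiber, much smaller than the frame; decomposed footprint for speed)
and subtracted, flooring at zero.  Mean foreground intensity is the mean of
pixels strictly above an Otsu threshold — Otsu because it is parameter-free
and therefore "consistent across samples" by construction.  Normalized
intensity is the ratio of batch means against the control batch, so the
control row is 1 by definition.

Nuclei are segmented by Otsu thresholding and 8-connected labeling;
components outside 50–500 μm² (inclusive) are discarded — debris below,
merged/overlapping nuclei above.  No watershed splitting is attempted:
merged blobs exceeding the gate are excluded, which is exactly what the
gate is for.  On noise-free synthetic sets the gated count equals the
ground-truth count of nuclei with realized area inside the gate, exactly.

## Membrane mechanics

The PDMS chamber membrane is modeled as an incompressible Mooney–Rivlin
sheet, W = C10(I1−3) + C01(I2−3) with C10 = 0.12 MPa, C01 = 0.03 MPa
(Sylgard 184 at 10:1).  Dimensionality: 2-D plane stress — out-of-plane
bending is neglected and the ~1 mm thickness enters only force integration —
which is appropriate for a thin stretched membrane with minimal out-of-plane
deformation.  Incompressibility is enforced exactly by λ₃ = 1/det F;
substituting it into W eliminates the pressure (the transverse normal Cauchy
stress vanishes identically), avoiding any penalty parameter.

The solver is total-Lagrangian with 4-node quadrilaterals and 2×2 Gauss
quadrature.  The residual is the analytic gradient of total strain energy
(second Piola–Kirchhoff stress S = 2∂W̃/∂C with the reduced energy W̃(C));
the Newton iteration matrix is assembled from batched central finite
differences of the element internal forces (h = 10⁻⁶ · max(1, |u|∞)), which
affects only the iteration path, never the converged solution.  Defaults:
10 equal load steps, relative residual tolerance 10⁻⁸, 25 iterations per
step; non-convergence raises with step/residual diagnostics rather than
returning a partial state.  Cauchy stress is σ = F S Fᵀ (exact here since
the 3-D Jacobian is 1); von Mises uses the plane-stress form.

Chamber geometry is not a measured quantity; the default is a 30×10×1 mm
membrane, nx=60 × ny=20 elements, one short edge clamped and the other
gripped (axial displacement prescribed, lateral motion suppressed), lateral
edges traction-free.  Nominal strain = end displacement / free length.  A
roller variant (axial-only constraints, one corner pinned) admits the
homogeneous uniaxial solution and is used to verify the solver against the
closed form σ = 2(λ²−1/λ)(C10+C01/λ) to 10⁻⁶.  The central-region report
takes elements whose centroids lie in the central third of the length, full
width minus one boundary element row.  With grips, the central-third mean
engineering strain slightly exceeds nominal (≈10.25 % and ≈1.02 % for 10 %
and 1 % end displacement) because suppressed lateral contraction at the
grips leaves the center carrying marginally more axial stretch; mesh
refinement (60→120 elements along the length) changes the central mean by
far less than 0.5 %.

The hydrogel is not modeled as a separate phase: the membrane strain field
is exported directly as the mechanical stimulus experienced by encapsulated
cells, consistent with near-complete strain transmission through a thin,
well-bonded gel.  No viscoelasticity, inertia or frequency dependence is
modeled.

## Strain–alignment correlation

Element strain measures and the image orientation field are averaged onto a
common coarse grid; principal directions are averaged as axial data
(doubled angles).  Per-bin CI is correlated (Pearson) with per-bin maximum
principal engineering strain, and the angular deviation between the mean
fiber axis and the principal strain direction is folded to [0°, 90°].  In a
uniform strain field the correlation is undefined by design and reported as
NaN.  Because the underlying experiment reports this correspondence only
qualitatively, the module is validated with constructed positive and
negative controls, not against a published number.  Whether fibers align
parallel or perpendicular to the stretch axis is deliberately not asserted:
the module measures the deviation and leaves the interpretation to the
caller.

## ΔΔCt quantification

Per condition, ΔCt = mean Ct(target) − mean Ct(reference, GAPDH by default);
ΔΔCt = ΔCt(stretched) − ΔCt(control); fold change = 2^(−ΔΔCt).  Replicates
aggregate by arithmetic mean of Ct; SDs propagate in quadrature and map to a
fold-change SD by first-order (delta-method) propagation.  Primer efficiency
(10^(−1/slope) − 1)·100 from a dilution-series slope is informational only;
the perfect-doubling assumption of 2^(−ΔΔCt) is retained.  Fold change is
exactly invariant to a common shift of all Ct values.  Because no raw Ct
tables exist for the biological experiment, only the arithmetic — not the
biological fold changes — is verifiable, and it is checked against direct
exponential evaluation.

## Statistics layer

The report layer compares condition batches by one-way ANOVA plus pairwise
two-sided t-tests, starred at 0.05/0.01/0.001.  Pairwise p-values are
reported unadjusted (mirroring the usual practice in this literature), with
a clearly labeled Bonferroni column alongside.  Zero-variance groups take an
exact-equality fast path instead of producing NaN statistics.

## Problem sizes and determinism

Default experiment sizes: 10 images of 1024² px per condition for the
headline recomputation (3 per condition in the default orchestration config,
mirroring n = 3 replicates), and the 60×20 membrane mesh; these sizes put
batch-mean sampling error well inside the tolerances above while keeping a
full recomputation in the low minutes on one core.  Every source of
randomness takes an explicit seed (NumPy `SeedSequence` spawning per image);
identical configuration and seed reproduce bit-identical images, CSV reports
and solver output.  Output files carry a hash of the full configuration.

## Known limitations

- The CI estimator's weighting bias (above) means image-derived CI is not an
  unbiased estimate of the population CI; it is consistent across conditions,
  which is what the relative comparisons rely on.
- Otsu thresholding assumes a bimodal histogram; images with negligible
  foreground are rejected rather than silently measured.
- The membrane model has no 3-D through-thickness resolution, no connector
  contact mechanics, and no rate effects; frequency is metadata.
- The synthetic-data defaults are conventions standing in for unreported
  acquisition parameters (magnification, bit depth, chamber dimensions);
  conclusions transfer to real data only insofar as those conventions are
  representative.
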