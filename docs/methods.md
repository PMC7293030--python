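# Methods

`loopfold` analyzes how a small, positively charged protein (protamine is the
motivating case) folds short DNA into loops, using two complementary
single-molecule views: a Tethered Particle Motion (TPM) assay that watches
folding in real time through the shrinking Brownian excursion of a
DNA-tethered bead, and an Atomic Force Microscopy (AFM) assay that images the
folded structures directly. A polymer-statistics layer then asks the
mechanistic question: does the protein *soften* the DNA (an entropic drop in
persistence length) or *bend* it along a preferred radius (an enthalpic
change)? Because no raw bead videos or AFM scans ship with the package, every
stage is validated against synthetic data generators whose ground truth is
known exactly.

## TPM analysis

A bead tethered by a DNA of contour length L explores a disc whose size
tracks the effective tether length; folding shows up as a drop in the
windowed standard deviation of the bead's x position, sigma_x.

**Model of the bead trace.** The generator draws per-frame positions as
independent Gaussians with the active state's sigma (5 Hz frame rate), adds
linear instrumental drift, and switches states either instantaneously or
through a linear sigma ramp. Real bead motion has a relaxation time; an
optional Ornstein–Uhlenbeck mode (`ou_tau_s`) exists for stress tests but
defaults off, because the downstream statistics use 10-s windows that are
long against bead relaxation at 5 Hz. Whether white noise reproduces the
window statistics of real beads exactly is untested against real data — the
generator emulates the *analysis contract*, not bead hydrodynamics.

**Pipeline.** Per condition segment, a least-squares line is subtracted from
each axis (drift removal; segments under 10 frames pass through with a
warning). Tether QC requires eccentricity `e = sqrt(|1 - sigma_x/sigma_y|) <
0.45` on the protamine-free segment (a bead held by two tethers moves
anisotropically) and a whole-trace standard deviation above a length-specific
cutoff (18/25/40 nm for L = 25/50/105 nm). Both statistics default to the
protamine-free segment: applying the sigma cutoff to the full recording would
reject every tether that folds deeply, defeating the experiment. Options
switch the axis, the scope, and a variance-ratio eccentricity.

Rolling sigma_x is the sample standard deviation (n−1) over a trailing
50-frame window advanced one frame at a time. States are called on a 1-nm
histogram of that trace: a candidate peak must be strictly taller than its
neighbours and hold more counts than the window size (a state must outlive
one window). Two refinements are needed on top of that rule, because
consecutive rolling-sigma values share 49 of 50 frames and a single state
therefore produces a *ragged cluster* of candidate bins spanning a few times
the sigma sampling SD, `sigma / sqrt(2 (window-1))` (≈ 6 nm at sigma = 59):

1. adjacent candidates merge when they are closer than
   `max(3 nm, 1.2 × sampling SD)` **or** when the histogram valley between
   them stays above 0.4× the smaller candidate (no real dip, only
   raggedness). Genuinely distinct states are separated by near-empty
   valleys and are never merged by the valley rule.
2. each state is located at the count-weighted centroid of all histogram
   bins in its territory (bounded by midpoints between clusters), i.e. the
   mean sigma of the frames assigned to the state — far more stable than the
   tallest ragged bin.

The resolvable state separation is therefore a few times `sigma/7`, tightest
for folded (small-sigma) states; the 6-nm detection limit (the end of the
second 3-nm pooled bin, set by stuck-bead controls at 3 ± 1 nm) flags
unreliable peaks. The middle state of a three-state ladder can be pulled a
couple of nm toward its neighbours by the centroid estimator; recovery tests
allow ±3 nm.

Transitions: frames within ±1.5 nm (half the pooled bin) of a peak are
assigned to it; a transition is emitted when the assignment moves to another
peak and no third peak is visited for 5 s (suppresses band-edge flicker).
Duration runs from the last in-band frame of the start peak to the first of
the end peak, classed discrete (≤ 2 s) / intermediate / gradual (> 10 s).
On a rolling-sigma trace these durations include the window's own ~10-s
response, so fast folds on real or simulated bead traces read as upper
bounds; the class boundaries are exact on the sigma trace itself.

Pooling: per-tether peak locations are histogrammed at 3-nm bins per
condition, with sub-6-nm bins flagged.

## AFM analysis

Height maps are nominally 1 μm × 1 μm at 256 × 256 px (3.90625 nm/px) with
DNA lying flat at ~0.5 nm height and imaging at ~2.5 px apparent width.

**Rasterization model.** Contours are stamped as ridges with a Gaussian
cross-section (FWHM = 2.5 px, peak 0.5 nm) — a pragmatic stand-in for tip
convolution, calibrated so the mask thresholded at half the ridge height is
exactly 2.5 px wide. Where a contour crosses *itself*, the strands stack and
the far part of the contour adds its contribution, so a crossing images at
about twice the ridge height, as in a real topograph (overlaps between
*different* molecules are max-combined and flagged in the ground truth).
Optional per-row polynomial offsets emulate scan-line bow; pixel noise is
white Gaussian.

**Pipeline.** Rows are leveled by per-row degree-5 polynomials fitted to
background pixels (two passes: sigma-clipped fit, then a refit excluding
pixels above the foreground threshold; a row with almost no background falls
back to an all-pixel fit with a warning). Thresholding at 0.25 nm (half the
expected ridge height; Otsu would also work but a fixed physical threshold is
reproducible) and 8-connected labeling yield candidate molecules, selected
by: not touching the border; at least 1 px of background to any neighbour;
ridge crest height (90th percentile of the footprint — the footprint *median*
sits on the ridge flank and cannot reject tall contaminants) within
[0.3, 0.8] nm; and traced contour length at least 80% of the expected value
(0.34 nm/bp), which selects molecules lying flat.

Free DNA ends are boundary-curvature maxima by the k-cosine measure (k = 5
boundary points): a free end is a sharp *convex* spike, so candidates whose
flanking-chord midpoint falls outside the mask (concave notches at
crossings) are rejected; the two best maxima above the 90th percentile,
separated by ≥ 25% of the boundary, are the endpoints. If that fails, the
farthest pair of skeleton tips is used and flagged `auto_fallback`; a closed
ring with no tips is flagged `endpoint_free` and handled as a loop.

The centerline of a simple open molecule is the pointwise average of the two
boundary arcs between the endpoints, trimmed by half a molecule width at
each end (the mask's rounded caps extend past the true contour) and
resampled at 1-px spacing. Molecules with an enclosed hole, a stacked-strand
crossing (pixels ≥ 1.5× ridge height), or skeleton junctions instead use the
skeleton: contour length is the skeleton graph length plus one molecule
width per junction cluster (a crossing collapses about that much length into
a node), cross-checked against a height-integral estimate — total height in
the molecule's neighbourhood divided by the per-length integral of the ridge
profile — which is immune to mask topology because stacked strands simply
count twice. On noisy masks the skeleton route can overestimate length by
~10–15%; this only lowers the fractional extension of molecules already
classified by topology, never their class.

Classification is ordered by strength of evidence: an enclosed hole
(4-connected background not reaching the border) → **loop**; fractional
extension (end-to-end / contour) ≥ 0.6 → **linear**; a detected crossing
without a hole → **pseudo-loop**; otherwise the signed curvature along the
centerline, smoothed over 10 nm with sub-10-nm sign excursions ignored,
separates **c-shape** (single sign) from **s-shape** (sign change). Loop
diameter is `d = 2 sqrt(A/pi) + width`, A the unfilled area: tip broadening
shrinks the hole by about one molecule width, so d estimates the centerline
diameter of the loop; the smallest measurable loop (1-px hole) is 14 nm.

## Polymer statistics

Tangents are the unit directions of consecutive segments, located at segment
midpoints. This estimator is exactly unbiased for both null models — for a
tangent-walk worm-like chain the expected correlation at separation l is
exactly `exp(-l/(2 Lp))`, for a polygonal circle exactly `cos(l/R)` — unlike
a centred difference, which smooths the tangent over two segments and biases
fitted parameters by a half-step. All segment pairs of all molecules are
pooled into 4-nm separation bins (one ensemble curve, matching how grouped
fits are reported; per-molecule fits are available); each bin reports the
*mean separation* of its pairs, not the bin centre, so regular sampling
grids do not bias the abscissa.

Models, with s the dimensionality (2 for surface-equilibrated molecules; the
s = 3 forms are implemented but not exercised against data):

* flexible polymer: `<cos theta> = exp(-l/(s Lp))`;
  `MSD(l) = 2 s Lp l (1 - (s Lp / l)(1 - exp(-l/(s Lp))))`
  (evaluated with `expm1` and a series branch, so the l → 0 limit l² and the
  l → ∞ limit 2 s Lp l are exact to 1e-3 relative);
* bent circle: `<cos theta> = cos(l/R)`; `MSD(l) = 4 R² sin²(l/2R)` —
  the correlation crosses zero and the MSD turns over, which no exponential
  can imitate. The residual-norm comparison between the two unweighted
  least-squares fits (over l ∈ [bin, 0.9 × median contour length];
  negative-correlation bins retained, since they penalize the exponential)
  is the entropic-vs-enthalpic verdict. A circle fit whose radius exceeds
  5× the probed range is flagged `poor_fit` (indistinguishable from
  straight).

Local curvature: each centerline is resampled at the nearest-neighbour scale
(4 nm; skipped if already sampled there, keeping concyclic points exact) and
the circumscribed-circle radius of every point triplet is histogrammed
(2-nm bins, capped at 100 nm, collinear → cap), with the mode and its
interpolated FWHM reported. The triplet estimator is noise-sensitive: at
4-nm spacing the sagitta of a 10-nm-radius arc is only 0.2 nm, so point
jitter ≥ ~0.3 nm skews the histogram mode low while the median stays
unbiased; traced centerlines (boundary-averaged, hence smooth) sit in the
low-noise regime.

Bend-angle arithmetic: with one binding site per ~11 bp of arc and a 30-bp
radius of curvature, each bound protein subtends `11/30` rad ≈ 21.0°,
reported both at full precision and at one significant figure (20°); a
75-bp duplex holds `floor(75/10.5) = 7` helical turns and hence up to seven
proteins.

## Synthetic-data design

Contours are built by a tangent-walk: equal chord steps of
`h = L / round(L/step)` (all segments exactly equal; the effective step can
differ from the request by < 2%) with a prescribed per-step turn — Gaussian
with variance h/Lp for chains, constant h/R for arcs. Loops and pseudo-loops
share an "alpha" geometry: a circular head of centreline radius R whose two
tails cross transversally below it (tail half-angle β = 0.8 rad, chosen so a
105-nm molecule's fractional extension sits well inside the intermediate
band), differing only in whether the head's hole survives rasterization
(R = 10 nm loops keep a ~5-nm-radius hole and measure d ≈ 2R ≈ 20 nm;
R ≈ 5.5 nm pseudo-loop heads fill in). Default study conditions follow the
assay geometry throughout: 5 Hz, 50-frame windows, 59-nm unfolded sigma for
105-nm tethers, 100–200-s dwells, 256-px 1-μm fields, 0.5-nm ridges.

**What the generators do not emulate** — and hence what passing tests do not
show about real data: bead-trace autocorrelation and blur, tip-shape
convolution beyond a Gaussian ridge, surface-deposition kinetics,
inter-molecular clumping, and salt/sequence effects on stiffness. Recovery
results certify the analysis chain, not the microscope.

## Problem sizes and numerical choices

Test ensembles: 2000 chains for persistence-recovery (±5% bands), 300–1000
for fit examples, 50 rasterized loops for the diameter pipeline, 20 random
placements per shape kind for class recovery, 20 seeds for state-ladder
recovery — sizes at which the checked tolerances are a few times the Monte
Carlo error. Stochastic tests run derandomized with fixed conventional
seeds. Fits use `scipy.optimize.curve_fit` with analytic-ish seeds
(log-linear for the exponential, first zero crossing for the circle) and
bounds away from zero; non-convergence raises with diagnostics rather than
returning garbage. Histogram bins are half-open `[k, k+1)` anchored at 0.

## Known limitations

* State resolution degrades with sigma (`sigma/7` sampling SD); states
  < 3 nm apart are never resolved, mirroring the instrument's own limit.
* Transition durations through the rolling window are upper bounds for fast
  events; single-transition timing carries ±5-s noise at this SNR.
* Skeleton-route contour lengths on noisy masks are 10–15% high; the
  boundary-average route does not handle multi-loop (toroid-like) masks,
  which are out of scope.
* The curvature-histogram mode is only trustworthy for smooth centerlines;
  use the median under heavy jitter.
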