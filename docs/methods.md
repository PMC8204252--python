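# Methods

## The measurement problem

Microglia survey brain tissue with fine, constantly moving processes.  In
ex-vivo slice (or cranial-window) two-photon recordings, a single
GFP-labelled cell is imaged as a short series of z-stacks — typically
around eight consecutive stacks, two images averaged per plane, over a
~130 µm field at 512×512 px — and its behaviour is summarized by four
readouts computed from binarized 2D projections:

* **retraction / extension areas** per frame transition t_n → t_n+1:
  pixels occupied at t_n but not t_n+1, and vice versa (set differences,
  never count differences — a shape-preserving movement has zero count
  difference but real turnover);
* **motility index**: relative retraction + relative extension (both
  normalized by the cell area at t_n), summarized per cell as the mean
  over transitions;
* **surveillance index**: the sum of absolute retraction and extension
  areas over the whole recording — the total tissue area sampled;
* **Sholl profile**: number of processes crossing concentric circles at
  1 µm radial steps around the soma, from the t₀ projection.

Every transition satisfies the conservation identity
`|t_n| − retraction + extension = |t_n+1|` exactly; the test suite asserts
it against a brute-force per-pixel implementation.

## Processing chain

Per cell: read stack → average plane replicates → maximum-intensity
z-projection → translation-only registration → temporal-color-code crop →
background subtraction → 2 px median filter → photobleach correction →
pooled contrast normalization → global-threshold binarization → dynamics +
Sholl.  Choices that matter:

* **Registration** maximizes plain (unnormalized) image cross-correlation,
  frame-to-previous, with Fourier-upsampled subpixel refinement, offsets
  accumulated to frame-0 coordinates.  Phase-normalized correlation is
  deliberately avoided: whitening the spectrum lets shot noise at high
  frequencies dominate on low-texture fluorescence frames, producing
  spurious ~1 px offsets on perfectly static scenes.  Plain correlation
  recovers planted drifts of up to 10 px cumulative within 0.25 px in our
  validation renders (asserted at 0.5 px).
* **One global threshold** (Otsu on the pooled multi-frame histogram, or a
  fixed value) binarizes every frame.  Per-frame thresholds would convert
  residual intensity drift into fictitious motility; with a global
  threshold a time-constant series yields identical masks and exactly zero
  motility.
* **Single-component policy**: each frame's mask is the 8-connected
  component containing the soma seed (largest-inscribed-disk center of
  frame 0).  Disconnected specks would otherwise inflate turnover areas.
  A seed that lands on background (sub-pixel registration residue) is
  snapped to the nearest foreground pixel within 10 px; beyond that the
  frame errors out.
* **Photobleach correction** defaults to ratio mode — frame t is scaled by
  `mean(frame 0)/mean(frame t)` over above-background pixels (per-frame
  Otsu split) — with an exponential-fit alternative (`exp(+k̂t)` from a
  log-linear fit of the foreground means).  On a planted `exp(−0.05 t)`
  decay both modes flatten foreground means to better than 2 %.
* **Background subtraction** is rolling-ball (default radius 50 px) with
  shrink acceleration for large radii: block-minimum downscale, ball on
  the reduced image, bilinear upscale, clamped to the frame.  This is the
  same trade the ImageJ Subtract Background implementation makes and is
  indistinguishable on flat-background fluorescence data.
* **Contrast normalization** computes its two clip points once from the
  pooled time-series histogram (0.35 % per tail by default) and applies
  them identically to all frames, preserving inter-frame comparability.

Both pixel- and µm-denominated outputs are always emitted; µm² values
require a pixel size (from OME metadata or an explicit override) and are
refused without one.

## Sholl analysis

Circles are realized as thin annuli (width = one pixel diagonal) on the
skeletonized t₀ mask, centered on the inscribed-disk soma center
(config-overridable).  Crossings per radius are connected angular arcs of
skeleton pixels within the annulus, with wrap-around at angle 0; when one
arc carries several distinct skeleton lines (a branch point or crossing
inside the annulus), it is counted once per 8-connected group of skeleton
pixels just outside the annulus that touches it.  Skeletons come from
topology-preserving thinning with spur pruning (default 2 px); externally
traced SWC morphologies can be imported instead and analyzed with exact
segment–circle intersection counts.

Two fidelity regimes, verified separately:

* On trees in *general position* — tips and junctions away from
  sampling-circle knife edges, distinct junction radii, disjoint primary
  sectors (`synth.random_planar_tree`) — discrete counts match the
  analytic segment–circle oracle to ±1 at every radius.
* On fully random trees rasterized at finite branch width, sibling
  branches that diverge slowly stay merged in the mask for a few radii
  past their junction, and two junctions at coincident radii can each
  contribute a −1; the mask→skeleton route is therefore asserted to ±2.
  This is a property of mask discretization, not of the counter.

## The simulator

`gliamotion.synth` generates the validation substrate: one ramified cell —
soma disk plus a recursively bifurcating segment tree (exponential segment
lengths, angular spread around the parent direction, field-clipped) —
evolved at a configured turnover rate and rendered through PSF blur,
exponential bleaching, stage drift and Poisson shot noise to a uint16
OME-TIFF.  Defaults mirror the canonical acquisition: 512×512 px over
129.5 µm (0.253 µm/px), 8 frames, two replicate images per plane, Poisson
noise at 100 photons per intensity unit (cell ≈ 1.0, background ≈ 0.05,
SNR ≈ 10).

Kinetics: per transition the terminal tips are split at random into a
retraction half and an extension half; tips retract / elongate in ~1 µm
steps until the pixels lost to (gained over) the previous mask each reach
`q × area`, measured exactly on the rasterized masks (batched with an
adaptive pixels-per-step estimate; overshoot is bounded by one step).  The
soma is never modified.  Ground truth records masks, generating segments,
exact per-transition counts and drift, so every downstream readout has an
exact reference.  Realized mean turnover at q = 0.1 is ≈ 0.207 (retraction
+ extension fraction) against the nominal 0.2.  All randomness flows from
the single config seed.

What the simulator does **not** emulate: z-resolved morphology (analysis
operates on 2D projections, so planes are duplicated rather than grown in
3D), neighbouring cells and neuropil background texture, anisotropic PSFs,
detector offsets/read noise, and biological heterogeneity of process
thickness.  Passing tests therefore demonstrate correctness of the
measurement chain under a controlled imaging model, not robustness to
every property of real tissue recordings.

## Validation problem sizes

Validation and the acceptance script run the simulator at a reduced field
— 160×160 px at 0.4 µm/px (64 µm) with soma radius 3.5 µm, mean branch
length 8 µm, branch width 1.3 µm, 8 frames — which preserves the
morphological regime (branch width ≈ 3 px, SNR ≈ 10, ~2–3·10³ cell pixels)
at a fraction of the full-field cost.  Cohort comparisons use n = 8 cells
per group, mirroring the slice-assay design (n = 8–10 cells per group).
Noise-floor and drift-recovery checks use the same configuration with
kinetics disabled.

## Numerical conventions

* Pixel indices 0-based, `(row, col) = (y, x)`; masks are half-open grids
  of pixel centers; offsets are (dy, dx) applied to move a frame into
  frame-0 coordinates.
* Otsu ties resolved to the lowest optimal threshold (deterministic,
  inclusive of dim processes).
* Soma-detection ties (equal distance-transform maxima) resolved to the
  lexicographically smallest (y, x).
* Empty masks are errors everywhere, never silent zeros: an empty cell
  mask always indicates an upstream failure, and the motility denominator
  |t_n| would be undefined.
* Division of readouts: motility is reported as the per-transition mean
  (`motility_summary: sum` is available); surveillance is reported both as
  a raw pixel count and in µm².
* The full chain is deterministic: identical input and config give
  bit-identical masks and CSVs (floats written at 6 decimals).

## Known limitations

* Registration is pure translation; rotational or non-rigid tissue motion
  is not corrected.
* Sholl is 2D on the t₀ projection; no 3D Sholl, branch-order analysis or
  time-resolved ramification.
* The relative motility index is reversal-symmetric only when the cell
  area is conserved (the normalization is the area at t_n); the
  surveillance index and absolute areas are reversal-invariant always.
* Automated thinning replaces manual tracing; for faithful reproduction of
  manually traced morphologies, import the SWC trace.
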