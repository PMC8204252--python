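# gliamotion

Quantification of microglial process dynamics from two-photon time-lapse
recordings: from raw multi-plane image stacks to the motility index,
surveillance index, cell area and Sholl ramification profile of a single
ramified cell — plus a synthetic cell simulator that provides exact ground
truth for every stage of the pipeline.

## Who this is for

Labs running slice-based (or cranial-window) two-photon assays of
microglial surveillance: one GFP-labelled cell is recorded as ~8
consecutive z-stacks, and its behaviour is summarized by a handful of
mask-based readouts.  `gliamotion` re-implements that measurement chain as
a reproducible, scriptable library and CLI, replacing interactive
ImageJ-macro workflows.

## The readouts

All dynamics math operates on binarized cell masks.  For a frame
transition t_n → t_n+1 with mask areas |A_n|, |A_n+1|:

* retraction area R_n = |A_n \ A_n+1|, extension area E_n = |A_n+1 \ A_n|
  (pixel set differences);
* relative retraction r_n = R_n / |A_n|, relative extension
  e_n = E_n / |A_n|;
* **motility index** = mean over transitions of (r_n + e_n) — the fraction
  of the cell footprint turned over per interval;
* **surveillance index** = Σ_n (R_n + E_n) — total area sampled by the
  processes during the recording, reported in pixels and µm²;
* **Sholl profile** N(r) = number of processes crossing a circle of
  radius r (1 µm steps) around the soma, from the t₀ projection.

Every transition satisfies |A_n| − R_n + E_n = |A_n+1| exactly.

The processing chain per cell: read TIFF/OME-TIFF → average plane
replicates → maximum-intensity z-projection → translation registration →
temporal-color-code crop → background removal, 2 px median filter,
photobleach correction, contrast normalization → global-threshold
binarization (pooled Otsu) → dynamics + Sholl.  See `docs/methods.md` for
the choices and their rationale.

## Worked example

Simulate one ramified cell (64 µm field, 8 frames, 10 % pixel turnover per
transition) and push it through the full analysis chain:

```python
from gliamotion import synth
from gliamotion.cli import analyze_stack

cfg = synth.SynthConfig(seed=7, field_px=(160, 160), pixel_size_um=0.4,
                        soma_radius_um=3.5, mean_branch_length_um=8.0,
                        n_frames=8, turnover_q=0.1)
stack, truth = synth.simulate(cfg)
result, profile, info = analyze_stack(stack)
print(f"motility index          {result.motility_index:.3f}")
print(f"surveillance index      {result.surveillance_index_px} px  "
      f"({result.surveillance_index_um2:.1f} um2)")
print(f"mean cell area          {result.mean_area_um2:.1f} um2")
print(f"max Sholl intersections {profile.max_intersections} "
      f"at {profile.critical_radius_um:.0f} um")
```

prints

```
motility index          0.230
surveillance index      5166 px  (826.6 um2)
mean cell area          513.2 um2
max Sholl intersections 8 at 17 um
```

A motility index of 0.23 means ~23 % of the cell footprint turned over per
frame interval (the planted rate is 2 × q = 0.2; the excess is boundary
noise, and the simulator's `truth` object carries the exact per-transition
counts to compare against).  The surveillance index is the cumulative area
the processes visited over the 8 frames; the Sholl peak of 8 crossings at
17 µm summarizes the ramification of this particular tree.

Batch processing, simulation, SWC-based Sholl and group comparison are
available from the shell:

```
gliamotion synth --config synth.yaml --seed 9 --out sim/
gliamotion run --manifest manifest.yaml --out results/
gliamotion sholl --swc traced_cell.swc --step 1.0
gliamotion compare --results results/results.csv --groups adult aged
```

`run` consumes a YAML manifest (cell id, stack path, group label, optional
slice age / soma seed / crop box per cell, plus the preprocessing config),
isolates per-cell failures, and writes tidy CSVs (`results.csv`,
`transitions.csv`, `sholl.csv`, `failures.csv`) and a log with every
number-affecting decision (threshold, registration offsets, config hash).

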