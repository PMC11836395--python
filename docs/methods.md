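# Methods

`shoalwatch` quantifies welfare-relevant behaviour of a fish group from
overhead tank video: group cohesion, swimming activity, occupation of a
suspended enrichment structure, and — after a novel-object stimulus — the
latency to resume normal swimming. Because raw rearing-tank footage is rarely
shareable, the package ships an agent-based tank-video simulator whose ground
truth exercises every stage of the pipeline.

## Scene model and coordinates

The scene is a circular tank (default 100 cm diameter, 0.785 m²) viewed from
above. The camera monitors only part of the tank: the monitored region is the
lower circular segment holding a configurable area fraction (default 0.5,
i.e. the lower half of the field of vision). An optional enrichment structure
is a disc (default 70 cm diameter) suspended in the tank and rendered as a
static, slightly darker texture.

World coordinates are centimetres with the origin at the tank centre, x along
image columns and y along image rows (downwards). The pixel scale is set by
drawing the tank across 92 % of the shorter image side; every frame sequence
records its own `px_per_cm`.

## Synthetic school simulator

Agents follow a discrete-time correlated random walk at fixed step length
`mean_speed_cmps / fps`. Each step the heading is the normalised blend of

- the previous heading (weight 0.6, persistence),
- a unit pull toward the current group centroid with weight `exp(-dispersion)`
  — dispersion 0 is a maximally tight group, large dispersion approaches free
  diffusion so the group can span the tank,
- a unit pull toward the enrichment centre, weight `1.5 × enrichment_affinity`,
  applied only to agents *outside* the structure's disc, so affinity tunes the
  dwell fraction rather than pinning agents to the disc centre,
- a unit push away from neighbours within one body length (weight 1.2, a zone
  of repulsion as in standard collective-behaviour models; without it agents
  stack on top of each other, which no real shoal does and which floods the
  detector with merge/split events),
- an isotropic unit noise vector (weight 0.8).

The tank wall reflects specularly with half a body length of clearance.
Swimming polarity is deliberately not modelled: the cohesion construct below
requires controllable dispersion only.

Darting emulates the post-stimulus response: an inhomogeneous Poisson process
per agent with rate `r0 · exp(-(t - onset)/τ)` (defaults r0 = 0.1 darts per
fish per second, τ = 15 s); each dart multiplies the step length by
`dart_speed_multiplier` (default 4) for `dart_duration_s` (default 0.5 s).
Expected darting counts per window therefore decay monotonically after onset.

Rendering draws each fish as a dark ellipse (length `body_length_cm`, default
5 cm; width `length / aspect_ratio`, default aspect 3) oriented along its
velocity on a smooth textured light background (level 200, texture SD 12, fish
intensity 60), the enrichment disc darkened to 0.85 of the background, plus
i.i.d. Gaussian pixel noise (default SD 2). Defaults (10 fps, 8-bit grayscale,
512 px frames; tests use 256 px for speed) are stand-ins chosen to keep a
desk-scale clip both realistic for a fry-rearing tank and fast to process; no
camera resolution or frame rate was available to copy. Everything is
deterministic given the school seed, the noise seed and the background
texture seed.

What the simulator does *not* emulate: water-surface glare and refraction,
shadows, fish occluding in depth (the scene is strictly 2-D), individual size
variation, growth within a clip, and camera distortion. Passing recovery
tests therefore show the pipeline's logic is correct under the stated optics,
not that it is robust to every artefact of real footage.

## Background model and segmentation

The scene is static over a clip (constant illumination, fixed structure), so
the background is modelled per pixel by the temporal *lower median* and a
scaled median absolute deviation (MAD × 1.4826), estimated over ~60 frames
sampled evenly across the clip. The lower median (element `(n-1)//2` of the
sorted sample) is a deterministic tie rule; both statistics are robust as
long as fish transit a pixel in under half the samples.

A pixel is foreground when its deviation from the background location — in
the configured polarity, default dark fish on light floor — exceeds
`k_sigma × max(spread, min_spread_floor)` with `k_sigma = 4` and a spread
floor of 1 intensity unit (which keeps noise-free synthetic frames from
thresholding at zero). The raw mask is cleaned by an opening *by
reconstruction* with a disc of radius 1 px: the opened mask seeds a
propagation back into the raw mask. Plain opening is available
(`reconstruct=False`) but at desk-scale resolution a fish body is only ~4 px
wide and plain opening shreds diagonal bodies into fragments; reconstruction
removes salt noise equally well while keeping thin bodies whole. Foreground
is finally intersected with the monitored-region mask. Foreground pixel
count is exactly non-increasing in `k_sigma`.

No background adaptation is performed within a clip; the enrichment
structure, being static, is absorbed into the background model and is
recovered from it, not from the foreground.

## Detection

Connected components (8-connectivity default) of at least `min_blob_px = 3`
pixels become objects with real-valued pixel centroids and areas in px and
cm². A tight shoal is a single merged object, so each object carries an
estimated fish count `area / single_fish_area`.

The single-fish area is the binned mode of the areas below the 50th
percentile of all object areas in the clip (isolated-fish candidates, 30
bins); when the group never splits the estimate falls back to mean total
area over the nominal group size. The working body length is
`sqrt(area × aspect_ratio)`. A `growth_correction_factor =
reference_area / current_area` (clamped to (0, 1], default 1 when no
reference session exists) rescales area-derived ratios to the first-session
scale so growing fish are not read as increasing dispersion; the exact
correction used by the original acquisition software is not public, so this
multiplicative realisation is this package's own.

Objects are clustered by single linkage on centroid distance with cutoff
`linkage_factor × body_length`. The cluster with the largest summed estimated
fish count is the main group; members farther from the group centroid than
`outlier_factor × RMS` member distance (defaults 2.5) are re-labelled
outliers in one pass; remaining objects are individuals. The linkage factor
defaults to 4 body lengths: with small factors a dispersed shoal fragments
into singleton clusters and the "main group" degenerates to a few fish,
destroying the monotone relation between true dispersion and the measured
cohesion ratio; 4 BL chains across a dispersed shoal while leaving genuinely
solitary fish out. All factors scale with the estimated body length, so one
configuration keeps working as fish grow.

Frame-to-frame correspondence is greedy mutual-nearest-centroid matching:
candidate pairs within `gate_factor × body_length` (default 2) are accepted
in ascending distance order, ties broken by lowest object index, each object
matched at most once. No persistent identities are kept — only per-step
links, which is all the metrics need.

## Behaviour metrics (per clip)

**Group cohesion** — per frame, the area occupied by the main group is the
convex hull of member centroids dilated by one body radius (Minkowski sum
with a disc); with one member it is that object's own pixel area, and a
`blob` mode (summed member pixel areas) is available behind a config switch.
The frame ratio is occupied area over monitored area, multiplied by the
growth-correction factor and clamped to [0, 1]; the clip value is the mean
over frames with a non-empty main group. The ordinal score is 0 (tight) for
ratio < 0.25, 2 (dispersed) for ratio > 0.75, else 1 (loose); both category
boundaries belong to "loose", a deliberate resolution of the ambiguous
printed middle interval that preserves the two strict outer inequalities.

**Activity** — the size-weighted mean of match displacements pooled over all
frame pairs: `Σ w·d / Σ w` with `w` the moving object's estimated fish count,
reported in cm per frame step and cm/s, with an optional across-clip
standardisation (mean-centred, unit SD) for model-ready export.

**Enrichment occupation** — per frame, 100 × (foreground fish pixels inside
the enrichment region) / (all foreground fish pixels); clip value averages
frames with any fish. The region comes from a configured circle/polygon or
is auto-detected from the background model as the largest dark static
component (Otsu split of monitored background intensities, tightened to at
most 0.92 of the bright-mode median — a plain global median fails when the
structure covers half the view).

Empty clips produce explicitly flagged missing values, never silent zeros.

## Novel-object latency

Tracklets chained from frame links yield per-step speeds. A dart event is an
excursion above `dart_speed_bl_per_s × body_length` (default 3 BL/s)
sustained for at least `min_dart_frames = 2` consecutive frames, one event
per excursion, timed at onset. Normal swimming is resumed at the start of
the first window (10 s long, sliding in 1 s steps; both configurable, as is
a required run of consecutive qualifying windows) in which fewer than 2
distinct fish dart; an object of ≥ 2 fish-equivalents darting counts as its
rounded size, a conservative reading of "fish per 10 s". If no window ever
qualifies the trial is censored at clip duration and flagged. Latencies are
exported with a √latency column for downstream mixed-model fitting; censored
trials keep their flag and are never silently transformed into observed
values. The same rule applies unchanged to externally scored event tables
(`time_s`, `subject_id` CSV), mirroring manual annotation workflows.

## Orchestration and exports

`run_pipeline` executes background → detection → metrics (→ latency for
trial clips) for every clip of a YAML-configured study, fails fast naming any
missing input, and writes tidy long-format CSVs plus a machine-readable
column dictionary and a structured parameter log. Aggregation to tank × week
(× timepoint) means re-derives the categorical score from the mean ratio and
counts contributing clips; empty groups are flagged. Morphological and
physiological indicator tables are validated (positive weights/lengths,
ordinal scores within a declared scale — the fin-damage scale is declared
explicitly as (0, 2) or (1, 3) because both conventions circulate) and merged
on (tank, session) for external statistical software; mixed-model fitting is
deliberately not re-implemented.

## Numerical and testing choices

- All randomness flows through `numpy.random.default_rng` seeds carried in
  the parameter objects; identical inputs and config give byte-identical CSV
  outputs.
- Degenerate geometry is handled explicitly: hulls of < 3 points have zero
  area (ground truth) or fall back to capsule/blob areas (metrics);
  coincident agents exert no repulsion; zero-speed fish keep their heading.
- Recovery tests run at 256 × 256 px, 60 s, 10 fps, 20 fish with ≥ 10 seeds
  per condition — the smallest scene at which a 5 cm fish still spans ~12 px
  — and assert: cohesion ratio monotone in simulator dispersion (Spearman
  ρ > 0.9), activity within 10 % of the true mean step when fish are
  isolated, enrichment occupation within ±5 percentage points of the true
  dwell fraction, and latency within ±10 s of the truth-derived latency in
  ≥ 80 % of 20 stimulus seeds. Segmentation quality (≥ 95 % fish-pixel
  recovery, ≤ 1 % false positives) is checked at the 512 px default.

## Known limitations

- The cohesion numerator (hull of centroids vs blob area) is a modelling
  choice; both are implemented, hull is default.
- Inside a merged group blob no per-fish information exists; activity then
  measures blob-centroid motion weighted by blob size, which understates
  within-group shuffling.
- Dart detection needs the darting fish to be resolvable as an object for at
  least two frames; darts inside a merged blob are invisible.
- Auto-detection of the enrichment region assumes it is the largest static
  dark structure in the monitored view.
- No occlusion resolution, no 3-D, no online background adaptation.
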