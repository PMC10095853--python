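# Methods

`pollenbeam` is a virtual re-creation of an automated infrared-laser
workflow for isolating labelled pollen: a population of grains in a dish
is imaged tile by tile, living grains are found by FDA staining, target
grains by nuclear tdTomato fluorescence, each target is protected by a
circular exclusion zone, and every other viable grain is disrupted by a
focused 1,480 nm laser shot at its centre.  This note documents the model
behind each stage, the parameters that matter, what the synthetic data do
and do not emulate, and the numerical choices made where the design was
genuinely open.

## World model

A field is a flat list of cells over a rectangular stage area (origin at
the top-left of the irradiation area, +x right, +y down, all coordinates
in µm).  Each cell carries a class (`viable-nontarget`, `viable-target`,
`dead`, `dust`), a diameter, an FDA state, a red-label state, and
shrunken/displaced flags.  Invariants enforced on construction: unique
ids, dust ≤ 12 µm, dead ⇒ FDA off, target ⇒ red on.

**Counts and classes.** The number of grains is Poisson(density × area).
Default density is 84.8 grains/mm² — one-sixth of an anther (12,717 ± 2,814
grains per anther) suspended over 25 mm²; the one-quarter-anther
counterpart is 127.2/mm², and observed samples span roughly 40–130/mm².
Each grain is viable with probability 0.77 (the measured wild-type FDA
positivity) and viable grains carry the target label with probability
0.058 (the mean observed target ratio; samples ranged 3.6–9.4 %).

**Placement.** Non-clumped grains are dart-thrown with a grid hash under a
pairwise minimum separation (default 40 µm, i.e. visibly separate 30 µm
grains); an explicit `PackingError` is raised when the requested density
cannot be packed.  A configurable `clump_fraction` of grains is instead
attached to a previously placed grain at centre distance 0.9 × the sum of
radii — touching/overlapping, the way real grains adhere — which is what
drives merged detections downstream.  Sub-12 µm dust is sprinkled
uniformly (default 5/mm², an arbitrary but harmless level whose only role
is to exercise the dust filter).

**Rendering.** Cells are filled disks projected at 0.5 µm/px (default)
into 16-bit green/red/brightfield tiles of 0.5 × 0.5 mm; neither pixel
scale nor tile size is dictated by the instrument description, so both are
explicit choices that keep a 30 µm grain ~60 px across and give
80–120 tiles over a ≥ 20 mm² area.  Tiles are half-open `[x0, x0+w)` and
must cover the field exactly; a disk straddling a boundary is rendered in
every tile it touches, as a real tiled acquisition would capture it.
Intensity levels (16-bit counts): background 1,000; viable-grain green
drawn per grain from N(20,000, 2,000²) clipped at mean − 3 sd so every
viable grain clears the 9,600-count positivity threshold by construction;
FDA-negative grains at 3,000 (faint autofluorescence — what threshold
calibration samples); dust at 12,000 (bright but small, so the diameter
filter, not brightness, excludes it); target red at the 65,535 saturation
level; all grains at 10,000 in brightfield.  Per-tile Gaussian read noise
(sd 100 by default) is keyed on (seed, tile id), so rendering is
bit-reproducible and independent of iteration order.  No PSF, z-structure
or photobleaching is modelled: blobs are top-hat disks, which is exactly
enough for threshold/label/measure detection to be meaningfully tested and
no more.

## Detection

Detection mirrors the acquisition program: threshold a channel strictly
above a level, label connected components (8-connectivity), convert
equivalent diameter 2·√(area/π) to µm via the pixel size, and drop
components ≤ 12 µm (strict, as the dust rule is stated).  Centroids are
reported in stage µm (pixel centre convention `(i + 0.5)·px`).

* **Viability:** mean green intensity > 9,600 counts — a region-level
  criterion matching the "signal intensity" language of the rule.
* **Targets:** the printed target threshold ("> 65,535") is unattainable
  on 16-bit data; it is read as *the region contains saturated red
  pixels*, which preserves the intent (very bright nuclear tdTomato,
  sub-region-sized because of the H2B fusion) on the stated camera depth.
  The criterion is therefore `max_red ≥ 65,535` rather than a mean.
* **Totals:** viable/target detection alone cannot count FDA-negative
  grains, which the bookkeeping needs; `detect_all` detects every grain on
  the brightfield channel and then applies both fluorescence criteria
  per region.  `detect_viable` (green-only) remains the primitive the
  acquisition loop describes.
* **Calibration:** the FDA threshold can be set the way the loop sets it —
  detect grains on brightfield, take the near-non-fluorescent ones (below
  an Otsu split of the region green means, or all candidates when the
  sample is unimodal), sample 10 at random, return their mean green
  intensity.
* **Clumps:** the workflow only defines the *outcome* (a tile either has
  all grains "recognised separately as single pollen" or not), not the
  computation.  The rule here: a region is a clump when its pixel area
  exceeds 1.5 × the sample median region area; a tile is "separated" iff
  it contains no clump.  The median is a robust single-grain reference as
  long as clumps are a minority, which holds at the clump fractions of
  interest.

The pipeline runs detection on the stitched mosaic (tiles are half-open
and non-overlapping, so stitching is a pure copy) and then assigns each
region to the tile owning its centroid.  This measures a grain that
straddles a tile boundary once instead of as two fragments, while keeping
the per-tile bookkeeping; per-tile detection remains available as the
public per-tile operations.

## Planning

One exclusion zone of diameter 60 µm is centred on each target centroid.
A shot is emitted at the centroid of every viable, non-target region whose
centroid lies inside no zone.  Three deliberate readings:

* membership is tested on the non-target's **centroid** (the shot point),
  consistent with masking "an area from the centre of the target" and
  shooting centres;
* a centroid at exactly 30 µm counts as masked (inclusive boundary —
  conservative toward protecting targets);
* a region inside two overlapping zones is excluded once (set semantics).

Shots are ordered by tile in row-major grid order; within a tile a
nearest-neighbour chain starts from the tile origin (the within-tile order
is unspecified in the source workflow, so the heuristic is seed-free and
deterministic), falling back to input order in the rare adversarial case
where the greedy chain would be longer.  Every generated plan is
brute-force checked against the zones before it is returned.

## Disruption model

The laser response is an empirical map from focal-plane power (mW) and
exposure (ms) to the time until the FDA signal drops below threshold:

| power | FDA decay time |
|---|---|
| 24 mW | never (any exposure 1–20 ms) |
| 48 mW | uniform 165–225 s |
| 96 mW | "short" — not quantified; default 10 s, configurable |
| 145 mW / 10 ms | within 42.5 s (the chosen operating condition) |
| 194 mW | instantaneous, and the grain jumps forward |

Between characterised powers the decay time is interpolated log-linearly;
below 48 mW the model returns "never" (no disappearance was observed
there), and queries outside 24–194 mW or 1–20 ms are refused rather than
extrapolated.  The 145 mW draw is uniform in (0, min(42.5, t₉₆)] — capping
at the 96 mW value keeps decay time non-increasing in power, which the
narrative implies and the model property-tests.  Exposure dependence is a
multiplicative `(10 ms / exposure)^g` with `g = 0` by default: the
observed exposure effect between 1 and 20 ms is negligible at both ends of
the power range, and `g ≥ 0` keeps the monotonicity-in-exposure guarantee
for anyone who enables it.  Breakpoint draws are keyed on the model seed
only, so repeated queries are consistent and deterministic.

`apply_plan` resolves each shot to the nearest cell within half that
cell's diameter (a shot that resolves to nothing is logged as a miss — in
practice this happens only for stale or corrupted plans).  With
probability `success_prob` (default 1.0; real disruption rates of
65.7–87.2 % motivate the knob without claiming a mechanism) the grain's
decay clock starts; once the observation time reaches it the grain is
FDA-negative (a step, not a bleach curve — threshold crossing is all
downstream detection uses), shrunken to 0.7 × its diameter, and at
≥ 194 mW displaced by a uniform 20–60 µm jump.  Cell count is always
conserved.  Protected targets independently lose FDA with
`target_attrition_prob` (default 0), modelling the spontaneous signal loss
of a few protected targets (developmental arrest, bombardment damage)
observed in real runs.

Note an emergent property, not a tuned one: clumped grains merge into one
detected region, which receives one shot; the shot kills at most the
nearest grain, its partner survives re-detection, and the measured
disruption success falls.  This is the mechanism by which high-density /
clumped samples underperform separated low-density ones in the simulated
trend analysis, mirroring the real workflow's density and separation
effects.

## Reporting

All percentages are rounded half-up to one decimal (the convention the
printed statistics use — Python's built-in banker's rounding would get
several of them wrong).  Fold enrichment is computed from the rounded
percentages, which is what reproduces the printed fold values; an
unrounded variant is also emitted.  Disruption success has an ambiguous
denominator ("among non-target pollen"): the primary figure divides by
irradiated non-targets, and the all-viable-non-target variant is reported
alongside.  FDA loss is measured the way a real re-capture would measure
it: an irradiated region is "lost" when no post-capture viable region
centroid lies within the pre region's radius.  The count identity
`post FDA-positive = surviving targets + unirradiated viable non-targets +
irradiation survivors` is cross-checked on every report; a non-zero gap is
possible when clumped grains merge into single regions, so it is stored
and logged rather than raised (it is asserted to be zero in tests under
clean, separated conditions).

## Randomness and reproducibility

Every stage draws from a named substream of a single integer seed
(`SeedSequence((seed, crc32(name)))`), so a fixed config reproduces the
entire artifact tree byte-for-byte and any single stage can be re-run in
isolation.  Artifacts are plain formats: field and region CSVs, plan and
report JSON, multi-channel TIFF tiles with JSON sidecars; every
writer/reader pair round-trips losslessly.

## Problem sizes

Tests and examples run on scaled-down stages — typically 1–6.25 mm² at
1 µm/px with 0.5 mm tiles, a few hundred grains — which preserve every
rate and ratio of the full-size runs (density, viability, target fraction
are intensive quantities; only the grain count shrinks).  The trend
analysis uses 50 seeds per condition at 1 mm².  Full-size runs (25 mm² at
0.5 µm/px) are supported and simply cost more memory and time.

## Known limitations

* Optics are idealised: top-hat disks, no PSF, no focus or z-stack
  modelling, Gaussian read noise only.  Detection results on real images
  will degrade in ways the synthetic fields cannot reveal (uneven
  illumination, debris mimicking grains, out-of-focus tiles).
* The decay-time surface is anchored at four powers; between them the
  log-linear interpolation is a modelling choice, guarded only by
  monotonicity.
* Per-shot failure is a single Bernoulli probability; the real failure
  modes (partial hits, refocusing error, stage drift) are not mechanistic
  here beyond the clump-merging effect described above.
* Pollen-tube biology is out of scope: the semi-in-vivo statistics are
  implemented as counting arithmetic on observed tube counts, not as a
  germination simulation.
* Table-level per-sample raw counts of the original runs are not public
  beyond the quoted examples, so sample-by-sample reproduction is not
  attempted; the package reproduces the derived statistics and the
  qualitative density/separation ordering instead.
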