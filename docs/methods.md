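# Methods

## Coordinate conventions and geometry

All computations use image coordinates: origin at the top-left corner,
x to the right, y downward, so "up" on screen means decreasing y. The
5-lane plate is modeled by its swimmable lane bottoms (66 × 14 mm,
vertical long axis, up = top of the image, 18 mm pitch); the 6-well plate
by six 27 mm discs on a 3 × 2 grid at 39 mm pitch. ROIs are constructed
by `build_layout` as a regular grid (the plates are placed by hand in
practice, so layouts are declared in the experiment config rather than
auto-detected from the image).

Two partitions feed the scoring rules. A lane point is "up" iff it lies
strictly on the up side of the transverse midline; points exactly on the
midline count as "down". A well point's quadrant (TL/TR/BL/BR) is taken
relative to the well center, with points on an axis assigned to the
right column / bottom row. Boundary ties are measure-zero for real
centroids; any fixed rule works, these were chosen once and documented.

## Stimuli

Six assay schedules are built in: bar–dots, two-bar and their 4×-repeated
and four-color variants for lanes, and the rotating-cross assays (all
five colors, or red 4×-repeated) for wells. Cross epochs rotate at
90°/5 s = 3 rotations per minute and are shown on a light gray background
(230,230,230) for color separation; bar/dot assays use white. Stimulus
colors are saturated primaries — red (255,0,0), green (0,255,0), blue
(0,0,255), yellow (255,255,0), cyan (0,255,255) — which makes the
channel-selection rule exact. Quantities the assay descriptions leave
open were fixed as renderer defaults, exposed in `StimulusParams`: bar
10 mm tall oscillating over its half-lane at 5 mm/s, dot grid at 5 mm
pitch drifting up at 5 mm/s, cross arms 2 mm wide and 0.9 well radii
long starting at angle 0. The cross renderer reduces its angle mod 360°
before any trigonometry, so frames one full period apart are
bit-identical.

## Behavior model (synthetic data)

Each larva performs a correlated random walk. Per behavior step its new
heading is the direction of

    persistence · u(θ_prev) + weight · u(target)   + von Mises noise,

where the target and weight depend on the active epoch: away from the
bar's half-lane (weight `beta_bar`), toward the lane's up end during
moving dots (`beta_dots`), or along the on-screen tangential direction of
cross rotation, (−d_y, d_x)/|d| at offset d from the well center, signed
by rotation direction (`kappa_cross`). The larva then advances
`step_length_mm` and reflects off the ROI walls (emulating the agarose
walls). Defaults: step 1 mm per 6-s step (10 mm/min, within the range of
measured larval swim speeds), persistence 0.7, noise concentration κ = 4,
all stimulus weights 0 (baseline). `responder` presets set the three
weights to 2.0 — strong, unambiguous responses for pipeline validation —
and `blind` forces all weights to zero regardless of their values,
emulating photoreceptor-ablated groups whose only difference is the
absence of visual response.

Behavior steps are defined on a fixed 6-s time base (`behavior_step_s`).
When frames are acquired more sparsely than that (reduced-scale runs),
the simulator advances the walk in 6-s micro-steps between rendered
frames rather than stretching a single step. This keeps the physical
trajectory — travel distance, heading decorrelation, stationary response
distribution — identical to a densely sampled run, which matters twice:
epoch-averaged location measures depend on how far larvae can drift, and
paired epochs must decorrelate under the null for the statistics to hold
their nominal error rate.

Rendered larvae are dark capsules (4 × 0.8 mm, gray 70) with a darker,
wider head disc (radius 0.7 mm, gray 30, centered 1.3 mm forward). The
head disc stays within the body's extent along the axis, so the bounding
box remains centered on the true position while the intensity-weighted
centroid is displaced ~2–3 px (at 10 px/mm) toward the head. This fixes
the sign convention the orientation rule needs: on real larvae the
direction of the centroid offset (toward head vs tail) would have to be
established once per imaging setup, and both the sign and the minimum
offset are configurable.

What the generator does **not** emulate: body bending and tail beats,
occlusions and touching-larva shape merging beyond simple union,
illumination flicker, sensor noise, moiré, reflections at the water
surface, and wall-following behavior. Passing tests therefore demonstrate
the correctness of the measurement pipeline — channel algebra,
segmentation, the scoring rules, the statistics — under controlled
contrast, not the robustness of segmentation to real-world image defects.

## Detection

The analysis channel is the one minimizing |stimulus − background|
intensity for the scheduled color (ties prefer R, then G, then B); it is
computed from the schedule, which always knows the active color, rather
than estimated from pixels. Background is estimated by grayscale
morphological closing with a square window of radius 5 mm — much wider
than a larva (0.8 mm), narrower than the stimulus feature scale — and the
darkness signal (background − image) is mapped onto a flat bright field.
Each ROI is then auto-thresholded from its own histogram (IsoData by
default, Otsu selectable); an ROI whose intensity range is below 25 gray
levels is treated as empty rather than thresholding noise. Connected
components within 0.5–8 mm² (scaled by px/mm²) become detections with an
intensity-weighted centroid and tight bounding box; the area window
passes single larvae and pairs but rejects specks and larger clumps.
Touching larvae may merge into one particle — a documented limitation,
not an error; fidelity metrics are therefore defined on larvae more than
one body length apart. Per-ROI processing runs on a crop padded by one
background radius, so closing edge artifacts stay outside the ROI.

## Scoring

A larval measurement is one detection in one frame. Heading is the
centroid − bounding-box-center offset quantized into four 90° sectors
centered on screen-up/right/down/left; offsets under `min_offset_px`
(default 1 px, the pixelation noise floor) yield no heading, and exact
45° boundaries break toward horizontal. A heading is clockwise in its
quadrant iff it points along the local clockwise tangent — equivalently
the 16-entry table TL:{up,right}, TR:{right,down}, BR:{down,left},
BL:{left,up}. Per well and epoch, %up = up/(up+down) and
%CW = cw/(cw+ccw); measurements without a heading are excluded from the
%CW denominator. Swim speed links detections across consecutive frames by
greedy nearest-neighbor assignment gated at 5 mm/frame and averages all
linked step speeds in the well (full crossing-resolution tracking is out
of scope; at the assay densities trajectories rarely cross within one
interval).

## Statistics

The statistical unit is the well or lane; all larval measurements within
a well are pooled first, which keeps data points independent even with
five larvae per well (5 larvae × 10 min × 10 frames/min = 500
measurements averaged as a whole). Pairwise epoch contrasts use Welch's
two-tailed unequal-variance t (Welch–Satterthwaite df), Bonferroni-
multiplied by the declared family size and capped at 1; the strict
significance tier is p < 0.01, with p < 0.05 reported as a text tier.
Repeated epoch sequences use the one-way within-subject decomposition
(SS_error = SS_total − SS_subjects − SS_condition,
F = MS_condition/MS_error on (k−1, (k−1)(n−1)) df). Sphericity is tested
with Mauchly's W using the two-term Box chi-square approximation (the
convention of the major ANOVA packages); when it rejects at 0.05 — or
always, on request — the df are scaled by the Greenhouse–Geisser
ε̂ = (Σλⱼ)²/((k−1)Σλⱼ²), λⱼ the eigenvalues of the double-centered
within-subject covariance, clipped to [1/(k−1), 1]. Degenerate inputs
take limiting forms: zero variance in both Welch samples gives t = 0,
p = 1 (equal means) or |t| = ∞, p = 0; a zero error SS gives F = 0 or ∞;
incomplete matrices are rejected rather than imputed.

## Validation experiments and problem sizes

`zebraplate.experiments` packages the standard validation runs used by
the test suite and `scripts/acceptance.py`. Group sizes mirror the assay
designs: two plates per experiment, i.e. n = 10 lanes or n = 12 wells,
5 larvae per well/lane (1 larva per well for the repeated-cross
RM-ANOVA design). Detection fidelity runs at the full 10 px/mm scale over
every stimulus kind and color (5 frames per condition) and requires
recall/precision ≥ 0.95 and heading agreement ≥ 0.90 on well-separated
larvae. The Monte-Carlo error-control study (200 replicates) and the
responder power runs use 5 px/mm and 10 sampled frames per 10-min cross
epoch; the lane power run keeps the full 150-frame/epoch acquisition
density because the epoch-averaged location measure depends on drift
time. These problem sizes were chosen as the package's standard
reduced-scale validation configuration; all of them are function
arguments and scale up freely.

## Known limitations

* Channel selection trusts the schedule; a mislabeled config defeats it.
* Merged (touching) larvae are counted as one measurement; the area
  filter drops clumps of three or more entirely.
* The greedy speed linker underestimates speed when larvae swap
  identities within one frame interval.
* The simulator's effect sizes are set by construction, so power numbers
  characterize the pipeline's sensitivity at those effect sizes, not any
  particular biological preparation.
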