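# Methods

This note documents the models, conventions and numerical choices behind
motiongate, the assumptions they rest on, and what the synthetic fixtures
do and do not demonstrate about real recordings.

## Dissimilarity scoring

The score of frame *t* is the mean squared difference between the frame and
its reference on a single designated channel, computed in float64 with no
8-bit saturation. Normalising by pixel count (rather than summing) makes
scores comparable across the 128×96 to 512×512 resolutions typical of
video-rate two-photon acquisition; the choice affects only the scale of the
score axis, never the ranking that gating consumes.

Scoring is restricted to the reference channel on the assumption that it
images a structure that is temporally stable over the session (blood
vessels are the canonical choice: they remodel over days, not minutes).
If the reference structure itself moves or bleaches strongly, score peaks
no longer isolate motion artifacts — this is an assumption of the method,
not of the implementation.

**Rolling references (RFG).** The reference for frame *t* in `rfg` mode is
the arithmetic mean of the window of `window` frames centred on *t*
(`window` odd, default 15 — the midpoint of the useful 5–30 range; small
windows track fast baseline change but are noisier references, large
windows the reverse). Two boundary conventions had to be fixed:

* windows **truncate** at the stack edges rather than pad — padding would
  invent content;
* the scored frame is **included** in its own window. This dampens its
  score by a factor ((n−1)/n)² relative to exclusion — an impulse of
  uniform deviation *v* in an otherwise constant stack scores exactly
  (v·(n−1)/n)², and its in-window neighbours (v/n)² — but never changes
  which frame in a window scores highest. The closed forms above are
  asserted in the tests.

## Gating

**Percentile filter.** "Cutoff percentile P" keeps the frames scoring at or
below the nearest-rank P-th percentile (the value at rank ⌈P/100·T⌉ of the
ascending sort) and removes the rest. Nearest-rank was chosen over
interpolating estimators because it is deterministic, exact on small T, and
makes the kept count predictable: exactly ⌈P/100·T⌉ frames survive when
scores are distinct. With all-equal scores the threshold equals every
score and nothing is removed.

**n-neighbor (relative-maximum) filter.** Frames are partitioned in
temporal order into consecutive non-overlapping groups of n; in each group
exactly the highest-scoring frame is removed (ties remove the earliest — a
deterministic convention that matters only on synthetic data, where exact
ties occur). A trailing partial group is still filtered if it holds at
least two frames; a lone trailing frame is never removed. Overlapping
(sliding) groups were rejected because they make the removal count
input-dependent and can cascade removals through clean stretches.

**Double filtering.** A neighbor pass removes at most one frame per group,
so two consecutive corrupted frames in one group cannot both be caught;
re-applying the same filter to the retained sequence catches the survivor.
Between passes, scores are recomputed by default when rolling references
are in use (removing an artifact changes every window that contained it)
and reused when a single reference is in use (the reference is unchanged;
restricting the pass-1 scores is cheaper and identical in ranking). On
clean footage a second pass still removes one frame per group — the
documented cost of the option.

**Order.** When both filters are configured, the percentile gate runs
first and the neighbor filter second on the survivors. The percentile
gate is the bulk-removal tool; the neighbor filter is a local mop-up, and
running it first would waste its one-per-group budget on frames the
percentile gate removes anyway.

## Registration

Four nested model families map a moving frame onto its predecessor:
translation (dx, dy), rigid (adds rotation θ), scaled rotation (adds
isotropic scale s) and full affine (2×3 matrix; shear/skew). Translation
is estimated by whole-frame phase correlation with 1/20-px subpixel
refinement. The richer families are estimated by **intensity-based
Gauss–Newton least squares**: the inverse map is parameterised directly,
residuals are intensity differences over the interior of the field (an 8 %
border margin excludes fill effects), Jacobians are analytic (chain rule
through cubic-interpolated image gradients), and the iteration starts from
the phase-correlation translation. A feature-matching estimator was
prototyped and rejected: corner matches on vessel-like imagery suffer the
aperture problem along tube directions (median match error of several
pixels), which no robust fit can repair, whereas whole-image least squares
uses every informative pixel. This mirrors the intensity-based design of
the classic stack-registration plug-ins this module replaces. A fit that
diverges (too few interior pixels, singular normal equations, or an
implausible displacement exceeding the field size) falls back to
translation-only with a logged warning.

Planted-transform recovery on the synthetic vessel image: translation
within 0.05 px, rigid within 0.01 %, shear-0.1 affine within 0.5 % matrix
error (about 2 % when the plant itself is rendered with bilinear rather
than cubic interpolation, whose anisotropic blur genuinely shifts the SSD
optimum); under additive Gaussian noise of σ = 10 intensity levels the
translation component degrades to ~0.15 px.

**Propagated alignment** anchors on frame 0; each later frame is
registered onto its *already aligned* predecessor, so the estimated model
is already expressed in anchor coordinates and is applied to all channels
of the frame. Propagation accumulates subpixel error over very long
sequences, but keeps consecutive frames — the pairs that matter for
visual stability — maximally aligned, and never requires a global
reference that drift would invalidate. Resampling is bilinear with
zero fill outside the field and round-half-up re-quantisation to 8 bits.
One consequence, asserted in the tests: a warp–unwarp round trip recovers
interior pixels only to within 2 intensity levels, because each of the two
warps re-quantises (up to 0.5 level each) on top of interpolation error.

**Displacement tracking** follows a small patch (radius 5 px) around a
user-chosen marker frame-to-frame by normalised cross-correlation within a
15 px search radius, with parabolic subpixel peak refinement, and sums the
per-frame displacement magnitudes — the "total artifactual displacement"
of an object, reported in px and µm when the pixel size is known. The
track truncates with a flag if the patch reaches the field border.

## Enhancement

**Channel subtraction** removes dye bleed-through as
clip(target − α·source, 0, 255) per pixel; α is user-set (default 1.0)
because estimating the spillover coefficient requires single-dye control
data the pipeline does not have.

**Grouped projections** collapse consecutive non-overlapping groups of *w*
frames by per-pixel max or rounded mean; the trailing partial group is
projected as-is, and each output frame inherits the origin index of its
group's first frame. Non-overlapping groups are deliberate: the
projection's purpose includes frame-rate reduction.

**Kalman stack filter.** A causal per-pixel temporal smoother,
reconstructed from first principles (no published equations exist for the
classic plug-in's parameterisation; equivalence is claimed only for the
contract — noise reduction at unchanged frame count — not the
coefficients). Fixed-gain mode: E₀ = obs₀, E_t = g·E_{t−1} + (1−g)·obs_t,
default g = 0.8; g = 0 is the identity. Adaptive mode: a scalar Kalman
recursion with constant measurement noise R = (ρ·255)², ρ default 0.05,
prior variance V₀ = R; the gain sequence is data-independent and shared by
all pixels. Internal state is float64; output is re-quantised once at the
end. At steady state the fixed-gain filter attenuates i.i.d. temporal
noise variance by (1−g)/(1+g) (= 1/9 at g = 0.8); the tests assert this
ratio plus quantisation slack on a static noisy scene.

## Annotation

Timestamps are a pure function of origin index × frame interval, formatted
MM:SS.mmm; burned-in text uses a built-in 5×7 bitmap font (white ink,
1-px black outline) so rendered pixels are identical across platforms.
Sidecar-only mode always leaves pixel data bit-exact. Scale bars are
round(length/pixel_size) px wide and refuse to render without a pixel size
or wider than the frame.

## I/O conventions

Stacks are multipage TIFF (8-bit per channel, RGB or grayscale) or a
directory of numbered single-page TIFF/PNG files; bit depths above 8 are
rejected with the found depth named, because the gating math and the
generator are defined on the 0–255 scale. Origin indices and channel
names travel in a `<stem>.frames.json` sidecar so that filtered stacks
re-load with their acquisition timeline intact. The metadata sidecar is a
deliberately minimal `key = value` dialect (frame_interval_s,
pixel_size_um, channels, reference_channel); it emulates the *role* of a
microscope TXT export without claiming any vendor's schema. Frame
intervals outside [1/15, 1/2.5] s — the usual video-rate acquisition
range — parse with a warning, not an error.

## Synthetic scenes and what they show

`generate_scene` renders a three-channel recording: red, a static vessel
network (smoothed random-walk tubes with Gaussian cross-section, default
peak intensity 170) plus per-frame Gaussian noise (default σ = 4); green,
moving Gaussian blobs (cells, default 8 blobs, speed 1 px/frame); blue,
empty by default (a two-dye experiment; a third-dye preset adds static
blobs). Corruptions are applied across all channels: **major** artifacts
are full-field translations (≥ 8 px), defocus blurs (σ ≥ 4 px) or smooth
elastic warps (≥ 6 px peak); **minor** artifacts are 1–3 px translations
or ≤ 2 px partial-field warps. The magnitude thresholds separating the
classes are generator parameters of this package — the underlying field
notion ("full-field distortion" vs "small glitch") is qualitative. An
optional sinusoidal drift on all frames emulates slow peristalsis-like
motion. Everything is reproducible bit-for-bit from the seed.

Presets define the study conditions used by tests and the acceptance
script:

* **separable** (headline fixture): majors only, shift-type, 12–20 px,
  noise σ = 2, placed with no two adjacent. Under these conditions every
  major's rolling-reference score provably exceeds every good frame's
  score (verified margin ≈ 1.5× at T = 1000, 39.8 % load), so the
  recall-100 % result is a construction guarantee, not a statistical
  accident.
* **drift**: adds 8 px sinusoidal drift (period ≥ 200 frames). The
  amplitude is commensurate with the vessel decorrelation length, so a
  single reference frame goes genuinely stale — the regime in which
  rolling references demonstrate their advantage (single-reference
  residual ≈ 5–11 % vs 0 % for RFG at the same cutoff).
* **pairs**: majors planted as adjacent pairs at the starts of
  non-adjacent neighbor-filter groups — the configuration in which a
  single 3-neighbor pass caps at 50 % recall by counting argument and
  double filtering reaches 100 %. Group spacing guarantees the two
  survivors of different pairs never share a regrouped pass-2 triplet.
* **jitter**: artifact-free 4 px sinusoidal full-field jitter for
  registration and displacement-tracking checks.

What passing these tests does **not** show: real artifacts are not cleanly
separable (minor artifacts overlap the clean-score distribution, which is
why residual rates on animal data are a few percent rather than zero);
real noise is photon-limited rather than Gaussian; defocus in vivo is
z-displacement, which no x–y method corrects; and the generator's optics
are schematic (no PSF model). The fixtures verify the machinery —
scoring, ranking, gating arithmetic, registration, bookkeeping — under
conditions where the right answer is known exactly.

## Problem sizes and determinism

Default test and acceptance runs use T ≤ 1000 frames at 48–128 px frames —
sizes at which the full suite completes in seconds while still exercising
the long-video regime (1000 frames) where rolling references matter. All
randomness flows from explicit seeds (`numpy.random.default_rng`); the
pipeline records a config hash and per-stage frame counts in a provenance
JSON with every run.

## Known limitations

* No interpolation or in-painting of removed frames: the method eliminates
  bad frames, it cannot create good ones; heavily corrupted recordings
  (artifact fraction approaching the rejection budget) lose coverage.
* Non-rigid (elastic) distortion within a retained frame is not corrected,
  only detected and rejected.
* Processing is 3-channel, 2-D + time; z-stacks and a fourth channel are
  out of scope.
* The percentile cutoff is global; a recording whose artifact rate differs
  grossly from the cutoff's complement either under- or over-rejects, so
  P should be chosen after inspecting the score trace (`score_report`).
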