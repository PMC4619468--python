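# Methods

This note documents the models, parameter choices and limitations behind
`kinegait`: what each pipeline stage assumes, what the synthetic walking
generator does and does not emulate, and where the design was genuinely
open.

## Data model

A recording is the 4-D field `T(m, n, j, k)`: 20 joints (1-based indices,
fixed name table with hip centre = 1 … foot right = 20), 3 coordinates
(x right, y up, z depth from the sensor, metres), frames within segments.
"Left/right" follow the sensor-image convention, not the subject's body;
no mirroring is applied.  Each segment is one straight walk; each subject
records five, walking back and forth, so consecutive segments alternate
direction.  Frames carry their original index so that wall-clock time
(`frame / fps`) survives frame rejection.

On disk, recordings are plain CSV in a `long` (one row per joint per
frame) or `wide` (one row per frame, 60 coordinate columns) dialect plus
a JSON sidecar (fps, subject id, group label, unit).  Millimetre sources
are converted on read.  Round-trip fidelity is 1e-9 m.

## Gross-error rejection

Depth sensors occasionally misplace the whole skeleton for a frame.  The
torso centre of mass (mean of joints 1–3) moves smoothly in depth during
a walk, so a frame whose COM-z deviates from the segment median by more
than `k_sd` scale units is removed (default `k_sd = 1`).

The scale estimator defaults to the normal-consistent MAD
(`1.4826 · median |z − median z|`) rather than the plain standard
deviation (`scale="sd"` restores the latter).  The reasons are practical:
the standard deviation is inflated by the very gross errors being
screened, so the acceptance band would widen with each injected outlier,
changing which ordinary frames survive and therefore the step count —
a rejection step whose output depends this strongly on the corruption it
removes makes paired clean/corrupted comparisons unstable.  On clean,
approximately Gaussian traces the two estimators coincide.

On a walking segment the COM-z spans the walk path, so a one-scale band
around the median always trims the extremes of the walk (and with them
the turn intervals, which sit at the path ends).  This mirrors the
intended behaviour: the retained frames are the central, steady part of
each walk.  Rejection is a single pass; the band is not recomputed after
removal.  Removed frames are dropped, not interpolated; the original
frame indices keep timing honest.

## Savitzky–Golay smoothing

The filter weights are derived from first principles: for polynomial
order R and half-window L_w, the weight vector is the first row of
`(AᵀA)⁻¹Aᵀ` for the Vandermonde matrix A over offsets −L_w..L_w, i.e. the
value at the window centre of the least-squares degree-R fit.  Defaults
are R = 2 and a 25-frame window (L_w = 12), the configuration used for
this class of 30-fps skeleton data.  Properties guaranteed (and tested):
weights sum to one, are symmetric, and reproduce polynomials of degree
≤ R exactly.

Edge frames use shrinking-window fits of the same order (the window is
truncated at the segment boundary and the fit evaluated at the target
frame), so segment lengths are preserved and degree-≤R inputs pass
through unchanged at *every* frame, not only the interior.

**Ordering.** Rejection runs first, on the raw COM trace; smoothing runs
on the retained frames.  Leg lengths are estimated from the retained
*unsmoothed* frames: the 25-frame quadratic filter attenuates the
ankle/knee swing component by 3–13 % at typical stride frequencies
(measured from the filter's frequency response), which displaces
swing-phase joints by up to ~1 cm and would bias limb lengths by several
millimetres.  Limb distances are already length-stable per frame, so
smoothing buys nothing there.  Step detection, walk-span identification
and walking distances do use the smoothed recording, where low-pass
behaviour is wanted.

## Gait features

- **Leg length** per side is hip–knee plus knee–ankle distance
  (joints 13-14-15 left, 17-18-19 right), averaged over all retained
  frames of all segments; frames with a degenerate (zero-length) limb are
  excluded and logged.  The left–right difference is reported as an
  asymmetry statistic.
- **Walk spans**: the whole-skeleton mean position is projected onto the
  dominant horizontal axis of its own trajectory (principal axis of the
  x–z covariance), which avoids hard-coding the depth axis and makes the
  features invariant to rotating the sensor about the vertical.  Maximal
  runs of same-sign projected velocity above a floor (0.1 m/s) are
  straight walks; frames within 15 frames of a direction-reversal
  extremum are excluded, and runs shorter than 30 frames discarded.
- **Steps** are local maxima of the inter-foot distance with prominence
  ≥ 0.05 m and separation ≥ 10 frames.  The prominence default sits below
  the physiological step scale (~0.3–0.8 m inter-foot swing) and above
  smoothed sensor noise; 10 frames ≈ 0.33 s, faster than any walking
  step.  Raising the prominence can only reduce the step count (tested).
- **Stride length and gait velocity**: the span is clipped to
  [first step, last step]; SL = walking distance / step count,
  GV = walking distance / elapsed time, with elapsed time computed from
  original frame indices.  Note that this operational "stride length" is
  a step-scale quantity (distance per counted step extremum, ~0.4–0.6 m),
  not the two-step stride of classical gait nomenclature; both the
  metre-valued and the leg-length-normalised variant are computed, and
  classification defaults to metres.
- Per-subject features are arithmetic means over valid spans; spans with
  fewer than two step peaks are flagged invalid and counted.

## Classification

The pattern matrix holds stride length and gait velocity per subject;
the disease group is the positive class and lies *low* on both features,
so threshold rules take an explicit `lower_is_positive` direction rather
than inferring it.

- **Threshold sweep**: candidate thresholds are the midpoints between
  consecutive sorted unique values plus ±∞; confusion counts come from a
  vectorised rank computation and are tested against brute-force
  enumeration.  The optimal threshold maximises accuracy; ties break
  toward the larger sensitivity + specificity, then the smaller
  threshold (36-subject cohorts produce accuracy plateaus, so the
  tie-break is part of the contract).
- **Sigmoidal network 2-4-2**: logistic activations in both layers,
  one-hot targets (row 0 reference, row 1 disease), decision by argmax.
  Training minimises the squared output error by full-batch gradient
  descent with momentum (lr 0.5, momentum 0.9, ≤ 800 epochs) on a
  stratified 60/20/20 train/validation/test split (per-class rounding;
  36 subjects split 22/7/7); the validation split drives early stopping
  with best-weights restore.  Inputs are standardised with training-split
  statistics.  Everything is deterministic given (data, seed).
- **RBF network**: seeded k-means centres (default 18), Gaussian units
  `exp(−‖x−c‖²/2S²)` with spread S = 0.1 on the raw feature scale
  (features are O(0.4–1) in m and m/s), linear output weights by least
  squares, decision threshold 0.5.  Duplicate feature rows reduce the
  centre count with a warning.
- **Perceptron**: hard-limit unit trained by the classic error-driven
  rule on standardised inputs, 200-epoch cap, best-so-far weights kept.
- **Cross-validation**: stratified K folds (seeded); K = Q reduces to
  leave-one-out.  Misclassification is counted over all held-out
  subjects.

## Synthetic walking generator

The generator emulates the acquisition protocol — five straight ~4 m
walks per subject at 30 fps, back and forth with turning intervals, 5 mm
isotropic Gaussian sensor noise (a ±40 mm uniform mode is available),
and occasional gross-error frames that displace the whole skeleton in
depth by several times the clean COM-z band.

Kinematics: the pelvis advances at constant speed; the two ankles
oscillate in antiphase about the pelvis along the travel axis with
amplitude half the step advance, so the inter-foot distance has exactly
one maximum per step; knees are placed by two-link inverse kinematics so
the configured thigh/shank lengths hold *exactly* in every frame; the
upper body rides rigidly on the pelvis, with lateral sway during turns.
This is deliberately non-biofidelic — no stance/swing asymmetry, no arm
swing, no ground contact, no joint-angle realism — but geometrically
exact, which is what the pipeline's distance-and-peak logic needs for
ground-truth testing.  Passing tests therefore demonstrate correct
signal processing and estimation under the stated noise model, not
robustness to the full variability of human gait.

**Ground truth and calibration.** The recorded true stride length is the
value an ideal noise-free measurement would return —
distance(first step, last step)/steps on the frames surviving the
rejection band — computed from the generator's closed form (analytic
peak times plus band arithmetic on its own clean depth trace),
independent of the pipeline code.  Because that quantity equals
`step_advance · (P−1)/P` for P counted steps, cohort generation
calibrates the per-step advance so the ideal measured value matches the
drawn cohort target, and nudges the foot-phase so no step extremum falls
within a few frames of the band edge (otherwise sensor noise could flip
the step count of a segment).  Frame rounding quantises the achievable
value, so calibration accepts the nearest attainable stride length; the
truth record always carries the actually attainable value.

**Cohorts.** Group presets (18 disease: SL 0.38±0.07 m, GV
0.61±0.12 m/s; 18 controls: 0.54±0.06, 0.81±0.15; 15 students:
0.61±0.04, 1.05±0.15; leg lengths 0.785±0.034 / 0.783±0.027 /
0.792±0.009 m) are sampled as independent Normals truncated to
[0.1, 1.5]× the group mean.  Left–right leg asymmetry is |N(0, 5 mm)|,
giving a mean difference of ~4 mm.  When full recordings are generated,
the stride/velocity pair is additionally constrained to a physiological
walking cadence (GV/SL within 0.6–2.6 steps/s): independent marginals
occasionally pair a short stride with a fast walk that no walking
subject produces and that the constant-cadence kinematic model cannot
realise.  Feature-only cohorts (used for classifier-level experiments)
keep the pure truncated-normal marginals.

## Numerical and scale choices

- Problem sizes: test cohorts use 36 recorded subjects (plus 15 young
  reference subjects in the full three-group runs) with 5 segments each,
  ~150–250 frames per segment; population-threshold estimates use
  100 000 subjects per group, at which size the empirical optimum is
  within ~0.01 of the analytic density-crossing points (0.462 m stride
  length, 0.718 m/s velocity for the preset distributions).
- The SL/GV recovery tolerance of a few percent is dominated by frame
  quantisation of peak positions (±0.5 frame per peak) and smoothing
  shifts near span edges; leg-length recovery is exact without noise and
  sub-millimetre at 5 mm noise because per-frame limb distances average
  over ~10³ frames.
- Degenerate inputs: constant COM traces retain all frames; constant
  features produce a degenerate two-point ROC with a warning; zero-length
  limbs exclude the frame; empty classes, empty segments and
  out-of-range indices raise.

## Known limitations

- The simulator's gait model is a geometric stand-in; none of the
  kinematic subtleties that complicate real skeleton tracking (self-
  occlusion during turns, tracking latency, soft-tissue artefacts) are
  modelled.  Cohort-level classification numbers therefore characterise
  the preset feature distributions, not clinical data.
- Stride length and gait velocity are drawn independently within a
  cadence band; real subjects show correlated features, which would make
  two-feature classifiers look better than the independent-draw setting
  does.
- The rejection band assumes one dominant walking direction per segment;
  recordings with meandering paths would need the span detector's
  principal-axis projection to be computed per span rather than per
  segment.
- Only two features enter classification; cadence, double-support time
  and trunk kinematics are out of scope.
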