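# kinegait

Skeleton-joint gait analysis for gait-disorder screening: from raw 3-D
joint recordings of walking subjects to per-subject digital gait
biomarkers (leg length, stride length, gait velocity) and
disease-vs-control classification.

The package targets recordings of the kind produced by consumer depth
sensors: 20 named joints per frame at 30 fps, organised into straight-walk
*segments* of roughly 4 m, with the subject turning between segments.
Sensor accuracy of a few centimetres and occasional gross tracking errors
are assumed.  It is written for motion-analysis researchers and for anyone
who wants a fully testable reference pipeline: a bundled kinematic walking
simulator generates labelled synthetic cohorts so that every stage can be
validated without clinical data.

## Method

Given the joint-position field `T(m, n, j, k)` (joint *m* = 1..20,
coordinate *n* = 1..3, frame *j*, segment *k*), the pipeline runs:

1. **Gross-error frame rejection.** The per-frame centre of mass
   `COM(n, j, k) = mean(T([1 2 3], n, j, k))` (hip centre, spine, shoulder
   centre) is tracked in depth *z*; frames outside
   `median ± k·scale` of the segment's COM-z values are dropped
   (default `k = 1`, robust scale estimate).
2. **Savitzky–Golay smoothing.** Each joint-coordinate sequence is
   filtered with `ŝ(j) = Σ aₗ s(j−l)`, the weights `aₗ` realising a local
   least-squares polynomial fit (order 2, 25-frame window, built from the
   normal equations — no library filter).
3. **Leg-length estimation.** `LL = D₁₃₋₁₄ + D₁₄₋₁₅` (left hip–knee +
   knee–ankle), `RL = D₁₇₋₁₈ + D₁₈₋₁₉`, `L = (LL + RL)/2`, averaged over
   retained frames; stride length is also reported normalised by `L`.
4. **Step detection.** The inter-foot distance
   `DIST(j,k) = ‖mean(T([15 16])) − mean(T([19 20]))‖` attains one local
   maximum per step; maxima with sufficient prominence are steps.
5. **Stride length and gait velocity.**  Within each straight-walk span
   (monotone depth progression, turn frames excluded), with the walking
   distance *d* between the whole-skeleton mean positions at the first and
   last step: `SL = d / steps`, `GV = d / elapsed time`; per-subject
   features are means over segments.
6. **Classification.**  Threshold sweeps with ROC analysis
   (`TPR = TP/(TP+FN)`, `TNR = TN/(FP+TN)`,
   `ACCU = (TP+TN)/(TP+TN+FP+FN)`), a two-layer sigmoidal network 2-4-2
   (`A1 = F(W1·P + b1)`, `A2 = F(W2·A1 + b2)`), an RBF network with
   k-means centres, a perceptron, and stratified K-fold / leave-one-out
   cross-validation.

## Worked example

```python
from kinegait import calibrated_walk_spec, extract_features, simulate_walk

spec = calibrated_walk_spec(target_sl=0.54, target_gv=0.81,
                            leg_length=0.785, asymmetry=0.004,
                            noise_sd=0.005, seed=42)
recording, truth = simulate_walk(spec)
features = extract_features(recording)
```

Running `python examples/simulate_and_extract.py` (the script above)
prints:

```
segments simulated : 5
steps per segment  : [5, 5, 5, 5, 5]
stride length  : 0.541 m   (truth 0.540)
gait velocity  : 0.809 m/s (truth 0.810)
leg length     : 0.7853 m (truth 0.7850)
L-R asymmetry  : 4.2 mm
```

i.e. under 5 mm sensor noise the pipeline recovers the configured stride
length and gait velocity to a few tenths of a percent and the leg length
to well under a millimetre.  `examples/threshold_classification.py` and
`examples/nn_classification.py` continue from there: on a simulated
36-subject cohort the stride-length threshold rule and the 2-4-2 network
print their optimal cuts, confusion matrices and leave-one-out errors.

The same workflow is available from the shell:

```sh
kinegait simulate --out rec --seed 3 --n-pd 18 --n-norm 18
kinegait extract  --input rec --out features.csv
kinegait classify --features features.csv --out metrics.json --model mlp
kinegait report   --features features.csv --metrics metrics.json
```

## Layout

- `src/kinegait/` — library: `joints`, `skeleton`, `io`, `preprocess`,
  `features`, `classify`, `simulate`, `config`, `cli`
- `examples/` — short narrative scripts, one per capability
- `tests/` — pytest suite (unit, property and acceptance tests)
- `docs/methods.md` — modelling assumptions, parameter choices, and
  limitations
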