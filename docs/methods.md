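# Methods note

This note records the model behind `volcert`'s synthetic generators, the
parameters and their rationale, what the simulation does and does not
emulate, the numerical conventions, and the known limitations. The
package re-implements, in software, a physical certification chain: a
water-displacement device whose pulse patterns are regressed onto object
volume, a 2 % certification rule, and a phantom study quantifying human
manual-segmentation error against the certified device.

## 1. Device model

### 1.1 Marbles and formulations

The reference objects are eight glass marbles with caliper-measured
diameters 24.9, 24.8, 24.1, 24.4, 24.7, 31.3, 35.5 and 48.6 mm; volumes
follow `V = πD³/6` (8.1, 8.0, 7.3, 7.6, 7.9, 16.1, 23.4 and 60.1 ml).
`generate_formulation_set` produces 44 distinct formulations per seed:
the 8 singletons plus rejection-sampled subsets of 2–4 marbles whose
total volume does not exceed the largest single marble (60.1 ml), so the
bench spans 7.3–60.1 ml. The cap keeps the synthetic bench on the same
volume range the recorded bench used; uncapped subsets reach ~138 ml and
inflate absolute MAE roughly proportionally.

### 1.2 Pump

The inter-pulse interval ("time slot") of event `k` follows a descending
exponential toward steady state:

```
ts(k) = steady_run + (start_run − steady_run) · exp(−k / τ)
```

with per-run lognormal-like variation `steady_run = ts_steady·(1 +
steady_rel_std·z)` (clipped at ±4σ) and likewise for the start level.
Observed slots add white Gaussian noise to each TTL *edge* time, so the
noise telescopes: an event's total displacement time carries only two
edges' worth of noise regardless of length, while each individual slot
carries two.

Defaults (all in seconds unless noted), fitted to the nine recorded
single-marble events:

| parameter        | default  | rationale |
| ---------------- | -------- | --------- |
| `ts_start`       | 0.0373   | largest recorded opening slot |
| `ts_steady`      | 0.0305   | recenters the simulated per-event mean slot on the recorded envelope [0.0298, 0.0315] |
| `tau`            | 3.5 slots| matches recorded settling within ~5 slots |
| `steady_rel_std` | 0.018    | relative spread of the nine recorded per-event mean slots |
| `start_rel_std`  | 0.03     | recorded opening-slot spread |
| `jitter_std`     | 0.00038  | edge-timing noise; reproduces recorded per-event slot stds 0.0005–0.0015 |
| `wander_std`     | 0 (off)  | optional AR(1) within-event drift (corr. length 15 slots), not needed to match the record |

`PumpModel.quiet()` returns a noise-free copy; with `flux_exponent = 0`
it realizes the idealized constant-quantum sensor, under which pulse
counts are exactly `round(V / q0)` — this mode backs the exact-count
unit tests (60.1 ml → 445 pulses, 8.1 ml → 60, 0.135 ml → 1).

### 1.3 Flux-dependent sensor quantum

A turbine flow sensor's volume-per-pulse is not constant across flux.
The recorded single-marble events show effective quanta from 0.11 to
0.14 ml/pulse, anti-correlated with the event's mean slot (log–log slope
≈ −3.7, r = −0.83 across nine points). We model

```
q(k) = q0 · (ts_ref / ts(k))^γ,   q0 = 0.135 ml,  ts_ref = 0.0305 s
```

and emit a pulse each time cumulative displaced volume crosses the next
quantum boundary (nearest-cumulative rounding; a request below half a
quantum raises `SensorRangeError`, as does flux outside the sensor's
0.1–3.0 L/min working range).

**Why γ = 1.2, not the raw fit of 3.7.** The nine ratio points carry
±12 % printed volume uncertainty — a constant 0.135 ml/pulse already
explains six of nine rows within those bars, so the slope estimate is
weak. More decisively, a γ as strong as 3.7 is inconsistent with the
certified accuracy the physical chain itself achieved (worst recorded
network MAE 129.99 mm³ = 1.77 % of 7 329 mm³): simulated at γ = 3.7, no
regressor in the bench stays under the 2 % bound. γ = 1.2 preserves the
qualitative physics (counts alone underdetermine volume; calibration
drifts with flux) while keeping the chain certifiable at the recorded
level. γ is an exposed parameter; γ = 0 recovers the ideal sensor and
γ = 3.7 the full-strength fit.

Each `MeasurementEvent` stores its realized `effective_ml_per_pulse`;
volume is conserved to within one *effective* quantum per event. A
"larger volume ⇒ more pulses, longer displacement" monotonicity holds
for a fixed realized pump draw (same seed), not across independent
events — the record itself violates cross-event ordering.

### 1.4 Measurement protocol

`MeasurementCycle` is a four-state machine (EMPTY → FULL → ZEROED →
SUBMERGED) mirroring the physical procedure (fill column, zero the
counter, submerge the formulation, drain). Out-of-order commands raise
`ProtocolError`; draining at zero level is a no-op.

## 2. Features

23 per event: `puc` (pulse count), `ts01…ts20` (first twenty observed
slots), `twd` (total displacement time), `a0f`. Events shorter than 21
pulses cannot fill the slot block and are rejected by
`extract_features` (`build_dataset` warns and drops them rather than
padding — padding would fabricate pump behavior).

`a0f` is the DC component of a 50 %-duty square wave reconstructed from
the pulse times and sampled at 1 kHz with midpoint sampling. For any
near-50 %-duty reconstruction it is ≈ 0.5 with variation in the fourth
decimal; it is retained as a single scalar because the feature list
counts it as one of the 23, not as a spectrum. It carries almost no
information and the regressors treat it accordingly.

## 3. Regression bench

Three *independent random* 70/30 train/test resamples (seeds 11, 23, 42
by default) — not a k-fold partition; the three test sets may overlap.
All five contenders see identical splits. Score: test MAE in mm³.

* **linear** — StandardScaler + OLS.
* **poly2** — degree-2 polynomial expansion (~300 terms) + OLS; on ~31
  training rows this is rank-deficient and overfits by construction,
  which is its documented role as a cautionary baseline.
* **neural_net** — see below.
* **decision_tree** — unlimited depth.
* **random_forest** — 10 estimators.

### 3.1 Network design

Architecture is fixed at 23-12-10-1 (ReLU, ReLU, linear; MSE; Adam,
batch 8, learning rate 1e-3, ≤1500 epochs with plateau patience 100,
L2 α = 1e-2). Three measures adapt it to ~31-row training sets:

1. **Ratio target.** The network predicts the per-pulse calibration
   `y / (q0 · puc)` instead of raw volume; predictions map back through
   the pulse count. This removes the dominant linear trend the tiny MLP
   would otherwise spend its capacity approximating.
2. **Group scaling.** The 20 slot columns are standardized by their
   *pooled* standard deviation. Per-column standardization inflates the
   late, nearly constant slots to unit variance — i.e. it turns ~18
   columns into pure-noise inputs, and a 30-sample MLP memorizes them
   (test MAE ~14 000 mm³ in that configuration).
3. **Committee.** Predictions are averaged over 10 random
   initializations (seeded via `numpy.random.SeedSequence`), damping
   individual interpolation variance.

A zero-variance training target short-circuits to a constant predictor;
a non-finite final loss raises `TrainingError` rather than returning a
silently broken model.

### 3.2 A design target left unmet

The recorded bench reports the network *both* as certifiable (<2 % of
the smallest volume) *and* as the lowest-average-MAE contender, with the
classical baselines failing badly on the real data (linear MAE ~1 684).
Under a generator faithful to the recorded slot statistics these two
properties are jointly unattainable: the recorded per-event mean-slot
envelope caps run-to-run calibration spread at ~1.8 %, which makes the
feature→volume map near-linear, and exact OLS then attains MAE ~50–90
mm³ — below any 30-sample MLP's generalization floor (~80–160 with the
committee). Raising γ to the raw fit (3.7) dethrones the linear model on
some splits but pushes *every* contender above the 2 % bound. We kept
the certifiable regime (the substance of the chain) and left the
"network ranks first" expectation as a deliberately red test in
`tests/test_acceptance.py` rather than weakening either the generator or
the test. The network does rank first among the four nonlinear
contenders on every seed triplet examined. The classical models' real-
data failure modes (unmodeled pump pathologies, sensor nonlinearity
beyond the flux law) are not reconstructible from the published record
alone.

## 4. Certification rule

`certify` compares an error summary — the worst of the supplied errors
(`method="worst"`, default) or their mean (`method="mae"`) — to a
percentage of the reference volume, **strictly** `percent < tolerance`:
the recorded worst case, 129.99 mm³ on 7 329 mm³, prints as exactly
1.77 % and certifies; 2.00 % does not. Percentages are rounded to two
decimals *before* comparison, matching the printed-table convention.
The supplied errors may be per-phantom errors (certifying the worst
case) or a single aggregate MAE; both interpretations are exposed
through `method` and documented at the call site.

Bench report tables floor (truncate), not round, their printed averages
at two decimals — the recorded tables print 1684.8166… as 1684.81 — so
`floor2` is the table-formatting primitive and exact reproduction of the
printed averages from the fold values is a tested property.

## 5. Phantoms and the operator study

### 5.1 Geometry

A subject phantom is a union of two mirrored ellipsoid pairs (an
antero-posterior body and an infero-lateral temporal horn per
hemisphere), shape-jittered ±8 % per seed so subjects are not rescaled
copies, then uniformly scaled so the analytic union volume equals the
target (by default the subject's certified gold volume; the 11 study
subjects span 3.39–115.48 ml). Union volume is exact for disjoint
components and otherwise seeded Monte-Carlo (400 000 samples, fixed seed
→ ~0.3 % relative error, deterministic).

### 5.2 Voxelization and volumetry

Masks are voxel-center tests on a 1 mm grid by default; volume is
foreground-voxel count × voxel volume. An empty voxelization raises
`EmptyMaskError`. Masks round-trip through NIfTI via nibabel; non-binary
images are binarized at 0.5 with a logged warning.

### 5.3 Operator simulation

An operator's segmentation is the truth mask with its boundary moved
through the Euclidean signed-distance transform (positive inside): keep
voxels with `sdt ≥ −offset(slice)`. Per-slice offsets along the viewing
axis are

```
offset = bias + view_factor(view) · jitter · |smooth(g)|
```

where `g` is white Gaussian noise smoothed along slices (Gaussian,
σ = 2 slices) and normalized. The folded (half-normal) form makes slice
errors one-sided toward over-inclusion — ambiguous boundary voxels get
traced in — which produces the recorded signature of harder views being
systematically *larger*, not merely noisier. View factors: axial 1.0,
coronal 1.6, sagittal 2.4. The threshold uses `≥` so that zero bias and
zero jitter reproduce the truth mask exactly.

Four default operators carry biases 0.55/0.80/0.35/0.20 mm and jitters
0.30/0.35/0.25/0.40 mm, chosen so the simulated error tables land on the
recorded magnitudes (sub-ml spread on small subjects, several-ml
over-segmentation on the large hydrocephalus-like subjects). Per-
(operator, view, repeat) seeds derive from a CRC32 of the identifying
tuple, so any cell of the study is reproducible in isolation.

### 5.4 Error analysis

Three experiments per subject, matching the recorded protocol (4
operators × 3 views × 3 repeats):

* **inter-operator** — mean over repeats per operator in the axial view,
  then mean/sd across the 4 operators;
* **inter-view** — per-view means pooled over operators and repeats,
  mean/sd across the 3 views;
* **intra-operator** — per-repeat means pooled across operators,
  mean/sd across the 3 repeats.

Reported errors are unsigned (the recorded summary prints magnitudes);
signed errors are retained in the table since the simulation, like the
record, over-segments almost everywhere. Records with duplicated
(subject, operator, view, repeat) keys or negative volumes are rejected;
subjects missing from the gold table are excluded with a logged warning.

## 6. Numerical conventions

* All stochastic code takes explicit seeds; `numpy.random.default_rng`
  throughout, `SeedSequence` for derived streams. Same seed ⇒
  bit-identical event logs.
* Slot envelopes are clipped to `[max(ts_steady/10, ts_steady − 5σ),
  ts_start + 5σ]` to keep pathological draws physical.
* Monte-Carlo union volume and EDT-based masks are deterministic given
  their seeds/grids.
* `scripts/acceptance.py` derives the device seed and the three split
  seeds from the single `--seed` argument and reports the **median** of
  the three per-split percentages (the certification bound is read as
  "holds in at least two of three runs"). The value is stochastic across
  seeds: typical draws land near 1.3–1.8 %, occasional draws exceed it.

## 7. What is emulated, and what is not

Emulated: the slot-envelope shape and spread of the recorded pump, the
flux-dependence of the sensor quantum, edge-level timing noise, the
measurement protocol, the feature definitions, the bench protocol and
its printed-table arithmetic, the 2 % rule, ventricle-scale phantom
geometry, view-dependent one-sided operator error, and the three error
experiments.

Not emulated: hydraulic transients and bubble artifacts in the water
column, temperature-dependent viscosity, sensor aging, true MR imaging
physics (partial volume, bias field, noise — operator error is applied
to geometry directly), intra-operator learning effects over repeats, and
the specific real-data pathologies that made classical regressors fail
by three orders of magnitude on the physical bench.

## 8. Limitations

* γ (flux exponent) is weakly identified from nine points with ±12 %
  volume uncertainty; the default 1.2 is a consistency argument, not a
  measurement.
* The network's superiority over OLS cannot be reproduced jointly with
  certifiability under this generator (§3.2); one acceptance test is
  intentionally red.
* Operator biases/jitters are calibrated to summary tables, not to raw
  tracings; per-slice error structure is a modeling choice.
* The 44-formulation bench is small; fold MAEs vary by tens of mm³
  across split seeds, and the certification percentage inherits that
  variance.
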