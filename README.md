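# volcert — certifying volumetry with a water-displacement bench

`volcert` is a synthetic, fully reproducible reimplementation of a
volumetry-certification chain built around a water-displacement device.
The original physical setup certifies an MRI-based ventricular-volume
pipeline: glass marbles of caliper-known volume are submerged in a water
column, a peristaltic pump restores the level, and a turbine flow sensor
emits one TTL pulse per displaced quantum of water (nominally 0.135 ml).
The pulse pattern of each measurement is condensed into 23 features, a
small bench of regressors maps features to volume, and the best model is
*certified* if its worst test error stays below 2 % of the smallest
reference volume. The certified device then serves as the gold standard
for quantifying how much human operators over- or under-segment
ventricle-like phantoms on MR images.

Everything physical in that chain is replaced here by tested synthetic
generators, so the statistics can be recomputed from scratch, on any
machine, from a single seed.

## The model in brief

**Device.** A pump's inter-pulse interval ("time slot") decays from a
start value to a steady state, `ts(k) = ts_steady + (ts_start −
ts_steady)·exp(−k/τ)`, with run-level lognormal variation of both levels
and white per-edge timing noise. The flow sensor's volume-per-pulse
follows the instantaneous flux, `q(k) = q0 · (ts_ref / ts(k))^γ`, so the
pulse count alone does not determine volume — which is exactly why a
feature-based regressor is needed.

**Features (23 per event).** `puc` (pulse count), `ts01…ts20` (the first
twenty observed slots), `twd` (total displacement time), and `a0f` (the
DC component of a 50 %-duty square wave reconstructed from the pulses and
sampled at 1 kHz).

**Bench.** Five contenders — ordinary linear regression, degree-2
polynomial regression, a 23-12-10-1 ReLU network (Adam, MSE), an
unlimited decision tree, and a 10-tree random forest — each evaluated by
mean absolute error (MAE, mm³) on three independent random 70/30 splits
of 44 simulated marble formulations spanning 7.3–60.1 ml.

**Certification.** A model is certified when its error is strictly below
2 % of the smallest gold volume (7 329 mm³ for the recorded marble set,
i.e. below 146.6 mm³).

**Operator study.** Lateral-ventricle-like phantoms (mirrored ellipsoid
pairs scaled to gold volumes) are voxelized; a simulated operator shifts
the truth boundary through the signed-distance transform by a personal
bias plus smooth one-sided per-slice noise, amplified in harder viewing
planes (axial < coronal < sagittal). Inter-operator, inter-view and
intra-operator error tables are then computed against the certified gold
volumes.

## Worked example

```python
from volcert import device, features, bench, certification

# 1. simulate the bench: 44 formulations, unstable pump, flux sensor
forms = device.generate_formulation_set(seed=7)
events = device.simulate_measurements(forms, device.PumpModel(seed=7), seed=7)

# 2. extract the 23 features per measurement event
data = features.build_dataset(events)        # X: (44, 23), y in mm^3

# 3. run the five-regressor benchmark (three random 70/30 splits)
result = bench.run_bench(data)
print(result.to_frame(printed=True))         # cells floored at 2 decimals

# 4. apply the 2% certification rule to the network's average MAE
nn_mae = result.average_mae[result.kinds.index("neural_net")]
print(certification.certify(errors=[nn_mae], gold=float(data.y.min())).to_text())
```

Actual output:

```
         linear     poly2  neural_net  decision_tree  random_forest
fold1     86.76  10204.13      111.25         722.84        1076.28
fold2    105.04   7831.94      134.73         221.74        2544.06
fold3     84.17   9664.78      126.78        1318.82        2742.78
Average   91.99   9233.62      124.26         754.47        2121.04
method: worst
worst_abs_error: 124.2607
reference_volume: 7329.0849
percent_of_reference: 1.70
tolerance_pct: 2.00
certified: true
```

A single event looks like this: formulation `F01` (true volume
8 083.4 mm³) produced `puc = 61` pulses, opening slots
`0.0373, 0.0360, 0.0343 s…`, `twd = 1.859 s` and `a0f = 0.4987`.

The operator study runs the same way:

```python
from volcert import phantom, errors

subjects = phantom.make_study_subjects()               # 11 voxelized phantoms
records, gold = phantom.simulate_study(subjects)       # 4 ops x 3 views x 3 reps
table = errors.error_table(records, gold)              # inter-op / inter-view / intra-op
```

which yields, e.g., a mean inter-operator over-segmentation of
+0.49 ml on the smallest subject (3.39 ml gold, 14.5 %) and +4.14 ml on
the largest (115.48 ml, 3.6 %), with inter-view spread roughly double the
inter-operator spread.

Every step is also exposed on the command line via the `volcert` console
script (`simulate-device`, `extract-features`, `bench`, `certify`,
`simulate-study`, `error-report`); each subcommand documents its options
under `--help`.

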