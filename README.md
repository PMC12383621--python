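# peblkit

Blood-loss and fluid-balance prediction from photoplethysmography (PPG)
waveforms.

Hemorrhage is the leading cause of preventable trauma death, and
compensatory mechanisms can mask critical blood loss until conventional
vital signs react. A promising non-invasive alternative is to estimate
**percent estimated blood loss** directly from the optical pulse
waveform a wearable PPG sensor records:

    PEBL(t) = V_hem(t) / V_total,          V_total = 60 mL/kg x weight

and, once resuscitation fluids flow, the net **fluid balance**

    FB(t) = (V_hem - V_wb - V_cr / 3) / V_total

(whole blood counts 1:1, crystalloid by the 3:1 replacement rule;
positive = net loss, negative = net gain).

`peblkit` implements the full study pipeline behind that idea as a
reusable, tested Python library:

* **`peblkit.synthetic`** — a seeded generator of hemorrhage /
  resuscitation cohorts: 500 Hz PPG with a two-lobe pulse template whose
  amplitude, heart rate and dicrotic wave are coupled monotonically to
  PEBL, plus a 0.2 Hz cumulative fluid log (the in-vivo data such
  studies use are not public, so the generator provides controlled,
  recoverable study conditions).
* **`peblkit.ground_truth`** — harmonization of both streams to 100 Hz
  (polyphase FIR decimation, linear volume interpolation), the PEBL and
  FB targets, and truncation to baseline + hemorrhage + hold for
  training.
* **`peblkit.features`** — pulse detection, fiducial points (foot,
  systolic peak, dicrotic notch, diastolic peak) and a frozen 58-feature
  manifest per sampling window (5/10/30/60 s) in five categories:
  morphology, width, derivative, frequency, statistical
  (see `docs/feature_manifest.md`), with optional per-subject 0–1
  normalization.
* **`peblkit.modeling` / `peblkit.tuning`** — XGBoost, random forest,
  elastic net and kernel SVR behind one `fit`/`predict` interface, and a
  Gaussian-process Bayesian tuner (100 iterations, 4 held-out validation
  subjects, RMSE objective) over declared search spaces.
* **`peblkit.evaluation` / `peblkit.stats`** — leave-one-subject-out
  (LOSO) evaluation with R²/MSE/MAE, the staged down-selection
  (window → normalization → tuning, eliminating one architecture per
  stage), the extended fluid-balance phase, and matched nonparametric
  comparisons (Shapiro–Wilk, Wilcoxon, Friedman + Dunn's post hoc,
  alpha = 0.05).

## Worked example

```python
from peblkit import (default_spec, feature_matrices, loso_evaluate,
                     simulate_aligned_cohort)

trunc, full = simulate_aligned_cohort(6, seed=11)      # 6 synthetic subjects
matrix = feature_matrices(trunc, (5,))[5]              # 5 s windows, 58 features
result = loso_evaluate(default_spec("rf", seed=0), matrix)
print(result.per_subject[["subject_id", "r2", "mae"]])
print(f"mean R2 = {result.mean_r2:.3f}")
```

`examples/04_loso_evaluation.py` runs the same evaluation on a compact
6-subject cohort and prints:

```
subject_id     r2    mse    mae  n_windows
    s00_00 0.7393 0.0047 0.0543        124
    s00_01 0.8627 0.0024 0.0387        134
    s00_02 0.9463 0.0009 0.0242        136
    s00_03 0.9376 0.0011 0.0272        127
    s00_04 0.9386 0.0011 0.0259        137
    s00_05 0.8977 0.0018 0.0381        138

mean R2 = 0.887 +/- 0.079 (over 6 blind subjects)
```

Each row is one fully blind subject: the forest never saw that subject's
windows and still recovers its blood-loss fraction from waveform
morphology, which is the recoverability premise the pipeline is built to
test. The scripts in `examples/` walk through each capability —
simulation, ground truth, feature extraction, LOSO evaluation, the
staged down-selection, and the extended fluid-balance phase with the
statistical battery.

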