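# fgl — future-guided learning for time-series forecasting

`fgl` implements **future-guided learning**: a knowledge-distillation scheme
in which a *teacher* model operating in the relative future of a *student* —
either a shorter-horizon forecaster or a direct event detector — transfers its
lower-uncertainty predictive distribution to a long-horizon student. It is
aimed at researchers studying long-horizon forecasting of nonlinear dynamics
(chaotic benchmarks such as Mackey-Glass) and biomedical event forecasting
(seizure-style prediction from multichannel recordings), who want a compact,
fully reproducible CPU-scale testbed for the method.

## The objective

Teacher `T_ϕ` and student `S_θ` both emit `C`-dimensional logits. With `σ` the
softmax, `τ` the distillation temperature and `α ∈ [0, 1]`, the student
minimizes

```
L(θ) = α · L_task(S_θ(x_t), y)  +  (1 − α) · τ² · KL( σ(T_ϕ(x′)/τ) ‖ σ(S_θ(x_t)/τ) )
```

The teacher is pretrained on its near-future task and **frozen**; gradients
flow only through the student. The `τ²` factor keeps the soft term's gradient
scale comparable across temperatures, and the teacher-first KL direction is
mode-covering: the student must spread mass over every class the teacher
considers plausible.

Two instantiations are provided:

* **Regression as binned classification** (Mackey-Glass). Scalar targets are
  quantized into `B` equal-width bins, so teacher (next-step forecaster, input
  window ending at `x_{t+n−1}`) and student (`n`-step forecaster, window ending
  at `x_t`) exchange same-dimensional categorical distributions over the same
  target `x_{t+n}`. Predictions are decoded from the argmax bin (expectation
  decoding is also available) and errors are reported as bin-index MSE.
* **Event forecasting** (synthetic seizure-like recordings). A detection
  teacher (ictal vs interictal, preictal windows excluded from its training)
  supplies softened event probabilities on the prediction student's windows
  (preictal vs interictal), stabilizing a student that sees only a handful of
  events.

## Worked example

Forecast the Mackey-Glass system 5 steps ahead at 25 bins, comparing the
baseline student (task loss only) with two future-guided students:

```python
import numpy as np
from dataclasses import replace
from fgl import (MGParams, integrate_mg, make_windows, split_train_test,
                 fit_bins, RunConfig, DistillConfig)
from fgl.training import (pretrain_teacher, train_student_baseline,
                          train_student_fgl, evaluate_regression)

series = integrate_mg(MGParams(), 3000, seed=1)           # chaotic trajectory
data = make_windows(series, window_len=24, horizon_n=5)   # 5 steps ahead
train, test = split_train_test(data, 0.8)                 # chronological split
codec = fit_bins(train.y, B=25)                           # 25 equal-width bins

mses = {"baseline": [], "fgl_a0": [], "fgl_a05": []}
for seed in (0, 1, 2):
    cfg = RunConfig(horizon_n=5, bins=25, seed=seed,
                    distill=DistillConfig(alpha=0.5, tau=4.0))
    teacher = pretrain_teacher(train, cfg, codec)         # frozen next-step teacher
    ev = lambda pair: evaluate_regression(pair.student, codec, test)["mse_bins"]
    mses["baseline"].append(ev(train_student_baseline(train, cfg, codec)))
    mses["fgl_a05"].append(ev(train_student_fgl(train, teacher, cfg, codec)))
    cfg0 = replace(cfg, distill=DistillConfig(alpha=0.0, tau=4.0))
    mses["fgl_a0"].append(ev(train_student_fgl(train, teacher, cfg0, codec)))

for name, vals in mses.items():
    print(f"{name:9s} test MSE {np.mean(vals):.2f} +- {np.std(vals):.2f} "
          "(bin-index units, 3 seeds)")
```

Output:

```
baseline  test MSE 1.38 +- 0.03 (bin-index units, 3 seeds)
fgl_a0    test MSE 1.08 +- 0.05 (bin-index units, 3 seeds)
fgl_a05   test MSE 0.95 +- 0.02 (bin-index units, 3 seeds)
```

`fgl_a0` trains on the distilled teacher signal alone; `fgl_a05` blends it
with the ground-truth bin labels. Both beat the baseline here, and blending
wins overall — the pattern the full benchmark quantifies across horizons 2-15
and both bin resolutions. An MSE of 1.0 in bin-index units means the argmax
prediction is, on RMS average, one 25th of the signal range away from the
true bin.

A command-line layer mirrors the library (`fgl simulate`, `fgl train-teacher`,
`fgl train-student`, `fgl sweep`, `fgl chain`, `fgl evaluate`,
`fgl benchmark`); every run writes JSON metadata with its config, seed and
parameter checksums.

## Layout

```
src/fgl/
  mackey_glass.py     delay-differential simulator (RK4), window slicing, splits
  bin_codec.py        equal-width binning: scalar <-> categorical
  fgl_core.py         temperature softmax, KL, the distillation objective
  models.py           seeded numpy MLP encoders, freeze contract, optimizers
  training.py         teacher pretraining, baseline/FGL students, alpha sweep,
                      chained multi-horizon distillation
  synthetic_events.py multichannel event recordings (interictal/preictal/ictal),
                      segment labeling, top-k channel selection
  evaluation.py       MSE, percent reduction, AUC-ROC, sensitivity/FPR, tables
  experiments.py      the full regression and event benchmark grids
  cli.py              thin command-line layer
docs/methods.md       model, assumptions, parameter choices, limitations
```
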