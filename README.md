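# hyotrack

Sensor-based tracking of hyoid bone movement during swallowing.

The hyoid bone's superior–anterior excursion during the pharyngeal swallow
drives airway protection and oesophageal opening, and reduced excursion is a
hallmark of dysphagia. The clinical gold standard for measuring it —
videofluoroscopy (VFSS) with frame-by-frame human annotation — involves
radiation and labour. `hyotrack` implements an alternative: regress the
hyoid's 2-D trajectory directly from a tri-axial accelerometer taped to the
anterior neck, using a stacked recurrent neural network (SRNN) trained
against VFSS annotations, and score the tracking with bounding-box overlap
metrics that account for how much human raters disagree with each other.

It is written for researchers in swallowing physiology and biomedical signal
processing who want a complete, testable reference pipeline: signal
conditioning, feature extraction, model, evaluation protocol, and a
synthetic-data generator with exact ground truth.

## Method

**Features.** Neck acceleration (anterior–posterior, superior–inferior,
medial–lateral; 20 kHz) is decimated to 4 kHz, double-integrated to
displacement with the trapezoid rule, and cut into consecutive 133-sample
slices — one per 30 Hz video frame. Each frame t gets a 10-vector

x(t) = [Dis_AP, Dis_SI, Dis_ML, mean_AP, mean_SI, mean_ML,
Var_AP, Var_SI, Var_ML, t]ᵀ,

min–max scaled to [0, 1] with training-set statistics only.

**Targets.** The annotated anterior hyoid point is expressed in a
patient-intrinsic vertebral frame (origin C4, superior axis C4→C2, unit
|C2−C4|), the swallow's starting offset removed
(y(t) ← y(t) − y(0)), and both axes min–max scaled on the training set.

**Model.** An m-layer stacked recurrent network (default m = 4, 64 units):

- h₁(t) = σ(W₁ h₁(t−1) + R x(t) + b₀)
- h_k(t) = σ(W_k h_k(t−1) + V_{k−1} h_{k−1}(t) + b_{k−1}), k = 2…m
- ŷ(t) = U h_m(t) + b_m

with σ = ReLU and h_k(−1) = 0. Each W_k is initialised symmetric
positive-definite with largest eigenvalue exactly 1 (the rest < 1);
R, V_k, U start uniform in [−0.01, 0.01]; biases at 0. Training is
full-sequence backpropagation through time (hand-written numpy), MSE loss,
Adam, early stopping on a validation set, inside participant-grouped 10-fold
cross-validation (70/20/10 train/validation/test; no participant ever spans
two roles in a fold).

**Metrics.** The hyoid body is a 35-px square (49-px diagonal). For boxes
centred on the true and predicted points,

η(t) = max(0, D−|Δx|)·max(0, D−|Δy|)/D² × 100 %, D = 35.

η_M−H scores machine vs one rater; η_H−H pools the same quantity over all
rater pairs and frames — the agreement ceiling set by labelling variability;
ROP(t) = η_M−H(t)/η_H−H × 100 % expresses machine accuracy on the human
scale. Also provided: the ±17 px deviation analysis, angular deviation
histograms, a two-way absolute-agreement ICC, and mean-ROP tables grouped by
stroke history × gender.

**Simulator.** Because no paired accelerometry + annotation dataset is
public, `hyotrack.simulate` generates cohorts with a known forward model:
smooth logistic-bump trajectories (~0.88 s, 30 Hz, 792×1008 px geometry),
sensor displacement affinely tied to the trajectory and differentiated
twice to acceleration (20 kHz), band-limited vibration + white sensor noise,
and per-rater Gaussian annotation jitter. Noise-free signals
double-integrate back to the latent displacement to < 1 % RMS, so every
pipeline stage is checkable against ground truth.

## Worked example

```python
from hyotrack.simulate import SwallowSimConfig, simulate_cohort
from hyotrack.pipeline import run_crossval
from hyotrack.srnn import SRNNConfig

cfg = SwallowSimConfig(rater_jitter_sd=3.0, n_raters=3, seed=0)
cohort = simulate_cohort(12, 2, cfg)          # 12 participants x 2 swallows
report = run_crossval(
    cohort, SRNNConfig(n_layers=2, units=32, max_epochs=150, patience=20),
    k=6, seed=0)
print(f"human-human agreement   eta_H-H = {report.eta_hh:.2f}%")
print(f"machine-human overlap   eta_M-H = {report.overall_mean_eta_mh:.2f}%")
print(f"relative overlap        ROP     = {report.overall_mean_rop:.2f}%")
print(f"frames within +-17 px           = {report.deviation.within_share:.2f}%")
print(report.groups.means.round(2))
```

prints

```
human-human agreement   eta_H-H = 81.86%
machine-human overlap   eta_M-H = 80.15%
relative overlap        ROP     = 97.91%
frames within +-17 px           = 99.68%
         no_stroke  stroke  overall
overall      98.47   96.24    97.91
male         98.57   99.70    98.95
female       98.39   89.31    96.87
```

Raters jittered by 3 px agree with each other 81.9 % of the time; the
network, trained and tested on disjoint participants, overlaps a single
noisy rater 80.2 % — i.e. ROP ≈ 98 %, it tracks the hyoid almost as
consistently as humans track each other. The group table breaks mean ROP
down by stroke history and gender (cells with few swallows are noisy at
this cohort size).

The same pipeline is scriptable from the shell: `hyotrack simulate`,
`preprocess`, `targets`, `train`, `predict`, `evaluate`, `crossval`
(see `hyotrack --help`).

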