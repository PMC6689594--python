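# Methods

This note records the modelling assumptions, parameter choices and numerical
conventions behind `hyotrack`, in the order data flows through the package.

## Signal path and features (`preprocess`)

Raw tri-axial acceleration arrives at 20 kHz. It is decimated to 4 kHz with
a zero-phase FIR low-pass (151 taps, cutoff 0.8× the target Nyquist, i.e.
1.6 kHz) followed by stride-5 subsampling; `filtfilt` keeps the passband
phase-free so displacement timing is not skewed. The intermediate 4 kHz rate
keeps the trapezoid integration accurate while discarding redundant samples.

Displacement is obtained by two cumulative trapezoid integrations with
v(0) = 0, d(0) = 0. Neither initial condition is observable from the sensor;
the error this introduces grows with time, which is acceptable only because
swallows are short (~0.88 s). No detrending or high-pass is applied before
integration by default, for the same reason. Analytic test oracles that need
a non-zero initial velocity (the sinusoid closed form) inject it through the
explicit `v0` parameter.

A 30 Hz video frame spans 4000/30 = 133⅓ samples at 4 kHz; slices are 133
samples, consecutive and non-overlapping, so slicing drifts by ⅓ sample per
frame and a trailing remainder is dropped. Per frame and channel the
features are: the integrated displacement at the slice's **final** sample
(causal — each frame's features summarise the same window), the slice mean,
and the slice **population** variance (divisor n; the convention is
configurable via `var_ddof`, and nothing downstream is sensitive to the
n vs n−1 choice at 133 samples). The tenth feature is the frame time
t = k/30 s.

Feature min–max scaling is computed per feature over **all frames of all
training swallows** (swallows have unequal lengths, so per-time-index
statistics would be ill-defined), applied unclipped to unseen data, and
inverted exactly on non-degenerate features. A constant feature maps to 0
with a warning — this legitimately happens for the medial–lateral channel
of noise-free synthetic cohorts.

## Targets and geometry (`targets`)

Image coordinates follow the video convention: origin top-left, y down. The
vertebral frame has its origin at C4, superior axis v = (C2−C4)/|C2−C4|,
anterior axis u = (v_y, −v_x) — the in-plane perpendicular such that a
patient facing image-left gets positive anterior displacement — and unit
length |C2−C4|. Standardization is applied per frame, so rigid patient
translation and rotation cancel exactly (property-tested). The processing
order is standardize → remove offset → scale; the offset removal anchors
each swallow at the origin so the model predicts movement, not position.

Predictions are mapped back to pixels before any metric is computed:
scaled output → inverse target scaling → re-anchor at the reference
annotation's first-frame standardized position → vertebral frame → pixels.
Evaluation therefore happens in raw image pixels with D = 35 px boxes.

Bounding boxes are axis-aligned squares: the separable overlap formula
(max(0, D−|Δx|)·max(0, D−|Δy|)/D²) requires axis alignment, and with
equal-sized boxes it coincides exactly with the Dice form
2·intersection/(area+area). Negative factors (disjoint boxes) are clamped
to zero. The side 35 comes from round(49/√2) for the 49-px mean hyoid
diagonal.

## Network (`srnn`)

Plain stacked recurrent layers with ReLU, linear readout, h_k(−1) = 0 (the
recurrence needs a pre-sequence state and zero is the only uninformative
choice). The bias indexing is b₀…b_{m−1} into layers 1…m plus an output
bias b_m.

Initialization: each recurrent matrix is built as S = GGᵀ + 10⁻³I with G
i.i.d. standard normal, then divided by its largest eigenvalue — symmetric
positive-definite, top eigenvalue exactly 1, remainder strictly below 1
(generically). This puts the recurrent dynamics at the edge of contraction,
avoiding both exploding and rapidly vanishing states at the start of
training. Input/inter-layer/readout matrices start uniform in [−0.01, 0.01]
so early outputs are near zero; biases start at zero.

Training: full-sequence (untruncated) backpropagation through time —
sequences are ~26 frames, so truncation would buy nothing; one swallow per
gradient step because sequences have unequal length; epochs visit swallows
in seeded shuffled order. "Gradient descent with adaptive learning rate" is
realised as Adam (lr 2·10⁻³ default, β = 0.9/0.999); the optimiser is the
standard per-parameter scheme and is not itself a subject of study. Loss is
MSE over all frames and axes. Early stopping keeps the parameters of the
epoch with minimum validation loss and halts after 20 epochs (default)
without improvement. ReLU gradient at exactly zero is taken as 0; the
finite-difference gradient check uses parameters perturbed away from the
tiny init so no pre-activation sits on the kink.

## Metrics (`evaluate`)

η_H−H with more than two raters averages over all unordered rater pairs per
frame, then pools over frames and swallows weighted by frame count. The
cohort-level mean ROP is reported two ways: mean of per-swallow means within
folds then across folds (the primary number), and a pooled per-frame mean;
both appear in the cross-validation report because the two averaging orders
differ at the second decimal on unbalanced cohorts.

The ±17 px criterion counts per-axis box containment (|Δx| ≤ 17 and
|Δy| ≤ 17); a Euclidean-radius mode exists as an alternative
interpretation. Angles are atan2(Δy, Δx) in image coordinates.

ICC is the two-way, absolute-agreement, average-measures form computed from
the ANOVA mean squares, ICC = (MSR−MSE)/(MSR+(MSC−MSE)/n). What quantity
enters the table is the analyst's choice; the acceptance script rates the
frame-wise superior coordinate (every annotated frame is a subject),
mirroring a frame-by-frame reliability test. Reliability statistics on
per-swallow summary measures are also possible but, in a homogeneous
simulated cohort, mostly measure the (deliberately small) between-swallow
variance rather than rater noise.

## Protocol (`pipeline`)

Participants are greedily packed into k swallow-count-balanced groups
(visited in seeded random order, heaviest first, each joining the lightest
group). Fold i tests group i, validates groups (i+1, i+2) mod k and trains
the rest — a deterministic rotation realising the 70/20/10 ratio at k = 10
on a balanced cohort. Feature normalizer and target scaler are fitted inside
each fold on its training swallows only; the per-fold normalizer minima are
retained in the report so leakage is testable. Feature sequences can exceed
the annotation frame count by one frame (133 vs 133⅓ samples per frame);
both streams are truncated to the common minimum when paired.

## Simulator (`simulate`)

What it emulates: ~0.88 ± 0.12 s swallows (rejection-sampled to span > 2
frames), 30 Hz annotation on 792×1008 px frames, 20 kHz signals, a hyoid
trajectory that rises superior-anteriorly and returns to its start
(logistic rise/fall bump per axis, the superior bump leading the anterior
by 80 ms), per-participant vertebral geometry (|C2−C4| ≈ 120 ± 4 px, small
tilt), and multi-rater labelling noise (i.i.d. Gaussian, rounded to integer
pixels). Peak excursion defaults to (25, 40) px (anterior, superior) —
roughly 1 cm anterior and 1.5 cm superior at this image scale — with mild
per-participant (σ = 3 %) and per-swallow (±5 %) variation. Cohort labels
default to 57.0 % male and 18.4 % stroke history.

The sensor forward model ties the latent displacement of each channel
affinely to the hyoid trajectory (gain 10⁻³ units/px), interpolates the
frame-rate trajectory with a clamped cubic spline (zero end velocity — the
same convention the integrator assumes, which is what makes the zero-noise
round trip exact to < 1 % RMS), differentiates twice analytically, and adds
band-limited vibration (Butterworth 50–500 Hz band, RMS set by
`vibration_snr`, default 10) plus white sensor noise (SD 0.05 acceleration
units). The spectral content of real swallow vibrations is not
characterised in the literature this models; these noise defaults are
placeholders exposed in the config, and the medial–lateral channel carries
noise only. An optional constant gravity bias on the A–P channel is off by
default.

What it does **not** emulate: bolus-consistency and volume effects,
sensor-skin coupling artefacts, device noise structure, patient motion
beyond rigid per-frame landmark geometry, swallow-segmentation errors, or
any nonlinear signal-trajectory relationship. Passing the end-to-end
recovery test therefore shows the pipeline is correct and the model can
learn an affine signal-kinematics tie from realistic geometry — not that
real accelerometry carries equivalent information.

## Calibrations and problem sizes

The rater-jitter level used for the human-agreement regime is derived in
closed form, not fitted: with per-axis label noise σ the difference of two
raters is N(0, 2σ²), E|Δ| = 2σ/√π, and the separable overlap factorises to
approximately (1 − E|Δ|/35)², which equals 0.79 at σ ≈ 3.45 px. Measured
pooled η_H−H at that σ is 79.0–79.2 %.

The built-in experiments use 20 participants × 3 swallows with a 2-layer,
32-unit network (300 epochs max, patience 30) under 10-fold grouped
cross-validation — sizes chosen so a full run completes in about two
minutes on one CPU while still exercising every stage at cohort scale.
Held-out tracking on the noise-free cohort reaches mean η_M−H ≈ 93–95 %;
with jittered raters, mean ROP ≈ 97 %.

## Known limitations

- The SRNN is plain-ReLU recurrence; no gating, no hyperparameter search.
- Double integration drifts on signals longer than a few seconds; the
  pipeline is only valid for short segmented swallows.
- `run_crossval` trains one model per fold and does not ensemble.
- The simulator's affine signal-trajectory tie makes the regression
  problem easier than physiological reality; treat absolute overlap
  numbers from synthetic cohorts as upper bounds.
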