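# Methods

This note records the modelling choices behind `cardiolead`: the
network and its analytics, the data preparation and augmentation
conventions, what the synthetic generator does and does not emulate,
and the numerical decisions a maintainer would want to know.

## The network

The model is a compact convolutional classifier mapping an L x W input
(L leads, W samples at 100 Hz) to 20 independent sigmoid scores, one
per diagnostic subclass.  All convolutions use valid padding; the lead
axis is treated as a spatial dimension of height L that is never mixed
until the final fully connected layer.

Layer by layer: a stem convolution with a single 1x1 filter (a scalar
affine map applied to every sample, shared across leads); six blocks of
[1xk convolution with dilation 2 → batch normalization → ReLU → 1x2
temporal max-pool], with kernels 5,5,5,3,3,3 and output channels
16,16,32,32,64,64; a per-lead 1x1 convolution with 128 filters and a
ReLU; and a dense layer from the concatenated L x 128 features to the
20 outputs.

Three analytic quantities are exposed as closed forms and must agree
with the built network (tests enforce both):

- **Receptive field.** Accumulating over layers — each valid dilated
  convolution adds (k_eff − 1)·jump with k_eff = d·(k − 1) + 1, each
  pool adds jump and doubles it — gives 344 samples for the default
  kernels.  344 samples at 100 Hz is 3.44 s of ECG, the amount of
  signal the model needs to emit a diagnosis.
- **Output length.** Iterating t ← ⌊(t − (k_eff − 1))/2⌋ over the six
  blocks maps width 344 to exactly one temporal position, so 344 is
  also the minimal valid input width and is used as the crop width.
- **Parameter count.** 2 (stem) + Σᵢ(kᵢ·cᵢ₋₁·cᵢ + cᵢ) + Σᵢ2cᵢ
  (batch-norm scale/shift; running statistics are not counted) +
  (64·128 + 128) + (128·L·20 + 20): 36,998 at L=1, 54,918 at L=8,
  65,158 at L=12.

**Lead-fusion placement.** Two designs are implemented.  The default
applies the 128-filter 1x1 convolution *per lead* and fuses leads only
at the output layer; this is the only reading consistent with a
sub-100,000-parameter 12-lead model.  A lead-spanning variant
(`fusion="spanning"`), in which the 128-unit projection consumes the
concatenated 64·L features, is available behind a config switch; it
costs 127,110 parameters at L=12.  No single design reproduces all of
the approximate parameter counts quoted in prior descriptions of this
family of models (≈36k/56k/96k for L=1/8/12); both variants' exact
counts are stated here instead.

**Other architectural choices.** Activations after each batch
normalization and after the 128-filter layer are ReLUs.  The stem's
single 1x1 filter is implemented as a per-sample scalar affine shared
across leads, preserving the later guarantee that no lead information
mixes before fusion.  Batch normalization uses momentum 0.9 and
eps 1e-5; pooling drops an odd trailing sample.  Weights use He-normal
initialization from a seeded generator.

**Implementation.** The layers (convolution via per-tap batched
matmuls, batch norm, ReLU, max-pool, dense) implement their own
forward and backward passes on NumPy arrays in single precision, with
Adam (β₁=0.9, β₂=0.999, eps=1e-8) as the optimizer.  The lead axis is
folded into the batch axis through the per-lead sections, so batch-norm
statistics pool over records, leads and time, exactly as a 2-D
convolutional implementation with 1xk kernels would.  Gradients are
verified against central finite differences in the test suite's
development history and indirectly by the capacity checks.

## Data preparation

Records are represented at 100 Hz (10 s → 1,000 samples per lead).
When the source is 500 Hz, decimation uses a polyphase FIR with
mean-padding at the edges, which passes DC exactly; the PTB-XL path
reads the released pre-decimated 100 Hz files instead of re-decimating.

Each lead is z-scored with the mean and standard deviation pooled over
*all samples of all training-split records* — split-level statistics,
not per-record — and the same statistics transform validation and test
records.  Statistics are computed on the 100 Hz representation the
network consumes.  A 1e-8 floor on the standard deviation keeps
degenerate (constant) leads finite.

Label aggregation maps SCP statement codes to the 20 diagnostic
subclasses; codes mapping elsewhere (rhythm/form statements, subclasses
such as PMI or RVH) are ignored.  A record is removed when (i) NORM
co-occurs with a pathological class, (ii) no class remains after
aggregation — which also covers records whose only diagnoses fall
outside the 20 subclasses — or (iii) any statement mapping into the 20
classes carries likelihood exactly 0.  Zero-likelihood statements
*outside* the 20 classes do not trigger rule (iii).  Folds 1–8 train,
9 validation, 10 test.

## Augmentation

Four transforms, applied per record per epoch in the order noise →
time-scale → amplitude → crop (the order is a convention; cropping last
guarantees the exact window width):

| transform | draw | note |
|---|---|---|
| Gaussian noise | σ ~ U[0.01, 0.1] mV | one σ per record (a per-lead option exists); noise i.i.d. per sample |
| time scale | factor ~ U[0.8, 1.2] | linear interpolation, endpoints map to endpoints, length rounds to nearest integer |
| amplitude | factor ~ U[0.7, 1.3] | one factor for all samples and leads |
| crop | start ~ U{0..T−W} | same window across leads; W queried from the network's receptive field, never hard-coded |

Only the crop applies at evaluation time; its position is a
deterministic draw keyed on (seed, record id), so reports are
reproducible record by record (a center-crop option exists).  With a
fixed seed the full pipeline is bit-reproducible.

## Training protocol

Sum of 20 binary cross-entropies, averaged over the batch; scores are
clamped at 1e-7 from the boundaries only where a log would diverge, so
exact predictions contribute exactly zero loss.  The learning rate
decays linearly *per epoch* from 1e-2 to 1e-4 with denominator
(epochs − 1), so both endpoints are attained exactly.  Batch size 32,
200 epochs, 50 seeded runs in the full-scale protocol.  Test scores
come from the final-epoch weights; the per-epoch validation macro AUC
is logged and a best-validation-epoch selection option exists, but no
early stopping is applied by default since the protocol defines a
validation fold without a selection rule.  A non-finite loss aborts the
run with a diagnostic.  Under a fixed seed and single-threaded BLAS,
training is bit-reproducible; otherwise the contract relaxes to
trace-equality.

## Evaluation

Per-class AUC is the Mann–Whitney probability (ties at 1/2), reported
on the percent scale; the macro AUC is the unweighted mean over classes
that have both a positive and a negative on the split (others are
excluded with a warning).  Confidence intervals over runs use the
normal approximation mean ± 1.96·sd/√n (sd with n−1 denominator); a
percentile bootstrap is available.  Operating points maximize Youden's
J = sensitivity + specificity − 1 over ROC thresholds, ties broken by
higher sensitivity then lower threshold.  Setups are compared by
relative percentage difference 100·(value − reference)/reference of
mean AUCs, reported to one decimal; because the difference of macro
means and the mean of per-class differences need not coincide, the
comparison table records both.

## Synthetic data generator

The generator exists so that every pipeline branch — including lead
ablations — is exercisable without downloads.  Each record is a
Gaussian-pulse dipole model: every beat is a sum of P, Q, R, S, T
pulses, each with an amplitude, width and fixed 3-D direction, repeated
at a heart rate drawn from U[50, 90] bpm; the 12 leads are dot products
of the dipole with fixed axes.  The limb-lead axes are built as the
exact linear combinations of the D1 and D2 axes, so the
Einthoven/Goldberger identities hold to machine precision on noise-free
output — this doubles as the oracle for `derive_dependent_leads`.
Per-lead sensor noise (default sd 0.01 mV) is added after projection.

Pathology classes perturb beat parameters: AV block draws PR from
0.24–0.32 s (normal 0.12–0.20 s); bundle branch blocks widen the QRS to
0.13–0.16 s (normal 0.08–0.10 s) and rotate its axis; LVH scales
amplitudes by 1.5–2.5x; infarction/ischemia classes add Q- and T-wave
deflections along the affected wall's axis — *inferior* classes (IMI,
ISCI) along +y, which is orthogonal to the D1 axis, so their signature
is invisible in D1 and strong in D2, reproducing the qualitative
failure mode that motivates two-lead setups.  AMI deflects along the
anterior axis (dominant in V2–V4), LMI along the lateral axis.  The
remaining classes alias to mild amplitude/interval perturbations
sufficient for smoke tests; they are not morphologically faithful.

Class priors are marginal; NORM is mutually exclusive with pathology
(mirroring filter rule (i)), pathological labels are drawn
independently given non-NORM and redrawn if empty, so NORM's frequency
matches its prior exactly and pathology frequencies are mildly inflated
by the at-least-one-label condition.  Default priors (NORM 0.40, CLBBB
0.10, CRBBB 0.08, _AVB 0.10, IMI 0.12, AMI 0.10, LVH 0.12, LMI 0.08)
cover the morphologically distinct classes.  Records carry a uniform
pseudo-fold in 1..10, and datasets can be exported as WFDB format-16
records with a metadata manifest in the PTB-XL layout, so the PTB-XL
reader round-trips them.

**What passing tests show and do not show.** The generator's records
are periodic, noise-stationary and free of baseline wander, electrode
artifacts, rhythm disturbances and inter-beat variability; its class
signatures are cleaner and more geometrically ideal than clinical ECGs.
Tests on it demonstrate that the pipeline is correct (shapes,
identities, determinism, learnability, the direction of lead-ablation
effects), not that the model attains clinical-grade AUCs — for that the
real PTB-XL corpus and the full training budget are required.

## Desk-scale test sizes

The test suite trains at deliberately small sizes chosen to demonstrate
each property: a capacity check memorizes 8 records in 50 epochs with
the stochastic transforms off (crop only — a capacity check against a
moving target would conflate memorization with invariance learning); a
separability check trains 12-lead on 500 records of three
well-separated classes (NORM/CLBBB/LVH) for 20 epochs; the
lead-ablation check trains D1 and D1+D2 on 240 NORM/IMI records for 15
epochs across three seeds.  The default harness plan (3 runs, 20
epochs, synthetic data) completes an ablation in minutes on one CPU;
full-scale reproduction keeps the same code paths with
`ExperimentPlan(n_runs=50, epochs=200, ...)`.

## Known limitations

- The trainer is CPU NumPy: fine at desk scale, slow at the full
  21k-record, 200-epoch protocol (multi-day on one core).
- WFDB support covers format 16 with a single multiplexed signal file —
  the subset PTB-XL uses — not the full WFDB specification.
- Evaluation-time cropping scores one window per record; multi-window
  averaging is not implemented.
- The spanning-fusion variant is provided for completeness but is not
  the default and is not covered by the lightweight (<100k) guarantee.
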