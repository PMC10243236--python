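# Methods

## The training process

`roidistill` implements a three-stage, human-guided knowledge-distillation
pipeline for image classification with expert-annotated training data.
Every training image exists in two variants: the *raw* image and an *ROI*
image — the same pixels with an expert's freehand outline of the lesion
drawn in one shared color (identical for every disease class, so the
annotation conveys localization, never the label) plus an outline of the
organ in a second color.

**Stage 1 (teacher).** A classifier `f_t` is trained on ROI images with
cross-entropy. Because the annotation points directly at the diagnostically
relevant region, the teacher converges quickly; its weights are then frozen.
The teacher cannot be deployed on raw images — it learns to rely on the
annotations.

**Stage 2 (teacher–student).** A student `f_s` with the same architecture
is trained on raw images under a combined loss

    L_C = α_e · MSE(f_t^(-1)(x_ROI), f_s^(-1)(x_raw))
        + (1 − α_e) · CE(f_s(x_raw), Y)

where `f^(-1)` denotes the post-activation output of the last convolutional
block, the MSE is the global mean over batch, channel and spatial axes, and
the CE is the batch mean. The weight decays linearly per epoch:

    α_e = ½ · (1 − e / E_distill)  for e < E_distill,  else 0.

Both members of a raw/ROI pair are augmented with the *identical* sampled
parameters (spatial and photometric) so the two feature maps stay
spatially comparable — the central correctness requirement of the whole
pipeline. Teacher activations are constants: no gradient reaches the
teacher, and epochs at or beyond `E_distill` never evaluate it.

**Stage 3 (fine-tuning).** The tail of the same run with α = 0: plain CE
on raw images. The final student is an ordinary raw-image classifier.

A *baseline* with identical architecture, hyperparameters and epoch budget,
trained end-to-end on raw images, is the comparison arm. Model selection
everywhere is the epoch with the lowest validation loss (earliest on ties);
for students the CE component only is used, computed on raw validation
images — the consistency term depends on α_e and would make epochs
incomparable. α is updated per epoch, not per step: every batch within an
epoch uses the same weight.

## Data handling

- **Patient-level split.** Validation is a random subject-based holdout
  (≈20 % of images): no patient contributes to both sides. Assignment is a
  seeded greedy pass over shuffled patients followed by local toggle
  refinement, minimizing the deviation of the achieved image fraction from
  the target plus the mean per-class share deviation — a best effort at
  stratification under the non-overlap constraint.
- **Preprocessing.** Bilinear resize to the target resolution and
  channelwise normalization with the ImageNet mean (0.485, 0.456, 0.406)
  and std (0.229, 0.224, 0.225). The constants are kept even for synthetic
  data so the pipeline is identical to the one used with pretrained
  backbones.
- **Augmentation.** Two pipelines. *Weak*: resize; shift/scale with
  shift_limit 0.1, scale_limit 0.5 and **zero rotation**; normalize.
  *Strong*: additionally, each with probability 0.9, exactly one of
  {CLAHE (clip 4, 8×8 tiles), brightness/contrast ±0.2, gamma 0.8–1.2},
  one of {sharpen (α 0.2–0.5, lightness 0.5–1.0), box blur ≤7,
  motion blur ≤7}, and one of {brightness/contrast, HSV shift (±20°,
  ±30/255, ±20/255)}. The affine warp is implemented as a separable
  axis-aligned bilinear resample (valid because rotation is never used)
  with reflect-101 border handling. Four standard configurations pair these
  pipelines with dropout: (1) dropout+strong, (2) strong, (3) dropout+weak,
  (4) weak; teachers always keep dropout.

## Models

`tiny_reference` is a from-scratch CPU-scale CNN: a parameter-free 2×2
average-pool stem, four 3×3 conv blocks of widths (8, 16, 32, 32) with
strides (2, 2, 1, 1), each followed by GroupNorm and ReLU; then global
average pooling, optional dropout (p = 0.5) directly before the linear
classification head. At 64×64 input the last conv block yields a 32×8×8
feature map — the tensor used both for the consistency loss and for
Grad-CAM. GroupNorm is used instead of batch normalization because training
runs at batch size 8 under heavy scale augmentation: batch statistics are
then so variable that eval-time running averages drift, whereas per-sample
group statistics make train and eval behavior identical and runs exactly
repeatable. Teacher and student must produce identical feature-map shapes;
a mismatch is a hard error (no projection adapter).

Names of standard pretrained backbones (ResNet50, EfficientNet-B0/B1,
ConvNeXt-T/S) are accepted in configurations for completeness, but this
package ships no pretrained weights, and requesting such an architecture
raises an explicit error rather than silently training from random
initialization.

Optimization is Adam (β₁ = 0.9, β₂ = 0.999) with per-epoch cosine decay of
the learning rate to zero over the stage's epoch budget, batch size 8.
`TrainConfig` defaults to the full-scale protocol (base LR 1e-4, 60 epochs
for baseline/student with `E_distill` = 40, 20 for teachers). The synthetic
benchmark harness uses base LR 2e-3, appropriate for from-scratch tiny
networks rather than pretrained-backbone fine-tuning.

## The synthetic benchmark

Real paired CXR datasets with freehand expert annotations are not publicly
available, so the package generates one with the same statistical
structure: ~1,880 images (940 patients, some contributing several images,
as in a 1082-images / 828-patients cohort), 64×64 px, five classes with
priors (62.2 % healthy, 9.2 % bacterial, 11.6 % fungal, 6.8 % viral,
10.2 % covid) matching the study-like label distribution, and a
subject-level split.

Each image contains: a patient-specific bright elliptical "organ" on a
darker background; for disease classes one elliptical lesion inside the
organ carrying a class-specific procedural texture (dots / stripes / blobs
/ speckle, each with a subtle class-specific color tint standing in for
the spectral signature of different opacification patterns); and several
distractor patches carrying *random* classes' textures at the same
amplitude, scattered anywhere in the frame. The only raw-visible cue
separating the true lesion from a distractor is a faint (+0.04 luminance)
inflammation halo around it. The ROI variant adds the lesion outline
(3 px, one shared color) and the organ outline (second color).

This construction plants exactly the epistemic situation the method
targets: the expert annotation is the *fast* route to knowing which patch
matters (the teacher exploits it within a few epochs), while a raw-only
learner must discover the subtle halo cue through slow cross-entropy
credit assignment. Distillation transfers the teacher's localization
knowledge through the feature-map consistency term, because the best
raw-computable approximation of the teacher's ring-gated features is a
halo-gated feature. The class tint makes the class-conditional features
fast-learnable from scratch, playing the role that ImageNet-pretrained
filters play at full scale (reproducing pretraining itself is out of
scope).

What the generator does **not** emulate: radiographic anatomy and
projection physics, AP/PA view differences (a view column is generated for
realism but unused), annotation noise or inter-rater variability, and
label noise. Passing benchmarks therefore demonstrate that the pipeline's
machinery works and that its directional claims hold when the planted
signal exists — not that comparable gains would appear on any particular
clinical dataset.

Two information-content audits guard the construction: a classifier
trained on (ROI − raw) difference images must stay near chance on disease
classes (the annotation itself leaks no label), and blanking the lesion
region must cost a trained classifier accuracy (the signal truly lives in
the lesion). `audit_label_leak` additionally checks, on any paired
dataset, that stroke colors do not differ by class and that stroke pixel
counts do not separate any pair of disease classes by more than a
standardized mean difference of 1.0 — the failure mode that makes
bounding-box-style annotations unusable for this method.

## Benchmark protocol and desk-scale budgets

The packaged experiment trains, per seed: the ROI teacher and a raw-image
ablation teacher (8 epochs each), the baseline and both student variants
(20 epochs, `E_distill` = 12). Five seeded repeats are summarized as
mean ± std accuracy and student-minus-baseline improvement in percentage
points. These budgets preserve the full-scale protocol's ratios (teacher
1:3 of student epochs; two thirds of student epochs guided) at sizes a
single CPU handles; one five-seed, five-arm run takes ≈12 minutes.

With partial annotations (the reduced-ROI experiment at fractions 0.1 /
0.3 / 0.5 / 1.0), the teacher trains on the sampled annotated subset, and
stage-2 batches mix annotated and unannotated samples: the consistency
term is restricted to annotated members while CE covers all — keeping
every image in training.

## Numerical and implementation notes

- All tensor math is float32 numpy; convolution is im2col + BLAS matmul
  with an explicit adjoint for the backward pass. A fixture-sized hand
  convolution and finite differences pin the gradients in the test suite.
- One integer seed per run drives splits, shuffling, augmentation draws,
  initialization and dropout; identical seeds give bitwise-identical
  weights single-threaded.
- Softmax/CE uses the max-subtracted fused form (stable to |logit| ≈ 100);
  CE gradients and the MSE gradient 2(f_s − f_t)/N flow only through
  student quantities.
- Grad-CAM hooks the same last conv block as the distillation loss;
  channel weights are spatially averaged gradients of the target logit,
  the map is rectified, bilinearly upsampled and per-image max-normalized
  (all-zero maps stay zero). Attribution/ROI agreement is summarized as
  the fraction of heatmap mass inside the expert lesion mask — a scalar
  operationalization chosen here; the zero-division convention is 0 for an
  empty mask.
- Per-class precision/recall with zero denominators are reported as 0 and
  the affected classes flagged, matching the regime where minority classes
  receive no predictions at all.
- Degenerate inputs fail loudly: a single-patient dataset cannot be split;
  `E_distill` = 0 is rejected (a schedule with no guided epochs is the
  baseline — the student trainer accepts `teacher=None` for exactly that
  path); mismatched pair sizes, unknown labels and out-of-range α raise
  descriptive errors.

## Known limitations

- Only `tiny_reference` is runnable; conclusions about large pretrained
  backbones cannot be drawn from this package alone.
- The benchmark's effect sizes (a few percentage points, seed std of
  similar magnitude) mirror the full-scale regime, so single-seed
  comparisons are noise; all directional claims are 5-seed means.
- The ROI-teacher-vs-raw-teacher comparison is the tightest margin: a
  frozen raw teacher still regularizes the student (an effect the
  raw-teacher ablation is designed to isolate), so the ROI advantage,
  while present in the mean, is within one seed-std on some seeds — as in
  the full-scale study, where one architecture showed the reversed sign.
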