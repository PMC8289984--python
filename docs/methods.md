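# Methods

## Model

The detector is an auto-encoding GAN: encoder, generator, image
discriminator, and code discriminator. The encoder and generator form an
autoencoder; the two discriminators supply adversarial pressure. The code
discriminator distinguishes standard-Gaussian prior draws from encoder
outputs, which drives the latent distribution of *training* (normal) images
toward N(0, I) without a closed-form KL term; consequently the encoder is
deterministic and both anomaly scores are deterministic functions of the
input.

Architecture (working resolution R, a power of two ≥ 4):

- channel schedule `channels(r) = min(512, 8·R/r)`, i.e. 8 channels at the
  working resolution doubling at each halving down to 4×4, capped at 512;
- generator: linear 128 → 4·4·channels(4), then per doubling a nearest-
  neighbor ×2 upsampling followed by one 3×3 convolution (leaky-ReLU,
  slope 0.2), and a final 1×1 convolution with tanh;
- encoder: the mirror — 1×1 convolution in, per resolution one 3×3
  convolution then 2×2 average-pool, a final linear map to the 128-D code;
- discriminator: the encoder trunk with a 1-D linear output (bare logit);
- code discriminator: 128 → 1500 (leaky-ReLU) → 1.

There are no normalization layers, and none of the equalized-learning-rate /
minibatch-stddev tricks of the progressive-growing literature — only the
fade-in schedule itself. "Same" zero padding keeps the printed shapes exact.
Weights are He-initialized (adjusted for the leaky-ReLU slope), biases zero.

## Losses and optimization

For a batch x of normal images, prior draws z ~ N(0, I), reconstructions
x̂ = Gen(Enc(x)) and samples x̃ = Gen(z), with σ the logistic function and
all classification terms binary logistic (numerically stable
softplus form):

- discriminator: −log σ(D(x)) − log(1−σ(D(x̂))) − log(1−σ(D(x̃)));
- code discriminator: −log σ(C(z)) − log(1−σ(C(Enc(x))));
- encoder+generator (one joint objective, minimized together):
  λ_rec · mean|x − x̂| − log σ(D(x̂)) − log σ(D(x̃)) − log σ(C(Enc(x))).

λ_rec defaults to 1 with the reconstruction term as a *mean* over pixels
(the anomaly score itself is the unnormalized sum; the mean keeps the loss
weight independent of resolution during progressive growth). The
non-saturating −log σ form is used for the encoder/generator adversarial
terms; the linear-in-logit density-ratio form was tried and destabilized
reconstruction at the small problem sizes this package targets.

Per batch, one shared forward pass produces all losses; the critics see
detached fakes and codes, so the three losses occupy disjoint subgraphs and
are backpropagated independently (the joint encoder+generator gradient that
passes through critic parameters is discarded), after which the three Adam
optimizers (α = 5·10⁻⁴, β₁ = 0.5, β₂ = 0.9) step in the order
discriminator, code discriminator, encoder+generator. All gradients are
taken at the pre-update parameters. Batch size defaults to 10. Non-finite
losses raise a divergence error with epoch/batch context.

## Progressive schedule and model selection

Epoch 1 trains at 4×4 (only the linear pathway and the 4×4 heads are
active). Each subsequent doubling takes two epochs: a fade epoch in which the
new stage's image-space blend weight ramps linearly over the epoch's batches
from 0 to 1 (at 0 the grown generator reproduces a nearest-neighbor
upsampling of its pre-grow output exactly), then a stabilization epoch at
blend 1. After the working resolution is reached, all remaining epochs train
there; for R = 256 the resolution ladder completes at epoch 13. Real images
are resampled to the phase resolution with the same Lanczos (a = 3) operator
used in preprocessing.

The model is checkpointed every epoch and scored by code-norm AUROC on the
validation set (Normal vs all abnormal). The selected checkpoint is the
argmax over epochs **after the growth curriculum has completed** (final
resolution, past its stabilization epoch), earliest epoch on ties. The gate
matters in practice: the epoch immediately after the final grow can post a
high validation code-norm AUROC while its reconstructions are still poor,
and the low-resolution phases are curriculum stages, not candidate models.

## Data protocol

Images are loaded at native bit depth, resampled square-to-square by
Pillow's Lanczos filter, and mapped affinely from the format's bit-depth
range onto [−1, 1]. Normalization never uses per-image statistics: a
globally inverted or uniformly over-exposed image must stay anomalous after
preprocessing.

Splitting: floor(70%) of Normal records are sampled (without replacement)
for training; the remaining records are split 1:2 into validation and test,
stratified within the leftover Normal group and within the pooled abnormal
group, validation receiving floor(group/3) of each. Pooling the abnormal
classes (rather than stratifying per label) is what reproduces the reference
breakdown exactly (6,853 train; 979/1,958 Normal and 6,631/13,263 abnormal
in validation/test from 9,790 + 19,894 records). Monte-Carlo
cross-validation derives one seed per repeat from a master seed
(`numpy.random.SeedSequence`); AUROCs across repeats are summarized by the
mean and a Student-t 95% interval, mean ± t₀.₉₇₅,ₙ₋₁·s/√n. The t construction
over repeats is a documented choice; a normal or percentile interval would
also have been defensible.

## ROC conventions

AUROC is the trapezoidal area over the full threshold sweep, identical to
the Mann–Whitney pairwise probability with ties counted half (verified
against a brute-force oracle to 1e−12). Class-restricted curves *exclude*
the other abnormal class rather than relabel it. Sensitivity at a target
false-positive rate interpolates linearly along the curve — tied scores thus
contribute diagonal segments (an all-ties score gives TPR = FPR) — taking
the upper TPR at vertical jumps.

## Synthetic phantoms

The fixture generator emulates the *structure* of a frontal chest
radiograph, not its appearance: a dark background (−0.85), two soft-edged
bright elliptical lung fields (intensity ≈ 0.55, semi-axes ≈ 0.16/0.27 of
the side), a brighter central mediastinal band, per-seed jitter of ±2% of
the side on positions and ±10% relative on sizes/intensities, and white
pixel noise (σ = 0.02). All pixels are clipped to [−1, 1] and every phantom
is a bit-identical function of (resolution, seed, anomaly kind, parameters).

Anomalies are applied to the normal phantom generated from the same seed:

| kind | transform | label | mask |
|---|---|---|---|
| focal_blob | truncated-Gaussian bright mass, radius 0.12 of the side, intensity 1.2 (saturating), placed inside a lung field | Opacity | yes |
| basal_fill | +0.55 over the basal 40% of both lung fields | Opacity | yes |
| central_enlargement | mediastinal band widened ×1.6 | NoOpacityNotNormal | yes |
| lr_flip / inversion / rotation | exact mirror / negation / right-angle rotation | NoOpacityNotNormal | — |

The focal mass is sized as a conspicuous lesion (diameter ≈ 24% of the image
side, several cm at radiograph scale) — the bulky kind of finding the code
norm score is sensitive to; its additive bump is truncated at the mask
radius so the ground-truth mask contains the entire difference. What the
phantoms do **not** capture: anatomical texture (ribs, vasculature),
exposure and positioning variability, patient habitus, and the long tail of
real abnormality — so green tests here demonstrate that the machinery works
end to end at desk scale, not clinical performance.

## Study sizes

The packaged efficacy study trains at 32×32 on 200 normal phantoms for 50
epochs (the full protocol's epoch count) with a validation set of 30 normal
+ 30 Opacity phantoms, and evaluates on a fixed held-out set of 50 normal +
50 focal-mass phantoms; resolution and sample counts are scaled down from
the clinical protocol so a run takes ~2 minutes on one CPU. At this scale
the code-norm score is the harder of the two: the encoder's code
distribution only gradually approaches the Gaussian prior, and an occasional
seed ends its session with the two scores' rankings still unstable —
the cross-seed acceptance condition tolerates one such seed in five.

## Numerical engine

The networks run on a purpose-built NumPy reverse-mode autodiff engine
(`anodet.nn`): dynamically recorded graphs, topological backward sweep,
float32 parameters. Convolutions are stride-1 with symmetric padding,
evaluated as a single GEMM over a cached channels-leading column buffer; the
input gradient is itself a convolution with the spatially flipped,
channel-transposed kernel. Correctness of every operation's gradient is
pinned by central-difference tests at 1e−7 tolerance in float64.

## Known limitations

- CPU-only and desk-scale; no multi-device execution or mixed precision.
- Phantom realism as above; per-disease evaluation is impossible on
  phantoms beyond the injected taxonomy.
- Rotation anomalies are restricted to right angles to keep fixtures exactly
  deterministic (no interpolation).
- DICOM reading is optional (requires pydicom) and untested against the
  breadth of real-world DICOM encodings.
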