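# Methods

## Problem and scope

`osascreen` frames OSA-risk screening as binary classification of fixed-
length EEG windows. A window is called high-risk when its spectral and
attentional structure matches the profile associated with OSA-related
cognitive strain: suppressed alpha (8–12 Hz), elevated theta (4–7 Hz) and an
attenuated evoked deflection near 400 ms post-stimulus. The package covers
the whole chain — cohort synthesis, signal preprocessing, the network, the
training protocol, evaluation, and a CLI — at desk scale (one CPU, minutes,
models of order 10⁴–10⁵ parameters). Clinical-scale claims are out of scope:
no AHI severity grades, no sleep staging, no real-dataset loaders.

## Synthetic cohort generator

Each subject's recording is, per channel,

    x(t) = noise_sd · ε(t) + a_α sin(2π f_α t + φ) + a_θ sin(2π f_θ t + φ') + ERP(t)

with ε white Gaussian noise, band frequencies drawn uniformly inside the
alpha/theta bands per channel, random phases, and ±15% amplitude jitter
across channels. The high-risk class multiplies the alpha amplitude by
`risk_alpha_factor` (default 0.5) and the theta amplitude by
`risk_theta_factor` (default 1.8). The optional event-related component is a
Gaussian-windowed negative deflection (width 50 ms) centred `erp_latency`
(default 0.4 s) after each stimulus onset (every 5 s), attenuated by
`erp_attenuation` (default 0.4) in the risk class. The class structure is
therefore entirely spectral/evoked; the context vector carries only
label-independent nuisance draws plus a noise-profile scalar.

Defaults: 30 subjects, 8 channels, 128 Hz, 300 s, `noise_sd` 1.0, rest-state
amplitudes alpha 1.0 / theta 0.5 (alpha high at rest, theta low at task
onset), balanced classes. At 60 s windows with 50% overlap this yields 270
windows, enough for the desk-scale learnability checks. Effect sizes are free
parameters of the generator — surrogate-labelled questionnaire risk has no
published mapping onto EEG band power — and were fixed once so a small model
can learn the contrast quickly.

Determinism: subject k's RNG is seeded by SHA-256 of `(cohort_seed, k)`, so
cohorts are bit-reproducible, subjects are independent, and a subject's
signal does not change when the cohort grows.

What the generator does **not** emulate: sleep-stage architecture, apnea
event waveforms, ocular/muscle artifacts, electrode drift, inter-subject
anatomical variability, volume conduction. Passing tests therefore
demonstrate that the pipeline recovers a planted spectral contrast under
Gaussian noise — not clinical screening performance.

## Preprocessing

Fixed stage order, recorded in a run manifest: artifact hook → bandpass →
per-channel standardization → windowing → CSP → STFT → feature
standardization.

* Bandpass: 4th-order Butterworth, 0.5–45 Hz, applied forward–backward
  (zero phase) as second-order sections.
* Artifact removal is an identity hook with a logged notice: synthetic data
  contain no ocular/muscular artifacts, and the stage slot exists so a real
  ICA step can be substituted for recorded data.
* Windows start at `k · window · (1 − overlap)` seconds; a trailing
  incomplete window is dropped rather than padded.
* CSP solves `eigh(Σ₁, Σ₁+Σ₂)` after adding `1e-6 · trace/dim · I` to each
  class covariance (per-window covariances are trace-normalized before
  averaging). Filters satisfy `wᵀ(Σ₁+Σ₂)w = 1`; eigenvalues lie in (0, 1);
  `m = 3` filters are kept from each spectral end. CSP is supervised and is
  fit on training-split window labels only.
* STFT: 1 s Hann frames at 50% hop, one-sided spectrum, natural log of the
  magnitude floored at 1e-10. Framing keeps only fully contained frames (no
  padding), so per-frame Parseval checks and tone-bin bookkeeping are exact.
  Features are stacked channel-major into `T × d`, `d = channels × bins`.
* Feature standardization statistics (per column, over training frames) are
  frozen and applied to the evaluation split.
* Augmentations (time/frequency masking with per-feature-column mean fill;
  mixup as a convex combination of features and one-hot labels) run only in
  the training loop; the evaluation path never applies them. Mask fill uses
  the column mean to keep batch statistics stable; mixup defaults to off at
  desk scale (`mixup_alpha = 0`), where the planted contrast is strong and
  label smoothing mainly slows convergence.

## Network

The model runs on a compact reverse-mode autodiff engine over float64 numpy
arrays (`osascreen.autodiff`); gradients are verified against central finite
differences in the test suite. Deployment-scale defaults are 6 encoder and 6
decoder layers, 8 heads, hidden size 512, feed-forward 2048, dropout 0.2;
`ModelConfig.tiny()` (2 layers, 2 heads, hidden 32, FFN 64, dropout 0.1) is
the desk-scale preset used in tests and examples.

Forward path: feature projection → positional encoding → learnable depthwise
temporal convolution (initialized to the identity kernel) → frame
re-weighting attention → encoder stack (post-norm residual blocks, dropout
after each sub-layer) → acoustic self-attention → gated context injection →
context-aware cross-attention from learned query tokens → temporal focus
onto the encoder states → contextual aggregation
`LayerNorm(C_focus + α·S + β·E)` with a residual feed-forward refinement →
pooled linear classifier.

Design choices where the design was genuinely open:

* **Classifier head.** The decoding machinery is transcription-shaped but
  the screening task is binary; the default head mean-pools the aggregated
  states and applies a 2-class softmax. A token-sequence head (vocabulary
  NEG/POS/EOS, autoregressive decoder, beam search with lexicographic
  tie-breaks) is retained so the sequence path is fully exercised.
* **Query states.** With no token sequence to decode, the cross-attention
  queries are a small bank of learned tokens (default 2) playing the role of
  linguistic states.
* **Literal self-attention.** The acoustic self-attention uses no learned
  projections (`softmax(H Hᵀ/√d_h)`); a flag enables projections for
  comparison.
* **Sparsity regularizer.** The entrywise L1 norm of a row-stochastic
  matrix equals its row count, a constant with zero gradient — a regression
  test documents this. The default objective therefore carries the term with
  weight 0; an entropy mode (mean row entropy: 0 at one-hot, log T at
  uniform) is provided for anyone who wants an active sparsity pressure.
* **Shape mismatches in the quadratic losses.** Consistency and alignment
  losses compare representations with different row counts (T frames vs N
  query states); both are mean-pooled over their time/position axes before
  the squared distance. The cross-attention residual likewise adds the
  time-pooled acoustic states when the query count differs from T (exact
  when they match).
* **Context gate.** `C_dyn = σ(W_c C + b_c) ⊙ C` after a bias-free linear
  projection of the per-recording context to model width; bias-free so that
  a zero context is exactly severed from the output whatever the gate
  parameters. Gate dropout applies to the sigmoid activations, not to C.
  The gate is a contraction elementwise only when dropout is off (the
  inverted-dropout rescaling can exceed 1 transiently during training).
* **Positional encodings.** Sinusoidal interleave by default (even
  dimensions sine, odd the matching cosine); a literal sine-only mode and a
  learned position table are selectable.

## Training protocol

AdamW (learning rate 3e-4, weight decay 1e-4, decoupled decay), cosine
annealing `η(e) = η_min + (η₀−η_min)/2 (1 + cos(π e / E))` with `η_min = 0`
over `max_epochs` (default 100), batch size 64, early stopping on validation
loss with patience 10 and `min_delta` 1e-4 (an improvement of exactly
`min_delta` resets the counter). The objective is
`λ₁·L_CE + λ₂·(L_consistency + L_alignment)` with `λ₁ = 1.0, λ₂ = 0.1`;
the weights are package defaults, chosen so the quadratic auxiliary terms
regularize without dominating the decision loss. Replicates use seeds
`base_seed + 0 … n_runs−1` (default 3 runs) and are aggregated as mean ±
sample standard deviation (ddof 1; a single run reports std 0 with a flag).
Splits are at the subject level, stratified by class; windows of one subject
never straddle splits. Everything is seeded: a (config, seed) pair
reproduces histories and checkpoints bit-identically.

Ablation harness: four variants retrained under identical protocol — full
model; frame re-weighting bypassed; consistency loss dropped (its λ₂ → 0);
context gate bypassed (raw projected context, so the gate parameters are
provably inert). These are the nearest concrete removals for the three
architectural components, since no operational definition of the removals
exists beyond the component names.

Transfer learning is exposed only as a load-then-finetune entry point
(`model_from_checkpoint` then further training); the package makes no claim
about cross-dataset pretraining fidelity.

## Evaluation

Window-level metrics are primary (windows inherit recording labels);
a subject-level majority-vote report is secondary, with prediction ties
resolved toward high-risk (screening errs toward sensitivity). Sensitivity =
TP/(TP+FN), specificity = TN/(TN+FP); an empty class makes them undefined
and they are reported as missing with a flag rather than imputed. F1 with
zero precision+recall is 0. AUC is the rank-based Mann–Whitney estimator
with midrank ties. Multi-run aggregation sorts run values before reducing so
the aggregate is invariant to run order, and reports an exact 0 spread for
identical runs. Cross-validation folds are not implemented: each run uses a
single held-out subject split, which under-estimates the variance a fold
average would show.

## Numerical choices

Float64 throughout. Softmax and log-softmax subtract a detached row maximum
(exact for gradients by shift invariance). Cross-entropy clamps target
probabilities at 1e-12 with a warning. Layer norm uses ε = 1e-5. Beam search
breaks ties lexicographically (smaller token sequence wins) so decoding is
deterministic. Constant channels fail standardization with an error naming
the channel. EDF is supported for reading (via mne); writing EDF needs the
`edfio` backend and the package otherwise uses its lossless npz container
(EDF is 16-bit quantized).

## Problem sizes used in tests and the acceptance script

The test suite and `scripts/acceptance.py` run the tiny preset on the
default 30-subject cohort (270 windows, 119 frames × 390 features per window
after CSP and STFT) for up to 30 epochs and 3 seeded runs, and smaller
cohorts (8–12 subjects, 120–180 s) for unit-level checks. These sizes are
the package's desk-scale operating point; scaling the cohort or the model up
changes compute, not code paths.

## Known limitations

* The synthetic contrast is strong and stationary; real OSA-related EEG
  changes are weaker, non-stationary and confounded (age, medication,
  drowsiness). Perfect desk-scale metrics say nothing about clinical
  performance.
* The literal projection-free self-attention and the constant L1 penalty are
  kept for fidelity to the method's stated form, not because they are the
  strongest design.
* No GPU path and no mixed precision; the autodiff engine is deliberately
  minimal (no kernel fusion, no graph reuse), adequate at desk scale only.
* Single-split validation rather than cross-validation folds.
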