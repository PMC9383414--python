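# Methods

## Problem and model

Cross-subject motor-imagery EEG classification suffers from domain shift:
the spatial statistics of scalp recordings differ between people, so a
classifier trained on a pool of subjects degrades on a new user.  The
package implements a three-part remedy:

1. **SPD descriptor.** Each d-channel trial `X ∈ R^{d×T}` is reduced to its
   spatial covariance `C = (1/T) X Xᵀ` after per-channel mean removal, a
   d×d symmetric positive-semidefinite matrix.  The descriptor discards
   trial length, captures per-channel power and inter-channel coupling,
   and — empirically — moves subjects' sample clouds closer together than
   the raw time series do (see the distance analysis below).  Descriptors
   are standardized elementwise, `C* = (C − C_mean) ⊘ C_std`, against
   statistics of a reference set.  By default the statistics are fitted on
   the *training subjects only* and reused for validation/test subjects;
   fitting on the whole pool is available (`norm_scope="all"`) but leaks
   test statistics in a cross-subject protocol.  The standard deviation is
   the population (1/n) form; entries below `epsilon = 1e-8` are replaced
   by 1 so constant entries map to exactly 0.

2. **Plain CNN.** Five valid stride-1 convolutions with 2×2 kernels and
   channel schedule (4, 8, 16, 32, 64), ReLU after each, one 2×2/stride-2
   max-pool between Conv3 and Conv4, then a two-layer fully-connected head
   (32 hidden units, ReLU) with softmax over K classes.  Each conv layer
   shrinks the spatial side by 1 and the pool halves it (floor), so the
   smallest workable input is d = 9.  Weights are He-normal initialized
   (fan-in), biases zero.  Every conv layer carries one scalar scale and
   one scalar shift (SS): `SS(X; W, b; s1, s2) = (W·s1) ⋆ X + (b + s2)`.
   With s1 = 1, s2 = 0 the network is exactly the plain CNN.

3. **Three-phase meta-transfer training.**
   * *Pre-train*: all training subjects' descriptors are pooled and
     F(Θ, θ) is trained jointly (Adam, batch 64, cross-entropy).
   * *Meta-update*: θ is re-initialized (θ*), the raw conv weights are
     frozen, and only the ten SS scalars are learned.  Subject-specific
     N-way K-shot tasks are drawn from training subjects, cycling subjects
     evenly; per task a copy of θ* is adapted on the support set by a few
     plain gradient steps and the query losses summed over a meta-batch
     drive one Adam step on Φ_ss (first-order meta-gradient: no second
     derivative through the inner loop).
   * *Domain adaptation*: for a new user only the classifier is fine-tuned
     (Adam) on the user's few labeled support trials; conv weights and SS
     scalars stay bit-frozen.

   All three phases share the schedule: base learning rate 0.001,
   multiplied by 0.99 every 10 epochs; Adam with β₁ = 0.9, β₂ = 0.999,
   eps = 1e-8.

## Design choices where the design was open

* **Deployment classifier.** The meta phase discards its transient θ*; a
  classifier must still be chosen as the starting point of per-user
  fine-tuning.  Starting from the *pre-trained* θ is used everywhere
  (plain transfer and meta-transfer alike): adaptation from a freshly
  random θ on 20–40 support samples reliably underperforms, and using the
  same initialization for both strategies isolates the effect of the
  learned Φ_ss.  The random θ* is used only inside the meta phase's inner
  loops, where it makes each task a fresh few-shot problem.
* **Snapshot selection.** After each meta epoch the current Φ_ss is scored
  by mean query accuracy over a *fixed* set of validation tasks (drawn
  once per run), adapted with the exact deployment procedure.  Scoring all
  candidates on the same tasks makes comparisons paired; re-drawing tasks
  each epoch would let the argmax select task-sampling noise.  The
  identity Φ_ss (evaluated before the first update) is always a candidate,
  and a learned snapshot displaces it only when its validation gain
  exceeds one standard error of the baseline estimate.  This
  one-standard-error rule is deliberately conservative: with only a few
  validation subjects the best-of-ten-snapshots estimate is biased upward,
  and a per-layer scalar SS often changes the loss (through logit scaling)
  without changing accuracy.  When the meta phase finds no real
  improvement the returned model is behaviorally identical to the
  pre-trained one.
* **Per-layer scalar SS.** The scale/shift pair is a single scalar per
  conv layer, applied to the whole weight/bias tensor.  This is the
  narrowest possible transfer parameterization (10 numbers); its limited
  capacity is a property of the method, not of this implementation.
* **Inner loop.** 5 plain gradient steps at rate 0.01 on the classifier
  only, full support batch.  Because the features are fixed during the
  inner loop, support/query features are computed once per task and the
  inner loop costs only two small matrix products per step.
* **Folds.** Validation/test subjects are drawn randomly without
  replacement per fold; folds are kept distinct as (val, test) pairs while
  combinatorially possible.  A round-robin `balanced` option cycles test
  users deterministically.

## Synthetic study conditions

The generator emulates multi-subject recordings whose class information
lives purely in spatial covariance:

* Class k has source covariance `Σ_k = B + 1.0·(u_k u_kᵀ + v_k v_kᵀ)`,
  where B is one shared background (random orthogonal eigenvectors,
  eigenvalues spread linearly over [1, 6]) standing in for the large
  class-independent structure of scalp EEG (volume conduction, common
  rhythms), and u_k, v_k are class-specific random unit vectors.
* Subject s mixes sources through `A_s = I + ε R_s`, R_s fixed per subject
  with iid N(0, 1/d²) entries; a trial is `X = A_s Z + E` with Z drawn
  columnwise from N(0, Σ_k) and E iid N(0, noise_sd²).  The expected trial
  covariance `A_s Σ_k A_sᵀ + noise_sd² I` is available in closed form so
  tests can use a Bayes (Gaussian log-likelihood) oracle.
* Defaults: d = 12 channels (smallest comfortable size for the conv
  geometry), K = 4 classes, T = 256 samples, 60 trials/class/subject,
  noise_sd = 1.0, ε = 0.3 for the hard cross-subject regime.  Under these
  conditions zero-shot cross-subject accuracy sits around 0.6 — clearly
  above chance (0.25) and clearly below the within-subject ceiling — while
  the likelihood oracle on true covariances still classifies perfectly,
  so the class signal is present and the difficulty is genuinely the
  subject shift.  The dominant shared background is what makes subject
  identity a strong confound: the mixing perturbs the whole covariance,
  so a perturbation of the large background swamps the small class bumps.

What the generator does **not** model: temporal EEG structure (1/f
spectra, band-limited rhythms, event-related time courses), non-Gaussian
artifacts, electrode dropout, and session-to-session drift within a
subject.  Passing tests therefore demonstrate the pipeline's behavior
when class information is exactly covariance-borne — the descriptor's own
operating assumption — and say nothing about temporal-feature competitors.

## Numerical choices

* Covariance matrices are symmetrized (`(C + Cᵀ)/2`) to kill rounding
  asymmetry; symmetry tolerance 1e-9, PSD eigenvalue tolerance −1e-9.
* Cross-entropy floors probabilities at 1e-12.
* Max-pool ties resolve to the first (row-major) element; argmax
  prediction ties resolve to the lowest class index.
* All randomness flows through `numpy.random.Generator` seeded from the
  run seed via `SeedSequence` streams, so every phase is bit-reproducible
  on a fixed platform (results can differ across BLAS builds at the
  1-ulp level; the contract is determinism within one environment).
* The conv forward/backward is written as four shifted tensor
  contractions (the kernel is always 2×2); gradients are verified against
  central finite differences in the test suite.

## Problem sizes used by the shipped studies

The transfer study in `scripts/acceptance.py` and the acceptance tests
runs 10 subjects (6 train / 2 validation / 2 test), 15 pre-train and 10
meta epochs, 10-shot episodes with 10 query trials per class, and 5 seeds
(tests) or 3 folds (script).  These sizes keep a full multi-seed study in
the minutes range on one CPU while leaving the qualitative ordering of
the strategies stable; the full-scale defaults (50 pre-train epochs, 40
meta epochs, 18 folds) remain the package defaults for real use.

## Known limitations

* The per-layer scalar SS gives the meta phase very little capacity; on
  the synthetic conditions its selected improvement is often zero, in
  which case meta-transfer deliberately degenerates to plain transfer.
* First-order meta-gradients only.
* The EDF/GDF adapter epochs by annotation events and applies no
  filtering; real-data preprocessing (band-pass, artifact rejection) is
  the caller's responsibility.
* `n_way` smaller than the number of classes is supported by the sampler
  but the shipped studies always use all classes per task.
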