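# Methods

## Problem setting

Given a differentiable fitness oracle `P` mapping a one-hot sequence pattern
`x ∈ {0,1}^{N×M}` (N positions, M monomer channels; M=4 for nucleic acids,
M=20 for proteins) to a scalar, activation maximization searches for a
sequence maximizing `P`. Because `x` is discrete, the search is carried out
over an `N×M` matrix of real-valued logits `l` that parameterize a sequence
distribution, and gradients reach `l` either through a continuous softmax
relaxation or through discrete samples with a straight-through estimator.

## The four gradient methods

All four minimize the train loss `L(l) = −P(x(l))`:

* **pwm** — `x(l) = σ(l)`, the row-wise softmax (a PSSM). Fully
  deterministic and differentiable, but the oracle is evaluated on a
  continuous pattern it was never meant to see, and the softmax Jacobian
  `∂σ_ij/∂l_ik = σ_ik(1[j=k] − σ_ij)` vanishes as probabilities saturate.
* **seqprop** — `x(l) = δ(l)`, a categorical one-hot sample per position
  drawn from `σ(l)`. The backward pass substitutes the softmax Jacobian for
  the non-existent sample derivative (the softmax straight-through
  estimator).
* **fast_pwm** — as `pwm`, with the logits standardized (below) and
  re-expanded by trainable `γ`/`β` before the softmax.
* **fast_seqprop** — as `seqprop`, on the standardized, `γ`/`β`-scaled
  logits. This is the method of interest; the others are its controls.

Two alternative estimators are available for the sampling methods: the
original straight-through estimator (backward pass is the identity,
`∂δ/∂l = 1`) and hard Gumbel-softmax (forward: argmax of Gumbel-perturbed
logits; backward: Jacobian of the tempered softmax of the perturbed logits,
default temperature 1.0, no annealing schedule).

## Logit normalization and the entropy parameters

Un-normalized logits drift to large, disproportionately scaled values during
optimization, which saturates the softmax Jacobian and freezes the search.
The fast variants therefore standardize the logits at every update:

* **instance mode** (default for DNA): each channel j is standardized across
  positions, `l^norm_ij = (l_ij − μ̄_j)/ε̄_j`, with the population (1/N)
  standard deviation;
* **layer mode** (default for proteins, where M=20 and sequences are short,
  making per-channel statistics noisy): all N·M entries are standardized
  jointly by the global mean and standard deviation.

The denominator is floored at 1e-6: channels with deviation below the floor
are treated as constant and normalize to zero. A floor (rather than an
additive stabilizer) keeps normalization exactly invariant to positive
affine reparameterizations of any non-degenerate channel, a property the
test suite pins. A `variance_denominator` flag divides by `ε̄²` instead for
users who want that variant; the default preserves `Var[l^norm] = 1`.

Standardized logits have limited expressiveness as distribution parameters,
so trainable scale `γ` and offset `β` re-expand them: per channel in
instance mode (β captures global composition bias, e.g. GC preference), as
scalars in layer mode. `γ` is initialized at 1, `β` at 0. `γ` acts as an
inverse sampling temperature and is updated by the same optimizer as the
logits: its fitness gradient is positive exactly when the upstream signal at
the sampled pattern is sign-consistent with the normalized logits, so
confident, fitness-raising monomers lower the sampling entropy (local
refinement) while sampled inconsistencies raise it again (global
exploration). `entropy_diagnostics()` exposes this mechanism per update.

## Gradients

No autodiff framework is used: every transform ships an explicit
vector-Jacobian product, and the design loop composes them (oracle input
gradient → softmax-ST backward → `γ` scaling → normalization backward).
The normalization statistics `μ̄, ε̄` are treated as constants within an
update step, so the backward factor through the normalizer is
`γ_j/max(ε̄_j, 1e-6)` and one `fast_seqprop` update admits closed-form
expressions for the `l`, `γ` and `β` gradients; a literal transcription of
those expressions (built from the full per-position softmax Jacobian) is
kept as an independent code path and the two routes are cross-checked to
1e-6 in the tests. Because the statistics are frozen per step, the
full-graph finite-difference check applies to the un-normalized `pwm` path,
where it holds at 1e-5 relative tolerance.

The optimizer is Adam (β₁=0.9, β₂=0.999). The package default step size is
0.05, chosen so toy-scale design runs (N ≤ 30) converge within a few hundred
updates; the head-to-head method comparisons in the tests instead use the
standard default 0.001, because the convergence-speed advantage of
normalization — the effect those comparisons measure — is expressed at the
default setting, while at 0.05 every method saturates the toy landscapes
and the ordering dissolves into sampling noise.

Per update, `grad_samples` straight-through samples may be drawn and their
gradients averaged (default 1; 10 demonstrably reduces gradient variance
and reaches the structure-recovery threshold in fewer updates).

A failure mode worth knowing about: when the entropy parameters share the
optimizer settings of the logits, γ can anneal the sampling temperature
faster than the logits learn. If the distribution saturates on a slightly
sub-optimal symbol, the softmax-ST gradient vanishes there and the run can
no longer escape. `gamma_learning_rate` therefore allows the entropy
parameters their own (slower) schedule; the exact-optimum recovery
experiments anneal γ at 1/5 of the logit rate, which removes this failure
mode on separable landscapes. Exact recovery is additionally only a
meaningful criterion when the optimum is identifiable: a per-position gap
of ~0.01 between the best and second-best symbol is below the resolution
of sampled gradients with O(1) noise at any reasonable budget, so
`random_identifiable_linear_oracle` samples benchmark landscapes with a
minimum argmax margin (default 0.2).

## Evaluation protocol

The test loss is always measured on discrete samples, regardless of method:
`L_test = −(1/KS) Σ_k Σ_s P(δ(l^(k))^(s))` over K independent optimization
runs and S samples per run (defaults K=10, S=10). Train loss is recorded
every update; test loss every `eval_every` updates (default 10, for cost
control) and always at the final update. Each deliverable per run is the
argmax (MAP) sequence of the final PSSM plus S sampled sequences — the MAP
sequence is what the recovery experiments score. Randomness is organized as
one `SeedSequence` per (run, purpose, step), so the K×S protocol is
bit-reproducible and order-independent.

Early stopping for recovery experiments (`stop_loss`) triggers on the loss
of the current MAP design, not the train loss: a multi-sample train loss is
an average and therefore a strictly harder quantity than a single sample's
loss, which would bias comparisons across `grad_samples` settings.

## Gradient-free baselines

* **evolution** — propose 1 or, with 50% probability, 2 random
  substitutions at distinct positions; accept only strict improvements.
* **simulated annealing** — 1 substitution per step; accept worse
  candidates with the Metropolis probability `exp(−(P(x)−P(x'))/T)` under
  geometric cooling `T_t = T₀·decay^t` (defaults T₀=1.0, decay=0.999; no
  schedule is canonical, so both are configurable). The reported design is
  the best-so-far over the walk, not the final state.

## Regularized objectives

* **Likelihood margin**: `λ·max(log₁₀ p_ref − log₁₀ p_model(x) − ρ, 0)`
  keeps designs within a slack ρ (log₁₀ units, default 1) of the training
  data's mean model likelihood `p_ref`. Exactly zero value and gradient in
  the inactive region. Defaults λ=1; `p_ref` is computed as the mean model
  log₁₀-likelihood of a provided training sample. The shipped likelihood
  model is an exact factorized position-categorical model; user-supplied
  latent-variable models plug in through the same contract with
  importance-weighted estimates (suggested 16 importance samples).
* **Probability of improvement**: `−log₁₀ Pr_{Normal(μ(x), ε(x))}(Y > q)`
  for oracles predicting a fitness mean and standard deviation, with `q`
  defaulting to the 95th percentile of oracle scores on a training sample.
  Implemented on the log-survival function so extreme tails stay finite.
  Base 10 is used for every log-likelihood-scaled quantity in the package.
* **Activity caps**: `Σ_k η_k·max(C_k(x) − c_k, 0)` over user-supplied
  activation-map extractors.
* **Structure matching**: the summed mean KL divergence over four pairwise
  distribution tensors (distances, 37 bins; two orientation angles, 24
  bins; one, 12 bins), each term
  `(1/N²)Σ_ij Σ_k Y_ijk·log(Y_ijk/X_ijk)` with the target as the weighting
  distribution Y and the prediction as X, natural log, `0·log(0/·) := 0`,
  and predictions floored at 1e-8 before the ratio. The direction
  (target-weighted) and the asymmetry of the divergence are pinned by
  regression tests.

All penalties compose with any base oracle through `composite_objective`,
which subtracts weighted penalty values (and gradients) from the base
fitness.

## Toy fixtures: what they emulate and what they do not

The fixtures stand in for trained deep-learning predictors so every code
path is testable offline:

* **linear** (separable): `P(x) = ⟨W, x⟩`; the global optimum is the
  positionwise argmax, checkable by exhaustive enumeration (≤ 10⁶
  sequences, lexicographic tie-break).
* **motif** (epistatic): smooth-max (log-sum-exp, sharpness 10 — a hard max
  is non-differentiable, and real oracles are smooth) over offsets of the
  cross-correlation with a planted k-mer weight pattern; windows compete
  for the motif.
* **hamming** (optionally deceptive): match count to a hidden target, with
  an optional down-weighted decoy creating a competing plateau.
* **toy structure predictor**: positions are embedded through a fixed
  random 20×4 matrix; pairwise bin logits combine a bilinear product of the
  two embeddings (genuine pairwise epistasis) with additive per-position
  terms, pushed through a per-pair softmax at the real tensor shapes
  (37/24/24/12 bins). The additive terms keep the designated solution
  identifiable at desk scale (N ≤ 50). Targets are generated by pushing a
  random solution sequence through the predictor, so zero loss is
  attainable by construction and recovery experiments are well-defined.

These landscapes are orders of magnitude smaller and smoother than trained
genomic or structural predictors: they have no learned feature hierarchy,
no out-of-distribution pathologies, and (except for the motif and bilinear
terms) little long-range epistasis. Tests passing on them demonstrate the
correctness of the estimators, losses and search loops and the *relative*
behavior of the methods — not absolute performance on real oracles, whose
published convergence and fitness numbers depend on trained model weights
this package deliberately does not bundle.

## Numerical choices

* Softmax rows are stabilized by row-max subtraction; categorical sampling
  inverts the row CDF with a single uniform draw per position.
* Argmax sequence extraction breaks ties toward the lowest channel index;
  sampling needs no tie-break.
* Non-finite losses or gradients abort a run with the step index in the
  error (CLI exit code 3).
* Logits initialize i.i.d. uniform on [−r, r], r=1 by default.
* MEME output rows are rounded to 6 decimals and renormalized by pushing
  the residual onto the largest entry; `nsites` is set to 10⁶ so
  count-quantizing parsers preserve the printed precision.

## Known limitations

* The frozen-statistics backward pass is a deliberate simplification; full
  backpropagation through the normalization statistics would add
  cross-position terms of order 1/N.
* Oracles must supply input gradients (analytically or via the provided
  finite-difference adapter); there is no tape-based autodiff, so deeply
  composed user objectives must provide their own chain rule or accept
  finite-difference cost.
* The importance-weighted likelihood contract for latent-variable models is
  specified but not exercised against a trained VAE in-repo.
* Batch/GPU execution is not implemented; everything is single-design,
  single-CPU numpy.
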