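# seqmax

Gradient-based activation maximization for DNA, RNA and protein sequence
design.

Sequence design guided by a trained, differentiable fitness predictor
("oracle") is a standard strategy in regulatory genomics and protein
engineering: find the one-hot pattern `x ∈ {0,1}^{N×M}` maximizing the
oracle score `P(x)`. Plain gradient ascent does not apply to discrete
sequences, and the classical work-arounds — optimizing a softmax relaxation
σ(l) of trainable logits `l`, or optimizing discrete categorical samples
δ(l) with a straight-through gradient estimator — converge slowly because
the logits drift to large, disproportionately scaled values that saturate
the softmax Jacobian.

This package implements the fast variant of stochastic sequence
backpropagation: the logits are standardized at every update (per channel
across positions for DNA, globally for proteins) and re-expanded through
trainable entropy parameters γ and β, so that discrete samples

    x = δ(γ · (l − μ̄)/ε̄ + β),   δ backed by the softmax-ST estimator
    ∂δ_ij/∂l_ik ≈ ∂σ_ij/∂l_ik = σ_ik(1[j=k] − σ_ij)

are optimized with respect to {l, γ, β} by Adam. γ acts as an inverse
sampling temperature that adapts automatically: consistent, fitness-raising
samples sharpen the distribution, inconsistent samples re-heat it. The
package also ships the predecessor methods (`pwm`, `fast_pwm`, `seqprop`),
gradient-free baselines (greedy substitution search and simulated annealing
with the Metropolis criterion), regularized objectives (likelihood-margin
hinge, probability of improvement, activity caps, KL-divergence structure
matching), and fully self-contained toy oracles so that everything runs
without trained model weights. It is aimed at computational biologists who
want to plug in their own differentiable predictors through a two-method
oracle contract (`predict`, `gradient`).

## Worked example

Design 8-nt sequences maximizing a random separable (linear) fitness
landscape, and compare against exhaustive enumeration of all 4^8
sequences:

```python
import numpy as np, seqmax as sm

rng = np.random.default_rng(0)
oracle = sm.random_linear_oracle(8, 4, rng)

cfg = sm.DesignConfig(length=8, method="fast_seqprop", updates=300,
                      runs=10, eval_samples=10, seed=1, eval_every=100)
result = sm.design(oracle, cfg)

best, best_score = sm.brute_force_optimum(oracle, 8, 4)
print("enumerated optimum :", sm.DNA.decode(best), f"(fitness {best_score:.4f})")
print("designed (MAP), run 0:", result.argmax_sequences[0])
print("runs matching optimum:", sum(s == sm.DNA.decode(best)
                                    for s in result.argmax_sequences), "/ 10")
print(f"test loss: start {result.test_losses[:,0].mean():.4f}"
      f" -> final {result.final_test_loss:.4f}")
print(f"mean gamma after 300 updates: {result.gamma_traj[:, -1].mean():.3f}")
```

prints

```
enumerated optimum : GGTCTCAC (fitness 5.2996)
designed (MAP), run 0: GGTCTCAC
runs matching optimum: 9 / 10
test loss: start -5.0309 -> final -5.1518
mean gamma after 300 updates: 3.604
```

Nine of ten independent runs recover the enumerated global optimum within
300 updates. The test loss is the mean negative fitness of discrete
samples drawn from each run's final distribution (K=10 runs × S=10
samples), so it sits slightly above the optimum's −5.2996 as long as the
distributions retain entropy; the entropy parameter γ has grown from 1 to
≈3.6, reflecting the adaptive sharpening of the sampling distribution as
runs converge.

The same loop runs from the shell, writing FASTA designs, MEME-format
PSSMs, a JSONL loss trajectory and a reproducibility manifest:

```
seqmax oracle-spec --kind linear --length 8 --seed 3 --out linear.yaml
seqmax design --method fast_seqprop --oracle linear.yaml --length 8 \
    --updates 300 --runs 10 --eval-samples 10 --seed 7 --out-dir out/
```

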