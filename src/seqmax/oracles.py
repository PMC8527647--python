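"""Self-contained toy fitness oracles and data generators.

These fixtures make every design method testable without any trained model:

* ``LinearOracle`` — separable landscape P(x) = <W, x>; its global optimum
  is the positionwise argmax of W, so recovery is checkable exactly.
* ``MotifOracle`` — epistatic landscape: smooth-max (log-sum-exp) over
  offsets of the cross-correlation between the sequence and a planted k-mer
  weight pattern.
* ``HammingOracle`` — match count against a hidden target; optionally with a
  lower-valued decoy target, which makes the landscape deceptive.
* ``ToyStructurePredictor`` — a small differentiable map from sequence to
  pairwise distance/orientation distribution tensors, with a designated
  solution sequence that reproduces a generated target exactly (zero
  structure loss), for desk-scale structure-matching experiments.
* ``FactorizedSequenceModel`` — an exact position-categorical likelihood
  model standing in for trained latent-variable likelihood models when
  exercising the margin penalty.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .logits import Alphabet, DNA, PROTEIN
from .objectives import (
    DistributionTensors,
    kl_structure_gradients,
    kl_structure_loss,
)
from .sampling import categorical_sample


@dataclass
class LinearOracle:
    """P(x) = sum_ij W_ij x_ij with exact gradient W."""

    weights: np.ndarray
    tag: str = "separable"

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("weight matrix must be finite")

    def predict(self, x: np.ndarray) -> float:
        return float((self.weights * x).sum())

    def gradient(self, x: np.ndarray) -> np.ndarray:
        return self.weights.copy()


def make_linear_oracle(weights: np.ndarray) -> LinearOracle:
    return LinearOracle(weights)


def random_linear_oracle(
    n: int, m: int, rng: np.random.Generator, scale: float = 1.0
) -> LinearOracle:
    return LinearOracle(rng.normal(0.0, scale, size=(n, m)))


def random_identifiable_linear_oracle(
    n: int, m: int, rng: np.random.Generator, *, min_gap: float = 0.2
) -> LinearOracle:
    """Random linear oracle with distinct per-position maxima.

    Weights are redrawn until the gap between the best and second-best
    symbol at every position is at least ``min_gap``, so the global optimum
    is statistically identifiable by a stochastic sampler: an
    epsilon-degenerate position cannot be resolved by sampled gradients at
    any reasonable update budget.
    """
    while True:
        w = rng.normal(0.0, 1.0, size=(n, m))
        srt = np.sort(w, axis=1)
        if float((srt[:, -1] - srt[:, -2]).min()) >= min_gap:
            return LinearOracle(w)


@dataclass
class MotifOracle:
    """Smooth-max cross-correlation with a planted k-mer weight pattern.

    P(x) = (1/s) * logsumexp_o(s * c_o) where c_o is the inner product of
    the k-mer weights with the window of x at offset o and ``s`` is the
    smooth-max sharpness.  The hard maximum is recovered as s -> inf; the
    value always lies within log(N-k+1)/s of it.
    """

    kmer_weights: np.ndarray
    length: int
    sharpness: float = 10.0
    tag: str = "epistatic"

    def __post_init__(self) -> None:
        self.kmer_weights = np.asarray(self.kmer_weights, dtype=float)
        if self.kmer_weights.shape[0] > self.length:
            raise ValueError("k-mer longer than the sequence")

    @property
    def k(self) -> int:
        return self.kmer_weights.shape[0]

    def _correlations(self, x: np.ndarray) -> np.ndarray:
        n_offsets = self.length - self.k + 1
        return np.array(
            [
                float((self.kmer_weights * x[o : o + self.k]).sum())
                for o in range(n_offsets)
            ]
        )

    def predict(self, x: np.ndarray) -> float:
        c = self._correlations(x)
        return float(logsumexp(self.sharpness * c) / self.sharpness)

    def gradient(self, x: np.ndarray) -> np.ndarray:
        c = self._correlations(x)
        w = np.exp(self.sharpness * c - logsumexp(self.sharpness * c))
        g = np.zeros_like(np.asarray(x, dtype=float))
        for o, weight in enumerate(w):
            g[o : o + self.k] += weight * self.kmer_weights
        return g


def make_motif_oracle(
    kmer_weights: np.ndarray, n: int, sharpness: float = 10.0
) -> MotifOracle:
    return MotifOracle(np.asarray(kmer_weights, dtype=float), n, sharpness)


def random_motif_oracle(
    n: int, m: int, k: int, rng: np.random.Generator, sharpness: float = 10.0
) -> MotifOracle:
    return MotifOracle(rng.normal(0.0, 1.0, size=(k, m)), n, sharpness)


@dataclass
class HammingOracle:
    """Match count to a hidden target; optionally deceptive via a decoy.

    Without a decoy P(x) = <T, x> (the number of matching positions), a
    linear landscape whose optimum is the target itself.  With a decoy, the
    landscape becomes a sharp smooth-max of the target match count and a
    down-weighted decoy match count, creating a competing plateau.
    """

    target: np.ndarray
    decoy: np.ndarray | None = None
    decoy_weight: float = 0.8
    sharpness: float = 10.0

    def __post_init__(self) -> None:
        self.target = np.asarray(self.target, dtype=float)
        self.tag = "separable" if self.decoy is None else "deceptive"

    def _branch_scores(self, x: np.ndarray) -> np.ndarray:
        scores = [float((self.target * x).sum())]
        if self.decoy is not None:
            scores.append(self.decoy_weight * float((self.decoy * x).sum()))
        return np.array(scores)

    def predict(self, x: np.ndarray) -> float:
        if self.decoy is None:
            return float((self.target * x).sum())
        return float(logsumexp(self.sharpness * self._branch_scores(x)) / self.sharpness)

    def gradient(self, x: np.ndarray) -> np.ndarray:
        if self.decoy is None:
            return self.target.copy()
        w = self._branch_scores(x) * self.sharpness
        w = np.exp(w - logsumexp(w))
        return w[0] * self.target + w[1] * self.decoy_weight * self.decoy


def make_hamming_oracle(
    target: str | np.ndarray,
    alphabet: Alphabet = DNA,
    decoy: str | np.ndarray | None = None,
    decoy_weight: float = 0.8,
) -> HammingOracle:
    if isinstance(target, str):
        target = alphabet.encode(target)
    if isinstance(decoy, str):
        decoy = alphabet.encode(decoy)
    return HammingOracle(np.asarray(target), decoy, decoy_weight)


# ---------------------------------------------------------------------------
# Brute-force ground truth
# ---------------------------------------------------------------------------

BRUTE_FORCE_LIMIT = 10**6


def brute_force_optimum(oracle, n: int, m: int) -> tuple[np.ndarray, float]:
    """Exhaustively enumerate all M^N one-hot sequences.

    Returns the strict maximum; ties break to the lexicographically lowest
    channel-index tuple.  Rejects search spaces above 10^6 sequences.
    """
    size = m**n
    if size > BRUTE_FORCE_LIMIT:
        raise ValueError(
            f"search space {m}^{n} = {size} exceeds the enumeration bound "
            f"{BRUTE_FORCE_LIMIT}"
        )
    best_score = -np.inf
    best = None
    x = np.zeros((n, m))
    rows = np.arange(n)
    for flat in range(size):
        idx = np.unravel_index(flat, (m,) * n)
        x[:] = 0.0
        x[rows, idx] = 1.0
        score = float(oracle.predict(x))
        if score > best_score:
            best_score = score
            best = x.copy()
    return best, best_score


# ---------------------------------------------------------------------------
# Toy structure predictor
# ---------------------------------------------------------------------------


@dataclass
class ToyStructurePredictor:
    """Differentiable map from a sequence to distribution tensors.

    Each position is embedded through a fixed random matrix; pairwise bin
    logits combine a bilinear product of the two embeddings with additive
    per-position terms, and a softmax over bins yields valid categorical
    distributions at the tensor shapes of real structure predictors
    (37/24/24/12 bins).  The additive terms keep the designated solution
    identifiable at desk scale while the bilinear term provides genuine
    pairwise (epistatic) structure.
    """

    n: int
    alphabet: Alphabet = PROTEIN
    embed_dim: int = 4
    bilinear_scale: float = 0.5
    seed: int = 0
    tag: str = "epistatic"

    def __post_init__(self) -> None:
        if self.n > 50:
            raise ValueError("toy structure predictor supports N <= 50")
        rng = np.random.default_rng(np.random.SeedSequence(self.seed, spawn_key=(71,)))
        m, d = self.alphabet.size, self.embed_dim
        self._embed = rng.normal(0.0, 1.0, size=(m, d))
        # All four tensors share one concatenated bin axis (37+24+24+12=97):
        # slices recover the per-tensor blocks, and the heavy contractions run
        # once per forward/backward instead of four times.
        bins = list(DistributionTensors._BINS.values())
        total = sum(bins)
        self._slices = {}
        offset = 0
        for name, b in DistributionTensors._BINS.items():
            self._slices[name] = slice(offset, offset + b)
            offset += b
        self._W = rng.normal(0.0, 0.5, size=(total, d * d))
        self._U = rng.normal(0.0, 0.75, size=(total, d))
        self._V = rng.normal(0.0, 0.75, size=(total, d))

    def _bin_probs(self, e: np.ndarray) -> np.ndarray:
        """Softmax bin probabilities over the concatenated bin axis blocks."""
        n, d = e.shape
        pair = np.einsum("ia,jb->ijab", e, e).reshape(n, n, d * d)
        z = self.bilinear_scale * (pair @ self._W.T)
        z += (e @ self._U.T)[:, None, :]
        z += (e @ self._V.T)[None, :, :]
        probs = np.empty_like(z)
        for sl in self._slices.values():
            block = z[..., sl]
            block = block - block.max(axis=-1, keepdims=True)
            np.exp(block, out=probs[..., sl])
            probs[..., sl] /= probs[..., sl].sum(axis=-1, keepdims=True)
        return probs

    def predict_tensors(self, x: np.ndarray) -> DistributionTensors:
        e = np.asarray(x, dtype=float) @ self._embed
        probs = self._bin_probs(e)
        return DistributionTensors(
            **{name: probs[..., sl] for name, sl in self._slices.items()}
        )

    def vjp(
        self,
        x: np.ndarray,
        grads: dict[str, np.ndarray],
        pred: DistributionTensors | None = None,
    ) -> np.ndarray:
        """Gradient w.r.t. x given upstream gradients on each tensor.

        ``pred`` may pass a precomputed forward output to avoid recomputing.
        """
        x = np.asarray(x, dtype=float)
        e = x @ self._embed
        n, d = e.shape
        if pred is None:
            pred = self.predict_tensors(x)
        g_z = np.zeros((n, n, self._W.shape[0]))
        for name, sl in self._slices.items():
            p = getattr(pred, name)
            g_p = grads[name]
            inner = (g_p * p).sum(axis=-1, keepdims=True)
            g_z[..., sl] = p * (g_p - inner)
        g_pair = (g_z @ self._W).reshape(n, n, d, d) * self.bilinear_scale
        g_e = np.einsum("ijab,jb->ia", g_pair, e)
        g_e += np.einsum("ijab,ia->jb", g_pair, e)
        g_e += g_z.sum(axis=1) @ self._U
        g_e += g_z.sum(axis=0) @ self._V
        return g_e @ self._embed.T


@dataclass
class StructureOracle:
    """Fitness = -structure KL loss against a fixed target tensor set."""

    predictor: ToyStructurePredictor
    target: DistributionTensors
    tag: str = "epistatic"

    def predict(self, x: np.ndarray) -> float:
        return -kl_structure_loss(self.predictor.predict_tensors(x), self.target)

    def gradient(self, x: np.ndarray) -> np.ndarray:
        pred = self.predictor.predict_tensors(x)
        grads = kl_structure_gradients(pred, self.target)
        return -self.predictor.vjp(x, grads, pred=pred)

    def loss(self, x: np.ndarray) -> float:
        return -self.predict(x)


def make_toy_structure_oracle(
    n: int, seed: int = 0, alphabet: Alphabet = PROTEIN
) -> tuple[StructureOracle, str]:
    """Build a structure-matching oracle whose target is realizable.

    A solution sequence is drawn at random, pushed through the predictor,
    and its output tensors are taken as the target — so the solution attains
    exactly zero structure loss and recovery experiments are well-defined.
    Returns the oracle and the solution sequence string.
    """
    predictor = ToyStructurePredictor(n=n, alphabet=alphabet, seed=seed)
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(72,)))
    solution_idx = rng.integers(alphabet.size, size=n)
    solution = "".join(alphabet.symbols[i] for i in solution_idx)
    target = predictor.predict_tensors(alphabet.encode(solution))
    return StructureOracle(predictor, target), solution


# ---------------------------------------------------------------------------
# Factorized likelihood model and training-set generators
# ---------------------------------------------------------------------------


@dataclass
class FactorizedSequenceModel:
    """Exact position-categorical sequence likelihood model.

    log10 p(x) = sum_ij x_ij log10 theta_ij, which is linear in x and hence
    exactly differentiable through the straight-through contract (the
    gradient is the log10 probability matrix itself).
    """

    probs: np.ndarray

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if np.abs(self.probs.sum(axis=1) - 1).max() > 1e-9 or self.probs.min() < 0:
            raise ValueError("rows of probs must be categorical distributions")
        self._log10 = np.log10(np.maximum(self.probs, 1e-300))

    @property
    def n(self) -> int:
        return self.probs.shape[0]

    def log10_marginal(self, x: np.ndarray) -> float:
        return float((self._log10 * x).sum())

    def gradient(self, x: np.ndarray) -> np.ndarray:
        return self._log10.copy()

    def sample(self, rng: np.random.Generator) -> np.ndarray:
        return categorical_sample(self.probs, rng)

    def entropy_nats(self) -> float:
        p = np.maximum(self.probs, 1e-300)
        return float(-(self.probs * np.log(p)).sum())


def random_factorized_model(
    n: int, m: int, rng: np.random.Generator, concentration: float = 2.0
) -> FactorizedSequenceModel:
    return FactorizedSequenceModel(rng.dirichlet(np.full(m, concentration), size=n))


def sample_training_set(
    model: FactorizedSequenceModel, n_samples: int, rng: np.random.Generator
) -> list[np.ndarray]:
    """i.i.d. one-hot samples, e.g. to compute p_ref and the fitness quantile."""
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    return [model.sample(rng) for _ in range(n_samples)]


def reference_stats(
    model: FactorizedSequenceModel,
    oracle,
    sample: list[np.ndarray],
    quantile: float = 95.0,
) -> tuple[float, float]:
    """(p_ref, q): mean log10 likelihood and fitness quantile of a sample."""
    p_ref = float(np.mean([model.log10_marginal(x) for x in sample]))
    q = float(np.percentile([oracle.predict(x) for x in sample], quantile))
    return p_ref, q


# ---------------------------------------------------------------------------
# Declarative oracle specs (YAML-friendly)
# ---------------------------------------------------------------------------


def oracle_from_spec(spec: dict):
    """Build a fixture oracle from a declarative spec dictionary.

    Supported kinds: ``linear``, ``motif``, ``hamming``, ``toy_structure``.
    Parameters are either given explicitly (``weights``, ``kmer_weights``,
    ``target``) or generated from ``seed`` at the stated shape.
    """
    spec = dict(spec)
    kind = spec.get("kind")
    alphabet_name = spec.get("alphabet", "dna")
    alphabet = PROTEIN if alphabet_name == "protein" else DNA
    n = int(spec.get("length", 0))
    rng = np.random.default_rng(int(spec.get("seed", 0)))
    if kind == "linear":
        if "weights" in spec:
            return make_linear_oracle(np.asarray(spec["weights"], dtype=float))
        return random_linear_oracle(n, alphabet.size, rng)
    if kind == "motif":
        sharpness = float(spec.get("sharpness", 10.0))
        if "kmer_weights" in spec:
            return make_motif_oracle(
                np.asarray(spec["kmer_weights"], dtype=float), n, sharpness
            )
        k = int(spec.get("k", 6))
        return random_motif_oracle(n, alphabet.size, k, rng, sharpness)
    if kind == "hamming":
        return make_hamming_oracle(
            spec["target"],
            alphabet,
            spec.get("decoy"),
            float(spec.get("decoy_weight", 0.8)),
        )
    if kind == "toy_structure":
        oracle, _ = make_toy_structure_oracle(
            n, int(spec.get("seed", 0)), alphabet=PROTEIN
        )
        return oracle
    raise ValueError(f"unknown oracle kind {kind!r}")
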