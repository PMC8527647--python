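"""Softmax relaxation, categorical sampling, and straight-through estimators.

The softmax of the logits, sigma(l), is a position-specific probability
matrix (PSSM); the categorical sampler delta(l) draws one monomer per
position from it.  Straight-through (ST) estimators make the discrete sample
differentiable-in-practice: the forward value is the one-hot sample, the
backward pass substitutes the Jacobian of a relaxation evaluated at the same
logits.  Three estimator kinds are supported:

``softmax_st``
    backward pass uses the softmax Jacobian at the sampling logits
    (d delta_ij / d l_ik ~ sigma_ik (1[j=k] - sigma_ij));
``original_st``
    backward pass is the identity (d delta / d l = 1);
``gumbel_softmax``
    forward is the hard argmax of Gumbel-perturbed logits, backward is the
    Jacobian of the tempered softmax of the perturbed logits.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .logits import _check_finite

ESTIMATOR_KINDS = ("softmax_st", "original_st", "gumbel_softmax")


@dataclass(frozen=True)
class EstimatorKind:
    kind: str = "softmax_st"
    temperature: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in ESTIMATOR_KINDS:
            raise ValueError(
                f"unknown estimator {self.kind!r}; expected one of {ESTIMATOR_KINDS}"
            )
        if self.kind == "gumbel_softmax" and not self.temperature > 0:
            raise ValueError("gumbel_softmax requires temperature > 0")


def softmax_relax(logits: np.ndarray) -> np.ndarray:
    """Row-wise softmax, stabilized by row-max subtraction."""
    logits = _check_finite(np.atleast_2d(logits), "logits")
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_vjp(probs: np.ndarray, grad_out: np.ndarray) -> np.ndarray:
    """Vector-Jacobian product of the row-wise softmax.

    Given ``probs = softmax(l)`` and an upstream gradient w.r.t. the
    probabilities, returns the gradient w.r.t. the logits:
    ``probs * (grad - <grad, probs>)`` per row.
    """
    inner = (grad_out * probs).sum(axis=1, keepdims=True)
    return probs * (grad_out - inner)


def categorical_sample(pssm: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Draw one monomer per position; returns an N x M one-hot matrix."""
    n, m = pssm.shape
    u = rng.random((n, 1))
    idx = (u > np.cumsum(pssm, axis=1)).sum(axis=1)
    idx = np.minimum(idx, m - 1)  # guard against rounding at the last bin
    out = np.zeros((n, m))
    out[np.arange(n), idx] = 1.0
    return out


def argmax_onehot(logits: np.ndarray) -> np.ndarray:
    """Deterministic one-hot at the row-wise argmax (lowest index on ties)."""
    n, m = logits.shape
    out = np.zeros((n, m))
    out[np.arange(n), np.argmax(logits, axis=1)] = 1.0
    return out


@dataclass
class STSample:
    """A discrete sample plus its straight-through backward closure.

    ``onehot`` is the forward value; ``backward(grad_wrt_onehot)`` returns the
    estimator's gradient w.r.t. the logits the sample was drawn from.
    """

    onehot: np.ndarray
    backward: Callable[[np.ndarray], np.ndarray]


def st_sample(
    logits: np.ndarray,
    estimator: EstimatorKind,
    rng: np.random.Generator,
) -> STSample:
    """Sample a one-hot sequence with a straight-through gradient contract."""
    logits = _check_finite(logits, "logits")
    if estimator.kind == "gumbel_softmax":
        gumbel = rng.gumbel(size=logits.shape)
        perturbed = logits + gumbel
        onehot = argmax_onehot(perturbed)
        tempered = softmax_relax(perturbed / estimator.temperature)
        temp = estimator.temperature

        def backward(grad_out: np.ndarray) -> np.ndarray:
            return softmax_vjp(tempered, grad_out) / temp

        return STSample(onehot, backward)

    probs = softmax_relax(logits)
    onehot = categorical_sample(probs, rng)
    if estimator.kind == "softmax_st":
        return STSample(onehot, lambda grad_out: softmax_vjp(probs, grad_out))
    # original_st: identity backward
    return STSample(onehot, lambda grad_out: np.array(grad_out, copy=True))


def expected_onehot(
    logits: np.ndarray, n_draws: int, rng: np.random.Generator
) -> np.ndarray:
    """Monte-Carlo mean of categorical one-hot draws (diagnostic).

    Converges to ``softmax_relax(logits)`` as ``n_draws`` grows.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    probs = softmax_relax(logits)
    total = np.zeros_like(probs)
    for _ in range(n_draws):
        total += categorical_sample(probs, rng)
    return total / n_draws
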