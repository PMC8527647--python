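"""Regularized and composite design objectives.

Activation maximization can drift out of the oracle's training distribution,
where predictions are untrustworthy.  This module provides the standard
counter-measures as penalty terms that compose with any base oracle:

* a likelihood margin (hinge) penalty that activates when a design's
  estimated log10 marginal likelihood falls more than a slack ``rho`` below
  a reference level ``p_ref`` (the mean likelihood of training data);
* a probability-of-improvement objective for oracles that predict both a
  mean and a standard deviation of fitness;
* activity (hinge) penalties on internal activation-map sums of a predictor;
* a KL-divergence structure-matching loss between predicted and target
  residue distance/orientation distribution tensors.

All terms are differentiable through the straight-through contract: the
sampled one-hot pattern is the forward input, and each term exposes an
analytic input gradient.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Protocol, Sequence, runtime_checkable

import numpy as np
from scipy.stats import norm

from .design import Oracle

KL_FLOOR = 1e-8  # predictions are clipped to this before the log-ratio
LN10 = np.log(10.0)


# ---------------------------------------------------------------------------
# Likelihood margin penalty
# ---------------------------------------------------------------------------


@runtime_checkable
class LikelihoodModel(Protocol):
    """Sequence likelihood model contract.

    ``log10_marginal`` returns the (estimated) log10 marginal likelihood of a
    one-hot sequence; for latent-variable models this is an importance-
    weighted estimate, for factorized models it is exact.  ``gradient``
    returns d log10 p / dx for the straight-through backward pass.
    """

    def log10_marginal(self, x: np.ndarray) -> float: ...

    def gradient(self, x: np.ndarray) -> np.ndarray: ...


@dataclass(frozen=True)
class MarginConfig:
    """Reference log10 likelihood, slack margin rho >= 0, weight lam >= 0."""

    p_ref: float
    rho: float = 1.0
    lam: float = 1.0

    def __post_init__(self) -> None:
        if self.rho < 0 or self.lam < 0:
            raise ValueError("rho and lam must be >= 0")


def vae_margin_penalty(
    x: np.ndarray, model: LikelihoodModel, cfg: MarginConfig
) -> float:
    """lam * max(p_ref - log10 p_model(x) - rho, 0)."""
    return cfg.lam * max(cfg.p_ref - model.log10_marginal(x) - cfg.rho, 0.0)


@dataclass
class MarginPenalty:
    """The likelihood hinge as a composable penalty term.

    Zero value and exactly zero gradient whenever the design's likelihood is
    within ``rho`` of the reference.
    """

    model: LikelihoodModel
    cfg: MarginConfig

    def value(self, x: np.ndarray) -> float:
        return vae_margin_penalty(x, self.model, self.cfg)

    def gradient(self, x: np.ndarray) -> np.ndarray:
        active = self.cfg.p_ref - self.model.log10_marginal(x) - self.cfg.rho > 0
        if not active or self.cfg.lam == 0:
            return np.zeros_like(np.asarray(x, dtype=float))
        return -self.cfg.lam * self.model.gradient(x)


# ---------------------------------------------------------------------------
# Probability of improvement
# ---------------------------------------------------------------------------


@runtime_checkable
class UncertaintyOracle(Protocol):
    """Oracle predicting a fitness mean and standard deviation per design."""

    def mean(self, x: np.ndarray) -> float: ...

    def sd(self, x: np.ndarray) -> float: ...

    def mean_gradient(self, x: np.ndarray) -> np.ndarray: ...

    def sd_gradient(self, x: np.ndarray) -> np.ndarray: ...


def pi_objective(mu: float, sd: float, q: float) -> float:
    """-log10 Pr_{Normal(mu, sd)}(Y > q), the probability-of-improvement loss.

    Uses the log-survival function, so extreme tails stay finite and
    numerically stable.
    """
    if sd <= 0:
        raise ValueError("sd must be > 0")
    return float(-norm.logsf(q, loc=mu, scale=sd) / LN10)


def _pi_partials(mu: float, sd: float, q: float) -> tuple[float, float]:
    """Partial derivatives of the PI loss w.r.t. mu and sd."""
    z = (q - mu) / sd
    hazard = np.exp(norm.logpdf(z) - norm.logsf(z))  # phi(z)/SF(z), stable
    d_mu = -hazard / sd / LN10
    d_sd = -hazard * z / sd / LN10
    return float(d_mu), float(d_sd)


@dataclass
class ProbabilityOfImprovementOracle:
    """Maximizes log10 Pr(Y > q) under an uncertainty-estimating oracle.

    ``predict`` returns +log10 Pr(Y > q) (so the design loop, which ascends
    fitness, minimizes the PI loss); gradients chain through the mean and
    standard-deviation heads.
    """

    model: UncertaintyOracle
    q: float

    def predict(self, x: np.ndarray) -> float:
        return -pi_objective(self.model.mean(x), self.model.sd(x), self.q)

    def gradient(self, x: np.ndarray) -> np.ndarray:
        mu, sd = self.model.mean(x), self.model.sd(x)
        d_mu, d_sd = _pi_partials(mu, sd, self.q)
        return -(d_mu * self.model.mean_gradient(x) + d_sd * self.model.sd_gradient(x))


# ---------------------------------------------------------------------------
# Activity penalties
# ---------------------------------------------------------------------------


@dataclass
class ActivityTerm:
    """One internal-activation cap: weight * max(extract(x) - cap, 0)."""

    extract: Callable[[np.ndarray], float]
    cap: float
    weight: float
    extract_gradient: Callable[[np.ndarray], np.ndarray] | None = None

    def __post_init__(self) -> None:
        if self.weight < 0:
            raise ValueError("activity penalty weights must be >= 0")


@dataclass
class ActivityPenaltyConfig:
    terms: Sequence[ActivityTerm] = field(default_factory=tuple)


def activity_penalty(x: np.ndarray, cfg: ActivityPenaltyConfig) -> float:
    """Sum of weighted hinges on activation-map sums exceeding their caps."""
    return sum(
        term.weight * max(float(term.extract(x)) - term.cap, 0.0)
        for term in cfg.terms
    )


@dataclass
class ActivityPenalty:
    cfg: ActivityPenaltyConfig

    def value(self, x: np.ndarray) -> float:
        return activity_penalty(x, self.cfg)

    def gradient(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        g = np.zeros_like(x)
        for term in self.cfg.terms:
            if term.weight == 0 or float(term.extract(x)) <= term.cap:
                continue
            if term.extract_gradient is None:
                raise ValueError("active ActivityTerm needs extract_gradient")
            g += term.weight * term.extract_gradient(x)
        return g


# ---------------------------------------------------------------------------
# Structure-matching KL loss
# ---------------------------------------------------------------------------


@dataclass
class DistributionTensors:
    """Pairwise residue distance/orientation distributions.

    ``distance`` is N x N x 37, ``theta`` and ``omega`` N x N x 24, ``phi``
    N x N x 12; the final axis is a categorical distribution per residue
    pair.
    """

    distance: np.ndarray
    theta: np.ndarray
    omega: np.ndarray
    phi: np.ndarray

    _BINS = {"distance": 37, "theta": 24, "omega": 24, "phi": 12}

    def __post_init__(self) -> None:
        n = self.distance.shape[0]
        for name, bins in self._BINS.items():
            t = np.asarray(getattr(self, name), dtype=float)
            if t.shape != (n, n, bins):
                raise ValueError(
                    f"{name} tensor must have shape ({n}, {n}, {bins}), got {t.shape}"
                )
            if t.min() < -1e-9 or t.max() > 1 + 1e-9:
                raise ValueError(f"{name} entries must lie in [0, 1]")
            sums = t.sum(axis=-1)
            if np.abs(sums - 1).max() > 1e-6:
                raise ValueError(f"{name} final-axis sums must equal 1")
            setattr(self, name, t)

    @property
    def n(self) -> int:
        return self.distance.shape[0]

    def as_dict(self) -> dict[str, np.ndarray]:
        return {name: getattr(self, name) for name in self._BINS}


def _mean_kl(pred: np.ndarray, target: np.ndarray) -> float:
    """(1/N^2) sum_ijk Y_ijk log(Y_ijk / X_ijk), target-weighted."""
    n = pred.shape[0]
    x = np.maximum(pred, KL_FLOOR)
    mask = target > 0  # 0 * log(0/.) := 0
    ratio = np.zeros_like(target)
    ratio[mask] = target[mask] * np.log(target[mask] / x[mask])
    return float(ratio.sum() / n**2)


def _mean_kl_grad(pred: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Gradient of the mean KL term w.r.t. the prediction tensor."""
    n = pred.shape[0]
    grad = np.zeros_like(pred)
    mask = (target > 0) & (pred > KL_FLOOR)
    grad[mask] = -target[mask] / pred[mask] / n**2
    return grad


def kl_structure_loss(pred: DistributionTensors, target: DistributionTensors) -> float:
    """Sum of the four target-weighted mean KL divergences.

    Zero iff prediction equals target (up to the floor); not symmetric in
    its arguments.
    """
    if pred.n != target.n:
        raise ValueError(f"shape mismatch: pred N={pred.n}, target N={target.n}")
    return sum(
        _mean_kl(getattr(pred, name), getattr(target, name))
        for name in DistributionTensors._BINS
    )


def kl_structure_gradients(
    pred: DistributionTensors, target: DistributionTensors
) -> dict[str, np.ndarray]:
    """Per-tensor gradients of the structure loss w.r.t. the predictions."""
    if pred.n != target.n:
        raise ValueError("shape mismatch between prediction and target tensors")
    return {
        name: _mean_kl_grad(getattr(pred, name), getattr(target, name))
        for name in DistributionTensors._BINS
    }


# ---------------------------------------------------------------------------
# Composition
# ---------------------------------------------------------------------------


@runtime_checkable
class PenaltyTerm(Protocol):
    def value(self, x: np.ndarray) -> float: ...

    def gradient(self, x: np.ndarray) -> np.ndarray: ...


@dataclass
class CompositeOracle:
    """Base fitness minus weighted penalties, as a single Oracle."""

    base: Oracle
    penalties: Sequence[PenaltyTerm] = field(default_factory=tuple)

    def predict(self, x: np.ndarray) -> float:
        value = float(self.base.predict(x))
        for pen in self.penalties:
            value -= float(pen.value(x))
        return value

    def gradient(self, x: np.ndarray) -> np.ndarray:
        g = np.asarray(self.base.gradient(x), dtype=float).copy()
        for pen in self.penalties:
            pg = np.asarray(pen.gradient(x), dtype=float)
            if pg.shape != g.shape:
                raise ValueError(
                    f"penalty gradient shape {pg.shape} incompatible with {g.shape}"
                )
            g -= pg
        return g


def composite_objective(
    base: Oracle, penalties: Sequence[PenaltyTerm] = ()
) -> CompositeOracle:
    """Compose a base oracle with penalty terms into one design objective."""
    return CompositeOracle(base=base, penalties=tuple(penalties))
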