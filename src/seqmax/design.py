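"""Activation-maximization design loops and their evaluation protocol.

Four gradient-based methods are provided, all maximizing a differentiable
fitness oracle P over an N x M sequence parameterization:

``pwm``
    optimize the softmax relaxation sigma(l) directly (continuous input);
``fast_pwm``
    as ``pwm`` but with logit normalization and trainable gamma/beta;
``seqprop``
    optimize discrete categorical samples delta(l) with a straight-through
    estimator (no normalization);
``fast_seqprop``
    straight-through sampling on normalized, gamma/beta-scaled logits — the
    fast variant whose entropy parameter gamma adaptively trades global
    exploration against local refinement.

The train loss is -P(x(l)) with x = sigma(l) for the relaxed methods and
x = delta(l) for the sampling methods.  The test loss is always measured on
discrete samples: -(1/(K*S)) sum_k sum_s P(delta(l^(k))^(s)) over K
independent runs and S samples per run.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Protocol, Sequence, runtime_checkable

import numpy as np

from .logits import (
    Alphabet,
    DNA,
    NormalizedLogits,
    ScaleOffset,
    init_logits,
    normalize,
    scale_shift,
)
from .sampling import (
    EstimatorKind,
    STSample,
    argmax_onehot,
    categorical_sample,
    softmax_relax,
    softmax_vjp,
    st_sample,
)

METHODS = ("pwm", "fast_pwm", "seqprop", "fast_seqprop")
GRADIENT_FREE_METHODS = ("evolution", "sa")


class DesignError(RuntimeError):
    """Raised when a design run cannot proceed (e.g. non-finite loss)."""


@runtime_checkable
class Oracle(Protocol):
    """Differentiable fitness function contract.

    ``predict`` maps a real N x M pattern (one-hot or relaxed) to a scalar
    fitness; ``gradient`` returns dP/dx at the same pattern.  Both must be
    deterministic and finite on finite input.
    """

    def predict(self, x: np.ndarray) -> float: ...

    def gradient(self, x: np.ndarray) -> np.ndarray: ...


def numerical_gradient(
    f: Callable[[np.ndarray], float], x: np.ndarray, h: float = 1e-5
) -> np.ndarray:
    """Central finite-difference gradient of a scalar function of a matrix."""
    g = np.zeros_like(x, dtype=float)
    it = np.nditer(x, flags=["multi_index"])
    for _ in it:
        ij = it.multi_index
        xp = x.copy()
        xp[ij] += h
        xm = x.copy()
        xm[ij] -= h
        g[ij] = (f(xp) - f(xm)) / (2 * h)
    return g


@dataclass
class FunctionOracle:
    """Adapter wrapping a plain callable as an Oracle.

    If no gradient function is supplied, central finite differences are used
    (adequate for smooth user oracles; the shipped fixtures provide analytic
    gradients).
    """

    fn: Callable[[np.ndarray], float]
    grad_fn: Callable[[np.ndarray], np.ndarray] | None = None

    def predict(self, x: np.ndarray) -> float:
        return float(self.fn(x))

    def gradient(self, x: np.ndarray) -> np.ndarray:
        if self.grad_fn is not None:
            return np.asarray(self.grad_fn(x), dtype=float)
        return numerical_gradient(self.fn, np.asarray(x, dtype=float))


# ---------------------------------------------------------------------------
# Optimizer
# ---------------------------------------------------------------------------


class Adam:
    """First-order optimizer with adaptive moment estimates."""

    def __init__(
        self,
        learning_rate: float = 0.05,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ) -> None:
        self.lr = learning_rate
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self._m: dict[str, np.ndarray] = {}
        self._v: dict[str, np.ndarray] = {}
        self._t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        """In-place descent step on every parameter given its loss gradient."""
        self._t += 1
        for key, g in grads.items():
            m = self._m.setdefault(key, np.zeros_like(params[key]))
            v = self._v.setdefault(key, np.zeros_like(params[key]))
            m += (1 - self.beta1) * (g - m)
            v += (1 - self.beta2) * (g * g - v)
            mhat = m / (1 - self.beta1**self._t)
            vhat = v / (1 - self.beta2**self._t)
            params[key] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


# ---------------------------------------------------------------------------
# Configuration and results
# ---------------------------------------------------------------------------


@dataclass
class DesignConfig:
    """Configuration of a design experiment.

    ``updates`` (T) gradient steps per run, ``runs`` (K) independent
    optimizations, ``eval_samples`` (S) discrete samples per run for the test
    loss (the benchmark protocol uses K = 10, S = 10), ``grad_samples``
    samples averaged per gradient update.  ``norm_mode`` defaults to instance
    normalization for nucleic alphabets and layer normalization for proteins.
    """

    length: int
    alphabet: Alphabet = DNA
    method: str = "fast_seqprop"
    estimator: EstimatorKind = field(default_factory=EstimatorKind)
    updates: int = 2000
    runs: int = 10
    eval_samples: int = 10
    grad_samples: int = 1
    learning_rate: float = 0.05
    gamma_learning_rate: float | None = None  # None: same as learning_rate
    beta1: float = 0.9
    beta2: float = 0.999
    init_scale: float = 1.0
    norm_mode: str | None = None
    variance_denominator: bool = False
    eval_every: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}; expected {METHODS}")
        for name in ("updates", "runs", "eval_samples", "grad_samples"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.norm_mode is None:
            self.norm_mode = "layer" if self.alphabet.mode == "protein" else "instance"

    @property
    def is_fast(self) -> bool:
        return self.method in ("fast_pwm", "fast_seqprop")

    @property
    def is_sampled(self) -> bool:
        return self.method in ("seqprop", "fast_seqprop")


@dataclass
class DesignResult:
    """Outputs of ``design()``: per-run parameters, sequences, trajectories."""

    config: DesignConfig
    logits: list[np.ndarray]
    scale_offsets: list[ScaleOffset] | None
    effective_logits: list[np.ndarray]
    pssms: list[np.ndarray]
    argmax_sequences: list[str]
    sampled_sequences: list[list[str]]
    train_losses: np.ndarray  # (K, T)
    test_loss_steps: list[int]
    test_losses: np.ndarray  # (K, n_evals), per-run mean over S samples
    gamma_traj: np.ndarray | None  # (K, T) mean gamma per update
    diagnostics: list[list[dict]] | None = None
    stop_steps: list[int | None] | None = None  # first update meeting stop_loss

    @property
    def final_test_loss(self) -> float:
        """Pooled test loss -(1/(K*S)) sum P at the last evaluation."""
        return float(self.test_losses[:, -1].mean())

    def pooled_test_losses(self) -> np.ndarray:
        return self.test_losses.mean(axis=0)


# ---------------------------------------------------------------------------
# Losses
# ---------------------------------------------------------------------------


def _effective_logits(
    l: np.ndarray,
    method: str,
    params: ScaleOffset | None,
    norm_mode: str,
    variance_denominator: bool = False,
) -> tuple[np.ndarray, NormalizedLogits | None]:
    if method in ("fast_pwm", "fast_seqprop"):
        l_norm = normalize(l, norm_mode, variance_denominator=variance_denominator)
        if params is None:
            params = ScaleOffset.init(
                l.shape[1], "instance" if norm_mode == "instance" else "layer"
            )
        return scale_shift(l_norm, params).values, l_norm
    return np.asarray(l, dtype=float), None


def train_loss(
    l: np.ndarray,
    method: str,
    oracle: Oracle,
    rng: np.random.Generator | None = None,
    *,
    params: ScaleOffset | None = None,
    norm_mode: str = "instance",
) -> float:
    """-P(x(l)) with x = sigma(l) (relaxed methods) or delta(l) (sampled)."""
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}")
    eff, _ = _effective_logits(l, method, params, norm_mode)
    if method in ("pwm", "fast_pwm"):
        x = softmax_relax(eff)
    else:
        if rng is None:
            raise ValueError("sampling methods need an rng for the train loss")
        x = categorical_sample(softmax_relax(eff), rng)
    try:
        value = float(oracle.predict(x))
    except Exception as exc:  # surface oracle failures with context
        raise DesignError(f"oracle failed on {method} train loss: {exc}") from exc
    return -value


def test_loss(
    runs_logits: Sequence[np.ndarray],
    oracle: Oracle,
    s: int,
    rng: np.random.Generator,
) -> float:
    """Mean negative fitness over K runs and S discrete samples per run."""
    if s < 1:
        raise ValueError("S must be >= 1")
    total = 0.0
    for l in runs_logits:
        probs = softmax_relax(l)
        for _ in range(s):
            total += oracle.predict(categorical_sample(probs, rng))
    return -total / (len(runs_logits) * s)


# ---------------------------------------------------------------------------
# Gradients
# ---------------------------------------------------------------------------


def _chain_to_params(
    g_eff: np.ndarray,
    l_norm: NormalizedLogits | None,
    params: ScaleOffset | None,
    norm_mode: str,
) -> dict[str, np.ndarray]:
    """Route a gradient at the effective logits back to the trainables.

    For fast methods the normalization statistics are held constant within
    the update, so the backward factor through the normalizer is
    gamma / (sd + guard) and the gamma/beta gradients are the normalized
    logits-weighted and unweighted sums of the upstream signal.
    """
    if l_norm is None:
        return {"l": g_eff}
    if norm_mode == "instance":
        g_gamma = (g_eff * l_norm.values).sum(axis=0)
        g_beta = g_eff.sum(axis=0)
    else:
        g_gamma = np.array([(g_eff * l_norm.values).sum()])
        g_beta = np.array([g_eff.sum()])
    g_l = g_eff * params.gamma / l_norm.denom
    return {"l": g_l, "gamma": g_gamma, "beta": g_beta}


def _ascent_gradients(
    l: np.ndarray,
    config: DesignConfig,
    oracle: Oracle,
    params: ScaleOffset | None,
    rng: np.random.Generator,
) -> tuple[dict[str, np.ndarray], float, np.ndarray, NormalizedLogits | None]:
    """One update's gradients of P w.r.t. the trainables.

    Returns (gradients, mean fitness over drawn samples/pattern, upstream
    gradient at the effective logits, normalized logits or None).
    """
    eff, l_norm = _effective_logits(
        l, config.method, params, config.norm_mode, config.variance_denominator
    )
    if config.method in ("pwm", "fast_pwm"):
        x = softmax_relax(eff)
        fitness = float(oracle.predict(x))
        g_eff = softmax_vjp(x, oracle.gradient(x))
    else:
        g_eff = np.zeros_like(eff)
        fitness = 0.0
        for s_idx in range(config.grad_samples):
            sample: STSample = st_sample(eff, config.estimator, rng)
            fitness += float(oracle.predict(sample.onehot))
            g_eff += sample.backward(oracle.gradient(sample.onehot))
        g_eff /= config.grad_samples
        fitness /= config.grad_samples
    grads = _chain_to_params(g_eff, l_norm, params, config.norm_mode)
    return grads, fitness, g_eff, l_norm


def fast_seqprop_reference_gradients(
    l: np.ndarray,
    params: ScaleOffset,
    grad_p: np.ndarray,
    *,
    norm_mode: str = "instance",
    variance_denominator: bool = False,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Literal closed-form gradients of P for one fast_seqprop update.

    Evaluates, term by term, the printed chain-rule expressions for the
    logit, gamma and beta gradients given the fitness gradient ``grad_p`` at
    the sampled one-hot pattern: the full per-position softmax Jacobian
    contracted with grad_p, then the frozen-statistics normalization factor.
    Kept deliberately independent of the vectorized backward pass so the two
    can be cross-checked.
    """
    n, m = l.shape
    l_norm = normalize(l, norm_mode, variance_denominator=variance_denominator)
    l_scaled = scale_shift(l_norm, params).values
    sig = softmax_relax(l_scaled)
    eye = np.eye(m)
    # jac[i, k, j] = d sigma_ik / d l_ij = sigma_ij * (1[k=j] - sigma_ik)
    jac = sig[:, None, :] * (eye[None, :, :] - sig[:, :, None])
    inner = np.einsum("ik,ikj->ij", grad_p, jac)
    if norm_mode == "instance":
        g_l = inner * params.gamma[None, :] / l_norm.denom[None, :]
        g_gamma = (inner * l_norm.values).sum(axis=0)
        g_beta = inner.sum(axis=0)
    else:
        g_l = inner * params.gamma[0] / l_norm.denom[0]
        g_gamma = np.array([(inner * l_norm.values).sum()])
        g_beta = np.array([inner.sum()])
    return g_l, g_gamma, g_beta


# ---------------------------------------------------------------------------
# The design loop
# ---------------------------------------------------------------------------


def _run_streams(seed: int, run: int) -> tuple[np.random.Generator, Callable]:
    """Deterministic, order-independent per-run random streams.

    The init stream seeds the logits; ``stream(tag, t)`` yields a fresh
    generator for update step or evaluation ``t`` of this run, so the K x S
    evaluation protocol is reproducible regardless of execution order.
    """
    init_rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(run, 0)))

    def stream(tag: int, t: int) -> np.random.Generator:
        return np.random.default_rng(
            np.random.SeedSequence(seed, spawn_key=(run, tag, t))
        )

    return init_rng, stream


def design(
    oracle: Oracle,
    config: DesignConfig,
    *,
    init_logits_list: Sequence[np.ndarray] | None = None,
    record_diagnostics: bool = False,
    stop_loss: float | None = None,
) -> DesignResult:
    """Run K independent activation-maximization optimizations of T updates.

    For the fast methods the trainables are {l, gamma, beta}; otherwise {l}
    only.  Per update, ``grad_samples`` straight-through samples are drawn
    and their gradients averaged (sampling methods).  Raises
    :class:`DesignError` with the step index if the loss turns non-finite.

    ``stop_loss`` enables early stopping for recovery experiments: a run
    halts at the first update after which the loss of the current argmax
    (MAP) design reaches the threshold (recorded in ``stop_steps``;
    trajectories are padded with the last value so their length stays T).
    """
    n, m = config.length, config.alphabet.size
    k_runs, t_updates = config.runs, config.updates
    arity_mode = "instance" if config.norm_mode == "instance" else "layer"

    logits_out: list[np.ndarray] = []
    so_out: list[ScaleOffset] = []
    eff_out: list[np.ndarray] = []
    train_losses = np.zeros((k_runs, t_updates))
    eval_steps = [
        t for t in range(t_updates) if (t + 1) % config.eval_every == 0 or t == t_updates - 1
    ]
    eval_steps = sorted(set(eval_steps))
    test_losses = np.zeros((k_runs, len(eval_steps)))
    gamma_traj = np.zeros((k_runs, t_updates)) if config.is_fast else None
    diagnostics: list[list[dict]] | None = (
        [] if (record_diagnostics and config.method == "fast_seqprop") else None
    )
    stop_steps_out: list[int | None] = []

    for k in range(k_runs):
        init_rng, stream = _run_streams(config.seed, k)
        if init_logits_list is not None:
            l = np.array(init_logits_list[k], dtype=float)
        else:
            l = init_logits(n, m, init_rng, scale=config.init_scale)
        params = ScaleOffset.init(m, arity_mode) if config.is_fast else None
        trainables = {"l": l}
        if config.is_fast:
            trainables["gamma"] = params.gamma
            trainables["beta"] = params.beta
        opt = Adam(config.learning_rate, config.beta1, config.beta2)
        gamma_lr = (
            config.learning_rate
            if config.gamma_learning_rate is None
            else config.gamma_learning_rate
        )
        opt_entropy = Adam(gamma_lr, config.beta1, config.beta2)
        run_diag: list[dict] = []
        eval_cursor = 0
        stop_step: int | None = None

        for t in range(t_updates):
            step_rng = stream(1, t)
            grads, fitness, g_eff, l_norm = _ascent_gradients(
                l, config, oracle, params, step_rng
            )
            loss = -fitness
            if not np.isfinite(loss) or not all(
                np.all(np.isfinite(g)) for g in grads.values()
            ):
                raise DesignError(
                    f"non-finite loss or gradient at step {t} of run {k} "
                    f"(method {config.method})"
                )
            train_losses[k, t] = loss
            if diagnostics is not None:
                g_gamma = grads["gamma"]
                mask = l_norm.values != 0
                consistent = np.sign(g_eff[mask]) == np.sign(l_norm.values[mask])
                run_diag.append(
                    {
                        "step": t,
                        "gamma_grad": g_gamma.copy(),
                        "gamma_grad_sign": np.sign(g_gamma).tolist(),
                        "frac_consistent": float(consistent.mean())
                        if consistent.size
                        else 0.0,
                    }
                )
            # descend the loss = ascend the fitness; the entropy parameters
            # may anneal on their own (slower) schedule
            loss_grads = {key: -g for key, g in grads.items()}
            opt.step({"l": trainables["l"]}, {"l": loss_grads["l"]})
            if config.is_fast:
                opt_entropy.step(
                    {k: trainables[k] for k in ("gamma", "beta")},
                    {k: loss_grads[k] for k in ("gamma", "beta")},
                )
            if config.is_fast:
                gamma_traj[k, t] = float(trainables["gamma"].mean())
            if stop_loss is not None:
                eff, _ = _effective_logits(
                    l, config.method, params, config.norm_mode,
                    config.variance_denominator,
                )
                if -float(oracle.predict(argmax_onehot(eff))) <= stop_loss:
                    stop_step = t
            if eval_cursor < len(eval_steps) and t == eval_steps[eval_cursor]:
                eff, _ = _effective_logits(
                    l, config.method, params, config.norm_mode,
                    config.variance_denominator,
                )
                test_losses[k, eval_cursor] = test_loss(
                    [eff], oracle, config.eval_samples, stream(2, t)
                )
                eval_cursor += 1
            if stop_step is not None:
                break

        if stop_step is not None:  # pad trajectories to length T
            train_losses[k, stop_step + 1 :] = train_losses[k, stop_step]
            if gamma_traj is not None:
                gamma_traj[k, stop_step + 1 :] = gamma_traj[k, stop_step]
            if eval_cursor < len(eval_steps):
                eff, _ = _effective_logits(
                    l, config.method, params, config.norm_mode,
                    config.variance_denominator,
                )
                final_eval = test_loss(
                    [eff], oracle, config.eval_samples, stream(2, stop_step)
                )
                test_losses[k, eval_cursor:] = final_eval
        stop_steps_out.append(stop_step)

        eff, _ = _effective_logits(
            l, config.method, params, config.norm_mode, config.variance_denominator
        )
        logits_out.append(l)
        eff_out.append(eff)
        if config.is_fast:
            so_out.append(params)
        if diagnostics is not None:
            diagnostics.append(run_diag)

    pssms = [softmax_relax(eff) for eff in eff_out]
    argmax_seqs = [config.alphabet.decode(argmax_onehot(eff)) for eff in eff_out]
    sampled: list[list[str]] = []
    for k, eff in enumerate(eff_out):
        _, stream = _run_streams(config.seed, k)
        rng = stream(3, 0)
        probs = softmax_relax(eff)
        sampled.append(
            [
                config.alphabet.decode(categorical_sample(probs, rng))
                for _ in range(config.eval_samples)
            ]
        )

    return DesignResult(
        config=config,
        logits=logits_out,
        scale_offsets=so_out if config.is_fast else None,
        effective_logits=eff_out,
        pssms=pssms,
        argmax_sequences=argmax_seqs,
        sampled_sequences=sampled,
        train_losses=train_losses,
        test_loss_steps=eval_steps,
        test_losses=test_losses,
        gamma_traj=gamma_traj,
        diagnostics=diagnostics,
        stop_steps=stop_steps_out,
    )


def entropy_diagnostics(result: DesignResult) -> list[list[dict]]:
    """Per-update gamma-gradient/consistency report for a fast_seqprop run.

    Exposes the adaptive-temperature mechanism: the gamma gradient component
    is positive exactly when the upstream fitness signal at the effective
    logits is sign-consistent with the normalized logits (confident, fitness-
    raising monomers push gamma up and lower the sampling entropy; sampled
    inconsistencies push it down, re-raising entropy).
    """
    if result.config.method != "fast_seqprop":
        raise ValueError("entropy diagnostics are defined for fast_seqprop results")
    if result.diagnostics is None:
        raise ValueError("run design() with record_diagnostics=True first")
    return result.diagnostics
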