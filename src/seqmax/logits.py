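"""Trainable sequence-distribution logits and their normalization transforms.

A designed sequence is parameterized by an ``N x M`` matrix of real-valued
logits ``l`` (N positions, M monomer channels).  The "fast" design variants
standardize these logits before the softmax/sampling layers: *instance*
normalization standardizes each channel independently across positions (the
DNA setting, where M is small), *layer* normalization standardizes all N*M
entries jointly (the protein setting, where M = 20 and sequences are short).
Normalized logits are then re-expanded by trainable entropy parameters
``gamma`` (scale) and ``beta`` (offset).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

# Denominator stabilizer: channels whose deviation falls below this floor
# are treated as constant (they normalize to zero).  A floor rather than an
# additive term keeps normalization exactly invariant to positive affine
# maps of any non-degenerate channel.
EPS_GUARD = 1e-6

DNA_SYMBOLS = "ACGT"
PROTEIN_SYMBOLS = "ACDEFGHIKLMNPQRSTVWY"  # canonical residues, alphabetical


@dataclass(frozen=True)
class Alphabet:
    """Ordered monomer alphabet.

    ``mode`` is ``"nucleic"`` (M=4), ``"protein"`` (M=20) or ``"custom"``
    for toy landscapes with arbitrary M >= 2.
    """

    symbols: str
    mode: str = "custom"

    def __post_init__(self) -> None:
        if len(set(self.symbols)) != len(self.symbols):
            raise ValueError("alphabet symbols must be unique")
        if len(self.symbols) < 2:
            raise ValueError("alphabet needs at least 2 symbols")
        if self.mode == "nucleic" and len(self.symbols) != 4:
            raise ValueError("nucleic alphabets have M=4")
        if self.mode == "protein" and len(self.symbols) != 20:
            raise ValueError("protein alphabets have M=20")

    @property
    def size(self) -> int:
        return len(self.symbols)

    def index(self, symbol: str) -> int:
        return self.symbols.index(symbol)

    def decode(self, onehot: np.ndarray) -> str:
        """One-hot N x M pattern -> string."""
        idx = np.argmax(onehot, axis=1)
        return "".join(self.symbols[i] for i in idx)

    def encode(self, sequence: str) -> np.ndarray:
        """String -> one-hot N x M pattern."""
        out = np.zeros((len(sequence), self.size))
        for i, ch in enumerate(sequence):
            out[i, self.index(ch)] = 1.0
        return out


DNA = Alphabet(DNA_SYMBOLS, "nucleic")
PROTEIN = Alphabet(PROTEIN_SYMBOLS, "protein")


def alphabet_by_name(name: str) -> Alphabet:
    try:
        return {"dna": DNA, "rna": DNA, "protein": PROTEIN}[name.lower()]
    except KeyError:
        raise ValueError(f"unknown alphabet {name!r}; use 'dna' or 'protein'")


@dataclass
class ScaleOffset:
    """Trainable entropy parameters.

    ``gamma`` scales the normalized logits (controls sampling temperature:
    larger gamma -> lower entropy) and ``beta`` re-centers them (captures a
    global per-channel composition bias).  In instance mode both are vectors
    of length M; in layer mode both are scalars stored as length-1 arrays.
    """

    gamma: np.ndarray
    beta: np.ndarray

    @classmethod
    def init(cls, n_channels: int, mode: str = "instance") -> "ScaleOffset":
        arity = n_channels if mode == "instance" else 1
        return cls(gamma=np.ones(arity), beta=np.zeros(arity))

    @property
    def arity(self) -> int:
        return self.gamma.shape[0]


@dataclass
class NormalizedLogits:
    """Standardized logits together with the statistics that produced them.

    ``mu`` and ``sd`` have length M (instance mode) or 1 (layer mode).
    """

    values: np.ndarray
    mu: np.ndarray
    sd: np.ndarray
    mode: str = "instance"
    denom: np.ndarray = field(default=None)  # actual denominator used

    @property
    def shape(self):
        return self.values.shape


def _check_finite(values: np.ndarray, what: str) -> np.ndarray:
    values = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(values)):
        bad = np.argwhere(~np.isfinite(values))[0]
        raise ValueError(f"non-finite {what} at index {tuple(bad)}")
    return values


def instance_normalize(
    logits: np.ndarray, *, variance_denominator: bool = False
) -> NormalizedLogits:
    """Standardize each channel to zero mean and unit s.d. across positions.

    ``variance_denominator=True`` divides by the squared deviation instead of
    the deviation (a literal reading of one printed formula variant); the
    default preserves the unit-variance property of the normalized logits.
    Uses the population (1/N) deviation; the denominator is floored at
    ``EPS_GUARD`` so constant channels map to zero.
    """
    logits = _check_finite(logits, "logits")
    if logits.ndim != 2 or logits.shape[0] < 1:
        raise ValueError("logits must be an N x M matrix with N >= 1")
    mu = logits.mean(axis=0)
    sd = logits.std(axis=0)
    denom = np.maximum(sd**2 if variance_denominator else sd, EPS_GUARD)
    values = (logits - mu) / denom
    return NormalizedLogits(values, mu=mu, sd=sd, mode="instance", denom=denom)


def layer_normalize(
    logits: np.ndarray, *, variance_denominator: bool = False
) -> NormalizedLogits:
    """Standardize all N*M entries jointly by the global mean and s.d."""
    logits = _check_finite(logits, "logits")
    if logits.ndim != 2 or logits.size < 2:
        raise ValueError("logits must be an N x M matrix with N*M >= 2")
    mu = np.array([logits.mean()])
    sd = np.array([logits.std()])
    denom = np.maximum(sd**2 if variance_denominator else sd, EPS_GUARD)
    values = (logits - mu) / denom
    return NormalizedLogits(values, mu=mu, sd=sd, mode="layer", denom=denom)


def normalize(
    logits: np.ndarray, mode: str, *, variance_denominator: bool = False
) -> NormalizedLogits:
    if mode == "instance":
        return instance_normalize(logits, variance_denominator=variance_denominator)
    if mode == "layer":
        return layer_normalize(logits, variance_denominator=variance_denominator)
    raise ValueError(f"unknown normalization mode {mode!r}")


def scale_shift(l_norm: NormalizedLogits, params: ScaleOffset) -> NormalizedLogits:
    """Apply the trainable affine expansion l_norm * gamma + beta.

    Instance mode broadcasts per channel; layer mode applies one scalar pair.
    """
    n_channels = l_norm.values.shape[1]
    expected = n_channels if l_norm.mode == "instance" else 1
    if params.arity != expected:
        raise ValueError(
            f"scale/offset arity {params.arity} does not match "
            f"{l_norm.mode} mode (expected {expected})"
        )
    values = l_norm.values * params.gamma + params.beta
    return NormalizedLogits(
        values, mu=l_norm.mu, sd=l_norm.sd, mode=l_norm.mode, denom=l_norm.denom
    )


def init_logits(
    n: int, m: int, rng: np.random.Generator, *, scale: float = 1.0
) -> np.ndarray:
    """Uniform random initialization on [-scale, scale]."""
    return rng.uniform(-scale, scale, size=(n, m))
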