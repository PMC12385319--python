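"""Bandt–Pompe ordinal-pattern encoding with quasi-non-overlapping windows.

A univariate signal ``{x_t}`` is divided into embedded vectors of ``D``
samples spaced ``tau`` apart.  Consecutive windows share exactly one sample
(stride ``(D-1)*tau``), so the encoding covers the whole signal with no
redundancy between consecutive patterns.  Each vector is mapped to an
ordinal-pattern (OP) symbol in ``1..D!`` that identifies the rank arrangement
of its components: the symbol is one plus the lexicographic (Lehmer) rank of
the permutation that sorts the vector ascending, so an increasing vector maps
to 1 and a decreasing one to ``D!``.  For ``D=2`` this is the familiar
"up -> 1, down -> 2" convention.

Magnitudes are *not* discarded: :func:`encode` returns the embedded vectors
alongside the symbol sequence so that within-pattern variability statistics
can be computed downstream.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "Signal",
    "EmbeddingConfig",
    "EmbeddedVectorSet",
    "SymbolSequence",
    "embed",
    "rank_pattern",
    "rank_patterns",
    "encode",
    "dither",
    "quantisation_amplitude",
    "resample",
    "TieWarning",
]


class TieWarning(UserWarning):
    """Emitted when tied magnitudes are broken by temporal order."""


@dataclass(frozen=True)
class Signal:
    """An ordered sequence of real magnitudes.

    Parameters
    ----------
    values
        One-dimensional array of finite magnitudes (arbitrary units).
    label
        Optional free-text provenance tag.
    """

    values: np.ndarray
    label: Optional[str] = None

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=np.float64)
        if arr.ndim != 1:
            raise ValueError(f"signal must be one-dimensional, got shape {arr.shape}")
        if arr.size < 1:
            raise ValueError("signal must contain at least one sample")
        if not np.all(np.isfinite(arr)):
            bad = int(np.flatnonzero(~np.isfinite(arr))[0])
            raise ValueError(f"signal contains a non-finite value at index {bad}")
        object.__setattr__(self, "values", arr)

    def __len__(self) -> int:
        return self.values.size

    @property
    def T(self) -> int:
        """Signal length."""
        return self.values.size


@dataclass(frozen=True)
class EmbeddingConfig:
    """Embedding dimension ``D`` and delay ``tau`` plus derived window geometry.

    ``stride = (D-1)*tau`` is the spacing between window starts, which makes
    consecutive windows share exactly one sample.  ``n_windows(T)`` gives the
    number of *complete* windows; incomplete tail windows are dropped.
    """

    D: int
    tau: int = 1

    def __post_init__(self) -> None:
        if int(self.D) != self.D or self.D < 2:
            raise ValueError(f"embedding dimension D must be an integer >= 2, got {self.D}")
        if int(self.tau) != self.tau or self.tau < 1:
            raise ValueError(f"embedding delay tau must be an integer >= 1, got {self.tau}")
        object.__setattr__(self, "D", int(self.D))
        object.__setattr__(self, "tau", int(self.tau))

    @property
    def stride(self) -> int:
        return (self.D - 1) * self.tau

    @property
    def min_length(self) -> int:
        """Shortest signal that yields one complete window."""
        return (self.D - 1) * self.tau + 1

    @property
    def n_patterns(self) -> int:
        """Number of possible OP symbols, ``D!``."""
        return math.factorial(self.D)

    def n_windows(self, T: int) -> int:
        """Number of complete windows in a signal of length ``T``."""
        if T < self.min_length:
            return 0
        return (T - 1) // self.stride


@dataclass(frozen=True)
class EmbeddedVectorSet:
    """The ``m x D`` matrix of embedded vectors with their start indices."""

    vectors: np.ndarray
    start_indices: np.ndarray
    config: EmbeddingConfig

    @property
    def m(self) -> int:
        return self.vectors.shape[0]


@dataclass(frozen=True)
class SymbolSequence:
    """Sequence of OP symbols, each in ``1..D!``."""

    symbols: np.ndarray
    config: EmbeddingConfig
    tie_fraction: float = 0.0

    @property
    def m(self) -> int:
        return self.symbols.size


def embed(signal: Signal, config: EmbeddingConfig) -> EmbeddedVectorSet:
    """Divide a signal into quasi-non-overlapping embedded vectors.

    Window ``i`` (0-based) starts at sample ``i*(D-1)*tau`` and contains ``D``
    samples spaced ``tau`` apart; only complete windows are produced, so for
    ``tau = 1`` consecutive windows share exactly one sample.  A note is
    logged (via :mod:`warnings` at the encode level) when tail samples are
    discarded.
    """
    T = signal.T
    if T < config.min_length:
        raise ValueError(
            f"signal of length {T} is too short for D={config.D}, tau={config.tau}; "
            f"at least {config.min_length} samples are required"
        )
    m = config.n_windows(T)
    starts = np.arange(m) * config.stride
    idx = starts[:, None] + config.tau * np.arange(config.D)[None, :]
    return EmbeddedVectorSet(vectors=signal.values[idx], start_indices=starts, config=config)


def _sorting_permutations(vectors: np.ndarray, tie_rule: str) -> np.ndarray:
    if tie_rule != "temporal":
        raise ValueError(f"unknown tie_rule {tie_rule!r}; only 'temporal' is supported")
    # stable sort: equal magnitudes keep temporal order, i.e. earlier = smaller
    return np.argsort(vectors, axis=1, kind="stable")


def rank_patterns(vectors: np.ndarray, tie_rule: str = "temporal") -> np.ndarray:
    """Vectorised OP labelling of an ``m x D`` matrix of embedded vectors.

    The label is ``1 +`` the lexicographic rank (Lehmer code) of the
    permutation that sorts each row ascending.  Ties are broken by temporal
    order (the earlier sample counts as smaller).
    """
    vectors = np.asarray(vectors, dtype=np.float64)
    if vectors.ndim != 2:
        raise ValueError("expected an m x D matrix of embedded vectors")
    if not np.all(np.isfinite(vectors)):
        raise ValueError("embedded vectors contain non-finite values; dither or clean the signal")
    D = vectors.shape[1]
    if D < 2:
        raise ValueError("embedding dimension must be >= 2")
    perm = _sorting_permutations(vectors, tie_rule)
    rank = np.zeros(vectors.shape[0], dtype=np.int64)
    for i in range(D - 1):
        smaller_later = (perm[:, i + 1 :] < perm[:, i : i + 1]).sum(axis=1)
        rank += smaller_later * math.factorial(D - 1 - i)
    return rank + 1


def rank_pattern(vector: Sequence[float], tie_rule: str = "temporal") -> int:
    """OP label in ``1..D!`` of a single embedded vector."""
    arr = np.asarray(vector, dtype=np.float64)
    return int(rank_patterns(arr[None, :], tie_rule=tie_rule)[0])


def _tie_fraction(vectors: np.ndarray) -> float:
    srt = np.sort(vectors, axis=1)
    has_tie = (np.diff(srt, axis=1) == 0.0).any(axis=1)
    return float(has_tie.mean()) if vectors.shape[0] else 0.0


def encode(
    signal: Signal,
    config: EmbeddingConfig,
    tie_rule: str = "temporal",
) -> tuple[SymbolSequence, EmbeddedVectorSet]:
    """Encode a signal into an OP symbol sequence, keeping the magnitudes.

    Returns the symbol sequence and the embedded vectors it was derived from;
    the vectors are needed for within-pattern variability statistics.  A
    :class:`TieWarning` reports the fraction of windows containing tied
    magnitudes (ties are broken by temporal order).
    """
    vset = embed(signal, config)
    tie_frac = _tie_fraction(vset.vectors)
    if tie_frac > 0.0:
        warnings.warn(
            f"{tie_frac:.2%} of windows contain tied magnitudes; ties broken by "
            "temporal order (consider dither() for quantised signals)",
            TieWarning,
            stacklevel=2,
        )
    symbols = rank_patterns(vset.vectors, tie_rule=tie_rule)
    return SymbolSequence(symbols=symbols, config=config, tie_fraction=tie_frac), vset


def quantisation_amplitude(signal: Signal, bits: int = 16) -> float:
    """Dither amplitude for a quantised signal: ``range(signal) * 2**-bits``."""
    return float(np.ptp(signal.values)) * 2.0 ** (-bits)


def dither(
    signal: Signal,
    amplitude: float,
    seed: Optional[int] = None,
    distribution: str = "gaussian",
) -> Signal:
    """Add tiny white noise to break magnitude degeneracies before ranking.

    ``distribution='gaussian'`` (default) adds zero-mean Gaussian noise with
    standard deviation ``amplitude``; ``'uniform'`` adds noise drawn uniformly
    from ``[-amplitude, amplitude]``.  ``amplitude=0`` returns the signal
    unchanged.
    """
    if amplitude < 0:
        raise ValueError("dither amplitude must be >= 0")
    if amplitude == 0:
        return Signal(signal.values.copy(), label=signal.label)
    rng = np.random.default_rng(seed)
    if distribution == "gaussian":
        noise = rng.normal(0.0, amplitude, signal.T)
    elif distribution == "uniform":
        noise = rng.uniform(-amplitude, amplitude, signal.T)
    else:
        raise ValueError(f"unknown dither distribution {distribution!r}")
    return Signal(signal.values + noise, label=signal.label)


def resample(signal: Signal, tau: int) -> Signal:
    """Subsample a signal with delay ``tau``: keeps indices ``0, tau, 2*tau, ...``

    The result has length ``n + 1`` with ``n = floor((T-1)/tau)``.
    """
    if int(tau) != tau or tau < 1:
        raise ValueError(f"tau must be an integer >= 1, got {tau}")
    if tau == 1:
        return Signal(signal.values.copy(), label=signal.label)
    return Signal(signal.values[::tau].copy(), label=signal.label)
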