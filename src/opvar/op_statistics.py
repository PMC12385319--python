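"""Ordinal-pattern statistics: entropies and within-pattern magnitude variability.

From the OP symbol distribution ``{P(alpha)}`` this module computes

* the permutation entropy ``H = -sum_alpha P(alpha) log2 P(alpha)`` (bits),
* the Renyi min-entropy ``H_inf = -log2 max_alpha P(alpha)`` (bits), the
  ``q -> inf`` limit of the Renyi family and a lower bound of it,
* the magnitude-variability panel: ``sigma_j(alpha)``, the standard deviation
  of the signal magnitudes at component ``j`` over all embedded vectors whose
  symbol is ``alpha``; its OP-weighted log mean
  ``<log2 sigma_j> = sum_alpha P(alpha) log2 sigma_j(alpha)``; and the
  component average ``avg_j{<log2 sigma_j>}``, which recovers the magnitude
  information the ordinal encoding otherwise discards.

Patterns with fewer than two occurrences (sigma undefined) or zero spread
(log2 0 = -inf) are excluded from the weighted means and the weights are
renormalised over the included patterns; the excluded probability mass is
reported.  For long signals and moderate D the excluded mass is negligible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .ordinal_encoding import (
    EmbeddedVectorSet,
    EmbeddingConfig,
    Signal,
    SymbolSequence,
    encode,
)

__all__ = [
    "OPDistribution",
    "EntropyPanel",
    "VariabilityPanel",
    "SummaryResult",
    "distribution",
    "permutation_entropy",
    "renyi_entropy",
    "min_entropy",
    "magnitude_variability",
    "summarize",
]


@dataclass(frozen=True)
class OPDistribution:
    """Counts and relative frequencies of the ``D!`` ordinal patterns."""

    counts: np.ndarray
    D: int

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        if counts.size != math.factorial(self.D):
            raise ValueError(
                f"expected {math.factorial(self.D)} counts for D={self.D}, got {counts.size}"
            )
        if (counts < 0).any():
            raise ValueError("counts must be non-negative")
        if counts.sum() == 0:
            raise ValueError("empty symbol sequence: no patterns to count")
        object.__setattr__(self, "counts", counts)

    @property
    def m(self) -> int:
        """Total number of symbols."""
        return int(self.counts.sum())

    @property
    def probabilities(self) -> np.ndarray:
        return self.counts / self.m


@dataclass(frozen=True)
class EntropyPanel:
    """Permutation entropy, Renyi min-entropy and the max-entropy, in bits."""

    H: float
    H_inf: float
    H_max: float


@dataclass(frozen=True)
class VariabilityPanel:
    """Per-pattern magnitude spreads and their OP-weighted log2 summaries.

    Attributes
    ----------
    sigma
        ``D! x D`` matrix of spreads ``sigma_j(alpha)`` (signal units); NaN
        where undefined (pattern seen fewer than twice).
    mean_log_sigma
        ``<log2 sigma_j>`` per component ``j`` (length ``D``).
    avg
        ``avg_j{<log2 sigma_j>}``, the headline scalar.
    dispersion
        Weighted standard deviation of ``log2 sigma_j(alpha)`` under
        ``P(alpha)`` per component (the error-bar quantity).
    included_mask
        Which patterns entered the weighted means.
    excluded_mass
        Probability mass of the excluded patterns (before renormalisation).
    """

    sigma: np.ndarray
    mean_log_sigma: np.ndarray
    avg: float
    dispersion: np.ndarray
    included_mask: np.ndarray
    excluded_mass: float
    estimator: str = "std"


@dataclass(frozen=True)
class SummaryResult:
    """One-call pipeline output: encode -> distribution -> entropies -> variability."""

    entropy: EntropyPanel
    variability: VariabilityPanel
    distribution: OPDistribution
    provenance: dict


def distribution(symbols: SymbolSequence) -> OPDistribution:
    """Count the OP symbols into a distribution over ``1..D!``."""
    if symbols.m == 0:
        raise ValueError("cannot build a distribution from an empty symbol sequence")
    n_pat = symbols.config.n_patterns
    counts = np.bincount(symbols.symbols, minlength=n_pat + 1)[1:]
    return OPDistribution(counts=counts, D=symbols.config.D)


def permutation_entropy(dist: OPDistribution) -> float:
    """Shannon entropy of the OP distribution, in bits; ``0 log(1/0) = 0``."""
    p = dist.probabilities
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def min_entropy(dist: OPDistribution) -> float:
    """Renyi min-entropy ``-log2 max_alpha P(alpha)``, in bits."""
    return float(-np.log2(dist.probabilities.max()))


def renyi_entropy(dist: OPDistribution, q: float) -> float:
    """Renyi entropy of order ``q`` in bits: ``(1/(1-q)) log2 sum P^q``.

    Tends to the permutation entropy as ``q -> 1`` (use
    :func:`permutation_entropy` there) and to the min-entropy as ``q -> inf``.
    """
    if q <= 0:
        raise ValueError("Renyi order q must be positive")
    if q == 1:
        raise ValueError("q=1 is the Shannon limit; use permutation_entropy")
    if math.isinf(q):
        return min_entropy(dist)
    p = dist.probabilities
    p = p[p > 0]
    return float(np.log2((p**q).sum()) / (1.0 - q))


def _group_spreads(
    vectors: np.ndarray, symbols: np.ndarray, n_patterns: int, estimator: str
) -> tuple[np.ndarray, np.ndarray]:
    """Per-pattern, per-component spread estimates.

    Returns ``(sigma, counts)`` where ``sigma`` is ``D! x D`` with NaN for
    patterns seen fewer than twice.  ``estimator='std'`` is the sample
    standard deviation (ddof=1); ``'iqr'`` the inter-quartile range, a robust
    alternative for short, outlier-prone signals.
    """
    m, D = vectors.shape
    counts = np.bincount(symbols, minlength=n_patterns + 1)[1:]
    order = np.argsort(symbols, kind="stable")
    sorted_vecs = vectors[order]
    offsets = np.concatenate(([0], np.cumsum(counts)))
    sigma = np.full((n_patterns, D), np.nan)
    occupied = np.flatnonzero(counts >= 2)
    if estimator == "std":
        # two-pass (mean then centred squares) per group for numerical safety;
        # reduceat runs over the nonempty groups only (their start offsets are
        # strictly increasing and in range), then scatters back
        group_of = np.repeat(np.arange(n_patterns), counts)
        nonempty = np.flatnonzero(counts > 0)
        starts = offsets[:-1][nonempty]
        means = np.zeros((n_patterns, D))
        means[nonempty] = np.add.reduceat(sorted_vecs, starts, axis=0) / counts[
            nonempty, None
        ]
        centred = sorted_vecs - means[group_of]
        ssq = np.add.reduceat(centred**2, starts, axis=0)
        keep = counts[nonempty] >= 2
        sigma[nonempty[keep]] = np.sqrt(ssq[keep] / (counts[nonempty[keep], None] - 1))
    elif estimator == "iqr":
        for a in occupied:
            sub = sorted_vecs[offsets[a] : offsets[a + 1]]
            q25, q75 = np.percentile(sub, [25.0, 75.0], axis=0)
            sigma[a] = q75 - q25
    else:
        raise ValueError(f"unknown spread estimator {estimator!r}; use 'std' or 'iqr'")
    return sigma, counts


def magnitude_variability(
    vectors: EmbeddedVectorSet,
    symbols: SymbolSequence,
    estimator: str = "std",
) -> VariabilityPanel:
    """Within-pattern magnitude variability of an encoded signal.

    ``vectors`` and ``symbols`` must come from the same :func:`~opvar.ordinal_encoding.encode`
    call.  Patterns with undefined or zero spread are excluded and the OP
    weights renormalised over the rest.
    """
    if vectors.m != symbols.m:
        raise ValueError("vectors and symbols have different lengths; encode them together")
    n_pat = symbols.config.n_patterns
    sigma, counts = _group_spreads(vectors.vectors, symbols.symbols, n_pat, estimator)
    p = counts / counts.sum()
    defined = counts >= 2
    with np.errstate(invalid="ignore"):
        positive = defined & np.all(sigma > 0, axis=1)
    if not positive.any():
        raise ValueError(
            "insufficient data for variability: every ordinal pattern has fewer "
            "than two occurrences or zero spread"
        )
    excluded_mass = float(p[~positive].sum())
    w = p[positive] / p[positive].sum()
    log_sigma = np.log2(sigma[positive])
    mean_log = w @ log_sigma
    second = w @ log_sigma**2
    dispersion = np.sqrt(np.maximum(second - mean_log**2, 0.0))
    return VariabilityPanel(
        sigma=sigma,
        mean_log_sigma=mean_log,
        avg=float(mean_log.mean()),
        dispersion=dispersion,
        included_mask=positive,
        excluded_mass=excluded_mass,
        estimator=estimator,
    )


def summarize(
    signal: Signal,
    config: EmbeddingConfig,
    tie_rule: str = "temporal",
    estimator: str = "std",
) -> SummaryResult:
    """Full OP characterisation of a signal: entropies plus variability panel."""
    symbols, vset = encode(signal, config, tie_rule=tie_rule)
    dist = distribution(symbols)
    panel = EntropyPanel(
        H=permutation_entropy(dist),
        H_inf=min_entropy(dist),
        H_max=math.log2(config.n_patterns),
    )
    var = magnitude_variability(vset, symbols, estimator=estimator)
    provenance = {
        "D": config.D,
        "tau": config.tau,
        "T": signal.T,
        "m": symbols.m,
        "tie_fraction": symbols.tie_fraction,
        "excluded_op_mass": var.excluded_mass,
        "estimator": estimator,
        "tie_rule": tie_rule,
        "label": signal.label,
    }
    return SummaryResult(entropy=panel, variability=var, distribution=dist, provenance=provenance)
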