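"""Scaling of the magnitude variability with embedding dimension and noise.

For deterministic (chaotic) signals, ``avg_j{<log2 sigma_j>}`` decays as a
power law in ``D*tau`` with a steep exponent, while observational noise
flattens the decay towards the -1/2 slope of uncorrelated noise.  Sweeping
the embedding dimension at several noise strengths and fitting the slope of
``avg`` against ``log2(D*tau)`` therefore discriminates deterministic-like
from noise-like signals.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np

from .map_simulators import NoiseSpec, add_observational_noise
from .op_statistics import summarize
from .ordinal_encoding import EmbeddingConfig, Signal

__all__ = ["ScalingCurve", "scaling_sweep", "classify_regime"]


@dataclass(frozen=True)
class ScalingCurve:
    """avg_j{<log2 sigma_j>} versus D*tau at one noise level, with its power-law fit."""

    points: tuple  # of (D, tau, avg) triples, sorted by D*tau
    slope: float
    intercept: float
    fit_range: tuple  # D values that entered the fit
    noise_std: float

    def avg_at(self, D: int) -> float:
        for d, _, avg in self.points:
            if d == D:
                return avg
        raise KeyError(f"no point for D={D}")


def _fit_slope(points, fit_range):
    xs = np.log2([d * t for d, t, _ in points if d in fit_range])
    ys = np.array([avg for d, _, avg in points if d in fit_range])
    if xs.size < 3:
        raise ValueError("power-law fit needs at least 3 points in fit_range")
    slope, intercept = np.polyfit(xs, ys, 1)
    return float(slope), float(intercept)


def scaling_sweep(
    signal_factory: Callable[[], Signal],
    D_values: Sequence[int],
    tau: int = 1,
    noise_specs: Sequence[NoiseSpec] = (NoiseSpec(0.0),),
    fit_range: Optional[Sequence[int]] = None,
    estimator: str = "std",
) -> list[ScalingCurve]:
    """Sweep D (and noise strength) and fit the power-law slope of ``avg``.

    For each noise spec the base signal is regenerated via ``signal_factory``
    and one noise realisation is shared across all D values, so the sweep
    varies only the encoding.  The slope is an ordinary least-squares fit of
    ``avg`` against ``log2(D*tau)`` over ``fit_range`` (default: all of
    ``D_values``).
    """
    D_values = sorted(int(d) for d in D_values)
    if any(d < 2 for d in D_values):
        raise ValueError("every embedding dimension must be >= 2")
    fit_range = tuple(D_values if fit_range is None else sorted(int(d) for d in fit_range))
    curves = []
    for spec in noise_specs:
        base = signal_factory()
        noisy = add_observational_noise(base, spec)
        points = []
        for D in D_values:
            res = summarize(noisy, EmbeddingConfig(D=D, tau=tau), estimator=estimator)
            points.append((D, tau, res.variability.avg))
        slope, intercept = _fit_slope(points, fit_range)
        curves.append(
            ScalingCurve(
                points=tuple(points),
                slope=slope,
                intercept=intercept,
                fit_range=fit_range,
                noise_std=spec.std,
            )
        )
    return curves


def classify_regime(curve: ScalingCurve, threshold_slope: float = -1.0) -> str:
    """Label a scaling curve as deterministic-like or noise-like.

    Slopes strictly steeper (more negative) than the threshold are
    deterministic-like; a slope exactly at the threshold is noise-like.
    """
    return "deterministic-like" if curve.slope < threshold_slope else "noise-like"
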