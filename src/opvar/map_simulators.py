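"""Chaotic-map trajectory generators: coupled logistic maps and the Henon map.

Coupled identical logistic maps:

    x_{t+1} = (1 - eps) f(x_t) + eps f(y_t)
    y_{t+1} = (1 - eps) f(y_t) + eps f(x_t),   f(z) = r z (1 - z)

with control parameter ``r`` in (3, 4] and coupling strength ``eps`` in
[0, 1].  At ``eps = 0`` the two maps are isolated logistic maps; for
``eps > 0`` the coupling can produce intermittent and more complex regimes.

Henon map:

    x_{t+1} = 1 - a x_t**2 + y_t
    y_{t+1} = b x_t

periodic e.g. at (a, b) = (1.0, 0.3), chaotic e.g. at (1.4, 0.3).

Default configuration: initial state (x1, y1) = (0.65, 0.44), a transient of
10**3 iterations discarded, and 10**6 retained samples.  Observational noise
(i.i.d. Gaussian, added to the retained signal only, never fed back into the
dynamics) is available via :func:`add_observational_noise`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .ordinal_encoding import Signal

__all__ = [
    "LogisticParams",
    "HenonParams",
    "NoiseSpec",
    "simulate_coupled_logistic",
    "simulate_henon",
    "add_observational_noise",
]

DEFAULT_X1 = 0.65
DEFAULT_Y1 = 0.44
DEFAULT_TRANSIENT = 1_000
DEFAULT_LENGTH = 1_000_000

_BOUND_TOL = 1e-12
_HENON_DIVERGENCE = 1e6


@dataclass(frozen=True)
class LogisticParams:
    """Parameters of the coupled identical logistic maps."""

    r: float
    eps: float = 0.0
    x1: float = DEFAULT_X1
    y1: float = DEFAULT_Y1
    transient: int = DEFAULT_TRANSIENT
    length: int = DEFAULT_LENGTH

    def __post_init__(self) -> None:
        if not (3.0 < self.r <= 4.0):
            raise ValueError(f"logistic control parameter r must be in (3, 4], got {self.r}")
        if not (0.0 <= self.eps <= 1.0):
            raise ValueError(f"coupling strength eps must be in [0, 1], got {self.eps}")
        if not (0.0 < self.x1 < 1.0 and 0.0 < self.y1 < 1.0):
            raise ValueError("initial states must lie in (0, 1)")
        if self.length < 1 or self.transient < 0:
            raise ValueError("length must be >= 1 and transient >= 0")


@dataclass(frozen=True)
class HenonParams:
    """Parameters of the Henon map."""

    a: float
    b: float = 0.3
    x1: float = DEFAULT_X1
    y1: float = DEFAULT_Y1
    transient: int = DEFAULT_TRANSIENT
    length: int = DEFAULT_LENGTH

    def __post_init__(self) -> None:
        if self.length < 1 or self.transient < 0:
            raise ValueError("length must be >= 1 and transient >= 0")


@dataclass(frozen=True)
class NoiseSpec:
    """Additive white Gaussian observational noise: standard deviation and seed."""

    std: float
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.std < 0:
            raise ValueError("noise standard deviation must be >= 0")


def simulate_coupled_logistic(params: LogisticParams) -> tuple[Signal, Signal]:
    """Iterate the coupled logistic maps; returns the retained (x, y) signals.

    The state is checked against the unit interval at every step; leaving
    [0, 1] beyond numerical tolerance raises with the offending iteration.
    """
    r, eps = params.r, params.eps
    x, y = params.x1, params.y1
    n_total = params.transient + params.length
    xs = np.empty(params.length)
    ys = np.empty(params.length)
    keep_from = params.transient
    one_m_eps = 1.0 - eps
    for t in range(n_total):
        fx = r * x * (1.0 - x)
        fy = r * y * (1.0 - y)
        x = one_m_eps * fx + eps * fy
        y = one_m_eps * fy + eps * fx
        if not (-_BOUND_TOL <= x <= 1.0 + _BOUND_TOL and -_BOUND_TOL <= y <= 1.0 + _BOUND_TOL):
            raise RuntimeError(
                f"coupled logistic state left [0, 1] at iteration {t + 1} "
                f"(x={x!r}, y={y!r}); check r and eps"
            )
        if t >= keep_from:
            xs[t - keep_from] = x
            ys[t - keep_from] = y
    lab = f"logistic(r={r}, eps={eps})"
    return Signal(xs, label=lab + " x"), Signal(ys, label=lab + " y")


def simulate_henon(params: HenonParams) -> tuple[Signal, Signal]:
    """Iterate the Henon map; returns the retained (x, y) signals.

    Divergence (|x| exceeding 1e6) aborts with the iteration index.
    """
    a, b = params.a, params.b
    x, y = params.x1, params.y1
    n_total = params.transient + params.length
    xs = np.empty(params.length)
    ys = np.empty(params.length)
    keep_from = params.transient
    for t in range(n_total):
        x, y = 1.0 - a * x * x + y, b * x
        if abs(x) > _HENON_DIVERGENCE:
            raise RuntimeError(
                f"Henon trajectory diverged at iteration {t + 1} (|x| > 1e6); "
                "the initial condition is outside the attractor basin for these (a, b)"
            )
        if t >= keep_from:
            xs[t - keep_from] = x
            ys[t - keep_from] = y
    lab = f"henon(a={a}, b={b})"
    return Signal(xs, label=lab + " x"), Signal(ys, label=lab + " y")


def add_observational_noise(signal: Signal, spec: NoiseSpec) -> Signal:
    """Add i.i.d. N(0, std**2) measurement noise to a signal.

    Observational, not dynamical: the underlying trajectory is untouched.
    ``std = 0`` returns a copy of the input.
    """
    if spec.std == 0:
        return Signal(signal.values.copy(), label=signal.label)
    rng = np.random.default_rng(spec.seed)
    return Signal(
        signal.values + rng.normal(0.0, spec.std, signal.T),
        label=signal.label,
    )
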