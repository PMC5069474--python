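"""Synthetic signal generators with known temporal structure.

Every generator is seed-deterministic.  ``gen_two_class_dataset`` builds a
two-class surrogate for the healthy-vs-ictal EEG experiment: class 0 is
short-memory filtered Gaussian noise (an AR(1) process, coefficient 0.9)
emulating background activity, class 1 is fully chaotic logistic-map
dynamics (r = 4) emulating strongly nonlinear ictal structure.  Each series
is standardized to zero mean and unit variance so the classes differ only
in temporal structure, not amplitude — visibility graphs are invariant
under positive affine amplitude transforms, so standardization cannot
create a spurious cue.
"""

from __future__ import annotations

import numpy as np

from .graph import TimeSeries

__all__ = [
    "gen_iid",
    "gen_periodic",
    "gen_ar1",
    "gen_logistic",
    "gen_two_class_dataset",
]


def gen_iid(length: int, seed: int = 0) -> TimeSeries:
    """I.i.d. uniform(0, 1) samples; continuous, so ties have probability 0."""
    if length < 2:
        raise ValueError("length must be >= 2")
    rng = np.random.default_rng(seed)
    return TimeSeries(rng.uniform(0.0, 1.0, size=length))


def gen_periodic(
    length: int,
    period: float = 20.0,
    amplitude: float = 1.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> TimeSeries:
    """Sinusoid of the given period (in samples), optionally plus Gaussian
    noise of standard deviation ``noise_sd``."""
    if period < 2:
        raise ValueError("period must be >= 2 samples")
    # phase computed modulo the period so the noiseless signal is exactly
    # periodic in floating point (repeated values are bitwise equal)
    phase = np.mod(np.arange(length), period) / period
    x = amplitude * np.sin(2.0 * np.pi * phase)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        x = x + rng.normal(0.0, noise_sd, size=length)
    return TimeSeries(x)


def gen_ar1(
    length: int, coefficient: float = 0.9, seed: int = 0, burn_in: int = 100
) -> TimeSeries:
    """Stationary AR(1) process with unit-variance Gaussian innovations."""
    if not -1 < coefficient < 1:
        raise ValueError("AR(1) coefficient must lie in (-1, 1)")
    rng = np.random.default_rng(seed)
    eps = rng.normal(0.0, 1.0, size=length + burn_in)
    x = np.empty(length + burn_in)
    x[0] = eps[0] / np.sqrt(1.0 - coefficient**2)
    for t in range(1, length + burn_in):
        x[t] = coefficient * x[t - 1] + eps[t]
    return TimeSeries(x[burn_in:])


def gen_logistic(
    length: int, r: float = 4.0, x0: float = 0.3, burn_in: int = 1000
) -> TimeSeries:
    """Logistic-map trajectory ``x_{t+1} = r x_t (1 - x_t)`` after
    discarding ``burn_in`` iterates.  Chaotic for r = 4, bounded in (0, 1)."""
    if not 0 < r <= 4:
        raise ValueError(f"logistic parameter r must lie in (0, 4], got {r}")
    if not 0 < x0 < 1:
        raise ValueError("initial condition x0 must lie in (0, 1)")
    if burn_in < 0:
        raise ValueError("burn_in must be non-negative")
    x = x0
    for _ in range(burn_in):
        x = r * x * (1.0 - x)
    out = np.empty(length)
    for t in range(length):
        out[t] = x
        x = r * x * (1.0 - x)
    return TimeSeries(out)


def _standardize(x: np.ndarray) -> np.ndarray:
    return (x - x.mean()) / x.std()


def gen_two_class_dataset(
    n_per_class: int = 100, length: int = 4096, seed: int = 0
) -> tuple[list[TimeSeries], np.ndarray]:
    """Labeled two-class surrogate dataset.

    Returns ``(signals, labels)``: ``n_per_class`` AR(1) signals (label 0)
    followed by ``n_per_class`` logistic-map signals (label 1), every series
    standardized to zero mean and unit variance.
    """
    if n_per_class < 2:
        raise ValueError("n_per_class must be >= 2")
    rng = np.random.default_rng(seed)
    signals: list[TimeSeries] = []
    for _ in range(n_per_class):
        s = int(rng.integers(0, 2**31 - 1))
        signals.append(TimeSeries(_standardize(gen_ar1(length, 0.9, seed=s).values)))
    for _ in range(n_per_class):
        x0 = float(rng.uniform(0.05, 0.95))
        signals.append(
            TimeSeries(_standardize(gen_logistic(length, 4.0, x0=x0).values))
        )
    labels = np.repeat([0, 1], n_per_class)
    return signals, labels
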