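"""Seeded white-noise generators with closed-form entropy references.

These families drive the estimator benchmarks: discrete uniform noise with
v gray levels has entropy log2(v) bits per sample, and a Bernoulli(p) train
has the binary entropy -p*log2(p) - (1-p)*log2(1-p).  Because the truth is
known in closed form, sweeping signal length and alphabet size exposes each
estimator's sampling bias and convergence behaviour.

All generators are pure functions of their spec: the PRNG is numpy's
``default_rng`` (PCG64), so the same seed yields byte-identical output on
every platform.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .png_codec import GrayImage, png_rate
from .shannon_direct import DiscreteSignal, entropy_rate_direct

__all__ = [
    "NoiseSpec",
    "uniform_noise",
    "bernoulli_signal",
    "ideal_entropy",
    "gray_levels",
    "sweep_experiment",
    "ALLOWED_LEVELS",
]

#: Uniform noise uses power-of-two alphabets spanning the 8-bit gray range.
ALLOWED_LEVELS = (2, 4, 8, 16, 32, 64, 128, 256)


@dataclass(frozen=True)
class NoiseSpec:
    """Either a v-level uniform source or a Bernoulli(p_white) source."""

    n_samples: int
    levels: int | None = None
    p_white: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if (self.levels is None) == (self.p_white is None):
            raise ValueError("set exactly one of levels / p_white")
        if self.levels is not None and self.levels not in ALLOWED_LEVELS:
            raise ValueError(f"levels must be one of {ALLOWED_LEVELS}")
        if self.p_white is not None and not 0.0 <= self.p_white <= 1.0:
            raise ValueError("p_white must lie in [0, 1]")


def gray_levels(v: int) -> np.ndarray:
    """The v evenly spaced gray values round(k * 255 / (v - 1)) on [0, 255]."""
    return np.round(np.arange(v) * 255.0 / (v - 1)).astype(np.uint8)


def uniform_noise(spec: NoiseSpec) -> DiscreteSignal:
    """I.i.d. uniform noise over v evenly spaced gray values."""
    if spec.levels is None:
        raise ValueError("uniform_noise requires a levels spec")
    rng = np.random.default_rng(spec.seed)
    vals = gray_levels(spec.levels)
    return DiscreteSignal(vals[rng.integers(0, spec.levels, spec.n_samples)]
                          .astype(float))


def bernoulli_signal(spec: NoiseSpec) -> DiscreteSignal:
    """I.i.d. 0/1 train with P(1) = p_white."""
    if spec.p_white is None:
        raise ValueError("bernoulli_signal requires a p_white spec")
    rng = np.random.default_rng(spec.seed)
    x = (rng.random(spec.n_samples) < spec.p_white).astype(float)
    return DiscreteSignal(x)


def ideal_entropy(spec: NoiseSpec) -> float:
    """Closed-form entropy in bits per sample for the spec's distribution."""
    if spec.levels is not None:
        return float(np.log2(spec.levels))
    p = spec.p_white
    if p in (0.0, 1.0):
        return 0.0
    return float(-p * np.log2(p) - (1 - p) * np.log2(1 - p))


def _signal_image(signal: DiscreteSignal) -> GrayImage:
    """Most-square image of a linear signal (trailing remainder dropped)."""
    n = len(signal)
    side = max(1, int(np.sqrt(n)))
    h = n // side
    px = signal.samples[: h * side].reshape(h, side)
    return GrayImage(np.round(px).astype(np.uint8) if px.max() > 1
                     else (px * 255).astype(np.uint8), 8)


def _apply_estimator(name: str, signal: DiscreteSignal) -> float:
    if name == "qem":
        return entropy_rate_direct(signal).rate
    if name == "png":
        return png_rate(_signal_image(signal)).rate_bytes_per_pixel
    raise ValueError(f"unknown estimator {name!r}")


def sweep_experiment(family: str,
                     n_samples: tuple[int, ...],
                     grid: tuple[float, ...] | tuple[int, ...],
                     estimators: tuple[str, ...] = ("qem", "png"),
                     seed: int = 0) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the estimators over a (signal length x parameter) grid.

    ``family`` is ``"uniform"`` (grid = levels) or ``"bernoulli"``
    (grid = p_white values).  Returns a tidy table of one row per
    (n, parameter, estimator) plus OLS fit summaries of estimate vs ideal
    entropy for each (estimator, n).
    """
    records = []
    for n in n_samples:
        for g in grid:
            if family == "uniform":
                spec = NoiseSpec(n_samples=n, levels=int(g), seed=seed)
                sig = uniform_noise(spec)
            elif family == "bernoulli":
                spec = NoiseSpec(n_samples=n, p_white=float(g), seed=seed)
                sig = bernoulli_signal(spec)
            else:
                raise ValueError(f"unknown family {family!r}")
            ideal = ideal_entropy(spec)
            for est in estimators:
                records.append({
                    "family": family, "n_samples": n, "param": g,
                    "estimator": est, "ideal_entropy": ideal,
                    "value": _apply_estimator(est, sig),
                })
    table = pd.DataFrame.from_records(records)

    fits = []
    for (est, n), sub in table.groupby(["estimator", "n_samples"]):
        x = sub["ideal_entropy"].to_numpy()
        y = sub["value"].to_numpy()
        if len(sub) >= 2 and np.ptp(x) > 0:
            slope, intercept = np.polyfit(x, y, 1)
            yhat = slope * x + intercept
            ss = ((y - y.mean()) ** 2).sum()
            r2 = 1 - ((y - yhat) ** 2).sum() / ss if ss > 0 else 1.0
        else:
            slope = intercept = r2 = np.nan
        fits.append({"estimator": est, "n_samples": n, "slope": slope,
                     "intercept": intercept, "r_squared": r2})
    return table, pd.DataFrame.from_records(fits)
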