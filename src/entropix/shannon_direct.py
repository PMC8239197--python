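"""Direct (plug-in) Shannon entropy and the quadratic-extrapolations entropy-rate estimator.

The entropy rate of a finite recording is not a single number: it depends on
how the amplitudes are quantized (``v`` levels), how many consecutive samples
are grouped into a word (``T``), and how much of the recording is used
(``Size`` fraction).  The direct method computes the plug-in entropy over a
whole grid of such probability spaces and then extrapolates three times —
to infinite recording length (1/Size -> 0), to infinite quantization
(1/v -> 0) and to infinite word length (1/T -> 0) — to estimate the entropy
rate R_S of the underlying source in bits per sample.

The same machinery applied *across* repeated trials at each time point
(operationally: to the transposed trial matrix) gives the noise entropy rate
R_N, and the information transfer rate between stimulus and response is
R = R_S - R_N.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "DiscreteSignal",
    "SymbolSequence",
    "ProbabilitySpaceParams",
    "EntropyGrid",
    "RateEstimate",
    "TrialMatrix",
    "QuadraticFit",
    "quantize",
    "make_words",
    "shannon_entropy",
    "entropy_grid",
    "quadratic_extrapolate",
    "entropy_rate_direct",
    "noise_entropy_rate",
    "information_rate",
    "DEFAULT_SIZE_FRACTIONS",
    "DEFAULT_QUANT_LEVELS",
    "DEFAULT_WORD_LENGTHS",
]

#: Default probability-space grids: 6 signal fractions x 8 quantization
#: ranges x 8 word lengths = 384 entropy values per signal.
DEFAULT_SIZE_FRACTIONS = (1.0, 0.9, 0.8, 0.7, 0.6, 0.5)
DEFAULT_QUANT_LEVELS = (2, 4, 8, 16, 32, 64, 128, 256)
DEFAULT_WORD_LENGTHS = (1, 2, 3, 4, 5, 6, 7, 8)

_INT64_SAFE = 2**62


class EstimationError(RuntimeError):
    """Raised when an extrapolation stage has too few usable points."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DiscreteSignal:
    """A finite sequence of real samples with a sampling rate in Hz."""

    samples: np.ndarray
    sampling_rate: float = 1.0

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        if samples.ndim != 1 or samples.size < 1:
            raise ValueError("signal must be a non-empty 1-D sequence")
        if not np.all(np.isfinite(samples)):
            raise ValueError("signal contains non-finite samples")
        if not (np.isfinite(self.sampling_rate) and self.sampling_rate > 0):
            raise ValueError("sampling_rate must be finite and positive")
        object.__setattr__(self, "samples", samples)

    def __len__(self) -> int:
        return int(self.samples.size)


@dataclass(frozen=True)
class SymbolSequence:
    """Integer symbols in [0, v-1] produced by quantization or word grouping.

    ``v`` is the alphabet size; for T-words it is ``v_base ** T`` and may be a
    Python int wider than 64 bits.
    """

    symbols: np.ndarray
    v: int

    def __post_init__(self) -> None:
        symbols = np.asarray(self.symbols)
        if self.v < 1:
            raise ValueError("alphabet size v must be >= 1")
        object.__setattr__(self, "symbols", symbols)

    def __len__(self) -> int:
        return int(self.symbols.size)


@dataclass(frozen=True)
class ProbabilitySpaceParams:
    """The grid of probability spaces explored by the direct method."""

    size_fractions: tuple[float, ...] = DEFAULT_SIZE_FRACTIONS
    quant_levels: tuple[int, ...] = DEFAULT_QUANT_LEVELS
    word_lengths: tuple[int, ...] = DEFAULT_WORD_LENGTHS

    def __post_init__(self) -> None:
        sizes = tuple(float(s) for s in self.size_fractions)
        vs = tuple(int(v) for v in self.quant_levels)
        ts = tuple(int(t) for t in self.word_lengths)
        for name, vals in (("size_fractions", sizes), ("quant_levels", vs),
                           ("word_lengths", ts)):
            if len(vals) == 0:
                raise ValueError(f"{name} must be non-empty")
            if len(set(vals)) != len(vals):
                raise ValueError(f"{name} contains duplicates")
        if not all(0 < s <= 1 for s in sizes):
            raise ValueError("size_fractions must lie in (0, 1]")
        if not all(v >= 2 for v in vs):
            raise ValueError("quant_levels must be >= 2")
        if not all(t >= 1 for t in ts):
            raise ValueError("word_lengths must be >= 1")
        object.__setattr__(self, "size_fractions", sizes)
        object.__setattr__(self, "quant_levels", vs)
        object.__setattr__(self, "word_lengths", ts)


@dataclass
class EntropyGrid:
    """Plug-in entropies H indexed by (size_fraction, v, T), in bits.

    ``n_words`` records how many words each entry was computed from;
    entries built from fewer than 2 words are listed in ``unreliable`` and
    excluded from the extrapolation fits rather than silently dropped.
    """

    entries: dict[tuple[float, int, int], float] = field(default_factory=dict)
    n_words: dict[tuple[float, int, int], int] = field(default_factory=dict)
    unreliable: set[tuple[float, int, int]] = field(default_factory=set)


@dataclass
class QuadraticFit:
    """Least-squares extrapolation to x = 0: intercept plus diagnostics."""

    intercept: float
    r_squared: float
    coefficients: tuple[float, ...]
    degree: int


@dataclass
class RateEstimate:
    """An entropy (or information) rate with fit diagnostics.

    ``rate`` is in bits per sample; ``rate_bits_per_s`` scales it by the
    sampling rate.  ``method_tag`` records which final-stage extrapolation
    was used: ``"quadratic"`` for the full quadratic fit, ``"linear_last2"``
    when the fallback through the two shortest-word points fired, or
    ``"mixed"`` for averages over rows that used both.
    """

    rate: float
    rate_bits_per_s: float
    method_tag: str
    diagnostics: dict = field(default_factory=dict)


@dataclass(frozen=True)
class TrialMatrix:
    """n_trials x n_samples matrix of aligned repeated responses."""

    trials: np.ndarray
    sampling_rate: float = 1.0

    def __post_init__(self) -> None:
        trials = np.asarray(self.trials, dtype=float)
        if trials.ndim != 2 or trials.size == 0:
            raise ValueError("trials must be a non-empty 2-D matrix")
        if not np.all(np.isfinite(trials)):
            raise ValueError("trial matrix contains non-finite values")
        if not (np.isfinite(self.sampling_rate) and self.sampling_rate > 0):
            raise ValueError("sampling_rate must be finite and positive")
        object.__setattr__(self, "trials", trials)

    @property
    def n_trials(self) -> int:
        return int(self.trials.shape[0])

    @property
    def n_samples(self) -> int:
        return int(self.trials.shape[1])


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------


def quantize(signal: DiscreteSignal | Sequence[float], v: int) -> SymbolSequence:
    """Equal-width quantization of a signal into ``v`` amplitude classes.

    Bin k covers [min + k*w, min + (k+1)*w) with w = (max - min)/v; the last
    bin is right-closed so the maximum maps to symbol v-1.  A constant signal
    maps to all zeros.
    """
    if v < 2:
        raise ValueError("quantization range v must be >= 2")
    if not isinstance(signal, DiscreteSignal):
        signal = DiscreteSignal(np.asarray(signal, dtype=float))
    x = signal.samples
    lo, hi = x.min(), x.max()
    if hi == lo:
        return SymbolSequence(np.zeros(x.size, dtype=np.int64), v)
    sym = np.floor((x - lo) / (hi - lo) * v).astype(np.int64)
    np.clip(sym, 0, v - 1, out=sym)
    return SymbolSequence(sym, v)


def make_words(seq: SymbolSequence, T: int) -> SymbolSequence:
    """Group symbols into non-overlapping blocks of T, base-v positional code.

    The trailing remainder shorter than T is discarded; the output length is
    floor(n / T).  ``T > n`` yields an empty sequence with a warning.
    """
    if T < 1:
        raise ValueError("word length T must be >= 1")
    if T == 1:
        return seq
    n = len(seq) // T
    if n == 0:
        warnings.warn("word length exceeds sequence length; no words formed",
                      stacklevel=2)
        return SymbolSequence(np.empty(0, dtype=np.int64), int(seq.v) ** T)
    blocks = np.asarray(seq.symbols[: n * T]).reshape(n, T)
    v = int(seq.v)
    if v**T < _INT64_SAFE:
        code = blocks[:, 0].astype(np.int64)
        for j in range(1, T):
            code = code * v + blocks[:, j]
    else:  # wide alphabets: exact Python-int codes
        code = np.array(
            [int.from_bytes(b"".join(int(s).to_bytes(8, "big") for s in row), "big")
             for row in blocks],
            dtype=object,
        )
    return SymbolSequence(code, v**T)


def shannon_entropy(seq: SymbolSequence | Sequence[int]) -> float:
    """Plug-in Shannon entropy in bits from empirical word frequencies."""
    symbols = seq.symbols if isinstance(seq, SymbolSequence) else np.asarray(seq)
    if symbols.size == 0:
        raise ValueError("cannot compute entropy of an empty sequence")
    _, counts = np.unique(symbols, return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log2(p)).sum()) + 0.0


def quadratic_extrapolate(x: Sequence[float], y: Sequence[float]) -> QuadraticFit:
    """OLS fit y = a + b*x + c*x^2 and its intercept at x = 0.

    With exactly two points a linear fit is used instead.  Fewer than two
    points is an error.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 2:
        raise ValueError("need at least 2 (x, y) points")
    deg = 2 if x.size >= 3 else 1
    coef = np.polyfit(x, y, deg)
    yhat = np.polyval(coef, x)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    ss_res = float(((y - yhat) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else (1.0 if ss_res == 0 else 0.0)
    return QuadraticFit(float(coef[-1]), r2, tuple(float(c) for c in coef), deg)


# ---------------------------------------------------------------------------
# vectorized grid engine (rows processed in parallel)
# ---------------------------------------------------------------------------


def _entropy_rows(codes: np.ndarray) -> np.ndarray:
    """Plug-in entropy (bits) of each row of an integer matrix."""
    r, n = codes.shape
    srt = np.sort(codes, axis=1)
    bound = np.concatenate(
        [np.ones((r, 1), dtype=bool), srt[:, 1:] != srt[:, :-1]], axis=1
    )
    flat = np.flatnonzero(bound.ravel())
    runs = np.diff(np.append(flat, r * n))
    p = runs / n
    contrib = -p * np.log2(p)
    return np.bincount(flat // n, weights=contrib, minlength=r)


def _quantize_rows(m: np.ndarray, v: int,
                   bounds: tuple[float, float] | None = None) -> np.ndarray:
    """Per-row equal-width quantization; ``bounds`` fixes shared bin edges.

    With ``bounds=(lo, hi)`` every row uses the same amplitude classes —
    required when rows are across-trial slices of one recording, so that
    signal and noise entropies live in the same probability space.
    """
    if bounds is not None:
        lo = np.full((m.shape[0], 1), bounds[0])
        rng = np.full((m.shape[0], 1), bounds[1] - bounds[0])
        flat = rng[:, 0] == 0
    else:
        lo = m.min(axis=1, keepdims=True)
        rng = m.max(axis=1, keepdims=True) - lo
        flat = rng[:, 0] == 0
    rng[flat] = 1.0
    sym = np.floor((m - lo) / rng * v).astype(np.int64)
    np.clip(sym, 0, v - 1, out=sym)
    sym[flat] = 0
    return sym


def _word_code_rows(sym: np.ndarray, v: int, T: int) -> np.ndarray:
    """Base-v codes of non-overlapping T-blocks along axis 1, per row.

    Codes are kept inside int64 by compacting the running alphabet (per-row
    relabelling by first occurrence of the sorted value) whenever the next
    base-v digit would overflow.  Relabelling is a bijection per row, so word
    counts — and hence entropies — are unchanged.
    """
    r, n = sym.shape
    nw = n // T
    if nw == 0:
        return np.empty((r, 0), dtype=np.int64)
    blocks = sym[:, : nw * T].reshape(r, nw, T)
    code = blocks[:, :, 0].astype(np.int64)
    hi = v  # exclusive upper bound on current codes
    for j in range(1, T):
        if hi > _INT64_SAFE // v:
            for i in range(r):  # compact each row's alphabet
                _, code[i] = np.unique(code[i], return_inverse=True)
            hi = min(hi, nw)
        code = code * v + blocks[:, :, j]
        hi = hi * v
    return code


def _fit_intercepts(x: np.ndarray, ys: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized polynomial extrapolation to x = 0 for many curves at once.

    ``ys`` has shape (len(x), k); returns intercepts and R^2, each (k,).
    Quadratic with >= 3 points, linear with 2, the value itself with 1.
    """
    npts = x.size
    if npts == 1:
        return ys[0].copy(), np.ones(ys.shape[1])
    deg = 2 if npts >= 3 else 1
    coef = np.polyfit(x, ys, deg)
    yhat = np.polyval(coef, x[:, None])
    ss_tot = ((ys - ys.mean(axis=0)) ** 2).sum(axis=0)
    ss_res = ((ys - yhat) ** 2).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = np.where(ss_tot > 0, 1.0 - ss_res / np.where(ss_tot > 0, ss_tot, 1.0),
                      np.where(ss_res == 0, 1.0, 0.0))
    return coef[-1], r2


def _qem_rows(matrix: np.ndarray, params: ProbabilitySpaceParams,
              bounds: tuple[float, float] | None = None
              ) -> tuple[np.ndarray, np.ndarray, dict]:
    """Triple-extrapolation entropy rate of every row of ``matrix``.

    Returns (rates_bits_per_sample, used_quadratic_mask, diagnostics).
    Rows are independent signals; the three extrapolation stages are the
    1/Size, 1/v and 1/T fits described in the module docstring.
    """
    m = np.asarray(matrix, dtype=float)
    r, n = m.shape
    sizes = sorted(params.size_fractions, reverse=True)
    vs = sorted(params.quant_levels)
    ts = sorted(params.word_lengths)
    v_max = vs[-1]

    # stage 0: plug-in entropies over the (Size, v, T) grid
    # H[vi][ti] is a list over usable sizes of (1/Size, entropies (r,))
    usable: dict[int, list[float]] = {
        t: [s for s in sizes if (int(np.floor(s * n)) // t) >= 2] for t in ts
    }
    stage1 = np.full((len(vs), len(ts), r), np.nan)
    for vi, v in enumerate(vs):
        sym = _quantize_rows(m, v, bounds)
        for ti, t in enumerate(ts):
            good = usable[t]
            if not good:
                continue
            hs = np.empty((len(good), r))
            for si, s in enumerate(good):
                k = int(np.floor(s * n))
                hs[si] = _entropy_rows(_word_code_rows(sym[:, :k], v, t))
            xs = 1.0 / np.asarray(good)
            stage1[vi, ti], _ = _fit_intercepts(xs, hs)

    # stage 2: extrapolate 1/v -> 0 for every T
    good_ts = [ti for ti, t in enumerate(ts) if usable[t]]
    if len(good_ts) < 2:
        raise EstimationError("fewer than 2 usable word lengths; signal too short")
    inv_v = 1.0 / np.asarray(vs, dtype=float)
    stage2 = np.empty((len(good_ts), r))
    for row_i, ti in enumerate(good_ts):
        stage2[row_i], _ = _fit_intercepts(inv_v, stage1[:, ti, :])

    # stage 3: divide by T, extrapolate 1/T -> 0
    t_vals = np.asarray([ts[ti] for ti in good_ts], dtype=float)
    inv_t = 1.0 / t_vals
    ys = stage2 / t_vals[:, None]  # (n_T, r)

    order = np.argsort(inv_t)[::-1]  # descending 1/T: shortest words first
    x0, x1 = inv_t[order[0]], inv_t[order[1]]
    y0, y1 = ys[order[0]], ys[order[1]]
    lin = y0 - (y1 - y0) / (x1 - x0) * x0

    if len(good_ts) >= 3:
        quad, r2 = _fit_intercepts(inv_t, ys)
        ok = (r2 >= 0.9) & (quad >= 0.0) & (quad <= np.log2(v_max))
        rates = np.where(ok, quad, lin)
        used_quad = ok
    else:
        rates = lin
        used_quad = np.zeros(r, dtype=bool)

    diag = {
        "stage3_inv_T": inv_t.tolist(),
        "stage3_H_over_T": ys.mean(axis=1).tolist(),
        "quadratic_rows": int(used_quad.sum()),
        "n_rows": r,
    }
    return rates, used_quad, diag


def _tag(used_quad: np.ndarray) -> str:
    if used_quad.all():
        return "quadratic"
    if not used_quad.any():
        return "linear_last2"
    return "mixed"


# ---------------------------------------------------------------------------
# public estimators
# ---------------------------------------------------------------------------


def entropy_grid(signal: DiscreteSignal,
                 params: ProbabilitySpaceParams | None = None) -> EntropyGrid:
    """Plug-in entropy for every (Size, v, T) probability space.

    Each entry takes the leading floor(Size * n) samples, quantizes with v
    equal-width levels and groups into non-overlapping T-words.  Entries
    with fewer than 2 words are flagged unreliable instead of dropped.
    """
    params = params or ProbabilitySpaceParams()
    x = signal.samples[None, :]
    n = x.shape[1]
    grid = EntropyGrid()
    for v in params.quant_levels:
        sym = _quantize_rows(x, v)
        for s in params.size_fractions:
            k = int(np.floor(s * n))
            if k < 1:
                continue
            for t in params.word_lengths:
                key = (float(s), int(v), int(t))
                nw = k // t
                grid.n_words[key] = nw
                if nw < 2:
                    grid.unreliable.add(key)
                    grid.entries[key] = (
                        float(_entropy_rows(_word_code_rows(sym[:, :k], v, t))[0])
                        if nw == 1 else float("nan")
                    )
                    continue
                grid.entries[key] = float(
                    _entropy_rows(_word_code_rows(sym[:, :k], v, t))[0]
                )
    return grid


def entropy_rate_direct(signal: DiscreteSignal,
                        params: ProbabilitySpaceParams | None = None
                        ) -> RateEstimate:
    """Entropy rate R_S of a signal by the triple quadratic extrapolation.

    Stage 1 extrapolates H to infinite recording (fit vs 1/Size), stage 2 to
    infinite quantization (vs 1/v), stage 3 divides by T and extrapolates to
    infinite word length (vs 1/T).  When the stage-3 quadratic is untrust-
    worthy (R^2 < 0.9, or an intercept outside [0, log2(v_max)]) the
    estimate falls back to the line through the two shortest-word points,
    recorded in ``method_tag``.
    """
    params = params or ProbabilitySpaceParams()
    rates, used_quad, diag = _qem_rows(signal.samples[None, :], params)
    rate = float(rates[0])
    return RateEstimate(rate, rate * signal.sampling_rate, _tag(used_quad), diag)


def noise_entropy_rate(trials: TrialMatrix,
                       params: ProbabilitySpaceParams | None = None,
                       column_stride: int = 1) -> RateEstimate:
    """Noise entropy rate R_N: the same estimator across trials.

    The trial matrix is transposed and the per-signal estimator applied to
    every time point's across-trial vector; R_N is the average over time
    points.  Captures the response variability that remains when the
    stimulus is identical on every trial.  ``column_stride`` > 1 estimates
    the average over a regular subgrid of time points (unbiased for the
    mean, proportionally faster on long recordings).
    """
    if trials.n_trials < 2:
        raise ValueError("noise entropy requires at least 2 trials")
    if column_stride < 1:
        raise ValueError("column_stride must be >= 1")
    params = params or ProbabilitySpaceParams()
    m = trials.trials
    bounds = (float(m.min()), float(m.max()))
    rates, used_quad, diag = _qem_rows(m.T[::column_stride], params,
                                       bounds=bounds)
    # an entropy rate is non-negative; undershooting extrapolations on
    # near-constant across-trial rows are floored rather than averaged in
    rates = np.maximum(rates, 0.0)
    rate = float(rates.mean())
    diag["per_time_rate_sd"] = float(rates.std())
    return RateEstimate(rate, rate * trials.sampling_rate, _tag(used_quad), diag)


def information_rate(trials: TrialMatrix,
                     params: ProbabilitySpaceParams | None = None,
                     noise_column_stride: int = 1) -> RateEstimate:
    """Information transfer rate R = R_S - R_N between stimulus and response.

    R_S is the arithmetic mean of the per-trial entropy-rate estimates; R_N
    is the across-trial noise entropy rate.  For independent trials R is
    close to zero; for perfectly reproducible trials R equals R_S.
    """
    if trials.n_trials < 2:
        raise ValueError("information rate requires at least 2 trials")
    params = params or ProbabilitySpaceParams()
    m = trials.trials
    bounds = (float(m.min()), float(m.max()))
    rs_rates, rs_quad, _ = _qem_rows(m, params, bounds=bounds)
    rs_rates = np.maximum(rs_rates, 0.0)
    rn = noise_entropy_rate(trials, params, column_stride=noise_column_stride)
    r_s = float(rs_rates.mean())
    rate = r_s - rn.rate
    diag = {
        "signal_rate": r_s,
        "noise_rate": rn.rate,
        "per_trial_signal_rates": rs_rates.tolist(),
    }
    if rs_quad.all() and rn.method_tag == "quadratic":
        tag = "quadratic"
    elif not rs_quad.any() and rn.method_tag == "linear_last2":
        tag = "linear_last2"
    else:
        tag = "mixed"
    return RateEstimate(rate, rate * trials.sampling_rate, tag, diag)
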