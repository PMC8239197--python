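"""Place-field random-walk simulator, Skaggs spatial information, and the
pairing-image route to compression-based mutual information.

A mock animal performs a random walk on a 20 x 20 bin arena (each step
occupies its bin for 1 s).  A place cell at the arena centre fires at a
rate set by a sigmoid of the distance x from the centre,
F_max / (1 + exp((x - x0) * Slope)) with x0 = 7, Slope = 2, F_max = 10,
giving a field of roughly 3 bins radius; independent background noise adds
one spike per step with probability 0.1.  The field's ``strength`` in
[0, 1] is the per-step probability that the place field fires at all, so
sweeping it emulates place cells of increasing reliability.

Spatial information is quantified two ways: the Skaggs information rate
I_sec = sum_i p_i * lambda_i * log2(lambda_i / lambda) in bits/s, and the
PNG-Rate difference of the "pairing image" — a 2-D array whose columns are
flattened arena bins and whose rows are successive visits to each bin, so
that compressing along rows vs columns contrasts spatial structure with
visit-to-visit noise.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np

from .png_codec import (
    GrayImage,
    MiPngResult,
    normalize_to_8bit,
    png_rate,
    rotate90,
)

__all__ = [
    "ArenaSpec",
    "FieldParams",
    "PlaceFieldSession",
    "random_walk",
    "field_rate",
    "simulate_session",
    "skaggs_isec",
    "pairing_image",
    "mi_place_png",
]


@dataclass(frozen=True)
class ArenaSpec:
    """Rectangular arena of width x height square bins; 1 s occupancy/step."""

    width: int = 20
    height: int = 20
    seconds_per_step: float = 1.0

    def __post_init__(self) -> None:
        if self.width < 1 or self.height < 1:
            raise ValueError("arena dimensions must be positive")

    @property
    def n_bins(self) -> int:
        return self.width * self.height

    @property
    def center(self) -> tuple[float, float]:
        return ((self.width - 1) / 2.0, (self.height - 1) / 2.0)


@dataclass(frozen=True)
class FieldParams:
    """Sigmoid place-field tuning and background noise."""

    x0: float = 7.0
    slope: float = 2.0
    f_max: float = 10.0
    strength: float = 1.0
    noise_p: float = 0.1

    def __post_init__(self) -> None:
        if not 0.0 <= self.strength <= 1.0:
            raise ValueError("strength must lie in [0, 1]")
        if self.f_max < 0:
            raise ValueError("f_max must be >= 0")


@dataclass(frozen=True)
class PlaceFieldSession:
    """Random-walk positions with per-step spike counts."""

    positions: np.ndarray  # (steps, 2) int bins (x, y)
    spikes: np.ndarray  # (steps,) int counts
    arena: ArenaSpec
    params: FieldParams
    seed: int

    def __post_init__(self) -> None:
        if len(self.positions) != len(self.spikes):
            raise ValueError("positions and spikes must have equal length")


_MOVES = np.array([(dx, dy) for dx in (-1, 0, 1) for dy in (-1, 0, 1)])


def random_walk(arena: ArenaSpec, steps: int, seed: int = 0) -> np.ndarray:
    """Uniform random walk over the 8-neighbourhood plus staying put.

    Moves that would leave the arena are excluded and the choice
    renormalized over the feasible moves, so every legal option stays
    equally likely.  The start bin is uniform over the arena.
    """
    if steps < 1:
        raise ValueError("steps must be >= 1")
    rng = np.random.default_rng(seed)
    pos = np.empty((steps, 2), dtype=np.int64)
    x = rng.integers(0, arena.width)
    y = rng.integers(0, arena.height)
    for i in range(steps):
        pos[i] = (x, y)
        nxt = _MOVES + (x, y)
        ok = ((nxt[:, 0] >= 0) & (nxt[:, 0] < arena.width)
              & (nxt[:, 1] >= 0) & (nxt[:, 1] < arena.height))
        feasible = nxt[ok]
        x, y = feasible[rng.integers(0, len(feasible))]
    return pos


def field_rate(position, params: FieldParams | None = None,
               arena: ArenaSpec | None = None) -> float | np.ndarray:
    """Expected field spikes/step at a position: sigmoid of centre distance."""
    params = params or FieldParams()
    arena = arena or ArenaSpec()
    p = np.asarray(position, dtype=float)
    cx, cy = arena.center
    x = np.hypot(p[..., 0] - cx, p[..., 1] - cy)
    rate = params.f_max / (1.0 + np.exp((x - params.x0) * params.slope))
    return float(rate) if rate.ndim == 0 else rate


def simulate_session(arena: ArenaSpec | None = None,
                     params: FieldParams | None = None,
                     steps: int = 10_000, seed: int = 0) -> PlaceFieldSession:
    """One recording session: walk plus field and noise spikes.

    Per step: with probability ``strength`` the field emits
    Poisson(field_rate) spikes; independently one noise spike is added with
    probability ``noise_p``.
    """
    arena = arena or ArenaSpec()
    params = params or FieldParams()
    pos = random_walk(arena, steps, seed)
    rng = np.random.default_rng(seed + 1)
    rates = field_rate(pos, params, arena)
    gate = rng.random(steps) < params.strength
    spikes = np.where(gate, rng.poisson(rates), 0)
    spikes = spikes + (rng.random(steps) < params.noise_p)
    return PlaceFieldSession(pos, spikes.astype(np.int64), arena, params, seed)


def skaggs_isec(session: PlaceFieldSession) -> float:
    """Skaggs spatial information rate I_sec in bits/s.

    I_sec = sum_i p_i * lambda_i * log2(lambda_i / lambda) over visited bins,
    with p_i the occupancy ratio, lambda_i the mean rate in bin i and lambda
    the overall mean rate (occupancy is 1 s per step).  Bins with zero rate
    contribute zero.
    """
    steps = len(session.spikes)
    if steps == 0:
        raise ValueError("empty session")
    per_s = session.arena.seconds_per_step
    flat = session.positions[:, 1] * session.arena.width + session.positions[:, 0]
    visits = np.bincount(flat, minlength=session.arena.n_bins)
    spike_sum = np.bincount(flat, weights=session.spikes,
                            minlength=session.arena.n_bins)
    total_spikes = session.spikes.sum()
    if total_spikes == 0:
        warnings.warn("session has no spikes; I_sec is 0", stacklevel=2)
        return 0.0
    occ = visits / steps
    with np.errstate(invalid="ignore", divide="ignore"):
        lam_i = np.where(visits > 0, spike_sum / np.maximum(visits, 1), 0.0) / per_s
    lam = total_spikes / (steps * per_s)
    pos_mask = lam_i > 0
    terms = occ[pos_mask] * lam_i[pos_mask] * np.log2(lam_i[pos_mask] / lam)
    return float(terms.sum())


def pairing_image(session: PlaceFieldSession) -> GrayImage:
    """The visit-by-bin occupancy image for compression-based MI.

    Column = row-major flattened bin index (0-based); the k-th visit to a
    bin writes that step's spike count into row k of its column.  Unvisited
    (bin, visit) cells are zero-filled, and counts are scaled to the 8-bit
    gray range.
    """
    flat = session.positions[:, 1] * session.arena.width + session.positions[:, 0]
    n_bins = session.arena.n_bins
    visit_ordinal = np.zeros(len(flat), dtype=np.int64)
    seen = np.zeros(n_bins, dtype=np.int64)
    for i, b in enumerate(flat):
        visit_ordinal[i] = seen[b]
        seen[b] += 1
    height = max(1, int(seen.max()))
    table = np.zeros((height, n_bins), dtype=np.int64)
    table[visit_ordinal, flat] = session.spikes
    if table.max() > 0:
        px = normalize_to_8bit(table)
    else:
        px = table.astype(np.uint8)
    return GrayImage(px, 8)


def mi_place_png(session: PlaceFieldSession) -> MiPngResult:
    """PNG-Rate difference of the pairing image vs its 90-degree rotation.

    Compressing along rows reads out spatial structure (columns near the
    field carry spikes); the rotated image compresses along visits.  The
    difference grows with field strength, mirroring I_sec.
    """
    img = pairing_image(session)
    signal = png_rate(img).rate_bytes_per_pixel
    noise = png_rate(rotate90(img)).rate_bytes_per_pixel
    return MiPngResult(signal, noise, signal - noise, units="bytes/pixel")
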