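"""Figure-replica experiment runners behind one seeded entry point.

Each experiment id reproduces one benchmark from the estimator study at a
configurable scale: noise-ladder linearity (fig1d), Bernoulli bell curves
(fig2a), length sweeps (fig2b), convergence of both estimators (fig2c),
neuron entropy vs rate (fig3), frozen-input mutual information (fig4a),
synaptic information efficacy (fig4c), place fields (fig5), and synthetic
2-D complexity (fig6-synthetic).  Every stochastic path takes its seed from
the config; the same config reproduces the same bundle.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import place_field as pf
from .image_complexity import column_profile, polar_unwrap, sholl_count, synthetic_arbor
from .neuron_sim import run_entropy_protocol, run_mi_protocol, run_sie_protocol
from .png_codec import GrayImage, png_overhead, png_rate
from .shannon_direct import DiscreteSignal, entropy_rate_direct
from .synth_signals import (
    NoiseSpec,
    bernoulli_signal,
    ideal_entropy,
    sweep_experiment,
    uniform_noise,
)

__all__ = ["ExperimentConfig", "run_experiment", "EXPERIMENT_IDS"]

EXPERIMENT_IDS = ("fig1d", "fig2a", "fig2b", "fig2c", "fig3", "fig4a",
                  "fig4c", "fig5", "fig6-synthetic")


@dataclass(frozen=True)
class ExperimentConfig:
    experiment: str
    scale: float = 1.0
    seed: int = 0
    outdir: str | Path | None = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.experiment not in EXPERIMENT_IDS:
            raise ValueError(f"unknown experiment {self.experiment!r}; "
                             f"choose from {EXPERIMENT_IDS}")
        if not 0 < self.scale <= 1:
            raise ValueError("scale must lie in (0, 1]")


def _scaled(n: int, scale: float, floor: int = 10) -> int:
    return max(floor, int(round(n * scale)))


def _fit(x: np.ndarray, y: np.ndarray) -> dict:
    slope, intercept = np.polyfit(x, y, 1)
    yhat = slope * x + intercept
    ss = ((y - y.mean()) ** 2).sum()
    r2 = 1.0 - ((y - yhat) ** 2).sum() / ss if ss > 0 else 1.0
    return {"slope": float(slope), "intercept": float(intercept),
            "r_squared": float(r2)}


def _fig1d(cfg: ExperimentConfig) -> dict:
    """PNG Rate vs true entropy over the 2..256-level noise ladder."""
    n = _scaled(10_000, cfg.scale, floor=1000)
    table, fits = sweep_experiment("uniform", (n,), (2, 4, 8, 16, 32, 64, 128, 256),
                                   estimators=("png",), seed=cfg.seed)
    png_fit = _fit(table["ideal_entropy"].to_numpy(), table["value"].to_numpy())
    return {"table": table, "fit": png_fit}


def _fig2a(cfg: ExperimentConfig) -> dict:
    """Bernoulli bell curve: estimates vs p for several signal lengths."""
    ps = tuple(np.round(np.linspace(0.0, 1.0, 11), 2))
    ns = tuple(_scaled(n, cfg.scale, floor=100) for n in (100, 1000, 10_000))
    table, fits = sweep_experiment("bernoulli", ns, ps, seed=cfg.seed)
    return {"table": table, "fits": fits}


def _fig2b(cfg: ExperimentConfig) -> dict:
    """Length dependence of both estimators over the level ladder."""
    ns = tuple(_scaled(n, cfg.scale, floor=500) for n in (1000, 10_000, 100_000))
    table, fits = sweep_experiment("uniform", ns, (2, 4, 8, 16, 32, 64, 128, 256),
                                   seed=cfg.seed)
    return {"table": table, "fits": fits}


def _fig2c(cfg: ExperimentConfig) -> dict:
    """Convergence: estimate vs number of points for 2- and 4-level noise."""
    ns = tuple(_scaled(n, cfg.scale, floor=100)
               for n in (100, 500, 1000, 5000, 10_000, 20_000))
    table, _ = sweep_experiment("uniform", ns, (2, 4), seed=cfg.seed)
    return {"table": table}


def _fig3(cfg: ExperimentConfig) -> dict:
    """Neuron entropy rate (direct and PNG) vs firing rate."""
    duration = max(1.0, 5.0 * cfg.scale)
    table = run_entropy_protocol((1, 5, 10, 20), duration_s=duration,
                                 seed=cfg.seed)
    f = _fit(table["entropy_rate_bits_per_sample"].to_numpy(),
             table["png_rate_bytes_per_pixel"].to_numpy())
    return {"table": table, "fit": f}


def _fig4a(cfg: ExperimentConfig) -> dict:
    """Frozen-input information transfer rate vs firing rate."""
    duration = max(0.5, 5.0 * cfg.scale)
    n_trials = _scaled(20, max(cfg.scale, 0.5), floor=8)
    table = run_mi_protocol((1, 5, 10, 20), n_trials=n_trials,
                            duration_s=duration, seed=cfg.seed)
    return {"table": table}


def _fig4c(cfg: ExperimentConfig) -> dict:
    """Synaptic information efficacy vs supplementary-synapse strength."""
    duration = max(0.5, 5.0 * cfg.scale)
    n_trials = _scaled(100, cfg.scale, floor=10)
    table = run_sie_protocol((0.5, 1, 2, 4, 8), n_trials=n_trials,
                             duration_s=duration, seed=cfg.seed)
    return {"table": table}


def _fig5(cfg: ExperimentConfig) -> dict:
    """Place-field strength ladder: I_sec and PNG difference."""
    steps = _scaled(10_000, cfg.scale, floor=1000)
    strengths = (0.0, 0.2, 0.4, 0.6, 0.8, 1.0)
    rows = []
    for si, s in enumerate(strengths):
        sess = pf.simulate_session(params=pf.FieldParams(strength=s),
                                   steps=steps, seed=cfg.seed + si)
        mi = pf.mi_place_png(sess)
        rows.append({"strength": s, "isec_bits_per_s": pf.skaggs_isec(sess),
                     "png_difference": mi.difference})
    return {"table": pd.DataFrame.from_records(rows)}


def _fig6(cfg: ExperimentConfig) -> dict:
    """Radial complexity of a synthetic arbor vs its Sholl curve."""
    size = _scaled(256, max(cfg.scale, 0.5), floor=128)
    img = synthetic_arbor(size=size, seed=cfg.seed)
    center = (size / 2.0, size / 2.0)
    unwrapped = polar_unwrap(img, center)
    prof = column_profile(unwrapped)
    radii = np.arange(5, size // 2, 5)
    sholl = sholl_count(img.pixels, center, radii)
    return {
        "profile": pd.DataFrame({"radius": prof.positions,
                                 "png_bytes": prof.sizes_bytes}),
        "sholl": pd.DataFrame({"radius": radii, "crossings": sholl}),
        "overhead": png_overhead(1, unwrapped.height),
    }


_RUNNERS = {
    "fig1d": _fig1d, "fig2a": _fig2a, "fig2b": _fig2b, "fig2c": _fig2c,
    "fig3": _fig3, "fig4a": _fig4a, "fig4c": _fig4c, "fig5": _fig5,
    "fig6-synthetic": _fig6,
}


def run_experiment(cfg: ExperimentConfig) -> dict:
    """Run one experiment bundle; optionally write CSV/JSON to cfg.outdir."""
    result = _RUNNERS[cfg.experiment](cfg)
    if cfg.outdir is not None:
        outdir = Path(cfg.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        summary = {"experiment": cfg.experiment, "scale": cfg.scale,
                   "seed": cfg.seed}
        for name, obj in result.items():
            if isinstance(obj, pd.DataFrame):
                obj.to_csv(outdir / f"{cfg.experiment}_{name}.csv", index=False)
            else:
                summary[name] = obj
        with open(outdir / f"{cfg.experiment}_summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, default=float)
    return result
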