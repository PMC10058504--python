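"""Synthetic bead-experiment generator.

Emulates the measurement tables produced by imaging colonies in nanoliter
agarose beads:

* founder counts per bead are independent Poisson draws, Poisson(λ·r) for
  strain B and Poisson(λ·(1−r)) for strain Y;
* every founder cell grows into one colony; all colonies in a bead share the
  bead's fixed nutrient budget, implemented by scaling each strain's carrying
  capacity A2 by 1/(total founders in the bead).  This makes the final
  *population* per bead roughly inoculum-independent and the mean *colony*
  size inversely related to the inoculum;
* trajectories follow the two-strain competition model of
  :mod:`beadcolony.growth` (monoculture closed form when only one strain is
  present), sampled at the configured imaging times;
* colony shapes are exact ellipses with per-colony aspect ratio drawn from a
  truncated normal (mode 1.3, spread 0.15 by default); the perimeter is
  Ramanujan's second approximation;
* measured area carries multiplicative mean-one log-normal noise of the
  configured CV; fluorescence intensity is k·area per strain until the colony
  reaches 99% of its final size, then decays exponentially
  (photobleaching / starvation, phenomenological), with independent
  multiplicative noise on top of the area noise.

A fixed seed yields a byte-identical table.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from .growth import (CompetitionParams, MonocultureParams,
                     baranyi_roberts_eval, lv_integrate)
from .io import COLUMNS, empty_table

#: imaging schedule of the study: every 2 h from 4 h, then 22 h and 32 h
DEFAULT_TIME_POINTS: Tuple[float, ...] = (4.0, 6.0, 8.0, 10.0, 12.0, 22.0, 32.0)

#: default per-strain growth truth: Y grows faster and larger than B
#: (rate ratio r_B/r_Y ≈ 0.81), stationary onset ≈ 11–12 h, mild mutual
#: inhibition with Y suppressing B more strongly.
DEFAULT_GROWTH = CompetitionParams(
    b=MonocultureParams(r=0.85, gamma=1.2, a1=5.0, a2=9000.0),
    y=MonocultureParams(r=1.05, gamma=1.2, a1=5.0, a2=11000.0),
    c_b=0.5, c_y=0.6,
)


@dataclass
class ExperimentConfig:
    """Study conditions for one synthetic bead experiment."""

    n_beads: int = 200
    bead_volume_nl: float = 240.0
    mean_inoculum: float = 2.0          # λ, cells/bead
    strain_ratio: float = 0.5           # fraction of strain B
    time_points: Sequence[float] = DEFAULT_TIME_POINTS
    noise_cv: float = 0.05              # relative measurement noise on area
    intensity_noise_cv: float = 0.05    # extra relative noise on intensity
    intensity_decay_rate: float = 0.08  # 1/h, post-stationary intensity decay
    intensity_scale_b: float = 1.0      # au per μm², strain B
    intensity_scale_y: float = 1.0      # au per μm², strain Y
    ar_mode: float = 1.3                # mode of the aspect-ratio distribution
    ar_spread: float = 0.15
    growth: CompetitionParams = field(default_factory=lambda: DEFAULT_GROWTH)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_beads < 1:
            raise ValueError("n_beads must be >= 1")
        if self.bead_volume_nl <= 0:
            raise ValueError("bead_volume_nl must be positive")
        if self.mean_inoculum < 0:
            raise ValueError("mean_inoculum must be >= 0")
        if not 0.0 <= self.strain_ratio <= 1.0:
            raise ValueError("strain_ratio must be in [0, 1]")
        tp = np.asarray(self.time_points, dtype=float)
        if tp.size == 0:
            raise ValueError("time_points must contain at least one time")
        if np.any(np.diff(tp) <= 0) or np.any(tp < 0):
            raise ValueError("time_points must be nonnegative and strictly increasing")
        if self.noise_cv < 0 or self.intensity_noise_cv < 0:
            raise ValueError("noise CVs must be >= 0")
        if self.intensity_decay_rate < 0:
            raise ValueError("intensity_decay_rate must be >= 0")
        if self.ar_mode < 1.0 or self.ar_spread < 0:
            raise ValueError("ar_mode must be >= 1 and ar_spread >= 0")


def sample_aspect_ratios(n: int, mode: float = 1.3, spread: float = 0.15,
                         rng: Optional[np.random.Generator] = None) -> np.ndarray:
    """Draw per-colony aspect ratios from a normal truncated at AR = 1."""
    if rng is None:
        rng = np.random.default_rng()
    if spread == 0:
        return np.full(n, float(mode))
    from scipy.stats import truncnorm
    a = (1.0 - mode) / spread
    return truncnorm.rvs(a, np.inf, loc=mode, scale=spread, size=n,
                         random_state=rng)


def ramanujan_perimeter(major, minor):
    """Ellipse perimeter by Ramanujan's second approximation (full axes)."""
    a = np.asarray(major, dtype=float) / 2.0
    b = np.asarray(minor, dtype=float) / 2.0
    h = ((a - b) / (a + b)) ** 2
    p = np.pi * (a + b) * (1.0 + 3.0 * h / (10.0 + np.sqrt(4.0 - 3.0 * h)))
    return p if np.ndim(p) else float(p)


def _lognormal_mult(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Mean-one multiplicative log-normal noise with the given CV."""
    if cv == 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv ** 2))
    return rng.lognormal(-sigma ** 2 / 2.0, sigma, size=size)


def _scaled_params(growth: CompetitionParams, n_total: int,
                   lam: float) -> CompetitionParams:
    """Per-bead effective parameters: capacities shared by all founders."""
    a2b = growth.b.a2 / n_total
    a2y = growth.y.a2 / n_total
    if a2b <= growth.b.a1 or a2y <= growth.y.a1:
        raise ValueError(
            f"inoculum too large: a bead with {n_total} founders (λ={lam}) "
            f"leaves a per-colony capacity ({min(a2b, a2y):.3g} μm²) at or "
            f"below the initial colony size; reduce mean_inoculum or raise A2")
    return replace(growth, b=replace(growth.b, a2=a2b),
                   y=replace(growth.y, a2=a2y))


def _pair_trajectories(config: ExperimentConfig, nb: int, ny: int,
                       tp: np.ndarray):
    """Noiseless per-colony area trajectories and stationary times for a bead
    with (nb, ny) founders.  Returns (area_b, area_y, ts_b, ts_y); absent
    strains yield None."""
    eff = _scaled_params(config.growth, nb + ny, config.mean_inoculum)
    dense = np.union1d(np.linspace(0.0, tp[-1], 513), tp)
    if nb > 0 and ny > 0:
        ab, ay = lv_integrate(eff, dense)
    elif nb > 0:
        ab, ay = np.asarray(baranyi_roberts_eval(eff.b, dense)), None
    else:
        ab, ay = None, np.asarray(baranyi_roberts_eval(eff.y, dense))

    idx = np.searchsorted(dense, tp)

    def finish(a):
        if a is None:
            return None, None
        ts = float(dense[np.argmax(a >= 0.99 * a[-1])])
        return a[idx], ts

    area_b, ts_b = finish(ab)
    area_y, ts_y = finish(ay)
    return area_b, area_y, ts_b, ts_y


def generate_experiment(config: ExperimentConfig) -> pd.DataFrame:
    """Generate a complete measurement table for one bead experiment.

    Deterministic for a fixed ``config.seed`` (three independent substreams:
    bead loading, colony shapes, measurement noise).  Raises a diagnostic
    error when the inoculum is so large that per-colony capacities fall below
    the initial colony size.
    """
    tp = np.asarray(config.time_points, dtype=float)
    ss = np.random.SeedSequence(config.seed)
    rng_counts, rng_shape, rng_noise = (np.random.default_rng(s)
                                        for s in ss.spawn(3))

    lam_b = config.mean_inoculum * config.strain_ratio
    lam_y = config.mean_inoculum * (1.0 - config.strain_ratio)
    n_b = rng_counts.poisson(lam_b, size=config.n_beads)
    n_y = rng_counts.poisson(lam_y, size=config.n_beads)

    pairs = sorted({(int(b), int(y)) for b, y in zip(n_b, n_y)} - {(0, 0)})
    if not pairs:
        out = empty_table()
        out.attrs.update(n_beads=config.n_beads, seed=config.seed,
                         mean_inoculum=config.mean_inoculum)
        return out

    nt = tp.size
    frames = []
    for nb, ny in pairs:
        area_b, area_y, ts_b, ts_y = _pair_trajectories(config, nb, ny, tp)
        bead_ids = np.nonzero((n_b == nb) & (n_y == ny))[0]
        m = bead_ids.size
        ntot = nb + ny

        base = np.vstack(([area_b] * nb if nb else [])
                         + ([area_y] * ny if ny else []))        # (ntot, nt)
        strains_bead = np.array(["B"] * nb + ["Y"] * ny)
        ts_vec = np.array([ts_b] * nb + [ts_y] * ny, dtype=float)
        k_vec = np.array([config.intensity_scale_b] * nb
                         + [config.intensity_scale_y] * ny, dtype=float)

        n_col = m * ntot
        ar = sample_aspect_ratios(n_col, config.ar_mode, config.ar_spread,
                                  rng_shape)
        area_noise = _lognormal_mult(rng_noise, config.noise_cv, (n_col, nt))
        int_noise = _lognormal_mult(rng_noise, config.intensity_noise_cv,
                                    (n_col, nt))

        area_true = np.tile(base, (m, 1))                        # (n_col, nt)
        area = area_true * area_noise
        decay = np.exp(-config.intensity_decay_rate
                       * np.clip(tp[None, :] - ts_vec[:, None], 0.0, None))
        decay = np.tile(decay, (m, 1))
        k = np.tile(np.repeat(k_vec, 1), m)[:, None]
        intensity = k * area * decay * int_noise

        ar_rows = np.repeat(ar, nt)
        area_rows = area.ravel()
        major = np.sqrt(4.0 * area_rows * ar_rows / np.pi)
        minor = np.sqrt(4.0 * area_rows / (np.pi * ar_rows))

        frames.append(pd.DataFrame({
            "bead_id": np.repeat(bead_ids, ntot * nt),
            "colony_id": np.tile(np.repeat(np.arange(ntot), nt), m),
            "strain": np.tile(np.repeat(strains_bead, nt), m),
            "time_h": np.tile(tp, n_col),
            "area_um2": area_rows,
            "perimeter_um": ramanujan_perimeter(major, minor),
            "major_axis_um": major,
            "minor_axis_um": minor,
            "intensity_au": intensity.ravel(),
        }))

    out = pd.concat(frames, ignore_index=True)
    out = out.sort_values(["bead_id", "colony_id", "time_h"],
                          kind="stable", ignore_index=True)
    out = out[list(COLUMNS)]
    out.attrs.update(n_beads=config.n_beads, seed=config.seed,
                     mean_inoculum=config.mean_inoculum)
    return out


# ---------------------------------------------------------------------------
# YAML configuration
# ---------------------------------------------------------------------------

def config_from_dict(data: dict) -> ExperimentConfig:
    """Build an :class:`ExperimentConfig` from a plain mapping (YAML block)."""
    data = dict(data)
    growth = data.pop("growth", None)
    if growth is not None:
        data["growth"] = CompetitionParams(
            b=MonocultureParams(**growth["b"]),
            y=MonocultureParams(**growth["y"]),
            c_b=float(growth.get("c_b", 0.0)),
            c_y=float(growth.get("c_y", 0.0)),
            normalization=growth.get("normalization", "focal"),
        )
    if "time_points" in data:
        data["time_points"] = tuple(float(t) for t in data["time_points"])
    return ExperimentConfig(**data)


def load_experiment_config(path) -> ExperimentConfig:
    """Load an experiment configuration from a YAML file."""
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    return config_from_dict(data)
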