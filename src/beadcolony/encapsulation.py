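"""Poisson statistics of two-strain bead loading.

When a dilute 1:1 mixture of two strains is dispersed into gel beads, the
founder counts per bead are independent Poisson draws with means λ·r (strain B)
and λ·(1−r) (strain Y), where λ is the mean total inoculum per bead and r the
mixing fraction of strain B.  This module provides the joint pmf, the
empty/monoculture/co-culture composition fractions, a Monte Carlo simulator,
and the monoculture-to-co-culture dominance crossover in λ.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


class NoCrossoverError(RuntimeError):
    """The co-culture fraction never exceeds the monoculture fraction in range."""


@dataclass(frozen=True)
class LoadingModel:
    """Two-strain Poisson loading: mean total inoculum λ and B-fraction r."""

    lam: float
    ratio: float = 0.5

    def __post_init__(self) -> None:
        if self.lam < 0:
            raise ValueError(f"lam must be >= 0, got {self.lam}")
        if not 0.0 <= self.ratio <= 1.0:
            raise ValueError(f"ratio must be in [0, 1], got {self.ratio}")

    @property
    def lam_b(self) -> float:
        return self.lam * self.ratio

    @property
    def lam_y(self) -> float:
        return self.lam * (1.0 - self.ratio)


@dataclass(frozen=True)
class CompositionFractions:
    """Fractions of empty, monoculture and co-culture beads (sum to 1)."""

    empty: float
    monoculture: float
    coculture: float


@dataclass
class BeadLoading:
    """Realized per-bead founder counts from a Monte Carlo draw."""

    n_b: np.ndarray
    n_y: np.ndarray

    @property
    def n_beads(self) -> int:
        return len(self.n_b)

    def joint_histogram(self, cap: int = 6):
        """Joint count histogram on the (0..cap)² grid plus one overflow cell.

        Returns ``(hist, overflow)`` where ``hist[i, j]`` counts beads with
        exactly i strain-B and j strain-Y founders and ``overflow`` counts
        beads where either strain exceeds ``cap``.  Total equals n_beads.
        """
        inside = (self.n_b <= cap) & (self.n_y <= cap)
        hist = np.zeros((cap + 1, cap + 1), dtype=int)
        np.add.at(hist, (self.n_b[inside], self.n_y[inside]), 1)
        return hist, int((~inside).sum())

    def composition_fractions(self) -> CompositionFractions:
        """Empirical empty/mono/co fractions of this draw."""
        empty = float(np.mean((self.n_b == 0) & (self.n_y == 0)))
        co = float(np.mean((self.n_b > 0) & (self.n_y > 0)))
        return CompositionFractions(empty, 1.0 - empty - co, co)


def joint_pmf(model: LoadingModel, n_b, n_y):
    """P(N_B = n_b, N_Y = n_y): product of the two independent Poisson pmfs."""
    n_b = np.asarray(n_b)
    n_y = np.asarray(n_y)
    if np.any(n_b < 0) or np.any(n_y < 0):
        raise ValueError("founder counts must be nonnegative")
    p = stats.poisson.pmf(n_b, model.lam_b) * stats.poisson.pmf(n_y, model.lam_y)
    return p if np.ndim(p) else float(p)


def composition_fractions(model: LoadingModel) -> CompositionFractions:
    """Closed-form fractions of empty, monoculture and co-culture beads.

    empty     = e^(−λ)
    coculture = (1 − e^(−λr))·(1 − e^(−λ(1−r)))
    mono      = 1 − empty − coculture
    """
    empty = float(np.exp(-model.lam))
    co = float((1.0 - np.exp(-model.lam_b)) * (1.0 - np.exp(-model.lam_y)))
    return CompositionFractions(empty, 1.0 - empty - co, co)


def simulate_loading(model: LoadingModel, n_beads: int, seed: int = 0) -> BeadLoading:
    """Monte Carlo draw of founder counts for ``n_beads`` beads."""
    if n_beads < 1:
        raise ValueError("n_beads must be >= 1")
    rng = np.random.default_rng(seed)
    return BeadLoading(
        n_b=rng.poisson(model.lam_b, size=n_beads),
        n_y=rng.poisson(model.lam_y, size=n_beads),
    )


def estimate_lambda(counts) -> float:
    """Maximum-likelihood λ from observed total founder counts (sample mean)."""
    counts = np.asarray(counts, dtype=float)
    if counts.size == 0:
        raise ValueError("need at least one observed count")
    return float(counts.mean())


def dominance_crossover(ratio: float = 0.5, step: float = 1e-3,
                        lam_max: float = 10.0) -> float:
    """Smallest grid λ at which co-culture beads outnumber monoculture beads.

    Scans λ on [0, lam_max] with the given step.  For a 1:1 mixture the exact
    crossover is λ* = 2·ln 3 ≈ 2.197 (root of e^(−λ/2) = 1/3); the grid value
    agrees within one step.  Raises :class:`NoCrossoverError` if the co-culture
    fraction never exceeds the monoculture fraction on the grid (e.g. r = 0).
    """
    if step <= 0:
        raise ValueError("step must be positive")
    lam = np.arange(0.0, lam_max + step / 2, step)
    co = (1.0 - np.exp(-lam * ratio)) * (1.0 - np.exp(-lam * (1.0 - ratio)))
    empty = np.exp(-lam)
    mono = 1.0 - empty - co
    above = np.nonzero(co > mono)[0]
    if above.size == 0:
        raise NoCrossoverError(
            f"co-culture fraction never exceeds monoculture for ratio={ratio} "
            f"on [0, {lam_max}]")
    return float(lam[above[0]])


def poisson_gof(loading: BeadLoading, model: LoadingModel, min_expected: float = 5.0):
    """Chi-square goodness of fit of a simulated draw against the joint pmf.

    Cells of the joint (n_B, n_Y) support with expected count below
    ``min_expected`` are pooled into a single tail cell.  Returns
    ``(chi2, p_value)``.
    """
    n = loading.n_beads
    cap = int(max(loading.n_b.max(initial=0), loading.n_y.max(initial=0),
                  np.ceil(model.lam + 6 * np.sqrt(model.lam + 1)))) + 1
    bb, yy = np.meshgrid(np.arange(cap + 1), np.arange(cap + 1), indexing="ij")
    expected = joint_pmf(model, bb, yy) * n
    hist = np.zeros((cap + 1, cap + 1), dtype=int)
    np.add.at(hist, (loading.n_b, loading.n_y), 1)

    keep = expected >= min_expected
    obs = np.append(hist[keep], hist[~keep].sum())
    exp = np.append(expected[keep], n - expected[keep].sum())
    # drop a pooled tail that is itself negligible to keep chisquare well posed
    if exp[-1] < min_expected:
        exp[-2] += exp[-1]
        obs[-2] += obs[-1]
        obs, exp = obs[:-1], exp[:-1]
    chi2, p = stats.chisquare(obs, exp)
    return float(chi2), float(p)
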