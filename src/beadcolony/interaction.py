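"""Median-quadrant classification of strain–strain interactions.

Final per-colony measurements (size or fluorescence intensity at a fixed
evaluation time, 12 h by default) from co-culture beads are randomly paired —
one strain-B value with one strain-Y value — and each pair is placed in a
four-quadrant map whose axes are split at the *monoculture* medians:

* both above their monoculture medians   → mutual facilitation
* B above, Y below                       → one-way inhibition of Y
* B below, Y above                       → one-way inhibition of B
* both below                             → mutual inhibition

Because the pairing is arbitrary, the procedure is repeated over many random
data sets (1000 by default) and quadrant percentages are reported as the mean
with a standard error across resamples.  Ties at the median count as "below";
for continuous measurements ties have probability ~0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Tuple

import numpy as np

QUADRANTS = ("both_above", "b_above_y_below", "b_below_y_above", "both_below")

#: human-oriented labels; only "mutual inhibition" is standard terminology
QUADRANT_LABELS = {
    "both_above": "mutual facilitation",
    "b_above_y_below": "one-way inhibition of Y",
    "b_below_y_above": "one-way inhibition of B",
    "both_below": "mutual inhibition",
}


@dataclass
class FinalMeasurements:
    """Per-strain final values in monoculture and co-culture conditions."""

    mono_b: np.ndarray
    mono_y: np.ndarray
    co_b: np.ndarray
    co_y: np.ndarray
    time_h: float = 12.0
    signal: str = "size"

    def __post_init__(self) -> None:
        for name in ("mono_b", "mono_y", "co_b", "co_y"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if np.any(arr < 0):
                raise ValueError(f"{name} contains negative values")
            setattr(self, name, arr)


@dataclass
class InteractionSummary:
    """Quadrant occupancies (mean % over resamples) with resampling spread.

    ``se`` is the standard error of the reported mean: SD of the quadrant
    fraction across resamples divided by √n_resamples.  ``resample_sd`` is
    the raw SD across resamples (the spread of a single random data set).
    """

    mean: Dict[str, float]
    se: Dict[str, float]
    resample_sd: Dict[str, float]
    n_pairs: int
    n_resamples: int
    median_b: float
    median_y: float
    time_h: float = 12.0
    signal: str = "size"
    condition: str = "co"


def monoculture_medians(meas: FinalMeasurements) -> Tuple[float, float]:
    """Sample medians of the monoculture values (midpoint for even n)."""
    if meas.mono_b.size == 0 or meas.mono_y.size == 0:
        raise ValueError("monoculture values required for both strains")
    return float(np.median(meas.mono_b)), float(np.median(meas.mono_y))


def random_pairs(values_b, values_y, rng) -> Tuple[np.ndarray, np.ndarray]:
    """Pair values by independent uniform shuffles, without replacement.

    ``n_pairs = min(len(values_b), len(values_y))``; surplus values of the
    longer list are left out of that data set.
    """
    values_b = np.asarray(values_b, dtype=float)
    values_y = np.asarray(values_y, dtype=float)
    if values_b.size == 0 or values_y.size == 0:
        raise ValueError("both value lists must be nonempty")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    n = min(values_b.size, values_y.size)
    b = rng.permutation(values_b)[:n]
    y = rng.permutation(values_y)[:n]
    return b, y


def quadrant_classify(pairs_b, pairs_y, median_b: float,
                      median_y: float) -> Dict[str, float]:
    """Quadrant percentages of one paired data set (sum to 100)."""
    if not (np.isfinite(median_b) and np.isfinite(median_y)):
        raise ValueError("medians must be finite")
    b = np.asarray(pairs_b, dtype=float)
    y = np.asarray(pairs_y, dtype=float)
    below_b = b <= median_b
    below_y = y <= median_y
    n = b.size
    return {
        "both_above": float(np.sum(~below_b & ~below_y)) / n * 100.0,
        "b_above_y_below": float(np.sum(~below_b & below_y)) / n * 100.0,
        "b_below_y_above": float(np.sum(below_b & ~below_y)) / n * 100.0,
        "both_below": float(np.sum(below_b & below_y)) / n * 100.0,
    }


def resample_interactions(meas: FinalMeasurements, n_resamples: int = 1000,
                          seed: int = 0, bootstrap: bool = False,
                          condition: str = "co",
                          medians: Optional[Tuple[float, float]] = None,
                          ) -> InteractionSummary:
    """Random-pairing resampling of the quadrant classification.

    Repeats :func:`random_pairs` + :func:`quadrant_classify` with independent
    pairing randomness.  ``condition`` selects which values are paired:
    "co" (default, the interaction readout) or "mono" (the neutral
    self-comparison reference).  With ``bootstrap=True`` the values are also
    resampled with replacement in every data set; the default redraws only
    the pairing.  Reference medians always come from the monoculture data
    unless overridden explicitly.
    """
    if n_resamples < 2:
        raise ValueError("n_resamples must be >= 2")
    if condition == "co":
        vb, vy = meas.co_b, meas.co_y
    elif condition == "mono":
        vb, vy = meas.mono_b, meas.mono_y
    else:
        raise ValueError("condition must be 'co' or 'mono'")
    med_b, med_y = monoculture_medians(meas) if medians is None else medians

    rng = np.random.default_rng(seed)
    fractions = np.empty((n_resamples, len(QUADRANTS)))
    for i in range(n_resamples):
        b_i, y_i = vb, vy
        if bootstrap:
            b_i = rng.choice(vb, size=vb.size, replace=True)
            y_i = rng.choice(vy, size=vy.size, replace=True)
        pb, py = random_pairs(b_i, y_i, rng)
        fr = quadrant_classify(pb, py, med_b, med_y)
        fractions[i] = [fr[q] for q in QUADRANTS]

    mean = fractions.mean(axis=0)
    sd = fractions.std(axis=0, ddof=1)
    se = sd / np.sqrt(n_resamples)
    return InteractionSummary(
        mean={q: float(mean[k]) for k, q in enumerate(QUADRANTS)},
        se={q: float(se[k]) for k, q in enumerate(QUADRANTS)},
        resample_sd={q: float(sd[k]) for k, q in enumerate(QUADRANTS)},
        n_pairs=min(vb.size, vy.size),
        n_resamples=n_resamples,
        median_b=med_b, median_y=med_y,
        time_h=meas.time_h, signal=meas.signal, condition=condition,
    )


def finals_from_tables(mono_b_table, mono_y_table, co_table,
                       time_h: float = 12.0,
                       signal: str = "size") -> FinalMeasurements:
    """Extract final per-colony values from measurement tables.

    Uses the table time point closest to ``time_h``.  Co-culture values come
    only from beads that contain both strains; the monoculture tables are
    single-strain experiments.
    """
    col = "area_um2" if signal == "size" else "intensity_au"

    def at_time(df):
        times = np.sort(df["time_h"].unique())
        if times.size == 0:
            raise ValueError("table has no rows")
        t = times[np.argmin(np.abs(times - time_h))]
        return df[df["time_h"] == t]

    def mono_values(df, strain):
        sub = at_time(df)
        sub = sub[sub["strain"] == strain]
        return sub[col].to_numpy(float)

    strains_per_bead = co_table.groupby("bead_id")["strain"].agg(set)
    co_beads = strains_per_bead[strains_per_bead == {"B", "Y"}].index
    co_final = at_time(co_table[co_table["bead_id"].isin(co_beads)])

    return FinalMeasurements(
        mono_b=mono_values(mono_b_table, "B"),
        mono_y=mono_values(mono_y_table, "Y"),
        co_b=co_final[co_final["strain"] == "B"][col].to_numpy(float),
        co_y=co_final[co_final["strain"] == "Y"][col].to_numpy(float),
        time_h=time_h, signal=signal,
    )


def plot_interaction_map(meas: FinalMeasurements, path=None, seed: int = 0,
                         ax=None):
    """Scatter of one random pairing: grey monoculture pairs, red co-culture
    pairs, dashed lines at the monoculture medians.  Returns the axes."""
    import matplotlib
    if path is not None:
        matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    med_b, med_y = monoculture_medians(meas)
    rng = np.random.default_rng(seed)
    mb, my = random_pairs(meas.mono_b, meas.mono_y, rng)
    cb, cy = random_pairs(meas.co_b, meas.co_y, rng)
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    ax.scatter(mb, my, s=10, c="grey", alpha=0.5, label="monoculture pairs")
    ax.scatter(cb, cy, s=10, c="crimson", alpha=0.6, label="co-culture pairs")
    ax.axvline(med_b, ls="--", c="steelblue")
    ax.axhline(med_y, ls="--", c="goldenrod")
    unit = "area (μm²)" if meas.signal == "size" else "intensity (au)"
    ax.set_xlabel(f"E. coli BFP final {unit}")
    ax.set_ylabel(f"E. coli YFP final {unit}")
    ax.legend(frameon=False)
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
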