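"""Measurement-table schema and CSV round-trip.

The contract replacing raw image analysis is a long-format CSV, one row per
(bead, colony, strain, time point), with fixed header::

    bead_id,colony_id,strain,time_h,area_um2,perimeter_um,major_axis_um,minor_axis_um,intensity_au

Strain labels are "B" (BFP-tagged) and "Y" (YFP-tagged).  Units are encoded in
the column names to prevent silent unit drift.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

COLUMNS = (
    "bead_id", "colony_id", "strain", "time_h", "area_um2", "perimeter_um",
    "major_axis_um", "minor_axis_um", "intensity_au",
)
STRAINS = ("B", "Y")

#: relative tolerance on area <= ellipse area for rasterized measurements
ELLIPSE_AREA_TOL = 0.05


class SchemaError(ValueError):
    """The table violates the measurement-table contract."""


def empty_table() -> pd.DataFrame:
    """A zero-row table with the contract's columns and dtypes."""
    return pd.DataFrame({
        "bead_id": pd.Series(dtype=int),
        "colony_id": pd.Series(dtype=int),
        "strain": pd.Series(dtype=str),
        "time_h": pd.Series(dtype=float),
        "area_um2": pd.Series(dtype=float),
        "perimeter_um": pd.Series(dtype=float),
        "major_axis_um": pd.Series(dtype=float),
        "minor_axis_um": pd.Series(dtype=float),
        "intensity_au": pd.Series(dtype=float),
    })


def validate_table(df: pd.DataFrame, area_tol: float = ELLIPSE_AREA_TOL) -> None:
    """Raise :class:`SchemaError` naming the offending column/row on violation."""
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing column(s): {', '.join(missing)}")
    extra = [c for c in df.columns if c not in COLUMNS]
    if extra:
        raise SchemaError(f"unknown column(s): {', '.join(extra)}")
    if len(df) == 0:
        return

    bad = ~df["strain"].isin(STRAINS)
    if bad.any():
        row = int(np.nonzero(bad.to_numpy())[0][0])
        raise SchemaError(
            f"row {row}: unknown strain label {df['strain'].iloc[row]!r} "
            f"(allowed: {', '.join(STRAINS)})")

    for col in ("area_um2", "perimeter_um", "major_axis_um", "minor_axis_um"):
        nonpos = ~(df[col].to_numpy(float) > 0)
        if nonpos.any():
            row = int(np.nonzero(nonpos)[0][0])
            raise SchemaError(f"row {row}: {col} must be positive "
                              f"({df[col].iloc[row]!r})")
    neg = df["intensity_au"].to_numpy(float) < 0
    if neg.any():
        row = int(np.nonzero(neg)[0][0])
        raise SchemaError(f"row {row}: intensity_au must be >= 0")

    sw = df["major_axis_um"].to_numpy(float) < df["minor_axis_um"].to_numpy(float)
    if sw.any():
        row = int(np.nonzero(sw)[0][0])
        raise SchemaError(f"row {row}: major_axis_um < minor_axis_um")

    ell = np.pi * (df["major_axis_um"].to_numpy(float) / 2) * \
        (df["minor_axis_um"].to_numpy(float) / 2)
    over = df["area_um2"].to_numpy(float) > ell * (1.0 + area_tol)
    if over.any():
        row = int(np.nonzero(over)[0][0])
        raise SchemaError(f"row {row}: area exceeds the fitted-ellipse area "
                          f"beyond tolerance ({area_tol:.0%})")

    # one strain per (bead, colony); strictly increasing times per colony
    grp = df.groupby(["bead_id", "colony_id"], sort=False)
    multi = grp["strain"].nunique()
    if (multi > 1).any():
        bead, colony = multi[multi > 1].index[0]
        raise SchemaError(f"colony (bead {bead}, colony {colony}) carries "
                          "more than one strain label")
    for (bead, colony), idx in grp.indices.items():
        tt = df["time_h"].to_numpy(float)[idx]
        if np.any(np.diff(tt) <= 0):
            k = int(np.nonzero(np.diff(tt) <= 0)[0][0])
            raise SchemaError(
                f"row {idx[k + 1]}: non-monotone time for (bead {bead}, "
                f"colony {colony}): {tt[k]} -> {tt[k + 1]}")


def write_table(df: pd.DataFrame, destination) -> None:
    """Validate and write a measurement table as UTF-8 CSV with fixed header."""
    validate_table(df)
    # %.17g guarantees exact float64 round-trip through the text file
    df.to_csv(destination, index=False, columns=list(COLUMNS),
              float_format=lambda v: format(float(v), ".17g"))


def read_table(source) -> pd.DataFrame:
    """Read and validate a measurement table; values round-trip exactly."""
    df = pd.read_csv(source, dtype={"strain": str},
                     float_precision="round_trip")
    validate_table(df)
    return df.astype({
        "bead_id": int, "colony_id": int, "time_h": float, "area_um2": float,
        "perimeter_um": float, "major_axis_um": float, "minor_axis_um": float,
        "intensity_au": float,
    })
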