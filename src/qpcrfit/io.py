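"""Reading and writing of amplification data and result reports.

The single input dialect is a long (tidy) delimited table with columns
``well``, ``dilution_exponent``, ``cycle``, ``fluorescence``.  Wide
cycle-by-well matrices are converted by :func:`wide_to_long`, not accepted
directly.  Results are serialized as JSON (key/value with nested lists),
which round-trips floats at full precision.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable

import numpy as np
import pandas as pd

from .exceptions import SeriesFormatError, SeriesIntegrityError, SeriesParseError

REQUIRED_COLUMNS = ("well", "dilution_exponent", "cycle", "fluorescence")


@dataclass
class AmplificationCurve:
    """One baselined fluorescence trace tagged with its dilution exponent.

    The concentration of the reaction is ``c0 / D**dilution_exponent`` where
    ``D`` is the dilution factor of the enclosing series.  Fluorescence is in
    RFU and may be slightly negative near zero after baselining.
    """

    well_id: str
    dilution_exponent: int
    cycles: np.ndarray
    fluorescence: np.ndarray

    def __post_init__(self) -> None:
        self.cycles = np.asarray(self.cycles)
        self.fluorescence = np.asarray(self.fluorescence, dtype=float)
        if self.cycles.shape != self.fluorescence.shape:
            raise SeriesIntegrityError(
                f"well {self.well_id!r}: cycles and fluorescence lengths differ "
                f"({self.cycles.size} vs {self.fluorescence.size})"
            )
        if self.cycles.size and np.any(np.diff(self.cycles) <= 0):
            raise SeriesIntegrityError(
                f"well {self.well_id!r}: cycles must be strictly increasing"
            )
        if self.dilution_exponent < 0:
            raise SeriesIntegrityError(
                f"well {self.well_id!r}: dilution exponent must be >= 0"
            )

    def __len__(self) -> int:
        return int(self.cycles.size)


@dataclass
class DilutionSeries:
    """A set of amplification curves related by a common dilution factor."""

    curves: list[AmplificationCurve]
    dilution_factor: float = 2.0

    def __post_init__(self) -> None:
        if self.dilution_factor <= 1:
            raise SeriesIntegrityError("dilution factor must be > 1")
        exponents = [c.dilution_exponent for c in self.curves]
        if len(set(exponents)) != len(exponents):
            raise SeriesIntegrityError(
                f"dilution exponents not unique across curves: {exponents}"
            )
        self.curves = sorted(self.curves, key=lambda c: c.dilution_exponent)

    def __len__(self) -> int:
        return len(self.curves)

    def __iter__(self):
        return iter(self.curves)


def _numeric_column(df: pd.DataFrame, name: str) -> pd.Series:
    converted = pd.to_numeric(df[name], errors="coerce")
    bad = converted.isna() & df[name].notna()
    if bad.any():
        row = int(bad.idxmax()) + 2  # +1 header, +1 one-based
        raise SeriesParseError(
            f"non-numeric value {df[name][bad.idxmax()]!r} in column "
            f"{name!r} at file row {row}"
        )
    if converted.isna().any():
        row = int(converted.isna().idxmax()) + 2
        raise SeriesParseError(f"missing value in column {name!r} at file row {row}")
    return converted


def read_series(
    path: str | Path,
    dilution_factor: float = 2.0,
    delimiter: str = ",",
) -> DilutionSeries:
    """Read a long-format delimited file into a :class:`DilutionSeries`.

    Rows are grouped by well and sorted by cycle, so the file row order is
    immaterial.  A missing required column raises :class:`SeriesFormatError`;
    a non-numeric cell raises :class:`SeriesParseError` with the offending
    file row; duplicate ``(well, cycle)`` rows raise
    :class:`SeriesIntegrityError`.
    """
    df = pd.read_csv(path, sep=delimiter, dtype=str, skipinitialspace=True)
    df.columns = [c.strip() for c in df.columns]
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise SeriesFormatError(f"missing required column {col!r}")

    exponent = _numeric_column(df, "dilution_exponent")
    cycle = _numeric_column(df, "cycle")
    fluor = _numeric_column(df, "fluorescence")
    well = df["well"].astype(str).str.strip()

    dup = pd.DataFrame({"well": well, "cycle": cycle}).duplicated()
    if dup.any():
        w, c = well[dup.idxmax()], cycle[dup.idxmax()]
        raise SeriesIntegrityError(f"duplicate (well, cycle) entry: ({w!r}, {c:g})")

    curves = []
    for well_id, grp in pd.DataFrame(
        {"well": well, "j": exponent, "cycle": cycle, "y": fluor}
    ).groupby("well", sort=True):
        js = grp["j"].unique()
        if js.size != 1:
            raise SeriesIntegrityError(
                f"well {well_id!r} has multiple dilution exponents: {sorted(js)}"
            )
        grp = grp.sort_values("cycle")
        curves.append(
            AmplificationCurve(
                well_id=str(well_id),
                dilution_exponent=int(js[0]),
                cycles=grp["cycle"].to_numpy(dtype=int),
                fluorescence=grp["y"].to_numpy(dtype=float),
            )
        )
    return DilutionSeries(curves=curves, dilution_factor=dilution_factor)


def write_series(series: DilutionSeries, path: str | Path) -> None:
    """Write a series as long-format CSV (inverse of :func:`read_series`)."""
    frames = [
        pd.DataFrame(
            {
                "well": c.well_id,
                "dilution_exponent": c.dilution_exponent,
                "cycle": c.cycles,
                "fluorescence": c.fluorescence,
            }
        )
        for c in series.curves
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def wide_to_long(
    df: pd.DataFrame, well_exponents: dict[str, int], cycle_column: str = "cycle"
) -> pd.DataFrame:
    """Convert a wide cycle-by-well matrix to the long schema.

    ``well_exponents`` maps wide column names to dilution exponents; columns
    not listed are dropped.
    """
    if cycle_column not in df.columns:
        raise SeriesFormatError(f"missing cycle column {cycle_column!r}")
    records = []
    for well, j in well_exponents.items():
        if well not in df.columns:
            raise SeriesFormatError(f"well column {well!r} not found")
        records.append(
            pd.DataFrame(
                {
                    "well": well,
                    "dilution_exponent": j,
                    "cycle": df[cycle_column],
                    "fluorescence": df[well],
                }
            )
        )
    return pd.concat(records, ignore_index=True)


def _jsonable(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        out = {"_type": type(obj).__name__}
        for f in dataclasses.fields(obj):
            out[f.name] = _jsonable(getattr(obj, f.name))
        return out
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_result(result: Any, path: str | Path) -> None:
    """Serialize any result object (dataclass, dict, list) to JSON text.

    Floats are written with full ``repr`` precision so read-back reproduces
    values exactly.
    """
    with open(path, "w") as fh:
        json.dump(_jsonable(result), fh, indent=2)
        fh.write("\n")


def read_result(path: str | Path) -> Any:
    """Read back a report written by :func:`write_result` (as plain dicts)."""
    with open(path) as fh:
        return json.load(fh)
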