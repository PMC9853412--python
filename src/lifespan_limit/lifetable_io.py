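"""Period life tables in the Human Mortality Database (HMD) text dialect.

An HMD "Life tables, period 1x1" file carries one population's period life
tables, one row per (Year, Age), with the standard columns

    Year  Age  mx  qx  ax  lx  dx  Lx  Tx  ex

on single-year ages ``0 .. 109`` plus the open interval ``110+``.  Files
begin with a short free-text preamble (population name, data revision) and a
column-header line; missing cells are written as ``"."``.  A plain CSV
mirror with the same columns is accepted/emitted when the path ends in
``.csv``.

This module reads and writes that dialect, validates the life-table
invariants (consecutive integer ages, non-increasing ``lx``, probabilities
in [0, 1]) and converts a table into a survival curve ``s(x) = lx / l0``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "HMD_COLUMNS",
    "OPEN_AGE",
    "LifeTable",
    "SurvivalCurve",
    "LifeTableError",
    "ParseError",
    "YearNotFoundError",
    "read_hmd_lifetable",
    "write_hmd_lifetable",
    "available_years",
    "survival_from_lifetable",
]

#: Column order of the HMD period 1x1 dialect.
HMD_COLUMNS = ("Year", "Age", "mx", "qx", "ax", "lx", "dx", "Lx", "Tx", "ex")

#: Optional columns carried through verbatim when present.
OPTIONAL_COLUMNS = ("mx", "ax", "dx", "Lx", "Tx", "ex")

#: Start of the open age interval ("110+") in HMD 1x1 tables.
OPEN_AGE = 110

#: Monotonicity tolerance for survival probabilities (input-error threshold).
MONOTONE_TOL = 1e-12


class LifeTableError(ValueError):
    """Invalid life-table content (failed invariant)."""


class ParseError(LifeTableError):
    """Malformed life-table file."""


class YearNotFoundError(LifeTableError):
    """Requested calendar year absent from the file."""


@dataclass
class LifeTable:
    """One population-year of period life-table columns on integer ages.

    ``qx`` and ``lx`` are required; the remaining HMD columns are carried in
    ``extras`` (float arrays, ``nan`` marking a missing cell — HMD files
    legitimately contain ``"."`` at old ages, and a missing cell must never
    silently become 0).
    """

    population_label: str
    year: int
    ages: np.ndarray
    qx: np.ndarray
    lx: np.ndarray
    radix: float = 100_000.0
    open_interval: bool = True
    extras: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.ages = np.asarray(self.ages, dtype=int)
        self.qx = np.asarray(self.qx, dtype=float)
        self.lx = np.asarray(self.lx, dtype=float)
        self.extras = {k: np.asarray(v, dtype=float) for k, v in self.extras.items()}
        self.validate()

    def validate(self) -> None:
        n = self.ages.size
        if n == 0:
            raise LifeTableError("life table has an empty age list")
        if self.qx.shape != (n,) or self.lx.shape != (n,):
            raise LifeTableError("qx/lx length does not match ages")
        if self.ages[0] != 0 or not np.array_equal(np.diff(self.ages), np.ones(n - 1, dtype=int)):
            raise LifeTableError("ages must be consecutive integers starting at 0")
        if not np.all(np.isfinite(self.lx)):
            raise LifeTableError("lx contains missing values")
        if self.radix <= 0:
            raise LifeTableError(f"radix must be positive, got {self.radix}")
        if self.lx[0] != self.radix:
            raise LifeTableError(
                f"lx[0] = {self.lx[0]} does not equal the radix {self.radix}"
            )
        if np.any(self.lx < 0):
            raise LifeTableError("lx contains negative values")
        if np.any(np.diff(self.lx) > MONOTONE_TOL * self.radix):
            bad = int(np.argmax(np.diff(self.lx) > MONOTONE_TOL * self.radix))
            raise LifeTableError(
                f"lx increases between ages {self.ages[bad]} and {self.ages[bad + 1]}"
            )
        finite_q = np.isfinite(self.qx)
        if np.any((self.qx[finite_q] < 0) | (self.qx[finite_q] > 1)):
            raise LifeTableError("qx outside [0, 1]")
        if self.open_interval and finite_q[-1] and abs(self.qx[-1] - 1.0) > 1e-9:
            raise LifeTableError(
                f"qx at the open interval {OPEN_AGE}+ must be 1, got {self.qx[-1]}"
            )
        for name, col in self.extras.items():
            if col.shape != (n,):
                raise LifeTableError(f"extra column {name!r} has wrong length")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, LifeTable):
            return NotImplemented
        same_extras = set(self.extras) == set(other.extras) and all(
            np.array_equal(self.extras[k], other.extras[k], equal_nan=True)
            for k in self.extras
        )
        return (
            self.population_label == other.population_label
            and self.year == other.year
            and self.radix == other.radix
            and self.open_interval == other.open_interval
            and np.array_equal(self.ages, other.ages)
            and np.array_equal(self.qx, other.qx, equal_nan=True)
            and np.array_equal(self.lx, other.lx)
            and same_extras
        )


@dataclass
class SurvivalCurve:
    """Ages paired with survival probabilities, ``s(0) = 1``, non-increasing."""

    ages: np.ndarray
    s: np.ndarray
    source_label: str = ""

    def __post_init__(self) -> None:
        self.ages = np.asarray(self.ages, dtype=float)
        self.s = np.asarray(self.s, dtype=float)
        self.validate()

    def validate(self) -> None:
        if self.ages.size < 2:
            raise LifeTableError("survival curve needs at least two ages")
        if self.ages.shape != self.s.shape:
            raise LifeTableError("ages and s have different lengths")
        if np.any(np.diff(self.ages) <= 0):
            raise LifeTableError("ages must be strictly increasing")
        if abs(self.s[0] - 1.0) > MONOTONE_TOL:
            raise LifeTableError(f"s[0] must be 1, got {self.s[0]}")
        if np.any((self.s < -MONOTONE_TOL) | (self.s > 1 + MONOTONE_TOL)):
            raise LifeTableError("s outside [0, 1]")
        if np.any(np.diff(self.s) > MONOTONE_TOL):
            bad = int(np.argmax(np.diff(self.s) > MONOTONE_TOL))
            raise LifeTableError(
                f"s increases between ages {self.ages[bad]} and {self.ages[bad + 1]}"
            )


# ---------------------------------------------------------------------------
# reading
# ---------------------------------------------------------------------------

def _parse_age(token: str, lineno: int | None = None) -> tuple[int, bool]:
    """Return (integer age, is_open_interval). '110+' maps to (110, True)."""
    open_iv = token.endswith("+")
    try:
        return int(token.rstrip("+")), open_iv
    except ValueError:
        where = f" on line {lineno}" if lineno is not None else ""
        raise ParseError(f"unparseable age {token!r}{where}") from None


def _cell(token: str, lineno: int) -> float:
    if token == ".":
        return math.nan
    try:
        return float(token)
    except ValueError:
        raise ParseError(f"unparseable value {token!r} on line {lineno}") from None


def _read_text_frame(path: Path) -> tuple[str, pd.DataFrame]:
    """Parse an HMD-dialect text file into (population label, raw frame).

    Preamble lines (anything before the first data row that does not start
    with a calendar year) are skipped; the first non-empty one is taken as
    the population label.
    """
    label = path.stem
    records: list[dict] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            tokens = line.split()
            if not tokens:
                continue
            try:
                year = int(tokens[0])
            except ValueError:
                if records:
                    raise ParseError(
                        f"non-data line {lineno} after data rows began"
                    ) from None
                if tokens[0] != "Year":  # header row is not a label
                    label = line.strip()
                    # HMD title lines read "<population>, Life tables (...)..."
                    cut = label.find(", Life tables")
                    if cut > 0:
                        label = label[:cut]
                continue
            if len(tokens) != len(HMD_COLUMNS):
                raise ParseError(
                    f"line {lineno}: expected {len(HMD_COLUMNS)} columns, "
                    f"got {len(tokens)}"
                )
            age, open_iv = _parse_age(tokens[1], lineno)
            rec = {"Year": year, "Age": age, "_open": open_iv}
            for name, tok in zip(HMD_COLUMNS[2:], tokens[2:]):
                rec[name] = _cell(tok, lineno)
            records.append(rec)
    if not records:
        raise ParseError(f"no data rows found in {path}")
    return label, pd.DataFrame.from_records(records)


def _read_csv_frame(path: Path) -> tuple[str, pd.DataFrame]:
    df = pd.read_csv(path, dtype=str, na_values=["."], keep_default_na=False)
    missing = [c for c in ("Year", "Age", "qx", "lx") if c not in df.columns]
    if missing:
        raise ParseError(f"CSV is missing required columns {missing}")
    out = pd.DataFrame()
    out["Year"] = df["Year"].astype(int)
    ages_open = [_parse_age(str(a)) for a in df["Age"]]
    out["Age"] = [a for a, _ in ages_open]
    out["_open"] = [o for _, o in ages_open]
    for name in HMD_COLUMNS[2:]:
        if name in df.columns:
            # float() is exact on shortest-repr output; pd.to_numeric is not
            out[name] = [
                float(v) if isinstance(v, str) and v != "" else math.nan
                for v in df[name]
            ]
    return path.stem, out


def _load_frame(path: str | Path) -> tuple[str, pd.DataFrame]:
    path = Path(path)
    if path.suffix.lower() == ".csv":
        return _read_csv_frame(path)
    return _read_text_frame(path)


def read_hmd_lifetable(path: str | Path, year: int) -> LifeTable:
    """Read one calendar year of a period 1x1 life-table file.

    The ``110+`` open-interval row is stored as integer age 110 and flagged;
    ``"."`` cells become ``nan`` (an explicit missing marker, never 0).

    Raises
    ------
    YearNotFoundError
        If `year` has no rows in the file.
    ParseError
        On malformed lines (wrong column count, unparseable cells).
    LifeTableError
        If the parsed table violates life-table invariants (e.g. ``lx``
        increasing with age).
    """
    label, frame = _load_frame(path)
    sub = frame[frame["Year"] == year]
    if sub.empty:
        years = sorted(frame["Year"].unique())
        raise YearNotFoundError(
            f"year {year} not found in {path} (available: {years[0]}–{years[-1]})"
        )
    sub = sub.sort_values("Age")
    ages = sub["Age"].to_numpy(dtype=int)
    lx = sub["lx"].to_numpy(dtype=float)
    qx = (
        sub["qx"].to_numpy(dtype=float)
        if "qx" in sub.columns
        else np.full(ages.size, math.nan)
    )
    open_iv = bool(sub["_open"].iloc[-1]) if "_open" in sub.columns else False
    extras = {
        name: sub[name].to_numpy(dtype=float)
        for name in OPTIONAL_COLUMNS
        if name in sub.columns and not sub[name].isna().all()
    }
    if not np.all(np.isfinite(lx)):
        raise LifeTableError(f"lx column for year {year} contains missing values")
    return LifeTable(
        population_label=label,
        year=year,
        ages=ages,
        qx=qx,
        lx=lx,
        radix=float(lx[0]),
        open_interval=open_iv,
        extras=extras,
    )


def available_years(path: str | Path) -> list[int]:
    """Calendar years present in a life-table file, sorted."""
    _, frame = _load_frame(path)
    return sorted(int(y) for y in frame["Year"].unique())


# ---------------------------------------------------------------------------
# writing
# ---------------------------------------------------------------------------

def _fmt(value: float) -> str:
    if not math.isfinite(value):
        return "."
    if value == int(value) and abs(value) < 1e15:
        return str(int(value))
    return repr(float(value))  # shortest round-trip representation


def _table_rows(table: LifeTable) -> list[list[str]]:
    rows = []
    n = table.ages.size
    for i in range(n):
        age_label = str(table.ages[i])
        if table.open_interval and i == n - 1:
            age_label += "+"
        cells = [str(table.year), age_label]
        for name in HMD_COLUMNS[2:]:
            if name == "qx":
                cells.append(_fmt(table.qx[i]))
            elif name == "lx":
                cells.append(_fmt(table.lx[i]))
            else:
                col = table.extras.get(name)
                cells.append(_fmt(col[i]) if col is not None else ".")
        rows.append(cells)
    return rows


def write_hmd_lifetable(
    table: LifeTable | Sequence[LifeTable], path: str | Path
) -> None:
    """Write one or more life tables to `path` in the HMD text dialect.

    Accepts a single table or a sequence sharing one population (a multi-year
    file, as HMD distributes them).  A ``.csv`` extension selects the CSV
    mirror.  Floats are written in shortest round-trip form so that
    ``read_hmd_lifetable(write(...)) == table`` exactly; missing cells are
    written as ``"."``.
    """
    tables = [table] if isinstance(table, LifeTable) else list(table)
    if not tables:
        raise LifeTableError("no tables to write")
    for t in tables:
        t.validate()
    path = Path(path)
    all_rows = [row for t in tables for row in _table_rows(t)]
    if path.suffix.lower() == ".csv":
        df = pd.DataFrame(all_rows, columns=list(HMD_COLUMNS))
        df.to_csv(path, index=False)
        return
    label = tables[0].population_label
    widths = [max(len(r[j]) for r in all_rows + [list(HMD_COLUMNS)]) for j in range(len(HMD_COLUMNS))]
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"{label}, Life tables (period 1x1)\n\n")
        fh.write("  ".join(c.rjust(w) for c, w in zip(HMD_COLUMNS, widths)) + "\n")
        for row in all_rows:
            fh.write("  ".join(c.rjust(w) for c, w in zip(row, widths)) + "\n")


# ---------------------------------------------------------------------------
# survival curves
# ---------------------------------------------------------------------------

def survival_from_lifetable(table: LifeTable) -> SurvivalCurve:
    """Survival curve ``s(x) = lx / l0`` of one life table.

    ``s(0)`` is set to exactly 1 after the division by the radix.
    """
    table.validate()
    s = table.lx / table.radix
    s[0] = 1.0
    return SurvivalCurve(
        ages=table.ages.astype(float),
        s=s,
        source_label=f"{table.population_label} {table.year}",
    )
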