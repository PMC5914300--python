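"""Typed schemas and validated CSV I/O for the eleven published tables.

The long-term spacing-trial dataset is distributed as plain CSV with fixed
column names: plot geometry (``corner``, ``area``), the tree register
(``pos``), the campaign calendar (``date``), repeated per-tree measurements
(``dbhObs``, ``crown``), stem-analysis references (``secDiam``, ``saTree``,
``saIr``, ``saDisc``) and the processed output (``dhcComplSmooth``).

Conventions, kept exactly as published:

* an empty CSV field means *absent*; ``"0"`` is a value (crown code 0 is
  "normal"), never a missing marker;
* dates are ISO ``Year-Month-Day``; internally, increment arithmetic uses
  decimal years (``year + day_of_year/365.25``);
* units are preserved as published (diameter mm, heights dm, crown radii m,
  ring widths 1/100 mm); conversions happen only inside computations.

The register's removal-reason column is spelled ``removeal`` in the published
files and that header is kept verbatim so round trips are field-for-field
identical.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from pathlib import Path
import numpy as np
import pandas as pd

__all__ = [
    "SCHEMAS",
    "SPECIES_CODES",
    "Schema",
    "Column",
    "Issue",
    "SchemaError",
    "ValidationError",
    "read_table",
    "write_table",
    "read_dataset",
    "write_dataset",
    "validate_dataset",
    "decimal_year",
    "from_decimal_year",
]

SPECIES_CODES = ("PCAB", "LADC", "PNSY", "FASY", "QCPE", "BTPE")


class SchemaError(ValueError):
    """Header does not match the published schema."""


class ValidationError(ValueError):
    """A value violates its published domain or an invariant."""


@dataclass(frozen=True)
class Column:
    name: str
    kind: str  # int | float | str | bool | date
    domain: tuple | None = None  # closed enumeration of allowed values
    minimum: float | None = None


@dataclass(frozen=True)
class Schema:
    name: str
    columns: tuple[Column, ...]

    @property
    def column_names(self) -> list[str]:
        return [c.name for c in self.columns]


def _cols(*specs) -> tuple[Column, ...]:
    return tuple(Column(*s) if isinstance(s, tuple) else s for s in specs)


_CROWN_DIRS = [17, 62, 107, 152, 197, 242, 287, 332]

SCHEMAS: dict[str, Schema] = {
    s.name: s
    for s in [
        Schema("corner", _cols(
            ("plot", "int", (1, 2, 3, 4)), ("corner", "int"), ("cor", "bool"),
            ("x", "float"), ("y", "float"), ("lon", "float"), ("lat", "float"),
        )),
        Schema("area", _cols(
            ("plot", "int", (1, 2, 3, 4)), ("area", "float", None, 0.0),
        )),
        Schema("pos", _cols(
            ("plot", "int", (1, 2, 3, 4)), ("tree", "int"),
            ("x", "float"), ("y", "float"), ("z", "float"),
            ("species", "str", SPECIES_CODES), ("posObs", "bool"),
            ("germinationYear", "int"), ("core", "bool"),
            ("removeDate", "date"),
            ("removeal", "int", tuple(range(1, 10))),
            ("lon", "float"), ("lat", "float"),
        )),
        Schema("date", _cols(
            ("plot", "int", (1, 2, 3, 4)), ("year", "int"), ("obs", "int"),
            ("date", "date"),
        )),
        Schema("dbhObs", _cols(
            ("plot", "int", (1, 2, 3, 4)), ("tree", "int"),
            ("year", "int"), ("obs", "int"),
            ("dbh", "float", None, 0.0), ("dbh2", "float", None, 0.0),
            ("hmk", "int", tuple(range(1, 8))), ("kh", "int", (0, 1)),
            ("ho", "float"), ("ka", "float"), ("kb", "float"), ("wka", "float"),
            ("kraft", "int", tuple(range(1, 6))),
            ("crown", "int", tuple(range(0, 7))),
            ("stem", "int", tuple(range(0, 10))),
            ("defoliation", "int", (1, 2, 3)),
        )),
        Schema("crown", _cols(
            ("plot", "int", (1, 2, 3, 4)), ("tree", "int"),
            ("year", "int"), ("obs", "int"),
            *[(f"d{d}", "float", None, 0.0) for d in _CROWN_DIRS],
        )),
        Schema("secDiam", _cols(
            ("plot", "int", (1, 2, 3, 4)), ("tree", "int"), ("year", "int"),
            ("species", "str", SPECIES_CODES),
            ("length", "float", None, 0.0), ("dbh", "float", None, 0.0),
            ("crownLength", "float", None, 0.0),
            ("crownWidth", "float", None, 0.0),
            *[(f"m{i}", "float", None, 0.0) for i in range(1, 28)],
        )),
        Schema("saTree", _cols(
            ("plot", "int", (1, 2, 3, 4)), ("tree", "int"),
            ("species", "str", SPECIES_CODES),
            ("dbh", "float", None, 0.0), ("height", "float", None, 0.0),
            ("hKrown", "float", None, 0.0),
        )),
        Schema("saIr", _cols(
            ("plot", "int", (1, 2, 3, 4)), ("tree", "int"), ("disc", "int"),
            ("dir", "str"), ("year", "int"), ("ir", "float", None, 0.0),
        )),
        Schema("saDisc", _cols(
            ("plot", "int", (1, 2, 3, 4)), ("tree", "int"), ("disc", "int"),
            ("h", "float", None, 0.0),
        )),
        Schema("dhcComplSmooth", _cols(
            ("plot", "int", (1, 2, 3, 4)), ("tree", "int"),
            ("year", "int"), ("obs", "int"),
            ("d", "float", None, 0.0), ("h", "float", None, 0.0),
            ("hCr", "float", None, 0.0),
        )),
    ]
}


# ---------------------------------------------------------------------------
# time helpers

def decimal_year(date) -> float:
    """Calendar date -> decimal year (``year + day_of_year/365.25``)."""
    ts = pd.Timestamp(date)
    return ts.year + ts.dayofyear / 365.25


def from_decimal_year(t: float) -> _dt.date:
    year = int(np.floor(t))
    doy = int(round((t - year) * 365.25))
    doy = min(max(doy, 1), 365)
    return _dt.date(year, 1, 1) + _dt.timedelta(days=doy - 1)


# ---------------------------------------------------------------------------
# reading

def _parse_column(raw: pd.Series, col: Column, table: str) -> pd.Series:
    absent = raw == ""
    out: pd.Series
    if col.kind == "int":
        vals = pd.to_numeric(raw.where(~absent), errors="coerce")
        bad = (~absent) & vals.isna()
        if bad.any():
            raise ValidationError(
                f"{table}.{col.name}: non-integer values at rows "
                f"{list(raw.index[bad][:5])}")
        out = vals.astype("Int64")
    elif col.kind == "float":
        vals = pd.to_numeric(raw.where(~absent), errors="coerce")
        bad = (~absent) & vals.isna()
        if bad.any():
            raise ValidationError(
                f"{table}.{col.name}: non-numeric values at rows "
                f"{list(raw.index[bad][:5])}")
        out = vals.astype(float)
    elif col.kind == "bool":
        up = raw.str.upper()
        ok = absent | up.isin(["TRUE", "FALSE"])
        if not ok.all():
            raise ValidationError(
                f"{table}.{col.name}: expected TRUE/FALSE, got "
                f"{raw[~ok].iloc[0]!r}")
        out = pd.Series(pd.array(
            [None if a else (v == "TRUE") for a, v in zip(absent, up)],
            dtype="boolean"), index=raw.index)
    elif col.kind == "date":
        try:
            out = pd.to_datetime(raw.where(~absent), format="%Y-%m-%d")
        except (ValueError, TypeError) as exc:
            raise ValidationError(
                f"{table}.{col.name}: unparseable date ({exc})") from exc
    else:  # str
        out = raw.where(~absent, other=pd.NA).astype("string")
    if col.domain is not None:
        present = out.notna()
        in_dom = out.isin(list(col.domain))
        bad = present & ~in_dom
        if bad.any():
            raise ValidationError(
                f"{table}.{col.name}: value {out[bad].iloc[0]!r} outside "
                f"published domain {col.domain} at rows "
                f"{list(out.index[bad][:5])}")
    if col.minimum is not None:
        bad = out.notna() & (out < col.minimum)
        if bad.any():
            raise ValidationError(
                f"{table}.{col.name}: value below {col.minimum} at rows "
                f"{list(out.index[bad][:5])}")
    return out


def _resolve_schema(schema: str | Schema) -> Schema:
    if isinstance(schema, Schema):
        return schema
    try:
        return SCHEMAS[schema]
    except KeyError:
        raise SchemaError(f"unknown schema {schema!r}; known: "
                          f"{sorted(SCHEMAS)}") from None


def read_table(path, schema: str | Schema) -> pd.DataFrame:
    """Read and validate one published CSV table.

    Every coded field is checked against its published enumeration; empty
    fields become missing values (``pd.NA``/``NaT``), distinct from zero.
    """
    sch = _resolve_schema(schema)
    raw = pd.read_csv(path, dtype=str, keep_default_na=False,
                      skipinitialspace=False)
    if list(raw.columns) != sch.column_names:
        raise SchemaError(
            f"{sch.name}: header mismatch; expected {sch.column_names}, "
            f"found {list(raw.columns)}")
    df = pd.DataFrame(
        {c.name: _parse_column(raw[c.name], c, sch.name) for c in sch.columns})
    _check_table_invariants(df, sch)
    return df


# ---------------------------------------------------------------------------
# per-table invariants (beyond column domains)

def _check_table_invariants(df: pd.DataFrame, sch: Schema) -> None:
    name = sch.name
    if name == "pos":
        dup = df.duplicated(["plot", "tree"])
        if dup.any():
            raise ValidationError(f"pos: duplicate (plot, tree) keys at rows "
                                  f"{list(df.index[dup][:5])}")
        mism = df["removeDate"].notna() != df["removeal"].notna()
        if mism.any():
            raise ValidationError(
                "pos: removeal must be present exactly when removeDate is "
                f"(rows {list(df.index[mism][:5])})")
    elif name == "date":
        dup = df.duplicated(["plot", "year", "obs"])
        if dup.any():
            raise ValidationError("date: duplicate (plot, year, obs) keys")
        for plot, grp in df.groupby("plot"):
            d = grp.sort_values(["year", "obs"])["date"]
            if d.isna().any():
                raise ValidationError(f"date: missing date on plot {plot}")
            if not d.is_monotonic_increasing or d.duplicated().any():
                raise ValidationError(
                    f"date: dates not strictly increasing on plot {plot}")
    elif name == "dbhObs":
        bad = df["dbh2"].notna() & df["dbh"].isna()
        if bad.any():
            raise ValidationError(
                f"dbhObs: dbh2 present without dbh at rows "
                f"{list(df.index[bad][:5])}")
    elif name == "saIr":
        for key, grp in df.groupby(["plot", "tree", "disc", "dir"]):
            years = np.sort(grp["year"].to_numpy(dtype=float))
            if years.size > 1 and not np.all(np.diff(years) == 1):
                raise ValidationError(
                    f"saIr: ring years not consecutive for {key}")
    elif name == "dhcComplSmooth":
        both = df["hCr"].notna() & df["h"].notna()
        bad = both & (df["hCr"] > df["h"])
        if bad.any():
            raise ValidationError(
                f"dhcComplSmooth: hCr > h at rows {list(df.index[bad][:5])}")


# ---------------------------------------------------------------------------
# writing

def _format_value(v, col: Column) -> str:
    if v is None or (isinstance(v, float) and np.isnan(v)) or v is pd.NaT or v is pd.NA:
        return ""
    if col.kind == "int":
        return str(int(v))
    if col.kind == "float":
        f = float(v)
        return str(int(f)) if f.is_integer() else repr(f)
    if col.kind == "bool":
        return "TRUE" if bool(v) else "FALSE"
    if col.kind == "date":
        return pd.Timestamp(v).strftime("%Y-%m-%d")
    return str(v)


def write_table(df: pd.DataFrame, schema: str | Schema, path) -> None:
    """Write a validated table with the published header.

    Absent values become empty fields; formatting is deterministic, so a
    second write of the same records is bit-identical.
    """
    sch = _resolve_schema(schema)
    missing = [c for c in sch.column_names if c not in df.columns]
    if missing:
        raise SchemaError(f"{sch.name}: records lack columns {missing}")
    df = df[sch.column_names]
    for c in sch.columns:
        series = df[c.name]
        if c.domain is not None:
            bad = series.notna() & ~series.isin(list(c.domain))
            if bad.any():
                raise ValidationError(
                    f"{sch.name}.{c.name}: out-of-domain value "
                    f"{series[bad].iloc[0]!r}")
    _check_table_invariants(df, sch)
    lines = [",".join(sch.column_names)]
    cols = [df[c.name].tolist() for c in sch.columns]
    for row in zip(*cols):
        lines.append(",".join(
            _format_value(v, c) for v, c in zip(row, sch.columns)))
    Path(path).write_text("\n".join(lines) + "\n")


def read_dataset(directory) -> dict[str, pd.DataFrame]:
    """Read every published table found in ``directory`` (by file name)."""
    directory = Path(directory)
    out = {}
    for name in SCHEMAS:
        p = directory / f"{name}.csv"
        if p.exists():
            out[name] = read_table(p, name)
    if not out:
        raise FileNotFoundError(f"no known tables in {directory}")
    return out


def write_dataset(tables: dict[str, pd.DataFrame], directory) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for name, df in tables.items():
        write_table(df, name, directory / f"{name}.csv")


# ---------------------------------------------------------------------------
# cross-table validation

@dataclass
class Issue:
    table: str
    kind: str  # referential | temporal | key | domain
    message: str
    rows: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {"table": self.table, "kind": self.kind,
                "message": self.message, "rows": list(self.rows)}


def validate_dataset(tables: dict[str, pd.DataFrame]) -> list[Issue]:
    """Cross-table referential and temporal checks. Reports, never raises."""
    issues: list[Issue] = []
    pos = tables.get("pos")
    dates = tables.get("date")

    def _ref_check(name: str):
        df = tables.get(name)
        if df is None or pos is None or "tree" not in df.columns:
            return
        keys = set(zip(pos["plot"], pos["tree"]))
        bad = [i for i, (p, t) in enumerate(zip(df["plot"], df["tree"]))
               if (p, t) not in keys]
        if bad:
            issues.append(Issue(name, "referential",
                                f"{len(bad)} rows reference trees absent "
                                "from pos", bad[:20]))

    for name in ("dbhObs", "crown", "secDiam", "saTree", "saIr", "saDisc",
                 "dhcComplSmooth"):
        _ref_check(name)

    if dates is not None:
        cal = set(zip(dates["plot"], dates["year"], dates["obs"]))
        for name in ("dbhObs", "crown", "dhcComplSmooth"):
            df = tables.get(name)
            if df is None:
                continue
            bad = [i for i, k in enumerate(zip(df["plot"], df["year"],
                                               df["obs"])) if k not in cal]
            if bad:
                issues.append(Issue(name, "referential",
                                    f"{len(bad)} rows have no matching "
                                    "campaign in date", bad[:20]))

    # observations after the recorded removal date
    obs = tables.get("dbhObs")
    if obs is not None and pos is not None and dates is not None:
        removed = pos[pos["removeDate"].notna()]
        rem = {(p, t): d for p, t, d in zip(removed["plot"], removed["tree"],
                                            removed["removeDate"])}
        cal = {(p, y, o): d for p, y, o, d in zip(dates["plot"], dates["year"],
                                                  dates["obs"], dates["date"])}
        bad = []
        for i, (p, t, y, o) in enumerate(zip(obs["plot"], obs["tree"],
                                             obs["year"], obs["obs"])):
            rd = rem.get((p, t))
            d = cal.get((p, y, o))
            if rd is not None and d is not None and d > rd:
                bad.append(i)
        if bad:
            issues.append(Issue("dbhObs", "temporal",
                                f"{len(bad)} observations dated after the "
                                "tree's removeDate", bad[:20]))

    for name, df in tables.items():
        key_cols = [c for c in ("plot", "tree", "disc", "dir", "year", "obs",
                                "corner") if c in df.columns]
        if name == "saIr":
            key_cols = ["plot", "tree", "disc", "dir", "year"]
        dup = df.duplicated(key_cols)
        if dup.any():
            issues.append(Issue(name, "key",
                                f"duplicate keys on {key_cols}",
                                list(df.index[dup][:20])))
    return issues
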