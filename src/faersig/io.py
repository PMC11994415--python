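"""Reading and writing FAERS quarterly ASCII tables.

The FDA Adverse Event Reporting System (FAERS) distributes each quarter as
seven "$"-delimited ASCII tables — DEMO (demographics), DRUG, REAC
(reactions), OUTC (outcomes), RPSR (report source), THER (therapy dates)
and INDI (indications) — linked by the report identifier PRIMARYID.  This
module reads and writes that dialect losslessly and supplies the low-level
field parsers (partial dates, age units) the rest of the pipeline builds on.

Conventions
-----------
* Files are read as Latin-1 with replacement: legacy FAERS archives contain
  non-UTF-8 bytes and line-level ingestion must never fail on them.
* The delimiter is exactly ``$`` with no quoting dialect.  An embedded
  ``$`` inside free text splits the field; this matches the distributed
  files and is a documented limitation.
* Column names are matched case-insensitively; unknown extra columns are
  carried through untouched.
* All values are kept as verbatim strings.  Typed interpretation (dates,
  ages, integer ids) is performed by the parsers here, on demand, so that
  ``write_archive`` after ``read_archive`` is a byte-level identity.
"""

from __future__ import annotations

import datetime as dt
import re
import zipfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "TABLE_KINDS",
    "REQUIRED_COLUMNS",
    "FaersFormatError",
    "QuarterlyArchive",
    "parse_partial_date",
    "age_to_years",
    "read_table",
    "write_table",
    "read_archive",
    "write_archive",
    "concat_tables",
]

TABLE_KINDS = ("demo", "drug", "reac", "outc", "rpsr", "ther", "indi")

QUARTER_RE = re.compile(r"^(20[0-9]{2})Q([1-4])$")

#: Columns a table must provide (hard error when absent).
REQUIRED_COLUMNS: Mapping[str, tuple[str, ...]] = {
    "demo": ("primaryid", "caseid", "fda_dt"),
    "drug": ("primaryid", "drug_seq", "role_cod", "drugname"),
    "reac": ("primaryid", "pt"),
    "outc": ("primaryid", "outc_cod"),
    "rpsr": ("primaryid",),
    "ther": ("primaryid", "dsg_drug_seq", "start_dt"),
    "indi": ("primaryid", "indi_drug_seq", "indi_pt"),
}

#: Columns filled with "" when a file does not carry them.
OPTIONAL_COLUMNS: Mapping[str, tuple[str, ...]] = {
    "demo": ("event_dt", "age", "age_cod", "sex", "occp_cod", "reporter_country"),
    "drug": ("prod_ai",),
    "reac": (),
    "outc": (),
    "rpsr": ("rpsr_cod",),
    "ther": (),
    "indi": (),
}

ROLE_CODES = ("PS", "SS", "C", "I")
OUTCOME_CODES = ("DE", "LT", "HO", "DS", "CA", "RI", "OT")

#: Multiplicative factors converting an age value to years, by AGE_COD.
AGE_UNIT_TO_YEARS = {
    "DEC": 10.0,
    "YR": 1.0,
    "MON": 1.0 / 12.0,
    "WK": 1.0 / 52.143,
    "DY": 1.0 / 365.25,
    "HR": 1.0 / 8766.0,
}


class FaersFormatError(ValueError):
    """A FAERS table violates the dialect (e.g. a required column is missing)."""


def parse_partial_date(text: str | None) -> tuple[dt.date | None, str | None]:
    """Parse a FAERS date field that may be given to day, month or year precision.

    FAERS date columns hold digit strings of length 8 (YYYYMMDD), 6 (YYYYMM)
    or 4 (YYYY); any of them may be empty.  Returns the earliest calendar
    date consistent with the text together with its precision
    (``"day"``, ``"month"`` or ``"year"``).  Empty or impossible values
    (wrong length, month 13, Feb 30, ...) yield ``(None, None)`` — never an
    exception, because downstream stages treat unusable dates as exclusions.
    """
    if text is None:
        return None, None
    s = str(text).strip()
    if not s:
        return None, None
    if not s.isdigit() or len(s) not in (4, 6, 8):
        return None, None
    year = int(s[:4])
    month = int(s[4:6]) if len(s) >= 6 else 1
    day = int(s[6:8]) if len(s) == 8 else 1
    try:
        date = dt.date(year, month, day)
    except ValueError:
        return None, None
    precision = {4: "year", 6: "month", 8: "day"}[len(s)]
    return date, precision


def age_to_years(value: str | float | None, unit: str | None) -> float | None:
    """Convert a FAERS AGE/AGE_COD pair to years.

    An empty AGE_COD is read as years (the FAERS default).  Values that do
    not parse, use an unknown unit, or normalize outside the plausible
    [0, 150] range return ``None`` (flagged invalid rather than guessed).
    """
    if value is None:
        return None
    s = str(value).strip()
    if not s:
        return None
    try:
        raw = float(s)
    except ValueError:
        return None
    code = (unit or "").strip().upper() or "YR"
    factor = AGE_UNIT_TO_YEARS.get(code)
    if factor is None:
        return None
    years = raw * factor
    if not (0.0 <= years <= 150.0):
        return None
    return years


def _read_lines(path: Path) -> list[str]:
    path = Path(path)
    if zipfile.is_zipfile(path):
        with zipfile.ZipFile(path) as zf:
            names = [n for n in zf.namelist() if not n.endswith("/")]
            if not names:
                raise FaersFormatError(f"{path}: zip archive contains no files")
            # FAERS zips hold a single ASCII member; take the first text-like one.
            member = next((n for n in names if n.lower().endswith(".txt")), names[0])
            data = zf.read(member)
        text = data.decode("latin-1", errors="replace")
    else:
        text = path.read_text(encoding="latin-1", errors="replace")
    lines = text.split("\n")
    if lines and lines[-1] == "":
        lines.pop()
    return [ln.rstrip("\r") for ln in lines]


def read_table(path: str | Path, table_kind: str) -> pd.DataFrame:
    """Read one FAERS ASCII table (plain text or zip-contained) into a DataFrame.

    The returned frame has lower-cased column names, one row per data line
    (line count is preserved; nothing is silently dropped) and all-string
    values.  Missing optional columns are added as empty strings.  Ingestion
    warnings — malformed rows, unparseable identifier or date fields — are
    collected in ``df.attrs["warnings"]``; the raw text is always retained.

    Raises
    ------
    FaersFormatError
        If ``table_kind`` is unknown or a required column is absent.
    """
    kind = table_kind.lower()
    if kind not in TABLE_KINDS:
        raise FaersFormatError(f"unknown table kind {table_kind!r}")
    lines = _read_lines(Path(path))
    warnings: list[str] = []
    if not lines:
        warnings.append(f"{path}: empty file")
        cols = list(REQUIRED_COLUMNS[kind] + OPTIONAL_COLUMNS[kind])
        df = pd.DataFrame(columns=cols, dtype=str)
        df.attrs["warnings"] = warnings
        return df

    header = [h.strip().lower() for h in lines[0].split("$")]
    missing = [c for c in REQUIRED_COLUMNS[kind] if c not in header]
    if missing:
        raise FaersFormatError(
            f"{path}: {kind.upper()} table is missing required column(s) "
            + ", ".join(missing)
        )

    ncol = len(header)
    rows: list[list[str]] = []
    for i, line in enumerate(lines[1:], start=2):
        fields = line.split("$")
        if len(fields) < ncol:
            fields = fields + [""] * (ncol - len(fields))
            warnings.append(f"{path}:{i}: short row padded to {ncol} fields")
        elif len(fields) > ncol:
            warnings.append(f"{path}:{i}: {len(fields)} fields for {ncol} columns; extras dropped")
            fields = fields[:ncol]
        rows.append(fields)

    df = pd.DataFrame(rows, columns=header, dtype=str)
    for col in OPTIONAL_COLUMNS[kind]:
        if col not in df.columns:
            df[col] = ""

    # Soft validation: identifiers must be integers, date fields must parse.
    for col in df.columns:
        if col in ("primaryid", "caseid", "drug_seq", "dsg_drug_seq", "indi_drug_seq"):
            bad = df.index[~df[col].str.strip().str.fullmatch(r"\d*")]
            for idx in bad:
                warnings.append(
                    f"{path}: row {idx + 1}: {col}={df.at[idx, col]!r} is not an integer"
                )
        elif col.endswith("_dt"):
            for idx, value in df[col].items():
                if value.strip() and parse_partial_date(value)[0] is None:
                    warnings.append(f"{path}: row {idx + 1}: {col}={value!r} unparseable")
    df.attrs["warnings"] = warnings
    return df


def write_table(df: pd.DataFrame, path: str | Path, kind: str | None = None) -> Path:
    """Write a table in the FAERS "$"-delimited dialect (Latin-1, one header line)."""
    path = Path(path)
    cols = list(df.columns)
    if kind is not None:
        canonical = [c for c in REQUIRED_COLUMNS[kind] + OPTIONAL_COLUMNS[kind] if c in cols]
        extras = [c for c in cols if c not in canonical]
        cols = canonical + extras
    out = df[cols].fillna("").astype(str)
    lines = ["$".join(cols)]
    lines.extend("$".join(row) for row in out.itertuples(index=False, name=None))
    path.write_text("\n".join(lines) + "\n", encoding="latin-1", errors="replace")
    return path


@dataclass
class QuarterlyArchive:
    """The seven parsed FAERS tables for one quarter, keyed by PRIMARYID.

    ``quarter_label`` follows the distribution naming, e.g. ``"2023Q1"``.
    Tables are all-string DataFrames in the dialect produced by
    :func:`read_table`; cross-table linkage is by ``primaryid`` only.
    """

    quarter_label: str
    tables: dict[str, pd.DataFrame] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not QUARTER_RE.match(self.quarter_label):
            raise ValueError(f"bad quarter label {self.quarter_label!r} (want YYYYQn)")
        for kind in TABLE_KINDS:
            if kind not in self.tables:
                cols = list(REQUIRED_COLUMNS[kind] + OPTIONAL_COLUMNS[kind])
                self.tables[kind] = pd.DataFrame(columns=cols, dtype=str)
        unknown = set(self.tables) - set(TABLE_KINDS)
        if unknown:
            raise ValueError(f"unknown table kinds {sorted(unknown)}")

    def __getattr__(self, name: str) -> pd.DataFrame:
        if name in TABLE_KINDS:
            return self.tables[name]
        raise AttributeError(name)

    @property
    def suffix(self) -> str:
        """File-name suffix used by the quarterly distribution, e.g. ``23Q1``."""
        m = QUARTER_RE.match(self.quarter_label)
        assert m is not None
        return m.group(1)[2:] + "Q" + m.group(2)


def archive_filename(kind: str, quarter_label: str) -> str:
    m = QUARTER_RE.match(quarter_label)
    if not m:
        raise ValueError(f"bad quarter label {quarter_label!r}")
    return f"{kind.upper()}{m.group(1)[2:]}Q{m.group(2)}.txt"


def write_archive(archive: QuarterlyArchive, directory: str | Path) -> dict[str, Path]:
    """Serialize all seven tables of a quarter; returns the paths written.

    ``read_archive`` on the result reproduces the archive field-for-field.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for kind in TABLE_KINDS:
        paths[kind] = write_table(
            archive.tables[kind], directory / archive_filename(kind, archive.quarter_label), kind
        )
    return paths


def read_archive(directory: str | Path, quarter_label: str) -> QuarterlyArchive:
    """Read the seven tables of one quarter from ``directory``."""
    directory = Path(directory)
    tables = {}
    for kind in TABLE_KINDS:
        fname = archive_filename(kind, quarter_label)
        candidates = [directory / fname, directory / (fname[: -len(".txt")] + ".zip")]
        path = next((p for p in candidates if p.exists()), None)
        if path is None:
            raise FileNotFoundError(f"{directory}: no {fname} (or .zip) for {quarter_label}")
        tables[kind] = read_table(path, kind)
    return QuarterlyArchive(quarter_label=quarter_label, tables=tables)


def discover_quarters(directory: str | Path) -> list[str]:
    """Quarter labels present in a directory, inferred from DEMO file names."""
    directory = Path(directory)
    labels = set()
    for p in directory.glob("DEMO*"):
        m = re.match(r"DEMO(\d{2})Q([1-4])\.(txt|zip)$", p.name, flags=re.IGNORECASE)
        if m:
            labels.add(f"20{m.group(1)}Q{m.group(2)}")
    return sorted(labels)


def concat_tables(archives: Iterable[QuarterlyArchive], kind: str) -> pd.DataFrame:
    """Concatenate one table kind across quarters (fresh integer index)."""
    frames = [a.tables[kind] for a in archives]
    if not frames:
        return pd.DataFrame(columns=list(REQUIRED_COLUMNS[kind] + OPTIONAL_COLUMNS[kind]), dtype=str)
    return pd.concat(frames, ignore_index=True).fillna("")
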