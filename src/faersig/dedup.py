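"""FDA-style duplicate-report removal.

FAERS cases accumulate follow-up versions: each revision of a case
(CASEID) arrives as a new report (PRIMARYID) with a later FDA receipt
date (FDA_DT).  The FDA-recommended de-duplication keeps, for every
CASEID, the report with the most recent FDA_DT, breaking exact date ties
by the numerically largest PRIMARYID.  Applied to the concatenation of
all quarters before any drug filtering.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .io import parse_partial_date

__all__ = ["DedupResult", "deduplicate", "write_dedup_audit"]

# Sorts before any real FDA_DT: an undated report never beats a dated revision.
_MISSING_DATE = dt.date.min


@dataclass(frozen=True)
class DedupResult:
    """Partition of the input PRIMARYIDs into kept and dropped reports."""

    kept_primaryids: frozenset[int]
    dropped_primaryids: frozenset[int]
    n_input: int
    n_kept: int

    def __post_init__(self) -> None:
        if self.kept_primaryids & self.dropped_primaryids:
            raise ValueError("kept and dropped sets overlap")


def _fda_date(value: str) -> dt.date:
    date, _ = parse_partial_date(value)
    return date if date is not None else _MISSING_DATE


def deduplicate(demo: pd.DataFrame) -> DedupResult:
    """Keep one report per CASEID: latest FDA_DT, then largest PRIMARYID.

    Deterministic for any input permutation.  A PRIMARYID occurring twice
    violates identifier integrity and raises ``ValueError``.
    """
    if demo.empty:
        return DedupResult(frozenset(), frozenset(), 0, 0)
    pid = pd.to_numeric(demo["primaryid"], errors="raise").astype("int64")
    if pid.duplicated().any():
        dupes = sorted(pid[pid.duplicated()].unique().tolist())
        raise ValueError(f"duplicate primaryid value(s): {dupes[:5]}")
    caseid = pd.to_numeric(demo["caseid"], errors="raise").astype("int64")
    fda = demo["fda_dt"].map(_fda_date)

    order = pd.DataFrame({"caseid": caseid, "fda": fda, "pid": pid})
    order = order.sort_values(["caseid", "fda", "pid"], kind="mergesort")
    kept = order.groupby("caseid", sort=False)["pid"].last()
    kept_set = frozenset(int(p) for p in kept)
    all_set = frozenset(int(p) for p in pid)
    return DedupResult(
        kept_primaryids=kept_set,
        dropped_primaryids=all_set - kept_set,
        n_input=len(pid),
        n_kept=len(kept_set),
    )


def write_dedup_audit(demo: pd.DataFrame, result: DedupResult, path: str | Path) -> Path:
    """Write a per-case audit log: caseid, kept primaryid, dropped primaryids."""
    path = Path(path)
    pid = pd.to_numeric(demo["primaryid"]).astype("int64")
    caseid = pd.to_numeric(demo["caseid"]).astype("int64")
    frame = pd.DataFrame({"caseid": caseid, "primaryid": pid})
    lines = ["caseid\tkept_primaryid\tdropped_primaryids"]
    for cid, grp in frame.groupby("caseid", sort=True):
        kept = [p for p in grp["primaryid"] if p in result.kept_primaryids]
        dropped = sorted(p for p in grp["primaryid"] if p in result.dropped_primaryids)
        lines.append(f"{cid}\t{kept[0]}\t{';'.join(str(p) for p in dropped)}")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path
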