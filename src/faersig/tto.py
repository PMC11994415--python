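"""Time-to-onset analysis.

Onset is the whole-day difference between the adverse-event date
(EVENT_DT) and the earliest day-precision therapy start (START_DT) of the
target drug.  Reports with a missing or partial date on either side, or a
negative difference, are excluded with a recorded reason — they are data
exclusions, not errors.  The summary reports the median and interquartile
range (linear-interpolation quantiles) plus a binned onset distribution.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .cohort import CaseRecord, percentage

__all__ = ["OnsetRecord", "OnsetSummary", "DEFAULT_BINS", "compute_onsets", "summarize_onsets", "write_onset_summary"]

#: (lo, hi) day intervals, inclusive on both ends; hi=None means open-ended.
DEFAULT_BINS: tuple[tuple[int, int | None], ...] = (
    (0, 30), (31, 60), (61, 90), (91, 180), (181, 360), (361, None),
)


@dataclass(frozen=True)
class OnsetRecord:
    """One report's onset attempt: the day count or an exclusion reason."""

    primaryid: int
    onset_days: int | None
    included: bool
    exclusion_reason: str | None  # missing_start | missing_event | partial_date | negative

    def __post_init__(self) -> None:
        if self.included and (self.onset_days is None or self.onset_days < 0):
            raise ValueError("included onset must be a non-negative day count")


@dataclass(frozen=True)
class OnsetSummary:
    n_included: int
    median_days: float
    iqr_lo: float
    iqr_hi: float
    bins: tuple[tuple[int, int | None], ...]
    bin_counts: tuple[int, ...]
    bin_proportions: tuple[float, ...]  # percent, two decimals


def compute_onsets(cases: Sequence[CaseRecord]) -> list[OnsetRecord]:
    """One onset per report: event date minus earliest day-precision therapy start.

    Exclusion reasons, in precedence order: ``missing_start`` (no therapy
    start at all), ``missing_event``, ``partial_date`` (either date present
    but not day-precise), ``negative`` (event before start).
    """
    out: list[OnsetRecord] = []
    for case in cases:
        reason: str | None = None
        if case.therapy_start is None:
            reason = "missing_start"
        elif case.event_date is None:
            reason = "missing_event"
        elif case.therapy_start_precision != "day" or case.event_precision != "day":
            reason = "partial_date"
        if reason is not None:
            out.append(OnsetRecord(case.primaryid, None, False, reason))
            continue
        days = (case.event_date - case.therapy_start).days
        if days < 0:
            out.append(OnsetRecord(case.primaryid, None, False, "negative"))
        else:
            out.append(OnsetRecord(case.primaryid, days, True, None))
    return out


def summarize_onsets(
    records: Sequence[OnsetRecord],
    bins: Sequence[tuple[int, int | None]] = DEFAULT_BINS,
) -> OnsetSummary:
    """Median/IQR and binned distribution of the included onsets.

    Quantiles use linear interpolation; day-0 onsets are valid and fall in
    the first bin.  Bin proportions are percentages of ``n_included``
    rounded half-up to two decimals.
    """
    days = np.array([r.onset_days for r in records if r.included], dtype=float)
    n = days.size
    if n == 0:
        return OnsetSummary(0, float("nan"), float("nan"), float("nan"),
                            tuple(bins), tuple(0 for _ in bins), tuple(0.0 for _ in bins))
    lo, med, hi = np.percentile(days, [25, 50, 75], method="linear")
    counts = []
    for b_lo, b_hi in bins:
        m = days >= b_lo if b_hi is None else (days >= b_lo) & (days <= b_hi)
        counts.append(int(m.sum()))
    props = tuple(percentage(c, n) for c in counts)
    return OnsetSummary(int(n), float(med), float(lo), float(hi),
                        tuple(bins), tuple(counts), props)


def exclusion_counts(records: Sequence[OnsetRecord]) -> dict[str, int]:
    out: dict[str, int] = {}
    for r in records:
        if not r.included:
            out[r.exclusion_reason] = out.get(r.exclusion_reason, 0) + 1
    return out


def write_onset_summary(summary: OnsetSummary, path: str | Path) -> Path:
    """TSV: one median/IQR line then (bin, count, proportion) rows."""
    path = Path(path)
    lines = ["metric\tvalue",
             f"n_included\t{summary.n_included}",
             f"median_days\t{summary.median_days:g}",
             f"iqr_lo\t{summary.iqr_lo:g}",
             f"iqr_hi\t{summary.iqr_hi:g}",
             "",
             "bin\tcount\tproportion_pct"]
    for (b_lo, b_hi), cnt, prop in zip(summary.bins, summary.bin_counts, summary.bin_proportions):
        label = f"{b_lo}-{b_hi}" if b_hi is not None else f">{b_lo - 1}"
        lines.append(f"{label}\t{cnt}\t{prop:.2f}")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path
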