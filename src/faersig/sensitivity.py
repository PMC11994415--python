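"""Healthcare-professional sensitivity analysis.

Spontaneous reports are mostly consumer-submitted; restricting the run to
reports filed by healthcare professionals (occupation codes MD and PH by
default) checks whether the positive signals survive in the better-
documented subset.  By default the 2x2 background is recomputed from the
subset universe — both target and comparator events come from
professional-reported cases — which keeps the marginals internally
consistent; pass the full-universe pairs instead to compare against the
whole database.
"""

from __future__ import annotations

import warnings as _warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .cohort import CaseRecord

__all__ = [
    "DEFAULT_PROFESSIONAL_CODES",
    "SensitivityComparison",
    "filter_professional",
    "professional_ids",
    "compare_runs",
    "write_comparison",
]

#: Physicians and pharmacists; HP/OT can be added via configuration.
DEFAULT_PROFESSIONAL_CODES = frozenset({"MD", "PH"})


def filter_professional(
    cases: Sequence[CaseRecord],
    codes: frozenset[str] = DEFAULT_PROFESSIONAL_CODES,
) -> list[CaseRecord]:
    """Cases whose reporter occupation code is in ``codes``.  Idempotent."""
    if not codes:
        _warnings.warn("empty occupation-code set: sensitivity subset is empty")
        return []
    return [c for c in cases if c.occp_cod in codes]


def professional_ids(
    demo: pd.DataFrame, codes: frozenset[str] = DEFAULT_PROFESSIONAL_CODES
) -> set[int]:
    """primaryids of all reports (any drug) filed by the given occupations.

    Used to restrict the comparator universe when the sensitivity run
    recomputes b, c, d from professional-reported cases only.
    """
    occp = demo["occp_cod"].fillna("").str.strip().str.upper()
    pid = pd.to_numeric(demo["primaryid"], errors="coerce")
    keep = occp.isin(codes) & pid.notna()
    return {int(p) for p in pid[keep]}


@dataclass(frozen=True)
class SensitivityComparison:
    """Set algebra over the positive PTs of the full and subset runs."""

    n_reports_subset: int
    n_events_subset: int
    overlap: frozenset[str]
    full_only: frozenset[str]
    subset_only: frozenset[str]

    def __post_init__(self) -> None:
        if self.overlap & self.full_only or self.overlap & self.subset_only:
            raise ValueError("overlap must be disjoint from the *_only sets")


def _positive_terms(table: pd.DataFrame) -> set[str]:
    if table.empty:
        return set()
    mask = table["positive"]
    if "excluded_reason" in table.columns:
        mask = mask & (table["excluded_reason"] == "")
    return set(table.loc[mask, "term"])


def compare_runs(
    full: pd.DataFrame,
    subset: pd.DataFrame,
    n_reports_subset: int = 0,
    n_events_subset: int = 0,
) -> SensitivityComparison:
    """PT-keyed overlap of positive signals between the full and subset runs."""
    f, s = _positive_terms(full), _positive_terms(subset)
    return SensitivityComparison(
        n_reports_subset=n_reports_subset,
        n_events_subset=n_events_subset,
        overlap=frozenset(f & s),
        full_only=frozenset(f - s),
        subset_only=frozenset(s - f),
    )


def write_comparison(
    comparison: SensitivityComparison,
    full: pd.DataFrame,
    path: str | Path,
    display: Mapping[str, str] | None = None,
) -> Path:
    """TSV of the full run's positives with an asterisk column marking the
    PTs that stayed positive in the professional-only subset, plus any
    subset-only PTs appended."""
    path = Path(path)
    display = display or {}
    lines = ["term\tin_subset\tstatus"]
    for term in sorted(comparison.overlap | comparison.full_only):
        star = "*" if term in comparison.overlap else ""
        lines.append(f"{display.get(term, term)}\t{star}\tfull")
    for term in sorted(comparison.subset_only):
        lines.append(f"{display.get(term, term)}\t*\tsubset_only")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path
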