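"""Target-drug cohort construction and clinical-characteristics summary.

A cohort member is a de-duplicated report in which the target drug appears
with the primary-suspect (PS) role, matched case-insensitively against
both DRUGNAME and the active-ingredient column PROD_AI via a synonym list
(generic + brand names).  Each member is condensed into a
:class:`CaseRecord`; :func:`summarize_cohort` then reproduces the standard
clinical-characteristics table (gender, age bands, reporter occupation,
country, report year, outcomes, indications) with half-up two-decimal
percentages.
"""

from __future__ import annotations

import re
import warnings as _warnings
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .dedup import DedupResult
from .io import age_to_years, parse_partial_date

__all__ = [
    "CaseRecord",
    "CohortSummary",
    "SERIOUS_OUTCOME_CODES",
    "match_target_drug",
    "build_cohort",
    "classify_seriousness",
    "summarize_cohort",
    "percentage",
    "write_summary",
]

#: Outcome codes that mark a report serious.  DE death, LT life-threatening,
#: HO hospitalization, DS disability, CA congenital anomaly, RI required
#: intervention, OT other serious.
SERIOUS_OUTCOME_CODES = frozenset({"DE", "LT", "HO", "DS", "CA", "RI", "OT"})

#: Display labels for the outcome block; CA/RI fold into "Other serious".
OUTCOME_LABELS = {
    "HO": "Hospitalization",
    "OT": "Other serious",
    "CA": "Other serious",
    "RI": "Other serious",
    "DE": "Death",
    "LT": "Life threatening",
    "DS": "Disability",
}

#: OCCP_COD -> reporter category.  HP (generic health professional) is kept
#: as its own bucket rather than folded into Physician, so the mapping
#: ambiguity stays visible in output.
REPORTER_MAP = {
    "CN": "Consumer",
    "PH": "Pharmacist",
    "MD": "Physician",
    "HP": "Health professional",
    "OT": "Other",
    "LW": "Lawyer",
    "": "Unknown",
}

AGE_BANDS = ("<18", "18-65", ">=65", "Unknown")


def percentage(count: int, denominator: int) -> float:
    """``100 * count / denominator`` rounded half-up to two decimals."""
    if denominator <= 0:
        return 0.0
    frac = Decimal(count) * 100 / Decimal(denominator)
    return float(frac.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class CaseRecord:
    """One de-duplicated report in the target-drug cohort."""

    primaryid: int
    caseid: int
    sex: str
    age_years: float | None
    occp_cod: str
    reporter_country: str
    report_year: int | None
    event_date: object  # datetime.date | None
    event_precision: str | None
    outcomes: frozenset[str]
    target_drug_seqs: frozenset[int]
    pts: tuple[str, ...]
    indications: tuple[str, ...]
    therapy_start: object  # datetime.date | None
    therapy_start_precision: str | None

    @property
    def serious(self) -> bool:
        return classify_seriousness(self)


def classify_seriousness(case: CaseRecord) -> bool:
    """Serious iff at least one serious outcome code was reported.

    Monotone: adding an outcome code can never flip serious to non-serious.
    """
    return bool(case.outcomes & SERIOUS_OUTCOME_CODES)


def match_target_drug(
    drug: pd.DataFrame, synonyms: Iterable[str]
) -> set[tuple[int, int]]:
    """(primaryid, drug_seq) pairs whose DRUGNAME or PROD_AI contains a synonym.

    Matching is case-insensitive substring, so trailing punctuation or salt
    suffixes in free-text drug names still match.  Role filtering is applied
    separately by :func:`build_cohort`.
    """
    syns = [s.strip().lower() for s in synonyms if s and s.strip()]
    if not syns:
        raise ValueError("synonym set must be non-empty")
    name = drug["drugname"].fillna("").str.lower()
    ai = drug["prod_ai"].fillna("").str.lower()
    mask = pd.Series(False, index=drug.index)
    for s in syns:
        pat = re.escape(s)
        mask |= name.str.contains(pat, regex=True) | ai.str.contains(pat, regex=True)
    matched = drug.loc[mask, ["primaryid", "drug_seq"]]
    out: set[tuple[int, int]] = set()
    for pid, seq in matched.itertuples(index=False, name=None):
        try:
            out.add((int(pid), int(seq)))
        except (TypeError, ValueError):
            continue  # malformed identifier rows were already warned at ingest
    return out


def _unique_preserving(values: Iterable[str]) -> tuple[str, ...]:
    """Unique values by case-insensitive key, first-seen spelling kept."""
    seen: dict[str, str] = {}
    for v in values:
        v = str(v).strip()
        if not v:
            continue
        key = v.lower()
        if key not in seen:
            seen[key] = v
    return tuple(seen.values())


def _int_series(s: pd.Series) -> pd.Series:
    return pd.to_numeric(s, errors="coerce").astype("Int64")


def build_cohort(
    tables: Mapping[str, pd.DataFrame],
    dedup: DedupResult,
    matched: set[tuple[int, int]],
    role_filter: frozenset[str] = frozenset({"PS"}),
) -> list[CaseRecord]:
    """Assemble one :class:`CaseRecord` per kept report with a matching PS drug row.

    ``tables`` holds the concatenated multi-quarter tables (see
    :func:`faersig.io.concat_tables`).  A report enters the cohort when at
    least one of its drug rows (i) matched the target-drug synonyms and
    (ii) carries a role in ``role_filter`` (default: primary suspect only).
    """
    drug = tables["drug"]
    pid = _int_series(drug["primaryid"])
    seq = _int_series(drug["drug_seq"])
    role = drug["role_cod"].fillna("").str.strip().str.upper()

    kept = dedup.kept_primaryids
    target_seqs: dict[int, set[int]] = defaultdict(set)
    for p, s, r in zip(pid, seq, role):
        if pd.isna(p) or pd.isna(s):
            continue
        p, s = int(p), int(s)
        if r in role_filter and (p, s) in matched and p in kept:
            target_seqs[p].add(s)
    cohort_pids = sorted(target_seqs)
    if not cohort_pids:
        _warnings.warn("empty cohort: no kept report matches the target drug as PS")
        return []

    cohort_set = set(cohort_pids)

    def by_pid(df: pd.DataFrame) -> dict[int, pd.DataFrame]:
        p = _int_series(df["primaryid"])
        sub = df[p.isin(cohort_set).fillna(False)]
        return {int(k): g for k, g in sub.groupby(_int_series(sub["primaryid"]))}

    demo = tables["demo"]
    demo_pid = _int_series(demo["primaryid"])
    demo_sub = demo[demo_pid.isin(cohort_set).fillna(False)]
    demo_rows = {int(row["primaryid"]): row for _, row in demo_sub.iterrows()}
    reac_g = by_pid(tables["reac"])
    outc_g = by_pid(tables["outc"])
    ther_g = by_pid(tables["ther"])
    indi_g = by_pid(tables["indi"])

    cases: list[CaseRecord] = []
    for p in cohort_pids:
        row = demo_rows.get(p)
        if row is None:
            continue  # a drug row without a DEMO parent cannot be a case
        seqs = frozenset(target_seqs[p])

        pts = _unique_preserving(reac_g[p]["pt"]) if p in reac_g else ()
        outcomes = (
            frozenset(outc_g[p]["outc_cod"].str.strip().str.upper()) - {""}
            if p in outc_g
            else frozenset()
        )

        therapy_start, start_prec = None, None
        if p in ther_g:
            g = ther_g[p]
            dseq = _int_series(g["dsg_drug_seq"])
            parsed = [
                parse_partial_date(v)
                for v, s in zip(g["start_dt"], dseq)
                if not pd.isna(s) and int(s) in seqs
            ]
            day_dates = [d for d, prec in parsed if d is not None and prec == "day"]
            any_dates = [(d, prec) for d, prec in parsed if d is not None]
            if day_dates:
                therapy_start, start_prec = min(day_dates), "day"
            elif any_dates:
                therapy_start, start_prec = min(any_dates)

        indications: tuple[str, ...] = ()
        if p in indi_g:
            g = indi_g[p]
            iseq = _int_series(g["indi_drug_seq"])
            indications = _unique_preserving(
                v for v, s in zip(g["indi_pt"], iseq) if not pd.isna(s) and int(s) in seqs
            )

        event_date, event_prec = parse_partial_date(row.get("event_dt", ""))
        fda_date, _ = parse_partial_date(row.get("fda_dt", ""))
        cases.append(
            CaseRecord(
                primaryid=p,
                caseid=int(row["caseid"]),
                sex=str(row.get("sex", "")).strip().upper(),
                age_years=age_to_years(row.get("age", ""), row.get("age_cod", "")),
                occp_cod=str(row.get("occp_cod", "")).strip().upper(),
                reporter_country=str(row.get("reporter_country", "")).strip(),
                report_year=fda_date.year if fda_date else None,
                event_date=event_date,
                event_precision=event_prec,
                outcomes=outcomes,
                target_drug_seqs=seqs,
                pts=pts,
                indications=indications,
                therapy_start=therapy_start,
                therapy_start_precision=start_prec,
            )
        )
    return cases


@dataclass
class CohortSummary:
    """Counts and half-up percentages for the clinical-characteristics table.

    ``blocks`` maps a block name (gender/age/reporter/country/year/outcomes/
    indications) to ordered ``(category, count, pct)`` triples.  The
    gender, age, reporter, country and year blocks use ``n_cases`` as
    percentage denominator and their counts sum to ``n_cases``; the outcome
    block uses the total number of reported outcome counts (a case
    contributes one count per distinct code) and the indication block uses
    ``n_cases`` although one case may carry several or no indications.
    """

    n_cases: int
    n_events: int
    n_serious: int
    blocks: dict[str, tuple[tuple[str, int, float], ...]] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (block, cat, count, pct)
            for block, items in self.blocks.items()
            for cat, count, pct in items
        ]
        return pd.DataFrame(rows, columns=["block", "category", "count", "pct"])


def _age_band(age: float | None) -> str:
    if age is None:
        return "Unknown"
    if age < 18:
        return "<18"
    if age < 65:
        return "18-65"
    return ">=65"


def _block(counter: Counter, order: Sequence[str], denom: int) -> tuple[tuple[str, int, float], ...]:
    return tuple((cat, counter.get(cat, 0), percentage(counter.get(cat, 0), denom)) for cat in order)


def summarize_cohort(
    cases: Sequence[CaseRecord],
    *,
    countries: Sequence[str] | None = None,
    n_countries: int = 4,
    n_indications: int = 4,
    reporter_map: Mapping[str, str] = REPORTER_MAP,
) -> CohortSummary:
    """Tabulate gender, age bands, reporter, country, year, outcomes, indications.

    ``countries`` pins the individually-listed countries (remainder →
    "Others"); by default the ``n_countries`` most frequent are listed.
    Indications behave the same with ``n_indications``.
    """
    n = len(cases)
    n_events = sum(len(c.pts) for c in cases)
    n_serious = sum(1 for c in cases if classify_seriousness(c))

    sex = Counter({"Male": 0, "Female": 0, "Unknown": 0})
    for c in cases:
        sex[{"M": "Male", "F": "Female"}.get(c.sex, "Unknown")] += 1
    age = Counter(_age_band(c.age_years) for c in cases)
    reporter = Counter(reporter_map.get(c.occp_cod, "Other") for c in cases)
    year = Counter(str(c.report_year) if c.report_year else "Unknown" for c in cases)

    country_counts = Counter(c.reporter_country or "Others" for c in cases)
    if countries is None:
        listed = [
            cat
            for cat, _ in sorted(country_counts.items(), key=lambda kv: (-kv[1], kv[0]))
            if cat != "Others"
        ][:n_countries]
    else:
        listed = list(countries)
    country = Counter({k: 0 for k in listed})
    for cat, cnt in country_counts.items():
        country[cat if cat in listed else "Others"] += cnt

    outcome = Counter()
    for c in cases:
        for code in c.outcomes:
            label = OUTCOME_LABELS.get(code)
            if label:
                outcome[label] += 1
    n_outcomes = sum(outcome.values())

    indi_counts: Counter = Counter()
    display: dict[str, str] = {}
    for c in cases:
        for ind in c.indications:
            key = ind.lower()
            display.setdefault(key, ind)
            indi_counts[key] += 1
    listed_ind = [
        k for k, _ in sorted(indi_counts.items(), key=lambda kv: (-kv[1], kv[0]))
    ][:n_indications]
    indication = Counter({display[k]: indi_counts[k] for k in listed_ind})
    indication["Others"] = sum(v for k, v in indi_counts.items() if k not in listed_ind)

    reporter_order = [
        cat for cat in dict.fromkeys(list(reporter_map.values()) + ["Other"]) if reporter[cat] > 0 or cat == "Unknown"
    ]
    outcome_order = [
        lab for lab in ("Hospitalization", "Other serious", "Death", "Life threatening", "Disability")
        if outcome[lab] > 0
    ]
    blocks = {
        "gender": _block(sex, ["Male", "Female", "Unknown"], n),
        "age": _block(age, list(AGE_BANDS), n),
        "reporter": _block(reporter, reporter_order, n),
        "country": _block(country, listed + ["Others"], n),
        "report_year": _block(year, sorted(year), n),
        "outcomes": _block(outcome, outcome_order, n_outcomes),
        "indications": _block(
            indication, [display[k] for k in listed_ind] + ["Others"], n
        ),
    }
    return CohortSummary(n_cases=n, n_events=n_events, n_serious=n_serious, blocks=blocks)


def write_summary(summary: CohortSummary, path: str | Path) -> Path:
    path = Path(path)
    frame = summary.to_frame()
    frame["pct"] = frame["pct"].map(lambda v: f"{v:.2f}")
    frame.to_csv(path, sep="\t", index=False)
    return path
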