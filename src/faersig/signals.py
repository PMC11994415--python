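"""Disproportionality statistics over 2x2 spontaneous-reporting tables.

For a target drug and an adverse-event term (a MedDRA Preferred Term or a
System Organ Class) the reporting universe of unique (report, term) pairs
is split into the classic 2x2 contingency table

    a  target-drug reports mentioning the term
    b  target-drug reports' other events (a + b = total target events)
    c  all-other-drug reports mentioning the term
    d  all-other-drug reports' other events,      N = a + b + c + d

on which four screening statistics are computed:

* ROR  — reporting odds ratio ``ad/bc`` with a Wald 95% CI on the log
  scale; flagged when ``a >= 3`` and the lower bound exceeds 1.
* PRR  — proportional reporting ratio ``[a/(a+b)] / [c/(c+d)]`` with the
  uncorrected Pearson chi-square companion; flagged when ``a >= 3``,
  ``PRR >= 2`` and ``chi2 >= 4``.
* BCPNN IC — information component ``log2(aN / ((a+b)(a+c)))`` with the
  closed-form posterior variance (unit hyperparameters) and lower
  credibility bound ``IC025 = IC - 2*sqrt(V)``; flagged when IC025 > 0.
* EBGM — the relative reporting ratio ``aN / ((a+b)(a+c))`` (the
  shrinkage-free empirical-Bayes geometric mean; the identity
  ``IC = log2(EBGM)`` holds exactly) with log-normal 90% lower bound
  ``EBGM05 = exp(ln EBGM - 1.645*SE)``; flagged when EBGM05 > 2.

A term is a *positive signal* when all four flags hold simultaneously.
Zero cells are handled by the Haldane–Anscombe correction (add 0.5 to
every cell) applied only when ``a*d == 0`` or ``b*c == 0``, and such rows
are marked ``corrected``.
"""

from __future__ import annotations

import math
import warnings as _warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

import pandas as pd

__all__ = [
    "ContingencyTable",
    "Thresholds",
    "SignalStats",
    "wald_log_se",
    "lognormal_lower",
    "ic_variance",
    "ic_variance_dominant",
    "ic_lower",
    "ror_stats",
    "prr_stats",
    "bcpnn_stats",
    "ebgm_stats",
    "signal_stats",
    "event_pairs",
    "build_contingency",
    "signal_table",
    "screen_signals",
    "positive_signals",
    "rank_by_ebgm",
    "write_signal_table",
]

Z_95_TWO_SIDED = 1.96
Z_90_ONE_SIDED = 1.645
_INV_LN2_SQ = 1.0 / math.log(2.0) ** 2


@dataclass(frozen=True)
class ContingencyTable:
    """The a/b/c/d counts for one (drug, term) pair."""

    a: float
    b: float
    c: float
    d: float

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency cells must be non-negative")
        if self.n <= 0:
            raise ValueError("contingency table is empty")

    @property
    def n(self) -> float:
        return self.a + self.b + self.c + self.d

    def corrected(self) -> "ContingencyTable":
        """Haldane–Anscombe corrected copy (+0.5 everywhere)."""
        return ContingencyTable(self.a + 0.5, self.b + 0.5, self.c + 0.5, self.d + 0.5)

    @property
    def needs_correction(self) -> bool:
        return self.a * self.d == 0 or self.b * self.c == 0


@dataclass(frozen=True)
class Thresholds:
    """Screening thresholds; defaults follow the conventional reading
    (PRR boundaries inclusive, lower-bound comparisons strict)."""

    min_count: int = 3
    ror_lower: float = 1.0
    prr: float = 2.0
    chi2: float = 4.0
    ic025: float = 0.0
    ebgm05: float = 2.0


DEFAULT_THRESHOLDS = Thresholds()


class RorResult(NamedTuple):
    ror: float
    lo: float
    hi: float
    flag: bool
    corrected: bool


class PrrResult(NamedTuple):
    prr: float
    chi2: float
    flag: bool


class BcpnnResult(NamedTuple):
    ic: float
    ic025: float
    flag: bool


class EbgmResult(NamedTuple):
    ebgm: float
    ebgm05: float
    flag: bool


# ---------------------------------------------------------------------------
# closed-form building blocks (also used stand-alone to recompute interval
# bounds from published point estimates)

def wald_log_se(a: float, b: float, c: float, d: float) -> float:
    """Standard error of ln(odds ratio): sqrt(1/a + 1/b + 1/c + 1/d)."""
    return math.sqrt(1.0 / a + 1.0 / b + 1.0 / c + 1.0 / d)


def lognormal_lower(point: float, se: float, z: float = Z_90_ONE_SIDED) -> float:
    """Lower bound ``exp(ln point - z*se)`` of a log-normally distributed estimate."""
    return math.exp(math.log(point) - z * se)


def ic_variance(a: float, row: float, col: float, n: float) -> float:
    """Posterior variance of the information component (unit hyperparameters).

    ``row = a + b`` (target margin), ``col = a + c`` (term margin).
    """
    return _INV_LN2_SQ * (
        (n - a + 1.0) / ((a + 1.0) * (n + 2.0))
        + (n - row + 1.0) / ((row + 1.0) * (n + 2.0))
        + (n - col + 1.0) / ((col + 1.0) * (n + 2.0))
    )


def ic_variance_dominant(a: float) -> float:
    """Large-N, small-margin limit of :func:`ic_variance`: ``(1/ln^2 2)/(a+1)``.

    Valid when N is huge and both margins dwarf ``a``, so the first term
    dominates; used to recompute credibility bounds from a published IC
    point estimate and case count alone.
    """
    return _INV_LN2_SQ / (a + 1.0)


def ic_lower(ic: float, variance: float, z: float = 2.0) -> float:
    """IC lower credibility bound ``ic - z*sqrt(variance)``."""
    return ic - z * math.sqrt(variance)


# ---------------------------------------------------------------------------
# the four algorithms

def ror_stats(t: ContingencyTable, thresholds: Thresholds = DEFAULT_THRESHOLDS) -> RorResult:
    """Reporting odds ratio with Wald 95% CI; flag = (a >= 3 and lower bound > 1)."""
    corrected = t.needs_correction
    u = t.corrected() if corrected else t
    ror = (u.a * u.d) / (u.b * u.c)
    se = wald_log_se(u.a, u.b, u.c, u.d)
    lo = math.exp(math.log(ror) - Z_95_TWO_SIDED * se)
    hi = math.exp(math.log(ror) + Z_95_TWO_SIDED * se)
    flag = t.a >= thresholds.min_count and lo > thresholds.ror_lower
    return RorResult(ror, lo, hi, bool(flag), corrected)


def _chi2(t: ContingencyTable, yates: bool) -> float:
    row1, row2 = t.a + t.b, t.c + t.d
    col1, col2 = t.a + t.c, t.b + t.d
    denom = row1 * row2 * col1 * col2
    if denom == 0:
        return float("nan")
    diff = abs(t.a * t.d - t.b * t.c)
    if yates:
        diff = max(diff - t.n / 2.0, 0.0)
    return t.n * diff * diff / denom


def prr_stats(
    t: ContingencyTable, thresholds: Thresholds = DEFAULT_THRESHOLDS, yates: bool = False
) -> PrrResult:
    """Proportional reporting ratio and Pearson chi-square (no continuity
    correction by default); flag = (a >= 3 and PRR >= 2 and chi2 >= 4)."""
    u = t.corrected() if t.needs_correction else t
    if u.a + u.b == 0 or u.c + u.d == 0 or u.c == 0:
        prr = float("nan")
    else:
        prr = (u.a / (u.a + u.b)) / (u.c / (u.c + u.d))
    chi2 = _chi2(t, yates)
    flag = (
        t.a >= thresholds.min_count
        and not math.isnan(prr)
        and prr >= thresholds.prr
        and not math.isnan(chi2)
        and chi2 >= thresholds.chi2
    )
    return PrrResult(prr, chi2, bool(flag))


def bcpnn_stats(t: ContingencyTable, thresholds: Thresholds = DEFAULT_THRESHOLDS) -> BcpnnResult:
    """Information component with IC025 = IC - 2*sqrt(V); flag = IC025 > 0.

    Undefined when ``a == 0`` (flag false, NaN estimates).
    """
    if t.a == 0:
        return BcpnnResult(float("nan"), float("nan"), False)
    ic = math.log2(t.a * t.n / ((t.a + t.b) * (t.a + t.c)))
    ic025 = ic_lower(ic, ic_variance(t.a, t.a + t.b, t.a + t.c, t.n))
    return BcpnnResult(ic, ic025, bool(ic025 > thresholds.ic025))


def ebgm_stats(t: ContingencyTable, thresholds: Thresholds = DEFAULT_THRESHOLDS) -> EbgmResult:
    """Relative-reporting EBGM with log-normal 90% lower bound; flag = EBGM05 > 2."""
    if t.a == 0:
        return EbgmResult(float("nan"), float("nan"), False)
    ebgm = t.a * t.n / ((t.a + t.b) * (t.a + t.c))
    u = t.corrected() if t.needs_correction else t
    ebgm05 = lognormal_lower(ebgm, wald_log_se(u.a, u.b, u.c, u.d))
    return EbgmResult(ebgm, ebgm05, bool(ebgm05 > thresholds.ebgm05))


@dataclass(frozen=True)
class SignalStats:
    """All four algorithms' estimates, bounds and flags for one table."""

    a: float
    ror: float
    ror_lo: float
    ror_hi: float
    prr: float
    chi2: float
    ic: float
    ic025: float
    ebgm: float
    ebgm05: float
    ror_flag: bool
    prr_flag: bool
    bcpnn_flag: bool
    ebgm_flag: bool
    corrected: bool

    @property
    def positive(self) -> bool:
        """The all-four screening conjunction."""
        return self.ror_flag and self.prr_flag and self.bcpnn_flag and self.ebgm_flag


def signal_stats(
    t: ContingencyTable, thresholds: Thresholds = DEFAULT_THRESHOLDS, yates: bool = False
) -> SignalStats:
    r = ror_stats(t, thresholds)
    p = prr_stats(t, thresholds, yates)
    b = bcpnn_stats(t, thresholds)
    e = ebgm_stats(t, thresholds)
    return SignalStats(
        a=t.a,
        ror=r.ror, ror_lo=r.lo, ror_hi=r.hi,
        prr=p.prr, chi2=p.chi2,
        ic=b.ic, ic025=b.ic025,
        ebgm=e.ebgm, ebgm05=e.ebgm05,
        ror_flag=r.flag, prr_flag=p.flag, bcpnn_flag=b.flag, ebgm_flag=e.flag,
        corrected=r.corrected,
    )


# ---------------------------------------------------------------------------
# event universes and tables over them

def event_pairs(
    reac: pd.DataFrame,
    keep_ids: set[int] | None = None,
    level: str = "pt",
    pt_soc: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Unique (primaryid, term) pairs from a REAC table.

    ``level="pt"`` canonicalizes the verbatim PT (lower-cased key, first-seen
    spelling kept in the ``display`` column).  ``level="soc"`` maps each PT
    through ``pt_soc`` (case-insensitive on PT) and merges a report's PTs of
    one SOC into a single pair; PTs absent from the map go to
    ``"unclassified"`` with a warning.
    """
    pid = pd.to_numeric(reac["primaryid"], errors="coerce")
    pt = reac["pt"].fillna("").astype(str).str.strip()
    frame = pd.DataFrame({"primaryid": pid, "pt": pt})
    frame = frame[frame["primaryid"].notna() & (frame["pt"] != "")]
    frame["primaryid"] = frame["primaryid"].astype("int64")
    if keep_ids is not None:
        frame = frame[frame["primaryid"].isin(keep_ids)]
    frame["term"] = frame["pt"].str.lower()
    frame["display"] = frame["pt"]
    if level == "soc":
        if pt_soc is None:
            raise ValueError("SOC-level pairs require a PT->SOC map")
        soc_map = {k.strip().lower(): v for k, v in pt_soc.items()}
        mapped = frame["term"].map(soc_map)
        n_miss = int(mapped.isna().sum())
        if n_miss:
            _warnings.warn(f"{n_miss} reaction rows with PTs absent from the PT->SOC map")
        frame["term"] = mapped.fillna("unclassified").astype(str).str.lower()
        frame["display"] = mapped.fillna("unclassified")
    elif level != "pt":
        raise ValueError(f"unknown level {level!r}")
    frame = frame.drop_duplicates(subset=["primaryid", "term"])
    return frame[["primaryid", "term", "display"]].reset_index(drop=True)


def build_contingency(
    pairs: pd.DataFrame, target_ids: set[int], term: str
) -> ContingencyTable:
    """2x2 table for one term from an event-pair universe.

    A term absent from the universe yields ``a = c = 0`` (warned); the four
    cells always sum to the number of unique pairs.
    """
    is_target = pairs["primaryid"].isin(target_ids)
    has_term = pairs["term"] == term.strip().lower()
    a = int((is_target & has_term).sum())
    b = int((is_target & ~has_term).sum())
    c = int((~is_target & has_term).sum())
    d = int((~is_target & ~has_term).sum())
    if a + c == 0:
        _warnings.warn(f"term {term!r} absent from the event universe")
    return ContingencyTable(a, b, c, d)


def signal_table(
    pairs: pd.DataFrame,
    target_ids: set[int],
    *,
    pt_soc: Mapping[str, str] | None = None,
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
    yates: bool = False,
    min_target_count: int = 1,
) -> pd.DataFrame:
    """Per-term signal statistics for every term the target drug reports.

    ``pairs`` is the full event universe (see :func:`event_pairs`);
    ``target_ids`` the cohort's primaryids.  Marginals are shared across all
    rows of one run: a+b is the target event total and N the size of the
    universe.  Returns one row per term with ``a >= min_target_count``.
    """
    is_target = pairs["primaryid"].isin(target_ids)
    total_target = int(is_target.sum())
    total_other = int(len(pairs) - total_target)
    if total_other == 0:
        _warnings.warn("empty background: statistics undefined for every term")

    a_counts = pairs.loc[is_target, "term"].value_counts()
    c_counts = pairs.loc[~is_target, "term"].value_counts()
    display = pairs.drop_duplicates("term").set_index("term")["display"]
    soc_map = {k.strip().lower(): v for k, v in pt_soc.items()} if pt_soc else {}

    rows = []
    for term, a in a_counts.items():
        if a < min_target_count:
            continue
        c = int(c_counts.get(term, 0))
        t = ContingencyTable(int(a), total_target - int(a), c, total_other - c)
        s = signal_stats(t, thresholds, yates)
        rows.append(
            {
                "term": term,
                "display": display.get(term, term),
                "soc": soc_map.get(term, ""),
                "a": int(a),
                "b": t.b,
                "c": t.c,
                "d": t.d,
                "ror": s.ror, "ror_lo": s.ror_lo, "ror_hi": s.ror_hi,
                "prr": s.prr, "chi2": s.chi2,
                "ic": s.ic, "ic025": s.ic025,
                "ebgm": s.ebgm, "ebgm05": s.ebgm05,
                "ror_flag": s.ror_flag, "prr_flag": s.prr_flag,
                "bcpnn_flag": s.bcpnn_flag, "ebgm_flag": s.ebgm_flag,
                "corrected": s.corrected,
                "positive": s.positive,
            }
        )
    frame = pd.DataFrame(rows)
    if not frame.empty:
        frame = frame.sort_values(["a", "term"], ascending=[False, True]).reset_index(drop=True)
    return frame


def screen_signals(
    table: pd.DataFrame, exclusions: Mapping[str, Iterable[str]] | None = None
) -> pd.DataFrame:
    """Annotate a signal table with per-category exclusion reasons.

    ``exclusions`` maps a reason label (e.g. ``disease-complication``,
    ``dosing-packaging``, ``unspecific``) to the PTs it removes; matching is
    case-insensitive.  Rows keep their statistics — ``excluded_reason`` is
    filled and :func:`positive_signals` then drops them, so every decision
    stays auditable.
    """
    frame = table.copy()
    frame["excluded_reason"] = ""
    if exclusions:
        for reason, terms in exclusions.items():
            keys = {str(t).strip().lower() for t in terms}
            hit = frame["term"].isin(keys) & (frame["excluded_reason"] == "")
            frame.loc[hit, "excluded_reason"] = reason
    return frame


def positive_signals(table: pd.DataFrame) -> pd.DataFrame:
    """Rows flagged by all four algorithms and not excluded."""
    if table.empty:
        return table
    mask = table["positive"]
    if "excluded_reason" in table.columns:
        mask = mask & (table["excluded_reason"] == "")
    return table[mask].reset_index(drop=True)


def rank_by_ebgm(table: pd.DataFrame, k: int | None = None) -> pd.DataFrame:
    """Descending EBGM, ties broken by case count then term; first ``k`` rows."""
    if table.empty:
        return table
    ranked = table.sort_values(
        ["ebgm", "a", "term"], ascending=[False, False, True]
    ).reset_index(drop=True)
    return ranked if k is None else ranked.head(k).reset_index(drop=True)


_REPORT_DECIMALS = {
    "ror": 2, "ror_lo": 2, "ror_hi": 2, "prr": 2, "chi2": 2,
    "ic": 2, "ic025": 2, "ebgm": 2, "ebgm05": 2,
}


def write_signal_table(table: pd.DataFrame, path: str | Path, report_view: bool = False) -> Path:
    """Write a signal table as TSV; the report view rounds to two decimals."""
    path = Path(path)
    out = table.copy()
    if report_view:
        for col, nd in _REPORT_DECIMALS.items():
            if col in out.columns:
                out[col] = out[col].map(lambda v: f"{v:.{nd}f}" if pd.notna(v) else "")
    out.to_csv(path, sep="\t", index=False)
    return path
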