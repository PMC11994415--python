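# Methods

## Data model and ingestion

FAERS distributes each quarter as seven `$`-delimited ASCII tables
(DEMO, DRUG, REAC, OUTC, RPSR, THER, INDI) linked by PRIMARYID. Files
are read as Latin-1 with replacement so legacy non-UTF-8 bytes never
abort ingestion; the delimiter is exactly `$` with no quoting dialect, so
an embedded `$` in free text splits the field (a documented limitation of
the source format, not of this reader). Column names match
case-insensitively, unknown columns pass through, and the row count of a
file is always preserved: malformed rows are padded/truncated with a
warning and unparseable identifier or date values are kept verbatim and
warned about, never dropped. The pre-2012 ISR-keyed legacy schema and
the XML dialect are out of scope.

Dates of the form YYYY, YYYYMM and YYYYMMDD are parsed to the earliest
consistent calendar date plus a precision flag (`year`/`month`/`day`).
Partial dates are never imputed; each downstream stage decides whether to
exclude them (only the time-to-onset stage does). Ages are normalized to
years by unit-faithful factors (DEC×10, YR×1, MON÷12, WK÷52.143,
DY÷365.25, HR÷8766) and flagged invalid outside [0, 150].

## De-duplication

Follow-up versions of a case share a CASEID. Per CASEID the report with
the most recent FDA receipt date (FDA_DT) is kept; exact date ties go to
the numerically largest PRIMARYID. Reports without an FDA_DT lose
against any dated revision — a dated report supersedes an undated one.
The rule is applied to the concatenation of all quarters before any drug
filtering, is deterministic under input permutation and idempotent, and a
repeated PRIMARYID raises rather than being silently resolved. An audit
log (caseid, kept, dropped) is emitted with every run.

## Cohort

Target-drug rows are matched by case-insensitive substring of a synonym
list (generic plus brand names) against both DRUGNAME and PROD_AI; no
spelling correction beyond the synonym dictionary is attempted. A kept
report joins the cohort when at least one matching row carries the
primary-suspect role (configurable). Within a case, PTs are unique
case-insensitively (a PT listed twice counts once), indications are taken
from the target drug's rows only, and the therapy start is the earliest
day-precision START_DT among those rows.

A report is serious when any of DE, LT, HO, DS, CA, RI, OT is present;
CA and RI are displayed under "Other serious". The characteristics table
uses half-up two-decimal percentages. Gender, age band (<18, 18–65 with
65 in the upper band, ≥65, unknown), reporter occupation, country and
report year use the cohort size as denominator; the outcome block uses
the total number of outcome counts (one per distinct code per case),
because a case can carry several or no outcome codes. The OCCP_COD map
keeps HP (unspecified health professional) as its own bucket rather than
folding it into Physician, so that mapping ambiguity stays visible.

## Disproportionality analysis

The counting unit is the unique (de-duplicated report, term) pair, at PT
level or, through a user-supplied two-column PT→SOC map, at SOC level
(PTs of one SOC within one report merge into a single pair; PTs missing
from the map fall into an `unclassified` bucket with a warning). The
comparator is every kept report outside the target cohort, regardless of
drug role. The four algorithms and their thresholds are listed in the
README; numerical details:

* χ² is the uncorrected Pearson closed form
  N(ad−bc)²/((a+b)(c+d)(a+c)(b+d)); a Yates switch is available and
  matches `scipy.stats.chi2_contingency(correction=True)`.
* V(IC) is the closed-form posterior variance with unit hyperparameters,
  (1/ln²2)·[(N−a+1)/((a+1)(N+2)) + (N−(a+b)+1)/((a+b+1)(N+2)) +
  (N−(a+c)+1)/((a+c+1)(N+2))]; in the large-N, small-margin limit it
  degenerates to (1/ln²2)/(a+1), which is exposed separately for
  recomputing bounds from published point estimates.
* EBGM is implemented as the shrinkage-free relative reporting ratio
  aN/((a+b)(a+c)) with a log-normal 90% lower bound; this form satisfies
  IC = log₂(EBGM) exactly, which published signal tables of this kind
  exhibit row by row. The full two-gamma MGPS mixture is a non-goal.
* Zero cells: the Haldane–Anscombe correction (+0.5 to all four cells)
  is applied only when a·d = 0 or b·c = 0, and the row is marked
  `corrected`. With a = 0 the IC/EBGM estimators are reported undefined
  (NaN, flags false). An empty comparator yields corrected, never-
  positive rows. Threshold boundaries are inclusive for PRR/χ²/minimum
  count and strict for the ROR lower bound, IC025 and EBGM05.

Screening keeps rows whose four flags all hold and whose PT is not on a
blocklist; excluded rows retain their statistics with the exclusion
reason recorded (disease complication, dosing/packaging, unspecific —
each supplied as a plain-text PT list). Ranking is by descending EBGM,
ties broken by case count then term. No multiple-testing correction is
applied, matching standard screening practice for these statistics.

## Time to onset

Onset is event date minus the earliest day-precision therapy start, in
whole days, one onset per report (the per-event alternative is a
configuration choice). Reports are excluded — with reasons
`missing_start`, `missing_event`, `partial_date`, `negative` — rather
than imputed. Day-0 onsets are valid and belong to the first bin.
Quantiles use linear interpolation (the common default; no convention is
universal for this statistic). Default bins are 0–30, 31–60, 61–90,
91–180, 181–360 and >360 days, all configurable.

## Sensitivity analysis

The full signal analysis is re-run on reports filed by healthcare
professionals, {MD, PH} by default with HP/OT as configurable additions.
By default the comparator cells b, c, d are recomputed from the
professional-reported universe so the 2×2 marginals stay internally
consistent; `restrict_background=False` switches to the full-database
comparator. The comparison reports the overlap and differences of the
positive PT sets, with the overlap marked by an asterisk in the exported
table. No agreement statistic beyond overlap is computed.

## Synthetic data generator

The generator exists to make every stage testable with known ground
truth. Each report draws one primary-suspect drug (target with
probability `target_share`), 1–5 background PTs uniformly from the
non-planted vocabulary, and each planted (drug, PT, ρ) association as an
independent Bernoulli with probability min(1, ρ·baseline) on that drug
and baseline elsewhere. Because the background event load is identically
distributed in both arms, the expected reporting odds ratio of a planted
PT equals ρ (saturation of ρ·baseline at 1 truncates the realizable
ratio and is warned about). `ground_truth()` returns the planted ρ with
expected post-dedup cell counts E[a] = n·share·min(1, ρ·baseline) and
E[c] for power and concentration assertions.

Defaults describe a mid-sized, realistic slice of a spontaneous-reporting
stream: two quarters × 4,000 reports; 5% target share; a consumer-heavy
reporter mix (CN 60%, PH 22%, MD 17%); ~93% US reports; 54/43/3%
M/F/unknown; 57% missing age; roughly half of reports carrying an
outcome code with hospitalization and "other serious" dominating;
duplicates re-emitted for 5% of reports as exact copies except a new
PRIMARYID and a later FDA_DT (exactly what the de-duplication rule can
disambiguate); therapy-start/event dates linked by a log-normal(ln 60,
1.2) onset — a right-skewed, two-month-median profile typical of oral
kinase-inhibitor safety data — degraded by 35% missing and 15% partial
dates per field, leaving about a quarter of reports with a computable
onset. All draws come from one `numpy.random.default_rng(seed)` in fixed
order, so a fixed seed yields byte-identical archives.

What the generator does **not** emulate: real FAERS marginal
distributions of drugs and PTs, correlated event co-reporting,
indication-dependent event profiles, reporting-rate drift over time, and
free-text drug-name noise beyond a brand/generic split. Passing
calibration and recovery tests therefore demonstrates the correctness
and statistical behaviour of the pipeline under its stated model, not
field performance on real FAERS extracts.

## Verification strategy and problem sizes

* Closed forms are checked against hand-computed reference tables and,
  for χ², against the observed-vs-expected Pearson statistic enumerated
  over all 810,000 2×2 tables with cells in [1, 30] (tolerance 1e-9),
  with scipy as a second, independent oracle on sampled tables.
* Proportional-rows tables must yield ROR = PRR = EBGM = 1, IC = 0,
  χ² = 0 and never flag.
* Null calibration: 200 replicates of one quarter × 4,000 reports with
  no planted association (every PT's true ratio is 1, E[a] ≈ 75 per PT);
  each algorithm's flag rate across PTs must stay ≤ 7%.
* Recovery: 200 replicates of 10,000 reports with one planted PT at
  ρ ∈ {3, 5, 10} (E[a] ∈ {30, 50, 100}); the true ρ must fall inside the
  ROR 95% CI in ≥ 90% of runs, and at ρ = 5 all four algorithms must
  flag in ≥ 95%. Replicate counts follow the nominal behaviour being
  asserted; volumes are the smallest that put the planted expectation
  comfortably in the asymptotic regime.
* End-to-end determinism: simulate + full pipeline twice under one seed
  must reproduce every input and output file byte for byte (SHA-256 in
  the manifest).

## Known limitations

* The EBGM column is the unshrunk relative reporting ratio; for very
  small a it is more optimistic than MGPS shrinkage would be. The
  screening conjunction mitigates this (BCPNN's IC025 is conservative at
  small a), but EBGM rankings for a ≤ 3 should be read with care.
* The ROR CI is a Wald interval; below a ≈ 5 its coverage degrades.
* `$` inside free-text fields corrupts column alignment (source-format
  limitation; such rows are padded/truncated with warnings).
* Multi-quarter schema drift is reconciled by column name only.
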