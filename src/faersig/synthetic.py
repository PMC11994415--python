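"""Synthetic seven-table FAERS-like archives with known ground truth.

The generator emulates the structure the pipeline consumes — DEMO, DRUG,
REAC, OUTC, RPSR, THER and INDI tables linked by PRIMARYID — with a
configurable report volume, a designated target drug carrying a share of
primary-suspect rows, planted drug–event associations of stated reporting-
rate ratio, duplicate-report injection (same CASEID, later FDA_DT, new
PRIMARYID), and realistic nuisance structure: reporter occupations,
outcome codes, therapy-start/event dates with a log-normal onset and
configurable missing/partial-date rates.

Event model
-----------
Every report draws one primary-suspect drug (the target with probability
``target_share``) and a handful of background PTs sampled uniformly from
the non-planted vocabulary.  Each planted (drug, PT, rho) association then
adds its PT as an independent Bernoulli event with probability
``min(1, rho * baseline)`` on reports of that drug and ``baseline``
elsewhere.  Because the background event load is identically distributed
in both arms, the expected reporting odds ratio of a planted PT equals
``rho`` (for ``rho * baseline <= 1``), which is what the recovery and
calibration tests lean on.

Everything is drawn from one ``numpy.random.default_rng(seed)`` in a fixed
order, so a fixed seed yields byte-identical archives.
"""

from __future__ import annotations

import math
import warnings as _warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import QuarterlyArchive, QUARTER_RE, write_archive

__all__ = [
    "PlantedAssociation",
    "SyntheticConfig",
    "DEFAULT_PT_SOC",
    "generate_archives",
    "generate",
    "ground_truth",
]

TARGET_DRUG = "RIPRETINIB"
TARGET_BRAND = "QINLOCK"

BACKGROUND_DRUGS = (
    "IMATINIB", "SUNITINIB", "REGORAFENIB", "AVAPRITINIB", "PEMBROLIZUMAB",
    "NIVOLUMAB", "PACLITAXEL", "CARBOPLATIN", "OSIMERTINIB", "LENVATINIB",
    "METFORMIN", "LISINOPRIL", "ATORVASTATIN", "OMEPRAZOLE", "LEVOTHYROXINE",
    "AMLODIPINE", "SERTRALINE", "GABAPENTIN", "WARFARIN", "PREDNISONE",
)

#: PT -> SOC vocabulary; MedDRA-style terms spanning the organ classes the
#: target-drug safety profile touches, plus broad nuisance terms.
DEFAULT_PT_SOC: Mapping[str, str] = {
    "Alopecia": "skin and subcutaneous tissue disorders",
    "Dry skin": "skin and subcutaneous tissue disorders",
    "Hyperkeratosis": "skin and subcutaneous tissue disorders",
    "Palmar-plantar erythrodysaesthesia syndrome": "skin and subcutaneous tissue disorders",
    "Blister": "skin and subcutaneous tissue disorders",
    "Skin fissures": "skin and subcutaneous tissue disorders",
    "Pruritus": "skin and subcutaneous tissue disorders",
    "Rash": "skin and subcutaneous tissue disorders",
    "Muscle spasms": "musculoskeletal and connective tissue disorders",
    "Myalgia": "musculoskeletal and connective tissue disorders",
    "Arthralgia": "musculoskeletal and connective tissue disorders",
    "Muscular weakness": "musculoskeletal and connective tissue disorders",
    "Constipation": "gastrointestinal disorders",
    "Diarrhoea": "gastrointestinal disorders",
    "Nausea": "gastrointestinal disorders",
    "Vomiting": "gastrointestinal disorders",
    "Abdominal pain": "gastrointestinal disorders",
    "Gingival bleeding": "gastrointestinal disorders",
    "Decreased appetite": "metabolism and nutrition disorders",
    "Dehydration": "metabolism and nutrition disorders",
    "Weight decreased": "investigations",
    "Blood bilirubin increased": "investigations",
    "Blood pressure increased": "investigations",
    "Haemoglobin decreased": "investigations",
    "Fatigue": "general disorders and administration site conditions",
    "Asthenia": "general disorders and administration site conditions",
    "Oedema peripheral": "general disorders and administration site conditions",
    "Pyrexia": "general disorders and administration site conditions",
    "Pain": "general disorders and administration site conditions",
    "Hypertension": "vascular disorders",
    "Haemorrhage": "vascular disorders",
    "Headache": "nervous system disorders",
    "Dizziness": "nervous system disorders",
    "Somnolence": "nervous system disorders",
    "Dyspnoea": "respiratory, thoracic and mediastinal disorders",
    "Cough": "respiratory, thoracic and mediastinal disorders",
    "Anaemia": "blood and lymphatic system disorders",
    "Thrombocytopenia": "blood and lymphatic system disorders",
    "Melanocytic naevus": "neoplasms benign, malignant and unspecified (incl cysts and polyps)",
    "Squamous cell carcinoma of skin": "neoplasms benign, malignant and unspecified (incl cysts and polyps)",
    "Skin papilloma": "neoplasms benign, malignant and unspecified (incl cysts and polyps)",
    "Liver abscess": "infections and infestations",
    "Pneumonia": "infections and infestations",
    "Urinary tract infection": "infections and infestations",
    "Insomnia": "psychiatric disorders",
    "Anxiety": "psychiatric disorders",
    "Renal impairment": "renal and urinary disorders",
    "Prostatomegaly": "reproductive system and breast disorders",
    "Hepatic lesion": "hepatobiliary disorders",
    "Vision blurred": "eye disorders",
}

INDICATIONS_TARGET = (
    "Gastrointestinal stromal tumour",
    "Gastric cancer",
    "Malignant melanoma",
    "Systemic mastocytosis",
    "Product used for unknown indication",
)
INDICATIONS_BACKGROUND = (
    "Hypertension", "Type 2 diabetes mellitus", "Neoplasm malignant",
    "Depression", "Pain", "Product used for unknown indication",
)


@dataclass(frozen=True)
class PlantedAssociation:
    """A (drug, PT) pair reported ``rate_ratio`` times its baseline rate."""

    drug: str
    pt: str
    rate_ratio: float
    baseline: float

    def __post_init__(self) -> None:
        if self.rate_ratio < 0:
            raise ValueError("rate_ratio must be >= 0")
        if not 0.0 < self.baseline <= 1.0:
            raise ValueError("baseline must be in (0, 1]")


DEFAULT_PLANTED = (
    PlantedAssociation(TARGET_DRUG, "Alopecia", 8.0, 0.010),
    PlantedAssociation(TARGET_DRUG, "Palmar-plantar erythrodysaesthesia syndrome", 10.0, 0.005),
    PlantedAssociation(TARGET_DRUG, "Muscle spasms", 5.0, 0.010),
)


@dataclass(frozen=True)
class SyntheticConfig:
    """Generative parameters for one synthetic dataset.

    Defaults emulate a mid-sized spontaneous-reporting slice: two quarters
    of 4,000 reports, a 5% target primary-suspect share, a mostly-US,
    consumer-heavy reporter mix, roughly half the reports carrying a
    serious outcome code, and a right-skewed log-normal onset centred near
    two months.  ``missing_date_rate``/``partial_date_rate`` degrade event
    and therapy-start dates independently, leaving roughly a quarter of
    reports with a computable onset.
    """

    n_reports: int = 4000
    quarters: tuple[str, ...] = ("2023Q1", "2023Q2")
    target_drug: str = TARGET_DRUG
    target_brand: str = TARGET_BRAND
    brand_name_rate: float = 0.3
    target_share: float = 0.05
    background_drugs: tuple[str, ...] = BACKGROUND_DRUGS
    pt_soc: Mapping[str, str] = field(default_factory=lambda: dict(DEFAULT_PT_SOC))
    planted: tuple[PlantedAssociation, ...] = DEFAULT_PLANTED
    bg_pts_min: int = 1
    bg_pts_max: int = 5
    duplicate_rate: float = 0.05
    missing_date_rate: float = 0.35
    partial_date_rate: float = 0.15
    occupation_dist: Mapping[str, float] = field(
        default_factory=lambda: {"CN": 0.60, "PH": 0.22, "MD": 0.17, "": 0.01}
    )
    outcome_count_dist: Mapping[int, float] = field(
        default_factory=lambda: {0: 0.52, 1: 0.38, 2: 0.10}
    )
    outcome_dist: Mapping[str, float] = field(
        default_factory=lambda: {"HO": 0.38, "OT": 0.36, "DE": 0.25, "LT": 0.008, "DS": 0.002}
    )
    sex_dist: Mapping[str, float] = field(
        default_factory=lambda: {"M": 0.54, "F": 0.43, "": 0.03}
    )
    country_dist: Mapping[str, float] = field(
        default_factory=lambda: {"US": 0.93, "FR": 0.02, "CA": 0.015, "CN": 0.008, "JP": 0.027}
    )
    age_missing_rate: float = 0.57
    onset_mu: float = math.log(60.0)
    onset_sigma: float = 1.2
    concomitant_rate: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_reports <= 0:
            raise ValueError("n_reports must be positive")
        for q in self.quarters:
            if not QUARTER_RE.match(q):
                raise ValueError(f"bad quarter label {q!r}")
        if not 0.0 <= self.duplicate_rate < 1.0:
            raise ValueError("duplicate_rate must lie in [0, 1)")
        for rate in (self.missing_date_rate, self.partial_date_rate,
                     self.target_share, self.brand_name_rate, self.age_missing_rate,
                     self.concomitant_rate):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates must lie in [0, 1]")
        if self.missing_date_rate + self.partial_date_rate > 1.0:
            raise ValueError("missing + partial date rates exceed 1")
        names = [self.target_drug, *self.background_drugs]
        if len(set(names)) != len(names):
            raise ValueError("drug vocabulary names must be unique")
        planted_pts = [p.pt for p in self.planted]
        if len(set(planted_pts)) != len(planted_pts):
            raise ValueError("planted PTs must be unique")
        for p in self.planted:
            if p.pt not in self.pt_soc:
                raise ValueError(f"planted PT {p.pt!r} missing from the PT->SOC vocabulary")
            if p.rate_ratio * p.baseline > 1.0:
                _warnings.warn(
                    f"planted probability for {p.pt!r} saturates at 1 "
                    f"(rho*baseline = {p.rate_ratio * p.baseline:.3g}); realizable ratio truncated"
                )

    @property
    def background_pts(self) -> tuple[str, ...]:
        planted = {p.pt for p in self.planted}
        return tuple(pt for pt in self.pt_soc if pt not in planted)

    @property
    def synonyms(self) -> tuple[str, ...]:
        return (self.target_drug.lower(), self.target_brand.lower())


def _choice(rng: np.random.Generator, labels: Sequence, probs: Mapping, size: int) -> np.ndarray:
    keys = list(labels)
    p = np.array([probs[k] for k in keys], dtype=float)
    p = p / p.sum()
    return rng.choice(np.array(keys, dtype=object), size=size, p=p)


def _date_strings(days: np.ndarray, missing: np.ndarray, partial: np.ndarray,
                  partial_year: np.ndarray) -> np.ndarray:
    """YYYYMMDD strings with the configured degradation applied."""
    as_dt = pd.Series(days.astype("datetime64[D]"))
    full = as_dt.dt.strftime("%Y%m%d").to_numpy(dtype=object)
    out = full.copy()
    out[partial & ~partial_year] = [s[:6] for s in full[partial & ~partial_year]]
    out[partial & partial_year] = [s[:4] for s in full[partial & partial_year]]
    out[missing] = ""
    return out


def _degrade(rng: np.random.Generator, cfg: SyntheticConfig, n: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    u = rng.random(n)
    missing = u < cfg.missing_date_rate
    partial = (~missing) & (u < cfg.missing_date_rate + cfg.partial_date_rate)
    partial_year = rng.random(n) < 0.5
    return missing, partial, partial_year


def _generate_quarter(cfg: SyntheticConfig, quarter: str, rng: np.random.Generator,
                      caseid_base: int) -> QuarterlyArchive:
    n = cfg.n_reports
    m = QUARTER_RE.match(quarter)
    assert m is not None
    q_start = np.datetime64(f"{m.group(1)}-{(int(m.group(2)) - 1) * 3 + 1:02d}-01", "D")

    caseid = caseid_base + np.arange(n, dtype=np.int64)
    primaryid = caseid * 100 + 1

    is_target = rng.random(n) < cfg.target_share
    drugname = rng.choice(np.array(cfg.background_drugs, dtype=object), size=n)
    prod_ai = drugname.copy()
    drugname[is_target] = cfg.target_drug
    prod_ai[is_target] = cfg.target_drug
    use_brand = is_target & (rng.random(n) < cfg.brand_name_rate)
    drugname[use_brand] = cfg.target_brand

    # background PT load: 1-5 uniform draws from the non-planted vocabulary
    bg_vocab = np.array(cfg.background_pts, dtype=object)
    k = rng.integers(cfg.bg_pts_min, cfg.bg_pts_max + 1, size=n)
    draws = rng.integers(0, len(bg_vocab), size=(n, cfg.bg_pts_max))
    mask = np.arange(cfg.bg_pts_max)[None, :] < k[:, None]
    reac_pid = np.repeat(primaryid, k)
    reac_pt = bg_vocab[draws[mask]]

    # planted associations: independent Bernoulli add-ons
    extra_pid, extra_pt = [], []
    for assoc in cfg.planted:
        on_drug = is_target if assoc.drug == cfg.target_drug else (drugname == assoc.drug)
        p = np.where(on_drug, min(1.0, assoc.rate_ratio * assoc.baseline), assoc.baseline)
        hit = rng.random(n) < p
        extra_pid.append(primaryid[hit])
        extra_pt.append(np.full(int(hit.sum()), assoc.pt, dtype=object))
    if extra_pid:
        reac_pid = np.concatenate([reac_pid, *extra_pid])
        reac_pt = np.concatenate([reac_pt, *extra_pt])

    # therapy start, onset, event and FDA receipt dates
    start_day = q_start + rng.integers(-180, 60, size=n)
    onset = np.rint(rng.lognormal(cfg.onset_mu, cfg.onset_sigma, size=n)).astype(np.int64)
    event_day = start_day + onset
    fda_day = event_day + rng.integers(3, 60, size=n)
    fda_dt = pd.Series(fda_day.astype("datetime64[D]")).dt.strftime("%Y%m%d").to_numpy(dtype=object)
    event_dt = _date_strings(event_day, *_degrade(rng, cfg, n))
    start_dt = _date_strings(start_day, *_degrade(rng, cfg, n))

    sex = _choice(rng, list(cfg.sex_dist), cfg.sex_dist, n)
    occp = _choice(rng, list(cfg.occupation_dist), cfg.occupation_dist, n)
    country = _choice(rng, list(cfg.country_dist), cfg.country_dist, n)
    age_years = np.clip(np.rint(rng.normal(62, 12, size=n)), 18, 95).astype(np.int64)
    age = age_years.astype(str).astype(object)
    age_cod = np.full(n, "YR", dtype=object)
    age_missing = rng.random(n) < cfg.age_missing_rate
    age[age_missing] = ""
    age_cod[age_missing] = ""

    n_out = _choice(rng, list(cfg.outcome_count_dist), cfg.outcome_count_dist, n).astype(int)
    outc_pid = np.repeat(primaryid, n_out)
    outc_cod = _choice(rng, list(cfg.outcome_dist), cfg.outcome_dist, int(n_out.sum()))
    outc = pd.DataFrame({"primaryid": outc_pid, "outc_cod": outc_cod}).drop_duplicates()

    has_conc = rng.random(n) < cfg.concomitant_rate
    conc_name = rng.choice(np.array(cfg.background_drugs, dtype=object), size=int(has_conc.sum()))

    indi_pt = np.empty(n, dtype=object)
    nt = int(is_target.sum())
    indi_pt[is_target] = _choice(
        rng, INDICATIONS_TARGET,
        {"Gastrointestinal stromal tumour": 0.72, "Gastric cancer": 0.02,
         "Malignant melanoma": 0.01, "Systemic mastocytosis": 0.01,
         "Product used for unknown indication": 0.24},
        nt,
    )
    indi_pt[~is_target] = rng.choice(np.array(INDICATIONS_BACKGROUND, dtype=object), size=n - nt)

    rpsr_cod = _choice(rng, ["FGN", "HP", "CSM", "OTH"],
                       {"FGN": 0.1, "HP": 0.3, "CSM": 0.55, "OTH": 0.05}, n)

    s = lambda arr: pd.array(arr, dtype=object)
    demo = pd.DataFrame({
        "primaryid": s(primaryid.astype(str)), "caseid": s(caseid.astype(str)),
        "fda_dt": s(fda_dt), "event_dt": s(event_dt),
        "age": s(age), "age_cod": s(age_cod), "sex": s(sex),
        "occp_cod": s(occp), "reporter_country": s(country),
    })
    drug = pd.DataFrame({
        "primaryid": s(primaryid.astype(str)), "drug_seq": "1",
        "role_cod": "PS", "drugname": s(drugname), "prod_ai": s(prod_ai),
    })
    conc = pd.DataFrame({
        "primaryid": s(primaryid[has_conc].astype(str)), "drug_seq": "2",
        "role_cod": "C", "drugname": s(conc_name), "prod_ai": s(conc_name),
    })
    drug = pd.concat([drug, conc], ignore_index=True)
    reac = pd.DataFrame({"primaryid": s(reac_pid.astype(str)), "pt": s(reac_pt)})
    outc = outc.astype(str)
    rpsr = pd.DataFrame({"primaryid": s(primaryid.astype(str)), "rpsr_cod": s(rpsr_cod)})
    ther = pd.DataFrame({
        "primaryid": s(primaryid.astype(str)), "dsg_drug_seq": "1", "start_dt": s(start_dt),
    })
    indi = pd.DataFrame({
        "primaryid": s(primaryid.astype(str)), "indi_drug_seq": "1", "indi_pt": s(indi_pt),
    })

    # duplicate injection: exact copies except a new PRIMARYID and later FDA_DT
    n_dup = int(round(cfg.duplicate_rate * n))
    if n_dup:
        dup_idx = np.sort(rng.choice(n, size=n_dup, replace=False))
        dup_pid = caseid[dup_idx] * 100 + 2
        dup_fda = pd.Series((fda_day[dup_idx] + rng.integers(1, 90, size=n_dup))
                            .astype("datetime64[D]")).dt.strftime("%Y%m%d").to_numpy(object)
        old_new = dict(zip(primaryid[dup_idx].astype(str), dup_pid.astype(str)))
        demo_dup = demo.iloc[dup_idx].copy()
        demo_dup["primaryid"] = dup_pid.astype(str)
        demo_dup["fda_dt"] = dup_fda
        demo = pd.concat([demo, demo_dup], ignore_index=True)

        def dup_rows(df: pd.DataFrame) -> pd.DataFrame:
            sub = df[df["primaryid"].isin(old_new)].copy()
            sub["primaryid"] = sub["primaryid"].map(old_new)
            return pd.concat([df, sub], ignore_index=True)

        drug, reac, outc, rpsr, ther, indi = (
            dup_rows(t) for t in (drug, reac, outc, rpsr, ther, indi)
        )

    tables = {"demo": demo, "drug": drug, "reac": reac, "outc": outc,
              "rpsr": rpsr, "ther": ther, "indi": indi}
    tables = {k: v.fillna("").astype(str) for k, v in tables.items()}
    return QuarterlyArchive(quarter_label=quarter, tables=tables)


def generate_archives(config: SyntheticConfig) -> list[QuarterlyArchive]:
    """Generate all configured quarters in memory (deterministic in the seed)."""
    rng = np.random.default_rng(config.seed)
    archives = []
    for i, quarter in enumerate(config.quarters):
        archives.append(_generate_quarter(config, quarter, rng, caseid_base=10_000_000 * (i + 1)))
    return archives


def generate(config: SyntheticConfig, directory: str | Path) -> list[QuarterlyArchive]:
    """Generate and serialize archives plus the PT->SOC map and ground truth."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    archives = generate_archives(config)
    for archive in archives:
        write_archive(archive, directory)
    pt_soc = pd.DataFrame(sorted(config.pt_soc.items()), columns=["pt", "soc"])
    pt_soc.to_csv(directory / "pt_soc.tsv", sep="\t", index=False)
    ground_truth(config).to_csv(directory / "ground_truth.tsv", sep="\t", index=False)
    return archives


def ground_truth(config: SyntheticConfig) -> pd.DataFrame:
    """Planted associations with their expected 2x2 target/background counts.

    ``expected_a`` counts unique reports (duplicates collapse under
    de-duplication), so it is the post-dedup expectation.
    """
    n_total = config.n_reports * len(config.quarters)
    drug_share = {config.target_drug: config.target_share}
    for name in config.background_drugs:
        drug_share[name] = (1.0 - config.target_share) / len(config.background_drugs)
    rows = []
    for assoc in config.planted:
        share = drug_share.get(assoc.drug, 0.0)
        p_on = min(1.0, assoc.rate_ratio * assoc.baseline)
        rows.append({
            "drug": assoc.drug,
            "pt": assoc.pt,
            "rate_ratio": assoc.rate_ratio,
            "baseline": assoc.baseline,
            "expected_a": n_total * share * p_on,
            "expected_c": n_total * (1.0 - share) * assoc.baseline,
        })
    return pd.DataFrame(rows)
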