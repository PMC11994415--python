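"""End-to-end run orchestration: ingest -> dedup -> cohort -> signals ->
screening -> ranking -> time-to-onset -> sensitivity, with a machine-
readable manifest (config hash, per-stage record counts, output hashes)
so that identical inputs and configuration reproduce identical bundles.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from . import cohort as cohort_mod
from . import dedup as dedup_mod
from . import io as faers_io
from . import sensitivity as sens_mod
from . import signals as signals_mod
from . import tto as tto_mod

__all__ = ["ConfigError", "DataError", "RunConfig", "load_config", "run_pipeline"]

log = logging.getLogger("faersig")

STAGES = ("ingest", "cohort", "signals", "tto", "sensitivity")


class ConfigError(ValueError):
    """Invalid or inconsistent run configuration (CLI exit code 2)."""


class DataError(ValueError):
    """Input data violates the expected dialect or contracts (exit code 3)."""


@dataclass
class RunConfig:
    """Everything one pipeline run depends on."""

    input_dir: str
    output_dir: str
    synonyms: tuple[str, ...]
    quarters: tuple[str, ...] | None = None  # None: discover from input_dir
    role_filter: tuple[str, ...] = ("PS",)
    pt_soc_path: str | None = None  # default: <input_dir>/pt_soc.tsv
    blocklists: Mapping[str, str] = field(default_factory=dict)  # reason -> path
    thresholds: signals_mod.Thresholds = signals_mod.DEFAULT_THRESHOLDS
    yates: bool = False
    top_k: int = 50
    tto_bins: tuple[tuple[int, int | None], ...] = tto_mod.DEFAULT_BINS
    professional_codes: tuple[str, ...] = tuple(sorted(sens_mod.DEFAULT_PROFESSIONAL_CODES))
    restrict_background: bool = True
    min_target_count: int = 1

    def validate(self) -> None:
        if not self.synonyms:
            raise ConfigError("target-drug synonym list is empty")
        if self.thresholds.min_count < 0 or self.thresholds.prr <= 0 or self.thresholds.chi2 < 0:
            raise ConfigError("thresholds must be positive")
        if not Path(self.input_dir).is_dir():
            raise ConfigError(f"input directory does not exist: {self.input_dir}")
        if self.pt_soc_path is not None and not Path(self.pt_soc_path).is_file():
            raise ConfigError(f"PT->SOC map not found: {self.pt_soc_path}")
        for reason, path in self.blocklists.items():
            if not Path(path).is_file():
                raise ConfigError(f"blocklist {reason!r} not found: {path}")

    def config_hash(self) -> str:
        """Hash of the analytic configuration (filesystem locations excluded,
        so identical analyses of identical data hash identically)."""
        payload = dataclasses.asdict(self)
        payload["thresholds"] = dataclasses.asdict(self.thresholds)
        for key in ("input_dir", "output_dir", "pt_soc_path"):
            payload.pop(key, None)
        payload["blocklists"] = sorted(payload.get("blocklists", {}))
        blob = json.dumps(payload, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()


def load_config(path: str | Path) -> RunConfig:
    """Build a RunConfig from a YAML file (flat keys mirroring the fields)."""
    try:
        raw = yaml.safe_load(Path(path).read_text())
    except (OSError, yaml.YAMLError) as exc:
        raise ConfigError(f"cannot read config {path}: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigError(f"config {path} must be a mapping")
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
    if "thresholds" in raw:
        raw["thresholds"] = signals_mod.Thresholds(**raw["thresholds"])
    for key in ("synonyms", "role_filter", "professional_codes", "quarters"):
        if key in raw and raw[key] is not None:
            raw[key] = tuple(raw[key])
    if "tto_bins" in raw:
        raw["tto_bins"] = tuple((lo, hi) for lo, hi in raw["tto_bins"])
    return RunConfig(**raw)


def _read_pt_soc(path: Path) -> dict[str, str]:
    frame = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    cols = [c.lower() for c in frame.columns]
    if "pt" not in cols or "soc" not in cols:
        raise DataError(f"{path}: PT->SOC map needs 'pt' and 'soc' columns")
    frame.columns = cols
    return dict(zip(frame["pt"], frame["soc"]))


def _read_blocklist(path: Path) -> set[str]:
    terms = set()
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            terms.add(line.lower())
    return terms


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig, stages: Sequence[str] | None = None) -> dict:
    """Execute the pipeline and write the report bundle; returns the manifest.

    ``stages`` selects a subset of {ingest, cohort, signals, tto,
    sensitivity}; prerequisites are implied (every stage needs ingest and
    cohort).  Outputs are plain delimited files under ``output_dir`` plus
    ``manifest.json``.
    """
    config.validate()
    wanted = set(stages or STAGES)
    bad = wanted - set(STAGES)
    if bad:
        raise ConfigError(f"unknown stage(s): {sorted(bad)}")
    wanted |= {"ingest", "cohort"}

    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    counts: dict[str, int] = {}
    outputs: dict[str, str] = {}

    def emit(name: str, path: Path) -> None:
        outputs[name] = _sha256(path)

    # -- ingest -------------------------------------------------------------
    quarters = list(config.quarters or faers_io.discover_quarters(config.input_dir))
    if not quarters:
        raise DataError(f"no FAERS quarters found in {config.input_dir}")
    log.info("ingest: reading %d quarter(s) from %s", len(quarters), config.input_dir)
    try:
        archives = [faers_io.read_archive(config.input_dir, q) for q in quarters]
    except (faers_io.FaersFormatError, FileNotFoundError) as exc:
        raise DataError(str(exc)) from exc
    tables = {k: faers_io.concat_tables(archives, k) for k in faers_io.TABLE_KINDS}
    counts["n_raw_reports"] = len(tables["demo"])

    try:
        dedup = dedup_mod.deduplicate(tables["demo"])
    except ValueError as exc:
        raise DataError(f"dedup: {exc}") from exc
    counts["n_dedup_reports"] = dedup.n_kept
    emit("dedup_audit", dedup_mod.write_dedup_audit(tables["demo"], dedup, out_dir / "dedup_audit.tsv"))
    log.info("dedup: %d raw -> %d unique cases", dedup.n_input, dedup.n_kept)

    # -- cohort -------------------------------------------------------------
    matched = cohort_mod.match_target_drug(tables["drug"], config.synonyms)
    cases = cohort_mod.build_cohort(tables, dedup, matched, frozenset(config.role_filter))
    counts["n_cohort_reports"] = len(cases)
    counts["n_cohort_events"] = sum(len(c.pts) for c in cases)
    summary = cohort_mod.summarize_cohort(cases)
    emit("cohort_summary", cohort_mod.write_summary(summary, out_dir / "cohort_summary.tsv"))
    log.info("cohort: %d reports, %d events", counts["n_cohort_reports"], counts["n_cohort_events"])

    target_ids = {c.primaryid for c in cases}

    pt_soc_path = Path(config.pt_soc_path) if config.pt_soc_path else Path(config.input_dir) / "pt_soc.tsv"
    pt_soc = _read_pt_soc(pt_soc_path) if pt_soc_path.is_file() else {}
    if not pt_soc and ("signals" in wanted or "sensitivity" in wanted):
        raise ConfigError(f"PT->SOC map required for signal analysis: {pt_soc_path} not found")

    blocklists = {reason: _read_blocklist(Path(p)) for reason, p in config.blocklists.items()}
    pt_table = pd.DataFrame()

    # -- signals ------------------------------------------------------------
    if "signals" in wanted or "sensitivity" in wanted:
        pairs_pt = signals_mod.event_pairs(tables["reac"], dedup.kept_primaryids, level="pt")
        pt_table = signals_mod.signal_table(
            pairs_pt, target_ids, pt_soc=pt_soc, thresholds=config.thresholds,
            yates=config.yates, min_target_count=config.min_target_count,
        )
        pt_table = signals_mod.screen_signals(pt_table, blocklists)
        counts["n_terms"] = len(pt_table)
        counts["n_positive_pts"] = len(signals_mod.positive_signals(pt_table))

        pairs_soc = signals_mod.event_pairs(tables["reac"], dedup.kept_primaryids,
                                            level="soc", pt_soc=pt_soc)
        soc_table = signals_mod.signal_table(
            pairs_soc, target_ids, thresholds=config.thresholds, yates=config.yates)
        top = signals_mod.rank_by_ebgm(signals_mod.positive_signals(pt_table), config.top_k)

        emit("signals_pt", signals_mod.write_signal_table(pt_table, out_dir / "signals_pt.tsv"))
        emit("signals_pt_report",
             signals_mod.write_signal_table(pt_table, out_dir / "signals_pt_report.tsv", report_view=True))
        emit("signals_soc", signals_mod.write_signal_table(soc_table, out_dir / "signals_soc.tsv"))
        emit("signals_top",
             signals_mod.write_signal_table(top, out_dir / "signals_top.tsv", report_view=True))
        log.info("signals: %d PTs, %d positive", counts["n_terms"], counts["n_positive_pts"])

    # -- time to onset ------------------------------------------------------
    if "tto" in wanted:
        onsets = tto_mod.compute_onsets(cases)
        onset_summary = tto_mod.summarize_onsets(onsets, config.tto_bins)
        counts["n_tto_included"] = onset_summary.n_included
        emit("tto_summary", tto_mod.write_onset_summary(onset_summary, out_dir / "tto_summary.tsv"))
        log.info("tto: %d onsets included (median %.0f d)",
                 onset_summary.n_included, onset_summary.median_days)

    # -- sensitivity --------------------------------------------------------
    if "sensitivity" in wanted:
        codes = frozenset(config.professional_codes)
        subset_cases = sens_mod.filter_professional(cases, codes)
        counts["n_sensitivity_reports"] = len(subset_cases)
        counts["n_sensitivity_events"] = sum(len(c.pts) for c in subset_cases)
        if config.restrict_background:
            universe = dedup.kept_primaryids & sens_mod.professional_ids(tables["demo"], codes)
        else:
            universe = dedup.kept_primaryids
        pairs_sub = signals_mod.event_pairs(tables["reac"], universe, level="pt")
        sub_table = signals_mod.signal_table(
            pairs_sub, {c.primaryid for c in subset_cases}, pt_soc=pt_soc,
            thresholds=config.thresholds, yates=config.yates,
            min_target_count=config.min_target_count,
        )
        sub_table = signals_mod.screen_signals(sub_table, blocklists)
        comparison = sens_mod.compare_runs(
            pt_table, sub_table, len(subset_cases), counts["n_sensitivity_events"])
        display = dict(zip(pt_table.get("term", []), pt_table.get("display", [])))
        emit("sensitivity_signals",
             signals_mod.write_signal_table(sub_table, out_dir / "sensitivity_signals.tsv"))
        emit("sensitivity_comparison",
             sens_mod.write_comparison(comparison, pt_table,
                                       out_dir / "sensitivity_comparison.tsv", display))
        log.info("sensitivity: %d professional reports, %d shared positives",
                 len(subset_cases), len(comparison.overlap))

    manifest = {
        "config_hash": config.config_hash(),
        "quarters": quarters,
        "stages": sorted(wanted),
        "counts": counts,
        "outputs": outputs,
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
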