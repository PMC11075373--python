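"""End-to-end pipeline: filter -> build -> analyze -> screen, plus the
per-year / per-drug usage tables.

Every artifact carries the run's seed and a hash of the configuration in
a leading comment line (CSV) or top-level keys (JSON), so a run is fully
identified by its inputs; with a fixed configuration and seed the whole
pipeline is deterministic and re-running it is byte-identical.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import hashlib
import json
import logging
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from . import metrics as nm
from . import network as nb
from . import screening as sc
from . import ssun
from .records import (
    ConfigError,
    DEFAULT_STUDY_WINDOW,
    Drug,
    HospitalAttributes,
    PrescriptionRecord,
    SSUNRule,
    default_ssun_rules,
    load_hospital_attributes,
    load_records,
    write_records,
)

logger = logging.getLogger("narcoscreen")

SCHEMA_VERSION = 1


# --------------------------------------------------------------------------
# Usage tables (per-year / per-drug descriptive reporting)
# --------------------------------------------------------------------------

def average_prescriptions_per_patient(
    n_prescriptions: int, n_patients: int
) -> float:
    """Prescriptions per patient, rounded half-up to two decimals."""
    if n_patients <= 0:
        raise ConfigError("n_patients must be positive")
    ratio = Decimal(n_prescriptions) / Decimal(n_patients)
    return float(ratio.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def usage_table(
    records: Sequence[PrescriptionRecord], group_by: str = "year"
) -> pd.DataFrame:
    """Patients, prescriptions and their ratio per year or per drug.

    Empty groups are omitted; the ratio uses half-up rounding to two
    decimals.
    """
    if group_by not in ("year", "drug"):
        raise ConfigError("group_by must be 'year' or 'drug'")
    keys: dict[object, tuple[set, int]] = {}
    for rec in records:
        key = rec.date.year if group_by == "year" else rec.drug.value
        patients, n = keys.setdefault(key, (set(), 0))
        patients.add(rec.patient_id)
        keys[key] = (patients, n + 1)
    rows = []
    for key in sorted(keys, key=str):
        patients, n_rx = keys[key]
        rows.append({
            group_by: key,
            "n_patients": len(patients),
            "n_prescriptions": n_rx,
            "avg_prescriptions_per_patient":
                average_prescriptions_per_patient(n_rx, len(patients)),
        })
    return pd.DataFrame(
        rows, columns=[group_by, "n_patients", "n_prescriptions",
                       "avg_prescriptions_per_patient"]
    )


# --------------------------------------------------------------------------
# Configuration
# --------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Everything a pipeline run depends on.

    ``rule_overrides`` maps drug tokens to field overrides of the default
    SSUN rules, e.g. ``{"zolpidem": {"max_daily_dose_mg": 12.5}}``.
    """

    records: str | Path
    outdir: str | Path
    attributes: str | Path | None = None
    drugs: tuple[str, ...] | None = None
    projection: str = "binary"            # or "weighted"
    resolution: float = 1.0
    k_percent: float = 1.0
    seed: int = 42
    delimiter: str | None = None
    study_window: tuple[dt.date, dt.date] | None = DEFAULT_STUDY_WINDOW
    episode_gap_days: int = ssun.EPISODE_GAP_DAYS
    whole_history: bool = True
    rule_overrides: Mapping[str, Mapping[str, object]] = field(
        default_factory=dict
    )

    def __post_init__(self) -> None:
        if self.projection not in ("binary", "weighted"):
            raise ConfigError("projection must be 'binary' or 'weighted'")
        if self.drugs is not None:
            self.drugs = tuple(Drug.from_token(d).value for d in self.drugs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        window = raw.pop("study_window", None)
        if window is not None:
            window = (dt.date.fromisoformat(str(window[0])),
                      dt.date.fromisoformat(str(window[1])))
            raw["study_window"] = window
        if "drugs" in raw and raw["drugs"] is not None:
            raw["drugs"] = tuple(raw["drugs"])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["records"] = str(self.records)
        d["outdir"] = str(self.outdir)
        d["attributes"] = None if self.attributes is None else str(self.attributes)
        if self.study_window is not None:
            d["study_window"] = [w.isoformat() for w in self.study_window]
        d["rule_overrides"] = {k: dict(v) for k, v in self.rule_overrides.items()}
        if self.drugs is not None:
            d["drugs"] = list(self.drugs)
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    def resolved_rules(self) -> dict[Drug, SSUNRule]:
        rules = default_ssun_rules()
        for token, fields in self.rule_overrides.items():
            drug = Drug.from_token(token)
            rules[drug] = dataclasses.replace(rules[drug], **dict(fields))
        return rules


# --------------------------------------------------------------------------
# Pipeline
# --------------------------------------------------------------------------

@dataclass
class PipelineResult:
    """Paths of the written artifacts plus the in-memory summary."""

    summary: dict
    paths: dict[str, Path]


def _summary_entry(obj) -> dict:
    d = dataclasses.asdict(obj)
    return {k: v for k, v in d.items()}


def run_pipeline(
    config: PipelineConfig,
    records: Sequence[PrescriptionRecord] | None = None,
    attributes: Mapping[str, HospitalAttributes] | None = None,
) -> PipelineResult:
    """Execute filter -> build -> analyze -> screen and write artifacts.

    ``records``/``attributes`` may be passed in memory; otherwise they
    are loaded from the configured paths.  Artifacts per drug: flagged
    records, flag list, two-/one-mode GraphML and edge lists, per-node
    metric table, screening report; plus ``summary.json`` and
    ``run.log``.

    Raises
    ------
    ConfigError
        On invalid configuration (unknown drug, missing files); any
        stage failure propagates with the stage named in the log.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tag = f"narcoscreen schema={SCHEMA_VERSION} seed={config.seed} config={config.config_hash()}"
    log_lines: list[str] = [tag]

    def log(msg: str) -> None:
        logger.info(msg)
        log_lines.append(msg)

    if records is None:
        result = load_records(config.records, delimiter=config.delimiter,
                              study_window=config.study_window)
        if result.errors:
            for err in result.errors[:10]:
                log(f"load: line {err.line}: {err.message}")
        log(f"load: {len(result.records)} records, "
            f"{len(result.errors)} malformed rows, "
            f"{result.n_outside_window} outside study window")
        records = result.records
    else:
        records = list(records)
        log(f"load: {len(records)} records supplied in memory")

    if attributes is None and config.attributes is not None:
        attributes = load_hospital_attributes(config.attributes)

    rules = config.resolved_rules()
    present = sorted({r.drug.value for r in records})
    drug_tokens = list(config.drugs) if config.drugs is not None else present
    paths: dict[str, Path] = {}
    summary: dict = {
        "schema_version": SCHEMA_VERSION,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "n_records": len(records),
        "drugs": {},
    }

    for token in drug_tokens:
        drug = Drug.from_token(token)
        sub = [r for r in records if r.drug is drug]
        log(f"{token}: stage=filter in={len(sub)} records")
        flags = ssun.flag_exceedances(sub, rules,
                                      episode_gap_days=config.episode_gap_days)
        flagged = ssun.flagged_subset(sub, flags,
                                      whole_history=config.whole_history)
        exceed = ssun.summarize_exceedance(flagged)[drug]
        log(f"{token}: stage=filter out={len(flagged)} flagged records, "
            f"{len(flags)} flags, {exceed.n_patients} flagged patients")
        if not flagged:
            summary["drugs"][token] = {
                "n_records": len(sub), "n_flags": 0, "n_flagged_records": 0,
                "n_flagged_patients": 0,
            }
            continue

        two_mode = nb.build_two_mode(flagged)
        one_mode = nb.project_one_mode(
            two_mode, weighted=config.projection == "weighted"
        )
        log(f"{token}: stage=build two_mode={two_mode.number_of_nodes()} nodes/"
            f"{two_mode.number_of_edges()} edges, "
            f"one_mode={one_mode.number_of_nodes()} nodes/"
            f"{one_mode.number_of_edges()} edges")

        louv = nm.communities_louvain(two_mode, resolution=config.resolution,
                                      seed=config.seed)
        table = nm.centrality_table(two_mode, louvain=louv)
        net_summary = nm.summarize_network(two_mode, louvain=louv)
        hospitals = nm.hospital_table(table)
        log(f"{token}: stage=analyze modularity={net_summary.modularity:.4f} "
            f"communities={net_summary.n_communities}")

        overlap = sc.top_percent_overlap(hospitals, k_percent=config.k_percent)
        report = sc.build_screening_report(hospitals, attributes,
                                           k_percent=config.k_percent)
        strata_size = sc.stratify(one_mode, attributes, by="size_category")
        strata_region = sc.stratify(one_mode, attributes, by="region")
        log(f"{token}: stage=screen n_top={overlap.n_top} "
            f"overlap={overlap.overlap_fraction:.3f}")

        # ---- artifacts ----
        p = {}
        p["flagged"] = outdir / f"flagged_{token}.csv"
        write_records(flagged, p["flagged"], header_comment=tag)
        p["flags"] = outdir / f"flags_{token}.csv"
        ssun.write_flags(flags, p["flags"], header_comment=tag)
        p["two_mode"] = outdir / f"two_mode_{token}.graphml"
        nb.write_graphml(two_mode, p["two_mode"])
        p["one_mode"] = outdir / f"one_mode_{token}.graphml"
        nb.write_graphml(one_mode, p["one_mode"])
        p["edges"] = outdir / f"two_mode_{token}_edges.csv"
        nb.write_edge_list(two_mode, p["edges"], header_comment=tag)
        p["metrics"] = outdir / f"metrics_{token}.csv"
        with open(p["metrics"], "w", encoding="utf-8", newline="") as fh:
            fh.write(f"# {tag}\n")
            table.to_csv(fh, float_format="%.10g", lineterminator="\n")
        p["screening"] = outdir / f"screening_{token}.csv"
        with open(p["screening"], "w", encoding="utf-8", newline="") as fh:
            fh.write(f"# {tag}\n")
            report.to_csv(fh, index=False, float_format="%.10g",
                          lineterminator="\n")
        paths.update({f"{token}_{k}": v for k, v in p.items()})

        top_nsi = report.head(10)
        summary["drugs"][token] = {
            "n_records": len(sub),
            "n_flags": len(flags),
            "n_flagged_records": len(flagged),
            "n_flagged_patients": exceed.n_patients,
            "exceedance_mean": exceed.mean,
            "exceedance_sd": exceed.sd,
            "two_mode": _summary_entry(net_summary),
            "one_mode": {
                "n_nodes": one_mode.number_of_nodes(),
                "n_edges": one_mode.number_of_edges(),
            },
            "overlap": {
                "k_percent": overlap.k_percent,
                "n_top": overlap.n_top,
                "overlap_fraction": overlap.overlap_fraction,
            },
            "nsi_top10": [
                {"hospital_id": r.hospital_id, "nsi": round(r.nsi, 6),
                 "degree": int(r.degree),
                 "weighted_degree": r.weighted_degree}
                for r in top_nsi.itertuples()
            ],
            "quadrant_counts": report["quadrant"].value_counts().to_dict(),
            "size_category_shares": {
                c: round(v, 6) for c, v in
                strata_size.table["weighted_degree_share"].items()
            },
            "cross_region_edge_fraction":
                strata_region.cross_category_edge_fraction,
        }

    paths["summary"] = outdir / "summary.json"
    with open(paths["summary"], "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    paths["log"] = outdir / "run.log"
    with open(paths["log"], "w", encoding="utf-8") as fh:
        fh.write("\n".join(log_lines) + "\n")
    return PipelineResult(summary=summary, paths=paths)
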