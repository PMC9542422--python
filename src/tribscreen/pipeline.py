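"""Full screening pipeline: from input tables to the report set.

``run_pipeline`` chains the stages — curation/validation, benchmark
derivation, EAR and TQ computation, site flags, prioritization, site
reports, hydrologic analyses and the gap report of detected chemicals
lacking any screening value — and writes plain-CSV reports plus a JSON
manifest (config hash and row counts; no timestamps, so reruns are
bit-identical).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from tribscreen.core import StudyBundle, detection_frequency
from tribscreen.ecotox import derive_benchmark_table
from tribscreen.hydro import hydro_summary
from tribscreen.io import read_acc, read_endpoints, read_tables
from tribscreen.screening import (
    EAR_THRESHOLD,
    MIN_SITE_FRACTION,
    TQ_THRESHOLD,
    compute_tq_table,
    prioritize,
    site_flags,
)
from tribscreen.site_metrics import build_site_reports
from tribscreen.toxcast import compute_ear_table, sum_ear_chem

log = logging.getLogger(__name__)

_PKG_VERSION = "0.1.0"


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Inputs, thresholds and output location for one pipeline run."""

    input_dir: str = "."
    endpoints: str | None = None  # endpoints.csv path (default input_dir/endpoints.csv)
    acc: str | None = None  # acc.csv path (default input_dir/acc.csv)
    out_dir: str = "reports"
    ear_threshold: float = EAR_THRESHOLD
    tq_threshold: float = TQ_THRESHOLD
    min_site_fraction: float = MIN_SITE_FRACTION
    missing_half_life_af: int = 5
    log_level: str = "INFO"
    seed: int = 0  # reserved for resampling extensions; the pipeline is deterministic

    def __post_init__(self):
        if self.ear_threshold <= 0 or self.tq_threshold <= 0:
            raise ValueError("thresholds must be positive")
        if not 0 < self.min_site_fraction <= 1:
            raise ValueError("min_site_fraction must be in (0, 1]")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**data)

    def config_hash(self) -> str:
        """Hash of the analytic configuration (paths and logging excluded)."""
        payload = dataclasses.asdict(self)
        for key in ("out_dir", "log_level"):
            payload.pop(key, None)
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:16]


def gap_report(
    detection: pd.DataFrame,
    acc_cas: set,
    benchmark_cas: set,
    pharmaceutical_cas: set | None = None,
) -> pd.DataFrame:
    """Detected chemicals with neither an ACC nor an ECOTOX-style benchmark.

    Set difference ``detected \\ (has ACC | has benchmark)``, restricted
    to pharmaceuticals when ``pharmaceutical_cas`` is given, sorted by
    detection frequency descending. ``detection`` is the output of
    :func:`tribscreen.core.detection_frequency`.
    """
    detected = detection[detection["sites_detected"] > 0]
    if pharmaceutical_cas is not None:
        detected = detected[detected["cas"].isin(pharmaceutical_cas)]
    gap = detected[~detected["cas"].isin(acc_cas | benchmark_cas)]
    return gap.sort_values(
        ["detection_pct", "cas"], ascending=[False, True]
    ).reset_index(drop=True)


def run_pipeline(
    config: RunConfig,
    bundle: StudyBundle | None = None,
    acc: pd.DataFrame | None = None,
    endpoints: pd.DataFrame | None = None,
    write: bool = True,
) -> dict:
    """Run every stage and (optionally) write the report set.

    In-memory tables may be passed directly (as the synthetic generator
    produces them); otherwise they are read from ``config`` paths.
    Returns a dict of result tables keyed by report name.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))

    def stage(name, fn):
        try:
            result = fn()
        except Exception as exc:  # noqa: BLE001 — re-raised with stage context
            raise StageError(name, exc) from exc
        log.info("stage %-18s done", name)
        return result

    if bundle is None:
        bundle = stage("read_tables", lambda: read_tables(config.input_dir))
    if acc is None:
        acc_path = config.acc or str(Path(config.input_dir) / "acc.csv")
        acc = stage("read_acc", lambda: read_acc(acc_path))
    if endpoints is None:
        end_path = config.endpoints or str(Path(config.input_dir) / "endpoints.csv")
        endpoints = stage("read_endpoints", lambda: read_endpoints(end_path))

    benchmarks, chem_min = stage(
        "derive_benchmarks",
        lambda: derive_benchmark_table(
            endpoints, bundle.catalog, missing_half_life_af=config.missing_half_life_af
        ),
    )
    ear = stage("compute_ear", lambda: compute_ear_table(bundle, acc))
    ear_chem = stage("sum_ear_chem", lambda: sum_ear_chem(ear))
    tq = stage("compute_tq", lambda: compute_tq_table(bundle, chem_min))
    flags = stage(
        "site_flags",
        lambda: site_flags(
            bundle, ear_chem, tq,
            ear_threshold=config.ear_threshold, tq_threshold=config.tq_threshold,
        ),
    )
    monitored = bundle.sites_monitored_count()
    priority = stage(
        "prioritize",
        lambda: prioritize(flags, monitored, min_fraction=config.min_site_fraction),
    )
    detection = stage("detection_frequency", lambda: detection_frequency(bundle))
    pharma = set(bundle.catalog.loc[bundle.catalog["is_pharmaceutical"], "cas"])
    gaps = stage(
        "gap_report",
        lambda: gap_report(
            detection,
            set(acc.loc[acc["included"].astype(bool), "cas"]),
            set(chem_min.index),
            pharmaceutical_cas=pharma,
        ),
    )
    site_report = stage(
        "site_reports",
        lambda: build_site_reports(
            bundle, ear, flags,
            ear_threshold=config.ear_threshold, tq_threshold=config.tq_threshold,
        ),
    )
    hydro = stage("hydrology", lambda: hydro_summary(bundle))

    names = bundle.catalog.set_index("cas")[["name", "class"]]
    priority_out = priority.merge(names, left_on="cas", right_index=True, how="left")
    priority_out = priority_out[
        ["cas", "name", "class", "ear_exceed_sites", "tq_exceed_sites",
         "sites_monitored", "priority"]
    ]

    results = {
        "benchmarks": benchmarks,
        "chem_min_benchmark": chem_min,
        "ear": ear,
        "earchem": ear_chem,
        "tq": tq,
        "flags": flags,
        "priority": priority_out,
        "detection": detection,
        "gap_report": gaps,
        "site_report": site_report,
        "hydro": hydro,
    }

    if write:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        csv_reports = {
            "benchmarks.csv": benchmarks,
            "ear.csv": ear,
            "earchem.csv": ear_chem,
            "priority.csv": priority_out,
            "gap_report.csv": gaps,
            "site_report.csv": site_report,
            "flow_report.csv": hydro["flow_comparisons"],
        }
        for name, df in csv_reports.items():
            df.to_csv(out / name, index=False)
        wwtp_df = hydro["site_median_sums"].rename("median_sum_ng_l").reset_index()
        wwtp_df = wwtp_df.merge(
            bundle.sites[["site_id", "wwtp_fraction"]], on="site_id", how="left"
        )
        wwtp_df.to_csv(out / "wwtp_report.csv", index=False)

        manifest = {
            "package_version": _PKG_VERSION,
            "config_hash": config.config_hash(),
            "row_counts": {
                "chemicals": len(bundle.catalog),
                "sites": len(bundle.sites),
                "samples": len(bundle.samples),
                "measurements": len(bundle.measurements),
                "acc": len(acc),
                "endpoints": len(endpoints),
                **{name: len(df) for name, df in csv_reports.items()},
            },
            "stats": {
                "n_priority": int(priority_out["priority"].sum()),
                "n_gap": len(gaps),
                "flow_test": (
                    None
                    if hydro["flow_test"] is None
                    else {
                        "statistic": hydro["flow_test"].statistic,
                        "pvalue": hydro["flow_test"].pvalue,
                        "percent_difference": hydro["flow_test"].percent_difference,
                    }
                ),
                "wwtp_correlation": (
                    None
                    if hydro["wwtp_correlation"] is None
                    else {
                        "r": hydro["wwtp_correlation"].r,
                        "pvalue": hydro["wwtp_correlation"].pvalue,
                        "slope": hydro["wwtp_correlation"].slope,
                    }
                ),
            },
        }
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        results["manifest"] = manifest
    return results
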