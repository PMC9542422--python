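"""Readers and writers for the pipeline's CSV tables.

All tables are UTF-8 CSV with a header row. Concentration units are fixed
per table: ng/L in measurement files, µg/L in endpoint/benchmark files,
µM in ACC files.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping

import pandas as pd

from tribscreen.core import (
    CHEMICAL_COLUMNS,
    MEASUREMENT_COLUMNS,
    SAMPLE_COLUMNS,
    SITE_COLUMNS,
    SchemaError,
    StudyBundle,
)

log = logging.getLogger(__name__)

TABLE_FILES = {
    "chemicals": "chemicals.csv",
    "sites": "sites.csv",
    "samples": "samples.csv",
    "measurements": "measurements.csv",
}

ENDPOINT_COLUMNS = [
    "cas",
    "endpoint_code",
    "effect_level",
    "conc_ug_l",
    "species",
    "species_group",
    "excluded",
    "exclusion_reason",
]
ACC_COLUMNS = ["cas", "assay_id", "acc_um", "included"]


def _read_csv(path: Path, required: list[str], label: str) -> pd.DataFrame:
    if not path.exists():
        raise FileNotFoundError(f"{label} table not found at {path}")
    df = pd.read_csv(path, dtype={"cas": str} if "cas" in required else None)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{label} table {path} missing column(s) {missing}")
    log.info("read %d %s rows from %s", len(df), label, path)
    return df


def read_tables(source: Mapping[str, Path] | str | Path) -> StudyBundle:
    """Read and validate a study bundle.

    Parameters
    ----------
    source
        Either a directory containing the standard file names
        (``chemicals.csv``, ``sites.csv``, ``samples.csv``,
        ``measurements.csv``) or a mapping of table role to file path.

    Returns
    -------
    StudyBundle
        Validated bundle: schemas checked, all cross-references resolved,
        curated values derived.
    """
    if isinstance(source, (str, Path)):
        base = Path(source)
        paths = {role: base / name for role, name in TABLE_FILES.items()}
    else:
        paths = {role: Path(p) for role, p in source.items()}
    bundle = StudyBundle(
        catalog=_read_csv(paths["chemicals"], CHEMICAL_COLUMNS, "chemicals"),
        sites=_read_csv(paths["sites"], SITE_COLUMNS, "sites"),
        samples=_read_csv(paths["samples"], SAMPLE_COLUMNS, "samples"),
        measurements=_read_csv(paths["measurements"], MEASUREMENT_COLUMNS, "measurements"),
    )
    return bundle.validate()


def write_tables(bundle: StudyBundle, out_dir: str | Path) -> dict[str, Path]:
    """Write a bundle back to the standard CSV file names."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = {}
    for role, df in [
        ("chemicals", bundle.catalog),
        ("sites", bundle.sites),
        ("samples", bundle.samples),
        ("measurements", bundle.measurements[MEASUREMENT_COLUMNS]),
    ]:
        path = out / TABLE_FILES[role]
        df.to_csv(path, index=False)
        written[role] = path
    return written


def read_endpoints(path: str | Path) -> pd.DataFrame:
    """Read an ecotoxicity endpoint table (concentrations in µg/L)."""
    df = _read_csv(Path(path), ENDPOINT_COLUMNS, "endpoints")
    df["excluded"] = df["excluded"].fillna(False).astype(bool)
    return df


def read_acc(path: str | Path) -> pd.DataFrame:
    """Read an ACC table (chemical x assay activity concentrations, µM)."""
    df = _read_csv(Path(path), ACC_COLUMNS, "acc")
    df["included"] = df["included"].fillna(False).astype(bool)
    if (df["acc_um"] <= 0).any():
        bad = df.loc[df["acc_um"] <= 0, "cas"].tolist()[:5]
        raise SchemaError(f"ACC values must be positive (CAS {bad})")
    if df.duplicated(["cas", "assay_id"]).any():
        raise SchemaError("duplicate (cas, assay_id) pairs in ACC table")
    return df
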