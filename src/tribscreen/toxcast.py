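"""Exposure-activity ratios (EARs) from a curated ACC table.

An EAR compares a measured water concentration with the activity
concentration at cutoff (ACC) of a high-throughput in vitro assay:

    EAR = measured concentration (µM) / ACC for the chemical-assay pair (µM)

Per-chemical EAR_Chem values sum the EARs over the chemical's included
assays in one sample, so a chemical activating several assays at low
concentrations screens higher than one hitting a single assay. Assay
curation (which assays are appropriate) is consumed as an ``included``
flag on the ACC table, not recomputed.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from tribscreen.core import SchemaError, StudyBundle

log = logging.getLogger(__name__)

EAR_COLUMNS = ["sample_id", "cas", "assay_id", "ear"]
EARCHEM_COLUMNS = ["sample_id", "cas", "ear_chem", "n_assays"]


def ng_per_l_to_micromolar(concentration_ng_l, molecular_weight: float):
    """Convert a mass concentration (ng/L) to a molar one (µM).

    µM = (ng/L) / (1000 * MW), with MW in g/mol: 1 µM of a 100 g/mol
    chemical is 100 µg/L.
    """
    mw = np.asarray(molecular_weight, dtype=float)
    if np.any(mw <= 0):
        raise SchemaError("molecular weight must be positive")
    conc = np.asarray(concentration_ng_l, dtype=float)
    if np.any(conc[~np.isnan(conc)] < 0):
        raise SchemaError("concentration must be nonnegative")
    out = conc / (1000.0 * mw)
    return float(out) if out.ndim == 0 else out


def micromolar_to_ng_per_l(concentration_um, molecular_weight: float):
    """Inverse of :func:`ng_per_l_to_micromolar`."""
    mw = np.asarray(molecular_weight, dtype=float)
    if np.any(mw <= 0):
        raise SchemaError("molecular weight must be positive")
    out = np.asarray(concentration_um, dtype=float) * 1000.0 * mw
    return float(out) if out.ndim == 0 else out


def compute_ear_table(bundle: StudyBundle, acc: pd.DataFrame) -> pd.DataFrame:
    """EARs for every (regular sample, chemical, included assay) triple.

    Measured curated concentrations are converted to µM using the catalog
    molecular weight and divided by each included assay ACC. Nondetects
    yield EAR 0; interference-voided rows yield no EAR; excluded assays
    are skipped (logged, never silently included). Chemicals absent from
    the ACC table produce no rows.
    """
    included = acc[acc["included"].astype(bool)]
    n_excluded = len(acc) - len(included)
    if n_excluded:
        log.info("skipping %d excluded chemical-assay ACC rows", n_excluded)
    meas = bundle.regular_measurements()
    meas = meas[meas["qualifier"] != "interference"]
    mw = bundle.catalog.set_index("cas")["mw_g_mol"]
    conc_um = ng_per_l_to_micromolar(
        meas["curated_ng_l"].to_numpy(), meas["cas"].map(mw).to_numpy()
    )
    meas = meas.assign(conc_um=conc_um)
    merged = meas.merge(
        included[["cas", "assay_id", "acc_um"]], on="cas", how="inner"
    )
    merged["ear"] = merged["conc_um"] / merged["acc_um"]
    return merged[EAR_COLUMNS].reset_index(drop=True)


def sum_ear_chem(ear_table: pd.DataFrame) -> pd.DataFrame:
    """Sum EARs over assays for each (sample, chemical) pair.

    Returns ``sample_id``, ``cas``, ``ear_chem``, ``n_assays``; the assay
    count is kept for assay-coverage bias diagnostics. Pairs with no EAR
    rows simply do not appear (no ToxCast representation).
    """
    if ear_table.empty:
        return pd.DataFrame(columns=EARCHEM_COLUMNS)
    grouped = (
        ear_table.groupby(["sample_id", "cas"], sort=False)["ear"]
        .agg(ear_chem="sum", n_assays="size")
        .reset_index()
    )
    grouped["n_assays"] = grouped["n_assays"].astype(int)
    return grouped[EARCHEM_COLUMNS]


def min_acc_table(acc: pd.DataFrame) -> pd.Series:
    """Minimum included ACC (µM) per chemical — the most sensitive assay."""
    included = acc[acc["included"].astype(bool)]
    return included.groupby("cas")["acc_um"].min().rename("min_acc_um")
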