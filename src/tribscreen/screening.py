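"""Toxicity quotients, threshold exceedance, and site-fraction prioritization.

A toxicity quotient compares a measured concentration with the
chemical-level minimum screening benchmark:

    TQ = measured concentration (µg/L) / benchmark (µg/L)

Using the minimum benchmark yields the maximum (most protective) TQ.
Exceedance is judged per site against strict thresholds (defaults:
EAR_Chem > 1e-3, TQ > 0.1), where the site-level value is the maximum
across the site's regular samples. A chemical is high priority when it
exceeds either threshold at >= 10% of the sites monitored for its
presence; the chemical-specific monitored-site denominator avoids bias
from unequal analytical panel coverage. A missing screening value is
"unavailable" (rendered as NA), never a zero and never an exceedance.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from tribscreen.core import SchemaError, StudyBundle

EAR_THRESHOLD = 1e-3
TQ_THRESHOLD = 0.1
MIN_SITE_FRACTION = 0.10

TQ_COLUMNS = ["sample_id", "cas", "tq"]
FLAG_COLUMNS = ["site_id", "cas", "max_ear_chem", "max_tq", "exceeds_ear", "exceeds_tq"]
PRIORITY_COLUMNS = [
    "cas",
    "sites_monitored",
    "ear_exceed_sites",
    "tq_exceed_sites",
    "priority",
]


def compute_tq_table(bundle: StudyBundle, chem_benchmarks: pd.Series) -> pd.DataFrame:
    """TQs for every (regular sample, chemical) pair with a benchmark.

    Parameters
    ----------
    bundle : StudyBundle
    chem_benchmarks : Series
        Chemical-level minimum benchmark (µg/L) indexed by CAS; chemicals
        absent from the index yield no TQ rows (not 0).

    Measured ng/L values are converted to µg/L (÷1000); nondetects yield
    TQ 0; interference-voided rows yield no TQ.
    """
    if (chem_benchmarks <= 0).any():
        raise SchemaError("benchmarks must be positive")
    meas = bundle.regular_measurements()
    meas = meas[meas["qualifier"] != "interference"]
    meas = meas[meas["cas"].isin(set(chem_benchmarks.index))]
    conc_ug_l = meas["curated_ng_l"].to_numpy() / 1000.0
    tq = conc_ug_l / meas["cas"].map(chem_benchmarks).to_numpy()
    out = meas[["sample_id", "cas"]].copy()
    out["tq"] = tq
    return out.reset_index(drop=True)


def site_flags(
    bundle: StudyBundle,
    ear_chem: pd.DataFrame,
    tq: pd.DataFrame,
    ear_threshold: float = EAR_THRESHOLD,
    tq_threshold: float = TQ_THRESHOLD,
) -> pd.DataFrame:
    """Site-level maxima and strict threshold exceedance per site x chemical.

    One row per (site, chemical) pair where the chemical was monitored at
    the site and carries at least one type of screening value anywhere in
    the study. ``max_ear_chem``/``max_tq`` are maxima across the site's
    regular samples; NaN marks an unavailable screening value and renders
    the corresponding ``exceeds_*`` flag NA (a chemical without ACC data
    can never be an EAR false-positive).
    """
    site_of = bundle.samples.set_index("sample_id")["site_id"]
    acc_cas = set(ear_chem["cas"].unique()) if len(ear_chem) else set()
    tq_cas = set(tq["cas"].unique()) if len(tq) else set()
    screened = acc_cas | tq_cas

    def site_max(table: pd.DataFrame, value_col: str) -> pd.Series:
        if table.empty:
            return pd.Series(dtype=float)
        t = table.assign(site_id=table["sample_id"].map(site_of))
        return t.groupby(["site_id", "cas"])[value_col].max()

    max_ear = site_max(ear_chem, "ear_chem")
    max_tq = site_max(tq, "tq")

    rows = []
    for site, cas_set in bundle.monitored_cas_by_site().items():
        for cas in sorted(cas_set & screened):
            me = max_ear.get((site, cas), np.nan) if cas in acc_cas else np.nan
            mt = max_tq.get((site, cas), np.nan) if cas in tq_cas else np.nan
            rows.append(
                {
                    "site_id": site,
                    "cas": cas,
                    "max_ear_chem": me,
                    "max_tq": mt,
                    "exceeds_ear": (me > ear_threshold) if not np.isnan(me) else pd.NA,
                    "exceeds_tq": (mt > tq_threshold) if not np.isnan(mt) else pd.NA,
                }
            )
    out = pd.DataFrame(rows, columns=FLAG_COLUMNS)
    out["exceeds_ear"] = out["exceeds_ear"].astype("boolean")
    out["exceeds_tq"] = out["exceeds_tq"].astype("boolean")
    return out


def prioritize(
    flags: pd.DataFrame,
    monitored_counts: pd.Series,
    min_fraction: float = MIN_SITE_FRACTION,
) -> pd.DataFrame:
    """Per-chemical exceedance tallies and the high-priority flag.

    Parameters
    ----------
    flags : DataFrame
        Output of :func:`site_flags`.
    monitored_counts : Series
        Sites monitored per CAS (the chemical-specific denominator).
    min_fraction : float
        Minimum fraction of monitored sites with an exceedance for
        priority (inclusive; default 0.10).

    A chemical is priority when either exceedance fraction is
    >= ``min_fraction``; an unavailable screening value contributes
    nothing (NA tally, treated as failing its clause).
    """
    rows = []
    for cas, part in flags.groupby("cas", sort=True):
        n_monitored = int(monitored_counts.get(cas, 0))
        if n_monitored < 1:
            raise SchemaError(f"chemical {cas} monitored at zero sites")

        def tally(col: str):
            vals = part[col]
            if vals.isna().all():
                return pd.NA
            return int((vals == True).sum())  # noqa: E712  (nullable boolean)

        ear_sites = tally("exceeds_ear")
        tq_sites = tally("exceeds_tq")
        priority = False
        for count in (ear_sites, tq_sites):
            if count is not pd.NA and count / n_monitored >= min_fraction:
                priority = True
        rows.append(
            {
                "cas": cas,
                "sites_monitored": n_monitored,
                "ear_exceed_sites": ear_sites,
                "tq_exceed_sites": tq_sites,
                "priority": priority,
            }
        )
    out = pd.DataFrame(rows, columns=PRIORITY_COLUMNS)
    if len(out):
        out["ear_exceed_sites"] = out["ear_exceed_sites"].astype("Int64")
        out["tq_exceed_sites"] = out["tq_exceed_sites"].astype("Int64")
    return out


def exceedance_percent(exceed_sites: int, sites_monitored: int) -> int:
    """Exceedance (or detection) frequency as a nearest-integer percent."""
    if sites_monitored < 1:
        raise SchemaError("sites_monitored must be >= 1")
    return int(np.floor(100.0 * exceed_sites / sites_monitored + 0.5))
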