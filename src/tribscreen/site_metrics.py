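"""Per-site hazard and detection summaries.

For each site: how many pharmaceuticals were monitored and detected, how
many exceeded the EAR/TQ base thresholds in incremental order-of-magnitude
bands (t, 10t], (10t, 100t], (100t, inf), and the site's summed maximum
EAR over chemical-assay pairs (take the max EAR across the site's samples
for each pair, then sum the maxima).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from tribscreen.core import DETECTED_QUALIFIERS, IntegrityError, StudyBundle
from tribscreen.screening import EAR_THRESHOLD, TQ_THRESHOLD

SITE_REPORT_COLUMNS = [
    "site_id",
    "n_monitored",
    "n_detected",
    "ear_band1",
    "ear_band2",
    "ear_band3",
    "tq_band1",
    "tq_band2",
    "tq_band3",
    "sum_max_ear",
]


def site_detection_summary(
    bundle: StudyBundle, site_id: str, pharmaceuticals_only: bool = True
) -> tuple[int, int]:
    """(n_monitored, n_detected) chemicals at one site.

    Counts pharmaceuticals by default; pass ``pharmaceuticals_only=False``
    for the contextual (nonpharmaceutical) analytes as well.
    """
    monitored = bundle.monitored_cas_by_site().get(site_id)
    if monitored is None:
        raise IntegrityError(f"unknown site {site_id!r}")
    if pharmaceuticals_only:
        pharma = set(bundle.catalog.loc[bundle.catalog["is_pharmaceutical"], "cas"])
        monitored = monitored & pharma
    sample_ids = set(
        bundle.regular_samples.loc[
            bundle.regular_samples["site_id"] == site_id, "sample_id"
        ]
    )
    meas = bundle.measurements
    detected = meas[
        meas["sample_id"].isin(sample_ids)
        & meas["qualifier"].isin(DETECTED_QUALIFIERS)
        & meas["cas"].isin(monitored)
    ]["cas"].nunique()
    return len(monitored), int(detected)


def tier_counts(max_quotients, base_threshold: float) -> tuple[int, int, int]:
    """Band counts of site-level maximum quotients at x1 / x10 / x100.

    Each chemical exceeding ``base_threshold`` falls in exactly one band:
    (t, 10t], (10t, 100t], or (100t, inf). The bands partition the
    exceeding chemicals, so the counts sum to the exceedance count.
    """
    q = np.asarray(list(max_quotients), dtype=float)
    q = q[~np.isnan(q)]
    t = base_threshold
    band1 = int(np.sum((q > t) & (q <= 10 * t)))
    band2 = int(np.sum((q > 10 * t) & (q <= 100 * t)))
    band3 = int(np.sum(q > 100 * t))
    return band1, band2, band3


def sum_max_ear(ear_table: pd.DataFrame, per_chemical: bool = False) -> float:
    """Sum of maximum EARs at one site.

    Default: for each chemical-assay pair take the maximum EAR across the
    site's samples, then sum over pairs (the "all assays" reading). With
    ``per_chemical=True``, sum the per-chemical maxima of EAR_Chem
    instead (max over samples of the per-sample assay sums).
    """
    if ear_table.empty:
        return 0.0
    if per_chemical:
        per_sample = ear_table.groupby(["sample_id", "cas"])["ear"].sum()
        return float(per_sample.groupby("cas").max().sum())
    return float(ear_table.groupby(["cas", "assay_id"])["ear"].max().sum())


def build_site_reports(
    bundle: StudyBundle,
    ear_table: pd.DataFrame,
    flags: pd.DataFrame,
    ear_threshold: float = EAR_THRESHOLD,
    tq_threshold: float = TQ_THRESHOLD,
    top_n: int = 3,
) -> pd.DataFrame:
    """One summary row per site (columns :data:`SITE_REPORT_COLUMNS`).

    ``flags`` is the output of :func:`tribscreen.screening.site_flags`;
    ``ear_table`` the per-sample EAR rows. Sites with no EAR rows report
    ``sum_max_ear`` 0 (no ToxCast coverage at that site).
    """
    site_of = bundle.samples.set_index("sample_id")["site_id"]
    ear_by_site = (
        dict(tuple(ear_table.assign(site_id=ear_table["sample_id"].map(site_of)).groupby("site_id")))
        if len(ear_table)
        else {}
    )
    flags_by_site = dict(tuple(flags.groupby("site_id"))) if len(flags) else {}
    rows = []
    for site in bundle.sites["site_id"]:
        n_mon, n_det = site_detection_summary(bundle, site)
        fpart = flags_by_site.get(site)
        if fpart is not None:
            eb = tier_counts(fpart["max_ear_chem"].dropna(), ear_threshold)
            tb = tier_counts(fpart["max_tq"].dropna(), tq_threshold)
        else:
            eb = tb = (0, 0, 0)
        epart = ear_by_site.get(site)
        s_max = sum_max_ear(epart) if epart is not None else 0.0
        rows.append(
            {
                "site_id": site,
                "n_monitored": n_mon,
                "n_detected": n_det,
                "ear_band1": eb[0],
                "ear_band2": eb[1],
                "ear_band3": eb[2],
                "tq_band1": tb[0],
                "tq_band2": tb[1],
                "tq_band3": tb[2],
                "sum_max_ear": s_max,
            }
        )
    return pd.DataFrame(rows, columns=SITE_REPORT_COLUMNS)


def top_chemicals_by_tq(flags: pd.DataFrame, site_id: str, top_n: int = 3) -> list[tuple[str, float]]:
    """The ``top_n`` chemicals by site-level maximum TQ at one site."""
    part = flags[(flags["site_id"] == site_id)].dropna(subset=["max_tq"])
    part = part.sort_values("max_tq", ascending=False).head(top_n)
    return list(zip(part["cas"], part["max_tq"]))
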