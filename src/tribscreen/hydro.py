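"""Hydrologic condition comparison and wastewater-effluent correlation.

Summed Method 1 pharmaceutical concentrations per sample are the working
quantity throughout (the Method 1 panel was run on every sample, so the
comparison is unbiased by panel coverage). Samples at each site are split
into low- and increased-flow classes by the site median of mean daily
discharge; concentrations are normalized by the site mean so sites of
very different absolute magnitude can be pooled; and the two normalized
groups are compared with a Welch two-sample t test. Separately, per-site
median summed concentrations are regressed on the fraction of streamflow
attributable to wastewater-treatment-plant effluent (Pearson).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from tribscreen.core import SchemaError, StudyBundle, sample_panel_sums

log = logging.getLogger(__name__)

LOW = "low"
INCREASED = "increased"


@dataclass
class FlowTestResult:
    statistic: float
    pvalue: float
    percent_difference: float  # (median_low - median_high) / median_high * 100
    n_low: int
    n_high: int
    degenerate: bool = False


@dataclass
class WwtpCorrelation:
    r: float
    pvalue: float
    slope: float
    intercept: float
    n_sites: int


def classify_flow(discharges: pd.Series) -> pd.Series:
    """Low/increased flow classes for one site's sample discharges.

    Samples at or below the site median discharge are ``low``; above it,
    ``increased``. For the common two-sample site this reduces to lowest
    vs highest. Requires at least two samples with discharge.
    """
    d = discharges.astype(float)
    if d.isna().any():
        raise SchemaError("all samples need a discharge value to classify flow")
    if len(d) < 2:
        raise SchemaError("flow classification needs at least two samples")
    med = d.median()
    return pd.Series(np.where(d <= med, LOW, INCREASED), index=d.index)


def normalize_by_site_mean(values) -> np.ndarray:
    """Divide each value by the mean; output mean is exactly 1.

    Raises for an all-zero site (no information to normalize).
    """
    v = np.asarray(list(values), dtype=float)
    m = v.mean()
    if not m > 0:
        raise SchemaError("site mean must be positive to normalize")
    return v / m


def flow_comparisons(bundle: StudyBundle) -> pd.DataFrame:
    """Per-sample flow classes and site-normalized Method 1 sums.

    Sites lacking discharge data or fewer than two regular samples are
    omitted (logged). Returns columns ``site_id``, ``sample_id``,
    ``discharge``, ``flow_class``, ``sum_ng_l``, ``normalized``.
    """
    sums = sample_panel_sums(bundle, panel="M1", pharmaceuticals_only=True)
    samples = bundle.regular_samples
    rows = []
    for site, part in samples.groupby("site_id"):
        if len(part) < 2 or part["discharge"].isna().any():
            log.info("site %s omitted from flow comparison (need >=2 samples with discharge)", site)
            continue
        site_sums = sums.reindex(part["sample_id"]).to_numpy(dtype=float)
        if not site_sums.mean() > 0:
            log.info("site %s omitted from flow comparison (all-zero concentrations)", site)
            continue
        classes = classify_flow(part.set_index("sample_id")["discharge"])
        normalized = normalize_by_site_mean(site_sums)
        for sample_id, disch, s, n in zip(
            part["sample_id"], part["discharge"], site_sums, normalized
        ):
            rows.append(
                {
                    "site_id": site,
                    "sample_id": sample_id,
                    "discharge": disch,
                    "flow_class": classes[sample_id],
                    "sum_ng_l": s,
                    "normalized": n,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["site_id", "sample_id", "discharge", "flow_class", "sum_ng_l", "normalized"],
    )


def flow_effect_test(low_values, high_values) -> FlowTestResult:
    """Welch two-sample t test of normalized low- vs increased-flow groups.

    Also reports the percent difference of the group medians,
    (median_low - median_high) / median_high * 100 — positive when
    low-flow samples are more concentrated. Zero-variance groups are
    flagged as degenerate (statistic 0, p 1 when the groups are
    identical in mean).
    """
    low = np.asarray(list(low_values), dtype=float)
    high = np.asarray(list(high_values), dtype=float)
    if len(low) < 2 or len(high) < 2:
        raise SchemaError("each flow group needs at least two values")
    med_high = np.median(high)
    pct = (np.median(low) - med_high) / med_high * 100.0 if med_high != 0 else np.nan
    if low.std(ddof=1) == 0 and high.std(ddof=1) == 0:
        equal = low.mean() == high.mean()
        return FlowTestResult(
            statistic=0.0 if equal else np.inf,
            pvalue=1.0 if equal else 0.0,
            percent_difference=pct,
            n_low=len(low),
            n_high=len(high),
            degenerate=True,
        )
    t, p = stats.ttest_ind(low, high, equal_var=False)
    return FlowTestResult(
        statistic=float(t),
        pvalue=float(p),
        percent_difference=float(pct),
        n_low=len(low),
        n_high=len(high),
    )


def wwtp_correlation(
    site_median_sums: pd.Series, wwtp_fraction: pd.Series
) -> WwtpCorrelation:
    """Pearson correlation and linear fit of per-site median concentration
    sums against the WWTP effluent fraction of streamflow.

    Both series are aligned on their (site) index; requires at least three
    sites and nonzero variance in each variable.
    """
    joined = pd.concat(
        [site_median_sums.rename("y"), wwtp_fraction.rename("x")], axis=1
    ).dropna()
    if len(joined) < 3:
        raise SchemaError("correlation needs at least three sites")
    x = joined["x"].to_numpy(dtype=float)
    y = joined["y"].to_numpy(dtype=float)
    if x.std() == 0 or y.std() == 0:
        raise SchemaError("zero variance: correlation undefined")
    fit = stats.linregress(x, y)
    return WwtpCorrelation(
        r=float(fit.rvalue),
        pvalue=float(fit.pvalue),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        n_sites=len(joined),
    )


def hydro_summary(bundle: StudyBundle) -> dict:
    """Run both hydrologic analyses on a bundle.

    Returns a dict with the flow-comparison table, the Welch test result,
    the per-site medians table, and the WWTP correlation.
    """
    comp = flow_comparisons(bundle)
    test = None
    if len(comp):
        low = comp.loc[comp["flow_class"] == LOW, "normalized"]
        high = comp.loc[comp["flow_class"] == INCREASED, "normalized"]
        if len(low) >= 2 and len(high) >= 2:
            test = flow_effect_test(low, high)
    sums = sample_panel_sums(bundle, panel="M1", pharmaceuticals_only=True)
    site_of = bundle.samples.set_index("sample_id")["site_id"]
    medians = sums.groupby(sums.index.map(site_of)).median()
    medians.index.name = "site_id"
    wwtp = bundle.sites.set_index("site_id")["wwtp_fraction"]
    correlation = wwtp_correlation(medians, wwtp) if len(medians) >= 3 else None
    return {
        "flow_comparisons": comp,
        "flow_test": test,
        "site_median_sums": medians,
        "wwtp_correlation": correlation,
    }
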