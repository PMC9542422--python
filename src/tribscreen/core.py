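"""Domain schemas, censored-concentration curation, and QC operations.

The pipeline's tabular containers are pandas DataFrames with fixed column
names (see :data:`CHEMICAL_COLUMNS` etc.); a :class:`StudyBundle` groups the
four monitoring tables and enforces their cross-references.

Curation rules for a raw laboratory concentration against its method
detection limit (MDL) and method reporting limit (MRL):

* value below the MDL (or absent)  -> nondetect, curated value 0
* MDL <= value < MRL               -> estimate, curated value kept
* value >= MRL                     -> detect, curated value kept
* severe analytical interference   -> interference flag, no curated value
* minor interference downgrades a detect to an estimate

Nondetects are carried as zeros; summary statistics downstream use only
values above the detection level, so the zeros act as censoring markers,
not as observations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple

import numpy as np
import pandas as pd

PANELS = ("M1", "M2neg", "M2pos")
QUALIFIERS = ("detect", "estimate", "nondetect", "interference")
DETECTED_QUALIFIERS = ("detect", "estimate")
QC_TYPES = ("regular", "blank", "duplicate")
INTERFERENCE_LEVELS = ("none", "minor", "severe")

CHEMICAL_COLUMNS = [
    "cas",
    "name",
    "class",
    "is_pharmaceutical",
    "panel",
    "mw_g_mol",
    "mrl_ng_l",
    "mdl_ng_l",
    "half_life_weeks",
]
SITE_COLUMNS = [
    "site_id",
    "watershed",
    "lake",
    "tier",
    "wwtp_fraction",
    "drainage_km2",
    "pop_density",
]
SAMPLE_COLUMNS = ["sample_id", "site_id", "date", "discharge", "qc_type", "panels"]
MEASUREMENT_COLUMNS = ["sample_id", "cas", "value_ng_l", "qualifier"]


class SchemaError(ValueError):
    """A table is missing a required column or holds an invalid value."""


class IntegrityError(ValueError):
    """A cross-reference between tables does not resolve."""


class CurationResult(NamedTuple):
    qualifier: str
    value: float | None


def curate_measurement(
    raw_value: float | None,
    mdl: float,
    mrl: float,
    interference: str = "none",
) -> CurationResult:
    """Apply the censoring/interference rules to one raw concentration.

    Parameters
    ----------
    raw_value : float or None
        Laboratory concentration in ng/L, or None when nothing was
        quantified.
    mdl, mrl : float
        Method detection limit and method reporting limit, ng/L.
    interference : {"none", "minor", "severe"}
        Analytical interference observed for this result.

    Returns
    -------
    CurationResult
        ``(qualifier, curated_value)``; the value is 0 for nondetects and
        None for interference-voided results.
    """
    if mdl <= 0 or mrl <= 0:
        raise SchemaError(f"mdl and mrl must be positive (got mdl={mdl}, mrl={mrl})")
    if interference not in INTERFERENCE_LEVELS:
        raise SchemaError(f"unknown interference level {interference!r}")
    if raw_value is not None and raw_value < 0:
        raise SchemaError(f"negative concentration {raw_value!r}")
    if interference == "severe":
        return CurationResult("interference", None)
    if raw_value is None or raw_value < mdl:
        return CurationResult("nondetect", 0.0)
    qualifier = "estimate" if raw_value < mrl else "detect"
    if interference == "minor" and qualifier == "detect":
        qualifier = "estimate"
    return CurationResult(qualifier, float(raw_value))


def curated_values(measurements: pd.DataFrame) -> pd.Series:
    """Curated ng/L values for a measurement table.

    nondetect -> 0, interference -> NaN, detect/estimate -> reported value.
    """
    values = measurements["value_ng_l"].astype(float).copy()
    values[measurements["qualifier"] == "nondetect"] = 0.0
    values[measurements["qualifier"] == "interference"] = np.nan
    return values


@dataclass
class StudyBundle:
    """The four monitoring tables of one study, with resolved references.

    Attributes
    ----------
    catalog : DataFrame
        One row per chemical (columns :data:`CHEMICAL_COLUMNS`).
    sites : DataFrame
        One row per monitoring site (columns :data:`SITE_COLUMNS`).
    samples : DataFrame
        One row per water sample; ``panels`` is a ``|``-joined set of
        analytical method panels run on the sample.
    measurements : DataFrame
        One row per chemical per sample with the reported value and its
        curation qualifier; a ``curated_ng_l`` column is derived on
        validation.
    """

    catalog: pd.DataFrame
    sites: pd.DataFrame
    samples: pd.DataFrame
    measurements: pd.DataFrame
    _site_panels: dict = field(default=None, repr=False, compare=False)

    def validate(self) -> "StudyBundle":
        for df, cols, label in [
            (self.catalog, CHEMICAL_COLUMNS, "chemicals"),
            (self.sites, SITE_COLUMNS, "sites"),
            (self.samples, SAMPLE_COLUMNS, "samples"),
            (self.measurements, MEASUREMENT_COLUMNS, "measurements"),
        ]:
            missing = [c for c in cols if c not in df.columns]
            if missing:
                raise SchemaError(f"{label} table missing column(s) {missing}")
        if self.catalog["cas"].duplicated().any():
            dups = self.catalog.loc[self.catalog["cas"].duplicated(), "cas"].tolist()
            raise SchemaError(f"duplicate CAS in catalog: {dups}")
        for col in ("mw_g_mol", "mrl_ng_l", "mdl_ng_l"):
            bad = self.catalog[self.catalog[col] <= 0]
            if len(bad):
                raise SchemaError(f"nonpositive {col} for CAS {bad['cas'].tolist()}")
        unknown_panel = set(self.catalog["panel"]) - set(PANELS)
        if unknown_panel:
            raise SchemaError(f"unknown method panel(s) {sorted(unknown_panel)}")
        if (self.sites["wwtp_fraction"] < 0).any():
            raise SchemaError("wwtp_fraction must be >= 0")
        unknown_qc = set(self.samples["qc_type"]) - set(QC_TYPES)
        if unknown_qc:
            raise SchemaError(f"unknown qc_type(s) {sorted(unknown_qc)}")
        unknown_q = set(self.measurements["qualifier"]) - set(QUALIFIERS)
        if unknown_q:
            raise SchemaError(f"unknown qualifier(s) {sorted(unknown_q)}")

        # referential integrity
        site_ids = set(self.sites["site_id"])
        dangling = self.samples.loc[~self.samples["site_id"].isin(site_ids)]
        if len(dangling):
            raise IntegrityError(
                f"samples reference unknown site(s): {dangling['sample_id'].tolist()[:5]}"
            )
        sample_ids = set(self.samples["sample_id"])
        dangling = self.measurements.loc[~self.measurements["sample_id"].isin(sample_ids)]
        if len(dangling):
            raise IntegrityError(
                f"measurements reference unknown sample(s): "
                f"{dangling['sample_id'].unique().tolist()[:5]}"
            )
        cas_ids = set(self.catalog["cas"])
        dangling = self.measurements.loc[~self.measurements["cas"].isin(cas_ids)]
        if len(dangling):
            raise IntegrityError(
                f"measurements reference unknown CAS: "
                f"{dangling['cas'].unique().tolist()[:5]}"
            )
        for _, row in self.samples.iterrows():
            if not parse_panels(row["panels"]):
                raise SchemaError(f"sample {row['sample_id']} ran no panels")

        nd = self.measurements["qualifier"] == "nondetect"
        bad = self.measurements.loc[nd & (self.measurements["value_ng_l"].fillna(0) != 0)]
        if len(bad):
            raise SchemaError(
                f"nondetect rows must carry value 0 (rows {bad.index.tolist()[:5]})"
            )
        pos = self.measurements["qualifier"].isin(DETECTED_QUALIFIERS)
        bad = self.measurements.loc[pos & ~(self.measurements["value_ng_l"] > 0)]
        if len(bad):
            raise SchemaError(
                f"detect/estimate rows must carry a positive value "
                f"(rows {bad.index.tolist()[:5]})"
            )
        self.measurements = self.measurements.copy()
        self.measurements["curated_ng_l"] = curated_values(self.measurements)
        self._site_panels = None
        return self

    # -- convenience views -------------------------------------------------
    @property
    def regular_samples(self) -> pd.DataFrame:
        return self.samples[self.samples["qc_type"] == "regular"]

    def regular_measurements(self) -> pd.DataFrame:
        keep = set(self.regular_samples["sample_id"])
        return self.measurements[self.measurements["sample_id"].isin(keep)]

    def site_panels(self) -> dict[str, frozenset]:
        """Panels run at each site, as the union over its regular samples."""
        if self._site_panels is None:
            out: dict[str, set] = {s: set() for s in self.sites["site_id"]}
            for _, row in self.regular_samples.iterrows():
                out[row["site_id"]] |= parse_panels(row["panels"])
            self._site_panels = {k: frozenset(v) for k, v in out.items()}
        return self._site_panels

    def monitored_cas_by_site(self) -> dict[str, frozenset]:
        """Chemicals monitored at each site, derived from the panels run."""
        by_panel = {
            p: frozenset(self.catalog.loc[self.catalog["panel"] == p, "cas"])
            for p in PANELS
        }
        return {
            site: frozenset().union(*(by_panel[p] for p in panels)) if panels else frozenset()
            for site, panels in self.site_panels().items()
        }

    def sites_monitored_count(self) -> pd.Series:
        """Number of sites at which each catalog chemical was monitored."""
        monitored = self.monitored_cas_by_site()
        counts = {cas: 0 for cas in self.catalog["cas"]}
        for cas_set in monitored.values():
            for cas in cas_set:
                counts[cas] += 1
        return pd.Series(counts, name="sites_monitored")


def parse_panels(panels: str | Iterable[str]) -> frozenset:
    """Parse a ``|``-joined panel field (or an iterable) into a frozenset."""
    if isinstance(panels, str):
        parts = [p for p in panels.split("|") if p]
    else:
        parts = list(panels)
    unknown = set(parts) - set(PANELS)
    if unknown:
        raise SchemaError(f"unknown panel(s) {sorted(unknown)}")
    return frozenset(parts)


def detection_frequency(bundle: StudyBundle) -> pd.DataFrame:
    """Per-chemical detection frequency as a percent of sites monitored.

    The denominator is the number of sites at which the chemical was
    monitored (not the total number of sites); the numerator counts sites
    with at least one detect- or estimate-qualified result in a regular
    sample. Chemicals monitored at zero sites are flagged with an
    undefined (NaN) frequency rather than 0.

    Returns
    -------
    DataFrame with columns ``cas``, ``sites_monitored``, ``sites_detected``,
    ``detection_pct`` (nearest-integer percent, NaN when undefined).
    """
    monitored_counts = bundle.sites_monitored_count()
    meas = bundle.regular_measurements()
    detected = meas[meas["qualifier"].isin(DETECTED_QUALIFIERS)]
    site_of = bundle.samples.set_index("sample_id")["site_id"]
    det_sites = (
        detected.assign(site_id=detected["sample_id"].map(site_of))
        .groupby("cas")["site_id"]
        .nunique()
    )
    out = pd.DataFrame(
        {
            "cas": bundle.catalog["cas"],
            "sites_monitored": bundle.catalog["cas"].map(monitored_counts).fillna(0).astype(int),
            "sites_detected": bundle.catalog["cas"].map(det_sites).fillna(0).astype(int),
        }
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = out["sites_detected"] / out["sites_monitored"]
    out["detection_pct"] = np.floor(100.0 * frac + 0.5)
    out.loc[out["sites_monitored"] == 0, "detection_pct"] = np.nan
    return out.reset_index(drop=True)


def relative_percent_difference(a: float, b: float) -> float:
    """RPD = |a - b| / mean(a, b) * 100; symmetric; undefined when a = b = 0."""
    if a < 0 or b < 0:
        raise SchemaError("RPD requires nonnegative concentrations")
    if a == 0 and b == 0:
        raise SchemaError("RPD undefined for two zero concentrations")
    return abs(a - b) / ((a + b) / 2.0) * 100.0


def blank_screen(bundle: StudyBundle) -> pd.DataFrame:
    """Report chemicals detected in blank samples against their MRLs.

    Purely diagnostic: regular-sample data are never adjusted. Returns one
    row per chemical with any blank detection: ``cas``,
    ``n_blank_detections``, ``max_blank_ng_l``, ``below_mrl``.
    """
    blanks = bundle.samples.loc[bundle.samples["qc_type"] == "blank", "sample_id"]
    meas = bundle.measurements
    hits = meas[
        meas["sample_id"].isin(set(blanks)) & meas["qualifier"].isin(DETECTED_QUALIFIERS)
    ]
    if hits.empty:
        return pd.DataFrame(
            columns=["cas", "n_blank_detections", "max_blank_ng_l", "below_mrl"]
        )
    mrl = bundle.catalog.set_index("cas")["mrl_ng_l"]
    grouped = hits.groupby("cas")["value_ng_l"].agg(["count", "max"]).reset_index()
    grouped.columns = ["cas", "n_blank_detections", "max_blank_ng_l"]
    grouped["below_mrl"] = grouped["max_blank_ng_l"] < grouped["cas"].map(mrl)
    return grouped


def sum_panel_concentrations(
    bundle: StudyBundle,
    sample_id: str,
    panel: str,
    pharmaceuticals_only: bool = False,
) -> float:
    """Sum curated concentrations over one panel's analytes in one sample.

    Nondetects contribute 0; interference-voided rows are skipped. Raises
    if the sample did not run the requested panel (a silent 0 would be
    indistinguishable from an all-nondetect sample).
    """
    row = bundle.samples.loc[bundle.samples["sample_id"] == sample_id]
    if row.empty:
        raise IntegrityError(f"unknown sample {sample_id!r}")
    if panel not in parse_panels(row.iloc[0]["panels"]):
        raise IntegrityError(f"sample {sample_id!r} did not run panel {panel!r}")
    cat = bundle.catalog
    cas_set = cat.loc[cat["panel"] == panel, "cas"]
    if pharmaceuticals_only:
        cas_set = cat.loc[(cat["panel"] == panel) & cat["is_pharmaceutical"], "cas"]
    meas = bundle.measurements
    rows = meas[(meas["sample_id"] == sample_id) & meas["cas"].isin(set(cas_set))]
    return float(rows["curated_ng_l"].sum(skipna=True))


def sample_panel_sums(
    bundle: StudyBundle,
    panel: str = "M1",
    pharmaceuticals_only: bool = True,
    regular_only: bool = True,
) -> pd.Series:
    """Per-sample summed curated concentrations over one panel (ng/L).

    Only samples that ran the panel appear in the result (indexed by
    ``sample_id``). Vectorized counterpart of
    :func:`sum_panel_concentrations`.
    """
    samples = bundle.regular_samples if regular_only else bundle.samples
    ran = samples[samples["panels"].map(lambda p: panel in parse_panels(p))]
    cat = bundle.catalog
    mask = cat["panel"] == panel
    if pharmaceuticals_only:
        mask &= cat["is_pharmaceutical"].astype(bool)
    cas_set = set(cat.loc[mask, "cas"])
    meas = bundle.measurements
    rows = meas[meas["sample_id"].isin(set(ran["sample_id"])) & meas["cas"].isin(cas_set)]
    sums = rows.groupby("sample_id")["curated_ng_l"].sum()
    return sums.reindex(ran["sample_id"], fill_value=0.0)
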