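"""Seeded generator of study-shaped monitoring bundles with known truth.

The generator emulates a two-tier tributary monitoring design: a set of
sites with wastewater effluent fractions spanning none to nearly half of
streamflow, tier-1 sites sampled quarterly (4 samples) and tier-2 sites
twice (one low-flow, one increased-flow sample), and a chemical catalog
split across three analytical method panels with unequal site coverage
(every site runs the M1 panel; subsets run M2neg/M2pos). Concentrations
are lognormal with a site log-mean tied positively to the WWTP fraction,
a multiplicative elevation for low-flow samples, and left-censoring at
the method detection limit. ACC (in vitro) and ecotoxicity-endpoint
coverage is sparse — roughly half of detected chemicals end up with no
screening value of either kind, mirroring the availability gap real
screening studies face.

Planted exceedance geometry: for chemicals listed in
``planted_priority``, ACC values and endpoint records are constructed
*from the realized concentrations* so that the chemical exceeds the
EAR/TQ prioritization thresholds by at least ``plant_margin`` at at least
``plant_exceed_fraction`` of its monitored sites; all other covered
chemicals are constructed to stay below threshold everywhere by the same
margin. Downstream prioritization should therefore recover the planted
set exactly, which is what the ground-truth object records.

Reproducibility: each output table draws from its own substream
``default_rng([seed, k])`` with a documented table key ``k``
(sites=1, chemicals=2, samples=3, concentrations=4, qc=5, acc=6,
endpoints=7), so adding a table never perturbs earlier draws.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from tribscreen.core import StudyBundle
from tribscreen.ecotox import (
    ACUTE_EFFECT,
    AF_ENDPOINT,
    LOW_EFFECT,
    NO_EFFECT,
    SUBSETS,
    persistence_af,
)
from tribscreen.screening import EAR_THRESHOLD, TQ_THRESHOLD

_TABLE_KEYS = {
    "sites": 1,
    "chemicals": 2,
    "samples": 3,
    "concentrations": 4,
    "qc": 5,
    "acc": 6,
    "endpoints": 7,
}

_LAKES = ("Superior", "Michigan", "Huron", "Erie", "Ontario")
_CLASSES = (
    "Stimulant",
    "Antibiotic",
    "Antidepressant",
    "Analgesic",
    "Anticonvulsant",
    "Cardiovascular care",
    "Antihistamine",
    "Anticholesteremic",
)


class ConfigError(ValueError):
    """The generator configuration is inconsistent or infeasible."""


@dataclass
class GeneratorConfig:
    """Study-design parameters of the synthetic bundle.

    Defaults reproduce the monitored study shape: 44 sites (16 tier-1
    with 4 samples, 28 tier-2 with 2), 257 pharmaceuticals plus 9
    contextual nonpharmaceuticals over three method panels, WWTP effluent
    fractions up to 0.45 of streamflow, a 1.5x low-flow concentration
    elevation, and left-censoring at the MDL.
    """

    seed: int = 0
    n_sites: int = 44
    n_tier1: int = 16  # tier-1 sites: 4 samples; tier-2 sites: 2 samples
    n_pharmaceuticals: int = 257
    n_contextual: int = 9
    m2neg_site_fraction: float = 0.68  # fraction of sites also running M2neg
    m2pos_site_fraction: float = 0.45  # subset of those also running M2pos
    wwtp_range: tuple[float, float] = (0.0, 0.45)
    log_conc_base: float = 0.3  # ng/L scale: median chemical's median conc
    chem_spread_decades: float = 2.0  # sd of per-chemical log10 median offsets
    sample_sigma_decades: float = 0.3  # per-sample lognormal noise, log10 sd
    wwtp_slope: float = 2.0  # log10 ng/L per unit WWTP fraction
    low_flow_multiplier: float = 1.5
    censor_at_mdl: bool = True
    interference_rate: float = 0.002
    acc_coverage: float = 0.45  # fraction of detected pharmaceuticals with ACC
    endpoint_coverage: float = 0.25  # fraction with ecotox endpoints
    benchmark_overlap: float = 0.65  # endpoint chems that also carry ACC
    n_assays_range: tuple[int, int] = (1, 15)
    planted_priority: tuple[int, ...] = (0, 1, 2, 3, 4, 5)  # catalog indices
    plant_exceed_fraction: float = 0.25
    plant_margin: float = 2.0
    n_blanks: int = 2
    n_duplicates: int = 2
    blank_detection: bool = True
    ear_threshold: float = EAR_THRESHOLD
    tq_threshold: float = TQ_THRESHOLD

    def validate(self) -> "GeneratorConfig":
        for name in (
            "m2neg_site_fraction",
            "m2pos_site_fraction",
            "acc_coverage",
            "endpoint_coverage",
            "benchmark_overlap",
            "plant_exceed_fraction",
            "interference_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        if self.low_flow_multiplier <= 0:
            raise ConfigError("low_flow_multiplier must be positive")
        if self.n_tier1 > self.n_sites:
            raise ConfigError("n_tier1 cannot exceed n_sites")
        n_chem = self.n_pharmaceuticals + self.n_contextual
        bad = [i for i in self.planted_priority if not 0 <= i < n_chem]
        if bad:
            raise ConfigError(f"planted_priority indices out of range: {bad}")
        if self.planted_priority and (
            self.acc_coverage == 0 and self.endpoint_coverage == 0
        ):
            raise ConfigError(
                "planted priority chemicals need ACC and/or endpoint coverage"
            )
        return self


@dataclass
class GroundTruth:
    """What the generator planted, keyed for downstream verification."""

    detected: set = field(default_factory=set)  # CAS detected in >=1 regular sample
    detected_by_site: dict = field(default_factory=dict)  # site_id -> set of CAS
    benchmarks: dict = field(default_factory=dict)  # CAS -> planted min benchmark µg/L
    min_acc: dict = field(default_factory=dict)  # CAS -> planted min included ACC µM
    priority: set = field(default_factory=set)  # CAS planted to be prioritized
    low_flow_multiplier: float = 1.0
    wwtp_slope: float = 0.0

    def to_jsonable(self) -> dict:
        d = asdict(self)
        d["detected"] = sorted(self.detected)
        d["detected_by_site"] = {k: sorted(v) for k, v in self.detected_by_site.items()}
        d["priority"] = sorted(self.priority)
        return d


def _rng(config: GeneratorConfig, table: str) -> np.random.Generator:
    return np.random.default_rng([int(config.seed), _TABLE_KEYS[table]])


def _make_sites(config: GeneratorConfig) -> pd.DataFrame:
    rng = _rng(config, "sites")
    n = config.n_sites
    lo, hi = config.wwtp_range
    return pd.DataFrame(
        {
            "site_id": [f"S{i + 1:02d}" for i in range(n)],
            "watershed": [f"Watershed_{i % 16 + 1:02d}" for i in range(n)],
            "lake": [_LAKES[i % len(_LAKES)] for i in range(n)],
            "tier": [1 if i < config.n_tier1 else 2 for i in range(n)],
            "wwtp_fraction": rng.uniform(lo, hi, size=n),
            "drainage_km2": np.round(rng.lognormal(6.5, 1.3, size=n), 1),
            "pop_density": np.round(rng.lognormal(4.5, 1.2, size=n), 1),
        }
    )


def _make_catalog(config: GeneratorConfig) -> pd.DataFrame:
    rng = _rng(config, "chemicals")
    n_ph, n_ctx = config.n_pharmaceuticals, config.n_contextual
    n = n_ph + n_ctx
    # panel split mirrors the three-panel catalog shape: ~41% of
    # pharmaceuticals on M1, ~19% on M2neg, the rest on M2pos; contextual
    # chemicals mostly on M1.
    panels = []
    n_m1 = max(1, round(n_ph * 106 / 257))
    n_m2neg = round(n_ph * 48 / 257)
    for i in range(n_ph):
        if i < n_m1:
            panels.append("M1")
        elif i < n_m1 + n_m2neg:
            panels.append("M2neg")
        else:
            panels.append("M2pos")
    for j in range(n_ctx):
        panels.append("M1" if j < max(1, round(n_ctx / 3)) else "M2pos")

    mdl = 10 ** rng.normal(np.log10(32.0), 0.55, size=n)
    mdl = np.clip(mdl, 2.0, 270.0)
    mrl = mdl * rng.uniform(1.5, 3.0, size=n)
    half_life = 10 ** rng.normal(np.log10(6.0), 0.45, size=n)
    half_life[rng.random(n) < 0.3] = np.nan  # no biodegradation estimate
    return pd.DataFrame(
        {
            "cas": [f"{100000 + i}-{10 + i % 90:02d}-{i % 10}" for i in range(n)],
            "name": [f"pharm_{i:03d}" if i < n_ph else f"context_{i - n_ph:02d}" for i in range(n)],
            "class": [
                _CLASSES[i % len(_CLASSES)] if i < n_ph else "Contextual"
                for i in range(n)
            ],
            "is_pharmaceutical": [i < n_ph for i in range(n)],
            "panel": panels,
            "mw_g_mol": rng.uniform(150.0, 500.0, size=n),
            "mrl_ng_l": mrl,
            "mdl_ng_l": mdl,
            "half_life_weeks": half_life,
        }
    )


def _make_samples(config: GeneratorConfig, sites: pd.DataFrame) -> pd.DataFrame:
    rng = _rng(config, "samples")
    n = config.n_sites
    n_m2neg = round(config.m2neg_site_fraction * n)
    n_m2pos = round(config.m2pos_site_fraction * n)
    # panel coverage is nested: every site runs M1; the first n_m2neg also
    # run M2neg; the first n_m2pos of those add M2pos.
    site_panels = {}
    for i, site in enumerate(sites["site_id"]):
        panels = ["M1"]
        if i < n_m2neg:
            panels.append("M2neg")
        if i < n_m2pos:
            panels.append("M2pos")
        site_panels[site] = "|".join(panels)

    tier1_dates = ["2017-11-15", "2018-02-15", "2018-04-15", "2018-07-15"]
    tier2_dates = ["2018-04-20", "2018-07-20"]
    rows = []
    for i, row in sites.iterrows():
        site = row["site_id"]
        base_q = math.exp(math.log(max(row["drainage_km2"], 1.0)) * 0.5)
        if row["tier"] == 1:
            dates, classes = tier1_dates, ["low", "low", "increased", "increased"]
        else:
            dates, classes = tier2_dates, ["low", "increased"]
        classes = list(rng.permutation(classes))
        for k, (date, cls) in enumerate(zip(dates, classes)):
            factor = rng.uniform(0.2, 0.6) if cls == "low" else rng.uniform(1.5, 4.0)
            rows.append(
                {
                    "sample_id": f"{site}-{k + 1}",
                    "site_id": site,
                    "date": date,
                    "discharge": base_q * factor,
                    "qc_type": "regular",
                    "panels": site_panels[site],
                    "_flow_class": cls,
                }
            )
    return pd.DataFrame(rows)


def _draw_concentrations(
    config: GeneratorConfig,
    catalog: pd.DataFrame,
    sites: pd.DataFrame,
    samples: pd.DataFrame,
) -> pd.DataFrame:
    """Long measurement table for regular samples (monitored pairs only)."""
    rng = _rng(config, "concentrations")
    n_chem = len(catalog)
    chem_offset = rng.normal(
        np.log10(config.log_conc_base), config.chem_spread_decades, size=n_chem
    )
    # planted chemicals must be detected broadly: pin their occurrence
    # well above typical reporting limits (hundreds of ng/L)
    for idx in config.planted_priority:
        chem_offset[idx] = 2.7 + rng.uniform(0, 0.5)

    wwtp = sites.set_index("site_id")["wwtp_fraction"]
    sample_site = samples["site_id"].to_numpy()
    site_term = wwtp.loc[sample_site].to_numpy() * config.wwtp_slope
    flow_term = np.where(
        samples["_flow_class"].to_numpy() == "low",
        np.log10(config.low_flow_multiplier),
        0.0,
    )
    n_samp = len(samples)
    noise = rng.normal(0.0, config.sample_sigma_decades, size=(n_samp, n_chem))
    log10_conc = chem_offset[None, :] + (site_term + flow_term)[:, None] + noise
    conc = 10.0 ** log10_conc

    # monitored mask: chemical's panel must be among the sample's panels
    panel_sets = samples["panels"].map(lambda p: set(p.split("|")))
    chem_panel = catalog["panel"].to_numpy()
    mask = np.zeros((n_samp, n_chem), dtype=bool)
    for p in ("M1", "M2neg", "M2pos"):
        ran = panel_sets.map(lambda s, p=p: p in s).to_numpy()
        mask[np.ix_(ran, chem_panel == p)] = True

    samp_idx, chem_idx = np.nonzero(mask)
    values = conc[samp_idx, chem_idx]
    mdl = catalog["mdl_ng_l"].to_numpy()[chem_idx]
    mrl = catalog["mrl_ng_l"].to_numpy()[chem_idx]

    qualifier = np.where(values >= mrl, "detect", "estimate")
    if config.censor_at_mdl:
        below = values < mdl
        qualifier = np.where(below, "nondetect", qualifier)
        values = np.where(below, 0.0, values)
    interference = rng.random(len(values)) < config.interference_rate
    qualifier = np.where(interference, "interference", qualifier)
    values = np.where(interference, np.nan, values)

    return pd.DataFrame(
        {
            "sample_id": samples["sample_id"].to_numpy()[samp_idx],
            "cas": catalog["cas"].to_numpy()[chem_idx],
            "value_ng_l": values,
            "qualifier": qualifier,
        }
    )


def _add_qc_samples(
    config: GeneratorConfig,
    catalog: pd.DataFrame,
    samples: pd.DataFrame,
    measurements: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    rng = _rng(config, "qc")
    sample_rows, meas_frames = [samples], [measurements]
    m1_cas = catalog.loc[catalog["panel"] == "M1", "cas"]

    for b in range(config.n_blanks):
        sid = f"BLANK-{b + 1}"
        host = samples.iloc[int(rng.integers(len(samples)))]
        sample_rows.append(
            pd.DataFrame(
                [
                    {
                        "sample_id": sid,
                        "site_id": host["site_id"],
                        "date": host["date"],
                        "discharge": np.nan,
                        "qc_type": "blank",
                        "panels": "M1",
                        "_flow_class": "",
                    }
                ]
            )
        )
        values = np.zeros(len(m1_cas))
        qualifier = np.full(len(m1_cas), "nondetect", dtype=object)
        if config.blank_detection and b == 0 and len(m1_cas):
            j = int(rng.integers(len(m1_cas)))
            cas = m1_cas.iloc[j]
            row = catalog.set_index("cas").loc[cas]
            # sub-MRL trace, as blank hits typically are
            values[j] = row["mdl_ng_l"] * 1.2
            qualifier[j] = "estimate"
        meas_frames.append(
            pd.DataFrame(
                {
                    "sample_id": sid,
                    "cas": m1_cas.to_numpy(),
                    "value_ng_l": values,
                    "qualifier": qualifier,
                }
            )
        )

    hosts = rng.choice(samples["sample_id"].to_numpy(), size=config.n_duplicates, replace=False)
    for d, host_id in enumerate(hosts):
        host = samples.set_index("sample_id").loc[host_id]
        sid = f"DUP-{d + 1}"
        sample_rows.append(
            pd.DataFrame(
                [
                    {
                        "sample_id": sid,
                        "site_id": host["site_id"],
                        "date": host["date"],
                        "discharge": host["discharge"],
                        "qc_type": "duplicate",
                        "panels": host["panels"],
                        "_flow_class": host["_flow_class"],
                    }
                ]
            )
        )
        base = measurements[measurements["sample_id"] == host_id].copy()
        # analytical repeatability: ~12% per-value noise gives duplicate
        # pair RPDs in the tens of percent
        ratio = 10 ** rng.normal(0.0, 0.05 * np.log(10), size=len(base))
        raw = base["value_ng_l"].to_numpy() * ratio
        cat = catalog.set_index("cas")
        mdl = cat.loc[base["cas"], "mdl_ng_l"].to_numpy()
        mrl = cat.loc[base["cas"], "mrl_ng_l"].to_numpy()
        qualifier = np.where(raw >= mrl, "detect", "estimate")
        if config.censor_at_mdl:
            below = ~(raw >= mdl)
            qualifier = np.where(below, "nondetect", qualifier)
            raw = np.where(below, 0.0, raw)
        keep_interf = base["qualifier"].to_numpy() == "interference"
        qualifier = np.where(keep_interf, "interference", qualifier)
        raw = np.where(keep_interf, np.nan, raw)
        meas_frames.append(
            pd.DataFrame(
                {
                    "sample_id": sid,
                    "cas": base["cas"].to_numpy(),
                    "value_ng_l": raw,
                    "qualifier": qualifier,
                }
            )
        )
    return (
        pd.concat(sample_rows, ignore_index=True),
        pd.concat(meas_frames, ignore_index=True),
    )


def generate_endpoints(
    cas: str,
    target_benchmark: float,
    subset: str = NO_EFFECT,
    species_rich: bool = False,
    half_life_weeks: float | None = None,
    rng: np.random.Generator | None = None,
    n_extra: int = 3,
    decoy_subsets: tuple[str, ...] = (),
) -> pd.DataFrame:
    """Endpoint records whose derived minimum benchmark equals ``target_benchmark``.

    Inverse of the benchmark arithmetic: the primary ``subset`` gets a
    minimum endpoint concentration of ``target * overall_AF`` where the
    overall AF follows from the requested species richness and the
    chemical's persistence; extra records and any ``decoy_subsets`` sit
    strictly above, so the chemical-level minimum benchmark is exactly
    the target.
    """
    if target_benchmark <= 0:
        raise ConfigError("target benchmark must be positive")
    if subset not in SUBSETS:
        raise ConfigError(f"unknown subset {subset!r}")
    rng = rng or np.random.default_rng(0)
    fish = [f"fish_{i:02d}" for i in range(6)]
    inverts = [f"invert_{i:02d}" for i in range(6)]
    plants = [f"plant_{i:02d}" for i in range(3)]

    def subset_rows(sub: str, benchmark: float) -> list[dict]:
        af_end = AF_ENDPOINT[sub]
        af_sp = 1 if species_rich else 2
        af_pers = persistence_af(half_life_weeks, sub)
        min_conc = benchmark * af_end * af_sp * af_pers
        if sub == NO_EFFECT:
            code_pool = [("NOEC", None), ("NOEL", None), ("EC", 10.0), ("LC", 5.0)]
        elif sub == LOW_EFFECT:
            code_pool = [("LOEC", None), ("LOEL", None), ("EC", 25.0), ("LC", 40.0)]
        else:
            code_pool = [("EC", 50.0), ("LC", 50.0)]
        if species_rich:
            species = [(f, "fish") for f in fish[:3]]
            species += [(i, "invertebrate") for i in inverts[:3]]
            species += [(plants[0], "plant")]
        else:
            species = [(fish[0], "fish"), (inverts[0], "invertebrate")]
        n_rows = max(len(species), 1 + n_extra)
        rows = []
        for k in range(n_rows):
            code, level = code_pool[k % len(code_pool)]
            sp, group = species[k % len(species)]
            conc = min_conc if k == 0 else min_conc * rng.uniform(1.5, 50.0)
            rows.append(
                {
                    "cas": cas,
                    "endpoint_code": code,
                    "effect_level": level,
                    "conc_ug_l": conc,
                    "species": sp,
                    "species_group": group,
                    "excluded": False,
                    "exclusion_reason": "",
                }
            )
        return rows

    rows = subset_rows(subset, target_benchmark)
    for decoy in decoy_subsets:
        if decoy == subset:
            continue
        rows += subset_rows(decoy, target_benchmark * rng.uniform(2.0, 10.0))
    # an out-of-scope high-effect record and a flagged-out record, both of
    # which derivation must ignore
    rows.append(
        {
            "cas": cas,
            "endpoint_code": "EC",
            "effect_level": 90.0,
            "conc_ug_l": target_benchmark * 0.01,
            "species": fish[0],
            "species_group": "fish",
            "excluded": False,
            "exclusion_reason": "",
        }
    )
    rows.append(
        {
            "cas": cas,
            "endpoint_code": "NOEC",
            "effect_level": None,
            "conc_ug_l": target_benchmark * 0.001,
            "species": fish[1],
            "species_group": "fish",
            "excluded": True,
            "exclusion_reason": "literature check: unverifiable outlier",
        }
    )
    return pd.DataFrame(rows)


def generate_acc(
    cas: str,
    target_min_acc: float,
    n_assays: int = 5,
    rng: np.random.Generator | None = None,
    decoy_excluded: bool = True,
) -> pd.DataFrame:
    """ACC records whose minimum *included* value equals ``target_min_acc``.

    Remaining included ACCs sit orders of magnitude above the minimum so
    the assay sum stays dominated by the most sensitive assay; an
    optional excluded decoy below the target checks that curation flags
    are honored.
    """
    if target_min_acc <= 0:
        raise ConfigError("target minimum ACC must be positive")
    if n_assays < 1:
        raise ConfigError("need at least one assay")
    rng = rng or np.random.default_rng(0)
    accs = [target_min_acc]
    accs += list(target_min_acc * 10 ** rng.uniform(3.0, 6.0, size=n_assays - 1))
    rows = [
        {
            "cas": cas,
            "assay_id": f"ASSAY_{cas}_{k:03d}",
            "acc_um": acc,
            "included": True,
        }
        for k, acc in enumerate(accs)
    ]
    if decoy_excluded:
        rows.append(
            {
                "cas": cas,
                "assay_id": f"ASSAY_{cas}_X",
                "acc_um": target_min_acc / 10.0,
                "included": False,
            }
        )
    return pd.DataFrame(rows)


def generate_bundle(
    config: GeneratorConfig | None = None,
) -> tuple[StudyBundle, pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Generate a full study bundle plus ACC and endpoint tables.

    Returns
    -------
    (bundle, acc, endpoints, truth)
        ``bundle`` is a validated :class:`StudyBundle`; ``acc`` and
        ``endpoints`` are the screening-value tables; ``truth`` records
        the planted benchmarks, ACC minima, detection sets and priority
        chemicals. Deterministic for a fixed seed.
    """
    config = (config or GeneratorConfig()).validate()
    sites = _make_sites(config)
    catalog = _make_catalog(config)
    samples = _make_samples(config, sites)
    measurements = _draw_concentrations(config, catalog, sites, samples)
    samples, measurements = _add_qc_samples(config, catalog, samples, measurements)
    samples = samples.drop(columns=["_flow_class"])

    bundle = StudyBundle(
        catalog=catalog, sites=sites, samples=samples, measurements=measurements
    ).validate()

    truth = GroundTruth(
        low_flow_multiplier=config.low_flow_multiplier,
        wwtp_slope=config.wwtp_slope,
    )

    # realized detection sets (regular samples only)
    meas = bundle.regular_measurements()
    detected_rows = meas[meas["qualifier"].isin(("detect", "estimate"))]
    site_of = bundle.samples.set_index("sample_id")["site_id"]
    det_with_site = detected_rows.assign(site_id=detected_rows["sample_id"].map(site_of))
    truth.detected = set(detected_rows["cas"].unique())
    truth.detected_by_site = {
        site: set(part["cas"].unique())
        for site, part in det_with_site.groupby("site_id")
    }
    for site in sites["site_id"]:
        truth.detected_by_site.setdefault(site, set())

    pharma = set(catalog.loc[catalog["is_pharmaceutical"], "cas"])
    detected_pharma = sorted(truth.detected & pharma)
    planted_cas = [catalog["cas"].iloc[i] for i in config.planted_priority]
    missing = [c for c in planted_cas if c not in truth.detected]
    if missing:
        raise ConfigError(
            f"planted priority chemicals never detected (infeasible geometry): {missing}"
        )

    # screening-value coverage: planted chemicals carry both value types;
    # the remaining detected pharmaceuticals fill the coverage fractions
    rng_acc = _rng(config, "acc")
    rng_end = _rng(config, "endpoints")
    pool = [c for c in detected_pharma if c not in planted_cas]
    n_acc = max(0, round(config.acc_coverage * len(detected_pharma)) - len(planted_cas))
    n_end = max(0, round(config.endpoint_coverage * len(detected_pharma)) - len(planted_cas))
    acc_extra = list(rng_acc.choice(pool, size=min(n_acc, len(pool)), replace=False)) if pool else []
    n_overlap = min(round(config.benchmark_overlap * n_end), len(acc_extra))
    end_extra = list(rng_end.choice(acc_extra, size=n_overlap, replace=False)) if n_overlap else []
    rest_pool = [c for c in pool if c not in set(acc_extra)]
    n_rest = min(max(n_end - n_overlap, 0), len(rest_pool))
    if n_rest:
        end_extra += list(rng_end.choice(rest_pool, size=n_rest, replace=False))
    acc_cas = (planted_cas if config.acc_coverage > 0 else []) + acc_extra
    end_cas = (planted_cas if config.endpoint_coverage > 0 else []) + end_extra

    # site-level maximum curated concentrations drive the planted targets
    cat_idx = catalog.set_index("cas")
    site_max_ng_l = (
        det_with_site.groupby(["cas", "site_id"])["curated_ng_l"].max()
        if len(det_with_site)
        else pd.Series(dtype=float)
    )
    monitored_counts = bundle.sites_monitored_count()

    def plant_target_ng_l(cas: str, planted: bool) -> float:
        maxima = (
            site_max_ng_l.loc[cas].to_numpy()
            if cas in site_max_ng_l.index.get_level_values(0)
            else np.array([])
        )
        if planted:
            n_mon = int(monitored_counts[cas])
            k = max(1, math.ceil(config.plant_exceed_fraction * n_mon))
            if len(maxima) < k or np.sort(maxima)[-k] <= 0:
                raise ConfigError(
                    f"planted chemical {cas} detected at fewer than {k} sites"
                )
            return float(np.sort(maxima)[-k])
        return float(maxima.max()) if len(maxima) else np.nan

    acc_frames = []
    for cas in acc_cas:
        planted = cas in planted_cas
        c_ng_l = plant_target_ng_l(cas, planted)
        mw = cat_idx.loc[cas, "mw_g_mol"]
        c_um = c_ng_l / (1000.0 * mw)
        if planted:
            # the k-th ranked site hits EAR = margin * threshold exactly
            target = c_um / (config.plant_margin * config.ear_threshold)
        else:
            # even the study maximum stays a margin below threshold
            target = c_um * config.plant_margin / config.ear_threshold
        n_assays = int(rng_acc.integers(*config.n_assays_range, endpoint=True))
        acc_frames.append(generate_acc(cas, target, n_assays, rng=rng_acc))
        truth.min_acc[cas] = target
    acc = (
        pd.concat(acc_frames, ignore_index=True)
        if acc_frames
        else pd.DataFrame(columns=["cas", "assay_id", "acc_um", "included"])
    )

    end_frames = []
    for cas in end_cas:
        planted = cas in planted_cas
        c_ng_l = plant_target_ng_l(cas, planted)
        c_ug_l = c_ng_l / 1000.0
        if planted:
            target = c_ug_l / (config.plant_margin * config.tq_threshold)
        else:
            target = c_ug_l * config.plant_margin / config.tq_threshold
        subset = rng_end.choice(SUBSETS, p=[0.5, 0.3, 0.2])
        decoys = tuple(s for s in SUBSETS if s != subset and rng_end.random() < 0.4)
        end_frames.append(
            generate_endpoints(
                cas,
                target,
                subset=subset,
                species_rich=bool(rng_end.random() < 0.4),
                half_life_weeks=cat_idx.loc[cas, "half_life_weeks"],
                rng=rng_end,
                decoy_subsets=decoys,
            )
        )
        truth.benchmarks[cas] = target
    endpoints = (
        pd.concat(end_frames, ignore_index=True)
        if end_frames
        else pd.DataFrame(
            columns=[
                "cas",
                "endpoint_code",
                "effect_level",
                "conc_ug_l",
                "species",
                "species_group",
                "excluded",
                "exclusion_reason",
            ]
        )
    )

    truth.priority = set(planted_cas)
    return bundle, acc, endpoints, truth
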