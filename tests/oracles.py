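"""Independent brute-force reference implementations used as test oracles.

Everything here is written as plain loops over rows, independently of the
library's vectorized paths, so the two can disagree.
"""

import math

import numpy as np


def classify_brute(code, level):
    code = str(code).upper()
    if code in ("NOEC", "NOEL"):
        return "NoEffect"
    if code in ("LOEC", "LOEL"):
        return "LowEffect"
    if code in ("EC", "LC"):
        x = float(level)
        if x <= 10:
            return "NoEffect"
        if x < 50:
            return "LowEffect"
        if x == 50:
            return "AcuteEffect"
        return None
    return None


def benchmarks_brute(endpoint_rows, half_life_weeks):
    """Min-over-subset benchmark computation by explicit looping.

    ``endpoint_rows``: iterable of dicts with endpoint_code, effect_level,
    conc_ug_l, species, species_group, excluded. Returns
    {subset: (min_conc, af_end, af_sp, af_pers, benchmark)}.
    """
    subsets = {}
    for row in endpoint_rows:
        if row.get("excluded"):
            continue
        label = classify_brute(row["endpoint_code"], row.get("effect_level"))
        if label is None:
            continue
        subsets.setdefault(label, []).append(row)
    out = {}
    for label, rows in subsets.items():
        fish = {r["species"] for r in rows if r["species_group"] == "fish"}
        inv = {r["species"] for r in rows if r["species_group"] == "invertebrate"}
        plant = {r["species"] for r in rows if r["species_group"] == "plant"}
        af_sp = 1 if (len(fish) >= 3 and len(inv) >= 3 and len(plant) >= 1) else 2
        if label == "AcuteEffect":
            af_pers = 1
        elif half_life_weeks is None or (
            isinstance(half_life_weeks, float) and math.isnan(half_life_weeks)
        ):
            af_pers = 5
        else:
            af_pers = 5 if half_life_weeks >= 8 else 1
        af_end = 100 if label == "AcuteEffect" else 10
        min_conc = min(r["conc_ug_l"] for r in rows)
        out[label] = (
            min_conc,
            af_end,
            af_sp,
            af_pers,
            min_conc / (af_end * af_sp * af_pers),
        )
    return out


def sum_ear_brute(ear_rows):
    """{(sample, cas): (sum, count)} by explicit accumulation."""
    out = {}
    for row in ear_rows:
        key = (row["sample_id"], row["cas"])
        s, n = out.get(key, (0.0, 0))
        out[key] = (s + row["ear"], n + 1)
    return out


def site_flags_brute(ear_chem_rows, tq_rows, sample_site, ear_t, tq_t):
    """{(site, cas): (max_ear, max_tq, exceeds_ear, exceeds_tq)}.

    Missing values are represented as None (unavailable).
    """
    max_ear, max_tq = {}, {}
    for row in ear_chem_rows:
        key = (sample_site[row["sample_id"]], row["cas"])
        max_ear[key] = max(max_ear.get(key, -np.inf), row["ear_chem"])
    for row in tq_rows:
        key = (sample_site[row["sample_id"]], row["cas"])
        max_tq[key] = max(max_tq.get(key, -np.inf), row["tq"])
    out = {}
    for key in set(max_ear) | set(max_tq):
        me = max_ear.get(key)
        mt = max_tq.get(key)
        out[key] = (
            me,
            mt,
            None if me is None else me > ear_t,
            None if mt is None else mt > tq_t,
        )
    return out


def priority_brute(flag_dict, monitored_counts, min_fraction):
    """{cas: priority_bool} from the brute-force flags."""
    by_cas = {}
    for (site, cas), (me, mt, ee, et) in flag_dict.items():
        by_cas.setdefault(cas, []).append((ee, et))
    out = {}
    for cas, pairs in by_cas.items():
        n = monitored_counts[cas]
        ear_count = sum(1 for ee, _ in pairs if ee is True)
        tq_count = sum(1 for _, et in pairs if et is True)
        ear_avail = any(ee is not None for ee, _ in pairs)
        tq_avail = any(et is not None for _, et in pairs)
        pri = False
        if ear_avail and ear_count / n >= min_fraction:
            pri = True
        if tq_avail and tq_count / n >= min_fraction:
            pri = True
        out[cas] = pri
    return out


def sum_max_ear_brute(ear_rows):
    """Max EAR per (cas, assay) then sum, by explicit loops."""
    maxima = {}
    for row in ear_rows:
        key = (row["cas"], row["assay_id"])
        maxima[key] = max(maxima.get(key, -np.inf), row["ear"])
    return sum(maxima.values()) if maxima else 0.0


def detection_frequency_brute(bundle):
    """{cas: (n_monitored, n_detected)} from first principles."""
    panel_of = dict(zip(bundle.catalog["cas"], bundle.catalog["panel"]))
    site_of = dict(zip(bundle.samples["sample_id"], bundle.samples["site_id"]))
    regular = set(
        bundle.samples.loc[bundle.samples["qc_type"] == "regular", "sample_id"]
    )
    site_panels = {}
    for _, row in bundle.samples.iterrows():
        if row["sample_id"] not in regular:
            continue
        site_panels.setdefault(row["site_id"], set()).update(row["panels"].split("|"))
    out = {}
    for cas in bundle.catalog["cas"]:
        monitored_sites = {
            s for s in bundle.sites["site_id"] if panel_of[cas] in site_panels.get(s, set())
        }
        detected_sites = set()
        for _, m in bundle.measurements.iterrows():
            if (
                m["cas"] == cas
                and m["sample_id"] in regular
                and m["qualifier"] in ("detect", "estimate")
                and site_of[m["sample_id"]] in monitored_sites
            ):
                detected_sites.add(site_of[m["sample_id"]])
        out[cas] = (len(monitored_sites), len(detected_sites))
    return out
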