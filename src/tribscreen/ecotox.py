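"""Screening-level benchmark derivation from in vivo ecotoxicity endpoints.

Endpoint records (NOEC/NOEL, LOEC/LOEL, ECx/LCx with an effect level x)
are classified into three endpoint subsets:

* *No Effect*   — NOEC/NOEL, or ECx/LCx with x <= 10    (AF_Endpoint = 10)
* *Low Effect*  — LOEC/LOEL, or ECx/LCx with 10 < x < 50 (AF_Endpoint = 10)
* *Acute Effect* — ECx/LCx with x = 50                   (AF_Endpoint = 100)

ECx/LCx endpoints with x > 50 and unrecognized endpoint codes are
excluded: for a minimum-based benchmark that exclusion is conservative.

For each non-empty subset the screening benchmark is

    benchmark = min subset concentration / (AF_Endpoint * AF_Species * AF_Persistence)

where AF_Species is 1 when the subset is well characterized by test
species (at least 3 distinct fish, 3 distinct invertebrate and 1 plant
species) and 2 otherwise, and AF_Persistence is 5 for chemicals with a
biodegradation half-life of 8 weeks or longer and 1 otherwise. The
persistence factor is never applied to the Acute Effect subset (even
nonpersistent chemicals can act in the short term). The chemical-level
benchmark used for toxicity quotients is the minimum over its subset
benchmarks — the most protective value available.

Admissible overall AFs are exactly {10, 20, 50, 100, 200}.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from tribscreen.core import SchemaError

NO_EFFECT = "NoEffect"
LOW_EFFECT = "LowEffect"
ACUTE_EFFECT = "AcuteEffect"
SUBSETS = (NO_EFFECT, LOW_EFFECT, ACUTE_EFFECT)

#: Endpoint-type application factor per subset.
AF_ENDPOINT = {NO_EFFECT: 10, LOW_EFFECT: 10, ACUTE_EFFECT: 100}

#: Codes carrying an effect level x (percent affected).
LEVEL_CODES = ("EC", "LC")
#: Codes classified directly, without an effect level.
PLAIN_CODES = {"NOEC": NO_EFFECT, "NOEL": NO_EFFECT, "LOEC": LOW_EFFECT, "LOEL": LOW_EFFECT}

SPECIES_GROUPS = ("fish", "invertebrate", "plant", "other")

BENCHMARK_COLUMNS = [
    "cas",
    "subset",
    "min_conc_ug_l",
    "af_endpoint",
    "af_species",
    "af_persistence",
    "overall_af",
    "benchmark_ug_l",
]


def classify_endpoint(endpoint_code: str, effect_level: float | None = None) -> str | None:
    """Assign an endpoint record to a subset, or None when excluded.

    Parameters
    ----------
    endpoint_code : str
        One of NOEC, NOEL, LOEC, LOEL, EC, LC (ECx/LCx codes carry their
        level separately).
    effect_level : float, optional
        Percent affected x for ECx/LCx codes; must be absent otherwise.

    Returns
    -------
    str or None
        Subset label, or None for excluded records (x > 50 or an
        unrecognized code).
    """
    code = str(endpoint_code).upper()
    if code in PLAIN_CODES:
        if effect_level is not None and not (
            isinstance(effect_level, float) and np.isnan(effect_level)
        ):
            raise SchemaError(f"{code} endpoints carry no effect level (got {effect_level})")
        return PLAIN_CODES[code]
    if code in LEVEL_CODES:
        if effect_level is None or (
            isinstance(effect_level, float) and np.isnan(effect_level)
        ):
            raise SchemaError(f"{code} endpoint requires an effect level")
        x = float(effect_level)
        if not 0 < x <= 100:
            raise SchemaError(f"effect level must be in (0, 100], got {x}")
        if x <= 10:
            return NO_EFFECT
        if x < 50:
            return LOW_EFFECT
        if x == 50:
            return ACUTE_EFFECT
        return None  # x > 50: excluded, conservative for a minimum
    return None  # unrecognized code: excluded by default


def species_af(species_by_group: Mapping[str, Iterable[str]]) -> int:
    """Species-coverage application factor for one endpoint subset.

    Returns 1 iff the subset holds at least three distinct fish species,
    three distinct invertebrate species, and one plant species; else 2.
    """
    counts = {g: len(set(species_by_group.get(g, ()))) for g in SPECIES_GROUPS}
    well = counts["fish"] >= 3 and counts["invertebrate"] >= 3 and counts["plant"] >= 1
    return 1 if well else 2


def persistence_af(
    half_life_weeks: float | None,
    subset: str,
    persistence_cutoff_weeks: float = 8.0,
    missing_half_life_af: int = 5,
) -> int:
    """Persistence application factor.

    Acute Effect subsets always receive 1. Otherwise chemicals with a
    biodegradation half-life of ``persistence_cutoff_weeks`` (8 weeks) or
    longer are treated as persistent (5); shorter half-lives get 1. A
    missing half-life defaults to the conservative factor
    (``missing_half_life_af``, configurable).
    """
    if subset not in SUBSETS:
        raise SchemaError(f"unknown endpoint subset {subset!r}")
    if subset == ACUTE_EFFECT:
        return 1
    if half_life_weeks is None or (
        isinstance(half_life_weeks, float) and np.isnan(half_life_weeks)
    ):
        return int(missing_half_life_af)
    if half_life_weeks <= 0:
        raise SchemaError(f"half-life must be positive, got {half_life_weeks}")
    return 5 if half_life_weeks >= persistence_cutoff_weeks else 1


def derive_benchmarks(
    endpoints: pd.DataFrame,
    half_life_weeks: float | None = None,
    missing_half_life_af: int = 5,
) -> pd.DataFrame:
    """Derive per-subset benchmarks for a single chemical.

    Parameters
    ----------
    endpoints : DataFrame
        Endpoint records for one chemical (columns ``endpoint_code``,
        ``effect_level``, ``conc_ug_l``, ``species``, ``species_group``,
        optional ``excluded``).
    half_life_weeks : float, optional
        Biodegradation half-life used for the persistence factor.

    Returns
    -------
    DataFrame
        One row per non-empty subset (columns :data:`BENCHMARK_COLUMNS`).
        Empty when no endpoint qualifies — "no benchmark", never 0 or inf.
    """
    rows = []
    if len(endpoints):
        if "excluded" in endpoints.columns:
            endpoints = endpoints[~endpoints["excluded"].fillna(False).astype(bool)]
        if (endpoints["conc_ug_l"] <= 0).any():
            raise SchemaError("endpoint concentrations must be positive")
        levels = (
            endpoints["effect_level"]
            if "effect_level" in endpoints.columns
            else pd.Series(np.nan, index=endpoints.index)
        )
        subsets = [
            classify_endpoint(code, lvl)
            for code, lvl in zip(endpoints["endpoint_code"], levels)
        ]
        endpoints = endpoints.assign(_subset=subsets)
        cas = endpoints["cas"].iloc[0] if "cas" in endpoints.columns and len(endpoints) else ""
        for subset in SUBSETS:
            part = endpoints[endpoints["_subset"] == subset]
            if part.empty:
                continue
            species = {
                g: part.loc[part["species_group"] == g, "species"]
                for g in SPECIES_GROUPS
            }
            af_sp = species_af(species)
            af_pers = persistence_af(
                half_life_weeks, subset, missing_half_life_af=missing_half_life_af
            )
            af_end = AF_ENDPOINT[subset]
            overall = af_end * af_sp * af_pers
            min_conc = float(part["conc_ug_l"].min())
            rows.append(
                {
                    "cas": cas,
                    "subset": subset,
                    "min_conc_ug_l": min_conc,
                    "af_endpoint": af_end,
                    "af_species": af_sp,
                    "af_persistence": af_pers,
                    "overall_af": overall,
                    "benchmark_ug_l": min_conc / overall,
                }
            )
    return pd.DataFrame(rows, columns=BENCHMARK_COLUMNS)


def derive_benchmark_table(
    endpoints: pd.DataFrame,
    catalog: pd.DataFrame | None = None,
    missing_half_life_af: int = 5,
) -> tuple[pd.DataFrame, pd.Series]:
    """Derive benchmarks for every chemical in an endpoint table.

    Parameters
    ----------
    endpoints : DataFrame
        Endpoint records for any number of chemicals.
    catalog : DataFrame, optional
        Chemical catalog supplying ``half_life_weeks`` per CAS; chemicals
        absent from the catalog (or without a half-life) fall back to the
        conservative persistence factor.

    Returns
    -------
    (benchmarks, chemical_minimum)
        ``benchmarks``: one row per chemical x non-empty subset;
        ``chemical_minimum``: Series of the minimum benchmark per CAS
        (µg/L) — chemicals with zero qualifying endpoints are absent.
    """
    half_life = {}
    if catalog is not None and "half_life_weeks" in catalog.columns:
        half_life = catalog.set_index("cas")["half_life_weeks"].to_dict()
    frames = []
    for cas, part in endpoints.groupby("cas", sort=True):
        frames.append(
            derive_benchmarks(
                part,
                half_life.get(cas),
                missing_half_life_af=missing_half_life_af,
            )
        )
    benchmarks = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=BENCHMARK_COLUMNS)
    )
    chem_min = benchmarks.groupby("cas")["benchmark_ug_l"].min()
    chem_min.name = "benchmark_ug_l"
    return benchmarks, chem_min


def enumerate_overall_afs() -> pd.DataFrame:
    """Enumerate every admissible (AF_Endpoint, AF_Species, AF_Persistence) triple.

    Respects the rule that Acute Effect subsets never receive a
    persistence factor. Returns one row per admissible combination with
    the overall AF product; the product set is {10, 20, 50, 100, 200}.
    """
    rows = []
    for subset in SUBSETS:
        af_end = AF_ENDPOINT[subset]
        for af_sp in (1, 2):
            pers_choices = (1,) if subset == ACUTE_EFFECT else (1, 5)
            for af_pers in pers_choices:
                rows.append(
                    {
                        "subset": subset,
                        "af_endpoint": af_end,
                        "af_species": af_sp,
                        "af_persistence": af_pers,
                        "overall_af": af_end * af_sp * af_pers,
                    }
                )
    return pd.DataFrame(rows)
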