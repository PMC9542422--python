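"""Endpoint classification, application factors, and benchmark derivation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import benchmarks_brute
from tribscreen.core import SchemaError
from tribscreen.ecotox import (
    classify_endpoint,
    derive_benchmark_table,
    derive_benchmarks,
    enumerate_overall_afs,
    persistence_af,
    species_af,
)


def endpoint(code, conc, level=None, species="fish_0", group="fish", excluded=False):
    return {
        "cas": "X",
        "endpoint_code": code,
        "effect_level": level,
        "conc_ug_l": conc,
        "species": species,
        "species_group": group,
        "excluded": excluded,
        "exclusion_reason": "",
    }


class TestClassification:
    @pytest.mark.parametrize(
        "code,level,expected",
        [
            ("NOEC", None, "NoEffect"),
            ("NOEL", None, "NoEffect"),
            ("EC", 10.0, "NoEffect"),
            ("EC", 5.0, "NoEffect"),
            ("EC", 25.0, "LowEffect"),
            ("EC", 49.9, "LowEffect"),
            ("LOEC", None, "LowEffect"),
            ("LOEL", None, "LowEffect"),
            ("LC", 50.0, "AcuteEffect"),
            ("EC", 50.0, "AcuteEffect"),
            ("EC", 90.0, None),  # beyond the acute definition: excluded
            ("LC", 51.0, None),
            ("MATC", None, None),  # unrecognized codes are excluded, not guessed
        ],
    )
    def test_subset_assignment(self, code, level, expected):
        assert classify_endpoint(code, level) == expected

    def test_level_required_for_ec_lc(self):
        with pytest.raises(SchemaError):
            classify_endpoint("EC", None)

    def test_level_forbidden_for_noec(self):
        with pytest.raises(SchemaError):
            classify_endpoint("NOEC", 10.0)

    def test_level_out_of_range(self):
        with pytest.raises(SchemaError):
            classify_endpoint("EC", 150.0)


class TestSpeciesAf:
    @pytest.mark.parametrize(
        "fish,inv,plant,expected",
        [(3, 3, 1, 1), (3, 3, 0, 2), (10, 10, 5, 1), (2, 3, 1, 2), (3, 2, 1, 2), (0, 0, 0, 2)],
    )
    def test_well_characterized_rule(self, fish, inv, plant, expected):
        groups = {
            "fish": [f"f{i}" for i in range(fish)],
            "invertebrate": [f"i{i}" for i in range(inv)],
            "plant": [f"p{i}" for i in range(plant)],
        }
        assert species_af(groups) == expected

    def test_duplicate_species_count_once(self):
        groups = {"fish": ["a"] * 5, "invertebrate": ["b", "c", "d"], "plant": ["e"]}
        assert species_af(groups) == 2  # only one distinct fish species


class TestPersistenceAf:
    @pytest.mark.parametrize(
        "half_life,subset,expected",
        [
            (12.0, "NoEffect", 5),
            (4.0, "LowEffect", 1),
            (12.0, "AcuteEffect", 1),  # never applied to acute subsets
            (8.0, "NoEffect", 5),  # boundary: 8 weeks counts as persistent
            (7.99, "NoEffect", 1),
            (None, "NoEffect", 5),  # missing half-life: conservative default
        ],
    )
    def test_rules(self, half_life, subset, expected):
        assert persistence_af(half_life, subset) == expected

    def test_missing_half_life_override(self):
        assert persistence_af(None, "NoEffect", missing_half_life_af=1) == 1


class TestDeriveBenchmarks:
    def test_worked_example(self):
        """Species-poor persistent chemical: NoEffect {100, 50} -> 50/(10*2*5)
        = 0.5 µg/L; an acute 500 µg/L endpoint adds 500/(100*2*1) = 2.5;
        the chemical minimum is 0.5."""
        eps = pd.DataFrame(
            [
                endpoint("NOEC", 100.0),
                endpoint("NOEC", 50.0, species="fish_1"),
                endpoint("LC", 500.0, level=50.0),
            ]
        )
        table = derive_benchmarks(eps, half_life_weeks=12.0)
        by_subset = table.set_index("subset")
        assert by_subset.loc["NoEffect", "benchmark_ug_l"] == pytest.approx(0.5)
        assert by_subset.loc["NoEffect", "overall_af"] == 100
        assert by_subset.loc["AcuteEffect", "benchmark_ug_l"] == pytest.approx(2.5)
        assert by_subset.loc["AcuteEffect", "overall_af"] == 200
        assert table["benchmark_ug_l"].min() == pytest.approx(0.5)

    def test_no_qualifying_endpoints_yield_no_benchmark(self):
        eps = pd.DataFrame([endpoint("EC", 10.0, level=90.0)])  # excluded class
        assert derive_benchmarks(eps, 12.0).empty
        assert derive_benchmarks(eps.iloc[:0], 12.0).empty

    def test_excluded_flag_honored(self):
        eps = pd.DataFrame(
            [endpoint("NOEC", 100.0), endpoint("NOEC", 0.001, excluded=True)]
        )
        table = derive_benchmarks(eps, 4.0)
        assert table["min_conc_ug_l"].iloc[0] == 100.0

    def test_adding_endpoint_never_increases_benchmark_with_fixed_species(self):
        """With the species-characterization status held fixed (new records
        reuse existing species), an added endpoint can only lower — never
        raise — the chemical benchmark. (A new *species* can legitimately
        raise it by flipping the species factor from 2 to 1.)"""
        rng = np.random.default_rng(11)
        codes = [("NOEC", None), ("LOEC", None), ("EC", 25.0), ("LC", 50.0)]
        species = [("f0", "fish"), ("i0", "invertebrate")]  # fixed, species-poor
        rows = []
        prev = None
        for _ in range(30):
            code, level = codes[rng.integers(len(codes))]
            sp, group = species[rng.integers(len(species))]
            rows.append(endpoint(code, float(rng.uniform(0.1, 1000)), level=level,
                                 species=sp, group=group))
            table = derive_benchmark_table(pd.DataFrame(rows))[1]
            current = table.get("X", np.nan)
            if prev is not None and not np.isnan(prev):
                assert current <= prev + 1e-12
            prev = current

    def test_new_species_can_raise_benchmark_via_species_factor(self):
        """Documented non-monotonicity: completing the 3-fish/3-invert/1-plant
        species set halves the overall AF, raising the benchmark."""
        base = [
            endpoint("NOEC", 100.0, species="f0", group="fish"),
            endpoint("NOEC", 100.0, species="f1", group="fish"),
            endpoint("NOEC", 100.0, species="f2", group="fish"),
            endpoint("NOEC", 100.0, species="i0", group="invertebrate"),
            endpoint("NOEC", 100.0, species="i1", group="invertebrate"),
            endpoint("NOEC", 100.0, species="i2", group="invertebrate"),
        ]
        poor = derive_benchmarks(pd.DataFrame(base), 4.0)["benchmark_ug_l"].min()
        rich = derive_benchmarks(
            pd.DataFrame(base + [endpoint("NOEC", 100.0, species="p0", group="plant")]),
            4.0,
        )["benchmark_ug_l"].min()
        assert rich == pytest.approx(2 * poor)

    @given(k=st.floats(min_value=1e-3, max_value=1e3))
    @settings(max_examples=50, deadline=None)
    def test_scale_equivariance(self, k):
        """Scaling all endpoint concentrations by k scales every benchmark by k."""
        eps = pd.DataFrame(
            [endpoint("NOEC", 100.0), endpoint("LOEC", 30.0), endpoint("EC", 400.0, level=50.0)]
        )
        base = derive_benchmarks(eps, 12.0).set_index("subset")["benchmark_ug_l"]
        scaled_eps = eps.assign(conc_ug_l=eps["conc_ug_l"] * k)
        scaled = derive_benchmarks(scaled_eps, 12.0).set_index("subset")["benchmark_ug_l"]
        for subset in base.index:
            assert scaled[subset] == pytest.approx(base[subset] * k, rel=1e-12)

    def test_matches_brute_force_on_random_fixtures(self):
        rng = np.random.default_rng(5)
        codes = [("NOEC", None), ("NOEL", None), ("LOEC", None), ("LOEL", None),
                 ("EC", 5.0), ("EC", 25.0), ("EC", 50.0), ("LC", 50.0), ("EC", 95.0)]
        for _ in range(50):
            rows = []
            for _ in range(rng.integers(1, 50)):
                code, level = codes[rng.integers(len(codes))]
                rows.append(
                    endpoint(
                        code,
                        float(10 ** rng.uniform(-2, 4)),
                        level=level,
                        species=f"sp{rng.integers(8)}",
                        group=rng.choice(["fish", "invertebrate", "plant", "other"]),
                        excluded=bool(rng.random() < 0.1),
                    )
                )
            half_life = None if rng.random() < 0.3 else float(rng.uniform(1, 20))
            got = derive_benchmarks(pd.DataFrame(rows), half_life).set_index("subset")
            want = benchmarks_brute(rows, half_life)
            assert set(got.index) == set(want)
            for subset, (min_conc, af_e, af_s, af_p, bench) in want.items():
                assert got.loc[subset, "min_conc_ug_l"] == pytest.approx(min_conc)
                assert got.loc[subset, "af_endpoint"] == af_e
                assert got.loc[subset, "af_species"] == af_s
                assert got.loc[subset, "af_persistence"] == af_p
                assert got.loc[subset, "benchmark_ug_l"] == pytest.approx(bench)


class TestAfEnumeration:
    def test_admissible_overall_afs(self):
        table = enumerate_overall_afs()
        assert set(table["overall_af"]) == {10, 20, 50, 100, 200}
        assert table["overall_af"].min() == 10
        assert table["overall_af"].max() == 200
        # acute subsets never receive a persistence factor
        acute = table[table["subset"] == "AcuteEffect"]
        assert (acute["af_persistence"] == 1).all()
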