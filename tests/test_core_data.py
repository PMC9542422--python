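"""Curation rules, detection frequencies, QC operations, and table IO."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import chem, make_bundle, meas, sample, site
from oracles import detection_frequency_brute
from tribscreen.core import (
    IntegrityError,
    SchemaError,
    blank_screen,
    curate_measurement,
    detection_frequency,
    relative_percent_difference,
    sample_panel_sums,
    sum_panel_concentrations,
)
from tribscreen.io import read_tables, write_tables


class TestCuration:
    @pytest.mark.parametrize(
        "value,mdl,mrl,interference,expected",
        [
            (5.0, 13.0, 30.0, "none", ("nondetect", 0.0)),  # below detection limit
            (20.0, 13.0, 30.0, "none", ("estimate", 20.0)),  # between MDL and MRL
            (100.0, 13.0, 30.0, "severe", ("interference", None)),
            (100.0, 13.0, 30.0, "none", ("detect", 100.0)),
            (100.0, 13.0, 30.0, "minor", ("estimate", 100.0)),  # minor downgrades
            (20.0, 13.0, 30.0, "minor", ("estimate", 20.0)),
            (None, 13.0, 30.0, "none", ("nondetect", 0.0)),
            (12.999, 13.0, 30.0, "none", ("nondetect", 0.0)),
            (13.0, 13.0, 30.0, "none", ("estimate", 13.0)),  # at the MDL
            (30.0, 13.0, 30.0, "none", ("detect", 30.0)),  # at the MRL
        ],
    )
    def test_censoring_rules(self, value, mdl, mrl, interference, expected):
        assert curate_measurement(value, mdl, mrl, interference) == expected

    def test_negative_value_rejected(self):
        with pytest.raises(SchemaError):
            curate_measurement(-1.0, 13.0, 30.0)

    def test_nonpositive_limits_rejected(self):
        with pytest.raises(SchemaError):
            curate_measurement(5.0, 0.0, 30.0)

    @given(
        value=st.floats(min_value=0, max_value=1e6),
        mdl=st.floats(min_value=1e-3, max_value=1e3),
        ratio=st.floats(min_value=1.0, max_value=10.0),
    )
    @settings(max_examples=200, deadline=None)
    def test_curation_idempotent(self, value, mdl, ratio):
        """Curating an already-curated value leaves it unchanged."""
        mrl = mdl * ratio
        qual, curated = curate_measurement(value, mdl, mrl)
        qual2, curated2 = curate_measurement(curated, mdl, mrl)
        if qual == "nondetect":
            assert (qual2, curated2) == ("nondetect", 0.0)
        else:
            assert curated2 == curated
            assert qual2 == qual

    @given(
        value=st.floats(min_value=0, max_value=1e4),
        mdl=st.floats(min_value=1e-2, max_value=1e3),
        bump=st.floats(min_value=1.0, max_value=100.0),
    )
    @settings(max_examples=200, deadline=None)
    def test_censoring_monotone_in_mdl(self, value, mdl, bump):
        """Raising the MDL never converts a nondetect into a detection."""
        mrl = 10 * (mdl + bump)
        q1, _ = curate_measurement(value, mdl, mrl)
        q2, _ = curate_measurement(value, mdl + bump, mrl)
        if q1 == "nondetect":
            assert q2 == "nondetect"


class TestDetectionFrequency:
    def test_denominator_is_sites_monitored(self):
        """An M2 chemical monitored at a site subset uses that subset as
        its denominator, not the total site count."""
        bundle = make_bundle(
            [chem("A"), chem("B", panel="M2pos")],
            [site("S1"), site("S2"), site("S3"), site("S4")],
            [
                sample("S1-1", "S1"),
                sample("S2-1", "S2"),
                sample("S3-1", "S3", panels="M1|M2pos"),
                sample("S4-1", "S4", panels="M1|M2pos"),
            ],
            [
                meas("S1-1", "A", 100.0, "detect"),
                meas("S2-1", "A", 0.0, "nondetect"),
                meas("S3-1", "A", 50.0, "detect"),
                meas("S4-1", "A", 0.0, "nondetect"),
                meas("S3-1", "B", 60.0, "detect"),
                meas("S4-1", "B", 70.0, "detect"),
            ],
        )
        freq = detection_frequency(bundle).set_index("cas")
        assert freq.loc["A", "sites_monitored"] == 4
        assert freq.loc["A", "detection_pct"] == 50
        assert freq.loc["B", "sites_monitored"] == 2
        assert freq.loc["B", "detection_pct"] == 100  # 2/2, not 2/4

    def test_unmonitored_chemical_flagged_not_zero(self):
        bundle = make_bundle(
            [chem("A"), chem("B", panel="M2neg")],
            [site("S1")],
            [sample("S1-1", "S1")],
            [meas("S1-1", "A", 100.0, "detect")],
        )
        freq = detection_frequency(bundle).set_index("cas")
        assert freq.loc["B", "sites_monitored"] == 0
        assert np.isnan(freq.loc["B", "detection_pct"])

    def test_matches_brute_force_on_random_fixtures(self):
        rng = np.random.default_rng(42)
        for _ in range(10):
            n_sites, n_chem = rng.integers(2, 8), rng.integers(2, 8)
            chems = [
                chem(f"C{j}", panel=rng.choice(["M1", "M2pos"])) for j in range(n_chem)
            ]
            sites_ = [site(f"S{i}") for i in range(n_sites)]
            samples_, meas_ = [], []
            for i in range(n_sites):
                panels = "M1|M2pos" if rng.random() < 0.5 else "M1"
                sid = f"S{i}-1"
                samples_.append(sample(sid, f"S{i}", panels=panels))
                for c in chems:
                    if c["panel"] in panels.split("|"):
                        detected = rng.random() < 0.5
                        meas_.append(
                            meas(sid, c["cas"], 50.0 if detected else 0.0,
                                 "detect" if detected else "nondetect")
                        )
            bundle = make_bundle(chems, sites_, samples_, meas_)
            got = detection_frequency(bundle).set_index("cas")
            want = detection_frequency_brute(bundle)
            for cas, (n_mon, n_det) in want.items():
                assert got.loc[cas, "sites_monitored"] == n_mon
                assert got.loc[cas, "sites_detected"] == n_det


class TestRpd:
    @pytest.mark.parametrize(
        "a,b,expected",
        [(100.0, 100.0, 0.0), (3.0, 1.0, 100.0), (100.0, 81.0, 2 * 19.0 / 181.0 * 100)],
    )
    def test_values(self, a, b, expected):
        assert relative_percent_difference(a, b) == pytest.approx(expected)
        assert relative_percent_difference(b, a) == pytest.approx(expected)

    def test_two_zeros_undefined(self):
        with pytest.raises(SchemaError):
            relative_percent_difference(0.0, 0.0)


class TestBlankScreen:
    def test_no_blank_detections_empty_report(self, tiny_bundle):
        assert blank_screen(tiny_bundle).empty

    def test_blank_detection_reported_not_adjusted(self):
        bundle = make_bundle(
            [chem("A", mrl=30.0)],
            [site("S1")],
            [sample("S1-1", "S1"), sample("BL-1", "S1", qc="blank")],
            [
                meas("S1-1", "A", 100.0, "detect"),
                meas("BL-1", "A", 10.0, "estimate"),
            ],
        )
        report = blank_screen(bundle)
        assert len(report) == 1
        row = report.iloc[0]
        assert row["n_blank_detections"] == 1
        assert row["max_blank_ng_l"] == 10.0
        assert bool(row["below_mrl"])
        # regular data untouched
        regular = bundle.measurements[bundle.measurements["sample_id"] == "S1-1"]
        assert regular["curated_ng_l"].iloc[0] == 100.0

    def test_counts_multiple_blank_detections(self):
        blanks = [sample(f"BL-{i}", "S1", qc="blank") for i in range(3)]
        bundle = make_bundle(
            [chem("A")],
            [site("S1")],
            [sample("S1-1", "S1")] + blanks,
            [meas("S1-1", "A", 0.0, "nondetect")]
            + [meas(f"BL-{i}", "A", 15.0, "estimate") for i in range(3)],
        )
        assert blank_screen(bundle).iloc[0]["n_blank_detections"] == 3


class TestPanelSums:
    def test_nondetects_contribute_zero(self, tiny_bundle):
        assert sum_panel_concentrations(tiny_bundle, "S1-1", "M1") == 100.0
        assert sum_panel_concentrations(tiny_bundle, "S1-2", "M1") == 70.0
        assert sum_panel_concentrations(tiny_bundle, "S2-2", "M1") == 0.0

    def test_panel_not_run_is_an_error(self, tiny_bundle):
        with pytest.raises(IntegrityError):
            sum_panel_concentrations(tiny_bundle, "S1-1", "M2pos")

    def test_m1_sum_invariant_to_m2_values(self, tiny_bundle):
        """Summing over the M1 panel ignores M2 chemicals entirely."""
        before = sum_panel_concentrations(tiny_bundle, "S2-1", "M1")
        tiny_bundle.measurements.loc[
            tiny_bundle.measurements["cas"] == "C", "curated_ng_l"
        ] *= 100
        after = sum_panel_concentrations(tiny_bundle, "S2-1", "M1")
        assert before == after == 40.0

    def test_additive_over_disjoint_subsets_and_row_order(self):
        rng = np.random.default_rng(3)
        chems = [chem(f"C{j}", panel="M1" if j < 4 else "M2pos") for j in range(8)]
        values = rng.uniform(30, 500, size=8)
        rows = [meas("S1-1", f"C{j}", values[j], "detect") for j in range(8)]
        bundle = make_bundle(
            chems, [site("S1")], [sample("S1-1", "S1", panels="M1|M2pos")], rows
        )
        shuffled = make_bundle(
            chems,
            [site("S1")],
            [sample("S1-1", "S1", panels="M1|M2pos")],
            [rows[i] for i in rng.permutation(8)],
        )
        total_m1 = sum_panel_concentrations(bundle, "S1-1", "M1")
        total_m2 = sum_panel_concentrations(bundle, "S1-1", "M2pos")
        assert total_m1 == pytest.approx(values[:4].sum())
        assert total_m1 + total_m2 == pytest.approx(values.sum())
        assert sum_panel_concentrations(shuffled, "S1-1", "M1") == pytest.approx(total_m1)

    def test_vectorized_sums_match_scalar(self, tiny_bundle):
        sums = sample_panel_sums(tiny_bundle, "M1", pharmaceuticals_only=False)
        for sid in ("S1-1", "S1-2", "S2-1", "S2-2"):
            assert sums[sid] == sum_panel_concentrations(tiny_bundle, sid, "M1")


class TestIo:
    def test_round_trip(self, tmp_path, tiny_bundle):
        write_tables(tiny_bundle, tmp_path)
        back = read_tables(tmp_path)
        assert len(back.catalog) == 3
        assert len(back.measurements) == len(tiny_bundle.measurements)
        assert set(back.samples["sample_id"]) == set(tiny_bundle.samples["sample_id"])

    def test_unknown_cas_is_integrity_error(self):
        with pytest.raises(IntegrityError, match="unknown CAS"):
            make_bundle(
                [chem("A")],
                [site("S1")],
                [sample("S1-1", "S1")],
                [meas("S1-1", "ZZZ", 10.0, "estimate")],
            )

    def test_missing_column_names_the_column(self, tmp_path, tiny_bundle):
        write_tables(tiny_bundle, tmp_path)
        broken = pd.read_csv(tmp_path / "sites.csv").drop(columns=["wwtp_fraction"])
        broken.to_csv(tmp_path / "sites.csv", index=False)
        with pytest.raises(SchemaError, match="wwtp_fraction"):
            read_tables(tmp_path)

    def test_generator_output_round_trips_with_site_count(self, tmp_path, small_bundle):
        bundle, _, _, _ = small_bundle
        write_tables(bundle, tmp_path)
        back = read_tables(tmp_path)
        assert len(back.sites) == 10
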