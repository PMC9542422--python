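import numpy as np
import pandas as pd
import pytest

from tribscreen.core import StudyBundle
from tribscreen.synthetic import GeneratorConfig, generate_bundle


def make_bundle(catalog_rows, site_rows, sample_rows, measurement_rows) -> StudyBundle:
    """Build a validated bundle from lists of row dicts."""
    return StudyBundle(
        catalog=pd.DataFrame(catalog_rows),
        sites=pd.DataFrame(site_rows),
        samples=pd.DataFrame(sample_rows),
        measurements=pd.DataFrame(measurement_rows),
    ).validate()


def chem(cas, panel="M1", mw=200.0, mrl=30.0, mdl=13.0, pharma=True, half_life=None):
    return {
        "cas": cas,
        "name": f"name_{cas}",
        "class": "TestClass",
        "is_pharmaceutical": pharma,
        "panel": panel,
        "mw_g_mol": mw,
        "mrl_ng_l": mrl,
        "mdl_ng_l": mdl,
        "half_life_weeks": half_life,
    }


def site(site_id, wwtp=0.05, tier=2):
    return {
        "site_id": site_id,
        "watershed": "W1",
        "lake": "LakeA",
        "tier": tier,
        "wwtp_fraction": wwtp,
        "drainage_km2": 100.0,
        "pop_density": 50.0,
    }


def sample(sample_id, site_id, panels="M1", qc="regular", discharge=10.0, date="2018-04-15"):
    return {
        "sample_id": sample_id,
        "site_id": site_id,
        "date": date,
        "discharge": discharge,
        "qc_type": qc,
        "panels": panels,
    }


def meas(sample_id, cas, value, qualifier):
    return {"sample_id": sample_id, "cas": cas, "value_ng_l": value, "qualifier": qualifier}


@pytest.fixture
def tiny_bundle():
    """Two sites, three chemicals (one M2pos), simple detections."""
    return make_bundle(
        [chem("A"), chem("B", mw=100.0), chem("C", panel="M2pos")],
        [site("S1", wwtp=0.0), site("S2", wwtp=0.2)],
        [
            sample("S1-1", "S1", discharge=5.0),
            sample("S1-2", "S1", discharge=50.0),
            sample("S2-1", "S2", panels="M1|M2pos", discharge=8.0),
            sample("S2-2", "S2", panels="M1|M2pos", discharge=80.0),
        ],
        [
            meas("S1-1", "A", 100.0, "detect"),
            meas("S1-1", "B", 0.0, "nondetect"),
            meas("S1-2", "A", 50.0, "detect"),
            meas("S1-2", "B", 20.0, "estimate"),
            meas("S2-1", "A", 0.0, "nondetect"),
            meas("S2-1", "B", 40.0, "detect"),
            meas("S2-1", "C", 200.0, "detect"),
            meas("S2-2", "A", 0.0, "nondetect"),
            meas("S2-2", "B", 0.0, "nondetect"),
            meas("S2-2", "C", 15.0, "estimate"),
        ],
    )


@pytest.fixture(scope="session")
def default_bundle():
    """One full-size synthetic bundle shared across read-only tests."""
    return generate_bundle(GeneratorConfig(seed=1))


@pytest.fixture(scope="session")
def small_bundle():
    """A reduced bundle for faster end-to-end tests."""
    cfg = GeneratorConfig(
        seed=7,
        n_sites=10,
        n_tier1=3,
        n_pharmaceuticals=30,
        n_contextual=2,
        planted_priority=(0, 1),
    )
    return generate_bundle(cfg)


def random_rng(seed=0):
    return np.random.default_rng(seed)
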