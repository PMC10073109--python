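import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from methrev.datatypes import AnalysisConfig, BetaMatrix, ProbeManifest, SampleSheet
from methrev.simulate import SimConfig, simulate_methylation_study

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def small_beta() -> BetaMatrix:
    values = pd.DataFrame(
        {
            "s1": [0.10, 0.80, 0.50, np.nan],
            "s2": [0.15, 0.85, 0.55, 0.40],
            "s3": [0.90, 0.10, 0.45, 0.35],
            "s4": [0.95, 0.20, 0.60, 0.30],
        },
        index=pd.Index(["cg01", "cg02", "cg03", "cg04"], name="probe_id"),
    )
    return BetaMatrix(values)


@pytest.fixture
def small_manifest() -> ProbeManifest:
    table = pd.DataFrame(
        {
            "chromosome": ["chr1", "chrX", "chr2", "chr3"],
            "position": [100, 200, 300, 400],
            "snp_in_last_10_bases": [False, False, True, False],
        },
        index=pd.Index(["cg01", "cg02", "cg03", "cg04"], name="probe_id"),
    )
    return ProbeManifest(table)


@pytest.fixture
def two_group_sheet() -> SampleSheet:
    table = pd.DataFrame(
        {"group": ["tumor", "tumor", "normal", "normal"], "study": ["s"] * 4},
        index=pd.Index(["s1", "s2", "s3", "s4"], name="sample_id"),
    )
    return SampleSheet(table)


@pytest.fixture(scope="session")
def default_sim():
    """One default-config synthetic study, shared across tests."""
    return simulate_methylation_study(SimConfig(rng_seed=11))


@pytest.fixture
def default_config() -> AnalysisConfig:
    return AnalysisConfig()
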