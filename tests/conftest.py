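import pytest
from hypothesis import HealthCheck, settings

from bilescreen import bile_chem, pipeline
from bilescreen.synthetic_data import PanelConfig

settings.register_profile(
    "ci", derandomize=True,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def cores():
    return {c.abbreviation: c for c in bile_chem.build_core_registry()}


@pytest.fixture(scope="session")
def amino_acids():
    return {a.name: a for a in bile_chem.build_amino_acid_registry()}


@pytest.fixture(scope="session")
def conjugates():
    return bile_chem.enumerate_conjugates()


@pytest.fixture(scope="session")
def conjugate_lib(conjugates):
    return bile_chem.library_frame(conjugates)


@pytest.fixture(scope="session")
def small_result():
    """One small end-to-end run shared by fast integration checks."""
    cfg = pipeline.RunConfig(
        panel=PanelConfig(n_strains=8, decoys_per_strain=40))
    return pipeline.run_pipeline(cfg, seed=11)
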