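import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from membranome import AnalysisConfig, SynthConfig, generate_dataset


@pytest.fixture
def config() -> AnalysisConfig:
    return AnalysisConfig()


@pytest.fixture(scope="session")
def small_dataset():
    """A small noisy synthetic experiment shared across tests."""
    cfg = SynthConfig(seed=7, n_proteins=80)
    return cfg, *generate_dataset(cfg)


@pytest.fixture
def psm_tsv(tmp_path):
    """Write a small well-formed PSM table and return its path."""

    def _write(rows, header="peptide\tcharge\txcorr\tprobability\taccession"):
        path = tmp_path / "psms.tsv"
        path.write_text("\n".join([header, *rows]) + "\n", encoding="utf-8")
        return path

    return _write


@pytest.fixture
def protein_tsv(tmp_path):
    def _write(rows, header="accession\tdescription\tscore\thits"):
        path = tmp_path / "proteins.tsv"
        path.write_text("\n".join([header, *rows]) + "\n", encoding="utf-8")
        return path

    return _write
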