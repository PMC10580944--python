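import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture()
def write_fasta(tmp_path):
    """Write a FASTA file into tmp_path and return its path."""

    def _write(text: str, name: str = "genome.fasta"):
        p = tmp_path / name
        p.write_text(text)
        return p

    return _write


@pytest.fixture(scope="session")
def default_chimera():
    """The standard scenario: 40,452 bp GC-0.5764 background, 6 kb GC-0.35 insert."""
    from phagesig import make_chimera

    return make_chimera(seed=7)
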