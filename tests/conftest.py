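import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from ppitriage.corpus_io import SyntheticSpec, generate_synthetic_corpus


@pytest.fixture(scope="session")
def small_synthetic():
    """A compact deterministic corpus shared by feature/pipeline tests."""
    spec = SyntheticSpec(n_docs=60, pos_fraction=0.5, seed=7)
    corpus, parses, mentions = generate_synthetic_corpus(spec)
    return spec, corpus, parses, mentions
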