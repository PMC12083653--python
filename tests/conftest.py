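import pytest

from socialhx.synthgen import CorpusSpec, generate_corpus


@pytest.fixture(scope="session")
def default_corpus():
    """A mid-size noise-free corpus with clean structured fields."""
    spec = CorpusSpec(
        n_notes=2000,
        structured_missing_rate=0.0,
        structured_stale_rate=0.0,
        seed=42,
    )
    return generate_corpus(spec)
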