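import pytest
from hypothesis import HealthCheck, settings

from pdblake import FixtureSpec, make_corpus

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def corpus_factory(tmp_path):
    """Materialize a synthetic corpus in a per-test temp dir."""
    counter = [0]

    def build(**kwargs):
        counter[0] += 1
        out = tmp_path / f"corpus{counter[0]}"
        spec = FixtureSpec(**kwargs)
        return make_corpus(spec, out), spec

    return build
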