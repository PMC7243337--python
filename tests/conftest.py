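import pytest

from telochec import pipeline

ACCEPTANCE_SEED = 11


@pytest.fixture(scope="session")
def analyzed():
    """Session-cached full pipeline runs, keyed by template name."""
    cache = {}

    def run(name: str, seed: int = ACCEPTANCE_SEED, **kw):
        key = (name, seed, tuple(sorted(kw.items())))
        if key not in cache:
            cache[key] = pipeline.analyze_template(name, seed=seed, **kw)
        return cache[key]

    return run
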