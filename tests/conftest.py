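import pytest

from rxnsa.fixtures import FixtureSpec, generate_reaction_corpus


@pytest.fixture(scope="session")
def clean_corpus():
    """Small layered corpus with no injected noise."""
    spec = FixtureSpec(n_building_blocks=12, depth=3, branching=2,
                       reagent_injection_rate=0.0, duplicate_rate=0.0, seed=7)
    return generate_reaction_corpus(spec)


@pytest.fixture(scope="session")
def noisy_corpus():
    """~1000-reaction depth-3 corpus with misfiled reagents and duplicates."""
    spec = FixtureSpec(n_building_blocks=72, depth=3, branching=2,
                       reagent_injection_rate=0.5, duplicate_rate=0.1, seed=11)
    return generate_reaction_corpus(spec)


@pytest.fixture(scope="session")
def noisy_report(noisy_corpus):
    from rxnsa.fixtures import verify_pipeline_against_truth

    lines, truth = noisy_corpus
    return verify_pipeline_against_truth(lines, truth)


@pytest.fixture(scope="session")
def clean_report(clean_corpus):
    from rxnsa.fixtures import verify_pipeline_against_truth

    lines, truth = clean_corpus
    return verify_pipeline_against_truth(lines, truth)
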