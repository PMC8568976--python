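import pytest

from foodsignal.synthetic import GeneratorConfig, WorkerProfile, generate_corpus, simulate_workers


@pytest.fixture(scope="session")
def small_corpus():
    """A 60-tweet corpus with planted gold labels."""
    return generate_corpus(GeneratorConfig(n_tweets=60, seed=11))


@pytest.fixture(scope="session")
def noisy_crowd(small_corpus):
    """Five workers on the small corpus: four mildly noisy, one spammer."""
    _, golds = small_corpus
    profiles = [WorkerProfile(score_noise=0.1, token_flip=0.1)] * 4 + [
        WorkerProfile(spammer=True)
    ]
    return simulate_workers(golds, profiles, seed=11)


@pytest.fixture(scope="session")
def trained_model():
    """A dual-task model trained on a small separable corpus (shared across
    tests that only need some trained weights)."""
    from foodsignal.aggregation import split_dataset
    from foodsignal.model import EncoderConfig, TrainConfig, train

    _, golds = generate_corpus(GeneratorConfig(n_tweets=240, seed=21))
    tr, va, _ = split_dataset(golds, seed=21)
    model, log = train(tr, va, EncoderConfig(), TrainConfig(epochs=8, seed=21))
    return model, log, golds
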