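import pytest

from subtypebench.corpus import Corpus, LabeledExample, SubtypeLabel, stratified_split
from subtypebench.synthetic import GeneratorConfig, build_lexicon, generate_corpus


@pytest.fixture(scope="session")
def separable_corpus():
    """200-example corpus with disjoint class vocabularies: linearly separable
    by construction, a keyword classifier is perfect on it."""
    config = GeneratorConfig(
        n_total=200, overlap=0.0, noise_rate=0.0, url_mention_rate=0.1, seed=11
    )
    return generate_corpus(config)


@pytest.fixture(scope="session")
def separable_bundle(separable_corpus):
    corpus, _ = separable_corpus
    return stratified_split(corpus, (0.6, 0.2, 0.2), seed=2)


@pytest.fixture(scope="session")
def lexicon():
    return build_lexicon(seed=11)


@pytest.fixture()
def tiny_corpus():
    """Six hand-written examples, one per class."""
    return Corpus(
        [
            LabeledExample("1", "newborn sleepless overwhelmed", SubtypeLabel.POSTPARTUM),
            LabeledExample("2", "hopeless tired empty weeks", SubtypeLabel.MAJOR),
            LabeledExample("3", "racing thoughts then crash", SubtypeLabel.BIPOLAR),
            LabeledExample("4", "voices telling me things", SubtypeLabel.PSYCHOTIC),
            LabeledExample("5", "great day at the park", SubtypeLabel.NO_DEPRESSION),
            LabeledExample("6", "sleeping all day eating lots", SubtypeLabel.ATYPICAL),
        ]
    )
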