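import pytest

from safescreen import (
    Corpus,
    CorpusSpec,
    Record,
    SafeConfig,
    ScreeningState,
    StoppingConfig,
    generate_corpus,
)
from safescreen.state import IRRELEVANT, RELEVANT


def make_record(i, title="", abstract="", label=IRRELEVANT, year=2000, key=False):
    return Record(
        record_id=f"d{i:03d}",
        title=title,
        abstract=abstract,
        year=year,
        oracle_label=label,
        is_key_paper=key,
    )


@pytest.fixture
def toy_corpus():
    """Six handmade documents: three on a shared topic (relevant), three background."""
    topic = "oxytocin bonding hormone attachment"
    noise = ["taxation policy fiscal revenue", "glacier erosion sediment basalt", "opera libretto soprano aria"]
    records = [
        make_record(0, "oxytocin study", f"{topic} infants", RELEVANT, 1995, key=True),
        make_record(1, "bonding hormone", f"{topic} adults", RELEVANT, 2000),
        make_record(2, "attachment theory", f"{topic} rodents", RELEVANT, 2005),
        make_record(3, "tax report", noise[0], IRRELEVANT, 1998),
        make_record(4, "geology notes", noise[1], IRRELEVANT, 2003),
        make_record(5, "music review", noise[2], IRRELEVANT, 2010),
    ]
    return Corpus(records)


@pytest.fixture
def state_factory():
    """Build a ScreeningState from compact (record_id, phase, label) tuples."""

    def build(entries):
        state = ScreeningState()
        for rid, phase, label in entries:
            state.append(rid, phase, 0, label)
        return state

    return build


@pytest.fixture
def label_only_corpus_factory():
    """Corpora of labeled stub records (no meaningful text) for criteria tests."""

    def build(labels, key_flags=None):
        key_flags = key_flags or [False] * len(labels)
        return Corpus(
            [
                make_record(i, title=f"t{i}", label=lab, key=flag)
                for i, (lab, flag) in enumerate(zip(labels, key_flags))
            ]
        )

    return build


@pytest.fixture(scope="session")
def small_separable_corpus():
    """T=200, 10% prevalence, separable: shared by the faster engine tests."""
    return generate_corpus(CorpusSpec(n_records=200, prevalence=0.10, n_key_papers=2, seed=11))


@pytest.fixture
def fast_config():
    """Small window/phase-1 so engine tests run in seconds on tiny corpora."""
    return SafeConfig(
        stopping=StoppingConfig(window=10, phase1_min=20),
        n_baseline_draws=50,
        seed=5,
    )
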