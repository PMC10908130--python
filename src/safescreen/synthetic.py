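"""Synthetic labeled screening corpora.

The generator emulates the statistical structure a title/abstract screening
corpus presents to a relevance ranker, not natural language: documents are
token streams over a pseudo-word vocabulary, and relevance is carried by a
class topic mixed into a shared background distribution.

Three populations of records exist:

* *main relevant* — tokens mixed from the main relevant topic;
* *hard relevant* — tokens mixed from a divergent topic whose pseudo-words
  share no word unigrams with the main topic, but do share character stems
  with it.  The divergent terms are *ambiguous*: they also occur diffusely
  (at ``ambient_hard_rate``) in irrelevant records, so a word-level model
  learns them as evidence of irrelevance, while a sub-lexical model can
  still connect them to the labeled relevants through their stems — the
  population the model-switching phase exists to find;
* *irrelevant* — background tokens only.

The relevant count is exact (``round(prevalence * n_records)``), not
binomial, so tests and metrics have a known true R.  Key papers are drawn
only from the main relevant population: expert-nominated key papers tend to
sit in the core of a topic, and keeping them out of the hard population
guarantees the model-switching phase has something only it can find.
"""

from __future__ import annotations

import string
from dataclasses import asdict, dataclass, replace

import numpy as np

from .corpus import Corpus, Record
from .state import IRRELEVANT, RELEVANT

_LETTERS = np.array(list(string.ascii_lowercase))


@dataclass(frozen=True)
class CorpusSpec:
    """Parameters of a synthetic screening corpus.

    separability is the odds weight of the class topic in a relevant
    record's token mixture: each token is a topic term with probability
    separability / (1 + separability).  At 0 relevant and irrelevant
    records are lexically indistinguishable; at the default 3.0 (75% topic
    tokens) a TF-IDF model separates the classes almost perfectly —
    the regime the procedure assumes for prioritized screening.
    """

    n_records: int = 1000
    prevalence: float = 0.05
    vocab_size: int = 2000
    n_topic_terms: int = 40
    separability: float = 3.0
    hard_fraction: float = 0.0
    ambient_hard_rate: float = 0.10
    n_key_papers: int = 3
    doc_length_mean: int = 60
    year_range: tuple[int, int] = (1990, 2023)
    missing_abstract_rate: float = 0.0
    duplicate_rate: float = 0.0
    seed: int = 0

    @property
    def n_relevant(self) -> int:
        return int(round(self.prevalence * self.n_records))

    @property
    def n_hard(self) -> int:
        return int(round(self.hard_fraction * self.n_relevant))

    def validate(self) -> None:
        if not 0 < self.prevalence < 1:
            raise ValueError("prevalence must be in (0,1)")
        if self.n_relevant < 1:
            raise ValueError("round(prevalence * n_records) must be >= 1")
        if not 0 <= self.hard_fraction < 1:
            raise ValueError("hard_fraction must be in [0,1)")
        if self.n_key_papers > self.n_relevant - self.n_hard:
            raise ValueError(
                f"n_key_papers={self.n_key_papers} exceeds the "
                f"{self.n_relevant - self.n_hard} non-hard relevant records"
            )
        if not (0 <= self.missing_abstract_rate < 1 and 0 <= self.duplicate_rate < 1):
            raise ValueError("noise rates must be in [0,1)")
        if not 0 <= self.ambient_hard_rate < 1:
            raise ValueError("ambient_hard_rate must be in [0,1)")
        if self.separability < 0:
            raise ValueError("separability must be >= 0")
        if self.year_range[0] > self.year_range[1]:
            raise ValueError("year_range must be (min, max)")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["year_range"] = list(self.year_range)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CorpusSpec":
        d = dict(d)
        if "year_range" in d:
            d["year_range"] = tuple(d["year_range"])
        return cls(**d)


def _random_words(rng: np.random.Generator, n: int, length: int, taken: set[str]) -> list[str]:
    words: list[str] = []
    while len(words) < n:
        w = "".join(rng.choice(_LETTERS, size=length))
        if w not in taken:
            taken.add(w)
            words.append(w)
    return words


def _make_vocabulary(spec: CorpusSpec, rng: np.random.Generator):
    taken: set[str] = set()
    background = _random_words(rng, spec.vocab_size, 7, taken)
    main = _random_words(rng, spec.n_topic_terms, 8, taken)
    # hard-topic terms: keep the 6-char stem of a main term, replace the
    # suffix — a new word unigram, but overlapping character n-grams
    hard: list[str] = []
    for m in main:
        while True:
            w = m[:6] + "".join(rng.choice(_LETTERS, size=2))
            if w not in taken:
                taken.add(w)
                hard.append(w)
                break
    return background, main, hard


def _zipf_weights(n: int) -> np.ndarray:
    w = 1.0 / np.arange(1, n + 1)
    return w / w.sum()


def _make_document(
    rng: np.random.Generator,
    background: list[str],
    bg_weights: np.ndarray,
    topic: list[str] | None,
    topic_weight: float,
    mean_length: int,
) -> tuple[str, str]:
    length = max(12, int(rng.poisson(mean_length)))
    n_topic = int(rng.binomial(length, topic_weight)) if topic else 0
    tokens = list(
        np.concatenate(
            [
                rng.choice(topic, size=n_topic) if n_topic else np.array([], dtype=object),
                rng.choice(background, size=length - n_topic, p=bg_weights),
            ]
        )
    )
    rng.shuffle(tokens)
    return " ".join(tokens[:8]), " ".join(tokens[8:])


def generate_corpus(spec: CorpusSpec, with_populations: bool = False):
    """Generate a labeled corpus; identical spec (incl. seed) → identical corpus.

    With ``with_populations=True`` also returns a mapping of the record-id
    populations the generator planted ({"main", "hard", "key"}), which
    evaluation code needs to ask questions like "did the model-switching
    phase find a hard relevant record".
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    background, main, hard = _make_vocabulary(spec, rng)
    bg_weights = _zipf_weights(spec.vocab_size)

    n, R, n_hard = spec.n_records, spec.n_relevant, spec.n_hard
    relevant_pos = rng.choice(n, size=R, replace=False)
    hard_pos = set(rng.choice(relevant_pos, size=n_hard, replace=False).tolist())
    relevant_pos = set(relevant_pos.tolist())
    main_pos = sorted(relevant_pos - hard_pos)
    key_pos = set(rng.choice(main_pos, size=spec.n_key_papers, replace=False).tolist())

    topic_weight = spec.separability / (1.0 + spec.separability)
    # ambiguous divergent terms occur diffusely in irrelevant records too
    ambient = spec.ambient_hard_rate if n_hard > 0 else 0.0
    lo, hi = spec.year_range
    width = len(str(n))
    records: list[Record] = []
    for i in range(n):
        if i in hard_pos:
            topic, weight, label = hard, topic_weight, RELEVANT
        elif i in relevant_pos:
            topic, weight, label = main, topic_weight, RELEVANT
        else:
            topic, weight, label = hard, ambient, IRRELEVANT
        title, abstract = _make_document(
            rng, background, bg_weights, topic, weight, spec.doc_length_mean
        )
        records.append(
            Record(
                record_id=f"r{i:0{width}d}",
                title=title,
                abstract=abstract,
                year=int(rng.integers(lo, hi + 1)),
                oracle_label=label,
                is_key_paper=i in key_pos,
            )
        )
    corpus = Corpus(records)
    if spec.missing_abstract_rate > 0 or spec.duplicate_rate > 0:
        corpus = inject_noise(
            corpus, spec.missing_abstract_rate, spec.duplicate_rate, seed=spec.seed + 1
        )
    if with_populations:
        rid = lambda i: f"r{i:0{width}d}"
        populations = {
            "main": {rid(i) for i in main_pos},
            "hard": {rid(i) for i in sorted(hard_pos)},
            "key": {rid(i) for i in sorted(key_pos)},
        }
        return corpus, populations
    return corpus


def inject_noise(
    corpus: Corpus,
    missing_abstract_rate: float = 0.0,
    duplicate_rate: float = 0.0,
    seed: int = 0,
) -> Corpus:
    """Blank abstracts / append exact text duplicates at the given rates.

    Counts are exact (``round(rate * T)``) and the affected records are a
    seeded draw; labels are never touched.  Duplicates copy title/abstract
    and label but get a fresh id and never inherit the key-paper flag.
    """
    if not (0 <= missing_abstract_rate < 1 and 0 <= duplicate_rate < 1):
        raise ValueError("noise rates must be in [0,1)")
    if missing_abstract_rate == 0 and duplicate_rate == 0:
        return corpus
    rng = np.random.default_rng(seed)
    records = list(corpus.records)
    n = len(records)

    n_blank = int(round(missing_abstract_rate * n))
    if n_blank:
        for i in rng.choice(n, size=n_blank, replace=False):
            records[i] = replace(records[i], abstract="")

    n_dup = int(round(duplicate_rate * n))
    if n_dup:
        for j, i in enumerate(rng.choice(n, size=n_dup, replace=False)):
            src = records[i]
            records.append(
                replace(src, record_id=f"{src.record_id}-dup{j}", is_key_paper=False)
            )
    return Corpus(records)
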