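"""Relevance-ranking model families for prioritized screening.

Two structurally different families are provided, matching the two stages
of model use in the screening procedure:

* ``simple_lexical`` — TF-IDF word unigrams with a cheap linear-ish
  classifier (naive Bayes or logistic regression).  Fast enough to refit
  after every label, which is what the active-learning loop does.
* ``alternative`` — a deliberately different inductive bias for the
  model-switching phase: character n-gram TF-IDF reduced by truncated SVD,
  scored by a small multi-layer perceptron.  Sub-lexical features let it
  score records whose word vocabulary does not overlap the labeled
  relevants, which is exactly the failure mode model switching targets.
  It is a deterministic, dependency-free family; users can register their
  own (e.g. a pretrained sentence-embedding model) via the registry.

Scores are monotone relevance scores, not calibrated probabilities — only
the induced order matters.  Rankings are strict total orders: descending
score, ties broken by ascending record id, so permuting the input never
changes the output.
"""

from __future__ import annotations

import warnings
from abc import ABC, abstractmethod
from typing import Callable, Sequence

import numpy as np
from sklearn.decomposition import TruncatedSVD
from sklearn.exceptions import ConvergenceWarning
from sklearn.feature_extraction.text import TfidfVectorizer
from sklearn.linear_model import LogisticRegression
from sklearn.naive_bayes import MultinomialNB
from sklearn.neural_network import MLPClassifier

from .corpus import Corpus, Record
from .state import IRRELEVANT, RELEVANT


class NotFittedError(RuntimeError):
    pass


class RankingModel(ABC):
    """Contract: ``fit`` on both-class labels, then ``rank`` unlabeled records."""

    family: str = "abstract"

    def __init__(self, seed: int = 0):
        self.seed = seed
        self.fitted = False
        self._vectorizer = None
        self._cached_rows: dict[str, int] = {}
        self._X_cache = None

    # -- feature plumbing -------------------------------------------------

    def prepare(self, corpus: Corpus) -> "RankingModel":
        """Fit the (unsupervised) feature extractor once on the whole corpus.

        Optional but recommended inside the screening loop: labels never
        enter the extractor, and caching document features makes per-label
        refits cheap.
        """
        texts = [r.text for r in corpus]
        self._vectorizer = self._build_extractor()
        self._X_cache = self._fit_extractor(texts)
        self._cached_rows = {r.record_id: i for i, r in enumerate(corpus)}
        return self

    def _features(self, records: Sequence[Record]) -> np.ndarray:
        if self._X_cache is not None and all(
            r.record_id in self._cached_rows for r in records
        ):
            idx = [self._cached_rows[r.record_id] for r in records]
            return self._X_cache[idx]
        return self._transform([r.text for r in records])

    # -- model-family hooks -----------------------------------------------

    @abstractmethod
    def _build_extractor(self): ...

    @abstractmethod
    def _fit_extractor(self, texts: list[str]): ...

    @abstractmethod
    def _transform(self, texts: list[str]): ...

    @abstractmethod
    def _fit_classifier(self, X, y: np.ndarray) -> None: ...

    @abstractmethod
    def _scores(self, X) -> np.ndarray: ...

    # -- public API --------------------------------------------------------

    def fit(self, labeled: Sequence[tuple[Record, str]]) -> "RankingModel":
        if not labeled:
            raise ValueError("empty training set")
        labels = {lab for _, lab in labeled}
        for cls in (RELEVANT, IRRELEVANT):
            if cls not in labels:
                raise ValueError(f"training set has no {cls} example")
        records = [r for r, _ in labeled]
        if self._vectorizer is None:
            # standalone use: fit the extractor on the training documents
            self._vectorizer = self._build_extractor()
            X = self._fit_extractor([r.text for r in records])
        else:
            X = self._features(records)
        y = np.array([lab for _, lab in labeled])
        self._fit_classifier(X, y)
        self.fitted = True
        return self

    def rank(self, unlabeled: Sequence[Record]) -> list[tuple[str, float]]:
        """Strict total order over ``unlabeled``, most-likely-relevant first."""
        if not self.fitted:
            raise NotFittedError("rank() requires a fitted model")
        if len(unlabeled) == 0:
            return []
        scores = self._scores(self._features(unlabeled))
        order = sorted(
            zip((r.record_id for r in unlabeled), scores.tolist()),
            key=lambda t: (-t[1], t[0]),
        )
        return order


def _relevant_column(classifier) -> int:
    return list(classifier.classes_).index(RELEVANT)


class SimpleLexicalModel(RankingModel):
    """TF-IDF word unigrams + naive Bayes or logistic regression.

    TF-IDF dialect: lowercased alphanumeric unigram tokens, min document
    frequency 1, smoothed IDF, L2-normalized rows.
    """

    family = "simple_lexical"

    def __init__(self, classifier: str = "naive_bayes", seed: int = 0):
        super().__init__(seed=seed)
        if classifier not in ("naive_bayes", "logistic"):
            raise ValueError(f"unknown classifier {classifier!r}")
        self.classifier_name = classifier
        self._clf = None

    def _build_extractor(self):
        return TfidfVectorizer(
            lowercase=True,
            token_pattern=r"[a-z0-9]+",
            ngram_range=(1, 1),
            min_df=1,
            smooth_idf=True,
            norm="l2",
        )

    def _fit_extractor(self, texts):
        return self._vectorizer.fit_transform(texts)

    def _transform(self, texts):
        return self._vectorizer.transform(texts)

    def _fit_classifier(self, X, y):
        if self.classifier_name == "naive_bayes":
            self._clf = MultinomialNB(alpha=1.0)
        else:
            self._clf = LogisticRegression(
                solver="liblinear", C=1.0, random_state=self.seed
            )
        self._clf.fit(X, y)

    def _scores(self, X):
        return self._clf.predict_proba(X)[:, _relevant_column(self._clf)]


class CharSvdModel(RankingModel):
    """Character n-gram TF-IDF → truncated SVD → small MLP.

    The 3–5 character n-grams give partial credit for shared word stems
    and morphology that word unigrams treat as disjoint vocabulary; the
    SVD compresses them into a dense document embedding and the MLP
    supplies a nonlinear decision surface.  Deterministic under ``seed``.
    """

    family = "alternative"

    def __init__(self, n_components: int = 100, seed: int = 0):
        super().__init__(seed=seed)
        self.n_components = n_components
        self._svd = None
        self._clf = None

    def _build_extractor(self):
        return TfidfVectorizer(
            lowercase=True, analyzer="char_wb", ngram_range=(3, 4), min_df=1
        )

    def _fit_extractor(self, texts):
        X = self._vectorizer.fit_transform(texts)
        k = max(1, min(self.n_components, X.shape[1] - 1, X.shape[0] - 1))
        self._svd = TruncatedSVD(n_components=k, n_iter=4, random_state=self.seed)
        return self._svd.fit_transform(X)

    def _transform(self, texts):
        return self._svd.transform(self._vectorizer.transform(texts))

    def _fit_classifier(self, X, y):
        # heavy weight decay: the embeddings are low-dimensional and the
        # training sets tiny, so without it the MLP latches onto a few
        # high-variance directions and ranking quality collapses
        self._clf = MLPClassifier(
            hidden_layer_sizes=(16,),
            alpha=10.0,
            max_iter=200,
            tol=1e-3,
            n_iter_no_change=5,
            random_state=self.seed,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            self._clf.fit(X, y)

    def _scores(self, X):
        return self._clf.predict_proba(X)[:, _relevant_column(self._clf)]


# -- registry --------------------------------------------------------------

ModelFactory = Callable[..., RankingModel]

_SIMPLE_REGISTRY: dict[str, ModelFactory] = {
    "naive_bayes": lambda seed=0: SimpleLexicalModel("naive_bayes", seed=seed),
    "logistic": lambda seed=0: SimpleLexicalModel("logistic", seed=seed),
}
_ALTERNATIVE_REGISTRY: dict[str, ModelFactory] = {
    "char_svd": lambda seed=0: CharSvdModel(seed=seed),
}


def make_simple_model(classifier: str = "naive_bayes", seed: int = 0) -> RankingModel:
    try:
        return _SIMPLE_REGISTRY[classifier](seed=seed)
    except KeyError:
        raise ValueError(
            f"unknown simple classifier {classifier!r}; known: {sorted(_SIMPLE_REGISTRY)}"
        ) from None


def make_alternative_model(kind: str = "char_svd", seed: int = 0) -> RankingModel:
    try:
        return _ALTERNATIVE_REGISTRY[kind](seed=seed)
    except KeyError:
        raise ValueError(
            f"unknown alternative model {kind!r}; known: {sorted(_ALTERNATIVE_REGISTRY)}"
        ) from None


def register_model_family(name: str, factory: ModelFactory, alternative: bool = True) -> None:
    """Register a user-supplied model family (e.g. a sentence-embedding model)."""
    (_ALTERNATIVE_REGISTRY if alternative else _SIMPLE_REGISTRY)[name] = factory
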