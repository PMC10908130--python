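"""Four-phase screening engine run against a simulated screener.

The procedure:

1. **Screen a random training set** — a stratified (oldest/newest/random
   intermediate by publication year) or purely random sample, continued
   until at least one relevant and one irrelevant label exist; yields the
   prevalence estimate RR_T_hat.
2. **Apply active learning** — a cheap lexical model is refit as labels
   arrive and always presents its top-ranked unscreened record; stops at
   the first record where the four-fold composite rule holds.
3. **Switch models** — a structurally different model re-orders the
   remaining unscreened records to surface relevants the first model's
   inductive bias missed; stops on a phase-scoped consecutive-irrelevant
   window.
4. **Evaluate quality** — an error-free second screener re-screens the
   records excluded so far, prioritized by a simple model trained on
   pseudo-labels (the 10 highest- and 10 lowest-ranked records of the
   final model-switching ranking); any relevant found flips that record's
   final label.  Stops on the same window rule.

The screener in phases 1–3 is an oracle that answers from the corpus
labels, optionally flipping relevant→irrelevant at a configurable
false-negative rate (humans miss roughly 10% of relevant records); the
phase-4 screener is error-free, which is what gives phase 4 something to
recover.  Everything is deterministic given (corpus, config, seed).
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field

import numpy as np

from .corpus import Corpus, Record, ValidationError, validate_corpus
from .estimation import Phase1Result, ceil_fraction
from .metrics import Metrics, compute_metrics, recall_curve
from .models import RankingModel, make_alternative_model, make_simple_model
from .state import IRRELEVANT, RELEVANT, ScreeningState
from .stopping import (
    CriterionResult,
    StoppingConfig,
    consecutive_irrelevant,
    fourfold_composite,
)

_SEED_NAMES = ("phase1", "oracle", "simple_model", "alternative_model", "phase4_model", "baseline")


def derive_seeds(master: int) -> dict[str, int]:
    """Expand one master seed into independent per-component seeds (< 2^31)."""
    children = np.random.SeedSequence(master).spawn(len(_SEED_NAMES))
    return {
        name: int(child.generate_state(1, dtype=np.uint32)[0] % (2**31))
        for name, child in zip(_SEED_NAMES, children)
    }


@dataclass(frozen=True)
class SafeConfig:
    """Run configuration; one ``seed`` reproduces the whole run."""

    stopping: StoppingConfig = field(default_factory=StoppingConfig)
    simple_classifier: str = "naive_bayes"
    alternative_kind: str = "char_svd"
    sampling: str = "stratified"  # or "random"
    oracle_mode: str = "perfect"  # or "noisy"
    false_negative_rate: float = 0.10
    refit_interval: int = 1
    phase4_n_pseudo: int = 10
    seed: int = 0
    required_key_papers: tuple[str, ...] = ()
    waived_key_papers: tuple[str, ...] = ()
    n_baseline_draws: int = 200

    def to_dict(self) -> dict:
        return {
            "stopping": self.stopping.to_dict(),
            "simple_classifier": self.simple_classifier,
            "alternative_kind": self.alternative_kind,
            "sampling": self.sampling,
            "oracle_mode": self.oracle_mode,
            "false_negative_rate": self.false_negative_rate,
            "refit_interval": self.refit_interval,
            "phase4_n_pseudo": self.phase4_n_pseudo,
            "seed": self.seed,
            "required_key_papers": list(self.required_key_papers),
            "waived_key_papers": list(self.waived_key_papers),
            "n_baseline_draws": self.n_baseline_draws,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SafeConfig":
        d = dict(d)
        if "stopping" in d and isinstance(d["stopping"], dict):
            d["stopping"] = StoppingConfig(**d["stopping"])
        for k in ("required_key_papers", "waived_key_papers"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)


class OracleScreener:
    """Simulated screener answering from the corpus oracle labels.

    In ``noisy`` mode a truly relevant record is labeled irrelevant with
    probability ``false_negative_rate``; an irrelevant record is never
    up-flipped.  The flip decision is a deterministic function of (seed,
    record_id), so it does not depend on presentation order.  Flipped ids
    are tracked for diagnostics.
    """

    def __init__(self, mode: str = "perfect", false_negative_rate: float = 0.10, seed: int = 0):
        if mode not in ("perfect", "noisy"):
            raise ValueError(f"unknown oracle mode {mode!r}")
        if not 0 <= false_negative_rate < 1:
            raise ValueError("false_negative_rate must be in [0, 1)")
        self.mode = mode
        self.false_negative_rate = false_negative_rate
        self.seed = seed
        self.flipped_ids: set[str] = set()

    def label(self, record: Record) -> str:
        true = record.oracle_label
        if true is None:
            raise ValueError(f"record {record.record_id!r} has no oracle label")
        if self.mode == "noisy" and true == RELEVANT:
            u = np.random.default_rng(
                [self.seed, zlib.crc32(record.record_id.encode())]
            ).random()
            if u < self.false_negative_rate:
                self.flipped_ids.add(record.record_id)
                return IRRELEVANT
        return true


@dataclass
class SafeResult:
    """Everything a finished run produced."""

    corpus: Corpus
    config: SafeConfig
    state: ScreeningState
    phase1: Phase1Result
    stop_diagnostics: dict[int, CriterionResult]
    phase4_corrections: list[str]
    flipped_ids: set[str]
    warnings: list[str]
    metrics: Metrics

    @property
    def included_ids(self) -> set[str]:
        return self.state.relevant_ids()

    @property
    def excluded_ids(self) -> set[str]:
        finals = self.state.final_labels()
        return {rid for rid, lab in finals.items() if lab == IRRELEVANT}

    def screened_per_phase(self) -> dict[int, int]:
        return {p: len(self.state.entries_in_phase(p)) for p in (1, 2, 3, 4)}

    def to_dict(self) -> dict:
        return {
            "config": self.config.to_dict(),
            "phase1": self.phase1.to_dict(),
            "screened_per_phase": {str(k): v for k, v in self.screened_per_phase().items()},
            "included": sorted(self.included_ids),
            "phase4_corrections": list(self.phase4_corrections),
            "stop_diagnostics": {
                str(p): {"satisfied": c.satisfied, "name": c.name, "diagnostics": c.diagnostics}
                for p, c in self.stop_diagnostics.items()
            },
            "warnings": list(self.warnings),
            "metrics": self.metrics.to_dict(),
        }


# -- phase 1 ---------------------------------------------------------------


def phase1_size(T: int, config: StoppingConfig) -> int:
    """max(phase1_min, ceil(phase1_fraction x T)), capped at a census."""
    return min(T, max(config.phase1_min, ceil_fraction(config.phase1_fraction, T)))


def run_phase1(
    corpus: Corpus,
    config: SafeConfig,
    oracle: OracleScreener,
    sampling: str | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[ScreeningState, Phase1Result]:
    """Screen the random training set and estimate prevalence.

    Stratified mode takes the k oldest and k newest records by year
    (k = ceil(n1/10)) plus seeded random intermediates; records without a
    year are eligible only for the random stratum.  If the n1 records do
    not contain both classes, screening continues with random draws until
    they do (the training set must seed the first model with at least one
    example of each class).
    """
    sampling = sampling or config.sampling
    if sampling not in ("stratified", "random"):
        raise ValueError(f"unknown sampling mode {sampling!r}")
    rng = rng or np.random.default_rng(derive_seeds(config.seed)["phase1"])
    T = corpus.T
    n1 = phase1_size(T, config.stopping)

    if sampling == "stratified":
        k = math.ceil(n1 / 10)
        with_year = [r.record_id for r in sorted(
            (r for r in corpus if r.year is not None),
            key=lambda r: (r.year, r.record_id),
        )]
        k_eff = min(k, len(with_year) // 2)
        oldest = with_year[:k_eff]
        newest = list(reversed(with_year[len(with_year) - k_eff:]))
        chosen = oldest + newest
        remaining = [r.record_id for r in corpus if r.record_id not in set(chosen)]
        n_mid = n1 - len(chosen)
        mid = list(rng.choice(remaining, size=n_mid, replace=False)) if n_mid > 0 else []
        selected = chosen + [str(m) for m in mid]
    else:
        selected = [str(x) for x in rng.choice(
            [r.record_id for r in corpus], size=n1, replace=False
        )]

    state = ScreeningState(rng_seed=config.seed)
    for rid in selected:
        state.append(rid, phase=1, presented_rank=0, label=oracle.label(corpus[rid]))

    # continue with random draws until both classes are present
    labels = {e.label for e in state.log}
    pool = [r.record_id for r in corpus if r.record_id not in state.labeled_ids()]
    rng.shuffle(pool)
    while len(labels) < 2 and pool:
        rid = pool.pop()
        state.append(rid, phase=1, presented_rank=0, label=oracle.label(corpus[rid]))
        labels.add(state.log[-1].label)
    if len(labels) < 2:
        missing = IRRELEVANT if RELEVANT in labels else RELEVANT
        raise ValidationError(
            f"corpus exhausted during the training phase without any {missing} label; "
            "the procedure is undefined on a single-class corpus"
        )

    entries = state.entries_in_phase(1)
    phase1 = Phase1Result.from_counts(
        RR_t=sum(e.label == RELEVANT for e in entries),
        t=len(entries),
        T=T,
        screened_ids=[e.record_id for e in entries],
    )
    return state, phase1


# -- shared ranking loop ---------------------------------------------------


def _labeled_pairs(state: ScreeningState, corpus: Corpus) -> list[tuple[Record, str]]:
    return [(corpus[rid], lab) for rid, lab in state.final_labels().items()]


def _unlabeled(corpus: Corpus, state: ScreeningState) -> list[Record]:
    labeled = state.labeled_ids()
    return [r for r in corpus if r.record_id not in labeled]


def _screening_loop(
    state: ScreeningState,
    corpus: Corpus,
    oracle: OracleScreener,
    model: RankingModel,
    phase: int,
    config: SafeConfig,
    stop_check,
    pool_fn,
    train_fn,
) -> CriterionResult:
    """Present-top / label / check-stop loop shared by phases 2-4.

    ``pool_fn`` yields the records still to screen, ``train_fn`` the
    training pairs for a refit, ``stop_check`` the stopping criterion.
    Returns the stop diagnostics; a census (exhausted pool) is reported,
    not raised.
    """
    queue: list[str] = []
    since_fit = config.refit_interval  # force a fit on the first step
    rank_at_present = 0
    while True:
        pool = pool_fn()
        if not pool:
            last = stop_check()
            return CriterionResult(
                last.satisfied, last.name, {**last.diagnostics, "census": True}
            )
        if since_fit >= config.refit_interval or not queue:
            model.fit(train_fn())
            queue = [rid for rid, _ in model.rank(pool)]
            since_fit = 0
            rank_at_present = 0
        rid = queue.pop(0)
        rank_at_present += 1
        state.append(rid, phase=phase, presented_rank=rank_at_present, label=oracle.label(corpus[rid]))
        since_fit += 1
        result = stop_check()
        if result.satisfied:
            return result


# -- phase 2 ---------------------------------------------------------------


def check_key_papers_present(corpus: Corpus, config: SafeConfig) -> None:
    """Refuse to start active learning if a required key paper is absent.

    The all-key-papers-found condition gates the four-fold rule; a key
    paper that is not in the dataset can never be found, so the rule could
    never fire.  Ids listed in ``waived_key_papers`` are exempt.
    """
    missing = [
        k
        for k in config.required_key_papers
        if k not in corpus and k not in config.waived_key_papers
    ]
    if missing:
        raise ValidationError(
            f"key papers not present in the corpus: {missing}; waive them explicitly "
            "or fix the dataset before screening"
        )


def run_phase2(
    state: ScreeningState,
    corpus: Corpus,
    phase1: Phase1Result,
    config: SafeConfig,
    oracle: OracleScreener,
    model: RankingModel,
) -> CriterionResult:
    """Active learning with the four-fold stopping rule."""
    check_key_papers_present(corpus, config)
    return _screening_loop(
        state,
        corpus,
        oracle,
        model,
        phase=2,
        config=config,
        stop_check=lambda: fourfold_composite(state, corpus, phase1, config.stopping, phase=2),
        pool_fn=lambda: _unlabeled(corpus, state),
        train_fn=lambda: _labeled_pairs(state, corpus),
    )


# -- phase 3 ---------------------------------------------------------------


def run_phase3(
    state: ScreeningState,
    corpus: Corpus,
    config: SafeConfig,
    oracle: OracleScreener,
    model: RankingModel,
) -> tuple[CriterionResult, list[tuple[str, float]]]:
    """Model switching over the remaining unscreened records.

    Returns the stop diagnostics and the *final ranking*: the final
    model's ordering of the records still unscreened when the phase
    stopped (empty at a census), which seeds phase 4's pseudo-labels.
    """
    diag = _screening_loop(
        state,
        corpus,
        oracle,
        model,
        phase=3,
        config=config,
        stop_check=lambda: consecutive_irrelevant(state, config.stopping, phase=3),
        pool_fn=lambda: _unlabeled(corpus, state),
        train_fn=lambda: _labeled_pairs(state, corpus),
    )
    remaining = _unlabeled(corpus, state)
    final_ranking: list[tuple[str, float]] = []
    if remaining:
        model.fit(_labeled_pairs(state, corpus))
        final_ranking = model.rank(remaining)
    return diag, final_ranking


# -- phase 4 ---------------------------------------------------------------


def run_phase4(
    state: ScreeningState,
    corpus: Corpus,
    config: SafeConfig,
    second_oracle: OracleScreener,
    model: RankingModel,
    phase3_ranking: list[tuple[str, float]],
) -> tuple[CriterionResult, list[str], list[str]]:
    """Quality check: re-screen the excluded records with a second screener.

    The prioritizing model is trained on pseudo-labels: the ``n_pseudo``
    highest-ranked records of the final model-switching ranking stand in
    as relevant, the ``n_pseudo`` lowest as irrelevant.  With fewer than
    2 x n_pseudo ranked records the split degrades to halves; with no
    ranking at all (model switching ran to a census) the model falls back
    to the real labels accumulated so far.  Relevant findings are logged
    as corrections that override the earlier exclusion.

    Returns (stop diagnostics, corrected record ids, warnings).
    """
    warnings: list[str] = []
    n = config.phase4_n_pseudo
    if len(phase3_ranking) >= 2:
        if len(phase3_ranking) < 2 * n:
            n_top = math.ceil(len(phase3_ranking) / 2)
            n_bot = len(phase3_ranking) - n_top
            warnings.append(
                f"only {len(phase3_ranking)} ranked records available for pseudo-labels; "
                f"using {n_top} highest / {n_bot} lowest"
            )
        else:
            n_top = n_bot = n
        pseudo = [(corpus[rid], RELEVANT) for rid, _ in phase3_ranking[:n_top]] + [
            (corpus[rid], IRRELEVANT) for rid, _ in phase3_ranking[-n_bot:]
        ]
    else:
        pseudo = []
        warnings.append(
            "no ranking left from the model-switching phase; training the quality-check "
            "model on the accumulated real labels instead of pseudo-labels"
        )

    excluded_at_start = sorted(
        rid for rid, lab in state.final_labels().items() if lab == IRRELEVANT
    )
    corrections: list[str] = []

    def pool_fn():
        labeled4 = {e.record_id for e in state.entries_in_phase(4)}
        return [corpus[rid] for rid in excluded_at_start if rid not in labeled4]

    def train_fn():
        phase4_pairs = [(corpus[e.record_id], e.label) for e in state.entries_in_phase(4)]
        if pseudo:
            return pseudo + phase4_pairs
        return _labeled_pairs(state, corpus)

    class _Recorder:
        def label(self, record: Record) -> str:
            lab = second_oracle.label(record)
            if lab == RELEVANT:
                corrections.append(record.record_id)
            return lab

    diag = _screening_loop(
        state,
        corpus,
        _Recorder(),
        model,
        phase=4,
        config=config,
        stop_check=lambda: consecutive_irrelevant(state, config.stopping, phase=4),
        pool_fn=pool_fn,
        train_fn=train_fn,
    )
    return diag, corrections, warnings


# -- full run --------------------------------------------------------------


def run_safe(corpus: Corpus, config: SafeConfig | None = None) -> SafeResult:
    """Execute all four phases and evaluate the run.

    Fully deterministic given (corpus, config): one master seed expands
    into independent seeds for phase-1 sampling, the screener's errors,
    each model family and the random-screening baseline.
    """
    config = config or SafeConfig()
    validate_corpus(corpus)  # raises on degenerate input; warnings are advisory
    seeds = derive_seeds(config.seed)

    oracle = OracleScreener(config.oracle_mode, config.false_negative_rate, seed=seeds["oracle"])
    second_oracle = OracleScreener("perfect")

    state, phase1 = run_phase1(
        corpus, config, oracle, rng=np.random.default_rng(seeds["phase1"])
    )

    simple = make_simple_model(config.simple_classifier, seed=seeds["simple_model"]).prepare(corpus)
    diag2 = run_phase2(state, corpus, phase1, config, oracle, simple)

    alternative = make_alternative_model(
        config.alternative_kind, seed=seeds["alternative_model"]
    ).prepare(corpus)
    diag3, phase3_ranking = run_phase3(state, corpus, config, oracle, alternative)

    phase4_model = make_simple_model(
        config.simple_classifier, seed=seeds["phase4_model"]
    ).prepare(corpus)
    diag4, corrections, warnings4 = run_phase4(
        state, corpus, config, second_oracle, phase4_model, phase3_ranking
    )

    metrics = compute_metrics(
        state, corpus, n_baseline_draws=config.n_baseline_draws, baseline_seed=seeds["baseline"]
    )
    return SafeResult(
        corpus=corpus,
        config=config,
        state=state,
        phase1=phase1,
        stop_diagnostics={2: diag2, 3: diag3, 4: diag4},
        phase4_corrections=corrections,
        flipped_ids=set(oracle.flipped_ids),
        warnings=list(corpus.validation_report) + warnings4,
        metrics=metrics,
    )
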