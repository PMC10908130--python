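"""Evaluation metrics and report artifacts for a simulated screening run.

The recall curve (cumulative relevant found vs records viewed) is the
run's central diagnostic; from it and the oracle labels come recall at
stop, the loss (missed relevant records), work saved over sampling (WSS),
and a Monte-Carlo random-screening baseline.  PRISMA-style flow counts
summarize the run for reporting.

WSS at the achieved recall is defined as

    WSS = (T - n_viewed) / T - (1 - recall_at_stop)

i.e. the fraction of the dataset left unscreened, penalized by the recall
that was given up.  Screening everything yields WSS <= 0; stopping early
at full recall yields the full savings fraction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING

import numpy as np

from .corpus import Corpus
from .estimation import ceil_fraction
from .state import RELEVANT, ScreeningState

if TYPE_CHECKING:  # pragma: no cover
    from .engine import SafeResult


@dataclass(frozen=True)
class RecallCurve:
    """Points (n_viewed, n_relevant_found), one per screening decision."""

    points: list[tuple[int, int]]

    def __post_init__(self) -> None:
        for i, (v, f) in enumerate(self.points):
            if v != i + 1:
                raise ValueError("n_viewed must increase by exactly 1")
            prev = self.points[i - 1][1] if i else 0
            if f - prev not in (0, 1):
                raise ValueError("n_relevant_found must step by 0 or 1")

    @property
    def n_viewed(self) -> int:
        return len(self.points)

    @property
    def n_found(self) -> int:
        return self.points[-1][1] if self.points else 0

    def viewed_to_reach(self, n_relevant: int) -> int | None:
        """Records viewed when the ``n_relevant``-th relevant was found."""
        if n_relevant <= 0:
            return 0
        for v, f in self.points:
            if f >= n_relevant:
                return v
        return None

    def write_csv(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("n_viewed,n_relevant_found\n")
            for v, f in self.points:
                fh.write(f"{v},{f}\n")


def recall_curve(state: ScreeningState, corpus: Corpus | None = None) -> RecallCurve:
    """Cumulative relevant found per decision, in log order."""
    if len(state) == 0:
        raise ValueError("empty screening log has no recall curve")
    points, cum = [], 0
    for i, e in enumerate(state.log, start=1):
        cum += e.label == RELEVANT
        points.append((i, cum))
    return RecallCurve(points)


@dataclass(frozen=True)
class Metrics:
    recall_at_stop: float
    loss: int  # relevant records never labeled relevant
    wss_at_stop: float
    wss_at_95: float | None  # reported only if recall 0.95 was reached
    screened_total: int
    screened_per_phase: dict[int, int]
    random_baseline_expected_viewed: float
    random_baseline_se: float
    true_R: int
    T: int

    def to_dict(self) -> dict:
        return {
            "recall_at_stop": self.recall_at_stop,
            "loss": self.loss,
            "wss_at_stop": self.wss_at_stop,
            "wss_at_95": self.wss_at_95,
            "screened_total": self.screened_total,
            "screened_per_phase": {str(k): v for k, v in sorted(self.screened_per_phase.items())},
            "random_baseline_expected_viewed": self.random_baseline_expected_viewed,
            "random_baseline_se": self.random_baseline_se,
            "true_R": self.true_R,
            "T": self.T,
        }

    def write_json(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")


def wss(T: int, n_viewed: int, recall: float) -> float:
    return (T - n_viewed) / T - (1.0 - recall)


def random_baseline_viewed(
    T: int, R: int, n_target: int, n_draws: int = 200, seed: int = 0
) -> tuple[float, float]:
    """Monte-Carlo mean (and SE) of records a uniform-random screening order
    views before finding ``n_target`` relevant records out of R in T."""
    if n_target == 0:
        return 0.0, 0.0
    rng = np.random.default_rng(seed)
    draws = np.empty(n_draws)
    labels = np.zeros(T, dtype=bool)
    labels[:R] = True
    for i in range(n_draws):
        perm = rng.permutation(labels)
        draws[i] = np.flatnonzero(perm)[n_target - 1] + 1
    return float(draws.mean()), float(draws.std(ddof=1) / np.sqrt(n_draws))


def compute_metrics(
    state: ScreeningState,
    corpus: Corpus,
    n_baseline_draws: int = 200,
    baseline_seed: int = 0,
) -> Metrics:
    """Evaluate a finished run against the oracle labels."""
    R = corpus.n_relevant
    if R == 0:
        raise ValueError("metrics undefined with zero relevant records")
    true_relevant = corpus.relevant_ids()
    found = state.relevant_ids() & true_relevant
    recall = len(found) / R
    n_viewed = len(state)
    curve = recall_curve(state, corpus)

    wss95: float | None = None
    target95 = ceil_fraction(0.95, R)
    v95 = curve.viewed_to_reach(target95)
    if v95 is not None:
        wss95 = wss(corpus.T, v95, 0.95)

    per_phase: dict[int, int] = {}
    for e in state.log:
        per_phase[e.phase] = per_phase.get(e.phase, 0) + 1

    baseline, se = random_baseline_viewed(
        corpus.T, R, len(found), n_draws=n_baseline_draws, seed=baseline_seed
    )
    return Metrics(
        recall_at_stop=recall,
        loss=R - len(found),
        wss_at_stop=wss(corpus.T, n_viewed, recall),
        wss_at_95=wss95,
        screened_total=n_viewed,
        screened_per_phase=per_phase,
        random_baseline_expected_viewed=baseline,
        random_baseline_se=se,
        true_R=R,
        T=corpus.T,
    )


def prisma_counts(result: "SafeResult") -> dict[str, int]:
    """Flat PRISMA-style flow counts for a completed run.

    ``identified = included + excluded + never_viewed`` by construction;
    phase-4 corrections move records from excluded to included without
    changing totals.
    """
    state, corpus = result.state, result.corpus
    finals = state.final_labels()
    included = sum(1 for lab in finals.values() if lab == RELEVANT)
    excluded = len(finals) - included
    counts = {
        "identified": corpus.T,
        "screened": len(finals),
        "included": included,
        "excluded": excluded,
        "never_viewed": corpus.T - len(finals),
        "phase4_corrections": len(result.phase4_corrections),
    }
    for phase in (1, 2, 3, 4):
        counts[f"screened_phase{phase}"] = len(state.entries_in_phase(phase))
    return counts


def plot_recall_curve(
    curve: RecallCurve,
    path: str | Path,
    true_R: int | None = None,
    baseline_T: int | None = None,
) -> None:
    """Optional convenience rendering of the recall plot (CSV is the tested artifact)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    xs = [p[0] for p in curve.points]
    ys = [p[1] for p in curve.points]
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.step(xs, ys, where="post", color="0.3", label="prioritized screening")
    if true_R is not None and baseline_T is not None:
        ax.plot(
            [0, baseline_T], [0, true_R], color="tab:blue", ls="--", label="random screening"
        )
    if true_R is not None:
        ax.axhline(true_R, color="tab:red", lw=0.8, ls=":", label="total relevant")
    ax.set_xlabel("records viewed")
    ax.set_ylabel("relevant records found")
    ax.legend(loc="lower right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
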