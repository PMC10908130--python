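"""Composable stopping criteria for prioritized screening.

Each criterion is a pure function of (screening state, corpus, training
estimate, config) returning a ``CriterionResult`` whose diagnostics are
always sufficient to explain the verdict.  The active-learning phase stops
at the first record where the four-fold composite holds:

1. every key paper has been labeled relevant;
2. at least ``rrt_multiplier`` x RR_T_hat records screened (cumulative
   over the training and active-learning phases);
3. at least ``min_fraction`` of the dataset screened (cumulative);
4. the last ``window`` decisions in the current phase were all irrelevant.

All thresholds are configurable — the defaults (50, 10%, 2x, 1%) are
conventional starting points, not universally applicable rules.  The
recall-plateau check is advisory only and never gates stopping by itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Sequence

from .corpus import Corpus
from .estimation import Phase1Result, ceil_fraction
from .state import RELEVANT, ScreeningState

if TYPE_CHECKING:  # pragma: no cover
    from .metrics import RecallCurve


@dataclass(frozen=True)
class CriterionResult:
    satisfied: bool
    name: str
    diagnostics: dict = field(default_factory=dict)

    def __bool__(self) -> bool:
        return self.satisfied


@dataclass(frozen=True)
class StoppingConfig:
    """Thresholds for every stopping rule in the procedure.

    window            consecutive-irrelevant streak length (phase-scoped)
    min_fraction      minimum fraction of the dataset to screen
    rrt_multiplier    multiple of the estimated relevant count to screen
    phase1_fraction   training-set size as a fraction of the dataset
    phase1_min        training-set floor for small datasets
    plateau_window    trailing records for the advisory plateau check
    plateau_slope_max max new-relevant-per-record to call it a plateau
    """

    window: int = 50
    min_fraction: float = 0.10
    rrt_multiplier: float = 2.0
    phase1_fraction: float = 0.01
    phase1_min: int = 50
    plateau_window: int = 100
    plateau_slope_max: float = 0.01

    def __post_init__(self) -> None:
        if self.window < 1:
            raise ValueError("window must be >= 1")
        if not 0 < self.min_fraction <= 1:
            raise ValueError("min_fraction must be in (0, 1]")
        if self.rrt_multiplier <= 0:
            raise ValueError("rrt_multiplier must be > 0")
        if self.phase1_min < 1 or not 0 < self.phase1_fraction <= 1:
            raise ValueError("invalid phase-1 sizing")

    def to_dict(self) -> dict:
        return {
            "window": self.window,
            "min_fraction": self.min_fraction,
            "rrt_multiplier": self.rrt_multiplier,
            "phase1_fraction": self.phase1_fraction,
            "phase1_min": self.phase1_min,
            "plateau_window": self.plateau_window,
            "plateau_slope_max": self.plateau_slope_max,
        }


def key_papers_found(state: ScreeningState, corpus: Corpus) -> CriterionResult:
    """All key papers labeled relevant in the log (vacuously true if none)."""
    key_ids = corpus.key_paper_ids()
    found = state.relevant_ids()
    missing = [k for k in key_ids if k not in found]
    diagnostics: dict = {"n_key_papers": len(key_ids), "missing_key_papers": missing}
    if not key_ids:
        diagnostics["warning"] = "no key papers designated; criterion is vacuous"
    return CriterionResult(not missing, "key_papers_found", diagnostics)


def min_screened_vs_estimate(
    state: ScreeningState, phase1: Phase1Result, config: StoppingConfig
) -> CriterionResult:
    """Cumulative screened (phases 1+2) >= rrt_multiplier x RR_T_hat."""
    screened = state.screened_in_phases((1, 2))
    threshold = config.rrt_multiplier * phase1.RR_T_hat
    return CriterionResult(
        screened >= threshold,
        "min_screened_vs_estimate",
        {
            "screened": screened,
            "RR_T_hat": phase1.RR_T_hat,
            "rrt_multiplier": config.rrt_multiplier,
            "threshold": threshold,
        },
    )


def min_fraction_screened(
    state: ScreeningState, corpus: Corpus, config: StoppingConfig
) -> CriterionResult:
    """Cumulative screened (phases 1+2) >= ceiling(min_fraction x T)."""
    screened = state.screened_in_phases((1, 2))
    threshold = ceil_fraction(config.min_fraction, corpus.T)
    return CriterionResult(
        screened >= threshold,
        "min_fraction_screened",
        {
            "screened": screened,
            "T": corpus.T,
            "min_fraction": config.min_fraction,
            "threshold": threshold,
        },
    )


def consecutive_irrelevant(
    state: ScreeningState, config: StoppingConfig, phase: int
) -> CriterionResult:
    """The last ``window`` decisions within ``phase`` were all irrelevant.

    The streak is scoped to the phase: each phase re-ranks with a different
    model, so a stale streak from an earlier phase never carries over.  A
    relevant find resets the streak; with fewer than ``window`` decisions
    in the phase the criterion cannot hold.
    """
    streak = state.trailing_irrelevant_streak(phase)
    n_in_phase = len(state.entries_in_phase(phase))
    return CriterionResult(
        streak >= config.window,
        "consecutive_irrelevant",
        {
            "streak": streak,
            "window": config.window,
            "phase": phase,
            "screened_in_phase": n_in_phase,
        },
    )


def composite_all(criteria: Sequence[CriterionResult]) -> CriterionResult:
    """Conjunction: satisfied iff every member criterion is satisfied."""
    if not criteria:
        raise ValueError("composite requires at least one criterion")
    return CriterionResult(
        all(c.satisfied for c in criteria),
        "composite_all",
        {
            "members": {
                c.name: {"satisfied": c.satisfied, **c.diagnostics} for c in criteria
            }
        },
    )


def plateau_reached(curve: "RecallCurve", config: StoppingConfig) -> CriterionResult:
    """Advisory: has the recall curve flattened over the trailing window?

    Satisfied iff the trailing ``plateau_window`` decisions yielded at most
    ``plateau_slope_max`` new relevant records per record.  This mirrors
    the visual inspection of a recall plot; it signals that checking the
    real stopping rules is worthwhile, and never gates stopping by itself.
    """
    points = curve.points
    w = config.plateau_window
    if len(points) < w:
        return CriterionResult(
            False,
            "plateau_reached",
            {"n_points": len(points), "plateau_window": w, "reason": "curve shorter than window"},
        )
    # relevant found within the trailing w decisions
    found_before_window = points[-w - 1][1] if len(points) > w else 0
    new_relevant = points[-1][1] - found_before_window
    slope = new_relevant / w
    return CriterionResult(
        slope <= config.plateau_slope_max,
        "plateau_reached",
        {
            "plateau_window": w,
            "new_relevant_in_window": new_relevant,
            "slope": slope,
            "plateau_slope_max": config.plateau_slope_max,
            "advisory": True,
        },
    )


def fourfold_composite(
    state: ScreeningState,
    corpus: Corpus,
    phase1: Phase1Result,
    config: StoppingConfig,
    phase: int = 2,
) -> CriterionResult:
    """The four-fold active-learning stopping rule as a single composite."""
    return composite_all(
        [
            key_papers_found(state, corpus),
            min_screened_vs_estimate(state, phase1, config),
            min_fraction_screened(state, corpus, config),
            consecutive_irrelevant(state, config, phase),
        ]
    )
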