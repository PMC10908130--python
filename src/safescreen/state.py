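"""Screening trajectory shared across phases.

The screening log is the central artifact of a simulated review: an
append-only sequence of labeling decisions, each tagged with the phase that
produced it and the rank at which the record was presented.  Every stopping
criterion, the recall curve and the final PRISMA counts are pure functions
of this log plus the corpus.
"""

from __future__ import annotations

from dataclasses import dataclass, field

RELEVANT = "relevant"
IRRELEVANT = "irrelevant"
LABELS = (RELEVANT, IRRELEVANT)


@dataclass(frozen=True)
class LogEntry:
    step: int  # 1-based position in the log
    record_id: str
    phase: int  # 1..4
    presented_rank: int  # rank at which the model presented the record
    label: str  # label assigned by the (possibly noisy) screener


@dataclass
class ScreeningState:
    """Append-only log of screening decisions plus derived counters.

    Phases 1-3 each label previously-unseen records; phase 4 re-screens
    records that were labeled irrelevant earlier, and a relevant phase-4
    decision overrides the earlier label (a "correction").
    """

    log: list[LogEntry] = field(default_factory=list)
    rng_seed: int | None = None

    def __post_init__(self) -> None:
        self._final: dict[str, str] = {}
        for e in self.log:
            self._final[e.record_id] = e.label

    def append(self, record_id: str, phase: int, presented_rank: int, label: str) -> LogEntry:
        if label not in LABELS:
            raise ValueError(f"unknown label {label!r}")
        if phase in (1, 2, 3) and record_id in self._final:
            raise ValueError(f"record {record_id!r} already labeled (phases 1-3 never repeat)")
        if phase == 4 and self._final.get(record_id) != IRRELEVANT:
            raise ValueError(
                f"phase 4 may only re-screen previously excluded records, got {record_id!r}"
            )
        entry = LogEntry(len(self.log) + 1, record_id, phase, presented_rank, label)
        self.log.append(entry)
        self._final[record_id] = label
        return entry

    # -- derived views ---------------------------------------------------

    def labeled_ids(self) -> set[str]:
        return set(self._final)

    def current_label(self, record_id: str) -> str | None:
        """Latest assigned label (phase-4 corrections override)."""
        return self._final.get(record_id)

    def final_labels(self) -> dict[str, str]:
        return dict(self._final)

    @property
    def found_relevant(self) -> int:
        return sum(1 for e in self.log if e.label == RELEVANT)

    def entries_in_phase(self, phase: int) -> list[LogEntry]:
        return [e for e in self.log if e.phase == phase]

    def screened_in_phases(self, phases: tuple[int, ...]) -> int:
        return sum(1 for e in self.log if e.phase in phases)

    def phase_boundaries(self) -> dict[int, tuple[int, int]]:
        """phase -> (first step, last step), 1-based inclusive."""
        bounds: dict[int, tuple[int, int]] = {}
        for e in self.log:
            lo, hi = bounds.get(e.phase, (e.step, e.step))
            bounds[e.phase] = (min(lo, e.step), max(hi, e.step))
        return bounds

    def trailing_irrelevant_streak(self, phase: int) -> int:
        """Consecutive irrelevant decisions at the tail of the given phase."""
        streak = 0
        for e in reversed(self.entries_in_phase(phase)):
            if e.label == IRRELEVANT:
                streak += 1
            else:
                break
        return streak

    def relevant_ids(self) -> set[str]:
        return {rid for rid, lab in self.final_labels().items() if lab == RELEVANT}

    def __len__(self) -> int:
        return len(self.log)
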