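"""Independent brute-force reference for the stopping rules.

Deliberately implemented with plain loops over (record_id, phase, label)
tuples — no package internals — so it can serve as an oracle for the
criteria implementations and for replaying the engine's stop decisions.
"""

from __future__ import annotations

import math

RELEVANT = "relevant"
IRRELEVANT = "irrelevant"

Entry = tuple[str, int, str]  # (record_id, phase, label)


def final_labels(entries: list[Entry]) -> dict[str, str]:
    out: dict[str, str] = {}
    for rid, _, lab in entries:
        out[rid] = lab
    return out


def brute_key_papers(entries: list[Entry], key_ids: list[str]) -> bool:
    finals = final_labels(entries)
    return all(finals.get(k) == RELEVANT for k in key_ids)


def brute_min_screened_vs_estimate(
    entries: list[Entry], rr_t_hat: int, multiplier: float
) -> bool:
    screened = sum(1 for _, p, _ in entries if p in (1, 2))
    return screened >= multiplier * rr_t_hat


def brute_min_fraction(entries: list[Entry], T: int, min_fraction: float) -> bool:
    screened = sum(1 for _, p, _ in entries if p in (1, 2))
    # ceiling of the exact rational fraction (0.1 * 200 is 20.000000000000004
    # in binary floating point; the rule means exactly 20)
    from fractions import Fraction

    return screened >= math.ceil(Fraction(min_fraction).limit_denominator(10**9) * T)


def brute_streak(entries: list[Entry], phase: int, window: int) -> bool:
    in_phase = [lab for _, p, lab in entries if p == phase]
    if len(in_phase) < window:
        return False
    return all(lab == IRRELEVANT for lab in in_phase[-window:])


def brute_composite(
    entries: list[Entry],
    key_ids: list[str],
    rr_t_hat: int,
    T: int,
    multiplier: float,
    min_fraction: float,
    window: int,
    phase: int = 2,
) -> bool:
    return (
        brute_key_papers(entries, key_ids)
        and brute_min_screened_vs_estimate(entries, rr_t_hat, multiplier)
        and brute_min_fraction(entries, T, min_fraction)
        and brute_streak(entries, phase, window)
    )


def first_composite_step(
    entries: list[Entry],
    key_ids: list[str],
    rr_t_hat: int,
    T: int,
    multiplier: float,
    min_fraction: float,
    window: int,
) -> int | None:
    """1-based step at which the four-fold rule first holds during phase 2."""
    for i in range(1, len(entries) + 1):
        if entries[i - 1][1] != 2:
            continue
        if brute_composite(
            entries[:i], key_ids, rr_t_hat, T, multiplier, min_fraction, window, phase=2
        ):
            return i
    return None


def first_streak_step(entries: list[Entry], phase: int, window: int) -> int | None:
    """1-based step at which the window rule first holds within ``phase``."""
    for i in range(1, len(entries) + 1):
        if entries[i - 1][1] != phase:
            continue
        if brute_streak(entries[:i], phase, window):
            return i
    return None
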