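"""Prevalence estimation from the random training phase.

After screening a random training set of t records of which RR_t were
relevant, the fraction FRR_t = RR_t / t extrapolates to a crude estimate
of the total number of relevant records, RR_T = FRR_t x T.  The estimate
is deliberately rounded *up* (ceiling): it feeds the "screen at least
twice the estimated relevant count" floor of the active-learning stopping
rule, and a conservative procedure must never shrink that floor.

An optional exact hypergeometric upper confidence bound is provided for
users who want a conservative alternative to the point estimate; it is
off by default and nothing in the default procedure consumes it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction

from scipy.stats import hypergeom


@dataclass(frozen=True)
class Phase1Result:
    """Summary of the random training phase."""

    t: int  # training-set size
    RR_t: int  # relevant records found in the training set
    FRR_t: float  # RR_t / t
    RR_T_hat: int  # ceiling(FRR_t * T)
    screened_ids: list[str] = field(default_factory=list)

    @classmethod
    def from_counts(cls, RR_t: int, t: int, T: int, screened_ids: list[str] | None = None):
        return cls(
            t=t,
            RR_t=RR_t,
            FRR_t=estimate_frr(RR_t, t),
            RR_T_hat=-(-RR_t * T) // t,  # integer ceiling of RR_t*T/t
            screened_ids=list(screened_ids or []),
        )

    def to_dict(self) -> dict:
        return {
            "t": self.t,
            "RR_t": self.RR_t,
            "FRR_t": self.FRR_t,
            "RR_T_hat": self.RR_T_hat,
            "screened_ids": list(self.screened_ids),
        }


def ceil_fraction(fraction: float, n: int) -> int:
    """ceil(fraction * n) on the exact rational value of ``fraction``.

    Guards every fraction-of-count threshold against binary-float noise
    (0.07 * 100 is 7.000000000000001, whose naive ceiling is 8).
    """
    return int(math.ceil(Fraction(fraction).limit_denominator(10**9) * n))


def estimate_frr(RR_t: int, t: int) -> float:
    """Fraction of relevant records in the training set, RR_t / t."""
    if t < 1:
        raise ValueError("t must be >= 1")
    if RR_t > t:
        raise ValueError("RR_t cannot exceed t")
    if RR_t < 1:
        raise ValueError(
            "RR_t must be >= 1: the training phase continues until at least one "
            "relevant record is found"
        )
    return RR_t / t


def estimate_total_relevant(FRR_t: float, T: int) -> int:
    """Crude total-relevant estimate: ceiling(FRR_t x T).

    The ceiling is taken on the exact rational value of the fraction
    (``Fraction(FRR_t).limit_denominator``), so a decimal like 0.05 on
    T=10000 yields 500, not the 501 naive binary-float ceiling would give.
    """
    if not 0 < FRR_t <= 1:
        raise ValueError("FRR_t must be in (0, 1]")
    if T < 1:
        raise ValueError("T must be >= 1")
    return ceil_fraction(FRR_t, T)


def upper_bound_relevant(RR_t: int, t: int, T: int, confidence: float = 0.95) -> int:
    """Exact hypergeometric upper confidence bound on the relevant count.

    Largest R such that a simple random sample of t from a population of T
    containing R relevant records would show <= RR_t relevant with
    probability at least 1 - confidence.  Always >= RR_t; at a census
    (t == T) it equals RR_t exactly.  Optional and off by default.
    """
    estimate_frr(RR_t, t)  # validate counts
    if T < t:
        raise ValueError("T must be >= t")
    if not 0 < confidence < 1:
        raise ValueError("confidence must be in (0, 1)")
    if t == T:
        return RR_t
    alpha = 1.0 - confidence
    # P(X <= RR_t; R) is non-increasing in R: binary search the threshold
    lo, hi = RR_t, T - (t - RR_t)  # R can't exceed T minus observed irrelevants
    if hypergeom.cdf(RR_t, T, hi, t) >= alpha:
        return hi
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if hypergeom.cdf(RR_t, T, mid, t) >= alpha:
            lo = mid
        else:
            hi = mid
    return lo
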