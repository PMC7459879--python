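"""Fuzzy-number primitives used by the second segmentation pass.

Two membership shapes are needed: the linear triangular fuzzy number
(background machinery, with its alpha-cut parametric form) and the
L-type fuzzy number whose defuzzified value supplies the dynamic
threshold of segmentation iteration II.

An L-type fuzzy number is flat at membership 1 up to ``alpha``, then
decays linearly to 0 at ``beta``.  Its crisp (defuzzified) value is
obtained by the area-approximation method: the left zone is a rectangle
of width ``alpha`` and height 1, the right zone a triangle of base
``beta - alpha`` and height 1, giving

    D = alpha + (beta - alpha) / 2 = (alpha + beta) / 2.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "TriangularFuzzyNumber",
    "LFuzzyNumber",
    "tfn_membership",
    "tfn_alpha_cut",
    "l_membership",
    "defuzzify",
]


@dataclass(frozen=True)
class TriangularFuzzyNumber:
    """Linear triangular fuzzy number (s1, s2, s3) with s1 <= s2 <= s3."""

    s1: float
    s2: float
    s3: float

    def __post_init__(self) -> None:
        if not (self.s1 <= self.s2 <= self.s3):
            raise ValueError(
                f"require s1 <= s2 <= s3, got ({self.s1}, {self.s2}, {self.s3})"
            )


@dataclass(frozen=True)
class LFuzzyNumber:
    """L-type fuzzy number: membership 1 on (-inf, alpha], 0 on [beta, inf)."""

    alpha: float
    beta: float

    def __post_init__(self) -> None:
        if not (self.alpha <= self.beta):
            raise ValueError(f"require alpha <= beta, got ({self.alpha}, {self.beta})")


def tfn_membership(t: TriangularFuzzyNumber, x: float) -> float:
    """Piecewise-linear triangular membership; 0 outside [s1, s3], 1 at s2."""
    if x < t.s1 or x > t.s3:
        return 0.0
    if x == t.s2:
        return 1.0
    if x < t.s2:
        # s1 < s2 here, otherwise x == s2 was caught above
        return (x - t.s1) / (t.s2 - t.s1)
    return (t.s3 - x) / (t.s3 - t.s2)


def tfn_alpha_cut(t: TriangularFuzzyNumber, a: float) -> tuple[float, float]:
    """Alpha-cut interval [s1 + a(s2-s1), s3 - a(s3-s2)] for a in [0, 1]."""
    if not (0.0 <= a <= 1.0):
        raise ValueError(f"alpha-cut level must be in [0, 1], got {a}")
    lo = t.s1 + a * (t.s2 - t.s1)
    hi = t.s3 - a * (t.s3 - t.s2)
    return (lo, hi)


def l_membership(f: LFuzzyNumber, x: float) -> float:
    """Decreasing L-shape: 1 for x <= alpha, linear ramp down, 0 for x >= beta.

    Degenerate alpha == beta collapses to a step function (1 then 0).
    """
    if x <= f.alpha:
        return 1.0
    if x >= f.beta:
        return 0.0
    return (f.beta - x) / (f.beta - f.alpha)


def defuzzify(f: LFuzzyNumber) -> float:
    """Area-approximation crisp value: rectangle + triangle = (alpha + beta)/2."""
    return (f.alpha + f.beta) / 2.0
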