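"""Combination-treatment synergy against the additive expectation.

Synergy is quantified on 24 h death fractions: the additive expectation
for two agents is the capped sum of their single-treatment death
fractions, and the excess of the combination over that expectation
(as a percentage of it) classifies the combination as synergistic,
additive or antagonistic.  Bliss independence is offered as an
alternative reference for regimes where the capped sum saturates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "SynergyReport",
    "additive_expectation",
    "bliss_expectation",
    "synergy_excess",
    "classify",
    "analyze",
]

#: classification tolerance in percentage points (replicate-noise scale
#: of viability assays)
DEFAULT_TOLERANCE = 5.0


def _check_fraction(x, name):
    if not 0.0 <= x <= 1.0:
        raise ValueError(f"{name} must be a fraction in [0, 1], got {x}")


def additive_expectation(d_a: float, d_b: float) -> float:
    """Capped sum of the two single-treatment death fractions."""
    _check_fraction(d_a, "d_a")
    _check_fraction(d_b, "d_b")
    return min(1.0, d_a + d_b)


def bliss_expectation(d_a: float, d_b: float) -> float:
    """Bliss-independence expectation ``d_a + d_b - d_a*d_b``."""
    _check_fraction(d_a, "d_a")
    _check_fraction(d_b, "d_b")
    return d_a + d_b - d_a * d_b


def synergy_excess(d_combo: float, d_a: float, d_b: float,
                   reference: str = "additive") -> float:
    """Excess of the combination over the expectation, in percent.

    Returns ``inf`` when the expectation is zero but the combination
    kills (infinite-synergy flag).
    """
    _check_fraction(d_combo, "d_combo")
    expect = (additive_expectation(d_a, d_b) if reference == "additive"
              else bliss_expectation(d_a, d_b))
    if expect == 0.0:
        return math.inf if d_combo > 0 else 0.0
    return 100.0 * (d_combo - expect) / expect


def classify(excess: float, tolerance: float = DEFAULT_TOLERANCE) -> str:
    """Synergistic / additive / antagonistic by sign of the excess."""
    if excess > tolerance:
        return "synergistic"
    if excess < -tolerance:
        return "antagonistic"
    return "additive"


@dataclass(frozen=True)
class SynergyReport:
    death_ly30: float
    death_trail: float
    death_combo: float
    additive_expectation: float
    excess_over_additive: float
    classification: str

    def to_dict(self) -> dict:
        return {
            "death_ly30": self.death_ly30,
            "death_trail": self.death_trail,
            "death_combo": self.death_combo,
            "additive_expectation": self.additive_expectation,
            "excess_over_additive_pct": self.excess_over_additive,
            "classification": self.classification,
        }


def analyze(death_ly30: float, death_trail: float, death_combo: float,
            tolerance: float = DEFAULT_TOLERANCE) -> SynergyReport:
    """Full synergy report from the three 24 h death fractions."""
    expect = additive_expectation(death_ly30, death_trail)
    excess = synergy_excess(death_combo, death_ly30, death_trail)
    return SynergyReport(death_ly30, death_trail, death_combo, expect,
                         excess, classify(excess, tolerance))
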