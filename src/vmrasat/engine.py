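"""Maturity classification.

A function's tier is the highest designation tier whose constraints — and
those of every tier below it — are met.  Three algorithms are defined:

strict
    Every applicable sub-indicator designated at or below the candidate tier
    must be Implemented.
flexible
    Per-tier fraction thresholds (floor on Implemented, caps on in-process
    and Not implemented), with all lower tiers fully Implemented except where
    a row pools its denominator with the lower tiers (the WHO ML2 rule).
restricted (restricted flexibility)
    The flexible thresholds, plus every applicable *critical* sub-indicator
    designated at or below the candidate tier must be Implemented.

Threshold comparisons are exact rational arithmetic: a floor of 95% over a
pool of 20 is met by exactly 19 Implemented.  A tier with an empty applicable
pool passes vacuously (consequently an all-not-applicable assessment
classifies to the top tier; real assessments always have applicable items).

The achieved tier carries a qualifier such as ``"Silver (flexible)"``; when
the strict algorithm would reach the same tier, the strict qualifier is
preferred, since it is the stronger statement.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from fractions import Fraction
from typing import Mapping

from .catalog import (
    IMPLEMENTED,
    NOT_APPLICABLE,
    Catalog,
    SubIndicator,
    TierThresholds,
    WHO_FLEXIBLE_ROWS,
)
from .ratings import Assessment, TierTally, tally

__all__ = [
    "UnknownAlgorithmError",
    "Shortfall",
    "check_tier",
    "MaturityResult",
    "InstitutionResult",
    "classify_function",
    "classify_institution",
    "who_flexible_thresholds",
]

logger = logging.getLogger("vmrasat")


class UnknownAlgorithmError(KeyError):
    """The requested algorithm is not defined for the catalog's profile."""


@dataclass(frozen=True)
class Shortfall:
    """One violated constraint: what was required and what was observed."""

    tier: str
    constraint: str
    required: Fraction
    observed: Fraction

    def to_dict(self) -> dict:
        return {
            "tier": self.tier,
            "constraint": self.constraint,
            "required": {"num": self.required.numerator, "den": self.required.denominator},
            "observed": {"num": self.observed.numerator, "den": self.observed.denominator},
        }


def check_tier(
    tally_: TierTally,
    tier: str,
    thresholds: TierThresholds,
    catalog: Catalog,
) -> tuple[bool, list[Shortfall]]:
    """Evaluate one tier's threshold row against a tally.

    Returns (passed, shortfalls).  Fractions are taken over the applicable
    pool (this tier's, or pooled with lower tiers where the row says so); an
    empty pool passes vacuously.
    """
    ladder = catalog.tiers
    shortfalls: list[Shortfall] = []

    if thresholds.lower_tiers_full:
        for lower in ladder.lower_designation_tiers(tier):
            c = tally_.counts[lower]
            if c.applicable and c.implemented != c.applicable:
                shortfalls.append(
                    Shortfall(
                        tier=tier,
                        constraint=f"lower_tier_full:{lower}",
                        required=Fraction(1),
                        observed=Fraction(c.implemented, c.applicable),
                    )
                )

    if thresholds.pooled_with_lower:
        pool = tally_.pooled(ladder.at_most(tier))
    else:
        pool = tally_.counts[tier]

    if pool.applicable:
        a = pool.applicable
        impl = Fraction(pool.implemented, a)
        in_process = Fraction(pool.in_process, a)
        not_impl = Fraction(pool.not_implemented, a)
        if impl < thresholds.min_implemented:
            shortfalls.append(
                Shortfall(tier, "min_implemented", thresholds.min_implemented, impl)
            )
        if in_process > thresholds.max_partial:
            shortfalls.append(
                Shortfall(tier, "max_partial", thresholds.max_partial, in_process)
            )
        if not_impl > thresholds.max_not_implemented:
            shortfalls.append(
                Shortfall(
                    tier, "max_not_implemented", thresholds.max_not_implemented, not_impl
                )
            )

    return (not shortfalls, shortfalls)


@dataclass(frozen=True)
class MaturityResult:
    """Classification of one function under one algorithm."""

    function_code: str
    algorithm: str
    achieved_tier: str
    qualifier: str
    shortfalls: tuple[Shortfall, ...]

    def to_dict(self) -> dict:
        return {
            "function_code": self.function_code,
            "algorithm": self.algorithm,
            "achieved_tier": self.achieved_tier,
            "qualifier": self.qualifier,
            "shortfalls": [s.to_dict() for s in self.shortfalls],
        }


@dataclass(frozen=True)
class InstitutionResult:
    """Institution-level classification: the weakest function bounds the
    institution, further capped by institution-mandatory sub-indicators."""

    algorithm: str
    functions: tuple[MaturityResult, ...]
    institution_tier: str
    mandatory_failures: tuple[str, ...]

    def to_dict(self) -> dict:
        return {
            "algorithm": self.algorithm,
            "institution_tier": self.institution_tier,
            "mandatory_failures": list(self.mandatory_failures),
            "functions": [r.to_dict() for r in self.functions],
        }


def _algorithm(catalog: Catalog, name: str):
    try:
        return catalog.algorithms[name]
    except KeyError:
        raise UnknownAlgorithmError(
            f"algorithm {name!r} is not defined for profile {catalog.profile!r} "
            f"(available: {sorted(catalog.algorithms)})"
        ) from None


def _critical_shortfalls(
    assessment: Assessment,
    subs: tuple[SubIndicator, ...],
    tier: str,
    catalog: Catalog,
) -> list[Shortfall]:
    """Applicable critical sub-indicators at or below *tier* that are not
    Implemented (the restricted-flexibility condition)."""
    allowed = set(catalog.tiers.at_most(tier))
    out = []
    for sub in subs:
        if not sub.critical or sub.designated_tier not in allowed:
            continue
        rating = assessment.rating_of(sub.sub_id)
        if rating == NOT_APPLICABLE or rating == IMPLEMENTED:
            continue
        out.append(
            Shortfall(
                tier=tier,
                constraint=f"critical_implemented:{sub.sub_id}",
                required=Fraction(1),
                observed=Fraction(0),
            )
        )
    return out


def _achieved_tier(
    assessment: Assessment,
    catalog: Catalog,
    function_code: str,
    algorithm: str,
    tally_: TierTally,
) -> tuple[str, tuple[Shortfall, ...]]:
    """Walk the designation tiers bottom-up; stop at the first failure."""
    alg = _algorithm(catalog, algorithm)
    if alg.require_critical and not any(s.critical for s in catalog.sub_indicators()):
        raise UnknownAlgorithmError(
            f"algorithm {algorithm!r} requires critical sub-indicators but the "
            f"catalog flags none"
        )
    rows: Mapping[str, TierThresholds] = {row.tier: row for row in alg.tiers}
    fn = catalog.function(function_code)
    achieved = catalog.tiers.floor
    for tier in catalog.tiers.designation_tiers:
        ok, shortfalls = check_tier(tally_, tier, rows[tier], catalog)
        if alg.require_critical:
            crit = _critical_shortfalls(assessment, fn.sub_indicators, tier, catalog)
            shortfalls = shortfalls + crit
            ok = ok and not crit
        if not ok:
            return achieved, tuple(shortfalls)
        achieved = tier
    return achieved, ()


def classify_function(
    assessment: Assessment,
    catalog: Catalog,
    function_code: str,
    algorithm: str = "flexible",
) -> MaturityResult:
    """Classify one function to its maturity tier under *algorithm*.

    The result's shortfalls describe the first failing tier above the
    achieved one (empty when the top tier is reached).
    """
    tally_ = tally(assessment, catalog, function_code)
    if all(c.applicable == 0 for c in tally_.counts.values()):
        logger.warning(
            "function %s: every response is NOT_APPLICABLE; all tiers pass "
            "vacuously",
            function_code,
        )
    achieved, shortfalls = _achieved_tier(
        assessment, catalog, function_code, algorithm, tally_
    )

    qualifier_alg = algorithm
    if (
        algorithm != "strict"
        and "strict" in catalog.algorithms
        and achieved != catalog.tiers.floor
    ):
        strict_achieved, _ = _achieved_tier(
            assessment, catalog, function_code, "strict", tally_
        )
        if strict_achieved == achieved:
            qualifier_alg = "strict"

    return MaturityResult(
        function_code=function_code,
        algorithm=algorithm,
        achieved_tier=achieved,
        qualifier=f"{catalog.tiers.label(achieved)} ({qualifier_alg})",
        shortfalls=shortfalls,
    )


def classify_institution(
    assessment: Assessment,
    catalog: Catalog,
    algorithm: str = "flexible",
) -> InstitutionResult:
    """Classify the institution: the minimum over per-function tiers, capped
    by the highest tier whose institution-mandatory sub-indicators (at or
    below it) are all Implemented."""
    results = tuple(
        classify_function(assessment, catalog, fn.function_code, algorithm)
        for fn in catalog.functions
    )
    ladder = catalog.tiers
    min_tier = min((r.achieved_tier for r in results), key=ladder.index)

    failing_by_tier: dict[str, list[str]] = {}
    for sub in catalog.sub_indicators():
        if not sub.institution_mandatory:
            continue
        rating = assessment.rating_of(sub.sub_id)
        if rating in (NOT_APPLICABLE, IMPLEMENTED):
            continue
        failing_by_tier.setdefault(sub.designated_tier, []).append(sub.sub_id)

    cap = ladder.top
    for tier in ladder.designation_tiers:
        if tier in failing_by_tier:
            cap = ladder.names[ladder.index(tier) - 1]
            break

    institution = min((min_tier, cap), key=ladder.index)
    failures = sorted(
        sub_id
        for tier, ids in failing_by_tier.items()
        if ladder.index(tier) <= ladder.index(min_tier)
        for sub_id in ids
    )
    return InstitutionResult(
        algorithm=algorithm,
        functions=results,
        institution_tier=institution,
        mandatory_failures=tuple(failures),
    )


def who_flexible_thresholds() -> tuple[TierThresholds, ...]:
    """The flexible threshold rows of the WHO profile (ML2 pooled with ML1)."""
    return WHO_FLEXIBLE_ROWS
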