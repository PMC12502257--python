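"""Synthetic catalogs, synthetic assessments, and an independent oracle.

Everything here is seeded and deterministic: the same seed reproduces the
same catalog or assessment on any platform (``random.Random`` has a stable
algorithm).  The generators exist to exercise the engine — they make no
attempt to model how real agencies answer — and ``oracle_classify`` is a
deliberately independent, straight-line re-implementation of tier
classification used to cross-check the engine in tests.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from fractions import Fraction
from math import ceil
from typing import Mapping

from .catalog import (
    IMPLEMENTED,
    NOT_APPLICABLE,
    NOT_IMPLEMENTED,
    ONGOING_IMPLEMENTATION,
    PARTIALLY_IMPLEMENTED,
    Catalog,
    CatalogError,
    FunctionDef,
    SubIndicator,
    reference_catalog,
)
from .ratings import Assessment, Response

__all__ = [
    "SynthSpec",
    "UnachievableTierError",
    "gen_catalog",
    "gen_assessment",
    "gen_assessment_at_tier",
    "oracle_classify",
]


class UnachievableTierError(CatalogError):
    """No assessment of this catalog can classify exactly to the target."""


@dataclass(frozen=True)
class SynthSpec:
    """Recipe for a synthetic catalog.

    tier_counts
        Sub-indicators per designation tier (e.g. ``{"BRONZE": 3}``).
    critical_fraction
        Probability that a sub-indicator is flagged critical (vmra only).
    profile
        Which reference profile's ladder, scale and algorithms to reuse.
    """

    tier_counts: Mapping[str, int]
    seed: int = 0
    critical_fraction: float = 0.0
    profile: str = "vmra"
    function_code: str = "SYN"

    def __post_init__(self) -> None:
        if any(n < 0 for n in self.tier_counts.values()):
            raise ValueError("tier counts must be non-negative")
        if not 0.0 <= self.critical_fraction <= 1.0:
            raise ValueError("critical_fraction must be in [0,1]")


def gen_catalog(spec: SynthSpec) -> Catalog:
    """A one-function catalog with exactly the requested tier counts."""
    base = reference_catalog(spec.profile)
    ladder = base.tiers
    unknown = set(spec.tier_counts) - set(ladder.designation_tiers)
    if unknown:
        raise ValueError(f"unknown tiers in spec: {sorted(unknown)}")
    rng = random.Random(spec.seed)
    subs = []
    indicator = base.indicators[0]
    for tier in ladder.designation_tiers:
        for k in range(1, spec.tier_counts.get(tier, 0) + 1):
            critical = (
                spec.profile == "vmra" and rng.random() < spec.critical_fraction
            )
            sub_id = f"{spec.function_code}-{tier}-{k:03d}"
            subs.append(
                SubIndicator(
                    sub_id=sub_id,
                    function_code=spec.function_code,
                    indicator_code=indicator.indicator_code,
                    text=f"Synthetic requirement {sub_id}.",
                    designated_tier=tier,
                    critical=critical,
                )
            )
    return Catalog(
        profile=base.profile,
        version=f"synthetic-seed{spec.seed}",
        tiers=ladder,
        scale=base.scale,
        algorithms=base.algorithms,
        indicators=(indicator,),
        functions=(
            FunctionDef(spec.function_code, "Synthetic function", tuple(subs)),
        ),
        notes=f"Synthetic catalog (seed {spec.seed}).",
    )


def gen_assessment(
    catalog: Catalog, mix: Mapping[str, float], seed: int = 0
) -> Assessment:
    """Draw one rating per sub-indicator from a probability mix."""
    total = sum(mix.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"rating mix must sum to 1, got {total}")
    for rating in mix:
        if not catalog.scale.allows(rating):
            raise ValueError(f"rating {rating!r} not allowed by this profile")
    rng = random.Random(seed)
    ratings = sorted(mix)  # stable draw order regardless of dict order
    weights = [mix[r] for r in ratings]
    responses = {
        sub.sub_id: Response(rating=rng.choices(ratings, weights=weights)[0])
        for sub in catalog.sub_indicators()
    }
    return Assessment(
        catalog_profile=catalog.profile,
        catalog_version=catalog.version,
        responses=responses,
    )


def gen_assessment_at_tier(
    catalog: Catalog, target: str, algorithm: str = "flexible", seed: int = 0
) -> Assessment:
    """Construct an assessment that classifies exactly to *target*.

    Tiers at or below the target are satisfied (with the flexible algorithms,
    the target tier is filled only to its exact implemented floor, the
    remainder left in process, critical and mandatory items implemented
    first); every tier above the target is rated entirely Not implemented,
    which violates its implemented floor.  On multi-function catalogs the
    guarantee is at institution level (functions with no items above the
    target pass the higher tiers vacuously).
    """
    ladder = catalog.tiers
    if target not in ladder.names:
        raise ValueError(f"unknown tier {target!r}")
    alg = catalog.algorithms.get(algorithm)
    if alg is None:
        raise UnachievableTierError(
            f"algorithm {algorithm!r} undefined for profile {catalog.profile!r}"
        )
    if alg.require_critical and not any(s.critical for s in catalog.sub_indicators()):
        raise UnachievableTierError(
            f"algorithm {algorithm!r} needs critical flags but the catalog has none"
        )
    target_i = ladder.index(target)
    if target_i < len(ladder.names) - 1:
        above = [
            s
            for s in catalog.sub_indicators()
            if ladder.index(s.designated_tier) > target_i
        ]
        if not above:
            raise UnachievableTierError(
                f"no sub-indicators above {target}: every assessment satisfying "
                f"{target} would classify higher"
            )
    rows = {row.tier: row for row in alg.tiers}
    rng = random.Random(seed)
    responses: dict[str, Response] = {}
    for fn in catalog.functions:
        for tier in ladder.designation_tiers:
            pool = [s for s in fn.sub_indicators if s.designated_tier == tier]
            if not pool:
                continue
            tier_i = ladder.index(tier)
            if tier_i > target_i:
                for s in pool:
                    responses[s.sub_id] = Response(rating=NOT_IMPLEMENTED)
            elif tier_i < target_i:
                for s in pool:
                    responses[s.sub_id] = Response(rating=IMPLEMENTED)
            else:
                row = rows[tier]
                if row.pooled_with_lower:
                    lower_n = sum(
                        1
                        for s in fn.sub_indicators
                        if s.designated_tier in ladder.lower_designation_tiers(tier)
                    )
                    pooled_n = lower_n + len(pool)
                    need = max(0, ceil(row.min_implemented * pooled_n) - lower_n)
                else:
                    need = ceil(row.min_implemented * len(pool))
                priority = [s for s in pool if s.critical or s.institution_mandatory]
                rest = [s for s in pool if s not in priority]
                rng.shuffle(rest)
                implemented = set(
                    s.sub_id for s in (priority + rest)[: max(need, len(priority))]
                )
                slack_rating = (
                    ONGOING_IMPLEMENTATION
                    if ONGOING_IMPLEMENTATION in catalog.scale.scores
                    else PARTIALLY_IMPLEMENTED
                )
                for s in pool:
                    responses[s.sub_id] = Response(
                        rating=IMPLEMENTED if s.sub_id in implemented else slack_rating
                    )
    return Assessment(
        catalog_profile=catalog.profile,
        catalog_version=catalog.version,
        responses=responses,
    )


def oracle_classify(
    assessment: Assessment,
    catalog: Catalog,
    algorithm: str,
    function_code: str | None = None,
) -> str:
    """Independent classification for cross-checking the engine.

    Recounts every tier directly from the raw responses, tests each tier's
    constraints in isolation with plain fraction comparisons, and returns the
    top of the maximal consecutive run of passing tiers from the bottom.
    Intended for small catalogs (brute-force clarity over speed).
    """
    if function_code is None:
        if len(catalog.functions) != 1:
            raise ValueError("function_code required for multi-function catalogs")
        function_code = catalog.functions[0].function_code
    fn = catalog.function(function_code)
    ladder = catalog.tiers
    alg = catalog.algorithms[algorithm]
    rows = {row.tier: row for row in alg.tiers}

    def counts(tier: str) -> tuple[int, int, int, int]:
        imp = proc = ni = 0
        for s in fn.sub_indicators:
            if s.designated_tier != tier:
                continue
            r = assessment.rating_of(s.sub_id)
            if r == NOT_APPLICABLE:
                continue
            if r == IMPLEMENTED:
                imp += 1
            elif r in (PARTIALLY_IMPLEMENTED, ONGOING_IMPLEMENTATION):
                proc += 1
            else:
                ni += 1
        return imp, proc, ni, imp + proc + ni

    passes: dict[str, bool] = {}
    for tier in ladder.designation_tiers:
        row = rows[tier]
        ok = True
        if row.lower_tiers_full:
            for lower in ladder.lower_designation_tiers(tier):
                imp, _, _, n = counts(lower)
                if n > 0 and imp < n:
                    ok = False
        if row.pooled_with_lower:
            imp = proc = ni = n = 0
            for t in ladder.at_most(tier):
                a, b, c, d = counts(t)
                imp, proc, ni, n = imp + a, proc + b, ni + c, n + d
        else:
            imp, proc, ni, n = counts(tier)
        if n > 0:
            if Fraction(imp, n) < row.min_implemented:
                ok = False
            if Fraction(proc, n) > row.max_partial:
                ok = False
            if Fraction(ni, n) > row.max_not_implemented:
                ok = False
        if alg.require_critical:
            for s in fn.sub_indicators:
                if (
                    s.critical
                    and ladder.index(s.designated_tier) <= ladder.index(tier)
                    and assessment.rating_of(s.sub_id)
                    not in (IMPLEMENTED, NOT_APPLICABLE)
                ):
                    ok = False
        passes[tier] = ok

    achieved = ladder.floor
    for tier in ladder.designation_tiers:
        if not passes[tier]:
            break
        achieved = tier
    return achieved
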