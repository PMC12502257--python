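"""Institutional Development Plan generation.

The IDP is the gap list: one entry for every applicable sub-indicator that is
not fully Implemented, prioritised by designated tier (ascending), critical
items first, then by id.  ``upgrade_path`` turns the gap list into a minimal
set of single-sub-indicator rating upgrades that lifts the institution to a
target tier under a chosen algorithm.

Minimality: upgrades that any feasible plan must contain (fully implementing
tiers that a higher row requires at 100%, implementing critical items under
restricted flexibility, implementing institution-mandatory items) are forced
first; each remaining threshold row is then solved exactly on its own pool by
enumerating move counts (Not implemented -> Implemented, Not implemented ->
Partially implemented, in-process -> Implemented) in increasing total.  Pools
of distinct rows are disjoint, so the per-pool optima sum to a global
optimum; this is cross-checked against a brute-force subset oracle in the
test suite.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, replace
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
    SubIndicator,
)
from .engine import classify_function, classify_institution
from .ratings import Assessment, Response

__all__ = ["IDPEntry", "extract_gaps", "upgrade_path", "gaps_to_csv", "gaps_to_markdown"]


@dataclass(frozen=True)
class IDPEntry:
    """One gap: a sub-indicator not fully met."""

    sub_id: str
    function_code: str
    current_rating: str
    designated_tier: str
    critical: bool
    blocking: bool
    suggested_action: str


def _sort_key(catalog: Catalog):
    ladder = catalog.tiers

    def key(entry: IDPEntry):
        return (ladder.index(entry.designated_tier), not entry.critical, entry.sub_id)

    return key


def _suggested_action(sub: SubIndicator, rating: str, catalog: Catalog) -> str:
    tier_label = catalog.tiers.label(sub.designated_tier)
    if rating == NOT_IMPLEMENTED:
        verb = "Establish and implement"
    else:
        verb = "Complete the implementation of"
    tag = " [critical]" if sub.critical else ""
    return (
        f"{verb} the {tier_label}-level requirement {sub.sub_id} "
        f"(indicator {sub.indicator_code}){tag}."
    )


def extract_gaps(
    assessment: Assessment,
    catalog: Catalog,
    algorithm: str = "flexible",
) -> list[IDPEntry]:
    """One entry per applicable, not-fully-implemented sub-indicator.

    An entry is *blocking* when it can stand in the way of the next tier
    above its function's achieved tier under *algorithm*: its designated
    tier is at or below that next tier.
    """
    next_tier_index: dict[str, int] = {}
    ladder = catalog.tiers
    for fn in catalog.functions:
        result = classify_function(assessment, catalog, fn.function_code, algorithm)
        i = ladder.index(result.achieved_tier)
        next_tier_index[fn.function_code] = min(i + 1, len(ladder.names) - 1) if i < len(ladder.names) - 1 else -1

    entries = []
    for sub in catalog.sub_indicators():
        rating = assessment.rating_of(sub.sub_id)
        if rating in (IMPLEMENTED, NOT_APPLICABLE):
            continue
        nti = next_tier_index[sub.function_code]
        blocking = nti >= 0 and ladder.index(sub.designated_tier) <= nti
        entries.append(
            IDPEntry(
                sub_id=sub.sub_id,
                function_code=sub.function_code,
                current_rating=rating,
                designated_tier=sub.designated_tier,
                critical=sub.critical,
                blocking=blocking,
                suggested_action=_suggested_action(sub, rating, catalog),
            )
        )
    entries.sort(key=_sort_key(catalog))
    return entries


# ---------------------------------------------------------------------------
# Minimal upgrade path
# ---------------------------------------------------------------------------

def _ceil_frac(f: Fraction, n: int) -> int:
    """Smallest integer k with k/n >= f."""
    return ceil(f * n)


def _floor_frac(f: Fraction, n: int) -> int:
    """Largest integer k with k/n <= f."""
    return int(f * n)


def _select(subs: list[SubIndicator], k: int) -> list[SubIndicator]:
    """Pick k items, critical first, then by id."""
    return sorted(subs, key=lambda s: (not s.critical, s.sub_id))[:k]


def upgrade_path(
    assessment: Assessment,
    catalog: Catalog,
    algorithm: str,
    target_tier: str,
) -> dict[str, str]:
    """A smallest set of rating upgrades reaching *target_tier*.

    Returns ``{sub_id: new_rating}``.  Applying the upgrades and
    reclassifying must reach the target at institution level (asserted
    before returning); already-met targets return an empty dict.
    """
    ladder = catalog.tiers
    if target_tier not in ladder.designation_tiers:
        raise ValueError(f"invalid target tier {target_tier!r}")
    current = classify_institution(assessment, catalog, algorithm)
    if ladder.index(current.institution_tier) >= ladder.index(target_tier):
        return {}

    alg = catalog.algorithms[algorithm]
    rows = {row.tier: row for row in alg.tiers}
    target_i = ladder.index(target_tier)

    upgrades: dict[str, str] = {}

    def rating_of(sub_id: str) -> str:
        if sub_id in upgrades:
            return upgrades[sub_id]
        return assessment.rating_of(sub_id)

    def force_implement(sub: SubIndicator) -> None:
        if rating_of(sub.sub_id) not in (IMPLEMENTED, NOT_APPLICABLE):
            upgrades[sub.sub_id] = IMPLEMENTED

    # Tiers that some row at or below the target requires at 100%.
    forced_full: set[str] = set()
    for tier in ladder.at_most(target_tier):
        row = rows[tier]
        if row.lower_tiers_full:
            forced_full.update(ladder.lower_designation_tiers(tier))
        if row.min_implemented == 1 and not row.pooled_with_lower:
            forced_full.add(tier)

    for sub in catalog.sub_indicators():
        tier_i = ladder.index(sub.designated_tier)
        if sub.designated_tier in forced_full:
            force_implement(sub)
        if alg.require_critical and sub.critical and tier_i <= target_i:
            force_implement(sub)
        if sub.institution_mandatory and tier_i <= target_i:
            force_implement(sub)

    # Solve each remaining row per function on its own pool.
    for fn in catalog.functions:
        for tier in ladder.at_most(target_tier):
            row = rows[tier]
            if tier in forced_full and not row.pooled_with_lower:
                continue
            pool_tiers = set(ladder.at_most(tier)) if row.pooled_with_lower else {tier}
            pool = [
                s
                for s in fn.sub_indicators
                if s.designated_tier in pool_tiers
                and rating_of(s.sub_id) != NOT_APPLICABLE
            ]
            not_items = [s for s in pool if rating_of(s.sub_id) == NOT_IMPLEMENTED]
            proc_items = [
                s
                for s in pool
                if rating_of(s.sub_id) in (PARTIALLY_IMPLEMENTED, ONGOING_IMPLEMENTATION)
            ]
            a = len(pool)
            if a == 0:
                continue
            i0 = a - len(not_items) - len(proc_items)
            p0, n0 = len(proc_items), len(not_items)
            need_i = _ceil_frac(row.min_implemented, a)
            cap_p = _floor_frac(row.max_partial, a)
            cap_n = _floor_frac(row.max_not_implemented, a)

            best = None
            for k in range(0, n0 + p0 + 1):
                for x in range(0, min(k, n0) + 1):  # NOT -> IMPLEMENTED
                    for y in range(0, min(k - x, n0 - x) + 1):  # NOT -> PARTIAL
                        z = k - x - y  # in-process -> IMPLEMENTED
                        if z > p0:
                            continue
                        if (
                            i0 + x + z >= need_i
                            and p0 + y - z <= cap_p
                            and n0 - x - y <= cap_n
                        ):
                            best = (x, y, z)
                            break
                    if best:
                        break
                if best:
                    break
            if best is None:  # unreachable: upgrading everything always works
                best = (n0, 0, p0)
            x, y, z = best
            promote_full = _select(not_items, x)
            for s in promote_full:
                upgrades[s.sub_id] = IMPLEMENTED
            remaining_not = [s for s in not_items if s not in promote_full]
            for s in _select(remaining_not, y):
                upgrades[s.sub_id] = PARTIALLY_IMPLEMENTED
            for s in _select(proc_items, z):
                upgrades[s.sub_id] = IMPLEMENTED

    # Self-consistency: the plan must reach the target.
    upgraded = apply_upgrades(assessment, upgrades)
    achieved = classify_institution(upgraded, catalog, algorithm).institution_tier
    if ladder.index(achieved) < target_i:  # pragma: no cover - defensive
        raise AssertionError(
            f"upgrade path failed to reach {target_tier} (got {achieved})"
        )
    return upgrades


def apply_upgrades(assessment: Assessment, upgrades: Mapping[str, str]) -> Assessment:
    """Return a new assessment with the upgrade ratings applied."""
    responses = dict(assessment.responses)
    for sub_id, rating in upgrades.items():
        old = responses.get(sub_id)
        responses[sub_id] = (
            replace(old, rating=rating) if old is not None else Response(rating=rating)
        )
    return Assessment(
        catalog_profile=assessment.catalog_profile,
        catalog_version=assessment.catalog_version,
        responses=responses,
    )


# ---------------------------------------------------------------------------
# Export
# ---------------------------------------------------------------------------

def gaps_to_csv(entries: list[IDPEntry]) -> str:
    out = io.StringIO()
    writer = csv.writer(out)
    writer.writerow(
        ["sub_id", "function_code", "designated_tier", "current_rating",
         "critical", "blocking", "suggested_action"]
    )
    for e in entries:
        writer.writerow(
            [e.sub_id, e.function_code, e.designated_tier, e.current_rating,
             str(e.critical).lower(), str(e.blocking).lower(), e.suggested_action]
        )
    return out.getvalue()


def gaps_to_markdown(entries: list[IDPEntry], catalog: Catalog) -> str:
    lines = ["# Institutional Development Plan", ""]
    ladder = catalog.tiers
    for tier in ladder.designation_tiers:
        tier_entries = [e for e in entries if e.designated_tier == tier]
        if not tier_entries:
            continue
        lines.append(f"## {ladder.label(tier)} ({len(tier_entries)} gap(s))")
        lines.append("")
        for e in tier_entries:
            flags = []
            if e.critical:
                flags.append("critical")
            if e.blocking:
                flags.append("blocking")
            suffix = f" ({', '.join(flags)})" if flags else ""
            lines.append(
                f"- **{e.sub_id}** [{e.current_rating}]{suffix}: {e.suggested_action}"
            )
        lines.append("")
    if len(lines) == 2:
        lines.append("No gaps: every applicable sub-indicator is implemented.")
        lines.append("")
    return "\n".join(lines)
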