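from __future__ import annotations

import pytest

import vmrasat as v


@pytest.fixture(scope="session")
def vmra_catalog() -> v.Catalog:
    return v.reference_catalog("vmra")


@pytest.fixture(scope="session")
def who_catalog() -> v.Catalog:
    return v.reference_catalog("who-gbt")


@pytest.fixture(scope="session")
def small_catalog() -> v.Catalog:
    """One-function vmra-profile catalog with a few items per tier."""
    return v.gen_catalog(
        v.SynthSpec(
            tier_counts={
                "PRE_BRONZE": 3,
                "BRONZE": 6,
                "SILVER": 6,
                "GOLD": 10,
                "GOLD_PLUS": 5,
            },
            seed=11,
            critical_fraction=0.2,
        )
    )


def make_assessment(catalog: v.Catalog, ratings: dict[str, str]) -> v.Assessment:
    """Assessment from explicit {sub_id: rating}; unlisted ids are omitted."""
    return v.Assessment(
        catalog_profile=catalog.profile,
        catalog_version=catalog.version,
        responses={sid: v.Response(rating=r) for sid, r in ratings.items()},
    )


def uniform_assessment(catalog: v.Catalog, rating: str) -> v.Assessment:
    return make_assessment(
        catalog, {s.sub_id: rating for s in catalog.sub_indicators()}
    )


def tiered_assessment(catalog: v.Catalog, per_tier: dict[str, list[str]]) -> v.Assessment:
    """Assign ratings positionally within each tier of a one-function catalog.

    per_tier maps tier -> list of ratings, one per sub-indicator of that tier
    (in catalog order); tiers not listed default to IMPLEMENTED.
    """
    ratings: dict[str, str] = {}
    seen: dict[str, int] = {}
    for sub in catalog.sub_indicators():
        t = sub.designated_tier
        i = seen.get(t, 0)
        seen[t] = i + 1
        if t in per_tier:
            ratings[sub.sub_id] = per_tier[t][i]
        else:
            ratings[sub.sub_id] = v.IMPLEMENTED
    return make_assessment(catalog, ratings)
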