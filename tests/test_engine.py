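"""Tier checks and maturity classification under all three algorithms."""

from __future__ import annotations

import random
from dataclasses import replace
from fractions import Fraction

import pytest

import vmrasat as v
from vmrasat.catalog import VMRA_FLEXIBLE_ROWS
from vmrasat.ratings import TierCount, TierTally

from conftest import make_assessment, tiered_assessment, uniform_assessment

FLEX = {row.tier: row for row in VMRA_FLEXIBLE_ROWS}


def vmra_tally(**per_tier: TierCount) -> TierTally:
    counts = {t: per_tier.get(t, TierCount()) for t in v.VMRA_LADDER.designation_tiers}
    return TierTally(function_code="SYN", counts=counts)


class TestCheckTier:
    def test_gold_within_all_caps_passes(self, vmra_catalog):
        t = vmra_tally(
            PRE_BRONZE=TierCount(implemented=6),
            BRONZE=TierCount(implemented=21),
            SILVER=TierCount(implemented=28),
            GOLD=TierCount(implemented=85, partial=10, not_implemented=5),
        )
        ok, shortfalls = v.check_tier(t, "GOLD", FLEX["GOLD"], vmra_catalog)
        assert ok and not shortfalls

    def test_bronze_tolerates_no_not_implemented(self, vmra_catalog):
        t = vmra_tally(
            PRE_BRONZE=TierCount(implemented=6),
            BRONZE=TierCount(implemented=19, not_implemented=1),
        )
        ok, shortfalls = v.check_tier(t, "BRONZE", FLEX["BRONZE"], vmra_catalog)
        assert not ok
        assert any(s.constraint == "max_not_implemented" for s in shortfalls)

    def test_empty_tier_passes_vacuously(self, vmra_catalog):
        ok, shortfalls = v.check_tier(vmra_tally(), "GOLD", FLEX["GOLD"], vmra_catalog)
        assert ok and not shortfalls

    def test_gold_below_floor_reports_exact_shortfall(self, vmra_catalog):
        t = vmra_tally(
            PRE_BRONZE=TierCount(implemented=6),
            BRONZE=TierCount(implemented=21),
            SILVER=TierCount(implemented=28),
            GOLD=TierCount(implemented=84, partial=16),
        )
        ok, shortfalls = v.check_tier(t, "GOLD", FLEX["GOLD"], vmra_catalog)
        assert not ok
        (sf,) = [s for s in shortfalls if s.constraint == "min_implemented"]
        assert sf.tier == "GOLD"
        assert sf.required == Fraction(85, 100)
        assert sf.observed == Fraction(84, 100)

    def test_incomplete_lower_tier_blocks_higher_tier(self, vmra_catalog):
        t = vmra_tally(
            PRE_BRONZE=TierCount(implemented=6),
            BRONZE=TierCount(implemented=19, partial=1),
            SILVER=TierCount(implemented=28),
        )
        ok, shortfalls = v.check_tier(t, "SILVER", FLEX["SILVER"], vmra_catalog)
        assert not ok
        assert any(s.constraint == "lower_tier_full:BRONZE" for s in shortfalls)


class TestClassifyFunction:
    def test_all_implemented_reaches_top_under_any_algorithm(self, small_catalog):
        a = uniform_assessment(small_catalog, v.IMPLEMENTED)
        for alg in ("strict", "flexible", "restricted"):
            res = v.classify_function(a, small_catalog, "SYN", alg)
            assert res.achieved_tier == "GOLD_PLUS"
            assert res.shortfalls == ()

    def test_bronze_at_95pc_with_silver_blocked_by_lower_full(self):
        """19/20 Bronze passes flexible Bronze, but Silver requires Bronze at
        100%, so the function stays Bronze."""
        cat = v.gen_catalog(
            v.SynthSpec(
                tier_counts={"PRE_BRONZE": 6, "BRONZE": 20, "SILVER": 10,
                             "GOLD": 10, "GOLD_PLUS": 5},
                seed=0,
            )
        )
        a = tiered_assessment(
            cat, {"BRONZE": [v.IMPLEMENTED] * 19 + [v.PARTIALLY_IMPLEMENTED]}
        )
        res = v.classify_function(a, cat, "SYN", "flexible")
        assert res.achieved_tier == "BRONZE"
        assert res.qualifier == "Bronze (flexible)"
        assert any(s.constraint == "lower_tier_full:BRONZE" for s in res.shortfalls)

    def test_restricted_fails_on_partial_critical_item(self):
        cat = v.gen_catalog(
            v.SynthSpec(
                tier_counts={"PRE_BRONZE": 6, "BRONZE": 20, "SILVER": 10,
                             "GOLD": 10, "GOLD_PLUS": 5},
                seed=0,
            )
        )
        bronze = [s for s in cat.sub_indicators() if s.designated_tier == "BRONZE"]
        # Flag the partial item (last Bronze) critical.
        flagged = bronze[-1]
        fn = cat.functions[0]
        subs = tuple(
            replace(s, critical=True) if s.sub_id == flagged.sub_id else s
            for s in fn.sub_indicators
        )
        cat = v.Catalog(
            profile=cat.profile, version=cat.version, tiers=cat.tiers,
            scale=cat.scale, algorithms=cat.algorithms, indicators=cat.indicators,
            functions=(v.FunctionDef("SYN", fn.name, subs),),
        )
        a = tiered_assessment(
            cat, {"BRONZE": [v.IMPLEMENTED] * 19 + [v.PARTIALLY_IMPLEMENTED]}
        )
        assert v.classify_function(a, cat, "SYN", "flexible").achieved_tier == "BRONZE"
        res = v.classify_function(a, cat, "SYN", "restricted")
        assert res.achieved_tier == "PRE_BRONZE"
        assert any(
            s.constraint == f"critical_implemented:{flagged.sub_id}"
            for s in res.shortfalls
        )

    def test_incomplete_pre_bronze_classifies_to_floor(self, small_catalog):
        a = tiered_assessment(
            small_catalog,
            {"PRE_BRONZE": [v.IMPLEMENTED, v.IMPLEMENTED, v.PARTIALLY_IMPLEMENTED]},
        )
        for alg in ("strict", "flexible"):
            assert v.classify_function(a, small_catalog, "SYN", alg).achieved_tier == "L0"

    def test_unknown_algorithm_raises(self, small_catalog):
        a = uniform_assessment(small_catalog, v.IMPLEMENTED)
        with pytest.raises(v.UnknownAlgorithmError):
            v.classify_function(a, small_catalog, "SYN", "lenient")

    def test_restricted_requires_critical_flags(self, who_catalog):
        a = uniform_assessment(who_catalog, v.IMPLEMENTED)
        with pytest.raises(v.UnknownAlgorithmError):
            v.classify_function(a, who_catalog, "RS", "restricted")

    def test_strict_qualifier_preferred_when_strict_also_passes(self, small_catalog):
        a = uniform_assessment(small_catalog, v.IMPLEMENTED)
        res = v.classify_function(a, small_catalog, "SYN", "flexible")
        assert res.qualifier == "Gold-plus (strict)"
        assert res.algorithm == "flexible"


class TestWhoThresholds:
    def test_rows_match_the_published_rules(self):
        rows = {r.tier: r for r in v.who_flexible_thresholds()}
        assert rows["ML2"].min_implemented == Fraction(19, 20)
        assert rows["ML2"].pooled_with_lower and not rows["ML2"].lower_tiers_full
        assert rows["ML3"].min_implemented == Fraction(9, 10)
        assert rows["ML4"].min_implemented == Fraction(4, 5)
        # Remainders must be in process: not-implemented cap is zero throughout.
        assert all(r.max_not_implemented == 0 for r in rows.values())

    @staticmethod
    def _who_cat(ml1: int, ml2: int, ml3: int = 0, ml4: int = 0) -> v.Catalog:
        return v.gen_catalog(
            v.SynthSpec(
                tier_counts={"ML1": ml1, "ML2": ml2, "ML3": ml3, "ML4": ml4},
                seed=0,
                profile="who-gbt",
            )
        )

    def test_ml3_passes_at_90pc_with_remainder_in_process(self):
        cat = self._who_cat(10, 10, 100, 5)
        a = tiered_assessment(
            cat, {"ML3": [v.IMPLEMENTED] * 90 + [v.PARTIALLY_IMPLEMENTED] * 10,
                  "ML4": [v.NOT_IMPLEMENTED] * 5}
        )
        assert v.classify_function(a, cat, "SYN", "flexible").achieved_tier == "ML3"

    @pytest.mark.parametrize("implemented,expected", [(38, "ML2"), (37, "ML1")])
    def test_ml2_pooled_95pc_boundary(self, implemented, expected):
        """38 of the pooled 40 (ML1+ML2) implemented passes; 37 fails."""
        cat = self._who_cat(20, 20, 5)
        k2 = implemented - 20  # ML1 kept fully implemented
        a = tiered_assessment(
            cat,
            {"ML2": [v.IMPLEMENTED] * k2
                    + [v.ONGOING_IMPLEMENTATION] * (20 - k2),
             "ML3": [v.NOT_IMPLEMENTED] * 5},
        )
        assert v.classify_function(a, cat, "SYN", "flexible").achieved_tier == expected

    def test_ml4_passes_at_80pc_with_remainder_ongoing(self):
        cat = self._who_cat(5, 5, 5, 100)
        a = tiered_assessment(
            cat, {"ML4": [v.IMPLEMENTED] * 80 + [v.ONGOING_IMPLEMENTATION] * 20}
        )
        assert v.classify_function(a, cat, "SYN", "flexible").achieved_tier == "ML4"


class TestClassifyInstitution:
    def test_all_functions_top_no_failures(self, vmra_catalog):
        a = uniform_assessment(vmra_catalog, v.IMPLEMENTED)
        res = v.classify_institution(a, vmra_catalog, "flexible")
        assert res.institution_tier == "GOLD_PLUS"
        assert res.mandatory_failures == ()

    def test_institution_is_minimum_over_functions(self, vmra_catalog):
        # Degrade one function (VBR) to Bronze level: all its Silver items partial.
        ratings = {s.sub_id: v.IMPLEMENTED for s in vmra_catalog.sub_indicators()}
        for s in vmra_catalog.function("VBR").sub_indicators:
            if s.designated_tier == "SILVER":
                ratings[s.sub_id] = v.NOT_IMPLEMENTED
        a = make_assessment(vmra_catalog, ratings)
        res = v.classify_institution(a, vmra_catalog, "flexible")
        per_fn = {r.function_code: r.achieved_tier for r in res.functions}
        assert per_fn["VBR"] == "BRONZE"
        assert all(t == "GOLD_PLUS" for c, t in per_fn.items() if c != "VBR")
        assert res.institution_tier == "BRONZE"

    def test_mandatory_item_caps_institution_below_function_minimum(self):
        """All functions reach Silver, but a mandatory Silver item left
        partially implemented caps the institution at Bronze."""
        cat = v.gen_catalog(
            v.SynthSpec(
                tier_counts={"PRE_BRONZE": 2, "BRONZE": 4, "SILVER": 20,
                             "GOLD": 4, "GOLD_PLUS": 2},
                seed=5,
            )
        )
        fn = cat.functions[0]
        silver = [s for s in fn.sub_indicators if s.designated_tier == "SILVER"]
        subs = tuple(
            replace(s, institution_mandatory=True) if s.sub_id == silver[0].sub_id else s
            for s in fn.sub_indicators
        )
        cat = v.Catalog(
            profile=cat.profile, version=cat.version, tiers=cat.tiers,
            scale=cat.scale, algorithms=cat.algorithms, indicators=cat.indicators,
            functions=(v.FunctionDef("SYN", fn.name, subs),),
        )
        ratings = {s.sub_id: v.IMPLEMENTED for s in cat.sub_indicators()}
        # 19/20 silver implemented keeps the function at Silver (>= 90% floor)
        # even though the one partial item happens to be mandatory.
        ratings[silver[0].sub_id] = v.PARTIALLY_IMPLEMENTED
        for s in cat.sub_indicators():
            if s.designated_tier in ("GOLD", "GOLD_PLUS"):
                ratings[s.sub_id] = v.NOT_IMPLEMENTED
        a = make_assessment(cat, ratings)
        res = v.classify_institution(a, cat, "flexible")
        assert res.functions[0].achieved_tier == "SILVER"
        assert res.institution_tier == "BRONZE"
        assert silver[0].sub_id in res.mandatory_failures


class TestAlgorithmProperties:
    MIX = {
        v.IMPLEMENTED: 0.62,
        v.PARTIALLY_IMPLEMENTED: 0.18,
        v.NOT_IMPLEMENTED: 0.12,
        v.NOT_APPLICABLE: 0.08,
    }

    def test_strict_le_restricted_le_flexible(self, small_catalog):
        ladder = small_catalog.tiers
        for seed in range(200):
            a = v.gen_assessment(small_catalog, self.MIX, seed=seed)
            tiers = {
                alg: ladder.index(
                    v.classify_function(a, small_catalog, "SYN", alg).achieved_tier
                )
                for alg in ("strict", "restricted", "flexible")
            }
            assert tiers["strict"] <= tiers["restricted"] <= tiers["flexible"], seed

    def test_single_upgrade_never_decreases_tier(self, small_catalog):
        ladder = small_catalog.tiers
        vmra_ladder = [r for r in v.RATING_LADDER if r in small_catalog.scale.scores]
        rng = random.Random(42)
        for seed in range(40):
            a = v.gen_assessment(small_catalog, self.MIX, seed=seed)
            before = {
                alg: ladder.index(
                    v.classify_function(a, small_catalog, "SYN", alg).achieved_tier
                )
                for alg in ("strict", "restricted", "flexible")
            }
            upgradable = [
                sid for sid, r in a.responses.items()
                if r.rating in vmra_ladder[:-1]
            ]
            if not upgradable:
                continue
            sid = rng.choice(upgradable)
            new_rating = vmra_ladder[vmra_ladder.index(a.responses[sid].rating) + 1]
            upgraded = v.apply_upgrades(a, {sid: new_rating})
            for alg, b in before.items():
                after = ladder.index(
                    v.classify_function(upgraded, small_catalog, "SYN", alg).achieved_tier
                )
                assert after >= b, (seed, sid, alg)

    def test_marking_na_equals_deleting_from_catalog(self, small_catalog):
        """NOT_APPLICABLE on a sub-indicator gives the same classification as
        removing that sub-indicator from the catalog entirely."""
        fn = small_catalog.functions[0]
        for seed in range(20):
            a = v.gen_assessment(small_catalog, self.MIX, seed=seed)
            victim = list(small_catalog.sub_indicators())[seed % 30]
            a_na = v.apply_upgrades(a, {})
            responses = dict(a.responses)
            responses[victim.sub_id] = v.Response(rating=v.NOT_APPLICABLE)
            a_na = v.Assessment(a.catalog_profile, a.catalog_version, responses)
            pruned = v.Catalog(
                profile=small_catalog.profile, version=small_catalog.version,
                tiers=small_catalog.tiers, scale=small_catalog.scale,
                algorithms=small_catalog.algorithms,
                indicators=small_catalog.indicators,
                functions=(
                    v.FunctionDef(
                        "SYN", fn.name,
                        tuple(s for s in fn.sub_indicators if s.sub_id != victim.sub_id),
                    ),
                ),
            )
            for alg in ("strict", "restricted", "flexible"):
                assert (
                    v.classify_function(a_na, small_catalog, "SYN", alg).achieved_tier
                    == v.classify_function(a_na, pruned, "SYN", alg).achieved_tier
                ), (seed, victim.sub_id, alg)

    def test_strict_equals_one_line_oracle(self, small_catalog):
        """Strict tier = highest T with every applicable sub-indicator at
        tiers <= T implemented."""
        ladder = small_catalog.tiers
        for seed in range(100):
            a = v.gen_assessment(small_catalog, self.MIX, seed=seed)
            achieved = v.classify_function(a, small_catalog, "SYN", "strict").achieved_tier
            expected = ladder.floor
            for t in ladder.designation_tiers:
                if all(
                    a.responses[s.sub_id].rating in (v.IMPLEMENTED, v.NOT_APPLICABLE)
                    for s in small_catalog.sub_indicators()
                    if ladder.index(s.designated_tier) <= ladder.index(t)
                ):
                    expected = t
                else:
                    break
            assert achieved == expected, seed

    def test_bronze_boundary_is_exact_at_95pc(self):
        cat = v.gen_catalog(
            v.SynthSpec(tier_counts={"PRE_BRONZE": 6, "BRONZE": 20, "SILVER": 5}, seed=0)
        )
        for k, expected in ((19, "BRONZE"), (18, "PRE_BRONZE")):
            a = tiered_assessment(
                cat,
                {"BRONZE": [v.IMPLEMENTED] * k + [v.PARTIALLY_IMPLEMENTED] * (20 - k),
                 "SILVER": [v.NOT_IMPLEMENTED] * 5},
            )
            assert v.classify_function(a, cat, "SYN", "flexible").achieved_tier == expected

    def test_all_na_classifies_top_vacuously(self, small_catalog):
        a = uniform_assessment(small_catalog, v.NOT_APPLICABLE)
        for alg in ("strict", "flexible", "restricted"):
            assert (
                v.classify_function(a, small_catalog, "SYN", alg).achieved_tier
                == "GOLD_PLUS"
            )
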