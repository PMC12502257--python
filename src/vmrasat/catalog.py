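"""Assessment-framework catalog model.

A *catalog* defines everything an assessment is scored against: the regulatory
functions, their indicators, the sub-indicators (each pre-designated to a
maturity tier), the rating scale, and the per-algorithm tier-threshold tables.
Two reference catalogs are built in:

``vmra``
    The veterinary-medicines self-assessment framework — 8 functions,
    13 indicators, 235 sub-indicators designated Pre-bronze (6), Bronze (21),
    Silver (28), Gold (154) and Gold-plus (26), a three-point rating scale
    (Implemented 1, Partially implemented 0.5, Not implemented 0, plus
    Not applicable) and three algorithms: strict, flexible and restricted
    flexibility.

``who-gbt``
    The WHO Global Benchmarking Tool profile for human-medicines regulators —
    9 functions, 268 sub-indicators over ML1–ML4, a four-point scale
    (1 / 0.75 / 0.25 / 0) and strict + flexible algorithms.

Sub-indicator texts in the reference catalogs are structured placeholders:
the framework's testable content here is its structure (codes, tiers, counts,
flags and thresholds), not the guidance prose.

All threshold fractions are exact :class:`fractions.Fraction` values so that
boundary comparisons (e.g. 19 of 20 against a 95% floor) are unambiguous.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from fractions import Fraction
from importlib import resources
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import yaml

__all__ = [
    "CatalogError",
    "CatalogParseError",
    "CatalogValidationError",
    "UnknownFunctionError",
    "TierLadder",
    "VMRA_LADDER",
    "WHO_LADDER",
    "RATING_LADDER",
    "IMPLEMENTED",
    "PARTIALLY_IMPLEMENTED",
    "ONGOING_IMPLEMENTATION",
    "NOT_IMPLEMENTED",
    "NOT_APPLICABLE",
    "RatingScale",
    "TierThresholds",
    "AlgorithmSpec",
    "SubIndicator",
    "IndicatorDef",
    "FunctionDef",
    "Catalog",
    "Finding",
    "ValidationReport",
    "validate_catalog",
    "load_catalog",
    "loads_catalog",
    "write_catalog",
    "dumps_catalog",
    "tier_counts",
    "reference_catalog",
    "VMRA_FLEXIBLE_ROWS",
    "WHO_FLEXIBLE_ROWS",
]

CATALOG_FORMAT_VERSION = 1

# Rating vocabulary, ordered from worst to best.  NOT_APPLICABLE sits outside
# the ladder: it removes a sub-indicator from every numerator and denominator.
NOT_IMPLEMENTED = "NOT_IMPLEMENTED"
ONGOING_IMPLEMENTATION = "ONGOING_IMPLEMENTATION"
PARTIALLY_IMPLEMENTED = "PARTIALLY_IMPLEMENTED"
IMPLEMENTED = "IMPLEMENTED"
NOT_APPLICABLE = "NOT_APPLICABLE"
RATING_LADDER = (
    NOT_IMPLEMENTED,
    ONGOING_IMPLEMENTATION,
    PARTIALLY_IMPLEMENTED,
    IMPLEMENTED,
)


class CatalogError(Exception):
    """Base class for catalog problems."""


class CatalogParseError(CatalogError):
    """The catalog file could not be parsed or has a malformed structure."""


class CatalogValidationError(CatalogError):
    """The catalog parsed but violates framework invariants."""

    def __init__(self, report: "ValidationReport") -> None:
        self.report = report
        lines = "; ".join(f.message for f in report.findings)
        super().__init__(f"invalid catalog: {lines}")


class UnknownFunctionError(CatalogError, KeyError):
    """A function code was requested that the catalog does not define."""


@dataclass(frozen=True)
class TierLadder:
    """Ordered maturity-tier vocabulary for one profile.

    ``names[0]`` is the floor (below the lowest designation tier); it is never
    a valid designation for a sub-indicator.
    """

    names: tuple[str, ...]
    display: Mapping[str, str]

    @property
    def floor(self) -> str:
        return self.names[0]

    @property
    def top(self) -> str:
        return self.names[-1]

    @property
    def designation_tiers(self) -> tuple[str, ...]:
        return self.names[1:]

    def index(self, tier: str) -> int:
        return self.names.index(tier)

    def __contains__(self, tier: object) -> bool:
        return tier in self.names

    def lower_designation_tiers(self, tier: str) -> tuple[str, ...]:
        """Designation tiers strictly below *tier*."""
        i = self.index(tier)
        return self.names[1:i]

    def at_most(self, tier: str) -> tuple[str, ...]:
        """Designation tiers at or below *tier*."""
        i = self.index(tier)
        return self.names[1 : i + 1]

    def label(self, tier: str) -> str:
        return self.display.get(tier, tier)


VMRA_LADDER = TierLadder(
    names=("L0", "PRE_BRONZE", "BRONZE", "SILVER", "GOLD", "GOLD_PLUS"),
    display={
        "L0": "Below Pre-bronze",
        "PRE_BRONZE": "Pre-bronze",
        "BRONZE": "Bronze",
        "SILVER": "Silver",
        "GOLD": "Gold",
        "GOLD_PLUS": "Gold-plus",
    },
)

WHO_LADDER = TierLadder(
    names=("ML0", "ML1", "ML2", "ML3", "ML4"),
    display={"ML0": "Below ML1", "ML1": "ML1", "ML2": "ML2", "ML3": "ML3", "ML4": "ML4"},
)

_PROFILE_LADDERS = {"vmra": VMRA_LADDER, "who-gbt": WHO_LADDER}


@dataclass(frozen=True)
class RatingScale:
    """The allowed ratings of a profile and their numeric scores.

    ``scores`` maps every scoreable rating to a Fraction in [0, 1];
    NOT_APPLICABLE is always allowed but never carries a number — it is
    excluded from all arithmetic.
    """

    profile: str
    scores: Mapping[str, Fraction]

    def allows(self, rating: str) -> bool:
        return rating == NOT_APPLICABLE or rating in self.scores

    @property
    def allowed(self) -> tuple[str, ...]:
        ordered = [r for r in RATING_LADDER if r in self.scores]
        return tuple(ordered) + (NOT_APPLICABLE,)


VMRA_SCALE = RatingScale(
    profile="vmra",
    scores={
        IMPLEMENTED: Fraction(1),
        PARTIALLY_IMPLEMENTED: Fraction(1, 2),
        NOT_IMPLEMENTED: Fraction(0),
    },
)

WHO_SCALE = RatingScale(
    profile="who-gbt",
    scores={
        IMPLEMENTED: Fraction(1),
        PARTIALLY_IMPLEMENTED: Fraction(3, 4),
        ONGOING_IMPLEMENTATION: Fraction(1, 4),
        NOT_IMPLEMENTED: Fraction(0),
    },
)


@dataclass(frozen=True)
class TierThresholds:
    """Constraints a function's ratings must meet at one designation tier.

    min_implemented
        Floor on the implemented fraction of the tier's pool.
    max_partial
        Cap on the fraction that is merely *in process* (partially implemented
        or, where the scale has it, ongoing implementation).
    max_not_implemented
        Cap on the not-implemented fraction (0 where the framework table
        shows "N/A").
    lower_tiers_full
        Whether every lower designation tier must be 100% implemented.
    pooled_with_lower
        Whether fractions are taken over the pool of this tier *plus all lower
        designation tiers* (the WHO ML2 rule) instead of this tier alone.
    """

    tier: str
    min_implemented: Fraction
    max_partial: Fraction
    max_not_implemented: Fraction
    lower_tiers_full: bool = True
    pooled_with_lower: bool = False


@dataclass(frozen=True)
class AlgorithmSpec:
    """A named classification algorithm: threshold rows plus flags."""

    name: str
    tiers: tuple[TierThresholds, ...]
    require_critical: bool = False


def _strict_rows(ladder: TierLadder) -> tuple[TierThresholds, ...]:
    return tuple(
        TierThresholds(t, Fraction(1), Fraction(0), Fraction(0), lower_tiers_full=True)
        for t in ladder.designation_tiers
    )


# Flexible thresholds for the veterinary profile: per-tier pools, lower tiers
# must always be fully implemented, and only Gold/Gold-plus tolerate any
# not-implemented items.
VMRA_FLEXIBLE_ROWS: tuple[TierThresholds, ...] = (
    TierThresholds("PRE_BRONZE", Fraction(1), Fraction(0), Fraction(0)),
    TierThresholds("BRONZE", Fraction(19, 20), Fraction(1, 20), Fraction(0)),
    TierThresholds("SILVER", Fraction(9, 10), Fraction(1, 10), Fraction(0)),
    TierThresholds("GOLD", Fraction(17, 20), Fraction(3, 20), Fraction(1, 20)),
    TierThresholds("GOLD_PLUS", Fraction(4, 5), Fraction(1, 5), Fraction(1, 10)),
)

# WHO flexible thresholds.  ML1 has no printed flexible rule and is taken as
# 100% of ML1 (same as strict).  ML2 is evaluated on the pooled ML1+ML2 set;
# the remainder must be in process of implementation, so the not-implemented
# cap is zero at every level.
WHO_FLEXIBLE_ROWS: tuple[TierThresholds, ...] = (
    TierThresholds("ML1", Fraction(1), Fraction(0), Fraction(0)),
    TierThresholds(
        "ML2",
        Fraction(19, 20),
        Fraction(1, 20),
        Fraction(0),
        lower_tiers_full=False,
        pooled_with_lower=True,
    ),
    TierThresholds("ML3", Fraction(9, 10), Fraction(1, 10), Fraction(0)),
    TierThresholds("ML4", Fraction(4, 5), Fraction(1, 5), Fraction(0)),
)


@dataclass(frozen=True)
class SubIndicator:
    """One atomic assessable requirement, designated to a maturity tier."""

    sub_id: str
    function_code: str
    indicator_code: str
    text: str
    designated_tier: str
    critical: bool = False
    institution_mandatory: bool = False


@dataclass(frozen=True)
class IndicatorDef:
    indicator_code: str
    name: str


@dataclass(frozen=True)
class FunctionDef:
    function_code: str
    name: str
    sub_indicators: tuple[SubIndicator, ...]


@dataclass(frozen=True)
class Catalog:
    """A complete assessment framework."""

    profile: str
    version: str
    tiers: TierLadder
    scale: RatingScale
    algorithms: Mapping[str, AlgorithmSpec]
    indicators: tuple[IndicatorDef, ...]
    functions: tuple[FunctionDef, ...]
    notes: str = ""

    def sub_indicators(self) -> Iterator[SubIndicator]:
        for fn in self.functions:
            yield from fn.sub_indicators

    def by_id(self) -> dict[str, SubIndicator]:
        return {s.sub_id: s for s in self.sub_indicators()}

    def function(self, function_code: str) -> FunctionDef:
        for fn in self.functions:
            if fn.function_code == function_code:
                return fn
        raise UnknownFunctionError(function_code)

    @property
    def function_codes(self) -> tuple[str, ...]:
        return tuple(fn.function_code for fn in self.functions)


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Finding:
    severity: str  # "error" | "warning"
    path: str
    message: str

    def to_json(self) -> str:
        return json.dumps(
            {"severity": self.severity, "path": self.path, "message": self.message}
        )


@dataclass(frozen=True)
class ValidationReport:
    findings: tuple[Finding, ...]

    @property
    def ok(self) -> bool:
        return not self.findings

    @property
    def errors(self) -> tuple[Finding, ...]:
        return tuple(f for f in self.findings if f.severity == "error")

    def to_jsonl(self) -> str:
        return "\n".join(f.to_json() for f in self.findings)


# Declared structural constants of the two reference profiles.
_PROFILE_EXPECTATIONS = {
    "vmra": {
        "functions": 8,
        "indicators": 13,
        "tier_counts": {
            "PRE_BRONZE": 6,
            "BRONZE": 21,
            "SILVER": 28,
            "GOLD": 154,
            "GOLD_PLUS": 26,
        },
        "total": 235,
    },
    "who-gbt": {"functions": 9, "indicators": 13, "total": 268},
}


def validate_catalog(catalog: Catalog, reference: bool = False) -> ValidationReport:
    """Check every catalog invariant; return findings rather than raising.

    With ``reference=True`` the profile's declared structural constants
    (function/indicator/sub-indicator counts) are additionally enforced.
    """
    findings: list[Finding] = []

    def err(path: str, message: str) -> None:
        findings.append(Finding("error", path, message))

    def warn(path: str, message: str) -> None:
        findings.append(Finding("warning", path, message))

    ladder = catalog.tiers
    indicator_codes = [i.indicator_code for i in catalog.indicators]
    if len(set(indicator_codes)) != len(indicator_codes):
        err("indicators", "duplicate indicator codes declared")
    if catalog.profile in _PROFILE_EXPECTATIONS:
        limit = _PROFILE_EXPECTATIONS[catalog.profile]["indicators"]
        if len(set(indicator_codes)) > limit:
            err(
                "indicators",
                f"profile {catalog.profile!r} declares at most {limit} indicators, "
                f"found {len(set(indicator_codes))}",
            )

    if not (IMPLEMENTED in catalog.scale.scores and NOT_IMPLEMENTED in catalog.scale.scores):
        err("scale", "scale must define IMPLEMENTED and NOT_IMPLEMENTED")
    else:
        if catalog.scale.scores[IMPLEMENTED] != 1:
            err("scale", "IMPLEMENTED must score 1")
        if catalog.scale.scores[NOT_IMPLEMENTED] != 0:
            err("scale", "NOT_IMPLEMENTED must score 0")
    for rating, score in catalog.scale.scores.items():
        if rating not in RATING_LADDER:
            err("scale", f"unknown rating {rating!r}")
        if not (0 <= score <= 1):
            err("scale", f"score of {rating} outside [0,1]")

    has_restricted = any(a.require_critical for a in catalog.algorithms.values())
    for name, alg in catalog.algorithms.items():
        seen_tiers = set()
        for row in alg.tiers:
            loc = f"algorithms.{name}.{row.tier}"
            if row.tier not in ladder.designation_tiers:
                err(loc, f"threshold row for non-designation tier {row.tier!r}")
            if row.tier in seen_tiers:
                err(loc, "duplicate threshold row")
            seen_tiers.add(row.tier)
            for label, frac in (
                ("min_implemented", row.min_implemented),
                ("max_partial", row.max_partial),
                ("max_not_implemented", row.max_not_implemented),
            ):
                if not (0 <= frac <= 1):
                    err(loc, f"{label} outside [0,1]")
        missing = set(ladder.designation_tiers) - seen_tiers
        if missing:
            err(f"algorithms.{name}", f"missing threshold rows for {sorted(missing)}")

    seen_ids: dict[str, str] = {}
    total = 0
    per_tier: dict[str, int] = {t: 0 for t in ladder.designation_tiers}
    seen_fn_codes = set()
    for fn in catalog.functions:
        floc = f"functions.{fn.function_code}"
        if fn.function_code in seen_fn_codes:
            err(floc, f"duplicate function code {fn.function_code!r}")
        seen_fn_codes.add(fn.function_code)
        if not fn.sub_indicators:
            err(floc, f"function {fn.function_code!r} has no sub-indicators")
        for sub in fn.sub_indicators:
            sloc = f"{floc}.{sub.sub_id}"
            total += 1
            if sub.sub_id in seen_ids:
                err(
                    sloc,
                    f"duplicate sub-indicator id {sub.sub_id!r} "
                    f"(also in function {seen_ids[sub.sub_id]!r})",
                )
            else:
                seen_ids[sub.sub_id] = fn.function_code
            if sub.function_code != fn.function_code:
                err(sloc, "sub-indicator function_code does not match its function")
            if sub.designated_tier not in ladder.designation_tiers:
                err(sloc, f"unknown or floor designation tier {sub.designated_tier!r}")
            else:
                per_tier[sub.designated_tier] += 1
            if sub.indicator_code not in indicator_codes:
                err(sloc, f"undeclared indicator code {sub.indicator_code!r}")
            if sub.critical and not has_restricted:
                err(
                    sloc,
                    "critical flag set but no algorithm of this profile "
                    "enforces critical sub-indicators",
                )

    if reference and catalog.profile in _PROFILE_EXPECTATIONS:
        exp = _PROFILE_EXPECTATIONS[catalog.profile]
        if len(catalog.functions) != exp["functions"]:
            err("functions", f"expected {exp['functions']} functions, found {len(catalog.functions)}")
        if total != exp["total"]:
            err("functions", f"count mismatch: expected {exp['total']} sub-indicators, found {total}")
        for tier, n in exp.get("tier_counts", {}).items():
            if per_tier.get(tier, 0) != n:
                err(
                    f"functions.{tier}",
                    f"count mismatch: expected {n} sub-indicators at {tier}, "
                    f"found {per_tier.get(tier, 0)}",
                )

    return ValidationReport(tuple(findings))


def tier_counts(
    catalog: Catalog, function_code: str | None = None
) -> dict[str, int]:
    """Count sub-indicators by designated tier, catalog-wide or per function.

    All designation tiers are present in the result (zero where empty);
    the values sum to the relevant sub-indicator total.
    """
    if function_code is None:
        subs: Sequence[SubIndicator] = list(catalog.sub_indicators())
    else:
        subs = catalog.function(function_code).sub_indicators
    counts = {t: 0 for t in catalog.tiers.designation_tiers}
    for sub in subs:
        counts[sub.designated_tier] += 1
    return counts


# ---------------------------------------------------------------------------
# File format (YAML dialect, versioned; unknown fields rejected)
# ---------------------------------------------------------------------------

def _frac_to_text(f: Fraction) -> str:
    return str(f.numerator) if f.denominator == 1 else f"{f.numerator}/{f.denominator}"

def _frac_from_text(value: object, where: str) -> Fraction:
    try:
        if isinstance(value, bool):
            raise ValueError
        if isinstance(value, int):
            return Fraction(value)
        if isinstance(value, str):
            return Fraction(value)
    except (ValueError, ZeroDivisionError):
        pass
    raise CatalogParseError(f"{where}: expected an exact fraction like '19/20', got {value!r}")


def _require_keys(mapping: Mapping, allowed: set[str], required: set[str], where: str) -> None:
    if not isinstance(mapping, Mapping):
        raise CatalogParseError(f"{where}: expected a mapping")
    unknown = set(mapping) - allowed
    if unknown:
        raise CatalogParseError(f"{where}: unknown fields {sorted(unknown)}")
    missing = required - set(mapping)
    if missing:
        raise CatalogParseError(f"{where}: missing required fields {sorted(missing)}")


def dumps_catalog(catalog: Catalog) -> str:
    """Serialise a catalog to the versioned YAML dialect (round-trip exact)."""
    doc: dict = {
        "format_version": CATALOG_FORMAT_VERSION,
        "profile": catalog.profile,
        "version": catalog.version,
        "tiers": list(catalog.tiers.names),
        "tier_labels": dict(catalog.tiers.display),
        "scale": {r: _frac_to_text(s) for r, s in catalog.scale.scores.items()},
        "algorithms": {
            name: {
                "require_critical": alg.require_critical,
                "tiers": [
                    {
                        "tier": row.tier,
                        "min_implemented": _frac_to_text(row.min_implemented),
                        "max_partial": _frac_to_text(row.max_partial),
                        "max_not_implemented": _frac_to_text(row.max_not_implemented),
                        "lower_tiers_full": row.lower_tiers_full,
                        "pooled_with_lower": row.pooled_with_lower,
                    }
                    for row in alg.tiers
                ],
            }
            for name, alg in catalog.algorithms.items()
        },
        "indicators": [
            {"code": i.indicator_code, "name": i.name} for i in catalog.indicators
        ],
        "functions": [
            {
                "code": fn.function_code,
                "name": fn.name,
                "sub_indicators": [
                    {
                        "id": s.sub_id,
                        "indicator": s.indicator_code,
                        "tier": s.designated_tier,
                        "text": s.text,
                        "critical": s.critical,
                        "mandatory": s.institution_mandatory,
                    }
                    for s in fn.sub_indicators
                ],
            }
            for fn in catalog.functions
        ],
    }
    if catalog.notes:
        doc["notes"] = catalog.notes
    return yaml.safe_dump(doc, sort_keys=False, allow_unicode=True)


def loads_catalog(text: str, source: str = "<string>") -> Catalog:
    """Parse and validate a catalog document; raise on any violation."""
    try:
        doc = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise CatalogParseError(f"{source}: not valid YAML: {exc}") from exc

    _require_keys(
        doc,
        allowed={
            "format_version", "profile", "version", "tiers", "tier_labels",
            "scale", "algorithms", "indicators", "functions", "notes",
        },
        required={"format_version", "profile", "scale", "algorithms", "indicators", "functions"},
        where=source,
    )
    if doc["format_version"] != CATALOG_FORMAT_VERSION:
        raise CatalogParseError(
            f"{source}: unsupported format_version {doc['format_version']!r}"
        )
    profile = str(doc["profile"])

    if "tiers" in doc:
        names = tuple(str(t) for t in doc["tiers"])
        if len(names) < 2 or len(set(names)) != len(names):
            raise CatalogParseError(f"{source}: tiers must be >=2 distinct names")
        labels = {str(k): str(v) for k, v in (doc.get("tier_labels") or {}).items()}
        ladder = TierLadder(names, labels or {n: n for n in names})
    elif profile in _PROFILE_LADDERS:
        ladder = _PROFILE_LADDERS[profile]
    else:
        raise CatalogParseError(
            f"{source}: custom profile {profile!r} must declare its 'tiers' ladder"
        )

    scale_doc = doc["scale"]
    if not isinstance(scale_doc, Mapping) or not scale_doc:
        raise CatalogParseError(f"{source}: scale must be a non-empty mapping")
    scores = {
        str(r): _frac_from_text(v, f"{source}: scale.{r}") for r, v in scale_doc.items()
    }
    scale = RatingScale(profile=profile, scores=scores)

    algorithms: dict[str, AlgorithmSpec] = {}
    if not isinstance(doc["algorithms"], Mapping):
        raise CatalogParseError(f"{source}: algorithms must be a mapping")
    for name, alg_doc in doc["algorithms"].items():
        _require_keys(
            alg_doc,
            allowed={"require_critical", "tiers"},
            required={"tiers"},
            where=f"{source}: algorithms.{name}",
        )
        rows = []
        for i, row in enumerate(alg_doc["tiers"]):
            where = f"{source}: algorithms.{name}.tiers[{i}]"
            _require_keys(
                row,
                allowed={
                    "tier", "min_implemented", "max_partial",
                    "max_not_implemented", "lower_tiers_full", "pooled_with_lower",
                },
                required={"tier", "min_implemented", "max_partial", "max_not_implemented"},
                where=where,
            )
            rows.append(
                TierThresholds(
                    tier=str(row["tier"]),
                    min_implemented=_frac_from_text(row["min_implemented"], where),
                    max_partial=_frac_from_text(row["max_partial"], where),
                    max_not_implemented=_frac_from_text(row["max_not_implemented"], where),
                    lower_tiers_full=bool(row.get("lower_tiers_full", True)),
                    pooled_with_lower=bool(row.get("pooled_with_lower", False)),
                )
            )
        rows.sort(key=lambda r: ladder.index(r.tier) if r.tier in ladder else 99)
        algorithms[str(name)] = AlgorithmSpec(
            name=str(name),
            tiers=tuple(rows),
            require_critical=bool(alg_doc.get("require_critical", False)),
        )

    indicators = []
    for i, ind in enumerate(doc["indicators"]):
        _require_keys(ind, {"code", "name"}, {"code", "name"}, f"{source}: indicators[{i}]")
        indicators.append(IndicatorDef(str(ind["code"]), str(ind["name"])))

    functions = []
    for i, fn_doc in enumerate(doc["functions"]):
        _require_keys(
            fn_doc,
            {"code", "name", "sub_indicators"},
            {"code", "name", "sub_indicators"},
            f"{source}: functions[{i}]",
        )
        subs = []
        for j, s in enumerate(fn_doc["sub_indicators"]):
            where = f"{source}: functions[{i}].sub_indicators[{j}]"
            _require_keys(
                s,
                {"id", "indicator", "tier", "text", "critical", "mandatory"},
                {"id", "indicator", "tier"},
                where,
            )
            subs.append(
                SubIndicator(
                    sub_id=str(s["id"]),
                    function_code=str(fn_doc["code"]),
                    indicator_code=str(s["indicator"]),
                    text=str(s.get("text", "")),
                    designated_tier=str(s["tier"]),
                    critical=bool(s.get("critical", False)),
                    institution_mandatory=bool(s.get("mandatory", False)),
                )
            )
        functions.append(
            FunctionDef(str(fn_doc["code"]), str(fn_doc["name"]), tuple(subs))
        )

    catalog = Catalog(
        profile=profile,
        version=str(doc.get("version", "1")),
        tiers=ladder,
        scale=scale,
        algorithms=algorithms,
        indicators=tuple(indicators),
        functions=tuple(functions),
        notes=str(doc.get("notes", "")),
    )
    report = validate_catalog(catalog)
    if report.errors:
        raise CatalogValidationError(ValidationReport(report.errors))
    return catalog


def load_catalog(path: str | Path) -> Catalog:
    path = Path(path)
    return loads_catalog(path.read_text(encoding="utf-8"), source=str(path))


def write_catalog(catalog: Catalog, path: str | Path) -> None:
    Path(path).write_text(dumps_catalog(catalog), encoding="utf-8")


# ---------------------------------------------------------------------------
# Reference catalogs
# ---------------------------------------------------------------------------

_VMRA_FUNCTIONS = (
    ("VRS", "Veterinary Medicines Regulatory Systems"),
    ("VMA", "Veterinary Medicines Registration and Marketing Authorisation"),
    ("VPV", "Veterinary Medicines Pharmacovigilance"),
    ("VMC", "Veterinary Medicines Market Surveillance and Control"),
    ("VLI", "Veterinary Medicines Licensing Establishments"),
    ("VRI", "Veterinary Medicines Regulatory Inspection"),
    ("VLT", "Veterinary Medicines Laboratory Testing"),
    ("VBR", "Veterinary Medicines Batch Release"),
)

_WHO_FUNCTIONS = (
    ("RS", "National Regulatory System"),
    ("MA", "Registration and Marketing Authorisation"),
    ("VL", "Vigilance"),
    ("MC", "Market Surveillance and Control"),
    ("LI", "Licensing Establishments"),
    ("RI", "Regulatory Inspection"),
    ("LT", "Laboratory Testing"),
    ("CT", "Clinical Trials Oversight"),
    ("LR", "NRA Lot Release"),
)

_INDICATORS = (
    ("I01", "Legal provisions, regulations, and guidelines"),
    ("I02", "Organisation and governance"),
    ("I03", "Policy and strategic planning"),
    ("I04", "Leadership and crisis management"),
    ("I05", "Transparency, accountability, and communication"),
    ("I06", "Financial resources"),
    ("I07", "Management of outsourced activities"),
    ("I08", "Quality and risk management system"),
    ("I09", "Regulatory process"),
    ("I10", "Human resources"),
    ("I11", "Monitoring progress and assessing impact"),
    ("I12", "Laboratory services"),
    ("I13", "Infrastructure and equipment"),
)

# The six Pre-bronze requirements: minimum operating capability.  Three legal-
# foundation items, an established funding source, published agency contacts,
# and an up-to-date list of products permitted on the national market.
_PRE_BRONZE_ITEMS = (
    ("I01", "Legal foundation: primary legislation establishing the national "
            "veterinary medicines regulatory authority and its mandate."),
    ("I01", "Legal foundation: legal provisions requiring authorisation of "
            "veterinary medicinal products before marketing."),
    ("I01", "Legal foundation: legal provisions empowering the authority to "
            "enforce veterinary medicines regulation."),
    ("I06", "An established source of funding for the regulatory authority."),
    ("I05", "Information on agency contacts for regulatory services is "
            "publicly available."),
    ("I05", "An up-to-date list of veterinary medicines permitted on the "
            "national market is published."),
)

# Per-function counts for the non-Pre-bronze tiers of the veterinary reference
# catalog.  The per-tier totals (21/28/154/26) are fixed framework constants;
# the split across functions is a documented editorial choice.
_VMRA_DISTRIBUTION = {
    #          B  S   G   GP
    "VRS": (6, 7, 24, 5),
    "VMA": (3, 4, 22, 4),
    "VPV": (2, 3, 19, 3),
    "VMC": (2, 3, 19, 3),
    "VLI": (2, 3, 18, 3),
    "VRI": (2, 3, 18, 3),
    "VLT": (2, 3, 17, 3),
    "VBR": (2, 2, 17, 2),
}

# Synthetic (non-normative) spread of the 268 WHO sub-indicators over ML1-ML4.
_WHO_DISTRIBUTION = {
    #         ML1 ML2 ML3 ML4
    "RS": (4, 6, 14, 8),
    "MA": (4, 6, 14, 8),
    "VL": (4, 6, 14, 8),
    "MC": (3, 6, 13, 8),
    "LI": (3, 6, 13, 8),
    "RI": (3, 5, 13, 7),
    "LT": (3, 5, 13, 7),
    "CT": (3, 5, 13, 7),
    "LR": (3, 5, 13, 7),
}

_TIER_ABBREV = {
    "PRE_BRONZE": "PB", "BRONZE": "B", "SILVER": "S", "GOLD": "G", "GOLD_PLUS": "GP",
    "ML1": "ML1", "ML2": "ML2", "ML3": "ML3", "ML4": "ML4",
}


def _placeholder_subs(
    function_code: str,
    tier: str,
    n: int,
    start_indicator: int,
    critical_ids: set[str] | None = None,
) -> list[SubIndicator]:
    subs = []
    abbrev = _TIER_ABBREV[tier]
    for k in range(1, n + 1):
        ind = _INDICATORS[(start_indicator + k - 1) % len(_INDICATORS)][0]
        sub_id = f"{function_code}-{abbrev}-{k:02d}"
        subs.append(
            SubIndicator(
                sub_id=sub_id,
                function_code=function_code,
                indicator_code=ind,
                text=(
                    f"Placeholder requirement {sub_id}: {tier.replace('_', ' ').title()}"
                    f"-level expectation for {function_code} under indicator {ind}."
                ),
                designated_tier=tier,
                critical=bool(critical_ids and sub_id in critical_ids),
            )
        )
    return subs


def _build_vmra_reference() -> Catalog:
    functions = []
    for fi, (code, name) in enumerate(_VMRA_FUNCTIONS):
        subs: list[SubIndicator] = []
        if code == "VRS":
            for k, (ind, text) in enumerate(_PRE_BRONZE_ITEMS, start=1):
                subs.append(
                    SubIndicator(
                        sub_id=f"VRS-PB-{k:02d}",
                        function_code="VRS",
                        indicator_code=ind,
                        text=text,
                        designated_tier="PRE_BRONZE",
                        critical=True,
                        institution_mandatory=True,
                    )
                )
        b, s, g, gp = _VMRA_DISTRIBUTION[code]
        # Placeholder critical set: the first Gold item of every function
        # (in VMA this is the clinical-field-trials requirement below).
        critical_ids = {f"{code}-G-01"}
        subs += _placeholder_subs(code, "BRONZE", b, fi, critical_ids)
        subs += _placeholder_subs(code, "SILVER", s, fi + 3, critical_ids)
        gold = _placeholder_subs(code, "GOLD", g, fi + 5, critical_ids)
        if code == "VMA":
            # The clinical-trials function of the human-medicines scheme is
            # replaced by a single critical sub-indicator on field trials.
            gold[0] = replace(
                gold[0],
                text=(
                    "Legal provisions and oversight for veterinary clinical "
                    "field trials (critical; replaces a dedicated clinical "
                    "trials function)."
                ),
            )
        subs += gold
        subs += _placeholder_subs(code, "GOLD_PLUS", gp, fi + 7, critical_ids=None)
        functions.append(FunctionDef(code, name, tuple(subs)))

    algorithms = {
        "strict": AlgorithmSpec("strict", _strict_rows(VMRA_LADDER)),
        "flexible": AlgorithmSpec("flexible", VMRA_FLEXIBLE_ROWS),
        "restricted": AlgorithmSpec("restricted", VMRA_FLEXIBLE_ROWS, require_critical=True),
    }
    return Catalog(
        profile="vmra",
        version="1.0",
        tiers=VMRA_LADDER,
        scale=VMRA_SCALE,
        algorithms=algorithms,
        indicators=tuple(IndicatorDef(c, n) for c, n in _INDICATORS),
        functions=tuple(functions),
        notes=(
            "Reference skeleton of the veterinary medicines self-assessment "
            "framework. Sub-indicator texts are structured placeholders; "
            "critical and mandatory flags beyond the six Pre-bronze items are "
            "an editable placeholder set."
        ),
    )


def _build_who_reference() -> Catalog:
    functions = []
    for fi, (code, name) in enumerate(_WHO_FUNCTIONS):
        subs: list[SubIndicator] = []
        counts = _WHO_DISTRIBUTION[code]
        for tier, n in zip(("ML1", "ML2", "ML3", "ML4"), counts):
            subs += _placeholder_subs(code, tier, n, fi + 2 * int(tier[-1]))
        functions.append(FunctionDef(code, name, tuple(subs)))
    algorithms = {
        "strict": AlgorithmSpec("strict", _strict_rows(WHO_LADDER)),
        "flexible": AlgorithmSpec("flexible", WHO_FLEXIBLE_ROWS),
    }
    return Catalog(
        profile="who-gbt",
        version="1.0",
        tiers=WHO_LADDER,
        scale=WHO_SCALE,
        algorithms=algorithms,
        indicators=tuple(IndicatorDef(c, n) for c, n in _INDICATORS),
        functions=tuple(functions),
        notes=(
            "Skeleton of the WHO Global Benchmarking Tool profile. The spread "
            "of the 268 sub-indicators across maturity levels is synthetic "
            "and non-normative; only the totals and the rating/threshold "
            "scheme are framework constants."
        ),
    )


def reference_catalog(profile: str = "vmra") -> Catalog:
    """Build a bundled reference catalog ("vmra" or "who-gbt")."""
    if profile == "vmra":
        return _build_vmra_reference()
    if profile == "who-gbt":
        return _build_who_reference()
    raise CatalogError(f"no reference catalog for profile {profile!r}")


def catalog_schema() -> dict:
    """The shipped JSON description of the catalog file dialect."""
    text = resources.files("vmrasat.schemas").joinpath("catalog_schema.json").read_text()
    return json.loads(text)
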