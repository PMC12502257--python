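"""Assessment responses and score arithmetic.

An :class:`Assessment` maps sub-indicator ids to ratings (with an evidence
note and a date).  Scores are exact rationals: Implemented is always 1,
Not implemented always 0, and the in-between ratings carry the profile's
values (0.5 for the veterinary scale, 0.75 / 0.25 for the WHO scale).
Not-applicable responses are excluded from every numerator and denominator,
signalled by the :data:`EXCLUDED` sentinel rather than any number.

A sub-indicator with no recorded response is treated as Not implemented and
a warning is logged — conservative, and it never inflates a score.
"""

from __future__ import annotations

import csv
import io
import logging
from dataclasses import dataclass
from datetime import date
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple

from .catalog import (
    IMPLEMENTED,
    NOT_APPLICABLE,
    NOT_IMPLEMENTED,
    ONGOING_IMPLEMENTATION,
    PARTIALLY_IMPLEMENTED,
    RATING_LADDER,
    Catalog,
    RatingScale,
)

__all__ = [
    "EXCLUDED",
    "RatingNotAllowedError",
    "Response",
    "Assessment",
    "score_rating",
    "FunctionScore",
    "function_score",
    "TierCount",
    "TierTally",
    "tally",
    "read_responses_csv",
    "write_responses_csv",
]

logger = logging.getLogger("vmrasat")


class _Excluded:
    """Sentinel for a quantity with no numeric value (all inputs were N/A)."""

    _instance = None

    def __new__(cls) -> "_Excluded":
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:
        return "EXCLUDED"


EXCLUDED = _Excluded()


class RatingNotAllowedError(ValueError):
    """A rating is not part of the active profile's scale."""


@dataclass(frozen=True)
class Response:
    rating: str
    evidence: str = ""
    assessed_on: date | None = None


@dataclass(frozen=True)
class Assessment:
    """A set of responses against one catalog (profile + version)."""

    catalog_profile: str
    catalog_version: str
    responses: Mapping[str, Response]

    def rating_of(self, sub_id: str) -> str:
        """The effective rating: missing responses count as Not implemented."""
        resp = self.responses.get(sub_id)
        return resp.rating if resp is not None else NOT_IMPLEMENTED

    def missing_ids(self, catalog: Catalog) -> tuple[str, ...]:
        return tuple(
            s.sub_id for s in catalog.sub_indicators() if s.sub_id not in self.responses
        )

    def unknown_ids(self, catalog: Catalog) -> tuple[str, ...]:
        known = {s.sub_id for s in catalog.sub_indicators()}
        return tuple(i for i in self.responses if i not in known)

    def validate_against(self, catalog: Catalog) -> None:
        """Raise if a response refers to an unknown sub-indicator or uses a
        rating outside the catalog's scale; warn about missing responses."""
        unknown = self.unknown_ids(catalog)
        if unknown:
            raise KeyError(
                f"responses refer to sub-indicators not in the catalog: {list(unknown)[:5]}"
            )
        for sub_id, resp in self.responses.items():
            if not catalog.scale.allows(resp.rating):
                raise RatingNotAllowedError(
                    f"{sub_id}: rating {resp.rating!r} not allowed by the "
                    f"{catalog.profile!r} scale"
                )
        missing = self.missing_ids(catalog)
        if missing:
            logger.warning(
                "%d sub-indicator(s) have no response and are treated as "
                "NOT_IMPLEMENTED (first: %s)",
                len(missing),
                missing[0],
            )


def score_rating(rating: str, scale: RatingScale) -> Fraction | _Excluded:
    """Numeric score of one rating under a scale; N/A returns EXCLUDED."""
    if rating == NOT_APPLICABLE:
        return EXCLUDED
    if rating not in scale.scores:
        raise RatingNotAllowedError(
            f"rating {rating!r} not allowed by the {scale.profile!r} scale"
        )
    return scale.scores[rating]


class FunctionScore(NamedTuple):
    score: Fraction | _Excluded
    applicable_count: int


def function_score(
    assessment: Assessment, catalog: Catalog, function_code: str
) -> FunctionScore:
    """Arithmetic mean score over the applicable sub-indicators of a function.

    Returns (EXCLUDED, 0) when every response is Not applicable.  Exact
    rational arithmetic throughout.
    """
    fn = catalog.function(function_code)
    total = Fraction(0)
    n = 0
    for sub in fn.sub_indicators:
        s = score_rating(assessment.rating_of(sub.sub_id), catalog.scale)
        if s is EXCLUDED:
            continue
        total += s
        n += 1
    if n == 0:
        return FunctionScore(EXCLUDED, 0)
    return FunctionScore(total / n, n)


@dataclass(frozen=True)
class TierCount:
    """Rating counts among the applicable sub-indicators of one tier."""

    implemented: int = 0
    partial: int = 0
    ongoing: int = 0
    not_implemented: int = 0

    @property
    def applicable(self) -> int:
        return self.implemented + self.partial + self.ongoing + self.not_implemented

    @property
    def in_process(self) -> int:
        """Partially implemented or ongoing implementation."""
        return self.partial + self.ongoing


@dataclass(frozen=True)
class TierTally:
    """Per-designation-tier rating counts for one function."""

    function_code: str
    counts: Mapping[str, TierCount]

    def pooled(self, tiers: Iterable[str]) -> TierCount:
        imp = par = ong = ni = 0
        for t in tiers:
            c = self.counts[t]
            imp += c.implemented
            par += c.partial
            ong += c.ongoing
            ni += c.not_implemented
        return TierCount(imp, par, ong, ni)


def tally(assessment: Assessment, catalog: Catalog, function_code: str) -> TierTally:
    """Count ratings per designation tier for one function (N/A excluded)."""
    fn = catalog.function(function_code)
    missing = [s.sub_id for s in fn.sub_indicators if s.sub_id not in assessment.responses]
    if missing:
        logger.warning(
            "function %s: %d missing response(s) counted as NOT_IMPLEMENTED",
            function_code,
            len(missing),
        )
    acc: dict[str, dict[str, int]] = {
        t: {"i": 0, "p": 0, "o": 0, "n": 0} for t in catalog.tiers.designation_tiers
    }
    for sub in fn.sub_indicators:
        rating = assessment.rating_of(sub.sub_id)
        if rating == NOT_APPLICABLE:
            continue
        if rating not in catalog.scale.scores:
            raise RatingNotAllowedError(
                f"{sub.sub_id}: rating {rating!r} not allowed by the "
                f"{catalog.profile!r} scale"
            )
        slot = {
            IMPLEMENTED: "i",
            PARTIALLY_IMPLEMENTED: "p",
            ONGOING_IMPLEMENTATION: "o",
            NOT_IMPLEMENTED: "n",
        }[rating]
        acc[sub.designated_tier][slot] += 1
    return TierTally(
        function_code=function_code,
        counts={
            t: TierCount(v["i"], v["p"], v["o"], v["n"]) for t, v in acc.items()
        },
    )


# ---------------------------------------------------------------------------
# Response file I/O (CSV: sub_indicator_id, rating, evidence, assessed_on)
# ---------------------------------------------------------------------------

_CSV_FIELDS = ("sub_indicator_id", "rating", "evidence", "assessed_on")

_RATING_TOKENS = {r.lower(): r for r in RATING_LADDER + (NOT_APPLICABLE,)}
# Friendlier spellings accepted on input.
_RATING_TOKENS.update(
    {
        "implemented": IMPLEMENTED,
        "partially implemented": PARTIALLY_IMPLEMENTED,
        "ongoing implementation": ONGOING_IMPLEMENTATION,
        "not implemented": NOT_IMPLEMENTED,
        "not applicable": NOT_APPLICABLE,
        "na": NOT_APPLICABLE,
        "n/a": NOT_APPLICABLE,
    }
)


def parse_rating_token(token: str) -> str:
    key = token.strip().lower().replace("-", " ")
    key_us = key.replace(" ", "_")
    if key in _RATING_TOKENS:
        return _RATING_TOKENS[key]
    if key_us in _RATING_TOKENS:
        return _RATING_TOKENS[key_us]
    raise RatingNotAllowedError(f"unrecognised rating token {token!r}")


def read_responses_csv(
    path_or_text: str | Path, catalog: Catalog | None = None
) -> Assessment:
    """Read a response table; rating tokens are case-insensitive.

    When *catalog* is given the assessment is validated against it.
    """
    if isinstance(path_or_text, Path) or "\n" not in str(path_or_text):
        text = Path(path_or_text).read_text(encoding="utf-8")
    else:
        text = str(path_or_text)
    reader = csv.DictReader(io.StringIO(text))
    if reader.fieldnames is None or set(reader.fieldnames) != set(_CSV_FIELDS):
        raise ValueError(
            f"response file must have columns {_CSV_FIELDS}, got {reader.fieldnames}"
        )
    responses: dict[str, Response] = {}
    for i, row in enumerate(reader, start=2):
        sub_id = row["sub_indicator_id"].strip()
        if not sub_id:
            raise ValueError(f"line {i}: empty sub_indicator_id")
        if sub_id in responses:
            raise ValueError(f"line {i}: duplicate response for {sub_id!r}")
        assessed = row.get("assessed_on") or ""
        responses[sub_id] = Response(
            rating=parse_rating_token(row["rating"]),
            evidence=row.get("evidence") or "",
            assessed_on=date.fromisoformat(assessed) if assessed else None,
        )
    assessment = Assessment(
        catalog_profile=catalog.profile if catalog else "",
        catalog_version=catalog.version if catalog else "",
        responses=responses,
    )
    if catalog is not None:
        assessment.validate_against(catalog)
    return assessment


def write_responses_csv(assessment: Assessment, path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.DictWriter(fh, fieldnames=_CSV_FIELDS)
        writer.writeheader()
        for sub_id in sorted(assessment.responses):
            resp = assessment.responses[sub_id]
            writer.writerow(
                {
                    "sub_indicator_id": sub_id,
                    "rating": resp.rating,
                    "evidence": resp.evidence,
                    "assessed_on": resp.assessed_on.isoformat() if resp.assessed_on else "",
                }
            )
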