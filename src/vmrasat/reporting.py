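"""Assessment reports.

``build_report`` assembles engine outputs (scores, tallies, per-function and
institution classifications, IDP summary counts) into a single structure;
``render`` serialises it to JSON, CSV or Markdown.  Rendering performs no
arithmetic: every number in a report is an engine output, with exact
rationals kept as numerator/denominator pairs in JSON and shown to one
decimal place as percentages in the human-readable formats.
"""

from __future__ import annotations

import csv
import io
import json
from dataclasses import dataclass
from fractions import Fraction
from importlib import resources

from .catalog import Catalog
from .engine import InstitutionResult, classify_institution
from .idp import extract_gaps
from .ratings import EXCLUDED, Assessment, FunctionScore, TierTally, function_score, tally

__all__ = ["Report", "build_report", "render", "report_from_json", "validate_report_doc"]

_FORMATS = ("json", "csv", "markdown")


def _frac_doc(f: Fraction) -> dict:
    return {"num": f.numerator, "den": f.denominator}


def _frac_from_doc(doc: dict) -> Fraction:
    return Fraction(doc["num"], doc["den"])


def _pct(f: Fraction | None) -> str:
    return "n/a" if f is None else f"{float(f) * 100:.1f}%"


@dataclass(frozen=True)
class FunctionReport:
    function_code: str
    name: str
    score: Fraction | None  # None when every response is not applicable
    applicable_count: int
    tally: TierTally
    result_doc: dict  # MaturityResult.to_dict()


@dataclass(frozen=True)
class Report:
    metadata: dict
    functions: tuple[FunctionReport, ...]
    institution: dict  # InstitutionResult.to_dict() minus per-function detail
    idp_summary: dict

    def to_dict(self) -> dict:
        return {
            "metadata": dict(self.metadata),
            "functions": [
                {
                    "function_code": fr.function_code,
                    "name": fr.name,
                    "score": None if fr.score is None else _frac_doc(fr.score),
                    "applicable_count": fr.applicable_count,
                    "tally": {
                        tier: {
                            "implemented": c.implemented,
                            "partial": c.partial,
                            "ongoing": c.ongoing,
                            "not_implemented": c.not_implemented,
                            "applicable": c.applicable,
                        }
                        for tier, c in fr.tally.counts.items()
                    },
                    "result": fr.result_doc,
                }
                for fr in self.functions
            ],
            "institution": dict(self.institution),
            "idp_summary": dict(self.idp_summary),
        }


def build_report(
    assessment: Assessment,
    catalog: Catalog,
    algorithm: str = "flexible",
    agency: str = "",
    assessment_date: str = "",
) -> Report:
    """Assemble a complete report; deterministic given its inputs."""
    inst: InstitutionResult = classify_institution(assessment, catalog, algorithm)
    by_code = {r.function_code: r for r in inst.functions}
    functions = []
    for fn in catalog.functions:
        fs: FunctionScore = function_score(assessment, catalog, fn.function_code)
        functions.append(
            FunctionReport(
                function_code=fn.function_code,
                name=fn.name,
                score=None if fs.score is EXCLUDED else fs.score,
                applicable_count=fs.applicable_count,
                tally=tally(assessment, catalog, fn.function_code),
                result_doc=by_code[fn.function_code].to_dict(),
            )
        )
    gaps = extract_gaps(assessment, catalog, algorithm)
    idp_summary = {
        "total_gaps": len(gaps),
        "blocking": sum(1 for g in gaps if g.blocking),
        "critical": sum(1 for g in gaps if g.critical),
    }
    institution_doc = inst.to_dict()
    institution_doc.pop("functions")
    institution_doc["institution_qualifier"] = (
        f"{catalog.tiers.label(inst.institution_tier)} ({algorithm})"
    )
    return Report(
        metadata={
            "agency": agency,
            "date": assessment_date,
            "profile": catalog.profile,
            "catalog_version": catalog.version,
            "algorithm": algorithm,
            "tiers": list(catalog.tiers.names),
            "tier_labels": {t: catalog.tiers.label(t) for t in catalog.tiers.names},
        },
        functions=tuple(functions),
        institution=institution_doc,
        idp_summary=idp_summary,
    )


def render(report: Report, format: str = "json") -> str:
    """Serialise a report; JSON is validated against the shipped schema."""
    if format not in _FORMATS:
        raise ValueError(f"unknown format {format!r} (supported: {_FORMATS})")
    doc = report.to_dict()
    if format == "json":
        validate_report_doc(doc)
        return json.dumps(doc, indent=2, sort_keys=True)
    if format == "csv":
        out = io.StringIO()
        writer = csv.writer(out)
        writer.writerow(
            ["function_code", "name", "score", "applicable_count",
             "achieved_tier", "qualifier"]
        )
        for fr in report.functions:
            writer.writerow(
                [
                    fr.function_code,
                    fr.name,
                    "" if fr.score is None else _pct(fr.score),
                    fr.applicable_count,
                    fr.result_doc["achieved_tier"],
                    fr.result_doc["qualifier"],
                ]
            )
        return out.getvalue()
    return _render_markdown(report)


def _render_markdown(report: Report) -> str:
    md = report.metadata
    lines = [
        "# Maturity assessment report",
        "",
        f"- Agency: {md['agency'] or '(unnamed)'}",
        f"- Date: {md['date'] or '(unspecified)'}",
        f"- Profile: {md['profile']} (catalog version {md['catalog_version']})",
        f"- Algorithm: {md['algorithm']}",
        "",
        "Maturity ladder: "
        + " < ".join(md["tier_labels"][t] for t in md["tiers"][1:]),
        "",
        "## Functions",
        "",
        "| Function | Score | Applicable | Maturity |",
        "|---|---|---|---|",
    ]
    for fr in report.functions:
        lines.append(
            f"| {fr.function_code} — {fr.name} | {_pct(fr.score)} "
            f"| {fr.applicable_count} | {fr.result_doc['qualifier']} |"
        )
    inst = report.institution
    lines += [
        "",
        "## Institution",
        "",
        f"- Overall maturity: **{inst['institution_qualifier']}**",
    ]
    if inst["mandatory_failures"]:
        lines.append(
            "- Mandatory sub-indicators not implemented: "
            + ", ".join(inst["mandatory_failures"])
        )
    idp = report.idp_summary
    lines += [
        "",
        "## Development plan summary",
        "",
        f"- Gaps: {idp['total_gaps']} (blocking: {idp['blocking']}, "
        f"critical: {idp['critical']})",
        "",
    ]
    return "\n".join(lines)


def report_from_json(text: str) -> Report:
    """Re-parse a JSON render into an equal Report."""
    doc = json.loads(text)
    validate_report_doc(doc)
    from .ratings import TierCount  # local import to avoid a cycle at module load

    functions = []
    for f in doc["functions"]:
        functions.append(
            FunctionReport(
                function_code=f["function_code"],
                name=f["name"],
                score=None if f["score"] is None else _frac_from_doc(f["score"]),
                applicable_count=f["applicable_count"],
                tally=TierTally(
                    function_code=f["function_code"],
                    counts={
                        tier: TierCount(
                            implemented=c["implemented"],
                            partial=c["partial"],
                            ongoing=c["ongoing"],
                            not_implemented=c["not_implemented"],
                        )
                        for tier, c in f["tally"].items()
                    },
                ),
                result_doc=f["result"],
            )
        )
    return Report(
        metadata=doc["metadata"],
        functions=tuple(functions),
        institution=doc["institution"],
        idp_summary=doc["idp_summary"],
    )


def _schema() -> dict:
    text = resources.files("vmrasat.schemas").joinpath("report_schema.json").read_text()
    return json.loads(text)


def validate_report_doc(doc: dict) -> None:
    """Structural validation of a report document against the shipped schema.

    Enforces required keys and primitive types at each level (a purposely
    small checker: the schema file is the normative description).
    """
    schema = _schema()

    def check(obj, node, path):
        t = node.get("type")
        if t == "object":
            if not isinstance(obj, dict):
                raise ValueError(f"{path}: expected object")
            for key, sub in node.get("properties", {}).items():
                if key in node.get("required", []) and key not in obj:
                    raise ValueError(f"{path}: missing required key {key!r}")
                if key in obj:
                    check(obj[key], sub, f"{path}.{key}")
        elif t == "array":
            if not isinstance(obj, list):
                raise ValueError(f"{path}: expected array")
            for i, item in enumerate(obj):
                check(item, node.get("items", {}), f"{path}[{i}]")
        elif t == "integer":
            if not isinstance(obj, int) or isinstance(obj, bool):
                raise ValueError(f"{path}: expected integer")
        elif t == "string":
            if not isinstance(obj, str):
                raise ValueError(f"{path}: expected string")
        elif t == "number_or_null":
            if obj is not None and not isinstance(obj, dict):
                raise ValueError(f"{path}: expected rational object or null")

    check(doc, schema, "report")
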