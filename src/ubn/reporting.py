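"""Assessment reports: direct uncertainty alongside a caveat ledger.

An assessment's direct uncertainty about its output can be expressed as a
point probability, a distribution over the query probability, lower/upper
bounds, or a set of scenario answers.  Its *indirect* uncertainty — the
strength of the knowledge behind those numbers — is communicated as a
structured list of caveats over the six locations where epistemic
uncertainty arises in a network-based risk assessment: the model structure,
the parameters, the expert judgment, the data, the risk-management
scenarios, and the output itself.  Every rendered report lists all six
locations, with empty ones shown explicitly: the absence of recorded
caveats is itself information.

Any single merged probability (a predictive-network output, or the mean of
a distribution over the query probability) is a *composite probability* —
an unknown mixture of aleatory and epistemic uncertainty — and is flagged
as such; the flag cannot be dropped silently.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .bn_core import InputError, SchemaError
from .credal import BoundsResult
from .ensemble import ScenarioResult
from .param_uncertainty import COMPOSITE_CAVEAT

LOCATIONS = (
    "structure",
    "parameters",
    "expert_judgment",
    "data",
    "management_scenarios",
    "output",
)

SEVERITIES = ("note", "concern", "major")

COMPOSITE_DEFINITION = (
    "A composite probability is an unknown mixture of aleatory and "
    "epistemic uncertainty."
)


@dataclass(frozen=True)
class CaveatEntry:
    """One indirect-uncertainty caveat, keyed to a location."""

    location: str
    text: str
    severity: str = "note"

    def __post_init__(self) -> None:
        if self.location not in LOCATIONS:
            raise SchemaError(
                f"location must be one of {LOCATIONS}, got {self.location!r}"
            )
        if self.severity not in SEVERITIES:
            raise SchemaError(
                f"severity must be one of {SEVERITIES}, got {self.severity!r}"
            )
        if not self.text.strip():
            raise SchemaError("caveat text must be non-empty")


# direct elements: a point probability (float), a summarize() dict,
# a BoundsResult, or a ScenarioResult
DirectElement = object


@dataclass(frozen=True)
class AssessmentReport:
    """The assessment output: question, direct elements, caveats, provenance."""

    question: str
    direct: tuple[DirectElement, ...]
    caveats: tuple[CaveatEntry, ...] = ()
    composite_flag: bool = False
    provenance: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "direct", tuple(self.direct))
        object.__setattr__(self, "caveats", tuple(self.caveats))
        object.__setattr__(self, "provenance", dict(self.provenance))
        if not self.direct:
            raise SchemaError("report needs at least one direct-uncertainty element")
        # any merged single probability makes the flag mandatory
        if self._has_composite_element() and not self.composite_flag:
            object.__setattr__(self, "composite_flag", True)

    def _has_composite_element(self) -> bool:
        for el in self.direct:
            if isinstance(el, dict) and "composite_probability" in el:
                return True
        return False


def _element_kind(el: DirectElement) -> str:
    if isinstance(el, float):
        return "probability"
    if isinstance(el, dict) and "composite_probability" in el:
        return "distribution summary"
    if isinstance(el, BoundsResult):
        return "bounds"
    if isinstance(el, ScenarioResult):
        return "scenarios"
    raise InputError(f"unknown direct-uncertainty element type {type(el).__name__}")


def render_report(report: AssessmentReport, format: str = "text") -> str | dict:
    """Render the report as human-readable text or a structured dict.

    The structured form round-trips: ``report_from_structured(render_report(
    r, "structured")) == r``.
    """
    if format == "structured":
        return _to_structured(report)
    if format != "text":
        raise InputError(f"format must be text|structured, got {format!r}")

    lines: list[str] = []
    lines.append(f"ASSESSMENT QUESTION: {report.question}")
    lines.append("")
    lines.append("DIRECT UNCERTAINTY")
    for el in report.direct:
        kind = _element_kind(el)
        if kind == "probability":
            lines.append(f"  [probability] {el:.6f}")
        elif kind == "distribution summary":
            lines.append(f"  [distribution] {el['query']}")
            lines.append(
                f"    composite probability (mean): {el['composite_probability']:.6f}"
            )
            for level, (lo, hi) in el["intervals"].items():
                lines.append(
                    f"    {100 * level:g}% probability interval: "
                    f"[{lo:.6f}, {hi:.6f}]"
                )
            for stmt in el["statements"]:
                lines.append(f"    {stmt}")
        elif kind == "bounds":
            tag = " (inner approximation)" if el.is_inner_approximation else ""
            lines.append(
                f"  [bounds] [{el.lower:.6f}, {el.upper:.6f}] "
                f"by {el.method}{tag}"
            )
        elif kind == "scenarios":
            lines.append("  [scenarios] (reported separately, not integrated)")
            for label, p in el.results.items():
                lines.append(f"    {label}: {p:.6f}")
            lo, hi = el.range
            lines.append(f"    scenario range: [{lo:.6f}, {hi:.6f}]")
    if report.composite_flag:
        lines.append("")
        lines.append(
            "  NOTE: a reported single value is a composite probability. "
            + COMPOSITE_DEFINITION
        )
    lines.append("")
    lines.append("INDIRECT UNCERTAINTY (caveats by location)")
    by_loc: dict[str, list[CaveatEntry]] = {loc: [] for loc in LOCATIONS}
    for c in report.caveats:
        by_loc[c.location].append(c)
    for loc in LOCATIONS:
        lines.append(f"  {loc}:")
        if not by_loc[loc]:
            lines.append("    no caveats recorded")
        for c in by_loc[loc]:
            lines.append(f"    [{c.severity}] {c.text}")
    lines.append("")
    lines.append("PROVENANCE")
    if not report.provenance:
        lines.append("  (none recorded)")
    for k in sorted(report.provenance):
        lines.append(f"  {k}: {report.provenance[k]}")
    return "\n".join(lines)


def _to_structured(report: AssessmentReport) -> dict:
    direct = []
    for el in report.direct:
        kind = _element_kind(el)
        if kind == "probability":
            direct.append({"kind": "probability", "value": float(el)})
        elif kind == "distribution summary":
            d = dict(el)
            d["intervals"] = {
                float(k): [float(v[0]), float(v[1])] for k, v in el["intervals"].items()
            }
            d["certainty"] = {float(k): float(v) for k, v in el["certainty"].items()}
            direct.append({"kind": "distribution_summary", "value": d})
        elif kind == "bounds":
            direct.append(
                {
                    "kind": "bounds",
                    "value": {
                        "lower": el.lower,
                        "upper": el.upper,
                        "method": el.method,
                        "evaluations": el.evaluations,
                    },
                }
            )
        elif kind == "scenarios":
            direct.append(
                {"kind": "scenarios", "value": {k: float(v) for k, v in el.results.items()}}
            )
    return {
        "question": report.question,
        "direct": direct,
        "composite_flag": bool(report.composite_flag),
        "caveats": [
            {"location": c.location, "severity": c.severity, "text": c.text}
            for c in report.caveats
        ],
        "provenance": dict(report.provenance),
    }


def report_from_structured(doc: Mapping) -> AssessmentReport:
    """Parse a structured rendering back into an equal AssessmentReport."""
    direct: list[DirectElement] = []
    for item in doc["direct"]:
        kind, value = item["kind"], item["value"]
        if kind == "probability":
            direct.append(float(value))
        elif kind == "distribution_summary":
            d = dict(value)
            d["intervals"] = {
                float(k): (float(v[0]), float(v[1])) for k, v in d["intervals"].items()
            }
            d["certainty"] = {float(k): float(v) for k, v in d["certainty"].items()}
            direct.append(d)
        elif kind == "bounds":
            direct.append(BoundsResult(**value))
        elif kind == "scenarios":
            direct.append(ScenarioResult(results=dict(value)))
        else:
            raise SchemaError(f"unknown direct element kind {kind!r}")
    return AssessmentReport(
        question=doc["question"],
        direct=tuple(direct),
        composite_flag=bool(doc["composite_flag"]),
        caveats=tuple(
            CaveatEntry(location=c["location"], text=c["text"], severity=c["severity"])
            for c in doc["caveats"]
        ),
        provenance=dict(doc.get("provenance", {})),
    )


def caveat_summary(caveats: Sequence[CaveatEntry]) -> pd.DataFrame:
    """Counts per (location, severity); always six location rows."""
    table = pd.DataFrame(0, index=list(LOCATIONS), columns=list(SEVERITIES))
    for c in caveats:
        table.loc[c.location, c.severity] += 1
    table.index.name = "location"
    return table
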