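"""MIRAGE-style metadata for glycan-array experiments, with completeness checks.

MIRAGE (Minimum Information Required for A Glycomics Experiment) defines a
reporting checklist for glycan microarray studies: what must be said about
the glycan-binding sample (analyte), the assay protocol, the scanner, and
the array itself.  The checklist used here ships as a versioned JSON file
(``data/mirage_checklist.json``) so categories can be revised without code
changes; validation reports each category present/missing and never raises
on incomplete records.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from importlib import resources
from typing import Any

__all__ = ["AnalyteMetadata", "ExperimentMetadata", "ProtocolStep",
           "ComplianceReport", "validate_mirage", "load_checklist",
           "metadata_to_json", "metadata_from_json"]

ORIGINS = ("synthetic", "natural", "recombinant")


@dataclass
class AnalyteMetadata:
    """The glycan-binding sample: antibody, lectin, virus, serum, ..."""

    name: str = ""
    origin: str = ""  # synthetic | natural | recombinant
    database_ids: list[tuple[str, str]] = field(default_factory=list)  # (source, id)
    purity: str = ""
    qc_info: str = ""
    concentration_used: str = ""
    detection_system: str = ""

    def __post_init__(self) -> None:
        if self.origin and self.origin not in ORIGINS:
            raise ValueError(f"origin must be one of {ORIGINS} (or empty)")


@dataclass
class ProtocolStep:
    step_name: str
    description: str = ""
    duration: str = ""
    temperature: str = ""
    buffer: str = ""


@dataclass
class ExperimentMetadata:
    """Assay conditions: incubation/washing steps, scanner settings, batch."""

    protocol_steps: list[ProtocolStep] = field(default_factory=list)
    scanner_settings: dict[str, str] = field(default_factory=dict)
    array_batch: str = ""
    assay_date: str = ""


@dataclass
class ComplianceReport:
    categories: list[dict[str, Any]]  # {category, present, missing_fields}
    complete: bool

    @property
    def missing(self) -> list[str]:
        return [c["category"] for c in self.categories if not c["present"]]


def load_checklist() -> dict:
    with resources.files("glyarray").joinpath("data", "mirage_checklist.json").open(
            encoding="utf-8") as fh:
        return json.load(fh)


def _present(value: Any) -> bool:
    if value is None:
        return False
    if isinstance(value, str):
        return bool(value.strip())
    if isinstance(value, (list, dict, tuple)):
        return len(value) > 0
    return True


def validate_mirage(analyte: AnalyteMetadata | None,
                    experiment: ExperimentMetadata | None,
                    array_info: dict | None = None) -> ComplianceReport:
    """Check records against the shipped MIRAGE checklist.

    ``array_info`` may carry ``probes`` (probe list / count) and ``geometry``
    (layout reference).  Missing records simply mark all their categories
    absent — validation is pure and never raises.
    """
    records = {"analyte": analyte, "experiment": experiment,
               "array": array_info or {}}
    results = []
    for item in load_checklist()["categories"]:
        rec = records[item["record"]]
        missing = []
        for f in item["fields"]:
            value = rec.get(f) if isinstance(rec, dict) else getattr(rec, f, None)
            if rec is None or not _present(value):
                missing.append(f)
        results.append({"category": item["category"],
                        "present": not missing,
                        "missing_fields": missing})
    return ComplianceReport(categories=results,
                            complete=all(c["present"] for c in results))


def metadata_to_json(analyte: AnalyteMetadata | None,
                     experiment: ExperimentMetadata | None) -> str:
    return json.dumps({
        "analyte": asdict(analyte) if analyte else None,
        "experiment": asdict(experiment) if experiment else None,
    }, indent=1)


def metadata_from_json(text: str) -> tuple[AnalyteMetadata | None,
                                           ExperimentMetadata | None]:
    doc = json.loads(text)
    analyte = None
    if doc.get("analyte") is not None:
        a = dict(doc["analyte"])
        a["database_ids"] = [tuple(x) for x in a.get("database_ids", [])]
        analyte = AnalyteMetadata(**a)
    experiment = None
    if doc.get("experiment") is not None:
        e = dict(doc["experiment"])
        e["protocol_steps"] = [ProtocolStep(**s) for s in e.get("protocol_steps", [])]
        experiment = ExperimentMetadata(**e)
    return analyte, experiment
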