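"""Export of processed datasets: CSV, XLSX, JSON, and a self-contained HTML
report (the distributable stand-in for word-processor report formats).

Every export embeds the processing provenance (input files, statistic,
averaging method, options, software version) so a reported dataset can be
regenerated from its inputs.  The JSON dialect is described by the shipped
``data/export_schema.json`` and checked by :func:`validate_export_json`.
"""

from __future__ import annotations

import html
import json
from dataclasses import asdict
from importlib import resources
from pathlib import Path

import pandas as pd

from .geometry import Quantity
from .glycans import GlycanProbe
from .mirage import AnalyteMetadata, ExperimentMetadata, \
    validate_mirage
from .quantify import OutlierRule, ProbeIntensity, ProcessedDataset, QuantOptions

__all__ = ["export_table", "import_table", "dataset_to_json", "dataset_from_json",
           "load_dataset", "validate_export_json", "render_report",
           "EXPORT_FORMATS"]

EXPORT_FORMATS = ("csv", "xlsx", "json")

SCHEMA_ID = "glyarray-dataset/1"


def _frame(ds: ProcessedDataset,
           probes: dict[str, GlycanProbe] | None = None) -> pd.DataFrame:
    probes = probes or {}
    rows = []
    for pi in ds.intensities:
        probe = probes.get(pi.probe_key)
        rows.append({
            "probe_key": pi.probe_key,
            "name": probe.display_name if probe else "",
            "sequence": (probe.iupac() or next(iter(probe.sequences.values()), "")
                         ) if probe else "",
            "tag": (probe.tag or {}).get("tag_name", "") if probe else "",
            "concentration": str(pi.concentration) if pi.concentration else "",
            "dose": str(pi.dose) if pi.dose else "",
            "block": pi.block if pi.block is not None else "",
            "n_spots": pi.n_spots,
            "n_used": pi.n_used,
            "value": pi.value,
            "sd": pi.sd,
            "percent_cv": pi.percent_cv,
            "exclusions": "; ".join(f"{addr}:{reason}" for addr, reason in pi.excluded),
        })
    return pd.DataFrame(rows)


def dataset_to_json(ds: ProcessedDataset) -> dict:
    return {
        "schema": SCHEMA_ID,
        "analyte_ref": ds.analyte_ref,
        "options": ds.options.to_dict(),
        "provenance": ds.provenance,
        "rejects": [
            {**r, "concentration": str(r["concentration"]) if r.get("concentration") else None,
             "dose": str(r["dose"]) if r.get("dose") else None,
             "excluded": [[list(a), reason] for a, reason in r.get("excluded", [])]}
            for r in ds.rejects],
        "intensities": [
            {"probe_key": pi.probe_key,
             "concentration": str(pi.concentration) if pi.concentration else None,
             "dose": str(pi.dose) if pi.dose else None,
             "block": pi.block,
             "n_spots": pi.n_spots, "n_used": pi.n_used,
             "value": pi.value, "sd": pi.sd, "percent_cv": pi.percent_cv,
             "excluded": [[list(a), reason] for a, reason in pi.excluded],
             "notes": pi.notes}
            for pi in ds.intensities],
    }


def dataset_from_json(doc: dict) -> ProcessedDataset:
    validate_export_json(doc)
    opts_d = dict(doc["options"])
    opts_d["outlier_rule"] = OutlierRule(**opts_d["outlier_rule"])
    opts = QuantOptions(**opts_d)
    intensities = []
    for d in doc["intensities"]:
        intensities.append(ProbeIntensity(
            probe_key=d["probe_key"],
            concentration=Quantity.parse(d["concentration"]) if d.get("concentration") else None,
            dose=Quantity.parse(d["dose"]) if d.get("dose") else None,
            block=d.get("block"),
            n_spots=d["n_spots"], n_used=d["n_used"],
            value=d["value"], sd=d["sd"], percent_cv=d["percent_cv"],
            excluded=[(tuple(a), reason) for a, reason in d.get("excluded", [])],
            notes=list(d.get("notes", []))))
    rejects = []
    for r in doc.get("rejects", []):
        r = dict(r)
        r["concentration"] = Quantity.parse(r["concentration"]) if r.get("concentration") else None
        r["dose"] = Quantity.parse(r["dose"]) if r.get("dose") else None
        r["excluded"] = [(tuple(a), reason) for a, reason in r.get("excluded", [])]
        rejects.append(r)
    return ProcessedDataset(analyte_ref=doc["analyte_ref"], options=opts,
                            intensities=intensities, rejects=rejects,
                            provenance=dict(doc["provenance"]))


def load_dataset(path: str | Path) -> ProcessedDataset:
    """Read back a dataset exported with ``format="json"``."""
    return dataset_from_json(json.loads(Path(path).read_text(encoding="utf-8")))


def _check(cond: bool, msg: str, errors: list[str]) -> None:
    if not cond:
        errors.append(msg)


def validate_export_json(doc: dict) -> None:
    """Structural validation against the shipped export schema.

    A compact walk of ``data/export_schema.json`` (required keys and types);
    raises ``ValueError`` listing every violation.
    """
    with resources.files("glyarray").joinpath("data", "export_schema.json").open(
            encoding="utf-8") as fh:
        schema = json.load(fh)
    errors: list[str] = []
    _check(isinstance(doc, dict), "document is not an object", errors)
    if isinstance(doc, dict):
        for key in schema["required"]:
            _check(key in doc, f"missing key {key!r}", errors)
        if doc.get("schema") != schema["properties"]["schema"]["const"]:
            errors.append(f"schema id must be {SCHEMA_ID!r}")
        item_schema = schema["properties"]["intensities"]["items"]
        for i, item in enumerate(doc.get("intensities", [])):
            for key in item_schema["required"]:
                _check(key in item, f"intensities[{i}] missing {key!r}", errors)
            if "value" in item:
                _check(isinstance(item["value"], (int, float)),
                       f"intensities[{i}].value not numeric", errors)
    if errors:
        raise ValueError("export JSON invalid: " + "; ".join(errors))


def export_table(ds: ProcessedDataset, format: str, path: str | Path,
                 probes: dict[str, GlycanProbe] | None = None,
                 analyte: AnalyteMetadata | None = None,
                 experiment: ExperimentMetadata | None = None) -> Path:
    """Write the dataset as ``csv``, ``xlsx`` or ``json``.

    One row per probe intensity; metadata, provenance and the MIRAGE
    compliance status go to a separate sheet (xlsx), a ``#``-commented
    trailer section (csv), or dedicated keys (json).  Full numeric
    precision is preserved (CSV reimports match to better than 1e-9).
    """
    if format not in EXPORT_FORMATS:
        raise ValueError(f"format must be one of {EXPORT_FORMATS}, got {format!r}")
    path = Path(path)
    frame = _frame(ds, probes)
    compliance = validate_mirage(analyte, experiment, _array_info(ds, probes))

    if format == "csv":
        with open(path, "w", newline="", encoding="utf-8") as fh:
            frame.to_csv(fh, index=False, float_format=None)
            fh.write("\n")
            for k, v in ds.provenance.items():
                fh.write(f"# provenance,{k},{json.dumps(v, default=str)}\n")
            fh.write(f"# mirage,complete,{compliance.complete}\n")
            for cat in compliance.missing:
                fh.write(f"# mirage,missing,{cat}\n")
    elif format == "xlsx":
        meta_rows = [("provenance", k, json.dumps(v, default=str))
                     for k, v in ds.provenance.items()]
        meta_rows.append(("mirage", "complete", str(compliance.complete)))
        meta_rows += [("mirage", "missing", cat) for cat in compliance.missing]
        if analyte is not None:
            meta_rows += [("analyte", k, json.dumps(v, default=str))
                          for k, v in asdict(analyte).items()]
        if experiment is not None:
            meta_rows += [("experiment", k, json.dumps(v, default=str))
                          for k, v in asdict(experiment).items()]
        with pd.ExcelWriter(path, engine="openpyxl") as writer:
            frame.to_excel(writer, sheet_name="data", index=False)
            pd.DataFrame(meta_rows, columns=["section", "key", "value"]).to_excel(
                writer, sheet_name="metadata", index=False)
    else:  # json
        doc = dataset_to_json(ds)
        doc["mirage"] = {"complete": compliance.complete,
                         "missing": compliance.missing}
        if analyte is not None:
            doc["analyte"] = asdict(analyte)
        if experiment is not None:
            doc["experiment"] = asdict(experiment)
        validate_export_json(doc)
        path.write_text(json.dumps(doc, indent=1), encoding="utf-8")
    return path


def _array_info(ds: ProcessedDataset,
                probes: dict[str, GlycanProbe] | None) -> dict:
    return {"probes": sorted({pi.probe_key for pi in ds.intensities}),
            "geometry": ds.provenance.get("geometry", "")}


def import_table(path: str | Path) -> pd.DataFrame:
    """Re-read the data section of a CSV export (provenance trailer skipped)."""
    return pd.read_csv(path, comment="#", skip_blank_lines=True)


def render_report(ds: ProcessedDataset,
                  analyte: AnalyteMetadata | None = None,
                  experiment: ExperimentMetadata | None = None,
                  heat=None,
                  probes: dict[str, GlycanProbe] | None = None) -> str:
    """Self-contained HTML report: intensity table, provenance, compliance.

    Renders an "incomplete" banner when MIRAGE metadata is missing and a
    zero-row notice for empty (e.g. fully filtered-out) datasets.
    """
    compliance = validate_mirage(analyte, experiment, _array_info(ds, probes))
    frame = _frame(ds, probes)
    parts = ["<!DOCTYPE html><html><head><meta charset='utf-8'>",
             f"<title>glyarray report: {html.escape(ds.analyte_ref or 'dataset')}</title>",
             "<style>table{border-collapse:collapse}td,th{border:1px solid #999;"
             "padding:2px 6px;font:12px sans-serif}.banner{padding:6px;margin:6px 0}"
             ".warn{background:#fdd}.ok{background:#dfd}</style></head><body>",
             f"<h1>Processed glycan-array dataset: "
             f"{html.escape(ds.analyte_ref or 'unnamed analyte')}</h1>"]
    if compliance.complete:
        parts.append("<div class='banner ok'>MIRAGE metadata: complete</div>")
    else:
        missing = ", ".join(html.escape(c) for c in compliance.missing)
        parts.append(f"<div class='banner warn'>MIRAGE metadata: incomplete "
                     f"(missing: {missing})</div>")
    if frame.empty:
        parts.append("<p><em>No probes in this dataset "
                     "(all filtered out or rejected).</em></p>")
    else:
        parts.append(frame.to_html(index=False, border=1))
    if heat is not None:
        parts.append("<h2>Heatmap matrix (% of row maximum)</h2>")
        parts.append(heat.values.round(2).to_html(border=1))
    parts.append("<h2>Provenance</h2><ul>")
    for k, v in ds.provenance.items():
        parts.append(f"<li><b>{html.escape(str(k))}</b>: "
                     f"{html.escape(json.dumps(v, default=str))}</li>")
    parts.append("</ul></body></html>")
    return "".join(parts)
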