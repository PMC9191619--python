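"""Presentation views of processed datasets: sorting, filtering, heatmaps.

Heatmap normalization follows the common glycan-array convention of percent
of row maximum: each analyte (row) is scaled so its strongest probe reads
100 %, with negative background-subtracted values clipped to 0 for display
only (the underlying dataset keeps them signed).
"""

from __future__ import annotations

import copy
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .glycans import GlycanProbe, ProbeQuery, composition, filter_probes
from .quantify import ProbeIntensity, ProcessedDataset

__all__ = ["SORT_KEYS", "sort_dataset", "filter_dataset",
           "HeatmapMatrix", "heatmap", "chart_series"]

SORT_KEYS = ("intensity_desc", "probe_order", "composition_feature")


def sort_dataset(ds: ProcessedDataset, key: str,
                 probes: dict[str, GlycanProbe] | None = None,
                 feature: str | None = None) -> list[ProbeIntensity]:
    """Return a stably ordered view of the dataset's intensities.

    ``intensity_desc`` orders by decreasing value; ``probe_order`` by probe
    key; ``composition_feature`` by decreasing count of monosaccharide
    ``feature`` (looked up in ``probes``; unparseable or absent → count 0).
    Ties always break by probe_key lexicographic order.
    """
    if key not in SORT_KEYS:
        raise ValueError(f"unknown sort key {key!r}; expected one of {SORT_KEYS}")
    items = list(ds.intensities)
    if key == "probe_order":
        return sorted(items, key=lambda pi: pi.probe_key)
    if key == "intensity_desc":
        return sorted(items, key=lambda pi: (-pi.value, pi.probe_key))
    if feature is None or probes is None:
        raise ValueError("composition_feature sort needs probes and feature")

    def count(pi: ProbeIntensity) -> int:
        probe = probes.get(pi.probe_key)
        tree = probe.tree() if probe else None
        return composition(tree).get(feature) if tree else 0

    return sorted(items, key=lambda pi: (-count(pi), pi.probe_key))


def filter_dataset(ds: ProcessedDataset, query: ProbeQuery,
                   probes: dict[str, GlycanProbe]) -> ProcessedDataset:
    """Subset a dataset to probes matching a structural/annotation query.

    Delegates the probe decision to :func:`glyarray.glycans.filter_probes`;
    intensities whose probe is not in the registry are dropped with reason
    "unknown probe".  Provenance records the predicate.
    """
    known = [probes[pi.probe_key] for pi in ds.intensities if pi.probe_key in probes]
    kept, explain = filter_probes(known, query)
    kept_keys = {p.probe_key for p in kept}
    out = copy.deepcopy(ds)
    out.intensities = [pi for pi in ds.intensities if pi.probe_key in kept_keys]
    out.provenance = dict(ds.provenance)
    out.provenance["filter"] = {
        "monosaccharide": query.monosaccharide,
        "min_count": query.min_count if query.monosaccharide else None,
        "motif": getattr(query.pattern(), "motif_name", None),
        "tag_name": query.tag_name,
        "custom": bool(query.custom),
        "excluded": {k: v for k, v in explain.items() if k not in kept_keys},
    }
    return out


@dataclass
class HeatmapMatrix:
    """Analytes × probes matrix, raw and normalized (0–100 % of row max)."""

    rows: list[str]  # analyte refs
    columns: list[str]  # probe keys, ordered
    values: pd.DataFrame  # normalized
    raw_values: pd.DataFrame
    normalization: str  # "percent_row_max" | "none"
    warnings: list[str]

    def to_csv(self, path) -> None:
        self.values.to_csv(path, index_label="analyte")


def heatmap(datasets: Sequence[ProcessedDataset],
            normalization: str = "percent_row_max") -> HeatmapMatrix:
    """Build the analyte × probe matrix over the union of probe universes.

    Probes missing from a dataset become NaN.  Under ``percent_row_max``
    every entry is 100·max(raw, 0)/row_max with row_max the largest positive
    raw in the row; rows with no positive value are set to all 0 with a
    warning.
    """
    if not datasets:
        raise ValueError("heatmap needs at least one dataset")
    if normalization not in ("percent_row_max", "none"):
        raise ValueError(f"unknown normalization {normalization!r}")
    columns: list[str] = []
    for ds in datasets:
        for pi in ds.intensities:
            if pi.probe_key not in columns:
                columns.append(pi.probe_key)
    rows = []
    for i, ds in enumerate(datasets):
        ref = ds.analyte_ref or f"analyte_{i + 1}"
        rows.append(ref if ref not in rows else f"{ref}#{i + 1}")
    raw = pd.DataFrame(np.nan, index=rows, columns=columns, dtype=float)
    for ref, ds in zip(rows, datasets):
        for pi in ds.intensities:
            raw.loc[ref, pi.probe_key] = pi.value

    warnings: list[str] = []
    if normalization == "none":
        norm = raw.copy()
    else:
        clipped = raw.clip(lower=0)
        norm = pd.DataFrame(index=rows, columns=columns, dtype=float)
        for ref in rows:
            row = clipped.loc[ref]
            row_max = row.max(skipna=True)
            if not np.isfinite(row_max) or row_max <= 0:
                warnings.append(f"row {ref!r} has no positive intensity; set to 0")
                norm.loc[ref] = row.where(row.isna(), 0.0)
            else:
                norm.loc[ref] = (row / row_max) * 100.0  # x/x == 1 ⇒ max exactly 100
    return HeatmapMatrix(rows=rows, columns=columns, values=norm,
                         raw_values=raw, normalization=normalization,
                         warnings=warnings)


def chart_series(ds: ProcessedDataset) -> pd.DataFrame:
    """Bar-chart data series: probe order, value, SD error bars."""
    return pd.DataFrame({
        "probe_key": [pi.probe_key for pi in ds.intensities],
        "value": [pi.value for pi in ds.intensities],
        "sd": [pi.sd for pi in ds.intensities],
        "n_used": [pi.n_used for pi in ds.intensities],
    })
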