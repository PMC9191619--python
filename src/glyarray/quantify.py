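"""Replicate-spot averaging: annotated spots → per-probe intensities.

Each glycan probe is printed as several replicate spots; quantification
selects one per-spot statistic (mean, median, mean − background, median −
background of the scanner's per-spot pixel statistics), excludes flagged
(negative GenePix flag) and NaN spots, optionally eliminates outliers, and
reports the mean of the surviving replicates with its sample SD and %CV.

The scanner literature names no outlier criterion, so two deterministic,
scale-free rules are provided and logged in provenance:

* ``mad`` (default): exclude x with |x − median| > k·MAD, k = 3; when
  MAD = 0 a narrow fallback band k·0.01·max(|median|, 1) is used so a
  single wild value among identical replicates is still caught;
* ``drop_min_max``: exclude one minimum and one maximum (needs ≥ 4 spots).

Either rule is suppressed (all values kept, annotated "rule-suppressed")
when it would leave fewer than ``min_survivors`` replicates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from datetime import datetime, timezone
from typing import Sequence

import numpy as np

from .geometry import ArrayGeometry, JoinResult, Quantity, join_spots, EMPTY_KEY
from .scan_io import ScanResult, SpotRecord

__all__ = ["QuantOptions", "OutlierRule", "ProbeIntensity", "ProcessedDataset",
           "spot_value", "eliminate_outliers", "process",
           "SPOT_STATISTICS", "AVERAGING_METHODS"]

SPOT_STATISTICS = ("mean", "median", "mean_minus_bg", "median_minus_bg")
AVERAGING_METHODS = ("plain_mean", "outlier_eliminated_mean")

#: marker used for %CV when the group mean is zero
CV_UNDEFINED = "undefined"


@dataclass
class OutlierRule:
    method: str = "mad"  # "mad" | "drop_min_max"
    k: float = 3.0
    min_survivors: int = 2

    def __post_init__(self) -> None:
        if self.method not in ("mad", "drop_min_max"):
            raise ValueError(f"unknown outlier method {self.method!r}")
        if self.k <= 0:
            raise ValueError("k must be > 0")
        if self.min_survivors < 1:
            raise ValueError("min_survivors must be >= 1")


@dataclass
class QuantOptions:
    """All knobs of one processing run; fully serializable into provenance."""

    channel: int = 532
    spot_statistic: str = "mean"
    averaging: str = "plain_mean"
    outlier_rule: OutlierRule = field(default_factory=OutlierRule)
    exclude_flagged: bool = True
    clip_negative: bool = False
    include_empty: bool = False  # report the EMPTY placeholder groups too

    def __post_init__(self) -> None:
        if self.spot_statistic not in SPOT_STATISTICS:
            raise ValueError(f"spot_statistic must be one of {SPOT_STATISTICS}")
        if self.averaging not in AVERAGING_METHODS:
            raise ValueError(f"averaging must be one of {AVERAGING_METHODS}")
        if isinstance(self.outlier_rule, dict):
            self.outlier_rule = OutlierRule(**self.outlier_rule)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class ProbeIntensity:
    """Averaged binding intensity for one replicate group."""

    probe_key: str
    concentration: Quantity | None
    dose: Quantity | None
    block: int | None  # None when replicate scope is the whole slide
    n_spots: int
    n_used: int
    value: float
    sd: float
    percent_cv: float | str
    excluded: list[tuple[tuple[int, int, int], str]] = field(default_factory=list)
    notes: list[str] = field(default_factory=list)  # e.g. "rule-suppressed"


@dataclass
class ProcessedDataset:
    """Per-probe averaged intensities plus full processing provenance."""

    analyte_ref: str
    options: QuantOptions
    intensities: list[ProbeIntensity]
    rejects: list[dict] = field(default_factory=list)  # groups with no usable spot
    provenance: dict = field(default_factory=dict)

    def intensity_map(self) -> dict[str, float]:
        return {pi.probe_key: pi.value for pi in self.intensities}


def spot_value(spot: SpotRecord, channel: int, statistic: str) -> float:
    """The selected per-spot statistic for one channel; NaN propagates."""
    if channel not in spot.channel_features:
        raise KeyError(f"channel {channel} not present on spot {spot.address}")
    cf = spot.channel_features[channel]
    if statistic == "mean":
        return cf.f_mean
    if statistic == "median":
        return cf.f_median
    if statistic == "mean_minus_bg":
        return cf.f_mean - cf.b_mean
    if statistic == "median_minus_bg":
        return cf.f_median - cf.b_median
    raise ValueError(f"unknown spot statistic {statistic!r}")


def eliminate_outliers(values: Sequence[float], rule: OutlierRule
                       ) -> tuple[list[bool], list[str]]:
    """Survivor mask + per-value reasons for one replicate group.

    Reasons are "" (kept), "outlier", or "rule-suppressed" on every value
    when applying the rule would leave fewer than ``rule.min_survivors``.
    """
    vals = [float(v) for v in values]
    if not vals or not any(math.isfinite(v) for v in vals):
        raise ValueError("eliminate_outliers needs at least one finite value")
    n = len(vals)
    if n <= rule.min_survivors:
        # any exclusion would drop the group below min_survivors
        return [True] * n, ["rule-suppressed"] * n
    if rule.method == "mad":
        med = float(np.median(vals))
        mad = float(np.median([abs(v - med) for v in vals]))
        band = rule.k * mad if mad > 0 else rule.k * 0.01 * max(abs(med), 1.0)
        mask = [abs(v - med) <= band for v in vals]
    else:  # drop_min_max
        if n < 4:
            return [True] * n, ["rule-suppressed"] * n
        if max(vals) == min(vals):
            return [True] * n, [""] * n  # zero dispersion: nothing to drop
        lo = vals.index(min(vals))
        hi = max(range(n), key=lambda i: (vals[i], i != lo))
        mask = [i not in (lo, hi) for i in range(n)]
    if sum(mask) < rule.min_survivors:
        return [True] * n, ["rule-suppressed"] * n
    return mask, ["" if m else "outlier" for m in mask]


def _group_key(assignment, scope: str):
    base = (assignment.probe_key, assignment.concentration, assignment.dose)
    return (assignment.block,) + base if scope == "block" else (None,) + base


def process(scan: ScanResult, geom: ArrayGeometry, opts: QuantOptions,
            analyte_ref: str = "", join: JoinResult | None = None
            ) -> ProcessedDataset:
    """Full quantification: join, group, exclude, average.

    Replicate groups are spots sharing (probe_key, concentration, dose)
    within the geometry's replicate scope (whole slide by default, or per
    block).  Exclusion order per spot: negative GenePix flag (when
    ``exclude_flagged``), NaN statistic, then the outlier rule (when
    ``averaging="outlier_eliminated_mean"``).  Every spot ends up exactly
    once in used / excluded-with-reason / unmatched bookkeeping.
    """
    if join is None:
        join = join_spots(scan, geom)
    if opts.channel not in scan.channels:
        raise KeyError(f"channel {opts.channel} not in scan channels {scan.channels}")

    groups: dict[tuple, list[tuple[SpotRecord, float]]] = {}
    excluded_pre: dict[tuple, list[tuple[tuple[int, int, int], str]]] = {}
    for spot, assignment in join.matched:
        if assignment.probe_key == EMPTY_KEY and not opts.include_empty:
            continue
        key = _group_key(assignment, geom.replicate_scope)
        groups.setdefault(key, [])
        excluded_pre.setdefault(key, [])
        if opts.exclude_flagged and spot.flags < 0:
            excluded_pre[key].append((spot.address, "flagged"))
            continue
        v = spot_value(spot, opts.channel, opts.spot_statistic)
        if math.isnan(v):
            excluded_pre[key].append((spot.address, "nan"))
            continue
        if opts.clip_negative and v < 0:
            v = 0.0
        groups[key].append((spot, v))

    intensities: list[ProbeIntensity] = []
    rejects: list[dict] = []
    for key in groups:
        block, probe_key, conc, dose = key
        usable = groups[key]
        excluded = list(excluded_pre[key])
        n_spots = len(usable) + len(excluded)
        if not usable:
            rejects.append({"probe_key": probe_key, "block": block,
                            "concentration": conc, "dose": dose,
                            "n_spots": n_spots, "excluded": excluded})
            continue
        vals = [v for _, v in usable]
        notes: list[str] = []
        if opts.averaging == "outlier_eliminated_mean":
            mask, reasons = eliminate_outliers(vals, opts.outlier_rule)
            survivors = [v for v, m in zip(vals, mask) if m]
            for (spot, _), m, r in zip(usable, mask, reasons):
                if not m:
                    excluded.append((spot.address, r))
            if "rule-suppressed" in reasons:
                notes.append("rule-suppressed")
        else:
            survivors = vals
        n_used = len(survivors)
        value = float(np.mean(survivors))
        sd = float(np.std(survivors, ddof=1)) if n_used > 1 else 0.0
        cv = 100.0 * sd / value if value != 0 else CV_UNDEFINED
        intensities.append(ProbeIntensity(
            probe_key=probe_key, concentration=conc, dose=dose, block=block,
            n_spots=n_spots, n_used=n_used, value=value, sd=sd, percent_cv=cv,
            excluded=sorted(excluded), notes=notes))

    intensities.sort(key=lambda pi: (pi.probe_key, pi.block or 0,
                                     str(pi.concentration), str(pi.dose)))
    provenance = {
        "scan": scan.slide_id,
        "geometry": geom.layout_id,
        "channel": opts.channel,
        "spot_statistic": opts.spot_statistic,
        "averaging": opts.averaging,
        "outlier_rule": asdict(opts.outlier_rule),
        "exclude_flagged": opts.exclude_flagged,
        "clip_negative": opts.clip_negative,
        "replicate_scope": geom.replicate_scope,
        "n_matched": join.n_matched,
        "n_scan_only": len(join.scan_only),
        "n_geometry_only": len(join.geometry_only),
        "software": "glyarray 0.1.0",
        "timestamp": datetime.now(timezone.utc).isoformat(timespec="seconds"),
    }
    return ProcessedDataset(analyte_ref=analyte_ref, options=opts,
                            intensities=intensities, rejects=rejects,
                            provenance=provenance)
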