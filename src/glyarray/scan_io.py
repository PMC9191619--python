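"""Reading and writing microarray scanner output.

Two scanner file families are supported: GenePix Result (GPR) files in the
Axon Text File (ATF) dialect, and generic tab-delimited exports such as those
produced by ProScanArray instruments.  Auxiliary scanner files (GenePix
Settings, TIFF images) are never parsed — they are carried as opaque
attachments and archived verbatim.

Per-spot fluorescence features are kept per channel (laser wavelength in nm):
foreground/background mean and median, from which the four reportable spot
statistics (mean, median, mean minus background, median minus background)
are later derived.
"""

from __future__ import annotations

import csv
import math
import re
import shutil
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping


class ScanIOError(Exception):
    """Base class for scanner-file errors."""


class AtfParseError(ScanIOError):
    """Malformed ATF preamble or structure; message names the offending line."""


class SchemaError(ScanIOError):
    """A mandatory or mapped column is absent; message names the column."""


class IntegrityError(ScanIOError):
    """Duplicate or inconsistent spot addresses."""


_FEATURE_COL = re.compile(r"^([FB])(\d+)\s+(Mean|Median)$")

#: roles accepted by :func:`read_tab_scan`; background roles are optional
TAB_ROLES = ("block", "row", "column", "probe_key",
             "f_mean", "f_median", "b_mean", "b_median", "name", "flags")


def _nan_eq(a: float, b: float) -> bool:
    if a is None or b is None:
        return a is b
    return (math.isnan(a) and math.isnan(b)) or a == b


@dataclass
class ChannelFeatures:
    """Foreground/background mean & median intensities (a.u.) for one channel."""

    f_mean: float
    f_median: float
    b_mean: float
    b_median: float

    def __eq__(self, other: object) -> bool:  # NaN-aware field equality
        if not isinstance(other, ChannelFeatures):
            return NotImplemented
        return all(_nan_eq(getattr(self, f), getattr(other, f))
                   for f in ("f_mean", "f_median", "b_mean", "b_median"))


@dataclass
class SpotRecord:
    """One printed spot: 1-based (block, row, column) address plus features.

    ``probe_key`` is the GAL/GPR "ID" field linking the spot to a glycan
    probe; ``flags`` follows the GenePix convention (negative = bad/absent/
    not found).
    """

    block: int
    row: int
    column: int
    name: str
    probe_key: str
    channel_features: dict[int, ChannelFeatures]
    flags: int = 0
    x_um: float | None = None
    y_um: float | None = None

    @property
    def address(self) -> tuple[int, int, int]:
        return (self.block, self.row, self.column)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SpotRecord):
            return NotImplemented
        return (self.address == other.address
                and self.name == other.name
                and self.probe_key == other.probe_key
                and self.flags == other.flags
                and _nan_eq(self.x_um, other.x_um)
                and _nan_eq(self.y_um, other.y_um)
                and self.channel_features == other.channel_features)


@dataclass
class Attachment:
    """Opaque auxiliary file (GPS settings, TIFF image, ...); never parsed."""

    kind: str  # "GPS" | "TIFF" | "other"
    path: str


@dataclass
class ScanResult:
    """One slide scan: spots, channel list, ATF header metadata, attachments."""

    slide_id: str
    channels: list[int]
    spots: list[SpotRecord]
    header_meta: dict[str, str] = field(default_factory=dict)
    attachments: list[Attachment] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    def validate(self) -> None:
        if not self.channels:
            raise IntegrityError("scan has no channels")
        if not self.spots:
            raise IntegrityError("scan has no spots")
        seen: set[tuple[int, int, int]] = set()
        for s in self.spots:
            if min(s.block, s.row, s.column) < 1:
                raise IntegrityError(f"non-positive spot address {s.address}")
            if s.address in seen:
                raise IntegrityError(f"duplicate spot address {s.address}")
            seen.add(s.address)
            missing = set(self.channels) - set(s.channel_features)
            if missing:
                raise IntegrityError(
                    f"spot {s.address} lacks features for channels {sorted(missing)}")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ScanResult):
            return NotImplemented
        return (self.slide_id == other.slide_id
                and self.channels == other.channels
                and self.header_meta == other.header_meta
                and [a.kind for a in self.attachments] == [a.kind for a in other.attachments]
                and [a.path for a in self.attachments] == [a.path for a in other.attachments]
                and self.spots == other.spots)


def _read_atf_preamble(rows: list[list[str]], path: Path) -> tuple[dict[str, str], int]:
    """Parse the ATF magic, count line and header records.

    Returns (header_meta, index of the column-header row).
    """
    if not rows or not rows[0] or not rows[0][0].strip().upper().startswith("ATF"):
        raise AtfParseError(f"{path}: line 1 does not declare an ATF file")
    if len(rows) < 2 or len(rows[1]) < 2:
        raise AtfParseError(f"{path}: line 2 must declare header and column counts")
    try:
        n_header = int(rows[1][0])
        int(rows[1][1])
    except ValueError as exc:
        raise AtfParseError(f"{path}: line 2 counts are not integers") from exc
    header_meta: dict[str, str] = {}
    for i in range(n_header):
        lineno = 3 + i
        if 2 + i >= len(rows) or not rows[2 + i]:
            raise AtfParseError(f"{path}: line {lineno}: missing declared header record")
        rec = rows[2 + i][0]
        if "=" not in rec:
            raise AtfParseError(f"{path}: line {lineno}: header record lacks '='")
        key, _, value = rec.partition("=")
        header_meta[key] = value
    return header_meta, 2 + n_header


def _to_float(cell: str) -> float:
    try:
        return float(cell)
    except (ValueError, TypeError):
        return math.nan


def read_gpr(path: str | Path, slide_id: str | None = None) -> ScanResult:
    """Read a GenePix Result file (ATF dialect).

    Channels are inferred from column names matching ``F<wl> Mean/Median`` and
    ``B<wl> Mean/Median``.  Non-numeric feature cells (scanner "Error" cells,
    blanks) become NaN with a recorded warning rather than dropping the row,
    so geometry joins stay intact.
    """
    path = Path(path)
    with open(path, newline="", encoding="utf-8") as fh:
        rows = [r for r in csv.reader(fh, delimiter="\t")]
    header_meta, hdr_idx = _read_atf_preamble(rows, path)
    if hdr_idx >= len(rows):
        raise AtfParseError(f"{path}: no column-header row after ATF preamble")
    columns = [c.strip() for c in rows[hdr_idx]]
    colpos = {c: i for i, c in enumerate(columns)}

    for mandatory in ("Block", "Column", "Row", "Name", "ID"):
        if mandatory not in colpos:
            raise SchemaError(f"{path}: mandatory column '{mandatory}' missing")
    channels = sorted({int(m.group(2)) for c in columns
                       if (m := _FEATURE_COL.match(c))})
    if not any(f"F{wl} Mean" in colpos for wl in channels):
        raise SchemaError(f"{path}: no 'F<wavelength> Mean' column found")

    warnings: list[str] = []
    spots: list[SpotRecord] = []
    seen: set[tuple[int, int, int]] = set()
    for lineno, row in enumerate(rows[hdr_idx + 1:], start=hdr_idx + 2):
        if not row or all(not c.strip() for c in row):
            continue

        def cell(col: str) -> str:
            i = colpos.get(col)
            return row[i] if i is not None and i < len(row) else ""

        try:
            address = (int(cell("Block")), int(cell("Row")), int(cell("Column")))
        except ValueError as exc:
            raise AtfParseError(
                f"{path}: line {lineno}: non-integer spot address") from exc
        if address in seen:
            raise IntegrityError(f"{path}: duplicate spot address {address}")
        seen.add(address)

        feats: dict[int, ChannelFeatures] = {}
        for wl in channels:
            vals = {}
            for role, col in (("f_mean", f"F{wl} Mean"), ("f_median", f"F{wl} Median"),
                              ("b_mean", f"B{wl} Mean"), ("b_median", f"B{wl} Median")):
                if col in colpos:
                    v = _to_float(cell(col))
                    if math.isnan(v) and cell(col).strip() not in ("", "nan", "NaN"):
                        warnings.append(
                            f"line {lineno}: non-numeric value {cell(col)!r} in {col} -> NaN")
                else:
                    v = math.nan
                vals[role] = v
            feats[wl] = ChannelFeatures(**vals)

        flags_cell = cell("Flags").strip()
        flags = int(float(flags_cell)) if flags_cell else 0
        x = _to_float(cell("X")) if "X" in colpos else None
        y = _to_float(cell("Y")) if "Y" in colpos else None
        spots.append(SpotRecord(
            block=address[0], row=address[1], column=address[2],
            name=cell("Name"), probe_key=cell("ID"), channel_features=feats,
            flags=flags,
            x_um=None if x is None or math.isnan(x) else x,
            y_um=None if y is None or math.isnan(y) else y))

    scan = ScanResult(
        slide_id=slide_id or header_meta.get("SlideID", path.stem),
        channels=channels, spots=spots, header_meta=header_meta,
        warnings=warnings)
    scan.validate()
    return scan


def read_tab_scan(path: str | Path, column_map: Mapping[str, str],
                  channel: int = 532, slide_id: str | None = None) -> ScanResult:
    """Read a generic tab-delimited scanner export (e.g. ProScanArray).

    ``column_map`` assigns file columns to roles (see :data:`TAB_ROLES`);
    block/row/column/probe_key/f_mean/f_median are required, background roles
    optional (absent backgrounds default to 0 with a recorded warning).  The
    export does not name its laser wavelength, so ``channel`` labels it.
    """
    path = Path(path)
    unknown = set(column_map) - set(TAB_ROLES)
    if unknown:
        raise SchemaError(f"unknown roles in column_map: {sorted(unknown)}")
    for role in ("block", "row", "column", "probe_key", "f_mean", "f_median"):
        if role not in column_map:
            raise SchemaError(f"column_map must assign role '{role}'")

    with open(path, newline="", encoding="utf-8") as fh:
        rows = [r for r in csv.reader(fh, delimiter="\t")]
    if not rows:
        raise AtfParseError(f"{path}: empty file")
    columns = [c.strip() for c in rows[0]]
    colpos = {c: i for i, c in enumerate(columns)}
    for role, col in column_map.items():
        if col not in colpos:
            raise SchemaError(f"{path}: mapped column '{col}' (role {role}) missing")

    warnings = []
    for role in ("b_mean", "b_median"):
        if role not in column_map:
            warnings.append(f"background role '{role}' unmapped; defaulting to 0")

    spots: list[SpotRecord] = []
    seen: set[tuple[int, int, int]] = set()
    for lineno, row in enumerate(rows[1:], start=2):
        if not row or all(not c.strip() for c in row):
            continue

        def cell(role: str) -> str:
            col = column_map.get(role)
            if col is None:
                return ""
            i = colpos[col]
            return row[i] if i < len(row) else ""

        try:
            address = (int(cell("block")), int(cell("row")), int(cell("column")))
        except ValueError as exc:
            raise AtfParseError(
                f"{path}: line {lineno}: non-integer spot address") from exc
        if address in seen:
            raise IntegrityError(f"{path}: duplicate spot address {address}")
        seen.add(address)
        feats = ChannelFeatures(
            f_mean=_to_float(cell("f_mean")),
            f_median=_to_float(cell("f_median")),
            b_mean=_to_float(cell("b_mean")) if "b_mean" in column_map else 0.0,
            b_median=_to_float(cell("b_median")) if "b_median" in column_map else 0.0)
        flags_cell = cell("flags").strip()
        spots.append(SpotRecord(
            block=address[0], row=address[1], column=address[2],
            name=cell("name"), probe_key=cell("probe_key"),
            channel_features={channel: feats},
            flags=int(float(flags_cell)) if flags_cell else 0))

    scan = ScanResult(slide_id=slide_id or path.stem, channels=[channel],
                      spots=spots, warnings=warnings)
    scan.validate()
    return scan


def _fmt(v: float) -> str:
    if v is None:
        return ""
    v = float(v)
    if math.isnan(v):
        return ""
    if v.is_integer():
        return str(int(v))
    return repr(v)


def write_gpr(scan: ScanResult, path: str | Path) -> Path:
    """Write ``scan`` as an ATF/GPR file; ``read_gpr(write_gpr(s)) == s``.

    The slide identifier survives the roundtrip only through the ``SlideID``
    header record, so callers wanting identity should keep one there (the
    synthetic-slide generator does).  Attachments live outside the GPR and
    are not serialized here.
    """
    path = Path(path)
    scan.validate()
    columns = ["Block", "Column", "Row", "Name", "ID"]
    has_xy = any(s.x_um is not None or s.y_um is not None for s in scan.spots)
    if has_xy:
        columns += ["X", "Y"]
    for wl in scan.channels:
        columns += [f"F{wl} Mean", f"F{wl} Median", f"B{wl} Mean", f"B{wl} Median"]
    columns.append("Flags")

    lines = ["ATF\t1.0", f"{len(scan.header_meta)}\t{len(columns)}"]
    for k, v in scan.header_meta.items():
        lines.append(f'"{k}={v}"')
    lines.append("\t".join(f'"{c}"' for c in columns))
    for s in scan.spots:
        row = [str(s.block), str(s.column), str(s.row), f'"{s.name}"', f'"{s.probe_key}"']
        if has_xy:
            row += [_fmt(s.x_um), _fmt(s.y_um)]
        for wl in scan.channels:
            cf = s.channel_features[wl]
            row += [_fmt(cf.f_mean), _fmt(cf.f_median), _fmt(cf.b_mean), _fmt(cf.b_median)]
        row.append(str(s.flags))
        lines.append("\t".join(row))
    path.write_text("\r\n".join(lines) + "\r\n", encoding="utf-8")
    return path


def attach(scan: ScanResult, kind: str, path: str | Path) -> Attachment:
    """Register an auxiliary file (GPS, TIFF, ...) with a scan, unparsed."""
    if kind not in ("GPS", "TIFF", "other"):
        raise ValueError(f"attachment kind must be GPS/TIFF/other, got {kind!r}")
    att = Attachment(kind=kind, path=str(path))
    scan.attachments.append(att)
    return att


def archive_attachments(scan: ScanResult, dest_dir: str | Path) -> list[Path]:
    """Copy every attachment verbatim into ``dest_dir``; returns new paths."""
    dest = Path(dest_dir)
    dest.mkdir(parents=True, exist_ok=True)
    out = []
    for att in scan.attachments:
        target = dest / Path(att.path).name
        shutil.copyfile(att.path, target)
        out.append(target)
    return out
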