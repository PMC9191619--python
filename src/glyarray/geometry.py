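"""Slide geometry: blocks (subarrays), spot→probe assignments, print conditions.

A slide carries ``n_blocks`` rectangular blocks, each printed by one pin pass;
every spot address (block, row, column — all 1-based, GenePix convention) is
assigned a probe key plus optional printing conditions (concentration in the
arrayed solution, or dose per spot).  Geometry is read from GenePix Array
List (GAL) files in the ATF dialect — optionally extended with Concentration
and Dose columns — or from an equivalent extended CSV/TSV table; it can also
be built programmatically from a subarray layout replicated across blocks.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from pathlib import Path

from .scan_io import AtfParseError, IntegrityError, ScanResult, SpotRecord, \
    _read_atf_preamble

__all__ = [
    "Quantity", "SpotAssignment", "ArrayGeometry", "SubarrayLayout",
    "ArrayLayout", "read_gal", "write_gal", "write_geometry_csv",
    "build_geometry", "join_spots", "JoinResult",
]

_QTY = re.compile(r"^\s*([+-]?\d+(?:\.\d+)?(?:[eE][+-]?\d+)?)\s*(\S.*?)?\s*$")

EMPTY_KEY = "EMPTY"


@dataclass(frozen=True)
class Quantity:
    """A number with a verbatim unit text, e.g. ``Quantity(50, "µM")``."""

    value: float
    unit: str = ""

    @classmethod
    def parse(cls, text: str) -> "Quantity | None":
        text = (text or "").strip()
        if not text:
            return None
        m = _QTY.match(text)
        if not m:
            raise ValueError(f"cannot parse quantity {text!r}")
        return cls(float(m.group(1)), (m.group(2) or "").strip())

    def __str__(self) -> str:
        return f"{self.value:g} {self.unit}".strip()


@dataclass(frozen=True)
class SpotAssignment:
    block: int
    row: int
    column: int
    probe_key: str
    concentration: Quantity | None = None
    dose: Quantity | None = None

    @property
    def address(self) -> tuple[int, int, int]:
        return (self.block, self.row, self.column)


@dataclass
class ArrayGeometry:
    """Full slide layout: one :class:`SpotAssignment` per printed position."""

    layout_id: str
    n_blocks: int
    spot_assignments: list[SpotAssignment]
    replicate_scope: str = "slide"  # replicate grouping: "slide" or "block"

    def validate(self) -> None:
        if self.replicate_scope not in ("slide", "block"):
            raise ValueError(f"replicate_scope must be slide/block, "
                             f"got {self.replicate_scope!r}")
        seen: set[tuple[int, int, int]] = set()
        for a in self.spot_assignments:
            if not a.probe_key:
                raise IntegrityError(f"empty probe key at {a.address} "
                                     f"(use {EMPTY_KEY!r} for blank cells)")
            if not 1 <= a.block <= self.n_blocks:
                raise IntegrityError(
                    f"spot {a.address}: block outside [1, {self.n_blocks}]")
            if a.row < 1 or a.column < 1:
                raise IntegrityError(f"non-positive address {a.address}")
            if a.address in seen:
                raise IntegrityError(f"duplicate geometry address {a.address}")
            seen.add(a.address)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ArrayGeometry):
            return NotImplemented
        return (self.layout_id == other.layout_id
                and self.n_blocks == other.n_blocks
                and self.replicate_scope == other.replicate_scope
                and sorted(self.spot_assignments, key=lambda a: a.address)
                == sorted(other.spot_assignments, key=lambda a: a.address))


@dataclass
class SubarrayLayout:
    """Assignment grid for one block: (row, column) → probe + condition."""

    rows: int
    columns: int
    cell_assignments: dict[tuple[int, int], tuple[str, Quantity | None, Quantity | None]] \
        = field(default_factory=dict)

    def assign(self, row: int, column: int, probe_key: str,
               concentration: Quantity | None = None,
               dose: Quantity | None = None) -> None:
        if not (1 <= row <= self.rows and 1 <= column <= self.columns):
            raise IntegrityError(
                f"cell ({row},{column}) outside {self.rows}x{self.columns} subarray")
        self.cell_assignments[(row, column)] = (probe_key, concentration, dose)


@dataclass
class ArrayLayout:
    """Placement of subarray blocks on the slide (offsets carried, unused)."""

    block_positions: list[int]
    offsets_um: dict[int, tuple[float, float]] = field(default_factory=dict)

    def validate(self) -> None:
        if sorted(self.block_positions) != list(range(1, len(self.block_positions) + 1)):
            raise IntegrityError(
                f"block indices must be contiguous from 1, got {self.block_positions}")


def read_gal(path: str | Path, layout_id: str | None = None,
             strip_keys: bool = True) -> ArrayGeometry:
    """Read array geometry from a GAL (ATF) file or an extended CSV/TSV table.

    The ATF route honours ``BlockCount`` and per-block ``BlockN=x,y,dia,
    nCols,colSpacing,nRows,rowSpacing`` records, rejecting addresses outside
    the declared grid.  The CSV/TSV route needs columns Block, Row, Column,
    ID, Name and optionally Concentration and Dose ("50 µM" style values).
    Probe keys are whitespace-trimmed by default (GAL files commonly carry
    trailing spaces).
    """
    path = Path(path)
    first = path.open(encoding="utf-8").readline()
    if first.split("\t")[0].split(",")[0].strip().upper().startswith("ATF"):
        return _read_gal_atf(path, layout_id, strip_keys)
    return _read_gal_table(path, layout_id, strip_keys)


def _read_gal_atf(path: Path, layout_id: str | None, strip_keys: bool) -> ArrayGeometry:
    with open(path, newline="", encoding="utf-8") as fh:
        rows = [r for r in csv.reader(fh, delimiter="\t")]
    header_meta, hdr_idx = _read_atf_preamble(rows, path)
    if hdr_idx >= len(rows):
        raise AtfParseError(f"{path}: no column-header row after ATF preamble")
    columns = [c.strip() for c in rows[hdr_idx]]
    colpos = {c: i for i, c in enumerate(columns)}
    for mandatory in ("Block", "Column", "Row", "ID"):
        if mandatory not in colpos:
            raise AtfParseError(f"{path}: mandatory GAL column '{mandatory}' missing")

    declared_blocks = header_meta.get("BlockCount")
    block_dims: dict[int, tuple[int, int]] = {}  # block -> (nRows, nCols)
    for key, val in header_meta.items():
        m = re.match(r"^Block(\d+)$", key)
        if m:
            parts = [p.strip() for p in val.split(",")]
            if len(parts) >= 7:
                block_dims[int(m.group(1))] = (int(float(parts[5])), int(float(parts[3])))

    assignments: list[SpotAssignment] = []
    for row in rows[hdr_idx + 1:]:
        if not row or all(not c.strip() for c in row):
            continue

        def cell(col: str) -> str:
            i = colpos.get(col)
            return row[i] if i is not None and i < len(row) else ""

        block, r, c = int(cell("Block")), int(cell("Row")), int(cell("Column"))
        if block in block_dims:
            n_r, n_c = block_dims[block]
            if r > n_r or c > n_c:
                raise IntegrityError(
                    f"{path}: spot ({block},{r},{c}) outside declared {n_r}x{n_c} block")
        key = cell("ID").strip() if strip_keys else cell("ID")
        assignments.append(SpotAssignment(
            block=block, row=r, column=c, probe_key=key or EMPTY_KEY,
            concentration=Quantity.parse(cell("Concentration")),
            dose=Quantity.parse(cell("Dose"))))

    n_blocks = int(declared_blocks) if declared_blocks else \
        max((a.block for a in assignments), default=0)
    geom = ArrayGeometry(
        layout_id=layout_id or header_meta.get("LayoutID", path.stem),
        n_blocks=n_blocks, spot_assignments=assignments,
        replicate_scope=header_meta.get("ReplicateScope", "slide"))
    geom.validate()
    return geom


def _read_gal_table(path: Path, layout_id: str | None, strip_keys: bool) -> ArrayGeometry:
    text = path.read_text(encoding="utf-8")
    delimiter = "\t" if "\t" in text.splitlines()[0] else ","
    rows = list(csv.reader(text.splitlines(), delimiter=delimiter))
    if not rows:
        raise AtfParseError(f"{path}: empty geometry table")
    columns = [c.strip() for c in rows[0]]
    colpos = {c: i for i, c in enumerate(columns)}
    for mandatory in ("Block", "Row", "Column", "ID"):
        if mandatory not in colpos:
            raise AtfParseError(f"{path}: mandatory column '{mandatory}' missing")
    assignments = []
    for row in rows[1:]:
        if not row or all(not c.strip() for c in row):
            continue

        def cell(col: str) -> str:
            i = colpos.get(col)
            return row[i] if i is not None and i < len(row) else ""

        key = cell("ID").strip() if strip_keys else cell("ID")
        assignments.append(SpotAssignment(
            block=int(cell("Block")), row=int(cell("Row")), column=int(cell("Column")),
            probe_key=key or EMPTY_KEY,
            concentration=Quantity.parse(cell("Concentration")),
            dose=Quantity.parse(cell("Dose"))))
    geom = ArrayGeometry(layout_id=layout_id or path.stem,
                         n_blocks=max((a.block for a in assignments), default=0),
                         spot_assignments=assignments)
    geom.validate()
    return geom


def write_gal(geom: ArrayGeometry, path: str | Path,
              block_dims: dict[int, tuple[int, int]] | None = None) -> Path:
    """Write geometry as an ATF GAL file (extended with Concentration/Dose).

    ``block_dims`` optionally declares per-block grid sizes (rows, columns)
    as ``BlockN`` records; by default each block declares the maximum row /
    column actually used.  ``read_gal(write_gal(g)) == g``.
    """
    path = Path(path)
    geom.validate()
    has_conc = any(a.concentration for a in geom.spot_assignments)
    has_dose = any(a.dose for a in geom.spot_assignments)
    columns = ["Block", "Column", "Row", "ID", "Name"]
    if has_conc:
        columns.append("Concentration")
    if has_dose:
        columns.append("Dose")

    if block_dims is None:
        block_dims = {}
        for a in geom.spot_assignments:
            r, c = block_dims.get(a.block, (0, 0))
            block_dims[a.block] = (max(r, a.row), max(c, a.column))

    header = {"Type": "GenePix ArrayList V1.0",
              "LayoutID": geom.layout_id,
              "BlockCount": str(geom.n_blocks),
              "ReplicateScope": geom.replicate_scope}
    for b in sorted(block_dims):
        n_r, n_c = block_dims[b]
        header[f"Block{b}"] = f"0,0,100,{n_c},200,{n_r},200"

    lines = ["ATF\t1.0", f"{len(header)}\t{len(columns)}"]
    lines += [f'"{k}={v}"' for k, v in header.items()]
    lines.append("\t".join(f'"{c}"' for c in columns))
    for a in sorted(geom.spot_assignments, key=lambda a: a.address):
        row = [str(a.block), str(a.column), str(a.row), f'"{a.probe_key}"',
               f'"{a.probe_key}"']
        if has_conc:
            row.append(f'"{a.concentration}"' if a.concentration else '""')
        if has_dose:
            row.append(f'"{a.dose}"' if a.dose else '""')
        lines.append("\t".join(row))
    path.write_text("\r\n".join(lines) + "\r\n", encoding="utf-8")
    return path


def write_geometry_csv(geom: ArrayGeometry, path: str | Path) -> Path:
    """Write geometry as the extended CSV table (the shipped template dialect)."""
    path = Path(path)
    geom.validate()
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["Block", "Row", "Column", "ID", "Name", "Concentration", "Dose"])
        for a in sorted(geom.spot_assignments, key=lambda a: a.address):
            w.writerow([a.block, a.row, a.column, a.probe_key, a.probe_key,
                        str(a.concentration) if a.concentration else "",
                        str(a.dose) if a.dose else ""])
    return path


def build_geometry(sub: SubarrayLayout, arr: ArrayLayout,
                   layout_id: str = "built",
                   replicate_scope: str = "slide") -> ArrayGeometry:
    """Replicate one subarray layout into every placed block.

    Grid cells without an assignment become ``EMPTY`` placeholders so the
    emitted geometry always covers the full ``rows × columns`` grid per block.
    """
    arr.validate()
    if len(set(arr.block_positions)) != len(arr.block_positions):
        raise IntegrityError("overlapping block indices in array layout")
    assignments = []
    for b in arr.block_positions:
        for r in range(1, sub.rows + 1):
            for c in range(1, sub.columns + 1):
                key, conc, dose = sub.cell_assignments.get((r, c), (EMPTY_KEY, None, None))
                assignments.append(SpotAssignment(
                    block=b, row=r, column=c, probe_key=key or EMPTY_KEY,
                    concentration=conc, dose=dose))
    geom = ArrayGeometry(layout_id=layout_id, n_blocks=len(arr.block_positions),
                         spot_assignments=assignments, replicate_scope=replicate_scope)
    geom.validate()
    return geom


@dataclass
class JoinResult:
    """Outcome of linking scan spots to geometry by (block, row, column)."""

    matched: list[tuple[SpotRecord, SpotAssignment]]
    scan_only: list[tuple[int, int, int]]
    geometry_only: list[tuple[int, int, int]]

    @property
    def n_matched(self) -> int:
        return len(self.matched)


def join_spots(scan: ScanResult, geom: ArrayGeometry) -> JoinResult:
    """Inner-join scan spots with geometry assignments on spot address.

    Unmatched addresses on either side are listed, never silently dropped.
    Zero matches raises — it almost always means the wrong GAL was supplied.
    """
    by_addr = {a.address: a for a in geom.spot_assignments}
    matched, scan_only = [], []
    seen = set()
    for spot in scan.spots:
        a = by_addr.get(spot.address)
        if a is None:
            scan_only.append(spot.address)
        else:
            matched.append((spot, a))
            seen.add(spot.address)
    geometry_only = sorted(addr for addr in by_addr if addr not in seen)
    if not matched:
        raise IntegrityError(
            "no spot addresses in common between scan and geometry "
            "(wrong GAL file for this slide?)")
    return JoinResult(matched=matched, scan_only=scan_only,
                      geometry_only=geometry_only)
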