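"""Reading, validation and resampling of closed 2D specimen outlines.

Outlines are stored *open*: the closing segment from the last point back to
the first is implicit and the last point must not duplicate the first.
Coordinates follow the dorsal-view convention of the package: y increases
upward and anterior is toward +y, so "forward-directed" is well defined for
the visual-field model.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import DataError, DegeneracyError, FormatError, ParameterError

#: Admissible specimen group labels.
GROUPS = ("extant", "fossil", "new")


def _check_group(group: str) -> str:
    if group not in GROUPS:
        raise ParameterError(f"unknown group {group!r}; expected one of {GROUPS}")
    return group


@dataclass
class Outline:
    """A closed planar outline of one specimen (head capsule + stylets).

    Parameters
    ----------
    specimen_id : str
        Unique identifier of the specimen.
    points : (n, 2) array_like
        Ordered outline coordinates. The loop is implicitly closed; the
        last point must not repeat the first.
    group : {"extant", "fossil", "new"}
        Provenance group used for morphospace occupancy.
    taxon_label : str, optional
        Free-text taxon annotation.
    """

    specimen_id: str
    points: np.ndarray
    group: str = "extant"
    taxon_label: str | None = None

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise FormatError(
                f"outline {self.specimen_id!r}: points must be (n, 2), got {pts.shape}"
            )
        if len(pts) < 3:
            raise FormatError(
                f"outline {self.specimen_id!r}: need at least 3 points, got {len(pts)}"
            )
        if not np.all(np.isfinite(pts)):
            raise FormatError(f"outline {self.specimen_id!r}: non-finite coordinate")
        # drop a duplicated closing point (common digitizing convention)
        if np.array_equal(pts[0], pts[-1]):
            pts = pts[:-1]
            if len(pts) < 3:
                raise FormatError(
                    f"outline {self.specimen_id!r}: fewer than 3 distinct points"
                )
        closed = np.vstack([pts, pts[:1]])
        seg = np.diff(closed, axis=0)
        if np.any(np.all(seg == 0.0, axis=1)):
            raise FormatError(
                f"outline {self.specimen_id!r}: consecutive duplicate points"
            )
        self.points = pts
        _check_group(self.group)
        if self.signed_area() == 0.0:
            raise DegeneracyError(
                f"outline {self.specimen_id!r}: zero signed area (collinear points?)"
            )

    # -- basic geometry -------------------------------------------------

    def signed_area(self) -> float:
        """Shoelace signed area; positive for counterclockwise order."""
        x, y = self.points[:, 0], self.points[:, 1]
        return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))

    def is_ccw(self) -> bool:
        return self.signed_area() > 0.0

    def perimeter(self) -> float:
        closed = np.vstack([self.points, self.points[:1]])
        return float(np.sum(np.hypot(*np.diff(closed, axis=0).T)))

    def centroid(self) -> np.ndarray:
        """Arc-length-weighted centroid of the boundary (not the region)."""
        closed = np.vstack([self.points, self.points[:1]])
        seg = np.diff(closed, axis=0)
        lens = np.hypot(seg[:, 0], seg[:, 1])
        mids = 0.5 * (closed[:-1] + closed[1:])
        return (mids * lens[:, None]).sum(axis=0) / lens.sum()

    def __len__(self) -> int:  # number of stored points
        return len(self.points)


@dataclass
class OutlineSet:
    """An ordered collection of outlines with dataset provenance."""

    outlines: list[Outline]
    provenance: str = ""

    def __post_init__(self) -> None:
        ids = [o.specimen_id for o in self.outlines]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise FormatError(f"duplicate specimen ids: {dup}")

    def __len__(self) -> int:
        return len(self.outlines)

    def __iter__(self):
        return iter(self.outlines)

    @property
    def specimen_ids(self) -> list[str]:
        return [o.specimen_id for o in self.outlines]

    @property
    def groups(self) -> list[str]:
        return [o.group for o in self.outlines]


@dataclass(frozen=True)
class MeasurementRecord:
    """Head length and largest-lens diameter of one specimen."""

    specimen_id: str
    head_length: float
    lens_diameter: float
    group: str = "extant"

    def __post_init__(self) -> None:
        if not (self.head_length > 0):
            raise DataError(
                f"specimen {self.specimen_id!r}: head_length must be > 0, "
                f"got {self.head_length}"
            )
        if not (self.lens_diameter > 0):
            raise DataError(
                f"specimen {self.specimen_id!r}: lens_diameter must be > 0, "
                f"got {self.lens_diameter}"
            )
        _check_group(self.group)


# ---------------------------------------------------------------------------
# orientation and resampling
# ---------------------------------------------------------------------------


def normalize_orientation(outline: Outline) -> Outline:
    """Force counterclockwise point order, keeping the starting point.

    Returns the outline unchanged if it is already counterclockwise.
    """
    if outline.is_ccw():
        return outline
    pts = outline.points
    # keep pts[0] first, reverse the rest
    rev = np.vstack([pts[:1], pts[1:][::-1]])
    return replace(outline, points=rev)


def resample_equal_arclength(outline: Outline, n_points: int) -> Outline:
    """Resample to exactly ``n_points`` equally spaced by arc length.

    The first resampled point coincides with the original starting point;
    spacing is perimeter / n_points along the closed polygon.
    """
    if n_points < 3:
        raise ParameterError(f"n_points must be >= 3, got {n_points}")
    closed = np.vstack([outline.points, outline.points[:1]])
    seg = np.diff(closed, axis=0)
    lens = np.hypot(seg[:, 0], seg[:, 1])
    t = np.concatenate([[0.0], np.cumsum(lens)])
    T = t[-1]
    targets = np.arange(n_points) * (T / n_points)
    x = np.interp(targets, t, closed[:, 0])
    y = np.interp(targets, t, closed[:, 1])
    return replace(outline, points=np.column_stack([x, y]))


# ---------------------------------------------------------------------------
# file formats
# ---------------------------------------------------------------------------


def _parse_xy_rows(rows: Iterable[Sequence[str]], source: str) -> np.ndarray:
    pts = []
    for i, row in enumerate(rows):
        cells = [c for c in row if c.strip() != ""]
        if not cells:
            continue
        if len(cells) < 2:
            raise FormatError(f"{source}: row {i} has fewer than 2 columns")
        try:
            pts.append((float(cells[0]), float(cells[1])))
        except ValueError:
            if i == 0:
                continue  # header row
            raise FormatError(f"{source}: non-numeric cell in row {i}") from None
    if len(pts) < 3:
        raise FormatError(f"{source}: fewer than 3 valid points ({len(pts)})")
    return np.asarray(pts, dtype=float)


def read_outline_table(
    path: str | Path, specimen_id: str, group: str = "extant", taxon_label: str | None = None
) -> Outline:
    """Read a two-column (x, y) CSV/TSV coordinate table as one Outline.

    An optional header row is tolerated; a duplicated closing point is
    dropped. Comma, tab and whitespace delimiters are accepted.
    """
    path = Path(path)
    text = path.read_text()
    rows = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "," in line:
            rows.append(line.split(","))
        else:
            rows.append(line.split())
    pts = _parse_xy_rows(rows, str(path))
    return Outline(specimen_id=specimen_id, points=pts, group=group, taxon_label=taxon_label)


def write_outline_table(outline: Outline, path: str | Path) -> None:
    """Write an outline as a two-column CSV with an ``x,y`` header."""
    path = Path(path)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["x", "y"])
        for x, y in outline.points:
            w.writerow([repr(float(x)), repr(float(y))])


def read_tps_outlines(path: str | Path, group: str = "extant") -> OutlineSet:
    """Read a TPS outline file (OUTLINES=/POINTS=/ID= records).

    One Outline per specimen; the ID record supplies the specimen id (a
    running index is used when absent). ``group`` is applied to every
    specimen since TPS files carry no group metadata.
    """
    path = Path(path)
    lines = [ln.strip() for ln in path.read_text().splitlines()]
    outlines: list[Outline] = []
    i = 0
    counter = 0

    def flush(pts_rows, declared, spec_id):
        nonlocal counter
        if pts_rows is None:
            return
        sid = spec_id if spec_id is not None else f"tps_{counter}"
        if declared is not None and declared != len(pts_rows):
            raise FormatError(
                f"{path}: specimen {sid!r} declares POINTS={declared} "
                f"but has {len(pts_rows)} coordinate rows"
            )
        pts = _parse_xy_rows(pts_rows, f"{path}:{sid}")
        outlines.append(Outline(specimen_id=sid, points=pts, group=group))
        counter += 1

    pts_rows: list[list[str]] | None = None
    declared: int | None = None
    spec_id: str | None = None
    for ln in lines:
        if not ln:
            continue
        upper = ln.upper()
        if upper.startswith("OUTLINES="):
            if pts_rows is not None:
                flush(pts_rows, declared, spec_id)
                pts_rows, declared, spec_id = None, None, None
            pts_rows = []
        elif upper.startswith("POINTS="):
            declared = int(ln.split("=", 1)[1])
            if pts_rows is None:
                pts_rows = []
        elif upper.startswith("ID="):
            spec_id = ln.split("=", 1)[1].strip()
            flush(pts_rows, declared, spec_id)
            pts_rows, declared, spec_id = None, None, None
        elif upper.startswith(("LM=", "IMAGE=", "SCALE=")):
            continue
        else:
            if pts_rows is None:
                raise FormatError(f"{path}: coordinate row outside a specimen block")
            pts_rows.append(ln.split())
    flush(pts_rows, declared, spec_id)
    if not outlines:
        raise FormatError(f"{path}: no specimens found")
    return OutlineSet(outlines=outlines, provenance=str(path))


def write_tps_outlines(outline_set: OutlineSet, path: str | Path) -> None:
    """Write an OutlineSet in the TPS outline dialect read by this module."""
    path = Path(path)
    with open(path, "w") as fh:
        for o in outline_set:
            fh.write("OUTLINES=1\n")
            fh.write(f"POINTS={len(o)}\n")
            for x, y in o.points:
                fh.write(f"{float(x)!r} {float(y)!r}\n")
            fh.write(f"ID={o.specimen_id}\n")


def read_manifest(path: str | Path) -> OutlineSet:
    """Read a specimen manifest CSV and load every referenced outline file.

    Columns: ``specimen_id, group, taxon_label, file``; file paths are
    resolved relative to the manifest's directory.
    """
    path = Path(path)
    df = pd.read_csv(path)
    required = {"specimen_id", "group", "file"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: manifest must have columns {sorted(required)}")
    outlines = []
    for _, row in df.iterrows():
        fpath = path.parent / str(row["file"])
        if not fpath.exists():
            raise FormatError(f"{path}: outline file not found: {fpath}")
        taxon = row.get("taxon_label")
        taxon = None if pd.isna(taxon) else str(taxon)
        outlines.append(
            read_outline_table(
                fpath, specimen_id=str(row["specimen_id"]),
                group=str(row["group"]), taxon_label=taxon,
            )
        )
    return OutlineSet(outlines=outlines, provenance=str(path))


def write_manifest(outline_set: OutlineSet, directory: str | Path) -> Path:
    """Write per-specimen coordinate CSVs plus a ``manifest.csv``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for o in outline_set:
        fname = f"{o.specimen_id}.csv"
        write_outline_table(o, directory / fname)
        rows.append(
            {"specimen_id": o.specimen_id, "group": o.group,
             "taxon_label": o.taxon_label or "", "file": fname}
        )
    manifest = directory / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def read_measurements(path: str | Path) -> list[MeasurementRecord]:
    """Read a measurement CSV (specimen_id, head_length, lens_diameter, group)."""
    path = Path(path)
    df = pd.read_csv(path)
    required = {"specimen_id", "head_length", "lens_diameter"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: measurement table must have columns {sorted(required)}")
    records = []
    for _, row in df.iterrows():
        records.append(
            MeasurementRecord(
                specimen_id=str(row["specimen_id"]),
                head_length=float(row["head_length"]),
                lens_diameter=float(row["lens_diameter"]),
                group=str(row.get("group", "extant")),
            )
        )
    return records


def write_measurements(records: Sequence[MeasurementRecord], path: str | Path) -> None:
    pd.DataFrame(
        [
            {"specimen_id": r.specimen_id, "head_length": r.head_length,
             "lens_diameter": r.lens_diameter, "group": r.group}
            for r in records
        ]
    ).to_csv(path, index=False)
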