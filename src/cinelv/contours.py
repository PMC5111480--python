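"""Contour tracings, planar geometry primitives and the contour CSV dialect.

A tracing is an ordered planar polygon in millimetres, implicitly closed
(the last vertex connects back to the first; files never repeat the first
vertex). Akinetic infarct segments are stored as half-open vertex-index
ranges on the same polygon, so arc length and circumference are always
measured on identical geometry and the arc can never exceed the perimeter.

The file dialect is one CSV row per vertex with columns::

    subject_id, timepoint, slice_index, phase_index, border {epi|endo},
    vertex_index, x_mm, y_mm, infarct {0|1}

preceded by ``#``-prefixed metadata lines (``# slice_thickness_mm=1.0``).
Infarct arcs are reconstructed as maximal runs of ``infarct=1`` vertices.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from shapely.geometry import Polygon as _ShapelyPolygon

from .errors import (
    ArcIndexError,
    ContourParseError,
    DegeneratePolygonError,
    InvalidPolygonError,
    PairingError,
    StudyStructureError,
)

__all__ = [
    "Border",
    "ContourTracing",
    "CineStudy",
    "polygon_area",
    "polyline_length",
    "infarct_edge_mask",
    "read_contours",
    "write_contours",
]

# coordinates are serialised at fixed precision; 1e-6 mm = 1 nm, far below
# any tracing noise, so the writer is lossless in practice
_COORD_DECIMALS = 6
_COORD_FMT = f"{{:.{_COORD_DECIMALS}f}}"


class Border(str, Enum):
    """Which myocardial border a tracing outlines."""

    EPICARDIAL = "epicardial"
    ENDOCARDIAL = "endocardial"

    @property
    def short(self) -> str:
        return "epi" if self is Border.EPICARDIAL else "endo"

    @classmethod
    def from_short(cls, s: str) -> "Border":
        if s == "epi":
            return cls.EPICARDIAL
        if s == "endo":
            return cls.ENDOCARDIAL
        raise ValueError(f"unknown border code {s!r} (expected 'epi' or 'endo')")


def _as_vertex_array(vertices: Iterable[Sequence[float]]) -> np.ndarray:
    arr = np.asarray(vertices, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise DegeneratePolygonError(
            f"vertices must be an (n, 2) array of planar points, got shape {arr.shape}"
        )
    return arr


def validate_polygon(vertices: np.ndarray) -> None:
    """Reject degenerate (<3 vertices, duplicate neighbours) and
    self-intersecting polygons. The closing edge is included in both checks."""
    n = len(vertices)
    if n < 3:
        raise DegeneratePolygonError(f"polygon needs >= 3 vertices, got {n}")
    diffs = np.diff(np.vstack([vertices, vertices[:1]]), axis=0)
    if np.any(np.all(diffs == 0.0, axis=1)):
        raise DegeneratePolygonError("consecutive duplicate vertices are forbidden")
    if not _ShapelyPolygon(vertices).is_valid:
        raise InvalidPolygonError("polygon is self-intersecting")


def polygon_area(vertices: Iterable[Sequence[float]]) -> float:
    """Absolute shoelace area (mm²) of a simple polygon.

    Orientation-independent; raises for degenerate or self-intersecting
    input.
    """
    arr = _as_vertex_array(vertices)
    validate_polygon(arr)
    x, y = arr[:, 0], arr[:, 1]
    signed = 0.5 * np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)
    return float(abs(signed))


def polyline_length(
    vertices: Iterable[Sequence[float]],
    index_range: tuple[int, int] | None = None,
    closed: bool = False,
) -> float:
    """Euclidean length (mm) of the open polyline over a half-open vertex
    range, or the full closed perimeter.

    ``index_range=(s, e)`` selects vertices ``s..e-1``; the length is the sum
    of the ``e - s - 1`` edges between consecutive selected vertices (0 for an
    empty or single-vertex range). With ``closed=True`` the range must cover
    all vertices and the closing edge back to the first vertex is included.
    """
    arr = _as_vertex_array(vertices)
    n = len(arr)
    if index_range is None:
        index_range = (0, n)
    s, e = index_range
    if not (0 <= s <= e <= n):
        raise IndexError(f"index range ({s}, {e}) invalid for {n} vertices")
    if closed and (s, e) != (0, n):
        raise IndexError("closed=True requires the range to cover all vertices")
    seg = arr[s:e]
    if closed:
        seg = np.vstack([seg, seg[:1]])
    if len(seg) < 2:
        return 0.0
    return float(np.sum(np.linalg.norm(np.diff(seg, axis=0), axis=1)))


@dataclass
class ContourTracing:
    """One traced border on one short-axis slice at one cardiac phase.

    Parameters
    ----------
    slice_index : int
        0-based, base -> apex.
    phase_index : int
        0-based position within the cardiac cycle.
    border : Border
        Epicardial or endocardial.
    vertices : (n, 2) array
        Ordered planar coordinates in mm; the polygon is implicitly closed.
    infarct_arcs : list of (start, end)
        Half-open vertex-index ranges marking akinetic segments.
    """

    slice_index: int
    phase_index: int
    border: Border
    vertices: np.ndarray
    infarct_arcs: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.border = Border(self.border)
        self.vertices = _as_vertex_array(self.vertices)
        validate_polygon(self.vertices)
        if self.slice_index < 0 or self.phase_index < 0:
            raise StudyStructureError("slice/phase indices must be non-negative")
        n = len(self.vertices)
        self.infarct_arcs = [(int(s), int(e)) for s, e in self.infarct_arcs]
        covered = np.zeros(n, dtype=bool)
        for s, e in self.infarct_arcs:
            if not (0 <= s < e <= n):
                raise ArcIndexError(
                    f"infarct arc ({s}, {e}) out of range for {n} vertices"
                )
            if covered[s:e].any():
                raise ArcIndexError("infarct arcs overlap")
            covered[s:e] = True

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    def area(self) -> float:
        """Enclosed area in mm²."""
        return polygon_area(self.vertices)

    def perimeter(self) -> float:
        """Closed circumference in mm (T_epi / T_endo of the slice)."""
        return polyline_length(self.vertices, closed=True)

    def infarct_vertex_mask(self) -> np.ndarray:
        mask = np.zeros(self.n_vertices, dtype=bool)
        for s, e in self.infarct_arcs:
            mask[s:e] = True
        return mask

    def infarct_length(self) -> float:
        """Total akinetic arc length in mm (I_epi / I_endo of the slice).

        Counted over the cyclic polygon: an edge contributes when both of
        its endpoints are marked, so a full marking yields the whole
        perimeter and the measure is monotone in the marked set.
        """
        mask = self.infarct_vertex_mask()
        if not mask.any():
            return 0.0
        edge_mask = infarct_edge_mask(mask)
        closed = np.vstack([self.vertices, self.vertices[:1]])
        edge_len = np.linalg.norm(np.diff(closed, axis=0), axis=1)
        return float(edge_len[edge_mask].sum())

    def equals(self, other: "ContourTracing", atol: float = 0.0) -> bool:
        return (
            self.slice_index == other.slice_index
            and self.phase_index == other.phase_index
            and self.border == other.border
            and self.vertices.shape == other.vertices.shape
            and np.allclose(self.vertices, other.vertices, atol=atol, rtol=0.0)
            and np.array_equal(self.infarct_vertex_mask(), other.infarct_vertex_mask())
        )


def infarct_edge_mask(vertex_mask: np.ndarray) -> np.ndarray:
    """Cyclic edge mask: edge i (vertex i -> i+1 mod n) is infarcted iff both
    endpoints are marked."""
    return vertex_mask & np.roll(vertex_mask, -1)


def _arcs_from_mask(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as half-open (start, end) ranges. A run that
    wraps past the last vertex is split at index 0 (two ranges); the cyclic
    edge between them is still counted by :func:`infarct_edge_mask`."""
    arcs: list[tuple[int, int]] = []
    n = len(mask)
    i = 0
    while i < n:
        if mask[i]:
            j = i
            while j < n and mask[j]:
                j += 1
            arcs.append((i, j))
            i = j
        else:
            i += 1
    return arcs


@dataclass
class CineStudy:
    """All contour tracings for one animal at one timepoint.

    Validation enforces the pairing of epicardial/endocardial borders on
    every (slice, phase), strict containment by area, an identical phase set
    on every slice, and contiguous slice indices.
    """

    subject_id: str
    timepoint: str
    tracings: list[ContourTracing]
    slice_thickness: float = 1.0

    def __post_init__(self) -> None:
        if self.slice_thickness <= 0:
            raise StudyStructureError("slice_thickness must be > 0 mm")
        if not self.tracings:
            raise StudyStructureError("study has no tracings")
        index: dict[tuple[int, int, Border], ContourTracing] = {}
        for t in self.tracings:
            key = (t.slice_index, t.phase_index, t.border)
            if key in index:
                raise PairingError(
                    f"duplicate tracing for slice {t.slice_index}, phase "
                    f"{t.phase_index}, border {t.border.value}"
                )
            index[key] = t
        self._index = index

        per_slice_phases: dict[int, set[int]] = {}
        for (sl, ph, _b) in index:
            per_slice_phases.setdefault(sl, set()).add(ph)
        slices = sorted(per_slice_phases)
        if slices != list(range(slices[0], slices[0] + len(slices))):
            raise StudyStructureError(f"slice indices not contiguous: {slices}")
        phase_sets = {frozenset(v) for v in per_slice_phases.values()}
        if len(phase_sets) != 1:
            raise StudyStructureError("phase set differs between slices")
        self._slices = slices
        self._phases = sorted(next(iter(phase_sets)))

        for sl in slices:
            for ph in self._phases:
                epi = index.get((sl, ph, Border.EPICARDIAL))
                endo = index.get((sl, ph, Border.ENDOCARDIAL))
                if epi is None or endo is None:
                    missing = "epicardial" if epi is None else "endocardial"
                    raise PairingError(
                        f"missing {missing} tracing for slice {sl}, phase {ph}"
                    )
                if not endo.area() < epi.area():
                    raise PairingError(
                        f"endocardial area must be < epicardial area "
                        f"(slice {sl}, phase {ph})"
                    )

    @property
    def slices(self) -> list[int]:
        return list(self._slices)

    @property
    def phases(self) -> list[int]:
        return list(self._phases)

    @property
    def n_slices(self) -> int:
        return len(self._slices)

    @property
    def n_phases(self) -> int:
        return len(self._phases)

    def get(self, slice_index: int, phase_index: int, border: Border) -> ContourTracing:
        key = (slice_index, phase_index, Border(border))
        try:
            return self._index[key]
        except KeyError:
            raise PairingError(
                f"no tracing for slice {slice_index}, phase {phase_index}, "
                f"border {Border(border).value}"
            ) from None

    def equals(self, other: "CineStudy", atol: float = 0.0) -> bool:
        if (
            self.subject_id != other.subject_id
            or self.timepoint != other.timepoint
            or self.slice_thickness != other.slice_thickness
            or len(self.tracings) != len(other.tracings)
        ):
            return False
        for key, t in self._index.items():
            o = other._index.get(key)
            if o is None or not t.equals(o, atol=atol):
                return False
        return True


_COLUMNS = [
    "subject_id",
    "timepoint",
    "slice_index",
    "phase_index",
    "border",
    "vertex_index",
    "x_mm",
    "y_mm",
    "infarct",
]


def write_contours(study: CineStudy, path: str | Path) -> None:
    """Serialise a study to the contour CSV dialect.

    Rows are sorted by (slice, phase, border) with vertices in order, and
    coordinates are written at fixed precision, so re-serialising a loaded
    file is byte-identical.
    """
    buf = io.StringIO()
    buf.write(f"# slice_thickness_mm={_COORD_FMT.format(study.slice_thickness)}\n")
    buf.write(",".join(_COLUMNS) + "\n")
    keys = sorted(
        study._index, key=lambda k: (k[0], k[1], k[2].short)
    )
    for key in keys:
        t = study._index[key]
        mask = t.infarct_vertex_mask()
        for vi, (x, y) in enumerate(t.vertices):
            buf.write(
                f"{study.subject_id},{study.timepoint},{t.slice_index},"
                f"{t.phase_index},{t.border.short},{vi},"
                f"{_COORD_FMT.format(x)},{_COORD_FMT.format(y)},"
                f"{int(mask[vi])}\n"
            )
    Path(path).write_text(buf.getvalue(), encoding="utf-8")


def read_contours(path: str | Path, slice_thickness: float | None = None) -> CineStudy:
    """Load and fully validate a study from the contour CSV dialect.

    Slice thickness comes from the ``# slice_thickness_mm=`` metadata line
    unless overridden; it defaults to 1 mm when absent.
    """
    path = Path(path)
    meta: dict[str, str] = {}
    header_lines = 0
    with path.open("r", encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            header_lines += 1
            body = line[1:].strip()
            if "=" in body:
                k, v = body.split("=", 1)
                meta[k.strip()] = v.strip()
    if slice_thickness is None:
        slice_thickness = float(meta.get("slice_thickness_mm", 1.0))

    try:
        df = pd.read_csv(path, comment="#", dtype=str, keep_default_na=False)
    except Exception as exc:  # pragma: no cover - pandas message varies
        raise ContourParseError(f"cannot parse CSV: {exc}") from exc
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise ContourParseError(
            f"missing column(s) {missing}", line=header_lines + 1
        )

    def _conv(row_pos: int, col: str, value: str, kind):
        try:
            return kind(value)
        except ValueError:
            # +2: 1-based and the column-header line
            raise ContourParseError(
                f"bad {col} value {value!r}", line=header_lines + row_pos + 2
            ) from None

    subject_ids = set(df["subject_id"])
    timepoints = set(df["timepoint"])
    if len(subject_ids) != 1 or len(timepoints) != 1:
        raise ContourParseError(
            f"file must contain exactly one subject/timepoint, got "
            f"{sorted(subject_ids)} / {sorted(timepoints)}"
        )

    tracings: list[ContourTracing] = []
    group_cols = ["slice_index", "phase_index", "border"]
    for pos, row in enumerate(df.itertuples(index=False)):
        # validate convertibility row-by-row so errors carry line numbers
        _conv(pos, "slice_index", row.slice_index, int)
        _conv(pos, "phase_index", row.phase_index, int)
        _conv(pos, "vertex_index", row.vertex_index, int)
        _conv(pos, "x_mm", row.x_mm, float)
        _conv(pos, "y_mm", row.y_mm, float)
        if row.infarct not in ("0", "1"):
            raise ContourParseError(
                f"bad infarct flag {row.infarct!r}", line=header_lines + pos + 2
            )
        if row.border not in ("epi", "endo"):
            raise ContourParseError(
                f"bad border {row.border!r}", line=header_lines + pos + 2
            )

    df = df.astype(
        {
            "slice_index": int,
            "phase_index": int,
            "vertex_index": int,
            "x_mm": float,
            "y_mm": float,
            "infarct": int,
        }
    )
    for (sl, ph, border_code), grp in df.groupby(group_cols, sort=True):
        grp = grp.sort_values("vertex_index")
        expected = np.arange(len(grp))
        if not np.array_equal(grp["vertex_index"].to_numpy(), expected):
            raise ContourParseError(
                f"vertex indices of slice {sl}, phase {ph}, border "
                f"{border_code} are not 0..n-1 without gaps"
            )
        mask = grp["infarct"].to_numpy().astype(bool)
        tracings.append(
            ContourTracing(
                slice_index=int(sl),
                phase_index=int(ph),
                border=Border.from_short(str(border_code)),
                vertices=grp[["x_mm", "y_mm"]].to_numpy(),
                infarct_arcs=_arcs_from_mask(mask),
            )
        )

    return CineStudy(
        subject_id=next(iter(subject_ids)),
        timepoint=next(iter(timepoints)),
        tracings=tracings,
        slice_thickness=slice_thickness,
    )
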