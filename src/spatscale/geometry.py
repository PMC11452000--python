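"""Point sets, grids, polygons and pairwise Euclidean distances.

All coordinates are planar, in a projected coordinate system with
consistent length units (e.g. km).  Distances are Euclidean in those
units; nothing here knows about the sphere.
"""

from __future__ import annotations

import json
import logging
import math
from csv import Error as CsvError
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import shapely
from scipy.spatial.distance import pdist, squareform
from shapely.geometry import LinearRing
from shapely.geometry import Polygon as _ShapelyPolygon

from .exceptions import InvalidParameterError

logger = logging.getLogger(__name__)

__all__ = [
    "PointSet",
    "Polygon",
    "DistanceMatrix",
    "make_rect_grid",
    "clip_to_polygon",
    "read_points_table",
    "subsample_points",
    "pairwise_distances",
    "make_fixture_polygon",
    "FIXTURE_POLYGONS",
]


@dataclass(frozen=True)
class PointSet:
    """An ordered collection of 2-D planar coordinates s_1..s_n.

    Parameters
    ----------
    coords
        Sequence of (x, y) pairs; stored as an (n, 2) float array.
    unit_label
        Free-text length unit used in reports and plots (e.g. ``"km"``).
    """

    coords: np.ndarray
    unit_label: str = "units"

    def __post_init__(self) -> None:
        arr = np.atleast_2d(np.asarray(self.coords, dtype=float))
        if arr.size == 0:
            arr = arr.reshape(0, 2)
        if arr.ndim != 2 or arr.shape[1] != 2:
            raise InvalidParameterError(
                f"coords must be an (n, 2) array of planar coordinates, got shape {arr.shape}"
            )
        if not np.all(np.isfinite(arr)):
            raise InvalidParameterError("coordinates must all be finite")
        arr.flags.writeable = False
        object.__setattr__(self, "coords", arr)
        ndup = self.duplicate_count()
        if ndup:
            logger.warning(
                "point set contains %d duplicated location(s); "
                "off-diagonal zero distances will appear",
                ndup,
            )

    def __len__(self) -> int:
        return self.coords.shape[0]

    @property
    def n(self) -> int:
        return self.coords.shape[0]

    @property
    def x(self) -> np.ndarray:
        return self.coords[:, 0]

    @property
    def y(self) -> np.ndarray:
        return self.coords[:, 1]

    def duplicate_count(self) -> int:
        """Number of points that coincide exactly with an earlier point."""
        if len(self) == 0:
            return 0
        return len(self) - np.unique(self.coords, axis=0).shape[0]


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric n x n Euclidean distance matrix with zero diagonal."""

    values: np.ndarray
    unit_label: str = "units"

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=float)
        if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
            raise InvalidParameterError(f"distance matrix must be square, got {arr.shape}")
        arr.flags.writeable = False
        object.__setattr__(self, "values", arr)

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def max(self) -> float:
        return float(self.values.max(initial=0.0))


def _close_ring(ring: np.ndarray) -> np.ndarray:
    if not np.array_equal(ring[0], ring[-1]):
        ring = np.vstack([ring, ring[0]])
    return ring


@dataclass(frozen=True)
class Polygon:
    """A simple polygon: one outer ring and zero or more hole rings.

    Rings are validated at construction: the outer ring needs at least
    three distinct vertices and every ring must be simple
    (non-self-intersecting); violations raise :class:`InvalidParameterError`.
    """

    shell: np.ndarray
    holes: tuple = ()
    _geom: _ShapelyPolygon = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        shell = np.asarray(self.shell, dtype=float)
        if shell.ndim != 2 or shell.shape[1] != 2:
            raise InvalidParameterError("polygon ring must be an (m, 2) vertex array")
        holes = tuple(np.asarray(h, dtype=float) for h in self.holes)
        distinct = np.unique(shell, axis=0).shape[0]
        if distinct < 3:
            raise InvalidParameterError(
                f"outer ring needs >= 3 distinct vertices, got {distinct}"
            )
        for name, ring in [("outer", shell)] + [
            (f"hole {i}", h) for i, h in enumerate(holes)
        ]:
            lr = LinearRing(_close_ring(ring))
            if not lr.is_simple:
                raise InvalidParameterError(f"{name} ring is self-intersecting")
        geom = _ShapelyPolygon(_close_ring(shell), [_close_ring(h) for h in holes])
        if not geom.is_valid:
            raise InvalidParameterError(
                f"invalid polygon: {shapely.validation.explain_validity(geom)}"
            )
        shell.flags.writeable = False
        object.__setattr__(self, "shell", shell)
        object.__setattr__(self, "holes", holes)
        object.__setattr__(self, "_geom", geom)

    @property
    def geom(self) -> _ShapelyPolygon:
        """The underlying shapely geometry."""
        return self._geom

    @property
    def area(self) -> float:
        return float(self._geom.area)

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        """(minx, miny, maxx, maxy)."""
        return self._geom.bounds

    @classmethod
    def from_shapely(cls, geom: _ShapelyPolygon) -> "Polygon":
        return cls(
            shell=np.asarray(geom.exterior.coords),
            holes=tuple(np.asarray(r.coords) for r in geom.interiors),
        )

    @classmethod
    def from_geojson(cls, source: str | Path | Mapping) -> "Polygon":
        """Load a Polygon geometry from a GeoJSON file, mapping or geometry dict.

        Accepts a bare geometry, a Feature, or a FeatureCollection whose
        first Polygon/MultiPolygon feature is used (MultiPolygon: the part
        with the largest area).
        """
        if isinstance(source, (str, Path)):
            with open(source) as fh:
                obj = json.load(fh)
        else:
            obj = dict(source)
        geom = _extract_polygon_geometry(obj)
        return cls.from_shapely(geom)

    @classmethod
    def from_vertex_text(cls, path: str | Path) -> "Polygon":
        """Load from a plain text vertex list.

        One ``x y`` (or ``x,y``) pair per line; a blank line starts a new
        ring, the first ring being the outer one.
        """
        rings: list[list[tuple[float, float]]] = [[]]
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
            line = raw.strip()
            if not line:
                if rings[-1]:
                    rings.append([])
                continue
            parts = line.replace(",", " ").split()
            if len(parts) != 2:
                raise InvalidParameterError(
                    f"{path}: line {lineno}: expected 'x y', got {raw!r}"
                )
            try:
                rings[-1].append((float(parts[0]), float(parts[1])))
            except ValueError as exc:
                raise InvalidParameterError(
                    f"{path}: line {lineno}: non-numeric vertex {raw!r}"
                ) from exc
        rings = [r for r in rings if r]
        if not rings:
            raise InvalidParameterError(f"{path}: no vertices found")
        return cls(shell=np.asarray(rings[0]), holes=tuple(np.asarray(r) for r in rings[1:]))


def _extract_polygon_geometry(obj: Mapping) -> _ShapelyPolygon:
    gtype = obj.get("type")
    if gtype == "FeatureCollection":
        for feature in obj.get("features", []):
            try:
                return _extract_polygon_geometry(feature)
            except InvalidParameterError:
                continue
        raise InvalidParameterError("no Polygon feature found in FeatureCollection")
    if gtype == "Feature":
        return _extract_polygon_geometry(obj["geometry"])
    if gtype == "Polygon":
        return shapely.geometry.shape(obj)
    if gtype == "MultiPolygon":
        parts = list(shapely.geometry.shape(obj).geoms)
        return max(parts, key=lambda g: g.area)
    raise InvalidParameterError(f"unsupported GeoJSON geometry type: {gtype!r}")


def make_rect_grid(
    width: float, height: float, increment: float, unit_label: str = "units"
) -> PointSet:
    """Regular grid over a width x height rectangle anchored at the origin.

    Points sit at ``(i*increment, j*increment)`` for
    ``0 <= i <= floor(width/increment)`` and ``0 <= j <= floor(height/increment)``,
    in row-major order (i outer, j inner).
    """
    for name, value in [("width", width), ("height", height), ("increment", increment)]:
        if not (np.isfinite(value) and value > 0):
            raise InvalidParameterError(f"{name} must be positive and finite, got {value}")
    # small forgiveness so e.g. 0.3/0.1 -> 3 cells, not 2
    nx = int(math.floor(width / increment + 1e-9))
    ny = int(math.floor(height / increment + 1e-9))
    xs = np.arange(nx + 1) * increment
    ys = np.arange(ny + 1) * increment
    coords = np.column_stack([np.repeat(xs, ny + 1), np.tile(ys, nx + 1)])
    return PointSet(coords, unit_label=unit_label)


def clip_to_polygon(points: PointSet, poly: Polygon) -> PointSet:
    """Keep the points inside the polygon, boundary included, in original order.

    Points on the outer ring count as inside; points strictly inside a hole
    are dropped (a point on a hole's rim is on the polygon's boundary and is
    kept).  An empty result is allowed and logged as a warning.
    """
    if len(points) == 0:
        return points
    mask = shapely.covers(poly.geom, shapely.points(points.coords))
    if not mask.any():
        logger.warning("clip_to_polygon: no points fall inside the polygon")
    return PointSet(points.coords[mask], unit_label=points.unit_label)


def read_points_table(
    path: str | Path, x_col: str, y_col: str, unit_label: str = "units"
) -> PointSet:
    """Read coordinates from a delimited text file with a header row.

    The delimiter is sniffed (comma, tab, semicolon, whitespace).  Rows with
    missing or non-numeric coordinates abort the read with an error naming
    the offending file rows (1-based, header = row 1).
    """
    path = Path(path)
    try:
        frame = pd.read_csv(path, sep=None, engine="python")
    except (pd.errors.EmptyDataError, pd.errors.ParserError, CsvError) as exc:
        raise InvalidParameterError(f"{path}: empty or unreadable file ({exc})") from exc
    if frame.empty:
        raise InvalidParameterError(f"{path}: no data rows")
    for col in (x_col, y_col):
        if col not in frame.columns:
            raise InvalidParameterError(
                f"{path}: column {col!r} not found; available columns: "
                + ", ".join(map(repr, frame.columns))
            )
    xs = pd.to_numeric(frame[x_col], errors="coerce")
    ys = pd.to_numeric(frame[y_col], errors="coerce")
    bad = xs.isna() | ys.isna()
    if bad.any():
        rows = [str(i + 2) for i in frame.index[bad][:10]]  # +2: header is row 1
        raise InvalidParameterError(
            f"{path}: missing or non-numeric coordinates in file row(s) "
            + ", ".join(rows)
            + (" ..." if bad.sum() > 10 else "")
        )
    return PointSet(np.column_stack([xs.to_numpy(), ys.to_numpy()]), unit_label=unit_label)


def subsample_points(points: PointSet, n_keep: int, seed: int) -> PointSet:
    """Uniform sample of ``min(n_keep, n)`` points without replacement.

    Deterministic for a fixed seed (NumPy PCG64 generator); the selected
    points keep their original relative order.  If ``n_keep >= n`` the
    point set is returned unchanged.
    """
    if n_keep < 1:
        raise InvalidParameterError(f"n_keep must be >= 1, got {n_keep}")
    if n_keep >= len(points):
        return points
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(len(points), size=n_keep, replace=False))
    return PointSet(points.coords[idx], unit_label=points.unit_label)


def pairwise_distances(points: PointSet) -> DistanceMatrix:
    """The n x n Euclidean distance matrix D between all point pairs."""
    if len(points) == 0:
        raise InvalidParameterError("cannot compute distances of an empty point set")
    if len(points) == 1:
        values = np.zeros((1, 1))
    else:
        values = squareform(pdist(points.coords))
    return DistanceMatrix(values, unit_label=points.unit_label)


# Unit-scale vertex lists; scaled by ``scale`` in make_fixture_polygon.
FIXTURE_POLYGONS: dict[str, np.ndarray] = {
    # 3/4 of the unit square (area 0.75 * scale^2)
    "l-shape": np.array(
        [(0, 0), (1, 0), (1, 0.5), (0.5, 0.5), (0.5, 1), (0, 1)], dtype=float
    ),
    # unit square with a rectangular bite taken out of the top edge
    "notched-rectangle": np.array(
        [
            (0, 0), (1, 0), (1, 1), (0.65, 1),
            (0.65, 0.7), (0.35, 0.7), (0.35, 1), (0, 1),
        ],
        dtype=float,
    ),
    # convex octagon inscribed in an ellipse inside the unit square
    "convex-blob": np.array(
        [
            (0.5 + 0.5 * math.cos(t), 0.5 + 0.45 * math.sin(t))
            for t in np.linspace(0.0, 2.0 * math.pi, 8, endpoint=False)
        ],
        dtype=float,
    ),
}


def make_fixture_polygon(kind: str, scale: float) -> Polygon:
    """Deterministic test-fixture polygon of the named shape.

    ``kind`` is one of ``l-shape``, ``notched-rectangle`` or ``convex-blob``;
    the unit-scale shape is multiplied by ``scale`` so it fits in
    ``[0, scale]^2``.
    """
    if not (np.isfinite(scale) and scale > 0):
        raise InvalidParameterError(f"scale must be positive, got {scale}")
    try:
        ring = FIXTURE_POLYGONS[kind]
    except KeyError:
        raise InvalidParameterError(
            f"unknown fixture kind {kind!r}; choose from "
            + ", ".join(sorted(FIXTURE_POLYGONS))
        ) from None
    return Polygon(shell=ring * float(scale))
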