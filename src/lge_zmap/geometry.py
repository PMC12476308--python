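"""Left-ventricular geometry: AHA 17-segment model, wall grouping, and the
nine-layer transmural partition.

The LV myocardium is partitioned two ways:

* circumferentially / longitudinally into the 17 AHA segments (6 basal,
  6 mid-ventricular, 4 apical, plus the apex as segment 17), grouped into
  four walls — anterior {1, 7, 13, 17}, lateral {5, 6, 11, 12, 16},
  inferior {4, 10, 15} and septal {2, 3, 8, 9, 14};
* transmurally into nine equally spaced layers labelled by depth fraction
  0.1 … 0.9, where 0 is the LV endocardium and 1 the epicardium.  In the
  septum the wall borders the RV cavity instead of the pericardium, so the
  septal "sub-epicardial" layers (0.7–0.9) are the RV-side sub-endocardium.

Layers group into three transmural bands: sub-endocardial (0.1–0.3),
mid-wall (0.4–0.6) and sub-epicardial (0.7–0.9).

``aggregate`` maps every myocardial pixel of a short-axis LGE stack to one
(segment, layer-shell) cell and averages intensities into a
``SegmentLayerTable`` (a tidy :class:`pandas.DataFrame`), the pipeline's
central exchange format.

Coordinate conventions
----------------------
Contours are closed planar polygons in physical millimetres, vertices
ordered counterclockwise.  Pixel (row i, col j) has its centre at
``x = (j + 0.5) * dx, y = (i + 0.5) * dy`` (half-open pixel convention).
Angles are measured in degrees, counterclockwise from the positive x axis;
the per-slice ``rv_insertion_angle`` is the direction of the anterior RV
insertion point seen from the LV blood-pool centroid.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import LinearRing, Point, Polygon

from .errors import AlignmentError, EmptyRegionError, GeometryError

# --------------------------------------------------------------------------
# Segment / layer bookkeeping
# --------------------------------------------------------------------------

SEGMENTS: tuple[int, ...] = tuple(range(1, 18))

#: Wall membership of each AHA segment.
WALL_OF_SEGMENT: dict[int, str] = {
    **{s: "anterior" for s in (1, 7, 13, 17)},
    **{s: "lateral" for s in (5, 6, 11, 12, 16)},
    **{s: "inferior" for s in (4, 10, 15)},
    **{s: "septal" for s in (2, 3, 8, 9, 14)},
}

WALLS: tuple[str, ...] = ("anterior", "lateral", "inferior", "septal")
SEGMENTS_OF_WALL: dict[str, tuple[int, ...]] = {
    w: tuple(s for s in SEGMENTS if WALL_OF_SEGMENT[s] == w) for w in WALLS
}

#: The nine transmural layer depths (fractions of wall thickness).
LAYER_GRID: tuple[float, ...] = tuple(round(0.1 * k, 1) for k in range(1, 10))

BANDS: tuple[str, ...] = ("sub_endo", "mid", "sub_epi")
LAYERS_OF_BAND: dict[str, tuple[float, ...]] = {
    "sub_endo": (0.1, 0.2, 0.3),
    "mid": (0.4, 0.5, 0.6),
    "sub_epi": (0.7, 0.8, 0.9),
}

#: Canonical SegmentLayerTable columns.
TABLE_COLUMNS: tuple[str, ...] = (
    "patient_id",
    "segment",
    "layer_depth",
    "wall",
    "band",
    "intensity",
    "artifact_flag",
)

LEVELS: tuple[str, ...] = ("basal", "mid", "apical", "apex")

# Circumferential sector order counterclockwise from the anterior RV
# insertion ray.  The insertion ray is the anterior/anteroseptal boundary,
# so the first 60 deg sector is anteroseptal.
_HEX_SECTOR_SEGMENTS = (2, 3, 4, 5, 6, 1)  # basal; mid adds 6
# Apical 90 deg sectors, centred so the septal sector spans [45, 135).
_QUAD_SECTOR_SEGMENTS = (14, 15, 16, 13)


def wall_of_segment(segment: int) -> str:
    """Return the wall ('anterior', 'lateral', 'inferior', 'septal') of an
    AHA segment (1–17)."""
    try:
        return WALL_OF_SEGMENT[int(segment)]
    except (KeyError, ValueError, TypeError):
        raise IndexError(f"segment must be an integer in 1..17, got {segment!r}")


def band_of_layer(layer_depth: float) -> str:
    """Return the transmural band of a layer depth on the 9-point grid.

    0.1–0.3 -> 'sub_endo', 0.4–0.6 -> 'mid', 0.7–0.9 -> 'sub_epi'.
    """
    key = round(float(layer_depth), 1)
    if key not in LAYER_GRID or abs(key - float(layer_depth)) > 1e-9:
        raise ValueError(
            f"layer_depth must lie on the 9-point grid 0.1..0.9, got {layer_depth!r}"
        )
    for band, layers in LAYERS_OF_BAND.items():
        if key in layers:
            return band
    raise AssertionError("unreachable")


def assign_slice_level(
    slice_index: int, n_slices: int, apex_slices: int = 0
) -> str:
    """Assign a short-axis slice to a longitudinal level.

    Slices are ordered base -> apex (index 0 = most basal).  The final
    ``apex_slices`` slices (those without a blood pool) are the apex; the
    remainder is split into basal/mid/apical thirds, with indivisible
    remainders assigned to the more basal level.

    Parameters
    ----------
    slice_index : 0-based position along the long axis.
    n_slices : total number of slices in the stack.
    apex_slices : number of trailing slices that show no blood pool.
    """
    if n_slices < 3:
        raise GeometryError(f"need at least 3 slices, got {n_slices}")
    if not 0 <= slice_index < n_slices:
        raise IndexError(f"slice_index {slice_index} outside 0..{n_slices - 1}")
    n_wall = n_slices - apex_slices
    if n_wall < 3:
        raise GeometryError(
            f"{n_wall} non-apex slices cannot form basal/mid/apical thirds"
        )
    if slice_index >= n_wall:
        return "apex"
    base, rem = divmod(n_wall, 3)
    n_basal = base + (1 if rem >= 1 else 0)
    n_mid = base + (1 if rem == 2 else 0)
    if slice_index < n_basal:
        return "basal"
    if slice_index < n_basal + n_mid:
        return "mid"
    return "apical"


def assign_aha_segment(level: str, angle: float) -> int:
    """Map (longitudinal level, circumferential angle) to an AHA segment.

    ``angle`` is measured counterclockwise from the anterior RV-insertion
    ray.  Basal and mid levels use six 60 deg sectors (the first being
    anteroseptal), the apical level four 90 deg sectors with the septal
    sector spanning 45–135 deg; the apex is segment 17 regardless of angle.
    """
    a = float(angle) % 360.0
    if level == "apex":
        return 17
    if level in ("basal", "mid"):
        seg = _HEX_SECTOR_SEGMENTS[int(a // 60.0) % 6]
        return seg + (6 if level == "mid" else 0)
    if level == "apical":
        return _QUAD_SECTOR_SEGMENTS[int(((a - 45.0) % 360.0) // 90.0) % 4]
    raise ValueError(f"unknown level {level!r}")


# --------------------------------------------------------------------------
# Contours and image stacks
# --------------------------------------------------------------------------


def _as_polygon(vertices) -> Polygon:
    if isinstance(vertices, Polygon):
        poly = vertices
    else:
        arr = np.asarray(vertices, dtype=float)
        if arr.ndim != 2 or arr.shape[0] < 3 or arr.shape[1] != 2:
            raise GeometryError("polygon needs an (N>=3, 2) vertex array")
        poly = Polygon(arr)
    if not poly.is_valid or poly.area <= 0:
        raise GeometryError("polygon is degenerate or self-intersecting")
    return poly


@dataclass(frozen=True)
class SliceContour:
    """Endo/epi contours of one short-axis slice.

    ``endo`` is None for apex-cap slices without a blood pool.
    """

    epi: object  # polygon vertices (N, 2) mm or shapely Polygon
    endo: object | None
    z_position: float
    rv_insertion_angle: float

    def epi_polygon(self) -> Polygon:
        return _as_polygon(self.epi)

    def endo_polygon(self) -> Polygon | None:
        if self.endo is None:
            return None
        return _as_polygon(self.endo)

    def validate(self) -> None:
        epi = self.epi_polygon()
        endo = self.endo_polygon()
        if endo is not None and not epi.contains(endo):
            raise GeometryError(
                "endocardial contour must lie strictly inside the epicardial contour"
            )


@dataclass(frozen=True)
class ContourStack:
    """Ordered (base -> apex) slice contours plus pixel spacing in mm."""

    slices: Sequence[SliceContour]
    pixel_spacing: tuple[float, float] = (1.0, 1.0)

    def __post_init__(self):
        for s in self.slices:
            s.validate()

    def __len__(self) -> int:
        return len(self.slices)

    def n_apex(self) -> int:
        """Number of trailing apex-cap slices (no blood pool)."""
        n = 0
        for s in reversed(self.slices):
            if s.endo is None or s.endo_polygon().area <= 1e-12:
                n += 1
            else:
                break
        return n


@dataclass(frozen=True)
class LGEImageStack:
    """Short-axis LGE frames (row-major 2D arrays) plus pixel spacing."""

    frames: Sequence[np.ndarray]
    pixel_spacing: tuple[float, float] = (1.0, 1.0)

    def __len__(self) -> int:
        return len(self.frames)


def transmural_depth(point, endo_polygon, epi_polygon) -> float:
    """Normalized transmural depth of a point in the myocardial annulus.

    depth = d_endo / (d_endo + d_epi), where the distances are Euclidean
    distances to the endocardial and epicardial contours: 0 on the
    endocardium, 1 on the epicardium (RV-side endocardium in the septum).
    """
    pt = Point(np.asarray(point, dtype=float))
    endo = _as_polygon(endo_polygon)
    epi = _as_polygon(epi_polygon)
    if not epi.covers(pt) or endo.contains(pt):
        raise GeometryError(f"point {point} is outside the myocardial annulus")
    d_endo = pt.distance(endo.exterior)
    d_epi = pt.distance(epi.exterior)
    total = d_endo + d_epi
    if total <= 0:
        raise GeometryError("degenerate annulus: endo and epi contours coincide")
    return d_endo / total


# --------------------------------------------------------------------------
# Pixel aggregation
# --------------------------------------------------------------------------

#: Pixels with depth outside [RIM_LO, RIM_HI) are discarded as partial-volume
#: rim (blood pool / epicardial fat contamination).
RIM_LO = 0.05
RIM_HI = 0.95


def _pixel_centres(shape: tuple[int, int], spacing: tuple[float, float]):
    dy, dx = float(spacing[0]), float(spacing[1])
    ii, jj = np.mgrid[0 : shape[0], 0 : shape[1]]
    x = (jj.ravel() + 0.5) * dx
    y = (ii.ravel() + 0.5) * dy
    return x, y


def _segments_from_angles(level: str, rel_angles: np.ndarray) -> np.ndarray:
    """Vectorized AHA sector lookup for one slice level."""
    a = np.mod(rel_angles, 360.0)
    if level == "apex":
        return np.full(a.shape, 17, dtype=int)
    if level in ("basal", "mid"):
        idx = (a // 60.0).astype(int) % 6
        segs = np.asarray(_HEX_SECTOR_SEGMENTS, dtype=int)[idx]
        return segs + (6 if level == "mid" else 0)
    idx = (np.mod(a - 45.0, 360.0) // 90.0).astype(int) % 4
    return np.asarray(_QUAD_SECTOR_SEGMENTS, dtype=int)[idx]


def empty_table(patient_id: str) -> pd.DataFrame:
    """A full 153-row SegmentLayerTable skeleton with NaN intensities."""
    rows = [
        (patient_id, s, d, WALL_OF_SEGMENT[s], band_of_layer(d), np.nan, True)
        for s in SEGMENTS
        for d in LAYER_GRID
    ]
    return pd.DataFrame(rows, columns=list(TABLE_COLUMNS))


def aggregate(
    stack: LGEImageStack, contours: ContourStack, patient_id: str = "P0"
) -> pd.DataFrame:
    """Aggregate an LGE image stack into a 153-row SegmentLayerTable.

    Every myocardial pixel (between the contours, with transmural depth in
    [0.05, 0.95)) is mapped to one (segment, shell) cell; shell k covers
    depths [(2k-1)/20, (2k+1)/20) and is labelled layer_depth = k/10.  Cell
    intensity is the mean of member pixels; cells that receive no pixels
    are emitted with ``artifact_flag=True`` and NaN intensity.
    """
    if len(stack) != len(contours):
        raise AlignmentError(
            f"stack has {len(stack)} frames but contours describe {len(contours)} slices"
        )
    if tuple(np.round(stack.pixel_spacing, 9)) != tuple(
        np.round(contours.pixel_spacing, 9)
    ):
        raise AlignmentError("pixel spacing differs between images and contours")

    n_slices = len(contours)
    n_apex = contours.n_apex()
    sums: dict[tuple[int, float], float] = {}
    counts: dict[tuple[int, float], int] = {}

    for idx, (frame, sl) in enumerate(zip(stack.frames, contours.slices)):
        frame = np.asarray(frame, dtype=float)
        level = assign_slice_level(idx, n_slices, apex_slices=n_apex)
        epi = sl.epi_polygon()
        endo = sl.endo_polygon()
        x, y = _pixel_centres(frame.shape, stack.pixel_spacing)
        pts = shapely.points(np.column_stack([x, y]))
        in_epi = shapely.contains(epi, pts)
        if endo is not None and endo.area > 1e-12:
            in_myo = in_epi & ~shapely.contains(endo, pts)
            centre = endo.centroid
            ring = LinearRing(endo.exterior.coords)
            d_inner = shapely.distance(pts, ring)
        else:
            in_myo = in_epi
            centre = epi.centroid
            # apex cap: pseudo-depth from the cap centre outwards
            d_inner = np.hypot(x - centre.x, y - centre.y)
        if not in_myo.any():
            continue
        d_epi = shapely.distance(pts, LinearRing(epi.exterior.coords))
        with np.errstate(invalid="ignore", divide="ignore"):
            depth = d_inner / (d_inner + d_epi)
        keep = in_myo & (depth >= RIM_LO) & (depth < RIM_HI)
        if not keep.any():
            continue
        depth_k = depth[keep]
        shell = np.floor(depth_k * 10.0 + 0.5).astype(int)  # 1..9
        theta = np.degrees(np.arctan2(y[keep] - centre.y, x[keep] - centre.x))
        rel = np.mod(theta - sl.rv_insertion_angle, 360.0)
        segs = _segments_from_angles(level, rel)
        vals = frame.ravel()[keep]
        for s, k, v in zip(segs, shell, vals):
            key = (int(s), round(k / 10.0, 1))
            sums[key] = sums.get(key, 0.0) + float(v)
            counts[key] = counts.get(key, 0) + 1

    if not counts:
        raise EmptyRegionError("no myocardial pixels found in any slice")

    table = empty_table(patient_id)
    for i, row in table.iterrows():
        key = (int(row["segment"]), float(row["layer_depth"]))
        if key in counts:
            table.at[i, "intensity"] = sums[key] / counts[key]
            table.at[i, "artifact_flag"] = False
    return table


def validate_table(table: pd.DataFrame) -> pd.DataFrame:
    """Validate a SegmentLayerTable and recompute wall/band labels.

    Raises :class:`~lge_zmap.errors.SchemaError` (or the ConsistencyError
    subclass) on missing columns, out-of-range segments/layers, duplicate
    (patient, segment, layer) cells, or wall/band labels that contradict
    the segment and layer maps.
    """
    from .errors import ConsistencyError, SchemaError

    missing = [c for c in TABLE_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"missing columns: {missing}")
    t = table.copy()
    segs = t["segment"].to_numpy()
    if not np.isin(segs, SEGMENTS).all():
        bad = sorted(set(segs) - set(SEGMENTS))
        raise SchemaError(f"segments outside 1..17: {bad}")
    depths = np.round(t["layer_depth"].astype(float), 1)
    if not np.isin(depths, LAYER_GRID).all():
        bad = sorted(set(depths) - set(LAYER_GRID))
        raise SchemaError(f"layer depths off the 9-point grid: {bad}")
    t["layer_depth"] = depths
    dup = t.duplicated(subset=["patient_id", "segment", "layer_depth"])
    if dup.any():
        raise SchemaError(
            f"duplicate (patient, segment, layer) cells: {t.loc[dup].head().to_dict('records')}"
        )
    expected_wall = t["segment"].map(WALL_OF_SEGMENT)
    if "wall" in table.columns and not (t["wall"] == expected_wall).all():
        raise ConsistencyError("wall column contradicts the segment->wall map")
    expected_band = t["layer_depth"].map(band_of_layer)
    if "band" in table.columns and not (t["band"] == expected_band).all():
        raise ConsistencyError("band column contradicts the layer->band map")
    t["wall"] = expected_wall
    t["band"] = expected_band
    t["artifact_flag"] = t["artifact_flag"].astype(bool)
    return t
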