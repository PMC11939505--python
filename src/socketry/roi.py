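"""Per-slice regions of interest: representation, persistence, rasterization
and measurement.

Two ROI shapes cover the measurement workflow: free-hand polygons that
trace the alveolus outline on each vestibulo-oral slice, and small
ellipses of uniform size placed in endogenous spongy bone as gray-value
reference regions. ROI coordinates are pixel units of the annotated
orientation, 0-based, ``(x, y) = (col, row)``; pixel ``(r, c)`` has its
center at ``(c + 0.5, r + 0.5)``.

Rasterization uses pixel-center containment: a pixel belongs to a
polygon if its center is inside by the even-odd rule, with points
exactly on an edge counting as inside (deterministic tie-break); it
belongs to an ellipse if ``(x-cx)^2/a^2 + (y-cy)^2/b^2 <= 1`` at the
center. Area is therefore pixel-count based, matching raster "measure"
semantics rather than the shoelace area of the vertex chain — the two
differ by boundary pixels, a sub-pixel-perimeter effect.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Union

import numpy as np

from .volume_io import VoxelVolume

SCHEMA_VERSION = 1

POLYGON_LABELS = ("alveolus", "other")
ELLIPSE_LABELS = ("reference_bone",)


class RoiError(ValueError):
    """Degenerate or inconsistent ROI annotation."""


class SchemaError(ValueError):
    """ROI file does not conform to the persisted schema."""


@dataclass(frozen=True)
class PolygonRoi:
    """A simple (non-self-intersecting) polygon on one slice."""

    slice_index: int
    vertices: tuple[tuple[float, float], ...]  # ordered (x, y) pixel units
    label: str = "alveolus"

    def __post_init__(self) -> None:
        verts = tuple((float(x), float(y)) for x, y in self.vertices)
        if len(verts) < 3:
            raise RoiError(f"polygon needs >=3 vertices, got {len(verts)}")
        if self.label not in POLYGON_LABELS:
            raise RoiError(f"polygon label must be one of {POLYGON_LABELS}, got {self.label!r}")
        object.__setattr__(self, "vertices", verts)

    @property
    def centroid(self) -> tuple[float, float]:
        """Vertex-mean centroid, the anchor used for landmark transfer."""
        arr = np.asarray(self.vertices)
        return float(arr[:, 0].mean()), float(arr[:, 1].mean())

    def translated(self, dx: float, dy: float) -> "PolygonRoi":
        return replace(self, vertices=tuple((x + dx, y + dy) for x, y in self.vertices))


@dataclass(frozen=True)
class EllipseRoi:
    """An axis-aligned ellipse on one slice (reference spongy bone)."""

    slice_index: int
    center: tuple[float, float]  # (x, y) pixel units
    semi_axes: tuple[float, float]  # (a, b) pixel units
    label: str = "reference_bone"

    def __post_init__(self) -> None:
        a, b = (float(s) for s in self.semi_axes)
        if a <= 0 or b <= 0:
            raise RoiError(f"ellipse semi-axes must be positive, got {self.semi_axes}")
        if self.label not in ELLIPSE_LABELS:
            raise RoiError(f"ellipse label must be one of {ELLIPSE_LABELS}, got {self.label!r}")
        object.__setattr__(self, "center", tuple(float(c) for c in self.center))
        object.__setattr__(self, "semi_axes", (a, b))

    def translated(self, dx: float, dy: float) -> "EllipseRoi":
        cx, cy = self.center
        return replace(self, center=(cx + dx, cy + dy))


Roi = Union[PolygonRoi, EllipseRoi]


@dataclass(frozen=True)
class RoiSet:
    """All ROIs annotated on one processed volume at one time point."""

    volume_id: str
    timepoint: str  # "t1" | "t2"
    rois: tuple[Roi, ...] = ()

    def __post_init__(self) -> None:
        if self.timepoint not in ("t1", "t2"):
            raise RoiError(f"timepoint must be t1|t2, got {self.timepoint!r}")
        rois = tuple(self.rois)
        seen: set[tuple[int, str]] = set()
        for r in rois:
            key = (r.slice_index, r.label)
            if key in seen:
                raise RoiError(f"duplicate {r.label!r} ROI on slice {r.slice_index}")
            seen.add(key)
        object.__setattr__(self, "rois", rois)

    def by_label(self, label: str) -> dict[int, Roi]:
        return {r.slice_index: r for r in self.rois if r.label == label}

    @property
    def slice_indices(self) -> tuple[int, ...]:
        return tuple(sorted({r.slice_index for r in self.rois}))

    def validate_against(self, volume: VoxelVolume) -> None:
        for r in self.rois:
            if not (0 <= r.slice_index < volume.n_slices):
                raise RoiError(
                    f"ROI slice index {r.slice_index} out of range for "
                    f"{volume.n_slices}-slice volume"
                )

    def subsampled(self, increment: int) -> "RoiSet":
        """Restrict to slices kept by increment-``k`` stack thinning and
        renumber the slice indices to the thinned stack."""
        if increment < 1:
            raise ValueError("increment must be >= 1")
        kept = tuple(
            replace(r, slice_index=r.slice_index // increment)
            for r in self.rois
            if r.slice_index % increment == 0
        )
        return replace(self, rois=kept)


# ---------------------------------------------------------------------------
# Geometry predicates and rasterization
# ---------------------------------------------------------------------------


def _orient(ax, ay, bx, by, cx, cy) -> float:
    return (bx - ax) * (cy - ay) - (by - ay) * (cx - ax)


def _on_segment(ax, ay, bx, by, px, py) -> bool:
    if _orient(ax, ay, bx, by, px, py) != 0:
        return False
    return min(ax, bx) <= px <= max(ax, bx) and min(ay, by) <= py <= max(ay, by)


def _segments_cross(a, b, c, d) -> bool:
    """Proper or improper intersection of segments ab and cd."""
    o1 = _orient(*a, *b, *c)
    o2 = _orient(*a, *b, *d)
    o3 = _orient(*c, *d, *a)
    o4 = _orient(*c, *d, *b)
    if ((o1 > 0) != (o2 > 0)) and ((o3 > 0) != (o4 > 0)) and o1 != 0 and o2 != 0 and o3 != 0 and o4 != 0:
        return True
    for seg, pt in (((a, b), c), ((a, b), d), ((c, d), a), ((c, d), b)):
        if _on_segment(*seg[0], *seg[1], *pt):
            return True
    return False


def is_simple_polygon(vertices: Iterable[tuple[float, float]]) -> bool:
    """True if no two non-adjacent edges intersect (self-touching counts
    as non-simple); fully degenerate (collinear) chains are allowed."""
    verts = list(vertices)
    n = len(verts)
    edges = [(verts[i], verts[(i + 1) % n]) for i in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            if j == i + 1 or (i == 0 and j == n - 1):
                continue  # adjacent edges share a vertex by construction
            if _segments_cross(*edges[i], *edges[j]):
                return False
    return True


def _polygon_mask(vertices: tuple[tuple[float, float], ...], shape: tuple[int, int]) -> np.ndarray:
    rows, cols = shape
    py, px = np.mgrid[0:rows, 0:cols].astype(np.float64)
    px += 0.5
    py += 0.5
    inside = np.zeros(shape, dtype=bool)
    on_edge = np.zeros(shape, dtype=bool)
    n = len(vertices)
    for i in range(n):
        x0, y0 = vertices[i]
        x1, y1 = vertices[(i + 1) % n]
        # even-odd ray cast toward -x
        crosses = (y0 > py) != (y1 > py)
        if crosses.any():
            with np.errstate(divide="ignore", invalid="ignore"):
                x_at = x0 + (py - y0) * (x1 - x0) / (y1 - y0)
            inside ^= crosses & (px < x_at)
        # exact on-edge test (boundary counts as inside)
        cross = (x1 - x0) * (py - y0) - (y1 - y0) * (px - x0)
        bbox = (
            (px >= min(x0, x1)) & (px <= max(x0, x1))
            & (py >= min(y0, y1)) & (py <= max(y0, y1))
        )
        on_edge |= (cross == 0) & bbox
    return inside | on_edge


def _ellipse_mask(roi: EllipseRoi, shape: tuple[int, int]) -> np.ndarray:
    rows, cols = shape
    py, px = np.mgrid[0:rows, 0:cols].astype(np.float64)
    px += 0.5
    py += 0.5
    cx, cy = roi.center
    a, b = roi.semi_axes
    return ((px - cx) / a) ** 2 + ((py - cy) / b) ** 2 <= 1.0


def rasterize(roi: Roi, slice_shape: tuple[int, int]) -> np.ndarray:
    """Binary pixel-center containment mask of an ROI on a slice grid."""
    if isinstance(roi, PolygonRoi):
        if not is_simple_polygon(roi.vertices):
            raise RoiError(f"self-intersecting polygon on slice {roi.slice_index}")
        return _polygon_mask(roi.vertices, slice_shape)
    if isinstance(roi, EllipseRoi):
        return _ellipse_mask(roi, slice_shape)
    raise TypeError(f"unsupported ROI type {type(roi).__name__}")


# ---------------------------------------------------------------------------
# Measurement
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RoiMeasurement:
    pixel_count: int
    area_mm2: float
    mean_gray: float


def measure(roi: Roi, volume: VoxelVolume) -> RoiMeasurement:
    """Measure area (pixel count x in-plane pixel area) and mean gray of
    an ROI on its slice of ``volume``.

    An empty mask signals a degenerate annotation and is a hard error.
    """
    if not (0 <= roi.slice_index < volume.n_slices):
        raise RoiError(f"slice index {roi.slice_index} out of range")
    mask = rasterize(roi, volume.data.shape[1:])
    count = int(mask.sum())
    if count == 0:
        raise RoiError(f"ROI covers no pixels (slice {roi.slice_index}, label {roi.label!r})")
    values = volume.data[roi.slice_index][mask]
    return RoiMeasurement(
        pixel_count=count,
        area_mm2=count * volume.in_plane_pixel_area_mm2,
        mean_gray=float(values.mean(dtype=np.float64)),
    )


def transfer_roiset(src: RoiSet, landmark_src: PolygonRoi, landmark_dst: PolygonRoi) -> RoiSet:
    """Transfer every ROI from the t1 frame to the t2 frame by the rigid
    translation that maps the t1 landmark centroid onto the t2 one.

    The landmark is an anatomical feature stable across the healing
    interval (a tooth or characteristic ridge contour) annotated in both
    scans on the same slice. Residual rotation is assumed removed during
    geometric alignment, so the transfer is translation-only.
    """
    if landmark_src.slice_index != landmark_dst.slice_index:
        raise RoiError(
            "landmark slice count mismatch: landmarks annotate slices "
            f"{landmark_src.slice_index} vs {landmark_dst.slice_index}"
        )
    sx, sy = landmark_src.centroid
    dx_, dy_ = landmark_dst.centroid
    dx, dy = dx_ - sx, dy_ - sy
    return replace(src, rois=tuple(r.translated(dx, dy) for r in src.rois))


# ---------------------------------------------------------------------------
# Persistence (versioned JSON)
# ---------------------------------------------------------------------------


def _roi_to_dict(r: Roi) -> dict:
    if isinstance(r, PolygonRoi):
        return {
            "type": "polygon",
            "slice_index": r.slice_index,
            "label": r.label,
            "vertices": [list(v) for v in r.vertices],
        }
    return {
        "type": "ellipse",
        "slice_index": r.slice_index,
        "label": r.label,
        "center": list(r.center),
        "semi_axes": list(r.semi_axes),
    }


def _require(d: dict, key: str, where: str):
    if key not in d:
        raise SchemaError(f"missing field {key!r} in {where}")
    return d[key]


def _roi_from_dict(d: dict, idx: int) -> Roi:
    where = f"rois[{idx}]"
    kind = _require(d, "type", where)
    slice_index = int(_require(d, "slice_index", where))
    label = _require(d, "label", where)
    if kind == "polygon":
        verts = _require(d, "vertices", where)
        return PolygonRoi(slice_index=slice_index, vertices=[tuple(v) for v in verts], label=label)
    if kind == "ellipse":
        center = _require(d, "center", where)
        semi = _require(d, "semi_axes", where)
        return EllipseRoi(slice_index=slice_index, center=tuple(center), semi_axes=tuple(semi), label=label)
    raise SchemaError(f"unknown ROI type {kind!r} in {where}")


def save_roiset(rs: RoiSet, path: str | Path) -> None:
    doc = {
        "schema_version": SCHEMA_VERSION,
        "volume_id": rs.volume_id,
        "timepoint": rs.timepoint,
        "rois": [_roi_to_dict(r) for r in rs.rois],
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def load_roiset(path: str | Path) -> RoiSet:
    doc = json.loads(Path(path).read_text())
    version = _require(doc, "schema_version", str(path))
    if version != SCHEMA_VERSION:
        raise SchemaError(f"unsupported schema_version {version} in {path}")
    rois = [_roi_from_dict(d, i) for i, d in enumerate(_require(doc, "rois", str(path)))]
    return RoiSet(
        volume_id=_require(doc, "volume_id", str(path)),
        timepoint=_require(doc, "timepoint", str(path)),
        rois=tuple(rois),
    )
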