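"""Synthetic paired-CBCT phantoms with analytically known ground truth.

Clinical socket-preservation data cannot be shipped, so validation runs
on phantoms that emulate what the measurement pipeline actually sees: a
spongy-bone background with Gaussian texture, a cortical shell, an
empty extraction socket at t1 (non-zero gray from artifacts and
soft-tissue projections), and at t2 the same socket partially refilled
from the apical end with new bone of configurable radiodensity. The two
scans get independent per-scan intensity gains (scanner settings drift
between visits) and additive Gaussian noise.

The socket is a vertically oriented cavity — a right circular cylinder
or an elliptic frustum — whose volume, per-slice cross-section areas
and fill state are known in closed form, so every estimator downstream
can be checked against an analytic truth. The generator also emits the
matching ground-truth annotations: an n-gon tracing the socket
cross-section on every vestibulo-oral slice, plus a reference ellipse
placed in guaranteed-spongy territory.

Axial frame conventions: axes are (slice = depth z, row = vestibulo-oral
y, col = mesio-distal x); the voxel ``(i, r, c)`` has its center at
``((i+0.5)dz, (r+0.5)dy, (c+0.5)dx)`` mm. The socket axis is vertical
(along z), opening at the crestal (low-z) end; "bottom-up" fill means
from high z (apical) toward the crest.

Not modelled: ray physics (beam hardening, scatter) and wall-collapse
changes of socket morphology during healing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Union

import numpy as np
from scipy.optimize import brentq

from .roi import EllipseRoi, PolygonRoi, RoiSet
from .volume_io import AXIAL, VoxelVolume


class PhantomError(ValueError):
    """Phantom specification is geometrically or numerically invalid."""


# ---------------------------------------------------------------------------
# Socket geometries
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Cylinder:
    """Right circular cylinder of radius ``radius_mm``, height ``height_mm``."""

    radius_mm: float
    height_mm: float

    def __post_init__(self) -> None:
        if self.radius_mm <= 0 or self.height_mm <= 0:
            raise PhantomError("cylinder dimensions must be positive")

    @property
    def height(self) -> float:
        return self.height_mm

    def semi_axes_at(self, s: float) -> tuple[float, float]:
        """Half-axes (a along x, b along y) at depth fraction s in [0, 1]."""
        return self.radius_mm, self.radius_mm

    @property
    def max_semi_axes(self) -> tuple[float, float]:
        return self.radius_mm, self.radius_mm

    def volume_mm3(self) -> float:
        return math.pi * self.radius_mm**2 * self.height_mm

    def volume_below_fraction(self, s: float) -> float:
        """Volume of the part deeper than depth fraction ``s``."""
        return self.volume_mm3() * (1.0 - s)


@dataclass(frozen=True)
class EllipticFrustum:
    """Elliptic cross-section tapering linearly from (a_top, b_top) at the
    crest to (a_bottom, b_bottom) at the apex."""

    a_top_mm: float
    b_top_mm: float
    a_bottom_mm: float
    b_bottom_mm: float
    height_mm: float

    def __post_init__(self) -> None:
        dims = (self.a_top_mm, self.b_top_mm, self.a_bottom_mm, self.b_bottom_mm, self.height_mm)
        if any(d <= 0 for d in dims):
            raise PhantomError("frustum dimensions must be positive")

    @property
    def height(self) -> float:
        return self.height_mm

    def semi_axes_at(self, s: float) -> tuple[float, float]:
        a = self.a_top_mm + (self.a_bottom_mm - self.a_top_mm) * s
        b = self.b_top_mm + (self.b_bottom_mm - self.b_top_mm) * s
        return a, b

    @property
    def max_semi_axes(self) -> tuple[float, float]:
        return max(self.a_top_mm, self.a_bottom_mm), max(self.b_top_mm, self.b_bottom_mm)

    def volume_mm3(self) -> float:
        # prismatoid rule — exact because the section area is quadratic in s
        a_m, b_m = self.semi_axes_at(0.5)
        A_top = math.pi * self.a_top_mm * self.b_top_mm
        A_mid = math.pi * a_m * b_m
        A_bot = math.pi * self.a_bottom_mm * self.b_bottom_mm
        return self.height_mm / 6.0 * (A_top + 4.0 * A_mid + A_bot)

    def volume_below_fraction(self, s: float) -> float:
        if s <= 0:
            return self.volume_mm3()
        if s >= 1:
            return 0.0
        sub = EllipticFrustum(*self.semi_axes_at(s), self.a_bottom_mm, self.b_bottom_mm,
                              self.height_mm * (1.0 - s))
        return sub.volume_mm3()


SocketGeometry = Union[Cylinder, EllipticFrustum]


def analytic_socket_volume(geometry: SocketGeometry) -> float:
    """Closed-form socket volume in mm^3."""
    return geometry.volume_mm3()


def fill_start_fraction(geometry: SocketGeometry, fill_fraction: float) -> float:
    """Depth fraction s* such that the region deeper than s* holds
    ``fill_fraction`` of the socket volume (bottom-up fill)."""
    if not 0.0 <= fill_fraction <= 1.0:
        raise PhantomError("fill_fraction must lie in [0, 1]")
    if fill_fraction == 0.0:
        return 1.0
    if fill_fraction == 1.0:
        return 0.0
    target = fill_fraction * geometry.volume_mm3()
    return float(brentq(lambda s: geometry.volume_below_fraction(s) - target, 0.0, 1.0,
                        xtol=1e-12))


# ---------------------------------------------------------------------------
# Specification
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one paired phantom.

    Gray levels are on the 8-bit scale: spongy bone 140 +/- 8 texture,
    cortical 230, empty socket 40 (the artifact/soft-tissue baseline);
    additive noise SD 5; t2 acquired with a slightly different gain than
    t1 (1.1 vs 1.0), emulating between-visit scanner drift. New bone
    fills the apical ``fill_fraction`` of the socket volume at gray
    ``empty + new_bone_fraction * (spongy - empty)``.
    """

    shape: tuple[int, int, int] = (64, 48, 64)  # (slices z, rows y, cols x)
    spacing: tuple[float, float, float] = (0.2, 0.2, 0.2)
    geometry: SocketGeometry = field(default_factory=lambda: Cylinder(3.0, 10.0))
    spongy_mean: float = 140.0
    spongy_sd: float = 8.0
    cortical_gray: float = 230.0
    empty_socket_mean: float = 40.0
    new_bone_fraction: float = 0.5  # f_d: radiodensity of new bone vs spongy
    fill_fraction: float = 0.6  # f_v: mineralized fraction of socket volume
    gains: tuple[float, float] = (1.0, 1.1)  # (g1, g2)
    noise_sd: float = 5.0
    seed: int = 0
    bit_depth: int = 8
    cortical_margin_voxels: int = 3
    ref_semi_axes_px: tuple[float, float] = (3.0, 3.0)
    ref_gap_px: float = 2.0
    source_id: str = "phantom"

    def __post_init__(self) -> None:
        if not (0.0 <= self.fill_fraction <= 1.0 and 0.0 <= self.new_bone_fraction <= 1.0):
            raise PhantomError("fill_fraction and new_bone_fraction must lie in [0, 1]")
        if any(g <= 0 for g in self.gains):
            raise PhantomError("gains must be positive")
        if self.noise_sd < 0 or self.spongy_sd < 0:
            raise PhantomError("noise/texture SDs must be >= 0")
        self._socket_extents()  # raises if the socket does not fit

    # -- derived placement -------------------------------------------

    @property
    def axis_center_mm(self) -> tuple[float, float]:
        """(y_c, x_c): socket axis position, centered in the grid."""
        _, rows, cols = self.shape
        return rows * self.spacing[1] / 2.0, cols * self.spacing[2] / 2.0

    @property
    def socket_top_mm(self) -> float:
        """Crestal end of the socket (z of its opening)."""
        return (self.cortical_margin_voxels + 2) * self.spacing[0]

    def _socket_extents(self) -> None:
        dz, dy, dx = self.spacing
        n_sl, rows, cols = self.shape
        margin = self.cortical_margin_voxels + 2
        z1 = self.socket_top_mm + self.geometry.height
        if z1 > (n_sl - margin) * dz:
            raise PhantomError("socket too deep for the grid (need >= 2-voxel spongy margin)")
        a_max, b_max = self.geometry.max_semi_axes
        y_c, x_c = self.axis_center_mm
        if y_c - b_max < margin * dy or y_c + b_max > (rows - margin) * dy:
            raise PhantomError("socket too wide (rows) for the grid")
        if x_c - a_max < margin * dx or x_c + a_max > (cols - margin) * dx:
            raise PhantomError("socket too wide (cols) for the grid")

    def reference_ellipse_center_px(self) -> tuple[float, float]:
        """(x, y=depth) pixel-unit center of the reference ellipse in the
        vestibulo-oral frame, lateral of the socket in spongy bone."""
        dz, dy, dx = self.spacing
        _, x_c = self.axis_center_mm
        a_max, _ = self.geometry.max_semi_axes
        x_px = (x_c + a_max) / dx + self.ref_gap_px + self.ref_semi_axes_px[0]
        z_px = (self.socket_top_mm + self.geometry.height / 2.0) / dz
        cols = self.shape[2]
        if x_px + self.ref_semi_axes_px[0] + 1 > cols - self.cortical_margin_voxels:
            raise PhantomError("no spongy territory left for the reference ellipse")
        return x_px, z_px


@dataclass(frozen=True)
class GroundTruth:
    """Analytic truths of one phantom pair."""

    V_socket_true_mm3: float
    V_mineralized_true_mm3: float
    fill_fraction: float
    new_bone_fraction: float
    roiset_t1: RoiSet
    roiset_t2: RoiSet
    section_areas_mm2: dict[int, float]  # vestibulo-oral slice -> analytic area

    def __post_init__(self) -> None:
        expected = self.fill_fraction * self.V_socket_true_mm3
        if not math.isclose(self.V_mineralized_true_mm3, expected, rel_tol=1e-9, abs_tol=1e-9):
            raise PhantomError("V_mineralized_true must equal fill_fraction * V_socket_true")


# ---------------------------------------------------------------------------
# Voxel masks
# ---------------------------------------------------------------------------


def _socket_masks(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray]:
    """Boolean (socket, filled-at-t2) voxel-center masks in the axial frame."""
    dz, dy, dx = spec.spacing
    n_sl, rows, cols = spec.shape
    y_c, x_c = spec.axis_center_mm
    z0 = spec.socket_top_mm
    h = spec.geometry.height
    s_fill = fill_start_fraction(spec.geometry, spec.fill_fraction)

    yy = (np.arange(rows) + 0.5) * dy - y_c
    xx = (np.arange(cols) + 0.5) * dx - x_c
    Y, X = np.meshgrid(yy, xx, indexing="ij")

    socket = np.zeros(spec.shape, dtype=bool)
    filled = np.zeros(spec.shape, dtype=bool)
    for i in range(n_sl):
        z = (i + 0.5) * dz
        if not (z0 <= z <= z0 + h):
            continue
        s = (z - z0) / h
        a, b = spec.geometry.semi_axes_at(s)
        inside = (X / a) ** 2 + (Y / b) ** 2 <= 1.0
        socket[i] = inside
        if s >= s_fill:
            filled[i] = inside
    return socket, filled


def _cortical_shell(spec: PhantomSpec) -> np.ndarray:
    m = spec.cortical_margin_voxels
    shell = np.zeros(spec.shape, dtype=bool)
    if m > 0:
        shell[:m] = shell[-m:] = True
        shell[:, :m] = shell[:, -m:] = True
        shell[:, :, :m] = shell[:, :, -m:] = True
    return shell


# ---------------------------------------------------------------------------
# Volume generation
# ---------------------------------------------------------------------------


def generate_pair(spec: PhantomSpec) -> tuple[VoxelVolume, VoxelVolume, GroundTruth]:
    """Generate the t1 (post-extraction) and t2 (post-regeneration)
    volumes plus the analytic ground truth.

    Both time points share one spongy-texture realization (the bone did
    not change; the scans did); each is then scaled by its per-scan gain
    and perturbed with additive Gaussian noise, rounded half-up and
    clipped to the bit depth. All randomness flows from ``spec.seed``,
    so identical specs yield bit-identical volumes.
    """
    rng = np.random.default_rng(spec.seed)
    max_val = 2 ** spec.bit_depth - 1

    base = rng.normal(spec.spongy_mean, spec.spongy_sd, size=spec.shape)
    base = np.clip(base, 0.0, max_val)
    shell = _cortical_shell(spec)
    base[shell] = spec.cortical_gray
    socket, filled = _socket_masks(spec)

    base_t1 = base.copy()
    base_t1[socket] = spec.empty_socket_mean
    base_t2 = base.copy()
    base_t2[socket] = spec.empty_socket_mean
    new_bone_gray = spec.empty_socket_mean + spec.new_bone_fraction * (
        spec.spongy_mean - spec.empty_socket_mean
    )
    base_t2[filled] = new_bone_gray

    volumes = []
    for tp, (b, gain) in enumerate(zip((base_t1, base_t2), spec.gains), start=1):
        noisy = b * gain + rng.normal(0.0, spec.noise_sd, size=spec.shape) \
            if spec.noise_sd > 0 else b * gain
        data = np.clip(np.floor(noisy + 0.5), 0, max_val).astype(
            np.uint8 if spec.bit_depth == 8 else np.uint16
        )
        volumes.append(
            VoxelVolume(
                data=data,
                spacing=spec.spacing,
                bit_depth=spec.bit_depth,
                orientation=AXIAL,
                source_id=f"{spec.source_id}-t{tp}-seed{spec.seed}",
            )
        )

    rs_t1, rs_t2 = ground_truth_rois(spec)
    truth = GroundTruth(
        V_socket_true_mm3=analytic_socket_volume(spec.geometry),
        V_mineralized_true_mm3=spec.fill_fraction * analytic_socket_volume(spec.geometry),
        fill_fraction=spec.fill_fraction,
        new_bone_fraction=spec.new_bone_fraction,
        roiset_t1=rs_t1,
        roiset_t2=rs_t2,
        section_areas_mm2=analytic_section_areas(spec),
    )
    return volumes[0], volumes[1], truth


# ---------------------------------------------------------------------------
# Analytic cross-sections and ground-truth annotations
# ---------------------------------------------------------------------------


def _section_halfwidth(spec: PhantomSpec, s: float, y_off_mm: float) -> float:
    """Half-width in x of the socket section at depth fraction s, for a
    vestibulo-oral plane offset ``y_off_mm`` from the axis."""
    a, b = spec.geometry.semi_axes_at(s)
    if abs(y_off_mm) >= b:
        return 0.0
    return a * math.sqrt(1.0 - (y_off_mm / b) ** 2)


def _valid_s_interval(spec: PhantomSpec, y_off_mm: float) -> Optional[tuple[float, float]]:
    """Depth-fraction interval where the vestibulo-oral plane cuts the socket."""
    geo = spec.geometry
    b0 = geo.semi_axes_at(0.0)[1]
    b1 = geo.semi_axes_at(1.0)[1]
    y = abs(y_off_mm)
    if max(b0, b1) <= y:
        return None
    if min(b0, b1) > y:
        return 0.0, 1.0
    s_star = (y - b0) / (b1 - b0)  # b(s) linear; crossing point
    if b1 > b0:
        return max(0.0, s_star), 1.0
    return 0.0, min(1.0, s_star)


def analytic_section_areas(spec: PhantomSpec) -> dict[int, float]:
    """Exact area (mm^2) of the socket cross-section on every
    vestibulo-oral slice that meets the socket."""
    dz, dy, dx = spec.spacing
    rows = spec.shape[1]
    y_c, _ = spec.axis_center_mm
    h = spec.geometry.height
    out: dict[int, float] = {}
    for r in range(rows):
        y = (r + 0.5) * dy - y_c
        interval = _valid_s_interval(spec, y)
        if interval is None:
            continue
        s_lo, s_hi = interval
        # width is smooth in s; high-order fixed quadrature is ample
        ss = np.linspace(s_lo, s_hi, 513)
        ws = np.array([_section_halfwidth(spec, s, y) for s in ss])
        area = 2.0 * h * np.trapezoid(ws, ss)
        if area > 0:
            out[r] = float(area)
    return out


def section_polygon(
    spec: PhantomSpec, vo_slice: int, n_vertices: int = 64, label: str = "alveolus"
) -> Optional[PolygonRoi]:
    """n-gon tracing the socket cross-section on one vestibulo-oral slice.

    Vertices lie exactly on the analytic boundary: down the +x side of
    the section, across the bottom, and back up the -x side. For a
    cylinder the section is a rectangle and the trace is exact.
    Coordinates are pixel units of the vestibulo-oral frame,
    ``(x = col, y = axial slice index direction)``.
    """
    dz, dy, dx = spec.spacing
    y_c, x_c = spec.axis_center_mm
    y = (vo_slice + 0.5) * dy - y_c
    interval = _valid_s_interval(spec, y)
    if interval is None:
        return None
    s_lo, s_hi = interval
    z0 = spec.socket_top_mm
    h = spec.geometry.height
    m = max(3, n_vertices // 2)
    ss = np.linspace(s_lo, s_hi, m)
    ws = np.array([_section_halfwidth(spec, s, y) for s in ss])
    if ws.max() < 0.25 * dx:  # grazing section narrower than half a pixel
        return None
    verts: list[tuple[float, float]] = []
    for s, w in zip(ss, ws):  # +x side, crest to apex
        verts.append(((x_c + w) / dx, (z0 + s * h) / dz))
    for s, w in zip(ss[::-1], ws[::-1]):  # -x side, apex to crest
        verts.append(((x_c - w) / dx, (z0 + s * h) / dz))
    # tapering sections pinch to zero width at the ends; drop the
    # duplicated tip vertices so the chain stays a simple polygon
    deduped: list[tuple[float, float]] = []
    for v in verts:
        if not deduped or math.hypot(v[0] - deduped[-1][0], v[1] - deduped[-1][1]) > 1e-9:
            deduped.append(v)
    while len(deduped) > 1 and math.hypot(
        deduped[0][0] - deduped[-1][0], deduped[0][1] - deduped[-1][1]
    ) <= 1e-9:
        deduped.pop()
    if len(deduped) < 3:
        return None
    return PolygonRoi(slice_index=vo_slice, vertices=deduped, label=label)


def ground_truth_rois(spec: PhantomSpec, n_vertices: int = 64) -> tuple[RoiSet, RoiSet]:
    """Ground-truth annotation sets for both time points.

    Per vestibulo-oral slice through the socket: an ``n_vertices``-gon
    tracing the analytic cross-section, plus a reference ellipse of the
    study-wide uniform size placed lateral of the socket in guaranteed
    spongy territory. The socket does not move between scans, so both
    sets share the same geometry.
    """
    ref_x, ref_z = spec.reference_ellipse_center_px()
    rois: list = []
    for r in sorted(analytic_section_areas(spec)):
        poly = section_polygon(spec, r, n_vertices=n_vertices)
        if poly is None:
            continue
        rois.append(poly)
        rois.append(
            EllipseRoi(
                slice_index=r,
                center=(ref_x, ref_z),
                semi_axes=spec.ref_semi_axes_px,
                label="reference_bone",
            )
        )
    rs_t1 = RoiSet(volume_id=f"{spec.source_id}-t1-seed{spec.seed}", timepoint="t1", rois=tuple(rois))
    rs_t2 = RoiSet(volume_id=f"{spec.source_id}-t2-seed{spec.seed}", timepoint="t2", rois=tuple(rois))
    return rs_t1, rs_t2
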