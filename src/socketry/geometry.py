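"""Deterministic geometric preprocessing of socket volumes.

The measurement workflow reduces a raw axial CBCT stack to an aligned
series of vestibulo-oral slices through the socket: drop apical/coronal
slices that contain unrelated anatomy, crop a rectangular block around
the socket and its neighbouring teeth, rotate each axial slice so the
socket and adjacent teeth line up vertically, reslice perpendicular to
the axial plane (vestibular to oral), thin the stack to every other
slice, and tile the remainder into a montage for annotation.

Every operation except bilinear rotation is an exact index manipulation:
gray values are moved, never resampled, so crop/keep/subsample outputs
are sub-multisets of the input values and reslicing is invertible
bit-exactly. Coordinates are 0-based ``(row, col)`` with row increasing
downward; pixel ``(r, c)`` occupies the half-open square
``[c, c+1) x [r, r+1)`` in pixel units.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from skimage.transform import rotate as _sk_rotate

from .volume_io import AXIAL, VESTIBULO_ORAL, VoxelVolume


@dataclass(frozen=True)
class CropBox:
    """Inclusive index bounds of a rectangular sub-block."""

    slice_first: int
    slice_last: int
    row_first: int
    row_last: int
    col_first: int
    col_last: int

    def validate(self, shape: tuple[int, int, int]) -> None:
        bounds = (
            ("slice", self.slice_first, self.slice_last, shape[0]),
            ("row", self.row_first, self.row_last, shape[1]),
            ("col", self.col_first, self.col_last, shape[2]),
        )
        for axis, first, last, extent in bounds:
            if not (0 <= first <= last < extent):
                raise ValueError(
                    f"invalid crop box on {axis} axis: [{first}, {last}] for extent {extent}"
                )

    @classmethod
    def full(cls, shape: tuple[int, int, int]) -> "CropBox":
        return cls(0, shape[0] - 1, 0, shape[1] - 1, 0, shape[2] - 1)


def keep_slices(v: VoxelVolume, first: int, last: int) -> VoxelVolume:
    """Keep slices ``first..last`` (inclusive); spacing unchanged.

    Removes unnecessary apical and coronal regions (mandibular canal,
    opposing jaw, maxillary sinus) before in-plane processing.
    """
    if not (0 <= first <= last < v.n_slices):
        raise ValueError(f"slice range [{first}, {last}] invalid for {v.n_slices} slices")
    return v.with_data(v.data[first : last + 1].copy())


def crop(v: VoxelVolume, box: CropBox) -> VoxelVolume:
    """Crop a rectangular block around the socket; gray values copied unchanged."""
    box.validate(v.shape)
    data = v.data[
        box.slice_first : box.slice_last + 1,
        box.row_first : box.row_last + 1,
        box.col_first : box.col_last + 1,
    ].copy()
    return v.with_data(data)


def rotate_slices(
    v: VoxelVolume, angle_deg: float, interpolation: str = "bilinear"
) -> VoxelVolume:
    """Rotate every axial slice about its center by ``angle_deg``
    (counter-clockwise positive), aligning socket and adjacent teeth
    along a vertical line.

    The rotation center is ``((rows-1)/2, (cols-1)/2)``; out-of-frame
    pixels are filled with 0. ``interpolation`` is ``nearest`` or
    ``bilinear``; bilinear output is rounded half-up back to the input
    integer dtype. 0 degrees is the identity for both modes.
    """
    if v.orientation != AXIAL:
        raise ValueError("rotation is defined on axial stacks")
    if abs(angle_deg) > 90:
        raise ValueError(f"|angle_deg| must be <= 90, got {angle_deg}")
    if interpolation not in ("nearest", "bilinear"):
        raise ValueError(f"unknown interpolation {interpolation!r}")
    if angle_deg == 0:
        return v.with_data(v.data.copy())
    order = 0 if interpolation == "nearest" else 1
    out = np.empty_like(v.data)
    for i in range(v.n_slices):
        rot = _sk_rotate(
            v.data[i].astype(np.float64),
            angle_deg,
            resize=False,
            center=None,  # ((cols-1)/2, (rows-1)/2)
            order=order,
            cval=0.0,
            preserve_range=True,
        )
        out[i] = np.clip(np.floor(rot + 0.5), 0, v.max_value).astype(v.data.dtype)
    return v.with_data(out)


def reslice_vestibulo_oral(v: VoxelVolume) -> VoxelVolume:
    """Reslice an axial stack perpendicular to the axial plane, producing
    slices running from vestibular to oral.

    Implemented as a pure axis permutation (no resampling): the voxel at
    axial index ``(i, r, c)`` appears at ``(r, i, c)`` in the new stack,
    whose slice axis is the former row (vestibulo-oral) axis. Spacing is
    permuted consistently; anisotropy is carried in metadata. Applying
    :func:`reslice_inverse` recovers the input bit-exactly.
    """
    if v.orientation != AXIAL:
        raise ValueError("input must be axial")
    data = np.ascontiguousarray(np.transpose(v.data, (1, 0, 2)))
    spacing = (v.spacing[1], v.spacing[0], v.spacing[2])
    return replace(v, data=data, spacing=spacing, orientation=VESTIBULO_ORAL)


def reslice_inverse(v: VoxelVolume) -> VoxelVolume:
    """Invert :func:`reslice_vestibulo_oral` bit-exactly."""
    if v.orientation != VESTIBULO_ORAL:
        raise ValueError("input must be vestibulo_oral")
    data = np.ascontiguousarray(np.transpose(v.data, (1, 0, 2)))
    spacing = (v.spacing[1], v.spacing[0], v.spacing[2])
    return replace(v, data=data, spacing=spacing, orientation=AXIAL)


def subsample_slices(v: VoxelVolume, increment: int) -> VoxelVolume:
    """Keep slices ``0, increment, 2*increment, ...`` and scale the
    slice-depth spacing by ``increment``.

    With increment 2 this halves the stack (40-70 socket slices become
    20-35) while doubling the recorded section thickness, so the
    Cavalieri sum of area x thickness still estimates the same volume.
    Feeding the *post-subsampling* slice depth to the volume estimator
    is what makes the thickness bookkeeping automatic.
    """
    if increment < 1:
        raise ValueError(f"increment must be >= 1, got {increment}")
    if increment == 1:
        return v.with_data(v.data.copy())
    data = v.data[::increment].copy()
    spacing = (v.spacing[0] * increment, v.spacing[1], v.spacing[2])
    return replace(v, data=data, spacing=spacing)


@dataclass(frozen=True)
class MontageLayout:
    """Bidirectional map between montage pixel coordinates and
    ``(slice_index, row, col)`` voxel coordinates."""

    n_slices: int
    tile_rows: int
    tile_cols: int
    columns: int

    @property
    def rows(self) -> int:
        return -(-self.n_slices // self.columns)  # ceil division

    def to_montage(self, slice_index: int, row: int, col: int) -> tuple[int, int]:
        if not (0 <= slice_index < self.n_slices):
            raise ValueError(f"slice index {slice_index} out of range")
        tr, tc = divmod(slice_index, self.columns)
        return tr * self.tile_rows + row, tc * self.tile_cols + col

    def to_volume(self, mont_row: int, mont_col: int) -> tuple[int, int, int]:
        tr, row = divmod(mont_row, self.tile_rows)
        tc, col = divmod(mont_col, self.tile_cols)
        slice_index = tr * self.columns + tc
        if slice_index >= self.n_slices:
            raise ValueError(f"montage position ({mont_row}, {mont_col}) is an unused tile")
        return slice_index, row, col


def montage(v: VoxelVolume, columns: int) -> tuple[np.ndarray, MontageLayout]:
    """Tile all slices row-major into one 2-D image for annotation.

    Slices run left-to-right, top-to-bottom (vestibular to oral for a
    resliced stack); unused tiles are zero-filled.
    """
    if columns < 1:
        raise ValueError(f"columns must be >= 1, got {columns}")
    n, tile_rows, tile_cols = v.shape
    layout = MontageLayout(n_slices=n, tile_rows=tile_rows, tile_cols=tile_cols, columns=columns)
    image = np.zeros((layout.rows * tile_rows, columns * tile_cols), dtype=v.data.dtype)
    for i in range(n):
        r0, c0 = layout.to_montage(i, 0, 0)
        image[r0 : r0 + tile_rows, c0 : c0 + tile_cols] = v.data[i]
    return image, layout
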