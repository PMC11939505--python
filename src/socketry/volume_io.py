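"""Reading, writing, normalisation and validation of CBCT-like volumes.

CBCT scans arrive either as a DICOM series (one file per axial slice), a
multiframe DICOM file, or — once exported for processing — a multi-page
TIFF stack accompanied by a JSON sidecar holding the voxel spacing. All
geometric and densitometric operations downstream work on the
:class:`VoxelVolume` container defined here, which carries the gray-value
grid together with its anisotropy-aware voxel spacing and an orientation
tag (``axial`` for the scanner frame, ``vestibulo_oral`` after reslicing).

Because CBCT gray values lack a standardized calibration (no Hounsfield
scale), volumes are homogenized to 8-bit before measurement and all
densitometry downstream is *relative* to reference spongy bone.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pydicom
import tifffile
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, generate_uid

AXIAL = "axial"
VESTIBULO_ORAL = "vestibulo_oral"

_ALLOWED_BIT_DEPTHS = (8, 12, 16)
_ALLOWED_ORIENTATIONS = (AXIAL, VESTIBULO_ORAL)

#: Slice-to-slice spacing agreement required within one loaded volume (mm).
INTRA_VOLUME_SPACING_TOL_MM = 1e-6

#: Default voxel-dimension agreement required between paired scans (mm).
#: Scanner metadata is typically rounded to ~1 µm, so anything below this
#: is metadata noise rather than a genuine acquisition difference.
DEFAULT_PAIR_SPACING_TOL_MM = 1e-3


class VolumeIOError(ValueError):
    """Raised when a volume cannot be read or its metadata is unusable."""


@dataclass(frozen=True)
class VoxelVolume:
    """A 3-D gray-value grid indexed ``(slice, row, col)``.

    Parameters
    ----------
    data
        Integer gray values, shape ``(n_slices, rows, cols)``.
    spacing
        Physical voxel extents ``(slice_depth_mm, row_mm, col_mm)`` of the
        *current* orientation; all strictly positive.
    bit_depth
        Nominal dynamic range: 8, 12 or 16. Every value must lie in
        ``[0, 2**bit_depth - 1]``.
    orientation
        ``"axial"`` or ``"vestibulo_oral"``.
    source_id
        Free-text provenance tag (file path, phantom spec id, ...).
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    bit_depth: int = 8
    orientation: str = AXIAL
    source_id: str = ""

    def __post_init__(self) -> None:
        data = np.asarray(self.data)
        if data.ndim != 3:
            raise ValueError(f"volume data must be 3-D, got ndim={data.ndim}")
        if min(data.shape) < 1:
            raise ValueError(f"volume must be non-empty, got shape {data.shape}")
        if self.bit_depth not in _ALLOWED_BIT_DEPTHS:
            raise ValueError(f"bit_depth must be one of {_ALLOWED_BIT_DEPTHS}")
        if self.orientation not in _ALLOWED_ORIENTATIONS:
            raise ValueError(f"orientation must be one of {_ALLOWED_ORIENTATIONS}")
        spacing = tuple(float(s) for s in self.spacing)
        if len(spacing) != 3 or not all(np.isfinite(s) and s > 0 for s in spacing):
            raise ValueError(f"spacing must be three positive finite mm values, got {self.spacing}")
        object.__setattr__(self, "spacing", spacing)
        lo, hi = data.min(), data.max()
        if lo < 0 or hi > self.max_value:
            raise ValueError(
                f"gray values [{lo}, {hi}] outside [0, {self.max_value}] for bit_depth {self.bit_depth}"
            )
        object.__setattr__(self, "data", data)

    # -- conveniences -------------------------------------------------

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(self.data.shape)

    @property
    def n_slices(self) -> int:
        return self.data.shape[0]

    @property
    def max_value(self) -> int:
        return 2 ** self.bit_depth - 1

    @property
    def slice_depth_mm(self) -> float:
        """Spacing along the slice axis — the Cavalieri section thickness."""
        return self.spacing[0]

    @property
    def in_plane_pixel_area_mm2(self) -> float:
        """Area of one pixel of a slice in the current orientation."""
        return self.spacing[1] * self.spacing[2]

    def with_data(self, data: np.ndarray, **changes) -> "VoxelVolume":
        return replace(self, data=data, **changes)


@dataclass(frozen=True)
class StudyRecord:
    """Per-socket study metadata.

    ``socket_type`` distinguishes sockets with both bony lamellae fully
    preserved (type 1) from those where at least one — typically the
    vestibular — is not (type 2). The classification is a human judgment
    made on axial slices; it is *annotation metadata only* and is never
    computed by this package.
    """

    socket_id: str
    tooth_class: str  # "premolar" | "molar"
    socket_type: str = "unknown"  # "1" | "2" | "unknown"
    group: str = ""
    timepoint: str = "t1"  # "t1" (post-extraction) | "t2" (post-regeneration)

    def __post_init__(self) -> None:
        if self.tooth_class not in ("premolar", "molar"):
            raise ValueError(f"tooth_class must be premolar|molar, got {self.tooth_class!r}")
        if str(self.socket_type) not in ("1", "2", "unknown"):
            raise ValueError(f"socket_type must be 1|2|unknown, got {self.socket_type!r}")
        object.__setattr__(self, "socket_type", str(self.socket_type))
        if self.timepoint not in ("t1", "t2"):
            raise ValueError(f"timepoint must be t1|t2, got {self.timepoint!r}")


# ---------------------------------------------------------------------------
# Loading
# ---------------------------------------------------------------------------


def load_volume(path: str | Path) -> VoxelVolume:
    """Load a volume from a DICOM series directory, a multiframe DICOM
    file, or a TIFF stack with a JSON spacing sidecar.

    Slices of a DICOM series are ordered by their spatial position along
    the slice axis; if position metadata is absent the filename sort order
    is used and a warning is emitted. Missing or zero spacing metadata is
    a hard error naming the missing tag.
    """
    path = Path(path)
    if path.is_dir():
        v = _load_dicom_series(path)
    elif not path.exists():
        raise VolumeIOError(f"no such file or directory: {path}")
    elif path.suffix.lower() in (".tif", ".tiff"):
        v = _load_tiff_stack(path)
    else:
        v = _load_multiframe_dicom(path)
    if v.data.shape[1] < 2 or v.data.shape[2] < 2:
        raise VolumeIOError(f"loaded scan slices must be >= 2x2 pixels, got {v.shape}")
    return v


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def _load_tiff_stack(path: Path) -> VoxelVolume:
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise VolumeIOError(
            f"spacing unavailable: TIFF stack {path} has no sidecar {sidecar.name}"
        )
    meta = json.loads(sidecar.read_text())
    try:
        spacing = tuple(float(x) for x in meta["spacing_mm"])
    except KeyError:
        raise VolumeIOError(f"spacing unavailable: sidecar {sidecar} lacks 'spacing_mm'")
    data = tifffile.imread(path)
    if data.ndim == 2:
        data = data[np.newaxis]
    bit_depth = int(meta.get("bit_depth", 8 * data.dtype.itemsize))
    return VoxelVolume(
        data=data,
        spacing=spacing,
        bit_depth=bit_depth,
        orientation=meta.get("orientation", AXIAL),
        source_id=meta.get("source_id", str(path)),
    )


def _dicom_spacing(ds: Dataset, context: str) -> tuple[float, float]:
    ps = getattr(ds, "PixelSpacing", None)
    if ps is None and "SharedFunctionalGroupsSequence" in ds:
        shared = ds.SharedFunctionalGroupsSequence[0]
        if "PixelMeasuresSequence" in shared:
            ps = getattr(shared.PixelMeasuresSequence[0], "PixelSpacing", None)
    if ps is None:
        raise VolumeIOError(f"missing PixelSpacing tag in {context}")
    row_mm, col_mm = float(ps[0]), float(ps[1])
    if row_mm <= 0 or col_mm <= 0:
        raise VolumeIOError(f"zero/negative PixelSpacing in {context}")
    return row_mm, col_mm


def _dicom_slice_depth(ds: Dataset, context: str) -> float | None:
    for tag in ("SpacingBetweenSlices", "SliceThickness"):
        val = getattr(ds, tag, None)
        if val is None and "SharedFunctionalGroupsSequence" in ds:
            shared = ds.SharedFunctionalGroupsSequence[0]
            if "PixelMeasuresSequence" in shared:
                val = getattr(shared.PixelMeasuresSequence[0], tag, None)
        if val is not None:
            depth = float(val)
            if depth <= 0:
                raise VolumeIOError(f"zero/negative {tag} in {context}")
            return depth
    return None


def _load_dicom_series(directory: Path) -> VoxelVolume:
    files = sorted(p for p in directory.iterdir() if p.is_file() and p.suffix.lower() != ".json")
    if not files:
        raise VolumeIOError(f"no DICOM files in {directory}")
    datasets = [pydicom.dcmread(str(p)) for p in files]

    positions = []
    for ds in datasets:
        ipp = getattr(ds, "ImagePositionPatient", None)
        positions.append(float(ipp[2]) if ipp is not None else None)
    if all(p is not None for p in positions):
        order = np.argsort(positions, kind="stable")
    else:
        warnings.warn(
            f"{directory}: slice positions unavailable; falling back to filename order",
            stacklevel=2,
        )
        order = np.arange(len(datasets))
    datasets = [datasets[i] for i in order]
    positions = [positions[i] for i in order]

    spacings = [_dicom_spacing(ds, str(directory)) for ds in datasets]
    row_mm, col_mm = spacings[0]
    for s in spacings[1:]:
        if abs(s[0] - row_mm) > INTRA_VOLUME_SPACING_TOL_MM or abs(s[1] - col_mm) > INTRA_VOLUME_SPACING_TOL_MM:
            raise VolumeIOError(f"mixed PixelSpacing across slices in {directory}")

    depth = _dicom_slice_depth(datasets[0], str(directory))
    if depth is None and len(datasets) > 1 and all(p is not None for p in positions):
        diffs = np.diff(positions)
        if diffs.size and np.ptp(diffs) > INTRA_VOLUME_SPACING_TOL_MM:
            raise VolumeIOError(f"mixed slice spacing across positions in {directory}")
        depth = float(abs(diffs[0])) if diffs.size else None
    if depth is None or depth <= 0:
        raise VolumeIOError(
            f"missing SpacingBetweenSlices/SliceThickness tag in {directory}"
        )

    data = np.stack([ds.pixel_array for ds in datasets])
    bits = int(getattr(datasets[0], "BitsStored", 8 * data.dtype.itemsize))
    bit_depth = bits if bits in _ALLOWED_BIT_DEPTHS else 8 * data.dtype.itemsize
    return VoxelVolume(
        data=data,
        spacing=(depth, row_mm, col_mm),
        bit_depth=bit_depth,
        orientation=AXIAL,
        source_id=str(directory),
    )


def _load_multiframe_dicom(path: Path) -> VoxelVolume:
    ds = pydicom.dcmread(str(path))
    n_frames = int(getattr(ds, "NumberOfFrames", 1))
    row_mm, col_mm = _dicom_spacing(ds, str(path))
    depth = _dicom_slice_depth(ds, str(path))
    if depth is None:
        raise VolumeIOError(f"missing SpacingBetweenSlices/SliceThickness tag in {path}")
    data = ds.pixel_array
    if data.ndim == 2:
        data = data[np.newaxis]
    if data.shape[0] != n_frames:
        raise VolumeIOError(f"frame count mismatch in {path}")
    bits = int(getattr(ds, "BitsStored", 8 * data.dtype.itemsize))
    bit_depth = bits if bits in _ALLOWED_BIT_DEPTHS else 8 * data.dtype.itemsize
    return VoxelVolume(
        data=data,
        spacing=(depth, row_mm, col_mm),
        bit_depth=bit_depth,
        orientation=AXIAL,
        source_id=str(path),
    )


# ---------------------------------------------------------------------------
# Normalisation
# ---------------------------------------------------------------------------


def normalize_to_8bit(v: VoxelVolume) -> VoxelVolume:
    """Homogenize the grayscale range to 8-bit (256 gray levels).

    The volume's global ``[0, max]`` is mapped linearly onto
    ``[0, 255]`` with round-half-up — a *zero-preserving* rescale. A
    constant (contrast-free) volume maps to all zeros, the conservative
    "no signal" convention for a degenerate scan. The map is monotone, so gray-value ordering is
    preserved, and a volume already spanning ``[0, 255]`` is returned
    unchanged in value.

    Zero is kept fixed deliberately: the downstream densitometry works
    on gray-value *quotients* (socket / reference bone), which a pure
    rescale leaves exactly invariant. Subtracting the global minimum
    instead would inject a noise-dependent offset into every quotient
    and defeat the gain robustness the reference normalization exists
    to provide.
    """
    data = v.data.astype(np.float64)
    hi = data.max()
    if hi == 0 or hi == data.min():
        out = np.zeros(v.shape, dtype=np.uint8)
    else:
        out = np.floor(data * (255.0 / hi) + 0.5).astype(np.uint8)
    return replace(v, data=out, bit_depth=8)


# ---------------------------------------------------------------------------
# Pair validation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ValidationCheck:
    name: str
    passed: bool
    detail: str = ""


@dataclass(frozen=True)
class PairValidation:
    """Report of the data-quality gates applied to a t1/t2 scan pair.

    A failed check marks the pair ``excluded`` — paired volumetry is only
    meaningful when both scans share voxel dimensions and dynamic range.
    """

    checks: tuple[ValidationCheck, ...]

    @property
    def passed(self) -> bool:
        return all(c.passed for c in self.checks)

    @property
    def excluded(self) -> bool:
        return not self.passed

    @property
    def reason(self) -> str:
        return "; ".join(c.detail for c in self.checks if not c.passed)


def validate_pair(
    v1: VoxelVolume, v2: VoxelVolume, tol_mm: float = DEFAULT_PAIR_SPACING_TOL_MM
) -> PairValidation:
    """Check that two scans of the same socket are comparable.

    Differing voxel dimensions between the paired scans is an exclusion
    criterion: component-wise spacing must agree within ``tol_mm``, and
    both volumes must share the same bit depth.
    """
    checks = []
    deltas = [abs(a - b) for a, b in zip(v1.spacing, v2.spacing)]
    spacing_ok = all(d <= tol_mm for d in deltas)
    checks.append(
        ValidationCheck(
            name="voxel_dimensions",
            passed=spacing_ok,
            detail=""
            if spacing_ok
            else f"voxel dimension mismatch: {v1.spacing} vs {v2.spacing} (tol {tol_mm} mm)",
        )
    )
    depth_ok = v1.bit_depth == v2.bit_depth
    checks.append(
        ValidationCheck(
            name="bit_depth",
            passed=depth_ok,
            detail="" if depth_ok else f"bit depth mismatch: {v1.bit_depth} vs {v2.bit_depth}",
        )
    )
    return PairValidation(checks=tuple(checks))


# ---------------------------------------------------------------------------
# Writing
# ---------------------------------------------------------------------------


def write_volume(v: VoxelVolume, path: str | Path, format: str = "tiff") -> None:
    """Write a volume to disk; ``load_volume`` reproduces it bit-exactly.

    ``tiff`` writes one multi-page file (page count = slice count) plus a
    JSON sidecar recording spacing, bit depth and orientation. ``dicom``
    writes a minimal secondary-capture series directory.
    """
    path = Path(path)
    if format == "tiff":
        _write_tiff(v, path)
    elif format == "dicom":
        _write_dicom_series(v, path)
    else:
        raise ValueError(f"unknown format {format!r}")


def _write_tiff(v: VoxelVolume, path: Path) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    data = v.data
    if data.dtype not in (np.uint8, np.uint16):
        data = data.astype(np.uint8 if v.bit_depth == 8 else np.uint16)
    tifffile.imwrite(str(path), data, photometric="minisblack")
    sidecar = {
        "spacing_mm": list(v.spacing),
        "bit_depth": v.bit_depth,
        "orientation": v.orientation,
        "source_id": v.source_id,
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1))


def _write_dicom_series(v: VoxelVolume, directory: Path) -> None:
    directory.mkdir(parents=True, exist_ok=True)
    data = v.data.astype(np.uint8 if v.bit_depth == 8 else np.uint16)
    series_uid = generate_uid()
    study_uid = generate_uid()
    for i in range(v.n_slices):
        ds = Dataset()
        ds.file_meta = FileMetaDataset()
        ds.file_meta.TransferSyntaxUID = ExplicitVRLittleEndian
        ds.file_meta.MediaStorageSOPClassUID = "1.2.840.10008.5.1.4.1.1.7"  # secondary capture
        ds.file_meta.MediaStorageSOPInstanceUID = generate_uid()
        ds.SOPClassUID = ds.file_meta.MediaStorageSOPClassUID
        ds.SOPInstanceUID = ds.file_meta.MediaStorageSOPInstanceUID
        ds.StudyInstanceUID = study_uid
        ds.SeriesInstanceUID = series_uid
        ds.Modality = "OT"
        ds.PatientName = ""
        ds.PatientID = v.source_id or "socketry"
        ds.InstanceNumber = i + 1
        ds.ImagePositionPatient = [0.0, 0.0, i * v.spacing[0]]
        ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
        ds.PixelSpacing = [v.spacing[1], v.spacing[2]]
        ds.SliceThickness = v.spacing[0]
        ds.SpacingBetweenSlices = v.spacing[0]
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.Rows, ds.Columns = data.shape[1], data.shape[2]
        ds.BitsAllocated = 8 * data.dtype.itemsize
        ds.BitsStored = v.bit_depth
        ds.HighBit = v.bit_depth - 1
        ds.PixelRepresentation = 0
        ds.PixelData = data[i].tobytes()
        ds.save_as(str(directory / f"slice_{i:04d}.dcm"), enforce_file_format=True)
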