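"""Workflow orchestration: configuration-driven preprocessing and
evaluation with provenance and CSV reporting.

Every interactive choice of the original workflow (slice range, crop
box, rotation angle, thinning increment, segmentation rule) is a config
field, so a run is fully auditable and bit-reproducible: the per-socket
provenance JSON records the ordered operation list, and replaying it on
the raw input reproduces the processed stacks exactly.

ROI files annotate the *full-resolution* vestibulo-oral stack; the
evaluation step maps them onto the thinned stack of the configured
increment. Failures of individual sockets (validation gate, missing
files, degenerate ROIs) exclude that socket with a logged reason and
the run continues, so the exclusion bookkeeping
``n_input = n_evaluated + n_excluded`` always holds.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import geometry, metrics, roi as roi_mod, volume_io
from .metrics import DEFAULT_THRESHOLD_RULE, ThresholdRule
from .volume_io import StudyRecord, VoxelVolume

logger = logging.getLogger("socketry")

PROVENANCE_SCHEMA_VERSION = 1


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SocketEntry:
    socket_id: str
    tooth_class: str
    t1_path: str
    t2_path: str
    roi_t1_path: str
    roi_t2_path: str
    socket_type: str = "unknown"
    group: str = ""
    keep: Optional[tuple[int, int]] = None
    crop: Optional[tuple[int, int, int, int, int, int]] = None
    rotation_deg: float = 0.0
    subsample_increment: int = 2
    threshold_rule: ThresholdRule = DEFAULT_THRESHOLD_RULE
    montage_columns: int = 5

    def __post_init__(self) -> None:
        if self.subsample_increment < 1:
            raise ValueError("subsample_increment must be >= 1")

    @property
    def record(self) -> StudyRecord:
        return StudyRecord(
            socket_id=self.socket_id,
            tooth_class=self.tooth_class,
            socket_type=self.socket_type,
            group=self.group,
        )


@dataclass(frozen=True)
class RunConfig:
    output_dir: str
    sockets: tuple[SocketEntry, ...] = ()
    spacing_tolerance_mm: float = volume_io.DEFAULT_PAIR_SPACING_TOL_MM
    baseline_floor: float = metrics.DEFAULT_BASELINE_FLOOR
    seed: int = 0


def _threshold_rule_from_dict(d) -> ThresholdRule:
    if d is None:
        return DEFAULT_THRESHOLD_RULE
    if isinstance(d, str):
        return ThresholdRule(kind=d)
    return ThresholdRule(kind=d["kind"], value=float(d.get("value", 0.5)))


def load_config(path: str | Path) -> RunConfig:
    doc = yaml.safe_load(Path(path).read_text()) or {}
    sockets = []
    for entry in doc.get("sockets", []):
        sockets.append(
            SocketEntry(
                socket_id=str(entry["socket_id"]),
                tooth_class=entry["tooth_class"],
                socket_type=str(entry.get("socket_type", "unknown")),
                group=entry.get("group", ""),
                t1_path=entry["t1_path"],
                t2_path=entry["t2_path"],
                roi_t1_path=entry["roi_t1_path"],
                roi_t2_path=entry["roi_t2_path"],
                keep=tuple(entry["keep"]) if entry.get("keep") else None,
                crop=tuple(entry["crop"]) if entry.get("crop") else None,
                rotation_deg=float(entry.get("rotation_deg", 0.0)),
                subsample_increment=int(entry.get("subsample_increment", 2)),
                threshold_rule=_threshold_rule_from_dict(entry.get("threshold_rule")),
                montage_columns=int(entry.get("montage_columns", 5)),
            )
        )
    return RunConfig(
        output_dir=doc.get("output_dir", "socketry_out"),
        sockets=tuple(sockets),
        spacing_tolerance_mm=float(doc.get("spacing_tolerance_mm", volume_io.DEFAULT_PAIR_SPACING_TOL_MM)),
        baseline_floor=float(doc.get("baseline_floor", metrics.DEFAULT_BASELINE_FLOOR)),
        seed=int(doc.get("seed", 0)),
    )


# ---------------------------------------------------------------------------
# Provenance
# ---------------------------------------------------------------------------


def preprocessing_operations(entry: SocketEntry) -> list[dict]:
    """Ordered, machine-readable operation list for one socket."""
    ops: list[dict] = [{"op": "normalize_to_8bit"}]
    if entry.keep is not None:
        ops.append({"op": "keep_slices", "first": entry.keep[0], "last": entry.keep[1]})
    if entry.crop is not None:
        ops.append({"op": "crop", "box": list(entry.crop)})
    ops.append({"op": "rotate_slices", "angle_deg": entry.rotation_deg,
                "interpolation": "bilinear"})
    ops.append({"op": "reslice_vestibulo_oral"})
    ops.append({"op": "subsample_slices", "increment": entry.subsample_increment})
    return ops


def apply_operations(volume: VoxelVolume, operations: list[dict]) -> VoxelVolume:
    """Apply a recorded operation list; the replay path used both for
    the run itself and for bit-exact reproduction from provenance."""
    v = volume
    for op in operations:
        name = op["op"]
        if name == "normalize_to_8bit":
            v = volume_io.normalize_to_8bit(v)
        elif name == "keep_slices":
            v = geometry.keep_slices(v, op["first"], op["last"])
        elif name == "crop":
            v = geometry.crop(v, geometry.CropBox(*op["box"]))
        elif name == "rotate_slices":
            v = geometry.rotate_slices(v, op["angle_deg"], op["interpolation"])
        elif name == "reslice_vestibulo_oral":
            v = geometry.reslice_vestibulo_oral(v)
        elif name == "subsample_slices":
            v = geometry.subsample_slices(v, op["increment"])
        else:
            raise ValueError(f"unknown operation {name!r} in provenance")
    return v


def _volume_digest(v: VoxelVolume) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(v.data).tobytes())
    h.update(json.dumps(v.spacing).encode())
    return h.hexdigest()


# ---------------------------------------------------------------------------
# Preprocess
# ---------------------------------------------------------------------------


@dataclass
class RunReport:
    n_input: int = 0
    processed: list[str] = field(default_factory=list)
    excluded: dict[str, str] = field(default_factory=dict)

    @property
    def n_processed(self) -> int:
        return len(self.processed)

    @property
    def n_excluded(self) -> int:
        return len(self.excluded)


def _socket_dir(config: RunConfig, socket_id: str) -> Path:
    return Path(config.output_dir) / socket_id


def run_preprocess(config: RunConfig) -> RunReport:
    """Normalize, align and reslice every configured socket pair.

    Writes per socket: processed t1/t2 TIFF stacks with spacing
    sidecars, annotation montages, and a provenance JSON sufficient to
    replay the run bit-exactly.
    """
    report = RunReport(n_input=len(config.sockets))
    for entry in config.sockets:
        try:
            v1 = volume_io.load_volume(entry.t1_path)
            v2 = volume_io.load_volume(entry.t2_path)
            validation = volume_io.validate_pair(v1, v2, tol_mm=config.spacing_tolerance_mm)
            if validation.excluded:
                report.excluded[entry.socket_id] = validation.reason
                logger.warning("socket %s excluded: %s", entry.socket_id, validation.reason)
                continue
            ops = preprocessing_operations(entry)
            out_dir = _socket_dir(config, entry.socket_id)
            out_dir.mkdir(parents=True, exist_ok=True)
            provenance = {
                "schema_version": PROVENANCE_SCHEMA_VERSION,
                "socket_id": entry.socket_id,
                "operations": ops,
                "timepoints": {},
            }
            for tp, (src, v) in (("t1", (entry.t1_path, v1)), ("t2", (entry.t2_path, v2))):
                processed = apply_operations(v, ops)
                out_path = out_dir / f"{tp}_processed.tif"
                volume_io.write_volume(processed, out_path, format="tiff")
                mont, layout = geometry.montage(processed, entry.montage_columns)
                import tifffile

                tifffile.imwrite(str(out_dir / f"{tp}_montage.tif"), mont)
                (out_dir / f"{tp}_montage_indexmap.json").write_text(
                    json.dumps(dataclasses.asdict(layout))
                )
                provenance["timepoints"][tp] = {
                    "source": str(src),
                    "output": str(out_path),
                    "sha256": _volume_digest(processed),
                }
            (out_dir / "provenance.json").write_text(json.dumps(provenance, indent=1))
            report.processed.append(entry.socket_id)
            logger.info("socket %s preprocessed", entry.socket_id)
        except Exception as exc:  # per-socket isolation: log and continue
            report.excluded[entry.socket_id] = str(exc)
            logger.warning("socket %s excluded: %s", entry.socket_id, exc)
    return report


def replay_socket(config: RunConfig, socket_id: str) -> dict[str, VoxelVolume]:
    """Re-run a socket's recorded preprocessing from its provenance log
    and verify the stored digests; returns the reproduced volumes."""
    prov = json.loads((_socket_dir(config, socket_id) / "provenance.json").read_text())
    out = {}
    for tp, info in prov["timepoints"].items():
        v = apply_operations(volume_io.load_volume(info["source"]), prov["operations"])
        if _volume_digest(v) != info["sha256"]:
            raise RuntimeError(f"provenance replay mismatch for {socket_id}/{tp}")
        out[tp] = v
    return out


# ---------------------------------------------------------------------------
# Evaluate
# ---------------------------------------------------------------------------


def run_evaluate(config: RunConfig) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, RunReport]:
    """Measure and evaluate every preprocessed socket.

    Returns (slices, sockets, strata) data frames — also written as CSV
    into the output directory — plus the exclusion report.
    """
    report = RunReport(n_input=len(config.sockets))
    slice_rows: list[dict] = []
    socket_rows: list[dict] = []
    evaluated: list[tuple[StudyRecord, metrics.SocketResult]] = []
    for entry in config.sockets:
        try:
            out_dir = _socket_dir(config, entry.socket_id)
            v1 = volume_io.load_volume(out_dir / "t1_processed.tif")
            v2 = volume_io.load_volume(out_dir / "t2_processed.tif")
            rs1 = roi_mod.load_roiset(entry.roi_t1_path).subsampled(entry.subsample_increment)
            rs2 = roi_mod.load_roiset(entry.roi_t2_path).subsampled(entry.subsample_increment)
            m1, m2 = metrics.measure_socket_pair(v1, v2, rs1, rs2, entry.threshold_rule)
            result = metrics.evaluate_socket(
                m1, m2, v1.slice_depth_mm,
                baseline_floor=config.baseline_floor,
                threshold_rule_label=entry.threshold_rule.describe(),
            )
            for m in m1 + m2:
                row = {"socket_id": entry.socket_id, **dataclasses.asdict(m)}
                slice_rows.append(row)
            socket_rows.append(
                {
                    "socket_id": entry.socket_id,
                    "tooth_class": entry.tooth_class,
                    "socket_type": entry.socket_type,
                    "group": entry.group,
                    **{
                        k: (";".join(v) if isinstance(v, tuple) else v)
                        for k, v in dataclasses.asdict(result).items()
                    },
                }
            )
            evaluated.append((entry.record, result))
            report.processed.append(entry.socket_id)
        except Exception as exc:
            report.excluded[entry.socket_id] = str(exc)
            logger.warning("socket %s excluded from evaluation: %s", entry.socket_id, exc)

    slices_df = pd.DataFrame(slice_rows)
    sockets_df = pd.DataFrame(socket_rows)
    strata_frames = []
    groups = sorted({rec.group for rec, _ in evaluated}) or []
    for grp in groups:
        sub = [(rec, res) for rec, res in evaluated if rec.group == grp]
        df = metrics.summarize_group(sub)
        df.insert(0, "group", grp)
        strata_frames.append(df)
    if evaluated:
        df_all = metrics.summarize_group(evaluated)
        df_all.insert(0, "group", "all")
        strata_frames.append(df_all)
    strata_df = pd.concat(strata_frames, ignore_index=True) if strata_frames else pd.DataFrame()

    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    slices_df.to_csv(out / "slices.csv", index=False, float_format="%.10g")
    sockets_df.to_csv(out / "sockets.csv", index=False, float_format="%.10g")
    strata_df.to_csv(out / "strata.csv", index=False, float_format="%.10g")
    exclusions = pd.DataFrame(
        [{"socket_id": k, "reason": v} for k, v in sorted(report.excluded.items())]
    )
    exclusions.to_csv(out / "exclusions.csv", index=False)
    return slices_df, sockets_df, strata_df, report


def evaluate_phantom(
    spec,
    *,
    increment: int = 2,
    threshold_rule: ThresholdRule = DEFAULT_THRESHOLD_RULE,
    rotation_deg: float = 0.0,
):
    """Run the full in-memory pipeline on one phantom pair.

    generate -> normalize -> rotate -> reslice -> thin -> measure ->
    evaluate, using the phantom's ground-truth annotations. Returns
    ``(SocketResult, GroundTruth)`` — the standard parameter-recovery
    experiment.
    """
    from . import phantom as phantom_mod

    v1, v2, truth = phantom_mod.generate_pair(spec)
    ops = [
        {"op": "normalize_to_8bit"},
        {"op": "rotate_slices", "angle_deg": rotation_deg, "interpolation": "bilinear"},
        {"op": "reslice_vestibulo_oral"},
        {"op": "subsample_slices", "increment": increment},
    ]
    p1 = apply_operations(v1, ops)
    p2 = apply_operations(v2, ops)
    m1, m2 = metrics.measure_socket_pair(
        p1, p2,
        truth.roiset_t1.subsampled(increment),
        truth.roiset_t2.subsampled(increment),
        threshold_rule,
    )
    result = metrics.evaluate_socket(
        m1, m2, p1.slice_depth_mm, threshold_rule_label=threshold_rule.describe()
    )
    return result, truth


# ---------------------------------------------------------------------------
# Simulate
# ---------------------------------------------------------------------------


def run_simulate(spec, out_dir: str | Path, *, increment: int = 2) -> dict:
    """Write one phantom pair plus annotations and a ready-to-run config.

    Outputs: axial t1/t2 TIFF stacks with sidecars, ground-truth ROI
    JSONs (full-resolution vestibulo-oral frame), a ground-truth JSON
    with the analytic volumes, and ``run_config.yaml`` wiring them into
    the preprocess/evaluate pipeline.
    """
    from . import phantom as phantom_mod

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    v1, v2, truth = phantom_mod.generate_pair(spec)
    volume_io.write_volume(v1, out / "t1.tif", format="tiff")
    volume_io.write_volume(v2, out / "t2.tif", format="tiff")
    roi_mod.save_roiset(truth.roiset_t1, out / "roi_t1.json")
    roi_mod.save_roiset(truth.roiset_t2, out / "roi_t2.json")
    truth_doc = {
        "V_socket_true_mm3": truth.V_socket_true_mm3,
        "V_mineralized_true_mm3": truth.V_mineralized_true_mm3,
        "fill_fraction": truth.fill_fraction,
        "new_bone_fraction": truth.new_bone_fraction,
        "section_areas_mm2": {str(k): v for k, v in truth.section_areas_mm2.items()},
    }
    (out / "ground_truth.json").write_text(json.dumps(truth_doc, indent=1))
    config_doc = {
        "output_dir": str(out / "results"),
        "seed": spec.seed,
        "sockets": [
            {
                "socket_id": "phantom",
                "tooth_class": "molar",
                "socket_type": "1",
                "group": "phantom",
                "t1_path": str(out / "t1.tif"),
                "t2_path": str(out / "t2.tif"),
                "roi_t1_path": str(out / "roi_t1.json"),
                "roi_t2_path": str(out / "roi_t2.json"),
                "subsample_increment": increment,
            }
        ],
    }
    (out / "run_config.yaml").write_text(yaml.safe_dump(config_doc, sort_keys=False))
    return truth_doc
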