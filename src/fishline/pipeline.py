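"""End-to-end landing-session orchestration and report export.

Per frame the chain is detect -> size filter -> multiclass NMS ->
morphometrics; every surviving detection becomes one LandingRecord
carrying timestamp, species, length, optional weight, confidence, the
detector identifier, gate and plant names and the frame id.  Discarded
detections are logged with a machine-parseable reason (``size_filter`` or
``nms``).  The summary aggregates per-species counts, total estimated
weight and length statistics over the session.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import CameraCalibration, Detection, SpeciesCatalog, default_catalog
from .detection import DetectorConfig, detect
from .morphometrics import Morphometry, measure
from .postprocessing import (
    NmsConfig,
    SizeFilterRule,
    multiclass_nms,
    rules_from_catalog,
    size_filter,
)

__all__ = [
    "PipelineConfig",
    "LandingRecord",
    "LandingSummary",
    "run_session",
    "export_report",
    "read_records_csv",
    "summarize",
]

logger = logging.getLogger("fishline")

RECORD_COLUMNS = [
    "timestamp",
    "plant",
    "gate",
    "frame_id",
    "species",
    "length_cm",
    "weight_g",
    "confidence",
    "model",
    "schema_version",
]

SCHEMA_VERSION = 1


@dataclass(frozen=True)
class PipelineConfig:
    catalog: SpeciesCatalog
    calibration: CameraCalibration
    detector: DetectorConfig = DetectorConfig()
    nms: NmsConfig = NmsConfig()
    size_rules: tuple[SizeFilterRule, ...] | None = None  # None: from catalog
    gate: str = "gate-1"
    plant: str = "plant-1"

    @classmethod
    def default(cls, **kw) -> "PipelineConfig":
        catalog, cal = default_catalog()
        return cls(catalog=catalog, calibration=cal, **kw)

    @property
    def model_id(self) -> str:
        """Detector backend identifier plus a short config hash, for audit."""
        payload = json.dumps(
            {
                "backend": self.detector.backend,
                "confidence_floor": self.detector.confidence_floor,
                "input_size": list(self.detector.input_size),
                "nms_iou": self.nms.iou_threshold,
            },
            sort_keys=True,
        )
        digest = hashlib.sha256(payload.encode()).hexdigest()[:8]
        return f"{self.detector.backend}-{digest}"


@dataclass(frozen=True)
class LandingRecord:
    timestamp: str
    species: str
    length_cm: float
    weight_g: float | None
    confidence: float
    model: str
    gate: str
    plant: str
    frame_id: str
    schema_version: int = SCHEMA_VERSION


@dataclass(frozen=True)
class LandingSummary:
    species_counts: dict
    total_weight_g: float
    length_min_cm: float | None
    length_mean_cm: float | None
    length_max_cm: float | None
    first_timestamp: str | None
    last_timestamp: str | None

    @property
    def total_count(self) -> int:
        return sum(self.species_counts.values())


def summarize(records: list[LandingRecord]) -> LandingSummary:
    counts: dict = {}
    for r in records:
        counts[r.species] = counts.get(r.species, 0) + 1
    weights = [r.weight_g for r in records if r.weight_g is not None]
    lengths = [r.length_cm for r in records]
    stamps = sorted(r.timestamp for r in records)
    return LandingSummary(
        species_counts=counts,
        total_weight_g=float(sum(weights)),
        length_min_cm=min(lengths) if lengths else None,
        length_mean_cm=float(np.mean(lengths)) if lengths else None,
        length_max_cm=max(lengths) if lengths else None,
        first_timestamp=stamps[0] if stamps else None,
        last_timestamp=stamps[-1] if stamps else None,
    )


def process_frame(
    image, cfg: PipelineConfig, frame_id: str, timestamp: str
) -> tuple[list[LandingRecord], list[Detection], list[tuple[Detection, Morphometry]]]:
    """Detect and postprocess one frame; returns (records, discarded, kept)."""
    dets = detect(image, cfg.detector, cfg.catalog, frame_id=frame_id)
    rules = (
        list(cfg.size_rules)
        if cfg.size_rules is not None
        else rules_from_catalog(cfg.catalog)
    )
    kept, size_discarded = size_filter(dets, rules, cfg.calibration)
    for d in size_discarded:
        logger.info(
            "discarded frame=%s species=%s confidence=%.3f reason=size_filter",
            frame_id, d.species, d.confidence,
        )
    survivors = multiclass_nms(kept, cfg.nms)
    for d in kept:
        if d not in survivors:
            logger.info(
                "discarded frame=%s species=%s confidence=%.3f reason=nms",
                frame_id, d.species, d.confidence,
            )
    records: list[LandingRecord] = []
    kept_pairs: list[tuple[Detection, Morphometry]] = []
    for d in survivors:
        m = measure(d.box, d.species, cfg.catalog, cfg.calibration)
        kept_pairs.append((d, m))
        records.append(
            LandingRecord(
                timestamp=timestamp,
                species=d.species,
                length_cm=m.length_cm,
                weight_g=m.weight_g,
                confidence=d.confidence,
                model=cfg.model_id,
                gate=cfg.gate,
                plant=cfg.plant,
                frame_id=frame_id,
            )
        )
    discarded = size_discarded + [d for d in kept if d not in survivors]
    return records, discarded, kept_pairs


def run_session(
    frames, cfg: PipelineConfig
) -> tuple[list[LandingRecord], LandingSummary, dict]:
    """Process a sequence of frames.

    ``frames`` yields (image-or-path, frame_id, timestamp) triples, or bare
    images/paths (ids and timestamps are then synthesized).  Unreadable
    frames are skipped with a warning; the session continues.
    """
    from PIL import Image

    records: list[LandingRecord] = []
    discarded_all: list[Detection] = []
    n_frames = 0
    for k, item in enumerate(frames):
        if isinstance(item, tuple) and len(item) == 3:
            image, frame_id, timestamp = item
        else:
            image, frame_id, timestamp = item, f"frame-{k}", "1970-01-01T00:00:00"
        if isinstance(image, (str, Path)):
            try:
                image = np.asarray(Image.open(image).convert("RGB"), dtype=np.uint8)
            except (OSError, ValueError) as exc:
                logger.warning("skipping unreadable frame %s: %s", image, exc)
                continue
        recs, discarded, _ = process_frame(image, cfg, frame_id, timestamp)
        records.extend(recs)
        discarded_all.extend(discarded)
        n_frames += 1
    summary = summarize(records)
    artifacts = {"n_frames": n_frames, "discarded": discarded_all}
    return records, summary, artifacts


def _records_frame(records: list[LandingRecord]) -> pd.DataFrame:
    rows = [
        {
            "timestamp": r.timestamp,
            "plant": r.plant,
            "gate": r.gate,
            "frame_id": r.frame_id,
            "species": r.species,
            "length_cm": r.length_cm,
            "weight_g": r.weight_g,
            "confidence": r.confidence,
            "model": r.model,
            "schema_version": r.schema_version,
        }
        for r in records
    ]
    return pd.DataFrame(rows, columns=RECORD_COLUMNS)


def export_report(
    records: list[LandingRecord],
    summary: LandingSummary,
    out_dir: str | Path,
    formats: tuple[str, ...] = ("csv", "json"),
) -> dict:
    """Write the session report; CSV rows round-trip losslessly."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict = {}
    if "csv" in formats:
        csv_path = out_dir / "records.csv"
        _records_frame(records).to_csv(csv_path, index=False)
        paths["csv"] = csv_path
    if "json" in formats:
        json_path = out_dir / "report.json"
        payload = {
            "records": [r.__dict__ for r in records],
            "summary": {
                "species_counts": summary.species_counts,
                "total_weight_g": summary.total_weight_g,
                "length_min_cm": summary.length_min_cm,
                "length_mean_cm": summary.length_mean_cm,
                "length_max_cm": summary.length_max_cm,
                "first_timestamp": summary.first_timestamp,
                "last_timestamp": summary.last_timestamp,
                "total_count": summary.total_count,
            },
        }
        with open(json_path, "w") as fh:
            json.dump(payload, fh, indent=2)
        paths["json"] = json_path
    return paths


def read_records_csv(path: str | Path) -> list[LandingRecord]:
    df = pd.read_csv(path, float_precision="round_trip")
    records = []
    for _, row in df.iterrows():
        weight = row["weight_g"]
        records.append(
            LandingRecord(
                timestamp=str(row["timestamp"]),
                species=str(row["species"]),
                length_cm=float(row["length_cm"]),
                weight_g=None if pd.isna(weight) else float(weight),
                confidence=float(row["confidence"]),
                model=str(row["model"]),
                gate=str(row["gate"]),
                plant=str(row["plant"]),
                frame_id=str(row["frame_id"]),
                schema_version=int(row["schema_version"]),
            )
        )
    return records
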