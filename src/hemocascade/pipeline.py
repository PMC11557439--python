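"""End-to-end per-patient pipeline: filter, segment, classify, quantify.

Each slice is screened by the binary hemorrhage filter; negatives get an
empty mask and an all-false label vector without touching the heavier
models.  Positives flow through the two-stage segmentation cascade, the
predicted mask and Stage-I ROI feed the fusion subtype classifier, and
the emitted masks are converted into a hematoma volume and scan-level
subtype labels (logical OR over slices) ready to merge with a clinical
table for outcome modelling.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np

from .classify import (
    BinaryFilterModel,
    FusionModel,
    build_fusion_input,
    predict_subtypes,
)
from .image_io import SUBTYPE_NAMES, CTSeries, LabelMask, SubtypeLabels
from .metrics import hematoma_volume_ml
from .roi import ROIBox
from .segmentation import SegModel, cascade_predict


@dataclass
class PipelineConfig:
    """Trained models plus the few inference knobs of the cascade."""

    binary_filter: BinaryFilterModel
    stage1: SegModel
    stage2: SegModel
    multilabel: FusionModel
    filter_threshold: float = 0.5
    seg_threshold: float = 0.5
    subtype_threshold: float = 0.5
    margin: int = 20
    vote_strategy: str = "mean"

    def __post_init__(self):
        sides = {
            self.binary_filter.input_side,
            self.stage1.input_side,
            self.multilabel.input_side,
        }
        if len(sides) != 1:
            raise ValueError(
                f"checkpoints declare incompatible input resolutions: {sorted(sides)}"
            )

    @staticmethod
    def from_checkpoints(
        filter_path, stage1_path, stage2_path, multilabel_path, **kwargs
    ) -> "PipelineConfig":
        return PipelineConfig(
            binary_filter=BinaryFilterModel.load(filter_path),
            stage1=SegModel.load(stage1_path),
            stage2=SegModel.load(stage2_path),
            multilabel=FusionModel.load(multilabel_path),
            **kwargs,
        )


@dataclass
class SliceResult:
    index: int
    passed_filter: bool
    filter_probability: float
    subtype_probabilities: List[float]
    labels: SubtypeLabels
    roi: Optional[ROIBox]


@dataclass
class PatientReport:
    patient_id: str
    slices: List[SliceResult]
    scan_labels: SubtypeLabels
    volume_ml: float
    config_hash: str
    input_hash: str = ""  # sha256 over the slice stack, for provenance
    output_hash: str = ""  # sha256 over the emitted masks

    def to_dict(self) -> dict:
        return {
            "patient_id": self.patient_id,
            "volume_ml": self.volume_ml,
            "scan_labels": {n: bool(getattr(self.scan_labels, n)) for n in SUBTYPE_NAMES},
            "config_hash": self.config_hash,
            "input_hash": self.input_hash,
            "output_hash": self.output_hash,
            "slices": [
                {
                    "index": s.index,
                    "passed_filter": s.passed_filter,
                    "filter_probability": s.filter_probability,
                    "subtype_probabilities": s.subtype_probabilities,
                    "labels": {n: bool(getattr(s.labels, n)) for n in SUBTYPE_NAMES},
                    "roi": json.loads(s.roi.to_json()) if s.roi is not None else None,
                }
                for s in self.slices
            ],
        }


def _config_hash(cfg: PipelineConfig) -> str:
    h = hashlib.sha256()
    for key in (
        cfg.filter_threshold,
        cfg.seg_threshold,
        cfg.subtype_threshold,
        cfg.margin,
        cfg.vote_strategy,
    ):
        h.update(repr(key).encode())
    return h.hexdigest()[:16]


def run_pipeline(
    series: CTSeries, cfg: PipelineConfig
) -> Tuple[List[LabelMask], PatientReport]:
    """Run the full cascade over a series; returns masks and report."""
    side = cfg.stage1.input_side
    if series.slice_shape != (side, side):
        raise ValueError(
            f"series resolution {series.slice_shape} does not match the "
            f"checkpoints' {side}x{side}"
        )
    masks: List[LabelMask] = []
    slice_results: List[SliceResult] = []
    empty = LabelMask(np.zeros((side, side), dtype=np.uint8))

    for i, slc in enumerate(series.slices):
        p_filter = cfg.binary_filter.predict_proba(slc)
        if p_filter < cfg.filter_threshold:
            masks.append(empty)
            slice_results.append(
                SliceResult(i, False, p_filter, [0.0] * 5, SubtypeLabels(), None)
            )
            continue
        mask, roi = cascade_predict(
            cfg.stage1,
            cfg.stage2,
            slc,
            threshold=cfg.seg_threshold,
            margin=cfg.margin,
            vote_strategy=cfg.vote_strategy,
        )
        fusion_in = build_fusion_input(slc, mask, roi)
        labels, probs = predict_subtypes(
            cfg.multilabel, fusion_in, threshold=cfg.subtype_threshold
        )
        masks.append(mask)
        slice_results.append(
            SliceResult(i, True, p_filter, [float(p) for p in probs], labels, roi)
        )

    scan_labels = SubtypeLabels()
    for s in slice_results:
        scan_labels = scan_labels | s.labels
    report = PatientReport(
        patient_id=series.patient_id,
        slices=slice_results,
        scan_labels=scan_labels,
        volume_ml=hematoma_volume_ml(masks, series),
        config_hash=_config_hash(cfg),
        input_hash=hashlib.sha256(
            b"".join(np.ascontiguousarray(s).tobytes() for s in series.slices)
        ).hexdigest()[:16],
        output_hash=hashlib.sha256(
            b"".join(np.ascontiguousarray(m.pixels).tobytes() for m in masks)
        ).hexdigest()[:16],
    )
    return masks, report


def extract_outcome_features(report: PatientReport) -> Dict[str, float]:
    """Cohort-CSV-convention features: volume and scan-level subtypes."""
    out: Dict[str, float] = {"volume_ml": report.volume_ml}
    for n in SUBTYPE_NAMES:
        out[n] = int(getattr(report.scan_labels, n))
    return out
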