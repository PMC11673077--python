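"""File formats, detection-based frame selection, and pipeline orchestration.

Label masks travel as indexed PNGs (palette indices 0 bg, 1 PA, 2 Ao, 3 SVC).
Object-detection output uses the YOLO text dialect — one line per box,
``class cx cy w h conf`` with box coordinates normalized to the unit square —
because the upstream three-vessel detector emits it; the detector itself is
never invoked here.  ``run_pipeline`` ties selection, measurement, capping
and classification together and writes deterministic CSV/JSON reports.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from PIL import Image

from . import cohort as _cohort
from .cohort import DEFAULT_STANDARD_RANGE, RatioRecord, StandardRange
from .errors import (
    Caliper3VVError,
    FormatError,
    ParseError,
    RangeError,
    UnknownLabel,
)
from .geometry import LabelMask, MeasureConfig, as_mask, measure_frame

logger = logging.getLogger("caliper3vv")

#: 0-based codes of the three vessels in the 18-substructure detector output
DETECTION_CLASS_MAP = {"PA": 8, "Ao": 9, "SVC": 10}

#: palette for indexed label-mask PNGs (bg, PA light blue, Ao yellow, SVC red)
MASK_PALETTE = [(0, 0, 0), (120, 200, 255), (255, 220, 0), (255, 40, 40)]

RECORD_COLUMNS = [
    "case_id", "frame_id", "cohort_label", "pa_px", "ao_px", "ratio", "clipped", "group",
]


@dataclass(frozen=True)
class Detection:
    """One detected box: substructure class, normalized box, confidence."""

    class_code: int
    box: tuple[float, float, float, float]  # (cx, cy, w, h), normalized
    confidence: float
    frame_id: str
    video_id: str


@dataclass(frozen=True)
class FrameSelectionConfig:
    """Thresholds and per-video cap for three-vessel-view frame selection.

    A frame is a candidate only when PA, Ao and SVC are all detected at or
    above their class thresholds simultaneously; the PA threshold is set very
    low because pulmonary-artery confidence is the limiting detection.
    """

    thresholds: Mapping[str, float] = field(
        default_factory=lambda: {"PA": 0.001, "Ao": 0.1, "SVC": 0.01}
    )
    max_frames_per_video: Optional[int] = 2
    seed: Optional[int] = None
    class_map: Mapping[str, int] = field(default_factory=lambda: dict(DETECTION_CLASS_MAP))

    def __post_init__(self):
        for name, thr in self.thresholds.items():
            if not 0.0 <= thr <= 1.0:
                raise ValueError(f"threshold for {name} outside [0,1]: {thr}")
        if self.max_frames_per_video is not None and self.max_frames_per_video < 1:
            raise ValueError("max_frames_per_video must be >= 1")


def parse_detections(
    path, video_id: Optional[str] = None, frame_id: Optional[str] = None
) -> list[Detection]:
    """Parse one YOLO-dialect detection file.

    Lines are ``class cx cy w h conf`` (whitespace-separated, normalized).
    Unless given, video and frame ids are taken from the filename stem
    ``{video_id}_{frame_id}``.  Malformed lines raise ParseError with the
    line number; values outside the unit interval raise RangeError.
    """
    path = Path(path)
    if video_id is None or frame_id is None:
        stem = path.stem
        if "_" in stem:
            vid, fid = stem.rsplit("_", 1)
        else:
            vid, fid = stem, "0"
        video_id = video_id or vid
        frame_id = frame_id or fid
    detections: list[Detection] = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) != 6:
                raise ParseError(path, line_no, f"expected 6 fields, got {len(fields)}")
            try:
                code = int(fields[0])
                cx, cy, w, h, conf = (float(v) for v in fields[1:])
            except ValueError as exc:
                raise ParseError(path, line_no, f"non-numeric field: {exc}") from None
            for name, val in zip(("cx", "cy", "w", "h"), (cx, cy, w, h)):
                if not 0.0 <= val <= 1.0:
                    raise RangeError(path, line_no, f"{name}={val} outside [0,1]")
            if not 0.0 <= conf <= 1.0:
                raise RangeError(path, line_no, f"confidence {conf} outside [0,1]")
            detections.append(
                Detection(
                    class_code=code,
                    box=(cx, cy, w, h),
                    confidence=conf,
                    frame_id=frame_id,
                    video_id=video_id,
                )
            )
    return detections


def frame_is_candidate(
    frame_detections: Sequence[Detection], config: FrameSelectionConfig
) -> bool:
    """All three vessels detected at or above their class thresholds."""
    for vessel, code in config.class_map.items():
        thr = config.thresholds.get(vessel)
        if thr is None:
            continue
        if not any(d.class_code == code and d.confidence >= thr for d in frame_detections):
            return False
    return True


def select_3vv_frames(
    detections: Iterable[Detection], config: FrameSelectionConfig | None = None
) -> dict[str, list[str]]:
    """Choose up to ``max_frames_per_video`` candidate frames per video.

    Candidates are drawn uniformly without replacement with the configured
    seed, so selection is reproducible; videos without candidates yield an
    empty list (logged).
    """
    config = config or FrameSelectionConfig()
    by_video_frame: dict[str, dict[str, list[Detection]]] = {}
    for det in detections:
        by_video_frame.setdefault(det.video_id, {}).setdefault(det.frame_id, []).append(det)
    rng = np.random.default_rng(config.seed)
    selected: dict[str, list[str]] = {}
    for video_id in sorted(by_video_frame):
        frames = by_video_frame[video_id]
        candidates = [fid for fid in sorted(frames) if frame_is_candidate(frames[fid], config)]
        if not candidates:
            logger.info("video %s: no 3VV candidate frames", video_id)
            selected[video_id] = []
            continue
        k = len(candidates)
        if config.max_frames_per_video is not None:
            k = min(k, config.max_frames_per_video)
        picks = rng.choice(len(candidates), size=k, replace=False)
        selected[video_id] = [candidates[i] for i in sorted(picks)]
    return selected


def write_label_mask(mask, path) -> None:
    """Write a label mask as an indexed (palette) PNG; round-trip bit-exact."""
    m = as_mask(mask)
    img = Image.fromarray(m.grid.astype(np.uint8), mode="P")
    palette = []
    for rgb in MASK_PALETTE:
        palette.extend(rgb)
    img.putpalette(palette)
    img.save(Path(path), format="PNG")


def read_label_mask(path, remap: Mapping[int, int] | None = None) -> LabelMask:
    """Read an indexed PNG into a LabelMask.

    ``remap`` translates foreign palette indices to the 0-3 alphabet;
    unmapped indices above 3 raise UnknownLabel.
    """
    path = Path(path)
    try:
        img = Image.open(path)
    except Exception as exc:
        raise FormatError(f"cannot read {path}: {exc}") from None
    if img.mode not in ("P", "L"):
        raise FormatError(f"{path}: expected an indexed (or 8-bit) PNG, got mode {img.mode}")
    grid = np.asarray(img, dtype=np.int64)
    if remap:
        for src, dst in remap.items():
            grid[grid == src] = dst
    bad = np.unique(grid[(grid < 0) | (grid > 3)])
    if bad.size:
        raise UnknownLabel(f"{path}: unmapped label indices {bad.tolist()}")
    return LabelMask(grid)


@dataclass(frozen=True)
class PipelineConfig:
    """Resolved configuration echoed into every pipeline report."""

    measure: MeasureConfig = field(default_factory=MeasureConfig)
    standard_range: StandardRange = DEFAULT_STANDARD_RANGE
    seed: int = 0

    def to_dict(self) -> dict:
        return {
            "measure": dataclasses.asdict(self.measure),
            "standard_range": dataclasses.asdict(self.standard_range),
            "seed": self.seed,
        }


@dataclass
class PipelineReport:
    """Outcome of a batch run: classified records, failures, summary."""

    records: list[RatioRecord]
    failures: list[dict]
    config: PipelineConfig

    def summary(self) -> dict:
        group_counts = {g: 0 for g in _cohort.GROUPS}
        for rec in self.records:
            group_counts[rec.group] += 1
        return {
            "n_cases": len(self.records) + len(self.failures),
            "n_measured": len(self.records),
            "n_failed": len(self.failures),
            "group_counts": group_counts,
            "failures": self.failures,
            "config": self.config.to_dict(),
        }

    def to_frame(self) -> pd.DataFrame:
        rows = [dataclasses.asdict(r) for r in self.records]
        return pd.DataFrame(rows, columns=RECORD_COLUMNS)


def write_records_csv(records: Iterable[RatioRecord], path) -> None:
    rows = [dataclasses.asdict(r) for r in records]
    df = pd.DataFrame(rows, columns=RECORD_COLUMNS)
    df.to_csv(Path(path), index=False, float_format="%.6f")


def read_records_csv(path) -> list[RatioRecord]:
    df = pd.read_csv(Path(path))
    records = []
    for row in df.itertuples(index=False):
        records.append(
            RatioRecord(
                case_id=str(row.case_id),
                frame_id=str(row.frame_id),
                cohort_label=str(row.cohort_label),
                pa_px=float(row.pa_px),
                ao_px=float(row.ao_px),
                ratio=float(row.ratio),
                clipped=bool(row.clipped),
                group=None if pd.isna(row.group) else str(row.group),
            )
        )
    return records


def run_pipeline(
    cases: Iterable[tuple[str, str, LabelMask]],
    config: PipelineConfig | None = None,
    labels: Mapping[str, str] | None = None,
    out_dir=None,
) -> PipelineReport:
    """Measure, cap and classify a batch of label masks.

    ``cases`` yields (case_id, frame_id, mask) triples; ``labels`` optionally
    maps case ids to their cohort label (default "normal").  Per-case errors
    are collected without aborting the batch; the batch fails (raises) only
    if no case succeeds.  With ``out_dir`` set, a records CSV and a JSON
    summary (full config echo included) are written; outputs are functions
    of the inputs, config and seed only, so reruns are byte-identical.
    """
    config = config or PipelineConfig()
    records: list[RatioRecord] = []
    failures: list[dict] = []
    n_seen = 0
    for case_id, frame_id, mask in cases:
        n_seen += 1
        try:
            fm = measure_frame(mask, config.measure)
        except Caliper3VVError as exc:
            logger.warning("case %s/%s failed: %s", case_id, frame_id, exc)
            failures.append(
                {"case_id": case_id, "frame_id": frame_id,
                 "error": type(exc).__name__, "message": str(exc)}
            )
            continue
        rec = RatioRecord(
            case_id=case_id,
            frame_id=frame_id,
            cohort_label=(labels or {}).get(case_id, "normal"),
            pa_px=fm.pa_px,
            ao_px=fm.ao_px,
            ratio=fm.ratio,
            clipped=fm.clipped,
        ).classified(config.standard_range)
        records.append(rec)
    if n_seen and not records:
        raise Caliper3VVError("no case in the batch could be measured")
    report = PipelineReport(records=records, failures=failures, config=config)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_records_csv(records, out_dir / "records.csv")
        with open(out_dir / "summary.json", "w") as fh:
            json.dump(report.summary(), fh, indent=2, sort_keys=True)
            fh.write("\n")
    return report
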