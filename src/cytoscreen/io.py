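"""Plain-text interchange formats: detection tables, manifests, features.

A real detector's output can be ingested unchanged as a CSV with
columns (slide_id, grade, confidence, x0, y0, x1, y1, epithelium_score)
or the equivalent JSON records.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Union

import pandas as pd

from .core import SlideGrade, SlideRecord
from .detection import PatchDetection, SlideDetectionSet

DETECTION_COLUMNS = [
    "slide_id",
    "grade",
    "confidence",
    "x0",
    "y0",
    "x1",
    "y1",
    "epithelium_score",
]


def detections_to_frame(slides: Sequence[SlideDetectionSet]) -> pd.DataFrame:
    rows = []
    for ds in slides:
        for det in ds:
            rows.append(
                {
                    "slide_id": ds.slide.slide_id,
                    "grade": det.grade.value,
                    "confidence": det.confidence,
                    "x0": det.box[0],
                    "y0": det.box[1],
                    "x1": det.box[2],
                    "y1": det.box[3],
                    "epithelium_score": det.epithelium_score,
                }
            )
    return pd.DataFrame(rows, columns=DETECTION_COLUMNS)


def write_detections_csv(slides: Sequence[SlideDetectionSet], path: Union[str, Path]) -> None:
    detections_to_frame(slides).to_csv(path, index=False)


def write_detections_json(slides: Sequence[SlideDetectionSet], path: Union[str, Path]) -> None:
    records = detections_to_frame(slides).to_dict(orient="records")
    Path(path).write_text(json.dumps(records, indent=2))


def read_detections(
    path: Union[str, Path],
    slide_records: Optional[Dict[str, SlideRecord]] = None,
    default_slide_px: int = 20000,
) -> List[SlideDetectionSet]:
    """Load a detection table (CSV or JSON) into per-slide sets.

    Unknown slides get a placeholder :class:`SlideRecord` sized
    ``default_slide_px`` unless ``slide_records`` supplies metadata.
    """
    p = Path(path)
    if p.suffix.lower() == ".json":
        frame = pd.DataFrame(json.loads(p.read_text()))
    else:
        frame = pd.read_csv(p)
    missing = set(DETECTION_COLUMNS) - set(frame.columns)
    if missing - {"epithelium_score"}:
        raise ValueError(f"detection table missing columns: {sorted(missing)}")
    if "epithelium_score" not in frame.columns:
        frame["epithelium_score"] = 1.0

    out: List[SlideDetectionSet] = []
    for slide_id, group in frame.groupby("slide_id", sort=True):
        if slide_records and str(slide_id) in slide_records:
            record = slide_records[str(slide_id)]
        else:
            record = SlideRecord(
                slide_id=str(slide_id),
                width_px=default_slide_px,
                height_px=default_slide_px,
            )
        dets = [
            PatchDetection(
                grade=row.grade,
                confidence=float(row.confidence),
                box=(float(row.x0), float(row.y0), float(row.x1), float(row.y1)),
                epithelium_score=float(row.epithelium_score),
            )
            for row in group.itertuples()
        ]
        out.append(SlideDetectionSet(slide=record, detections=dets))
    return out


def write_manifest_csv(
    slides: Sequence[SlideDetectionSet],
    truths: Sequence[SlideGrade],
    path: Union[str, Path],
) -> None:
    """Slide manifest: id, dimensions, pixel size and true grade."""
    rows = [
        {
            "slide_id": ds.slide.slide_id,
            "width_px": ds.slide.width_px,
            "height_px": ds.slide.height_px,
            "pixel_size_um": ds.slide.pixel_size_um,
            "true_grade": g.value,
        }
        for ds, g in zip(slides, truths)
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_manifest_csv(path: Union[str, Path]) -> pd.DataFrame:
    frame = pd.read_csv(path)
    required = {"slide_id", "true_grade"}
    if required - set(frame.columns):
        raise ValueError(f"manifest missing columns: {sorted(required - set(frame.columns))}")
    return frame
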