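"""File formats: 8-bit grayscale PNG frames, JSON annotations, CSV results."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .echogenicity import AnnotationSet, EchogenicityResult, UltrasoundFrame

RESULT_COLUMNS = [
    "frame_id", "observer_id", "n_pixels",
    "gsm_min", "gsm_max", "gsm_mean", "gsm_median",
]


def read_frame(path) -> UltrasoundFrame:
    path = Path(path)
    img = Image.open(path).convert("L")
    return UltrasoundFrame(pixels=np.asarray(img, dtype=np.uint8),
                           frame_id=path.stem)


def write_frame(frame: UltrasoundFrame, path) -> None:
    Image.fromarray(frame.pixels.astype(np.uint8), mode="L").save(path)


def read_annotation(path) -> AnnotationSet:
    """One JSON file per frame: named polygons plus observer id."""
    payload = json.loads(Path(path).read_text())
    polys = payload["polygons"]
    return AnnotationSet(
        frame_id=payload.get("frame_id", Path(path).stem),
        observer_id=payload.get("observer_id", ""),
        plaque_polygon=polys["plaque"],
        lumen_region=polys["lumen"],
        adventitia_region=polys["adventitia"],
    )


def write_annotation(annotation: AnnotationSet, path) -> None:
    payload = {
        "frame_id": annotation.frame_id,
        "observer_id": annotation.observer_id,
        "polygons": {
            "plaque": np.asarray(annotation.plaque_polygon).tolist(),
            "lumen": np.asarray(annotation.lumen_region).tolist(),
            "adventitia": np.asarray(annotation.adventitia_region).tolist(),
        },
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def results_to_frame(results) -> pd.DataFrame:
    rows = [
        {c: getattr(r, c) for c in RESULT_COLUMNS}
        for r in results
    ]
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


def write_results(results, path) -> None:
    results_to_frame(results).to_csv(path, index=False)


def read_results(path):
    df = pd.read_csv(path)
    return [EchogenicityResult(
        frame_id=row.frame_id, observer_id=row.observer_id,
        gsm_min=row.gsm_min, gsm_max=row.gsm_max,
        gsm_mean=row.gsm_mean, gsm_median=row.gsm_median,
        n_pixels=int(row.n_pixels),
    ) for row in df.itertuples()]
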