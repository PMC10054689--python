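"""Plaque echogenicity from annotated B-mode ultrasound frames.

The gray-scale median (GSM) workflow: rasterize the manually outlined
plaque / lumen / adventitia polygons, normalize frame brightness with the
vessel lumen anchored at gray value 0 and the adventitia at 190, then
summarize the normalized plaque pixels (min / max / mean / median).  The
per-participant outcome is the flat mean over all plaque x observer
measurements.  Interobserver agreement is quantified on a random
participant subsample with a two-way single-measurement ICC (absolute
agreement) plus Bland-Altman style limits of agreement.

Coordinate convention: 0-based row-major pixel grid, origin at the
top-left corner; the pixel at (row r, column c) has its center at
cartesian point (x, y) = (c + 0.5, r + 0.5).  Point-in-polygon membership
uses the even-odd (crossing-number) rule evaluated at pixel centers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import (
    DegeneratePolygonError,
    EmptyRegionError,
    InsufficientDataError,
    NonDiscriminatingReferencesError,
)

#: Normalized gray value assigned to the lumen (darkness) reference.
LUMEN_ANCHOR = 0
#: Normalized gray value assigned to the adventitia (brightness) reference.
ADVENTITIA_ANCHOR = 190


@dataclass
class UltrasoundFrame:
    """8-bit grayscale raster.

    Attributes
    ----------
    pixels : (height, width) uint8 array of gray values in [0, 255].
    frame_id : identifier used to join against annotations.
    """

    pixels: np.ndarray
    frame_id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError("frame pixels must be a 2-D array")
        h, w = self.pixels.shape
        if h < 16 or w < 16:
            raise ValueError("frame must be at least 16x16 pixels")
        if self.pixels.min() < 0 or self.pixels.max() > 255:
            raise ValueError("pixel values must lie in [0, 255]")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass
class AnnotationSet:
    """One observer's polygons for one frame.

    Polygons are sequences of (x, y) vertices in pixel coordinates.
    """

    frame_id: str
    observer_id: str
    plaque_polygon: Sequence[Sequence[float]]
    lumen_region: Sequence[Sequence[float]]
    adventitia_region: Sequence[Sequence[float]]


@dataclass
class EchogenicityResult:
    """Normalized gray-scale statistics of one plaque segmentation."""

    frame_id: str
    observer_id: str
    gsm_min: float
    gsm_max: float
    gsm_mean: float
    gsm_median: float
    n_pixels: int


@dataclass
class ParticipantGSM:
    """Per-participant echogenicity outcome (mean over measurements)."""

    participant_id: str
    gsm: float
    n_measurements: int


@dataclass
class AgreementReport:
    """Interobserver agreement summary for paired measurements."""

    icc: float
    mean_difference: float
    sd_difference: float
    loa_lower: float
    loa_upper: float
    n_pairs: int
    outlier_indices: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# geometry


def rasterize_polygon(polygon, frame_dims) -> np.ndarray:
    """Boolean mask of pixels whose centers fall inside ``polygon``.

    Membership follows the even-odd rule: a pixel center is inside if a
    ray cast in +x direction crosses the polygon boundary an odd number
    of times.  Works for convex, concave and self-intersecting outlines.

    Parameters
    ----------
    polygon : sequence of (x, y) vertices (at least 3).
    frame_dims : (height, width) of the target grid.

    Raises
    ------
    DegeneratePolygonError : fewer than 3 vertices.
    EmptyRegionError : no pixel center falls inside.
    """
    verts = np.asarray(polygon, dtype=float)
    if verts.ndim != 2 or verts.shape[0] < 3 or verts.shape[1] != 2:
        raise DegeneratePolygonError(
            f"polygon needs >=3 (x, y) vertices, got shape {verts.shape}"
        )
    h, w = frame_dims
    # pixel centers
    xs = np.arange(w) + 0.5
    ys = np.arange(h) + 0.5
    X, Y = np.meshgrid(xs, ys)

    crossings = np.zeros((h, w), dtype=np.int64)
    x1, y1 = verts[:, 0], verts[:, 1]
    x2, y2 = np.roll(x1, -1), np.roll(y1, -1)
    for ax, ay, bx, by in zip(x1, y1, x2, y2):
        if ay == by:  # horizontal edge never crosses a horizontal ray
            continue
        straddles = (ay > Y) != (by > Y)
        with np.errstate(invalid="ignore"):
            x_int = ax + (Y - ay) * (bx - ax) / (by - ay)
        crossings += straddles & (X < x_int)
    mask = (crossings % 2).astype(bool)
    if not mask.any():
        raise EmptyRegionError("polygon encloses no pixel centers")
    return mask


def crop_to_roi(frame: UltrasoundFrame, mask: np.ndarray):
    """Crop ``frame`` to the minimal bounding box of ``mask``.

    Returns ``(cropped_pixels, cropped_mask, (row_offset, col_offset))``
    so that cropped coordinates plus the offset recover frame coordinates.
    """
    if not np.asarray(mask).any():
        raise EmptyRegionError("cannot crop to an empty mask")
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    r0, r1 = rows[0], rows[-1] + 1
    c0, c1 = cols[0], cols[-1] + 1
    return frame.pixels[r0:r1, c0:c1], mask[r0:r1, c0:c1], (int(r0), int(c0))


# ---------------------------------------------------------------------------
# intensity processing


def denoise(frame: UltrasoundFrame) -> UltrasoundFrame:
    """Single-pass 3x3 median filter with reflected borders."""
    filtered = ndimage.median_filter(frame.pixels, size=3, mode="reflect")
    return UltrasoundFrame(pixels=filtered, frame_id=frame.frame_id)


def normalize_brightness(
    frame: UltrasoundFrame, annotation: AnnotationSet
) -> UltrasoundFrame:
    """Two-point linear brightness normalization.

    The median gray value L of the lumen region is mapped to 0 and the
    median A of the adventitia region to 190:

        g' = clip(round(190 * (g - L) / (A - L)), 0, 255)

    with round-half-up.  Raises NonDiscriminatingReferencesError when
    A <= L, which indicates a bad annotation.
    """
    dims = (frame.height, frame.width)
    lumen_mask = rasterize_polygon(annotation.lumen_region, dims)
    adv_mask = rasterize_polygon(annotation.adventitia_region, dims)
    lum = float(np.median(frame.pixels[lumen_mask]))
    adv = float(np.median(frame.pixels[adv_mask]))
    if adv <= lum:
        raise NonDiscriminatingReferencesError(
            f"adventitia median ({adv}) must exceed lumen median ({lum})"
        )
    scaled = ADVENTITIA_ANCHOR * (frame.pixels.astype(float) - lum) / (adv - lum)
    out = np.clip(np.floor(scaled + 0.5), 0, 255).astype(np.uint8)
    return UltrasoundFrame(pixels=out, frame_id=frame.frame_id)


def compute_gsm_stats(
    normalized_frame: UltrasoundFrame,
    plaque_mask: np.ndarray,
    frame_id: str = "",
    observer_id: str = "",
) -> EchogenicityResult:
    """Min / max / mean / median of normalized gray values under the mask."""
    values = normalized_frame.pixels[np.asarray(plaque_mask, dtype=bool)]
    if values.size == 0:
        raise EmptyRegionError("plaque mask selects no pixels")
    return EchogenicityResult(
        frame_id=frame_id or normalized_frame.frame_id,
        observer_id=observer_id,
        gsm_min=float(values.min()),
        gsm_max=float(values.max()),
        gsm_mean=float(values.mean()),
        gsm_median=float(np.median(values)),
        n_pixels=int(values.size),
    )


def measure_frame(
    frame: UltrasoundFrame,
    annotation: AnnotationSet,
    apply_denoise: bool = True,
    denoise_before_normalize: bool = True,
) -> EchogenicityResult:
    """Full single-frame pipeline: (denoise) -> normalize -> statistics."""
    work = frame
    if apply_denoise and denoise_before_normalize:
        work = denoise(work)
    normalized = normalize_brightness(work, annotation)
    if apply_denoise and not denoise_before_normalize:
        normalized = denoise(normalized)
    mask = rasterize_polygon(
        annotation.plaque_polygon, (frame.height, frame.width)
    )
    return compute_gsm_stats(normalized, mask, frame.frame_id, annotation.observer_id)


# ---------------------------------------------------------------------------
# participant aggregation and agreement


def aggregate_participant(
    participant_id: str,
    results: Iterable[EchogenicityResult],
    statistic: str = "gsm_mean",
    per_plaque_first: bool = False,
) -> ParticipantGSM:
    """Participant-level GSM: mean of the chosen per-plaque statistic.

    By default every plaque x observer measurement contributes once to a
    flat arithmetic mean.  With ``per_plaque_first=True`` measurements of
    the same frame are averaged across observers before the plaque-level
    means are averaged.
    """
    results = list(results)
    if not results:
        raise InsufficientDataError(
            f"participant {participant_id!r} has no echogenicity measurements"
        )
    values = pd.Series(
        [getattr(r, statistic) for r in results],
        index=[r.frame_id for r in results],
        dtype=float,
    )
    if per_plaque_first:
        gsm = float(values.groupby(level=0).mean().mean())
    else:
        gsm = float(values.mean())
    return ParticipantGSM(
        participant_id=participant_id, gsm=gsm, n_measurements=len(results)
    )


def interobserver_subsample(participant_ids, fraction: float = 0.05, seed=None):
    """Reproducible simple random sample of ceil(fraction * n) participants."""
    ids = list(participant_ids)
    if not ids:
        raise InsufficientDataError("no participant ids to sample from")
    if not 0 < fraction <= 1:
        raise ValueError("fraction must lie in (0, 1]")
    k = int(np.ceil(fraction * len(ids)))
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(ids), size=k, replace=False)
    return [ids[i] for i in sorted(chosen)]


def interobserver_agreement(
    first: Sequence[float], second: Sequence[float], outlier_k: float = 3.0
) -> AgreementReport:
    """Agreement between two observers' paired GSM measurements.

    Reports the two-way random-effects single-measurement ICC with
    absolute agreement (ICC(2,1)), the mean paired difference with its
    SD, 95% limits of agreement, and indices of pairs whose difference
    deviates from the mean difference by more than ``outlier_k`` SDs
    (candidates for remeasurement).
    """
    a = np.asarray(first, dtype=float)
    b = np.asarray(second, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired measurements must be equal-length 1-D arrays")
    n = a.size
    if n < 2:
        raise InsufficientDataError("need at least 2 pairs for agreement")

    import pingouin as pg  # deferred: heavy import

    long = pd.DataFrame(
        {
            "target": np.tile(np.arange(n), 2),
            "rater": np.repeat(["obs1", "obs2"], n),
            "score": np.concatenate([a, b]),
        }
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        icc_table = pg.intraclass_corr(
            data=long, targets="target", raters="rater", ratings="score"
        )
    icc = float(icc_table.set_index("Type").loc["ICC(A,1)", "ICC"])
    if not np.isfinite(icc):
        # zero residual variance (perfect agreement) yields 0/0 upstream
        icc = 1.0 if np.allclose(a, b) and np.var(a) > 0 else np.nan

    diff = a - b
    mean_d = float(diff.mean())
    sd_d = float(diff.std(ddof=1))
    if sd_d > 0:
        outliers = np.flatnonzero(np.abs(diff - mean_d) > outlier_k * sd_d)
    else:
        outliers = np.array([], dtype=int)
    return AgreementReport(
        icc=icc,
        mean_difference=mean_d,
        sd_difference=sd_d,
        loa_lower=mean_d - 1.96 * sd_d,
        loa_upper=mean_d + 1.96 * sd_d,
        n_pairs=n,
        outlier_indices=outliers.tolist(),
    )
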