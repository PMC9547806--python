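"""Neuromuscular-junction morphometry from multichannel muscle-section images.

The junction is delineated from the presynaptic-marker channel (SV2A): the
same entropy threshold used by the cluster pipeline, morphological closing,
and a minimum-area filter yield labelled junction masks.  Within each mask
the receptor content is reported as the ratio of mean receptor-label (α-BTX)
intensity to mean SV2A intensity — mean, not integrated, so the ratio is
invariant to mask area — and complement deposition as the mean C3 intensity.
Fragmentation of the receptor-positive area is quantified as the number,
area and mean fluorescence of 8-connected receptor-label objects after
background reduction and entropy thresholding.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import measure, morphology

from .errors import DegenerateHistogramError, InvalidArgumentError
from .clusters import project_stack, subtract_background
from .threshold import threshold_image

DEFAULT_MIN_AREA_UM2 = 20.0
DEFAULT_CLOSING_RADIUS = 3


def delineate_nmj(
    sv2a_frame: np.ndarray,
    pixel_size: float,
    min_area_um2: float = DEFAULT_MIN_AREA_UM2,
    closing_radius: int = DEFAULT_CLOSING_RADIUS,
    method: str = "sahoo_combined",
    rho: float = 1.0,
) -> np.ndarray:
    """Label junction regions in the presynaptic-marker channel.

    Entropy threshold -> morphological closing -> removal of components below
    ``min_area_um2``.  A blank/flat image yields an all-zero label image.
    """
    if pixel_size <= 0:
        raise InvalidArgumentError("pixel_size must be > 0")
    sv2a_frame = np.asarray(sv2a_frame)
    try:
        thr = threshold_image(sv2a_frame, method=method, rho=rho)
    except DegenerateHistogramError:
        return np.zeros(sv2a_frame.shape, dtype=np.int32)
    mask = sv2a_frame > thr
    if closing_radius and closing_radius > 0:
        mask = morphology.closing(mask, morphology.disk(closing_radius))
    min_px = int(np.ceil(min_area_um2 / pixel_size**2))
    labels = measure.label(mask, connectivity=2)
    out = np.zeros_like(labels, dtype=np.int32)
    next_id = 1
    for region in measure.regionprops(labels):
        if region.area >= min_px:
            out[labels == region.label] = next_id
            next_id += 1
    return out


@dataclass(frozen=True)
class NMJRecord:
    """Morphometry of one labelled junction."""

    nmj_id: int
    area_um2: float
    btx_sv2a_ratio: float
    c3_mean_intensity: float
    animal_id: str = ""
    group: str = ""


def _median_background(frame: np.ndarray, labels: np.ndarray) -> float:
    outside = frame[labels == 0]
    return float(np.median(outside)) if outside.size else 0.0


def achr_content(
    btx_frame: np.ndarray,
    sv2a_frame: np.ndarray,
    masks: np.ndarray,
    subtract_channel_background: bool = True,
) -> pd.DataFrame:
    """Receptor retention per junction: mean BTX / mean SV2A within each mask.

    Channels must be co-registered and the same shape.  By default the
    per-channel median of non-junction pixels is subtracted before ratioing
    (disable with ``subtract_channel_background=False``).  A junction with no
    SV2A signal yields NaN with a warning.
    """
    btx_frame = np.asarray(btx_frame, dtype=float)
    sv2a_frame = np.asarray(sv2a_frame, dtype=float)
    if btx_frame.shape != sv2a_frame.shape or btx_frame.shape != masks.shape:
        raise InvalidArgumentError("frames and masks must share a shape")
    if subtract_channel_background:
        btx_frame = btx_frame - _median_background(btx_frame, masks)
        sv2a_frame = sv2a_frame - _median_background(sv2a_frame, masks)
    rows = []
    for nmj_id in np.unique(masks[masks > 0]):
        sel = masks == nmj_id
        denom = float(sv2a_frame[sel].mean())
        if denom <= 0:
            warnings.warn(f"junction {nmj_id}: no SV2A signal; ratio undefined")
            ratio = float("nan")
        else:
            ratio = float(btx_frame[sel].mean()) / denom
        rows.append({"nmj_id": int(nmj_id), "btx_sv2a_ratio": ratio,
                     "n_pixels": int(sel.sum())})
    return pd.DataFrame(rows, columns=["nmj_id", "btx_sv2a_ratio", "n_pixels"])


def c3_at_nmj(c3_frame: np.ndarray, masks: np.ndarray) -> pd.DataFrame:
    """Mean complement-deposit intensity within each junction mask."""
    c3_frame = np.asarray(c3_frame, dtype=float)
    if c3_frame.shape != masks.shape:
        raise InvalidArgumentError("frame and masks must share a shape")
    rows = [
        {"nmj_id": int(i), "c3_mean_intensity": float(c3_frame[masks == i].mean())}
        for i in np.unique(masks[masks > 0])
    ]
    return pd.DataFrame(rows, columns=["nmj_id", "c3_mean_intensity"])


@dataclass(frozen=True)
class FragmentationResult:
    """Receptor-positive objects within one junction region."""

    nmj_id: int
    n_fragments: int
    fragment_areas_um2: tuple[float, ...]
    total_area_um2: float
    mean_fluorescence: float

    def __post_init__(self) -> None:
        assert self.n_fragments == len(self.fragment_areas_um2)


def fragmentation_analysis(
    btx_stack: np.ndarray,
    pixel_size: float,
    nmj_labels: np.ndarray | None = None,
    background_radius: int | None = None,
    threshold: float | None = None,
    method: str = "sahoo_combined",
    rho: float = 1.0,
    bbox_margin_px: int = 5,
    min_fragment_area_um2: float = 0.2,
) -> list[FragmentationResult]:
    """Count and measure receptor-label fragments.

    ``btx_stack`` may be a Z-stack (projected by per-pixel maximum) or a
    single frame.  After optional background reduction and entropy
    thresholding, 8-connected objects are counted — within the (margin-padded)
    bounding box of each junction label when ``nmj_labels`` is given,
    otherwise over the whole frame as a single region (``nmj_id = 1``).
    Objects below ``min_fragment_area_um2`` are treated as shot-noise speckle
    and discarded (set to 0 to keep everything).
    """
    if pixel_size <= 0:
        raise InvalidArgumentError("pixel_size must be > 0")
    frame = project_stack(np.asarray(btx_stack))
    work = subtract_background(frame, background_radius) if background_radius \
        else frame.astype(float)
    if threshold is None:
        try:
            threshold = threshold_image(work, method=method, rho=rho)
        except DegenerateHistogramError:
            threshold = float("inf")
    mask = work > threshold
    px2 = pixel_size**2

    regions: list[tuple[int, tuple[slice, slice]]] = []
    if nmj_labels is None:
        regions.append((1, (slice(None), slice(None))))
    else:
        for region in measure.regionprops(np.asarray(nmj_labels)):
            r0, c0, r1, c1 = region.bbox
            m = bbox_margin_px
            sl = (slice(max(r0 - m, 0), min(r1 + m, frame.shape[0])),
                  slice(max(c0 - m, 0), min(c1 + m, frame.shape[1])))
            regions.append((int(region.label), sl))

    out: list[FragmentationResult] = []
    for nmj_id, sl in regions:
        sub_mask = mask[sl]
        labels = measure.label(sub_mask, connectivity=2)
        kept = [r for r in measure.regionprops(labels)
                if r.area * px2 >= min_fragment_area_um2]
        areas = tuple(float(r.area) * px2 for r in kept)
        keep_mask = np.isin(labels, [r.label for r in kept])
        fluor = float(np.asarray(frame, dtype=float)[sl][keep_mask].mean()) \
            if keep_mask.any() else float("nan")
        sub_mask = keep_mask
        out.append(
            FragmentationResult(
                nmj_id=nmj_id,
                n_fragments=len(areas),
                fragment_areas_um2=areas,
                total_area_um2=float(sum(areas)),
                mean_fluorescence=fluor,
            )
        )
    return out


def summarize_per_animal(
    records: pd.DataFrame,
    group_cols: tuple[str, ...] = ("animal_id",),
) -> pd.DataFrame:
    """Per-animal means of every numeric metric, in long format.

    Each record must carry the grouping columns (``animal_id`` at minimum);
    the output has one row per animal x metric with the mean value and the
    number of junctions contributing.
    """
    if not isinstance(records, pd.DataFrame) or records.empty:
        raise InvalidArgumentError("records must be a non-empty DataFrame")
    for col in group_cols:
        if col not in records.columns:
            raise InvalidArgumentError(f"records lack grouping column {col!r}")
        if records[col].isna().any():
            raise InvalidArgumentError(f"missing values in grouping column {col!r}")
    value_cols = [
        c for c in records.columns
        if c not in group_cols and c != "nmj_id" and pd.api.types.is_numeric_dtype(records[c])
    ]
    grouped = records.groupby(list(group_cols), sort=True)
    long = (
        grouped[value_cols]
        .mean()
        .reset_index()
        .melt(id_vars=list(group_cols), var_name="metric", value_name="mean")
    )
    counts = grouped.size().rename("n_records").reset_index()
    return long.merge(counts, on=list(group_cols))
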