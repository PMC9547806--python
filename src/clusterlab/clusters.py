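"""Live-cell receptor-cluster quantification.

Pipeline, per time point: maximum-intensity projection of the acquired
Z-planes, optional background reduction, automatic entropy thresholding of
the receptor-label channel, 8-connected component labelling, and a size
filter keeping components of 0.8-10.0 square micrometres ("clusters").
Per-frame totals (count, total area, mean area) are summarised as growth
rates: ordinary-least-squares slopes of each metric against time on the
post-antibody-addition segment, with pre-addition slopes reported as a
baseline control.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from skimage import measure

from .errors import (
    DegenerateHistogramError,
    InsufficientDataError,
    InvalidArgumentError,
)
from .synth import ImageStack
from .threshold import threshold_image

DEFAULT_AREA_MIN = 0.8   # square micrometres
DEFAULT_AREA_MAX = 10.0


def project_stack(zstack: np.ndarray) -> np.ndarray:
    """Maximum-intensity projection across the leading (plane) axis."""
    zstack = np.asarray(zstack)
    if zstack.ndim < 2 or zstack.shape[0] < 1:
        raise InvalidArgumentError("need at least one plane")
    if zstack.ndim == 2:
        return zstack
    return zstack.max(axis=0)


def subtract_background(frame: np.ndarray, radius: int = 50) -> np.ndarray:
    """Rolling-ball-style background reduction.

    The background is estimated by a grey-level morphological opening with a
    flat square structuring element of side ``2 * radius + 1`` and subtracted,
    so structures smaller than the footprint survive on a near-zero baseline.
    """
    if radius < 1:
        raise InvalidArgumentError("radius must be >= 1")
    frame = np.asarray(frame, dtype=float)
    size = 2 * radius + 1
    background = ndimage.grey_opening(frame, size=(size, size), mode="nearest")
    return frame - background


@dataclass(frozen=True)
class ClusterRecord:
    """One size-filtered connected component."""

    label: int
    area_um2: float
    centroid_xy: tuple[float, float]   # (x, y) in pixels, 0-based
    mean_intensity: float
    frame_index: int = 0


def segment_clusters(
    frame: np.ndarray,
    pixel_size: float,
    threshold: float | None = None,
    area_min: float = DEFAULT_AREA_MIN,
    area_max: float = DEFAULT_AREA_MAX,
    background_radius: int | None = None,
    method: str = "sahoo_combined",
    rho: float = 1.0,
    frame_index: int = 0,
) -> list[ClusterRecord]:
    """Extract clusters from a single 2-D frame.

    Pixels strictly above ``threshold`` (auto-selected by the entropy method
    when ``None``) are labelled by 8-connectivity; components whose pixel area
    falls inside ``[area_min, area_max]`` square micrometres are returned.
    A blank or flat frame yields an empty list, not an error.
    """
    if pixel_size <= 0:
        raise InvalidArgumentError("pixel_size must be > 0")
    if not area_min < area_max:
        raise InvalidArgumentError("area_min must be < area_max")
    frame = np.asarray(frame)
    work = subtract_background(frame, background_radius) if background_radius else \
        frame.astype(float)
    if threshold is None:
        try:
            threshold = threshold_image(work, method=method, rho=rho)
        except DegenerateHistogramError:
            return []
    mask = work > threshold
    labels = measure.label(mask, connectivity=2)
    out: list[ClusterRecord] = []
    px2 = pixel_size**2
    for region in measure.regionprops(labels, intensity_image=np.asarray(frame, dtype=float)):
        area = region.area * px2
        if area_min <= area <= area_max:
            cy, cx = region.centroid
            out.append(
                ClusterRecord(
                    label=region.label,
                    area_um2=float(area),
                    centroid_xy=(float(cx), float(cy)),
                    mean_intensity=float(region.intensity_mean),
                    frame_index=frame_index,
                )
            )
    return out


@dataclass(frozen=True)
class FrameMetrics:
    """Per-frame cluster population summary."""

    frame_time: float
    n_clusters: int
    total_area_um2: float
    mean_area_um2: float       # NaN when no clusters
    mean_intensity: float      # NaN when no clusters


def frame_metrics(clusters: list[ClusterRecord], frame_time: float) -> FrameMetrics:
    """Exact totals and means over a frame's cluster records."""
    n = len(clusters)
    total = float(sum(c.area_um2 for c in clusters))
    return FrameMetrics(
        frame_time=float(frame_time),
        n_clusters=n,
        total_area_um2=total,
        mean_area_um2=total / n if n else float("nan"),
        mean_intensity=float(np.mean([c.mean_intensity for c in clusters])) if n
        else float("nan"),
    )


@dataclass
class ClusterTimeSeries:
    """Per-frame metrics split by the antibody-addition time."""

    frames: list[FrameMetrics]
    addition_time: float

    def __post_init__(self) -> None:
        times = [f.frame_time for f in self.frames]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise InvalidArgumentError("frame times must be strictly increasing")
        if times and not (times[0] <= self.addition_time <= times[-1]):
            raise InvalidArgumentError("addition_time outside the observed time range")

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame([vars(f) for f in self.frames])
        df["phase"] = np.where(df["frame_time"] < self.addition_time, "pre", "post")
        return df


@dataclass(frozen=True)
class SlopeFit:
    """OLS slope of one metric against time (per second)."""

    slope: float
    stderr: float
    intercept: float
    n: int


@dataclass(frozen=True)
class GrowthRates:
    """Post-addition growth slopes with pre-addition baselines."""

    post: dict[str, SlopeFit]
    pre: dict[str, SlopeFit]


_METRICS = ("n_clusters", "mean_area_um2", "total_area_um2")


def _ols(t: np.ndarray, y: np.ndarray) -> SlopeFit:
    ok = np.isfinite(y)
    t, y = t[ok], y[ok]
    if t.size < 2 or np.ptp(t) == 0:
        return SlopeFit(float("nan"), float("nan"), float("nan"), int(t.size))
    res = stats.linregress(t, y)
    stderr = float(res.stderr)
    if not np.isfinite(stderr):  # constant y gives 0/0 in the r-based formula
        resid = y - (res.intercept + res.slope * t)
        stderr = float(np.sqrt(np.sum(resid**2) / max(t.size - 2, 1)
                               / np.sum((t - t.mean()) ** 2)))
    return SlopeFit(float(res.slope), stderr, float(res.intercept), int(t.size))


def growth_rates(series: ClusterTimeSeries) -> GrowthRates:
    """Slopes of cluster count / mean area / total area vs. time.

    Computed by ordinary least squares on the post-addition frames; the
    pre-addition slopes are reported alongside as a no-antibody control.
    Requires at least two post-addition frames.
    """
    df = series.to_dataframe()
    post = df[df["phase"] == "post"]
    pre = df[df["phase"] == "pre"]
    if len(post) < 2:
        raise InsufficientDataError("need >= 2 frames after antibody addition")
    t_post = post["frame_time"].to_numpy(float)
    t_pre = pre["frame_time"].to_numpy(float)
    return GrowthRates(
        post={m: _ols(t_post, post[m].to_numpy(float)) for m in _METRICS},
        pre={m: _ols(t_pre, pre[m].to_numpy(float)) for m in _METRICS},
    )


@dataclass(frozen=True)
class QuantConfig:
    """Configuration of the end-to-end cluster quantification."""

    channel: str | int = "BTX"
    area_min: float = DEFAULT_AREA_MIN
    area_max: float = DEFAULT_AREA_MAX
    background_radius: int | None = 50
    threshold_method: str = "sahoo_combined"
    rho: float = 1.0
    per_frame_threshold: bool = True   # False: one threshold from the first post frame


@dataclass
class ClusterQuantResult:
    """Everything the cluster pipeline produces for one stack."""

    series: ClusterTimeSeries
    rates: GrowthRates
    per_frame: pd.DataFrame
    clusters: pd.DataFrame
    bubble: pd.DataFrame


def quantify_stack(
    stack: ImageStack,
    addition_time: float,
    config: QuantConfig | None = None,
) -> ClusterQuantResult:
    """Run projection, thresholding, segmentation and growth-rate fitting.

    The stack must contain the configured receptor-label channel (Z is
    assumed already projected; pass planes through :func:`project_stack`
    first if not).  Deterministic: identical stack and config give identical
    tables.
    """
    config = config or QuantConfig()
    frames = stack.channel(config.channel)
    fixed_threshold: float | None = None
    if not config.per_frame_threshold:
        ref = frames[min(int(np.searchsorted(stack.frame_times, addition_time)),
                         len(frames) - 1)]
        work = subtract_background(ref, config.background_radius) \
            if config.background_radius else ref.astype(float)
        fixed_threshold = threshold_image(work, method=config.threshold_method, rho=config.rho)

    all_clusters: list[ClusterRecord] = []
    metrics: list[FrameMetrics] = []
    for i, frame in enumerate(frames):
        recs = segment_clusters(
            frame,
            pixel_size=stack.pixel_size,
            threshold=fixed_threshold,
            area_min=config.area_min,
            area_max=config.area_max,
            background_radius=config.background_radius,
            method=config.threshold_method,
            rho=config.rho,
            frame_index=i,
        )
        all_clusters.extend(recs)
        metrics.append(frame_metrics(recs, stack.frame_times[i]))

    series = ClusterTimeSeries(frames=metrics, addition_time=addition_time)
    rates = growth_rates(series)
    per_frame = series.to_dataframe()
    clusters_df = pd.DataFrame(
        [
            {
                "frame_index": c.frame_index,
                "frame_time": stack.frame_times[c.frame_index],
                "label": c.label,
                "area_um2": c.area_um2,
                "x": c.centroid_xy[0],
                "y": c.centroid_xy[1],
                "mean_intensity": c.mean_intensity,
            }
            for c in all_clusters
        ]
    )
    bubble = per_frame[["frame_time", "n_clusters", "mean_area_um2", "phase"]].copy()
    return ClusterQuantResult(series=series, rates=rates, per_frame=per_frame,
                              clusters=clusters_df, bubble=bubble)


def bubble_chart(series: ClusterTimeSeries, ax=None):
    """Cluster count vs. time, bubble size = mean cluster area.

    Pre-addition points are drawn in blue, post-addition in red, mirroring the
    usual presentation of clustering time-lapses.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    df = series.to_dataframe()
    sizes = 30 * np.nan_to_num(df["mean_area_um2"], nan=0.1)
    for phase, color in (("pre", "tab:blue"), ("post", "tab:red")):
        sel = df["phase"] == phase
        ax.scatter(df.loc[sel, "frame_time"], df.loc[sel, "n_clusters"],
                   s=sizes[sel], c=color, alpha=0.6, label=phase)
    ax.axvline(series.addition_time, ls="--", c="grey")
    ax.set_xlabel("time (s)")
    ax.set_ylabel("clusters per frame")
    ax.legend()
    return ax
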