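"""Synthetic-data generators with exact ground truth.

Everything downstream of raw data — cluster quantification, NMJ morphometry,
flow-style statistics, calcium-trace analysis — is tested against data
produced here, where the truth is known by construction:

* ``synth_cluster_timelapse`` — a receptor-labelling time-lapse: diffuse
  membrane signal before antibody addition, then disk-shaped clusters whose
  count and mean area grow linearly at planted rates;
* ``synth_nmj_image`` — a 3-channel muscle-section field (receptor label,
  presynaptic marker, complement deposit) with controllable receptor
  retention and fragmentation;
* ``synth_flow_events`` — a two-population flow-cytometry event table with a
  planted geometric-mean ratio between transfected and untransfected cells;
* ``synth_calcium_traces`` — fluorescence traces with a stimulus-evoked
  decaying transient of known amplitude;
* ``render_simulated_field`` — couples the crosslinking simulator to imaging
  by rendering a geometric-mode binding state as a fluorescence frame.

Noise model: Poisson shot noise on the expected photon counts plus Gaussian
read noise (the standard fluorescence-camera model).  All generators are
seed-deterministic and record ground truth measured from the noise-free
render, so truth is consistent with the arrays by construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import InvalidArgumentError

CHANNELS_NMJ = ("BTX", "SV2A", "C3")


@dataclass(frozen=True)
class OpticsParams:
    """Camera/optics description used by all image generators.

    ``photon_scale`` is the expected signal (counts) contributed per unit of
    labelled structure intensity; SNR of a planted object over background is
    roughly ``photon_scale / sqrt(background_level + photon_scale)``.
    """

    pixel_size: float = 0.16       # micrometres per pixel
    psf_sigma: float = 0.2         # micrometres
    background_level: float = 20.0  # counts
    photon_scale: float = 200.0    # counts per labelled unit
    read_noise_sd: float = 2.0     # counts
    bit_depth: int = 16

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise InvalidArgumentError("pixel_size must be > 0")
        if self.psf_sigma < 0 or self.background_level < 0:
            raise InvalidArgumentError("psf_sigma and background must be >= 0")
        if self.bit_depth not in (8, 16):
            raise InvalidArgumentError("bit_depth must be 8 or 16")

    @property
    def dtype(self):
        return np.uint8 if self.bit_depth == 8 else np.uint16

    @property
    def snr(self) -> float:
        """Approximate planted-object SNR over background."""
        return self.photon_scale / np.sqrt(self.background_level + self.photon_scale
                                           + self.read_noise_sd**2)


@dataclass
class ImageStack:
    """T x C x Y x X image data with acquisition metadata."""

    data: np.ndarray
    frame_times: np.ndarray       # seconds
    channel_names: list[str]
    pixel_size: float             # micrometres per pixel

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        if self.data.ndim != 4:
            raise InvalidArgumentError("data must be T x C x Y x X")
        if self.data.shape[0] != self.frame_times.size:
            raise InvalidArgumentError("frame_times must match T")
        if self.data.shape[1] != len(self.channel_names):
            raise InvalidArgumentError("channel_names must match C")
        if self.frame_times.size > 1 and np.any(np.diff(self.frame_times) <= 0):
            raise InvalidArgumentError("frame_times must be strictly increasing")
        if self.pixel_size <= 0:
            raise InvalidArgumentError("pixel_size must be > 0")

    def channel(self, name_or_index: str | int) -> np.ndarray:
        """(T, Y, X) view of one channel."""
        if isinstance(name_or_index, str):
            try:
                idx = self.channel_names.index(name_or_index)
            except ValueError:
                raise InvalidArgumentError(
                    f"no channel {name_or_index!r}; have {self.channel_names}"
                ) from None
        else:
            idx = int(name_or_index)
        return self.data[:, idx]


def _finish_frame(expected: np.ndarray, optics: OpticsParams, rng: np.random.Generator,
                  apply_noise: bool) -> np.ndarray:
    top = 2**optics.bit_depth - 1
    if not apply_noise:
        # noise-free renders stay unquantised so planted values are exact
        return np.clip(expected, 0, top).astype(np.float64)
    img = rng.poisson(np.clip(expected, 0, None)).astype(float)
    if optics.read_noise_sd > 0:
        img += rng.normal(0.0, optics.read_noise_sd, size=img.shape)
    return np.clip(np.rint(img), 0, top).astype(optics.dtype)


def _disk_mask(shape: tuple[int, int], center: tuple[float, float], radius_px: float) -> np.ndarray:
    yy, xx = np.ogrid[: shape[0], : shape[1]]
    return (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius_px**2


@dataclass
class ClusterTimelapseTruth:
    """Planted-object record for a clustering time-lapse."""

    frame_times: np.ndarray
    addition_time: float
    n_pre: int
    count_slope_per_frame: float
    mean_area_slope_per_frame: float
    frame_interval: float
    label_masks: list[np.ndarray]        # per-frame integer label image (0 = none)
    areas_um2: list[np.ndarray]          # per-frame planted areas (rendered pixel areas)
    centers: list[np.ndarray]            # per-frame (n, 2) row/col centres

    @property
    def counts(self) -> np.ndarray:
        return np.array([len(a) for a in self.areas_um2])

    @property
    def count_slope_per_second(self) -> float:
        return self.count_slope_per_frame / self.frame_interval

    @property
    def mean_area_slope_per_second(self) -> float:
        return self.mean_area_slope_per_frame / self.frame_interval


def synth_cluster_timelapse(
    n_pre: int = 10,
    n_post: int = 20,
    frame_interval: float = 20.0,
    count_slope: float = 1.0,
    mean_area_slope: float = 0.0,
    initial_count: int = 4,
    initial_mean_area: float = 2.0,
    cluster_area_range: tuple[float, float] = (0.8, 10.0),
    shape: tuple[int, int] = (256, 256),
    optics: OpticsParams | None = None,
    diffuse_fraction: float = 0.15,
    apply_noise: bool = True,
    seed: int = 0,
) -> tuple[ImageStack, ClusterTimelapseTruth]:
    """Time-lapse with clusters appearing after an antibody-addition frame.

    Pre-addition frames carry diffuse signal only; post-addition frame ``k``
    carries ``round(initial_count + count_slope * k)`` disk clusters whose
    areas average ``initial_mean_area + mean_area_slope * k`` (clipped to
    ``cluster_area_range``).  Cluster positions persist across frames; count
    growth adds new positions.  Truth areas are remeasured from the rendered
    noise-free masks, so they are exact in pixel units.
    """
    if n_pre < 2 or n_post < 2:
        raise InvalidArgumentError("need at least two frames in each segment")
    optics = optics or OpticsParams()
    rng = np.random.default_rng(seed)
    n_frames = n_pre + n_post
    times = np.arange(n_frames) * frame_interval
    addition_time = 0.5 * (times[n_pre - 1] + times[n_pre])
    px = optics.pixel_size
    amin, amax = cluster_area_range

    max_radius_px = np.sqrt(amax / np.pi) / px
    margin = int(np.ceil(max_radius_px + 5 * max(optics.psf_sigma / px, 1.0)))
    if shape[0] - 2 * margin < 10 or shape[1] - 2 * margin < 10:
        raise InvalidArgumentError("image too small for the requested cluster sizes")

    # persistent, non-overlapping cluster centres (rejection sampling)
    max_count = int(round(initial_count + max(count_slope, 0) * (n_post - 1))) + 2
    centers: list[tuple[float, float]] = []
    min_sep = 2.2 * max_radius_px
    attempts = 0
    while len(centers) < max_count and attempts < 20000:
        c = (rng.uniform(margin, shape[0] - margin), rng.uniform(margin, shape[1] - margin))
        if all((c[0] - o[0]) ** 2 + (c[1] - o[1]) ** 2 > min_sep**2 for o in centers):
            centers.append(c)
        attempts += 1
    if len(centers) < max_count:
        raise InvalidArgumentError("could not place clusters without overlap; enlarge image")

    diffuse = diffuse_fraction * optics.photon_scale
    frames, label_masks, truth_areas, truth_centers = [], [], [], []
    for f in range(n_frames):
        expected = np.full(shape, optics.background_level + diffuse, dtype=float)
        labels = np.zeros(shape, dtype=np.int32)
        areas: list[float] = []
        ctrs: list[tuple[float, float]] = []
        if f >= n_pre:
            k = f - n_pre
            count = int(round(initial_count + count_slope * k))
            if count < 0:
                warnings.warn("planted count slope gives negative count; clipped at 0")
                count = 0
            mean_area = float(np.clip(initial_mean_area + mean_area_slope * k, amin, amax))
            # areas spread symmetrically around the target mean, inside range
            spread = min(mean_area - amin, amax - mean_area, 0.3 * mean_area)
            target = mean_area + (spread * np.linspace(-1, 1, count) if count > 1
                                  else np.zeros(max(count, 0)))
            signal = np.zeros(shape, dtype=float)
            for i in range(count):
                radius_px = np.sqrt(target[i] / np.pi) / px
                m = _disk_mask(shape, centers[i], radius_px)
                signal[m] += optics.photon_scale
                labels[m] = i + 1
                areas.append(float(m.sum()) * px**2)
                ctrs.append(centers[i])
            if optics.psf_sigma > 0:
                signal = ndimage.gaussian_filter(signal, optics.psf_sigma / px)
            expected += signal
        frames.append(_finish_frame(expected, optics, rng, apply_noise))
        label_masks.append(labels)
        truth_areas.append(np.asarray(areas))
        truth_centers.append(np.asarray(ctrs).reshape(-1, 2))

    stack = ImageStack(
        data=np.stack(frames)[:, None, :, :],
        frame_times=times,
        channel_names=["BTX"],
        pixel_size=px,
    )
    truth = ClusterTimelapseTruth(
        frame_times=times,
        addition_time=float(addition_time),
        n_pre=n_pre,
        count_slope_per_frame=count_slope,
        mean_area_slope_per_frame=mean_area_slope,
        frame_interval=frame_interval,
        label_masks=label_masks,
        areas_um2=truth_areas,
        centers=truth_centers,
    )
    return stack, truth


@dataclass
class NMJTruth:
    """Ground truth for one synthetic neuromuscular junction."""

    mask: np.ndarray               # boolean junction mask (from the presynaptic marker)
    fragment_labels: np.ndarray    # integer labels of receptor-positive blobs
    n_fragments: int
    retention: float               # mask-mean BTX / mask-mean SV2A of the clean render
    c3_level: float
    area_um2: float


def _pretzel_mask(shape: tuple[int, int], center: tuple[float, float],
                  r_mid_px: float, half_width_px: float, wobble: float = 0.18) -> np.ndarray:
    """Closed elliptical band with angular radius modulation (pretzel-ish)."""
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    dy = (yy - center[0]) * 1.25   # slight ellipticity
    dx = xx - center[1]
    r = np.hypot(dy, dx)
    theta = np.arctan2(dy, dx)
    r_target = r_mid_px * (1.0 + wobble * np.sin(2 * theta))
    return np.abs(r - r_target) <= half_width_px


def synth_nmj_image(
    n_fragments: int,
    achr_retention: float,
    c3_level: float,
    optics: OpticsParams | None = None,
    shape: tuple[int, int] = (192, 192),
    sv2a_level: float | None = None,
    gap_px: int = 5,
    apply_noise: bool = True,
    seed: int = 0,
) -> tuple[ImageStack, NMJTruth]:
    """One junction rendered into BTX / SV2A / C3 channels.

    The SV2A channel is a smooth pretzel-shaped band of uniform intensity.
    The BTX channel covers exactly ``n_fragments`` disjoint arcs of that band
    (``0`` leaves it blank); fragment intensity is scaled so that the
    mask-mean BTX / mask-mean SV2A ratio equals ``achr_retention`` exactly in
    the noise-free render, regardless of how much band area the inter-fragment
    gaps remove.  The C3 channel is the band at ``c3_level`` counts.
    """
    if n_fragments < 0:
        raise InvalidArgumentError("n_fragments must be >= 0")
    if not 0.0 <= achr_retention <= 1.0:
        raise InvalidArgumentError("achr_retention must be in [0, 1]")
    optics = optics or OpticsParams()
    rng = np.random.default_rng(seed)
    sv2a_level = optics.photon_scale if sv2a_level is None else sv2a_level
    px = optics.pixel_size

    center = (shape[0] / 2 + rng.uniform(-3, 3), shape[1] / 2 + rng.uniform(-3, 3))
    r_mid = min(shape) * 0.22
    half_width = min(shape) * 0.045
    mask = _pretzel_mask(shape, center, r_mid, half_width)

    yy, xx = np.mgrid[: shape[0], : shape[1]]
    theta = np.arctan2((yy - center[0]) * 1.25, xx - center[1])

    frag_labels = np.zeros(shape, dtype=np.int32)
    if n_fragments == 1:
        frag_labels[mask] = 1
    elif n_fragments > 1:
        phase = rng.uniform(0, 2 * np.pi)
        gap_angle = gap_px / r_mid
        sector = 2 * np.pi / n_fragments
        ang = np.mod(theta - phase, 2 * np.pi)
        idx = np.floor(ang / sector).astype(int)
        within = np.mod(ang, sector)
        keep = (within > gap_angle / 2) & (within < sector - gap_angle / 2)
        frag_labels[mask & keep] = idx[mask & keep] + 1

    sv2a = np.where(mask, sv2a_level, 0.0)
    btx = np.zeros(shape, dtype=float)
    if n_fragments > 0 and achr_retention > 0:
        frag_mask = frag_labels > 0
        comp = mask.sum() / frag_mask.sum()   # compensate for gap area
        btx[frag_mask] = achr_retention * sv2a_level * comp
    c3 = np.where(mask, float(c3_level), 0.0)

    retention_achieved = (
        float(btx[mask].mean() / sv2a[mask].mean()) if mask.any() and sv2a_level > 0 else 0.0
    )

    chans = []
    for expected in (btx, sv2a, c3):
        chans.append(_finish_frame(expected + optics.background_level, optics, rng, apply_noise))
    stack = ImageStack(
        data=np.stack(chans)[None, :, :, :],
        frame_times=np.array([0.0]),
        channel_names=list(CHANNELS_NMJ),
        pixel_size=px,
    )
    truth = NMJTruth(
        mask=mask,
        fragment_labels=frag_labels,
        n_fragments=n_fragments,
        retention=retention_achieved,
        c3_level=float(c3_level),
        area_um2=float(mask.sum()) * px**2,
    )
    return stack, truth


def synth_flow_events(
    n_events: int = 10_000,
    frac_transfected: float = 0.5,
    gfp_params: tuple[tuple[float, float], tuple[float, float]] = ((50.0, 0.4), (5000.0, 0.5)),
    binding_ratio: float = 10.0,
    c3_ratio: float = 1.0,
    baseline_gm: float = 100.0,
    log_sd: float = 0.5,
    seed: int = 0,
) -> pd.DataFrame:
    """Two-population flow-style event table (columns gfp, igg, c3, population).

    GFP is log-normal in both populations (``gfp_params`` gives the geometric
    mean and log-sd of the untransfected and transfected populations); the
    antibody (igg) and complement (c3) channels are log-normal with geometric
    means differing between populations by exactly the planted ratios.
    """
    if n_events < 1:
        raise InvalidArgumentError("n_events must be >= 1")
    if not 0.0 < frac_transfected < 1.0:
        raise InvalidArgumentError("frac_transfected must be in (0, 1)")
    if binding_ratio <= 0 or c3_ratio <= 0:
        raise InvalidArgumentError("planted ratios must be > 0")
    rng = np.random.default_rng(seed)
    pos = rng.random(n_events) < frac_transfected
    (gm_neg, sd_neg), (gm_pos, sd_pos) = gfp_params

    gfp = np.where(
        pos,
        rng.lognormal(np.log(gm_pos), sd_pos, n_events),
        rng.lognormal(np.log(gm_neg), sd_neg, n_events),
    )
    igg = rng.lognormal(np.log(baseline_gm), log_sd, n_events) * np.where(pos, binding_ratio, 1.0)
    c3 = rng.lognormal(np.log(baseline_gm), log_sd, n_events) * np.where(pos, c3_ratio, 1.0)
    return pd.DataFrame(
        {"gfp": gfp, "igg": igg, "c3": c3,
         "population": np.where(pos, "transfected", "untransfected")}
    )


@dataclass
class TraceSet:
    """Per-well fluorescence traces with a common stimulus frame."""

    traces: np.ndarray        # (n_wells, n_frames)
    stim_index: int
    peak_amplitude: float     # planted transient height
    baseline: float

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.traces.T,
                          columns=[f"well_{i}" for i in range(self.traces.shape[0])])
        df.insert(0, "frame", np.arange(self.traces.shape[1]))
        return df


def synth_calcium_traces(
    n_wells: int = 12,
    n_frames: int = 200,
    stim_index: int = 50,
    peak_amplitude: float = 5.0,
    baseline: float = 10.0,
    noise_sd: float = 0.2,
    decay_tau: float = 20.0,
    seed: int = 0,
) -> TraceSet:
    """Baseline + noise traces with a decaying transient starting at ``stim_index``."""
    if not 0 < stim_index < n_frames:
        raise InvalidArgumentError("stim_index must lie inside the trace")
    rng = np.random.default_rng(seed)
    t = np.arange(n_frames)
    transient = np.where(
        t >= stim_index, peak_amplitude * np.exp(-(t - stim_index) / decay_tau), 0.0
    )
    traces = baseline + transient[None, :] + (
        rng.normal(0.0, noise_sd, size=(n_wells, n_frames)) if noise_sd > 0 else 0.0
    )
    return TraceSet(traces=traces, stim_index=stim_index,
                    peak_amplitude=peak_amplitude, baseline=baseline)


def render_simulated_field(
    graph,
    optics: OpticsParams | None = None,
    seed: int = 0,
    apply_noise: bool = True,
    jitter_um: float = 0.03,
    margin_um: float = 1.0,
) -> tuple[ImageStack, dict]:
    """Render a geometric-mode crosslink graph as a single fluorescence frame.

    Each receptor is a point emitter of ``photon_scale`` expected counts;
    members of a multi-receptor aggregate are co-located at the component
    centroid with Gaussian jitter, so aggregates appear as bright puncta.
    Returns the frame and a truth dict with emitter positions and counts.
    """
    optics = optics or OpticsParams()
    if graph.positions is None:
        raise InvalidArgumentError("graph has no receptor positions; use geometric mode")
    rng = np.random.default_rng(seed)
    pos = np.array(graph.positions, dtype=float)

    import networkx as nx  # local import to keep module load light

    for comp in nx.connected_components(graph.to_networkx()):
        comp = list(comp)
        if len(comp) > 1:
            centroid = pos[comp].mean(axis=0)
            pos[comp] = centroid + rng.normal(0.0, jitter_um, size=(len(comp), 2))

    px = optics.pixel_size
    lo = pos.min(axis=0) - margin_um if len(pos) else np.zeros(2)
    hi = pos.max(axis=0) + margin_um if len(pos) else np.ones(2)
    shape = (int(np.ceil((hi[0] - lo[0]) / px)) + 1, int(np.ceil((hi[1] - lo[1]) / px)) + 1)
    expected = np.zeros(shape, dtype=float)
    ij = np.clip(np.rint((pos - lo) / px).astype(int), 0, np.array(shape) - 1)
    np.add.at(expected, (ij[:, 0], ij[:, 1]), optics.photon_scale)
    if optics.psf_sigma > 0:
        expected = ndimage.gaussian_filter(expected, optics.psf_sigma / px)
    expected += optics.background_level
    frame = _finish_frame(expected, optics, rng, apply_noise)
    stack = ImageStack(
        data=frame[None, None, :, :],
        frame_times=np.array([0.0]),
        channel_names=["BTX"],
        pixel_size=px,
    )
    truth = {"emitter_positions_um": pos, "n_emitters": int(len(pos)),
             "photon_scale": optics.photon_scale}
    return stack, truth
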