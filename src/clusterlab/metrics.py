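"""Flow-cytometry-style and functional assay statistics.

* geometric-mean fluorescence intensity (GMFI) ratios between a
  antigen-positive and an antigen-negative gate — the specific-binding and
  complement-deposition readout of live-cell assays;
* four-parameter logistic (4PL) dose-response fits and the half-maximal
  concentration EC50;
* fold-enhancement synergy indices for antibody combinations measured at
  matched total concentration;
* calcium-trace peak quantification and normalisation to untreated wells;
* Spearman rank correlation with a two-tailed permutation test (exact
  enumeration for small samples).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import (
    FitFailureError,
    InsufficientDataError,
    InsufficientEventsError,
    InvalidArgumentError,
    InvalidDataError,
    UndefinedCorrelationError,
)


@dataclass(frozen=True)
class GateSpec:
    """Rectangular gate: events with ``lower <= channel value < upper``."""

    channel: str
    lower: float
    upper: float

    def __post_init__(self) -> None:
        if not self.lower < self.upper:
            raise InvalidArgumentError("gate lower bound must be below upper bound")

    def select(self, events: pd.DataFrame) -> pd.Series:
        if self.channel not in events.columns:
            raise InvalidArgumentError(f"no channel {self.channel!r} in event table")
        v = events[self.channel]
        return (v >= self.lower) & (v < self.upper)


def default_gates(untransfected_gfp: np.ndarray, channel: str = "gfp",
                  percentile: float = 99.5) -> tuple[GateSpec, GateSpec]:
    """Positive/negative GFP gates from an untransfected control sample.

    The negative gate is everything below the control's ``percentile`` GFP
    value, the positive gate everything above it.
    """
    cut = float(np.percentile(np.asarray(untransfected_gfp, dtype=float), percentile))
    return (GateSpec(channel, cut, math.inf), GateSpec(channel, -math.inf, cut))


@dataclass(frozen=True)
class GMFIResult:
    """Geometric-mean intensities in the two gates and their ratio."""

    gm_pos: float
    gm_neg: float
    ratio: float
    n_pos: int
    n_neg: int
    n_excluded_nonpositive: int = 0


def _geometric_mean(values: np.ndarray) -> tuple[float, int, int]:
    values = np.asarray(values, dtype=float)
    positive = values[values > 0]
    if positive.size == 0:
        raise InvalidDataError("all gated values are <= 0; geometric mean undefined")
    return float(np.exp(np.mean(np.log(positive)))), int(positive.size), \
        int(values.size - positive.size)


def gmfi_ratio(
    events: pd.DataFrame,
    pos_gate: GateSpec,
    neg_gate: GateSpec,
    channel: str = "igg",
    min_events: int = 100,
    geometric: bool = True,
) -> GMFIResult:
    """Specific-signal ratio: GMFI in the positive gate over the negative gate.

    The geometric mean is ``exp(mean(log x))`` over strictly positive values;
    non-positive events (possible in compensated exports) are excluded and
    counted.  ``geometric=False`` switches to arithmetic means.
    """
    if channel not in events.columns:
        raise InvalidArgumentError(f"no channel {channel!r} in event table")
    pos = events.loc[pos_gate.select(events), channel].to_numpy(float)
    neg = events.loc[neg_gate.select(events), channel].to_numpy(float)
    if pos.size < min_events or neg.size < min_events:
        raise InsufficientEventsError(
            f"gates contain {pos.size}/{neg.size} events; need >= {min_events}"
        )
    if geometric:
        gm_pos, n_pos, excl_pos = _geometric_mean(pos)
        gm_neg, n_neg, excl_neg = _geometric_mean(neg)
    else:
        gm_pos, n_pos, excl_pos = float(pos.mean()), pos.size, 0
        gm_neg, n_neg, excl_neg = float(neg.mean()), neg.size, 0
    if gm_neg <= 0:
        raise InvalidDataError("negative-gate mean is not positive; ratio undefined")
    return GMFIResult(
        gm_pos=gm_pos,
        gm_neg=gm_neg,
        ratio=gm_pos / gm_neg,
        n_pos=n_pos,
        n_neg=n_neg,
        n_excluded_nonpositive=excl_pos + excl_neg,
    )


@dataclass(frozen=True)
class FourPLFit:
    """Four-parameter logistic fit R(c) = bottom + (top-bottom)/(1+(ec50/c)^h)."""

    bottom: float
    top: float
    ec50: float
    hill: float
    residual_norm: float

    def predict(self, conc: np.ndarray) -> np.ndarray:
        conc = np.asarray(conc, dtype=float)
        return self.bottom + (self.top - self.bottom) / (1.0 + (self.ec50 / conc) ** self.hill)


def _4pl_logc(logc: np.ndarray, bottom: float, top: float, log_ec50: float,
              hill: float) -> np.ndarray:
    return bottom + (top - bottom) / (1.0 + np.exp(hill * (log_ec50 - logc)))


def fit_4pl(conc: np.ndarray, response: np.ndarray,
            flat_tolerance: float = 0.05) -> FourPLFit:
    """Least-squares 4PL fit in log-concentration space.

    Requires at least five concentrations spanning two orders of magnitude.
    The fit is multi-started over Hill slopes {0.5, 1, 2}; the best converged
    start (lowest residual norm) wins.  A response whose dynamic range is
    below ``flat_tolerance`` of its magnitude raises ``FitFailureError``.
    """
    conc = np.asarray(conc, dtype=float)
    response = np.asarray(response, dtype=float)
    if conc.shape != response.shape or conc.ndim != 1:
        raise InvalidArgumentError("conc and response must be matching 1-D arrays")
    if np.any(conc <= 0):
        raise InvalidArgumentError("concentrations must be > 0")
    if conc.size < 5:
        raise InsufficientDataError("need >= 5 concentrations")
    if np.log10(conc.max() / conc.min()) < 2.0:
        raise InsufficientDataError("concentrations must span >= 2 orders of magnitude")
    span = response.max() - response.min()
    if span <= flat_tolerance * max(abs(response).max(), 1e-12):
        raise FitFailureError("flat response: no dose dependence to fit")

    logc = np.log(conc)
    p_bottom, p_top = float(response.min()), float(response.max())
    best: tuple[float, np.ndarray] | None = None
    for h0 in (0.5, 1.0, 2.0):
        p0 = [p_bottom, p_top, float(np.median(logc)), h0]
        try:
            popt, _ = optimize.curve_fit(_4pl_logc, logc, response, p0=p0, maxfev=20000)
        except (RuntimeError, optimize.OptimizeWarning):
            continue
        resid = float(np.linalg.norm(_4pl_logc(logc, *popt) - response))
        if best is None or resid < best[0]:
            best = (resid, popt)
    if best is None:
        raise FitFailureError("4PL fit did not converge from any start")
    resid, (bottom, top, log_ec50, hill) = best
    if top < bottom:  # re-express as an ascending curve
        bottom, top, hill = top, bottom, -hill
    return FourPLFit(bottom=float(bottom), top=float(top), ec50=float(np.exp(log_ec50)),
                     hill=float(hill), residual_norm=resid)


def fit_dose_response(df: pd.DataFrame, conc_col: str = "conc",
                      response_col: str = "response") -> FourPLFit:
    """4PL fit from a tidy concentration/response table."""
    for col in (conc_col, response_col):
        if col not in df.columns:
            raise InvalidArgumentError(f"dose-response table lacks column {col!r}")
    return fit_4pl(df[conc_col].to_numpy(float), df[response_col].to_numpy(float))


def synergy_index(single_a: float, single_b: float, combo: float) -> float:
    """Fold enhancement of a combination over its best constituent single.

    All three measurements must come from matched total antibody
    concentration (each constituent at half concentration in the combination).
    """
    if single_a <= 0 or single_b <= 0 or combo <= 0:
        raise InvalidArgumentError("all inputs must be > 0")
    return combo / max(single_a, single_b)


def build_synergy_matrix(
    singles: dict[str, float],
    combos: dict[tuple[str, str], float],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Assemble the species-by-species response and fold-enhancement matrices.

    Diagonal entries are the singles; off-diagonal entries the pair
    measurements (symmetric).  The fold matrix divides each entry by the best
    constituent single, so its diagonal is identically 1.
    """
    if not singles:
        raise InvalidArgumentError("need at least one single measurement")
    labels = list(singles)
    resp = pd.DataFrame(np.nan, index=labels, columns=labels, dtype=float)
    fold = pd.DataFrame(np.nan, index=labels, columns=labels, dtype=float)
    for a in labels:
        resp.loc[a, a] = singles[a]
        fold.loc[a, a] = 1.0
    for (a, b), value in combos.items():
        if a not in singles or b not in singles:
            raise InvalidArgumentError(f"combination ({a}, {b}) lacks single measurements")
        resp.loc[a, b] = resp.loc[b, a] = value
        f = synergy_index(singles[a], singles[b], value)
        fold.loc[a, b] = fold.loc[b, a] = f
    return resp, fold


def trace_peak(trace: np.ndarray, stim_index: int,
               baseline_window: tuple[int, int] | None = None) -> float:
    """Stimulus-evoked peak height: post-stimulus maximum minus baseline median."""
    trace = np.asarray(trace, dtype=float)
    if not 0 < stim_index < trace.size:
        raise InvalidArgumentError("stim_index out of range")
    if baseline_window is None:
        baseline_window = (0, stim_index)
    b0, b1 = baseline_window
    if not (0 <= b0 < b1 <= stim_index):
        raise InvalidArgumentError("baseline window must precede the stimulus")
    return float(trace[stim_index:].max() - np.median(trace[b0:b1]))


def normalize_transmission(peaks: np.ndarray, untreated_peaks: np.ndarray) -> np.ndarray:
    """Peak heights divided by the mean peak of untreated wells."""
    peaks = np.asarray(peaks, dtype=float)
    untreated = np.asarray(untreated_peaks, dtype=float)
    if untreated.size == 0:
        raise InvalidDataError("no untreated wells supplied")
    divisor = float(untreated.mean())
    if divisor <= 0:
        raise InvalidDataError("mean untreated peak is not positive")
    return peaks / divisor


@dataclass(frozen=True)
class CorrelationResult:
    """Spearman rho with a two-tailed permutation p-value."""

    rho: float
    p_two_tailed: float
    n_perm: int
    exact: bool


def _rank_rho(rank_x: np.ndarray, rank_y: np.ndarray) -> float:
    rx = rank_x - rank_x.mean()
    ry = rank_y - rank_y.mean()
    return float((rx * ry).sum() / np.sqrt((rx**2).sum() * (ry**2).sum()))


def spearman_permutation(
    x: np.ndarray,
    y: np.ndarray,
    n_perm: int = 10_000,
    seed: int = 0,
) -> CorrelationResult:
    """Spearman rank correlation with a two-tailed permutation test.

    Ranks are mid-ranks (ties averaged).  When ``n! <= n_perm`` the test
    enumerates all permutations exactly (p = fraction of permutations with
    ``|rho*| >= |rho|``); otherwise it samples ``n_perm`` permutations and
    applies the add-one correction ``p = (1 + hits) / (1 + n_perm)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InvalidArgumentError("x and y must be matching 1-D arrays")
    n = x.size
    if n < 3:
        raise InvalidArgumentError("need at least 3 paired observations")
    if n_perm < 1:
        raise InvalidArgumentError("n_perm must be >= 1")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("constant input; correlation undefined")

    rank_x = stats.rankdata(x)
    rank_y = stats.rankdata(y)
    rho = _rank_rho(rank_x, rank_y)
    eps = 1e-12

    if math.factorial(n) <= n_perm:
        total = hits = 0
        for perm in itertools.permutations(rank_y):
            total += 1
            if abs(_rank_rho(rank_x, np.asarray(perm))) >= abs(rho) - eps:
                hits += 1
        return CorrelationResult(rho=rho, p_two_tailed=hits / total,
                                 n_perm=total, exact=True)

    rng = np.random.default_rng(seed)
    rx = rank_x - rank_x.mean()
    ry = rank_y - rank_y.mean()
    denom = np.sqrt((rx**2).sum() * (ry**2).sum())
    perms = rng.permuted(np.tile(ry, (n_perm, 1)), axis=1)
    rho_star = perms @ rx / denom
    hits = int(np.sum(np.abs(rho_star) >= abs(rho) - eps))
    return CorrelationResult(rho=rho, p_two_tailed=(1 + hits) / (1 + n_perm),
                             n_perm=n_perm, exact=False)
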