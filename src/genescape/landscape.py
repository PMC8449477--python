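"""Sliding-window genome landscapes, region detection and track correlations.

Any per-gene statistic (presence index, length index, GC%, GARP%, nPD, ...)
laid out in reference-genome gene order becomes a *landscape* after boxcar
smoothing: the value at rank i is the mean of the focal gene and its h
neighbors on each side (window size 2h+1, default 101). Smoothing turns the
erratic behaviour of single genes into visible regional structure; windows
below/above a calibrated threshold are merged into regions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .catalog import ReferenceOrder
from .errors import ConfigError, UndefinedValueError


@dataclass(frozen=True)
class WindowSpec:
    """Boxcar window: odd size (focal gene +- (size-1)/2 neighbors).

    ``edge_policy``: ``"truncate"`` shrinks the window at track edges so
    every rank gets a value; ``"drop"`` leaves edge ranks missing.
    ``min_valid_fraction``: minimum fraction of non-missing values within the
    (possibly truncated) window for the mean to be defined.
    ``span_chromosomes``: whether windows run across chromosome boundaries
    (genome-wide landscapes are drawn continuously, so the default is True).
    """

    size: int = 101
    edge_policy: str = "truncate"
    min_valid_fraction: float = 0.5
    span_chromosomes: bool = True

    def __post_init__(self) -> None:
        if self.size < 1 or self.size % 2 == 0:
            raise ConfigError(f"window size must be odd and positive, got {self.size}")
        if self.edge_policy not in {"truncate", "drop"}:
            raise ConfigError(f"unknown edge policy {self.edge_policy!r}")
        if not (0.0 < self.min_valid_fraction <= 1.0):
            raise ConfigError("min_valid_fraction must be in (0, 1]")

    @property
    def half(self) -> int:
        return (self.size - 1) // 2


@dataclass
class LandscapeTrack:
    """Raw per-rank values plus their sliding-window means, in reference order."""

    order: ReferenceOrder
    raw: np.ndarray
    smoothed: np.ndarray
    name: str
    spec: WindowSpec = field(default_factory=WindowSpec)

    def __post_init__(self) -> None:
        self.raw = np.asarray(self.raw, dtype=float)
        self.smoothed = np.asarray(self.smoothed, dtype=float)
        if len(self.raw) != self.order.size or len(self.smoothed) != self.order.size:
            raise ConfigError("track length must equal the reference-order size")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rank": np.arange(self.order.size),
                "symbol": self.order.symbols,
                "chromosome": self.order.chromosomes,
                "raw": self.raw,
                "smoothed": self.smoothed,
            }
        )


@dataclass
class Region:
    """Half-open rank interval of windows beyond a threshold."""

    start_rank: int
    end_rank: int
    direction: str
    threshold: float
    extreme: float
    n_windows: int

    @property
    def width(self) -> int:
        return self.end_rank - self.start_rank


def sliding_window(
    raw: Sequence[float] | np.ndarray,
    spec: WindowSpec | None = None,
    chromosome_bounds: Sequence[tuple[str, int, int]] | None = None,
) -> np.ndarray:
    """Centered skip-missing boxcar mean of a per-rank track.

    Missing raw values (NaN) are skipped: each window mean runs over its
    non-missing members, and is itself missing where fewer than
    ``min_valid_fraction`` of the window's ranks are valid. With
    ``span_chromosomes=False``, windows are clipped at the chromosome bounds.
    """
    spec = spec or WindowSpec()
    x = np.asarray(raw, dtype=float)
    if x.ndim != 1:
        raise ConfigError("raw track must be one-dimensional")
    if not np.isfinite(x).any():
        raise UndefinedValueError("sliding window over an all-missing track")

    if spec.span_chromosomes or chromosome_bounds is None:
        segments = [(0, len(x))]
    else:
        segments = [(s, e) for _, s, e in chromosome_bounds]

    out = np.full(len(x), np.nan)
    for s, e in segments:
        out[s:e] = _smooth_segment(x[s:e], spec)
    return out


def _smooth_segment(x: np.ndarray, spec: WindowSpec) -> np.ndarray:
    ser = pd.Series(x)
    counts = ser.rolling(spec.size, center=True, min_periods=1).count().to_numpy()
    sums = ser.rolling(spec.size, center=True, min_periods=1).sum().to_numpy()
    # number of ranks actually inside each (edge-truncated) window
    extent = (
        pd.Series(np.ones(len(x)))
        .rolling(spec.size, center=True, min_periods=1)
        .count()
        .to_numpy()
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = sums / counts
    mean[counts < spec.min_valid_fraction * extent] = np.nan
    mean[counts == 0] = np.nan
    if spec.edge_policy == "drop":
        h = spec.half
        mean[:h] = np.nan
        if h:
            mean[-h:] = np.nan
    return mean


def make_track(
    order: ReferenceOrder,
    values: Mapping[str, float] | pd.Series,
    name: str,
    spec: WindowSpec | None = None,
) -> LandscapeTrack:
    """Align per-symbol values to the reference order and smooth them."""
    spec = spec or WindowSpec()
    if isinstance(values, pd.Series):
        values = values.to_dict()
    raw = np.array([values.get(s, np.nan) for s in order.symbols], dtype=float)
    smoothed = sliding_window(
        raw, spec, None if spec.span_chromosomes else order.chromosome_bounds
    )
    return LandscapeTrack(order=order, raw=raw, smoothed=smoothed, name=name, spec=spec)


def detect_regions(
    track: LandscapeTrack | np.ndarray,
    threshold: float,
    direction: str,
    gap_max: int = 25,
    min_width: int = 5,
    refine_fraction: float = 0.0,
) -> list[Region]:
    """Merge threshold-crossing windows into regions.

    Maximal runs of ranks with smoothed value strictly below (``"below"``) or
    above (``"above"``) the threshold; runs separated by at most ``gap_max``
    non-satisfying ranks are merged, and merged regions narrower than
    ``min_width`` are dropped.

    ``refine_fraction`` in (0, 1] optionally trims each region to the span
    where the track passes that fraction of the way from the threshold to the
    region's extreme — a boxcar-deconvolution step that counteracts the
    half-window dilation the smoothing imposes on a compact anomaly (see the
    methods note). 0 disables refinement.
    """
    smoothed = track.smoothed if isinstance(track, LandscapeTrack) else np.asarray(track, float)
    if direction not in {"below", "above"}:
        raise ConfigError(f"direction must be 'below' or 'above', got {direction!r}")
    with np.errstate(invalid="ignore"):
        mask = smoothed < threshold if direction == "below" else smoothed > threshold

    runs = _runs(mask)
    merged: list[list[int]] = []
    for s, e in runs:
        if merged and s - merged[-1][1] <= gap_max:
            merged[-1][1] = e
        else:
            merged.append([s, e])

    regions = []
    for s, e in merged:
        if e - s < min_width:
            continue
        seg = smoothed[s:e]
        extreme = float(np.nanmin(seg) if direction == "below" else np.nanmax(seg))
        if refine_fraction > 0.0:
            level = extreme + refine_fraction * (threshold - extreme)
            with np.errstate(invalid="ignore"):
                core = seg <= level if direction == "below" else seg >= level
            idx = np.flatnonzero(core)
            s, e = s + int(idx[0]), s + int(idx[-1]) + 1
        n_win = int(np.sum(mask[s:e]))
        regions.append(
            Region(
                start_rank=s,
                end_rank=e,
                direction=direction,
                threshold=float(threshold),
                extreme=extreme,
                n_windows=n_win,
            )
        )
    return regions


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    padded = np.concatenate([[False], mask, [False]])
    diff = np.diff(padded.astype(int))
    starts = np.flatnonzero(diff == 1)
    ends = np.flatnonzero(diff == -1)
    return list(zip(starts.tolist(), ends.tolist()))


def track_correlation(a: LandscapeTrack | np.ndarray, b: LandscapeTrack | np.ndarray) -> float:
    """Pearson r between two smoothed tracks over jointly non-missing ranks."""
    xa = a.smoothed if isinstance(a, LandscapeTrack) else np.asarray(a, float)
    xb = b.smoothed if isinstance(b, LandscapeTrack) else np.asarray(b, float)
    if len(xa) != len(xb):
        raise ConfigError("tracks differ in length")
    ok = np.isfinite(xa) & np.isfinite(xb)
    if ok.sum() < 3:
        raise UndefinedValueError("fewer than 3 jointly non-missing ranks")
    if np.std(xa[ok]) == 0.0 or np.std(xb[ok]) == 0.0:
        raise UndefinedValueError("zero variance track; correlation undefined")
    return float(stats.pearsonr(xa[ok], xb[ok]).statistic)


def heatmap_matrix(tracks: Sequence[LandscapeTrack]) -> pd.DataFrame:
    """Stack smoothed tracks into a rows-by-rank matrix (NaN = missing cell).

    All tracks must share one reference order; row order is the order the
    tracks are given in (pair-class order for divergence heatmaps).
    """
    if not tracks:
        raise ConfigError("no tracks given")
    ref = tracks[0].order
    for t in tracks[1:]:
        if t.order.symbols != ref.symbols:
            raise ConfigError(f"track {t.name!r} uses a different reference order")
    return pd.DataFrame(
        np.vstack([t.smoothed for t in tracks]),
        index=[t.name for t in tracks],
        columns=np.arange(ref.size),
    )


def regions_to_bed(regions: Sequence[Region], order: ReferenceOrder) -> pd.DataFrame:
    """Regions as BED-like rows (1 kb-resolution genomic when positions exist).

    Regions are split at chromosome boundaries; blocks whose genes carry
    genomic positions get genomic start/end (half-open), others (PU block)
    fall back to rank intervals. Score is the region extreme x1000 clamped to
    [0, 1000].
    """
    rows = []
    for reg in regions:
        for chrom, cs, ce in order.chromosome_bounds:
            s, e = max(reg.start_rank, cs), min(reg.end_rank, ce)
            if s >= e:
                continue
            pos_s, pos_e = order.positions[s], order.positions[e - 1]
            if pos_s is not None and pos_e is not None:
                start, end = pos_s, pos_e + 1
            else:
                start, end = s, e
            rows.append(
                {
                    "chrom": chrom,
                    "start": start,
                    "end": end,
                    "name": reg.direction,
                    "score": int(np.clip(reg.extreme * 1000, 0, 1000)),
                    "start_rank": s,
                    "end_rank": e,
                }
            )
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "name", "score", "start_rank", "end_rank"]
    )
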