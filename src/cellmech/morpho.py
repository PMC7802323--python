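"""Cell-shape descriptors and single-cell motility metrics.

Shape: the equivalent ellipse of a binary cell mask (matched second
image moments); the aspect ratio is major/minor axis and equals 1 for
a round cell.  Motility: travel distance, net displacement, and mean
velocity (path length over elapsed time) from centroid tracks sampled
at a fixed interval.  Group statistics follow one-way ANOVA with
Bonferroni-adjusted pairwise comparisons at alpha = 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from skimage.measure import label, regionprops

from .errors import MaskError


# --------------------------------------------------------------------------
# shape
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class CellShape:
    area_um2: float
    major_axis_um: float
    minor_axis_um: float
    orientation_deg: float
    aspect_ratio: float


def fit_equivalent_ellipse(mask: np.ndarray, pixel_size: float = 1.0) -> CellShape:
    """Equivalent-ellipse descriptors of a single-cell mask.

    The ellipse shares the mask's second-order image moments; the
    aspect ratio is the major over the minor axis length.

    Raises
    ------
    MaskError
        For an empty mask, more than one connected component (split
        components first), or fewer than 20 pixels.
    """
    mask = np.asarray(mask).astype(bool)
    labels, n = label(mask, return_num=True)
    if n == 0:
        raise MaskError("empty mask")
    if n > 1:
        raise MaskError(f"mask has {n} connected components; split them before fitting")
    props = regionprops(labels)[0]
    if props.area < 20:
        raise MaskError(f"component has only {props.area} pixels; need >= 20")
    major = props.axis_major_length * pixel_size
    minor = props.axis_minor_length * pixel_size
    if minor <= 0:
        raise MaskError("degenerate (line-like) mask; minor axis is zero")
    return CellShape(
        area_um2=float(props.area) * pixel_size**2,
        major_axis_um=float(major),
        minor_axis_um=float(minor),
        orientation_deg=float(np.rad2deg(props.orientation)),
        aspect_ratio=float(major / minor),
    )


# --------------------------------------------------------------------------
# tracks
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class CellTrack:
    """Time-stamped centroid path of one cell (uniform sampling)."""

    cell_id: int
    t_min: np.ndarray
    positions_um: np.ndarray  # (n, 2)

    def __post_init__(self) -> None:
        t = np.asarray(self.t_min, dtype=float)
        if len(t) != len(self.positions_um):
            raise ValueError("timestamps and positions must have equal length")
        if len(t) >= 2:
            dt = np.diff(t)
            if np.any(dt <= 0):
                raise ValueError("timestamps must be strictly increasing")
            if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
                raise ValueError("timestamps must be uniformly spaced")

    @property
    def sampling_interval_min(self) -> float:
        return float(self.t_min[1] - self.t_min[0])


@dataclass(frozen=True)
class TrackMetrics:
    cell_id: int
    path_distance_um: float
    net_displacement_um: float
    mean_velocity_um_per_min: float
    instantaneous_speeds_um_per_min: np.ndarray


def track_metrics(track: CellTrack) -> TrackMetrics:
    """Travel distance, net displacement, and mean velocity of a track.

    Velocity is path length divided by total elapsed time (not the mean
    of per-step speeds, which is identical for uniform sampling);
    instantaneous per-step speeds are also returned.
    """
    if len(track.t_min) < 2:
        raise ValueError("track needs at least 2 positions")
    steps = np.diff(track.positions_um, axis=0)
    step_lengths = np.hypot(steps[:, 0], steps[:, 1])
    distance = float(step_lengths.sum())
    elapsed = float(track.t_min[-1] - track.t_min[0])
    net = float(np.hypot(*(track.positions_um[-1] - track.positions_um[0])))
    return TrackMetrics(
        cell_id=track.cell_id,
        path_distance_um=distance,
        net_displacement_um=net,
        mean_velocity_um_per_min=distance / elapsed,
        instantaneous_speeds_um_per_min=step_lengths / np.diff(track.t_min),
    )


def tracks_from_table(
    table: pd.DataFrame, sampling_interval_min: float, max_gap: int = 2
) -> list[CellTrack]:
    """Build tracks from a (cell_id, t_min, x_um, y_um) table.

    Missing samples are bridged by linear interpolation when a gap is
    at most ``max_gap`` consecutive frames; longer gaps split the track
    into separate segments (sub-id appended to the cell id as
    ``cell_id * 1000 + segment``).
    """
    tracks: list[CellTrack] = []
    for cid, sub in table.groupby("cell_id"):
        sub = sub.sort_values("t_min")
        t = sub["t_min"].to_numpy(dtype=float)
        xy = sub[["x_um", "y_um"]].to_numpy(dtype=float)
        steps = np.rint(np.diff(t) / sampling_interval_min).astype(int)
        if np.any(steps < 1):
            raise ValueError(f"cell {cid}: duplicate or non-monotone timestamps")
        # split where the gap is too long
        cut = np.nonzero(steps > max_gap + 1)[0]
        segments = np.split(np.arange(len(t)), cut + 1)
        multi = len(segments) > 1
        for s, seg in enumerate(segments):
            if len(seg) < 2:
                continue
            ts, ps = t[seg], xy[seg]
            full_t = np.arange(ts[0], ts[-1] + sampling_interval_min / 2, sampling_interval_min)
            fx = np.interp(full_t, ts, ps[:, 0])
            fy = np.interp(full_t, ts, ps[:, 1])
            out_id = int(cid) * 1000 + s if multi else int(cid)
            tracks.append(CellTrack(out_id, full_t, np.column_stack([fx, fy])))
    return tracks


# --------------------------------------------------------------------------
# group statistics
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PairwiseComparison:
    group_a: str
    group_b: str
    p_raw: float
    p_adjusted: float
    significant: bool


@dataclass(frozen=True)
class GroupComparison:
    group_means: dict[str, float]
    group_sds: dict[str, float]
    group_ns: dict[str, int]
    f_statistic: float
    p_anova: float
    pairwise: list[PairwiseComparison]
    n_comparisons: int
    alpha: float


def group_compare(
    groups: Mapping[str, Sequence[float]], alpha: float = 0.05
) -> GroupComparison:
    """One-way ANOVA with Bonferroni-adjusted pairwise t tests.

    Adjusted p is ``min(1, m * p_raw)`` with ``m`` the number of
    pairwise comparisons; significance is flagged at ``p < alpha``
    (0.05 by default).

    Raises
    ------
    ValueError
        With fewer than 2 groups, fewer than 2 values in any group, or
        zero within-group variance everywhere.
    """
    names = list(groups)
    if len(names) < 2:
        raise ValueError("need at least 2 groups")
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    for k, a in arrays.items():
        if len(a) < 2:
            raise ValueError(f"group {k!r} has fewer than 2 values")
    if all(np.var(a) == 0 for a in arrays.values()):
        raise ValueError("zero within-group variance in every group; ANOVA undefined")
    f_stat, p_anova = stats.f_oneway(*arrays.values())
    pairs = list(combinations(names, 2))
    m = len(pairs)
    pairwise = []
    for a, b in pairs:
        _, p_raw = stats.ttest_ind(arrays[a], arrays[b])
        p_adj = min(1.0, m * float(p_raw))
        pairwise.append(PairwiseComparison(a, b, float(p_raw), p_adj, p_adj < alpha))
    return GroupComparison(
        group_means={k: float(a.mean()) for k, a in arrays.items()},
        group_sds={k: float(a.std(ddof=1)) for k, a in arrays.items()},
        group_ns={k: int(len(a)) for k, a in arrays.items()},
        f_statistic=float(f_stat),
        p_anova=float(p_anova),
        pairwise=pairwise,
        n_comparisons=m,
        alpha=alpha,
    )
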