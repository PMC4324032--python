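"""Peak calling on smoothed ratio tracks and the ChIPScore statistic.

The corrected log2 ratio track is smoothed by repeated centered sliding-window
averaging (two rounds of 29 probes, about 320 bp, by default).  A probe is a
maximum (minimum) when its smoothed value is the highest (lowest) within the
smoothing window centered on it, with runs of exact ties collapsed to their
leftmost probe.  Maxima within the same merge window (300 bp) are merged,
peak height is the smoothed maximum minus the mean of the two flanking
minima, and each peak's enrichment is expressed as its ChIPScore

    ChIPScore = (height - median) / (upper quartile - median)

relative to the distribution of all peak heights in the same replicate — a
robust, unit-free distance from the bulk of (mostly noise) peaks.  Putative
binding sites are peaks scoring at least the cutoff (4.0) in both replicates,
matched across replicates by position.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.ndimage import maximum_filter1d, minimum_filter1d

from ._util import circ_distance, circ_signed_delta
from .normalize import RatioTrack


@dataclass(frozen=True)
class PeakCallingParams:
    window_probes: int = 29
    smoothing_rounds: int = 2
    merge_window: int = 300
    score_cutoff: float = 4.0
    replicate_match_dist: int = 300
    circular: bool = True

    def __post_init__(self):
        if self.window_probes < 3 or self.window_probes % 2 == 0:
            raise ValueError("window_probes must be an odd integer >= 3")
        if self.smoothing_rounds < 0:
            raise ValueError("smoothing_rounds must be >= 0")
        if self.merge_window <= 0:
            raise ValueError("merge_window must be > 0")
        if not np.isfinite(self.score_cutoff):
            raise ValueError("score_cutoff must be finite")


@dataclass(frozen=True)
class Peak:
    replicate: str
    max_position: int
    left_min_position: Optional[int]
    right_min_position: Optional[int]
    smoothed_max: float
    height: float
    chip_score: Optional[float] = None


@dataclass(frozen=True)
class ConsensusPeak:
    """A replicate-reconciled binding site: both replicate scores >= cutoff."""

    max_position: int
    chip_score: float
    rep1: Peak
    rep2: Peak


def _moving_mean(values: np.ndarray, window: int, circular: bool) -> np.ndarray:
    n = len(values)
    if window > n:
        raise ValueError(f"smoothing window ({window}) larger than track ({n} probes)")
    h = window // 2
    if circular:
        padded = np.concatenate([values[n - h :], values, values[:h]])
        return sliding_window_view(padded, window).mean(axis=-1)
    out = np.empty(n)
    out[h : n - h] = sliding_window_view(values, window).mean(axis=-1)
    for i in range(h):  # truncated edge windows
        out[i] = np.mean(values[: i + h + 1])
        out[n - 1 - i] = np.mean(values[n - 1 - i - h :])
    return out


def smooth(track: RatioTrack, params: PeakCallingParams) -> RatioTrack:
    """Centered moving mean of ``window_probes``, repeated ``smoothing_rounds``
    times; windows wrap at the origin when ``circular`` else truncate."""
    v = track.m
    for _ in range(params.smoothing_rounds):
        v = _moving_mean(v, params.window_probes, params.circular)
    return RatioTrack(track.positions, v, track.a, track.replicate, corrected=track.corrected)


def _leftmost_of_runs(cand: np.ndarray, v: np.ndarray, circular: bool) -> np.ndarray:
    """Suppress all but the leftmost probe of each run of tied candidates."""
    n = len(v)
    if circular:
        prev = np.roll(cand, 1) & (np.roll(v, 1) == v)
    else:
        prev = np.concatenate([[False], cand[:-1] & (v[:-1] == v[1:])])
    keep = cand & ~prev
    if circular and cand.any() and not keep.any():  # one run spanning the whole circle
        keep = np.zeros(n, dtype=bool)
        keep[int(np.argmax(cand))] = True
    return np.flatnonzero(keep)


def find_extrema(
    smoothed: RatioTrack, params: PeakCallingParams
) -> tuple[np.ndarray, np.ndarray]:
    """Indices of window maxima and minima of a smoothed track.

    Probe i is a maximum iff its value equals the maximum over the
    window_probes window centered on it; ties go to the leftmost probe of the
    tying run.  Minima are symmetric.
    """
    v = smoothed.m
    if params.window_probes > len(v):
        raise ValueError("window larger than track")
    mode = "wrap" if params.circular else "nearest"
    rmax = maximum_filter1d(v, size=params.window_probes, mode=mode)
    rmin = minimum_filter1d(v, size=params.window_probes, mode=mode)
    maxima = _leftmost_of_runs(v == rmax, v, params.circular)
    minima = _leftmost_of_runs(v == rmin, v, params.circular)
    return maxima, minima


def merge_peaks(
    positions: np.ndarray,
    values: Optional[np.ndarray] = None,
    params: PeakCallingParams = PeakCallingParams(),
    genome_length: Optional[int] = None,
) -> np.ndarray:
    """Single-linkage merge of maxima within ``merge_window`` bp of each other.

    Returns indices (into the input arrays) of cluster representatives: the
    highest maximum of each cluster, leftmost on ties.
    """
    positions = np.asarray(positions)
    if len(positions) == 0:
        return np.array([], dtype=np.int64)
    if values is None:
        values = np.zeros(len(positions))
    values = np.asarray(values, dtype=float)
    order = np.argsort(positions, kind="stable")
    clusters: list[list[int]] = []
    for idx in order:
        if clusters and positions[idx] - positions[clusters[-1][-1]] <= params.merge_window:
            clusters[-1].append(int(idx))
        else:
            clusters.append([int(idx)])
    if params.circular and genome_length is not None and len(clusters) > 1:
        wrap_gap = genome_length - positions[clusters[-1][-1]] + positions[clusters[0][0]]
        if wrap_gap <= params.merge_window:
            clusters[0] = clusters.pop() + clusters[0]
    reps = []
    for cluster in clusters:
        best = cluster[0]
        for idx in cluster:
            if values[idx] > values[best] or (
                values[idx] == values[best] and positions[idx] < positions[best]
            ):
                best = idx
        reps.append(best)
    return np.array(sorted(reps), dtype=np.int64)


def _flanking_minima(
    max_pos: int, min_positions: np.ndarray, circular: bool
) -> tuple[Optional[int], Optional[int]]:
    """Index of the nearest minimum on each side of a maximum (None at a
    linear track end with no minimum on that side)."""
    n = len(min_positions)
    if n == 0:
        return None, None
    j = int(np.searchsorted(min_positions, max_pos))
    left = j - 1 if j > 0 else (n - 1 if circular else None)
    right = j if j < n else (0 if circular else None)
    return left, right


def peak_height(
    smoothed_max: float,
    left_min_value: Optional[float],
    right_min_value: Optional[float],
) -> float:
    """height = smoothed maximum - mean of the two flanking minima, >= 0.

    At a non-circular track end with a single flanking minimum, that one
    value is used.
    """
    flanks = [v for v in (left_min_value, right_min_value) if v is not None]
    if not flanks:
        return 0.0
    return max(0.0, float(smoothed_max) - float(np.mean(flanks)))


def call_peaks(
    track: RatioTrack,
    params: PeakCallingParams = PeakCallingParams(),
    genome_length: Optional[int] = None,
) -> tuple[list[Peak], RatioTrack]:
    """Smooth, detect extrema, merge maxima, and measure peak heights.

    Returns the (unscored) peaks sorted by position plus the smoothed track.
    ``genome_length`` is required for circular tracks (wrap-around merging).
    """
    if params.circular and genome_length is None:
        raise ValueError("genome_length required for a circular track")
    smoothed = smooth(track, params)
    max_idx, min_idx = find_extrema(smoothed, params)
    if len(max_idx) == 0:
        return [], smoothed
    pos, v = smoothed.positions, smoothed.m
    reps = merge_peaks(pos[max_idx], v[max_idx], params, genome_length)
    min_pos, min_val = pos[min_idx], v[min_idx]
    peaks = []
    for r in reps:
        i = max_idx[r]
        li, ri = _flanking_minima(int(pos[i]), min_pos, params.circular)
        lv = None if li is None else float(min_val[li])
        rv = None if ri is None else float(min_val[ri])
        peaks.append(
            Peak(
                replicate=track.replicate,
                max_position=int(pos[i]),
                left_min_position=None if li is None else int(min_pos[li]),
                right_min_position=None if ri is None else int(min_pos[ri]),
                smoothed_max=float(v[i]),
                height=peak_height(float(v[i]), lv, rv),
            )
        )
    peaks.sort(key=lambda p: p.max_position)
    return peaks, smoothed


def chip_scores(peaks: Sequence[Peak]) -> list[Peak]:
    """Attach ChIPScores relative to the replicate's peak-height distribution.

    Quantiles use linear interpolation of order statistics.  Raises if fewer
    than 4 peaks (quartiles undefined) or if Q3 equals the median.
    """
    if len(peaks) < 4:
        raise ValueError(f"ChIPScore needs >= 4 peaks per replicate, got {len(peaks)}")
    H = np.array([p.height for p in peaks], dtype=float)
    med = float(np.quantile(H, 0.5))
    q3 = float(np.quantile(H, 0.75))
    if not q3 > med:
        raise ValueError("degenerate height distribution (upper quartile == median)")
    return [replace(p, chip_score=(p.height - med) / (q3 - med)) for p in peaks]


def consensus_peaks(
    rep1: Sequence[Peak],
    rep2: Sequence[Peak],
    params: PeakCallingParams = PeakCallingParams(),
    genome_length: Optional[int] = None,
) -> list[ConsensusPeak]:
    """Reconcile two scored replicate peak sets into consensus binding sites.

    Maxima are matched greedily by ascending pairwise distance, each peak
    used at most once, within ``replicate_match_dist``; matched pairs where
    both ChIPScores reach ``score_cutoff`` become consensus peaks positioned
    at the (rounded) midpoint with the mean of the two scores.
    """
    L = genome_length if params.circular else None
    pairs = []
    for i, p1 in enumerate(rep1):
        for j, p2 in enumerate(rep2):
            d = float(circ_distance(p1.max_position, p2.max_position, L))
            if d <= params.replicate_match_dist:
                pairs.append((d, p1.max_position, p2.max_position, i, j))
    pairs.sort()
    used1: set[int] = set()
    used2: set[int] = set()
    out = []
    for d, _, _, i, j in pairs:
        if i in used1 or j in used2:
            continue
        used1.add(i)
        used2.add(j)
        p1, p2 = rep1[i], rep2[j]
        if p1.chip_score is None or p2.chip_score is None:
            raise ValueError("consensus matching requires scored peaks")
        if p1.chip_score >= params.score_cutoff and p2.chip_score >= params.score_cutoff:
            delta = float(circ_signed_delta(p2.max_position, p1.max_position, L))
            mid = p1.max_position + delta / 2.0
            if L is not None:
                mid = (mid - 1) % L + 1
            out.append(
                ConsensusPeak(
                    max_position=int(round(mid)),
                    chip_score=(p1.chip_score + p2.chip_score) / 2.0,
                    rep1=p1,
                    rep2=p2,
                )
            )
    out.sort(key=lambda c: c.max_position)
    return out
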