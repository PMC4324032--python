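"""Two-channel normalization: MA transform and loess dye-bias correction.

The IP/WCE log2 ratio of a two-color array carries an intensity-dependent
dye bias that shows up as curvature of the MA cloud (M = log2 IP/WCE against
A = mean log2 intensity).  A robust locally weighted linear regression of M
on A estimates that bias, and subtracting the fit leaves ratios centred on
zero for unenriched probes.  Enriched probes are a small fraction of a
genome-tiling array, so the robust fit is computed on all probes without
masking.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
import statsmodels.api as sm


@dataclass
class RatioTrack:
    """Position-ordered M/A values for one replicate."""

    positions: np.ndarray
    m: np.ndarray
    a: np.ndarray
    replicate: str = ""
    corrected: bool = False

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.m = np.asarray(self.m, dtype=float)
        self.a = np.asarray(self.a, dtype=float)
        if not (len(self.positions) == len(self.m) == len(self.a)):
            raise ValueError("positions, m and a must have equal length")
        if len(self.positions) > 1 and not np.all(np.diff(self.positions) > 0):
            raise ValueError("positions must be strictly increasing")

    def __len__(self) -> int:
        return len(self.positions)


def compute_ma(signals: pd.DataFrame, replicate: Optional[str] = None) -> RatioTrack:
    """MA transform of a probe-signal table (columns position, ip, wce).

    m = log2(ip/wce), a = (log2 ip + log2 wce)/2, probe order preserved.
    Raises on any non-positive intensity, naming the offending probe.
    """
    ip = np.asarray(signals["ip"], dtype=float)
    wce = np.asarray(signals["wce"], dtype=float)
    bad = ~((ip > 0) & (wce > 0))
    if bad.any():
        i = int(np.flatnonzero(bad)[0])
        pid = signals["probe_id"].iloc[i] if "probe_id" in signals else f"#{i}"
        raise ValueError(f"non-positive intensity for probe {pid!r}")
    m = np.log2(ip) - np.log2(wce)
    a = (np.log2(ip) + np.log2(wce)) / 2.0
    if replicate is None:
        replicate = str(signals["replicate"].iloc[0]) if "replicate" in signals else ""
    return RatioTrack(np.asarray(signals["position"]), m, a, replicate=replicate)


def loess_correct(
    track: RatioTrack,
    span: float = 0.4,
    iterations: int = 3,
    delta: Optional[float] = None,
) -> RatioTrack:
    """Subtract a robust loess fit of M on A (degree-1 local regression).

    ``span`` is the fraction of probes in each local window; ``iterations``
    are bisquare robustness reweightings; ``delta`` is the interpolation
    shortcut of the fitter (default 1% of the A range — negligible error on a
    smooth bias, large speedup on dense tracks).  If the A values are all
    equal the fit is undefined and the mean of M is subtracted instead, with
    a warning.
    """
    if not 0 < span <= 1:
        raise ValueError(f"span must be in (0, 1], got {span}")
    if len(track) < 50:
        raise ValueError(f"loess correction needs >= 50 probes, got {len(track)}")
    a_range = float(np.ptp(track.a))
    if a_range == 0.0:
        warnings.warn(
            "degenerate A values (all equal); subtracting the mean of M instead of a loess fit",
            stacklevel=2,
        )
        fit = np.full(len(track), track.m.mean())
    else:
        if delta is None:
            delta = 0.01 * a_range
        fit = sm.nonparametric.lowess(
            track.m, track.a, frac=span, it=iterations, delta=delta, return_sorted=False
        )
    return RatioTrack(
        track.positions, track.m - fit, track.a, replicate=track.replicate, corrected=True
    )
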