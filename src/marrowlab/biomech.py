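"""Failure-load extraction from uniaxial compression load-displacement curves.

The vertebral failure load is the load at the first local maximum of the
load-displacement curve that is followed by a drop of strictly more than 10%
before the load first exceeds that maximum again.  Normalizing by the minimum
transverse cross-sectional area yields a size-adjusted strength in N/cm^2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

DROP_THRESHOLD = 0.10   # strict: the post-peak minimum must fall below 0.9*peak


@dataclass
class LoadCurve:
    """Recorded compression test: displacement (mm) and load (N)."""

    displacement: np.ndarray
    load: np.ndarray

    def __post_init__(self) -> None:
        self.displacement = np.asarray(self.displacement, dtype=float)
        self.load = np.asarray(self.load, dtype=float)
        if self.displacement.shape != self.load.shape:
            raise ValueError("displacement and load must have the same length")
        if self.displacement.size < 3:
            raise ValueError("a load curve needs at least three samples")
        if not np.all(np.isfinite(self.load)):
            raise ValueError("loads must be finite")
        if np.any(np.diff(self.displacement) < 0):
            raise ValueError("displacement must be non-decreasing")


@dataclass
class FailureResult:
    """Outcome of the first-peak / >10%-drop rule."""

    detected: bool
    failure_load: float | None = None          # N, from the unsmoothed record
    failure_index: int | None = None
    drop_observed: float | None = None         # fraction of the peak load
    normalized_failure_load: float | None = None   # N/cm^2


def detect_failure_load(curve: LoadCurve, smoothing_window: int = 1,
                        min_area: float | None = None) -> FailureResult:
    """Apply the first-peak rule, optionally after moving-average smoothing.

    Local maxima of the (optionally smoothed) load are scanned in order of
    displacement.  A maximum M qualifies if the minimum load after it — up to
    the point where the load first exceeds M again, or the end of the record —
    is strictly below (1 - 0.10) * M.  The reported failure load is the
    unsmoothed load at the first qualifying maximum.  If no maximum
    qualifies, an explicit no-failure result is returned.
    """
    if smoothing_window < 1 or smoothing_window % 2 == 0:
        raise ValueError("smoothing_window must be odd and >= 1")
    y = curve.load
    if smoothing_window > 1:
        kernel = np.ones(smoothing_window) / smoothing_window
        y = np.convolve(curve.load, kernel, mode="same")

    n = y.size
    for i in range(1, n - 1):
        if not (y[i] >= y[i - 1] and y[i] > y[i + 1]):
            continue
        peak = y[i]
        if peak <= 0:
            continue
        exceed = np.nonzero(y[i + 1:] > peak)[0]
        end = i + 1 + exceed[0] if exceed.size else n
        window = y[i + 1:end]
        if window.size == 0:
            continue
        trough = window.min()
        drop = 1.0 - trough / peak
        if drop > DROP_THRESHOLD:   # strict ">10%"
            fl = float(curve.load[i])
            norm = None
            if min_area is not None:
                norm = normalize_fl(fl, min_area)
            return FailureResult(detected=True, failure_load=fl,
                                 failure_index=i, drop_observed=float(drop),
                                 normalized_failure_load=norm)
    return FailureResult(detected=False)


def normalize_fl(failure_load: float, min_area: float) -> float:
    """Failure load divided by the minimum cross-sectional area, N/cm^2."""
    if min_area <= 0:
        raise ValueError("min_area must be positive")
    return float(failure_load / min_area)
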