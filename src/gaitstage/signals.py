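"""Gait-signal construction, conditioning and extrema detection.

Two one-dimensional signals summarize a sagittal-view walk:

* **Type I** — the *signed* anterior–posterior separation of the two ankles
  along the walking axis, ``x_left(t) − x_right(t)``.  Its extrema mark heel
  strikes: a maximum when the left foot leads, a minimum when the right foot
  leads, so consecutive extrema alternate in sign and their magnitudes are
  per-step foot separations.
* **Type II** — one foot's height above ground over time.  Image coordinates
  grow downward, so the raw y-trace is flipped (``max(y) − y``) to make
  ground contact a *minimum* of the signal.

Signals are amplitude-normalized (divided by max |value|), resampled onto a
uniform grid by linear interpolation, low-pass denoised by zeroing the upper
part of the Fourier spectrum, and their extrema located with a prominence- and
spacing-gated peak detector followed by a cleanup pass that enforces strict
max/min alternation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import find_peaks

from .errors import (
    DegenerateSignalError,
    GridMismatchError,
    InsufficientCyclesError,
    NonUniformGridError,
    NoOverlapError,
    OutOfSupportError,
)
from .io_keypoints import LandmarkTrack

_GRID_RTOL = 1e-9


@dataclass
class GaitSignal:
    """A named 1-D gait time series.

    kind is one of {"T1", "T2_foot1", "T2_foot2", "synthetic"}; values are in
    pixels before normalization and dimensionless after.
    """

    kind: str
    times: np.ndarray
    values: np.ndarray
    normalized: bool = False
    meta: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise GridMismatchError("times and values must have equal length")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise GridMismatchError("signal times must be strictly increasing")
        if not np.all(np.isfinite(self.values)):
            raise DegenerateSignalError("signal values must all be finite")

    @property
    def support(self) -> tuple[float, float]:
        return float(self.times[0]), float(self.times[-1])

    def is_uniform(self) -> bool:
        dt = np.diff(self.times)
        return len(dt) == 0 or np.allclose(dt, dt[0], rtol=1e-6, atol=1e-12)


@dataclass
class ExtremaSet:
    """Detected maxima and minima of a signal, plus the time-merged view.

    ``merged_*`` interleave all extrema in time order; ``merged_signs`` is +1
    for a maximum and −1 for a minimum, strictly alternating after cleanup.
    """

    maxima_times: np.ndarray
    maxima_values: np.ndarray
    minima_times: np.ndarray
    minima_values: np.ndarray
    merged_times: np.ndarray = field(default=None)  # type: ignore[assignment]
    merged_values: np.ndarray = field(default=None)  # type: ignore[assignment]
    merged_signs: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        for name in ("maxima_times", "maxima_values", "minima_times", "minima_values"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if self.merged_times is None:
            t = np.concatenate([self.maxima_times, self.minima_times])
            v = np.concatenate([self.maxima_values, self.minima_values])
            s = np.concatenate(
                [np.ones(len(self.maxima_times)), -np.ones(len(self.minima_times))]
            )
            order = np.argsort(t)
            self.merged_times = t[order]
            self.merged_values = v[order]
            self.merged_signs = s[order]
        else:
            self.merged_times = np.asarray(self.merged_times, dtype=float)
            self.merged_values = np.asarray(self.merged_values, dtype=float)
            self.merged_signs = np.asarray(self.merged_signs, dtype=float)

    @property
    def n_extrema(self) -> int:
        return len(self.merged_times)


def _common_grid(a: np.ndarray, b: np.ndarray) -> None:
    if len(a) != len(b) or not np.allclose(a, b, rtol=_GRID_RTOL, atol=1e-12):
        raise GridMismatchError(
            "tracks/signals are on different time grids; resample onto a "
            "common grid first (see resample_to_grid)"
        )


def build_type1(left_ankle: LandmarkTrack, right_ankle: LandmarkTrack) -> GaitSignal:
    """Signed inter-ankle separation along the walking (image-x) axis.

    The sign alternates as the leading foot alternates, which is what makes
    "sum of consecutive extremum magnitudes" a stride length.
    """
    _common_grid(left_ankle.times, right_ankle.times)
    values = left_ankle.x - right_ankle.x
    if np.ptp(values) <= 1e-12:
        raise DegenerateSignalError(
            "inter-ankle separation is constant; tracks look identical"
        )
    return GaitSignal(kind="T1", times=left_ankle.times.copy(), values=values,
                      meta=f"{left_ankle.name}-{right_ankle.name}")


def build_type2(
    foot: LandmarkTrack, orientation: str = "image_y_down", kind: str = "T2_foot1"
) -> GaitSignal:
    """One foot's vertical signal with ground contact at the minima.

    With image_y_down (the default), larger y means lower in the image, so
    the trace is flipped to ``max(y) − y``: zero at the lowest observed point
    (the ground) and positive during swing.  height_up passes y through.
    """
    if len(foot.times) == 0:
        raise DegenerateSignalError(f"empty track for {foot.name}")
    if orientation == "image_y_down":
        values = np.max(foot.y) - foot.y
    elif orientation == "height_up":
        values = foot.y.copy()
    else:
        raise ValueError(f"unknown orientation {orientation!r}")
    return GaitSignal(kind=kind, times=foot.times.copy(), values=values, meta=foot.name)


def normalize_amplitude(signal: GaitSignal) -> GaitSignal:
    """Scale values by 1/max|value| so the signal lies in [−1, 1]; idempotent."""
    peak = float(np.max(np.abs(signal.values)))
    if peak == 0.0:
        raise DegenerateSignalError("cannot normalize an all-zero signal")
    return replace(signal, values=signal.values / peak, normalized=True)


def overlap_window(a: GaitSignal, b: GaitSignal) -> tuple[float, float]:
    """Intersection of the two signals' time supports."""
    lo = max(a.support[0], b.support[0])
    hi = min(a.support[1], b.support[1])
    if lo >= hi:
        raise NoOverlapError(
            f"supports {a.support} and {b.support} do not overlap"
        )
    return lo, hi


def resample_to_grid(
    signal: GaitSignal, t_start: float, t_end: float, n_points: int = 1000
) -> GaitSignal:
    """Linear interpolation onto a uniform n-point grid over [t_start, t_end].

    Never extrapolates: the window must lie within the signal's support.
    """
    if n_points < 4:
        raise ValueError("n_points must be >= 4")
    lo, hi = signal.support
    if t_start < lo - 1e-12 or t_end > hi + 1e-12 or t_start >= t_end:
        raise OutOfSupportError(
            f"window [{t_start}, {t_end}] outside signal support [{lo}, {hi}]"
        )
    grid = np.linspace(t_start, t_end, n_points)
    values = np.interp(grid, signal.times, signal.values)
    return replace(signal, times=grid, values=values)


def fft_denoise(signal: GaitSignal, keep_fraction: float = 0.1) -> GaitSignal:
    """Low-pass denoise by zeroing the top (1−keep_fraction) of the spectrum.

    Keeps the Fourier coefficients whose index is at most
    ``keep_fraction × (n // 2)`` (the DC term is always kept, so the mean is
    preserved exactly); keep_fraction = 1 is the identity up to round-off.
    """
    if not 0 < keep_fraction <= 1:
        raise ValueError("keep_fraction must be in (0, 1]")
    if not signal.is_uniform():
        raise NonUniformGridError("fft_denoise requires a uniform grid; resample first")
    n = len(signal.values)
    spec = np.fft.rfft(signal.values)
    cutoff = int(np.floor(keep_fraction * (n // 2)))
    spec[cutoff + 1:] = 0.0
    values = np.fft.irfft(spec, n=n)
    return replace(signal, values=values)


def _alternate_cleanup(
    times: np.ndarray, values: np.ndarray, signs: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Force strict max/min alternation: of adjacent same-sign extrema keep
    the more extreme one (larger value for maxima, smaller for minima)."""
    keep_t: list[float] = []
    keep_v: list[float] = []
    keep_s: list[float] = []
    for t, v, s in zip(times, values, signs):
        if keep_s and keep_s[-1] == s:
            better = v > keep_v[-1] if s > 0 else v < keep_v[-1]
            if better:
                keep_t[-1], keep_v[-1] = t, v
        else:
            keep_t.append(t)
            keep_v.append(v)
            keep_s.append(s)
    return np.asarray(keep_t), np.asarray(keep_v), np.asarray(keep_s)


def find_extrema(
    signal: GaitSignal,
    min_prominence: float = 0.1,
    min_separation: float = 0.25,
) -> ExtremaSet:
    """Detect maxima and minima with prominence and spacing gates.

    min_prominence is a fraction of the signal's peak-to-peak amplitude;
    min_separation is in seconds and is converted to a sample distance on the
    (required) uniform grid.  After detection, a cleanup pass enforces strict
    alternation of maxima and minima in time order.
    """
    if not signal.is_uniform():
        raise NonUniformGridError("find_extrema requires a uniform grid")
    if len(signal.values) < 8:
        raise InsufficientCyclesError("need at least 8 samples for peak detection")
    span = float(np.ptp(signal.values))
    if span <= 0:
        raise DegenerateSignalError("constant signal has no extrema")
    dt = float(signal.times[1] - signal.times[0])
    distance = max(1, int(round(min_separation / dt)))
    prominence = min_prominence * span

    imax, _ = find_peaks(signal.values, prominence=prominence, distance=distance)
    imin, _ = find_peaks(-signal.values, prominence=prominence, distance=distance)

    t = np.concatenate([signal.times[imax], signal.times[imin]])
    v = np.concatenate([signal.values[imax], signal.values[imin]])
    s = np.concatenate([np.ones(len(imax)), -np.ones(len(imin))])
    order = np.argsort(t)
    mt, mv, ms = _alternate_cleanup(t[order], v[order], s[order])

    if len(mt) < 2:
        raise InsufficientCyclesError(
            f"only {len(mt)} extremum(a) found in {signal.kind}; need >= 2 "
            "(too few gait cycles, or prominence/spacing too strict)"
        )
    pos = ms > 0
    return ExtremaSet(
        maxima_times=mt[pos],
        maxima_values=mv[pos],
        minima_times=mt[~pos],
        minima_values=mv[~pos],
        merged_times=mt,
        merged_values=mv,
        merged_signs=ms,
    )
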