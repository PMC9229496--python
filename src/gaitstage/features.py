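"""Spatiotemporal gait features from Type I / Type II extrema.

Six classical features are computed per gait cycle from the extrema of the
two segmentation signals:

==================  ==========  ==================================================
feature             signal      definition (over time-merged extrema e_i at t_i)
==================  ==========  ==================================================
step time           Type I      t_{i+1} − t_i
stride time         Type I      t_{i+2} − t_i
step length         Type I      |e_i|  (foot separation at heel strike)
stride length       Type I      |e_i| + |e_{i+1}|
swing time          Type II     Δt of one foot's consecutive contact minima
double support      Type II     |t_i(foot1) − t_i(foot2)| of paired contact minima
==================  ==========  ==================================================

Lengths are in normalized amplitude units (no pixel-to-metre calibration is
attempted); times are in seconds.  Two definitional quirks are kept
deliberately and documented in the methods note: "swing time" as defined here
spans a full stride of one foot, and "double support" is the contact lag
between the two feet rather than a dual-stance duration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import GridMismatchError, InsufficientCyclesError, SchemaError
from .signals import ExtremaSet, GaitSignal, find_extrema

#: Canonical feature-column order of a feature table.
FEATURE_NAMES: tuple[str, ...] = (
    "step_length",
    "step_time",
    "stride_time",
    "stride_length",
    "swing_time_foot1",
    "swing_time_foot2",
    "double_support",
)

#: Optional label columns appended to a labeled table.
LABEL_COLUMNS: tuple[str, ...] = ("omega", "stage")


@dataclass(frozen=True)
class PeakConfig:
    """Peak-detection settings shared by all three signals."""

    min_prominence: float = 0.1
    min_separation_s: float = 0.25


def step_times(t1_extrema: ExtremaSet) -> np.ndarray:
    """Consecutive differences of the merged Type I extrema times."""
    t = t1_extrema.merged_times
    if len(t) < 2:
        raise InsufficientCyclesError("step time needs >= 2 Type I extrema")
    return np.diff(t)


def stride_times(t1_extrema: ExtremaSet) -> np.ndarray:
    """Every-other differences t_{i+2} − t_i of the merged Type I extrema."""
    t = t1_extrema.merged_times
    if len(t) < 3:
        raise InsufficientCyclesError("stride time needs >= 3 Type I extrema")
    return t[2:] - t[:-2]


def step_lengths(t1_extrema: ExtremaSet) -> np.ndarray:
    """Magnitude of each merged Type I extremum (foot separation at strike)."""
    v = t1_extrema.merged_values
    if len(v) < 1:
        raise InsufficientCyclesError("step length needs >= 1 Type I extremum")
    return np.abs(v)


def stride_lengths(t1_extrema: ExtremaSet) -> np.ndarray:
    """|e_i| + |e_{i+1}| over consecutive merged Type I extrema.

    Because merged extrema alternate in sign, this adds a left-leading and a
    right-leading separation — two steps, i.e. one stride.
    """
    v = np.abs(t1_extrema.merged_values)
    if len(v) < 2:
        raise InsufficientCyclesError("stride length needs >= 2 Type I extrema")
    return v[:-1] + v[1:]


def swing_times(t2_extrema_one_foot: ExtremaSet) -> np.ndarray:
    """Consecutive differences of one foot's contact (minima) times."""
    t = t2_extrema_one_foot.minima_times
    if len(t) < 2:
        raise InsufficientCyclesError("swing time needs >= 2 contact minima for the foot")
    return np.diff(t)


def double_support_times(
    t2_foot1: ExtremaSet, t2_foot2: ExtremaSet
) -> np.ndarray:
    """Lag between the two feet's paired contact minima.

    The two minima lists are first trimmed so they start within half a cycle
    of each other (the cycle estimated from foot1's median inter-contact
    interval), then paired index-by-index and truncated to the shorter list;
    absolute differences keep durations positive.
    """
    t1 = np.asarray(t2_foot1.minima_times, dtype=float)
    t2 = np.asarray(t2_foot2.minima_times, dtype=float)
    if len(t1) == 0 or len(t2) == 0:
        raise InsufficientCyclesError("double support needs contact minima for both feet")
    if len(t1) >= 2:
        half_cycle = float(np.median(np.diff(t1))) / 2.0
    elif len(t2) >= 2:
        half_cycle = float(np.median(np.diff(t2))) / 2.0
    else:
        half_cycle = np.inf
    # Trim leading minima of the earlier-starting foot until the list heads
    # are within half a cycle of each other.
    while len(t1) and len(t2) and abs(t1[0] - t2[0]) > half_cycle:
        if t1[0] < t2[0]:
            t1 = t1[1:]
        else:
            t2 = t2[1:]
    k = min(len(t1), len(t2))
    if k == 0:
        raise InsufficientCyclesError("no alignable contact minima between the feet")
    return np.abs(t1[:k] - t2[:k])


def extract_feature_table(
    t1: GaitSignal,
    t2_foot1: GaitSignal,
    t2_foot2: GaitSignal,
    peak_cfg: PeakConfig = PeakConfig(),
) -> pd.DataFrame:
    """Detect extrema on the three signals and assemble per-cycle rows.

    Row k holds the k-th available value of each of the seven feature
    streams; the table is truncated to the shortest stream, so the row count
    equals the number of complete cycles observed by every stream.
    """
    for sig in (t2_foot1, t2_foot2):
        if len(sig.times) != len(t1.times) or not np.allclose(
            sig.times, t1.times, rtol=1e-9, atol=1e-12
        ):
            raise GridMismatchError("all three signals must share one uniform grid")
    kw = dict(
        min_prominence=peak_cfg.min_prominence,
        min_separation=peak_cfg.min_separation_s,
    )
    e1 = find_extrema(t1, **kw)
    ef1 = find_extrema(t2_foot1, **kw)
    ef2 = find_extrema(t2_foot2, **kw)

    streams = {
        "step_length": step_lengths(e1),
        "step_time": step_times(e1),
        "stride_time": stride_times(e1),
        "stride_length": stride_lengths(e1),
        "swing_time_foot1": swing_times(ef1),
        "swing_time_foot2": swing_times(ef2),
        "double_support": double_support_times(ef1, ef2),
    }
    for name, values in streams.items():
        if len(values) == 0:
            raise InsufficientCyclesError(f"feature stream {name!r} is empty")
    n_rows = min(len(v) for v in streams.values())
    if n_rows == 0:
        raise InsufficientCyclesError("no complete gait cycle observed")
    data = {name: np.asarray(values[:n_rows], dtype=float) for name, values in streams.items()}
    table = pd.DataFrame(data, columns=list(FEATURE_NAMES))
    table.insert(0, "cycle_index", np.arange(n_rows))
    return table


def feature_matrix(table: pd.DataFrame) -> np.ndarray:
    """The (n_rows, 7) feature matrix in canonical column order."""
    return table.loc[:, list(FEATURE_NAMES)].to_numpy(dtype=float)


def write_feature_csv(table: pd.DataFrame, path) -> None:
    cols = ["cycle_index", *FEATURE_NAMES] + [c for c in LABEL_COLUMNS if c in table.columns]
    table.loc[:, cols].to_csv(path, index=False)


def read_feature_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(FEATURE_NAMES) - set(df.columns)
    if missing:
        raise SchemaError(f"feature CSV missing column(s) {sorted(missing)}")
    return df
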