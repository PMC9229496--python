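"""Reading, writing and selection of 2-D pose-keypoint trajectories.

The pipeline consumes the output of markerless pose estimators (OpenPose-style
per-frame JSON, or a long CSV) and only ever needs a handful of lower-body
landmarks: heels, ankles and hips, one per side.  Missing detections are kept
explicit as NaN — a zero-confidence keypoint is *missing*, never "at (0, 0)".

Coordinates follow the image convention: x grows rightward, y grows downward.
Conversion of y into a height-above-ground signal happens in :mod:`.signals`.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import (
    EmptyInputError,
    InputFormatError,
    PersonIndexError,
    SchemaError,
    TooShortTrackError,
    UnknownLandmarkError,
)

logger = logging.getLogger(__name__)

#: Landmark order of the 25-point body model used by common pose estimators.
BODY_25: tuple[str, ...] = (
    "Nose", "Neck", "RShoulder", "RElbow", "RWrist",
    "LShoulder", "LElbow", "LWrist", "MidHip", "RHip",
    "RKnee", "RAnkle", "LHip", "LKnee", "LAnkle",
    "REye", "LEye", "REar", "LEar", "LBigToe",
    "LSmallToe", "LHeel", "RBigToe", "RSmallToe", "RHeel",
)

#: The landmarks the gait pipeline actually uses.
GAIT_LANDMARKS: tuple[str, ...] = ("LHeel", "RHeel", "LAnkle", "RAnkle", "LHip", "RHip")

CSV_COLUMNS = ("frame", "time_s", "landmark", "x", "y", "confidence")


@dataclass
class KeypointSeries:
    """Per-frame landmark coordinates with timestamps.

    Attributes
    ----------
    frame_times : (n_frames,) seconds, strictly increasing.
    landmarks : ordered landmark names.
    coords : (n_frames, n_landmarks, 2) pixel x/y; NaN marks a missing
        detection.
    confidence : (n_frames, n_landmarks) in [0, 1], or None when unknown.
    fps : nominal frame rate, > 0.
    source_id : free-text provenance.
    """

    frame_times: np.ndarray
    landmarks: list[str]
    coords: np.ndarray
    confidence: np.ndarray | None = None
    fps: float = 30.0
    source_id: str = ""

    def __post_init__(self) -> None:
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        self.coords = np.asarray(self.coords, dtype=float)
        if self.confidence is not None:
            self.confidence = np.asarray(self.confidence, dtype=float)
        n, m = len(self.frame_times), len(self.landmarks)
        if self.coords.shape != (n, m, 2):
            raise SchemaError(
                f"coords shape {self.coords.shape} != ({n}, {m}, 2)"
            )
        if n > 1 and not np.all(np.diff(self.frame_times) > 0):
            raise SchemaError("frame_times must be strictly increasing")
        if self.fps <= 0:
            raise SchemaError("fps must be positive")

    @property
    def n_frames(self) -> int:
        return len(self.frame_times)

    def landmark_index(self, name: str) -> int:
        try:
            return self.landmarks.index(name)
        except ValueError:
            raise UnknownLandmarkError(
                f"unknown landmark {name!r}; available: {', '.join(self.landmarks)}"
            ) from None


@dataclass
class LandmarkTrack:
    """One landmark's (t, x, y) trajectory, gaps already resolved."""

    name: str
    times: np.ndarray
    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (len(self.times) == len(self.x) == len(self.y)):
            raise SchemaError("track arrays must have equal length")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise SchemaError("track times must be strictly increasing")


def _parse_frame_people(obj, path: str) -> list[list[float]]:
    """Extract the per-person flat keypoint lists from one frame object."""
    if isinstance(obj, dict) and "people" in obj:
        people = obj["people"]
    elif isinstance(obj, list):
        people = obj
    else:
        raise InputFormatError(f"{path}: expected a 'people' object or array")
    flat = []
    for person in people:
        if isinstance(person, dict):
            kp = person.get("pose_keypoints_2d")
            if kp is None:
                raise InputFormatError(f"{path}: person without pose_keypoints_2d")
        else:
            kp = person
        flat.append([float(v) for v in kp])
    return flat


def read_openpose_json(
    path_or_dir: str | Path,
    person_index: int = 0,
    fps: float = 30.0,
    body_model: Sequence[str] = BODY_25,
    source_id: str | None = None,
) -> KeypointSeries:
    """Read OpenPose-style keypoints into a :class:`KeypointSeries`.

    Accepts either a directory of per-frame JSON files (sorted by filename)
    or a single JSON file holding a list of frame objects.  Each frame holds
    a list of people, each with a flat ``[x1, y1, c1, x2, y2, c2, ...]``
    keypoint vector.  Zero-confidence keypoints become missing (NaN).
    """
    path = Path(path_or_dir)
    if path.is_dir():
        files = sorted(path.glob("*.json"))
        if not files:
            raise EmptyInputError(f"no JSON frame files in {path}")
        frames = []
        for f in files:
            try:
                obj = json.loads(f.read_text())
            except json.JSONDecodeError as exc:
                raise InputFormatError(f"unparsable JSON in {f}: {exc}") from exc
            frames.append(_parse_frame_people(obj, str(f)))
    else:
        try:
            obj = json.loads(path.read_text())
        except json.JSONDecodeError as exc:
            raise InputFormatError(f"unparsable JSON in {path}: {exc}") from exc
        except FileNotFoundError:
            raise InputFormatError(f"no such file: {path}") from None
        if not isinstance(obj, list):
            raise InputFormatError(f"{path}: concatenated form must be a JSON array")
        frames = [_parse_frame_people(frame, str(path)) for frame in obj]
    if not frames:
        raise EmptyInputError(f"no frames found in {path}")

    landmarks = list(body_model)
    m = len(landmarks)
    n = len(frames)
    coords = np.full((n, m, 2), np.nan)
    conf = np.full((n, m), np.nan)
    for i, people in enumerate(frames):
        if len(people) > 1:
            logger.warning(
                "frame %d has %d people; using person_index=%d", i, len(people), person_index
            )
        if not people:
            continue  # nobody detected: whole frame missing
        if person_index >= len(people):
            raise PersonIndexError(
                f"person_index {person_index} out of range: frame {i} has "
                f"{len(people)} people"
            )
        kp = people[person_index]
        if len(kp) < 3 * m:
            raise InputFormatError(
                f"frame {i}: expected {3 * m} keypoint values, got {len(kp)}"
            )
        arr = np.asarray(kp[: 3 * m]).reshape(m, 3)
        c = arr[:, 2]
        present = c > 0
        coords[i, present] = arr[present, :2]
        conf[i] = c
    times = np.arange(n) / fps
    return KeypointSeries(
        frame_times=times,
        landmarks=landmarks,
        coords=coords,
        confidence=conf,
        fps=fps,
        source_id=source_id or str(path),
    )


def read_keypoint_csv(path: str | Path) -> KeypointSeries:
    """Read a long CSV (``frame,time_s,landmark,x,y,confidence``)."""
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise InputFormatError(f"unreadable CSV {path}: {exc}") from exc
    missing = set(CSV_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {sorted(missing)}")
    if df.empty:
        raise EmptyInputError(f"{path}: no rows")

    landmarks = list(dict.fromkeys(df["landmark"]))
    frames = np.sort(df["frame"].unique())
    frame_pos = {f: i for i, f in enumerate(frames)}
    lm_pos = {name: j for j, name in enumerate(landmarks)}
    n, m = len(frames), len(landmarks)
    times = np.full(n, np.nan)
    coords = np.full((n, m, 2), np.nan)
    conf = np.full((n, m), np.nan)
    for row in df.itertuples(index=False):
        i, j = frame_pos[row.frame], lm_pos[row.landmark]
        times[i] = row.time_s
        coords[i, j, 0] = row.x
        coords[i, j, 1] = row.y
        conf[i, j] = row.confidence
    if np.isnan(times).any():
        raise SchemaError(f"{path}: frame with no time_s value")
    if n > 1 and not np.all(np.diff(times) > 0):
        raise SchemaError(f"{path}: time_s not strictly increasing across frames")
    fps = 1.0 / float(np.median(np.diff(times))) if n > 1 else 30.0
    return KeypointSeries(
        frame_times=times,
        landmarks=landmarks,
        coords=coords,
        confidence=conf,
        fps=fps,
        source_id=str(path),
    )


def write_keypoint_csv(series: KeypointSeries, path: str | Path) -> Path:
    """Write the long-CSV form; missing values become empty cells.

    Row order is deterministic: frame-major, then the series' landmark order,
    so identical series produce byte-identical files.
    """
    path = Path(path)
    records = []
    for i, t in enumerate(series.frame_times):
        for j, name in enumerate(series.landmarks):
            x, y = series.coords[i, j]
            c = series.confidence[i, j] if series.confidence is not None else np.nan
            records.append((i, t, name, x, y, c))
    df = pd.DataFrame.from_records(records, columns=CSV_COLUMNS)
    # %.17g round-trips every finite double exactly
    df.to_csv(path, index=False, na_rep="", float_format="%.17g")
    return path


def _interpolate_track(times: np.ndarray, v: np.ndarray, present: np.ndarray) -> np.ndarray:
    """Linear-in-time fill of interior gaps; caller trims the edges."""
    return np.interp(times, times[present], v[present])


def select_landmarks(
    series: KeypointSeries,
    names: Iterable[str],
    gap_policy: str = "interpolate",
) -> list[LandmarkTrack]:
    """Extract per-landmark tracks, resolving missing frames.

    gap_policy="interpolate" fills interior gaps linearly in time and drops
    leading/trailing gaps; "drop" removes every frame missing in *any*
    requested landmark, so all returned tracks share one grid.
    """
    names = list(names)
    if gap_policy not in ("interpolate", "drop"):
        raise ValueError(f"gap_policy must be 'interpolate' or 'drop', got {gap_policy!r}")
    idx = [series.landmark_index(n) for n in names]
    times = series.frame_times

    tracks: list[LandmarkTrack] = []
    if gap_policy == "drop":
        present = np.ones(series.n_frames, dtype=bool)
        for j in idx:
            present &= np.isfinite(series.coords[:, j]).all(axis=1)
        if present.sum() < 4:
            raise TooShortTrackError(
                f"fewer than 4 frames survive gap_policy=drop for {names}"
            )
        for name, j in zip(names, idx):
            tracks.append(
                LandmarkTrack(
                    name=name,
                    times=times[present],
                    x=series.coords[present, j, 0],
                    y=series.coords[present, j, 1],
                )
            )
        return tracks

    for name, j in zip(names, idx):
        present = np.isfinite(series.coords[:, j]).all(axis=1)
        if present.sum() < 4:
            raise TooShortTrackError(
                f"landmark {name!r} has only {int(present.sum())} present frames (< 4)"
            )
        lo, hi = np.flatnonzero(present)[[0, -1]]
        sl = slice(lo, hi + 1)
        x = _interpolate_track(times[sl], series.coords[sl, j, 0], present[sl])
        y = _interpolate_track(times[sl], series.coords[sl, j, 1], present[sl])
        tracks.append(LandmarkTrack(name=name, times=times[sl], x=x, y=y))
    return tracks
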