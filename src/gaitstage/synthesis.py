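"""Severity-graded synthetic gait generation.

The central idea: given one Parkinsonian gait exemplar and one normal gait
exemplar, reduced to normalized segmentation signals on a shared uniform time
grid, a continuum of intermediate gaits is manufactured by pointwise linear
combination

    l_C(t) = omega * l_P(t) + (1 - omega) * l_N(t),        0 <= omega <= 1,

so omega = 0 reproduces the normal gait and omega = 1 the Parkinsonian one.
Each combined gait is run through the full feature extractor, and every
resulting per-cycle feature row is labeled with a four-level severity stage
(I healthy, II mild, III moderate, IV severe) derived from omega by
quarter-interval binning on the Hoehn & Yahr pattern:

    I: 0.00 <= omega < 0.25      II: 0.25 <= omega < 0.50
    III: 0.50 <= omega < 0.75    IV: 0.75 <= omega <= 1.00

The module also ships a parametric sagittal-view gait simulator that serves
as the packaged exemplar source: antiphase sinusoidal ankle x-trajectories of
configurable step amplitude and cadence, rectified-sinusoid foot clearance in
image-down y, Gaussian pixel jitter and an optional tremor component.  A
Parkinsonian preset shortens steps, reduces clearance, raises cadence and
adds tremor relative to the normal preset.  Real keypoint recordings are
accepted interchangeably through :mod:`.io_keypoints`.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, replace as dc_replace

import numpy as np
import pandas as pd

from .errors import ConfigError, GridMismatchError, InsufficientCyclesError
from .features import PeakConfig, extract_feature_table
from .io_keypoints import BODY_25, KeypointSeries, select_landmarks
from .signals import (
    GaitSignal,
    build_type1,
    build_type2,
    fft_denoise,
    normalize_amplitude,
    overlap_window,
    resample_to_grid,
)


class Stage(enum.Enum):
    """Four-level severity stage with its clinical meaning."""

    I = "healthy"
    II = "mild"
    III = "moderate"
    IV = "severe"

    @property
    def level(self) -> str:
        return self.name

    @property
    def meaning(self) -> str:
        return self.value

    @property
    def ordinal(self) -> int:
        return ("I", "II", "III", "IV").index(self.name)


STAGE_ORDER: tuple[Stage, ...] = (Stage.I, Stage.II, Stage.III, Stage.IV)


def omega_grid(n_combinations: int) -> np.ndarray:
    """n evenly spaced mixing weights spanning [0, 1] inclusive."""
    if n_combinations < 2:
        raise ConfigError("n_combinations must be >= 2")
    return np.linspace(0.0, 1.0, n_combinations)


def stage_label(omega: float) -> Stage:
    """Quarter-interval severity binning of the mixing weight."""
    if not 0.0 <= omega <= 1.0:
        raise ConfigError(f"omega must be in [0, 1], got {omega}")
    if omega < 0.25:
        return Stage.I
    if omega < 0.50:
        return Stage.II
    if omega < 0.75:
        return Stage.III
    return Stage.IV


def linear_combine(sig_p: GaitSignal, sig_n: GaitSignal, omega: float) -> GaitSignal:
    """Pointwise convex combination of a Parkinsonian and a normal signal.

    Both signals must be normalized and share the identical uniform grid.
    The endpoints are exact: omega = 0 returns the normal values bit-for-bit,
    omega = 1 the Parkinsonian ones.
    """
    if not 0.0 <= omega <= 1.0:
        raise ConfigError(f"omega must be in [0, 1], got {omega}")
    if len(sig_p.times) != len(sig_n.times) or not np.array_equal(sig_p.times, sig_n.times):
        raise GridMismatchError("linear_combine requires identical time grids")
    if omega == 0.0:
        values = sig_n.values.copy()
    elif omega == 1.0:
        values = sig_p.values.copy()
    else:
        values = omega * sig_p.values + (1.0 - omega) * sig_n.values
    return GaitSignal(
        kind="synthetic",
        times=sig_p.times.copy(),
        values=values,
        normalized=sig_p.normalized and sig_n.normalized,
        meta=f"omega={omega:g} of ({sig_p.meta} | {sig_n.meta})",
    )


# ---------------------------------------------------------------------------
# Parametric gait simulator
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GaitSimParams:
    """Parameters of the sagittal-view keypoint simulator.

    cadence_hz is the stride frequency (full left+right cycles per second);
    step amplitude and foot clearance are pixel half-amplitudes;
    phase_offset_rad is the contact-phase offset between the feet (pi = the
    feet alternate evenly); jitter is i.i.d. Gaussian pixel noise on every
    coordinate; tremor is a sinusoidal oscillation added to the forward
    coordinates of the distal landmarks.
    """

    cadence_hz: float = 0.9
    step_amplitude_px: float = 90.0
    foot_clearance_px: float = 35.0
    phase_offset_rad: float = math.pi
    jitter_sd_px: float = 1.0
    tremor_amplitude_px: float = 0.0
    tremor_hz: float = 5.0
    duration_s: float = 14.0
    fps: float = 30.0
    seed: int = 22

    def validate(self) -> None:
        positive = {
            "cadence_hz": self.cadence_hz,
            "step_amplitude_px": self.step_amplitude_px,
            "foot_clearance_px": self.foot_clearance_px,
            "duration_s": self.duration_s,
            "fps": self.fps,
        }
        for name, value in positive.items():
            if value <= 0:
                raise ConfigError(f"{name} must be positive, got {value}")
        for name, value in {
            "jitter_sd_px": self.jitter_sd_px,
            "tremor_amplitude_px": self.tremor_amplitude_px,
            "tremor_hz": self.tremor_hz,
        }.items():
            if value < 0:
                raise ConfigError(f"{name} must be nonnegative, got {value}")
        if self.fps * self.duration_s < 64:
            raise ConfigError("fps * duration_s must give at least 64 samples")


def normal_gait(seed: int = 22, **overrides) -> GaitSimParams:
    """Preset emulating an unimpaired treadmill walk."""
    return dc_replace(GaitSimParams(seed=seed), **overrides)


def parkinsonian_gait(seed: int = 22, **overrides) -> GaitSimParams:
    """Preset emulating a Parkinsonian gait: short shuffling steps (0.39x the
    normal step amplitude), reduced foot clearance (0.34x), faster cadence
    (1.39x) and a resting-tremor component."""
    params = GaitSimParams(
        cadence_hz=1.25,
        step_amplitude_px=35.0,
        foot_clearance_px=12.0,
        jitter_sd_px=2.0,
        tremor_amplitude_px=4.0,
        tremor_hz=5.0,
        seed=seed,
    )
    return dc_replace(params, **overrides)


# Static scene layout (pixels, image convention: y grows downward).
_HIP_X, _HIP_Y = 400.0, 300.0
_GROUND_Y = 600.0
_HEEL_DX, _HEEL_DY = -12.0, 8.0
_HIP_HALF_WIDTH = 12.0


def simulate_gait(params: GaitSimParams) -> KeypointSeries:
    """Deterministic-given-seed keypoint series for one simulated walk.

    Ankle forward (x) trajectories are antiphase sinusoids of half-amplitude
    ``step_amplitude_px`` about the hip midline; ankle/heel vertical (y)
    trajectories are rectified sinusoids of height ``foot_clearance_px``
    above the ground line, one ground contact per stride per foot, the two
    feet offset by ``phase_offset_rad``.  All coordinates then receive
    Gaussian jitter, and distal x additionally receives the tremor sinusoid.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    n = int(round(params.fps * params.duration_s))
    t = np.arange(n) / params.fps
    f = params.cadence_hz

    forward = params.step_amplitude_px * np.sin(2 * np.pi * f * t)
    lx = _HIP_X + forward
    rx = _HIP_X - forward

    # One contact (height == 0) per stride per foot; the second foot's
    # contacts lag the first's by phase_offset_rad / (2 pi f) seconds.
    h1 = params.foot_clearance_px * np.abs(np.sin(np.pi * f * t))
    h2 = params.foot_clearance_px * np.abs(
        np.sin(np.pi * f * t + params.phase_offset_rad / 2.0)
    )
    ly = _GROUND_Y - h1
    ry = _GROUND_Y - h2

    tremor = params.tremor_amplitude_px * np.sin(2 * np.pi * params.tremor_hz * t)

    coords = np.full((n, len(BODY_25), 2), np.nan)
    conf = np.zeros((n, len(BODY_25)))

    def put(name: str, x: np.ndarray, y: np.ndarray) -> None:
        j = BODY_25.index(name)
        coords[:, j, 0] = x
        coords[:, j, 1] = y
        conf[:, j] = 1.0

    put("LAnkle", lx + tremor, ly)
    put("RAnkle", rx + tremor, ry)
    put("LHeel", lx + tremor + _HEEL_DX, ly + _HEEL_DY)
    put("RHeel", rx + tremor + _HEEL_DX, ry + _HEEL_DY)
    put("LHip", np.full(n, _HIP_X + _HIP_HALF_WIDTH), np.full(n, _HIP_Y))
    put("RHip", np.full(n, _HIP_X - _HIP_HALF_WIDTH), np.full(n, _HIP_Y))

    present = conf > 0
    coords[present] += rng.normal(0.0, params.jitter_sd_px, size=(int(present.sum()), 2))

    return KeypointSeries(
        frame_times=t,
        landmarks=list(BODY_25),
        coords=coords,
        confidence=conf,
        fps=params.fps,
        source_id=f"simulated(cadence={f:g},amp={params.step_amplitude_px:g},seed={params.seed})",
    )


# ---------------------------------------------------------------------------
# Exemplar preparation and dataset assembly
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SignalConfig:
    """Signal-conditioning settings used when turning keypoints into the
    three segmentation signals."""

    fft_keep_fraction: float = 0.1
    resample_points: int = 1000
    t2_landmarks: tuple[str, str] = ("LHeel", "RHeel")


GaitTriple = tuple[GaitSignal, GaitSignal, GaitSignal]


def gait_signals_from_keypoints(
    series: KeypointSeries, cfg: SignalConfig = SignalConfig()
) -> GaitTriple:
    """Raw (un-resampled, un-normalized) T1 and per-foot T2 signals."""
    la, ra = select_landmarks(series, ["LAnkle", "RAnkle"], gap_policy="drop")
    f1, f2 = select_landmarks(series, list(cfg.t2_landmarks), gap_policy="drop")
    t1 = build_type1(la, ra)
    t2a = build_type2(f1, kind="T2_foot1")
    t2b = build_type2(f2, kind="T2_foot2")
    return t1, t2a, t2b


def _condition(triple: GaitTriple, t_lo: float, t_hi: float, cfg: SignalConfig) -> GaitTriple:
    out = []
    for sig in triple:
        sig = resample_to_grid(sig, t_lo, t_hi, cfg.resample_points)
        sig = fft_denoise(sig, cfg.fft_keep_fraction)
        out.append(normalize_amplitude(sig))
    return tuple(out)  # type: ignore[return-value]


def prepare_exemplars(
    series_p: KeypointSeries,
    series_n: KeypointSeries,
    cfg: SignalConfig = SignalConfig(),
) -> tuple[GaitTriple, GaitTriple]:
    """Reduce two keypoint recordings to combination-ready signal triples.

    Both gaits' signals are resampled onto one uniform grid spanning the
    window where *both* recordings have detections, low-pass denoised, and
    amplitude-normalized — the preconditions of :func:`linear_combine`.
    """
    trip_p = gait_signals_from_keypoints(series_p, cfg)
    trip_n = gait_signals_from_keypoints(series_n, cfg)
    lo = -np.inf
    hi = np.inf
    for a in trip_p:
        for b in trip_n:
            w_lo, w_hi = overlap_window(a, b)
            lo, hi = max(lo, w_lo), min(hi, w_hi)
    for sig in (*trip_p, *trip_n):
        lo = max(lo, sig.support[0])
        hi = min(hi, sig.support[1])
    return _condition(trip_p, lo, hi, cfg), _condition(trip_n, lo, hi, cfg)


def prepare_single_gait(
    series: KeypointSeries, cfg: SignalConfig = SignalConfig()
) -> GaitTriple:
    """Condition one recording on its own support (for feature extraction)."""
    triple = gait_signals_from_keypoints(series, cfg)
    lo = max(sig.support[0] for sig in triple)
    hi = min(sig.support[1] for sig in triple)
    return _condition(triple, lo, hi, cfg)


def build_synthetic_dataset(
    gait_p: GaitTriple,
    gait_n: GaitTriple,
    n_combinations: int,
    peak_cfg: PeakConfig = PeakConfig(),
) -> pd.DataFrame:
    """Labeled per-cycle feature table over the full omega grid.

    For each omega, all three segmentation signals are combined with the
    *same* weight, the combined curves are run through the feature extractor,
    and every row is tagged with omega and its severity stage.
    """
    tables = []
    for omega in omega_grid(n_combinations):
        combined = [linear_combine(p, n, float(omega)) for p, n in zip(gait_p, gait_n)]
        try:
            table = extract_feature_table(*combined, peak_cfg=peak_cfg)
        except InsufficientCyclesError as exc:
            raise InsufficientCyclesError(f"omega={omega:g}: {exc}") from exc
        table["omega"] = float(omega)
        table["stage"] = stage_label(float(omega)).name
        tables.append(table)
    return pd.concat(tables, ignore_index=True)
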