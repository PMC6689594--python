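"""Synthetic swallow cohorts with a known forward model.

No public dataset pairs neck accelerometry with frame-by-frame hyoid
annotations, so every downstream stage is exercised against a simulator whose
ground truth is known exactly:

1. A smooth hyoid trajectory in image pixels — the bone rises
   superior-anteriorly and returns to (near) its start, modelled per axis as
   a logistic rise/fall bump, the superior component leading the anterior one
   by a short lag.
2. A latent sensor displacement that is an affine map of that trajectory per
   anatomical axis.  Acceleration is its exact second time derivative
   (cubic-spline interpolated to the sensor rate), so noise-free signals
   double-integrate back to the latent displacement — the recovery property
   the whole method rests on.
3. Band-limited vibration plus white sensor noise on all three channels; the
   medial-lateral channel carries noise only (hyoid movement is 2-D).
4. Multi-rater annotations: the true trajectory plus i.i.d. Gaussian pixel
   jitter per rater, rounded to integer pixels, emulating human labelling
   variability.

Default geometry follows the study conditions: ~0.88 s swallows annotated at
30 Hz on 792x1008-pixel frames, signals at 20 kHz, a 49-pixel hyoid extent,
and a cohort that is ~57% male with an ~18.4% stroke history.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy.interpolate import CubicSpline

from .preprocess import RawSwallowSignal
from .targets import HyoidAnnotation

__all__ = [
    "SwallowSimConfig",
    "SimulatedSwallow",
    "Cohort",
    "simulate_trajectory",
    "trajectory_to_signal",
    "apply_rater_jitter",
    "simulate_swallow",
    "simulate_cohort",
]


@dataclass
class SwallowSimConfig:
    """Knobs of the synthetic swallow generator.

    Durations are drawn N(duration_mean, duration_sd) and rejected until they
    span more than two video frames.  ``excursion_px`` is the (anterior,
    superior) peak hyoid displacement in pixels; per-participant and
    per-swallow multiplicative factors keep realised peaks within +-20% of it.
    ``vibration_snr`` is the clean-signal-to-vibration RMS amplitude ratio
    (0 disables vibration); ``sensor_noise_sd`` is white noise in acceleration
    units; ``rater_jitter_sd`` is labelling noise in pixels.
    """

    duration_mean: float = 0.88
    duration_sd: float = 0.12
    frame_rate: float = 30.0
    signal_rate: float = 20000.0
    image_size: tuple[int, int] = (792, 1008)   # (width, height) px
    hyoid_extent: float = 49.0
    excursion_px: tuple[float, float] = (25.0, 40.0)
    si_ap_lag: float = 0.08            # s, superior movement leads anterior
    vibration_snr: float = 10.0
    vibration_band: tuple[float, float] = (50.0, 500.0)   # Hz
    sensor_noise_sd: float = 0.05
    rater_jitter_sd: float = 0.0
    n_raters: int = 3
    signal_gain: tuple[float, float] = (1e-3, 1e-3)   # disp units per px (A-P, S-I)
    gravity_bias: float = 0.0          # constant A-P acceleration offset
    vertebral_length_px: float = 120.0
    vertebral_length_sd: float = 4.0
    stroke_proportion: float = 0.1842
    male_proportion: float = 0.5702
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_mean <= 0:
            raise ValueError("duration_mean must be positive")
        if self.signal_rate <= self.frame_rate:
            raise ValueError("signal_rate must exceed frame_rate")
        for name in ("duration_sd", "sensor_noise_sd", "rater_jitter_sd",
                     "vibration_snr"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if min(self.excursion_px) < 0:
            raise ValueError("excursion_px components must be non-negative")

    def with_(self, **kw) -> "SwallowSimConfig":
        return replace(self, **kw)


@dataclass
class SimulatedSwallow:
    """One synthetic swallow: signal, ground truth, and rater annotations."""

    signal: RawSwallowSignal
    true_trajectory: np.ndarray           # (n_frames, 2) pixels
    annotations: list[HyoidAnnotation]
    participant_id: str
    gender: str = "male"
    stroke_history: bool = False
    swallow_id: str = ""

    def __post_init__(self) -> None:
        n = self.true_trajectory.shape[0]
        if n < 2:
            raise ValueError("trajectory needs at least 2 frames")
        for ann in self.annotations:
            if ann.n_frames != n:
                raise ValueError("annotation frame count mismatch")

    @property
    def n_frames(self) -> int:
        return self.true_trajectory.shape[0]


@dataclass
class Cohort:
    swallows: list[SimulatedSwallow]
    config: SwallowSimConfig

    @property
    def metadata(self) -> pd.DataFrame:
        return pd.DataFrame({
            "swallow_id": [s.swallow_id for s in self.swallows],
            "participant_id": [s.participant_id for s in self.swallows],
            "gender": [s.gender for s in self.swallows],
            "stroke_history": [s.stroke_history for s in self.swallows],
        })

    def __len__(self) -> int:
        return len(self.swallows)


def _bump(t: np.ndarray, onset: float, offset: float, tau: float) -> np.ndarray:
    """Smooth rise-and-fall in [0, 1]: product of two logistics, peak 1."""
    f = 1.0 / (1.0 + np.exp(-(t - onset) / tau))
    f *= 1.0 / (1.0 + np.exp(-(offset - t) / tau))
    peak = f.max()
    if peak <= 0:
        raise ValueError("degenerate bump")
    return f / peak


def _draw_n_frames(config: SwallowSimConfig, rng: np.random.Generator) -> int:
    for _ in range(1000):
        dur = rng.normal(config.duration_mean, config.duration_sd)
        n = int(np.floor(dur * config.frame_rate))
        if n > 2:
            return n
    raise RuntimeError("could not draw a duration longer than 2 frames")


def simulate_trajectory(config: SwallowSimConfig, rng: np.random.Generator,
                        start: np.ndarray | None = None,
                        duration: float | None = None,
                        excursion_scale: float = 1.0) -> np.ndarray:
    """Per-frame hyoid anterior-point trajectory in image pixels.

    The bone moves superior-anteriorly (image up-left, patient facing left)
    and returns near its start; the superior bump leads the anterior one by
    ``si_ap_lag``.  The frame count is floor(duration * frame_rate), with the
    duration drawn N(duration_mean, duration_sd) unless given; durations
    spanning two frames or fewer are redrawn (or rejected when explicit).
    Returns shape (n_frames, 2).
    """
    if min(config.excursion_px) < 0:
        raise ValueError("excursion must be non-negative")
    if duration is not None:
        n_frames = int(np.floor(duration * config.frame_rate))
        if n_frames < 2:
            raise ValueError("duration spans fewer than 2 frames")
    else:
        n_frames = _draw_n_frames(config, rng)
    w, h = config.image_size
    if start is None:
        start = np.array([0.55 * w, 0.55 * h])
    t = np.arange(n_frames) / config.frame_rate
    duration = n_frames / config.frame_rate
    tau = rng.uniform(0.035, 0.055)
    onset_si = rng.uniform(0.18, 0.26) * duration
    offset_si = rng.uniform(0.60, 0.72) * duration
    onset_ap = onset_si + config.si_ap_lag
    offset_ap = min(offset_si + config.si_ap_lag, 0.92 * duration)
    ant, sup = (e * excursion_scale for e in config.excursion_px)
    ant_disp = ant * _bump(t, onset_ap, offset_ap, tau) if ant > 0 else np.zeros(n_frames)
    sup_disp = sup * _bump(t, onset_si, offset_si, tau) if sup > 0 else np.zeros(n_frames)
    # anterior = image-left (-x), superior = image-up (-y)
    traj = np.column_stack([start[0] - ant_disp, start[1] - sup_disp])
    return traj


def _bandlimited_noise(n: int, rate: float, band: tuple[float, float],
                       rms: float, rng: np.random.Generator) -> np.ndarray:
    white = rng.standard_normal(n)
    nyq = rate / 2.0
    lo, hi = min(band[0], 0.9 * nyq), min(band[1], 0.95 * nyq)
    b, a = sps.butter(2, [lo / nyq, hi / nyq], btype="band")
    x = sps.lfilter(b, a, white)
    std = x.std()
    return x * (rms / std) if std > 0 else x


def trajectory_to_signal(trajectory: np.ndarray, config: SwallowSimConfig,
                         rng: np.random.Generator) -> RawSwallowSignal:
    """Forward model: hyoid trajectory -> tri-axial acceleration at 20 kHz.

    The latent sensor displacement on the A-P (resp. S-I) channel is
    ``signal_gain`` times the anterior (resp. superior) pixel excursion; the
    M-L channel carries no trajectory information.  The trajectory is
    interpolated with a clamped cubic spline (zero velocity at both ends,
    matching the integrator's v(0)=0 convention) and differentiated twice
    analytically, then vibration and sensor noise are added.
    """
    traj = np.asarray(trajectory, dtype=float)
    if np.isnan(traj).any():
        raise ValueError("trajectory contains NaN")
    if traj.shape[0] < 2:
        raise ValueError("trajectory needs at least 2 frames")
    n_frames = traj.shape[0]
    # anatomical excursions in pixels, zero at t=0
    ant = traj[0, 0] - traj[:, 0]
    sup = traj[0, 1] - traj[:, 1]
    # hold the final position for one extra frame so the signal spans
    # n_frames full video frames
    knots = np.arange(n_frames + 1) / config.frame_rate
    n_samples = int(round(n_frames * config.signal_rate / config.frame_rate))
    t_sig = np.arange(n_samples) / config.signal_rate
    channels = []
    for axis_disp, gain in zip((ant, sup), config.signal_gain):
        latent = np.append(axis_disp, axis_disp[-1]) * gain
        spline = CubicSpline(knots, latent, bc_type="clamped")
        channels.append(spline(t_sig, 2))
    channels.append(np.zeros(n_samples))    # M-L: no trajectory signal
    data = np.column_stack(channels)
    if config.vibration_snr > 0:
        clean_rms = np.sqrt(np.mean(data[:, :2] ** 2))
        if clean_rms > 0:
            rms = clean_rms / config.vibration_snr
            for ch in range(3):
                data[:, ch] += _bandlimited_noise(
                    n_samples, config.signal_rate, config.vibration_band,
                    rms, rng)
    if config.sensor_noise_sd > 0:
        data += rng.normal(0.0, config.sensor_noise_sd, size=data.shape)
    if config.gravity_bias:
        data[:, 0] += config.gravity_bias
    return RawSwallowSignal(data, config.signal_rate)


def apply_rater_jitter(trajectory: np.ndarray, jitter_sd: float,
                       rng: np.random.Generator,
                       c2: np.ndarray, c4: np.ndarray,
                       rater_id: str = "rater0") -> HyoidAnnotation:
    """Emulate one human rater: true point + Gaussian jitter, integer pixels."""
    if jitter_sd < 0:
        raise ValueError("jitter_sd must be >= 0")
    traj = np.asarray(trajectory, dtype=float)
    noisy = traj + rng.normal(0.0, jitter_sd, size=traj.shape)
    return HyoidAnnotation(np.round(noisy), c2, c4, rater_id=rater_id)


@dataclass
class _Participant:
    participant_id: str
    gender: str
    stroke_history: bool
    c2: np.ndarray
    c4: np.ndarray
    hyoid_start: np.ndarray
    excursion_factor: float


def _draw_participant(pid: str, config: SwallowSimConfig,
                      rng: np.random.Generator) -> _Participant:
    w, h = config.image_size
    gender = "male" if rng.random() < config.male_proportion else "female"
    stroke = bool(rng.random() < config.stroke_proportion)
    L = max(rng.normal(config.vertebral_length_px, config.vertebral_length_sd),
            10.0)
    tilt = np.deg2rad(rng.normal(0.0, 3.0))
    c4 = np.array([rng.normal(0.62 * w, 8.0), rng.normal(0.58 * h, 10.0)])
    v = np.array([np.sin(tilt), -np.cos(tilt)])     # superior, image up
    u = np.array([v[1], -v[0]])                     # anterior, image left
    c2 = c4 + L * v
    start = c4 + (0.9 + rng.normal(0, 0.03)) * L * u \
        + (0.25 + rng.normal(0, 0.03)) * L * v
    return _Participant(pid, gender, stroke, c2, c4, start,
                        excursion_factor=rng.normal(1.0, 0.03))


def simulate_swallow(config: SwallowSimConfig, rng: np.random.Generator,
                     participant: _Participant,
                     swallow_id: str = "s0") -> SimulatedSwallow:
    scale = participant.excursion_factor * rng.uniform(0.95, 1.05)
    traj = simulate_trajectory(config, rng, start=participant.hyoid_start,
                               excursion_scale=scale)
    sig = trajectory_to_signal(traj, config, rng)
    sig.swallow_id = swallow_id
    sig.participant_id = participant.participant_id
    anns = [
        apply_rater_jitter(traj, config.rater_jitter_sd, rng,
                           participant.c2, participant.c4,
                           rater_id=f"rater{r}")
        for r in range(config.n_raters)
    ]
    return SimulatedSwallow(sig, traj, anns, participant.participant_id,
                            participant.gender, participant.stroke_history,
                            swallow_id)


def simulate_cohort(n_participants: int, swallows_per_participant: int,
                    config: SwallowSimConfig | None = None,
                    seed: int | None = None) -> Cohort:
    """Generate a reproducible cohort of paired signals and annotations."""
    if config is None:
        config = SwallowSimConfig()
    if n_participants < 1:
        raise ValueError("need at least one participant")
    if swallows_per_participant <= 0:
        raise ValueError("swallows_per_participant must be positive")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    swallows: list[SimulatedSwallow] = []
    for p in range(n_participants):
        part = _draw_participant(f"p{p:03d}", config, rng)
        for s in range(swallows_per_participant):
            swallows.append(simulate_swallow(
                config, rng, part, swallow_id=f"p{p:03d}_s{s:02d}"))
    return Cohort(swallows, config)
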