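"""Raw tri-axial accelerometry -> per-frame 10-dimensional feature sequences.

The sensor chain records neck-surface acceleration on the anterior-posterior
(A-P), superior-inferior (S-I) and medial-lateral (M-L) axes at 20 kHz.  To
feed a frame-rate regressor the signal is decimated to an intermediate rate
(4 kHz), double-integrated to displacement with the trapezoid rule, and cut
into consecutive video-frame slices (133 samples per 30 Hz frame at 4 kHz).
Each frame contributes ten features: the three displacement values at the end
of the slice, the per-slice mean and variance of the raw acceleration on each
axis, and the frame time t.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps
from scipy.integrate import cumulative_trapezoid

__all__ = [
    "RawSwallowSignal",
    "FrameFeatureSequence",
    "FeatureNormalizer",
    "FEATURE_NAMES",
    "decimate",
    "double_integrate",
    "slice_frames",
    "slice_stats",
    "build_features",
    "samples_per_frame",
]

CHANNEL_NAMES = ("ap", "si", "ml")

FEATURE_NAMES = (
    "dis_ap", "dis_si", "dis_ml",
    "mean_ap", "mean_si", "mean_ml",
    "var_ap", "var_si", "var_ml",
    "t",
)


@dataclass
class RawSwallowSignal:
    """Tri-axial acceleration time series.

    ``data`` has shape (n_samples, 3) with columns A-P, S-I, M-L in
    acceleration units; ``sampling_rate`` in Hz.
    """

    data: np.ndarray
    sampling_rate: float
    swallow_id: str = ""
    participant_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[1] != 3:
            raise ValueError("signal data must have shape (n_samples, 3)")
        if self.data.shape[0] < 2:
            raise ValueError("signal needs at least 2 samples")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate


@dataclass
class FrameFeatureSequence:
    """Per-frame feature vectors x(t), shape (n_frames, 10).

    Column order follows :data:`FEATURE_NAMES`: displacement (A-P, S-I, M-L),
    slice means, slice variances, frame time in seconds.
    """

    values: np.ndarray
    frame_rate: float = 30.0
    swallow_id: str = ""
    participant_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != len(FEATURE_NAMES):
            raise ValueError(
                f"feature array must have {len(FEATURE_NAMES)} columns"
            )

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]


def samples_per_frame(intermediate_rate: float = 4000.0,
                      frame_rate: float = 30.0) -> int:
    """Number of intermediate-rate samples spanned by one video frame.

    At 4 kHz against a 30 Hz video this is floor(4000/30) = 133.
    """
    return int(intermediate_rate // frame_rate)


def decimate(sig: RawSwallowSignal, target_rate: float,
             cutoff_fraction: float = 0.8, numtaps: int = 151) -> RawSwallowSignal:
    """Anti-alias low-pass then subsample to ``target_rate``.

    The low-pass is a zero-phase FIR at ``cutoff_fraction`` of the target
    Nyquist frequency (default 0.8, i.e. 1.6 kHz when going to 4 kHz).
    ``target_rate`` must divide the input rate.
    """
    ratio = sig.sampling_rate / target_rate
    q = int(round(ratio))
    if q < 1 or abs(ratio - q) > 1e-9:
        raise ValueError(
            f"target rate {target_rate} does not divide sampling rate "
            f"{sig.sampling_rate}")
    if q == 1:
        return RawSwallowSignal(sig.data.copy(), target_rate,
                                sig.swallow_id, sig.participant_id)
    cutoff = cutoff_fraction * (target_rate / 2.0)
    taps = sps.firwin(numtaps, cutoff, fs=sig.sampling_rate)
    filtered = sps.filtfilt(taps, [1.0], sig.data, axis=0)
    return RawSwallowSignal(filtered[::q], target_rate,
                            sig.swallow_id, sig.participant_id)


def double_integrate(channel: np.ndarray, sampling_rate: float,
                     v0: float = 0.0, d0: float = 0.0) -> np.ndarray:
    """Acceleration -> displacement via two cumulative trapezoid passes.

    Initial velocity and displacement default to zero: neither is observable
    from the sensor, and swallows are short enough (~0.88 s) that the
    resulting drift stays small.  ``v0``/``d0`` exist so analytic oracles can
    inject their true initial conditions.
    """
    a = np.asarray(channel, dtype=float)
    if a.ndim != 1 or a.size < 2:
        raise ValueError("channel must be 1-D with length >= 2")
    if np.isnan(a).any():
        raise ValueError("channel contains NaN")
    dt = 1.0 / sampling_rate
    v = cumulative_trapezoid(a, dx=dt, initial=0.0) + v0
    d = cumulative_trapezoid(v, dx=dt, initial=0.0) + d0
    return d


def slice_frames(channel: np.ndarray, slice_len: int = 133) -> np.ndarray:
    """Cut a channel into consecutive non-overlapping frame slices.

    Returns shape (n_slices, slice_len); a trailing remainder shorter than
    one slice is dropped.  Raises if the channel cannot fill a single slice.
    """
    x = np.asarray(channel, dtype=float)
    n = x.shape[0] // slice_len
    if n == 0:
        raise ValueError(
            f"swallow too short: {x.shape[0]} samples < one slice of {slice_len}")
    return x[: n * slice_len].reshape(n, slice_len)


def slice_stats(slc: np.ndarray, ddof: int = 0) -> tuple[float, float]:
    """Arithmetic mean and variance of one slice (population variance by default)."""
    x = np.asarray(slc, dtype=float)
    if x.size < 2:
        raise ValueError("slice needs at least 2 samples")
    return float(x.mean()), float(x.var(ddof=ddof))


def build_features(sig: RawSwallowSignal, frame_rate: float = 30.0,
                   intermediate_rate: float = 4000.0,
                   var_ddof: int = 0) -> FrameFeatureSequence:
    """Assemble the 10-dimensional per-frame input sequence.

    Per frame and channel: displacement sampled at the final sample of the
    frame's slice (the causal choice: each frame's features summarise the same
    window), the slice mean and the slice variance of the raw acceleration;
    plus the frame time t = frame_index / frame_rate.
    """
    if sig.sampling_rate > intermediate_rate:
        sig = decimate(sig, intermediate_rate)
    elif sig.sampling_rate != intermediate_rate:
        raise ValueError(
            f"signal rate {sig.sampling_rate} below intermediate rate "
            f"{intermediate_rate}")
    slice_len = samples_per_frame(intermediate_rate, frame_rate)
    n_frames = sig.n_samples // slice_len
    if n_frames == 0:
        raise ValueError("swallow too short for a single frame slice")

    cols: list[np.ndarray] = []
    disp_cols, mean_cols, var_cols = [], [], []
    for ch in range(3):
        raw = sig.data[:, ch]
        disp = double_integrate(raw, intermediate_rate)
        sl = slice_frames(raw, slice_len)
        disp_cols.append(disp[slice_len - 1::slice_len][:n_frames])
        mean_cols.append(sl.mean(axis=1))
        var_cols.append(sl.var(axis=1, ddof=var_ddof))
    cols.extend(disp_cols + mean_cols + var_cols)
    cols.append(np.arange(n_frames) / frame_rate)
    values = np.column_stack(cols)
    return FrameFeatureSequence(values, frame_rate,
                                sig.swallow_id, sig.participant_id)


@dataclass
class FeatureNormalizer:
    """Per-feature min-max scaler fitted on the training set only.

    Maps each feature to [0, 1] on the training data; unseen data may land
    outside [0, 1] and is deliberately not clipped.  A constant feature
    (max == min) maps to 0 with a warning.
    """

    minimum: np.ndarray | None = None
    maximum: np.ndarray | None = None
    _degenerate: np.ndarray = field(default=None, repr=False)

    @property
    def fitted(self) -> bool:
        return self.minimum is not None

    def fit(self, training: list[FrameFeatureSequence]) -> "FeatureNormalizer":
        if not training:
            raise ValueError("training set is empty")
        stacked = np.vstack([seq.values for seq in training])
        self.minimum = stacked.min(axis=0)
        self.maximum = stacked.max(axis=0)
        self._degenerate = self.maximum <= self.minimum
        if self._degenerate.any():
            names = [FEATURE_NAMES[i] for i in np.flatnonzero(self._degenerate)]
            warnings.warn(
                f"constant feature(s) {names}: mapped to 0", stacklevel=2)
        return self

    def _check(self) -> None:
        if not self.fitted:
            raise ValueError("normalizer has not been fitted")

    def transform(self, seq: FrameFeatureSequence) -> FrameFeatureSequence:
        self._check()
        span = np.where(self._degenerate, 1.0, self.maximum - self.minimum)
        scaled = (seq.values - self.minimum) / span
        scaled[:, self._degenerate] = 0.0
        return FrameFeatureSequence(scaled, seq.frame_rate,
                                    seq.swallow_id, seq.participant_id)

    def inverse_transform(self, seq: FrameFeatureSequence) -> FrameFeatureSequence:
        self._check()
        span = np.where(self._degenerate, 1.0, self.maximum - self.minimum)
        raw = seq.values * span + self.minimum
        raw[:, self._degenerate] = self.minimum[self._degenerate]
        return FrameFeatureSequence(raw, seq.frame_rate,
                                    seq.swallow_id, seq.participant_id)

    # -- serialisation ------------------------------------------------------
    def to_json(self) -> str:
        self._check()
        return json.dumps({
            "minimum": self.minimum.tolist(),
            "maximum": self.maximum.tolist(),
        })

    @classmethod
    def from_json(cls, text: str) -> "FeatureNormalizer":
        obj = json.loads(text)
        norm = cls(np.asarray(obj["minimum"]), np.asarray(obj["maximum"]))
        norm._degenerate = norm.maximum <= norm.minimum
        return norm
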