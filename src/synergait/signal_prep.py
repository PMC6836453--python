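"""Preprocessing of multichannel gait sEMG.

Turns raw recordings plus gait events into per-stride, amplitude-normalized
envelope matrices and 200-point phase-normalized activation profiles.

The gait cycle of the reference (instrumented) leg is split into four
sub-phases bounded by heel-strike (HS) and toe-off (TO) events of both legs:

* ``DS1``    — reference HS to contralateral TO (first double support)
* ``Stance`` — contralateral TO to contralateral HS (single support)
* ``DS2``    — contralateral HS to reference TO (second double support)
* ``Swing``  — reference TO to the next reference HS

Time normalization resamples each sub-phase to a fixed number of samples
(20 / 80 / 20 / 80), producing a 200-sample profile per stride.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as _sig
from scipy.ndimage import uniform_filter1d

__all__ = [
    "PHASE_NAMES",
    "PHASE_SAMPLES",
    "PHASE_SAMPLE_EDGES",
    "N_PROFILE_SAMPLES",
    "EVENT_NAMES",
    "EmgRecording",
    "GaitEvents",
    "StridePhases",
    "EnvelopeMatrix",
    "NormalizedProfile",
    "bandpass_filter",
    "compute_envelope",
    "segment_strides",
    "parse_phases",
    "normalize_amplitude",
    "resample_linear",
    "time_normalize",
    "time_normalize_all",
    "mean_profile",
]

PHASE_NAMES = ("DS1", "Stance", "DS2", "Swing")
PHASE_SAMPLES = (20, 80, 20, 80)
PHASE_SAMPLE_EDGES = (0, 20, 100, 120, 200)
N_PROFILE_SAMPLES = 200
EVENT_NAMES = ("HS_ref", "TO_contra", "HS_contra", "TO_ref", "HS_ref_next")

_ADAPTIVE_LADDER_MS = (25.0, 50.0, 100.0, 200.0, 400.0)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class EmgRecording:
    """Multichannel sEMG: ``samples`` is muscles x time, in arbitrary units."""

    muscle_labels: tuple[str, ...]
    samples: np.ndarray
    fs: float = 1000.0

    def __post_init__(self) -> None:
        self.muscle_labels = tuple(str(m) for m in self.muscle_labels)
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        if self.samples.ndim != 2:
            raise ValueError("samples must be a 2-D muscles x time array")
        if len(self.muscle_labels) != self.samples.shape[0]:
            raise ValueError(
                f"{len(self.muscle_labels)} labels for "
                f"{self.samples.shape[0]} channels"
            )
        if not self.fs > 0:
            raise ValueError("sampling rate must be positive")

    @property
    def n_muscles(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


@dataclass
class GaitEvents:
    """Stride-wise event times in seconds.

    ``times`` has one row per stride with columns
    (HS_ref, TO_contra, HS_contra, TO_ref, HS_ref_next).
    """

    times: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.atleast_2d(np.asarray(self.times, dtype=float))
        if self.times.ndim != 2 or self.times.shape[1] != 5:
            raise ValueError("event table must have 5 columns per stride")
        for k, row in enumerate(self.times):
            if not np.all(np.diff(row) > 0):
                raise ValueError(
                    f"events of stride {k} are not strictly increasing: {row}"
                )
        starts = self.times[:, 0]
        ends = self.times[:, 4]
        if np.any(starts[1:] < ends[:-1] - 1e-12):
            bad = int(np.argmax(starts[1:] < ends[:-1] - 1e-12)) + 1
            raise ValueError(f"stride {bad} overlaps the previous stride")

    @property
    def n_strides(self) -> int:
        return self.times.shape[0]


@dataclass
class StridePhases:
    """Per-stride boundaries (seconds) of the four sub-phases.

    ``bounds`` row k holds the 5 boundary times of stride k; the four
    half-open phase intervals are ``[bounds[j], bounds[j+1])``.
    """

    bounds: np.ndarray

    def __post_init__(self) -> None:
        self.bounds = np.atleast_2d(np.asarray(self.bounds, dtype=float))
        if self.bounds.shape[1] != 5:
            raise ValueError("phase bounds must have 5 columns per stride")

    @property
    def n_strides(self) -> int:
        return self.bounds.shape[0]

    def durations(self) -> np.ndarray:
        """Phase durations, strides x 4, in seconds."""
        return np.diff(self.bounds, axis=1)

    def intervals(self, stride: int) -> list[tuple[float, float]]:
        b = self.bounds[stride]
        return [(b[j], b[j + 1]) for j in range(4)]


@dataclass
class EnvelopeMatrix:
    """Nonnegative muscles x samples activation matrix.

    ``stride_boundaries`` holds n_strides + 1 sample indices delimiting the
    concatenated strides; a single block [0, N] means "unsegmented".
    """

    values: np.ndarray
    stride_boundaries: np.ndarray = field(default=None)  # type: ignore[assignment]
    muscle_labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if np.min(self.values, initial=0.0) < -1e-9:
            raise ValueError("envelope values must be nonnegative")
        self.values = np.clip(self.values, 0.0, None)
        if self.stride_boundaries is None:
            self.stride_boundaries = np.array([0, self.values.shape[1]])
        self.stride_boundaries = np.asarray(self.stride_boundaries, dtype=int)
        b = self.stride_boundaries
        if b[0] != 0 or b[-1] != self.values.shape[1] or np.any(np.diff(b) <= 0):
            raise ValueError("stride boundaries must be sorted and span the matrix")
        if self.muscle_labels is not None:
            self.muscle_labels = tuple(self.muscle_labels)
            if len(self.muscle_labels) != self.values.shape[0]:
                raise ValueError("label count does not match row count")

    @property
    def n_strides(self) -> int:
        return len(self.stride_boundaries) - 1

    def stride(self, k: int) -> np.ndarray:
        b = self.stride_boundaries
        return self.values[:, b[k] : b[k + 1]]


@dataclass
class NormalizedProfile:
    """Rows x 200 phase-normalized profile (20/80/20/80 sample blocks)."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.shape[1] != N_PROFILE_SAMPLES:
            raise ValueError(
                f"profile must have {N_PROFILE_SAMPLES} columns, "
                f"got {self.values.shape[1]}"
            )
        if np.min(self.values, initial=0.0) < -1e-9:
            raise ValueError("profile values must be nonnegative")
        self.values = np.clip(self.values, 0.0, None)


# ---------------------------------------------------------------------------
# Filtering and envelopes
# ---------------------------------------------------------------------------


def bandpass_filter(
    rec: EmgRecording,
    low_hz: float = 35.0,
    high_hz: float = 450.0,
    order: int = 4,
) -> EmgRecording:
    """Zero-phase Butterworth band-pass applied per channel.

    Raises if ``high_hz`` is at or above the Nyquist frequency.
    """
    nyq = rec.fs / 2.0
    if high_hz >= nyq:
        raise ValueError(
            f"band edge {high_hz} Hz violates the Nyquist limit {nyq} Hz "
            f"at fs={rec.fs} Hz"
        )
    if not 0 < low_hz < high_hz:
        raise ValueError("require 0 < low_hz < high_hz")
    sos = _sig.butter(order, [low_hz, high_hz], btype="bandpass", fs=rec.fs, output="sos")
    filtered = _sig.sosfiltfilt(sos, rec.samples, axis=1)
    return EmgRecording(rec.muscle_labels, filtered, rec.fs)


def bandpass_sos(fs: float, low_hz: float = 35.0, high_hz: float = 450.0, order: int = 4):
    """Second-order sections of the default band-pass (for frequency-response checks)."""
    return _sig.butter(order, [low_hz, high_hz], btype="bandpass", fs=fs, output="sos")


def _moving_mean_square(x: np.ndarray, win: int) -> np.ndarray:
    return uniform_filter1d(x * x, size=win, axis=-1, mode="nearest")


def compute_envelope(
    rec: EmgRecording,
    method: str = "fixed_rms",
    window_ms: float = 100.0,
) -> EnvelopeMatrix:
    """Smoothed nonnegative amplitude per channel.

    ``fixed_rms`` is a centered moving RMS of the stated window.
    ``adaptive_rms`` picks, per sample, a window from a dyadic ladder
    (25–400 ms) minimizing an estimated bias^2 + variance criterion on the
    local mean-square, then takes its square root.
    """
    x = rec.samples
    n = rec.n_samples
    if method == "fixed_rms":
        win = max(1, int(round(rec.fs * window_ms / 1000.0)))
        if win > n:
            raise ValueError(f"window of {win} samples longer than signal ({n})")
        env = np.sqrt(_moving_mean_square(x, win))
    elif method == "adaptive_rms":
        wins = []
        for w_ms in _ADAPTIVE_LADDER_MS:
            w = max(1, int(round(rec.fs * w_ms / 1000.0)))
            if w <= n and w not in wins:
                wins.append(w)
        if not wins:
            raise ValueError("signal shorter than the smallest adaptive window")
        x2 = x * x
        means = np.stack([uniform_filter1d(x2, w, axis=-1, mode="nearest") for w in wins])
        sq = np.stack([uniform_filter1d(x2 * x2, w, axis=-1, mode="nearest") for w in wins])
        var_of_mean = np.clip(sq - means**2, 0.0, None) / np.asarray(wins)[:, None, None]
        bias2 = (means - means[0]) ** 2
        choice = np.argmin(bias2 + var_of_mean, axis=0)
        env = np.sqrt(np.take_along_axis(means, choice[None], axis=0)[0])
    else:
        raise ValueError(f"unknown envelope method {method!r}")
    return EnvelopeMatrix(env, muscle_labels=rec.muscle_labels)


# ---------------------------------------------------------------------------
# Stride segmentation and phase parsing
# ---------------------------------------------------------------------------


def parse_phases(events: GaitEvents) -> StridePhases:
    """Map event times to the four half-open sub-phase intervals.

    DS1 = [HS_ref, TO_contra), Stance = [TO_contra, HS_contra),
    DS2 = [HS_contra, TO_ref), Swing = [TO_ref, HS_ref_next).
    """
    if not isinstance(events, GaitEvents):
        events = GaitEvents(np.asarray(events))
    return StridePhases(events.times.copy())


def phase_sample_bounds(phases: StridePhases, fs: float) -> np.ndarray:
    """Phase boundary times mapped to absolute sample indices (rounded)."""
    return np.round(phases.bounds * fs).astype(int)


def segment_strides(
    env: EnvelopeMatrix | np.ndarray,
    events: GaitEvents,
    fs: float,
) -> EnvelopeMatrix:
    """Concatenate the stride portions of an envelope, recording boundaries."""
    values = env.values if isinstance(env, EnvelopeMatrix) else np.atleast_2d(env)
    labels = env.muscle_labels if isinstance(env, EnvelopeMatrix) else None
    n = values.shape[1]
    idx = np.round(events.times[:, [0, 4]] * fs).astype(int)
    chunks = []
    bounds = [0]
    for k, (a, b) in enumerate(idx):
        if a < 0 or b > n:
            raise ValueError(f"stride {k} [{a}:{b}] outside recording of {n} samples")
        if b <= a:
            raise ValueError(f"stride {k} is empty after rounding")
        chunks.append(values[:, a:b])
        bounds.append(bounds[-1] + (b - a))
    return EnvelopeMatrix(np.hstack(chunks), np.asarray(bounds), labels)


def normalize_amplitude(env: EnvelopeMatrix) -> EnvelopeMatrix:
    """Divide each muscle by the median across strides of its per-stride peak."""
    if env.n_strides < 1:
        raise ValueError("need at least one stride")
    peaks = np.stack(
        [env.stride(k).max(axis=1) for k in range(env.n_strides)], axis=1
    )  # muscles x strides
    divisors = np.median(peaks, axis=1)
    zero = np.nonzero(divisors <= 0)[0]
    if zero.size:
        m = zero[0]
        name = env.muscle_labels[m] if env.muscle_labels else f"muscle {m}"
        raise ValueError(f"median peak of {name} is zero; cannot normalize amplitude")
    return EnvelopeMatrix(
        env.values / divisors[:, None], env.stride_boundaries.copy(), env.muscle_labels
    )


# ---------------------------------------------------------------------------
# Time normalization
# ---------------------------------------------------------------------------


def resample_linear(block: np.ndarray, n_out: int) -> np.ndarray:
    """Linearly resample rows x n_in to rows x n_out, endpoints preserved."""
    block = np.atleast_2d(np.asarray(block, dtype=float))
    n_in = block.shape[1]
    if n_in == 0:
        raise ValueError("cannot resample an empty segment")
    if n_in == 1:
        return np.repeat(block, n_out, axis=1)
    pos = np.linspace(0.0, n_in - 1.0, n_out)
    lo = np.floor(pos).astype(int)
    hi = np.minimum(lo + 1, n_in - 1)
    frac = pos - lo
    return block[:, lo] * (1.0 - frac) + block[:, hi] * frac


def time_normalize(
    values: np.ndarray,
    phase_bounds: np.ndarray,
) -> NormalizedProfile:
    """Phase-wise resample one stride to the fixed 20/80/20/80 sample grid.

    ``values`` is rows x stride_samples; ``phase_bounds`` gives the 5 sample
    indices of the phase boundaries relative to the stride (half-open blocks).
    """
    values = np.atleast_2d(np.asarray(values, dtype=float))
    b = np.asarray(phase_bounds, dtype=int)
    if b.shape != (5,):
        raise ValueError("phase_bounds must contain 5 sample indices")
    if b[0] != 0 or b[-1] != values.shape[1] or np.any(np.diff(b) <= 0):
        raise ValueError(
            f"phase bounds {b.tolist()} do not partition a stride of "
            f"{values.shape[1]} samples into non-empty segments"
        )
    blocks = [
        resample_linear(values[:, b[j] : b[j + 1]], PHASE_SAMPLES[j]) for j in range(4)
    ]
    return NormalizedProfile(np.hstack(blocks))


def time_normalize_all(
    env: EnvelopeMatrix,
    phases: StridePhases,
    fs: float,
) -> np.ndarray:
    """Time-normalize every stride; returns n_strides x rows x 200.

    Phase times are mapped to samples of the concatenated matrix through the
    per-stride boundaries of ``env``.
    """
    if env.n_strides != phases.n_strides:
        raise ValueError("stride count mismatch between envelope and phases")
    abs_bounds = phase_sample_bounds(phases, fs)
    out = []
    for k in range(env.n_strides):
        stride = env.stride(k)
        rel = abs_bounds[k] - abs_bounds[k, 0]
        rel = np.clip(rel, 0, stride.shape[1])
        rel[-1] = stride.shape[1]
        out.append(time_normalize(stride, rel).values)
    return np.stack(out)


def mean_profile(profiles: np.ndarray) -> NormalizedProfile:
    """Average per-stride profiles (n_strides x rows x 200) across strides."""
    profiles = np.asarray(profiles, dtype=float)
    if profiles.ndim != 3 or profiles.shape[0] < 1:
        raise ValueError("expected a non-empty n_strides x rows x 200 stack")
    return NormalizedProfile(profiles.mean(axis=0))
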