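"""Synthetic multi-subject gait sEMG from known ground-truth synergies.

Envelopes are composed as W x H where W holds fixed spatial synergy vectors
and H rows are sums of gait-phase-locked Gaussian activation bumps. The
generator supports per-subject synergy perturbation, inter-stride timing
jitter, additive noise at a target SNR, an amplitude-modulated raw-carrier
mode, and a group-level timing alteration preset (``tf_like``) that prolongs
the calf module's activity through stance and both double supports and adds
a hamstrings-module bump around the contralateral heel strike.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from numpy.random import Generator, SeedSequence, default_rng
from scipy import signal as _sig

from .signal_prep import EmgRecording, EnvelopeMatrix, GaitEvents

__all__ = [
    "MUSCLES",
    "Bump",
    "SynergyTemplate",
    "CohortConfig",
    "SubjectTruth",
    "GroundTruthBundle",
    "default_template",
    "generate_stride",
    "generate_cohort",
    "TF_LIKE_EXTRA_BUMPS",
]

MUSCLES = (
    "RF", "VL", "VM", "GLU_MED", "TFL", "ST",
    "BF", "TA", "PL", "SOL", "GL", "GAS_MED",
)

DEFAULT_PHASE_FRACTIONS = (0.12, 0.38, 0.12, 0.38)


@dataclass(frozen=True)
class Bump:
    """One activation bump: center/width as fractions of the gait cycle."""

    center: float
    width: float
    amplitude: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.center < 1.0:
            raise ValueError(f"bump center {self.center} outside [0, 1)")
        if not self.width > 0:
            raise ValueError("bump width must be positive")
        if self.amplitude < 0:
            raise ValueError("bump amplitude must be nonnegative")


@dataclass
class SynergyTemplate:
    """Ground-truth synergy vectors plus their activation bump timings."""

    muscle_labels: tuple[str, ...]
    W_true: np.ndarray
    bump_params: tuple[tuple[Bump, ...], ...]

    def __post_init__(self) -> None:
        self.muscle_labels = tuple(self.muscle_labels)
        self.W_true = np.asarray(self.W_true, dtype=float)
        if self.W_true.ndim != 2 or self.W_true.shape[0] != len(self.muscle_labels):
            raise ValueError("W_true must be n_muscles x n_synergies")
        if np.any(self.W_true < 0):
            raise ValueError("W_true entries must be nonnegative")
        norms = np.linalg.norm(self.W_true, axis=0)
        if np.any(np.abs(norms - 1.0) > 1e-9):
            raise ValueError("W_true columns must have unit Euclidean norm")
        self.bump_params = tuple(tuple(b) for b in self.bump_params)
        if len(self.bump_params) != self.W_true.shape[1]:
            raise ValueError("one bump list required per synergy")

    @property
    def n_synergies(self) -> int:
        return self.W_true.shape[1]


def _unit_columns(W: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(W, axis=0)
    if np.any(norms == 0):
        raise ValueError("cannot normalize a zero synergy column")
    return W / norms


def default_template() -> SynergyTemplate:
    """Packaged 12-muscle, 4-synergy template.

    Synergy 1: knee extensors + gluteus medius, early-stance bump (weight
    acceptance). Synergy 2: calf muscles, late-stance bump (propulsion).
    Synergy 3: TFL with minor knee-extensor/TA/PL contributions, bumps in
    early stance and swing. Synergy 4: hamstrings + TA, late-swing bump.
    """
    idx = {m: i for i, m in enumerate(MUSCLES)}
    W = np.zeros((12, 4))
    W[[idx["RF"], idx["VL"], idx["VM"], idx["GLU_MED"]], 0] = [0.80, 1.00, 1.00, 0.70]
    W[[idx["PL"], idx["SOL"], idx["GL"], idx["GAS_MED"]], 1] = [0.60, 1.00, 0.90, 1.00]
    W[[idx["TFL"], idx["RF"], idx["VL"], idx["VM"], idx["TA"], idx["PL"]], 2] = [
        1.00, 0.20, 0.15, 0.15, 0.25, 0.20,
    ]
    W[[idx["ST"], idx["BF"], idx["TA"]], 3] = [1.00, 0.95, 0.60]
    bumps = (
        (Bump(0.18, 0.07, 1.0),),
        (Bump(0.44, 0.08, 1.0),),
        (Bump(0.04, 0.04, 0.9), Bump(0.70, 0.07, 1.0)),
        (Bump(0.93, 0.07, 1.2),),
    )
    return SynergyTemplate(MUSCLES, _unit_columns(W), bumps)


# Extra bumps injected per synergy index for group_effect="tf_like":
# prolonged calf-module (synergy 2) activity across both double supports and
# an added hamstrings-module (synergy 4) burst around contralateral HS.
TF_LIKE_EXTRA_BUMPS: dict[int, tuple[Bump, ...]] = {
    1: (Bump(0.06, 0.05, 0.6), Bump(0.56, 0.05, 0.6)),
    3: (Bump(0.50, 0.05, 0.5),),
}


def stride_phase_samples(phase_durations: np.ndarray, fs: float) -> np.ndarray:
    """Samples allocated to each phase (at least 1 per phase)."""
    d = np.asarray(phase_durations, dtype=float)
    if d.shape != (4,):
        raise ValueError("need exactly four phase durations")
    if np.any(d <= 0):
        raise ValueError("phase durations must all be positive")
    return np.maximum(1, np.round(d * fs).astype(int))


def _bump_profile(frac: np.ndarray, bumps: tuple[Bump, ...]) -> np.ndarray:
    """Sum of cycle-wrapped Gaussian bumps evaluated on cycle fractions."""
    h = np.zeros_like(frac)
    for b in bumps:
        for wrap in (-1.0, 0.0, 1.0):
            h += b.amplitude * np.exp(-0.5 * ((frac - b.center - wrap) / b.width) ** 2)
    return h


def generate_stride(
    template: SynergyTemplate,
    phase_durations: np.ndarray,
    fs: float = 1000.0,
    rng: Generator | None = None,
    W: np.ndarray | None = None,
    bump_params: tuple[tuple[Bump, ...], ...] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """One stride of ground-truth activations and the resulting envelope.

    Returns ``(H_true, envelope)`` with ``envelope = W @ H_true`` exactly.
    ``W`` and ``bump_params`` default to the template's (overridable so that a
    cohort can reuse per-subject perturbed versions).
    """
    n_per_phase = stride_phase_samples(phase_durations, fs)
    n = int(n_per_phase.sum())
    frac = np.arange(n) / n
    bumps = template.bump_params if bump_params is None else bump_params
    H = np.stack([_bump_profile(frac, b) for b in bumps])
    W_use = template.W_true if W is None else np.asarray(W, dtype=float)
    envelope = W_use @ H
    return H, envelope


@dataclass(frozen=True)
class CohortConfig:
    """Configuration of one simulated group of walking subjects."""

    n_subjects: int
    strides_per_subject: int = 8
    stride_duration_mean_s: float = 1.1
    stride_duration_sd_s: float = 0.08
    phase_fractions: tuple[float, float, float, float] = DEFAULT_PHASE_FRACTIONS
    snr_db: float = 20.0
    subject_perturbation_sd: float = 0.1
    group_effect: str = "none"
    sampling_rate_hz: float = 1000.0
    mode: str = "envelope"
    seed: int = 0
    group_label: str = "G1"

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be at least 1")
        if self.strides_per_subject < 1:
            raise ValueError("strides_per_subject must be at least 1")
        if not self.stride_duration_mean_s > 0:
            raise ValueError("stride duration must be positive")
        if abs(sum(self.phase_fractions) - 1.0) > 1e-9:
            raise ValueError("phase fractions must sum to 1")
        if any(f <= 0 for f in self.phase_fractions):
            raise ValueError("phase fractions must be positive")
        if self.group_effect not in ("none", "tf_like"):
            raise ValueError(f"unknown group_effect {self.group_effect!r}")
        if self.mode not in ("envelope", "raw"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "raw" and self.sampling_rate_hz <= 900:
            raise ValueError("raw mode requires fs > 900 Hz for the 35-450 Hz carrier")


@dataclass
class SubjectTruth:
    """Everything known about one simulated subject."""

    subject_id: str
    group: str
    W_subject: np.ndarray
    H_true: list[np.ndarray]
    events: GaitEvents
    recording: EmgRecording
    clean_envelope: EnvelopeMatrix
    phase_bounds_samples: np.ndarray  # strides x 5, absolute sample indices


@dataclass
class GroundTruthBundle:
    template: SynergyTemplate
    config: CohortConfig
    subjects: list[SubjectTruth]


def _apply_group_effect(
    bumps: tuple[tuple[Bump, ...], ...], effect: str
) -> tuple[tuple[Bump, ...], ...]:
    if effect == "none":
        return bumps
    out = []
    for i, b in enumerate(bumps):
        out.append(tuple(b) + TF_LIKE_EXTRA_BUMPS.get(i, ()))
    return tuple(out)


def _perturb_template(
    W: np.ndarray, sd: float, rng: Generator
) -> np.ndarray:
    if sd == 0:
        return W.copy()
    Wp = np.clip(W + rng.normal(0.0, sd, size=W.shape), 0.0, None)
    norms = np.linalg.norm(Wp, axis=0)
    for j in np.nonzero(norms == 0)[0]:  # pathological draw: fall back to template
        Wp[:, j] = W[:, j]
        norms[j] = 1.0
    return Wp / np.linalg.norm(Wp, axis=0)


def _band_limited_carrier(
    shape: tuple[int, int], fs: float, rng: Generator
) -> np.ndarray:
    sos = _sig.butter(4, [35.0, 450.0], btype="bandpass", fs=fs, output="sos")
    carrier = _sig.sosfiltfilt(sos, rng.standard_normal(shape), axis=1)
    rms = np.sqrt(np.mean(carrier**2, axis=1, keepdims=True))
    return carrier / np.maximum(rms, 1e-12)


def generate_cohort(
    config: CohortConfig,
    template: SynergyTemplate | None = None,
) -> GroundTruthBundle:
    """Simulate one group; a pure, bit-reproducible function of its inputs."""
    if template is None:
        template = default_template()
    fs = config.sampling_rate_hz
    fractions = np.asarray(config.phase_fractions)
    bumps = _apply_group_effect(template.bump_params, config.group_effect)
    children = SeedSequence(config.seed).spawn(config.n_subjects)

    subjects: list[SubjectTruth] = []
    for s in range(config.n_subjects):
        rng = default_rng(children[s])
        W_subject = _perturb_template(
            template.W_true, config.subject_perturbation_sd, rng
        )
        H_list: list[np.ndarray] = []
        env_chunks: list[np.ndarray] = []
        bounds_rows: list[np.ndarray] = []
        cursor = 0
        for _ in range(config.strides_per_subject):
            if config.stride_duration_sd_s > 0:
                dur = rng.normal(config.stride_duration_mean_s, config.stride_duration_sd_s)
                dur = max(dur, 0.25 * config.stride_duration_mean_s)
            else:
                dur = config.stride_duration_mean_s
            n_per_phase = stride_phase_samples(fractions * dur, fs)
            H, env = generate_stride(
                template, fractions * dur, fs, W=W_subject, bump_params=bumps
            )
            H_list.append(H)
            env_chunks.append(env)
            bounds_rows.append(cursor + np.concatenate(([0], np.cumsum(n_per_phase))))
            cursor += int(n_per_phase.sum())

        clean = np.hstack(env_chunks)
        phase_bounds = np.stack(bounds_rows)
        stride_bounds = np.concatenate(([0], phase_bounds[:, 4]))
        events = GaitEvents(phase_bounds / fs)

        samples = clean
        if np.isfinite(config.snr_db):
            power = np.mean(clean**2, axis=1, keepdims=True)
            noise_sd = np.sqrt(power / 10.0 ** (config.snr_db / 10.0))
            samples = np.clip(
                clean + noise_sd * rng.standard_normal(clean.shape), 0.0, None
            )
        if config.mode == "raw":
            samples = samples * _band_limited_carrier(samples.shape, fs, rng)

        subjects.append(
            SubjectTruth(
                subject_id=f"S{s:02d}",
                group=config.group_label,
                W_subject=W_subject,
                H_true=H_list,
                events=events,
                recording=EmgRecording(template.muscle_labels, samples, fs),
                clean_envelope=EnvelopeMatrix(
                    clean, stride_bounds, template.muscle_labels
                ),
                phase_bounds_samples=phase_bounds,
            )
        )
    return GroundTruthBundle(template, config, subjects)
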