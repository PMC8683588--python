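"""Propagating-velocity-waveform phantom for PWV validation.

A parameterized systolic pulse travels along the centerline at a known speed:
the waveform observed at arc length ``s`` is the template delayed by
``s / PWV_true``, sampled at the scanner's temporal resolution (8.6 ms by
default, matching retrospectively gated in-plane velocity encoding) with
optional additive Gaussian velocity noise.  Ground truth is the propagation
speed itself, so arrival-time detection and the distance-vs-time regression
can be validated end to end.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..errors import AliasingError
from ..morphometry import SegmentPartition
from ..pwv import VelocityEncodedSeries

__all__ = ["WavePhantomSpec", "make_wave_phantom", "make_chord_samples", "pulse_template"]


@dataclass(frozen=True)
class WavePhantomSpec:
    """Stated acquisition and physiology parameters of the wave phantom.

    Defaults: venc 150 cm/s and 8.6 ms true temporal resolution (the in-plane
    velocity-encoded protocol), a 7 m/s propagation speed typical of thoracic
    aneurysm cohorts, and a 100 cm/s peak systolic velocity below venc so the
    clean phantom is alias-free.
    """

    true_pwv_m_per_s: float = 7.0
    onset_time_ms: float = 60.0
    upstroke_duration_ms: float = 80.0
    decay_duration_ms: float = 200.0
    peak_velocity_cm_per_s: float = 100.0
    chord_positions_mm: np.ndarray | None = None  # default: 200 chords over 450 mm
    temporal_resolution_ms: float = 8.6
    n_phases: int = 110
    venc_cm_per_s: float = 150.0
    noise_sd_cm_per_s: float = 2.0
    allow_aliasing: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.true_pwv_m_per_s <= 0:
            raise ValueError("true_pwv_m_per_s must be positive")
        if self.temporal_resolution_ms <= 0:
            raise ValueError("temporal_resolution_ms must be positive")
        if self.n_phases < 10:
            raise ValueError(
                f"n_phases = {self.n_phases}: too few phases for foot detection (need >= 10)"
            )
        if self.upstroke_duration_ms <= 0 or self.decay_duration_ms <= 0:
            raise ValueError("upstroke and decay durations must be positive")
        if self.peak_velocity_cm_per_s >= self.venc_cm_per_s and not self.allow_aliasing:
            raise AliasingError(
                f"peak velocity {self.peak_velocity_cm_per_s} cm/s reaches venc "
                f"{self.venc_cm_per_s} cm/s: the phantom would alias "
                "(set allow_aliasing=True to wrap deliberately)"
            )

    def positions(self) -> np.ndarray:
        if self.chord_positions_mm is not None:
            return np.asarray(self.chord_positions_mm, dtype=float)
        return np.linspace(0.0, 450.0, 200)


def pulse_template(spec: WavePhantomSpec, t_ms: np.ndarray) -> np.ndarray:
    """Systolic pulse: linear upstroke then half-cosine decay back to baseline."""
    t = np.asarray(t_ms, dtype=float)
    v = np.zeros_like(t)
    t0, tu, td = spec.onset_time_ms, spec.upstroke_duration_ms, spec.decay_duration_ms
    up = (t >= t0) & (t < t0 + tu)
    v[up] = spec.peak_velocity_cm_per_s * (t[up] - t0) / tu
    down = (t >= t0 + tu) & (t < t0 + tu + td)
    v[down] = spec.peak_velocity_cm_per_s * 0.5 * (1.0 + np.cos(np.pi * (t[down] - t0 - tu) / td))
    return v


def _wrap_venc(v: np.ndarray, venc: float) -> np.ndarray:
    """Phase wrap into (-venc, venc]."""
    return -((-v + venc) % (2.0 * venc) - venc)


def make_wave_phantom(
    spec: WavePhantomSpec, partition: SegmentPartition | None = None
) -> VelocityEncodedSeries:
    """Sampled per-chord waveforms: v(s, t) = w(t - s / PWV_true) + noise.

    With zero noise the arrival-time difference between chords at arc lengths
    s1 and s2 is exactly (s2 - s1) / PWV_true before time discretization.
    """
    positions = spec.positions()
    t = np.arange(spec.n_phases) * spec.temporal_resolution_ms
    delay_ms = positions / spec.true_pwv_m_per_s  # mm / (m/s) = ms
    waves = pulse_template(spec, t[None, :] - delay_ms[:, None])
    if spec.noise_sd_cm_per_s > 0:
        rng = np.random.default_rng(spec.seed)
        waves = waves + rng.normal(0.0, spec.noise_sd_cm_per_s, size=waves.shape)
    if spec.allow_aliasing:
        waves = _wrap_venc(waves, spec.venc_cm_per_s)
    else:
        # noise tails may graze venc; clip rather than alias in the clean phantom
        waves = np.clip(waves, -spec.venc_cm_per_s, spec.venc_cm_per_s)
    labels = partition.label_of(positions) if partition is not None else None
    return VelocityEncodedSeries(
        chord_arc_length_mm=positions,
        waveforms=waves,
        temporal_resolution_ms=spec.temporal_resolution_ms,
        venc_cm_per_s=spec.venc_cm_per_s,
        segment_labels=labels,
    )


def make_chord_samples(spec: WavePhantomSpec, n_samples: int = 9) -> np.ndarray:
    """Raw lumen samples per chord with a parabolic in-plane profile.

    Returns (n_chords, n_samples, n_phases); sample k at normalized radius
    rho_k carries v * (1 - rho_k^2), so the max over samples recovers the
    centerline waveform.  Used to exercise the max-velocity reduction.
    """
    positions = spec.positions()
    t = np.arange(spec.n_phases) * spec.temporal_resolution_ms
    delay_ms = positions / spec.true_pwv_m_per_s
    center = pulse_template(spec, t[None, :] - delay_ms[:, None])  # (chords, phases)
    rho = np.linspace(-0.9, 0.9, n_samples)
    profile = 1.0 - rho**2
    samples = center[:, None, :] * profile[None, :, None]
    if spec.noise_sd_cm_per_s > 0:
        rng = np.random.default_rng(spec.seed + 1)
        samples = samples + rng.normal(0.0, spec.noise_sd_cm_per_s, size=samples.shape)
    return samples
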