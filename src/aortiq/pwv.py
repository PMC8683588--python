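"""Regional pulse wave velocity from velocity-encoded waveforms.

The aortic lumen is sampled on chords placed perpendicular to the centerline
at equal arc-length spacing (200 by default).  Each chord yields a maximal
velocity waveform over the cardiac cycle; the systolic upstroke's foot is
detected per chord, and the regional pulse wave velocity of a segment is the
inverse slope of the ordinary-least-squares fit of foot time against chord
arc-length position.

Foot detection uses the intersecting-lines rule: a least-squares line through
the upstroke samples between 20% and 80% of the waveform peak is intersected
with the pre-upstroke baseline level, giving sub-sample time resolution at the
8.6 ms temporal resolution typical of retrospectively gated in-plane
velocity-encoded acquisitions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import WaveformError
from .morphometry import SEGMENT_LABELS, Centerline, SegmentPartition

logger = logging.getLogger(__name__)


@dataclass
class VelocityEncodedSeries:
    """Per-chord maximal-velocity waveforms along the aorta.

    ``waveforms`` is (n_chords, n_phases) in cm/s, signed with forward flow
    positive; ``chord_arc_length_mm`` gives each chord's centerline position
    and must be sorted ascending.
    """

    chord_arc_length_mm: np.ndarray
    waveforms: np.ndarray
    temporal_resolution_ms: float = 8.6
    venc_cm_per_s: float = 150.0
    segment_labels: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.chord_arc_length_mm = np.asarray(self.chord_arc_length_mm, dtype=float)
        self.waveforms = np.asarray(self.waveforms, dtype=float)
        if self.waveforms.ndim != 2 or self.waveforms.shape[0] != len(self.chord_arc_length_mm):
            raise ValueError("waveforms must be (n_chords, n_phases)")
        if self.waveforms.shape[1] < 10:
            raise ValueError("need at least 10 cardiac phases")
        if np.any(np.diff(self.chord_arc_length_mm) < 0):
            raise ValueError("chords must be sorted by arc length")
        if np.any(np.abs(self.waveforms) > self.venc_cm_per_s + 1e-9):
            raise ValueError("waveform velocities exceed venc; data would be aliased")
        if self.segment_labels is not None:
            self.segment_labels = np.asarray(self.segment_labels)

    @property
    def phase_times_ms(self) -> np.ndarray:
        return np.arange(self.waveforms.shape[1]) * self.temporal_resolution_ms


@dataclass
class ArrivalTimes:
    foot_time_ms: np.ndarray          # NaN where detection failed
    quality_ok: np.ndarray            # bool per chord

    def __post_init__(self) -> None:
        self.foot_time_ms = np.asarray(self.foot_time_ms, dtype=float)
        self.quality_ok = np.asarray(self.quality_ok, dtype=bool)


@dataclass
class RegionalPWV:
    segment_id: str
    pwv_m_per_s: float
    fit_r2: float
    n_chords_used: int
    valid: bool = True
    diagnostic: str = ""


# ---------------------------------------------------------------------------
# chord placement and waveform reduction
# ---------------------------------------------------------------------------


def place_chords(
    centerline: Centerline,
    n: int = 200,
    partition: SegmentPartition | None = None,
    min_spacing_mm: float = 0.5,
) -> tuple[np.ndarray, np.ndarray | None]:
    """Equally spaced chord arc-length positions, optionally segment-labelled.

    Returns ``(positions_mm, segment_labels)``; labels are None when no
    partition is given.  If the centerline is too short for ``n`` chords at the
    minimum spacing, ``n`` is reduced with a warning.
    """
    if n < 10:
        raise ValueError("need at least 10 chords")
    total = centerline.length_mm
    max_n = int(np.floor(total / min_spacing_mm)) + 1
    if n > max_n:
        logger.warning("centerline too short for %d chords; reduced to %d", n, max_n)
        n = max_n
        if n < 10:
            raise ValueError("centerline too short for a minimal chord set")
    positions = np.linspace(0.0, total, n)
    labels = partition.label_of(positions) if partition is not None else None
    return positions, labels


def max_velocity_waveform(chord_samples: np.ndarray) -> np.ndarray:
    """Maximal (signed, forward-positive) velocity per phase over a chord's lumen samples.

    ``chord_samples`` is (n_samples, n_phases); an empty chord raises
    WaveformError so the caller can flag it.
    """
    chord_samples = np.asarray(chord_samples, dtype=float)
    if chord_samples.ndim != 2 or chord_samples.shape[0] == 0:
        raise WaveformError("chord has no lumen samples")
    return chord_samples.max(axis=0)


# ---------------------------------------------------------------------------
# arrival-time (foot) detection
# ---------------------------------------------------------------------------


def detect_arrival_time(
    waveform: np.ndarray,
    temporal_resolution_ms: float,
    min_snr: float = 5.0,
) -> float:
    """Foot time (ms) of the systolic upstroke by the intersecting-lines rule.

    The upstroke is the rising limb before the global peak.  A least-squares
    line through the samples between 20% and 80% of peak is intersected with
    the pre-upstroke baseline level (mean of the samples before the upstroke).
    Raises WaveformError when no credible upstroke exists (flat, monotone
    decreasing, or peak below ``min_snr`` times the baseline noise).
    """
    w = np.asarray(waveform, dtype=float)
    if w.ndim != 1 or len(w) < 5:
        raise WaveformError("waveform must be 1D with at least 5 phases")
    t = np.arange(len(w)) * temporal_resolution_ms
    i_peak = int(np.argmax(w))
    peak = w[i_peak]
    if i_peak == 0 or peak <= 0:
        raise WaveformError("no systolic upstroke: waveform is flat or monotone-decreasing")

    rising = w[: i_peak + 1]
    lo, hi = 0.2 * peak, 0.8 * peak
    # last excursion below 20% before the peak marks the upstroke start
    below = np.nonzero(rising < lo)[0]
    i_start = int(below[-1]) if len(below) else 0
    band = np.nonzero((rising >= lo) & (rising <= hi) & (np.arange(len(rising)) >= i_start))[0]
    if len(band) < 2:
        # steep upstroke: fall back to the two samples bracketing the 50% level
        crossing = np.nonzero(rising >= 0.5 * peak)[0]
        if len(crossing) == 0 or crossing[0] == 0:
            raise WaveformError("upstroke too abrupt to localize at this temporal resolution")
        band = np.array([crossing[0] - 1, crossing[0]])

    # robust baseline: the last below-20% sample may already sit on the ramp,
    # so the median (and MAD for the noise floor) ignores it
    baseline_sl = rising[: max(i_start + 1, 1)]
    baseline = float(np.median(baseline_sl))
    if len(baseline_sl) > 2:
        noise_sd = 1.4826 * float(np.median(np.abs(baseline_sl - baseline)))
    else:
        noise_sd = 0.0
    if noise_sd > 0 and (peak - baseline) < min_snr * noise_sd:
        raise WaveformError("peak below the noise floor; no credible upstroke")

    x, y = t[band], rising[band]
    slope, intercept = np.polyfit(x, y, 1)
    if slope <= 0:
        raise WaveformError("upstroke fit has non-positive slope")
    foot = (baseline - intercept) / slope
    if not (t[0] - temporal_resolution_ms <= foot <= t[-1]):
        raise WaveformError(f"detected foot {foot:.1f} ms outside the cardiac cycle")
    return float(foot)


def detect_arrival_times(series: VelocityEncodedSeries, min_snr: float = 5.0) -> ArrivalTimes:
    """Per-chord foot detection; failures are flagged, not fatal."""
    n = series.waveforms.shape[0]
    feet = np.full(n, np.nan)
    ok = np.zeros(n, dtype=bool)
    for i in range(n):
        try:
            feet[i] = detect_arrival_time(
                series.waveforms[i], series.temporal_resolution_ms, min_snr=min_snr
            )
            ok[i] = True
        except WaveformError:
            pass
    n_bad = int((~ok).sum())
    if n_bad:
        logger.warning("%d of %d chords flagged: no detectable upstroke", n_bad, n)
    return ArrivalTimes(feet, ok)


# ---------------------------------------------------------------------------
# regional PWV
# ---------------------------------------------------------------------------


def estimate_regional_pwv(
    arrival: ArrivalTimes,
    positions_mm: np.ndarray,
    segment_id: str = "total",
    chord_mask: np.ndarray | None = None,
    mad_multiplier: float = 3.0,
) -> RegionalPWV:
    """PWV (m/s) = 1 / slope of foot time (s) regressed on arc length (m).

    Distance is the low-noise variable, so time is regressed on distance.
    Chords whose residual from an initial fit exceeds ``mad_multiplier`` times
    the median absolute deviation are excluded once (single deterministic
    pass) before the final fit.  A non-positive slope (wave apparently
    travelling backward) yields an invalid result with a diagnostic rather
    than a bogus speed.
    """
    positions_mm = np.asarray(positions_mm, dtype=float)
    use = arrival.quality_ok.copy()
    if chord_mask is not None:
        use &= np.asarray(chord_mask, dtype=bool)
    if use.sum() < 3:
        raise ValueError(
            f"segment {segment_id}: only {int(use.sum())} usable chords; need at least 3"
        )
    s_m = positions_mm[use] / 1000.0
    t_s = arrival.foot_time_ms[use] / 1000.0

    slope, intercept = np.polyfit(s_m, t_s, 1)
    resid = t_s - (slope * s_m + intercept)
    mad = np.median(np.abs(resid - np.median(resid)))
    if mad > 0:
        keep = np.abs(resid - np.median(resid)) <= mad_multiplier * mad
        if keep.sum() >= 3 and keep.sum() < len(resid):
            s_m, t_s = s_m[keep], t_s[keep]
            slope, intercept = np.polyfit(s_m, t_s, 1)

    pred = slope * s_m + intercept
    ss_res = float(np.sum((t_s - pred) ** 2))
    ss_tot = float(np.sum((t_s - t_s.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0

    if slope <= 0:
        return RegionalPWV(
            segment_id=segment_id,
            pwv_m_per_s=float("nan"),
            fit_r2=r2,
            n_chords_used=len(s_m),
            valid=False,
            diagnostic="non-positive time-vs-distance slope: wave appears to travel backward",
        )
    return RegionalPWV(
        segment_id=segment_id,
        pwv_m_per_s=float(1.0 / slope),
        fit_r2=r2,
        n_chords_used=len(s_m),
    )


def regional_pwv_all_segments(
    series: VelocityEncodedSeries,
    min_snr: float = 5.0,
) -> list[RegionalPWV]:
    """Per-segment PWV (S1..S4, where labelled) plus the whole-aorta 'total'."""
    arrival = detect_arrival_times(series, min_snr=min_snr)
    out = []
    if series.segment_labels is not None:
        for seg in SEGMENT_LABELS:
            m = series.segment_labels == seg
            if m.sum() == 0:
                continue
            out.append(
                estimate_regional_pwv(arrival, series.chord_arc_length_mm, seg, chord_mask=m)
            )
    out.append(estimate_regional_pwv(arrival, series.chord_arc_length_mm, "total"))
    return out
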