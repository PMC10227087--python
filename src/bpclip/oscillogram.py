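"""Oscillogram construction: band-pass, pulse prominence, screening.

Each completed force level contributes one point to the subsampled blood
volume oscillogram: the 5-s PPG recording at that level is band-pass filtered
to the cardiac band (0.5-10 Hz), individual pulses are detected by peak
prominence, and the peak-to-trough amplitudes of all *complete* pulses (both
flanking troughs inside the window) are averaged. Across the 20 levels this
yields pulse amplitude versus applied force — the oscillogram — whose
envelope encodes blood pressure: maximal near mean arterial pressure,
collapsing to zero above systolic.

Before estimation the lowest and highest force levels are dropped (the finger
can leave the clip at the bottom of the range, and the spring bottoms out at
the top) and the remaining 18 amplitudes are min-max normalized to [0, 1].
Subjects are screened out when no level shows a usable pulse or when the
reference pulse pressure exceeds 80 mmHg.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from . import mechanics
from .mechanics import ContactGeometry, SpringModel
from .protocol import LevelRecord

BANDPASS_HZ = (0.5, 10.0)
MIN_PROMINENCE = 0.5  # grey levels; floor for calling something a pulse
MIN_PEAK_SPACING_S = 60.0 / 180.0  # one beat at the 180 bpm physiological cap
NO_PULSE_FLOOR = 1.0  # grey levels; below this a subject has no usable pulse
PULSE_PRESSURE_LIMIT = 80.0  # mmHg; exclusion threshold on SBP - DBP


def bandpass_ppg(series, frame_rate: float) -> np.ndarray:
    """Zero-phase 0.5-10 Hz band-pass of a uniformly sampled PPG series.

    4th-order Butterworth run forward-backward (sosfiltfilt); DC is removed
    and length preserved. Requires at least 20 Hz sampling so the 10 Hz band
    edge is below Nyquist; the upper edge is capped just under Nyquist when
    it would otherwise touch it.
    """
    if frame_rate < 20.0:
        raise ValueError(
            f"frame_rate {frame_rate} Hz too low: the 10 Hz band edge needs "
            ">= 20 Hz sampling"
        )
    x = np.asarray(series, dtype=float)
    lo, hi = BANDPASS_HZ
    hi = min(hi, 0.95 * frame_rate / 2.0)
    sos = signal.butter(4, [lo, hi], btype="band", fs=frame_rate, output="sos")
    return signal.sosfiltfilt(sos, x)


@dataclass(frozen=True)
class PulseAmplitude:
    """Mean complete-pulse amplitude of one level, with pulse count."""

    amplitude: float
    n_pulses: int

    @property
    def flagged(self) -> bool:
        """True when no complete pulse was found (amplitude forced to 0)."""
        return self.n_pulses == 0


def mean_pulse_amplitude(
    filtered,
    frame_rate: float,
    min_prominence: float = MIN_PROMINENCE,
    min_spacing_s: float = MIN_PEAK_SPACING_S,
) -> PulseAmplitude:
    """Average peak-to-trough amplitude of all complete pulses in a window.

    Peaks are detected with a minimum prominence floor and a minimum spacing
    of one beat at 180 bpm. A pulse is *complete* when troughs exist on both
    sides of its peak inside the window; its amplitude is the peak value
    minus the mean of its two flanking troughs. Returns amplitude 0 with
    ``n_pulses = 0`` when nothing qualifies.
    """
    x = np.asarray(filtered, dtype=float)
    if len(x) < 3:
        return PulseAmplitude(0.0, 0)
    distance = max(int(round(min_spacing_s * frame_rate)), 1)
    peaks, _ = signal.find_peaks(x, prominence=min_prominence, distance=distance)
    troughs, _ = signal.find_peaks(-x, prominence=min_prominence, distance=distance)
    if len(peaks) == 0 or len(troughs) == 0:
        return PulseAmplitude(0.0, 0)
    amplitudes = []
    for p in peaks:
        left = troughs[troughs < p]
        right = troughs[troughs > p]
        if len(left) == 0 or len(right) == 0:
            continue  # incomplete pulse at the window edge
        lo = x[left[-1]]
        hi = x[right[0]]
        amplitudes.append(x[p] - 0.5 * (lo + hi))
    if not amplitudes:
        return PulseAmplitude(0.0, 0)
    return PulseAmplitude(float(np.mean(amplitudes)), len(amplitudes))


@dataclass
class Oscillogram:
    """Per-level (force scale, applied pressure, pulse amplitude) points.

    Points are ordered by force. ``flags`` marks levels where no complete
    pulse was found. ``n_raw`` is the point count before endpoint exclusion;
    once ``normalized``, the retained amplitudes span exactly [0, 1].
    """

    force_scale: np.ndarray
    pressure_mmhg: np.ndarray
    amplitude: np.ndarray
    flags: np.ndarray = field(default_factory=lambda: np.array([], dtype=bool))
    n_raw: int = 0
    normalized: bool = False

    def __post_init__(self) -> None:
        self.force_scale = np.asarray(self.force_scale, dtype=float)
        self.pressure_mmhg = np.asarray(self.pressure_mmhg, dtype=float)
        self.amplitude = np.asarray(self.amplitude, dtype=float)
        if len(self.flags) == 0:
            self.flags = np.zeros(len(self.amplitude), dtype=bool)
        if self.n_raw == 0:
            self.n_raw = len(self.amplitude)

    def __len__(self) -> int:
        return len(self.amplitude)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "force_scale": self.force_scale,
                "pressure_mmhg": self.pressure_mmhg,
                "amplitude": self.amplitude,
                "no_pulse": self.flags,
            }
        )


def build_oscillogram(
    levels: list[LevelRecord],
    frame_rate: float,
    spring: SpringModel = mechanics.DEFAULT_SPRING,
    geometry: ContactGeometry = mechanics.DEFAULT_GEOMETRY,
) -> Oscillogram:
    """One oscillogram point per completed level.

    The level's force position is the median recorded force scale; its
    applied pressure follows from the spring/contact mechanics; its amplitude
    is the mean complete-pulse amplitude of the band-passed PPG. Raises if
    any level index in the range is missing.
    """
    if not levels:
        raise ValueError("no level records supplied")
    indices = sorted(r.level_index for r in levels)
    expected = list(range(indices[0], indices[0] + len(indices)))
    if indices != expected:
        gaps = sorted(set(expected) - set(indices))
        raise ValueError(f"missing levels in session: {gaps}")
    rows = []
    for rec in levels:
        scale = float(np.median(rec.force_scale))
        filtered = bandpass_ppg(rec.ppg, frame_rate)
        pulse = mean_pulse_amplitude(filtered, frame_rate)
        rows.append((scale, pulse.amplitude, pulse.flagged))
    rows.sort(key=lambda r: r[0])
    scales = np.array([r[0] for r in rows])
    pressures = mechanics.pressure_at_scale(
        np.clip(scales, 0.0, 100.0), spring, geometry
    )
    return Oscillogram(
        force_scale=scales,
        pressure_mmhg=np.asarray(pressures),
        amplitude=np.array([r[1] for r in rows]),
        flags=np.array([r[2] for r in rows]),
        n_raw=len(rows),
    )


def exclude_and_normalize(osc: Oscillogram, mode: str = "minmax") -> Oscillogram:
    """Drop the endpoint force levels and rescale amplitudes to [0, 1].

    ``mode="minmax"`` (default) maps the retained minimum to 0 and maximum to
    1; ``mode="max"`` divides by the retained maximum instead. Degenerate
    input (all retained amplitudes equal) raises.
    """
    if len(osc) < 3:
        raise ValueError("need at least 3 oscillogram points to exclude endpoints")
    sl = slice(1, -1)
    amp = osc.amplitude[sl].astype(float)
    lo, hi = amp.min(), amp.max()
    if hi == lo:
        raise ValueError("degenerate oscillogram: all amplitudes equal")
    if mode == "minmax":
        amp = (amp - lo) / (hi - lo)
    elif mode == "max":
        amp = amp / hi
    else:
        raise ValueError(f"unknown normalization mode {mode!r}")
    return Oscillogram(
        force_scale=osc.force_scale[sl].copy(),
        pressure_mmhg=osc.pressure_mmhg[sl].copy(),
        amplitude=amp,
        flags=osc.flags[sl].copy(),
        n_raw=osc.n_raw,
        normalized=True,
    )


@dataclass(frozen=True)
class ScreeningResult:
    """Outcome of the per-subject inclusion screening."""

    retained: bool
    reason: str  # "ok" | "no_pulse" | "pulse_pressure_gt_80"

    def __post_init__(self) -> None:
        if (self.reason == "ok") != self.retained:
            raise ValueError("reason must be 'ok' exactly when retained")


def screen_subject(
    osc: Oscillogram,
    sbp_ref: float,
    dbp_ref: float,
    no_pulse_floor: float = NO_PULSE_FLOOR,
) -> ScreeningResult:
    """Apply the preprocessing exclusion rules to one subject.

    A subject is dropped when the raw oscillogram never reaches the pulse
    floor (insufficient perfusion) or when the reference pulse pressure
    exceeds 80 mmHg; insufficient perfusion takes precedence when both hold.
    """
    if osc.normalized:
        raise ValueError("screening must run on the raw (un-normalized) oscillogram")
    if len(osc) == 0 or float(np.max(osc.amplitude)) < no_pulse_floor:
        return ScreeningResult(retained=False, reason="no_pulse")
    if sbp_ref - dbp_ref > PULSE_PRESSURE_LIMIT:
        return ScreeningResult(retained=False, reason="pulse_pressure_gt_80")
    return ScreeningResult(retained=True, reason="ok")
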