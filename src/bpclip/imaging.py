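"""Per-frame extraction of force (disc size) and PPG (disc brightness).

Mirrors the measurement app's three per-frame features:

1. **Applied force** — the pinhole projection's area is the number of pixels
   brighter than a fixed threshold of 20 grey levels, counted after global
   histogram equalization of the raw frame (equalization makes the count
   robust to how bright the disc happens to be for a given finger); the
   circle diameter follows from the area, and the force scale is the
   diameter's position within the per-session 0 %/100 % calibration range.
2. **PPG** — the mean of the raw pixel values in the closed band [20, 254]
   (saturated pixels excluded), i.e. the disc's mean brightness.
3. **Force display smoothing** — a zero-phase low-pass filter below the
   cardiac band removes the pulse artifact from the force trace.

Interpretation constants (documented here because the thresholds admit open
and closed readings): the area threshold is strict (``value > 20``); the PPG
band is the closed interval ``[20, 254]``; the PPG mean is computed on the
raw, un-equalized frame.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

from .protocol import LevelRecord, SessionRecording

logger = logging.getLogger(__name__)

AREA_THRESHOLD = 20
PPG_BAND = (20, 254)  # closed interval of raw grey values
DEFAULT_FORCE_LOWPASS_HZ = 0.4  # below the slowest plausible heart rate


class CalibrationError(ValueError):
    """Raised when the 0 %/100 % force-scale calibration is unusable."""


@dataclass(frozen=True)
class ForceScaleCalibration:
    """Disc diameters (px) recorded at rest (0 %) and fully pressed (100 %)."""

    size_at_0pct: float
    size_at_100pct: float

    def __post_init__(self) -> None:
        if not self.size_at_0pct > 0:
            raise CalibrationError("size_at_0pct must be > 0")
        if not self.size_at_100pct > self.size_at_0pct:
            raise CalibrationError("size_at_100pct must exceed size_at_0pct")


@dataclass(frozen=True)
class FrameFeatures:
    """Quantities extracted from a single frame."""

    area: int
    diameter: float
    force_scale: float
    ppg_value: float
    timestamp: float


def _check_uint8(frame: np.ndarray) -> np.ndarray:
    frame = np.asarray(frame)
    if frame.dtype != np.uint8:
        raise ValueError(f"expected an 8-bit frame, got dtype {frame.dtype}")
    return frame


def equalize_histogram(frame: np.ndarray) -> np.ndarray:
    """Global 8-bit histogram equalization (integer CDF lookup table).

    The standard formulation maps grey value ``v`` to
    ``round(255 * (cdf(v) - cdf_min) / (n_pixels - cdf_min))`` so the
    occupied range is stretched to the full [0, 255]. A frame with a single
    grey value is returned unchanged. Pixel counts per mapped value are
    conserved.
    """
    frame = _check_uint8(frame)
    hist = np.bincount(frame.ravel(), minlength=256)
    cdf = hist.cumsum()
    cdf_min = cdf[int(frame.min())]
    total = cdf[-1]
    if cdf_min == total:  # single grey value: no contrast to redistribute
        return frame.copy()
    lut = np.rint((cdf - cdf_min) * 255.0 / (total - cdf_min))
    return np.clip(lut, 0, 255).astype(np.uint8)[frame]


def detect_projection_area(frame: np.ndarray) -> int:
    """Projection area in pixels: count of values strictly above 20.

    The frame is expected to have been histogram-equalized already.
    """
    frame = _check_uint8(frame)
    return int(np.count_nonzero(frame > AREA_THRESHOLD))


def diameter_from_area(area: float) -> float:
    """Circle diameter (px) of a disc with the given pixel area."""
    return 2.0 * math.sqrt(area / math.pi)


def extract_ppg_sample(frame: np.ndarray) -> float:
    """Mean raw grey level of pixels in the closed band [20, 254].

    Saturated (255) and background (< 20) pixels are excluded. Returns NaN —
    the null marker — when no pixel qualifies, and logs the event.
    """
    frame = _check_uint8(frame)
    lo, hi = PPG_BAND
    mask = (frame >= lo) & (frame <= hi)
    if not mask.any():
        logger.warning("no pixels in PPG band [%d, %d]; returning NaN", lo, hi)
        return float("nan")
    return float(frame[mask].mean())


def force_scale_from_diameter(
    d: float, cal: ForceScaleCalibration
) -> float:
    """Force scale in % of the calibrated 0-100 % diameter range.

    Linear in diameter; clipped to the diagnostic range [-10, 110] so that
    slightly out-of-range frames remain visible rather than silently capped
    at the working range.
    """
    span = cal.size_at_100pct - cal.size_at_0pct
    if span <= 0:
        raise CalibrationError("degenerate calibration: equal disc sizes")
    value = 100.0 * (d - cal.size_at_0pct) / span
    return float(np.clip(value, -10.0, 110.0))


def smooth_force_signal(
    series,
    frame_rate: float,
    cutoff_hz: float = DEFAULT_FORCE_LOWPASS_HZ,
) -> np.ndarray:
    """Zero-phase low-pass of the force trace to remove the pulse artifact.

    4th-order Butterworth run forward-backward; unit gain at DC, length
    preserved. Series too short for the filter warm-up pass through
    unchanged with a warning.
    """
    x = np.asarray(series, dtype=float)
    sos = signal.butter(4, cutoff_hz, btype="low", fs=frame_rate, output="sos")
    padlen = 3 * (2 * sos.shape[0] + 1)
    if len(x) <= padlen:
        warnings.warn(
            f"series of length {len(x)} too short for low-pass warm-up; "
            "returning it unchanged",
            stacklevel=2,
        )
        return x.copy()
    return signal.sosfiltfilt(sos, x)


def calibration_from_frames(
    frame_at_rest: np.ndarray, frame_pressed: np.ndarray
) -> ForceScaleCalibration:
    """Build the force-scale calibration from the 0 % and 100 % frames."""
    d0 = diameter_from_area(
        detect_projection_area(equalize_histogram(frame_at_rest))
    )
    d100 = diameter_from_area(
        detect_projection_area(equalize_histogram(frame_pressed))
    )
    if d0 <= 0 or d100 <= d0:
        raise CalibrationError(
            f"calibration discs not resolvable (d0={d0:.1f}, d100={d100:.1f})"
        )
    return ForceScaleCalibration(size_at_0pct=d0, size_at_100pct=d100)


def extract_frame_features(
    frame: np.ndarray, timestamp: float, cal: ForceScaleCalibration
) -> FrameFeatures:
    """All per-frame features: area and force from the equalized frame, PPG
    from the raw frame."""
    area = detect_projection_area(equalize_histogram(frame))
    d = diameter_from_area(area)
    return FrameFeatures(
        area=area,
        diameter=d,
        force_scale=force_scale_from_diameter(d, cal),
        ppg_value=extract_ppg_sample(frame),
        timestamp=timestamp,
    )


def extract_session_features(
    session: SessionRecording,
    cal: ForceScaleCalibration | None = None,
) -> pd.DataFrame:
    """Per-frame feature table for a recorded session.

    Uses the session's stored calibration frames when ``cal`` is not given.
    Columns: timestamp, level_index, area, diameter, force_scale, ppg_value.
    """
    if session.frames is None or len(session.frames) == 0:
        raise ValueError("session has no frames to extract features from")
    if cal is None:
        if session.calibration_frames is None:
            raise CalibrationError(
                "no calibration supplied and session has no calibration frames"
            )
        cal = calibration_from_frames(*session.calibration_frames)
    rows = []
    for frame, t, lvl in zip(
        session.frames, session.frame_timestamps, session.frame_levels
    ):
        f = extract_frame_features(frame, float(t), cal)
        rows.append(
            {
                "timestamp": f.timestamp,
                "level_index": int(lvl),
                "area": f.area,
                "diameter": f.diameter,
                "force_scale": f.force_scale,
                "ppg_value": f.ppg_value,
            }
        )
    return pd.DataFrame(rows)


def levels_from_features(
    features: pd.DataFrame, session: SessionRecording
) -> list[LevelRecord]:
    """Re-assemble per-level records from an extracted feature table.

    The returned records carry the image-derived force scale and PPG series,
    making the downstream oscillogram independent of any ground truth the
    synthetic session may carry.
    """
    records = []
    for lvl, grp in features.groupby("level_index", sort=True):
        target = next(
            (r.target_scale for r in session.levels if r.level_index == lvl),
            float("nan"),
        )
        attempts = next(
            (r.attempts for r in session.levels if r.level_index == lvl), 1
        )
        records.append(
            LevelRecord(
                level_index=int(lvl),
                target_scale=float(target),
                timestamps=grp["timestamp"].to_numpy(),
                force_scale=grp["force_scale"].to_numpy(),
                ppg=grp["ppg_value"].to_numpy(),
                attempts=int(attempts),
            )
        )
    return records


def session_levels(
    session: SessionRecording, use_frames: bool | None = None
) -> list[LevelRecord]:
    """Per-level force/PPG records for a session.

    When frames are present (and ``use_frames`` is not False) the records are
    re-extracted through the imaging pipeline; otherwise the session's stored
    signal-level records are returned.
    """
    has_frames = session.frames is not None and len(session.frames) > 0
    if use_frames is None:
        use_frames = has_frames
    if use_frames:
        if not has_frames:
            raise ValueError("use_frames=True but session has no frames")
        return levels_from_features(extract_session_features(session), session)
    return session.levels
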