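"""Guided measurement protocol: target levels, tolerance band, state machine.

The measurement app walks the user through a staircase of force targets. For
each target the on-screen indicator is RED until the applied force enters the
tolerance band around the target, YELLOW while the user holds the force
steadily for ``hold_s`` seconds, and GREEN while ``record_s`` seconds of data
are collected. Leaving the band at any point during YELLOW or GREEN discards
the partial data and restarts the level. After all levels are completed the
session terminates automatically. Movement is detected through the only
concrete signal the protocol defines: the force leaving the tolerance band.

With the defaults (20 levels, 2 s hold + 5 s record) an ideal user who
acquires each target instantly and never leaves the band finishes in exactly
``20 * 7 = 140`` seconds.
"""

from __future__ import annotations

import dataclasses
import enum
from dataclasses import dataclass, field

import numpy as np

_T_EPS = 1e-9  # tolerance for floating-point elapsed-time comparisons


@dataclass(frozen=True)
class ProtocolConfig:
    """Staircase protocol parameters.

    ``tolerance`` is in absolute percentage points of the 0-100 % force scale.
    """

    n_levels: int = 20
    scale_lo: float = 5.0
    scale_hi: float = 95.0
    tolerance: float = 2.0
    hold_s: float = 2.0
    record_s: float = 5.0

    def __post_init__(self) -> None:
        if self.n_levels < 2:
            raise ValueError("n_levels must be >= 2")
        if not self.scale_lo < self.scale_hi:
            raise ValueError("scale_lo must be < scale_hi")
        if not self.tolerance > 0:
            raise ValueError("tolerance must be > 0")
        if self.hold_s < 0 or not self.record_s > 0:
            raise ValueError("hold_s must be >= 0 and record_s > 0")


DEFAULT_PROTOCOL = ProtocolConfig()


def target_levels(cfg: ProtocolConfig = DEFAULT_PROTOCOL) -> np.ndarray:
    """Force-scale targets in %, endpoint-inclusive and uniformly spaced."""
    return np.linspace(cfg.scale_lo, cfg.scale_hi, cfg.n_levels)


class GuidanceState(enum.Enum):
    RED = "red"
    YELLOW = "yellow"
    GREEN = "green"
    TERMINATED = "terminated"


@dataclass
class LevelRecord:
    """Data recorded for one completed force level."""

    level_index: int
    target_scale: float
    timestamps: np.ndarray
    force_scale: np.ndarray
    ppg: np.ndarray
    attempts: int = 1

    @property
    def recorded_duration(self) -> float:
        """Nominal recorded duration in s (sample count over sampling rate)."""
        if len(self.timestamps) < 2:
            return 0.0
        dt = float(np.median(np.diff(self.timestamps)))
        return len(self.timestamps) * dt


@dataclass
class SessionRecording:
    """One measurement session: per-level records plus optional frame stack."""

    levels: list[LevelRecord]
    complete: bool
    duration_s: float
    frame_rate: float
    config: dict = field(default_factory=dict)
    seed: int | None = None
    frames: np.ndarray | None = None  # (n, rows, cols) uint8, recorded only
    frame_timestamps: np.ndarray | None = None
    frame_levels: np.ndarray | None = None  # level index of each frame
    calibration_frames: np.ndarray | None = None  # (2, rows, cols): 0 %, 100 %
    subject: object | None = None  # ground truth for synthetic sessions

    @property
    def n_levels(self) -> int:
        return len(self.levels)


class GuidanceStateMachine:
    """Sample-driven implementation of the RED/YELLOW/GREEN indicator.

    Feed ``advance(force_scale, t, ppg)`` with samples in non-decreasing time
    order. Completed levels accumulate in :attr:`completed`; the recorded
    window of a level is exactly ``[t_enter + hold_s, t_enter + hold_s +
    record_s)``. Completion is timestamped at the exact window end rather than
    the triggering sample's timestamp, so session timing is free of
    sampling-grid jitter.
    """

    def __init__(self, cfg: ProtocolConfig = DEFAULT_PROTOCOL):
        self.cfg = cfg
        self.targets = target_levels(cfg)
        self.state = GuidanceState.RED
        self.level_index = 0
        self.attempts = 1
        self.completed: list[LevelRecord] = []
        self._t_enter: float | None = None
        self._buffer: list[tuple[float, float, float]] = []
        self._last_t: float | None = None
        self.last_completion_time: float | None = None

    @property
    def current_target(self) -> float | None:
        if self.level_index >= len(self.targets):
            return None
        return float(self.targets[self.level_index])

    def _in_band(self, force_scale: float) -> bool:
        return abs(force_scale - self.current_target) <= self.cfg.tolerance

    def _discard(self) -> None:
        self.state = GuidanceState.RED
        self._t_enter = None
        self._buffer = []
        self.attempts += 1

    def _complete_level(self) -> None:
        record_start = self._t_enter + self.cfg.hold_s
        end = record_start + self.cfg.record_s
        kept = [
            s for s in self._buffer if record_start - _T_EPS <= s[0] < end - _T_EPS
        ]
        ts, fs, pg = (np.array(col) for col in zip(*kept)) if kept else (
            np.array([]),
            np.array([]),
            np.array([]),
        )
        self.completed.append(
            LevelRecord(
                level_index=self.level_index,
                target_scale=self.current_target,
                timestamps=ts,
                force_scale=fs,
                ppg=pg,
                attempts=self.attempts,
            )
        )
        self.last_completion_time = end
        self.level_index += 1
        self.attempts = 1
        self._t_enter = None
        self._buffer = []
        self.state = (
            GuidanceState.TERMINATED
            if self.level_index >= self.cfg.n_levels
            else GuidanceState.RED
        )

    def advance(self, force_scale: float, t: float, ppg: float = np.nan) -> GuidanceState:
        """Process one (force, time, ppg) sample and return the new state."""
        if self._last_t is not None and t < self._last_t - _T_EPS:
            raise ValueError(
                f"timestamps must be non-decreasing: {t} after {self._last_t}"
            )
        self._last_t = t
        if self.state is GuidanceState.TERMINATED:
            return self.state

        if self.state is GuidanceState.RED:
            if self._in_band(force_scale):
                self.state = GuidanceState.YELLOW
                self._t_enter = t
                self._buffer = [(t, force_scale, ppg)]
            return self.state

        if not self._in_band(force_scale):
            self._discard()
            return self.state

        self._buffer.append((t, force_scale, ppg))
        if self.state is GuidanceState.YELLOW:
            if t - self._t_enter >= self.cfg.hold_s - _T_EPS:
                self.state = GuidanceState.GREEN
        if self.state is GuidanceState.GREEN:
            record_start = self._t_enter + self.cfg.hold_s
            if t - record_start >= self.cfg.record_s - _T_EPS:
                self._complete_level()
        return self.state


@dataclass(frozen=True)
class UserModel:
    """Behavioural model of the person driving the clip.

    ``acquisition_delay_s`` is the time spent ramping to each new target;
    ``tremor_sd`` the within-band force jitter in percentage points (truncated
    so it never causes an accidental violation on its own); ``violation_rate``
    the per-attempt probability of leaving the band mid-level, which restarts
    that level. The ideal user has all three at zero.
    """

    acquisition_delay_s: float = 0.5
    tremor_sd: float = 0.3
    violation_rate: float = 0.05
    max_attempts: int = 10


IDEAL_USER = UserModel(acquisition_delay_s=0.0, tremor_sd=0.0, violation_rate=0.0)


def _attempt_times(t0: float, duration: float, dt: float) -> np.ndarray:
    n = int(np.floor(duration / dt + _T_EPS))
    times = t0 + np.arange(n + 1) * dt
    end = t0 + duration
    if times[-1] < end - _T_EPS:
        times = np.append(times, end)
    else:
        times[-1] = end  # pin the boundary sample to the exact window end
    return times


def run_session(
    user: UserModel = IDEAL_USER,
    cfg: ProtocolConfig = DEFAULT_PROTOCOL,
    seed: int = 0,
    sampler=None,
    frame_rate: float = 30.0,
) -> SessionRecording:
    """Drive the guidance state machine with a simulated user.

    ``sampler(times, force_scales)`` supplies the PPG value seen at each
    sample (e.g. the synthetic subject's in-disc brightness); ``None`` records
    NaNs. Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    machine = GuidanceStateMachine(cfg)
    dt = 1.0 / frame_rate
    attempt_len = cfg.hold_s + cfg.record_s
    t = 0.0
    complete = True

    for target in machine.targets:
        t += user.acquisition_delay_s
        while True:
            if machine.attempts > user.max_attempts:
                complete = False
                break
            violated = rng.random() < user.violation_rate
            # a violation can strike anywhere in the hold+record window
            duration = (
                rng.uniform(dt, attempt_len - dt) if violated else attempt_len
            )
            times = _attempt_times(t, duration, dt)
            tremor = (
                np.clip(
                    rng.normal(0.0, user.tremor_sd, len(times)),
                    -0.9 * cfg.tolerance,
                    0.9 * cfg.tolerance,
                )
                if user.tremor_sd > 0
                else np.zeros(len(times))
            )
            forces = target + tremor
            ppg = (
                sampler(times, forces)
                if sampler is not None
                else np.full(len(times), np.nan)
            )
            for ti, fi, pi in zip(times, forces, ppg):
                machine.advance(fi, ti, pi)
            if violated:
                t = times[-1]
                machine.advance(target + 1.5 * cfg.tolerance, t)  # leave band
                continue
            t = machine.last_completion_time
            break
        if not complete:
            break

    return SessionRecording(
        levels=machine.completed,
        complete=complete and len(machine.completed) == cfg.n_levels,
        duration_s=t,
        frame_rate=frame_rate,
        config={
            "protocol": dataclasses.asdict(cfg),
            "user": dataclasses.asdict(user),
        },
        seed=seed,
    )
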