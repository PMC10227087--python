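"""Physics-based synthetic frame and cohort generator.

This module is the forward model of the whole measurement chain, run in
reverse: given a virtual subject with known systolic/diastolic pressure, it
renders the 8-bit camera frames the clip would produce while the subject
follows the guided force staircase. Each frame contains a bright disc — the
pinhole projection — whose diameter encodes spring compression (and hence
applied force) and whose brightness pulses with the cardiac cycle. The pulse
amplitude follows a Gaussian oscillometric envelope centred on mean arterial
pressure that collapses to zero once the applied pressure occludes the artery
(at and above systolic pressure).

Three fidelity levels are offered, all sharing the same physics:

``"frames"``
    Full frame stacks (uint8), for exercising the imaging pipeline.
``"signal"``
    Per-level PPG time series as the in-disc spatial mean would see them
    (pixel noise attenuated by the square root of the disc pixel count),
    skipping rasterisation. This is the default cohort condition.
``"amplitude"``
    No time series at all; the envelope evaluated at the level pressures.
    Used for cheap statistical checks of the population model.

The rendered background is a flat dark level: the clip is a sealed enclosure,
so outside the projection the sensor reads an essentially constant black
level, while photon/sensor noise is modelled inside the disc where there is
signal. Sessions are reproducible bit-for-bit for a fixed seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

from . import mechanics, protocol
from .mechanics import (
    DEFAULT_GEOMETRY,
    DEFAULT_SPRING,
    ContactGeometry,
    SpringModel,
)
from .protocol import (
    DEFAULT_PROTOCOL,
    IDEAL_USER,
    ProtocolConfig,
    SessionRecording,
    UserModel,
)

SBP_COLLAPSE_WIDTH = 5.0
"""Width in mmHg of the smooth collapse of the envelope just below SBP."""


@dataclass(frozen=True)
class VirtualSubject:
    """Ground-truth physiology of one simulated participant.

    ``perfusion_gain`` scales the pulse amplitude in grey levels at the
    envelope peak; ``envelope_width`` is the Gaussian width of the
    oscillometric envelope in mmHg; ``skin_baseline`` the brightness of the
    projection with the pulse at its trough of blood volume (0-255).
    """

    sbp_true: float
    dbp_true: float
    heart_rate: float = 72.0
    perfusion_gain: float = 30.0
    envelope_width: float = 22.0
    skin_baseline: float = 180.0

    def __post_init__(self) -> None:
        if not self.sbp_true > self.dbp_true:
            raise ValueError("sbp_true must exceed dbp_true")
        if not 36.0 <= self.heart_rate <= 180.0:
            raise ValueError("heart_rate must lie in [36, 180] bpm")
        if self.perfusion_gain < 0:
            raise ValueError("perfusion_gain must be >= 0")

    @property
    def mbp_true(self) -> float:
        """Mean arterial pressure, SBP/3 + 2*DBP/3."""
        return self.sbp_true / 3.0 + 2.0 * self.dbp_true / 3.0

    @property
    def pulse_pressure(self) -> float:
        return self.sbp_true - self.dbp_true


@dataclass(frozen=True)
class OpticsModel:
    """Pinhole-projection optics of the synthetic camera.

    The projected disc grows linearly with spring compression from ``d_min``
    (finger resting, no force) to ``d_max`` pixels (fully pressed).
    ``noise_sd`` is per-pixel Gaussian sensor noise in grey levels, applied
    within the disc.
    """

    d_min: float = 24.0
    d_max: float = 120.0
    frame_shape: tuple[int, int] = (128, 128)
    background_level: float = 2.0
    noise_sd: float = 2.0

    def __post_init__(self) -> None:
        if not 0 < self.d_min < self.d_max:
            raise ValueError("need 0 < d_min < d_max")
        if self.d_max > min(self.frame_shape):
            raise ValueError("d_max must fit inside the frame")
        if not 0 <= self.background_level < 20:
            raise ValueError(
                "background_level must stay below the detection threshold (20)"
            )
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


DEFAULT_OPTICS = OpticsModel()

# Reduced-resolution optics for fast full-frame cohort work. The larger
# d_min keeps the resting disc well resolved at 64 px frames.
SMALL_OPTICS = OpticsModel(d_min=16.0, d_max=56.0, frame_shape=(64, 64))


def envelope_amplitude(applied_pressure, subject: VirtualSubject):
    """Pulse amplitude (grey levels) at an external applied pressure (mmHg).

    Gaussian in ``applied_pressure - MBP`` with scale ``perfusion_gain`` and
    width ``envelope_width``, multiplied by a smoothstep factor that falls
    from 1 to 0 over the ``SBP_COLLAPSE_WIDTH`` mmHg below systolic pressure:
    at and above SBP the artery is occluded and the pulse vanishes.
    """
    p = np.asarray(applied_pressure, dtype=float)
    if np.any(p < 0):
        raise ValueError("applied_pressure must be >= 0")
    gauss = np.exp(-((p - subject.mbp_true) ** 2) / (2.0 * subject.envelope_width**2))
    t = np.clip((subject.sbp_true - p) / SBP_COLLAPSE_WIDTH, 0.0, 1.0)
    out = subject.perfusion_gain * gauss * t * t * (3.0 - 2.0 * t)
    if np.ndim(applied_pressure) == 0:
        return float(out)
    return out


def pulse_waveform(phase, dicrotic: float = 0.0):
    """Cardiac blood-volume waveform versus phase, peak-to-trough 1.

    A raised cosine (maximum blood volume at phase 0); ``dicrotic`` adds an
    optional second-harmonic notch, after which the waveform is renormalised
    numerically to unit peak-to-trough amplitude.
    """
    w = 0.5 * (1.0 + np.cos(np.asarray(phase, dtype=float)))
    if dicrotic:
        w = w + dicrotic * 0.5 * (1.0 + np.cos(2.0 * np.asarray(phase) - np.pi / 2))
        grid = np.linspace(0, 2 * np.pi, 2048)
        ref = 0.5 * (1.0 + np.cos(grid)) + dicrotic * 0.5 * (
            1.0 + np.cos(2.0 * grid - np.pi / 2)
        )
        w = (w - ref.min()) / (ref.max() - ref.min())
    return w


def disc_diameter(
    compression: float,
    optics: OpticsModel = DEFAULT_OPTICS,
    spring: SpringModel = DEFAULT_SPRING,
) -> float:
    """Projected disc diameter in px at a given spring compression in mm."""
    frac = compression / spring.max_travel
    return optics.d_min + (optics.d_max - optics.d_min) * frac


def _disc_mask(shape: tuple[int, int], diameter: float) -> np.ndarray:
    rows, cols = shape
    cy, cx = (rows - 1) / 2.0, (cols - 1) / 2.0
    yy, xx = np.ogrid[:rows, :cols]
    return (yy - cy) ** 2 + (xx - cx) ** 2 <= (diameter / 2.0) ** 2


def render_frame(
    compression: float,
    phase: float,
    subject: VirtualSubject,
    optics: OpticsModel = DEFAULT_OPTICS,
    spring: SpringModel = DEFAULT_SPRING,
    geometry: ContactGeometry = DEFAULT_GEOMETRY,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Render one uint8 camera frame at a spring compression and cardiac phase.

    The disc's interior brightness is ``skin_baseline`` minus the pulse
    modulation (more blood absorbs more light), plus in-disc sensor noise;
    the surround sits at the flat enclosure background level.
    """
    d = disc_diameter(compression, optics, spring)
    if d > min(optics.frame_shape):
        raise ValueError(
            f"disc diameter {d:.1f} px exceeds frame {optics.frame_shape}"
        )
    pressure = mechanics.pressure_from_compression(compression, spring, geometry)
    amp = envelope_amplitude(pressure, subject)
    value = subject.skin_baseline - amp * float(pulse_waveform(phase))
    img = np.full(optics.frame_shape, float(optics.background_level))
    mask = _disc_mask(optics.frame_shape, d)
    img[mask] = value
    if rng is not None and optics.noise_sd > 0:
        img[mask] += rng.normal(0.0, optics.noise_sd, int(mask.sum()))
    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


def ppg_sampler(
    subject: VirtualSubject,
    optics: OpticsModel = DEFAULT_OPTICS,
    spring: SpringModel = DEFAULT_SPRING,
    geometry: ContactGeometry = DEFAULT_GEOMETRY,
    rng: np.random.Generator | None = None,
):
    """Build ``sample(times, force_scales) -> ppg`` for signal-level synthesis.

    Returns the in-disc spatial mean brightness the imaging stage would
    extract from frames: per-pixel noise is attenuated by sqrt of the disc
    pixel count at the current compression.
    """

    def sample(times, force_scales):
        times = np.asarray(times, dtype=float)
        scales = np.asarray(force_scales, dtype=float)
        comp = mechanics.compression_from_scale(
            np.clip(scales, 0.0, 100.0), spring
        )
        pressure = mechanics.pressure_from_compression(comp, spring, geometry)
        amp = envelope_amplitude(pressure, subject)
        phase = 2.0 * np.pi * subject.heart_rate / 60.0 * times
        v = subject.skin_baseline - amp * pulse_waveform(phase)
        if rng is not None and optics.noise_sd > 0:
            d = disc_diameter(comp, optics, spring)
            n_px = np.maximum(np.pi * d**2 / 4.0, 1.0)
            v = v + rng.normal(0.0, 1.0, len(times)) * optics.noise_sd / np.sqrt(
                n_px
            )
        return np.clip(v, 0.0, 255.0)

    return sample


def _render_session_frames(
    session: SessionRecording,
    subject: VirtualSubject,
    optics: OpticsModel,
    spring: SpringModel,
    geometry: ContactGeometry,
    rng: np.random.Generator,
) -> None:
    frames, stamps, level_ids = [], [], []
    for rec in session.levels:
        comp = mechanics.compression_from_scale(
            np.clip(rec.force_scale, 0.0, 100.0), spring
        )
        for t, c in zip(rec.timestamps, comp):
            phase = 2.0 * np.pi * subject.heart_rate / 60.0 * t
            frames.append(
                render_frame(c, phase, subject, optics, spring, geometry, rng)
            )
            stamps.append(t)
            level_ids.append(rec.level_index)
    session.frames = np.stack(frames) if frames else None
    session.frame_timestamps = np.asarray(stamps)
    session.frame_levels = np.asarray(level_ids, dtype=int)
    # brightness-adjustment replay: disc size at rest and fully pressed
    session.calibration_frames = np.stack(
        [
            render_frame(0.0, 0.0, subject, optics, spring, geometry, rng),
            render_frame(
                spring.max_travel, 0.0, subject, optics, spring, geometry, rng
            ),
        ]
    )


def synth_session(
    subject: VirtualSubject,
    optics: OpticsModel = DEFAULT_OPTICS,
    cfg: ProtocolConfig = DEFAULT_PROTOCOL,
    frame_rate: float = 30.0,
    seed: int = 0,
    spring: SpringModel = DEFAULT_SPRING,
    geometry: ContactGeometry = DEFAULT_GEOMETRY,
    user: UserModel = IDEAL_USER,
    fidelity: str = "frames",
) -> SessionRecording:
    """Simulate one full guided session for a virtual subject.

    Runs the protocol state machine with the given user model, then (for
    ``fidelity="frames"``) rasterises a frame for every recorded sample plus
    the two brightness-adjustment calibration frames. Bit-identical for a
    fixed seed.
    """
    if fidelity not in ("frames", "signal"):
        raise ValueError(f"unknown fidelity {fidelity!r}")
    rng = np.random.default_rng(seed)
    sig_rng = np.random.default_rng(rng.integers(2**31))
    frame_rng = np.random.default_rng(rng.integers(2**31))
    user_seed = int(rng.integers(2**31))
    sampler = ppg_sampler(
        subject, optics, spring, geometry, rng=sig_rng
    )
    session = protocol.run_session(
        user=user, cfg=cfg, seed=user_seed, sampler=sampler, frame_rate=frame_rate
    )
    session.seed = seed
    session.subject = subject
    session.config["optics"] = dataclasses.asdict(optics)
    session.config["spring"] = dataclasses.asdict(spring)
    session.config["geometry"] = dataclasses.asdict(geometry)
    session.config["fidelity"] = fidelity
    if fidelity == "frames" and session.complete:
        _render_session_frames(
            session, subject, optics, spring, geometry, frame_rng
        )
    return session


@dataclass(frozen=True)
class PopulationModel:
    """Sampling distributions for synthetic cohorts.

    Blood pressures are drawn from normal distributions matching the study
    population (SBP 116.8 +/- 20.3 mmHg, DBP 73.5 +/- 12.3 mmHg), with
    rejection sampling enforcing a physiological pulse pressure between
    ``pp_min`` and ``pp_max``. Heart rate is normal, truncated to [36, 180].
    Perfusion gain and envelope width vary uniformly/normally across subjects.
    """

    sbp_mean: float = 116.8
    sbp_sd: float = 20.3
    dbp_mean: float = 73.5
    dbp_sd: float = 12.3
    hr_mean: float = 72.0
    hr_sd: float = 10.0
    gain_lo: float = 15.0
    gain_hi: float = 45.0
    envelope_width_mean: float = 22.0
    envelope_width_sd: float = 3.0
    baseline_lo: float = 150.0
    baseline_hi: float = 210.0
    pp_min: float = 15.0
    pp_max: float = 80.0
    pulseless_gain: float = 0.05
    wide_pp_lo: float = 85.0
    wide_pp_hi: float = 95.0


DEFAULT_POPULATION = PopulationModel()


def draw_subject(
    rng: np.random.Generator,
    population: PopulationModel = DEFAULT_POPULATION,
    pulseless: bool = False,
    wide_pulse_pressure: bool = False,
) -> VirtualSubject:
    """Draw one subject; forced flags override perfusion or pulse pressure."""
    pop = population
    for _ in range(10_000):
        sbp = rng.normal(pop.sbp_mean, pop.sbp_sd)
        dbp = rng.normal(pop.dbp_mean, pop.dbp_sd)
        if wide_pulse_pressure:
            sbp = dbp + rng.uniform(pop.wide_pp_lo, pop.wide_pp_hi)
        if pop.pp_min <= sbp - dbp <= pop.pp_max or wide_pulse_pressure:
            if dbp > 20 and sbp < 250:
                break
    else:  # pragma: no cover - astronomically unlikely
        raise RuntimeError("rejection sampling failed")
    hr = float(np.clip(rng.normal(pop.hr_mean, pop.hr_sd), 36.0, 180.0))
    gain = (
        pop.pulseless_gain
        if pulseless
        else float(rng.uniform(pop.gain_lo, pop.gain_hi))
    )
    width = float(
        np.clip(rng.normal(pop.envelope_width_mean, pop.envelope_width_sd), 10, 40)
    )
    return VirtualSubject(
        sbp_true=float(sbp),
        dbp_true=float(dbp),
        heart_rate=hr,
        perfusion_gain=gain,
        envelope_width=width,
        skin_baseline=float(rng.uniform(pop.baseline_lo, pop.baseline_hi)),
    )


def draw_population(
    n: int,
    seed: int = 0,
    population: PopulationModel = DEFAULT_POPULATION,
) -> list[VirtualSubject]:
    """Draw ``n`` ordinary subjects (no forced flags), reproducibly."""
    rng = np.random.default_rng(seed)
    return [draw_subject(rng, population) for _ in range(n)]


def synth_cohort(
    n: int,
    seed: int = 0,
    population: PopulationModel = DEFAULT_POPULATION,
    n_pulseless: int = 0,
    n_wide_pulse_pressure: int = 0,
    optics: OpticsModel = DEFAULT_OPTICS,
    cfg: ProtocolConfig = DEFAULT_PROTOCOL,
    frame_rate: float = 30.0,
    spring: SpringModel = DEFAULT_SPRING,
    geometry: ContactGeometry = DEFAULT_GEOMETRY,
    user: UserModel = IDEAL_USER,
    fidelity: str = "signal",
) -> list[SessionRecording]:
    """Simulate a cohort of guided sessions with known ground truth.

    ``n_pulseless`` subjects are forced below the perfusion detection floor
    and ``n_wide_pulse_pressure`` subjects are forced to a reference pulse
    pressure above 80 mmHg, at seeded random positions in the roster; all
    other subjects satisfy the ordinary population constraints. Each returned
    session carries its :class:`VirtualSubject` ground truth.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if n_pulseless + n_wide_pulse_pressure > n:
        raise ValueError("more forced flags than subjects")
    rng = np.random.default_rng(seed)
    flagged = rng.choice(n, size=n_pulseless + n_wide_pulse_pressure, replace=False)
    pulseless_idx = set(flagged[:n_pulseless].tolist())
    wide_idx = set(flagged[n_pulseless:].tolist())
    sessions = []
    for i in range(n):
        subject = draw_subject(
            rng,
            population,
            pulseless=i in pulseless_idx,
            wide_pulse_pressure=i in wide_idx,
        )
        sess_seed = int(rng.integers(2**31))
        if fidelity == "amplitude":
            session = SessionRecording(
                levels=[],
                complete=True,
                duration_s=0.0,
                frame_rate=frame_rate,
                seed=sess_seed,
                subject=subject,
            )
        else:
            session = synth_session(
                subject,
                optics=optics,
                cfg=cfg,
                frame_rate=frame_rate,
                seed=sess_seed,
                spring=spring,
                geometry=geometry,
                user=user,
                fidelity=fidelity,
            )
        sessions.append(session)
    return sessions


def cohort_manifest(sessions: list[SessionRecording]):
    """Ground-truth manifest of a synthetic cohort as a DataFrame."""
    import pandas as pd

    rows = []
    for i, s in enumerate(sessions):
        sub = s.subject
        rows.append(
            {
                "subject_id": i,
                "sbp_true": sub.sbp_true,
                "dbp_true": sub.dbp_true,
                "mbp_true": sub.mbp_true,
                "heart_rate": sub.heart_rate,
                "perfusion_gain": sub.perfusion_gain,
                "envelope_width": sub.envelope_width,
                "skin_baseline": sub.skin_baseline,
                "complete": s.complete,
                "seed": s.seed,
            }
        )
    return pd.DataFrame(rows)
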